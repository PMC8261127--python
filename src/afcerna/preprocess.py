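"""Expression preprocessing: count filtering, variance stabilization,
surrogate-variable estimation and covariate residualization.

The stage order mirrors a standard bulk RNA-seq cleanup ahead of network
construction: drop genes with low counts in most samples, variance-stabilize
(log2 of median-of-ratios-normalized counts), estimate surrogate variables as
principal components of the residual after regressing out the protected
(rhythm) and adjustment (sex) designs, regress out sex plus the surrogate
variables while protecting rhythm, then keep the top-variance genes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "ExpressionDataset",
    "filter_low_counts",
    "size_factors",
    "vst_transform",
    "rhythm_design",
    "estimate_svs",
    "residualize",
    "select_top_variance",
    "preprocess_pipeline",
]

RHYTHM_LEVELS = ("SR/SR", "AF/SR", "AF/AF")


@dataclass
class ExpressionDataset:
    """Gene x sample matrix with biotypes and per-sample phenotypes."""

    matrix: pd.DataFrame  # genes x samples
    biotypes: pd.Series  # gene -> {"lncRNA", "mRNA"}
    phenotypes: pd.DataFrame  # samples x (rhythm, sex, batch)

    def __post_init__(self) -> None:
        if self.matrix.index.duplicated().any():
            raise ValueError("duplicate gene identifiers")
        if self.matrix.isna().any().any():
            raise ValueError("missing values in expression matrix")
        if not self.matrix.columns.equals(self.phenotypes.index):
            if set(self.matrix.columns) != set(self.phenotypes.index):
                raise ValueError("samples differ between matrix and phenotypes")
            self.phenotypes = self.phenotypes.loc[self.matrix.columns]
        bad = set(self.biotypes.unique()) - {"lncRNA", "mRNA"}
        if bad:
            raise ValueError(f"unknown biotypes: {sorted(bad)}")
        self.biotypes = self.biotypes.reindex(self.matrix.index)
        if self.biotypes.isna().any():
            raise ValueError("every gene needs a biotype label")

    def subset_genes(self, genes) -> "ExpressionDataset":
        return ExpressionDataset(
            self.matrix.loc[genes], self.biotypes.loc[genes], self.phenotypes
        )


def filter_low_counts(
    counts: pd.DataFrame, min_count: int = 10, max_low_fraction: float = 0.8
) -> pd.DataFrame:
    """Drop genes whose count is below ``min_count`` in more than
    ``max_low_fraction`` of samples (strictly more than; the boundary gene is
    retained)."""
    arr = counts.to_numpy()
    if np.any(arr < 0):
        raise ValueError("counts must be nonnegative")
    low_frac = (arr < min_count).mean(axis=1)
    keep = low_frac <= max_low_fraction
    if not keep.any():
        raise ValueError("all genes removed by the low-count filter")
    return counts.loc[keep]


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors (reference = per-gene geometric mean over
    samples, computed on genes expressed in every sample)."""
    arr = counts.to_numpy(dtype=float)
    if np.any(arr.sum(axis=0) == 0):
        raise ValueError("sample with all-zero counts")
    allpos = (arr > 0).all(axis=1)
    if not allpos.any():
        raise ValueError("no gene expressed in every sample; cannot form reference")
    ref = np.exp(np.log(arr[allpos]).mean(axis=1))
    ratios = arr[allpos] / ref[:, None]
    sf = np.median(ratios, axis=0)
    if np.any(sf <= 0):
        raise ValueError("nonpositive size factor")
    return pd.Series(sf, index=counts.columns, name="size_factor")


def vst_transform(counts: pd.DataFrame) -> pd.DataFrame:
    """Variance-stabilizing stand-in: ``log2(count / size_factor + 1)``.

    Deterministic and monotone within each sample; a zero count maps to zero
    for any size factor.
    """
    sf = size_factors(counts)
    return np.log2(counts.div(sf, axis=1) + 1.0)


def rhythm_design(phenotypes: pd.DataFrame, drop_first: bool = True) -> np.ndarray:
    """Indicator columns for the rhythm groups (reference level dropped)."""
    levels = [g for g in RHYTHM_LEVELS if g in set(phenotypes["rhythm"])]
    if drop_first:
        levels = levels[1:]
    return np.column_stack(
        [(phenotypes["rhythm"] == g).to_numpy(float) for g in levels]
    ) if levels else np.empty((len(phenotypes), 0))


def _sex_design(phenotypes: pd.DataFrame) -> np.ndarray:
    if "sex" not in phenotypes:
        return np.empty((len(phenotypes), 0))
    levels = sorted(set(phenotypes["sex"]))[1:]
    return np.column_stack(
        [(phenotypes["sex"] == s).to_numpy(float) for s in levels]
    ) if levels else np.empty((len(phenotypes), 0))


def estimate_svs(
    expr: pd.DataFrame,
    phenotypes: pd.DataFrame,
    n_sv: int = 2,
    protected: np.ndarray | None = None,
    adjustment: np.ndarray | None = None,
) -> np.ndarray:
    """Surrogate variables as top principal components of the residual.

    Expression is regressed on [intercept | protected | adjustment] (defaults:
    rhythm indicators and sex); the top ``n_sv`` right singular vectors of the
    residual matrix are returned as a samples x n_sv array.  This is a
    residual-PCA stand-in with a user-fixed dimension; no permutation-based
    dimension selection is performed.
    """
    n_samples = expr.shape[1]
    if n_sv < 0:
        raise ValueError("n_sv must be >= 0")
    if n_sv >= n_samples:
        raise ValueError("n_sv must be smaller than the sample count")
    if n_sv == 0:
        return np.empty((n_samples, 0))
    if protected is None:
        protected = rhythm_design(phenotypes)
    if adjustment is None:
        adjustment = _sex_design(phenotypes)
    X = np.column_stack([np.ones(n_samples), protected, adjustment])
    Y = expr.to_numpy(dtype=float).T  # samples x genes
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    if np.linalg.norm(resid) < 1e-10 * max(np.linalg.norm(Y), 1.0):
        raise ValueError("zero residual after the protected fit; SVs undefined")
    # right singular vectors of genes x samples residual = left of samples x genes
    u, s, _ = np.linalg.svd(resid, full_matrices=False)
    return u[:, :n_sv] * np.sign(s[:n_sv])  # columns are unit-norm sample scores


def residualize(
    expr: pd.DataFrame,
    keep: np.ndarray | None,
    remove: np.ndarray | None,
) -> pd.DataFrame:
    """Per-gene least squares on [keep | remove]; subtract the remove-part fit.

    The kept (protected) component and the residual are returned; the output is
    orthogonal to the remove columns after the keep columns are projected out.
    An intercept is expected inside ``keep`` if desired.  Idempotent.
    """
    n_samples = expr.shape[1]
    keep = np.empty((n_samples, 0)) if keep is None else np.atleast_2d(keep)
    remove = np.empty((n_samples, 0)) if remove is None else np.atleast_2d(remove)
    if keep.shape[0] != n_samples or remove.shape[0] != n_samples:
        raise ValueError("design rows must match the sample count")
    if remove.shape[1] == 0:
        return expr.copy()
    X = np.column_stack([keep, remove])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient combined design")
    Y = expr.to_numpy(dtype=float).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted_remove = remove @ beta[keep.shape[1] :]
    cleaned = (Y - fitted_remove).T
    return pd.DataFrame(cleaned, index=expr.index, columns=expr.columns)


def select_top_variance(expr: pd.DataFrame, k: int = 5000) -> pd.DataFrame:
    """Top-k genes by sample variance; ties break lexicographically by gene."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > expr.shape[0]:
        warnings.warn(
            f"requested top {k} genes but only {expr.shape[0]} available; keeping all"
        )
        k = expr.shape[0]
    var = expr.var(axis=1, ddof=1)
    order = sorted(expr.index, key=lambda g: (-var[g], g))
    return expr.loc[order[:k]]


def preprocess_pipeline(
    dataset: ExpressionDataset,
    min_count: int = 10,
    max_low_fraction: float = 0.8,
    n_sv: int = 2,
    top_k: int = 5000,
) -> tuple[ExpressionDataset, dict]:
    """filter -> VST -> SV estimation -> residualization -> top-k selection."""
    for g, cnt in dataset.phenotypes["rhythm"].value_counts().items():
        if cnt < 3:
            raise ValueError(f"rhythm group {g} has fewer than 3 samples")
    filtered = filter_low_counts(dataset.matrix, min_count, max_low_fraction)
    vst = vst_transform(filtered)
    svs = estimate_svs(vst, dataset.phenotypes, n_sv=n_sv)
    keep = np.column_stack(
        [np.ones(vst.shape[1]), rhythm_design(dataset.phenotypes)]
    )
    remove = np.column_stack([_sex_design(dataset.phenotypes), svs])
    cleaned = residualize(vst, keep, remove)
    top = select_top_variance(cleaned, k=top_k)
    out = ExpressionDataset(top, dataset.biotypes.loc[top.index], dataset.phenotypes)
    info = {
        "n_genes_in": int(dataset.matrix.shape[0]),
        "n_genes_filtered": int(filtered.shape[0]),
        "n_genes_selected": int(top.shape[0]),
        "n_sv": int(svs.shape[1]),
        "svs": svs,
    }
    return out, info
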