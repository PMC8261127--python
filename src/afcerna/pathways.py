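"""Single-sample gene-set activity scoring and lncRNA-pathway association.

Gene-set activity per sample is the mean of the member genes' z-standardized
expression (a transparent, deterministic single-sample score).  Each set's
activity is then regressed on the atrial rhythm covariate plus the expression
of a chosen lncRNA; the lncRNA coefficient and its two-sided t-test p-value
quantify rhythm-adjusted pathway association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "GeneSetCollection",
    "load_gmt",
    "parse_gmt",
    "filter_gene_sets",
    "sample_set_score",
    "rhythm_covariate",
    "lncrna_pathway_lm",
    "pathway_association",
]

RHYTHM_ORDINAL = {"SR/SR": 0.0, "AF/SR": 1.0, "AF/AF": 2.0}


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.sets)


def parse_gmt(lines: Iterable[str]) -> GeneSetCollection:
    sets: dict[str, frozenset] = {}
    desc: dict[str, str] = {}
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) < 3:
            raise ValueError(f"malformed GMT line {lineno}: expected name, "
                             "description and at least one gene")
        name = parts[0]
        sets[name] = frozenset(g for g in parts[2:] if g)
        desc[name] = parts[1]
    return GeneSetCollection(sets, desc)


def filter_gene_sets(
    collection: GeneSetCollection,
    universe: Iterable[str] | None = None,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    """Intersect each set with the expression universe, then keep sets with
    ``min_size <= |set| <= max_size`` (bounds inclusive)."""
    uni = frozenset(universe) if universe is not None else None
    sets = {}
    for name, members in collection.sets.items():
        if uni is not None:
            members = members & uni
        if min_size <= len(members) <= max_size:
            sets[name] = members
    return GeneSetCollection(sets, {n: collection.descriptions.get(n, "") for n in sets})


def load_gmt(
    path,
    universe: Iterable[str] | None = None,
    min_size: int = 10,
    max_size: int = 500,
) -> GeneSetCollection:
    with open(path) as fh:
        collection = parse_gmt(fh)
    return filter_gene_sets(collection, universe, min_size, max_size)


def sample_set_score(expr: pd.DataFrame, gene_set: Iterable[str]) -> pd.Series:
    """Mean z-score of the set genes in each sample.

    Genes are z-standardized across samples first, so the score is invariant
    to gene-wise affine rescaling of the expression matrix.  Zero-variance
    genes are skipped with a warning.
    """
    genes = [g for g in gene_set if g in expr.index]
    if not genes:
        raise ValueError("no set gene present in the expression matrix")
    sub = expr.loc[genes]
    sd = sub.std(axis=1, ddof=1)
    if (sd == 0).any():
        warnings.warn(f"skipping {int((sd == 0).sum())} zero-variance gene(s)")
        sub = sub.loc[sd > 0]
        if sub.empty:
            raise ValueError("all set genes have zero variance")
        sd = sd[sd > 0]
    z = sub.sub(sub.mean(axis=1), axis=0).div(sd, axis=0)
    return z.mean(axis=0)


def rhythm_covariate(phenotypes: pd.DataFrame, coding: str = "ordinal") -> np.ndarray:
    """Rhythm covariate columns: ordinal (SR/SR=0, AF/SR=1, AF/AF=2, default)
    or dummy indicator columns."""
    rhythm = phenotypes["rhythm"]
    if coding == "ordinal":
        return rhythm.map(RHYTHM_ORDINAL).to_numpy(float)[:, None]
    if coding == "dummy":
        levels = [g for g in ("AF/SR", "AF/AF") if g in set(rhythm)]
        return np.column_stack([(rhythm == g).to_numpy(float) for g in levels])
    raise ValueError("coding must be 'ordinal' or 'dummy'")


def lncrna_pathway_lm(
    score: np.ndarray | pd.Series,
    rhythm: np.ndarray,
    lnc_expr: np.ndarray | pd.Series,
) -> tuple[float, float]:
    """OLS of the set score on intercept + rhythm + lncRNA expression.

    Returns the lncRNA coefficient and its two-sided t-test p-value.  A
    collinear design (e.g. lncRNA expression proportional to rhythm) raises.
    """
    y = np.asarray(score, dtype=float)
    lnc = np.asarray(lnc_expr, dtype=float)
    rhythm = np.atleast_2d(np.asarray(rhythm, dtype=float))
    if rhythm.shape[0] != y.size:
        rhythm = rhythm.T
    X = np.column_stack([np.ones(y.size), rhythm, lnc])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("collinear design: rhythm and lncRNA expression")
    fit = sm.OLS(y, X).fit()
    return float(fit.params[-1]), float(fit.pvalues[-1])


def pathway_association(
    expr: pd.DataFrame,
    collection: GeneSetCollection,
    phenotypes: pd.DataFrame,
    lncrna: str,
    rhythm_coding: str = "ordinal",
) -> pd.DataFrame:
    """Per-set lncRNA association table, sorted by coefficient (descending)."""
    if lncrna not in expr.index:
        raise ValueError(f"lncRNA {lncrna} absent from expression matrix")
    rhythm = rhythm_covariate(phenotypes.loc[expr.columns], rhythm_coding)
    lnc = expr.loc[lncrna].to_numpy(float)
    rows = []
    for name in sorted(collection.sets):
        members = collection.sets[name] - {lncrna}
        if not members:
            continue
        score = sample_set_score(expr, members).to_numpy()
        coef, p = lncrna_pathway_lm(score, rhythm, lnc)
        rows.append((name, len(collection.sets[name]), coef, p, len(score)))
    df = pd.DataFrame(rows, columns=["set", "set_size", "coefficient", "p", "n"])
    return df.sort_values(
        ["coefficient", "set"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
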