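"""Signed weighted co-expression network, module detection and module-trait
association.

The network follows the signed weighted gene co-expression construction:
adjacency ``a_ij = ((1 + cor(x_i, x_j)) / 2) ** beta`` so anticorrelated genes
get near-zero weight, with the soft threshold ``beta`` chosen as the smallest
integer whose connectivity distribution satisfies a scale-free topology fit
above a threshold.  The topological overlap measure (TOM) counts shared
neighbors to damp spurious edges; modules come from average-linkage
hierarchical clustering of ``1 - TOM`` with a static height cut plus a minimum
module size, and close modules are merged by eigengene similarity.  Each
module is summarized by its eigengene (first principal component) and
correlated with the binary trait contrasts:

* susceptibility: AF/SR (coded 1) vs SR/SR (coded 0) samples only;
* persistence:    AF/AF (coded 1) vs AF/SR (coded 0) samples only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import linregress, pearsonr

__all__ = [
    "ModuleAssignment",
    "signed_adjacency",
    "scale_free_fit",
    "pick_beta",
    "compute_tom",
    "cluster_modules",
    "module_eigengene",
    "compute_eigengenes",
    "merge_modules",
    "module_trait_correlation",
    "top_modules",
]

CONTRASTS = {
    "susceptibility": ("SR/SR", "AF/SR"),  # (coded 0, coded 1)
    "persistence": ("AF/SR", "AF/AF"),
}


def _corr_matrix(expr: pd.DataFrame) -> np.ndarray:
    X = expr.to_numpy(dtype=float)
    if X.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    sd = X.std(axis=1)
    if np.any(sd == 0):
        bad = expr.index[sd == 0][:5].tolist()
        raise ValueError(f"zero-variance gene(s), correlation undefined: {bad}")
    c = np.corrcoef(X)
    return np.clip(c, -1.0, 1.0)


def signed_adjacency(expr: pd.DataFrame, beta: int) -> pd.DataFrame:
    """Signed adjacency ``((1 + cor) / 2) ** beta`` in [0, 1]."""
    if beta < 1 or int(beta) != beta:
        raise ValueError("beta must be a positive integer")
    c = _corr_matrix(expr)
    a = ((1.0 + c) / 2.0) ** int(beta)
    a = (a + a.T) / 2.0
    return pd.DataFrame(a, index=expr.index, columns=expr.index)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = 10) -> tuple[float, float]:
    """Scale-free topology fit of a connectivity vector.

    Connectivities are binned into ``n_bins`` equal-width bins; empty bins are
    dropped and ``log10(frequency)`` is regressed on ``log10(mean k)``.
    Returns ``(fit, slope)`` where fit = R^2 for a negative slope and 0.0
    otherwise, so only decaying degree distributions can qualify.
    """
    k = np.asarray(connectivity, dtype=float)
    k = k[k > 0]
    if k.size < 2 or np.ptp(k) == 0:
        raise ValueError("degenerate connectivity distribution; fit undefined")
    edges = np.linspace(k.min(), k.max() + 1e-12, n_bins + 1)
    idx = np.clip(np.digitize(k, edges) - 1, 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if mask.sum() == 0:
            continue
        mk = k[mask].mean()
        if mk <= 0:
            continue
        xs.append(np.log10(mk))
        ys.append(np.log10(mask.sum()))
    if len(xs) < 2:
        raise ValueError("fewer than two occupied bins; fit undefined")
    res = linregress(xs, ys)
    r2 = float(res.rvalue**2)
    return (r2 if res.slope < 0 else 0.0), float(res.slope)


def pick_beta(
    expr: pd.DataFrame,
    candidates: Sequence[int] = tuple(range(1, 21)),
    fit_threshold: float = 0.9,
    n_bins: int = 10,
) -> int:
    """Smallest candidate beta whose scale-free fit reaches the threshold."""
    if not len(candidates):
        raise ValueError("no candidate beta values")
    base = (1.0 + _corr_matrix(expr)) / 2.0
    best: tuple[float, int] | None = None
    for beta in sorted(int(b) for b in candidates):
        a = base**beta
        k = a.sum(axis=0) - np.diag(a)
        fit, _ = scale_free_fit(k, n_bins=n_bins)
        if best is None or fit > best[0]:
            best = (fit, beta)
        if fit >= fit_threshold:
            return beta
    raise ValueError(
        f"no candidate reached fit {fit_threshold}; best was "
        f"{best[0]:.3f} at beta={best[1]}"
    )


def compute_tom(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Topological overlap ``(sum_u a_iu a_uj + a_ij) / (min(k_i,k_j)+1-a_ij)``.

    The adjacency diagonal is treated as zero for connectivity; the TOM
    diagonal is 1 by convention.  Values stay in [0, 1].
    """
    index = adjacency.index if isinstance(adjacency, pd.DataFrame) else None
    a = np.asarray(adjacency, dtype=float).copy()
    if not np.allclose(a, a.T, atol=1e-12):
        raise ValueError("adjacency must be symmetric")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=0)
    num = a @ a + a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = num / denom
    np.fill_diagonal(tom, 1.0)
    tom = np.clip((tom + tom.T) / 2.0, 0.0, 1.0)
    if index is not None:
        return pd.DataFrame(tom, index=index, columns=index)
    return tom


@dataclass
class ModuleAssignment:
    """Gene -> module labels (0 = unassigned) with per-module eigengenes."""

    labels: pd.Series
    eigengenes: dict[int, np.ndarray] = field(default_factory=dict)
    merge_history: list[tuple[int, int, float]] = field(default_factory=list)

    def modules(self) -> list[int]:
        return sorted(m for m in self.labels.unique() if m != 0)

    def genes_in(self, module: int) -> list[str]:
        return self.labels.index[self.labels == module].tolist()

    def eigengene_frame(self, samples: Sequence[str]) -> pd.DataFrame:
        return pd.DataFrame(
            {f"ME{m}": self.eigengenes[m] for m in self.modules()}, index=list(samples)
        )


def cluster_modules(
    tom: pd.DataFrame,
    min_module_size: int = 30,
    deep_split: int = 2,
    cut_height: float | None = None,
) -> ModuleAssignment:
    """Average-linkage clustering of ``1 - TOM`` with a static height cut.

    ``cut_height=None`` cuts at 0.99 x the maximum merge height.  Clusters
    smaller than ``min_module_size`` are assigned label 0; surviving clusters
    are relabeled 1..K by decreasing size.  ``deep_split`` is accepted for
    interface compatibility and logged but does not alter the static cut.
    """
    genes = list(tom.index)
    if deep_split != 2:
        warnings.warn("deep_split is accepted but ignored by the static height cut")
    if len(genes) < min_module_size:
        warnings.warn("fewer genes than min_module_size; all genes unassigned")
        return ModuleAssignment(pd.Series(0, index=genes, name="module"))
    d = 1.0 - np.asarray(tom, dtype=float)
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    Z = linkage(squareform(d, checks=False), method="average")
    heights = Z[:, 2]
    cut = 0.99 * float(heights.max()) if cut_height is None else float(cut_height)
    raw = fcluster(Z, t=cut, criterion="distance")
    labels = pd.Series(raw, index=genes, name="module")
    sizes = labels.value_counts()
    keep = sizes[sizes >= min_module_size].index
    relabel = {
        old: new + 1
        for new, old in enumerate(
            sorted(keep, key=lambda c: (-sizes[c], c))
        )
    }
    labels = labels.map(lambda c: relabel.get(c, 0))
    return ModuleAssignment(labels)


def module_eigengene(expr: pd.DataFrame, member_genes: Sequence[str]) -> np.ndarray:
    """First principal component of the standardized member submatrix.

    Genes are standardized across samples; the eigengene is the first right
    singular vector, sign-aligned to correlate nonnegatively with the mean
    standardized member profile, and has unit norm.
    """
    if len(member_genes) == 0:
        raise ValueError("module has no member genes")
    sub = expr.loc[list(member_genes)].to_numpy(dtype=float)
    mu = sub.mean(axis=1, keepdims=True)
    sd = sub.std(axis=1, ddof=1, keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance member gene")
    z = (sub - mu) / sd
    _, _, vt = np.linalg.svd(z, full_matrices=False)
    me = vt[0]
    mean_profile = z.mean(axis=0)
    if np.dot(me, mean_profile) < 0:
        me = -me
    return me


def compute_eigengenes(expr: pd.DataFrame, labels: pd.Series) -> dict[int, np.ndarray]:
    return {
        m: module_eigengene(expr, labels.index[labels == m])
        for m in sorted(labels.unique())
        if m != 0
    }


def merge_modules(
    assignment: ModuleAssignment,
    expr: pd.DataFrame,
    cut_height: float = 0.25,
) -> ModuleAssignment:
    """Merge module pairs whose eigengene dissimilarity ``1 - cor`` is below
    ``cut_height``, closest pair first, recomputing eigengenes after each
    merge until no pair qualifies."""
    labels = assignment.labels.copy()
    history: list[tuple[int, int, float]] = []
    while True:
        mods = sorted(m for m in labels.unique() if m != 0)
        if len(mods) < 2:
            break
        mes = compute_eigengenes(expr, labels)
        best = None
        for i, a in enumerate(mods):
            for b in mods[i + 1 :]:
                diss = 1.0 - float(np.corrcoef(mes[a], mes[b])[0, 1])
                if best is None or diss < best[0]:
                    best = (diss, a, b)
        if best is None or best[0] >= cut_height:
            break
        diss, a, b = best
        labels[labels == b] = a
        history.append((a, b, diss))
    # renumber surviving modules by decreasing size
    sizes = labels[labels != 0].value_counts()
    relabel = {old: i + 1 for i, old in enumerate(sorted(sizes.index, key=lambda c: (-sizes[c], c)))}
    labels = labels.map(lambda c: relabel.get(c, 0))
    out = ModuleAssignment(labels, merge_history=assignment.merge_history + history)
    out.eigengenes = compute_eigengenes(expr, labels)
    return out


def module_trait_correlation(
    eigengenes: Mapping[int, np.ndarray],
    phenotypes: pd.DataFrame,
    contrast: str,
) -> pd.DataFrame:
    """Pearson correlation of each module eigengene with a binary contrast.

    Only the two rhythm groups defining the contrast enter; the p-value is the
    two-sided t-based test of ``r``.  Modules are ranked by p within the
    contrast.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast: {contrast}")
    zero_grp, one_grp = CONTRASTS[contrast]
    rhythm = phenotypes["rhythm"].to_numpy()
    mask = (rhythm == zero_grp) | (rhythm == one_grp)
    if not mask.any():
        raise ValueError("contrast subset is empty")
    code = (rhythm[mask] == one_grp).astype(float)
    if code.min() == code.max():
        raise ValueError("constant trait in contrast subset")
    rows = []
    for m in sorted(eigengenes):
        me = np.asarray(eigengenes[m], dtype=float)[mask]
        r, p = pearsonr(me, code)
        rows.append((m, float(r), float(p), int(mask.sum())))
    df = pd.DataFrame(rows, columns=["module", "r", "p", "n"])
    return df.sort_values(["p", "module"], kind="stable").reset_index(drop=True)


def top_modules(trait_result: pd.DataFrame, n_top: int = 2) -> list[int]:
    """The n_top smallest-p modules of a contrast's trait table."""
    return trait_result["module"].head(n_top).astype(int).tolist()
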