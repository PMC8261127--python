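"""Module-specific lncRNA-mRNA ceRNA inference by the shared-miRNA hypergeometric test.

Two transcripts that are targeted by many of the same miRNAs are candidate
competing endogenous RNAs (ceRNAs): changes in one transcript's abundance can
titrate the shared miRNA pool and thereby de-repress the other.  Within each
co-expression module, every lncRNA x mRNA pair with at least one shared miRNA
is scored with the upper-tail hypergeometric probability

    p = P(X >= t),   X ~ Hypergeometric(N, M, n)

where ``N`` is the number of distinct miRNAs in the target database, ``M`` the
number targeting the mRNA, ``n`` the number targeting the lncRNA and ``t`` the
number shared.  Pairs crossing the significance threshold form the module's
bipartite ceRNA network; pairing is strictly intramodule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

__all__ = [
    "MiRNATargetDB",
    "CeRNAPair",
    "CeRNANetwork",
    "hypergeom_p",
    "bh_adjust",
    "build_module_cerna",
    "aggregate_networks",
    "enrich_ora",
]


def _log_comb(a: np.ndarray | float, b: np.ndarray | float) -> np.ndarray:
    return gammaln(a + 1.0) - gammaln(b + 1.0) - gammaln(a - b + 1.0)


def hypergeom_p(N: int, M: int, n: int, t: int) -> float:
    """Upper-tail probability ``P(X >= t)`` of a hypergeometric variable.

    Population of ``N`` miRNAs of which ``M`` target the mRNA; ``n`` draws
    (miRNAs targeting the lncRNA); ``t`` observed shared miRNAs.  Computed as a
    log-gamma stabilized finite sum over the feasible support, equivalent to
    ``1 - sum_{k<t} C(M,k) C(N-M,n-k) / C(N,n)``.

    ``t = 0`` returns exactly 1 (the empty lower sum).
    """
    N, M, n, t = int(N), int(M), int(n), int(t)
    if N < 1:
        raise ValueError("N must be >= 1")
    if not (0 <= M <= N and 0 <= n <= N):
        raise ValueError(f"require 0 <= M, n <= N; got N={N}, M={M}, n={n}")
    if not (0 <= t <= min(n, M)):
        raise ValueError(f"require 0 <= t <= min(n, M); got t={t}, n={n}, M={M}")
    if t == 0:
        return 1.0
    # feasible k: max(t, n-(N-M)) .. min(n, M)
    lo = max(t, n - (N - M))
    hi = min(n, M)
    k = np.arange(lo, hi + 1, dtype=float)
    log_terms = _log_comb(M, k) + _log_comb(N - M, n - k) - _log_comb(N, n)
    # sum in linear space via max-shift for stability
    m = log_terms.max()
    p = float(np.exp(m) * np.exp(log_terms - m).sum())
    return min(p, 1.0)


def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, returned in input order.

    ``adj_(i) = min_{j >= i}( p_(j) * m / j )`` over the ascending ordering,
    capped at 1.  Empty input yields an empty array.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p <= 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


@dataclass(frozen=True)
class MiRNATargetDB:
    """Bipartite gene-miRNA target tables for lncRNAs and mRNAs.

    The miRNA universe is the union of miRNAs appearing in either table; its
    size ``N`` is always computed from the loaded data, never hard-coded.
    """

    lnc_targets: Mapping[str, frozenset]
    mrna_targets: Mapping[str, frozenset]

    @classmethod
    def from_pairs(
        cls,
        lnc_pairs: Iterable[tuple[str, str]],
        mrna_pairs: Iterable[tuple[str, str]],
    ) -> "MiRNATargetDB":
        lnc: dict[str, set] = {}
        mrna: dict[str, set] = {}
        for g, mir in lnc_pairs:
            lnc.setdefault(g, set()).add(mir)
        for g, mir in mrna_pairs:
            mrna.setdefault(g, set()).add(mir)
        return cls(
            {g: frozenset(s) for g, s in lnc.items()},
            {g: frozenset(s) for g, s in mrna.items()},
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MiRNATargetDB":
        """Build from a long table with columns gene_id, biotype, mirna_id."""
        lnc = df[df["biotype"] == "lncRNA"]
        mr = df[df["biotype"] == "mRNA"]
        return cls.from_pairs(
            zip(lnc["gene_id"], lnc["mirna_id"]),
            zip(mr["gene_id"], mr["mirna_id"]),
        )

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in sorted(self.lnc_targets):
            for mir in sorted(self.lnc_targets[g]):
                rows.append((g, "lncRNA", mir))
        for g in sorted(self.mrna_targets):
            for mir in sorted(self.mrna_targets[g]):
                rows.append((g, "mRNA", mir))
        return pd.DataFrame(rows, columns=["gene_id", "biotype", "mirna_id"])

    @property
    def universe(self) -> frozenset:
        mirs: set = set()
        for s in self.lnc_targets.values():
            mirs |= s
        for s in self.mrna_targets.values():
            mirs |= s
        return frozenset(mirs)

    @property
    def N(self) -> int:
        return len(self.universe)


@dataclass(frozen=True)
class CeRNAPair:
    """A scored intramodule lncRNA-mRNA edge."""

    lncrna: str
    mrna: str
    module: int
    shared_mirnas: frozenset
    t: int
    n: int
    M: int
    N: int
    p: float
    p_adj: float


@dataclass
class CeRNANetwork:
    """Bipartite lncRNA-mRNA ceRNA network (edges restricted to modules)."""

    edges: list[CeRNAPair] = field(default_factory=list)
    disease_genes: frozenset = frozenset()

    def nodes(self) -> list[str]:
        out: set = set()
        for e in self.edges:
            out.add(e.lncrna)
            out.add(e.mrna)
        return sorted(out)

    def lncrnas(self) -> list[str]:
        return sorted({e.lncrna for e in self.edges})

    def mrnas(self) -> list[str]:
        return sorted({e.mrna for e in self.edges})

    def partners(self, lncrna: str) -> list[str]:
        return sorted({e.mrna for e in self.edges if e.lncrna == lncrna})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (
                e.lncrna,
                e.mrna,
                e.module,
                e.t,
                e.n,
                e.M,
                e.N,
                e.p,
                e.p_adj,
                ";".join(sorted(e.shared_mirnas)),
            )
            for e in self.edges
        ]
        return pd.DataFrame(
            rows,
            columns=[
                "lncRNA",
                "mRNA",
                "module",
                "t",
                "n",
                "M",
                "N",
                "p",
                "p_adj",
                "shared_miRNA_ids",
            ],
        )


def build_module_cerna(
    module_genes: Sequence[str],
    biotypes: Mapping[str, str],
    db: MiRNATargetDB,
    module: int = 0,
    alpha: float = 0.05,
    use_adjusted: bool = False,
    lnc_is_draws: bool = True,
) -> CeRNANetwork:
    """Score every intramodule lncRNA x mRNA pair with >= 1 shared miRNA.

    Pairs without any shared miRNA are not tested (their p would be 1); BH
    adjustment is applied across the module's tested pairs.  ``lnc_is_draws``
    assigns ``n`` to the lncRNA's target count and ``M`` to the mRNA's (the
    default convention); the alternative swaps the roles.
    """
    N = db.N
    lncs = [g for g in module_genes if biotypes.get(g) == "lncRNA" and g in db.lnc_targets]
    mrnas = [g for g in module_genes if biotypes.get(g) == "mRNA" and g in db.mrna_targets]
    tested: list[CeRNAPair] = []
    for lnc in lncs:
        lt = db.lnc_targets[lnc]
        for mr in mrnas:
            mt = db.mrna_targets[mr]
            shared = lt & mt
            t = len(shared)
            if t == 0:
                continue
            n, M = len(lt), len(mt)
            if lnc_is_draws:
                p = hypergeom_p(N, M, n, t)
            else:
                p = hypergeom_p(N, n, M, t)
            tested.append(
                CeRNAPair(lnc, mr, module, frozenset(shared), t, n, M, N, p, np.nan)
            )
    if not tested:
        return CeRNANetwork([])
    adj = bh_adjust([e.p for e in tested])
    scored = [
        CeRNAPair(e.lncrna, e.mrna, e.module, e.shared_mirnas, e.t, e.n, e.M, e.N, e.p, a)
        for e, a in zip(tested, adj)
    ]
    crit = (lambda e: e.p_adj) if use_adjusted else (lambda e: e.p)
    kept = [e for e in scored if crit(e) < alpha]
    return CeRNANetwork(kept)


def aggregate_networks(
    networks: Sequence[CeRNANetwork],
    seed_genes: Iterable[str] = (),
) -> CeRNANetwork:
    """Union of the per-module networks, with known disease genes flagged.

    Modules are disjoint so the union cannot contain duplicate edges; the
    disease-gene annotation is the intersection of the seed list with the
    aggregated node set.
    """
    edges: list[CeRNAPair] = []
    for net in networks:
        edges.extend(net.edges)
    out = CeRNANetwork(edges)
    out.disease_genes = frozenset(seed_genes) & frozenset(out.nodes())
    return out


def enrich_ora(
    gene_list: Iterable[str],
    universe: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
) -> pd.DataFrame:
    """Over-representation test of a gene list against named gene sets.

    For each set: ``p = P(X >= t)`` with population the universe, successes the
    set members present in the universe and draws the gene list; BH across
    sets.  ``gene_list`` must be a subset of the universe.
    """
    uni = frozenset(universe)
    if not uni:
        raise ValueError("empty universe")
    gl = frozenset(gene_list)
    if not gl <= uni:
        raise ValueError("gene_list must be a subset of the universe")
    rows = []
    for name in sorted(gene_sets):
        members = frozenset(gene_sets[name]) & uni
        overlap = members & gl
        p = hypergeom_p(len(uni), len(members), len(gl), len(overlap))
        rows.append((name, len(members), len(overlap), p))
    df = pd.DataFrame(rows, columns=["set", "set_size", "overlap", "p"])
    df["p_adj"] = bh_adjust(df["p"].to_numpy()) if len(df) else []
    return df.sort_values(["p", "set"], kind="stable").reset_index(drop=True)
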