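"""Random walk with restart on multiplex networks (RWR-M).

A multiplex graph stacks L undirected layers over one shared node set of size
n.  A walker either moves within its current layer (probability ``1 - delta``)
or jumps to the same node in another layer (probability ``delta``, split
uniformly over the L - 1 other layers).  The supra-transition matrix is the
column normalization of the nL x nL block matrix with ``(1 - delta) A[alpha]``
on the diagonal blocks and ``delta / (L - 1) I`` off-diagonal.  At every step
the walker restarts with probability ``r`` onto the seed distribution, whose
mass is split across layers by the layer weights ``tau``.  The stationary
probabilities measure each node's proximity to the seed genes and are used to
prioritize candidate disease lncRNAs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "MultiplexGraph",
    "RWRMParams",
    "RWRMResult",
    "layer_weights",
    "build_supra_transition",
    "rwrm_scores",
    "prioritize_lncrnas",
]


@dataclass
class MultiplexGraph:
    """L symmetric, nonnegative adjacency layers over one ordered node list."""

    nodes: list[str]
    layers: list[np.ndarray]

    def __post_init__(self) -> None:
        n = len(self.nodes)
        if len(set(self.nodes)) != n:
            raise ValueError("duplicate node identifiers")
        if not self.layers:
            raise ValueError("need at least one layer")
        cleaned = []
        for a in self.layers:
            a = np.asarray(a, dtype=float)
            if a.shape != (n, n):
                raise ValueError("layer shape does not match node count")
            if np.any(a < 0):
                raise ValueError("adjacency must be nonnegative")
            if not np.allclose(a, a.T, atol=1e-12):
                raise ValueError("adjacency must be symmetric")
            a = a.copy()
            np.fill_diagonal(a, 0.0)
            cleaned.append(a)
        self.layers = cleaned

    @property
    def n(self) -> int:
        return len(self.nodes)

    @property
    def L(self) -> int:
        return len(self.layers)

    @classmethod
    def from_edge_lists(
        cls,
        nodes: Sequence[str],
        edge_lists: Sequence[Iterable[tuple]],
        weighted: bool = False,
    ) -> "MultiplexGraph":
        """Build layers from (gene_a, gene_b[, weight]) tuples; edges whose
        endpoints are outside ``nodes`` are dropped."""
        index = {g: i for i, g in enumerate(nodes)}
        layers = []
        for edges in edge_lists:
            a = np.zeros((len(nodes), len(nodes)))
            for edge in edges:
                u, v = edge[0], edge[1]
                if u not in index or v not in index or u == v:
                    continue
                w = float(edge[2]) if (weighted and len(edge) > 2) else 1.0
                a[index[u], index[v]] = w
                a[index[v], index[u]] = w
            layers.append(a)
        return cls(list(nodes), layers)


@dataclass
class RWRMParams:
    """Walk parameters.

    delta : probability of jumping between layers at a step (default 0.5)
    r     : restart probability onto the seed distribution (default 0.7)
    tau   : per-layer weights summing to L; None means uniform
    """

    delta: float = 0.5
    r: float = 0.7
    tau: np.ndarray | None = None
    tolerance: float = 1e-10
    max_iter: int = 10_000

    def resolve_tau(self, L: int) -> np.ndarray:
        if self.tau is None:
            return np.ones(L)
        tau = np.asarray(self.tau, dtype=float)
        if tau.shape != (L,) or np.any(tau < 0):
            raise ValueError("tau must be a length-L nonnegative vector")
        if not np.isclose(tau.sum(), L):
            raise ValueError("tau must sum to L")
        return tau


def layer_weights(R: float) -> np.ndarray:
    """Two-layer weights ``tau = [2/(1+R), 2R/(1+R)]``.

    ``R`` is the ratio of layer-1 (ceRNA-guided) to layer-2 (functional
    interaction) edge counts; the weights always sum to L = 2.
    """
    if R <= 0:
        raise ValueError("R must be positive")
    return np.array([2.0 / (1.0 + R), 2.0 * R / (1.0 + R)])


def build_supra_transition(graph: MultiplexGraph, delta: float = 0.5) -> np.ndarray:
    """Column-stochastic nL x nL supra-transition matrix.

    For L = 1 the inter-layer jump is meaningless, so delta degenerates to 0
    and the result is the column-normalized single layer.  Columns that sum to
    zero (a node isolated in every layer, with no inter-layer mass) are
    replaced by the uniform distribution to keep the matrix stochastic.
    """
    if not 0.0 <= delta <= 1.0:
        raise ValueError("delta must lie in [0, 1]")
    n, L = graph.n, graph.L
    if L == 1:
        delta = 0.0
    S = np.zeros((n * L, n * L))
    eye = np.eye(n)
    for a in range(L):
        for b in range(L):
            block = (1.0 - delta) * graph.layers[a] if a == b else (delta / (L - 1)) * eye
            S[a * n : (a + 1) * n, b * n : (b + 1) * n] = block
    colsum = S.sum(axis=0)
    dead = colsum <= 0
    if np.any(dead):
        warnings.warn(
            f"{int(dead.sum())} isolated column(s) replaced by uniform teleportation"
        )
        S[:, dead] = 1.0 / (n * L)
        colsum = S.sum(axis=0)
    return S / colsum


@dataclass
class RWRMResult:
    """Stationary proximity of every node to the seed set."""

    nodes: list[str]
    per_layer: np.ndarray  # n x L stationary probabilities
    global_scores: np.ndarray  # length n, aggregated over layers
    seeds: frozenset
    n_iter: int

    def to_frame(self, biotypes: Mapping[str, str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"node": self.nodes})
        for a in range(self.per_layer.shape[1]):
            df[f"p_layer{a + 1}"] = self.per_layer[:, a]
        df["global_score"] = self.global_scores
        df["is_seed"] = [g in self.seeds for g in self.nodes]
        if biotypes is not None:
            df.insert(1, "biotype", [biotypes.get(g, "") for g in self.nodes])
        return df.sort_values(
            ["global_score", "node"], ascending=[False, True], kind="stable"
        ).reset_index(drop=True)


def rwrm_scores(
    graph: MultiplexGraph,
    seeds: Iterable[str],
    params: RWRMParams | None = None,
    aggregate: str = "sum",
) -> RWRMResult:
    """Iterate ``p <- (1 - r) M p + r p_RS`` to the stationary distribution.

    The initial distribution assigns 1/k to each of the k seeds within every
    layer; the restart vector weights layer alpha by ``tau_alpha / L`` so that
    it remains a probability vector.  Convergence is declared when the L1
    change drops below ``tolerance``; non-convergence raises.  The global node
    score aggregates the node's per-layer stationary probabilities
    (``sum`` default, ``geometric`` optional).
    """
    params = params or RWRMParams()
    n, L = graph.n, graph.L
    node_index = {g: i for i, g in enumerate(graph.nodes)}
    seed_idx = sorted(node_index[s] for s in set(seeds) if s in node_index)
    if not seed_idx:
        raise ValueError("no seed gene present in the network")
    if not 0.0 < params.r <= 1.0:
        raise ValueError("restart probability r must lie in (0, 1]")
    tau = params.resolve_tau(L)
    M = build_supra_transition(graph, params.delta)
    p0_layer = np.zeros(n)
    p0_layer[seed_idx] = 1.0 / len(seed_idx)
    p_rs = np.concatenate([(tau[a] / L) * p0_layer for a in range(L)])
    p = p_rs.copy()
    n_iter = 0
    for n_iter in range(1, params.max_iter + 1):
        p_next = (1.0 - params.r) * (M @ p) + params.r * p_rs
        delta = np.abs(p_next - p).sum()
        p = p_next
        if delta < params.tolerance:
            break
    else:
        raise RuntimeError(f"RWR-M did not converge in {params.max_iter} iterations")
    per_layer = p.reshape(L, n).T
    if aggregate == "sum":
        global_scores = per_layer.sum(axis=1)
    elif aggregate == "geometric":
        global_scores = np.exp(np.log(np.maximum(per_layer, 1e-300)).mean(axis=1))
    else:
        raise ValueError("aggregate must be 'sum' or 'geometric'")
    return RWRMResult(
        nodes=list(graph.nodes),
        per_layer=per_layer,
        global_scores=global_scores,
        seeds=frozenset(graph.nodes[i] for i in seed_idx),
        n_iter=n_iter,
    )


def prioritize_lncrnas(
    result: RWRMResult,
    biotypes: Mapping[str, str],
    top_k: int = 2,
) -> list[tuple[str, float]]:
    """Top-k lncRNAs by global proximity score.

    Seed nodes are excluded from candidacy; ties break by node identifier.
    """
    cands = [
        (g, float(s))
        for g, s in zip(result.nodes, result.global_scores)
        if biotypes.get(g) == "lncRNA" and g not in result.seeds
    ]
    if not cands:
        raise ValueError("no lncRNA node available for prioritization")
    cands.sort(key=lambda gs: (-gs[1], gs[0]))
    return cands[:top_k]
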