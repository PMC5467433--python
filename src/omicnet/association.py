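"""Pairwise association networks between two omics blocks.

For a block pair (X, Y) the sparse-PLS association matrix is computed in
both orientations (X predicting Y and Y predicting X) and combined,

    M(X, Y) = Ma(X, Y) + t(Mb(Y, X)),

so the combined weight of a feature pair reaches twice its Pearson
correlation when both orientations select it.  The network keeps only the
extreme tails of the combined weights: dynamic dual thresholds retain the
top ``fraction`` of the positive and the bottom ``fraction`` of the
negative nonzero entries (default 5% per sign), yielding a binary
adjacency whose nonzero cells form a strictly bipartite weighted network.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import ceil

import networkx as nx
import numpy as np

from .blocks import OmicsBlock
from .spls import SplsConfig, association_ma, dependency_pairs, spls_fit

__all__ = [
    "AssociationMatrix",
    "PairwiseNetwork",
    "align_samples",
    "combine",
    "dynamic_thresholds",
    "adjacency",
    "build_pairwise_network",
]


def align_samples(
    block_x: OmicsBlock, block_y: OmicsBlock
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Restrict both blocks to their shared samples, identically ordered.

    Returns samples-by-features matrices and the shared sample list (in
    ``block_x`` order).  Requires at least 3 shared samples (a Pearson
    correlation on fewer is meaningless).
    """
    in_y = set(block_y.sample_ids)
    shared = [s for s in block_x.sample_ids if s in in_y]
    if len(shared) < 3:
        raise ValueError(
            f"only {len(shared)} shared samples between "
            f"{block_x.data_type!r} and {block_y.data_type!r}; need >= 3"
        )
    bx = block_x.subset_samples(shared)
    by = block_y.subset_samples(shared)
    # subset preserves each block's own order; re-order Y to match X
    order = {s: k for k, s in enumerate(by.sample_ids)}
    idx = [order[s] for s in bx.sample_ids]
    return bx.values.T, by.values.T[idx, :], list(bx.sample_ids)


def combine(ma: np.ndarray, mb: np.ndarray) -> np.ndarray:
    """Combined weight matrix ``ma + mb.T`` (orientation symmetrization)."""
    ma = np.asarray(ma, dtype=float)
    mb = np.asarray(mb, dtype=float)
    if ma.shape != mb.shape[::-1]:
        raise ValueError(
            f"shape mismatch: ma is {ma.shape}, mb is {mb.shape} "
            "(expected transposed shapes)"
        )
    return ma + mb.T


def dynamic_thresholds(
    m: np.ndarray, fraction: float = 0.05
) -> tuple[float, float]:
    """Dual tail thresholds over the nonzero entries of ``m``.

    ``th_h`` is the smallest value such that the entries ``>= th_h`` are
    the top ``fraction`` of the positive nonzero entries (the
    ``1 - fraction`` quantile, inclusive so ties at the boundary are
    kept); ``th_l`` symmetrically for the negative entries.  When one sign
    is absent, that side's threshold is set to +-inf (retaining nothing)
    with a warning.
    """
    if not (0 < fraction <= 0.5):
        raise ValueError("fraction must be in (0, 0.5]")
    m = np.asarray(m, dtype=float)
    pos = np.sort(m[m > 0])[::-1]
    neg = np.sort(m[m < 0])
    if pos.size:
        th_h = float(pos[min(ceil(fraction * pos.size), pos.size) - 1])
    else:
        warnings.warn("no positive weights; positive threshold disabled", stacklevel=2)
        th_h = np.inf
    if neg.size:
        th_l = float(neg[min(ceil(fraction * neg.size), neg.size) - 1])
    else:
        warnings.warn("no negative weights; negative threshold disabled", stacklevel=2)
        th_l = -np.inf
    return th_l, th_h


def adjacency(m: np.ndarray, th_l: float, th_h: float) -> np.ndarray:
    """Binary adjacency: 1 where ``m >= th_h`` or ``m <= th_l``."""
    if not (th_l < 0 < th_h):
        raise ValueError(f"need th_l < 0 < th_h, got ({th_l}, {th_h})")
    m = np.asarray(m, dtype=float)
    return ((m >= th_h) | (m <= th_l)).astype(int)


@dataclass
class AssociationMatrix:
    """All matrices and thresholds for one block pair."""

    ma: np.ndarray  # n_x x n_y, X -> Y orientation
    mb: np.ndarray  # n_y x n_x, Y -> X orientation
    m: np.ndarray  # combined, n_x x n_y
    th_l: float
    th_h: float
    a: np.ndarray  # binary adjacency, n_x x n_y
    data_type_x: str
    data_type_y: str
    feature_ids_x: list[str]
    feature_ids_y: list[str]


@dataclass
class PairwiseNetwork:
    """Weighted bipartite edge list between two data types."""

    data_type_x: str
    data_type_y: str
    #: (feature_x, feature_y, weight, sign) with sign in {+1, -1}
    edges: list[tuple[str, str, float, int]]
    nodes_x: list[str] = field(default_factory=list)
    nodes_y: list[str] = field(default_factory=list)
    n_components: int = 0

    @property
    def name(self) -> str:
        return f"{self.data_type_x}&{self.data_type_y}"

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        for f in self.nodes_x:
            g.add_node(f, data_type=self.data_type_x)
        for f in self.nodes_y:
            g.add_node(f, data_type=self.data_type_y)
        for fx, fy, w, s in self.edges:
            g.add_edge(fx, fy, weight=w, sign=s)
        return g


def build_pairwise_network(
    block_x: OmicsBlock,
    block_y: OmicsBlock,
    spls_config: SplsConfig | None = None,
    fraction: float = 0.05,
) -> tuple[AssociationMatrix, PairwiseNetwork]:
    """Run the full two-orientation integration for one block pair.

    Both blocks are expected to carry only screened (selected) features
    and linear-scale values are fine: sPLS standardizes columns, and the
    Pearson correlations are taken on the aligned values as passed in.
    Isolated features (never crossing a threshold) are not part of the
    returned network.
    """
    if block_x.data_type == block_y.data_type:
        raise ValueError("pairwise integration needs two distinct data types")
    config = spls_config or SplsConfig()
    X, Y, _shared = align_samples(block_x, block_y)
    ncomp = min(config.ncomp, X.shape[1], Y.shape[1], X.shape[0] - 1)
    if ncomp < config.ncomp:
        config = SplsConfig(
            ncomp=ncomp,
            keep_x=config.keep_x,
            keep_y=config.keep_y,
            max_iter=config.max_iter,
            tol=config.tol,
            scale=config.scale,
        )
    fit_a = spls_fit(X, Y, config)
    ma = association_ma(X, Y, dependency_pairs(fit_a))
    fit_b = spls_fit(Y, X, config)
    mb = association_ma(Y, X, dependency_pairs(fit_b))
    m = combine(ma, mb)
    th_l, th_h = dynamic_thresholds(m, fraction)
    a = adjacency(m, th_l, th_h)

    edges = [
        (
            block_x.feature_ids[i],
            block_y.feature_ids[j],
            float(m[i, j]),
            1 if m[i, j] > 0 else -1,
        )
        for i, j in np.argwhere(a)
    ]
    assoc = AssociationMatrix(
        ma=ma,
        mb=mb,
        m=m,
        th_l=th_l,
        th_h=th_h,
        a=a,
        data_type_x=block_x.data_type,
        data_type_y=block_y.data_type,
        feature_ids_x=list(block_x.feature_ids),
        feature_ids_y=list(block_y.feature_ids),
    )
    nodes_x = sorted({fx for fx, _, _, _ in edges})
    nodes_y = sorted({fy for _, fy, _, _ in edges})
    net = PairwiseNetwork(
        data_type_x=block_x.data_type,
        data_type_y=block_y.data_type,
        edges=edges,
        nodes_x=nodes_x,
        nodes_y=nodes_y,
    )
    net.n_components = (
        nx.number_connected_components(net.to_graph()) if edges else 0
    )
    return assoc, net


def all_pairs(blocks: list[OmicsBlock]) -> list[tuple[OmicsBlock, OmicsBlock]]:
    """All unordered block pairs, in input order."""
    return list(itertools.combinations(blocks, 2))
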