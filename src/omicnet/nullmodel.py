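"""Permutation null model for the dynamic network thresholds.

Each iteration permutes every feature's measured values independently over
samples (preserving each variable's value distribution while destroying
all within- and between-block correlation), reruns the full pairwise
integration, and records the dynamic cut-offs (th_lk, th_hk).  Comparing
the real network's thresholds and retained weights with this distribution
shows whether the retained tails could arise from chance alone.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .association import build_pairwise_network
from .blocks import OmicsBlock
from .spls import SplsConfig

__all__ = [
    "NullThresholdDistribution",
    "NullComparison",
    "permute_block",
    "null_threshold_distribution",
    "compare_to_null",
]

logger = logging.getLogger(__name__)


def permute_block(block: OmicsBlock, rng: np.random.Generator) -> OmicsBlock:
    """Shuffle each feature's values independently across samples.

    Group labels and all identifiers are untouched, so every variable
    keeps its exact value multiset while all correlations are broken.
    """
    if block.n_samples < 2:
        raise ValueError("need at least 2 samples to permute")
    return replace(block, values=rng.permuted(block.values, axis=1))


@dataclass
class NullThresholdDistribution:
    """Recorded dynamic cut-offs over the null iterations.

    Failed iterations (degenerate fits) are stored as NaN; they are
    excluded from comparisons but keep the vectors at full length.
    """

    th_lk: np.ndarray
    th_hk: np.ndarray
    n_iterations: int
    seed: int
    pair_label: str
    n_failures: int = 0

    def valid(self) -> tuple[np.ndarray, np.ndarray]:
        ok = ~(np.isnan(self.th_lk) | np.isnan(self.th_hk))
        return self.th_lk[ok], self.th_hk[ok]


def null_threshold_distribution(
    block_x: OmicsBlock,
    block_y: OmicsBlock,
    spls_config: SplsConfig | None = None,
    fraction: float = 0.05,
    n_iterations: int = 200,
    seed: int = 0,
    permute_both: bool = True,
) -> NullThresholdDistribution:
    """Record (th_lk, th_hk) over ``n_iterations`` permuted integrations.

    Both blocks are permuted each iteration by default (``permute_both``);
    permuting only the predictor block is available as the weaker
    alternative.  Reproducible from ``seed``; iterations use independent
    spawned random streams.  More than 10% failed iterations is an error.
    """
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(n_iterations)
    th_lk = np.full(n_iterations, np.nan)
    th_hk = np.full(n_iterations, np.nan)
    failures = 0
    for k in range(n_iterations):
        rng = np.random.default_rng(streams[k])
        px = permute_block(block_x, rng)
        py = permute_block(block_y, rng) if permute_both else block_y
        try:
            assoc, _ = build_pairwise_network(
                px, py, spls_config=spls_config, fraction=fraction
            )
        except ValueError as exc:
            failures += 1
            logger.warning("null iteration %d failed: %s", k, exc)
            continue
        th_lk[k] = assoc.th_l
        th_hk[k] = assoc.th_h
    if failures > 0.1 * n_iterations:
        raise RuntimeError(
            f"{failures}/{n_iterations} null iterations failed; "
            "the null distribution is unreliable"
        )
    return NullThresholdDistribution(
        th_lk=th_lk,
        th_hk=th_hk,
        n_iterations=n_iterations,
        seed=seed,
        pair_label=f"{block_x.data_type}&{block_y.data_type}",
        n_failures=failures,
    )


@dataclass
class NullComparison:
    """Separation report of real thresholds/weights vs the null."""

    p_high: float  # exceedance p of the real positive threshold
    p_low: float  # exceedance p of the real negative threshold
    overlap_positive: bool
    overlap_negative: bool
    null_high_max: float
    null_low_min: float

    @property
    def overlap(self) -> bool:
        return self.overlap_positive or self.overlap_negative


def compare_to_null(
    real_thresholds: tuple[float, float],
    real_weights: np.ndarray,
    null: NullThresholdDistribution,
) -> NullComparison:
    """Empirical tail p-values and weight/threshold overlap flags.

    The exceedance p-value of the positive tail is
    ``(1 + #{th_hk >= real th_h}) / (N_it + 1)`` (add-one smoothing keeps
    p > 0 at finite N_it); the negative tail symmetrically.  A tail
    "overlaps" when some retained real edge weight of that sign lies
    inside the null threshold range (below the largest null th_hk /
    above the smallest null th_lk).
    """
    th_l, th_h = real_thresholds
    lk, hk = null.valid()
    if lk.size == 0:
        raise ValueError("null distribution has no valid iterations")
    n = null.n_iterations
    p_high = (1 + int((hk >= th_h).sum())) / (n + 1)
    p_low = (1 + int((lk <= th_l).sum())) / (n + 1)
    w = np.asarray(real_weights, dtype=float).ravel()
    retained_pos = w[(w > 0) & (w >= th_h)]
    retained_neg = w[(w < 0) & (w <= th_l)]
    hi_max = float(hk.max())
    lo_min = float(lk.min())
    return NullComparison(
        p_high=p_high,
        p_low=p_low,
        overlap_positive=bool((retained_pos < hi_max).any()),
        overlap_negative=bool((retained_neg > lo_min).any()),
        null_high_max=hi_max,
        null_low_min=lo_min,
    )


def threshold_histogram(
    null: NullThresholdDistribution, real_weights: np.ndarray, bins: int = 40
) -> dict:
    """Binned counts for a separation plot: null cut-offs vs real weights."""
    lk, hk = null.valid()
    w = np.asarray(real_weights, dtype=float).ravel()
    w = w[w != 0]
    lo = min(float(w.min(initial=0.0)), float(lk.min()))
    hi = max(float(w.max(initial=0.0)), float(hk.max()))
    edges = np.linspace(lo, hi, bins + 1)
    return {
        "bin_edges": edges,
        "null_low_counts": np.histogram(lk, bins=edges)[0],
        "null_high_counts": np.histogram(hk, bins=edges)[0],
        "weight_counts": np.histogram(w, bins=edges)[0],
    }
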