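"""Synthetic multi-block omics generator with planted cross-block structure.

The generator emulates the statistical structure the downstream analysis
assumes: several omics blocks measured on (partially) overlapping samples
from a multi-group dietary intervention, with

* diet-responsive features whose group means shift on the log scale,
* planted cross-block feature pairs whose correlation is induced through
  shared latent factors with an exact closed-form target, and
* independent Gaussian measurement noise per feature.

Values are generated on the log2 scale and exponentiated on output, so the
pipeline's own log transform is exercised on realistic positive data.

The closed form: a planted feature is
``baseline + sd * (a * Z + b * eps)`` with ``a = sqrt(|r|)``,
``b = sqrt(1 - sum of |r| over its pairs)`` and ``Z`` the pair's shared
unit-variance latent factor (sign-flipped on one side for negative ``r``).
Both members then have unit standardized variance and Pearson correlation
exactly ``r``.  Latent factors are partially diet-coupled so that planted
features also respond to diet and survive differential screening.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .blocks import OmicsBlock, write_group_map

__all__ = [
    "BlockSpec",
    "PlantedPair",
    "SimConfig",
    "GroundTruth",
    "generate_blocks",
    "write_simulation",
    "DEFAULT_DIETS",
]

#: The six dietary protein sources of the motivating design; the first is
#: the reference diet.
DEFAULT_DIETS = ("soy", "casein", "whey", "plasma", "gluten", "mealworm")


@dataclass(frozen=True)
class BlockSpec:
    """Shape and noise description of one omics block."""

    data_type: str
    n_features: int
    n_samples_retained: int
    noise_sd: float = 1.0
    #: fraction of features given an explicit diet effect
    responsive_fraction: float = 0.0


@dataclass(frozen=True)
class PlantedPair:
    """A cross-block feature pair with a target Pearson correlation."""

    block_a: str
    feature_a: int
    block_b: str
    feature_b: int
    r: float


@dataclass
class SimConfig:
    """Study design for the synthetic experiment.

    Defaults mirror a six-diet mouse trial with six animals per group;
    per-block sample retention models quality-control dropout.
    """

    block_specs: list[BlockSpec]
    n_groups: int = 6
    mice_per_group: int = 6
    group_labels: tuple[str, ...] | None = None
    reference_group: str | None = None
    planted_pairs: list[PlantedPair] = field(default_factory=list)
    effect_size: float = 2.0
    #: fraction of a planted latent factor's variance explained by diet
    #: (as sqrt: the loading of the standardized group pattern on Z)
    diet_coupling: float = 0.6
    #: extra weak shared background factors (0 keeps planted correlations exact)
    n_latent: int = 0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.group_labels is None:
            if self.n_groups == len(DEFAULT_DIETS):
                self.group_labels = DEFAULT_DIETS
            else:
                self.group_labels = tuple(
                    f"diet{i + 1}" for i in range(self.n_groups)
                )
        if len(self.group_labels) != self.n_groups:
            raise ValueError("group_labels length must equal n_groups")
        if self.reference_group is None:
            self.reference_group = self.group_labels[0]
        if self.reference_group not in self.group_labels:
            raise ValueError(f"unknown reference group {self.reference_group!r}")
        if len(self.block_specs) < 2:
            raise ValueError("need at least two block specs")
        labels = [b.data_type for b in self.block_specs]
        if len(set(labels)) != len(labels):
            raise ValueError("block data_type labels must be distinct")
        n_total = self.n_groups * self.mice_per_group
        for b in self.block_specs:
            if not (1 <= b.n_samples_retained <= n_total):
                raise ValueError(
                    f"block {b.data_type!r}: n_samples_retained must be in "
                    f"[1, {n_total}]"
                )
            if b.noise_sd <= 0:
                raise ValueError(f"block {b.data_type!r}: noise_sd must be > 0")
        by_type = {b.data_type: b for b in self.block_specs}
        for p in self.planted_pairs:
            if p.block_a == p.block_b:
                raise ValueError("planted pairs must join two distinct blocks")
            for blk, feat in ((p.block_a, p.feature_a), (p.block_b, p.feature_b)):
                if blk not in by_type:
                    raise ValueError(f"planted pair names unknown block {blk!r}")
                if not (0 <= feat < by_type[blk].n_features):
                    raise ValueError(
                        f"planted feature index {feat} out of range for {blk!r}"
                    )
            if not (-1.0 <= p.r <= 1.0):
                raise ValueError(f"target correlation {p.r} outside [-1, 1]")
        if not (0.0 <= self.diet_coupling < 1.0):
            raise ValueError("diet_coupling must be in [0, 1)")


class InfeasibleCorrelationError(ValueError):
    """Planted correlations cannot be realized by the generative model."""


@dataclass
class GroundTruth:
    """Oracle describing what was planted, for recovery tests."""

    #: (block_a, feature_id_a, block_b, feature_id_b, target r)
    true_edges: list[tuple[str, str, str, str, float]]
    #: per-block set of diet-responsive feature ids (explicit shifts plus
    #: planted features whose latent factor is diet-coupled)
    responsive_features: dict[str, set[str]]


def _feature_id(data_type: str, i: int) -> str:
    return f"{data_type}_{i + 1:03d}"


def generate_blocks(config: SimConfig) -> tuple[list[OmicsBlock], GroundTruth]:
    """Draw one synthetic multi-omics experiment.

    Returns one :class:`OmicsBlock` per block spec (linear scale, strictly
    positive values) and the :class:`GroundTruth` oracle.  Deterministic
    for a fixed ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    labels = list(config.group_labels)
    n_total = config.n_groups * config.mice_per_group
    all_samples = [f"m{i + 1:02d}" for i in range(n_total)]
    groups = {
        s: labels[i // config.mice_per_group] for i, s in enumerate(all_samples)
    }
    group_vec = np.array([groups[s] for s in all_samples])

    # Per-feature latent loadings: feature -> list of (pair index, loading sign)
    by_type = {b.data_type: b for b in config.block_specs}
    pair_loadings: dict[tuple[str, int], list[tuple[int, float]]] = {}
    for k, p in enumerate(config.planted_pairs):
        a = np.sqrt(abs(p.r))
        pair_loadings.setdefault((p.block_a, p.feature_a), []).append((k, a))
        sign = 1.0 if p.r >= 0 else -1.0
        pair_loadings.setdefault((p.block_b, p.feature_b), []).append(
            (k, sign * a)
        )
    for (blk, feat), loads in pair_loadings.items():
        tot = sum(l * l for _, l in loads)
        if tot > 1.0 + 1e-12:
            raise InfeasibleCorrelationError(
                f"feature {feat} of block {blk!r} participates in planted "
                f"pairs whose |r| sum to {tot:.3f} > 1; the requested "
                "correlations cannot coexist"
            )

    # Shared latent factors, one per planted pair, partially diet-coupled.
    n_pairs = len(config.planted_pairs)
    latents = np.empty((n_pairs, n_total))
    d = config.diet_coupling
    for k in range(n_pairs):
        shifts = dict.fromkeys(labels, 0.0)
        for g in labels:
            if g != config.reference_group:
                shifts[g] = rng.choice([-1.0, 1.0])
        pattern = np.array([shifts[g] for g in group_vec])
        sd = pattern.std()
        if sd > 0:
            pattern = (pattern - pattern.mean()) / sd
        latents[k] = d * pattern + np.sqrt(1.0 - d * d) * rng.normal(
            size=n_total
        )

    background = rng.normal(size=(config.n_latent, n_total))

    blocks: list[OmicsBlock] = []
    true_edges: list[tuple[str, str, str, str, float]] = []
    responsive: dict[str, set[str]] = {}
    for spec in config.block_specs:
        nf = spec.n_features
        feature_ids = [_feature_id(spec.data_type, i) for i in range(nf)]
        baselines = rng.normal(config.baseline_mean, config.baseline_sd, size=nf)

        # explicit diet effects, excluding planted features so their
        # correlation stays exactly at target
        planted_idx = {
            feat for (blk, feat) in pair_loadings if blk == spec.data_type
        }
        candidates = [i for i in range(nf) if i not in planted_idx]
        n_resp = int(round(spec.responsive_fraction * nf))
        n_resp = min(n_resp, len(candidates))
        resp_idx = sorted(
            rng.choice(candidates, size=n_resp, replace=False).tolist()
        ) if n_resp else []
        effect = np.zeros((nf, n_total))
        for i in resp_idx:
            signs = dict.fromkeys(labels, 0.0)
            treat = [g for g in labels if g != config.reference_group]
            hit = [g for g in treat if rng.random() < 0.5]
            if not hit:
                hit = [treat[rng.integers(len(treat))]]
            s = rng.choice([-1.0, 1.0])
            for g in hit:
                signs[g] = s * config.effect_size
            effect[i] = np.array([signs[g] for g in group_vec])

        # standardized component: latent loadings + residual noise
        z = np.zeros((nf, n_total))
        noise_scale = np.ones(nf)
        for i in range(nf):
            loads = pair_loadings.get((spec.data_type, i), [])
            var_latent = sum(l * l for _, l in loads)
            noise_scale[i] = np.sqrt(max(0.0, 1.0 - var_latent))
            for k, l in loads:
                z[i] += l * latents[k]
        if config.n_latent:
            bg_load = rng.uniform(-0.2, 0.2, size=(nf, config.n_latent))
            z += bg_load @ background
        z += noise_scale[:, None] * rng.normal(size=(nf, n_total))

        log_values = baselines[:, None] + effect + spec.noise_sd * z
        values = np.exp2(log_values)

        # quality-control dropout: keep a sorted random subset of samples
        keep = np.sort(
            rng.choice(n_total, size=spec.n_samples_retained, replace=False)
        )
        sample_ids = [all_samples[j] for j in keep]
        blocks.append(
            OmicsBlock(
                values=values[:, keep],
                feature_ids=feature_ids,
                sample_ids=sample_ids,
                data_type=spec.data_type,
                groups={s: groups[s] for s in sample_ids},
                reference_group=config.reference_group,
            )
        )
        resp_ids = {feature_ids[i] for i in resp_idx}
        if config.diet_coupling > 0:
            resp_ids |= {feature_ids[i] for i in planted_idx}
        responsive[spec.data_type] = resp_ids

    for p in config.planted_pairs:
        true_edges.append(
            (
                p.block_a,
                _feature_id(p.block_a, p.feature_a),
                p.block_b,
                _feature_id(p.block_b, p.feature_b),
                p.r,
            )
        )
    return blocks, GroundTruth(true_edges=true_edges, responsive_features=responsive)


def write_simulation(
    blocks: list[OmicsBlock], truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write each block, the sample->group map and the true edge list as TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    groups: dict[str, str] = {}
    for b in blocks:
        b.write_tsv(out / f"{b.data_type}.tsv")
        groups.update(b.groups)
    write_group_map(groups, out / "groups.tsv")
    pd.DataFrame(
        truth.true_edges,
        columns=["block_a", "feature_a", "block_b", "feature_b", "r_target"],
    ).to_csv(out / "true_edges.tsv", sep="\t", index=False)
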