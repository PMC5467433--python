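"""Per-block differential screening against the reference diet.

The screen mirrors the standard moderated linear-model workflow for small-n
omics experiments: log2 transform, per-feature cell-means OLS over the diet
groups, empirical-Bayes shrinkage of the residual variances toward a common
prior (method of moments on log variances), moderated t statistics for each
treatment-vs-reference contrast, Benjamini-Hochberg FDR per contrast, and
selection of features significant in at least one contrast.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import special, stats

from .blocks import OmicsBlock

__all__ = [
    "GroupFit",
    "ScreenResult",
    "log_transform",
    "fit_group_model",
    "moderate_statistics",
    "bh_adjust",
    "select_significant",
    "screen_block",
]


def log_transform(block: OmicsBlock, offset: float = 0.0) -> OmicsBlock:
    """Elementwise ``log2(value + offset)``; metadata unchanged.

    Raises
    ------
    ValueError
        If any shifted value is non-positive, naming the first offending
        feature/sample cell.
    """
    if offset < 0:
        raise ValueError("offset must be non-negative")
    shifted = block.values + offset
    bad = np.argwhere(shifted <= 0)
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-positive value after offset {offset} at feature "
            f"{block.feature_ids[i]!r}, sample {block.sample_ids[j]!r} "
            f"({block.values[i, j]!r})"
        )
    return replace(block, values=np.log2(shifted))


@dataclass
class GroupFit:
    """Per-feature OLS fit of the cell-means diet model."""

    #: treatment mean minus reference mean, shape (n_features, n_contrasts)
    coefficients: np.ndarray
    #: pooled within-group residual variance per feature
    residual_variances: np.ndarray
    #: n_samples - n_groups
    residual_df: int
    #: sqrt(1/n_treat + 1/n_ref) per contrast
    stdev_unscaled: np.ndarray
    contrast_labels: list[str]
    feature_ids: list[str]


def fit_group_model(block: OmicsBlock) -> GroupFit:
    """Fit the group-means model feature by feature.

    The contrast coefficients are each treatment group's mean minus the
    reference group's mean (log fold changes when values are on the log
    scale); the residual variance pools squared deviations from group means
    over ``n_samples - n_groups`` degrees of freedom.
    """
    if not block.groups:
        raise ValueError("block has no group labels")
    if block.reference_group is None:
        raise ValueError("block has no designated reference group")
    labels = block.group_labels()
    ref = block.reference_group
    if ref not in labels:
        raise ValueError(f"reference group {ref!r} has no samples in this block")
    # sorted so the contrast order does not depend on sample order
    treatments = sorted(g for g in labels if g != ref)
    if not treatments:
        raise ValueError("need at least one non-reference group")
    group_of = np.array([block.groups[s] for s in block.sample_ids])
    counts = {g: int((group_of == g).sum()) for g in labels}
    empty = [g for g, c in counts.items() if c < 1]
    if empty:
        raise ValueError(f"groups with no samples: {empty}")
    df = block.n_samples - len(labels)
    if df < 1:
        raise ValueError(
            f"zero residual degrees of freedom "
            f"({block.n_samples} samples, {len(labels)} groups)"
        )
    means = {g: block.values[:, group_of == g].mean(axis=1) for g in labels}
    rss = np.zeros(block.n_features)
    for g in labels:
        resid = block.values[:, group_of == g] - means[g][:, None]
        rss += (resid**2).sum(axis=1)
    s2 = rss / df
    coef = np.column_stack([means[g] - means[ref] for g in treatments])
    stdev = np.array([np.sqrt(1.0 / counts[g] + 1.0 / counts[ref]) for g in treatments])
    return GroupFit(
        coefficients=coef,
        residual_variances=s2,
        residual_df=df,
        stdev_unscaled=stdev,
        contrast_labels=[f"{g}-{ref}" for g in treatments],
        feature_ids=list(block.feature_ids),
    )


def _trigamma_inverse(y: float) -> float:
    """Solve ``trigamma(x) = y`` for x > 0 (Newton on the monotone map)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def _fit_variance_prior(s2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of a scaled inverse-chi-square prior to the
    observed residual variances; returns (prior_df d0, prior_variance s0^2).

    Works on ``e = log(s2) - digamma(df/2) + log(df/2)`` whose mean and
    excess variance identify the prior (infinite d0 when the observed
    spread is no larger than the chi-square sampling spread)."""
    ok = s2 > 0
    if not ok.any():
        raise ValueError("all residual variances are zero; moderation undefined")
    # zero variances carry no usable log information; limma offsets them,
    # we simply drop them from the moment fit
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1)) - float(special.polygamma(1, df / 2.0))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s0 = float(
            np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0))
        )
    else:
        d0 = np.inf
        s0 = float(np.exp(emean))
    return d0, s0


def moderate_statistics(
    fit: GroupFit,
    proportion: float = 0.01,
    prior_df: float | None = None,
    prior_variance: float | None = None,
) -> dict:
    """Empirical-Bayes moderated t statistics and two-sided p-values.

    Residual variances are squeezed toward the fitted prior,
    ``s2_post = (d0*s0 + df*s2) / (d0 + df)``, and each contrast's
    moderated t uses ``df + d0`` total degrees of freedom.  ``proportion``
    is the assumed fraction of truly changed features; it is stored for
    reporting only (it would enter log-odds ranking, which the screen does
    not use) and affects no p-value.  ``prior_df``/``prior_variance`` may
    be supplied to override the moment fit (0 recovers ordinary t,
    ``inf`` pins every variance at the prior).
    """
    if not (0 < proportion < 1):
        raise ValueError("proportion must be in (0, 1)")
    if len(fit.feature_ids) < 2 and prior_df is None:
        raise ValueError("variance moderation needs at least two features")
    s2 = fit.residual_variances
    df = fit.residual_df
    if prior_df is None:
        d0, s0 = _fit_variance_prior(s2, df)
    else:
        d0 = float(prior_df)
        s0 = (
            float(prior_variance)
            if prior_variance is not None
            else _fit_variance_prior(s2, df)[1]
        )
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0)
    elif d0 == 0:
        s2_post = s2.copy()
    else:
        s2_post = (d0 * s0 + df * s2) / (d0 + df)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = fit.coefficients / (
            np.sqrt(s2_post)[:, None] * fit.stdev_unscaled[None, :]
        )
    df_total = df + d0
    if np.isinf(df_total):
        p = 2.0 * stats.norm.sf(np.abs(t))
    else:
        p = 2.0 * stats.t.sf(np.abs(t), df=df_total)
    return {
        "moderated_t": t,
        "p_values": p,
        "prior_df": d0,
        "prior_variance": s0,
        "posterior_variances": s2_post,
        "df_total": df_total,
        "proportion": proportion,
    }


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values for one vector.

    ``adj[i] = min over j with p_j >= p_i of (n * p_j / rank_j)``, capped
    at 1; monotone non-decreasing in p.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("bh_adjust expects a 1-D vector")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    from statsmodels.stats.multitest import multipletests

    return multipletests(p, method="fdr_bh")[1]


@dataclass
class ScreenResult:
    """Outcome of screening one omics block."""

    feature_ids: list[str]
    contrast_labels: list[str]
    log_fold_changes: np.ndarray
    moderated_t: np.ndarray
    p_values: np.ndarray
    fdr: np.ndarray
    residual_df: int
    prior_df: float
    prior_variance: float
    fdr_threshold: float
    selected_features: set[str]


def select_significant(
    fdr: np.ndarray, feature_ids: list[str], fdr_threshold: float
) -> set[str]:
    """Features whose minimum FDR over the contrasts is <= the threshold."""
    if not (0 < fdr_threshold <= 1):
        raise ValueError("fdr_threshold must be in (0, 1]")
    min_fdr = np.asarray(fdr).min(axis=1)
    selected = {f for f, q in zip(feature_ids, min_fdr) if q <= fdr_threshold}
    if not selected:
        warnings.warn(
            "no feature passed the FDR threshold "
            f"{fdr_threshold}; the block cannot enter integration",
            stacklevel=2,
        )
    return selected


def screen_block(
    block: OmicsBlock,
    fdr_threshold: float = 0.05,
    log_offset: float = 0.0,
    proportion: float = 0.01,
    already_log: bool = False,
) -> ScreenResult:
    """Full screen of one block: log2 -> OLS -> moderation -> BH -> select.

    BH adjustment is applied within each contrast (the convention of the
    moderated-statistics workflow this mirrors).
    """
    logged = block if already_log else log_transform(block, offset=log_offset)
    fit = fit_group_model(logged)
    mod = moderate_statistics(fit, proportion=proportion)
    fdr = np.column_stack(
        [bh_adjust(mod["p_values"][:, c]) for c in range(len(fit.contrast_labels))]
    )
    selected = select_significant(fdr, fit.feature_ids, fdr_threshold)
    return ScreenResult(
        feature_ids=fit.feature_ids,
        contrast_labels=fit.contrast_labels,
        log_fold_changes=fit.coefficients,
        moderated_t=mod["moderated_t"],
        p_values=mod["p_values"],
        fdr=fdr,
        residual_df=fit.residual_df,
        prior_df=mod["prior_df"],
        prior_variance=mod["prior_variance"],
        fdr_threshold=fdr_threshold,
        selected_features=selected,
    )
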