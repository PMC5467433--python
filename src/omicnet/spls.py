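"""Sparse partial least squares (regression mode) with LASSO-thresholded
loading vectors, and the masked cross-block correlation matrix built from
the selected variables.

The fit alternates soft-thresholded power iterations on the cross-product
matrix ``M = X'Y`` (NIPALS style): for each component the predictor and
response loading vectors are shrunk so that exactly ``keep_x`` / ``keep_y``
entries survive, normalized to unit length, and iterated to convergence.
Deflation is asymmetric ("regression mode"): both blocks are deflated by
the projection onto the predictor scores, so the response block is modeled
by regression on the predictor's latent variables.

A pair of features (i, j) is *dependent* when some component selects both;
the association matrix carries the plain Pearson correlation for dependent
pairs and an exact 0 elsewhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SplsConfig",
    "SplsFit",
    "soft_threshold",
    "spls_fit",
    "dependency_pairs",
    "association_ma",
]


@dataclass
class SplsConfig:
    """Settings for one sPLS fit.

    ``keep_x`` / ``keep_y`` give the number of nonzero loadings per
    component (int applied to all components, or one value per component);
    ``None`` keeps every variable (no sparsity).
    """

    ncomp: int = 5
    keep_x: int | list[int] | None = None
    keep_y: int | list[int] | None = None
    max_iter: int = 500
    tol: float = 1e-9
    scale: bool = True

    def keep_list(self, which: str, n_var: int) -> list[int]:
        raw = self.keep_x if which == "x" else self.keep_y
        if raw is None:
            keep = [n_var] * self.ncomp
        elif isinstance(raw, int):
            keep = [raw] * self.ncomp
        else:
            keep = list(raw)
            if len(keep) != self.ncomp:
                raise ValueError(
                    f"keep_{which} must have one entry per component"
                )
        for k in keep:
            if not (1 <= k <= n_var):
                raise ValueError(
                    f"keep_{which} entries must be in [1, {n_var}], got {k}"
                )
        return keep


@dataclass
class SplsFit:
    x_loadings: np.ndarray  # (n_x, ncomp), unit columns
    y_loadings: np.ndarray  # (n_y, ncomp)
    x_scores: np.ndarray  # (n_samples, ncomp)
    y_scores: np.ndarray
    selected_x: list[set[int]] = field(default_factory=list)
    selected_y: list[set[int]] = field(default_factory=list)
    n_iterations: list[int] = field(default_factory=list)


def soft_threshold(w: np.ndarray, lam: float) -> np.ndarray:
    """Elementwise ``sign(w) * max(|w| - lam, 0)``."""
    return np.sign(w) * np.maximum(np.abs(w) - lam, 0.0)


def _keep_top(w: np.ndarray, k: int) -> np.ndarray:
    """Soft-threshold ``w`` so that at most ``k`` entries survive.

    The threshold is the (k+1)-th largest |w|; ties at the boundary are
    broken deterministically by retaining the lower index.  If shrinkage
    annihilates every kept entry (an exact tie among the top k+1), the top
    k entries are retained unshrunk so the component stays defined.
    """
    n = w.size
    if k >= n:
        return w.copy()
    order = np.lexsort((np.arange(n), -np.abs(w)))
    kept = order[:k]
    lam = np.abs(w[order[k]])
    out = np.zeros_like(w)
    out[kept] = soft_threshold(w[kept], lam)
    if not np.any(out):
        out[kept] = w[kept]
    return out


def _center_scale(a: np.ndarray, scale: bool) -> np.ndarray:
    a = np.asarray(a, dtype=float)
    out = a - a.mean(axis=0)
    if scale:
        sd = a.std(axis=0, ddof=1)
        if np.any(sd == 0):
            bad = int(np.flatnonzero(sd == 0)[0])
            raise ValueError(f"constant column {bad} cannot be scaled")
        out = out / sd
    return out


def _fix_sign(v: np.ndarray) -> float:
    """Return the factor (+-1) making the largest-|.| entry positive."""
    if not np.any(v):
        return 1.0
    return 1.0 if v[np.argmax(np.abs(v))] >= 0 else -1.0


def spls_fit(X: np.ndarray, Y: np.ndarray, config: SplsConfig) -> SplsFit:
    """Fit sparse PLS in regression mode on samples-by-features matrices.

    ``X`` and ``Y`` must share an identically ordered sample set; columns
    are centered (and unit-variance scaled when ``config.scale``) before
    fitting.  Loading vectors are sign-fixed so that each vector's
    largest-magnitude entry is positive.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2:
        raise ValueError("X and Y must be 2-D (samples x features)")
    if X.shape[0] != Y.shape[0]:
        raise ValueError(
            f"sample mismatch: X has {X.shape[0]} rows, Y has {Y.shape[0]}"
        )
    n, n_x = X.shape
    n_y = Y.shape[1]
    if config.ncomp > min(n_x, n_y, n - 1):
        raise ValueError(
            f"ncomp={config.ncomp} exceeds min(n_x, n_y, n_samples-1)="
            f"{min(n_x, n_y, n - 1)}"
        )
    keep_x = config.keep_list("x", n_x)
    keep_y = config.keep_list("y", n_y)
    Xd = _center_scale(X, config.scale)
    Yd = _center_scale(Y, config.scale)

    U = np.zeros((n_x, config.ncomp))
    V = np.zeros((n_y, config.ncomp))
    T = np.zeros((n, config.ncomp))
    W = np.zeros((n, config.ncomp))
    sel_x: list[set[int]] = []
    sel_y: list[set[int]] = []
    iters: list[int] = []
    for h in range(config.ncomp):
        M = Xd.T @ Yd
        if not np.any(M):
            raise ValueError(
                f"degenerate component {h + 1}: cross-product matrix is zero"
            )
        # initialize from the dominant singular pair of M
        _, _, vt = np.linalg.svd(M, full_matrices=False)
        v = vt[0]
        u = np.zeros(n_x)
        it = 0
        for it in range(1, config.max_iter + 1):
            u_new = _keep_top(M @ v, keep_x[h])
            nu = np.linalg.norm(u_new)
            if nu == 0:
                raise ValueError(f"degenerate component {h + 1}: zero x-loading")
            u_new /= nu
            v_new = _keep_top(M.T @ u_new, keep_y[h])
            nv = np.linalg.norm(v_new)
            if nv == 0:
                raise ValueError(f"degenerate component {h + 1}: zero y-loading")
            v_new /= nv
            delta = max(
                np.abs(u_new - u).max(initial=0.0),
                np.abs(v_new - v).max(initial=0.0),
            )
            u, v = u_new, v_new
            if delta < config.tol:
                break
        u = u * _fix_sign(u)
        v = v * _fix_sign(v)
        xi = Xd @ u
        omega = Yd @ v
        ss = xi @ xi
        if ss == 0:
            raise ValueError(f"degenerate component {h + 1}: zero x-score")
        # regression-mode deflation: both blocks regressed on the x-scores
        Xd = Xd - np.outer(xi, (Xd.T @ xi) / ss)
        Yd = Yd - np.outer(xi, (Yd.T @ xi) / ss)
        U[:, h] = u
        V[:, h] = v
        T[:, h] = xi
        W[:, h] = omega
        sel_x.append(set(np.flatnonzero(u).tolist()))
        sel_y.append(set(np.flatnonzero(v).tolist()))
        iters.append(it)
    return SplsFit(
        x_loadings=U,
        y_loadings=V,
        x_scores=T,
        y_scores=W,
        selected_x=sel_x,
        selected_y=sel_y,
        n_iterations=iters,
    )


def dependency_pairs(fit: SplsFit) -> set[tuple[int, int]]:
    """Feature pairs co-selected on at least one component.

    (i, j) is dependent iff some component has a nonzero loading for
    predictor i and for response j; pairs selected on *different*
    components only are not dependent.
    """
    pairs: set[tuple[int, int]] = set()
    for sx, sy in zip(fit.selected_x, fit.selected_y):
        pairs.update((i, j) for i in sx for j in sy)
    return pairs


def association_ma(
    X: np.ndarray,
    Y: np.ndarray,
    pairs: set[tuple[int, int]],
) -> np.ndarray:
    """Masked Pearson correlation matrix over the shared samples.

    Entry (i, j) is ``cor(X_i, Y_j)`` when the pair was deemed dependent
    and exactly 0 otherwise.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n_x, n_y = X.shape[1], Y.shape[1]
    ma = np.zeros((n_x, n_y))
    if not pairs:
        return ma
    used_x = sorted({i for i, _ in pairs})
    used_y = sorted({j for _, j in pairs})
    for idx, cols, name in ((used_x, X, "X"), (used_y, Y, "Y")):
        sd = cols[:, idx].std(axis=0)
        if np.any(sd == 0):
            bad = idx[int(np.flatnonzero(sd == 0)[0])]
            raise ValueError(
                f"zero-variance feature {bad} of {name} among dependent pairs"
            )
    Xc = (X[:, used_x] - X[:, used_x].mean(axis=0)) / X[:, used_x].std(axis=0)
    Yc = (Y[:, used_y] - Y[:, used_y].mean(axis=0)) / Y[:, used_y].std(axis=0)
    corr = (Xc.T @ Yc) / X.shape[0]
    pos_x = {i: a for a, i in enumerate(used_x)}
    pos_y = {j: b for b, j in enumerate(used_y)}
    for i, j in pairs:
        ma[i, j] = corr[pos_x[i], pos_y[j]]
    return ma
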