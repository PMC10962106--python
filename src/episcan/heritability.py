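"""Principal-component-regression estimates of variance explained.

Heritability here is the in-sample adjusted R^2 of a linear model fitted on
the leading principal components of a selected feature set (PCR).  The
adjusted R^2 penalizes dimensionality, which matters because the feature
sets are selected from a candidate space vastly larger than n.  Comparing
the curve of a 1D feature set (selected SNP dosages) against 1D + selected
pair products, with 1D + random pair products as the control, measures how
much extra ("missing") heritability the epistatic signal carries.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["PCRCurve", "adjusted_r2", "pcr_curve", "compare_feature_sets"]

DEFAULT_GRID = (1, 2, 5, 10, 20, 30, 50)


def adjusted_r2(Y: np.ndarray, Y_hat: np.ndarray, q: int) -> float:
    """1 - (1 - R^2)(n - 1)/(n - q - 1) for a fit with q regressors."""
    y = np.asarray(Y, dtype=float)
    f = np.asarray(Y_hat, dtype=float)
    n = y.shape[0]
    if n <= q + 1:
        raise ValueError(f"adjusted R^2 needs n > q + 1 (n={n}, q={q})")
    ss_tot = float(np.square(y - y.mean()).sum())
    if ss_tot == 0.0:
        raise ValueError("constant response")
    r2 = 1.0 - float(np.square(y - f).sum()) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


@dataclass
class PCRCurve:
    label: str
    n_components: list[int]
    adj_r2: list[float]
    r2: list[float]

    def best(self) -> float:
        return max(self.adj_r2)


def _standardize(F: np.ndarray) -> np.ndarray:
    F = np.asarray(F, dtype=float)
    mu = F.mean(axis=0)
    sd = F.std(axis=0)
    sd[sd == 0.0] = np.inf
    return (F - mu) / sd


def pcr_curve(
    features: np.ndarray,
    Y: np.ndarray,
    component_grid=DEFAULT_GRID,
    label: str = "features",
) -> PCRCurve:
    """OLS of Y on the top-c principal components, for each c in the grid.

    The PCA is the SVD of the column-standardized feature matrix;
    components are ordered by singular value with a deterministic sign
    convention (largest-magnitude loading positive).  Grid entries above
    the matrix rank are truncated (with a warning).
    """
    F = _standardize(features)
    y = np.asarray(Y, dtype=float)
    if F.shape[0] != y.shape[0]:
        raise ValueError("feature rows must match phenotype length")
    yc = y - y.mean()
    U, s, Vt = np.linalg.svd(F, full_matrices=False)
    tol = s.max(initial=0.0) * max(F.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    # sign convention so scores are reproducible across SVD implementations
    flip = np.sign(Vt[np.arange(len(s)), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    scores = U * s * flip  # n x rank component scores
    grid = sorted({int(c) for c in component_grid if c >= 1})
    used, adj, plain = [], [], []
    truncated = False
    for c in grid:
        if c > rank:
            truncated = True
            c = rank
        if used and c == used[-1]:
            continue
        S = scores[:, :c]
        coef, *_ = np.linalg.lstsq(S, yc, rcond=None)
        fitted = S @ coef + y.mean()
        used.append(c)
        adj.append(adjusted_r2(y, fitted, q=c))
        plain.append(
            1.0 - float(np.square(y - fitted).sum()) / float(np.square(yc).sum())
        )
    if truncated:
        import warnings

        warnings.warn(f"component grid truncated to rank {rank}")
    return PCRCurve(label=label, n_components=used, adj_r2=adj, r2=plain)


def compare_feature_sets(
    X_selected: np.ndarray,
    Z_selected: np.ndarray,
    Z_random: np.ndarray,
    Y: np.ndarray,
    component_grid=DEFAULT_GRID,
) -> tuple[PCRCurve, PCRCurve, PCRCurve, float]:
    """PCR curves for [1D], [1D + 2D] and [1D + 2D_random] feature sets.

    ``Z_random`` must have the same column count as ``Z_selected`` (pairs
    sampled uniformly outside the selected set).  Returns the three curves
    plus the retrieved heritability: the max-over-grid gap between the
    1D+2D curve and the 1D curve.
    """
    if Z_random.shape[1] != Z_selected.shape[1]:
        raise ValueError("control must have as many columns as the 2D selection")
    c1 = pcr_curve(X_selected, Y, component_grid, label="1D")
    c2 = pcr_curve(
        np.column_stack([X_selected, Z_selected]), Y, component_grid, label="1D+2D"
    )
    c3 = pcr_curve(
        np.column_stack([X_selected, Z_random]), Y, component_grid, label="1D+2D_random"
    )
    by_c1 = dict(zip(c1.n_components, c1.adj_r2))
    gap = max(
        (r2 - by_c1[c]) for c, r2 in zip(c2.n_components, c2.adj_r2) if c in by_c1
    )
    gap = max(gap, c2.best() - c1.best())
    return c1, c2, c3, float(gap)
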