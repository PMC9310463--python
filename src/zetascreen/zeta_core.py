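"""Z-transformation, zeta curves, SVM background boundary and zeta scores.

The scoring logic: every column of the screen matrix is Z-scored against the
negative-control rows.  For each perturbation and each direction of effect a
survival curve is drawn — the fraction of readouts whose Z-score lies beyond a
sliding cutoff, with cutoffs spanning [2, |Z|_0.999] (positive direction) or
[-|Z|_0.999, -2] (negative direction) in 100 equal bins.  When both control
classes are available, a radial-kernel SVM is trained on the control curves in
the (cutoff, survival-fraction) plane and its decision boundary serves as the
background to subtract.  The zeta score of a perturbation is the area of its
curve above the boundary (or above the x-axis without an SVM); the weighted
variant multiplies each bin's area by the |Z| at the bin midpoint, favouring
hits that persist to stringent cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_preprocess import ScreenMatrix

__all__ = [
    "ZMatrix",
    "ZetaCurve",
    "SVMBoundary",
    "z_transform",
    "build_zeta_curves",
    "fit_svm_boundary",
    "zeta_score",
    "combine_directions",
    "compute_zeta_scores",
]


@dataclass
class ZMatrix:
    """Column-wise Z-scored matrix with the control-derived moments."""

    z: pd.DataFrame
    mu: pd.Series
    sigma: pd.Series

    @property
    def shape(self):
        return self.z.shape

    def transform(self, m: ScreenMatrix) -> "ZMatrix":
        """Apply this matrix's column moments to new rows (e.g. a secondary
        screen measured on the same readouts)."""
        z = (m.values[self.mu.index] - self.mu) / self.sigma
        return ZMatrix(z=z, mu=self.mu, sigma=self.sigma)


@dataclass
class ZetaCurve:
    """Survival curves P for a set of perturbations in one direction.

    ``cutoffs`` holds the ``n_bins + 1`` bin edges ordered by increasing
    |cutoff| (so index 0 is the +/-2 noise edge); ``P`` has one row per
    perturbation and one column per edge, P[i, m] being the fraction of
    readouts with Z beyond edge m.  P is monotone non-increasing along m.
    """

    direction: str  # "positive" | "negative"
    cutoffs: np.ndarray
    step: float
    P: pd.DataFrame

    def subset(self, ids) -> "ZetaCurve":
        return ZetaCurve(self.direction, self.cutoffs, self.step, self.P.loc[ids])


@dataclass
class SVMBoundary:
    """Background survival fraction S per bin edge from the control SVM."""

    S: np.ndarray
    model_params: dict = field(default_factory=dict)


def z_transform(m: ScreenMatrix, ann: pd.Series) -> ZMatrix:
    """Z-score each column against the negative-control rows.

    Z_ij = (N_ij - mu_j) / sigma_j with mu_j, sigma_j the mean and sample SD
    of the negative controls in column j.  Columns whose negative controls are
    constant (sigma 0) are dropped with a warning.
    """
    classes = ann.loc[m.row_ids]
    neg = m.values.loc[classes == "negative_control"]
    if len(neg) < 2:
        raise ValueError("z_transform requires >= 2 negative-control rows")
    if m.values.isna().any().any():
        raise ValueError("z_transform requires a complete matrix (impute first)")
    mu = neg.mean(axis=0)
    sigma = neg.std(axis=0, ddof=1)
    bad = sigma <= 0
    if bad.any():
        warnings.warn(
            f"dropping {int(bad.sum())} column(s) with zero negative-control SD: "
            f"{sigma.index[bad].tolist()[:5]}",
            stacklevel=2,
        )
    keep = ~bad
    z = (m.values.loc[:, keep] - mu[keep]) / sigma[keep]
    return ZMatrix(z=z, mu=mu[keep], sigma=sigma[keep])


def _z_range(z: np.ndarray) -> float:
    """99.9th-percentile |Z| taken as the value at rank floor(N*M*0.999) of
    the ascending |Z| (ties kept in stable order)."""
    absz = np.sort(np.abs(z), axis=None, kind="stable")
    k = int(np.floor(absz.size * 0.999))
    k = max(k, 1)
    return float(absz[k - 1])


def build_zeta_curves(
    zm: ZMatrix, direction: str, n_bins: int = 100, noise_edge: float = 2.0
) -> ZetaCurve:
    """Survival curves for all perturbations in one direction.

    The cutoff grid partitions [noise_edge, |Z|_0.999] (positive) or its
    mirror image (negative) into ``n_bins`` equal bins; the |Z| < noise_edge
    region is excluded as experimental noise (two-sided p < 0.05 at |Z| = 2
    under the standard normal).
    """
    if direction not in ("positive", "negative"):
        raise ValueError("direction must be 'positive' or 'negative'")
    Z = zm.z.to_numpy(dtype=float)
    if not np.isfinite(Z).all():
        raise ValueError("Z matrix must be finite")
    zmax = _z_range(Z)
    if zmax <= noise_edge:
        raise ValueError("signal range does not exceed noise threshold")
    edges = np.linspace(noise_edge, zmax, n_bins + 1)
    step = (zmax - noise_edge) / n_bins

    n, M = Z.shape
    Zs = np.sort(Z, axis=1)
    if direction == "positive":
        # count of Z >= edge per row
        idx = np.apply_along_axis(np.searchsorted, 1, Zs, edges, side="left")
        P = (M - idx) / M
        cutoffs = edges
    else:
        idx = np.apply_along_axis(np.searchsorted, 1, Zs, -edges, side="right")
        P = idx / M
        cutoffs = -edges
    return ZetaCurve(direction=direction, cutoffs=cutoffs, step=step, P=pd.DataFrame(P, index=zm.z.index))


def _median_heuristic_gamma(X: np.ndarray, rng: np.random.Generator) -> float:
    n = X.shape[0]
    sub = X if n <= 2000 else X[rng.choice(n, 2000, replace=False)]
    from scipy.spatial.distance import pdist

    d2 = pdist(sub, metric="sqeuclidean")
    med = np.median(d2[d2 > 0]) if (d2 > 0).any() else 1.0
    return float(1.0 / med)


def fit_svm_boundary(
    curves_pos: ZetaCurve,
    curves_neg: ZetaCurve,
    seed: int = 0,
    C: float = 1.0,
    tol: float = 1e-6,
) -> SVMBoundary:
    """Radial-kernel SVM decision boundary between control curves.

    Training points are (cutoff, P) pairs from every bin edge of every control
    curve, labeled by control class; the cutoff axis is standardized before
    training and the kernel width follows the median heuristic.  For each bin
    edge the boundary value S_m is where the decision function crosses zero
    along P (bisection); if the whole [0, 1] column lies on one side, S_m is 0
    (boundary below all data) or 1 (above).
    """
    from sklearn.svm import SVC

    if curves_pos.P.shape[0] < 5 or curves_neg.P.shape[0] < 5:
        raise ValueError("need >= 5 control curves per class")
    if not np.allclose(curves_pos.cutoffs, curves_neg.cutoffs):
        raise ValueError("control curves are on different bins")

    cutoffs = curves_pos.cutoffs
    rng = np.random.default_rng(seed)

    def _points(curve, label):
        x = np.tile(cutoffs, curve.P.shape[0])
        y = curve.P.to_numpy().ravel()
        return np.column_stack([x, y]), np.full(x.size, label)

    Xp, yp = _points(curves_pos, 1)
    Xn, yn = _points(curves_neg, 0)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([yp, yn])

    x_mean, x_sd = X[:, 0].mean(), X[:, 0].std()
    x_sd = x_sd if x_sd > 0 else 1.0
    Xs = X.copy()
    Xs[:, 0] = (Xs[:, 0] - x_mean) / x_sd

    gamma = _median_heuristic_gamma(Xs, rng)
    clf = SVC(kernel="rbf", C=C, gamma=gamma, random_state=seed)
    clf.fit(Xs, y)
    acc = float(clf.score(Xs, y))
    if acc < 0.6:
        warnings.warn(
            f"control classes poorly separated (training accuracy {acc:.2f}); "
            "boundary returned anyway, zeta scores may be near zero",
            stacklevel=2,
        )

    xs = (cutoffs - x_mean) / x_sd

    def f(yv: np.ndarray) -> np.ndarray:
        return clf.decision_function(np.column_stack([xs, yv]))

    lo = np.zeros_like(xs)
    hi = np.ones_like(xs)
    f_lo, f_hi = f(lo), f(hi)
    S = np.full_like(xs, np.nan)
    no_cross = np.sign(f_lo) == np.sign(f_hi)
    # whole column on the positive-control side -> boundary below the data
    S[no_cross & (f_lo > 0)] = 0.0
    S[no_cross & (f_lo <= 0)] = 1.0
    active = ~no_cross
    a, b = lo.copy(), hi.copy()
    fa = f_lo.copy()
    n_iter = int(np.ceil(np.log2(1.0 / tol)))
    for _ in range(n_iter):
        mid = 0.5 * (a + b)
        fm = f(mid)
        left = np.sign(fm) == np.sign(fa)
        a = np.where(active & left, mid, a)
        fa = np.where(active & left, fm, fa)
        b = np.where(active & ~left, mid, b)
    S[active] = 0.5 * (a + b)[active]

    return SVMBoundary(
        S=S,
        model_params={
            "kernel": "rbf",
            "C": C,
            "gamma": gamma,
            "seed": seed,
            "train_accuracy": acc,
            "x_mean": x_mean,
            "x_sd": x_sd,
            "bisection_tol": tol,
        },
    )


def zeta_score(
    curve: ZetaCurve, boundary: SVMBoundary | None = None, weighted: bool = True
) -> pd.Series:
    """Zeta scores (area-based) for every perturbation in ``curve``.

    With a boundary, each bin contributes
    Area_m = ((P_m + P_{m+1}) - (S_m + S_{m+1})) * step / 2 clipped at zero;
    without one, Area_m = (P_m + P_{m+1}) * step / 2.  The weighted score
    multiplies each bin's area by the |Z| at the bin midpoint.
    """
    P = curve.P.to_numpy(dtype=float)
    n_edges = P.shape[1]
    if boundary is not None:
        S = np.asarray(boundary.S, dtype=float)
        if S.shape[0] != n_edges:
            raise ValueError("boundary and curve are on different bins")
        pair = (P[:, :-1] + P[:, 1:]) - (S[:-1] + S[1:])
        area = np.where(pair > 0, pair, 0.0) * curve.step / 2.0
    else:
        area = (P[:, :-1] + P[:, 1:]) * curve.step / 2.0
    if weighted:
        w = np.abs((curve.cutoffs[:-1] + curve.cutoffs[1:]) / 2.0)
        area = area * w
    return pd.Series(area.sum(axis=1), index=curve.P.index, name=f"zeta_{curve.direction}")


def combine_directions(pos: pd.Series, neg: pd.Series, combine: bool = True):
    """Sum the two directional zeta scores (default) or report both.

    Both components are non-negative by construction, so the combined score
    equals zeta_pos + zeta_neg.
    """
    if (pos < 0).any() or (neg < 0).any():
        raise ValueError("zeta components must be non-negative")
    if combine:
        out = pos.add(neg, fill_value=0.0)
        out.name = "zeta"
        return out
    return pd.DataFrame({"zeta_pos": pos, "zeta_neg": neg})


def compute_zeta_scores(
    zm: ZMatrix,
    ann: pd.Series | None = None,
    use_svm: bool = True,
    weighted: bool = True,
    combine: bool = True,
    n_bins: int = 100,
    seed: int = 0,
):
    """End-to-end scoring: curves in both directions, optional SVM boundary
    from the control curves, zeta per direction, optional combination.

    Returns ``(scores, details)`` where ``details`` holds the curves and
    boundaries for inspection.
    """
    curves = {d: build_zeta_curves(zm, d, n_bins=n_bins) for d in ("positive", "negative")}
    boundaries: dict[str, SVMBoundary | None] = {"positive": None, "negative": None}
    if use_svm:
        if ann is None:
            raise ValueError("annotation required to fit the SVM boundary")
        classes = ann.loc[zm.z.index]
        pos_ids = zm.z.index[classes == "positive_control"]
        neg_ids = zm.z.index[classes == "negative_control"]
        for d in curves:
            boundaries[d] = fit_svm_boundary(
                curves[d].subset(pos_ids), curves[d].subset(neg_ids), seed=seed
            )
    parts = {
        d: zeta_score(curves[d], boundaries[d], weighted=weighted) for d in curves
    }
    scores = combine_directions(parts["positive"], parts["negative"], combine=combine)
    details = {"curves": curves, "boundaries": boundaries, "directional": parts}
    return scores, details
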