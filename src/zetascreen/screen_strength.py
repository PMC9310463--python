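"""Screen-Strength curves, balance points, empirical FPL cutoffs and hit calls.

Screen Strength measures how much better a zeta cutoff performs than a random
draw: SS = 1 - aFDR/bFDR, where aFDR (apparent FDR) is the fraction of hits at
the cutoff that are non-expressors and bFDR (baseline FDR) is the overall
fraction of non-expressors among all screened genes.  SS rises with cutoff
stringency and plateaus; the onsets of those plateaus are the balance points
(BP1, BP2, ...) that delimit candidate and high-confidence hits.

Balance-point detection is defined operationally here (the concept itself is
qualitative): the smoothed SS curve must rise into a sustained low-slope run,
and each successive balance point must improve on the previous one.  Permuted
(signal-free) rankings produce no such structure and yield no balance point.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "SSCurve",
    "screen_strength_curve",
    "find_balance_points",
    "fpl_cutoffs",
    "call_hits",
]

_SCREENED_CLASSES = ("sample", "non_expressor")


@dataclass
class SSCurve:
    """Screen-Strength values over an even grid of zeta cutoffs."""

    cutoffs: np.ndarray
    n_hits: np.ndarray
    afdr: np.ndarray
    ss: np.ndarray
    bfdr: float
    balance_points: list[int] = field(default_factory=list)
    fpl_cutoffs: dict[float, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cutoff": self.cutoffs, "n_hits": self.n_hits, "aFDR": self.afdr, "SS": self.ss}
        )

    def to_files(self, tsv_path, json_path) -> None:
        self.to_frame().to_csv(tsv_path, sep="\t", index=False)
        with open(json_path, "w") as fh:
            json.dump(
                {
                    "bFDR": self.bfdr,
                    "balance_points": [int(i) for i in self.balance_points],
                    "balance_point_cutoffs": [float(self.cutoffs[i]) for i in self.balance_points],
                    "fpl_cutoffs": {str(k): float(v) for k, v in self.fpl_cutoffs.items()},
                },
                fh,
                indent=2,
            )


def _screened(scores: pd.Series, ann: pd.Series) -> tuple[pd.Series, pd.Series]:
    classes = ann.loc[scores.index]
    mask = classes.isin(_SCREENED_CLASSES)
    return scores[mask], classes[mask]


def screen_strength_curve(scores: pd.Series, ann: pd.Series, n_cutoffs: int = 100) -> SSCurve:
    """SS over ``n_cutoffs`` evenly spaced zeta cutoffs from min to max score.

    Controls are excluded; only screened genes (samples and non-expressors)
    enter the counts.  Cutoffs that catch zero hits are trimmed off the tail.
    """
    sc, classes = _screened(scores, ann)
    if not np.isfinite(sc.to_numpy(float)).all():
        raise ValueError("scores must be finite")
    is_ne = (classes == "non_expressor").to_numpy()
    if is_ne.sum() == 0:
        raise ValueError("no non-expressors annotated; Screen Strength is undefined")
    vals = sc.to_numpy(float)
    bfdr = is_ne.sum() / vals.size

    cutoffs = np.linspace(vals.min(), vals.max(), n_cutoffs)
    n_hits = (vals[None, :] >= cutoffs[:, None]).sum(axis=1)
    ne_hits = ((vals[None, :] >= cutoffs[:, None]) & is_ne[None, :]).sum(axis=1)
    keep = n_hits > 0
    # n_hits is non-increasing, so zero-hit cutoffs form a tail
    cutoffs, n_hits, ne_hits = cutoffs[keep], n_hits[keep], ne_hits[keep]
    afdr = ne_hits / n_hits
    ss = 1.0 - afdr / bfdr
    return SSCurve(cutoffs=cutoffs, n_hits=n_hits, afdr=afdr, ss=ss, bfdr=float(bfdr))


def find_balance_points(
    curve: SSCurve,
    slope_tol: float = 0.05,
    window: int = 5,
    min_hits: int = 5,
) -> list[int]:
    """Indices of balance points on the SS curve (possibly empty).

    The SS values (restricted to cutoffs with at least ``min_hits`` hits, to
    avoid unstable aFDR denominators) are smoothed with a centered moving
    average of width ``window``.  A balance point is the first cutoff of each
    maximal run where the forward slope stays below
    ``slope_tol * (SS range) / (cutoff range)`` for at least ``window``
    consecutive steps, provided (i) the curve was rising into the run, (ii)
    the smoothed SS there exceeds the value at the previous balance point (or
    zero, for the first), (iii) the plateau sits at the running maximum of
    the smoothed curve (within ``slope_tol`` of the SS range) — a balance
    point marks saturation of cumulative gain, so nothing higher can have been
    seen before it — and (iv) the SS there is significantly above the
    random-draw level: under random hit drawing aFDR is binomial with mean
    bFDR, so SS has mean 0 and SD sqrt((1 - bFDR) / (n_hits * bFDR)); the
    plateau must clear twice that.  Signal-free (permuted or effect-free)
    rankings fluctuate around zero and fail these conditions.
    """
    stable = curve.n_hits >= min_hits
    c = curve.cutoffs[stable]
    s = curve.ss[stable]
    n_hits = curve.n_hits[stable]
    ss_null_sd = np.sqrt((1.0 - curve.bfdr) / (n_hits * curve.bfdr))
    if c.size < max(window + 1, 3):
        return []
    sm = pd.Series(s).rolling(window, center=True, min_periods=1).mean().to_numpy()
    dc = np.diff(c)
    if not (dc > 0).all():
        raise ValueError("cutoffs must be strictly increasing")
    slopes = np.diff(sm) / dc
    rng_s = sm.max() - sm.min()
    rng_c = c[-1] - c[0]
    thr = slope_tol * rng_s / rng_c if rng_c > 0 else np.inf
    flat = slopes < thr

    bps: list[int] = []
    prev_level = 0.0
    i = 0
    n = flat.size
    stable_idx = np.where(stable)[0]
    while i < n:
        if not flat[i]:
            i += 1
            continue
        j = i
        while j < n and flat[j]:
            j += 1
        run_len = j - i
        rising_into = i > 0 and slopes[i - 1] >= thr
        at_running_max = sm[i] >= np.max(sm[: i + 1]) - slope_tol * rng_s
        significant = sm[i] > 2.0 * ss_null_sd[i]
        if run_len >= window and rising_into and sm[i] > prev_level and at_running_max and significant:
            bps.append(int(stable_idx[i]))
            prev_level = sm[i]
        i = j
    return bps


def fpl_cutoffs(
    scores: pd.Series,
    ann: pd.Series,
    levels=(0.05, 0.01),
) -> dict[float, float]:
    """Zeta cutoffs at empirical false-positive levels.

    FPL(c) is the fraction of non-expressors with zeta >= c; the returned
    cutoff for each level is the smallest observed score value c (over all
    screened genes, plus one value just above the maximum) with FPL(c) <=
    level.
    """
    sc, classes = _screened(scores, ann)
    ne = sc[(classes == "non_expressor").to_numpy()].to_numpy(float)
    if ne.size == 0:
        raise ValueError("no non-expressors annotated")
    if ne.size < 20:
        warnings.warn(
            f"only {ne.size} non-expressors; FPL cutoffs will be coarse", stacklevel=2
        )
    vals = np.unique(sc.to_numpy(float))
    candidates = np.append(vals, np.nextafter(vals[-1], np.inf))
    out: dict[float, float] = {}
    ne_sorted = np.sort(ne)
    for level in levels:
        if not (0.0 < level <= 1.0):
            raise ValueError(f"FPL level must be in (0, 1]: {level}")
        # fraction of non-expressors >= c, vectorized over candidates
        frac = (ne.size - np.searchsorted(ne_sorted, candidates, side="left")) / ne.size
        ok = np.where(frac <= level)[0]
        out[float(level)] = float(candidates[ok[0]]) if ok.size else float(candidates[-1])
    return out


def call_hits(
    scores: pd.Series,
    ann: pd.Series,
    curve: SSCurve,
    mode: str = "BP2",
) -> pd.DataFrame:
    """Label screened genes none / candidate / high_confidence.

    ``mode`` is one of ``"BP1"`` (candidate at or above BP1), ``"BP2"``
    (candidate between BP1 and BP2, high confidence at or above BP2),
    ``"FPL:<level>"`` or ``"manual:<zeta>"``.  Output is sorted by zeta
    descending.
    """
    sc, _ = _screened(scores, ann)
    vals = sc.to_numpy(float)
    labels = np.full(vals.size, "none", dtype=object)

    if mode == "BP1":
        if len(curve.balance_points) < 1:
            raise ValueError("no balance point found; consider FPL:<level> mode")
        c1 = curve.cutoffs[curve.balance_points[0]]
        labels[vals >= c1] = "candidate"
    elif mode == "BP2":
        if len(curve.balance_points) < 2:
            raise ValueError(
                "fewer than 2 balance points found; consider FPL:<level> mode"
            )
        c1 = curve.cutoffs[curve.balance_points[0]]
        c2 = curve.cutoffs[curve.balance_points[1]]
        labels[(vals >= c1) & (vals < c2)] = "candidate"
        labels[vals >= c2] = "high_confidence"
    elif mode.startswith("FPL:"):
        level = float(mode.split(":", 1)[1])
        cut = curve.fpl_cutoffs.get(level)
        if cut is None:
            raise ValueError(f"FPL level {level} not present on the curve")
        labels[vals >= cut] = "candidate"
    elif mode.startswith("manual:"):
        cut = float(mode.split(":", 1)[1])
        labels[vals >= cut] = "candidate"
    else:
        raise ValueError(f"unknown hit-calling mode: {mode}")

    out = pd.DataFrame({"gene": sc.index, "zeta": vals, "label": labels})
    return out.sort_values("zeta", ascending=False, kind="stable").reset_index(drop=True)
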