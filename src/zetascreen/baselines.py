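"""Multiple-testing baselines and the readout down-sampling evaluation.

These baselines show why per-readout corrections fail in two dimensions: a
Bonferroni correction over ~15,000 tests per readout moves the Z cutoff to
~4.97 yet leaves the false-positive level high, and an extreme-value (Gumbel)
fit to per-row maximum |Z| pushes the cutoff so far out that genuine hits are
discarded.  The down-sampling evaluation measures how hit recovery degrades as
the number of functional readouts shrinks.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ThresholdResult",
    "bonferroni_z_threshold",
    "gumbel_threshold",
    "downsample_readout_eval",
]

_EULER_GAMMA = 0.5772156649015329


@dataclass
class ThresholdResult:
    method: str  # bonferroni | fdr | gumbel
    alpha_family: float
    per_test_p: float
    z_cutoff: float
    gumbel_params: tuple[float, float] | None = None  # (location, scale)
    extra: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = {
            "method": self.method,
            "alpha_family": self.alpha_family,
            "per_test_p": self.per_test_p,
            "z_cutoff": self.z_cutoff,
            "gumbel_params": list(self.gumbel_params) if self.gumbel_params else None,
            "extra": self.extra,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


def bonferroni_z_threshold(alpha: float, m_tests: int) -> ThresholdResult:
    """Two-sided standard-normal Z cutoff after Bonferroni correction.

    per_test_p = alpha / m_tests and z = Phi^-1(1 - per_test_p / 2); e.g.
    alpha 0.01 over 15,000 tests gives p = 6.67e-7 and Z = 4.97.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must be in (0, 1): {alpha}")
    if m_tests < 1:
        raise ValueError("m_tests must be >= 1")
    per_test_p = alpha / m_tests
    z = float(stats.norm.isf(per_test_p / 2.0))
    return ThresholdResult(
        method="bonferroni", alpha_family=alpha, per_test_p=per_test_p, z_cutoff=z
    )


def fit_gumbel_mle(x: np.ndarray) -> tuple[float, float]:
    """Gumbel (right-skewed) MLE with moment-based start values."""
    x = np.asarray(x, dtype=float)
    beta0 = x.std(ddof=1) * np.sqrt(6.0) / np.pi
    mu0 = x.mean() - _EULER_GAMMA * beta0
    mu, beta = stats.gumbel_r.fit(x, loc=mu0, scale=beta0)
    return float(mu), float(beta)


def gumbel_threshold(zm, alpha: float = 0.01, correction: str = "bonferroni") -> ThresholdResult:
    """Extreme-value threshold on per-row maximum |Z|.

    The per-row max |Z| is fitted with a Gumbel distribution by maximum
    likelihood; each row's upper-tail p-value under the fit is corrected with
    Bonferroni or Benjamini-Hochberg, and the reported cutoff is the |Z| at
    family level ``alpha``.
    """
    if correction not in ("bonferroni", "bh"):
        raise ValueError("correction must be 'bonferroni' or 'bh'")
    maxima = np.abs(zm.z.to_numpy(float)).max(axis=1)
    if np.allclose(maxima, maxima[0]):
        raise ValueError("degenerate row maxima (all equal); cannot fit Gumbel")
    mu, beta = fit_gumbel_mle(maxima)
    n = maxima.size
    pvals = stats.gumbel_r.sf(maxima, mu, beta)
    if correction == "bonferroni":
        per_test_p = alpha / n
        cutoff = float(stats.gumbel_r.isf(per_test_p, mu, beta))
        n_pass = int((pvals <= per_test_p).sum())
    else:
        from statsmodels.stats.multitest import multipletests

        reject, adj, *_ = multipletests(pvals, alpha=alpha, method="fdr_bh")
        if reject.any():
            cutoff = float(maxima[reject].min())
            per_test_p = float(pvals[reject].max())
        else:
            cutoff = float(stats.gumbel_r.isf(alpha / n, mu, beta))
            per_test_p = alpha / n
        n_pass = int(reject.sum())
    return ThresholdResult(
        method="gumbel",
        alpha_family=alpha,
        per_test_p=float(per_test_p),
        z_cutoff=cutoff,
        gumbel_params=(mu, beta),
        extra={"correction": correction, "n_rows": n, "n_passing": n_pass},
    )


def downsample_readout_eval(
    m,
    ann: pd.Series,
    reference_hits,
    sizes=(50, 100, 150, 200, 250, 300),
    reps: int = 3,
    seed: int = 0,
    use_svm: bool = True,
    weighted: bool = True,
    fpl_level: float = 0.05,
) -> pd.DataFrame:
    """Hit recovery as a function of the number of readouts.

    For each target size and replicate, readout columns are sampled without
    replacement, the full zeta pipeline (Z-transform, curves, optional SVM
    boundary, zeta, FPL cutoff) is rerun, and the fraction of
    ``reference_hits`` recovered is recorded.
    """
    from .io_preprocess import ScreenMatrix
    from .screen_strength import fpl_cutoffs
    from .zeta_core import compute_zeta_scores, z_transform

    reference_hits = set(reference_hits)
    if not reference_hits:
        raise ValueError("reference_hits is empty")
    M = m.values.shape[1]
    rng = np.random.default_rng(seed)
    rows = []
    for size in sizes:
        if size > M:
            raise ValueError(f"size {size} exceeds the number of readouts {M}")
        for rep in range(reps):
            cols = rng.choice(M, size=size, replace=False)
            sub = ScreenMatrix(m.values.iloc[:, np.sort(cols)])
            zm = z_transform(sub, ann)
            scores, _ = compute_zeta_scores(
                zm, ann, use_svm=use_svm, weighted=weighted, seed=seed
            )
            cut = fpl_cutoffs(scores, ann, levels=(fpl_level,))[fpl_level]
            classes = ann.loc[scores.index]
            screened = scores[classes.isin(("sample", "non_expressor"))]
            hits = set(screened.index[screened >= cut])
            rows.append(
                {
                    "size": size,
                    "rep": rep,
                    "recovery": len(hits & reference_hits) / len(reference_hits),
                }
            )
    return pd.DataFrame(rows)
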