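import numpy as np
import pandas as pd
import pytest

from zetascreen import synthetic, zeta_core


@pytest.fixture(scope="session")
def small_screen():
    """A small but well-powered synthetic screen (shared, read-only)."""
    cfg = synthetic.ScreenSimConfig(
        n_readouts=100,
        n_regulators=20,
        n_inert=100,
        n_non_expressors=40,
        seed=11,
    )
    return synthetic.simulate_screen(cfg)


@pytest.fixture(scope="session")
def small_screen_zm(small_screen):
    return zeta_core.z_transform(small_screen.matrix, small_screen.annotation)


@pytest.fixture(scope="session")
def small_screen_scores(small_screen, small_screen_zm):
    scores, details = zeta_core.compute_zeta_scores(
        small_screen_zm, small_screen.annotation, seed=11
    )
    return scores, details


@pytest.fixture(scope="session")
def full_screen():
    """Full default study conditions: 2,000 genes x 300 readouts."""
    return synthetic.simulate_screen(synthetic.ScreenSimConfig(seed=1))


@pytest.fixture(scope="session")
def full_screen_scores(full_screen):
    zm = zeta_core.z_transform(full_screen.matrix, full_screen.annotation)
    scores, details = zeta_core.compute_zeta_scores(zm, full_screen.annotation, seed=1)
    return scores, details


@pytest.fixture(scope="session")
def offtarget_screen():
    """Screen with two planted off-target pools plus library and secondary."""
    cfg = synthetic.ScreenSimConfig(
        n_readouts=100,
        n_regulators=20,
        n_inert=100,
        n_non_expressors=40,
        n_offtarget_plants=2,
        seed=3,
    )
    return synthetic.simulate_screen(cfg)


@pytest.fixture(scope="session")
def full_droplets():
    """Full default droplet conditions: 10,000 droplets across 4 classes."""
    return synthetic.simulate_droplets(synthetic.DropletSimConfig(seed=1))


@pytest.fixture(scope="session")
def small_droplets():
    """Reduced droplet mixture keeping the default class proportions."""
    cfg = synthetic.DropletSimConfig(
        n_high_quality=1200,
        n_empty=1200,
        n_broken=300,
        n_stripped_nuclei=300,
        n_genes=800,
        seed=7,
    )
    return synthetic.simulate_droplets(cfg)


def brute_force_zeta(P, S, cutoffs, step, weighted, use_svm):
    """Scalar reference implementation of the area sum (independent oracle)."""
    total = 0.0
    for m in range(len(cutoffs) - 1):
        if use_svm:
            pair = (P[m + 1] + P[m]) - (S[m + 1] + S[m])
            area = pair * step / 2.0 if pair > 0 else 0.0
        else:
            area = (P[m + 1] + P[m]) * step / 2.0
        if weighted:
            area *= abs((cutoffs[m] + cutoffs[m + 1]) / 2.0)
        total += area
    return total


def brute_force_lcs(a: str, b: str) -> int:
    """Quadratic longest-common-substring length (independent oracle)."""
    best = 0
    prev = [0] * (len(b) + 1)
    for i in range(1, len(a) + 1):
        cur = [0] * (len(b) + 1)
        for j in range(1, len(b) + 1):
            if a[i - 1] == b[j - 1]:
                cur[j] = prev[j - 1] + 1
                best = max(best, cur[j])
        prev = cur
    return best
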