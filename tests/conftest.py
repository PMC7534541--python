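import numpy as np
import pytest

from powderscreen.reduction import AxisKind, Pattern1D, subtract_buffer
from powderscreen.synthetic import (
    ExperimentConfig,
    default_grid,
    paper_phantoms,
    simulate_profile_pair,
)

TRUE_CELLS = {
    "luc": ("P41212", 129.13, 97.1),
    "impdh": ("P4212", 209.3, 93.44),
    "catb": ("P42212", 125.69, 54.408),
    "hex1": ("P6522", 58.01, 195.2),
}


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def experiment():
    return ExperimentConfig(seed=1)


@pytest.fixture(scope="session")
def phantoms():
    return paper_phantoms()


@pytest.fixture(scope="session")
def catb_pair(phantoms, experiment, grid):
    """One seeded (sample, buffer) profile pair for the CatB-like phase."""
    return simulate_profile_pair(phantoms["catb"], experiment, grid, 1)


@pytest.fixture(scope="session")
def catb_subtracted(catb_pair):
    return subtract_buffer(*catb_pair)


@pytest.fixture(scope="session")
def phase_replicates(phantoms, experiment, grid):
    """3 noisy replicates of each of the 4 phases, buffer-subtracted."""
    patterns, labels = [], []
    for pi, name in enumerate(sorted(phantoms)):
        for rep in range(3):
            s, b = simulate_profile_pair(phantoms[name], experiment, grid, 100 * pi + rep)
            patterns.append(subtract_buffer(s, b))
            labels.append(pi)
    return patterns, labels


# --- analytic screening fixture -------------------------------------------
# Triangle-wave dither of period 8 and amplitude 4δ: its sliding median is
# 2δ and sliding MAD is exactly δ for any window much longer than a period,
# so the screener's robust noise scale is 1.4826·δ by construction and peak
# SNRs can be dialled in exactly.


def triangle_profile(n=1200, delta=1.0, lo=0.4, hi=2.4):
    axis = np.linspace(lo, hi, n)
    tri = np.array([0, 1, 2, 3, 4, 3, 2, 1], float) * delta
    dither = np.tile(tri, n // 8 + 1)[:n]
    return Pattern1D(AxisKind.TWO_THETA, axis, dither, np.ones(n))


def mesa_profile(snr_targets, sites=(400, 800), n=1200, delta=1.0):
    """Flat-top peaks whose measured SNR equals the requested targets exactly."""
    from powderscreen.screening import estimate_baseline, local_noise_sigma

    base = triangle_profile(n=n, delta=delta)
    b0 = estimate_baseline(base)
    s0 = local_noise_sigma(base, b0)
    y = base.intensity.copy()
    for site, snr in zip(sites, snr_targets):
        for i in range(site, site + 5):
            y[i] = b0[i] + snr * s0[i]
    return Pattern1D(AxisKind.TWO_THETA, base.axis, y, np.ones(n))
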