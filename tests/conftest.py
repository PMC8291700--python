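"""Shared fixtures: noiseless and noisy default curves, a small study."""

from dataclasses import replace

import numpy as np
import pytest

from icgperf.simulate import (
    KineticParams,
    default_params,
    noiseless_signal,
    simulate_curve,
    simulate_study,
)


@pytest.fixture(scope="session")
def control_baseline_params() -> KineticParams:
    """Noiseless control-tissue (D3) kinetics at baseline."""
    return default_params("I", "D3", "T0", noise_sd=0.0)


@pytest.fixture(scope="session")
def control_baseline_curve(control_baseline_params):
    return simulate_curve(control_baseline_params, seed=0)


@pytest.fixture(scope="session")
def small_study():
    """A reduced study (2/2/2 animals) for fast end-to-end tests."""
    return simulate_study(n_per_group={"I": 2, "II": 2, "III": 2}, seed=42)


def fine_grid_oracle(params: KineticParams, duration: float = 120.0,
                     dt_fine: float = 0.02) -> tuple[float, float]:
    """Independent fine-grid oracle for the noiseless curve model.

    Evaluates the generative convolution model on a grid ten times finer
    than the default camera sampling and reads off the defined quantities
    directly: the peak above baseline within 60 s of the ground-truth dye
    arrival, and the maximal forward-difference slope up to that peak.
    """
    horizon = min(params.aif_delay + 60.0, duration)
    t = np.arange(0.0, duration + dt_fine / 2, dt_fine)
    y = noiseless_signal(params, t, dt_fine)
    n_h = int(round(horizon / dt_fine)) + 1
    yh = y[:n_h]
    ipeak = int(np.argmax(yh))
    peak_minus_baseline = float(yh[ipeak] - params.baseline_offset)
    rising = np.diff(yh[: ipeak + 1]) / dt_fine if ipeak >= 1 else np.array([0.0])
    return peak_minus_baseline, float(rising.max())


def random_draw_params(rng: np.random.Generator, noise_sd: float = 0.0) -> KineticParams:
    """A realistic random kinetic parameter draw for property tests."""
    return KineticParams(
        baseline_offset=rng.uniform(2.0, 10.0),
        inflow_rate=rng.uniform(0.5, 5.0),
        washout_rate=rng.uniform(0.05, 0.25),
        leak_fraction=rng.choice([0.0, rng.uniform(0.0, 0.6)]),
        aif_delay=rng.uniform(2.0, 10.0),
        aif_shape=rng.uniform(2.0, 4.0),
        aif_scale=rng.uniform(2.0, 4.0),
        aif_amplitude=rng.uniform(0.5, 2.0),
        recirc_fraction=rng.uniform(0.0, 0.3),
        recirc_delay=rng.uniform(20.0, 40.0),
        noise_sd=noise_sd,
    )
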