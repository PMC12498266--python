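"""Shared fixtures.

Expensive synthetic recordings are session-scoped so recovery experiments
and acceptance checks reuse the same simulations. Sweeps run at a reduced
sampling rate (2.5 kHz) where the full 10 kHz rate adds nothing to the
quantity under test; canonical bin-geometry checks use 10 kHz.
"""

import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from oscilact.fret import calibrate_two_point, compute_ratio
from oscilact.gamma import assess_gamma_presence
from oscilact.simulate import (
    FretSimParams,
    GammaSimParams,
    SPWRSimParams,
    calibration_protocol,
    gen_fret_trace,
    gen_gamma_lfp,
    gen_nonoscillatory_lfp,
    gen_spwr_lfp,
)
from oscilact.spwr import analyze_spwr

SWEEP_FS = 2500.0  # Hz; gamma-band content is fully resolved here


@pytest.fixture(scope="session")
def spwr_run():
    """300-s sharp wave-ripple simulation at 3/s with its full analysis."""
    params = SPWRSimParams(seed=7)
    rec, truth = gen_spwr_lfp(params)
    events, summary = analyze_spwr(rec)
    return {"params": params, "rec": rec, "truth": truth, "events": events, "summary": summary}


@pytest.fixture(scope="session")
def gamma_presence_runs():
    """Presence verdicts for 10 default gamma simulations (seeds 0..9)."""
    out = []
    for seed in range(10):
        rec = gen_gamma_lfp(GammaSimParams(sampling_rate=SWEEP_FS, seed=seed))
        out.append(assess_gamma_presence(rec))
    return out

@pytest.fixture(scope="session")
def pink_presence_runs():
    """Presence verdicts for 20 pink-noise control traces (seeds 100..119)."""
    out = []
    for seed in range(100, 120):
        rec = gen_nonoscillatory_lfp(300.0, SWEEP_FS, 0.05, seed)
        out.append(assess_gamma_presence(rec))
    return out


@pytest.fixture(scope="session")
def calibration_run():
    """Low-noise two-point calibration trace with its recovered calibration."""
    params = FretSimParams(protocol=calibration_protocol(), seed=1)
    trace, lactate = gen_fret_trace(params)
    compute_ratio(trace)
    cal = calibrate_two_point(trace, lactate_window=(120.0, 390.0), pyruvate_window=(390.0, 660.0))
    return {"params": params, "trace": trace, "lactate": lactate, "cal": cal}


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
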