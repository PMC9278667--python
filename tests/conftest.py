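"""Shared fixtures: phantom specs, WED profiles and simulated acquisitions.

Expensive objects (fits, rendered series) are session-scoped so the fitting,
noise and acceptance tests can share them.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pytest

from atcmlab import (DEFAULT_WEIGHTS, THORAX_PLAIN, analytic_wed_profile,
                     build_phantom, fit_model, render_series,
                     simulate_modulation)


@pytest.fixture(scope="session")
def mercury():
    return build_phantom("mercury4")


@pytest.fixture(scope="session")
def mercury_profile(mercury):
    """Analytic WED profile in table coordinates, 2 mm sampling, 60 mm air."""
    return analytic_wed_profile(mercury, dz=2.0, margin=60.0)


@pytest.fixture(scope="session")
def hf_curve(mercury_profile):
    """Noise-free HF helical acquisition, 40 mm lookahead, default protocol."""
    return simulate_modulation(mercury_profile, THORAX_PLAIN, "HF",
                               lookahead_mm=40.0, seed=1)


@pytest.fixture(scope="session")
def unclamped_protocol():
    """Thorax protocol without tube-current limits (pure exponential
    response), used for exact parameter-recovery checks."""
    return replace(THORAX_PLAIN, min_ma=0.0, max_ma=1e9)


@pytest.fixture(scope="session")
def unclamped_fit(mercury_profile, unclamped_protocol):
    curve = simulate_modulation(mercury_profile, unclamped_protocol, "HF",
                                lookahead_mm=40.0, seed=1)
    result = fit_model([(curve, mercury_profile)], d_candidates=range(1, 41))
    return curve, result


@pytest.fixture(scope="session")
def p08_fit(mercury_profile, hf_curve):
    """Grid-search fit of the default pitch-0.8 acquisition."""
    return fit_model([(hf_curve, mercury_profile)],
                     d_candidates=range(1, 41))


@pytest.fixture(scope="session")
def pitch_sweep_fits(mercury_profile):
    """Best-fit results across the pitch family (window grows with pitch)."""
    results = {}
    for pitch, lookahead in [(0.6, 32.0), (0.8, 40.0), (1.0, 50.0),
                             (1.2, 52.0)]:
        protocol = replace(THORAX_PLAIN, pitch=pitch)
        curve = simulate_modulation(mercury_profile, protocol, "HF",
                                    lookahead_mm=lookahead, seed=1)
        results[pitch] = fit_model([(curve, mercury_profile)],
                                   d_candidates=range(1, 41))
    return results


@pytest.fixture(scope="session")
def mercury_series(hf_curve, mercury):
    """Rendered noisy slice series for the default HF acquisition."""
    return render_series(hf_curve, mercury, seed=2)


@pytest.fixture(scope="session")
def weights():
    return np.asarray(DEFAULT_WEIGHTS)
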