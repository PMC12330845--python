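"""Shared fixtures: small phantoms and simulated sessions reused across tests.

Sessions are session-scoped because signal synthesis builds a cached
matrix-formalism table on first use; reusing one phantom/session pair keeps
the suite fast without weakening the checks.
"""

from __future__ import annotations

import numpy as np
import pytest

from reffmap.preprocess_real import PhaseFilterConfig, rectify_volume
from reffmap.reff_fit import fit_volume
from reffmap.spherical_mean import powder_decay
from reffmap.synthetic_data import SessionSpec, default_phantom, simulate_session


def rectify_stack(data: np.ndarray, config: PhaseFilterConfig | None = None):
    """Apply the phase filter volume by volume to a complex 4-D stack."""
    out = np.empty(data.shape)
    for j in range(data.shape[-1]):
        out[..., j], _, _ = rectify_volume(data[..., j], config)
    return out


def fit_reff_stack(data, bvals, bvecs, mask, b_local=None, r_min=None):
    """signals (4-D real) -> MicrostructureMaps over the flattened mask."""
    n_vol = data.shape[-1]
    decay = powder_decay(data.reshape(-1, n_vol), bvals, bvecs, b_local=b_local)
    return fit_volume(decay, 18.8, 26.8, mask=mask.reshape(-1), r_min=r_min)


@pytest.fixture(scope="session")
def recovery_phantom():
    """Uniform gamma ensemble (k=2, s=0.5 um) with >= 200 WM voxels."""
    ph = default_phantom(
        shape=(20, 20, 6),
        s_base=0.5,
        s_multipliers=np.ones(6),
        s_heterogeneity=0.0,
        asymmetry={},
        seed=5,
    )
    assert (ph.prob_wm > 0.55).sum() >= 200
    return ph


@pytest.fixture(scope="session")
def recovery_session(recovery_phantom):
    """One noisy retest acquisition of the recovery phantom (SNR 20)."""
    return simulate_session(
        recovery_phantom, SessionSpec(preset="retest", snr=20.0, seed=7)
    )


@pytest.fixture(scope="session")
def noiseless_session(recovery_phantom):
    return simulate_session(
        recovery_phantom, SessionSpec(preset="retest", snr=np.inf, seed=7)
    )


@pytest.fixture(scope="session")
def tiny_phantom():
    """Small default-parameter phantom with parcels, for fast structural tests."""
    return default_phantom(shape=(12, 12, 6), seed=3)
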