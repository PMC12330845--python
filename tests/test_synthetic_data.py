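"""Synthetic phantom / session generator tests."""

import numpy as np
import pytest

from reffmap.reff_fit import daperp_from_reff
from reffmap.synthetic_data import (
    SessionSpec,
    default_phantom,
    generate_directions,
    make_retest_pair,
    perturb_phantom,
    protocol_preset,
    sample_watson,
    simulate_session,
    volume_table,
)


class TestDirections:
    def test_sixty_directions_well_spread(self):
        d = generate_directions(60, seed=42)
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        min_angle = np.degrees(np.arccos(dots.max()))
        assert min_angle > 12.0

    def test_sixty_directions_isotropic(self):
        d = generate_directions(60, seed=42)
        scatter = d.T @ d / 60
        assert np.linalg.norm(scatter - np.eye(3) / 3, ord=2) < 0.02

    def test_deterministic(self):
        assert np.array_equal(
            generate_directions(30, seed=1), generate_directions(30, seed=1)
        )

    def test_three_directions_converge_to_orthogonal_triplet(self):
        d = generate_directions(3, seed=0, n_iter=600)
        dots = np.abs(d @ d.T)
        np.fill_diagonal(dots, 0.0)
        assert dots.max() < 0.05

    def test_too_few(self):
        with pytest.raises(ValueError):
            generate_directions(2)


class TestProtocolPresets:
    def test_feasibility_counts(self):
        p = protocol_preset("feasibility")
        assert p.n_volumes == 428
        assert p.shells == [7.0, 11.0, 13.0, 16.0, 21.0, 25.0, 30.0]
        assert p.n_b0 == 8

    def test_retest_counts(self):
        p = protocol_preset("retest")
        assert p.n_volumes == 245
        assert p.shells == [7.0, 18.0, 25.0, 30.0]
        assert p.n_b0 == 5

    def test_shared_timings(self):
        a, b = protocol_preset("feasibility"), protocol_preset("retest")
        assert (a.delta, a.Delta) == (b.delta, b.Delta) == (18.8, 26.8)

    def test_unknown_preset_lists_options(self):
        with pytest.raises(ValueError, match="feasibility"):
            protocol_preset("bogus")

    def test_volume_table_interspersed_b0(self):
        p = protocol_preset("retest")
        bvals, bvecs = volume_table(p)
        assert (bvals == 0).sum() == 5
        assert bvals[0] == 0.0  # leading b0
        nrm = np.linalg.norm(bvecs[bvals > 0], axis=1)
        assert np.allclose(nrm, 1.0, atol=1e-9)


class TestWatson:
    def test_concentration(self):
        rng = np.random.default_rng(0)
        mu = np.array([0.0, 1.0, 0.0])
        v = sample_watson(mu, 16.0, 4000, rng)
        c2 = np.mean((v @ mu) ** 2)
        assert 0.8 < c2 < 0.95  # concentrated but dispersed

    def test_unit_norm_and_mu_rotation(self):
        rng = np.random.default_rng(1)
        mu = np.array([0.6, 0.64, 0.48])
        mu /= np.linalg.norm(mu)
        v = sample_watson(mu, 50.0, 500, rng)
        assert np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=1e-12)
        assert np.mean((v @ mu) ** 2) > 0.9


class TestSimulateSession:
    def test_deterministic_given_seed(self):
        ph = default_phantom(shape=(8, 8, 4), seed=1)
        spec = SessionSpec(preset="retest", snr=20.0, seed=5)
        a = simulate_session(ph, spec)
        b = simulate_session(ph, spec)
        assert np.array_equal(a.data, b.data)

    def test_noiseless_magnitude_equals_forward_signal(self, noiseless_session):
        # phase rotation is modulus-preserving and noise is absent, so the
        # magnitude equals the noiseless forward signal; different phase
        # seeds leave the magnitude untouched
        ph = noiseless_session.phantom
        other = simulate_session(
            ph, SessionSpec(preset="retest", snr=np.inf, seed=99)
        )
        assert np.allclose(
            np.abs(noiseless_session.data), np.abs(other.data), atol=1e-12
        )

    def test_background_noise_statistics(self, recovery_session):
        bg = recovery_session.s0_map == 0
        sigma = recovery_session.sigma
        mag = np.abs(recovery_session.data[bg])
        assert mag.mean() == pytest.approx(sigma * np.sqrt(np.pi / 2), rel=0.02)
        # real channel of the raw (not demodulated) data is zero-mean too
        assert abs(recovery_session.data[bg].real.mean()) < 0.02 * sigma

    def test_noise_independent_across_volumes(self, recovery_session):
        bg = recovery_session.s0_map == 0
        noise = recovery_session.data[bg].real  # (n_bg, n_vol)
        # population inter-volume correlation: average over many volume
        # pairs so the estimate's own sampling noise is << the 0.02 bound
        rng = np.random.default_rng(0)
        corrs = []
        for _ in range(80):
            i, j = rng.choice(noise.shape[1], size=2, replace=False)
            corrs.append(np.corrcoef(noise[:, i], noise[:, j])[0, 1])
        assert abs(np.mean(corrs)) < 0.02

    def test_truth_maps_consistent(self, noiseless_session):
        wm = noiseless_session.phantom.k_map > 0
        r = noiseless_session.truth_reff[wm]
        da = noiseless_session.truth_daperp[wm]
        assert np.allclose(da, daperp_from_reff(r, 18.8, 26.8, 2.0), rtol=1e-12)

    def test_invalid_snr(self):
        with pytest.raises(ValueError):
            SessionSpec(snr=0.0)

    def test_write_round_trip(self, tmp_path):
        import nibabel as nib

        ph = default_phantom(shape=(8, 8, 4), seed=1)
        sess = simulate_session(ph, SessionSpec(preset="retest", snr=30.0, seed=2))
        out = tmp_path / "sess"
        sess.write(out)
        re = np.asarray(nib.load(out / "dwi_real.nii").dataobj)
        assert np.allclose(re, sess.data.real.astype(np.float32))
        bvals = np.loadtxt(out / "dwi.bval")
        assert bvals.shape == (245,)
        import json

        meta = json.loads((out / "session.json").read_text())
        assert meta["seed"] == 2 and meta["snr"] == 30.0


class TestRetestPair:
    def test_zero_perturbation_noiseless_identical(self):
        ph = default_phantom(shape=(8, 8, 4), seed=1)
        spec = SessionSpec(preset="retest", snr=np.inf)
        a, b = make_retest_pair(ph, spec, perturbation=0.0, seeds=(1, 2))
        assert np.allclose(np.abs(a.data), np.abs(b.data), atol=1e-12)
        assert np.array_equal(a.truth_reff, b.truth_reff)

    def test_perturbation_scales_daperp(self):
        ph = default_phantom(shape=(8, 8, 4), seed=1)
        rng = np.random.default_rng(0)
        pert = perturb_phantom(ph, 0.05, rng)
        wm = ph.k_map > 0
        ratio = pert.true_reff()[wm] ** 4 / ph.true_reff()[wm] ** 4
        # Da_perp ~ r_eff^4 gets a lognormal factor of the requested scale
        assert np.std(np.log(ratio)) == pytest.approx(0.05, rel=0.15)
        assert abs(np.mean(np.log(ratio))) < 0.01
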