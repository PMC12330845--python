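"""Forward-model unit tests: b-factors, Neuman limit, GPA/matrix formalism."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from reffmap.forward_model import (
    CylinderEnsemble,
    DetectabilityConfig,
    InvalidProtocolError,
    Protocol,
    compute_b_value,
    cylinder_signal,
    distribution_reff,
    g_for_b,
    gpa_cylinder_perp,
    mcf_cylinder_perp,
    neuman_kappa,
    neuman_signal,
    powder_average,
    resolution_limit,
    stick_spherical_mean,
)

DELTA, DELTA_BIG, D0 = 18.8, 26.8, 2.0


class TestBValue:
    def test_zero_gradient(self):
        assert compute_b_value(0.0, DELTA, DELTA_BIG) == 0.0

    def test_round_trip_at_b30(self):
        # inverting the b-factor at the 300 mT/m protocol timings lands near
        # 240 mT/m, and the round trip is exact
        g = g_for_b(30.0, DELTA, DELTA_BIG)
        assert g == pytest.approx(240.33, abs=0.5)
        assert compute_b_value(g, DELTA, DELTA_BIG) == pytest.approx(30.0, rel=1e-12)

    def test_quadratic_scaling(self):
        b1 = compute_b_value(120.0, DELTA, DELTA_BIG)
        b2 = compute_b_value(240.0, DELTA, DELTA_BIG)
        assert b2 == pytest.approx(4.0 * b1, rel=1e-12)

    @pytest.mark.parametrize("delta,Delta", [(0.0, 26.8), (-1.0, 26.8), (26.8, 18.8)])
    def test_invalid_timings(self, delta, Delta):
        with pytest.raises(InvalidProtocolError):
            compute_b_value(100.0, delta, Delta)

    def test_negative_gradient_rejected(self):
        with pytest.raises(InvalidProtocolError):
            compute_b_value(-1.0, DELTA, DELTA_BIG)


class TestNeuman:
    def test_kappa_against_si_units(self):
        # independent evaluation in SI units, converted m^-4 -> um^-4
        gamma_si = 2.6752218744e8  # rad / s / T
        kappa_si = (
            (7.0 / 96.0) * gamma_si**2 * 0.3**2 * 18.8e-3 / 2.0e-9
        )  # m^-4
        expected = kappa_si * 1e-24
        assert neuman_kappa(300.0, DELTA, D0) == pytest.approx(expected, rel=1e-9)
        assert neuman_kappa(300.0, DELTA, D0) == pytest.approx(4.41e-3, rel=2e-3)

    def test_gradient_squared_scaling(self):
        assert neuman_kappa(200.0, DELTA, D0) * 4 == pytest.approx(
            neuman_kappa(400.0, DELTA, D0), rel=1e-12
        )

    def test_vanishes_for_fast_diffusion(self):
        assert neuman_kappa(300.0, DELTA, 1e9) < 1e-10

    def test_signal_examples(self):
        assert neuman_signal(0.0, 1.0) == 1.0
        assert neuman_signal(2.0, 4.41e-3) == pytest.approx(np.exp(-0.0706), rel=1e-4)

    def test_signal_strictly_decreasing_in_radius(self):
        r = np.linspace(0.1, 5, 40)
        s = neuman_signal(r, 4.41e-3)
        assert np.all(np.diff(s) < 0)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            neuman_kappa(300.0, DELTA, 0.0)
        with pytest.raises(ValueError):
            neuman_signal(-1.0, 1.0)


class TestGpaCylinder:
    def test_vanishing_radius(self):
        assert gpa_cylinder_perp(0.01, 300.0, DELTA, DELTA_BIG, D0) > 0.9999

    def test_matches_neuman_in_long_pulse_regime(self):
        # delta * D0 / r^2 >= 10 across this radius range; the physical
        # long-pulse attenuation constant is twice the detectability kappa
        # (see neuman_kappa docstring)
        g = g_for_b(30.0, DELTA, DELTA_BIG)
        for r in [0.5, 1.0, 1.5, 1.9]:
            assert DELTA * D0 / r**2 >= 10
            s_gpa = gpa_cylinder_perp(r, g, DELTA, DELTA_BIG, D0)
            s_neu = neuman_signal(r, 2.0 * neuman_kappa(g, DELTA, D0))
            assert s_gpa == pytest.approx(s_neu, rel=0.03)

    def test_matches_free_diffusion_for_huge_radius(self):
        # r^2 / (D0 * Delta) >= 25: restriction invisible, Gaussian decay
        r, g = 60.0, 10.0
        assert r**2 / (D0 * DELTA_BIG) >= 25
        b_perp = compute_b_value(g, DELTA, DELTA_BIG)
        s = gpa_cylinder_perp(r, g, DELTA, DELTA_BIG, D0, n_roots=200)
        assert s == pytest.approx(np.exp(-b_perp * D0), rel=0.02)

    def test_converged_at_default_roots(self):
        s20 = gpa_cylinder_perp(3.0, 240.0, DELTA, DELTA_BIG, D0, n_roots=20)
        s40 = gpa_cylinder_perp(3.0, 240.0, DELTA, DELTA_BIG, D0, n_roots=40)
        assert abs(s40 / s20 - 1) < 1e-6

    def test_too_few_roots_rejected(self):
        with pytest.raises(ValueError):
            gpa_cylinder_perp(1.0, 240.0, DELTA, DELTA_BIG, D0, n_roots=5)


class TestMatrixFormalism:
    def test_agrees_with_gpa_at_weak_dephasing(self):
        for r in [0.5, 1.0, 1.5]:
            s_mcf = mcf_cylinder_perp(r, 240.0, DELTA, DELTA_BIG, D0)
            s_gpa = gpa_cylinder_perp(r, 240.0, DELTA, DELTA_BIG, D0)
            assert s_mcf == pytest.approx(s_gpa, rel=5e-3)

    def test_basis_convergence(self):
        lo = mcf_cylinder_perp(5.0, 240.0, DELTA, DELTA_BIG, D0)
        hi = mcf_cylinder_perp(5.0, 240.0, DELTA, DELTA_BIG, D0, n_ang=14, n_rad=12)
        assert lo == pytest.approx(hi, rel=1e-4)

    def test_zero_gradient_or_radius(self):
        assert mcf_cylinder_perp(2.0, 0.0, DELTA, DELTA_BIG, D0) == 1.0
        assert mcf_cylinder_perp(0.0, 240.0, DELTA, DELTA_BIG, D0) == 1.0


class TestCylinderSignal:
    def test_parallel_is_pure_stick_decay(self):
        s = cylinder_signal(2.0, 0.0, 30.0, DELTA, DELTA_BIG, D0)
        assert s == pytest.approx(np.exp(-30.0 * D0), rel=1e-9)

    def test_perpendicular_stick_barely_attenuates(self):
        s = cylinder_signal(0.01, np.pi / 2, 30.0, DELTA, DELTA_BIG, D0)
        assert s > 0.999

    def test_antipodal_symmetry(self):
        for theta in [0.3, 0.9, 1.4]:
            s1 = cylinder_signal(2.0, theta, 21.0, DELTA, DELTA_BIG, D0)
            s2 = cylinder_signal(2.0, np.pi - theta, 21.0, DELTA, DELTA_BIG, D0)
            assert s1 == pytest.approx(s2, rel=1e-10)


class TestPowderAverage:
    def test_stick_closed_form(self):
        sticks = CylinderEnsemble(kind="delta", radius=1e-6)
        b = np.array([7.0, 16.0, 30.0])
        for method in ("gpa", "mcf"):
            s = powder_average(sticks, b, DELTA, DELTA_BIG, method=method)
            assert np.allclose(s, stick_spherical_mean(b, D0), atol=1e-6)

    def test_b_zero_normalisation(self):
        ens = CylinderEnsemble(k=2.0, s=0.35)
        assert powder_average(ens, 0.0, DELTA, DELTA_BIG) == 1.0

    def test_small_cylinders_attenuate_less(self):
        # mean diameters ~1 um vs ~5 um (k=2 -> mean radius 2ks)
        small = CylinderEnsemble(k=2.0, s=0.25)
        large = CylinderEnsemble(k=2.0, s=1.25)
        b = np.array([7.0, 13.0, 21.0, 30.0])
        s_small = powder_average(small, b, DELTA, DELTA_BIG)
        s_large = powder_average(large, b, DELTA, DELTA_BIG)
        assert np.all(s_small > s_large)

    def test_monotone_in_b(self):
        ens = CylinderEnsemble(k=2.0, s=0.5)
        b = np.linspace(0, 30, 8)
        s = powder_average(ens, b, DELTA, DELTA_BIG)
        assert np.all(np.diff(s) < 0)


class TestDistributionReff:
    def test_single_radius(self):
        assert CylinderEnsemble(kind="delta", radius=1.7).effective_radius() == 1.7

    def test_gamma_closed_form(self):
        assert distribution_reff(2.0, 0.5) == pytest.approx(
            0.5 * 840.0**0.25, rel=1e-12
        )

    def test_truncation_reduces_reff(self):
        assert distribution_reff(2.0, 0.5, support=(0.25, 5.0)) < distribution_reff(
            2.0, 0.5
        )

    @given(st.floats(0.2, 1.0), st.floats(0.25, 1.0))
    @settings(deadline=None, max_examples=25)
    def test_increasing_in_scale(self, s_lo, ds):
        assert distribution_reff(2.0, s_lo + ds) > distribution_reff(2.0, s_lo)


class TestResolutionLimit:
    def test_kappa_quarter_power_scaling(self):
        cfg = DetectabilityConfig()
        kappa = neuman_kappa(300.0, DELTA, D0)
        assert resolution_limit(cfg, kappa / 2) == pytest.approx(
            2**0.25 * resolution_limit(cfg, kappa), rel=1e-12
        )

    def test_noiseless_limit(self):
        kappa = neuman_kappa(300.0, DELTA, D0)
        assert resolution_limit(DetectabilityConfig(SNR=1e12), kappa) < 1e-2

    def test_config_validation(self):
        with pytest.raises(ValueError):
            DetectabilityConfig(SNR=-1.0)


def test_attenuation_curve_tsv_round_trip(tmp_path):
    from reffmap.forward_model import AttenuationCurve

    curve = AttenuationCurve(
        b=np.array([7.0, 18.0, 30.0]), S=np.array([0.23, 0.13, 0.097])
    )
    curve.to_tsv(tmp_path / "curve.tsv")
    back = AttenuationCurve.from_tsv(tmp_path / "curve.tsv")
    assert np.allclose(back.b, curve.b) and np.allclose(back.S, curve.S)


class TestProtocolType:
    def test_direction_norm_enforced(self):
        with pytest.raises(InvalidProtocolError):
            Protocol(
                shells=[7.0],
                directions=[np.array([[1.0, 1.0, 0.0]])],
                n_b0=1,
                delta=DELTA,
                Delta=DELTA_BIG,
                g_nominal=300.0,
            )

    def test_json_round_trip(self, tmp_path):
        p = Protocol(
            shells=[7.0, 30.0],
            directions=[np.eye(3)[:2], np.eye(3)[:2]],
            n_b0=2,
            delta=DELTA,
            Delta=DELTA_BIG,
            g_nominal=300.0,
            name="mini",
        )
        p.to_json(tmp_path / "p.json")
        q = Protocol.from_json(tmp_path / "p.json")
        assert q.shells == p.shells and q.n_b0 == 2 and q.name == "mini"
        assert np.allclose(q.directions[0], p.directions[0])
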