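"""Masking, parcel summaries and test-retest statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from reffmap.repeatability import (
    asymmetry_table,
    bland_altman,
    cov_within_subject,
    icc,
    parcel_summary,
    repeatability_report,
    rpc,
    tissue_masks,
)


class TestTissueMasks:
    def test_strict_threshold_boundaries(self):
        p = np.array([0.55, 0.56, 0.54])
        zeros = np.zeros(3)
        wm, gm, csf = tissue_masks(p, zeros, zeros)
        assert wm.tolist() == [False, True, False]

    def test_priority_makes_masks_disjoint(self):
        wm_p = np.array([0.9, 0.9, 0.9])
        gm_p = np.array([0.85, 0.0, 0.85])
        csf_p = np.array([0.95, 0.0, 0.0])
        wm, gm, csf = tissue_masks(wm_p, gm_p, csf_p)
        assert csf.tolist() == [True, False, False]
        assert gm.tolist() == [False, False, True]
        assert wm.tolist() == [False, True, False]
        assert not np.any(wm & gm) and not np.any(gm & csf) and not np.any(wm & csf)

    def test_known_voxel_counts(self, tiny_phantom):
        wm, gm, csf = tissue_masks(
            tiny_phantom.prob_wm, tiny_phantom.prob_gm, tiny_phantom.prob_csf
        )
        assert wm.sum() == (tiny_phantom.prob_wm > 0.55).sum()
        assert csf.sum() == (tiny_phantom.prob_csf > 0.9).sum()

    def test_validation(self):
        with pytest.raises(ValueError):
            tissue_masks(np.ones(3), np.ones(4), np.ones(3))
        with pytest.raises(ValueError):
            tissue_masks(np.array([1.5]), np.array([0.0]), np.array([0.0]))


class TestBlandAltman:
    def test_identical_sessions(self):
        assert bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == (0, 0, 0, 0)

    def test_constant_offset(self):
        md, sd, lo, hi = bland_altman([1.0, 2.0], [1.1, 2.1])
        assert md == pytest.approx(0.1, rel=1e-12)
        assert sd == pytest.approx(0.0, abs=1e-12)

    def test_worked_triple(self):
        md, sd, lo, hi = bland_altman([2.0, 2.5, 3.0], [2.1, 2.4, 3.2])
        assert md == pytest.approx(0.0666667, abs=1e-6)
        assert sd == pytest.approx(0.1527525, abs=1e-6)
        assert lo == pytest.approx(md - 1.96 * sd, rel=1e-12)
        assert hi == pytest.approx(md + 1.96 * sd, rel=1e-12)

    def test_too_short(self):
        with pytest.raises(ValueError):
            bland_altman([1.0], [2.0])


class TestRpc:
    def test_zero_differences(self):
        assert rpc(np.zeros(5), grand_mean=2.0)[0] == 0.0

    def test_known_sd(self):
        d = np.array([-0.0816, 0.0816])  # sample SD ~ 0.1154; scale instead:
        d = 0.0816 * np.array([-1.0, 1.0]) / np.std([-1.0, 1.0], ddof=1)
        r, pct = rpc(d, grand_mean=2.42)
        assert r == pytest.approx(1.96 * 0.0816, rel=1e-9)
        assert pct == pytest.approx(100 * 1.96 * 0.0816 / 2.42, rel=1e-9)

    def test_percent_missing_without_mean(self):
        r, pct = rpc(np.array([0.1, -0.1]))
        assert np.isnan(pct)


class TestCov:
    def test_identical_pairs(self):
        assert cov_within_subject([2.0, 3.0], [2.0, 3.0]) == 0.0

    def test_algebraic_example(self):
        # each pair differs by 0.2*sqrt(2): per-pair variance d^2/2 = 0.04
        x = np.full(6, 2.0)
        y = np.full(6, 2.0 + 0.2 * np.sqrt(2))
        gm = np.mean((x + y) / 2)
        assert cov_within_subject(x, y) == pytest.approx(100 * 0.2 / gm, rel=1e-12)

    def test_multiplicative_noise_recovers_scale(self):
        rng = np.random.default_rng(0)
        base = rng.uniform(2.0, 3.0, size=4000)
        x = base * rng.lognormal(0.0, 0.03, size=4000)
        y = base * rng.lognormal(0.0, 0.03, size=4000)
        # within-pair CoV of two independent 3% lognormals: 3% * sqrt(2)/sqrt(2)
        assert cov_within_subject(x, y) == pytest.approx(
            100 * 0.03 * np.sqrt(2) / np.sqrt(2), rel=0.1
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ZeroDivisionError):
            cov_within_subject([-1.0, 1.0], [1.0, -1.0])


class TestIcc:
    def test_duplicated_column_is_one(self):
        v = np.array([[1.0, 1.0], [2.0, 2.0], [5.0, 5.0]])
        assert icc(v) == pytest.approx(1.0, rel=1e-12)

    def test_worked_tables_exact(self):
        # hand-computed via the two-way mean-squares decomposition
        assert icc(np.array([[9.0, 8], [1, 2], [8, 7], [6, 7]])) == pytest.approx(
            56.0 / 59.0, abs=1e-12
        )
        assert icc(np.array([[9.0, 2], [1, 10], [8, 4], [6, 8]])) == pytest.approx(
            -16.0 / 9.0, abs=1e-12
        )

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(2)
        v = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        df = pd.DataFrame(
            {
                "subj": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": v.ravel(),
            }
        )
        res = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="score")
        sel = res["Type"].isin(["ICC2", "ICC(A,1)"])
        ref = float(res.loc[sel, "ICC"].iloc[0])
        assert icc(v) == pytest.approx(ref, abs=1e-10)

    def test_independent_noise_near_zero(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(1000, 2))
        assert abs(icc(v)) < 0.05

    def test_degenerate_input(self):
        assert np.isnan(icc(np.ones((4, 2))))
        with pytest.raises(ValueError):
            icc(np.ones((1, 2)))


class TestAsymmetry:
    @staticmethod
    def _summaries(l_means, r_means):
        mk = lambda means, h: pd.DataFrame(
            {
                "parcel_id": range(len(means)),
                "name": [f"p{i}_{h}" for i in range(len(means))],
                "hemisphere": h,
                "pair": range(1, len(means) + 1),
                "mean": means,
                "sd": 0.0,
                "n_voxels": 10,
            }
        )
        return mk(l_means, "L"), mk(r_means, "R")

    def test_symmetric_is_zero(self):
        l, r = self._summaries([2.0, 2.5], [2.0, 2.5])
        tab = asymmetry_table(l, r)
        assert np.allclose(tab["asymmetry_index"], 0.0)

    def test_ten_percent_ratio(self):
        l, r = self._summaries([1.1], [1.0])
        tab = asymmetry_table(l, r)
        assert tab["asymmetry_index"].iloc[0] == pytest.approx(0.2 / 2.1, rel=1e-12)

    def test_builtin_phantom_asymmetry_ranks_first(self, tiny_phantom):
        truth = np.zeros(tiny_phantom.shape)
        wm = tiny_phantom.k_map > 0
        truth[wm] = tiny_phantom.s_map[wm]  # r_eff ~ s at fixed k
        summary = parcel_summary(
            truth, tiny_phantom.parcels, tiny_phantom.parcel_table
        )
        tab = asymmetry_table(
            summary[summary.hemisphere == "L"], summary[summary.hemisphere == "R"]
        )
        top = tab.loc[tab["asymmetry_index"].abs().idxmax(), "pair"]
        assert top == 2  # the phantom builds 5% L>R into pair 2

    def test_missing_hemisphere_skipped(self):
        l, r = self._summaries([1.0, 2.0], [1.0])
        tab = asymmetry_table(l, r)
        assert len(tab) == 1


class TestScaleInvariance:
    @given(st.floats(0.5, 20.0))
    @settings(deadline=None, max_examples=20)
    def test_common_rescaling(self, c):
        rng = np.random.default_rng(0)
        x = rng.uniform(2, 3, 30)
        y = x + rng.normal(0, 0.1, 30)
        assert cov_within_subject(c * x, c * y) == pytest.approx(
            cov_within_subject(x, y), rel=1e-9
        )
        assert icc(np.stack([c * x, c * y], 1)) == pytest.approx(
            icc(np.stack([x, y], 1)), rel=1e-9
        )
        assert rpc(c * (y - x), grand_mean=c * x.mean())[0] == pytest.approx(
            c * rpc(y - x, grand_mean=x.mean())[0], rel=1e-9
        )


def test_report_deterministic_and_serialisable(tiny_phantom, tmp_path):
    rng = np.random.default_rng(5)
    wm = tiny_phantom.k_map > 0
    map_a = np.where(wm, 2.5 + 0.1 * rng.standard_normal(tiny_phantom.shape), np.nan)
    map_b = map_a * rng.lognormal(0.0, 0.02, size=tiny_phantom.shape)
    rep1 = repeatability_report(
        map_a, map_b, tiny_phantom.parcels, tiny_phantom.parcel_table, wm
    )
    rep2 = repeatability_report(
        map_a, map_b, tiny_phantom.parcels, tiny_phantom.parcel_table, wm
    )
    assert rep1["cov_percent"] == rep2["cov_percent"]
    assert -1 <= rep1["icc"] <= 1
    assert rep1["rpc"] >= 0
    from reffmap.repeatability import report_to_tsv

    report_to_tsv(rep1, tmp_path / "rep.tsv")
    back = pd.read_csv(tmp_path / "rep.tsv", sep="\t")
    assert back.loc[back.statistic == "rpc", "value"].iloc[0] == pytest.approx(
        rep1["rpc"], rel=1e-12
    )
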