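"""Clonogenic analysis: plating efficiency, surviving fraction, LQ fit,
isoeffect dose and RBE."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from radcell.clonogenic import (
    ColonyRecord,
    LQFit,
    SurvivalPoint,
    dose_at_sf,
    fit_lq,
    fit_lq_from_records,
    plating_efficiency,
    rbe,
    read_colony_csv,
    records_to_frame,
    survival_points_from_records,
    surviving_fraction,
)


def make_record(colonies, seeded=1000, dose=0.0, rep=1, control=None):
    return ColonyRecord(sample_id=f"d{dose}r{rep}", dose_gy=dose,
                        exposure_days=6.0, cells_seeded=seeded,
                        colonies=colonies, replicate=rep,
                        is_control=control if control is not None else dose == 0)


class TestPlatingEfficiency:
    def test_definition(self):
        pe = plating_efficiency([make_record(100, seeded=200)])
        assert pe.mean == 0.5
        assert pe.se is None  # single replicate: undefined, not zero

    def test_replicate_statistics(self):
        recs = [make_record(int(1000 * p), rep=i)
                for i, p in enumerate([0.4, 0.5, 0.6])]
        pe = plating_efficiency(recs)
        assert pe.mean == pytest.approx(0.5)
        assert pe.se == pytest.approx(0.1 / math.sqrt(3), rel=1e-3)  # 0.0577

    def test_zero_colonies(self):
        assert plating_efficiency([make_record(0)]).mean == 0.0

    def test_zero_seeded_rejected(self):
        with pytest.raises(ValueError, match="exceed|zero|seeded"):
            plating_efficiency([make_record(0, seeded=0)])


class TestSurvivingFraction:
    def test_equal_pe_gives_unity(self):
        pe = plating_efficiency([make_record(int(500 * f), rep=i)
                                 for i, f in enumerate([0.9, 1.0, 1.1])])
        assert surviving_fraction(pe, pe).surviving_fraction == pytest.approx(1.0)

    def test_error_propagation(self):
        from radcell.clonogenic import PlatingEfficiency
        pe_t = PlatingEfficiency((0.1,), 0.1, 0.01)
        pe_c = PlatingEfficiency((0.5,), 0.5, 0.02)
        sp = surviving_fraction(pe_t, pe_c, dose_gy=2.0)
        assert sp.surviving_fraction == pytest.approx(0.2)
        # quadrature of relative errors: 0.2 * sqrt(0.1^2 + 0.04^2)
        assert sp.se == pytest.approx(0.2 * math.hypot(0.1, 0.04), rel=1e-9)
        assert sp.se == pytest.approx(0.0215, abs=2e-4)

    def test_zero_control_rejected(self):
        from radcell.clonogenic import PlatingEfficiency
        with pytest.raises(ValueError):
            surviving_fraction(PlatingEfficiency((0.1,), 0.1, None),
                               PlatingEfficiency((0.0,), 0.0, None))


def lq_points(alpha, beta, doses=(0.5, 1, 2, 4), se=0.01):
    pts = [SurvivalPoint(0.0, 1.0, se)]
    for d in doses:
        sf = math.exp(-(alpha * d + beta * d * d))
        pts.append(SurvivalPoint(d, sf, se * sf))
    return pts


def grid_search_oracle(points, alphas, betas):
    """Brute-force weighted SSE minimisation over an (alpha, beta >= 0) grid."""
    best, arg = np.inf, None
    for a in alphas:
        for b in betas:
            sse = sum(((math.log(p.surviving_fraction) + a * p.dose_gy
                        + b * p.dose_gy ** 2) / (p.se / p.surviving_fraction)) ** 2
                      for p in points)
            if sse < best:
                best, arg = sse, (a, b)
    return arg


class TestFitLQ:
    def test_noiseless_exact_recovery(self):
        fit = fit_lq(lq_points(0.5, 0.04))
        assert fit.alpha == pytest.approx(0.5, abs=1e-6)
        assert fit.beta == pytest.approx(0.04, abs=1e-6)
        assert not fit.beta_bound_active

    def test_negative_beta_truth_hits_bound(self):
        fit = fit_lq(lq_points(1.0, -0.02))
        assert fit.beta == 0.0
        assert fit.beta_bound_active
        # grid-search oracle agrees the optimum sits on the boundary
        a, b = grid_search_oracle(lq_points(1.0, -0.02),
                                  np.linspace(0.7, 1.1, 81),
                                  np.linspace(0.0, 0.05, 26))
        assert b == 0.0
        assert fit.alpha == pytest.approx(a, abs=0.01)

    def test_order_invariance(self):
        pts = lq_points(0.5, 0.04)
        f1 = fit_lq(pts)
        f2 = fit_lq(list(reversed(pts)))
        assert f1.alpha == pytest.approx(f2.alpha, rel=1e-12)
        assert f1.beta == pytest.approx(f2.beta, rel=1e-12)

    def test_duplicated_point_with_inflated_se_is_neutral(self, rng):
        # duplicating a point while multiplying its SE by sqrt(2) halves
        # each copy's weight: the fit must not move.  Needs noisy points,
        # otherwise any weighting fits exactly.
        pts = [SurvivalPoint(p.dose_gy,
                             p.surviving_fraction * rng.uniform(0.9, 1.1),
                             p.se)
               for p in lq_points(0.5, 0.04)]
        dup = pts[:-1] + [
            SurvivalPoint(pts[-1].dose_gy, pts[-1].surviving_fraction,
                          pts[-1].se * math.sqrt(2))] * 2
        f1, f2 = fit_lq(pts), fit_lq(dup)
        assert f1.alpha == pytest.approx(f2.alpha, rel=1e-9)
        assert f1.beta == pytest.approx(f2.beta, rel=1e-9)

    def test_all_zero_dose_rejected(self):
        with pytest.raises(ValueError):
            fit_lq([SurvivalPoint(0, 1.0, 0.01), SurvivalPoint(0, 0.9, 0.01)])

    def test_count_based_fit_noise_free(self):
        from radcell.synthetic import ClonogenicSimConfig, simulate_clonogenic
        recs = simulate_clonogenic(ClonogenicSimConfig(alpha=0.5, beta=0.04),
                                   noise_free=True)
        fit = fit_lq_from_records(recs)
        assert fit.alpha == pytest.approx(0.5, abs=1e-5)
        assert fit.beta == pytest.approx(0.04, abs=1e-5)


class TestDoseAtSF:
    def test_linear_closed_form(self):
        assert dose_at_sf((1.0, 0.0), math.exp(-1)) == pytest.approx(1.0)

    @pytest.mark.parametrize("alpha, beta, expected",
                             [(0.12, 0.06, 5.275), (0.5, 0.04, 3.580)])
    def test_against_bisection_oracle(self, alpha, beta, expected):
        def survival(d):
            return math.exp(-(alpha * d + beta * d * d)) - 0.1
        oracle = brentq(survival, 0.0, 100.0, rtol=1e-13)
        got = dose_at_sf((alpha, beta), 0.1)
        assert got == pytest.approx(oracle, rel=1e-9)
        assert got == pytest.approx(expected, abs=5e-3)

    def test_roundtrip_survival(self, rng):
        for _ in range(50):
            alpha = rng.uniform(0.05, 2.0)
            beta = rng.uniform(0.0, 0.3)
            sf = rng.uniform(0.001, 0.99)
            d = dose_at_sf((alpha, beta), sf)
            assert math.exp(-(alpha * d + beta * d * d)) == pytest.approx(
                sf, rel=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(alpha=st.floats(0.01, 3.0), beta=st.floats(0.0, 0.5),
           sf=st.floats(0.001, 0.999))
    def test_isoeffect_dose_is_positive_and_consistent(self, alpha, beta, sf):
        d = dose_at_sf((alpha, beta), sf)
        assert d > 0
        assert math.exp(-(alpha * d + beta * d * d)) == pytest.approx(
            sf, rel=1e-9)

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            dose_at_sf((0.0, 0.0), 0.1)
        with pytest.raises(ValueError):
            dose_at_sf((1.0, 0.0), 1.5)


class TestRBE:
    def test_identical_fits_give_unity(self):
        assert rbe((0.3, 0.02), (0.3, 0.02), 0.1) == pytest.approx(1.0)

    def test_printed_parameters(self):
        # Co-60 reference (alpha 0.12, beta 0.06) vs the 6-day exposure of
        # the osteosarcoma line (alpha 0.5, beta 0.04) at 10% survival
        value = rbe((0.5, 0.04), (0.12, 0.06), 0.1)
        assert value == pytest.approx(1.47, abs=0.005)
        assert value == pytest.approx(1.43, rel=0.05)

    def test_linear_test_curve_scaling(self):
        ref = (0.12, 0.06)
        r1 = rbe((0.4, 0.0), ref, 0.1)
        r2 = rbe((0.8, 0.0), ref, 0.1)
        assert r2 == pytest.approx(2 * r1, rel=1e-9)

    def test_more_effective_radiation_has_rbe_above_one(self, rng):
        for _ in range(20):
            ref = (rng.uniform(0.05, 0.5), rng.uniform(0.0, 0.1))
            scale = rng.uniform(1.1, 3.0)
            test = (ref[0] * scale, ref[1] * scale)
            assert rbe(test, ref, rng.uniform(0.01, 0.5)) > 1.0


class TestColonyIO:
    def test_csv_roundtrip(self, tmp_path):
        from radcell.synthetic import ClonogenicSimConfig, simulate_clonogenic
        recs = simulate_clonogenic(ClonogenicSimConfig(seed=4))
        path = tmp_path / "colonies.csv"
        records_to_frame(recs).to_csv(path, index=False)
        back = read_colony_csv(path)
        assert back == recs

    def test_schema_violation_reports_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        frame = records_to_frame(
            [make_record(100), make_record(50, dose=1.0)])
        frame.loc[1, "colonies"] = 5000  # exceeds seeded
        frame.to_csv(path, index=False)
        with pytest.raises(ValueError, match="row 3"):
            read_colony_csv(path)

    def test_missing_column_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("sample_id,dose_Gy\nx,1\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_colony_csv(path)

    def test_survival_points_grouping(self):
        recs = ([make_record(500, rep=i) for i in range(3)]
                + [make_record(250, dose=2.0, rep=i) for i in range(3)])
        pts = survival_points_from_records(recs)
        assert [p.dose_gy for p in pts] == [0.0, 2.0]
        assert pts[0].surviving_fraction == 1.0
        assert pts[1].surviving_fraction == pytest.approx(0.5)
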