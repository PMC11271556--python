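import numpy as np
import pytest

from mfrkit.kinetics import (
    ExtractionModel,
    RetentionConfig,
    aggregate_territories,
    compute_mfr,
    fit_1cm,
    flow_from_uptake,
    flow_result_from_uptake,
    ret_uptake,
)
from mfrkit.study import aha17_scheme
from mfrkit.synth import gamma_variate_aif, simulate_true_tac

from conftest import make_study


class TestRetUptake:
    def test_pure_spillover_cancels(self, schedule, aif):
        """A segment that is exactly beta times the blood curve retains nothing."""
        tac, *_ = aif
        beta = 0.15
        study = make_study(schedule, tac.values, np.tile(beta * tac.values, (17, 1)))
        r, clipped = ret_uptake(study, RetentionConfig(beta=beta))
        assert np.allclose(r, 0.0, atol=1e-12)
        assert not clipped.any()

    def test_constant_blood_closed_form(self, schedule):
        """beta=0, constant blood c, late myocardial mean h: R = 60 h/(c T0)."""
        c, h = 2.0, 0.5
        blood = np.full(schedule.n_frames, c)
        study = make_study(schedule, blood, np.tile(np.full(23, h), (17, 1)))
        cfg = RetentionConfig(beta=0.0)
        r, _ = ret_uptake(study, cfg)
        t0 = cfg.blood_integral_window[1]
        assert np.allclose(r, 60.0 * h / (c * t0), rtol=1e-12)

    def test_recovers_uptake_on_slow_washout_segment(self, schedule):
        """Noiseless one-compartment segment with f_v = beta and near-zero
        washout: retention approximates K1 up to the (1-beta) spillover
        normalisation and window truncation."""
        beta, k1 = 0.15, 0.9
        _, t, fine = gamma_variate_aif(
            schedule, tail_fraction=0.0, background_level=0.0
        )
        tac_vals = simulate_true_tac(0.0, 0.0, 1.0, t, fine, schedule)
        seg = simulate_true_tac(k1, 0.01, beta, t, fine, schedule)
        study = make_study(schedule, tac_vals, np.tile(seg, (17, 1)))
        r, _ = ret_uptake(study, RetentionConfig(beta=beta))
        assert abs(r[0] / (1.0 - beta) - k1) / k1 < 0.05

    def test_zero_blood_integral_rejected(self, schedule):
        study = make_study(schedule, np.zeros(23), np.ones((17, 23)))
        with pytest.raises(ValueError):
            ret_uptake(study)

    def test_negative_numerator_clipped_and_flagged(self, schedule, aif):
        tac, *_ = aif
        study = make_study(schedule, tac.values, np.zeros((17, 23)))
        r, clipped = ret_uptake(study, RetentionConfig(beta=0.3))
        assert np.all(r == 0.0)
        assert clipped.all()

    def test_global_blood_shift_moves_all_segments_identically(self, schedule, aif):
        """RET applies one global spillover correction, so adding d*C_b to every
        segment shifts every retention value by the same amount."""
        tac, t, fine = aif
        rng = np.random.default_rng(0)
        segs = np.vstack(
            [
                simulate_true_tac(k1, 0.1, 0.25, t, fine, schedule)
                for k1 in rng.uniform(0.3, 1.5, 17)
            ]
        )
        study = make_study(schedule, tac.values, segs)
        shifted = make_study(schedule, tac.values, segs + 0.05 * tac.values)
        r0, _ = ret_uptake(study)
        r1, _ = ret_uptake(shifted)
        shifts = r1 - r0
        assert np.allclose(shifts, shifts[0], atol=1e-9)


class TestFit1cm:
    def test_recovers_noiseless_parameters(self, uniform_study):
        fit = fit_1cm(uniform_study)
        assert abs(fit.k1[0] - 0.8) / 0.8 < 0.005
        assert abs(fit.f_v[0] - 0.3) < 0.01
        assert abs(fit.k2[0] - 0.15) < 0.01
        assert fit.converged.all()

    def test_pure_blood_segment_goes_to_full_spillover(self, schedule, aif):
        tac, *_ = aif
        study = make_study(schedule, tac.values, np.tile(tac.values, (17, 1)))
        fit = fit_1cm(study)
        assert np.all(fit.k1 <= 1e-3)
        assert np.all(fit.f_v >= 1.0 - 1e-3)

    def test_all_zero_segment_gives_exact_zero(self, schedule, aif):
        tac, *_ = aif
        study = make_study(schedule, tac.values, np.zeros((17, 23)))
        fit = fit_1cm(study)
        assert np.all(fit.k1 == 0.0)
        assert np.all(fit.f_v == 0.0)

    def test_scale_invariance(self, schedule, aif):
        """Scaling blood and myocardium together leaves K1, k2, f_v unchanged."""
        tac, t, fine = aif
        seg = simulate_true_tac(1.1, 0.2, 0.2, t, fine, schedule)
        s1 = make_study(schedule, tac.values, np.tile(seg, (17, 1)))
        s2 = make_study(schedule, 7.3 * tac.values, np.tile(7.3 * seg, (17, 1)))
        f1, f2 = fit_1cm(s1), fit_1cm(s2)
        assert np.allclose(f1.k1, f2.k1, rtol=1e-6)
        assert np.allclose(f1.f_v, f2.f_v, atol=1e-6)

    def test_degenerate_blood_rejected(self, schedule):
        study = make_study(schedule, np.ones(23), np.ones((17, 23)))
        with pytest.raises(ValueError):
            fit_1cm(study)

    def test_determinism(self, uniform_study):
        a, b = fit_1cm(uniform_study), fit_1cm(uniform_study)
        assert np.array_equal(a.k1, b.k1)
        assert np.array_equal(a.k2, b.k2)


class TestFlowFromUptake:
    def test_identity_passes_through(self):
        m = ExtractionModel(form="identity")
        assert flow_from_uptake(1.23, m) == 1.23

    @pytest.mark.parametrize("mbf", [0.5, 1.0, 2.0, 3.0])
    def test_renkin_crone_round_trip(self, mbf):
        m = ExtractionModel(ps=1.0)
        uptake = m.uptake_from_flow(mbf)
        assert abs(flow_from_uptake(uptake, m) - mbf) < 1e-6

    def test_zero_uptake_gives_zero_flow(self):
        assert flow_from_uptake(0.0, ExtractionModel(ps=1.0)) == 0.0

    def test_saturated_uptake_returns_upper_bound(self):
        m = ExtractionModel(ps=1.0)
        assert flow_from_uptake(1.5, m) == 10.0  # above the PS=1 supremum

    def test_negative_uptake_rejected(self):
        with pytest.raises(ValueError):
            flow_from_uptake(-0.1, ExtractionModel())


class TestAggregation:
    def test_uniform_field_aggregates_to_itself(self):
        scheme = aha17_scheme()
        out = aggregate_territories(np.ones(17), scheme)
        assert all(np.isclose(v, 1.0) for v in out.values())

    def test_rca_elevation_arithmetic(self):
        scheme = aha17_scheme()
        vals = np.ones(17)
        rca = [i for i, s in enumerate(scheme.segment_ids)
               if scheme.territory_of[s] == "RCA"]
        vals[rca] = 2.0
        out = aggregate_territories(vals, scheme)
        assert np.isclose(out["RCA"], 2.0)
        assert np.isclose(out["TOT"], (5 * 2 + 12 * 1) / 17)

    def test_weights_renormalised_after_exclusion(self):
        scheme = aha17_scheme()
        vals = np.ones(17)
        vals[0] = 100.0
        include = np.ones(17, dtype=bool)
        include[0] = False
        out = aggregate_territories(vals, scheme, include=include)
        assert np.isclose(out["LAD"], 1.0)
        assert np.isclose(out["TOT"], 1.0)


class TestMfr:
    def _flow(self, mbf, scheme, condition):
        return flow_result_from_uptake(
            condition, np.asarray(mbf), scheme, ExtractionModel(form="identity")
        )

    def test_stress_equals_rest_gives_unit_mfr(self):
        scheme = aha17_scheme()
        f = self._flow(np.full(17, 1.3), scheme, "rest")
        g = self._flow(np.full(17, 1.3), scheme, "stress")
        res = compute_mfr(g, f, scheme)
        assert np.all(res.mfr == 1.0)
        assert all(np.isclose(v, 1.0) for v in res.territories.values())

    def test_single_segment_ratio(self):
        scheme = aha17_scheme()
        rest = np.ones(17)
        stress = np.ones(17)
        stress[3] = 2.0
        res = compute_mfr(
            self._flow(stress, scheme, "stress"),
            self._flow(rest, scheme, "rest"),
            scheme,
        )
        assert res.mfr[3] == 2.0

    def test_uniform_mfr_independent_of_weights(self):
        """A constant stress/rest ratio aggregates to itself whatever the
        mass weights are."""
        w = np.linspace(1, 3, 17)
        weights = {f"seg{i + 1:02d}": float(x / w.sum()) for i, x in enumerate(w)}
        scheme = aha17_scheme(weights=weights)
        res = compute_mfr(
            self._flow(np.full(17, 1.8), scheme, "stress"),
            self._flow(np.full(17, 0.9), scheme, "rest"),
            scheme,
        )
        assert all(np.isclose(v, 2.0) for v in res.territories.values())

    def test_near_zero_rest_segment_excluded(self):
        scheme = aha17_scheme()
        rest = np.ones(17)
        rest[5] = 0.01  # below the reliability threshold
        stress = np.full(17, 2.0)
        res = compute_mfr(
            self._flow(stress, scheme, "stress"),
            self._flow(rest, scheme, "rest"),
            scheme,
        )
        assert res.excluded[5]
        assert np.isnan(res.mfr[5])
        assert np.isclose(res.territories["TOT"], 2.0)

    def test_all_excluded_rejected(self):
        scheme = aha17_scheme()
        with pytest.raises(ValueError):
            compute_mfr(
                self._flow(np.ones(17), scheme, "stress"),
                self._flow(np.zeros(17), scheme, "rest"),
                scheme,
            )


class TestKnownTruthRecovery:
    def test_both_models_recover_mfr_on_clean_studies(self, schedule):
        """Noiseless, unperturbed stress/rest pair, identity extraction:
        both models' TOT MFR matches the true flow ratio within 5%."""
        scheme = aha17_scheme()
        identity = ExtractionModel(form="identity")
        _, t, fine = gamma_variate_aif(schedule)
        tac_vals = simulate_true_tac(0.0, 0.0, 1.0, t, fine, schedule)
        rng = np.random.default_rng(12)
        rest_k1 = rng.uniform(0.5, 0.9, 17)
        true_ratio = 1.9
        k2, f_v = 0.05, 0.25
        flows = {}
        for cond, k1s in (("rest", rest_k1), ("stress", rest_k1 * true_ratio)):
            segs = np.vstack(
                [simulate_true_tac(k, k2, f_v, t, fine, schedule) for k in k1s]
            )
            study = make_study(schedule, tac_vals, segs, condition=cond)
            ret_r, _ = ret_uptake(study, RetentionConfig(beta=f_v))
            cm = fit_1cm(study)
            flows[("RET", cond)] = flow_result_from_uptake(
                cond, ret_r, scheme, identity
            )
            flows[("1CM", cond)] = flow_result_from_uptake(
                cond, cm.k1, scheme, identity
            )
        for model in ("RET", "1CM"):
            mfr = compute_mfr(flows[(model, "stress")], flows[(model, "rest")], scheme)
            assert abs(mfr.territories["TOT"] - true_ratio) / true_ratio < 0.05
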