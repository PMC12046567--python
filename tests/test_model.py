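"""Design construction, REML estimation, elimination and prediction."""

import numpy as np
import pandas as pd
import pytest

from sleepart.model import (
    backward_eliminate,
    build_design,
    design_row,
    eligible_terms,
    fit_mixed_spline,
    predict_typical,
    term_blockers,
)
from sleepart.synthetic import (
    SimConfig,
    TrajectoryParams,
    generate_cohort,
    simulate_feature_outcomes,
)


def _simple_pathways():
    return pd.DataFrame(
        {
            "subject": ["n1", "m1", "d1"],
            "pathway": ["normal", "stableMCI", "dementia"],
            "mci_onset_age": [np.nan, 84.0, 86.0],
            "dementia_onset_age": [np.nan, np.nan, 90.0],
        }
    )


class TestBuildDesign:
    def _outcomes(self, rows):
        return pd.DataFrame(rows, columns=["subject", "age", "outcome"])

    def test_knot_columns_zero_for_normal_path(self):
        d = build_design(
            self._outcomes([("n1", 80.0, 1.0), ("n1", 95.0, 1.0)]),
            _simple_pathways(),
        )
        assert (d.X["knot_mci"] == 0).all() and (d.X["knot_dem"] == 0).all()

    def test_knot_zero_before_onset(self):
        d = build_design(
            self._outcomes([("d1", 85.0, 1.0)]), _simple_pathways()
        )
        assert d.X["knot_mci"].iloc[0] == 0.0

    def test_knot_cubic_after_onset(self):
        d = build_design(
            self._outcomes([("d1", 90.0, 1.0)]), _simple_pathways()
        )
        assert d.X["knot_mci"].iloc[0] == pytest.approx((90 - 86) ** 3)
        assert d.X["knot_dem"].iloc[0] == 0.0  # exactly at the dementia knot

    def test_dementia_without_onset_rejected(self):
        p = _simple_pathways()
        p.loc[p.subject == "d1", "dementia_onset_age"] = np.nan
        with pytest.raises(ValueError):
            build_design(self._outcomes([("d1", 90.0, 1.0)]), p)

    def test_covariates_centred(self):
        cov = pd.DataFrame({"subject": ["n1", "m1", "d1"], "edu": [12.0, 16.0, 14.0]})
        d = build_design(
            self._outcomes([("n1", 80.0, 1.0), ("m1", 85.0, 2.0), ("d1", 91.0, 3.0)]),
            _simple_pathways(),
            covariates=cov,
        )
        assert d.X["edu"].mean() == pytest.approx(0.0, abs=1e-12)
        assert "edu" in d.covariate_cols


class TestFitMixedSpline:
    def test_noise_free_interpolation(self, small_cohort):
        visits, truth = small_cohort
        coefs = {"const": 3.0, "age": -0.1, "age2": 0.01, "path[dementia]": -0.5,
                 "knot_dem": -0.003}
        tp = TrajectoryParams(coefficients=coefs, resid_var=0.0)
        out = simulate_feature_outcomes(visits, truth, tp, seed=1)
        m = fit_mixed_spline(build_design(out, truth))
        for name, val in coefs.items():
            assert m.params[name] == pytest.approx(val, abs=1e-8)

    def test_matches_wls_oracle_without_random_effects(self, small_cohort):
        """Zero random-effect truth with weights: beta within 3 SE of the
        closed-form weighted-least-squares solution (and near-equal)."""
        rng = np.random.default_rng(3)
        visits, truth = small_cohort
        tp = TrajectoryParams(coefficients={"const": 5.0, "age": -0.05}, resid_var=0.3)
        out = simulate_feature_outcomes(visits, truth, tp, seed=5)
        out["w"] = rng.integers(5, 11, size=len(out)).astype(float)
        design = build_design(out, truth, weight_col="w")
        m = fit_mixed_spline(design)
        X, y, w = design.X.to_numpy(), design.y, design.weights
        beta_wls = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
        assert np.abs(m.params.to_numpy() - beta_wls).max() < 3 * m.bse.max()

    def test_cross_check_against_statsmodels_reml(self, small_cohort):
        """Independent oracle: statsmodels MixedLM, equal weights."""
        import statsmodels.api as sm

        visits, truth = small_cohort
        tp = TrajectoryParams(
            coefficients={"const": 7.0, "age": -0.03, "path[dementia]": -0.4},
            re_cov=np.array([[0.5, 0.04], [0.04, 0.02]]),
            resid_var=0.4,
        )
        out = simulate_feature_outcomes(visits, truth, tp, seed=8)
        design = build_design(out, truth)
        mine = fit_mixed_spline(design)
        exog_re = np.column_stack([np.ones(len(out)), design.age_c])
        ref = sm.MixedLM(
            design.y, design.X.to_numpy(), groups=design.subject, exog_re=exog_re
        ).fit(reml=True)
        assert np.abs(mine.params.to_numpy() - ref.fe_params).max() < 1e-4
        assert mine.loglik_reml == pytest.approx(ref.llf, abs=1e-4)
        assert mine.var_resid == pytest.approx(ref.scale, rel=1e-3)

    def test_weight_invariance(self, small_cohort):
        visits, truth = small_cohort
        tp = TrajectoryParams(
            coefficients={"const": 7.0, "age": -0.03},
            re_cov=np.array([[0.3, 0.0], [0.0, 0.01]]),
            resid_var=0.4,
        )
        out = simulate_feature_outcomes(visits, truth, tp, seed=9)
        out["w"] = np.tile([5.0, 7.0, 9.0, 6.0], len(out))[: len(out)]
        d1 = build_design(out, truth, weight_col="w")
        out2 = out.copy()
        out2["w"] = out2["w"] * 13.0
        d2 = build_design(out2, truth, weight_col="w")
        m1, m2 = fit_mixed_spline(d1), fit_mixed_spline(d2)
        assert np.allclose(m1.params, m2.params, atol=1e-8)
        assert m1.var_resid == pytest.approx(m2.var_resid, rel=1e-6)

    def test_rank_deficient_rejected(self, small_cohort):
        visits, truth = small_cohort
        out = simulate_feature_outcomes(
            visits, truth, TrajectoryParams(coefficients={"const": 1.0}), seed=0
        )
        design = build_design(out, truth)
        design.X["dup"] = design.X["age"]
        with pytest.raises(ValueError):
            fit_mixed_spline(design)


class TestBackwardElimination:
    def test_hierarchy_blockers(self):
        cols = ["const", "age", "age2", "age3", "age3:path[dementia]",
                "age:path[dementia]", "knot_mci"]
        assert "age3:path[dementia]" in term_blockers("age3", cols)
        assert term_blockers("age3:path[dementia]", cols) == []
        assert "age3" in term_blockers("age2", cols)
        assert term_blockers("knot_mci", cols) == []
        assert "const" not in eligible_terms(cols)
        assert "knot_mci" in eligible_terms(cols)

    def test_interaction_removed_before_main(self, small_cohort):
        """With a null cubic, the age3 x pathway interactions must leave the
        model before age3 itself is ever a candidate."""
        visits, truth = small_cohort
        tp = TrajectoryParams(
            coefficients={"const": 5.0, "age": -0.1},
            re_cov=np.array([[0.2, 0.0], [0.0, 0.005]]),
            resid_var=0.3,
        )
        out = simulate_feature_outcomes(visits, truth, tp, seed=13)
        design = build_design(out, truth)
        m, _ = backward_eliminate(fit_mixed_spline(design), design)
        order = list(m.eliminated)
        if "age3" in order:
            for inter in ("age3:path[stableMCI]", "age3:path[dementia]"):
                assert order.index(inter) < order.index("age3")

    def test_all_significant_model_unchanged(self, small_cohort):
        visits, truth = small_cohort
        out = simulate_feature_outcomes(
            visits, truth, TrajectoryParams(coefficients={"const": 5.0}), seed=2
        )
        design = build_design(out, truth)
        m0 = fit_mixed_spline(design)
        m1, d1 = backward_eliminate(m0, design, alpha=1.0 + 1e-9)
        assert m1.eliminated == ()
        assert list(d1.columns) == list(design.columns)


class TestPredictTypical:
    def _known_model(self, coefs):
        visits, truth = generate_cohort(SimConfig(n_subjects=120, seed=31))
        tp = TrajectoryParams(coefficients=coefs, resid_var=0.0)
        out = simulate_feature_outcomes(visits, truth, tp, seed=1)
        return fit_mixed_spline(build_design(out, truth))

    def test_polynomial_evaluation(self):
        coefs = {"const": 2.0, "age": 0.5, "age2": -0.02, "age3": 0.001}
        m = self._known_model(coefs)
        a = 94.0 - 82.0
        expected = 2.0 + 0.5 * a - 0.02 * a**2 + 0.001 * a**3
        pred, se = predict_typical(m, "normal", 94.0)
        assert pred == pytest.approx(expected, abs=1e-6)

    def test_continuity_at_knot(self):
        # only knot terms, so any step across the knot is a discontinuity
        coefs = {"const": 2.0, "knot_mci": -0.05, "knot_dem": 0.02}
        m = self._known_model(coefs)
        sched = (86.0, 90.0)
        below, _ = predict_typical(m, "dementia", 86.0 - 1e-6, sched)
        at, _ = predict_typical(m, "dementia", 86.0, sched)
        assert abs(at - below) < 1e-9

    def test_c2_continuity_at_knots(self):
        """Second differences of the predicted trajectory stay smooth across
        the knots (truncated cubic basis is C2)."""
        coefs = {"const": 1.0, "age": 0.2, "age2": -0.01, "knot_mci": -0.03,
                 "knot_dem": 0.04}
        m = self._known_model(coefs)
        sched = (86.0, 90.0)
        h = 1e-3
        for knot in sched:
            f = [
                predict_typical(m, "dementia", knot + k * h, sched)[0]
                for k in (-2, -1, 0, 1, 2)
            ]
            d2_left = (f[0] - 2 * f[1] + f[2]) / h**2
            d2_right = (f[2] - 2 * f[3] + f[4]) / h**2
            assert abs(d2_left - d2_right) < 1e-3

    def test_schedule_validation(self):
        m = self._known_model({"const": 1.0})
        with pytest.raises(ValueError):
            predict_typical(m, "normal", 90.0, (86.0, 90.0))

    def test_intercept_only_prediction(self):
        m = self._known_model({"const": 4.2})
        for pathway, sched in (
            ("normal", (None, None)),
            ("stableMCI", (86.0, None)),
            ("dementia", (86.0, 90.0)),
        ):
            pred, se = predict_typical(m, pathway, 88.0, sched)
            assert pred == pytest.approx(4.2, abs=1e-6)

    def test_json_round_trip(self, tmp_path):
        m = self._known_model({"const": 1.5, "age": 0.1})
        path = tmp_path / "model.json"
        m.to_json(path)
        from sleepart.model import FittedTrajectoryModel

        back = FittedTrajectoryModel.from_json(path)
        assert np.allclose(back.params, m.params)
        assert np.allclose(back.cov_params, m.cov_params)
        assert back.center_age == m.center_age
        p1, s1 = predict_typical(back, "dementia", 93.0, (86.0, 90.0))
        p2, s2 = predict_typical(m, "dementia", 93.0, (86.0, 90.0))
        assert (p1, s1) == (p2, s2)
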