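"""Standardized contrasts, BH adjustment, effect labels, and the grid."""

import numpy as np
import pandas as pd
import pytest

from sleepart import contrasts as con
from sleepart.contrasts import (
    ALL_BENCHMARK_SETS,
    PRIMARY_BENCHMARK_SET,
    BenchmarkSet,
    adjust_bh,
    between_pathway_difference,
    label_effect_size,
    run_benchmark_grid,
    within_pathway_change,
)
from sleepart.model import build_design, fit_mixed_spline, predict_typical
from sleepart.synthetic import (
    SimConfig,
    TrajectoryParams,
    generate_cohort,
    simulate_feature_outcomes,
)


@pytest.fixture(scope="module")
def known_model():
    """Deterministic fit of a known-coefficient trajectory model."""
    visits, truth = generate_cohort(SimConfig(n_subjects=150, seed=77))
    coefs = {
        "const": 5.0,
        "age": -0.06,
        "age2": 0.003,
        "path[dementia]": -0.3,
        "age:path[dementia]": -0.02,
        "knot_mci": -0.002,
        "knot_dem": -0.004,
    }
    tp = TrajectoryParams(
        coefficients=coefs,
        re_cov=np.array([[0.25, 0.0], [0.0, 0.0]]),
        resid_var=0.75,
    )
    out = simulate_feature_outcomes(visits, truth, tp, seed=1)
    return fit_mixed_spline(build_design(out, truth)), coefs


@pytest.fixture(scope="module")
def intercept_only_model():
    """A model whose only fixed effect is the intercept."""
    visits, truth = generate_cohort(SimConfig(n_subjects=100, seed=78))
    tp = TrajectoryParams(
        coefficients={"const": 3.0},
        re_cov=np.array([[0.3, 0.0], [0.0, 0.001]]),
        resid_var=0.4,
    )
    out = simulate_feature_outcomes(visits, truth, tp, seed=2)
    design = build_design(out, truth)
    for col in list(design.columns):
        if col != "const":
            design = design.drop_term(col)
    return fit_mixed_spline(design)


class TestBenchmarkSets:
    def test_named_sets(self):
        ages = {s.name: s.ages for s in ALL_BENCHMARK_SETS}
        assert ages["primary"] == (82, 86, 90, 94)
        assert (80, 84, 88, 92) in ages.values()
        assert (84, 88, 92, 96) in ages.values()
        assert (82, 85, 88, 91) in ages.values()
        assert (80, 86, 90, 94) in ages.values()

    def test_schedules(self):
        s = PRIMARY_BENCHMARK_SET
        assert s.schedule("normal") == (None, None)
        assert s.schedule("stableMCI") == (86.0, None)
        assert s.schedule("dementia") == (86.0, 90.0)

    def test_segments(self):
        assert PRIMARY_BENCHMARK_SET.segments() == [
            (82.0, 86.0), (86.1, 90.0), (90.1, 94.0)
        ]

    def test_non_increasing_rejected(self):
        with pytest.raises(ValueError):
            BenchmarkSet("bad", (82.0, 82.0, 90.0, 94.0))


class TestEffectLabels:
    @pytest.mark.parametrize(
        "d,label",
        [
            (0.917, "large"),       # printed as a large increase
            (0.698, "moderate"),
            (0.222, "small"),
            (-0.3, "small"),        # absolute-value rule
            (0.19, "very small"),
            (-0.85, "large"),
            (0.5, "moderate"),
            (0.8, "large"),
        ],
    )
    def test_taxonomy(self, d, label):
        assert label_effect_size(d) == label


class TestWithinChange:
    def test_zero_span_zero_d(self, known_model):
        m, _ = known_model
        r = within_pathway_change(m, "normal", PRIMARY_BENCHMARK_SET,
                                  from_age=86.0, to_age=86.0, sigma=1.0)
        assert r.d == 0.0
        assert r.ci[0] <= 0.0 <= r.ci[1]

    def test_intercept_only_all_zero(self, intercept_only_model):
        for p in ("normal", "stableMCI", "dementia"):
            r = within_pathway_change(intercept_only_model, p, PRIMARY_BENCHMARK_SET)
            assert abs(r.d) < 1e-6
            assert r.label == "very small"

    def test_matches_hand_computed_difference(self, known_model):
        m, _ = known_model
        sched = PRIMARY_BENCHMARK_SET.schedule("dementia")
        p94, _ = predict_typical(m, "dementia", 94.0, sched)
        p82, _ = predict_typical(m, "dementia", 82.0, sched)
        r = within_pathway_change(m, "dementia", PRIMARY_BENCHMARK_SET, sigma=1.0)
        assert r.d == pytest.approx(p94 - p82, abs=1e-10)

    def test_segment_additivity_with_abutting_boundaries(self, known_model):
        m, _ = known_model
        bset = PRIMARY_BENCHMARK_SET
        total = within_pathway_change(m, "dementia", bset, sigma=1.0).d
        parts = sum(
            within_pathway_change(m, "dementia", bset, from_age=lo, to_age=hi,
                                  sigma=1.0).d
            for lo, hi in bset.segments(offset=0.0)
        )
        assert parts == pytest.approx(total, abs=1e-12)


class TestBetweenDifference:
    def test_antisymmetry_exact(self, known_model):
        m, _ = known_model
        r1 = between_pathway_difference(m, "dementia", "normal", 94.0,
                                        PRIMARY_BENCHMARK_SET, sigma=1.0)
        r2 = between_pathway_difference(m, "normal", "dementia", 94.0,
                                        PRIMARY_BENCHMARK_SET, sigma=1.0)
        assert r1.d == -r2.d
        assert r1.se == r2.se

    def test_identical_pathway_rejected(self, known_model):
        m, _ = known_model
        with pytest.raises(ValueError):
            between_pathway_difference(m, "normal", "normal", 82.0,
                                       PRIMARY_BENCHMARK_SET)

    def test_zero_before_onset_without_pathway_effects(self):
        """At the first benchmark age all knots are inactive; with no pathway
        main effects or interactions in truth, the pathways coincide."""
        visits, truth = generate_cohort(SimConfig(n_subjects=150, seed=79))
        tp = TrajectoryParams(
            coefficients={"const": 5.0, "age": -0.06, "knot_dem": -0.004},
            resid_var=0.0,
        )
        out = simulate_feature_outcomes(visits, truth, tp, seed=3)
        m = fit_mixed_spline(build_design(out, truth))
        # force pathway terms to their (noise-free) zero estimates
        r = between_pathway_difference(m, "dementia", "normal", 82.0,
                                       PRIMARY_BENCHMARK_SET, sigma=1.0)
        assert abs(r.d) < 1e-6


class TestBenjaminiHochberg:
    def _results(self, ps, **meta):
        return [
            con.ContrastResult(kind="within-change", pathways=("normal",),
                               ages=(82.0, 94.0), d=0.1, se=0.05, p=p, **meta)
            for p in ps
        ]

    def test_single_p_unchanged(self):
        (r,) = adjust_bh(self._results([0.03]))
        assert r.p_adj == pytest.approx(0.03)

    def test_step_up_hand_computation(self):
        adj = [r.p_adj for r in adjust_bh(self._results([0.01, 0.02, 0.04]))]
        assert adj == pytest.approx([0.03, 0.03, 0.04])

    def test_large_ps_not_significant(self):
        adj = [r.p_adj for r in adjust_bh(self._results([0.6, 0.7]))]
        assert all(a >= 0.6 for a in adj)

    def test_grouping_by_domain(self):
        rs = self._results([0.01, 0.02], domain="amount", aim="1") + self._results(
            [0.03], domain="timing", aim="1"
        )
        adj = adjust_bh(rs)
        assert adj[2].p_adj == pytest.approx(0.03)  # alone in its family
        assert adj[0].p_adj == pytest.approx(0.02)

    def test_never_more_discoveries_than_unadjusted(self):
        rng = np.random.default_rng(5)
        ps = list(rng.uniform(0, 1, 20))
        adj = adjust_bh(self._results(ps))
        assert sum(r.p_adj < 0.05 for r in adj) <= sum(p < 0.05 for p in ps)

    def test_adjusted_monotone_in_raw(self):
        rng = np.random.default_rng(6)
        ps = list(rng.uniform(0, 1, 15))
        adj = adjust_bh(self._results(ps))
        order = np.argsort(ps)
        padj = np.array([r.p_adj for r in adj])[order]
        assert (np.diff(padj) >= -1e-12).all()


class TestBenchmarkGrid:
    def test_intercept_only_grid_all_null(self, intercept_only_model):
        frame = run_benchmark_grid(
            {"alpha": (intercept_only_model, "amount")},
            benchmark_sets=(PRIMARY_BENCHMARK_SET,),
        )
        assert (frame["label"] == "very small").all()
        assert frame["d"].abs().max() < 1e-6

    def test_primary_set_combinatorics(self, known_model):
        m, _ = known_model
        frame = run_benchmark_grid(
            {"alpha": (m, "amount")}, benchmark_sets=(PRIMARY_BENCHMARK_SET,)
        )
        assert (frame["aim"] == "1").sum() == 3  # overall change per pathway
        assert (frame["aim"] == "2a").sum() == 3  # pairs at first age
        assert (frame["aim"] == "2b").sum() == 3  # pairs at last age
        assert (frame["aim"] == "1-segments").sum() == 9
        assert frame["p_adj"].notna().all()

    def test_full_grid_covers_all_sets(self, known_model):
        m, _ = known_model
        frame = run_benchmark_grid({"alpha": (m, "amount"), "IS": (m, "regularity")})
        assert set(frame["set"]) == {s.name for s in ALL_BENCHMARK_SETS}
        assert set(frame["feature"]) == {"alpha", "IS"}
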