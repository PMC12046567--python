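"""Standardized benchmark-age contrasts on fitted trajectory models.

Fitted spline models predict each sleep/rhythm outcome for a "typical"
(average-covariate) subject of each cognitive pathway at four benchmark ages
under an assumed diagnosis schedule: the normal pathway stays unimpaired
throughout; the stable-MCI pathway develops MCI at the second benchmark age;
the dementia pathway develops MCI at the second and dementia at the third.
Within-pathway change from the first to the last benchmark age (Aim 1),
between-pathway differences at the first and last ages (Aims 2a/2b), and
segment changes are standardized as d = (difference) / sigma_std and labelled
very small / small / moderate / large at |d| = 0.2 / 0.5 / 0.8.  P-values are
Benjamini-Hochberg adjusted within each (aim, domain) family, domain being
amount, regularity or timing.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .model import FittedTrajectoryModel, design_row

DOMAINS = ("amount", "regularity", "timing")
#: Offset between abutting segments, as in schedules like "MCI from 86.1".
SEGMENT_OFFSET_YR = 0.1


@dataclass(frozen=True)
class BenchmarkSet:
    """Four ordered benchmark ages plus the implied diagnosis schedules."""

    name: str
    ages: tuple[float, float, float, float]

    def __post_init__(self) -> None:
        if len(self.ages) != 4 or any(
            b <= a for a, b in zip(self.ages, self.ages[1:])
        ):
            raise ValueError("benchmark ages must be four strictly increasing values")

    def schedule(self, pathway: str) -> tuple[float | None, float | None]:
        """(MCI onset, dementia onset) assumed for ``pathway`` in this set."""
        if pathway == "normal":
            return (None, None)
        if pathway == "stableMCI":
            return (self.ages[1], None)
        if pathway == "dementia":
            return (self.ages[1], self.ages[2])
        raise ValueError(f"unknown pathway: {pathway!r}")

    def segments(self, offset: float = SEGMENT_OFFSET_YR) -> list[tuple[float, float]]:
        """Key age segments: normal, post-MCI, post-dementia eras."""
        a0, a1, a2, a3 = self.ages
        return [(a0, a1), (a1 + offset, a2), (a2 + offset, a3)]


PRIMARY_BENCHMARK_SET = BenchmarkSet("primary", (82.0, 86.0, 90.0, 94.0))
SENSITIVITY_BENCHMARK_SETS = (
    BenchmarkSet("shift-2yr-earlier", (80.0, 84.0, 88.0, 92.0)),
    BenchmarkSet("shift-2yr-later", (84.0, 88.0, 92.0, 96.0)),
    BenchmarkSet("3yr-intervals", (82.0, 85.0, 88.0, 91.0)),
    BenchmarkSet("longer-normal", (80.0, 86.0, 90.0, 94.0)),
)
ALL_BENCHMARK_SETS = (PRIMARY_BENCHMARK_SET,) + SENSITIVITY_BENCHMARK_SETS


def label_effect_size(d: float) -> str:
    """Effect-size taxonomy on |d|: 0.2 / 0.5 / 0.8 cut points."""
    m = abs(float(d))
    if not np.isfinite(m):
        raise ValueError("effect size must be finite")
    if m < 0.2:
        return "very small"
    if m < 0.5:
        return "small"
    if m < 0.8:
        return "moderate"
    return "large"


@dataclass(frozen=True)
class ContrastResult:
    """A single standardized contrast with its uncertainty and metadata."""

    kind: str  # "within-change" | "between-difference" | "segment-change"
    pathways: tuple[str, ...]
    ages: tuple[float, ...]
    d: float
    se: float
    p: float
    domain: str | None = None
    feature: str | None = None
    aim: str | None = None
    set_name: str | None = None
    p_adj: float | None = None

    @property
    def ci(self) -> tuple[float, float]:
        half = 1.959963984540054 * self.se
        return (self.d - half, self.d + half)

    @property
    def label(self) -> str:
        return label_effect_size(self.d)


def sigma_std(model: FittedTrajectoryModel, method: str = "intercept+resid") -> float:
    """Standardizer for d: the model-based SD of a single observation.

    ``"intercept+resid"`` (default) is sqrt(intercept variance + residual
    variance) — the marginal SD of one observation for an average-age
    subject; ``"resid"`` uses the residual SD only.
    """
    if method == "intercept+resid":
        out = float(np.sqrt(model.var_intercept + model.var_resid))
    elif method == "resid":
        out = float(np.sqrt(model.var_resid))
    else:
        raise ValueError(f"unknown standardizer: {method!r}")
    if out <= 0:
        raise ValueError(
            "degenerate model: zero variance leaves d undefined; pass sigma"
        )
    return out


def _contrast_from_rows(
    model: FittedTrajectoryModel, dx: np.ndarray, sigma: float
) -> tuple[float, float, float]:
    diff = float(dx @ model.params.to_numpy())
    se_raw = float(np.sqrt(max(dx @ model.cov_params.to_numpy() @ dx, 0.0)))
    d = diff / sigma
    se = se_raw / sigma
    if se > 0:
        p = float(2.0 * stats.norm.sf(abs(diff) / se_raw))
    else:
        p = 1.0 if diff == 0 else 0.0
    return d, se, p


def within_pathway_change(
    model: FittedTrajectoryModel,
    pathway: str,
    benchmark_set: BenchmarkSet,
    from_age: float | None = None,
    to_age: float | None = None,
    sigma: float | None = None,
    kind: str = "within-change",
) -> ContrastResult:
    """Standardized mean change along one pathway between two benchmark ages.

    Defaults to the first-to-last benchmark span.  Both endpoints are
    evaluated under the set's diagnosis schedule for this pathway.
    """
    if from_age is None:
        from_age = benchmark_set.ages[0]
    if to_age is None:
        to_age = benchmark_set.ages[-1]
    sched = benchmark_set.schedule(pathway)
    dx = design_row(model, pathway, to_age, sched) - design_row(
        model, pathway, from_age, sched
    )
    d, se, p = _contrast_from_rows(model, dx, sigma or sigma_std(model))
    return ContrastResult(
        kind=kind,
        pathways=(pathway,),
        ages=(from_age, to_age),
        d=d,
        se=se,
        p=p,
        set_name=benchmark_set.name,
    )


def between_pathway_difference(
    model: FittedTrajectoryModel,
    pathway_a: str,
    pathway_b: str,
    age: float,
    benchmark_set: BenchmarkSet,
    sigma: float | None = None,
) -> ContrastResult:
    """Standardized difference (A - B) between two pathways at one age."""
    if pathway_a == pathway_b:
        raise ValueError("between-pathway contrast needs two distinct pathways")
    dx = design_row(
        model, pathway_a, age, benchmark_set.schedule(pathway_a)
    ) - design_row(model, pathway_b, age, benchmark_set.schedule(pathway_b))
    d, se, p = _contrast_from_rows(model, dx, sigma or sigma_std(model))
    return ContrastResult(
        kind="between-difference",
        pathways=(pathway_a, pathway_b),
        ages=(age,),
        d=d,
        se=se,
        p=p,
        set_name=benchmark_set.name,
    )


def adjust_bh(
    results: Sequence[ContrastResult],
    group_keys: tuple[str, ...] = ("aim", "domain", "set_name"),
) -> list[ContrastResult]:
    """Benjamini-Hochberg step-up within each group of contrasts.

    Groups are formed on the given metadata attributes (``None`` values form
    their own group); adjusted p-values are monotone in the raw p-values
    within a group.
    """
    results = list(results)
    groups: dict[tuple, list[int]] = {}
    for i, r in enumerate(results):
        key = tuple(getattr(r, k) for k in group_keys)
        groups.setdefault(key, []).append(i)
    out = list(results)
    for idx in groups.values():
        raw = [results[i].p for i in idx]
        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        for i, a in zip(idx, adj):
            out[i] = replace(results[i], p_adj=float(a))
    return out


PATHWAY_PAIRS = (
    ("stableMCI", "normal"),
    ("dementia", "normal"),
    ("dementia", "stableMCI"),
)


def run_benchmark_grid(
    models: Mapping[str, tuple[FittedTrajectoryModel, str]],
    benchmark_sets: Iterable[BenchmarkSet] = ALL_BENCHMARK_SETS,
    segment_offset: float = SEGMENT_OFFSET_YR,
    segment_threshold: float | None = None,
    standardizer: str = "intercept+resid",
) -> pd.DataFrame:
    """Full contrast grid over features and benchmark sets, BH-adjusted.

    ``models`` maps feature name -> (fitted model, domain).  Per feature and
    set: overall within-pathway changes for each pathway (aim 1), segment
    changes (aim 1-segments; restricted to features whose overall |d| meets
    ``segment_threshold`` when given), and between-pathway differences at the
    first (aim 2a) and last (aim 2b) benchmark ages.  BH runs within each
    (aim, domain, set) family.  Returns a long-format table.
    """
    results: list[ContrastResult] = []
    for feature, (model, domain) in models.items():
        if domain not in DOMAINS:
            raise ValueError(f"unknown domain {domain!r} for feature {feature!r}")
        sigma = sigma_std(model, standardizer)
        for bset in benchmark_sets:
            overall = {}
            for pathway in ("normal", "stableMCI", "dementia"):
                r = within_pathway_change(model, pathway, bset, sigma=sigma)
                r = replace(r, feature=feature, domain=domain, aim="1")
                overall[pathway] = r
                results.append(r)
            do_segments = segment_threshold is None or any(
                abs(r.d) >= segment_threshold for r in overall.values()
            )
            if do_segments:
                for pathway in ("normal", "stableMCI", "dementia"):
                    for lo, hi in bset.segments(segment_offset):
                        r = within_pathway_change(
                            model, pathway, bset, from_age=lo, to_age=hi,
                            sigma=sigma, kind="segment-change",
                        )
                        results.append(
                            replace(r, feature=feature, domain=domain, aim="1-segments")
                        )
            for pa, pb in PATHWAY_PAIRS:
                for aim, age in (("2a", bset.ages[0]), ("2b", bset.ages[-1])):
                    r = between_pathway_difference(model, pa, pb, age, bset, sigma=sigma)
                    results.append(replace(r, feature=feature, domain=domain, aim=aim))
    results = adjust_bh(results)
    return results_to_frame(results)


def results_to_frame(results: Sequence[ContrastResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        lo, hi = r.ci
        rows.append(
            {
                "feature": r.feature,
                "domain": r.domain,
                "set": r.set_name,
                "aim": r.aim,
                "kind": r.kind,
                "pathway_a": r.pathways[0],
                "pathway_b": r.pathways[1] if len(r.pathways) > 1 else None,
                "from_age": r.ages[0] if len(r.ages) > 1 else None,
                "to_age": r.ages[1] if len(r.ages) > 1 else None,
                "age": r.ages[0] if len(r.ages) == 1 else None,
                "d": r.d,
                "ci_lo": lo,
                "ci_hi": hi,
                "p": r.p,
                "p_adj": r.p_adj,
                "label": r.label,
            }
        )
    return pd.DataFrame(rows)


def format_effects_table(frame: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Compact presentation table: d (95% CI) with label and direction arrow."""
    def fmt(row) -> str:
        arrow = "-" if abs(row.d) < 0.2 else ("up" if row.d > 0 else "down")
        star = "*" if row.p_adj is not None and row.p_adj < alpha else ""
        return (
            f"{row.d:.3f} ({row.ci_lo:.3f}, {row.ci_hi:.3f}) "
            f"[{row.label} {arrow}]{star}"
        )

    out = frame.copy()
    out["summary"] = [fmt(r) for r in frame.itertuples()]
    return out
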