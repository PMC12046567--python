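"""Seeded synthetic cohorts at two fidelity levels.

A feature-level generator draws longitudinal sleep/rhythm outcomes from a
*known* trajectory model over a simulated cohort (pathway mixture, onset
ages, annual visit cadence with dropout), which is what estimator tests
need; an epoch-level generator produces 15 s wrist-actigraphy counts from an
extended-cosine mean curve with an embedded sleep window and nonwear
insertions, which is what the feature extractors need.  Every function is a
pure function of (inputs, seed).

Defaults emulate the structure of a community cognitive-aging cohort of
adults aged 65+: pathway mixture 59% normal / 13% stable MCI / 28% dementia,
entry age 81 (SD 7, minimum 65), annual visits with ~1 yr spacing truncated
by a per-year dropout hazard giving ~4 visits on average, MCI onset ~N(85.7,
6.05) and dementia onset ~N(88.2, 6.7) snapped to the realized visit grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EpochSeries
from .model import CENTER_AGE, build_design
from .pathways import PathwayLabel

CovariateSpec = tuple[str, str, object]  # (name, kind, params)

DEFAULT_COVARIATES: tuple[CovariateSpec, ...] = (
    ("sex_female", "binary", 0.75),
    ("education_yr", "normal", (15.3, 3.05)),
    ("died", "binary", 0.495),
)


@dataclass(frozen=True)
class SimConfig:
    """Cohort-level generative settings.

    ``pathway_probs`` orders as (normal, stableMCI, dementia) and must sum to
    one; entry ages are truncated-normal with a hard floor of 65 (the cohort
    enrols adults aged >= 65 only).
    """

    n_subjects: int = 500
    pathway_probs: tuple[float, float, float] = (0.59, 0.134, 0.276)
    age_at_entry_dist: tuple[float, float, float] = (81.2, 7.1, 65.0)
    visit_interval_yr: float = 1.0
    visit_jitter_yr: float = 0.1
    max_visits: int = 10
    dropout_hazard: float = 0.2
    mci_onset_dist: tuple[float, float] = (85.7, 6.05)
    dementia_onset_dist: tuple[float, float] = (88.2, 6.7)
    prob_mci_before_dementia: float = 0.51
    prob_isolated_mci: float = 0.10
    covariate_spec: tuple[CovariateSpec, ...] = DEFAULT_COVARIATES
    seed: int = 0

    def __post_init__(self) -> None:
        p = np.asarray(self.pathway_probs, dtype=float)
        if len(p) != 3 or np.any(p < 0) or abs(p.sum() - 1.0) > 1e-12:
            raise ValueError("pathway_probs must be 3 non-negative values summing to 1")
        mean, sd, floor = self.age_at_entry_dist
        if floor < 65.0:
            raise ValueError("entry ages below 65 are outside the cohort definition")
        if sd <= 0 or self.visit_interval_yr <= 0 or self.max_visits < 1:
            raise ValueError("invalid entry-age / visit settings")
        if not (0 <= self.dropout_hazard < 1):
            raise ValueError("dropout_hazard must be in [0, 1)")
        for name, dist in (
            ("mci_onset_dist", self.mci_onset_dist),
            ("dementia_onset_dist", self.dementia_onset_dist),
        ):
            m, s = dist
            if s < 0:
                raise ValueError(f"{name}: negative SD")
            if m + 3 * s < floor:
                raise ValueError(
                    f"{name}: onsets would precede study entry for all subjects"
                )


def _truncated_normal(rng: np.random.Generator, mean, sd, lower) -> float:
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if x >= lower:
            return float(x)
    return float(lower)  # pathological truncation; clamp


def _sample_covariates(rng: np.random.Generator, spec) -> dict[str, float]:
    out = {}
    for name, kind, params in spec:
        if kind == "binary":
            out[name] = float(rng.random() < float(params))
        elif kind == "normal":
            m, s = params
            out[name] = float(rng.normal(m, s))
        elif kind == "uniform":
            lo, hi = params
            out[name] = float(rng.uniform(lo, hi))
        else:
            raise ValueError(f"unknown covariate kind: {kind!r}")
    return out


def _visit_ages(rng: np.random.Generator, cfg: SimConfig, entry: float, min_visits: int) -> np.ndarray:
    n = 1
    while n < cfg.max_visits and rng.random() >= cfg.dropout_hazard:
        n += 1
    n = max(n, min_visits)
    jitter = rng.uniform(-cfg.visit_jitter_yr, cfg.visit_jitter_yr, size=n)
    jitter[0] = 0.0
    return entry + np.arange(n) * cfg.visit_interval_yr + jitter


def generate_cohort(config: SimConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a longitudinal cohort with known pathway truth.

    Returns ``(visits, truth)``: ``visits`` has one row per subject-visit
    (subject, visit, age, diagnosis, covariates, self-report sleep items);
    ``truth`` one row per subject (pathway, onset ages) — the generating
    labels, which the diagnosis sequences reproduce exactly under the
    pathway-assignment rules (dementia is never reverted; stable MCI means
    one run of >= 2 consecutive MCI visits; normal allows only isolated
    MCI visits).
    """
    rng = np.random.default_rng(config.seed)
    mean_e, sd_e, floor_e = config.age_at_entry_dist
    visit_rows: list[dict] = []
    truth_rows: list[dict] = []

    pathway_idx = rng.choice(3, size=config.n_subjects, p=config.pathway_probs)
    names = ("normal", "stableMCI", "dementia")

    for i in range(config.n_subjects):
        subject = f"S{i:05d}"
        pathway = names[pathway_idx[i]]
        entry = _truncated_normal(rng, mean_e, sd_e, floor_e)
        min_visits = 2 if pathway == "stableMCI" else 1
        ages = _visit_ages(rng, config, entry, min_visits)
        n = len(ages)
        dx = np.array(["NCI"] * n, dtype=object)
        mci_onset = dem_onset = None

        if pathway == "normal":
            for j in range(n):
                prev_mci = j > 0 and dx[j - 1] == "MCI"
                if not prev_mci and rng.random() < config.prob_isolated_mci:
                    dx[j] = "MCI"
        elif pathway == "stableMCI":
            m, s = config.mci_onset_dist
            target = _truncated_normal(rng, m, s, entry)
            idx = int(np.clip(np.argmin(np.abs(ages - target)), 0, n - 2))
            dx[idx:] = "MCI"
            mci_onset = float(ages[idx])
        else:  # dementia
            m, s = config.dementia_onset_dist
            target = _truncated_normal(rng, m, s, entry)
            idx_d = int(np.argmin(np.abs(ages - target)))
            dx[idx_d:] = "dementia"
            dem_onset = float(ages[idx_d])
            if idx_d >= 2 and rng.random() < config.prob_mci_before_dementia:
                mm, ms = config.mci_onset_dist
                target_m = _truncated_normal(rng, mm, ms, entry)
                idx_m = int(np.clip(np.argmin(np.abs(ages[: idx_d] - target_m)), 0, idx_d - 2))
                dx[idx_m:idx_d] = "MCI"
                mci_onset = float(ages[idx_m])

        covs = _sample_covariates(rng, config.covariate_spec)
        # self-report sleep items: stable habitual schedule with visit noise
        tst_base = rng.normal(7.0, 0.9)
        bed_base = rng.normal(22.5, 0.8) % 24.0
        for j, age in enumerate(ages):
            tst = max(tst_base + rng.normal(0, 0.3), 3.0)
            bed = (bed_base + rng.normal(0, 0.25)) % 24.0
            wake = (bed + tst + abs(rng.normal(0.5, 0.2))) % 24.0
            visit_rows.append(
                {
                    "subject": subject,
                    "visit": j,
                    "age": float(age),
                    "diagnosis": dx[j],
                    "selfreport_tst_h": float(tst),
                    "selfreport_bed_h": float(bed),
                    "selfreport_wake_h": float(wake),
                    **covs,
                }
            )
        truth_rows.append(
            {
                "subject": subject,
                "pathway": pathway,
                "mci_onset_age": mci_onset,
                "dementia_onset_age": dem_onset,
            }
        )

    visits = pd.DataFrame(visit_rows)
    truth = pd.DataFrame(truth_rows)
    return visits, truth


def truth_labels(truth: pd.DataFrame) -> dict[str, PathwayLabel]:
    """Per-subject :class:`PathwayLabel` objects from a truth table."""
    out = {}
    for row in truth.itertuples():
        out[row.subject] = PathwayLabel(
            pathway=row.pathway,
            mci_onset_age=None if pd.isna(row.mci_onset_age) else float(row.mci_onset_age),
            dementia_onset_age=None
            if pd.isna(row.dementia_onset_age)
            else float(row.dementia_onset_age),
        )
    return out


# ---------------------------------------------------------------------------
# feature-level outcome simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrajectoryParams:
    """Generating parameters for the trajectory model.

    ``coefficients`` maps fixed-effect design-column names to values (columns
    not named get coefficient 0; unknown names are a schema error at
    simulation time).  ``re_cov`` is the 2x2 covariance of the subject random
    intercept and age slope; ``resid_var`` the residual variance.
    """

    coefficients: dict[str, float]
    re_cov: np.ndarray = field(
        default_factory=lambda: np.zeros((2, 2))
    )
    resid_var: float = 1.0

    def __post_init__(self) -> None:
        cov = np.asarray(self.re_cov, dtype=float)
        if cov.shape != (2, 2) or abs(cov[0, 1] - cov[1, 0]) > 1e-12:
            raise ValueError("re_cov must be a symmetric 2x2 matrix")
        if np.min(np.linalg.eigvalsh(cov)) < -1e-10:
            raise ValueError("re_cov must be positive semidefinite")
        if self.resid_var < 0:
            raise ValueError("resid_var must be non-negative")
        object.__setattr__(self, "re_cov", cov)


def simulate_feature_outcomes(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    params: TrajectoryParams,
    seed: int,
    covariates: pd.DataFrame | None = None,
    center_age: float = CENTER_AGE,
) -> pd.DataFrame:
    """Draw one longitudinal outcome column from a known trajectory model.

    The fixed-effect part uses exactly the design construction the estimator
    uses (:func:`sleepart.build_design`), so recovery tests compare like with
    like.  Returns the cohort visit rows plus ``outcome`` and the noise-free
    linear predictor ``eta`` for truth-linked checks.
    """
    rng = np.random.default_rng(seed)
    work = cohort[["subject", "age"]].copy()
    work["outcome"] = 0.0
    design = build_design(
        work, truth, covariates=covariates, center_age=center_age
    )
    unknown = set(params.coefficients) - set(design.columns)
    if unknown:
        raise KeyError(f"coefficients do not match design columns: {sorted(unknown)}")
    beta = np.array([params.coefficients.get(c, 0.0) for c in design.columns])
    eta = design.X.to_numpy(dtype=float) @ beta

    codes, subjects = pd.factorize(cohort["subject"])
    b = rng.multivariate_normal(np.zeros(2), params.re_cov, size=len(subjects))
    age_c = cohort["age"].to_numpy(dtype=float) - center_age
    ranef = b[codes, 0] + b[codes, 1] * age_c
    eps = (
        rng.normal(0.0, np.sqrt(params.resid_var), size=len(cohort))
        if params.resid_var > 0
        else np.zeros(len(cohort))
    )
    out = cohort.copy()
    out["eta"] = eta
    out["outcome"] = eta + ranef + eps
    return out


# ---------------------------------------------------------------------------
# epoch-level actigraphy simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ActigraphySimParams:
    """Generative settings for one session of 15 s activity counts.

    The mean curve is the extended cosine model; counts in the sleep window
    are multiplied by ``suppression`` (< 1 so sleep remains detectable;
    ``sleep_onset=None`` disables the window entirely, giving data exactly
    from the model — useful for cosinor-recovery oracles).  ``dispersion`` is
    the negative-binomial size parameter (over-dispersion typical of wrist
    counts); 0 means deterministic rounded means.  Nonwear insertions are
    (start hour from recording start, duration hours) runs forced to zero.
    """

    minimum: float = 10.0
    amplitude: float = 100.0
    acrophase: float = 14.0
    alpha: float = -0.4
    beta: float = 8.0
    dispersion: float = 5.0
    sleep_onset: float | None = 23.5  # clock hours
    sleep_duration_h: float = 8.0
    suppression: float = 0.05
    nonwear: tuple[tuple[float, float], ...] = ()
    days: int = 9
    epoch_s: int = 15
    start: str = "2020-01-06 12:00:00"
    subject: str = "S00000"
    session: str = "A"

    def __post_init__(self) -> None:
        if self.days < 1:
            raise ValueError("days must be >= 1")
        if not -1.0 <= self.alpha <= 1.0 or self.beta <= 0:
            raise ValueError("alpha in [-1, 1] and beta > 0 required")
        if self.sleep_onset is not None:
            if not 0.0 <= self.suppression < 1.0:
                raise ValueError("suppression must be in [0, 1) so sleep is detectable")
            if self.sleep_duration_h < 0:
                raise ValueError("negative sleep duration")
        if any(d < 0 or s < 0 for s, d in self.nonwear):
            raise ValueError("nonwear insertions need non-negative start/duration")
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")


def simulate_epoch_actigraphy(params: ActigraphySimParams, seed: int) -> EpochSeries:
    """Simulate one session of epoch-level activity counts."""
    from .features import extended_cosine_curve  # local import: avoid cycle

    per_h = 3600 // params.epoch_s
    n = params.days * 24 * per_h
    start = pd.Timestamp(params.start)
    start_clock = start.hour + start.minute / 60.0 + start.second / 3600.0
    t_h = np.arange(n) / per_h
    clock = (start_clock + t_h) % 24.0
    mean = extended_cosine_curve(
        clock, params.minimum, params.amplitude, params.acrophase,
        params.alpha, params.beta,
    )
    if params.sleep_onset is not None and params.sleep_duration_h > 0:
        in_sleep = ((clock - params.sleep_onset) % 24.0) < params.sleep_duration_h
        mean = np.where(in_sleep, params.suppression * mean, mean)

    rng = np.random.default_rng(seed)
    if params.dispersion == 0:
        counts = np.rint(mean)
    else:
        k = params.dispersion
        p = k / (k + np.maximum(mean, 1e-12))
        counts = rng.negative_binomial(k, p).astype(float)

    for start_h, dur_h in params.nonwear:
        a = int(round(start_h * per_h))
        b = int(round((start_h + dur_h) * per_h))
        counts[max(a, 0) : min(b, n)] = 0.0

    return EpochSeries(
        subject=params.subject,
        session=params.session,
        start=start,
        epoch_s=params.epoch_s,
        counts=counts,
    )


# ---------------------------------------------------------------------------
# CSV writers (the dialects the downstream readers consume)
# ---------------------------------------------------------------------------

def write_epoch_csv(series_list, path) -> None:
    """Write epoch series as ``subject,session,timestamp,count`` CSV rows."""
    frames = []
    for s in series_list:
        frames.append(
            pd.DataFrame(
                {
                    "subject": s.subject,
                    "session": s.session,
                    "timestamp": s.timestamps().strftime("%Y-%m-%dT%H:%M:%S"),
                    "count": s.counts.astype(int)
                    if np.allclose(s.counts, np.rint(s.counts))
                    else s.counts,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def write_cohort_csvs(visits: pd.DataFrame, truth: pd.DataFrame, out_dir) -> dict[str, Path]:
    """Write the visit, self-report and truth tables to ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    visit_cols = [
        c for c in visits.columns if not c.startswith("selfreport_")
    ]
    paths["visits"] = out_dir / "visits.csv"
    visits[visit_cols].to_csv(paths["visits"], index=False)
    paths["selfreport"] = out_dir / "selfreport.csv"
    visits[
        ["subject", "age", "selfreport_tst_h", "selfreport_bed_h", "selfreport_wake_h"]
    ].to_csv(paths["selfreport"], index=False)
    paths["pathways_truth"] = out_dir / "pathways_truth.csv"
    truth.to_csv(paths["pathways_truth"], index=False)
    return paths


def read_epoch_csv(path) -> list[EpochSeries]:
    """Read an epoch CSV back into per-session :class:`EpochSeries`."""
    df = pd.read_csv(path, parse_dates=["timestamp"])
    out = []
    for (subject, session), grp in df.groupby(["subject", "session"], sort=True):
        grp = grp.sort_values("timestamp")
        stamps = grp["timestamp"]
        if len(grp) < 2:
            raise ValueError("epoch series needs >= 2 rows to infer epoch length")
        epoch_s = int(round((stamps.iloc[1] - stamps.iloc[0]).total_seconds()))
        out.append(
            EpochSeries(
                subject=str(subject),
                session=str(session),
                start=stamps.iloc[0],
                epoch_s=epoch_s,
                counts=grp["count"].to_numpy(dtype=float),
            )
        )
    return out
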