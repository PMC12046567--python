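"""Mixed-effects cubic-spline trajectory models with diagnosis-onset knots.

Each sleep/rhythm outcome is modelled as a smooth function of age,

    y_ij = x_ij' beta + b0_i + b1_i * a_ij + e_ij,

where ``a`` is age centred at 82 (the median first-visit age), the fixed
design holds a cubic polynomial in ``a``, pathway main effects, age-by-pathway
interactions, truncated cubic terms ((age - k)_+)^3 at each subject's own MCI
and dementia onset ages, and mean-centred covariates.  The truncated cubic
basis keeps every fitted trajectory continuous with continuous first and
second derivatives at its knots, so diagnosis-related change is gradual
rather than an "elbow".  Random intercepts and age slopes per subject carry
within-subject correlation, and the residual variance is divided by
per-observation weights (the number of valid actigraphy days; 1 for
self-report models).

Estimation is by restricted maximum likelihood, profiling out the fixed
effects and the residual scale and optimising the 2x2 relative random-effect
covariance through its Cholesky factor.  Per-subject Woodbury identities keep
each objective evaluation linear in the number of observations.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import optimize, stats

CENTER_AGE = 82.0
PATHWAYS = ("normal", "stableMCI", "dementia")
_THETA_BOUND = 9.0


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryDesign:
    """Response, named fixed-effect matrix, grouping and weights for one fit."""

    y: np.ndarray
    X: pd.DataFrame
    subject: np.ndarray
    age_c: np.ndarray  # centred age, the random-slope covariate
    weights: np.ndarray
    center_age: float
    covariate_cols: tuple[str, ...] = ()

    @property
    def columns(self) -> list[str]:
        return list(self.X.columns)

    def drop_term(self, name: str) -> "TrajectoryDesign":
        return replace(self, X=self.X.drop(columns=[name]))


def _knot_basis(age: np.ndarray, onset: np.ndarray) -> np.ndarray:
    """Truncated cubic ((age - k)_+)^3; zero where the onset is absent."""
    k = np.where(np.isnan(onset), np.inf, onset)
    return np.clip(age - k, 0.0, None) ** 3


def build_design(
    outcomes: pd.DataFrame,
    pathways: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    center_age: float = CENTER_AGE,
    outcome_col: str = "outcome",
    weight_col: str | None = None,
) -> TrajectoryDesign:
    """Assemble the fixed-effect design for one outcome.

    ``outcomes`` has columns ``subject``, ``age``, ``outcome_col`` and
    optionally ``weight_col``; ``pathways`` is one row per subject with
    ``pathway`` and onset ages (as from :func:`sleepart.assign_pathways`).
    ``covariates`` (optional) is merged on ``subject`` (and ``age`` when
    present); numeric covariates are mean-centred and categorical ones expand
    to proportion-centred dummies, so the all-zero covariate profile *is* the
    average-covariate reference used for typical-subject predictions.
    """
    df = outcomes.merge(
        pathways[["subject", "pathway", "mci_onset_age", "dementia_onset_age"]],
        on="subject",
        how="left",
        validate="many_to_one",
    )
    if df["pathway"].isna().any():
        missing = df.loc[df["pathway"].isna(), "subject"].unique()
        raise ValueError(f"subjects without a pathway label: {missing[:5]}")
    bad = (df["pathway"] == "dementia") & df["dementia_onset_age"].isna()
    if bad.any():
        raise ValueError("dementia-pathway subject without a dementia onset age")

    a = df["age"].to_numpy(dtype=float) - center_age
    X = pd.DataFrame(index=df.index)
    X["const"] = 1.0
    X["age"] = a
    X["age2"] = a**2
    X["age3"] = a**3
    for p in ("stableMCI", "dementia"):
        dummy = (df["pathway"] == p).to_numpy(dtype=float)
        X[f"path[{p}]"] = dummy
        for k in (1, 2, 3):
            X[f"age{k if k > 1 else ''}:path[{p}]"] = (a**k) * dummy
    X["knot_mci"] = _knot_basis(
        df["age"].to_numpy(dtype=float), df["mci_onset_age"].to_numpy(dtype=float)
    )
    X["knot_dem"] = _knot_basis(
        df["age"].to_numpy(dtype=float), df["dementia_onset_age"].to_numpy(dtype=float)
    )

    covariate_cols: list[str] = []
    if covariates is not None:
        on = ["subject"] + (["age"] if "age" in covariates.columns else [])
        cov = df[["subject", "age"]].merge(covariates, on=on, how="left")
        for col in cov.columns:
            if col in ("subject", "age"):
                continue
            series = cov[col]
            if series.isna().any():
                raise ValueError(f"missing covariate values in {col!r}")
            if series.dtype == object or isinstance(
                series.dtype, pd.CategoricalDtype
            ):
                dummies = pd.get_dummies(series, prefix=col, drop_first=True)
                for dcol in dummies.columns:
                    vals = dummies[dcol].to_numpy(dtype=float)
                    X[dcol] = vals - vals.mean()
                    covariate_cols.append(dcol)
            else:
                vals = series.to_numpy(dtype=float)
                X[col] = vals - vals.mean()
                covariate_cols.append(col)

    weights = (
        df[weight_col].to_numpy(dtype=float)
        if weight_col is not None and weight_col in df.columns
        else np.ones(len(df))
    )
    if np.any(weights <= 0):
        raise ValueError("observation weights must be positive")

    return TrajectoryDesign(
        y=df[outcome_col].to_numpy(dtype=float),
        X=X,
        subject=df["subject"].to_numpy(),
        age_c=a,
        weights=weights,
        center_age=center_age,
        covariate_cols=tuple(covariate_cols),
    )


# ---------------------------------------------------------------------------
# REML fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedTrajectoryModel:
    """REML fit: fixed effects, their covariance, and variance components."""

    params: pd.Series
    cov_params: pd.DataFrame
    var_intercept: float
    var_slope: float
    cov_intercept_slope: float
    var_resid: float
    loglik_reml: float
    n_obs: int
    n_subjects: int
    center_age: float
    covariate_cols: tuple[str, ...]
    converged: bool = True
    boundary: bool = False
    eliminated: tuple[str, ...] = ()

    @property
    def df_resid(self) -> int:
        return self.n_obs - len(self.params)

    @property
    def bse(self) -> pd.Series:
        return pd.Series(
            np.sqrt(np.diag(self.cov_params.to_numpy())), index=self.params.index
        )

    @property
    def tvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        """Wald t p-values with residual df = n_obs - rank."""
        return pd.Series(
            2.0 * stats.t.sf(np.abs(self.tvalues), df=self.df_resid),
            index=self.params.index,
        )

    # -- serialisation ------------------------------------------------------
    def to_json(self, path=None) -> str | None:
        payload = {
            "params": self.params.to_dict(),
            "cov_params": {
                "columns": list(self.cov_params.columns),
                "values": self.cov_params.to_numpy().tolist(),
            },
            "var_intercept": self.var_intercept,
            "var_slope": self.var_slope,
            "cov_intercept_slope": self.cov_intercept_slope,
            "var_resid": self.var_resid,
            "loglik_reml": self.loglik_reml,
            "n_obs": self.n_obs,
            "n_subjects": self.n_subjects,
            "center_age": self.center_age,
            "covariate_cols": list(self.covariate_cols),
            "converged": self.converged,
            "boundary": self.boundary,
            "eliminated": list(self.eliminated),
        }
        text = json.dumps(payload, indent=2)
        if path is None:
            return text
        with open(path, "w") as fh:
            fh.write(text)
        return None

    @classmethod
    def from_json(cls, source) -> "FittedTrajectoryModel":
        if isinstance(source, (str, bytes)) and str(source).lstrip().startswith("{"):
            payload = json.loads(source)
        else:
            with open(source) as fh:
                payload = json.load(fh)
        cols = payload["cov_params"]["columns"]
        return cls(
            params=pd.Series(payload["params"]),
            cov_params=pd.DataFrame(
                payload["cov_params"]["values"], index=cols, columns=cols
            ),
            var_intercept=payload["var_intercept"],
            var_slope=payload["var_slope"],
            cov_intercept_slope=payload["cov_intercept_slope"],
            var_resid=payload["var_resid"],
            loglik_reml=payload["loglik_reml"],
            n_obs=payload["n_obs"],
            n_subjects=payload["n_subjects"],
            center_age=payload["center_age"],
            covariate_cols=tuple(payload["covariate_cols"]),
            converged=payload["converged"],
            boundary=payload["boundary"],
            eliminated=tuple(payload["eliminated"]),
        )


class _REMLWork:
    """Precomputed per-subject blocks for the profiled REML objective.

    With V* = W^-1 + Z D Z' (D the relative random-effect covariance,
    Z = [1, a] per subject) and D = L L', Woodbury gives

        V*^-1 = W - W Z L (I + L' Z'WZ L)^-1 L' Z' W,

    which needs only the per-subject 2x2 blocks A_i = Z_i'W_iZ_i, the 2xp
    blocks U_i = Z_i'W_iX_i and the 2-vectors v_i = Z_i'W_iy_i — all fixed
    across objective evaluations.
    """

    def __init__(self, design: TrajectoryDesign):
        order = np.argsort(design.subject, kind="stable")
        self.X = design.X.to_numpy(dtype=float)[order]
        self.y = design.y[order]
        self.a = design.age_c[order]
        w = design.weights[order]
        self.w = w / w.mean()  # weights matter only relatively
        subj = design.subject[order]
        _, starts, counts = np.unique(subj, return_index=True, return_counts=True)
        self.starts, self.counts = starts, counts
        self.n, self.p = self.X.shape
        self.s = len(starts)

        wa = self.w * self.a
        self.A = np.empty((self.s, 2, 2))
        self.A[:, 0, 0] = np.add.reduceat(self.w, starts)
        self.A[:, 0, 1] = self.A[:, 1, 0] = np.add.reduceat(wa, starts)
        self.A[:, 1, 1] = np.add.reduceat(wa * self.a, starts)
        WX = self.w[:, None] * self.X
        self.U = np.stack(
            [np.add.reduceat(WX, starts, axis=0),
             np.add.reduceat(self.a[:, None] * WX, starts, axis=0)],
            axis=1,
        )  # (s, 2, p)
        wy = self.w * self.y
        self.v = np.stack(
            [np.add.reduceat(wy, starts), np.add.reduceat(wy * self.a, starts)],
            axis=1,
        )  # (s, 2)
        self.XtWX = self.X.T @ WX
        self.XtWy = self.X.T @ wy
        self.ytWy = float(self.y @ wy)
        self.sum_log_w = float(np.sum(np.log(self.w)))

    @staticmethod
    def _chol(theta: np.ndarray) -> np.ndarray:
        t = np.clip(theta, -_THETA_BOUND, _THETA_BOUND)
        return np.array([[np.exp(t[0]), 0.0], [t[1], np.exp(t[2])]])

    def _solve_pieces(self, theta: np.ndarray):
        L = self._chol(theta)
        At = np.einsum("ba,sbc,cd->sad", L, self.A, L)  # L' A L
        M = At.copy()
        M[:, 0, 0] += 1.0
        M[:, 1, 1] += 1.0
        detM = M[:, 0, 0] * M[:, 1, 1] - M[:, 0, 1] * M[:, 1, 0]
        Minv = np.empty_like(M)
        Minv[:, 0, 0] = M[:, 1, 1] / detM
        Minv[:, 1, 1] = M[:, 0, 0] / detM
        Minv[:, 0, 1] = -M[:, 0, 1] / detM
        Minv[:, 1, 0] = -M[:, 1, 0] / detM
        Ut = np.einsum("ba,sbp->sap", L, self.U)
        vt = np.einsum("ba,sb->sa", L, self.v)
        XtVX = self.XtWX - np.einsum("sap,sab,sbq->pq", Ut, Minv, Ut)
        XtVy = self.XtWy - np.einsum("sap,sab,sb->p", Ut, Minv, vt)
        ytVy = self.ytWy - float(np.einsum("sa,sab,sb->", vt, Minv, vt))
        return XtVX, XtVy, ytVy, detM, L

    def deviance(self, theta: np.ndarray) -> float:
        """-2 * restricted log-likelihood up to an additive constant."""
        XtVX, XtVy, ytVy, detM, _ = self._solve_pieces(theta)
        try:
            beta = np.linalg.solve(XtVX, XtVy)
            sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        except np.linalg.LinAlgError:
            return np.inf
        if sign <= 0 or np.any(detM <= 0):
            return np.inf
        rss = max(ytVy - float(beta @ XtVy), 1e-300)
        nm = self.n - self.p
        sigma2 = rss / nm
        return nm * np.log(sigma2) + float(np.sum(np.log(detM))) + logdet_XtVX

    def finish(self, theta: np.ndarray):
        XtVX, XtVy, ytVy, detM, L = self._solve_pieces(theta)
        XtVX_inv = np.linalg.inv(XtVX)
        beta = XtVX_inv @ XtVy
        nm = self.n - self.p
        sigma2 = max(ytVy - float(beta @ XtVy), 0.0) / nm
        cov_beta = sigma2 * XtVX_inv
        D = L @ L.T
        psi = sigma2 * D
        sign, logdet_XtVX = np.linalg.slogdet(XtVX)
        loglik = -0.5 * (
            nm * np.log(max(sigma2, 1e-300))
            + float(np.sum(np.log(detM)))
            - self.sum_log_w
            + logdet_XtVX
            + nm * (1.0 + np.log(2.0 * np.pi))
        )
        return beta, cov_beta, sigma2, psi, loglik


def fit_mixed_spline(design: TrajectoryDesign) -> FittedTrajectoryModel:
    """REML fit of the weighted mixed model with random intercept + age slope.

    The 2x2 random-effect covariance is unstructured; zero variance
    components are admitted as boundary solutions (``boundary=True``).
    Raises on a rank-deficient fixed-effect matrix or non-convergence.
    """
    Xmat = design.X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xmat) < Xmat.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    work = _REMLWork(design)

    best = None
    for x0 in ([-1.0, 0.0, -1.0], [-4.0, 0.0, -4.0]):
        res = optimize.minimize(
            work.deviance,
            x0=np.array(x0),
            method="L-BFGS-B",
            bounds=[(-_THETA_BOUND, _THETA_BOUND)] * 3,
            options={"maxiter": 200},
        )
        if best is None or res.fun < best.fun:
            best = res
        if best.success and np.isfinite(best.fun):
            break
    # polish with a derivative-free pass; REML surfaces can be flat in the
    # off-diagonal parameter and L-BFGS-B's numeric gradient may stall early
    res = optimize.minimize(
        work.deviance,
        x0=best.x,
        method="Nelder-Mead",
        options={"xatol": 1e-7, "fatol": 1e-9, "maxiter": 400},
    )
    if res.fun <= best.fun:
        best = res
    if best is None or not np.isfinite(best.fun):
        raise RuntimeError("REML optimisation failed to produce a finite deviance")

    theta = np.clip(best.x, -_THETA_BOUND, _THETA_BOUND)
    beta, cov_beta, sigma2, psi, loglik = work.finish(theta)
    boundary = bool(np.any(np.abs(theta) >= _THETA_BOUND - 1e-6))
    cols = design.columns
    return FittedTrajectoryModel(
        params=pd.Series(beta, index=cols),
        cov_params=pd.DataFrame(cov_beta, index=cols, columns=cols),
        var_intercept=float(psi[0, 0]),
        var_slope=float(psi[1, 1]),
        cov_intercept_slope=float(psi[0, 1]),
        var_resid=float(sigma2),
        loglik_reml=float(loglik),
        n_obs=work.n,
        n_subjects=work.s,
        center_age=design.center_age,
        covariate_cols=design.covariate_cols,
        converged=bool(best.success),
        boundary=boundary,
    )


# ---------------------------------------------------------------------------
# backward elimination
# ---------------------------------------------------------------------------

_MAIN_RE = re.compile(r"^age(\d?)$")
_INTER_RE = re.compile(r"^age(\d?):path\[(\w+)\]$")


def _age_order(match_group: str) -> int:
    return int(match_group) if match_group else 1


def eligible_terms(columns: list[str]) -> list[str]:
    """Terms the elimination may touch: age mains, age-by-pathway, knots."""
    out = []
    for c in columns:
        if _MAIN_RE.match(c) or _INTER_RE.match(c) or c in ("knot_mci", "knot_dem"):
            out.append(c)
    return out


def term_blockers(column: str, columns: list[str]) -> list[str]:
    """Columns whose presence forbids removing ``column`` (hierarchy rule).

    An age main effect is blocked by any higher-order age main and by any
    age-by-pathway interaction of the same or higher order; an interaction is
    blocked by higher-order interactions with the same pathway.  Knot terms
    are unblocked.
    """
    m = _MAIN_RE.match(column)
    if m:
        k = _age_order(m.group(1))
        blockers = []
        for c in columns:
            mm = _MAIN_RE.match(c)
            if mm and _age_order(mm.group(1)) > k:
                blockers.append(c)
            mi = _INTER_RE.match(c)
            if mi and _age_order(mi.group(1)) >= k:
                blockers.append(c)
        return blockers
    mi = _INTER_RE.match(column)
    if mi:
        k, path = _age_order(mi.group(1)), mi.group(2)
        return [
            c
            for c in columns
            if (m2 := _INTER_RE.match(c))
            and m2.group(2) == path
            and _age_order(m2.group(1)) > k
        ]
    return []


def backward_eliminate(
    model: FittedTrajectoryModel,
    design: TrajectoryDesign,
    alpha: float = 0.05,
) -> tuple[FittedTrajectoryModel, TrajectoryDesign]:
    """Prune non-significant higher-order age, interaction and knot terms.

    One term per step: among currently removable terms (eligible and not
    protected by a retained higher-order term), drop the one with the largest
    p-value if that p-value is >= ``alpha``, refit, repeat.  Pathway main
    effects, the intercept and covariates are never candidates.  Returns the
    final model and the pruned design; the removal order is recorded on the
    model's ``eliminated`` attribute.
    """
    eliminated: list[str] = []
    while True:
        cols = design.columns
        removable = [
            c
            for c in eligible_terms(cols)
            if not any(b in cols for b in term_blockers(c, cols))
        ]
        if not removable:
            break
        pvals = model.pvalues[removable]
        worst = pvals.idxmax()
        if pvals[worst] < alpha:
            break
        design = design.drop_term(worst)
        eliminated.append(worst)
        model = fit_mixed_spline(design)
    return replace(model, eliminated=tuple(eliminated)), design


# ---------------------------------------------------------------------------
# typical-subject prediction
# ---------------------------------------------------------------------------

def design_row(
    model: FittedTrajectoryModel,
    pathway: str,
    age: float,
    schedule: tuple[float | None, float | None] = (None, None),
) -> np.ndarray:
    """Fixed-effect row vector for a typical subject of ``pathway`` at ``age``.

    ``schedule`` is (MCI onset age, dementia onset age or None) — the
    benchmark diagnosis schedule at which knot terms are evaluated.
    Covariates sit at the average-covariate reference (zero, by centring).
    """
    if pathway not in PATHWAYS:
        raise ValueError(f"unknown pathway: {pathway!r}")
    k_mci, k_dem = schedule
    if k_dem is not None and pathway != "dementia":
        raise ValueError("dementia knot supplied for a non-dementia pathway")
    a = age - model.center_age
    values = {
        "const": 1.0,
        "age": a,
        "age2": a**2,
        "age3": a**3,
        "knot_mci": max(age - k_mci, 0.0) ** 3 if k_mci is not None else 0.0,
        "knot_dem": max(age - k_dem, 0.0) ** 3 if k_dem is not None else 0.0,
    }
    for p in ("stableMCI", "dementia"):
        dummy = 1.0 if pathway == p else 0.0
        values[f"path[{p}]"] = dummy
        values[f"age:path[{p}]"] = a * dummy
        values[f"age2:path[{p}]"] = a**2 * dummy
        values[f"age3:path[{p}]"] = a**3 * dummy
    return np.array([values.get(c, 0.0) for c in model.params.index])


def predict_typical(
    model: FittedTrajectoryModel,
    pathway: str,
    age: float,
    schedule: tuple[float | None, float | None] = (None, None),
) -> tuple[float, float]:
    """Expected outcome and its SE for an average-covariate subject."""
    x = design_row(model, pathway, age, schedule)
    pred = float(x @ model.params.to_numpy())
    se = float(np.sqrt(x @ model.cov_params.to_numpy() @ x))
    return pred, se
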