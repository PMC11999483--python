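"""Phase binning, analysis-table assembly, and mixed-model contrasts.

The analysis follows the standard two-arm repeated-measures scheme for a
randomized actigraphy trial: days are binned into a pre-randomization
run-in (day -14..0) and post-randomization weeks 1-4; linear mixed models
(REML) estimate group x phase interaction contrasts referenced to the
placebo arm and the run-in phase, controlling for daily log positive
affect, positive-affect volatility, age, sex, and season of intake.

Three model families are provided:

* activity model - M10 and L5 levels (or onset times) in one model with
  an activity-type factor and a by-participant random intercept and
  random activity-type slope;
* variability model - filter-estimated log-volatility and log-noise in
  one model with activity-type and variability-type factors;
* rhythm model - per-period relative amplitude / IS / IV with a random
  intercept only.

Inference conventions
---------------------
Fixed-effect standard errors default to a participant-clustered sandwich
("cluster"): M10 and L5 share one model (as do volatility and noise), so
their residual scales differ by orders of magnitude, and a pooled
residual variance would understate the reference-level contrast SEs; the
cluster sandwich is consistent under that heteroscedasticity and under
within-person day-to-day correlation.  The accompanying t reference uses
(number of participants - 1) degrees of freedom.  The naive
pooled-variance convention remains available as ``p_method='residual'``.
The standardized effect size is d = 2t/sqrt(df_residual).  P-values are
unadjusted - no multiplicity correction is applied across the four
post-randomization weeks.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.formula.api as smf

__all__ = [
    "PHASES",
    "EffectEstimate",
    "CorrelationResult",
    "ModelFit",
    "assign_phase",
    "build_long_table",
    "fit_activity_model",
    "fit_variability_model",
    "fit_rhythm_model",
    "within_subject_correlation",
    "change_score_correlation",
    "effect_size",
]

PHASES = ("run-in", "week1", "week2", "week3", "week4")
NO_ADJUSTMENT_CAVEAT = (
    "p-values are unadjusted; no correction for multiple comparisons is applied "
    "across the four post-randomization weeks"
)
D_CONVENTION = "d = 2*t/sqrt(df_residual); p from participant-clustered sandwich SE, t(df = n_participants - 1)"


def assign_phase(day: int) -> str | None:
    """Map a day index (relative to randomization) to its phase.

    Run-in covers day -14..0; weeks 1-4 cover days 1-7, 8-14, 15-21,
    22-28.  Days outside -14..28 are excluded (None).
    """
    day = int(day)
    if day < -14 or day > 28:
        return None
    if day <= 0:
        return "run-in"
    return f"week{(day - 1) // 7 + 1}"


@dataclass(frozen=True)
class EffectEstimate:
    """One fixed-effect contrast from a mixed model."""

    term: str
    B: float
    se: float
    t: float
    df: float
    p: float
    d: float
    reference: str = "arm=placebo, phase=run-in"


@dataclass(frozen=True)
class CorrelationResult:
    """Standardized mixed-model slope used as a correlation proxy."""

    pair: tuple[str, str]
    beta: float
    se: float
    p: float
    n: int
    degenerate: bool = False


@dataclass
class ModelFit:
    """A fitted mixed model plus its tidied contrasts and provenance."""

    formula: str
    estimates: pd.DataFrame  # every fixed effect
    contrasts: pd.DataFrame  # group x phase rows at the reference levels
    converged: bool
    warnings: list = field(default_factory=list)
    result: object = None
    notes: tuple[str, ...] = (NO_ADJUSTMENT_CAVEAT, D_CONVENTION)

    def effect_estimates(self) -> list[EffectEstimate]:
        """The group x phase contrasts as typed records."""
        return [
            EffectEstimate(term=r.term, B=r.B, se=r.se, t=r.t, df=r.df, p=r.p, d=r.d)
            for r in self.contrasts.itertuples()
        ]


def effect_size(B: float, t: float, df: float) -> float:
    """Standardized effect size d = 2t/sqrt(df) (sign follows B and t)."""
    if not all(math.isfinite(v) for v in (B, t, df)):
        raise ValueError("inputs must be finite")
    if df < 1:
        raise ValueError("df must be >= 1")
    return 2.0 * t / math.sqrt(df)


# ---------------------------------------------------------------------------
# analysis table
# ---------------------------------------------------------------------------

def build_long_table(dataset, estimates=None) -> pd.DataFrame:
    """Assemble the long analysis table from a trial dataset and (optionally)
    a per-participant filter-estimates bundle.

    Rows carry id, arm, day, phase, activity_type (M10|L5), source
    (level|onset), role (level|onset|volatility|noise), and value, plus
    covariates.  Level and onset rows exist only for valid observed days;
    volatility and noise rows cover every filter day (the filter estimates
    them through gaps).  Daily log-PA on missing days is imputed from the
    PA track's back-transformed posterior mean when estimates are given.
    """
    days = dataset.days.merge(
        dataset.participants[["id", "age", "sex", "season_of_intake"]], on="id"
    )
    days = days[days["day"].between(-14, 28)].copy()
    days["phase"] = days["day"].map(assign_phase)
    days["weekday"] = (days["day"] % 7) < 5  # synthetic 7-day cycle convention

    # daily PA covariates
    pa_cov = {}
    for r in days.itertuples():
        if r.valid and np.isfinite(r.pa) and r.pa > 0:
            pa_cov[(r.id, r.day)] = math.log(r.pa)
    pa_vol = {}
    if estimates:
        day_grid = np.arange(-14, 29)
        for (pid, meas), est in estimates.items():
            if meas != "pa" or est is None:
                continue
            raw = np.clip(est.mu_raw(), 5.0, 25.0)
            for i, d in enumerate(day_grid):
                pa_vol[(pid, int(d))] = float(est.log_vmu[i])
                if (pid, int(d)) not in pa_cov:
                    pa_cov[(pid, int(d))] = math.log(max(raw[i], 1e-9))

    base_cols = ["id", "arm", "day", "phase", "age", "sex", "season_of_intake", "weekday"]
    rows = []
    obs = days[days["valid"]]
    for at, src, col in (
        ("M10", "level", "m10"),
        ("L5", "level", "l5"),
        ("M10", "onset", "m10_onset"),
        ("L5", "onset", "l5_onset"),
    ):
        sub = obs[base_cols].copy()
        sub["activity_type"] = at
        sub["source"] = src
        sub["role"] = src
        sub["value"] = obs[col].to_numpy()
        rows.append(sub)

    if estimates:
        meta = days.drop_duplicates("id").set_index("id")
        day_grid = np.arange(-14, 29)
        meas_map = {
            "m10": ("M10", "level"),
            "l5": ("L5", "level"),
            "m10_onset": ("M10", "onset"),
            "l5_onset": ("L5", "onset"),
        }
        for (pid, meas), est in estimates.items():
            if meas not in meas_map or est is None or pid not in meta.index:
                continue
            at, src = meas_map[meas]
            info = meta.loc[pid]
            for role, vals in (("volatility", est.log_vmu), ("noise", est.log_sd)):
                sub = pd.DataFrame(
                    {
                        "id": pid,
                        "arm": info["arm"],
                        "day": day_grid,
                        "phase": [assign_phase(int(d)) for d in day_grid],
                        "age": info["age"],
                        "sex": info["sex"],
                        "season_of_intake": info["season_of_intake"],
                        "weekday": (day_grid % 7) < 5,
                        "activity_type": at,
                        "source": src,
                        "role": role,
                        "value": vals,
                    }
                )
                rows.append(sub)

    table = pd.concat(rows, ignore_index=True)
    table["log_pa"] = [pa_cov.get((r.id, r.day), np.nan) for r in table.itertuples()]
    table["pa_volatility"] = [pa_vol.get((r.id, r.day), np.nan) for r in table.itertuples()]
    table = table.sort_values(
        ["id", "day", "activity_type", "source", "role"], kind="mergesort"
    ).reset_index(drop=True)
    return table


# ---------------------------------------------------------------------------
# mixed-model machinery
# ---------------------------------------------------------------------------

def _covariate_terms(df: pd.DataFrame, weekday: bool) -> str:
    terms = []
    for c in ("log_pa", "pa_volatility"):
        if c in df.columns and df[c].notna().any() and df[c].nunique(dropna=True) > 1:
            terms.append(c)
    terms += ["age", "C(sex)", "C(season_of_intake)"]
    if weekday:
        terms.append("C(weekday)")
    return " + ".join(terms)


def _fit(formula: str, df: pd.DataFrame, re_formula: str | None) -> tuple[object, bool, list]:
    caught: list[str] = []
    # drop rows with missing values in any column the formula references,
    # keeping the grouping vector aligned with the design matrix
    used = [c for c in df.columns if c == "id" or c in formula]
    df = df.dropna(subset=[c for c in used if c != "id"])
    last_err = None
    for method in ("powell", "lbfgs", "bfgs"):
        try:
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                model = smf.mixedlm(formula, df, groups=df["id"], re_formula=re_formula)
                res = model.fit(reml=True, method=method, maxiter=500)
            caught = [str(w.message) for w in wlist]
            return res, bool(res.converged), caught
        except (np.linalg.LinAlgError, ValueError) as err:  # singular/failed fit
            last_err = err
    raise RuntimeError(f"mixed model failed to fit: {last_err}")


def _cluster_robust_cov(res) -> np.ndarray:
    """Participant-clustered sandwich covariance of the fixed effects.

    The marginal model per participant is y_g ~ N(X_g b, V_g) with
    V_g = Z_g D Z_g' + s2 I.  The GLS bread is A = sum X_g' V_g^-1 X_g and
    the meat stacks the per-cluster score outer products, so the result is
    consistent under residual heteroscedasticity (e.g. very different M10
    and L5 residual scales) and within-person correlation the random
    effects do not capture.
    """
    model = res.model
    X = model.exog
    y = model.endog
    Z = np.asarray(model.exog_re) if model.exog_re is not None else None
    D = np.atleast_2d(np.asarray(res.cov_re))
    s2 = float(res.scale)
    beta = np.asarray(res.fe_params)
    k = X.shape[1]
    bread = np.zeros((k, k))
    meat = np.zeros((k, k))
    for g in model.group_labels:
        idx = model.row_indices[g]
        Xg = X[idx]
        rg = y[idx] - Xg @ beta
        Vg = s2 * np.eye(len(idx))
        if Z is not None and D.size:
            Zg = Z[idx]
            Vg = Vg + Zg @ D @ Zg.T
        Wg = np.linalg.solve(Vg, np.column_stack([Xg, rg]))
        XtW = Xg.T @ Wg[:, :k]
        score = Xg.T @ Wg[:, k]
        bread += XtW
        meat += np.outer(score, score)
    bread_inv = np.linalg.pinv(bread)
    return bread_inv @ meat @ bread_inv


def _tidy(res, p_method: str = "cluster") -> pd.DataFrame:
    df_resid = res.nobs - np.linalg.matrix_rank(res.model.exog)
    if p_method == "cluster":
        rcov = _cluster_robust_cov(res)
        ses = np.sqrt(np.clip(np.diag(rcov), 0.0, None))
        df_t = max(len(res.model.group_labels) - 1, 1)
    elif p_method == "residual":
        ses = np.asarray(res.bse_fe)
        df_t = df_resid
    else:
        raise ValueError("p_method must be 'cluster' or 'residual'")
    out = []
    for i, term in enumerate(res.fe_params.index):
        B = float(res.fe_params[term])
        se = float(ses[i])
        t = B / se if se > 0 else np.nan
        p = 2 * stats.t.sf(abs(t), df_t) if np.isfinite(t) else np.nan
        d = effect_size(B, t, df_resid) if np.isfinite(t) else np.nan
        out.append({"term": term, "B": B, "se": se, "t": t, "df": df_t, "p": p, "d": d})
    return pd.DataFrame(out)


def _group_phase_contrasts(est: pd.DataFrame) -> pd.DataFrame:
    """Rows for arm x phase two-way terms (contrasts at the reference
    levels of every other factor)."""
    keep = est["term"].str.contains("arm") & est["term"].str.contains("phase")
    keep &= ~est["term"].str.contains("activity_type")
    keep &= ~est["term"].str.contains("variability_type")
    sub = est[keep].copy()
    sub["term"] = [
        "lithium:" + t.split("[T.")[-1].rstrip("]") for t in sub["term"]
    ]
    return sub.reset_index(drop=True)


def _prep_categories(df: pd.DataFrame, activity_reference: str) -> pd.DataFrame:
    df = df.copy()
    df["arm"] = pd.Categorical(df["arm"], categories=["placebo", "lithium"])
    df["phase"] = pd.Categorical(df["phase"], categories=list(PHASES))
    at_levels = [activity_reference] + [a for a in ("M10", "L5") if a != activity_reference]
    df["activity_type"] = pd.Categorical(df["activity_type"], categories=at_levels)
    return df


def fit_activity_model(
    table: pd.DataFrame,
    role: str = "level",
    activity_reference: str = "M10",
    weekday_covariate: bool = False,
    p_method: str = "cluster",
) -> ModelFit:
    """Three-way (arm x activity_type x phase) REML model for M10/L5 levels
    (or onset times, ``role='onset'``), with a by-participant random
    intercept and random activity-type slope.

    The returned contrasts are the arm x phase interactions at the
    reference activity type, i.e. the treatment effect per week relative
    to placebo and run-in; relevel via ``activity_reference`` for the
    other activity type.
    """
    df = table[table["role"] == role].dropna(subset=["value"])
    if df["id"].nunique() < 4 or df.empty:
        raise ValueError("need at least 2 participants per arm with data")
    df = _prep_categories(df, activity_reference)
    formula = (
        "value ~ arm * activity_type * phase + " + _covariate_terms(df, weekday_covariate)
    )
    res, converged, caught = _fit(formula, df, re_formula="~activity_type")
    est = _tidy(res, p_method=p_method)
    return ModelFit(
        formula=formula,
        estimates=est,
        contrasts=_group_phase_contrasts(est),
        converged=converged,
        warnings=caught,
        result=res,
    )


def fit_variability_model(
    table: pd.DataFrame,
    activity_reference: str = "M10",
    variability_reference: str = "volatility",
    weekday_covariate: bool = False,
    source: str = "level",
    p_method: str = "cluster",
) -> ModelFit:
    """Four-way model for filter-derived variability: volatility and noise
    of M10 and L5 (levels by default; ``source='onset'`` for onset-time
    variability) share one model with activity-type and variability-type
    factors.  Contrasts are reported at the chosen reference combination
    (headline: M10 volatility)."""
    df = table[(table["role"].isin(["volatility", "noise"])) & (table["source"] == source)]
    df = df.dropna(subset=["value"])
    if df.empty:
        raise ValueError("no volatility/noise rows present (run the filter first)")
    df = df.rename(columns={"role": "variability_type"})
    df = _prep_categories(df, activity_reference)
    v_levels = [variability_reference] + [
        v for v in ("volatility", "noise") if v != variability_reference
    ]
    df["variability_type"] = pd.Categorical(df["variability_type"], categories=v_levels)
    formula = (
        "value ~ arm * activity_type * variability_type * phase + "
        + _covariate_terms(df, weekday_covariate)
    )
    res, converged, caught = _fit(formula, df, re_formula="~activity_type")
    est = _tidy(res, p_method=p_method)
    return ModelFit(
        formula=formula,
        estimates=est,
        contrasts=_group_phase_contrasts(est),
        converged=converged,
        warnings=caught,
        result=res,
    )


def fit_rhythm_model(
    rhythm_table: pd.DataFrame,
    outcome: str,
    weekday_covariate: bool = False,
    p_method: str = "cluster",
) -> ModelFit:
    """Random-intercept model for a per-period rhythmicity outcome
    (``ra``, ``is`` or ``iv``): value ~ arm * phase + covariates + (1|id)."""
    col = {"ra": "ra", "is": "is_", "iv": "iv", "is_": "is_"}[outcome.lower()]
    df = rhythm_table.dropna(subset=[col]).copy()
    if df["phase"].nunique() < 2:
        raise ValueError("phase contrast not estimable from a single period")
    df["value"] = df[col]
    df["arm"] = pd.Categorical(df["arm"], categories=["placebo", "lithium"])
    df["phase"] = pd.Categorical(
        df["phase"], categories=[p for p in PHASES if p in set(df["phase"])]
    )
    formula = "value ~ arm * phase + " + _covariate_terms(df, weekday_covariate)
    res, converged, caught = _fit(formula, df, re_formula=None)
    est = _tidy(res, p_method=p_method)
    return ModelFit(
        formula=formula,
        estimates=est,
        contrasts=_group_phase_contrasts(est),
        converged=converged,
        warnings=caught,
        result=res,
    )


# ---------------------------------------------------------------------------
# correlations
# ---------------------------------------------------------------------------

def within_subject_correlation(
    paired: pd.DataFrame, var_a: str, var_b: str
) -> CorrelationResult:
    """Correlation proxy between two daily variables across time.

    Both variables are z-scored over all rows, then ``var_b ~ var_a`` is
    fitted with a per-participant random intercept; the standardized
    fixed slope approximates the pooled within-subject Pearson r.
    """
    df = paired[["id", var_a, var_b]].dropna()
    counts = df.groupby("id").size()
    if (counts >= 3).sum() == 0:
        raise ValueError("no participant has >= 3 paired observations")
    za = (df[var_a] - df[var_a].mean()) / df[var_a].std(ddof=0)
    zb = (df[var_b] - df[var_b].mean()) / df[var_b].std(ddof=0)
    work = pd.DataFrame({"id": df["id"].to_numpy(), "za": za.to_numpy(), "zb": zb.to_numpy()})
    if np.allclose(work["za"], work["zb"]):
        return CorrelationResult(
            pair=(var_a, var_b), beta=1.0, se=0.0, p=0.0, n=len(work), degenerate=True
        )
    res, _, _ = _fit("zb ~ za", work, re_formula=None)
    beta = float(res.fe_params["za"])
    se = float(res.bse_fe["za"])
    dfree = res.nobs - 2
    p = 2 * stats.t.sf(abs(beta / se), dfree) if se > 0 else 0.0
    return CorrelationResult(pair=(var_a, var_b), beta=beta, se=se, p=p, n=len(work))


def change_score_correlation(
    table: pd.DataFrame,
    measure_a: str,
    measure_b: str,
    covariates: pd.DataFrame | None = None,
) -> dict:
    """Partial correlation between per-participant week-4 change scores.

    Measures are ``"<activity_type>.<role>"`` strings (e.g. ``"M10.level"``,
    ``"M10.volatility"``); each participant's delta is the week-4 mean
    minus the run-in mean of that row set.  ``covariates`` is a per-id
    frame (e.g. age, sex, season) partialled out of both deltas;
    categorical covariates are dummy-coded.  Returns r, t, p, n.
    """
    def deltas(measure: str) -> pd.Series:
        at, role = measure.split(".")
        sub = table[(table["activity_type"] == at) & (table["role"] == role)]
        piv = sub.pivot_table(index="id", columns="phase", values="value", aggfunc="mean")
        if "run-in" not in piv or "week4" not in piv:
            raise ValueError(f"missing run-in or week4 summaries for {measure}")
        return (piv["week4"] - piv["run-in"]).dropna()

    da, db = deltas(measure_a), deltas(measure_b)
    ids = da.index.intersection(db.index)
    if len(ids) < 5:
        raise ValueError("fewer than 5 participants with both change scores")
    data = pd.DataFrame({"delta_a": da[ids], "delta_b": db[ids]})
    covs: list[str] = []
    if covariates is not None and len(covariates.columns):
        cv = covariates.set_index("id").loc[ids] if "id" in covariates else covariates.loc[ids]
        cv = pd.get_dummies(cv, drop_first=True).astype(float)
        cv = cv.loc[:, cv.std(ddof=0) > 0]
        data = data.join(cv)
        covs = list(cv.columns)
    if covs:
        import pingouin as pg

        out = pg.partial_corr(
            data=data.reset_index(drop=True), x="delta_a", y="delta_b", covar=covs
        )
        r = float(out["r"].iloc[0])
        pcol = "p_val" if "p_val" in out.columns else "p-val"
        p = float(out[pcol].iloc[0])
    else:  # null covariate set: plain Pearson correlation
        r, p = stats.pearsonr(data["delta_a"], data["delta_b"])
        r, p = float(r), float(p)
    n = len(ids)
    dfree = n - 2 - len(covs)
    t = r * math.sqrt(dfree / max(1 - r**2, 1e-12)) if dfree > 0 else np.nan
    return {"r": r, "t": t, "p": p, "n": n, "df": dfree}
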