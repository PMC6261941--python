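"""Participant QC, single-trial regression suite, and post-error summaries.

All binary task factors are coded -1/+1 (congruent/incongruent,
correct/error, close/far, short/long interval, left/right hand), matching
the convention of the regression equations, so that flipping a factor's
coding flips only that coefficient's sign.  Within-participant regressions
use robust (bisquare) linear models for RT-like responses and
maximum-likelihood logistic models for binary responses; group-level
inference applies one-sample t-tests to the per-participant t-values with
Bonferroni correction over the regressor family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

#: bisquare tuning constant giving 95% Gaussian efficiency
BISQUARE_C = 4.685


# ---------------------------------------------------------------------------
# participant QC

@dataclass
class OutlierResult:
    flagged: np.ndarray     # boolean, one per participant
    cutoff: float           # realised decision threshold (nan if undefined)
    n_iterations: int


def detect_noncompliant(rates: np.ndarray, alpha: float = 0.01,
                        side: str = "upper") -> OutlierResult:
    """Iterative one-sided Grubbs test on per-participant rates.

    At each step the most extreme remaining value is tested against the
    critical studentised deviation at ``alpha``; flagged values are
    removed and the test repeated until no outlier remains.  Returns the
    flags and the realised cutoff (the critical threshold of the final
    iteration).  Constant input yields no outliers and an undefined
    cutoff.
    """
    rates = np.asarray(rates, float)
    n_total = len(rates)
    if n_total < 3:
        raise ValueError("Grubbs test needs at least 3 participants")
    active = np.ones(n_total, bool)
    flagged = np.zeros(n_total, bool)
    cutoff = np.nan
    it = 0
    while active.sum() >= 3:
        x = rates[active]
        n = len(x)
        sd = x.std(ddof=1)
        if sd == 0:
            break
        mean = x.mean()
        t_crit = stats.t.ppf(1 - alpha / n, n - 2)
        g_crit = (n - 1) / np.sqrt(n) * np.sqrt(t_crit**2 / (n - 2 + t_crit**2))
        cutoff_here = mean + g_crit * sd if side == "upper" else mean - g_crit * sd
        if side == "upper":
            i = np.flatnonzero(active)[np.argmax(x)]
            g = (rates[i] - mean) / sd
        else:
            i = np.flatnonzero(active)[np.argmin(x)]
            g = (mean - rates[i]) / sd
        cutoff = cutoff_here
        if g > g_crit:
            flagged[i] = True
            active[i] = False
            it += 1
        else:
            break
    if not flagged.any() and np.isnan(cutoff):
        pass  # constant data: cutoff stays undefined
    return OutlierResult(flagged=flagged, cutoff=float(cutoff), n_iterations=it)


# ---------------------------------------------------------------------------
# design construction

def _pm1(series: pd.Series, positive) -> np.ndarray:
    return np.where(series == positive, 1.0, -1.0)


def _factor_columns(df: pd.DataFrame) -> dict[str, np.ndarray]:
    cols: dict[str, np.ndarray] = {}
    if "congruent" in df:
        cols["incongruence"] = _pm1(df["congruent"], False)
    if "correct" in df:
        cols["error"] = _pm1(df["correct"], False)
    if "distance" in df:
        cols["distance"] = _pm1(df["distance"], "far")
    if "rsi" in df:
        r = df["rsi"]
        cols["rsi"] = _pm1(r, r.max()) if r.dtype != object else _pm1(r, "long")
    if "prev_accuracy" in df:
        cols["prev_accuracy"] = df["prev_accuracy"].to_numpy(float)
    if "trials_since_break" in df:
        cols["nld"] = -np.log1p(df["trials_since_break"].to_numpy(float))
    if "trial" in df:
        cols["trial"] = np.log(df["trial"].to_numpy(float))
    if "rt" in df:
        with np.errstate(invalid="ignore", divide="ignore"):
            cols["log_rt"] = np.log(df["rt"].to_numpy(float))
    if "hand" in df:
        cols["hand"] = df["hand"].to_numpy(float)
    if "following_rsi" in df:
        fr = df["following_rsi"].to_numpy(float)
        cols["following_rsi"] = np.where(fr == np.nanmax(fr), 1.0, -1.0)
    if "prev_congruent" in df:
        cols["prev_congruence"] = _pm1(df["prev_congruent"], False)
    # model internals (within-model regression)
    if "z_t" in df and "choice" in df:
        z = df["z_t"].to_numpy(float)
        ch = df["choice"].to_numpy(float)
        cols["sp"] = z
        cols["sp_resp"] = z * ch
        cols["sp_abs"] = np.abs(z)
    for src, name in (("v_t", "drift"), ("f_t", "flanker_weighting"),
                      ("ter_t", "ter")):
        if src in df:
            cols[name] = df[src].to_numpy(float)
    return cols


#: regressor sets of the single-trial regression equations
EQUATIONS: dict[str, dict] = {
    "eq1": {"x": ["incongruence", "error", "distance", "rsi", "prev_accuracy",
                  "nld", "trial"], "y": "log_rt"},
    "eq2": {"x": ["incongruence", "distance", "rsi", "prev_accuracy", "nld",
                  "trial"], "y": "accuracy"},
    "eq4": {"x": ["sp", "sp_resp", "sp_abs", "drift", "flanker_weighting",
                  "ter", "incongruence"], "y": None},
    "eq5": {"x": ["v", "a", "ter", "f"], "y": "trial_type"},
    "eq6": {"x": ["hand", "incongruence", "distance", "rsi", "following_rsi",
                  "trial", "log_rt"], "y": None},
    "eq7": {"x": ["incongruence", "error", "distance", "rsi", "prev_accuracy",
                  "nld", "trial", "log_rt"], "y": None},
}


def build_design(trials: pd.DataFrame, equation_id: str,
                 options: dict | None = None
                 ) -> tuple[pd.DataFrame, pd.Series | None]:
    """Intercept-plus-regressors design matrix for one equation.

    Rows with missing required values (misses, first trial after a break
    for the history equations) are dropped.  Returns (X, y); y is None
    for the equations whose response (beta power, lateralisation
    threshold) is supplied by the caller.
    """
    options = options or {}
    if equation_id not in EQUATIONS:
        raise KeyError(f"unknown equation {equation_id!r}")
    eq = EQUATIONS[equation_id]
    names = list(eq["x"])
    if options.get("previous_congruence") and equation_id in ("eq1", "eq2"):
        names.append("prev_congruence")
    df = trials
    if equation_id in ("eq1", "eq2", "eq7"):
        if "first_of_block" in df:
            df = df.loc[~df["first_of_block"].astype(bool)]
        if "miss" in df:
            df = df.loc[~df["miss"].astype(bool)]
    if equation_id == "eq4" and "miss" in df:
        df = df.loc[~df["miss"].astype(bool)]

    if equation_id == "eq5":
        cols = {n: df[n].to_numpy(float) for n in names if n in df}
    else:
        cols = _factor_columns(df)
    missing = [n for n in names if n not in cols]
    if missing:
        raise KeyError(f"missing columns for {equation_id}: {missing}")
    X = pd.DataFrame({n: cols[n] for n in names}, index=df.index)
    ok = np.isfinite(X.to_numpy(float)).all(axis=1)
    X = X.loc[ok]
    df = df.loc[X.index]
    for n in names:
        if X[n].nunique() <= 1:
            warnings.warn(f"regressor {n} is constant; design is rank deficient")
    X.insert(0, "intercept", 1.0)

    y: pd.Series | None = None
    if eq["y"] == "log_rt":
        y = pd.Series(np.log(df["rt"].to_numpy(float)), index=X.index,
                      name="log_rt")
    elif eq["y"] == "accuracy":
        y = df["correct"].astype(int).rename("accuracy")
    elif eq["y"] == "trial_type" and "trial_type" in df:
        y = df["trial_type"].astype(int).rename("trial_type")
    return X, y


# ---------------------------------------------------------------------------
# regression engines

@dataclass
class RegressionResult:
    names: list[str]
    coef: np.ndarray
    tvalues: np.ndarray
    method: str
    n_obs: int
    resid_scale: float = np.nan
    flags: list[str] = field(default_factory=list)

    def coef_named(self) -> pd.Series:
        return pd.Series(self.coef, index=self.names)

    def t_named(self) -> pd.Series:
        return pd.Series(self.tvalues, index=self.names)


def _drop_rank_deficient(X: pd.DataFrame) -> pd.DataFrame:
    keep = [c for c in X.columns
            if c == "intercept" or X[c].nunique() > 1]
    dropped = set(X.columns) - set(keep)
    if dropped:
        warnings.warn(f"dropping constant regressors: {sorted(dropped)}")
    return X[keep]


def robust_regress(design: pd.DataFrame, y) -> RegressionResult:
    """Iteratively-reweighted least squares with a bisquare weight
    function (tuning constant 4.685) and MAD scale."""
    X = _drop_rank_deficient(design)
    yv = np.asarray(y, float)
    if len(yv) <= X.shape[1]:
        raise ValueError("need more observations than regressors")
    model = sm.RLM(yv, X.to_numpy(float),
                   M=sm.robust.norms.TukeyBiweight(c=BISQUARE_C))
    res = model.fit(scale_est="mad")
    return RegressionResult(names=list(X.columns), coef=np.asarray(res.params),
                            tvalues=np.asarray(res.tvalues), method="robust",
                            n_obs=len(yv), resid_scale=float(res.scale))


def ordinary_regress(design: pd.DataFrame, y) -> RegressionResult:
    X = _drop_rank_deficient(design)
    res = sm.OLS(np.asarray(y, float), X.to_numpy(float)).fit()
    return RegressionResult(names=list(X.columns), coef=np.asarray(res.params),
                            tvalues=np.asarray(res.tvalues), method="ordinary",
                            n_obs=int(res.nobs),
                            resid_scale=float(np.sqrt(res.scale)))


def logistic_regress(design: pd.DataFrame, y_binary) -> RegressionResult:
    """Maximum-likelihood logit with Wald t-values.

    Perfect separation is flagged and the coefficients come from a
    lightly ridge-penalised refit instead of raising.
    """
    X = _drop_rank_deficient(design)
    yv = np.asarray(y_binary)
    classes = np.unique(yv)
    if len(classes) != 2:
        raise ValueError("response must have exactly two classes")
    yv = (yv == classes.max()).astype(float)
    flags: list[str] = []
    Xv = X.to_numpy(float)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(yv, Xv).fit(disp=0, maxiter=200)
            if not res.mle_retvals.get("converged", True):
                flags.append("not_converged")
            coef, tv = np.asarray(res.params), np.asarray(res.tvalues)
        except Exception:
            res = sm.Logit(yv, Xv).fit_regularized(alpha=1e-3, disp=0,
                                                   maxiter=500)
            coef = np.asarray(res.params)
            tv = np.full_like(coef, np.nan)
            flags.append("perfect_separation")
    cap = 50.0
    if np.any(np.abs(coef) > cap):
        coef = np.clip(coef, -cap, cap)
        flags.append("capped_coefficients")
    return RegressionResult(names=list(X.columns), coef=coef, tvalues=tv,
                            method="logistic", n_obs=len(yv), flags=flags)


# ---------------------------------------------------------------------------
# group-level inference

@dataclass
class GroupTest:
    table: pd.DataFrame      # per-regressor mean t, group t, p, significant
    family_size: int
    alpha: float
    n_participants: int


def group_level_test(per_participant: pd.DataFrame,
                     family_size: int | None = None,
                     alpha: float = 0.05) -> GroupTest:
    """Two-sided one-sample t-tests of per-participant values (typically
    within-participant t-values) against zero, Bonferroni-corrected over
    the regressor family."""
    df = pd.DataFrame(per_participant)
    if len(df) < 2:
        raise ValueError("need at least two participants")
    family = family_size or df.shape[1]
    rows = []
    for col in df.columns:
        vals = df[col].to_numpy(float)
        vals = vals[np.isfinite(vals)]
        sd = vals.std(ddof=1)
        if sd == 0:
            t = np.inf if vals.mean() != 0 else 0.0
            p = 0.0 if vals.mean() != 0 else 1.0
            flag = "zero_variance"
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
            flag = ""
        rows.append({"regressor": col, "mean_value": vals.mean(),
                     "group_t": float(t), "p": float(p),
                     "significant": bool(p < alpha / family), "flag": flag})
    return GroupTest(table=pd.DataFrame(rows).set_index("regressor"),
                     family_size=family, alpha=alpha,
                     n_participants=len(df))


# ---------------------------------------------------------------------------
# model-internal regression (within-model analysis)

def within_model_regression(sim: pd.DataFrame
                            ) -> tuple[RegressionResult, RegressionResult]:
    """Regress simulated accuracy and log RT on the trial-wise realised
    model parameters (start point raw / response-rectified / absolute,
    drift, flanker weighting, non-decision time, incongruence).

    Returns (accuracy model, RT model); accuracy is logistic, RT robust.
    The RT model is restricted to trials with a response.
    """
    X, _ = build_design(sim, "eq4")
    sub = sim.loc[X.index]
    acc = logistic_regress(X, sub["correct"].astype(int))
    rt = robust_regress(X, np.log(sub["rt"].to_numpy(float)))
    return acc, rt


# ---------------------------------------------------------------------------
# post-error behavioural summaries

@dataclass
class PostErrorSummary:
    pes_ms: float    # post-error slowing: median RT difference
    peri_ms: float   # post-error reduction of interference
    pia: float       # post-error increase in incongruent accuracy
    n_posterror: int
    flags: list[str] = field(default_factory=list)


def posterror_summaries(dataset: pd.DataFrame) -> PostErrorSummary:
    """PES, PERI and PIA from a trial table.

    RT quantities use correct trials and within-split medians (in ms);
    interference is incongruent minus congruent RT.  First trials of a
    block (undefined history) and misses are excluded.
    """
    df = dataset
    if "first_of_block" in df:
        df = df.loc[~df["first_of_block"].astype(bool)]
    df = df.loc[~df["miss"].astype(bool)] if "miss" in df else df
    pe = df["prev_accuracy"] == 1
    flags: list[str] = []
    n_pe = int(pe.sum())
    if n_pe == 0:
        return PostErrorSummary(np.nan, np.nan, np.nan, 0, ["no_posterror_trials"])
    corr = df["correct"].astype(bool)
    cong = df["congruent"].astype(bool)
    rt = df["rt_ms"] if "rt_ms" in df else df["rt"] * 1000.0

    def med(mask) -> float:
        vals = rt[mask]
        return float(vals.median()) if len(vals) else np.nan

    pes = med(corr & pe) - med(corr & ~pe)
    interf_pc = med(corr & ~pe & ~cong) - med(corr & ~pe & cong)
    interf_pe = med(corr & pe & ~cong) - med(corr & pe & cong)
    peri = interf_pc - interf_pe
    pia = float(corr[pe & ~cong].mean() - corr[~pe & ~cong].mean())
    for name, v in (("pes", pes), ("peri", peri), ("pia", pia)):
        if not np.isfinite(v):
            flags.append(f"{name}_undefined")
    return PostErrorSummary(pes_ms=float(pes), peri_ms=float(peri), pia=pia,
                            n_posterror=n_pe, flags=flags)


def across_participant_regression(param_table: pd.DataFrame,
                                  participant_factor) -> RegressionResult:
    """Ordinary multiple regression of a per-participant behavioural
    scalar on the eight fitted diffusion parameters."""
    names = [c for c in ("v", "sv", "a", "sz", "ter", "st", "f", "sf")
             if c in param_table.columns]
    X = param_table[names].copy()
    cond = np.linalg.cond(np.c_[np.ones(len(X)), X.to_numpy(float)])
    if cond > 1e8:
        warnings.warn(f"ill-conditioned parameter design (cond={cond:.2g})")
    X.insert(0, "intercept", 1.0)
    return ordinary_regress(X, participant_factor)
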