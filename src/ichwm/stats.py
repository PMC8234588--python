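"""Cohort-level statistics for longitudinal FA>0.5 tables.

The statistical layer mirrors a small-cohort longitudinal imaging analysis:

* mean ± SD summaries per location × day;
* paired t-tests for within-subject change across days (complete cases);
* ordinary least-squares regression of white-matter loss on hematoma size;
* ANCOVA (slope-homogeneity F-test) comparing those regressions across
  timepoints;
* a linear mixed model with fixed effects for location (4 levels) and day
  (3 levels, categorical), an optional location × day interaction and a
  random intercept per subject (variance-components covariance), fit by
  REML;
* Bonferroni-adjusted pairwise location contrasts (m = 6 for four
  locations).

Fixed-effect tests use Wald F statistics with containment denominator
degrees of freedom (observations − fixed-effect rank − (subjects − 1)), a
small-sample convention that keeps the location test close to its nominal
size in cohorts of a dozen subjects. All tests are two-tailed at α = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

LOCATION_LEVELS = ("contralateral_sphere", "ipsilateral_sphere", "perilesion", "lesion")


@dataclass(frozen=True)
class PairedTResult:
    t: float
    df: int
    p_value: float
    n: int
    mean_difference: float
    zero_variance: bool = False


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_value: float       # two-tailed test of the slope
    n: int


@dataclass(frozen=True)
class AncovaResult:
    f: float
    p_value: float
    df_num: int
    df_den: int


@dataclass(frozen=True)
class BonferroniThreshold:
    alpha: float
    m: int
    threshold: float          # full precision alpha / m
    threshold_4dp: float      # as conventionally printed

    def __float__(self):
        return self.threshold


@dataclass
class MixedModelResult:
    fixed_effects: pd.DataFrame        # term, estimate, se
    tests: dict                        # effect -> dict(F, df_num, df_den, p)
    contrasts: pd.DataFrame            # pairwise location contrasts, Bonferroni-adjusted
    random_intercept_sd: float
    residual_sd: float
    n_obs: int
    n_subjects: int
    converged: bool
    singular: bool
    m_comparisons: int = 6


def summarize_by_location_day(table: pd.DataFrame,
                              value: str = "fa_gt_pct") -> pd.DataFrame:
    """Mean ± SD (n−1 denominator) and n per location × day cell.

    Cells with a single observation report SD as NaN (undefined), never 0.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    g = table.groupby(["location", "day"])[value]
    out = g.agg(mean="mean", sd=lambda v: v.std(ddof=1) if len(v) > 1 else np.nan,
                n="count").reset_index()
    return out


def paired_t_test(x, y) -> PairedTResult:
    """Two-tailed paired t-test, t = mean(d) / (SD(d)/√n), df = n − 1.

    Degenerate cases are reported explicitly: identical pairs give t = 0,
    p = 1; a constant nonzero difference gives an infinite t with p = 0 and
    the ``zero_variance`` flag set.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1D arrays")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = x.size
    if n < 2:
        raise ValueError("paired t-test needs at least 2 complete pairs")
    d = x - y
    md = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if md == 0:
            return PairedTResult(0.0, df, 1.0, n, 0.0)
        return PairedTResult(float(np.sign(md)) * np.inf, df, 0.0, n, float(md),
                             zero_variance=True)
    t = md / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df)
    return PairedTResult(float(t), df, float(p), n, float(md))


def linear_regression(x, y) -> RegressionResult:
    """OLS of y on x with a two-tailed slope test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("regression needs at least 3 finite pairs")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return RegressionResult(
        slope=float(res.params[1]), intercept=float(res.params[0]),
        r_squared=float(res.rsquared), p_value=float(res.pvalues[1]), n=int(x.size),
    )


def ancova_compare_slopes(groups: dict) -> AncovaResult:
    """Slope-homogeneity ANCOVA across labeled (x, y) groups.

    F-tests the group × covariate interaction in the pooled linear model
    ``y ~ x + group + x:group`` against the common-slope reduction.
    """
    if len(groups) < 2:
        raise ValueError("ANCOVA needs at least 2 groups")
    frames = []
    for label, (x, y) in groups.items():
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        keep = np.isfinite(x) & np.isfinite(y)
        x, y = x[keep], y[keep]
        if x.size < 3:
            raise ValueError(f"group {label!r} has fewer than 3 finite pairs")
        if np.ptp(x) == 0:
            raise ValueError(f"group {label!r} has zero x-variance")
        frames.append(pd.DataFrame({"x": x, "y": y, "g": str(label)}))
    data = pd.concat(frames, ignore_index=True)
    full = smf.ols("y ~ x * C(g)", data=data).fit()
    reduced = smf.ols("y ~ x + C(g)", data=data).fit()
    f, p, df_num = full.compare_f_test(reduced)
    return AncovaResult(float(f), float(p), int(df_num), int(full.df_resid))


def bonferroni_threshold(alpha: float, m: int) -> BonferroniThreshold:
    """Per-comparison significance threshold α / m for m comparisons."""
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    if m < 1:
        raise ValueError("m must be a positive integer")
    thr = alpha / m
    return BonferroniThreshold(alpha, int(m), thr, round(thr, 4))


def _wald_f(result, names: list[str], ddf: int):
    """Joint Wald F-test that the named fixed effects are all zero."""
    beta = result.fe_params[names].to_numpy()
    cov = result.cov_params().loc[names, names].to_numpy()
    q = len(names)
    w = float(beta @ np.linalg.solve(cov, beta))
    f = w / q
    return {"F": f, "df_num": q, "df_den": int(ddf), "p": float(sps.f.sf(f, q, ddf))}


def mixed_model_location_time(table: pd.DataFrame,
                              include_day: bool = True,
                              include_interaction: bool = False,
                              value: str = "fa_gt_pct",
                              alpha: float = 0.05) -> MixedModelResult:
    """Random-intercept mixed model of FA>0.5 percentage on location (× day).

    Location (and optionally day, both categorical) enter as fixed effects;
    each subject contributes a random intercept (variance-components
    structure). Estimation is REML. Wald F tests are reported per effect
    and all C(4,2) = 6 pairwise location contrasts are Bonferroni-adjusted.
    A fit whose random-intercept variance collapses to ~0 is flagged
    singular rather than silently accepted.
    """
    required = {"subject_id", "location", value}
    if include_day:
        required.add("day")
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    data = table.dropna(subset=[value]).copy()
    if data["subject_id"].nunique() < 2:
        raise ValueError("mixed model needs at least 2 subjects")
    if include_day and data["day"].nunique() < 2:
        include_day = False        # a single timepoint has no day effect
        if include_interaction:
            raise ValueError("interaction requires at least 2 distinct days")
    if data.groupby("subject_id")["location"].nunique().max() < 2:
        raise ValueError("mixed model needs at least 2 locations within a subject")

    levels = [l for l in LOCATION_LEVELS if l in set(data["location"])]
    data["location"] = pd.Categorical(data["location"], categories=levels)

    rhs = f"C(location, Treatment(reference='{levels[0]}'))"
    terms = [rhs]
    if include_day:
        terms.append("C(day)")
    if include_interaction:
        if not include_day:
            raise ValueError("interaction requires the day effect")
        terms.append(f"{rhs}:C(day)")
    formula = f"{value} ~ " + " + ".join(terms)

    model = smf.mixedlm(formula, data=data, groups=data["subject_id"])
    import warnings as _warnings
    with _warnings.catch_warnings():
        # optimizer retries / flat-likelihood warnings are reflected in the
        # converged/singular flags instead of leaking to the caller
        _warnings.simplefilter("ignore")
        result = model.fit(reml=True)

    n_obs = int(result.nobs)
    n_sub = int(data["subject_id"].nunique())
    k_fe = len(result.fe_params)
    ddf = max(n_obs - k_fe - (n_sub - 1), 1)

    names = list(result.fe_params.index)
    loc_names = [n for n in names if n.startswith("C(location") and ":" not in n]
    tests = {"location": _wald_f(result, loc_names, ddf)}
    if include_day:
        day_names = [n for n in names if n.startswith("C(day)") and ":" not in n]
        tests["day"] = _wald_f(result, day_names, ddf)
    if include_interaction:
        int_names = [n for n in names if ":" in n]
        tests["location:day"] = _wald_f(result, int_names, ddf)

    # pairwise location contrasts from the treatment-coded coefficients
    coef = {levels[0]: 0.0}
    se_cov = result.cov_params()
    full_names = {lvl: f"C(location, Treatment(reference='{levels[0]}'))[T.{lvl}]"
                  for lvl in levels[1:]}
    for lvl, nm in full_names.items():
        coef[lvl] = float(result.fe_params[nm])

    def _contrast_var(a, b):
        va = vb = cab = 0.0
        if a in full_names:
            va = float(se_cov.loc[full_names[a], full_names[a]])
        if b in full_names:
            vb = float(se_cov.loc[full_names[b], full_names[b]])
        if a in full_names and b in full_names:
            cab = float(se_cov.loc[full_names[a], full_names[b]])
        return va + vb - 2.0 * cab

    pairs = list(itertools.combinations(levels, 2))
    m = len(pairs)
    rows = []
    for a, b in pairs:
        est = coef[a] - coef[b]
        se = float(np.sqrt(_contrast_var(a, b)))
        tstat = est / se if se > 0 else 0.0
        p = 2.0 * sps.t.sf(abs(tstat), ddf) if se > 0 else 1.0
        rows.append({"contrast": f"{a} - {b}", "estimate": est, "se": se,
                     "t": tstat, "df": ddf, "p": p,
                     "p_bonferroni": min(1.0, p * m),
                     "significant": p < alpha / m})
    contrasts = pd.DataFrame(rows)

    re_var = float(np.asarray(result.cov_re).ravel()[0])
    singular = (not result.converged) or re_var < 1e-10
    fe = pd.DataFrame({"term": names,
                       "estimate": result.fe_params.to_numpy(),
                       "se": result.bse_fe.to_numpy()})
    return MixedModelResult(
        fixed_effects=fe, tests=tests, contrasts=contrasts,
        random_intercept_sd=float(np.sqrt(max(re_var, 0.0))),
        residual_sd=float(np.sqrt(result.scale)),
        n_obs=n_obs, n_subjects=n_sub,
        converged=bool(result.converged), singular=bool(singular),
        m_comparisons=m,
    )
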