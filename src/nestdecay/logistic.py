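"""Retrospective single-revisit decay estimation by logistic regression.

Mark-and-revisit protocol: each nest is marked (at construction) and
revisited once; its status at revisit is binary -- Decayed (0) if the
revisit falls after the known decay date, Alive (1) otherwise.  A logistic
regression of status on age at revisit,

    P(alive at age t) = 1 / (1 + exp(-(a + b t))),    b < 0,

yields the mean decay time as the area under the fitted curve,

    mean decay = integral_0^inf p(t) dt = log(1 + exp(a)) / (-b),

i.e. the expected persistence time of a nest.  Scenario builders derive the
single-revisit snapshots from longitudinal ground truth; bootstrap
resampling of nest groups gives confidence intervals, and group-subsampling
experiments probe how small a monitoring effort can get before the estimate
destabilises.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import ValidationError

__all__ = [
    "SCENARIOS",
    "MethodInvalidError",
    "SeparationError",
    "LogisticFit",
    "build_scenario",
    "fit_logistic",
    "mean_decay_from_logistic",
    "mean_decay_numerical",
    "bootstrap_mean_decay",
    "subsample_experiment",
]

# Revisit-timing scenarios; offsets are calendar days.
SCENARIOS = {
    "two_weeks_after_last": 14,
    "one_month_after_last": 30,
    "three_months_after_last": 91,
    "three_months_after_each": 91,
    "random_7_360": None,
}


class MethodInvalidError(ValueError):
    """The revisit scenario leaves no nest in one of the status classes, so
    the retrospective method cannot be applied."""


class SeparationError(ValueError):
    """The statuses are perfectly separated by age; the ML fit diverges."""


@dataclass
class LogisticFit:
    """Fitted survival-versus-age logistic curve."""

    intercept: float
    slope: float
    mean_decay: float
    converged: bool
    n_records: int


def build_scenario(ages: pd.DataFrame, scenario: str, seed: int = 0,
                   unit: str = "group",
                   visit_interval_days: int = 7) -> pd.DataFrame:
    """Reduce longitudinal monitoring truth to single-revisit records.

    Parameters
    ----------
    ages : DataFrame
        Columns ``nest_id, group_id, age_days, censored``; decayed nests'
        ``age_days`` is the known decay age, censored nests' a lower bound.
    scenario : one of ``SCENARIOS``
        ``*_after_last`` scenarios revisit every nest a fixed offset after
        the *last* group was marked; ``three_months_after_each`` revisits 91
        days after each group's own marking; ``random_7_360`` draws an
        independent uniform offset in [7, 360] days per group (or per nest
        with ``unit="nest"``).
    unit : {"group", "nest"}
        Resolution of the random offset.  Groups are marked together, so the
        default draws one offset per group.

    Censored nests whose censoring age precedes their revisit age have an
    unknown status and are dropped with a warning.

    Because the scenarios are defined by *ages* at revisit (offsets from
    each nest's own marking date, or from the latest marking), the
    construction calendar dates themselves are not needed: a nest marked on
    day m and revisited on day r has age r - m at revisit.  For the
    ``*_after_last`` scenarios the marking spread enters through the ages
    table's ``mark_offset_days`` column when present (days between each
    group's marking and the last group's marking), else all groups are
    treated as marked simultaneously.
    """
    if scenario not in SCENARIOS:
        raise ValidationError(f"unknown scenario {scenario!r}; choose from "
                              f"{sorted(SCENARIOS)}")
    df = ages.copy()
    required = {"nest_id", "group_id", "age_days", "censored"}
    if not required <= set(df.columns):
        raise ValidationError(f"ages table needs columns {sorted(required)}")
    if "mark_offset_days" not in df.columns:
        df["mark_offset_days"] = 0
    rng = np.random.default_rng(seed)
    last_to_revisit = SCENARIOS[scenario]
    if scenario == "three_months_after_each":
        # Revisit at the first shared weekly field visit on/after each
        # group's marking + 91 days; the shared visit calendar spreads the
        # realized ages over [91, 91 + interval).
        target = df["mark_offset_days"] + 91
        iv = max(1, int(visit_interval_days))
        revisit_cal = iv * np.ceil(target / iv).astype(int)
        df["age_at_revisit"] = revisit_cal - df["mark_offset_days"]
    elif scenario == "random_7_360":
        if unit == "group":
            groups = df["group_id"].unique()
            offs = dict(zip(groups, rng.integers(7, 361, size=len(groups))))
            df["age_at_revisit"] = df["group_id"].map(offs)
        elif unit == "nest":
            df["age_at_revisit"] = rng.integers(7, 361, size=len(df))
        else:
            raise ValidationError("unit must be 'group' or 'nest'")
    else:
        # Revisit happens `offset` days after the LAST group was marked:
        # a group marked earlier has a correspondingly older nest at revisit.
        lag = df["mark_offset_days"].max() - df["mark_offset_days"]
        df["age_at_revisit"] = last_to_revisit + lag
    df["age_at_revisit"] = df["age_at_revisit"].astype(int)

    known = ~df["censored"] | (df["age_at_revisit"] <= df["age_days"])
    n_dropped = int((~known).sum())
    if n_dropped:
        warnings.warn(f"{n_dropped} censored nests dropped: censored before "
                      "their scenario revisit, status unknown", stacklevel=2)
    df = df[known].copy()
    df["status"] = (df["age_at_revisit"] <= df["age_days"]).astype(int)
    out = df[["nest_id", "group_id", "age_at_revisit", "status"]].reset_index(
        drop=True)
    if out.empty or out["status"].nunique() < 2:
        n_alive = int(out["status"].sum()) if not out.empty else 0
        raise MethodInvalidError(
            f"scenario {scenario!r} leaves {n_alive} alive of {len(out)} "
            "nests: method invalid (needs both statuses at revisit)")
    return out


def fit_logistic(records: pd.DataFrame) -> LogisticFit:
    """Maximum-likelihood logistic regression of status on age at revisit.

    Raises :class:`SeparationError` on complete separation instead of
    returning silently huge coefficients, and :class:`MethodInvalidError`
    when only one status is present.
    """
    import statsmodels.api as sm
    from statsmodels.tools.sm_exceptions import PerfectSeparationError

    if len(records) < 2:
        raise ValidationError("need at least 2 records")
    y = records["status"].to_numpy(dtype=float)
    t = records["age_at_revisit"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise MethodInvalidError("all nests share one status; cannot fit")
    if np.ptp(t) == 0:
        raise MethodInvalidError("no variation in age at revisit; the "
                                 "survival-versus-age curve is undefined")
    # Complete separation: every alive nest younger than every decayed one
    # (or vice versa) with no overlap.
    if t[y == 1].max() < t[y == 0].min() or t[y == 0].max() < t[y == 1].min():
        raise SeparationError("statuses perfectly separated by age")
    X = sm.add_constant(t)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = sm.GLM(y, X, family=sm.families.Binomial()).fit(tol=1e-10)
    except PerfectSeparationError as exc:  # pragma: no cover - pre-checked
        raise SeparationError("statuses perfectly separated by age") from exc
    a, b = float(res.params[0]), float(res.params[1])
    converged = bool(res.converged)
    # A slope indistinguishable from zero (or positive) carries no decay
    # signal; the implied mean would be meaningless, so flag it as NaN.
    mean = mean_decay_from_logistic(a, b) if b < -1e-8 else float("nan")
    return LogisticFit(intercept=a, slope=b, mean_decay=mean,
                       converged=converged, n_records=len(records))


def mean_decay_from_logistic(intercept: float, slope: float) -> float:
    """Mean decay time (days): closed form log(1 + exp(a)) / (-b).

    The integrand ``1/(1 + exp(-(a + b t)))`` has antiderivative
    ``log(1 + exp(a + b t)) / b``, giving the softplus form at the limits.
    """
    if slope >= 0:
        raise ValidationError("non-decaying fit (slope >= 0): infinite mean")
    return float(np.logaddexp(0.0, intercept) / (-slope))


def mean_decay_numerical(intercept: float, slope: float) -> float:
    """Adaptive numerical integration of the fitted curve; cross-check for
    the closed form."""
    from scipy.integrate import quad

    if slope >= 0:
        raise ValidationError("non-decaying fit (slope >= 0): infinite mean")

    def p(t: float) -> float:
        return 1.0 / (1.0 + np.exp(-(intercept + slope * t)))

    upper = (intercept + 50.0) / (-slope)  # p(t) < ~2e-22 beyond here
    val, _ = quad(p, 0.0, max(upper, 1.0), limit=200)
    return float(val)


def bootstrap_mean_decay(records: pd.DataFrame, n_boot: int = 500,
                         unit: str = "group", seed: int = 0) -> dict:
    """Bootstrap the mean-decay estimate.

    Resamples with replacement at the nest-group level by default (nests in
    a group share construction night and weather exposure; resampling
    individual nests would understate variance).  Failed replicates (one
    status only, separation) are recorded, never silently dropped.

    Returns a dict with the point estimate, the replicate estimates, a
    percentile 95% CI, and a failure taxonomy.
    """
    rng = np.random.default_rng(seed)
    point = fit_logistic(records).mean_decay
    if unit == "group":
        keys = records["group_id"].unique()
        grouped = {g: sub for g, sub in records.groupby("group_id")}
        if len(keys) < 2:
            raise ValidationError("need >= 2 groups for group bootstrap")
    elif unit == "nest":
        keys = records["nest_id"].to_numpy()
    else:
        raise ValidationError("unit must be 'group' or 'nest'")
    estimates, failures = [], []
    for rep in range(n_boot):
        pick = rng.choice(keys, size=len(keys), replace=True)
        if unit == "group":
            sample = pd.concat([grouped[g] for g in pick], ignore_index=True)
        else:
            sample = records.set_index("nest_id").loc[pick].reset_index()
        try:
            estimates.append(fit_logistic(sample).mean_decay)
        except (MethodInvalidError, SeparationError, ValidationError) as exc:
            failures.append({"replicate": rep, "reason": type(exc).__name__})
    est = np.asarray(estimates, dtype=float)
    ok = est[np.isfinite(est)]
    n_nan = int((~np.isfinite(est)).sum())
    if len(failures) + n_nan > 0.2 * n_boot:
        taxonomy = pd.Series([f["reason"] for f in failures]).value_counts() \
            .to_dict()
        taxonomy["NoDecaySignal"] = n_nan
        warnings.warn(
            f"{len(failures) + n_nan} of {n_boot} bootstrap replicates "
            f"unusable ({taxonomy})", stacklevel=2)
    ci = (float(np.percentile(ok, 2.5)), float(np.percentile(ok, 97.5))) \
        if ok.size else (float("nan"), float("nan"))
    return {"estimate": point, "replicates": est, "ci_low": ci[0],
            "ci_high": ci[1], "n_failed": len(failures), "failures": failures}


def subsample_experiment(records: pd.DataFrame,
                         fractions=(0.75, 0.5, 0.25), n_draws: int = 10,
                         n_boot: int = 500, seed: int = 0) -> pd.DataFrame:
    """Group-subsampling robustness experiment.

    For each fraction, draws ``n_draws`` random subsets of nest groups
    (without replacement within a draw), analyses each by logistic fit plus
    group bootstrap, and tabulates the estimates.  Fraction 1.0 reproduces
    the full-data estimate.  Draws whose subset cannot be fitted are marked
    failed rather than dropped.
    """
    groups = records["group_id"].unique()
    if len(groups) < 4:
        raise ValidationError("need >= 4 groups for subsampling")
    rng = np.random.default_rng(seed)
    rows = []
    for frac in fractions:
        size = max(2, int(round(frac * len(groups))))
        for draw in range(n_draws if frac < 1.0 else 1):
            chosen = rng.choice(groups, size=size, replace=False) \
                if frac < 1.0 else groups
            sub = records[records["group_id"].isin(chosen)]
            row = {"fraction": frac, "draw": draw, "n_groups": size,
                   "n_nests": len(sub)}
            try:
                boot = bootstrap_mean_decay(sub, n_boot=n_boot,
                                            seed=seed + 1000 * draw + 1)
                row.update(mean_decay=boot["estimate"],
                           ci_low=boot["ci_low"], ci_high=boot["ci_high"],
                           failed=False)
            except (MethodInvalidError, SeparationError, ValidationError):
                row.update(mean_decay=float("nan"), ci_low=float("nan"),
                           ci_high=float("nan"), failed=True)
            rows.append(row)
    return pd.DataFrame(rows)
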