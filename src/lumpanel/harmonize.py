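"""Outcome harmonization, cohort pooling, non-mover restriction, imputation.

Two questionnaire instruments are harmonized to the common outcome
"average minutes per week of walking (cycling)":

* SQUASH-style items report days/week and minutes/day.  Respondents who
  reported a duration but omitted days are assumed active at least 1 day;
  respondents who reported days without a duration get the cohort median
  minutes/day substituted.
* LAPAQ-style items report sessions and minutes/session over the last two
  weeks; minutes/week is sessions * minutes/session / 2.

The analysis sample is restricted to persons observed in every wave whose
residence did not change (non-movers), covariate missingness is handled by
chained-equations multiple imputation, and the two cohorts are pooled with
the cohort label retained as a covariate.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.imputation.mice import MICEData

from lumpanel.errors import ValidationError

logger = logging.getLogger(__name__)

RESIDENCE_TOL_M = 1.0  # geocoding jitter absorbed when comparing addresses

#: covariates and auxiliaries used as predictors in the imputation model
IMPUTATION_VARS = [
    "sex",
    "education",
    "age",
    "marital_status",
    "income",
    "employment",
    "self_rated_health",
    "smoking",
    "bmi",
]

CATEGORICAL_COVARIATES = [
    "sex",
    "education",
    "marital_status",
    "income",
    "employment",
    "self_rated_health",
    "smoking",
]


@dataclass(frozen=True)
class SquashItem:
    """One SQUASH walking/cycling item; any field may be missing (None)."""

    days_per_week: float | None = None
    minutes_per_day: float | None = None
    minutes_per_week_direct: float | None = None


@dataclass(frozen=True)
class LapaqItem:
    """One LAPAQ item: frequency and duration over the last 2 weeks."""

    sessions_last_2wk: float
    minutes_per_session: float


def _is_missing(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def squash_minutes_per_week(
    item: SquashItem, cohort_median_min_per_day: float | None = None
) -> float:
    """Minutes/week from a SQUASH item, applying the instrument's rules.

    Complete item: days * minutes/day.  Duration without days: counted as
    one day of activity per week.  Days without duration: days * the
    cohort median minutes/day (computed over complete responders for the
    same wave and activity).  All fields missing: NaN.
    """
    days, mins, direct = (
        item.days_per_week,
        item.minutes_per_day,
        item.minutes_per_week_direct,
    )
    for name, v in (("days_per_week", days), ("minutes_per_day", mins),
                    ("minutes_per_week_direct", direct)):
        if not _is_missing(v) and v < 0:
            raise ValidationError(f"negative SQUASH field {name}: {v}")
    if not _is_missing(direct) and _is_missing(days) and _is_missing(mins):
        return float(direct)
    if not _is_missing(days) and not _is_missing(mins):
        return float(days) * float(mins)
    if _is_missing(days) and not _is_missing(mins):
        return float(mins)  # active at least 1 day/week
    if not _is_missing(days) and _is_missing(mins):
        if _is_missing(cohort_median_min_per_day):
            raise ValidationError(
                "days without duration requires a cohort median minutes/day"
            )
        return float(days) * float(cohort_median_min_per_day)
    return float("nan")


def lapaq_minutes_per_week(item: LapaqItem) -> float:
    """Minutes/week from a LAPAQ item: sessions * minutes/session / 2."""
    if item.sessions_last_2wk < 0 or item.minutes_per_session < 0:
        raise ValidationError("negative LAPAQ field")
    return float(item.sessions_last_2wk) * float(item.minutes_per_session) / 2.0


def squash_column(
    days: pd.Series, minutes: pd.Series, median_by: pd.Series | None = None
) -> pd.Series:
    """Vectorized SQUASH harmonization for a panel column pair.

    ``median_by`` optionally stratifies the median substitute (wave and
    activity are separate calls; this groups within those, e.g. by wave);
    when None one unstratified median is used.
    """
    complete = days.notna() & minutes.notna()
    if median_by is None:
        med = pd.Series(minutes[complete].median(), index=days.index)
    else:
        med = (
            minutes[complete]
            .groupby(median_by[complete])
            .median()
            .reindex(median_by)
            .set_axis(days.index)
        )
    out = pd.Series(np.nan, index=days.index, dtype=float)
    out[complete] = days[complete] * minutes[complete]
    only_minutes = days.isna() & minutes.notna()
    out[only_minutes] = minutes[only_minutes]
    only_days = days.notna() & minutes.isna()
    out[only_days] = days[only_days] * med[only_days]
    return out


def filter_nonmovers(
    panel: pd.DataFrame,
    required_waves: tuple[int, ...] = (1, 2, 3),
    residence_tol_m: float = RESIDENCE_TOL_M,
) -> tuple[pd.DataFrame, dict]:
    """Keep persons observed at every wave from one unchanged residence.

    Returns the filtered panel and exclusion counts by rule (incomplete
    follow-up first, then relocation), for sample-flow accounting.
    """
    need = {"person_id", "wave_id", "res_x", "res_y"}
    if not need <= set(panel.columns):
        raise ValidationError(f"panel lacks columns {sorted(need - set(panel.columns))}")
    counts = {"persons_in": int(panel["person_id"].nunique())}
    by_person = panel.groupby("person_id")["wave_id"].agg(set)
    complete_ids = set(by_person[by_person.apply(lambda s: set(required_waves) <= s)].index)
    counts["excluded_incomplete_followup"] = counts["persons_in"] - len(complete_ids)
    sub = panel[panel["person_id"].isin(complete_ids)]

    def _stationary(g: pd.DataFrame) -> bool:
        dx = g["res_x"].max() - g["res_x"].min()
        dy = g["res_y"].max() - g["res_y"].min()
        return math.hypot(dx, dy) <= residence_tol_m

    stays = sub.groupby("person_id")[["res_x", "res_y"]].apply(
        lambda g: _stationary(g)
    )
    kept_ids = set(stays[stays].index)
    counts["excluded_movers"] = len(complete_ids) - len(kept_ids)
    counts["persons_kept"] = len(kept_ids)
    out = panel[panel["person_id"].isin(kept_ids)].reset_index(drop=True)
    return out, counts


def pool_cohorts(panel_a: pd.DataFrame, panel_b: pd.DataFrame) -> pd.DataFrame:
    """Concatenate two harmonized cohort panels.

    Both panels must share the harmonized schema (including the common
    4-level income coding); ``cohort_id`` is retained so models can adjust
    for study.
    """
    if panel_b.empty:
        logger.warning("pool_cohorts: second panel is empty; pooled = first")
        return panel_a.copy()
    cols_a, cols_b = set(panel_a.columns), set(panel_b.columns)
    if cols_a != cols_b:
        raise ValidationError(
            f"schema mismatch: only in A {sorted(cols_a - cols_b)}, "
            f"only in B {sorted(cols_b - cols_a)}"
        )
    for col in ("income",):
        if col in cols_a:
            codes_a = set(pd.unique(panel_a[col].dropna()))
            codes_b = set(pd.unique(panel_b[col].dropna()))
            if not (codes_a | codes_b) <= {1, 2, 3, 4}:
                raise ValidationError(
                    f"income codings conflict: {sorted(codes_a)} vs {sorted(codes_b)}; "
                    "map both cohorts onto the shared 4-level coding first"
                )
    if set(panel_a["person_id"]) & set(panel_b["person_id"]):
        raise ValidationError("person_id collision between cohorts")
    return pd.concat([panel_a, panel_b], ignore_index=True)


def enforce_time_invariant(panel: pd.DataFrame, cols=("sex", "education")) -> pd.DataFrame:
    """Fix time-invariant covariates at their baseline (first-wave) value."""
    out = panel.sort_values(["person_id", "wave_id"]).copy()
    for col in cols:
        if col in out.columns:
            out[col] = out.groupby("person_id")[col].transform("first")
    return out.reset_index(drop=True)


def impute_missing(
    panel: pd.DataFrame,
    m: int = 5,
    seed: int = 0,
    n_burn: int = 5,
    variables: list[str] | None = None,
) -> list[pd.DataFrame]:
    """Chained-equations multiple imputation of covariates.

    Produces ``m`` completed copies of the panel.  Only covariates are
    imputed (outcomes and exposures must be complete for included rows);
    predictive mean matching keeps categorical codes valid because imputed
    values are drawn from observed donors.  ``seed`` fixes the chain.
    """
    if m < 1:
        raise ValidationError("m must be >= 1")
    variables = [v for v in (variables or IMPUTATION_VARS) if v in panel.columns]
    work = panel[variables].copy().astype(float)
    miss_frac = work.isna().mean()
    for var, frac in miss_frac.items():
        if frac == 1.0:
            raise ValidationError(f"variable {var!r} is entirely missing; cannot impute")
        if frac > 0.5:
            logger.warning("variable %r has %.0f%% missing", var, 100 * frac)
    if not work.isna().any().any():
        if m == 1:
            logger.warning("impute_missing: m = 1 gives no between-imputation variance")
        return [panel.copy() for _ in range(m)]
    rng_state = np.random.get_state()
    np.random.seed(seed % (2**31))
    try:
        md = MICEData(work)
        md.update_all(n_burn)
        completed = []
        for _ in range(m):
            md.update_all(1)
            filled = panel.copy()
            for var in variables:
                filled[var] = md.data[var].to_numpy()
            completed.append(filled)
    finally:
        np.random.set_state(rng_state)
    if m == 1:
        logger.warning("impute_missing: m = 1 gives no between-imputation variance")
    for df in completed:
        assert not df[variables].isna().any().any()
    return completed


def missingness_report(panel: pd.DataFrame, variables=None) -> pd.Series:
    """Per-variable missing fractions for the imputation log."""
    variables = [v for v in (variables or IMPUTATION_VARS) if v in panel.columns]
    return panel[variables].isna().mean()
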