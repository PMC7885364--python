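"""Random-effects within-between (REWB / hybrid / Mundlak) model.

The time-varying exposure ``x_it`` (LUM per-10% units) is decomposed into a
person mean ``xbar_i`` and deviations ``x_it - xbar_i``; both enter a
linear mixed model with a person random intercept::

    PA_it = b0 + b1W (x_it - xbar_i) + b2B xbar_i + b3 Z_i + b4 g_it
            + v_i + eps_it

``b1W`` is the average within effect (outcome change when a person's own
exposure deviates from their mean), ``b2B`` the between effect (outcome
difference across persons with different average exposure).  Estimation is
REML by default, with Wald normal-approximation 95% intervals; results from
multiply imputed datasets are combined with Rubin's rules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.formula.api as smf

from lumpanel.errors import InestimableError, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_COVARIATES = (
    "C(cohort_id)",
    "C(sex)",
    "C(education)",
    "age",
    "C(employment)",
    "C(income)",
    "C(marital_status)",
)

Z975 = float(scipy.stats.norm.ppf(0.975))


@dataclass
class REWBResult:
    """Fixed effects, variance components and inference for one fit."""

    params: pd.Series  # point estimates by term name
    se: pd.Series
    var_v: float  # random-intercept variance
    var_eps: float  # residual variance
    n_persons: int
    n_person_observations: int
    converged: bool = True
    boundary_variance: bool = False
    spec_key: tuple = ()  # (outcome, sorted fixed-effect terms) for pooling

    @property
    def ci_low(self) -> pd.Series:
        return self.params - Z975 * self.se

    @property
    def ci_high(self) -> pd.Series:
        return self.params + Z975 * self.se

    @property
    def p_values(self) -> pd.Series:
        z = self.params / self.se
        return pd.Series(
            2 * scipy.stats.norm.sf(np.abs(z)), index=self.params.index
        )

    def summary_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "beta": self.params,
                "se": self.se,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_values,
            }
        )


def decompose_within_between(
    df: pd.DataFrame,
    exposure_col: str = "lum_scaled",
    person_col: str = "person_id",
) -> pd.DataFrame:
    """Split an exposure into person means and deviations.

    Adds ``<col>_bar`` (arithmetic mean over the person's observed waves)
    and ``<col>_dev`` (exact deviations, summing to zero within person).
    """
    if df.empty:
        raise ValidationError("empty analysis table")
    out = df.copy()
    bar = out.groupby(person_col)[exposure_col].transform("mean")
    out[f"{exposure_col}_bar"] = bar
    out[f"{exposure_col}_dev"] = out[exposure_col] - bar
    return out


def fit_rewb(
    df: pd.DataFrame,
    outcome: str,
    exposure_col: str = "lum_scaled",
    covariates: tuple[str, ...] = (),
    person_col: str = "person_id",
    reml: bool = True,
) -> REWBResult:
    """Fit the REWB linear mixed model with a person random intercept.

    ``df`` must already carry the decomposition columns ``<exposure>_dev``
    and ``<exposure>_bar``.  Degenerate fits with the random-intercept
    variance at the zero boundary are reported (flagged), not hidden.
    """
    dev, bar = f"{exposure_col}_dev", f"{exposure_col}_bar"
    for col in (outcome, dev, bar):
        if col not in df.columns:
            raise ValidationError(f"missing column {col!r}; run the decomposition first")
    wave_counts = df.groupby(person_col).size()
    if (wave_counts >= 2).sum() < 2:
        raise ValidationError("need >=2 persons with >=2 waves to separate variance components")
    if float(np.abs(df[dev]).max()) < 1e-12:
        raise InestimableError(
            "within-person exposure variance is zero for all persons; "
            "the within coefficient is inestimable"
        )
    rhs = " + ".join([dev, bar, *covariates])
    formula = f"{outcome} ~ {rhs}"
    model = smf.mixedlm(formula, data=df, groups=person_col, missing="drop")
    # rank check on the fixed-effects design, reporting aliased terms
    exog = model.exog
    names = model.exog_names
    rank = np.linalg.matrix_rank(exog)
    if rank < exog.shape[1]:
        q, r = np.linalg.qr(exog)
        aliased = [names[j] for j in range(exog.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValidationError(f"rank-deficient design; aliased terms: {aliased}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # boundary fits emit ConvergenceWarning
        try:
            fit = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=reml, method="powell")
        fe = fit.fe_params
        se = fit.bse_fe  # NaN for fully degenerate (noise-free) fits
    var_v = float(np.asarray(fit.cov_re)[0, 0])
    var_eps = float(fit.scale)
    boundary = var_v < 1e-8 * max(var_eps, 1.0)
    if boundary:
        logger.warning("random-intercept variance estimated at the zero boundary")
    return REWBResult(
        params=pd.Series(fe, index=model.exog_names),
        se=pd.Series(np.asarray(se)[: len(model.exog_names)], index=model.exog_names),
        var_v=var_v,
        var_eps=var_eps,
        n_persons=int(df[person_col].nunique()),
        n_person_observations=int(len(df)),
        converged=bool(fit.converged),
        boundary_variance=boundary,
        spec_key=(outcome, tuple(model.exog_names)),
    )


def rubin_pool(results: list[REWBResult], barnard_rubin: bool = False) -> REWBResult:
    """Combine estimates across imputations with Rubin's rules.

    Pooled estimate: mean of the m estimates.  Total variance: mean
    within-imputation variance plus (1 + 1/m) times the between-imputation
    variance.  Intervals use the normal approximation by default; the
    Barnard–Rubin small-sample degrees of freedom are available behind a
    flag (t reference instead of z).
    """
    if not results:
        raise ValidationError("no results to pool")
    m = len(results)
    spec = results[0].spec_key
    for r in results[1:]:
        if r.spec_key != spec:
            raise ValidationError("cannot pool results from different model specifications")
    if m == 1:
        logger.warning("rubin_pool: single imputation; between-imputation variance unknown")
        return results[0]
    est = pd.concat([r.params for r in results], axis=1)
    var_w = pd.concat([r.se**2 for r in results], axis=1)
    qbar = est.mean(axis=1)
    ubar = var_w.mean(axis=1)
    b = est.var(axis=1, ddof=1)
    total = ubar + (1.0 + 1.0 / m) * b
    se = np.sqrt(total)
    pooled = REWBResult(
        params=qbar,
        se=se,
        var_v=float(np.mean([r.var_v for r in results])),
        var_eps=float(np.mean([r.var_eps for r in results])),
        n_persons=results[0].n_persons,
        n_person_observations=results[0].n_person_observations,
        converged=all(r.converged for r in results),
        boundary_variance=any(r.boundary_variance for r in results),
        spec_key=spec,
    )
    if barnard_rubin:
        # Barnard-Rubin adjusted df with the complete-data df taken as
        # n_obs - n_params
        with np.errstate(divide="ignore", invalid="ignore"):
            r_frac = (1.0 + 1.0 / m) * b / ubar
            df_old = (m - 1) * (1.0 + 1.0 / r_frac) ** 2
            df_com = pooled.n_person_observations - len(qbar)
            lam = (1.0 + 1.0 / m) * b / total
            df_obs = (df_com + 1) / (df_com + 3) * df_com * (1 - lam)
            df_adj = 1.0 / (1.0 / df_old + 1.0 / df_obs)
        df_adj = df_adj.fillna(df_com)
        tcrit = pd.Series(scipy.stats.t.ppf(0.975, df_adj), index=qbar.index)
        pooled._t_crit = tcrit  # type: ignore[attr-defined]
    return pooled


def run_all_models(
    analysis: pd.DataFrame,
    outcomes: tuple[str, ...] = ("walk_min_wk", "cycle_min_wk"),
    buffer_sizes: tuple[float, ...] = (500.0, 1000.0, 1600.0),
    covariates: tuple[str, ...] = DEFAULT_COVARIATES,
    exposure_col: str = "lum_scaled",
    imputations: list[pd.DataFrame] | None = None,
    reml: bool = True,
) -> pd.DataFrame:
    """Fit every outcome x buffer-size cell and emit a tidy results table.

    ``analysis`` (or each imputed copy) must be in long format with a
    ``buffer_size_m`` column.  Output columns: outcome, buffer_size,
    effect_type in {within, between}, beta, ci_low, ci_high, p, plus the
    variance components and sample sizes; failed cells are marked and the
    run continues.
    """
    datasets = imputations if imputations is not None else [analysis]
    rows = []
    for outcome in outcomes:
        for size in buffer_sizes:
            subsets = [
                d[d["buffer_size_m"] == size].reset_index(drop=True) for d in datasets
            ]
            try:
                if any(s.empty for s in subsets):
                    raise InestimableError(f"no exposure data for buffer size {size}")
                fits = []
                for s in subsets:
                    s = decompose_within_between(s, exposure_col)
                    fits.append(
                        fit_rewb(
                            s,
                            outcome,
                            exposure_col,
                            covariates=covariates,
                            reml=reml,
                        )
                    )
                pooled = fits[0] if len(fits) == 1 else rubin_pool(fits)
            except Exception as exc:  # noqa: BLE001 - cell failures are data
                logger.warning("model cell (%s, %s) failed: %s", outcome, size, exc)
                for effect in ("within", "between"):
                    rows.append(
                        {
                            "outcome": outcome,
                            "buffer_size": size,
                            "effect_type": effect,
                            "beta": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                            "p": np.nan,
                            "var_v": np.nan,
                            "var_eps": np.nan,
                            "n_persons": 0,
                            "n_person_observations": 0,
                            "status": f"failed: {exc}",
                        }
                    )
                continue
            frame = pooled.summary_frame()
            for effect, term in (
                ("within", f"{exposure_col}_dev"),
                ("between", f"{exposure_col}_bar"),
            ):
                rows.append(
                    {
                        "outcome": outcome,
                        "buffer_size": size,
                        "effect_type": effect,
                        "beta": frame.loc[term, "beta"],
                        "ci_low": frame.loc[term, "ci_low"],
                        "ci_high": frame.loc[term, "ci_high"],
                        "p": frame.loc[term, "p"],
                        "var_v": pooled.var_v,
                        "var_eps": pooled.var_eps,
                        "n_persons": pooled.n_persons,
                        "n_person_observations": pooled.n_person_observations,
                        "status": "ok" if pooled.converged else "not converged",
                    }
                )
    return pd.DataFrame(rows)
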