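"""Posterior effect summaries: one-SD marginal effects in percentage points.

A "one-SD effect" is the change in the predicted mode share (in percentage
points, on the transit-excluded denominator) when one covariate moves up
by one standard deviation from a reference profile, holding the rest
fixed. The reference profile sets every standardized covariate to zero —
the pooled-sample mean — and uses each country's own intercept, so effects
differ across countries both through the country-varying slopes and
through the nonlinearity of the logistic link.

The "median-country" effect is the median of the per-country effects,
taken within each posterior draw and then summarized across draws.

The minimum-temperature covariate enters the model twice (linear and
squared on the raw °C scale), so its one-SD effect perturbs raw tmin and
moves both standardized columns coherently.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import expit

from .model import PosteriorDraws

logger = logging.getLogger(__name__)


@dataclass
class EffectSummary:
    """Posterior summary of a one-SD marginal effect (percentage points)."""

    covariate: str
    outcome: str
    country: str              # a country_id or "median-country"
    effect: float             # posterior mean
    lower: float              # 2.5% quantile
    upper: float              # 97.5% quantile
    baseline: str = "all covariates at pooled mean"

    def __post_init__(self):
        if not (self.lower <= self.effect <= self.upper):
            raise ValueError("effect summary interval must bracket the mean")


def _profiles(draws: PosteriorDraws, covariate: str) -> tuple[np.ndarray, np.ndarray]:
    """Baseline and +1 SD standardized city-covariate rows for one effect."""
    covs = draws.city_covariates
    if covariate not in covs:
        raise KeyError(f"{covariate!r} not among fitted city covariates {covs}")
    base = np.zeros(len(covs))
    pert = np.zeros(len(covs))
    if covariate == "tmin" and "tmin2" in covs:
        m, s = draws.registry["tmin"]
        m2, s2 = draws.registry["tmin2"]
        i, i2 = covs.index("tmin"), covs.index("tmin2")
        # perturb raw tmin by +1 SD; both columns move coherently
        base[i2] = (m ** 2 - m2) / s2
        pert[i] = 1.0
        pert[i2] = ((m + s) ** 2 - m2) / s2
    else:
        pert[covs.index(covariate)] = 1.0
    return base, pert


def _effect_draws_all_countries(draws: PosteriorDraws, covariate: str) -> np.ndarray:
    """(D, J) per-draw, per-country one-SD effects in percentage points."""
    base, pert = _profiles(draws, covariate)
    z = draws.z_terms                      # (D, J)
    eta_base = draws.alpha + draws.beta @ base + z
    eta_pert = draws.alpha + draws.beta @ pert + z
    return 100.0 * (expit(eta_pert) - expit(eta_base))


def _summarize(covariate, outcome, country, eff: np.ndarray) -> EffectSummary:
    lo, hi = np.percentile(eff, [2.5, 97.5])
    return EffectSummary(covariate=covariate, outcome=outcome, country=country,
                         effect=float(eff.mean()), lower=float(lo), upper=float(hi))


def marginal_effect(draws: PosteriorDraws, covariate: str, country_id: str) -> EffectSummary:
    """One-SD effect of ``covariate`` in a single country."""
    j = draws.country_pos(country_id)
    eff = _effect_draws_all_countries(draws, covariate)[:, j]
    return _summarize(covariate, draws.outcome, country_id, eff)


def country_effect(draws: PosteriorDraws, country_covariate: str) -> EffectSummary:
    """One-SD effect of a country-level covariate (single shared coefficient).

    Evaluated at the median-country baseline: per draw, the predictor at
    every country's intercept with city covariates at the pooled mean, the
    covariate shifted +1 SD, and the median of the per-country differences.
    """
    try:
        m = draws.country_covariates.index(country_covariate)
    except ValueError:
        raise KeyError(f"{country_covariate!r} not among fitted country covariates") from None
    z = draws.z_terms
    eta_base = draws.alpha + z
    eta_pert = eta_base + draws.delta[:, [m]]
    eff = np.median(100.0 * (expit(eta_pert) - expit(eta_base)), axis=1)
    return _summarize(country_covariate, draws.outcome, "median-country", eff)


def median_country_effect(draws: PosteriorDraws, covariate: str) -> EffectSummary:
    """One-SD effect of a city covariate in the median country."""
    if not draws.country_ids:
        raise ValueError("posterior has no countries")
    eff = np.median(_effect_draws_all_countries(draws, covariate), axis=1)
    return _summarize(covariate, draws.outcome, "median-country", eff)


def moderation_summary(draws: PosteriorDraws, covariate: str,
                       moderator: str = "ln_gdp_pc") -> dict:
    """How a country covariate moderates a city covariate's slope.

    Returns two complementary views:

    * ``"gamma1"`` — the model's own cross-level interaction coefficient
      (posterior mean and 95% credible interval), when ``moderator`` is a
      fitted moderator;
    * ``"descriptive"`` — an ordinary least-squares regression of the
      posterior-mean per-country effects (percentage points) on the
      standardized moderator, with slope, 95% confidence interval and R²,
      mirroring a scatter-of-country-coefficients presentation. With only
      two countries the regression has zero residual degrees of freedom
      and is flagged degenerate.
    """
    out: dict = {"covariate": covariate, "moderator": moderator}
    k = draws.city_covariates.index(covariate)
    if moderator in draws.moderators:
        g = draws.gamma1[:, k, draws.moderators.index(moderator)]
        lo, hi = np.percentile(g, [2.5, 97.5])
        out["gamma1"] = {"mean": float(g.mean()), "lower": float(lo), "upper": float(hi)}
    else:
        logger.warning("%r is not a fitted moderator; reporting the descriptive "
                       "regression only", moderator)

    eff = _effect_draws_all_countries(draws, covariate).mean(axis=0)  # (J,)
    zmod = draws.moderator_values(moderator)
    res = sm.OLS(eff, sm.add_constant(zmod)).fit()
    degenerate = res.df_resid <= 0
    if degenerate:
        ci = (float("nan"), float("nan"))
    else:
        ci = tuple(np.asarray(res.conf_int())[1])
    out["descriptive"] = {
        "slope": float(res.params[1]),
        "lower": float(ci[0]), "upper": float(ci[1]),
        "r_squared": float(res.rsquared),
        "n_countries": int(len(eff)),
        "degenerate": bool(degenerate),
    }
    return out


def effect_table(draws_by_outcome: dict[str, PosteriorDraws]) -> pd.DataFrame:
    """Median-country effect table for both outcomes, ordered by magnitude.

    City covariates contribute country-varying effects; country covariates
    a single shared coefficient each. Rows are ordered by the absolute
    median-country effect (descending), ties broken lexicographically by
    covariate name. An outcome missing from ``draws_by_outcome`` is
    omitted with a warning.
    """
    rows = []
    for outcome in ("walk", "cycle"):
        draws = draws_by_outcome.get(outcome)
        if draws is None:
            logger.warning("no posterior draws for outcome %r; omitting", outcome)
            continue
        for k in draws.city_covariates:
            rows.append(median_country_effect(draws, k))
        for m in draws.country_covariates:
            rows.append(country_effect(draws, m))
    if not rows:
        raise ValueError("no posterior draws supplied")
    df = pd.DataFrame([vars(e) for e in rows])
    df["abs_effect"] = df["effect"].abs()
    df = (df.sort_values(["outcome", "abs_effect", "covariate"],
                         ascending=[True, False, True])
            .drop(columns="abs_effect").reset_index(drop=True))
    return df


def country_effect_distribution(draws: PosteriorDraws, covariate: str) -> pd.DataFrame:
    """Posterior-mean one-SD effect per country (the coefficient spread)."""
    eff = _effect_draws_all_countries(draws, covariate)
    lo, hi = np.percentile(eff, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "country_id": draws.country_ids,
        "covariate": covariate,
        "outcome": draws.outcome,
        "effect": eff.mean(axis=0),
        "lower": lo,
        "upper": hi,
    })
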