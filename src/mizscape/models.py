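"""Random-intercept mixed models of dive characteristics.

Each model regresses one dive criterion (maximum depth, undulations, light,
edge distance, ...) on a single fixed covariate — distance to the fast ice
edge, or a fixed daily cosine peaking at 14:00 local solar time — with a
random intercept per individual penguin, fitted by REML.  Reported alongside
the Wald slope test are the marginal r-squared (variance explained by the
fixed effect over total variance), the random-intercept and residual
variances, and the lag-1 within-individual residual autocorrelation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "MixedModelFit",
    "diel_cosine",
    "solar_hour",
    "fit_random_intercept_model",
    "predict_fixed_effect",
    "dives_per_hour_table",
]

DIEL_PEAK_HOUR = 14.0  # local solar hour of the diel-cosine maximum


def solar_hour(timestamps, lon: float = 166.0):
    """Local solar hour-of-day for UTC timestamps at longitude ``lon``
    (decimal hours; 166 deg E is a +11.07 h offset)."""
    ts = pd.to_datetime(pd.Series(np.atleast_1d(timestamps)))
    hours = ts.dt.hour + ts.dt.minute / 60.0 + ts.dt.second / 3600.0
    out = (hours + lon / 15.0) % 24.0
    return out.to_numpy() if np.ndim(timestamps) else float(out.iloc[0])


def diel_cosine(local_hour):
    """Daily cosine covariate: cos(2*pi*(t - 14 h)/24 h), peaking at 14:00.

    Accepts hour-of-day floats (or arrays); bounded in [-1, 1] with a 24-h
    period, so one unit of the fitted coefficient is the peak-to-mean swing.
    """
    h = np.asarray(local_hour, dtype=float)
    val = np.cos(2.0 * np.pi * (h - DIEL_PEAK_HOUR) / 24.0)
    return float(val) if np.ndim(local_hour) == 0 else val


@dataclass
class MixedModelFit:
    """REML fit of criterion ~ fixed covariate + (1 | individual)."""

    criterion: str
    fixed: str
    coefficient: float
    se: float
    z: float
    p: float
    intercept: float
    marginal_r2: float
    var_intercept: float
    var_residual: float
    within_id_corr: float
    n_obs: int
    n_groups: int
    log_transformed: bool = False
    singular: bool = False

    @property
    def sd_intercept(self) -> float:
        return float(np.sqrt(self.var_intercept))

    @property
    def sd_residual(self) -> float:
        return float(np.sqrt(self.var_residual))


def fit_random_intercept_model(
    data: pd.DataFrame,
    criterion: str,
    fixed: str,
    group: str = "penguin_id",
    log_criterion: bool = False,
    log_fixed: bool = False,
    log_offset: float = 0.1,
) -> MixedModelFit:
    """Fit one dive criterion on one fixed covariate with a penguin random
    intercept (REML).

    ``log_criterion``/``log_fixed`` apply natural-log transforms (with
    ``log_offset`` added, for light counts and km distances that can be 0).
    Near-zero random-intercept variance is flagged ``singular`` rather than
    silently dropped.
    """
    df = data[[criterion, fixed, group]].dropna()
    if df[group].nunique() < 2:
        raise ValueError("need at least 2 individuals for a random intercept")
    y = df[criterion].to_numpy(dtype=float)
    x = df[fixed].to_numpy(dtype=float)
    if log_criterion:
        y = np.log(y + log_offset)
    if log_fixed:
        x = np.log(x + log_offset)

    exog = sm.add_constant(x)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, exog, groups=df[group].to_numpy())
        fit = model.fit(reml=True)

    coef = float(fit.fe_params[1])
    se = float(fit.bse_fe[1])
    zval = coef / se if se > 0 else np.nan
    pval = 2.0 * stats.norm.sf(abs(zval)) if np.isfinite(zval) else np.nan
    var_id = float(np.asarray(fit.cov_re)[0, 0])
    var_res = float(fit.scale)
    var_fixed = float(np.var(coef * x))
    denom = var_fixed + var_id + var_res
    marg_r2 = var_fixed / denom if denom > 0 else 0.0

    # lag-1 autocorrelation of conditional residuals within individuals
    resid = fit.resid
    corrs = []
    for _, g in pd.DataFrame({"g": df[group].to_numpy(), "r": resid}).groupby("g"):
        r = g["r"].to_numpy()
        if r.size >= 3 and np.std(r[:-1]) > 0 and np.std(r[1:]) > 0:
            corrs.append(np.corrcoef(r[:-1], r[1:])[0, 1])
    within_corr = float(np.mean(corrs)) if corrs else np.nan

    return MixedModelFit(
        criterion=criterion,
        fixed=fixed,
        coefficient=coef,
        se=se,
        z=float(zval),
        p=float(pval),
        intercept=float(fit.fe_params[0]),
        marginal_r2=float(marg_r2),
        var_intercept=var_id,
        var_residual=var_res,
        within_id_corr=within_corr,
        n_obs=len(df),
        n_groups=int(df[group].nunique()),
        log_transformed=log_criterion,
        singular=bool(var_id < 1e-8 * max(var_res, 1e-12)),
    )


def predict_fixed_effect(fit, delta_x: float) -> float:
    """Change in the criterion for a ``delta_x`` change in the fixed covariate.

    Only meaningful on untransformed criteria (a log-criterion fit raises:
    its coefficient lives on the log scale and needs a back-transform).
    Accepts a :class:`MixedModelFit` or a bare coefficient.
    """
    if isinstance(fit, MixedModelFit):
        if fit.log_transformed:
            raise ValueError(
                "criterion was log-transformed; back-transform explicitly instead"
            )
        coef = fit.coefficient
    else:
        coef = float(fit)
    return coef * delta_x


def dives_per_hour_table(dive_table: pd.DataFrame, group: str = "penguin_id"):
    """Dives per penguin-hour with the hour's mean diel covariate attached
    (the per-time-bin counting interpretation of a 'number of dives' model)."""
    df = dive_table.dropna(subset=["start_time"]).copy()
    df["hour_bin"] = pd.to_datetime(df["start_time"]).dt.floor("h")
    out = df.groupby([group, "hour_bin"]).size().rename("n_dives").reset_index()
    hours = pd.to_datetime(out["hour_bin"]).dt.hour + 0.5
    out["diel"] = diel_cosine(hours.to_numpy())
    return out
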