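"""Fecal glucocorticoid metabolite (FGM) response models.

Four hypothesized post-tagging response shapes are expressed as
piecewise regressions on day relative to collar fitting (day 0), fit by
MCMC, and compared by leave-one-out cross-validation scored with the
sum of squared held-out errors.

Response shapes (k1 = fixed 1-day gut-passage lag):

* ``none``        — constant baseline beta0.
* ``stress``      — step up by beta1 at k1, sustained.
* ``habituation`` — step up by beta1 at k1, then linear slope beta2 per day.
* ``handling``    — step up by beta1 at k1, full return to beta0 at an
  estimated second breakpoint k2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bayescore
from .bayescore import CVResult, FitError, MCMCSettings, ModelFit

__all__ = [
    "MODEL_TYPES",
    "DAY_RANGE",
    "FGMModelSpec",
    "FGMPriors",
    "align_and_window",
    "predict_response",
    "fit_model",
    "posterior_mean_prediction",
    "loo_cv_select",
]

MODEL_TYPES = ("none", "stress", "habituation", "handling")

#: Analysis window in days relative to collaring: 8 days prior through
#: 10 days after.
DAY_RANGE = (-8, 10)

_PARAMS = {
    "none": ["beta0", "sigma"],
    "stress": ["beta0", "beta1", "sigma"],
    "habituation": ["beta0", "beta1", "beta2", "sigma"],
    "handling": ["beta0", "beta1", "k2", "sigma"],
}


@dataclass(frozen=True)
class FGMModelSpec:
    """Parameter set for one response model (used for prediction)."""

    model_type: str
    beta0: float
    beta1: float = 0.0
    beta2: float = 0.0
    k1: float = 1.0
    k2: float | None = None

    def __post_init__(self) -> None:
        if self.model_type not in MODEL_TYPES:
            raise ValueError(f"unknown model_type {self.model_type!r}")
        if self.model_type == "handling":
            if self.k2 is None:
                raise ValueError("handling model requires k2")
            if not self.k2 > self.k1:
                raise ValueError("k2 must exceed k1")


@dataclass(frozen=True)
class FGMPriors:
    """Gaussian-likelihood priors; defaults are weakly informative.

    beta0 is centred on the observed data mean at fit time unless
    ``beta0_loc`` is set.
    """

    beta0_loc: float | None = None
    beta0_scale: float = 50.0
    beta1_scale: float = 25.0
    beta2_scale: float = 10.0
    sigma_scale: float = 25.0
    k2_upper: float | None = None  # defaults to max observed day


def align_and_window(
    samples: pd.DataFrame,
    collar_dates: dict[str, object] | pd.Series,
    control_date: object | None = None,
    day_range: tuple[int, int] = DAY_RANGE,
) -> pd.DataFrame:
    """Compute days relative to collaring and window to ``day_range``.

    ``samples`` needs columns ``individual``, ``group``, ``date`` (any
    pandas-parseable date) and ``fgm_ng_g``.  Treatment individuals are
    aligned to their own collar date; control individuals to the shared
    ``control_date`` (required if any controls are present).  Samples
    outside the closed window are dropped.
    """
    required = {"individual", "group", "date", "fgm_ng_g"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples missing columns: {sorted(missing)}")
    collar_dates = dict(collar_dates)

    out = samples.copy()
    dates = pd.to_datetime(out["date"])
    rel = np.empty(len(out), dtype=float)
    for i, (ind, grp, d) in enumerate(
        zip(out["individual"], out["group"], dates)
    ):
        if grp == "treatment":
            if ind not in collar_dates:
                raise ValueError(f"no collar date for treatment individual {ind!r}")
            origin = pd.to_datetime(collar_dates[ind])
        elif grp == "control":
            if ind in collar_dates:
                origin = pd.to_datetime(collar_dates[ind])
            elif control_date is not None:
                origin = pd.to_datetime(control_date)
            else:
                raise ValueError(
                    "control samples present but no control alignment date given"
                )
        else:
            raise ValueError(f"unknown group {grp!r} for individual {ind!r}")
        rel[i] = (d - origin).days
    out["rel_day"] = rel.astype(int)
    lo, hi = day_range
    out = out[(out["rel_day"] >= lo) & (out["rel_day"] <= hi)]
    return out.reset_index(drop=True)


def predict_response(spec: FGMModelSpec, rel_day) -> np.ndarray | float:
    """Expected FGM concentration (ng/g) under a response model.

    Vectorized over ``rel_day``; returns a scalar for scalar input.
    """
    day = np.asarray(rel_day, dtype=float)
    b0, b1, b2, k1 = spec.beta0, spec.beta1, spec.beta2, spec.k1
    if spec.model_type == "none":
        mu = np.full_like(day, b0)
    elif spec.model_type == "stress":
        mu = np.where(day < k1, b0, b0 + b1)
    elif spec.model_type == "habituation":
        mu = np.where(day < k1, b0, b0 + b1 + b2 * (day - k1))
    else:  # handling
        mu = np.where((day >= k1) & (day < spec.k2), b0 + b1, b0)
    return mu if mu.ndim else float(mu)


def _spec_from_theta(model_type: str, theta: np.ndarray, k1: float) -> FGMModelSpec:
    if model_type == "none":
        return FGMModelSpec("none", beta0=theta[0], k1=k1)
    if model_type == "stress":
        return FGMModelSpec("stress", beta0=theta[0], beta1=theta[1], k1=k1)
    if model_type == "habituation":
        return FGMModelSpec(
            "habituation", beta0=theta[0], beta1=theta[1], beta2=theta[2], k1=k1
        )
    return FGMModelSpec(
        "handling", beta0=theta[0], beta1=theta[1], k2=theta[2], k1=k1
    )


def _make_log_density(
    model_type: str,
    days: np.ndarray,
    values: np.ndarray,
    priors: FGMPriors,
    k1: float,
):
    b0_loc = priors.beta0_loc if priors.beta0_loc is not None else float(values.mean())
    k2_hi = priors.k2_upper if priors.k2_upper is not None else float(days.max())
    n = values.size

    def logp(theta: np.ndarray) -> float:
        sigma = theta[-1]
        if sigma <= 0:
            return -np.inf
        if model_type == "none":
            mu = np.full(n, theta[0])
            lprior = -0.5 * ((theta[0] - b0_loc) / priors.beta0_scale) ** 2
        elif model_type == "stress":
            mu = np.where(days < k1, theta[0], theta[0] + theta[1])
            lprior = (
                -0.5 * ((theta[0] - b0_loc) / priors.beta0_scale) ** 2
                - 0.5 * (theta[1] / priors.beta1_scale) ** 2
            )
        elif model_type == "habituation":
            mu = np.where(
                days < k1, theta[0], theta[0] + theta[1] + theta[2] * (days - k1)
            )
            lprior = (
                -0.5 * ((theta[0] - b0_loc) / priors.beta0_scale) ** 2
                - 0.5 * (theta[1] / priors.beta1_scale) ** 2
                - 0.5 * (theta[2] / priors.beta2_scale) ** 2
            )
        else:  # handling
            k2 = theta[2]
            if not (k1 < k2 <= k2_hi):
                return -np.inf
            mu = np.where((days >= k1) & (days < k2), theta[0] + theta[1], theta[0])
            lprior = (
                -0.5 * ((theta[0] - b0_loc) / priors.beta0_scale) ** 2
                - 0.5 * (theta[1] / priors.beta1_scale) ** 2
            )
        # half-normal prior on sigma
        lprior += -0.5 * (sigma / priors.sigma_scale) ** 2
        resid = values - mu
        llik = -n * np.log(sigma) - 0.5 * np.dot(resid, resid) / (sigma * sigma)
        return llik + lprior

    return logp, k2_hi


def fit_model(
    data: pd.DataFrame,
    model_type: str,
    settings: MCMCSettings,
    priors: FGMPriors | None = None,
    k1: float = 1.0,
) -> ModelFit:
    """Fit one response model by MCMC.

    ``data`` needs columns ``rel_day`` and ``fgm_ng_g``.  The handling
    model's recovery breakpoint k2 is sampled as a continuous parameter
    on (k1, max observed day].
    """
    if model_type not in MODEL_TYPES:
        raise ValueError(f"unknown model_type {model_type!r}")
    priors = priors or FGMPriors()
    days = np.asarray(data["rel_day"], dtype=float)
    values = np.asarray(data["fgm_ng_g"], dtype=float)
    if values.size < 2:
        raise FitError("need at least 2 samples")
    if model_type != "none":
        if not ((days < k1).any() and (days >= k1).any()):
            raise FitError(
                f"{model_type} model needs samples on both sides of the lag day k1={k1}"
            )
        if values.size < 4:
            raise FitError("breakpoint models need at least 4 samples")

    logp, k2_hi = _make_log_density(model_type, days, values, priors, k1)
    names = _PARAMS[model_type]
    sd0 = float(values.std(ddof=1)) if values.size > 1 else 1.0
    sd0 = max(sd0, 1e-3)
    init = {"beta0": float(values.mean()), "beta1": 0.0, "beta2": 0.0,
            "k2": (k1 + k2_hi) / 2.0, "sigma": sd0}
    x0 = np.array([init[p] for p in names])
    scales = {"beta0": max(sd0, 1.0), "beta1": max(sd0, 1.0), "beta2": 1.0,
              "k2": (k2_hi - k1) / 4.0, "sigma": sd0 / 2.0}
    s0 = np.array([scales[p] for p in names])
    return bayescore.sample_posterior(logp, x0, settings, names, init_scales=s0)


def posterior_mean_prediction(
    fit: ModelFit, model_type: str, rel_day, k1: float = 1.0
) -> np.ndarray | float:
    """Posterior-mean expected response at ``rel_day`` (draw-wise mean)."""
    day = np.atleast_1d(np.asarray(rel_day, dtype=float))
    theta = np.column_stack(
        [fit.stacked(p) for p in _PARAMS[model_type] if p != "sigma"]
    )
    preds = np.empty((theta.shape[0], day.size))
    b0 = theta[:, 0][:, None]
    if model_type == "none":
        preds[:] = b0
    elif model_type == "stress":
        b1 = theta[:, 1][:, None]
        preds = np.where(day[None, :] < k1, b0, b0 + b1)
    elif model_type == "habituation":
        b1, b2 = theta[:, 1][:, None], theta[:, 2][:, None]
        preds = np.where(day[None, :] < k1, b0, b0 + b1 + b2 * (day[None, :] - k1))
    else:
        b1, k2 = theta[:, 1][:, None], theta[:, 2][:, None]
        preds = np.where(
            (day[None, :] >= k1) & (day[None, :] < k2), b0 + b1, b0
        )
    out = preds.mean(axis=0)
    return out if np.ndim(rel_day) else float(out[0])


def loo_cv_select(
    data: pd.DataFrame,
    settings: MCMCSettings,
    model_types: tuple[str, ...] = MODEL_TYPES,
    priors: FGMPriors | None = None,
    k1: float = 1.0,
    holdout_indices: list[int] | None = None,
) -> CVResult:
    """Leave-one-out CV across candidate response models.

    For each model and held-out sample: refit on the remainder, predict
    the held-out value as the posterior-mean expected response at its
    day, accumulate the squared error.  The winner minimizes SSE.
    """
    n = len(data)
    if n < 5:
        raise ValueError("need at least 5 samples for model selection by LOO-CV")
    data = data.reset_index(drop=True)
    values = np.asarray(data["fgm_ng_g"], dtype=float)
    # freeze the k2 support and beta0 centring on the FULL dataset so
    # every held-out refit targets the same parameter space
    base_priors = priors or FGMPriors()
    if base_priors.k2_upper is None:
        base_priors = FGMPriors(
            beta0_loc=(
                base_priors.beta0_loc
                if base_priors.beta0_loc is not None
                else float(values.mean())
            ),
            beta0_scale=base_priors.beta0_scale,
            beta1_scale=base_priors.beta1_scale,
            beta2_scale=base_priors.beta2_scale,
            sigma_scale=base_priors.sigma_scale,
            k2_upper=float(data["rel_day"].max()),
        )

    sse: dict[str, float] = {}
    per_unit: dict[str, np.ndarray] = {}
    failed: dict[str, list[int]] = {}
    holdouts: list[int] = []
    for m, mtype in enumerate(model_types):
        def fit_without(i: int, unit_seed: int, _mtype=mtype) -> ModelFit:
            rest = data.drop(index=i)
            s = MCMCSettings(
                n_chains=settings.n_chains,
                n_iter=settings.n_iter,
                burn_in=settings.burn_in,
                thin=settings.thin,
                seed=unit_seed,
            )
            return fit_model(rest, _mtype, s, priors=base_priors, k1=k1)

        def predict(fit: ModelFit, i: int, _mtype=mtype) -> float:
            return float(
                posterior_mean_prediction(
                    fit, _mtype, float(data.loc[i, "rel_day"]), k1=k1
                )
            )

        res = bayescore.loo_cv(
            n,
            fit_without,
            predict,
            values,
            seed=settings.seed + 7919 * m,
            holdout_indices=holdout_indices,
            model_name=mtype,
        )
        sse[mtype] = res.sse[mtype]
        per_unit[mtype] = res.per_unit_errors[mtype]
        failed[mtype] = res.failed_units[mtype]
        holdouts = res.holdout_indices
    return CVResult(
        sse=sse,
        per_unit_errors=per_unit,
        failed_units=failed,
        n_units=n,
        holdout_indices=holdouts,
    )
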