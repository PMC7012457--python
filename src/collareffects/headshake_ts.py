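"""Binomial time-series models for post-collaring headshaking.

Hourly headshake counts y_t out of N_t accelerometer records are
modelled three ways, all sharing a logit-scale exponential decay of the
collaring effect:

* model 1 — ``logit(p_t) = a * exp(-b t) + c``
* model 2 — model 1 plus a daytime amplification exponent ``d``:
  ``p_t = phi_t`` at night, ``phi_t ** d`` during the day
* model 3 — mixture of two harmonic processes with mixture weight
  ``alpha_1t = exp(-b t)`` transferring from the post-collaring process
  to the baseline process

Derived quantities: the treatment-effect half-life ln(2)/b and the
percent treatment effect (handling - recovery) / recovery * 100.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import bayescore
from .bayescore import CVResult, FitError, MCMCSettings, ModelFit

__all__ = [
    "DecayModelParams",
    "HarmonicMixParams",
    "DerivedEffects",
    "TSPriors",
    "predict_p_model1",
    "predict_p_model2",
    "predict_p_model3",
    "fit_headshake_model",
    "half_life",
    "treatment_effect",
    "loo_cv_select_ts",
    "MODEL_PARAM_NAMES",
]

OMEGA_DEFAULT = 1.0 / 24.0

MODEL_PARAM_NAMES = {
    1: ["a", "b", "c"],
    2: ["a", "b", "c", "d"],
    3: ["mu1", "mu2", "U11", "U12", "U21", "U22", "b"],
}


@dataclass(frozen=True)
class DecayModelParams:
    """Parameters for models 1 and 2 (d is ignored by model 1)."""

    a: float
    b: float
    c: float
    d: float = 1.0

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("daytime exponent d must be positive")


@dataclass(frozen=True)
class HarmonicMixParams:
    """Parameters for the two-process harmonic mixture (model 3)."""

    mu1: float
    mu2: float
    U11: float = 0.0
    U12: float = 0.0
    U21: float = 0.0
    U22: float = 0.0
    b: float = 0.0
    omega: float = OMEGA_DEFAULT


@dataclass(frozen=True)
class TSPriors:
    loc_scale: float = 5.0  # a, c, mu_k
    harmonic_scale: float = 2.0  # U_kj
    decay_scale: float = 1.0  # half-normal on b
    log_d_sd: float = 0.5  # lognormal on d


@dataclass
class DerivedEffects:
    """Posterior summary of half-life and treatment effect for one fit."""

    half_life_draws: np.ndarray
    handling_rate_draws: np.ndarray
    recovery_rate_draws: np.ndarray
    treatment_effect_pct_draws: np.ndarray

    def summary(self) -> pd.DataFrame:
        rows = []
        for name, x in [
            ("half_life_h", self.half_life_draws),
            ("handling_rate", self.handling_rate_draws),
            ("recovery_rate", self.recovery_rate_draws),
            ("treatment_effect_pct", self.treatment_effect_pct_draws),
        ]:
            rows.append(
                {
                    "quantity": name,
                    "mean": float(np.mean(x)),
                    "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                    "median": float(np.median(x)),
                    "q2.5": float(np.quantile(x, 0.025)),
                    "q97.5": float(np.quantile(x, 0.975)),
                }
            )
        return pd.DataFrame(rows)


def predict_p_model1(params: DecayModelParams, t) -> np.ndarray | float:
    """p_t = inv-logit(a exp(-b t) + c)."""
    t = np.asarray(t, dtype=float)
    p = expit(params.a * np.exp(-params.b * t) + params.c)
    return p if p.ndim else float(p)


def predict_p_model2(params: DecayModelParams, t, is_day) -> np.ndarray | float:
    """Model 1 with the daytime probability raised to the power d."""
    t = np.asarray(t, dtype=float)
    phi = expit(params.a * np.exp(-params.b * t) + params.c)
    day = np.asarray(is_day, dtype=bool)
    p = np.where(day, phi**params.d, phi)
    return p if p.ndim else float(p)


def predict_p_model3(params: HarmonicMixParams, t) -> np.ndarray | float:
    """Two-process harmonic mixture with decaying weight on process 1."""
    t = np.asarray(t, dtype=float)
    a1 = np.exp(-params.b * t)
    a2 = 1.0 - a1
    w = 2.0 * np.pi * params.omega * t
    proc1 = params.mu1 + params.U11 * np.cos(w) + params.U12 * np.sin(w)
    proc2 = params.mu2 + params.U21 * np.cos(w) + params.U22 * np.sin(w)
    p = expit(a1 * proc1 + a2 * proc2)
    return p if p.ndim else float(p)


def half_life(b: float) -> float:
    """Hours for the decaying treatment effect to halve: ln(2)/b."""
    if b <= 0:
        raise ValueError("decay rate b must be positive")
    return float(np.log(2.0) / b)


def _series_arrays(series: pd.DataFrame) -> tuple[np.ndarray, ...]:
    required = {"t_hours", "y", "N"}
    missing = required - set(series.columns)
    if missing:
        raise ValueError(f"series missing columns: {sorted(missing)}")
    t = np.asarray(series["t_hours"], dtype=float)
    y = np.asarray(series["y"], dtype=float)
    n = np.asarray(series["N"], dtype=float)
    if np.any(y > n) or np.any(y < 0):
        raise ValueError("need 0 <= y <= N")
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_hours must be strictly increasing")
    day = (
        np.asarray(series["is_day"], dtype=bool)
        if "is_day" in series.columns
        else np.zeros(t.size, dtype=bool)
    )
    return t, y, n, day


def _binom_loglik(y: np.ndarray, n: np.ndarray, p: np.ndarray) -> float:
    p = np.clip(p, 1e-12, 1.0 - 1e-12)
    return float(np.sum(y * np.log(p) + (n - y) * np.log1p(-p)))


def _make_ts_log_density(
    model_type: int,
    t: np.ndarray,
    y: np.ndarray,
    n: np.ndarray,
    day: np.ndarray,
    priors: TSPriors,
    omega: float,
):
    w = 2.0 * np.pi * omega * t

    # b (and d) are sampled on the log scale: the decay rate's posterior
    # ridge is far closer to Gaussian there.  Priors stay on the natural
    # scale (half-normal on b, lognormal on d); the log|Jacobian| term
    # for b is +log_b.

    if model_type == 1:

        def logp(theta: np.ndarray) -> float:
            a, log_b, c = theta
            b = np.exp(log_b)
            p = expit(a * np.exp(-b * t) + c)
            lp = _binom_loglik(y, n, p)
            lp += -0.5 * (a / priors.loc_scale) ** 2
            lp += -0.5 * (c / priors.loc_scale) ** 2
            lp += -0.5 * (b / priors.decay_scale) ** 2 + log_b
            return lp

    elif model_type == 2:

        def logp(theta: np.ndarray) -> float:
            a, log_b, c, log_d = theta
            b = np.exp(log_b)
            phi = expit(a * np.exp(-b * t) + c)
            p = np.where(day, phi ** np.exp(log_d), phi)
            lp = _binom_loglik(y, n, p)
            lp += -0.5 * (a / priors.loc_scale) ** 2
            lp += -0.5 * (c / priors.loc_scale) ** 2
            lp += -0.5 * (b / priors.decay_scale) ** 2 + log_b
            # lognormal(0, log_d_sd) on d, i.e. Normal on log_d
            lp += -0.5 * (log_d / priors.log_d_sd) ** 2
            return lp

    elif model_type == 3:
        cos_w = np.cos(w)
        sin_w = np.sin(w)

        def logp(theta: np.ndarray) -> float:
            mu1, mu2, u11, u12, u21, u22, log_b = theta
            b = np.exp(log_b)
            a1 = np.exp(-b * t)
            proc1 = mu1 + u11 * cos_w + u12 * sin_w
            proc2 = mu2 + u21 * cos_w + u22 * sin_w
            p = expit(a1 * proc1 + (1.0 - a1) * proc2)
            lp = _binom_loglik(y, n, p)
            lp += -0.5 * ((mu1 / priors.loc_scale) ** 2 + (mu2 / priors.loc_scale) ** 2)
            lp += -0.5 * (
                (u11 / priors.harmonic_scale) ** 2
                + (u12 / priors.harmonic_scale) ** 2
                + (u21 / priors.harmonic_scale) ** 2
                + (u22 / priors.harmonic_scale) ** 2
            )
            lp += -0.5 * (b / priors.decay_scale) ** 2 + log_b
            return lp

    else:
        raise ValueError(f"unknown model_type {model_type!r}")

    return logp


def fit_headshake_model(
    series: pd.DataFrame,
    model_type: int,
    settings: MCMCSettings,
    priors: TSPriors | None = None,
    omega: float = OMEGA_DEFAULT,
) -> ModelFit:
    """Fit one binomial time-series model by MCMC.

    ``series`` needs columns ``t_hours``, ``y``, ``N`` and (for model 2)
    ``is_day``.  A series with no headshakes at all leaves the baseline
    level unidentified at the boundary; the fit proceeds but the result
    carries ``converged = False`` when the diagnostic flags it.
    """
    priors = priors or TSPriors()
    t, y, n, day = _series_arrays(series)
    logp = _make_ts_log_density(model_type, t, y, n, day, priors, omega)

    # crude empirical initialization on the logit scale
    frac = np.clip((y + 0.5) / (n + 1.0), 1e-9, 1 - 1e-9)
    lf = logit(frac)
    base = float(np.median(lf[t > np.median(t)]))
    onset = float(lf[0])
    names = MODEL_PARAM_NAMES[model_type]
    if model_type in (1, 2):
        x0 = {"a": onset - base, "b": np.log(0.2), "c": base, "d": 0.0}
        s0 = {"a": 0.5, "b": 0.5, "c": 0.5, "d": 0.2}
    else:
        x0 = {"mu1": onset, "mu2": base, "U11": 0.0, "U12": 0.0,
              "U21": 0.0, "U22": 0.0, "b": np.log(0.2)}
        s0 = {"mu1": 0.5, "mu2": 0.5, "U11": 0.3, "U12": 0.3,
              "U21": 0.3, "U22": 0.3, "b": 0.5}
    init = np.array([x0[p] for p in names])
    scales = np.array([s0[p] for p in names])
    fit = bayescore.sample_posterior(
        logp, init, settings, names, init_scales=scales, optimize_init=True
    )
    # b (and d) were sampled on the log scale; report natural-scale draws
    for p in ("b", "d") if model_type == 2 else ("b",):
        fit.draws[p] = np.exp(fit.draws[p])
        fit.rhat[p] = bayescore.split_rhat(fit.draws[p])
    return fit


def _predict_from_draws(
    model_type: int,
    draws: dict[str, np.ndarray],
    t: np.ndarray,
    day: np.ndarray,
    omega: float,
) -> np.ndarray:
    """Per-draw p_t matrix of shape (n_draws, len(t))."""
    t = np.atleast_1d(t)
    if model_type in (1, 2):
        a = draws["a"].reshape(-1, 1)
        b = draws["b"].reshape(-1, 1)
        c = draws["c"].reshape(-1, 1)
        phi = expit(a * np.exp(-b * t[None, :]) + c)
        if model_type == 2:
            d = draws["d"].reshape(-1, 1)
            return np.where(day[None, :], phi**d, phi)
        return phi
    w = 2.0 * np.pi * omega * t[None, :]
    a1 = np.exp(-draws["b"].reshape(-1, 1) * t[None, :])
    proc1 = (
        draws["mu1"].reshape(-1, 1)
        + draws["U11"].reshape(-1, 1) * np.cos(w)
        + draws["U12"].reshape(-1, 1) * np.sin(w)
    )
    proc2 = (
        draws["mu2"].reshape(-1, 1)
        + draws["U21"].reshape(-1, 1) * np.cos(w)
        + draws["U22"].reshape(-1, 1) * np.sin(w)
    )
    return expit(a1 * proc1 + (1.0 - a1) * proc2)


def treatment_effect(
    fit: ModelFit,
    model_type: int,
    omega: float = OMEGA_DEFAULT,
    recovery: str = "cycle_average",
) -> DerivedEffects:
    """Half-life, handling rate, recovery rate and percent effect.

    Computed per posterior draw, then summarized.  The handling rate is
    the predicted headshake probability at t = 0.  The recovery rate is
    the baseline probability with the treatment term removed: for
    models 1 and 2 this is inv-logit(c) (night scale); for model 3 the
    process-2-only prediction, by default averaged over one 24-hour
    cycle (``recovery="onset_phase"`` uses the t = 0 phase instead).
    """
    stacked = {p: fit.stacked(p) for p in fit.param_names}
    b = stacked["b"]
    hl = np.log(2.0) / b

    if model_type in (1, 2):
        handling = expit(stacked["a"] + stacked["c"])
        rec = expit(stacked["c"])
    elif model_type == 3:
        handling = expit(stacked["mu1"] + stacked["U11"])
        if recovery == "cycle_average":
            tt = np.arange(24.0)
            w = 2.0 * np.pi * omega * tt
            proc2 = (
                stacked["mu2"].reshape(-1, 1)
                + stacked["U21"].reshape(-1, 1) * np.cos(w)[None, :]
                + stacked["U22"].reshape(-1, 1) * np.sin(w)[None, :]
            )
            rec = expit(proc2).mean(axis=1)
        elif recovery == "onset_phase":
            rec = expit(stacked["mu2"] + stacked["U21"])
        else:
            raise ValueError(f"unknown recovery convention {recovery!r}")
    else:
        raise ValueError(f"unknown model_type {model_type!r}")

    if np.any(rec <= 0):
        raise ValueError("recovery rate of zero: treatment effect undefined")
    effect = (handling - rec) / rec * 100.0
    return DerivedEffects(
        half_life_draws=hl,
        handling_rate_draws=handling,
        recovery_rate_draws=rec,
        treatment_effect_pct_draws=effect,
    )


def loo_cv_select_ts(
    series: pd.DataFrame,
    settings: MCMCSettings,
    model_types: tuple[int, ...] = (1, 2, 3),
    priors: TSPriors | None = None,
    omega: float = OMEGA_DEFAULT,
    holdout_indices: list[int] | None = None,
) -> CVResult:
    """Leave-one-out CV over the three time-series models.

    Held-out squared errors are computed on the proportion scale y/N so
    hours with unequal N are comparable.  ``holdout_indices`` may
    subsample the hold-out set for desk-scale runs; the indices used
    are recorded in the result.
    """
    series = series.reset_index(drop=True)
    t, y, n, day = _series_arrays(series)
    props = y / n
    n_units = len(series)

    sse: dict[str, float] = {}
    per_unit: dict[str, np.ndarray] = {}
    failed: dict[str, list[int]] = {}
    holdouts: list[int] = []
    for m, mtype in enumerate(model_types):
        name = f"model{mtype}"

        def fit_without(i: int, unit_seed: int, _mtype=mtype) -> ModelFit:
            rest = series.drop(index=i)
            s = MCMCSettings(
                n_chains=settings.n_chains,
                n_iter=settings.n_iter,
                burn_in=settings.burn_in,
                thin=settings.thin,
                seed=unit_seed,
            )
            return fit_headshake_model(rest, _mtype, s, priors=priors, omega=omega)

        def predict(fit: ModelFit, i: int, _mtype=mtype) -> float:
            draws = {p: fit.stacked(p) for p in fit.param_names}
            p = _predict_from_draws(
                _mtype, draws, np.array([t[i]]), np.array([day[i]]), omega
            )
            return float(p.mean())

        res = bayescore.loo_cv(
            n_units,
            fit_without,
            predict,
            props,
            seed=settings.seed + 104729 * m,
            holdout_indices=holdout_indices,
            model_name=name,
        )
        sse[name] = res.sse[name]
        per_unit[name] = res.per_unit_errors[name]
        failed[name] = res.failed_units[name]
        holdouts = res.holdout_indices
    return CVResult(
        sse=sse,
        per_unit_errors=per_unit,
        failed_units=failed,
        n_units=n_units,
        holdout_indices=holdouts,
    )
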