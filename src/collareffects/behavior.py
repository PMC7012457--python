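"""Bayesian multinomial model for ethogram tallies across treatment periods.

Counts of six behaviors per 10-minute observation window are modelled
as multinomial draws with period-specific probabilities and a
per-individual random effect, fit by MCMC.  Significance of treatment
and post-treatment shifts is judged by whether a period's credible
interval excludes the pre-treatment posterior median.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from . import bayescore
from .bayescore import MCMCSettings, ModelFit

__all__ = [
    "BEHAVIOR_CODES",
    "PERIODS",
    "SCANS_PER_WINDOW",
    "BehaviorPriors",
    "tally_scans",
    "summarize_windows",
    "fit_multinomial",
    "period_probability_draws",
    "assess_significance",
    "behavior_correlations",
]

BEHAVIOR_CODES = ("HU", "HD", "LAY", "HDSK", "SCRATCH", "LOCO")
PERIODS = ("pre", "treatment", "post")

#: 10-minute window scanned every 15 seconds.
SCANS_PER_WINDOW = 40

#: Reference category for the multinomial logits (most common behavior).
REFERENCE = "HU"


@dataclass(frozen=True)
class BehaviorPriors:
    logit_scale: float = 2.0  # Normal(0, logit_scale) on period logits
    re_scale: float = 1.0  # half-Normal(re_scale) on the random-effect sd


def tally_scans(scan_records: pd.DataFrame) -> pd.DataFrame:
    """Count 15-second scan codes into per-window behavior tallies.

    ``scan_records`` needs columns ``individual``, ``period``,
    ``window_id`` and ``code``.  Returns one row per window with one
    count column per behavior.
    """
    required = {"individual", "period", "window_id", "code"}
    missing = required - set(scan_records.columns)
    if missing:
        raise ValueError(f"scan records missing columns: {sorted(missing)}")
    if len(scan_records) == 0:
        raise ValueError("no scan records")
    bad = ~scan_records["code"].isin(BEHAVIOR_CODES)
    if bad.any():
        offender = scan_records.loc[bad].iloc[0]
        raise ValueError(
            f"unknown behavior code {offender['code']!r} "
            f"(individual {offender['individual']!r}, window {offender['window_id']!r})"
        )
    counts = (
        scan_records.groupby(["individual", "period", "window_id"])["code"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=list(BEHAVIOR_CODES), fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    return counts


def summarize_windows(windows: pd.DataFrame) -> dict:
    """Descriptive design summary of a behavior-window table.

    Reports observation-period counts per treatment period and overall,
    plus total and per-individual mean behavior tallies per period.
    """
    counts = windows[list(BEHAVIOR_CODES)].to_numpy()
    n_individuals = windows["individual"].nunique()
    per_period_windows = {
        p: int((windows["period"] == p).sum()) for p in PERIODS
    }
    per_period_behaviors = {
        p: int(counts[(windows["period"] == p).to_numpy()].sum()) for p in PERIODS
    }
    return {
        "n_individuals": n_individuals,
        "n_windows": int(len(windows)),
        "windows_per_period": per_period_windows,
        "behaviors_per_period": per_period_behaviors,
        "behaviors_per_individual_per_period": {
            p: per_period_behaviors[p] / n_individuals for p in PERIODS
        },
    }


def _prepare_arrays(data: pd.DataFrame):
    for col in ("individual", "period", *BEHAVIOR_CODES):
        if col not in data.columns:
            raise ValueError(f"behavior data missing column {col!r}")
    missing_periods = set(PERIODS) - set(data["period"].unique())
    if missing_periods:
        raise ValueError(f"missing periods in data: {sorted(missing_periods)}")
    individuals = sorted(data["individual"].unique())
    if len(individuals) < 2:
        raise ValueError("need at least 2 individuals")
    raw = data[list(BEHAVIOR_CODES)].to_numpy(dtype=float)
    if (raw < 0).any():
        raise ValueError("negative counts")
    if (raw.sum(axis=1) <= 0).any():
        raise ValueError("window with no observed behaviors")
    # windows sharing (individual, period) share a probability vector, so
    # their multinomial counts collapse to one summed row — likelihood
    # identical up to a constant, evaluation ~10x cheaper
    grouped = (
        data.groupby(["individual", "period"])[list(BEHAVIOR_CODES)]
        .sum()
        .reset_index()
    )
    ind_idx = grouped["individual"].map({v: i for i, v in enumerate(individuals)})
    per_idx = grouped["period"].map({p: i for i, p in enumerate(PERIODS)})
    counts = grouped[list(BEHAVIOR_CODES)].to_numpy(dtype=float)
    return counts, per_idx.to_numpy(), ind_idx.to_numpy(), individuals


def fit_multinomial(
    data: pd.DataFrame,
    settings: MCMCSettings,
    priors: BehaviorPriors | None = None,
    random_effect: str = "per_behavior",
) -> ModelFit:
    """Fit the period-probability model with individual random effects.

    Parameterization: per-period logits for the 5 non-reference
    behaviors (reference = HU) plus per-individual random intercepts —
    either one vector per behavior (``per_behavior``, default) or a
    single shared intercept per individual (``shared``) — with a common
    half-normal scale hyperparameter, non-centred.
    """
    priors = priors or BehaviorPriors()
    counts, per_idx, ind_idx, individuals = _prepare_arrays(data)
    n_ind = len(individuals)
    n_beh = len(BEHAVIOR_CODES)
    n_free = n_beh - 1
    if random_effect not in ("per_behavior", "shared", "none"):
        raise ValueError(f"unknown random_effect {random_effect!r}")

    n_period_params = len(PERIODS) * n_free
    if random_effect == "per_behavior":
        n_re = n_ind * n_free
    elif random_effect == "shared":
        n_re = n_ind
    else:
        n_re = 0
    has_re = n_re > 0

    names = [
        f"logit_{p}_{b}" for p in PERIODS for b in BEHAVIOR_CODES if b != REFERENCE
    ]
    if has_re:
        if random_effect == "per_behavior":
            names += [f"z_{i}_{j}" for i in range(n_ind) for j in range(n_free)]
        else:
            names += [f"z_{i}" for i in range(n_ind)]
        names += ["re_sd"]

    ls, rs = priors.logit_scale, priors.re_scale
    row_totals = counts.sum(axis=1)

    def logp(theta: np.ndarray) -> float:
        logits = theta[:n_period_params].reshape(len(PERIODS), n_free)
        lprior = -0.5 * np.sum((logits / ls) ** 2)
        # full (n_windows, n_beh) logit matrix; reference column fixed at 0
        eta = np.zeros((counts.shape[0], n_beh))
        eta[:, 1:] = logits[per_idx]
        if has_re:
            re_sd = theta[-1]
            if re_sd < 0:
                return -np.inf
            z = theta[n_period_params:-1]
            lprior += -0.5 * np.sum(z * z) - 0.5 * (re_sd / rs) ** 2
            if random_effect == "per_behavior":
                u = re_sd * z.reshape(n_ind, n_free)
                eta[:, 1:] += u[ind_idx]
            else:
                eta[:, 1:] += (re_sd * z)[ind_idx][:, None]
        # multinomial log-likelihood up to a counts-only constant
        m = eta.max(axis=1)
        lse = m + np.log(np.exp(eta - m[:, None]).sum(axis=1))
        llik = float(np.sum(counts[:, 1:] * eta[:, 1:])) - float(
            np.sum(row_totals * lse)
        )
        return llik + lprior

    # empirical initialization from pooled per-period frequencies
    x0 = np.zeros(n_period_params + n_re + (1 if has_re else 0))
    for pi in range(len(PERIODS)):
        sel = per_idx == pi
        freq = counts[sel].sum(axis=0) + 0.5
        freq = freq / freq.sum()
        x0[pi * n_free : (pi + 1) * n_free] = np.log(freq[1:] / freq[0])
    if has_re:
        x0[-1] = 0.1
    scales = np.full(x0.size, 0.3)
    if has_re:
        scales[-1] = 0.1
    fit = bayescore.sample_posterior(
        logp, x0, settings, names, init_scales=scales
    )
    fit.meta = {  # type: ignore[attr-defined]
        "individuals": individuals,
        "random_effect": random_effect,
    }
    return fit


def period_probability_draws(fit: ModelFit) -> dict[str, np.ndarray]:
    """Per-period behavior probability draws for a typical individual.

    Softmax of the period logits at zero random effect; every draw's
    six probabilities sum to one.  Returns period -> array of shape
    (n_draws, 6) ordered by ``BEHAVIOR_CODES``.
    """
    n_free = len(BEHAVIOR_CODES) - 1
    out = {}
    for p in PERIODS:
        cols = [
            fit.stacked(f"logit_{p}_{b}") for b in BEHAVIOR_CODES if b != REFERENCE
        ]
        eta = np.zeros((cols[0].size, n_free + 1))
        eta[:, 1:] = np.column_stack(cols)
        eta -= logsumexp(eta, axis=1, keepdims=True)
        out[p] = np.exp(eta)
    return out


def assess_significance(
    prob_draws: dict[str, np.ndarray] | ModelFit,
) -> pd.DataFrame:
    """Credible-interval significance table vs the pre-treatment median.

    For each behavior and each of the treatment/post periods: posterior
    median, 50% and 95% equal-tailed CIs, and overlap flags.  A cell is
    ``significant`` iff its 95% CI excludes the pre-treatment posterior
    median; ``overlap_50`` records whether even the 50% CI contains it
    (the open/closed marker distinction).
    """
    if isinstance(prob_draws, ModelFit):
        prob_draws = period_probability_draws(prob_draws)
    missing = set(PERIODS) - set(prob_draws)
    if missing:
        raise ValueError(f"missing period draws: {sorted(missing)}")
    rows = []
    pre = prob_draws["pre"]
    for j, beh in enumerate(BEHAVIOR_CODES):
        pre_med = float(np.median(pre[:, j]))
        for period in ("treatment", "post"):
            x = prob_draws[period][:, j]
            lo95, hi95 = np.quantile(x, [0.025, 0.975])
            lo50, hi50 = np.quantile(x, [0.25, 0.75])
            rows.append(
                {
                    "behavior": beh,
                    "period": period,
                    "pre_median": pre_med,
                    "median": float(np.median(x)),
                    "ci50_lo": float(lo50),
                    "ci50_hi": float(hi50),
                    "ci95_lo": float(lo95),
                    "ci95_hi": float(hi95),
                    "overlap_50": bool(lo50 <= pre_med <= hi50),
                    "overlap_95": bool(lo95 <= pre_med <= hi95),
                    "significant": not bool(lo95 <= pre_med <= hi95),
                }
            )
    return pd.DataFrame(rows)


def behavior_correlations(windows: pd.DataFrame) -> pd.DataFrame:
    """Descriptive Pearson correlations of within-window behavior counts."""
    return windows[list(BEHAVIOR_CODES)].corr(method="pearson")
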