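"""Synthetic datasets with the statistical structure the analyses assume.

Three generators replace the study animals:

* behavior-tally tables — multinomial windows with period-specific
  probabilities and individual random effects on the logit scale;
* FGM sample tables — the four piecewise response shapes plus Gaussian
  noise, floored at 0 ng/g;
* 8 Hz tri-axial accelerometer streams — behavior-labelled records with
  a post-collaring exponential-decay elevation in headshaking, diel
  amplification, and behavior-specific signal archetypes.

A single global integer seed expands to per-component sub-seeds via
``numpy.random.SeedSequence(seed).spawn`` in a fixed order, so every
dataset is bit-identical under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import softmax

from .behavior import BEHAVIOR_CODES, PERIODS
from .fgm import DAY_RANGE, FGMModelSpec, predict_response
from .headshake_ts import (
    DecayModelParams,
    HarmonicMixParams,
    predict_p_model1,
    predict_p_model2,
    predict_p_model3,
)

__all__ = [
    "BehaviorSimConfig",
    "FGMSimConfig",
    "AccelSimConfig",
    "SignalArchetype",
    "DEFAULT_ARCHETYPES",
    "simulate_behavior_dataset",
    "simulate_fgm_dataset",
    "simulate_accel_stream",
    "simulate_headshake_series",
]

_PROB_TOL = 1e-12


# ---------------------------------------------------------------------------
# behavior tallies


@dataclass(frozen=True)
class BehaviorSimConfig:
    n_individuals: int = 10
    windows_per_period: dict = field(
        default_factory=lambda: {"pre": 6, "treatment": 3, "post": 11}
    )
    scans_per_window: int = 40
    period_probs: dict = field(
        default_factory=lambda: {
            p: (0.42, 0.20, 0.12, 0.05, 0.07, 0.14) for p in PERIODS
        }
    )
    individual_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1 or self.scans_per_window < 1:
            raise ValueError("counts must be positive")
        if set(self.windows_per_period) != set(PERIODS):
            raise ValueError(f"windows_per_period must key {PERIODS}")
        if any(v < 1 for v in self.windows_per_period.values()):
            raise ValueError("windows per period must be positive")
        if set(self.period_probs) != set(PERIODS):
            raise ValueError(f"period_probs must key {PERIODS}")
        for p, vec in self.period_probs.items():
            vec = np.asarray(vec, dtype=float)
            if vec.size != len(BEHAVIOR_CODES):
                raise ValueError(f"period {p!r}: need {len(BEHAVIOR_CODES)} probabilities")
            if (vec < 0).any() or abs(vec.sum() - 1.0) > _PROB_TOL:
                raise ValueError(f"period {p!r}: probabilities must be >= 0 and sum to 1")
        if self.individual_sd < 0:
            raise ValueError("individual_sd must be >= 0")


def simulate_behavior_dataset(config: BehaviorSimConfig) -> pd.DataFrame:
    """Multinomial behavior windows with individual logit offsets.

    Each individual carries a fixed random offset (sd
    ``individual_sd``) on the non-reference logits; window counts are
    multinomial with ``scans_per_window`` trials and softmax-perturbed
    period probabilities.  With ``individual_sd = 0`` the cell
    probabilities equal ``period_probs`` exactly.
    """
    root = np.random.SeedSequence(config.seed).spawn(2)
    rng_re = np.random.default_rng(root[0])
    rng_win = np.random.default_rng(root[1])
    n_beh = len(BEHAVIOR_CODES)
    offsets = config.individual_sd * rng_re.standard_normal(
        (config.n_individuals, n_beh - 1)
    )
    rows = []
    for i in range(config.n_individuals):
        ind = f"ind{i:02d}"
        for period in PERIODS:
            base = np.asarray(config.period_probs[period], dtype=float)
            with np.errstate(divide="ignore"):
                eta = np.log(base)
            eta[1:] = eta[1:] + offsets[i]
            probs = softmax(eta) if np.isfinite(eta).all() else None
            if probs is None:
                # degenerate vector with zero cells: softmax on the support
                probs = np.zeros(n_beh)
                support = base > 0
                e = eta[support]
                probs[support] = softmax(e)
            for w in range(config.windows_per_period[period]):
                counts = rng_win.multinomial(config.scans_per_window, probs)
                rows.append(
                    {
                        "individual": ind,
                        "period": period,
                        "window_id": f"{period}_{w:03d}",
                        **dict(zip(BEHAVIOR_CODES, counts.astype(int))),
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# FGM samples


@dataclass(frozen=True)
class FGMSimConfig:
    response_type: str = "handling"
    beta0: float = 43.35
    beta1: float = 6.59
    beta2: float = 0.0
    k1: float = 1.0
    k2: float | None = 5.03
    noise_sd: float = 8.0
    samples_per_day: int = 3
    day_range: tuple[int, int] = DAY_RANGE
    group: str = "treatment"
    individual: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.beta0 <= 0:
            raise ValueError("beta0 must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.samples_per_day < 1:
            raise ValueError("samples_per_day must be positive")
        # delegates response-shape validation (incl. k2 > k1) to the model spec
        self.model_spec()

    def model_spec(self) -> FGMModelSpec:
        return FGMModelSpec(
            model_type=self.response_type,
            beta0=self.beta0,
            beta1=self.beta1,
            beta2=self.beta2,
            k1=self.k1,
            k2=self.k2 if self.response_type == "handling" else None,
        )


def simulate_fgm_dataset(config: FGMSimConfig) -> pd.DataFrame:
    """FGM samples following a hypothesized response shape plus noise.

    Mean structure comes from :func:`collareffects.fgm.predict_response`;
    noise is additive Gaussian on the ng/g scale, floored at 0.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed))
    spec = config.model_spec()
    lo, hi = config.day_range
    days = np.repeat(np.arange(lo, hi + 1), config.samples_per_day)
    mu = np.asarray(predict_response(spec, days), dtype=float)
    values = mu + config.noise_sd * rng.standard_normal(days.size)
    values = np.maximum(values, 0.0)
    return pd.DataFrame(
        {
            "individual": config.individual,
            "group": config.group,
            "rel_day": days.astype(int),
            "fgm_ng_g": values,
        }
    )


# ---------------------------------------------------------------------------
# accelerometer streams


@dataclass(frozen=True)
class SignalArchetype:
    """Per-behavior signal shape: static gravity orientation (g units on
    x/y/z), dynamic sinusoid amplitude, dominant frequency (Hz), the
    axis carrying the sinusoid, and white-noise sd."""

    orientation: tuple[float, float, float]
    amplitude: float
    frequency_hz: float
    axis: int
    noise_sd: float


#: Separable stand-in archetypes: rest = gravity on heave + faint noise;
#: feed = head-down tilt + moderate noise; locomote = 1.5 Hz stride on
#: surge; headshake = high-amplitude 3.5 Hz burst on sway.
DEFAULT_ARCHETYPES: dict[str, SignalArchetype] = {
    "rest": SignalArchetype((0.0, 0.0, 1.0), 0.02, 0.5, 2, 0.02),
    "feed": SignalArchetype((0.45, 0.0, 0.89), 0.10, 0.8, 0, 0.08),
    "locomote": SignalArchetype((0.0, 0.0, 1.0), 0.45, 1.5, 0, 0.10),
    "headshake": SignalArchetype((0.0, 0.0, 1.0), 1.20, 3.5, 1, 0.12),
}


@dataclass(frozen=True)
class AccelSimConfig:
    duration_h: float = 2.0
    rate_hz: float = 8.0
    behavior_signal_params: dict = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPES)
    )
    baseline_headshake_logit: float = -5.0  # c
    initial_effect: float = 2.0  # a
    decay_rate: float = 0.2  # b, per hour
    day_amplification: float = 1.0  # d (exponent; 1 = no diel cycle)
    day_hours: tuple[int, int] = (8, 17)
    collar_clock_hour: int = 10
    base_behavior_probs: dict = field(
        default_factory=lambda: {"rest": 0.5, "feed": 0.3, "locomote": 0.2}
    )
    burst_len_s: tuple[float, float] = (1.0, 3.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate_hz <= 0 or self.duration_h <= 0:
            raise ValueError("rate_hz and duration_h must be positive")
        if self.decay_rate < 0:
            raise ValueError("decay_rate must be >= 0")
        if self.day_amplification <= 0:
            raise ValueError("day_amplification must be positive")
        missing = {"rest", "feed", "locomote", "headshake"} - set(
            self.behavior_signal_params
        )
        if missing:
            raise ValueError(f"missing signal archetypes: {sorted(missing)}")
        s = sum(self.base_behavior_probs.values())
        if abs(s - 1.0) > 1e-9:
            raise ValueError("base_behavior_probs must sum to 1")


def true_hourly_headshake_prob(config: AccelSimConfig, t_hours) -> np.ndarray:
    """The headshake-probability curve the stream generator targets."""
    t = np.atleast_1d(np.asarray(t_hours, dtype=float))
    clock = (config.collar_clock_hour + np.floor(t)) % 24
    is_day = (clock >= config.day_hours[0]) & (clock < config.day_hours[1])
    params = DecayModelParams(
        a=config.initial_effect,
        b=config.decay_rate,
        c=config.baseline_headshake_logit,
        d=config.day_amplification,
    )
    return np.asarray(predict_p_model2(params, t, is_day))


def simulate_accel_stream(config: AccelSimConfig) -> pd.DataFrame:
    """Labelled 8 Hz stream with decaying post-collaring headshaking.

    Headshakes occur as 1–3 s bursts whose per-hour expected record
    fraction follows :func:`true_hourly_headshake_prob`; every other
    record carries one of the background behaviors in contiguous
    segments.  Signal per record = archetype static orientation +
    sinusoidal dynamic component + white noise.

    Returns columns ``timestamp``, ``ax``, ``ay``, ``az``, ``label``.
    """
    rate = config.rate_hz
    per_hour = int(round(rate * 3600))
    n_hours = int(np.ceil(config.duration_h))
    n_total = int(round(config.duration_h * 3600 * rate))
    root = np.random.SeedSequence(config.seed).spawn(3)
    rng_beh = np.random.default_rng(root[0])
    rng_burst = np.random.default_rng(root[1])
    rng_sig = np.random.default_rng(root[2])

    # background behavior in contiguous segments (mean 30 s)
    labels = np.empty(n_total, dtype=object)
    base_names = list(config.base_behavior_probs)
    base_p = np.array([config.base_behavior_probs[b] for b in base_names])
    pos = 0
    while pos < n_total:
        seg = int(rng_beh.exponential(30.0) * rate) + 1
        beh = base_names[rng_beh.choice(len(base_names), p=base_p)]
        labels[pos : pos + seg] = beh
        pos += seg

    # overlay headshake bursts, hour by hour
    lo_len = int(round(config.burst_len_s[0] * rate))
    hi_len = int(round(config.burst_len_s[1] * rate))
    mean_len = (lo_len + hi_len) / 2.0
    p_curve = true_hourly_headshake_prob(config, np.arange(n_hours))
    for h in range(n_hours):
        start = h * per_hour
        stop = min((h + 1) * per_hour, n_total)
        n_rec = stop - start
        if n_rec <= 0:
            break
        lam = n_rec * p_curve[h] / mean_len
        n_bursts = rng_burst.poisson(lam)
        for _ in range(n_bursts):
            length = int(rng_burst.integers(lo_len, hi_len + 1))
            s = start + int(rng_burst.integers(0, n_rec))
            labels[s : min(s + length, stop)] = "headshake"

    # signals from archetypes
    t_s = np.arange(n_total) / rate
    xyz = np.empty((n_total, 3))
    phases = {b: rng_sig.uniform(0, 2 * np.pi) for b in config.behavior_signal_params}
    for beh, arch in config.behavior_signal_params.items():
        sel = labels == beh
        if not sel.any():
            continue
        n_sel = int(sel.sum())
        base = np.tile(np.asarray(arch.orientation, dtype=float), (n_sel, 1))
        wave = arch.amplitude * np.sin(
            2 * np.pi * arch.frequency_hz * t_s[sel] + phases[beh]
        )
        base[:, arch.axis] += wave
        base += arch.noise_sd * rng_sig.standard_normal((n_sel, 3))
        xyz[sel] = base

    origin = pd.Timestamp("2015-10-22") + pd.Timedelta(hours=config.collar_clock_hour)
    timestamps = origin + pd.to_timedelta(t_s, unit="s")
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "ax": xyz[:, 0],
            "ay": xyz[:, 1],
            "az": xyz[:, 2],
            "label": labels,
        }
    )


# ---------------------------------------------------------------------------
# hourly headshake series (bypasses per-record simulation)


def simulate_headshake_series(
    params: DecayModelParams | HarmonicMixParams,
    n_hours: int,
    seed: int,
    model_type: int | None = None,
    n_per_hour: int = 28_800,
    day_hours: tuple[int, int] = (8, 17),
    collar_clock_hour: int = 10,
) -> pd.DataFrame:
    """Hourly binomial counts drawn directly from a time-series model.

    Convenience generator for testing the fitting machinery without the
    per-record accelerometer pipeline.
    """
    if model_type is None:
        model_type = 3 if isinstance(params, HarmonicMixParams) else 1
    t = np.arange(n_hours, dtype=float)
    clock = (collar_clock_hour + t) % 24
    is_day = (clock >= day_hours[0]) & (clock < day_hours[1])
    if model_type == 1:
        p = predict_p_model1(params, t)
    elif model_type == 2:
        p = predict_p_model2(params, t, is_day)
    elif model_type == 3:
        p = predict_p_model3(params, t)
    else:
        raise ValueError(f"unknown model_type {model_type!r}")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    y = rng.binomial(n_per_hour, np.atleast_1d(p))
    return pd.DataFrame(
        {
            "t_hours": t.astype(int),
            "y": y,
            "N": n_per_hour,
            "is_day": is_day,
            "p_true": np.atleast_1d(p),
        }
    )
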