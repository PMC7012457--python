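"""Shared Bayesian fitting engine.

Gradient-free adaptive random-walk Metropolis sampling, split-chain
convergence diagnostics, posterior summarization, and a generic
leave-one-out cross-validation driver.  The sampler is deliberately
gradient-free so that non-smooth targets (e.g. piecewise-regression
breakpoints) are sampleable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "MCMCSettings",
    "ModelFit",
    "CVResult",
    "FitError",
    "sample_posterior",
    "summarize",
    "split_rhat",
    "loo_cv",
    "PAPER_SETTINGS",
]

RHAT_THRESHOLD = 1.1


class FitError(RuntimeError):
    """Raised when MCMC sampling cannot proceed (non-finite density, etc.)."""


@dataclass(frozen=True)
class MCMCSettings:
    """Chain configuration.

    ``n_chains * n_iter * (1 - burn_in) / thin`` draws are retained in
    total; choose ``n_iter`` so that the post-burn-in count divides
    evenly by ``thin`` if an exact count matters.
    """

    n_chains: int = 3
    n_iter: int = 20_000
    burn_in: float = 0.2
    thin: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence diagnostics")
        if not (0.0 <= self.burn_in < 1.0):
            raise ValueError("burn_in fraction must lie in [0, 1)")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.n_iter < self.thin:
            raise ValueError("n_iter too small for requested thinning")

    @property
    def n_burn(self) -> int:
        return int(round(self.n_iter * self.burn_in))

    @property
    def n_kept_per_chain(self) -> int:
        return (self.n_iter - self.n_burn) // self.thin


#: Full-scale settings matching the published supplementary runs
#: (3 chains x 400,000 iterations, 20% burn-in, 1:100 thinning).
PAPER_SETTINGS = MCMCSettings(n_chains=3, n_iter=400_000, burn_in=0.2, thin=100)


@dataclass
class ModelFit:
    """Posterior draws plus diagnostics for one fitted model.

    ``draws`` maps parameter name -> array of shape (n_chains, n_kept).
    """

    param_names: list[str]
    draws: dict[str, np.ndarray]
    rhat: dict[str, float]
    settings: MCMCSettings
    acceptance_rate: float
    converged: bool = field(init=False)

    def __post_init__(self) -> None:
        self.converged = all(
            np.isfinite(r) and r <= RHAT_THRESHOLD for r in self.rhat.values()
        )

    def stacked(self, name: str) -> np.ndarray:
        """All post-burn-in draws of one parameter, chains concatenated."""
        return self.draws[name].reshape(-1)

    def median(self, name: str) -> float:
        return float(np.median(self.stacked(name)))

    def mean(self, name: str) -> float:
        return float(np.mean(self.stacked(name)))

    def ci(self, name: str, level: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - level) / 2.0
        x = self.stacked(name)
        return (float(np.quantile(x, lo)), float(np.quantile(x, 1.0 - lo)))

    def summary(self) -> pd.DataFrame:
        return summarize(self)


@dataclass
class CVResult:
    """Leave-one-out cross-validation scores for a set of candidate models."""

    sse: dict[str, float]
    per_unit_errors: dict[str, np.ndarray]
    failed_units: dict[str, list[int]]
    n_units: int
    holdout_indices: list[int]

    @property
    def winner(self) -> str:
        valid = {m: s for m, s in self.sse.items() if np.isfinite(s)}
        if not valid:
            raise FitError("no candidate model produced a valid SSE")
        return min(valid, key=valid.get)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"model": list(self.sse), "sse": [self.sse[m] for m in self.sse]}
        )
        df["rank"] = df["sse"].rank(method="min")
        return df.sort_values("rank").reset_index(drop=True)


def _adaptive_rw_chain(
    log_density: Callable[[np.ndarray], float],
    x0: np.ndarray,
    n_iter: int,
    n_burn: int,
    thin: int,
    rng: np.random.Generator,
    init_scales: np.ndarray,
) -> tuple[np.ndarray, float]:
    """One adaptive random-walk Metropolis chain.

    Haario-style adaptation during burn-in: the proposal covariance is
    refreshed from the running sample covariance (with a diagonal
    fallback before enough history accumulates) and a global scale is
    tuned toward ~28% acceptance.  Adaptation freezes at the end of
    burn-in so retained draws target the exact posterior.
    """
    d = x0.size
    x = x0.copy()
    lp = log_density(x)
    if not np.isfinite(lp):
        raise FitError("log density not finite at initial values")

    chol = np.diag(init_scales)
    global_scale = 2.38 / np.sqrt(d)
    n_kept = (n_iter - n_burn) // thin
    kept = np.empty((n_kept, d))
    k = 0
    n_accept_total = 0
    accept_window = 0
    batch = 50
    # running moments for covariance adaptation
    run_mean = x.copy()
    run_m2 = np.zeros((d, d))
    n_seen = 1
    min_history = max(200, 10 * d)

    for i in range(n_iter):
        prop = x + global_scale * (chol @ rng.standard_normal(d))
        lp_prop = log_density(prop)
        if np.log(rng.random()) < lp_prop - lp:
            x = prop
            lp = lp_prop
            n_accept_total += 1
            accept_window += 1

        if i < n_burn:
            n_seen += 1
            delta = x - run_mean
            run_mean += delta / n_seen
            run_m2 += np.outer(delta, x - run_mean)
            if (i + 1) % batch == 0:
                rate = accept_window / batch
                global_scale *= float(np.exp((rate - 0.28) * 0.7))
                accept_window = 0
                if n_seen > min_history:
                    cov = run_m2 / (n_seen - 1)
                    jitter = 1e-10 * max(np.trace(cov) / d, 1e-8)
                    try:
                        chol = np.linalg.cholesky(cov + jitter * np.eye(d))
                    except np.linalg.LinAlgError:
                        pass  # keep previous proposal shape
        else:
            j = i - n_burn
            if j % thin == 0 and k < n_kept:
                kept[k] = x
                k += 1

    return kept, n_accept_total / n_iter


def sample_posterior(
    log_density: Callable[[np.ndarray], float],
    init: Sequence[float] | np.ndarray,
    settings: MCMCSettings,
    param_names: Sequence[str] | None = None,
    init_scales: Sequence[float] | np.ndarray | None = None,
    init_jitter: float = 0.1,
    optimize_init: bool = False,
) -> ModelFit:
    """Sample a target density with adaptive random-walk Metropolis.

    Parameters
    ----------
    log_density
        Maps a parameter vector to an (unnormalized) log posterior
        density.  Return ``-inf`` outside the support.
    init
        Initial parameter vector; the density must be finite there.
    settings
        Chain configuration; ``settings.seed`` fully determines the run.
    param_names
        Names for the output draws; defaults to ``p0, p1, ...``.
    init_scales
        Per-coordinate initial proposal scales (adapted during burn-in).
    init_jitter
        Relative magnitude of per-chain initial-value jitter (chains are
        over-dispersed so the split-chain diagnostic is meaningful).
    optimize_init
        Run a gradient-free (Nelder-Mead) posterior-mode search from
        ``init`` and start all chains near the mode.  Helps targets
        with weakly identified ridges.
    """
    x0 = np.asarray(init, dtype=float)
    d = x0.size
    if param_names is None:
        param_names = [f"p{i}" for i in range(d)]
    if len(param_names) != d:
        raise ValueError("param_names length must match init length")
    if init_scales is None:
        init_scales = np.maximum(np.abs(x0) * 0.1, 0.1)
    else:
        init_scales = np.asarray(init_scales, dtype=float)

    lp0 = log_density(x0)
    if not np.isfinite(lp0):
        raise FitError(
            f"log density not finite at initial values {x0!r} (lp={lp0})"
        )

    if optimize_init:
        res = optimize.minimize(
            lambda th: -log_density(th),
            x0,
            method="Nelder-Mead",
            options={"maxiter": 400 * d, "xatol": 1e-6, "fatol": 1e-6},
        )
        if np.isfinite(res.fun):
            x0 = res.x

    root = np.random.SeedSequence(settings.seed)
    chain_seeds = root.spawn(settings.n_chains)
    chains = []
    acc_rates = []
    for c in range(settings.n_chains):
        rng = np.random.Generator(np.random.PCG64(chain_seeds[c]))
        # jitter initial values, retrying until the density is finite
        for _attempt in range(100):
            jitter = init_jitter * init_scales * rng.standard_normal(d)
            xc = x0 + jitter
            if np.isfinite(log_density(xc)):
                break
        else:
            xc = x0
        kept, rate = _adaptive_rw_chain(
            log_density,
            xc,
            settings.n_iter,
            settings.n_burn,
            settings.thin,
            rng,
            init_scales,
        )
        chains.append(kept)
        acc_rates.append(rate)

    all_draws = np.stack(chains)  # (n_chains, n_kept, d)
    draws = {name: all_draws[:, :, j] for j, name in enumerate(param_names)}
    rhat = {name: split_rhat(draws[name]) for name in param_names}
    return ModelFit(
        param_names=list(param_names),
        draws=draws,
        rhat=rhat,
        settings=settings,
        acceptance_rate=float(np.mean(acc_rates)),
    )


def split_rhat(chain_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chain_draws`` has shape (n_chains, n_draws); each chain is split
    in half before computing the classic between/within variance ratio.
    """
    m, n = chain_draws.shape
    half = n // 2
    if half < 2:
        return float("nan")
    segs = np.concatenate(
        [chain_draws[:, :half], chain_draws[:, half : 2 * half]], axis=0
    )
    seg_means = segs.mean(axis=1)
    seg_vars = segs.var(axis=1, ddof=1)
    w = seg_vars.mean()
    b = half * seg_means.var(ddof=1)
    if w <= 0:
        return 1.0 if b <= 0 else float("inf")
    var_plus = (half - 1) / half * w + b / half
    return float(np.sqrt(var_plus / w))


def summarize(fit: ModelFit) -> pd.DataFrame:
    """Posterior summary table: mean, sd, median, equal-tailed 2.5%/97.5%."""
    rows = []
    for name in fit.param_names:
        x = fit.stacked(name)
        rows.append(
            {
                "parameter": name,
                "mean": float(np.mean(x)),
                "sd": float(np.std(x, ddof=1)) if x.size > 1 else 0.0,
                "median": float(np.median(x)),
                "q2.5": float(np.quantile(x, 0.025)),
                "q97.5": float(np.quantile(x, 0.975)),
                "rhat": fit.rhat[name],
            }
        )
    return pd.DataFrame(rows)


def loo_cv(
    n_units: int,
    fit_without: Callable[[int, int], object],
    predict_heldout: Callable[[object, int], float],
    observed: Sequence[float] | np.ndarray,
    seed: int = 0,
    holdout_indices: Sequence[int] | None = None,
    model_name: str = "model",
) -> CVResult:
    """Generic leave-one-out cross-validation driver.

    For each held-out unit ``i``: refit via ``fit_without(i, seed_i)``,
    predict the unit via ``predict_heldout(fit, i)``, and accumulate the
    squared error against ``observed[i]``.  Per-unit failures are
    recorded and the SSE marked invalid (NaN) rather than raised.

    ``holdout_indices`` optionally restricts the hold-out set (block or
    subsampled CV at desk scale); the indices used are reported.
    """
    observed = np.asarray(observed, dtype=float)
    if observed.size != n_units:
        raise ValueError("observed length must equal n_units")
    if n_units < 3:
        raise ValueError("need at least 3 units for leave-one-out CV")
    if holdout_indices is None:
        holdout_indices = list(range(n_units))
    else:
        holdout_indices = list(holdout_indices)

    sub = np.random.SeedSequence(seed).spawn(n_units)
    errors = np.full(len(holdout_indices), np.nan)
    failed: list[int] = []
    for j, i in enumerate(holdout_indices):
        unit_seed = int(sub[i].generate_state(1)[0] % (2**31 - 1))
        try:
            fit = fit_without(i, unit_seed)
            pred = predict_heldout(fit, i)
            errors[j] = (pred - observed[i]) ** 2
        except FitError:
            failed.append(i)
    sse = float(np.nansum(errors)) if not failed else float("nan")
    return CVResult(
        sse={model_name: sse},
        per_unit_errors={model_name: errors},
        failed_units={model_name: failed},
        n_units=n_units,
        holdout_indices=holdout_indices,
    )
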