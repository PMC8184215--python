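"""Synthetic trial generator for the full threshold + gain decision model.

Emulates the structure of classic single-unit motion-discrimination data sets:
~10 signed coherence levels per cell, unequal trial counts per level (more
trials at weak coherences, typically 30 at high coherence and 60 at zero), a
binary choice produced by a linear readout plus threshold, and Poisson spike
counts modulated by a multiplicative gain shared across the population.

Generative model per trial k at stimulus level s:

1. draw a gain ``g_k ~ Gamma(mean 1, variance sigma_g2)``,
2. set latent rates ``g_k * f_i(s)`` with linearized tuning
   ``f_i(s) = f0_i + fprime_i * s`` (floored at a small positive rate),
3. draw counts ``r_i ~ Poisson(g_k * f_i(s))``, optionally coupled through a
   Gaussian copula to add non-gain correlated noise,
4. read out ``d = w^T r`` and set ``D = +1`` iff ``d > theta``.

With the default (diagonal) non-gain noise the count variance decomposes as
``var r_i = f_i(s) + sigma_g2 * f_i(s)^2`` (Poisson-gamma mixture, i.e.
negative-binomial marginals), which is exactly the mean-variance relation the
moment estimator :func:`estimate_gain_variance` inverts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gain_model import PopulationEncoding, optimal_weights

__all__ = [
    "TRIAL_COLUMNS",
    "SimulationConfig",
    "default_config",
    "simulate_trials",
    "simulate_threshold_trials",
    "estimate_gain_variance",
    "encoding_from_config",
    "simulated_covariance",
    "psychometric_truth",
]

#: Canonical column order of a trial table.
TRIAL_COLUMNS = ["cell_id", "trial_id", "coherence", "choice", "count"]

#: Default signed coherence levels (%), mirroring the random-dot task design.
DEFAULT_COHERENCES = (
    -51.2, -25.6, -12.8, -6.4, -3.2, -1.6, 0.0, 1.6, 3.2, 6.4, 12.8, 25.6, 51.2
)

_RATE_FLOOR = 0.1  # spikes per trial; keeps linearized tuning positive


def _default_trials(coherence: float) -> int:
    # archive-like design: most trials at weak evidence, 30 at high coherence
    c = abs(coherence)
    if c == 0.0:
        return 60
    if c < 10.0:
        return 40
    return 30


@dataclass
class SimulationConfig:
    """Full specification of a simulated session.

    ``f0`` and ``fprime`` give per-neuron linearized tuning (counts, counts
    per % coherence).  ``sigma_g2`` is the shared gain variance.
    ``noise_corr`` adds pairwise non-gain count correlation through a
    Gaussian copula (0 = conditionally independent Poisson).  ``weights``
    and ``threshold`` default to the readout optimal for the covariance at
    zero coherence and to an unbiased threshold ``w^T f(0)``.  A fixed seed
    makes the output byte-identical.
    """

    f0: np.ndarray
    fprime: np.ndarray
    sigma_g2: float = 0.0
    noise_corr: float = 0.0
    coherences: tuple = DEFAULT_COHERENCES
    trials_per_level: dict | int | None = None
    weights: np.ndarray | None = None
    threshold: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.f0 = np.asarray(self.f0, dtype=float)
        self.fprime = np.asarray(self.fprime, dtype=float)
        if self.f0.shape != self.fprime.shape:
            raise ValueError("f0 and fprime must have matching shapes")
        if np.any(self.f0 <= 0):
            raise ValueError("f0 must be positive")
        if self.sigma_g2 < 0:
            raise ValueError("sigma_g2 must be non-negative")
        if not -1.0 / max(self.n_neurons - 1, 1) < self.noise_corr < 1.0:
            raise ValueError("noise_corr outside the valid correlation range")

    @property
    def n_neurons(self) -> int:
        return self.f0.size

    def tuning(self, s: float) -> np.ndarray:
        return np.maximum(self.f0 + self.fprime * s, _RATE_FLOOR)

    def n_trials(self, s: float) -> int:
        if self.trials_per_level is None:
            return _default_trials(s)
        if isinstance(self.trials_per_level, dict):
            return int(self.trials_per_level[s])
        return int(self.trials_per_level)


def default_config(
    n_neurons: int = 20, sigma_g2: float = 0.0, seed: int = 0, **kwargs
) -> SimulationConfig:
    """A heterogeneous population with both choice preferences.

    Baseline rates are drawn uniformly in [5, 40] counts per trial and tuning
    slopes scaled so the tuning stays positive over the full +-51.2% range;
    half the neurons prefer each motion direction.
    """
    rng = np.random.default_rng(seed)
    f0 = rng.uniform(5.0, 40.0, size=n_neurons)
    sign = np.where(np.arange(n_neurons) % 2 == 0, 1.0, -1.0)
    gamma = rng.uniform(0.3, 1.0, size=n_neurons)
    fprime = sign * gamma * f0 * 0.8 / 51.2
    return SimulationConfig(
        f0=f0, fprime=fprime, sigma_g2=sigma_g2, seed=seed, **kwargs
    )


def encoding_from_config(cfg: SimulationConfig) -> PopulationEncoding:
    """Analytic encoding implied by the simulator at zero coherence.

    Non-gain variance equals the rate (Poisson), so ``Sigma_bar`` is
    ``diag(f0)`` plus the copula-induced off-diagonal part if requested.
    """
    sigma_bar = np.diag(cfg.f0).astype(float)
    if cfg.noise_corr != 0.0:
        sd = np.sqrt(cfg.f0)
        off = cfg.noise_corr * np.outer(sd, sd)
        sigma_bar = sigma_bar + off - np.diag(np.diag(off))
    return PopulationEncoding(
        f0=cfg.f0, fprime0=cfg.fprime, sigma_base=sigma_bar, sigma_g2=cfg.sigma_g2
    )


def _resolve_readout(cfg: SimulationConfig) -> tuple[np.ndarray, float]:
    if cfg.weights is None:
        w = optimal_weights(encoding_from_config(cfg)).weights
    else:
        w = np.asarray(cfg.weights, dtype=float)
    theta = float(w @ cfg.f0) if cfg.threshold is None else float(cfg.threshold)
    return w, theta


def simulated_covariance(cfg: SimulationConfig, s: float) -> np.ndarray:
    """Count covariance implied by the generative model at level ``s``."""
    f = cfg.tuning(s)
    sigma = np.diag(f) + cfg.sigma_g2 * np.outer(f, f)
    if cfg.noise_corr != 0.0:
        sd = np.sqrt(f)
        off = cfg.noise_corr * np.outer(sd, sd)
        sigma = sigma + off - np.diag(np.diag(off))
    return sigma


def psychometric_truth(cfg: SimulationConfig):
    """Model-implied psychometric map ``s -> p_cr`` (Gaussian approximation).

    ``p_cr(s) = Phi((w^T f(s) - theta) / sd_d(s))`` with ``sd_d`` from the
    generative count covariance at ``s``.
    """
    w, theta = _resolve_readout(cfg)

    def pcr(s: float) -> float:
        mean_d = float(w @ cfg.tuning(s))
        sd_d = float(np.sqrt(w @ simulated_covariance(cfg, s) @ w))
        return float(stats.norm.cdf((mean_d - theta) / sd_d))

    return pcr


def simulate_trials(
    cfg: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_decision: bool = False,
):
    """Generate a long-format trial table from the full generative model.

    Returns a DataFrame with columns ``cell_id, trial_id, coherence, choice,
    count`` (one row per neuron and trial); with ``return_decision=True``
    also returns the hidden per-trial decision variable as a DataFrame with
    columns ``trial_id, coherence, d, choice``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    w, theta = _resolve_readout(cfg)
    n = cfg.n_neurons
    chol = None
    if cfg.noise_corr != 0.0:
        corr = np.full((n, n), cfg.noise_corr)
        np.fill_diagonal(corr, 1.0)
        chol = np.linalg.cholesky(corr)

    frames = []
    decisions = []
    trial0 = 0
    for s in cfg.coherences:
        k = cfg.n_trials(s)
        f = cfg.tuning(s)
        if cfg.sigma_g2 > 0:
            shape = 1.0 / cfg.sigma_g2
            g = rng.gamma(shape, scale=cfg.sigma_g2, size=k)
        else:
            g = np.ones(k)
        rates = g[:, None] * f[None, :]
        if chol is None:
            counts = rng.poisson(rates)
        else:
            z = rng.standard_normal((k, n)) @ chol.T
            u = stats.norm.cdf(z)
            counts = stats.poisson.ppf(u, rates).astype(np.int64)
        d = counts @ w
        choice = np.where(d > theta, 1, -1)
        trial_ids = np.arange(trial0, trial0 + k)
        trial0 += k
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": np.repeat(np.arange(n), k),
                    "trial_id": np.tile(trial_ids, n),
                    "coherence": s,
                    "choice": np.tile(choice, n),
                    "count": counts.T.reshape(-1),
                }
            )
        )
        decisions.append(
            pd.DataFrame(
                {"trial_id": trial_ids, "coherence": s, "d": d, "choice": choice}
            )
        )
    table = pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]
    if return_decision:
        return table, pd.concat(decisions, ignore_index=True)
    return table


def simulate_threshold_trials(
    rho: float,
    pcr_by_level: dict,
    n_by_level: dict | int = 30,
    seed: int = 0,
    mean_count: float = 100.0,
    sd_count: float = 15.0,
    cell_id: int = 0,
) -> pd.DataFrame:
    """Single-cell data drawn directly from the bivariate-Gaussian model.

    For each stimulus level with choice rate ``p``, the response z-score and
    decision variable are jointly Gaussian with correlation ``rho`` and the
    choice thresholds ``d`` at ``Phi^-1(1 - p)``.  Counts are an affine,
    rounded transform of the z-scores (rank statistics are unaffected up to
    rounding ties).  Useful as ground truth for profile estimators.
    """
    rng = np.random.default_rng(seed)
    frames = []
    trial0 = 0
    for s, p in pcr_by_level.items():
        k = n_by_level[s] if isinstance(n_by_level, dict) else int(n_by_level)
        d = rng.standard_normal(k)
        z = rho * d + np.sqrt(1.0 - rho**2) * rng.standard_normal(k)
        choice = np.where(d > stats.norm.ppf(1.0 - p), 1, -1)
        counts = np.maximum(np.rint(mean_count + sd_count * z), 0).astype(np.int64)
        frames.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "trial_id": np.arange(trial0, trial0 + k),
                    "coherence": s,
                    "choice": choice,
                    "count": counts,
                }
            )
        )
        trial0 += k
    return pd.concat(frames, ignore_index=True)[TRIAL_COLUMNS]


def estimate_gain_variance(counts_by_level, min_trials: int = 10) -> float:
    """Moment estimator of the gain variance from one cell's counts.

    Fits the negative-binomial mean-variance relation ``var = mu + sigma_g2 *
    mu^2`` across stimulus levels by least squares on the per-level sample
    moments and clips the estimate at zero.  ``counts_by_level`` is an
    iterable of per-level count arrays (or a DataFrame with ``coherence`` and
    ``count`` columns); levels with fewer than ``min_trials`` trials are
    dropped.
    """
    if isinstance(counts_by_level, pd.DataFrame):
        counts_by_level = [
            grp["count"].to_numpy() for _, grp in counts_by_level.groupby("coherence")
        ]
    mus, vs = [], []
    for arr in counts_by_level:
        arr = np.asarray(arr, dtype=float)
        if arr.size < min_trials:
            continue
        mus.append(arr.mean())
        vs.append(arr.var(ddof=1))
    mus = np.asarray(mus)
    vs = np.asarray(vs)
    if mus.size < 2:
        raise ValueError("need at least two stimulus levels with enough trials")
    if np.all(mus == 0):
        raise ValueError("all level means are zero")
    # least squares of (v - mu) on mu^2 through the origin
    est = float(np.sum(mus**2 * (vs - mus)) / np.sum(mus**4))
    if est < 0:
        warnings.warn("gain variance estimate clipped at 0", stacklevel=2)
    return max(est, 0.0)
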