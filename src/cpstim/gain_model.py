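"""Feedforward encoding/decoding model with shared multiplicative gain.

A population of sensory neurons with tuning curves ``f(s)`` (linearized as
``f(s) = f0 + fprime0 * ds`` around the uninformative stimulus ``s0``) feeds
a linear readout ``d = w^T r``.  A multiplicative gain factor ``g`` (mean 1,
variance ``sigma_g2``) shared by the whole population adds a rank-one,
stimulus-dependent component to the response covariance,

    Sigma(s) = Sigma_bar + sigma_g2 * f(s) f(s)^T,

where ``Sigma_bar`` is the (stimulus-independent) covariance not associated
with the gain.  Under the readout that is optimal for ``Sigma(s0)``, the
choice correlation of neuron ``i`` acquires a linear stimulus dependence

    CC_i(ds) = CC_i(0) + sigma_g * lambda_i * (1 - CC_i(0)^2) * ds / sd_d,

with ``lambda_i^2`` the fraction of the neuron's variance caused by the gain.
Composed with the threshold-model factor ``h(p_cr)`` this predicts
cell-specific CP(p_cr) profiles: a symmetric component from the decision
threshold plus an asymmetric (monotone) component whose slope grows with
``lambda_i``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .threshold_model import ThresholdModelParams, cp_exact

__all__ = [
    "PopulationEncoding",
    "ReadoutSpec",
    "GainCPPrediction",
    "total_covariance",
    "optimal_weights",
    "cc_from_readout",
    "lambda_fraction",
    "cc_gain_profile",
    "gain_cp_prediction",
    "cp_profile_prediction",
]


@dataclass(frozen=True)
class PopulationEncoding:
    """Tuning, base covariance and gain variance of a neural population.

    ``f0`` are the tuning values at the uninformative stimulus (all > 0),
    ``fprime0`` the tuning derivatives, ``sigma_base`` the symmetric
    positive-definite covariance not associated with the gain, and
    ``sigma_g2 >= 0`` the variance of the shared multiplicative gain.
    Stimuli are expressed as offsets ``ds = s - s0``.
    """

    f0: np.ndarray
    fprime0: np.ndarray
    sigma_base: np.ndarray
    sigma_g2: float = 0.0

    def __post_init__(self) -> None:
        f0 = np.asarray(self.f0, dtype=float)
        fp = np.asarray(self.fprime0, dtype=float)
        sb = np.asarray(self.sigma_base, dtype=float)
        object.__setattr__(self, "f0", f0)
        object.__setattr__(self, "fprime0", fp)
        object.__setattr__(self, "sigma_base", sb)
        n = f0.size
        if fp.size != n or sb.shape != (n, n):
            raise ValueError("inconsistent dimensions in PopulationEncoding")
        if np.any(f0 <= 0):
            raise ValueError("tuning values f0 must be positive")
        if self.sigma_g2 < 0:
            raise ValueError("sigma_g2 must be non-negative")
        if not np.allclose(sb, sb.T):
            raise ValueError("sigma_base must be symmetric")
        try:
            np.linalg.cholesky(sb)
        except np.linalg.LinAlgError as exc:
            raise ValueError("sigma_base must be positive-definite") from exc

    @property
    def n_neurons(self) -> int:
        return self.f0.size

    def tuning(self, delta_s: float) -> np.ndarray:
        """Linearized tuning ``f(s0 + ds) = f0 + fprime0 * ds``."""
        return self.f0 + self.fprime0 * delta_s


@dataclass(frozen=True)
class ReadoutSpec:
    """Linear readout weights ``w`` (at least one must be nonzero)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if not np.any(w != 0):
            raise ValueError("readout requires at least one nonzero weight")


@dataclass(frozen=True)
class GainCPPrediction:
    """Per-neuron gain-model prediction: lambda, CC at p_cr = 0.5, slope."""

    lambda_i: np.ndarray
    cc_half: np.ndarray
    slope: np.ndarray  # beta_pCR, per unit ds / sd_d


def total_covariance(enc: PopulationEncoding, delta_s: float = 0.0) -> np.ndarray:
    """Total covariance ``Sigma_bar + sigma_g2 * f(s) f(s)^T`` at offset ds."""
    f = enc.tuning(delta_s)
    sigma = enc.sigma_base + enc.sigma_g2 * np.outer(f, f)
    try:
        np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise FloatingPointError("total covariance is not positive-definite") from exc
    return sigma


def optimal_weights(enc: PopulationEncoding) -> ReadoutSpec:
    """Readout optimal for the covariance at the decision boundary.

    ``w = Sigma^-1(s0) f' / (f'^T Sigma^-1(s0) f')``, normalized so that the
    readout is locally unbiased in stimulus units: ``w^T f' = 1``.
    """
    sigma0 = total_covariance(enc, 0.0)
    x = np.linalg.solve(sigma0, enc.fprime0)
    denom = float(enc.fprime0 @ x)
    if denom == 0:
        raise ValueError("tuning derivative orthogonal to decoded direction")
    return ReadoutSpec(weights=x / denom)


def cc_from_readout(
    enc: PopulationEncoding, ro: ReadoutSpec, delta_s: float = 0.0
) -> np.ndarray:
    """Choice correlations ``CC_i = (Sigma w)_i / sqrt(Sigma_ii w^T Sigma w)``."""
    sigma = total_covariance(enc, delta_s)
    w = ro.weights
    cov_rd = sigma @ w
    var_d = float(w @ cov_rd)
    var_r = np.diag(sigma)
    if var_d <= 0 or np.any(var_r <= 0):
        raise ValueError("zero variance in readout or responses")
    return cov_rd / np.sqrt(var_r * var_d)


def lambda_fraction(enc: PopulationEncoding, i: int) -> float:
    """Gain-driven fraction of neuron i's standard deviation, ``lambda_i``.

    ``lambda_i^2 = sigma_g2 * f0_i^2 / Sigma_ii(s0)`` with
    ``Sigma_ii(s0) = Sigma_bar_ii + sigma_g2 * f0_i^2``; the squared value is
    the fraction of the neuron's variance caused by the gain fluctuations.
    """
    var_gain = enc.sigma_g2 * enc.f0[i] ** 2
    var_total = enc.sigma_base[i, i] + var_gain
    if var_total <= 0:
        raise ValueError("neuron has zero total variance")
    return float(np.sqrt(var_gain / var_total))


def cc_gain_profile(
    enc: PopulationEncoding, i: int, delta_s, readout: ReadoutSpec | None = None
) -> np.ndarray:
    """Gain-induced choice-correlation profile of neuron i versus ``ds``.

    ``CC_i(ds) = CC_i(0) + sigma_g * lambda_i * (1 - CC_i(0)^2) * ds / sd_d``
    with ``sd_d`` evaluated at the decision boundary.  Raises if the linear
    regime is violated (|CC| would reach 1).
    """
    ro = optimal_weights(enc) if readout is None else readout
    cc0 = float(cc_from_readout(enc, ro, 0.0)[i])
    sigma0 = total_covariance(enc, 0.0)
    sd_d = float(np.sqrt(ro.weights @ sigma0 @ ro.weights))
    lam = lambda_fraction(enc, i)
    slope = np.sqrt(enc.sigma_g2) * lam * (1.0 - cc0**2)
    cc = cc0 + slope * np.asarray(delta_s, dtype=float) / sd_d
    if np.any(np.abs(cc) >= 1.0):
        raise ValueError("linear regime violated: |CC| >= 1 at requested ds")
    return cc if cc.ndim else float(cc)


def gain_cp_prediction(
    enc: PopulationEncoding, readout: ReadoutSpec | None = None
) -> GainCPPrediction:
    """Per-neuron lambda, CC(p_cr=0.5) and asymmetry slope beta_pCR.

    ``beta_pCR = sigma_g * lambda_i * (1 - CC_i(0.5)^2)`` is non-negative
    whenever ``sigma_g >= 0``: under the optimal decoder all its factors are
    positive.
    """
    ro = optimal_weights(enc) if readout is None else readout
    cc0 = cc_from_readout(enc, ro, 0.0)
    lam = np.array([lambda_fraction(enc, i) for i in range(enc.n_neurons)])
    slope = np.sqrt(enc.sigma_g2) * lam * (1.0 - cc0**2)
    return GainCPPrediction(lambda_i=lam, cc_half=cc0, slope=slope)


def cp_profile_prediction(
    enc: PopulationEncoding,
    i: int,
    pcr_grid,
    readout: ReadoutSpec | None = None,
    pcr_to_ds=None,
) -> np.ndarray:
    """Model CP(p_cr) profile for neuron i.

    Maps each choice rate on ``pcr_grid`` to a stimulus offset (by default
    the model-implied psychometric inverse ``ds = sd_d * Phi^-1(p_cr)``),
    evaluates the gain-induced CC at that offset and converts to a CP with
    the exact threshold-model solution.  The symmetric profile component
    comes from h(p_cr), the asymmetric one from the gain slope.
    """
    pcr = np.asarray(pcr_grid, dtype=float)
    if np.any((pcr <= 0) | (pcr >= 1)):
        raise ValueError("pcr_grid must lie strictly inside (0, 1)")
    ro = optimal_weights(enc) if readout is None else readout
    if pcr_to_ds is None:
        sigma0 = total_covariance(enc, 0.0)
        sd_d = float(np.sqrt(ro.weights @ sigma0 @ ro.weights))
        ds = sd_d * stats.norm.ppf(pcr)
    else:
        ds = np.asarray([pcr_to_ds(p) for p in pcr], dtype=float)
    cc = np.atleast_1d(cc_gain_profile(enc, i, ds, readout=ro))
    return np.array(
        [cp_exact(ThresholdModelParams(rho=c, p_cr=p)) for c, p in zip(cc, pcr)]
    )
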