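"""Empirical CP estimation and within-cell CP(p_cr) profiles.

The choice probability of a cell at one stimulus level is the Mann-Whitney
(rank-sum) estimator of ``p(r | D=+1 > r | D=-1)`` with half credit for ties,
computed only when enough trials are available (by default at least 15 in
total and 4 per choice).  Its standard error is approximated as

    SEM(CP) ~= 1 / sqrt(12 * K * p_cr * (1 - p_cr)),

which motivates the weighting used everywhere downstream: CP values are
combined with weights proportional to ``K * p_cr * (1 - p_cr)``, and the
standard error of a weighted combination of M estimates is
``1 / sqrt(12 * M * <w_U>)`` with ``<w_U>`` the mean unnormalized weight.

A cell's profile assigns its stimulus levels to five choice-rate bins

    [0, 0.3], [0.3, 0.5 - eps], (central: zero coherence only),
    [0.5 + eps, 0.7], [0.7, 1],

with ``eps`` chosen per data set so that only the uninformative stimulus
falls in the central bin.  The map from signed coherence to choice rate comes
from a psychometric fit (cumulative Gaussian with bias by default).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

__all__ = [
    "CPEstimate",
    "ExcludedCP",
    "PsychometricFit",
    "CPProfile",
    "N_BINS",
    "estimate_cp",
    "rank_auc",
    "cp_sem",
    "expected_choice_counts",
    "fit_psychometric",
    "build_cell_profile",
    "average_profiles",
]

N_BINS = 5
_CENTRAL = N_BINS // 2

#: psychometric predictions are clipped into this range before use
PCR_CLIP = (0.01, 0.99)


@dataclass(frozen=True)
class CPEstimate:
    """A single-level CP estimate with its approximate standard error."""

    cp: float
    sem: float
    n_trials: int
    p_cr: float
    coherence: float

    @property
    def weight(self) -> float:
        """Unnormalized combination weight ``K * p_cr * (1 - p_cr)``."""
        return self.n_trials * self.p_cr * (1.0 - self.p_cr)


@dataclass(frozen=True)
class ExcludedCP:
    """Sentinel returned when a level fails the inclusion criteria."""

    reason: str
    coherence: float = math.nan


def rank_auc(pos, neg) -> float:
    """Rank-based AUC: ``(#{pairs pos > neg} + 0.5 * #ties) / (n+ * n-)``.

    Tied pairs receive half credit (standard AUC convention), so identical
    samples give exactly 0.5.  Invariant under strictly monotone transforms.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def cp_sem(K: int, p_cr: float) -> float:
    """Approximate CP standard error, ``1 / sqrt(12 * K * p_cr * (1-p_cr))``."""
    if K < 1:
        raise ValueError("K must be at least 1")
    if not 0.0 < p_cr < 1.0:
        raise ValueError("p_cr must lie in (0, 1)")
    return 1.0 / math.sqrt(12.0 * K * p_cr * (1.0 - p_cr))


def expected_choice_counts(K: int, p_cr: float) -> tuple[float, float]:
    """Expected (D=+1, D=-1) trial counts among K trials at choice rate p_cr."""
    return K * p_cr, K * (1.0 - p_cr)


def estimate_cp(
    counts_choice_pos,
    counts_choice_neg,
    p_cr: float | None = None,
    coherence: float = math.nan,
    min_total: int = 15,
    min_per_choice: int = 4,
):
    """Rank-sum CP estimate for one stimulus level.

    Returns a :class:`CPEstimate`, or an :class:`ExcludedCP` sentinel when
    fewer than ``min_total`` trials or ``min_per_choice`` trials per choice
    are available.  ``p_cr`` (used for the SEM and weights) defaults to the
    empirical choice fraction, but callers should pass the
    psychometric-predicted rate where available — it is stabler at high
    coherence.
    """
    pos = np.asarray(counts_choice_pos, dtype=float)
    neg = np.asarray(counts_choice_neg, dtype=float)
    k = pos.size + neg.size
    if min(pos.size, neg.size) < min_per_choice:
        return ExcludedCP(
            reason=f"fewer than {min_per_choice} trials for one choice",
            coherence=coherence,
        )
    if k < min_total:
        return ExcludedCP(
            reason=f"fewer than {min_total} trials in total", coherence=coherence
        )
    if p_cr is None:
        p_cr = pos.size / k
    p_cr = float(np.clip(p_cr, *PCR_CLIP))
    return CPEstimate(
        cp=rank_auc(pos, neg),
        sem=cp_sem(k, p_cr),
        n_trials=k,
        p_cr=p_cr,
        coherence=coherence,
    )


@dataclass(frozen=True)
class PsychometricFit:
    """Monotone map from signed coherence to choice rate.

    ``family`` is "probit" (cumulative Gaussian, the default) or "logit".
    ``bias`` and ``slope`` parameterize the linear predictor
    ``eta = slope * (s - bias)``; ``slope > 0`` so the map is strictly
    increasing.  Predictions are clipped to [0.01, 0.99].
    """

    bias: float
    slope: float
    family: str = "probit"

    def predict(self, s) -> np.ndarray:
        eta = self.slope * (np.asarray(s, dtype=float) - self.bias)
        if self.family == "probit":
            p = stats.norm.cdf(eta)
        else:
            p = 1.0 / (1.0 + np.exp(-eta))
        out = np.clip(p, *PCR_CLIP)
        return out if out.ndim else float(out)

    def inverse(self, p_cr) -> np.ndarray:
        p = np.asarray(p_cr, dtype=float)
        if self.family == "probit":
            eta = stats.norm.ppf(p)
        else:
            eta = np.log(p / (1.0 - p))
        out = self.bias + eta / self.slope
        return out if out.ndim else float(out)


def fit_psychometric(trials: pd.DataFrame, family: str = "probit") -> PsychometricFit:
    """Fit the psychometric function by binomial maximum likelihood.

    ``trials`` needs ``coherence`` and ``choice`` columns (one row per trial;
    a per-neuron trial table may be passed after de-duplicating trials).
    Requires at least three coherence levels spanning both signs and both
    choices present overall.
    """
    if family not in ("probit", "logit"):
        raise ValueError(f"unknown psychometric family {family!r}")
    per_trial = trials.drop_duplicates(subset=["trial_id"]) if "trial_id" in trials else trials
    grouped = per_trial.groupby("coherence")["choice"]
    n_pos = grouped.apply(lambda c: int((c == 1).sum()))
    n_tot = grouped.size()
    s = n_pos.index.to_numpy(dtype=float)
    if s.size < 3 or s.min() >= 0 or s.max() <= 0:
        raise ValueError("need at least three coherence levels spanning both signs")
    if n_pos.sum() == 0 or n_pos.sum() == n_tot.sum():
        raise ValueError("degenerate data: all trials have the same choice")
    endog = np.column_stack([n_pos.to_numpy(), (n_tot - n_pos).to_numpy()])
    exog = sm.add_constant(s)
    link = sm.families.links.Probit() if family == "probit" else sm.families.links.Logit()
    res = sm.GLM(endog, exog, family=sm.families.Binomial(link=link)).fit()
    b0, b1 = res.params
    if b1 <= 0:
        raise ValueError("fitted psychometric slope is not positive")
    return PsychometricFit(bias=-b0 / b1, slope=b1, family=family)


@dataclass
class CPProfile:
    """Five-bin CP(p_cr) profile of one cell (or a cell average).

    ``cp_by_bin``/``sem_by_bin`` hold NaN for empty bins; ``weight_by_bin``
    is the total unnormalized weight ``sum_j K_j p_j (1 - p_j)`` of each bin
    and doubles as the weight of the bin value in across-cell averages.
    """

    cell_id: object
    cp_by_bin: np.ndarray
    sem_by_bin: np.ndarray
    weight_by_bin: np.ndarray
    pcr_by_bin: np.ndarray

    @property
    def complete(self) -> bool:
        return bool(np.all(np.isfinite(self.cp_by_bin)))

    @property
    def mean_cp(self) -> float:
        """Bin-weighted mean CP (inverse-error weighting across bins)."""
        mask = np.isfinite(self.cp_by_bin)
        w = self.weight_by_bin[mask]
        return float(np.sum(w * self.cp_by_bin[mask]) / np.sum(w))

    @property
    def group(self) -> str:
        """"above" if the weighted mean CP is >= 0.5 else "below"."""
        return "above" if self.mean_cp >= 0.5 else "below"


def central_epsilon(pcr_levels, coherences) -> float:
    """Half-width of the central bin: half the minimum |p_cr - 0.5| over
    informative (nonzero coherence) levels, so only zero coherence can land
    in the central bin."""
    pcr_levels = np.asarray(pcr_levels, dtype=float)
    coherences = np.asarray(coherences, dtype=float)
    informative = coherences != 0.0
    if not np.any(informative):
        return 0.05
    return 0.5 * float(np.min(np.abs(pcr_levels[informative] - 0.5)))


def assign_bin(p_cr: float, coherence: float, eps: float) -> int:
    """Bin index (0..4) of a stimulus level given its choice rate."""
    if coherence == 0.0 or abs(p_cr - 0.5) < eps:
        return _CENTRAL
    if p_cr <= 0.3:
        return 0
    if p_cr < 0.5:
        return 1
    if p_cr < 0.7:
        return 3
    return 4


def _combine_estimates(estimates: list[CPEstimate]) -> tuple[float, float, float, float]:
    """Weighted CP, SEM per the pooled-error rule, total weight, mean p_cr."""
    w = np.array([e.weight for e in estimates])
    cp = np.array([e.cp for e in estimates])
    pcr = np.array([e.p_cr for e in estimates])
    wsum = float(w.sum())
    cp_bar = float(np.sum(w * cp) / wsum)
    sem = 1.0 / math.sqrt(12.0 * wsum)  # = 1/sqrt(12 * M * <w_U>)
    pcr_bar = float(np.sum(w * pcr) / wsum)
    return cp_bar, sem, wsum, pcr_bar


def build_cell_profile(
    cell_trials: pd.DataFrame,
    psych: PsychometricFit,
    min_total: int = 15,
    min_per_choice: int = 4,
    eps: float | None = None,
    response_col: str = "count",
) -> CPProfile:
    """Construct the five-bin CP(p_cr) profile of one cell.

    Levels failing the inclusion criteria are dropped; incompleteness is
    encoded in the profile's ``complete`` flag rather than raised.
    """
    levels = np.sort(cell_trials["coherence"].unique())
    pcr_levels = np.atleast_1d(psych.predict(levels))
    if eps is None:
        eps = central_epsilon(pcr_levels, levels)
    per_bin: list[list[CPEstimate]] = [[] for _ in range(N_BINS)]
    for s, p in zip(levels, pcr_levels):
        grp = cell_trials[cell_trials["coherence"] == s]
        est = estimate_cp(
            grp.loc[grp["choice"] == 1, response_col],
            grp.loc[grp["choice"] == -1, response_col],
            p_cr=p,
            coherence=s,
            min_total=min_total,
            min_per_choice=min_per_choice,
        )
        if isinstance(est, CPEstimate):
            per_bin[assign_bin(p, s, eps)].append(est)
    cp = np.full(N_BINS, np.nan)
    sem = np.full(N_BINS, np.nan)
    weight = np.zeros(N_BINS)
    pcr = np.full(N_BINS, np.nan)
    for k, ests in enumerate(per_bin):
        if ests:
            cp[k], sem[k], weight[k], pcr[k] = _combine_estimates(ests)
    cell_id = cell_trials["cell_id"].iloc[0] if "cell_id" in cell_trials else None
    return CPProfile(
        cell_id=cell_id,
        cp_by_bin=cp,
        sem_by_bin=sem,
        weight_by_bin=weight,
        pcr_by_bin=pcr,
    )


def average_profiles(profiles: list[CPProfile], group: str = "above") -> CPProfile:
    """Across-cell weighted average of complete profiles in one CP group.

    Uses the same inverse-error weighting as within-cell combination: each
    cell's bin value enters with its total unnormalized bin weight, and the
    pooled SEM is ``1/sqrt(12 * sum of weights)``.  Cells with weighted mean
    CP exactly 0.5 belong to the "above" group.
    """
    if group not in ("above", "below"):
        raise ValueError("group must be 'above' or 'below'")
    members = [p for p in profiles if p.complete and p.group == group]
    if not members:
        raise ValueError(f"no complete profiles in group {group!r}")
    w = np.stack([p.weight_by_bin for p in members])
    cp = np.stack([p.cp_by_bin for p in members])
    pcr = np.stack([p.pcr_by_bin for p in members])
    wsum = w.sum(axis=0)
    return CPProfile(
        cell_id=f"average({group}, n={len(members)})",
        cp_by_bin=(w * cp).sum(axis=0) / wsum,
        sem_by_bin=1.0 / np.sqrt(12.0 * wsum),
        weight_by_bin=wsum,
        pcr_by_bin=(w * pcr).sum(axis=0) / wsum,
    )
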