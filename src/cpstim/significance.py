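"""Surrogate test of the null hypothesis of a choice-rate-independent CP.

The null states that a cell's CP is flat across stimulus levels; any
structure in an estimated CP(p_cr) profile would then be an artifact of the
varying trial counts and choice rates across bins.  Surrogate data sets are
built to be exactly compatible with that null while preserving the per-level,
per-choice trial counts of the original data:

1. Responses from levels inside a low-information coherence window (default
   -1.6% to +1.6%) are pooled after a *choice-conditioned* z-scoring: the
   level mean is the unweighted average of the two choice-conditional means
   and the level SD is built from the balanced pooled deviations, so that
   choice-rate imbalance does not bias the normalization (ordinary z-scoring
   would shrink the choice separation and underestimate CPs).
2. Each surrogate redraws, for every stimulus level of the cell, the original
   number of D=+1 trials from the D=+1 pool and of D=-1 trials from the D=-1
   pool, with replacement.
3. A CP(p_cr) profile is computed from each surrogate exactly as from the
   data, summarized by the mean of consecutive bin differences (optionally
   sign-flipped below p_cr = 0.5 to target symmetric modulation, and
   additionally inverted for cells with mean CP below 0.5 to target the
   threshold-model prediction), and the one-sided p-value is the fraction of
   surrogates whose statistic reaches the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cp_profiles import (
    CPEstimate,
    CPProfile,
    N_BINS,
    assign_bin,
    central_epsilon,
    estimate_cp,
)

__all__ = [
    "SurrogateConfig",
    "choice_conditioned_zscore",
    "generate_surrogate",
    "delta_cp_statistic",
    "empirical_pvalue",
    "surrogate_test",
]

_VARIANTS = ("asymmetric", "symmetric", "threshold-model")


@dataclass
class SurrogateConfig:
    """Configuration of the surrogate test."""

    n_surrogates: int = 8000
    window: tuple = (-1.6, 1.6)
    variant: str = "symmetric"
    seed: int = 0
    min_total: int = 15
    min_per_choice: int = 4
    response_col: str = "count"

    def __post_init__(self) -> None:
        if self.n_surrogates < 100:
            raise ValueError("n_surrogates must be at least 100")
        lo, hi = self.window
        if not np.isclose(lo, -hi):
            raise ValueError("pooling window must be symmetric about 0")
        if self.variant not in _VARIANTS:
            raise ValueError(f"variant must be one of {_VARIANTS}")


def choice_conditioned_zscore(
    cell_trials: pd.DataFrame,
    window: tuple = (-1.6, 1.6),
    response_col: str = "count",
) -> dict:
    """Choice-balanced z-scored response pool from the low-information window.

    Within each level of the window, responses are normalized with a mean
    equal to the unweighted average of the two choice-conditional means and
    an SD from the balanced (choice-unweighted) pooled squared deviations.
    With exactly balanced choices this reduces to ordinary per-level
    z-scoring.  Levels with one choice absent are skipped with a warning.
    Returns ``{+1: z_pos, -1: z_neg}``.
    """
    lo, hi = window
    sel = cell_trials[(cell_trials["coherence"] >= lo) & (cell_trials["coherence"] <= hi)]
    pool = {1: [], -1: []}
    for s, grp in sel.groupby("coherence"):
        pos = grp.loc[grp["choice"] == 1, response_col].to_numpy(dtype=float)
        neg = grp.loc[grp["choice"] == -1, response_col].to_numpy(dtype=float)
        if pos.size == 0 or neg.size == 0:
            warnings.warn(
                f"level {s}: one choice absent inside the pooling window; skipped",
                stacklevel=2,
            )
            continue
        m = 0.5 * (pos.mean() + neg.mean())
        var = 0.5 * (np.mean((pos - m) ** 2) + np.mean((neg - m) ** 2))
        if var <= 0:
            warnings.warn(f"level {s}: zero variance; skipped", stacklevel=2)
            continue
        sd = np.sqrt(var)
        pool[1].append((pos - m) / sd)
        pool[-1].append((neg - m) / sd)
    if not pool[1] or not pool[-1]:
        raise ValueError("both choices must be present in the pooling window")
    return {c: np.concatenate(v) for c, v in pool.items()}


def generate_surrogate(
    cell_trials: pd.DataFrame,
    pool: dict,
    rng: np.random.Generator,
    response_col: str = "count",
) -> pd.DataFrame:
    """One surrogate slice: per-level per-choice counts preserved exactly.

    The returned table has the original structure with the response column
    replaced by values resampled (with replacement) from the choice-matched
    normalized pool; responses are floats on the z-score scale, which is
    irrelevant to the rank-based CP estimator.
    """
    for c in (1, -1):
        if len(pool.get(c, ())) == 0:
            raise ValueError(f"empty pool for choice {c}")
    out = cell_trials.copy()
    values = np.empty(len(out), dtype=float)
    for c in (1, -1):
        mask = (out["choice"] == c).to_numpy()
        values[mask] = rng.choice(pool[c], size=int(mask.sum()), replace=True)
    out[response_col] = values
    return out


def _delta_stats(cp: np.ndarray, variant: str, mean_cp: np.ndarray | None = None):
    """Vectorized delta-CP statistic over rows of a (S, 5) bin-CP matrix."""
    d = np.diff(cp, axis=1)
    if variant == "asymmetric":
        return d.mean(axis=1)
    flip = np.array([-1.0, -1.0, 1.0, 1.0])  # bins 1..2 lie below p_cr = 0.5
    s = (d * flip).mean(axis=1)
    if variant == "symmetric":
        return s
    sign = np.where(mean_cp >= 0.5, 1.0, -1.0)
    return s * sign


def delta_cp_statistic(profile: CPProfile, variant: str = "symmetric") -> float:
    """Scalar modulation statistic of one complete profile.

    asymmetric: mean of consecutive bin differences; symmetric: same after
    flipping the sign of differences between bins below p_cr = 0.5;
    threshold-model: symmetric, additionally inverted when the cell's mean
    CP is below 0.5.
    """
    if variant not in _VARIANTS:
        raise ValueError(f"variant must be one of {_VARIANTS}")
    if not profile.complete:
        raise ValueError("delta-CP statistic requires a complete profile")
    return float(
        _delta_stats(
            profile.cp_by_bin[None, :], variant, np.array([profile.mean_cp])
        )[0]
    )


def empirical_pvalue(observed: float, surrogate_stats) -> float:
    """One-sided p-value: fraction of surrogates with statistic >= observed."""
    surrogate_stats = np.asarray(surrogate_stats, dtype=float)
    if surrogate_stats.size < 100:
        raise ValueError("need at least 100 surrogate statistics")
    return float(np.mean(surrogate_stats >= observed))


# ---------------------------------------------------------------------------
# batched surrogate engine


@dataclass
class _CellStructure:
    """Frozen per-cell level structure reused across surrogates."""

    levels: list = field(default_factory=list)  # (n_pos, n_neg, bin, weight)
    observed_cp: np.ndarray = None
    bin_weights: np.ndarray = None
    observed_profile: CPProfile = None
    pool: dict = None


def _cell_structure(cell_trials, psych, config) -> _CellStructure | None:
    """Per-level observed CPs, bin assignment and pools for one cell."""
    predict = psych.predict if hasattr(psych, "predict") else psych
    levels = np.sort(cell_trials["coherence"].unique())
    pcr = np.atleast_1d(np.asarray([predict(s) for s in levels], dtype=float))
    eps = central_epsilon(pcr, levels)
    struct = _CellStructure()
    ests = []
    for s, p in zip(levels, pcr):
        grp = cell_trials[cell_trials["coherence"] == s]
        est = estimate_cp(
            grp.loc[grp["choice"] == 1, config.response_col],
            grp.loc[grp["choice"] == -1, config.response_col],
            p_cr=p,
            coherence=s,
            min_total=config.min_total,
            min_per_choice=config.min_per_choice,
        )
        if isinstance(est, CPEstimate):
            n_pos = int((grp["choice"] == 1).sum())
            n_neg = est.n_trials - n_pos
            struct.levels.append((n_pos, n_neg, assign_bin(p, s, eps), est.weight))
            ests.append(est)
    if not struct.levels:
        return None
    bins = np.array([lv[2] for lv in struct.levels])
    weights = np.array([lv[3] for lv in struct.levels])
    bin_w = np.zeros(N_BINS)
    np.add.at(bin_w, bins, weights)
    if np.any(bin_w == 0):
        return None  # incomplete profile: cell excluded from the test
    struct.observed_cp = np.array([e.cp for e in ests])
    struct.bin_weights = bin_w
    struct.pool = choice_conditioned_zscore(
        cell_trials, window=config.window, response_col=config.response_col
    )
    return struct


def _bin_profiles(level_cps: np.ndarray, struct: _CellStructure) -> np.ndarray:
    """Weighted (S, 5) bin-CP matrix from an (S, L) level-CP matrix."""
    s = level_cps.shape[0]
    num = np.zeros((s, N_BINS))
    for j, (_, _, b, w) in enumerate(struct.levels):
        num[:, b] += w * level_cps[:, j]
    return num / struct.bin_weights


def _batched_auc(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Row-wise rank AUC for (S, n+) vs (S, n-) samples with half tie credit."""
    gt = (pos[:, :, None] > neg[:, None, :]).sum(axis=(1, 2))
    eq = (pos[:, :, None] == neg[:, None, :]).sum(axis=(1, 2))
    return (gt + 0.5 * eq) / (pos.shape[1] * neg.shape[1])


def _surrogate_level_cps(
    struct: _CellStructure, n_surrogates: int, rng: np.random.Generator,
    chunk: int = 2000,
) -> np.ndarray:
    """(S, L) matrix of surrogate per-level CPs for one cell."""
    pos_pool = struct.pool[1]
    neg_pool = struct.pool[-1]
    out = np.empty((n_surrogates, len(struct.levels)))
    for j, (n_pos, n_neg, _, _) in enumerate(struct.levels):
        done = 0
        while done < n_surrogates:
            s = min(chunk, n_surrogates - done)
            pos = pos_pool[rng.integers(0, pos_pool.size, size=(s, n_pos))]
            neg = neg_pool[rng.integers(0, neg_pool.size, size=(s, n_neg))]
            out[done : done + s, j] = _batched_auc(pos, neg)
            done += s
    return out


def surrogate_test(
    cells,
    psych,
    config: SurrogateConfig | None = None,
) -> dict:
    """Run the surrogate test on one cell or on a group of cells.

    ``cells`` is a single-cell trial table or a list of them (the grouped
    statistic is computed on the across-cell weighted-average profile, using
    only cells with complete profiles).  ``psych`` is a
    :class:`~cpstim.cp_profiles.PsychometricFit` or any callable mapping a
    signed coherence to a choice rate.  Returns a dict with the observed
    statistic, the surrogate statistics, the one-sided p-value and the
    number of cells used.
    """
    config = SurrogateConfig() if config is None else config
    if isinstance(cells, pd.DataFrame):
        cells = [cells]
    rng = np.random.default_rng(config.seed)
    structs = []
    for cell in cells:
        st = _cell_structure(cell, psych, config)
        if st is not None:
            structs.append(st)
    if not structs:
        raise ValueError("no cell yields a complete CP(p_cr) profile")

    total_w = np.sum([st.bin_weights for st in structs], axis=0)
    obs_bins = np.zeros((1, N_BINS))
    surr_bins = np.zeros((config.n_surrogates, N_BINS))
    for st in structs:
        obs_bins += st.bin_weights * _bin_profiles(st.observed_cp[None, :], st)
        level_cps = _surrogate_level_cps(st, config.n_surrogates, rng)
        surr_bins += st.bin_weights * _bin_profiles(level_cps, st)
    obs_bins /= total_w
    surr_bins /= total_w

    mean_w = total_w / total_w.sum()
    obs_mean = float(obs_bins[0] @ mean_w)
    surr_mean = surr_bins @ mean_w
    observed = float(_delta_stats(obs_bins, config.variant, np.array([obs_mean]))[0])
    surr_stats = _delta_stats(surr_bins, config.variant, surr_mean)
    return {
        "statistic": observed,
        "p_value": empirical_pvalue(observed, surr_stats),
        "n_surrogates": config.n_surrogates,
        "n_cells": len(structs),
        "variant": config.variant,
        "surrogate_stats": surr_stats,
        "profile_cp": obs_bins[0],
    }
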