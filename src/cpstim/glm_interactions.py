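"""Poisson GLMs of spike counts with stimulus-choice interaction terms.

Three nested models of a cell's per-trial count ``r`` are compared:

* stimulus-only:            ``log mu = sum_{j=0..4} a_j s^j``
* stimulus-independent-choice: adds a single choice term ``b D``
* stimulus-dependent-choice:   adds ``sum_{j=1..Nc} I_{Pj}(p_cr) b_j D``,
  where the indicator partitions the choice-rate bins into ``Nc`` subsets,
  allowing the strength — and the sign — of the choice influence on the rate
  to differ across stimulus levels.

The partition is derived from the cell's CP(p_cr) profile by exact 1-D
k-means on the bin CPs (non-contiguous groupings allowed: a symmetric
profile groups the two extreme bins together, which plain p_cr tiling could
not represent).  Models are compared by the cross-validated relative
increase in likelihood,

    RIL = (L(choice, stimulus) - L(stimulus)) / (L(stimulus) - L0),

with L0 the constant-rate null, using a trial-matched scheme: within each
choice-level group the training set contains equal numbers of trials of the
two choices (80% of the smaller choice pool), so the fitted choice
coefficients are not biased by choice-rate imbalance.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cp_profiles import CPProfile, N_BINS

__all__ = [
    "GLMSpec",
    "GLMFit",
    "RILResult",
    "partition_choice_levels",
    "fit_poisson_glm",
    "crossval_ril",
    "ril_summary",
    "MODEL_TYPES",
]

POLY_ORDER = 4
MODEL_TYPES = ("stimulus", "stim-indep-choice", "stim-dep-choice")


@dataclass
class GLMSpec:
    """Model structure: polynomial order, choice levels, bin partition.

    ``partition`` maps each p_cr bin index (0..4) to a choice-level index in
    ``0..n_choice_levels-1``; with ``n_choice_levels == 0`` the model has no
    choice terms (stimulus-only).
    """

    n_choice_levels: int
    partition: dict = field(default_factory=dict)
    poly_order: int = POLY_ORDER

    def __post_init__(self) -> None:
        if self.n_choice_levels < 0 or self.n_choice_levels > N_BINS:
            raise ValueError("n_choice_levels must lie in 0..5")
        if self.n_choice_levels > 0:
            covered = set(self.partition.values())
            if covered != set(range(self.n_choice_levels)):
                raise ValueError("partition must cover every choice level")


@dataclass
class GLMFit:
    """Fitted coefficients (raw stimulus scale) and log-likelihoods."""

    a: np.ndarray  # a0..a4, log-rate units per stimulus power
    b: np.ndarray  # one choice coefficient per choice level (may be empty)
    loglik_train: float
    converged: bool
    scale: float  # internal stimulus standardization factor


@dataclass
class RILResult:
    """Cross-validated relative increase in likelihood for one model type."""

    ril: float
    loglik_null: float
    loglik_stimulus: float
    loglik_choice: float
    n_repeats: int
    n_choice_levels: int = 0


def _kmeans_1d(values: np.ndarray, k: int) -> np.ndarray:
    """Exact 1-D k-means by enumeration of contiguous splits in sorted order.

    Optimal 1-D k-means clusters are contiguous after sorting; with five
    values and k <= 3 full enumeration is trivial.  Returns cluster labels
    ordered by cluster mean.
    """
    n = values.size
    if k > np.unique(values).size:
        raise ValueError("more clusters than distinct values")
    order = np.argsort(values, kind="stable")
    best_sse, best_labels = np.inf, None
    for cuts in itertools.combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        labels = np.empty(n, dtype=int)
        sse = 0.0
        for j in range(k):
            idx = order[bounds[j] : bounds[j + 1]]
            vals = values[idx]
            sse += float(np.sum((vals - vals.mean()) ** 2))
            labels[idx] = j
        if sse < best_sse - 1e-15:
            best_sse, best_labels = sse, labels
    return best_labels


def partition_choice_levels(profile, n_levels: int) -> GLMSpec:
    """Derive the bin-to-choice-level partition from a CP(p_cr) profile.

    Euclidean k-means on the five scalar bin CPs (solved exactly); bins in
    the same cluster share one choice coefficient.
    """
    cps = (
        profile.cp_by_bin if isinstance(profile, CPProfile) else np.asarray(profile)
    )
    if not np.all(np.isfinite(cps)):
        raise ValueError("partitioning requires a complete profile")
    if n_levels == 1:
        return GLMSpec(n_choice_levels=1, partition={b: 0 for b in range(N_BINS)})
    labels = _kmeans_1d(np.asarray(cps, dtype=float), n_levels)
    return GLMSpec(
        n_choice_levels=n_levels, partition={b: int(l) for b, l in enumerate(labels)}
    )


def _design_matrix(
    s: np.ndarray, choice: np.ndarray, bins: np.ndarray, spec: GLMSpec, scale: float
) -> np.ndarray:
    cols = [(s / scale) ** j for j in range(spec.poly_order + 1)]
    for level in range(spec.n_choice_levels):
        member = np.array(
            [spec.partition.get(int(b), -1) == level for b in bins], dtype=float
        )
        cols.append(member * choice)
    return np.column_stack(cols)


def fit_poisson_glm(
    trials: pd.DataFrame,
    spec: GLMSpec,
    bin_col: str = "pcr_bin",
    response_col: str = "count",
) -> GLMFit:
    """Maximum-likelihood Poisson fit with log link (IRLS).

    ``trials`` needs ``coherence``, ``choice`` (in {-1, +1}), the response
    column, and — when the model has choice terms — a ``pcr_bin`` column
    with the p_cr bin index of each trial.  The stimulus covariate is
    standardized internally for conditioning; polynomial coefficients are
    reported on the raw scale.
    """
    s = trials["coherence"].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy(dtype=float)
    if not set(np.unique(choice)) <= {-1.0, 1.0}:
        raise ValueError("choice must be coded as -1/+1")
    y = trials[response_col].to_numpy(dtype=float)
    bins = (
        trials[bin_col].to_numpy()
        if spec.n_choice_levels > 0
        else np.zeros(len(trials), dtype=int)
    )
    scale = float(np.max(np.abs(s))) or 1.0
    design = _design_matrix(s, choice, bins, spec, scale)
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("design matrix is rank deficient")
    converged = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.GLM(y, design, family=sm.families.Poisson()).fit(
                maxiter=200, tol=1e-10
            )
            params = res.params
            loglik = float(res.llf)
            if not np.all(np.isfinite(params)):
                converged = False
        except Exception:  # separation / divergence
            converged = False
            params = np.full(design.shape[1], np.nan)
            loglik = -np.inf
    a_scaled = params[: spec.poly_order + 1]
    a_raw = a_scaled / scale ** np.arange(spec.poly_order + 1)
    return GLMFit(
        a=a_raw,
        b=params[spec.poly_order + 1 :],
        loglik_train=loglik,
        converged=converged,
        scale=scale,
    )


def _predict_loglik(
    fit: GLMFit, spec: GLMSpec, trials: pd.DataFrame,
    bin_col: str = "pcr_bin", response_col: str = "count",
) -> float:
    """Summed Poisson log-likelihood of held-out trials under a fit."""
    s = trials["coherence"].to_numpy(dtype=float)
    choice = trials["choice"].to_numpy(dtype=float)
    y = trials[response_col].to_numpy(dtype=float)
    bins = (
        trials[bin_col].to_numpy()
        if spec.n_choice_levels > 0
        else np.zeros(len(trials), dtype=int)
    )
    design = _design_matrix(s, choice, bins, spec, fit.scale)
    params = np.concatenate([fit.a * fit.scale ** np.arange(spec.poly_order + 1), fit.b])
    eta = design @ params
    mu = np.exp(np.clip(eta, -30, 30))
    from scipy.special import gammaln

    return float(np.sum(y * eta - mu - gammaln(y + 1.0)))


def _assign_bins(trials: pd.DataFrame, psych, eps: float | None = None) -> pd.DataFrame:
    """Attach the p_cr bin index of each trial (via the psychometric map)."""
    from .cp_profiles import assign_bin, central_epsilon

    predict = psych.predict if hasattr(psych, "predict") else psych
    levels = np.sort(trials["coherence"].unique())
    pcr = np.atleast_1d(np.asarray([predict(s) for s in levels], dtype=float))
    if eps is None:
        eps = central_epsilon(pcr, levels)
    mapping = {
        s: assign_bin(p, s, eps) for s, p in zip(levels, pcr)
    }
    out = trials.copy()
    out["pcr_bin"] = out["coherence"].map(mapping)
    out["p_cr"] = out["coherence"].map(dict(zip(levels, pcr)))
    return out


def _matched_split(
    trials: pd.DataFrame, spec: GLMSpec, rng: np.random.Generator,
    train_frac: float = 0.8,
) -> tuple[np.ndarray, np.ndarray]:
    """Choice-balanced train/test split within each choice-level group.

    Within every choice-level group, the training set receives the same
    number of trials of each choice — ``floor(train_frac * size of the
    smaller choice pool)`` — drawn at random; all remaining trials form the
    test set.
    """
    groups = trials["pcr_bin"].map(lambda b: spec.partition.get(int(b), 0))
    train_idx = []
    for _, grp in trials.groupby(groups):
        pos = grp.index[grp["choice"] == 1].to_numpy()
        neg = grp.index[grp["choice"] == -1].to_numpy()
        n_train = int(train_frac * min(pos.size, neg.size))
        if n_train < 1:
            continue
        train_idx.append(rng.choice(pos, size=n_train, replace=False))
        train_idx.append(rng.choice(neg, size=n_train, replace=False))
    if not train_idx:
        raise ValueError("no choice-level group has enough trials of each choice")
    train = np.concatenate(train_idx)
    test = trials.index.difference(train).to_numpy()
    return train, test


def crossval_ril(
    trials: pd.DataFrame,
    profile,
    psych,
    n_repeats: int = 50,
    seed: int = 0,
    nc_candidates: tuple = (2, 3),
    response_col: str = "count",
) -> dict:
    """Trial-matched cross-validated RIL for the three model types.

    Per repeat, a fresh choice-balanced split is drawn (sub-seeded from the
    master seed); all models are fitted on the same training set and their
    held-out log-likelihoods accumulated.  Log-likelihoods are averaged over
    repeats before forming the RIL ratio against the constant-rate null.
    For the stimulus-dependent-choice family the most predictive of
    ``Nc in nc_candidates`` is reported.  Returns ``{model_type: RILResult}``.
    """
    trials = _assign_bins(trials, psych)
    specs: dict = {
        "stimulus": GLMSpec(n_choice_levels=0),
        "stim-indep-choice": partition_choice_levels(profile, 1),
    }
    dep_specs = {}
    for nc in nc_candidates:
        try:
            dep_specs[nc] = partition_choice_levels(profile, nc)
        except ValueError:
            continue
    if not dep_specs:
        raise ValueError("no feasible Nc for the stimulus-dependent-choice model")

    # the split must balance choices within the finest partition in play
    split_spec = dep_specs[max(dep_specs)]
    rng = np.random.default_rng(seed)
    keys = ["null", *specs.keys(), *[("dep", nc) for nc in dep_specs]]
    tot = {k: 0.0 for k in keys}
    n_done = 0
    for _ in range(n_repeats):
        sub_rng = np.random.default_rng(rng.integers(2**31))
        try:
            train, test = _matched_split(trials, split_spec, sub_rng)
        except ValueError:
            continue
        tr, te = trials.loc[train], trials.loc[test]
        if len(te) == 0:
            continue
        y_tr = tr[response_col].to_numpy(dtype=float)
        y_te = te[response_col].to_numpy(dtype=float)
        mu0 = max(y_tr.mean(), 1e-12)
        from scipy.special import gammaln

        tot["null"] += float(
            np.sum(y_te * np.log(mu0) - mu0 - gammaln(y_te + 1.0))
        )
        for name, spec in specs.items():
            fit = fit_poisson_glm(tr, spec, response_col=response_col)
            tot[name] += _predict_loglik(fit, spec, te, response_col=response_col)
        for nc, spec in dep_specs.items():
            fit = fit_poisson_glm(tr, spec, response_col=response_col)
            tot[("dep", nc)] += _predict_loglik(fit, spec, te, response_col=response_col)
        n_done += 1
    if n_done == 0:
        raise ValueError("all cross-validation repeats were skipped")
    avg = {k: v / n_done for k, v in tot.items()}
    l0, l_stim = avg["null"], avg["stimulus"]
    denom = l_stim - l0
    if denom <= 0:
        warnings.warn("stimulus model does not beat the null; RIL unstable",
                      stacklevel=2)
        denom = max(denom, 1e-12)

    def _result(l_choice: float, nc: int) -> RILResult:
        return RILResult(
            ril=(l_choice - l_stim) / denom,
            loglik_null=l0,
            loglik_stimulus=l_stim,
            loglik_choice=l_choice,
            n_repeats=n_done,
            n_choice_levels=nc,
        )

    best_nc = max(dep_specs, key=lambda nc: avg[("dep", nc)])
    return {
        "stim-indep-choice": _result(avg["stim-indep-choice"], 1),
        "stim-dep-choice": _result(avg[("dep", best_nc)], best_nc),
    }


def ril_summary(results_per_cell: dict, threshold: float = 0.1) -> pd.DataFrame:
    """Mean RIL and fraction of cells above threshold, per model type.

    ``results_per_cell`` maps a cell id to the dict returned by
    :func:`crossval_ril` (optionally grouped upstream); empty groups are
    omitted by construction.
    """
    rows = []
    for model in ("stim-indep-choice", "stim-dep-choice"):
        rils = np.array(
            [res[model].ril for res in results_per_cell.values() if model in res]
        )
        if rils.size == 0:
            continue
        rows.append(
            {
                "model": model,
                "n_cells": rils.size,
                "mean_ril": float(rils.mean()),
                "prop_above_threshold": float(np.mean(rils > threshold)),
            }
        )
    return pd.DataFrame(rows)
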