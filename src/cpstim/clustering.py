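"""Discovery of shared CP(p_cr) patterns across cells.

Profiles are represented as the five-vectors ``CP - 0.5`` and compared by
cosine distance, which is sensitive to both the shape and the sign of the
modulation (so cells with CP above and below 0.5 separate naturally at
k = 2).  Beyond exploratory k-means the module provides: projections onto a
symmetric (constant) and an asymmetric (centered linear) template, the 2-D
embedding spanned by the main-cluster and subcluster center directions, the
quadratic fit that extracts an empirical asymmetry slope from CP versus
stimulus level, and a surrogate-based significance test of per-cluster
modulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .cp_profiles import CPProfile, N_BINS
from .significance import (
    SurrogateConfig,
    _bin_profiles,
    _cell_structure,
    _delta_stats,
    _surrogate_level_cps,
    empirical_pvalue,
)

__all__ = [
    "ClusterResult",
    "kmeans_cosine",
    "template_projection",
    "embed_2d",
    "fit_cp_quadratic",
    "cluster_significance",
    "SYMMETRIC_TEMPLATE",
    "ASYMMETRIC_TEMPLATE",
]

#: unit-norm constant template (magnitude of CP - 0.5)
SYMMETRIC_TEMPLATE = np.ones(N_BINS) / np.sqrt(N_BINS)
#: unit-norm centered slope-1 template (monotone asymmetry)
ASYMMETRIC_TEMPLATE = (np.arange(N_BINS) - (N_BINS - 1) / 2) / np.sqrt(
    np.sum((np.arange(N_BINS) - (N_BINS - 1) / 2) ** 2)
)


@dataclass
class ClusterResult:
    """k-means result: labels per profile, centers, mean cosine dissimilarity."""

    labels: np.ndarray
    centers: np.ndarray
    inertia: float
    kept: np.ndarray  # indices of profiles actually clustered


def _profile_vectors(profiles) -> np.ndarray:
    if isinstance(profiles[0], CPProfile):
        return np.stack([p.cp_by_bin for p in profiles]) - 0.5
    return np.asarray(profiles, dtype=float) - 0.5


def kmeans_cosine(
    profiles, k: int, seed: int = 0, n_restarts: int = 100, max_iter: int = 100
) -> ClusterResult:
    """k-means on ``CP - 0.5`` vectors under cosine distance.

    Spherical k-means: vectors are scale-normalized, assignment maximizes
    cosine similarity to the (normalized) cluster centers, and the best of
    ``n_restarts`` random initializations (fixed master seed) is kept.
    Zero vectors are excluded with a warning (cosine undefined); their
    labels are -1 in the returned assignment.
    """
    x = _profile_vectors(profiles)
    if not np.all(np.isfinite(x)):
        raise ValueError("profiles must be complete (finite in all bins)")
    norms = np.linalg.norm(x, axis=1)
    kept = np.flatnonzero(norms > 0)
    if kept.size < len(x):
        warnings.warn("zero-vector profiles excluded from clustering", stacklevel=2)
    if kept.size < k:
        raise ValueError("need at least k nonzero profiles")
    u = x[kept] / norms[kept, None]
    rng = np.random.default_rng(seed)
    best = None
    for _ in range(n_restarts):
        centers = u[rng.choice(kept.size, size=k, replace=False)]
        labels = np.zeros(kept.size, dtype=int)
        for _ in range(max_iter):
            sim = u @ centers.T
            new_labels = sim.argmax(axis=1)
            new_centers = centers.copy()
            for j in range(k):
                members = u[new_labels == j]
                if len(members):
                    c = members.mean(axis=0)
                    nc = np.linalg.norm(c)
                    if nc > 0:
                        new_centers[j] = c / nc
            if np.array_equal(new_labels, labels) and np.allclose(
                new_centers, centers
            ):
                break
            labels, centers = new_labels, new_centers
        inertia = float(np.mean(1.0 - (u @ centers.T)[np.arange(kept.size), labels]))
        if best is None or inertia < best.inertia - 1e-12:
            best = ClusterResult(
                labels=labels.copy(), centers=centers.copy(), inertia=inertia,
                kept=kept.copy(),
            )
    full_labels = np.full(len(x), -1, dtype=int)
    full_labels[best.kept] = best.labels
    return ClusterResult(
        labels=full_labels, centers=best.centers, inertia=best.inertia, kept=best.kept
    )


def template_projection(profile) -> tuple[float, float]:
    """(symmetric, asymmetric) scores of a profile.

    Inner products of ``CP - 0.5`` with the unit-norm constant and centered
    slope-1 templates; a flat profile has zero asymmetric score and a
    centered monotone profile zero symmetric score.
    """
    v = (
        profile.cp_by_bin - 0.5
        if isinstance(profile, CPProfile)
        else np.asarray(profile, dtype=float) - 0.5
    )
    if not np.all(np.isfinite(v)):
        raise ValueError("template projection requires a complete profile")
    return float(v @ SYMMETRIC_TEMPLATE), float(v @ ASYMMETRIC_TEMPLATE)


def embed_2d(
    profiles,
    main_centers: np.ndarray,
    sub_centers_by_group: dict,
    groups=None,
) -> np.ndarray:
    """Project profiles into the plane spanned by cluster-center directions.

    The horizontal axis is the difference between the two main-cluster
    centers (closely aligned with CP - 0.5); the vertical axis is, within
    each CP-sign group, the component of the subcluster-center difference
    orthogonal to the horizontal axis.  ``sub_centers_by_group`` maps a
    group key to a (2, 5) array of subcluster centers; ``groups`` assigns a
    key to each profile (a single key is broadcast).
    """
    x = _profile_vectors(profiles)
    main_centers = np.asarray(main_centers, dtype=float)
    axis1 = main_centers[0] - main_centers[1]
    n1 = np.linalg.norm(axis1)
    if n1 == 0:
        raise ValueError("coincident main-cluster centers")
    axis1 = axis1 / n1
    axes2 = {}
    for key, subs in sub_centers_by_group.items():
        subs = np.asarray(subs, dtype=float)
        diff = subs[0] - subs[1]
        diff = diff - (diff @ axis1) * axis1
        n2 = np.linalg.norm(diff)
        if n2 == 0:
            raise ValueError(f"coincident subcluster centers in group {key!r}")
        axes2[key] = diff / n2
    if groups is None:
        if len(axes2) != 1:
            raise ValueError("groups required when several subcluster groups exist")
        groups = [next(iter(axes2))] * len(x)
    coords = np.empty((len(x), 2))
    for i, (v, g) in enumerate(zip(x, groups)):
        coords[i] = (v @ axis1, v @ axes2[g])
    return coords


def fit_cp_quadratic(cp_values, stimulus_levels) -> float:
    """Linear coefficient of a least-squares quadratic fit of CP on stimulus.

    ``CP(s) = c0 + c1 s + c2 s^2``; returns ``c1``, the observed asymmetry
    slope.  Requires at least four points and a full-rank design.
    """
    s = np.asarray(stimulus_levels, dtype=float)
    y = np.asarray(cp_values, dtype=float)
    if s.size < 4:
        raise ValueError("need at least four points for the quadratic fit")
    design = np.column_stack([np.ones_like(s), s, s**2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("rank-deficient design (too few distinct levels)")
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    return float(coef[1])


def _match_clusters(surr_centers: np.ndarray, orig_centers: np.ndarray) -> np.ndarray:
    """Map original cluster index -> surrogate cluster index.

    Surrogate cluster labels are arbitrary, so clusters are matched to the
    originals greedily by center correlation (cosine similarity of the
    ``CP - 0.5`` center directions), which also respects the CP-sign split.
    """
    k = orig_centers.shape[0]
    sim = (orig_centers @ surr_centers.T).copy()
    mapping = np.full(k, -1, dtype=int)
    for _ in range(k):
        i, j = np.unravel_index(np.argmax(sim), sim.shape)
        mapping[i] = j
        sim[i, :] = -np.inf
        sim[:, j] = -np.inf
    return mapping


def cluster_significance(
    cells,
    psych,
    k: int = 2,
    config: SurrogateConfig | None = None,
    n_restarts: int = 10,
) -> dict:
    """Per-cluster surrogate p-values of the CP(p_cr) modulation.

    Clusters the observed profiles (cosine k-means), then for each surrogate
    replicate regenerates every cell's profile from its choice-conditioned
    null pool, re-runs the identical clustering, matches surrogate clusters
    to the originals by center correlation / CP sign, and computes the
    delta-CP statistic on each matched cluster's weighted-average profile.
    Returns ``{label: {"statistic", "p_value", "n_cells"}}`` plus the
    original labels under the key ``"labels"``.
    """
    config = SurrogateConfig() if config is None else config
    structs = [
        st for st in (_cell_structure(c, psych, config) for c in cells) if st is not None
    ]
    if len(structs) < k:
        raise ValueError("need at least k cells with complete profiles")
    obs_profiles = np.stack(
        [_bin_profiles(st.observed_cp[None, :], st)[0] for st in structs]
    )
    weights = np.stack([st.bin_weights for st in structs])
    orig = kmeans_cosine(obs_profiles, k, seed=config.seed, n_restarts=100)

    rng = np.random.default_rng(config.seed)
    surr_profiles = np.stack(
        [
            _bin_profiles(_surrogate_level_cps(st, config.n_surrogates, rng), st)
            for st in structs
        ],
        axis=1,
    )  # (S, n_cells, 5)

    def _cluster_stat(profiles: np.ndarray, labels: np.ndarray, lab: int) -> float:
        members = labels == lab
        w = weights[members]
        avg = (w * profiles[members]).sum(axis=0) / w.sum(axis=0)
        mean_w = w.sum(axis=0) / w.sum()
        return float(
            _delta_stats(avg[None, :], config.variant, np.array([avg @ mean_w]))[0]
        )

    observed = {
        int(lab): _cluster_stat(obs_profiles, orig.labels, lab) for lab in range(k)
    }
    surr_stats = {int(lab): np.empty(config.n_surrogates) for lab in range(k)}
    for s in range(config.n_surrogates):
        res = kmeans_cosine(surr_profiles[s], k, seed=int(rng.integers(2**31)),
                            n_restarts=n_restarts)
        mapping = _match_clusters(res.centers, orig.centers)
        for lab in range(k):
            surr_stats[lab][s] = _cluster_stat(
                surr_profiles[s], res.labels, mapping[lab]
            )
    out = {"labels": orig.labels, "centers": orig.centers}
    for lab in range(k):
        out[int(lab)] = {
            "statistic": observed[lab],
            "p_value": empirical_pvalue(observed[lab], surr_stats[lab]),
            "n_cells": int(np.sum(orig.labels == lab)),
        }
    return out
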