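"""CP estimation, psychometric fitting and profile construction."""

from itertools import product
from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cpstim as cp
from cpstim.cp_profiles import (
    CPEstimate,
    ExcludedCP,
    build_cell_profile,
    central_epsilon,
    cp_sem,
    estimate_cp,
    expected_choice_counts,
    rank_auc,
)
from cpstim.simulator import simulate_threshold_trials
from cpstim.threshold_model import ThresholdModelParams, cp_exact


def brute_force_auc(pos, neg):
    wins = sum(
        1.0 if a > b else (0.5 if a == b else 0.0) for a, b in product(pos, neg)
    )
    return wins / (len(pos) * len(neg))


class TestRankAUC:
    @pytest.mark.parametrize(
        "pos, neg, expected",
        [
            ([2, 4, 6], [1, 4, 5], 5.5 / 9),  # enumeration with half tie credit
            ([3, 3, 3], [3, 3, 3], 0.5),
            ([5, 6, 7, 8], [1, 2, 3, 4], 1.0),
        ],
    )
    def test_examples(self, pos, neg, expected):
        assert rank_auc(pos, neg) == pytest.approx(expected)
        assert rank_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    @given(
        st.lists(st.integers(0, 30), min_size=4, max_size=12),
        st.lists(st.integers(0, 30), min_size=4, max_size=12),
    )
    @settings(max_examples=60, deadline=None)
    def test_matches_enumeration_and_complement(self, pos, neg):
        assert rank_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))
        assert rank_auc(pos, neg) == pytest.approx(1.0 - rank_auc(neg, pos))

    @given(st.lists(st.integers(0, 50), min_size=4, max_size=10),
           st.lists(st.integers(0, 50), min_size=4, max_size=10))
    @settings(max_examples=40, deadline=None)
    def test_monotone_transform_invariance(self, pos, neg):
        f = lambda x: np.exp(0.3 * np.asarray(x, dtype=float)) + 2.0
        assert rank_auc(pos, neg) == pytest.approx(rank_auc(f(pos), f(neg)))


class TestCPEstimate:
    def test_inclusion_criteria(self):
        out = estimate_cp([1, 2, 3], [4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15])
        assert isinstance(out, ExcludedCP)
        assert "4 trials" in out.reason
        out = estimate_cp([1, 2, 3, 4], [5, 6, 7, 8])
        assert isinstance(out, ExcludedCP)
        assert "15 trials" in out.reason

    def test_estimate_fields(self):
        pos = list(range(10, 20))
        neg = list(range(8))
        est = estimate_cp(pos, neg, p_cr=0.6, coherence=3.2)
        assert isinstance(est, CPEstimate)
        assert est.cp == 1.0
        assert est.n_trials == 18
        assert est.sem == pytest.approx(cp_sem(18, 0.6))
        assert est.weight == pytest.approx(18 * 0.6 * 0.4)


class TestSEM:
    def test_printed_value(self):
        assert round(cp_sem(30, 0.9), 2) == 0.18

    def test_balanced_value(self):
        assert cp_sem(30, 0.5) == pytest.approx(1.0 / np.sqrt(90))

    def test_inverse_square_root_scaling(self):
        assert cp_sem(120, 0.7) == pytest.approx(cp_sem(30, 0.7) / 2)

    def test_expected_minority_trials(self):
        n_pos, n_neg = expected_choice_counts(30, 0.9)
        assert n_neg == pytest.approx(3.0)
        assert n_pos == pytest.approx(27.0)


class TestPsychometric:
    def _simulate_observer(self, mu, sigma, levels, n, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        from scipy import stats as sps

        for tid, s in enumerate(np.repeat(levels, n)):
            p = sps.norm.cdf((s - mu) / sigma)
            rows.append(
                {
                    "cell_id": 0,
                    "trial_id": tid,
                    "coherence": s,
                    "choice": 1 if rng.random() < p else -1,
                    "count": 0,
                }
            )
        return pd.DataFrame(rows)

    def test_parameter_recovery(self):
        levels = np.array([-12.8, -6.4, -3.2, 0.0, 3.2, 6.4, 12.8])
        trials = self._simulate_observer(mu=1.0, sigma=5.0, levels=levels, n=200)
        fit = cp.fit_psychometric(trials)
        assert fit.bias == pytest.approx(1.0, abs=0.5)
        assert 1.0 / fit.slope == pytest.approx(5.0, rel=0.1)

    def test_unbiased_observer_is_balanced_at_zero(self):
        levels = np.array([-6.4, -3.2, 0.0, 3.2, 6.4])
        trials = self._simulate_observer(mu=0.0, sigma=4.0, levels=levels, n=300)
        fit = cp.fit_psychometric(trials)
        assert fit.predict(0.0) == pytest.approx(0.5, abs=0.03)

    def test_strictly_increasing_and_invertible(self):
        fit = cp.PsychometricFit(bias=0.5, slope=0.2)
        s = np.linspace(-10, 10, 41)
        p = fit.predict(s)
        assert np.all(np.diff(p) >= 0)
        mid = (p > 0.011) & (p < 0.989)  # away from the clipping range
        np.testing.assert_allclose(fit.inverse(p[mid]), s[mid], atol=1e-8)

    def test_degenerate_choices_rejected(self):
        trials = self._simulate_observer(mu=0.0, sigma=1.0,
                                         levels=np.array([-5.0, 0.0, 5.0]), n=5)
        trials["choice"] = 1
        with pytest.raises(ValueError):
            cp.fit_psychometric(trials)


def _cell_table(level_data):
    """Build a cell table from {coherence: (pos_counts, neg_counts)}."""
    rows, tid = [], 0
    for s, (pos, neg) in level_data.items():
        for c, vals in ((1, pos), (-1, neg)):
            for v in vals:
                rows.append(
                    {"cell_id": 0, "trial_id": tid, "coherence": s,
                     "choice": c, "count": v}
                )
                tid += 1
    return pd.DataFrame(rows)


class TestBuildProfile:
    def test_single_level_per_bin_passthrough(self, britten_psych):
        rng = np.random.default_rng(0)
        data = {
            s: (rng.poisson(22, 30), rng.poisson(20, 30))
            for s in (-6.4, -3.2, 0.0, 3.2, 6.4)
        }
        table = _cell_table(data)
        prof = build_cell_profile(table, britten_psych)
        assert prof.complete
        for s, b in [(-6.4, 0), (-3.2, 1), (0.0, 2), (3.2, 3), (6.4, 4)]:
            pos, neg = data[s]
            est = estimate_cp(pos, neg, p_cr=float(britten_psych.predict(s)))
            assert prof.cp_by_bin[b] == pytest.approx(est.cp)

    def test_weighted_average_matches_hand_computation(self):
        # two levels in the high bin: (K=60, p=0.75) and (K=30, p=0.9) give
        # unnormalized weights K*p*(1-p) of 11.25 and 2.7
        psych = SimpleNamespace(
            predict=np.vectorize(lambda s: {3.2: 0.75, 6.4: 0.9, 0.0: 0.5,
                                            -3.2: 0.4, -6.4: 0.2}[float(s)])
        )
        rng = np.random.default_rng(1)
        data = {
            3.2: (rng.poisson(25, 45), rng.poisson(20, 15)),
            6.4: (rng.poisson(25, 26), rng.poisson(20, 4)),
        }
        table = _cell_table(data)
        prof = build_cell_profile(table, psych)
        cp1 = rank_auc(*data[3.2])
        cp2 = rank_auc(*data[6.4])
        w1, w2 = 60 * 0.75 * 0.25, 30 * 0.9 * 0.1
        expected = (w1 * cp1 + w2 * cp2) / (w1 + w2)
        assert prof.cp_by_bin[4] == pytest.approx(expected)
        assert prof.sem_by_bin[4] == pytest.approx(1.0 / np.sqrt(12 * (w1 + w2)))

    def test_equal_weights_give_plain_mean(self):
        psych = SimpleNamespace(
            predict=np.vectorize(lambda s: {3.2: 0.75, 6.4: 0.75}[float(s)])
        )
        rng = np.random.default_rng(3)
        data = {
            3.2: (rng.poisson(25, 45), rng.poisson(20, 15)),
            6.4: (rng.poisson(25, 45), rng.poisson(20, 15)),
        }
        prof = build_cell_profile(_cell_table(data), psych, eps=0.01)
        plain = 0.5 * (rank_auc(*data[3.2]) + rank_auc(*data[6.4]))
        assert prof.cp_by_bin[4] == pytest.approx(plain)

    def test_bin_sem_never_exceeds_largest_level_sem(self, britten_psych):
        rng = np.random.default_rng(5)
        data = {s: (rng.poisson(22, 30), rng.poisson(20, 30))
                for s in (-6.4, -3.2, 0.0, 3.2, 6.4)}
        prof = build_cell_profile(_cell_table(data), britten_psych)
        max_level_sem = max(
            cp_sem(60, float(britten_psych.predict(s))) for s in data
        )
        assert np.nanmax(prof.sem_by_bin) <= max_level_sem + 1e-12

    def test_central_epsilon_keeps_informative_levels_out(self):
        pcr = np.array([0.2, 0.45, 0.5, 0.55, 0.8])
        coh = np.array([-6.4, -1.6, 0.0, 1.6, 6.4])
        eps = central_epsilon(pcr, coh)
        assert eps == pytest.approx(0.025)

    def test_incomplete_profile_flag(self, britten_psych):
        rng = np.random.default_rng(2)
        data = {s: (rng.poisson(22, 30), rng.poisson(20, 30)) for s in (0.0, 3.2, 6.4)}
        prof = build_cell_profile(_cell_table(data), britten_psych)
        assert not prof.complete


class TestAverageProfiles:
    def _profiles(self, cps, weight=10.0):
        return [
            cp.CPProfile(
                cell_id=i,
                cp_by_bin=np.asarray(v, dtype=float),
                sem_by_bin=np.full(5, 0.05),
                weight_by_bin=np.full(5, weight),
                pcr_by_bin=np.array([0.2, 0.4, 0.5, 0.6, 0.8]),
            )
            for i, v in enumerate(cps)
        ]

    def test_identical_profiles_average_to_themselves(self):
        profs = self._profiles([[0.6, 0.55, 0.52, 0.55, 0.6]] * 4)
        avg = cp.average_profiles(profs, "above")
        np.testing.assert_allclose(avg.cp_by_bin, profs[0].cp_by_bin)

    def test_mean_cp_exactly_half_goes_to_above_group(self):
        profs = self._profiles([[0.5] * 5])
        assert profs[0].group == "above"
        avg = cp.average_profiles(profs, "above")
        np.testing.assert_allclose(avg.cp_by_bin, 0.5)

    def test_empty_group_raises(self):
        profs = self._profiles([[0.6] * 5])
        with pytest.raises(ValueError):
            cp.average_profiles(profs, "below")

    def test_threshold_model_bins_match_exact_cp(self):
        # simulated bivariate-Gaussian cells with known (rho, p_cr):
        # averaged bin CPs within 3 pooled SEM of the exact solution
        pcr_map = {-6.4: 0.2, -3.2: 0.35, 0.0: 0.5, 3.2: 0.65, 6.4: 0.8}
        psych = SimpleNamespace(predict=np.vectorize(lambda s: pcr_map[float(s)]))
        rho = 0.2
        profs = [
            build_cell_profile(
                simulate_threshold_trials(rho, pcr_map, 60, seed=100 + i, cell_id=i),
                psych,
            )
            for i in range(40)
        ]
        avg = cp.average_profiles([p for p in profs if p.complete], "above")
        exact = np.array(
            [cp_exact(ThresholdModelParams(rho, p)) for p in avg.pcr_by_bin]
        )
        assert np.all(np.abs(avg.cp_by_bin - exact) < 3 * avg.sem_by_bin)
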