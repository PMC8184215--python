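"""Shared fixtures: small synthetic sessions and psychometric maps."""

from types import SimpleNamespace

import numpy as np
import pandas as pd
import pytest

# level -> choice rate, emulating a coarse-discrimination session design
BRITTEN_PCR = {-6.4: 0.2, -3.2: 0.35, -1.6: 0.45, 0.0: 0.5, 1.6: 0.55, 3.2: 0.65, 6.4: 0.8}
BRITTEN_K = {-6.4: 60, -3.2: 40, -1.6: 40, 0.0: 60, 1.6: 40, 3.2: 65, 6.4: 60}


@pytest.fixture
def britten_psych():
    """Callable/predict wrapper exposing the fixed pCR map above."""
    table = dict(BRITTEN_PCR)
    return SimpleNamespace(predict=np.vectorize(lambda s: table[float(s)]))


def make_constant_cp_cell(rng, delta=2.0, base=20.0, cell_id=0):
    """A cell whose CP is constant across levels (flat-CP null).

    Counts are Poisson with a fixed choice-dependent mean shift, identical at
    every level; choices are Bernoulli at the level's choice rate.
    """
    rows, tid = [], 0
    for s, p in BRITTEN_PCR.items():
        k = BRITTEN_K[s]
        n_pos = rng.binomial(k, p)
        choice = np.array([1] * n_pos + [-1] * (k - n_pos))
        counts = rng.poisson(base + delta * (choice == 1))
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "trial_id": np.arange(tid, tid + k),
                    "coherence": s,
                    "choice": choice,
                    "count": counts,
                }
            )
        )
        tid += k
    return pd.concat(rows, ignore_index=True)


def make_glm_cell(rng, mode, base_rate=15.0, tuning=0.03, b=0.25, cell_id=0):
    """A cell generated from the choice GLM itself.

    ``mode``: "flip" gives a choice effect whose sign follows the stimulus
    (positive for high choice rates, negative for low), "const" a single
    stimulus-independent choice gain, "none" no choice effect.
    """
    pcr = {-12.8: 0.1, -6.4: 0.25, -3.2: 0.4, 0.0: 0.5, 3.2: 0.6, 6.4: 0.75, 12.8: 0.9}
    rows, tid = [], 0
    for s, p in pcr.items():
        k = 60 if s == 0.0 else (40 if abs(s) < 10 else 30)
        choice = np.where(rng.random(k) < p, 1, -1)
        if mode == "flip":
            bj = b if p > 0.55 else (-b if p < 0.45 else 0.0)
        elif mode == "const":
            bj = 0.6 * b
        else:
            bj = 0.0
        mu = np.exp(np.log(base_rate) + tuning * s + bj * choice)
        rows.append(
            pd.DataFrame(
                {
                    "cell_id": cell_id,
                    "trial_id": np.arange(tid, tid + k),
                    "coherence": s,
                    "choice": choice,
                    "count": rng.poisson(mu),
                }
            )
        )
        tid += k
    table = pd.concat(rows, ignore_index=True)
    psych = SimpleNamespace(predict=np.vectorize(lambda s: pcr[float(s)]))
    return table, psych
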