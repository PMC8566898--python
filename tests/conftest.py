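"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities with the most naive
possible code (dict-based step-by-step model evaluation, raw
sums-of-squares ANOVA) so they share no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

import stressrl as s
from stressrl.cohort import EffectSpec, cohort_bold, generate_cohort


# ---------------------------------------------------------------- oracles
def stepwise_model_eval(trials: pd.DataFrame, alpha_pos, alpha_neg, beta):
    """Naive step-by-step evaluation of the learning model.

    Returns (nll, trace rows as list of (q_chosen, delta)) over
    non-missing gain/loss trials in presentation order. Written
    independently of the package's vectorized/numba path.
    """
    q: dict[str, list[float]] = {}
    nll = 0.0
    rows = []
    for row in trials.itertuples(index=False):
        if row.valence not in ("gain", "loss") or row.choice == "missing":
            continue
        vals = q.setdefault(row.pair_id, [0.0, 0.0])
        ci = 0 if row.choice == "correct" else 1
        chosen, other = vals[ci], vals[1 - ci]
        p = 1.0 / (1.0 + math.exp(-beta * (chosen - other)))
        nll -= math.log(p)
        d = row.outcome_r - chosen
        rows.append((chosen, d))
        if d > 0:
            vals[ci] = chosen + alpha_pos * d
        elif d < 0:
            vals[ci] = chosen + alpha_neg * d
    return nll, rows


def rm_anova_oracle(df: pd.DataFrame, dv, within_a, within_b, subject):
    """Two-way fully-within ANOVA by direct sums-of-squares decomposition."""
    y = df.pivot_table(index=subject, columns=[within_a, within_b], values=dv)
    a_levels = sorted({a for a, _ in y.columns})
    b_levels = sorted({b for _, b in y.columns})
    n = len(y)
    grand = y.to_numpy().mean()
    mean_a = {a: y[[c for c in y.columns if c[0] == a]].to_numpy().mean() for a in a_levels}
    mean_b = {b: y[[c for c in y.columns if c[1] == b]].to_numpy().mean() for b in b_levels}
    mean_ab = {c: y[c].mean() for c in y.columns}
    mean_s = y.mean(axis=1)
    mean_as = {(a, sub): np.mean([y.loc[sub, (a, b)] for b in b_levels])
               for a in a_levels for sub in y.index}
    mean_bs = {(b, sub): np.mean([y.loc[sub, (a, b)] for a in a_levels])
               for b in b_levels for sub in y.index}
    ss_a = n * len(b_levels) * sum((mean_a[a] - grand) ** 2 for a in a_levels)
    ss_b = n * len(a_levels) * sum((mean_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = n * sum(
        (mean_ab[(a, b)] - mean_a[a] - mean_b[b] + grand) ** 2
        for a in a_levels
        for b in b_levels
    )
    ss_as = len(b_levels) * sum(
        (mean_as[(a, sub)] - mean_a[a] - mean_s[sub] + grand) ** 2
        for a in a_levels
        for sub in y.index
    )
    ss_bs = len(a_levels) * sum(
        (mean_bs[(b, sub)] - mean_b[b] - mean_s[sub] + grand) ** 2
        for b in b_levels
        for sub in y.index
    )
    ss_abs = sum(
        (
            y.loc[sub, (a, b)]
            - mean_ab[(a, b)]
            - mean_as[(a, sub)]
            - mean_bs[(b, sub)]
            + mean_a[a]
            + mean_b[b]
            + mean_s[sub]
            - grand
        )
        ** 2
        for a in a_levels
        for b in b_levels
        for sub in y.index
    )
    from scipy.stats import f as fdist

    out = {}
    for name, ss_eff, ss_err in (
        ("a", ss_a, ss_as),
        ("b", ss_b, ss_bs),
        ("ab", ss_ab, ss_abs),
    ):
        df1, df2 = 1, n - 1
        if ss_err == 0:
            F = np.inf if ss_eff > 0 else 0.0
        else:
            F = (ss_eff / df1) / (ss_err / df2)
        out[name] = {
            "F": F,
            "p": float(fdist.sf(F, df1, df2)) if np.isfinite(F) else 0.0,
            "pes": ss_eff / (ss_eff + ss_err) if (ss_eff + ss_err) > 0 else 0.0,
        }
    return out


def toy_trials(rows):
    """Build a minimal choice-annotated trial table from tuples of
    (pair_id, valence, choice, outcome_r)."""
    recs = []
    for i, (pair, val, choice, r) in enumerate(rows):
        recs.append(
            {
                "run": 1,
                "block_pos": 1,
                "condition": "control",
                "block": 1,
                "valence": val,
                "pair_id": pair,
                "presentation": i + 1,
                "side_of_correct": "left",
                "stim_onset": 6.0 * i,
                "outcome_onset": 6.0 * i + 4.0,
                "chosen_side": "left" if choice == "correct" else "right",
                "choice": choice,
                "outcome_r": np.nan if choice == "missing" else r,
            }
        )
    return pd.DataFrame(recs)


# ---------------------------------------------------------------- fixtures
@pytest.fixture(scope="session")
def default_schedule():
    sched = s.build_schedule(0, seed=7)
    return sched


@pytest.fixture(scope="session")
def sim_session(default_schedule):
    """One simulated session with distinct stress/control parameters."""
    params = {
        "stress": s.RLParams(0.2, 0.3, 3.0),
        "control": s.RLParams(0.4, 0.3, 3.0),
    }
    trials, trace = s.simulate_agent(
        default_schedule, params, np.random.default_rng(11)
    )
    return trials, trace, params


@pytest.fixture(scope="session")
def small_cohort():
    """Default-effect cohort of 10 participants, with ROI BOLD."""
    spec = EffectSpec(n_participants=10, seed=5)
    coh = generate_cohort(spec)
    bold = cohort_bold(coh)
    return coh, bold
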