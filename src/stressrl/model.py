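"""Dual-learning-rate Q-learning with softmax choice.

The model tracks, for each stimulus pair, the value Q of both stimuli
(initialized at 0 when the pair is introduced). On every non-missing
monetary trial the value of the chosen stimulus is updated by

    Q_chosen(t+1) = Q_chosen(t) + alpha * delta(t),
    delta(t)      = r(t) - Q_chosen(t),

where the reinforcement r(t) is +0.5, 0 or -0.5 EUR and the learning rate
alpha equals ``alpha_pos`` for positive prediction errors and ``alpha_neg``
for negative ones (a zero prediction error triggers no update). Choices
follow a two-option logistic softmax with inverse temperature beta:
P(left) = sigma(beta * (Q_left - Q_right)).

Neutral trials carry no monetary reinforcement; they contribute neither
value updates nor likelihood terms and never appear in the latent trace.
The latent per-trial quantities (Q_chosen at choice time and delta at
outcome time) are what the ROI GLM uses as parametric modulators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import expit

from .task import SessionSchedule, sample_outcome

#: columns of a latent trace, one row per non-missing monetary trial
TRACE_COLUMNS = [
    "trial_index",
    "run",
    "block_pos",
    "condition",
    "block",
    "valence",
    "pair_id",
    "stim_onset",
    "outcome_onset",
    "q_chosen",
    "delta",
]


@dataclass(frozen=True)
class RLParams:
    """Model parameters: learning rates for positive/negative prediction
    errors (both in [0, 1]) and the softmax inverse temperature (>= 0)."""

    alpha_pos: float
    alpha_neg: float
    beta: float

    def __post_init__(self) -> None:
        for name in ("alpha_pos", "alpha_neg", "beta"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite")
        if not 0.0 <= self.alpha_pos <= 1.0:
            raise ValueError("alpha_pos must lie in [0, 1]")
        if not 0.0 <= self.alpha_neg <= 1.0:
            raise ValueError("alpha_neg must lie in [0, 1]")
        if self.beta < 0.0:
            raise ValueError("beta must be non-negative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.alpha_pos, self.alpha_neg, self.beta)


def prediction_error(r: float, q_chosen: float) -> float:
    """delta(t) = r(t) - Q_chosen(t)."""
    return r - q_chosen


def update_value(q: float, delta: float, params: RLParams) -> float:
    """One step of the asymmetric value update for the chosen stimulus."""
    if delta > 0:
        return q + params.alpha_pos * delta
    if delta < 0:
        return q + params.alpha_neg * delta
    return q


def choice_probability(q_left: float, q_right: float, beta: float) -> float:
    """P(choose left) under the two-option logistic softmax."""
    if beta < 0:
        raise ValueError("beta must be non-negative")
    return float(expit(beta * (q_left - q_right)))


@njit(cache=True)
def _nll_core(pair_idx, chose_correct, r, n_pairs, a_pos, a_neg, beta):
    """Sequential NLL of observed choices on monetary trials.

    Q state is (n_pairs, 2): column 0 the correct stimulus of the pair,
    column 1 the incorrect one. Returns -sum log P(observed choice).
    """
    q = np.zeros((n_pairs, 2))
    nll = 0.0
    for t in range(pair_idx.shape[0]):
        p = pair_idx[t]
        if chose_correct[t] == 1:
            ch = 0
        else:
            ch = 1
        x = beta * (q[p, ch] - q[p, 1 - ch])
        # -log sigma(x), overflow-safe
        if x < -30.0:
            nll += -x
        else:
            nll += np.log1p(np.exp(-x))
        q_ch = q[p, ch]
        delta = r[t] - q_ch
        if delta > 0.0:
            q[p, ch] = q_ch + a_pos * delta
        elif delta < 0.0:
            q[p, ch] = q_ch + a_neg * delta
    return nll


@njit(cache=True)
def _trace_core(pair_idx, chose_correct, r, n_pairs, a_pos, a_neg):
    """Replay the learning rule; returns (q_chosen, delta) per trial."""
    q = np.zeros((n_pairs, 2))
    n = pair_idx.shape[0]
    q_chosen = np.empty(n)
    delta = np.empty(n)
    for t in range(n):
        p = pair_idx[t]
        ch = 0 if chose_correct[t] == 1 else 1
        q_ch = q[p, ch]
        d = r[t] - q_ch
        q_chosen[t] = q_ch
        delta[t] = d
        if d > 0.0:
            q[p, ch] = q_ch + a_pos * d
        elif d < 0.0:
            q[p, ch] = q_ch + a_neg * d
    return q_chosen, delta


def financial_trials(trials: pd.DataFrame) -> pd.DataFrame:
    """Non-missing gain/loss trials of a choice-annotated trial table."""
    mask = trials["valence"].isin(("gain", "loss")) & (
        trials["choice"] != "missing"
    )
    return trials.loc[mask]


def encode_trials(trials: pd.DataFrame):
    """Encode monetary trials as arrays for the sequential kernels.

    Returns (pair_idx, chose_correct, r, n_pairs) over non-missing
    gain/loss trials in presentation order.
    """
    fin = financial_trials(trials)
    if fin["outcome_r"].isna().any():
        raise ValueError("non-missing monetary trial without an outcome")
    missing = trials["choice"] == "missing"
    if missing.any() and trials.loc[missing, "outcome_r"].notna().any():
        raise ValueError("outcome recorded on a missing trial")
    pair_idx, _ = pd.factorize(fin["pair_id"])
    chose_correct = (fin["choice"] == "correct").to_numpy(np.int8)
    r = fin["outcome_r"].to_numpy(np.float64)
    return (
        pair_idx.astype(np.int64),
        chose_correct,
        r,
        int(pair_idx.max()) + 1 if len(fin) else 0,
    )


def negative_log_likelihood(trials: pd.DataFrame, params: RLParams) -> float:
    """NLL of the observed choices on non-missing monetary trials."""
    pair_idx, chose_correct, r, n_pairs = encode_trials(trials)
    if len(pair_idx) == 0:
        return 0.0
    return float(
        _nll_core(
            pair_idx,
            chose_correct,
            r,
            n_pairs,
            params.alpha_pos,
            params.alpha_neg,
            params.beta,
        )
    )


def trace_from_choices(
    trials: pd.DataFrame, params_by_condition: dict[str, RLParams] | RLParams
) -> pd.DataFrame:
    """Deterministically replay the learning rule over observed choices.

    Values and prediction errors are computed per condition with that
    condition's parameters (a single ``RLParams`` applies to both).
    Missing and neutral trials produce no update and no trace row.
    """
    if isinstance(params_by_condition, RLParams):
        params_by_condition = {
            c: params_by_condition for c in trials["condition"].unique()
        }
    out = []
    for cond, ct in trials.groupby("condition", sort=False):
        params = params_by_condition[cond]
        pair_idx, chose_correct, r, n_pairs = encode_trials(ct)
        fin = financial_trials(ct)
        if len(fin) == 0:
            continue
        q_chosen, delta = _trace_core(
            pair_idx, chose_correct, r, n_pairs,
            params.alpha_pos, params.alpha_neg,
        )
        tr = fin[
            [
                "run",
                "block_pos",
                "condition",
                "block",
                "valence",
                "pair_id",
                "stim_onset",
                "outcome_onset",
            ]
        ].copy()
        tr.insert(0, "trial_index", fin.index)
        tr["q_chosen"] = q_chosen
        tr["delta"] = delta
        out.append(tr)
    if not out:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    trace = pd.concat(out).sort_values("trial_index").reset_index(drop=True)
    return trace[TRACE_COLUMNS]


def simulate_agent(
    schedule: SessionSchedule,
    params_by_condition: dict[str, RLParams] | RLParams,
    rng: np.random.Generator,
    miss_rate: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate choices and outcomes for one session.

    Returns ``(trials, trace)``: the trial table annotated with
    ``chosen_side``/``choice``/``outcome_r``, and the latent trace of the
    generating parameters. Each condition uses its own parameter set and
    its own Q state (pairs are condition-specific by construction).
    Misses occur independently with probability ``miss_rate``.
    """
    if isinstance(params_by_condition, RLParams):
        params_by_condition = {c: params_by_condition for c in ("stress", "control")}
    cfg = schedule.config
    trials = schedule.trials.copy()
    q_state: dict[str, np.ndarray] = {}
    chosen_side = np.empty(len(trials), dtype=object)
    choice = np.empty(len(trials), dtype=object)
    outcome = np.full(len(trials), np.nan)
    trace_rows = []
    for i, row in enumerate(trials.itertuples(index=False)):
        if miss_rate > 0 and rng.random() < miss_rate:
            chosen_side[i] = None
            choice[i] = "missing"
            continue
        params = params_by_condition[row.condition]
        q = q_state.setdefault(row.pair_id, np.zeros(2))
        q_correct, q_incorrect = q
        if row.side_of_correct == "left":
            q_left, q_right = q_correct, q_incorrect
        else:
            q_left, q_right = q_incorrect, q_correct
        p_left = choice_probability(q_left, q_right, params.beta)
        side = "left" if rng.random() < p_left else "right"
        chosen_side[i] = side
        is_correct = side == row.side_of_correct
        choice[i] = "correct" if is_correct else "incorrect"
        r = sample_outcome(
            row.valence, choice[i], rng, cfg.p_good, cfg.magnitude
        )
        outcome[i] = r
        if row.valence in ("gain", "loss"):
            ch = 0 if is_correct else 1
            delta = prediction_error(r, q[ch])
            trace_rows.append(
                {
                    "trial_index": i,
                    "run": row.run,
                    "block_pos": row.block_pos,
                    "condition": row.condition,
                    "block": row.block,
                    "valence": row.valence,
                    "pair_id": row.pair_id,
                    "stim_onset": row.stim_onset,
                    "outcome_onset": row.outcome_onset,
                    "q_chosen": q[ch],
                    "delta": delta,
                }
            )
            q[ch] = update_value(q[ch], delta, params)
    trials["chosen_side"] = chosen_side
    trials["choice"] = choice
    trials["outcome_r"] = outcome
    trace = pd.DataFrame(trace_rows, columns=TRACE_COLUMNS)
    return trials, trace
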