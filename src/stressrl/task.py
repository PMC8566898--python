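"""Generative structure of the probabilistic gain/loss selection task.

The task is a two-alternative forced-choice instrumental learning task run
under alternating stress and control blocks. Each block presents three fresh
pairs of abstract stimuli -- one pair per valence (gain, loss, neutral) --
24 times each, for 72 trials per block. Within a pair the two stimuli carry
reciprocal outcome probabilities (by default 0.75 / 0.25) of delivering the
better outcome: winning 0.5 EUR on gain trials, avoiding a 0.5 EUR loss on
loss trials, and a non-monetary outcome on neutral trials. A session holds
two runs, each containing one stress and one control block, with the
condition order counterbalanced across runs.

This module builds randomized but structurally audited trial schedules
(with stimulus/outcome onsets on a continuous within-run clock) and samples
trial outcomes from the task contingencies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

VALENCES = ("gain", "loss", "neutral")
CONDITIONS = ("stress", "control")
SIDES = ("left", "right")

#: columns of the canonical trial table, one row per trial
TRIAL_COLUMNS = [
    "run",
    "block_pos",
    "condition",
    "block",
    "valence",
    "pair_id",
    "presentation",
    "side_of_correct",
    "stim_onset",
    "outcome_onset",
]


@dataclass(frozen=True)
class TimingConfig:
    """Event timing for one trial: stimulus, outcome, inter-trial gap.

    ``iti`` is the interval between an outcome onset and the next stimulus
    onset; it is fixed when ``iti_min == iti_max`` and uniformly jittered
    otherwise. ``block_gap`` separates the two blocks of a run (the
    self-report rating period); the clock restarts at 0 for each run.
    """

    stim_outcome_delay: float = 4.0
    iti_min: float = 2.0
    iti_max: float = 6.0
    block_gap: float = 16.0

    def __post_init__(self) -> None:
        if self.stim_outcome_delay <= 0:
            raise ValueError("stimulus-to-outcome delay must be positive")
        if self.iti_min <= 0 or self.iti_max < self.iti_min:
            raise ValueError("ITI bounds must satisfy 0 < iti_min <= iti_max")
        if self.block_gap < 0:
            raise ValueError("block gap must be non-negative")


@dataclass(frozen=True)
class TaskConfig:
    """Structural parameters of the task.

    Defaults reproduce the published design: 3 pairs per block (one per
    valence), 24 presentations each, reciprocal 0.75/0.25 contingencies,
    0.5 EUR stakes, 2 runs x 2 alternating stress/control blocks.
    """

    valences: tuple[str, ...] = VALENCES
    presentations_per_pair: int = 24
    p_good: float = 0.75
    magnitude: float = 0.5
    n_runs: int = 2
    blocks_per_run: int = 2
    timing: TimingConfig = field(default_factory=TimingConfig)

    def __post_init__(self) -> None:
        if not 0.5 < self.p_good <= 1.0:
            raise ValueError("p_good must lie in (0.5, 1]")
        if self.magnitude <= 0:
            raise ValueError("magnitude must be positive")
        if self.presentations_per_pair % 2 != 0:
            raise ValueError(
                "presentations_per_pair must be even so that left/right "
                "placement of the correct stimulus can be balanced"
            )
        unknown = set(self.valences) - set(VALENCES)
        if unknown:
            raise ValueError(f"unknown valences: {sorted(unknown)}")

    @property
    def trials_per_block(self) -> int:
        return len(self.valences) * self.presentations_per_pair

    @property
    def n_blocks(self) -> int:
        return self.n_runs * self.blocks_per_run

    @property
    def trials_per_session(self) -> int:
        return self.n_blocks * self.trials_per_block


@dataclass
class SessionSchedule:
    """One participant's trial-by-trial session structure.

    ``trials`` is a DataFrame with one row per trial (``TRIAL_COLUMNS``),
    ordered by run and onset. After simulation or data loading it also
    carries ``chosen_side``, ``choice`` and ``outcome_r`` columns.
    """

    participant_id: int
    trials: pd.DataFrame
    config: TaskConfig
    counterbalance_order: tuple[str, ...]

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def audit(self) -> None:
        """Raise AssertionError if any structural invariant is violated."""
        cfg = self.config
        t = self.trials
        assert len(t) == cfg.trials_per_session, "wrong session length"
        n_blocks = t.groupby(["run", "block_pos"]).ngroups
        assert n_blocks == cfg.n_blocks, "wrong number of blocks"
        for (_run, _pos), blk in t.groupby(["run", "block_pos"]):
            assert len(blk) == cfg.trials_per_block, "wrong block length"
            assert blk["condition"].nunique() == 1, "mixed conditions in block"
            assert tuple(sorted(blk["valence"].unique())) == tuple(
                sorted(cfg.valences)
            ), "valence set wrong within block"
            for _pid, grp in blk.groupby("pair_id"):
                assert len(grp) == cfg.presentations_per_pair
                sides = grp["side_of_correct"].value_counts()
                assert sides.get("left", 0) == sides.get("right", 0), (
                    "side of correct stimulus not balanced"
                )
        # new pair ids per block
        pair_blocks = t.groupby("pair_id")[["run", "block_pos"]].nunique()
        assert (pair_blocks == 1).all().all(), "pair ids reused across blocks"
        # conditions alternate within a run
        for _run, rt in t.groupby("run"):
            conds = rt.drop_duplicates("block_pos")["condition"].tolist()
            assert len(set(conds)) == len(conds), "conditions repeat in a run"
        # onsets strictly increasing within run, outcome after stimulus
        for _run, rt in t.groupby("run"):
            on = rt["stim_onset"].to_numpy()
            assert (np.diff(on) > 0).all(), "non-increasing onsets"
        assert (t["outcome_onset"] > t["stim_onset"]).all()


def build_schedule(
    participant_id: int,
    config: TaskConfig | None = None,
    seed: int = 0,
    first_condition: str | None = None,
) -> SessionSchedule:
    """Construct a randomized session schedule for one participant.

    The order of pair presentations within a block is a uniform random
    permutation subject to the presentations-per-pair constraint; the side
    on which the correct stimulus appears is balanced within each pair.
    Identical ``seed`` (and configuration) yields an identical schedule.

    ``first_condition`` sets the condition of the first block of run 1;
    by default even participant ids start with stress, odd with control.
    Run 2 starts with the other condition.
    """
    config = config or TaskConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if first_condition is None:
        first_condition = "stress" if participant_id % 2 == 0 else "control"
    if first_condition not in CONDITIONS:
        raise ValueError(f"unknown condition {first_condition!r}")
    other = "control" if first_condition == "stress" else "stress"

    counterbalance = []
    rows: list[dict] = []
    cond_block_count = {c: 0 for c in CONDITIONS}
    for run in range(1, config.n_runs + 1):
        run_first = first_condition if run % 2 == 1 else other
        run_other = other if run_first == first_condition else first_condition
        counterbalance.append(run_first)
        clock = 0.0
        for pos in range(1, config.blocks_per_run + 1):
            condition = run_first if pos % 2 == 1 else run_other
            cond_block_count[condition] += 1
            block = cond_block_count[condition]
            n_pres = config.presentations_per_pair
            valences = list(config.valences)
            # presentation order: each pair appears exactly n_pres times
            order = rng.permutation(np.repeat(np.arange(len(valences)), n_pres))
            # balanced sides per pair, consumed in presentation order
            sides = {
                v: rng.permutation(
                    np.array(["left", "right"]).repeat(n_pres // 2)
                )
                for v in valences
            }
            counters = {v: 0 for v in valences}
            for k in order:
                valence = valences[k]
                i = counters[valence]
                counters[valence] += 1
                stim_onset = clock
                outcome_onset = stim_onset + config.timing.stim_outcome_delay
                if config.timing.iti_max > config.timing.iti_min:
                    iti = rng.uniform(config.timing.iti_min, config.timing.iti_max)
                else:
                    iti = config.timing.iti_min
                clock = outcome_onset + iti
                rows.append(
                    {
                        "run": run,
                        "block_pos": pos,
                        "condition": condition,
                        "block": block,
                        "valence": valence,
                        "pair_id": f"run{run}-block{pos}-{valence}",
                        "presentation": i + 1,
                        "side_of_correct": sides[valence][i],
                        "stim_onset": stim_onset,
                        "outcome_onset": outcome_onset,
                    }
                )
            clock += config.timing.block_gap
    trials = pd.DataFrame(rows, columns=TRIAL_COLUMNS)
    return SessionSchedule(
        participant_id=participant_id,
        trials=trials,
        config=config,
        counterbalance_order=tuple(counterbalance),
    )


def assign_onsets(
    schedule: SessionSchedule, timing: TimingConfig, seed: int = 0
) -> SessionSchedule:
    """Return a copy of ``schedule`` with onsets rebuilt under ``timing``.

    The clock restarts at 0 at the start of each run and advances by
    ``stim_outcome_delay`` + ITI per trial, plus ``block_gap`` between
    blocks. Jittered ITIs are drawn from the given seeded stream.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    trials = schedule.trials.copy()
    stim = np.empty(len(trials))
    out = np.empty(len(trials))
    pos_index = trials.groupby("run", sort=True).cumcount()  # noqa: F841
    for run, rt in trials.groupby("run", sort=True):
        clock = 0.0
        last_pos = None
        for idx in rt.index:
            pos = trials.at[idx, "block_pos"]
            if last_pos is not None and pos != last_pos:
                clock += timing.block_gap
            last_pos = pos
            stim[trials.index.get_loc(idx)] = clock
            out[trials.index.get_loc(idx)] = clock + timing.stim_outcome_delay
            if timing.iti_max > timing.iti_min:
                iti = rng.uniform(timing.iti_min, timing.iti_max)
            else:
                iti = timing.iti_min
            clock = clock + timing.stim_outcome_delay + iti
    trials["stim_onset"] = stim
    trials["outcome_onset"] = out
    cfg = replace(schedule.config, timing=timing)
    return SessionSchedule(
        participant_id=schedule.participant_id,
        trials=trials,
        config=cfg,
        counterbalance_order=schedule.counterbalance_order,
    )


def sample_outcome(
    valence: str,
    choice: str,
    rng: np.random.Generator,
    p_good: float = 0.75,
    magnitude: float = 0.5,
) -> float:
    """Sample the monetary outcome of one trial.

    Gain pairs pay +``magnitude`` with probability ``p_good`` after a
    correct choice (1 - ``p_good`` after an incorrect one), else nothing;
    loss pairs charge -``magnitude`` with probability ``p_good`` after an
    incorrect choice, else nothing. Neutral trials always return 0 under
    the monetary coding.
    """
    if choice == "missing":
        raise ValueError("missing choices have no outcome")
    if choice not in ("correct", "incorrect"):
        raise ValueError(f"unknown choice {choice!r}")
    if valence == "neutral":
        return 0.0
    if valence == "gain":
        p_win = p_good if choice == "correct" else 1.0 - p_good
        return magnitude if rng.random() < p_win else 0.0
    if valence == "loss":
        p_lose = p_good if choice == "incorrect" else 1.0 - p_good
        return -magnitude if rng.random() < p_lose else 0.0
    raise ValueError(f"unknown valence {valence!r}")
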