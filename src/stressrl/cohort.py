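"""Synthetic cohort generator: behaviour, self-reports and ROI BOLD.

Every dataset the analysis consumes can be generated here with known
ground truth, so each pipeline stage is testable end to end. Choices are
produced by the dual-learning-rate model playing the actual task
schedules; self-reports are built with a configurable fraction of stress
responders; ROI BOLD series are built from each participant's true
latent trace -- stimulus/outcome responses plus Q-value and
prediction-error modulations convolved with the canonical HRF -- with a
slow drift and AR(1) noise. Stress blunts the prediction-error
modulation by a configurable multiplicative factor, optionally restricted
to gain trials or to positive prediction errors, and optionally coupled
to the participant's self-reported stress responsivity.

Default effect sizes emulate the study conditions this pipeline is meant
to analyse: 37 participants of whom 23 respond to the stressor, a lower
positive-error learning rate under stress (0.20 vs 0.40), and stress
shrinking the prediction-error BOLD slope to 0.3 of its control value.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .glm import canonical_hrf
from .model import RLParams, simulate_agent
from .task import SessionSchedule, TaskConfig, build_schedule

TR_DEFAULT = 2.0


@dataclass(frozen=True)
class EffectSpec:
    """Ground-truth effect structure of a synthetic cohort."""

    n_participants: int = 37
    responder_fraction: float = 23 / 37
    # learning-model parameter distributions (truncated normal draws)
    alpha_pos_control: float = 0.40
    alpha_pos_stress: float = 0.20
    alpha_neg_mean: float = 0.30
    alpha_sd: float = 0.10
    beta_mean: float = 3.0
    beta_sd: float = 1.0
    # self-reports (1-9 scale)
    # responders: stress = control + 1..4 points; non-responders: <= control
    # BOLD ground truth
    pe_slope_gain: float = 1.0
    pe_slope_loss: float = 1.0
    q_slope: float = 0.5
    stick_amp: float = 1.0
    blunting: float = 0.3
    blunt_gain_only: bool = False
    blunt_positive_only: bool = False
    slope_sd: float = 0.3
    ar1_rho: float = 0.3
    noise_sd: float = 1.0
    drift_amp: float = 1.0
    stress_coupling: float = 0.0
    miss_rate: float = 13 / 6624
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if not 0.0 <= self.blunting <= 1.0:
            raise ValueError("blunting factor must lie in [0, 1]")
        if self.noise_sd < 0 or self.slope_sd < 0:
            raise ValueError("standard deviations must be non-negative")
        if not -1.0 < self.ar1_rho < 1.0:
            raise ValueError("AR(1) rho must lie in (-1, 1)")
        if not 0.0 <= self.miss_rate < 1.0:
            raise ValueError("miss_rate must lie in [0, 1)")
        if self.n_participants < 0:
            raise ValueError("n_participants must be non-negative")


@dataclass
class Participant:
    participant_id: int
    schedule: SessionSchedule
    trials: pd.DataFrame
    trace: pd.DataFrame
    true_params: dict[str, RLParams]
    responder: bool
    ratings: pd.DataFrame
    true_slopes: dict  # (condition, valence) -> {"pos": slope, "neg": slope}
    blunting_applied: float


@dataclass
class Cohort:
    spec: EffectSpec
    config: TaskConfig
    participants: list[Participant]

    @property
    def reports(self) -> pd.DataFrame:
        return pd.concat(
            [p.ratings for p in self.participants], ignore_index=True
        )

    @property
    def trials(self) -> pd.DataFrame:
        frames = []
        for p in self.participants:
            t = p.trials.copy()
            t.insert(0, "participant", p.participant_id)
            frames.append(t)
        return pd.concat(frames, ignore_index=True)


def _truncnorm(rng, mean, sd, lo, hi):
    return float(np.clip(rng.normal(mean, sd), lo, hi))


def _draw_params(spec: EffectSpec, rng) -> dict[str, RLParams]:
    out = {}
    for cond in ("stress", "control"):
        ap_mean = (
            spec.alpha_pos_stress if cond == "stress" else spec.alpha_pos_control
        )
        out[cond] = RLParams(
            alpha_pos=_truncnorm(rng, ap_mean, spec.alpha_sd, 0.01, 0.99),
            alpha_neg=_truncnorm(
                rng, spec.alpha_neg_mean, spec.alpha_sd, 0.01, 0.99
            ),
            beta=_truncnorm(rng, spec.beta_mean, spec.beta_sd, 0.5, 10.0),
        )
    return out


def _draw_ratings(pid: int, responder: bool, rng) -> pd.DataFrame:
    """Integer 1-9 ratings per condition x block.

    Responders are constructed with stress ratings 1-4 points above their
    control rating of the same block (so Delta >= 1 by construction);
    non-responders with stress ratings at or below control (Delta <= 0).
    """
    rows = []
    for block in (1, 2):
        if responder:
            control = int(np.clip(round(rng.normal(3.0, 1.0)), 1, 5))
            stress = int(np.clip(control + rng.integers(1, 5), 1, 9))
        else:
            control = int(np.clip(round(rng.normal(4.0, 1.0)), 1, 9))
            stress = int(np.clip(control - rng.integers(0, 3), 1, 9))
        rows.append(
            {
                "participant": pid,
                "condition": "control",
                "block": block,
                "rating": control,
            }
        )
        rows.append(
            {
                "participant": pid,
                "condition": "stress",
                "block": block,
                "rating": stress,
            }
        )
    return pd.DataFrame(rows)


def _true_slopes(
    spec: EffectSpec, blunt: float, rng
) -> dict:
    """Per-cell ground-truth modulation slopes.

    The unblunted slope is a subject-level trait drawn once per valence
    and shared across conditions; stress multiplies it by the blunting
    factor (optionally only on gain trials, or only for positive errors).
    """
    slopes = {}
    for val in ("gain", "loss"):
        base = spec.pe_slope_gain if val == "gain" else spec.pe_slope_loss
        base = base + rng.normal(0.0, spec.slope_sd)
        for cond in ("stress", "control"):
            m = 1.0
            if cond == "stress" and not (spec.blunt_gain_only and val == "loss"):
                m = blunt
            if spec.blunt_positive_only:
                slopes[(cond, val)] = {"pos": base * m, "neg": base}
            else:
                slopes[(cond, val)] = {"pos": base * m, "neg": base * m}
    return slopes


def generate_cohort(
    spec: EffectSpec | None = None, config: TaskConfig | None = None
) -> Cohort:
    """Simulate behaviour and self-reports for a full cohort.

    Deterministic given ``spec.seed``. Exactly
    ``round(responder_fraction * n_participants)`` participants are
    responders (assignment randomized over ids).
    """
    spec = spec or EffectSpec()
    config = config or TaskConfig()
    master = np.random.default_rng(np.random.SeedSequence([spec.seed, 0]))
    n = spec.n_participants
    n_resp = int(round(spec.responder_fraction * n))
    responder_ids = set(master.permutation(n)[:n_resp].tolist())
    participants = []
    for pid in range(n):
        rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 1, pid]))
        schedule = build_schedule(
            pid, config, seed=int(rng.integers(0, 2**31))
        )
        params = _draw_params(spec, rng)
        trials, trace = simulate_agent(
            schedule, params, rng, miss_rate=spec.miss_rate
        )
        responder = pid in responder_ids
        ratings = _draw_ratings(pid, responder, rng)
        delta = (
            ratings[ratings["condition"] == "stress"]["rating"].mean()
            - ratings[ratings["condition"] == "control"]["rating"].mean()
        )
        blunt = float(
            np.clip(
                spec.blunting - spec.stress_coupling * (delta - 2.5), 0.0, 1.0
            )
        )
        slopes = _true_slopes(spec, blunt, rng)
        participants.append(
            Participant(
                participant_id=pid,
                schedule=schedule,
                trials=trials,
                trace=trace,
                true_params=params,
                responder=responder,
                ratings=ratings,
                true_slopes=slopes,
                blunting_applied=blunt,
            )
        )
    return Cohort(spec=spec, config=config, participants=participants)


def n_scans_for_run(trials: pd.DataFrame, tr: float = TR_DEFAULT) -> int:
    """Scans needed to cover the run plus the 32-s haemodynamic tail."""
    return int(np.ceil((trials["outcome_onset"].max() + 33.0) / tr))


def generate_roi_bold(
    participant: Participant,
    spec: EffectSpec,
    rng: np.random.Generator,
    tr: float = TR_DEFAULT,
) -> dict[int, np.ndarray]:
    """Simulate one ROI series per run from the participant's true trace.

    Signal = unit stimulus/outcome responses (amplitude ``stick_amp``)
    + ``q_slope`` * Q_chosen at stimulus onset
    + cell-specific slope * delta at outcome onset (sign-resolved),
    convolved with the canonical HRF, plus a slow cosine drift, a 100-unit
    baseline and stationary AR(1) noise of sd ``noise_sd``.
    """
    kernel = canonical_hrf(tr)
    out = {}
    for run, trials in participant.trials.groupby("run"):
        n_scans = n_scans_for_run(trials, tr)
        sticks = np.zeros(n_scans)
        trace = participant.trace[participant.trace["run"] == run]
        for row in trials.itertuples(index=False):
            i = int(row.stim_onset // tr)
            sticks[i] += spec.stick_amp
            if row.choice != "missing":
                j = int(row.outcome_onset // tr)
                sticks[j] += spec.stick_amp
        for row in trace.itertuples(index=False):
            i = int(row.stim_onset // tr)
            sticks[i] += spec.q_slope * row.q_chosen
            j = int(row.outcome_onset // tr)
            s = participant.true_slopes[(row.condition, row.valence)]
            slope = s["pos"] if row.delta >= 0 else s["neg"]
            sticks[j] += slope * row.delta
        signal = np.convolve(sticks, kernel)[:n_scans]
        t = np.arange(n_scans) * tr
        drift = spec.drift_amp * np.cos(
            2 * np.pi * t / 300.0 + rng.uniform(0, 2 * np.pi)
        )
        if spec.noise_sd > 0:
            innov_sd = spec.noise_sd * np.sqrt(1 - spec.ar1_rho**2)
            eps = rng.normal(0.0, innov_sd, n_scans)
            noise = np.empty(n_scans)
            acc = rng.normal(0.0, spec.noise_sd)
            for i in range(n_scans):
                acc = spec.ar1_rho * acc + eps[i]
                noise[i] = acc
        else:
            noise = np.zeros(n_scans)
        out[int(run)] = 100.0 + signal + drift + noise
    return out


def cohort_bold(
    cohort: Cohort, tr: float = TR_DEFAULT
) -> dict[int, dict[int, np.ndarray]]:
    """ROI series for every participant, deterministically seeded."""
    out = {}
    for p in cohort.participants:
        rng = np.random.default_rng(
            np.random.SeedSequence([cohort.spec.seed, 2, p.participant_id])
        )
        out[p.participant_id] = generate_roi_bold(p, cohort.spec, rng, tr)
    return out


def end_to_end_fixture(
    outdir: Path,
    spec: EffectSpec | None = None,
    config: TaskConfig | None = None,
    tr: float = TR_DEFAULT,
) -> Path:
    """Write a self-contained dataset directory the full pipeline can run on.

    Layout: ``events/sub-<id>_run-<r>_events.tsv``,
    ``roi/sub-<id>_run-<r>_roi.tsv``, ``selfreports.csv`` and
    ``ground_truth.json`` (true parameters, slopes, responder status).
    Regenerating with the same spec yields byte-identical files.
    """
    spec = spec or EffectSpec()
    outdir = Path(outdir)
    (outdir / "events").mkdir(parents=True, exist_ok=True)
    (outdir / "roi").mkdir(parents=True, exist_ok=True)
    cohort = generate_cohort(spec, config)
    bold = cohort_bold(cohort, tr)
    truth: dict = {"tr": tr, "spec": asdict(spec), "participants": {}}
    for p in cohort.participants:
        for run, rt in p.trials.groupby("run"):
            io.write_events(
                rt,
                outdir
                / "events"
                / f"sub-{p.participant_id:02d}_run-{run}_events.tsv",
            )
        for run, y in bold[p.participant_id].items():
            io.write_roi(
                y,
                outdir / "roi" / f"sub-{p.participant_id:02d}_run-{run}_roi.tsv",
            )
        truth["participants"][str(p.participant_id)] = {
            "responder": p.responder,
            "blunting_applied": p.blunting_applied,
            "params": {
                c: list(p.true_params[c].as_tuple())
                for c in ("stress", "control")
            },
            "slopes": {
                f"{c}:{v}": p.true_slopes[(c, v)]
                for c in ("stress", "control")
                for v in ("gain", "loss")
            },
        }
    io.write_selfreports(cohort.reports, outdir / "selfreports.csv")
    (outdir / "ground_truth.json").write_text(
        json.dumps(truth, indent=1, sort_keys=True)
    )
    return outdir


def with_overrides(spec: EffectSpec, **kwargs) -> EffectSpec:
    """Convenience: a copy of ``spec`` with fields replaced."""
    return replace(spec, **kwargs)


# re-export for pipeline convenience
__all__ = [
    "EffectSpec",
    "Participant",
    "Cohort",
    "generate_cohort",
    "generate_roi_bold",
    "cohort_bold",
    "n_scans_for_run",
    "end_to_end_fixture",
    "with_overrides",
]
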