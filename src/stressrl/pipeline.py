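"""End-to-end orchestration: simulate (or load) -> behavioural statistics
-> model fitting -> first-level GLM -> second-level tests -> subsidiary
models -> responsivity correlation, with per-stage CSV outputs, a config
snapshot and a summary of the qualitative effect-pattern checks
(gain-specific behavioural impairment, prediction-error slope blunting
under stress, and the condition x sign interaction).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, cohort as cohort_mod, glm, io
from .cohort import Cohort, EffectSpec, Participant
from .fitting import FitSettings, fit_condition
from .model import RLParams, trace_from_choices
from .task import TaskConfig

log = logging.getLogger("stressrl")

ALL_STAGES = ("behavior", "fit", "glm", "subsidiary", "responsivity")


@dataclass
class RunConfig:
    """One reproducible pipeline run.

    ``seed`` is mandatory and fans out to per-stage child seeds by fixed
    offsets; ``effects`` overrides fields of the default ``EffectSpec``;
    ``data_dir`` (optional) points at an existing fixture-format dataset
    instead of simulating one; ``analyses`` selects stages (an empty list
    validates inputs only).
    """

    out_dir: Path
    seed: int
    data_dir: Path | None = None
    effects: dict = field(default_factory=dict)
    n_starts: int = 20
    tr: float = 2.0
    analyses: tuple[str, ...] = ALL_STAGES
    apply_responder_filter: bool = True

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        unknown = set(self.analyses) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown analyses: {sorted(unknown)}")
        self.out_dir = Path(self.out_dir)
        if self.data_dir is not None:
            self.data_dir = Path(self.data_dir)

    @classmethod
    def from_yaml(cls, path: Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update(overrides)
        if "analyses" in raw and raw["analyses"] is not None:
            raw["analyses"] = tuple(raw["analyses"])
        return cls(**raw)

    def snapshot(self) -> str:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(d["out_dir"])
        d["data_dir"] = None if d["data_dir"] is None else str(d["data_dir"])
        d["analyses"] = list(d["analyses"])
        return yaml.safe_dump(d, sort_keys=True)


def _load_dataset(data_dir: Path, tr: float):
    """Load a fixture-format dataset written by ``end_to_end_fixture``."""
    events = sorted((data_dir / "events").glob("sub-*_events.tsv"))
    if not events:
        raise FileNotFoundError(f"no events files under {data_dir}/events")
    trials_by_pid: dict[int, list[pd.DataFrame]] = {}
    for path in events:
        m = re.match(r"sub-(\d+)_run-(\d+)_events\.tsv", path.name)
        if not m:
            raise ValueError(f"unrecognized events filename: {path.name}")
        pid = int(m.group(1))
        trials_by_pid.setdefault(pid, []).append(io.read_events(path))
    trials = {
        pid: pd.concat(parts, ignore_index=True)
        for pid, parts in trials_by_pid.items()
    }
    bold: dict[int, dict[int, np.ndarray]] = {}
    for path in sorted((data_dir / "roi").glob("sub-*_roi.tsv")):
        m = re.match(r"sub-(\d+)_run-(\d+)_roi\.tsv", path.name)
        if not m:
            raise ValueError(f"unrecognized ROI filename: {path.name}")
        bold.setdefault(int(m.group(1)), {})[int(m.group(2))] = io.read_roi(
            path
        )
    reports = io.read_selfreports(data_dir / "selfreports.csv")
    return trials, bold, reports


def _simulate_dataset(config: RunConfig):
    spec = EffectSpec(**{"seed": config.seed, **config.effects})
    coh = cohort_mod.generate_cohort(spec)
    bold = cohort_mod.cohort_bold(coh, config.tr)
    trials = {p.participant_id: p.trials for p in coh.participants}
    return trials, bold, coh.reports, coh


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the summary dictionary.

    Outputs are written under ``config.out_dir`` together with a
    ``config.yaml`` snapshot. Raises on hard errors (missing inputs,
    malformed files); statistical null results are reported, not raised.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(config.snapshot())
    summary: dict = {"seed": config.seed, "checks": {}}

    if config.data_dir is not None:
        trials, bold, reports = _load_dataset(config.data_dir, config.tr)
    else:
        trials, bold, reports, _ = _simulate_dataset(config)

    included, delta_stress = behavior.responder_filter(reports)
    if not config.apply_responder_filter:
        included = sorted(trials)
    summary["n_participants"] = len(trials)
    summary["n_included"] = len(included)
    delta_stress.rename_axis("participant").reset_index().to_csv(
        out / "responders.csv", index=False
    )
    if not config.analyses:
        log.info("no analyses requested; inputs validated")
        (out / "summary.json").write_text(json.dumps(summary, indent=1))
        return summary

    trials_included = {pid: trials[pid] for pid in included}
    choice_frames = []
    for pid, t in trials_included.items():
        t = t.copy()
        t.insert(0, "participant", pid)
        choice_frames.append(t)
    all_trials = pd.concat(choice_frames, ignore_index=True)
    choices = behavior.code_correct(all_trials)

    if "behavior" in config.analyses:
        aov = behavior.manipulation_anova(
            reports[reports["participant"].isin(included)]
        )
        aov.to_csv(out / "manipulation_anova.csv", index=False)
        glme = behavior.performance_glme(choices)
        glme.coefficients.to_csv(out / "glme_coefficients.csv", index=False)
        f_gain, p_gain = behavior.posthoc_contrast(glme, "gain")
        f_loss, p_loss = behavior.posthoc_contrast(glme, "loss")
        curves = behavior.learning_curves(choices)
        curves.to_csv(out / "learning_curves.csv", index=False)
        cond_beta = glme.coef("condition")
        summary["checks"]["behavioural_gain_impairment"] = {
            "condition_beta_gain": cond_beta,
            "F_gain": f_gain,
            "p_gain": p_gain,
            "F_loss": f_loss,
            "p_loss": p_loss,
            "pattern": bool(cond_beta < 0 and p_gain < 0.05 and p_loss > 0.05),
        }

    fits: dict[int, dict[str, object]] = {}
    if "fit" in config.analyses or "glm" in config.analyses:
        for pid, t in trials_included.items():
            fits[pid] = {}
            for cond in ("stress", "control"):
                fits[pid][cond] = fit_condition(
                    t[t["condition"] == cond],
                    FitSettings(
                        n_starts=config.n_starts,
                        seed=(config.seed + 1009 * (pid + 1)) % 2**31,
                    ),
                )
        io.params_to_frame(fits).to_csv(out / "rl_parameters.csv", index=False)

    slope_table = pd.DataFrame()
    traces: dict[int, pd.DataFrame] = {}
    if "glm" in config.analyses or "subsidiary" in config.analyses:
        slope_rows = []
        for pid, t in trials_included.items():
            params = {c: fits[pid][c].params for c in ("stress", "control")}
            traces[pid] = trace_from_choices(t, params)
        for pid, t in trials_included.items():
            run_fits = {}
            for run, y in bold[pid].items():
                rt = t[t["run"] == run]
                rtrace = traces[pid][traces[pid]["run"] == run]
                design = glm.build_design(
                    rt, rtrace, config.tr, len(y)
                )
                run_fits[run] = glm.fit_ar1_glm(y, design)
            slope_rows.append(glm.first_level_slopes(run_fits, pid))
        slope_table = pd.concat(slope_rows, ignore_index=True)
        slope_table.to_csv(out / "pe_slopes.csv", index=False)

    if "glm" in config.analyses:
        tests = glm.second_level_tests(slope_table)
        tests.to_csv(out / "second_level_tests.csv", index=False)
        main = tests.set_index("test").loc["main_effect_control_gt_stress"]
        summary["checks"]["pe_slope_blunting"] = {
            "mean_control_minus_stress": float(main["estimate"]),
            "t": float(main["t"]),
            "p": float(main["p"]),
            "pattern": bool(main["estimate"] > 0 and main["p"] < 0.05),
        }

    if "subsidiary" in config.analyses:
        bin_frames, bound_frames, sign_frames = [], [], []
        for pid, t in trials_included.items():
            est, bounds = glm.subsidiary_bins(
                t, traces[pid], bold[pid], config.tr, participant=pid
            )
            bin_frames.append(est)
            bound_frames.append(bounds)
            sign_frames.append(
                glm.subsidiary_sign(
                    t, traces[pid], bold[pid], config.tr, participant=pid
                )
            )
        bins = pd.concat(bin_frames, ignore_index=True)
        bins.to_csv(out / "subsidiary_bins.csv", index=False)
        boundaries = pd.concat(bound_frames, ignore_index=True)
        glm.boundary_comparison(boundaries).to_csv(
            out / "bin_boundary_tests.csv", index=False
        )
        signs = pd.concat(sign_frames, ignore_index=True)
        signs.to_csv(out / "subsidiary_sign.csv", index=False)
        res = glm.sign_split_anova(signs)
        res["anova"].to_csv(out / "sign_anova.csv", index=False)
        res["paired"].to_csv(out / "sign_paired_tests.csv", index=False)
        inter = res["anova"].set_index("effect")
        inter_row = inter.loc["condition:pe_sign"]
        d = res["paired"].set_index(["valence", "pe_sign"])["cohens_d"]
        summary["checks"]["sign_split_interaction"] = {
            "F": float(inter_row["F"]),
            "p": float(inter_row["p"]),
            "d_gain_pos": float(d.loc[("gain", "pos")]),
            "d_gain_neg": float(d.loc[("gain", "neg")]),
            "d_loss_pos": float(d.loc[("loss", "pos")]),
            "d_loss_neg": float(d.loc[("loss", "neg")]),
            "pattern": bool(inter_row["p"] < 0.05),
        }

    if "responsivity" in config.analyses and len(slope_table):
        resp = glm.responsivity_correlation(slope_table, delta_stress)
        summary["checks"]["responsivity_correlation"] = resp

    (out / "summary.json").write_text(json.dumps(summary, indent=1))
    log.info("pipeline finished: %s", out / "summary.json")
    return summary
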