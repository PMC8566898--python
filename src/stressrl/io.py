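"""Readers and writers for the pipeline's plain-text file dialects.

Events files are BIDS-style tab-separated tables with two rows per trial
(``trial_type`` stimulus / outcome) plus the task-specific columns needed
to rebuild the internal one-row-per-trial table; unavailable values
(e.g. the outcome of a missed trial) are written as ``n/a``. ROI series
are two-column TSVs (scan index, value), self-reports and parameter
tables plain CSVs.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

EVENT_COLUMNS = [
    "onset",
    "duration",
    "trial_type",
    "run",
    "block_pos",
    "condition",
    "block",
    "valence",
    "pair_id",
    "presentation",
    "side_of_correct",
    "chosen_side",
    "choice",
    "outcome_r",
]


def trials_to_events(trials: pd.DataFrame) -> pd.DataFrame:
    """Long (two rows per trial) events table from a trial table."""
    common = trials[
        [
            "run",
            "block_pos",
            "condition",
            "block",
            "valence",
            "pair_id",
            "presentation",
            "side_of_correct",
            "chosen_side",
            "choice",
            "outcome_r",
        ]
    ]
    stim = common.copy()
    stim.insert(0, "onset", trials["stim_onset"].to_numpy())
    stim.insert(1, "duration", 0.0)
    stim.insert(2, "trial_type", "stimulus")
    out = common[trials["choice"] != "missing"].copy()
    out.insert(
        0, "onset", trials.loc[trials["choice"] != "missing", "outcome_onset"]
    )
    out.insert(1, "duration", 0.0)
    out.insert(2, "trial_type", "outcome")
    events = pd.concat([stim, out]).sort_values(["run", "onset"], kind="stable")
    return events[EVENT_COLUMNS].reset_index(drop=True)


def write_events(trials: pd.DataFrame, path: Path) -> None:
    events = trials_to_events(trials)
    events.to_csv(
        path, sep="\t", index=False, na_rep="n/a", float_format="%.10g"
    )


def read_events(path: Path) -> pd.DataFrame:
    """Rebuild the one-row-per-trial table from an events file."""
    ev = pd.read_csv(path, sep="\t", na_values=["n/a"])
    stim = ev[ev["trial_type"] == "stimulus"].copy()
    out = ev[ev["trial_type"] == "outcome"]
    key = ["run", "pair_id", "presentation"]
    outcome_onset = out.set_index(key)["onset"]
    stim = stim.rename(columns={"onset": "stim_onset"})
    idx = pd.MultiIndex.from_frame(stim[key])
    stim["outcome_onset"] = outcome_onset.reindex(idx).to_numpy()
    stim = stim.drop(columns=["duration", "trial_type"])
    stim["choice"] = stim["choice"].fillna("missing")
    miss = stim["choice"] == "missing"
    if (~miss & stim["outcome_onset"].isna()).any():
        raise ValueError(f"{path}: non-missing trial without an outcome row")
    cols = [
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
        "chosen_side",
        "choice",
        "outcome_r",
    ]
    return (
        stim[cols]
        .sort_values(["run", "stim_onset"], kind="stable")
        .reset_index(drop=True)
    )


def write_roi(y: np.ndarray, path: Path) -> None:
    pd.DataFrame({"scan": np.arange(len(y)), "value": y}).to_csv(
        path, sep="\t", index=False, float_format="%.10g"
    )


def read_roi(path: Path) -> np.ndarray:
    df = pd.read_csv(path, sep="\t")
    if not np.isfinite(df["value"].to_numpy()).all():
        raise ValueError(f"{path}: non-finite BOLD values")
    return df["value"].to_numpy(float)


def read_roi_nifti(img_path: Path, mask_path: Path) -> np.ndarray:
    """Convenience reader: mean time series of a 4D NIfTI over a binary
    mask, as an alternative to the 2-column ROI TSV dialect."""
    import nibabel as nib

    img = np.asanyarray(nib.load(str(img_path)).dataobj)
    mask = np.asanyarray(nib.load(str(mask_path)).dataobj) > 0
    if img.shape[:3] != mask.shape:
        raise ValueError("image and mask grids differ")
    return img[mask].mean(axis=0).astype(float)


def write_selfreports(reports: pd.DataFrame, path: Path) -> None:
    reports.to_csv(path, index=False)


def read_selfreports(path: Path) -> pd.DataFrame:
    return pd.read_csv(path)


def params_to_frame(params_by_participant: dict) -> pd.DataFrame:
    """CSV-ready parameter table: one row per participant x condition."""
    rows = []
    for pid, by_cond in params_by_participant.items():
        for cond, fit in by_cond.items():
            rows.append(
                {
                    "participant_id": pid,
                    "condition": cond,
                    "alpha_pos": fit.params.alpha_pos,
                    "alpha_neg": fit.params.alpha_neg,
                    "beta": fit.params.beta,
                    "nll": fit.nll,
                    "n_trials": fit.n_trials,
                }
            )
    return pd.DataFrame(rows)
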