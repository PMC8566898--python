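"""Behavioural analysis chain: correct-choice coding, stress-responder
filtering, the manipulation-check repeated-measures ANOVA, the trial-wise
mixed-effects logistic model of performance, planned contrasts, and
learning curves.

Predictor coding for the mixed model (documented because only signs and
simple effects are interpreted): condition is a 0/1 dummy with control as
reference, valence a 0/1 dummy with gain as reference, block is 1/2 and
trial 1-24 entered as numeric covariates. Under this coding the condition
coefficient is the stress effect on gain trials (negative when stress
impairs reward learning) and the condition x valence coefficient is the
difference between the stress effect on loss and on gain trials (positive
when the impairment is gain-specific).
"""

from __future__ import annotations

import json
import shutil
import subprocess
import tempfile
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats


def code_correct(trials: pd.DataFrame) -> pd.DataFrame:
    """Code trial-wise choices as correct (1) / incorrect (0).

    On gain trials the correct stimulus is the one more likely to win; on
    loss trials, the one more likely to avoid the loss. Neutral trials
    (no correct response defined) and missing trials are dropped. The
    returned table has one row per retained trial with columns
    participant, condition, valence, block, trial (the presentation count
    of the pair within its block, 1-24) and correct.
    """
    required = {"participant", "valence", "choice"}
    missing_cols = required - set(trials.columns)
    if missing_cols:
        raise ValueError(f"trial table lacks columns {sorted(missing_cols)}")
    unknown = set(trials["valence"].unique()) - {"gain", "loss", "neutral"}
    if unknown:
        raise ValueError(f"unknown valence values: {sorted(unknown)}")
    kept = trials[
        trials["valence"].isin(("gain", "loss"))
        & (trials["choice"] != "missing")
    ]
    out = pd.DataFrame(
        {
            "participant": kept["participant"].to_numpy(),
            "condition": kept["condition"].to_numpy(),
            "valence": kept["valence"].to_numpy(),
            "block": kept["block"].to_numpy(),
            "trial": kept["presentation"].to_numpy(),
            "correct": (kept["choice"] == "correct").astype(int).to_numpy(),
        }
    )
    return out.reset_index(drop=True)


def responder_filter(
    reports: pd.DataFrame,
) -> tuple[list, pd.Series]:
    """Keep participants who reported more stress under the stressor.

    ``reports`` has one rating (1-9) per participant x condition x block.
    Delta = mean(stress ratings) - mean(control ratings); a participant is
    included iff Delta > 0. Returns the included ids and the per-
    participant Delta series (all participants).
    """
    deltas = {}
    for pid, sub in reports.groupby("participant", sort=True):
        blocks = {
            cond: set(grp["block"]) for cond, grp in sub.groupby("condition")
        }
        if (
            set(blocks) != {"stress", "control"}
            or blocks["stress"] != blocks["control"]
            or sub["rating"].isna().any()
        ):
            raise ValueError(f"incomplete self-reports for participant {pid}")
        mean = sub.groupby("condition")["rating"].mean()
        deltas[pid] = float(mean["stress"] - mean["control"])
    delta = pd.Series(deltas, name="delta_stress")
    included = [pid for pid, d in delta.items() if d > 0]
    return included, delta


def rm_anova_2x2(
    data: pd.DataFrame, dv: str, within: list[str], subject: str
) -> pd.DataFrame:
    """Two-way fully-within ANOVA with partial eta squared.

    Thin wrapper around pingouin's repeated-measures ANOVA that treats a
    zero sum-of-squares effect as an exact null (F = 0, p = 1) instead of
    the 0/0 indeterminate pingouin would propagate. Two-level factors
    need no sphericity correction.
    """
    with warnings.catch_warnings():
        # degenerate (zero-SS) effects divide 0/0 inside pingouin; they
        # are overwritten with exact nulls below
        warnings.simplefilter("ignore", RuntimeWarning)
        aov = pg.rm_anova(
            data=data,
            dv=dv,
            within=within,
            subject=subject,
            detailed=True,
            effsize="np2",
        )
    out = aov.rename(
        columns={"Source": "effect", "p_unc": "p", "p-unc": "p",
                 "np2": "partial_eta_sq"}
    )
    null = out["SS"].abs() < 1e-12
    out.loc[null, "F"] = 0.0
    out.loc[null, "p"] = 1.0
    out.loc[null, "partial_eta_sq"] = 0.0
    out = out[["effect", "F", "p", "partial_eta_sq"]]
    out["effect"] = out["effect"].str.replace(" * ", ":", regex=False)
    return out.reset_index(drop=True)


def manipulation_anova(reports: pd.DataFrame) -> pd.DataFrame:
    """2 x 2 within-subject ANOVA on self-reported stress ratings.

    Factors: condition (stress/control) and block (1/2). Returns one row
    per effect with F, p and partial eta squared.
    """
    counts = reports.groupby(["participant", "condition", "block"]).size()
    if (counts != 1).any():
        raise ValueError("design must have exactly one rating per cell")
    n_cells = reports.groupby("participant").size()
    if n_cells.nunique() != 1 or n_cells.iloc[0] != 4:
        raise ValueError("unbalanced design: each participant needs 4 cells")
    return rm_anova_2x2(reports, "rating", ["condition", "block"], "participant")


@dataclass
class GlmeResult:
    """Fitted mixed-effects logistic model of trial-wise accuracy."""

    coefficients: pd.DataFrame  # term, estimate, se, z, p, ci_low, ci_high
    vcov: np.ndarray  # fixed-effects covariance, term order as above
    random_intercept_var: float
    n_obs: int
    converged: bool
    separation_flag: bool

    def coef(self, term: str) -> float:
        row = self.coefficients.set_index("term").loc[term]
        return float(row["estimate"])


_GLMER_SCRIPT = r"""
suppressMessages(library(lme4))
suppressMessages(library(jsonlite))
args <- commandArgs(trailingOnly = TRUE)
d <- read.csv(args[1])
d$participant <- factor(d$participant)
m <- glmer(
  correct ~ condition + valence + block + trial + condition:valence
    + (1 | participant),
  data = d, family = binomial,
  control = glmerControl(optimizer = "bobyqa")
)
s <- summary(m)
co <- s$coefficients
msgs <- unlist(m@optinfo$conv$lme4$messages)
out <- list(
  terms = rownames(co),
  estimate = unname(co[, 1]),
  se = unname(co[, 2]),
  z = unname(co[, 3]),
  p = unname(co[, 4]),
  vcov = as.matrix(vcov(m)),
  re_var = as.numeric(VarCorr(m)$participant[1]),
  nobs = nobs(m),
  messages = if (is.null(msgs)) character(0) else msgs
)
writeLines(toJSON(out, digits = 15, auto_unbox = FALSE), args[2])
"""


def performance_glme(choices: pd.DataFrame) -> GlmeResult:
    """Mixed-effects logistic regression of trial-wise accuracy.

    Fixed effects: condition, valence, block, trial and the condition x
    valence interaction (coding in the module docstring); random
    intercepts per participant. Estimated with lme4::glmer (Laplace
    approximation) through Rscript; Wald 95% CIs.
    """
    if choices["participant"].nunique() < 2:
        raise ValueError("need at least 2 participants for a mixed model")
    for col, levels in (("condition", {"stress", "control"}),
                        ("valence", {"gain", "loss"})):
        if set(choices[col].unique()) != levels:
            raise ValueError(f"both {col} levels must be present")
    if shutil.which("Rscript") is None:
        raise RuntimeError("Rscript not found on PATH (needed for glmer)")
    d = pd.DataFrame(
        {
            "participant": choices["participant"],
            "condition": (choices["condition"] == "stress").astype(int),
            "valence": (choices["valence"] == "loss").astype(int),
            "block": choices["block"].astype(float),
            "trial": choices["trial"].astype(float),
            "correct": choices["correct"].astype(int),
        }
    )
    with tempfile.TemporaryDirectory() as tmp:
        tmp = Path(tmp)
        csv = tmp / "choices.csv"
        script = tmp / "glmer.R"
        out_json = tmp / "fit.json"
        d.to_csv(csv, index=False)
        script.write_text(_GLMER_SCRIPT)
        proc = subprocess.run(
            ["Rscript", "--vanilla", str(script), str(csv), str(out_json)],
            capture_output=True,
            text=True,
        )
        if proc.returncode != 0 or not out_json.exists():
            raise RuntimeError(f"glmer failed:\n{proc.stderr[-2000:]}")
        res = json.loads(out_json.read_text())
    est = np.asarray(res["estimate"], float)
    se = np.asarray(res["se"], float)
    coefs = pd.DataFrame(
        {
            "term": res["terms"],
            "estimate": est,
            "se": se,
            "z": np.asarray(res["z"], float),
            "p": np.asarray(res["p"], float),
            "ci_low": est - 1.959963984540054 * se,
            "ci_high": est + 1.959963984540054 * se,
        }
    )
    messages = " ".join(res.get("messages", []))
    separation = bool(np.any(np.abs(est) > 10) or np.any(se > 10))

    def scalar(v):
        return v[0] if isinstance(v, list) else v

    return GlmeResult(
        coefficients=coefs,
        vcov=np.asarray(res["vcov"], float),
        random_intercept_var=float(scalar(res["re_var"])),
        n_obs=int(scalar(res["nobs"])),
        converged="failed to converge" not in messages,
        separation_flag=separation,
    )


def posthoc_contrast(fit: GlmeResult, valence: str) -> tuple[float, float]:
    """Wald F-test of the stress-vs-control simple effect within a valence.

    Under the documented coding the contrast is the condition coefficient
    on gain trials and condition + condition:valence on loss trials.
    Returns (F, p) with 1 and n_obs - k denominator degrees of freedom.
    """
    terms = list(fit.coefficients["term"])
    c = np.zeros(len(terms))
    try:
        c[terms.index("condition")] = 1.0
        if valence == "loss":
            c[terms.index("condition:valence")] = 1.0
        elif valence != "gain":
            raise ValueError(f"unknown valence {valence!r}")
    except ValueError as err:
        raise ValueError(f"contrast inestimable: {err}") from err
    est = fit.coefficients["estimate"].to_numpy()
    var = float(c @ fit.vcov @ c)
    if var <= 0:
        raise ValueError("contrast inestimable: non-positive variance")
    F = float((c @ est) ** 2 / var)
    df2 = fit.n_obs - len(terms)
    p = float(stats.f.sf(F, 1, df2))
    return F, p


def learning_curves(choices: pd.DataFrame) -> pd.DataFrame:
    """Per-trial mean fraction of correct choices, by condition x valence.

    Within each participant the two blocks of a condition are averaged
    first; the mean and SEM are then taken across participants, giving
    one 24-point curve per condition x valence cell.
    """
    if len(choices) == 0:
        raise ValueError("empty choice table")
    per_subj = (
        choices.groupby(["condition", "valence", "trial", "participant"])[
            "correct"
        ]
        .mean()
        .reset_index()
    )
    grp = per_subj.groupby(["condition", "valence", "trial"])["correct"]
    out = grp.agg(
        mean="mean", sem=lambda x: x.std(ddof=1) / np.sqrt(len(x)), n="size"
    ).reset_index()
    return out
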