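"""Model-based GLM on ROI-averaged BOLD time series.

First-level analysis: every trial contributes stick (zero-duration)
regressors at stimulus and outcome onset, separated by condition x
valence; monetary trials additionally carry parametric modulators --
the value of the chosen option Q_chosen at stimulus onset and the
prediction error delta at outcome onset, per condition x valence.
Modulators are mean-centered within run (and not serially orthogonalized
against their parent sticks, so their slopes keep a direct
interpretation). All event regressors are binned to the scan grid
(floor to the containing TR), convolved with the canonical double-gamma
haemodynamic response, complemented with a 128-s discrete-cosine
high-pass basis and an intercept, and fitted with AR(1) prewhitening.

Second-level analysis operates on the per-subject delta-modulator slopes
(one per condition x valence, inverse-variance averaged over runs):
one-sample t-tests per cell, a paired t-test for the control > stress
main effect, and a paired t-test for the condition x valence
interaction. Two subsidiary, modulator-free models bin outcomes by
prediction-error quartile or sign to visualise how the BOLD response
tracks the prediction error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .behavior import rm_anova_2x2

CELLS = [
    (c, v) for c in ("stress", "control") for v in ("gain", "loss")
]


def canonical_hrf(tr: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma haemodynamic response sampled every ``tr`` s.

    Difference of two gamma densities (peak ~5 s, undershoot ~15 s,
    undershoot ratio 1/6) on a 32-s support, normalized to unit peak on
    the evaluation grid. Deterministic.
    """
    if tr <= 0:
        raise ValueError("TR must be positive")
    t = np.arange(0.0, duration, tr)
    h = stats.gamma.pdf(t, a=6.0, scale=1.0) - stats.gamma.pdf(
        t, a=16.0, scale=1.0
    ) / 6.0
    peak = h.max()
    if peak > 0:
        h = h / peak
    return h


def highpass_dct(n_scans: int, tr: float, cutoff: float = 128.0) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff`` s.

    Columns are the unit-norm DCT-II basis functions with order
    k = 1 .. floor(2 * n_scans * tr / cutoff); projecting them out
    high-pass filters the series at ``cutoff`` seconds (the constant term
    is left to the design intercept).
    """
    if n_scans < 2:
        raise ValueError("need at least two scans")
    order = int(np.floor(2.0 * n_scans * tr / cutoff))
    n = np.arange(n_scans)
    basis = np.empty((n_scans, order))
    for k in range(1, order + 1):
        col = np.cos(np.pi * k * (2 * n + 1) / (2.0 * n_scans))
        basis[:, k - 1] = col / np.linalg.norm(col)
    return basis


@dataclass
class DesignMatrix:
    """First-level design for one run: named columns plus bookkeeping of
    omitted (event type absent) and flagged (degenerate) columns."""

    frame: pd.DataFrame
    tr: float
    omitted: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)

    @property
    def task_columns(self) -> list[str]:
        return [
            c
            for c in self.frame.columns
            if not c.startswith("drift:") and c != "const"
        ]


def _sticks(
    n_scans: int, tr: float, onsets: np.ndarray, amplitudes: np.ndarray
) -> np.ndarray:
    col = np.zeros(n_scans)
    idx = np.floor(np.asarray(onsets) / tr).astype(int)
    if np.any(idx >= n_scans) or np.any(idx < 0):
        raise ValueError("event onset outside the scanned run")
    np.add.at(col, idx, amplitudes)
    return col


def _convolve(col: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    return np.convolve(col, kernel)[: len(col)]


def build_design(
    trials: pd.DataFrame,
    trace: pd.DataFrame,
    tr: float,
    n_scans: int,
    hp_cutoff: float = 128.0,
    extra_columns: pd.DataFrame | None = None,
) -> DesignMatrix:
    """Build the primary first-level design matrix for one run.

    ``trials`` and ``trace`` must belong to a single run (onsets on the
    run clock). Columns: ``stim:<cond>:<val>`` and ``out:<cond>:<val>``
    sticks for every condition x valence present (outcome sticks only for
    non-missing trials), ``q:<cond>:<val>`` and ``pe:<cond>:<val>``
    mean-centered parametric modulators for monetary trials, a
    ``missing`` stick regressor if any trial was missed, optional extra
    nuisance columns, the DCT drift basis and an intercept.

    Event types absent from the run are omitted and recorded in
    ``omitted``; modulators that are constant (centered column
    identically zero, hence unestimable) are left out and recorded in
    ``flagged``.
    """
    if trials["run"].nunique() > 1:
        raise ValueError("build_design expects trials from a single run")
    if len(trace) and trace["run"].nunique() > 1:
        raise ValueError("build_design expects a single-run trace")
    if len(trace) != len(
        trials[
            trials["valence"].isin(("gain", "loss"))
            & (trials["choice"] != "missing")
        ]
    ):
        raise ValueError("trace length does not match monetary trials")
    kernel = canonical_hrf(tr)
    cols: dict[str, np.ndarray] = {}
    omitted: list[str] = []
    flagged: list[str] = []
    present = trials[trials["choice"] != "missing"]
    for cond in ("stress", "control"):
        for val in ("gain", "loss", "neutral"):
            sub = present[
                (present["condition"] == cond) & (present["valence"] == val)
            ]
            for kind, onset_col in (
                ("stim", "stim_onset"),
                ("out", "outcome_onset"),
            ):
                name = f"{kind}:{cond}:{val}"
                if len(sub) == 0:
                    omitted.append(name)
                    continue
                cols[name] = _sticks(
                    n_scans,
                    tr,
                    sub[onset_col].to_numpy(),
                    np.ones(len(sub)),
                )
    for cond in ("stress", "control"):
        for val in ("gain", "loss"):
            tsub = trace[
                (trace["condition"] == cond) & (trace["valence"] == val)
            ]
            for kind, onset_col, value_col in (
                ("q", "stim_onset", "q_chosen"),
                ("pe", "outcome_onset", "delta"),
            ):
                name = f"{kind}:{cond}:{val}"
                if len(tsub) == 0:
                    omitted.append(name)
                    continue
                values = tsub[value_col].to_numpy(float)
                centered = values - values.mean()
                if np.allclose(centered, 0.0):
                    # constant modulator: centered column would be all-zero
                    # (unestimable), so flag it and leave it out
                    flagged.append(name)
                    continue
                cols[name] = _sticks(
                    n_scans, tr, tsub[onset_col].to_numpy(), centered
                )
    missed = trials[trials["choice"] == "missing"]
    if len(missed):
        cols["missing"] = _sticks(
            n_scans, tr, missed["stim_onset"].to_numpy(), np.ones(len(missed))
        )
    frame = pd.DataFrame(
        {name: _convolve(col, kernel) for name, col in cols.items()}
    )
    if extra_columns is not None:
        for name in extra_columns.columns:
            frame[name] = np.asarray(extra_columns[name], float)
    drift = highpass_dct(n_scans, tr, hp_cutoff)
    for k in range(drift.shape[1]):
        frame[f"drift:{k + 1}"] = drift[:, k]
    frame["const"] = 1.0
    return DesignMatrix(frame=frame, tr=tr, omitted=omitted, flagged=flagged)


@dataclass
class GLMFit:
    """AR(1)-prewhitened GLM fit of one run."""

    beta: pd.Series
    beta_var: pd.Series
    rho: float
    sigma2: float
    dof: int
    whitened_lag1: float


def _lag1_autocorr(x: np.ndarray) -> float:
    x = x - x.mean()
    denom = float(x @ x)
    if denom <= 0:
        return 0.0
    return float(x[1:] @ x[:-1] / denom)


def fit_ar1_glm(y: np.ndarray, design: DesignMatrix) -> GLMFit:
    """Fit the GLM with AR(1) prewhitening.

    The AR coefficient is estimated from the lag-1 autocorrelation of the
    OLS residuals; data and design are then transformed (Prais-Winsten:
    first observation scaled by sqrt(1 - rho^2), the rest differenced by
    rho) and refitted by OLS. Degenerate, noise-free residuals yield
    rho = 0 and a plain OLS fit.
    """
    X = design.frame.to_numpy(float)
    y = np.asarray(y, float)
    n, p = X.shape
    if len(y) != n:
        raise ValueError("time series and design have different lengths")
    if n <= p:
        raise ValueError("more design columns than scans")
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the offending columns via tiny R diagonal of a pivoted QR
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [
            design.frame.columns[i]
            for i in range(p)
            if diag[i] < 1e-8 * diag.max()
        ]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    if float(resid @ resid) < 1e-12 * max(1.0, float(y @ y)):
        rho = 0.0
    else:
        rho = _lag1_autocorr(resid)
        rho = float(np.clip(rho, -0.99, 0.99))
    if rho != 0.0:
        w = math.sqrt(1.0 - rho**2)
        yw = np.empty_like(y)
        Xw = np.empty_like(X)
        yw[0] = w * y[0]
        Xw[0] = w * X[0]
        yw[1:] = y[1:] - rho * y[:-1]
        Xw[1:] = X[1:] - rho * X[:-1]
    else:
        yw, Xw = y, X
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    residw = yw - Xw @ beta
    dof = n - p
    sigma2 = float(residw @ residw) / dof
    xtx_inv = np.linalg.inv(Xw.T @ Xw)
    beta_var = sigma2 * np.diag(xtx_inv)
    cols = design.frame.columns
    return GLMFit(
        beta=pd.Series(beta, index=cols),
        beta_var=pd.Series(beta_var, index=cols),
        rho=rho,
        sigma2=sigma2,
        dof=dof,
        whitened_lag1=_lag1_autocorr(residw),
    )


def first_level_slopes(
    run_fits: dict[int, GLMFit], participant
) -> pd.DataFrame:
    """Per-cell prediction-error modulation slopes for one participant.

    For each condition x valence, the ``pe`` modulator betas of the runs
    in which the cell is present are combined by inverse-variance
    weighting. Cells absent from every run are returned with NaN slope
    and ``absent = True``.
    """
    rows = []
    for cond, val in CELLS:
        name = f"pe:{cond}:{val}"
        betas, variances = [], []
        for fit in run_fits.values():
            if name in fit.beta.index:
                betas.append(fit.beta[name])
                variances.append(fit.beta_var[name])
        if betas:
            w = 1.0 / np.asarray(variances)
            slope = float(np.sum(w * np.asarray(betas)) / np.sum(w))
            var = float(1.0 / np.sum(w))
            absent = False
        else:
            slope, var, absent = np.nan, np.nan, True
        rows.append(
            {
                "participant": participant,
                "condition": cond,
                "valence": val,
                "slope": slope,
                "var": var,
                "n_runs": len(betas),
                "absent": absent,
            }
        )
    return pd.DataFrame(rows)


def second_level_tests(slopes: pd.DataFrame) -> pd.DataFrame:
    """Group-level tests on the delta-modulation slopes.

    (i) one-sample t-test of each condition x valence cell against zero;
    (ii) paired t-test of the control > stress main effect (slopes
    averaged over valences); (iii) paired t-test of the condition x
    valence interaction. Participants missing any cell are dropped (and
    counted in the ``n_dropped`` attribute of the returned frame).
    """
    wide = slopes.pivot_table(
        index="participant", columns=["condition", "valence"], values="slope"
    )
    complete = wide.dropna()
    n_dropped = len(wide) - len(complete)
    if len(complete) < 3:
        raise ValueError(
            f"need >= 3 participants with complete cells, got {len(complete)}"
        )
    rows = []
    for cond, val in CELLS:
        x = complete[(cond, val)].to_numpy()
        t, p = stats.ttest_1samp(x, 0.0)
        rows.append(
            {
                "test": f"one_sample:{cond}:{val}",
                "estimate": float(x.mean()),
                "t": float(t),
                "p": float(p),
                "n": len(x),
            }
        )
    control = (complete[("control", "gain")] + complete[("control", "loss")]) / 2
    stress = (complete[("stress", "gain")] + complete[("stress", "loss")]) / 2
    diff = control - stress
    t, p = stats.ttest_1samp(diff.to_numpy(), 0.0)
    rows.append(
        {
            "test": "main_effect_control_gt_stress",
            "estimate": float(diff.mean()),
            "t": float(t),
            "p": float(p),
            "n": len(diff),
        }
    )
    inter = (
        complete[("control", "gain")]
        - complete[("stress", "gain")]
        - (complete[("control", "loss")] - complete[("stress", "loss")])
    )
    t, p = stats.ttest_1samp(inter.to_numpy(), 0.0)
    rows.append(
        {
            "test": "condition_x_valence_interaction",
            "estimate": float(inter.mean()),
            "t": float(t),
            "p": float(p),
            "n": len(inter),
        }
    )
    out = pd.DataFrame(rows)
    out.attrs["n_dropped"] = n_dropped
    return out


def quartile_bins(delta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Assign prediction errors to four (near-)equally sized bins.

    Trials are stably sorted by (delta, original index) and split into
    four contiguous groups whose sizes differ by at most one, so ties
    never empty a bin. Returns (labels 1-4 in original order, the
    0.25/0.5/0.75 empirical quantiles used as bin boundaries).
    """
    delta = np.asarray(delta, float)
    if len(delta) < 4:
        raise ValueError("need at least 4 trials to form quartile bins")
    order = np.lexsort((np.arange(len(delta)), delta))
    labels = np.empty(len(delta), int)
    for b, chunk in enumerate(np.array_split(order, 4)):
        labels[chunk] = b + 1
    boundaries = np.quantile(delta, [0.25, 0.5, 0.75])
    return labels, boundaries


def _subsidiary_design(
    trials: pd.DataFrame,
    trace: pd.DataFrame,
    labels: pd.Series,
    prefix_values: list,
    tr: float,
    n_scans: int,
    hp_cutoff: float = 128.0,
) -> DesignMatrix:
    """Modulator-free design with per-category outcome/stimulus sticks.

    ``labels`` maps trace rows to a category (bin number or sign); one
    stick regressor per condition x valence x category is created at
    both stimulus and outcome onsets, neutral and missing regressors are
    kept as in the primary model.
    """
    kernel = canonical_hrf(tr)
    cols: dict[str, np.ndarray] = {}
    omitted: list[str] = []
    for cond in ("stress", "control"):
        for val in ("gain", "loss"):
            tsub = trace[
                (trace["condition"] == cond) & (trace["valence"] == val)
            ]
            for cat in prefix_values:
                sel = tsub[labels.loc[tsub.index] == cat]
                for kind, onset_col in (
                    ("stimbin", "stim_onset"),
                    ("outbin", "outcome_onset"),
                ):
                    name = f"{kind}:{cond}:{val}:{cat}"
                    if len(sel) == 0:
                        omitted.append(name)
                        continue
                    cols[name] = _sticks(
                        n_scans,
                        tr,
                        sel[onset_col].to_numpy(),
                        np.ones(len(sel)),
                    )
    present = trials[trials["choice"] != "missing"]
    for cond in ("stress", "control"):
        sub = present[
            (present["condition"] == cond) & (present["valence"] == "neutral")
        ]
        for kind, onset_col in (("stim", "stim_onset"), ("out", "outcome_onset")):
            name = f"{kind}:{cond}:neutral"
            if len(sub) == 0:
                omitted.append(name)
                continue
            cols[name] = _sticks(
                n_scans, tr, sub[onset_col].to_numpy(), np.ones(len(sub))
            )
    missed = trials[trials["choice"] == "missing"]
    if len(missed):
        cols["missing"] = _sticks(
            n_scans, tr, missed["stim_onset"].to_numpy(), np.ones(len(missed))
        )
    frame = pd.DataFrame(
        {name: _convolve(col, kernel) for name, col in cols.items()}
    )
    drift = highpass_dct(n_scans, tr, hp_cutoff)
    for k in range(drift.shape[1]):
        frame[f"drift:{k + 1}"] = drift[:, k]
    frame["const"] = 1.0
    return DesignMatrix(frame=frame, tr=tr, omitted=omitted)


def _extract_outbin(
    run_fits: dict[int, GLMFit], cats: list, participant
) -> pd.DataFrame:
    rows = []
    for cond, val in CELLS:
        for cat in cats:
            name = f"outbin:{cond}:{val}:{cat}"
            betas, variances = [], []
            for fit in run_fits.values():
                if name in fit.beta.index:
                    betas.append(fit.beta[name])
                    variances.append(fit.beta_var[name])
            if betas:
                w = 1.0 / np.asarray(variances)
                est = float(np.sum(w * np.asarray(betas)) / np.sum(w))
            else:
                est = np.nan
            rows.append(
                {
                    "participant": participant,
                    "condition": cond,
                    "valence": val,
                    "category": cat,
                    "estimate": est,
                }
            )
    return pd.DataFrame(rows)


def subsidiary_bins(
    trials: pd.DataFrame,
    trace: pd.DataFrame,
    bold: dict[int, np.ndarray],
    tr: float,
    participant=0,
    hp_cutoff: float = 128.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quartile-bin subsidiary model for one participant.

    Prediction errors are binned into quartiles within condition x
    valence (pooling runs); a modulator-free GLM with one outcome (and
    stimulus) regressor per bin is fitted per run with AR(1)
    prewhitening, and the outcome estimates are inverse-variance averaged
    over runs. Returns (per-bin estimates, bin boundaries per cell).
    """
    labels = pd.Series(index=trace.index, dtype=int)
    brows = []
    for cond, val in CELLS:
        sel = trace[(trace["condition"] == cond) & (trace["valence"] == val)]
        if len(sel) < 4:
            raise ValueError(f"fewer than 4 monetary trials in {cond}/{val}")
        lab, bounds = quartile_bins(sel["delta"].to_numpy())
        labels.loc[sel.index] = lab
        degenerate = bool(np.ptp(sel["delta"].to_numpy()) == 0)
        brows.append(
            {
                "participant": participant,
                "condition": cond,
                "valence": val,
                "q25": bounds[0],
                "q50": bounds[1],
                "q75": bounds[2],
                "degenerate": degenerate,
            }
        )
    cats = [1, 2, 3, 4]
    run_fits = {}
    for run, y in bold.items():
        rt = trials[trials["run"] == run]
        rtrace = trace[trace["run"] == run]
        design = _subsidiary_design(
            rt, rtrace, labels, cats, tr, len(y), hp_cutoff
        )
        run_fits[run] = fit_ar1_glm(y, design)
    estimates = _extract_outbin(run_fits, cats, participant)
    estimates = estimates.rename(columns={"category": "bin"})
    return estimates, pd.DataFrame(brows)


def boundary_comparison(boundaries: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests of quartile-bin boundaries, stress vs control.

    One test per valence x boundary across participants. Degenerate
    inputs (zero-variance differences) are flagged with NaN statistics.
    """
    rows = []
    for val in ("gain", "loss"):
        for q in ("q25", "q50", "q75"):
            wide = boundaries[boundaries["valence"] == val].pivot(
                index="participant", columns="condition", values=q
            )
            diff = (wide["stress"] - wide["control"]).to_numpy()
            if len(diff) < 2 or np.allclose(diff.std(ddof=1), 0):
                t = p = np.nan
                flag = True
            else:
                t, p = stats.ttest_1samp(diff, 0.0)
                t, p, flag = float(t), float(p), False
            rows.append(
                {
                    "valence": val,
                    "boundary": q,
                    "mean_diff": float(np.mean(diff)),
                    "t": t,
                    "p": p,
                    "degenerate": flag,
                }
            )
    return pd.DataFrame(rows)


def subsidiary_sign(
    trials: pd.DataFrame,
    trace: pd.DataFrame,
    bold: dict[int, np.ndarray],
    tr: float,
    participant=0,
    hp_cutoff: float = 128.0,
) -> pd.DataFrame:
    """Sign-split subsidiary model for one participant.

    Prediction errors are labelled positive when delta >= 0 and negative
    otherwise; a modulator-free GLM with one outcome (and stimulus)
    regressor per condition x valence x sign is fitted per run and
    outcome estimates averaged over runs (inverse-variance). Cells with
    no trials of one sign are returned as NaN.
    """
    labels = pd.Series(
        np.where(trace["delta"].to_numpy() >= 0, "pos", "neg"),
        index=trace.index,
    )
    cats = ["neg", "pos"]
    run_fits = {}
    for run, y in bold.items():
        rt = trials[trials["run"] == run]
        rtrace = trace[trace["run"] == run]
        design = _subsidiary_design(
            rt, rtrace, labels, cats, tr, len(y), hp_cutoff
        )
        run_fits[run] = fit_ar1_glm(y, design)
    estimates = _extract_outbin(run_fits, cats, participant)
    return estimates.rename(columns={"category": "pe_sign"})


def sign_split_anova(estimates: pd.DataFrame) -> dict:
    """Group-level analysis of the sign-split estimates.

    Returns the condition x prediction-error-sign repeated-measures ANOVA
    (on estimates averaged over trial valence), the three-way
    condition x sign x valence contrast, and per-valence x sign paired
    t-tests (stress - control) with Cohen's d = mean(diff) / sd(diff).
    Participants with any missing cell are excluded (listed in
    ``dropped``).
    """
    wide = estimates.pivot_table(
        index="participant",
        columns=["condition", "valence", "pe_sign"],
        values="estimate",
    )
    complete = wide.dropna()
    dropped = sorted(set(wide.index) - set(complete.index))
    if len(complete) < 3:
        raise ValueError("need >= 3 participants with all sign cells")
    long = (
        complete.stack(["condition", "valence", "pe_sign"], future_stack=True)
        .rename("estimate")
        .reset_index()
    )
    avg = (
        long.groupby(["participant", "condition", "pe_sign"])["estimate"]
        .mean()
        .reset_index()
    )
    aov = rm_anova_2x2(
        avg, "estimate", ["condition", "pe_sign"], "participant"
    )
    # three-way contrast: does the condition x sign difference differ by valence
    def cell(c, v, s):
        return complete[(c, v, s)]

    d3 = (
        (cell("stress", "gain", "pos") - cell("stress", "gain", "neg"))
        - (cell("control", "gain", "pos") - cell("control", "gain", "neg"))
    ) - (
        (cell("stress", "loss", "pos") - cell("stress", "loss", "neg"))
        - (cell("control", "loss", "pos") - cell("control", "loss", "neg"))
    )
    t3, p3 = stats.ttest_1samp(d3.to_numpy(), 0.0)
    rows = []
    for val in ("gain", "loss"):
        for sign in ("pos", "neg"):
            diff = (
                cell("stress", val, sign) - cell("control", val, sign)
            ).to_numpy()
            sd = diff.std(ddof=1)
            if np.allclose(sd, 0):
                t = p = d = np.nan
                flag = True
            else:
                t, p = stats.ttest_1samp(diff, 0.0)
                d = float(diff.mean() / sd)
                t, p, flag = float(t), float(p), False
            rows.append(
                {
                    "valence": val,
                    "pe_sign": sign,
                    "mean_diff": float(diff.mean()),
                    "t": t,
                    "p": p,
                    "cohens_d": d,
                    "degenerate": flag,
                }
            )
    return {
        "anova": aov,
        "three_way": {"t": float(t3), "p": float(p3)},
        "paired": pd.DataFrame(rows),
        "dropped": dropped,
        "n": len(complete),
    }


def responsivity_correlation(
    slopes: pd.DataFrame, delta_stress: pd.Series
) -> dict:
    """Spearman correlation between the gain-stress delta-modulation slope
    and self-reported stress responsivity (Delta stress rating).

    Returns rho, p, n and a ``constant_input`` flag (rho undefined when
    either variable has no rank variation). Requires n >= 4 pairs.
    """
    cell = slopes[
        (slopes["condition"] == "stress") & (slopes["valence"] == "gain")
    ].set_index("participant")["slope"]
    common = cell.index.intersection(delta_stress.index)
    x = cell.loc[common].to_numpy(float)
    y = delta_stress.loc[common].to_numpy(float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 4:
        raise ValueError("need at least 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return {"rho": np.nan, "p": np.nan, "n": len(x), "constant_input": True}
    res = stats.spearmanr(x, y)
    return {
        "rho": float(res.statistic),
        "p": float(res.pvalue),
        "n": len(x),
        "constant_input": False,
    }
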