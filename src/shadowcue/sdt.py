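"""Signal-detection analysis of trial logs.

Congruent trials are treated as signal trials; a "hit" is a congruent
response on a congruent trial and a "false alarm" a congruent response on an
incongruent trial, so a lax criterion (negative c) means a disposition
toward reporting "congruent".  Sensitivity and bias follow the equal-
variance closed forms d' = Phi^-1(p_hit) - Phi^-1(p_fa) and
c = -[Phi^-1(p_hit) + Phi^-1(p_fa)] / 2; their projection onto the negative
diagonal is the diagonal shift d' - c.  Hit/false-alarm proportions of 0 or
1 are corrected by 1/(2N) before the inverse-normal transform.  Invalid
responses are excluded from every analysis.

The primary effect measure is the differential sensitivity
DeltaSensitivity = d'(image-driven insertions) - d'(object-driven
insertions), tracked over block time with a sliding window (2 min default)
and summarized by early/late half-block splits.  Configuration contrasts
use paired Wilcoxon signed-rank tests on per-observer diagonal shifts with
a 3x Bonferroni correction, alongside an optional two-way repeated-measures
ANOVA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .session import TrialRecord

MIN_TRIALS_DEFAULT = 10


@dataclass
class SDTSummary:
    n_signal: int
    n_noise: int
    p_hit: float
    p_fa: float
    dprime: float
    criterion: float

    @property
    def diagonal_shift(self) -> float:
        return self.dprime - self.criterion


@dataclass
class TimeCourse:
    centers: np.ndarray  # seconds
    delta_sensitivity: np.ndarray  # across-observer mean per center
    sem: np.ndarray  # across-observer SEM (NaN where uncomputable)
    n_valid: np.ndarray  # observers contributing per center
    window: float
    step: float


def sdt_metrics(n_hit: int, n_miss: int, n_fa: int, n_cr: int) -> SDTSummary:
    """d', criterion and diagonal shift from response counts.

    Proportions of exactly 0 or 1 are replaced by 1/(2N) resp. 1 - 1/(2N)
    before the inverse-normal transform.
    """
    if min(n_hit, n_miss, n_fa, n_cr) < 0:
        raise ValueError("counts must be nonnegative")
    n_signal = n_hit + n_miss
    n_noise = n_fa + n_cr
    if n_signal == 0 or n_noise == 0:
        raise ValueError("both signal and noise trials are required")
    p_hit = _corrected_proportion(n_hit, n_signal)
    p_fa = _corrected_proportion(n_fa, n_noise)
    z_hit = sps.norm.ppf(p_hit)
    z_fa = sps.norm.ppf(p_fa)
    return SDTSummary(
        n_signal=n_signal,
        n_noise=n_noise,
        p_hit=p_hit,
        p_fa=p_fa,
        dprime=z_hit - z_fa,
        criterion=-(z_hit + z_fa) / 2.0,
    )


def _corrected_proportion(k: int, n: int) -> float:
    p = k / n
    if p == 0.0:
        return 1.0 / (2 * n)
    if p == 1.0:
        return 1.0 - 1.0 / (2 * n)
    return p


def _records_frame(trials: Sequence[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return pd.DataFrame([vars(t) for t in trials])


def _valid(df: pd.DataFrame) -> pd.DataFrame:
    return df[df["response"] != "invalid"]


def sdt_from_frame(df: pd.DataFrame) -> SDTSummary:
    """SDT summary of a (valid-trial) frame with congruent/response columns."""
    hit = int(((df["congruent"]) & (df["response"] == "congruent")).sum())
    miss = int(((df["congruent"]) & (df["response"] == "incongruent")).sum())
    fa = int(((~df["congruent"]) & (df["response"] == "congruent")).sum())
    cr = int(((~df["congruent"]) & (df["response"] == "incongruent")).sum())
    return sdt_metrics(hit, miss, fa, cr)


def differential_sensitivity(
    trials: Sequence[TrialRecord] | pd.DataFrame, min_trials: int = MIN_TRIALS_DEFAULT
) -> float:
    """d'(image-driven) - d'(object-driven) over valid trials.

    Returns NaN (an insufficient-data marker, not an exception) when either
    insertion type has fewer than ``min_trials`` valid trials or lacks
    signal/noise trials.
    """
    df = _valid(_records_frame(trials))
    out = {}
    for itype in ("image_driven", "object_driven"):
        sub = df[df["insertion_type"] == itype]
        if len(sub) < min_trials:
            return float("nan")
        try:
            out[itype] = sdt_from_frame(sub).dprime
        except ValueError:
            return float("nan")
    return out["image_driven"] - out["object_driven"]


def sliding_timecourse(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    window: float = 120.0,
    step: float = 10.0,
    min_trials: int = MIN_TRIALS_DEFAULT,
    block_duration: float = 300.0,
) -> TimeCourse:
    """Across-observer DeltaSensitivity time course.

    Per center, trials with t_probe inside the centered window are pooled
    across blocks within each observer, DeltaSensitivity is computed per
    observer, then averaged across observers; SEM is across observers.
    Centers with no computable observer value carry NaN (the analysis
    flags them rather than raising).
    """
    df = _valid(_records_frame(trials))
    centers = np.arange(window / 2.0, block_duration - window / 2.0 + 1e-9, step)
    if centers.size == 0:
        centers = np.array([block_duration / 2.0])
    means, sems, counts = [], [], []
    observers = sorted(df["observer_id"].unique())
    for c in centers:
        lo, hi = c - window / 2.0, c + window / 2.0
        vals = []
        for obs in observers:
            sub = df[(df["observer_id"] == obs) & (df["t_probe"] >= lo) & (df["t_probe"] <= hi)]
            v = differential_sensitivity(sub, min_trials=min_trials)
            if not math.isnan(v):
                vals.append(v)
        counts.append(len(vals))
        if vals:
            means.append(float(np.mean(vals)))
            sems.append(float(np.std(vals, ddof=1) / np.sqrt(len(vals))) if len(vals) > 1 else float("nan"))
        else:
            means.append(float("nan"))
            sems.append(float("nan"))
    return TimeCourse(
        centers=centers,
        delta_sensitivity=np.array(means),
        sem=np.array(sems),
        n_valid=np.array(counts),
        window=window,
        step=step,
    )


def split_half_summary(
    trials: Sequence[TrialRecord] | pd.DataFrame,
    split_time: float = 150.0,
    min_trials: int = MIN_TRIALS_DEFAULT,
) -> pd.DataFrame:
    """Per-observer early/late DeltaSensitivity with across-observer 95% CIs.

    The split sits at the block midpoint (2.5 min of a 5-min block).
    Returns a tidy frame with one row per observer x half, plus the
    across-observer mean and t-based 95% confidence interval attached as
    frame attrs ``ci`` (dict half -> (lo, hi)).
    """
    df = _valid(_records_frame(trials))
    rows = []
    for obs in sorted(df["observer_id"].unique()):
        sub = df[df["observer_id"] == obs]
        for half, mask in (
            ("early", sub["t_probe"] < split_time),
            ("late", sub["t_probe"] >= split_time),
        ):
            rows.append(
                {
                    "observer_id": obs,
                    "half": half,
                    "delta_sensitivity": differential_sensitivity(sub[mask], min_trials),
                }
            )
    out = pd.DataFrame(rows)
    ci = {}
    for half in ("early", "late"):
        vals = out.loc[out["half"] == half, "delta_sensitivity"].dropna().to_numpy()
        if vals.size > 1:
            m = vals.mean()
            h = sps.t.ppf(0.975, vals.size - 1) * vals.std(ddof=1) / np.sqrt(vals.size)
            ci[half] = (m - h, m + h)
        else:
            ci[half] = (float("nan"), float("nan"))
    out.attrs["ci"] = ci
    return out


def per_observer_shifts(trials: Sequence[TrialRecord] | pd.DataFrame) -> pd.DataFrame:
    """Per observer x shadow configuration x insertion type diagonal shifts."""
    df = _valid(_records_frame(trials))
    rows = []
    for (obs, mode, itype), sub in df.groupby(
        ["observer_id", "shadow_mode", "insertion_type"]
    ):
        try:
            s = sdt_from_frame(sub)
        except ValueError:
            continue
        rows.append(
            {
                "observer_id": obs,
                "shadow_mode": mode,
                "insertion_type": itype,
                "dprime": s.dprime,
                "criterion": s.criterion,
                "diagonal_shift": s.diagonal_shift,
            }
        )
    return pd.DataFrame(rows)


def config_comparison_stats(
    shifts: pd.DataFrame,
    value: str = "diagonal_shift",
    n_correction: int = 3,
    run_anova: bool = True,
) -> dict:
    """Paired Wilcoxon tests (image vs object) per shadow configuration.

    ``shifts`` is the output of :func:`per_observer_shifts`.  P-values are
    Bonferroni-multiplied by ``n_correction`` and capped at 1.  An optional
    two-way repeated-measures ANOVA (shadow mode x insertion type) is
    reported alongside when every observer contributes every cell.
    """
    report: dict = {"wilcoxon": {}, "anova": None}
    for mode, sub in shifts.groupby("shadow_mode"):
        wide = sub.pivot(index="observer_id", columns="insertion_type", values=value).dropna()
        if len(wide) < 5:
            raise ValueError(f"fewer than 5 paired observers for {mode}; test ill-posed")
        img = wide["image_driven"].to_numpy()
        obj = wide["object_driven"].to_numpy()
        if np.allclose(img, obj):
            stat, p = float("nan"), 1.0
        else:
            stat, p = sps.wilcoxon(img, obj)
        report["wilcoxon"][mode] = {
            "statistic": float(stat),
            "p_raw": float(p),
            "p_corrected": float(min(p * n_correction, 1.0)),
            "n": int(len(wide)),
            "median_difference": float(np.median(img - obj)),
        }
    if run_anova:
        try:
            from statsmodels.stats.anova import AnovaRM

            res = AnovaRM(
                shifts,
                depvar=value,
                subject="observer_id",
                within=["shadow_mode", "insertion_type"],
            ).fit()
            tbl = res.anova_table
            report["anova"] = {
                idx: {"F": float(r["F Value"]), "p": float(r["Pr > F"])}
                for idx, r in tbl.iterrows()
            }
        except Exception:
            report["anova"] = None
    return report
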