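"""Group-level statistics on readiness-potential amplitudes.

The dependent measure is the signed area under the averaged Cz waveform
(AUC, µV·ms) over a premovement window; more negative means a stronger
RP.  Analyses: one-way repeated-measures ANOVA with the within-subject
factor TrialType, Holm-corrected pairwise paired contrasts, a
pressed/press-free contrast within condition, and an F5−F6 frontal
lateralization index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as sps

from .game_engine import CONDITIONS
from .erp_pipeline import ParticipantSummary

__all__ = [
    "AnovaResult",
    "ContrastResult",
    "compute_auc",
    "build_auc_table",
    "anova_trialtype",
    "pairwise_contrast",
    "pairwise_contrasts",
    "press_factor_test",
    "lateralization_index",
]


@dataclass
class ContrastResult:
    pair: tuple[str, str]
    mean_diff: float  # mean(a) - mean(b)
    t: float
    p: float
    z: float
    p_holm: Optional[float] = None


@dataclass
class AnovaResult:
    factor: str
    F: float
    p: float
    df_num: float
    df_den: float
    contrasts: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# AUC
# ---------------------------------------------------------------------------

def compute_auc(waveform: np.ndarray, times_ms: np.ndarray,
                window_ms: tuple[float, float] = (-2000.0, 0.0)) -> float:
    """Signed trapezoidal integral of a waveform over a window, in µV·ms."""
    t = np.asarray(times_ms, dtype=float)
    w = np.asarray(waveform, dtype=float)
    lo, hi = window_ms
    if lo < t[0] or hi > t[-1] or lo >= hi:
        raise ValueError(f"window {window_ms} outside waveform extent "
                         f"[{t[0]}, {t[-1]}]")
    mask = (t >= lo) & (t <= hi)
    return float(np.trapezoid(w[mask], t[mask]))


def build_auc_table(summaries: list[ParticipantSummary],
                    lock: str = "press",
                    window_ms: tuple[float, float] = (-2000.0, 0.0),
                    channel: str = "Cz") -> pd.DataFrame:
    """AUC table: one row per (participant, condition[, pressed flag]).

    For the press lock, rows carry flag "pooled".  For the trial-end lock
    a row is produced for each of pooled / pressed / press_free whenever
    the participant has an average for that cell.
    """
    rows = []
    for s in summaries:
        ci = s.channel_index(channel)
        if lock == "press":
            for cond in CONDITIONS:
                if cond in s.avg_press:
                    auc = compute_auc(s.avg_press[cond][ci], s.times_press_ms,
                                      window_ms)
                    rows.append((s.participant, cond, lock, "pooled", auc))
        else:
            for (cond, flag), avg in sorted(s.avg_end.items()):
                auc = compute_auc(avg[ci], s.times_end_ms, window_ms)
                rows.append((s.participant, cond, lock, flag, auc))
    return pd.DataFrame(rows, columns=["participant", "condition", "lock",
                                       "pressed", "auc"])


# ---------------------------------------------------------------------------
# ANOVA and contrasts
# ---------------------------------------------------------------------------

def _check_balanced(table: pd.DataFrame, value_col: str = "auc") -> pd.DataFrame:
    counts = table.groupby(["participant", "condition"]).size()
    bad = counts[counts != 1]
    if len(bad):
        cell = bad.index[0]
        raise ValueError(f"table is not one row per cell: {cell} has "
                         f"{bad.iloc[0]} rows")
    wide = table.pivot(index="participant", columns="condition", values=value_col)
    if wide.isna().any().any():
        missing = wide.isna().stack()
        cell = missing[missing].index[0]
        raise ValueError(f"missing cell {cell}")
    return wide


def anova_trialtype(table: pd.DataFrame, flag: str = "pooled") -> AnovaResult:
    """One-way repeated-measures ANOVA of AUC across the three trial types.

    ``table`` is a long AUC table as produced by :func:`build_auc_table`;
    rows are filtered to the given pressed flag.  Delegates to
    statsmodels' AnovaRM; a fully degenerate table (all values identical)
    returns F=0, p=1.
    """
    sub = table[table["pressed"] == flag][["participant", "condition", "auc"]]
    if sub["condition"].nunique() < 2:
        raise ValueError("need at least two conditions")
    if sub["participant"].nunique() < 2:
        raise ValueError("need at least two participants")
    wide = _check_balanced(sub)
    k = wide.shape[1]
    n = wide.shape[0]
    if np.allclose(wide.to_numpy(), wide.to_numpy().flat[0]):
        return AnovaResult("TrialType", 0.0, 1.0, k - 1, (k - 1) * (n - 1))

    from statsmodels.stats.anova import AnovaRM

    res = AnovaRM(sub, depvar="auc", subject="participant",
                  within=["condition"]).fit()
    row = res.anova_table.iloc[0]
    return AnovaResult("TrialType", float(row["F Value"]),
                       float(row["Pr > F"]), float(row["Num DF"]),
                       float(row["Den DF"]))


def _paired_contrast(a: np.ndarray, b: np.ndarray,
                     pair: tuple[str, str]) -> ContrastResult:
    d = np.asarray(a, dtype=float) - np.asarray(b, dtype=float)
    if np.allclose(d, 0.0):
        return ContrastResult(pair, 0.0, 0.0, 1.0, 0.0)
    t, p = sps.ttest_rel(a, b)
    z = float(np.sign(t) * sps.norm.isf(max(p, 1e-300) / 2.0))
    return ContrastResult(pair, float(d.mean()), float(t), float(p), z)


def pairwise_contrast(table: pd.DataFrame, cond_a: str, cond_b: str,
                      flag: str = "pooled") -> ContrastResult:
    """Paired t-test on participant-wise AUC differences between two
    conditions (two-sided), with a z-value derived from the p-value."""
    sub = table[table["pressed"] == flag]
    wide = _check_balanced(sub[sub["condition"].isin([cond_a, cond_b])])
    for c in (cond_a, cond_b):
        if c not in wide.columns:
            raise ValueError(f"condition {c!r} absent from table")
    return _paired_contrast(wide[cond_a].to_numpy(), wide[cond_b].to_numpy(),
                            (cond_a, cond_b))


def pairwise_contrasts(table: pd.DataFrame,
                       flag: str = "pooled") -> list[ContrastResult]:
    """All three pairwise contrasts with Holm-corrected p-values."""
    pairs = [("easy", "medium"), ("easy", "hard"), ("medium", "hard")]
    results = [pairwise_contrast(table, a, b, flag) for a, b in pairs]
    order = np.argsort([r.p for r in results])
    m = len(results)
    prev = 0.0
    for rank, idx in enumerate(order):
        adj = min(1.0, (m - rank) * results[idx].p)
        prev = max(prev, adj)
        results[idx].p_holm = prev
    return results


def press_factor_test(table: pd.DataFrame, condition: str) -> ContrastResult:
    """Paired contrast of pressed vs press-free trial-end-locked AUC
    within one condition (the IsPressed factor)."""
    sub = table[(table["condition"] == condition)
                & (table["pressed"].isin(["pressed", "press_free"]))]
    wide = sub.pivot(index="participant", columns="pressed", values="auc")
    for level in ("pressed", "press_free"):
        if level not in wide.columns:
            raise ValueError(f"flag level {level!r} absent for {condition!r}")
    wide = wide.dropna()
    if len(wide) < 2:
        raise ValueError("need >= 2 participants with both flag levels")
    return _paired_contrast(wide["pressed"].to_numpy(),
                            wide["press_free"].to_numpy(),
                            ("pressed", "press_free"))


# ---------------------------------------------------------------------------
# Lateralization
# ---------------------------------------------------------------------------

def lateralization_index(summary: ParticipantSummary,
                         window_ms: tuple[float, float] = (-400.0, -300.0),
                         lock: str = "press",
                         ) -> dict[str, tuple[float, float, float]]:
    """Mean F5 and F6 amplitude in a premovement window, per condition.

    Returns ``{condition: (f5_mean_uV, f6_mean_uV, f5_minus_f6)}``.
    """
    for ch in ("F5", "F6"):
        if ch not in summary.channels:
            raise ValueError(f"channel {ch} missing from montage")
    i5, i6 = summary.channel_index("F5"), summary.channel_index("F6")
    times = summary.times_press_ms if lock == "press" else summary.times_end_ms
    lo, hi = window_ms
    mask = (times >= lo) & (times <= hi)
    if not mask.any():
        raise ValueError(f"window {window_ms} contains no samples")
    out = {}
    avgs = summary.avg_press if lock == "press" else {
        c: summary.avg_end[(c, "pooled")]
        for (c, f) in summary.avg_end if f == "pooled"
    }
    for cond, avg in avgs.items():
        f5 = float(avg[i5, mask].mean())
        f6 = float(avg[i6, mask].mean())
        out[cond] = (f5, f6, f5 - f6)
    return out
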