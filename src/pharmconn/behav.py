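"""Subjective and cardiovascular drug-effect analysis.

Covers mean arterial pressure, the two-factor (drug x time) fully
within-subject repeated-measures ANOVA, peak change scores (PCS: maximum
post-dose deviation from the same-session pre-dose baseline), and
Bonferroni-corrected Pearson correlations between per-subject connectivity
change scores and subjective-response change scores.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "AnovaResult",
    "PeakChangeScores",
    "mean_arterial_pressure",
    "rm_anova",
    "peak_change_score",
    "fc_behavior_correlation",
    "plot_timecourse",
]


@dataclass
class AnovaResult:
    """F, df pair and p for the drug, time and drug x time effects."""

    effects: dict[str, dict]

    def __getitem__(self, key: str) -> dict:
        return self.effects[key]


@dataclass
class PeakChangeScores:
    """Per-subject PCS per condition and the drug-minus-placebo delta."""

    pcs: pd.DataFrame          # columns: subject, condition, pcs
    delta: pd.Series           # index: subject; PCS_drug - PCS_placebo


def mean_arterial_pressure(sbp, dbp):
    """MAP = (systolic + 2 x diastolic) / 3, in mmHg.

    The diastolic phase occupies roughly two thirds of the cardiac cycle,
    hence the 2:1 weighting.  Requires sbp > dbp > 0.
    """
    sbp = np.asarray(sbp, float)
    dbp = np.asarray(dbp, float)
    if np.any(dbp <= 0) or np.any(sbp <= dbp):
        raise ValueError("require sbp > dbp > 0")
    out = (sbp + 2.0 * dbp) / 3.0
    return float(out) if out.ndim == 0 else out


def _complete_cube(table: pd.DataFrame, measure: str) -> tuple[np.ndarray, list, list]:
    """Pivot the long table to a (subjects, 2 conditions, timepoints) cube,
    rejecting missing cells and keeping complete cases only."""
    df = table[table["measure"] == measure]
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    conditions = ["placebo", "drug"]
    times = sorted(df["time_min"].unique())
    piv = df.pivot_table(index="subject", columns=["condition", "time_min"],
                         values="value", aggfunc="mean")
    full_cols = [(c, t) for c in conditions for t in times]
    missing = [c for c in full_cols if c not in piv.columns]
    if missing:
        raise ValueError(f"missing cells for measure {measure!r}: {missing}")
    piv = piv[full_cols]
    complete = piv.dropna()
    dropped = sorted(set(piv.index) - set(complete.index))
    if dropped:
        logger.info("measure %s: dropping incomplete subjects %s",
                    measure, dropped)
    if complete.shape[0] < 3:
        raise ValueError("need at least 3 complete subjects")
    cube = complete.to_numpy().reshape(len(complete), len(conditions),
                                       len(times))
    return cube, list(complete.index), times


def rm_anova(table: pd.DataFrame, measure: str) -> AnovaResult:
    """Two-way fully within-subject ANOVA by sum-of-squares decomposition.

    Factors: drug (2 levels) and time (timepoints), both within subject;
    each effect is tested against its own subject-interaction error term
    with uncorrected degrees of freedom.
    """
    cube, subjects, times = _complete_cube(table, measure)
    n, a, b = cube.shape
    grand = cube.mean()
    m_s = cube.mean(axis=(1, 2))          # subject means
    m_a = cube.mean(axis=(0, 2))          # drug means
    m_b = cube.mean(axis=(0, 1))          # time means
    m_sa = cube.mean(axis=2)              # (n, a)
    m_sb = cube.mean(axis=1)              # (n, b)
    m_ab = cube.mean(axis=0)              # (a, b)

    ss_a = n * b * ((m_a - grand) ** 2).sum()
    ss_b = n * a * ((m_b - grand) ** 2).sum()
    ss_ab = n * ((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2).sum()
    ss_as = b * ((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2).sum()
    ss_bs = a * ((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2).sum()
    resid = (cube - m_sa[:, :, None] - m_sb[:, None, :] - m_ab[None, :, :]
             + m_s[:, None, None] + m_a[None, :, None] + m_b[None, None, :]
             - grand)
    ss_abs = (resid ** 2).sum()

    def effect(ss, df_num, ss_err, df_err):
        ms = ss / df_num
        ms_err = ss_err / df_err
        F = ms / ms_err if ms_err > 0 else 0.0
        p = float(stats.f.sf(F, df_num, df_err)) if ms_err > 0 else 1.0
        return {"F": float(F), "df": (df_num, df_err), "p": p,
                "ss": float(ss), "ss_error": float(ss_err)}

    effects = {
        "drug": effect(ss_a, a - 1, ss_as, (a - 1) * (n - 1)),
        "time": effect(ss_b, b - 1, ss_bs, (b - 1) * (n - 1)),
        "drug x time": effect(ss_ab, (a - 1) * (b - 1), ss_abs,
                              (a - 1) * (b - 1) * (n - 1)),
    }
    return AnovaResult(effects=effects)


def peak_change_score(table: pd.DataFrame, measure: str) -> PeakChangeScores:
    """PCS per session: max over post-dose timepoints of (value - baseline).

    The baseline is the single pre-dose (negative time) measurement of the
    same session; delta = PCS(drug) - PCS(placebo) per subject.
    """
    df = table[table["measure"] == measure]
    if df.empty:
        raise ValueError(f"no rows for measure {measure!r}")
    rows = []
    for (subject, condition), grp in df.groupby(["subject", "condition"]):
        base = grp[grp["time_min"] < 0]
        post = grp[grp["time_min"] > 0]
        if base.empty:
            raise ValueError(f"missing baseline for {subject}/{condition}")
        if post.empty:
            raise ValueError(f"no post-dose values for {subject}/{condition}")
        baseline = base["value"].mean()
        rows.append({"subject": subject, "condition": condition,
                     "pcs": float((post["value"] - baseline).max())})
    pcs = pd.DataFrame(rows)
    wide = pcs.pivot(index="subject", columns="condition", values="pcs")
    delta = (wide["drug"] - wide["placebo"]).dropna()
    delta.name = "pcs_delta"
    return PeakChangeScores(pcs=pcs, delta=delta)


def fc_behavior_correlation(fc_deltas: dict[str, np.ndarray],
                            pcs_deltas: np.ndarray,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Pearson correlation of each connectivity change score with the
    subjective-response change score, Bonferroni-corrected over pairings.
    """
    y = np.asarray(pcs_deltas, float)
    m = len(fc_deltas)
    if m == 0:
        return pd.DataFrame(columns=["fc_measure", "r", "p_raw",
                                     "p_bonferroni", "significant"])
    rows = []
    for name, x in fc_deltas.items():
        x = np.asarray(x, float)
        if len(x) != len(y):
            raise ValueError(f"{name}: length mismatch with pcs_deltas")
        if len(x) < 4:
            raise ValueError(f"{name}: need at least 4 paired observations")
        if x.std() == 0 or y.std() == 0:
            rows.append({"fc_measure": name, "r": np.nan, "p_raw": np.nan,
                         "p_bonferroni": np.nan, "significant": False})
            continue
        r, p = stats.pearsonr(x, y)
        p_bonf = min(1.0, p * m)
        rows.append({"fc_measure": name, "r": float(r), "p_raw": float(p),
                     "p_bonferroni": float(p_bonf),
                     "significant": bool(p_bonf < alpha)})
    return pd.DataFrame(rows)


def plot_timecourse(table: pd.DataFrame, measure: str, ax=None):
    """Mean +/- SEM per timepoint per condition (the standard pharmacology
    time-course figure layout)."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    df = table[table["measure"] == measure]
    for condition, marker in (("placebo", "o"), ("drug", "s")):
        sub = df[df["condition"] == condition]
        g = sub.groupby("time_min")["value"]
        mean = g.mean()
        sem = g.std(ddof=1) / np.sqrt(g.count())
        ax.errorbar(mean.index, mean.values, yerr=sem.values, marker=marker,
                    capsize=3, label=condition)
    ax.set_xlabel("time after dosing (min)")
    ax.set_ylabel(measure)
    ax.legend()
    return ax
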