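"""Statistical inference on activation metrics.

Three layers, mirroring the study design:

* individual subject — one-tailed paired t-test of the VisStim vs noStim
  activation metric across the voxels of an anatomical ROI (the occipital
  pole), separately for the SLon and SLoff streams;
* group — the same paired test on ROI-averaged metrics across subjects,
  repeated over every subject subset of a given size to gauge robustness;
* parcel-wise two-way ANOVA — fixed-effects 2x2 model with factors SL
  (preparation on/off) and Stim (noStim/VisStim) plus their interaction,
  subjects as replicates, restricted to parcels covered by every subject.

All p-values are uncorrected (the study reports uncorrected p < 0.05); a
Benjamini-Hochberg adjustment is available but off by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sst
import statsmodels.api as sm
from statsmodels.formula.api import ols
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "TTestResult",
    "SubsetResult",
    "paired_ttest_onetailed",
    "roi_individual_test",
    "group_subset_analysis",
    "parcelwise_anova",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    p: float
    df: int
    n: int
    direction: str = "a>b"


def paired_ttest_onetailed(a, b, alternative: str = "greater") -> TTestResult:
    """One-tailed paired t-test of ``a`` vs ``b``.

    ``t = mean(d) / (sd(d)/sqrt(n))`` with ``d = a - b`` and sample sd
    (divisor n-1); ``p`` is the upper tail of the t-distribution with n-1
    degrees of freedom for ``alternative='greater'`` (lower tail for
    ``'less'``).  Degenerate inputs: all-zero differences give t=0, p=0.5;
    zero-variance nonzero differences give p of 0 or 1 by sign (logged).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired test needs two equal-length 1-D arrays")
    n = a.size
    if n < 2:
        raise ValueError(f"need at least 2 pairs, got {n}")
    if alternative not in ("greater", "less"):
        raise ValueError("alternative must be 'greater' or 'less'")
    d = a - b
    mean = d.mean()
    sd = d.std(ddof=1)
    df = n - 1
    if sd == 0:
        if mean == 0:
            return TTestResult(t=0.0, p=0.5, df=df, n=n,
                               direction=f"a{'>' if alternative == 'greater' else '<'}b")
        logger.warning("paired_ttest_onetailed: zero-variance nonzero "
                       "differences (mean=%g)", mean)
        sign_win = (mean > 0) == (alternative == "greater")
        return TTestResult(t=math.copysign(math.inf, mean), p=0.0 if sign_win else 1.0,
                           df=df, n=n,
                           direction=f"a{'>' if alternative == 'greater' else '<'}b")
    t = mean / (sd / math.sqrt(n))
    p = sst.t.sf(t, df) if alternative == "greater" else sst.t.cdf(t, df)
    return TTestResult(t=float(t), p=float(p), df=df, n=n,
                       direction=f"a{'>' if alternative == 'greater' else '<'}b")


def roi_individual_test(maps: dict, atlas: np.ndarray, roi_label: int,
                        alternative: str = "greater") -> dict:
    """Individual activation test: pair the VisStim and noStim metric values
    voxel-by-voxel within the ROI, one test per stream.

    ``maps`` holds the four :class:`~resl_sirs.rfr.ActivationMap` objects
    keyed by ``(stream, condition)``.
    """
    atlas = np.asarray(atlas)
    roi = atlas == roi_label
    n_vox = int(roi.sum())
    if n_vox == 0:
        raise ValueError(f"ROI label {roi_label} selects no voxels")
    if n_vox < 2:
        raise ValueError(f"ROI label {roi_label} has {n_vox} voxel; "
                         "the paired test needs at least 2")
    out = {}
    for stream in ("SLon", "SLoff"):
        vis = maps[(stream, "VisStim")].values[roi]
        rest = maps[(stream, "noStim")].values[roi]
        out[stream] = paired_ttest_onetailed(vis, rest, alternative=alternative)
    return out


@dataclass
class SubsetResult:
    k: int
    n_combinations: int
    fraction_significant: float
    sorted_p: np.ndarray
    alpha: float


def group_subset_analysis(vis: np.ndarray, nostim: np.ndarray, k: int,
                          alpha: float = 0.05) -> SubsetResult:
    """Group robustness analysis over all C(n, k) subject subsets.

    ``vis`` and ``nostim`` are per-subject ROI-averaged metrics.  For each
    subset a one-tailed paired t-test (VisStim > noStim) is run across the
    selected subjects; the fraction of subsets with p < alpha and the sorted
    p-value list are returned.
    """
    vis = np.asarray(vis, dtype=float)
    nostim = np.asarray(nostim, dtype=float)
    n = vis.size
    if nostim.size != n:
        raise ValueError("vis and nostim must have equal length")
    if not 2 <= k <= n:
        raise ValueError(f"subset size k={k} must satisfy 2 <= k <= {n}")
    pvals = []
    for idx in combinations(range(n), k):
        sel = list(idx)
        pvals.append(paired_ttest_onetailed(vis[sel], nostim[sel]).p)
    pvals = np.sort(np.asarray(pvals))
    return SubsetResult(k=k, n_combinations=len(pvals),
                        fraction_significant=float(np.mean(pvals < alpha)),
                        sorted_p=pvals, alpha=alpha)


def parcelwise_anova(metrics: pd.DataFrame, value: str = "value",
                     adjust: str | None = None) -> tuple[pd.DataFrame, list]:
    """Fixed-effects 2x2 ANOVA per parcel: factors SL and Stim plus
    interaction, subjects as replicates.

    ``metrics`` is long-format with columns ``subject``, ``sl`` ("SLon" /
    "SLoff"), ``stim`` ("noStim" / "VisStim"), ``parcel`` and the metric
    column named by ``value``.  Parcels missing entirely for some subject
    are excluded (returned in the second element); a parcel with a partial
    cell structure for some subject raises.  ``adjust='bh'`` appends
    Benjamini-Hochberg adjusted p-values.
    """
    required = {"subject", "sl", "stim", "parcel", value}
    missing = required - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table is missing columns {sorted(missing)}")
    subjects = metrics["subject"].unique()
    n_sub = len(subjects)
    rows, excluded = [], []
    for parcel, grp in metrics.groupby("parcel"):
        cells = grp.groupby(["subject", "sl", "stim"]).size()
        if (cells != 1).any():
            bad = cells[cells != 1].index[0]
            raise ValueError(
                f"unbalanced input: parcel {parcel}, subject {bad[0]} has "
                f"{int(cells.max())} observations in cell {bad[1:]}")
        per_subject = grp.groupby("subject").size()
        if len(per_subject) < n_sub or (per_subject != 4).any():
            excluded.append(parcel)
            continue
        if np.ptp(grp[value].to_numpy()) == 0:
            # all observations identical: every sum of squares is zero
            rows.append({"parcel": parcel,
                         "F_sl": 0.0, "p_sl": 1.0,
                         "F_stim": 0.0, "p_stim": 1.0,
                         "F_interaction": 0.0, "p_interaction": 1.0,
                         "df_num": 1, "df_den": 4 * n_sub - 4})
            continue
        model = ols(f"{value} ~ C(sl) * C(stim)", data=grp).fit()
        table = sm.stats.anova_lm(model, typ=2)
        f_sl, p_sl = table.loc["C(sl)", ["F", "PR(>F)"]]
        f_st, p_st = table.loc["C(stim)", ["F", "PR(>F)"]]
        f_ix, p_ix = table.loc["C(sl):C(stim)", ["F", "PR(>F)"]]
        rows.append({
            "parcel": parcel,
            "F_sl": float(f_sl), "p_sl": float(p_sl),
            "F_stim": float(f_st), "p_stim": float(p_st),
            "F_interaction": float(f_ix), "p_interaction": float(p_ix),
            "df_num": 1, "df_den": int(table.loc["Residual", "df"]),
        })
    result = pd.DataFrame(rows)
    if adjust == "bh" and len(result):
        for term in ("sl", "stim", "interaction"):
            result[f"p_{term}_bh"] = multipletests(
                result[f"p_{term}"], method="fdr_bh")[1]
    return result, excluded
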