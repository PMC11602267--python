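"""Cohort-level analysis drivers shared by the CLI, the analysis scripts
and the acceptance checks."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ns import VARIANT_DEFAULT, ns_maps
from .rfr import rfr_maps
from .stats import (
    TTestResult,
    group_subset_analysis,
    paired_ttest_onetailed,
    parcelwise_anova,
    roi_individual_test,
)

__all__ = [
    "rfr_roi_table",
    "ns_roi_table",
    "individual_tests",
    "group_tests",
    "subset_table",
    "parcel_metric_table",
    "analyze_cohort",
]


def rfr_roi_table(datasets, cutoff: float = 0.1) -> pd.DataFrame:
    """ROI-averaged RFR metric per subject, stream and condition, plus the
    VisStim - noStim contrast."""
    rows = []
    for i, ds in enumerate(datasets):
        res = rfr_maps(ds, cutoff=cutoff)
        roi = ds.atlas == ds.roi_label
        for stream in ("SLon", "SLoff"):
            vis = float(res.maps[(stream, "VisStim")].values[roi].mean())
            rest = float(res.maps[(stream, "noStim")].values[roi].mean())
            rows.append({"subject": i, "stream": stream, "vis": vis,
                         "nostim": rest, "contrast": vis - rest,
                         "responder": bool(ds.truth.get("responder", False))})
    return pd.DataFrame(rows)


def ns_roi_table(datasets, apply_highpass: bool = True,
                 variant: str = VARIANT_DEFAULT) -> pd.DataFrame:
    """ROI-averaged NS std contrast per subject and condition."""
    rows = []
    for i, ds in enumerate(datasets):
        res = ns_maps(ds, apply_highpass=apply_highpass, variant=variant)
        roi = ds.atlas == ds.roi_label
        vis = float(res.maps["VisStim"].values[roi].mean())
        rest = float(res.maps["noStim"].values[roi].mean())
        rows.append({"subject": i, "vis": vis, "nostim": rest,
                     "contrast": vis - rest,
                     "responder": bool(ds.truth.get("responder", False))})
    return pd.DataFrame(rows)


def individual_tests(datasets, cutoff: float = 0.1,
                     alpha: float = 0.05) -> pd.DataFrame:
    """Per-subject occipital-pole test (voxel-paired, one-tailed) for both
    streams."""
    rows = []
    for i, ds in enumerate(datasets):
        res = rfr_maps(ds, cutoff=cutoff)
        tests = roi_individual_test(res.maps, ds.atlas, ds.roi_label)
        for stream, tt in tests.items():
            rows.append({"subject": i, "stream": stream, "t": tt.t, "p": tt.p,
                         "df": tt.df, "n_voxels": tt.n,
                         "significant": tt.p < alpha,
                         "responder": bool(ds.truth.get("responder", False))})
    return pd.DataFrame(rows)


def group_tests(roi_table: pd.DataFrame) -> dict:
    """Paired group test (VisStim > noStim across subjects) per stream."""
    out = {}
    for stream, grp in roi_table.groupby("stream"):
        out[stream] = paired_ttest_onetailed(grp["vis"].to_numpy(),
                                             grp["nostim"].to_numpy())
    return out


def subset_table(roi_table: pd.DataFrame, subset_sizes,
                 alpha: float = 0.05) -> pd.DataFrame:
    """Fraction of significant subject subsets per stream and subset size."""
    rows = []
    for stream, grp in roi_table.groupby("stream"):
        vis = grp["vis"].to_numpy()
        rest = grp["nostim"].to_numpy()
        for k in subset_sizes:
            res = group_subset_analysis(vis, rest, k, alpha=alpha)
            rows.append({"stream": stream, "k": k,
                         "n_combinations": res.n_combinations,
                         "fraction_significant": res.fraction_significant,
                         "min_p": float(res.sorted_p[0])})
    return pd.DataFrame(rows)


def parcel_metric_table(datasets, cutoff: float = 0.1) -> pd.DataFrame:
    """Long-format parcel means of the RFR metric (subject x stream x
    condition x parcel), the input of the parcel-wise ANOVA."""
    rows = []
    for i, ds in enumerate(datasets):
        res = rfr_maps(ds, cutoff=cutoff)
        labels = np.unique(ds.atlas)
        labels = labels[labels > 0]
        for (stream, cond), amap in res.maps.items():
            for lab in labels:
                sel = ds.atlas == lab
                rows.append({"subject": i, "sl": stream, "stim": cond,
                             "parcel": int(lab),
                             "value": float(amap.values[sel].mean())})
    return pd.DataFrame(rows)


def analyze_cohort(datasets, cutoff: float = 0.1, alpha: float = 0.05,
                   subset_sizes=(12, 11, 10, 9, 8, 7)) -> dict:
    """Full statistical battery of the study on one cohort."""
    roi = rfr_roi_table(datasets, cutoff=cutoff)
    indiv = individual_tests(datasets, cutoff=cutoff, alpha=alpha)
    groups = group_tests(roi)
    n = roi["subject"].nunique()
    sizes = [k for k in subset_sizes if 2 <= k <= n]
    subsets = subset_table(roi, sizes, alpha=alpha)
    anova, excluded = parcelwise_anova(parcel_metric_table(datasets,
                                                           cutoff=cutoff))
    return {"roi_table": roi, "individual": indiv, "group": groups,
            "subsets": subsets, "anova": anova, "anova_excluded": excluded}
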