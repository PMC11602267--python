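"""Normalized subtraction (NS) of paired SLon/SLoff time courses.

Because prepared and non-prepared volumes alternate within one run, any
confound slower than TR_eff (hemodynamics, drift, spurious peaks from the
shared EPI readout) is encoded nearly identically in both streams and
cancels in their difference.  The difference is normalised by the first
post-dummy baselines SLon_0 and SLoff_0; the temporal standard deviation of
the NS series is the activation contrast used here, while the legacy
max-z contrast of the original (epilepsy-oriented) formulation is kept for
reference.

The printed source formula for NS_t is typographically ambiguous; the
default variant reads it literally as ``(SLon_t - SLoff_t)/(SLon_0 * SLoff_0)``
and two plausible alternates are selectable.  All outputs record the
variant used.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

from .rfr import ActivationMap, highpass_filter

if TYPE_CHECKING:  # pragma: no cover
    from .synth import SubjectDataset

logger = logging.getLogger(__name__)

#: NS_t = (SLon_t - SLoff_t) / (SLon_0 * SLoff_0)  — literal reading
VARIANT_DEFAULT = "difference-over-product"
#: NS_t = SLon_t/SLon_0 - SLoff_t/SLoff_0
VARIANT_RATIO_DIFFERENCE = "ratio-difference"
#: NS_t = (SLon_t - SLoff_t) / sqrt(SLon_0 * SLoff_0)
VARIANT_SQRT_PRODUCT = "sqrt-product"

VARIANTS = (VARIANT_DEFAULT, VARIANT_RATIO_DIFFERENCE, VARIANT_SQRT_PRODUCT)

__all__ = [
    "NSSeries",
    "NsResult",
    "ns_series",
    "ns_contrast",
    "ns_zscore_contrast",
    "ns_maps",
    "VARIANT_DEFAULT",
    "VARIANT_RATIO_DIFFERENCE",
    "VARIANT_SQRT_PRODUCT",
    "VARIANTS",
]


@dataclass
class NSSeries:
    """NS time course(s) with the baselines and formula variant that
    produced them.  Time is the last axis."""

    ns: np.ndarray
    baseline_on: np.ndarray
    baseline_off: np.ndarray
    variant: str = VARIANT_DEFAULT


def ns_series(slon: np.ndarray, sloff: np.ndarray, baseline_index: int = 0,
              variant: str = VARIANT_DEFAULT, baseline_k: int = 1) -> NSSeries:
    """Combine paired SLon/SLoff series into the NS time course.

    ``baseline_index`` selects the first post-dummy time point;
    ``baseline_k > 1`` averages that many consecutive points instead (a
    robustness option, off by default).
    """
    slon = np.asarray(slon, dtype=float)
    sloff = np.asarray(sloff, dtype=float)
    if slon.shape != sloff.shape:
        raise ValueError(
            f"SLon shape {slon.shape} != SLoff shape {sloff.shape}")
    if variant not in VARIANTS:
        raise ValueError(f"unknown NS variant {variant!r}; choose from {VARIANTS}")
    nt = slon.shape[-1]
    if not 0 <= baseline_index < nt:
        raise ValueError(f"baseline_index {baseline_index} out of range")
    if baseline_k < 1 or baseline_index + baseline_k > nt:
        raise ValueError("baseline window exceeds series length")
    sel = slice(baseline_index, baseline_index + baseline_k)
    on0 = slon[..., sel].mean(axis=-1)
    off0 = sloff[..., sel].mean(axis=-1)
    bad = (on0 == 0) | (off0 == 0)
    if np.any(bad):
        idx = np.argwhere(np.atleast_1d(bad))[0]
        raise ZeroDivisionError(
            f"zero NS baseline at voxel index {tuple(int(i) for i in idx)}")
    diff = slon - sloff
    if variant == VARIANT_DEFAULT:
        ns = diff / (on0 * off0)[..., None]
    elif variant == VARIANT_RATIO_DIFFERENCE:
        ns = slon / on0[..., None] - sloff / off0[..., None]
    else:  # sqrt-product
        ns = diff / np.sqrt(on0 * off0)[..., None]
    return NSSeries(ns=ns, baseline_on=on0, baseline_off=off0, variant=variant)


def ns_contrast(nss: NSSeries) -> np.ndarray:
    """Temporal standard deviation of the NS series (population convention,
    divisor N).  Scalar for 1-D input."""
    ns = nss.ns
    if ns.shape[-1] < 2:
        raise ValueError("ns_contrast needs at least 2 time points")
    out = ns.std(axis=-1, ddof=0)
    return float(out) if out.ndim == 0 else out


def ns_zscore_contrast(nss: NSSeries) -> float:
    """Legacy contrast of the original NS formulation: ``max(z) - mean(z)``
    with z the absolute z-score of the NS series.  Sensitive to short
    sporadic saturation events; a zero-variance series returns 0 by
    convention (logged)."""
    ns = np.asarray(nss.ns, dtype=float)
    if ns.ndim != 1:
        raise ValueError("ns_zscore_contrast expects a single 1-D series")
    sd = ns.std(ddof=0)
    if sd == 0:
        logger.warning("ns_zscore_contrast: zero-variance series, returning 0")
        return 0.0
    z = np.abs((ns - ns.mean()) / sd)
    return float(z.max() - z.mean())


@dataclass
class NsResult:
    """Per-condition NS std maps and their VisStim - noStim contrast."""

    maps: dict
    contrast: np.ndarray
    variant: str
    highpass: bool


def ns_maps(dataset: "SubjectDataset", apply_highpass: bool = True,
            cutoff: float = 0.1, variant: str = VARIANT_DEFAULT) -> NsResult:
    """NS pipeline per condition: voxel-wise NS series, optional 0.1-Hz
    high-pass (residual drift survives the subtraction when the two streams
    drift unequally), then the std contrast."""
    fs = 1.0 / dataset.params.tr_eff
    maps = {}
    for cond in ("noStim", "VisStim"):
        for stream in ("SLon", "SLoff"):
            if (stream, cond) not in dataset.streams:
                raise KeyError(f"dataset is missing stream {stream}/{cond}")
        nss = ns_series(dataset.streams[("SLon", cond)],
                        dataset.streams[("SLoff", cond)], variant=variant)
        ns = nss.ns
        if apply_highpass:
            ns = highpass_filter(ns, cutoff=cutoff, fs=fs)
        values = NSSeries(ns=ns, baseline_on=nss.baseline_on,
                          baseline_off=nss.baseline_off, variant=variant)
        maps[cond] = ActivationMap(values=ns_contrast(values), stream="NS",
                                   condition=cond, metric_name="ns_std",
                                   voxel_size=dataset.voxel_size,
                                   meta={"variant": variant,
                                         "highpass": apply_highpass,
                                         "cutoff_hz": cutoff})
    contrast = maps["VisStim"].values - maps["noStim"].values
    return NsResult(maps=maps, contrast=contrast, variant=variant,
                    highpass=apply_highpass)
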