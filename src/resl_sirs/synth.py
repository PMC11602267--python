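"""Synthetic subject and cohort generator.

Emulates the statistical structure of an alternating SLon/SLoff visual
stimulation experiment so that every downstream stage is testable without
scanner data:

* a voxel grid (default 64x64x6, voxel 3.6x3.6x4 mm) with a constant
  baseline signal level;
* an "occipital pole" region that, in responder subjects, carries the Bloch
  simulator's phase-sampled rotary-saturation series in the SLon x VisStim
  stream (per-voxel amplitude jitter emulates spatially varying neuronal
  currents);
* a BOLD-like hemodynamic confound — a gamma-convolved boxcar — added
  bit-identically to the SLon and SLoff streams of the VisStim condition
  inside the active region, since both streams share the EPI readout;
* slow drift (linear plus 0.005-0.03 Hz cosines, partly voxel-dependent),
  white thermal noise, sparse spurious peaks common to both streams, and a
  static chemical-shift-like offset band with zero temporal variance;
* a synthetic parcellation whose designated occipital-pole parcel coincides
  with the active region.

All randomness flows through explicit integer seeds; a cohort derives
per-subject seeds deterministically from its master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .bloch import TissueParams, simulate_run
from .protocol import NeuronalField, ProtocolParams

__all__ = [
    "PhantomSpec",
    "CohortSpec",
    "SubjectDataset",
    "default_roi",
    "generate_atlas",
    "generate_subject",
    "generate_cohort",
    "bold_response",
]

STREAMS = ("SLon", "SLoff")
CONDITIONS = ("noStim", "VisStim")


def default_roi(grid: tuple) -> np.ndarray:
    """Posterior block standing in for the occipital pole: the rear quarter
    of x, the middle third of y, all slices."""
    nx, ny, nz = grid
    mask = np.zeros(grid, dtype=bool)
    mask[int(0.70 * nx):int(0.95 * nx), int(0.35 * ny):int(0.65 * ny), :] = True
    return mask


@dataclass
class PhantomSpec:
    """Geometry and nuisance amplitudes of one synthetic subject.

    Fractions are relative to the baseline signal level.  The defaults place
    the rotary-saturation effect (a few 1e-4 fractional at 4 nT) in the
    detectable regime of the study: thermal noise 1e-4, BOLD 1e-2, drift
    3e-3, two spurious peaks per run on average.
    """

    grid: tuple = (64, 64, 6)
    voxel_size: tuple = (3.6, 3.6, 4.0)
    baseline: float = 1000.0
    active_roi: np.ndarray | None = None
    n_parcels: int = 74
    bold_amplitude: float = 0.01
    bold_onset_tau: float = 6.0        # s, gamma-kernel time-to-peak scale
    drift_amplitude: float = 0.003
    noise_sigma: float = 1e-4
    spike_rate: float = 2.0
    static_ghost: bool = True
    amp_jitter: tuple = (0.5, 1.5)     # per-voxel neuronal amplitude range
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < 1 for g in self.grid):
            raise ValueError(f"grid must be positive, got {self.grid}")
        for name in ("baseline", "bold_amplitude", "drift_amplitude",
                     "noise_sigma", "spike_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.active_roi is not None:
            self.active_roi = np.asarray(self.active_roi, dtype=bool)
            if self.active_roi.shape != tuple(self.grid):
                raise ValueError(
                    f"active_roi shape {self.active_roi.shape} does not match "
                    f"grid {self.grid}")
        if self.n_parcels < 2:
            raise ValueError("need at least 2 parcels")

    def roi(self) -> np.ndarray:
        return (self.active_roi if self.active_roi is not None
                else default_roi(self.grid))


@dataclass(frozen=True)
class CohortSpec:
    """Cohort layout: 12 subjects of whom a third respond, as in the
    emulated study."""

    n_subjects: int = 12
    responder_fraction: float = 1.0 / 3.0
    baseline_jitter: float = 0.05      # lognormal sigma of per-subject scale
    bn_jitter: float = 0.1             # lognormal sigma of responder b_n
    master_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.responder_fraction <= 1.0:
            raise ValueError("responder_fraction must lie in [0, 1]")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    @property
    def n_responders(self) -> int:
        return int(round(self.n_subjects * self.responder_fraction))


@dataclass
class SubjectDataset:
    """Four 4-D streams (SLon/SLoff x noStim/VisStim), atlas labels on the
    same grid, and a record of every injected effect."""

    streams: dict
    atlas: np.ndarray
    roi_label: int
    params: ProtocolParams
    voxel_size: tuple
    truth: dict

    def stream(self, stream: str, condition: str) -> np.ndarray:
        return self.streams[(stream, condition)]

    @property
    def grid(self) -> tuple:
        return self.atlas.shape


def generate_atlas(grid: tuple, n_parcels: int, roi_mask: np.ndarray,
                   seed: int = 0) -> np.ndarray:
    """Synthetic parcellation: label 1 is the designated occipital-pole
    parcel and equals ``roi_mask``; the remaining voxels are split into
    parcels 2..n_parcels by nearest-seed-point (Voronoi) assignment.
    Deterministic for a given seed."""
    if n_parcels < 2:
        raise ValueError("need at least 2 parcels")
    roi_mask = np.asarray(roi_mask, dtype=bool)
    if roi_mask.shape != tuple(grid):
        raise ValueError(f"roi mask shape {roi_mask.shape} exceeds or does "
                         f"not match grid {tuple(grid)}")
    if not roi_mask.any():
        raise ValueError("roi mask is empty")
    rng = np.random.default_rng(seed)
    labels = np.zeros(grid, dtype=np.int32)
    labels[roi_mask] = 1
    rest = np.argwhere(~roi_mask)
    n_rest_parcels = n_parcels - 1
    if len(rest) < n_rest_parcels:
        raise ValueError(f"grid too small for {n_parcels} parcels")
    seed_idx = rng.choice(len(rest), size=n_rest_parcels, replace=False)
    seeds = rest[seed_idx].astype(float)
    # nearest seed point; ties broken by lowest parcel id (argmin order)
    d2 = ((rest[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = d2.argmin(axis=1) + 2
    labels[tuple(rest.T)] = assign
    return labels


def bold_response(n_reps: int, tr_eff: float, tau: float = 6.0) -> np.ndarray:
    """Hemodynamic confound shape: a whole-run boxcar convolved with a
    gamma kernel (shape 3, scale tau/3 so the kernel peaks near ``tau`` s),
    normalised to unit plateau."""
    t = np.arange(n_reps) * tr_eff
    shape_k, scale = 3.0, tau / 3.0
    kernel = (t ** (shape_k - 1)) * np.exp(-t / scale)
    if kernel.sum() == 0:
        return np.ones(n_reps)
    kernel /= kernel.sum()
    h = np.convolve(np.ones(n_reps), kernel)[:n_reps]
    return h / h.max()


def _drift(rng: np.random.Generator, n_reps: int, tr_eff: float) -> np.ndarray:
    """Standardised slow nuisance: linear trend plus three cosines in the
    0.005-0.03 Hz band, unit peak amplitude."""
    t = np.arange(n_reps) * tr_eff
    d = rng.uniform(-1, 1) * np.linspace(-0.5, 0.5, n_reps)
    for _ in range(3):
        f = rng.uniform(0.005, 0.03)
        d = d + rng.uniform(0.2, 0.5) * np.cos(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    peak = np.abs(d).max()
    return d / peak if peak > 0 else d


def generate_subject(
    spec: PhantomSpec,
    params: ProtocolParams,
    responder: bool = True,
    seed: int | Sequence[int] = 0,
    field: NeuronalField | None = None,
    tissue: TissueParams | None = None,
    atlas: np.ndarray | None = None,
) -> SubjectDataset:
    """Generate the four 4-D streams of one subject.

    A responder's SLon x VisStim stream carries the simulator's
    rotary-saturation modulation inside the active ROI, scaled per voxel by
    a uniform amplitude-jitter factor.  Every nuisance term respects the
    study's symmetry: BOLD and spurious peaks are identical in SLon and
    SLoff of the same condition, drift and thermal noise are drawn per
    stream.
    """
    rng = np.random.default_rng(seed)
    grid = tuple(spec.grid)
    n_reps = params.n_reps
    roi = spec.roi()
    tissue = tissue or TissueParams()
    field = field or NeuronalField()
    if atlas is None:
        atlas = generate_atlas(grid, spec.n_parcels, roi,
                               seed=int(rng.integers(2 ** 31)))
    b = spec.baseline

    streams = {s: np.full(grid + (n_reps,), b) for s in
               ((st, c) for st in STREAMS for c in CONDITIONS)}

    # rotary-saturation modulation (responders, VisStim, SLon, inside ROI)
    amp_map = np.zeros(grid)
    ratio = np.ones(n_reps)
    if responder and field.b_n > 0:
        phi0 = rng.uniform(0, 2 * np.pi)
        run = simulate_run(params, field.replace(phi0=phi0), tissue=tissue)
        amp_map[roi] = rng.uniform(*spec.amp_jitter, size=int(roi.sum()))
        rel = run.slon / run.sloff - 1.0            # (n_reps, n_slices)
        sat = amp_map[..., None] * rel.T[None, None, :, :]
        streams[("SLon", "VisStim")] = b * (1.0 + sat)
        ratio = rel[:, 0] + 1.0

    # BOLD-like confound: identical in SLon and SLoff under VisStim
    h = bold_response(n_reps, params.tr_eff, tau=spec.bold_onset_tau)
    bold_term = np.zeros(grid + (n_reps,))
    bold_term[roi] = spec.bold_amplitude * b * h
    streams[("SLon", "VisStim")] = streams[("SLon", "VisStim")] + bold_term
    streams[("SLoff", "VisStim")] = streams[("SLoff", "VisStim")] + bold_term

    # slow drift: per-stream shape, mildly voxel-dependent gain
    drift_info = {}
    if spec.drift_amplitude > 0:
        gain = 1.0 + 0.3 * rng.standard_normal(grid)
        for key in streams:
            d = _drift(rng, n_reps, params.tr_eff)
            streams[key] = streams[key] + (spec.drift_amplitude * b) * gain[..., None] * d
            drift_info[key] = d

    # spurious peaks: common to SLon and SLoff of a condition
    spikes = {}
    for cond in CONDITIONS:
        n_spk = rng.poisson(spec.spike_rate)
        reps = np.sort(rng.choice(n_reps, size=min(n_spk, n_reps), replace=False))
        amps = rng.uniform(3.0, 6.0, size=len(reps)) * spec.noise_sigma * b
        spike_t = np.zeros(n_reps)
        spike_t[reps] = amps
        for stream in STREAMS:
            streams[(stream, cond)] = streams[(stream, cond)] + spike_t
        spikes[cond] = {"repetitions": reps.tolist(), "amplitudes": amps.tolist()}

    # thermal noise, independent everywhere
    if spec.noise_sigma > 0:
        for key in streams:
            streams[key] = streams[key] + rng.normal(
                0.0, spec.noise_sigma * b, size=grid + (n_reps,))

    # static chemical-shift-like offset band: constant in time
    if spec.static_ghost:
        ghost = np.zeros(grid)
        ghost[:, : max(1, grid[1] // 16), :] = 0.05 * b
        for key in streams:
            streams[key] = streams[key] + ghost[..., None]

    truth = {
        "responder": bool(responder),
        "b_n": field.b_n if responder else 0.0,
        "f_n": field.f_n,
        "amp_map": amp_map,
        "saturation_ratio_slice1": ratio,
        "bold_amplitude": spec.bold_amplitude,
        "bold_shape": h,
        "drift_amplitude": spec.drift_amplitude,
        "spikes": spikes,
        "noise_sigma": spec.noise_sigma,
        "seed": seed,
    }
    return SubjectDataset(streams=streams, atlas=atlas, roi_label=1,
                          params=params, voxel_size=tuple(spec.voxel_size),
                          truth=truth)


def generate_cohort(
    cspec: CohortSpec,
    spec: PhantomSpec,
    params: ProtocolParams,
    field: NeuronalField | None = None,
    tissue: TissueParams | None = None,
) -> list:
    """Generate a cohort with a deterministic per-subject seed chain.

    The first ``round(n_subjects * responder_fraction)`` subjects respond;
    responder field amplitudes are jittered lognormally (sigma ``bn_jitter``)
    and per-subject baselines lognormally (sigma ``baseline_jitter``).  All
    subjects share one atlas.
    """
    field = field or NeuronalField()
    master = cspec.master_seed
    atlas = generate_atlas(tuple(spec.grid), spec.n_parcels, spec.roi(),
                           seed=int(np.random.default_rng(
                               [master, 0xA71A5]).integers(2 ** 31)))
    subjects = []
    n_resp = cspec.n_responders
    for i in range(cspec.n_subjects):
        rng_i = np.random.default_rng([master, i, 0x5EED])
        responder = i < n_resp
        sub_field = field
        if responder and cspec.bn_jitter > 0:
            sub_field = field.replace(
                b_n=field.b_n * rng_i.lognormal(0.0, cspec.bn_jitter))
        sub_spec_baseline = spec.baseline
        if cspec.baseline_jitter > 0:
            sub_spec_baseline = spec.baseline * rng_i.lognormal(
                0.0, cspec.baseline_jitter)
        sub_spec = PhantomSpec(
            grid=spec.grid, voxel_size=spec.voxel_size,
            baseline=sub_spec_baseline, active_roi=spec.active_roi,
            n_parcels=spec.n_parcels, bold_amplitude=spec.bold_amplitude,
            bold_onset_tau=spec.bold_onset_tau,
            drift_amplitude=spec.drift_amplitude,
            noise_sigma=spec.noise_sigma, spike_rate=spec.spike_rate,
            static_ghost=spec.static_ghost, amp_jitter=spec.amp_jitter,
            seed=spec.seed)
        subjects.append(generate_subject(
            sub_spec, params, responder=responder,
            seed=[master, i, 0xDA7A], field=sub_field, tissue=tissue,
            atlas=atlas))
    return subjects
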