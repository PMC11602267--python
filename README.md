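# resl-sirs

Analysis pipeline for spin-lock MRI detection of neuronal currents via
stimulus-induced rotary saturation (SIRS), with a rotary-echo spin-lock
(RESL) preparation.

## The problem

Oscillating neuronal magnetic fields (nanotesla scale) can in principle be
detected directly with MRI: during a spin-lock pulse of amplitude B_SL the
magnetization precesses about the lock axis at f_SL = (γ/2π)·B_SL, and a
z-field oscillating at f_SL acts like a resonant excitation in the rotating
frame, saturating the locked magnetization. When prepared (SLon) and
non-prepared (SLoff) volumes alternate, each preparation samples the
neuronal oscillation at a different initial phase φ_N, so the saturation —
and hence the prepared signal — fluctuates from repetition to repetition.
**Temporal variance of the SLon stream, above that of the SLoff stream and
higher under stimulation than at rest, is the activation signature.**

This package provides everything needed to study that design end to end
without scanner data:

- `resl_sirs.protocol` — sequence timing (TR, TR_eff, TSL, θ = π·f_SL·TSL)
  and the phase-sampling schedule;
- `resl_sirs.bloch` — Bloch simulation of the RESL composite
  (90° – SL(+) – SL(−) – 90° – spoil) under an oscillating z-field, the
  multi-slice T1-decay readout model, and saturation-vs-frequency sweeps;
- `resl_sirs.synth` — synthetic subjects/cohorts: rotary-saturation series
  in an occipital ROI for responders, a BOLD-like confound encoded
  identically in SLon and SLoff, drift, thermal noise, spurious peaks, a
  static chemical-shift-like band, and a synthetic parcellation;
- `resl_sirs.rfr` — the regression-filtering-rectification (RFR) pipeline:
  parcel-mean regression, zero-phase 0.1 Hz Butterworth high-pass,
  rectification; metric = temporal mean of the rectified signal;
- `resl_sirs.ns` — normalized subtraction (NS) of paired SLon/SLoff series
  with the std-based contrast and the legacy max-z contrast;
- `resl_sirs.stats` — one-tailed paired t-tests (voxel-paired individual
  tests, subject-paired group tests over all C(n,k) subsets) and the
  parcel-wise two-way ANOVA (factors SL × Stim plus interaction);
- `resl_sirs.io` / `resl_sirs.cli` — NIfTI/CSV/YAML I/O and a `resl-sirs`
  command with `simulate`, `cohort`, `rfr`, `ns`, `stats`, `report`
  subcommands.

The numbered scripts under `analysis/` run the emulated study start to
finish and write their tables to `results/`.

## Worked example

Simulate one run at the study protocol (TR = 139.55 ms, six slices,
TR_eff = 1674.6 ms, TSL = 70 ms, f_SL = 8 Hz) with a 4 nT neuronal field
at 8 Hz, then inspect the variance contrast:

```python
import numpy as np
from resl_sirs import ProtocolParams, NeuronalField, simulate_run

params = ProtocolParams()           # the study protocol
field = NeuronalField(b_n=4e-9, f_n=8.0)
run = simulate_run(params, field)
print(run.slon[:, 0].var(), run.sloff[:, 0].var())
```

prints `3.9e-08` versus `1.2e-32` (slice 1): phase sampling converts the
rotary saturation into temporal variance of the prepared stream only, the
non-prepared stream being noise-free constant here.

Running the emulated cohort study (`python analysis/03_rfr_analysis.py`
and `python analysis/05_group_stats.py`, master seed 1) prints, among
others:

```
6/12 subjects significant in SLon (responders: [0, 1, 2, 3], detected: [0, 1, 2, 3, 8, 11])
group tests (VisStim > noStim):
stream        t        p  df
 SLoff 0.069702 0.472923  11
  SLon 2.182389 0.025570  11
```

The four injected responders are detected (plus two borderline false
positives at this seed), the SLon group test rejects at p ≈ 0.026 while
the SLoff group test — which sees the hemodynamic confound but not the
rotary saturation — does not, and the fraction of significant subject
subsets decays from 92% (k = 11) to 24% (k = 7).

A noteworthy physics result from `analysis/01_simulate_preparation.py`:
at the study settings the lock completes only f_SL·TSL = 0.56 cycles, so
the phase-averaged saturation-vs-frequency curve has no peak at f_SL —
quasi-static fields saturate more (the preparation is known to remain
sensitive to static B0 offsets). A clean rotary-resonance peak at f_SL
appears once the lock runs several cycles (e.g. f_SL = 80 Hz). Frequency
selectivity at the study settings therefore rests on phase sampling, not
on a narrow saturation resonance. See `docs/methods.md`.

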