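# Methods

## Physical model

### RESL preparation

The rotary-echo spin-lock composite is modeled as four ideal RF events on
a magnetization vector **M** (units of M0):

1. hard 90° pulse about +x (right-handed; +z → −y),
2. spin-lock of duration TSL/2 with the lock field along −y,
3. spin-lock of duration TSL/2 with the lock field along +y (opposite RF
   phase — the rotary echo),
4. hard 90° pulse about +x by −90° (−y → +z), followed by a spoiler that
   zeroes the transverse components.

During each lock half the magnetization precesses about the instantaneous
effective field, expressed in frequency units: the lock term f_SL along
±y plus the neuronal term (γ/2π)·b_n·sin(2π f_n t + φ) along z, with
γ/2π = 42.577 MHz/T (¹H, fixed). The integrator composes exact Rodrigues
rotations over piecewise-constant steps of dt = 0.1 ms (mid-step field
evaluation); at the default parameters it agrees with a 1 µs integration
to ~1e-7 and with an independent adaptive ODE solution to 4+ significant
digits. Rotations preserve |**M**| to 1e-12 per step, so with relaxation
off the b_n = 0 composite is the identity on Mz to better than 1e-9
(rotary-echo refocusing), which the tests assert.

Relaxation during the ~70 ms preparation is off by default (the
saturation mechanism is then isolated); an optional per-axis decay
(T1ρ along the lock axis, T2 transverse, T1 recovery of Mz) can be
enabled. T1 always acts on the readout side, below.

### Multi-slice readout

Each slice k (1-based, acquired sequentially TR apart) samples

signal_k = sin(flip) · (Mz_ss + (Mz_prep − Mz_ss) · exp(−(k−1)·TR/T1)),

with Mz_ss = M0·(1 − exp(−TR_eff/T1)) the steady state of a slice excited
by 90° pulses every TR_eff (T1 = 1.3 s default, grey-matter-like at 3 T).
The prepared-minus-unprepared signal difference therefore decays as
exp(−(k−1)·TR/T1) across slices regardless of the steady-state
convention, and the tests check it against a step-by-step Mz recursion.
Two dummy volume pairs are simulated and discarded to realise the steady
state; SLoff volumes receive no RF by default (a "preparation with
B_SL = 0" variant is available).

### Sub-cycle lock: no saturation resonance peak at f_SL

At the study settings (f_SL = 8 Hz, TSL = 70 ms) the lock completes only
0.56 cycles. In this regime the counter-rotating component of the
oscillating z-field does not average out and the quasi-static pathway —
the same mechanism that makes the preparation sensitive to static B0
offsets — produces *more* phase-averaged saturation than the resonant
pathway. The saturation-vs-frequency curve consequently decreases
monotonically from DC through f_SL (its maximum still lies within 1/TSL
of f_SL, the linewidth being that broad). The textbook rotary-resonance
peak at f_SL, within a 1/(2·TSL) linewidth, appears once the lock runs
several cycles (verified at f_SL = 80 Hz, TSL = 70 ms and at f_SL = 40 Hz,
TSL = 0.5 s). Similarly, the single-half resonant deviation angle matches
the rotating-wave value (γ·b_n·t/2 ≈ 0.0187 rad at 35 ms, 4 nT) only
phase-averaged (within 8%); at a fixed phase it deviates by ~20%.
Practical consequence: at these settings the frequency selectivity of the
measurement comes from the *phase-sampling* mechanism (a field must
oscillate to produce repetition-to-repetition variance; a DC offset
saturates constantly and adds none), not from a narrow resonance.

## Synthetic data

The generator emulates the statistical structure the analysis assumes,
per subject on a grid (default 64×64×6 at 3.6×3.6×4 mm; the desk-scale
analyses use 16×16×3 with 3 slices and 90 repetitions):

- **Baseline**: spatially constant level (1000 a.u.), lognormally
  jittered (σ = 0.05) across subjects.
- **Rotary saturation** (responders, SLon×VisStim, active ROI only): the
  simulator's phase-sampled SLon/SLoff modulation ratio applied
  multiplicatively, scaled per voxel by a U(0.5, 1.5) amplitude factor
  (neuronal currents vary across voxels; a spatially uniform effect would
  be annihilated by parcel-mean regression). Responder field amplitudes
  are lognormally jittered around 4 nT.
- **BOLD-like confound**: whole-run boxcar convolved with a gamma kernel
  (shape 3, peak ≈ 6 s), fractional amplitude 0.01, added bit-identically
  to SLon and SLoff under VisStim inside the ROI — the two streams share
  the EPI readout, so a hemodynamic mean shift is common to both.
- **Drift**: linear trend plus three cosines in 0.005–0.03 Hz, fractional
  amplitude 0.003, drawn per stream with a mildly voxel-dependent gain —
  deliberately *not* identical across streams, so residual drift survives
  normalized subtraction (the observed false-positive mechanism) while
  the 0.1 Hz high-pass removes it.
- **Thermal noise**: white Gaussian, fraction 1e-4 of baseline.
- **Spurious peaks**: Poisson(2) repetitions per run, amplitude 3–6× the
  noise σ, added identically to both streams of a condition and uniformly
  in space. Being spatially uniform, they are removed exactly by
  parcel-mean regression in this synthetic setting (in real data they
  survive RFR; the NS-vs-RFR spike comparison is therefore tested on
  constructed series).
- **Chemical-shift stand-in**: a constant offset band with zero temporal
  variance.
- **Parcellation**: label 1 is the active ROI ("occipital pole"); the
  rest of the grid is split into n_parcels − 1 nearest-seed parcels
  (74 by default, mirroring a Destrieux-style atlas; 12 at desk scale).
  One atlas is shared across a cohort.

All randomness flows through explicit integer seeds; cohorts derive
per-subject seeds deterministically from the master seed, and the first
round(n·fraction) subjects respond (4 of 12 by default).

### Calibration

The study reports no noise or confound amplitudes, so these defaults were
chosen once to land the pipeline in the study's qualitative regime — a
group-level SLon rejection around p ≈ 0.02 with roughly a third of
subjects individually significant. Two numbers were set by a structural
Monte-Carlo of the group test: noise σ = 1e-4 (the ~2e-4-fractional
saturation variance at 4 nT must clear the rectified-noise floor at the
ROI-average level) and responder-amplitude jitter σ = 0.1 (the metric
scales as b_n², doubling any amplitude jitter; larger values push the
4-responders-in-12 group test below useful power, contrary to the regime
being emulated). With these settings the SLon group test rejects on
essentially every master seed (median p ≈ 0.025) while the SLoff test
rejects at its nominal 5%.

What passing tests do **not** show about real data: the generator has no
motion, no spatially structured (vascular/respiratory) noise, no
voxel-correlated BOLD heterogeneity, spatially uniform spikes, and an
atlas aligned with the true effect boundary — all of which make the real
problem harder than the synthetic one.

## Pipelines

**RFR** (per voxel, per stream/condition): (1) subtract the parcel-mean
time course (literal subtraction, not a fitted coefficient — a fitted
slope is out of scope); (2) zero-phase 4th-order Butterworth high-pass,
0.1 Hz cutoff at fs = 1/TR_eff, applied forward-backward (DC gain 0;
two-pass passband gain ≥ 0.95 above 1.5× cutoff; edges handled by
scipy's anti-symmetric reflection padding, which continues linear trends
smoothly); (3) subtract the temporal mean and take absolute values. The
activation metric is the temporal mean of the rectified series;
contrasts are VisStim − noStim, optionally normalized by the noStim map
where it exceeds 1e-6 of its median (masked elsewhere).

**NS** (per voxel, per condition): NS_t = (SLon_t − SLoff_t)/
(SLon_0·SLoff_0) with the baselines taken from the first post-dummy time
point. The printed source formula is typographically ambiguous, so this
literal reading is the default and two alternates are selectable
(SLon_t/SLon_0 − SLoff_t/SLoff_0, and division by √(SLon_0·SLoff_0));
every output records the variant. The contrast is the temporal standard
deviation of NS_t (population convention, divisor N, fixed); the legacy
epilepsy-oriented contrast max|z| − mean|z| is provided for reference and
returns 0 on zero-variance input by convention. An optional 0.1 Hz
high-pass (the same filter) is applied to NS_t before the std.

## Statistics

- Individual test: one-tailed paired t-test (VisStim > noStim), pairing
  the metric voxel-by-voxel within the anatomical ROI, per stream. The
  voxel-pairing reading was chosen over time-segment pairing. Note the
  caveat: voxels are treated as independent pairs; parcel-mean regression
  induces a weak negative dependence, measured empirically as a 4–5%
  type-I rate at nominal 5% on all-null data.
- Group/subset analysis: the same paired test on ROI-averaged metrics
  across subjects, enumerated over all C(n, k) subsets for k = n..7;
  reported as the fraction of subsets with p < 0.05 plus the sorted
  p-values. Subset tests share subjects and are strongly dependent.
- Parcel-wise ANOVA: fixed-effects 2×2 with interaction (statsmodels OLS,
  type-II table; equals the closed-form sums-of-squares decomposition to
  1e-10 on balanced data), subjects as replicates (error df = 4n − 4),
  restricted to parcels covered by all subjects; a repeated-measures
  treatment of subject is a known limitation, not modeled. All-constant
  parcels return F = 0 by convention. p-values are uncorrected
  (a Benjamini–Hochberg option exists, off by default).
- One-tailed direction is fixed as VisStim > noStim throughout
  (the variance-increase hypothesis).
- Degenerate paired inputs: all-zero differences give t = 0, p = 0.5;
  zero-variance nonzero differences give p ∈ {0, 1} by sign (logged).

## Problem sizes

The desk-scale condition used by the tests, the analysis scripts and the
acceptance script is a 16×16×3 grid, 3 slices, 90 repetitions, 12
parcels, 12 subjects with 4 responders — the full 64×64×6/180-repetition
protocol is supported by the same code paths and differs only in cost.
Robustness numbers use 20 master seeds (group detection) and 400
replicates (type-I rate).

## Known limitations

- No B0/B1 inhomogeneity maps, diffusion, motion or EPI ghosting physics;
  the chemical-shift artifact is a static offset band only.
- The simulator's SLoff stream is noise-free constant; all realism lives
  in the synthetic-data layer.
- The sub-cycle saturation curve (above) means resonance-sweep
  diagnostics at the study settings characterise a broadband response,
  not a peak.
- NIfTI affines are float32 (format limitation); values round-trip at
  float32 precision.
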