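#!/usr/bin/env python
"""Bloch-simulate the rotary-echo spin-lock preparation.

Writes to results/: the phase-sampled SLon/SLoff run table at the study
parameters, and two saturation-vs-frequency curves — one at the study's
sub-cycle lock settings (f_SL = 8 Hz, TSL = 70 ms), one in a multi-cycle
regime (f_SL = 80 Hz) where the classic rotary-resonance peak forms.

Finding: at the study settings the lock completes only 0.56 cycles, so the
phase-averaged saturation is largest for quasi-static fields and decreases
through 8 Hz; the selectivity of the preparation at these settings comes
from phase sampling (temporal variance), not from a narrow resonance.
"""

from pathlib import Path

import numpy as np

from resl_sirs.protocol import NeuronalField, ProtocolParams
from resl_sirs.bloch import resonance_curve, simulate_run

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    params = ProtocolParams()
    field = NeuronalField(b_n=4e-9, f_n=8.0)

    run = simulate_run(params.replace(n_reps=60), field)
    run.to_frame().to_csv(RESULTS / "run_table.csv", index=False)
    v_on = run.slon[:, 0].var()
    v_off = run.sloff[:, 0].var()
    print(f"slice-1 temporal variance: SLon {v_on:.3e}, SLoff {v_off:.3e}")

    sub = resonance_curve(params, 4e-9, np.linspace(0.0, 24.0, 49))
    sub.to_csv(RESULTS / "resonance_curve_subcycle.csv", index=False)
    print(f"sub-cycle curve peak: {sub.f_n[sub.saturation.idxmax()]:.1f} Hz "
          f"(lock at {params.f_sl} Hz, {params.f_sl * params.tsl:.2f} cycles)")

    multi_params = ProtocolParams(f_sl=80.0)
    multi = resonance_curve(multi_params, 4e-9, np.linspace(40.0, 120.0, 81))
    multi.to_csv(RESULTS / "resonance_curve_multicycle.csv", index=False)
    print(f"multi-cycle curve peak: "
          f"{multi.f_n[multi.saturation.idxmax()]:.1f} Hz "
          f"(lock at 80 Hz, {80 * multi_params.tsl:.1f} cycles)")


if __name__ == "__main__":
    main()
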