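#!/usr/bin/env python
"""Normalized-subtraction analysis with and without the post-subtraction
0.1 Hz high-pass.

Writes results/ns_comparison.csv (per-subject ROI-mean NS std contrast,
raw and filtered).  The raw NS output retains stream-specific drift and
can flag non-responders; the high-pass removes it, reproducing the
false-positive-suppression pattern of the study."""

from pathlib import Path

import pandas as pd

from resl_sirs.workflow import ns_roi_table

from cohort_common import make_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = make_cohort()
    raw = ns_roi_table(cohort, apply_highpass=False)
    filt = ns_roi_table(cohort, apply_highpass=True)
    df = raw.merge(filt, on=["subject", "responder"],
                   suffixes=("_raw", "_filtered"))
    df.to_csv(RESULTS / "ns_comparison.csv", index=False)
    print(df.to_string(index=False))
    drop = 1.0 - df.vis_filtered.mean() / df.vis_raw.mean()
    print(f"\nhigh-pass removes {100 * drop:.1f}% of the mean VisStim NS "
          "level (drift suppression)")


if __name__ == "__main__":
    main()
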