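"""Shared cohort definition for the numbered analysis scripts: a
desk-scale emulation of the study (12 subjects, 4 responders, 16x16x3
grid, 90 repetitions, 3 slices)."""

from resl_sirs.protocol import ProtocolParams
from resl_sirs.synth import CohortSpec, PhantomSpec, generate_cohort

MASTER_SEED = 1


def scaled_params() -> ProtocolParams:
    return ProtocolParams(n_slices=3, n_reps=90)


def scaled_spec() -> PhantomSpec:
    return PhantomSpec(grid=(16, 16, 3), n_parcels=12)


def make_cohort(master_seed: int = MASTER_SEED):
    return generate_cohort(CohortSpec(master_seed=master_seed),
                           scaled_spec(), scaled_params())
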