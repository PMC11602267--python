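"""Sequence timing and spin-lock amplitude/frequency relations.

The rotary-echo spin-lock (RESL) preparation locks the transverse
magnetization with an RF field of amplitude ``B_SL``.  The lock frequency
``f_SL = (gamma/2pi) * B_SL`` sets the rotary-resonance condition: an
oscillating z-field at ``f_SL`` saturates the locked magnetization.  Prepared
(SLon) and non-prepared (SLoff) volumes alternate, so each stream is sampled
every ``TR_eff``; successive preparations therefore catch the neuronal
oscillation at different initial phases, which converts saturation into
temporal variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

#: Proton gyromagnetic ratio over 2*pi, Hz per Tesla.
GAMMA_HZ_PER_T = 42.577e6

__all__ = [
    "GAMMA_HZ_PER_T",
    "ProtocolParams",
    "NeuronalField",
    "effective_tr",
    "sl_amplitude_for_frequency",
    "sl_frequency_for_amplitude",
    "rotation_angle",
    "phase_schedule",
    "run_duration",
    "load_protocol",
]


def effective_tr(tr_ms: float, n_slices: int, alternating: bool = True) -> float:
    """Effective repetition time between two prepared (or two non-prepared)
    acquisitions, in ms.

    With interleaved SLon/SLoff volumes a full cycle spans two volumes, hence
    ``TR_eff = 2 * n_slices * TR``; without interleaving it is one volume.
    """
    if tr_ms <= 0:
        raise ValueError(f"TR must be positive, got {tr_ms}")
    if n_slices < 1:
        raise ValueError(f"n_slices must be >= 1, got {n_slices}")
    factor = 2 if alternating else 1
    return factor * n_slices * tr_ms


def sl_amplitude_for_frequency(f_sl: float) -> float:
    """Spin-lock amplitude B_SL (Tesla) producing lock frequency ``f_sl`` (Hz),
    via ``f_SL = (gamma/2pi) B_SL`` for protons."""
    if f_sl < 0:
        raise ValueError(f"spin-lock frequency must be >= 0, got {f_sl}")
    return f_sl / GAMMA_HZ_PER_T


def sl_frequency_for_amplitude(b_sl: float) -> float:
    """Inverse of :func:`sl_amplitude_for_frequency`: Hz for a given Tesla."""
    if b_sl < 0:
        raise ValueError(f"spin-lock amplitude must be >= 0, got {b_sl}")
    return b_sl * GAMMA_HZ_PER_T


def rotation_angle(f_sl: float, tsl_s: float) -> float:
    """Rotation angle (rad) induced by one spin-lock half of duration
    ``tsl_s`` seconds: ``theta = pi * f_SL * TSL``."""
    if f_sl < 0:
        raise ValueError(f"spin-lock frequency must be >= 0, got {f_sl}")
    if tsl_s < 0:
        raise ValueError(f"spin-lock duration must be >= 0, got {tsl_s}")
    return math.pi * f_sl * tsl_s


def phase_schedule(
    f_n: float, tr_eff_s: float, phi0: float, n_reps: int
) -> np.ndarray:
    """Initial phase of the oscillating neuronal field at each prepared
    acquisition: ``phi_k = (phi0 + 2 pi f_n TR_eff k) mod 2 pi``.

    Because ``f_n * TR_eff`` is in general non-integer, the repetitions sample
    the oscillation at a rotating set of phases.
    """
    if n_reps < 1:
        raise ValueError(f"n_reps must be >= 1, got {n_reps}")
    k = np.arange(n_reps)
    return np.mod(phi0 + 2.0 * math.pi * f_n * tr_eff_s * k, 2.0 * math.pi)


@dataclass(frozen=True)
class ProtocolParams:
    """Acquisition parameters of an alternating SLon/SLoff run.

    Durations are stored in seconds internally; the ``*_ms`` constructor
    arguments of :meth:`from_ms` convert once at the interface.  Defaults are
    the study protocol: TR = 139.55 ms, 6 slices, TSL = 70 ms, f_SL = 8 Hz,
    180 prepared repetitions.
    """

    tr: float = 0.13955            # slice repetition time, s
    te: float = 0.029              # echo time, s (metadata only)
    tsl: float = 0.070             # total spin-lock duration, s
    f_sl: float = 8.0              # spin-lock / rotary-resonance frequency, Hz
    n_slices: int = 6
    n_reps: int = 180
    n_dummies: int = 2             # discarded lead-in volume pairs
    alternating: bool = True
    readout_flip_deg: float = 90.0

    def __post_init__(self) -> None:
        for name in ("tr", "te", "tsl"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if self.f_sl < 0:
            raise ValueError("f_sl must be >= 0")
        if self.n_slices < 1 or self.n_reps < 1:
            raise ValueError("n_slices and n_reps must be >= 1")
        if self.n_dummies < 0:
            raise ValueError("n_dummies must be >= 0")

    @classmethod
    def from_ms(cls, tr_ms: float = 139.55, te_ms: float = 29.0,
                tsl_ms: float = 70.0, **kwargs) -> "ProtocolParams":
        return cls(tr=tr_ms / 1000.0, te=te_ms / 1000.0, tsl=tsl_ms / 1000.0,
                   **kwargs)

    @property
    def tr_eff(self) -> float:
        """Sampling interval of each stream, s."""
        return effective_tr(self.tr * 1e3, self.n_slices, self.alternating) / 1e3

    @property
    def b_sl(self) -> float:
        """Spin-lock amplitude, Tesla (consistent with f_sl)."""
        return sl_amplitude_for_frequency(self.f_sl)

    @property
    def theta(self) -> float:
        """Rotation angle per SL half, rad (pi * f_SL * TSL)."""
        return rotation_angle(self.f_sl, self.tsl)

    def replace(self, **changes) -> "ProtocolParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class NeuronalField:
    """Oscillating neuronal z-field targeted by the rotary-resonance
    condition.

    Defaults match the simulated scenario: amplitude 4 nT at 8 Hz (the
    flicker frequency, equal to the spin-lock frequency).
    """

    b_n: float = 4e-9     # amplitude, Tesla
    f_n: float = 8.0      # frequency, Hz
    phi0: float = 0.0     # initial phase at run start, rad
    active: bool = True   # present only during visual stimulation

    def __post_init__(self) -> None:
        if self.b_n < 0 or self.f_n < 0:
            raise ValueError("b_n and f_n must be >= 0")
        if not (0.0 <= self.phi0 < 2.0 * math.pi):
            raise ValueError("phi0 must lie in [0, 2*pi)")

    def replace(self, **changes) -> "NeuronalField":
        return replace(self, **changes)


def run_duration(params: ProtocolParams, include_dummies: bool = False) -> float:
    """Total run duration in seconds: ``n_reps * TR_eff`` (lead-in dummy
    volume pairs excluded unless requested)."""
    n = params.n_reps + (params.n_dummies if include_dummies else 0)
    return n * params.tr_eff


def load_protocol(path: str | Path) -> ProtocolParams:
    """Read protocol parameters from a flat YAML mapping.

    Recognised keys (all optional; ms accepted for durations): ``tr_ms``,
    ``te_ms``, ``tsl_ms``, ``f_sl``, ``n_slices``, ``n_reps``, ``n_dummies``,
    ``alternating``, ``readout_flip_deg``.  Unknown keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"protocol config must be a mapping, got {type(raw)}")
    ms_keys = {"tr_ms", "te_ms", "tsl_ms"}
    allowed = ms_keys | {"f_sl", "n_slices", "n_reps", "n_dummies",
                         "alternating", "readout_flip_deg"}
    unknown = set(raw) - allowed
    if unknown:
        raise ValueError(f"unknown protocol keys: {sorted(unknown)}")
    return ProtocolParams.from_ms(**raw)
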