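"""In-memory containers for sweeps and per-neuron recordings.

Units convention (validated, never silently converted):

==============  ===========  ============
mode            command      response
==============  ===========  ============
current_clamp   pA           mV
voltage_clamp   mV           pA
==============  ===========  ============

All times in ms, indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .protocols import ProtocolSpec

#: expected (command, response) units per mode
MODE_UNITS = {
    "current_clamp": ("pA", "mV"),
    "voltage_clamp": ("mV", "pA"),
}

#: bregma offsets (mm) of the four recording planes along the rostro-caudal axis
AP_PLANES = (0.26, 0.14, 0.02, -0.10)


class UnitError(ValueError):
    """Raised when trace units do not match the mode convention."""


@dataclass
class Sweep:
    """One stimulus-response episode."""

    dt: float                   # ms per sample
    command: np.ndarray         # pA (CC) or mV (VC)
    response: np.ndarray        # mV (CC) or pA (VC)
    step_amplitude: float
    mode: str
    protocol: Optional[ProtocolSpec] = None

    def __post_init__(self) -> None:
        self.command = np.asarray(self.command, dtype=np.float64)
        self.response = np.asarray(self.response, dtype=np.float64)
        if self.dt <= 0:
            raise ValueError("sweep dt must be > 0")
        if self.command.shape != self.response.shape:
            raise ValueError("command and response must have the same length")
        if self.mode not in MODE_UNITS:
            raise ValueError(f"unknown sweep mode {self.mode!r}")

    @property
    def n_samples(self) -> int:
        return self.response.size

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.n_samples) * self.dt

    def window_slice(self, t0: float, t1: float) -> slice:
        """Index slice for the half-open time window [t0, t1) ms."""
        i0 = int(np.ceil(t0 / self.dt - 1e-9))
        i1 = int(np.ceil(t1 / self.dt - 1e-9))
        return slice(max(i0, 0), min(max(i1, 0), self.n_samples))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Sweep):
            return NotImplemented
        return (
            self.dt == other.dt
            and self.mode == other.mode
            and self.step_amplitude == other.step_amplitude
            and np.array_equal(self.command, other.command)
            and np.array_equal(self.response, other.response)
        )


@dataclass
class SweepSet:
    """All sweeps of one protocol for one neuron, keyed by step amplitude."""

    protocol: ProtocolSpec
    sweeps: list[Sweep] = field(default_factory=list)

    def __post_init__(self) -> None:
        for sw in self.sweeps:
            if sw.mode != self.protocol.mode:
                raise ValueError(
                    f"sweep mode {sw.mode!r} does not match protocol "
                    f"{self.protocol.name!r} ({self.protocol.mode})"
                )

    def __len__(self) -> int:
        return len(self.sweeps)

    def __iter__(self):
        return iter(self.sweeps)

    def by_amplitude(self, amplitude: float, atol: float = 1e-6) -> Sweep:
        for sw in self.sweeps:
            if abs(sw.step_amplitude - amplitude) <= atol:
                return sw
        raise KeyError(f"no sweep at amplitude {amplitude} in {self.protocol.name}")

    def amplitudes(self) -> list[float]:
        return [sw.step_amplitude for sw in self.sweeps]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SweepSet):
            return NotImplemented
        return (
            self.protocol.name == other.protocol.name
            and len(self) == len(other)
            and all(a == b for a, b in zip(self.sweeps, other.sweeps))
        )


@dataclass
class NeuronRecord:
    """One neuron: metadata, measured passives, and per-protocol sweep sets."""

    neuron_id: str
    mouse_id: str = ""
    ap_position_mm: Optional[float] = None   # bregma offset along the AP axis
    rmp: Optional[float] = None              # mV, recorded at I = 0
    capacitance: Optional[float] = None      # pF
    input_resistance: Optional[float] = None  # MΩ
    sweep_sets: dict[str, SweepSet] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.capacitance is not None and self.capacitance <= 0:
            raise ValueError(f"{self.neuron_id}: capacitance must be > 0")
        if self.ap_position_mm is not None and not (
            -0.2 <= self.ap_position_mm <= 0.4
        ):
            raise ValueError(
                f"{self.neuron_id}: ap_position_mm {self.ap_position_mm} outside "
                "[-0.2, +0.4] mm"
            )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, NeuronRecord):
            return NotImplemented
        return (
            self.neuron_id == other.neuron_id
            and self.mouse_id == other.mouse_id
            and self.ap_position_mm == other.ap_position_mm
            and self.rmp == other.rmp
            and self.capacitance == other.capacitance
            and self.input_resistance == other.input_resistance
            and set(self.sweep_sets) == set(other.sweep_sets)
            and all(self.sweep_sets[k] == other.sweep_sets[k] for k in self.sweep_sets)
        )
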