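"""Stimulus protocol definitions.

All times are in milliseconds; current-clamp amplitudes in pA, voltage-clamp
amplitudes in mV.  Step windows are half-open ``[onset, onset + duration)``.

Three canonical step protocols are provided:

``EXCITABILITY``
    Current clamp, −80 → +60 pA in 10 pA increments, 500 ms steps, from a
    −60 mV holding potential.  Used for evoked spike counts, voltage sag,
    rebound spikes, ISIs, first-spike latency and passive properties.
``IH``
    Voltage clamp, −60 → −150 mV in 10 mV increments, 800 ms steps.  Used to
    measure the hyperpolarization-activated current I_h.
``MFR``
    Current clamp, +50 → +750 pA in 50 pA increments, 1000 ms steps.  Used
    for the maximum firing rate and the current step attaining it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

Mode = Literal["current_clamp", "voltage_clamp"]


@dataclass(frozen=True)
class ProtocolSpec:
    """A family of step sweeps sharing timing, differing only in amplitude."""

    name: str
    mode: Mode
    holding: float              # mV
    step_onset: float           # ms
    step_duration: float        # ms
    post_window: float          # ms recorded after step offset
    amplitudes: tuple           # pA (current clamp) or mV (voltage clamp)
    apply_holding: bool = True  # False → no bias current (RMP measurement)

    def __post_init__(self) -> None:
        amps = tuple(float(a) for a in self.amplitudes)
        object.__setattr__(self, "amplitudes", amps)
        if self.step_duration <= 0:
            raise ValueError(f"protocol {self.name!r}: step_duration must be > 0")
        if len(amps) > 1:
            diffs = [b - a for a, b in zip(amps, amps[1:])]
            if not (all(d > 0 for d in diffs) or all(d < 0 for d in diffs)):
                raise ValueError(
                    f"protocol {self.name!r}: amplitudes must be strictly ordered"
                )
        if self.mode not in ("current_clamp", "voltage_clamp"):
            raise ValueError(f"protocol {self.name!r}: unknown mode {self.mode!r}")

    @property
    def step_offset(self) -> float:
        return self.step_onset + self.step_duration

    @property
    def sweep_duration(self) -> float:
        return self.step_offset + self.post_window

    def n_samples(self, dt: float) -> int:
        return int(round(self.sweep_duration / dt))

    def command_waveform(self, amplitude: float, dt: float):
        """Command time series for one sweep (baseline 0 pA / holding mV)."""
        import numpy as np

        n = self.n_samples(dt)
        t = np.arange(n) * dt
        base = 0.0 if self.mode == "current_clamp" else self.holding
        cmd = np.full(n, base, dtype=np.float64)
        in_step = (t >= self.step_onset) & (t < self.step_offset)
        cmd[in_step] = amplitude
        return cmd


def _steps(start: float, stop: float, inc: float) -> tuple:
    import numpy as np

    n = int(round((stop - start) / inc)) + 1
    return tuple(float(start + i * inc) for i in range(n))


EXCITABILITY = ProtocolSpec(
    name="excitability",
    mode="current_clamp",
    holding=-60.0,
    step_onset=100.0,
    step_duration=500.0,
    post_window=500.0,
    amplitudes=_steps(-80.0, 60.0, 10.0),
)

IH = ProtocolSpec(
    name="ih",
    mode="voltage_clamp",
    holding=-60.0,
    step_onset=100.0,
    step_duration=800.0,
    post_window=100.0,
    amplitudes=_steps(-150.0, -60.0, 10.0),
)

MFR = ProtocolSpec(
    name="mfr",
    mode="current_clamp",
    holding=-60.0,
    step_onset=100.0,
    step_duration=1000.0,
    post_window=100.0,
    amplitudes=_steps(50.0, 750.0, 50.0),
)

#: Zero-current sweep with no holding bias; the settled voltage is the RMP.
RMP = ProtocolSpec(
    name="rmp",
    mode="current_clamp",
    holding=-60.0,
    step_onset=100.0,
    step_duration=400.0,
    post_window=0.0,
    amplitudes=(0.0,),
    apply_holding=False,
)

CANONICAL: dict[str, ProtocolSpec] = {
    p.name: p for p in (EXCITABILITY, IH, MFR, RMP)
}
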