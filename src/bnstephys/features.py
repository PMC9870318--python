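"""Intrinsic-property feature extraction from sweep sets.

Every quantity measured from the recordings lives here: spike detection,
evoked spike counts, voltage sag, rebound spikes, maximum firing rate with
depolarization-block handling, I_h amplitude/density, inter-spike intervals,
first-spike latency, and the passive properties (RMP, input resistance,
capacitance).

Conventions (all configurable through the keyword arguments):

* spike criterion: upward crossing of 0 mV followed by a local maximum, with
  a 2 ms minimum inter-event interval (closer events merge to the larger
  peak);
* depolarization block within a sweep: first instant where the 5 ms low-pass
  filtered voltage stays above -20 mV for >= 50 ms with no spike; spikes
  after that instant are not counted toward the MFR;
* sag windows: peak searched in the first 150 ms of the step, steady state =
  mean of the last 100 ms of the step; clipped at 0;
* I_h windows: instantaneous current = mean over [onset+10, onset+30] ms,
  steady state = mean over the last 50 ms of the step;
* rebound window: 500 ms after step offset (or sweep end if sooner);
* MFR tie-break: lowest current step attaining the maximum count;
* features that require spikes are missing (None / NaN), never zero, when no
  spikes occur.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .traces import Sweep, SweepSet, NeuronRecord

SPIKE_THRESHOLD = 0.0       # mV
MIN_INTERVAL = 2.0          # ms
SAG_PEAK_WINDOW = 150.0     # ms after onset
SAG_STEADY_WINDOW = 100.0   # ms before offset
IH_INSTANT_WINDOW = (10.0, 30.0)   # ms after onset
IH_STEADY_WINDOW = 50.0     # ms before offset
REBOUND_WINDOW = 500.0      # ms after offset
BLOCK_LEVEL = -20.0         # mV
BLOCK_MIN_DURATION = 50.0   # ms
BLOCK_FILTER_TAU = 5.0      # ms
ISI_BIN = 5.0               # ms


class ModeError(ValueError):
    """Raised when an operation receives a sweep of the wrong clamp mode."""


def _require_mode(sweep: Sweep, mode: str, op: str) -> None:
    if sweep.mode != mode:
        raise ModeError(f"{op} requires a {mode} sweep, got {sweep.mode}")


# ---------------------------------------------------------------------------
# spikes

def detect_spikes(
    sweep: Sweep,
    threshold: float = SPIKE_THRESHOLD,
    min_interval: float = MIN_INTERVAL,
) -> np.ndarray:
    """Spike peak times (ms, ascending) in a current-clamp sweep.

    One event per upward threshold crossing followed by a local maximum;
    events closer than ``min_interval`` merge to the larger peak.
    """
    _require_mode(sweep, "current_clamp", "detect_spikes")
    v = sweep.response
    above = v >= threshold
    # upward crossings: sample i is the first above-threshold sample of a run
    crossings = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    if above.size and above[0]:
        crossings = np.concatenate(([0], crossings))
    peaks = []
    for c in crossings:
        end = c
        while end < v.size and above[end]:
            end += 1
        seg = v[c:end]
        if seg.size == 0:
            continue
        peaks.append(c + int(np.argmax(seg)))
    if not peaks:
        return np.empty(0, dtype=np.float64)
    # merge events closer than min_interval, keeping the larger peak
    merged = [peaks[0]]
    for pk in peaks[1:]:
        if (pk - merged[-1]) * sweep.dt < min_interval:
            if v[pk] > v[merged[-1]]:
                merged[-1] = pk
        else:
            merged.append(pk)
    return np.array(merged, dtype=np.float64) * sweep.dt


def count_evoked_spikes(sweep: Sweep, **kw) -> int:
    """Number of spikes inside the step window [onset, onset+duration)."""
    proto = sweep.protocol
    times = detect_spikes(sweep, **kw)
    return int(np.sum((times >= proto.step_onset) & (times < proto.step_offset)))


def rebound_spikes(sweep: Sweep, rebound_window: float = REBOUND_WINDOW,
                   **kw) -> int:
    """Spikes in the post-offset window (offset, offset + rebound_window]."""
    proto = sweep.protocol
    times = detect_spikes(sweep, **kw)
    t1 = min(proto.step_offset + rebound_window,
             sweep.n_samples * sweep.dt)
    return int(np.sum((times > proto.step_offset) & (times <= t1)))


# ---------------------------------------------------------------------------
# sag and I_h

def voltage_sag(sweep: Sweep, peak_window: float = SAG_PEAK_WINDOW,
                steady_window: float = SAG_STEADY_WINDOW) -> float:
    """Sag amplitude (mV, >= 0) of a hyperpolarizing current-clamp sweep.

    sag = V_steady - V_peak, where V_peak is the minimum in the early window
    after onset and V_steady the mean over the final window of the step.
    Offset-invariant and clipped at 0.
    """
    _require_mode(sweep, "current_clamp", "voltage_sag")
    proto = sweep.protocol
    early = sweep.response[sweep.window_slice(proto.step_onset,
                                              proto.step_onset + peak_window)]
    late = sweep.response[sweep.window_slice(proto.step_offset - steady_window,
                                             proto.step_offset)]
    if early.size == 0 or late.size == 0:
        raise ValueError("sag windows fall outside the sweep")
    v_peak = float(np.min(early))
    v_steady = float(np.mean(late))
    return max(v_steady - v_peak, 0.0)


def ih_amplitude(sweep: Sweep,
                 instant_window: tuple = IH_INSTANT_WINDOW,
                 steady_window: float = IH_STEADY_WINDOW) -> float:
    """|I_steady - I_instant| (pA) of a voltage-clamp sweep.

    The instantaneous current is averaged over a short window after the
    capacitive transient settles, the steady-state current over the final
    window of the step.  The absolute value absorbs the sign convention.
    """
    _require_mode(sweep, "voltage_clamp", "ih_amplitude")
    proto = sweep.protocol
    inst = sweep.response[sweep.window_slice(proto.step_onset + instant_window[0],
                                             proto.step_onset + instant_window[1])]
    late = sweep.response[sweep.window_slice(proto.step_offset - steady_window,
                                             proto.step_offset)]
    if inst.size == 0 or late.size == 0:
        raise ValueError("I_h windows fall outside the sweep")
    return abs(float(np.mean(late)) - float(np.mean(inst)))


def ih_density(amplitude: float, capacitance: Optional[float]) -> Optional[float]:
    """Current density pA/pF; None when capacitance is unavailable."""
    if capacitance is None:
        return None
    if capacitance <= 0:
        raise ValueError("capacitance must be > 0")
    return amplitude / capacitance


# ---------------------------------------------------------------------------
# depolarization block and maximum firing rate

def detect_block(sweep: Sweep, level: float = BLOCK_LEVEL,
                 min_duration: float = BLOCK_MIN_DURATION,
                 filter_tau: float = BLOCK_FILTER_TAU,
                 spike_times: Optional[np.ndarray] = None,
                 **kw) -> Optional[float]:
    """Onset time (ms) of a depolarization block within a sweep, or None.

    Block is declared at the first time the low-pass-filtered voltage stays
    above ``level`` for at least ``min_duration`` ms with no spike inside
    that stretch.
    """
    _require_mode(sweep, "current_clamp", "detect_block")
    if spike_times is None:
        spike_times = detect_spikes(sweep, **kw)
    v = sweep.response
    alpha = math.exp(-sweep.dt / filter_tau)
    # one-pole low-pass; lfilter keeps it vectorized
    from scipy.signal import lfilter
    vf = lfilter([1.0 - alpha], [1.0, -alpha], v, zi=[alpha * v[0]])[0]
    above = vf > level
    need = int(round(min_duration / sweep.dt))
    if spike_times.size:
        spike_idx = np.clip(np.round(spike_times / sweep.dt).astype(int),
                            0, v.size - 1)
        above[spike_idx] = False        # a spike interrupts the stretch
    # run-length encode the boolean mask
    padded = np.concatenate(([False], above, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    for s, e in zip(starts, ends):
        if e - s >= need:
            return s * sweep.dt
    return None


def spikes_before_block(sweep: Sweep, **kw) -> int:
    """Step-window spike count, truncated at the first depolarization block."""
    proto = sweep.protocol
    times = detect_spikes(sweep, **kw)
    t_block = detect_block(sweep, spike_times=times, **kw)
    hi = proto.step_offset if t_block is None else min(t_block, proto.step_offset)
    return int(np.sum((times >= proto.step_onset) & (times < hi)))


def max_firing_rate(sweepset: SweepSet, **kw) -> tuple[Optional[int], Optional[float]]:
    """(MFR count, current step attaining it) over an MFR sweep set.

    Per sweep only spikes before the first depolarization block count; the
    MFR is the maximum over sweeps and ties break to the lowest step.
    Returns (None, None) when no sweep has any spike.
    """
    best_count: Optional[int] = None
    best_step: Optional[float] = None
    for sw in sweepset:
        c = spikes_before_block(sw, **kw)
        if best_count is None or c > best_count:
            best_count, best_step = c, sw.step_amplitude
    if best_count is None or best_count == 0:
        return None, None
    return best_count, best_step


# ---------------------------------------------------------------------------
# spike timing

def isi_list(sweep: Sweep, **kw) -> np.ndarray:
    """Successive spike-peak intervals (ms) within the step window."""
    proto = sweep.protocol
    times = detect_spikes(sweep, **kw)
    times = times[(times >= proto.step_onset) & (times < proto.step_offset)]
    return np.diff(times)


def first_isi(sweep: Sweep, **kw) -> Optional[float]:
    """Earliest ISI (ms) in the step window; None with fewer than 2 spikes."""
    isis = isi_list(sweep, **kw)
    return float(isis[0]) if isis.size else None


def first_spike_latency(sweep: Sweep, **kw) -> Optional[float]:
    """Time (ms) from step onset to the first spike peak; None if no spike."""
    proto = sweep.protocol
    times = detect_spikes(sweep, **kw)
    times = times[(times >= proto.step_onset) & (times < proto.step_offset)]
    if times.size == 0:
        return None
    return float(times[0] - proto.step_onset)


def isi_histogram(per_type_isis: dict[str, list], bin_ms: float = ISI_BIN,
                  n_per_type: Optional[dict[str, int]] = None
                  ) -> "pd.DataFrame":
    """Normalized ISI histogram per neuron type.

    Bins are half-open ``[k*bin, (k+1)*bin)`` ms; each type's counts are
    divided by its neuron sample size.
    """
    import pandas as pd

    all_isis = [x for v in per_type_isis.values() for x in v]
    if not all_isis:
        return pd.DataFrame()
    n_bins = int(math.floor(max(all_isis) / bin_ms)) + 1
    edges = np.arange(n_bins + 1) * bin_ms
    out = {}
    for typ, isis in per_type_isis.items():
        counts, _ = np.histogram(isis, bins=edges)
        n = n_per_type[typ] if n_per_type else 1
        out[typ] = counts / max(n, 1)
    df = pd.DataFrame(out, index=pd.IntervalIndex.from_breaks(edges, closed="left"))
    df.index.name = "isi_bin_ms"
    return df


# ---------------------------------------------------------------------------
# passive properties

def _fit_monoexp_tau(t: np.ndarray, v: np.ndarray) -> float:
    """Least-squares mono-exponential time constant (ms) of a step onset."""
    from scipy.optimize import curve_fit

    v0 = v[0]
    v_inf = float(np.mean(v[int(0.8 * v.size):]))

    def model(tt, tau, a, c):
        return c + a * np.exp(-tt / tau)

    p0 = (max((t[-1] - t[0]) / 5.0, 1.0), v0 - v_inf, v_inf)
    popt, _ = curve_fit(model, t - t[0], v, p0=p0, maxfev=10000)
    return abs(float(popt[0]))


def passive_properties(
    record_or_sweeps,
    rin_steps: tuple = (-30.0, -20.0, -10.0),
    tau_step: float = -20.0,
    tau_fit_window: float = 100.0,
) -> tuple[Optional[float], Optional[float], Optional[float]]:
    """(RMP mV, input resistance MΩ, capacitance pF) for one neuron.

    * RMP: mean of the settled zero-current ("rmp") trace.
    * R_in: regression slope of steady-state ΔV against ΔI over the small
      hyperpolarizing excitability steps (MΩ, since mV/pA = GΩ × 1000).
    * C: τ / R_in with τ from a mono-exponential fit to the onset of the
      ``tau_step`` sweep.
    """
    if isinstance(record_or_sweeps, NeuronRecord):
        sets = record_or_sweeps.sweep_sets
    else:
        sets = record_or_sweeps

    rmp = None
    if "rmp" in sets and len(sets["rmp"]):
        sw = sets["rmp"].sweeps[0]
        tail = sw.response[int(0.5 * sw.n_samples):]
        rmp = float(np.mean(tail))

    rin = None
    cap = None
    exc = sets.get("excitability")
    if exc is not None:
        proto = exc.protocol
        dv, di = [], []
        baseline = None
        for sw in exc:
            if abs(sw.step_amplitude) < 1e-9:
                seg = sw.response[sw.window_slice(
                    proto.step_offset - SAG_STEADY_WINDOW, proto.step_offset)]
                baseline = float(np.mean(seg))
        for sw in exc:
            if any(abs(sw.step_amplitude - s) < 1e-6 for s in rin_steps):
                seg = sw.response[sw.window_slice(
                    proto.step_offset - SAG_STEADY_WINDOW, proto.step_offset)]
                dv.append(float(np.mean(seg)))
                di.append(sw.step_amplitude)
        if len(dv) >= 2:
            slope = float(np.polyfit(di, dv, 1)[0])   # mV/pA = GΩ
            rin = slope * 1000.0                       # MΩ
        elif len(dv) == 1 and baseline is not None:
            rin = (dv[0] - baseline) / di[0] * 1000.0
        if rin is not None and rin > 0:
            try:
                sw = exc.by_amplitude(tau_step)
            except KeyError:
                sw = None
            if sw is not None:
                sl = sw.window_slice(proto.step_onset,
                                     proto.step_onset + tau_fit_window)
                tau = _fit_monoexp_tau(sw.time[sl], sw.response[sl])
                cap = tau / rin * 1000.0   # ms / MΩ = nF → pF ×1000
    return rmp, rin, cap


# ---------------------------------------------------------------------------
# per-neuron assembly

@dataclass
class FeatureVector:
    """All derived quantities for one neuron.

    Maps are keyed by step amplitude (pA for current clamp, mV for voltage
    clamp).  Missing values are None (scalar) or absent keys (maps).
    """

    neuron_id: str
    evoked_spikes: dict = field(default_factory=dict)   # step pA -> count
    mfr: Optional[int] = None
    mfr_step: Optional[float] = None
    sag: dict = field(default_factory=dict)             # step pA -> mV
    rebound: dict = field(default_factory=dict)         # step pA -> count
    ih_amp: dict = field(default_factory=dict)          # step mV -> pA
    ih_dens: dict = field(default_factory=dict)         # step mV -> pA/pF
    isis: dict = field(default_factory=dict)            # step pA -> list ms
    first_isi: dict = field(default_factory=dict)       # step pA -> ms
    fsl: dict = field(default_factory=dict)             # step pA -> ms
    rmp: Optional[float] = None
    capacitance: Optional[float] = None
    input_resistance: Optional[float] = None


def extract_features(record: NeuronRecord, **kw) -> FeatureVector:
    """Compute the full feature vector of one neuron from its sweep sets."""
    fv = FeatureVector(neuron_id=record.neuron_id)
    rmp, rin, cap = passive_properties(record)
    fv.rmp, fv.input_resistance, fv.capacitance = rmp, rin, cap
    record.rmp, record.input_resistance = rmp, rin
    if cap is not None:
        record.capacitance = cap

    exc = record.sweep_sets.get("excitability")
    if exc is not None:
        for sw in exc:
            amp = sw.step_amplitude
            if amp > 0:
                fv.evoked_spikes[amp] = count_evoked_spikes(sw, **kw)
                isis = isi_list(sw, **kw)
                fv.isis[amp] = isis.tolist()
                fi = first_isi(sw, **kw)
                if fi is not None:
                    fv.first_isi[amp] = fi
                lat = first_spike_latency(sw, **kw)
                if lat is not None:
                    fv.fsl[amp] = lat
            elif amp < 0:
                fv.sag[amp] = voltage_sag(sw)
                fv.rebound[amp] = rebound_spikes(sw, **kw)
            else:
                fv.evoked_spikes[amp] = count_evoked_spikes(sw, **kw)

    mfr_set = record.sweep_sets.get("mfr")
    if mfr_set is not None:
        fv.mfr, fv.mfr_step = max_firing_rate(mfr_set, **kw)

    ih_set = record.sweep_sets.get("ih")
    if ih_set is not None:
        for sw in ih_set:
            amp = ih_amplitude(sw)
            fv.ih_amp[sw.step_amplitude] = amp
            dens = ih_density(amp, fv.capacitance)
            if dens is not None:
                fv.ih_dens[sw.step_amplitude] = dens
    return fv


def features_to_frame(fvs: list[FeatureVector]) -> "pd.DataFrame":
    """Wide per-neuron feature table (one row per neuron, NaN = missing)."""
    import pandas as pd

    rows = []
    for fv in fvs:
        row: dict = {"neuron_id": fv.neuron_id,
                     "rmp": fv.rmp,
                     "capacitance": fv.capacitance,
                     "input_resistance": fv.input_resistance,
                     "mfr": fv.mfr,
                     "mfr_step": fv.mfr_step}
        for amp, v in sorted(fv.evoked_spikes.items()):
            row[f"evoked_spikes_{amp:+.0f}pA"] = v
        for amp, v in sorted(fv.sag.items()):
            row[f"sag_{amp:+.0f}pA"] = v
        for amp, v in sorted(fv.rebound.items()):
            row[f"rebound_{amp:+.0f}pA"] = v
        for amp, v in sorted(fv.ih_amp.items()):
            row[f"ih_amp_{amp:+.0f}mV"] = v
        for amp, v in sorted(fv.ih_dens.items()):
            row[f"ih_density_{amp:+.0f}mV"] = v
        for amp, v in sorted(fv.first_isi.items()):
            row[f"first_isi_{amp:+.0f}pA"] = v
        for amp, v in sorted(fv.fsl.items()):
            row[f"fsl_{amp:+.0f}pA"] = v
        rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty:
        df = df.set_index("neuron_id")
    return df
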