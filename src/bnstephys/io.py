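"""Reading and writing of trace containers and feature tables.

Internal trace format: one HDF5 file, one group per neuron, one subgroup per
protocol, one 2-row dataset (command, response) per sweep.  Units and the
schema version are stored as attributes and validated on read — a file whose
response is not in the unit the mode demands raises :class:`UnitError`
naming the offending sweep rather than converting silently.

Feature tables are TSV/CSV with one row per neuron, one column per named
feature and empty cells for missing values; the round trip preserves NaN.
"""

from __future__ import annotations

import json
from typing import Iterable, Optional

import h5py
import numpy as np
import pandas as pd

from .protocols import ProtocolSpec, CANONICAL
from .traces import Sweep, SweepSet, NeuronRecord, MODE_UNITS, UnitError

SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for schema or structural problems in a trace file."""


def _protocol_to_attrs(grp: h5py.Group, proto: ProtocolSpec) -> None:
    grp.attrs["protocol_name"] = proto.name
    grp.attrs["mode"] = proto.mode
    grp.attrs["holding"] = proto.holding
    grp.attrs["step_onset"] = proto.step_onset
    grp.attrs["step_duration"] = proto.step_duration
    grp.attrs["post_window"] = proto.post_window
    grp.attrs["amplitudes"] = np.asarray(proto.amplitudes, dtype=np.float64)
    grp.attrs["apply_holding"] = bool(getattr(proto, "apply_holding", True))


def _protocol_from_attrs(grp: h5py.Group) -> ProtocolSpec:
    return ProtocolSpec(
        name=str(grp.attrs["protocol_name"]),
        mode=str(grp.attrs["mode"]),
        holding=float(grp.attrs["holding"]),
        step_onset=float(grp.attrs["step_onset"]),
        step_duration=float(grp.attrs["step_duration"]),
        post_window=float(grp.attrs["post_window"]),
        amplitudes=tuple(np.asarray(grp.attrs["amplitudes"], dtype=float)),
        apply_holding=bool(grp.attrs.get("apply_holding", True)),
    )


def write_traces(records: Iterable[NeuronRecord], path) -> None:
    """Write neuron records (sweeps + metadata) losslessly to HDF5."""
    records = list(records)
    with h5py.File(path, "w") as fh:
        fh.attrs["schema_version"] = SCHEMA_VERSION
        fh.attrs["container"] = "bnstephys-traces"
        root = fh.create_group("neurons")
        for rec in records:
            g = root.create_group(rec.neuron_id)
            g.attrs["mouse_id"] = rec.mouse_id
            for name, val in (("ap_position_mm", rec.ap_position_mm),
                              ("rmp", rec.rmp),
                              ("capacitance", rec.capacitance),
                              ("input_resistance", rec.input_resistance)):
                if val is not None:
                    g.attrs[name] = float(val)
            for pname, ss in rec.sweep_sets.items():
                pg = g.create_group(pname)
                _protocol_to_attrs(pg, ss.protocol)
                cu, ru = MODE_UNITS[ss.protocol.mode]
                for i, sw in enumerate(ss):
                    ds = pg.create_dataset(
                        f"sweep_{i:03d}",
                        data=np.vstack([sw.command, sw.response]))
                    ds.attrs["dt"] = sw.dt
                    ds.attrs["step_amplitude"] = sw.step_amplitude
                    ds.attrs["mode"] = sw.mode
                    ds.attrs["command_units"] = cu
                    ds.attrs["response_units"] = ru


def read_traces(path) -> list[NeuronRecord]:
    """Read a trace container; validates schema and units."""
    out: list[NeuronRecord] = []
    with h5py.File(path, "r") as fh:
        if fh.attrs.get("container") != "bnstephys-traces":
            raise FormatError(f"{path}: not a bnstephys trace container")
        ver = int(fh.attrs.get("schema_version", -1))
        if ver != SCHEMA_VERSION:
            raise FormatError(f"{path}: unsupported schema version {ver}")
        for nid, g in fh["neurons"].items():
            rec = NeuronRecord(
                neuron_id=str(nid),
                mouse_id=str(g.attrs.get("mouse_id", "")),
                ap_position_mm=(float(g.attrs["ap_position_mm"])
                                if "ap_position_mm" in g.attrs else None),
                rmp=float(g.attrs["rmp"]) if "rmp" in g.attrs else None,
                capacitance=(float(g.attrs["capacitance"])
                             if "capacitance" in g.attrs else None),
                input_resistance=(float(g.attrs["input_resistance"])
                                  if "input_resistance" in g.attrs else None),
            )
            for pname, pg in g.items():
                proto = _protocol_from_attrs(pg)
                cu, ru = MODE_UNITS[proto.mode]
                sweeps = []
                for dname in sorted(pg.keys()):
                    ds = pg[dname]
                    got_cu = str(ds.attrs.get("command_units", ""))
                    got_ru = str(ds.attrs.get("response_units", ""))
                    if (got_cu, got_ru) != (cu, ru):
                        raise UnitError(
                            f"{nid}/{pname}/{dname}: units "
                            f"({got_cu}, {got_ru}) do not match mode "
                            f"{proto.mode} which requires ({cu}, {ru})")
                    arr = ds[()]
                    if arr.ndim != 2 or arr.shape[0] != 2:
                        raise FormatError(
                            f"{nid}/{pname}/{dname}: malformed sweep dataset")
                    sweeps.append(Sweep(
                        dt=float(ds.attrs["dt"]),
                        command=arr[0], response=arr[1],
                        step_amplitude=float(ds.attrs["step_amplitude"]),
                        mode=str(ds.attrs["mode"]),
                        protocol=proto))
                rec.sweep_sets[pname] = SweepSet(protocol=proto, sweeps=sweeps)
            out.append(rec)
    return out


def write_manifest(records: Iterable[NeuronRecord], path,
                   extra: Optional[dict] = None) -> None:
    """JSON sidecar manifest listing neurons and their metadata."""
    rows = []
    for rec in records:
        rows.append({
            "neuron_id": rec.neuron_id,
            "mouse_id": rec.mouse_id,
            "ap_position_mm": rec.ap_position_mm,
            "protocols": sorted(rec.sweep_sets.keys()),
        })
    doc = {"schema_version": SCHEMA_VERSION, "neurons": rows}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


# ---------------------------------------------------------------------------
# feature tables

def export_feature_table(table: pd.DataFrame, path, sep: str = "\t") -> None:
    """One row per neuron, one column per feature; missing cells left empty."""
    table.to_csv(path, sep=sep, index=True, na_rep="")


def read_feature_table(path, sep: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    return df


# ---------------------------------------------------------------------------
# protocol matching

def match_protocol(
    sweeps: Iterable[Sweep],
    protocols: Optional[dict[str, ProtocolSpec]] = None,
    atol: float = 2.0,
) -> tuple[dict[str, SweepSet], list[Sweep]]:
    """Assign loose sweeps to protocols by their command waveform.

    A sweep matches a protocol when its command equals the protocol's
    command for one of its amplitudes within ``atol`` (pA or mV) everywhere.
    Returns ({protocol name: SweepSet}, unmatched sweeps) — unmatched sweeps
    are reported, never dropped silently.
    """
    if protocols is None:
        protocols = {k: v for k, v in CANONICAL.items()}
    matched: dict[str, list[Sweep]] = {}
    unmatched: list[Sweep] = []
    for sw in sweeps:
        hit = None
        for proto in protocols.values():
            if proto.mode != sw.mode:
                continue
            if proto.n_samples(sw.dt) != sw.n_samples:
                continue
            base = 0.0 if proto.mode == "current_clamp" else proto.holding
            sl = sw.window_slice(proto.step_onset, proto.step_offset)
            step_level = float(np.median(sw.command[sl]))
            for amp in proto.amplitudes:
                if abs(step_level - amp) > atol:
                    continue
                ref = proto.command_waveform(amp, sw.dt)
                if np.max(np.abs(sw.command - ref)) <= atol:
                    hit = (proto, amp)
                    break
            if hit:
                break
        if hit is None:
            unmatched.append(sw)
        else:
            proto, amp = hit
            sw2 = Sweep(dt=sw.dt, command=sw.command, response=sw.response,
                        step_amplitude=amp, mode=sw.mode, protocol=proto)
            matched.setdefault(proto.name, []).append(sw2)
    out = {}
    for name, sws in matched.items():
        sws.sort(key=lambda s: s.step_amplitude)
        out[name] = SweepSet(protocol=protocols[name], sweeps=sws)
    return out, unmatched
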