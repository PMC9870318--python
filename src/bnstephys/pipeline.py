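"""End-to-end orchestration: simulate → extract → classify → cluster → stats.

One :func:`run_pipeline` call produces a fully deterministic run directory:
cohort manifest, per-neuron feature table, type labels, proportion report,
Ward linkages (three- and six-parameter sets) with heatmap exports, the
ANOVA/Tukey statistical surface, and a JSON report.  Any stage failure
aborts the run with the stage name; there is no partial-failure resumption.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import classify as _classify
from . import cluster as _cluster
from . import stats as _stats
from .features import extract_features, features_to_frame
from .io import export_feature_table, write_traces
from .simulate import SimConfig, make_cohort, simulate_neuron
from .traces import AP_PLANES
from .simulate import AP_WEIGHTS

log = logging.getLogger("bnstephys.pipeline")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (serialized verbatim to the output)."""

    seed: int
    out_dir: str = "run"
    n_per_type: tuple = (30, 30, 30, 30)
    jitter: float = 0.1
    dt: float = 0.05
    noise_sd: float = 0.0
    sag_threshold: float = _classify.SAG_THRESHOLD_MV
    others_current_threshold: float = _classify.OTHERS_CURRENT_THRESHOLD_PA
    others_max_spikes: int = _classify.OTHERS_MAX_SPIKES
    rmp_cutoff: float = _classify.RMP_EXCLUSION_MV
    cluster_k: dict = field(default_factory=lambda: {"three": 4, "six": 3})
    scale_for_clustering: bool = True
    n_mice: int = 22
    save_traces: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        doc["n_per_type"] = tuple(doc.get("n_per_type", (30, 30, 30, 30)))
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_per_type"] = list(self.n_per_type)
        return d


def report_proportions(counts) -> dict:
    """Formatted per-type proportion report from raw counts (I, II, III, Others).

    Percentages to two decimals over the classified total.
    """
    if isinstance(counts, dict):
        counts = [counts.get(t, 0) for t in _classify.LABELS]
    counts = [int(c) for c in counts]
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    total = sum(counts)
    pct = [round(100.0 * c / total, 2) if total else 0.0 for c in counts]
    return {
        "counts": dict(zip(_classify.LABELS, counts)),
        "percent": dict(zip(_classify.LABELS, pct)),
        "total": total,
    }


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return json.loads(o.to_json(orient="split"))
    raise TypeError(type(o))


def _dump(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_json_default)


def _stage(name):
    def deco(fn):
        def wrapper(*a, **kw):
            try:
                return fn(*a, **kw)
            except Exception as e:
                raise RuntimeError(f"pipeline stage {name!r} failed: {e}") from e
        return wrapper
    return deco


@_stage("simulate")
def _simulate_stage(cfg: RunConfig):
    cohort = make_cohort(cfg.n_per_type, cfg.jitter, cfg.seed)
    sim = SimConfig(dt=cfg.dt, noise_sd=cfg.noise_sd,
                    jitter=cfg.jitter, n_per_type=tuple(cfg.n_per_type))
    meta_rng = np.random.default_rng(cfg.seed + 1)
    records, truth, params_rows = [], {}, []
    for i, p in enumerate(cohort):
        nid = f"n{i:03d}"
        mouse = f"m{int(meta_rng.integers(0, max(cfg.n_mice, 1))):02d}"
        ap = float(meta_rng.choice(AP_PLANES, p=np.array(AP_WEIGHTS)))
        rec = simulate_neuron(p, sim, neuron_id=nid, mouse_id=mouse,
                              ap_position_mm=ap)
        records.append(rec)
        truth[nid] = p.phenotype
        row = {"neuron_id": nid, "mouse_id": mouse, "ap_position_mm": ap}
        row.update({k: v for k, v in dataclasses.asdict(p).items()})
        params_rows.append(row)
    return records, truth, pd.DataFrame(params_rows)


@_stage("features")
def _features_stage(records):
    return [extract_features(rec) for rec in records]


@_stage("classify")
def _classify_stage(fvs, cfg: RunConfig):
    labels = {}
    rationale = {}
    for fv in fvs:
        lab = _classify.classify_neuron(
            fv, sag_threshold=cfg.sag_threshold,
            others_current_threshold=cfg.others_current_threshold,
            others_max_spikes=cfg.others_max_spikes,
            rmp_cutoff=cfg.rmp_cutoff)
        labels[fv.neuron_id] = lab.label
        rationale[fv.neuron_id] = lab.rationale
    return labels, rationale


@_stage("cluster")
def _cluster_stage(table, labels, cfg: RunConfig, out: Path):
    results = {}
    for pset, k in cfg.cluster_k.items():
        fm = _cluster.build_feature_matrix(table, pset, labels=labels)
        if len(fm.values) < max(k, 2):
            results[pset] = {"skipped": f"only {len(fm.values)} complete rows"}
            continue
        mat = _cluster.standardize(fm) if cfg.scale_for_clustering else fm
        tree = _cluster.ward_linkage(mat)
        cl = _cluster.cut_tree(tree, k)
        ag = _cluster.agreement(cl, labels)
        pd.DataFrame(tree.merges,
                     columns=["a", "b", "height", "size"]).to_csv(
            out / f"linkage_{pset}.tsv", sep="\t", index=False)
        _cluster.export_dendrogram_newick(tree, out / f"dendrogram_{pset}.nwk")
        _cluster.export_heatmap(mat, tree, type_labels=labels,
                                path=out / f"heatmap_{pset}.png",
                                tsv_path=out / f"heatmap_{pset}.tsv")
        results[pset] = {
            "n_rows": len(fm.values),
            "dropped": fm.dropped,
            "k": k,
            "purity": ag["purity"],
            "majority": ag["majority"],
            "contingency": ag["table"],
            "clusters": {str(i): int(c) for i, c in cl.items()},
        }
    return results


@_stage("stats")
def _stats_stage(fvs, labels):
    """Two-way type×step ANOVA on evoked spikes and sag; one-way + Tukey on
    the passive properties."""
    out: dict = {}
    kept = [fv for fv in fvs if labels[fv.neuron_id] in _classify.LABELS]

    def long_table(attr, steps):
        vals, fa, fb = [], [], []
        for fv in kept:
            d = getattr(fv, attr)
            for s in steps:
                if s in d:
                    vals.append(d[s])
                    fa.append(labels[fv.neuron_id])
                    fb.append(f"{s:+.0f}")
        return vals, fa, fb

    exc_steps = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
    try:
        v, a, b = long_table("evoked_spikes", exc_steps)
        res = _stats.two_way_anova(v, a, b, names=("type", "step"))
        out["evoked_spikes"] = {
            k: dataclasses.asdict(r) for k, r in res.effects.items()}
    except _stats.DesignError as e:
        out["evoked_spikes"] = {"error": str(e)}
    sag_steps = [-80.0, -70.0, -60.0, -50.0, -40.0, -30.0, -20.0, -10.0]
    try:
        v, a, b = long_table("sag", sag_steps)
        res = _stats.two_way_anova(v, a, b, names=("type", "step"))
        out["sag"] = {k: dataclasses.asdict(r) for k, r in res.effects.items()}
    except _stats.DesignError as e:
        out["sag"] = {"error": str(e)}

    for attr in ("rmp", "capacitance", "input_resistance"):
        groups: dict[str, list] = {}
        for fv in kept:
            val = getattr(fv, attr)
            if val is not None:
                groups.setdefault(labels[fv.neuron_id], []).append(val)
        groups = {g: v for g, v in groups.items() if len(v) >= 2}
        entry: dict = {
            "summary": _stats.summarize(groups).to_dict(orient="index")}
        try:
            res = _stats.one_way_anova(groups)
            entry["anova"] = dataclasses.asdict(res.effects["group"])
            tk = _stats.tukey_hsd(groups)
            entry["tukey"] = [dataclasses.asdict(p) for p in tk.pairs]
        except _stats.DesignError as e:
            entry["error"] = str(e)
        out[attr] = entry
    return out


@_stage("report")
def _report_stage(fvs, labels, truth, records, cluster_res, stats_res,
                  cfg: RunConfig):
    props = _classify.proportions(list(labels.values()))
    per_type_feats = {}
    for t in _classify.LABELS:
        sub = [fv for fv in fvs if labels[fv.neuron_id] == t]
        feats = {}
        for attr in ("rmp", "capacitance", "input_resistance"):
            vals = [getattr(fv, attr) for fv in sub
                    if getattr(fv, attr) is not None]
            if vals:
                arr = np.asarray(vals)
                feats[attr] = {
                    "mean": float(arr.mean()),
                    "sem": (float(arr.std(ddof=1) / np.sqrt(arr.size))
                            if arr.size > 1 else None),
                    "n": int(arr.size)}
        per_type_feats[t] = feats

    # rostro-caudal grouping (passives by AP plane, per type)
    ap_summary: dict = {}
    ap_of = {r.neuron_id: r.ap_position_mm for r in records}
    if any(v is not None for v in ap_of.values()):
        for t in _classify.LABELS:
            ids = [i for i, lb in labels.items() if lb == t]
            by_plane: dict[str, list] = {}
            for i in ids:
                fv = next(f for f in fvs if f.neuron_id == i)
                if ap_of[i] is not None and fv.rmp is not None:
                    by_plane.setdefault(f"{ap_of[i]:+.2f}", []).append(fv.rmp)
            by_plane = {k: v for k, v in by_plane.items() if len(v) >= 2}
            if len(by_plane) >= 2:
                res = _stats.one_way_anova(by_plane)
                ap_summary[t] = {
                    "rmp_anova": dataclasses.asdict(res.effects["group"]),
                    "n_per_plane": {k: len(v) for k, v in by_plane.items()}}
            else:
                ap_summary[t] = {"skipped": "too few planes with n >= 2"}

    agreement_truth = {}
    if truth:
        n_match = sum(labels[i] == truth[i] for i in labels)
        agreement_truth = {
            "accuracy": n_match / len(labels) if labels else None,
            "n": len(labels)}

    return {
        "proportions": props,
        "per_type_features": per_type_feats,
        "cluster": cluster_res,
        "stats": stats_res,
        "rostrocaudal": ap_summary,
        "ground_truth_agreement": agreement_truth,
    }


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full pipeline; returns the report dict and writes the run
    directory.  Fully deterministic given the config (seed included)."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_doc = cfg.to_dict()
    cfg_json = json.dumps(cfg_doc, sort_keys=True)
    _dump(cfg_doc, out / "config.json")

    records, truth, params_df = _simulate_stage(cfg)
    params_df.to_csv(out / "cohort.csv", index=False)
    log.info("simulated %d neurons", len(records))
    if cfg.save_traces:
        write_traces(records, out / "traces.h5")

    if not records:
        report = {
            "proportions": report_proportions([0, 0, 0, 0]),
            "per_type_features": {}, "cluster": {}, "stats": {},
            "rostrocaudal": {}, "ground_truth_agreement": {},
        }
        manifest = {"config_sha256": hashlib.sha256(
            cfg_json.encode()).hexdigest(),
            "stage_counts": {"simulated": 0, "classified": 0, "excluded": 0}}
        _dump(manifest, out / "manifest.json")
        _dump(report, out / "report.json")
        return report

    fvs = _features_stage(records)
    table = features_to_frame(fvs)
    export_feature_table(table, out / "features.tsv")

    labels, rationale = _classify_stage(fvs, cfg)
    lab_df = pd.DataFrame({
        "neuron_id": list(labels),
        "label": [labels[i] for i in labels],
        "ground_truth": [truth[i] for i in labels],
        "rationale": [rationale[i] for i in labels]})
    lab_df.to_csv(out / "labels.tsv", sep="\t", index=False)
    props = _classify.proportions(list(labels.values()))
    _dump(props, out / "proportions.json")

    cluster_res = _cluster_stage(table, labels, cfg, out)
    scatter = _cluster.scatter3d_export(table, labels)
    scatter.to_csv(out / "scatter3d.tsv", sep="\t")

    stats_res = _stats_stage(fvs, labels)
    _dump(stats_res, out / "stats.json")

    report = _report_stage(fvs, labels, truth, records, cluster_res,
                           stats_res, cfg)
    n_excluded = sum(1 for lb in labels.values() if lb == "Excluded")
    manifest = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "stage_counts": {
            "simulated": len(records),
            "features": len(fvs),
            "classified": len(labels) - n_excluded,
            "excluded": n_excluded,
            "cluster_rows": {p: r.get("n_rows") for p, r in cluster_res.items()
                             if isinstance(r, dict)},
        },
    }
    _dump(manifest, out / "manifest.json")
    _dump(report, out / "report.json")
    return report
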