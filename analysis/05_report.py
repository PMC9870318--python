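"""Assemble the final report: proportions, per-type summaries, clustering
agreement, and ground-truth recovery, from the artifacts of steps 01-04.

Writes ``results/report.json`` and prints the headline numbers.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

OUT = Path(__file__).resolve().parents[1] / "results"

labels = pd.read_csv(OUT / "labels.tsv", sep="\t", index_col=0)
table = pd.read_csv(OUT / "features.tsv", sep="\t", index_col=0)
props = json.loads((OUT / "proportions.json").read_text())
cluster = json.loads((OUT / "cluster_summary.json").read_text())
stats = json.loads((OUT / "stats.json").read_text())

per_type = {}
for t in ("I", "II", "III", "Others"):
    ids = labels.index[labels["label"] == t]
    sub = table.loc[ids]
    per_type[t] = {
        attr: {"mean": float(sub[attr].mean()),
               "sem": float(sub[attr].sem()),
               "n": int(sub[attr].notna().sum())}
        for attr in ("rmp", "capacitance", "input_resistance")
    }

acc = float(np.mean(labels["label"] == labels["ground_truth"]))
report = {
    "proportions": props,
    "per_type_passives": per_type,
    "cluster": cluster,
    "stats_keys": sorted(stats),
    "ground_truth_recovery": acc,
}
with open(OUT / "report.json", "w") as fh:
    json.dump(report, fh, indent=1, sort_keys=True)

print("=== cohort report ===")
print("percent per type:", props["percent"])
print(f"ground-truth recovery: {acc:.1%}")
for pset, res in cluster.items():
    print(f"{pset}-parameter clustering: majority {res['majority']} "
          f"purity {res['purity']}")
print(f"wrote {OUT / 'report.json'}")
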