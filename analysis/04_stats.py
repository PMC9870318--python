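"""Statistical surface: type × step ANOVAs and Tukey post-hoc tests.

Reads the feature table and labels and computes, per the analysis plan:
two-way (type × current step) ANOVA with interaction on evoked spike counts
and on voltage sag, one-way ANOVAs with Tukey HSD on the passive properties
(RMP, capacitance, input resistance), and mean ± SEM summaries.  Writes
``results/stats.json`` and a Tukey pair table ``results/tukey_passives.tsv``.
"""

import dataclasses
import json
from pathlib import Path

import pandas as pd

from bnstephys import stats as bstats

OUT = Path(__file__).resolve().parents[1] / "results"
table = pd.read_csv(OUT / "features.tsv", sep="\t", index_col=0)
labels = pd.read_csv(OUT / "labels.tsv", sep="\t", index_col=0)["label"]

out = {}

def melt(prefix, steps):
    vals, fa, fb = [], [], []
    for nid, row in table.iterrows():
        for s in steps:
            col = f"{prefix}_{s:+.0f}pA"
            if col in row and pd.notna(row[col]):
                vals.append(float(row[col]))
                fa.append(labels[nid])
                fb.append(f"{s:+.0f}")
    return vals, fa, fb


for name, prefix, steps in (
        ("evoked_spikes", "evoked_spikes", range(10, 70, 10)),
        ("sag", "sag", range(-80, 0, 10))):
    try:
        res = bstats.two_way_anova(*melt(prefix, steps), names=("type", "step"))
        out[name] = {k: dataclasses.asdict(v) for k, v in res.effects.items()}
        e = res.effects
        print(f"{name}: interaction F({e['interaction'].df_num:.0f},"
              f"{e['interaction'].df_den:.0f}) = {e['interaction'].F:.2f}, "
              f"p = {e['interaction'].p:.2e}")
    except bstats.DesignError as err:
        out[name] = {"error": str(err)}
        print(f"{name}: design error: {err}")

tukey_rows = []
for attr in ("rmp", "capacitance", "input_resistance"):
    groups = {}
    for nid, v in table[attr].items():
        if pd.notna(v) and labels[nid] in ("I", "II", "III", "Others"):
            groups.setdefault(labels[nid], []).append(float(v))
    groups = {g: v for g, v in groups.items() if len(v) >= 2}
    entry = {"summary": bstats.summarize(groups).to_dict(orient="index")}
    try:
        res = bstats.one_way_anova(groups)
        entry["anova"] = dataclasses.asdict(res.effects["group"])
        tk = bstats.tukey_hsd(groups)
        entry["tukey"] = [dataclasses.asdict(p) for p in tk.pairs]
        for p in tk.pairs:
            tukey_rows.append({"feature": attr, **dataclasses.asdict(p)})
        e = res.effects["group"]
        print(f"{attr}: one-way F({e.df_num:.0f},{e.df_den:.0f}) = "
              f"{e.F:.2f}, p = {e.p:.2e}")
    except bstats.DesignError as err:
        entry["error"] = str(err)
    out[attr] = entry

pd.DataFrame(tukey_rows).to_csv(OUT / "tukey_passives.tsv", sep="\t",
                                index=False)
with open(OUT / "stats.json", "w") as fh:
    json.dump(out, fh, indent=1, sort_keys=True)
print(f"wrote {OUT / 'stats.json'}")
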