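import numpy as np
import pytest

from bnstephys import (
    TEMPLATES, SimConfig, simulate_neuron, extract_features, classify_neuron,
    make_cohort, features_to_frame,
)


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def template_runs(sim_config):
    """(params, record, feature vector) for each of the four templates."""
    out = {}
    for name, p in TEMPLATES.items():
        rec = simulate_neuron(p, sim_config, neuron_id=name)
        out[name] = (p, rec, extract_features(rec))
    return out


@pytest.fixture(scope="session")
def cohort_run(sim_config):
    """Default synthetic cohort (30/type, jitter 0.1, seed 1): feature
    vectors, rule-based labels, ground truth, and the wide feature table."""
    cohort = make_cohort((30, 30, 30, 30), jitter=0.1, seed=1)
    fvs, truth = [], {}
    for i, p in enumerate(cohort):
        nid = f"n{i:03d}"
        rec = simulate_neuron(p, sim_config, neuron_id=nid)
        fvs.append(extract_features(rec))
        truth[nid] = p.phenotype
    labels = {fv.neuron_id: classify_neuron(fv).label for fv in fvs}
    table = features_to_frame(fvs)
    return {"fvs": fvs, "labels": labels, "truth": truth, "table": table}
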