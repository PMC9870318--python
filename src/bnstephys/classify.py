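"""Rule-based assignment of the four intrinsic phenotypes.

Exclusion first: a neuron with RMP more positive than -50 mV (strict) or
with no spike at any depolarizing excitability step is excluded from all
analysis.

Classification rules, in order of precedence:

1. "Others" — no spikes at any excitability step below the late-firing
   current threshold (default +30 pA) and at most ``others_max_spikes``
   (default 1) evoked spikes at any step.
2. Type II — at least one rebound spike after the -80 pA step.  Rebound
   takes precedence over sag because rebound spiking is exclusive to
   Type II; a rebound-without-sag neuron is still II (flagged in the
   rationale).
3. Type I — voltage sag at -80 pA at or above ``sag_threshold``
   (default 3 mV; sag presence is a visual call in the source protocol, the
   numeric default separates the simulated templates and is configurable).
4. Type III — everything else (no sag, no rebound).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np

from .features import FeatureVector

RMP_EXCLUSION_MV = -50.0
SAG_THRESHOLD_MV = 3.0
OTHERS_CURRENT_THRESHOLD_PA = 30.0
OTHERS_MAX_SPIKES = 1
CLASSIFIER_SAG_STEP = -80.0
CLASSIFIER_REBOUND_STEP = -80.0

LABELS = ("I", "II", "III", "Others")


@dataclass(frozen=True)
class TypeLabel:
    label: str          # one of {"I", "II", "III", "Others", "Excluded"}
    rationale: str      # which rule fired


class ClassificationError(ValueError):
    """Raised when required features are missing."""


def apply_exclusion(fv: FeatureVector,
                    rmp_cutoff: float = RMP_EXCLUSION_MV) -> Optional[TypeLabel]:
    """Return an Excluded label, or None if the neuron is kept.

    Excluded iff RMP > cutoff (strict inequality, so exactly -50 mV is kept)
    or the neuron fired no spike at any depolarizing excitability step.
    """
    if fv.rmp is None:
        raise ClassificationError(f"{fv.neuron_id}: missing rmp")
    if fv.rmp > rmp_cutoff:
        return TypeLabel("Excluded", f"rmp {fv.rmp:.1f} mV > {rmp_cutoff:g} mV")
    depol = {a: c for a, c in fv.evoked_spikes.items() if a > 0}
    if not depol:
        raise ClassificationError(f"{fv.neuron_id}: no depolarizing step counts")
    if all(c == 0 for c in depol.values()):
        return TypeLabel("Excluded", "no spikes at any excitability step")
    return None


def classify_neuron(
    fv: FeatureVector,
    sag_threshold: float = SAG_THRESHOLD_MV,
    others_current_threshold: float = OTHERS_CURRENT_THRESHOLD_PA,
    others_max_spikes: int = OTHERS_MAX_SPIKES,
    rmp_cutoff: float = RMP_EXCLUSION_MV,
) -> TypeLabel:
    """Classify one neuron (after exclusion) into I / II / III / Others."""
    excl = apply_exclusion(fv, rmp_cutoff)
    if excl is not None:
        return excl

    missing = []
    if CLASSIFIER_SAG_STEP not in fv.sag:
        missing.append(f"sag at {CLASSIFIER_SAG_STEP:g} pA")
    if CLASSIFIER_REBOUND_STEP not in fv.rebound:
        missing.append(f"rebound at {CLASSIFIER_REBOUND_STEP:g} pA")
    if missing:
        raise ClassificationError(f"{fv.neuron_id}: missing {', '.join(missing)}")

    depol = {a: c for a, c in fv.evoked_spikes.items() if a > 0}
    below = [c for a, c in depol.items() if a < others_current_threshold]
    max_spikes = max(depol.values())
    if below and all(c == 0 for c in below) and max_spikes <= others_max_spikes:
        return TypeLabel(
            "Others",
            f"late firing: silent below {others_current_threshold:g} pA, "
            f"max {max_spikes} spike(s) per step",
        )

    sag = fv.sag[CLASSIFIER_SAG_STEP]
    reb = fv.rebound[CLASSIFIER_REBOUND_STEP]
    if reb >= 1:
        note = "rebound spikes at -80 pA"
        if sag < sag_threshold:
            note += " (rebound without sag)"
        return TypeLabel("II", note)
    if sag >= sag_threshold:
        return TypeLabel("I", f"sag {sag:.1f} mV >= {sag_threshold:g} mV, no rebound")
    return TypeLabel("III", "no sag, no rebound")


def classify_cohort(fvs: Iterable[FeatureVector], **kw) -> dict[str, TypeLabel]:
    return {fv.neuron_id: classify_neuron(fv, **kw) for fv in fvs}


def proportions(labels: Iterable[TypeLabel] | Iterable[str]) -> dict:
    """Per-type counts and percentages over the classified (non-excluded) total.

    Percentages are reported to two decimals and computed over neurons that
    received one of the four labels.
    """
    names = [lb.label if isinstance(lb, TypeLabel) else str(lb) for lb in labels]
    counts = {t: names.count(t) for t in LABELS}
    n_excluded = names.count("Excluded")
    total = sum(counts.values())
    pct = {t: (round(100.0 * c / total, 2) if total else 0.0)
           for t, c in counts.items()}
    return {
        "counts": counts,
        "percent": pct,
        "total_classified": total,
        "excluded": n_excluded,
    }
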