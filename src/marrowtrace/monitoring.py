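"""Longitudinal two-timepoint molecular classification.

Each patient's mutation burden per analyte is summarized as the mean VAF
over a mutation class (drivers = JAK2/CALR/MPL; everything else
non-driver) at two treatment timepoints T1 and T2.  The change
``delta = VAF(T2) - VAF(T1)`` in absolute VAF points is classified:

* ``delta <= -0.05`` -> molecular response
* ``delta >= +0.05`` -> molecular resistance
* otherwise        -> stable

with disease progression flagged at ``delta >= +0.10``.  Both boundaries
are inclusive.  Cohort-level summaries report the per-analyte proportions
of each category and the cross-analyte agreement, the quantities used to
contrast cfDNA (more sensitive to emerging resistance) with gDNA (more
often confirming response).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import ValidationError, VariantObservation, round_half_up

logger = logging.getLogger("marrowtrace")

DRIVER_GENES = frozenset({"JAK2", "CALR", "MPL"})
CATEGORIES = ("response", "stable", "resistance")

# guard against binary rounding when a VAF difference printed at the
# threshold (e.g. 0.45 -> 0.50) lands a few ulp short of it
_EPS = 1e-12

__all__ = [
    "DRIVER_GENES",
    "MolecularCall",
    "summarize_patient_vaf",
    "classify_molecular",
    "call_patients",
    "cohort_classification",
    "group_delta_summary",
]


@dataclass(frozen=True)
class MolecularCall:
    """Per-patient, per-analyte molecular response classification."""

    patient_id: str
    analyte: str
    delta_vaf: float  # T2 - T1 summary VAF, fraction scale
    category: str
    progression: bool
    mutation_class: str = "all"

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValidationError(f"invalid category {self.category!r}")


def _in_class(gene: str, mutation_class: str) -> bool:
    if mutation_class == "all":
        return True
    if mutation_class == "driver":
        return gene in DRIVER_GENES
    if mutation_class == "non_driver":
        return gene not in DRIVER_GENES
    raise ValidationError("mutation_class must be 'driver', 'non_driver' or 'all'")


def summarize_patient_vaf(
    observations: Iterable[VariantObservation],
    analyte: str,
    mutation_class: str = "all",
    threshold: float = 0.02,
) -> float | None:
    """Unweighted mean VAF over one patient-timepoint's detected mutations
    of a class, or None when nothing in the class is detected."""
    vafs = [
        o.vaf
        for o in observations
        if o.analyte == analyte and o.vaf > threshold and _in_class(o.gene, mutation_class)
    ]
    if not vafs:
        return None
    return float(np.mean(vafs))


def classify_molecular(
    vaf_t1: float | None,
    vaf_t2: float | None,
    response_thr: float = 0.05,
    progression_thr: float = 0.10,
    relative: bool = False,
) -> tuple[float, str, bool]:
    """Classify a two-timepoint VAF change.

    Returns ``(delta, category, progression)`` where ``delta = vaf_t2 -
    vaf_t1`` in absolute VAF points (or the relative change
    ``delta / vaf_t1`` when ``relative=True``).  Thresholds are inclusive.
    """
    if vaf_t1 is None or vaf_t2 is None:
        which = "T1" if vaf_t1 is None else "T2"
        raise ValidationError(f"missing {which} summary VAF; cannot classify")
    if not (0 < response_thr < 1 and 0 < progression_thr < 1):
        raise ValidationError("thresholds must be in (0,1)")
    delta = vaf_t2 - vaf_t1
    if relative:
        if vaf_t1 <= 0:
            raise ValidationError("relative change undefined at vaf_t1 = 0")
        delta = delta / vaf_t1
    if delta <= -(response_thr - _EPS):
        category = "response"
    elif delta >= response_thr - _EPS:
        category = "resistance"
    else:
        category = "stable"
    progression = delta >= progression_thr - _EPS
    return delta, category, progression


def call_patients(
    observations: Iterable[VariantObservation],
    analyte: str,
    t1: str = "T1",
    t2: str = "T2",
    mutation_class: str = "all",
    threshold: float = 0.02,
    response_thr: float = 0.05,
    progression_thr: float = 0.10,
    relative: bool = False,
) -> list[MolecularCall]:
    """Per-patient molecular calls for one analyte across two timepoints.

    Patients missing a detected summary at either timepoint are skipped
    with a log entry (no imputation)."""
    obs = list(observations)
    patients = sorted({o.patient_id for o in obs})
    calls = []
    for pid in patients:
        mine = [o for o in obs if o.patient_id == pid]
        s1 = summarize_patient_vaf(
            [o for o in mine if o.timepoint == t1], analyte, mutation_class, threshold
        )
        s2 = summarize_patient_vaf(
            [o for o in mine if o.timepoint == t2], analyte, mutation_class, threshold
        )
        if s1 is None or s2 is None:
            logger.info(
                "patient %s skipped for %s: no detected %s mutations at %s",
                pid, analyte, mutation_class, t1 if s1 is None else t2,
            )
            continue
        delta, category, progression = classify_molecular(
            s1, s2, response_thr, progression_thr, relative
        )
        calls.append(
            MolecularCall(
                patient_id=pid,
                analyte=analyte,
                delta_vaf=delta,
                category=category,
                progression=progression,
                mutation_class=mutation_class,
            )
        )
    return calls


def cohort_classification(calls: Sequence[MolecularCall]) -> dict:
    """Per-analyte category proportions plus the cross-analyte agreement.

    Proportions are count/total*100 rounded half-up to one decimal; the
    contingency counts patients with calls in two analytes that agree or
    disagree on the category.
    """
    if not calls:
        raise ValidationError("cohort_classification requires at least one call")
    analytes = sorted({c.analyte for c in calls})
    summary: dict = {"analytes": {}}
    for analyte in analytes:
        mine = [c for c in calls if c.analyte == analyte]
        total = len(mine)
        entry = {"n": total, "proportions": {}, "progression_pct": 0.0}
        for cat in CATEGORIES:
            count = sum(c.category == cat for c in mine)
            entry["proportions"][cat] = round_half_up(100.0 * count / total)
        entry["progression_pct"] = round_half_up(
            100.0 * sum(c.progression for c in mine) / total
        )
        summary["analytes"][analyte] = entry

    if len(analytes) == 2:
        a, b = analytes
        cat_a = {c.patient_id: c.category for c in calls if c.analyte == a}
        cat_b = {c.patient_id: c.category for c in calls if c.analyte == b}
        shared = sorted(set(cat_a) & set(cat_b))
        concordant = sum(cat_a[p] == cat_b[p] for p in shared)
        summary["cross_analyte"] = {
            "n_shared": len(shared),
            "concordant": concordant,
            "discordant": len(shared) - concordant,
        }
    return summary


def group_delta_summary(
    calls: Sequence[MolecularCall],
    groups: Mapping[str, str],
) -> dict:
    """Per-group mean VAF change per analyte with a paired cross-analyte
    test.

    ``groups`` maps patient_id to a label (hematologic response category,
    treatment regimen, ...).  Within each group the summary reports mean
    and SEM of delta-VAF per analyte, and a two-sided paired t-test
    between the two analytes' deltas over patients called in both.
    Groups of size one are reported without a test and flagged.
    """
    if not calls:
        raise ValidationError("group_delta_summary requires calls")
    analytes = sorted({c.analyte for c in calls})
    by_pa = {(c.patient_id, c.analyte): c.delta_vaf for c in calls}
    labels = sorted(set(groups.values()))
    out: dict = {}
    for label in labels:
        members = sorted(p for p, g in groups.items() if g == label)
        entry: dict = {"n_patients": len(members), "analytes": {}}
        for analyte in analytes:
            deltas = [by_pa[(p, analyte)] for p in members if (p, analyte) in by_pa]
            if deltas:
                entry["analytes"][analyte] = {
                    "n": len(deltas),
                    "mean_delta": float(np.mean(deltas)),
                    "sem_delta": float(stats.sem(deltas)) if len(deltas) > 1 else float("nan"),
                }
        if len(analytes) == 2:
            a, b = analytes
            paired = [
                (by_pa[(p, a)], by_pa[(p, b)])
                for p in members
                if (p, a) in by_pa and (p, b) in by_pa
            ]
            if len(paired) >= 2:
                xa = np.array([x for x, _ in paired])
                xb = np.array([y for _, y in paired])
                if np.std(xa - xb) == 0:
                    entry["paired_p"] = float("nan")
                    entry["flag"] = "identical deltas; test undefined"
                else:
                    entry["paired_p"] = float(stats.ttest_rel(xa, xb).pvalue)
            else:
                entry["paired_p"] = float("nan")
                entry["flag"] = "group too small for paired test"
        out[label] = entry
    return out
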