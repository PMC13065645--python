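"""Cross-analyte VAF concordance statistics.

Paired cfDNA / gDNA variant observations are joined on
(patient, gene, mutation, timepoint), detection is called at a strict
VAF threshold (default 2%), and the module computes:

* overlap accounting — how many mutations each analyte detected,
  both / cfDNA-only / gDNA-only, as counts and percentages;
* the per-gene cfDNA advantage — the mean relative VAF difference
  (cfDNA - gDNA) / gDNA over both-detected pairs, in percent, with a
  paired test and a test-selection recommendation label;
* cfDNA vs gDNA VAF correlation (Pearson or Spearman);
* stratified comparisons by white-blood-cell count (threshold or
  quartiles), where gDNA is expected to be count-dependent and cfDNA
  relatively stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .io import (
    ClinicalRecord,
    ValidationError,
    VariantObservation,
    round_half_up,
)

__all__ = [
    "PairedVariant",
    "AdvantageStat",
    "pair_variants",
    "overlap_summary",
    "cfdna_advantage",
    "advantage_table",
    "vaf_correlation",
    "stratify_by_wbc",
    "recommend",
]


@dataclass(frozen=True)
class PairedVariant:
    """One mutation matched across cfDNA and gDNA at one timepoint.

    ``vaf_cf`` / ``vaf_g`` are None when the analyte did not report the
    mutation at all; detection additionally requires the VAF to exceed
    the reporting threshold.
    """

    patient_id: str
    gene: str
    mutation: str
    timepoint: str
    vaf_cf: float | None
    vaf_g: float | None
    detected_cf: bool
    detected_g: bool

    @property
    def both_detected(self) -> bool:
        return self.detected_cf and self.detected_g


@dataclass
class AdvantageStat:
    """Gene-level cfDNA advantage: mean relative VAF difference in percent."""

    gene: str
    n: int
    mean_advantage: float  # percent
    p_value: float  # NaN flags an undefined paired test (zero variance)
    recommendation: str

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValidationError("AdvantageStat requires n >= 1")
        if not math.isfinite(self.mean_advantage):
            raise ValidationError("mean advantage must be finite")


def pair_variants(
    observations: Iterable[VariantObservation],
    threshold: float = 0.02,
    gdna_analyte: str = "gDNA_PB",
) -> list[PairedVariant]:
    """Join cfDNA and gDNA observations into pairs with detection flags.

    Detection is strict: ``vaf > threshold`` (a VAF exactly at the
    threshold is not reported, per the '>2%' convention).  Only keys where
    at least one analyte is detected yield a pair.
    """
    by_key: dict[tuple, dict[str, float]] = {}
    for obs in observations:
        if obs.analyte not in ("cfDNA", gdna_analyte):
            continue
        slot = by_key.setdefault(obs.key, {})
        if obs.analyte in slot:
            raise ValidationError(
                f"duplicate observation for {obs.key} / {obs.analyte}"
            )
        slot[obs.analyte] = obs.vaf

    pairs = []
    for key in sorted(by_key):
        vafs = by_key[key]
        vaf_cf = vafs.get("cfDNA")
        vaf_g = vafs.get(gdna_analyte)
        detected_cf = vaf_cf is not None and vaf_cf > threshold
        detected_g = vaf_g is not None and vaf_g > threshold
        if not (detected_cf or detected_g):
            continue
        pairs.append(
            PairedVariant(
                patient_id=key[0],
                gene=key[1],
                mutation=key[2],
                timepoint=key[3],
                vaf_cf=vaf_cf,
                vaf_g=vaf_g,
                detected_cf=detected_cf,
                detected_g=detected_g,
            )
        )
    return pairs


def overlap_summary(pairs: Sequence[PairedVariant]) -> dict:
    """Counts and percentages for {both, cfDNA_only, gDNA_only}.

    Percentages are count/total*100 rounded half-up to one decimal, the
    convention of clinical overlap reporting.
    """
    if not pairs:
        raise ValidationError("overlap_summary requires at least one pair")
    both = sum(p.both_detected for p in pairs)
    cf_only = sum(p.detected_cf and not p.detected_g for p in pairs)
    g_only = sum(p.detected_g and not p.detected_cf for p in pairs)
    total = len(pairs)
    assert both + cf_only + g_only == total
    return {
        "total": total,
        "counts": {"both": both, "cfDNA_only": cf_only, "gDNA_only": g_only},
        "percentages": {
            "both": round_half_up(100.0 * both / total),
            "cfDNA_only": round_half_up(100.0 * cf_only / total),
            "gDNA_only": round_half_up(100.0 * g_only / total),
        },
    }


def recommend(mean_advantage_pct: float, p_value: float) -> str:
    """Map a gene's advantage and paired-test p-value to a test-selection
    label.

    Rubric: advantage >= 30% with p < 0.05 -> 'Prioritize cfDNA';
    >= 30% with p < 0.10 -> 'cfDNA preferred'; > 5% otherwise ->
    'Consider cfDNA'; <= 5% -> 'Consider gDNA'.
    """
    if mean_advantage_pct >= 30.0 and p_value < 0.05:
        return "Prioritize cfDNA"
    if mean_advantage_pct >= 30.0 and p_value < 0.10:
        return "cfDNA preferred"
    if mean_advantage_pct > 5.0:
        return "Consider cfDNA"
    return "Consider gDNA"


def _paired_ttest(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided paired t-test p-value; NaN when the differences have zero
    variance (identical vectors), which is flagged rather than reported
    as a spurious 0 or 1."""
    if len(x) < 2 or np.std(x - y) == 0:
        return float("nan")
    with np.errstate(invalid="ignore"):
        return float(stats.ttest_rel(x, y).pvalue)


def cfdna_advantage(
    pairs: Sequence[PairedVariant],
    gene: str | None = None,
    test: str = "ttest",
) -> AdvantageStat:
    """Gene-level (or overall, ``gene=None``) cfDNA advantage statistic.

    Only both-detected pairs qualify, guaranteeing ``vaf_g > 0`` so the
    relative difference is defined.  ``test`` selects the paired
    comparison: two-sided t-test (default) or Wilcoxon signed-rank.
    """
    qual = [
        p for p in pairs
        if p.both_detected and (gene is None or p.gene == gene)
    ]
    if not qual:
        raise ValidationError(
            f"no both-detected pairs for gene {gene if gene else '(all)'}"
        )
    cf = np.array([p.vaf_cf for p in qual])
    g = np.array([p.vaf_g for p in qual])
    advantage = float(np.mean((cf - g) / g) * 100.0)
    if test == "wilcoxon":
        if len(qual) < 2 or np.all(cf == g):
            p_value = float("nan")
        else:
            p_value = float(stats.wilcoxon(cf, g).pvalue)
    else:
        p_value = _paired_ttest(cf, g)
    rec = recommend(advantage, p_value if math.isfinite(p_value) else 1.0)
    return AdvantageStat(
        gene=gene if gene else "all",
        n=len(qual),
        mean_advantage=advantage,
        p_value=p_value,
        recommendation=rec,
    )


def advantage_table(pairs: Sequence[PairedVariant], test: str = "ttest") -> list[AdvantageStat]:
    """Per-gene advantage statistics over every gene with at least one
    both-detected pair, ordered by descending advantage."""
    genes = sorted({p.gene for p in pairs if p.both_detected})
    table = [cfdna_advantage(pairs, gene=g, test=test) for g in genes]
    return sorted(table, key=lambda a: -a.mean_advantage)


def vaf_correlation(
    pairs: Sequence[PairedVariant], method: str = "pearson"
) -> tuple[float, float]:
    """Correlation of cfDNA vs gDNA VAF over both-detected pairs."""
    qual = [p for p in pairs if p.both_detected]
    if len(qual) < 3:
        raise ValidationError("correlation requires at least 3 both-detected pairs")
    cf = np.array([p.vaf_cf for p in qual])
    g = np.array([p.vaf_g for p in qual])
    if np.ptp(cf) == 0 or np.ptp(g) == 0:
        raise ValidationError("zero variance in a VAF vector; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(g, cf)
    elif method == "spearman":
        r, p = stats.spearmanr(g, cf)
    else:
        raise ValidationError("method must be 'pearson' or 'spearman'")
    return float(r), float(p)


# ---------------------------------------------------------------------------
# hematologic stratification
# ---------------------------------------------------------------------------


def _join_wbc(
    pairs: Sequence[PairedVariant], clinical: Sequence[ClinicalRecord]
) -> list[tuple[PairedVariant, float]]:
    wbc_by_key = {(c.patient_id, c.timepoint): c.wbc for c in clinical}
    joined = []
    for p in pairs:
        key = (p.patient_id, p.timepoint)
        if key not in wbc_by_key:
            raise ValidationError(f"no clinical WBC for pair {key}")
        joined.append((p, wbc_by_key[key]))
    return joined


def _stratum_stats(members: list[PairedVariant]) -> dict:
    out: dict = {"n_pairs": len(members)}
    if len(members) < 2:
        out["insufficient"] = True
        return out
    out["insufficient"] = False
    both = [p for p in members if p.both_detected]
    cf = np.array([p.vaf_cf for p in members if p.detected_cf])
    g = np.array([p.vaf_g for p in members if p.detected_g])
    out["mean_vaf_cf"] = float(cf.mean()) if cf.size else float("nan")
    out["mean_vaf_g"] = float(g.mean()) if g.size else float("nan")
    if len(both) >= 2:
        out["paired_p"] = _paired_ttest(
            np.array([p.vaf_cf for p in both]), np.array([p.vaf_g for p in both])
        )
    else:
        out["paired_p"] = float("nan")
    return out


def stratify_by_wbc(
    pairs: Sequence[PairedVariant],
    clinical: Sequence[ClinicalRecord],
    mode: str = "threshold",
    threshold: float = 10.0,
) -> dict:
    """Stratify paired VAFs by white-blood-cell count.

    ``threshold`` mode splits at the given WBC (x10^9/L; 'high' is closed
    on the left, i.e. wbc >= threshold).  ``quartiles`` mode uses patient-
    level WBC quartile boundaries (25/50/75th percentiles with linear
    interpolation; strata closed on the left).  Each stratum reports mean
    VAF per analyte and a within-stratum paired cfDNA-vs-gDNA t-test;
    across-strata two-sample t-tests per analyte compare low vs high
    (threshold mode) or Q1 vs Q4 (quartile mode).  Strata with fewer than
    two pairs are reported as insufficient rather than dropped.
    """
    joined = _join_wbc(pairs, clinical)
    if mode == "threshold":
        strata = {
            f"wbc<{threshold:g}": [p for p, w in joined if w < threshold],
            f"wbc>={threshold:g}": [p for p, w in joined if w >= threshold],
        }
        compare = list(strata)
    elif mode == "quartiles":
        patient_wbc = {}
        for p, w in joined:
            patient_wbc.setdefault(p.patient_id, w)
        if len(patient_wbc) < 8:
            raise ValidationError("quartile stratification requires >= 8 patients")
        q25, q50, q75 = np.percentile(
            list(patient_wbc.values()), [25, 50, 75], method="linear"
        )
        def quartile(w: float) -> str:
            if w < q25:
                return "Q1"
            if w < q50:
                return "Q2"
            if w < q75:
                return "Q3"
            return "Q4"
        strata = {q: [] for q in ("Q1", "Q2", "Q3", "Q4")}
        for p, w in joined:
            strata[quartile(w)].append(p)
        compare = ["Q1", "Q4"]
    else:
        raise ValidationError("mode must be 'threshold' or 'quartiles'")

    result: dict = {"mode": mode, "strata": {}}
    if mode == "threshold":
        result["threshold"] = threshold
    else:
        result["boundaries"] = {"q25": float(q25), "q50": float(q50), "q75": float(q75)}
    for label, members in strata.items():
        result["strata"][label] = _stratum_stats(members)

    across: dict = {}
    lo, hi = (strata[compare[0]], strata[compare[1]])
    for analyte, pick, flag in (
        ("cfDNA", lambda p: p.vaf_cf, lambda p: p.detected_cf),
        ("gDNA", lambda p: p.vaf_g, lambda p: p.detected_g),
    ):
        a = np.array([pick(p) for p in lo if flag(p)])
        b = np.array([pick(p) for p in hi if flag(p)])
        if len(a) >= 2 and len(b) >= 2 and np.ptp(np.concatenate([a, b])) > 0:
            across[analyte] = float(stats.ttest_ind(a, b).pvalue)
        else:
            across[analyte] = float("nan")
    result["across_strata_p"] = across
    result["compared_strata"] = compare
    return result
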