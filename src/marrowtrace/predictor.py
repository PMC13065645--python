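"""Lymphocyte-percentage predictor of cfDNA advantage and test selection.

In MPN monitoring the relative VAF advantage of plasma cfDNA over
peripheral-blood gDNA grows with the lymphocyte fraction of the
differential count: lymphocyte predominance dilutes the circulating
myeloid clone in gDNA, whereas marrow-derived cfDNA is comparatively
unaffected.  This module fits the ordinary-least-squares line

    advantage% = intercept + slope * LYMPH%

at the patient level, applies it, and combines the lymphocyte rule
(LYMPH% above a cutoff, default 20%) with gene-level advantage labels
into a cfDNA / gDNA / dual test recommendation.

Advantage is expressed in percent throughout this module so fitted
coefficients are on the scale clinicians read.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .concordance import AdvantageStat, PairedVariant
from .io import ValidationError

__all__ = [
    "LymphModel",
    "patient_advantage",
    "fit_lymph_model",
    "predict_advantage",
    "select_test",
]

_CF_LABELS = {"Prioritize cfDNA", "cfDNA preferred"}


@dataclass
class LymphModel:
    """Linear model of per-patient cfDNA advantage (%) on lymphocyte %."""

    intercept: float  # advantage-% at LYMPH% = 0
    slope: float  # advantage-% per lymphocyte-%
    r: float  # Pearson correlation; NaN when the response is constant
    n: int
    p_value: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValidationError("LymphModel requires n >= 3")
        if math.isfinite(self.r) and abs(self.r) > 1 + 1e-12:
            raise ValidationError("|r| must be <= 1")

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=2)

    @classmethod
    def from_json(cls, path: str | Path) -> "LymphModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def patient_advantage(pairs: Sequence[PairedVariant]) -> float:
    """Mean relative advantage (cfDNA - gDNA)/gDNA across one patient's
    both-detected pairs, in percent."""
    qual = [p for p in pairs if p.both_detected]
    if not qual:
        raise ValidationError(
            "patient advantage undefined: no both-detected mutation pairs"
        )
    return float(np.mean([(p.vaf_cf - p.vaf_g) / p.vaf_g for p in qual]) * 100.0)


def fit_lymph_model(points: Sequence[tuple[float, float]]) -> LymphModel:
    """Ordinary least squares of advantage-% on lymphocyte-%.

    ``points`` are per-patient ``(lymph_pct, advantage_pct)``.  A constant
    response yields slope 0 and ``r = NaN`` (correlation undefined); a
    constant predictor is an error.
    """
    if len(points) < 3:
        raise ValidationError("fit requires at least 3 points")
    x = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if np.std(x) == 0:
        raise ValidationError("zero variance in lymphocyte percentage; fit undefined")
    if np.std(y) == 0:
        return LymphModel(
            intercept=float(y[0]), slope=0.0, r=float("nan"),
            n=len(points), p_value=float("nan"),
        )
    fit = stats.linregress(x, y)
    return LymphModel(
        intercept=float(fit.intercept),
        slope=float(fit.slope),
        r=float(fit.rvalue),
        n=len(points),
        p_value=float(fit.pvalue),
    )


def predict_advantage(model: LymphModel, lymph_pct: float) -> float:
    """Predicted cfDNA advantage (%) at a lymphocyte percentage."""
    if not 0.0 <= lymph_pct <= 100.0:
        raise ValidationError("lymph_pct must lie in [0,100]")
    return model.intercept + model.slope * lymph_pct


def select_test(
    lymph_pct: float | None,
    genes: Sequence[str],
    advantage_table: Mapping[str, AdvantageStat | str],
    cutoff: float = 20.0,
    decision_point: bool = False,
) -> str:
    """Recommend the monitoring analyte for a patient.

    Either signal suffices for cfDNA: lymphocyte percentage strictly above
    ``cutoff``, or any panel gene labelled 'Prioritize cfDNA' /
    'cfDNA preferred'.  gDNA is recommended only when every gene maps to
    'Consider gDNA' and the lymphocyte rule does not fire.  'dual' is
    emitted only at a flagged decision point when the lymphocyte-level and
    gene-level signals conflict.  The rule is monotone in ``lymph_pct``:
    raising it never flips a cfDNA recommendation to gDNA.
    """
    if lymph_pct is None and not genes:
        raise ValidationError("need a lymphocyte percentage or a gene list")

    def label(g: str) -> str:
        entry = advantage_table.get(g)
        if entry is None:
            raise ValidationError(f"gene {g!r} not in the advantage table")
        return entry if isinstance(entry, str) else entry.recommendation

    labels = [label(g) for g in genes]
    lymph_cf = lymph_pct is not None and lymph_pct > cutoff
    gene_cf = any(l in _CF_LABELS for l in labels)
    gene_g = bool(labels) and all(l == "Consider gDNA" for l in labels)

    if decision_point and ((lymph_cf and gene_g) or (not lymph_cf and gene_cf)):
        return "dual"
    if lymph_cf or gene_cf:
        return "cfDNA"
    if gene_g:
        return "gDNA"
    # remaining genes lean cfDNA ('Consider cfDNA') without a strong signal
    return "cfDNA" if labels else "gDNA"
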