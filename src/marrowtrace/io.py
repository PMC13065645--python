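"""Readers, writers, configuration and shared validation for the tabular
formats the pipeline touches.

Conventions enforced at this boundary:

* Methylation beta values live in ``[0, 1]``; missing cells are carried as
  ``NaN`` in the matrix and flagged through :attr:`MethylationMatrix.missing`,
  never silently zeroed or imputed.
* Variant allele frequencies (VAF) are stored internally as fractions in
  ``[0, 1]``.  Tables reported in percent are converted here, once, so that
  downstream arithmetic is never mixed-scale.
* Analyte labels are restricted to ``cfDNA`` (plasma cell-free DNA),
  ``gDNA_PB`` (peripheral-blood genomic DNA) and ``gDNA_BM`` (bone-marrow
  genomic DNA).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("marrowtrace")

ANALYTES = ("cfDNA", "gDNA_PB", "gDNA_BM")
MISSING_TOKENS = {"", "NA", "NaN", "nan", "na", "null", "None", "."}

__all__ = [
    "ANALYTES",
    "MethylationMatrix",
    "VariantObservation",
    "ClinicalRecord",
    "RunConfig",
    "ValidationError",
    "read_methylation_matrix",
    "write_methylation_matrix",
    "read_variant_table",
    "write_variant_table",
    "read_clinical_table",
    "write_clinical_table",
    "round_half_up",
]


class ValidationError(ValueError):
    """Raised when an input file or record violates a documented invariant."""


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero, matching how clinical tables print
    percentages (``89.65 -> 89.7``), unlike banker's rounding."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class MethylationMatrix:
    """CpG x sample matrix of methylation beta values.

    ``betas`` is dense float64 with ``NaN`` marking missing cells; the
    boolean ``missing`` mask is derived and kept consistent.
    """

    cpg_ids: list[str]
    sample_ids: list[str]
    betas: np.ndarray

    def __post_init__(self) -> None:
        self.cpg_ids = list(self.cpg_ids)
        self.sample_ids = list(self.sample_ids)
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.cpg_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.betas.shape} does not match "
                f"{len(self.cpg_ids)} CpGs x {len(self.sample_ids)} samples"
            )
        for name, ids in (("CpG", self.cpg_ids), ("sample", self.sample_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValidationError(f"duplicate {name} ids: {dupes[:5]}")
        finite = self.betas[np.isfinite(self.betas)]
        if finite.size and (finite.min() < -1e-9 or finite.max() > 1 + 1e-9):
            bad = np.argwhere(
                np.isfinite(self.betas) & ((self.betas < -1e-9) | (self.betas > 1 + 1e-9))
            )[0]
            raise ValidationError(
                f"beta outside [0,1] at CpG {self.cpg_ids[bad[0]]!r}, "
                f"sample {self.sample_ids[bad[1]]!r}: {self.betas[bad[0], bad[1]]}"
            )

    @property
    def missing(self) -> np.ndarray:
        return ~np.isfinite(self.betas)

    @property
    def shape(self) -> tuple[int, int]:
        return self.betas.shape

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.betas, index=self.cpg_ids, columns=self.sample_ids)

    def sample(self, sample_id: str) -> pd.Series:
        """Per-CpG betas of one sample as a Series indexed by CpG id."""
        j = self.sample_ids.index(sample_id)
        return pd.Series(self.betas[:, j], index=self.cpg_ids, name=sample_id)


@dataclass(frozen=True)
class VariantObservation:
    """A single VAF measurement of one mutation in one analyte."""

    patient_id: str
    gene: str
    mutation: str
    analyte: str
    timepoint: str
    vaf: float

    def __post_init__(self) -> None:
        if self.analyte not in ANALYTES:
            raise ValidationError(
                f"unknown analyte {self.analyte!r}; permitted: {list(ANALYTES)}"
            )
        if not 0.0 <= self.vaf <= 1.0:
            raise ValidationError(
                f"VAF {self.vaf} outside [0,1] for {self.patient_id}/{self.gene}"
                f"/{self.mutation}/{self.analyte}/{self.timepoint}"
            )

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.patient_id, self.gene, self.mutation, self.timepoint)


@dataclass(frozen=True)
class ClinicalRecord:
    """Complete-blood-count covariates and labels for one patient-timepoint."""

    patient_id: str
    timepoint: str
    wbc: float  # x10^9/L
    lymph_pct: float  # % of differential
    hct: float = float("nan")  # %
    plt: float = float("nan")  # x10^9/L
    hgb: float = float("nan")  # g/L
    treatment: str = "unknown"
    hematologic_response: str = "unknown"

    def __post_init__(self) -> None:
        if self.wbc < 0:
            raise ValidationError(f"negative WBC for {self.patient_id}/{self.timepoint}")
        if not 0.0 <= self.lymph_pct <= 100.0:
            raise ValidationError(
                f"lymph_pct {self.lymph_pct} outside [0,100] for "
                f"{self.patient_id}/{self.timepoint}"
            )
        if self.hematologic_response not in ("CR", "PR", "NR", "unknown"):
            raise ValidationError(
                f"hematologic_response must be CR/PR/NR/unknown, "
                f"got {self.hematologic_response!r}"
            )


@dataclass
class RunConfig:
    """All printed thresholds of the analysis chain in one place.

    Thresholds are on the fraction scale except ``lymph_cutoff`` which is a
    percentage, matching how the rule is stated clinically.
    """

    atlas_k: int = 582
    min_delta: float = 0.2
    vaf_threshold: float = 0.02  # detection: VAF strictly above
    response_threshold: float = 0.05  # molecular response/resistance
    progression_threshold: float = 0.10  # disease progression
    lymph_cutoff: float = 20.0  # % lymphocytes favouring cfDNA testing
    seed: int = 0
    lod_replicates: int = 50
    lod_reliability: float = 0.95

    def __post_init__(self) -> None:
        for name in ("vaf_threshold", "response_threshold", "progression_threshold"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValidationError(f"{name} must be in (0,1), got {v}")
        if not 0.0 < self.lod_reliability < 1.0:
            raise ValidationError("lod_reliability must be in (0,1)")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.__dict__, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# methylation matrix I/O
# ---------------------------------------------------------------------------


def _sniff_delimiter(path: Path) -> str:
    with open(path) as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_methylation_matrix(path: str | Path, dialect: str | None = None) -> MethylationMatrix:
    """Read a CpG x sample beta matrix from TSV/CSV.

    First column: CpG identifiers; header row: sample ids.  Cells must be
    numeric in [0,1] or an explicit missing token (NA and friends).
    Delimiter is auto-detected between tab and comma unless ``dialect``
    is given.
    """
    path = Path(path)
    sep = dialect or _sniff_delimiter(path)
    raw = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    cpg_ids = [str(i) for i in raw.index]
    sample_ids = [str(c) for c in raw.columns]
    betas = np.full(raw.shape, np.nan)
    for j, col in enumerate(raw.columns):
        for i, cell in enumerate(raw[col]):
            cell = cell.strip()
            if cell in MISSING_TOKENS:
                continue
            try:
                betas[i, j] = float(cell)
            except ValueError:
                raise ValidationError(
                    f"{path.name}: malformed numeric cell {cell!r} at "
                    f"CpG {cpg_ids[i]!r}, sample {sample_ids[j]!r}"
                ) from None
    return MethylationMatrix(cpg_ids, sample_ids, betas)


def write_methylation_matrix(
    matrix: MethylationMatrix, path: str | Path, dialect: str = "\t"
) -> None:
    matrix.to_frame().to_csv(path, sep=dialect, index_label="cpg_id", na_rep="NA")


# ---------------------------------------------------------------------------
# variant table I/O
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["patient_id", "gene", "mutation", "analyte", "timepoint", "vaf"]


def read_variant_table(
    path: str | Path, vaf_units: str = "fraction", dialect: str | None = None
) -> list[VariantObservation]:
    """Read a curated variant table into validated observations.

    ``vaf_units`` declares the scale of the file's ``vaf`` column
    (``fraction`` or ``percent``); values are normalized to fractions.
    Normalizing an already-fraction table is a no-op by construction.
    """
    if vaf_units not in ("fraction", "percent"):
        raise ValidationError("vaf_units must be 'fraction' or 'percent'")
    path = Path(path)
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, dtype={c: str for c in _VARIANT_COLUMNS[:-1]},
        float_precision="round_trip",
    )
    missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path.name}: missing columns {missing}")
    if df.empty:
        logger.warning("%s: variant table is empty", path.name)
        return []
    scale = 0.01 if vaf_units == "percent" else 1.0
    obs = [
        VariantObservation(
            patient_id=row.patient_id,
            gene=row.gene,
            mutation=row.mutation,
            analyte=row.analyte,
            timepoint=row.timepoint,
            vaf=float(row.vaf) * scale,
        )
        for row in df.itertuples()
    ]
    return obs


def write_variant_table(
    observations: Iterable[VariantObservation], path: str | Path
) -> None:
    df = pd.DataFrame([o.__dict__ for o in observations], columns=_VARIANT_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# clinical table I/O
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = [
    "patient_id",
    "timepoint",
    "wbc",
    "lymph_pct",
    "hct",
    "plt",
    "hgb",
    "treatment",
    "hematologic_response",
]


def read_clinical_table(path: str | Path, dialect: str | None = None) -> list[ClinicalRecord]:
    """Read the clinical covariate table keyed on (patient_id, timepoint)."""
    path = Path(path)
    sep = dialect or _sniff_delimiter(path)
    df = pd.read_csv(
        path, sep=sep, dtype={"patient_id": str, "timepoint": str},
        float_precision="round_trip",
    )
    required = {"patient_id", "timepoint", "wbc", "lymph_pct"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"{path.name}: missing columns {sorted(missing)}")
    records = []
    seen: set[tuple[str, str]] = set()
    for row in df.itertuples():
        key = (row.patient_id, row.timepoint)
        if key in seen:
            raise ValidationError(f"{path.name}: duplicate (patient, timepoint) {key}")
        seen.add(key)
        records.append(
            ClinicalRecord(
                patient_id=row.patient_id,
                timepoint=row.timepoint,
                wbc=float(row.wbc),
                lymph_pct=float(row.lymph_pct),
                hct=float(getattr(row, "hct", np.nan)),
                plt=float(getattr(row, "plt", np.nan)),
                hgb=float(getattr(row, "hgb", np.nan)),
                treatment=str(getattr(row, "treatment", "unknown")),
                hematologic_response=str(getattr(row, "hematologic_response", "unknown")),
            )
        )
    return records


def write_clinical_table(records: Iterable[ClinicalRecord], path: str | Path) -> None:
    df = pd.DataFrame([r.__dict__ for r in records], columns=_CLINICAL_COLUMNS)
    df.to_csv(path, sep="\t", index=False, float_format="%.17g")
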