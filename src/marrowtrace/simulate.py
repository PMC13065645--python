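"""Synthetic data with the statistical structure the analysis assumes.

Two generators:

* **Methylation**: healthy BM / PB reference profiles with a planted set
  of discriminative CpGs (tissue means separated by a chosen delta-beta,
  balanced hyper/hypo directions) over a uniform background, plus
  two-tissue mixture samples at known BM fractions — the inputs for atlas
  construction, deconvolution recovery and limit-of-detection experiments.

* **Paired cohort**: patients carrying one MPN driver (JAK2/CALR/MPL)
  and optionally one non-driver mutation, measured in cfDNA and PB gDNA
  at two treatment timepoints.  cfDNA VAF is the true clonal VAF times a
  gene-specific shedding multiplier (megakaryocyte-biology genes such as
  CALR and MPL shed preferentially); gDNA VAF is the true VAF diluted
  linearly by the lymphocyte percentage (lymphoid cells crowd the myeloid
  clone out of the nucleated-cell compartment); treatment shifts T2 VAFs
  per regimen; WBC is generated correlated with the gDNA VAF.

All draws flow from a single seed through named substreams per table, so
identical configurations reproduce byte-identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ClinicalRecord, MethylationMatrix, ValidationError, VariantObservation
from .monitoring import DRIVER_GENES

logger = logging.getLogger("marrowtrace")

__all__ = [
    "MethylSimConfig",
    "CohortSimConfig",
    "GeneSpec",
    "simulate_reference_profiles",
    "simulate_mixture_samples",
    "simulate_paired_cohort",
]


def _substream(seed: int, *labels: str | int) -> np.random.Generator:
    """Named substream: deterministic child generator for one table/axis."""
    key = [seed] + [
        l if isinstance(l, int) else int.from_bytes(l.encode(), "little") % (2**31)
        for l in labels
    ]
    return np.random.default_rng(key)


def _truncnorm(rng: np.random.Generator, loc, sd: float, size) -> np.ndarray:
    """Gaussian noise added and clipped to [0,1] (truncation by clipping)."""
    vals = np.asarray(loc) + sd * rng.standard_normal(size)
    return np.clip(vals, 0.0, 1.0)


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------


@dataclass
class MethylSimConfig:
    """Geometry of the synthetic methylation references.

    Defaults give 1000 CpGs of which 600 separate the tissues by
    delta-beta 0.3 — enough candidates to select the standard 582-site
    atlas — measured in 6 reference samples per tissue with beta-scale
    noise sd 0.02.
    """

    n_cpgs: int = 1000
    n_discriminative: int = 600
    delta_beta: float = 0.3
    reference_noise_sd: float = 0.02
    mixture_noise_sd: float = 0.05
    n_reference_samples: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_discriminative > self.n_cpgs:
            raise ValidationError("n_discriminative cannot exceed n_cpgs")
        if not 0.0 < self.delta_beta < 1.0:
            raise ValidationError("delta_beta must be in (0,1)")
        if self.reference_noise_sd < 0 or self.mixture_noise_sd < 0:
            raise ValidationError("noise sds must be non-negative")


def _cpg_names(n: int) -> list[str]:
    return [f"cg{i:08d}" for i in range(n)]


def simulate_reference_profiles(
    config: MethylSimConfig,
) -> tuple[MethylationMatrix, MethylationMatrix, set[str]]:
    """Generate BM and PB healthy reference profiles with planted
    discriminative CpGs.

    Returns ``(bm, pb, truth)`` where ``truth`` is the planted CpG id set.
    Background CpGs share a common mean drawn uniform [0.1, 0.9];
    discriminative CpGs have tissue means separated by ``delta_beta`` with
    random balanced direction, midpoints re-drawn (bounded retries) if a
    mean would leave [0,1].
    """
    cfg = config
    rng = _substream(cfg.seed, "reference_means")
    cpg_ids = _cpg_names(cfg.n_cpgs)
    disc_idx = rng.choice(cfg.n_cpgs, size=cfg.n_discriminative, replace=False)
    disc_idx.sort()

    base = rng.uniform(0.1, 0.9, size=cfg.n_cpgs)
    bm_mean = base.copy()
    pb_mean = base.copy()

    # balanced random directions: half BM-hyper, half BM-hypo
    directions = np.ones(cfg.n_discriminative)
    directions[: cfg.n_discriminative // 2] = -1.0
    rng.shuffle(directions)

    half = cfg.delta_beta / 2.0
    for j, i in enumerate(disc_idx):
        mid = base[i]
        retries = 0
        while not (half <= mid <= 1.0 - half):
            mid = rng.uniform(0.1, 0.9)
            retries += 1
            if retries > 100:
                raise ValidationError(
                    f"cannot place delta_beta={cfg.delta_beta} within [0,1]"
                )
        bm_mean[i] = mid + directions[j] * half
        pb_mean[i] = mid - directions[j] * half

    def profiles(mean: np.ndarray, label: str) -> MethylationMatrix:
        srng = _substream(cfg.seed, f"reference_samples_{label}")
        betas = np.column_stack(
            [
                _truncnorm(srng, mean, cfg.reference_noise_sd, cfg.n_cpgs)
                for _ in range(cfg.n_reference_samples)
            ]
        )
        sample_ids = [f"{label}_{k + 1}" for k in range(cfg.n_reference_samples)]
        return MethylationMatrix(cpg_ids, sample_ids, betas)

    truth = {cpg_ids[i] for i in disc_idx}
    return profiles(bm_mean, "BM"), profiles(pb_mean, "PB"), truth


def simulate_mixture_samples(
    bm: MethylationMatrix,
    pb: MethylationMatrix,
    fractions: Sequence[float],
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[MethylationMatrix, list[float]]:
    """Two-tissue mixtures at known BM fractions.

    Each sample is ``f * mean(BM) + (1 - f) * mean(PB)`` over the shared
    CpG universe plus truncated Gaussian noise.  Returns the matrix and
    the ground-truth fractions (in sample order).
    """
    fractions = [float(f) for f in fractions]
    if any(not 0.0 <= f <= 1.0 for f in fractions):
        raise ValidationError("mixture fractions must lie in [0,1]")
    if bm.cpg_ids != pb.cpg_ids:
        raise ValidationError("BM and PB references must share the CpG universe")
    bm_mean = np.nanmean(bm.betas, axis=1)
    pb_mean = np.nanmean(pb.betas, axis=1)
    rng = _substream(seed, "mixtures")
    cols = []
    for f in fractions:
        mix = f * bm_mean + (1.0 - f) * pb_mean
        cols.append(_truncnorm(rng, mix, noise_sd, len(mix)) if noise_sd > 0 else mix)
    sample_ids = [f"mix_{k + 1}" for k in range(len(fractions))]
    return MethylationMatrix(bm.cpg_ids, sample_ids, np.column_stack(cols)), fractions


# ---------------------------------------------------------------------------
# paired cfDNA / gDNA cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSpec:
    """Panel gene: cohort prevalence, cfDNA shedding multiplier, mutation label."""

    prevalence: float
    multiplier: float
    mutation: str = "mut1"

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValidationError("prevalence must lie in [0,1]")
        if self.multiplier <= 0:
            raise ValidationError("multiplier must be positive")


def _default_panel() -> dict[str, GeneSpec]:
    # prevalences follow the validation-cohort mutation landscape;
    # multipliers are 1 + advantage/100 from the gene-specific advantage table
    return {
        "JAK2": GeneSpec(0.80, 1.119, "V617F"),
        "CALR": GeneSpec(0.15, 1.593, "type1"),
        "MPL": GeneSpec(0.08, 1.361, "W515L"),
        "DNMT3A": GeneSpec(0.23, 0.972, "R882H"),
        "TET2": GeneSpec(0.15, 0.997, "Q1523*"),
        "ASXL1": GeneSpec(0.10, 1.157, "G646fs"),
        "SF3B1": GeneSpec(0.08, 1.436, "K700E"),
    }


def _default_treatment_effects() -> dict[str, tuple[float, float]]:
    # (delta cfDNA, delta gDNA) per regimen, on the VAF fraction scale;
    # values follow the observed treatment-specific divergences
    return {
        "HU": (0.038, -0.011),
        "IFN": (-0.015, 0.089),
        "IFN+HU": (-0.026, 0.041),
        "RUX": (0.0, 0.0),
        "aspirin": (0.0, 0.0),
    }


def _default_treatment_probs() -> dict[str, float]:
    return {"HU": 0.70, "IFN": 0.13, "IFN+HU": 0.08, "RUX": 0.03, "aspirin": 0.06}


@dataclass
class CohortSimConfig:
    """Generative model of the paired two-timepoint cohort.

    ``dilution_coeff`` scales the linear lymphocyte dilution of gDNA VAF:
    ``gDNA = true * (1 - dilution_coeff * LYMPH%)``; the default 0.006
    places the advantage-vs-lymphocyte slope near the clinically observed
    ~6 percentage points per lymphocyte-%.  The base true-VAF distribution
    is Beta(5,5) rescaled to [0.05, 0.95] (clonal burdens centred near
    0.5, matching driver VAF means around 0.45-0.52).
    """

    n_patients: int = 40
    panel: dict[str, GeneSpec] = field(default_factory=_default_panel)
    dilution_coeff: float = 0.006  # per lymphocyte-%
    base_vaf_alpha: float = 5.0
    base_vaf_beta: float = 5.0
    base_vaf_range: tuple[float, float] = (0.05, 0.95)
    noise_sd: float = 0.02  # measurement noise per analyte, VAF scale
    lymph_range: tuple[float, float] = (5.0, 45.0)
    treatment_effects: dict[str, tuple[float, float]] = field(
        default_factory=_default_treatment_effects
    )
    treatment_probs: dict[str, float] = field(default_factory=_default_treatment_probs)
    detection_threshold: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValidationError("n_patients must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValidationError("seed must be an integer")
        if self.dilution_coeff < 0:
            raise ValidationError("dilution_coeff must be non-negative")
        lo, hi = self.base_vaf_range
        if not 0.0 <= lo < hi <= 1.0:
            raise ValidationError("base_vaf_range must be an increasing range in [0,1]")

    def null(self) -> "CohortSimConfig":
        """Null configuration: unit multipliers, no dilution, no treatment
        effect — cfDNA and gDNA become exchangeable up to noise."""
        panel = {
            g: GeneSpec(s.prevalence, 1.0, s.mutation) for g, s in self.panel.items()
        }
        effects = {t: (0.0, 0.0) for t in self.treatment_effects}
        return CohortSimConfig(
            n_patients=self.n_patients,
            panel=panel,
            dilution_coeff=0.0,
            base_vaf_alpha=self.base_vaf_alpha,
            base_vaf_beta=self.base_vaf_beta,
            base_vaf_range=self.base_vaf_range,
            noise_sd=self.noise_sd,
            lymph_range=self.lymph_range,
            treatment_effects=effects,
            treatment_probs=self.treatment_probs,
            detection_threshold=self.detection_threshold,
            seed=self.seed,
        )


def simulate_paired_cohort(
    config: CohortSimConfig,
) -> tuple[list[VariantObservation], list[ClinicalRecord]]:
    """Generate the paired two-timepoint variant and clinical tables.

    Per patient: one driver gene drawn by prevalence, each non-driver
    carried independently at its prevalence; a true clonal VAF per
    mutation; cfDNA VAF = true x gene multiplier, gDNA VAF = true x
    (1 - dilution x LYMPH%), both plus truncated measurement noise;
    T2 VAFs shifted by the assigned regimen's (cfDNA, gDNA) effects.
    Observations at or below the detection threshold are not emitted.
    WBC is constructed correlated with the patient's gDNA VAF.
    """
    cfg = config
    drivers = [g for g in cfg.panel if g in DRIVER_GENES]
    non_drivers = [g for g in cfg.panel if g not in DRIVER_GENES]
    if not drivers:
        raise ValidationError("panel must contain at least one driver gene")
    driver_p = np.array([cfg.panel[g].prevalence for g in drivers], dtype=float)
    if driver_p.sum() <= 0:
        raise ValidationError("driver prevalences sum to zero")
    driver_p = driver_p / driver_p.sum()

    g_rng = _substream(cfg.seed, "genes")
    v_rng = _substream(cfg.seed, "true_vaf")
    n_rng = _substream(cfg.seed, "measurement_noise")
    c_rng = _substream(cfg.seed, "clinical")
    t_rng = _substream(cfg.seed, "treatment")

    treatments = list(cfg.treatment_probs)
    t_probs = np.array([cfg.treatment_probs[t] for t in treatments], dtype=float)
    t_probs = t_probs / t_probs.sum()

    lo, hi = cfg.base_vaf_range
    variants: list[VariantObservation] = []
    clinical: list[ClinicalRecord] = []
    n_values = 0
    n_clamped = 0

    def emit(pid: str, gene: str, analyte: str, tp: str, vaf_raw: float) -> None:
        nonlocal n_values, n_clamped
        n_values += 1
        vaf = float(np.clip(vaf_raw, 0.0, 1.0))
        if vaf != vaf_raw:
            n_clamped += 1
        if vaf > cfg.detection_threshold:
            variants.append(
                VariantObservation(
                    patient_id=pid,
                    gene=gene,
                    mutation=cfg.panel[gene].mutation,
                    analyte=analyte,
                    timepoint=tp,
                    vaf=vaf,
                )
            )

    for i in range(cfg.n_patients):
        pid = f"P{i + 1:03d}"
        genes = [drivers[g_rng.choice(len(drivers), p=driver_p)]]
        for g in non_drivers:
            if g_rng.random() < cfg.panel[g].prevalence:
                genes.append(g)
        regimen = treatments[t_rng.choice(len(treatments), p=t_probs)]
        d_cf, d_g = cfg.treatment_effects.get(regimen, (0.0, 0.0))

        lymph_t1 = c_rng.uniform(*cfg.lymph_range)
        lymph_t2 = float(np.clip(lymph_t1 + c_rng.normal(0.0, 2.0), 0.0, 100.0))

        gdna_true_t1 = []
        for gene in genes:
            spec = cfg.panel[gene]
            true_vaf = lo + (hi - lo) * v_rng.beta(cfg.base_vaf_alpha, cfg.base_vaf_beta)
            cf_t1 = true_vaf * spec.multiplier
            g_t1 = true_vaf * (1.0 - cfg.dilution_coeff * lymph_t1)
            gdna_true_t1.append(g_t1)
            noise = (
                n_rng.normal(0.0, cfg.noise_sd, size=4)
                if cfg.noise_sd > 0
                else np.zeros(4)
            )
            emit(pid, gene, "cfDNA", "T1", cf_t1 + noise[0])
            emit(pid, gene, "gDNA_PB", "T1", g_t1 + noise[1])
            emit(pid, gene, "cfDNA", "T2", cf_t1 + d_cf + noise[2])
            emit(pid, gene, "gDNA_PB", "T2", true_vaf * (1.0 - cfg.dilution_coeff * lymph_t2) + d_g + noise[3])

        # WBC correlated with the gDNA clonal burden by construction
        mean_g = float(np.mean(gdna_true_t1))
        for tp, lymph in (("T1", lymph_t1), ("T2", lymph_t2)):
            wbc = max(0.5, 4.0 + 25.0 * mean_g + c_rng.normal(0.0, 2.0))
            clinical.append(
                ClinicalRecord(
                    patient_id=pid,
                    timepoint=tp,
                    wbc=wbc,
                    lymph_pct=lymph if tp == "T1" else lymph_t2,
                    hct=c_rng.uniform(30.0, 55.0),
                    plt=c_rng.uniform(150.0, 900.0),
                    hgb=c_rng.uniform(100.0, 180.0),
                    treatment=regimen,
                    hematologic_response=_draw_response(c_rng, tp),
                )
            )

    if n_values and n_clamped / n_values > 0.20:
        logger.warning(
            "%.0f%% of generated VAFs were clamped to [0,1]; effect sizes may be "
            "implausible for the base VAF distribution",
            100.0 * n_clamped / n_values,
        )
    return variants, clinical


def _draw_response(rng: np.random.Generator, timepoint: str) -> str:
    # CR/PR/NR frequencies follow the monitored cohort at each timepoint
    if timepoint == "T1":
        probs = np.array([10, 17, 12], dtype=float) / 39.0
    else:
        probs = np.array([8, 14, 17], dtype=float) / 39.0
    return ("CR", "PR", "NR")[rng.choice(3, p=probs)]


def cohort_to_frames(
    variants: Sequence[VariantObservation], clinical: Sequence[ClinicalRecord]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Convenience: the generated tables as DataFrames in the file dialects
    the readers expect."""
    vdf = pd.DataFrame([v.__dict__ for v in variants])
    cdf = pd.DataFrame([c.__dict__ for c in clinical])
    return vdf, cdf
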