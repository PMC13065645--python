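"""Reference-based tissue-of-origin deconvolution and in-silico limit of
detection.

A sample's methylation profile over the atlas CpGs is modelled as a
non-negative mixture of the per-tissue reference means:

    min_{f >= 0} || A f - b ||_2

with ``A`` the atlas mean-beta matrix (CpGs x tissues) and ``b`` the
sample betas.  The non-negative least-squares solution is renormalized to
sum to one, so the reported fractions are tissue proportions while the
residual retains its meaning on the beta scale.  CpGs missing in the
sample are dropped from both ``A`` and ``b`` for that solve (never
imputed), subject to a minimum-coverage floor.

The limit of detection (LoD) is estimated by spike-in simulation: mixtures
of a spike tissue into a background tissue at a grid of fractions, with
truncated Gaussian noise on the beta scale, are deconvolved; the blank
(0% spike) replicates define a detection cutoff and the LoD is the
smallest grid fraction detected at the configured reliability.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls

from .atlas import ReferenceAtlas
from .io import MethylationMatrix, ValidationError, round_half_up

__all__ = [
    "TissueFractionEstimate",
    "LodResult",
    "deconvolve",
    "deconvolve_matrix",
    "estimate_lod",
    "fold_enrichment",
]


@dataclass
class TissueFractionEstimate:
    """Per-sample non-negative tissue proportions summing to one."""

    sample_id: str
    tissues: tuple[str, ...]
    fractions: np.ndarray
    residual: float  # RMS of A f* - b at the unnormalized NNLS solution
    n_cpgs_used: int

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if abs(self.fractions.sum() - 1.0) > 1e-9:
            raise ValidationError("tissue fractions must sum to 1")
        if np.any(self.fractions < -1e-12) or np.any(self.fractions > 1 + 1e-12):
            raise ValidationError("tissue fractions must lie in [0,1]")

    def fraction(self, tissue: str) -> float:
        return float(self.fractions[self.tissues.index(tissue)])


@dataclass
class LodResult:
    """Outcome of a spike-in limit-of-detection simulation."""

    tissue: str
    lod_fraction: float | None  # None when nothing on the grid was reliable
    blank_threshold: float
    detection_rate_at_lod: float
    detected: bool
    detection_rates: dict[float, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


def _align_sample(
    sample_betas, atlas: ReferenceAtlas
) -> np.ndarray:
    """Return sample betas ordered as atlas.cpg_ids, NaN for missing."""
    if isinstance(sample_betas, pd.Series):
        return sample_betas.reindex(atlas.cpg_ids).to_numpy(dtype=float)
    if isinstance(sample_betas, Mapping):
        return np.array([sample_betas.get(c, np.nan) for c in atlas.cpg_ids], dtype=float)
    arr = np.asarray(sample_betas, dtype=float)
    if arr.shape != (len(atlas),):
        raise ValidationError(
            f"sample vector of length {arr.shape} does not match atlas size {len(atlas)}"
        )
    return arr


def deconvolve(
    sample_betas,
    atlas: ReferenceAtlas,
    sample_id: str = "sample",
    min_coverage: float = 0.5,
) -> TissueFractionEstimate:
    """Estimate tissue proportions for one sample by NNLS on atlas CpGs.

    Parameters
    ----------
    sample_betas
        Per-CpG beta values: a mapping or Series keyed by CpG id, or an
        array already ordered as ``atlas.cpg_ids``.  NaN marks missing.
    min_coverage
        Minimum fraction of atlas CpGs that must be non-missing.
    """
    b = _align_sample(sample_betas, atlas)
    ok = np.isfinite(b)
    coverage = ok.mean() if len(b) else 0.0
    if coverage < min_coverage:
        raise ValidationError(
            f"sample {sample_id!r} covers {coverage:.1%} of atlas CpGs, "
            f"below the {min_coverage:.0%} floor"
        )
    A = atlas.mean_betas[ok]
    f, rnorm = nnls(A, b[ok])
    total = f.sum()
    if total <= 0:
        raise ValidationError(
            f"degenerate all-zero NNLS solution for sample {sample_id!r}"
        )
    return TissueFractionEstimate(
        sample_id=sample_id,
        tissues=tuple(atlas.tissues),
        fractions=f / total,
        residual=float(rnorm / np.sqrt(ok.sum())),
        n_cpgs_used=int(ok.sum()),
    )


def deconvolve_matrix(
    samples: MethylationMatrix, atlas: ReferenceAtlas, min_coverage: float = 0.5
) -> list[TissueFractionEstimate]:
    """Deconvolve every sample of a matrix; rows are matched to atlas CpGs
    by identifier."""
    frame = samples.to_frame()
    return [
        deconvolve(frame[sid], atlas, sample_id=sid, min_coverage=min_coverage)
        for sid in samples.sample_ids
    ]


def fold_enrichment(mean_fraction_a: float, mean_fraction_b: float, ndigits: int = 1) -> float:
    """Ratio of two mean tissue fractions (e.g. BM fraction in cfDNA over
    gDNA), rounded half-up — the 'x-fold enrichment' figure."""
    if mean_fraction_b <= 0:
        raise ValidationError("denominator fraction must be positive")
    return round_half_up(mean_fraction_a / mean_fraction_b, ndigits)


# ---------------------------------------------------------------------------
# limit of detection
# ---------------------------------------------------------------------------


def _profile_means(profiles, atlas: ReferenceAtlas) -> np.ndarray:
    """Mean beta per atlas CpG from donor profiles (matrix, Series/mapping
    or aligned array)."""
    if isinstance(profiles, MethylationMatrix):
        frame = profiles.to_frame().reindex(atlas.cpg_ids)
        return frame.mean(axis=1, skipna=True).to_numpy(dtype=float)
    return _align_sample(profiles, atlas)


def estimate_lod(
    atlas: ReferenceAtlas,
    donor_profiles: Mapping[str, object],
    spike_tissue: str,
    grid: Sequence[float],
    noise_sd: float,
    n_reps: int = 50,
    reliability: float = 0.95,
    seed: int = 0,
    blank_quantile: float = 95.0,
) -> LodResult:
    """Estimate the smallest reliably detected spike fraction.

    For each grid fraction ``f`` (plus an implicit blank at 0), ``n_reps``
    mixtures ``f * spike + (1 - f) * background`` over atlas CpGs receive
    truncated Gaussian noise of sd ``noise_sd`` and are deconvolved.  The
    blank replicates define ``blank_threshold`` (the ``blank_quantile``-th
    percentile of the spike-tissue estimate); the LoD is the smallest grid
    fraction whose detection rate (estimate strictly above the blank
    threshold) reaches ``reliability``.

    Randomness flows from ``seed`` through one substream per (grid point,
    replicate); the standard-normal draws do not depend on ``noise_sd``,
    so runs at different noise levels share common random numbers.
    """
    grid = sorted(float(g) for g in grid)
    if any(g <= 0 or g > 1 for g in grid):
        raise ValidationError("grid fractions must lie in (0, 1]")
    if n_reps < 20:
        raise ValidationError("n_reps must be at least 20 for a stable blank threshold")
    if spike_tissue not in atlas.tissues:
        raise ValidationError(f"spike tissue {spike_tissue!r} not in atlas tissues")
    background = [t for t in atlas.tissues if t != spike_tissue][0]
    spike_mean = _profile_means(donor_profiles[spike_tissue], atlas)
    bg_mean = _profile_means(donor_profiles[background], atlas)

    def estimates_at(f: float, grid_index: int) -> np.ndarray:
        mix = f * spike_mean + (1.0 - f) * bg_mean
        out = np.empty(n_reps)
        for rep in range(n_reps):
            rng = np.random.default_rng([seed, grid_index, rep])
            z = rng.standard_normal(len(atlas))
            b = np.clip(mix + noise_sd * z, 0.0, 1.0)
            est = deconvolve(b, atlas, sample_id=f"spike_{f}_{rep}")
            out[rep] = est.fraction(spike_tissue)
        return out

    blanks = estimates_at(0.0, 0)
    blank_threshold = float(np.percentile(blanks, blank_quantile))

    rates: dict[float, float] = {}
    lod = None
    rate_at_lod = 0.0
    for gi, f in enumerate(grid, start=1):
        ests = estimates_at(f, gi)
        rate = float((ests > blank_threshold).mean())
        rates[f] = rate
        if lod is None and rate >= reliability:
            lod, rate_at_lod = f, rate
    return LodResult(
        tissue=spike_tissue,
        lod_fraction=lod,
        blank_threshold=blank_threshold,
        detection_rate_at_lod=rate_at_lod,
        detected=lod is not None,
        detection_rates=rates,
        params={
            "grid": grid,
            "noise_sd": noise_sd,
            "n_reps": n_reps,
            "reliability": reliability,
            "seed": seed,
            "blank_quantile": blank_quantile,
        },
    )
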