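"""Construction of a two-tissue (bone marrow vs peripheral blood)
discriminative CpG reference atlas from healthy reference methylation
profiles.

The atlas is the reference matrix consumed by tissue-of-origin
deconvolution: a set of CpG sites whose mean methylation separates whole
bone marrow (BM) from whole peripheral blood (PB), with per-tissue mean
beta values.  Selection ranks CpGs by the absolute difference of
per-tissue mean betas and balances hyper- and hypomethylated directions,
the convention of reference-atlas construction for cell-free DNA
deconvolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import MethylationMatrix, ValidationError

TISSUES = ("BM", "PB")
BM_HYPER = "BM_hyper"  # mean beta higher in bone marrow
BM_HYPO = "BM_hypo"

__all__ = ["ReferenceAtlas", "select_differential_cpgs", "read_atlas", "write_atlas"]


@dataclass
class ReferenceAtlas:
    """Selected discriminative CpGs with per-tissue mean betas.

    ``mean_betas`` has shape (n_cpgs, 2) with columns ordered as
    ``tissues`` (BM, PB by default).  ``direction`` records which tissue
    is hypermethylated at each site.
    """

    cpg_ids: list[str]
    mean_betas: np.ndarray
    direction: list[str]
    tissues: tuple[str, str] = TISSUES
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cpg_ids = list(self.cpg_ids)
        self.mean_betas = np.asarray(self.mean_betas, dtype=float)
        self.direction = list(self.direction)
        if len(set(self.cpg_ids)) != len(self.cpg_ids):
            raise ValidationError("atlas contains duplicate CpG ids")
        if self.mean_betas.shape != (len(self.cpg_ids), len(self.tissues)):
            raise ValidationError(
                f"mean_betas shape {self.mean_betas.shape} inconsistent with "
                f"{len(self.cpg_ids)} CpGs x {len(self.tissues)} tissues"
            )
        if len(self.direction) != len(self.cpg_ids):
            raise ValidationError("direction length does not match CpG count")
        if np.any(~np.isfinite(self.mean_betas)):
            raise ValidationError("atlas mean betas must be finite")
        if self.mean_betas.min() < -1e-9 or self.mean_betas.max() > 1 + 1e-9:
            raise ValidationError("atlas mean betas must lie in [0,1]")
        delta = self.mean_betas[:, 0] - self.mean_betas[:, 1]
        for i, d in enumerate(self.direction):
            if d not in (BM_HYPER, BM_HYPO):
                raise ValidationError(f"invalid direction {d!r} at {self.cpg_ids[i]}")
            if (d == BM_HYPER) != (delta[i] > 0):
                raise ValidationError(
                    f"direction {d} inconsistent with mean difference at {self.cpg_ids[i]}"
                )

    def __len__(self) -> int:
        return len(self.cpg_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.mean_betas,
            index=pd.Index(self.cpg_ids, name="cpg_id"),
            columns=[f"mean_beta_{t}" for t in self.tissues],
        )
        df["direction"] = self.direction
        return df


def _tissue_means(matrix: MethylationMatrix, max_missing_frac: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-CpG mean over non-missing samples, plus a keep mask for CpGs
    observed in enough reference samples."""
    betas = matrix.betas
    n_obs = np.isfinite(betas).sum(axis=1)
    n = betas.shape[1]
    keep = n_obs >= (1.0 - max_missing_frac) * n
    with np.errstate(invalid="ignore"):
        means = np.nanmean(np.where(np.isfinite(betas), betas, np.nan), axis=1)
    return means, keep


def select_differential_cpgs(
    bm_profiles: MethylationMatrix,
    pb_profiles: MethylationMatrix,
    k: int = 582,
    min_delta: float = 0.2,
    max_missing_frac: float = 0.2,
) -> ReferenceAtlas:
    """Select the ``k`` CpGs that best distinguish BM from PB.

    Candidates are CpGs with ``|mean(BM) - mean(PB)| >= min_delta``, each
    tissue mean taken over non-missing reference samples; CpGs missing in
    more than ``max_missing_frac`` of either tissue's samples are excluded
    before ranking.  The result is balanced between BM-hypermethylated and
    BM-hypomethylated sites (ceil(k/2) / floor(k/2)), falling back to the
    available count in the scarcer direction.  Ranking is by descending
    ``|delta|`` with ties broken lexicographically by CpG id, so the atlas
    is deterministic and invariant to input ordering.
    """
    if k <= 0:
        raise ValidationError("k must be positive")
    if bm_profiles.shape[1] < 2 or pb_profiles.shape[1] < 2:
        raise ValidationError("each tissue needs at least 2 reference samples")
    if set(bm_profiles.cpg_ids) != set(pb_profiles.cpg_ids):
        n_mismatch = len(set(bm_profiles.cpg_ids) ^ set(pb_profiles.cpg_ids))
        raise ValidationError(
            f"BM and PB profiles cover different CpG universes ({n_mismatch} mismatched ids)"
        )

    # align PB rows to the BM CpG order
    if bm_profiles.cpg_ids != pb_profiles.cpg_ids:
        pb_index = {c: i for i, c in enumerate(pb_profiles.cpg_ids)}
        order = [pb_index[c] for c in bm_profiles.cpg_ids]
        pb_betas = pb_profiles.betas[order]
    else:
        pb_betas = pb_profiles.betas
    pb_aligned = MethylationMatrix(bm_profiles.cpg_ids, pb_profiles.sample_ids, pb_betas)

    bm_mean, bm_keep = _tissue_means(bm_profiles, max_missing_frac)
    pb_mean, pb_keep = _tissue_means(pb_aligned, max_missing_frac)
    delta = bm_mean - pb_mean
    candidate = bm_keep & pb_keep & np.isfinite(delta) & (np.abs(delta) >= min_delta)
    if candidate.sum() < k:
        raise ValidationError(
            f"only {int(candidate.sum())} CpGs pass min_delta={min_delta}; "
            f"cannot select k={k} (achievable maximum: {int(candidate.sum())})"
        )

    idx = np.flatnonzero(candidate)
    # sort by (-|delta|, cpg_id); |delta| is rounded so that summation-order
    # float noise cannot reorder effective ties, keeping the selection
    # permutation-invariant
    rank_key = lambda i: (-round(abs(delta[i]), 10), bm_profiles.cpg_ids[i])
    ranked = sorted(idx, key=rank_key)
    hyper = [i for i in ranked if delta[i] > 0]
    hypo = [i for i in ranked if delta[i] < 0]

    n_hyper = int(np.ceil(k / 2))
    n_hypo = k - n_hyper
    if len(hyper) < n_hyper:  # deficit taken from the other direction
        n_hyper = len(hyper)
        n_hypo = k - n_hyper
    elif len(hypo) < n_hypo:
        n_hypo = len(hypo)
        n_hyper = k - n_hypo
    chosen = sorted(hyper[:n_hyper] + hypo[:n_hypo], key=rank_key)

    cpg_ids = [bm_profiles.cpg_ids[i] for i in chosen]
    mean_betas = np.column_stack([bm_mean[chosen], pb_mean[chosen]])
    direction = [BM_HYPER if delta[i] > 0 else BM_HYPO for i in chosen]
    metadata = {
        "k": k,
        "min_delta": min_delta,
        "n_bm_samples": bm_profiles.shape[1],
        "n_pb_samples": pb_profiles.shape[1],
        "n_candidates": int(candidate.sum()),
    }
    return ReferenceAtlas(cpg_ids, mean_betas, direction, TISSUES, metadata)


# ---------------------------------------------------------------------------
# atlas file I/O: TSV with '#'-prefixed metadata header lines
# ---------------------------------------------------------------------------


def write_atlas(atlas: ReferenceAtlas, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in atlas.metadata.items():
            fh.write(f"# {key}={value}\n")
        atlas.to_frame().to_csv(fh, sep="\t")


def read_atlas(path: str | Path) -> ReferenceAtlas:
    path = Path(path)
    metadata: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, value = line[1:].strip().partition("=")
            try:
                metadata[key.strip()] = int(value)
            except ValueError:
                try:
                    metadata[key.strip()] = float(value)
                except ValueError:
                    metadata[key.strip()] = value
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", index_col=0, dtype={"direction": str})
    mean_cols = [c for c in df.columns if c.startswith("mean_beta_")]
    if "direction" not in df.columns or len(mean_cols) < 2:
        raise ValidationError(
            f"{path.name}: atlas file must have mean_beta_<tissue> columns and a direction column"
        )
    tissues = tuple(c.removeprefix("mean_beta_") for c in mean_cols)
    if df.index.has_duplicates:
        raise ValidationError(f"{path.name}: duplicate CpG ids in atlas file")
    return ReferenceAtlas(
        cpg_ids=[str(i) for i in df.index],
        mean_betas=df[mean_cols].to_numpy(),
        direction=list(df["direction"]),
        tissues=tissues,  # type: ignore[arg-type]
        metadata=metadata,
    )
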