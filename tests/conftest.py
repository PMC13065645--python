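import numpy as np
import pytest

import marrowtrace as mt


def grid_search_fractions(atlas, sample_betas, step=1e-3):
    """Independent brute-force oracle for two-tissue deconvolution: scan the
    BM proportion over the simplex at the given step, minimizing the same
    least-squares residual the solver minimizes.  The solver's objective is
    scale-free (non-negative weights are only normalized afterwards), so for
    each candidate direction (f, 1-f) the optimal non-negative scale has the
    closed form s* = max(0, <mix, b> / ||mix||^2)."""
    b = np.asarray(sample_betas, dtype=float)
    ok = np.isfinite(b)
    A = atlas.mean_betas[ok]
    b = b[ok]
    fs = np.arange(0.0, 1.0 + step / 2, step)
    mixes = np.outer(A[:, 0], fs) + np.outer(A[:, 1], 1.0 - fs)
    norms = (mixes**2).sum(axis=0)
    scales = np.maximum(0.0, (mixes * b[:, None]).sum(axis=0) / norms)
    sse = (b @ b) - 2 * scales * (mixes * b[:, None]).sum(axis=0) + scales**2 * norms
    return float(fs[int(np.argmin(sse))])


@pytest.fixture(scope="session")
def planted_refs():
    """Healthy BM/PB references with 600 planted CpGs (delta-beta 0.3)."""
    cfg = mt.MethylSimConfig(seed=11)
    bm, pb, truth = mt.simulate_reference_profiles(cfg)
    return bm, pb, truth


@pytest.fixture(scope="session")
def planted_atlas(planted_refs):
    bm, pb, _ = planted_refs
    return mt.select_differential_cpgs(bm, pb, k=582, min_delta=0.2)


@pytest.fixture(scope="session")
def toy_atlas():
    """Handmade 20-CpG atlas with well-separated tissue means."""
    rng = np.random.default_rng(5)
    bm = rng.uniform(0.6, 0.95, size=20)
    pb = rng.uniform(0.05, 0.4, size=20)
    cpgs = [f"cg{i:08d}" for i in range(20)]
    direction = ["BM_hyper" if b > p else "BM_hypo" for b, p in zip(bm, pb)]
    return mt.ReferenceAtlas(cpgs, np.column_stack([bm, pb]), direction)


@pytest.fixture(scope="session")
def default_cohort():
    cfg = mt.CohortSimConfig(seed=7)
    variants, clinical = mt.simulate_paired_cohort(cfg)
    return variants, clinical
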