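# marrowtrace

Tooling for comparing plasma **cell-free DNA (cfDNA)** with peripheral-blood
**genomic DNA (gDNA)** in the molecular monitoring of Philadelphia-negative
myeloproliferative neoplasms (MPN).

MPN clones live in the bone marrow (BM), but routine molecular monitoring
samples peripheral blood (PB) leukocytes.  cfDNA — fragments released largely
by apoptosis of marrow-resident cells — is enriched for BM-derived material,
so the variant allele frequency (VAF) it reports can track marrow clonal
burden more directly than PB gDNA, whose VAF is diluted whenever lymphoid
cells crowd out the myeloid clone.  `marrowtrace` implements the full
analytical chain for quantifying and exploiting that difference, for
hematology labs and methods researchers working with paired-analyte panels:

1. **Methylation atlas construction** — select the `k` CpG sites (default
   582) whose per-tissue mean beta values best separate whole BM from whole
   PB in healthy reference arrays, balanced between BM-hyper- and
   hypomethylated directions.
2. **Tissue-of-origin deconvolution** — model a sample's betas over atlas
   CpGs as a non-negative mixture of the reference columns,
   `min_{f>=0} ||A f − b||₂`, solve by NNLS and renormalize `f` to the
   simplex; plus an in-silico spike-in **limit of detection**: the smallest
   spiked tissue fraction whose estimate exceeds the 95th percentile of
   blank replicates in ≥95% of noisy simulations.
3. **Concordance statistics** — detection-overlap accounting at the strict
   `VAF > 2%` reporting threshold, cfDNA-vs-gDNA correlation, and the
   per-gene **cfDNA advantage** `mean[(VAF_cf − VAF_g)/VAF_g]` (in %) with a
   paired t-test and a test-selection label.
4. **Longitudinal classification** — per patient and analyte, the change in
   summary VAF between timepoints T1 and T2: `ΔVAF ≤ −5` points → molecular
   response, `≥ +5` → resistance, `≥ +10` → progression (boundaries
   inclusive), with cohort proportions and cross-analyte agreement.
5. **Lymphocyte predictor** — OLS of per-patient advantage (%) on
   lymphocyte percentage, `advantage = a + b·LYMPH%`, and a deterministic
   cfDNA/gDNA/dual test-selection rule (lymphocytes > 20% or a prioritized
   gene favour cfDNA).
6. **Synthetic data** — generators for planted-CpG reference profiles,
   known-fraction mixtures, and paired two-timepoint cohorts with
   gene-specific shedding multipliers, lymphocyte dilution of gDNA and
   regimen-specific treatment effects, so the entire chain is testable
   without any external download.

## Worked example

```python
import marrowtrace as mt

# 1. atlas from synthetic healthy references (600 planted CpGs, Δβ = 0.3)
bm, pb, truth = mt.simulate_reference_profiles(mt.MethylSimConfig(seed=11))
atlas = mt.select_differential_cpgs(bm, pb, k=582, min_delta=0.2)

# 2. deconvolve a noisy 30% BM / 70% PB mixture
mix, _ = mt.simulate_mixture_samples(bm, pb, [0.3], noise_sd=0.05, seed=12)
est = mt.deconvolve(mix.sample("mix_1"), atlas)
print(f"estimated BM fraction: {est.fraction('BM'):.3f}")

# 3. paired cfDNA/gDNA cohort statistics
variants, clinical = mt.simulate_paired_cohort(mt.CohortSimConfig(n_patients=40, seed=7))
pairs = mt.pair_variants(variants)
calr = mt.cfdna_advantage(pairs, gene="CALR")
print(f"CALR advantage: {calr.mean_advantage:+.1f}% (n={calr.n}) -> {calr.recommendation}")

# 4. two-timepoint molecular classification per analyte
calls = mt.call_patients(variants, "cfDNA") + mt.call_patients(variants, "gDNA_PB")
for analyte, entry in mt.cohort_classification(calls)["analytes"].items():
    print(analyte, entry["proportions"])
```

prints

```
estimated BM fraction: 0.305
CALR advantage: +85.9% (n=8) -> Prioritize cfDNA
cfDNA {'response': 7.5, 'stable': 77.5, 'resistance': 15.0}
gDNA_PB {'response': 5.0, 'stable': 87.5, 'resistance': 7.5}
```

The deconvolution recovers the known 30% spike within half a VAF point of
noise; the generated CALR clone (shedding multiplier 1.593, further helped
by lymphocyte dilution of gDNA) shows a large positive cfDNA advantage; and
cfDNA calls more patients resistant than gDNA does, while gDNA calls more
stable — the complementary pattern the toolkit is built to expose.

The same operations are available from the shell:

```bash
marrowtrace simulate methyl --cpgs 1000 --disc 600 --seed 3 -o refs/
marrowtrace atlas --bm refs/bm_reference.tsv --pb refs/pb_reference.tsv -k 582 -o atlas.tsv
marrowtrace deconvolve --atlas atlas.tsv --samples betas.tsv -o fractions.tsv
marrowtrace lod --atlas atlas.tsv --bm refs/bm_reference.tsv --pb refs/pb_reference.tsv \
    --spike BM --grid 0.005,0.01,0.02,0.05 --noise-sd 0.05 --reps 50 --seed 17
marrowtrace concordance --variants variants.tsv --clinical clinical.tsv --stratify wbc:10
marrowtrace classify --variants variants.tsv --class driver
marrowtrace fit --points points.tsv -o model.json && marrowtrace predict --model model.json --lymph 32.5
```

## Layout

| module | contents |
| --- | --- |
| `marrowtrace.io` | typed containers (beta matrix, variant, clinical record), TSV/CSV readers/writers, unit normalization, run configuration |
| `marrowtrace.atlas` | discriminative-CpG selection and atlas file I/O |
| `marrowtrace.deconv` | NNLS deconvolution, fold enrichment, limit-of-detection simulation |
| `marrowtrace.concordance` | pairing, overlap, advantage, correlation, WBC stratification |
| `marrowtrace.monitoring` | summary VAF, two-timepoint classification, cohort and group summaries |
| `marrowtrace.predictor` | lymphocyte-percentage model and test selection |
| `marrowtrace.simulate` | synthetic reference profiles, mixtures and paired cohorts |

See `docs/methods.md` for the statistical model, parameter defaults and
known limitations.
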