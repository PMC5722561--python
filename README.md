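# biomepair

Paired tumor / non-tumor **two-kingdom microbiome analysis**: a tested,
reusable implementation of the workflow used to compare the bacteriome (16S)
and mycobiome (ITS) of matched tumor and adjacent-normal tissue samples, for
researchers analyzing taxon-by-sample count tables from paired designs.

The pipeline covers:

- **Community metrics** — per-sample Shannon diversity
  *H = −Σᵢ pᵢ ln pᵢ* and richness *S* = #{i : xᵢ > 0}; Bray–Curtis
  dissimilarity *BC(a,b) = 1 − 2·Σ min(aᵢ,bᵢ)/(Σaᵢ+Σbᵢ)*; unweighted UniFrac
  on a rooted phylogeny; classical-scaling PCoA; UPGMA dendrograms.
- **Differential abundance** — per-taxon Kruskal–Wallis tests on
  within-kingdom relative abundances with Bonferroni adjustment over the
  taxon family, plus Dunn's post-hoc z for multi-level groupings.
- **Correlation screens** — Spearman correlations between taxa within and
  across kingdoms, Benjamini–Hochberg adjusted.
- **Random-forest layer** — a forest (default ntree = 2001, mtry = 10) on
  the merged 112-genus relative-abundance matrix; per-sample **OOB vote
  fractions** (fraction of out-of-bag trees voting "tumor"); permutation
  importance compared against a null band of label-randomized refits;
  backward variable elimination; the **0.632+ bootstrap** prediction-error
  estimate

      Err₁′ = min(Err₁, γ̂),  R̂ = (Err₁′ − err̄)/(γ̂ − err̄),
      ŵ = 0.632/(1 − 0.368·R̂),  err₆₃₂₊ = (1 − ŵ)·err̄ + ŵ·Err₁′

  with γ̂ the no-information rate; and the paired **vote-fraction
  difference** *d = vote(tumor) − vote(non-tumor)* per patient, compared
  across clinical groups to quantify a field effect (tumor-like profiles in
  the normal tissue of high-T-stage patients).
- **Synthetic cohort generator** — a Dirichlet-multinomial simulator of
  paired two-kingdom cohorts with planted fold-changes, patient-level
  offsets, tissue-specific sequencing depths and a tunable field-effect
  attenuation, so every stage is testable without access data.

## Worked example

```python
import numpy as np
from biomepair import (GeneratorConfig, RFConfig, simulate_cohort,
                       filter_low_depth_pairs, merge_genus_tables, fit_rf,
                       vote_fraction_differences, field_effect_test)

cohort, truth = simulate_cohort(GeneratorConfig(seed=1))
cohort, removed = filter_low_depth_pairs(cohort, min_reads=50)
features, _ = merge_genus_tables(cohort)          # 78 samples x 112 genera
labels = cohort.metadata_frame().loc[features.index, "tissue"].to_numpy()

fit = fit_rf(features, labels, RFConfig(ntree=501, seed=3))
print(round(fit.oob_error, 3))                    # 0.282

vd = vote_fraction_differences(fit, cohort)
fe = field_effect_test(vd, cohort, grouping="t_stage")
print({k: round(v, 2) for k, v in fe.group_means.items()},
      round(fe.p_value, 3))                       # {'high': 0.08, 'low': 0.2} 0.014
```

The forest separates tumor from normal tissue well above chance (OOB error
0.28 on 78 samples), and the per-patient vote-fraction difference is
markedly smaller in high-T-stage patients (mean d 0.08 vs 0.20, Welch
p = 0.014): under the generator's default field-effect attenuation, the
normal tissue of high-T-stage patients already looks partly tumor-like to
the classifier.

The `examples/` directory holds one short script per capability
(simulation, diversity/ordination, differential abundance, correlation
screens, RF classification, field effect); each prints the numbers it
computes and what they mean. A thin CLI is available for shell use:

```sh
biomepair simulate --out-dir data --seed 1
biomepair run --bacteria data/bacteria.tsv --fungi data/fungi.tsv \
    --metadata data/metadata.tsv --tree data/tree.nwk --out-dir results
biomepair report results
```

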