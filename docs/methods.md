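# Methods

## Scope and data model

The package analyzes **paired tumor / non-tumor two-kingdom microbiome
cohorts**: one genus-level (or finer) count table per kingdom — bacteria
from 16S amplicons, fungi from ITS amplicons — over the same tissue
samples, plus per-sample clinical metadata and a patient→(tumor, non-tumor)
pairing map. Counts are kept as raw integers until an analysis explicitly
normalizes them; relative abundance is always computed **within a sample
and within a kingdom**, because the two amplicon libraries have
incomparable sequencing depths (a joint-normalization switch exists on
`merge_genus_tables` for users who pooled libraries).

Quality filtering follows amplicon practice for paired designs: a pair is
removed entirely — both tissues, both kingdoms — when either member's
*bacterial* read total falls below `min_reads` (default 50, strict
less-than). Filtering on the deeper, more reliable bacterial library and
removing whole pairs preserves the matched structure; removals are logged.

## Synthetic cohort generator

The generator is first-class, tested code: it defines the conditions under
which every downstream claim is verified.

**Taxonomy and baseline.** Genera are partitioned into phyla by a
stick-breaking (Dirichlet) split with at least one genus per phylum
(defaults: 90 bacterial genera in 25 phyla, 22 fungal genera in 7 phyla —
112 genera total). The baseline expected composition follows a power-law
rank-abundance curve, weight ∝ rank^(−1.2) within each kingdom, giving one
dominant genus in the 20–30 % range and a long tail — the shape typical of
oral amplicon data.

**Per-sample model.** For patient *j* with per-genus baseline log-weights
*b*:

1. patient offset: `normal_log = b + N(0, σ_patient²)` per genus
   (σ_patient = 0.6 by default), optionally plus a shared latent factor on
   designated genus pairs (off by default) that induces co-occurrence;
2. tumor shift: `tumor_log = normal_log + ln2 · fc` where `fc` holds the
   planted log2 fold-changes (default: 10 genera across both kingdoms,
   |log2 FC| 0.63–2, mixed signs, including a modest elevation of the
   dominant genus — which simultaneously concentrates tumor compositions
   and thus lowers tumor Shannon diversity);
3. **field effect**: for high-T-stage patients (default 54 % of the
   cohort), `normal_log ← normal_log + a · (tumor_log − normal_log)` with
   attenuation *a* = `field_attenuation_high` (default 0.3). The pair
   difference shrinks by the factor (1 − a); at *a* = 1 the normal sample's
   expected composition equals the tumor's;
4. compositions are softmax-normalized per kingdom; sequencing depth is
   drawn log-normally per tissue and kingdom (bacteria: median 13 561 reads
   with σ = 0.587 for non-tumor vs median 6 294 with σ = 2.20 for tumor —
   the wide tumor spread produces occasional pairs under the 50-read QC
   threshold, exercising the depth filter; fungi: 3 482/σ = 1.05 vs
   1 806/σ = 1.16);
5. counts are **Dirichlet-multinomial**: `p ~ Dirichlet(c·composition)`
   with concentration *c* = 50 (moderate overdispersion), then
   `counts ~ Multinomial(depth, p)`. Column sums equal the drawn depths
   exactly.

Everything flows from one `numpy` Generator, so a seed fixes the cohort
bit-for-bit.

**What the generator does *not* emulate**: taxonomic misassignment, chimeras,
PCR/primer bias, contamination, zero-inflation beyond what the DM model
produces, and real phylogenies (trees are random topologies consistent with
the taxonomy, with uniform branch lengths). Passing recovery tests therefore
demonstrates that the *methods* behave correctly under a plausible
overdispersed compositional model — not that real tissue cohorts will yield
the same effect sizes.

## Community metrics

Shannon diversity uses natural log by default (log2/log10 via `base`);
zero proportions contribute nothing. Richness counts strictly positive
entries. **No rarefaction** is applied: with tumor libraries several-fold
shallower than normals, richness comparisons partially reflect depth, as in
the emulated workflow; users who want depth-corrected diversity should
rarefy upstream.

Bray–Curtis is computed on abundances via `scipy.spatial.distance`;
unweighted UniFrac (presence/absence) via scikit-bio on a rooted tree whose
leaves must cover all table taxa — for ITS data no curated phylogeny
exists, so the tree input is explicit and the generator's random tree is a
stand-in. PCoA is classical scaling (double-center −D²/2, eigendecompose):
all eigenvalues are reported, negatives included; by default negative
eigenvalues are excluded from the variance-explained denominator (switch
available). The implementation is cross-checked against scikit-bio's PCoA
in the test suite. Dendrograms use average linkage (UPGMA) for determinism
and ultrametric output, with node height = linkage distance / 2 and samples
pre-sorted lexicographically so tied merges resolve deterministically;
complete linkage is available.

## Hypothesis testing

Per-taxon differential abundance uses the Kruskal–Wallis rank test
(mid-ranks, tie correction, chi-square reference with k−1 df) on
within-kingdom relative abundances; the tested family is every taxon with a
nonzero total among retained samples, and the reported adjusted p is
Bonferroni over that family. Dunn's post-hoc z on pooled mid-ranks (with
the Σ(t³−t)/(12(n−1)) tie term) handles multi-level groupings, Bonferroni
over group pairs. The chi-square reference is an approximation: at very
small n it deviates from the exact permutation distribution (the suite
checks agreement within 0.05 at n = 8).

Two deliberate statistical properties of this screen, reproduced from the
emulated workflow, deserve note. First, tumor-vs-normal tests are
**unpaired** even though the design is paired; with positive within-patient
correlation (σ_patient > 0) this is conservative. Second, rank tests on
sparse taxa are conservative through tie discreteness. Consequently, null
calibration of the implementation is checked on an i.i.d. null
(σ_patient = 0, no planted effects, no attenuation), where the empirical
type-I rate is statistically compatible with the nominal 0.05. A paired
Wilcoxon signed-rank variant is available behind `paired=True`, labeled as
an extension.

Correlation screens use Spearman rank correlation (Pearson via `method`)
across samples of one tissue, with t-distributed p-values and
Benjamini–Hochberg adjustment within scope (intra-bacteria, intra-fungi,
or the rectangular bacteria×fungi screen); BH rather than Bonferroni
because the inter-kingdom family holds ~2000 exploratory pairs. Constant
taxa yield undefined coefficients, reported as missing and excluded from
the BH family.

## Random-forest layer

`fit_rf` wraps an ensemble of bootstrap-resampled CART trees
(scikit-learn; ntree = 2001 by default, odd to preclude vote ties;
mtry = 10 candidate features per split). All downstream statistics are
**out-of-bag**: a sample's vote fraction averages only trees in which it
was out of bag (full-ensemble votes would be optimistically biased), OOB
error is the misclassification rate at the 0.5 vote threshold, and
importance is mean decrease in OOB accuracy under per-tree feature
permutation (only features a tree actually uses are permuted; unused
features contribute exactly zero). Tumor and normal samples of one patient
enter fitting as independent rows — the pairing enters only through the
*d* statistic — matching the emulated workflow; patient-grouped bootstrap
resampling is available in `bootstrap_632plus` as an extension.

**Importance null**: the sorted importance curve is compared rank-wise
against `n_random_models` (default 20) refits on label permutations that
preserve class sizes.

**Backward elimination**: features are ranked once by full-model importance
(not re-ranked after drops, avoiding selection bias); each step removes
`drop_fraction` (default 0.2) of the remaining features, recording OOB
error at each size down to 2. With `c_sd = 0` the minimum-error subset is
selected, exact ties resolving toward the smaller subset (parsimony);
`c_sd > 0` applies the usual within-c·SE rule.

**0.632+ bootstrap** (default 1000 iterations): each iteration resamples
rows with replacement as training and predicts the never-drawn rows;
Err₁ averages per-item held-out error; err̄ is the apparent error of the
full-data forest predicting its own training data with all trees (the
standard apparent-error convention — near zero for fully grown forests,
which is precisely why the estimator blends it against Err₁); γ̂ is the
no-information rate Σₖ p̂ₖ(1−q̂ₖ) from observed and predicted class
marginals. Then Err₁′ = min(Err₁, γ̂), R̂ = (Err₁′−err̄)/(γ̂−err̄) clipped to
[0,1] (0 when Err₁′ ≤ err̄ or γ̂ ≤ err̄), ŵ = 0.632/(1−0.368·R̂), and
err₆₃₂₊ = (1−ŵ)·err̄ + ŵ·Err₁′. With `with_selection=True` backward
elimination runs inside every bootstrap and per-variable selection
frequencies are reported. An item never held out across all iterations
raises an error instructing a larger `n_bootstrap`.

**Field-effect statistic**: d = vote(tumor) − vote(non-tumor) per patient
(d > 0 = correct direction even when one member is misclassified). Group
comparison across a two-level patient covariate (e.g. T-stage) uses
Welch's t by default (`ranksum` optional) — operationalizing the
between-group test of the tissue×group interaction in a two-level
repeated-measures design as a two-sample comparison of the per-patient
paired differences, which is algebraically the same contrast; the original
repeated-measures MANOVA specification is not reverse-engineered further.
Identical group d-vectors return p = 1 by convention.

## Determinism and problem sizes

A single master seed derives named substreams (FNV-hash of
`"{seed}:{stage}"`, kept below 2³¹) for the forest, permutations and
bootstraps, so each stage is independently reproducible and two pipeline
runs with the same config and seed are byte-identical. The test suite and
the acceptance script run resampling-heavy stages at reduced sizes chosen
to keep the statistical claims testable — forests of 101–501 trees,
bootstraps of 50–100 iterations, 15–20 replicate cohorts per recovery
claim — while the library defaults remain ntree = 2001 and
n_bootstrap = 1000.

## Known limitations

- Compositional closure means taxon "correlations" partly reflect the
  simplex constraint; the screen is exploratory, not a causal network.
- Unpaired rank tests on paired data are conservative (see above); the
  paired variant changes the estimand and is flagged as an extension.
- UniFrac for fungi depends on a user-supplied tree; no curated ITS
  phylogeny ships with the package.
- Richness and (to a lesser degree) Shannon are depth-sensitive without
  rarefaction; the generator's depth asymmetry makes this visible.
- The 0.632+ resampling treats samples as exchangeable rows by default;
  with paired samples the leave-one-out bootstrap error is slightly
  optimistic unless patient-grouped resampling is enabled.
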