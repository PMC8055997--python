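# Methods

This note documents the models, default parameters and numerical choices
behind `snpdelim`, and what the simulation-based tests do and do not
demonstrate.

## Data model

The central container is a haplotype-row diploid SNP matrix: rows `2i`
and `2i+1` hold the two allele copies of individual *i*, one integer
allele code per site (`0/1` biallelic, `0..3` nucleotide), `-9` missing.
Phase in RAD data is arbitrary, so every sample-level computation is
symmetric in the two rows. Coverage filtering is locus-based ("fraction
of loci with at least one called site"), with a strict `<` threshold at
the default 20%. Thinning to unlinked SNPs draws one site per locus
uniformly; each locus uses a counter-keyed random sub-stream (keyed by
its first-appearance index), so appending loci never changes earlier
choices. Subsetting samples deliberately leaves the site set untouched so
a subset matrix stays locus-for-locus comparable to its parent; an
explicit `prune_uninformative_sites` is provided but never applied
implicitly.

The STRUCTURE reader tolerates ragged whitespace and auto-detects an
optional population column only when that column is constant within
every row pair *and* contains a token that cannot be an allele code;
purely numeric population labels are genuinely ambiguous with a
homozygous first site, and callers must disambiguate explicitly.

## Simulator

Loci are biallelic and independent (no linkage or sequencing-error
model). Per locus, an ancestral frequency `p ~ Uniform(0.05, 0.95)`;
population *k* with drift `F_k` draws its frequency from the
Balding–Nichols construction
`Beta(p(1−F)/F, (1−p)(1−F)/F)`, whose mean is `p` and variance
`F·p(1−p)` — `F` is an FST-like divergence. `F = 0` degenerates to the
ancestral vector; `F > 0.999` is rejected. Each haplotype copy picks a
source population from the individual's ancestry row (identity rows
without admixture; a Dirichlet blend anchored at the home population
with `admix_alpha > 0`) and then a Bernoulli allele. Missingness is MCAR
per haplotype × site entry. A cryptic-complex variant replaces one
population by two daughters drifted from it by `split_F < min(F)`,
emulating recently separated sister lineages. Default scale (8 diploids
per population, 5,000 loci, 40% missing) mirrors the ddRADseq matrices
this pipeline targets.

What the simulator does *not* emulate: linkage between SNPs on one
locus, allele dropout correlated with divergence, batch/library effects,
and missingness that depends on genotype — all present in real RAD data.
Recovery results on simulations are therefore evidence that the
*pipeline logic* works, not a calibration of its accuracy on real
matrices.

## VAE

Architecture: one-hot input flattened to `sites × states` features; two
dense ELU hidden layers (widths `max(64, sites/10)` and 32) to a
`latent_dim = 2` diagonal-Gaussian posterior, mirrored decoder with a
per-site softmax; full batch; Adam at 1e-3; 500 epochs; Glorot
initialisation. Implemented directly in numpy with hand-written
gradients (checked against finite differences in the test suite) — at
≤ ~130 haplotypes the matrices are small enough that a framework would
add nothing but a dependency.

Loss per haplotype = categorical cross-entropy summed over *observed*
sites (missing sites contribute zero input and zero loss; no imputation)
plus `kl_weight · KL(N(μ, σ²) ‖ N(0, I))`. The default
`kl_weight = "auto" = max(1, 0.02 · sites)` keeps the shrinkage toward
the standard normal at a constant strength relative to the
reconstruction term, which grows linearly with sites. This matters: with
an unscaled KL the network eventually memorises individual haplotypes
and the latent fragments into per-sample micro-clusters, which wrecks
cluster-number selection; with KL too strong the posterior collapses.
Five replicates are trained from independent initialisations and the one
with the lowest mean loss over the second half of the epochs is kept
(ties go to the lowest index) — the burn-in convention of MCMC
summaries applied to training traces. The selection demonstrably earns
its keep: badly converged replicates have visibly higher post-burn-in
loss and distorted latents.

Latent geometry is only identified up to rotation/reflection, so tests
compare embeddings exclusively through label-invariant statistics
(silhouette, recovered K, ARI), never coordinates.

The SD-overlap criterion operationalises "overlapping latent standard
deviations": sample radius `r = mean over its two haplotypes of
‖σ‖₂/√d`, and two samples overlap iff the distance between their
haplotype-mean positions is ≤ `r_i + r_j`.

## Cluster-number selection

All three methods run on the haplotype μ points by default (two per
sample; `cluster_unit: sample` switches to per-sample means) over
`k = 2..10` (gap and BIC also evaluate `k = 1`).

* **PAM/silhouette** — exact build + swap k-medoids (deterministic, ties
  to the lowest index); K maximises the average silhouette width. All
  points identical is reported as a degenerate-input error.
* **Gap statistic** — `W_k` from k-means (k-means++ init, 25 restarts),
  reference sets uniform over the data's bounding box, `B = 100` draws
  (reduced in tests). Selection uses the `firstSEmax` convention
  (smallest k within one SE of the global gap maximum); the textbook
  "first crossing" rule is available as `method="firstmax_se"` but fires
  spuriously at k = 1 whenever `Gap(1) ≈ Gap(2)`.
* **GMM-BIC** — EM over spherical/diagonal/tied/full covariance
  families, initialised from a Ward agglomerative partition, selected by
  BIC reported as `ℓ − ½·p·log n` (maximised). The covariance floor
  defaults to `1e-3` of the mean per-dimension variance: with a
  near-zero floor the likelihood blow-up of a component collapsing onto
  a few coincident points makes BIC over-split even clean data.

Haplotype labels reduce to sample labels by agreement; disagreeing pairs
resolve to the nearer cluster centre and are reported as conflicts
(candidate admixture). The consensus favours the modal K across methods
(smallest K plus a `no_concordance` flag when all disagree — a
deliberately conservative formalisation of a judgement the source
analyses made narratively). For any method reporting a larger K, splits
of a favoured cluster whose parts are connected by overlapping SD
circles are flagged as probable over-splitting; nothing is merged
silently.

## Admixture model and Evanno ΔK

The Gibbs sampler implements the classic admixture model with
independent allele frequencies: symmetric Dirichlet priors (`α = 1`
fixed on ancestry rows, `λ = 1` on frequencies), conditional draws of Z
(origin of each allele copy), P, and Q; missing copies carry no weight
anywhere. Chains warm-start from a k-means partition of per-sample
allele dosages (`init="prior"` restores flat starts): at desk-scale
chain lengths, flat starts frequently stall in poor modes at higher K,
which inflates the replicate spread of the evidence exactly where ΔK
must detect its peak. Model evidence per K is the moment estimator
`mean(L) − var(L)/2` over the post-burn-in log-likelihood trace
(burn-in = first 10%) — an approximation with a known optimistic bias;
the K = 1 test brackets it between the exact Beta-binomial marginal and
the plug-in maximum likelihood. Default run lengths are desk-scale
(2,000 sweeps); the heavy settings of a production STRUCTURE run (10⁶
sweeps, 10⁵ burn-in) are plain configuration. Replicate Q matrices are
aligned by optimal column assignment (Hungarian algorithm on the
absolute-difference cost) before averaging. The Evanno table follows the
standard definition `ΔK = |L′(K+1) − L′(K)| / sd(L(K))`, defined for
interior K only; a zero sd yields +inf with a warning (0 when the
curvature is also zero).

## Pipeline

Stages run in a fixed order: read/simulate → coverage filter → explicit
exclusions → unlinked thinning → replicated VAE → three selections →
consensus → optional admixture + ΔK → report. One top-level seed fans
out to named sub-streams per stage (SeedSequence spawning), so reports
are bit-reproducible given seed and backend. Problem-sample flags
(missingness strictly above 80%; latent position > 3× the median
within-label distance from the metadata label centroid, computed only
for labels with ≥ 3 members) are advisory: exclusion always requires an
explicit entry with a reason, keeping analyst decisions auditable.

## Test and acceptance problem sizes

Recovery experiments run at a desk scale chosen once: 600 loci, 6
diploids per population, F = 0.3, 40% missing, K_true cycling 3–6 over
20 seeds for the end-to-end modal-K check (≥ 80% required); 2,000 loci
and 20+20 diploids for the admixture ARI check; 400–600 sweeps and 3–4
replicates for Evanno recovery. These sizes keep the full suite at
minutes on one CPU while staying inside the parameter regime of the
motivating matrices (27–40 samples, ~4–5k loci, ~40% missing).

## Known limitations

* The latent bottleneck is 2-D by design (it is a visualisation-first
  method); beyond ~6–7 well-separated populations, distinct clusters can
  collide in the plane and selection methods disagree more.
* ΔK cannot evaluate K = K_min or K_max, and inherits the known bias of
  evidence-difference methods toward intermediate K.
* The GMM route uses Ward-initialised EM, not the exact model-based
  agglomeration of the R implementation it parallels; BIC values match
  closed forms but model rankings can differ near ties.
* The `mean − var/2` evidence estimator is not a marginal likelihood;
  ΔK uses differences, which cancels much — but not all — of its bias.
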