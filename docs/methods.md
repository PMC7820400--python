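# Methods

## Data model

Allele labels follow capillary-electrophoresis (CE) nomenclature: an
integer count of full repeat units with an optional `.x` suffix for x extra
bases (microvariants such as `9.3` or `29.2`). Labels are stored as exact
`(repeats, partial)` integer pairs, never floats, so microvariant
arithmetic is exact and rendering round-trips. Off-ladder calls (`OL`) are
carried as flagged labels and excluded from all statistics until resolved
by the nomenclature machinery.

Genotype tables hold an unordered pair of labels per sample × locus, with
an empty cell as the missing sentinel; each locus's sampled-allele count 2n
is computed per locus, so partial missingness at one locus does not distort
another. Frequency tables tolerate per-locus sums in [0.99, 1.01] because
published tables round to three decimals; all estimators renormalise
internally before use.

### Packaged survey fixture

The package ships the allele frequencies and per-locus summary statistics
of a published survey of 400 Kuwaiti individuals typed at the 23 autosomal
PowerPlex Fusion 6C loci (2n = 800 per locus), plus the repeat structures
of the off-ladder alleles observed in that sample. Transcription QC for the
frequency table: every locus's frequencies sum to within ±0.01 of one, the
per-locus distinct-allele counts equal the published "Alleles(v)" row, and
recomputing He and PIC from the transcribed frequencies reproduces every
published value to within 0.0009 (the tests assert ±0.002, the rounding
limit of 3-decimal inputs).

## Forensic statistics

* Ho — fraction of called individuals with two distinct alleles.
* He — unbiased gene diversity `(2n/(2n-1)) * (1 - sum p^2)`; the raw
  (uncorrected) gene diversity is available separately.
* PIC — `1 - sum p^2 - (sum p^2)^2 + sum p^4`.
* PM — by default the sum of squared *observed genotype* relative
  frequencies (what forensic STR reporting tools compute); an HWE-expected
  variant `sum p_i^4 + sum_{i<j} (2 p_i p_j)^2` exists because published
  tables print only frequencies, not genotypes. DP = 1 − PM in both modes.
* PE and TPI are the standard functions of Ho alone (see README); both are
  strictly increasing in Ho, which the tests assert on a grid.
* Combined parameters multiply across loci in log space (a 23-locus CMP is
  ~1e-30 and would underflow a naive running product long before 23 loci
  on shorter floats; log accumulation also keeps CPE = 1 − Π(1−PE) accurate
  via `log1p`).

Values are never rounded internally; the reporting layer (CLI `popreport`)
rounds half-even to a requested number of decimals.

## Equilibrium testing

The HWE test is the conditional exact test: given allele counts, the
probability of genotype array {n_ij} is
`n! Π n_i! 2^h / ((2n)! Π n_ij!)` with h heterozygotes, evaluated in log
space with `gammaln`. The p-value is the total probability of arrays no
more probable than the observed one (ties included with a 1e-9 log
tolerance).

* Exhaustive path: all arrays compatible with the allele counts are
  enumerated by a pruned recursion whose work is proportional to the number
  of arrays. It is used when that number is at most 1e5; a bounded counting
  pass (plain recursion, capped node budget, and a shortcut for ≥15 alleles
  where the matching count (2n−1)!! alone exceeds the cap) decides
  feasibility cheaply.
* Monte-Carlo path: the pooled 2n gene copies are shuffled into n pairs
  (this is exactly the conditional null), vectorised over permutation
  chunks; per-row `sum log(count!)` is computed from occurrence ranks
  within sorted runs rather than per-row bincounts. The estimator is
  `(hits + 1) / (n_perm + 1)`, so a permutation p-value is never zero, and
  a seed is mandatory.

The LD test is a permutation G-test of independence on the two-locus
genotype contingency table (single-locus genotypes as categories),
permuting one locus's genotypes across individuals. It deliberately avoids
the EM/haplotype-phase likelihood-ratio formulation: no downstream analysis
uses phase, and the permutation null is assumption-free. Monomorphic loci
return p = 1 with a note, in both tests.

Bonferroni correction and the pair count L(L−1)/2 are provided as helpers;
23 loci give 253 pairwise tests and a corrected α of 0.05/253 = 0.000198.

## Synthetic data

Subpopulation divergence uses the Balding–Nichols model: frequencies drawn
from Dirichlet(p·(1−F)/F) around ancestral p, so each allele frequency has
mean p and variance F·p(1−p); F = 0 is the defined limit returning the base
table unchanged. Genotypes are drawn under HWE within each (sub)population;
admixed individuals draw each gene copy's population of origin
independently from their ancestry vector — deliberately the same likelihood
the admixture sampler assumes, so parameter-recovery tests are
well-posed. Tiny Dirichlet draws are floored at 1e-12 and renormalised to
keep the allele support identical to the base table.

The generator reproduces the survey's sampling frame by default in the CLI
(n = 400, 23 loci; the study's subgroup sizes 162/163/75 are used in
tests). What it does **not** emulate: genotyping error, allelic dropout,
mutation, relatedness between samples, and real (surname-derived) subgroup
labels. Passing recovery tests therefore show correctness of the inference
machinery under the model's own assumptions, not robustness to real-data
artefacts.

Determinism: one `numpy` Generator seeded from the config drives
subpopulation frequency draws and genotype sampling in a fixed order, so a
seed fixes the output byte-for-byte.

## Distance, trees and ordination

Nei's DA averages (not sums) the per-locus Bhattacharyya affinities, so
panels with different locus counts (23- vs 13-locus analyses) remain
comparable. Harmonisation intersects loci across populations, unions
alleles per locus (absent alleles imputed 0) and renormalises.

Neighbour joining is the Saitou–Nei agglomeration with the standard
Q-criterion; ties break toward the lowest (row, column) index, so the
topology is deterministic. Additive matrices are recovered exactly (tested
against an independent path-length oracle on random trees and against
scikit-bio's implementation). Negative branch lengths are kept by default —
they are part of the algorithm's output — with an opt-in clamp to zero for
display. Two taxa yield a single edge of the given length; three yield the
closed-form star.

PCA is plain column-centred SVD (no variable scaling). At the population
level the variables are allele frequencies over the harmonised union —
frequencies share a scale, so a correlation-matrix PCA would only inflate
rare-allele noise. At the individual level the variables are per-allele
dosages (0/1/2); missing calls are mean-imputed per column and all-missing
columns dropped with a warning. Requesting more components than the
centred-data rank is an error.

## Admixture inference

The sampler implements the admixture model with *uncorrelated* cluster
allele frequencies: Dirichlet(λ) priors on each cluster's per-locus
frequencies, a symmetric Dirichlet(α) prior on each individual's ancestry
Q, and a latent cluster of origin per gene copy. Updates per sweep: gene
copy origins z (categorical, ∝ q_ik · p_kla), P (Dirichlet with λ + counts),
Q (Dirichlet with α + counts), and α by symmetric random-walk Metropolis on
log α (step 0.05, uniform prior on (0, 10), with the log-transform
Jacobian). The correlated-frequencies (F-model) prior is out of scope; the
uncorrelated variant is the canonical fully-specified model, and all
recovery tests simulate from the matched generative process.

Defaults: λ = 1, α₀ = 1, burn-in 5,000 and 10,000 recorded sweeps with
thinning 10 — desk-scale settings chosen so a 200-individual, 10-locus run
takes seconds; publication-scale chains (1e5/1e5) are a config away. K = 1
is handled in closed form for Q (identically 1) while still sampling P for
a comparable likelihood trace.

Ln P(X|K) is estimated as mean − sample-variance/2 of the recorded
log-likelihood trace, and Evanno's ΔK = |L″(K)|/SD(L(K)) is computed across
replicate runs, defined only for interior K of a contiguous sweep with ≥2
runs per K; a zero SD yields a missing ΔK with a warning rather than an
infinity. Cluster labels are arbitrary per run; a greedy Q-column matcher
is provided for cross-run alignment. Within-run label switching is not
corrected — for the well-separated test regimes the chains do not switch
after burn-in, but posterior-mean Q from a switching chain would shrink
toward uniformity.

## Repeat-structure nomenclature

Bracketed structures parse by a character-level scan (whitespace optional,
so published forms like `(CTTT)9T` work): `(MOTIF)` with an optional count,
or a bare DNA run with count 1. Designation is purely length-based within
the analysed region (ISFG convention): repeats = ⌊L/m⌋, partial = L mod m,
with an optional per-locus length offset. This reproduces every published
off-ladder identification at PentaE, PentaD and D22S1045 with offset 0.

SE33 is shipped with designation disabled: its CE nomenclature is not
total-length/4, and the published SE33 structures are mutually inconsistent
under any single offset (two imply 39, one implies 27 — likely a
transcription artefact in the source), so no default offset is defensible.
The offset is a config field; calibrate it against the flanking region your
assay reports before enabling.

Novel-allele reporting only ever claims "absent from the supplied
catalogue/ladder"; the package does not attempt authority lookups.

## Test and acceptance problem sizes

The test suite runs desk-scale problems chosen to keep the full run around
two minutes while leaving every statistical check well-powered: HWE
calibration uses 500 replicates × 200 permutations at n = 50; Monte-Carlo
vs exact agreement covers all ~150 biallelic arrays with n ≤ 8 at 1e4
permutations under a family-wise 3.5-SE envelope plus a mean-bias check;
sampler recovery uses 10 loci and 200–240 individuals with 300–600 sweep
chains; the Evanno sweep spans K = 1..5 × 3 replicates. Fixed seeds make
every stochastic assertion reproducible.

## Known limitations

* No θ-corrected (subpopulation) match probabilities; kinship indices
  beyond TPI are out of scope.
* The LD test detects genotype association, not gametic-phase
  disequilibrium; with strong HWE departure at both loci the two differ.
* The admixture sampler has no linkage model and no prior-population mode.
* NJ reports no bootstrap support values.
* The simulator's idealisations listed above bound what green tests imply
  about behaviour on real casework data.
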