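# Methods

`tetradqtl` reimplements, as a tested pipeline over synthetic data, the
statistical route from sparse sequencing of a two-parent yeast cross to a
mapped binary-trait QTL: a generative model of the cross, HMM genotype
inference, pre-mapping QC, single-QTL genome scans with permutation
thresholds, penalized stepwise multi-QTL selection with held-out fitting,
and bulk-segregant pool enrichment. This note records the models, the
parameters that matter, and the places where the design was genuinely open.

## Generative model of the cross (`cross_sim`)

Meiosis follows a Haldane (no-interference) crossover process: within a
chromosome a gamete's state at the first marker is B or W with probability
1/2 and switches between adjacent markers with probability
r = (1 − e^(−2d/100))/2 for a separation of d cM; chromosomes assort
independently. A tetrad is {s₁, s̄₁, s₂, s̄₂} for two independent gametes
s₁, s₂ — the simplest construction that guarantees exact 2:2 segregation at
every marker while preserving the correct single-spore marginal. Chromatid
interference and gene conversion are not modeled; "selected spores"
(isolated in bulk rather than dissected) are independent gametes with no
tetrad structure.

The binary phenotype (population autodiploidization after laboratory
evolution) is Bernoulli per segregant, with penetrance 0.69 for carriers of
the functional B allele at the causal locus and 0.18 for carriers of the
truncated W allele — so a balanced cross diploidizes at (0.69 + 0.18)/2 =
43.5% of populations. Diploidization events are independent across
populations; whether that independence holds exactly in real evolving
populations is unknowable from endpoint data, and it is the natural default.

Sequencing is emulated at the count level only (no reads): depth per
segregant × marker is Poisson(mean_depth, default 5 — low-coverage
whole-genome sequencing), of which Binomial(depth, 1 − ε) reads match the
true parental allele and the rest report the other allele. The error ε
(default 0.005) is symmetric between parents; nothing in the design
suggests an asymmetry, and the HMM below assumes the same symmetry. Pools
draw Poisson(pool_depth) reads per marker with B-probability
f_B(1 − ε) + (1 − f_B)ε for pool allele frequency f_B.

The default marker map is deterministic and yeast-proportioned: markers are
allocated to the 16 chromosomes proportionally to physical size
(~12.07 Mb total) and evenly spaced, with genetic positions at the
genome-wide average 1 cM per 2.5 kb (so the full map is ~4,830 cM, ~48
expected crossovers per gamete). When a user map lacks genetic positions
the same conversion applies; it is configurable.

## Genotype HMM (`genotype_hmm`)

Each segregant × chromosome is a two-state chain over parental origins.
Transitions between adjacent markers use the Haldane fraction of their cM
separation; the chain restarts at chromosome boundaries. Emissions are
Binomial(n_B + n_W, 1 − ε) on the reads matching the state's allele;
zero-depth markers are uninformative. Decoding is marginal
(forward–backward) rather than Viterbi: the scan consumes per-locus
genotype probabilities, so the marginal posterior is the natural output,
and thresholding it (default 0.95) gives calls with controlled
missingness. ε defaults to 0.005 and is configurable; with ε = 0,
internally inconsistent counts (reads for both alleles at one marker) have
zero likelihood under every path, and such all-impossible positions are
treated as uninformative rather than propagating NaNs.

The implementation is the scaled (normalized) forward–backward recursion,
vectorized across segregants; correctness is pinned to brute-force
enumeration over all 2^L state paths for L ≤ 12 (agreement to 1e−9) and to
the label-swap symmetry B↔W. On simulated 5X crosses the calls are >99%
accurate with ~99.9% call rate, and per-spore crossover counts are
recovered within ±1 for ≥95% of spores.

## QC (`qc`)

Three probes guard the scan: (1) per-marker segregation distortion —
chi-square goodness of fit of B:W calls against 1:1 (1 df), dropped when
p < α/n_markers (Bonferroni at family-wise α = 0.05); (2) pairwise
genotype similarity over co-called markers — pairs above 0.90 identity are
treated as duplicates and the member with more missing data is dropped
(ties toward keeping the lexicographically smaller id, so the procedure is
deterministic); (3) per-segregant crossover counts — outliers beyond
median + 5·MAD (MAD floored at 1) or twice the expected map length in
Morgans. The thresholds are package defaults, exposed in configuration;
they remove nothing from clean simulator output. QC only removes rows and
columns; it never edits calls, and rerunning it on its own output is a
no-op in practice (the MAD rule is recomputed on the filtered set, so
pathological distributions could in principle flag anew).

## Single-QTL scan (`scan`)

Genotype probabilities are computed on a pseudomarker grid (markers plus an
optional 1 cM lattice; the analysis scripts scan at markers only, which at
the default marker densities leaves no gap wider than a few cM) by the same
forward–backward machinery, with genotype *calls* as emissions at per-call
error ε and pure grid positions uninformative.

Two statistics per position:

* **EM interval mapping** — the phenotype likelihood is the two-component
  Bernoulli mixture Σᵢ log[qᵢ p_B^{yᵢ}(1−p_B)^{1−yᵢ} + (1−qᵢ) p_W^{yᵢ}(1−p_W)^{1−yᵢ}]
  with qᵢ = P(B) at the position, maximized over the penetrances (p_B, p_W)
  by EM. Initialization is the phenotype mean ± 0.1 clamped into (0,1);
  convergence when no position improves by 1e−8 log-likelihood, cap 1,000
  iterations; the EM trajectory is non-decreasing and the LOD is clipped at
  0 (the offset initialization does not formally guarantee ll ≥ ll_null).
  LOD = log₁₀ of the mixture/null likelihood ratio, the null being the
  phenotype-only Bernoulli fit.
* **Haley–Knott regression** — OLS of the 0/1 phenotype on P(B);
  LOD = (n/2) log₁₀(RSS₀/RSS₁). Degenerate positions (no genotype
  variance) and constant phenotypes give LOD 0.

Genome-wide significance: phenotype labels are permuted jointly against
whole genotype rows (unstratified), the max LOD across the genome is
recorded per permutation, the threshold is the (1 − α) quantile (default
α = 0.05, 1,000 permutations), and the genome-wide p-value of the observed
maximum uses the add-one rule (k + 1)/(n_perm + 1) so it is never exactly
zero. The HK permutation null is a single matrix product, which is what
makes the calibration study (1,000 null crosses × 200 permutations)
affordable; measured type-I error at α = 0.05 is ~0.05.

**Regress-out rescan.** With a mapped QTL as covariate, HK residualizes
both the phenotype and every genotype-probability column on
[1, covariate] (Frisch–Waugh), so the covariate's own position has LOD
exactly 0. The EM variant carries the covariate genotype as a mixture
class in both models — null: two penetrance classes weighted by the
covariate's P(B); alternative: the four (covariate × position) cells with
product weights. The null is nested, so LODs are non-negative; because the
product weights overstate the joint where the position is tightly linked
to the covariate, the EM self-LOD is near zero (~0.05 at n = 255) rather
than exactly zero. HK is the primary route for residual scans.

## Multi-QTL search (`multiqtl`)

The stepwise search maximizes the penalized LOD
pLOD = LOD(model) − T_main·(#loci) − T_int·(#interactions), with model LOD
from Haley–Knott multiple regression (locus probabilities plus product
terms for interactions). T_main is a genome-wide permutation threshold
computed on the training split over the allowed chromosomes; T_int
defaults to T_main — without a prescribed two-dimensional permutation
scheme, penalizing interactions at least as hard as main effects is the
conservative choice. Forward steps add the best locus (profiled by
residualizing on the current model) or the best interaction among included
loci, up to 4 loci; backward steps delete the element whose removal is
best; the best model visited is returned after a final descent that
guarantees no single deletion improves pLOD (a local-optimum certificate).
An empty model is returned when nothing beats pLOD 0.

Held-out fitting reports both scales: an F test from the regression design,
and a likelihood-ratio chi-square from a penetrance-per-genotype-class
model (2^m classes with product mixture weights; EM initialized at the
phenotype mean so the maximized likelihood can never fall below the null).
Variance explained is 1 − RSS_model/RSS_null on the 0/1 phenotype scale —
chosen to pair with the HK fit — with a deviance-based alternative
(1 − ll_model/ll_null on the log-likelihood scale) reported alongside,
since "variance explained" for a binary trait is scale-dependent.
Position refinement re-profiles each locus over its chromosome holding the
others fixed until nothing moves; the profiled model LOD is non-decreasing
by construction.

Allele effects at a locus are posterior-weighted phenotype means: carriers
contribute weight q (B) or 1 − q (W), the effective n is the weight sum,
and SE = √(p̂(1 − p̂)/n_eff) — the binomial SE matching the Bernoulli
phenotype.

## Pools (`pools`)

The pool statistic is the B-read fraction at one marker with a binomial CI
(Wilson by default; Clopper–Pearson available). The diploid-vs-haploid
contrast aggregates counts within each phenotype group and applies the
Pearson two-proportion chi-square without continuity correction (pool
depths are large; the correction is available as a flag). A `by=` argument
stratifies the contrast by covariate tags (e.g., auxotrophy classes) while
the headline contrast pools all strata. With penetrances p_B/p_W and a
balanced cross, Bayes' rule predicts pool fractions
P(B|diploid) = p_B/(p_B + p_W) ≈ 0.79 and
P(B|haploid) = (1 − p_B)/((1 − p_B) + (1 − p_W)) ≈ 0.27, which the
simulated pools reproduce.

## Orchestration, determinism, formats

One global seed expands into per-stage generators through a fixed
`numpy.random.SeedSequence.spawn` derivation, so any stage can be rerun
independently and a full pipeline rerun is bit-identical; every run writes
a manifest (version, seed, parameters). All formats are headered TSV
(marker map; long-form counts; segregant × marker call matrix with a
companion posterior matrix; phenotype and pool tables), scan TSVs carry
their threshold in `#` footer lines, models are JSON, and marker maps can
be imported from a VCF of biallelic parent-vs-parent SNPs (multi-allelic
and non-SNP records are skipped with a warning). Coordinates are 1-based
bp and real-valued cM; chromosome labels are opaque strings.

## Problem sizes in the test and validation studies

The validation studies run at sizes chosen to exercise the full pipeline
densely enough to be informative: recovery replicates use 255 segregants
on a 2,000-marker genome-proportional map (≈2.4 cM marker spacing — well
inside the 10 cM localization criterion; the qualitative results are
unchanged at 8,505 markers), 5X coverage, ε = 0.005, penetrances
0.69/0.18, scan thresholds from 1,000 permutations and stepwise penalties
from 400 permutations on the 150-segregant training split. Threshold
calibration uses 1,000 null crosses of 100 segregants at 192 markers with
fully observed genotypes, since the property under test is the permutation
null, not the genotyper. The tetrad diploidization rate averages 1,000
replicate 65-tetrad crosses.

## What the synthetic data does and does not show

The generator reproduces the statistical structure the analysis relies on:
tetrad 2:2 segregation, Haldane linkage, sparse binomial counts, a single
penetrant locus, phenotype-sorted pools. It omits real-data complications —
alignment and reference bias (asymmetric ε), coverage heterogeneity along
the genome, crossover interference (real yeast shows positive
interference, so simulated crossover counts are slightly overdispersed
relative to real tetrads), aneuploidy and gene conversion, and any
polygenic background beyond the single causal locus. Passing tests
therefore demonstrate that the inference machinery is correct and
calibrated under its stated model, not that the model captures every
artifact of a real sequencing experiment.

A known property of the regress-out validation: after the causal locus is
regressed out, the residual genome-wide maximum exceeds the 5% permutation
threshold in ~5% of replicates — that is what a calibrated 5% threshold
means — and the exceedances land on chromosomes unlinked to the causal
locus. The residual rescan is a null-calibration check, not an event with
probability zero.
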