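# Methods

This note documents the models and procedures implemented in `nlrkit`, the
parameters that matter, the numerical conventions, and what the synthetic
validation does and does not demonstrate.

## Entropy classification

Each receptor gene is represented by a clade alignment: one allele per
accession, aligned as proteins. Diversity is summarized per column with the
plug-in (maximum-likelihood) Shannon entropy in bits,
H = −Σ p·log₂ p over amino-acid frequencies, with 0·log 0 ≡ 0. Three
conventions are deliberate:

* **Focal coordinates.** Only columns where the designated focal (reference)
  allele is non-gap are scored, so profile position *k* is the *k*-th residue
  of the ungapped focal protein. This keeps profiles of different clades
  comparable and tied to reference-genome annotation.
* **Gap handling.** Gaps are excluded from column counts rather than treated
  as a 21st symbol; whether to count gaps is genuinely open, so the choice is
  isolated in one place (`entropy_profile`) and documented here. Ambiguous
  residues (`X`, `?`, `*`) are excluded and logged; `N` is asparagine and is
  counted.
* **Low-support columns.** Columns with fewer than two usable residues get
  entropy 0 and a `low_support` flag, never a spurious "variable" call.
  All-gap columns raise an error rather than silently scoring 0.

The hv rule — at least `min_positions = 10` positions with entropy strictly
greater than `threshold = 1.5` bits — uses a strict inequality on the
threshold and an inclusive count, which the tests pin down at both boundaries.
The plug-in estimator is biased downward at small n; no shrinkage correction
is applied because the 1.5-bit cutoff is calibrated against plug-in values.

## Population-genetic statistics

For n haplotypes over L sites: π is the mean number of pairwise differences
(total and per site), S counts columns with ≥ 2 distinct A/C/G/T states among
non-gap sequences, θ_W = S/a₁ with a₁ = Σ_{i<n} 1/i, and Tajima's
D = (π_tot − θ_tot)/√(e₁S + e₂S(S−1)) with the standard constants
(a₂, b₁, b₂, c₁, c₂, e₁, e₂ as deterministic functions of n).

Numerical conventions:

* **Per-site denominator.** L is the full alignment/CDS length, including
  monomorphic and gap-containing columns. Gaps and N reduce which pairs are
  compared at a column, never L. This matches per-site reporting against a
  fixed gene length; the alternative (accessible-site normalization) would
  change values for gappy alignments and is intentionally not implemented.
* **Indels are not variants.** A column with one real allele plus gaps is not
  segregating.
* **Undefined D.** D is NaN (never 0) when S = 0. At n = 3 the variance
  constants vanish identically (c₁ = c₂ = 0), making D a 0/0 form; it is
  reported as 0 when the numerator also vanishes and NaN otherwise.
* **SNP-matrix inputs.** Statistics from VCF-derived haplotype matrices use
  the gene's CDS length as L, so monomorphic positions count toward the
  denominator exactly as in the alignment path (the two paths are checked for
  equality on simulated data).

### π_N / π_S

Nei–Gojobori (NG86, unweighted) was chosen because it is fully specifiable:
potential synonymous sites per codon are the summed fractions of non-stop
single-base changes that preserve the amino acid (so synonymous +
nonsynonymous sites = 3 per codon exactly); pairwise differences are averaged
over shortest mutational pathways, excluding pathways through stop codons
(if every pathway is blocked, all are used); π_N = mean pairwise
nonsynonymous differences / mean nonsynonymous sites, and likewise π_S. No
multiple-hit (Jukes–Cantor-style) correction is applied — values are
interpreted as intraspecies polymorphism, not divergence. The ratio is NaN
when π_S = 0. Internal stop codons are an error; terminal stops are excluded
from site counts; codon pairs containing gaps or ambiguous bases are skipped
and counted. The 64×64 difference tables are precomputed once.

A known property of NG86 pathway averaging: when recurrent mutation places
two or more differences in one codon, fractional nonsynonymous differences
can be counted even for a history of purely synonymous substitutions, because
half of the shortest pathways may pass through a different amino acid. This
is inherent to the estimator, not a defect of the implementation, and shapes
the generator default described below.

### Domains, windows, tails

Alignment columns are assigned to CC/TIR/NBARC/LRR domains by plurality vote
among non-gap sequences, with per-sequence intervals given on ungapped
coordinates; ties (including with "no domain") give `none`. The five column
classes partition the alignment, so per-domain S sums exactly to gene-wide S.

Sliding windows are 300 bp with a 75 bp step, defined on the focal
sequence's ungapped CDS coordinates (so tracks from different clades share an
x-axis); incomplete tail windows are dropped and the value is plotted at the
midpoint s + 149. Window counts follow ⌊(L−300)/75⌋ + 1.

Empirical-tail tests compare a gene's statistic to the genome-wide
distribution: thresholds are linear-interpolation quantiles, membership is
strict inequality, and the balancing-selection criterion requires the top 5%
of both π and D jointly.

## Genomic features

* **Expression.** TPM per sample (rate = count/length_kb, scaled to 10⁶),
  then TPM averaged across replicates, then log₂(mean + 1) — the averaging
  deliberately precedes the log.
* **Methylation.** Per-cytosine percentages for cytosines with ≥ 5 reads;
  symmetric CG partners (positions i/+ and i+1/−) averaged into one site when
  both pass, the passing strand used alone otherwise; site percentages
  averaged unweighted across the full annotated gene span (UTRs and introns
  included); replicate pooling weighted by covered-site counts. Genes with no
  qualifying site are NA and listed in the exclusion sidecar, not zero-filled.
* **TE distance.** 0 when any TE interval overlaps the gene span (TEs in
  introns/UTRs are genic); otherwise the number of bases strictly between the
  intervals (gene [1001, 2000] vs TE [2501, 2600] → 500 bp). Strand ignored.
* **Clusters.** Single-linkage chaining of receptor genes with ≤ 50 kb
  (inclusive) between neighbors, gaps measured end-to-start in intervening
  bases; size-1 clusters are singletons; the assignment partitions the input
  and is order-invariant.
* **Neighbor pairs.** Two-member clusters with one hv and one non-hv member,
  within 2 kb or directly adjacent in annotation order.

## Set statistics

Permutation machinery reports both the raw null fraction `p_raw` (which can
be 0) and the add-one estimator `(b+1)/(R+1)` (which cannot); summaries use
the add-one value. Every test takes an explicit seed and reproduces exactly;
the pipeline derives independent child seeds from one master seed so results
do not depend on execution order.

The covariate-matched test realizes "matched on CG sites per gene" as
stratified resampling: the pooled genes are binned by covariate quantiles
(edges from the background; `n_bins = 10` by default), and each null draw
samples, per bin, as many genes as the observed set has there. With one bin
it reduces — same seed, same draws — to the plain permutation test. A bin
containing set genes but no background candidates is an error naming the bin
(possible when tied covariate values collapse quantile edges). Whether the
original analyses matched at this granularity is unknowable from the outside;
the bin count is therefore a parameter, not a constant.

Wilcoxon rank-sum uses exact enumeration for combined samples of ≤ 12 without
ties, otherwise the tie-corrected normal approximation with continuity
correction; Kruskal–Wallis and Fisher's exact test delegate to scipy;
Benjamini–Hochberg to statsmodels. BH correction is applied within each test
family (the figure-panel equivalents: features, popgen, per-domain, 
association, subsets, enrichment, tails), not across the whole battery.
Directions are explicit per test (hv higher expression, lower methylation,
smaller TE distance) to avoid silent one-/two-sided mismatches.

## The synthetic-data generator

The generator exists to validate the machinery against known truth, not to
imitate any particular dataset.

**Coalescent core.** A hand-coded Kingman coalescent with the `ms` scaling:
k lineages coalesce at rate k(k−1)/2 (time in 4N generations) and mutations
are Poisson with mean (θ/2) × total branch length, so E[π_tot] = θ and
E[S] = a₁θ hold exactly and serve as closed-form acceptance checks. Haplotype
simulation is infinite-sites on a finite site grid; collisions are re-drawn
(bounded), and an over-dense request errors with advice to increase L. The
simulator is cross-checked in the test suite against an independent
coalescent simulator (msprime) at matched scaling.

**Codon clades.** Mutations placed on the genealogy propose random
single-base changes; synonymous proposals are always accepted, nonsynonymous
ones with probability ω, stop-creating ones re-drawn. ω is an acceptance
probability, not a substitution-matrix likelihood: simple, and monotone in
realized π_N/π_S, which is what the validation needs. By default each codon
hosts at most one substitution across the genealogy (infinite sites at the
codon level): every pairwise codon difference is then single-base, NG86
pathway counting is exact, and ω = 0 yields π_N = 0 on every replicate. For
the deep hv-like clades this is disabled — columns can only reach more than
two amino acids through recurrent hits — at the cost of the small NG86
pathway artifact described above.

**Cohort defaults** mirror the study design the package targets: 132
receptor genes (35 hv-like, 97 non-hv-like), 32 accessions, 150 codons per
gene. θ = 300 per gene (hv-like) emulates the near-saturated allelic series
characteristic of hv receptors and puts label recovery comfortably above the
95% bar across seeds; θ = 4 (non-hv-like) is a typical conserved gene.
ω = 0.9 vs 0.15 gives hv clades their excess nonsynonymous diversity.
Feature effects are +2 log₂-fold expression, −40 percentage points of CG
methylation, and TE-overlap probability 0.6 vs 0.1 for hv-like genes —
directions and magnitudes chosen to be unambiguous at the cohort size. 600
background genes with baseline distributions stand in for the genome in
enrichment and tail tests; the empirical π/D background is simulated as
neutral coalescent genes at θ = 4 over 1.2 kb.

**What the generator does not emulate:** recombination, demography,
selection acting within the genealogy, linked sites between genes, realistic
TE families, alignment error, mapping bias, or coverage structure beyond
Poisson depth. Passing tests therefore demonstrate the correctness and
calibration of the statistics and the recoverability of planted effects —
not that real hv/non-hv differences of any particular magnitude will be
detected in real data.

## Degenerate inputs and tie-breaks

* All-gap entropy columns, empty backgrounds, empty reports, overlapping
  set/background, sets smaller than 3, groups smaller than 2: errors.
* Zero-SNP regions from VCF: empty matrix, not an error.
* All-zero count samples: TPM 0 with a warning (the 10⁶ column sum cannot
  hold).
* Domain vote ties and zero-vote columns: `none`.
* Heterozygous genotypes in inbred panels: both haplotypes emitted, counted,
  and reported rather than silently collapsed.

## Problem sizes used in validation

The automated checks run at desk scale, chosen as the smallest sizes at which
the distributional claims are stable: 2,000 coalescent replicates (n = 10,
θ = 5) for the calibration of π, θ_W and D; 200 clades per ω for the
π_N/π_S response; 1,000 null simulations at R = 1,000 for permutation
type-I calibration; the default 132-gene cohort for label recovery. The same
quantities at the same sizes are recomputed by `scripts/acceptance.py`.

## Known limitations

* NG86 only; no Ina/Li-style weighting, no codon-model likelihoods, and no
  site-level selection tests (those are treated as external inputs).
* The VCF reader iterates plain-text VCF without index support and expects
  GT-only biallelic SNP extraction; it is not a general-purpose variant API.
* Domain annotation is consumed, not predicted.
* The empirical-tail framework presumes the background distribution is dense
  enough for stable 5% quantiles (a warning fires below 100 values).
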