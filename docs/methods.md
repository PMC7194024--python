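# Methods

## Data model and formats

Genotypes are held as a samples × variants matrix counting copies of the
A1 allele (0/1/2, −1 missing), with optional per-sample haplotype pairs
whose sums must equal the calls at every non-missing site.  PLINK 1
binary I/O is bit-exact against the published layout (SNP-major, two
bits per call, zeroed padding); sample-major files are rejected rather
than transposed, and the half-missing code 0b01 is treated strictly as
missing.  Positions are 1-based base pairs; all internal distance
arithmetic is in bp and converts to Mb/kb only at reporting.  When
datasets are merged, variants are matched by id, A1/A2 swaps flip calls
0 ↔ 2 (an involution), and irreconcilable alleles are an error; the
flips are logged.

## Quality control

Filters run in a fixed order so per-criterion removal counts are
unambiguous: (1) unknown/duplicated positions and sex-linked SNPs — both
members of a duplicated-position pair are removed; (2) MAF < 0.01;
(3) call rate < 95%; (4) Hardy–Weinberg exact p < 10⁻¹⁵.  The HWE test
is the genotype-conditional two-sided exact test (outcomes no more
probable than the observed heterozygote count), evaluated with a
log-space ratio recurrence so it is stable at tens of thousands of
genotypes; degenerate tables return p = 1.  Pooled-mode QC applies the
same test to the merged sample, so Wahlund-effect removals are the
intended pooled behavior.  An all-missing SNP has undefined frequency
and falls to the call-rate rule.  Heterozygosity analyses reuse the QC
but drop the HWE criterion; the polymorphic-SNP proportion drops the MAF
criterion (with it, the proportion is trivially 100%).

LD pruning is the sliding-window VIF procedure: within each 50-SNP
window the SNP with the largest VIF = 1/(1 − R²) (from the inverse of
the window genotype-correlation matrix) is removed until all VIF ≤ 2,
then the window advances 5 SNPs.  Monomorphic SNPs are skipped in the
regression and never trigger removals; near-singular windows get a 1e-8
ridge on the correlation diagonal; ties break toward lower MAF, then
toward the later input position (the earlier SNP survives), making the
procedure deterministic.

## Linkage disequilibrium and gametic phase

Haplotype frequencies come from direct counting when phase is known.
For unphased data the EM over the double-heterozygote ambiguity is used
(converged when successive f(AB) differ < 1e-10, max 1,000 iterations);
this is the genotype-likelihood ML estimate, which equals direct
counting exactly when no individual is heterozygous at both loci and
differs from the realized phase counts by O(sampling noise) otherwise —
the test suite quantifies that gap.  r² carries no reporting floor: all
pair estimates enter the bin means.  Distance bins are half-open
(lower, upper]; the 20-bin scheme is < 0.01 Mb, nine 0.01-Mb bins to
0.10, nine 0.1-Mb bins to 1.0, and an open top bin, so the bins cover
(0, ∞).  Bins are reported at ≥ 50 pairs (configurable); pair
enumeration defaults to a 5-Mb cap.  Pairs whose pairwise-complete
subset keeps less than half the samples are skipped.

Phase consistency between two populations matches variants by id, aligns
alleles via the flip log, computes signed r per shared pair in each
population, and reports the Pearson correlation per bin and pooled over
all pairs (the pooled value is the headline number; bin correlations are
exposed separately).

## Runs of homozygosity

The scan follows sliding-window semantics: 50-SNP windows with ≤ 1
heterozygous and ≤ 5 missing calls are "homozygous"; a SNP is eligible
when ≥ 5% of the windows containing it are homozygous; maximal eligible
runs are split at inter-SNP gaps > 1,000 kb, trimmed to called
homozygous end-SNPs, and kept if they satisfy the minimum SNP count,
minimum length (1,000 kb) and density (≤ 50 kb per SNP).  The minimum
SNP count defaults to the false-positive rule
ceil( ln(α / (n_snps · n_individuals)) / ln(1 − het) ) at α = 0.05,
with het taken as the mean per-individual observed heterozygosity of the
analyzed set (the per-SNP alternative differs little); it can be
overridden.  F_ROH divides ROH-covered length by the SNP-covered span
(first to last SNP per autosome) rather than physical assembly length,
since only the typed span is observable; segment length is end − start
in bp.

## Inbreeding estimators

F_E uses E_hom = Σ_j [1 − 2 p_j q_j · A_j/(A_j − 1)] with A_j the called
allele count — the standard small-sample correction.  F_G is diag(G) − 1
with G = ZZ′/2Σp_j q_j (method 1, observed frequencies); missing calls
are mean-imputed to 2p_j and the imputation count is recorded.  Pedigree
F is computed by the Meuwissen–Luo-style recursion: each individual's
numerator-relationship diagonal is accumulated from path coefficients
over its ancestor tree with the within-family segregation coefficients
D_j, in linear memory; founders (unknown parents) are unrelated and
non-inbred, and a detected cycle is an error.  The recursion agrees with
the full tabular A-matrix to machine precision.

## Structure and differentiation

PCA decomposes the variance-standardised (method 2) GRM; coordinates are
eigenvectors scaled by √eigenvalue, variance fractions use the full
spectrum with negative eigenvalues floored at zero, and each component's
largest-magnitude loading is made positive for reproducible orientation.
The population tree uses 1 − (average IBS) over cross-population sample
pairs (optionally a seeded per-population subsample), clustered with
complete linkage and serialised as Newick.  F_ST is the two-population
Weir–Cockerham variance-components estimator (sample-size weighted,
heterozygosity corrected); the naive (p₁ − p₂)²/(4 p̄ q̄) form is
available behind a flag because the two are often conflated.  Both the
unweighted mean of per-SNP values and the ratio-of-summed-components
mean are reported; outliers are SNPs above mean + 3 SD, and FST scans
are strictly pairwise.

## The simulator: what it emulates and what it does not

The generator is a forward Wright–Fisher model with standing variation
only: founders are drawn in linkage equilibrium at uniform founder MAF,
LD then builds by drift over a burn-in, and populations branch from the
ancestral lineage at configured split times.  Mating is monogamous
random pairing (shuffled halves are sires and dams, each offspring draws
a random couple → near-Poisson litter sizes, no selfing).  Recombination
follows the Haldane no-interference model, implemented as independent
Bernoulli phase switches between adjacent markers at the map-distance
recombination fraction — distribution-identical to a Poisson crossover
count with uniform placement — on a uniform map (bp ∝ Morgans, no
hotspots).  Every haplotype carries founder-ancestry labels through the
same transmissions, so autozygosity (both labels equal) is known
exactly; `gene_drop` runs the same transmission through an arbitrary
pedigree for scripted matings.  A fixed seed reproduces output exactly.

The reference scenario (`study_config`) uses desk-scale sizes: three
populations (N_e 200 / 40 / 300, splits 80 and 30 generations ago,
ancestral N_e 150, 150 burn-in generations), four 30-Mb chromosomes with
2,000 raw markers each (15-kb grid), and array-style ascertainment that
keeps markers with pooled MAF ≥ 0.05 — emulating that a chip carries
jointly segregating SNPs, and leaving the panel spacing compatible with
the kb-scale ROH density rule.  Because effective sizes are two orders
of magnitude below real composite sheep populations, absolute LD and
drift levels are higher than an HD-panel study (adjacent r² ≈ 0.45–0.77
versus ~0.16–0.23; F_ROH ≈ 0.1 versus ≤ 0.02): the scenario preserves
the *orderings* a real study interprets — the bottlenecked population
has the most LD, the lowest phase consistency with the main population,
the most MAF-filter losses and the highest marker-based inbreeding —
not the absolute magnitudes.  Passing tests therefore demonstrate
estimator correctness (against enumeration, closed-form drift theory,
planted tracts, and the tabular pedigree method) and qualitative
behavior, not calibration to any particular breed.  The simulator has
no mutation, selection, migration after splits, sex chromosomes, or
variable-density maps.

## Numerical and design choices

* Wherever a statistic divides by an allele-frequency variance, SNPs
  monomorphic in the relevant subset are excluded (LD pairs skipped,
  method-2 GRM requires pre-filtering, jointly monomorphic SNPs dropped
  from FST).
* The Weir–Cockerham estimator may dip slightly below zero per SNP;
  values are not clipped.
* Acceptance-style validation sizes (e.g. 50 drift replicates at
  N_e = 100, 20 tree-recovery replicates, 10,000-SNP GRM calibration)
  were chosen so the whole suite runs in a few minutes on one CPU while
  keeping Monte-Carlo error well inside the asserted bounds.
* The average-IBS population tree reflects within-population diversity
  as well as divergence: a strong bottleneck shortens a population's
  distances to everyone by raising its homozygosity.  In the reference
  scenario this makes the FIN branch sit closer to NWS than the
  divergence times alone would suggest; topology recovery is validated
  under matched effective sizes, where the distance ordering is driven
  by the splits.

## Known limitations

Two-locus EM is the only phasing performed; interchromosomal LD,
ROH-island mapping, model-based admixture decomposition and
meta-founder pedigree models are out of scope.  F_PED treats all
founders as unrelated, so deep but unrecorded inbreeding is invisible
to it — the simulator's truth tracts make exactly this gap measurable.
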