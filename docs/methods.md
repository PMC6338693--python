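# Methods

This note records the models, parameter choices and numerical
conventions behind `oligopipe`, and what the synthetic-data tests do and
do not demonstrate about real data.

## Gene-based GWAS association test

The per-gene statistic is the sum of the top *k* squared SNP z-scores in
the gene window (default *k* = 10).  The null is simulated: 10,000
z-vectors are drawn from MVN(0, *R*), with *R* the gene's SNP–SNP
Pearson LD matrix, and scored with the same statistic.  The p-value is
the add-one tail frequency (r + 1)/(n + 1), which is never 0 and never
below 1/(n + 1) — a deliberate finite-sample convention so downstream
−log₁₀ transforms are always defined.

Choices that matter:

* **Gene window.**  SNPs are assigned to every gene whose interval,
  flanked by ±50 kb (configurable), contains them; SNPs in overlapping
  windows count for all such genes.  BED input is 0-based half-open,
  summary-statistic positions are 1-based; the conversion lives in one
  place (`assign_snps_to_genes`).  The 50 kb default is the conventional
  gene-based-test window; there is no single "correct" value and results
  at loci with long-range LD are sensitive to it.
* **LD matrices.**  Validated symmetric with unit diagonal; eigenvalues
  in (−10⁻⁸, 10⁻¹⁰) are clipped to a 10⁻¹⁰ floor and the diagonal
  renormalized, because LD estimated from finite reference panels is
  routinely marginally indefinite.  Anything more indefinite is an
  error, not repaired silently.
* **Seeding.**  Every gene gets an independent stream derived from
  (global seed, CRC32 of the gene id), so results are identical whether
  genes are processed serially or in parallel, and stable under gene
  reordering.
* **p-to-z input.**  If only p-values are supplied they are converted to
  |z| via the standard normal quantile of p/2; the statistic squares z,
  so the lost sign is irrelevant.

## Co-expression modules

Signed adjacency a_ij = ((1 + cor_ij)/2)^β with Pearson correlation
across samples and β = 12, the customary power for signed networks; a
`scale_free_fit` helper reports the scale-free topology R² over
β ∈ {4…20} for users who want to choose β from their data.  Topological
overlap is

    TOM_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),

diagonal 1.  Modules come from average-linkage hierarchical clustering
of 1 − TOM with a **static** cut (dynamic tree cut is deliberately out
of scope), followed by k-means-style refinement: 30 iterations of
reassigning each module gene to the module eigengene (PC1 of the
standardized member submatrix, sign-oriented to correlate positively
with its members) it correlates with most, dissolving modules that fall
under `min_size` (default 30) and stopping at a fixed point.

Two design points were genuinely open:

* **Cut height.**  The default is 0.95.  On simulated data the heights
  at which module genes finish merging (~0.86–0.93 for within-module
  correlation 0.7–0.8) and the heights at which unrelated background
  genes attach to module clusters through shared-neighbour overlap
  (~0.955 upward) are separated by a gap; 0.95 sits inside it.  A cut at
  0.99 demonstrably sweeps background genes into modules.  On real data
  this gap depends on sample size and correlation structure, and the
  parameter is exposed for that reason.
* **Grey genes in refinement.**  Refinement repartitions the genes the
  clustering assigned to modules; background ("grey") genes stay grey.
  Reassigning every gene including grey would pull unassigned genes into
  their nearest module and erase the background/module distinction the
  clustering just established.  Genes of dissolved modules likewise stay
  grey.  Consequently refinement can never increase the number of
  non-grey modules.

## Module enrichment

x is the module mean of −log₁₀ gene p; z standardizes x against the mean
and **population** standard deviation (divisor n) of the same values
over all network genes — the divisor choice is immaterial at realistic
network sizes but is fixed for reproducibility.  The null is 10,000
random same-size modules drawn uniformly without replacement within each
draw (genes may recur across draws); the empirical p is one-sided
(enrichment = large z) with the add-one convention, then Bonferroni
multiplied by the number of modules tested in the run.  Grey genes are
part of the network gene set G by default (`exclude_grey` inverts this):
they carry gene-level p-values like any other gene and belong to the
sampling frame the observed module was drawn from.

Marker-set overlap is a hypergeometric upper tail (P[X ≥ observed
overlap]) with the network genes as the universe and case-insensitive
gene-id matching.  The choice of test is an assumption — the overlap
test used for the original marker claims is not specified anywhere we
could implement from — and hypergeometric is the field default.

## Burst simulation and sm-FRET analysis

The trace generator emulates a confocal two-channel (donor AF488 /
acceptor AF594) experiment at 1:1 labelling stoichiometry, binned in
time.  Per bin and channel, background is Poisson (default mean 2
counts/bin).  Monomers arrive per bin with probability
`monomer_event_rate` (default 0.05) and add Poisson donor-only signal of
mean `monomer_brightness` (default 100 counts).  An oligomer of size *s*
with efficiency *E* adds Poisson signal of mean (s/2)·B·(1 − E) in the
donor and γ·(s/2)·B·E in the acceptor channel — the s/2 reflects that
half the subunits carry each dye — so the efficiency and apparent-size
estimators below are unbiased in expectation.  The oligomer event rate
is derived from `oligomer_mass_fraction` (default 1.5 % of all
monomer-equivalents, the load a typical late-lag-phase aggregation
mixture shows) and the mean of `oligomer_size_dist` (default sizes
2–10, consistent with small soluble oligomers below 20-mers).  Dust is a
bright flat artifact spanning 2–3 consecutive bins in both channels.
Ground truth records every planted event with its bin, span, species,
true size, and an `isolated` flag (no other event within one bin),
enabling exact accounting.

What the generator does **not** model: diffusion kinetics and residence
times (events live in exactly one bin), dye photophysics (blinking,
bleaching, quenching), spectral crosstalk, and afterpulsing.  Passing
tests therefore demonstrate the estimators and filters are correct under
shot noise and Poisson background, not robustness to those instrument
effects.  The Poisson noise model itself is a stand-in: real detector
noise statistics are instrument-specific.

Analysis conventions:

* **Burst detection.**  A bin is a burst bin when either channel exceeds
  its background mean plus 5·√background (5σ under Poisson,
  configurable).  Maximal runs of consecutive burst bins form one burst;
  intensities are background-subtracted, clipped at 0, summed over the
  run.  No crosstalk corrections are applied by default ("corrected"
  intensity = background-corrected).
* **Coincidence.**  A burst is coincident when *both* channels
  individually exceed their detection thresholds within the run.
  Testing the background-subtracted acceptor against zero instead would
  misclassify roughly half of all monomers under Poisson background
  (the subtracted value is positive with probability ≈ 0.5), destroying
  the monomer/oligomer distinction the analysis rests on.
* **Monomer brightness.**  I_monomer is the mean donor intensity of
  non-coincident single-bin bursts — monomers by the above definition.
* **Filters.**  Retained oligomeric bursts are coincident, single-bin,
  and apparent size ≤ 150 ("greater than 150-mers" is read strictly:
  150 is kept, 150.0001 removed).  Any burst in a run of ≥ 2 bins is
  removed entirely, not trimmed.  Removal reasons are logged per burst.
* **Histogram.**  20 bins of width 0.05 on [0, 1]; left-closed,
  right-open, except the last bin is closed so E = 1 is representable.
* **GaussAmp fit.**  Levenberg–Marquardt (trust-region with bounds
  x_c ∈ [0, 1], w ∈ (0, 1], A ≥ 0) from the initialization (min count,
  max − min, argmax centre, w = 0.1).  Fits on histograms with fewer
  than 4 occupied bins are refused; optimizer non-convergence sets
  `converged = False` rather than raising.
* **Oligomer mass fraction.**  100 × Σ(apparent sizes of retained
  oligomeric bursts) / (that sum + number of monomeric bursts), i.e.
  monomer-equivalents in oligomers over all detected monomer-equivalents.
  This convention is defined here explicitly; it reproduces the planted
  ground-truth fraction to well within ±0.5 percentage points at 10⁵
  bins in the shipped tests.

## Synthetic GWAS and expression generators

* **LD.**  One AR(1) block per gene (entries ρ^|i−j|, default ρ = 0.5),
  no inter-gene LD.  AR(1) with |ρ| < 1 is positive definite by
  construction, which keeps every simulated block Cholesky-factorizable.
  Real LD is block-irregular and long-tailed; the AR(1) choice matches
  the per-gene MVN null exactly and is not intended as a human LD map.
* **Effects.**  Causal genes receive a mean shift (`effect_size`,
  default study condition 2.0 in the enrichment-recovery experiments) on
  every SNP z — a summary-statistic-level noncentrality, not a genotype
  model.  Every downstream stage consumes summary statistics only, so
  this is sufficient and much cheaper.
* **Expression.**  Modules share a latent sample profile; member genes
  are a·latent + noise with a set so the expected within-module Pearson
  correlation equals `within_module_cor` (default 0.8; the recovery
  experiments also run 0.7).  Defaults — three modules of 40 genes, 40
  background genes, 60 samples — approximate a small brain-tissue
  expression panel while keeping the TOM computation instant.
* **Scale.**  The shipped experiments run at hundreds of genes rather
  than the ~19,000 probesets of a full-array network; all statistics
  scale per-gene and the module test is exchangeable in gene identity,
  so the calibration properties checked here (null uniformity, type-I
  error, enumeration equivalence) carry over, but absolute power at
  consortium scale is not measured by this package.

## Known limitations

* The static cut height, β and minimum module size interact; the
  defaults are tuned for well-separated planted modules and will need
  data-driven choice (and possibly dynamic tree cut, not provided) on
  real expression data.
* The enrichment null treats gene p-values as exchangeable across the
  network; gene size and LD-driven correlation between neighbouring
  genes' p-values are not modelled in the random-module null, exactly as
  in the statistic this package implements.
* The burst analysis is binned, not photon-by-photon; shot-noise
  broadening of the efficiency histogram is inherent and the GaussAmp
  width w conflates it with true conformational heterogeneity.
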