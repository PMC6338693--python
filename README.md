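# oligopipe

Analysis toolkit for studies connecting protein-aggregate biology to
disease genetics, built around two questions about α-synuclein oligomers
and Parkinson's disease:

1. **Are disease-associated genes concentrated in particular brain
   co-expression modules?**  A VEGAS-style gene-based GWAS test feeds a
   randomization enrichment statistic over signed-TOM co-expression
   modules, with cell-type marker-set overlap as a follow-up.
2. **What species are present in an aggregating α-synuclein solution?**
   Single-molecule FRET burst analysis of two-channel photon traces:
   per-burst efficiency and apparent oligomer size, artifact filters,
   efficiency histograms and a baseline-plus-Gaussian fit.

It is aimed at computational biologists who want these two pipelines as
tested, seeded, scriptable components rather than one-off notebook code.
Because consortium GWAS data, brain expression arrays and confocal
instrument traces cannot be bundled, a synthetic-data module generates
statistically faithful stand-ins with known ground truth, and the whole
test suite runs against those.

## The statistics

**Gene-based GWAS test.**  For a gene with SNP z-scores *z₁…z_m* and LD
correlation matrix *R*, the statistic is the sum of the top *k* = 10
squared z-scores.  Its null distribution is simulated with 10,000 draws
from MVN(0, *R*) scored identically; the p-value is the add-one tail
frequency (r + 1)/(n + 1).

**Module enrichment.**  For a network *G* of *n* genes and a module *m*
with genes *G(m)*, |G(m)| = k:

    x  = (1/k) Σᵢ −log₁₀ p(gᵢ)          over G(m)
    z  = (x − X̄) / σ(X)                 X̄, σ(X) over all of G

Significance comes from 10,000 random size-k modules sampled from *G*
(empirical one-sided p, add-one), Bonferroni-corrected across modules.
Marker-set overlap is a hypergeometric upper tail.

**Co-expression modules.**  Signed adjacency a = ((1 + cor)/2)^β with
β = 12, topological overlap TOM, average-linkage clustering of 1 − TOM
with a static cut, then 30 iterations of k-means-style refinement on
module-eigengene correlation.

**sm-FRET.**  For a coincident burst with corrected intensities I_D, I_A
and instrument factor γ = 0.99:

    E             = I_A / (I_A + γ I_D)
    apparent size = 2 (I_D + γ⁻¹ I_A) / I_monomer

Bursts larger than 150-mers or spanning multiple consecutive time bins
are discarded (fibrils/dust).  Efficiencies are histogrammed at bin
width 0.05 and fitted with y = y₀ + A·exp(−(x − x_c)²/2w²); x_c is the
mean FRET efficiency.

## Worked example

Simulate both arms and run them end to end (all commands are also
available as `oligopipe simulate / genetics run / smfret run`):

```python
from oligopipe.pipeline import run_simulate, run_genetics, run_smfret

cfg = {
    "seed": 11,
    "gwas_sim": {"n_genes": 120, "snps_per_gene": 10,
                 "causal_gene_ids": [f"G{i:04d}" for i in range(40)],
                 "effect_size": 2.0},
    "expr_sim": {"module_sizes": [40, 40, 40], "n_samples": 60,
                 "background_genes": 0},
    "burst_sim": {"n_bins": 100_000, "background_mean": 2.0,
                  "monomer_event_rate": 0.05,
                  "oligomer_mass_fraction": 0.015},
    "smfret": {"donor_background": 2.0, "acceptor_background": 2.0},
}
run_simulate(cfg, "demo")          # writes gwas.tsv, genes.bed, ld/, expression.tsv, trace.csv
print(run_genetics(cfg, "demo").to_string(index=False))
sm = run_smfret(cfg, "demo")
```

The 40 causal genes coincide with expression module M1, and the
enrichment table singles it out:

```
module  k        x         z  emp_p  bonf_p  n_random
    M1 40 3.271239  1.255294 0.0001  0.0003     10000
    M2 40 0.431591 -0.652153 1.0000  1.0000     10000
    M3 40 0.504555 -0.603141 1.0000  1.0000     10000
```

`x` is the module's mean −log₁₀ gene p-value, `z` its standardized
enrichment score, `emp_p` the random-module empirical p (here at the
add-one floor 1/10001) and `bonf_p` the Bonferroni-corrected value.

The burst pipeline on the simulated trace (planted oligomer mass
fraction 1.5 %, planted E = 0.65) reports:

```
I_monomer=99.6  oligomeric_bursts=15  mass_fraction=1.74%  E_center=0.667
```

i.e. monomer brightness recovered at ~100 donor counts, an oligomer
mass fraction of 1.74 % of all detected monomer-equivalents, and a
fitted efficiency-histogram centre near the planted high-FRET value.

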