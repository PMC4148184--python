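# haplomix

Joint haplotype / somatic copy-number hidden Markov model for detecting
**subtle allelic imbalance** in SNP-array data from unpaired mixed samples —
down to a few percent aberrant-cell fraction, well below where conventional
BAF/LRR segmentation stops working.

## Who this is for

Groups analyzing SNP genotyping arrays of samples that are mostly normal
DNA with a small aberrant component: adjacent-normal tissue with tumor
contamination, high-stromal tumors, clonal mosaicism in blood, or rare
subclones.  Input is a per-marker table of B allele frequencies (BAF) and
log R ratios (LRR) plus a phased reference haplotype panel of matched
ancestry; output is per-marker posterior probabilities over aberration
categories, merged segments, an estimate of the aberrant-cell proportion,
and per-marker probabilities for which allele/haplotype is over-represented.

## The model in brief

Two hidden Markov chains run along the genome and are decoded jointly:

- a **haplotype-cluster chain** (fastPHASE-type), fitted to a phased
  reference panel: `K` latent ancestral haplotypes with per-marker allele
  frequencies `theta[m, k]`, weights `alpha[m, k]` and distance-dependent
  jump probabilities capture linkage disequilibrium.  The individual's two
  haplotypes are an *ordered* pair `z_m = (k1, k2)` of cluster memberships;
- an **aberration chain** over ordered parent-specific copy numbers
  `l_m = (c1, c2)` in the aberrant cells (total ≤ 5: 21 states, reported as
  12 mirror-collapsed categories), with a normal-hub transition matrix
  parameterized by mean event length and aberrant genome fraction.

Given both chains and the aberrant-cell proportion `w`, observations are
independent across markers.  At a heterozygous marker the BAF is a
two-component normal mixture over the haplotype configurations,

    E[BAF] = [(1 - w) + w·c_B] / [(1 - w)·2 + w·(c1 + c2)],

with mixture weights supplied by the haplotype model (this is where phase
information enters — an imbalanced segment shifts all its het markers
*coherently* toward one haplotype); the LRR is normal with mean
`o + q·log2(((1 - w)·2 + w·(c1 + c2))/2)`.  Exact forward–backward
recursions on the factorized product chain give per-marker posteriors, and
a generalized EM estimates `{w, sigma_b, sigma_r, o, q}` per sample.  A
`K = 1` mode (no haplotype information) and a reduced BAF-only mode are
included as baselines.

## Worked example

`examples/03_simulate_and_run.py` plants a cn-LOH and a deletion segment in
an 8,000-marker chromosome at **5% purity** — BAF bands at 0.5 ± 0.025
against noise of sd 0.03, invisible in a scatter plot — then fits and
decodes:

```
simulated 8000 markers; aberrant: 3300
estimated purity w = 0.0467 (truth 0.05), sigma_b = 0.0305, sigma_r = 0.1792, 5 EM iterations

called segments (1-based, inclusive):
chrom    start      end category  n_markers  mean_posterior
 chr1     9000  9126000      1-1       1014        0.988493
 chr1  9135000 22680000      2-0       1506        0.978081
 chr1 22689000 44793000      1-1       2457        0.982382
 chr1 44802000 61425000      1-0       1848        0.986250
 chr1 61434000 72000000      1-1       1175        0.982354

marker-level sensitivity 0.996, specificity 0.986 (aberrant vs normal)
```

The planted cn-LOH (`2-0`, markers 1000–2500) and deletion (`1-0`, markers
5000–6800) are recovered essentially marker-exactly, and the EM lands
within half a point of the true mixing proportion.  The other examples
cover the state space (`01`), panel fitting and what the configuration
probabilities mean (`02`), over-represented-allele inference vs the naive
BAF rule (`04`), and the minimal detectable cn-LOH length at a given purity
(`05`).

A thin command-line interface wraps the same pipeline for shell use:

```bash
haplomix simulate  --purity 0.05 --seed 1 --out-prefix sim
haplomix fit-panel --haps sim.panel.haps --map sim.panel.map --k 5 \
                   --n-starts 2 --seed 1 --out-prefix panel
haplomix run sim.sample.tsv --model panel.start1.cluster.json \
             --model panel.start2.cluster.json \
             --purity-init fixed:0.05 --seed 1 --out-prefix out
haplomix evaluate out.posterior.tsv sim.truth.tsv --out metrics.json
```

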