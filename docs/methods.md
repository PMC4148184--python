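# Methods

## The problem

A DNA sample from tumor-adjacent or poorly dissectable tissue is a mixture:
a large germline (normal) component plus a small fraction `w` of cells
carrying somatic chromosomal aberrations.  On a SNP genotyping array the
evidence for those aberrations lives in two per-marker summaries: the
B allele frequency (BAF), whose heterozygous band shifts away from 0.5 in
regions of allelic imbalance (AI), and the log R ratio (LRR), which tracks
total copy number.  Below roughly 10% aberrant-cell fraction the BAF shift
(e.g. ±0.025 at `w = 0.05` for copy-neutral LOH) is smaller than the BAF
noise, so single-marker methods fail.  What still identifies the signal is
its *direction*: within one AI segment, every heterozygous marker shifts
toward the allele carried by the same physical haplotype.  Knowing the
individual's haplotypes therefore turns many weak, incoherent shifts into
one long, coherent one.  haplomix models the haplotypes and the aberrations
jointly and integrates over haplotype uncertainty instead of committing to
a single phasing.

## Model

### Germline: haplotype-cluster chain

Haplotypes are mosaics of `K` latent clusters ("ancestral haplotypes").
Cluster `k` emits allele B at marker `m` with frequency `theta[m, k]`;
cluster membership follows a Markov jump chain: between adjacent markers a
haplotype jumps with probability `rho[m] = 1 - exp(-gamma * d[m])` (`d[m]`
the physical distance, `gamma` a fitted global rate) and, if it jumps,
lands in cluster `k` with weight `alpha[m+1, k]`.  An individual's two
haplotypes are independent draws; the model tracks the **ordered** pair
`z_m = (k1, k2)` because pointing an imbalance at a specific haplotype is
exactly what the ordering provides.  Conditional on `z`, the genotype is
two independent Bernoulli draws, and at a heterozygous marker the
probability that haplotype 1 carries the B allele (the "configuration") is

    P(h1 = B | AB, z) = t1 (1 - t2) / [t1 (1 - t2) + (1 - t1) t2].

The model is fitted to a phased reference panel by EM; the chains for the
panel haplotypes are independent, so the E-step is one scaled
forward-backward pass per haplotype.  `theta` and `alpha` have closed-form
updates (posterior-weighted allele fractions; normalized expected jump
landings); `gamma` is a guarded 1-D bounded maximization, making the whole
procedure a generalized EM with a non-decreasing panel log-likelihood.

Initialization seeds each cluster's `theta` from a randomly chosen panel
haplotype, softened toward the panel frequency.  We found this materially
better than starting all clusters at a perturbed allele frequency: with
frequency-based starts the clusters begin nearly indistinguishable and EM
settles into weakly separated optima whose phase information is visibly
poorer downstream (on one 3%-purity benchmark sample, marker sensitivity
0.53 vs 0.66 with identical data and seeds).  Because the surface is
multi-modal either way, the engine accepts several fitted models (random
starts) and averages posteriors across them, which is also how the fitted
models are meant to be consumed.

### Somatic: parent-specific copy-number chain

The aberration state at a marker is an ordered pair `(c1, c2)`: the copy
numbers of haplotype 1 and 2 in the aberrant cells.  With total copy number
capped at 5 there are 21 states; `(1,1)` is normal, `(1,0)/(0,1)`
hemizygous deletion, `(2,0)/(0,2)` copy-neutral LOH, and so on.  Mirror
states describe the same unordered event with opposite haplotype
assignment, so reported posteriors collapse mirror pairs into 12 categories
(3 balanced + 9 imbalanced); the collapse is exact because every part of
the model is mirror-symmetric.

Transitions form a "normal hub": the chain enters an aberrant state from
normal with total probability `p_enter = f / ((1 - f) L)` (split equally
over the 20 aberrant states) and exits with probability `1 / L`, giving
stationary aberrant mass `f` and mean sojourn `L` markers.  Defaults
`L = 600`, `f = 0.1`.  Direct aberrant-to-aberrant transitions are
disallowed — the simplest structure satisfying the symmetry, mean-length
and coverage constraints.  Chains restart from the stationary distribution
at each chromosome; aberration events are independent across chromosomes.

### Emissions under admixture

At a heterozygous marker with aberration state `(c1, c2)` and configuration
`h` (which haplotype carries B), the BAF is normal with mean

    mu_b = [(1 - w) + w c_B] / [(1 - w) 2 + w (c1 + c2)],

a mixture over the two configurations weighted by the configuration
probability from the haplotype model.  At homozygous or genotype-missing
markers the BAF factor is 1 (BAF carries no aberration information there).
The LRR is normal with mean `o + q log2(((1 - w) 2 + w (c1 + c2)) / 2) +
gc_coef * gc`, with a sample-specific scale `q`, baseline `o`, and an
optional linear correction on mean-centered GC content (zero when no GC
track is supplied).  One shared `sigma_b` and one `sigma_r` serve all
states.  BAFs are clipped to [0, 1] on input; the density itself is an
untruncated normal.  Genotypes are called from BAF by simple thresholds
(AB in [0.2, 0.8], boundaries inclusive), adequate at low purity where
genotype calls are essentially unperturbed.

### Joint inference

The joint hidden state is `(l_m, z_m)` with `21 K^2` combinations; the two
chains are a priori independent and the observations are conditionally
independent given both.  Exact marginals come from scaled forward-backward
recursions per chromosome.  Transitions are applied in factorized form —
an aberration step along `l`, then one jump step per haplotype chain — so
the per-marker cost is `O(21 K^2 (21 + K))` instead of the dense
`O((21 K^2)^2)`; a test verifies the factorized recursion against a dense
Kronecker-product chain.  Scaling constants per marker keep 300k-marker
chromosomes in range.  The per-chromosome E-step is embarrassingly
parallel by construction; the implementation runs it serially with
identical results.

### EM for sample parameters

`{w, sigma_b, sigma_r, o, q, gc_coef}` are estimated by generalized EM.
The E-step stores, per marker, the aberration-state posterior and the joint
(state, configuration) posterior at heterozygous markers, reduced to
per-state sufficient statistics.  The M-step profiles everything except
`w`: given `w`, `(o, q[, gc_coef])` solve a posterior-weighted least
squares on the LRR means and both sigmas are closed-form weighted second
moments; `w` itself is a bounded 1-D maximization of the profiled expected
complete-data log-likelihood on [1e-4, 0.6], guarded so the objective never
decreases.  Initialization is either a likelihood grid search over
proportions 6%..30% in steps of 2% (ties toward the smaller value) or a
fixed low value (0.05) for the low-purity protocol.  Stopping: 25
iterations or successive change in `w` below 1e-4.  The aberration TPM is
fixed by default; an optional flag re-estimates `(L, f)` each M-step from
expected hub transition counts.

At very low purity the likelihood in `w` is nearly flat and the estimate
can settle 1-2 percentage points from the truth with compensating drift in
`q`; region detection is robust to this because the posterior odds of
"aberrant vs normal" are driven by segment-scale coherence rather than the
precise `w`.

### Reporting

Per-marker posteriors over the 12 categories; the modal category (ties
broken toward normal — a conservative calling rule); merged same-category
segments with marker counts and mean posterior (BED output is 0-based
half-open; everything else is 1-based); the probability that allele B (or
A) is over-represented, obtained by summing joint (state, configuration)
posterior mass over states where the B-carrying haplotype has the larger
parent-specific copy number; and the analogous per-cluster probability
that the over-represented haplotype derives from each haplotype cluster.
Homozygous markers report "balanced" with probability 1.

### Model variants

`K = 1` removes all haplotype information: the configuration weight is 0.5
everywhere and the BAF emission becomes an equal-weight two-normal mixture
(verified against an independently coded mixture HMM).  The reduced
variant restricts the states to {normal, deletion, cn-LOH} and ignores the
LRR channel, approximating BAF-only haplotype methods.

## Synthetic data

The simulator draws from the model's own distributions, emulating a
computational dilution experiment on a genome-wide array:

- **Panel**: a random cluster model (per-marker base frequency uniform on
  [0.05, 0.95]; cluster frequencies Beta around it with concentration 0.5,
  so clusters carry near-fixed alleles; weights Dirichlet(5); jump rate
  3e-6 per bp, i.e. LD blocks of a few hundred kb) and i.i.d. haplotypes
  sampled from it.
- **Genome**: 6 chromosomes x 13,400 markers at one marker per 9 kb
  (~80k markers, 370K-array density, "3 Mb = 333 markers").
- **Aberrations**: segment lengths log-normal (log-sd 0.9) truncated to
  [250, 10720] markers with mean 2918, drawn until 10% of markers are
  covered; types assigned greedily so realized marker shares track 68%
  hemizygous deletion / 32% cn-LOH, with random haplotype orientation;
  placed uniformly without overlap.
- **Observations**: BAF normal around the configuration-specific mean at
  heterozygous markers (sd 0.03, clipped to [0, 1]), tight 0/1 bands at
  homozygous markers (sd 0.01, uninformative for the aberration state);
  LRR normal (sd 0.18) around the admixed copy-number mean.  The BAF/LRR
  dispersions are calibration choices mimicking a well-normalized Illumina
  370K array; the array does not print them, so they are exposed as
  configuration.

What the simulator does *not* emulate: genotyping error (the "spikes" real
data show at miscalled homozygotes), genomic waves and GC artifacts in the
LRR, heavy-tailed BAF noise, probe-specific biases, and subclonal mixtures.
Passing the round-trip benchmarks therefore demonstrates correctness and
statistical efficiency of the inference under the model's own assumptions —
a best-case bound, not a field guarantee for raw array data.

## Benchmarks computed by the acceptance script

All quantities are recomputed from scratch at run time; sizes were chosen
so the whole script completes comfortably on one CPU.

- Marker-level sensitivity at specificity >= 0.99, at 5% and 3% purity,
  averaged over 3 seeded replicate genomes (~80k markers each, K = 5
  clusters fitted to a 120-haplotype panel with 2-start averaging, fixed
  TPM (600, 0.1), purity initialized at 5%); scoring is binary aberrant vs
  normal on modal categories.  The haplotype-free `K = 1` variant is scored
  on the same 5% samples.
- EM iterations until the purity estimate stabilizes (change < 1e-4) on a
  50k-marker sample at 20% purity with grid initialization.
- The detection ladder at 5% and 3% purity: single cn-LOH regions of
  0.5-12 Mb on an 11,000-marker chromosome, 5 replicates each, decoding at
  the design emission parameters with the purity fixed at its true value;
  a region counts as detected when more than half of its markers receive
  an aberrant modal category, and a length when the majority of replicates
  detect it.  Fixing the parameters isolates the detection question from
  purity estimation, which a single small region cannot inform; the
  detection rule itself (>50% of markers, majority of replicates) is this
  package's reconstruction, as no canonical rule exists.

## Numerical and degenerate-input policy

- Cluster frequencies are clamped to [1e-4, 1 - 1e-4] so genotyping errors
  cannot produce zero-probability heterozygotes; degenerate configuration
  denominators return 0.5.
- Sigma floors: 1e-4 (BAF), 1e-3 (LRR); `w` is bounded away from 1 (total
  admixed copy number zero is rejected).
- Missing BAF/LRR at a marker sets that channel's emission factor to 1;
  chromosome blocks with fewer than 2 markers are skipped with a warning
  and report the stationary prior.
- Marker subsetting (panel/sample intersection) accumulates jump
  probabilities across removed intervals (stay-probabilities multiply) and
  re-imposes exact restarts at chromosome boundaries.
- All randomness flows through explicit seeds; identical seed and
  configuration give byte-identical outputs.

## Known limitations

- A single global `w`: multiple subclones with different fractions are
  outside the model, though a dominant clone degrades gracefully.
- Diploid background assumed; aneuploid genomes shift the LRR baseline in
  ways the linear `o`/`q` calibration only partly absorbs.
- Genotype calls are taken as correct; no genotype-error model.
- The normal-hub TPM forbids adjacent distinct events (they merge or are
  separated by a normal gap).
- At 3% purity and below, `w` is weakly identified; interpret the fitted
  proportion with its EM trace, not as a point estimate.
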