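# Methods

`haplogen` trains generative models on phased binary haplotype matrices
(rows = haplotypes, columns = biallelic SNPs, entries 0/1) and audits the
artificial genomes (AGs) they produce. This note records the models, the
evaluation statistics, the synthetic data the package tests itself on, and
the numerical choices made where the design was genuinely open.

## Data model

The universal container is a haplotype-by-SNP 0/1 matrix with optional
strictly increasing bp positions, SNP ids and per-row population labels.
Phased data use one column per site; the genotype layout packs the two
alleles of an individual into adjacent columns (site-major order: site *t*
occupies columns 2*t*, 2*t*+1, chromosome A before B — any fixed invertible
order works; this one is documented and round-trip tested). On disk the
package reads/writes a plain-text `hapt` dialect (group label, sample id,
then one 0/1 token per SNP; optional `#` header of SNP ids) and phased VCF
(`|`-separated GT; REF→0, ALT→1; each sample contributes its left then
right haplotype; positions stay 1-based as stored).

## Generative models

**Bernoulli.** Each allele is drawn independently from the per-site
training frequency. Matches single-site statistics by construction and
nothing else; it is the floor every structured model must beat.

**Markov chain.** Alleles are generated left to right. Position 0 draws
from the marginal frequency; position *p* draws from the empirical
conditional P(h_p | previous min(p, w) alleles) with the context window
growing incrementally to *w* (typically 5 or 10). Conditional tables are
raw count ratios with no smoothing. A context never observed in training is
resolved by truncating it one allele at a time from the oldest side until a
seen context remains, with the marginal frequency as the final fallback —
this guarantees totality without introducing smoothing hyperparameters.

**GAN.** Fully connected generator 600 → round(L/1.2) → round(L/1.1) → L
and discriminator L → round(L/2) → round(L/3) → 1, LeakyReLU(0.01) on all
hidden outputs, tanh generator output, sigmoid discriminator output, L2
weight decay 1e-4. Adam with binary cross-entropy; discriminator learning
rate 8e-4 and combined (generator-through-frozen-discriminator) rate 1e-4,
both dropped tenfold for panels of 5000+ SNPs; batch size 32; latent
vectors are standard normal. During discriminator updates the real labels
are smoothed into [0.9, 1.0] by a uniform draw — adding U(0, 0.1) to the
hard label 1 would exceed 1 and break cross-entropy semantics, so the
smoothing is read as 0.9 + U(0, 0.1), preserving the stated width. Per
minibatch the discriminator takes two optimizer steps — one on the
smoothed-label real batch, one on the fake batch — followed by one
generator step through the frozen discriminator. Generated outputs are
rounded to {0, 1}. Layer-width rounding is half-away-from-zero
(805/2 = 402.5 → 403); banker's rounding would differ by one unit at
exact halves.

*Probing and checkpoint selection*: the data are split 3:1 (the split
permutation depends only on the seed, so an external split with the same
seed selects identical rows); every `probe_interval` epochs (200 by
default) the trainer records (a) the adversarial accuracy AA_TS between a
fresh artificial sample and the held-out quarter and (b) a PCA-coherence
score — the entropic 2-D Wasserstein distance between a fresh
training-split-sized sample and the training split on their joint PCA.
Adversarial quality at small sample sizes cycles rather than converging,
and the AA probe at held-out sizes is too noisy to rank checkpoints, so by
default the returned model is the recorded checkpoint with the best
PCA-coherence score (`restore_best_probe=False` returns the final epoch;
`stop_at_aats` halts once two consecutive AA probes sit within 0.05 of
0.5).

*Data/tanh domain*: training data are kept as 0/1 and the tanh output is
thresholded at 0.5 (default); a `data_mode="signed"` option rescales data
to ±1 and thresholds at 0. Both are coherent pairings of an asymmetric
output activation with binary data; the default is exposed and logged.

The networks, backpropagation and Adam are implemented directly on numpy
arrays (Glorot-uniform init, seeded); a finite-difference test pins the
gradients.

**RBM.** Energy model P(v, h) ∝ exp(−E) with
E = −Σ W_ij v_i h_j − Σ a_i v_i − Σ b_j h_j over binary visibles (one per
SNP) and sigmoid (binary) or ReLU (non-negative continuous) hidden units;
conditioned on the visibles, ReLU units follow a unit-variance Gaussian
truncated to [0, ∞) (variance fixed at 1; sampled by inverse-CDF).
Training is persistent contrastive divergence: positive statistics from the
data batch (Rao-Blackwellized hidden means), negative statistics from 100
persistent chains advanced k = 10 Gibbs sweeps per update; learning rate
in [1e-4, 1e-3] (values outside warn but are allowed — tiny toy models
need aggressive rates to break weight symmetry within a test budget);
batch size 32; weights init N(0, 0.01), biases 0. The sign convention
(minus signs in E) makes larger W_ij v_i h_j mean higher probability; it is
internal and unobservable in any statistic.

Sampling runs `n_gibbs` alternating sweeps (default 100, logged) from one
of three starts: fair-coin visibles (`random`), training rows
(`train_set`), or rows of an independent `sampling_set` — the latter
mitigates the overfitting that training-set starts exacerbate on
memorizing models. For models small enough to enumerate (N_v + N_h ≤ 20,
sigmoid), the package computes the exact partition function, visible
marginal and log-likelihood gradient; PCD and Gibbs sampling are tested
against these oracles. Latent analyses: `hidden_encoding` returns the
noise-free conditional mean activation per haplotype, and `svd_axes`
decomposes W into visible axes (PCA-like) and hidden axes; projecting onto
dominant hidden axes gives the non-linear dimension reduction.

## Evaluation suite

All distances between haplotypes are raw Hamming counts (number of
differing sites) unless stated.

- **Allele-frequency comparison**: Pearson r between per-site frequency
  vectors (undefined, with a warning, if either vector is constant).
- **LD**: r² = squared Pearson correlation between site columns. The decay
  curve removes sites fixed in *either* dataset, stratifies all remaining
  pairs into 50 equal-width distance bins (SNP-index distance, bp when
  positions exist) and averages r² per bin. `ld_correlation` is the Pearson
  r between the two r² vectors over all retained pairs.
- **3-point correlations**: the connected third moment
  c_ijk(a,b,c) = f_ijk − f_ij f_k − f_ik f_j − f_jk f_i + 2 f_i f_j f_k,
  evaluated at (1,1,1) by default (all 8 combinations available) for 8000
  randomly picked triplets at separations 1, 4, 16, 64, 256, 512, 1024 or
  at random; it vanishes identically when any site is fixed.
- **Pairwise-distance distributions**: within-real, within-artificial and
  between distances; 1-D Wasserstein distance between the two within-set
  distributions (raw Hamming counts, not normalized); the number of
  exactly-zero between-distances is a direct copy detector.
- **Nearest-neighbour adversarial accuracy**: with d_TS(i) the distance of
  real haplotype i to its nearest artificial neighbour, d_TT(i) to its
  nearest *other* real haplotype (leave-one-out; d_ST, d_SS analogous):
  AA_truth = mean 1(d_TS > d_TT), AA_syn = mean 1(d_ST > d_SS),
  AA_TS = (AA_truth + AA_syn)/2. 0.5 is optimal; < 0.5 flags artificial
  points sitting too close to real ones (overfitting / privacy risk),
  > 0.5 underfitting. The components are reported separately: AA_TS = 0.5
  with AA_truth = 0, AA_syn = 1 still signals collapse onto clusters of
  real genomes. **Privacy loss** = AA_TS against a held-out test set minus
  AA_TS against the training set; positive means training information
  leaked; range ≈ [−0.5, 0.5] (values outside are flagged).
- **Spike-in sensitivity**: replace k artificial rows with k training rows
  (k = 0, 1, 10, 50, …) and track AA_TS / privacy loss — a release audit
  for real genomes smuggled into an artificial set.
- **Joint PCA**: one PCA fitted on the row-concatenation of all datasets;
  coordinates are returned per dataset. By default each component's
  coordinate vector is normalized to unit Euclidean norm over the combined
  rows (the plotting convention of population-genetics PCA tools), which
  puts coordinates at the O(1/√n) scale; `scale="raw"` keeps untouched
  scores.
- **2-D Wasserstein**: entropic-regularized optimal transport between two
  point clouds (PCs 1–2), squared-Euclidean cost, uniform weights,
  regularization 0.001. Implemented as log-domain Sinkhorn with epsilon
  annealing (warm-started stages halving from the cost scale down to the
  target). The stopping tolerance on the L1 marginal error is
  max(1e-6, (n+m)·5e-8) — float64 roundoff floors the achievable error —
  and a run that stalls two orders above tolerance raises with iteration
  diagnostics. The reported value is the transport cost ⟨P, C⟩.
- **Fixed-site report**: counts of sites fixed (at 0 / at 1) in one dataset
  but polymorphic in the other.

### Discreteness bias of AA_TS on narrow panels

Because Hamming distances are integers and the AA indicators use the
strict inequality (a tie contributes 0), the null expectation of AA_TS for
two same-distribution samples is not 0.5 but 0.5 − (tie rate)/2, where the
tie rate is the probability that the two nearest-neighbour distances being
compared coincide. At 100 SNPs with 200 haplotypes per set the tie rate is
≈ 0.18 and the null mean sits near 0.40–0.44; at 805 SNPs it is ≈ 0.06 and
the null mean ≈ 0.46–0.50. The property suite verifies this law exactly
(null deficit = half the tie rate) and verifies ±0.05 calibration on wide
panels. Consequences: AA_TS scores on narrow panels read slightly
"overfit" even for perfect generators, while *differences* of AA_TS scores
— the privacy loss — are immune, because the bias cancels. Reports on
panels much narrower than ~800 SNPs should lean on privacy loss and on the
separate AA components rather than the absolute AA_TS level.

## Synthetic data

Two generators provide ground-truth test beds (no external cohorts are
required or downloaded):

- **Structured frequencies** (Balding–Nichols): per site an ancestral
  frequency p ~ Uniform(0.05, 0.95) (optionally a Beta(0.2, 2) rare-allele
  spike on a configurable fraction of sites); each population draws its
  frequency from a Beta with mean p and variance p(1−p)·F, where F is the
  differentiation parameter (an F_ST analogue, checked against the Hudson
  estimator); alleles are then independent draws. Defaults: 2 populations,
  250 haplotypes each, 100 SNPs, F = 0.2 — a panel at which joint PCA
  separates the populations clearly (label silhouette > 0.2), giving the
  embedding metrics real signal.
- **Mosaic copying**: each output haplotype copies a founder left to right,
  switching to a freshly drawn founder with per-SNP probability 0.05 and
  flipping each emitted allele with probability 0.01. This produces the
  decaying LD that the r²-decay and 3-point statistics measure (r² at
  adjacent sites ≫ r² at distance 50). `structured_mosaic_dataset` draws
  20 founders per population from the frequency model and expands each
  population by copying — structure and LD together.

What the generator does *not* emulate: recombination-map heterogeneity,
selection, realistic site-frequency spectra, and the sample sizes of real
biobanks. Tests passing on these data show the machinery is correct and
that the models can recover planted structure at desk scale; they do not
certify performance on real cohorts.

## Benchmark and problem sizes

The end-to-end benchmark simulates 500 haplotypes × 100 SNPs (2
populations, F = 0.2), splits 3:1 into train/test (seeded,
haplotype-wise), trains all four generators on the training split,
generates one artificial set per model of the training-set size, and runs
the full audit for each. Model budgets, chosen as the smallest that
reliably converge at this scale: GAN 5000 epochs with probes every 100
epochs (the GAN receives the full dataset and, sharing the benchmark seed,
trains on exactly the benchmark's training rows while probing on the
held-out quarter — at this scale the training-set size is decisive);
RBM 50 hidden ReLU units, learning rate 1e-3, 400 epochs, sampled with
100 Gibbs sweeps from training-set starts; Markov window 10. At these
budgets the expected ordering reproduces: GAN and RBM recover the
two-population PCA geometry (2-D Wasserstein ~10⁻³, allele-frequency
correlation ≥ 0.95) while the Bernoulli cloud collapses to the PCA centre;
on a 100-SNP panel the window-10 Markov model is also strong — its known
failure mode (no long-range structure) only bites on panels much wider
than its window.

## Known limitations

- The GAN is a deliberately minimal dense prototype; it underperforms the
  RBM on LD recovery at desk scale and is sensitive to seed and epoch
  budget (adversarial training is not variance-reduced here) — on some
  seeds its PCA-Wasserstein distance lands at, rather than below, the
  Bernoulli baseline's.
- RBM training at the standard learning rates needs thousands of updates
  before weight symmetry breaks on tiny toys; the tests use larger init
  scale and learning rate for those cases (the config warns).
- `exact_*` oracles require sigmoid hidden units and N_v + N_h ≤ 20.
- The Markov sampler loops in Python over rows; it is fine at benchmark
  scale but not optimized for biobank-size generation.
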