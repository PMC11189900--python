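# Methods

This note documents the models implemented in `utrforge`, the synthetic
study conditions used to validate them, and the numerical choices that a
maintainer would otherwise have to reverse-engineer from the code.

## Mean ribosome load

Polysome profiling separates mRNAs by the number of bound ribosomes.
For a variant *v* with UMI count *c<sub>vf</sub>* in polysome fraction
*f* (ribosome load *r<sub>f</sub>*, fraction library total
*N<sub>f</sub>*), the mean ribosome load is

    MRL_v = Σ_f (c_vf / N_f) · r_f  /  Σ_f (c_vf / N_f)

over fractions with *r<sub>f</sub>* ≥ 1.  The ribosome-free fraction is
carried through the pipeline but excluded from both sums; it feeds the
free-to-total ratio instead.  The estimator is exactly invariant to
rescaling any single fraction's counts (sequencing depth), which the
test suite asserts at 1e-12 precision against an independently coded
evaluation of the formula.

Upstream of the MRL sit the read filters (mean q-score strictly above
25; template-switch suffix within edit distance 5 of the expected oligo,
random-end libraries only) and UMI collapse.  UMI collapse is a
deterministic greedy directional clustering: exact duplicates merge
first, then, visiting UMIs by descending count with lexicographic
tie-break, any UMI within Hamming distance 1 of an already-placed,
more-abundant UMI joins that UMI's cluster.  This is reproducible and
dependency-free; for 10 nt UMIs at the depths simulated here it recovers
planted molecule counts to well under 1%.

Replicate aggregation keeps variants with at least `min_reads` (default
100) total reads in *every* replicate and averages MRL across replicates
weighted by per-replicate total UMI reads.

## Planted ground-truth model (synthetic study conditions)

All validation runs on data from a planted sequence → MRL model:

    MRL(s) = μ0 − Σ_uAUG penalty(p, frame) + Σ_tracts boost(p),  clipped ≥ 0.1

* μ0 = 5.0 (baseline, motif-free sequence).
* Upstream-AUG penalty saturating with distance from the cap:
  `penalty_max · p/(p + 6)` with `penalty_max` = 3.0 out-of-frame and
  1.2 in-frame (frame relative to the main ORF start).  5'-proximal
  uAUGs are therefore attenuated, and out-of-frame uAUGs hurt more —
  the qualitative structure positional-effect analyses must recover.
* 5 nt oligopyrimidine (C/T) tract bonus `0.5 · exp(−p/10)` per
  (overlapping) tract.  The per-tract bonus is small; cumulatively it
  extends the planted dynamic range to roughly 1–8, matching the
  polysome detection range (loads 1..8), so that design targets across
  the full scale are reachable by a predictor trained on this data.
* Observation noise: Gaussian, σ = 0.3 by default.
* Free-fraction link: φ(MRL) = 0.02 + 0.58·σ((3 − MRL)/1), a monotone
  decreasing logistic — low-MRL variants accumulate in the ribosome-free
  fraction, giving the negative free-to-total vs MRL rank correlation
  the functional analyses test for.

These parameters are study conditions chosen once; they emulate the
*statistical structure* of a fixed/random-end MPRA (multinomial fraction
counts driven by a sequence-dependent MRL, read-depth variation, UMI
duplication, biphasic decay with spike-ins), not any measured effect
size.  Passing tests therefore demonstrate that the algorithms recover
what was planted at realistic depths — not that real 5'UTR biology has
these magnitudes.  Features of real data deliberately not emulated:
sequencing error beyond uniform substitution, fraction cross-
contamination, position-specific base-calling quality, secondary-
structure effects.

### Occupancy calibration

Fraction counts are multinomial draws per fraction with per-variant
occupancy from a Poisson truncated to loads {1..F}.  Because the MRL
formula normalizes each fraction by its library total, it effectively
reweights fraction *f* by the inverse of the library-wide occupancy mass
in *f*.  Matching the plain conditional-on-loaded mean to the target MRL
therefore leaves a systematic recovery bias (~0.3 MRL units at typical
library compositions).  The simulator instead solves a small fixed
point: bisection matches the *depth-normalized weighted* occupancy mean
per variant, the per-fraction weights are recomputed from the implied
library totals (including each variant's loaded share 1 − φ), and the
loop repeats (~10 iterations, bisection tolerance 1e-9).  The planted
truth is then by construction what the assay formula measures at
infinite depth; recovered MRLs at 10⁷ reads agree with truth to < 0.05.
A truncated Poisson has conditional mean > 1, so targets are clipped
into (1, F) before count simulation and the clipped value is recorded as
the truth.  `calibration="occupancy"` switches back to the plain
conditional-mean matching for users who want the uncorrected process.

Read simulation gives every counted molecule a UMI kept ≥ 2 edits from
the other molecule UMIs of its (variant, fraction) group — the
"unsaturated UMI space" regime — so that with zero error rate collapse
is exactly the identity; PCR duplicates are 1 + geometric copies and
sequencing errors hit UMI/adapter bases per read at a uniform rate.

## Predictors

All neural components run on the package's reverse-mode autodiff engine
(`utrforge.autodiff`), a small NumPy tensor graph with exactly the
operator set these models need.  Gradients are float64 and are checked
against central finite differences in the test suite.  Training is
single-threaded and bit-for-bit reproducible given a seed.

**Convolutional MRL regression.**  VGG-style blocks — two ReLU
convolutions, max-pool size/stride 2, dropout — followed by a ReLU dense
layer and a linear output; filters double per block.  Search ranges:
blocks 1–5, kernel 2–7, base filters 16–128, dropouts 0–0.5, dense units
10–100; a local random-search helper samples them.  Defaults (2 blocks,
32 base filters, kernel 5, dense 40, dropouts 0.1) were chosen once
inside those ranges for the 25 nt library.  Training: MSE loss, Adam
(lr 1e-3), batch 128, early stopping on validation loss with patience 5
(the run-length defaults in the acceptance pipeline use max 10 epochs,
which this data does not need to exceed).  Splits are depth-stratified:
deepest 2000 variants test, next 2000 validation, remainder train, ties
broken by variant id.

**Positional 3-mer model.**  Linear regression on binary (offset,
3-mer) indicators with a tiny ridge stabilizer (α = 1e-6) for the
rank-deficient design.  Note the identifiability caveat: overlapping
windows give the 1472-dimensional weight vector a large null space
(only 1 + 75 + 216 + 621 = 913 dimensions act on sequences of length
25), so weights are comparable only within the identifiable span.
Recovery tests compare a noisy fit against the noise-free least-squares
representation of the planted model — the same planted function, in its
identifiable parameterization.  An intercept is included.

**k-mer oracle.**  log2(1 + count) features for k = 2..6 (5,456
features), training-set filters (≥ 250 reads, no uAUG, no initial
TG when the upstream constant region ends in A), Lasso (α = 0.001,
default subset 50,000 sequences) for support selection, then an
*unpenalized* least-squares refit on the selected features — the
"ridge with α = 0" contract taken literally.

r² throughout is the squared Pearson correlation (configurable away
where a coefficient of determination against the identity is wanted).

## Generative models and design

**VAE.**  Dense encoder/decoder (default widths 128/128, latent 16)
over flattened one-hot sequences with a categorical reconstruction
likelihood; natural-log units everywhere.  The sequence log-likelihood
is estimated by the single-sample ELBO by default (the margin in the
design losses absorbs the bound's bias); an importance-weighted
estimator (log-mean-exp over K posterior samples) is available and is
checked to dominate the ELBO on average.  Training sets follow the
coverage-then-top-MRL recipe: filter to > 2000 reads (fixed-end 50 nt)
or > 500 (25 nt), take the top 10,000 by MRL, then draw 5000 train /
1000 test sequences disjointly.

**Fast SeqProp.**  Trainable L×4 logits are standardized per position,
softmaxed, and sampled to a discrete one-hot on each forward pass with
straight-through gradients.  Loss = −predicted MRL (or squared deviation
from a target) + w_aug · soft AUG count + w_ug · initial-TG indicator +
w_vae · max(0, margin − ELBO).  Conventional settings: fixed-end 50 nt
designs use margin −30 with weight 0.2 and the UG term (the constant
region ends in A); 25 nt designs use margin −15.6, weight 0.4, no UG
term; 20,000 iterations without VAE regularization and 5,000 with it.
Optimizer Adam at lr 0.05.  The reported design is the lowest-total-loss
discrete sequence over the whole trace (the sampled forward pass makes
the last iterate noisy); the best-so-far trace is monotone by
construction and the tests assert it.

**Deep exploration networks.**  A dense generator maps latent seeds
(and, in inverse-regression mode, a target MRL input) to per-position
softmax distributions; training samples sequences straight-through
against the frozen predictor.  The diversity term is a hinge on the
cosine similarity of co-sampled pairs (margin 0.3) — only pairs more
similar than the margin are pushed apart — with weight 10 by default;
at weight 0 the generator collapses to near-identical outputs, the
documented control.  Generation decodes by sampling the per-position
distributions (matching the training path); argmax decoding is
available.

*Inverse-regression mode.*  Targets are sampled uniformly over
(1.5, 8.5) — slightly beyond the planted range — during training, and
the diversity hinge is kept on (weight 5): without it the generator can
stall on a plateau where high conditioning values all map to the same
medium-MRL output, since nothing forces exploration of the narrow
high-MRL sequence manifold.  Straight-through training still leaves a
small systematic bias between the conditioning value and the mean
predicted MRL of generated batches, so `calibrate_targets()` measures
the generator's monotone conditioning → mean-prediction response on a
grid (batches of 64 per grid point) and inverts it at generation time;
the requested target is then hit on the predictor scale with residual
error ~0.1 MRL units across seeds.  Because the training objective is
non-convex and occasional inits still stall on a flat response,
`fit(n_restarts=k)` trains k seeded restarts and keeps the one whose
calibrated response spans the widest predicted-MRL range; the
validation runs use three restarts.

## Kinetics and editing

Spike-in calibration fits a least-squares line in (log10 count, log10
concentration) per timepoint — five decades of concentration only make
sense on logs — anchored so the most abundant control maps to relative
abundance 1.  Abundances are then divided by the variant's relative
count in the untransfected input library (loading normalization).  The
protein-output proxy is the trapezoidal integral of abundance from the
first (0.5 h) to the last (24 h) timepoint, with no extrapolation to
t = 0.  Single-exponential fits use nonlinear least squares initialized
from a log-linear fit; a relative RMSE above 5% of the mean abundance
(or non-convergence) flags the series as poorly described by one
exponential — the diagnostic used to call biphasic decay.  Editing
efficiency is the percentage of reads (MAPQ > 20, mean q > 30) whose
CIGAR-derived indel intervals intersect the ±5 nt window around the
nuclease breakpoint; insertions count as zero-width events at their
reference position.  Kozak normalization divides each efficiency by the
strong-Kozak control at the matched (dosage, replicate) and summarizes
per UTR by mean ± SD across the retained points; flagged points are
removed only via an explicit exclusion list, never auto-detected.

## Problem sizes and numerical conventions

The validation suite trains the convolutional model on 30,000 sequences,
the linear recoveries on 50,000, design batches of 64, MRL round trips
at 10⁷ reads over 100 variants, and free/total rank tests at 200
variants.  Coordinates are 0-based from the transcript 5' end (the
first G of the IVT "GGG"), intervals half-open; the internal alphabet is
DNA with U mapped to T on input; one-hot channel order is (A, C, G, T)
everywhere; likelihoods are natural-log.  The fixed-end constant 25 nt
prefix is configuration (a placeholder ending in A is the default), not
a constant.

## Known limitations

* The planted model is additive; epistasis, secondary structure and
  cell-type specificity are out of its scope, so predictor performance
  here is an algorithmic check, not a biological benchmark.
* The UMI clusterer merges only at Hamming distance 1 (directionally);
  heavily saturated UMI spaces or indel-containing UMIs would need a
  different tool.
* The single-exponential misfit flag is a diagnostic threshold, not a
  model-selection test; no mechanistic two-phase model is fitted.
* Positional 3-mer weights are reported in the minimum-norm
  parameterization; individual raw weights are not biologically
  interpretable outside the identifiable span.
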