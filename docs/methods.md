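# Methods

## The model

`neuroclr` learns a nonlinear embedding of a multidimensional time series
(typically binned neural activity) by contrastive estimation with
user-designed positive and negative distributions.  A reference sample
**x** and a candidate **y** are mapped by encoders f, f′ into a common
space Z; a bounded similarity φ scores the pair.  With one positive and n
negatives per reference, training minimizes the InfoNCE form

    L_n = E[ −ψ(x, y₊) + log Σᵢ exp ψ(x, yᵢ) ],    ψ(x, y) = φ(f(x), f′(y)),

where the positive conditional p(y|x) and the negative conditional q(y|x)
are chosen to encode the scientific question: positives may share a
categorical label, lie at small time offsets, or have nearby continuous
context (behaviour); making both positives and negatives uniform over a
category renders the embedding invariant to it.  Minimizing L_n estimates
the density ratio p/q, so the geometry of Z reflects exactly the structure
the sampling scheme injects — the central design idea of the framework.

Two similarity families are supported: the temperature-scaled dot product
of unit vectors (`cosine`, embeddings on the hypersphere S^{E−1}) and the
temperature-scaled negative squared distance (`negative_mse`, embeddings in
ℝ^E).  The encoder output is L2-normalized exactly when the similarity is
cosine; the pairing is validated at configuration time.

## Numerical form of the loss

Similarities are computed as an n-vector (reference·positive) and an n×n
matrix (reference·negatives, negatives shared across references).  The
log-sum-exp uses a detached per-row maximum shift, which cancels
analytically: the stabilized value equals the naive double-loop formula in
exact arithmetic (tested to 1e−6 on random batches).  With a learnable
temperature the parameter is α = −log τ and every similarity is scaled by
min(exp α, 1/τ_min), so the effective inverse temperature lies in
(0, 1/τ_min]; α joins the encoder parameters in the same optimizer group.
Defaults: fixed τ = 1; learnable mode starts at τ = 1 with floor
τ_min = 0.1.

Two reference values calibrate the loss scale.  A constant ψ — a collapsed
encoder, or labels unrelated to the signal — gives exactly L_n = log n, and
the infimum of the objective is log n − D_KL(p‖q).  The *goodness of fit*
L_n − log n is therefore batch-size independent, ≈ 0 for uninformative
embeddings and bounded below by −D_KL(p‖q).  The test suite checks the
bound on a designed two-label problem where D_KL enumerates to log 2.

## Encoders

Three architectures, chosen by receptive field (the number of consecutive
samples consumed per embedding vector):

* **RF 1** — four dense layers D→H, H→H, H→H/2, H/2→E.
* **RF 10** — five valid time-convolutions with kernels [2, 3, 3, 3, 3];
  the three middle layers are additive skip blocks (cropped identity +
  GELU∘conv); the last maps H→E.
* **RF 40** — a front end concatenating a fixed 2× average-pool downsample
  with a learned stride-2 kernel-4 convolution, directly followed (no
  activation between) by a stride-2 kernel-3 convolution — net 4×
  subsampling, a 40-sample window reduced to a 9-sample intermediate —
  then three kernel-3 skip blocks and a final kernel-3 layer to E.

GELU (exact, erf form) follows every layer except the last.  Windows are
time-centred by default (RF 10 covers t−5..t+4); a causal option exists.
No padding anywhere: a session of length T yields T − RF + 1 embeddings.
Weight initialization is fan-in-scaled uniform, seedable; hidden widths are
constant (H) through the skip stack, including inside the RF-40 front end.

Training runs on a small reverse-mode automatic-differentiation core over
numpy (`neuroclr._tensor`), written for exactly the operations these
encoders and the loss need; gradients are validated against finite
differences.  All computation is float64, which makes runs bit-reproducible
given the seed.

## Sampling details

Valid window centres are precomputed per (session, receptive field).
Continuous conditionals locate positives by nearest context in the
Euclidean norm; ties break to the smallest time index.  The
empirical-difference conditional draws **d** uniformly from the multiset
D = {c_{t+τ} − c_t : τ ∈ Δ} and finds the sample nearest to c_ref + **d**;
the `delta` conditional instead perturbs with N(0, δ²I).  One-dimensional
contexts use an exact sorted-array bisection (cached per session); higher
dimensions use a full distance computation.  The reference itself is not
excluded from positive candidacy (self-positives are measure-zero for
continuous contexts), and negatives may collide with references —
both choices configurable in principle but fixed here for parity with the
batch definition.  In time mode, references are drawn only from indices
that admit at least one in-range offset.

Multi-session batches draw an equal quota ⌈n/N⌉ of references per session
regardless of session length, choose each positive's session uniformly and
match it there by continuous context, and pool negatives uniformly across
sessions; one encoder per session maps into the shared space, which makes
the embedding invariant to session identity.

## Synthetic benchmark

The generator emulates an artificial spiking population driven by a 1-D
circular behaviour variable c ~ U[0, 2π).  The true 2-D latent is
z | c ~ N(μ(c), Σ(c)) with μ(c) = (c, 2 sin c)ᵀ and
Σ(c) = diag(0.6 − 0.3|sin c|, 0.3|sin c|).  The latent is padded to the
neuron dimension with independent N(0, 0.01²) coordinates (coupling flows
preserve dimension), pushed through four randomly initialized RealNVP
blocks (two-layer width-64 coupling networks, tanh-capped log-scales),
mapped to non-negative rates by softplus, and rescaled to a mean of
5 counts/bin for the count-noise models (the original construction states
no link or scale; this calibration is ours).  Observation noise: Poisson
counts (default); additive truncated-[0, 1000] Gaussian (σ = 1); additive
U[0, 2]; or refractory-Poisson — rates rescaled to a 110 Hz average,
interspike intervals drawn as a 10 ms dead time plus an exponential wait,
counted in 10 ms bins.  Defaults produce 15,000 samples × 100 neurons,
split 80/20 into train and validation.  A `ring` latent variant
(μ(c) = (cos c, sin c)ᵀ, isotropic noise, context stored as (cos c, sin c)
so distances respect the wrap) exists for topology analyses that need a
closed circular latent; the spiral law above remains the default.

What the generator does *not* emulate: temporal autocorrelation of real
neural dynamics (samples are i.i.d. given c), cell-type heterogeneity,
non-stationarity, and measurement artefacts.  Passing the recovery tests
therefore demonstrates correctness of the estimation machinery, not
performance on real recordings.

`reconstruction_score` fits a linear map (with intercept) from an embedding
to the true 2-D latent and reports the uniform-average R² over latent
dimensions — invariant to affine transformations of the embedding, as the
identifiability theory predicts for a successful fit.

## Evaluation suite

*Consistency.*  R² of linear regression (with intercept) from one embedding
onto another, uniform-averaged over target dimensions; computed in-sample
by default (it is an alignment score, not a predictive model; an
out-of-sample mode exists for null checks).  Ten runs yield 90 ordered
comparisons.  Subjects with different neurons are first aligned by
behaviour: unit-norm embeddings are averaged within position × direction
bins (100 bins per direction by default), renormalized onto the
hypersphere, and empty bins are imputed from the pooled raw members of the
two adjacent bins.

*Decoding.*  A kNN regressor/classifier (scikit-learn) with the metric
matching the training similarity (cosine or Euclidean); k is selected on
the validation split over [1, 4, 9, 16, 25] and test metrics are computed
once; positional decoding reports the median absolute error.

*Topology.*  Vietoris–Rips persistent cohomology over Z/2 up to dimension
2 on a uniform random subsample (default 100 points at desk scale), with
the filtration ceiling at infinity.  The backend reduces the coboundary
matrix in reverse filtration order with on-the-fly cofacet generation and
clearing; the filtration is truncated at the enclosing radius, which
provably changes no diagram.  A direct boundary-matrix reduction is kept as
an independent oracle and the two are tested to produce identical diagrams.
Betti numbers count classes whose lifespan exceeds a per-dimension
threshold; essential (never-dying) classes always count.  Thresholds come
from the shuffled-label null — refit the pipeline with permuted context
labels and take the maximum lifespan per dimension over 20 shuffles (a
desk-scale surrogate for a much larger null ensemble) — with one guard: at
this scale shuffled refits often produce *no* dim-2 bars at all, so
thresholds for dimensions ≥ 2 are floored by the dimension below (noise
lifespans in Rips filtrations shrink with dimension; the floor is inactive
when the null is well-behaved).  For bare point clouds without labels, a
prominence rule is used instead: dimensions ≥ 1 are thresholded at half
the longest finite lifespan across those dimensions, and dimension 0
counts only essential components.

## Training loops

Every step draws a fresh batch from the full dataset (never from within a
pre-drawn minibatch); `batch_size="full"` uses every valid window per step.
Adam is the default optimizer (the choice of gradient method is free in the
framework; Adam is the field default), learning rate 3e−4 in general and
1e−4 for the synthetic benchmark.  No early stopping: a fixed number of
iterations with the full loss, alignment/uniformity, goodness-of-fit and
temperature traces recorded, since loss comparisons at the same point in
training are the model-selection tool.  Hybrid training splits the
embedding coordinates into a behaviour-shaped block and a time-shaped
block, evaluates one InfoNCE per block (same references and negatives,
block-specific positives) and optimizes their unweighted sum (a weight is
available).  Adaptation to a session with a different neuron count
re-initializes only the input layer and trains it while the trunk stays
frozen (full fine-tuning behind a flag).

## Problem sizes and defaults used in the checks

The package's own validation runs use: 2,000 optimizer steps at batch 512
for the benchmark recovery and identifiability fits (recovery plateaus
from ~1,000 steps); a 2,000 × 32 ring dataset with 500-step fits for the
topology pipeline and its 20-shuffle null; for the multi-session property,
a 4,000 × 40 run split into two sessions with disjoint 20-neuron subsets
*and complementary behaviour coverage* (each biased to one half of the
circular range, with an overlap band and a 10% floor elsewhere), evaluated
row-aligned over the full run — when sessions share identical behaviour
trajectories, behaviour-conditioned single-session fits are already
aligned by identifiability and joint training adds nothing measurable at
desk scale; the joint advantage appears exactly when the sessions'
behaviour statistics differ, which is also the realistic multi-animal
setting;
a 100-point Fibonacci lattice as the canonical uniform two-sphere cloud
(its equal-area covering separates signal from sampling noise at a size
the persistence backend handles in seconds, where a random-uniform sample
would need twice the points); and 10⁴ draws with α = 0.01 for the
chi-square/KS sampler checks.

## Known limitations

* The autodiff core is single-threaded numpy; at these problem sizes a
  step costs ~50 ms, but very large models or receptive field 40 at long
  sessions will be slow compared to GPU-backed implementations.
* The persistence backend targets ≤ ~150 points at maxdim 2; it is exact
  but not competitive with specialized packages on large clouds.
* The refractory-Poisson simulator treats the rate as constant within each
  10 ms bin and conditions the waiting time on the bin of the previous
  spike.
* Multi-session positive matching uses the within-session continuous
  conditional of the drawn session; other conventions (e.g. matching in a
  pooled context space) are possible and would change the geometry only
  through the sampled pairs.
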