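# neuroclr

Contrastive joint embeddings of neural and behavioural time series.

Systems neuroscientists routinely record the activity of dozens to
thousands of neurons alongside behaviour (position, movement, stimuli) and
need low-dimensional latent spaces that are *consistent* — across runs,
animals, sessions and recording modalities — and *decodable*.  `neuroclr`
implements a contrastive-learning framework for this problem: the user
designs the distributions of positive and negative sample pairs from
auxiliary variables (time offsets, discrete condition labels, continuous
behaviour), and convolutional encoders are trained with an InfoNCE
objective so that the geometry of the embedding reflects exactly the
structure those distributions inject.

With a reference sample **x**, one positive **y₊** ~ p(y|x) and n negatives
**yᵢ** ~ q(y|x), the empirical loss per batch is

    L_n = mean_x [ −ψ(x, y₊) + log Σᵢ exp ψ(x, yᵢ) ],
    ψ(x, y) = φ(f(x), f′(y)),

with φ either the temperature-scaled cosine similarity (unit-norm
embeddings on the hypersphere) or the temperature-scaled negative squared
distance (Euclidean embeddings), optionally with a learnable temperature
α = −log τ floored at τ_min.  The transform L_n − log n ("goodness of
fit") is batch-size independent, ≈ 0 for uninformative embeddings and
bounded below by −D_KL(p‖q).

The package covers, in pure scientific Python (numpy/scipy/scikit-learn
plus a small in-package autodiff core and a numba-backed persistence
reduction):

* **data** — validated session containers (signal [T×D], continuous and
  discrete context), sliding-window extraction for receptive fields
  1/10/40, NPZ/HDF5/CSV I/O;
* **sampling** — reference/positive/negative samplers: time-offset,
  discrete, continuous (empirical context differences), `delta` (Gaussian
  context perturbation), mixed, uniform-over-category invariance sampling,
  and multi-session batches;
* **encoders** — MLP (RF 1) and time-convolutional networks with skip
  connections (RF 10/40), GELU activations, optional output normalization;
* **objective** — stabilized InfoNCE, learnable temperature, goodness of
  fit;
* **solver** — single-session, hybrid (behaviour+time on split coordinate
  blocks) and multi-session training, label-free `transform`, and one-step
  `adapt` to unseen sessions with different neuron counts;
* **synthetic** — an artificial spiking benchmark: 1-D circular behaviour
  drives a 2-D latent, lifted to 100 neurons through random coupling-flow
  (RealNVP) blocks with Poisson/Gaussian/uniform/refractory noise, plus a
  linear-regression reconstruction score against the known latent;
* **evaluation** — linear consistency across runs and (behaviour-binned)
  across subjects, kNN decoding;
* **topology** — Vietoris–Rips persistent cohomology (dims 0–2), Betti
  numbers under shuffled-label null thresholds.

## Worked example

```python
import numpy as np
import neuroclr as nc
from neuroclr.synthetic import (SyntheticDatasetSpec, generate_dataset,
                                train_session, reconstruction_score)

# 15,000 samples x 100 neurons, Poisson spiking driven by a 2-D latent
session, truth = generate_dataset(SyntheticDatasetSpec(seed=42))
train = train_session(session, truth)          # 80% training split

model = nc.fit(
    train,
    nc.EncoderSpec(receptive_field=1, num_input=100, num_hidden=32,
                   output_dim=2, normalize=False),
    nc.SamplingConfig(mode="delta", delta=0.1),
    nc.SimilarityConfig(kind="negative_mse"),
    nc.FitConfig(max_iterations=2000, batch_size=512, learning_rate=1e-4,
                 seed=0),
)
embedding, _ = nc.transform(model, session)    # label-free
print(f"final loss      {model.loss_history[-1]:.3f}")
print(f"goodness of fit {model.gof_history[-1]:.3f}")
print(f"reconstruction R2 {reconstruction_score(embedding, truth.latent):.3f}")
```

Output:

```
final loss      5.215
goodness of fit -1.023
reconstruction R2 0.941
```

The goodness of fit is clearly below the 0.0 of an uninformative
embedding, and a linear map from the 2-D embedding recovers 94% of the
variance of the true latent — the behaviour-conditioned embedding has found
the generative coordinates up to an affine transformation.  Refitting with
permuted behaviour labels drives the goodness of fit to ≈ 0 and the
reconstruction R² to ≈ 0.04, and independent seeds agree with each other
at mean pairwise linear consistency R² ≈ 0.98.

A command-line interface mirrors the library
(`neuroclr simulate|fit|transform|adapt|evaluate|topology`); see
`neuroclr --help`.  The science behind each module — the sampling schemes,
the loss calibration, the synthetic generator and what it does and does not
emulate, and all numerical choices — is documented in `docs/methods.md`.

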