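"""Synthetic spiking benchmark with known ground-truth latents.

A 1-D circular behaviour variable c ~ U[0, 2π) drives a 2-D latent z drawn
from N(μ(c), Σ(c)).  The default ("spiral") geometry uses
μ(c) = (c, 2 sin c)ᵀ and Σ(c) = diag(0.6 − 0.3|sin c|, 0.3|sin c|); a "ring"
geometry (μ(c) = (cos c, sin c)ᵀ, isotropic noise) is provided for topology
analyses that require a closed circular latent.  The latent is padded with
small-variance Gaussian coordinates to the full neuron dimensionality,
pushed through a stack of randomly initialized coupling-flow (RealNVP)
blocks, mapped to non-negative firing rates by a softplus link calibrated to
a target mean rate, and finally observed under one of four noise models
(Poisson counts, additive truncated Gaussian, additive uniform, or Poisson
spiking with a refractory period).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import truncnorm

from .data import SessionData, make_session

NOISE_MODELS = ("poisson", "gaussian", "uniform", "refractory_poisson")


@dataclass(frozen=True)
class SyntheticDatasetSpec:
    n_samples: int = 15000
    n_neurons: int = 100
    noise_model: str = "poisson"
    flow_depth: int = 4
    seed: int = 0
    train_fraction: float = 0.8
    latent: str = "spiral"        # or "ring"
    mean_rate: float = 5.0        # counts per bin after calibration
    pad_std: float = 0.01         # sd of the padding coordinates
    ring_noise: float = 0.1       # sd of the ring geometry's latent noise
    refractory_s: float = 0.010   # refractory period (seconds)
    refractory_rate_hz: float = 110.0
    bin_width_s: float = 0.010    # bin width for the refractory model

    def __post_init__(self):
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie in (0, 1)")
        if self.noise_model not in NOISE_MODELS:
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.latent not in ("spiral", "ring"):
            raise ValueError(f"unknown latent geometry {self.latent!r}")


@dataclass
class SyntheticGroundTruth:
    behaviour: np.ndarray          # c in [0, 2π), shape [N]
    latent: np.ndarray             # true 2-D latent z, shape [N x 2]
    rates: np.ndarray              # non-negative firing rates [N x D]
    counts: np.ndarray             # observed activity [N x D]
    train_mask: np.ndarray = field(default=None)
    val_mask: np.ndarray = field(default=None)


def latent_mean_cov(c: np.ndarray, latent: str = "spiral",
                    ring_noise: float = 0.1
                    ) -> tuple[np.ndarray, np.ndarray]:
    """μ(c) [N x 2] and the diagonal of Σ(c) [N x 2]."""
    c = np.asarray(c, dtype=np.float64)
    if latent == "spiral":
        mu = np.stack([c, 2.0 * np.sin(c)], axis=1)
        var = np.stack([0.6 - 0.3 * np.abs(np.sin(c)),
                        0.3 * np.abs(np.sin(c))], axis=1)
    else:
        mu = np.stack([np.cos(c), np.sin(c)], axis=1)
        var = np.full((c.size, 2), ring_noise ** 2)
    return mu, var


def sample_behaviour_and_latent(spec: SyntheticDatasetSpec,
                                rng: np.random.Generator
                                ) -> tuple[np.ndarray, np.ndarray]:
    """c ~ U[0, 2π); z | c ~ N(μ(c), Σ(c)) with independent coordinates."""
    c = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_samples)
    mu, var = latent_mean_cov(c, spec.latent, spec.ring_noise)
    z = mu + np.sqrt(var) * rng.standard_normal(mu.shape)
    return c, z


class CouplingFlow:
    """A stack of randomly initialized affine coupling (RealNVP) blocks.

    Each block freezes one half of the coordinates and applies an affine map
    ``y = x * exp(s) + t`` to the other half, with ``s`` and ``t`` produced
    by a two-layer network of width 64 conditioned on the frozen half.  The
    log-scale is tanh-capped for numerical stability.  The flow is a fixed
    (untrained) bijection; ``inverse`` undoes ``forward`` exactly up to
    floating-point error.
    """

    HIDDEN = 64
    SCALE_CAP = 1.0

    def __init__(self, dim: int, depth: int, rng: np.random.Generator):
        self.dim = dim
        self.depth = depth
        self.blocks = []
        half = dim // 2
        for b in range(depth):
            d_in, d_out = (half, dim - half) if b % 2 == 0 else (dim - half,
                                                                 half)
            def mat(n_out, n_in):
                return rng.standard_normal((n_out, n_in)) / np.sqrt(n_in)
            self.blocks.append({
                "swap": b % 2 == 1,
                "w1": mat(self.HIDDEN, d_in), "b1": np.zeros(self.HIDDEN),
                "ws": mat(d_out, self.HIDDEN), "bs": np.zeros(d_out),
                "wt": mat(d_out, self.HIDDEN), "bt": np.zeros(d_out)})

    def _split(self, x: np.ndarray, swap: bool):
        half = self.dim // 2
        if swap:
            return x[:, half:], x[:, :half]
        return x[:, :half], x[:, half:]

    def _join(self, frozen: np.ndarray, moved: np.ndarray, swap: bool):
        if swap:
            return np.concatenate([moved, frozen], axis=1)
        return np.concatenate([frozen, moved], axis=1)

    def _st(self, block, frozen):
        h = np.tanh(frozen @ block["w1"].T + block["b1"])
        s = self.SCALE_CAP * np.tanh(h @ block["ws"].T + block["bs"])
        t = h @ block["wt"].T + block["bt"]
        return s, t

    def forward(self, x: np.ndarray) -> np.ndarray:
        y = np.asarray(x, dtype=np.float64)
        for block in self.blocks:
            frozen, moved = self._split(y, block["swap"])
            s, t = self._st(block, frozen)
            y = self._join(frozen, moved * np.exp(s) + t, block["swap"])
        return y

    def inverse(self, y: np.ndarray) -> np.ndarray:
        x = np.asarray(y, dtype=np.float64)
        for block in reversed(self.blocks):
            frozen, moved = self._split(x, block["swap"])
            s, t = self._st(block, frozen)
            x = self._join(frozen, (moved - t) * np.exp(-s), block["swap"])
        return x


def build_flow_decoder(spec: SyntheticDatasetSpec,
                       rng: np.random.Generator) -> CouplingFlow:
    """The fixed random bijection lifting the padded latent to rate space."""
    if spec.flow_depth < 1:
        raise ValueError("flow_depth must be >= 1")
    return CouplingFlow(spec.n_neurons, spec.flow_depth, rng)


def latent_to_rates(z: np.ndarray, flow: CouplingFlow,
                    rng: np.random.Generator, pad_std: float = 0.01,
                    mean_rate: float = 5.0) -> np.ndarray:
    """Lift the 2-D latent to non-negative rates of ``flow.dim`` neurons.

    Coupling flows preserve dimension, so z is padded with independent
    N(0, pad_std²) coordinates before the flow; the flow output is mapped
    through softplus and rescaled to the requested mean rate.
    """
    z = np.asarray(z, dtype=np.float64)
    pad = pad_std * rng.standard_normal((z.shape[0], flow.dim - z.shape[1]))
    lifted = flow.forward(np.concatenate([z, pad], axis=1))
    soft = np.logaddexp(0.0, lifted)  # softplus, overflow-safe
    return soft * (mean_rate / soft.mean())


def simulate_refractory_train(rate_hz: np.ndarray, bin_width_s: float,
                              refractory_s: float,
                              rng: np.random.Generator) -> np.ndarray:
    """Spike times for one neuron with piecewise-constant rate per bin.

    Interspike intervals are a dead time plus an exponential waiting time at
    the rate of the bin containing the previous spike (hazard after the
    refractory period).
    """
    T = rate_hz.size
    t_end = T * bin_width_s
    spikes = []
    # draws consumed one at a time; refill in blocks for speed
    block = max(64, int(rate_hz.mean() * t_end * 1.5) + 64)
    exps = rng.exponential(size=block)
    k = 0
    t = 0.0
    while True:
        b = min(int(t / bin_width_s), T - 1)
        lam = rate_hz[b]
        if lam <= 0:
            t = (b + 1) * bin_width_s
            if t >= t_end:
                break
            continue
        if k >= exps.size:
            exps = np.concatenate([exps, rng.exponential(size=block)])
        t = t + exps[k] / lam
        k += 1
        if t >= t_end:
            break
        spikes.append(t)
        t += refractory_s
    return np.asarray(spikes)


def rates_to_observations(rates: np.ndarray, noise_model: str,
                          rng: np.random.Generator,
                          spec: SyntheticDatasetSpec | None = None
                          ) -> np.ndarray:
    """Apply the observation noise model to non-negative rates."""
    rates = np.asarray(rates, dtype=np.float64)
    if (rates < 0).any():
        raise ValueError("rates must be non-negative")
    if noise_model == "poisson":
        return rng.poisson(rates).astype(np.float64)
    if noise_model == "gaussian":
        noise = truncnorm.rvs(0.0, 1000.0, loc=0.0, scale=1.0,
                              size=rates.shape, random_state=rng)
        return rates + noise
    if noise_model == "uniform":
        return rates + rng.uniform(0.0, 2.0, size=rates.shape)
    if noise_model == "refractory_poisson":
        spec = spec or SyntheticDatasetSpec()
        # rescale to the target average rate in Hz, then count spikes from
        # refractory interspike-interval sampling in each bin
        rate_hz = rates * (spec.refractory_rate_hz / rates.mean())
        T, D = rates.shape
        counts = np.zeros((T, D))
        edges = np.arange(T + 1) * spec.bin_width_s
        for j in range(D):
            times = simulate_refractory_train(rate_hz[:, j], spec.bin_width_s,
                                              spec.refractory_s, rng)
            counts[:, j] = np.histogram(times, bins=edges)[0]
        return counts
    raise ValueError(f"unknown noise model {noise_model!r}")


def generate_dataset(spec: SyntheticDatasetSpec
                     ) -> tuple[SessionData, SyntheticGroundTruth]:
    """Run the full generative pipeline; deterministic given ``spec.seed``.

    The session's continuous context is the behaviour variable: the raw
    angle for the spiral geometry, or its (cos, sin) embedding for the ring
    geometry so that context distances respect the wrap-around.
    """
    rng = np.random.default_rng(spec.seed)
    c, z = sample_behaviour_and_latent(spec, rng)
    flow = build_flow_decoder(spec, rng)
    rates = latent_to_rates(z, flow, rng, spec.pad_std, spec.mean_rate)
    counts = rates_to_observations(rates, spec.noise_model, rng, spec)
    n_train = int(round(spec.train_fraction * spec.n_samples))
    train_mask = np.zeros(spec.n_samples, dtype=bool)
    train_mask[:n_train] = True
    if spec.latent == "ring":
        context = np.stack([np.cos(c), np.sin(c)], axis=1)
    else:
        context = c[:, None]
    session = make_session(counts, continuous_context=context,
                           sample_rate_hz=1.0 / spec.bin_width_s,
                           session_id=f"synthetic-{spec.noise_model}")
    gt = SyntheticGroundTruth(behaviour=c, latent=z, rates=rates,
                              counts=counts, train_mask=train_mask,
                              val_mask=~train_mask)
    return session, gt


def train_session(session: SessionData, gt: SyntheticGroundTruth
                  ) -> SessionData:
    """The training split of a generated session."""
    m = gt.train_mask
    return make_session(
        session.signal[m],
        continuous_context=None if session.continuous_context is None
        else session.continuous_context[m],
        discrete_context=None if session.discrete_context is None
        else session.discrete_context[m],
        sample_rate_hz=session.sample_rate_hz,
        session_id=session.session_id + "-train")


def disjoint_neuron_sessions(session: SessionData, n_sessions: int,
                             rng: np.random.Generator) -> list[SessionData]:
    """Split one session's neurons into disjoint subsets (multi-session toy).

    All resulting sessions observe the same underlying latent process through
    different neuron subsets and share the behavioural context.
    """
    D = session.n_features
    perm = rng.permutation(D)
    parts = np.array_split(perm, n_sessions)
    return [make_session(session.signal[:, np.sort(p)],
                         continuous_context=session.continuous_context,
                         discrete_context=session.discrete_context,
                         sample_rate_hz=session.sample_rate_hz,
                         session_id=f"{session.session_id}-part{i}")
            for i, p in enumerate(parts)]


def complementary_coverage_sessions(session: SessionData,
                                    behaviour: np.ndarray,
                                    rng: np.random.Generator,
                                    overlap: float = 0.1,
                                    floor: float = 0.1,
                                    ) -> tuple[list[SessionData],
                                               list[SessionData]]:
    """Two sessions with disjoint neurons and complementary behaviour cover.

    Emulates recordings from different animals: each session observes its
    own neuron subset of one generative run, and its time points are biased
    to one half of the circular behaviour range (with an ``overlap`` band
    around the boundary and a ``floor`` fraction of samples kept
    everywhere).  Single-session fits are then only constrained on their
    covered region, which is the regime where joint training into a shared
    space pays off.

    Returns ``(training_sessions, full_views)`` where the full views expose
    every time point of the run through each session's neuron subset, for
    row-aligned cross-session evaluation.
    """
    T, D = session.signal.shape
    perm = rng.permutation(D)
    subsets = [np.sort(perm[:D // 2]), np.sort(perm[D // 2:])]
    keep = [
        (behaviour < (1.0 + overlap) * np.pi) | (rng.random(T) < floor),
        (behaviour > (1.0 - overlap) * np.pi) | (rng.random(T) < floor),
    ]
    training, full = [], []
    for i, (cols, mask) in enumerate(zip(subsets, keep)):
        training.append(make_session(
            session.signal[mask][:, cols],
            continuous_context=session.continuous_context[mask],
            sample_rate_hz=session.sample_rate_hz,
            session_id=f"{session.session_id}-cov{i}"))
        full.append(make_session(
            session.signal[:, cols],
            continuous_context=session.continuous_context,
            sample_rate_hz=session.sample_rate_hz,
            session_id=f"{session.session_id}-cov{i}-full"))
    return training, full


def reconstruction_score(embedding: np.ndarray, true_latent: np.ndarray,
                         fit_mask: np.ndarray | None = None) -> float:
    """R² of a linear regression (with intercept) embedding -> true latent.

    Aggregated as the uniform average over the latent dimensions; invariant
    to affine transformations of the embedding.  With ``fit_mask`` the map
    is fitted on the masked rows and scored on the complement.
    """
    from sklearn.linear_model import LinearRegression
    from sklearn.metrics import r2_score
    embedding = np.asarray(embedding, dtype=np.float64)
    true_latent = np.asarray(true_latent, dtype=np.float64)
    if embedding.shape[0] != true_latent.shape[0]:
        raise ValueError("embedding and latent row counts differ")
    reg = LinearRegression()
    if fit_mask is None:
        reg.fit(embedding, true_latent)
        return float(r2_score(true_latent, reg.predict(embedding),
                              multioutput="uniform_average"))
    fit_mask = np.asarray(fit_mask, dtype=bool)
    reg.fit(embedding[fit_mask], true_latent[fit_mask])
    return float(r2_score(true_latent[~fit_mask],
                          reg.predict(embedding[~fit_mask]),
                          multioutput="uniform_average"))
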