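"""Training loops: single-session, hybrid, multi-session, and adaptation.

Every optimizer step draws a fresh contrastive batch from the *full*
dataset (positives and negatives are never restricted to a pre-drawn
minibatch), embeds the three window sets, evaluates the InfoNCE loss and
takes one gradient step.  Training is deterministic given the seed; the loss
and goodness-of-fit traces are recorded at every step, since comparing loss
values at the same point in training is the model-selection tool.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import _tensor as tg
from ._tensor import Adam, SGD, Tensor
from .data import MultiSessionDataset, SessionData, extract_window_batch
from .encoders import EncoderParams, EncoderSpec, build_encoder, encode, \
    encode_session
from .objective import (LossResult, SimilarityConfig, TemperatureState,
                        check_compatibility, goodness_of_fit, infonce)
from .sampling import (ConfigError, ContrastiveBatch, SamplingConfig,
                       merge_batches, sample_batch, sample_multisession_batch)


@dataclass
class FitConfig:
    max_iterations: int = 1000
    batch_size: int | str = 512        # or "full"
    learning_rate: float = 3e-4
    optimizer: str = "adam"            # or "sgd"
    seed: int = 0
    hybrid_split: tuple[int, int] | None = None
    hybrid_weight: float = 1.0         # weight of the time-conditioned term

    def make_optimizer(self, params):
        if self.optimizer == "adam":
            return Adam(params, lr=self.learning_rate)
        if self.optimizer == "sgd":
            return SGD(params, lr=self.learning_rate)
        raise ConfigError(f"unknown optimizer {self.optimizer!r}")


@dataclass
class TrainedModel:
    """Encoder(s) plus configs and the full training trace."""

    encoders: list[EncoderParams]
    similarity: SimilarityConfig
    temperature: TemperatureState
    sampling: SamplingConfig
    fit_config: FitConfig
    loss_history: list[float] = field(default_factory=list)
    gof_history: list[float] = field(default_factory=list)
    temperature_history: list[float] = field(default_factory=list)
    alignment_history: list[float] = field(default_factory=list)
    uniformity_history: list[float] = field(default_factory=list)

    @property
    def encoder(self) -> EncoderParams:
        return self.encoders[0]

    def record(self, result: LossResult) -> None:
        self.loss_history.append(result.total)
        self.gof_history.append(goodness_of_fit(result.total,
                                                result.batch_size))
        self.temperature_history.append(result.temperature)
        self.alignment_history.append(result.alignment_term)
        self.uniformity_history.append(result.uniformity_term)

    def history_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "step": np.arange(len(self.loss_history)),
            "total": self.loss_history,
            "alignment": self.alignment_history,
            "uniformity": self.uniformity_history,
            "goodness_of_fit": self.gof_history,
            "temperature": self.temperature_history})

    def save_loss_csv(self, path) -> None:
        self.history_frame().to_csv(path, index=False)


def _validate(spec: EncoderSpec, sampling: SamplingConfig,
              similarity: SimilarityConfig) -> SamplingConfig:
    spec.validate()
    check_compatibility(similarity, spec.normalize)
    if sampling.receptive_field != spec.receptive_field:
        sampling = replace(sampling, receptive_field=spec.receptive_field)
    return sampling


def _embed_triplet(params: EncoderParams, session: SessionData,
                   batch: ContrastiveBatch, causal: bool):
    """Embed reference/positive/negative windows with one forward pass."""
    rf = params.spec.receptive_field
    idx = np.concatenate([batch.reference, batch.positive, batch.negative])
    win = extract_window_batch(session, idx, rf, causal)
    z = encode(params, win, grad=True)
    n = batch.n
    return (tg.take_rows(z, np.arange(n)),
            tg.take_rows(z, np.arange(n, 2 * n)),
            tg.take_rows(z, np.arange(2 * n, 3 * n)))


def fit(session: SessionData, encoder_spec: EncoderSpec,
        sampling_config: SamplingConfig, similarity_config: SimilarityConfig,
        fit_config: FitConfig) -> TrainedModel:
    """Single-session contrastive training."""
    sampling_config = _validate(encoder_spec, sampling_config,
                                similarity_config)
    sampling_config.validate(session)
    rng = np.random.default_rng(fit_config.seed)
    params = build_encoder(encoder_spec, rng)
    state = TemperatureState(similarity_config)
    opt = fit_config.make_optimizer(params.parameters() + state.parameters())
    model = TrainedModel([params], similarity_config, state, sampling_config,
                         fit_config)
    for _ in range(fit_config.max_iterations):
        batch = sample_batch(session, fit_config.batch_size, sampling_config,
                             rng)
        ref, pos, neg = _embed_triplet(params, session, batch,
                                       sampling_config.causal)
        result = infonce(ref, pos, neg, similarity_config, state)
        opt.zero_grad()
        result.loss_tensor.backward()
        opt.step()
        model.record(result)
    return model


def fit_hybrid(session: SessionData, encoder_spec: EncoderSpec,
               sampling_config: SamplingConfig,
               similarity_config: SimilarityConfig,
               fit_config: FitConfig) -> TrainedModel:
    """Hybrid training: one encoder, two objectives on disjoint coordinate
    blocks — the first block is shaped by the behaviour-conditioned loss, the
    remaining block by the time-conditioned loss (their sum is optimized).
    """
    if fit_config.hybrid_split is None:
        raise ConfigError("fit_hybrid requires fit_config.hybrid_split")
    b_dims, t_dims = fit_config.hybrid_split
    if b_dims + t_dims != encoder_spec.output_dim:
        raise ConfigError(
            f"hybrid split {fit_config.hybrid_split} does not sum to the "
            f"output dimension {encoder_spec.output_dim}")
    sampling_config = _validate(encoder_spec, sampling_config,
                                similarity_config)
    sampling_config.validate(session)
    time_config = replace(sampling_config, mode="time")
    rng = np.random.default_rng(fit_config.seed)
    params = build_encoder(encoder_spec, rng)
    state = TemperatureState(similarity_config)
    opt = fit_config.make_optimizer(params.parameters() + state.parameters())
    model = TrainedModel([params], similarity_config, state, sampling_config,
                         fit_config)
    for _ in range(fit_config.max_iterations):
        batch_b = sample_batch(session, fit_config.batch_size,
                               sampling_config, rng)
        ref, pos, neg = _embed_triplet(params, session, batch_b,
                                       sampling_config.causal)
        if t_dims == 0:
            result = infonce(ref, pos, neg, similarity_config, state)
            total = result.loss_tensor
        else:
            res_b = infonce(tg.slice_cols(ref, 0, b_dims),
                            tg.slice_cols(pos, 0, b_dims),
                            tg.slice_cols(neg, 0, b_dims),
                            similarity_config, state)
            batch_t = sample_batch(session, fit_config.batch_size,
                                   time_config, rng)
            ref_t, pos_t, neg_t = _embed_triplet(params, session, batch_t,
                                                 sampling_config.causal)
            E = encoder_spec.output_dim
            res_t = infonce(tg.slice_cols(ref_t, b_dims, E),
                            tg.slice_cols(pos_t, b_dims, E),
                            tg.slice_cols(neg_t, b_dims, E),
                            similarity_config, state)
            total = res_b.loss_tensor + tg.mul_scalar(
                res_t.loss_tensor, fit_config.hybrid_weight)
            result = LossResult(
                total=float(total.data),
                alignment_term=res_b.alignment_term + res_t.alignment_term,
                uniformity_term=res_b.uniformity_term + res_t.uniformity_term,
                batch_size=batch_b.n, temperature=state.temperature)
        opt.zero_grad()
        total.backward()
        opt.step()
        model.record(result)
    return model


def fit_multisession(dataset: MultiSessionDataset, encoder_spec: EncoderSpec,
                     sampling_config: SamplingConfig,
                     similarity_config: SimilarityConfig,
                     fit_config: FitConfig) -> TrainedModel:
    """Joint training of one encoder per session into a shared space.

    Each batch draws the same number of references from every session, so
    the embedding becomes invariant to the session identity.
    """
    if len(dataset) == 1:
        return fit(dataset[0], encoder_spec, sampling_config,
                   similarity_config, fit_config)
    sampling_config = _validate(encoder_spec, sampling_config,
                                similarity_config)
    for s in dataset.sessions:
        sampling_config.validate(s)
    rng = np.random.default_rng(fit_config.seed)
    encoders = [build_encoder(replace(encoder_spec, num_input=s.n_features),
                              rng) for s in dataset.sessions]
    state = TemperatureState(similarity_config)
    all_params = [p for e in encoders for p in e.parameters()]
    opt = fit_config.make_optimizer(all_params + state.parameters())
    model = TrainedModel(encoders, similarity_config, state, sampling_config,
                         fit_config)
    rf = encoder_spec.receptive_field
    for _ in range(fit_config.max_iterations):
        batch = merge_batches(sample_multisession_batch(
            dataset, fit_config.batch_size, sampling_config, rng))
        embs = {}
        for role, t_idx, s_idx in (
                ("ref", batch.reference, batch.reference_session),
                ("pos", batch.positive, batch.positive_session),
                ("neg", batch.negative, batch.negative_session)):
            parts, order = [], []
            for j in np.unique(s_idx):
                sel = np.flatnonzero(s_idx == j)
                win = extract_window_batch(dataset[j], t_idx[sel], rf,
                                           sampling_config.causal)
                parts.append(encode(encoders[j], win, grad=True))
                order.append(sel)
            order = np.concatenate(order)
            perm = np.empty_like(order)
            perm[order] = np.arange(order.size)
            embs[role] = tg.take_rows(tg.concat_rows(parts), perm)
        result = infonce(embs["ref"], embs["pos"], embs["neg"],
                         similarity_config, state)
        opt.zero_grad()
        result.loss_tensor.backward()
        opt.step()
        model.record(result)
    return model


def adapt(model: TrainedModel, new_session: SessionData,
          fit_config: FitConfig, adapt_steps: int,
          full_finetune: bool = False, session_index: int = 0
          ) -> TrainedModel:
    """Adapt a pretrained encoder to a session with a new signal space.

    A fresh input layer matching the new dimensionality is initialized and
    trained for ``adapt_steps`` while all downstream layers stay frozen
    (default); ``full_finetune=True`` also updates the trunk.
    """
    rng = np.random.default_rng(fit_config.seed)
    old = model.encoders[session_index]
    spec = replace(old.spec, num_input=new_session.n_features)
    params = old.copy()
    if new_session.n_features != old.spec.num_input:
        fresh = build_encoder(spec, rng)
        params.layers[0] = fresh.layers[0]
    params.spec = spec
    trainable = (params.parameters() if full_finetune
                 else list(params.layers[0]))
    sampling_config = replace(model.sampling,
                              receptive_field=spec.receptive_field)
    sampling_config.validate(new_session)
    state = model.temperature
    opt = fit_config.make_optimizer(trainable + state.parameters())
    adapted = TrainedModel([params], model.similarity, state,
                           sampling_config, fit_config)
    for _ in range(adapt_steps):
        batch = sample_batch(new_session, fit_config.batch_size,
                             sampling_config, rng)
        ref, pos, neg = _embed_triplet(params, new_session, batch,
                                       sampling_config.causal)
        result = infonce(ref, pos, neg, model.similarity, state)
        opt.zero_grad()
        result.loss_tensor.backward()
        opt.step()
        adapted.record(result)
    return adapted


def evaluate_loss(model: TrainedModel, session: SessionData,
                  batch_size: int | str, seed: int,
                  session_index: int = 0) -> LossResult:
    """Loss of a (possibly adapted) model on a session, without training."""
    rng = np.random.default_rng(seed)
    batch = sample_batch(session, batch_size, model.sampling, rng)
    params = model.encoders[session_index]
    ref, pos, neg = _embed_triplet(params, session, batch,
                                   model.sampling.causal)
    return infonce(ref, pos, neg, model.similarity, model.temperature)


def transform(model: TrainedModel, session: SessionData,
              session_index: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Embed a session with a trained encoder (no labels required).

    Returns ``(embedding [T' x E], time_index [T'])``.
    """
    params = model.encoders[session_index]
    if session.n_features != params.spec.num_input:
        raise ValueError(
            f"session has {session.n_features} signal dimensions but the "
            f"encoder expects {params.spec.num_input}; use adapt() to fit a "
            f"new input layer")
    return encode_session(params, session, causal=model.sampling.causal)
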