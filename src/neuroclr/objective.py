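"""Similarity measures, the InfoNCE loss and the goodness-of-fit statistic.

The loss for a batch of n triplets (reference x, positive y+, negatives
y_1..y_n, negatives shared across references) is

    L_n = mean_x [ -psi(x, y+) + log sum_i exp psi(x, y_i) ],

where psi is either the temperature-scaled dot product of unit vectors
(cosine) or the temperature-scaled negative squared Euclidean distance.
The log-sum-exp is computed with a detached per-row maximum shift, so the
value equals the naive formula exactly in exact arithmetic while staying
finite for sharp temperatures.

Two reference points calibrate the scale of the loss: a constant similarity
(e.g. a collapsed encoder, or labels unrelated to the signal) gives exactly
L_n = log n, and the infimum of the objective is -D_KL(p||q) + log n.  The
*goodness of fit* L_n - log n is therefore batch-size independent, zero for
uninformative embeddings and bounded below by -D_KL(p||q).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _tensor as tg
from ._tensor import Tensor


class SimilarityConfigError(ValueError):
    pass


@dataclass
class SimilarityConfig:
    kind: str = "cosine"                 # or "negative_mse"
    temperature_mode: str = "fixed"      # or "learnable"
    tau: float = 1.0
    tau_min: float = 0.1

    def __post_init__(self):
        if self.kind not in ("cosine", "negative_mse"):
            raise SimilarityConfigError(f"unknown similarity kind {self.kind!r}")
        if self.temperature_mode not in ("fixed", "learnable"):
            raise SimilarityConfigError(
                f"unknown temperature mode {self.temperature_mode!r}")
        if self.tau <= 0 or self.tau_min <= 0:
            raise SimilarityConfigError("temperatures must be positive")


class TemperatureState:
    """Holds the learnable log-inverse-temperature alpha = -log tau.

    The scale applied to similarities is min(exp(alpha), 1/tau_min), so the
    effective inverse temperature always lies in (0, 1/tau_min].
    """

    def __init__(self, config: SimilarityConfig):
        self.config = config
        self.alpha: Tensor | None = None
        if config.temperature_mode == "learnable":
            self.alpha = Tensor(-np.log(config.tau), requires_grad=True)

    def parameters(self) -> list[Tensor]:
        return [] if self.alpha is None else [self.alpha]

    def scale(self):
        """Inverse temperature as a Tensor (learnable) or float (fixed)."""
        if self.alpha is None:
            return 1.0 / self.config.tau
        return tg.clamp_max(tg.exp(self.alpha), 1.0 / self.config.tau_min)

    @property
    def temperature(self) -> float:
        if self.alpha is None:
            return self.config.tau
        return float(1.0 / min(np.exp(self.alpha.data), 1.0 / self.config.tau_min))


def effective_inverse_temperature(alpha: float, tau_min: float) -> float:
    """min(exp(alpha), 1/tau_min) — the scale applied to all similarities."""
    if tau_min <= 0:
        raise SimilarityConfigError("tau_min must be positive")
    return float(min(np.exp(alpha), 1.0 / tau_min))


@dataclass
class LossResult:
    total: float
    alignment_term: float     # -mean positive similarity
    uniformity_term: float    # mean log-sum-exp over negatives
    batch_size: int
    temperature: float
    loss_tensor: Tensor | None = None


def similarity(z: np.ndarray, z_prime: np.ndarray,
               config: SimilarityConfig, check: bool = True) -> np.ndarray:
    """Pairwise similarity scores phi(z, z') (row-wise on matching rows).

    cosine: z.z' / tau (requires unit-norm inputs); negative_mse:
    -||z - z'||^2 / tau.  Both are bounded above.
    """
    z = np.atleast_2d(np.asarray(z, dtype=np.float64))
    z_prime = np.atleast_2d(np.asarray(z_prime, dtype=np.float64))
    if config.kind == "cosine":
        if check:
            for name, v in (("z", z), ("z_prime", z_prime)):
                norms = np.linalg.norm(v, axis=1)
                if not np.allclose(norms, 1.0, atol=1e-6):
                    raise SimilarityConfigError(
                        f"cosine similarity requires unit-norm {name}")
        return (z * z_prime).sum(axis=1) / config.tau
    return -((z - z_prime) ** 2).sum(axis=1) / config.tau


def _similarities(ref: Tensor, pos: Tensor, neg: Tensor, kind: str,
                  scale) -> tuple[Tensor, Tensor]:
    """(pos_sim [n], neg_sim [n x n]) before-and-after temperature scaling."""
    if kind == "cosine":
        pos_sim = tg.row_dot(ref, pos)
        neg_sim = tg.matmul_t(ref, neg)
    else:
        pos_sim = tg.mul_scalar(tg.row_sum(tg.mul(ref - pos, ref - pos)), -1.0)
        r2 = tg.row_sum(tg.mul(ref, ref), keepdims=True)      # [n x 1]
        n2 = tg.row_sum(tg.mul(neg, neg), keepdims=True)      # [n x 1]
        cross = tg.matmul_t(ref, neg)
        neg_sim = tg.mul_scalar(cross, 2.0) - r2 - _transpose_row(n2)
    if isinstance(scale, Tensor):
        pos_sim = tg.mul(pos_sim, _broadcast_scalar(scale))
        neg_sim = tg.mul(neg_sim, _broadcast_scalar(scale))
    else:
        pos_sim = tg.mul_scalar(pos_sim, scale)
        neg_sim = tg.mul_scalar(neg_sim, scale)
    return pos_sim, neg_sim


def _broadcast_scalar(s: Tensor) -> Tensor:
    return s  # numpy broadcasting in tg.mul handles 0-d against any shape


def _transpose_row(t: Tensor) -> Tensor:
    out = Tensor(t.data.T, requires_grad=t.requires_grad)
    if t.requires_grad:
        out._parents = (t,)
        out._backward = lambda g: t._accumulate(g.T)
    return out


def infonce(ref: Tensor | np.ndarray, pos: Tensor | np.ndarray,
            neg: Tensor | np.ndarray, config: SimilarityConfig,
            state: TemperatureState | None = None) -> LossResult:
    """InfoNCE over n references/positives and n shared negatives.

    Accepts raw arrays (evaluation) or graph tensors (training).  The total
    is alignment + uniformity with alignment = -mean(pos_sim) and
    uniformity = mean(logsumexp(neg_sim, rows)).
    """
    ref = ref if isinstance(ref, Tensor) else Tensor(ref)
    pos = pos if isinstance(pos, Tensor) else Tensor(pos)
    neg = neg if isinstance(neg, Tensor) else Tensor(neg)
    n = ref.shape[0]
    if pos.shape[0] != n or neg.shape[0] != n:
        raise ValueError("reference/positive/negative batch sizes differ")
    if n < 1:
        raise ValueError("batch must contain at least one triplet")
    if state is None:
        state = TemperatureState(config)
    pos_sim, neg_sim = _similarities(ref, pos, neg, config.kind, state.scale())
    align = tg.mean_all(tg.mul_scalar(pos_sim, -1.0))
    unif = tg.mean_all(tg.logsumexp_rows(neg_sim))
    total = align + unif
    return LossResult(total=float(total.data),
                      alignment_term=float(align.data),
                      uniformity_term=float(unif.data),
                      batch_size=n,
                      temperature=state.temperature,
                      loss_tensor=total)


def infonce_naive(ref: np.ndarray, pos: np.ndarray, neg: np.ndarray,
                  config: SimilarityConfig) -> float:
    """Unstabilized double-loop InfoNCE (independent oracle for tests)."""
    ref, pos, neg = (np.asarray(a, dtype=np.float64) for a in (ref, pos, neg))
    inv_tau = 1.0 / config.tau
    total = 0.0
    n = ref.shape[0]
    for i in range(n):
        if config.kind == "cosine":
            psi_pos = float(ref[i] @ pos[i]) * inv_tau
            psi_negs = [float(ref[i] @ neg[j]) * inv_tau for j in range(n)]
        else:
            psi_pos = -float(((ref[i] - pos[i]) ** 2).sum()) * inv_tau
            psi_negs = [-float(((ref[i] - neg[j]) ** 2).sum()) * inv_tau
                        for j in range(n)]
        total += -psi_pos + np.log(np.sum(np.exp(psi_negs)))
    return total / n


def goodness_of_fit(loss_total: float, n: int) -> float:
    """L_n - log n: 0 for uninformative embeddings, >= -D_KL(p||q)."""
    if n < 2:
        raise ValueError("goodness of fit requires a batch size of at least 2")
    return float(loss_total - np.log(n))


def check_compatibility(similarity_config: SimilarityConfig,
                        normalize_output: bool) -> None:
    """Cosine requires unit-norm encoder outputs; negative MSE forbids them."""
    if similarity_config.kind == "cosine" and not normalize_output:
        raise SimilarityConfigError(
            "cosine similarity requires a normalized encoder output")
    if similarity_config.kind == "negative_mse" and normalize_output:
        raise SimilarityConfigError(
            "negative MSE similarity requires an un-normalized encoder output")
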