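"""Convolutional feature extractors mapping signal windows to embeddings.

Three architectures, selected by receptive field:

* ``1``  — a four-layer MLP: D -> H, H -> H, H -> H/2, H/2 -> E.
* ``10`` — five time-convolutional layers with kernel sizes [2, 3, 3, 3, 3];
  the three middle layers carry additive skip connections; the final layer
  maps H -> E.
* ``40`` — a front end concatenating a fixed 2x average-pool downsample of
  the input with a learned downsample (kernel 4, stride 2), directly followed
  (no activation in between) by a kernel-3 stride-2 convolution for a net 4x
  subsampling; then three kernel-3 skip layers and a final kernel-3 layer
  to E.

GELU follows every layer except the last.  When the paired similarity is the
cosine, the output is projected onto the unit hypersphere; with a mean
squared error similarity the output is left un-normalized (Euclidean latent
space).  All convolutions are valid (no padding), consistent with the
window-index contract: a session of length T yields T - RF + 1 embeddings.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from . import _tensor as tg
from ._tensor import Tensor
from .data import SessionData, extract_window_batch, valid_window_indices

RECEPTIVE_FIELDS = (1, 10, 40)


@dataclass(frozen=True)
class EncoderSpec:
    receptive_field: int
    num_input: int
    num_hidden: int = 32
    output_dim: int = 8
    normalize: bool = True

    def validate(self) -> None:
        if self.receptive_field not in RECEPTIVE_FIELDS:
            raise ValueError(
                f"receptive field must be one of {RECEPTIVE_FIELDS}")
        if self.num_hidden // 2 < 1:
            raise ValueError("num_hidden must be at least 2")
        if self.num_input < 1 or self.output_dim < 1:
            raise ValueError("num_input and output_dim must be positive")


class EncoderParams:
    """Ordered weight/bias tensors for one encoder, plus the init seed."""

    def __init__(self, spec: EncoderSpec, layers: list[tuple[Tensor, Tensor]],
                 seed: int):
        self.spec = spec
        self.layers = layers
        self.seed = seed

    def parameters(self) -> list[Tensor]:
        return [t for pair in self.layers for t in pair]

    def copy(self) -> "EncoderParams":
        layers = [(Tensor(w.data.copy(), requires_grad=True),
                   Tensor(b.data.copy(), requires_grad=True))
                  for w, b in self.layers]
        return EncoderParams(self.spec, layers, self.seed)


def _init_pair(rng: np.random.Generator, w_shape: tuple[int, ...],
               fan_in: int) -> tuple[Tensor, Tensor]:
    # fan-in-scaled uniform initialization for weight and bias
    bound = 1.0 / np.sqrt(fan_in)
    w = Tensor(rng.uniform(-bound, bound, size=w_shape), requires_grad=True)
    b = Tensor(rng.uniform(-bound, bound, size=w_shape[0]), requires_grad=True)
    return w, b


def _layer_plan(spec: EncoderSpec) -> list[dict]:
    d, h, e = spec.num_input, spec.num_hidden, spec.output_dim
    if spec.receptive_field == 1:
        return [dict(kind="dense", shape=(h, d)),
                dict(kind="dense", shape=(h, h)),
                dict(kind="dense", shape=(h // 2, h)),
                dict(kind="dense", shape=(e, h // 2), last=True)]
    if spec.receptive_field == 10:
        return [dict(kind="conv", shape=(h, d, 2)),
                dict(kind="conv", shape=(h, h, 3), skip=True),
                dict(kind="conv", shape=(h, h, 3), skip=True),
                dict(kind="conv", shape=(h, h, 3), skip=True),
                dict(kind="conv", shape=(e, h, 3), last=True)]
    # receptive field 40: learned downsample runs alongside a fixed 2x
    # average pool; their concatenation feeds the second strided conv
    return [dict(kind="conv", shape=(h, d, 4), stride=2, mean_concat=True),
            dict(kind="conv", shape=(h, h + d, 3), stride=2, no_act_before=True),
            dict(kind="conv", shape=(h, h, 3), skip=True),
            dict(kind="conv", shape=(h, h, 3), skip=True),
            dict(kind="conv", shape=(h, h, 3), skip=True),
            dict(kind="conv", shape=(e, h, 3), last=True)]


def build_encoder(spec: EncoderSpec, rng: np.random.Generator | int
                  ) -> EncoderParams:
    """Initialize encoder parameters (seedable, fan-in-scaled uniform)."""
    spec.validate()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    layers = []
    for layer in _layer_plan(spec):
        shape = layer["shape"]
        fan_in = int(np.prod(shape[1:]))
        layers.append(_init_pair(rng, shape, fan_in))
    return EncoderParams(spec, layers, seed if seed is not None else -1)


def front_end_length(window_length: int) -> int:
    """Length of the intermediate sequence after the RF-40 front end."""
    l1 = (window_length - 4) // 2 + 1
    return (l1 - 3) // 2 + 1


def _forward(params: EncoderParams, x: Tensor) -> Tensor:
    """x: (N, C, L) for conv models, (N, D) for the MLP; returns (N, E)."""
    spec = params.spec
    plan = _layer_plan(spec)
    h = x
    for (w, b), layer in zip(params.layers, plan):
        if layer["kind"] == "dense":
            h = tg.add(tg.matmul(h, _transposed(w)), _row(b))
        else:
            stride = layer.get("stride", 1)
            if layer.get("mean_concat"):
                conv = tg.conv1d(h, w, b, stride=stride)
                pooled = tg.avgpool2(h)
                lout = conv.shape[2]
                h = tg.concat_channels(conv, tg.slice_time(pooled, 0, lout))
                continue  # no activation between the two downsampling convs
            if layer.get("skip"):
                inner = tg.gelu(tg.conv1d(h, w, b, stride=stride))
                h = tg.add(tg.slice_time(h, 1, h.shape[2] - 1), inner)
                continue
            h = tg.conv1d(h, w, b, stride=stride)
        if not layer.get("last"):
            h = tg.gelu(h)
    if spec.receptive_field > 1:
        if h.shape[2] != 1:
            raise ValueError(
                f"window length does not match receptive field: trailing "
                f"temporal extent {h.shape[2]}")
        h = _squeeze_time(h)
    if spec.normalize:
        h = tg.normalize_rows(h)
    return h


def _transposed(w: Tensor) -> Tensor:
    out = Tensor(w.data.T, requires_grad=w.requires_grad)
    if w.requires_grad:
        out._parents = (w,)
        out._backward = lambda g: w._accumulate(g.T)
    return out


def _row(b: Tensor) -> Tensor:
    out = Tensor(b.data[None, :], requires_grad=b.requires_grad)
    if b.requires_grad:
        out._parents = (b,)
        out._backward = lambda g: b._accumulate(g.sum(axis=0))
    return out


def _squeeze_time(h: Tensor) -> Tensor:
    out = Tensor(h.data[:, :, 0], requires_grad=h.requires_grad)
    if h.requires_grad:
        out._parents = (h,)
        out._backward = lambda g: h._accumulate(g[:, :, None])
    return out


def encode(params: EncoderParams, windows: np.ndarray,
           grad: bool = False) -> Tensor:
    """Embed a batch of signal windows ``[n x RF x D]`` -> ``[n x E]``.

    With ``grad=True`` the returned tensor participates in backprop.
    """
    spec = params.spec
    windows = np.asarray(windows, dtype=np.float64)
    if windows.ndim == 2:  # allow [n x D] for receptive field 1
        windows = windows[:, None, :]
    if windows.shape[1] != spec.receptive_field:
        raise ValueError(
            f"window length {windows.shape[1]} != receptive field "
            f"{spec.receptive_field}")
    if windows.shape[2] != spec.num_input:
        raise ValueError(
            f"window has {windows.shape[2]} channels, encoder expects "
            f"{spec.num_input}")
    if spec.receptive_field == 1:
        x = Tensor(windows[:, 0, :])
    else:
        x = Tensor(np.ascontiguousarray(windows.transpose(0, 2, 1)))
    out = _forward(params, x)
    if not grad:
        return Tensor(out.data)
    return out


def encode_session(params: EncoderParams, session: SessionData,
                   causal: bool = False, chunk: int = 2048
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Sliding-window embedding of a whole session.

    Returns ``(embedding [T' x E], time_index [T'])`` where row ``i`` is the
    window centred at ``time_index[i]`` and ``T' = T - RF + 1``.
    """
    rf = params.spec.receptive_field
    idx = valid_window_indices(session, rf, causal)
    outs = []
    for a in range(0, idx.size, chunk):
        win = extract_window_batch(session, idx[a:a + chunk], rf, causal)
        outs.append(encode(params, win).data)
    return np.concatenate(outs, axis=0), idx


# -- checkpoint serialization ---------------------------------------------

def save_encoder(path, params: EncoderParams) -> None:
    arrays = {"__spec__": np.frombuffer(
        json.dumps(asdict(params.spec)).encode(), dtype=np.uint8),
        "__seed__": np.array(params.seed)}
    for i, (w, b) in enumerate(params.layers):
        arrays[f"w{i}"] = w.data
        arrays[f"b{i}"] = b.data
    np.savez(path, **arrays)


def load_encoder(path) -> EncoderParams:
    with np.load(path, allow_pickle=False) as z:
        spec = EncoderSpec(**json.loads(bytes(z["__spec__"]).decode()))
        n_layers = len([k for k in z.files if k.startswith("w")])
        layers = [(Tensor(z[f"w{i}"], requires_grad=True),
                   Tensor(z[f"b{i}"], requires_grad=True))
                  for i in range(n_layers)]
        return EncoderParams(spec, layers, int(z["__seed__"]))
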