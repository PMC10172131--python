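"""Session containers, sliding-window indexing and array-container I/O.

A *session* is one time-aligned recording: a real-valued signal matrix
``[T x D]`` (for example binned spike counts or calcium traces), an optional
continuous context matrix ``[T x m]`` (behavioural covariates) and an
optional discrete context vector ``[T]`` (categorical condition labels).
Encoders with a finite receptive field consume contiguous windows of the
signal; a window "centred" at index ``t`` with receptive field ``r`` covers
rows ``t - r//2 .. t + (r - r//2) - 1`` (0-based, half-open), so a session of
length ``T`` yields ``T - r + 1`` valid windows.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Arrays that must share the time axis have different lengths."""


class DataError(ValueError):
    """Non-finite or otherwise invalid values in an input array."""


class FormatError(ValueError):
    """An on-disk container does not match the expected layout."""


@dataclass
class SessionData:
    """One recording session with time-aligned signal and context."""

    signal: np.ndarray
    continuous_context: np.ndarray | None = None
    discrete_context: np.ndarray | None = None
    sample_rate_hz: float = 1.0
    session_id: str = "session0"
    #: original categorical labels, indexed by the dense 0..K-1 codes
    discrete_labels: np.ndarray | None = None
    #: scratch cache for derived sampler structures (not persisted)
    cache: dict = field(default_factory=dict, repr=False, compare=False)

    @property
    def n_samples(self) -> int:
        return self.signal.shape[0]

    @property
    def n_features(self) -> int:
        return self.signal.shape[1]

    @property
    def n_categories(self) -> int:
        if self.discrete_context is None:
            return 0
        return int(self.discrete_context.max()) + 1


@dataclass
class MultiSessionDataset:
    """An ordered list of sessions; signal dimensionality may differ."""

    sessions: list[SessionData] = field(default_factory=list)

    def __post_init__(self):
        dims = {s.continuous_context.shape[1]
                for s in self.sessions if s.continuous_context is not None}
        if len(dims) > 1:
            raise AlignmentError(
                f"continuous context dimensionality differs across sessions: {dims}")

    def __len__(self) -> int:
        return len(self.sessions)

    def __getitem__(self, i: int) -> SessionData:
        return self.sessions[i]


@dataclass(frozen=True)
class WindowIndex:
    """Address of one signal window: (session, centre time, receptive field)."""

    session_index: int
    time_index: int
    receptive_field: int


def make_session(signal,
                 continuous_context=None,
                 discrete_context=None,
                 sample_rate_hz: float = 1.0,
                 session_id: str = "session0") -> SessionData:
    """Validate and assemble a :class:`SessionData`.

    Discrete labels of any hashable type are re-encoded to a dense
    ``0..K-1`` alphabet; the original labels are retained in
    ``discrete_labels`` for reporting.
    """
    signal = np.atleast_2d(np.asarray(signal, dtype=np.float64))
    if signal.ndim != 2:
        raise DataError(f"signal must be 2-D, got shape {signal.shape}")
    if not np.isfinite(signal).all():
        raise DataError("signal contains non-finite values")
    T = signal.shape[0]

    if continuous_context is not None:
        continuous_context = np.asarray(continuous_context, dtype=np.float64)
        if continuous_context.ndim == 1:
            continuous_context = continuous_context[:, None]
        if continuous_context.shape[0] != T:
            raise AlignmentError(
                f"continuous context length {continuous_context.shape[0]} "
                f"!= signal length {T}")
        if not np.isfinite(continuous_context).all():
            raise DataError("continuous context contains non-finite values")

    labels = None
    if discrete_context is not None:
        discrete_context = np.asarray(discrete_context)
        if discrete_context.ndim != 1:
            raise DataError("discrete context must be a 1-D vector")
        if discrete_context.shape[0] != T:
            raise AlignmentError(
                f"discrete context length {discrete_context.shape[0]} "
                f"!= signal length {T}")
        labels, codes = np.unique(discrete_context, return_inverse=True)
        discrete_context = codes.astype(np.int64)

    return SessionData(signal=signal,
                       continuous_context=continuous_context,
                       discrete_context=discrete_context,
                       sample_rate_hz=sample_rate_hz,
                       session_id=session_id,
                       discrete_labels=labels)


def window_offsets(receptive_field: int,
                   causal: bool = False) -> tuple[int, int]:
    """(left, right) extents of a window around its centre index.

    Centred (default): receptive field ``r`` covers ``t - r//2`` through
    ``t + (r - r//2) - 1``.  Causal: the window ends at ``t``.
    """
    if receptive_field < 1:
        raise ValueError("receptive field must be >= 1")
    if causal:
        return receptive_field - 1, 0
    left = receptive_field // 2
    return left, receptive_field - 1 - left


def valid_window_indices(session: SessionData, receptive_field: int,
                         causal: bool = False) -> np.ndarray:
    """All centre indices whose full window fits inside [0, T)."""
    T = session.n_samples
    if receptive_field > T:
        raise DataError(
            f"receptive field {receptive_field} exceeds session length {T}")
    left, right = window_offsets(receptive_field, causal)
    return np.arange(left, T - right, dtype=np.int64)


def extract_window(session: SessionData, t: int, receptive_field: int,
                   causal: bool = False) -> np.ndarray:
    """The ``[receptive_field x D]`` signal slice for centre index ``t``."""
    left, right = window_offsets(receptive_field, causal)
    lo, hi = t - left, t + right + 1
    if lo < 0 or hi > session.n_samples:
        raise IndexError(
            f"window [{lo}, {hi}) outside session of length {session.n_samples}")
    return session.signal[lo:hi]


def extract_window_batch(session: SessionData, idx: np.ndarray,
                         receptive_field: int,
                         causal: bool = False) -> np.ndarray:
    """Stack windows for many centre indices -> ``[n x RF x D]`` (no copy loop)."""
    left, right = window_offsets(receptive_field, causal)
    idx = np.asarray(idx, dtype=np.int64)
    if idx.size and (idx.min() - left < 0
                     or idx.max() + right + 1 > session.n_samples):
        raise IndexError("window index out of range")
    sig = session.signal
    s0, s1 = sig.strides
    T = session.n_samples
    view = np.lib.stride_tricks.as_strided(
        sig, shape=(T - receptive_field + 1, receptive_field, sig.shape[1]),
        strides=(s0, s0, s1), writeable=False)
    return view[idx - left]


# -- I/O -------------------------------------------------------------------

_SESSION_KEYS = ("signal", "continuous", "discrete")


def _session_arrays(session: SessionData) -> dict[str, np.ndarray]:
    out = {"signal": session.signal}
    if session.continuous_context is not None:
        out["continuous"] = session.continuous_context
    if session.discrete_context is not None:
        out["discrete"] = session.discrete_context
    return out


def write_dataset(path, dataset: MultiSessionDataset | SessionData) -> None:
    """Write sessions to an NPZ or HDF5 container with per-session groups."""
    if isinstance(dataset, SessionData):
        dataset = MultiSessionDataset([dataset])
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            for i, s in enumerate(dataset.sessions):
                g = f.create_group(f"session{i}")
                g.attrs["session_id"] = s.session_id
                g.attrs["sample_rate_hz"] = s.sample_rate_hz
                for k, v in _session_arrays(s).items():
                    g.create_dataset(k, data=v)
    else:
        arrays = {}
        meta = []
        for i, s in enumerate(dataset.sessions):
            for k, v in _session_arrays(s).items():
                arrays[f"session{i}/{k}"] = v
            meta.append({"session_id": s.session_id,
                         "sample_rate_hz": s.sample_rate_hz})
        arrays["__meta__"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)


def _build_session(arrays: dict[str, np.ndarray], meta: dict) -> SessionData:
    if "signal" not in arrays:
        raise FormatError("container session is missing the 'signal' array")
    unknown = set(arrays) - set(_SESSION_KEYS)
    if unknown:
        raise FormatError(f"unknown keys in session group: {sorted(unknown)}")
    return make_session(arrays["signal"],
                        continuous_context=arrays.get("continuous"),
                        discrete_context=arrays.get("discrete"),
                        sample_rate_hz=float(meta.get("sample_rate_hz", 1.0)),
                        session_id=str(meta.get("session_id", "session0")))


def read_dataset(path) -> MultiSessionDataset:
    """Read a container written by :func:`write_dataset` (NPZ or HDF5)."""
    path = Path(path)
    sessions = []
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            names = sorted((k for k in f if k.startswith("session")),
                           key=lambda k: int(k[len("session"):]))
            for name in names:
                g = f[name]
                arrays = {k: g[k][()] for k in g}
                sessions.append(_build_session(arrays, dict(g.attrs)))
    else:
        with np.load(path, allow_pickle=False) as z:
            meta = [{} for _ in range(0)]
            if "__meta__" in z.files:
                meta = json.loads(bytes(z["__meta__"]).decode())
            groups: dict[int, dict[str, np.ndarray]] = {}
            for key in z.files:
                if key == "__meta__":
                    continue
                try:
                    sess, arr = key.split("/", 1)
                    i = int(sess[len("session"):])
                except ValueError as e:
                    raise FormatError(f"unrecognized container key: {key}") from e
                groups.setdefault(i, {})[arr] = z[key]
            for i in sorted(groups):
                m = meta[i] if i < len(meta) else {}
                sessions.append(_build_session(groups[i], m))
    if not sessions:
        raise FormatError(f"no sessions found in {path}")
    return MultiSessionDataset(sessions)


def read_context_csv(path) -> np.ndarray:
    """Read a continuous-context matrix from a headered CSV file."""
    frame = pd.read_csv(path)
    values = frame.to_numpy(dtype=np.float64)
    if values.ndim == 1:
        values = values[:, None]
    return values


def write_embedding(path, embedding: np.ndarray, time_index: np.ndarray,
                    session_id: str = "session0",
                    metadata: dict | None = None) -> None:
    """Write an embedding time series as NPZ (round-trip exact)."""
    arrays = {"embedding": np.asarray(embedding),
              "time_index": np.asarray(time_index, dtype=np.int64),
              "session_id": np.array(session_id)}
    if metadata:
        arrays["__meta__"] = np.frombuffer(
            json.dumps(metadata, sort_keys=True).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def read_embedding(path) -> tuple[np.ndarray, np.ndarray, str, dict]:
    with np.load(path, allow_pickle=False) as z:
        meta = {}
        if "__meta__" in z.files:
            meta = json.loads(bytes(z["__meta__"]).decode())
        return (z["embedding"], z["time_index"], str(z["session_id"]), meta)
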