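"""Reference, positive and negative sampling for contrastive training.

The geometry of the learned embedding is controlled entirely by three
distributions: the reference marginal ``p(x)``, the positive conditional
``p(y|x)`` and the negative conditional ``q(y|x)``.  This module implements
the predefined schemes:

``time``
    positives are the reference shifted by an offset drawn from a set Δ.
``discrete``
    positives share the categorical label of the reference.
``continuous``
    positives are found by perturbing the reference's continuous context with
    an empirical context difference ``c_{t+τ} - c_t`` (τ ∈ Δ) and taking the
    sample whose context is nearest to the perturbed value.
``delta``
    like ``continuous`` but the perturbation is an isotropic Gaussian with
    scale δ.
``mixed``
    the continuous conditional restricted to candidates sharing the
    categorical label of the reference.

Negatives (and optionally references) are drawn from the empirical
distribution over valid windows, or uniformly over a categorical variable via
cumulative-histogram inversion — applying the uniform option to both
positives and negatives makes the embedding invariant to that variable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from .data import (MultiSessionDataset, SessionData, valid_window_indices)

MODES = ("time", "discrete", "continuous", "mixed", "delta")


class SamplingError(RuntimeError):
    """A conditional distribution has no valid candidate."""


class ConfigError(ValueError):
    """Sampling configuration inconsistent with the available contexts."""


@dataclass(frozen=True)
class SamplingConfig:
    mode: str = "time"
    time_offsets: tuple[int, ...] = (10,)
    delta: float = 0.1
    negative_mode: str = "empirical"       # or "uniform_over_category"
    reference_mode: str = "empirical"      # or "uniform_over_category"
    receptive_field: int = 1
    causal: bool = False
    seed: int = 0

    def validate(self, session: SessionData) -> None:
        if self.mode not in MODES:
            raise ConfigError(f"unknown sampling mode {self.mode!r}")
        if self.mode == "discrete" and session.discrete_context is None:
            raise ConfigError("mode='discrete' requires a discrete context")
        if self.mode in ("continuous", "delta") and session.continuous_context is None:
            raise ConfigError(f"mode={self.mode!r} requires a continuous context")
        if self.mode == "mixed" and (session.continuous_context is None
                                     or session.discrete_context is None):
            raise ConfigError("mode='mixed' requires both context types")
        if self.mode in ("time", "continuous", "mixed") and not self.time_offsets:
            raise ConfigError(f"mode={self.mode!r} requires non-empty time offsets")
        if "uniform_over_category" in (self.negative_mode, self.reference_mode) \
                and session.discrete_context is None:
            raise ConfigError("uniform_over_category requires a discrete context")


@dataclass
class ContrastiveBatch:
    """n (reference, positive) pairs plus n shared negatives.

    Time indices address window centres; the session arrays allow positives
    and negatives to live in a different session than their reference (used
    by multi-session training; all zero for single sessions).
    """

    reference: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    receptive_field: int
    reference_session: np.ndarray = field(default=None)
    positive_session: np.ndarray = field(default=None)
    negative_session: np.ndarray = field(default=None)

    def __post_init__(self):
        n = len(self.reference)
        if not (len(self.positive) == len(self.negative) == n):
            raise ValueError("reference/positive/negative lengths differ")
        for name in ("reference_session", "positive_session", "negative_session"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n, dtype=np.int64))

    @property
    def n(self) -> int:
        return len(self.reference)


# -- internal helpers ------------------------------------------------------

def _valid_context(session: SessionData, config: SamplingConfig):
    """Valid window centres and their context slices."""
    valid = valid_window_indices(session, config.receptive_field, config.causal)
    cont = (session.continuous_context[valid]
            if session.continuous_context is not None else None)
    disc = (session.discrete_context[valid]
            if session.discrete_context is not None else None)
    return valid, cont, disc


def _category_members(disc: np.ndarray) -> list[np.ndarray]:
    k = int(disc.max()) + 1
    return [np.flatnonzero(disc == j) for j in range(k)]


def _uniform_over_category(members: list[np.ndarray], n: int,
                           rng: np.random.Generator) -> np.ndarray:
    """Sample positions with a uniform marginal over categories.

    Equivalent to inverting the cumulative histogram of the categorical
    variable: the category is uniform, the member uniform within category.
    Returns positions into the valid-window array.
    """
    sizes = np.array([len(m) for m in members])
    usable = np.flatnonzero(sizes > 0)
    if usable.size == 0:
        raise SamplingError("no category has a valid member")
    cat = usable[rng.integers(usable.size, size=n)]
    within = np.floor(rng.random(n) * sizes[cat]).astype(np.int64)
    return np.array([members[c][w] for c, w in zip(cat, within)], dtype=np.int64)


def _nearest_context(context: np.ndarray, targets: np.ndarray,
                     candidate_pos: np.ndarray | None = None,
                     cache: dict | None = None,
                     cache_key=None) -> np.ndarray:
    """Positions (into `context`) nearest to each target in Euclidean norm.

    Ties break to the smallest time index.  One-dimensional contexts use a
    sorted-array bisection (with an optional per-session cache of the sort);
    higher dimensions fall back to a full distance matrix, where argmin's
    first-occurrence rule realizes the same tie-break.
    """
    cand = context if candidate_pos is None else context[candidate_pos]
    if cand.shape[1] == 1:
        pos = _nearest_1d(cand[:, 0], targets[:, 0], cache, cache_key)
    else:
        d2 = cdist(targets, cand, "sqeuclidean")
        pos = d2.argmin(axis=1)
    if candidate_pos is not None:
        pos = candidate_pos[pos]
    return pos


def _nearest_1d(values: np.ndarray, targets: np.ndarray,
                cache: dict | None, cache_key) -> np.ndarray:
    """Exact 1-D nearest neighbour; ties resolve to the smallest position."""
    if cache is not None and cache_key in cache:
        order, sorted_vals, best_pos = cache[cache_key]
    else:
        order = np.argsort(values, kind="stable")
        sorted_vals = values[order]
        # smallest original position within each run of equal values
        new_run = np.concatenate([[True], sorted_vals[1:] != sorted_vals[:-1]])
        run_start = np.flatnonzero(new_run)
        run_id = np.cumsum(new_run) - 1
        best_pos = order[run_start[run_id]]
        if cache is not None:
            cache[cache_key] = (order, sorted_vals, best_pos)
    j = np.searchsorted(sorted_vals, targets)
    left = np.clip(j - 1, 0, sorted_vals.size - 1)
    right = np.clip(j, 0, sorted_vals.size - 1)
    dl = np.abs(targets - sorted_vals[left])
    dr = np.abs(sorted_vals[right] - targets)
    pos = np.where(dl < dr, best_pos[left],
                   np.where(dr < dl, best_pos[right],
                            np.minimum(best_pos[left], best_pos[right])))
    return pos


def empirical_differences(session: SessionData, time_offsets: tuple[int, ...],
                          config: SamplingConfig | None = None) -> np.ndarray:
    """The multiset D = {c_{t+τ} - c_t : t, τ ∈ Δ} of context differences."""
    c = session.continuous_context
    if c is None:
        raise ConfigError("continuous context required")
    rows = []
    T = session.n_samples
    for tau in time_offsets:
        if tau < T:
            rows.append(c[tau:] - c[:-tau])
    if not rows:
        raise SamplingError(
            f"no usable offsets: T={T}, offsets={time_offsets}")
    return np.concatenate(rows, axis=0)


# -- single-session samplers ----------------------------------------------

def sample_reference(session: SessionData, n: int, config: SamplingConfig,
                     rng: np.random.Generator) -> np.ndarray:
    """n i.i.d. reference window centres."""
    if n <= 0:
        raise ValueError("n must be positive")
    config.validate(session)
    valid, _, disc = _valid_context(session, config)
    if config.reference_mode == "uniform_over_category":
        pos = _uniform_over_category(_category_members(disc), n, rng)
    else:
        pos = rng.integers(valid.size, size=n)
    return valid[pos]


def sample_negative(session: SessionData, n: int, config: SamplingConfig,
                    rng: np.random.Generator) -> np.ndarray:
    """n negative window centres (empirical or uniform-over-category)."""
    if n <= 0:
        raise ValueError("n must be positive")
    config.validate(session)
    valid, _, disc = _valid_context(session, config)
    if config.negative_mode == "uniform_over_category":
        pos = _uniform_over_category(_category_members(disc), n, rng)
    else:
        pos = rng.integers(valid.size, size=n)
    return valid[pos]


def sample_positive_discrete(session: SessionData, ref_t: np.ndarray,
                             config: SamplingConfig,
                             rng: np.random.Generator) -> np.ndarray:
    """Uniform draw among valid windows sharing the reference's category."""
    valid, _, disc = _valid_context(session, config)
    members = _category_members(disc)
    lookup = np.full(session.n_samples, -1, dtype=np.int64)
    lookup[valid] = np.arange(valid.size)
    ref_t = np.atleast_1d(np.asarray(ref_t, dtype=np.int64))
    out = np.empty(ref_t.size, dtype=np.int64)
    for i, t in enumerate(ref_t):
        k = session.discrete_context[t]
        cand = members[k]
        if cand.size == 0:
            raise SamplingError(f"category {k} has no valid member")
        out[i] = valid[cand[rng.integers(cand.size)]]
    return out


def sample_positive_time(session: SessionData, ref_t: np.ndarray,
                         config: SamplingConfig,
                         rng: np.random.Generator) -> np.ndarray:
    """Reference shifted by an offset drawn uniformly from Δ (valid ones)."""
    valid, _, _ = _valid_context(session, config)
    lo, hi = valid[0], valid[-1]
    offsets = np.asarray(config.time_offsets, dtype=np.int64)
    ref_t = np.atleast_1d(np.asarray(ref_t, dtype=np.int64))
    out = np.empty(ref_t.size, dtype=np.int64)
    for i, t in enumerate(ref_t):
        usable = offsets[(t + offsets >= lo) & (t + offsets <= hi)]
        if usable.size == 0:
            raise SamplingError(f"no valid time offset for reference {t}")
        out[i] = t + usable[rng.integers(usable.size)]
    return out


def _positive_targets(session: SessionData, ref_t: np.ndarray,
                      config: SamplingConfig,
                      rng: np.random.Generator) -> np.ndarray:
    """Perturbed context values c_ref + d for the continuous conditionals."""
    c_ref = session.continuous_context[ref_t]
    if config.mode == "delta":
        d = config.delta * rng.standard_normal(c_ref.shape)
    else:
        diffs = empirical_differences(session, config.time_offsets)
        d = diffs[rng.integers(diffs.shape[0], size=len(ref_t))]
    return c_ref + d


def sample_positive_continuous(session: SessionData, ref_t: np.ndarray,
                               config: SamplingConfig,
                               rng: np.random.Generator) -> np.ndarray:
    """Empirical-difference conditional positive (modes continuous/delta)."""
    valid, cont, _ = _valid_context(session, config)
    ref_t = np.atleast_1d(np.asarray(ref_t, dtype=np.int64))
    targets = _positive_targets(session, ref_t, config, rng)
    key = ("nn", config.receptive_field, config.causal)
    return valid[_nearest_context(cont, targets, cache=session.cache,
                                  cache_key=key)]


sample_positive_delta = sample_positive_continuous


def sample_positive_mixed(session: SessionData, ref_t: np.ndarray,
                          config: SamplingConfig,
                          rng: np.random.Generator) -> np.ndarray:
    """Continuous conditional restricted to the reference's category."""
    valid, cont, disc = _valid_context(session, config)
    members = _category_members(disc)
    ref_t = np.atleast_1d(np.asarray(ref_t, dtype=np.int64))
    targets = _positive_targets(session, ref_t, config, rng)
    out = np.empty(ref_t.size, dtype=np.int64)
    for k in range(len(members)):
        sel = np.flatnonzero(session.discrete_context[ref_t] == k)
        if sel.size == 0:
            continue
        if members[k].size == 0:
            raise SamplingError(f"category {k} has no valid candidate")
        pos = _nearest_context(cont, targets[sel], candidate_pos=members[k],
                               cache=session.cache,
                               cache_key=("nn", config.receptive_field,
                                          config.causal, k))
        out[sel] = valid[pos]
    return out


_POSITIVE = {
    "time": sample_positive_time,
    "discrete": sample_positive_discrete,
    "continuous": sample_positive_continuous,
    "delta": sample_positive_continuous,
    "mixed": sample_positive_mixed,
}


def sample_batch(session: SessionData, n: int | str, config: SamplingConfig,
                 rng: np.random.Generator) -> ContrastiveBatch:
    """Draw a full contrastive batch from the whole session.

    ``n="full"`` uses every valid window as a reference (batch gradient
    descent on the whole dataset).  Positives and negatives are drawn from
    all valid windows, never from within a pre-drawn minibatch.
    """
    config.validate(session)
    if n == "full":
        reference = valid_window_indices(session, config.receptive_field,
                                         config.causal).copy()
        rng.shuffle(reference)
        n = reference.size
    else:
        reference = sample_reference(session, n, config, rng)
    if config.mode == "time":
        # keep only references with at least one in-range offset
        valid = valid_window_indices(session, config.receptive_field,
                                     config.causal)
        lo, hi = valid[0], valid[-1]
        offsets = np.asarray(config.time_offsets)
        allowed = valid[
            ((valid[:, None] + offsets[None, :] >= lo)
             & (valid[:, None] + offsets[None, :] <= hi)).any(axis=1)]
        if allowed.size == 0:
            raise SamplingError("no reference admits a valid time offset")
        bad = ~np.isin(reference, allowed)
        if bad.any():
            reference = reference.copy()
            reference[bad] = allowed[rng.integers(allowed.size,
                                                  size=int(bad.sum()))]
    positive = _POSITIVE[config.mode](session, reference, config, rng)
    negative = sample_negative(session, n, config, rng)
    return ContrastiveBatch(reference=reference, positive=positive,
                            negative=negative,
                            receptive_field=config.receptive_field)


# -- multi-session sampling ------------------------------------------------

def sample_multisession_batch(dataset: MultiSessionDataset, n: int,
                              config: SamplingConfig,
                              rng: np.random.Generator,
                              ) -> list[ContrastiveBatch]:
    """Per-session batches for joint training of a shared embedding space.

    Each session contributes an equal quota of ``ceil(n / N)`` references,
    irrespective of session length.  For every reference a positive session
    is drawn uniformly and the positive is located there by continuous
    context matching against the reference's context; negatives are drawn
    uniformly across sessions from their empirical distributions.
    """
    if config.mode not in ("continuous", "delta", "mixed"):
        raise ConfigError(
            "multi-session sampling requires a continuous conditional")
    N = len(dataset)
    if N == 1:
        return [sample_batch(dataset[0], n, config, rng)]
    dims = {s.continuous_context.shape[1] for s in dataset.sessions}
    if len(dims) != 1:
        raise ConfigError(f"context dimensionality differs across sessions: {dims}")
    quota = -(-n // N)
    valid_all, cont_all = [], []
    for s in dataset.sessions:
        v, c, _ = _valid_context(s, config)
        valid_all.append(v)
        cont_all.append(c)

    batches = []
    for i, session in enumerate(dataset.sessions):
        reference = sample_reference(session, quota, config, rng)
        c_ref = session.continuous_context[reference]
        # positive session uniform over N, then the continuous conditional of
        # that session applied around the reference's context value
        pos_sess = rng.integers(N, size=quota)
        positive = np.empty(quota, dtype=np.int64)
        for j in np.unique(pos_sess):
            sel = np.flatnonzero(pos_sess == j)
            if config.mode == "delta":
                d = config.delta * rng.standard_normal((sel.size,
                                                        c_ref.shape[1]))
            else:
                diffs = empirical_differences(dataset[j], config.time_offsets)
                d = diffs[rng.integers(diffs.shape[0], size=sel.size)]
            targets = c_ref[sel] + d
            positive[sel] = valid_all[j][_nearest_context(
                cont_all[j], targets, cache=dataset[j].cache,
                cache_key=("nn", config.receptive_field, config.causal))]
        neg_sess = rng.integers(N, size=quota)
        negative = np.empty(quota, dtype=np.int64)
        for j in np.unique(neg_sess):
            sel = np.flatnonzero(neg_sess == j)
            negative[sel] = valid_all[j][rng.integers(valid_all[j].size,
                                                      size=sel.size)]
        batches.append(ContrastiveBatch(
            reference=reference, positive=positive, negative=negative,
            receptive_field=config.receptive_field,
            reference_session=np.full(quota, i, dtype=np.int64),
            positive_session=pos_sess.astype(np.int64),
            negative_session=neg_sess.astype(np.int64)))
    return batches


def merge_batches(batches: list[ContrastiveBatch]) -> ContrastiveBatch:
    """Concatenate per-session batches into one flat batch."""
    return ContrastiveBatch(
        reference=np.concatenate([b.reference for b in batches]),
        positive=np.concatenate([b.positive for b in batches]),
        negative=np.concatenate([b.negative for b in batches]),
        receptive_field=batches[0].receptive_field,
        reference_session=np.concatenate([b.reference_session for b in batches]),
        positive_session=np.concatenate([b.positive_session for b in batches]),
        negative_session=np.concatenate([b.negative_session for b in batches]))
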