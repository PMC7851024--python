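"""Discrete-observation ergodic hidden Markov models.

The model is the classical tuple ``lambda = (A, B, pi)`` over ``N``
hidden states and an alphabet of ``M`` symbols: ``A`` is the ``N x N``
row-stochastic transition matrix, ``B`` the ``N x M`` row-stochastic
emission matrix, and ``pi`` the initial-state distribution.  Throughout
this package ``pi`` is *fixed* to the unit vector ``(1, 0, ..., 0)`` —
the process always starts in state 1 — and is never re-estimated.

Likelihoods are computed by the scaled forward recursion (per-step
normalization constants whose logs sum to the sequence log-likelihood),
which is numerically stable for the 127-step sequences this package
models.  Training uses multi-sequence Baum–Welch EM: per-sequence
forward–backward passes accumulate expected transition and emission
counts, which re-estimate ``A`` and ``B``; a probability floor keeps
every entry strictly positive so that unseen test symbols never produce
a degenerate ``-inf`` likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NumericalError, ValidationError
from .preprocess import SymbolSequence

_ROW_TOL = 1e-9


def _unit_start(n_states: int) -> np.ndarray:
    start = np.zeros(n_states, dtype=float)
    start[0] = 1.0
    return start


@dataclass(eq=False)
class DiscreteHMM:
    """Ergodic discrete HMM with the start distribution pinned to state 1."""

    n_states: int
    n_symbols: int
    transition: np.ndarray
    emission: np.ndarray
    start: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.emission = np.asarray(self.emission, dtype=float)
        if self.start is None:
            self.start = _unit_start(self.n_states)
        else:
            self.start = np.asarray(self.start, dtype=float)
        self.validate()

    def validate(self) -> None:
        n, m = self.n_states, self.n_symbols
        if n < 1 or m < 1:
            raise ValidationError("n_states and n_symbols must be >= 1")
        if self.transition.shape != (n, n):
            raise ValidationError(f"transition must be {n}x{n}")
        if self.emission.shape != (n, m):
            raise ValidationError(f"emission must be {n}x{m}")
        for name, mat in (("transition", self.transition), ("emission", self.emission)):
            if np.any(mat < 0):
                raise ValidationError(f"{name} has negative entries")
            if np.any(np.abs(mat.sum(axis=1) - 1.0) > _ROW_TOL):
                raise ValidationError(f"{name} rows must sum to 1 within {_ROW_TOL}")
        if not np.array_equal(self.start, _unit_start(n)):
            raise ValidationError("start must be the fixed unit vector (state 1)")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DiscreteHMM):
            return NotImplemented
        return (
            self.n_states == other.n_states
            and self.n_symbols == other.n_symbols
            and np.array_equal(self.transition, other.transition)
            and np.array_equal(self.emission, other.emission)
            and np.array_equal(self.start, other.start)
        )


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters for one HMM pair.

    ``tol`` is the relative log-likelihood change below which EM stops;
    ``prob_floor`` is the minimum allowed transition/emission entry after
    each M-step (keeps likelihoods finite on symbols unseen in training).
    """

    n_states: int
    alphabet_size: int
    tol: float = 1e-6
    max_iter: int = 200
    prob_floor: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 1:
            raise ValidationError("n_states must be >= 1")
        if self.alphabet_size < 2:
            raise ValidationError("alphabet_size must be >= 2")
        if self.tol <= 0:
            raise ValidationError("tol must be > 0")
        if self.max_iter < 1:
            raise ValidationError("max_iter must be >= 1")
        if not (0 <= self.prob_floor < 1.0 / max(self.n_states, self.alphabet_size)):
            raise ValidationError("prob_floor must satisfy 0 <= floor < 1/max(N, M)")


@dataclass(eq=False)
class FitResult:
    """A trained model plus its EM trajectory."""

    model: DiscreteHMM
    loglik_trace: np.ndarray
    converged: bool
    n_iter: int

    def __post_init__(self) -> None:
        self.loglik_trace = np.asarray(self.loglik_trace, dtype=float)
        if np.any(np.diff(self.loglik_trace) < -1e-8):
            raise ValidationError("log-likelihood trace decreased beyond slack")


# ---------------------------------------------------------------------------
# internal batched recursions (0-based symbols, sequences of equal length)


def _check_sequences(
    sequences: list[SymbolSequence], n_symbols: int
) -> list[np.ndarray]:
    if not sequences:
        raise ValidationError("at least one sequence is required")
    obs = []
    for s in sequences:
        if s.alphabet_size != n_symbols or s.symbols.max() > n_symbols:
            raise ValidationError(
                f"sequence {s.roi_id!r} uses symbols beyond alphabet size {n_symbols}"
            )
        obs.append(s.symbols - 1)
    return obs


def _group_by_length(obs: list[np.ndarray]) -> list[np.ndarray]:
    """Stack equal-length sequences into 2-D batches for vectorized passes."""
    groups: dict[int, list[np.ndarray]] = {}
    for o in obs:
        groups.setdefault(o.size, []).append(o)
    return [np.stack(g) for _, g in sorted(groups.items())]


def _forward_batch(
    A: np.ndarray, B: np.ndarray, start: np.ndarray, obs: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Scaled forward pass over a batch of equal-length sequences.

    Returns ``(alpha, c, loglik)`` where ``alpha`` has shape ``(S, T, N)``
    (each time slice normalized to sum 1), ``c`` the scale factors
    ``(S, T)``, and ``loglik`` the per-sequence log-likelihoods ``(S,)``.
    A zero scale factor yields ``-inf`` log-likelihood for that sequence.
    """
    S, T = obs.shape
    N = A.shape[0]
    alpha = np.empty((S, T, N))
    c = np.empty((S, T))
    a = start[None, :] * B[:, obs[:, 0]].T
    for t in range(T):
        if t > 0:
            a = (alpha[:, t - 1] @ A) * B[:, obs[:, t]].T
        ct = a.sum(axis=1)
        c[:, t] = ct
        safe = np.where(ct > 0, ct, 1.0)
        alpha[:, t] = a / safe[:, None]
        a = alpha[:, t]
    with np.errstate(divide="ignore"):
        loglik = np.where(c > 0, np.log(np.where(c > 0, c, 1.0)), -np.inf).sum(axis=1)
    return alpha, c, loglik


def forward_loglik(model: DiscreteHMM, seq: SymbolSequence) -> float:
    """Log-probability ``log Pr(O | lambda)`` of one symbol sequence.

    Computed with the scaling-factor forward recursion; returns ``-inf``
    only if some required probability is exactly zero (impossible for
    floored models).
    """
    (obs,) = _check_sequences([seq], model.n_symbols)
    _, _, ll = _forward_batch(
        model.transition, model.emission, model.start, obs[None, :]
    )
    return float(ll[0])


def _floor_normalize(rows: np.ndarray, prob_floor: float) -> np.ndarray:
    """Row-normalize counts, raising entries below the floor.

    All-zero rows (a state never visited) become uniform.
    """
    rows = np.asarray(rows, dtype=float)
    out = np.empty_like(rows)
    for i, row in enumerate(rows):
        s = row.sum()
        p = row / s if s > 0 else np.full(row.size, 1.0 / row.size)
        if prob_floor > 0:
            p = np.maximum(p, prob_floor)
            p = p / p.sum()
        out[i] = p
    return out


# ---------------------------------------------------------------------------
# K-means initialization


def _kmeans_1d(values: np.ndarray, counts: np.ndarray, k: int) -> np.ndarray:
    """Deterministic weighted Lloyd's algorithm on sorted unique values.

    Centroids start at the k evenly spaced quantiles of the weighted data;
    if quantiles collide, k distinct values evenly spread over the support
    are used instead.  Assignment ties break toward the lower-index
    cluster; empty clusters keep their centroid.  Returns the cluster
    index of each unique value, relabeled by ascending centroid.
    """
    data = np.repeat(values, counts)
    centroids = np.quantile(data, (np.arange(k) + 0.5) / k)
    if np.unique(centroids).size < k:
        idx = np.linspace(0, values.size - 1, k).astype(int)
        centroids = values[idx].astype(float)
    assign = np.zeros(values.size, dtype=int)
    for _ in range(100):
        dist = np.abs(values[:, None] - centroids[None, :])
        new_assign = np.argmin(dist, axis=1)  # argmin -> lowest index on ties
        if np.array_equal(new_assign, assign) and _ > 0:
            break
        assign = new_assign
        for j in range(k):
            mask = assign == j
            if counts[mask].sum() > 0:
                centroids[j] = np.average(values[mask], weights=counts[mask])
    order = np.argsort(centroids, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(k)
    return relabel[assign]


def init_kmeans(
    sequences: list[SymbolSequence],
    n_states: int,
    prob_floor: float = 1e-6,
    seed: int | None = None,
) -> DiscreteHMM:
    """Initialize an HMM by 1-D K-means over the observed symbol values.

    The multiset of symbol values pooled over all training sequences is
    clustered into ``K = n_states`` groups (deterministic quantile
    initialization; ``seed`` is accepted for interface symmetry but the
    procedure draws no random numbers).  Emission row ``i`` is the
    floor-smoothed empirical symbol distribution of cluster ``i``;
    transition row ``i`` counts consecutive-position cluster moves
    ``i -> j`` pooled over sequences.  The start vector is the fixed unit
    vector.
    """
    del seed  # deterministic initialization
    if n_states < 1:
        raise ValidationError("n_states must be >= 1")
    if not sequences:
        raise ValidationError("at least one sequence is required")
    m = sequences[0].alphabet_size
    obs = _check_sequences(sequences, m)
    pooled = np.concatenate(obs)
    values, counts = np.unique(pooled, return_counts=True)
    if n_states > values.size:
        raise ValidationError(
            f"n_states={n_states} exceeds the {values.size} distinct observed "
            "symbols: reduce states or enlarge alphabet"
        )
    if n_states == 1:
        value_cluster = np.zeros(values.size, dtype=int)
    else:
        value_cluster = _kmeans_1d(values.astype(float), counts, n_states)
    symbol_to_cluster = np.zeros(m, dtype=int)
    symbol_to_cluster[values] = value_cluster

    b_counts = np.zeros((n_states, m))
    np.add.at(b_counts, (value_cluster, values), counts)
    a_counts = np.zeros((n_states, n_states))
    for o in obs:
        cl = symbol_to_cluster[o]
        np.add.at(a_counts, (cl[:-1], cl[1:]), 1)
    return DiscreteHMM(
        n_states=n_states,
        n_symbols=m,
        transition=_floor_normalize(a_counts, prob_floor),
        emission=_floor_normalize(b_counts, prob_floor),
    )


# ---------------------------------------------------------------------------
# Baum–Welch


def baum_welch(
    sequences: list[SymbolSequence],
    init: DiscreteHMM,
    config: TrainConfig,
) -> FitResult:
    """Multi-sequence Baum–Welch EM with the start vector held fixed.

    Sequences are treated as independent draws from the model, so the
    objective is the sum of per-sequence log-likelihoods.  Each iteration
    runs a scaled forward–backward pass per sequence, accumulates expected
    transition and emission counts, and re-estimates ``A`` and ``B``
    (floored and renormalized); ``pi`` stays pinned to state 1.  Stops
    when the relative log-likelihood change drops below ``config.tol`` or
    after ``config.max_iter`` iterations.
    """
    obs = _check_sequences(sequences, init.n_symbols)
    batches = _group_by_length(obs)
    N, M = init.n_states, init.n_symbols
    A = init.transition.copy()
    B = init.emission.copy()
    start = init.start.copy()

    trace: list[float] = []
    converged = False
    prev_ll: float | None = None
    n_iter = 0
    for it in range(config.max_iter):
        n_iter = it + 1
        a_num = np.zeros((N, N))
        b_num_t = np.zeros((M, N))  # transposed for scatter-add over symbols
        total_ll = 0.0
        for batch in batches:
            S, T = batch.shape
            alpha, c, ll = _forward_batch(A, B, start, batch)
            total_ll += float(ll.sum())
            if not np.isfinite(total_ll):
                raise NumericalError(
                    f"non-finite likelihood at EM iteration {n_iter}"
                )
            # backward pass, accumulating xi and gamma on the fly
            beta = np.ones((S, N))
            gamma = alpha[:, T - 1]  # beta_{T-1} = 1
            np.add.at(b_num_t, batch[:, T - 1], gamma)
            for t in range(T - 2, -1, -1):
                bo = B[:, batch[:, t + 1]].T  # (S, N)
                w = (bo * beta) / c[:, t + 1, None]
                xi = alpha[:, t, :, None] * A[None, :, :] * w[:, None, :]
                a_num += xi.sum(axis=0)
                gamma = xi.sum(axis=2)
                np.add.at(b_num_t, batch[:, t], gamma)
                beta = w @ A.T
        trace.append(total_ll)
        if prev_ll is not None:
            denom = max(abs(total_ll), 1e-300)
            if abs(total_ll - prev_ll) / denom < config.tol:
                converged = True
                break
        prev_ll = total_ll
        A = _floor_normalize(a_num, config.prob_floor)
        B = _floor_normalize(b_num_t.T, config.prob_floor)

    model = DiscreteHMM(n_states=N, n_symbols=M, transition=A, emission=B)
    return FitResult(
        model=model,
        loglik_trace=np.asarray(trace),
        converged=converged,
        n_iter=n_iter,
    )
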