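"""Temporal ordering of snapshot cohorts by a periodicity objective.

A cohort of M fixed samples is a set of snapshots of a periodic traveling
wave taken at unknown clock phases.  Re-ordering the columns of the
intensity matrix f(i, j) so that each spatial row becomes temporally
periodic recovers the phase order.  The objective is

    g(pi) = sum_i sum_k [ A(f_i o pi; k) - A_T(k) ]^2

where A(.; k) is the circular, mean-removed, variance-normalized
autocorrelation of spatial row i read along the ordered sample axis, and
A_T(k) = cos(2 pi k / P) is the target autocorrelation of a signal that is
periodic with period P samples (default P = M: the cohort spans one clock
cycle).  g is minimized over permutations with a Metropolis /
simulated-annealing search; an exhaustive minimizer doubles as a validation
oracle for small M.

Because circular autocorrelation is invariant to cyclic rotation and
reversal of the sample order, g determines the ordering only up to the
dihedral symmetry group; returned orderings are canonicalized (lowest
sample first, wave drifting posterior -> anterior) and recovery is scored
with a symmetry-aware Kendall distance.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .profiles import IntensityMatrix

__all__ = [
    "AutocorrSpec",
    "OrderingState",
    "AnnealConfig",
    "PeriodicityObjective",
    "autocorrelation",
    "target_autocorr",
    "objective_g",
    "anneal_order",
    "brute_force_order",
    "ordering_distance",
    "order_partner_channel",
    "canonicalize_permutation",
]

BRUTE_FORCE_LIMIT = 9


@dataclass
class AutocorrSpec:
    """Parameters of the autocorrelation objective.

    ``lags``: positive lags k entering g; ``None`` means 1..floor(M/2)
    (longer lags duplicate information under circularity).
    ``target_period``: period P of the target autocorrelation, in units of
    sample count; ``None`` means M (one full clock cycle per cohort).
    ``min_row_variance``: rows of f whose variance (under any ordering; the
    variance is permutation-invariant) is at or below this are excluded
    from g — their autocorrelation is undefined and they carry no signal.
    """

    lags: Sequence[int] | None = None
    target_period: float | None = None
    min_row_variance: float = 1e-12

    def resolve(self, n_samples: int) -> tuple[np.ndarray, float]:
        if self.lags is None:
            lags = np.arange(1, n_samples // 2 + 1)
        else:
            lags = np.asarray(list(self.lags), dtype=int)
        if lags.size == 0:
            raise ValueError("need at least one lag")
        if np.any(lags < 1) or np.any(lags >= n_samples):
            raise ValueError("lags must satisfy 1 <= k < M")
        period = float(self.target_period) if self.target_period else float(n_samples)
        if period <= 0:
            raise ValueError("target_period must be positive")
        return lags, period


@dataclass
class OrderingState:
    """A permutation of sample indices (temporal rank -> sample index)."""

    permutation: np.ndarray
    objective: float
    channel: str = ""
    n_admissible_rows: int = 0

    def __post_init__(self) -> None:
        self.permutation = np.asarray(self.permutation, dtype=int)
        m = self.permutation.size
        if not np.array_equal(np.sort(self.permutation), np.arange(m)):
            raise ValueError("permutation must be a bijection on 0..M-1")
        if not (np.isfinite(self.objective) and self.objective >= 0):
            raise ValueError("objective must be finite and non-negative")


@dataclass
class AnnealConfig:
    """Simulated-annealing schedule for the permutation search.

    ``initial_temperature="auto"`` sets T0 per chain to the median |dg| of
    100 random swap proposals from the starting permutation; temperature
    decays geometrically by ``cooling_factor`` each iteration.  The
    ``reverse-segment`` proposal (reverse a random contiguous block) mixes
    better on permutation spaces than swapping two entries; both are
    available.  ``restarts`` independent chains run from seeded random
    starts and the best-ever state is returned.
    """

    iterations: int = 20000
    initial_temperature: float | str = "auto"
    cooling_factor: float = 0.999
    proposal: str = "reverse-segment"
    seed: int = 0
    restarts: int = 5

    def __post_init__(self) -> None:
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")
        if not 0 < self.cooling_factor < 1:
            raise ValueError("cooling_factor must be in (0, 1)")
        if self.proposal not in ("swap-two", "reverse-segment"):
            raise ValueError(f"unknown proposal {self.proposal!r}")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        if self.initial_temperature != "auto" and not self.initial_temperature > 0:
            raise ValueError("initial_temperature must be positive or 'auto'")


# ---------------------------------------------------------------------------
# autocorrelation and objective
# ---------------------------------------------------------------------------

def autocorrelation(series: np.ndarray, k: int, min_variance: float = 0.0) -> float:
    """Circular, mean-removed, variance-normalized autocorrelation at lag k.

    A(k) = sum_j (s_j - sbar)(s_{(j+k) mod M} - sbar) / sum_j (s_j - sbar)^2.
    A(0) = 1 exactly; for a sampled sinusoid s_j = cos(2 pi j / M),
    A(k) = cos(2 pi k / M).
    """
    s = np.asarray(series, dtype=float)
    m = s.size
    if m < 2:
        raise ValueError("series must have length >= 2")
    if not 0 <= k < m:
        raise ValueError("lag must satisfy 0 <= k < M")
    c = s - s.mean()
    denom = float(np.dot(c, c))
    if denom / m <= min_variance:
        raise ValueError("series variance is below the admissibility tolerance")
    return float(np.dot(c, np.roll(c, -k)) / denom)


def target_autocorr(k: int, spec: AutocorrSpec, n_samples: int | None = None) -> float:
    """Target autocorrelation A_T(k) = cos(2 pi k / P) enforcing periodicity."""
    if k < 0:
        raise ValueError("lag must be non-negative")
    if spec.target_period:
        period = float(spec.target_period)
    elif n_samples:
        period = float(n_samples)
    else:
        raise ValueError("spec has no target_period; pass n_samples")
    return float(np.cos(2 * np.pi * k / period))


class PeriodicityObjective:
    """Pre-factored evaluator of g(pi) for one intensity matrix.

    Row means and variances are permutation-invariant, so rows are centered,
    admissibility-filtered and variance-normalized once; each evaluation then
    costs one gather and one fused multiply-sum over (rows x lags x M).
    """

    def __init__(self, matrix: IntensityMatrix | np.ndarray, spec: AutocorrSpec | None = None):
        values = matrix.values if isinstance(matrix, IntensityMatrix) else np.asarray(matrix, float)
        spec = spec or AutocorrSpec()
        n, m = values.shape
        if m < 2:
            raise ValueError("need at least two samples to order")
        lags, period = spec.resolve(m)
        centered = values - values.mean(axis=1, keepdims=True)
        sumsq = (centered ** 2).sum(axis=1)
        admissible = sumsq / m > spec.min_row_variance
        if not np.any(admissible):
            raise ValueError("no spatial row has variance above min_row_variance")
        self.n_samples = m
        self.n_admissible = int(admissible.sum())
        self.spec = spec
        # rows scaled so that A(k) = sum_j y_j y_{j+k}
        self._rows = centered[admissible] / np.sqrt(sumsq[admissible])[:, None]
        self._shift = (np.arange(m)[None, :] + lags[:, None]) % m  # (K, M)
        self._target = np.cos(2 * np.pi * lags / period)  # (K,)

    def value(self, permutation: np.ndarray) -> float:
        z = self._rows[:, permutation]
        # batched row-wise dot: (R, K, M) @ (R, M, 1) -> circular ACF at all lags
        acf = (z[:, self._shift] @ z[:, :, None])[:, :, 0]
        diff = acf - self._target
        return float((diff * diff).sum())


def objective_g(
    matrix: IntensityMatrix | np.ndarray,
    permutation: Sequence[int] | np.ndarray,
    spec: AutocorrSpec | None = None,
) -> tuple[float, int]:
    """Evaluate g under one ordering; returns (g, number of admissible rows)."""
    ev = PeriodicityObjective(matrix, spec)
    perm = np.asarray(permutation, dtype=int)
    if not np.array_equal(np.sort(perm), np.arange(ev.n_samples)):
        raise ValueError("permutation is not a bijection on the matrix columns")
    return ev.value(perm), ev.n_admissible


# ---------------------------------------------------------------------------
# canonical form under the dihedral symmetry of g
# ---------------------------------------------------------------------------

def _wave_drift(matrix: IntensityMatrix | np.ndarray, permutation: np.ndarray) -> float:
    """Mean circular drift of the band centroid along the ranked cohort.

    Positive drift means the expression band moves posterior -> anterior
    (centroid increasing, wrapping 1 -> 0) with increasing rank.
    """
    if isinstance(matrix, IntensityMatrix):
        values, centers = matrix.values, matrix.bin_centers
    else:
        values = np.asarray(matrix, float)
        centers = (np.arange(values.shape[0]) + 0.5) / values.shape[0]
    weights = values[:, permutation]
    totals = weights.sum(axis=0)
    totals[totals == 0] = 1.0
    centroid = (centers[:, None] * weights).sum(axis=0) / totals
    step = np.diff(centroid, append=centroid[:1])
    return float(np.mean((step + 0.5) % 1.0 - 0.5))


def canonicalize_permutation(
    permutation: np.ndarray, matrix: IntensityMatrix | np.ndarray | None = None
) -> np.ndarray:
    """Pick a fixed representative of the rotation/reflection orbit.

    Rotates so the first-listed sample (index 0, the lowest id) sits at rank
    0; if a matrix is given, the direction is chosen so the band centroid
    drifts posterior -> anterior with increasing rank (the known direction
    of the segmentation-clock wave).  Cosmetic: g is identical across the
    orbit.
    """
    perm = np.asarray(permutation, dtype=int)
    if matrix is not None and _wave_drift(matrix, perm) < 0:
        perm = perm[::-1]
    if isinstance(matrix, IntensityMatrix):
        first = min(range(len(matrix.sample_ids)), key=lambda j: matrix.sample_ids[j])
    else:
        first = 0
    anchor = int(np.nonzero(perm == first)[0][0])
    return np.roll(perm, -anchor)


# ---------------------------------------------------------------------------
# minimizers
# ---------------------------------------------------------------------------

def _chain(ev, rng, config, trace, offset):
    m = ev.n_samples
    perm = rng.permutation(m)
    g = ev.value(perm)
    if config.initial_temperature == "auto":
        deltas = []
        for _ in range(100):
            i, j = rng.integers(0, m, size=2)
            q = perm.copy()
            q[i], q[j] = q[j], q[i]
            deltas.append(abs(ev.value(q) - g))
        temperature = float(np.median(deltas)) or 1e-3
    else:
        temperature = float(config.initial_temperature)
    best_g, best_perm = g, perm.copy()
    reverse = config.proposal == "reverse-segment"
    for it in range(config.iterations):
        i, j = np.sort(rng.integers(0, m, size=2))
        cand = perm.copy()
        if reverse:
            cand[i : j + 1] = cand[i : j + 1][::-1]
        else:
            cand[i], cand[j] = cand[j], cand[i]
        g_cand = ev.value(cand)
        delta = g_cand - g
        if delta <= 0 or rng.random() < math.exp(-delta / temperature):
            perm, g = cand, g_cand
            if g < best_g:
                best_g, best_perm = g, perm.copy()
        trace.append((offset + it, g, best_g, temperature))
        temperature *= config.cooling_factor
    return best_g, best_perm


def anneal_order(
    matrix: IntensityMatrix | np.ndarray,
    spec: AutocorrSpec | None = None,
    config: AnnealConfig | None = None,
) -> tuple[OrderingState, pd.DataFrame]:
    """Minimize g over permutations with Metropolis acceptance and cooling.

    Runs ``config.restarts`` independent chains from seeded random starting
    permutations; a proposed neighbour is accepted with probability
    min(1, exp(-dg / T)) and T decays geometrically.  Returns the best-ever
    state across chains (canonicalized) and a per-iteration trace with
    columns chain, iteration, current_g, best_g, temperature; best_g is the
    global best so far, hence non-increasing down the trace.  The same seed
    and config reproduce the result exactly.
    """
    ev = PeriodicityObjective(matrix, spec)
    config = config or AnnealConfig()
    rngs = [np.random.default_rng(s) for s in np.random.SeedSequence(config.seed).spawn(config.restarts)]
    records: list[tuple[int, float, float, float]] = []
    best_g, best_perm = np.inf, None
    chain_col = []
    for chain_idx, rng in enumerate(rngs):
        chain_trace: list[tuple[int, float, float, float]] = []
        g, perm = _chain(ev, rng, config, chain_trace, offset=0)
        if g < best_g:
            best_g, best_perm = g, perm
        records.extend(chain_trace)
        chain_col.extend([chain_idx] * len(chain_trace))
    trace = pd.DataFrame(records, columns=["iteration", "current_g", "best_g", "temperature"])
    trace.insert(0, "chain", chain_col)
    # make best_g global (monotone across the concatenated chains)
    trace["best_g"] = np.minimum.accumulate(trace["best_g"].to_numpy())
    perm = canonicalize_permutation(best_perm, matrix)
    channel = matrix.channel if isinstance(matrix, IntensityMatrix) else ""
    state = OrderingState(
        permutation=perm,
        objective=float(best_g),
        channel=channel,
        n_admissible_rows=ev.n_admissible,
    )
    return state, trace


def brute_force_order(
    matrix: IntensityMatrix | np.ndarray,
    spec: AutocorrSpec | None = None,
    limit: int = BRUTE_FORCE_LIMIT,
    allow_large: bool = False,
) -> OrderingState:
    """Exhaustive global minimizer of g, for validation at small M.

    Fixes sample 0 at rank 0 (g is rotation-invariant) and, for M >= 3,
    keeps one of each mirrored pair (g is reflection-invariant); both
    reductions are result-equivalent to full enumeration.  Exact ties are
    broken by the lexicographically smallest canonical permutation.
    """
    values = matrix.values if isinstance(matrix, IntensityMatrix) else np.asarray(matrix, float)
    if values.shape[1] == 1:  # a single sample is trivially ordered
        channel = matrix.channel if isinstance(matrix, IntensityMatrix) else ""
        return OrderingState(np.array([0]), 0.0, channel, 0)
    ev = PeriodicityObjective(matrix, spec)
    m = ev.n_samples
    if m > limit and not allow_large:
        raise ValueError(
            f"M={m} exceeds the brute-force guard ({limit}); pass allow_large=True"
        )
    best_g = np.inf
    best: list[np.ndarray] = []
    for rest in itertools.permutations(range(1, m)):
        if m >= 3 and rest[0] > rest[-1]:
            continue  # reflection-reduced
        perm = np.array((0,) + rest)
        g = ev.value(perm)
        if g < best_g:
            best_g, best = g, [perm]
        elif g == best_g:
            best.append(perm)
    canon = sorted(tuple(canonicalize_permutation(p, matrix)) for p in best)[0]
    channel = matrix.channel if isinstance(matrix, IntensityMatrix) else ""
    return OrderingState(
        permutation=np.array(canon),
        objective=float(best_g),
        channel=channel,
        n_admissible_rows=ev.n_admissible,
    )


# ---------------------------------------------------------------------------
# scoring and transfer
# ---------------------------------------------------------------------------

def _kendall_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Normalized Kendall tau distance: fraction of discordant sample pairs."""
    m = a.size
    rank_a = np.argsort(a)
    rank_b = np.argsort(b)
    i, j = np.triu_indices(m, k=1)
    return float(np.mean((rank_a[i] - rank_a[j]) * (rank_b[i] - rank_b[j]) < 0))


def ordering_distance(a: Sequence[int], b: Sequence[int]) -> float:
    """Distance between orderings modulo the rotation/reflection symmetry.

    Minimum over all 2M compositions of ``b`` with cyclic rotations and the
    reversal of the normalized Kendall tau distance to ``a``; 0 iff the two
    orderings agree up to the dihedral symmetry that g cannot resolve.
    """
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("orderings must have the same length")
    m = a.size
    if m < 2:
        return 0.0
    best = 1.0
    for variant in (b, b[::-1]):
        for shift in range(m):
            best = min(best, _kendall_distance(a, np.roll(variant, shift)))
            if best == 0.0:
                return 0.0
    return best


def order_partner_channel(
    reference_matrix: IntensityMatrix,
    partner_matrix: IntensityMatrix,
    ordering: OrderingState,
) -> IntensityMatrix:
    """Transfer the clock-channel ordering to the contralateral channel.

    The two matrices must cover the same samples (contralateral pairs share
    an embryo identifier).  The output's column at rank r is the partner
    column of the sample ranked r by the reference ordering.
    """
    if set(reference_matrix.sample_ids) != set(partner_matrix.sample_ids):
        raise ValueError("reference and partner matrices cover different samples")
    if ordering.permutation.size != reference_matrix.n_samples:
        raise ValueError("ordering length does not match the reference matrix")
    ranked_ids = [reference_matrix.sample_ids[j] for j in ordering.permutation]
    col_of = {sid: j for j, sid in enumerate(partner_matrix.sample_ids)}
    cols = [col_of[sid] for sid in ranked_ids]
    return IntensityMatrix(
        values=partner_matrix.values[:, cols],
        bin_centers=partner_matrix.bin_centers.copy(),
        sample_ids=ranked_ids,
        channel=partner_matrix.channel,
    )
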