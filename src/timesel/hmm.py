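"""Hidden Markov model over a discretized allele-frequency space.

The hidden state is the population frequency of the focal allele ``A`` on a
grid over [0, 1] with dedicated boundary states at exactly 0 and 1.
Transitions over ``dt`` generations are approximated by a Gaussian whose
mean is the deterministic selection+mutation map iterated ``dt`` times and
whose variance accumulates the per-generation binomial sampling noise along
the mean path.  Observations are binomial draws of alleles from the
population at the sampling times, so emissions are binomial probabilities
and the scaled forward algorithm yields per-locus log-likelihoods,
vectorized across loci that share a sampling schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import betainc

from .wf_core import (
    DiploidFitness,
    PopParams,
    SelectionSchedule,
    _check_generations,
    deterministic_step,
    step_derivative,
)

__all__ = [
    "FrequencyGrid",
    "TransitionMatrix",
    "InitialCondition",
    "TemporalSamples",
    "build_grid",
    "gaussian_moments",
    "one_generation_matrix",
    "build_transition_matrix",
    "emission_probability",
    "initial_distribution",
    "forward_log_likelihood",
    "batch_log_likelihood",
]

_ROW_SUM_TOL = 1e-9


@dataclass(frozen=True)
class FrequencyGrid:
    """Ordered frequency states in [0, 1] and the cells they represent.

    ``points`` always includes both endpoints 0 and 1.  ``cell_edges`` has
    one more entry than ``points``; cell ``j`` is ``[edges[j], edges[j+1]]``
    with edges at midpoints between adjacent points, so the cells tile [0, 1]
    without overlap.
    """

    points: np.ndarray
    cell_edges: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "cell_edges", np.asarray(self.cell_edges, dtype=float))
        if pts[0] != 0.0 or pts[-1] != 1.0:
            raise ValueError("grid must include both endpoints 0 and 1")
        if np.any(np.diff(pts) <= 0):
            raise ValueError("grid points must be strictly increasing")
        if len(self.cell_edges) != len(pts) + 1:
            raise ValueError("need len(points)+1 cell edges")

    @property
    def n(self) -> int:
        return len(self.points)

    @property
    def cell_widths(self) -> np.ndarray:
        return np.diff(self.cell_edges)


def build_grid(n_interior: int = 500, refinement: int = 0) -> FrequencyGrid:
    """Frequency grid with ``n_interior`` uniform interior points plus 0 and 1.

    Interior points sit at ``k / (n_interior + 1)``.  With ``refinement = r``
    an extra geometric ladder of ``r`` points is inserted near each boundary
    (at spacings ``delta/2, delta/4, ...``), concentrating states where
    absorption makes the frequency distribution steep.
    """
    if n_interior < 3:
        raise ValueError(f"need at least 3 interior points, got {n_interior}")
    if refinement < 0:
        raise ValueError("refinement must be >= 0")
    delta = 1.0 / (n_interior + 1)
    pts = np.linspace(0.0, 1.0, n_interior + 2)
    if refinement:
        ladder = delta / 2.0 ** np.arange(1, refinement + 1)
        pts = np.unique(np.concatenate([pts, ladder, 1.0 - ladder]))
    edges = np.empty(len(pts) + 1)
    edges[0] = 0.0
    edges[-1] = 1.0
    edges[1:-1] = 0.5 * (pts[:-1] + pts[1:])
    return FrequencyGrid(points=pts, cell_edges=edges)


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic transition kernel over a grid, for one fitness epoch."""

    matrix: np.ndarray
    dt: int
    fitness: DiploidFitness

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        if np.any(m < 0):
            raise ValueError("transition matrix has negative entries")
        rowsum = m.sum(axis=1)
        if np.any(np.abs(rowsum - 1.0) > _ROW_SUM_TOL):
            raise ValueError("transition matrix rows must sum to 1")


@dataclass(frozen=True)
class InitialCondition:
    """Distribution of the population frequency at the first sampling time.

    ``kind`` is one of ``"fixed"`` (point mass at ``x0``), ``"uniform"``
    (flat over [0, 1]), ``"stationary-beta"`` (mutation-drift stationary
    density Beta(4*Ne*u01, 4*Ne*u10)), or ``"explicit"`` (caller-supplied
    ``weights`` over the grid points).
    """

    kind: str = "uniform"
    x0: float | None = None
    weights: np.ndarray | None = None

    _KINDS = ("fixed", "uniform", "stationary-beta", "explicit")

    def __post_init__(self) -> None:
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}, got {self.kind!r}")
        if self.kind == "fixed":
            if self.x0 is None or not (0.0 <= self.x0 <= 1.0):
                raise ValueError("fixed initial condition needs x0 in [0, 1]")
        if self.kind == "explicit":
            if self.weights is None:
                raise ValueError("explicit initial condition needs weights")
            object.__setattr__(
                self, "weights", np.asarray(self.weights, dtype=float)
            )

    @classmethod
    def fixed(cls, x0: float) -> "InitialCondition":
        return cls(kind="fixed", x0=x0)

    @classmethod
    def uniform(cls) -> "InitialCondition":
        return cls(kind="uniform")

    @classmethod
    def stationary_beta(cls) -> "InitialCondition":
        return cls(kind="stationary-beta")

    @classmethod
    def explicit(cls, weights) -> "InitialCondition":
        return cls(kind="explicit", weights=weights)


@dataclass(frozen=True)
class TemporalSamples:
    """Per-locus time series of allele counts.

    ``times`` are sampling generations (non-decreasing integers), ``sizes``
    haploid sample sizes (pseudo-haploid individuals contribute 1 each, a
    size of 0 marks missing data) and ``counts`` the number of sampled
    chromosomes carrying the focal allele.
    """

    times: np.ndarray
    sizes: np.ndarray
    counts: np.ndarray
    locus_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        n = np.asarray(self.sizes, dtype=int)
        c = np.asarray(self.counts, dtype=int)
        if not (len(t) == len(n) == len(c)):
            raise ValueError("times, sizes and counts must have equal length")
        if len(t) == 0:
            raise ValueError("need at least one sampling time")
        if np.any(np.diff(t) < 0):
            raise ValueError(f"sampling times must be non-decreasing: {t}")
        if np.any(n < 0):
            raise ValueError("sample sizes must be non-negative")
        if np.any((c < 0) | (c > n)):
            raise ValueError("counts must satisfy 0 <= count <= size")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "sizes", n)
        object.__setattr__(self, "counts", c)

    @property
    def pooled_size(self) -> int:
        return int(self.sizes.sum())

    @property
    def pooled_count(self) -> int:
        return int(self.counts.sum())


def gaussian_moments(
    x, fit: DiploidFitness, pop: PopParams, dt: int
) -> tuple[np.ndarray, np.ndarray]:
    """Mean and variance of the frequency after ``dt`` generations.

    The mean is the ``dt``-fold composition of the deterministic map ``f``
    (selection then mutation); the variance follows the linearized
    law-of-total-variance recursion

        v[g+1] = v[g] * f'(m[g])^2 * (1 - 1/(2*Ne)) + m[g+1](1-m[g+1])/(2*Ne)

    started from v[0] = 0, which for neutral dynamics reproduces the exact
    Wright-Fisher variance ``x(1-x)(1 - (1 - 1/(2Ne))^dt)``.  Accepts scalar
    or array ``x``.
    """
    dt = _check_generations(dt)
    m = np.asarray(x, dtype=float).copy()
    v = np.zeros_like(m)
    shrink = 1.0 - 1.0 / (2.0 * pop.Ne)
    for _ in range(dt):
        d = step_derivative(m, fit, pop)
        m = np.asarray(deterministic_step(m, fit, pop))
        v = v * d * d * shrink + m * (1.0 - m) / (2.0 * pop.Ne)
    return m, v


# one-generation rows whose expected allele count is closer to a boundary
# than this many copies use the exact binomial law instead of its Gaussian
# approximation (the binomial is strongly skewed in that Poisson-like regime
# and the Gaussian badly misjudges absorption)
_BOUNDARY_COPIES = 20.0


def one_generation_matrix(
    grid: FrequencyGrid, fit: DiploidFitness, pop: PopParams
) -> np.ndarray:
    """Single-generation transition kernel over the grid.

    Interior rows integrate the Gaussian with mean ``f(x)`` (one
    deterministic generation of selection and mutation) and binomial
    sampling variance ``f(x)(1-f(x))/(2 Ne)`` over each grid cell, with tail
    mass beyond [0, 1] collected into the boundary states.  Rows whose
    expected allele count lies within ``_BOUNDARY_COPIES`` copies of either
    boundary instead place the exact Binomial(2Ne, f(x)) atoms on the grid,
    splitting each atom linearly between its flanking grid points (which
    preserves the mean); in this near-boundary regime the binomial is
    Poisson-like and the Gaussian misjudges loss and fixation.  Rows with
    zero variance degenerate to a point mass on the cell containing the mean.
    """
    pts = grid.points
    k = grid.n
    two_ne = max(int(round(2.0 * pop.Ne)), 1)
    m = np.asarray(deterministic_step(pts, fit, pop))
    sd = np.sqrt(m * (1.0 - m) / two_ne)
    edges = grid.cell_edges
    mat = np.zeros((k, k))
    degenerate = sd <= 0.0
    near = (
        ((m * two_ne < _BOUNDARY_COPIES) | ((1.0 - m) * two_ne < _BOUNDARY_COPIES))
        & ~degenerate
    )
    gauss = ~near & ~degenerate
    if np.any(gauss):
        # interior cell edges; the two outermost cells absorb the tails
        z = (edges[None, 1:-1] - m[gauss, None]) / sd[gauss, None]
        cdf = stats.norm.cdf(z)
        rows = np.empty((int(gauss.sum()), k))
        rows[:, 0] = cdf[:, 0]
        rows[:, 1:-1] = np.diff(cdf, axis=1)
        rows[:, -1] = 1.0 - cdf[:, -1]
        mat[gauss] = rows
    for i in np.flatnonzero(near):
        mu = m[i] * two_ne
        if mu < two_ne / 2:
            hi_k = stats.poisson.ppf(1.0 - 1e-14, max(mu, 1e-12)) + 10
            ks = np.arange(0, int(min(two_ne, hi_k)) + 1)
        else:
            lo_mu = (1.0 - m[i]) * two_ne
            lo_k = two_ne - stats.poisson.ppf(1.0 - 1e-14, max(lo_mu, 1e-12)) - 10
            ks = np.arange(int(max(0, lo_k)), two_ne + 1)
        pm = stats.binom.pmf(ks, two_ne, m[i])
        xk = ks / two_ne
        hi = np.clip(np.searchsorted(pts, xk), 1, k - 1)
        lo = hi - 1
        w_hi = (xk - pts[lo]) / (pts[hi] - pts[lo])
        np.add.at(mat[i], lo, pm * (1.0 - w_hi))
        np.add.at(mat[i], hi, pm * w_hi)
        mat[i] /= mat[i].sum()
    if np.any(degenerate):
        idx = np.clip(
            np.searchsorted(edges, m[degenerate], side="right") - 1, 0, k - 1
        )
        rows = np.zeros((int(degenerate.sum()), k))
        rows[np.arange(len(idx)), idx] = 1.0
        mat[degenerate] = rows
    mat /= mat.sum(axis=1, keepdims=True)
    return mat


def build_transition_matrix(
    grid: FrequencyGrid, fit: DiploidFitness, pop: PopParams, dt: int
) -> TransitionMatrix:
    """Transition kernel over ``dt`` generations of one fitness epoch.

    The ``dt``-generation kernel is the ``dt``-th matrix power of the
    one-generation kernel (:func:`one_generation_matrix`), so probability is
    re-absorbed at the boundaries every generation exactly as in the
    per-generation model; ``dt = 0`` yields the identity.
    """
    dt = _check_generations(dt)
    if dt == 0:
        return TransitionMatrix(np.eye(grid.n), 0, fit)
    t1 = one_generation_matrix(grid, fit, pop)
    mat = np.linalg.matrix_power(t1, dt) if dt > 1 else t1
    return TransitionMatrix(mat, dt, fit)


def emission_probability(x: float, size: int, count: int) -> float:
    """Binomial probability of observing ``count`` focal alleles in ``size``
    sampled chromosomes when the population frequency is ``x``.

    A sample size of 0 denotes missing data and returns 1.
    """
    if count < 0 or count > size:
        raise ValueError(f"need 0 <= count <= size, got count={count}, size={size}")
    if size == 0:
        return 1.0
    return float(stats.binom.pmf(count, size, x))


def initial_distribution(
    init: InitialCondition, grid: FrequencyGrid, pop: PopParams
) -> np.ndarray:
    """Probability vector of the initial frequency over the grid points."""
    k = grid.n
    if init.kind == "fixed":
        w = np.zeros(k)
        j = int(np.searchsorted(grid.points, init.x0))
        if j < k and grid.points[j] == init.x0:
            w[j] = 1.0
        else:  # split the mass linearly between the flanking points
            lo, hi = grid.points[j - 1], grid.points[j]
            frac = (init.x0 - lo) / (hi - lo)
            w[j - 1] = 1.0 - frac
            w[j] = frac
    elif init.kind == "uniform":
        w = grid.cell_widths.copy()
    elif init.kind == "stationary-beta":
        if pop.u01 <= 0.0 or pop.u10 <= 0.0:
            raise ValueError(
                "stationary-beta initial condition requires u01 > 0 and u10 > 0"
            )
        a = 4.0 * pop.Ne * pop.u01
        b = 4.0 * pop.Ne * pop.u10
        cdf = betainc(a, b, grid.cell_edges)
        w = np.diff(cdf)
    else:  # explicit
        w = np.asarray(init.weights, dtype=float)
        if len(w) != k:
            raise ValueError(f"explicit weights have length {len(w)}, grid has {k}")
        if np.any(w < 0):
            raise ValueError("explicit weights must be non-negative")
    total = w.sum()
    if not np.isfinite(total) or total <= 0:
        raise ValueError("initial distribution has no mass")
    if abs(total - 1.0) > _ROW_SUM_TOL:
        w = w / total
    return w


class _ForwardEngine:
    """Shared machinery for (batched) forward passes over one time schedule.

    Emission matrices depend only on the data and grid, so they are computed
    once and reused across selection parameters; transition matrices are
    cached per (fitness, dt) across calls through ``trans_cache``.
    """

    def __init__(
        self,
        loci: Sequence[TemporalSamples],
        pop: PopParams,
        init: InitialCondition,
        grid: FrequencyGrid,
        trans_cache: dict | None = None,
    ):
        if len(loci) == 0:
            raise ValueError("need at least one locus")
        times = loci[0].times
        for loc in loci[1:]:
            if not np.array_equal(loc.times, times):
                raise ValueError("all loci in a batch must share sampling times")
        for t in times:
            _check_generations(t)
        self.times = times.astype(int)
        self.pop = pop
        self.grid = grid
        self.init = initial_distribution(init, grid, pop)
        self.trans_cache = {} if trans_cache is None else trans_cache
        sizes = np.array([loc.sizes for loc in loci])  # (L, T)
        counts = np.array([loc.counts for loc in loci])
        # (T, L, K) binomial emissions; size 0 gives pmf(0; 0, x) = 1
        pts = grid.points[None, None, :]
        self.emissions = stats.binom.pmf(
            counts.T[:, :, None], sizes.T[:, :, None], pts
        )

    def _transition(self, fit: DiploidFitness, dt: int) -> np.ndarray:
        # per-fitness cache of power-of-two kernels plus assembled dts
        powers = self.trans_cache.setdefault((fit.sAa, fit.sAA), {})
        dt = int(dt)
        if dt not in powers:
            if 1 not in powers:
                powers[1] = one_generation_matrix(self.grid, fit, self.pop)
            result = None
            bit = 1
            while bit <= dt:
                if dt & bit:
                    m = _pow2(powers, bit)
                    result = m if result is None else result @ m
                bit <<= 1
            powers[dt] = result
        return powers[dt]

    def log_likelihoods(self, sched: SelectionSchedule) -> np.ndarray:
        """Scaled forward recursion; returns per-locus log-likelihoods."""
        if self.times[0] < sched.epoch_starts[0]:
            raise ValueError(
                f"first sampling time {self.times[0]} precedes schedule start "
                f"{sched.epoch_starts[0]}"
            )
        alpha = self.init[None, :] * self.emissions[0]
        loglik = _rescale(alpha)
        for k in range(1, len(self.times)):
            for dt, fit in sched.segments(self.times[k - 1], self.times[k]):
                dt = _check_generations(dt)
                if dt:
                    alpha = alpha @ self._transition(fit, dt)
            alpha = alpha * self.emissions[k]
            loglik += _rescale(alpha)
        return loglik


def _pow2(powers: dict, p: int) -> np.ndarray:
    if p not in powers:
        half = _pow2(powers, p // 2)
        powers[p] = half @ half
    return powers[p]


def _rescale(alpha: np.ndarray) -> np.ndarray:
    c = alpha.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        np.divide(alpha, c[:, None], out=alpha, where=c[:, None] > 0)
        return np.where(c > 0, np.log(c), -np.inf)


def forward_log_likelihood(
    samples: TemporalSamples,
    sched: SelectionSchedule,
    pop: PopParams,
    init: InitialCondition,
    grid: FrequencyGrid,
) -> float:
    """Log-likelihood of one locus's temporal counts under the HMM."""
    engine = _ForwardEngine([samples], pop, init, grid)
    return float(engine.log_likelihoods(sched)[0])


def batch_log_likelihood(
    loci: Sequence[TemporalSamples],
    sched: SelectionSchedule,
    pop: PopParams,
    init: InitialCondition,
    grid: FrequencyGrid,
    trans_cache: dict | None = None,
) -> np.ndarray:
    """Per-locus log-likelihoods for loci sharing one sampling schedule.

    Identical (to machine precision) to mapping :func:`forward_log_likelihood`
    over ``loci``, but the transition matrices are built once per
    (fitness epoch, dt) and applied to all loci at once.
    """
    engine = _ForwardEngine(loci, pop, init, grid, trans_cache=trans_cache)
    return engine.log_likelihoods(sched)
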