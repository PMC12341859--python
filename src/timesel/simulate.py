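"""Discrete Wright-Fisher simulation of temporal allele-count samples.

Unlike the inference machinery, which approximates frequency dynamics with
Gaussians on a grid, the simulator reproduces the discrete binomial
Wright-Fisher model exactly: each generation the frequency moves to
``B / (2*Ne)`` with ``B ~ Binomial(2*Ne, f(x))`` where ``f`` is one
deterministic generation of selection followed by mutation.  Samples at the
requested times are binomial draws from the population frequency.
Replicates failing the configured filters are redrawn (rejection), so the
output is the conditional distribution given the filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .hmm import FrequencyGrid, InitialCondition, TemporalSamples
from .wf_core import (
    PopParams,
    SelectionSchedule,
    _check_generations,
    deterministic_step,
)

__all__ = ["SimFilters", "SimSpec", "SimResult", "simulate_trajectory", "simulate_samples"]


@dataclass(frozen=True)
class SimFilters:
    """Replicate-retention predicates, applied after sampling.

    ``min_pooled_maf`` keeps replicates whose pooled-sample minor allele
    frequency reaches the threshold; ``pooled_segregating`` requires the
    pooled count to be strictly between 0 and the total sample size;
    ``last_freq_segregating`` requires the population frequency at the last
    sampling time to lie strictly inside (0, 1).
    """

    min_pooled_maf: float | None = None
    pooled_segregating: bool = False
    last_freq_segregating: bool = False

    def __post_init__(self) -> None:
        t = self.min_pooled_maf
        if t is not None and not (0.0 <= t <= 0.5):
            raise ValueError(f"min_pooled_maf must lie in [0, 0.5], got {t}")

    @property
    def active(self) -> bool:
        return (
            self.min_pooled_maf is not None
            or self.pooled_segregating
            or self.last_freq_segregating
        )


@dataclass(frozen=True)
class SimSpec:
    """Full description of a temporal-sampling simulation experiment."""

    pop: PopParams
    sched: SelectionSchedule
    init: InitialCondition
    sample_times: tuple
    sample_sizes: tuple
    n_replicates: int
    seed: int
    keep_trajectories: bool = False
    filters: SimFilters = field(default_factory=SimFilters)
    init_grid: FrequencyGrid | None = None  # for explicit initial weights

    def __post_init__(self) -> None:
        times = tuple(int(_check_generations(t)) for t in self.sample_times)
        sizes = tuple(int(n) for n in self.sample_sizes)
        object.__setattr__(self, "sample_times", times)
        object.__setattr__(self, "sample_sizes", sizes)
        if len(times) != len(sizes):
            raise ValueError("sample_times and sample_sizes must match in length")
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times must be non-decreasing")
        if times and times[0] < self.sched.epoch_starts[0]:
            raise ValueError("sample times precede the schedule start")
        if any(n < 0 for n in sizes):
            raise ValueError("sample sizes must be non-negative")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class SimResult:
    """Retained replicates of a simulation run.

    ``counts`` has one row per retained replicate and one column per
    sampling time; ``trajectories`` (if kept) holds the population frequency
    from the schedule start through the last sampling time.  ``n_attempted``
    counts every replicate drawn, including those rejected by filters.
    """

    counts: np.ndarray
    trajectories: np.ndarray | None
    n_attempted: int
    sample_times: tuple
    sample_sizes: tuple
    seed: int

    def to_temporal_samples(self) -> list[TemporalSamples]:
        return [
            TemporalSamples(
                times=np.array(self.sample_times),
                sizes=np.array(self.sample_sizes),
                counts=row,
                locus_id=f"rep{i}",
            )
            for i, row in enumerate(self.counts)
        ]


def simulate_trajectory(
    x0: float,
    sched: SelectionSchedule,
    pop: PopParams,
    t_end: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """One binomial Wright-Fisher frequency path of length ``t_end + 1``.

    Starts at ``x0`` at the schedule's first epoch start; generation ``t``
    uses the fitness of the epoch containing ``t``.  Absorbing boundaries
    (frequency 0 or 1 with no mutation pushing back) short-circuit the loop.
    """
    t_end = _check_generations(t_end)
    two_ne = int(round(2 * pop.Ne))
    start = sched.epoch_starts[0]
    traj = np.empty(t_end + 1)
    traj[0] = x = float(x0)
    for t in range(t_end):
        if (x == 0.0 and pop.u01 == 0.0) or (x == 1.0 and pop.u10 == 0.0):
            traj[t + 1 :] = x
            break
        p = deterministic_step(x, sched.fitness_at(start + t), pop)
        x = rng.binomial(two_ne, p) / two_ne
        traj[t + 1] = x
    return traj


def _draw_x0(spec: SimSpec, rng: np.random.Generator) -> float:
    init = spec.init
    if init.kind == "fixed":
        return float(init.x0)
    if init.kind == "uniform":
        return float(rng.uniform())
    if init.kind == "stationary-beta":
        pop = spec.pop
        if pop.u01 <= 0 or pop.u10 <= 0:
            raise ValueError("stationary-beta initial condition needs u01, u10 > 0")
        return float(rng.beta(4 * pop.Ne * pop.u01, 4 * pop.Ne * pop.u10))
    if spec.init_grid is None:
        raise ValueError("explicit initial condition requires init_grid")
    w = np.asarray(init.weights, dtype=float)
    w = w / w.sum()
    return float(rng.choice(spec.init_grid.points, p=w))


def _passes(spec: SimSpec, counts: np.ndarray, traj: np.ndarray) -> bool:
    f = spec.filters
    if not f.active:
        return True
    total = sum(spec.sample_sizes)
    pooled = counts.sum()
    if f.pooled_segregating and not (0 < pooled < total):
        return False
    if f.min_pooled_maf is not None:
        if total == 0:
            return False
        freq = pooled / total
        if min(freq, 1.0 - freq) < f.min_pooled_maf:
            return False
    if f.last_freq_segregating:
        x_last = traj[spec.sample_times[-1] - int(spec.sched.epoch_starts[0])]
        if not (0.0 < x_last < 1.0):
            return False
    return True


# rejection sampling aborts when acceptance stays below this rate
_MIN_ACCEPT_RATE = 1e-3
_ABORT_CHECK_FROM = 10_000
_HARD_ATTEMPT_CAP = 1_000_000


def simulate_samples(spec: SimSpec) -> SimResult:
    """Simulate ``spec.n_replicates`` retained replicates of temporal counts.

    Each attempt draws a fresh trajectory and binomial sample counts from a
    dedicated random stream derived from ``spec.seed`` and the attempt
    counter, so results are reproducible regardless of how rejections fall.
    Aborts with a diagnostic if the filter acceptance rate drops below 0.1%.
    """
    start = int(spec.sched.epoch_starts[0])
    t_end = (spec.sample_times[-1] - start) if spec.sample_times else 0
    t_idx = np.array(spec.sample_times, dtype=int) - start
    sizes = np.array(spec.sample_sizes, dtype=int)
    kept_counts: list[np.ndarray] = []
    kept_traj: list[np.ndarray] = []
    attempt = 0
    while len(kept_counts) < spec.n_replicates:
        if attempt >= _ABORT_CHECK_FROM or attempt >= _HARD_ATTEMPT_CAP:
            rate = len(kept_counts) / attempt
            if rate < _MIN_ACCEPT_RATE or attempt >= _HARD_ATTEMPT_CAP:
                raise RuntimeError(
                    f"filter acceptance rate {rate:.2e} after {attempt} attempts; "
                    "filters may be unsatisfiable under these parameters"
                )
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=spec.seed, spawn_key=(attempt,))
        )
        attempt += 1
        x0 = _draw_x0(spec, rng)
        traj = simulate_trajectory(x0, spec.sched, spec.pop, t_end, rng)
        counts = rng.binomial(sizes, traj[t_idx])
        if _passes(spec, counts, traj):
            kept_counts.append(counts)
            if spec.keep_trajectories:
                kept_traj.append(traj)
    return SimResult(
        counts=np.array(kept_counts, dtype=int),
        trajectories=np.array(kept_traj) if spec.keep_trajectories else None,
        n_attempted=attempt,
        sample_times=spec.sample_times,
        sample_sizes=spec.sample_sizes,
        seed=spec.seed,
    )
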