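"""Deterministic Wright-Fisher dynamics under general diploid selection.

The model is a single bi-allelic locus with alleles ``a`` and ``A`` in a
panmictic diploid population of constant effective size ``Ne``.  Genotypes
``aa``, ``aA`` and ``AA`` have relative fitnesses ``1``, ``1 + sAa`` and
``1 + sAA``; recurrent mutation occurs at per-generation rates ``u01``
(a -> A) and ``u10`` (A -> a).  Within one generation selection acts first,
then mutation.  All times are integer generations counted forward from the
start of the analysis.

Selection may change over time in a piece-wise constant manner: a
:class:`SelectionSchedule` assigns one :class:`DiploidFitness` to each epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "PopParams",
    "DiploidFitness",
    "SelectionSchedule",
    "from_s_h",
    "deterministic_step",
    "step_derivative",
    "deterministic_trajectory",
]


@dataclass(frozen=True)
class PopParams:
    """Fixed population parameters of the diffusion.

    Parameters
    ----------
    Ne
        Diploid effective population size (individuals, > 0).
    u01
        Per-generation mutation probability a -> A.
    u10
        Per-generation mutation probability A -> a.
    """

    Ne: float
    u01: float = 0.0
    u10: float = 0.0

    def __post_init__(self) -> None:
        if not self.Ne > 0:
            raise ValueError(f"Ne must be positive, got {self.Ne}")
        for name in ("u01", "u10"):
            u = getattr(self, name)
            if not (0.0 <= u < 1.0):
                raise ValueError(f"{name} must lie in [0, 1), got {u}")


@dataclass(frozen=True)
class DiploidFitness:
    """Relative fitness advantages (1 + sAa, 1 + sAA) of aA and AA genotypes."""

    sAa: float = 0.0
    sAA: float = 0.0

    def __post_init__(self) -> None:
        if 1.0 + self.sAa <= 0.0 or 1.0 + self.sAA <= 0.0:
            raise ValueError(
                f"fitnesses must stay positive: 1+sAa={1 + self.sAa}, "
                f"1+sAA={1 + self.sAA}"
            )

    @property
    def is_neutral(self) -> bool:
        return self.sAa == 0.0 and self.sAA == 0.0


NEUTRAL = DiploidFitness(0.0, 0.0)


def from_s_h(s: float, h: float) -> DiploidFitness:
    """Build a fitness from selection coefficient ``s`` and dominance ``h``.

    Uses the convention ``sAa = h * s`` and ``sAA = s``; ``h = 0.5`` is
    additive (semidominant) selection and ``h = 1`` full dominance.
    """
    return DiploidFitness(sAa=h * s, sAA=s)


@dataclass(frozen=True)
class SelectionSchedule:
    """Piece-wise constant selection over forward time.

    ``epoch_starts[k]`` is the generation at which ``epoch_fitness[k]`` takes
    effect; the first entry marks the start of the analysis and the last
    epoch extends indefinitely.  A selection-onset model is the two-epoch
    special case: neutral from the start, then (h*s, s) from generation t0.
    """

    epoch_starts: tuple[float, ...]
    epoch_fitness: tuple[DiploidFitness, ...]

    def __post_init__(self) -> None:
        starts = tuple(float(t) for t in self.epoch_starts)
        object.__setattr__(self, "epoch_starts", starts)
        object.__setattr__(self, "epoch_fitness", tuple(self.epoch_fitness))
        if len(self.epoch_starts) != len(self.epoch_fitness):
            raise ValueError("need one fitness per epoch")
        if len(self.epoch_starts) == 0:
            raise ValueError("schedule needs at least one epoch")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError(f"epoch_starts must be strictly increasing: {starts}")

    @classmethod
    def constant(cls, fit: DiploidFitness, start: float = 0.0) -> "SelectionSchedule":
        return cls((start,), (fit,))

    @classmethod
    def with_onset(
        cls, fit: DiploidFitness, t0: float, start: float = 0.0
    ) -> "SelectionSchedule":
        """Neutral from ``start``, then ``fit`` from generation ``t0`` on."""
        if t0 <= start:
            return cls((start,), (fit,))
        return cls((start, float(t0)), (NEUTRAL, fit))

    def fitness_at(self, t: float) -> DiploidFitness:
        """Fitness in effect during generation ``t`` (t >= epoch_starts[0])."""
        if t < self.epoch_starts[0]:
            raise ValueError(f"generation {t} precedes schedule start")
        idx = int(np.searchsorted(self.epoch_starts, t, side="right")) - 1
        return self.epoch_fitness[idx]

    def segments(self, t_from: float, t_to: float):
        """Split [t_from, t_to) at epoch boundaries.

        Yields ``(dt, fitness)`` pairs whose dts sum to ``t_to - t_from``.
        """
        if t_to < t_from:
            raise ValueError("t_to must be >= t_from")
        cuts = [t_from]
        cuts += [b for b in self.epoch_starts if t_from < b < t_to]
        cuts.append(t_to)
        for a, b in zip(cuts, cuts[1:]):
            yield b - a, self.fitness_at(a)


def deterministic_step(x, fit: DiploidFitness, pop: PopParams):
    """One generation of deterministic selection followed by mutation.

    Accepts scalars or numpy arrays of frequencies in [0, 1] and returns the
    same shape.  Selection maps ``x`` to the post-selection frequency

        x_sel = [x^2 (1+sAA) + x(1-x)(1+sAa)] / w_bar,
        w_bar = x^2 (1+sAA) + 2 x (1-x)(1+sAa) + (1-x)^2,

    and mutation then gives ``x' = x_sel (1 - u10) + (1 - x_sel) u01``.
    """
    x = np.asarray(x, dtype=float)
    w1 = 1.0 + fit.sAa
    w2 = 1.0 + fit.sAA
    num = x * x * w2 + x * (1.0 - x) * w1
    wbar = x * x * w2 + 2.0 * x * (1.0 - x) * w1 + (1.0 - x) ** 2
    x_sel = num / wbar
    out = x_sel * (1.0 - pop.u10) + (1.0 - x_sel) * pop.u01
    return out if out.ndim else float(out)


def step_derivative(x, fit: DiploidFitness, pop: PopParams):
    """d(deterministic_step)/dx, used to propagate variance along the mean path."""
    x = np.asarray(x, dtype=float)
    w1 = 1.0 + fit.sAa
    w2 = 1.0 + fit.sAA
    num = x * x * w2 + x * (1.0 - x) * w1
    dnum = 2.0 * x * w2 + (1.0 - 2.0 * x) * w1
    wbar = x * x * w2 + 2.0 * x * (1.0 - x) * w1 + (1.0 - x) ** 2
    dwbar = 2.0 * x * w2 + 2.0 * (1.0 - 2.0 * x) * w1 - 2.0 * (1.0 - x)
    dsel = (dnum * wbar - num * dwbar) / (wbar * wbar)
    out = dsel * (1.0 - pop.u01 - pop.u10)
    return out if out.ndim else float(out)


def deterministic_trajectory(
    x0: float,
    sched: SelectionSchedule,
    pop: PopParams,
    t_end: int,
) -> np.ndarray:
    """Iterate :func:`deterministic_step` for ``t_end`` generations.

    Returns an array of length ``t_end + 1`` starting at ``x0``; the fitness
    applied during generation ``t`` is ``sched.fitness_at(t)`` counted from
    the schedule start.
    """
    t_end = _check_generations(t_end)
    t0 = sched.epoch_starts[0]
    traj = np.empty(t_end + 1)
    traj[0] = x0
    x = float(x0)
    for t in range(t_end):
        x = deterministic_step(x, sched.fitness_at(t0 + t), pop)
        traj[t + 1] = x
    return traj


def _check_generations(dt) -> int:
    if dt != int(dt) or dt < 0:
        raise ValueError(f"time must be a non-negative integer number of generations, got {dt}")
    return int(dt)
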