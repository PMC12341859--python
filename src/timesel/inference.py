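"""Likelihood surfaces over selection-parameter grids and derived statistics.

Per-locus log-likelihoods are evaluated on a 1D grid of selection
coefficients ``s`` (with fixed dominance ``h``, so ``sAa = h*s`` and
``sAA = s``) or a 2D grid of ``(sAa, sAA)`` pairs.  1D surfaces are
interpolated with cubic splines to yield off-grid maximum-likelihood
estimates; likelihood-ratio statistics against neutrality (``s = 0``) are
referred to a chi-squared distribution with one degree of freedom.
P-values from independent biological replicates can be combined with
Fisher's method.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.stats import chi2

from .hmm import (
    FrequencyGrid,
    InitialCondition,
    TemporalSamples,
    _ForwardEngine,
    batch_log_likelihood,
)
from .wf_core import DiploidFitness, PopParams, SelectionSchedule, from_s_h

__all__ = [
    "ParamGrid",
    "LikelihoodSurface",
    "MleResult",
    "make_grid",
    "scan_1d",
    "scan_2d",
    "interpolate_mle",
    "lrt_pvalue",
    "estimate_onset",
    "fisher_combine",
]


@dataclass(frozen=True)
class ParamGrid:
    """Definition of one selection-coefficient axis.

    ``spacing`` is ``"linear"`` (evenly spaced between ``bounds``) or
    ``"geometric"`` (log-spaced magnitudes between ``bounds``, with
    ``negative=True`` mirroring the limb to negative values).  ``count`` is
    points per limb; ``include_zero`` inserts 0 exactly once.
    """

    spacing: str = "linear"
    bounds: tuple[float, float] = (-0.1, 0.1)
    count: int = 51
    include_zero: bool = False
    negative: bool = False  # geometric grids only: mirror to a negative limb

    def __post_init__(self) -> None:
        if self.spacing not in ("linear", "geometric"):
            raise ValueError(f"unknown spacing {self.spacing!r}")
        lo, hi = self.bounds
        if not (np.isfinite(lo) and np.isfinite(hi)):
            raise ValueError("grid bounds must be finite")
        if self.count < 1:
            raise ValueError("count must be >= 1")
        if self.spacing == "geometric" and (lo <= 0 or hi < lo):
            raise ValueError("geometric bounds are magnitudes: need 0 < lo <= hi")


def make_grid(spec: ParamGrid) -> np.ndarray:
    """Materialize a :class:`ParamGrid` as an increasing array of values."""
    lo, hi = spec.bounds
    if spec.spacing == "linear":
        vals = np.linspace(lo, hi, spec.count)
        if spec.include_zero and not np.any(vals == 0.0):
            vals = np.sort(np.append(vals, 0.0))
        if lo < 0 < hi and not np.any(vals == 0.0):
            raise ValueError(
                "grid spans 0 without containing it; set include_zero=True"
            )
        return vals
    mags = np.geomspace(lo, hi, spec.count)
    limbs = [mags]
    if spec.negative:
        limbs.append(-mags)
        if not spec.include_zero:
            raise ValueError(
                "geometric grid spanning 0 requires include_zero=True"
            )
    vals = np.concatenate(limbs)
    if spec.include_zero:
        vals = np.append(vals, 0.0)
    return np.unique(vals)


@dataclass
class LikelihoodSurface:
    """Per-locus log-likelihoods over a selection grid.

    For 1D scans ``loglik`` has shape (loci, len(s_values)) and ``h`` is the
    fixed dominance coefficient; for 2D scans it has shape
    (loci, len(sAa_values), len(sAA_values)).  ``neutral_loglik`` holds the
    per-locus value at ``sAa = sAA = 0``.
    """

    loglik: np.ndarray
    neutral_loglik: np.ndarray
    s_values: np.ndarray | None = None
    h: float | None = None
    sAa_values: np.ndarray | None = None
    sAA_values: np.ndarray | None = None
    locus_ids: list | None = None

    @property
    def n_loci(self) -> int:
        return self.loglik.shape[0]


@dataclass(frozen=True)
class MleResult:
    """Maximum-likelihood summary of one locus's 1D likelihood surface."""

    ongrid_mle: float
    offgrid_mle: float
    max_loglik: float
    neutral_loglik: float
    lrt_stat: float
    p_value: float
    interpolated: bool = True


def _neutral_sched() -> SelectionSchedule:
    return SelectionSchedule.constant(DiploidFitness(0.0, 0.0))


def scan_1d(
    loci: Sequence[TemporalSamples],
    s_values,
    h: float,
    pop: PopParams,
    init: InitialCondition,
    grid: FrequencyGrid,
    sched_for=None,
) -> LikelihoodSurface:
    """Log-likelihoods over a 1D grid of ``s`` with fixed dominance ``h``.

    ``sched_for(fit)`` maps each grid fitness to the selection schedule to
    evaluate (default: selection constant from generation of the first
    sample); this hook lets onset models reuse the scan machinery.
    """
    s_values = np.asarray(s_values, dtype=float)
    if sched_for is None:
        sched_for = SelectionSchedule.constant
    engine = _ForwardEngine(loci, pop, init, grid)
    cols = []
    for s in s_values:
        fit = from_s_h(s, h)
        cols.append(engine.log_likelihoods(sched_for(fit)))
        if s != 0.0:  # cap memory: transition kernels are per-fitness
            engine.trans_cache.pop((fit.sAa, fit.sAA), None)
    loglik = np.column_stack(cols) if cols else np.empty((len(loci), 0))
    zero = np.flatnonzero(s_values == 0.0)
    if len(zero):
        neutral = loglik[:, zero[0]].copy()
    else:
        neutral = engine.log_likelihoods(_neutral_sched())
    return LikelihoodSurface(
        loglik=loglik,
        neutral_loglik=neutral,
        s_values=s_values,
        h=h,
        locus_ids=[loc.locus_id for loc in loci],
    )


def scan_2d(
    loci: Sequence[TemporalSamples],
    sAa_values,
    sAA_values,
    pop: PopParams,
    init: InitialCondition,
    grid: FrequencyGrid,
) -> LikelihoodSurface:
    """Log-likelihoods over the outer product of ``sAa`` and ``sAA`` grids."""
    sAa_values = np.asarray(sAa_values, dtype=float)
    sAA_values = np.asarray(sAA_values, dtype=float)
    engine = _ForwardEngine(loci, pop, init, grid)
    loglik = np.empty((len(loci), len(sAa_values), len(sAA_values)))
    for i, saa in enumerate(sAa_values):
        for j, sAA in enumerate(sAA_values):
            fit = DiploidFitness(saa, sAA)
            loglik[:, i, j] = engine.log_likelihoods(
                SelectionSchedule.constant(fit)
            )
            if not fit.is_neutral:
                engine.trans_cache.pop((fit.sAa, fit.sAA), None)
    neutral = engine.log_likelihoods(_neutral_sched())
    return LikelihoodSurface(
        loglik=loglik,
        neutral_loglik=neutral,
        sAa_values=sAa_values,
        sAA_values=sAA_values,
        locus_ids=[loc.locus_id for loc in loci],
    )


def _ongrid_argmax(s_values: np.ndarray, ll: np.ndarray) -> int:
    """Argmax with ties broken toward small |s|, then the negative sign."""
    best = np.flatnonzero(ll == ll.max())
    if len(best) == 1:
        return int(best[0])
    order = sorted(best, key=lambda j: (abs(s_values[j]), s_values[j]))
    return int(order[0])


def interpolate_mle(surface: LikelihoodSurface, locus: int = 0) -> MleResult:
    """On- and off-grid MLE of ``s`` for one locus of a 1D surface.

    The off-grid estimate maximizes a cubic-spline interpolant of the
    log-likelihood over the grid's range; when the on-grid maximum sits on a
    boundary node the off-grid estimate falls back to it.
    """
    if surface.s_values is None:
        raise ValueError("off-grid interpolation is defined for 1D surfaces only")
    s = surface.s_values
    ll = surface.loglik[locus]
    j = _ongrid_argmax(s, ll)
    ongrid = float(s[j])
    neutral = float(surface.neutral_loglik[locus])
    if len(s) < 3:
        warnings.warn("fewer than 3 grid points; off-grid MLE equals on-grid")
        return _finish(ongrid, ongrid, float(ll[j]), neutral, interpolated=False)
    if j == 0 or j == len(s) - 1:
        return _finish(ongrid, ongrid, float(ll[j]), neutral)
    spline = CubicSpline(s, ll)
    crit = spline.derivative().roots(extrapolate=False)
    crit = crit[np.isreal(crit)].real
    cand = np.concatenate([crit, [ongrid]])
    cand = np.clip(cand, s[0], s[-1])
    vals = spline(cand)
    k = int(np.argmax(vals))
    offgrid = float(cand[k])
    max_ll = float(max(vals[k], ll[j]))  # never below the on-grid maximum
    return _finish(ongrid, offgrid, max_ll, neutral)


def _finish(ongrid, offgrid, max_ll, neutral, interpolated=True) -> MleResult:
    stat, p = lrt_pvalue(max_ll, neutral)
    return MleResult(
        ongrid_mle=ongrid,
        offgrid_mle=offgrid,
        max_loglik=max_ll,
        neutral_loglik=neutral,
        lrt_stat=stat,
        p_value=p,
        interpolated=interpolated,
    )


def lrt_pvalue(max_loglik: float, neutral_loglik: float) -> tuple[float, float]:
    """Likelihood-ratio statistic against neutrality and its chi2(1) p-value.

    The statistic ``2*(max_loglik - neutral_loglik)`` is floored at 0 (tiny
    negative values can arise from interpolation).
    """
    stat = max(0.0, 2.0 * (max_loglik - neutral_loglik))
    return stat, float(chi2.sf(stat, df=1))


def estimate_onset(
    loci,
    onset_grid,
    s_grid,
    h: float,
    pop: PopParams,
    init: InitialCondition,
    grid: FrequencyGrid,
    start: float | None = None,
):
    """Joint grid search over selection onset time t0 and coefficient s.

    Selection is 0 before t0 and ``(h*s, s)`` afterwards.  Returns
    ``(t0_hat, s_hat, surface)`` where ``surface`` has shape
    (loci, onsets, s values) and the estimates are the marginal coordinates
    of the per-locus joint argmax.  Accepts a single :class:`TemporalSamples`
    (returning scalars) or a batch (returning arrays).
    """
    single = isinstance(loci, TemporalSamples)
    batch = [loci] if single else list(loci)
    onset_grid = np.asarray(onset_grid, dtype=float)
    s_grid = np.asarray(s_grid, dtype=float)
    if start is None:
        start = float(batch[0].times[0])
    if np.any(onset_grid < start):
        raise ValueError("onset candidates must not precede the first sample")
    engine = _ForwardEngine(batch, pop, init, grid)
    surf = np.empty((len(batch), len(onset_grid), len(s_grid)))
    # s in the outer loop so each fitness's kernels are built once and freed
    for b, s in enumerate(s_grid):
        fit = from_s_h(s, h)
        for a, t0 in enumerate(onset_grid):
            sched = SelectionSchedule.with_onset(fit, t0, start=start)
            surf[:, a, b] = engine.log_likelihoods(sched)
        if not fit.is_neutral:
            engine.trans_cache.pop((fit.sAa, fit.sAA), None)
    flat = surf.reshape(len(batch), -1)
    idx = flat.argmax(axis=1)
    a_idx, b_idx = np.unravel_index(idx, (len(onset_grid), len(s_grid)))
    t0_hat = onset_grid[a_idx]
    s_hat = s_grid[b_idx]
    if single:
        return float(t0_hat[0]), float(s_hat[0]), surf[0]
    return t0_hat, s_hat, surf


_P_FLOOR = 1e-300


def fisher_combine(p_values) -> float:
    """Combine independent p-values with Fisher's method.

    ``-2 * sum(log p)`` is referred to a chi-squared distribution with
    ``2k`` degrees of freedom.  Zero p-values are floored at 1e-300 with a
    warning.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if np.any(p == 0):
        warnings.warn(f"zero p-values floored at {_P_FLOOR}")
        p = np.maximum(p, _P_FLOOR)
    stat = -2.0 * np.log(p).sum()
    return float(chi2.sf(stat, df=2 * p.size))
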