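"""Standard synthetic study designs for power, calibration and recovery.

These are the package's reference benchmark conditions: a population of
diploid effective size 10,000 with symmetric recurrent mutation at 1e-6 and
nine temporal samples taken every 500 generations (generations 0 through
4,000).  Twenty diploid individuals (40 haploids) are sampled per time
point in the power/recovery design, fifty (100 haploids) in the
onset-estimation design.  The focal allele is standing variation: its
frequency at the first sampling time is drawn uniformly on (0, 1), and
inference uses the matching uniform initial distribution.  Replicates are
retained only if the pooled sample segregates; the onset study additionally
requires pooled minor-allele frequency >= 5%, since it concerns sweeps
strong enough to be detected at all.

Inference on these designs uses the default frequency grid and a 51-point
linear grid of s on [-0.05, 0.05] with dominance fixed at the simulated
value.
"""

from __future__ import annotations

import numpy as np

from .hmm import InitialCondition, build_grid
from .inference import interpolate_mle, scan_1d
from .simulate import SimFilters, SimSpec, SimResult, simulate_samples
from .wf_core import PopParams, SelectionSchedule, from_s_h

NE = 10_000.0
U = 1e-6
SAMPLE_TIMES = tuple(range(0, 4001, 500))
N_HAPLOIDS = 40
ONSET_N_HAPLOIDS = 100
S_GRID = np.linspace(-0.05, 0.05, 51)


def benchmark_pop() -> PopParams:
    return PopParams(Ne=NE, u01=U, u10=U)


def simulate_design(
    s: float,
    h: float,
    n_replicates: int,
    seed: int,
    n_haploids: int = N_HAPLOIDS,
    onset: float | None = None,
    filters: SimFilters | None = None,
    keep_trajectories: bool = False,
) -> SimResult:
    """Simulate replicates of the standard temporal-sampling design."""
    fit = from_s_h(s, h)
    if onset is None:
        sched = SelectionSchedule.constant(fit, start=SAMPLE_TIMES[0])
    else:
        sched = SelectionSchedule.with_onset(fit, onset, start=SAMPLE_TIMES[0])
    if filters is None:
        filters = SimFilters(pooled_segregating=True)
    spec = SimSpec(
        pop=benchmark_pop(),
        sched=sched,
        init=InitialCondition.uniform(),
        sample_times=SAMPLE_TIMES,
        sample_sizes=(n_haploids,) * len(SAMPLE_TIMES),
        n_replicates=n_replicates,
        seed=seed,
        keep_trajectories=keep_trajectories,
        filters=filters,
    )
    return simulate_samples(spec)


def scan_design(loci, h: float = 0.5, s_values=None, n_interior: int = 500):
    """1D selection scan of benchmark replicates with the uniform prior."""
    if s_values is None:
        s_values = S_GRID
    return scan_1d(
        loci,
        s_values,
        h,
        benchmark_pop(),
        InitialCondition.uniform(),
        build_grid(n_interior),
    )


def mles_and_pvalues(surface):
    """Off-grid MLEs, LRT statistics and p-values for every locus of a scan."""
    res = [interpolate_mle(surface, i) for i in range(surface.n_loci)]
    return (
        np.array([r.offgrid_mle for r in res]),
        np.array([r.lrt_stat for r in res]),
        np.array([r.p_value for r in res]),
    )
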