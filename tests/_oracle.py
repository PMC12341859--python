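"""Independent brute-force oracle: the exact discrete Wright-Fisher HMM.

States are the 2N+1 possible allele counts in the population; transitions
are exact binomial reproduction probabilities and emissions exact binomial
sampling probabilities.  Feasible only for small Ne, which is precisely why
it serves as the reference for the grid/Gaussian implementation.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from timesel.wf_core import DiploidFitness, PopParams, SelectionSchedule, deterministic_step


def exact_wf_log_likelihood(
    samples,
    fit: DiploidFitness,
    pop: PopParams,
    init,
) -> float:
    """Forward log-likelihood under the exact 2N+1-state Wright-Fisher HMM.

    ``init`` is either a float (point mass at the nearest count state) or a
    vector of length 2N+1.
    """
    two_ne = int(round(2 * pop.Ne))
    xs = np.arange(two_ne + 1) / two_ne
    f = deterministic_step(xs, fit, pop)
    t1 = stats.binom.pmf(np.arange(two_ne + 1)[None, :], two_ne, f[:, None])
    if np.isscalar(init):
        alpha = np.zeros(two_ne + 1)
        alpha[int(round(init * two_ne))] = 1.0
    else:
        alpha = np.asarray(init, dtype=float).copy()
    times = samples.times.astype(int)
    sizes, counts = samples.sizes, samples.counts
    ll = 0.0
    alpha = alpha * stats.binom.pmf(counts[0], sizes[0], xs)
    c = alpha.sum()
    ll += np.log(c)
    alpha /= c
    powers: dict[int, np.ndarray] = {}
    for k in range(1, len(times)):
        dt = times[k] - times[k - 1]
        if dt not in powers:
            powers[dt] = np.linalg.matrix_power(t1, dt)
        alpha = alpha @ powers[dt]
        alpha = alpha * stats.binom.pmf(counts[k], sizes[k], xs)
        c = alpha.sum()
        ll += np.log(c)
        alpha /= c
    return float(ll)
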