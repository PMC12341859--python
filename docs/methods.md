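# Methods

## Model

`timesel` analyzes a single biallelic locus in a panmictic diploid
population of constant effective size `Ne` (individuals). The focal allele
`A` (by convention the ALT allele of a VCF, or the counted allele of a
count table) has population frequency `x`. One generation applies
selection, then mutation:

```
x_sel = [x²(1+sAA) + x(1−x)(1+sAa)] / [x²(1+sAA) + 2x(1−x)(1+sAa) + (1−x)²]
x'    = x_sel (1 − u10) + (1 − x_sel) u01
```

Genotype fitnesses are `1 : 1+sAa : 1+sAA` for `aa : aA : AA`; both must be
positive. The `(s, h)` parametrization maps to `sAa = h·s`, `sAA = s`.
Selection may be piece-wise constant over time (`SelectionSchedule`), with
the two-epoch "onset" model (neutral before `t0`, selected after) as the
common special case. Time is measured in integer generations, forward from
the analysis start; calendar-to-generation conversion is the caller's
responsibility. The order *selection then mutation* within a generation is
a documented convention; the alternative order differs at `O(u·s)` per
generation, far below every tolerance used here.

## Hidden Markov model

Hidden states are population frequencies on a grid: `n_interior` uniformly
spaced interior points (default 500) plus dedicated boundary states at
exactly 0 and 1; each state owns the cell between the midpoints to its
neighbours, so the cells tile [0, 1]. An optional geometric refinement
ladder adds states near the boundaries.

**Transitions.** The one-generation kernel from state `x` has mean
`f(x)` (the deterministic map above) and variance `f(x)(1−f(x))/(2Ne)`,
the binomial reproduction variance. For rows whose expected allele count
is at least 20 copies away from both boundaries, the Gaussian with these
moments is integrated over each grid cell, with the tail mass beyond
[0, 1] collected into the boundary states (absorption is real under
drift, so the mass is kept, not discarded). Within 20 copies of a
boundary the offspring-count distribution is Poisson-like and strongly
skewed, and a Gaussian badly misjudges the per-generation loss/fixation
probability; those rows instead place the exact `Binomial(2Ne, f(x))`
atoms on the grid, splitting each atom linearly between its two flanking
grid points (which preserves the mean). Zero-variance rows degenerate to
a point mass on the cell containing the mean. Transitions over `dt`
generations are the `dt`-th matrix power of this kernel, computed by
binary exponentiation with cached squarings, so probability re-absorbs at
the boundaries every generation; intervals spanning epoch boundaries
compose the per-epoch powers. The threshold of 20 copies and the
composition-by-power construction were chosen by validation against the
exact `2N+1`-state discrete Wright–Fisher HMM at `Ne = 100` (see below):
a single Gaussian per sampling interval errs by more than one log-unit in
that regime, per-generation Gaussians without the exact boundary rows by
up to ~0.13, and the final construction by ≤ ~0.06 across 600 tested
configurations.

A closed-form moment API (`gaussian_moments`) propagates mean and
variance over `dt` generations by the linearized law-of-total-variance
recursion

```
v[g+1] = v[g]·f'(m[g])²·(1 − 1/(2Ne)) + m[g+1](1 − m[g+1])/(2Ne)
```

whose neutral solution is the exact Wright–Fisher variance
`x(1−x)(1 − (1 − 1/(2Ne))^dt)`.

**Emissions.** At each sampling time, `count ~ Binomial(size, x)` with
`size` the number of sampled haploid genomes: a diploid genotype
contributes 2 draws, a pseudo-haploid genotype 1 draw, missing data 0
draws (emission 1).

**Initial condition.** The distribution of `x` at the *first sampling
time*: a point mass (`fixed`, interpolated linearly between flanking grid
points when off-grid, which preserves the mean), `uniform` (mass
proportional to cell widths), the mutation–drift stationary density
`Beta(4·Ne·u01, 4·Ne·u10)` integrated per cell (requires both rates
positive), or an explicit weight vector.

**Forward algorithm.** Standard per-step rescaling (sums of log scale
factors), vectorized across all loci that share a sampling schedule; the
emission tensor is computed once per data set and the transition kernels
once per (fitness, `dt`) pair, then reused across loci and parameter-grid
values. Sampling times must be integers in generations; non-integer
intervals are rejected rather than silently rounded, because the model is
defined by the per-generation recursion.

## Inference

Log-likelihoods are evaluated on a linear or geometric grid of `s` with
fixed `h` (1D) or on the outer product of `sAa`/`sAA` grids (2D).
Off-grid MLEs interpolate the 1D surface with a natural cubic spline
(`not-a-knot`): the spline's critical points are found exactly from its
derivative, clamped to the grid range, and compared with the best grid
node, so a quadratic surface is reproduced to machine precision and the
reported maximum is never below the on-grid maximum. Off-grid estimation
is restricted to 1D sections; 2D surfaces report on-grid maxima only.
When the on-grid argmax is a boundary node the off-grid estimate falls
back to it (extrapolation beyond the grid is never attempted). Ties at
equal grid maxima resolve toward the smaller |s|, then the negative sign
— conservative toward neutrality and deterministic.

The likelihood-ratio statistic `2(ℓ̂ − ℓ₀)` against neutrality is floored
at 0 (spline interpolation can yield tiny negative differences) and
referred to χ²(1); this applies to the 1D scan, which has one free
parameter. Fisher's method combines independent replicate p-values via
`−2Σ ln p ~ χ²(2k)`; exact zeros are floored at 1e-300 with a warning.
Onset estimation evaluates the likelihood on an `onset × s` grid of
two-epoch schedules and reports the marginal coordinates of the joint
argmax, without profile smoothing.

## Simulator

The simulator is deliberately *not* the Gaussian approximation: each
generation draws `B ~ Binomial(2Ne, f(x))` and sets `x' = B/(2Ne)`, the
exact discrete Wright–Fisher model, so that inference and simulation are
independent model realizations and recovery tests are meaningful. Counts
at the sampling times are binomial draws from the trajectory. Replicate
filters (pooled-sample segregation, pooled minor-allele frequency
threshold, final population frequency strictly inside (0,1)) are applied
by rejection, so the output is explicitly the conditional distribution
given the filter; `n_attempted` records the total draws. Each attempt
uses a dedicated random stream derived from the root seed and the attempt
counter, making results bit-reproducible and independent of batching.
If the acceptance rate stays below 0.1% (checked from 10,000 attempts
on), the run aborts with a diagnostic rather than looping forever.

## Benchmark designs

The statistical properties quoted in the README are measured on standard
synthetic designs (`timesel.benchmark`), chosen once as realistic
mid-scale study conditions:

- `Ne = 10,000`, `u01 = u10 = 1e-6`; nine sampling times at generations
  0, 500, …, 4000; 40 haploids per time (100 in the onset design).
- The focal allele is standing variation: its frequency at the first
  sampling time is uniform on (0, 1), and inference uses the matching
  uniform initial distribution. Replicates must segregate in the pooled
  sample; the onset design additionally requires pooled MAF ≥ 5%,
  because onset timing is only meaningful for sweeps strong enough to be
  detected. A fixed low starting frequency (e.g. 1%) was considered and
  rejected for the calibration design: nearly all neutral replicates then
  carry 0–2 observed copies, a regime where the χ²(1) reference is
  severely conservative for any likelihood implementation.
- Inference scans a 51-point linear grid of `s` on [−0.05, 0.05] with
  `h` fixed at the simulated value; onset candidates are every 250
  generations with a 10-point `s` grid spanning 0.001–0.05.

Problem sizes (1,000 neutral replicates for calibration, 200 for
recovery/power, 100 for onset, 20 random count configurations per
scenario for the exact-HMM comparison) are the package's own benchmark
choices, balancing statistical resolution against a few minutes of
single-core runtime.

What the generator does **not** emulate: linkage between loci, genotyping
error and reference bias in aDNA, pool-sequencing depth noise in E&R
data, demographic change, or variable generation times. Passing
benchmarks therefore demonstrate correctness of the likelihood machinery
under the model's own assumptions, not robustness to their violation on
real data.

## Numerical choices and limitations

- Row-stochasticity of every transition kernel is asserted at
  construction (tolerance 1e-9 on row sums, entries non-negative).
- Likelihoods can be −inf only for data that are impossible under a
  degenerate (point-mass) initial condition; with any mutation or spread
  in the initial condition they are finite.
- The frequency grid cannot resolve frequencies below the first interior
  point (2e-3 by default); at very large `Ne` the fate of single-copy
  alleles is therefore aggregated into the boundary region. The optional
  boundary refinement ladder mitigates this when needed.
- Constant `Ne` and constant mutation rates are assumed throughout;
  population-size histories are out of scope.
- Multiple-testing correction, confidence intervals and Bayesian
  posteriors are out of scope; users apply their own genome-wide
  procedures to the per-locus p-values.
- The VCF reader takes the ALT allele as focal and applies no
  ancestral-allele polarization; pre-polarize if derived-allele
  orientation matters. Coordinates are reported 1-based as read.
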