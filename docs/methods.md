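# Methods

This note records the models implemented in `odfpeaks`, the defaults chosen
where a design was genuinely open, and the limits of what the synthetic
benchmark can show.

## Spherical parameterization

All angular quantities use azimuth `theta` measured in the x-y plane from
+x, and elevation `phi` measured from that plane toward +z, so
`(theta, phi) = (0, 0)` is the +x axis and
`u = (cos phi cos theta, cos phi sin theta, sin phi)`. Angles wrap as
`theta mod 2 pi`; a step across a pole reflects the elevation
(`phi -> pi - phi`) and shifts the azimuth by `pi`, which is the identity on
the underlying unit vector. The azimuth of a pole vector is defined as 0.
Orientations are projective (an ODF satisfies `psi(u) = psi(-u)`); reported
peaks use the representative with `v_z > 0` (ties: `v_y > 0`, then `+x`),
and all peak-to-peak distances are antipodal arcs `arccos |u . v|`.

## Sphere sampling and interpolation

Evaluation meshes are spherical Fibonacci lattices (area-uniform in `z`,
azimuth stepped by the golden angle), triangulated by their convex hull —
deterministic, available at any vertex count `n >= 4`, with 724 vertices as
the default working resolution and 2562 for dense oracle scans. Because the
lattice is equal-area, quadrature uses equal weights `4 pi / n`; on a
general mesh the fallback is one third of the incident spherical triangle
areas per vertex. Sample fields are interpolated by locating the enclosing
triangle of the query's central projection (brute force over the candidate
triangles around the nearest vertex) and taking either the nearest vertex's
value or the barycentric average.

## Multi-tensor phantom

A phantom voxel is a mixture of Gaussian compartments with volume fractions
summing to one. Signals follow
`S(g, b) = S0 sum_i f_i exp(-b g^T D_i g)`; the default acquisition is one
`b = 0` volume plus 64 Fibonacci-distributed directions at
`b = 3000 s/mm^2`. Default tensor eigenvalues are
`(1.7, 0.3, 0.3) x 10^-3 mm^2/s` — typical deep-white-matter diffusivities,
giving realistic attenuation at `b = 3000` and an ODF peak-to-perpendicular
ratio of `(1.7/0.3)^{3/2} ≈ 13.5`; they are configurable. The benchmark
voxels place one fiber along `(0, 0)`, two fibers at `(0, 0)` and
`(1.22, 0)` (69.9 degrees apart), and three fibers adding `(0.52, 1.05)`,
with equal fractions (nominal fractions of 0.33 are renormalized to sum
exactly to one).

The exact solid-angle ODF of the mixture (radial second-moment projection
of the Gaussian propagator; the `r^2` Jacobian gives the `-3/2` exponent) is

    psi(u) = (1 / 4 pi) sum_i f_i det(D_i)^{-1/2} (u^T D_i^{-1} u)^{-3/2},

which integrates to one exactly; sampled fields are additionally rescaled
so the mesh-quadrature integral is exactly one.

Rician noise follows the standard magnitude-MRI convention
`sqrt((S + n1)^2 + n2^2)` with independent Gaussian channels of standard
deviation `sigma = S0 / SNR`; the benchmark noise level is SNR = 20. All
draws are seeded.

### What the phantom does not emulate

No non-Gaussian compartments (ball, stick, kurtosis), no partial-volume CSF
or exchange, no spatial correlation between voxels, no eddy-current or
motion artifacts, and an idealized scheme rather than a scanner's
electrostatic-repulsion table. Passing the benchmark therefore demonstrates
the optimizer's correctness on realistic ODF shapes and noise levels, not
end-to-end fidelity on clinical data.

## ODF reconstruction

Signals are represented on the real, even-order, symmetric spherical-
harmonic basis (order 8, 45 coefficients — high enough to resolve small
crossing angles). Fits are regularized least squares with a
Laplace-Beltrami penalty `lambda ||diag(l(l+1)) c||^2`; `lambda = 0.006`,
the standard value in the analytic q-ball literature. Two single-shell
reconstructions are provided:

- **QBI**: the Funk-Radon transform applied coefficient-wise,
  `c' = 2 pi P_l(0) c`, to the SH fit of `E = S/S0`.
- **CSA-QBI**: `E` clamped into `[delta, 1 - delta]` (`delta = 1e-3`), SH
  fit of `ln(-ln E)`, then
  `ODF = 1/(4 pi) - (1/(16 pi^2)) 2 pi P_l(0) l (l+1) c_lm` for `l >= 2`.

ODF samples are min-max normalized to `[0, 1]` before thresholding, because
the peak threshold `P = 0.02` is expressed in normalized ODF units;
normalization to unit integral is available separately. A log-linear tensor
fit supplies FA (mask threshold 0.20 for white matter in volume pipelines).
The diffusion orientation transform (DOT) is not implemented; QBI, CSA-QBI
and the analytic phantom ODF provide the three objective surfaces used.

## Hybrid optimizer

Defaults are the reference parameter set: swarm `N = 100`, inertia
`omega(k)` decaying linearly from 0.2 to 0.1 over `t_max = 120` iterations,
cognitive factor `c1 = 0.5`, social factor `c2 = 0`, transfer/peak
threshold `P = 0.02`, at most `M = 20` hybrid rounds.

Choices made where the design was open:

- **Transfer tolerance.** `Tolerance_PSO(k)` is the swarm-mean improvement
  of personal-best fitness during iteration `k`; the Powell stage starts
  once it drops below `P`. Under this definition the derandomized swarm
  (whose particles only contract toward their own trajectory's best point)
  typically transfers within a few iterations, so the swarm's main role is
  seeded stratified multistart for the Powell stage. Alternative tolerance
  definitions can be plugged in.
- **Velocity initialization.** Velocities are drawn uniformly from
  `[-0.3, 0.3]^2` rad/iteration. A zero-velocity swarm would be a fixed
  point of the update `V' = omega V + c1 (P_id - X)` (positions start equal
  to personal bests), freezing the global stage entirely; a small random
  velocity lets each particle sweep a short decaying trajectory.
- **Powell details.** The modified scheme's direction-retention inequality
  is applied on the negated objective (the direction-set formulas are
  written for minimization); a strict classical (Numerical Recipes)
  criterion is available as `direction_update="classical"`. The max-drop index is taken
  over the `D` axis line searches of the cycle. Step tolerance
  `epsilon = 1e-5` rad, cycle cap 100.
- **Line search.** Outward geometric bracketing from the current point
  (first-decrease stopping) plus bounded parabolic/golden refinement to
  1e-6 rad, domain `[-pi, pi]` per step, ties broken toward a zero step. The
  first-decrease rule confines each search to its local basin — a global
  line scan would funnel every start into the global maximum and lose
  secondary fibers under noise.
- **Powell starts.** The local stage starts from every particle's personal
  best (dominant over current positions under the derandomized update).
- **Saddle guard.** A converged candidate is accepted only if its value is
  within 1e-9 of the maximum over 8 probe points 0.5 degrees around it;
  sequential line searches can in principle stall on a saddle.
- **Peak merging.** Antipodal deduplication at 10 degrees (configurable);
  the higher ODF value wins.
- **Early exit.** Rounds stop after 3 consecutive rounds that add no new
  extremum (set `early_exit_rounds=0` to force all `M` rounds).
- **Objective modes.** The optimizer maximizes any continuous function on
  the sphere: closed-form analytic ODFs, SH evaluation, or interpolated
  samples. Nearest-neighbor interpolation makes the objective piecewise
  constant — line searches then stall on plateaus and peaks snap to sample
  directions — so the continuous modes (SH, analytic, barycentric) are the
  defaults and nearest-neighbor must be requested explicitly.

Determinism: the entire pipeline is a pure function of
`(objective, params, seed)`; per-round swarm draws derive from a single
seed sequence.

## Evaluation harness

Recovered peaks are matched one-to-one to ground truth by minimizing total
antipodal arc (Hungarian assignment, identical to exhaustive enumeration at
these sizes); pairs farther than 20 degrees count as missed/spurious. Per
matched fiber the harness reports the azimuth and elevation deviations in
radians (reduced under the antipodal equivalence, azimuth additionally
modulo pi) and the antipodal arc in degrees. A recovery is a *success* when
the found count equals the true count and all matched arcs are within the
threshold. The independent oracle is a dense-mesh (2562-vertex) strict
1-ring local-maxima scan with the same antipodal deduplication.

The factorial benchmark runs {1, 2, 3}-fiber voxels x {analytic, QBI,
CSA-QBI} x {noiseless, SNR 20} x repetitions, all seeded, and emits a tidy
CSV. Problem sizes used throughout the validation suite: 724-vertex
objective meshes, 2562-vertex oracle meshes, 64-direction schemes, 50
random phantoms for the oracle-equivalence study and 100 noise seeds for
the robustness study.

## Known limitations

- QBI's Funk-Radon smoothing biases crossing-fiber maxima toward each other
  by a few degrees at a 69.9-degree crossing; this is a property of the
  transform, not the optimizer (the CSA and analytic routes are sharper).
- With ~400 Powell starts per voxel the method is seconds-per-voxel in pure
  Python; volume pipelines are practical for ROIs, not whole brains.
- The derandomized PSO stage contributes stratified restarts rather than
  genuine swarm dynamics under the implemented transfer tolerance (see
  above); all quantitative results are driven by the multistart Powell
  stage.
- Peak count equality with the dense-grid oracle can fail when an ODF
  maximum sits exactly between mesh vertices of the oracle, or when two
  lobes merge near the minimum separation; the validation suite tolerates
  2 such cases in 50.
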