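# odfpeaks

Extraction of white-matter fiber orientations from diffusion MRI orientation
distribution functions (ODFs), built around a **derandomized particle-swarm +
modified Powell hybrid optimizer** that finds *all* local maxima of a
spherical function.

## The problem

In high angular resolution diffusion imaging (HARDI), the ODF
`psi(theta, phi)` describes the probability that water diffuses into each
solid angle; its local maxima align with the axon bundles crossing a voxel.
Reliable tractography therefore needs every ODF maximum — not just the
global one — located accurately, at every voxel, without derivatives (the
ODF is often only known through interpolated samples or a spherical-harmonic
fit). `odfpeaks` treats this as multimodal maximization on the unit sphere,
parameterized by azimuth `theta` and elevation `phi`.

## The method

The hybrid search alternates two stages, up to `M = 20` rounds:

1. **Derandomized PSO (global stage).** A swarm of `N = 100` particles is
   drawn area-uniformly on the sphere. The velocity update drops both
   `rand()` factors and the social term (`c2 = 0`):

   `V' = omega(k) V + c1 (P_id - X)`, `X' = X + V'`

   with `c1 = 0.5` and inertia `omega` decaying linearly from 0.2 to 0.1
   over at most `t_max = 120` iterations. Each particle contracts onto the
   best point of its own trajectory (`P_id`). When the swarm-mean
   personal-best improvement drops below `P = 0.02` (normalized ODF units),
   the local stage takes over.
2. **Modified Powell search (local stage).** From every particle's personal
   best, a derivative-free direction-set search runs sequential line
   maximizations along `(theta, phi)` axes, tests the composite step
   `d_D = x_D - x_0` against the step tolerance `epsilon`, and replaces the
   max-drop direction by `d_D` when the direction-retention inequality fails.
   Line searches bracket outward from the current point and refine by
   bounded parabolic/golden interpolation to 1e-6 rad, staying inside the
   current local basin.

Converged extrema are verified as spherical local maxima, merged into an
**extreme set** with antipodal deduplication (orientations are projective:
`psi(u) = psi(-u)`), and the swarm is reinitialized for the next round.
Finally, peaks whose ODF value falls below the spherical mean, or whose
normalized value falls below `P`, are discarded as noise ripples.

Around the optimizer the package provides:

- **Phantom simulation** — multi-tensor signals
  `S/S0 = sum_i f_i exp(-b g^T D_i g)` at `b = 3000 s/mm^2` over 64
  quasi-uniform directions, Rician noise at a chosen SNR, and the exact
  solid-angle ODF of a Gaussian mixture,
  `psi(u) ∝ sum_i f_i det(D_i)^{-1/2} (u^T D_i^{-1} u)^{-3/2}`.
- **ODF reconstruction** — order-8 real symmetric spherical harmonics, the
  analytic Funk-Radon transform (QBI, multipliers `2 pi P_l(0)`), the
  constant-solid-angle variant (CSA-QBI), and a log-linear tensor fit with
  FA for white-matter masking.
- **Evaluation** — optimal peak-to-truth matching and azimuth / elevation /
  arc deviation reports, plus a dense-mesh brute-force peak oracle.
- **I/O and CLI** — NIfTI volumes, FSL-dialect bval/bvec, text configs.

## Worked example

```python
import odfpeaks as op

mesh = op.even_sphere(724)                      # quasi-uniform directions
phantom = op.benchmark_phantoms()[1]               # 2 fibers at (0,0) and (1.22,0) rad
objective = op.objective_from(phantom, mode="analytic", mesh=mesh)
peaks = op.hybrid_find_peaks(objective, op.HybridParams(seed=1))
for p in peaks:
    theta, phi = op.unit_to_sph(p.direction)
    print(f"theta={theta:.4f} phi={phi:.4f} normalized={p.normalized_value:.3f}")
```

prints

```
theta=0.0056 phi=0.0000 normalized=1.014
theta=4.3560 phi=0.0000 normalized=1.014
```

— two peaks, on the canonical hemisphere, whose orientations are
`theta = 0.0056` and `theta = 4.3560 - pi = 1.2144` rad after antipodal
reduction: the two crossing fibers recovered to a fraction of a degree (the
residual ~0.3 degree offset is the genuine shift of the mixture ODF's
maxima toward each other, not an optimizer error).

The same pipeline from the shell:

```sh
odfpeaks simulate --fibers 2 --out dwi.nii --seed 1
odfpeaks reconstruct --dwi dwi.nii --bval dwi.bval --bvec dwi.bvec --method qbi --out sh.nii
odfpeaks peaks --sh sh.nii --out-csv peaks.csv --seed 2
odfpeaks evaluate --peaks-csv peaks.csv --truth-config dwi.phantom.cfg --out deviations.csv
odfpeaks demo --outdir demo --noise none        # full 1/2/3-fiber benchmark
```

## Documentation

See `docs/methods.md` for the model, parameter defaults, numerical choices
and known limitations.
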