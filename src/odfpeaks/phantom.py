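"""Multi-tensor HARDI phantoms: signal synthesis, Rician noise and exact ODFs.

A phantom voxel is a mixture of Gaussian diffusion tensors.  The diffusion
signal on a single shell follows the multi-tensor decay
``S(g)/S0 = sum_i f_i exp(-b g^T D_i g)`` and the corresponding solid-angle
orientation distribution function has the closed form

    psi(u) = (1 / 4 pi) sum_i f_i det(D_i)^{-1/2} (u^T D_i^{-1} u)^{-3/2},

which integrates to one over the sphere.  These exact ODFs are the ground
truth against which reconstruction and peak extraction are validated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .sphere import SphereMesh, SphericalSamples, sph_to_unit

__all__ = [
    "WM_EIGENVALUES",
    "AcquisitionScheme",
    "TensorCompartment",
    "PhantomConfig",
    "NoiseSpec",
    "default_scheme",
    "benchmark_phantoms",
    "random_phantom",
    "simulate_signal",
    "add_rician",
    "analytic_odf",
    "analytic_odf_func",
]

#: Default single-fiber tensor eigenvalues, mm^2/s: typical deep white matter.
WM_EIGENVALUES = (1.7e-3, 0.3e-3, 0.3e-3)


@dataclass(frozen=True)
class AcquisitionScheme:
    """Single- or multi-shell gradient scheme (b-values in s/mm^2, unit gradients)."""

    b_values: np.ndarray   # (N,)
    gradients: np.ndarray  # (N, 3); zero rows allowed where b == 0

    def __post_init__(self):
        b = np.atleast_1d(np.asarray(self.b_values, dtype=float))
        g = np.atleast_2d(np.asarray(self.gradients, dtype=float))
        if b.shape[0] != g.shape[0] or g.shape[1] != 3:
            raise ValueError("b_values and gradients must have matching lengths")
        if np.any(b < 0):
            raise ValueError("b-values must be nonnegative")
        dwi = b > 0
        norms = np.linalg.norm(g[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-6):
            raise ValueError("diffusion-weighted gradients must be unit vectors")
        object.__setattr__(self, "b_values", b)
        object.__setattr__(self, "gradients", g)

    @property
    def dwi_mask(self) -> np.ndarray:
        return self.b_values > 0

    @property
    def shells(self) -> np.ndarray:
        return np.unique(self.b_values[self.dwi_mask])


@dataclass(frozen=True)
class TensorCompartment:
    """One Gaussian tensor: eigenvalues (mm^2/s), principal direction, volume fraction."""

    eigenvalues: tuple = WM_EIGENVALUES
    azimuth: float = 0.0    # rad
    elevation: float = 0.0  # rad
    fraction: float = 1.0

    def __post_init__(self):
        lam = tuple(float(x) for x in self.eigenvalues)
        if len(lam) != 3 or lam[2] <= 0 or not (lam[0] >= lam[1] >= lam[2]):
            raise ValueError("eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("volume fraction must lie in [0, 1]")
        object.__setattr__(self, "eigenvalues", lam)

    @property
    def principal_direction(self) -> np.ndarray:
        return sph_to_unit(self.azimuth, self.elevation)

    def tensor(self) -> np.ndarray:
        """3x3 diffusion tensor with the lambda-1 axis along the principal direction.

        The eigenframe completes the principal direction with any orthonormal
        pair; with axially symmetric defaults (l2 = l3) the choice is
        immaterial, and it is deterministic either way.
        """
        e1 = self.principal_direction
        helper = np.array([0.0, 0.0, 1.0]) if abs(e1[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e2 = np.cross(e1, helper)
        e2 /= np.linalg.norm(e2)
        e3 = np.cross(e1, e2)
        basis = np.column_stack([e1, e2, e3])
        return basis @ np.diag(self.eigenvalues) @ basis.T


@dataclass(frozen=True)
class PhantomConfig:
    """A voxel's mixture of tensor compartments; fractions must sum to one."""

    compartments: tuple
    s0: float = 1.0

    def __post_init__(self):
        comps = tuple(self.compartments)
        if not comps:
            raise ValueError("at least one compartment required")
        total = sum(c.fraction for c in comps)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"volume fractions must sum to 1 (got {total})")
        object.__setattr__(self, "compartments", comps)

    @property
    def n_fibers(self) -> int:
        return len(self.compartments)

    @property
    def true_directions(self) -> np.ndarray:
        return np.array([c.principal_direction for c in self.compartments])


@dataclass(frozen=True)
class NoiseSpec:
    """Rician noise level: snr = S0 / (Gaussian sigma per channel)."""

    snr: float
    seed: int = 0

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")


def default_scheme(n_directions: int = 64, b_value: float = 3000.0,
                   n_b0: int = 1) -> AcquisitionScheme:
    """Deterministic quasi-uniform single-shell scheme (plus leading b=0 volumes).

    Shell directions come from the same spherical Fibonacci construction used
    for ODF evaluation meshes, so the scheme is reproducible at any count.
    """
    from .sphere import even_sphere

    dirs = even_sphere(max(n_directions, 4)).vertices[:n_directions]
    dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
    b = np.concatenate([np.zeros(n_b0), np.full(n_directions, float(b_value))])
    g = np.vstack([np.zeros((n_b0, 3)), dirs])
    return AcquisitionScheme(b, g)


def _equal_fraction_phantom(angles) -> PhantomConfig:
    n = len(angles)
    comps = [
        TensorCompartment(azimuth=t, elevation=p, fraction=1.0 / n)
        for t, p in angles
    ]
    return PhantomConfig(tuple(comps))


def benchmark_phantoms() -> list:
    """The three benchmark voxels: 1, 2 and 3 crossing fibers.

    Orientations (azimuth, elevation) in radians: (0, 0); (0, 0) with
    (1.22, 0); and those two plus (0.52, 1.05).  Fractions are equal within
    each voxel (nominal 0.33 fractions renormalized to sum to one).
    """
    return [
        _equal_fraction_phantom([(0.0, 0.0)]),
        _equal_fraction_phantom([(0.0, 0.0), (1.22, 0.0)]),
        _equal_fraction_phantom([(0.0, 0.0), (1.22, 0.0), (0.52, 1.05)]),
    ]


def random_phantom(rng: np.random.Generator, n_fibers: int | None = None,
                   min_separation_deg: float = 40.0) -> PhantomConfig:
    """Random 1-3 fiber phantom with pairwise (antipodal) separation >= the bound."""
    from .sphere import arc_angle, unit_to_sph

    if n_fibers is None:
        n_fibers = int(rng.integers(1, 4))
    dirs: list = []
    while len(dirs) < n_fibers:
        v = rng.normal(size=3)
        v /= np.linalg.norm(v)
        if all(arc_angle(v, u, antipodal=True) >= min_separation_deg for u in dirs):
            dirs.append(v)
    return _equal_fraction_phantom([unit_to_sph(v) for v in dirs])


def simulate_signal(phantom: PhantomConfig, scheme: AcquisitionScheme) -> np.ndarray:
    """Noiseless multi-tensor signal S(g, b) = S0 sum_i f_i exp(-b g^T D_i g)."""
    g = scheme.gradients
    b = scheme.b_values
    signal = np.zeros(len(b))
    for comp in phantom.compartments:
        d = comp.tensor()
        signal += comp.fraction * np.exp(-b * np.einsum("ij,jk,ik->i", g, d, g))
    return phantom.s0 * signal


def add_rician(signals, s0: float, noise: NoiseSpec) -> np.ndarray:
    """Corrupt signals with Rician noise: sqrt((S + n1)^2 + n2^2), sigma = S0/snr."""
    signals = np.asarray(signals, dtype=float)
    sigma = s0 / noise.snr
    rng = np.random.default_rng(noise.seed)
    n1 = rng.normal(0.0, sigma, signals.shape)
    n2 = rng.normal(0.0, sigma, signals.shape)
    return np.sqrt((signals + n1) ** 2 + n2**2)


def analytic_odf_func(phantom: PhantomConfig):
    """Closed-form solid-angle ODF of the mixture as a vectorized function of directions.

    Returns ``psi(u)`` accepting an ``(..., 3)`` array of unit vectors.  The
    per-compartment constant (1/4pi) f det(D)^{-1/2} makes the exact integral
    over the sphere equal one.
    """
    inv_tensors = []
    consts = []
    for comp in phantom.compartments:
        d = comp.tensor()
        det = np.linalg.det(d)
        if det <= 0 or not np.all(np.isfinite(d)):
            raise ValueError("singular diffusion tensor")
        inv_tensors.append(np.linalg.inv(d))
        consts.append(comp.fraction / (4.0 * np.pi * np.sqrt(det)))

    def psi(u: np.ndarray) -> np.ndarray:
        u = np.asarray(u, dtype=float)
        out = np.zeros(u.shape[:-1])
        for c, dinv in zip(consts, inv_tensors):
            q = np.einsum("...i,ij,...j->...", u, dinv, u)
            out = out + c * q ** (-1.5)
        return out

    return psi


def analytic_odf(phantom: PhantomConfig, mesh: SphereMesh,
                 normalize: bool = True) -> SphericalSamples:
    """Exact mixture ODF sampled at the mesh vertices.

    With ``normalize=True`` the samples are rescaled so the mesh-quadrature
    integral is exactly one (the analytic constant already puts it within the
    quadrature error of one).
    """
    psi = analytic_odf_func(phantom)
    values = psi(mesh.vertices)
    samples = SphericalSamples(mesh, values)
    if normalize:
        samples = SphericalSamples(mesh, values / samples.integral())
    return samples
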