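"""Spherical-harmonic signal representation and ODF reconstruction.

Two single-shell reconstructions are provided on the real, even-order,
symmetric SH basis (order 8 by default, 45 coefficients):

* **QBI** — the analytic Funk-Radon transform, diagonal in SH with
  multipliers ``2 pi P_l(0)``;
* **CSA-QBI** — the constant-solid-angle variant, built from the
  Laplace-Beltrami transform of ``ln(-ln E)``:
  ``ODF = 1/(4 pi) + (1/(16 pi^2)) FRT{Lap ln(-ln E)}``.

A log-linear diffusion-tensor fit supplies FA for white-matter masking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import eval_legendre, sph_harm_y_all

from .phantom import AcquisitionScheme

__all__ = [
    "SHCoefficients",
    "DiffusionTensorFit",
    "sh_index_list",
    "n_coefficients",
    "sh_basis",
    "fit_sh",
    "evaluate_sh",
    "frt_multipliers",
    "qbi_odf",
    "csa_odf",
    "fit_tensor",
]


def sh_index_list(lmax: int) -> list:
    """(l, m) pairs of the even symmetric basis, l = 0, 2, ..., lmax, m = -l..l."""
    if lmax < 0 or lmax % 2:
        raise ValueError("lmax must be even and nonnegative")
    return [(l, m) for l in range(0, lmax + 1, 2) for m in range(-l, l + 1)]


def n_coefficients(lmax: int) -> int:
    return (lmax + 1) * (lmax + 2) // 2


@dataclass(frozen=True)
class SHCoefficients:
    """Coefficients on the real even symmetric SH basis in (l, m) order."""

    lmax: int
    coeffs: np.ndarray

    def __post_init__(self):
        c = np.asarray(self.coeffs, dtype=float)
        if c.shape != (n_coefficients(self.lmax),):
            raise ValueError(
                f"need {n_coefficients(self.lmax)} coefficients for lmax={self.lmax}"
            )
        object.__setattr__(self, "coeffs", c)

    @property
    def degrees(self) -> np.ndarray:
        return np.array([l for l, _ in sh_index_list(self.lmax)])


@dataclass(frozen=True)
class DiffusionTensorFit:
    """Log-linear tensor fit: 6 unique elements, eigensystem and FA."""

    tensor: np.ndarray       # 3x3 symmetric, mm^2/s
    eigenvalues: np.ndarray  # descending
    principal_direction: np.ndarray
    fa: float


def _basis_tables(lmax: int):
    """Cached (l, |m|, sign-of-m, scale) arrays for fast basis assembly."""
    idx = sh_index_list(lmax)
    l_arr = np.array([l for l, _ in idx])
    m_arr = np.array([m for _, m in idx])
    scale = np.where(m_arr == 0, 1.0, np.sqrt(2.0) * (-1.0) ** np.abs(m_arr))
    return l_arr, np.abs(m_arr), m_arr < 0, scale


_BASIS_TABLE_CACHE: dict = {}


def sh_basis(lmax: int, directions: np.ndarray) -> np.ndarray:
    """Design matrix of the real even symmetric SH basis at unit directions.

    Real basis from the complex harmonics Y_l^m: for m < 0 the (scaled)
    imaginary part, for m > 0 the real part, for m = 0 the real Y_l^0; only
    even l, so every basis function is antipodally symmetric.  Orthonormal
    over the sphere in the continuum.
    """
    if lmax % 2:
        raise ValueError("lmax must be even")
    d = np.atleast_2d(np.asarray(directions, dtype=float))
    polar = np.arccos(np.clip(d[:, 2], -1.0, 1.0))
    azimuth = np.arctan2(d[:, 1], d[:, 0])
    ylm = sph_harm_y_all(lmax, lmax, polar, azimuth)  # (l, m-wrapped, N), complex
    if lmax not in _BASIS_TABLE_CACHE:
        _BASIS_TABLE_CACHE[lmax] = _basis_tables(lmax)
    l_arr, m_abs, m_neg, scale = _BASIS_TABLE_CACHE[lmax]
    g = ylm[l_arr, m_abs]  # (R, N) complex
    vals = np.where(m_neg[:, None], g.imag, g.real) * scale[:, None]
    return np.ascontiguousarray(vals.T)


def fit_sh(values: np.ndarray, basis: np.ndarray, lmax: int,
           lambda_reg: float = 0.0) -> SHCoefficients:
    """Laplace-Beltrami-regularized least-squares SH fit.

    Solves ``argmin ||B c - s||^2 + lambda ||L c||^2`` with
    ``L = diag(l (l+1))``.  With ``lambda_reg = 0`` the system must be
    overdetermined and full rank.
    """
    values = np.asarray(values, dtype=float)
    n = n_coefficients(lmax)
    if basis.shape[1] != n:
        raise ValueError("basis does not match lmax")
    ell = np.array([l for l, _ in sh_index_list(lmax)], dtype=float)
    lap = ell * (ell + 1.0)
    gram = basis.T @ basis + lambda_reg * np.diag(lap**2)
    if lambda_reg == 0.0:
        if basis.shape[0] < n or np.linalg.matrix_rank(basis) < n:
            raise np.linalg.LinAlgError(
                "unregularized SH fit requires at least as many independent "
                "directions as coefficients"
            )
    coeffs = np.linalg.solve(gram, basis.T @ values)
    return SHCoefficients(lmax, coeffs)


def evaluate_sh(c: SHCoefficients, directions: np.ndarray) -> np.ndarray:
    """Evaluate the band-limited function at arbitrary unit directions."""
    return sh_basis(c.lmax, directions) @ c.coeffs


def frt_multipliers(lmax: int) -> np.ndarray:
    """Funk-Radon eigenvalues 2 pi P_l(0) per coefficient (l, m)."""
    ell = np.array([l for l, _ in sh_index_list(lmax)], dtype=float)
    return 2.0 * np.pi * eval_legendre(ell, 0.0)


def _single_shell_signal(signals: np.ndarray, scheme: AcquisitionScheme):
    signals = np.asarray(signals, dtype=float)
    if signals.shape[0] != scheme.b_values.shape[0]:
        raise ValueError("signal length must match the acquisition scheme")
    if scheme.shells.size != 1:
        raise ValueError("QBI/CSA reconstructions require a single-shell scheme")
    dwi = scheme.dwi_mask
    if not (~dwi).any():
        raise ValueError("a b=0 measurement is required to normalize the signal")
    s0 = float(signals[~dwi].mean())
    if s0 <= 0:
        raise ValueError("nonpositive b=0 signal")
    return signals[dwi] / s0, scheme.gradients[dwi]


def qbi_odf(signals: np.ndarray, scheme: AcquisitionScheme, lmax: int = 8,
            lambda_reg: float = 0.006) -> SHCoefficients:
    """Analytic q-ball ODF: SH fit of E = S/S0 followed by the Funk-Radon transform.

    The returned coefficients represent the (unnormalized) Funk-Radon ODF;
    min-max normalization to [0, 1] is applied downstream where a normalized
    scale is needed (peak thresholding, optimizer objective).
    """
    e, g = _single_shell_signal(signals, scheme)
    basis = sh_basis(lmax, g)
    c = fit_sh(e, basis, lmax, lambda_reg)
    return SHCoefficients(lmax, frt_multipliers(lmax) * c.coeffs)


def csa_odf(signals: np.ndarray, scheme: AcquisitionScheme, lmax: int = 8,
            lambda_reg: float = 0.006, delta: float = 1e-3) -> SHCoefficients:
    """Constant-solid-angle q-ball ODF.

    E = S/S0 is clamped into [delta, 1 - delta]; SH coefficients of
    ``ln(-ln E)`` are mapped through ``-(1/(16 pi^2)) 2 pi P_l(0) l (l+1)``
    for l >= 2, and the isotropic 1/(4 pi) term is added on Y00.
    """
    if not 0.0 < delta < 0.5:
        raise ValueError("delta must lie in (0, 0.5)")
    e, g = _single_shell_signal(signals, scheme)
    e = np.clip(e, delta, 1.0 - delta)
    basis = sh_basis(lmax, g)
    c = fit_sh(np.log(-np.log(e)), basis, lmax, lambda_reg)
    ell = np.array([l for l, _ in sh_index_list(lmax)], dtype=float)
    mult = -(1.0 / (16.0 * np.pi**2)) * frt_multipliers(lmax) * ell * (ell + 1.0)
    out = mult * c.coeffs
    out[0] += 1.0 / (4.0 * np.pi) * np.sqrt(4.0 * np.pi)  # constant term on Y00
    return SHCoefficients(lmax, out)


def fit_tensor(signals: np.ndarray, scheme: AcquisitionScheme) -> DiffusionTensorFit:
    """Log-linear least-squares single-tensor fit with FA.

    Nonpositive signals are clamped to a small fraction of S0 before the log
    (noise floor protection).  Needs >= 6 diffusion-weighted directions and a
    b=0 measurement.
    """
    signals = np.asarray(signals, dtype=float)
    dwi = scheme.dwi_mask
    if dwi.sum() < 6 or not (~dwi).any():
        raise ValueError("tensor fit needs >= 6 DWI directions and a b=0 volume")
    s0 = float(signals[~dwi].mean())
    e = signals[dwi] / s0
    e = np.clip(e, 1e-8, None)
    g = scheme.gradients[dwi]
    b = scheme.b_values[dwi]
    # design for the 6 unique elements Dxx, Dyy, Dzz, Dxy, Dxz, Dyz
    design = -b[:, None] * np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    d6, *_ = np.linalg.lstsq(design, np.log(e), rcond=None)
    dxx, dyy, dzz, dxy, dxz, dyz = d6
    tensor = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    evals, evecs = np.linalg.eigh(tensor)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    lam = evals
    denom = float(lam @ lam)
    if denom <= 0:
        fa = 0.0
    else:
        fa = float(
            np.sqrt(
                0.5
                * ((lam[0] - lam[1]) ** 2 + (lam[1] - lam[2]) ** 2 + (lam[0] - lam[2]) ** 2)
                / denom
            )
        )
    return DiffusionTensorFit(tensor, lam, evecs[:, 0], min(max(fa, 0.0), 1.0))
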