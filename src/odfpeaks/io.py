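"""Standard-format I/O: FSL-dialect bval/bvec tables, NIfTI volumes, text configs.

Conventions: bvals are one whitespace-separated row; bvecs three rows
(x, y, z components).  Volumes are NIfTI-1 with the affine governing world
(RAS) coordinates.  Phantom configurations and hybrid parameters use a flat
``key = value`` text format.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import nibabel as nib
import numpy as np

from .phantom import AcquisitionScheme, PhantomConfig, TensorCompartment

logger = logging.getLogger("odfpeaks")

__all__ = [
    "GradientTable",
    "read_gradient_table",
    "write_gradient_table",
    "VolumeGrid",
    "read_volume",
    "write_volume",
    "read_phantom_config",
    "write_phantom_config",
    "read_params_config",
]


@dataclass(frozen=True)
class GradientTable:
    """FSL-style gradient table: bvals (N,), bvecs (3, N)."""

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.atleast_1d(np.asarray(self.bvals, dtype=float))
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (3, bvals.shape[0]):
            raise ValueError(
                f"bvecs shape {bvecs.shape} does not match {bvals.shape[0]} bvals"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def to_scheme(self) -> AcquisitionScheme:
        return AcquisitionScheme(self.bvals, self.bvecs.T)

    @classmethod
    def from_scheme(cls, scheme: AcquisitionScheme) -> "GradientTable":
        return cls(scheme.b_values, scheme.gradients.T)


def read_gradient_table(bval_path, bvec_path) -> GradientTable:
    """Parse FSL-dialect bval/bvec text; normalizes off-unit nonzero bvecs."""
    try:
        bvals = np.loadtxt(bval_path, ndmin=1).ravel()
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {bval_path}: {exc}") from exc
    try:
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"non-numeric entry in {bvec_path}: {exc}") from exc
    if bvecs.shape[0] != 3:
        if bvecs.shape[1] == 3:  # column-layout file: transpose
            bvecs = bvecs.T
        else:
            raise ValueError("bvec files must have three rows (x, y, z)")
    if bvecs.shape[1] != bvals.shape[0]:
        raise ValueError(
            f"length mismatch: {bvals.shape[0]} bvals vs {bvecs.shape[1]} bvec columns"
        )
    norms = np.linalg.norm(bvecs, axis=0)
    for col in np.nonzero((bvals > 0) & (np.abs(norms - 1.0) > 1e-3))[0]:
        warnings.warn(
            f"bvec column {col} has norm {norms[col]:.4f}; renormalizing to unit length"
        )
        logger.warning("renormalizing bvec column %d (norm %.4f)", col, norms[col])
        bvecs[:, col] /= norms[col]
    return GradientTable(bvals, bvecs)


def write_gradient_table(table: GradientTable, bval_path, bvec_path) -> None:
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in table.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in table.bvecs:
            fh.write(" ".join(f"{x:.17g}" for x in row) + "\n")


@dataclass(frozen=True)
class VolumeGrid:
    """A 3D/4D image array plus its NIfTI affine."""

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self):
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine[:3, :3])) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        data = np.asarray(self.data)
        if data.ndim not in (3, 4):
            raise ValueError("volumes must be 3D or 4D")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "affine", affine)


def read_volume(path) -> VolumeGrid:
    img = nib.load(str(path))
    return VolumeGrid(np.asarray(img.dataobj), np.asarray(img.affine))


def write_volume(grid: VolumeGrid, path) -> None:
    nib.save(nib.Nifti1Image(grid.data, grid.affine), str(path))


# --- flat key = value configs -------------------------------------------------

def _parse_kv(path) -> dict:
    out = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, value = line.split("=", 1)
            out[key.strip()] = value.strip()
    return out


def write_phantom_config(phantom: PhantomConfig, path) -> None:
    """Write a phantom voxel as a flat text config.

    Schema: ``s0``, ``n_compartments``, then per compartment ``cK.fraction``,
    ``cK.eigenvalues`` (three values, mm^2/s), ``cK.azimuth`` and
    ``cK.elevation`` (rad), K = 1-based index.
    """
    lines = [
        "# odfpeaks multi-tensor phantom",
        f"s0 = {phantom.s0:g}",
        f"n_compartments = {phantom.n_fibers}",
    ]
    for k, comp in enumerate(phantom.compartments, 1):
        lam = " ".join(f"{x:.10g}" for x in comp.eigenvalues)
        lines += [
            f"c{k}.fraction = {comp.fraction!r}",
            f"c{k}.eigenvalues = {lam}",
            f"c{k}.azimuth = {comp.azimuth!r}",
            f"c{k}.elevation = {comp.elevation!r}",
        ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_phantom_config(path) -> PhantomConfig:
    kv = _parse_kv(path)
    n = int(kv["n_compartments"])
    comps = []
    for k in range(1, n + 1):
        lam = tuple(float(x) for x in kv[f"c{k}.eigenvalues"].split())
        comps.append(
            TensorCompartment(
                eigenvalues=lam,
                azimuth=float(kv[f"c{k}.azimuth"]),
                elevation=float(kv[f"c{k}.elevation"]),
                fraction=float(kv[f"c{k}.fraction"]),
            )
        )
    return PhantomConfig(tuple(comps), s0=float(kv.get("s0", 1.0)))


def read_params_config(path) -> dict:
    """Read hybrid-parameter overrides from a flat key = value file."""
    from .hybrid import HybridParams

    kv = _parse_kv(path)
    valid = HybridParams.__dataclass_fields__
    out: dict = {}
    for key, value in kv.items():
        if key not in valid:
            raise ValueError(f"unknown hybrid parameter {key!r}")
        typ = valid[key].type
        if typ in ("int",):
            out[key] = int(value)
        elif typ in ("float",):
            out[key] = float(value)
        else:
            out[key] = value
    return out
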