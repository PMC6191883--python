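"""Shared file I/O: NIfTI volumes, FSL schemes, transforms, run configs.

World convention is RAS+; images read in another orientation are reoriented
to the closest canonical axes with a warning.  Transforms are stored as
whitespace-separated 4x4 blocks keyed by the global slice index, field-map
stacks as 4-D NIfTI plus a JSON sidecar with timestamps.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import nibabel as nib
import numpy as np

from .schedule import (AcquisitionGeometry, ConfigurationError, DiffusionScheme,
                       make_superblock_scheme)
from .transforms import RigidTransform

__all__ = [
    "read_image",
    "write_image",
    "read_scheme",
    "write_scheme",
    "read_transforms",
    "write_transforms",
    "RunConfig",
]


def write_image(path, data: np.ndarray, affine: np.ndarray | None = None,
                voxel_size=(2.2, 2.2, 2.2)) -> None:
    """Write a volume as NIfTI-1, float32, RAS+ affine centred on the volume."""
    data = np.asarray(data, dtype=np.float32)
    if affine is None:
        affine = np.diag(list(voxel_size[:3]) + [1.0])
        for ax in range(3):
            n = data.shape[ax] if ax < data.ndim else 1
            affine[ax, 3] = -(n - 1) / 2.0 * voxel_size[ax]
    nib.Nifti1Image(data, affine).to_filename(str(path))


def read_image(path) -> tuple[np.ndarray, np.ndarray]:
    """Read a NIfTI volume; reorient to RAS+ with a warning if needed."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    orig = nib.aff2axcodes(img.affine)
    canonical = nib.as_closest_canonical(img)
    if orig != nib.aff2axcodes(canonical.affine):
        warnings.warn(f"{path.name}: reoriented from {orig} to RAS+")
    aff = canonical.affine
    rot = aff[:3, :3]
    scales = np.linalg.norm(rot, axis=0)
    ortho = rot / scales
    if not np.allclose(ortho.T @ ortho, np.eye(3), atol=1e-4):
        warnings.warn(f"{path.name}: affine contains shear; voxel grid is "
                      "treated as rectilinear")
    return np.asarray(canonical.get_fdata(dtype=np.float32)), aff


def read_scheme(bvals_path, bvecs_path,
                low_b_threshold: float = 0.0) -> DiffusionScheme:
    """Read an FSL-dialect bvals/bvecs pair.

    bvals is one whitespace-separated row; bvecs has three rows (x, y, z).
    b-vectors with |g| off unity by more than 1e-3 are renormalized with a
    warning.
    """
    with open(bvals_path) as fh:
        rows = [line.split() for line in fh if line.strip()]
    if len(rows) != 1:
        raise ValueError(f"bvals must be a single row, got {len(rows)} rows")
    bvals = np.array([float(x) for x in rows[0]])
    with open(bvecs_path) as fh:
        vec_rows = [line.split() for line in fh if line.strip()]
    if len(vec_rows) != 3:
        raise ValueError(f"bvecs must have three rows, got {len(vec_rows)}")
    if any(len(r) != bvals.size for r in vec_rows):
        raise ValueError(
            f"bvecs column count {[len(r) for r in vec_rows]} does not match "
            f"{bvals.size} bvals")
    bvecs = np.array(vec_rows, dtype=float).T
    norms = np.linalg.norm(bvecs, axis=1)
    off = (bvals > 0) & (np.abs(norms - 1.0) > 1e-3)
    if np.any(off):
        warnings.warn(f"renormalized {int(off.sum())} b-vectors with |g| "
                      "deviating > 1e-3 from unity")
    nz = (bvals > 0) & (norms > 0)
    bvecs[nz] = bvecs[nz] / norms[nz, None]
    return DiffusionScheme(bvals=bvals, bvecs=bvecs,
                           low_b_threshold=low_b_threshold)


def write_scheme(scheme: DiffusionScheme, bvals_path, bvecs_path) -> None:
    from .schedule import write_fsl_scheme
    write_fsl_scheme(scheme, bvals_path, bvecs_path)


def write_transforms(path, transforms: dict[int, RigidTransform]) -> None:
    """Whitespace 4x4 blocks keyed by global slice index t."""
    with open(path, "w") as fh:
        for t in sorted(transforms):
            fh.write(f"# t {t}\n")
            for row in transforms[t].matrix:
                fh.write(" ".join(f"{x:.10g}" for x in row) + "\n")


def read_transforms(path) -> dict[int, RigidTransform]:
    out: dict[int, RigidTransform] = {}
    current_t = None
    rows: list[list[float]] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if current_t is not None and rows:
                    out[current_t] = RigidTransform(np.array(rows))
                current_t = int(line.split()[-1])
                rows = []
            else:
                rows.append([float(x) for x in line.split()])
    if current_t is not None and rows:
        out[current_t] = RigidTransform(np.array(rows))
    return out


_SCHEMA = {
    "geometry": {"n_slices", "tr", "voxel_size", "slice_thickness",
                 "sao_kind", "pe_axis", "pixel_bandwidth_pe"},
    "scheme": {"n_superblocks", "b_low", "b_high", "low_b_threshold",
               "bvals_file", "bvecs_file"},
    "superblock": {"L", "f"},
    "simulation": {"amplitude_mm", "period_s", "axis", "noise_sigma",
                   "te", "double_echo", "field_scenario", "peak_hz",
                   "grid_inplane"},
    "pipeline": {"n_iterations", "lambda_recon", "lambda_field", "l_max"},
}
_TOP_KEYS = set(_SCHEMA) | {"seed", "out_dir"}


@dataclass
class RunConfig:
    """Validated run configuration; unknown keys are rejected."""

    geometry: dict
    superblock: dict
    scheme: dict = dataclass_field(default_factory=dict)
    simulation: dict = dataclass_field(default_factory=dict)
    pipeline: dict = dataclass_field(default_factory=dict)
    seed: int = 0
    out_dir: str | None = None

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        unknown = set(raw) - _TOP_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        for section, allowed in _SCHEMA.items():
            extra = set(raw.get(section, {})) - allowed
            if extra:
                raise ConfigurationError(
                    f"unknown keys in [{section}]: {sorted(extra)}")
        if "geometry" not in raw or "superblock" not in raw:
            raise ConfigurationError("config requires geometry and superblock")
        return cls(
            geometry=dict(raw["geometry"]),
            superblock=dict(raw["superblock"]),
            scheme=dict(raw.get("scheme", {})),
            simulation=dict(raw.get("simulation", {})),
            pipeline=dict(raw.get("pipeline", {})),
            seed=int(raw.get("seed", 0)),
            out_dir=raw.get("out_dir"),
        )

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "geometry": self.geometry, "superblock": self.superblock,
            "scheme": self.scheme, "simulation": self.simulation,
            "pipeline": self.pipeline, "seed": self.seed,
            "out_dir": self.out_dir,
        }

    def build_geometry(self) -> AcquisitionGeometry:
        g = dict(self.geometry)
        if "voxel_size" in g:
            g["voxel_size"] = tuple(g["voxel_size"])
        return AcquisitionGeometry(**g)

    def build_scheme(self) -> DiffusionScheme:
        s = dict(self.scheme)
        L = int(self.superblock["L"])
        if "bvals_file" in s:
            return read_scheme(s["bvals_file"], s["bvecs_file"],
                               s.get("low_b_threshold", 0.0))
        return make_superblock_scheme(
            n_superblocks=int(s.get("n_superblocks", 8)), L=L,
            b_low=s.get("b_low", 0.0), b_high=s.get("b_high", 1000.0),
            low_b_threshold=s.get("low_b_threshold", 0.0), seed=self.seed)
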