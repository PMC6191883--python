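"""Slice-level diffusion-encoding schedules.

Conventional dMRI acquires one diffusion encoding per volume: all ``Ns``
slices of volume ``v`` share encoding ``d = v``.  Single-shot EPI is however
an intrinsically planar acquisition, so the encoding may be chosen freely per
slice.  This module plans such slice-level schedules with the
*superblock & interleave* layout: the sequence of ``Nd`` encodings is split
into superblocks of ``L`` consecutive encodings, and within each superblock
every volume interleaves all ``L`` encodings, shifting the pattern from one
volume to the next so that after ``L`` volumes every slice location has been
acquired with every encoding of the block.  Keeping one low-b encoding per
superblock turns the sparse once-per-volume b=0 sampling of a conventional
scan into a dense, uniform stream of anatomically reliable slices usable for
motion and distortion estimation.

Index conventions: the global slice counter ``t`` is 0-based; volume ``v``,
within-volume counter ``s``, geometric location ``z``, encoding ``d``,
superblock ``l`` and echo ``e`` are all 1-based.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ConfigurationError",
    "AcquisitionGeometry",
    "DiffusionScheme",
    "SliceTag",
    "Schedule",
    "make_sao",
    "slice_params",
    "build_schedule",
    "classify_spatial_pattern",
    "low_b_sampling_stats",
    "write_slice_table",
    "read_slice_table",
    "sort_to_volumes",
    "make_superblock_scheme",
    "round_half_up",
]

SAO_KINDS = ("ascending", "odd_even")


class ConfigurationError(ValueError):
    """A schedule or geometry parameter violates a structural constraint."""


class ScheduleParseError(ValueError):
    """A slice table on disk is malformed; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Static geometry and timing of a 2-D multi-slice EPI acquisition."""

    n_slices: int
    tr: float
    voxel_size: tuple[float, float, float] = (2.2, 2.2, 2.2)
    slice_thickness: float | None = None
    sao_kind: str = "odd_even"
    pe_axis: str = "y"
    pixel_bandwidth_pe: float = 20.0

    def __post_init__(self):
        if self.n_slices < 2:
            raise ConfigurationError("need at least 2 slices")
        if self.tr <= 0:
            raise ConfigurationError("TR must be positive")
        if self.sao_kind not in SAO_KINDS:
            raise ConfigurationError(
                f"unknown slice acquisition order {self.sao_kind!r}; "
                f"supported: {SAO_KINDS}"
            )
        if self.slice_thickness is None:
            object.__setattr__(self, "slice_thickness", self.voxel_size[2])

    @property
    def slice_time(self) -> float:
        """Time per slice excitation, TR / Ns (s)."""
        return self.tr / self.n_slices

    @property
    def sao(self) -> np.ndarray:
        return make_sao(self.sao_kind, self.n_slices)


@dataclass(frozen=True)
class DiffusionScheme:
    """Ordered list of (b-value, b-vector) encodings, plus the low-b cut."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (Nd, 3), unit vectors for b > 0
    low_b_threshold: float = 0.0

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float)
        bvecs = np.asarray(self.bvecs, dtype=float)
        if bvecs.shape != (bvals.size, 3):
            raise ConfigurationError("bvecs must have shape (Nd, 3)")
        norms = np.linalg.norm(bvecs, axis=1)
        bad = (bvals > 0) & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            raise ConfigurationError(
                f"non-unit b-vector for b > 0 at indices {np.where(bad)[0]}"
            )
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    @property
    def n_encodings(self) -> int:
        return int(self.bvals.size)

    def is_low_b(self, d: int) -> bool:
        """Whether 1-based encoding ``d`` counts as low-b."""
        return bool(self.bvals[d - 1] <= self.low_b_threshold)

    @property
    def low_b_indices(self) -> np.ndarray:
        """1-based encoding indices at or below the low-b threshold."""
        return np.where(self.bvals <= self.low_b_threshold)[0] + 1


@dataclass(frozen=True)
class SliceTag:
    """One slice excitation: temporal, volumetric and encoding indices."""

    t: int   # global slice index, 0-based
    d: int   # encoding index, 1-based
    v: int   # volume index, 1-based
    s: int   # within-volume slice counter, 1-based
    z: int   # geometric slice location, 1-based
    l: int   # superblock index, 1-based
    e: int = 1  # echo index


def make_sao(kind: str, n_slices: int) -> np.ndarray:
    """Slice acquisition order: permutation mapping counter s to location z.

    ``ascending`` is the identity; ``odd_even`` excites all odd locations
    first, then all even ones, so spatially adjacent slices are never excited
    back-to-back.
    """
    if n_slices < 2:
        raise ConfigurationError("need at least 2 slices")
    if kind == "ascending":
        return np.arange(1, n_slices + 1)
    if kind == "odd_even":
        return np.concatenate(
            [np.arange(1, n_slices + 1, 2), np.arange(2, n_slices + 1, 2)]
        )
    raise ConfigurationError(f"unknown slice acquisition order {kind!r}")


def slice_params(t: int, n_slices: int, sao: np.ndarray | str) -> tuple[int, int, int]:
    """Volume, slice counter and geometric location of global slice ``t``.

    v = floor(t/Ns) + 1, s = (t mod Ns) + 1, z = SAO(s); ``t`` is 0-based.
    """
    if isinstance(sao, str):
        sao = make_sao(sao, n_slices)
    if t < 0:
        raise IndexError(f"slice index {t} out of range")
    v = t // n_slices + 1
    s = t % n_slices + 1
    z = int(sao[s - 1])
    return v, s, z


def build_schedule(
    scheme: DiffusionScheme,
    geometry: AcquisitionGeometry,
    L: int,
    f: int = 0,
) -> "Schedule":
    """Build a superblock & interleave schedule.

    Within superblock ``l`` (local volumes j = 0..L-1), the 0-based slice
    counter ``i`` receives local encoding ``(i + j*(1+f)) mod L`` and hence
    global encoding ``d = (l-1)*L + ((i + j*(1+f)) mod L) + 1``.  The shift
    factor ``f`` (0 in the simplest case) rotates the interleave from volume
    to volume; ``gcd(1+f, L) == 1`` guarantees every slice location sees all
    L encodings of its superblock after L volumes.  ``L == 1`` reduces to the
    conventional one-volume-one-encoding layout.
    """
    Ns = geometry.n_slices
    Nd = scheme.n_encodings
    if L < 1:
        raise ConfigurationError("superblock length L must be >= 1")
    if Ns % L != 0:
        raise ConfigurationError(
            f"superblock length L={L} must be a divisor of the number of "
            f"slices Ns={Ns}"
        )
    if Nd % L != 0:
        raise ConfigurationError(
            f"superblock length L={L} must divide the number of encodings "
            f"Nd={Nd}"
        )
    if f < 0:
        raise ConfigurationError("shift factor f must be >= 0")
    if math.gcd(1 + f, L) != 1:
        raise ConfigurationError(
            f"gcd(1+f, L) must be 1 for completeness; got f={f}, L={L}"
        )
    sao = geometry.sao
    tags = []
    for t in range(Nd * Ns):
        v, s, z = slice_params(t, Ns, sao)
        l = (v - 1) // L + 1
        j = (v - 1) % L
        i = s - 1
        e_loc = (i + j * (1 + f)) % L
        d = (l - 1) * L + e_loc + 1
        tags.append(SliceTag(t=t, d=d, v=v, s=s, z=z, l=l))
    return Schedule(geometry=geometry, scheme=scheme, superblock_length=L,
                    shift_factor=f, tags=tuple(tags))


@dataclass(frozen=True)
class Schedule:
    """Ordered slice tags plus geometry, diffusion scheme and (L, f)."""

    geometry: AcquisitionGeometry
    scheme: DiffusionScheme
    superblock_length: int
    shift_factor: int
    tags: tuple[SliceTag, ...]

    @property
    def n_volumes(self) -> int:
        return self.scheme.n_encodings

    @property
    def n_superblocks(self) -> int:
        return self.scheme.n_encodings // self.superblock_length

    @property
    def n_tags(self) -> int:
        return len(self.tags)

    def times(self) -> np.ndarray:
        """Excitation time (s) of every tag, t * TR/Ns."""
        return np.arange(self.n_tags) * self.geometry.slice_time

    def low_b_tags(self) -> list[SliceTag]:
        low = set(self.scheme.low_b_indices.tolist())
        return [tag for tag in self.tags if tag.d in low]

    def validate(self) -> None:
        """Check superblock completeness; warn on violation."""
        L = self.superblock_length
        Ns = self.geometry.n_slices
        seen: dict[tuple[int, int, int], int] = {}
        for tag in self.tags:
            key = (tag.l, tag.s, tag.d)
            seen[key] = seen.get(key, 0) + 1
        for l in range(1, self.n_superblocks + 1):
            for s in range(1, Ns + 1):
                ds = [d for (ll, ss, d), c in seen.items()
                      if ll == l and ss == s for _ in range(c)]
                if sorted(ds) != list(range((l - 1) * L + 1, l * L + 1)):
                    warnings.warn(
                        f"superblock {l}, slice counter {s}: encodings {sorted(ds)} "
                        f"do not cover the superblock exactly once",
                        stacklevel=2,
                    )
                    return


def classify_spatial_pattern(
    n_slices: int, L: int, sao: str | np.ndarray
) -> str:
    """Classify the spatial spread of same-encoding slices within one volume.

    In volume 1 the slices sharing one encoding sit at counters
    s = d, d+L, d+2L, ...; their geometric locations z = SAO(s) are sorted and
    the gaps between consecutive z examined (no wraparound):

    - any gap of 1 slice       -> ``"suboptimal"`` (back-to-back neighbours)
    - all gaps equal           -> ``"optimal"`` (equal inter-slice distance)
    - otherwise                -> ``"non_uniform"``

    For odd-even ordering an optimal pattern is only attainable with an odd
    number of slices.
    """
    if isinstance(sao, str):
        sao = make_sao(sao, n_slices)
    if n_slices % L != 0:
        raise ConfigurationError(f"L={L} must divide Ns={n_slices}")
    counters = np.arange(0, n_slices, L)  # 0-based counters of encoding d=1
    z = np.sort(sao[counters])
    if z.size < 2:
        return "optimal"
    gaps = np.diff(z)
    if np.any(gaps == 1):
        return "suboptimal"
    if np.all(gaps == gaps[0]):
        return "optimal"
    return "non_uniform"


def round_half_up(x: float) -> int:
    """Round to nearest integer with .5 rounding up (12.5 -> 13)."""
    return int(math.floor(x + 0.5))


def low_b_sampling_stats(
    schedule: Schedule, cycle_length_s: float
) -> tuple[float, int]:
    """Temporal spacing of low-b slices and count per (breathing) cycle.

    With exactly one low-b encoding per superblock the interleave spaces the
    low-b excitations uniformly at L*TR/Ns seconds; the samples-per-cycle
    count is then cycle/spacing rounded half-up.  Schedules with several
    low-b encodings per superblock fall back to the mean inter-excitation
    spacing.
    """
    low = schedule.low_b_tags()
    if not low:
        raise ValueError("schedule contains no low-b encodings")
    L = schedule.superblock_length
    geo = schedule.geometry
    per_block: dict[int, set[int]] = {}
    for tag in low:
        per_block.setdefault(tag.l, set()).add(tag.d)
    if all(len(ds) == 1 for ds in per_block.values()):
        spacing = L * geo.tr / geo.n_slices
    else:
        times = np.sort(np.array([tag.t for tag in low]) * geo.slice_time)
        spacing = float(np.mean(np.diff(times)))
    return spacing, round_half_up(cycle_length_s / spacing)


def sort_to_volumes(schedule: Schedule, slice_data: Sequence[np.ndarray]) -> np.ndarray:
    """Sort acquisition-ordered slices into conventional encoding volumes.

    ``slice_data[t]`` is the 2-D image of tag t.  Returns an array of shape
    (nx, ny, Ns, Nd) where volume d-1 collects the slices acquired with
    encoding d at their geometric locations z.
    """
    first = np.asarray(slice_data[0])
    Ns = schedule.geometry.n_slices
    Nd = schedule.scheme.n_encodings
    out = np.zeros(first.shape + (Ns, Nd), dtype=first.dtype)
    for tag in schedule.tags:
        out[:, :, tag.z - 1, tag.d - 1] = slice_data[tag.t]
    return out


def make_superblock_scheme(
    n_superblocks: int,
    L: int,
    b_low: float = 0.0,
    b_high: float = 1000.0,
    low_b_threshold: float = 0.0,
    seed: int = 0,
) -> DiffusionScheme:
    """Shelled scheme with one low-b plus L-1 high-b encodings per superblock.

    High-b directions are spread over the sphere with a golden-angle spiral,
    deterministic given the seed (the seed rotates the spiral's phase).
    """
    n_high = n_superblocks * (L - 1)
    dirs = _golden_directions(max(n_high, 1), seed)
    bvals = []
    bvecs = []
    k = 0
    for _ in range(n_superblocks):
        bvals.append(b_low)
        bvecs.append((0.0, 0.0, 0.0) if b_low == 0 else tuple(dirs[k % len(dirs)]))
        for _ in range(L - 1):
            bvals.append(b_high)
            bvecs.append(tuple(dirs[k]))
            k += 1
    return DiffusionScheme(
        bvals=np.array(bvals), bvecs=np.array(bvecs),
        low_b_threshold=low_b_threshold,
    )


def _golden_directions(n: int, seed: int = 0) -> np.ndarray:
    """n approximately uniform unit vectors on the hemisphere (z >= 0)."""
    i = np.arange(n) + 0.5
    phi = 2 * np.pi * i * (1 + 5**0.5) / 2 + seed * 0.61803
    cos_theta = i / n  # hemisphere
    sin_theta = np.sqrt(1 - cos_theta**2)
    v = np.stack(
        [sin_theta * np.cos(phi), sin_theta * np.sin(phi), cos_theta], axis=1
    )
    return v / np.linalg.norm(v, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# serialization

_TSV_COLUMNS = ["t", "v", "s", "z", "l", "echo", "bval", "gx", "gy", "gz"]


def write_slice_table(schedule: Schedule, path) -> None:
    """Write the per-slice schedule as TSV with an embedded JSON header.

    Header comment lines (``#``) carry geometry, scheme threshold and (L, f)
    so the schedule round-trips exactly; companion FSL-style ``.bvals`` /
    ``.bvecs`` files are written beside the table in volume-sorted order.
    """
    geo = schedule.geometry
    meta = {
        "n_slices": geo.n_slices,
        "tr": geo.tr,
        "voxel_size": list(geo.voxel_size),
        "slice_thickness": geo.slice_thickness,
        "sao_kind": geo.sao_kind,
        "pe_axis": geo.pe_axis,
        "pixel_bandwidth_pe": geo.pixel_bandwidth_pe,
        "low_b_threshold": schedule.scheme.low_b_threshold,
        "L": schedule.superblock_length,
        "f": schedule.shift_factor,
    }
    rows = []
    for tag in schedule.tags:
        b = schedule.scheme.bvals[tag.d - 1]
        g = schedule.scheme.bvecs[tag.d - 1]
        rows.append((tag.t, tag.v, tag.s, tag.z, tag.l, tag.e,
                     _fmt(b), _fmt(g[0]), _fmt(g[1]), _fmt(g[2])))
    path = str(path)
    with open(path, "w") as fh:
        fh.write("# slicedwi schedule " + json.dumps(meta) + "\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")
    base = path[:-4] if path.endswith(".tsv") else path
    write_fsl_scheme(schedule.scheme, base + ".bvals", base + ".bvecs")


def write_fsl_scheme(scheme: DiffusionScheme, bvals_path, bvecs_path) -> None:
    """FSL dialect: bvals one space-separated row; bvecs three rows."""
    with open(bvals_path, "w") as fh:
        fh.write(" ".join(_fmt(b) for b in scheme.bvals) + "\n")
    with open(bvecs_path, "w") as fh:
        for row in scheme.bvecs.T:
            fh.write(" ".join(_fmt(x) for x in row) + "\n")


def _fmt(x) -> str:
    return f"{float(x):.6g}"


def read_slice_table(path) -> Schedule:
    """Read a schedule TSV written by :func:`write_slice_table`."""
    meta = None
    rows = []
    with open(path) as fh:
        lines = fh.readlines()
    header_cols = None
    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line:
            continue
        if line.startswith("#"):
            idx = line.find("{")
            if idx >= 0:
                try:
                    meta = json.loads(line[idx:])
                except json.JSONDecodeError as exc:
                    raise ScheduleParseError(f"bad metadata JSON: {exc}", lineno)
            continue
        fields = line.split("\t")
        if header_cols is None:
            if fields != _TSV_COLUMNS:
                raise ScheduleParseError(
                    f"expected columns {_TSV_COLUMNS}, got {fields}", lineno)
            header_cols = fields
            continue
        if len(fields) != len(_TSV_COLUMNS):
            raise ScheduleParseError(
                f"expected {len(_TSV_COLUMNS)} fields, got {len(fields)}", lineno)
        try:
            rows.append([float(x) for x in fields])
        except ValueError as exc:
            raise ScheduleParseError(str(exc), lineno)
    if meta is None:
        raise ScheduleParseError("missing schedule metadata header")
    df = pd.DataFrame(rows, columns=_TSV_COLUMNS)
    Ns = int(meta["n_slices"])
    Nd = len(df) // Ns if Ns else 0
    if Nd * Ns != len(df):
        raise ScheduleParseError(
            f"table has {len(df)} rows, not a multiple of Ns={Ns}",
            len(lines))
    geometry = AcquisitionGeometry(
        n_slices=Ns, tr=meta["tr"], voxel_size=tuple(meta["voxel_size"]),
        slice_thickness=meta["slice_thickness"], sao_kind=meta["sao_kind"],
        pe_axis=meta["pe_axis"], pixel_bandwidth_pe=meta["pixel_bandwidth_pe"],
    )
    # reconstruct the scheme in volume-sorted (encoding) order
    bvals = np.zeros(Nd)
    bvecs = np.zeros((Nd, 3))
    d_col = np.zeros(len(df), dtype=int)
    L = int(meta["L"])
    for r in range(len(df)):
        row = df.iloc[r]
        l = int(row["l"])
        i = int(row["s"]) - 1
        j = (int(row["v"]) - 1) % L
        e_loc = (i + j * (1 + int(meta["f"]))) % L
        d = (l - 1) * L + e_loc + 1
        d_col[r] = d
        bvals[d - 1] = row["bval"]
        bvecs[d - 1] = (row["gx"], row["gy"], row["gz"])
    scheme = DiffusionScheme(bvals=bvals, bvecs=bvecs,
                             low_b_threshold=meta["low_b_threshold"])
    tags = tuple(
        SliceTag(t=int(row.t), d=int(d_col[r]), v=int(row.v), s=int(row.s),
                 z=int(row.z), l=int(row.l), e=int(row.echo))
        for r, row in enumerate(df.itertuples(index=False))
    )
    sched = Schedule(geometry=geometry, scheme=scheme, superblock_length=L,
                     shift_factor=int(meta["f"]), tags=tags)
    sched.validate()
    return sched
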