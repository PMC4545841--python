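"""3D scalar volumes on voxel grids, NIfTI-1 I/O, and grid resampling.

Every other module consumes the types defined here: a :class:`VoxelGrid`
(shape + voxel->world affine), a :class:`ScalarVolume` (grid + values +
modality tag) and a :class:`DualEchoVolume` (two co-registered UTE echo
magnitude volumes with their echo times).

Conventions
-----------
* On-disk format is NIfTI-1 (``.nii`` / ``.nii.gz``); world coordinates
  follow the NIfTI affine convention, voxel indices are 0-based.
* Label volumes use the alphabet ``0 = air, 1 = soft tissue, 2 = bone``
  and are stored as integers; all other modalities as floating point.
* CT intensities are Hounsfield units (may be negative); MR echo
  intensities are arbitrary units and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

from .errors import FormatError, GeometryError

__all__ = [
    "AIR",
    "SOFT",
    "BONE",
    "LABELS",
    "Modality",
    "VoxelGrid",
    "ScalarVolume",
    "DualEchoVolume",
    "read_volume",
    "write_volume",
    "resample_to_grid",
]

# Tissue label alphabet, shared across the whole package.
AIR, SOFT, BONE = 0, 1, 2
LABELS = (AIR, SOFT, BONE)

Modality = Literal["MR_echo1", "MR_echo2", "CT", "label", "probability"]

#: fill value used when a resampled voxel maps outside the source volume
_FILL_VALUE = {"CT": -1000.0}  # air in HU; every other modality fills with 0


@dataclass(frozen=True)
class VoxelGrid:
    """A 3D voxel lattice with its voxel-to-world affine (mm).

    Parameters
    ----------
    shape
        Number of voxels along each axis; every entry >= 1.
    affine
        4x4 voxel-index -> world (mm) homogeneous transform; must be
        invertible.
    """

    shape: tuple[int, int, int]
    affine: np.ndarray

    def __post_init__(self) -> None:
        shape = tuple(int(s) for s in self.shape)
        object.__setattr__(self, "shape", shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise GeometryError(f"grid shape must be a positive triple, got {shape}")
        aff = np.asarray(self.affine, dtype=float)
        if aff.shape != (4, 4):
            raise GeometryError(f"affine must be 4x4, got {aff.shape}")
        if abs(np.linalg.det(aff[:3, :3])) < 1e-12:
            raise GeometryError("affine is not invertible")
        spacing = np.linalg.norm(aff[:3, :3], axis=0)
        if np.any(spacing <= 0):
            raise GeometryError(f"voxel spacing must be positive, got {spacing}")
        object.__setattr__(self, "affine", aff)

    @property
    def spacing(self) -> tuple[float, float, float]:
        """Voxel spacing in mm (column norms of the affine)."""
        return tuple(np.linalg.norm(self.affine[:3, :3], axis=0))

    @classmethod
    def centered(
        cls, shape: tuple[int, int, int], spacing: tuple[float, float, float]
    ) -> "VoxelGrid":
        """Axis-aligned grid with the world origin at the volume center."""
        shape = tuple(int(s) for s in shape)
        aff = np.eye(4)
        aff[:3, :3] = np.diag(spacing)
        aff[:3, 3] = -(np.asarray(shape) - 1) * np.asarray(spacing) / 2.0
        return cls(shape, aff)

    def matches(self, other: "VoxelGrid", tol: float = 1e-5) -> bool:
        """True if both grids have the same shape and affines agree to *tol* mm."""
        return self.shape == other.shape and bool(
            np.allclose(self.affine, other.affine, atol=tol)
        )

    def voxel_centers_world(self) -> np.ndarray:
        """World coordinates (mm) of all voxel centers, shape ``(*shape, 3)``."""
        idx = np.indices(self.shape, dtype=float)
        pts = np.stack([idx[0], idx[1], idx[2], np.ones(self.shape)], axis=-1)
        world = pts @ self.affine.T
        return world[..., :3]


@dataclass
class ScalarVolume:
    """A single 3D scalar volume tied to a :class:`VoxelGrid`."""

    grid: VoxelGrid
    values: np.ndarray
    modality: Modality

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.shape != self.grid.shape:
            raise GeometryError(
                f"values shape {vals.shape} does not match grid shape {self.grid.shape}"
            )
        if self.modality == "label":
            if not np.issubdtype(vals.dtype, np.integer):
                rounded = np.rint(vals)
                if not np.array_equal(rounded, vals):
                    raise FormatError("label volume has non-integer values")
                vals = rounded.astype(np.int16)
            # tissue labels use {0=air,1=soft,2=bone}; agreement maps add a
            # fourth state — anything beyond a small categorical alphabet is
            # a sign of intensity data mislabeled as categories
            if vals.size and (vals.min() < 0 or vals.max() > 3):
                raise FormatError(
                    "label volume contains values outside the categorical alphabet 0..3"
                )
        elif self.modality == "probability":
            vals = np.asarray(vals, dtype=float)
            if vals.size and (np.nanmin(vals) < -1e-9 or np.nanmax(vals) > 1 + 1e-9):
                raise FormatError("probability volume has values outside [0, 1]")
        else:
            vals = np.asarray(vals, dtype=float)
        self.values = vals

    def with_values(self, values: np.ndarray) -> "ScalarVolume":
        return ScalarVolume(self.grid, values, self.modality)


@dataclass
class DualEchoVolume:
    """Paired UTE echo magnitude volumes on one grid.

    ``te1``/``te2`` are echo times in ms; the reference acquisition uses
    TE1 = 0.03 ms (30 us) and TE2 = 1.7 ms.
    """

    echo1: ScalarVolume
    echo2: ScalarVolume
    te1: float
    te2: float

    def __post_init__(self) -> None:
        if not self.echo1.grid.matches(self.echo2.grid):
            raise GeometryError("echo1 and echo2 must share one voxel grid")
        if not (0 < self.te1 < self.te2):
            raise GeometryError(f"need 0 < te1 < te2, got ({self.te1}, {self.te2})")
        for echo in (self.echo1, self.echo2):
            if echo.values.size and echo.values.min() < 0:
                raise FormatError("echo intensities must be non-negative")

    @property
    def grid(self) -> VoxelGrid:
        return self.echo1.grid

    @property
    def delta_te(self) -> float:
        """TE2 - TE1 in ms."""
        return self.te2 - self.te1

    def scaled(self, s1: float, s2: float) -> "DualEchoVolume":
        """Voxelwise multiplication of each echo by a positive factor."""
        return DualEchoVolume(
            self.echo1.with_values(self.echo1.values * s1),
            self.echo2.with_values(self.echo2.values * s2),
            self.te1,
            self.te2,
        )


def read_volume(path: str | Path, expected_modality: Modality) -> ScalarVolume:
    """Read a NIfTI-1 file as a :class:`ScalarVolume`.

    The grid is taken from the file header; intensities are passed
    through unchanged.

    Raises
    ------
    OSError
        If the file is missing, truncated or otherwise unreadable.
    FormatError
        If the data are not a scalar 3D volume.
    """
    path = Path(path)
    try:
        img = nib.load(path)
        data = np.asanyarray(img.dataobj)
    except FormatError:
        raise
    except (nib.filebasedimages.ImageFileError, EOFError, ValueError, OSError) as exc:
        raise OSError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected scalar 3D data, got shape {data.shape}")
    grid = VoxelGrid(data.shape, img.affine)
    if expected_modality == "label":
        data = np.rint(data).astype(np.int16)
    return ScalarVolume(grid, data, expected_modality)


def write_volume(vol: ScalarVolume, path: str | Path) -> None:
    """Write a volume as NIfTI-1; labels as int16, everything else float64."""
    if vol.modality == "label":
        data = vol.values.astype(np.int16)
    else:
        data = vol.values.astype(np.float64)
    img = nib.Nifti1Image(data, vol.grid.affine)
    nib.save(img, str(path))


def resample_to_grid(
    src: ScalarVolume,
    target: VoxelGrid,
    method: Literal["nearest", "trilinear"] = "trilinear",
) -> ScalarVolume:
    """Resample *src* onto *target* by pulling through both affines.

    ``nearest`` preserves the label alphabet exactly and never
    introduces values absent from the source; ``trilinear`` is intended
    for intensity volumes (e.g. CT pulled onto the MR grid). Voxels that
    map outside the source field of view receive -1000 HU for CT and 0
    otherwise.
    """
    if method not in ("nearest", "trilinear"):
        raise ValueError(f"unknown interpolation method {method!r}")
    if method == "nearest" and target.matches(src.grid):
        return ScalarVolume(target, src.values.copy(), src.modality)

    try:
        src_inv = np.linalg.inv(src.grid.affine)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded in VoxelGrid
        raise GeometryError("source affine is not invertible") from exc
    # voxel_target -> world -> voxel_source
    composed = src_inv @ target.affine
    idx = np.indices(target.shape, dtype=float).reshape(3, -1)
    src_idx = composed[:3, :3] @ idx + composed[:3, 3:4]

    order = 0 if method == "nearest" else 1
    cval = _FILL_VALUE.get(src.modality, 0.0)
    out = ndimage.map_coordinates(
        src.values.astype(float), src_idx, order=order, mode="constant", cval=cval
    ).reshape(target.shape)
    if src.modality == "label":
        out = np.rint(out).astype(np.int16)
    return ScalarVolume(target, out, src.modality)
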