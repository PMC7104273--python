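"""Image/mask containers, NIfTI I/O and ROI eligibility rules.

In-memory arrays use ``(slice, row, col)`` axis order (axial slices first);
voxel spacing is ``(dz, dy, dx)`` in millimetres.  On disk, volumes are NIfTI
with the conventional ``(x, y, z)`` data layout and a diagonal affine built
from the spacing, so files interoperate with standard viewers.

The mask for one nodule is shared across every energy of its stack: virtual
monochromatic images reconstructed from a single dual-energy acquisition are
natively coregistered, so there is no per-energy re-segmentation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .errors import CoregistrationError, InputError, RoiError

MANIFEST_BASE_COLUMNS = ["nodule_id", "label", "mask_path", "iodine_path"]


@dataclass(frozen=True)
class VmiStack:
    """Coregistered virtual monochromatic volumes plus an optional iodine map.

    Parameters
    ----------
    volumes : dict
        Map from energy in keV to a 3D HU array of shape (slices, rows, cols).
    spacing : tuple of float
        Voxel spacing (dz, dy, dx) in mm.
    iodine : ndarray, optional
        Iodine density map in mg/mL on the same grid.
    """

    volumes: Mapping[float, np.ndarray]
    spacing: tuple[float, float, float]
    iodine: np.ndarray | None = None

    def __post_init__(self):
        vols = dict(self.volumes)
        if not vols:
            raise InputError("stack needs at least one energy volume")
        shapes = {v.shape for v in vols.values()}
        if len(shapes) != 1:
            raise CoregistrationError(f"energy volumes disagree in shape: {shapes}")
        if any(e <= 0 for e in vols):
            raise InputError("energies must be strictly positive keV")
        if self.iodine is not None and self.iodine.shape != self.shape:
            raise CoregistrationError(
                f"iodine map shape {self.iodine.shape} != volume shape {self.shape}"
            )
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise InputError(f"spacing must be three positive lengths, got {self.spacing}")
        object.__setattr__(self, "volumes", vols)

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.volumes.values())).shape

    @property
    def energies(self) -> list[float]:
        return sorted(self.volumes)

    def volume(self, energy_keV: float) -> np.ndarray:
        try:
            return self.volumes[energy_keV]
        except KeyError:
            raise InputError(
                f"energy {energy_keV} keV not in stack (have {self.energies})"
            ) from None


@dataclass(frozen=True)
class RoiMask:
    """Binary solid-component mask for one nodule, shared across energies."""

    data: np.ndarray
    nodule_id: str
    excluded_slices: tuple[int, ...] = field(default_factory=tuple)

    def __post_init__(self):
        data = np.asarray(self.data, dtype=bool)
        if data.ndim != 3:
            raise RoiError(f"mask must be 3D, got ndim={data.ndim}")
        if not data.any():
            raise RoiError(f"mask for nodule {self.nodule_id!r} is empty")
        object.__setattr__(self, "data", data)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    def check_congruent(self, stack: VmiStack) -> None:
        if self.shape != stack.shape:
            raise CoregistrationError(
                f"mask shape {self.shape} != stack shape {stack.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI round-trip
# ---------------------------------------------------------------------------

def write_volume(path: str | Path, array: np.ndarray, spacing: Sequence[float]) -> None:
    """Write a (slice,row,col) array as NIfTI with an (x,y,z) on-disk layout."""
    dz, dy, dx = spacing
    data = np.ascontiguousarray(np.transpose(np.asarray(array), (2, 1, 0)))
    affine = np.diag([dx, dy, dz, 1.0])
    nib.save(nib.Nifti1Image(data.astype(np.float64), affine), str(path))


def read_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Read a NIfTI volume back into (slice,row,col) order; returns (array, spacing)."""
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float64)
    if data.ndim != 3:
        raise InputError(f"{path}: expected 3D volume, got ndim={data.ndim}")
    dx, dy, dz = img.header.get_zooms()[:3]
    return np.transpose(data, (2, 1, 0)), (float(dz), float(dy), float(dx))


def load_stack(
    energy_paths: Mapping[float, str | Path],
    mask_path: str | Path,
    iodine_path: str | Path | None = None,
    nodule_id: str = "",
) -> tuple[VmiStack, RoiMask]:
    """Load per-energy volumes, optional iodine map and the shared ROI mask.

    Raises
    ------
    CoregistrationError
        If any volume, map or mask disagrees in shape or spacing.
    RoiError
        If the mask is empty.
    """
    volumes: dict[float, np.ndarray] = {}
    spacing: tuple[float, float, float] | None = None
    for energy, path in energy_paths.items():
        arr, sp = read_volume(path)
        if spacing is None:
            spacing = sp
        elif not np.allclose(sp, spacing):
            raise CoregistrationError(f"{path}: spacing {sp} != {spacing}")
        volumes[float(energy)] = arr
    assert spacing is not None

    iodine = None
    if iodine_path is not None:
        iodine, sp = read_volume(iodine_path)
        if not np.allclose(sp, spacing):
            raise CoregistrationError(f"{iodine_path}: spacing {sp} != {spacing}")

    mask_arr, sp = read_volume(mask_path)
    if not np.allclose(sp, spacing):
        raise CoregistrationError(f"{mask_path}: spacing {sp} != {spacing}")

    stack = VmiStack(volumes=volumes, spacing=spacing, iodine=iodine)
    mask = RoiMask(data=mask_arr > 0.5, nodule_id=nodule_id or Path(mask_path).stem)
    mask.check_congruent(stack)
    return stack, mask


# ---------------------------------------------------------------------------
# ROI conventions
# ---------------------------------------------------------------------------

def max_inplane_diameter(mask: RoiMask, spacing: Sequence[float]) -> float:
    """Maximum in-plane (axial) diameter of the mask in mm.

    The diameter of one axial slice is the maximum center-to-center distance
    between any two mask voxels in that slice; the result is the maximum over
    slices.  A single-voxel slice has diameter 0.
    """
    _, dy, dx = spacing
    best = -1.0
    for z in range(mask.shape[0]):
        rows, cols = np.nonzero(mask.data[z])
        if rows.size == 0:
            continue
        pts = np.column_stack([rows * dy, cols * dx])
        best = max(best, _max_pairwise_distance(pts))
    if best < 0:
        raise RoiError(f"mask for nodule {mask.nodule_id!r} has no in-plane voxels")
    return best


def _max_pairwise_distance(pts: np.ndarray) -> float:
    if len(pts) == 1:
        return 0.0
    if len(pts) > 400:
        # the diameter is attained on the convex hull; fall back for
        # degenerate (collinear) point sets that Qhull rejects
        try:
            from scipy.spatial import ConvexHull, QhullError

            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass
    diff = pts[:, None, :] - pts[None, :, :]
    return float(np.sqrt((diff ** 2).sum(-1)).max())


def eligible(mask: RoiMask, spacing: Sequence[float], threshold_mm: float = 10.0) -> bool:
    """True iff the solid component meets the biopsy size criterion.

    The default 10 mm threshold is the minimum fine-needle-aspiration size in
    ACR TI-RADS; nodules below it are dropped from the analysis.
    """
    return max_inplane_diameter(mask, spacing) >= threshold_mm


def exclude_slices(mask: RoiMask, slice_indices: Sequence[int]) -> RoiMask:
    """Zero out artifact-affected axial slices; errors if nothing remains."""
    n = mask.shape[0]
    for idx in slice_indices:
        if not (0 <= idx < n):
            raise InputError(f"slice index {idx} out of range [0, {n})")
    if not slice_indices:
        return mask
    data = mask.data.copy()
    data[list(slice_indices)] = False
    if not data.any():
        raise RoiError(
            f"excluding slices {sorted(slice_indices)} empties the mask for "
            f"nodule {mask.nodule_id!r}"
        )
    merged = tuple(sorted(set(mask.excluded_slices) | set(slice_indices)))
    return replace(mask, data=data, excluded_slices=merged)


# ---------------------------------------------------------------------------
# Cohort manifest
# ---------------------------------------------------------------------------

def energy_column(energy_keV: float) -> str:
    e = int(round(energy_keV))
    return f"e{e}_path"


def write_manifest(path: str | Path, rows: list[dict],
                   header_comment: str | None = None) -> None:
    df = pd.DataFrame(rows)
    extra = [c for c in df.columns if c not in MANIFEST_BASE_COLUMNS]
    df = df[MANIFEST_BASE_COLUMNS + sorted(extra, key=_energy_key)]
    write_csv(df, path, header_comment)


def write_csv(df: pd.DataFrame, path: str | Path,
              header_comment: str | None = None) -> None:
    """Write a CSV, optionally preceded by one ``#`` provenance comment line."""
    with open(path, "w") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        df.to_csv(fh, index=False)


def read_csv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, comment="#", **kwargs)


def _energy_key(col: str) -> float:
    if col.startswith("e") and col.endswith("_path"):
        try:
            return float(col[1:-5])
        except ValueError:
            pass
    return float("inf")


def read_manifest(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#", dtype={"nodule_id": str})
    missing = [c for c in MANIFEST_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise InputError(f"manifest {path} missing columns {missing}")
    return df


def manifest_energies(df: pd.DataFrame) -> list[float]:
    """Energies present in a manifest, from its ``e<keV>_path`` columns."""
    energies = [
        float(c[1:-5])
        for c in df.columns
        if c.startswith("e") and c.endswith("_path") and c[1:-5].replace(".", "").isdigit()
    ]
    if not energies:
        raise InputError("manifest has no e<keV>_path columns")
    return sorted(energies)


def load_nodule(row: pd.Series, energies: Sequence[float] | None = None,
                base_dir: str | Path | None = None) -> tuple[VmiStack, RoiMask]:
    """Load one manifest row into a validated (stack, mask) pair."""
    base = Path(base_dir) if base_dir is not None else Path(".")

    def resolve(p: str) -> Path:
        q = Path(p)
        return q if q.is_absolute() else base / q

    if energies is None:
        energies = [
            float(c[1:-5]) for c in row.index
            if c.startswith("e") and c.endswith("_path") and pd.notna(row[c])
        ]
    energy_paths = {e: resolve(row[energy_column(e)]) for e in energies}
    iodine_path = None
    if "iodine_path" in row.index and pd.notna(row["iodine_path"]):
        iodine_path = resolve(row["iodine_path"])
    return load_stack(
        energy_paths,
        mask_path=resolve(row["mask_path"]),
        iodine_path=iodine_path,
        nodule_id=str(row["nodule_id"]),
    )
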