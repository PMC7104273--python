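"""Synthetic dual-energy CT phantom cohorts.

Generates per-nodule virtual monochromatic image (VMI) stacks, an iodine
density map and a solid-component ROI mask on one shared voxel grid, with two
nodule classes that differ in mean iodine content and in spatial texture
heterogeneity.  The attenuation model inside a nodule at energy E is

    HU(E) = base_tissue_HU(E) + c_iodine * enhancement(E) + texture + noise

where ``enhancement(E)`` (HU per mg/mL) decreases strictly with energy, as
iodine attenuation does, and the zero-mean texture field is shared across
energies (heterogeneity is a tissue property, not an energy artifact).  The
expectation of HU over the noise is exactly the deterministic sum, which makes
downstream estimators testable against ground truth.

The texture field is white Gaussian noise smoothed by an isotropic Gaussian
kernel whose width sets the correlation length, then rescaled to the target
standard deviation — the simplest heterogeneity model with independently
controllable amplitude and length scale.  Malignant nodules default to a
shorter correlation length and larger amplitude (more heterogeneous tissue);
benign nodules are smoother.

Cohort generation is a pure function of (config, seed): identical inputs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage

from .errors import ConfigurationError
from .io import (
    RoiMask,
    VmiStack,
    energy_column,
    max_inplane_diameter,
    write_manifest,
    write_volume,
)

BENIGN = "benign"
MALIGNANT = "malignant"

DEFAULT_SWEEP = tuple(float(e) for e in range(40, 200, 10))


def default_enhancement(energy_keV: float) -> float:
    """Placeholder iodine enhancement (HU per mg/mL): ~50 at 40 keV to ~4 at 190.

    Only strict monotone decay and linearity in concentration are contractual;
    absolute values do not model any particular scanner.
    """
    return 50.0 * (40.0 / energy_keV) ** 1.6


def default_base_tissue(energy_keV: float) -> float:
    """Soft-tissue background on the offset CT-number scale used throughout."""
    return 1030.0 + 3200.0 / energy_keV


def default_noise_sd(energy_keV: float) -> float:
    """Image noise SD (HU): larger at low keV, as in monochromatic stacks."""
    return 5.0 + 1000.0 / energy_keV


@dataclass(frozen=True)
class PhantomConfig:
    """Study-design parameters for one synthetic cohort.

    Defaults mirror the target study: 14 benign / 20 malignant nodules on
    3 mm axial slices, VMIs at 40/60/80 keV plus a 40-190 keV sweep for the
    attenuation-slope measurement, class mean iodine 0.54 vs 0.437 mg/mL with
    an illustrative within-class dispersion of 0.37 mg/mL borrowed from ex
    vivo thyroid measurements, and a more heterogeneous malignant texture
    field (shorter correlation length, larger amplitude).
    """

    image_shape: tuple[int, int, int] = (5, 64, 64)          # (slices, rows, cols)
    voxel_size_mm: tuple[float, float, float] = (3.0, 0.6, 0.6)  # (dz, dy, dx)
    energies_keV: tuple[float, ...] = (40.0, 60.0, 80.0)
    sweep_energies_keV: tuple[float, ...] = DEFAULT_SWEEP
    n_benign: int = 14
    n_malignant: int = 20
    nodule_axes_mm: tuple[float, float] = (5.5, 9.0)   # in-plane semi-axis range
    nodule_z_semi_axis_mm: float = 4.5
    iodine_mean_benign: float = 0.54
    iodine_mean_malignant: float = 0.437
    iodine_sd: float = 0.37
    iodine_map_noise_sd: float = 0.05
    texture_correlation_length_mm: Mapping[str, float] = field(
        default_factory=lambda: {BENIGN: 4.0, MALIGNANT: 1.5}
    )
    texture_amplitude_HU: Mapping[str, float] = field(
        default_factory=lambda: {BENIGN: 15.0, MALIGNANT: 30.0}
    )
    noise_sd_HU: Mapping[float, float] | None = None   # None -> default_noise_sd(E)
    iodine_enhancement_table: Mapping[float, float] | None = None
    base_tissue_HU: Mapping[float, float] | None = None
    rng_seed: int = 0

    # ---- derived -----------------------------------------------------------

    @property
    def all_energies(self) -> tuple[float, ...]:
        return tuple(sorted(set(self.energies_keV) | set(self.sweep_energies_keV)))

    def enhancement(self, energy: float) -> float:
        if self.iodine_enhancement_table is not None:
            return float(self.iodine_enhancement_table[energy])
        return default_enhancement(energy)

    def base_tissue(self, energy: float) -> float:
        if self.base_tissue_HU is not None:
            return float(self.base_tissue_HU[energy])
        return default_base_tissue(energy)

    def noise_sd(self, energy: float) -> float:
        if self.noise_sd_HU is not None:
            return float(self.noise_sd_HU[energy])
        return default_noise_sd(energy)

    def validate(self) -> None:
        if self.n_benign < 0 or self.n_malignant < 0:
            raise ConfigurationError("class counts must be non-negative")
        if any(d <= 0 for d in self.image_shape) or any(s <= 0 for s in self.voxel_size_mm):
            raise ConfigurationError("image dimensions and voxel sizes must be positive")
        if not self.all_energies:
            raise ConfigurationError("at least one energy is required")
        if any(e <= 0 for e in self.all_energies):
            raise ConfigurationError("energies must be positive keV")
        enh = [self.enhancement(e) for e in self.all_energies]
        if any(b >= a for a, b in zip(enh, enh[1:])):
            raise ConfigurationError(
                "iodine enhancement table must be strictly decreasing with energy"
            )
        lo, hi = self.nodule_axes_mm
        if not (0 < lo <= hi):
            raise ConfigurationError(f"invalid nodule semi-axis range {self.nodule_axes_mm}")
        _, dy, dx = self.voxel_size_mm
        _, ny, nx = self.image_shape
        if 2 * hi >= min(ny * dy, nx * dx):
            raise ConfigurationError(
                f"nodule (diameter up to {2 * hi} mm) does not fit the "
                f"{ny * dy} x {nx * dx} mm field of view"
            )
        if self.iodine_sd < 0 or self.iodine_map_noise_sd < 0:
            raise ConfigurationError("iodine dispersions must be non-negative")
        for cls in (BENIGN, MALIGNANT):
            if self.texture_correlation_length_mm[cls] <= 0:
                raise ConfigurationError("texture correlation lengths must be positive")
            if self.texture_amplitude_HU[cls] < 0:
                raise ConfigurationError("texture amplitudes must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["texture_correlation_length_mm"] = dict(self.texture_correlation_length_mm)
        d["texture_amplitude_HU"] = dict(self.texture_amplitude_HU)
        for key in ("noise_sd_HU", "iodine_enhancement_table", "base_tissue_HU"):
            if d[key] is not None:
                d[key] = {float(k): float(v) for k, v in d[key].items()}
        return d


@dataclass(frozen=True)
class PhantomNodule:
    """One synthetic nodule: VMI stack + iodine map + mask + ground truth."""

    nodule_id: str
    class_label: str
    true_iodine_mg_per_ml: float
    stack: VmiStack
    mask: RoiMask
    max_diameter_mm: float
    meets_size_criterion: bool   # max in-plane diameter >= 10 mm


def gaussian_random_field(
    shape: Sequence[int],
    correlation_length: float | Sequence[float],
    amplitude: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Zero-mean Gaussian random field with a set correlation length and SD.

    White noise is smoothed by an isotropic Gaussian kernel of width
    ``correlation_length`` (in voxels; a per-axis sequence gives an
    anisotropic kernel, e.g. for non-cubic voxels), mean-subtracted and
    rescaled so its empirical standard deviation equals ``amplitude``
    exactly.  Deterministic given the seed.
    """
    if amplitude < 0:
        raise ConfigurationError(f"amplitude must be non-negative, got {amplitude}")
    sigmas = np.atleast_1d(np.asarray(correlation_length, dtype=float))
    if np.any(sigmas <= 0):
        raise ConfigurationError(f"correlation length must be positive, got {correlation_length}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if amplitude == 0:
        return np.zeros(tuple(shape))
    white = rng.standard_normal(tuple(shape))
    # wrap mode keeps the field statistically stationary across the grid
    smooth = ndimage.gaussian_filter(white, sigma=sigmas if sigmas.size > 1 else float(sigmas[0]),
                                     mode="wrap")
    smooth -= smooth.mean()
    sd = smooth.std()
    if sd == 0:  # pathological single-voxel field
        return np.zeros(tuple(shape))
    return smooth * (amplitude / sd)


def _ellipsoid_mask(shape, spacing, center_vox, semi_axes_mm) -> np.ndarray:
    zz, yy, xx = np.indices(shape, dtype=float)
    dz, dy, dx = spacing
    cz, cy, cx = center_vox
    az, ay, ax = semi_axes_mm
    r2 = (
        ((zz - cz) * dz / az) ** 2
        + ((yy - cy) * dy / ay) ** 2
        + ((xx - cx) * dx / ax) ** 2
    )
    return r2 <= 1.0


def _make_nodule(config: PhantomConfig, label: str, nodule_id: str,
                 rng: np.random.Generator) -> PhantomNodule:
    shape = config.image_shape
    spacing = config.voxel_size_mm
    dz, dy, dx = spacing

    lo, hi = config.nodule_axes_mm
    ay, ax = rng.uniform(lo, hi, size=2)
    az = config.nodule_z_semi_axis_mm
    # small in-plane jitter so nodules are not all concentric with the grid
    jitter = rng.uniform(-1.0, 1.0, size=2)
    center = ((shape[0] - 1) / 2.0,
              (shape[1] - 1) / 2.0 + jitter[0],
              (shape[2] - 1) / 2.0 + jitter[1])
    mask_arr = _ellipsoid_mask(shape, spacing, center, (az, ay, ax))

    mean = config.iodine_mean_benign if label == BENIGN else config.iodine_mean_malignant
    true_iodine = float(rng.normal(mean, config.iodine_sd))

    corr_mm = config.texture_correlation_length_mm[label]
    amp = config.texture_amplitude_HU[label]
    sigma_vox = (corr_mm / dz, corr_mm / dy, corr_mm / dx)
    texture = gaussian_random_field(shape, sigma_vox, amp, rng) if amp > 0 else 0.0

    iodine_map = true_iodine * mask_arr.astype(float)
    if config.iodine_map_noise_sd > 0:
        iodine_map = iodine_map + rng.normal(0.0, config.iodine_map_noise_sd, size=shape)

    volumes: dict[float, np.ndarray] = {}
    for energy in config.all_energies:
        hu = np.full(shape, config.base_tissue(energy), dtype=float)
        hu += true_iodine * config.enhancement(energy) * mask_arr
        if amp > 0:
            hu += np.where(mask_arr, texture, 0.0)
        noise_sd = config.noise_sd(energy)
        if noise_sd > 0:
            hu += rng.normal(0.0, noise_sd, size=shape)
        volumes[energy] = hu

    stack = VmiStack(volumes=volumes, spacing=spacing, iodine=iodine_map)
    mask = RoiMask(data=mask_arr, nodule_id=nodule_id)
    diameter = max_inplane_diameter(mask, spacing)
    return PhantomNodule(
        nodule_id=nodule_id,
        class_label=label,
        true_iodine_mg_per_ml=true_iodine,
        stack=stack,
        mask=mask,
        max_diameter_mm=diameter,
        meets_size_criterion=diameter >= 10.0,
    )


def generate_cohort(config: PhantomConfig) -> list[PhantomNodule]:
    """Generate a full synthetic cohort; deterministic given ``config.rng_seed``."""
    config.validate()
    rng = np.random.default_rng(config.rng_seed)
    cohort = []
    for i in range(config.n_benign):
        cohort.append(_make_nodule(config, BENIGN, f"benign_{i:03d}", rng))
    for i in range(config.n_malignant):
        cohort.append(_make_nodule(config, MALIGNANT, f"malignant_{i:03d}", rng))
    return cohort


def write_cohort(cohort: Sequence[PhantomNodule], out_dir: str | Path,
                 config: PhantomConfig | None = None) -> Path:
    """Write per-nodule NIfTI volumes, the manifest CSV and a config echo.

    Returns the path to ``manifest.csv``.  File names are relative to
    ``out_dir`` in the manifest so the cohort directory is relocatable.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for nod in cohort:
        row = {
            "nodule_id": nod.nodule_id,
            "label": nod.class_label,
            "mask_path": f"{nod.nodule_id}_mask.nii.gz",
            "iodine_path": f"{nod.nodule_id}_iodine.nii.gz",
        }
        write_volume(out / row["mask_path"], nod.mask.data.astype(np.float32),
                     nod.stack.spacing)
        write_volume(out / row["iodine_path"], nod.stack.iodine, nod.stack.spacing)
        for energy in nod.stack.energies:
            col = energy_column(energy)
            row[col] = f"{nod.nodule_id}_{col[1:-5]}keV.nii.gz"
            write_volume(out / row[col], nod.stack.volume(energy), nod.stack.spacing)
        row["true_iodine"] = nod.true_iodine_mg_per_ml
        row["max_diameter_mm"] = nod.max_diameter_mm
        rows.append(row)
    manifest = out / "manifest.csv"
    write_manifest(manifest, rows)
    if config is not None:
        with open(out / "phantom_config.yaml", "w") as fh:
            yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
    return manifest
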