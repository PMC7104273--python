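"""Iodine quantification and spectral HU-curve slope.

The iodine concentration of a nodule is the unweighted ROI mean of the
material-decomposition iodine map (mg/mL).  The spectral slope is the
ordinary-least-squares slope of the ROI mean HU against VMI energy over the
40-190 keV sweep; iodine-rich tissue attenuates strongly at low keV, so the
raw slope of an enhancing nodule is negative.  The reported ``slope``
statistic is the magnitude by default, matching the positive scale used in
clinical tables; the signed value is always retained.  Two normalizations are
reported because the field uses both: the raw |slope| and |slope| divided by
|mean HU| at a reference energy (default the top of the sweep, 190 keV).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import InputError, RoiError
from .io import RoiMask, VmiStack

DEFAULT_REFERENCE_KEV = 190.0


@dataclass(frozen=True)
class SpectralResult:
    """Per-nodule spectral quantities."""

    nodule_id: str
    iodine_mg_per_ml: float | None
    hu_by_energy: Mapping[float, float]
    slope: float                 # |OLS slope|, HU per keV
    slope_signed: float
    normalized_slope: float      # |slope| / |HU(reference)|; nan if ref HU == 0
    reference_keV: float


def iodine_content(stack: VmiStack, mask: RoiMask) -> float:
    """Unweighted mean iodine density (mg/mL) over the ROI."""
    if stack.iodine is None:
        raise InputError("stack has no iodine map")
    mask.check_congruent(stack)
    if not mask.data.any():
        raise RoiError("empty ROI")
    return float(stack.iodine[mask.data].mean())


def hu_curve(stack: VmiStack, mask: RoiMask,
             energies: Sequence[float] | None = None) -> dict[float, float]:
    """Per-energy unweighted ROI mean HU, keyed by energy in keV."""
    mask.check_congruent(stack)
    if not mask.data.any():
        raise RoiError("empty ROI")
    energies = stack.energies if energies is None else sorted(energies)
    return {float(e): float(stack.volume(e)[mask.data].mean()) for e in energies}


def attenuation_slope(
    hu_by_energy: Mapping[float, float],
    normalize: bool = True,
    reference_keV: float | None = None,
) -> tuple[float, float, float]:
    """OLS slope of mean HU against energy.

    Returns ``(signed_slope, magnitude, normalized_magnitude)`` where the
    normalized value divides by |HU(reference)| and is nan when the reference
    HU is zero (or ``normalize`` is off).  With exactly two energies the OLS
    slope reduces to the two-point difference quotient.
    """
    if len(hu_by_energy) < 2:
        raise InputError("slope needs at least two energies")
    energies = np.array(sorted(hu_by_energy), dtype=float)
    hu = np.array([hu_by_energy[e] for e in energies], dtype=float)
    signed = float(np.polyfit(energies, hu, 1)[0])
    magnitude = abs(signed)
    normalized = float("nan")
    if normalize:
        ref = float(energies[-1]) if reference_keV is None else float(reference_keV)
        if ref not in hu_by_energy:
            raise InputError(f"reference energy {ref} keV not in curve")
        ref_hu = hu_by_energy[ref]
        if ref_hu != 0:
            normalized = magnitude / abs(ref_hu)
    return signed, magnitude, normalized


def analyze_nodule(stack: VmiStack, mask: RoiMask,
                   sweep_energies: Sequence[float] | None = None,
                   reference_keV: float | None = DEFAULT_REFERENCE_KEV) -> SpectralResult:
    """Full spectral quantification of one nodule."""
    curve = hu_curve(stack, mask, sweep_energies)
    ref = reference_keV if (reference_keV is None or reference_keV in curve) \
        else max(curve)
    signed, magnitude, normalized = attenuation_slope(curve, normalize=True,
                                                      reference_keV=ref)
    iodine = iodine_content(stack, mask) if stack.iodine is not None else None
    return SpectralResult(
        nodule_id=mask.nodule_id,
        iodine_mg_per_ml=iodine,
        hu_by_energy=curve,
        slope=magnitude,
        slope_signed=signed,
        normalized_slope=normalized,
        reference_keV=float(ref if ref is not None else max(curve)),
    )


def spectral_table(results: Sequence[tuple[SpectralResult, str]]) -> pd.DataFrame:
    """Table of spectral quantities: one row per nodule.

    ``results`` pairs each SpectralResult with its class label.  Columns:
    nodule_id, label, iodine_mg_per_ml, slope, normalized_slope, hu_<keV>...
    """
    rows = []
    for res, label in results:
        row = {
            "nodule_id": res.nodule_id,
            "label": label,
            "iodine_mg_per_ml": res.iodine_mg_per_ml,
            "slope": res.slope,
            "normalized_slope": res.normalized_slope,
        }
        for e in sorted(res.hu_by_energy):
            row[f"hu_{int(round(e))}"] = res.hu_by_energy[e]
        rows.append(row)
    return pd.DataFrame(rows)
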