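"""End-to-end orchestration: cohort -> feature table -> spectral table -> report.

Functions here work either on in-memory phantom cohorts or on a written
cohort directory (manifest + NIfTI files); the CLI is a thin shell over
these.  Nodules whose solid component misses the 10 mm in-plane diameter
criterion are dropped before analysis, and the drop is logged.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Sequence

import pandas as pd

from . import spectral as spectral_mod
from .errors import InputError
from .io import RoiMask, VmiStack, eligible, load_nodule, read_manifest
from .phantom import PhantomNodule
from .texture import QuantizationSpec, feature_table, nodule_features

log = logging.getLogger("dectexture")

SIZE_THRESHOLD_MM = 10.0


def _iter_manifest(manifest_path: str | Path, energies: Sequence[float] | None):
    df = read_manifest(manifest_path)
    base = Path(manifest_path).parent
    for _, row in df.iterrows():
        stack, mask = load_nodule(row, energies=energies, base_dir=base)
        yield str(row["nodule_id"]), str(row["label"]), stack, mask


def _screen(nodule_id: str, stack: VmiStack, mask: RoiMask,
            threshold_mm: float) -> bool:
    if not eligible(mask, stack.spacing, threshold_mm):
        log.info("dropping nodule %s: solid component < %g mm", nodule_id, threshold_mm)
        return False
    return True


def extract_features_cohort(
    cohort: Sequence[PhantomNodule],
    energies: Sequence[float],
    spec: QuantizationSpec = QuantizationSpec(),
    size_threshold_mm: float = SIZE_THRESHOLD_MM,
) -> pd.DataFrame:
    """Wide feature table for an in-memory cohort at the requested energies."""
    records = []
    for nod in cohort:
        if not _screen(nod.nodule_id, nod.stack, nod.mask, size_threshold_mm):
            continue
        for energy in energies:
            records.append((nodule_features(nod.stack, nod.mask, energy, spec),
                            nod.class_label))
    if not records:
        raise InputError("no eligible nodule in cohort")
    return feature_table(records)


def extract_features_manifest(
    manifest_path: str | Path,
    energies: Sequence[float],
    spec: QuantizationSpec = QuantizationSpec(),
    size_threshold_mm: float = SIZE_THRESHOLD_MM,
) -> pd.DataFrame:
    """Wide feature table from a written cohort directory."""
    records = []
    for nodule_id, label, stack, mask in _iter_manifest(manifest_path, energies):
        if not _screen(nodule_id, stack, mask, size_threshold_mm):
            continue
        for energy in energies:
            records.append((nodule_features(stack, mask, energy, spec), label))
    if not records:
        raise InputError(f"no eligible nodule in manifest {manifest_path}")
    return feature_table(records)


def spectral_cohort(
    cohort: Sequence[PhantomNodule],
    sweep_energies: Sequence[float] | None = None,
    size_threshold_mm: float = SIZE_THRESHOLD_MM,
) -> pd.DataFrame:
    """Spectral table (iodine, slope, HU curve) for an in-memory cohort."""
    results = []
    for nod in cohort:
        if not _screen(nod.nodule_id, nod.stack, nod.mask, size_threshold_mm):
            continue
        results.append((spectral_mod.analyze_nodule(nod.stack, nod.mask,
                                                    sweep_energies), nod.class_label))
    if not results:
        raise InputError("no eligible nodule in cohort")
    return spectral_mod.spectral_table(results)


def spectral_manifest(
    manifest_path: str | Path,
    sweep_energies: Sequence[float] | None = None,
    size_threshold_mm: float = SIZE_THRESHOLD_MM,
) -> pd.DataFrame:
    """Spectral table from a written cohort directory (uses all manifest energies)."""
    results = []
    for nodule_id, label, stack, mask in _iter_manifest(manifest_path, None):
        if not _screen(nodule_id, stack, mask, size_threshold_mm):
            continue
        results.append((spectral_mod.analyze_nodule(stack, mask, sweep_energies),
                        label))
    if not results:
        raise InputError(f"no eligible nodule in manifest {manifest_path}")
    return spectral_mod.spectral_table(results)
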