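"""Lung-parenchyma segmentation by thresholding and morphology.

The region the histogram sees is the parenchyma: the lung mask minus
nodules, vessels, bronchi, bullae and hilar structures.  This module
defines that interface (volume -> RegionMasks) with a classical
implementation — HU thresholding, border-component removal, selection of
the two largest in-body components, hole filling and a light closing —
so that any segmenter producing the same mask type (e.g. a learned model)
can be swapped in behind it.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Tuple

import numpy as np
from scipy import ndimage

from .volume import CTVolume, ValidationError

#: default air/parenchyma threshold (HU); lung tissue sits far below this
DEFAULT_AIR_THRESHOLD = -320.0
#: default cut separating soft-tissue structures (vessels, nodules) from lung
DEFAULT_VESSEL_CUT = -300.0
#: HU at or below which an in-lung voxel is treated as bullous air
DEFAULT_BULLA_CUT = -980.0

_CROSS = ndimage.generate_binary_structure(3, 1)


@dataclass
class RegionMasks:
    """Boolean masks congruent with one volume grid.

    ``lung`` is the full lung region; ``excluded`` maps structure names
    (nodule, vessel, bronchus, bulla, hilum) to masks of voxels removed
    from the analysis; ``parenchyma`` is always ``lung AND NOT any
    excluded``, recomputed on access so the identity is unbreakable.
    """

    lung: np.ndarray
    excluded: Dict[str, np.ndarray] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    removed_voxels: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.lung = np.asarray(self.lung, dtype=bool)
        for name, m in self.excluded.items():
            m = np.asarray(m, dtype=bool)
            if m.shape != self.lung.shape:
                raise ValidationError(
                    f"excluded[{name}]: shape {m.shape} does not match lung "
                    f"grid {self.lung.shape}")
            self.excluded[name] = m

    @property
    def parenchyma(self) -> np.ndarray:
        out = self.lung.copy()
        for m in self.excluded.values():
            out &= ~m
        return out

    def counts(self) -> Dict[str, int]:
        c = {"lung": int(self.lung.sum()),
             "parenchyma": int(self.parenchyma.sum())}
        for name, m in self.excluded.items():
            c[name] = int(m.sum())
        return c


def _border_labels(labels: np.ndarray) -> set:
    faces = [labels[0], labels[-1], labels[:, 0], labels[:, -1],
             labels[:, :, 0], labels[:, :, -1]]
    return set(np.unique(np.concatenate([f.ravel() for f in faces]))) - {0}


def segment_lungs(volume: CTVolume,
                  air_threshold: float = DEFAULT_AIR_THRESHOLD,
                  closing_radius: int = 1,
                  n_components: int = 2) -> RegionMasks:
    """Threshold-based lung extraction.

    Voxels below ``air_threshold`` are air candidates; connected
    components touching the volume border (exterior air) are discarded,
    the ``n_components`` largest remaining in-body components are kept,
    holes are filled and a closing of ``closing_radius`` smooths the
    boundary.  If nothing remains, an empty mask is returned with a
    warning recorded on the result rather than an exception.
    """
    air = volume.voxels < air_threshold
    labels, n = ndimage.label(air, structure=_CROSS)
    warnings: List[str] = []
    if n == 0:
        warnings.append("segment_lungs: no sub-threshold voxels; empty lung mask")
        return RegionMasks(lung=np.zeros(volume.shape, bool), warnings=warnings)

    keep = [lab for lab in range(1, n + 1) if lab not in _border_labels(labels)]
    if not keep:
        warnings.append("segment_lungs: no interior air component; empty lung mask")
        return RegionMasks(lung=np.zeros(volume.shape, bool), warnings=warnings)

    sizes = ndimage.sum_labels(np.ones_like(labels), labels, keep)
    order = np.argsort(sizes)[::-1][:n_components]
    lung = np.isin(labels, [keep[i] for i in order])
    lung = ndimage.binary_fill_holes(lung, structure=_CROSS)
    if closing_radius > 0:
        lung = ndimage.binary_closing(lung, structure=_CROSS,
                                      iterations=closing_radius)
    return RegionMasks(lung=lung, warnings=warnings)


def detect_vessels(volume: CTVolume, masks: RegionMasks,
                   hu_cut: float = DEFAULT_VESSEL_CUT,
                   opening_radius: int = 1) -> np.ndarray:
    """High-HU in-lung voxels (vessels, soft-tissue structures).

    Thresholds above ``hu_cut`` inside the lung, then opens with a
    6-connected element of ``opening_radius`` to suppress single-voxel
    noise.  Hilar structures are captured by the same cut (no separate
    detector).
    """
    if not masks.lung.any():
        raise ValidationError("masks.lung: empty lung mask")
    high = (volume.voxels > hu_cut) & masks.lung
    if opening_radius > 0:
        high = ndimage.binary_opening(high, structure=_CROSS,
                                      iterations=opening_radius)
    return high


def detect_bullae(volume: CTVolume, masks: RegionMasks,
                  hu_cut: float = DEFAULT_BULLA_CUT) -> np.ndarray:
    """Near-air in-lung voxels (emphysematous bullae), HU <= ``hu_cut``."""
    return (volume.voxels <= hu_cut) & masks.lung


def remove_structures(masks: RegionMasks,
                      structure_masks: Dict[str, np.ndarray]) -> RegionMasks:
    """Merge structure masks into ``excluded``, reporting removed counts.

    Idempotent: re-applying the same structures changes nothing.  The
    per-structure ``removed_voxels`` counts are voxels that were in the
    parenchyma before this call and are excluded by the named structure.
    """
    before = masks.parenchyma
    excluded = {k: v.copy() for k, v in masks.excluded.items()}
    removed = dict(masks.removed_voxels)
    for name, m in structure_masks.items():
        m = np.asarray(m, dtype=bool)
        if m.shape != masks.lung.shape:
            raise ValidationError(
                f"structure_masks[{name}]: shape {m.shape} does not match "
                f"lung grid {masks.lung.shape}")
        removed[name] = int((m & before).sum())
        excluded[name] = excluded.get(name, np.zeros_like(m)) | m
    return RegionMasks(lung=masks.lung, excluded=excluded,
                       warnings=list(masks.warnings), removed_voxels=removed)


def segment_volume(volume: CTVolume,
                   air_threshold: float = DEFAULT_AIR_THRESHOLD,
                   vessel_cut: float = DEFAULT_VESSEL_CUT,
                   bulla_cut: float = DEFAULT_BULLA_CUT) -> RegionMasks:
    """Full classical pipeline: lungs, then vessel and bulla removal."""
    masks = segment_lungs(volume, air_threshold=air_threshold)
    if not masks.lung.any():
        return masks
    vessels = detect_vessels(volume, masks, hu_cut=vessel_cut)
    bullae = detect_bullae(volume, masks, hu_cut=bulla_cut)
    return remove_structures(masks, {"vessel": vessels, "bulla": bullae})


def dice_coefficient(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap 2|A∩B| / (|A|+|B|); 1.0 for two empty masks."""
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    denom = a.sum() + b.sum()
    if denom == 0:
        return 1.0
    return 2.0 * np.logical_and(a, b).sum() / denom


def write_mask_nifti(mask: np.ndarray, spacing, path: os.PathLike | str) -> Path:
    import nibabel as nib

    path = Path(path)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(mask.astype(np.uint8), affine=affine), path)
    return path
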