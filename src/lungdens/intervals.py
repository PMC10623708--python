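"""HU-interval pixel distributions and the dominant-interval feature.

The measurement at the heart of the pipeline: count parenchymal voxels in
fixed HU intervals over [-1000, 0], then — because absolute lung voxel
counts vary hugely with body size — compare only the two adjacent
candidate intervals where lung pixel mass concentrates, and record which
one dominates.  Two interval schemes are used:

* ``distribution_1``: 100-HU bins from -950 to -50 (9 bins); candidates
  [-950,-850) vs [-850,-750).
* ``distribution_2``: 50-HU bins from -950 to 0 (19 bins); candidates
  [-950,-900) vs [-900,-850).

Bins are half-open [lo, hi), with the scheme's final bin closed at its
top edge.  Voxels in [-1000, -950) or above the scheme's top edge (but
within [-1000, 0]) are tallied as out-of-coverage, and voxels outside
[-1000, 0] as below/above range, so the bookkeeping is exact:
``sum(counts) + out_of_coverage + below_range + above_range ==
total_in_mask``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np

from .segmentation import RegionMasks
from .volume import CTVolume, ValidationError

HU_RANGE = (-1000.0, 0.0)


@dataclass(frozen=True)
class IntervalScheme:
    """An ordered HU binning with one adjacent candidate pair."""

    name: str
    bin_edges: Tuple[float, ...]
    candidate_pair: Tuple[int, int]  # bin indices (lower-HU, higher-HU)

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, dtype=float)
        if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
            raise ValidationError("bin_edges: must be strictly increasing")
        lo, hi = self.candidate_pair
        if hi != lo + 1 or lo < 0 or hi >= len(edges) - 1:
            raise ValidationError("candidate_pair: intervals must be adjacent bins")
        object.__setattr__(self, "bin_edges", tuple(float(e) for e in edges))

    @property
    def n_bins(self) -> int:
        return len(self.bin_edges) - 1

    def bin_label(self, i: int) -> str:
        lo, hi = self.bin_edges[i], self.bin_edges[i + 1]
        close = "]" if i == self.n_bins - 1 else ")"
        return f"[{lo:g},{hi:g}{close}"


DISTRIBUTION_1 = IntervalScheme(
    name="distribution_1",
    bin_edges=tuple(float(e) for e in range(-950, -49 + 1, 100)),
    candidate_pair=(0, 1),
)
DISTRIBUTION_2 = IntervalScheme(
    name="distribution_2",
    bin_edges=tuple(float(e) for e in range(-950, 0 + 1, 50)),
    candidate_pair=(0, 1),
)
SCHEMES: Dict[str, IntervalScheme] = {
    s.name: s for s in (DISTRIBUTION_1, DISTRIBUTION_2)
}


@dataclass
class PixelHistogram:
    scheme: IntervalScheme
    counts: np.ndarray           # per-bin voxel counts, len == scheme.n_bins
    below_range: int             # HU < -1000
    above_range: int             # HU > 0
    out_of_coverage: int         # within [-1000, 0] but outside the scheme's edges
    total_in_mask: int
    warnings: List[str] = field(default_factory=list)

    def conservation_holds(self) -> bool:
        return (int(self.counts.sum()) + self.below_range + self.above_range
                + self.out_of_coverage) == self.total_in_mask

    @property
    def candidate_counts(self) -> Tuple[int, int]:
        lo, hi = self.scheme.candidate_pair
        return int(self.counts[lo]), int(self.counts[hi])


@dataclass
class DominantIntervalFeature:
    """Which of the two candidate intervals holds more pixel mass."""

    scheme_name: str
    chosen_interval: str
    indicator: int               # 1 iff the higher-HU candidate dominates
    warnings: List[str] = field(default_factory=list)


def compute_histogram(volume: CTVolume, parenchyma: np.ndarray,
                      scheme: IntervalScheme) -> PixelHistogram:
    """Per-bin voxel counts of the masked volume under ``scheme``.

    Float volumes are rounded half-to-even to integer HU first, since bin
    membership at an edge depends on it.  Every in-mask voxel lands in
    exactly one tally.
    """
    parenchyma = np.asarray(parenchyma, dtype=bool)
    if parenchyma.shape != volume.shape:
        raise ValidationError(
            f"parenchyma: shape {parenchyma.shape} does not match volume "
            f"grid {volume.shape}")
    vals = volume.voxels[parenchyma]
    if not np.issubdtype(vals.dtype, np.integer):
        vals = np.rint(vals)
    total = int(vals.size)
    warnings: List[str] = []
    if total == 0:
        warnings.append(f"compute_histogram[{scheme.name}]: empty mask")
        return PixelHistogram(scheme=scheme,
                              counts=np.zeros(scheme.n_bins, dtype=np.int64),
                              below_range=0, above_range=0, out_of_coverage=0,
                              total_in_mask=0, warnings=warnings)

    below = int((vals < HU_RANGE[0]).sum())
    above = int((vals > HU_RANGE[1]).sum())
    edges = np.asarray(scheme.bin_edges)
    in_range = vals[(vals >= HU_RANGE[0]) & (vals <= HU_RANGE[1])]
    # half-open bins [lo, hi); the top edge itself belongs to the last bin
    idx = np.searchsorted(edges, in_range, side="right") - 1
    idx[in_range == edges[-1]] = scheme.n_bins - 1
    covered = (idx >= 0) & (idx < scheme.n_bins) & \
        (in_range >= edges[0]) & (in_range <= edges[-1])
    counts = np.bincount(idx[covered], minlength=scheme.n_bins).astype(np.int64)
    out_of_coverage = int(in_range.size - covered.sum())
    return PixelHistogram(scheme=scheme, counts=counts, below_range=below,
                          above_range=above, out_of_coverage=out_of_coverage,
                          total_in_mask=total, warnings=warnings)


def dominant_interval(hist: PixelHistogram) -> DominantIntervalFeature:
    """Dichotomize: 1 if the higher-HU candidate has strictly more voxels.

    Ties (and the degenerate both-zero case) resolve to the lower-HU
    candidate, the control-typical reference category.
    """
    lo_idx, hi_idx = hist.scheme.candidate_pair
    lo_count, hi_count = hist.candidate_counts
    warnings: List[str] = []
    if lo_count == 0 and hi_count == 0:
        warnings.append(
            f"dominant_interval[{hist.scheme.name}]: both candidates empty; "
            "defaulting to the lower-HU reference interval")
    if hi_count > lo_count:
        chosen, indicator = hi_idx, 1
    else:
        chosen, indicator = lo_idx, 0
        if hi_count == lo_count and lo_count > 0:
            warnings.append(
                f"dominant_interval[{hist.scheme.name}]: tie broken to the "
                "lower-HU reference interval")
    return DominantIntervalFeature(
        scheme_name=hist.scheme.name,
        chosen_interval=hist.scheme.bin_label(chosen),
        indicator=indicator,
        warnings=warnings,
    )


def extract_features(volume: CTVolume, masks: RegionMasks,
                     schemes: Dict[str, IntervalScheme] | None = None,
                     ) -> Tuple[Dict[str, DominantIntervalFeature],
                                Dict[str, PixelHistogram]]:
    """Both interval features, computed from one parenchyma mask pass."""
    schemes = schemes or SCHEMES
    parenchyma = masks.parenchyma
    hists = {name: compute_histogram(volume, parenchyma, scheme)
             for name, scheme in schemes.items()}
    feats = {name: dominant_interval(h) for name, h in hists.items()}
    return feats, hists
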