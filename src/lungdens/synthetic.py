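"""Synthetic CT phantoms and case-control cohorts with known ground truth.

The volume generator builds a torso-like phantom: air outside an
ellipsoidal body, soft tissue inside it, and two ellipsoidal lungs whose
voxels are drawn from a truncated-Gaussian HU mixture concentrated around
the aerated-parenchyma range (most lung voxels fall in [-950, -750] HU).
High-HU vessels (random-walk tubes), soft-tissue nodules and near-air
bullae are embedded and recorded in ground-truth masks, so segmentation
and histogram code can be scored against a known answer.

"Case" phantoms are produced by shifting every parenchyma component mean
upward (toward 0 HU) by ``case_shift_hu``, instantiating the finding that
occult central airway disease shows as lung pixel mass migrating into
higher-HU intervals.

The cohort generator draws a two-group (case/control) table with a binary
heavy-smoking exposure of specified odds ratio, log-normal tumour markers
parameterised by per-group median and IQR, binary radiological flags, and
per-group probabilities for the two dominant-interval indicators.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .segmentation import RegionMasks
from .volume import CTVolume, ValidationError

# 3D cross-shaped structuring element (6-connectivity); the vessel tubes
# are dilations by this element, so a morphological opening with the same
# element recovers them exactly.
STRUCT_CROSS = ndimage.generate_binary_structure(3, 1)


# ---------------------------------------------------------------------------
# volume generation
# ---------------------------------------------------------------------------

@dataclass
class VolumeSpec:
    """Parameters of one phantom volume.

    parenchyma_mixture is a sequence of (mean HU, sd HU, weight); weights
    must be positive and sum to 1, means must lie in [-1000, 0].  The
    mixture is truncated to [-1000, 0] by resampling.  ``case_shift_hu``
    is added to every component mean (positive values move mass toward
    higher HU, the case-typical direction).
    """

    grid_shape: Tuple[int, int, int] = (40, 72, 72)
    voxel_spacing: Tuple[float, float, float] = (5.0, 0.7, 0.7)
    parenchyma_mixture: Sequence[Tuple[float, float, float]] = (
        (-905.0, 40.0, 0.85),
        (-810.0, 50.0, 0.15),
    )
    case_shift_hu: float = 0.0
    vessel_fraction: float = 0.02
    n_nodules: int = 2
    nodule_radius_mm: Tuple[float, float] = (2.0, 6.0)
    n_bullae: int = 1
    bulla_radius_mm: Tuple[float, float] = (3.0, 8.0)
    body_hu: float = 40.0
    air_hu: float = -1000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.grid_shape) != 3 or any(int(n) < 8 for n in self.grid_shape):
            raise ValidationError("grid_shape: need three axes of at least 8 voxels")
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.voxel_spacing) != 3 or any(s <= 0 for s in self.voxel_spacing):
            raise ValidationError("voxel_spacing: three positive mm extents required")
        mix = [tuple(map(float, c)) for c in self.parenchyma_mixture]
        if not mix:
            raise ValidationError("parenchyma_mixture: at least one component")
        weights = [w for _, _, w in mix]
        if any(w <= 0 for w in weights):
            raise ValidationError("parenchyma_mixture: weights must be positive")
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValidationError("parenchyma_mixture: weights must sum to 1")
        for m, s, _ in mix:
            if not (-1000.0 <= m <= 0.0):
                raise ValidationError(
                    "parenchyma_mixture: component means must lie in [-1000, 0]")
            if s < 0:
                raise ValidationError("parenchyma_mixture: sd must be non-negative")
        self.parenchyma_mixture = mix
        if not (0.0 <= self.vessel_fraction < 1.0):
            raise ValidationError("vessel_fraction: must lie in [0, 1)")
        if self.n_nodules < 0 or self.n_bullae < 0:
            raise ValidationError("n_nodules/n_bullae: counts must be non-negative")

    def shifted(self, delta_hu: float) -> "VolumeSpec":
        """A copy with ``case_shift_hu`` increased by ``delta_hu``."""
        return replace(self, case_shift_hu=self.case_shift_hu + delta_hu)


@dataclass
class GroundTruth:
    """Masks and bookkeeping as constructed by the generator."""

    true_masks: RegionMasks
    generating_parameters: VolumeSpec
    voxel_accounting: Dict[str, int] = field(default_factory=dict)


def _ellipsoid(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    acc = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return acc <= 1.0


def _sample_truncated_mixture(rng: np.random.Generator, n: int,
                              mixture, lo=-1000.0, hi=0.0) -> np.ndarray:
    means = np.array([m for m, _, _ in mixture])
    sds = np.array([s for _, s, _ in mixture])
    weights = np.array([w for _, _, w in mixture])
    comp = rng.choice(len(mixture), size=n, p=weights)
    vals = rng.normal(means[comp], sds[comp])
    # truncation by resampling; clip as a last resort for pathological sds
    for _ in range(100):
        bad = (vals < lo) | (vals > hi)
        if not bad.any():
            break
        vals[bad] = rng.normal(means[comp[bad]], sds[comp[bad]])
    return np.clip(vals, lo, hi)


def _carve_vessels(rng: np.random.Generator, allowed: np.ndarray,
                   target_voxels: int) -> np.ndarray:
    """Random-walk tubes: 26-connected walks dilated by the cross element,
    constrained so that the dilated tube stays inside ``allowed``."""
    core_allowed = ndimage.binary_erosion(allowed, structure=STRUCT_CROSS)
    path = np.zeros(allowed.shape, dtype=bool)
    idx = np.argwhere(core_allowed)
    if idx.size == 0 or target_voxels <= 0:
        return path
    vessels = np.zeros_like(path)
    attempts = 0
    while vessels.sum() < target_voxels and attempts < 200:
        attempts += 1
        pos = idx[rng.integers(len(idx))].copy()
        for _ in range(rng.integers(20, 60)):
            path[tuple(pos)] = True
            step = rng.integers(-1, 2, size=3)
            nxt = pos + step
            if np.all(nxt >= 0) and np.all(nxt < allowed.shape) and \
                    core_allowed[tuple(nxt)]:
                pos = nxt
        vessels = ndimage.binary_dilation(path, structure=STRUCT_CROSS)
        vessels &= allowed
    return vessels


def _place_spheres(rng: np.random.Generator, allowed: np.ndarray,
                   spacing, n: int, radius_mm: Tuple[float, float]) -> np.ndarray:
    out = np.zeros(allowed.shape, dtype=bool)
    centers = np.argwhere(ndimage.binary_erosion(allowed, iterations=1))
    if centers.size == 0:
        return out
    for _ in range(n):
        c = centers[rng.integers(len(centers))]
        r = rng.uniform(*radius_mm)
        semi = tuple(max(r / s, 0.5) for s in spacing)
        sphere = _ellipsoid(allowed.shape, c, semi)
        out |= sphere & allowed
    return out


def generate_volume(spec: VolumeSpec) -> Tuple[CTVolume, GroundTruth]:
    """Build one phantom volume and its ground-truth region masks.

    Deterministic: identical spec (including seed) gives a bit-identical
    voxel array.  Returns the volume (integer HU) and a :class:`GroundTruth`
    whose ``voxel_accounting`` partitions the grid exactly into
    air / body / parenchyma / structure voxels.
    """
    ss = np.random.SeedSequence(spec.seed)
    rng_mix, rng_ves, rng_nod, rng_bul = (
        np.random.default_rng(s) for s in ss.spawn(4))

    shape = spec.grid_shape
    center = tuple((n - 1) / 2 for n in shape)
    body = _ellipsoid(shape, center, tuple(0.48 * n for n in shape))

    lung_semi = (0.40 * shape[0], 0.34 * shape[1], 0.20 * shape[2])
    offset = 0.24 * shape[2]
    left = _ellipsoid(shape, (center[0], center[1], center[2] - offset), lung_semi)
    right = _ellipsoid(shape, (center[0], center[1], center[2] + offset), lung_semi)
    # keep a soft-tissue shell around the lungs so lung air never touches
    # exterior air (the classical segmenter relies on that separation)
    interior = ndimage.binary_erosion(body, structure=STRUCT_CROSS, iterations=2)
    lung = (left | right) & interior

    hu = np.full(shape, spec.air_hu, dtype=np.float64)
    hu[body] = spec.body_hu

    mixture = [(m + spec.case_shift_hu, s, w)
               for m, s, w in spec.parenchyma_mixture]
    for m, _, _ in mixture:
        if not (-1000.0 <= m <= 0.0):
            raise ValidationError(
                "case_shift_hu: shifted component mean leaves [-1000, 0]")
    n_lung = int(lung.sum())
    hu[lung] = _sample_truncated_mixture(rng_mix, n_lung, mixture)

    vessels = _carve_vessels(rng_ves, lung,
                             int(round(spec.vessel_fraction * n_lung)))
    hu[vessels] = 50.0

    nodules = _place_spheres(rng_nod, lung, spec.voxel_spacing,
                             spec.n_nodules, spec.nodule_radius_mm)
    nodules &= ~vessels
    if nodules.any():
        hu[nodules] = rng_nod.uniform(-50.0, 100.0)

    bullae = _place_spheres(rng_bul, lung, spec.voxel_spacing,
                            spec.n_bullae, spec.bulla_radius_mm)
    bullae &= ~(vessels | nodules)
    if bullae.any():
        hu[bullae] = rng_bul.uniform(-1000.0, -980.0)

    volume = CTVolume(voxels=np.rint(hu).astype(np.int16),
                      spacing=spec.voxel_spacing)
    masks = RegionMasks(lung=lung, excluded={
        "vessel": vessels, "nodule": nodules, "bulla": bullae})
    structures = vessels | nodules | bullae
    accounting = {
        "air": int((~body).sum()),
        "body": int((body & ~lung).sum()),
        "parenchyma": int((lung & ~structures).sum()),
        "structure": int(structures.sum()),
        "total": int(np.prod(shape)),
    }
    return volume, GroundTruth(true_masks=masks, generating_parameters=spec,
                               voxel_accounting=accounting)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

_Z75 = 0.6744897501960817  # Phi^{-1}(0.75)


def lognormal_from_median_iqr(median: float, iqr: float) -> Tuple[float, float]:
    """(mu, sigma) of the log-normal with the given median and IQR.

    Uses IQR = 2 * median * sinh(z75 * sigma), hence
    sigma = asinh(iqr / (2 median)) / z75.
    """
    if median <= 0 or iqr <= 0:
        raise ValidationError("marker_params: median and IQR must be positive")
    return math.log(median), math.asinh(iqr / (2.0 * median)) / _Z75


#: Table-style defaults: per marker, per group, (median, IQR).
DEFAULT_MARKER_PARAMS: Dict[str, Dict[str, Tuple[float, float]]] = {
    "cea": {"case": (1.97, 2.57), "control": (1.285, 1.62)},
    "ca125": {"case": (10.4, 8.85), "control": (7.95, 5.5)},
    "ca199": {"case": (8.63, 10.26), "control": (9.99, 7.32)},
}

DEFAULT_INTERVAL_SHIFT = {
    "case": {"distribution_1": 11 / 41, "distribution_2": 34 / 41},
    "control": {"distribution_1": 3 / 48, "distribution_2": 24 / 48},
}

DEFAULT_FLAG_PREVALENCES = {
    "other_nodules": {"case": 34 / 41, "control": 46 / 48},
    "focal_fibrosis": {"case": 24 / 41, "control": 24 / 48},
    "bulla": {"case": 9 / 41, "control": 7 / 48},
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic case-control cohort.

    ``smoking_effect`` is the odds ratio of heavy smoking for case status;
    together with ``smoking_control_prevalence`` it fixes the case-group
    prevalence.  ``interval_shift_probability[group][scheme]`` is the
    probability that the higher-HU candidate interval dominates.  With
    ``exact=True`` every binary variable is assigned to exactly
    ``round(p * n)`` randomly chosen subjects instead of i.i.d. draws.
    """

    n_case: int = 41
    n_control: int = 48
    smoking_effect: float = 3.5
    smoking_control_prevalence: float = 30 / 48
    marker_params: Dict[str, Dict[str, Tuple[float, float]]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_MARKER_PARAMS.items()})
    interval_shift_probability: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_INTERVAL_SHIFT.items()})
    flag_prevalences: Dict[str, Dict[str, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_FLAG_PREVALENCES.items()})
    age_params: Dict[str, Tuple[float, float]] = field(
        default_factory=lambda: {"case": (62.0, 10.0), "control": (60.05, 10.0)})
    age_range: Tuple[float, float] = (49.0, 70.0)
    exact: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        # normalize sequence types so specs round-trip through YAML/JSON
        self.marker_params = {k: {g: tuple(v) for g, v in d.items()}
                              for k, d in self.marker_params.items()}
        self.age_params = {g: tuple(v) for g, v in self.age_params.items()}
        self.age_range = tuple(self.age_range)
        if self.n_case <= 0 or self.n_control <= 0:
            raise ValidationError("n_case/n_control: counts must be positive")
        if self.smoking_effect <= 0:
            raise ValidationError("smoking_effect: odds ratio must be positive")
        if not (0.0 <= self.smoking_control_prevalence <= 1.0):
            raise ValidationError("smoking_control_prevalence: must lie in [0, 1]")
        for group, d in self.interval_shift_probability.items():
            for scheme, p in d.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"interval_shift_probability[{group}][{scheme}]: not in [0,1]")
        for flag, d in self.flag_prevalences.items():
            for group, p in d.items():
                if not (0.0 <= p <= 1.0):
                    raise ValidationError(
                        f"flag_prevalences[{flag}][{group}]: not in [0,1]")

    @property
    def smoking_case_prevalence(self) -> float:
        odds = (self.smoking_control_prevalence
                / (1.0 - self.smoking_control_prevalence)
                if self.smoking_control_prevalence < 1.0 else math.inf)
        case_odds = self.smoking_effect * odds
        return case_odds / (1.0 + case_odds) if math.isfinite(case_odds) else 1.0


@dataclass
class PatientRecord:
    """One cohort row: outcome, covariates and the two interval indicators."""

    id: str
    outcome: int            # 1 = case (occult lesion present), 0 = control
    age: float
    heavy_smoker: int       # pack-years >= 20
    ex_or_current_smoker: int
    cea: float
    ca125: float
    ca199: float
    other_nodules: int
    focal_fibrosis: int
    bulla: int
    dist1_indicator: int    # 1 if the higher-HU 100-HU candidate dominates
    dist2_indicator: int    # 1 if the higher-HU 50-HU candidate dominates


def _draw_binary(rng: np.random.Generator, n: int, p: float,
                 exact: bool) -> np.ndarray:
    if exact:
        k = int(round(p * n))
        out = np.zeros(n, dtype=int)
        out[rng.permutation(n)[:k]] = 1
        return out
    return rng.binomial(1, p, size=n)


def generate_cohort(spec: CohortSpec) -> List[PatientRecord]:
    """Draw the cohort; deterministic given the spec (incl. seed)."""
    ss = np.random.SeedSequence(spec.seed)
    rngs = {name: np.random.default_rng(s) for name, s in zip(
        ("smoking", "markers", "flags", "intervals", "age"), ss.spawn(5))}

    records: List[PatientRecord] = []
    for group, n in (("case", spec.n_case), ("control", spec.n_control)):
        outcome = 1 if group == "case" else 0
        p_smoke = (spec.smoking_case_prevalence if outcome
                   else spec.smoking_control_prevalence)
        smoke = _draw_binary(rngs["smoking"], n, p_smoke, spec.exact)

        markers = {}
        for name, params in spec.marker_params.items():
            mu, sigma = lognormal_from_median_iqr(*params[group])
            markers[name] = rngs["markers"].lognormal(mu, sigma, size=n)

        flags = {name: _draw_binary(rngs["flags"], n, d[group], spec.exact)
                 for name, d in spec.flag_prevalences.items()}
        ind = {scheme: _draw_binary(rngs["intervals"], n,
                                    spec.interval_shift_probability[group][scheme],
                                    spec.exact)
               for scheme in ("distribution_1", "distribution_2")}

        loc, iqr = spec.age_params[group]
        age = np.clip(rngs["age"].normal(loc, iqr / (2 * _Z75), size=n),
                      *spec.age_range)

        prefix = "case" if outcome else "ctrl"
        for i in range(n):
            records.append(PatientRecord(
                id=f"{prefix}_{i + 1:03d}",
                outcome=outcome,
                age=float(np.round(age[i], 1)),
                heavy_smoker=int(smoke[i]),
                ex_or_current_smoker=int(smoke[i]),
                cea=float(np.round(markers["cea"][i], 3)),
                ca125=float(np.round(markers["ca125"][i], 3)),
                ca199=float(np.round(markers["ca199"][i], 3)),
                other_nodules=int(flags["other_nodules"][i]),
                focal_fibrosis=int(flags["focal_fibrosis"][i]),
                bulla=int(flags["bulla"][i]),
                dist1_indicator=int(ind["distribution_1"][i]),
                dist2_indicator=int(ind["distribution_2"][i]),
            ))
    return records


COHORT_COLUMNS = [
    "id", "outcome", "age", "heavy_smoker", "ex_or_current_smoker",
    "cea", "ca125", "ca199", "other_nodules", "focal_fibrosis", "bulla",
    "dist1_indicator", "dist2_indicator",
]


def records_to_dataframe(records: Sequence[PatientRecord]):
    import pandas as pd

    return pd.DataFrame([vars(r) for r in records], columns=COHORT_COLUMNS)


def dataframe_to_records(df) -> List[PatientRecord]:
    return [PatientRecord(**{k: row[k] for k in COHORT_COLUMNS})
            for _, row in df.iterrows()]
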