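"""End-to-end orchestration: config -> generate -> segment -> features ->
statistics -> reports, with a manifest for reproducibility.

A single config (YAML mapping, or :class:`PipelineConfig` built in code)
fully determines a run.  The resolved config is echoed into the output
directory; every written artifact is checksummed into ``manifest.json``
so that re-running an unchanged config reproduces all checksums except
timestamps.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Dict, List, Optional

import numpy as np

from . import __version__
from .intervals import extract_features
from .segmentation import segment_volume
from .stats import build_table1, build_table2, roc_analysis
from .synthetic import (CohortSpec, VolumeSpec, generate_cohort,
                        generate_volume, records_to_dataframe,
                        dataframe_to_records)
from .volume import ValidationError


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible run.

    If ``cohort_csv`` is set, the cohort is read from it; otherwise it is
    generated from ``cohort``.  If ``imaging`` is true, one phantom
    volume is generated, segmented and featurized per patient, and the
    image-derived interval indicators replace the cohort-drawn ones;
    ``case_shift_hu`` is applied to case-group phantoms.
    """

    output_dir: str = "lungdens_run"
    seed: int = 0
    cohort: CohortSpec = field(default_factory=CohortSpec)
    cohort_csv: Optional[str] = None
    imaging: bool = False
    volume: VolumeSpec = field(default_factory=VolumeSpec)
    case_shift_hu: float = 40.0
    air_threshold: float = -320.0
    vessel_cut: float = -300.0
    bulla_cut: float = -980.0
    confidence: float = 0.95
    ci_method: str = "delong"
    alpha_select: float = 0.05
    make_plots: bool = False

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict[str, Any]) -> "PipelineConfig":
        raw = dict(raw)
        if "cohort" in raw and isinstance(raw["cohort"], dict):
            raw["cohort"] = CohortSpec(**raw["cohort"])
        if "volume" in raw and isinstance(raw["volume"], dict):
            vol = dict(raw["volume"])
            for key in ("grid_shape", "voxel_spacing", "nodule_radius_mm",
                        "bulla_radius_mm"):
                if key in vol:
                    vol[key] = tuple(vol[key])
            if "parenchyma_mixture" in vol:
                vol["parenchyma_mixture"] = [tuple(c) for c in
                                             vol["parenchyma_mixture"]]
            raw["volume"] = VolumeSpec(**vol)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"config: unknown keys {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> Dict[str, Any]:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunManifest:
    version: str
    seed: int
    started: float
    finished: float = 0.0
    stages: List[str] = field(default_factory=list)
    checksums: Dict[str, str] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)
    error: Optional[Dict[str, str]] = None

    def write(self, path: Path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _child_seed(master: int, *key: int) -> int:
    ss = np.random.SeedSequence([master, *key])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute the full analysis; returns the run manifest.

    Stage order: cohort -> (optional) imaging -> statistics -> reports.
    Any stage failure writes the manifest with a machine-readable error
    record and raises :class:`PipelineError`; no partial statistics are
    written after a failed stage.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(version=__version__, seed=config.seed,
                           started=time.time())
    import yaml

    with open(out / "config_resolved.yaml", "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)

    def fail(stage: str, exc: Exception):
        manifest.error = {"stage": stage, "type": type(exc).__name__,
                          "message": str(exc)}
        manifest.finished = time.time()
        manifest.write(out / "manifest.json")
        raise PipelineError(stage, str(exc)) from exc

    # ---- stage 1: cohort -------------------------------------------------
    try:
        if config.cohort_csv is not None:
            import pandas as pd

            path = Path(config.cohort_csv)
            if not path.exists():
                raise FileNotFoundError(f"cohort_csv not found: {path}")
            records = dataframe_to_records(pd.read_csv(path))
        else:
            spec = dataclasses.replace(
                config.cohort, seed=_child_seed(config.seed, 1))
            records = generate_cohort(spec)
    except Exception as exc:  # noqa: BLE001 - converted to manifest record
        fail("cohort", exc)
    manifest.stages.append("cohort")

    # ---- stage 2: imaging ------------------------------------------------
    feature_rows = []
    if config.imaging:
        try:
            for i, rec in enumerate(records):
                shift = config.case_shift_hu if rec.outcome else 0.0
                vspec = dataclasses.replace(
                    config.volume,
                    case_shift_hu=config.volume.case_shift_hu + shift,
                    seed=_child_seed(config.seed, 2, i))
                vol, _truth = generate_volume(vspec)
                masks = segment_volume(vol,
                                       air_threshold=config.air_threshold,
                                       vessel_cut=config.vessel_cut,
                                       bulla_cut=config.bulla_cut)
                manifest.warnings.extend(
                    f"{rec.id}: {w}" for w in masks.warnings)
                feats, hists = extract_features(vol, masks)
                rec.dist1_indicator = feats["distribution_1"].indicator
                rec.dist2_indicator = feats["distribution_2"].indicator
                for f in feats.values():
                    manifest.warnings.extend(
                        f"{rec.id}: {w}" for w in f.warnings)
                row = {"id": rec.id,
                       "dist1_indicator": rec.dist1_indicator,
                       "dist2_indicator": rec.dist2_indicator}
                for name, h in hists.items():
                    row.update({f"{name}_bin{j}": int(c)
                                for j, c in enumerate(h.counts)})
                    row[f"{name}_total_in_mask"] = h.total_in_mask
                feature_rows.append(row)
        except Exception as exc:  # noqa: BLE001
            fail("imaging", exc)
        manifest.stages.append("imaging")

    # ---- stage 3: statistics --------------------------------------------
    try:
        table1 = build_table1(records)
        table2, multi, selected = build_table2(
            records, alpha_select=config.alpha_select)
        roc = None
        if multi is not None:
            y = records_to_dataframe(records)["outcome"].to_numpy(int)
            roc = roc_analysis(y, multi.predicted,
                               confidence=config.confidence,
                               ci_method=config.ci_method)
        else:
            manifest.warnings.append(
                "statistics: no multivariate model (screen selected nothing)")
    except Exception as exc:  # noqa: BLE001
        fail("statistics", exc)
    manifest.stages.append("statistics")

    # ---- stage 4: reports ------------------------------------------------
    try:
        import pandas as pd

        records_to_dataframe(records).to_csv(out / "cohort.csv", index=False)
        table1.to_csv(out / "table1.csv", index=False)
        table2.to_csv(out / "table2.csv", index=False)
        if feature_rows:
            pd.DataFrame(feature_rows).to_csv(out / "features.csv",
                                              index=False)
        if roc is not None:
            pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr,
                          "threshold": roc.thresholds}).to_csv(
                out / "roc_points.csv", index=False)
            with open(out / "roc_summary.json", "w") as fh:
                json.dump({"auc": roc.auc, "ci_low": roc.ci_low,
                           "ci_high": roc.ci_high,
                           "sensitivity": roc.sensitivity,
                           "specificity": roc.specificity,
                           "threshold": roc.threshold,
                           "selected_variables": selected}, fh, indent=2)
        if config.make_plots and roc is not None:
            plot_roc(roc, out / "roc_curve.png")
    except Exception as exc:  # noqa: BLE001
        fail("reports", exc)
    manifest.stages.append("reports")

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest.checksums[f.name] = _sha256(f)
    manifest.finished = time.time()
    manifest.write(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# plots
# ---------------------------------------------------------------------------

def plot_histogram(hist, path) -> Path:
    """Bar plot of one interval scheme's per-bin voxel counts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.asarray(hist.scheme.bin_edges)
    centers = (edges[:-1] + edges[1:]) / 2
    widths = np.diff(edges)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(centers, hist.counts, width=0.9 * widths, color="steelblue")
    ax.set_xlabel("CT value (HU)")
    ax.set_ylabel("voxel count")
    ax.set_title(f"Pixel distribution — {hist.scheme.name}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_roc(roc, path) -> Path:
    """ROC curve with AUC annotation and the Youden operating point."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.plot(roc.fpr, roc.tpr, color="firebrick",
            label=f"AUC = {roc.auc:.3f} "
                  f"({roc.ci_low:.3f}–{roc.ci_high:.3f})")
    ax.plot([0, 1], [0, 1], ls="--", color="grey", lw=1)
    ax.plot(1 - roc.specificity, roc.sensitivity, "o", color="black",
            label=f"sens {100 * roc.sensitivity:.1f}%, "
                  f"spec {100 * roc.specificity:.1f}%")
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("sensitivity")
    ax.set_xlim(-0.02, 1.02)
    ax.set_ylim(-0.02, 1.02)
    ax.legend(loc="lower right")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
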