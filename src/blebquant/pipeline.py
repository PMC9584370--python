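"""End-to-end orchestration, configuration and run manifests.

A run takes any mix of segmentation volumes (measured per eye) and a
per-patient cohort table (compared across groups) and writes its
artifacts under one output directory:

* ``measurement_<id>.json`` — one per segmented eye;
* ``measurements.csv`` — the assembled morphometry table;
* ``comparisons.csv`` — the group-comparison panel (cohort mode);
* ``manifest.json`` — configuration, package version and stage list;
  identical inputs and configuration yield identical manifests.

All randomness in a run flows through the single seed recorded in the
configuration.  Units are mm and mm³ throughout; inputs with other
units must declare their spacing accordingly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import pandas as pd

from . import __version__
from .cohort import compare_groups, comparisons_to_frame, read_cohort, write_cohort
from .errors import StageError
from .quantify import BGIMeasurement, MeasureConfig, measure
from .surface import COMPONENTS, LabelVolume

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger("blebquant")


@dataclass
class RunConfig:
    """Run-level configuration (houses the pipeline's constants)."""

    resolution: float = 0.1             # analysis grid voxel edge, mm
    max_gap: float = 0.2                # gap-closure reach, mm
    large_bleb_threshold: float = 1100.0
    quartile_method: str = "linear"     # inclusive linear interpolation
    seed: int = 0
    label_map: Dict[str, int] = field(default_factory=lambda: dict(COMPONENTS))
    smooth_iterations: int = 10
    smooth_strength: float = 0.5
    output_dir: str = "blebquant_run"

    def measure_config(self) -> MeasureConfig:
        return MeasureConfig(
            resolution=self.resolution,
            max_gap=self.max_gap,
            large_bleb_threshold=self.large_bleb_threshold,
            smooth_iterations=self.smooth_iterations,
            smooth_strength=self.smooth_strength,
        )

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        if path.suffix.lower() in (".yaml", ".yml"):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls(**data)


def _setup_run_logging(out_dir: Path) -> logging.Handler:
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter(
        "%(asctime)s %(levelname)s %(message)s", datefmt="%Y-%m-%dT%H:%M:%S"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    return handler


def run_pipeline(
    segmentations: Optional[Sequence[Union[str, Path, LabelVolume]]] = None,
    cohort: Optional[Union[str, Path, pd.DataFrame]] = None,
    config: Optional[RunConfig] = None,
    mapping=None,
) -> Dict[str, object]:
    """Run measurement and/or cohort comparison and write all artifacts.

    ``segmentations`` are NIfTI paths or in-memory label volumes; each
    is measured with the run's configuration.  ``cohort`` is a path or
    DataFrame with per-patient rows; when present, the comparison panel
    is produced.  Either modality may be omitted.  Returns the manifest.

    Raises
    ------
    StageError
        if any stage fails, naming the stage.
    """
    config = config or RunConfig()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = _setup_run_logging(out_dir)
    stages: List[str] = []
    try:
        measurements: List[BGIMeasurement] = []
        rows = []
        for i, seg in enumerate(segmentations or []):
            name = f"{i:03d}"
            if isinstance(seg, (str, Path)):
                name = Path(seg).name.split(".")[0]
                logger.info("loading segmentation %s", seg)
                try:
                    seg = LabelVolume.from_nifti(seg, label_map=config.label_map)
                except Exception as exc:
                    raise StageError(f"load[{name}]", exc) from exc
            logger.info("measuring eye %s", name)
            m = measure(seg, config.measure_config())
            m.to_json(out_dir / f"measurement_{name}.json")
            measurements.append(m)
            rows.append({
                "id": name,
                "volume_inner": m.volume_inner,
                "volume_outer": m.volume_outer,
                "volume_plate": m.volume_plate,
                "volume_total": m.volume_total,
                "height": m.height,
                "merged": m.merged,
                "large_bleb": m.large_bleb,
            })
            stages.append(f"measure[{name}]")
        if rows:
            pd.DataFrame(rows).to_csv(out_dir / "measurements.csv", index=False)
            stages.append("write[measurements.csv]")

        if cohort is not None:
            if isinstance(cohort, (str, Path)):
                logger.info("loading cohort %s", cohort)
                try:
                    cohort = read_cohort(cohort, mapping=mapping)
                except Exception as exc:
                    raise StageError("read_cohort", exc) from exc
            try:
                panel = compare_groups(cohort)
            except Exception as exc:
                raise StageError("compare_groups", exc) from exc
            comparisons_to_frame(panel).to_csv(out_dir / "comparisons.csv", index=False)
            write_cohort(pd.DataFrame(cohort), out_dir / "cohort.csv")
            stages.append("compare_groups")

        manifest = {
            "package": "blebquant",
            "version": __version__,
            "config": asdict(config),
            "n_segmentations": len(measurements),
            "cohort_rows": int(len(cohort)) if cohort is not None else 0,
            "stages": stages,
        }
        with open(out_dir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        logger.info("run complete: %d stages", len(stages))
        return manifest
    finally:
        logger.removeHandler(handler)
        handler.close()
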