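"""Batch orchestration: fields -> spots -> nuclei -> counts -> stats.

A batch runs under a single frozen parameter set: the detection
thresholds (th1, th2, th4), DoG sigmas, segmentation parameters and the
assignment radius are fixed once — chosen on a sample image with
:func:`tune_preview` — and recorded verbatim in the run log, which also
proves that one parameter tuple covered the whole batch.

The manifest is a CSV with columns ``field_path, animal_id, group,
field_index, assay`` (assay selects the channel->marker panel) and an
optional ``label_path`` column carrying an externally corrected
label-map TIFF that overrides the built-in segmentation for that field.

Partial failures are reported, not fatal: an unreadable field is
skipped with a logged reason and the batch continues; the run summary
carries a nonzero failure count.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from .detection import PROBE_CHANNELS, DoGParams, SpotSet, detect_spots, dog_filter
from .exceptions import ConfigurationError
from .quantify import (
    ASSAY_PANELS,
    AnimalSummary,
    aggregate_animal,
    assign_spots,
)
from .segmentation import NucleusLabelMap, SegmentationParams, segment_nuclei
from .stats import kruskal_wallis, phenotype_quartiles, spearman_bh

__all__ = ["RunConfig", "BatchResult", "run_batch", "tune_preview", "build_metric_table"]

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

MANIFEST_COLUMNS = ["field_path", "animal_id", "group", "field_index", "assay"]


@dataclass(frozen=True)
class RunConfig:
    """Frozen parameter set for one batch.

    ``thresholds`` maps probe channel (1, 2, 4) to its detection
    threshold; ``positivity_thresholds`` maps marker name to the copy
    count that makes a cell positive.
    """

    thresholds: dict[int, float]
    dog: DoGParams = DoGParams()
    seg: SegmentationParams = SegmentationParams()
    max_dist: float = 10.0
    min_separation: float = 2.0
    positivity_thresholds: dict[str, int] = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        missing = set(PROBE_CHANNELS) - set(self.thresholds)
        if missing:
            raise ConfigurationError(f"thresholds missing for channels {sorted(missing)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["thresholds"] = {str(k): v for k, v in self.thresholds.items()}
        return d

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "dog" in kwargs:
            kwargs["dog"] = DoGParams(**kwargs["dog"])
        if "seg" in kwargs:
            kwargs["seg"] = SegmentationParams(**kwargs["seg"])
        if "thresholds" in kwargs:
            kwargs["thresholds"] = {int(k): float(v) for k, v in kwargs["thresholds"].items()}
        return cls(**kwargs)


@dataclass
class BatchResult:
    output_dir: Path
    n_fields_ok: int
    n_fields_failed: int
    failures: list[dict]
    summaries: list[AnimalSummary]

    @property
    def ok(self) -> bool:
        return self.n_fields_failed == 0


def _detect_field_spots(field, config: RunConfig) -> SpotSet:
    parts = []
    for c in PROBE_CHANNELS:
        filtered = dog_filter(field.channel(c), config.dog)
        parts.append(detect_spots(filtered, config.thresholds[c], config.min_separation))
    return SpotSet.concatenate(parts)


def process_field(
    field, config: RunConfig, labels: NucleusLabelMap | None = None
):
    """Detect, segment (unless an override label map is given) and assign."""
    spots = _detect_field_spots(field, config)
    if labels is None:
        labels = segment_nuclei(field.channel(3), config.seg)
    table = assign_spots(spots, labels, max_dist=config.max_dist, field_id=field.field_id)
    return spots, labels, table


def build_metric_table(summaries: list[AnimalSummary]) -> pd.DataFrame:
    """Animal x metric table: marker copy totals and ensemble percentages."""
    rows = {}
    for s in summaries:
        row = {f"total_{m}": v for m, v in s.totals.items()}
        if s.ensemble_pct is not None:
            row.update({f"pct_{k}": v for k, v in s.ensemble_pct.items()})
        rows[s.animal_id] = row
    out = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    out.index.name = "animal_id"
    return out


def run_batch(
    config: RunConfig,
    manifest: pd.DataFrame | str | Path,
    output_dir: str | Path,
    behavior: "str | Path | None" = None,
) -> BatchResult:
    """Process every manifest field and aggregate to animals.

    Writes, under ``output_dir``: per-field spot/cell CSVs and label
    TIFFs, ``animals.csv``, a JSON run log (config + hash + per-field
    status), and — when a behaviour CSV is supplied — phenotypes,
    HD-vs-LD Kruskal-Wallis contrasts and session x metric correlation
    matrices.  Identical inputs and config give byte-identical CSVs.
    """
    if not isinstance(manifest, pd.DataFrame):
        manifest = pd.read_csv(manifest)
    missing = set(MANIFEST_COLUMNS) - set(manifest.columns)
    if missing:
        raise ConfigurationError(f"manifest missing columns: {sorted(missing)}")
    out = Path(output_dir)
    (out / "fields").mkdir(parents=True, exist_ok=True)

    log: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.digest(),
        "fields": [],
    }
    failures: list[dict] = []
    tables_by_animal: dict[str, list] = {}
    meta_by_animal: dict[str, dict] = {}

    if len(manifest) == 0:
        logger.warning("empty manifest: nothing to process")

    for _, row in manifest.iterrows():
        t0 = time.perf_counter()
        field_path = str(row["field_path"])
        try:
            field = rio.read_field_tiff(
                field_path,
                animal_id=str(row["animal_id"]),
                field_index=int(row["field_index"]),
            )
            override = None
            if "label_path" in row and isinstance(row.get("label_path"), str) and row["label_path"]:
                override = rio.read_label_tiff(row["label_path"])
                if override.shape != field.shape:
                    raise ValueError("label override has wrong shape")
            spots, labels, table = process_field(field, config, labels=override)
            stem = Path(field_path).stem
            rio.write_spots_csv(spots, out / "fields" / f"{stem}_spots.csv", field_id=stem)
            rio.write_label_tiff(labels, out / "fields" / f"{stem}_labels.tif")
            rio.write_cell_table_csv(table, out / "fields" / f"{stem}_cells.csv")
            animal = str(row["animal_id"])
            tables_by_animal.setdefault(animal, []).append(table)
            meta_by_animal[animal] = {
                "group": row.get("group"),
                "assay": row.get("assay", "TH-panel"),
            }
            log["fields"].append(
                {
                    "field": field_path,
                    "status": "ok",
                    "n_nuclei": labels.n_nuclei,
                    "n_spots": len(spots),
                    "seconds": round(time.perf_counter() - t0, 3),
                }
            )
        except Exception as exc:  # noqa: BLE001 - field-level isolation
            logger.error("field %s skipped: %s", field_path, exc)
            failures.append({"field": field_path, "error": str(exc)})
            log["fields"].append({"field": field_path, "status": "failed", "error": str(exc)})

    summaries: list[AnimalSummary] = []
    for animal in sorted(tables_by_animal):
        meta = meta_by_animal[animal]
        panel = ASSAY_PANELS.get(str(meta["assay"]), ASSAY_PANELS["TH-panel"])
        summaries.append(
            aggregate_animal(
                tables_by_animal[animal],
                animal_id=animal,
                channel_map=panel,
                thresholds=config.positivity_thresholds or None,
                group=meta["group"],
            )
        )

    if summaries:
        metric_table = build_metric_table(summaries)
        animals = metric_table.copy()
        animals.insert(0, "group", [s.group for s in sorted(summaries, key=lambda s: s.animal_id)])
        animals.insert(1, "n_fields", [s.n_fields for s in sorted(summaries, key=lambda s: s.animal_id)])
        animals.insert(2, "n_cells", [s.n_cells for s in sorted(summaries, key=lambda s: s.animal_id)])
        animals.to_csv(out / "animals.csv")
    else:
        metric_table = pd.DataFrame()

    if behavior is not None:
        _run_stats(out, metric_table, behavior)

    log["n_failed"] = len(failures)
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return BatchResult(
        output_dir=out,
        n_fields_ok=sum(1 for f in log["fields"] if f["status"] == "ok"),
        n_fields_failed=len(failures),
        failures=failures,
        summaries=summaries,
    )


def _run_stats(out: Path, metric_table: pd.DataFrame, behavior_path) -> None:
    behavior = rio.read_behavior_csv(behavior_path)
    pheno = phenotype_quartiles(behavior)
    pd.DataFrame(
        {"phenotype": pheno.phenotype, "final3_mean_ml": pheno.statistic}
    ).rename_axis("animal_id").sort_index().to_csv(out / "phenotypes.csv")

    if metric_table.empty:
        return
    shared = metric_table.index.intersection(pheno.phenotype.index)
    hd = [a for a in shared if pheno.phenotype[a] == "HD"]
    ld = [a for a in shared if pheno.phenotype[a] == "LD"]
    if hd and ld:
        rows = []
        for col in metric_table.columns:
            if not col.startswith("total_"):
                continue
            res = kruskal_wallis(metric_table.loc[hd, col], metric_table.loc[ld, col])
            rows.append({"metric": col, "H": res.H, "df": res.df, "p": res.p})
        pd.DataFrame(rows, columns=["metric", "H", "df", "p"]).to_csv(
            out / "kruskal_hd_vs_ld.csv", index=False
        )
    if len(shared) >= 4:
        matrix = spearman_bh(behavior.intake.loc[shared], metric_table.loc[shared])
        rio.write_correlation_csv(matrix, out / "correlation")
        rio.plot_correlation_heatmap(matrix, out / "correlation_heatmap.png")


@dataclass
class PreviewResult:
    """Counts and overlay produced by :func:`tune_preview`."""

    spot_counts: dict[int, int]
    n_nuclei: int
    figure_path: Path | None


def tune_preview(
    field,
    config: RunConfig,
    out_path: str | Path | None = None,
) -> PreviewResult:
    """Render detections and nucleus outlines for visual threshold tuning.

    Never mutates the batch config; meant to be run on a sample field
    until the detections look right, after which the chosen parameters
    are frozen for the whole batch.
    """
    spots, labels, _ = process_field(field, config)
    counts = {c: int(len(spots.for_channel(c))) for c in PROBE_CHANNELS}

    fig_path = None
    if out_path is not None:
        import matplotlib

        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt
        from skimage.segmentation import find_boundaries

        outline = find_boundaries(labels.labels, mode="outer")
        fig, axes = plt.subplots(2, 2, figsize=(9, 9))
        for ax, c in zip(axes.ravel(), (1, 2, 3, 4)):
            plane = field.channel(c).pixels
            ax.imshow(plane, cmap="gray")
            ys, xs = np.nonzero(outline)
            ax.plot(xs, ys, ".", color="cyan", markersize=0.4)
            if c != 3:
                ch = spots.for_channel(c)
                ax.plot(ch[:, 0], ch[:, 1], "o", mfc="none", mec="red", markersize=5)
                ax.set_title(f"channel {c}: {counts[c]} dots (th={config.thresholds[c]})")
            else:
                ax.set_title(f"DAPI: {labels.n_nuclei} nuclei")
            ax.axis("off")
        fig.tight_layout()
        fig_path = Path(out_path)
        fig.savefig(fig_path, dpi=120)
        plt.close(fig)
    return PreviewResult(spot_counts=counts, n_nuclei=labels.n_nuclei, figure_path=fig_path)
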