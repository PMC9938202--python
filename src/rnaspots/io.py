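"""Reading and writing the pipeline's file formats.

Images travel as multi-channel TIFF (channel axis first), label maps as
16-bit single-channel TIFF, and all tables as CSV: spot tables
(field_id, channel, x, y, intensity), per-nucleus tables, behaviour
tables (animal_id, session, intake_ml) and correlation matrices.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .detection import SpotSet
from .quantify import CellCountTable
from .segmentation import NucleusLabelMap
from .stats import BehaviorTable, CorrelationMatrix
from .synthetic import MultiplexField

__all__ = [
    "write_field_tiff",
    "read_field_tiff",
    "write_label_tiff",
    "read_label_tiff",
    "write_spots_csv",
    "write_cell_table_csv",
    "write_behavior_csv",
    "read_behavior_csv",
    "write_correlation_csv",
    "plot_correlation_heatmap",
]


def write_field_tiff(field: MultiplexField, path: str | Path) -> None:
    tifffile.imwrite(str(path), field.image.astype(np.float32), photometric="minisblack")


def read_field_tiff(path: str | Path, **meta) -> MultiplexField:
    img = tifffile.imread(str(path))
    if img.ndim != 3:
        raise ValueError(f"{path}: expected a multi-channel TIFF, got shape {img.shape}")
    if img.shape[0] != 4 and img.shape[-1] == 4:  # channel-last stacks
        img = np.moveaxis(img, -1, 0)
    meta.setdefault("field_id", Path(path).stem)
    return MultiplexField(img.astype(float), **meta)


def write_label_tiff(labels: NucleusLabelMap, path: str | Path) -> None:
    if labels.n_nuclei > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label TIFF")
    tifffile.imwrite(str(path), labels.labels.astype(np.uint16))


def read_label_tiff(path: str | Path) -> NucleusLabelMap:
    return NucleusLabelMap(tifffile.imread(str(path)).astype(np.int32))


def write_spots_csv(spots: SpotSet, path: str | Path, field_id: str = "field") -> None:
    frame = pd.DataFrame(spots.spots, columns=["x", "y", "channel", "intensity"])
    frame.insert(0, "field_id", field_id)
    frame = frame.astype({"x": int, "y": int, "channel": int})
    frame.to_csv(path, index=False)


def write_cell_table_csv(table: CellCountTable, path: str | Path) -> None:
    table.cells.to_csv(path, index=False)


def write_behavior_csv(behavior: BehaviorTable, path: str | Path) -> None:
    long = behavior.intake.rename_axis("animal_id").reset_index().melt(
        id_vars="animal_id", var_name="session", value_name="intake_ml"
    )
    long = long.sort_values(["animal_id", "session"]).reset_index(drop=True)
    long.to_csv(path, index=False)


def read_behavior_csv(
    path: str | Path, baseline_sessions: int = 2, final_window: int = 3
) -> BehaviorTable:
    long = pd.read_csv(path)
    wide = long.pivot(index="animal_id", columns="session", values="intake_ml")
    wide.columns = wide.columns.astype(int)
    wide = wide.sort_index(axis=1)
    return BehaviorTable(
        intake=wide, baseline_sessions=baseline_sessions, final_window=final_window
    )


def write_correlation_csv(matrix: CorrelationMatrix, prefix: str | Path) -> list[Path]:
    """Write r / p / q / significance as four CSVs sharing a prefix."""
    prefix = Path(prefix)
    written = []
    for name, frame in [
        ("r", matrix.r),
        ("p", matrix.p),
        ("q", matrix.q),
        ("significant", matrix.significant),
    ]:
        out = prefix.with_name(prefix.name + f"_{name}.csv")
        frame.rename_axis("session").to_csv(out)
        written.append(out)
    return written


def plot_correlation_heatmap(matrix: CorrelationMatrix, path: str | Path) -> None:
    """Render the r matrix as a heat map, flagging BH-significant cells."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    r = matrix.r
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.6 * len(r.columns) + 2), max(3.0, 0.3 * len(r) + 1))
    )
    im = ax.imshow(r.to_numpy(), vmin=-1, vmax=1, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(len(r.columns)), r.columns, rotation=60, ha="right", fontsize=7)
    ax.set_yticks(range(len(r)), r.index, fontsize=7)
    ax.set_ylabel("session")
    for i in range(len(r)):
        for j in range(len(r.columns)):
            val = r.iloc[i, j]
            if np.isnan(val):
                continue
            mark = "*" if bool(matrix.significant.iloc[i, j]) else ""
            ax.text(j, i, f"{val:.2f}{mark}", ha="center", va="center", fontsize=5)
    fig.colorbar(im, ax=ax, label="Spearman r (* = BH-significant)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
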