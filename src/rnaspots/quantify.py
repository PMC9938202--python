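"""Dot-to-nucleus assignment, per-cell counting and animal aggregation.

A detected mRNA dot is attributed to a nucleus if it lies within
``max_dist`` pixels (default 10, inclusive) of that nucleus' mask,
where the distance is the Euclidean distance from the dot's pixel to
the nearest pixel of the mask (0 for dots inside the nucleus).  A dot
within reach of several nuclei goes to the nearest one; exact ties go
to the lower nucleus label so assignment is deterministic.  Dots
farther than ``max_dist`` from every nucleus are counted as unassigned
per channel, so dots are conserved: assigned + unassigned = detected.

Cells are then flagged positive for each marker when their copy count
reaches the marker's threshold (default 1 copy), which partitions the
cells into marker-combination ensembles (e.g. Arc+/TH+/zif268-), and
field tables are summed per animal before any group statistic.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

from .detection import PROBE_CHANNELS, SpotSet
from .exceptions import ConfigurationError
from .segmentation import NucleusLabelMap

__all__ = [
    "CellCountTable",
    "AnimalSummary",
    "ASSAY_PANELS",
    "assign_spots",
    "positivity",
    "ensemble_percentages",
    "aggregate_animal",
    "group_mean",
]

logger = logging.getLogger(__name__)

#: Channel -> marker maps for the two multiplex panels.  The channel
#: order within a panel is a fixed convention, recorded in every output.
ASSAY_PANELS: dict[str, dict[int, str]] = {
    "TH-panel": {1: "TH", 2: "zif268", 4: "Arc"},
    "GFAP-panel": {1: "GFAP", 2: "zif268", 4: "Arc"},
}

COUNT_COLUMNS = [f"count_ch{c}" for c in PROBE_CHANNELS]


@dataclass
class CellCountTable:
    """Per-nucleus per-channel mRNA copy counts for one field.

    ``cells`` has one row per nucleus: field_id, nucleus_id, x, y
    (centroid, px), area (px^2) and integer columns count_ch1,
    count_ch2, count_ch4.  ``unassigned`` counts the dots of each
    channel that were farther than the assignment radius from every
    nucleus.
    """

    cells: pd.DataFrame
    unassigned: dict[int, int] = field(default_factory=dict)
    field_id: str = "field"

    def total(self, channel_id: int) -> int:
        return int(self.cells[f"count_ch{channel_id}"].sum())

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class AnimalSummary:
    """Animal-level totals and ensemble percentages.

    ``totals``: total mRNA copies per marker, summed over the animal's
    fields.  ``ensemble_pct``: percentage of the animal's cells in each
    marker-positivity combination; the combinations partition the cells,
    so the percentages sum to 100 (None when the animal has no cells).
    """

    animal_id: str
    group: str | None
    n_fields: int
    n_cells: int
    totals: dict[str, int]
    ensemble_pct: pd.Series | None
    positivity_thresholds: dict[str, int]


def _spot_distances(
    xy: np.ndarray, labels: np.ndarray, max_dist: float
) -> tuple[np.ndarray, np.ndarray]:
    """Nearest nucleus and mask distance per spot, searching only the
    (2*max_dist+1)^2 window around each spot; exact for d <= max_dist."""
    h, w = labels.shape
    r = int(math.ceil(max_dist))
    owner = np.zeros(len(xy), dtype=np.int32)
    dist = np.full(len(xy), np.inf)
    for i, (x, y) in enumerate(xy):
        xi, yi = int(round(x)), int(round(y))
        x0, x1 = max(0, xi - r - 1), min(w, xi + r + 2)
        y0, y1 = max(0, yi - r - 1), min(h, yi + r + 2)
        win = labels[y0:y1, x0:x1]
        fg = np.argwhere(win > 0)
        if len(fg) == 0:
            continue
        d = np.hypot(fg[:, 1] + x0 - x, fg[:, 0] + y0 - y)
        labs = win[fg[:, 0], fg[:, 1]]
        ok = d <= max_dist
        if not ok.any():
            continue
        d, labs = d[ok], labs[ok]
        best = d.min()
        # exact ties at the minimum distance: lowest label wins
        owner[i] = labs[np.isclose(d, best)].min()
        dist[i] = best
    return owner, dist


def assign_spots(
    spots: SpotSet,
    labels: NucleusLabelMap,
    max_dist: float = 10.0,
    field_id: str = "field",
) -> CellCountTable:
    """Assign detected dots to nuclei by the inclusive ``max_dist`` rule.

    Every nucleus appears in the output, including those with zero
    dots.  Raises on a dimension mismatch between the spots' source
    image and the label map.
    """
    if spots.image_shape is not None and tuple(spots.image_shape) != labels.shape:
        raise ValueError(
            f"spots come from an image of shape {spots.image_shape} but the "
            f"label map has shape {labels.shape}"
        )
    n = labels.n_nuclei
    areas = labels.areas()
    centroids = labels.centroids()
    counts = {c: np.zeros(n, dtype=int) for c in PROBE_CHANNELS}
    unassigned = {c: 0 for c in PROBE_CHANNELS}

    for c in PROBE_CHANNELS:
        rows = spots.for_channel(c)
        if len(rows) == 0:
            continue
        owner, _ = _spot_distances(rows[:, :2], labels.labels, max_dist)
        for o in owner:
            if o > 0:
                counts[c][o - 1] += 1
            else:
                unassigned[c] += 1

    cells = pd.DataFrame(
        {
            "field_id": field_id,
            "nucleus_id": np.arange(1, n + 1),
            "x": [centroids[i][0] for i in range(1, n + 1)],
            "y": [centroids[i][1] for i in range(1, n + 1)],
            "area": [areas[i] for i in range(1, n + 1)],
            **{f"count_ch{c}": counts[c] for c in PROBE_CHANNELS},
        }
    )
    return CellCountTable(cells=cells, unassigned=unassigned, field_id=field_id)


def positivity(
    table: CellCountTable | pd.DataFrame,
    channel_map: dict[int, str],
    thresholds: dict[str, int] | None = None,
) -> pd.DataFrame:
    """Marker-positivity flags per cell.

    A cell is positive for a marker iff its copy count in that marker's
    channel is >= the marker's threshold (default 1 copy for every
    marker).  Unknown marker names in ``thresholds`` are a
    configuration error.
    """
    cells = table.cells if isinstance(table, CellCountTable) else table
    markers = list(channel_map.values())
    thresholds = dict(thresholds or {})
    unknown = set(thresholds) - set(markers)
    if unknown:
        raise ConfigurationError(f"unknown marker(s) in thresholds: {sorted(unknown)}")
    for m in markers:
        thresholds.setdefault(m, 1)
    if any(t < 1 for t in thresholds.values()):
        raise ConfigurationError("positivity thresholds must be >= 1 copy")
    flags = {}
    for channel, marker in channel_map.items():
        flags[marker] = cells[f"count_ch{channel}"] >= thresholds[marker]
    return pd.DataFrame(flags, index=cells.index)


def ensemble_percentages(flags: pd.DataFrame) -> pd.Series:
    """Percentage of cells in each marker-positivity combination.

    The 2^k combinations (e.g. ``TH+/zif268-/Arc+``) partition the
    cells exhaustively, so the returned percentages sum to 100.
    """
    markers = list(flags.columns)
    n = len(flags)
    if n == 0:
        raise ValueError("no cells: ensemble percentages undefined")
    out = {}
    for combo in product([True, False], repeat=len(markers)):
        name = "/".join(f"{m}{'+' if pos else '-'}" for m, pos in zip(markers, combo))
        match = np.ones(n, dtype=bool)
        for m, pos in zip(markers, combo):
            match &= flags[m].to_numpy() == pos
        out[name] = 100.0 * match.sum() / n
    return pd.Series(out, name="pct_cells")


def aggregate_animal(
    tables: list[CellCountTable],
    animal_id: str,
    channel_map: dict[int, str],
    thresholds: dict[str, int] | None = None,
    group: str | None = None,
) -> AnimalSummary:
    """Sum one animal's field tables and compute its ensemble profile.

    Totals are column sums over all the animal's fields; ensemble
    percentages are computed over all its cells pooled.  An animal with
    zero cells gets ``ensemble_pct=None`` with a logged warning.
    """
    if not tables:
        raise ValueError("aggregate_animal needs at least one field table")
    all_cells = pd.concat([t.cells for t in tables], ignore_index=True)
    totals = {
        marker: int(all_cells[f"count_ch{channel}"].sum())
        for channel, marker in channel_map.items()
    }
    flags = positivity(all_cells, channel_map, thresholds)
    resolved = {m: (thresholds or {}).get(m, 1) for m in channel_map.values()}
    if len(all_cells) == 0:
        logger.warning("animal %s has zero cells; ensemble percentages undefined", animal_id)
        pct = None
    else:
        pct = ensemble_percentages(flags)
    return AnimalSummary(
        animal_id=animal_id,
        group=group,
        n_fields=len(tables),
        n_cells=len(all_cells),
        totals=totals,
        ensemble_pct=pct,
        positivity_thresholds=resolved,
    )


def group_mean(summaries: list[AnimalSummary]) -> pd.Series:
    """Group-level means of animal totals and ensemble percentages.

    The animal, not the cell, is the unit: each animal contributes one
    value per quantity regardless of its cell count.
    """
    if not summaries:
        raise ValueError("group_mean needs at least one animal")
    rows = []
    for s in summaries:
        row = {f"total_{m}": v for m, v in s.totals.items()}
        if s.ensemble_pct is not None:
            row.update(s.ensemble_pct.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).mean()
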