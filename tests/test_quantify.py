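"""Assignment against a brute-force oracle; positivity and aggregation."""

import numpy as np
import pandas as pd
import pytest

from rnaspots.detection import SpotSet
from rnaspots.exceptions import ConfigurationError
from rnaspots.quantify import (
    ASSAY_PANELS,
    CellCountTable,
    aggregate_animal,
    assign_spots,
    ensemble_percentages,
    group_mean,
    positivity,
)
from rnaspots.segmentation import NucleusLabelMap


def brute_force_owner(xy, labels, max_dist):
    """Exhaustive oracle: distance from every spot to every mask pixel."""
    owners = []
    coords = {
        lab: np.argwhere(labels == lab) for lab in range(1, labels.max() + 1)
    }
    for x, y in xy:
        best_lab, best_d = 0, np.inf
        for lab in sorted(coords):
            pix = coords[lab]
            if len(pix) == 0:
                continue
            d = np.hypot(pix[:, 1] - x, pix[:, 0] - y).min()
            if d < best_d - 1e-12:  # strict improvement; ties keep lower label
                best_lab, best_d = lab, d
        owners.append(best_lab if best_d <= max_dist else 0)
    return np.array(owners)


def spotset(xy, channel=1, shape=None):
    rows = [(x, y, channel, 99.0) for x, y in xy]
    return SpotSet(np.array(rows, dtype=float), image_shape=shape)


def random_instance(rng, size=60):
    """Small random label map (disc nuclei) + random dots."""
    labels = np.zeros((size, size), dtype=np.int32)
    n_nuclei = rng.integers(1, 11)
    yy, xx = np.mgrid[0:size, 0:size]
    for lab in range(1, n_nuclei + 1):
        cx, cy = rng.uniform(5, size - 5, 2)
        r = rng.uniform(2, 6)
        m = (xx - cx) ** 2 + (yy - cy) ** 2 <= r**2
        labels[m & (labels == 0)] = lab
    # contiguous relabel (some discs may be fully hidden)
    present = np.unique(labels[labels > 0])
    remap = {old: new for new, old in enumerate(present, start=1)}
    labels = np.vectorize(lambda v: remap.get(v, 0))(labels).astype(np.int32)
    n_dots = rng.integers(1, 101)
    xy = rng.integers(0, size, size=(n_dots, 2))
    return labels, xy


class TestAssignSpots:
    def test_spot_inside_nucleus_assigned_to_it(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[10:20, 10:20] = 1
        table = assign_spots(spotset([(15, 15)]), NucleusLabelMap(labels))
        assert table.cells.loc[0, "count_ch1"] == 1
        assert table.unassigned[1] == 0

    def test_distance_exactly_ten_is_assigned_inclusive(self):
        labels = np.zeros((40, 40), dtype=int)
        labels[5:15, 5:15] = 1
        # nearest mask pixel (14, 14); spot 10 px to the right
        table = assign_spots(spotset([(24, 14)]), NucleusLabelMap(labels))
        assert table.cells.loc[0, "count_ch1"] == 1
        table = assign_spots(spotset([(25, 14)]), NucleusLabelMap(labels))
        assert table.unassigned[1] == 1

    def test_tie_between_nuclei_goes_to_lower_label(self):
        labels = np.zeros((20, 40), dtype=int)
        labels[:, 5] = 2  # column of label 2 at x=5
        labels[:, 15] = 1  # column of label 1 at x=15
        # spot at x=10 is exactly 5 px from both
        table = assign_spots(spotset([(10, 10)]), NucleusLabelMap(labels))
        row = table.cells.set_index("nucleus_id")
        assert row.loc[1, "count_ch1"] == 1
        assert row.loc[2, "count_ch1"] == 0

    def test_matches_brute_force_oracle_on_random_instances(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            labels, xy = random_instance(rng)
            lm = NucleusLabelMap(labels)
            table = assign_spots(spotset(xy), lm)
            oracle = brute_force_owner(xy, labels, 10.0)
            got = np.zeros(lm.n_nuclei, dtype=int)
            for o in oracle:
                if o > 0:
                    got[o - 1] += 1
            assert np.array_equal(
                table.cells["count_ch1"].to_numpy(), got
            )
            assert table.unassigned[1] == int((oracle == 0).sum())

    def test_conservation_assigned_plus_unassigned_equals_detected(self):
        rng = np.random.default_rng(5)
        labels, xy = random_instance(rng)
        table = assign_spots(spotset(xy), NucleusLabelMap(labels))
        assert table.cells["count_ch1"].sum() + table.unassigned[1] == len(xy)

    def test_dimension_mismatch_rejected(self):
        labels = NucleusLabelMap(np.zeros((32, 32), dtype=int))
        with pytest.raises(ValueError):
            assign_spots(spotset([(1, 1)], shape=(64, 64)), labels)

    def test_nuclei_with_zero_dots_still_listed(self):
        labels = np.zeros((32, 32), dtype=int)
        labels[2:8, 2:8] = 1
        labels[20:28, 20:28] = 2
        table = assign_spots(spotset([(5, 5)]), NucleusLabelMap(labels))
        assert len(table.cells) == 2
        assert table.cells.set_index("nucleus_id").loc[2, "count_ch1"] == 0


TABLE_COLUMNS = ["field_id", "nucleus_id", "x", "y", "area",
                 "count_ch1", "count_ch2", "count_ch4"]


def make_table(counts, field_id="f1"):
    rows = [
        {"field_id": field_id, "nucleus_id": i, "x": 0.0, "y": 0.0,
         "area": 200, "count_ch1": c1, "count_ch2": c2, "count_ch4": c4}
        for i, (c1, c2, c4) in enumerate(counts, start=1)
    ]
    return CellCountTable(
        cells=pd.DataFrame(rows, columns=TABLE_COLUMNS), field_id=field_id
    )


class TestPositivityAndAggregation:
    def test_positivity_definition_at_threshold_one(self):
        table = make_table([(4, 0, 2)])
        flags = positivity(table, ASSAY_PANELS["TH-panel"])
        assert flags.loc[0, "TH"] and flags.loc[0, "Arc"]
        assert not flags.loc[0, "zif268"]

    def test_all_zero_counts_all_negative(self):
        flags = positivity(make_table([(0, 0, 0)]), ASSAY_PANELS["GFAP-panel"])
        assert not flags.any().any()

    def test_threshold_respected(self):
        flags = positivity(
            make_table([(3, 3, 3)]), ASSAY_PANELS["TH-panel"], {"TH": 4}
        )
        assert not flags.loc[0, "TH"] and flags.loc[0, "zif268"]

    def test_unknown_marker_rejected(self):
        with pytest.raises(ConfigurationError):
            positivity(make_table([(1, 1, 1)]), ASSAY_PANELS["TH-panel"], {"nope": 1})

    def test_ensemble_percentages_partition_to_100(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.integers(0, 4, size=(50, 3)))
        pct = ensemble_percentages(positivity(table, ASSAY_PANELS["TH-panel"]))
        assert len(pct) == 8
        assert pct.sum() == pytest.approx(100.0)

    def test_planted_negative_fraction_recovered(self):
        # half the cells have zero zif268 by construction
        counts = [(2, 0, 1)] * 10 + [(2, 3, 1)] * 10
        flags = positivity(make_table(counts), ASSAY_PANELS["TH-panel"])
        assert (~flags["zif268"]).mean() == 0.5

    def test_animal_totals_are_field_sums(self):
        t1 = make_table([(4, 1, 0), (6, 0, 2)], "f1")  # ch1 total 10
        t2 = make_table([(15, 2, 3)], "f2")  # ch1 total 15
        s = aggregate_animal([t1, t2], "ratA", ASSAY_PANELS["TH-panel"])
        assert s.totals["TH"] == 25
        assert s.n_fields == 2 and s.n_cells == 3
        assert s.ensemble_pct.sum() == pytest.approx(100.0)

    def test_group_mean_averages_animals_not_cells(self):
        a = aggregate_animal([make_table([(25, 0, 0)])], "a", ASSAY_PANELS["TH-panel"])
        b = aggregate_animal(
            [make_table([(5, 0, 0), (10, 0, 0), (20, 0, 0)])], "b",
            ASSAY_PANELS["TH-panel"],
        )
        gm = group_mean([a, b])
        assert gm["total_TH"] == pytest.approx(30.0)

    def test_zero_cell_animal_reports_missing_percentages(self, caplog):
        empty = CellCountTable(cells=make_table([]).cells)
        s = aggregate_animal([empty], "ratZ", ASSAY_PANELS["TH-panel"])
        assert s.ensemble_pct is None
        assert s.n_cells == 0
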