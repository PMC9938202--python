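"""Statistics against hand formulas and closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from rnaspots.stats import (
    BehaviorTable,
    kruskal_wallis,
    pairwise_kruskal,
    phenotype_quartiles,
    spearman_bh,
)


def behavior_from_matrix(arr, animals=None):
    arr = np.asarray(arr, dtype=float)
    animals = animals or [f"a{i:02d}" for i in range(arr.shape[0])]
    frame = pd.DataFrame(
        arr, index=pd.Index(animals, name="animal_id"),
        columns=range(1, arr.shape[1] + 1),
    )
    return BehaviorTable(intake=frame)


def bh_closed_form(p):
    """Step-up FDR oracle: q_(i) = min_{j>=i} ( m * p_(j) / j ), by rank."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = np.minimum.accumulate((m * p[order] / np.arange(1, m + 1))[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


class TestPhenotypeQuartiles:
    def test_textbook_eight_animal_split(self):
        arr = np.tile(np.arange(1.0, 9.0)[:, None], (1, 5))  # final-3 means 1..8
        ph = phenotype_quartiles(behavior_from_matrix(arr))
        assert ph.hd == ["a06", "a07"]  # means 7 and 8
        assert ph.ld == ["a00", "a01"]  # means 1 and 2
        assert len(ph.intermediate) == 4

    def test_all_identical_uses_documented_tie_break(self):
        ph = phenotype_quartiles(behavior_from_matrix(np.full((8, 5), 10.0)))
        assert len(ph.hd) == 2 and len(ph.ld) == 2
        assert ph.ld == ["a00", "a01"]  # animal-id order is the final tie-break

    def test_boundary_tie_resolved_by_earlier_sessions(self):
        arr = np.full((4, 6), 5.0)
        arr[:, -3:] = [[9], [9], [1], [1]]  # two-way ties at both quartiles
        arr[0, 0] = 20.0  # animal 0 drank more earlier -> ranks above animal 1
        ph = phenotype_quartiles(behavior_from_matrix(arr))
        assert ph.hd == ["a00"] and ph.ld == ["a02"]

    def test_permutation_invariant(self):
        rng = np.random.default_rng(0)
        arr = rng.uniform(5, 40, size=(12, 8))
        bt = behavior_from_matrix(arr)
        perm = rng.permutation(12)
        bt_perm = BehaviorTable(intake=bt.intake.iloc[perm])
        a, b = phenotype_quartiles(bt), phenotype_quartiles(bt_perm)
        assert a.hd == b.hd and a.ld == b.ld

    def test_fewer_than_four_animals_rejected(self):
        with pytest.raises(ValueError):
            phenotype_quartiles(behavior_from_matrix(np.ones((3, 5))))


class TestKruskalWallis:
    def test_hand_formula_no_ties(self):
        # ranks 1..6, R1=6, R2=15: H = 12/(6*7) * (36/3 + 225/3) - 3*7 = 3.857
        res = kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert res.H == pytest.approx(3.857, abs=5e-4)
        assert res.df == 1
        assert not res.degenerate

    def test_identical_groups_give_zero(self):
        res = kruskal_wallis([1, 2, 3], [1, 2, 3])
        assert res.H == pytest.approx(0.0, abs=1e-12)

    def test_all_equal_values_degenerate_flag(self):
        res = kruskal_wallis([7, 7, 7], [7, 7])
        assert res.H == 0.0 and res.degenerate and res.p == 1.0

    def test_matches_textbook_formula_on_random_groups(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            sizes = rng.integers(3, 8, size=rng.integers(2, 5))
            vals = rng.permutation(sizes.sum()) + 1.0  # distinct -> no ties
            groups, start = [], 0
            for s in sizes:
                groups.append(vals[start : start + s])
                start += s
            n = sizes.sum()
            ranks = vals  # values already are the ranks
            H = 12 / (n * (n + 1)) * sum(
                g.sum() ** 2 / len(g) for g in groups
            ) - 3 * (n + 1)
            assert kruskal_wallis(*groups).H == pytest.approx(H, rel=1e-10)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([1, 2], [])

    def test_pairwise_contrasts_cover_all_pairs(self):
        out = pairwise_kruskal(
            {"HD-B": [9, 8, 7], "LD-B": [1, 2, 3], "HD-NB": [5, 5, 6]}, bh=True
        )
        assert len(out) == 3
        assert (out["q"] >= out["p"] - 1e-12).all()


class TestSpearmanBH:
    def test_perfect_monotone_gives_plus_minus_one(self):
        drinking = pd.DataFrame(
            {1: [1, 2, 3, 4, 5]}, index=[f"a{i}" for i in range(5)]
        )
        metrics = pd.DataFrame(
            {"up": [2, 4, 6, 8, 10], "down": [10, 8, 6, 4, 2]},
            index=drinking.index,
        )
        cm = spearman_bh(drinking, metrics)
        assert cm.r.loc[1, "up"] == pytest.approx(1.0)
        assert cm.r.loc[1, "down"] == pytest.approx(-1.0)

    def test_bh_hand_case(self):
        # p = (.01,.02,.03,.04), m=4 -> all q = .04 by step-up minima
        assert np.allclose(bh_closed_form([0.01, 0.02, 0.03, 0.04]), 0.04)

    @settings(max_examples=1000, deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=1e-9, max_value=1.0), min_size=1, max_size=40)
    )
    def test_bh_matches_closed_form_property(self, pvals):
        q = multipletests(pvals, method="fdr_bh")[1]
        assert np.allclose(q, bh_closed_form(pvals), atol=1e-12)

    def test_spearman_equals_pearson_on_midranks(self):
        rng = np.random.default_rng(2)
        for _ in range(30):
            x = rng.integers(0, 10, size=12).astype(float)  # ties likely
            y = rng.integers(0, 10, size=12).astype(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                continue
            rho = sps.spearmanr(x, y).statistic
            pearson_on_ranks = sps.pearsonr(
                sps.rankdata(x), sps.rankdata(y)
            ).statistic
            assert rho == pytest.approx(pearson_on_ranks, rel=1e-12)

    def test_constant_metric_reported_missing_not_error(self):
        drinking = pd.DataFrame(
            {1: [1.0, 2, 3, 4, 5], 2: [2.0, 1, 4, 3, 5]},
            index=[f"a{i}" for i in range(5)],
        )
        metrics = pd.DataFrame({"flat": [7.0] * 5, "ok": [1.0, 2, 3, 4, 5]},
                               index=drinking.index)
        cm = spearman_bh(drinking, metrics)
        assert cm.r["flat"].isna().all()
        assert cm.r["ok"].notna().all()

    def test_q_at_least_p_and_significance_flags(self):
        rng = np.random.default_rng(3)
        drinking = pd.DataFrame(
            rng.uniform(0, 30, size=(10, 4)), columns=range(1, 5),
            index=[f"a{i}" for i in range(10)],
        )
        metrics = pd.DataFrame(
            {"m1": drinking[4] + rng.normal(0, 1, 10), "m2": rng.uniform(0, 1, 10)},
            index=drinking.index,
        )
        cm = spearman_bh(drinking, metrics)
        mask = cm.p.notna()
        assert (cm.q[mask] >= cm.p[mask] - 1e-12).all().all()
        assert cm.significant.to_numpy().dtype == bool

    def test_too_few_paired_animals_rejected(self):
        d = pd.DataFrame({1: [1.0, 2, 3]}, index=["a", "b", "c"])
        m = pd.DataFrame({"x": [1.0, 2, 3]}, index=["a", "b", "c"])
        with pytest.raises(ValueError):
            spearman_bh(d, m)
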