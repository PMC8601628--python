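import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from netpotential import (
    RepressionModel,
    build_gene_sets,
    build_target_map,
    candidate_mirnas,
    cocktail_loss,
    mirna_frequency_summary,
    rank_cocktails,
    rank_targets,
    repression_fraction,
    sensitivity_grid,
)

from conftest import brute_force_loss, enumerate_cocktails_brute


class TestRepressionFraction:
    @pytest.mark.parametrize(
        "c, expected",
        [(0, 0.0), (1, 0.0), (2, 0.4), (3, 0.6), (4, 0.8), (5, 1.0), (6, 1.0), (10, 1.0)],
    )
    def test_default_model(self, c, expected):
        assert repression_fraction(c) == pytest.approx(expected)

    def test_saturation_caps_high_slopes(self):
        assert repression_fraction(2, RepressionModel(r=0.5)) == 1.0

    def test_minimum_multiplicity_is_two_by_default(self):
        model = RepressionModel()
        smallest = next(c for c in range(0, 10) if repression_fraction(c, model) > 0)
        assert smallest == 2

    def test_negative_multiplicity_rejected(self):
        with pytest.raises(ValueError):
            repression_fraction(-1)

    def test_invalid_model_rejected(self):
        with pytest.raises(ValueError):
            RepressionModel(r=0.0)
        with pytest.raises(ValueError):
            RepressionModel(r=1.5)

    @given(
        c=st.integers(min_value=0, max_value=30),
        r=st.floats(min_value=0.01, max_value=1.0),
        min_mult=st.integers(min_value=1, max_value=5),
    )
    @settings(derandomize=True)
    def test_bounded_and_non_decreasing(self, c, r, min_mult):
        model = RepressionModel(r=r, min_multiplicity=min_mult)
        a = repression_fraction(c, model)
        assert 0.0 <= a <= 1.0
        assert repression_fraction(c + 1, model) >= a


def simple_ranked(values: dict[str, float]):
    return rank_targets({"S1": values})


class TestBuildGeneSets:
    def test_overlapping_gene_counts_as_target_only(self):
        ranked = simple_ranked({"A": 5.0, "B": 4.0, "C": 1.0})
        sets = build_gene_sets(ranked, ["A", "C"], top_k=2)
        assert sets.targets == ["A", "B"]
        assert sets.housekeeping == {"C"}
        assert sets.signed_delta_g["A"] == -5.0
        assert sets.signed_delta_g["C"] == 1.0

    def test_top_k_one(self):
        sets = build_gene_sets(simple_ranked({"A": 2.0, "B": 1.0}), ["B"], top_k=1)
        assert sets.targets == ["A"]

    def test_all_equal_delta_g_selects_lexicographically(self):
        sets = build_gene_sets(simple_ranked({"C": 1.0, "A": 1.0, "B": 1.0}), ["C"], top_k=2)
        assert sets.targets == ["A", "B"]

    def test_top_k_exceeding_universe_rejected(self):
        with pytest.raises(ValueError):
            build_gene_sets(simple_ranked({"A": 1.0}), ["B"], top_k=2)

    def test_empty_housekeeping_rejected(self):
        with pytest.raises(ValueError):
            build_gene_sets(simple_ranked({"A": 1.0}), [], top_k=1)


class TestCandidateMirnas:
    tmap = build_target_map(
        [("m2", "T1", 2), ("m2", "T2", 2), ("m1", "T1", 2), ("m3", "X", 2)]
    )

    def test_at_least_two_hits_is_inclusive(self):
        assert candidate_mirnas(self.tmap, ["T1", "T2"], min_hits=2) == ["m2"]

    def test_single_hit_excluded(self):
        assert "m1" not in candidate_mirnas(self.tmap, ["T1", "T2"], min_hits=2)

    def test_min_hits_zero_returns_everything(self):
        assert candidate_mirnas(self.tmap, ["T1"], min_hits=0) == ["m1", "m2", "m3"]

    def test_empty_result_is_not_an_error(self):
        assert candidate_mirnas(self.tmap, ["Z1", "Z2"], min_hits=2) == []


class TestCocktailLoss:
    def toy(self, promisc_hits_housekeeping: bool):
        rows = [(m, "T", 3) for m in ("m1", "m2", "m3")]
        if promisc_hits_housekeeping:
            rows += [(m, "H", 3) for m in ("m1", "m2", "m3")]
        tmap = build_target_map(rows)
        ranked = simple_ranked({"T": 5.0, "H": 3.0})
        sets = build_gene_sets(ranked, ["H"], top_k=1)
        return tmap, sets

    def test_three_mirnas_on_target_only(self):
        tmap, sets = self.toy(promisc_hits_housekeeping=False)
        score = cocktail_loss({"m1", "m2", "m3"}, tmap, sets)
        assert score.loss == pytest.approx(-0.6 * 5.0)  # A(3) = 0.6
        assert score.n_targets_hit == 1 and score.n_housekeeping_hit == 0

    def test_housekeeping_hits_offset_target_gain(self):
        tmap, sets = self.toy(promisc_hits_housekeeping=True)
        score = cocktail_loss({"m1", "m2", "m3"}, tmap, sets)
        assert score.loss == pytest.approx(0.6 * 3.0 - 0.6 * 5.0)
        assert score.n_housekeeping_hit == 1

    def test_no_cooperative_hits_gives_zero_loss(self):
        tmap = build_target_map([("m1", "T", 3), ("m2", "H", 3), ("m3", "X", 3)])
        ranked = simple_ranked({"T": 5.0, "H": 3.0})
        sets = build_gene_sets(ranked, ["H"], top_k=1)
        score = cocktail_loss({"m1", "m2", "m3"}, tmap, sets)
        assert score.loss == 0.0
        assert score.multiplicity == {"T": 1, "H": 1}

    def test_wrong_cocktail_size_rejected(self):
        tmap, sets = self.toy(False)
        with pytest.raises(ValueError):
            cocktail_loss({"m1", "m2"}, tmap, sets, k=3)


def random_instance(seed, n_mirnas=8, n_targets=6, n_hk=6):
    rng = np.random.default_rng(seed)
    targets = [f"T{i}" for i in range(n_targets)]
    hk = [f"H{i}" for i in range(n_hk)]
    values = {g: float(rng.lognormal(1.0, 0.8)) for g in targets + hk}
    # targets must outrank housekeeping genes in mean ΔG for build_gene_sets
    values = dict(values)
    for g in targets:
        values[g] += 100.0
    ranked = simple_ranked(values)
    rows = []
    for i in range(n_mirnas):
        for g in targets + hk:
            if rng.random() < 0.4:
                rows.append((f"m{i}", g, int(rng.integers(2, 6))))
    for i in range(n_mirnas):  # guarantee candidacy
        rows += [(f"m{i}", targets[0], 3), (f"m{i}", targets[1], 3)]
    tmap = build_target_map(rows)
    sets = build_gene_sets(ranked, hk, top_k=n_targets)
    return tmap, sets


class TestRankCocktails:
    def test_three_candidates_give_one_cocktail(self):
        tmap, sets = random_instance(0, n_mirnas=3)
        assert len(rank_cocktails(["m0", "m1", "m2"], 3, tmap, sets)) == 1

    def test_binomial_enumeration_count(self):
        tmap, sets = random_instance(1, n_mirnas=6)
        ranking = rank_cocktails([f"m{i}" for i in range(6)], 3, tmap, sets)
        assert len(ranking) == math.comb(6, 3)
        assert sorted(s.rank for s in ranking) == list(range(1, 21))

    def test_too_few_candidates_rejected(self):
        tmap, sets = random_instance(2, n_mirnas=2)
        with pytest.raises(ValueError):
            rank_cocktails(["m0", "m1"], 3, tmap, sets)

    def test_equal_losses_tie_break_on_id_tuple(self):
        # two disjoint miRNA pairs with identical effects
        tmap = build_target_map(
            [("a1", "T0", 3), ("a2", "T0", 3), ("b1", "T0", 3), ("b2", "T0", 3),
             ("a1", "T1", 3), ("a2", "T1", 3), ("b1", "T1", 3), ("b2", "T1", 3)]
        )
        ranked = simple_ranked({"T0": 2.0, "T1": 1.0, "H": 0.5})
        sets = build_gene_sets(ranked, ["H"], top_k=2)
        ranking = rank_cocktails(["a1", "a2", "b1", "b2"], 2, tmap, sets)
        equal = [s.ids for s in ranking if s.loss == ranking[0].loss]
        assert equal == sorted(equal)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        tmap, sets = random_instance(seed)
        candidates = sorted(tmap.mirnas)
        ranking = rank_cocktails(candidates, 3, tmap, sets)
        oracle = enumerate_cocktails_brute(candidates, 3, tmap, sets)
        assert len(ranking) == len(oracle)
        for score in ranking:
            assert score.loss == pytest.approx(
                brute_force_loss(score.mirnas, tmap, sets), abs=1e-12
            )
        assert [s.ids for s in ranking] == [ids for _, ids in oracle]

    def test_loss_decomposes_into_signed_components(self):
        tmap, sets = random_instance(7)
        model = RepressionModel()
        for combo in itertools.combinations(sorted(tmap.mirnas), 3):
            score = cocktail_loss(frozenset(combo), tmap, sets, model)
            hk_part = sum(
                repression_fraction(score.multiplicity[g], model) * abs(sets.signed_delta_g[g])
                for g in sets.housekeeping
            )
            target_part = sum(
                repression_fraction(score.multiplicity[g], model) * abs(sets.signed_delta_g[g])
                for g in sets.targets
            )
            assert hk_part >= 0 and target_part >= 0
            assert score.loss == pytest.approx(hk_part - target_part, abs=1e-12)

    def test_dominance(self):
        """Hitting more targets and fewer housekeeping genes can only improve
        (lower) the loss."""
        targets = ["T0", "T1", "T2"]
        hk = ["H0", "H1"]
        values = {g: 10.0 - i for i, g in enumerate(targets)}
        values.update({g: 1.0 + i for i, g in enumerate(hk)})
        ranked = simple_ranked(values)
        sets = build_gene_sets(ranked, hk, top_k=3)
        base = [("m1", "T0", 3), ("m2", "T0", 3), ("m1", "T1", 3), ("m2", "T1", 3)]
        x = build_target_map(base + [("m1", "T2", 3), ("m2", "T2", 3)])
        y = build_target_map(base + [("m1", "H0", 3), ("m2", "H0", 3)])
        loss_x = cocktail_loss({"m1", "m2"}, x, sets).loss
        loss_y = cocktail_loss({"m1", "m2"}, y, sets).loss
        assert loss_x <= loss_y


class TestSensitivityGrid:
    def grid(self, seed=3):
        # generic (tie-free) ΔG values: exact loss ties then only arise from
        # identical multiplicity vectors, which tie consistently at every r
        rng = np.random.default_rng(seed + 100)
        tmap, _ = random_instance(seed)
        targets = [f"T{i}" for i in range(6)]
        hk = [f"H{i}" for i in range(6)]
        values = {g: float(100 + rng.random() * 10) for g in targets}
        values.update({g: float(rng.lognormal(0.5, 0.5)) for g in hk})
        ranked = simple_ranked(values)
        return ranked, hk, tmap

    def test_grid_has_one_cell_per_combination(self):
        ranked, hk, tmap = self.grid()
        grid = sensitivity_grid(
            ranked, hk, tmap, r_values=(0.1, 0.2, 0.3, 0.4, 0.5),
            top_k_values=(2, 4, 6), k=3,
        )
        assert len(grid.cells) == 15

    def test_ranking_invariant_to_r_below_saturation(self):
        # With k=3 the largest multiplicity is 3; for r <= 1/3 no gene
        # saturates, so losses scale linearly in r and the order is unchanged.
        ranked, hk, tmap = self.grid()
        grid = sensitivity_grid(ranked, hk, tmap, r_values=(0.1, 0.2, 0.3),
                                top_k_values=(4,), k=3)
        orders = [
            [s.ids for s in cell] for (r, _), cell in sorted(grid.cells.items())
        ]
        assert orders[0] == orders[1] == orders[2]

    def test_smaller_target_sets_are_prefixes(self):
        ranked, hk, tmap = self.grid()
        top5 = ranked.top(4)
        top10 = ranked.top(6)
        assert top10[:4] == top5


class TestFrequencySummary:
    def test_counts_and_totals(self):
        tmap, sets = random_instance(4)
        ranking = rank_cocktails(sorted(tmap.mirnas), 3, tmap, sets)
        freq = mirna_frequency_summary(ranking, n_head=10)
        assert freq["n_best"].sum() == 3 * 10
        assert freq["n_worst"].sum() == 3 * 10
        assert (freq >= 0).all().all()

    def test_absent_mirna_counts_zero(self):
        tmap, sets = random_instance(5)
        ranking = rank_cocktails(sorted(tmap.mirnas), 3, tmap, sets)
        freq = mirna_frequency_summary(ranking, n_head=1)
        present = set(ranking[0].mirnas) | set(ranking[-1].mirnas)
        absent = [m for m in freq.index if m not in present]
        if absent:
            assert freq.loc[absent, ["n_best", "n_worst"]].to_numpy().sum() == 0
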