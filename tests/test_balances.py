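"""Balance scores, variance conservation, ranking and subsetting."""

import numpy as np
import pandas as pd
import pytest

import balancekit as bk
from conftest import random_composition, random_sbp


def balances_via_contrast(data: bk.CompositionTable,
                          sbp: bk.SbpMatrix) -> np.ndarray:
    """Independent route: ilr through the contrast matrix, Psi @ ln(x)."""
    contrast = bk.sbp_to_contrast(sbp)
    logs = np.log(data.data[contrast.component_ids].to_numpy())
    return logs @ contrast.values.T


class TestComputeBalances:
    def test_first_fixture_sample_z1_oracle(self, expenditures,
                                            expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        gp = np.exp(np.mean(np.log([640.0, 328.0, 147.0])))
        gn = np.exp(np.mean(np.log([169.0, 196.0])))
        expected = np.sqrt(6.0 / 5.0) * np.log(gp / gn)
        assert table.scores.loc["i01", "z1"] == pytest.approx(expected,
                                                              abs=1e-12)
        assert expected == pytest.approx(0.596, abs=5e-4)

    def test_uniform_composition_gives_zero_everywhere(self, expenditures_sbp):
        data = bk.validate_composition(
            np.full((3, 5), 7.0),
            component_ids=expenditures_sbp.component_ids)
        table = bk.compute_balances(data, expenditures_sbp)
        np.testing.assert_allclose(table.values, 0.0, atol=1e-12)

    def test_fixture_z1_median_positive(self, expenditures, expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        assert table.summary.loc["z1", "median"] > 0

    def test_label_matching_ignores_column_order(self, expenditures,
                                                 expenditures_sbp):
        shuffled = bk.validate_composition(
            expenditures.data[["services", "alcohol", "housing",
                               "other", "foodstuffs"]])
        a = bk.compute_balances(expenditures, expenditures_sbp).values
        b = bk.compute_balances(shuffled, expenditures_sbp).values
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_component_mismatch_raises(self, expenditures, expenditures_sbp):
        renamed = bk.validate_composition(
            expenditures.data.rename(columns={"housing": "rent"}))
        with pytest.raises(bk.AlignmentError, match="rent"):
            bk.compute_balances(renamed, expenditures_sbp)

    def test_zero_flagged_data_directed_to_replacement(self, expenditures_sbp):
        data = bk.validate_composition(
            [[0, 1, 2, 3, 4], [1, 1, 1, 1, 1.0]],
            component_ids=expenditures_sbp.component_ids, allow_zero=True)
        with pytest.raises(bk.DomainError, match="replace_zeros"):
            bk.compute_balances(data, expenditures_sbp)

    @pytest.mark.parametrize("seed", range(5))
    def test_formula_agrees_with_contrast_route(self, seed):
        rng = np.random.default_rng(seed)
        D = int(rng.integers(3, 30))
        data = random_composition(rng, 8, D)
        sbp = random_sbp(rng, D)
        got = bk.compute_balances(data, sbp).values
        np.testing.assert_allclose(got, balances_via_contrast(data, sbp),
                                   atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_scale_invariance_per_sample(self, seed):
        rng = np.random.default_rng(50 + seed)
        data = random_composition(rng, 6, 8)
        sbp = random_sbp(rng, 8)
        k = rng.uniform(1e-3, 1e3, size=(6, 1))
        scaled = bk.validate_composition(data.data * k)
        np.testing.assert_allclose(
            bk.compute_balances(scaled, sbp).values,
            bk.compute_balances(data, sbp).values, atol=1e-12)

    def test_sign_semantics_increasing_plus_part(self, expenditures_sbp):
        base = bk.validate_composition(
            [[2.0, 3.0, 4.0, 5.0, 6.0]],
            component_ids=expenditures_sbp.component_ids)
        bumped_values = base.data.copy()
        bumped_values["housing"] *= 1.5  # housing is +1 in z1
        bumped = bk.validate_composition(bumped_values)
        b0 = bk.compute_balances(base, expenditures_sbp).scores
        b1 = bk.compute_balances(bumped, expenditures_sbp).scores
        assert b1.loc["s1", "z1"] > b0.loc["s1", "z1"]


class TestVarianceDecomposition:
    def test_fixture_identity(self, expenditures, expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        vd = bk.variance_decomposition(table, bk.clr(expenditures))
        total_b = vd.attrs["total_balance_variance"]
        total_clr = vd.attrs["total_clr_variance"]
        assert total_b == pytest.approx(total_clr, rel=1e-9)
        assert vd["proportion"].sum() == pytest.approx(1.0, abs=1e-9)

    def test_two_samples_identity_still_holds(self, expenditures_sbp):
        rng = np.random.default_rng(3)
        data = bk.validate_composition(
            np.exp(rng.normal(size=(2, 5))),
            component_ids=expenditures_sbp.component_ids)
        table = bk.compute_balances(data, expenditures_sbp)
        vd = bk.variance_decomposition(table, bk.clr(data))
        assert vd.attrs["total_balance_variance"] == pytest.approx(
            vd.attrs["total_clr_variance"], rel=1e-9)

    def test_random_d32_identity(self):
        rng = np.random.default_rng(11)
        data = random_composition(rng, 25, 32)
        sbp = random_sbp(rng, 32)
        table = bk.compute_balances(data, sbp)
        vd = bk.variance_decomposition(table, bk.clr(data))
        assert vd.attrs["total_balance_variance"] == pytest.approx(
            vd.attrs["total_clr_variance"], rel=1e-9)

    def test_single_sample_rejected(self, expenditures, expenditures_sbp):
        one = bk.validate_composition(expenditures.data.iloc[:1])
        table = bk.compute_balances(one, expenditures_sbp)
        with pytest.raises(bk.DomainError, match="2 samples"):
            bk.variance_decomposition(table, bk.clr(one))

    def test_incomplete_sbp_rejected(self, expenditures, expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        partial = bk.subset_balances(table, ["z1", "z2"])
        with pytest.raises(bk.DomainError, match="complete"):
            bk.variance_decomposition(partial, bk.clr(expenditures))


class TestRankAndSubset:
    def test_full_selection_sorted_by_variance(self, expenditures,
                                               expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        ranked = bk.rank_balances(table, 4)
        variances = table.summary.loc[ranked, "variance"].to_numpy()
        assert (np.diff(variances) <= 0).all()
        assert set(ranked) == set(table.balance_ids)

    def test_top_10_of_499(self):
        rng = np.random.default_rng(21)
        data = random_composition(rng, 12, 60)
        sbp = random_sbp(rng, 60)
        table = bk.compute_balances(data, sbp)
        top = bk.rank_balances(table, 10)
        cutoff = np.sort(table.summary["variance"].to_numpy())[-10]
        assert all(table.summary.loc[b, "variance"] >= cutoff for b in top)

    def test_exact_tie_goes_to_earlier_column(self):
        # two structurally mirrored pairs -> identical variances
        data = bk.validate_composition(
            [[1.0, 2.0, 1.0, 2.0], [2.0, 1.0, 2.0, 1.0],
             [1.0, 1.0, 1.0, 1.0]])
        sbp = bk.validate_sbp(pd.DataFrame(
            {"b1": [1, 1, -1, -1], "b2": [1, -1, 0, 0], "b3": [0, 0, 1, -1]},
            index=["c1", "c2", "c3", "c4"]))
        table = bk.compute_balances(data, sbp)
        v = table.summary["variance"]
        assert v["b2"] == pytest.approx(v["b3"], abs=0)
        assert bk.rank_balances(table, 3) == ["b2", "b3", "b1"]

    @pytest.mark.parametrize("k", [0, 5])
    def test_rank_range_errors(self, k, expenditures, expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        with pytest.raises(bk.DomainError):
            bk.rank_balances(table, k)

    def test_subset_scores_bitwise_identical(self, expenditures,
                                             expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        sub = bk.subset_balances(table, ["z3", "z1"])
        assert sub.balance_ids == ["z3", "z1"]
        for b in sub.balance_ids:
            assert (sub.scores[b].to_numpy() ==
                    table.scores[b].to_numpy()).all()

    def test_subset_keeps_full_proportions(self, expenditures,
                                            expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        sub = bk.subset_balances(table, ["z2"])
        assert sub.summary.loc["z2", "proportion_of_total_variance"] == \
            table.summary.loc["z2", "proportion_of_total_variance"]
        assert sub.summary["proportion_of_total_variance"].sum() < 1.0

    def test_empty_subset_rejected(self, expenditures, expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        with pytest.raises(bk.DomainError, match="non-empty"):
            bk.subset_balances(table, [])

    def test_unknown_subset_id_rejected(self, expenditures, expenditures_sbp):
        table = bk.compute_balances(expenditures, expenditures_sbp)
        with pytest.raises(bk.BalanceLookupError):
            bk.subset_balances(table, ["z9"])
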