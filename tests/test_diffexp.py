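"""Consistency score, Welch test, BH adjustment, candidate selection.

Independent oracles: a brute-force pair loop for the CS, the closed-form
Student-t tail at df=2 for the Welch toy, and a literal step-up
implementation of Benjamini-Hochberg.
"""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cryogill as cg
from conftest import make_table


def brute_force_cs(ant_row, oth_row, fc_threshold=1.5, pseudocount=0.1):
    """Literal double loop over all cross-group pairs."""
    cs = 0
    for a in ant_row:
        for b in oth_row:
            num, den = a + pseudocount, b + pseudocount
            if den == 0:
                attained = num > 0
            else:
                attained = num / den > fc_threshold
            if attained:
                cs += 1
    return cs


def stepup_bh(p):
    """Hand-applied BH step-up: q_(i) = min_{j>=i} m p_(j) / j, clipped."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = min(running, 1.0)
    return q


class TestConsistencyScore:
    def test_full_attainment_is_48_for_6x8(self, table_factory):
        table = table_factory([[100.0] * 6], [[10.0] * 8])
        rec = cg.consistency_score(table)
        assert rec["cs"].iloc[0] == 48
        assert rec["n_comparisons"].iloc[0] == 48

    def test_identical_expression_scores_zero(self, table_factory):
        table = table_factory([[7.0] * 6], [[7.0] * 8])
        assert cg.consistency_score(table)["cs"].iloc[0] == 0

    def test_two_by_two_toy_enumerated_by_hand(self, table_factory):
        # pairs (3,1) attained twice (3.1/1.1 ~ 2.82); pairs (1,1) not
        table = table_factory([[3.0, 1.0]], [[1.0, 1.0]])
        assert cg.consistency_score(table, pseudocount=0.1)["cs"].iloc[0] == 2

    def test_zero_pseudocount_zero_rules(self, table_factory):
        # x/0 (x>0) attained; 0/0 not attained
        table = table_factory([[5.0, 0.0]], [[0.0, 0.0]])
        assert cg.consistency_score(table, pseudocount=0.0)["cs"].iloc[0] == 2

    def test_matches_brute_force_on_random_tables(self, table_factory):
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            na, nb = rng.integers(1, 5), rng.integers(1, 5)
            ant = np.round(rng.gamma(1.0, 50.0, na), 3)
            oth = np.round(rng.gamma(1.0, 50.0, nb), 3)
            table = make_table([ant], [oth])
            got = cg.consistency_score(table)["cs"].iloc[0]
            assert got == brute_force_cs(ant, oth)

    @settings(deadline=None, max_examples=60)
    @given(
        ant=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=4),
        oth=st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=4),
        bump=st.floats(0.1, 1e3, allow_nan=False),
        data=st.data(),
    )
    def test_monotone_in_single_species_shift(self, ant, oth, bump, data):
        """Raising one Antarctic value never lowers CS; raising one
        other-group value never raises it."""
        base = cg.consistency_score(make_table([ant], [oth]))["cs"].iloc[0]
        i = data.draw(st.integers(0, len(ant) - 1))
        up = list(ant)
        up[i] += bump
        assert cg.consistency_score(make_table([up], [oth]))["cs"].iloc[0] >= base
        j = data.draw(st.integers(0, len(oth) - 1))
        upo = list(oth)
        upo[j] += bump
        assert cg.consistency_score(make_table([ant], [upo]))["cs"].iloc[0] <= base

    def test_bounds_and_errors(self, table_factory):
        table = table_factory([[1.0] * 3], [[1.0] * 4])
        rec = cg.consistency_score(table)
        assert 0 <= rec["cs"].iloc[0] <= 12
        with pytest.raises(cg.ValidationError):
            cg.consistency_score(table, fc_threshold=0.0)


class TestTwoGroupTest:
    def test_welch_toy_matches_closed_form_df2(self):
        """antarctic (5,6) vs other (1,2) on the log2 scale: t = 4*sqrt(2),
        Welch-Satterthwaite df = 2, and the Student-t tail at df=2 has the
        closed form P(T > t) = (1 - t / sqrt(2 + t^2)) / 2."""
        # choose TPM so that log2(TPM + 1) hits the toy vectors exactly
        ant = [2.0**5 - 1, 2.0**6 - 1]
        oth = [2.0**1 - 1, 2.0**2 - 1]
        table = make_table([ant], [oth])
        p = cg.two_group_test(table).iloc[0]
        t = 4.0 * math.sqrt(2.0)
        expected = 0.5 * (1.0 - t / math.sqrt(2.0 + t * t))
        assert p == pytest.approx(expected, rel=1e-10)

    def test_identical_constant_groups_give_p_one(self, table_factory):
        table = table_factory([[3.0] * 6], [[3.0] * 8])
        assert cg.two_group_test(table).iloc[0] == 1.0

    def test_strong_separation_gives_tiny_p(self, table_factory):
        rng = np.random.default_rng(0)
        ant = 255.0 + rng.normal(0, 1e-3, 6)  # log2(TPM+1) ~ 8
        oth = 1.0 + rng.normal(0, 1e-3, 8)  # log2(TPM+1) ~ 1
        table = table_factory([ant], [oth])
        assert cg.two_group_test(table).iloc[0] < 1e-6

    def test_downregulated_constant_groups_give_p_one(self, table_factory):
        table = table_factory([[1.0] * 2], [[9.0] * 2])
        assert cg.two_group_test(table).iloc[0] == 1.0

    def test_small_groups_rejected(self, table_factory):
        table = table_factory([[1.0]], [[2.0, 3.0]])
        with pytest.raises(cg.ValidationError, match="CS|consistency"):
            cg.two_group_test(table)


class TestBhAdjust:
    def test_hand_example(self):
        np.testing.assert_allclose(
            cg.bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03], rtol=1e-12
        )

    def test_single_p_identity(self):
        assert cg.bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_all_ones_boundary(self):
        np.testing.assert_allclose(cg.bh_adjust([1.0, 1.0]), [1.0, 1.0])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            m = int(rng.integers(1, 40))
            p = rng.random(m)
            np.testing.assert_allclose(cg.bh_adjust(p), stepup_bh(p), rtol=1e-12)

    def test_deterministic_and_order_restored(self):
        p = [0.04, 0.001, 0.9, 0.02]
        q1, q2 = cg.bh_adjust(p), cg.bh_adjust(p)
        np.testing.assert_array_equal(q1, q2)
        # sorted inputs give monotone non-decreasing q
        qs = cg.bh_adjust(sorted(p))
        assert (np.diff(qs) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(cg.ValidationError):
            cg.bh_adjust([0.5, 1.5])


class TestSelectCandidates:
    def _records(self, cs, q, fc=10.0, n_comp=48):
        return pd.DataFrame(
            {
                "cs": [cs],
                "n_comparisons": [n_comp],
                "fold_change": [fc],
                "q_value": [q],
            },
            index=["og1"],
        )

    @pytest.mark.parametrize(
        "cs, q, expected",
        [
            (48, 1e-6, True),
            (36, 1e-6, True),
            (35, 1e-6, False),  # CS threshold is inclusive at 36
            (40, 0.05, False),  # q threshold is strict
            (40, 0.0499, True),
        ],
    )
    def test_threshold_boundaries(self, cs, q, expected):
        out = cg.select_candidates(self._records(cs, q))
        assert bool(out["selected"].iloc[0]) is expected

    def test_downregulated_never_selected(self):
        out = cg.select_candidates(self._records(48, 1e-6, fc=0.5))
        assert not out["selected"].iloc[0]

    def test_unsatisfiable_threshold_rejected(self):
        with pytest.raises(cg.ValidationError, match="unsatisfiable"):
            cg.select_candidates(self._records(48, 1e-6), cs_min=50)

    def test_shortlist_ordering(self):
        rec = pd.DataFrame(
            {
                "cs": [48, 40, 44, 30],
                "n_comparisons": 48,
                "fold_change": [10.0, 5.0, 3.0, 9.0],
                "q_value": [1e-8, 1e-3, 1e-3, 1e-9],
            },
            index=["a", "b", "c", "d"],
        )
        out = cg.select_candidates(rec)
        short = cg.shortlist(out)
        assert list(short.index) == ["a", "c", "b"]  # q asc, then CS desc


class TestParameterRecovery:
    def test_planted_effects_recovered(self, default_dataset):
        """On the default synthetic design, CS >= 36 & q < 0.05 recovers
        >= 90% of planted orthologs with <= 10% false discoveries."""
        deg = default_dataset["deg"]
        truth = default_dataset["truth"]
        selected = set(deg.index[deg["selected"]])
        planted = set(truth.planted_deg)
        sensitivity = len(selected & planted) / len(planted)
        fdp = len(selected - planted) / max(len(selected), 1)
        assert sensitivity >= 0.90
        assert fdp <= 0.10

    def test_null_dataset_selects_almost_nothing(self):
        params = cg.SimulationParams(seed=1, planted_deg_fraction=0.0)
        matrices, config, _ = cg.simulate_cross_species(params)
        table = cg.build_ortholog_table(
            matrices, cg.identity_membership(matrices), config
        )
        deg = cg.differential_expression(table)
        assert deg["selected"].sum() <= 0.01 * len(deg)
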