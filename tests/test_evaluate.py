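"""Null-distribution weights, calibrated confusion, precision model,
per-bin association statistics."""
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nautica.classify import InteractionLabel
from nautica.evaluate import (
    NullDistribution,
    PrecisionModel,
    bin_association_stats,
    build_null,
    calibrated_confusion,
    confusion,
    contingency_stats,
    fold_over_random,
    precision_interaction,
)

COOP, COMP, NINT = (InteractionLabel.COOP, InteractionLabel.COMP,
                    InteractionLabel.NINT)


class TestBuildNull:
    def test_floor_ratio_weights(self):
        # counts 7/2/3 over bins 0..2 -> base bin 1, weights floor(c/2)
        null = build_null([0] * 7 + [1] * 2 + [2] * 3)
        assert null.base_bin == 1
        assert null.weights[0] == 3 and null.weights[1] == 1 and null.weights[2] == 1

    def test_equal_counts_all_weights_one(self):
        null = build_null([b for b in range(11) for _ in range(4)])
        assert all(w == 1 for w in null.weights.values())

    def test_tied_minimum_takes_smallest_bin(self):
        # bins 6 and 7 tied for smallest -> bin 6 is the base
        bins = [0] * 10 + [6] * 2 + [7] * 2
        null = build_null(bins)
        assert null.base_bin == 6

    def test_tail_values_collapse_into_bin_ten(self):
        null = build_null([12, 47, 10, 0])
        assert null.bin_counts[10] == 3 and null.bin_counts[0] == 1

    def test_all_empty_rejected(self):
        with pytest.raises(ValueError):
            build_null([])

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.integers(0, 10), min_size=1, max_size=200))
    def test_weight_law(self, bins):
        """w[b] * base_count <= count[b] < (w[b]+1) * base_count."""
        null = build_null(bins)
        base = null.bin_counts[null.base_bin]
        for b, w in null.weights.items():
            assert w * base <= null.bin_counts[b] < (w + 1) * base
        assert null.weights[null.base_bin] == 1

    def test_tsv_round_trip(self, tmp_path):
        null = build_null([0] * 7 + [1] * 2 + [2] * 3)
        null.to_tsv(tmp_path / "null.tsv")
        back = NullDistribution.from_tsv(tmp_path / "null.tsv")
        assert back.weights == null.weights and back.base_bin == null.base_bin


class TestCalibratedConfusion:
    def test_weighted_cells_match_hand_tally(self):
        # NINT null counts: bin0 x 6, bin1 x 2 -> weights 3 and 1
        nint_null = build_null([0] * 6 + [1] * 2)
        # COOP null counts: bin0 x 2, bin1 x 2 -> weights 1 and 1
        coop_null = build_null([0] * 2 + [1] * 2)
        test = [
            (0, NINT, COOP),   # weight 3 into (NINT, COOP)
            (0, NINT, NINT),   # weight 3 into (NINT, NINT)
            (1, COMP, COMP),   # COMP uses the NINT null: weight 1
            (0, COOP, COOP),   # COOP null: weight 1
        ]
        cm = calibrated_confusion(test, nint_null, coop_null)
        assert cm.cells.loc["NINT", "COOP"] == 3
        assert cm.cells.loc["NINT", "NINT"] == 3
        assert cm.cells.loc["COMP", "COMP"] == 1
        assert cm.cells.loc["COOP", "COOP"] == 1
        assert cm.recalls[NINT] == pytest.approx(0.5)

    def test_comp_pairs_use_nint_null(self):
        nint_null = build_null([0] * 10 + [1])   # weight of bin 0 is 10
        coop_null = build_null([0, 1])           # all weights 1
        cm = calibrated_confusion([(0, COMP, COMP)], nint_null, coop_null)
        assert cm.cells.loc["COMP", "COMP"] == 10

    def test_all_weights_one_equals_raw(self):
        """Calibration with unit weights is the identity (exact)."""
        rng = np.random.default_rng(0)
        labels = [COOP, COMP, NINT]
        test = [
            (int(rng.integers(0, 11)),
             labels[rng.integers(3)], labels[rng.integers(3)])
            for _ in range(60)
        ]
        flat_null = build_null(list(range(11)))  # every count 1 -> weight 1
        raw = confusion(test)
        cal = calibrated_confusion(test, flat_null, flat_null)
        assert (raw.cells == cal.cells).all().all()
        assert raw.recalls == cal.recalls

    def test_missing_bin_falls_back_to_unit_weight(self, caplog):
        nint_null = build_null([0] * 4)   # only bin 0 populated
        with caplog.at_level("WARNING"):
            cm = calibrated_confusion([(5, NINT, NINT)], nint_null, nint_null)
        assert cm.cells.loc["NINT", "NINT"] == 1
        assert "fallback" in caplog.text

    def test_empty_test_set_rejected(self):
        null = build_null([0])
        with pytest.raises(ValueError):
            calibrated_confusion([], null, null)


class TestPrecisionModel:
    def test_reference_split_with_tree_recalls(self):
        model = PrecisionModel(split=(0.8, 0.1, 0.1),
                               r_nint=0.83, r_comp=0.39, r_coop=0.75)
        assert precision_interaction(model) == pytest.approx(0.456, abs=5e-4)

    def test_reference_split_with_baseline_recalls(self):
        model = PrecisionModel(split=(0.8, 0.1, 0.1),
                               r_nint=0.79, r_comp=0.96, r_coop=0.40)
        assert round(precision_interaction(model), 2) == 0.45

    def test_perfect_recalls_give_precision_one(self):
        model = PrecisionModel(r_nint=1.0, r_comp=1.0, r_coop=1.0)
        assert precision_interaction(model) == 1.0

    def test_undefined_case_returns_nan(self):
        model = PrecisionModel(r_nint=1.0, r_comp=0.0, r_coop=0.0)
        assert math.isnan(precision_interaction(model))

    def test_invalid_split_rejected(self):
        with pytest.raises(ValueError):
            PrecisionModel(split=(0.5, 0.2, 0.2))

    @settings(derandomize=True, max_examples=80)
    @given(
        rn=st.floats(0, 1), rc=st.floats(0, 1), rp=st.floats(0, 1),
        y=st.floats(0.01, 0.98),
    )
    def test_bounded_and_monotone_in_recalls(self, rn, rc, rp, y):
        x = (1 - y) / 2
        model = PrecisionModel(split=(y, x, x), r_nint=rn, r_comp=rc, r_coop=rp)
        p = precision_interaction(model)
        if not math.isnan(p):
            assert 0.0 <= p <= 1.0
            bumped = PrecisionModel(split=(y, x, x),
                                    r_nint=min(1.0, rn + 0.05),
                                    r_comp=rc, r_coop=rp)
            p2 = precision_interaction(bumped)
            if not math.isnan(p2):
                assert p2 >= p - 1e-12


class TestFoldOverRandom:
    def test_hand_computed_value_at_x_010(self):
        # P_INT(0.8/0.1/0.1) = 0.456; random precision = 0.2
        assert fold_over_random(0.1) == pytest.approx(2.28, abs=5e-3)

    def test_at_least_two_fold_below_x_014(self):
        assert fold_over_random(0.14) >= 2.0

    def test_monotone_decreasing_in_x(self):
        xs = np.linspace(0.01, 0.49, 40)
        folds = [fold_over_random(float(x)) for x in xs]
        assert all(a >= b for a, b in zip(folds, folds[1:]))

    @pytest.mark.parametrize("x", [0.0, 0.5, -0.1, 1.0])
    def test_domain_check(self, x):
        with pytest.raises(ValueError):
            fold_over_random(x)


class TestBinAssociation:
    def test_contingency_arithmetic(self):
        rr, or_ = contingency_stats(10, 5, 20, 40)
        assert rr == pytest.approx(2.0)
        assert or_ == pytest.approx(4.0)

    def test_zero_numerator(self):
        rr, or_ = contingency_stats(0, 5, 20, 40)
        assert rr == 0.0 and or_ == 0.0

    def test_symmetric_table(self):
        rr, or_ = contingency_stats(3, 3, 3, 3)
        assert rr == 1.0 and or_ == 1.0

    def test_per_bin_table_flags_undefined_margins(self):
        labelled = [(COOP, 0)] * 5 + [(COOP, 2)] * 5 + [(NINT, 0)] * 10
        table = bin_association_stats(labelled, COOP, NINT)
        row0 = table[table.bin == 0].iloc[0]
        assert row0["relative_risk"] == pytest.approx(0.5)
        # no NINT pair in bin 2 -> RR/OR undefined there
        row2 = table[table.bin == 2].iloc[0]
        assert math.isnan(row2["relative_risk"])
        # bins with nothing at all have a zero column margin -> NaN p
        row5 = table[table.bin == 5].iloc[0]
        assert math.isnan(row5["chi2_p"])

    def test_chi2_matches_scipy_direct(self):
        from scipy.stats import chi2_contingency

        labelled = [(COOP, 0)] * 8 + [(COOP, 1)] * 12 + \
                   [(NINT, 0)] * 15 + [(NINT, 1)] * 5
        table = bin_association_stats(labelled, COOP, NINT)
        row = table[table.bin == 0].iloc[0]
        expected = chi2_contingency(np.array([[8, 12], [15, 5]]),
                                    correction=False)[1]
        assert row["chi2_p"] == pytest.approx(expected)

    def test_requires_both_classes(self):
        with pytest.raises(ValueError):
            bin_association_stats([(COOP, 0)], COOP, NINT)
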