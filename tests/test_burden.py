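"""Burden testing: normality routing, BH adjustment, above-1SD relative
burden, and the demographics summary."""

from math import comb

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from homburden import burden
from homburden.io_model import (
    ASD,
    BENIGN_LB,
    CANCER,
    FEMALE,
    MALE,
    NDD,
    OTHER_GROUP,
    PATHOGENIC_LP,
    VUS,
    SampleRecord,
)


class TestOverallBurden:
    def test_identical_multisets_give_p_one(self):
        r = burden.overall_burden_test([0.1, 0.2, 0.3], [0.3, 0.1, 0.2])
        assert r.p_raw == pytest.approx(1.0)
        assert r.direction == 0

    def test_forced_t_test_matches_closed_form(self):
        # pooled-variance t with df=4: t = -0.3 / (0.1*sqrt(2/3))
        r = burden.overall_burden_test(
            [0.1, 0.2, 0.3], [0.4, 0.5, 0.6], force_test=burden.T_TEST
        )
        assert r.statistic == pytest.approx(-3.674, abs=5e-4)
        assert r.p_raw == pytest.approx(0.0213, abs=5e-4)
        assert r.direction == -1

    def test_small_groups_route_to_mann_whitney(self):
        rng = np.random.default_rng(3)
        r = burden.overall_burden_test(rng.normal(size=5), rng.normal(size=5))
        assert r.test_used == burden.MANN_WHITNEY

    def test_normal_large_groups_route_to_t(self):
        rng = np.random.default_rng(4)
        r = burden.overall_burden_test(rng.normal(size=60), rng.normal(1, 1, size=60))
        assert r.test_used == burden.T_TEST

    def test_skewed_group_routes_to_mann_whitney(self):
        rng = np.random.default_rng(5)
        r = burden.overall_burden_test(
            rng.normal(size=60), rng.lognormal(sigma=1.5, size=60)
        )
        assert r.test_used == burden.MANN_WHITNEY

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            burden.overall_burden_test([0.1], [0.2, 0.3])


class TestBenjaminiHochberg:
    def test_hand_computed_example(self):
        adj = burden.adjust_bh([0.01, 0.02, 0.04, 0.8])
        assert adj == pytest.approx([0.04, 0.04, 0.04 * 4 / 3, 0.8])

    def test_single_p_unchanged(self):
        assert burden.adjust_bh([0.3]).tolist() == [0.3]

    def test_all_equal_ties(self):
        assert burden.adjust_bh([0.04] * 5) == pytest.approx([0.04] * 5)

    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=1, max_size=20))
    def test_never_decreases_and_stays_in_unit_interval(self, ps):
        adj = burden.adjust_bh(ps)
        assert (adj >= np.asarray(ps) - 1e-12).all()
        assert (adj <= 1.0 + 1e-12).all()


class TestRelativeBurden:
    def test_worked_example(self):
        # pooled mean 0.5667, SD 0.1751 -> threshold 0.7417 -> table (1,2|0,3)
        r = burden.relative_burden_test([0.5, 0.6, 0.9], [0.4, 0.5, 0.5])
        assert r.threshold == pytest.approx(0.74174, abs=1e-4)
        assert (r.table.a, r.table.b, r.table.c, r.table.d) == (1, 2, 0, 3)
        assert r.assoc.p_two_sided == pytest.approx(1.0)

    def test_constant_rates_degenerate(self):
        r = burden.relative_burden_test([0.2, 0.2], [0.2, 0.2])
        assert r.degenerate and r.assoc.p_two_sided == 1.0
        assert r.assoc.or_cmle == 1.0

    def test_separated_groups_match_enumeration(self):
        # threshold falls between the groups only if the top group spreads
        # enough; construct a at 0.8-1.0, b at 0.0-0.05 with na=3, nb=6
        a = [0.8, 0.9, 1.0]
        b = [0.0, 0.01, 0.02, 0.03, 0.04, 0.05]
        r = burden.relative_burden_test(a, b)
        assert (r.table.a, r.table.c) == (3, 0)  # threshold splits the groups
        # probability-ordering oracle on the support {0..3}: the opposite
        # tail (20/84) is far likelier than the observed table (1/84), so
        # only the observed table is summed
        assert r.assoc.p_two_sided == pytest.approx(1 / comb(9, 3))

    def test_label_exchange_inverts_odds(self):
        rng = np.random.default_rng(8)
        a, b = rng.normal(0.5, 0.2, 30), rng.normal(0.4, 0.2, 40)
        r1 = burden.relative_burden_test(a, b)
        r2 = burden.relative_burden_test(b, a)
        assert r1.assoc.p_two_sided == pytest.approx(r2.assoc.p_two_sided, abs=1e-10)
        if 0 < r1.assoc.or_cmle < np.inf:
            assert r2.assoc.or_cmle == pytest.approx(1 / r1.assoc.or_cmle, rel=1e-5)


def _records():
    records = []
    k = 0

    def add(n, sex, flags, vclass):
        nonlocal k
        for _ in range(n):
            records.append(SampleRecord(f"s{k}", sex, frozenset(flags), vclass))
            k += 1

    # NDD block (117 = 81 male / 36 female; 108 P/LP, 9 VUS), first 57 ASD
    add(42, MALE, {NDD, ASD}, PATHOGENIC_LP)
    add(15, FEMALE, {NDD, ASD}, PATHOGENIC_LP)
    add(39, MALE, {NDD}, PATHOGENIC_LP)
    add(12, FEMALE, {NDD}, PATHOGENIC_LP)
    add(9, FEMALE, {NDD}, VUS)
    # cancer block (175 = 32 male / 143 female; 131 P/LP, 11 B/LB, 33 VUS)
    add(32, MALE, {CANCER}, PATHOGENIC_LP)
    add(99, FEMALE, {CANCER}, PATHOGENIC_LP)
    add(11, FEMALE, {CANCER}, BENIGN_LB)
    add(33, FEMALE, {CANCER}, VUS)
    # other block (84 = 45 male / 39 female; 73 P/LP, 1 B/LB, 10 VUS)
    add(45, MALE, {OTHER_GROUP}, PATHOGENIC_LP)
    add(28, FEMALE, {OTHER_GROUP}, PATHOGENIC_LP)
    add(1, FEMALE, {OTHER_GROUP}, BENIGN_LB)
    add(10, FEMALE, {OTHER_GROUP}, VUS)
    return records


class TestCohortSummary:
    def test_group_sizes_and_percentages(self):
        summary = burden.cohort_summary(_records())
        assert summary.loc[NDD, "n"] == 117
        assert summary.loc[NDD, "male_pct"] == 69
        assert summary.loc[NDD, "pathogenic_lp_pct"] == 92
        assert summary.loc[CANCER, "female_pct"] == 82
        assert summary.loc[OTHER_GROUP, "pathogenic_lp_pct"] == 87
        assert summary.loc[ASD, "n"] == 57

    def test_empty_group_gives_na(self):
        records = [SampleRecord("a", MALE, frozenset({NDD}), VUS),
                   SampleRecord("b", FEMALE, frozenset({NDD}), VUS),
                   SampleRecord("c", FEMALE, frozenset({CANCER}), VUS)]
        summary = burden.cohort_summary(records)
        assert summary.loc[OTHER_GROUP, "n"] == 0
        assert np.isnan(summary.loc[OTHER_GROUP, "male_pct"])


class TestGroupSelection:
    def test_contrast_groups(self):
        records = _records()
        assert len(burden.select_group(records, NDD)) == 117
        assert len(burden.select_group(records, "ASD")) == 57
        assert len(burden.select_group(records, burden.NON_NDD)) == 259
        assert len(burden.select_group(records, CANCER)) == 175
        assert len(burden.select_group(records, OTHER_GROUP)) == 84

    def test_only_groups_exclude_cancer_comorbidity(self):
        records = [
            SampleRecord("a", MALE, frozenset({NDD, ASD, CANCER}), VUS),
            SampleRecord("b", MALE, frozenset({NDD, ASD}), VUS),
            SampleRecord("c", FEMALE, frozenset({NDD}), VUS),
        ]
        assert burden.select_group(records, burden.NDD_ONLY) == ["b", "c"]
        assert burden.select_group(records, burden.ASD_ONLY) == ["b"]
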