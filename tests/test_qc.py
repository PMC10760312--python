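"""Quality control: exact HWE test against an independent oracle, and the
variant/sample filter stages."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from homburden import qc
from homburden.io_model import MISSING, GenotypeMatrix


def hwe_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Independent construction of the exact HWE p-value: builds the
    conditional het-count distribution by the mid-support recurrence
    (ratio of consecutive probabilities) instead of closed-form weights."""
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    hets = list(range(n_minor % 2, n_minor + 1, 2))
    # start from the modal region and recurse outward via
    # P(h+2)/P(h) = 4*hom_minor*hom_major / ((h+1)(h+2))
    probs = {hets[0]: 1.0}
    for h in hets[:-1]:
        hom_minor = (n_minor - h) // 2
        hom_major = n - h - hom_minor
        probs[h + 2] = probs[h] * 4 * hom_minor * hom_major / ((h + 1) * (h + 2))
    total = sum(probs.values())
    probs = {k: v / total for k, v in probs.items()}
    obs = probs[n_het]
    return min(1.0, sum(v for v in probs.values() if v <= obs * (1 + 1e-12)))


def _matrix(calls, sample_ids=None):
    calls = np.asarray(calls, dtype=np.int8)
    n, m = calls.shape
    variants = pd.DataFrame(
        {"chrom": [1] * m, "pos": range(100, 100 + m), "ref": "A", "alt": "G"}
    )
    return GenotypeMatrix(sample_ids or [f"s{i}" for i in range(n)], variants, calls)


class TestHweExact:
    def test_monomorphic_site_is_one(self):
        assert qc.hwe_exact_test(10, 0, 0) == 1.0
        assert qc.hwe_exact_test(0, 0, 10) == 1.0

    def test_small_table_matches_enumeration(self):
        # 9 diploids, 5 minor alleles: support het in {1,3,5}
        assert qc.hwe_exact_test(5, 3, 1) == pytest.approx(hwe_oracle(5, 3, 1), abs=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            qc.hwe_exact_test(0, 0, 0)

    @given(
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
        st.integers(min_value=0, max_value=60),
    )
    def test_agrees_with_oracle_and_is_label_symmetric(self, a, b, c):
        if a + b + c == 0:
            return
        p = qc.hwe_exact_test(a, b, c)
        assert p == pytest.approx(hwe_oracle(a, b, c), abs=1e-12)
        assert p == pytest.approx(qc.hwe_exact_test(c, b, a), abs=1e-12)
        assert 0 < p <= 1


class TestVariantFilters:
    def test_final_missingness_boundary(self):
        # variant 0: 2/30 missing (6.7%) -> removed; variant 1: 1/30 (3.3%) -> kept
        calls = np.ones((30, 2), dtype=np.int8)
        calls[0, 0] = calls[1, 0] = MISSING
        calls[0, 1] = MISSING
        gm = _matrix(calls)
        out, report = qc.filter_variants(gm, stage="final")
        assert out.n_variants == 1
        assert list(report.variants_removed.values()) == [qc.MISSINGNESS]

    def test_hwe_threshold_is_inclusive(self):
        thr = qc.QcThresholds()
        assert 0.0005 <= thr.hwe_p_max  # flagged
        assert 0.01 > thr.hwe_p_max  # retained
        # a wildly HWE-discordant variant is removed at the pre-stage
        calls = np.zeros((60, 2), dtype=np.int8)
        calls[:30, 0] = 2  # 30 hom-ref / 0 het / 30 hom-alt: p ~ 0
        calls[:, 1] = np.tile([0, 1, 1, 2], 15)  # near-HWE
        gm = _matrix(calls)
        out, report = qc.filter_variants(gm, stage="pre")
        assert list(report.variants_removed.values()) == [qc.HWE]
        assert out.n_variants == 1

    def test_call_rate_prestage(self):
        calls = np.ones((50, 1), dtype=np.int8)
        calls[:2, 0] = MISSING  # call rate 0.96 < 0.98
        _, report = qc.filter_variants(_matrix(calls), stage="pre")
        assert list(report.variants_removed.values()) == [qc.CALL_RATE]


class TestSampleFilters:
    def test_missingness_above_three_percent_removed(self):
        calls = np.ones((10, 100), dtype=np.int8)
        calls[0, :4] = MISSING  # 4% missing
        out, report = qc.filter_samples(_matrix(calls))
        assert report.samples_removed == {"s0": qc.MISSINGNESS}
        assert out.n_samples == 9

    def test_constant_het_rate_removes_nobody(self):
        calls = np.tile([0, 1], (10, 50)).astype(np.int8)
        out, report = qc.filter_samples(_matrix(calls))
        assert report.samples_removed == {}
        assert out.n_samples == 10

    def test_planted_het_outlier_removed(self, null_cohort):
        gm = null_cohort.genotypes
        calls = gm.calls.copy()
        calls[5] = np.where(calls[5] != MISSING, 1, MISSING)  # all-het sample
        planted = GenotypeMatrix(gm.sample_ids, gm.variants, calls)
        _, report = qc.filter_samples(planted)
        assert report.samples_removed.get(gm.sample_ids[5]) == qc.HET_OUTLIER

    def test_sex_discordance_predicate_is_injected(self):
        calls = np.tile([0, 1, 2], (5, 20)).astype(np.int8)
        _, report = qc.filter_samples(_matrix(calls), sex_discordant=lambda sid: sid == "s2")
        assert report.samples_removed == {"s2": qc.SEX_DISCORDANT}

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            qc.filter_samples(_matrix(np.ones((2, 5), dtype=np.int8)))


class TestFullPass:
    def test_idempotent_and_conservation(self, null_cohort):
        gm = null_cohort.genotypes
        out, report = qc.run_qc(gm)
        # removed + retained equals input on both axes
        assert out.n_samples + len(report.samples_removed) == gm.n_samples
        assert out.n_variants + len(report.variants_removed) == gm.n_variants
        again, report2 = qc.run_qc(out)
        assert again.equals(out)
        assert report2.counts() == {}
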