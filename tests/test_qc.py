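import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from rohscan.datamodel import MISSING
from rohscan.qc import (
    QCConfig,
    filter_samples_by_callrate,
    filter_snps_by_callrate,
    filter_snps_by_hwe,
    hwe_exact_pvalue,
    run_qc,
)

from conftest import make_dataset
from oracles import hwe_exact_pvalue_rational


class TestCallrateFilters:
    def test_sample_below_threshold_removed(self):
        calls = np.zeros((2, 100), dtype=np.int8)
        calls[1, :11] = MISSING  # callrate 0.89
        ds, removed = filter_samples_by_callrate(make_dataset(calls), 0.90)
        assert removed == ["S2"]
        assert ds.samples == ["S1"]
        assert ds.n_markers == 100

    def test_threshold_one_drops_any_missing(self):
        calls = np.zeros((2, 10), dtype=np.int8)
        calls[0, 3] = MISSING
        ds, removed = filter_samples_by_callrate(make_dataset(calls), 1.0)
        assert removed == ["S1"]

    def test_all_samples_removed_raises(self):
        calls = np.full((2, 4), MISSING, dtype=np.int8)
        with pytest.raises(ValueError, match="empty"):
            filter_samples_by_callrate(make_dataset(calls), 0.5)

    def test_snp_filter_matches_brute_force_recount(self, rng):
        calls = rng.integers(0, 3, size=(10, 10)).astype(np.int8)
        miss = rng.random((10, 10)) < 0.15
        calls[miss] = MISSING
        ds = make_dataset(calls)
        _, removed = filter_snps_by_callrate(ds, 0.90)
        expected = [
            ds.markers[j].id
            for j in range(10)
            if (calls[:, j] != MISSING).sum() / 10 < 0.90
        ]
        assert removed == expected

    def test_fully_observed_marker_kept(self):
        ds = make_dataset(np.ones((5, 3), dtype=np.int8))
        _, removed = filter_snps_by_callrate(ds, 1.0)
        assert removed == []

    def test_qcconfig_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            QCConfig(min_sample_callrate=0.0)
        with pytest.raises(ValueError):
            QCConfig(hwe_p_threshold=1.5)


class TestHWEExact:
    def test_monomorphic_is_one(self):
        assert hwe_exact_pvalue(50, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 50) == 1.0

    @pytest.mark.parametrize(
        "table",
        [(3, 4, 3), (5, 0, 5), (0, 10, 0), (12, 5, 1), (7, 7, 7), (1, 1, 1)],
    )
    def test_matches_rational_enumeration(self, table):
        expected = float(hwe_exact_pvalue_rational(*table))
        assert hwe_exact_pvalue(*table) == pytest.approx(expected, rel=1e-10)

    @pytest.mark.parametrize(
        "table,tol",
        [
            # discreteness at n=1000 keeps the exact test ~0.05 from the
            # asymptote; by n=10,000 genotypes they agree within 0.02
            ((300, 500, 200), 0.05),
            ((3000, 5000, 2000), 0.02),
        ],
    )
    def test_large_balanced_table_near_chi_square(self, table, tol):
        nAA, nAb, nbb = table
        n = nAA + nAb + nbb
        p = (2 * nAA + nAb) / (2 * n)
        exp = np.array([n * p**2, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        chi2 = (((np.array([nAA, nAb, nbb]) - exp) ** 2) / exp).sum()
        p_asym = float(sps.chi2.sf(chi2, df=1))
        assert abs(hwe_exact_pvalue(nAA, nAb, nbb) - p_asym) < tol

    def test_exact_value_at_n1000_matches_rational_oracle(self):
        # the rational oracle is the authority where the asymptote is loose
        assert hwe_exact_pvalue(300, 500, 200) == pytest.approx(
            float(hwe_exact_pvalue_rational(300, 500, 200)), rel=1e-9
        )

    @given(
        st.integers(0, 20), st.integers(0, 20), st.integers(0, 20)
    )
    @settings(max_examples=150, deadline=None)
    def test_symmetric_in_homozygotes(self, a, h, b):
        if a + h + b == 0:
            return
        assert hwe_exact_pvalue(a, h, b) == pytest.approx(
            hwe_exact_pvalue(b, h, a), rel=1e-12
        )

    def test_all_zero_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(0, 0, 0)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            hwe_exact_pvalue(-1, 2, 3)


class TestHWEFilter:
    def test_hwe_proportioned_marker_retained(self):
        col = np.array([0] * 25 + [1] * 50 + [2] * 25, dtype=np.int8)
        ds = make_dataset(col[:, None])
        _, removed = filter_snps_by_hwe(ds, 1e-6)
        assert removed == []

    def test_het_depleted_marker_removed(self):
        col = np.array([0] * 50 + [2] * 50, dtype=np.int8)
        assert float(hwe_exact_pvalue_rational(50, 0, 50)) < 1e-6
        ds = make_dataset(col[:, None])
        _, removed = filter_snps_by_hwe(ds, 1e-6)
        assert removed == ["snp1"]

    def test_monomorphic_marker_retained(self):
        ds = make_dataset(np.zeros((30, 1), dtype=np.int8))
        _, removed = filter_snps_by_hwe(ds, 1e-6)
        assert removed == []

    def test_missing_calls_excluded_from_counts(self):
        col = np.array([0] * 25 + [1] * 50 + [2] * 25 + [MISSING] * 10, dtype=np.int8)
        ds = make_dataset(col[:, None])
        _, removed = filter_snps_by_hwe(ds, 1e-6)
        assert removed == []


class TestRunQC:
    def _fixture(self):
        # 20 samples x 12 markers: S20 entirely missing (bad sample);
        # marker 2 missing in half the cohort (low call rate); marker 3
        # het-free at 50/50 hom split (HWE violation); the rest clean
        calls = np.zeros((20, 12), dtype=np.int8)
        for j in range(12):
            calls[:, j] = ([0, 1, 2, 1] * 5) if j >= 3 else 0
        calls[:, 0] = [0, 1] * 10
        calls[:10, 1] = MISSING
        calls[10:, 1] = [0, 1] * 5
        calls[:, 2] = [0] * 10 + [2] * 10
        calls[19, :] = MISSING
        return make_dataset(calls)

    def test_clean_dataset_removes_nothing(self):
        ds = make_dataset(np.array([[0, 1], [1, 0], [2, 1], [0, 0]], dtype=np.int8))
        _, report = run_qc(ds, QCConfig(hwe_p_threshold=1e-6))
        assert (
            report.n_samples_removed,
            report.n_snps_removed_callrate,
            report.n_snps_removed_hwe,
        ) == (0, 0, 0)

    def test_one_of_each_removed(self):
        ds = self._fixture()
        filtered, report = run_qc(ds, QCConfig(0.90, 0.90, 1e-3))
        assert report.n_samples_removed == 1
        assert report.n_snps_removed_callrate == 1
        assert report.n_snps_removed_hwe == 1
        assert report.n_samples_kept == 19
        assert report.n_snps_kept == 10

    def test_idempotent(self):
        ds = self._fixture()
        once, _ = run_qc(ds, QCConfig(0.90, 0.90, 1e-3))
        twice, report2 = run_qc(once, QCConfig(0.90, 0.90, 1e-3))
        assert twice == once
        assert report2.n_samples_removed == 0
        assert report2.n_snps_removed_callrate + report2.n_snps_removed_hwe == 0

    def test_sample_removal_can_rescue_marker(self):
        # marker misses only in the bad sample; dropping the sample first
        # restores the marker's call rate
        calls = np.zeros((10, 10), dtype=np.int8)
        calls[0, :] = MISSING
        calls[0, 0] = 0  # sample call rate 0.1 -> removed
        ds = make_dataset(calls)
        filtered, report = run_qc(ds, QCConfig(0.90, 0.95, 1e-6))
        assert report.n_samples_removed == 1
        assert report.n_snps_removed_callrate == 0
        assert filtered.n_markers == 10
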