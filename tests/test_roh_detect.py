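import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rohscan.datamodel import MISSING
from rohscan.roh_detect import (
    ROHDetectionConfig,
    ROHSegment,
    detect_roh,
    min_snp_count,
    roh_length,
)

from conftest import make_dataset
from oracles import brute_force_roh, min_snp_count_decimal


def segments_as_windows(segments, positions):
    pos_idx = {p: i for i, p in enumerate(positions)}
    return sorted(
        (pos_idx[s.start_bp], pos_idx[s.end_bp], s.n_het, s.n_missing)
        for s in segments
    )


class TestMinSnpCount:
    def test_equal_logs_give_one(self):
        assert min_snp_count(1, 1, 0.5, 0.5) == 1

    def test_direct_evaluation(self):
        # ln(0.05 / 100000) / ln(0.5) = 20.93... -> 21
        assert min_snp_count(1000, 100, 0.05, 0.5) == 21
        assert min_snp_count(1000, 100, 0.05, 0.5) == min_snp_count_decimal(
            1000, 100, "0.05", "0.5"
        )

    def test_array_scale_evaluation(self):
        assert min_snp_count(106_828, 189, 0.05, 0.37) == 43
        assert min_snp_count(106_828, 189, 0.05, 0.37) == min_snp_count_decimal(
            106_828, 189, "0.05", "0.37"
        )

    @pytest.mark.parametrize(
        "n_s,n_i,alpha,het",
        [
            (n_s, n_i, a, h)
            for n_s in (10, 5_000, 106_828)
            for n_i in (1, 189)
            for a in ("0.01", "0.05", "0.5")
            for h in ("0.05", "0.37", "0.9")
        ],
    )
    def test_grid_matches_decimal_oracle(self, n_s, n_i, alpha, het):
        assert min_snp_count(n_s, n_i, float(alpha), float(het)) == min_snp_count_decimal(
            n_s, n_i, alpha, het
        )

    def test_monotonicity(self):
        base = dict(n_s=10_000, n_i=100, alpha=0.05, mean_het=0.3)
        l0 = min_snp_count(**base)
        assert min_snp_count(20_000, 100, 0.05, 0.3) >= l0  # more SNPs
        assert min_snp_count(10_000, 200, 0.05, 0.3) >= l0  # more individuals
        assert min_snp_count(10_000, 100, 0.01, 0.3) >= l0  # stricter alpha
        assert min_snp_count(10_000, 100, 0.05, 0.4) <= l0  # higher het

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            min_snp_count(100, 10, 0.05, 1.0)
        with pytest.raises(ValueError):
            min_snp_count(0, 10, 0.05, 0.3)


class TestDetectROH:
    def cfg(self, **kw):
        kw.setdefault("mean_het", 0.35)
        kw.setdefault("min_snps", 20)
        return ROHDetectionConfig(**kw)

    def test_all_heterozygous_yields_nothing(self):
        ds = make_dataset(np.ones((1, 40), dtype=np.int8))
        assert detect_roh(ds, self.cfg()) == []

    def test_clean_homozygous_run(self):
        # 25 hom SNPs at 25 kb spacing -> span 600 kb
        ds = make_dataset(np.zeros((1, 25), dtype=np.int8))
        segs = detect_roh(ds, self.cfg())
        assert len(segs) == 1
        s = segs[0]
        assert (s.start_bp, s.end_bp, s.n_snps, s.n_het) == (25_000, 625_000, 25, 0)
        assert roh_length(s) == 600_000

    def test_single_het_tolerated_or_splitting(self):
        calls = np.zeros((1, 25), dtype=np.int8)
        calls[0, 12] = 1  # position 13
        segs = detect_roh(make_dataset(calls), self.cfg(max_het_in_run=1))
        assert len(segs) == 1 and segs[0].n_het == 1
        segs0 = detect_roh(make_dataset(calls), self.cfg(max_het_in_run=0))
        assert segs0 == []  # each half has only 12-13 SNPs < 20

    def test_gap_splits_run(self):
        pos = [25_000 * (j + 1) for j in range(25)]
        pos = pos[:10] + [p + 2_000_000 for p in pos[10:]]
        ds = make_dataset(np.zeros((1, 25), dtype=np.int8), positions=pos)
        assert detect_roh(ds, self.cfg()) == []  # neither block reaches 20 SNPs

    def test_run_trimmed_to_homozygous_ends(self):
        calls = np.zeros((1, 27), dtype=np.int8)
        calls[0, 0] = 1
        calls[0, 26] = MISSING
        segs = detect_roh(make_dataset(calls), self.cfg())
        assert len(segs) == 1
        assert segs[0].start_bp == 50_000  # first hom SNP
        assert segs[0].end_bp == 650_000  # last hom SNP
        assert segs[0].n_het == 0 and segs[0].n_missing == 0

    def test_emitted_segments_satisfy_invariants(self, rng):
        cfg = self.cfg(min_snps=10, min_length_bp=100_000)
        calls = rng.choice(
            [0, 1, 2, MISSING], size=(20, 300), p=[0.45, 0.2, 0.3, 0.05]
        ).astype(np.int8)
        ds = make_dataset(calls, positions=sorted(rng.choice(
            np.arange(1, 3_000_000), size=300, replace=False).tolist()))
        for s in detect_roh(ds, cfg):
            assert s.end_bp > s.start_bp
            assert s.n_het <= cfg.max_het_in_run
            assert s.n_missing <= cfg.max_missing_in_run
            assert s.n_snps >= cfg.min_snps
            assert roh_length(s) >= cfg.min_length_bp

    def test_oracle_equivalence_random_chromosomes(self, rng):
        for _ in range(40):
            n = int(rng.integers(5, 200))
            pos = np.sort(rng.choice(np.arange(1, 5_000_001), size=n, replace=False))
            calls = rng.choice(
                [0, 1, 2, MISSING], size=n, p=[0.55, 0.15, 0.25, 0.05]
            ).astype(np.int8)
            cfg = ROHDetectionConfig(
                mean_het=0.3,
                min_snps=int(rng.integers(2, 15)),
                min_length_bp=int(rng.integers(1, 800_000)),
                max_het_in_run=int(rng.integers(0, 3)),
                max_missing_in_run=int(rng.integers(0, 3)),
                max_gap_bp=int(rng.integers(100_000, 2_000_000)),
            )
            ds = make_dataset(calls, positions=pos.tolist())
            got = segments_as_windows(detect_roh(ds, cfg), pos.tolist())
            expected = brute_force_roh(
                calls, pos,
                min_snps=cfg.min_snps, min_length_bp=cfg.min_length_bp,
                max_het=cfg.max_het_in_run, max_missing=cfg.max_missing_in_run,
                max_gap_bp=cfg.max_gap_bp,
            )
            assert got == expected

    def test_monotone_in_thresholds(self, rng):
        calls = rng.choice([0, 1, 2], size=(5, 200), p=[0.5, 0.15, 0.35]).astype(np.int8)
        ds = make_dataset(calls)
        base = detect_roh(ds, self.cfg(min_snps=8, min_length_bp=100_000))
        stricter = detect_roh(ds, self.cfg(min_snps=12, min_length_bp=100_000))
        longer = detect_roh(ds, self.cfg(min_snps=8, min_length_bp=300_000))
        assert len(stricter) <= len(base)
        assert len(longer) <= len(base)

        lax_het = detect_roh(ds, self.cfg(min_snps=8, min_length_bp=100_000, max_het_in_run=2))
        # union of covered bp never shrinks when the het allowance grows
        base_cov = set()
        for s in base:
            base_cov |= set(range(s.start_bp, s.end_bp + 1, 25_000))
        lax_cov = set()
        for s in lax_het:
            lax_cov |= set(range(s.start_bp, s.end_bp + 1, 25_000))
        assert base_cov <= lax_cov


class TestROHLength:
    @pytest.mark.parametrize(
        "start,end,expected",
        [(64_228_423, 66_040_326, 1_811_903), (24_326_513, 25_098_364, 771_851)],
    )
    def test_published_convention(self, start, end, expected):
        seg = ROHSegment("s", "13", start, end, 47)
        assert roh_length(seg) == expected

    def test_degenerate_segment_forbidden(self):
        with pytest.raises(ValueError):
            ROHSegment("s", "1", 100, 100, 1)


@given(st.data())
@settings(max_examples=40, deadline=None)
def test_detector_equals_oracle_property(data):
    n = data.draw(st.integers(5, 60))
    calls = np.array(
        data.draw(st.lists(st.sampled_from([0, 1, 2, MISSING]), min_size=n, max_size=n)),
        dtype=np.int8,
    )
    gaps = data.draw(st.lists(st.integers(1, 200_000), min_size=n, max_size=n))
    pos = np.cumsum(gaps)
    cfg = ROHDetectionConfig(
        mean_het=0.3,
        min_snps=data.draw(st.integers(1, 10)),
        min_length_bp=data.draw(st.integers(1, 500_000)),
        max_het_in_run=data.draw(st.integers(0, 2)),
        max_missing_in_run=data.draw(st.integers(0, 2)),
        max_gap_bp=data.draw(st.integers(50_000, 500_000)),
    )
    ds = make_dataset(calls, positions=pos.tolist())
    got = segments_as_windows(detect_roh(ds, cfg), pos.tolist())
    expected = brute_force_roh(
        calls, pos,
        min_snps=cfg.min_snps, min_length_bp=cfg.min_length_bp,
        max_het=cfg.max_het_in_run, max_missing=cfg.max_missing_in_run,
        max_gap_bp=cfg.max_gap_bp,
    )
    assert got == expected
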