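"""Fragment extraction, profile counting, QC, centering and clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from fragscreen import fragmentation_profile as fp
from fragscreen import synthetic_data as sd
from fragscreen.fragmentation_profile import FragmentRecord, ProfileMatrix


class TestReadFragments:
    def test_bed_line_length_arithmetic(self, tmp_path):
        bed = tmp_path / "f.bed"
        bed.write_text("chr1\t100\t267\n")
        (rec,) = list(fp.read_fragments(bed))
        assert rec.length == 167

    def test_mapq_filter_drops_known_fraction(self, tmp_path, small_binset, rng):
        # 1000 fragments, exactly 100 at mapq 20 (below the default 30)
        lines = []
        for i in range(1000):
            mapq = 20 if i < 100 else 60
            lines.append(f"chr1\t{1000 + i}\t{1160 + i}\tfrag{i}\t{mapq}")
        bed = tmp_path / "f.bed"
        bed.write_text("\n".join(lines) + "\n")
        stats = fp.ReadStats()
        recs = list(fp.read_fragments(bed, stats=stats))
        assert len(recs) == 900
        assert stats.n_low_mapq == 100

    def test_degenerate_span_skipped_with_counter(self, tmp_path):
        bed = tmp_path / "f.bed"
        bed.write_text("chr1\t100\t100\nchr1\t200\t360\n")
        stats = fp.ReadStats()
        recs = list(fp.read_fragments(bed, stats=stats))
        assert len(recs) == 1
        assert stats.n_degenerate == 1

    def test_bam_pairs_yield_outer_coordinates(self, tmp_path):
        pysam = pytest.importorskip("pysam")
        header = {"HD": {"VN": "1.6", "SO": "coordinate"},
                  "SQ": [{"SN": "chr1", "LN": 10_000_000}]}
        bam_path = tmp_path / "t.bam"
        with pysam.AlignmentFile(bam_path, "wb", header=header) as bam:
            for i, (pos, tlen, mapq) in enumerate(
                [(1000, 167, 60), (2000, 150, 60), (3000, 200, 10)]
            ):
                for read1 in (True, False):
                    a = pysam.AlignedSegment()
                    a.query_name = f"pair{i}"
                    a.query_sequence = "A" * 50
                    a.reference_id = 0
                    a.reference_start = pos if read1 else pos + tlen - 50
                    a.cigarstring = "50M"
                    a.flag = (0x1 | 0x2) | (0x40 if read1 else 0x80) | (0x10 if not read1 else 0x20)
                    a.mapping_quality = mapq
                    a.template_length = tlen if read1 else -tlen
                    a.next_reference_id = 0
                    a.next_reference_start = pos + tlen - 50 if read1 else pos
                    bam.write(a)
        pysam.index(str(bam_path))
        recs = list(fp.read_fragments(bam_path))
        assert [(r.start, r.end) for r in recs] == [(1000, 1167), (2000, 2150)]


def _frag(chrom, start, length, mapq=60):
    return FragmentRecord(chrom=chrom, start=start, end=start + length, mapq=mapq)


class TestComputeProfile:
    def test_all_short_fragments_saturate(self, small_binset):
        frags = [_frag("chr1", 1000 + i, 150) for i in range(100)]
        prof = fp.compute_profile(frags, small_binset)
        occupied = prof.total_counts > 0
        assert occupied.sum() == 1
        assert prof.proportions[occupied][0] == 1.0

    def test_size_window_inclusive_on_both_ends(self, small_binset):
        frags = [_frag("chr1", 1000, L) for L in (99, 100, 167, 168)]
        prof = fp.compute_profile(frags, small_binset)
        b = np.argmax(prof.total_counts)
        assert prof.total_counts[b] == 4
        assert prof.short_counts[b] == 2
        assert prof.proportions[b] == 0.5

    def test_no_fragments_fails_qc(self, small_binset):
        prof = fp.compute_profile([], small_binset)
        assert not prof.qc_pass
        assert np.isnan(prof.proportions).all()

    def test_matches_naive_double_loop(self, small_binset, rng):
        n = 3000
        chroms = rng.choice([b.chrom for b in small_binset.bins], n)
        starts = rng.integers(0, 4_000_000, n)
        lengths = rng.integers(50, 1200, n)
        frags = [_frag(c, int(s), int(L)) for c, s, L in zip(chroms, starts, lengths)]
        prof = fp.compute_profile(frags, small_binset)

        short = np.zeros(len(small_binset), dtype=int)
        total = np.zeros(len(small_binset), dtype=int)
        for f in frags:
            if not 1 <= f.length <= fp.DEFAULT_MAX_LENGTH:
                continue
            mid = (f.start + f.end) // 2
            for j, b in enumerate(small_binset.bins):
                if b.chrom == f.chrom and b.start <= mid < b.end:
                    total[j] += 1
                    if 100 <= f.length <= 167:
                        short[j] += 1
                    break
        assert np.array_equal(prof.total_counts, total)
        assert np.array_equal(prof.short_counts, short)

    def test_short_count_conservation(self, small_binset, rng):
        frags = [
            _frag("chr1", int(s), int(L))
            for s, L in zip(rng.integers(0, 4_500_000, 2000), rng.integers(90, 200, 2000))
        ]
        prof = fp.compute_profile(frags, small_binset)
        expected = sum(
            1 for f in frags
            if 100 <= f.length <= 167
            and small_binset.lookup_midpoint(f.chrom, f.start, f.end) is not None
        )
        assert prof.short_counts.sum() == expected

    def test_order_invariance(self, small_binset, rng):
        frags = [
            _frag("chr2", int(s), int(L))
            for s, L in zip(rng.integers(0, 4_000_000, 500), rng.integers(90, 300, 500))
        ]
        p1 = fp.compute_profile(frags, small_binset)
        p2 = fp.compute_profile(frags[::-1], small_binset)
        assert np.array_equal(p1.total_counts, p2.total_counts)
        assert np.array_equal(p1.short_counts, p2.short_counts)

    def test_recovers_programmed_proportions_within_3se(self, rng):
        """Estimated per-bin proportions converge to generator truth."""
        cfg = sd.CohortConfig(n_bins=500, n_arms=5, sample_noise_sd=0.0, global_noise_sd=0.0)
        binset = sd.make_binset(cfg)
        truth = sd.draw_truth(cfg, binset, rng)
        short, total = sd.sample_profile_counts(
            cfg, truth, binset, rng, tumor_fraction=0.0, n_fragments=500_000
        )
        p_true = truth.p0
        p_hat = short / total
        se = np.sqrt(p_true * (1 - p_true) / total)
        within = np.abs(p_hat - p_true) <= 3 * se
        assert within.mean() >= 0.99


class TestQCFilter:
    def test_boundary(self, small_binset):
        prof = fp.SampleProfile(
            "s", small_binset.labels,
            np.zeros(len(small_binset), dtype=int),
            np.full(len(small_binset), 4_999_999 // len(small_binset) + 1, dtype=int),
        )
        prof.total_counts[0] -= prof.n_fragments_total - 4_999_999
        assert prof.n_fragments_total == 4_999_999
        assert not fp.qc_filter(prof)

    def test_cohort_retention_bookkeeping(self, small_binset, rng):
        # 427 profiles of which 24 are under-sequenced -> 403 retained
        n_bins = len(small_binset)
        profiles = []
        for i in range(427):
            n = 1000 if i >= 24 else 10
            total = rng.multinomial(n, np.ones(n_bins) / n_bins)
            profiles.append(
                fp.SampleProfile(f"s{i}", small_binset.labels, np.zeros(n_bins, int), total)
            )
        retained = [p for p in profiles if fp.qc_filter(p, min_fragments=1000)]
        assert len(retained) == 403

    def test_zero_threshold_disables_filter(self, small_binset):
        prof = fp.SampleProfile(
            "s", small_binset.labels,
            np.zeros(len(small_binset), int), np.zeros(len(small_binset), int),
        )
        assert fp.qc_filter(prof, min_fragments=0)


class TestCenterRows:
    def test_arithmetic(self):
        m = ProfileMatrix(["a"], ["b1", "b2", "b3"], np.array([[0.2, 0.4, 0.6]]))
        c = fp.center_rows(m)
        assert np.allclose(c.values, [[-0.2, 0.0, 0.2]])
        assert c.centered

    def test_idempotence(self, rng):
        m = ProfileMatrix(
            [f"s{i}" for i in range(5)], [f"b{j}" for j in range(8)], rng.random((5, 8))
        )
        once = fp.center_rows(m)
        twice = fp.center_rows(once)
        assert np.allclose(once.values, twice.values)

    def test_row_means_vanish(self, rng):
        m = ProfileMatrix(
            [f"s{i}" for i in range(20)], [f"b{j}" for j in range(50)], rng.random((20, 50))
        )
        c = fp.center_rows(m)
        assert np.abs(c.values.mean(axis=1)).max() < 1e-12

    def test_all_missing_row_names_sample(self):
        m = ProfileMatrix(["bad"], ["b1", "b2"], np.array([[np.nan, np.nan]]))
        with pytest.raises(ValueError, match="bad"):
            fp.impute_missing(m)

    def test_imputation_neutral_under_centering(self):
        m = ProfileMatrix(["s"], ["b1", "b2", "b3"], np.array([[0.2, np.nan, 0.4]]))
        c = fp.center_rows(fp.impute_missing(m))
        assert c.values[0, 1] == pytest.approx(0.0)


class TestCaseControlRatio:
    def test_identical_groups_give_unit_ratio(self, rng):
        vals = np.tile(rng.random(10), (6, 1))
        m = ProfileMatrix([f"s{i}" for i in range(6)], [f"b{j}" for j in range(10)], vals)
        ratio = fp.case_control_ratio(m, [1, 1, 1, 0, 0, 0])
        assert np.allclose(ratio, 1.0)

    def test_programmed_enrichment_recovered_exactly(self):
        p0 = np.full(10, 0.2)
        case = p0.copy()
        case[[2, 5]] *= 2.0
        vals = np.vstack([case, case, p0, p0])
        m = ProfileMatrix(["c1", "c2", "n1", "n2"], [f"b{j}" for j in range(10)], vals)
        ratio = fp.case_control_ratio(m, [1, 1, 0, 0])
        assert np.allclose(ratio[[2, 5]], 2.0)
        assert np.allclose(np.delete(ratio, [2, 5]), 1.0)

    def test_one_class_empty_rejected(self, rng):
        m = ProfileMatrix(["a", "b"], ["b1"], rng.random((2, 1)))
        with pytest.raises(ValueError):
            fp.case_control_ratio(m, [1, 1])


class TestClusterSamples:
    def test_two_identical_blocks_recovered(self):
        block1 = np.tile([0.1, 0.9, 0.1, 0.9], (4, 1))
        block2 = np.tile([0.9, 0.1, 0.9, 0.1], (4, 1))
        m = ProfileMatrix(
            [f"s{i}" for i in range(8)], [f"b{j}" for j in range(4)],
            np.vstack([block1, block2]),
        )
        res = fp.cluster_samples(m)
        assert len(set(res.two_group_labels[:4])) == 1
        assert len(set(res.two_group_labels[4:])) == 1
        assert res.two_group_labels[0] != res.two_group_labels[-1]

    def test_single_outlier_merges_last(self, rng):
        base = np.tile(rng.random(6), (5, 1))
        outlier = base[0] + 5.0
        m = ProfileMatrix(
            [f"s{i}" for i in range(6)], [f"b{j}" for j in range(6)],
            np.vstack([base, outlier]),
        )
        res = fp.cluster_samples(m)
        # last merge in the linkage joins the outlier singleton
        np.testing.assert_array_equal(np.sort(res.two_group_labels), [1, 1, 1, 1, 1, 2])

    def test_synthetic_cohort_separates_cases(self, small_cohort):
        res = fp.cluster_samples(small_cohort.matrix)
        y = (small_cohort.metadata["label"] == "case").astype(int)
        assert adjusted_rand_score(y, res.two_group_labels) > 0.9

    def test_fewer_than_two_samples_rejected(self):
        m = ProfileMatrix(["s"], ["b1"], np.array([[0.5]]))
        with pytest.raises(ValueError):
            fp.cluster_samples(m)
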