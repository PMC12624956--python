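"""Event-track conversions, normalization, metagene projection, sRNA filter."""

import numpy as np
import pytest

from trctools.coverage import (
    EmptyLibraryError,
    LayoutMismatchError,
    StrandedCoverage,
    StrandedRead,
    filter_srna_reads,
    log2_ratio,
    metaplot_matrix,
    reads_to_3oh_events,
    reads_to_5prime_events,
    rpm_normalize,
    subtract,
)
from trctools.genome import ConfigurationError, GeneAnnotation, GenomeLayout


class TestFivePrimeEvents:
    def test_plus_read_counts_at_start(self, small_layout):
        cov = reads_to_5prime_events([StrandedRead("chr1", 100, 128, "+")], small_layout)
        assert cov.get("chr1", "+")[100] == 1
        assert cov.get("chr1", "+").sum() == 1

    def test_minus_read_counts_at_end_minus_one(self, small_layout):
        cov = reads_to_5prime_events([StrandedRead("chr1", 100, 128, "-")], small_layout)
        assert cov.get("chr1", "-")[127] == 1

    def test_count_conservation(self, small_layout, rng):
        reads = [
            StrandedRead("chr1", int(s), int(s) + 30, "+" if b else "-")
            for s, b in zip(rng.integers(0, 19_000, 10_000), rng.integers(0, 2, 10_000))
        ]
        cov = reads_to_5prime_events(reads, small_layout)
        assert cov.total_events == 10_000
        assert cov.sum() == 10_000

    def test_out_of_bounds_read_raises(self, small_layout):
        with pytest.raises(Exception, match="read 0"):
            reads_to_5prime_events([StrandedRead("chr1", 19_990, 20_020, "+")], small_layout)


class TestThreePrimeOHEvents:
    @pytest.mark.parametrize(
        "read,mode,strand,pos",
        [
            (StrandedRead("chr1", 100, 128, "+"), "adjacent", "-", 99),
            (StrandedRead("chr1", 100, 128, "-"), "adjacent", "+", 128),
            (StrandedRead("chr1", 100, 128, "+"), "coincident", "-", 100),
            (StrandedRead("chr1", 100, 128, "-"), "coincident", "+", 127),
        ],
    )
    def test_placement_conventions(self, small_layout, read, mode, strand, pos):
        cov = reads_to_3oh_events([read], small_layout, shift_mode=mode)
        assert cov.get("chr1", strand)[pos] == 1

    def test_off_chromosome_event_dropped_and_counted(self, small_layout):
        with pytest.warns(UserWarning):
            cov = reads_to_3oh_events([StrandedRead("chr1", 0, 28, "+")], small_layout)
        assert cov.n_dropped == 1
        assert cov.total_events == 0


class TestNormalization:
    def test_rpm_arithmetic(self, small_layout):
        cov = StrandedCoverage.zeros(small_layout)
        cov.data["chr1"]["+"][10] = 4
        cov.total_events = 4
        out = rpm_normalize(cov, library_total=2_000_000)
        assert out.get("chr1", "+")[10] == 2.0
        assert out.norm_state == "RPM"

    def test_whole_library_sums_to_1e6(self, small_layout, rng):
        reads = [StrandedRead("chr1", int(s), int(s) + 30, "+") for s in rng.integers(0, 19000, 500)]
        out = rpm_normalize(reads_to_5prime_events(reads, small_layout))
        assert out.sum() == pytest.approx(1e6)

    def test_scale_invariance(self, small_layout):
        reads = [StrandedRead("chr1", 100, 130, "+"), StrandedRead("chr1", 200, 230, "-")]
        a = rpm_normalize(reads_to_5prime_events(reads, small_layout))
        b = rpm_normalize(reads_to_5prime_events(reads * 7, small_layout))
        for strand in "+-":
            np.testing.assert_allclose(a.get("chr1", strand), b.get("chr1", strand))

    def test_empty_library_raises(self, small_layout):
        with pytest.raises(EmptyLibraryError):
            rpm_normalize(StrandedCoverage.zeros(small_layout))

    def test_log2_ratio_arithmetic(self, small_layout):
        a = StrandedCoverage.zeros(small_layout, norm_state="RPM")
        b = StrandedCoverage.zeros(small_layout, norm_state="RPM")
        a.data["chr1"]["+"][5] = 4.0
        b.data["chr1"]["+"][5] = 1.0
        out = log2_ratio(a, b, pseudocount=1.0)
        assert out.get("chr1", "+")[5] == pytest.approx(np.log2(5 / 2))
        assert out.get("chr1", "+")[6] == 0.0  # 0 vs 0 with pseudocount

    def test_log2_identity_is_zero(self, small_layout, rng):
        a = StrandedCoverage.zeros(small_layout, norm_state="RPM")
        a.data["chr1"]["+"][:] = rng.random(20_000)
        out = log2_ratio(a, a)
        assert np.all(out.get("chr1", "+") == 0)

    def test_bad_pseudocount(self, small_layout):
        a = StrandedCoverage.zeros(small_layout, norm_state="RPM")
        with pytest.raises(ConfigurationError):
            log2_ratio(a, a, pseudocount=0)

    def test_subtract(self, small_layout):
        a = StrandedCoverage.zeros(small_layout, norm_state="log2ratio")
        b = StrandedCoverage.zeros(small_layout, norm_state="log2ratio")
        a.data["chr1"]["+"][3] = 1.5
        b.data["chr1"]["+"][3] = 0.5
        out = subtract(a, b)
        assert out.get("chr1", "+")[3] == 1.0
        assert subtract(a, a).sum() == 0.0

    def test_subtract_layout_mismatch(self, small_layout):
        other = StrandedCoverage.zeros(GenomeLayout({"chrX": 100}))
        with pytest.raises(LayoutMismatchError):
            subtract(StrandedCoverage.zeros(small_layout), other)


class TestMetaplot:
    def uniform_cov(self, layout, c=2.0):
        cov = StrandedCoverage.zeros(layout, norm_state="RPM")
        for chrom in layout.chroms:
            cov.data[chrom]["+"][:] = c
            cov.data[chrom]["-"][:] = c
        return cov

    def test_uniform_coverage_gives_constant_matrix(self, small_layout, plus_gene, minus_gene):
        cov = self.uniform_cov(small_layout, 2.0)
        m = metaplot_matrix(cov, [plus_gene, minus_gene], orientation="sense")
        np.testing.assert_allclose(m.values, 2.0)
        assert m.values.shape == (2, 50 + 100 + 50)

    def test_tss_event_lands_in_first_body_bin_plus(self, small_layout, plus_gene):
        cov = StrandedCoverage.zeros(small_layout)
        cov.data["chr1"]["+"][plus_gene.tss] = 1
        m = metaplot_matrix(cov, [plus_gene], orientation="sense")
        row = m.values[0]
        body = row[m.n_up : m.n_up + m.n_body]
        assert body[0] > 0
        assert np.count_nonzero(row) == 1

    def test_tss_event_first_body_bin_minus_transcription_order(self, small_layout, minus_gene):
        cov = StrandedCoverage.zeros(small_layout)
        cov.data["chr1"]["-"][minus_gene.tss] = 1  # tss = end - 1
        m = metaplot_matrix(cov, [minus_gene], orientation="sense")
        row = m.values[0]
        assert row[m.n_up] > 0  # first transcription-order body bin
        assert np.count_nonzero(row) == 1

    def test_strand_flip_symmetry(self, small_layout, rng):
        cov = StrandedCoverage.zeros(small_layout)
        pos = rng.integers(1000, 10_000, 300)
        np.add.at(cov.data["chr1"]["+"], pos, 1.0)
        gene = GeneAnnotation("g", "chr1", 2000, 5000, "+")
        m1 = metaplot_matrix(cov, [gene], orientation="sense")

        flipped = StrandedCoverage.zeros(small_layout)
        flipped.data["chr1"]["-"] = cov.data["chr1"]["+"][::-1].copy()
        L = small_layout.length("chr1")
        gene_f = GeneAnnotation("g", "chr1", L - 5000, L - 2000, "-")
        m2 = metaplot_matrix(flipped, [gene_f], orientation="sense")
        np.testing.assert_allclose(m1.values, m2.values)

    def test_antisense_orientation_selects_opposite_strand(self, small_layout, plus_gene):
        cov = StrandedCoverage.zeros(small_layout)
        cov.data["chr1"]["-"][plus_gene.start + 50] = 1
        assert metaplot_matrix(cov, [plus_gene], orientation="sense").values.sum() == 0
        assert metaplot_matrix(cov, [plus_gene], orientation="antisense").values.sum() > 0

    def test_commutes_with_rpm_up_to_scalar(self, small_layout, plus_gene, rng):
        reads = [
            StrandedRead("chr1", int(s), int(s) + 30, "+") for s in rng.integers(1000, 9000, 400)
        ]
        raw = reads_to_5prime_events(reads, small_layout)
        m_raw = metaplot_matrix(raw, [plus_gene])
        m_rpm = metaplot_matrix(rpm_normalize(raw), [plus_gene])
        np.testing.assert_allclose(m_rpm.values, m_raw.values * 1e6 / 400)

    def test_flank_not_multiple_of_bin_raises(self, small_layout, plus_gene):
        cov = self.uniform_cov(small_layout)
        with pytest.raises(ConfigurationError):
            metaplot_matrix(cov, [plus_gene], up=505, flank_bin=10)

    def test_short_gene_dropped_with_warning(self, small_layout):
        cov = self.uniform_cov(small_layout)
        short = GeneAnnotation("tiny", "chr1", 100, 150, "+")
        with pytest.warns(UserWarning):
            m = metaplot_matrix(cov, [short], body_bins=100)
        assert m.gene_ids == []
        assert m.dropped_gene_ids == ["tiny"]


class TestSrnaFilter:
    def test_worked_example(self):
        reads = ["A" * 19, "C" * 20, "G" * 45, "G" * 45, "T" * 70, "A" * 71]
        out = filter_srna_reads(reads)
        assert sorted(len(s) for s in out) == [20, 45, 70]

    def test_idempotent(self):
        reads = ["ACGT" * 6, "ACGT" * 6, "TTTTT" * 5]
        once = filter_srna_reads(reads)
        assert filter_srna_reads(once) == once

    def test_identity_when_clean(self):
        reads = ["A" * 25, "C" * 30]
        assert filter_srna_reads(reads) == reads

    def test_empty(self):
        assert filter_srna_reads([]) == []
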