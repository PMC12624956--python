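"""Simulator contracts: determinism, exact counts, closed-form expectations."""

import numpy as np
import pytest

from trctools.coverage import reads_to_5prime_events, rpm_normalize, log2_ratio
from trctools.genome import ConfigurationError, GeneAnnotation, GenomeLayout, OriginAnnotation
from trctools.simulate import (
    SimConfig,
    events_to_coverage,
    simulate_brdu_reads,
    simulate_chip_pair,
    simulate_gloeseq,
    simulate_proseq,
    simulate_srna,
    toy_genome,
    trapezoid_profile,
)


def single_gene_config(seed=1, L=1100, r=10.0, w_p=100, n=50_000, **kw):
    layout = GenomeLayout({"chr1": 100_000})
    gene = GeneAnnotation("g1", "chr1", 10_000, 10_000 + L, "+")
    origin = OriginAnnotation("o1", "chr1", 50_000)
    return SimConfig(
        seed=seed, layout=layout, genes=[gene], origins=[origin],
        n_reads_proseq=n, pause_ratio=r, pause_width=w_p,
        background_fraction=0.0, **kw,
    )


class TestDeterminism:
    def test_same_seed_identical_outputs(self):
        layout, genes, origins = toy_genome(3)
        mk = lambda: SimConfig(seed=3, layout=layout, genes=genes, origins=origins,
                               n_reads_proseq=5000, n_reads_gloeseq=5000,
                               n_reads_chip=2000, n_reads_srna=500, n_brdu_reads=5)
        a, b = mk(), mk()
        assert simulate_proseq(a)[0] == simulate_proseq(b)[0]
        assert simulate_gloeseq(a)[0] == simulate_gloeseq(b)[0]
        assert simulate_srna(a) == simulate_srna(b)
        ra, _ = simulate_brdu_reads(a)
        rb, _ = simulate_brdu_reads(b)
        for x, y in zip(ra, rb):
            np.testing.assert_array_equal(x.values, y.values)

    def test_different_seeds_differ(self):
        a = single_gene_config(seed=1, n=1000)
        b = single_gene_config(seed=2, n=1000)
        assert simulate_proseq(a)[0] != simulate_proseq(b)[0]

    def test_assay_streams_independent(self):
        # consuming one assay's stream must not perturb another's
        cfg1 = single_gene_config(seed=5, n=1000)
        _ = simulate_gloeseq(single_gene_config(seed=5, n=1000))
        cfg2 = single_gene_config(seed=5, n=1000)
        assert simulate_proseq(cfg1)[0] == simulate_proseq(cfg2)[0]


class TestProseq:
    def test_read_count_exact(self):
        reads, _ = simulate_proseq(single_gene_config(n=12_345))
        assert len(reads) == 12_345

    def test_pause_window_mixture_weight(self):
        # r=10, w_p=100, L=1100 -> q = 1000/(1000+1000) = 0.5
        cfg = single_gene_config(L=1100, r=10.0, w_p=100, n=50_000)
        reads, _ = simulate_proseq(cfg)
        gene = cfg.genes[0]
        in_pause = sum(1 for rd in reads if gene.start <= rd.start < gene.start + 100)
        frac = in_pause / len(reads)
        se = np.sqrt(0.25 / len(reads))
        assert abs(frac - 0.5) <= 3 * se

    def test_uniform_limit_r1_gives_pi_one(self):
        cfg = single_gene_config(L=2100, r=1.0, n=80_000)
        reads, _ = simulate_proseq(cfg)
        cov = rpm_normalize(reads_to_5prime_events(reads, cfg.layout))
        from trctools.pausing import PauseConfig, pausing_index

        pi, _ = pausing_index(cov, cfg.genes[0], PauseConfig())
        assert pi == pytest.approx(1.0, rel=0.1)

    def test_reads_carry_gene_strand(self):
        layout = GenomeLayout({"chr1": 100_000})
        gene = GeneAnnotation("g", "chr1", 10_000, 14_000, "-")
        cfg = SimConfig(seed=1, layout=layout, genes=[gene],
                        origins=[OriginAnnotation("o", "chr1", 50_000)],
                        n_reads_proseq=500, background_fraction=0.0)
        reads, _ = simulate_proseq(cfg)
        assert all(r.strand == "-" for r in reads)

    def test_short_gene_rejected_by_name(self):
        layout = GenomeLayout({"chr1": 100_000})
        gene = GeneAnnotation("stub", "chr1", 10, 180, "+")
        with pytest.raises(ConfigurationError, match="stub"):
            simulate_proseq(
                SimConfig(seed=1, layout=layout, genes=[gene],
                          origins=[OriginAnnotation("o", "chr1", 50)], n_reads_proseq=10)
            )


class TestGloeseq:
    def layout_one_origin(self):
        return GenomeLayout({"chr1": 100_000}), [OriginAnnotation("o", "chr1", 50_000)]

    def test_noiseless_rightward_region_all_reverse(self):
        layout, origins = self.layout_one_origin()
        cfg = SimConfig(seed=2, layout=layout, genes=[], origins=origins,
                        n_reads_gloeseq=5000, strand_noise=0.0)
        events, _ = simulate_gloeseq(cfg)
        right = [e for e in events if e.pos > 50_000]
        assert right and all(e.strand == "-" for e in right)
        left = [e for e in events if e.pos < 50_000]
        assert left and all(e.strand == "+" for e in left)

    def test_expected_rfd_one_minus_two_eps(self):
        layout, origins = self.layout_one_origin()
        cfg = SimConfig(seed=2, layout=layout, genes=[], origins=origins,
                        n_reads_gloeseq=100_000, strand_noise=0.05)
        events, _ = simulate_gloeseq(cfg)
        right = [e for e in events if e.pos > 50_000]
        rev = sum(1 for e in right if e.strand == "-")
        rfd = (rev - (len(right) - rev)) / len(right)
        se = 2 * np.sqrt(0.05 * 0.95 / len(right))  # d(rfd) = 2 d(p)
        assert abs(rfd - 0.9) <= 3 * se

    def test_symmetric_noise_rfd_zero(self):
        layout, origins = self.layout_one_origin()
        cfg = SimConfig(seed=2, layout=layout, genes=[], origins=origins,
                        n_reads_gloeseq=50_000, strand_noise=0.5)
        events, _ = simulate_gloeseq(cfg)
        rev = sum(1 for e in events if e.strand == "-")
        rfd = (2 * rev - len(events)) / len(events)
        assert abs(rfd) <= 3 * 2 / np.sqrt(len(events))

    def test_event_count_exact_and_noise_bound(self):
        layout, origins = self.layout_one_origin()
        cfg = SimConfig(seed=2, layout=layout, genes=[], origins=origins, n_reads_gloeseq=777)
        events, _ = simulate_gloeseq(cfg)
        assert len(events) == 777
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, layout=layout, genes=[], origins=origins, strand_noise=0.6)

    def test_chromosome_without_origin_rejected(self):
        layout = GenomeLayout({"chr1": 100_000, "chr2": 100_000})
        cfg = SimConfig(seed=1, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 50_000)], n_reads_gloeseq=100)
        with pytest.raises(ConfigurationError):
            simulate_gloeseq(cfg)


class TestBrdu:
    def test_trapezoid_half_amplitude_crossings_closed_form(self):
        # s=1800 nt/min, t_pulse=2, t_fall=1, r_w=100:
        # x_L = x0 + r_w/2 = 50; x_R = x0 + r_w + s*t_pulse + s*t_fall/2 = 4600
        prob = trapezoid_profile((1800.0, 2.0, 1.0, 100), 0.0, 1.0, 20_000, 0)
        half = 0.5
        x_l = np.argmax(prob >= half)
        x_r = len(prob) - np.argmax(prob[::-1] >= half) - 1
        assert x_l == pytest.approx(50, abs=1)
        assert x_r == pytest.approx(4600, abs=1)

    def test_read_without_fork_is_background(self):
        prob = trapezoid_profile((1800.0, 2.0, 1.0, 100), 0.02, 0.8, 5000, 100_000)
        np.testing.assert_allclose(prob, 0.02)

    def test_mirrored_fork_is_reflection(self):
        layout = GenomeLayout({"chr1": 200_000})
        cfg = SimConfig(seed=9, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 100_000)],
                        n_brdu_reads=20, brdu_bernoulli=False)
        reads, truth = simulate_brdu_reads(cfg)
        for rd, t in zip(reads, truth.forks):
            prof = rd.values
            s_nt = t.speed * 1000
            if t.direction == "left":
                prof = prof[::-1]
            rel = np.flatnonzero(prof > cfg.brdu_background + 0.5 * (cfg.brdu_high - cfg.brdu_background))
            span = rel[-1] - rel[0]
            # (r_w + s*t_pulse + s*t_fall/2) - r_w/2
            expected = 50 + s_nt * 2.5
            assert span == pytest.approx(expected, abs=5)

    def test_truth_records_speed_and_direction(self):
        layout = GenomeLayout({"chr1": 200_000})
        cfg = SimConfig(seed=9, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 100_000)], n_brdu_reads=10)
        reads, truth = simulate_brdu_reads(cfg)
        assert len(reads) == len(truth.forks) == 10
        assert all(t.speed > 0 and t.direction in ("left", "right") for t in truth.forks)


class TestChip:
    def test_fold_four_log2_ratio_near_two(self):
        # target small relative to the genome, so RPM renormalization of the
        # IP library barely deflates the in-target log2 ratio below log2(fold)
        layout = GenomeLayout({"chr1": 200_000})
        target = ("chr1", 50_000, 52_000)
        cfg = SimConfig(seed=4, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 100_000)],
                        n_reads_chip=200_000, chip_enrichment=4.0, chip_targets=[target])
        ip, inp, truth = simulate_chip_pair(cfg)
        assert len(ip) == len(inp) == 200_000
        ip_cov = rpm_normalize(reads_to_5prime_events(ip, layout))
        in_cov = rpm_normalize(reads_to_5prime_events(inp, layout))
        ip_in = sum(ip_cov.data["chr1"][s][50_000:52_000].sum() for s in "+-")
        in_in = sum(in_cov.data["chr1"][s][50_000:52_000].sum() for s in "+-")
        assert np.log2(ip_in / in_in) == pytest.approx(2.0, abs=0.15)

    def test_fold_one_exchangeable(self):
        layout = GenomeLayout({"chr1": 100_000})
        cfg = SimConfig(seed=4, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 50_000)],
                        n_reads_chip=20_000, chip_enrichment=1.0,
                        chip_targets=[("chr1", 10_000, 20_000)])
        ip, inp, _ = simulate_chip_pair(cfg)
        frac_ip = sum(1 for r in ip if 10_000 <= r.start < 20_000) / len(ip)
        frac_in = sum(1 for r in inp if 10_000 <= r.start < 20_000) / len(inp)
        assert frac_ip == pytest.approx(frac_in, abs=0.02)

    def test_zero_reads_empty(self):
        layout = GenomeLayout({"chr1": 100_000})
        cfg = SimConfig(seed=4, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 50_000)],
                        n_reads_chip=0, chip_targets=[("chr1", 10, 20)])
        ip, inp, _ = simulate_chip_pair(cfg)
        assert ip == [] and inp == []

    def test_bad_fold_rejected(self):
        layout = GenomeLayout({"chr1": 100_000})
        with pytest.raises(ConfigurationError):
            SimConfig(seed=1, layout=layout, genes=[],
                      origins=[OriginAnnotation("o", "chr1", 50)], chip_enrichment=0.0)


class TestSrna:
    def test_lengths_follow_support(self):
        layout = GenomeLayout({"chr1": 10_000})
        cfg = SimConfig(seed=6, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 5000)],
                        n_reads_srna=1000, duplicate_fraction=0.0,
                        srna_length_weights={n: 1.0 for n in range(25, 41)})
        reads = simulate_srna(cfg)
        assert len(reads) == 1000
        assert all(25 <= len(s) <= 40 for s in reads)

    def test_duplicate_fraction_approximate(self):
        layout = GenomeLayout({"chr1": 10_000})
        cfg = SimConfig(seed=6, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 5000)],
                        n_reads_srna=1000, duplicate_fraction=0.2)
        reads = simulate_srna(cfg)
        n_dup = len(reads) - len(set(reads))
        assert abs(n_dup - 200) <= 3 * np.sqrt(1000 * 0.2 * 0.8)

    def test_zero_reads(self):
        layout = GenomeLayout({"chr1": 10_000})
        cfg = SimConfig(seed=6, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 5000)], n_reads_srna=0)
        assert simulate_srna(cfg) == []

    def test_degenerate_weights_rejected(self):
        layout = GenomeLayout({"chr1": 10_000})
        cfg = SimConfig(seed=6, layout=layout, genes=[],
                        origins=[OriginAnnotation("o", "chr1", 5000)],
                        srna_length_weights={25: 0.0})
        with pytest.raises(ConfigurationError):
            simulate_srna(cfg)
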