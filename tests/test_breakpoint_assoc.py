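"""Window construction, breakpoint enrichment, kataegis detection."""

import numpy as np
import pytest

from breaksig import (Breakpoint, Callset, GenomeRef, VariantCall, SNS, INS,
                      DEL, build_windows, enrichment, per_breakpoint_counts,
                      detect_kataegis, rainfall_table)
from breaksig.breakpoint_assoc import WindowError


def genome_of(length=1_000_000, chrom="chr1", n_at=None):
    seq = list("A" * length)
    if n_at:
        for s, e in n_at:
            seq[s:e] = "N" * (e - s)
    return GenomeRef.from_sequences({chrom: "".join(seq)})


def snv(chrom, pos, ref="A", alt="G", vclass=SNS):
    return VariantCall(chrom, pos, ref, alt, vclass, 60.0, 30, "1/1", 1.0)


def callset(variants):
    return Callset("s", "ESC", sorted(variants, key=lambda v: (v.chrom, v.pos)),
                   mean_coverage=30.0)


class TestBuildWindows:
    def test_single_window(self):
        g = genome_of()
        ws = build_windows([Breakpoint("chr1", 100_000)], g, 50_000)
        assert ws.windows["chr1"].tolist() == [[50_000, 150_000]]
        assert ws.total_window_bp == 100_000
        assert ws.total_window_bp + ws.total_outside_bp == 1_000_000

    def test_merge_overlapping(self):
        g = genome_of()
        ws = build_windows([Breakpoint("chr1", 200_000),
                            Breakpoint("chr1", 260_000)], g, 50_000)
        assert ws.windows["chr1"].tolist() == [[150_000, 310_000]]
        assert ws.total_window_bp == 160_000

    def test_clip_to_chromosome(self):
        g = genome_of()
        ws = build_windows([Breakpoint("chr1", 10_000)], g, 50_000)
        assert ws.windows["chr1"].tolist() == [[0, 60_000]]

    def test_empty_breakpoints_refused(self):
        with pytest.raises(WindowError):
            build_windows([], genome_of(), 50_000)

    def test_effective_accounting_with_n_runs(self):
        g = genome_of(n_at=[(60_000, 80_000), (500_000, 510_000)])
        ws = build_windows([Breakpoint("chr1", 100_000)], g, 50_000)
        # brute-force oracle over every base
        seq = g.sequences["chr1"]
        inside = sum(1 for i in range(50_000, 150_000) if seq[i] != "N")
        total_eff = sum(1 for b in seq if b != "N")
        assert ws.total_window_bp == inside
        assert ws.total_window_bp + ws.total_outside_bp == total_eff

    def test_accounting_invariant_random_breakpoints(self, tiny_genome):
        rng = np.random.default_rng(0)
        for _ in range(10):
            bps = [Breakpoint(c, int(rng.integers(0, len(s))))
                   for c, s in tiny_genome.sequences.items()
                   for _ in range(rng.integers(1, 5))]
            ws = build_windows(bps, tiny_genome, int(rng.integers(50, 2000)))
            assert (ws.total_window_bp + ws.total_outside_bp
                    == tiny_genome.total_effective_size)


class TestEnrichment:
    def test_constructed_densities(self):
        # windows cover 10% of a 1 Mb genome; 10 SNSs inside, 10 outside
        g = genome_of()
        ws = build_windows([Breakpoint("chr1", 100_000)], g, 50_000)
        inside = [snv("chr1", p) for p in range(60_000, 70_000, 1000)]
        outside = [snv("chr1", p) for p in range(300_000, 400_000, 10_000)]
        res = enrichment(callset(inside + outside), ws, n_perm=100, seed=0)[SNS]
        assert (res.n_near, res.n_far) == (10, 10)
        assert res.density_near == pytest.approx(100.0)
        assert res.density_far == pytest.approx(10 / 0.9)
        assert res.ratio == pytest.approx(9.0)

    def test_uniform_null_ratio_near_one(self):
        g = genome_of()
        rng = np.random.default_rng(1)
        ws = build_windows([Breakpoint("chr1", int(p)) for p in
                            rng.integers(60_000, 940_000, 5)], g, 50_000)
        muts = [snv("chr1", int(p)) for p in
                np.unique(rng.integers(0, 1_000_000, 5000))]
        res = enrichment(callset(muts), ws, n_perm=200, seed=2)[SNS]
        assert 0.8 <= res.ratio <= 1.2

    def test_zero_variants_flagged(self):
        g = genome_of()
        ws = build_windows([Breakpoint("chr1", 100_000)], g, 50_000)
        res = enrichment(callset([]), ws, n_perm=50, seed=0)[SNS]
        assert np.isnan(res.ratio) and res.n_near == 0

    def test_all_inside_gives_inf_sentinel(self):
        g = genome_of()
        ws = build_windows([Breakpoint("chr1", 100_000)], g, 50_000)
        res = enrichment(callset([snv("chr1", 100_000)]), ws,
                         n_perm=50, seed=0)[SNS]
        assert res.ratio == float("inf") and res.n_far == 0

    def test_invariant_under_chromosome_renaming(self):
        g1 = genome_of(chrom="chr1")
        g2 = genome_of(chrom="alias")
        muts1 = [snv("chr1", p) for p in range(80_000, 120_000, 2000)]
        muts2 = [snv("alias", p) for p in range(80_000, 120_000, 2000)]
        r1 = enrichment(callset(muts1),
                        build_windows([Breakpoint("chr1", 100_000)], g1),
                        n_perm=10, seed=0)[SNS]
        r2 = enrichment(callset(muts2),
                        build_windows([Breakpoint("alias", 100_000)], g2),
                        n_perm=10, seed=0)[SNS]
        assert r1.ratio == r2.ratio and r1.n_near == r2.n_near

    def test_classes_partitioned(self):
        g = genome_of()
        ws = build_windows([Breakpoint("chr1", 100_000)], g, 50_000)
        muts = [snv("chr1", 90_000),
                VariantCall("chr1", 91_000, "A", "AT", INS, 60, 30, "1/1", 1.0),
                VariantCall("chr1", 500_000, "AT", "A", DEL, 60, 30, "1/1", 1.0)]
        res = enrichment(callset(muts), ws, n_perm=10, seed=0)
        assert res[SNS].total == 1 and res[INS].total == 1 and res[DEL].total == 1
        assert res[DEL].n_near == 0


class TestPerBreakpointCounts:
    def test_planted_counts(self):
        bps = [Breakpoint("chr1", 100_000), Breakpoint("chr1", 800_000)]
        muts = [snv("chr1", p) for p in (60_000, 100_000, 140_000)]
        df = per_breakpoint_counts(callset(muts), bps, w=50_000)
        assert df[SNS].tolist() == [3, 0]

    def test_overlapping_windows_double_count(self):
        bps = [Breakpoint("chr1", 100_000), Breakpoint("chr1", 160_000)]
        df = per_breakpoint_counts(callset([snv("chr1", 130_000)]), bps,
                                   w=50_000)
        assert df[SNS].tolist() == [1, 1]

    def test_window_is_half_open(self):
        bps = [Breakpoint("chr1", 100_000)]
        muts = [snv("chr1", 50_000), snv("chr1", 150_000)]
        df = per_breakpoint_counts(callset(muts), bps, w=50_000)
        assert df[SNS].tolist() == [1]  # [50000, 150000): right edge out


class TestDetectKataegis:
    def test_six_close_mutations_form_cluster(self):
        muts = [snv("chr1", 1000 + 100 * i, "C", "T") for i in range(6)]
        (cl,) = detect_kataegis(callset(muts))
        assert cl.n_mut == 6 and cl.mean_imd == 100.0
        assert (cl.start, cl.end) == (1000, 1501)
        assert cl.n_apobec_type == 6

    def test_five_is_below_min_size(self):
        muts = [snv("chr1", 1000 + 100 * i, "C", "T") for i in range(5)]
        assert detect_kataegis(callset(muts)) == []

    def test_gap_splits_run(self):
        muts = [snv("chr1", 1000 + 100 * i, "C", "T") for i in range(6)]
        muts += [snv("chr1", 10_000 + 100 * i, "C", "G") for i in range(6)]
        clusters = detect_kataegis(callset(muts))
        assert len(clusters) == 2

    def test_order_independence(self):
        rng = np.random.default_rng(9)
        muts = [snv("chr1", 1000 + 150 * i, "C", "T") for i in range(8)]
        shuffled = list(muts)
        rng.shuffle(shuffled)
        a = detect_kataegis(Callset("s", "ESC", muts))
        b = detect_kataegis(Callset("s", "ESC", shuffled))
        assert [(c.start, c.end, c.n_mut) for c in a] == \
               [(c.start, c.end, c.n_mut) for c in b]

    def test_apobec_typing_is_strand_collapsed(self):
        # G>A on the purine strand is a C>T transition
        muts = [snv("chr1", 1000 + 100 * i, "G", "A") for i in range(3)]
        muts += [snv("chr1", 1300 + 100 * i, "T", "A") for i in range(3)]
        (cl,) = detect_kataegis(callset(muts))
        assert cl.n_apobec_type == 3

    def test_nearest_breakpoint_distance(self):
        muts = [snv("chr1", 1000 + 100 * i, "C", "T") for i in range(6)]
        (cl,) = detect_kataegis(callset(muts),
                                breakpoints=[Breakpoint("chr1", 5000),
                                             Breakpoint("chr2", 0)])
        assert cl.nearest_breakpoint_distance == 5000 - 1500

    def test_indels_ignored(self):
        muts = [VariantCall("chr1", 1000 + 100 * i, "A", "AT", INS, 60, 30,
                            "1/1", 1.0) for i in range(10)]
        assert detect_kataegis(callset(muts)) == []


def test_rainfall_table_distances():
    muts = [snv("chr1", p, "C", "T") for p in (100, 350, 1000)]
    df = rainfall_table(callset(muts))
    assert df["imd"].tolist()[1:] == [250, 650]
    assert np.isnan(df["imd"].iloc[0])
    assert set(df["substitution"]) == {"C>T"}
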