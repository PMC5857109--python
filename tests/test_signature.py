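"""96-channel context counting, triplet correction, catalog ranking."""

import numpy as np
import pytest

from breaksig import (GenomeRef, VariantCall, SNS, CHANNELS, TRIPLETS,
                      mutation_context, count_contexts, genome_triplets,
                      correct_profile, cosine_rank, cosine_similarity,
                      SignatureCatalog, read_catalog, write_catalog)
from breaksig.signature import (SignatureProfile, TripletTable, ProfileError,
                                channel_index)

COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(s):
    return "".join(COMP[b] for b in reversed(s))


def genome(**seqs):
    return GenomeRef.from_sequences(seqs)


def snv(chrom, pos, ref, alt):
    return VariantCall(chrom, pos, ref, alt, SNS, 60.0, 30, "1/1", 1.0)


# -- independent brute-force oracles -----------------------------------------

def oracle_channel(seq, pos, ref, alt):
    """Rescan the sequence around one substitution and name its channel."""
    if pos < 1 or pos >= len(seq) - 1:
        return None
    tri = seq[pos - 1:pos + 2]
    if any(b not in "ACGT" for b in tri):
        return None
    if ref in "AG":
        tri, ref, alt = revcomp(tri), COMP[ref], COMP[alt]
    return f"{tri[0]}[{ref}>{alt}]{tri[2]}"


def oracle_triplets(g):
    counts = {t: 0 for t in TRIPLETS}
    for seq in g.sequences.values():
        for i in range(len(seq) - 2):
            tri = seq[i:i + 3]
            if any(b not in "ACGT" for b in tri):
                continue
            if tri[1] in "AG":
                tri = revcomp(tri)
            counts[tri] += 1
    return counts


class TestMutationContext:
    def test_pyrimidine_center(self):
        g = genome(a="TTACATT")
        ch = mutation_context(snv("a", 3, "C", "T"), g)
        assert ch.label == "A[C>T]A"

    def test_purine_center_collapses(self):
        g = genome(a="TTTGTTT")
        ch = mutation_context(snv("a", 3, "G", "A"), g)
        assert ch.label == "A[C>T]A"

    def test_n_flank_excluded(self):
        g = genome(a="TNCAT")
        assert mutation_context(snv("a", 2, "C", "T"), g) is None

    def test_contig_edge_excluded(self):
        g = genome(a="CAT")
        assert mutation_context(snv("a", 0, "C", "T"), g) is None
        assert mutation_context(snv("a", 2, "T", "C"), g) is None

    def test_ref_mismatch_raises(self):
        g = genome(a="TTACATT")
        with pytest.raises(ProfileError):
            mutation_context(snv("a", 3, "G", "A"), g)

    def test_strand_collapse_involution(self):
        """Reverse-complementing genome and variant keeps every channel."""
        rng = np.random.default_rng(7)
        seq = "".join(rng.choice(list("ACGT"), 500))
        g_fwd = genome(a=seq)
        g_rev = genome(a=revcomp(seq))
        for pos in rng.integers(1, len(seq) - 1, 60):
            pos = int(pos)
            ref = seq[pos]
            alt = rng.choice([b for b in "ACGT" if b != ref])
            fwd = mutation_context(snv("a", pos, ref, alt), g_fwd)
            rev = mutation_context(
                snv("a", len(seq) - 1 - pos, COMP[ref], COMP[alt]), g_rev)
            assert fwd.label == rev.label


class TestCountContexts:
    def test_one_hot(self):
        g = genome(a="TTACATT")
        p = count_contexts([snv("a", 3, "C", "T")], g)
        expected = np.zeros(96)
        expected[channel_index("C>T", "A", "A")] = 1
        assert np.array_equal(p.raw_counts, expected)

    def test_empty_input(self):
        p = count_contexts([], genome(a="ACGT"))
        assert p.raw_counts.sum() == 0 and p.n_mutations == 0

    def test_matches_brute_force_on_random_genome(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGTN"), 1000, p=[.24, .24, .24, .24, .04]))
        g = genome(a=seq)
        variants, expected = [], np.zeros(96)
        excluded = 0
        for pos in rng.choice(len(seq), 50, replace=False):
            pos = int(pos)
            ref = seq[pos]
            if ref == "N":
                continue
            alt = rng.choice([b for b in "ACGT" if b != ref])
            variants.append(snv("a", pos, ref, alt))
            label = oracle_channel(seq, pos, ref, alt)
            if label is None:
                excluded += 1
            else:
                expected[CHANNELS.index(label)] += 1
        p = count_contexts(variants, g)
        assert np.array_equal(p.raw_counts, expected)
        assert p.n_excluded == excluded
        assert p.raw_counts.sum() + p.n_excluded == len(variants)


class TestGenomeTriplets:
    def test_hand_enumeration(self):
        t = genome_triplets(genome(a="ACAT"))
        # windows ACA (center C) and CAT (center A -> revcomp ATG)
        assert t.as_dict()["ACA"] == 1 and t.as_dict()["ATG"] == 1
        assert t.total == 2

    def test_revcomp_symmetry(self):
        assert genome_triplets(genome(a="TGT"))["ACA"] == 1

    def test_all_n_empty(self):
        assert genome_triplets(genome(a="NNN")).total == 0

    def test_matches_brute_force_on_random_genome(self, tiny_genome):
        t = genome_triplets(tiny_genome)
        assert t.as_dict() == oracle_triplets(tiny_genome)


class TestCorrectProfile:
    def _profile(self, raw):
        return SignatureProfile(raw_counts=np.asarray(raw, dtype=np.int64),
                                n_mutations=int(np.sum(raw)))

    def test_two_channel_example(self):
        # equal raw counts over triplets seen 100 and 300 times
        raw = np.zeros(96, dtype=np.int64)
        raw[0] = raw[1] = 10          # A[C>A]A and A[C>A]C
        counts = np.zeros(32, dtype=np.int64)
        counts[TRIPLETS.index("ACA")] = 100
        counts[TRIPLETS.index("ACC")] = 300
        p = correct_profile(self._profile(raw), TripletTable(counts))
        assert p.corrected[0] == pytest.approx(0.75)
        assert p.corrected[1] == pytest.approx(0.25)

    def test_uniform_triplets_is_identity_up_to_scale(self):
        rng = np.random.default_rng(3)
        raw = rng.integers(0, 50, 96)
        t = TripletTable(np.full(32, 1000, dtype=np.int64))
        p = correct_profile(self._profile(raw), t)
        assert np.allclose(p.corrected, raw / raw.sum())

    def test_corrected_sums_to_one(self):
        rng = np.random.default_rng(4)
        p = correct_profile(self._profile(rng.integers(0, 9, 96)),
                            TripletTable(rng.integers(50, 500, 32)))
        assert p.corrected.sum() == pytest.approx(1.0, abs=1e-9)

    def test_zero_raw_flagged(self):
        p = correct_profile(self._profile(np.zeros(96)),
                            TripletTable(np.full(32, 10, dtype=np.int64)))
        assert p.corrected is None

    def test_absent_context_inconsistency(self):
        raw = np.zeros(96, dtype=np.int64)
        raw[0] = 5
        with pytest.raises(ProfileError):
            correct_profile(self._profile(raw),
                            TripletTable(np.zeros(32, dtype=np.int64)))


class TestCosineRank:
    def test_identical_entry_first_with_one(self):
        rng = np.random.default_rng(5)
        prof = rng.random(96)
        prof /= prof.sum()
        other = rng.random(96)
        cat = SignatureCatalog(names=["match", "other"],
                               profiles=np.column_stack([prof, other]))
        p = SignatureProfile(raw_counts=np.zeros(96), corrected=prof)
        ranks = cosine_rank(p, cat)
        assert ranks[0][0] == "match"
        assert ranks[0][1] == pytest.approx(1.0)

    def test_orthogonal_one_hot_zero(self):
        a, b = np.zeros(96), np.zeros(96)
        a[0], b[1] = 1, 1
        assert cosine_similarity(a, b) == 0.0

    def test_toy_three_channel_value(self):
        assert cosine_similarity(np.array([1.0, 0, 1]),
                                 np.array([1.0, 1, 0])) == pytest.approx(0.5)

    def test_zero_norm_errors(self):
        with pytest.raises(ProfileError):
            cosine_similarity(np.zeros(3), np.ones(3))


def test_catalog_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(6)
    mat = rng.random((96, 3))
    cat = SignatureCatalog(names=["s1", "s2", "s3"], profiles=mat)
    path = tmp_path / "cat.tsv"
    write_catalog(cat, path)
    back = read_catalog(path)
    assert back.names == cat.names
    assert np.allclose(back.profiles, cat.profiles)


def test_catalog_rejects_incomplete_contexts(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("context\ts1\nA[C>A]A\t1.0\n")
    with pytest.raises(ProfileError):
        read_catalog(path)
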