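"""Canonical keys, unique-read counting, HQ/SHQ/comprehensive sets."""

import itertools

import pytest
from hypothesis import given, settings, strategies as st

from idnaseq.refset import (
    DEFAULT_MIN_COPIES,
    UniqueReadCounts,
    build_sample_sets,
    canonical_key,
    comprehensive_set,
    count_unique,
    high_quality_set,
    read_keyset,
    revcomp,
    super_high_quality_set,
    write_keyset,
)

from conftest import make_pair

dna = st.text(alphabet="ACGTN", min_size=1, max_size=30)


class TestCanonicalKey:
    def test_pair_and_its_reverse_complement_share_a_key(self):
        # revcomp of ("ACGT","TTTT") read the other way round is ("AAAA","ACGT")
        assert canonical_key("ACGT", "TTTT") == canonical_key("AAAA", "ACGT")

    def test_palindromic_pair_is_a_fixed_point(self):
        assert canonical_key("ACGT", "ACGT") == "ACGT#ACGT"

    def test_idempotent_on_reconstructed_pair(self):
        key = canonical_key("GGGA", "CCTT")
        r1, r2 = key.split("#")
        assert canonical_key(r1, r2) == key

    def test_invalid_nucleotide_rejected(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            canonical_key("ACGU", "ACGT")

    def test_n_complement_is_n(self):
        assert revcomp("ANT") == "ANT"
        assert canonical_key("NNN", "NNN") == "NNN#NNN"

    @settings(max_examples=300, deadline=None)
    @given(dna, dna)
    def test_strand_folding_invariant(self, r1, r2):
        """key(pair) == key(reverse-complemented pair), always."""
        key = canonical_key(r1, r2)
        assert canonical_key(revcomp(r2), revcomp(r1)) == key
        assert key.count("#") == 1


class TestCountUnique:
    def test_copies_pool_into_one_key(self):
        pairs = [make_pair(r1="ACGTACGT", r2="TTGGCCAA")] * 5
        counts = count_unique(pairs, "S1", "rep1")
        assert len(counts.counts) == 1
        assert counts.total_pairs == 5

    def test_strand_pooling_merges_orientations(self):
        fwd = make_pair(r1="ACGTACGT", r2="TTGGCCAA")
        flip = make_pair(r1=revcomp("TTGGCCAA"), r2=revcomp("ACGTACGT"))
        counts = count_unique([fwd] * 3 + [flip] * 2, "S1", "rep1")
        assert list(counts.counts.values()) == [5]

    def test_no_strand_pooling_dialect_counts_best_orientation(self):
        fwd = make_pair(r1="ACGTACGT", r2="TTGGCCAA")
        flip = make_pair(r1=revcomp("TTGGCCAA"), r2=revcomp("ACGTACGT"))
        counts = count_unique([fwd] * 3 + [flip] * 2, "S1", "rep1", strand_pool=False)
        assert list(counts.counts.values()) == [3]

    def test_empty_stream(self):
        assert count_unique([], "S1", "rep1").counts == {}

    def test_naive_all_pairs_oracle_equivalence(self):
        """Hashed canonical-key counting equals a quadratic string-comparison
        oracle that checks reverse complements explicitly."""
        import random

        rng = random.Random(7)
        fragments = [
            ("".join(rng.choices("ACGT", k=12)), "".join(rng.choices("ACGT", k=12)))
            for _ in range(8)
        ]
        reads = []
        for r1, r2 in fragments:
            for _ in range(rng.randint(1, 6)):
                if rng.random() < 0.5:
                    reads.append((r1, r2))
                else:
                    reads.append((revcomp(r2), revcomp(r1)))
        rng.shuffle(reads)

        def same_fragment(a, b):
            return a == b or (revcomp(b[1]), revcomp(b[0])) == a

        # naive: group reads by pairwise comparison only
        groups = []
        for read in reads:
            for g in groups:
                if same_fragment(read, g[0]):
                    g.append(read)
                    break
            else:
                groups.append([read])
        naive = sorted(len(g) for g in groups)

        counts = count_unique(
            [make_pair(r1=a, r2=b) for a, b in reads], "S", "d"
        )
        assert sorted(counts.counts.values()) == naive


class TestThresholdSets:
    def _counts(self, mapping):
        return UniqueReadCounts("S1", "rep1", dict(mapping))

    def test_over_ten_means_eleven(self):
        counts = self._counts({"A#A": 11, "C#C": 10, "G#G": 30})
        assert high_quality_set(counts) == {"A#A", "G#G"}

    def test_all_singletons_give_empty_hq(self):
        counts = self._counts({"A#A": 1, "C#C": 1})
        assert high_quality_set(counts) == set()

    def test_antitone_in_min_copies(self):
        counts = self._counts({k: n for k, n in zip("ABCDEFGH", range(1, 30, 4))})
        sets = [high_quality_set(counts, m) for m in range(1, 32, 3)]
        for smaller_thresh, larger_thresh in itertools.pairwise(sets):
            assert larger_thresh <= smaller_thresh

    def test_shq_is_the_intersection(self):
        ref = super_high_quality_set([{"k1", "k2", "k3"}, {"k2", "k3", "k4"}], "S1")
        assert ref.shq == {"k2", "k3"}

    def test_identical_and_disjoint_duplicates(self):
        assert super_high_quality_set([{"a"}, {"a"}], "S").shq == {"a"}
        assert super_high_quality_set([{"a"}, {"b"}], "S").shq == set()

    def test_single_duplicate_needs_explicit_mode(self):
        with pytest.raises(ValueError, match="need >=2 PCR duplicates"):
            super_high_quality_set([{"a"}], "S1")
        assert super_high_quality_set([{"a"}], "S1", allow_single=True).shq == {"a"}

    def test_comprehensive_union_and_superset_invariant(self):
        c1 = self._counts({"k1": 12, "k2": 1})
        c2 = UniqueReadCounts("S1", "rep2", {"k1": 15, "k3": 2})
        comp = comprehensive_set([c1, c2])
        assert comp.keys == {"k1", "k2", "k3"}
        ref, comp2 = build_sample_sets([c1, c2])
        assert ref.shq == {"k1"}
        assert ref.shq <= comp2.keys

    def test_comprehensive_rejects_mixed_samples(self):
        with pytest.raises(ValueError, match="multiple samples"):
            comprehensive_set(
                [self._counts({"a": 1}), UniqueReadCounts("S2", "rep1", {"b": 1})]
            )


def test_full_library_strand_flip_leaves_sets_unchanged():
    """Reverse-complementing every read (and swapping mates) is a no-op on
    counts, HQ, SHQ and comprehensive sets."""
    import random

    rng = random.Random(3)
    reads = []
    for _ in range(6):
        r1 = "".join(rng.choices("ACGT", k=10))
        r2 = "".join(rng.choices("ACGT", k=10))
        reads += [(r1, r2)] * rng.randint(1, 14)
    flipped = [(revcomp(r2), revcomp(r1)) for r1, r2 in reads]

    def sets_of(readlist):
        counts = count_unique([make_pair(r1=a, r2=b) for a, b in readlist], "S", "d")
        return counts.counts, high_quality_set(counts)

    assert sets_of(reads) == sets_of(flipped)


def test_keyset_serialization_roundtrip_and_determinism(tmp_path):
    keys = {canonical_key("ACGT", "TTTT"), canonical_key("GGGG", "CCCC")}
    p1, p2 = tmp_path / "a.keys", tmp_path / "b.keys"
    for p in (p1, p2):
        write_keyset(p, "S1", keys, "shq", provenance=["rep1", "rep2"],
                     min_copies=DEFAULT_MIN_COPIES)
    assert p1.read_bytes() == p2.read_bytes()  # reruns byte-identical
    meta, back = read_keyset(p1)
    assert back == keys
    assert meta["sample_id"] == "S1"
    assert meta["duplicates"] == "rep1,rep2"
    assert int(meta["min_copies"]) == 11
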