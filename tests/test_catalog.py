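"""Spacer matching (88/17 rule), clustering and protospacer search."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from crisprpop.catalog import (
    ProtospacerHit,
    build_catalog,
    match_matrix,
    pair_match,
    pam_context,
    search_protospacers,
)
from crisprpop.arrays import revcomp

dna = st.text(alphabet="ACGT", min_size=18, max_size=45)


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


class TestPairMatch:
    def test_identical_spacers(self):
        rng = np.random.default_rng(0)
        s = random_dna(rng, 39)
        m = pair_match(s, s)
        assert (m.offset, m.overlap_length, m.identity, m.is_match) == (0, 39, 1.0, True)

    def test_offset_substring_match(self):
        """A spacer vs its own 5-shifted substring: the offset signature."""
        rng = np.random.default_rng(1)
        s = random_dna(rng, 39)
        m = pair_match(s, s[5:])
        assert m.is_match and m.offset == 5 and m.overlap_length == 34 and m.snps == 0

    def test_snp_threshold_boundary(self):
        """4 SNPs over 39 nt pass the 88% rule; 5 SNPs fail (max 4 SNPs/pair)."""
        rng = np.random.default_rng(2)
        s = random_dna(rng, 39)
        other = {"A": "C", "C": "G", "G": "T", "T": "A"}

        def mutate(seq, k):
            out = list(seq)
            for i in range(k):
                out[i * 7] = other[out[i * 7]]
            return "".join(out)

        assert pair_match(s, mutate(s, 4)).is_match
        assert not pair_match(s, mutate(s, 5)).is_match
        m4 = pair_match(s, mutate(s, 4))
        assert m4.snps == 4 and m4.identity == pytest.approx(35 / 39)

    def test_short_overlap_rejected(self):
        """Perfect identity on <17 nt of overlap is not a match."""
        rng = np.random.default_rng(3)
        s = random_dna(rng, 39)
        b = s[29:]  # a 10-nt perfect substring: identity 1.0 but overlap < 17
        assert not pair_match(s, b).is_match

    def test_revcomp_orientation(self):
        rng = np.random.default_rng(4)
        s = random_dna(rng, 39)
        assert not pair_match(s, revcomp(s)).is_match or s == revcomp(s)
        m = pair_match(s, revcomp(s), allow_revcomp=True)
        assert m.is_match and m.orientation == "reverse-complement"

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dna, dna)
    def test_symmetry(self, a, b):
        """is_match is symmetric and the offset negates on swap."""
        m1, m2 = pair_match(a, b), pair_match(b, a)
        assert m1.is_match == m2.is_match
        if m1.is_match:
            assert m1.offset == -m2.offset
            assert m1.overlap_length == m2.overlap_length
            assert m1.snps == m2.snps

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(dna)
    def test_full_length_identity_always_matches(self, s):
        assert pair_match(s, s).is_match  # length >= 17 by construction

    def test_snps_identity_consistency(self):
        rng = np.random.default_rng(5)
        a, b = random_dna(rng, 40), random_dna(rng, 37)
        m = pair_match(a, b)
        assert m.identity == pytest.approx(1 - m.snps / m.overlap_length)


class TestBuildCatalog:
    def test_trivial_classes_and_clusters(self):
        seqs = ["ACGT" * 10, "ACGT" * 10, "TTTTGGGGCCCCAAAATTTTG"]
        cat = build_catalog(seqs)
        assert cat.n_exact == 2 and cat.n_unique == 2

    def test_single_linkage_transitivity(self):
        rng = np.random.default_rng(6)
        a = random_dna(rng, 39)
        b = a[4:] + random_dna(rng, 4)  # matches a (offset 4)
        c = b[4:] + random_dna(rng, 4)  # matches b; a-c overlap too diverged
        assert pair_match(a, b).is_match and pair_match(b, c).is_match
        cat = build_catalog([a, b, c])
        assert cat.n_unique == 1

    def test_matches_union_find_oracle(self):
        """Cluster count equals a brute-force all-pairs union-find on pair_match."""
        rng = np.random.default_rng(7)
        seqs = [random_dna(rng, 39) for _ in range(120)]
        for i in range(20):  # planted near-duplicates
            src = seqs[i]
            dup = list(src)
            dup[int(rng.integers(39))] = "ACGT"[rng.integers(4)]
            seqs.append("".join(dup))
        uniq = sorted(set(seqs))
        parent = list(range(len(uniq)))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(len(uniq)):
            for j in range(i + 1, len(uniq)):
                if pair_match(uniq[i], uniq[j]).is_match:
                    ri, rj = find(i), find(j)
                    if ri != rj:
                        parent[ri] = rj
        expected = len({find(i) for i in range(len(uniq))})
        cat = build_catalog(seqs)
        assert cat.n_unique == expected

    def test_match_matrix_equals_pair_match(self):
        rng = np.random.default_rng(8)
        seqs = [random_dna(rng, int(rng.integers(35, 43))) for _ in range(40)]
        mat = match_matrix(seqs)
        for i in range(len(seqs)):
            for j in range(len(seqs)):
                assert mat[i, j] == pair_match(seqs[i], seqs[j]).is_match

    def test_exact_refines_fuzzy(self, sim_arrays):
        spacers = [s for a in sim_arrays.arrays for s in a.spacers]
        cat = build_catalog(spacers)
        assert cat.n_exact >= cat.n_unique
        for cid, members in cat.exact_classes.items():
            clusters = {cat.cluster_of_class[cid]}
            assert len(clusters) == 1
            assert all(m.sequence == members[0].sequence for m in members)

    def test_complete_linkage_never_coarser(self):
        rng = np.random.default_rng(9)
        seqs = [random_dna(rng, 39) for _ in range(30)]
        seqs += [seqs[0][3:] + random_dna(rng, 3), seqs[0][:36] + random_dna(rng, 3)]
        single = build_catalog(seqs, linkage="single").n_unique
        complete = build_catalog(seqs, linkage="complete").n_unique
        assert complete >= single


class TestProtospacerSearch:
    def test_planted_exact_hit(self):
        rng = np.random.default_rng(10)
        spacer = random_dna(rng, 39)
        target = random_dna(rng, 2000) + spacer + random_dna(rng, 2961)
        hits = search_protospacers([spacer], {"virus1": target}, min_identity=1.0)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.end, h.strand, h.exact, h.score) == (2000, 2039, "+", True, 39)

    def test_absent_spacer_no_hits(self):
        rng = np.random.default_rng(11)
        assert search_protospacers([random_dna(rng, 39)], {"v": random_dna(rng, 3000)}, 0.9) == []

    def test_minus_strand_hit(self):
        rng = np.random.default_rng(12)
        spacer = random_dna(rng, 39)
        target = random_dna(rng, 500) + revcomp(spacer) + random_dna(rng, 500)
        hits = search_protospacers([spacer], {"v": target}, min_identity=1.0)
        assert [h.strand for h in hits] == ["-"]
        assert hits[0].start == 500

    def test_matches_exhaustive_oracle(self):
        """Planted 0-3 substitution hits equal a per-offset recount."""
        rng = np.random.default_rng(13)
        targets = {f"t{k}": random_dna(rng, 1500) for k in range(10)}
        spacers = []
        planted = []
        tkeys = list(targets)
        for i in range(50):
            tid = tkeys[int(rng.integers(10))]
            pos = int(rng.integers(0, 1500 - 39))
            spacer = list(targets[tid][pos : pos + 39])
            for p in rng.choice(39, int(rng.integers(0, 4)), replace=False):
                spacer[p] = "ACGT"[rng.integers(4)]
            spacers.append("".join(spacer))
            planted.append((spacers[-1], tid, pos))
        hits = search_protospacers(spacers, targets, min_identity=0.9)
        got = {(h.spacer, h.target, h.start, h.strand) for h in hits}

        expected = set()
        for sp in set(spacers):
            for tid, tseq in targets.items():
                for strand in "+-":
                    q = sp if strand == "+" else revcomp(sp)
                    for i in range(len(tseq) - 39 + 1):
                        matches = sum(a == b for a, b in zip(tseq[i : i + 39], q))
                        if matches / 39 >= 0.9:
                            expected.add((sp, tid, i, strand))
        assert got == expected

    def test_gapped_mode_runs(self):
        rng = np.random.default_rng(14)
        spacer = random_dna(rng, 39)
        target = random_dna(rng, 300) + spacer + random_dna(rng, 300)
        hits = search_protospacers([spacer], {"v": target}, 0.9, mode="gapped")
        assert any(h.exact for h in hits)


class TestPamContext:
    def _hit(self, start, end, strand="+"):
        return ProtospacerHit("x" * (end - start), "t", start, end, strand, end - start, 1.0, end - start, True)

    def test_plus_strand(self):
        rng = np.random.default_rng(15)
        t = {"t": random_dna(rng, 300)}
        ctx = pam_context(self._hit(100, 139), t, k=2)
        assert ctx.upstream == t["t"][98:100]
        assert ctx.downstream == t["t"][139:141]
        assert not ctx.truncated

    def test_minus_strand_swaps_and_complements(self):
        rng = np.random.default_rng(16)
        t = {"t": random_dna(rng, 300)}
        ctx = pam_context(self._hit(100, 139, "-"), t, k=2)
        assert ctx.upstream == revcomp(t["t"][139:141])
        assert ctx.downstream == revcomp(t["t"][98:100])

    def test_boundary_truncated(self):
        rng = np.random.default_rng(17)
        t = {"t": random_dna(rng, 100)}
        ctx = pam_context(self._hit(0, 39), t, k=2)
        assert ctx.upstream == "" and ctx.truncated
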