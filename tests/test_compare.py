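"""Array alignment, loss detection, ancestry grouping, acquisition calls."""

import itertools

import numpy as np
import pytest

from crisprpop.catalog import build_catalog
from crisprpop.compare import (
    acquisition_end_summary,
    align_all,
    align_arrays,
    classify_acquisitions,
    detect_losses,
    group_ancestral,
    leader_internal_check,
)
from conftest import make_array


def random_dna(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def enumeration_score(a, b, match=2, gap=-1):
    """Independent oracle: exhaustive recursion over all alignments."""

    def rec(i, j):
        if i == len(a) and j == len(b):
            return 0
        best = float("-inf")
        if i < len(a) and j < len(b) and a[i] == b[j]:
            best = max(best, match + rec(i + 1, j + 1))
        if i < len(a):
            best = max(best, gap + rec(i + 1, j))
        if j < len(b):
            best = max(best, gap + rec(i, j + 1))
        return best

    return rec(0, 0)


class TestAlignArrays:
    def test_identical_arrays(self):
        a = make_array("x", ["S1", "S2", "S3", "S4", "S5"])
        b = make_array("y", ["S1", "S2", "S3", "S4", "S5"])
        aln = align_arrays(a, b)
        assert len(aln.match_columns) == 5
        assert all(x is not None and y is not None for x, y in aln.columns)
        assert aln.score == 10

    def test_internal_deletion(self):
        a = make_array("x", ["S1", "S2", "S3", "S4", "S5"])
        b = make_array("y", ["S1", "S4", "S5"])
        aln = align_arrays(a, b)
        matched = [x.sequence for i, (x, _) in enumerate(aln.columns) if i in aln.match_columns]
        assert matched == ["S1", "S4", "S5"]
        gaps = [i for i, (_, y) in enumerate(aln.columns) if y is None]
        assert gaps == [1, 2]

    def test_ungapping_reproduces_arrays(self):
        rng = np.random.default_rng(0)
        symbols = [f"SYM{k}" for k in range(6)]
        for _ in range(50):
            sa = [symbols[i] for i in rng.integers(0, 6, rng.integers(1, 9))]
            sb = [symbols[i] for i in rng.integers(0, 6, rng.integers(1, 9))]
            aln = align_arrays(make_array("x", sa), make_array("y", sb))
            assert [c[0].sequence for c in aln.columns if c[0] is not None] == sa
            assert [c[1].sequence for c in aln.columns if c[1] is not None] == sb
            assert not any(x is None and y is None for x, y in aln.columns)

    def test_score_matches_enumeration_oracle(self):
        rng = np.random.default_rng(1)
        symbols = [f"SYM{k}" for k in range(5)]
        for _ in range(100):
            sa = [symbols[i] for i in rng.integers(0, 5, rng.integers(1, 9))]
            sb = [symbols[i] for i in rng.integers(0, 5, rng.integers(1, 9))]
            aln = align_arrays(make_array("x", sa), make_array("y", sb))
            assert aln.score == enumeration_score(sa, sb)

    def test_locus_contract(self):
        a = make_array("x", ["S1"], locus="C")
        b = make_array("y", ["S1"], locus="A1")
        with pytest.raises(ValueError, match="locus"):
            align_arrays(a, b)
        with pytest.raises(ValueError):
            align_arrays(make_array("x", ["S1"], end="leader"), make_array("y", ["S1"], end="trailer"))

    def test_full_end_is_compatible(self):
        a = make_array("x", ["S1", "S2"], end="leader")
        b = make_array("y", ["S1", "S2"], end="full")
        assert len(align_arrays(a, b).match_columns) == 2


class TestDetectLosses:
    def test_flanked_gap_is_loss(self):
        a = make_array("x", ["S1", "S2", "S3", "S4", "S5"])
        b = make_array("y", ["S1", "S4", "S5"])
        events = detect_losses(align_arrays(a, b))
        assert len(events) == 1
        ev = events[0]
        assert (ev.strain, ev.run_length) == ("y", 2)
        assert (ev.left_flank, ev.right_flank) == ("S1", "S4")

    def test_terminal_gap_is_not_loss(self):
        a = make_array("x", ["S1", "S2", "S3", "S4"])
        b = make_array("y", ["S3", "S4"])
        assert detect_losses(align_arrays(a, b)) == []

    def test_events_equal_independent_column_scan(self):
        """Detected events match an independent recount of internal flanked
        gap runs, so no event ever touches an alignment terminus."""
        rng = np.random.default_rng(2)
        symbols = [f"SYM{k}" for k in range(6)]
        for _ in range(100):
            sa = [symbols[i] for i in rng.integers(0, 6, rng.integers(2, 10))]
            sb = [symbols[i] for i in rng.integers(0, 6, rng.integers(2, 10))]
            aln = align_arrays(make_array("x", sa), make_array("y", sb))
            cols = aln.columns
            match = [
                x is not None and y is not None and x.sequence == y.sequence
                for x, y in cols
            ]
            expected = []
            for row, strain in ((0, "x"), (1, "y")):
                i = 0
                while i < len(cols):
                    if cols[i][row] is None:
                        j = i
                        while j < len(cols) and cols[j][row] is None:
                            j += 1
                        if i > 0 and j < len(cols) and match[i - 1] and match[j]:
                            expected.append((strain, j - i))
                        i = j
                    else:
                        i += 1
            got = [(ev.strain, ev.run_length) for ev in detect_losses(aln)]
            assert sorted(got) == sorted(expected)

    def test_simulator_loss_recovery(self, sim, sim_arrays):
        """Planted losses with surviving flanks are recovered with exact run lengths."""
        from crisprpop.pipeline import run_analysis
        from crisprpop.simulate import summary_stats

        ana = run_analysis(sim_arrays.arrays)
        rep = summary_stats(sim.truth, ana.losses, ana.groups_by_locus, ana.pairs)
        losses = rep["losses"]
        assert losses["recoverable"] > 0
        assert losses["recall"] == 1.0
        assert max(losses["matched_run_lengths"]) <= 5


class TestGroupAncestral:
    def test_below_threshold_separate(self):
        a = make_array("x", ["S1", "A1", "A2"])
        b = make_array("y", ["S1", "B1", "B2"])
        groups = group_ancestral([a, b], min_run=2)
        assert sorted(len(g.members) for g in groups) == [1, 1]

    def test_run_links(self):
        a = make_array("x", ["N1", "S1", "S2", "S3"])
        b = make_array("y", ["N2", "S1", "S2", "S3"])
        groups = group_ancestral([a, b], min_run=3)
        assert len(groups) == 1 and groups[0].members == ["x", "y"]

    def test_trailer_only_flagged(self):
        ax = make_array("x", ["XL1", "XL2", "XL3"], end="leader")
        ay = make_array("y", ["YL1", "YL2", "YL3"], end="leader")
        tx = make_array("x", ["T1", "T2", "T3"], end="trailer")
        ty = make_array("y", ["T1", "T2", "T3"], end="trailer")
        groups = group_ancestral([ax, ay, tx, ty], min_run=3)
        assert len(groups) == 1
        assert ("x", "y") in groups[0].trailer_only_pairs

    def test_order_invariance(self):
        rng = np.random.default_rng(3)
        symbols = [f"SYM{k}" for k in range(8)]
        arrays = [
            make_array(f"s{i}", [symbols[k] for k in rng.integers(0, 8, 6)])
            for i in range(8)
        ]
        ref = {frozenset(g.members) for g in group_ancestral(arrays)}
        for _ in range(5):
            perm = list(arrays)
            rng.shuffle(perm)
            assert {frozenset(g.members) for g in group_ancestral(perm)} == ref

    def test_single_locus_contract(self):
        with pytest.raises(ValueError, match="single locus"):
            group_ancestral([make_array("x", ["S1"], locus="C"), make_array("y", ["S1"], locus="A1")])

    def test_simulator_founder_partition(self, sim, sim_arrays):
        from collections import defaultdict

        by_locus = defaultdict(list)
        for arr in sim_arrays.arrays:
            by_locus[arr.locus].append(arr)
        for locus, arrs in by_locus.items():
            groups = group_ancestral(arrs)
            detected = {s: g.group_id for g in groups for s in g.members}
            truth = sim.truth.true_groups(locus)
            for x, y in itertools.combinations(sorted(set(detected) & set(truth)), 2):
                assert (detected[x] == detected[y]) == (truth[x] == truth[y]), (locus, x, y)


class TestLeaderInternalCheck:
    def test_planted_positive(self):
        rng = np.random.default_rng(4)
        shared = random_dna(rng, 39)
        leader = make_array("x", [random_dna(rng, 39), shared, random_dna(rng, 39)], end="leader")
        full = make_array(
            "y", [random_dna(rng, 39) for _ in range(11)] + [shared, random_dna(rng, 39)], end="full"
        )
        hits = leader_internal_check([leader], [full], leader_depth=10)
        assert len(hits) == 1
        assert hits[0][0].strain == "x" and hits[0][1].position == 12

    def test_fragment_terminal_spacer_not_queried(self):
        """A short array's last spacer is its conserved trailer end, not a
        leader-end spacer, so it is not searched."""
        rng = np.random.default_rng(7)
        shared = random_dna(rng, 39)
        leader = make_array("x", [random_dna(rng, 39), shared], end="leader")
        full = make_array(
            "y", [random_dna(rng, 39) for _ in range(11)] + [shared], end="full"
        )
        assert leader_internal_check([leader], [full], leader_depth=10) == []

    def test_aligned_context_not_reported(self):
        """An identical spacer vertically aligned between two related arrays
        (shared context at different leader depths) is common ancestry."""
        rng = np.random.default_rng(8)
        ctx = [random_dna(rng, 39) for _ in range(4)]
        leader = make_array("x", [random_dna(rng, 39)] + ctx + [random_dna(rng, 39)], end="leader")
        full = make_array(
            "y",
            [random_dna(rng, 39) for _ in range(9)] + ctx + [random_dna(rng, 39)],
            end="full",
        )
        assert leader_internal_check([leader], [full], leader_depth=10) == []

    def test_disjoint_sets_empty(self):
        rng = np.random.default_rng(5)
        leader = make_array("x", [random_dna(rng, 39) for _ in range(3)], end="leader")
        full = make_array("y", [random_dna(rng, 39) for _ in range(15)], end="full")
        assert leader_internal_check([leader], [full]) == []

    def test_same_strain_not_reported(self):
        rng = np.random.default_rng(6)
        shared = random_dna(rng, 39)
        leader = make_array("x", [shared], end="leader")
        full = make_array("x", [random_dna(rng, 39) for _ in range(11)] + [shared], end="full")
        assert leader_internal_check([leader], [full]) == []


def _classify(arrays, min_run=3):
    spacers = [s for a in arrays for s in a.spacers]
    catalog = build_catalog(spacers)
    alignments = align_all(arrays)
    groups = group_ancestral(arrays, min_run=min_run)
    return classify_acquisitions(catalog, groups, alignments)


class TestClassifyAcquisitions:
    def test_shared_ancestral_array_yields_nothing(self):
        rng = np.random.default_rng(7)
        seqs = [random_dna(rng, 39) for _ in range(6)]
        pairs = _classify([make_array("x", seqs), make_array("y", seqs)])
        assert pairs == []

    def test_offset_leader_pair(self):
        rng = np.random.default_rng(8)
        s = random_dna(rng, 39)
        x = make_array("x", [random_dna(rng, 39), random_dna(rng, 39), s])
        y = make_array("y", [random_dna(rng, 39), random_dna(rng, 39), s[4:] + random_dna(rng, 4)])
        pairs = _classify([x, y])
        live = [p for p in pairs if not p.excluded]
        assert len(live) == 1
        p = live[0]
        assert p.end_class == "leader-leader"
        assert "offset" in p.signature
        assert abs(p.match.offset) == 4

    def test_consecutive_exact_excluded(self):
        rng = np.random.default_rng(9)
        e1, e2 = random_dna(rng, 39), random_dna(rng, 39)
        x = make_array("x", [random_dna(rng, 39), e1, e2, random_dna(rng, 39)])
        y = make_array("y", [random_dna(rng, 39), e1, e2, random_dna(rng, 39)])
        pairs = _classify([x, y])
        assert len(pairs) == 2
        assert all(p.excluded and p.reason == "consecutive-exact" for p in pairs)

    def test_isolated_exact_pair_stays_candidate(self):
        rng = np.random.default_rng(10)
        e = random_dna(rng, 39)
        x = make_array("x", [random_dna(rng, 39), e, random_dna(rng, 39)])
        y = make_array("y", [random_dna(rng, 39), e, random_dna(rng, 39)])
        pairs = _classify([x, y])
        assert len(pairs) == 1 and not pairs[0].excluded

    def test_cross_locus_pair_is_candidate(self):
        rng = np.random.default_rng(11)
        s = random_dna(rng, 39)
        x = make_array("x", [random_dna(rng, 39), s], locus="C")
        y = make_array("y", [random_dna(rng, 39), s[3:] + random_dna(rng, 3)], locus="A1")
        spacers = [sp for a in (x, y) for sp in a.spacers]
        catalog = build_catalog(spacers)
        alignments = align_all([x, y])
        groups = group_ancestral([x], min_run=3) + group_ancestral([y], min_run=3)
        pairs = classify_acquisitions(catalog, groups, alignments)
        assert len([p for p in pairs if not p.excluded]) == 1

    def test_simulator_trichotomy_precision(self, sim, sim_arrays):
        """No inherited (same-event) spacer pair is called an acquisition."""
        from crisprpop.pipeline import run_analysis
        from crisprpop.simulate import summary_stats

        ana = run_analysis(sim_arrays.arrays)
        rep = summary_stats(sim.truth, ana.losses, ana.groups_by_locus, ana.pairs)
        assert rep["acquisitions"]["false_ancestral"] == 0
        assert rep["acquisitions"]["precision"] == 1.0


class TestEndSummary:
    def test_empty(self):
        s = acquisition_end_summary([])
        assert s["total"] == 0 and all(v == 0 for v in s["counts"].values())

    def test_fractions(self):
        rng = np.random.default_rng(12)

        class P:
            def __init__(self, end_class):
                self.end_class = end_class
                self.excluded = False

        pairs = [P("leader-leader")] * 4 + [P("trailer-trailer")] * 3 + [P("mixed")] * 3
        s = acquisition_end_summary(pairs)
        assert s["fractions"] == {
            "leader-leader": pytest.approx(0.4),
            "trailer-trailer": pytest.approx(0.3),
            "mixed": pytest.approx(0.3),
        }
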