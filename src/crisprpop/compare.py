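"""Spacer-level array comparison: alignment, loss, ancestry, acquisition.

Arrays are aligned as sequences of symbols, where the symbol is the exact
(100% full-length) identity class of each spacer. The evolutionary model
behind the alignment is acquisition at the leader end plus deletion of
contiguous internal runs — not in-place substitution — so mismatch columns
are disallowed by default and differences surface as paired gaps.

Internal gap runs flanked on both sides by matching spacers are read as
spacer-loss events. Arrays sharing runs of identical spacers in the same
order (loss gaps permitted) are grouped as ancestrally related. Fuzzy
(88/17) matches between spacers of different strains that are *not*
explained by shared ancestry are classified as independent acquisitions of
near-identical sequence from the same viral source, with the offset/SNP
signature and the sequenced end (leader/trailer) of each partner recorded.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from dataclasses import dataclass, field

from .arrays import Spacer, SpacerArray
from .catalog import SpacerCatalog, pair_match

__all__ = [
    "ArrayAlignment",
    "LossEvent",
    "AncestralGroup",
    "AcquisitionPair",
    "align_arrays",
    "align_all",
    "detect_losses",
    "group_ancestral",
    "leader_internal_check",
    "classify_acquisitions",
    "acquisition_end_summary",
    "DEFAULT_LEADER_DEPTH",
]

DEFAULT_LEADER_DEPTH = 10

_MATCH = 2
_MISMATCH = -2
_GAP = -1
_NEG_INF = float("-inf")


@dataclass
class ArrayAlignment:
    """Pairwise global alignment of two spacer arrays over identity symbols.

    ``columns`` is a list of (spacer-or-None, spacer-or-None); no column is
    (None, None) and ungapping either row reproduces the source array.
    """

    a: SpacerArray
    b: SpacerArray
    columns: list[tuple[Spacer | None, Spacer | None]]
    score: float

    @property
    def match_columns(self) -> list[int]:
        return [
            i
            for i, (x, y) in enumerate(self.columns)
            if x is not None and y is not None and x.sequence == y.sequence
        ]

    @property
    def match_sequences(self) -> set[str]:
        return {self.columns[i][0].sequence for i in self.match_columns}


def align_arrays(
    a: SpacerArray,
    b: SpacerArray,
    match: float = _MATCH,
    gap: float = _GAP,
    allow_mismatch: bool = False,
    mismatch: float = _MISMATCH,
) -> ArrayAlignment:
    """Needleman-Wunsch over spacer symbols with deterministic tie-breaks.

    By default a column may pair two spacers only when their sequences are
    identical; differing spacers are forced into paired gaps. Tie-breaking
    during traceback prefers a diagonal move, then gap-in-a, then gap-in-b,
    which fixes a unique leftmost alignment among the optima.

    Arrays must come from the same locus and compatible ends: identical
    ends, or one array fully sequenced ("full"), which is comparable with
    either end fragment.
    """
    compatible = a.end == b.end or "full" in (a.end, b.end)
    if a.locus != b.locus or not compatible:
        raise ValueError(
            f"cannot align arrays from different locus/end: "
            f"{a.strain}:{a.locus}:{a.end} vs {b.strain}:{b.locus}:{b.end}"
        )
    sa, sb = a.spacers, b.spacers
    la, lb = len(sa), len(sb)
    score = [[0.0] * (lb + 1) for _ in range(la + 1)]
    for i in range(1, la + 1):
        score[i][0] = i * gap
    for j in range(1, lb + 1):
        score[0][j] = j * gap
    for i in range(1, la + 1):
        row, prev = score[i], score[i - 1]
        ai = sa[i - 1].sequence
        for j in range(1, lb + 1):
            if ai == sb[j - 1].sequence:
                diag = prev[j - 1] + match
            elif allow_mismatch:
                diag = prev[j - 1] + mismatch
            else:
                diag = _NEG_INF
            row[j] = max(diag, row[j - 1] + gap, prev[j] + gap)

    # traceback: diag, then gap-in-a (consume b), then gap-in-b (consume a)
    cols: list[tuple[Spacer | None, Spacer | None]] = []
    i, j = la, lb
    while i > 0 or j > 0:
        here = score[i][j]
        if i > 0 and j > 0:
            ai, bj = sa[i - 1], sb[j - 1]
            same = ai.sequence == bj.sequence
            diag_ok = (same and score[i - 1][j - 1] + match == here) or (
                allow_mismatch and not same and score[i - 1][j - 1] + mismatch == here
            )
            if diag_ok:
                cols.append((ai, bj))
                i, j = i - 1, j - 1
                continue
        if j > 0 and score[i][j - 1] + gap == here:
            cols.append((None, sb[j - 1]))
            j -= 1
            continue
        cols.append((sa[i - 1], None))
        i -= 1
    cols.reverse()
    return ArrayAlignment(a, b, cols, score[la][lb])


def _compatible_ends(ex: str, ey: str) -> bool:
    return ex == ey or "full" in (ex, ey)


def align_all(arrays: list[SpacerArray]) -> dict[tuple, list[ArrayAlignment]]:
    """Pairwise alignments for every compatible strain pair per locus.

    Keys are (strain_a, strain_b, locus) with strains in sorted order; the
    value lists one alignment per compatible end combination (leader vs
    leader, trailer vs trailer, and full arrays against anything).
    """
    by_locus: dict[str, list[SpacerArray]] = defaultdict(list)
    for arr in arrays:
        by_locus[arr.locus].append(arr)
    out: dict[tuple, list[ArrayAlignment]] = defaultdict(list)
    for locus, arrs in by_locus.items():
        by_strain: dict[str, list[SpacerArray]] = defaultdict(list)
        for arr in arrs:
            by_strain[arr.strain].append(arr)
        strains = sorted(by_strain)
        for x, y in itertools.combinations(strains, 2):
            for ax in sorted(by_strain[x], key=lambda a: a.end):
                for ay in sorted(by_strain[y], key=lambda a: a.end):
                    if _compatible_ends(ax.end, ay.end):
                        out[(x, y, locus)].append(align_arrays(ax, ay))
    return dict(out)


@dataclass(frozen=True)
class LossEvent:
    """A contiguous run of spacers absent from one strain relative to another.

    Evidence requires matching spacers immediately flanking the gap on both
    sides; terminal gaps are never loss events (missing data at a fragment
    boundary is indistinguishable from a shorter amplicon).
    """

    strain: str
    locus: str
    end: str
    run_length: int
    partner: str
    left_flank: str
    right_flank: str


def detect_losses(alignment: ArrayAlignment) -> list[LossEvent]:
    """Read internal gap runs flanked by match columns as loss events."""
    cols = alignment.columns
    match_col = [
        x is not None and y is not None and x.sequence == y.sequence for x, y in cols
    ]
    events: list[LossEvent] = []
    for row, arr, other in ((0, alignment.a, alignment.b), (1, alignment.b, alignment.a)):
        i = 0
        while i < len(cols):
            if cols[i][row] is None:
                j = i
                while j < len(cols) and cols[j][row] is None:
                    j += 1
                if i > 0 and j < len(cols) and match_col[i - 1] and match_col[j]:
                    events.append(
                        LossEvent(
                            strain=arr.strain,
                            locus=arr.locus,
                            end=arr.end,
                            run_length=j - i,
                            partner=other.strain,
                            left_flank=cols[i - 1][row].sequence,
                            right_flank=cols[j][row].sequence,
                        )
                    )
                i = j
            else:
                i += 1
    return events


@dataclass
class AncestralGroup:
    """Strains whose arrays at one locus share ancestral spacer context."""

    locus: str
    group_id: str
    members: list[str]
    evidence: list[tuple[str, str, str, int]] = field(default_factory=list)  # (a, b, end, run)
    trailer_only_pairs: list[tuple[str, str]] = field(default_factory=list)


def _best_match_run(alignment: ArrayAlignment) -> int:
    """Longest stretch of match columns uninterrupted by mismatch columns.

    Gap columns (spacer loss) are allowed within a run; a mismatch column
    (only possible when alignment permitted them) resets the run.
    """
    best = run = 0
    for x, y in alignment.columns:
        if x is not None and y is not None:
            if x.sequence == y.sequence:
                run += 1
                best = max(best, run)
            else:
                run = 0
    return best


def group_ancestral(arrays: list[SpacerArray], min_run: int = 3) -> list[AncestralGroup]:
    """Single-linkage grouping of strains by shared spacer context at one locus.

    Two strains are linked when, at any sequenced end they share, their
    alignment contains at least ``min_run`` identical spacers in a row
    (loss gaps allowed between them), or at least two identical spacers in
    the same order around an internal flanked gap — the spacer-loss
    signature, which itself evidences shared context. The default of 3
    keeps ancestry grouping disjoint from the consecutive-exact
    acquisition exclusion: a bare pair of adjacent identical spacers
    between two otherwise unrelated strains is treated as probable descent
    of those two spacers (and excluded from acquisition analysis) but not
    as evidence that the whole arrays share an ancestor. Pairs whose only
    linking evidence comes from trailer-end fragments are flagged: the
    very first conserved trailer spacers may be the only remnant of deep
    shared ancestry.
    """
    if min_run < 1:
        raise ValueError("min_run must be >= 1")
    loci = {arr.locus for arr in arrays}
    if len(loci) > 1:
        raise ValueError(f"group_ancestral expects arrays from a single locus, got {sorted(loci)}")
    locus = loci.pop() if loci else ""

    strains = sorted({arr.strain for arr in arrays})
    index = {s: i for i, s in enumerate(strains)}
    by_strain: dict[str, list[SpacerArray]] = defaultdict(list)
    for arr in arrays:
        by_strain[arr.strain].append(arr)

    uf = _GroupUnionFind(len(strains))
    evidence: list[tuple[str, str, str, int]] = []
    pair_ends: dict[tuple[str, str], set[str]] = defaultdict(set)
    for x, y in itertools.combinations(strains, 2):
        for ax in sorted(by_strain[x], key=lambda a: a.end):
            for ay in sorted(by_strain[y], key=lambda a: a.end):
                if not _compatible_ends(ax.end, ay.end):
                    continue
                aln = align_arrays(ax, ay)
                run = _best_match_run(aln)
                if run < min_run and run >= 2 and detect_losses(aln):
                    run = min_run  # loss-flanked context counts as ancestry evidence
                if run >= min_run:
                    uf.union(index[x], index[y])
                    end = ax.end if ax.end == ay.end else f"{ax.end}~{ay.end}"
                    evidence.append((x, y, end, run))
                    pair_ends[(x, y)].add(end)

    members: dict[int, list[str]] = defaultdict(list)
    for s in strains:
        members[uf.find(index[s])].append(s)
    groups = []
    for k, root in enumerate(sorted(members, key=lambda r: strains[r])):
        mem = sorted(members[root])
        grp = AncestralGroup(locus=locus, group_id=f"{locus}-{k + 1}", members=mem)
        mem_set = set(mem)
        grp.evidence = [e for e in evidence if e[0] in mem_set]
        grp.trailer_only_pairs = [
            p for p, es in pair_ends.items() if p[0] in mem_set and es == {"trailer"}
        ]
        groups.append(grp)
    return groups


class _GroupUnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def leader_internal_check(
    leader_arrays: list[SpacerArray],
    full_arrays: list[SpacerArray],
    leader_depth: int = DEFAULT_LEADER_DEPTH,
) -> list[tuple[Spacer, Spacer]]:
    """Search leader-end spacers against internal positions of full loci.

    If leader-end variability were caused by spacer loss rather than new
    acquisition, leader spacers of one strain would reappear internally
    (past the leader run) in another strain's fully sequenced locus — in a
    *different* spacer context. Matches that are part of the two arrays'
    shared aligned context are therefore not reported: an identical spacer
    vertically aligned between the two arrays, with further shared context
    around it, is ordinary common ancestry at different leader depths, not
    evidence of leader erosion. The expected result on real and simulated
    data is an empty list.
    """
    internal: dict[str, list[tuple[Spacer, SpacerArray]]] = defaultdict(list)
    for arr in full_arrays:
        for s in arr.spacers:
            if s.position > leader_depth:
                internal[s.sequence].append((s, arr))
    hits: list[tuple[Spacer, Spacer]] = []
    aln_cache: dict[tuple[int, int], set[tuple[int, int]]] = {}
    for arr in leader_arrays:
        for s in arr.spacers:
            if s.position == len(arr):
                continue  # the fragment-terminal spacer may be the locus's
                # conserved trailer-most spacer (short arrays), never leader-end
            for t, tarr in internal.get(s.sequence, ()):
                if t.strain == s.strain or tarr.locus != arr.locus:
                    continue
                key = (id(arr), id(tarr))
                if key not in aln_cache:
                    aln = align_arrays(arr, tarr)
                    cols = {
                        (x.position, y.position)
                        for i, (x, y) in enumerate(aln.columns)
                        if i in aln.match_columns
                    }
                    aln_cache[key] = cols if len(cols) >= 2 else set()
                if (s.position, t.position) in aln_cache[key]:
                    continue  # shared aligned context, not leader erosion
                hits.append((s, t))
    return hits


@dataclass
class AcquisitionPair:
    """A cross-strain fuzzy spacer match not explained by shared ancestry.

    ``end_class`` is leader-leader / trailer-trailer / mixed from the
    sequenced ends the two spacers came from. ``signature`` summarizes the
    match geometry (exact, offset, length-difference, offset+snps).
    ``excluded`` pairs (consecutive runs of 100% full-length matches
    between the same two strains) are retained but flagged: consecutive
    exact sharing is almost certainly common descent, not independent
    acquisition.
    """

    spacer_a: Spacer
    spacer_b: Spacer
    match: object
    end_class: str
    signature: str
    excluded: bool = False
    reason: str = ""
    n_copies: int = 1


def _end_of(spacer: Spacer, array_len: int, leader_depth: int) -> str:
    if spacer.end in ("leader", "trailer"):
        return spacer.end
    return "leader" if spacer.position <= leader_depth else "trailer"


def _signature(m) -> str:
    if m.offset == 0 and m.snps == 0 and m.overlap_length == max(
        len(_seq(m.spacer_a)), len(_seq(m.spacer_b))
    ):
        return "exact"
    parts = []
    if m.offset != 0:
        parts.append("offset")
    if len(_seq(m.spacer_a)) != len(_seq(m.spacer_b)):
        parts.append("length-difference")
    if m.snps > 0:
        parts.append(f"{m.snps}snp")
    return "+".join(parts) if parts else "exact-overlap"


def _seq(x) -> str:
    return x.sequence if hasattr(x, "sequence") else str(x)


def classify_acquisitions(
    catalog: SpacerCatalog,
    groups: list[AncestralGroup],
    alignments: dict[tuple, ArrayAlignment],
    leader_depth: int = DEFAULT_LEADER_DEPTH,
) -> list[AcquisitionPair]:
    """Classify every cross-strain fuzzy match as ancestral, excluded or acquired.

    For each pair of spacers from different strains whose sequences satisfy
    the 88/17 rule:

    1. *ancestral* (discarded) — the pair is 100% identical full length,
       same locus, and the two strains belong to the same ancestral group
       there (adjudication is group-based rather than per match column so
       that a spacer visible only in the leader fragment of one strain and
       only in the trailer fragment of the other is still recognized).
    2. *excluded* — the pair is exact and an adjacent pair (next or
       previous position in both arrays, same order) is exact too;
       consecutive exact sharing between two strains is almost certainly
       descent of that block even when array-wide ancestry is not
       supported. Also excluded (reason "intra-genome") are pairs whose
       two identity classes co-occur within a single strain's genome: two
       matching spacers (overlapping windows of one virus) carried by the
       same strain are inherited as a unit, so their cross-strain
       recurrence is not evidence of independent acquisition by different
       strains.
    3. otherwise an :class:`AcquisitionPair`.

    Pairs are de-duplicated so that ancestrally identical copies of a
    spacer across strains of one group count once, mirroring how matches
    are tabulated per spacer rather than per strain pair.
    """
    group_of: dict[tuple[str, str], str] = {}
    for g in groups:
        for s in g.members:
            group_of[(s, g.locus)] = g.group_id

    spacers_at: dict[tuple[str, str, str], dict[int, Spacer]] = defaultdict(dict)
    array_len: dict[tuple[str, str, str], int] = {}
    for s in catalog.spacers:
        key = (s.strain, s.locus, s.end)
        spacers_at[key][s.position] = s
        array_len[key] = max(array_len.get(key, 0), s.position)

    by_class: dict[str, list[Spacer]] = defaultdict(list)
    for s in catalog.spacers:
        by_class[catalog.class_of(s)].append(s)
    for lst in by_class.values():
        lst.sort(key=lambda s: (s.strain, s.locus, s.end, s.position))

    def alns_for(sa: str, sb: str, locus: str) -> list[ArrayAlignment]:
        return alignments.get((min(sa, sb), max(sa, sb), locus), [])

    # matching class pairs carried together within one strain's genome:
    # such configurations are heritable as a unit, so their cross-strain
    # recurrence is descent, not independent acquisition
    classes_by_strain: dict[str, set[str]] = defaultdict(set)
    for s in catalog.spacers:
        classes_by_strain[s.strain].add(catalog.class_of(s))
    co_resident: set[frozenset] = set()
    for strain, classes in classes_by_strain.items():
        cls = sorted(classes)
        for i, ci in enumerate(cls):
            for cj in cls[i + 1 :]:
                if catalog.classes_match(ci, cj):
                    co_resident.add(frozenset((ci, cj)))

    def is_exact(a: Spacer, b: Spacer) -> bool:
        return a.sequence == b.sequence

    def has_consecutive_exact(a: Spacer, b: Spacer) -> bool:
        if not is_exact(a, b):
            return False
        arr_a = spacers_at[(a.strain, a.locus, a.end)]
        arr_b = spacers_at[(b.strain, b.locus, b.end)]
        for d in (-1, 1):
            na, nb = arr_a.get(a.position + d), arr_b.get(b.position + d)
            if na is not None and nb is not None and na.sequence == nb.sequence:
                return True
        return False

    def is_ancestral(a: Spacer, b: Spacer) -> bool:
        if a.locus != b.locus or not is_exact(a, b):
            return False
        ga = group_of.get((a.strain, a.locus))
        gb = group_of.get((b.strain, b.locus))
        if ga is not None and ga == gb:
            return True
        # fall back to the pairwise alignments when groups were built from a
        # different array set than the catalog
        for aln in alns_for(a.strain, b.strain, a.locus):
            if len(aln.match_sequences) > 2 and a.sequence in aln.match_sequences:
                return True
        return False

    seen: dict[frozenset, AcquisitionPair] = {}
    results: list[AcquisitionPair] = []
    class_pairs = catalog.matching_class_pairs()
    for ca, cb in class_pairs:
        for a in by_class[ca]:
            for b in by_class[cb]:
                if a.strain == b.strain:
                    continue
                if ca == cb and (b.strain, b.locus, b.end, b.position) <= (
                    a.strain,
                    a.locus,
                    a.end,
                    a.position,
                ):
                    continue
                if is_ancestral(a, b):
                    continue
                excluded, reason = False, ""
                if has_consecutive_exact(a, b):
                    excluded, reason = True, "consecutive-exact"
                elif frozenset((ca, cb)) in co_resident:
                    excluded, reason = True, "intra-genome"
                occ_a = (catalog.class_of(a), a.locus, group_of.get((a.strain, a.locus), a.strain))
                occ_b = (catalog.class_of(b), b.locus, group_of.get((b.strain, b.locus), b.strain))
                dedup = frozenset((occ_a, occ_b))
                if dedup in seen:
                    seen[dedup].n_copies += 1
                    continue
                m = pair_match(a, b, catalog.min_identity, catalog.min_overlap)
                ends = sorted(
                    (
                        _end_of(a, array_len[(a.strain, a.locus, a.end)], leader_depth),
                        _end_of(b, array_len[(b.strain, b.locus, b.end)], leader_depth),
                    )
                )
                end_class = (
                    "leader-leader"
                    if ends == ["leader", "leader"]
                    else "trailer-trailer"
                    if ends == ["trailer", "trailer"]
                    else "mixed"
                )
                pair = AcquisitionPair(
                    spacer_a=a,
                    spacer_b=b,
                    match=m,
                    end_class=end_class,
                    signature=_signature(m),
                    excluded=excluded,
                    reason=reason,
                )
                seen[dedup] = pair
                results.append(pair)
    return results


def acquisition_end_summary(pairs: list[AcquisitionPair]) -> dict:
    """Counts and fractions of leader-leader / trailer-trailer / mixed pairs."""
    counts = {"leader-leader": 0, "trailer-trailer": 0, "mixed": 0}
    for p in pairs:
        if not p.excluded:
            counts[p.end_class] += 1
    total = sum(counts.values())
    fractions = {k: (v / total if total else 0.0) for k, v in counts.items()}
    return {"counts": counts, "fractions": fractions, "total": total}
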