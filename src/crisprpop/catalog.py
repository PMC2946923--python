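"""Spacer identity, similarity and protospacer search.

Two notions of spacer equivalence are kept separate throughout the
package:

* **exact classes** — full-length identical sequences (after arrays have
  been orientation-normalized). These are the symbols used for array
  alignment and ancestry.
* **fuzzy clusters** — single-linkage components over the assembly-style
  match rule: two spacers match when some ungapped overlap of at least 17
  nt reaches at least 88% identity. On a full 39-nt overlap that admits at
  most 4 mismatches.

Protospacer search scans spacers against a target database (virus,
plasmid or genome FASTA) with an exhaustive ungapped scan scored
match +1 / mismatch -1; an optional gapped mode adds a -4 gap penalty via
Biopython's pairwise aligner.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

from .arrays import Spacer, revcomp

__all__ = [
    "MatchResult",
    "SpacerCatalog",
    "ProtospacerHit",
    "PamContext",
    "DEFAULT_MIN_IDENTITY",
    "DEFAULT_MIN_OVERLAP",
    "pair_match",
    "build_catalog",
    "search_protospacers",
    "pam_context",
]

DEFAULT_MIN_IDENTITY = 0.88
DEFAULT_MIN_OVERLAP = 17


def _seq_of(x) -> str:
    return x.sequence if hasattr(x, "sequence") else str(x)


@dataclass(frozen=True)
class MatchResult:
    """Best ungapped overlap between two spacers under the 88/17 rule.

    ``offset`` is the start coordinate of b in a's coordinate system (sign
    flips when arguments are swapped). ``snps`` is the mismatch count
    within the reported overlap, so identity = 1 - snps/overlap_length
    exactly.
    """

    spacer_a: object
    spacer_b: object
    offset: int
    overlap_length: int
    identity: float
    snps: int
    is_match: bool
    orientation: str  # "same" or "reverse-complement"


def _overlap_stats(a: str, b: str, offset: int) -> tuple[int, int]:
    """(overlap_length, matches) for b placed at position `offset` of a."""
    start = max(0, offset)
    end = min(len(a), offset + len(b))
    if end <= start:
        return 0, 0
    matches = sum(1 for i in range(start, end) if a[i] == b[i - offset])
    return end - start, matches


def pair_match(
    a,
    b,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    allow_revcomp: bool = False,
) -> MatchResult:
    """Best ungapped overlap alignment of two spacers.

    ``is_match`` is true iff *some* offset (and orientation, if enabled)
    achieves both thresholds. Among qualifying offsets the reported one
    maximizes (identity, overlap length), breaking ties by smaller
    |offset| and then same orientation; if none qualifies the best offset
    with overlap >= min_overlap is reported instead (falling back to the
    globally best overlap for very short spacers).
    """
    sa, sb = _seq_of(a), _seq_of(b)
    if not sa or not sb:
        raise ValueError("pair_match requires non-empty sequences")

    orientations = [("same", sb)]
    if allow_revcomp:
        orientations.append(("reverse-complement", revcomp(sb)))

    best_q = None  # qualifying
    best_l = None  # overlap >= min_overlap
    best_any = None
    for orient, bs in orientations:
        for off in range(-(len(bs) - 1), len(sa)):
            ov, matches = _overlap_stats(sa, bs, off)
            if ov == 0:
                continue
            ident = matches / ov
            key = (ident, ov, -abs(off), orient == "same")
            cand = (key, off, ov, ident, ov - matches, orient)
            if best_any is None or key > best_any[0]:
                best_any = cand
            if ov >= min_overlap and (best_l is None or key > best_l[0]):
                best_l = cand
            if ov >= min_overlap and ident >= min_identity and (best_q is None or key > best_q[0]):
                best_q = cand

    is_match = best_q is not None
    chosen = best_q if best_q is not None else (best_l if best_l is not None else best_any)
    _, off, ov, ident, snps, orient = chosen
    return MatchResult(a, b, off, ov, ident, snps, is_match, orient)


def _encode_padded(seqs: list[str]) -> tuple[np.ndarray, np.ndarray]:
    lens = np.array([len(s) for s in seqs])
    lmax = int(lens.max())
    mat = np.zeros((len(seqs), lmax), dtype=np.uint8)
    for i, s in enumerate(seqs):
        mat[i, : len(s)] = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
    return mat, lens


def match_matrix(
    seqs: list[str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    allow_revcomp: bool = False,
) -> np.ndarray:
    """Boolean n x n matrix of the 88/17 rule over unique sequences.

    Vectorized across all pairs per offset; equivalent to calling
    :func:`pair_match` on every pair (tested against it), but usable on
    thousands of spacers.
    """
    n = len(seqs)
    out = np.zeros((n, n), dtype=bool)
    variants = [seqs]
    if allow_revcomp:
        variants.append([revcomp(s) for s in seqs])
    mat_a, lens = _encode_padded(seqs)
    lmax = mat_a.shape[1]
    for var in variants:
        mat_b, lens_b = _encode_padded(var)
        wb = mat_b.shape[1]
        for off in range(0, lmax):
            w = min(lmax - off, wb)
            if w < min_overlap:
                break
            a_sl = mat_a[:, off : off + w]
            b_sl = mat_b[:, :w]
            eq = (a_sl[:, None, :] == b_sl[None, :, :]) & (a_sl[:, None, :] != 0) & (b_sl[None, :, :] != 0)
            matches = eq.sum(axis=2)
            ov = np.minimum(lens[:, None] - off, lens_b[None, :])
            ov = np.maximum(ov, 0)
            with np.errstate(invalid="ignore", divide="ignore"):
                ok = (ov >= min_overlap) & (matches >= min_identity * ov - 1e-9)
            out |= ok
            out |= ok.T  # offset -off of the swapped pair
    np.fill_diagonal(out, [len(s) >= min_overlap for s in seqs])
    return out


class _UnionFind:
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


@dataclass
class SpacerCatalog:
    """Exact identity classes and fuzzy match clusters over a spacer set.

    Class and cluster ids are deterministic: classes are numbered by
    sorted sequence, clusters by their smallest member class id, so the
    catalog is invariant to input order up to the spacers' own identity.
    """

    spacers: list[Spacer]
    exact_classes: dict[str, list[Spacer]] = field(default_factory=dict)
    fuzzy_clusters: dict[str, list[Spacer]] = field(default_factory=dict)
    class_of_seq: dict[str, str] = field(default_factory=dict)
    cluster_of_class: dict[str, str] = field(default_factory=dict)
    class_match: dict[str, object] = field(default_factory=dict)  # class id -> row index / matrix
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_overlap: int = DEFAULT_MIN_OVERLAP

    @property
    def n_unique(self) -> int:
        """Unique-spacer count = number of fuzzy clusters."""
        return len(self.fuzzy_clusters)

    @property
    def n_exact(self) -> int:
        return len(self.exact_classes)

    def class_of(self, spacer) -> str:
        return self.class_of_seq[_seq_of(spacer)]

    def classes_match(self, class_a: str, class_b: str) -> bool:
        """Whether two exact classes satisfy the fuzzy match rule."""
        mat = self.class_match["matrix"]
        idx = self.class_match["index"]
        return bool(mat[idx[class_a], idx[class_b]])

    def matching_class_pairs(self):
        """Unordered pairs of class ids (including identical pairs) that match."""
        mat = self.class_match["matrix"]
        ids = self.class_match["ids"]
        ii, jj = np.nonzero(np.triu(mat))
        return [(ids[i], ids[j]) for i, j in zip(ii, jj)]


def build_catalog(
    spacers: list[Spacer],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    linkage: str = "single",
    allow_revcomp: bool = False,
) -> SpacerCatalog:
    """Group spacers into exact classes and fuzzy clusters.

    Fuzzy clusters are single-linkage components over pairwise matches by
    default, mirroring contig-assembly semantics (a chain of pairwise
    overlaps forms one contig); ``linkage="complete"`` instead requires
    every pair within a cluster to match.
    """
    if not spacers:
        raise ValueError("build_catalog requires at least one spacer")
    if linkage not in ("single", "complete"):
        raise ValueError("linkage must be 'single' or 'complete'")

    uniq = sorted({_seq_of(s) for s in spacers})
    class_ids = [f"E{i:04d}" for i in range(len(uniq))]
    class_of_seq = dict(zip(uniq, class_ids))

    mat = match_matrix(uniq, min_identity, min_overlap, allow_revcomp)

    n = len(uniq)
    if linkage == "single":
        uf = _UnionFind(n)
        ii, jj = np.nonzero(np.triu(mat, k=1))
        for i, j in zip(ii, jj):
            uf.union(int(i), int(j))
        comp = [uf.find(i) for i in range(n)]
    else:
        from scipy.cluster.hierarchy import fcluster, linkage as sp_linkage
        from scipy.spatial.distance import squareform

        if n == 1:
            comp = [0]
        else:
            dist = 1.0 - mat.astype(float)
            np.fill_diagonal(dist, 0.0)
            labels = fcluster(sp_linkage(squareform(dist, checks=False), "complete"), 0.5, "distance")
            # relabel by smallest member index for determinism
            first = {}
            for i, lab in enumerate(labels):
                first.setdefault(lab, i)
            comp = [first[lab] for lab in labels]

    cluster_of_class = {}
    roots = sorted(set(comp))
    root_id = {r: f"U{k:04d}" for k, r in enumerate(roots)}
    for i, r in enumerate(comp):
        cluster_of_class[class_ids[i]] = root_id[r]

    exact_classes: dict[str, list[Spacer]] = {c: [] for c in class_ids}
    fuzzy_clusters: dict[str, list[Spacer]] = {u: [] for u in root_id.values()}
    for s in spacers:
        cid = class_of_seq[_seq_of(s)]
        exact_classes[cid].append(s)
        fuzzy_clusters[cluster_of_class[cid]].append(s)

    return SpacerCatalog(
        spacers=list(spacers),
        exact_classes=exact_classes,
        fuzzy_clusters=fuzzy_clusters,
        class_of_seq=class_of_seq,
        cluster_of_class=cluster_of_class,
        class_match={"matrix": mat, "index": {c: i for i, c in enumerate(class_ids)}, "ids": class_ids},
        min_identity=min_identity,
        min_overlap=min_overlap,
    )


@dataclass(frozen=True)
class ProtospacerHit:
    """A spacer hit inside a target sequence.

    Coordinates are 0-based half-open on the target's plus strand
    regardless of hit strand. Score is matches - mismatches (gap -4 in the
    optional gapped mode). ``exact`` flags 100%-identity full-length hits.
    """

    spacer: str
    target: str
    start: int
    end: int
    strand: str
    length: int
    identity: float
    score: int
    exact: bool


def _load_targets(targets) -> dict[str, str]:
    if isinstance(targets, (str, Path)):
        recs = list(SeqIO.parse(str(targets), "fasta"))
        if not recs:
            raise IOError(f"no target sequences found in {targets}")
        return {r.id: str(r.seq).upper() for r in recs}
    if hasattr(targets, "items"):
        return {k: str(v).upper() for k, v in targets.items()}
    return {r.id: str(r.seq).upper() for r in targets}


def _scan_one(spacer_seq: str, target_seq: str, min_identity: float):
    """Yield (start, matches) for all full-length ungapped placements."""
    m = len(spacer_seq)
    if len(target_seq) < m:
        return
    windows = np.lib.stride_tricks.sliding_window_view(
        np.frombuffer(target_seq.encode("ascii"), dtype=np.uint8), m
    )
    matches = (windows == np.frombuffer(spacer_seq.encode("ascii"), dtype=np.uint8)).sum(axis=1)
    thresh = min_identity * m - 1e-9
    for i in np.nonzero(matches >= thresh)[0]:
        yield int(i), int(matches[i])


def search_protospacers(
    catalog,
    targets,
    min_identity: float = 0.9,
    min_length: int = DEFAULT_MIN_OVERLAP,
    mode: str = "ungapped",
) -> list[ProtospacerHit]:
    """Search spacers against a target database on both strands.

    ``catalog`` may be a SpacerCatalog, a list of Spacer objects, or plain
    sequences. The default is an exhaustive full-length ungapped scan
    scored match +1 / mismatch -1; ``mode="gapped"`` uses a local aligner
    with gap penalty -4 and reports the best hit per spacer/target/strand.
    """
    if isinstance(catalog, SpacerCatalog):
        seqs = sorted({_seq_of(s) for s in catalog.spacers})
    elif isinstance(catalog, (list, tuple)):
        seqs = sorted({_seq_of(s) for s in catalog})
    else:
        seqs = [str(catalog)]
    tdb = _load_targets(targets)

    hits: list[ProtospacerHit] = []
    for sp in seqs:
        if len(sp) < min_length:
            continue
        for tid, tseq in tdb.items():
            if mode == "gapped":
                hits.extend(_gapped_hits(sp, tid, tseq, min_identity, min_length))
                continue
            m = len(sp)
            for strand in "+-":
                query = sp if strand == "+" else revcomp(sp)
                for start, matches in _scan_one(query, tseq, min_identity):
                    ident = matches / m
                    hits.append(
                        ProtospacerHit(
                            spacer=sp,
                            target=tid,
                            start=start,
                            end=start + m,
                            strand=strand,
                            length=m,
                            identity=ident,
                            score=2 * matches - m,
                            exact=matches == m,
                        )
                    )
    hits.sort(key=lambda h: (h.spacer, h.target, h.start, h.strand))
    return hits


def _gapped_hits(sp: str, tid: str, tseq: str, min_identity: float, min_length: int):
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner(mode="local", match_score=1, mismatch_score=-1,
                              open_gap_score=-4, extend_gap_score=-4)
    for strand in "+-":
        query = sp if strand == "+" else revcomp(sp)
        alns = aligner.align(tseq, query)
        if not alns or alns.score <= 0:
            continue
        aln = alns[0]
        t0, t1 = int(aln.aligned[0][0][0]), int(aln.aligned[0][-1][1])
        length = t1 - t0
        counts = aln.counts()
        cols = counts.identities + counts.mismatches + counts.gaps
        ident = counts.identities / cols if cols else 0.0
        if length >= min_length and ident >= min_identity:
            yield ProtospacerHit(
                spacer=sp, target=tid, start=t0, end=t1, strand=strand,
                length=length, identity=ident, score=int(alns.score),
                exact=ident == 1.0 and length == len(sp),
            )


@dataclass(frozen=True)
class PamContext:
    """Flanking target sequence around a protospacer, strand-aware.

    "Upstream"/"downstream" are in the protospacer's own reading frame:
    for minus-strand hits the flanks are reverse-complemented and swapped.
    ``truncated`` flags contexts clipped at a target boundary.
    """

    upstream: str
    downstream: str
    truncated: bool


def pam_context(hit: ProtospacerHit, targets, k: int = 2) -> PamContext:
    """Extract k nt of flanking target sequence either side of a hit.

    This is context extraction only — no motif calling. The
    protospacer-associated motif (PAM) in *Sulfolobus* is a dinucleotide,
    hence the default k=2.
    """
    tdb = _load_targets(targets)
    tseq = tdb[hit.target]
    if not (0 <= hit.start < hit.end <= len(tseq)):
        raise ValueError("hit coordinates out of target bounds")
    left = tseq[max(0, hit.start - k) : hit.start]
    right = tseq[hit.end : hit.end + k]
    truncated = len(left) < k or len(right) < k
    if hit.strand == "+":
        return PamContext(left, right, truncated)
    return PamContext(revcomp(right), revcomp(left), truncated)
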