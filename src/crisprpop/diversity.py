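"""Diversity estimation: OTU binning, rarefaction, Chao1, rank abundance.

Strain-level diversity is measured two ways, mirroring the two data
sources:

* MLSA — pairwise p-distance on concatenated housekeeping alignments;
* CRISPR — the "coded array" representation, where each spacer column is
  a categorical character (identical spacers in a column share a code) and
  distance is the fraction of differing comparable columns.

OTUs are furthest-neighbor (complete-linkage) clusters at a distance
cutoff. Rarefaction is the analytic individual-based expectation
E[S_n] = S - sum_i C(N - N_i, n) / C(N, n); Chao1 is reported in its
bias-corrected form S_obs + F1(F1-1)/(2(F2+1)) alongside the classical
F1^2/(2 F2) estimate.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage as _linkage
from scipy.spatial.distance import squareform
from scipy.special import gammaln

__all__ = [
    "DistanceMatrix",
    "CodedArrayMatrix",
    "DiversityEstimate",
    "mlsa_distance",
    "build_coded_matrix",
    "coded_array_distance",
    "bin_otus",
    "rarefy",
    "chao1",
    "rank_abundance",
]

MISSING = -1  # strain lacks the fragment (white box: absent data)
GAP = -2  # fragment sequenced but no spacer at this column (counts as a difference)


@dataclass
class DistanceMatrix:
    """Symmetric strain-by-strain distance matrix with zero diagonal."""

    strains: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.strains), len(self.strains)):
            raise ValueError("distance matrix shape does not match strain list")
        if not np.allclose(v, v.T) or not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        self.values = v

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def __getitem__(self, pair) -> float:
        i = self.strains.index(pair[0])
        j = self.strains.index(pair[1])
        return float(self.values[i, j])


def mlsa_distance(profiles) -> DistanceMatrix:
    """Pairwise p-distance over concatenated MLSA sequences.

    Accepts GenotypeProfile objects or a {strain: sequence} mapping. N and
    gap columns are skipped pairwise; a pair with zero comparable columns
    is an error.
    """
    if hasattr(profiles, "items"):
        seqs = dict(profiles)
    else:
        seqs = {p.strain: p.concatenated for p in profiles}
    strains = sorted(seqs)
    arr = {s: np.frombuffer(seqs[s].encode("ascii"), dtype=np.uint8) for s in strains}
    bad = {ord("N"), ord("-")}
    valid = {s: ~np.isin(arr[s], list(bad)) for s in strains}
    n = len(strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[strains[i]] & valid[strains[j]]
            m = int(both.sum())
            if m == 0:
                raise ValueError(f"no comparable columns between {strains[i]} and {strains[j]}")
            d[i, j] = d[j, i] = (arr[strains[i]][both] != arr[strains[j]][both]).sum() / m
    return DistanceMatrix(strains, d)


@dataclass
class CodedArrayMatrix:
    """Categorical coding of spacer arrays: strains x columns.

    Each column is one (locus, end, position); the cell holds an integer
    code shared by identical spacers in that column, GAP when the fragment
    is sequenced but too short to reach the column, or MISSING when the
    strain has no data for the fragment.
    """

    strains: list[str]
    columns: list[tuple[str, str, int]]
    codes: np.ndarray

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes)
        if self.codes.shape != (len(self.strains), len(self.columns)):
            raise ValueError("codes shape does not match strains x columns")


def build_coded_matrix(arrays, loci: list[str] | None = None, end_depth: int = 10) -> CodedArrayMatrix:
    """Code spacer arrays into a strains-x-columns categorical matrix.

    Columns are positions within each sequenced fragment (locus x end),
    concatenated across loci; identical spacer sequences in one column
    receive the same code. A strain with no fragment for a (locus, end)
    gets MISSING across its columns; a sequenced but shorter fragment gets
    GAP beyond its last spacer. Fully sequenced arrays ("full" end) are
    clipped into leader and trailer views of ``end_depth`` spacers so they
    share the column space of end-fragment strains.
    """
    arrays = list(arrays)
    strains = sorted({a.strain for a in arrays})
    if loci is None:
        loci = sorted({a.locus for a in arrays})
    by_frag: dict[tuple[str, str, str], list] = {}
    for a in arrays:
        if a.end == "full":
            by_frag.setdefault((a.strain, a.locus, "leader"), a.sequences[:end_depth])
            by_frag.setdefault((a.strain, a.locus, "trailer"), a.sequences[-end_depth:])
        else:
            by_frag[(a.strain, a.locus, a.end)] = a.sequences
    ends = sorted({k[2] for k in by_frag})

    columns: list[tuple[str, str, int]] = []
    for locus in loci:
        for end in ends:
            max_len = max(
                (len(by_frag[k]) for k in by_frag if k[1] == locus and k[2] == end),
                default=0,
            )
            columns.extend((locus, end, p) for p in range(1, max_len + 1))

    codes = np.full((len(strains), len(columns)), MISSING, dtype=int)
    for j, (locus, end, pos) in enumerate(columns):
        col_seqs: dict[str, int] = {}
        for i, strain in enumerate(strains):
            frag = by_frag.get((strain, locus, end))
            if frag is None:
                continue
            if pos > len(frag):
                codes[i, j] = GAP
                continue
            seq = frag[pos - 1]
            codes[i, j] = col_seqs.setdefault(seq, len(col_seqs))
    return CodedArrayMatrix(strains, columns, codes)


def coded_array_distance(matrix: CodedArrayMatrix, drop_incomparable: bool = False) -> DistanceMatrix:
    """Fraction of differing columns among columns comparable for a pair.

    Gap vs spacer counts as a difference (a real absence); MISSING columns
    are dropped pairwise. A pair with no comparable column is an error
    naming the strains; with ``drop_incomparable`` the strains responsible
    for the most incomparable pairs are removed instead (a strain that
    lost or failed to amplify every locus shared with another strain
    carries no usable comparison).
    """
    if len(matrix.strains) < 2:
        raise ValueError("coded_array_distance requires at least 2 strains")
    strains = list(matrix.strains)
    codes = matrix.codes
    if drop_incomparable:
        while True:
            present = codes != MISSING
            comparable = present @ present.T  # shared non-missing column counts
            bad = (comparable == 0).sum(axis=1)
            if not bad.any() or len(strains) <= 2:
                break
            worst = int(np.argmax(bad))
            strains.pop(worst)
            codes = np.delete(codes, worst, axis=0)
    n = len(strains)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = (codes[i] != MISSING) & (codes[j] != MISSING)
            m = int(both.sum())
            if m == 0:
                raise ValueError(
                    f"strains {strains[i]} and {strains[j]} share no comparable columns"
                )
            d[i, j] = d[j, i] = (codes[i][both] != codes[j][both]).sum() / m
    return DistanceMatrix(strains, d)


def bin_otus(d: DistanceMatrix, cutoff: float, method: str = "complete") -> dict[str, int]:
    """Cluster strains into OTUs at a distance cutoff.

    Furthest-neighbor (complete-linkage) clustering by default, the
    convention of classical OTU binning tools; cutoff 0 groups identical
    individuals only ("unique"). Returns strain -> OTU label (labels are
    renumbered 0.. by first strain in sorted order).
    """
    if not 0 <= cutoff <= 1:
        raise ValueError("cutoff must be in [0, 1]")
    n = len(d.strains)
    if n == 1:
        return {d.strains[0]: 0}
    labels = fcluster(_linkage(d.condensed(), method), t=cutoff, criterion="distance")
    remap: dict[int, int] = {}
    out = {}
    for s, lab in zip(d.strains, labels):
        out[s] = remap.setdefault(int(lab), len(remap))
    return out


def _abundances(assignment) -> np.ndarray:
    if hasattr(assignment, "values") and not isinstance(assignment, np.ndarray):
        counts = Counter(assignment.values())
    elif isinstance(assignment, (list, tuple, np.ndarray)) and all(
        isinstance(x, (int, np.integer)) for x in assignment
    ):
        # already an abundance vector
        return np.asarray(assignment, dtype=int)
    else:
        counts = Counter(assignment)
    return np.array(sorted(counts.values(), reverse=True), dtype=int)


def rarefy(assignment) -> np.ndarray:
    """Analytic individual-based rarefaction curve E[S_n], n = 1..N.

    ``assignment`` is a strain -> OTU mapping or an abundance vector.
    Uses the hypergeometric expectation; the returned array has length N
    with E[S_N] = S_obs exactly.
    """
    ab = _abundances(assignment)
    if ab.size == 0 or ab.sum() == 0:
        raise ValueError("rarefy requires at least one individual")
    big_n = int(ab.sum())
    s = len(ab)
    ns = np.arange(1, big_n + 1)

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    curve = np.empty(big_n, dtype=float)
    denom = log_comb(big_n, ns)
    for k, n in enumerate(ns):
        rest = big_n - ab
        ok = rest >= n
        terms = np.zeros(s)
        terms[ok] = np.exp(log_comb(rest[ok], n) - denom[k])
        curve[k] = s - terms.sum()
    return curve


@dataclass
class DiversityEstimate:
    """Observed richness, singleton/doubleton counts and Chao1 estimates."""

    s_obs: int
    f1: int
    f2: int
    chao1: float
    chao1_classical: float | None
    rarefaction: np.ndarray = field(repr=False, default=None)


def chao1(assignment, with_rarefaction: bool = True) -> DiversityEstimate:
    """Bias-corrected Chao1 richness: S_obs + F1(F1-1) / (2(F2+1)).

    The classical form S_obs + F1^2/(2 F2) is reported alongside when
    doubletons exist (None otherwise). chao1 >= S_obs always, with
    equality iff F1 <= 1.
    """
    ab = _abundances(assignment)
    if ab.size == 0:
        raise ValueError("chao1 requires at least one OTU")
    s_obs = len(ab)
    f1 = int((ab == 1).sum())
    f2 = int((ab == 2).sum())
    est = s_obs + f1 * (f1 - 1) / (2 * (f2 + 1))
    classical = s_obs + f1 * f1 / (2 * f2) if f2 > 0 else None
    return DiversityEstimate(
        s_obs=s_obs,
        f1=f1,
        f2=f2,
        chao1=est,
        chao1_classical=classical,
        rarefaction=rarefy(ab) if with_rarefaction else None,
    )


def rank_abundance(groupings) -> list[tuple[str, int]]:
    """Group sizes sorted largest to smallest (ties by group id).

    Accepts a strain -> group mapping or an iterable of (group, size)
    pairs; works for both MLSA genotypes and CRISPR ancestral groupings.
    """
    if hasattr(groupings, "values") and not isinstance(groupings, np.ndarray):
        counts = Counter(groupings.values())
    else:
        groupings = list(groupings)
        if groupings and isinstance(groupings[0], tuple) and len(groupings[0]) == 2:
            counts = dict(groupings)
        else:
            counts = Counter(groupings)
    return sorted(counts.items(), key=lambda kv: (-kv[1], str(kv[0])))
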