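"""Repeat-delimited CRISPR spacer extraction.

A CRISPR locus is a series of near-identical direct repeats separated by
short "spacer" sequences acquired from invading viruses and plasmids. This
module locates the repeats in an amplicon (or full-locus) sequence and
emits the ordered spacers between them, oriented leader-to-trailer. The
leader end is where new spacers are inserted; the trailer end carries the
oldest spacers.

Built-in repeats are the two *Sulfolobus islandicus* repeat families used
by the A1/A2 loci (24 nt) and the C locus (25 nt).
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

__all__ = [
    "RepeatDefinition",
    "RepeatHit",
    "Spacer",
    "SpacerArray",
    "LoadResult",
    "A_REPEAT",
    "C_REPEAT",
    "BUILTIN_REPEATS",
    "EmptySequenceError",
    "UnparseableLocusError",
    "MetadataError",
    "revcomp",
    "find_repeats",
    "extract_spacers",
    "load_locus_fasta",
    "spacer_table",
]

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

DEFAULT_HEADER_PATTERN = "{strain}|{locus}|{end}"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


class EmptySequenceError(ValueError):
    """Raised when an operation receives an empty input sequence."""


class UnparseableLocusError(ValueError):
    """Raised when a record does not contain enough repeats to delimit a spacer."""


class MetadataError(ValueError):
    """Raised when a FASTA header does not match the configured metadata pattern."""


@dataclass(frozen=True)
class RepeatDefinition:
    """A direct-repeat sequence identified by its locus family (A or C)."""

    locus_family: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("repeat sequence must be non-empty")
        if not re.fullmatch(r"[ACGT]+", self.sequence):
            raise ValueError("repeat sequence must be uppercase DNA over {A,C,G,T}")

    def __len__(self) -> int:
        return len(self.sequence)


A_REPEAT = RepeatDefinition("A", "GATAATCTACTATAGAATTGAAAG")
C_REPEAT = RepeatDefinition("C", "GATTAATCCTAAAAGGAATTGAAAG")

#: Repeat to use for each locus name; A1/A2 share the A-family repeat.
BUILTIN_REPEATS = {"A": A_REPEAT, "A1": A_REPEAT, "A2": A_REPEAT, "C": C_REPEAT}


@dataclass(frozen=True, order=True)
class RepeatHit:
    """Location of one repeat copy: 0-based half-open coordinates."""

    start: int
    end: int
    mismatches: int
    strand: str  # "+" or "-"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError("invalid repeat hit coordinates")
        if self.strand not in "+-":
            raise ValueError("strand must be '+' or '-'")


@dataclass(frozen=True)
class Spacer:
    """One spacer with its provenance metadata.

    ``position`` is 1-based from the leader-most spacer of the sequenced
    fragment the spacer came from. ``end`` is which end of the locus the
    fragment represents: leader, trailer, or full (whole locus).
    """

    sequence: str
    strain: str
    locus: str
    end: str
    position: int

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError("spacer sequence must be non-empty")
        if self.position < 1:
            raise ValueError("spacer position is 1-based")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SpacerArray:
    """Ordered spacers for one strain x locus x end, leader-to-trailer."""

    strain: str
    locus: str
    end: str
    spacers: list[Spacer]
    source_record: str = ""
    leader_flank: str = ""
    trailer_flank: str = ""

    def __len__(self) -> int:
        return len(self.spacers)

    def __iter__(self):
        return iter(self.spacers)

    @property
    def sequences(self) -> list[str]:
        return [s.sequence for s in self.spacers]


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def _hamming_candidates(sequence: str, pattern: str, max_mismatches: int) -> list[tuple[int, int]]:
    """All (start, mismatches) where pattern occurs with <= max_mismatches."""
    m = len(pattern)
    if len(sequence) < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(_encode(sequence), m)
    mism = (windows != _encode(pattern)).sum(axis=1)
    idx = np.nonzero(mism <= max_mismatches)[0]
    return [(int(i), int(mism[i])) for i in idx]


def find_repeats(sequence: str, repeat: RepeatDefinition, max_mismatches: int = 0) -> list[RepeatHit]:
    """Locate all non-overlapping copies of a repeat on both strands.

    Candidates within ``max_mismatches`` Hamming distance are collected on
    both strands; overlapping candidates are resolved greedily left to
    right, preferring fewer mismatches and then the leftmost start (repeats
    never legitimately overlap within a locus). Hits are returned sorted by
    start coordinate.
    """
    if max_mismatches < 0:
        raise ValueError("max_mismatches must be >= 0")
    if not sequence:
        raise EmptySequenceError("cannot search for repeats in an empty sequence")
    if len(sequence) < len(repeat):
        raise ValueError("sequence shorter than the repeat")
    sequence = sequence.upper()

    m = len(repeat)
    cands: list[RepeatHit] = []
    for strand, pat in (("+", repeat.sequence), ("-", revcomp(repeat.sequence))):
        for start, mm in _hamming_candidates(sequence, pat, max_mismatches):
            cands.append(RepeatHit(start, start + m, mm, strand))
    cands.sort(key=lambda h: (h.start, h.mismatches, h.strand))

    accepted: list[RepeatHit] = []
    for hit in cands:
        if accepted and hit.start < accepted[-1].end:
            if hit.mismatches < accepted[-1].mismatches:
                accepted[-1] = hit
        else:
            accepted.append(hit)
    return accepted


def _majority_strand(hits: list[RepeatHit]) -> str:
    plus = sum(1 for h in hits if h.strand == "+")
    return "+" if plus * 2 >= len(hits) else "-"


def extract_spacers(
    record,
    repeat: RepeatDefinition,
    max_mismatches: int = 0,
    *,
    strain: str | None = None,
    locus: str | None = None,
    end: str | None = None,
) -> SpacerArray:
    """Extract the ordered spacer array from one locus sequence.

    ``record`` may be a Bio.SeqRecord (metadata passed via keywords) or a
    plain string. Spacers are the substrings strictly between consecutive
    repeat copies. If the repeats lie on the minus strand the sequence is
    reverse-complemented first, so the emitted array is always oriented
    leader-to-trailer as written in the plus-strand convention of the
    repeat. Flanking sequence outside the outermost repeats is retained on
    the array but not emitted as spacers. Zero-length gaps between abutting
    repeats are skipped with a warning.
    """
    if hasattr(record, "seq"):
        sequence = str(record.seq)
        record_id = record.id
    else:
        sequence = str(record)
        record_id = ""
    if strain is None or locus is None or end is None:
        raise MetadataError("extract_spacers requires strain, locus and end metadata")
    if not sequence:
        raise EmptySequenceError(f"record {record_id or strain} has an empty sequence")
    sequence = sequence.upper()

    hits = find_repeats(sequence, repeat, max_mismatches)
    if len(hits) >= 2 and _majority_strand(hits) == "-":
        sequence = revcomp(sequence)
        hits = find_repeats(sequence, repeat, max_mismatches)
    hits = [h for h in hits if h.strand == "+"]
    if len(hits) < 2:
        raise UnparseableLocusError(
            f"unparseable locus: record '{record_id or strain}|{locus}|{end}' has "
            f"{len(hits)} repeat hit(s); at least 2 are needed to delimit a spacer"
        )

    spacers: list[Spacer] = []
    for prev, nxt in zip(hits, hits[1:]):
        gap = sequence[prev.end : nxt.start]
        if not gap:
            warnings.warn(
                f"zero-length spacer between repeats at {prev.end} in record "
                f"'{record_id or strain}'; skipped",
                stacklevel=2,
            )
            continue
        spacers.append(
            Spacer(sequence=gap, strain=strain, locus=locus, end=end, position=len(spacers) + 1)
        )
    return SpacerArray(
        strain=strain,
        locus=locus,
        end=end,
        spacers=spacers,
        source_record=record_id,
        leader_flank=sequence[: hits[0].start],
        trailer_flank=sequence[hits[-1].end :],
    )


def _pattern_to_regex(pattern: str) -> re.Pattern:
    """Compile a '{strain}|{locus}|{end}' style pattern into a named regex."""
    out = []
    pos = 0
    for m in re.finditer(r"\{(\w+)\}", pattern):
        out.append(re.escape(pattern[pos : m.start()]))
        out.append(f"(?P<{m.group(1)}>[^|]+)")
        pos = m.end()
    out.append(re.escape(pattern[pos:]))
    # optional trailing "|X" flag marks a locus known to be absent
    out.append(r"(?:\|(?P<absent>X))?")
    return re.compile("".join(out))


@dataclass
class LoadResult:
    """Arrays parsed from a locus FASTA plus a per-record status report.

    Statuses follow the field convention: "OK" parsed, "NA" could not be
    parsed (repeats not found, mirroring loci that could not be sequenced),
    "X" the locus is flagged absent in the record metadata.
    """

    arrays: list[SpacerArray] = field(default_factory=list)
    statuses: dict[str, str] = field(default_factory=dict)

    def __iter__(self):
        return iter(self.arrays)

    def __len__(self) -> int:
        return len(self.arrays)


def load_locus_fasta(
    path,
    metadata_pattern: str = DEFAULT_HEADER_PATTERN,
    repeats: dict[str, RepeatDefinition] | None = None,
    max_mismatches: int = 2,
) -> LoadResult:
    """Parse a multi-record locus FASTA into spacer arrays.

    Headers must match ``metadata_pattern`` (default ``{strain}|{locus}|{end}``);
    an extra trailing ``|X`` field flags a locus absent from that strain.
    Records whose repeats cannot be located are reported with status "NA"
    and excluded, with a warning.
    """
    repeats = BUILTIN_REPEATS if repeats is None else repeats
    regex = _pattern_to_regex(metadata_pattern)
    result = LoadResult()
    n_records = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n_records += 1
        m = regex.fullmatch(rec.id)
        if m is None:
            raise MetadataError(
                f"record '{rec.id}' does not match header pattern '{metadata_pattern}'"
            )
        meta = m.groupdict()
        if meta.pop("absent", None):
            result.statuses[rec.id] = "X"
            continue
        locus = meta["locus"]
        if locus not in repeats:
            raise MetadataError(f"record '{rec.id}': no repeat defined for locus '{locus}'")
        try:
            arr = extract_spacers(
                rec,
                repeats[locus],
                max_mismatches,
                strain=meta["strain"],
                locus=locus,
                end=meta["end"],
            )
        except (UnparseableLocusError, EmptySequenceError) as exc:
            warnings.warn(str(exc), stacklevel=2)
            result.statuses[rec.id] = "NA"
            continue
        result.arrays.append(arr)
        result.statuses[rec.id] = "OK"
    if n_records == 0:
        warnings.warn(f"no records found in {path}", stacklevel=2)
    return result


def spacer_table(arrays: list[SpacerArray]):
    """All spacers as a tidy pandas DataFrame (strain, locus, end, position, sequence, length)."""
    import pandas as pd

    rows = [
        (s.strain, s.locus, s.end, s.position, s.sequence, len(s))
        for arr in arrays
        for s in arr.spacers
    ]
    return pd.DataFrame(rows, columns=["strain", "locus", "end", "position", "sequence", "length"])
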