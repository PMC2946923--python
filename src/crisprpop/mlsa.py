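"""Multi-locus sequence analysis (MLSA) genotyping.

Housekeeping loci are consumed as pre-aligned, equal-length sequences (one
FASTA per locus, headers = strain ids). Alleles at each locus are assigned
by sequence identity: allele 1 is the dominant (most frequent) allele and
any sequence with one or more polymorphisms from it receives its own
number, ordered by decreasing frequency. Strain genotypes are the ordered
allele vectors over all loci; per-strain SNP counts are computed on the
concatenated alignment against a configurable reference strain.

Ambiguous bases: by default N matches anything, so single-read ambiguity
does not split alleles. Identity under that convention is not transitive;
sequences are therefore merged greedily into the most frequent compatible
allele, iterating exact-sequence groups from largest to smallest
(lexicographic sequence order breaking ties), which is deterministic and
permutation-invariant.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "LocusAlignment",
    "AlleleTable",
    "GenotypeProfile",
    "load_locus_alignment",
    "assign_alleles",
    "build_allele_table",
    "concatenate_profiles",
    "epidemic_summary",
    "snp_count",
]

_ALPHABET = set("ACGTN-")


@dataclass
class LocusAlignment:
    """Equal-length sequences for one locus, keyed by strain."""

    locus: str
    sequences: dict[str, str]

    def __post_init__(self) -> None:
        lens = {len(s) for s in self.sequences.values()}
        if len(lens) > 1:
            raise ValueError(f"locus {self.locus}: sequences have unequal lengths {sorted(lens)}")
        bad = {c for s in self.sequences.values() for c in s} - _ALPHABET
        if bad:
            raise ValueError(f"locus {self.locus}: invalid characters {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values()))) if self.sequences else 0


def load_locus_alignment(path, locus: str) -> LocusAlignment:
    """Read one pre-aligned locus FASTA; record ids are strain names."""
    seqs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
    return LocusAlignment(locus=locus, sequences=seqs)


def _compatible(a: str, b: str) -> bool:
    """Sequence identity with N matching any base (gaps must agree)."""
    return all(x == y or x == "N" or y == "N" for x, y in zip(a, b))


@dataclass
class AlleleTable:
    """Allele ids per strain for each locus; allele 1 is the dominant allele."""

    assignments: dict[str, dict[str, int]] = field(default_factory=dict)  # locus -> strain -> id
    allele_seqs: dict[str, dict[int, str]] = field(default_factory=dict)  # locus -> id -> seq

    def loci(self) -> list[str]:
        return list(self.assignments)


def assign_alleles(alignment: LocusAlignment, n_insensitive: bool = True) -> tuple[dict[str, int], dict[int, str]]:
    """Assign allele ids at one locus.

    Returns (strain -> allele id, allele id -> representative sequence).
    Exact-sequence groups are formed first; with ``n_insensitive`` each
    group is then merged into the first already-accepted allele whose
    representative it is compatible with. Allele 1 is the largest group
    (ties broken by lexicographically smallest sequence); the rest are
    numbered by decreasing frequency, then first-seen order.
    """
    if not alignment.sequences:
        raise ValueError("assign_alleles requires at least one strain")
    groups: dict[str, list[str]] = {}
    for strain, seq in alignment.sequences.items():
        groups.setdefault(seq, []).append(strain)
    ordered = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))

    reps: list[str] = []  # representative sequence per accepted allele, pre-numbering
    members: list[list[str]] = []
    for seq, strains in ordered:
        target = None
        if n_insensitive:
            for k, rep in enumerate(reps):
                if _compatible(seq, rep):
                    target = k
                    break
        if target is None:
            reps.append(seq)
            members.append(list(strains))
        else:
            members[target].extend(strains)
            # prefer the representative with fewer ambiguous bases
            if seq.count("N") < reps[target].count("N"):
                reps[target] = seq

    order = sorted(range(len(reps)), key=lambda k: (-len(members[k]), reps[k]))
    strain_to_id: dict[str, int] = {}
    id_to_seq: dict[int, str] = {}
    for new_id, k in enumerate(order, start=1):
        id_to_seq[new_id] = reps[k]
        for strain in members[k]:
            strain_to_id[strain] = new_id
    return strain_to_id, id_to_seq


def build_allele_table(alignments: list[LocusAlignment], n_insensitive: bool = True) -> AlleleTable:
    table = AlleleTable()
    for aln in alignments:
        ids, seqs = assign_alleles(aln, n_insensitive)
        table.assignments[aln.locus] = ids
        table.allele_seqs[aln.locus] = seqs
    return table


def snp_count(a: str, b: str) -> int:
    """Mismatches between equal-length sequences, skipping N/gap columns."""
    if len(a) != len(b):
        raise ValueError("snp_count requires equal-length sequences")
    skip = set("N-")
    return sum(1 for x, y in zip(a, b) if x != y and x not in skip and y not in skip)


@dataclass
class GenotypeProfile:
    """One strain's MLSA genotype: allele vector, concatenation, SNPs vs reference."""

    strain: str
    alleles: tuple[int, ...]
    concatenated: str
    snps_vs_reference: int


def concatenate_profiles(
    table: AlleleTable,
    alignments: list[LocusAlignment],
    locus_order: list[str] | None = None,
    reference: str | None = None,
) -> list[GenotypeProfile]:
    """Concatenate loci into per-strain genotype profiles.

    Strains missing any locus are excluded with a warning. The reference
    strain for SNP counting defaults to the first strain in sorted order;
    SNPs are counted on the concatenation with N and gap columns skipped.
    """
    by_locus = {aln.locus: aln for aln in alignments}
    if locus_order is None:
        locus_order = sorted(by_locus)
    missing = [l for l in locus_order if l not in by_locus]
    if missing:
        raise ValueError(f"alignments missing for loci: {missing}")

    strains = set.intersection(*(set(by_locus[l].sequences) for l in locus_order))
    all_strains = set.union(*(set(by_locus[l].sequences) for l in locus_order))
    for s in sorted(all_strains - strains):
        warnings.warn(f"strain {s} missing at one or more loci; excluded", stacklevel=2)
    if not strains:
        raise ValueError("no strain is present at every locus")

    if reference is None:
        reference = min(strains)
    if reference not in strains:
        raise ValueError(f"reference strain {reference} not present at every locus")

    ref_concat = "".join(by_locus[l].sequences[reference] for l in locus_order)
    profiles = []
    for s in sorted(strains):
        concat = "".join(by_locus[l].sequences[s] for l in locus_order)
        profiles.append(
            GenotypeProfile(
                strain=s,
                alleles=tuple(table.assignments[l][s] for l in locus_order),
                concatenated=concat,
                snps_vs_reference=snp_count(concat, ref_concat),
            )
        )
    return profiles


def epidemic_summary(profiles: list[GenotypeProfile]) -> dict:
    """Genotype table ranked by abundance plus the dominant genotype's share.

    An epidemic population structure shows one dominant clonal genotype
    coexisting with rare recombinant genotypes; the dominant fraction is
    the direct statistic for that regime.
    """
    if not profiles:
        raise ValueError("epidemic_summary requires at least one profile")
    groups: dict[tuple[int, ...], list[str]] = {}
    for p in profiles:
        groups.setdefault(p.alleles, []).append(p.strain)
    ranked = sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    table = [
        {"genotype": list(alleles), "strains": sorted(strains), "count": len(strains)}
        for alleles, strains in ranked
    ]
    return {
        "n_strains": len(profiles),
        "n_genotypes": len(groups),
        "dominant_fraction": table[0]["count"] / len(profiles),
        "genotypes": table,
    }
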