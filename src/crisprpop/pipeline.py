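"""End-to-end orchestration: arrays -> catalog -> comparison -> summaries.

Thin glue over the analysis modules so scripts, tests and the CLI run the
same path: build the spacer catalog, align all same-locus same-end strain
pairs, group strains by shared ancestry per locus, collect loss events and
classify independent-acquisition pairs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

from . import catalog as cat
from .arrays import SpacerArray
from .compare import (
    AcquisitionPair,
    AncestralGroup,
    LossEvent,
    acquisition_end_summary,
    align_all,
    classify_acquisitions,
    detect_losses,
    group_ancestral,
)

__all__ = ["AnalysisResult", "run_analysis"]


@dataclass
class AnalysisResult:
    arrays: list[SpacerArray]
    catalog: cat.SpacerCatalog
    alignments: dict
    groups_by_locus: dict[str, list[AncestralGroup]]
    losses: list[LossEvent]
    pairs: list[AcquisitionPair]
    end_summary: dict = field(default_factory=dict)

    @property
    def acquisition_pairs(self) -> list[AcquisitionPair]:
        return [p for p in self.pairs if not p.excluded]

    @property
    def groups(self) -> list[AncestralGroup]:
        return [g for groups in self.groups_by_locus.values() for g in groups]


def run_analysis(
    arrays: list[SpacerArray],
    min_identity: float = cat.DEFAULT_MIN_IDENTITY,
    min_overlap: int = cat.DEFAULT_MIN_OVERLAP,
    min_run: int = 3,
    leader_depth: int = 10,
) -> AnalysisResult:
    """Run the full spacer-comparison pipeline on extracted arrays."""
    spacers = [s for arr in arrays for s in arr.spacers]
    catalog = cat.build_catalog(spacers, min_identity, min_overlap)
    alignments = align_all(arrays)

    by_locus: dict[str, list[SpacerArray]] = defaultdict(list)
    for arr in arrays:
        by_locus[arr.locus].append(arr)
    groups_by_locus = {
        locus: group_ancestral(arrs, min_run=min_run) for locus, arrs in sorted(by_locus.items())
    }
    all_groups = [g for gs in groups_by_locus.values() for g in gs]

    seen = set()
    losses: list[LossEvent] = []
    for alns in alignments.values():
        for aln in alns:
            for ev in detect_losses(aln):
                key = (ev.strain, ev.locus, ev.left_flank, ev.right_flank, ev.run_length)
                if key not in seen:
                    seen.add(key)
                    losses.append(ev)

    pairs = classify_acquisitions(catalog, all_groups, alignments, leader_depth=leader_depth)
    result = AnalysisResult(
        arrays=arrays,
        catalog=catalog,
        alignments=alignments,
        groups_by_locus=groups_by_locus,
        losses=losses,
        pairs=pairs,
    )
    result.end_summary = acquisition_end_summary(pairs)
    return result
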