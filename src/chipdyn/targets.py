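"""Gene-level target calls: FDR filtering, promoter-window intersection,
knockout-control subtraction, and unions over a time course."""

from __future__ import annotations

from typing import Iterable, Mapping, Sequence

from .io import window_to_genomic
from .types import (
    ChipdynError,
    LookupGeneError,
    Peak,
    PromoterAnnotation,
    SampleKey,
    TargetSet,
)


def peaks_to_genes(
    peaks: Sequence[Peak],
    annotations: Mapping[str, PromoterAnnotation],
    sample: SampleKey,
    fdr_threshold: float,
    flank_bp: int = 4000,
) -> TargetSet:
    """A gene is a target iff one of its peaks passes the FDR threshold and
    its genomic span intersects the promoter window [tss−flank, tss+flank).

    The FDR cut is inclusive (fdr <= threshold); a single base of overlap
    with the half-open promoter window suffices.
    """
    genes: set[str] = set()
    for peak in peaks:
        ann = annotations.get(peak.gene_id)
        if ann is None:
            raise LookupGeneError(f"peak gene {peak.gene_id!r} not in annotations")
        if peak.gene_id in genes:
            continue
        if not peak.fdr <= fdr_threshold:  # NaN-safe: NaN fails
            continue
        gstart, gend = window_to_genomic(peak.start, peak.end, ann)
        wstart, wend = ann.tss - flank_bp, ann.tss + flank_bp
        if gstart < wend and wstart < gend:
            genes.add(peak.gene_id)
    return TargetSet.from_sample(sample, genes)


def subtract_knockout_control(wt: TargetSet, ko: TargetSet) -> TargetSet:
    """Remove targets also called in the knockout (antibody-specificity) control."""
    if wt.factor != ko.factor or wt.timepoint_label != ko.timepoint_label:
        raise ChipdynError(
            f"control subtraction needs matching factor and timepoint, got "
            f"{wt.factor}@{wt.timepoint_label} vs {ko.factor}@{ko.timepoint_label}"
        )
    return TargetSet(wt.factor, wt.genotype, wt.timepoint_label, wt.genes - ko.genes)


def union_over_timepoints(sets: Iterable[TargetSet]) -> TargetSet:
    """Union of per-timepoint target sets for one factor/genotype; the result
    carries timepoint label "any" (genes bound at >= 1 timepoint)."""
    sets = list(sets)
    if not sets:
        raise ChipdynError("union_over_timepoints needs at least one set")
    factor, genotype = sets[0].factor, sets[0].genotype
    for ts in sets[1:]:
        if ts.factor != factor or ts.genotype != genotype:
            raise ChipdynError("all sets in a union must share factor and genotype")
    genes: frozenset[str] = frozenset().union(*(ts.genes for ts in sets))
    return TargetSet(factor, genotype, "any", genes)
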