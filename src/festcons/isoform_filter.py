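"""Evidence filters applied to assembled isoforms before event calling.

Two filters are applied per gene, in two passes:

1. *Junction support* — an isoform is discarded if any of its splice
   junctions is supported by fewer than ``min_junction_reads`` reads
   (default 2).  Junctions absent from the support table count as zero.
2. *Retained-intron coverage* — against the survivors of pass 1, an isoform
   that exonically spans (retains) an intron of a kept sibling isoform is
   discarded if the retained region's median per-base depth is below
   ``min_retained_depth`` (default 2).

The two-pass order resolves the circularity between "sibling" and "kept":
retention is only evaluated against introns of isoforms that themselves
passed the junction filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .annotation_io import GeneModel, JunctionSupport, TranscriptIsoform

logger = logging.getLogger(__name__)

WEAK_JUNCTION = "weak-junction"
WEAK_RETAINED_INTRON = "weak-retained-intron"

__all__ = ["FilterReport", "filter_isoforms", "select_expressed_multiexonic"]


@dataclass
class FilterReport:
    """Outcome of filtering one gene's isoforms."""

    gene_id: str
    kept: list[str] = field(default_factory=list)
    dropped: dict[str, str] = field(default_factory=dict)

    def kept_isoforms(self, gene: GeneModel) -> list[TranscriptIsoform]:
        keep = set(self.kept)
        return [iso for iso in gene.isoforms if iso.isoform_id in keep]


def _retains(retainer: TranscriptIsoform, intron: tuple[int, int]) -> bool:
    # retained = the intron plus at least one flanking base lies inside one exon
    s, e = intron
    return any(a < s and e < b for a, b in retainer.exons)


def filter_isoforms(
    gene: GeneModel,
    support: JunctionSupport,
    min_junction_reads: int = 2,
    min_retained_depth: float = 2.0,
) -> FilterReport:
    report = FilterReport(gene_id=gene.gene_id)
    chrom, strand = gene.chromosome, gene.strand

    survivors: list[TranscriptIsoform] = []
    for iso in gene.isoforms:
        weak = [
            intron
            for intron in iso.introns
            if support.junction_reads(chrom, *intron, strand) < min_junction_reads
        ]
        if weak:
            report.dropped[iso.isoform_id] = WEAK_JUNCTION
            logger.info(
                "%s: dropped (%s) — junction(s) %s under %d reads",
                iso.isoform_id, WEAK_JUNCTION, weak, min_junction_reads,
            )
        else:
            survivors.append(iso)

    sibling_introns = {
        intron for iso in survivors for intron in iso.introns
    }
    for iso in survivors:
        weak_retained = [
            intron
            for intron in sibling_introns
            if intron not in iso.introns
            and _retains(iso, intron)
            and support.retained_depth(chrom, *intron, strand) < min_retained_depth
        ]
        if weak_retained:
            report.dropped[iso.isoform_id] = WEAK_RETAINED_INTRON
            logger.info(
                "%s: dropped (%s) — retained region(s) %s under depth %.1f",
                iso.isoform_id, WEAK_RETAINED_INTRON, weak_retained,
                min_retained_depth,
            )
        else:
            report.kept.append(iso.isoform_id)
    return report


def select_expressed_multiexonic(
    genes: list[GeneModel],
    reports: dict[str, FilterReport],
) -> list[GeneModel]:
    """Genes with >=1 kept isoform and >=1 multi-exon isoform.

    This set is the denominator "expressed multi-exonic protein-coding
    genes" used by all downstream percentage summaries.
    """
    out = []
    for gene in genes:
        report = reports.get(gene.gene_id)
        if report is None or not report.kept:
            continue
        if gene.is_multi_exonic:
            out.append(gene)
    return out
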