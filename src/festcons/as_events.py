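"""Calling the four alternative-splicing event types from isoform pairs.

Events are detected by pairwise comparison of transcript isoforms of one
gene.  In genomic coordinates (0-based half-open; the *donor* of an intron
is its genomic start on the plus strand and its genomic end on the minus
strand):

* **IntronR** — an intron of one isoform lies strictly inside an exon of the
  other (the intron is retained).
* **AltD / AltA** — two overlapping introns, one per isoform, share one
  boundary and differ at the other; the region between the two differing
  boundaries must be exonic in the isoform carrying the shorter intron.
  Whether the differing side is the donor or the acceptor depends on strand.
* **ExonS** — an intron of one isoform spans one or more complete exons of
  the other, and both of its boundaries coincide with intron boundaries of
  the other isoform; a run of consecutively skipped exons is a single event
  keyed by the outer junctions.
* **AltDA** — an overlapping intron pair differing at *both* boundaries
  (simultaneous alternative 5' and 3' splice sites).  Pairwise comparison
  first emits provisional AltD and AltA records for such pairs;
  :func:`reclassify_dual_events` merges each co-located provisional pair
  into a single AltDA event.  AltDA events are tabulated separately and are
  excluded from the four per-type conservation databases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Sequence

from .annotation_io import GeneModel, TranscriptIsoform

ALTD = "AltD"
ALTA = "AltA"
EXONS = "ExonS"
INTRONR = "IntronR"
ALTDA = "AltDA"

EVENT_TYPES = (ALTD, ALTA, EXONS, INTRONR)  # the four tallied types

__all__ = [
    "ASEvent",
    "EVENT_TYPES",
    "ALTD", "ALTA", "EXONS", "INTRONR", "ALTDA",
    "compare_isoform_pair",
    "reclassify_dual_events",
    "collect_gene_events",
]


@dataclass(frozen=True)
class ASEvent:
    """One typed alternative-splicing event at a gene locus.

    ``junctions`` is type-specific, always in ascending genomic order:

    - IntronR: ``(intron_start, intron_end)``
    - AltD/AltA with shared boundary: the two alternative boundaries
      followed by the shared boundary, i.e. ``(alt_a, alt_b, common)``
      when the alternatives are genomically left of the shared boundary,
      else ``(common, alt_a, alt_b)``
    - ExonS: ``(outer_donor_side, outer_acceptor_side)`` = the skipping
      intron's bounds; the skipped exon intervals ride along in
      ``skipped_exons`` but do not enter the identity key
    - AltDA: ``(start_a, end_a, start_b, end_b)`` — both introns
    """

    species: str
    gene_id: str
    chromosome: str
    strand: str
    event_type: str
    junctions: tuple[int, ...]
    skipped_exons: tuple[tuple[int, int], ...] = field(default=(), compare=False)
    witnesses: tuple[str, str] = field(default=("", ""), compare=False)
    provisional: bool = field(default=False, compare=False)

    @property
    def key(self) -> tuple:
        return (self.gene_id, self.event_type, self.junctions)

    @property
    def event_id(self) -> str:
        coords = "-".join(str(p) for p in self.junctions)
        return f"{self.species}|{self.gene_id}|{self.event_type}|{coords}"


def _check_pair(iso1: TranscriptIsoform, iso2: TranscriptIsoform) -> None:
    if (
        iso1.gene_id != iso2.gene_id
        or iso1.chromosome != iso2.chromosome
        or iso1.strand != iso2.strand
    ):
        raise ValueError(
            f"isoforms {iso1.isoform_id}/{iso2.isoform_id} are not comparable "
            "(different gene, chromosome or strand)"
        )


def _intron_retention(
    a: TranscriptIsoform, b: TranscriptIsoform
) -> Iterable[tuple[int, int]]:
    """Introns of `a` strictly contained in an exon of `b`."""
    for s, e in a.introns:
        if any(xs < s and e < xe for xs, xe in b.exons):
            yield (s, e)


def _exon_skipping(a: TranscriptIsoform, b: TranscriptIsoform):
    """Skipping introns of `a` spanning complete exons of `b`."""
    b_intron_starts = {s for s, _ in b.introns}
    b_intron_ends = {e for _, e in b.introns}
    for s, e in a.introns:
        if s not in b_intron_starts or e not in b_intron_ends:
            continue
        skipped = tuple(x for x in b.exons if s <= x[0] and x[1] <= e)
        if skipped:
            yield (s, e), skipped


def compare_isoform_pair(
    iso1: TranscriptIsoform, iso2: TranscriptIsoform
) -> list[ASEvent]:
    """Raw (pre-reclassification) events implied by one isoform pair.

    Symmetric in its arguments.  Overlapping intron pairs that differ at
    both boundaries yield *provisional* AltD and AltA records which
    :func:`reclassify_dual_events` merges into AltDA.
    """
    _check_pair(iso1, iso2)
    species, gene = iso1.species, iso1.gene_id
    chrom, strand = iso1.chromosome, iso1.strand
    witnesses = (iso1.isoform_id, iso2.isoform_id)

    def make(event_type, junctions, skipped=(), provisional=False):
        return ASEvent(
            species=species, gene_id=gene, chromosome=chrom, strand=strand,
            event_type=event_type, junctions=tuple(junctions),
            skipped_exons=tuple(skipped), witnesses=witnesses,
            provisional=provisional,
        )

    events: list[ASEvent] = []

    for a, b in ((iso1, iso2), (iso2, iso1)):
        for intron in _intron_retention(a, b):
            events.append(make(INTRONR, intron))
        for (s, e), skipped in _exon_skipping(a, b):
            events.append(make(EXONS, (s, e), skipped=skipped))

    # Overlapping intron pairs -> alternative donor/acceptor sites.
    # On the plus strand the genomic-start side is the donor side; on the
    # minus strand it is the acceptor side.
    start_side_type = ALTD if strand == "+" else ALTA
    end_side_type = ALTA if strand == "+" else ALTD
    for i1 in iso1.introns:
        for i2 in iso2.introns:
            if i1 == i2 or i1[0] >= i2[1] or i2[0] >= i1[1]:
                continue
            p, q = sorted((i1, i2))
            start_differs = p[0] != q[0]
            end_differs = p[1] != q[1]
            start_ok = end_ok = False
            if start_differs:
                # region between the two starts must be exonic in the
                # isoform carrying the later-starting intron q
                carrier_q = iso1 if q == i1 else iso2
                start_ok = carrier_q.exonic(p[0], q[0])
            if end_differs:
                # region between the two ends: exonic in the carrier of the
                # earlier-ending intron (not necessarily p when nested)
                lo = p if p[1] < q[1] else q
                carrier_lo = iso1 if lo == i1 else iso2
                end_ok = carrier_lo.exonic(min(p[1], q[1]), max(p[1], q[1]))

            if start_differs and not end_differs:
                if start_ok:
                    events.append(
                        make(start_side_type, (p[0], q[0], p[1]))
                    )
            elif end_differs and not start_differs:
                if end_ok:
                    events.append(
                        make(end_side_type, (p[0], p[1], q[1]))
                    )
            elif start_differs and end_differs:
                dual = p + q
                if start_ok:
                    events.append(make(start_side_type, dual, provisional=True))
                if end_ok:
                    events.append(make(end_side_type, dual, provisional=True))
    return events


def reclassify_dual_events(raw: Sequence[ASEvent]) -> list[ASEvent]:
    """Merge provisional alternative-donor/acceptor pairs into AltDA.

    A provisional AltD and AltA describing the same two introns (no shared
    boundary) become one AltDA event.  A provisional record whose partner
    side did not qualify (its between-boundary region was not exonic in the
    sibling isoform) describes no well-formed event and is discarded.
    Complete events pass through unchanged.
    """
    out: list[ASEvent] = []
    pending: dict[tuple, dict[str, ASEvent]] = {}
    for ev in raw:
        if not ev.provisional:
            out.append(ev)
            continue
        pending.setdefault(ev.junctions, {})[ev.event_type] = ev
    for junctions, sides in pending.items():
        if ALTD in sides and ALTA in sides:
            template = sides[ALTD]
            out.append(
                ASEvent(
                    species=template.species, gene_id=template.gene_id,
                    chromosome=template.chromosome, strand=template.strand,
                    event_type=ALTDA, junctions=junctions,
                    witnesses=template.witnesses,
                )
            )
    return out


def collect_gene_events(
    gene: GeneModel,
    kept_isoforms: Sequence[TranscriptIsoform] | None = None,
) -> list[ASEvent]:
    """Deduplicated events over all pairs of (kept) isoforms of one gene.

    Events are keyed by ``(gene, event_type, junctions)``; the recorded
    witnesses are those of the first pair (in deterministic isoform order)
    supporting the event.  Output is sorted by coordinates.
    """
    isoforms = list(kept_isoforms) if kept_isoforms is not None else list(gene.isoforms)
    isoforms.sort(key=lambda i: i.isoform_id)
    seen: dict[tuple, ASEvent] = {}
    for a, b in combinations(isoforms, 2):
        for ev in reclassify_dual_events(compare_isoform_pair(a, b)):
            seen.setdefault(ev.key, ev)
    return sorted(seen.values(), key=lambda e: (e.junctions, e.event_type))
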