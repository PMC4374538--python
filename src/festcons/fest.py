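"""Flanking exon sequence tags (FESTs) for alternative-splicing events.

A FEST is 30-300 bp of exonic sequence immediately flanking the alternative
junctions of an event, taken from sequence exonic in *both* witness isoforms
(outside the variable region) so that cross-species tag matching reflects
the junction context rather than the variant region.  Tags are oriented on
the transcribed strand and numbered 1 (transcript-downstream of the
junction) and 2 (transcript-upstream).

For each event the two genomic anchor junctions are, left to right:

- IntronR / ExonS: the (outer) intron bounds;
- AltD on plus / AltA on minus: the transcript-proximal alternative
  boundary and the shared boundary;
- AltA on plus / AltD on minus: the shared boundary and the distal
  alternative boundary.

The left tag ends at the left anchor, the right tag begins at the right
anchor; each is truncated to ``max_len`` bp nearest its junction, and the
event is dropped from conservation analysis (with a log entry) if either
tag would be shorter than ``min_len`` bp.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from Bio.Seq import reverse_complement

from .annotation_io import GenomeStore, GeneModel, TranscriptIsoform
from .as_events import ALTDA, ASEvent

logger = logging.getLogger(__name__)

MIN_FEST_LEN = 30
MAX_FEST_LEN = 300

__all__ = [
    "FEST",
    "MIN_FEST_LEN",
    "MAX_FEST_LEN",
    "extract_fests",
    "fest_id",
    "parse_fest_id",
    "write_fest_fasta",
    "read_fest_fasta",
]


@dataclass(frozen=True)
class FEST:
    """One flanking exon sequence tag of one event."""

    event_ref: str            # the event id this tag belongs to
    fest_number: int          # 1 = transcript-downstream, 2 = upstream
    sequence: str             # transcribed-strand orientation
    chromosome: str
    interval: tuple[int, int]  # genomic, 0-based half-open

    def __post_init__(self) -> None:
        if self.fest_number not in (1, 2):
            raise ValueError("fest_number must be 1 or 2")
        n = len(self.sequence)
        if not (MIN_FEST_LEN <= n <= MAX_FEST_LEN):
            raise ValueError(f"FEST length {n} outside [{MIN_FEST_LEN},{MAX_FEST_LEN}]")


def _anchors(event: ASEvent) -> tuple[int, int]:
    j = event.junctions
    if event.event_type == ALTDA:
        return j[0], max(j[1], j[3])
    return j[0], j[-1]


def _exon_covering(iso: TranscriptIsoform, pos: int) -> tuple[int, int] | None:
    for s, e in iso.exons:
        if s <= pos < e:
            return (s, e)
    return None


def extract_fests(
    event: ASEvent,
    gene: GeneModel,
    genome: GenomeStore,
    max_len: int = MAX_FEST_LEN,
    min_len: int = MIN_FEST_LEN,
) -> tuple[FEST, FEST] | None:
    """Extract the (upstream FEST2, downstream FEST1) pair for an event.

    Returns ``None`` (and logs the reason) when either flanking tag would
    be shorter than ``min_len`` after intersecting the witness isoforms'
    exons.  Raises if the event's junctions fall outside the gene span.
    """
    iso_by_id = {i.isoform_id: i for i in gene.isoforms}
    try:
        w1, w2 = (iso_by_id[w] for w in event.witnesses)
    except KeyError as exc:
        raise ValueError(f"witness isoform {exc} not found in gene {gene.gene_id}")
    left, right = _anchors(event)
    span_lo = min(w1.span[0], w2.span[0])
    span_hi = max(w1.span[1], w2.span[1])
    if left < span_lo or right > span_hi:
        raise ValueError(
            f"{event.event_id}: junctions ({left},{right}) outside gene span"
        )

    # common exonic region ending at the left anchor
    lx1 = _exon_covering(w1, left - 1)
    lx2 = _exon_covering(w2, left - 1)
    # common exonic region starting at the right anchor
    rx1 = _exon_covering(w1, right)
    rx2 = _exon_covering(w2, right)
    if None in (lx1, lx2, rx1, rx2):
        logger.info(
            "%s: dropped (no-common-flank) — a witness lacks exonic sequence "
            "at a junction", event.event_id,
        )
        return None
    left_start = max(lx1[0], lx2[0], left - max_len)
    right_end = min(rx1[1], rx2[1], right + max_len)
    if left - left_start < min_len or right_end - right < min_len:
        logger.info(
            "%s: dropped (below-min-fest) — flank lengths %d/%d under %d bp",
            event.event_id, left - left_start, right_end - right, min_len,
        )
        return None

    left_seq = genome.fetch(event.chromosome, left_start, left)
    right_seq = genome.fetch(event.chromosome, right, right_end)
    if event.strand == "+":
        upstream = FEST(event.event_id, 2, left_seq, event.chromosome,
                        (left_start, left))
        downstream = FEST(event.event_id, 1, right_seq, event.chromosome,
                          (right, right_end))
    else:
        upstream = FEST(event.event_id, 2, reverse_complement(right_seq),
                        event.chromosome, (right, right_end))
        downstream = FEST(event.event_id, 1, reverse_complement(left_seq),
                          event.chromosome, (left_start, left))
    return upstream, downstream


def fest_id(fest: FEST) -> str:
    """Deterministic parseable tag: ``species|gene|type|coords|festN``."""
    return f"{fest.event_ref}|fest{fest.fest_number}"


def parse_fest_id(tag: str) -> dict[str, str | int]:
    species, gene, event_type, coords, fest_n = tag.rsplit("|", 4)[-5:]
    if not fest_n.startswith("fest"):
        raise ValueError(f"malformed FEST tag {tag!r}")
    return {
        "species": species,
        "gene_id": gene,
        "event_type": event_type,
        "coords": coords,
        "fest_number": int(fest_n[4:]),
    }


def write_fest_fasta(fests: Iterable[FEST], path: str | Path) -> None:
    """Write one event-type database as FASTA with fest_id headers."""
    with open(path, "w") as fh:
        for fest in fests:
            fh.write(f">{fest_id(fest)}\n{fest.sequence}\n")


def read_fest_fasta(path: str | Path) -> list[FEST]:
    fests = []
    with open(path) as fh:
        header, chunks = None, []
        for line in list(fh) + [">"]:
            line = line.strip()
            if line.startswith(">"):
                if header is not None:
                    meta = parse_fest_id(header)
                    fests.append(
                        FEST(
                            event_ref=header.rsplit("|", 1)[0],
                            fest_number=int(meta["fest_number"]),
                            sequence="".join(chunks),
                            chromosome="",
                            interval=(0, 0),
                        )
                    )
                header, chunks = line[1:], []
            elif line:
                chunks.append(line)
    return fests
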