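"""Summary tables: per-species event tallies and conservation breakdowns.

All percentages are rounded half-away-from-zero to the printed precision of
the corresponding table (one decimal for per-species event summaries,
integers for conserved-event summaries).  The per-species denominator is
always the count of expressed multi-exonic protein-coding genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .annotation_io import GeneModel
from .as_events import ALTA, ALTD, EVENT_TYPES, EXONS, INTRONR, ASEvent
from .conservation import ConservedEventCluster

__all__ = [
    "SpeciesSummary",
    "ConservationSummary",
    "round_half_away",
    "pct",
    "summarize_species",
    "summarize_conservation",
    "genes_with_conserved_events",
    "family_summary",
]


def round_half_away(value: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention used by the tables here)."""
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def pct(part: float, whole: float, decimals: int = 1) -> float:
    """Percentage with half-away-from-zero rounding; errors on zero whole."""
    if whole == 0:
        raise ZeroDivisionError("percentage with zero denominator")
    return round_half_away(100.0 * part / whole, decimals)


@dataclass
class SpeciesSummary:
    """Event and gene tallies of one species, per event type.

    ``table`` rows are the four event types plus ``Total``; columns are
    events, event_pct, genes, gene_pct.  ``denominator`` is the expressed
    multi-exonic gene count.
    """

    species: str
    table: pd.DataFrame
    denominator: int


@dataclass
class ConservationSummary:
    """Cluster counts stratified by number of distinct species.

    ``table`` rows are species-count strata (2..max); columns the four
    event types, ``Total`` and ``Total_pct``.
    """

    table: pd.DataFrame


def summarize_species(
    species: str,
    events: Sequence[ASEvent],
    expressed_multiexonic_genes: Sequence[GeneModel],
) -> SpeciesSummary:
    """Per-type event counts/percentages and gene counts/percentages.

    Event percentages are relative to the species' total events; gene
    percentages to the expressed multi-exonic denominator.  AltDA events
    are excluded from the four-type tally.
    """
    denominator = len(expressed_multiexonic_genes)
    if denominator == 0:
        raise ZeroDivisionError("no expressed multi-exonic genes")
    events = [e for e in events if e.event_type in EVENT_TYPES]
    total_events = len(events)
    rows = {}
    genes_with_as = {e.gene_id for e in events}
    for etype in EVENT_TYPES:
        typed = [e for e in events if e.event_type == etype]
        genes = {e.gene_id for e in typed}
        rows[etype] = {
            "events": len(typed),
            "event_pct": pct(len(typed), total_events) if total_events else 0.0,
            "genes": len(genes),
            "gene_pct": pct(len(genes), denominator),
        }
    rows["Total"] = {
        "events": total_events,
        "event_pct": 100.0 if total_events else 0.0,
        "genes": len(genes_with_as),
        "gene_pct": pct(len(genes_with_as), denominator),
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    return SpeciesSummary(species=species, table=table, denominator=denominator)


def summarize_conservation(
    clusters: Sequence[ConservedEventCluster],
) -> ConservationSummary:
    """Stratify clusters by the number of distinct species they span."""
    if clusters:
        max_n = max(c.n_species for c in clusters)
    else:
        max_n = 2
    total = len(clusters)
    rows = {}
    for n in range(2, max_n + 1):
        stratum = [c for c in clusters if c.n_species == n]
        row = {
            etype: sum(1 for c in stratum if c.event_type == etype)
            for etype in EVENT_TYPES
        }
        row["Total"] = len(stratum)
        row["Total_pct"] = pct(len(stratum), total) if total else 0.0
        rows[n] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "n_species"
    return ConservationSummary(table=table)


def genes_with_conserved_events(
    clusters: Sequence[ConservedEventCluster],
    denominators: Mapping[str, int],
) -> pd.DataFrame:
    """Distinct genes per species and type in multi-species clusters.

    A gene is counted once per event type when it appears in at least one
    cluster spanning at least one other species.  Rows are the four event
    types plus ``Total`` (distinct genes over all types) and ``Total_pct``
    (relative to each species' expressed multi-exonic denominator).
    """
    species = sorted(denominators)
    per_type: dict[str, dict[str, set]] = {
        etype: {sp: set() for sp in species} for etype in EVENT_TYPES
    }
    overall: dict[str, set] = {sp: set() for sp in species}
    for cl in clusters:
        if cl.n_species < 2:
            continue
        for sp, gene in cl.genes:
            if sp in overall:
                per_type[cl.event_type][sp].add(gene)
                overall[sp].add(gene)
    rows = {}
    for etype in EVENT_TYPES:
        rows[etype] = {sp: len(per_type[etype][sp]) for sp in species}
        rows[etype]["Total"] = sum(rows[etype][sp] for sp in species)
    rows["Total"] = {sp: len(overall[sp]) for sp in species}
    rows["Total"]["Total"] = sum(len(overall[sp]) for sp in species)
    rows["Total_pct"] = {
        sp: pct(len(overall[sp]), denominators[sp]) for sp in species
    }
    rows["Total_pct"]["Total"] = float("nan")
    return pd.DataFrame.from_dict(rows, orient="index")


def family_summary(
    clusters: Sequence[ConservedEventCluster],
    events: Mapping[tuple[str, str], Sequence[ASEvent]],
    family_membership: Mapping[str, Iterable[tuple[str, str]]],
    expressed_multiexonic: set[tuple[str, str]],
    outgroup_species: str | None = None,
) -> pd.DataFrame:
    """Per-gene-family splicing and conservation statistics.

    For each family: expressed multi-exonic members, members with at least
    one event (count and percentage), conserved events spanning >= 2
    species, and conserved events including a designated outgroup taxon.
    Family genes absent from the annotation are excluded with a warning.
    """
    import logging

    logger = logging.getLogger(__name__)
    rows = {}
    for family, members in family_membership.items():
        members = list(members)
        known = [m for m in members if m in expressed_multiexonic or m in events]
        missing = [m for m in members if m not in known]
        if missing:
            logger.warning(
                "family %s: %d member(s) absent from annotation, excluded",
                family, len(missing),
            )
        expressed = [m for m in known if m in expressed_multiexonic]
        with_as = [m for m in expressed if events.get(m)]
        member_set = set(known)
        fam_clusters = [
            c for c in clusters
            if c.n_species >= 2 and (c.genes & member_set)
        ]
        with_outgroup = [
            c for c in fam_clusters
            if outgroup_species is not None and outgroup_species in c.species_set
        ]
        rows[family] = {
            "expressed_multiexonic": len(expressed),
            "with_as": len(with_as),
            "with_as_pct": (
                pct(len(with_as), len(expressed)) if expressed else 0.0
            ),
            "conserved_clusters": len(fam_clusters),
            "conserved_with_outgroup": len(with_outgroup),
        }
    return pd.DataFrame.from_dict(rows, orient="index")
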