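"""AS-event conservation categories in whole-genome-duplication ortholog sets.

A WGD ortholog set is one singleton gene in a diploid-like species paired
with its two homeologous orthologs in a species that underwent a recent WGD
(e.g. one common-bean gene : two soybean genes).  Each splicing event found
in the set's three genes receives exactly one of five categories describing
which genes share it as a conserved event *within the triplet*:

===========  ======================================================
``1:2``      clustered across the singleton and both duplicates
``1:1``      clustered across the singleton and exactly one duplicate
``0:2``      clustered across both duplicates only
``1:0``      unclustered event of the singleton
``0:1``      unclustered event of one duplicate
===========  ======================================================

Conservation with species outside the triplet does not affect the category
(an event conserved only with a third species still counts as 1:0/0:1); it
enters only through :func:`outgroup_rescue`, which asks how many
duplicate-only (0:2) events are nevertheless conserved in at least one
outgroup species and may therefore represent losses in the singleton
lineage rather than post-divergence gains.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .annotation_io import GeneModel, OrthogroupTable
from .as_events import ASEvent
from .conservation import (
    ConservationConfig,
    ConservedEventCluster,
    cluster_conserved_events,
)
from .fest import FEST
from .isoform_filter import FilterReport

CATEGORIES = ("1:2", "1:1", "0:2", "1:0", "0:1")

__all__ = [
    "WGDOrthologSet",
    "WGDCategoryAssignment",
    "CATEGORIES",
    "read_wgd_sets",
    "write_wgd_sets",
    "select_eligible_sets",
    "classify_wgd_events",
    "outgroup_rescue",
]


@dataclass(frozen=True)
class WGDOrthologSet:
    """One singleton gene and the duplicate gene pair orthologous to it."""

    set_id: str
    singleton: tuple[str, str]                  # (species, gene_id)
    duplicates: tuple[tuple[str, str], tuple[str, str]]

    def __post_init__(self) -> None:
        sp = {s for s, _ in self.duplicates}
        if len(sp) != 1:
            raise ValueError(f"{self.set_id}: duplicate pair spans two species")
        if self.singleton[0] == next(iter(sp)):
            raise ValueError(f"{self.set_id}: singleton from the duplicate species")

    @property
    def genes(self) -> tuple[tuple[str, str], ...]:
        return (self.singleton, *self.duplicates)


@dataclass(frozen=True)
class WGDCategoryAssignment:
    """One clustered or solo event of a WGD set with its category."""

    set_id: str
    category: str
    event_ids: tuple[str, ...]      # all member events within the triplet
    genes: frozenset[tuple[str, str]]
    event_type: str


def read_wgd_sets(tsv) -> list[WGDOrthologSet]:
    """Read a WGD set table: set_id, sp1|gene, sp2|geneA, sp2|geneB rows."""
    sets = []
    with open(tsv) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            set_id, single, dup1, dup2 = line.split("\t")
            parse = lambda tok: tuple(tok.split("|", 1))
            sets.append(
                WGDOrthologSet(set_id, parse(single), (parse(dup1), parse(dup2)))
            )
    return sets


def write_wgd_sets(sets: Sequence[WGDOrthologSet], path) -> None:
    with open(path, "w") as fh:
        for s in sets:
            d1, d2 = s.duplicates
            fh.write(
                f"{s.set_id}\t{s.singleton[0]}|{s.singleton[1]}\t"
                f"{d1[0]}|{d1[1]}\t{d2[0]}|{d2[1]}\n"
            )


def select_eligible_sets(
    sets: Sequence[WGDOrthologSet],
    genes: Mapping[tuple[str, str], GeneModel],
    reports: Mapping[tuple[str, str], FilterReport],
    events: Mapping[tuple[str, str], Sequence[ASEvent]],
) -> list[WGDOrthologSet]:
    """Sets where all members are expressed, >=1 member is multi-exonic and
    the three genes carry at least one splicing event in total."""
    eligible = []
    for s in sets:
        expressed = all(
            key in reports and reports[key].kept for key in s.genes
        )
        if not expressed:
            continue
        if not any(
            key in genes and genes[key].is_multi_exonic for key in s.genes
        ):
            continue
        if not any(events.get(key) for key in s.genes):
            continue
        eligible.append(s)
    return eligible


def classify_wgd_events(
    wgd_set: WGDOrthologSet,
    events: Mapping[tuple[str, str], Sequence[ASEvent]],
    fests: Mapping[str, tuple[FEST, FEST]],
    config: ConservationConfig | None = None,
) -> list[WGDCategoryAssignment]:
    """Categorise every event of the set's three genes.

    Conservation is evaluated within the triplet only: the three genes are
    clustered as a private orthogroup and each resulting cluster (or
    unclustered solo event) is assigned its category from which genes carry
    it.  The assignments partition the set's events.
    """
    triplet_events = [
        ev for key in wgd_set.genes for ev in events.get(key, ())
    ]
    private_og = OrthogroupTable(groups={wgd_set.set_id: set(wgd_set.genes)})
    clusters = cluster_conserved_events(triplet_events, fests, private_og, config)

    singleton = wgd_set.singleton
    dup_set = set(wgd_set.duplicates)
    assignments: list[WGDCategoryAssignment] = []
    clustered_ids: set[str] = set()
    for cl in clusters:
        clustered_ids.update(cl.members)
        has_single = singleton in cl.genes
        n_dups = len(cl.genes & dup_set)
        if has_single and n_dups == 2:
            cat = "1:2"
        elif has_single and n_dups == 1:
            cat = "1:1"
        elif not has_single and n_dups == 2:
            cat = "0:2"
        else:  # pragma: no cover - a cluster needs >= 2 distinct genes
            raise AssertionError("cluster with fewer than two triplet genes")
        assignments.append(
            WGDCategoryAssignment(
                set_id=wgd_set.set_id, category=cat, event_ids=cl.members,
                genes=cl.genes, event_type=cl.event_type,
            )
        )
    for ev in triplet_events:
        if ev.event_id in clustered_ids:
            continue
        owner = (ev.species, ev.gene_id)
        cat = "1:0" if owner == singleton else "0:1"
        assignments.append(
            WGDCategoryAssignment(
                set_id=wgd_set.set_id, category=cat,
                event_ids=(ev.event_id,), genes=frozenset([owner]),
                event_type=ev.event_type,
            )
        )
    return assignments


def outgroup_rescue(
    zero_two: Sequence[WGDCategoryAssignment],
    global_clusters: Sequence[ConservedEventCluster],
    pair_species: frozenset[str] | set[str],
) -> tuple[float, list[bool]]:
    """Fraction of duplicate-only (0:2) events conserved in an outgroup.

    For each 0:2 assignment, checks whether any global multi-species
    cluster containing one of its member events also contains a species
    outside ``pair_species`` (the singleton + duplicate species pair).
    Returns the fraction and the per-assignment flags.
    """
    membership: dict[str, ConservedEventCluster] = {}
    for cl in global_clusters:
        for member in cl.members:
            membership[member] = cl
    flags = []
    for assignment in zero_two:
        if assignment.category != "0:2":
            raise ValueError("outgroup_rescue expects 0:2 assignments only")
        rescued = any(
            bool(membership[eid].species_set - set(pair_species))
            for eid in assignment.event_ids
            if eid in membership
        )
        flags.append(rescued)
    fraction = sum(flags) / len(flags) if flags else 0.0
    return fraction, flags
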