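"""End-to-end orchestration: files in, conserved-event clusters out.

Thin glue over the per-stage modules, used by the command-line interface,
the test-suite and downstream summaries.  Expects the on-disk layout the
fixture generator produces: per species ``{sp}.fasta``, ``{sp}.gtf``,
``{sp}.junctions.tsv``, ``{sp}.coverage.tsv`` plus ``orthogroups.tsv``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from . import annotation_io as aio
from .as_events import ALTDA, ASEvent, collect_gene_events
from .conservation import (
    ConservationConfig,
    ConservedEventCluster,
    cluster_conserved_events,
)
from .fest import FEST, extract_fests
from .isoform_filter import FilterReport, filter_isoforms, select_expressed_multiexonic

__all__ = ["SpeciesData", "PipelineResult", "load_species", "run_species", "run_pipeline"]


@dataclass
class SpeciesData:
    species: str
    genome: aio.GenomeStore
    genes: list[aio.GeneModel]
    support: aio.JunctionSupport


@dataclass
class PipelineResult:
    species: list[str]
    genes: dict[tuple[str, str], aio.GeneModel] = field(default_factory=dict)
    reports: dict[tuple[str, str], FilterReport] = field(default_factory=dict)
    expressed_multiexonic: dict[str, list[aio.GeneModel]] = field(default_factory=dict)
    events: dict[tuple[str, str], list[ASEvent]] = field(default_factory=dict)
    fests: dict[str, tuple[FEST, FEST]] = field(default_factory=dict)
    clusters: list[ConservedEventCluster] = field(default_factory=list)

    def all_events(self, include_altda: bool = False) -> list[ASEvent]:
        out = [
            ev
            for evs in self.events.values()
            for ev in evs
            if include_altda or ev.event_type != ALTDA
        ]
        return sorted(out, key=lambda e: e.event_id)

    def species_events(self, species: str) -> list[ASEvent]:
        return [e for e in self.all_events() if e.species == species]


def load_species(datadir: str | Path, species: str) -> SpeciesData:
    datadir = Path(datadir)
    return SpeciesData(
        species=species,
        genome=aio.read_genome(datadir / f"{species}.fasta", species),
        genes=aio.read_gene_models(datadir / f"{species}.gtf", species),
        support=aio.read_junction_support(
            datadir / f"{species}.junctions.tsv",
            datadir / f"{species}.coverage.tsv",
            species,
        ),
    )


def run_species(
    data: SpeciesData,
    result: PipelineResult,
    min_junction_reads: int = 2,
    min_retained_depth: float = 2.0,
) -> None:
    """Filter isoforms, call events and extract tags for one species."""
    reports = {}
    for gene in data.genes:
        key = (data.species, gene.gene_id)
        result.genes[key] = gene
        report = filter_isoforms(
            gene, data.support, min_junction_reads, min_retained_depth
        )
        reports[gene.gene_id] = report
        result.reports[key] = report
    result.expressed_multiexonic[data.species] = select_expressed_multiexonic(
        data.genes, reports
    )
    for gene in data.genes:
        kept = reports[gene.gene_id].kept_isoforms(gene)
        events = collect_gene_events(gene, kept)
        result.events[(data.species, gene.gene_id)] = events
        for ev in events:
            if ev.event_type == ALTDA:
                continue  # separate table; excluded from the four databases
            pair = extract_fests(ev, gene, data.genome)
            if pair is not None:
                result.fests[ev.event_id] = pair


def run_pipeline(
    datadir: str | Path,
    species: Sequence[str] | None = None,
    config: ConservationConfig | None = None,
    min_junction_reads: int = 2,
    min_retained_depth: float = 2.0,
) -> PipelineResult:
    """Run filtering, event calling, tag extraction and clustering."""
    datadir = Path(datadir)
    if species is None:
        # a species needs the full file set; stray GTFs are not species
        species = sorted(
            p.stem
            for p in datadir.glob("*.gtf")
            if (datadir / f"{p.stem}.fasta").exists()
            and (datadir / f"{p.stem}.junctions.tsv").exists()
        )
    result = PipelineResult(species=list(species))
    for sp in species:
        run_species(
            load_species(datadir, sp), result, min_junction_reads, min_retained_depth
        )
    orthogroups = aio.read_orthogroups(datadir / "orthogroups.tsv")
    result.clusters = cluster_conserved_events(
        result.all_events(), result.fests, orthogroups, config
    )
    return result
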