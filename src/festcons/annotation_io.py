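"""Input/output for gene annotations, genomes and cross-species tables.

Coordinate convention
---------------------
All in-memory intervals are **0-based, half-open** ``[start, end)`` on the
forward genomic strand, regardless of the transcribed strand.  GFF3/GTF files
are 1-based inclusive and are converted at the I/O boundary; the conversion is
``file (s, e)  ->  memory (s - 1, e)`` and is its own inverse.

Splice-junction support and retained-intron coverage tables (tab-separated,
columns documented on the readers) use the internal 0-based half-open intron
coordinates directly, since they are produced and consumed by this package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_NT = frozenset("ACGTRYSWKMBDHVN")

__all__ = [
    "GenomeStore",
    "TranscriptIsoform",
    "GeneModel",
    "JunctionSupport",
    "OrthogroupTable",
    "ParseError",
    "ValidationError",
    "read_gene_models",
    "write_gene_models",
    "read_genome",
    "write_genome",
    "read_orthogroups",
    "write_orthogroups",
    "read_junction_support",
    "write_junction_support",
    "compute_max_intron_length",
    "to_internal",
    "to_file",
]


class ParseError(ValueError):
    """A record in an input file could not be interpreted."""


class ValidationError(ValueError):
    """Parsed data violate a structural invariant."""


def to_internal(start_1based: int, end_inclusive: int) -> tuple[int, int]:
    """Convert a 1-based inclusive interval to 0-based half-open."""
    return start_1based - 1, end_inclusive


def to_file(start0: int, end0: int) -> tuple[int, int]:
    """Convert a 0-based half-open interval to 1-based inclusive."""
    return start0 + 1, end0


@dataclass
class GenomeStore:
    """Nucleotide sequences of one species, keyed by chromosome id."""

    species: str
    sequences: dict[str, str] = field(default_factory=dict)

    def fetch(self, chrom: str, start: int, end: int) -> str:
        seq = self.sequences[chrom]
        if start < 0 or end > len(seq):
            raise ValueError(
                f"slice [{start},{end}) outside {chrom} (length {len(seq)})"
            )
        return seq[start:end]


@dataclass(frozen=True)
class TranscriptIsoform:
    """One assembled transcript isoform as an ordered genomic exon chain."""

    isoform_id: str
    gene_id: str
    species: str
    chromosome: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValidationError(f"{self.isoform_id}: strand must be + or -")
        if not self.exons:
            raise ValidationError(f"{self.isoform_id}: isoform has no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        object.__setattr__(self, "exons", exons)
        prev_end = None
        for s, e in exons:
            if e <= s:
                raise ValidationError(f"{self.isoform_id}: empty exon [{s},{e})")
            if prev_end is not None and s <= prev_end:
                raise ValidationError(
                    f"{self.isoform_id}: exons overlap or abut at {s} "
                    "(introns must have length >= 1)"
                )
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive exons, genomic order."""
        return tuple(
            (self.exons[i][1], self.exons[i + 1][0])
            for i in range(len(self.exons) - 1)
        )

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    def exonic(self, start: int, end: int) -> bool:
        """True iff [start, end) is fully contained in a single exon."""
        return any(s <= start and end <= e for s, e in self.exons)


@dataclass
class GeneModel:
    """A gene locus with its set of transcript isoforms."""

    gene_id: str
    species: str
    isoforms: list[TranscriptIsoform] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.isoforms:
            chroms = {i.chromosome for i in self.isoforms}
            strands = {i.strand for i in self.isoforms}
            genes = {i.gene_id for i in self.isoforms}
            if len(chroms) > 1 or len(strands) > 1 or genes != {self.gene_id}:
                raise ValidationError(
                    f"{self.gene_id}: isoforms disagree on gene/chromosome/strand"
                )

    @property
    def chromosome(self) -> str:
        return self.isoforms[0].chromosome

    @property
    def strand(self) -> str:
        return self.isoforms[0].strand

    @property
    def is_multi_exonic(self) -> bool:
        return any(len(i.exons) >= 2 for i in self.isoforms)


@dataclass
class JunctionSupport:
    """Read support for splice junctions and retained-intron regions.

    Keys are ``(chromosome, intron_start, intron_end, strand)`` with internal
    0-based half-open intron coordinates.  Pooled across libraries.
    """

    species: str
    junction_counts: dict[tuple[str, int, int, str], int] = field(default_factory=dict)
    intron_coverage: dict[tuple[str, int, int, str], float] = field(default_factory=dict)

    def junction_reads(self, chrom: str, start: int, end: int, strand: str) -> int:
        key = (chrom, start, end, strand)
        if key not in self.junction_counts:
            logger.warning(
                "junction %s:%d-%d(%s) absent from support table; treated as 0 reads",
                chrom, start, end, strand,
            )
            return 0
        return self.junction_counts[key]

    def retained_depth(self, chrom: str, start: int, end: int, strand: str) -> float:
        key = (chrom, start, end, strand)
        if key not in self.intron_coverage:
            logger.warning(
                "retained intron %s:%d-%d(%s) absent from coverage table; "
                "treated as depth 0", chrom, start, end, strand,
            )
            return 0.0
        return self.intron_coverage[key]


@dataclass
class OrthogroupTable:
    """Orthogroup membership: group id -> set of (species, gene_id)."""

    groups: dict[str, set[tuple[str, str]]] = field(default_factory=dict)
    _gene_to_group: dict[tuple[str, str], str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._gene_to_group = {}
        for og, members in self.groups.items():
            for member in members:
                if member in self._gene_to_group:
                    raise ValidationError(
                        f"gene {member[1]} ({member[0]}) assigned to both "
                        f"{self._gene_to_group[member]} and {og}"
                    )
                self._gene_to_group[member] = og

    def group_of(self, species: str, gene_id: str) -> str | None:
        return self._gene_to_group.get((species, gene_id))

    def same_group(self, a: tuple[str, str], b: tuple[str, str]) -> bool:
        ga = self._gene_to_group.get(a)
        return ga is not None and ga == self._gene_to_group.get(b)


# ---------------------------------------------------------------------------
# GFF3 / GTF


def _is_gff3(path: Path) -> bool:
    if path.suffix.lower() in {".gff", ".gff3"}:
        return True
    if path.suffix.lower() == ".gtf":
        return False
    with open(path) as fh:
        for line in fh:
            if line.startswith("##gff-version"):
                return True
            if line.strip() and not line.startswith("#"):
                return "=" in line.split("\t")[-1]
    return False


def read_gene_models(annotation_file: str | Path, species: str) -> list[GeneModel]:
    """Read gene models from a GTF or GFF3 annotation.

    Exon features must carry transcript and gene identifiers: ``gene_id`` /
    ``transcript_id`` attributes (GTF) or a ``Parent`` transcript whose own
    ``Parent`` is the gene (GFF3).  File coordinates (1-based inclusive) are
    converted to internal 0-based half-open intervals.
    """
    path = Path(annotation_file)
    if not path.exists():
        raise FileNotFoundError(path)
    gff3 = _is_gff3(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    tx_to_gene: dict[str, str] = {}
    if gff3:
        for feat in db.all_features():
            if feat.featuretype in {"mRNA", "transcript"}:
                parents = feat.attributes.get("Parent", [])
                tx_to_gene[feat.id] = parents[0] if parents else feat.id

    exons: dict[tuple[str, str], list] = {}  # (gene, transcript) -> records
    for feat in db.features_of_type("exon"):
        if gff3:
            parents = feat.attributes.get("Parent")
            if not parents:
                raise ParseError(
                    f"exon at {feat.seqid}:{feat.start}-{feat.end} has no Parent"
                )
            tx = parents[0]
            gene = tx_to_gene.get(tx, feat.attributes.get("gene_id", [tx])[0])
        else:
            try:
                gene = feat.attributes["gene_id"][0]
                tx = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise ParseError(
                    f"exon at {feat.seqid}:{feat.start}-{feat.end} "
                    f"lacks attribute {exc}"
                ) from exc
        exons.setdefault((gene, tx), []).append(feat)

    genes: dict[str, GeneModel] = {}
    for (gene, tx), feats in exons.items():
        chrom = feats[0].seqid
        strand = feats[0].strand
        intervals = tuple(to_internal(f.start, f.end) for f in feats)
        iso = TranscriptIsoform(tx, gene, species, chrom, strand, intervals)
        genes.setdefault(gene, GeneModel(gene, species)).isoforms.append(iso)
    out = []
    for gm in genes.values():
        gm.__post_init__()  # re-validate cross-isoform invariants
        gm.isoforms.sort(key=lambda i: (i.span, i.isoform_id))
        out.append(gm)
    out.sort(key=lambda g: (g.chromosome, g.isoforms[0].span, g.gene_id))
    return out


def write_gene_models(genes: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as GTF (1-based inclusive exon features)."""
    with open(path, "w") as fh:
        for gene in genes:
            for iso in gene.isoforms:
                for s0, e0 in iso.exons:
                    s1, e1 = to_file(s0, e0)
                    fh.write(
                        f"{gene.chromosome}\tfestcons\texon\t{s1}\t{e1}\t.\t"
                        f"{gene.strand}\t.\t"
                        f'gene_id "{gene.gene_id}"; transcript_id "{iso.isoform_id}";\n'
                    )


# ---------------------------------------------------------------------------
# FASTA


def read_genome(fasta: str | Path, species: str) -> GenomeStore:
    """Load a genome FASTA; sequences are uppercased, ids must be unique."""
    store = GenomeStore(species=species)
    n = 0
    for record in SeqIO.parse(str(fasta), "fasta"):
        if record.id in store.sequences:
            raise ValidationError(f"duplicate FASTA record id {record.id!r}")
        seq = str(record.seq).upper()
        bad = set(seq) - IUPAC_NT
        if bad:
            raise ValidationError(
                f"record {record.id!r} contains non-IUPAC characters {sorted(bad)}"
            )
        store.sequences[record.id] = seq
        n += 1
    if n == 0:
        logger.warning("FASTA %s contains no records; empty genome store", fasta)
    return store


def write_genome(store: GenomeStore, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in store.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Orthogroups


def read_orthogroups(tsv: str | Path) -> OrthogroupTable:
    """Read an orthogroup table: ``orthogroup_id<TAB>species|gene ...`` rows."""
    groups: dict[str, set[tuple[str, str]]] = {}
    with open(tsv) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tokens = line.split("\t")
            og, members = tokens[0], tokens[1:]
            if og in groups:
                raise ParseError(f"line {lineno}: orthogroup {og} listed twice")
            parsed = set()
            for tok in members:
                if "|" not in tok:
                    raise ParseError(
                        f"line {lineno}: member {tok!r} is not species|gene"
                    )
                sp, gene = tok.split("|", 1)
                parsed.add((sp, gene))
            groups[og] = parsed
    return OrthogroupTable(groups=groups)  # validates one-group-per-gene


def write_orthogroups(table: OrthogroupTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        for og in sorted(table.groups):
            members = "\t".join(
                f"{sp}|{g}" for sp, g in sorted(table.groups[og])
            )
            fh.write(f"{og}\t{members}\n")


# ---------------------------------------------------------------------------
# Junction support / intron coverage


def read_junction_support(
    junction_tsv: str | Path,
    coverage_tsv: str | Path,
    species: str,
) -> JunctionSupport:
    """Read pooled junction read counts and retained-intron median depths.

    ``junction_tsv`` columns: chrom, intron_start, intron_end, strand,
    read_count.  ``coverage_tsv`` columns: chrom, intron_start, intron_end,
    strand, median_depth.  Intron coordinates are 0-based half-open.
    """
    sup = JunctionSupport(species=species)
    jc = pd.read_csv(junction_tsv, sep="\t")
    for row in jc.itertuples(index=False):
        count = int(row.read_count)
        if count < 0:
            raise ValidationError("negative junction read count")
        sup.junction_counts[
            (str(row.chrom), int(row.intron_start), int(row.intron_end), str(row.strand))
        ] = count
    cov = pd.read_csv(coverage_tsv, sep="\t")
    for row in cov.itertuples(index=False):
        depth = float(row.median_depth)
        if depth < 0:
            raise ValidationError("negative median depth")
        sup.intron_coverage[
            (str(row.chrom), int(row.intron_start), int(row.intron_end), str(row.strand))
        ] = depth
    return sup


def write_junction_support(sup: JunctionSupport, junction_tsv, coverage_tsv) -> None:
    pd.DataFrame(
        [(c, s, e, st, n) for (c, s, e, st), n in sorted(sup.junction_counts.items())],
        columns=["chrom", "intron_start", "intron_end", "strand", "read_count"],
    ).to_csv(junction_tsv, sep="\t", index=False)
    pd.DataFrame(
        [(c, s, e, st, d) for (c, s, e, st), d in sorted(sup.intron_coverage.items())],
        columns=["chrom", "intron_start", "intron_end", "strand", "median_depth"],
    ).to_csv(coverage_tsv, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Intron-size utility


def compute_max_intron_length(genes: Iterable[GeneModel]) -> int:
    """99th percentile of annotated intron lengths, as an integer bp ceiling.

    This mirrors the common practice of capping spliced-alignment intron size
    at the 99th percentile of the annotated intron-length distribution
    (linear interpolation between order statistics, then ceiling).
    """
    lengths = [
        e - s
        for gene in genes
        for iso in gene.isoforms
        for s, e in iso.introns
    ]
    if not lengths:
        raise ValueError("no introns in the provided gene models")
    return int(math.ceil(float(np.percentile(lengths, 99))))
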