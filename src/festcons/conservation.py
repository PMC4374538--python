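"""Cross-species matching of FEST pairs and conserved-event clustering.

Two events (same type, genes in the same orthogroup) are *conserved* when
both of their flanking-tag correspondences align well: FEST1 with FEST1 and
FEST2 with FEST2, in either nucleotide or translated mode.  Conserved pairs
are edges of a graph whose connected components are the conserved-event
clusters; each cluster represents one ancestral splicing event shared by
two or more genes (possibly including several paralogs of one species).

"Aligns well" means a local alignment with expectation value at most
``max_evalue`` (default 1e-5) covering at least ``min_nt_aligned`` columns
(nucleotide, default 30) or ``min_aa_aligned`` residues (translated,
default 10).  Expectation values use the Karlin-Altschul formula
``E = K * m * n * exp(-lambda * S)`` with ``lambda`` solved numerically for
the scoring scheme and ``K`` set to the standard ungapped value for that
scheme; ``n`` is the total length of the event-type tag database at search
time.  Translated mode scores the best of the 3x3 reading-frame pairs on
the transcribed strand with BLOSUM62 (tags are strand-oriented by
construction, so the reverse frames are not searched).
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Seq import Seq
from scipy.optimize import brentq

from .annotation_io import IUPAC_NT, OrthogroupTable
from .as_events import ASEvent
from .fest import FEST

logger = logging.getLogger(__name__)

__all__ = [
    "AlignmentHit",
    "ConservedEventCluster",
    "ConservationConfig",
    "align_fests",
    "fest_pair_conserved",
    "cluster_conserved_events",
    "pairwise_conservation_matrix",
]

# Robinson & Robinson amino-acid background frequencies (standard in
# BLAST statistics), indexed by one-letter code.
_AA_FREQS = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

NUCLEOTIDE = "nucleotide"
TRANSLATED = "translated"

# scoring schemes: (match, mismatch, gap open, gap extend) for nucleotide;
# BLOSUM62 with affine gaps for translated.  K values are the standard
# published ungapped constants for these schemes.
NT_MATCH, NT_MISMATCH = 1, -2
NT_OPEN, NT_EXTEND = -5, -2
AA_OPEN, AA_EXTEND = -11, -1
K_NT = 0.46
K_AA = 0.13


@lru_cache(maxsize=None)
def _lambda_nt() -> float:
    f = lambda lam: 0.25 * math.exp(lam * NT_MATCH) + 0.75 * math.exp(lam * NT_MISMATCH) - 1.0
    return brentq(f, 1e-6, 10.0)


@lru_cache(maxsize=None)
def _lambda_aa() -> float:
    mat = substitution_matrices.load("BLOSUM62")
    letters = list(_AA_FREQS)
    p = np.array([_AA_FREQS[a] for a in letters])
    p = p / p.sum()
    s = np.array([[mat[a, b] for b in letters] for a in letters])

    def f(lam):
        return float(np.sum(np.outer(p, p) * np.exp(lam * s)) - 1.0)

    return brentq(f, 1e-6, 2.0)


@lru_cache(maxsize=4)
def _aligner(mode: str) -> PairwiseAligner:
    aligner = PairwiseAligner(mode="local")
    if mode == NUCLEOTIDE:
        aligner.match_score = NT_MATCH
        aligner.mismatch_score = NT_MISMATCH
        aligner.open_gap_score = NT_OPEN
        aligner.extend_gap_score = NT_EXTEND
    else:
        aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
        aligner.open_gap_score = AA_OPEN
        aligner.extend_gap_score = AA_EXTEND
    return aligner


@dataclass(frozen=True)
class AlignmentHit:
    query: str
    subject: str
    mode: str
    score: float
    evalue: float
    aligned_length: int


@dataclass(frozen=True)
class ConservedEventCluster:
    """A set of same-type events linked by FEST similarity in one orthogroup."""

    cluster_id: str
    event_type: str
    members: tuple[str, ...]            # sorted event ids, >= 2 distinct genes
    genes: frozenset[tuple[str, str]]   # (species, gene_id)
    species_set: frozenset[str]
    orthogroup_id: str

    @property
    def n_species(self) -> int:
        return len(self.species_set)


@dataclass
class ConservationConfig:
    """Thresholds defining a qualifying alignment hit."""

    max_evalue: float = 1e-5
    min_nt_aligned: int = 30
    min_aa_aligned: int = 10


def _evalue(score: float, m: int, n: int, lam: float, k: float) -> float:
    return k * m * n * math.exp(-lam * score)


def _frames(seq: str) -> list[str]:
    out = []
    for f in range(3):
        sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
        if len(sub) >= 3:
            out.append(str(Seq(sub).translate()))
    return out


def align_fests(
    a: FEST,
    b: FEST,
    mode: str = NUCLEOTIDE,
    db_size: int | None = None,
) -> AlignmentHit | None:
    """Best local alignment of two tags; ``None`` when nothing scores > 0.

    ``db_size`` is the total letter count of the database the subject tag
    came from (used for the e-value); it defaults to the subject length.
    """
    for fest in (a, b):
        bad = set(fest.sequence) - IUPAC_NT
        if bad:
            raise ValueError(f"non-IUPAC characters {sorted(bad)} in FEST sequence")
    aligner = _aligner(mode)
    if mode == NUCLEOTIDE:
        qseq, sseqs = a.sequence, [b.sequence]
        qlens = [len(a.sequence)]
        lam, k = _lambda_nt(), K_NT
        n = db_size if db_size is not None else len(b.sequence)
    elif mode == TRANSLATED:
        qframes, sframes = _frames(a.sequence), _frames(b.sequence)
        lam, k = _lambda_aa(), K_AA
        n = (db_size // 3) if db_size is not None else max(len(s) for s in sframes)
    else:
        raise ValueError(f"unknown mode {mode!r}")

    best: tuple[float, str, str] | None = None
    pairs = (
        [(a.sequence, b.sequence)]
        if mode == NUCLEOTIDE
        else list(itertools.product(qframes, sframes))
    )
    for q, s in pairs:
        if not q or not s:
            continue
        score = aligner.score(q, s)
        if best is None or score > best[0]:
            best = (score, q, s)
    if best is None or best[0] <= 0:
        return None
    score, q, s = best
    evalue = _evalue(score, len(q), n, lam, k)
    alignment = aligner.align(q, s)[0]
    aligned_length = int(alignment.shape[1])
    return AlignmentHit(
        query=f"{a.event_ref}|fest{a.fest_number}",
        subject=f"{b.event_ref}|fest{b.fest_number}",
        mode=mode,
        score=float(score),
        evalue=float(evalue),
        aligned_length=aligned_length,
    )


def _qualifies(hit: AlignmentHit | None, config: ConservationConfig) -> bool:
    if hit is None:
        return False
    min_len = (
        config.min_nt_aligned if hit.mode == NUCLEOTIDE else config.min_aa_aligned
    )
    return hit.evalue <= config.max_evalue and hit.aligned_length >= min_len


def _tags_match(
    a: FEST, b: FEST, config: ConservationConfig, db_size: int | None
) -> bool:
    if _qualifies(align_fests(a, b, NUCLEOTIDE, db_size), config):
        return True
    return _qualifies(align_fests(a, b, TRANSLATED, db_size), config)


def fest_pair_conserved(
    event_a: ASEvent,
    event_b: ASEvent,
    fests: Mapping[str, tuple[FEST, FEST]],
    orthogroups: OrthogroupTable,
    config: ConservationConfig | None = None,
    db_size: int | None = None,
) -> bool:
    """True iff the two events are conserved counterparts.

    Requires same event type, genes sharing an orthogroup, and qualifying
    hits for both tag correspondences (FEST1-FEST1 and FEST2-FEST2, in
    nucleotide or translated mode).  Symmetric in its arguments.
    """
    config = config or ConservationConfig()
    if event_a.event_type != event_b.event_type:
        return False
    if not orthogroups.same_group(
        (event_a.species, event_a.gene_id), (event_b.species, event_b.gene_id)
    ):
        return False
    if event_a.event_id not in fests or event_b.event_id not in fests:
        return False
    up_a, down_a = fests[event_a.event_id]
    up_b, down_b = fests[event_b.event_id]
    return _tags_match(down_a, down_b, config, db_size) and _tags_match(
        up_a, up_b, config, db_size
    )


def cluster_conserved_events(
    events: Sequence[ASEvent],
    fests: Mapping[str, tuple[FEST, FEST]],
    orthogroups: OrthogroupTable,
    config: ConservationConfig | None = None,
) -> list[ConservedEventCluster]:
    """Single-linkage clusters of conserved events, per event-type database.

    Only event pairs whose genes share an orthogroup are aligned (the
    orthogroup constraint); clusters are connected components with at least
    two distinct member genes.  Cluster ids are deterministic, assigned in
    sorted order of member lists.
    """
    config = config or ConservationConfig()
    events = [e for e in events if e.event_id in fests]
    by_type: dict[str, list[ASEvent]] = {}
    for ev in events:
        by_type.setdefault(ev.event_type, []).append(ev)

    graph = nx.Graph()
    event_by_id = {e.event_id: e for e in events}
    for etype, evs in sorted(by_type.items()):
        db_size = sum(
            len(f.sequence) for e in evs for f in fests[e.event_id]
        )
        # candidate pairs: same orthogroup only
        by_group: dict[str, list[ASEvent]] = {}
        for ev in evs:
            og = orthogroups.group_of(ev.species, ev.gene_id)
            if og is not None:
                by_group.setdefault(og, []).append(ev)
        for og, group_events in sorted(by_group.items()):
            graph.add_nodes_from(e.event_id for e in group_events)
            for ea, eb in itertools.combinations(group_events, 2):
                if ea.gene_id == eb.gene_id and ea.species == eb.species:
                    continue  # conservation is between distinct genes
                if fest_pair_conserved(ea, eb, fests, orthogroups, config, db_size):
                    graph.add_edge(ea.event_id, eb.event_id)

    raw_clusters = []
    for component in nx.connected_components(graph):
        members = tuple(sorted(component))
        if len(members) < 2:
            continue
        evs = [event_by_id[m] for m in members]
        genes = frozenset((e.species, e.gene_id) for e in evs)
        if len(genes) < 2:
            continue
        etypes = {e.event_type for e in evs}
        ogs = {orthogroups.group_of(e.species, e.gene_id) for e in evs}
        assert len(etypes) == 1, "cluster mixes event types"
        assert len(ogs) == 1, "cluster spans orthogroups"
        raw_clusters.append((members, evs, genes, etypes.pop(), ogs.pop()))

    raw_clusters.sort(key=lambda c: c[0])
    clusters = []
    for idx, (members, evs, genes, etype, og) in enumerate(raw_clusters, 1):
        clusters.append(
            ConservedEventCluster(
                cluster_id=f"CL{idx:05d}",
                event_type=etype,
                members=members,
                genes=genes,
                species_set=frozenset(sp for sp, _ in genes),
                orthogroup_id=og,
            )
        )
    return clusters


def pairwise_conservation_matrix(
    clusters: Sequence[ConservedEventCluster],
    species_list: Sequence[str],
) -> pd.DataFrame:
    """Percentage of species-i conserved clusters shared with species j.

    Entry (i, j) = 100 x (clusters containing both i and j) / (clusters
    containing i and at least one other species).  The diagonal is NaN.
    """
    mat = pd.DataFrame(
        np.nan, index=list(species_list), columns=list(species_list), dtype=float
    )
    for i in species_list:
        denom = sum(
            1 for c in clusters if i in c.species_set and c.n_species >= 2
        )
        if denom == 0:
            logger.warning("species %s has no multi-species conserved clusters", i)
            for j in species_list:
                if j != i:
                    mat.loc[i, j] = 0.0
            continue
        for j in species_list:
            if j == i:
                continue
            both = sum(
                1 for c in clusters if i in c.species_set and j in c.species_set
            )
            mat.loc[i, j] = 100.0 * both / denom
    return mat
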