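"""Shared test utilities: independent oracles and random gene construction.

The oracles here deliberately use different mechanisms than the package:
event calling works on exonic *base sets* (membership arithmetic instead of
interval containment) and alignment scoring is a plain-Python affine-gap
Smith-Waterman, so agreement is meaningful evidence of correctness.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

from festcons.annotation_io import GeneModel, TranscriptIsoform
from festcons.as_events import ALTA, ALTD, ALTDA, EXONS, INTRONR

BASES = "ACGT"


def make_iso(iso_id, exons, gene="g1", species="spA", chrom="chr1", strand="+"):
    return TranscriptIsoform(iso_id, gene, species, chrom, strand, tuple(exons))


def make_gene(isoform_exons, gene="g1", species="spA", strand="+", chrom="chr1"):
    isoforms = [
        make_iso(f"{gene}.t{i+1}", exons, gene, species, chrom, strand)
        for i, exons in enumerate(isoform_exons)
    ]
    return GeneModel(gene, species, isoforms)


# ---------------------------------------------------------------------------
# brute-force event-calling oracle (exonic base sets)


def _introns(iso):
    return [(iso.exons[i][1], iso.exons[i + 1][0]) for i in range(len(iso.exons) - 1)]


def _bases(iso):
    out = set()
    for s, e in iso.exons:
        out.update(range(s, e))
    return out


def oracle_pair_events(a: TranscriptIsoform, b: TranscriptIsoform) -> set:
    """All events of one isoform pair, as (type, junctions) keys.

    Because introns are >= 1 bp, a contiguous base range fully inside the
    exonic base set of an isoform necessarily lies within a single exon,
    which makes set membership an independent route to every containment
    rule used by the caller.
    """
    events = set()
    strand = a.strand
    for x, y in ((a, b), (b, a)):
        ybases = _bases(y)
        y_starts = {s for s, _ in _introns(y)}
        y_ends = {e for _, e in _introns(y)}
        for s, e in _introns(x):
            if set(range(s - 1, e + 1)) <= ybases:
                events.add((INTRONR, (s, e)))
            if s in y_starts and e in y_ends and any(
                s <= xs and xe <= e for xs, xe in y.exons
            ):
                events.add((EXONS, (s, e)))
    start_type = ALTD if strand == "+" else ALTA
    end_type = ALTA if strand == "+" else ALTD
    for i in _introns(a):
        for j in _introns(b):
            if i == j or i[0] >= j[1] or j[0] >= i[1]:
                continue
            p, q = sorted((i, j))
            carrier = {tuple(i): a, tuple(j): b}
            start_ok = end_ok = False
            if p[0] != q[0]:
                start_ok = set(range(p[0], q[0])) <= _bases(carrier[q])
            if p[1] != q[1]:
                lo = p if p[1] < q[1] else q
                end_ok = set(range(min(p[1], q[1]), max(p[1], q[1]))) <= _bases(
                    carrier[lo]
                )
            if p[0] != q[0] and p[1] != q[1]:
                if start_ok and end_ok:
                    events.add((ALTDA, p + q))
            elif p[0] != q[0]:
                if start_ok:
                    events.add((start_type, (p[0], q[0], p[1])))
            elif p[1] != q[1]:
                if end_ok:
                    events.add((end_type, (p[0], p[1], q[1])))
    return events


def oracle_gene_events(isoforms) -> set:
    events = set()
    for a, b in combinations(isoforms, 2):
        events |= oracle_pair_events(a, b)
    return events


# ---------------------------------------------------------------------------
# random gene construction (unconstrained event interactions)


def random_gene(rng: np.random.Generator, gene="g", species="spA"):
    """A random multi-isoform gene: constitutive chain plus variants.

    Variants apply 1-2 random structural edits (retention, donor/acceptor
    shifts, dual-site shifts, skipping) at arbitrary sites, without the
    spacing constraints the fixture generator uses — adjacent and
    interacting edits are the point here.
    """
    n_exons = int(rng.integers(3, 7))
    exons, pos = [], int(rng.integers(0, 50))
    for i in range(n_exons):
        length = int(rng.integers(40, 121))
        exons.append((pos, pos + length))
        pos += length + int(rng.integers(40, 121))
    strand = "+" if rng.random() < 0.5 else "-"

    def variants(base):
        out = [tuple(base)]
        for _ in range(int(rng.integers(1, 3))):
            cur = [list(e) for e in out[-1]]
            n_int = len(cur) - 1
            if n_int == 0:
                break
            op = rng.choice(["retain", "left", "right", "both", "skip"])
            k = int(rng.integers(n_int))
            gap = cur[k + 1][0] - cur[k][1]
            if op == "retain":
                cur[k][1] = cur[k + 1][1]
                del cur[k + 1]
            elif op == "left":
                if gap < 2:
                    continue
                d = int(rng.integers(1, gap))
                cur[k][1] += d
            elif op == "right":
                if gap < 2:
                    continue
                d = int(rng.integers(1, gap))
                cur[k + 1][0] -= d
            elif op == "both":
                if gap < 3:
                    continue
                d1 = int(rng.integers(1, gap - 1))
                d2 = int(rng.integers(1, gap - d1))
                cur[k][1] += d1
                cur[k + 1][0] -= d2
            elif op == "skip":
                if len(cur) < 3 or k == 0:
                    continue
                del cur[k]
            out.append(tuple(tuple(e) for e in cur))
        return out

    chains = [tuple(exons)]
    for _ in range(int(rng.integers(1, 4))):
        chains.extend(variants(exons)[1:])
    # dedup chains, keep deterministic order
    seen, uniq = set(), []
    for ch in chains:
        if ch not in seen:
            seen.add(ch)
            uniq.append(ch)
    isoforms = [
        make_iso(f"{gene}.t{i+1}", ch, gene, species, "chr1", strand)
        for i, ch in enumerate(uniq[:4])
    ]
    return GeneModel(gene, species, isoforms)


# ---------------------------------------------------------------------------
# affine-gap Smith-Waterman oracle (Gotoh)


def gotoh_local(a: str, b: str, score_fn, gap_open: float, gap_extend: float) -> float:
    """Best local alignment score; gap of length L costs open+(L-1)*extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] + gap_open, E[i][j - 1] + gap_extend)
            F[i][j] = max(H[i - 1][j] + gap_open, F[i - 1][j] + gap_extend)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + score_fn(a[i - 1], b[j - 1]),
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


def gotoh_nt(a: str, b: str) -> float:
    return gotoh_local(
        a, b, lambda x, y: 1 if x == y else -2, gap_open=-5, gap_extend=-2
    )


_B62 = substitution_matrices.load("BLOSUM62")


def gotoh_translated(a: str, b: str) -> float:
    """Best protein-level score over the 3x3 forward reading-frame pairs."""
    def frames(seq):
        out = []
        for f in range(3):
            sub = seq[f : f + 3 * ((len(seq) - f) // 3)]
            if len(sub) >= 3:
                out.append(str(Seq(sub).translate()))
        return out

    best = 0.0
    for qa in frames(a):
        for qb in frames(b):
            best = max(
                best,
                gotoh_local(
                    qa, qb, lambda x, y: _B62[x, y], gap_open=-11, gap_extend=-1
                ),
            )
    return best


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))


def mutate_seq(seq: str, rate: float, rng: np.random.Generator) -> str:
    out = []
    for c in seq:
        if rng.random() < rate:
            out.append(BASES[(BASES.index(c) + int(rng.integers(1, 4))) % 4])
        else:
            out.append(c)
    return "".join(out)
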