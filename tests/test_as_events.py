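"""Alternative-splicing event calling, reclassification and deduplication."""

import numpy as np
import pytest

from festcons.as_events import (
    ALTA,
    ALTD,
    ALTDA,
    EXONS,
    INTRONR,
    collect_gene_events,
    compare_isoform_pair,
    reclassify_dual_events,
)
from helpers import make_gene, make_iso, oracle_gene_events, random_gene


def called(iso1, iso2):
    return {
        (e.event_type, e.junctions)
        for e in reclassify_dual_events(compare_isoform_pair(iso1, iso2))
    }


class TestPairComparison:
    def test_intron_retention(self):
        iso1 = make_iso("t1", [(0, 100), (200, 300)])
        iso2 = make_iso("t2", [(0, 300)])
        assert called(iso1, iso2) == {(INTRONR, (100, 200))}

    def test_alternative_donor_plus_strand(self):
        iso1 = make_iso("t1", [(0, 100), (200, 300)])
        iso2 = make_iso("t2", [(0, 120), (200, 300)])
        assert called(iso1, iso2) == {(ALTD, (100, 120, 200))}

    def test_alternative_acceptor_plus_strand(self):
        iso1 = make_iso("t1", [(0, 100), (180, 300)])
        iso2 = make_iso("t2", [(0, 100), (200, 300)])
        assert called(iso1, iso2) == {(ALTA, (100, 180, 200))}

    def test_exon_skipping(self):
        iso1 = make_iso("t1", [(0, 100), (150, 180), (200, 300)])
        iso2 = make_iso("t2", [(0, 100), (200, 300)])
        assert called(iso1, iso2) == {(EXONS, (100, 200))}

    def test_skipping_not_miscalled_as_alternative_site(self):
        # the spanning intron shares each boundary with a different intron
        # of the inclusion isoform; neither side has exonic context
        iso1 = make_iso("t1", [(0, 100), (150, 180), (200, 300)])
        iso2 = make_iso("t2", [(0, 100), (200, 300)])
        types = {t for t, _ in called(iso1, iso2)}
        assert ALTD not in types and ALTA not in types

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            gene = random_gene(rng)
            for a in gene.isoforms:
                for b in gene.isoforms:
                    if a is not b:
                        assert called(a, b) == called(b, a)

    def test_different_genes_rejected(self):
        a = make_iso("t1", [(0, 100), (200, 300)], gene="g1")
        b = make_iso("t2", [(0, 100), (200, 300)], gene="g2")
        with pytest.raises(ValueError):
            compare_isoform_pair(a, b)


class TestDualReclassification:
    def test_both_sites_differ_becomes_altda(self):
        iso1 = make_iso("t1", [(0, 100), (200, 320)])
        iso2 = make_iso("t2", [(0, 120), (220, 320)])
        events = called(iso1, iso2)
        assert events == {(ALTDA, (100, 200, 120, 220))}

    def test_shared_acceptor_left_unchanged(self):
        iso1 = make_iso("t1", [(0, 100), (200, 300)])
        iso2 = make_iso("t2", [(0, 120), (200, 300)])
        raw = compare_isoform_pair(iso1, iso2)
        assert {(e.event_type, e.junctions) for e in reclassify_dual_events(raw)} == {
            (ALTD, (100, 120, 200))
        }

    def test_merge_equals_brute_force_pairing(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            gene = random_gene(rng)
            for i, a in enumerate(gene.isoforms):
                for b in gene.isoforms[i + 1:]:
                    raw = compare_isoform_pair(a, b)
                    merged = reclassify_dual_events(raw)
                    # AltDA events must pair one provisional AltD and one
                    # provisional AltA on exactly the same intron pair
                    for ev in merged:
                        if ev.event_type == ALTDA:
                            sides = {
                                r.event_type
                                for r in raw
                                if r.provisional and r.junctions == ev.junctions
                            }
                            assert sides == {ALTD, ALTA}
                    assert not any(e.provisional for e in merged)


class TestStrandSemantics:
    def test_flipping_strand_swaps_donor_and_acceptor_events(self):
        plus = make_gene([[(0, 100), (200, 300)], [(0, 120), (200, 300)]])
        minus = make_gene(
            [[(0, 100), (200, 300)], [(0, 120), (200, 300)]], strand="-"
        )
        plus_types = {e.event_type for e in collect_gene_events(plus)}
        minus_types = {e.event_type for e in collect_gene_events(minus)}
        assert plus_types == {ALTD} and minus_types == {ALTA}

    def test_mirroring_and_flipping_preserves_event_multiset(self):
        # reverse-complementing the locus (mirror coordinates + flip
        # strand) must leave the typed event multiset unchanged
        rng = np.random.default_rng(2)
        for _ in range(20):
            gene = random_gene(rng)
            L = max(e for iso in gene.isoforms for _, e in iso.exons) + 10
            flipped = "-" if gene.strand == "+" else "+"
            mirrored = make_gene(
                [
                    [(L - e, L - s) for s, e in reversed(iso.exons)]
                    for iso in gene.isoforms
                ],
                strand=flipped,
            )
            counts = lambda g: sorted(
                e.event_type for e in collect_gene_events(g)
            )
            assert counts(gene) == counts(mirrored)


class TestGeneLevelCollection:
    def test_same_event_from_two_pairs_counted_once(self):
        gene = make_gene([
            [(0, 100), (200, 300)],
            [(0, 300)],
            [(0, 50), (60, 100), (200, 300)],  # also splices (100,200)
        ])
        events = collect_gene_events(gene)
        assert sum(1 for e in events if e.junctions == (100, 200)) == 1

    def test_single_isoform_gene_yields_nothing(self):
        gene = make_gene([[(0, 100), (200, 300)]])
        assert collect_gene_events(gene) == []

    def test_planted_fixture_events_recovered(self, toy_dataset, toy_result):
        _, manifest = toy_dataset
        with_events = {
            key: evs for key, evs in toy_result.events.items() if evs
        }
        assert {f"{sp}|{g}" for sp, g in with_events} == set(manifest.events)
        for (sp, g), evs in with_events.items():
            got = {(e.event_type, e.junctions) for e in evs}
            want = {(t, tuple(j)) for t, j in manifest.events[f"{sp}|{g}"]}
            assert got == want, (sp, g)

    def test_gene_contributes_once_per_type_to_gene_tallies(self, toy_result):
        events = toy_result.all_events()
        for etype in {e.event_type for e in events}:
            genes = {e.gene_id for e in events if e.event_type == etype}
            assert len(genes) <= len({(e.species, e.gene_id) for e in events})


def test_calls_match_brute_force_oracle_on_random_genes():
    """Independent base-set oracle agrees exactly on 200 random genes."""
    rng = np.random.default_rng(42)
    for i in range(200):
        gene = random_gene(rng, gene=f"g{i}")
        got = {(e.event_type, e.junctions) for e in collect_gene_events(gene)}
        want = oracle_gene_events(gene.isoforms)
        assert got == want, f"gene {i}: {got ^ want}"
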