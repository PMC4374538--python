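"""Summary tables: rounding, tallies and reproduction of published
percentages from published counts."""

import math

import pytest

from festcons import published
from festcons.as_events import ASEvent
from festcons.reporting import (
    family_summary,
    genes_with_conserved_events,
    pct,
    round_half_away,
    summarize_conservation,
    summarize_species,
)
from helpers import make_gene


def event(gene, etype, junctions, species="spA"):
    return ASEvent(species=species, gene_id=gene, chromosome="chr1",
                   strand="+", event_type=etype, junctions=junctions)


class TestRounding:
    @pytest.mark.parametrize(
        "value,decimals,expected",
        [(0.25, 1, 0.3), (0.35, 1, 0.4), (17.96, 0, 18.0), (32.78, 0, 33.0),
         (60.53, 1, 60.5), (-0.25, 1, -0.3)],
    )
    def test_half_away_from_zero(self, value, decimals, expected):
        assert round_half_away(value, decimals) == expected

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            pct(1, 0)


class TestPublishedArithmetic:
    """The survey's printed percentages must follow from its printed counts."""

    def test_alternative_acceptor_share_basal_angiosperm(self):
        counts = published.EVENT_COUNTS["AltA"]
        assert pct(counts["Amborella"], published.TOTAL_EVENTS["Amborella"]) == 18.5

    def test_intron_retention_mean_share(self):
        # recomputed shares agree with the printed ones to their printed
        # precision (one printed cell is off by a final-digit rounding step
        # relative to its own counts, hence the 0.1 tolerance), and the
        # unweighted mean reproduces the headline figure of 56%
        shares = [
            pct(published.EVENT_COUNTS["IntronR"][sp], published.TOTAL_EVENTS[sp])
            for sp in published.SPECIES
        ]
        for share, sp in zip(shares, published.SPECIES):
            assert share == pytest.approx(
                published.PRINTED_INTRONR_PCT[sp], abs=0.100001
            ), sp
        assert round_half_away(sum(shares) / len(shares)) == 56.0

    def test_two_species_stratum_share(self):
        totals = published.strata_totals()
        assert totals[2] == 16416
        assert pct(totals[2], published.grand_total()) == 60.5

    def test_intron_retention_cluster_share(self):
        assert pct(published.type_totals()["IntronR"], published.grand_total()) == 65.6

    def test_legume_pair_conserved_event_shares(self):
        lp = published.LEGUME_PAIR
        assert pct(lp["conserved_events"]["Common bean"],
                   lp["total_events"]["Common bean"], 0) == 33.0
        assert pct(lp["conserved_events"]["Soybean"],
                   lp["total_events"]["Soybean"], 0) == 18.0
        assert pct(lp["conserved_genes"]["Common bean"],
                   lp["total_genes"]["Common bean"], 0) == 45.0
        assert pct(lp["conserved_genes"]["Soybean"],
                   lp["total_genes"]["Soybean"], 0) == 31.0


class TestSpeciesSummary:
    def test_single_type_is_100_percent(self):
        genes = [make_gene([[(0, 50), (100, 150)]], gene=f"g{i}") for i in range(4)]
        events = [event("g0", "IntronR", (50, 100))]
        summary = summarize_species("spA", events, genes)
        assert summary.table.loc["IntronR", "event_pct"] == 100.0
        assert summary.table.loc["AltA", "events"] == 0
        assert summary.table.loc["IntronR", "gene_pct"] == 25.0

    def test_matches_independent_tally(self, toy_result):
        for sp in toy_result.species:
            events = toy_result.species_events(sp)
            genes = toy_result.expressed_multiexonic[sp]
            summary = summarize_species(sp, events, genes)
            for etype in ("AltA", "AltD", "ExonS", "IntronR"):
                assert summary.table.loc[etype, "events"] == sum(
                    1 for e in events if e.event_type == etype
                )
                assert summary.table.loc[etype, "genes"] == len(
                    {e.gene_id for e in events if e.event_type == etype}
                )
            assert summary.table.loc["Total", "events"] == len(events)
            # shares sum to 100 up to rounding
            total_pct = sum(
                summary.table.loc[t, "event_pct"]
                for t in ("AltA", "AltD", "ExonS", "IntronR")
            )
            assert math.isclose(total_pct, 100.0, abs_tol=0.2)

    def test_zero_denominator_is_an_error(self):
        with pytest.raises(ZeroDivisionError):
            summarize_species("spA", [], [])


class TestConservationSummary:
    def test_single_two_species_cluster(self, toy_result):
        summary = summarize_conservation(toy_result.clusters[:1])
        assert summary.table.loc[toy_result.clusters[0].n_species, "Total_pct"] == 100.0

    def test_matches_brute_force_stratification(self, toy_result):
        clusters = toy_result.clusters
        summary = summarize_conservation(clusters)
        for n in summary.table.index:
            stratum = [c for c in clusters if c.n_species == n]
            assert summary.table.loc[n, "Total"] == len(stratum)
        assert summary.table["Total"].sum() == len(clusters)


class TestGenesWithConservedEvents:
    def test_gene_in_two_clusters_counted_once(self, toy_result):
        denominators = {
            sp: len(toy_result.expressed_multiexonic[sp])
            for sp in toy_result.species
        }
        table = genes_with_conserved_events(toy_result.clusters, denominators)
        for etype in ("AltA", "AltD", "ExonS", "IntronR"):
            for sp in toy_result.species:
                expected = len({
                    g for c in toy_result.clusters
                    if c.event_type == etype and c.n_species >= 2
                    for s, g in c.genes if s == sp
                })
                assert table.loc[etype, sp] == expected

    def test_row_total_is_sum_of_species_cells(self, toy_result):
        denominators = {
            sp: len(toy_result.expressed_multiexonic[sp])
            for sp in toy_result.species
        }
        table = genes_with_conserved_events(toy_result.clusters, denominators)
        for etype in ("AltA", "AltD", "ExonS", "IntronR", "Total"):
            assert table.loc[etype, "Total"] == sum(
                table.loc[etype, sp] for sp in toy_result.species
            )


class TestFamilySummary:
    def test_fully_spliced_family_is_100_percent(self, toy_result):
        sp = toy_result.species[0]
        members = [
            (s, g) for (s, g), evs in toy_result.events.items()
            if s == sp and evs
        ][:4]
        expressed = {
            (s, g.gene_id)
            for s, genes in toy_result.expressed_multiexonic.items()
            for g in genes
        }
        table = family_summary(
            toy_result.clusters, toy_result.events, {"famX": members}, expressed
        )
        assert table.loc["famX", "with_as_pct"] == 100.0

    def test_family_without_expressed_members_is_zero(self, toy_result):
        expressed = set()
        table = family_summary(
            toy_result.clusters, toy_result.events,
            {"famY": [("spZ", "nope")]}, expressed,
        )
        assert table.loc["famY", "expressed_multiexonic"] == 0
        assert table.loc["famY", "with_as_pct"] == 0.0

    def test_outgroup_restricted_count(self, toy_result):
        expressed = {
            (s, g.gene_id)
            for s, genes in toy_result.expressed_multiexonic.items()
            for g in genes
        }
        members = sorted({g for c in toy_result.clusters for g in c.genes})
        table = family_summary(
            toy_result.clusters, toy_result.events, {"fam": members},
            expressed, outgroup_species="spC",
        )
        expected = sum(
            1 for c in toy_result.clusters
            if c.n_species >= 2 and "spC" in c.species_set
        )
        assert table.loc["fam", "conserved_with_outgroup"] == expected
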