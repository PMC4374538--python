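"""FEST alignment, conservation decisions and cluster construction."""

import random

import numpy as np
import pytest

from festcons.annotation_io import OrthogroupTable
from festcons.conservation import (
    NUCLEOTIDE,
    TRANSLATED,
    ConservationConfig,
    align_fests,
    cluster_conserved_events,
    fest_pair_conserved,
    pairwise_conservation_matrix,
)
from festcons.fest import FEST
from helpers import gotoh_nt, gotoh_translated, mutate_seq, random_seq


def tag(seq, ref="spA|g1|IntronR|100-200", number=1):
    return FEST(event_ref=ref, fest_number=number, sequence=seq,
                chromosome="chr1", interval=(0, len(seq)))


class TestAlignment:
    def test_identical_sequences_full_length_hit(self):
        rng = np.random.default_rng(0)
        seq = random_seq(rng, 100)
        hit = align_fests(tag(seq), tag(seq))
        assert hit is not None
        assert hit.score == 100  # match score 1, no gaps
        assert hit.aligned_length == 100

    def test_disjoint_alphabets_give_no_hit(self):
        hit = align_fests(tag("A" * 40), tag("T" * 40))
        assert hit is None

    def test_non_iupac_characters_rejected(self):
        with pytest.raises(ValueError):
            align_fests(tag("ACGT" * 10 + "Z" * 2), tag("ACGT" * 10))

    def test_scores_match_dynamic_programming_oracle(self):
        rng = np.random.default_rng(7)
        for i in range(60):
            a = random_seq(rng, int(rng.integers(60, 150)))
            b = mutate_seq(a, float(rng.uniform(0, 0.4)), rng)
            if rng.random() < 0.2:
                b = random_seq(rng, len(a))  # unrelated pair
            hit = align_fests(tag(a), tag(b), NUCLEOTIDE)
            expected = gotoh_nt(a, b)
            got = 0.0 if hit is None else hit.score
            assert got == expected, f"pair {i}"

    def test_translated_scores_match_oracle(self):
        rng = np.random.default_rng(8)
        for i in range(10):
            a = random_seq(rng, 90)
            b = mutate_seq(a, 0.1, rng)
            hit = align_fests(tag(a), tag(b), TRANSLATED)
            expected = gotoh_translated(a, b)
            got = 0.0 if hit is None else hit.score
            assert got == expected, f"pair {i}"


def synonymous_scramble(seq, rng):
    """Recode a reading frame with random synonymous codons."""
    from Bio.Data.CodonTable import standard_dna_table

    by_aa = {}
    for codon, aa in standard_dna_table.forward_table.items():
        by_aa.setdefault(aa, []).append(codon)
    out = []
    for i in range(0, len(seq) - len(seq) % 3, 3):
        codon = seq[i:i + 3]
        aa = standard_dna_table.forward_table.get(codon)
        if aa is None:  # stop codon: keep
            out.append(codon)
        else:
            out.append(by_aa[aa][rng.integers(len(by_aa[aa]))])
    return "".join(out)


class TestTranslatedRescue:
    def test_heavy_synonymous_divergence_recovered_in_translated_mode(self):
        # same peptide, maximally divergent codon usage: the nucleotide
        # threshold fails but the protein-level search qualifies
        rng = np.random.default_rng(3)
        config = ConservationConfig()
        for attempt in range(5):
            a = random_seq(rng, 120)
            b = synonymous_scramble(a, rng)
            nt = align_fests(tag(a), tag(b), NUCLEOTIDE, db_size=100_000)
            tr = align_fests(tag(a), tag(b), TRANSLATED, db_size=100_000)
            nt_pass = nt is not None and nt.evalue <= config.max_evalue \
                and nt.aligned_length >= config.min_nt_aligned
            tr_pass = tr is not None and tr.evalue <= config.max_evalue \
                and tr.aligned_length >= config.min_aa_aligned
            assert tr_pass
            if not nt_pass:
                return
        pytest.fail("nucleotide mode never failed on scrambled codons")


def events_with_identical_fests():
    from festcons.as_events import ASEvent

    rng = np.random.default_rng(5)
    up_seq, down_seq = random_seq(rng, 120), random_seq(rng, 120)
    events, fests = [], {}
    for sp, gene in (("spA", "a1"), ("spB", "b1"), ("spC", "c1")):
        ev = ASEvent(species=sp, gene_id=gene, chromosome="chr1", strand="+",
                     event_type="IntronR", junctions=(100, 200))
        events.append(ev)
        fests[ev.event_id] = (
            tag(up_seq, ev.event_id, 2), tag(down_seq, ev.event_id, 1)
        )
    return events, fests


class TestConservationDecision:
    def test_identical_pairs_in_same_orthogroup_conserved(self):
        events, fests = events_with_identical_fests()
        og = OrthogroupTable(groups={"OG1": {("spA", "a1"), ("spB", "b1")}})
        assert fest_pair_conserved(events[0], events[1], fests, og)
        assert fest_pair_conserved(events[1], events[0], fests, og)

    def test_different_orthogroups_block_conservation(self):
        events, fests = events_with_identical_fests()
        og = OrthogroupTable(
            groups={"OG1": {("spA", "a1")}, "OG2": {("spB", "b1")}}
        )
        assert not fest_pair_conserved(events[0], events[1], fests, og)

    def test_both_tag_correspondences_required(self):
        events, fests = events_with_identical_fests()
        og = OrthogroupTable(groups={"OG1": {("spA", "a1"), ("spB", "b1")}})
        rng = np.random.default_rng(9)
        e0, e1 = events[0], events[1]
        up, _down = fests[e1.event_id]
        fests[e1.event_id] = (up, tag(random_seq(rng, 120), e1.event_id, 1))
        assert not fest_pair_conserved(e0, e1, fests, og)


class TestClustering:
    def test_pairwise_conserved_events_form_cluster(self):
        events, fests = events_with_identical_fests()
        og = OrthogroupTable(
            groups={"OG1": {("spA", "a1"), ("spB", "b1"), ("spC", "c1")}}
        )
        clusters = cluster_conserved_events(events, fests, og)
        assert len(clusters) == 1
        assert clusters[0].species_set == {"spA", "spB", "spC"}
        assert clusters[0].orthogroup_id == "OG1"

    def test_single_linkage_transitivity(self):
        # B matches both A and C, but A and C were mutated apart: still one
        # cluster through the shared neighbour
        rng = np.random.default_rng(11)
        events, fests = events_with_identical_fests()
        a, b, c = events
        up, down = fests[a.event_id]
        fests[a.event_id] = (
            tag(mutate_seq(up.sequence, 0.12, rng), a.event_id, 2),
            tag(mutate_seq(down.sequence, 0.12, rng), a.event_id, 1),
        )
        up_c, down_c = fests[c.event_id]
        fests[c.event_id] = (
            tag(mutate_seq(up_c.sequence, 0.12, rng), c.event_id, 2),
            tag(mutate_seq(down_c.sequence, 0.12, rng), c.event_id, 1),
        )
        og = OrthogroupTable(
            groups={"OG1": {("spA", "a1"), ("spB", "b1"), ("spC", "c1")}}
        )
        clusters = cluster_conserved_events(events, fests, og)
        assert len(clusters) == 1 and len(clusters[0].members) == 3

    def test_identical_fests_outside_orthogroup_never_cluster(self, toy_result):
        # same events, orthogroups split so cross-species genes never share
        # a group: specificity must be absolute
        events, fests = events_with_identical_fests()
        og = OrthogroupTable(
            groups={"OG1": {("spA", "a1")}, "OG2": {("spB", "b1")},
                    "OG3": {("spC", "c1")}}
        )
        assert cluster_conserved_events(events, fests, og) == []

    def test_cluster_type_and_orthogroup_homogeneity(self, toy_dataset, toy_result):
        outdir, _ = toy_dataset
        from festcons.annotation_io import read_orthogroups

        og = read_orthogroups(outdir / "orthogroups.tsv")
        by_id = {e.event_id: e for e in toy_result.all_events()}
        for cluster in toy_result.clusters:
            types = {by_id[m].event_type for m in cluster.members}
            groups = {
                og.group_of(by_id[m].species, by_id[m].gene_id)
                for m in cluster.members
            }
            assert types == {cluster.event_type}
            assert groups == {cluster.orthogroup_id}
            assert len(cluster.genes) >= 2

    def test_clustering_invariant_to_input_order(self, toy_dataset, toy_result):
        outdir, _ = toy_dataset
        from festcons.annotation_io import read_orthogroups

        og = read_orthogroups(outdir / "orthogroups.tsv")
        events = toy_result.all_events()
        shuffled = events[::-1]
        random.Random(4).shuffle(shuffled)
        clusters = cluster_conserved_events(shuffled, toy_result.fests, og)
        assert [
            (c.members, c.event_type) for c in clusters
        ] == [(c.members, c.event_type) for c in toy_result.clusters]


class TestPairwiseMatrix:
    def _cluster(self, cid, species):
        from festcons.conservation import ConservedEventCluster

        genes = frozenset((sp, f"{sp}_g") for sp in species)
        return ConservedEventCluster(
            cluster_id=cid, event_type="IntronR",
            members=tuple(sorted(f"{sp}|g|IntronR|1-2" for sp in species)),
            genes=genes, species_set=frozenset(species), orthogroup_id="OG1",
        )

    def test_single_shared_cluster_is_100_percent(self):
        mat = pairwise_conservation_matrix([self._cluster("c1", ["A", "B"])],
                                           ["A", "B"])
        assert mat.loc["A", "B"] == 100.0 and mat.loc["B", "A"] == 100.0

    def test_half_shared(self):
        clusters = [self._cluster("c1", ["A", "B"]), self._cluster("c2", ["A", "C"])]
        mat = pairwise_conservation_matrix(clusters, ["A", "B", "C"])
        assert mat.loc["A", "B"] == 50.0
        assert mat.loc["B", "A"] == 100.0

    def test_matches_brute_force_counting(self, toy_result):
        clusters = toy_result.clusters
        species = toy_result.species
        mat = pairwise_conservation_matrix(clusters, species)
        for i in species:
            denom = [c for c in clusters if i in c.species_set and c.n_species > 1]
            for j in species:
                if i == j:
                    continue
                both = [c for c in denom if j in c.species_set]
                assert mat.loc[i, j] == pytest.approx(100 * len(both) / len(denom))
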