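"""Seeded synthetic multi-species datasets with planted splicing events.

The generator builds an ancestral gene per orthogroup (random exon/intron
structure and sequence), lays one ortholog per species at identical
coordinates on a per-species chromosome, and evolves sequences by seeded
point substitutions only — so orthologous junction context is preserved by
construction and the conservation matcher, not an aligner's gap model, is
what gets tested.  Alternative isoforms are planted as structural recipes:

- ``retain``       — merge the exons around intron *k* (intron retention)
- ``extend_left``  — extend the exon left of intron *k* into it by delta
  (alternative donor on the plus strand, alternative acceptor on minus)
- ``extend_right`` — extend the exon right of intron *k* likewise
  (alternative acceptor on plus, donor on minus)
- ``skip``         — splice out exon *j* with one spanning intron

Conserved events replicate one recipe across designated species' orthologs
at orthologous coordinates; lineage-specific events are planted
independently.  Junction-support tables are written directly (the filters
consume counts, so no reads are simulated): supported junctions/introns get
count/depth 5, and deliberately weak isoforms get a 1-read junction or a
depth-1 retained intron so the evidence filters must remove them exactly as
the manifest records.

Everything is driven by a single integer seed; identical parameters and
seed produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .annotation_io import (
    GenomeStore,
    GeneModel,
    JunctionSupport,
    OrthogroupTable,
    TranscriptIsoform,
    write_gene_models,
    write_genome,
    write_junction_support,
    write_orthogroups,
)
from .as_events import ALTA, ALTD, EXONS, INTRONR
from .isoform_filter import WEAK_JUNCTION, WEAK_RETAINED_INTRON
from .wgd import WGDOrthologSet, write_wgd_sets

SPACER = 100
BASES = np.array(list("ACGT"))

__all__ = ["FixtureParams", "FixtureManifest", "generate_toy_dataset",
           "generate_wgd_dataset"]


@dataclass
class FixtureParams:
    """Study conditions for the synthetic dataset.

    Defaults give a small three-species family collection with the event
    mix seen in flowering plants (intron retention dominating, exon
    skipping rarest) and zero sequence divergence; raise
    ``substitution_rate`` to test matcher robustness.
    """

    n_species: int = 3
    n_orthogroups: int = 40
    n_conserved_clusters: int = 20
    lineage_specific_per_species: int = 10
    n_weak_junction_isoforms: int = 2
    n_weak_retention_isoforms: int = 2
    substitution_rate: float = 0.0
    exon_count_range: tuple[int, int] = (4, 7)
    exon_len_range: tuple[int, int] = (80, 300)
    intron_len_range: tuple[int, int] = (80, 200)
    event_mix: tuple[tuple[str, float], ...] = (
        (INTRONR, 0.56), (ALTA, 0.21), (ALTD, 0.14), (EXONS, 0.09),
    )
    minus_strand_prob: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 <= self.substitution_rate < 1.0):
            raise ValueError("substitution rate must be in [0, 1)")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        if self.n_conserved_clusters > self.n_orthogroups:
            raise ValueError("more conserved clusters than orthogroups")


@dataclass
class FixtureManifest:
    """Ground truth for a generated dataset (JSON-serializable)."""

    seed: int
    species: list[str]
    tree_newick: str
    n_orthogroups: int
    files: dict[str, str] = field(default_factory=dict)
    # per species|gene: list of [event_type, [junctions...]] expected after filtering
    events: dict[str, list] = field(default_factory=dict)
    dropped_isoforms: dict[str, str] = field(default_factory=dict)
    conserved_clusters: list[dict] = field(default_factory=list)
    wgd_sets: dict[str, dict] = field(default_factory=dict)
    expected_rescued_sets: list[str] = field(default_factory=list)
    gene_count: dict[str, int] = field(default_factory=dict)
    isoform_count: dict[str, int] = field(default_factory=dict)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def load(cls, path: str | Path) -> "FixtureManifest":
        with open(path) as fh:
            return cls(**json.load(fh))


# ---------------------------------------------------------------------------
# structural recipes


def _apply_recipe(exons: list[tuple[int, int]], recipe: dict) -> list[tuple[int, int]]:
    kind, idx = recipe["kind"], recipe["index"]
    exons = [tuple(e) for e in exons]
    if kind == "retain":
        merged = (exons[idx][0], exons[idx + 1][1])
        return exons[:idx] + [merged] + exons[idx + 2:]
    if kind == "extend_left":
        d = recipe["delta"]
        s, e = exons[idx]
        return exons[:idx] + [(s, e + d)] + exons[idx + 1:]
    if kind == "extend_right":
        d = recipe["delta"]
        s, e = exons[idx + 1]
        return exons[:idx + 1] + [(s - d, e)] + exons[idx + 2:]
    if kind == "skip":
        return exons[:idx] + exons[idx + 1:]
    raise ValueError(f"unknown recipe kind {kind!r}")


def _expected_event(
    exons: list[tuple[int, int]], strand: str, recipe: dict
) -> tuple[str, tuple[int, ...]]:
    """Event type and junction key implied by a recipe vs the full chain."""
    kind, idx = recipe["kind"], recipe["index"]
    introns = [
        (exons[i][1], exons[i + 1][0]) for i in range(len(exons) - 1)
    ]
    if kind == "retain":
        return INTRONR, tuple(introns[idx])
    if kind == "extend_left":
        s, e = introns[idx]
        d = recipe["delta"]
        etype = ALTD if strand == "+" else ALTA
        return etype, (s, s + d, e)
    if kind == "extend_right":
        s, e = introns[idx]
        d = recipe["delta"]
        etype = ALTA if strand == "+" else ALTD
        return etype, (s, e - d, e)
    if kind == "skip":
        return EXONS, (exons[idx - 1][1], exons[idx + 1][0])
    raise ValueError(kind)


def _blocked(recipe: dict) -> set[int]:
    """Intron indices a recipe occupies (with a one-intron buffer)."""
    kind, idx = recipe["kind"], recipe["index"]
    if kind == "skip":
        return set(range(idx - 2, idx + 2))
    return {idx - 1, idx, idx + 1}


def _free_recipe(
    rng: np.random.Generator,
    kind: str,
    n_exons: int,
    used: set[int],
) -> dict | None:
    """Pick an event site not clashing with already-planted events."""
    if kind == "skip":
        candidates = [
            j for j in range(1, n_exons - 1)
            if not (set(range(j - 2, j + 2)) & used)
        ]
    else:
        candidates = [
            k for k in range(n_exons - 1)
            if not ({k - 1, k, k + 1} & used)
        ]
    if not candidates:
        return None
    idx = int(candidates[rng.integers(len(candidates))])
    recipe = {"kind": kind, "index": idx}
    if kind in ("extend_left", "extend_right"):
        recipe["delta"] = int(rng.integers(35, 56))
    used |= _blocked(recipe)
    return recipe


def _kind_for(event_type: str, strand: str) -> str:
    if event_type == INTRONR:
        return "retain"
    if event_type == EXONS:
        return "skip"
    if event_type == ALTD:
        return "extend_left" if strand == "+" else "extend_right"
    return "extend_right" if strand == "+" else "extend_left"


# ---------------------------------------------------------------------------
# sequence machinery


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.integers(0, 4, size=n)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hit = rng.random(len(seq)) < rate
    # substitute with one of the three other bases
    out[hit] = (out[hit] + rng.integers(1, 4, size=int(hit.sum()))) % 4
    return out


def _to_str(codes: np.ndarray) -> str:
    return "".join(BASES[codes])


def _caterpillar_newick(species: list[str]) -> str:
    tree = species[0]
    for sp in species[1:]:
        tree = f"({tree},{sp})"
    return tree + ";"


# ---------------------------------------------------------------------------
# main generator


@dataclass
class _GeneDraft:
    species: str
    gene_id: str
    orthogroup: str
    strand: str
    exons: list[tuple[int, int]]
    recipes: list[dict] = field(default_factory=list)      # events that survive
    weak_recipes: list[tuple[dict, str]] = field(default_factory=list)  # (recipe, reason)
    used_sites: set[int] = field(default_factory=set)


def _draft_to_isoforms(draft: _GeneDraft, chrom: str) -> list[TranscriptIsoform]:
    isoforms = [
        TranscriptIsoform(
            f"{draft.gene_id}.t1", draft.gene_id, draft.species, chrom,
            draft.strand, tuple(draft.exons),
        )
    ]
    n = 2
    for recipe in draft.recipes:
        isoforms.append(
            TranscriptIsoform(
                f"{draft.gene_id}.t{n}", draft.gene_id, draft.species, chrom,
                draft.strand, tuple(_apply_recipe(draft.exons, recipe)),
            )
        )
        n += 1
    for recipe, _reason in draft.weak_recipes:
        isoforms.append(
            TranscriptIsoform(
                f"{draft.gene_id}.t{n}", draft.gene_id, draft.species, chrom,
                draft.strand, tuple(_apply_recipe(draft.exons, recipe)),
            )
        )
        n += 1
    return isoforms


def generate_toy_dataset(
    params: FixtureParams,
    seed: int,
    outdir: str | Path,
) -> FixtureManifest:
    """Generate a multi-species dataset and write all pipeline inputs.

    Writes per species ``{sp}.fasta``, ``{sp}.gtf``, ``{sp}.junctions.tsv``
    and ``{sp}.coverage.tsv``, plus ``orthogroups.tsv``, ``tree.nwk`` and
    ``manifest.json`` under ``outdir``; returns the manifest.
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    species = [f"sp{chr(ord('A') + i)}" for i in range(params.n_species)]
    chrom = "chr1"

    # ancestral structures, shared layout across species
    offset = SPACER
    og_structures: list[dict] = []
    mix_types = [t for t, _ in params.event_mix]
    mix_probs = np.array([w for _, w in params.event_mix], dtype=float)
    mix_probs /= mix_probs.sum()
    for og_idx in range(params.n_orthogroups):
        n_exons = int(rng.integers(*params.exon_count_range))
        exons = []
        pos = offset
        for i in range(n_exons):
            length = int(rng.integers(*params.exon_len_range))
            exons.append((pos, pos + length))
            pos = pos + length
            if i < n_exons - 1:
                pos += int(rng.integers(*params.intron_len_range))
        strand = "-" if rng.random() < params.minus_strand_prob else "+"
        og_structures.append(
            {"og": f"OG{og_idx + 1:04d}", "exons": exons, "strand": strand,
             "n_exons": n_exons}
        )
        offset = pos + SPACER
    chrom_len = offset
    ancestral = _random_seq(rng, chrom_len)

    drafts: dict[tuple[str, str], _GeneDraft] = {}
    for sp in species:
        for st in og_structures:
            gene_id = f"{sp}_{st['og']}"
            drafts[(sp, st["og"])] = _GeneDraft(
                species=sp, gene_id=gene_id, orthogroup=st["og"],
                strand=st["strand"], exons=st["exons"],
            )

    manifest = FixtureManifest(
        seed=seed,
        species=species,
        tree_newick=_caterpillar_newick(species),
        n_orthogroups=params.n_orthogroups,
    )

    # conserved events: one shared recipe across all species of chosen OGs.
    # og_used is a cross-species site registry per orthogroup: without it,
    # independently planted lineage-specific events could land on the same
    # orthologous intron in two species and be genuinely conserved, which
    # would corrupt the planted-cluster ground truth.
    conserved_ogs = list(
        rng.choice(params.n_orthogroups, size=params.n_conserved_clusters,
                   replace=False)
    )
    og_used: dict[str, set[int]] = {}
    for og_idx in sorted(int(i) for i in conserved_ogs):
        st = og_structures[og_idx]
        etype = mix_types[int(rng.choice(len(mix_types), p=mix_probs))]
        used = og_used.setdefault(st["og"], set())
        recipe = _free_recipe(
            rng, _kind_for(etype, st["strand"]), st["n_exons"], used
        )
        if recipe is None:
            raise RuntimeError(
                f"{st['og']}: cannot place a conserved {etype} event "
                "(all sites blocked) — increase exon count range"
            )
        etype_out, junctions = _expected_event(st["exons"], st["strand"], recipe)
        members = []
        for sp in species:
            draft = drafts[(sp, st["og"])]
            draft.recipes.append(recipe)
            draft.used_sites |= _blocked(recipe)
            members.append([sp, draft.gene_id])
        manifest.conserved_clusters.append(
            {"orthogroup": st["og"], "event_type": etype_out,
             "junctions": list(junctions), "members": members}
        )

    # lineage-specific events, independent per species; sites are reserved
    # in the cross-species registry so no two species converge on one
    # orthologous junction by chance
    for sp in species:
        planted = 0
        attempts = 0
        budget = 100 * max(params.lineage_specific_per_species, 1)
        while planted < params.lineage_specific_per_species and attempts < budget:
            attempts += 1
            og_idx = int(rng.integers(params.n_orthogroups))
            st = og_structures[og_idx]
            draft = drafts[(sp, st["og"])]
            etype = mix_types[int(rng.choice(len(mix_types), p=mix_probs))]
            combined = draft.used_sites | og_used.get(st["og"], set())
            recipe = _free_recipe(
                rng, _kind_for(etype, st["strand"]), st["n_exons"], combined
            )
            if recipe is None:
                continue
            draft.recipes.append(recipe)
            draft.used_sites |= _blocked(recipe)
            og_used.setdefault(st["og"], set()).update(_blocked(recipe))
            planted += 1

    # deliberately weak isoforms: new-junction recipes failing read support,
    # retention recipes failing coverage
    for sp in species:
        for reason, n_weak, kinds in (
            (WEAK_JUNCTION, params.n_weak_junction_isoforms,
             ("extend_left", "extend_right", "skip")),
            (WEAK_RETAINED_INTRON, params.n_weak_retention_isoforms,
             ("retain",)),
        ):
            planted = 0
            attempts = 0
            while planted < n_weak and attempts < 50 * max(n_weak, 1):
                attempts += 1
                og_idx = int(rng.integers(params.n_orthogroups))
                st = og_structures[og_idx]
                draft = drafts[(sp, st["og"])]
                kind = kinds[int(rng.integers(len(kinds)))]
                recipe = _free_recipe(rng, kind, st["n_exons"], draft.used_sites)
                if recipe is None:
                    continue
                draft.weak_recipes.append((recipe, reason))
                planted += 1

    # materialise per-species files
    orthogroups = OrthogroupTable(
        groups={
            st["og"]: {
                (sp, drafts[(sp, st["og"])].gene_id) for sp in species
            }
            for st in og_structures
        }
    )
    for sp_i, sp in enumerate(species):
        sp_rng = np.random.default_rng(seed + 1000 + sp_i)
        seq = _mutate(ancestral, params.substitution_rate, sp_rng)
        genome = GenomeStore(species=sp, sequences={chrom: _to_str(seq)})
        genes, support = [], JunctionSupport(species=sp)
        n_iso = 0
        for st in og_structures:
            draft = drafts[(sp, st["og"])]
            isoforms = _draft_to_isoforms(draft, chrom)
            n_iso += len(isoforms)
            genes.append(GeneModel(draft.gene_id, sp, isoforms))

            weak_junctions: set[tuple[int, int]] = set()
            weak_introns: set[tuple[int, int]] = set()
            weak_iso_ids = []
            base = 2 + len(draft.recipes)
            for w_i, (recipe, reason) in enumerate(draft.weak_recipes):
                iso_id = f"{draft.gene_id}.t{base + w_i}"
                weak_iso_ids.append(iso_id)
                manifest.dropped_isoforms[f"{sp}|{iso_id}"] = reason
                if reason == WEAK_JUNCTION:
                    # the recipe's novel junction gets 1 read
                    alt = _apply_recipe(draft.exons, recipe)
                    base_introns = set(
                        (draft.exons[i][1], draft.exons[i + 1][0])
                        for i in range(len(draft.exons) - 1)
                    )
                    for i in range(len(alt) - 1):
                        intron = (alt[i][1], alt[i + 1][0])
                        if intron not in base_introns:
                            weak_junctions.add(intron)
                else:
                    _t, junctions = _expected_event(
                        draft.exons, draft.strand, recipe
                    )
                    weak_introns.add((junctions[0], junctions[-1]))

            for iso in genes[-1].isoforms:
                for intron in iso.introns:
                    key = (chrom, *intron, draft.strand)
                    count = 1 if intron in weak_junctions else 5
                    prev = support.junction_counts.get(key)
                    support.junction_counts[key] = (
                        count if prev is None else min(prev, count)
                    )
                    depth = 1.0 if intron in weak_introns else 5.0
                    prev_d = support.intron_coverage.get(key)
                    support.intron_coverage[key] = (
                        depth if prev_d is None else min(prev_d, depth)
                    )

            # expected surviving events
            expected = [
                list(_expected_event(draft.exons, draft.strand, r))
                for r in draft.recipes
            ]
            if expected:
                manifest.events[f"{sp}|{draft.gene_id}"] = [
                    [t, list(j)] for t, j in expected
                ]

        write_genome(genome, outdir / f"{sp}.fasta")
        write_gene_models(genes, outdir / f"{sp}.gtf")
        write_junction_support(
            support, outdir / f"{sp}.junctions.tsv", outdir / f"{sp}.coverage.tsv"
        )
        manifest.gene_count[sp] = len(genes)
        manifest.isoform_count[sp] = n_iso
        manifest.files[f"{sp}.fasta"] = f"{sp}.fasta"
        manifest.files[f"{sp}.gtf"] = f"{sp}.gtf"
        manifest.files[f"{sp}.junctions"] = f"{sp}.junctions.tsv"
        manifest.files[f"{sp}.coverage"] = f"{sp}.coverage.tsv"

    write_orthogroups(orthogroups, outdir / "orthogroups.tsv")
    (outdir / "tree.nwk").write_text(manifest.tree_newick + "\n")
    manifest.files["orthogroups"] = "orthogroups.tsv"
    manifest.files["tree"] = "tree.nwk"
    manifest.save(outdir / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# WGD fixture


def generate_wgd_dataset(
    category_counts: dict[str, int],
    seed: int,
    outdir: str | Path,
    n_unexpressed: int = 1,
    n_no_event: int = 1,
    rescued_fraction: float = 0.5,
    substitution_rate: float = 0.0,
) -> FixtureManifest:
    """Dataset of 1-singleton : 2-duplicate ortholog sets plus an outgroup.

    Each set receives one planted event whose members encode its category
    (``1:2``, ``1:1``, ``0:2``, ``1:0`` or ``0:1``); ``rescued_fraction``
    of the 0:2 sets also carry the event in the outgroup species so that
    outgroup rescue has known ground truth.  ``n_unexpressed`` extra sets
    have an unexpressed singleton and ``n_no_event`` have no event at all
    (both must be rejected by eligibility selection).
    """
    rng = np.random.default_rng(seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    single_sp, dup_sp, out_sp = "spCB", "spSB", "spOUT"
    chrom = "chr1"

    plan: list[tuple[str, str]] = []  # (set_id, category-or-flag)
    i = 1
    for cat in ("1:2", "1:1", "0:2", "1:0", "0:1"):
        for _ in range(category_counts.get(cat, 0)):
            plan.append((f"W{i:03d}", cat))
            i += 1
    for _ in range(n_unexpressed):
        plan.append((f"W{i:03d}", "unexpressed"))
        i += 1
    for _ in range(n_no_event):
        plan.append((f"W{i:03d}", "no-event"))
        i += 1

    n02 = category_counts.get("0:2", 0)
    n_rescued = int(round(rescued_fraction * n02))

    offset = SPACER
    structures = []
    for set_id, flag in plan:
        n_exons = int(rng.integers(4, 7))
        exons, pos = [], offset
        for k in range(n_exons):
            length = int(rng.integers(80, 301))
            exons.append((pos, pos + length))
            pos += length
            if k < n_exons - 1:
                pos += int(rng.integers(80, 201))
        strand = "-" if rng.random() < 0.5 else "+"
        structures.append(
            {"set_id": set_id, "flag": flag, "exons": exons, "strand": strand,
             "n_exons": n_exons}
        )
        offset = pos + SPACER
    ancestral = _random_seq(rng, offset)

    manifest = FixtureManifest(
        seed=seed,
        species=[single_sp, dup_sp, out_sp],
        tree_newick=f"(({single_sp},{dup_sp}),{out_sp});",
        n_orthogroups=len(plan),
    )

    # which genes of a set carry the planted event, by category
    carriers = {
        "1:2": ("cb", "sb1", "sb2"),
        "1:1": ("cb", "sb1"),
        "0:2": ("sb1", "sb2"),
        "1:0": ("cb",),
        "0:1": ("sb1",),
        # ineligible-by-expression sets still carry an event so that the
        # eligibility test rejects them for expression, not for lack of AS
        "unexpressed": ("sb1",),
    }

    gene_sets: dict[str, dict[str, str]] = {}
    recipes: dict[str, tuple[dict, str, tuple[int, ...]]] = {}
    rescued_ids: list[str] = []
    n02_seen = 0
    for st in structures:
        set_id, flag = st["set_id"], st["flag"]
        gene_sets[set_id] = {
            "cb": f"{single_sp}_{set_id}",
            "sb1": f"{dup_sp}_{set_id}a",
            "sb2": f"{dup_sp}_{set_id}b",
            "out": f"{out_sp}_{set_id}",
        }
        if flag in carriers:
            etype = (INTRONR, ALTA, ALTD, EXONS)[int(rng.integers(4))]
            recipe = _free_recipe(
                rng, _kind_for(etype, st["strand"]), st["n_exons"], set()
            )
            assert recipe is not None
            t, junctions = _expected_event(st["exons"], st["strand"], recipe)
            recipes[set_id] = (recipe, t, junctions)
            manifest.wgd_sets[set_id] = {
                "category": flag,
                "event_type": t,
                "junctions": list(junctions),
                "genes": gene_sets[set_id],
            }
            if flag == "0:2":
                n02_seen += 1
                if n02_seen <= n_rescued:
                    rescued_ids.append(set_id)
        else:
            manifest.wgd_sets[set_id] = {
                "category": flag, "genes": gene_sets[set_id]
            }
    manifest.expected_rescued_sets = rescued_ids

    # materialise: three species, duplicate species holds two gene copies at
    # shifted offsets on its own chromosome
    sp_layout = {
        single_sp: [("cb",)], dup_sp: [("sb1", "sb2")], out_sp: [("out",)],
    }
    orthogroup_rows = {}
    for sp_i, sp in enumerate((single_sp, dup_sp, out_sp)):
        sp_rng = np.random.default_rng(seed + 2000 + sp_i)
        roles = sp_layout[sp][0]
        # duplicate species: two full copies of the ancestral chromosome
        copies = []
        for copy_i in range(len(roles)):
            copies.append(_mutate(ancestral, substitution_rate, sp_rng))
        seq = np.concatenate(copies)
        genome = GenomeStore(species=sp, sequences={chrom: _to_str(seq)})
        genes, support = [], JunctionSupport(species=sp)
        for st in structures:
            set_id, flag = st["set_id"], st["flag"]
            for copy_i, role in enumerate(roles):
                shift = copy_i * len(ancestral)
                exons = [(s + shift, e + shift) for s, e in st["exons"]]
                gene_id = gene_sets[set_id][role]
                draft = _GeneDraft(
                    species=sp, gene_id=gene_id, orthogroup=set_id,
                    strand=st["strand"], exons=exons,
                )
                cat = manifest.wgd_sets[set_id]["category"]
                carries = (
                    cat in carriers and role in carriers[cat]
                ) or (role == "out" and set_id in rescued_ids)
                if carries:
                    recipe = recipes[set_id][0]
                    draft.recipes.append(recipe)
                isoforms = _draft_to_isoforms(draft, chrom)
                genes.append(GeneModel(gene_id, sp, isoforms))
                unexpressed = flag == "unexpressed" and role == "cb"
                for iso in genes[-1].isoforms:
                    if unexpressed:
                        manifest.dropped_isoforms[f"{sp}|{iso.isoform_id}"] = (
                            WEAK_JUNCTION
                        )
                    for intron in iso.introns:
                        key = (chrom, *intron, st["strand"])
                        count = 1 if unexpressed else 5
                        prev = support.junction_counts.get(key)
                        support.junction_counts[key] = (
                            count if prev is None else min(prev, count)
                        )
                        support.intron_coverage.setdefault(key, 5.0)
                if carries and not unexpressed:
                    t, junctions = recipes[set_id][1], recipes[set_id][2]
                    shifted = tuple(j + shift for j in junctions)
                    manifest.events[f"{sp}|{gene_id}"] = [[t, list(shifted)]]
                orthogroup_rows.setdefault(set_id, set()).add((sp, gene_id))
        write_genome(genome, outdir / f"{sp}.fasta")
        write_gene_models(genes, outdir / f"{sp}.gtf")
        write_junction_support(
            support, outdir / f"{sp}.junctions.tsv", outdir / f"{sp}.coverage.tsv"
        )
        manifest.gene_count[sp] = len(genes)
        manifest.isoform_count[sp] = sum(len(g.isoforms) for g in genes)
        for suffix in ("fasta", "gtf"):
            manifest.files[f"{sp}.{suffix}"] = f"{sp}.{suffix}"
        manifest.files[f"{sp}.junctions"] = f"{sp}.junctions.tsv"
        manifest.files[f"{sp}.coverage"] = f"{sp}.coverage.tsv"

    write_orthogroups(
        OrthogroupTable(groups=orthogroup_rows), outdir / "orthogroups.tsv"
    )
    sets = [
        WGDOrthologSet(
            set_id,
            (single_sp, gene_sets[set_id]["cb"]),
            ((dup_sp, gene_sets[set_id]["sb1"]),
             (dup_sp, gene_sets[set_id]["sb2"])),
        )
        for set_id, _ in plan
    ]
    write_wgd_sets(sets, outdir / "wgd_sets.tsv")
    (outdir / "tree.nwk").write_text(manifest.tree_newick + "\n")
    manifest.files["orthogroups"] = "orthogroups.tsv"
    manifest.files["wgd_sets"] = "wgd_sets.tsv"
    manifest.files["tree"] = "tree.nwk"
    manifest.save(outdir / "manifest.json")
    return manifest
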