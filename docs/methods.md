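# Methods

## Scope and model

`festcons` treats a transcript isoform as an ordered chain of genomic exon
intervals (internally 0-based half-open; GFF3/GTF I/O converts from 1-based
inclusive at the boundary). Alternative splicing is defined purely
structurally, by pairwise comparison of isoforms of one gene:

- **IntronR** — an intron of one isoform lies strictly inside an exon of
  the other. Strictness matters: an intron whose boundary coincides with
  the containing exon's boundary would imply a shared splice site, not
  retention.
- **AltD / AltA** — two overlapping introns, one per isoform, share one
  boundary and differ at the other; the region between the differing
  boundaries must be exonic in the isoform carrying the shorter intron.
  Donor vs acceptor is resolved by strand (the donor is the intron's
  genomic start on `+`, its genomic end on `-`). The exonic-context
  requirement is what prevents an exon-skipping configuration (where the
  spanning intron shares each boundary with a *different* intron of the
  inclusion isoform) from being miscalled as an alternative site.
- **ExonS** — an intron of one isoform spans ≥ 1 complete exons of the
  other and both of its boundaries coincide with intron boundaries of the
  other isoform. A run of consecutively skipped exons is one event, keyed
  by the outer junctions, since a single spanning intron defines it.
- **AltDA** — an overlapping intron pair differing at *both* boundaries.
  The caller emits provisional AltD and AltA records for such pairs and a
  re-classification pass merges each co-located pair into one AltDA event;
  a provisional record whose partner side lacks exonic context describes
  no well-formed event and is discarded. AltDA events are tabulated
  separately and excluded from the four per-type conservation databases.

With *k* alternative donors sharing one acceptor, one event is emitted per
unordered donor pair (*k·(k−1)/2*), deduplicated by coordinates — the
natural convention under pairwise comparison. Gene-level events are the
union over all isoform pairs, deduplicated by (gene, type, junctions), with
deterministic coordinate ordering; the recorded witness pair is the first
supporting pair in isoform-id order.

## Evidence filters

Isoforms are filtered before calling, in two passes per gene: first the
junction filter (any junction with < 2 supporting reads drops the isoform;
junctions missing from the support table count as zero and are logged
distinctly), then the retention filter evaluated against the *survivors*
of the first pass (an isoform exonically spanning a surviving sibling's
intron is dropped when the retained region's median depth is < 2). The
two-pass order resolves the circularity in "sibling": retention evidence
is only demanded against isoforms that are themselves credible. Both
thresholds use ≥ semantics ("minimum of two" ⇒ count ≤ 1 fails) and are
configurable. Support tables are accepted pooled across libraries.
Downstream denominators ("expressed multi-exonic genes") are genes with
≥ 1 kept isoform and ≥ 1 multi-exon isoform.

The upstream alignment-stringency filtering of a spliced aligner (identity
and coverage of the transcript alignment) is assumed already applied to
the input isoform structures.

## FEST extraction

Each event yields two flanking exon sequence tags: FEST1 transcript-
downstream of the alternative junctions, FEST2 upstream, both 30–300 bp,
oriented on the transcribed strand. Tags are taken from exonic sequence
present in **both** witness isoforms, outside the variable region — for
IntronR the exons flanking the spliced intron; for AltD the region ending
at the transcript-proximal donor and the region starting at the shared
acceptor; for AltA symmetrically from the shared donor and the distal
acceptor; for ExonS the flanks of the outer junctions. This is the only
choice that keeps both tags alignable across species for all four types:
the tags then describe the conserved junction context, never the variant
region itself. Long flanks are truncated to the 300 bp nearest the
junction (the junction-proximal context is the conserved signal); events
whose flank would be < 30 bp are dropped from conservation analysis and
logged rather than padded across the next junction — padding would splice
sequence from a different exon into the tag. Tags are identified as
`species|gene|type|coords|festN`, which is parseable and injective.

## Conservation matching

"Aligns well" is made explicit: a qualifying hit is a local alignment with
expectation value ≤ 10⁻⁵ spanning ≥ 30 aligned columns (nucleotide mode:
match +1, mismatch −2, gap open −5, extend −2) or ≥ 10 residues
(translated mode: BLOSUM62, gap open −11, extend −1, best of the 3×3
forward reading-frame pairs — tags are strand-oriented by construction, so
reverse frames are not searched). Expectation values use the
Karlin–Altschul form *E = K·m·n·exp(−λS)* with λ solved numerically for
each scoring scheme (Robinson–Robinson residue frequencies for protein)
and *K* fixed at the standard ungapped constants for these schemes (0.46
nucleotide, 0.13 BLOSUM62); *n* is the total letter count of the
event-type tag database at search time, recorded for reproducibility.
Computing *K* exactly requires the full random-walk machinery and changes
no decision at these thresholds. Gapped optimal scores are never smaller
than ungapped ones, so the calibration errs conservative.

Two events are conserved when they have the same type, their genes share
an orthogroup, and both tag correspondences qualify (FEST1↔FEST1 *and*
FEST2↔FEST2, nucleotide or translated; no cross-pairing, which would
scramble junction orientation). Conserved pairs are edges; clusters are
connected components (single linkage — the simplest rule consistent with
"a cluster of conserved events", and transitive matching through an
intermediate species is scientifically desirable at long distances).
Clusters need ≥ 2 distinct genes and may contain several paralogs of one
species. Only same-orthogroup pairs are ever aligned, so a component can
never span orthogroups (asserted). Cluster ids are assigned in sorted
member order, making output order-invariant.

A note on the translated-rescue property: moderate synonymous divergence
(~30% of wobble positions) leaves nucleotide identity near 90% and still
passes the nucleotide threshold; the regression fixture therefore
randomises *every* synonymous codon choice (~30% overall nucleotide
divergence), which reliably fails nucleotide mode while the identical
peptide qualifies in translated mode.

## WGD categories and ancestral counts

For 1-singleton : 2-homeolog ortholog sets, eligibility requires all three
genes expressed, ≥ 1 multi-exonic member and ≥ 1 event. Conservation for
categorisation is evaluated *within the triplet only* (the three genes are
clustered as a private orthogroup); events conserved with outside species
but not within the triplet still count as 1:0/0:1. Categories — 1:2, 1:1,
0:2 for clustered events by which genes carry them; 1:0/0:1 for
unclustered solo events — partition the set's events, and the labels are
symmetric in the two duplicates. Outgroup information enters only through
the rescue analysis: the fraction of 0:2 events whose *global* cluster
contains a species beyond the singleton/duplicate pair, i.e. events whose
absence from the singleton lineage is most parsimoniously a loss.

On a rooted species tree, counts attach to every non-root internal node:
a cluster is counted at node *v* when it contains ≥ 1 species of *v*'s
sister clade and ≥ *k* species of *v*'s ingroup (descendants), *k* ∈
{1, 2}. Treating *any* sister-clade species as the outgroup generalises
the single-outgroup root computation to internal nodes with multi-species
sisters; a per-node pinned outgroup is possible by restricting the sister
set. *k* = 2 is the guard against counting a single convergent gain as
ancestral and is necessarily ≤ the *k* = 1 count.

## Summary arithmetic

Percentages are rounded half-away-from-zero at the precision the
corresponding summary prints (one decimal for per-species event tables,
integers for conservation tables); the rounding rule is a package choice,
stated because reference material rarely states its own. The multi-species
intron-retention share is the unweighted mean of per-species percentages
(the pooled ratio differs at the integer level). Shipped published counts
(`festcons.published`) are validation *inputs* for this arithmetic, not
package results; one shipped cell (Medicago intron retention) is off by a
final rounding digit relative to its own counts, and the tests assert
agreement to the printed rounding step for that reason.

## Synthetic data

The generator builds an ancestral gene per orthogroup (4–7 exons of
80–300 bp, introns 80–200 bp, ~half of genes on the minus strand), lays
one ortholog per species at identical coordinates, and evolves sequences
by seeded point substitutions only, so orthologous junction context is
preserved by construction — the conservation matcher is tested, not an
aligner's gap model. Events are planted as structural recipes (retention,
donor/acceptor shifts of 35–55 bp, skipping) with the event-type mix of
plant transcriptomes (IntronR 0.56, AltA 0.21, AltD 0.14, ExonS 0.09);
conserved events replicate one recipe across species, and a cross-species
per-orthogroup site registry guarantees that independently planted
lineage-specific events can never converge on one orthologous junction —
the planted cluster list is therefore exact ground truth. Support tables
are written directly (count/depth 5 for supported junctions, 1 for
deliberately weak isoforms); no reads are simulated because the filters
consume counts. Exon minima guarantee every planted event's flanks are
≥ 30 bp.

What the generator does **not** emulate: insertions/deletions, splice-site
motifs and their evolution, expression-level variation, incomplete
transcriptome sampling, assembly artifacts, and gene gain/loss within
orthogroups. Passing tests demonstrate the correctness of event logic,
tag extraction, matching and clustering under controlled divergence; they
do not measure sensitivity on real RNA-seq, where sampling depth and
assembly quality dominate.

## Problem sizes and numerical choices

The test-suite and acceptance script use: 200 random genes for the
event-calling oracle, 60 sequence pairs (60–150 bp, 0–35% divergence) for
the alignment oracle, 200 planted clusters across 3 species at
substitution rate 0 for end-to-end recovery (with rates 0.05/0.10 asserted
at ≥ 95%/≥ 90% sensitivity on smaller runs), and 16 WGD sets across the
five categories. These sizes make the whole suite run in seconds while
exercising every code path; recovery results are stable across seeds.

Other fixed choices: the intron-size utility returns the 99th percentile
of annotated intron lengths with linear interpolation then integer
ceiling; junction keys are strand-aware with donor/acceptor roles derived
from strand rather than stored; empty genomes load with a warning while
duplicate FASTA ids, orthogroup double-membership and overlapping exons
are hard errors; a species with no multi-species clusters gets a zero row
(with a warning) in the pairwise conservation matrix rather than NaNs.

## Known limitations

The AltDA merge rule is a reconstruction of "simultaneous alternative 5′
and 3′ sites" from first principles; other conventions (e.g. counting the
pair as separate AltD and AltA) exist. WU-BLAST-era reporting thresholds
are not public, so the qualifying-hit rule is a documented, configurable
surrogate rather than a re-implementation. Reciprocal-best matching is not
required (either direction suffices), and single-linkage clustering can
chain distantly related events through intermediates — acceptable for
orthogroup-constrained components, but worth remembering when orthogroups
are large.
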