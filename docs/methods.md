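# Methods

This note documents the models, algorithms and numerical choices behind
`pseudotrace`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## The species tree as coordinate system

All events are placed on a rooted, binary, ultrametric species tree with
branch lengths in million years (MY). Ultrametricity is *required*, not
normalized away: the protein-level conservation test divides identities by
divergence ages, which are only well defined when every leaf sits at the same
depth (tolerance: 1e-6 of the reference leaf depth). Divergence time between
two species is the age of their LCA below the present, not the leaf-to-leaf
path length.

## Gene phylogeny and reconciliation

The family tree is distance-based: the homologs are aligned together (MAFFT,
run with fixed deterministic options `--retree 2 --maxiterate 0`), each pair
is scored over its mutually ungapped columns as `d = -ln(1 - p)` with `p` the
mismatch proportion (saturated pairs, `p >= 0.95`, are capped at 5.0 with a
warning), and the matrix goes through standard Saitou–Nei neighbor joining.
NJ ties on the Q criterion are broken by the lexicographically smallest label
pair, where a cluster is identified by its smallest leaf label, so the
topology is reproducible. The unrooted tree is rooted at the edge minimizing
the number of duplications implied by reconciliation, with ties broken by the
midpoint criterion and then by the lexicographically smallest left leaf set.

Reconciliation is plain LCA mapping: each gene-tree node maps to the
species-tree LCA of its descendant species; a node is a duplication iff its
mapping equals a child's. The ortholog group containing the query at a chosen
ancestor is read off the query-to-root path: among speciation nodes mapping
to the ancestor or below, the one whose mapping is closest to the ancestor
wins (nearest the root on mapping ties). Distance/NJ is a deliberate
simplification of likelihood-based tree building: the downstream logic
consumes only a labeled topology, and the rooting criterion ("fewest
duplications") encodes the same parsimony bias a curated family tree would.

Orthology of a sequence recovered from a genome is re-checked by inserting it
into a gene tree with the group: it is accepted when its LCA with at least
one group member is a speciation node. Two guards make the check robust:
a hit whose identity to the search reference already reaches the test-1
similarity threshold is accepted directly (duplication labels on a tree of
near-identical sequences are arbitrary), and the annotated-gene check (below)
runs first, so a database gene eliminated by the phylogeny is still
recognized as Present.

## Translated search and locus extraction

The search is seed-and-extend: exact protein 4-mers (configurable) of the
reference are matched against all six reading frames, seeds sharing a
diagonal are extended to the maximal-scoring ungapped segment (BLOSUM62;
Kadane's algorithm on per-position scores), and segments above 50 matrix
units are reported. An in-frame stop codon scores −6 — a strong mismatch —
but does not terminate the segment, which is what lets pseudogenized loci
surface. Gapped extension is deliberately omitted: chaining absorbs
indel-split hits, and hits are only signposts for locus extraction, not final
alignments. Hits on one chromosome and strand, collinear in both genome and
protein order, with genomic gaps ≤ 50 kb (intron allowance) and protein
overlaps ≤ 5 aa, are chained greedily in descending score order. The locus is
the chained span ± 5 kb, clamped to the chromosome and reverse-complemented
for minus-strand candidates, with the offset kept so local coordinates map
back to the genome.

## Gene prediction

`predict_protein` is a spliced alignment of the reference protein against the
locus: codons are consumed 3 nt at a time (BLOSUM62 against the reference
residue), reference residues may be skipped and extra codons inserted at −12
each, and an intron (flat −15) may open between codons at a GT donor and
close ≥ 20 nt later at an AG acceptor. Stop codons are barred from exons
outright, so the optimum must trim, splice out, or walk around nonsense
codons — exactly the behavior that makes a shrinking prediction a
pseudogenization signal. The alignment is local on both sequences (a
prediction may cover part of the reference); the result is rejected below 40%
of the reference self-score. Introns are modeled phase-0 (between codons)
only; a phase-1/2 intron in real data would surface as a slightly shortened
prediction around the junction rather than a wrong frame. The per-row
dynamic program is vectorized: the insertion chain is a prefix-max in a gauge
where each step costs a constant, reset at stop codons, and intron jumps are
a delayed prefix-max over donor positions; all penalties are integral so
traceback can re-derive decisions by exact equality.

## The decision tests

**Test 1 (signal gate).** Both the translated hit and the prediction are
compared to the reference by Needleman–Wunsch global alignment (BLOSUM62,
gap open 10, extend 0.5, end gaps penalized; Biopython's PairwiseAligner).
Identity is counted over the full alignment length including gap columns, so
truncation hurts identity as well as the separate length ratio
(100 × candidate/reference length). If *either* sequence reaches both
thresholds (defaults: 50% identity, 60% length), the study proceeds to the
nucleotide level. Both sequences are tested because nonsense codons shorten
predictions while barely affecting translated hits.

**Test 2 (conservation).** Identity is assumed inversely proportional to
divergence age. With knowns at distinct LCAs, the verdict is a direct
comparison (candidate vs nearer known must beat the more divergent known
pair). With one shared LCA, the most divergent known pair (D2, Value2)
calibrates the decay and the candidate pair (D1, Value1) must satisfy
`Value1 > D2·Value2/D1`. The division is by the candidate pair's divergence
D1: this is the only reading under which the threshold reduces to Value2 when
the two pairs coincide. When several knowns tie (same LCA ⇒ same D1), Value1
is the best identity to a calibration-pair member — the benefit of the doubt
goes to "gene". The verdict is scale-invariant in (D1, D2) and monotone in
Value1 by construction.

**Test 3 (reconstruction set).** At most one sequence per species enters the
reconstruction; knowns whose protein identity to the query falls below
(100 − max divergence, default 60) are dropped; fewer than 3 surviving
sequences aborts to the protein-level verdict.

## Guided alignment, ancestors, and the scan

All loci selected for one study are aligned together (MAFFT, deterministic
options) and compacted to the reference exon projection ± 20 nt — enough to
keep every splice dinucleotide plus context in view. Insertions of other rows
*inside* an exon's span survive compaction (they are evidence); interior
intron bulk does not. Ancestral rows for every internal node of the guide
tree are reconstructed column-wise by Sankoff parsimony over `{A,C,G,T,-}`
with unit cost for every state change (substitutions and gap transitions
alike); ties are resolved in a preorder pass preferring the parent's state,
then the fixed order A, C, G, T, gap. By default the guide tree is the
species tree restricted to the reconstruction taxa, which makes every scanned
branch a species-tree branch and branch attribution exact; an NJ guide on
closed-form TN93 distances over the compacted columns is available
(`force_species_tree: false`) for cases where incomplete lineage sorting is a
concern — TN93 is the closed-form stand-in for an HKY-type model, needing no
numerical optimization.

Each branch is scanned descendant-vs-ancestor inside the projected exons:
codons are read in the frame carried across junctions from the reference
annotation; a stop codon gained by the descendant is a nonsense mutation
(start and terminator positions are classified separately as start/stop
loss); gap runs present in one row only are insertions/deletions, with a
derived frameshift record when the length is not a multiple of 3 (the
frameshift is an annotation of the causal indel, not an independent event);
donor/acceptor dinucleotides are compared in the retained flanks; an exon
≥ 90% gapped in the descendant but < 50% in the ancestor is an exon loss
(both thresholds are package choices). Mutations found on
ancestor-vs-ancestor branches are reported once, on that internal branch, and
inherited by every target below — which is why all recovered loci are
reconstructed *jointly*: sister pseudogenes sharing a mutation place it on
their common stem. Exon boundaries that align to gaps in at least half the
rows flag the exon low-confidence in the report: a misprojected boundary
shifts the scanning frame silently, and flagged exons should be reviewed
rather than trusted.

A sequence is classified a pseudogene iff its path carries at least one
mutation of a disabling kind (nonsense, frameshift, splice change, start/stop
loss, exon loss); in-frame indels alone never condemn.

## Event synthesis

Leaf verdicts map to ancestral states as Present/Saved → Gene,
Pseudogene → Pseudogene, Lost → Absent. Sankoff parsimony runs under the
irreversibility costs Gene→Pseudogene = Gene→Absent = Pseudogene→Absent = 1,
reversals = ∞, diagonal 0 (configurable); a Lost leaf under a Pseudogene
ancestor is modeled as erosion to undetectability (cost 1). Saved collapses
into Gene for ancestors because "saved" is provenance (how the gene was
found), not a distinct biological state. Ties prefer Gene, then Pseudogene.
Every parent→child state change is an event on that branch; the gene birth
is the highest node assigned Gene. Simple mode uses Dollo parsimony directly
on presence/absence: birth at the LCA of present species, one loss on the
stem of each maximal absent clade — provably minimal (checked against
exhaustive subset search in the tests).

## The synthetic-data generator

The generator is the package's test substrate and defines its validation
conditions. The root gene has 5 exons × 90 nt (ATG first, TAA terminator,
GT..AG introns of 80 nt, phase 0) — mid-sized and multi-exon, like the genes
such studies target, so that losing any one exon leaves most of the protein
intact and every planted event class remains analyzable. The root protein is
drawn from a codon-diverse residue pool and back-translated with
most-frequent human codons; intergenic flanks (2 kb per side) are generated
once at the root and inherited down the tree, as homologous flanking DNA in
real congeneric genomes is. Evolution is uniform substitution at 0.02
substitutions/site/100 MY by default (Poisson per branch, transitions twice
as likely as transversions). Losses excise the gene; pseudogenization
recipes apply explicit nonsense/indel/splice/exon-loss edits at recorded
reference-frame positions and withhold the species from proteome and
annotations; "saved" species are withheld from annotations only.

Two constraints keep the truth ledger deterministic: background
substitutions never create an in-frame stop and never touch the start codon,
terminator, splice dinucleotides or planted mutation sites; and planted
indels are placed ≥ 12 nt from exon boundaries, ≥ 9 nt from planted nonsense
codons, and only where no nearby offset (± 6 nt) would produce an identical
edited sequence — otherwise the alignment could legitimately place the gap
elsewhere and "exact position" would be ill-defined. These constraints are
what the generator does *not* emulate about real data, along with: no rate
heterogeneity or codon model, no segmental duplication or gene conversion,
no polymorphism, no assembly gaps, single-copy families only, plus-strand
placement in generated genomes (minus-strand handling is exercised by unit
tests at the search/extraction layer). Passing the recovery tests therefore
shows the pipeline's logic is sound under its stated model — not that real
genomes, with their messier alignments and annotation errors, will yield
100% recovery.

## Problem sizes and runtime choices

Validation studies use a 5-species tree with ~4.8 kb genomes per species;
recovery rates are measured over 20 seeded scenarios per condition
(substitution rate 0 for exact-position recovery, 0.02–0.05 for rate
robustness), and oracle agreement over exhaustive small cases (all alignment
pairs at lengths ≤ 6 over a two-letter alphabet; all 3⁴ leaf labelings on 4
leaves) plus seeded random batches (1,000 alignment pairs, 100 additive
matrices, 200 gene trees, 500 eight-leaf labelings). The reconstruction stage
receives a tight locus (hit span + 200 nt) rather than the full 5 kb
prediction locus: non-homologous tail sequence contributes nothing and can
only mislead the aligner near the terminal exon.

## Known limitations

- Insertion-vs-deletion polarity comes from parsimony gap states on the two
  branch endpoints; on deep branches with few taxa the polarity can flip
  relative to a probabilistic indel model.
- The scanner reads only positions opposite the projected reference exons; a
  mis-projected boundary (flagged low-confidence, not corrected) can hide a
  frameshift at the exon edge.
- The conservation test assumes clock-like protein divergence; a gene under
  accelerated evolution in one lineage can be called a putative pseudogene at
  protein level without nucleotide evidence (the report's `test2_failure_flag`
  marks such verdicts).
- Simple mode cannot distinguish deletion from pseudogenization — by design,
  it is meant for old losses whose traces have eroded.
- Phase-0 introns only in prediction; non-canonical splice sites are never
  *predicted* (they are *detected* as splice mutations by the scanner).
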