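# pseudotrace

Automated detection and forensic analysis of **lineage-specific gene losses**
and **unitary pseudogenes** on a dated species tree.

A well-established ancestral gene is normally found, in one or more copies,
in every descendant species. Sometimes all representatives disappear in one
lineage — by outright deletion of the locus, or by pseudogenization: a
disabling mutation inactivates the gene, selection stops acting, and the
sequence erodes until it is unrecognizable. While the erosion is still
partial, the disabling mutations remain readable in the genome. `pseudotrace`
takes a query protein, a rooted ultrametric species tree (branch lengths in
million years), per-species proteomes and (optionally) genomes, and for every
species of the study set decides whether a representative of the query's
family is **Present**, **Saved** (intact in the genome but missing from the
annotations), a **Pseudogene** (with its disabling mutations characterized
and dated branch-by-branch), or **Lost**, and places every inferred event on
the species tree.

It is intended for molecular evolutionists studying gene-family retention:
"which lineages lost this gene, when, and by what mutations?"

## Method

The pipeline runs in three phases.

**Phase 1 — detection.** Proteome homologs of the query are collected and a
gene phylogeny is built (pairwise distances from a multiple protein
alignment, neighbor joining, rooting that minimizes inferred duplications).
The gene tree is reconciled with the species tree by LCA mapping: a node is a
*duplication* when its mapping equals a child's, otherwise a *speciation*.
The ortholog group is the leaf set under the speciation node established at
the chosen ancestor (or the next speciation node toward the leaves); species
of the study set with no member in the group are candidates for
lineage-specific loss. In *simple* mode the analysis stops here and a
Dollo-like parsimony (single birth at the LCA of the present species, one
irreversible loss per maximal absent clade) places the losses.

**Phase 2 — rescue.** In *complete* mode each candidate genome is searched
with a six-frame translated seed-and-extend scan (BLOSUM62) using the
ortholog of the phylogenetically closest species as reference; in-frame stop
codons penalize but do not break a hit, so degraded pseudogenes stay
findable. Collinear hits on one chromosome and strand are chained into locus
candidates. No hit means **Lost**. Otherwise each candidate locus is checked:
an annotated gene already described at the location means **Present**;
otherwise a reference-guided spliced alignment predicts the most similar
protein the locus can still encode (codon-level dynamic programming, introns
only at GT..AG, stop codons excluded from exons). A signal gate (test 1)
routes the study: if either the translated hit or the prediction reaches the
identity and length-ratio thresholds against the reference, the locus is
clean enough for nucleotide-level forensics; otherwise the verdict comes from
protein conservation alone.

*Protein level (test 2).* Sequence identity within an ortholog group is
assumed inversely proportional to divergence time. With knowns at unequal
LCAs from the candidate, the candidate must be more similar to its nearer
known than the two knowns are to each other. With a single shared LCA, a
calibration pair of knowns at divergence `D2` and identity `Value2` sets the
minimum expected identity at the candidate pair's divergence `D1`:

```
threshold = D2 * Value2 / D1        # putative gene iff Value1 > threshold
```

*Nucleotide level (test 3 + scan).* All recovered loci plus the
not-too-divergent known loci (one sequence per species) are aligned together,
the alignment is compacted to the reference exon regions (keeping a short
intron flank so splice dinucleotides stay visible), and ancestral rows are
reconstructed for every internal node by Sankoff parsimony over
`{A,C,G,T,-}`. Each branch is then scanned descendant-vs-ancestor in the
reading frame projected from an annotated reference gene, emitting: start/stop
codon loss, nonsense codons, insertions and deletions (flagged as frameshifts
when the length is not a multiple of 3), splice-site changes, and exon
losses. A mutation first seen on an ancestor-vs-ancestor comparison is
reported once, on that internal branch. Any disabling mutation on a
candidate's path makes it a **Pseudogene**; a clean scan means **Saved**.

**Phase 3 — synthesis.** Leaf verdicts become ancestral states
(`Gene`/`Pseudogene`/`Absent`) by Sankoff parsimony under an irreversibility
cost matrix (a pseudogene never reverts; an absent gene never returns). Every
parent-to-child state change is an event on that branch; pseudogenization
branches carry their mutation inventories; the gene birth is the highest node
assigned `Gene`. The result is a JSON report plus an NHX-annotated Newick
tree.

A seeded synthetic-data generator (`pseudotrace.synth_data`) produces
complete study inputs — a gene family evolved along the species tree with
planted losses and pseudogenization recipes, embedded in inherited intergenic
DNA — together with a machine-readable truth ledger, so the whole pipeline
can be validated against known ground truth.

## Worked example

Simulate a five-species study with a gene loss in rat, a pseudogenization in
human (one nonsense codon plus a 4-nt insertion), and an intact but
un-annotated gene in macaque; then analyze it:

```bash
cat > params.yaml <<'EOF'
tree: "(((Hsa:6,Ptr:6)Hpa:19,Mmu:25)Ctr:65,(Mus:20,Rno:20)Mur:70)Eth;"
subst_rate: 0.02
planted_events:
  - branch: [Mur, Rno]
    kind: loss
  - branch: [Hpa, Hsa]
    kind: pseudogenization
    recipe: [[nonsense], [insertion, 4]]
unannotated_species: [Mmu]
EOF

pseudotrace simulate --params params.yaml --seed 11 --out data
pseudotrace run --query data/proteomes/Ptr.fa \
    --proteomes data/proteomes --genomes data/genomes \
    --species-tree data/species_tree.nwk --exons data/exons.tsv \
    --ancestor Eth --mode complete --out study
```

which prints

```
verdicts: {'Mus': 'Present', 'Ptr': 'Present', 'Rno': 'Lost', 'Hsa': 'Pseudogene', 'Mmu': 'Saved'}
birth node: Eth; 2 event(s) placed
```

`study/mutations.tsv` lists the disabling mutations with their branch
attribution (positions are 0-based within the projected exon; the frameshift
row is derived from the causal insertion):

```
branch	kind	exon	position	detail
Hpa->Hsa	insertion	2	27	4
Hpa->Hsa	frameshift	2	27	4
Hpa->Hsa	nonsense	3	18	TAA
```

This matches the generator's truth ledger (`data/truth.json`) exactly: the
4-nt insertion was planted at offset 27 of exon 2 and the TAA nonsense codon
at codon 18 of exon 3, both on the branch from the Homo/Pan ancestor to
human. `study/events.nhx` carries the same verdicts and events as NHX tags on
the species tree, and `study/report.json` holds the full evidence chain
(hits, predictions, test outcomes) per species.

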