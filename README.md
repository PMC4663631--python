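# mitokaryo

Comparative analysis of **fragmented mitochondrial genomes** ("mitochondrial
karyotypes") in parasitic lice.

Most bilaterian animals carry a single circular mitochondrial chromosome with
37 genes. Sucking lice (Anoplura) and the elephant louse lineage
(Rhynchophthirina) instead carry 9–20 **minichromosomes**, each a small circle
pairing a distinct coding region with a shared, repeat-bearing non-coding
region (NCR). This package implements the comparative machinery such a study
needs, end to end, with a synthetic-data generator so every stage is testable
offline:

- **Karyotype notation** — parse/format gene-arrangement strings
  ("hyphens link neighbouring genes on the same minichromosome, commas
  separate minichromosomes"; a leading `-` marks minority-strand
  transcription), gene inventories and summaries.
- **Adjacency characters** — strand-aware, transcription-direction gene
  adjacencies (an ordered pair `u→v` with no NCR or strand switch between
  the genes), polarized against the packaged insect ground-pattern
  arrangement: a character is *ancestral* iff it occurs in the ground
  pattern, else *derived*. Presence/absence character matrices and
  shared-exclusive character screens.
- **Ancestral inference** — Fitch (unit-cost Sankoff, with full
  most-parsimonious state sets and explicit ambiguity) and Dollo
  reconstruction of karyotype features at the Anoplura+Rhynchophthirina
  most recent common ancestor on a fixed phylogeny; Spearman rank test of
  the life-cycle-length vs fragmentation association.
- **Concerted evolution** — from-scratch p-distance (pairwise deletion),
  neighbor joining (Q criterion), column bootstrap, and classification of
  each species' trnL1(tag)/trnL2(taa) paralog pair as *concerted* (the two
  copies group together, the signature of gene conversion), *independent*
  (each copy groups with its orthologs) or *unresolved*.
- **Minicircle assembly** — a small greedy overlap-layout-consensus
  assembler honouring four explicit thresholds (minimum overlap 100 bp,
  minimum overlap identity 90%, maximum gaps per read 10%, maximum gap size
  10 bp for the long-read preset; 70 bp/90%/5%/5 bp for the short-read
  preset), with circularization, rotation normalization, heteroplasmy
  calling (inclusive 50x coverage / 10% minor-allele thresholds) and
  tandem-repeat detection.
- **Synthetic data** — fragmentation of the ancestral circle into k
  minichromosomes, minichromosome sequences with a shared GC-controlled
  NCR (tandem-repeat arrays, conserved anchor motif, >=97% cross-copy
  identity), long variable-length (100–611 bp, mean 344, sd 108) and short
  fixed-length (90 bp) read profiles, injected heteroplasmy, and paralog
  pairs evolving with or without gene conversion — all pure functions of a
  seeded configuration with full ground truth.

## Worked example

```python
import mitokaryo as mk
from mitokaryo import reference

elephant = reference.load_elephant_karyotype()
ancestral = reference.load_ancestral_arrangement()

print(mk.karyotype_summary(elephant))
# {'n_minichromosomes': 10, 'genes_per_minichromosome': (2, 6),
#  'minus_strand_genes': {'T', 'Q', 'nad1'}}

inv = mk.gene_inventory(elephant)
print(len(inv["distinct"]), sorted(inv["missing"]))
# 33 ['D', 'N', 'S1', 'nad2']

shared = mk.extract_adjacencies(elephant) & mk.extract_adjacencies(ancestral)
print(sorted(map(str, shared)))
# ['G-nad3', 'H-nad5', 'atp8-atp6']
```

The elephant louse keeps 33 of the 37 genes on 10 minichromosomes (2–6 genes
each, with trnT/nad1/trnQ as a minus-strand cluster and trnE duplicated), and
retains exactly three ground-pattern adjacencies — everything else about its
gene order is derived. Building the character matrix for the four derived
characters `L1-rrnL`, `L2-rrnS`, `T-nad1-Q` and `rrnL-V` across the packaged
louse karyotypes shows them present only in the elephant louse + sucking
lice, the gene-order evidence for the sister-group relationship of the two
suborders:

```python
m = mk.build_character_matrix(
    list(reference.load_reference_karyotypes().values()),
    ["L1-rrnL", "L2-rrnS", "T-nad1-Q", "rrnL-V"], ancestral)
print([str(c) for c in mk.shared_exclusive_characters(
    m, set(reference.INGROUP_SPECIES))])
# ['L1-rrnL', 'L2-rrnS', 'T-nad1-Q', 'rrnL-V']
```

A CLI mirrors the library: `mitokaryo parse`, `adjacency`, `matrix`,
`infer-mrca`, `concerted`, `assemble`, `simulate` (see `mitokaryo --help`).

## Fixture provenance

The elephant-louse karyotype and minichromosome lengths are transcribed from
the published genome report (GenBank KF933032–KF933041). The anopluran
karyotypes are *reconstructions* constrained by the published
minichromosome counts, shared-character states, solo-gene and
cluster-orientation statements — gene placements not fixed by those sources
were chosen here and are flagged in the fixture's provenance column; they
are suitable for exercising the analyses, not for citation as literature
arrangements. Outgroup taxa carry the ancestral single-chromosome
arrangement as a documented stand-in. Analyses that need the deposited
minichromosome sequences accept user-supplied FASTA files via
`mitokaryo.assembly.read_fasta_sequences`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the package's main computations from scratch — karyotype parsing and
summaries, the shared-character screen, MRCA feature inference, the
life-cycle association, paralog-regime classification on freshly simulated
alignments, and a simulate-assemble-call round trip (contig counts,
circularity, heteroplasmy, NCR GC and tandem repeats) — printing each result
and writing the results file.
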