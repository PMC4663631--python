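# Methods

This note documents the models, conventions and numerical choices behind
`mitokaryo`, and what its synthetic-data tests do and do not establish.

## Karyotype model and text notation

A mitochondrial karyotype is a set of minichromosomes; each minichromosome
is a circular molecule with one non-coding region (NCR) and an ordered,
stranded gene list drawn from the canonical 37-gene animal mitochondrial
vocabulary (13 protein-coding, 2 rRNA, 22 tRNA; L1(tag)/L2(taa) and
S1(tct)/S2(tga) are distinct symbols). Token normalization accepts the
spellings that circulate in gene-arrangement tables (`trnI`, `I`,
`trnL1(tag)`, `L1`, case variants of `nad4L`); bare `L`/`S` are ambiguous
and rejected.

Orientation is stored relative to the reference direction defined by the
shared NCR (+1 = majority strand). The gene list begins at the first gene
downstream of the NCR, fixing the rotation of the circle.

**Reading convention (important).** A karyotype string lists the genes of
each same-strand run in *transcription* order; the sign only marks which
strand the run lies on. So `-T--nad1--Q` denotes a minus-strand cluster
read T→nad1→Q, and contributes the adjacencies T→nad1 and nad1→Q. This is
the convention under which (a) reversing all of a minichromosome's
orientation flags leaves its adjacency set unchanged, and (b) the
cluster's published name matches its adjacency content. The one exception
is the packaged ancestral arrangement (below), which is stored in physical
map order because that is how ground-pattern gene orders are tabulated;
its minus-strand runs are reversed during adjacency extraction.

## Adjacency characters and polarity

An adjacency is an ordered pair of genes that are immediate neighbours in
transcription direction on the same strand, with no NCR/control region and
no strand switch between them. Direction is essential: in the insect
ground pattern the rRNA block is transcribed rrnS→V→rrnL→L1→nad1, so
rrnL→L1 is ancestral while L1→rrnL — the arrangement found in the lice —
is derived, even though the two genes are map neighbours in both.

The polarizing standard is the single-chromosome pancrustacean/insect
ground pattern (Drosophila-type order), packaged with its control region
marked; the control region breaks adjacency exactly as an NCR does. A
character (single adjacency or a composite conjunction such as `T-nad1-Q`
= T→nad1 ∧ nad1→Q) is *ancestral* iff all member adjacencies occur in the
ground pattern, else *derived*.

## Ancestral-state inference

Binary characters scored on the tips (adjacency presence, "solo-gene"
predicates — a protein-coding or rRNA gene sharing its minichromosome with
no other protein-coding/rRNA gene — and the minus-strand T-nad1-Q cluster)
are optimized on a fixed rooted topology. Genes never identified in a
species make the character *missing data* at that tip (admitting both
states), not absent.

- **Fitch (default):** unit-cost Sankoff dynamic programming; an up pass
  for subtree costs and a down pass for whole-tree conditional costs, so
  each node reports the exact set of states it takes across all
  most-parsimonious reconstructions. Ties (e.g. a dual-gain reconstruction
  costing the same as gain-plus-loss) are reported as *ambiguous*, never
  silently resolved.
- **Dollo (option):** the character is gained once — at the MRCA of all
  carriers — and can only be lost. This is the standard assumption for
  rare genomic changes like gene-order characters, where parallel gain of
  the same derived adjacency is considered implausible. On the packaged
  fixtures, characters carried only by the elephant louse and a minority
  of sucking lice (T-nad1-Q, L2-rrnS, rrnL-V, L1-rrnL-V) are Fitch-
  ambiguous at the ingroup MRCA but Dollo-present; the package reports
  both rather than privileging either reading.

The life-cycle/fragmentation association is a Spearman rank correlation
(scipy, midranks for ties) between the midpoint of each species' published
life-cycle range and its minichromosome count; the packaged four records
give rho = −1 (a perfect inverse ranking), which with n = 4 is suggestive,
not significant.

## Concerted-evolution engine

Distances are uncorrected p-distances with pairwise deletion (sites with a
gap or N in either sequence are excluded per pair) — chosen to preserve
signal in short tRNA alignments; a divergence risk versus complete
deletion is accepted and noted. Neighbor joining follows the classical Q
criterion; ties are broken by the lexicographic order of the joined
clusters' smallest leaf labels, and a negative branch length is clamped to
zero with the deficit moved to its sibling (preserving the pair's
distance). NJ recovers the generating topology exactly on additive inputs
(property-tested). Bootstrap resamples alignment columns with replacement
(default 500 replicates — the desk-scale stand-in for the conventional
5,000 — under a mandatory seed) and reports bipartition frequencies.

A species' trnL1/trnL2 pair is *concerted* when some split of the tree
gathers the species' own paralogs apart from all other species (for a
two-copy species, a cherry); *independent* when the L1 leaf lies in an
all-L1 split with at least one other species and the L2 leaf does so
symmetrically; otherwise *unresolved*.

## Minicircle assembler

A deliberately small greedy overlap-layout-consensus assembler built
around four explicit thresholds: minimum overlap length, minimum overlap
identity, maximum gap fraction per read and maximum gap size. Presets:
long variable-length reads 100 bp / 90% / 10% / 10 bp; short fixed-length
reads 70 bp / 90% / 5% / 5 bp. All threshold comparisons are inclusive
(boundary behaviour is unstated in assembler folklore; inclusive is
documented and tested at the boundary). Gap columns (not gap opens) count
toward the per-read gap budget.

Mechanics: the longest unused read seeds a contig, which is repeatedly
extended by the qualifying unused read with the longest end overlap (ties:
higher identity, then smaller read id); fully contained reads are absorbed
each sweep. Overlaps are evaluated gap-free (Hamming) first, with a banded
dynamic-programming fallback within the gap limits. After extension
stalls, a self-overlap of the contig's two ends meeting the same
thresholds marks it circular and trims the duplicated segment (the best
gap-free self-overlap is preferred, because a gapped aligner can also
"match" a slightly rotated circle). The consensus is the per-column
majority over all placements (ties alphabetical; columns wrap modulo the
circle length), so a greedy mis-threading is corrected wherever coverage
is honest. This is greedy longest-overlap *extension* rather than a global
longest-pair-first merge queue — same thresholds, same acceptance
behaviour, simpler state.

Limitations: no quality-aware error correction, no scaffolding, and no
reverse-complement overlap search (reads are modelled strand-resolved, as
for amplicons of a known template); near-identical NCRs shared between
distinct minichromosomes will chimerize if amplicons include NCR stretches
at or above the minimum overlap — which is exactly why the emulated
protocol amplifies coding regions with primers sitting in the conserved
NCR close to the coding region.

Heteroplasmy calling: a site is reported iff called-base coverage ≥ 50 and
the most frequent alternative base reaches a 10% minor-allele fraction
(both inclusive; both parameters exposed).

Tandem repeats: for every candidate period d the sequence is compared with
itself shifted by d; maximal regions whose length-d windows match the next
copy at or above the identity floor become candidate arrays (copy number =
region length / d, fractional); overlapping candidates — harmonics,
off-by-one periods — are resolved by the highest copies × identity score.
Arrays shorter than two full copies are not reported.

## Synthetic-data generator

Every generator is a pure function of a seeded configuration and returns
its ground truth. The stated world mirrors the emulated study system:

- **Fragmentation:** the ancestral circle is cut at the control region
  plus k−1 random junctions; cutting can only remove adjacencies, so any
  derived adjacency traces to a recorded single-gene excision/reinsertion
  event (with optional strand flip).
- **Sequences:** gene placeholders of realistic animal-mtDNA lengths
  (tRNA 65 bp, rRNA 750/1,200 bp, proteins 159–1,719 bp; duplicated genes
  share one sequence, emulating the identical trnE copies), plus a shared
  NCR: GC-controlled background (default 40%, the unusual GC-rich NCR of
  the emulated genome), tandem-repeat arrays (defaults 225 bp × 4 and
  346 bp × 2 at ~85% pairwise copy identity), a conserved 20-bp anchor
  motif at the NCR 3' end, and ~1% divergence between minichromosome NCR
  copies (the observed floor is 97% identity). Background sequences use
  exact-composition sampling and NCR divergence uses composition-
  preserving base permutation, so the stated GC is realized exactly —
  appropriate for a stand-in for a fixed real sequence.
- **Reads:** truncated-normal long reads (mean 344, sd 108, range
  100–611 bp; only these moments are published, hence the truncated
  normal) or fixed 90-bp short reads; wrap-around starts on circular
  templates; clipped overhangs on linear amplicons so ends get interior
  coverage; per-base substitution errors; heteroplasmy injected per read
  at the configured minor-allele frequency.
- **Paralog pairs:** duplication at the root (total depth 0.45
  substitutions/site), simultaneous species splits at depth 0.15 —
  reflecting the fast interspecific divergence of louse mitochondrial
  tRNAs — and, under the concerted regime, Poisson(5) gene-conversion
  events per terminal branch copying tracts that span at least half the
  gene, reproducing the observed near-complete homogenization. Three
  consecutive sites (default 35–37, the region downstream of the third
  anticodon position) are frozen and never converted, so converted pairs
  still differ at exactly three positions.

What a green synthetic test establishes: the algorithms are correct on
data with the assumed structure (substitution-only errors, strand-resolved
reads, NCR-shared minichromosomes, the stated read-length moments). What
it does not: robustness to indel-rich platforms, primer artefacts,
chimeric PCR, nuclear mitochondrial insertions, or alignment error in real
tRNA alignments. Scaled-down worlds (gene lengths × 0.4–0.5, NCR ~1.2 kb,
amplicon flanks 30 bp) are used in tests for runtime only; the mechanics
are scale-free.

## Numerical and degenerate-input choices

- Parsing rejects unknown tokens with the token and position; empty groups
  and dangling signs are errors.
- `gene_inventory` counts a duplicated gene once in `distinct` (the
  convention behind "33 genes") and per copy in `occurrences`; both counts
  are exposed rather than guessing which a reader wants.
- Fitch requires a state (or explicit missing data) for every tip;
  contradictory constraints raise.
- p-distance raises on zero comparable sites; NJ requires ≥3 taxa and a
  symmetric, zero-diagonal matrix.
- The assembler raises on an empty read set and on duplicate read ids;
  rotation normalization is only defined for circular contigs and raises
  when the anchor is absent on both strands.
- All stochastic operations take an explicit seed; fixed seed ⇒ identical
  output, byte for byte.

## Known limitations

- The anopluran fixture karyotypes are reconstructions constrained by
  published counts and character states, not verbatim transcriptions of
  the cited genome reports (see the provenance column in the fixture
  file); conclusions that depend on gene placements those sources do not
  fix should be re-run against user-supplied karyotype files.
- The fixed tree is an input; the package deliberately implements no tree
  inference, so phylogenomic support values are out of scope.
- Concerted/independent classification is topological; the per-window mode
  (`classify_paralog_windows`) supports part-gene conversion analyses
  (identical arms with divergent arms elsewhere), but window boundaries
  are a user choice — no default boundary is claimed.
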