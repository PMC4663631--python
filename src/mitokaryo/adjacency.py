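"""Strand-aware gene-adjacency characters and their polarity.

An adjacency is an *ordered* pair of genes that are immediate neighbours in
transcription direction on the same strand, with no non-coding/control
region between them.  Direction matters: rrnL→L1 is part of the insect
ground pattern while L1→rrnL is a derived rearrangement, even though the
two genes are map neighbours in both.  A composite character (``T-nad1-Q``,
``L1-rrnL-V``) is the conjunction of its member adjacencies.

Polarity is assessed against the ancestral single-chromosome arrangement:
a character is *ancestral* iff every member adjacency occurs in the ground
pattern, otherwise *derived*.
"""

from __future__ import annotations

from dataclasses import dataclass

from .genes import GeneSymbol, gene
from .karyotype import AncestralArrangement, GeneCopy, MitoKaryotype, Minichromosome


@dataclass(frozen=True)
class Adjacency:
    """Ordered gene pair in transcription direction (upstream→downstream)."""

    upstream: GeneSymbol
    downstream: GeneSymbol

    def __str__(self) -> str:
        return f"{self.upstream}-{self.downstream}"


@dataclass(frozen=True)
class CompositeCharacter:
    """A named conjunction of adjacencies; present iff all members are."""

    name: str
    adjacencies: tuple[Adjacency, ...]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


Character = Adjacency | CompositeCharacter


def character(spec: str) -> Character:
    """Build a character from a hyphenated gene chain, e.g. ``"T-nad1-Q"``.

    Two genes give a plain adjacency; longer chains give a composite of the
    consecutive pairs.
    """
    symbols = [gene(tok) for tok in spec.split("-") if tok]
    if len(symbols) < 2:
        raise ValueError(f"a character needs at least two genes: {spec!r}")
    pairs = tuple(Adjacency(a, b) for a, b in zip(symbols, symbols[1:]))
    if len(pairs) == 1:
        return pairs[0]
    return CompositeCharacter("-".join(s.name for s in symbols), pairs)


def _member_adjacencies(c: Character) -> tuple[Adjacency, ...]:
    return (c,) if isinstance(c, Adjacency) else c.adjacencies


def _runs(genes: tuple[GeneCopy, ...]):
    """Maximal runs of consecutive same-orientation genes."""
    run: list[GeneCopy] = []
    for g in genes:
        if run and g.orientation != run[-1].orientation:
            yield run
            run = []
        run.append(g)
    if run:
        yield run


def extract_adjacencies(k: MitoKaryotype | AncestralArrangement | Minichromosome
                        ) -> frozenset[Adjacency]:
    """Transcription-direction adjacency set of a karyotype or arrangement.

    Pairs never span an NCR/control region or a strand switch.  Karyotype
    gene lists are already transcription-ordered within each run; the
    ancestral arrangement is map-ordered, so its minus-strand runs are read
    in reverse map order.
    """
    if isinstance(k, AncestralArrangement):
        genes = k.genes[k.control_region_index:] + k.genes[:k.control_region_index]
        pairs = set()
        for run in _runs(genes):
            ordered = run[::-1] if run[0].orientation == -1 else run
            pairs.update(Adjacency(a.symbol, b.symbol)
                         for a, b in zip(ordered, ordered[1:]))
        return frozenset(pairs)
    minis = (k,) if isinstance(k, Minichromosome) else k.minichromosomes
    pairs = set()
    for mc in minis:
        for run in _runs(mc.genes):
            pairs.update(Adjacency(a.symbol, b.symbol)
                         for a, b in zip(run, run[1:]))
    return frozenset(pairs)


def has_character(k: MitoKaryotype, c: Character) -> bool:
    return set(_member_adjacencies(c)) <= extract_adjacencies(k)


def classify_polarity(c: Character, ancestral: AncestralArrangement) -> str:
    """``"ancestral"`` iff every member adjacency is in the ground pattern."""
    anc = extract_adjacencies(ancestral)
    return "ancestral" if set(_member_adjacencies(c)) <= anc else "derived"


# ---------------------------------------------------------------------------
# character matrix

@dataclass(frozen=True)
class CharacterMatrix:
    """Presence/absence of arrangement characters across taxa."""

    taxa: tuple[str, ...]
    characters: tuple[Character, ...]
    states: tuple[tuple[bool, ...], ...]  # taxa x characters
    polarity: tuple[str, ...]             # per character

    def state(self, taxon: str, char: Character | str) -> bool:
        ti = self.taxa.index(taxon)
        names = [str(c) for c in self.characters]
        ci = names.index(str(char))
        return self.states[ti][ci]

    def to_tsv(self) -> str:
        lines = ["taxon\t" + "\t".join(str(c) for c in self.characters),
                 "polarity\t" + "\t".join(self.polarity)]
        for taxon, row in zip(self.taxa, self.states):
            cells = "\t".join("+" if s else "-" for s in row)
            lines.append(f"{taxon}\t{cells}")
        return "\n".join(lines) + "\n"


#: the four derived characters shared exclusively by the elephant louse and
#: the sucking lice, in the order they are conventionally tabulated
SHARED_DERIVED_CHARACTERS = ("L1-rrnL", "L2-rrnS", "T-nad1-Q", "rrnL-V")

#: ancestral arrangement characters retained in the elephant louse
RETAINED_ANCESTRAL_CHARACTERS = ("atp8-atp6", "G-nad3", "H-nad5")

#: derived arrangement characters inferred present in the ingroup ancestor
MRCA_DERIVED_CHARACTERS = ("P-cox3", "F-nad6", "I-cox1", "Y-cox2", "K-nad4",
                           "L1-rrnL-V")


def build_character_matrix(karyotypes: list[MitoKaryotype],
                           characters: list[Character | str],
                           ancestral: AncestralArrangement) -> CharacterMatrix:
    chars = tuple(character(c) if isinstance(c, str) else c for c in characters)
    states = tuple(
        tuple(has_character(k, c) for c in chars) for k in karyotypes)
    polarity = tuple(classify_polarity(c, ancestral) for c in chars)
    return CharacterMatrix(taxa=tuple(k.species for k in karyotypes),
                           characters=chars, states=states, polarity=polarity)


def shared_exclusive_characters(m: CharacterMatrix, ingroup: set[str],
                                partitions: list[set[str]] | None = None
                                ) -> list[Character]:
    """Derived characters present in the ingroup and absent from all others.

    Returns characters with derived polarity that occur in at least one
    ingroup taxon and in no taxon outside the ingroup.  If *partitions* is
    given (e.g. the two suborders composing the ingroup), the character must
    additionally be present in at least one taxon of every partition to
    count as shared.
    """
    if not ingroup <= set(m.taxa):
        raise ValueError("ingroup is not a subset of the matrix taxa")
    out = []
    for ci, c in enumerate(m.characters):
        if m.polarity[ci] != "derived":
            continue
        present = {t for t, row in zip(m.taxa, m.states) if row[ci]}
        if not present or not present <= ingroup:
            continue
        if partitions and any(not (present & p) for p in partitions):
            continue
        out.append(c)
    return out
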