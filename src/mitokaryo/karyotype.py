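"""Data model and text notation for fragmented mitochondrial karyotypes.

A *mitochondrial karyotype* is the number, topology, gene content and gene
arrangement of an organism's mitochondrial minichromosomes.  The text
notation follows the convention of the comparative-louse literature: hyphens
link neighbouring genes on the same minichromosome, commas separate
minichromosomes.  Two dialects are supported:

``plain``
    bare tokens, all genes on the reference strand (``trnI-cox1-trnE``).
``signed``
    a leading ``-`` on a token marks transcription on the minority strand
    relative to the shared non-coding region (``-T--nad1--Q``).

Gene lists are stored in transcription order within each same-strand run:
the string names a minus-strand cluster the way its genes are read, so
``-T--nad1--Q`` carries the T→nad1 and nad1→Q adjacencies.  Only the
packaged ancestral single-chromosome arrangement is kept in physical map
order (see :class:`AncestralArrangement`).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field, replace

from .genes import VOCABULARY, GeneSymbol, UnknownGeneError, normalize_gene_token


class KaryotypeParseError(ValueError):
    pass


@dataclass(frozen=True)
class GeneCopy:
    """A gene occurrence on a minichromosome with its transcription strand.

    ``orientation`` is +1 when the gene is transcribed in the reference
    direction defined by the shared non-coding region (the majority strand),
    -1 otherwise.
    """

    symbol: GeneSymbol
    orientation: int = 1
    length_bp: int | None = None

    def __post_init__(self) -> None:
        if self.orientation not in (1, -1):
            raise ValueError("orientation must be +1 or -1")
        if self.length_bp is not None and self.length_bp <= 0:
            raise ValueError("length_bp must be positive")


@dataclass(frozen=True)
class Minichromosome:
    """A circular mitochondrial minichromosome: ordered genes + one NCR.

    The gene list starts at the first gene downstream of the non-coding
    region, which fixes the rotation of the circular molecule.
    """

    genes: tuple[GeneCopy, ...]
    coding_length_bp: int | None = None
    ncr_length_bp: int | None = None
    circular: bool = True

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError("a minichromosome needs at least one gene")

    @property
    def label(self) -> str:
        """Canonical name: gene tokens joined by hyphens (unsigned)."""
        return "-".join(g.symbol.name for g in self.genes)

    @property
    def total_length_bp(self) -> int | None:
        if self.coding_length_bp is None or self.ncr_length_bp is None:
            return None
        return self.coding_length_bp + self.ncr_length_bp

    @property
    def ncr_fraction(self) -> float | None:
        """NCR length over total minichromosome length."""
        total = self.total_length_bp
        if total is None:
            return None
        return self.ncr_length_bp / total


@dataclass(frozen=True)
class MitoKaryotype:
    species: str
    minichromosomes: tuple[Minichromosome, ...]
    source: str = ""

    def __post_init__(self) -> None:
        labels = [m.label for m in self.minichromosomes]
        if len(labels) != len(set(labels)):
            dup = [l for l, n in Counter(labels).items() if n > 1]
            raise ValueError(f"duplicate minichromosome labels: {dup}")

    def __len__(self) -> int:
        return len(self.minichromosomes)

    def gene_copies(self):
        for mc in self.minichromosomes:
            yield from mc.genes


@dataclass(frozen=True)
class AncestralArrangement:
    """The single-chromosome insect ground pattern in physical map order.

    ``genes`` lists all 37 genes around the circle in map order on the
    reference strand, with ``control_region_index`` marking the junction
    occupied by the control region (which breaks gene adjacency exactly as
    a minichromosome NCR does).  Minus-strand genes are transcribed in
    reverse map order.
    """

    genes: tuple[GeneCopy, ...]
    control_region_index: int = 0  # CR sits before genes[control_region_index]

    def __post_init__(self) -> None:
        names = [g.symbol.name for g in self.genes]
        if sorted(names) != sorted(VOCABULARY):
            raise ValueError("ancestral arrangement must contain each of the "
                             "37 genes exactly once")

    def rotated(self, offset: int) -> "AncestralArrangement":
        """Rotate the circular representation; the CR marker moves with it."""
        n = len(self.genes)
        off = offset % n
        genes = self.genes[off:] + self.genes[:off]
        return replace(self, genes=genes,
                       control_region_index=(self.control_region_index - off) % n)


# ---------------------------------------------------------------------------
# parsing / formatting

def _tokenize_group(group: str, dialect: str, group_idx: int):
    parts = group.split("-")
    tokens: list[tuple[str, int]] = []
    i = 0
    while i < len(parts):
        part = parts[i]
        if part == "":
            if dialect != "signed":
                raise KaryotypeParseError(
                    f"empty gene token in group {group_idx + 1} "
                    f"(stray hyphen in plain dialect?)")
            # a leading empty field marks the next token as minus-strand
            if i + 1 >= len(parts) or parts[i + 1] == "":
                raise KaryotypeParseError(
                    f"dangling '-' in group {group_idx + 1}")
            tokens.append((parts[i + 1], -1))
            i += 2
        else:
            tokens.append((part, 1))
            i += 1
    return tokens


def parse_karyotype(text: str, species: str = "", source: str = "",
                    orientation_dialect: str = "signed") -> MitoKaryotype:
    """Parse a karyotype string into a :class:`MitoKaryotype`.

    Hyphens link neighbouring genes on the same minichromosome; commas
    separate minichromosomes.  In the ``signed`` dialect a leading ``-`` on
    a token marks minority-strand transcription.  Whitespace around tokens
    and separators is tolerated.
    """
    if orientation_dialect not in ("plain", "signed"):
        raise ValueError(f"unknown dialect {orientation_dialect!r}")
    if not text.strip():
        raise KaryotypeParseError("empty karyotype string")
    minis = []
    for gi, group in enumerate(text.split(",")):
        group = "".join(group.split())  # strip all whitespace
        if not group:
            raise KaryotypeParseError(f"empty minichromosome group {gi + 1}")
        copies = []
        for ti, (tok, orient) in enumerate(_tokenize_group(group, orientation_dialect, gi)):
            try:
                name = normalize_gene_token(tok)
            except UnknownGeneError as exc:
                raise KaryotypeParseError(
                    f"group {gi + 1}, token {ti + 1}: {exc}") from exc
            copies.append(GeneCopy(GeneSymbol(name), orient))
        minis.append(Minichromosome(genes=tuple(copies)))
    return MitoKaryotype(species=species, minichromosomes=tuple(minis),
                         source=source)


def format_karyotype(k: MitoKaryotype, dialect: str = "signed") -> str:
    """Render a karyotype back to its text notation (inverse of parsing)."""
    groups = []
    for mc in k.minichromosomes:
        toks = []
        for g in mc.genes:
            if g.orientation == -1:
                if dialect == "plain":
                    raise ValueError(
                        "plain dialect cannot represent minus-strand genes")
                toks.append("-" + g.symbol.name)
            else:
                toks.append(g.symbol.name)
        groups.append("-".join(toks))
    return ",".join(groups)


# ---------------------------------------------------------------------------
# summaries

def gene_inventory(k: MitoKaryotype) -> dict:
    """Distinct genes, per-gene occurrence counts, and missing genes.

    ``distinct`` and ``missing`` partition the 37-gene vocabulary; a gene
    duplicated across minichromosomes (e.g. trnE in the elephant louse)
    counts once in ``distinct`` but its copies are tallied in
    ``occurrences``.
    """
    occurrences: Counter[str] = Counter(
        g.symbol.name for g in k.gene_copies())
    distinct = set(occurrences)
    return {
        "distinct": distinct,
        "occurrences": dict(occurrences),
        "missing": set(VOCABULARY) - distinct,
        "n_gene_copies": sum(occurrences.values()),
    }


def karyotype_summary(k: MitoKaryotype) -> dict:
    """Minichromosome count, genes-per-minichromosome range, minus-strand genes."""
    sizes = [len(mc.genes) for mc in k.minichromosomes]
    minus = {g.symbol.name for g in k.gene_copies() if g.orientation == -1}
    return {
        "n_minichromosomes": len(k.minichromosomes),
        "genes_per_minichromosome": (min(sizes), max(sizes)),
        "minus_strand_genes": minus,
    }
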