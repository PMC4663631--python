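"""Packaged reference data: louse karyotypes, the insect ground pattern,
the fixed louse phylogeny, and life-cycle records.

Karyotype text files follow the external format: one record per line,
``species<TAB>karyotype-string`` (optionally a third provenance column),
UTF-8, ``#`` comments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path

import dendropy

from .karyotype import (AncestralArrangement, GeneCopy, MitoKaryotype,
                        Minichromosome, _tokenize_group, parse_karyotype)
from .genes import GeneSymbol, normalize_gene_token

#: chewing lice / psocopteran outgroups carrying the typical single
#: mitochondrial chromosome (the four shared derived characters of the
#: elephant louse + sucking lice are absent in all of them); packaged as the
#: ancestral arrangement, a documented stand-in for their true arrangements.
OUTGROUP_SPECIES = (
    "Heterodoxus_macropus",
    "Campanulotes_bidentatus",
    "Ibidoecus_bisignatus",
    "Bothriometopus_macrocnemis",
    "Liposcelis_bostrychophila",
)

#: the ingroup whose most recent common ancestor the analysis targets
INGROUP_SPECIES = (
    "Haematomyzus_elephantis",      # Rhynchophthirina
    "Haematopinus_suis",            # Anoplura
    "Haematopinus_apri",
    "Polyplax_asiatica",
    "Polyplax_spinulosa",
    "Pthirus_pubis",
    "Pediculus_humanus_capitis",
    "Pediculus_humanus_humanus",
)


def _data_path(name: str):
    return resources.files("mitokaryo.data").joinpath(name)


def _read_lines(name: str) -> list[str]:
    text = _data_path(name).read_text(encoding="utf-8")
    return [ln for ln in (l.strip() for l in text.splitlines())
            if ln and not ln.startswith("#")]


# ---------------------------------------------------------------------------
# karyotype files

def read_karyotype_file(path) -> dict[str, MitoKaryotype]:
    """Read a species<TAB>karyotype[<TAB>provenance] file (signed dialect)."""
    out: dict[str, MitoKaryotype] = {}
    for raw in Path(path).read_text(encoding="utf-8").splitlines():
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise ValueError(f"malformed karyotype record: {line!r}")
        species, karyo = fields[0], fields[1]
        source = fields[2] if len(fields) > 2 else ""
        out[species] = parse_karyotype(karyo, species=species, source=source)
    return out


def write_karyotype_file(path, karyotypes, dialect: str = "signed") -> None:
    from .karyotype import format_karyotype
    with open(path, "w", encoding="utf-8") as fh:
        for k in karyotypes:
            fh.write(f"{k.species}\t{format_karyotype(k, dialect)}\t{k.source}\n")


# ---------------------------------------------------------------------------
# packaged fixtures

def load_ancestral_arrangement() -> AncestralArrangement:
    """The 37-gene single-chromosome insect ground pattern, map order."""
    (line,) = _read_lines("ancestral_insect.txt")
    copies = [GeneCopy(GeneSymbol(normalize_gene_token(tok)), orient)
              for tok, orient in _tokenize_group(line, "signed", 0)]
    return AncestralArrangement(genes=tuple(copies), control_region_index=0)


def ancestral_as_karyotype(species: str,
                           source: str = "ancestral single-chromosome stand-in"
                           ) -> MitoKaryotype:
    """Render the ground pattern as a one-minichromosome karyotype.

    Minus-strand map runs are reversed into transcription order so the
    resulting karyotype carries exactly the ancestral adjacency set, with
    the control region as the rotation break point.
    """
    anc = load_ancestral_arrangement()
    genes = anc.genes[anc.control_region_index:] + anc.genes[:anc.control_region_index]
    ordered: list[GeneCopy] = []
    run: list[GeneCopy] = []
    for g in genes:
        if run and g.orientation != run[-1].orientation:
            ordered.extend(reversed(run) if run[-1].orientation == -1 else run)
            run = []
        run.append(g)
    if run:
        ordered.extend(reversed(run) if run[-1].orientation == -1 else run)
    mc = Minichromosome(genes=tuple(ordered))
    return MitoKaryotype(species=species, minichromosomes=(mc,), source=source)


def load_reference_karyotypes(include_outgroups: bool = True
                              ) -> dict[str, MitoKaryotype]:
    """All packaged louse karyotypes keyed by species name."""
    out: dict[str, MitoKaryotype] = {}
    for line in _read_lines("louse_karyotypes.tsv"):
        species, karyo, source = line.split("\t")
        out[species] = parse_karyotype(karyo, species=species, source=source)
    if include_outgroups:
        for sp in OUTGROUP_SPECIES:
            out[sp] = ancestral_as_karyotype(sp)
    return out


def load_elephant_karyotype() -> MitoKaryotype:
    """The elephant-louse karyotype with its known minichromosome lengths."""
    k = load_reference_karyotypes(include_outgroups=False)["Haematomyzus_elephantis"]
    lengths = {}
    for line in _read_lines("elephant_minichromosomes.tsv"):
        fields = line.split("\t")
        label = fields[0]
        coding = int(fields[1])
        ncr = int(fields[2]) if len(fields) > 2 and fields[2] else None
        lengths[label] = (coding, ncr)
    minis = []
    for mc in k.minichromosomes:
        coding, ncr = lengths[mc.label]
        minis.append(replace(mc, coding_length_bp=coding, ncr_length_bp=ncr))
    return replace(k, minichromosomes=tuple(minis))


def load_phthiraptera_tree() -> dendropy.Tree:
    """The fixed louse/psocopteran topology used for ancestral inference."""
    (newick,) = _read_lines("phthiraptera_tree.nwk")
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = True
    return tree


@dataclass(frozen=True)
class LifeCycleRecord:
    """A species' published life-cycle range (days) and minichromosome count."""

    species: str
    life_cycle_min_days: float
    life_cycle_max_days: float
    n_minichromosomes: int

    def __post_init__(self) -> None:
        if self.life_cycle_min_days > self.life_cycle_max_days:
            raise ValueError("life-cycle min exceeds max")
        if self.n_minichromosomes < 1:
            raise ValueError("minichromosome count must be >= 1")

    @property
    def life_cycle_midpoint(self) -> float:
        return 0.5 * (self.life_cycle_min_days + self.life_cycle_max_days)


def load_life_cycle_records() -> list[LifeCycleRecord]:
    records = []
    for line in _read_lines("life_cycles.tsv"):
        sp, lo, hi, n = line.split("\t")
        records.append(LifeCycleRecord(sp, float(lo), float(hi), int(n)))
    return records
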