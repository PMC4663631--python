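"""Canonical 37-gene animal mitochondrial vocabulary and token normalization.

Animal mitochondrial genomes encode 13 protein-coding genes, 2 rRNAs and 22
tRNAs.  The two leucine and two serine tRNAs are distinguished by anticodon:
L1(tag)/L2(taa) and S1(tct)/S2(tga).  Published gene-arrangement tables mix
several spellings for the same gene (``trnI``, ``I``, ``trnL1(tag)``,
``L1``); everything here is normalized to one canonical token per gene.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

PROTEIN_GENES = (
    "atp6", "atp8", "cob", "cox1", "cox2", "cox3",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6",
)
RRNA_GENES = ("rrnS", "rrnL")
TRNA_GENES = (
    "A", "C", "D", "E", "F", "G", "H", "I", "K", "L1", "L2",
    "M", "N", "P", "Q", "R", "S1", "S2", "T", "V", "W", "Y",
)

#: the full 37-token vocabulary
VOCABULARY = frozenset(PROTEIN_GENES) | frozenset(RRNA_GENES) | frozenset(TRNA_GENES)

_CATEGORY = {g: "protein" for g in PROTEIN_GENES}
_CATEGORY.update({g: "rRNA" for g in RRNA_GENES})
_CATEGORY.update({g: "tRNA" for g in TRNA_GENES})

# anticodon suffixes used to disambiguate the duplicated tRNA families
_ANTICODON = {("L", "tag"): "L1", ("L", "taa"): "L2",
              ("S", "tct"): "S1", ("S", "tga"): "S2"}

_MULTI = {g.lower(): g for g in PROTEIN_GENES + RRNA_GENES}
_TRNA_TOKEN = re.compile(r"^(?:trn)?([A-Za-z])([12]?)(?:\((\w{3})\))?$")


class UnknownGeneError(ValueError):
    """Raised for a token outside the 37-gene vocabulary."""


@dataclass(frozen=True)
class GeneSymbol:
    """One of the 37 canonical mitochondrial gene symbols."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in VOCABULARY:
            raise UnknownGeneError(f"unknown gene symbol {self.name!r}")

    @property
    def category(self) -> str:
        return _CATEGORY[self.name]

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.name


def normalize_gene_token(token: str) -> str:
    """Map any accepted spelling of a gene name to its canonical token.

    Accepted spellings: canonical tokens themselves; case variants of the
    protein/rRNA names (``NAD4l`` -> ``nad4L``); tRNAs as single letters with
    optional ``trn`` prefix, paralog index, and anticodon in parentheses
    (``trnL1(tag)``, ``L1(tag)``, ``trnL(taa)``, ``L1`` -> ``L1``/``L2``).

    Bare ``L`` or ``S`` without index or anticodon is ambiguous and rejected.
    """
    tok = token.strip()
    if not tok:
        raise UnknownGeneError("empty gene token")
    low = tok.lower()
    if low in _MULTI:
        return _MULTI[low]
    m = _TRNA_TOKEN.match(tok)
    if m:
        letter, index, anticodon = m.group(1).upper(), m.group(2), m.group(3)
        if letter in ("L", "S"):
            if anticodon:
                key = (letter, anticodon.lower())
                if key not in _ANTICODON:
                    raise UnknownGeneError(f"unknown anticodon in {token!r}")
                name = _ANTICODON[key]
                if index and name[-1] != index:
                    raise UnknownGeneError(
                        f"index/anticodon mismatch in {token!r}")
                return name
            if index:
                return letter + index
            raise UnknownGeneError(
                f"ambiguous tRNA token {token!r}: L/S need an index or anticodon")
        if index or (anticodon and letter not in ("L", "S")):
            raise UnknownGeneError(f"unknown gene token {token!r}")
        if letter in TRNA_GENES:
            return letter
    raise UnknownGeneError(f"unknown gene token {token!r}")


def gene(token: str) -> GeneSymbol:
    """Normalize *token* and return its :class:`GeneSymbol`."""
    return GeneSymbol(normalize_gene_token(token))
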