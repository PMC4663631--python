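"""Ancestral mitochondrial-karyotype features on a fixed phylogeny.

Binary arrangement characters (gene adjacencies, solo-gene minichromosome
predicates, the minus-strand T-nad1-Q cluster) are scored on the tips and
optimized on the fixed tree with unordered (Fitch) parsimony; a Dollo
option treats each derived character as gained once with losses only, the
standard assumption for rare genomic changes.  Characters whose member
genes were not identified in a species are treated as missing data at that
tip and flagged, never as absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
from scipy import stats

from .adjacency import (MRCA_DERIVED_CHARACTERS, RETAINED_ANCESTRAL_CHARACTERS,
                        SHARED_DERIVED_CHARACTERS, Character, character,
                        classify_polarity, extract_adjacencies,
                        _member_adjacencies)
from .genes import PROTEIN_GENES, RRNA_GENES
from .karyotype import MitoKaryotype, gene_inventory
from .reference import (INGROUP_SPECIES, LifeCycleRecord,
                        load_ancestral_arrangement)

_INF = float("inf")


class TipStateError(ValueError):
    pass


def _tip_sets(tree: dendropy.Tree, tip_states: dict) -> dict:
    """Normalize tip states to frozensets over {0, 1}; None = missing data."""
    out = {}
    for leaf in tree.leaf_node_iter():
        name = leaf.taxon.label.replace(" ", "_")
        if name not in tip_states:
            raise TipStateError(f"no state for tip {name!r}")
        s = tip_states[name]
        if s is None:
            out[leaf] = frozenset((0, 1))
        elif isinstance(s, (set, frozenset)):
            out[leaf] = frozenset(int(bool(x)) for x in s)
        else:
            out[leaf] = frozenset((int(bool(s)),))
    return out


def fitch_states(tree: dendropy.Tree, tip_states: dict):
    """Small-parsimony optimization of a binary character on a rooted tree.

    *tip_states* maps tip labels to 0/1 (or a set of admissible states;
    ``None`` for missing data).  Returns ``(states, cost)`` where *states*
    maps every node to the set of states it takes in at least one
    maximally parsimonious reconstruction — a two-element set flags
    ambiguity — and *cost* is the minimal number of state changes.

    Implemented as unit-cost Sankoff dynamic programming (up pass for the
    subtree costs, down pass for whole-tree conditional costs), which for
    binary unit costs coincides with Fitch optimization.
    """
    tree.is_rooted = True
    allowed = _tip_sets(tree, tip_states)
    up: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            up[node] = [0 if s in allowed[node] else _INF for s in (0, 1)]
        else:
            costs = [0.0, 0.0]
            for child in node.child_nodes():
                cc = up[child]
                for s in (0, 1):
                    costs[s] += min(cc[t] + (s != t) for t in (0, 1))
            up[node] = costs
    root = tree.seed_node
    cost = min(up[root])
    if cost == _INF:
        raise TipStateError("contradictory tip states")
    # down pass: total tree cost conditional on each node's state
    down = {root: list(up[root])}
    for node in tree.preorder_node_iter():
        if node is root:
            pass
        for child in node.child_nodes():
            cc = up[child]
            contrib = [min(cc[t] + (s != t) for t in (0, 1)) for s in (0, 1)]
            down[child] = [
                cc[t] + min(down[node][s] - contrib[s] + (s != t)
                            for s in (0, 1))
                for t in (0, 1)
            ]
    states = {node: frozenset(s for s in (0, 1) if down[node][s] == cost)
              for node in tree.preorder_node_iter()}
    return states, cost


def dollo_states(tree: dendropy.Tree, tip_states: dict):
    """Dollo reconstruction: one gain, losses only.

    The gain is placed at the most recent common ancestor of all tips that
    carry the character; a node has the character iff it lies on a path
    from that gain node to a carrying tip.  Missing-data tips do not force
    presence.  Returns ``(states, n_losses)``.
    """
    tree.is_rooted = True
    allowed = _tip_sets(tree, tip_states)
    present_leaves = [leaf for leaf, s in allowed.items() if s == {1}]
    states = {node: frozenset((0,)) for node in tree.preorder_node_iter()}
    if not present_leaves:
        return states, 0
    taxa = [leaf.taxon for leaf in present_leaves]
    gain = (present_leaves[0] if len(taxa) == 1
            else tree.mrca(taxa=taxa))
    # mark path nodes: descendants of the gain node with a carrying tip below
    carrier: dict = {}
    n_losses = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            carrier[node] = allowed[node] == {1}
        else:
            carrier[node] = any(carrier[c] for c in node.child_nodes())
    in_gain_subtree = set()
    stack = [gain]
    while stack:
        n = stack.pop()
        in_gain_subtree.add(n)
        stack.extend(n.child_nodes())
    for node in in_gain_subtree:
        if carrier[node] or allowed.get(node) == frozenset((0, 1)):
            states[node] = frozenset((1,))
    for node in in_gain_subtree:
        if states[node] == {0}:
            parent = node.parent_node
            if parent in in_gain_subtree and states[parent] == {1}:
                n_losses += 1
    return states, n_losses


def ancestral_state(tree: dendropy.Tree, tip_states: dict, ingroup: set[str],
                    method: str = "fitch") -> str:
    """State of the ingroup MRCA: ``present``/``absent``/``ambiguous``."""
    if method == "fitch":
        states, _ = fitch_states(tree, tip_states)
    elif method == "dollo":
        states, _ = dollo_states(tree, tip_states)
    else:
        raise ValueError(f"unknown method {method!r}")
    node = _mrca_node(tree, ingroup)
    s = states[node]
    if s == {1}:
        return "present"
    if s == {0}:
        return "absent"
    return "ambiguous"


def _mrca_node(tree: dendropy.Tree, tips: set[str]):
    tree.is_rooted = True
    taxa = [leaf.taxon for leaf in tree.leaf_node_iter()
            if leaf.taxon.label.replace(" ", "_") in tips]
    if not taxa:
        raise ValueError("no matching tips for the requested MRCA")
    if len(taxa) == 1:
        (taxon,) = taxa
        return tree.find_node_with_taxon_label(taxon.label)
    return tree.mrca(taxa=taxa)


# ---------------------------------------------------------------------------
# tip scoring of karyotype features

def _observable(k: MitoKaryotype, c: Character) -> bool:
    present = gene_inventory(k)["distinct"]
    genes = {a.upstream.name for a in _member_adjacencies(c)}
    genes |= {a.downstream.name for a in _member_adjacencies(c)}
    return genes <= present

def adjacency_tip_state(k: MitoKaryotype, c: Character):
    """1/0 presence, or ``None`` if a member gene was never identified."""
    if not _observable(k, c):
        return None
    return int(set(_member_adjacencies(c)) <= extract_adjacencies(k))


def solo_gene_tip_state(k: MitoKaryotype, gene_name: str):
    """Whether *gene_name* occupies a minichromosome with no other
    protein-coding or rRNA gene (tRNA companions allowed)."""
    major = set(PROTEIN_GENES) | set(RRNA_GENES)
    found = None
    for mc in k.minichromosomes:
        names = [g.symbol.name for g in mc.genes]
        if gene_name in names:
            others = [n for n in names if n != gene_name and n in major]
            solo = not others
            found = solo if found is None else (found and solo)
    if found is None:
        return None  # gene not identified
    return int(found)


def reverse_cluster_tip_state(k: MitoKaryotype):
    """The minus-strand T-nad1-Q cluster: both adjacencies present with all
    three genes transcribed on the minority strand."""
    c = character("T-nad1-Q")
    obs = adjacency_tip_state(k, c)
    if obs is None:
        return None
    if not obs:
        return 0
    minus = {g.symbol.name for g in k.gene_copies() if g.orientation == -1}
    return int({"T", "nad1", "Q"} <= minus)


@dataclass
class MrcaReport:
    """Inferred mitochondrial-karyotype features of the ingroup MRCA."""

    method: str
    character_states: dict[str, str] = field(default_factory=dict)
    characters_present: set[str] = field(default_factory=set)
    characters_ambiguous: set[str] = field(default_factory=set)
    solo_gene_minichromosomes: set[str] = field(default_factory=set)
    solo_gene_ambiguous: set[str] = field(default_factory=set)
    reverse_cluster: bool | None = None

    @property
    def retained_ancestral_present(self) -> set[str]:
        return self.characters_present & set(RETAINED_ANCESTRAL_CHARACTERS)

    @property
    def derived_present(self) -> set[str]:
        return self.characters_present - set(RETAINED_ANCESTRAL_CHARACTERS)


DEFAULT_MRCA_CHARACTERS = tuple(dict.fromkeys(
    RETAINED_ANCESTRAL_CHARACTERS + MRCA_DERIVED_CHARACTERS
    + SHARED_DERIVED_CHARACTERS))


def infer_mrca_karyotype_features(tree: dendropy.Tree,
                                  karyotypes: dict[str, MitoKaryotype],
                                  ingroup: set[str] | None = None,
                                  characters=DEFAULT_MRCA_CHARACTERS,
                                  method: str = "fitch") -> MrcaReport:
    """Reconstruct arrangement features at the ingroup MRCA.

    Every tree tip must have a karyotype.  *ingroup* defaults to the
    packaged Rhynchophthirina + Anoplura species present in the tree.
    """
    tips = [leaf.taxon.label.replace(" ", "_")
            for leaf in tree.leaf_node_iter()]
    missing = [t for t in tips if t not in karyotypes]
    if missing:
        raise ValueError(f"no karyotype for tree tips: {missing}")
    if ingroup is None:
        ingroup = {t for t in tips if t in INGROUP_SPECIES}
        if not ingroup:
            raise ValueError("no packaged ingroup species in the tree; "
                             "pass ingroup= explicitly")
    report = MrcaReport(method=method)
    for spec in characters:
        c = character(spec) if isinstance(spec, str) else spec
        tip_states = {t: adjacency_tip_state(karyotypes[t], c) for t in tips}
        state = ancestral_state(tree, tip_states, ingroup, method)
        report.character_states[str(c)] = state
        if state == "present":
            report.characters_present.add(str(c))
        elif state == "ambiguous":
            report.characters_ambiguous.add(str(c))
    for gname in PROTEIN_GENES + RRNA_GENES:
        tip_states = {t: solo_gene_tip_state(karyotypes[t], gname)
                      for t in tips}
        if all(s is None for s in tip_states.values()):
            continue
        state = ancestral_state(tree, tip_states, ingroup, method)
        if state == "present":
            report.solo_gene_minichromosomes.add(gname)
        elif state == "ambiguous":
            report.solo_gene_ambiguous.add(gname)
    tip_states = {t: reverse_cluster_tip_state(karyotypes[t]) for t in tips}
    state = ancestral_state(tree, tip_states, ingroup, method)
    report.reverse_cluster = (True if state == "present"
                              else False if state == "absent" else None)
    return report


# ---------------------------------------------------------------------------
# life cycle vs fragmentation

def fragmentation_lifecycle_association(records: list[LifeCycleRecord]) -> dict:
    """Spearman rank correlation of life-cycle midpoint vs minichromosome
    count.  An inverse association (negative rho) means shorter-lived
    species carry more fragmented mitochondrial genomes."""
    if len(records) < 3:
        raise ValueError("need at least 3 records for a rank correlation")
    midpoints = [r.life_cycle_midpoint for r in records]
    counts = [r.n_minichromosomes for r in records]
    rho, pvalue = stats.spearmanr(midpoints, counts)
    direction = ("inverse" if rho < 0 else
                 "positive" if rho > 0 else "none")
    return {"rho": float(rho), "p_value": float(pvalue),
            "direction": direction, "n": len(records)}
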