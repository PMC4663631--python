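"""Concerted vs independent evolution of the two mitochondrial leucine
tRNA paralogs (trnL1(tag), trnL2(taa)).

The engine is deliberately self-contained: uncorrected p-distances under
pairwise deletion, classical neighbor joining on the Q criterion, and
nonparametric bootstrap over alignment columns.  A species' paralog pair is
classified *concerted* when its two leaves group together on the tree to
the exclusion of every other species (homogenization by gene conversion),
*independent* when each paralog instead groups with its orthologs in other
species, and *unresolved* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

_ALPHABET = set("ACGT-N")


@dataclass(frozen=True)
class AlignedSeqSet:
    """A gapped nucleotide alignment; record names ``Species|L1`` etc."""

    records: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.records.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must have equal length")
        for name, seq in self.records.items():
            bad = set(seq.upper()) - _ALPHABET
            if bad:
                raise ValueError(f"{name}: illegal characters {bad}")

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(self.records)

    @property
    def length(self) -> int:
        return len(next(iter(self.records.values())))

    def matrix(self) -> np.ndarray:
        return np.array([list(self.records[n].upper()) for n in self.names])

    @staticmethod
    def from_fasta(path) -> "AlignedSeqSet":
        records = {r.id: str(r.seq) for r in SeqIO.parse(str(path), "fasta")}
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return AlignedSeqSet(records)

    def to_fasta(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for name, seq in self.records.items():
                fh.write(f">{name}\n{seq}\n")


def split_label(name: str) -> tuple[str, str]:
    """``"Species|L1"`` -> ``("Species", "L1")``."""
    species, _, paralog = name.rpartition("|")
    if paralog not in ("L1", "L2") or not species:
        raise ValueError(f"record name {name!r} is not 'Species|L1' / 'Species|L2'")
    return species, paralog


# ---------------------------------------------------------------------------
# distances

def p_distance(a: str, b: str) -> float:
    """Proportion of differing sites, excluding sites with a gap or N in
    either sequence (pairwise deletion)."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    x = np.frombuffer(a.upper().encode(), dtype="S1")
    y = np.frombuffer(b.upper().encode(), dtype="S1")
    usable = ~(np.isin(x, (b"-", b"N")) | np.isin(y, (b"-", b"N")))
    n = int(usable.sum())
    if n == 0:
        raise ValueError("no comparable sites between sequences")
    return float((x[usable] != y[usable]).sum() / n)


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0):
            raise ValueError("distance matrix must have zero diagonal")

    @staticmethod
    def from_alignment(seqs: AlignedSeqSet) -> "DistanceMatrix":
        names = seqs.names
        n = len(names)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                d[i, j] = d[j, i] = p_distance(seqs.records[names[i]],
                                               seqs.records[names[j]])
        return DistanceMatrix(names, d)


# ---------------------------------------------------------------------------
# neighbor joining

@dataclass
class TreeNode:
    """Node of an (unrooted) NJ tree; the top node is a trifurcation."""

    label: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if self.label is not None and not self.children:
            return [self.label]
        out: list[str] = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.label or ""
        inner = ",".join(f"{c._newick()}:{bl:.6g}" for c, bl in self.children)
        return f"({inner})"


def _min_leaf(node: TreeNode) -> str:
    return min(node.leaves())


def neighbor_joining(d: DistanceMatrix) -> TreeNode:
    """Classical NJ agglomeration on the Q criterion.

    Ties in Q are broken by the lexicographic order of the joined clusters'
    smallest leaf labels; negative branch lengths are clamped to zero with
    the deficit transferred to the sibling branch, preserving the joined
    pair's distance.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    nodes = [TreeNode(label=l) for l in d.labels]
    keys = [l for l in d.labels]
    dist = d.values.astype(float).copy()
    active = list(range(n))
    next_index = n
    store: dict[int, TreeNode] = {i: nodes[i] for i in range(n)}
    key_of: dict[int, str] = {i: keys[i] for i in range(n)}
    D: dict[tuple[int, int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            D[(i, j)] = dist[i, j]

    def get(i: int, j: int) -> float:
        return 0.0 if i == j else D[(min(i, j), max(i, j))]

    while len(active) > 3:
        m = len(active)
        r = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * get(i, j) - r[i] - r[j]
                tie = tuple(sorted((key_of[i], key_of[j])))
                cand = (q, tie, i, j)
                if best is None or cand < best:
                    best = cand
        _, _, i, j = best
        dij = get(i, j)
        li = dij / 2 + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = TreeNode(children=[(store[i], li), (store[j], lj)])
        u = next_index
        next_index += 1
        for k in active:
            if k in (i, j):
                continue
            D[(min(u, k), max(u, k))] = (get(i, k) + get(j, k) - dij) / 2
        active = [k for k in active if k not in (i, j)] + [u]
        store[u] = new
        key_of[u] = min(key_of[i], key_of[j])

    a, b, c = sorted(active, key=lambda k: key_of[k])
    dab, dac, dbc = get(a, b), get(a, c), get(b, c)
    la = max((dab + dac - dbc) / 2, 0.0)
    lb = max((dab + dbc - dac) / 2, 0.0)
    lc = max((dac + dbc - dab) / 2, 0.0)
    return TreeNode(children=[(store[a], la), (store[b], lb), (store[c], lc)])


# ---------------------------------------------------------------------------
# bipartitions and bootstrap

def bipartitions(tree: TreeNode) -> set[frozenset[str]]:
    """Nontrivial splits of the unrooted tree, each canonicalized to the
    side that excludes the lexicographically smallest leaf."""
    all_leaves = frozenset(tree.leaves())
    ref = min(all_leaves)
    splits: set[frozenset[str]] = set()

    def walk(node: TreeNode):
        below = frozenset(node.leaves())
        if 2 <= len(below) <= len(all_leaves) - 2:
            side = below if ref not in below else all_leaves - below
            splits.add(side)
        for child, _ in node.children:
            walk(child)

    for child, _ in tree.children:
        walk(child)
    return splits


def bootstrap_support(seqs: AlignedSeqSet, n_reps: int = 500,
                      seed: int | None = None) -> dict[frozenset[str], float]:
    """Column-resampling bootstrap proportions for every split observed in
    any replicate NJ tree.  Reproducible under a fixed seed."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    mat = seqs.matrix()
    names = seqs.names
    counts: dict[frozenset[str], int] = {}
    ncol = mat.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        boot = AlignedSeqSet({name: "".join(row)
                              for name, row in zip(names, mat[:, cols])})
        tree = neighbor_joining(DistanceMatrix.from_alignment(boot))
        for split in bipartitions(tree):
            counts[split] = counts.get(split, 0) + 1
    return {s: c / n_reps for s, c in counts.items()}


# ---------------------------------------------------------------------------
# paralog classification

@dataclass(frozen=True)
class ParalogVerdict:
    species: str
    pattern: str  # concerted | independent | unresolved
    support: float | None = None


def classify_paralog_pattern(tree: TreeNode, species: str,
                             support: dict[frozenset[str], float] | None = None
                             ) -> ParalogVerdict:
    """Classify a species' trnL1/trnL2 pair on an NJ tree.

    *concerted*: some split gathers the species' own paralogs apart from
    every other species (for a two-copy species, a cherry).  *independent*:
    the L1 leaf sits in an all-L1 split with at least one other species,
    and the L2 leaf symmetrically.  Otherwise *unresolved*.
    """
    leaves = set(tree.leaves())
    own_l1, own_l2 = f"{species}|L1", f"{species}|L2"
    if own_l1 not in leaves or own_l2 not in leaves:
        raise ValueError(f"tree lacks a trnL paralog of {species}")
    others = {l for l in leaves if split_label(l)[0] != species}
    if not others:
        return ParalogVerdict(species, "unresolved")
    own = {l for l in leaves if split_label(l)[0] == species}
    splits = bipartitions(tree)

    def lookup(side: frozenset[str]) -> float | None:
        if support is None:
            return None
        ref = min(leaves)
        canon = side if ref not in side else frozenset(leaves) - side
        return support.get(canon, 0.0)

    pair = frozenset((own_l1, own_l2))
    concerted_sides = [s for s in (splits | {frozenset(leaves) - s for s in splits})
                       if pair <= s and s <= own]
    if concerted_sides:
        side = min(concerted_sides, key=len)
        return ParalogVerdict(species, "concerted", lookup(side))

    def pure_side(leaf: str, paralog: str):
        cands = []
        for s in splits | {frozenset(leaves) - s for s in splits}:
            if leaf in s and len(s) >= 2 and all(
                    split_label(l)[1] == paralog for l in s):
                cands.append(s)
        return min(cands, key=len) if cands else None

    s1 = pure_side(own_l1, "L1")
    s2 = pure_side(own_l2, "L2")
    if s1 is not None and s2 is not None:
        sups = [x for x in (lookup(s1), lookup(s2)) if x is not None]
        return ParalogVerdict(species, "independent",
                              min(sups) if sups else None)
    return ParalogVerdict(species, "unresolved")


def classify_paralog_windows(seqs: AlignedSeqSet, species: str, window: int,
                             step: int | None = None
                             ) -> list[tuple[int, int, str]]:
    """Per-window paralog verdicts for part-gene conversion analyses.

    Recombination restricted to part of a gene homogenizes only that part,
    so different alignment windows can show different evolutionary
    patterns.  Each window of *window* columns (advancing by *step*,
    default non-overlapping) is analysed independently: NJ on the window's
    p-distances, then the usual concerted/independent classification.
    Windows with too little signal come back ``"unresolved"``.  Window
    boundaries are a user choice; no default is claimed.
    """
    if window < 4 or window > seqs.length:
        raise ValueError("window must be between 4 and the alignment length")
    step = step or window
    out: list[tuple[int, int, str]] = []
    for start in range(0, seqs.length - window + 1, step):
        sub = AlignedSeqSet({name: seq[start:start + window]
                             for name, seq in seqs.records.items()})
        try:
            tree = neighbor_joining(DistanceMatrix.from_alignment(sub))
            pattern = classify_paralog_pattern(tree, species).pattern
        except ValueError:
            pattern = "unresolved"
        out.append((start + 1, start + window, pattern))
    return out


def paralog_difference(a: str, b: str) -> tuple[int, tuple[int, ...]]:
    """Count and 1-based alignment positions of differing sites."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    positions = tuple(i + 1 for i, (x, y) in enumerate(zip(a.upper(), b.upper()))
                      if x != y)
    return len(positions), positions
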