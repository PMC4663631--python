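"""Amplicon assembly of circular mitochondrial minichromosomes.

A deliberately small overlap-layout-consensus assembler honouring four
thresholds: minimum overlap length, minimum overlap identity, maximum gap
fraction per read and maximum gap size.  Presets mirror the settings used
for long variable-length pyrosequencing reads (100 bp / 90% / 10% / 10 bp)
and short fixed-length 90 bp reads (70 bp / 90% / 5% / 5 bp).  Assembly is
greedy: a seed read is extended by the qualifying read with the longest end
overlap, contained reads are absorbed, and a contig whose two ends overlap
under the same thresholds is circularized with the duplicated segment
trimmed.  The consensus is the per-column majority over all placed reads;
per-column base counts feed heteroplasmy calling.

Not a general-purpose assembler: no error correction, no scaffolding, and
reads are assumed to be in template orientation (no reverse-complement
overlap search).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

_BASES = "ACGTN"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Read:
    id: str
    sequence: str
    quality: str | None = None
    platform: str | None = None  # long-variable | short-fixed

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("empty read sequence")
        bad = set(self.sequence.upper()) - set(_BASES)
        if bad:
            raise ValueError(f"read {self.id}: illegal characters {bad}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AssemblyParams:
    min_overlap_bp: int = 100
    min_overlap_identity: float = 0.90
    max_gaps_per_read: float = 0.10
    max_gap_size_bp: int = 10

    def __post_init__(self) -> None:
        if self.min_overlap_bp <= 0 or self.max_gap_size_bp < 0:
            raise ValueError("overlap/gap sizes must be positive")
        if not 0 < self.min_overlap_identity <= 1:
            raise ValueError("identity must be in (0, 1]")


ROCHE_PARAMS = AssemblyParams(100, 0.90, 0.10, 10)
ILLUMINA_PARAMS = AssemblyParams(70, 0.90, 0.05, 5)
PRESETS = {"roche": ROCHE_PARAMS, "illumina": ILLUMINA_PARAMS}


@dataclass
class Placement:
    read_id: str
    offset: int
    sequence: str


@dataclass
class Contig:
    consensus: str
    circular: bool
    placements: list[Placement] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.consensus)

    @property
    def base_counts(self) -> np.ndarray:
        """5 x L matrix of A/C/G/T/N counts per consensus column."""
        L = len(self.consensus)
        counts = np.zeros((5, L), dtype=int)
        for p in self.placements:
            for i, base in enumerate(p.sequence.upper()):
                col = p.offset + i
                if self.circular:
                    col %= L
                elif col < 0 or col >= L:
                    continue
                counts[_BASE_INDEX.get(base, 4), col] += 1
        return counts

    @property
    def coverage(self) -> np.ndarray:
        """Per-column called-base depth (N excluded)."""
        return self.base_counts[:4].sum(axis=0)


# ---------------------------------------------------------------------------
# overlap evaluation

def _hamming_identity(a: str, b: str) -> float:
    x = np.frombuffer(a.upper().encode(), dtype="S1")
    y = np.frombuffer(b.upper().encode(), dtype="S1")
    return float((x == y).mean())


def _banded_identity(a: str, b: str, band: int) -> tuple[float, int]:
    """Identity and gap-column count of a banded global alignment of two
    same-region strings; fallback when a gap-free comparison fails."""
    n, m = len(a), len(b)
    if band == 0 or n == 0 or m == 0:
        return (_hamming_identity(a, b) if n == m else 0.0), 0
    prev = {0: (0, 0, 0)}  # diag offset -> (cost, matches, gaps)
    au, bu = a.upper(), b.upper()
    for i in range(1, n + 1):
        cur: dict[int, tuple[int, int, int]] = {}
        # descending so cur[off + 1] exists when a gap in `a` is considered
        for off in range(band, -band - 1, -1):
            j = i + off
            if j < 0 or j > m:
                continue
            best = None
            if off in prev and j >= 1:
                c, mt, gp = prev[off]
                match = au[i - 1] == bu[j - 1]
                cand = (c + (0 if match else 1), mt + (1 if match else 0), gp)
                best = cand
            if off - 1 in prev:  # gap in b
                c, mt, gp = prev[off - 1]
                cand = (c + 1, mt, gp + 1)
                if best is None or cand < best:
                    best = cand
            if off + 1 in cur:  # gap in a
                c, mt, gp = cur[off + 1]
                cand = (c + 1, mt, gp + 1)
                if best is None or cand < best:
                    best = cand
            if best is not None:
                cur[off] = best
        prev = cur
        if not prev:
            return 0.0, 0
    off = m - n
    if off not in prev:
        return 0.0, 0
    _, matches, gaps = prev[off]
    cols = max(n, m)
    return matches / cols, gaps


def _overlap_ok(a: str, b: str, params: AssemblyParams, read_len: int
                ) -> tuple[bool, float]:
    """Check the overlap region *a* (consensus) vs *b* (read) against the
    thresholds; gap-free first, banded fallback."""
    ident = _hamming_identity(a, b)
    if ident >= params.min_overlap_identity:
        return True, ident
    if params.max_gap_size_bp > 0:
        ident2, gaps = _banded_identity(a, b, params.max_gap_size_bp)
        if (ident2 >= params.min_overlap_identity
                and gaps <= params.max_gaps_per_read * read_len):
            return True, ident2
    return False, ident


# ---------------------------------------------------------------------------
# assembly

def _kmer_map(seq: str, k: int) -> dict[str, list[int]]:
    out: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        out.setdefault(seq[i:i + k], []).append(i)
    return out


def _candidate_offsets(cons_map: dict[str, list[int]], read: Read, k: int
                       ) -> set[int]:
    offs: set[int] = set()
    seq = read.sequence
    for pos in range(0, max(1, len(seq) - k + 1), k):
        for hit in cons_map.get(seq[pos:pos + k], ()):
            offs.add(hit - pos)
    return offs


def _better(best, key: tuple[int, float], read_id: str) -> bool:
    """Longest overlap wins, then identity, then the smaller read id."""
    if best is None:
        return True
    if key != best[0]:
        return key > best[0]
    return read_id < best[1].id


def assemble(reads: list[Read], params: AssemblyParams = ROCHE_PARAMS,
             kmer: int = 21) -> list[Contig]:
    """Greedy OLC assembly of *reads* into (possibly circular) contigs."""
    if not reads:
        raise ValueError("empty read set")
    if len({r.id for r in reads}) != len(reads):
        raise ValueError("duplicate read ids")
    unused = {r.id: r for r in sorted(reads, key=lambda r: (-len(r), r.id))}
    contigs: list[Contig] = []
    while unused:
        seed = next(iter(unused.values()))
        del unused[seed.id]
        placements = [Placement(seed.id, 0, seed.sequence)]
        cons = seed.sequence
        while True:
            cons_map = _kmer_map(cons, kmer)
            best = None  # ((overlap_len, identity), read, offset, side)
            absorbed = []
            for rid, read in unused.items():
                for off in sorted(_candidate_offsets(cons_map, read, kmer)):
                    rlen = len(read)
                    if off >= 0 and off + rlen <= len(cons):
                        ok, _ = _overlap_ok(cons[off:off + rlen],
                                            read.sequence, params, rlen)
                        if ok:
                            absorbed.append((read, off))
                            break
                    elif off >= 0 and off < len(cons):
                        ov = len(cons) - off
                        if ov < params.min_overlap_bp:
                            continue
                        ok, ident = _overlap_ok(cons[off:], read.sequence[:ov],
                                                params, rlen)
                        if ok and _better(best, (ov, ident), read.id):
                            best = ((ov, ident), read, off, "right")
                    elif off < 0 and rlen + off >= params.min_overlap_bp:
                        ov = rlen + off
                        if ov > len(cons):
                            continue
                        ok, ident = _overlap_ok(cons[:ov], read.sequence[-ov:],
                                                params, rlen)
                        if ok and _better(best, (ov, ident), read.id):
                            best = ((ov, ident), read, off, "left")
            for read, off in absorbed:
                if read.id in unused:
                    placements.append(Placement(read.id, off, read.sequence))
                    del unused[read.id]
            if best is None:
                if absorbed:
                    continue
                break
            _, read, off, side = best
            if read.id not in unused:  # already absorbed this sweep
                continue
            del unused[read.id]
            if side == "right":
                placements.append(Placement(read.id, off, read.sequence))
                cons = cons[:off] + read.sequence
            else:
                shift = -off
                for p in placements:
                    p.offset += shift
                placements.append(Placement(read.id, 0, read.sequence))
                cons = read.sequence + cons[len(read) - shift:]
        circular, trimmed = _circularize(cons, params)
        contig = Contig(consensus=trimmed, circular=circular,
                        placements=placements)
        contig = replace(contig, consensus=_majority_consensus(contig))
        contigs.append(contig)
    return contigs


def _circularize(cons: str, params: AssemblyParams) -> tuple[bool, str]:
    """Detect an end-to-end self-overlap meeting the merge thresholds and
    trim the duplicated suffix."""
    L = len(cons)
    limit = L // 2
    best = None  # (identity, ov)
    for ov in range(limit, params.min_overlap_bp - 1, -1):
        ident = _hamming_identity(cons[L - ov:], cons[:ov])
        if ident >= params.min_overlap_identity:
            if best is None or ident > best[0]:
                best = (ident, ov)
    if best is None and params.max_gap_size_bp > 0:
        # gapped fallback: first qualifying overlap, largest first
        for ov in range(limit, params.min_overlap_bp - 1, -1):
            ok, _ = _overlap_ok(cons[L - ov:], cons[:ov], params, ov)
            if ok:
                best = (0.0, ov)
                break
    if best is not None:
        return True, cons[:L - best[1]]
    return False, cons


def _majority_consensus(contig: Contig) -> str:
    counts = contig.base_counts[:4]
    called = counts.sum(axis=0) > 0
    # highest count wins; ties resolved alphabetically (argmax keeps the
    # first, and rows are already in alphabetical base order)
    best = counts.argmax(axis=0)
    out = np.array(list("ACGT"))[best]
    out[~called] = "N"
    return "".join(out)


# ---------------------------------------------------------------------------
# variant calling

@dataclass(frozen=True)
class HeteroplasmyCall:
    position: int          # 1-based on the consensus
    major: str
    minor: str
    minor_frequency: float
    coverage: int


def call_heteroplasmy(contig: Contig, min_coverage: int = 50,
                      min_variant_frequency: float = 0.10
                      ) -> list[HeteroplasmyCall]:
    """Call within-individual variant sites from per-column base counts.

    A site is called iff its called-base coverage is at least
    *min_coverage* and the most frequent alternative base reaches
    *min_variant_frequency*; both thresholds are inclusive.
    """
    counts = contig.base_counts[:4]
    cov = counts.sum(axis=0)
    calls = []
    for col in np.nonzero(cov >= min_coverage)[0]:
        col_counts = counts[:, col]
        # sort by count descending, alphabetical base on ties
        order = np.lexsort((np.arange(4), -col_counts))
        major_i, minor_i = order[0], order[1]
        if col_counts[minor_i] == 0:
            continue
        freq = col_counts[minor_i] / cov[col]
        if freq >= min_variant_frequency:
            calls.append(HeteroplasmyCall(
                position=int(col) + 1,
                major="ACGT"[major_i], minor="ACGT"[minor_i],
                minor_frequency=float(freq), coverage=int(cov[col])))
    return calls


def heteroplasmy_table(calls: list[HeteroplasmyCall], chrom: str = "contig"
                       ) -> str:
    """VCF-like TSV (CHROM, POS, REF, ALT, AF, DP)."""
    lines = ["CHROM\tPOS\tREF\tALT\tAF\tDP"]
    for c in calls:
        lines.append(f"{chrom}\t{c.position}\t{c.major}\t{c.minor}"
                     f"\t{c.minor_frequency:.4f}\t{c.coverage}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# tandem repeats

@dataclass(frozen=True)
class RepeatAnnotation:
    unit_length: int
    copies: float
    start: int             # 1-based
    mean_identity: float   # between consecutive copies

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.start + int(round(self.copies * self.unit_length))


def find_tandem_repeats(seq: str, min_unit: int, min_copies: float = 2.0,
                        min_identity: float = 0.8) -> list[RepeatAnnotation]:
    """Detect tandem-repeat arrays by periodic self-identity.

    For every candidate period d the sequence is compared with itself
    shifted by d; maximal regions where every length-d window matches its
    successor copy at *min_identity* or better become candidate arrays.
    Overlapping candidates (harmonics, off-by-one periods) are resolved by
    the highest copies x identity score.
    """
    L = len(seq)
    if L < 2 * min_unit:
        raise ValueError("sequence shorter than two repeat units")
    s = np.frombuffer(seq.upper().encode(), dtype="S1")
    candidates: list[tuple[float, RepeatAnnotation]] = []
    for d in range(min_unit, L // 2 + 1):
        m = (s[:-d] == s[d:]).astype(float)
        if len(m) < d:
            continue
        csum = np.concatenate(([0.0], np.cumsum(m)))
        win = (csum[d:] - csum[:-d]) / d  # win[i] = identity(seq[i:i+d], next copy)
        good = win >= min_identity
        if not good.any():
            continue
        # maximal runs of good windows
        idx = np.nonzero(good)[0]
        breaks = np.nonzero(np.diff(idx) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(idx) - 1]))
        for a, b in zip(starts, ends):
            i0, i1 = int(idx[a]), int(idx[b])
            span = (i1 - i0) + 2 * d
            copies = span / d
            if copies < min_copies:
                continue
            stacked = win[i0:i1 + 1:d]
            ann = RepeatAnnotation(unit_length=d, copies=float(copies),
                                   start=i0 + 1,
                                   mean_identity=float(stacked.mean()))
            candidates.append((ann.copies * ann.mean_identity, ann))
    candidates.sort(key=lambda t: (-t[0], t[1].unit_length))
    kept: list[RepeatAnnotation] = []
    for _, ann in candidates:
        lo, hi = ann.start, ann.start + ann.copies * ann.unit_length
        overlap = any(not (hi <= k.start or lo >= k.start + k.copies * k.unit_length)
                      for k in kept)
        if not overlap:
            kept.append(ann)
    kept.sort(key=lambda a: a.start)
    return kept


def repeat_table(annotations: list[RepeatAnnotation], chrom: str = "contig"
                 ) -> str:
    """BED-like TSV of repeat arrays (0-based half-open intervals)."""
    lines = ["#chrom\tstart\tend\tunit_bp\tcopies\tidentity"]
    for a in annotations:
        end = a.start - 1 + int(round(a.copies * a.unit_length))
        lines.append(f"{chrom}\t{a.start - 1}\t{end}\t{a.unit_length}"
                     f"\t{a.copies:.2f}\t{a.mean_identity:.3f}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# rotation normalization

def rotate_normalize(contig: Contig, anchor: str) -> Contig:
    """Rotate a circular contig so *anchor* starts at position 1; if the
    anchor lies on the minus strand the contig is reverse-complemented
    first.  Idempotent."""
    if not contig.circular:
        raise ValueError("rotation is only defined for circular contigs")
    anchor = anchor.upper()
    L = len(contig.consensus)
    doubled = (contig.consensus + contig.consensus).upper()
    pos = doubled.find(anchor)
    if 0 <= pos < L:
        return _rotate(contig, pos)
    rc = reverse_complement(contig.consensus)
    pos = (rc + rc).upper().find(anchor)
    if 0 <= pos < L:
        flipped = Contig(
            consensus=rc, circular=True,
            placements=[Placement(p.read_id,
                                  (L - p.offset - len(p.sequence)) % L,
                                  reverse_complement(p.sequence))
                        for p in contig.placements])
        return _rotate(flipped, pos)
    raise ValueError("anchor not found on either strand")


def _rotate(contig: Contig, pos: int) -> Contig:
    L = len(contig.consensus)
    cons = contig.consensus[pos:] + contig.consensus[:pos]
    placements = [Placement(p.read_id, (p.offset - pos) % L, p.sequence)
                  for p in contig.placements]
    return Contig(consensus=cons, circular=True, placements=placements)


# ---------------------------------------------------------------------------
# sequence statistics / IO helpers

def gc_fraction(seq: str) -> float:
    s = seq.upper()
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise ValueError("no called bases")
    return (s.count("G") + s.count("C")) / acgt


def read_fasta_sequences(path, fmt: str = "fasta") -> dict[str, str]:
    """Load user-supplied sequence records (e.g. the deposited
    minichromosome accessions) as a name → sequence mapping; *fmt* is any
    Biopython SeqIO format, typically ``"fasta"`` or ``"genbank"``."""
    from Bio import SeqIO
    records = {r.id: str(r.seq).upper() for r in SeqIO.parse(str(path), fmt)}
    if not records:
        raise ValueError(f"no {fmt} records in {path}")
    return records


def read_fastq(path) -> list[Read]:
    from Bio import SeqIO
    return [Read(r.id, str(r.seq).upper(),
                 quality="".join(chr(q + 33) for q in
                                 r.letter_annotations.get("phred_quality", [])))
            for r in SeqIO.parse(str(path), "fastq")]


def write_fastq(reads: list[Read], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            qual = r.quality or "I" * len(r)
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
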