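"""Synthetic fragmented-mitochondrial-genome data with known ground truth.

The generator emulates the structure the analysis modules assume: one
ancestral circular chromosome with the 37-gene insect ground pattern,
fragmented into circular minichromosomes that each pair a distinct coding
region with a near-identical shared non-coding region (NCR); the NCR
carries a GC-rich background, tandem-repeat arrays and a conserved anchor
motif; paralogous leucine tRNAs evolve with or without gene conversion;
reads come from a long variable-length profile (100–611 bp, mean 344,
sd 108) or a short fixed-length 90 bp profile, with optional substitution
errors and heteroplasmic sites at set minor-allele frequencies.

Every generator is a pure function of its configuration (the seed is
mandatory); defaults state the emulated system once and are not tuning
knobs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .assembly import Read, reverse_complement
from .concerted import AlignedSeqSet
from .genes import PROTEIN_GENES, RRNA_GENES, TRNA_GENES
from .karyotype import (AncestralArrangement, GeneCopy, MitoKaryotype,
                        Minichromosome)

# typical animal mitochondrial gene lengths (bp)
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "atp6": 678, "atp8": 159, "cob": 1137, "cox1": 1536, "cox2": 682,
    "cox3": 786, "nad1": 939, "nad2": 1020, "nad3": 351, "nad4": 1338,
    "nad4L": 291, "nad5": 1719, "nad6": 522, "rrnS": 750, "rrnL": 1200,
}
DEFAULT_GENE_LENGTHS.update({t: 65 for t in TRNA_GENES})


@dataclass(frozen=True)
class ReadProfile:
    name: str
    length_mean: float = 344.0
    length_sd: float = 108.0
    length_min: int = 100
    length_max: int = 611
    fixed_length: int | None = None


LONG_VARIABLE = ReadProfile("long-variable")
SHORT_FIXED = ReadProfile("short-fixed", fixed_length=90)


@dataclass(frozen=True)
class RepeatSpec:
    """A tandem-repeat array: unit length, copy number, and the target
    pairwise identity between copies."""
    unit_length: int = 225
    copies: int = 4
    identity: float = 0.85


@dataclass(frozen=True)
class HeteroplasmySite:
    template: str
    position: int      # 0-based on the template
    frequency: float


@dataclass(frozen=True)
class SimulationConfig:
    seed: int
    n_minichromosomes: int = 10
    ncr_length_bp: int = 2400
    ncr_repeat_specs: tuple[RepeatSpec, ...] = (RepeatSpec(225, 4, 0.85),
                                                RepeatSpec(346, 2, 0.85))
    ncr_gc_fraction: float = 0.40
    ncr_divergence: float = 0.01   # pairwise divergence between NCR copies (<=0.03)
    private_insert_bp: int = 0     # minichromosome-specific NCR insert (e.g. 99)
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    gene_length_scale: float = 1.0
    substitution_rate: float = 0.01
    gene_conversion_rate: float = 0.0
    read_profile: ReadProfile = LONG_VARIABLE
    error_rate: float = 0.0
    coverage: float = 30.0
    heteroplasmy_sites: tuple[HeteroplasmySite, ...] = ()

    def __post_init__(self) -> None:
        for r in (self.ncr_divergence, self.substitution_rate,
                  self.error_rate, self.ncr_gc_fraction):
            if not 0 <= r <= 1:
                raise ValueError("rates must lie in [0, 1]")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


_BASES = np.array(list("ACGT"))


def _random_seq(rng, n: int, gc: float = 0.5) -> str:
    """Random sequence with exact base composition (a shuffled multiset),
    so the realized GC fraction equals the target to within one base."""
    if n == 0:
        return ""
    n_g = int(round(n * gc / 2))
    n_c = int(round(n * gc)) - n_g
    n_a = (n - n_g - n_c + 1) // 2
    n_t = n - n_g - n_c - n_a
    arr = np.array(["G"] * n_g + ["C"] * n_c + ["A"] * n_a + ["T"] * n_t)
    return "".join(rng.permutation(arr))


def _mutate(rng, seq: str, rate: float, frozen: set[int] = frozenset()) -> str:
    """Per-site substitutions with uniform replacement."""
    if rate <= 0:
        return seq
    arr = np.array(list(seq))
    hits = np.nonzero(rng.random(len(arr)) < rate)[0]
    for i in hits:
        if int(i) in frozen:
            continue
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _shuffle_mutate(rng, seq: str, rate: float) -> str:
    """Composition-preserving divergence: cyclically permute the bases at a
    random subset of positions, so the sequence's base composition (and GC
    fraction) is exactly conserved.  The subset is inflated to compensate
    for same-base collisions, so the realized fraction of changed sites
    approximates *rate*."""
    n = len(seq)
    if rate <= 0 or n < 2:
        return seq
    arr = np.array(list(seq))
    _, counts = np.unique(arr, return_counts=True)
    p_collide = float(((counts / n) ** 2).sum())
    m = int(round(rate * n / max(1 - p_collide, 0.1)))
    m = min(max(m, 2), n)
    pos = rng.choice(n, size=m, replace=False)
    arr[pos] = np.roll(arr[pos], 1)
    return "".join(arr)


# ---------------------------------------------------------------------------
# fragmentation

def simulate_fragmentation(ancestral: AncestralArrangement, k: int,
                           n_rearrangements: int = 0, seed: int = 0
                           ) -> tuple[MitoKaryotype, dict]:
    """Cut the ancestral circle into *k* minichromosomes, then apply random
    single-gene excision/reinsertion moves (with optional strand flip).

    Cutting only removes adjacencies; every derived adjacency in the output
    comes from a recorded rearrangement event.
    """
    genes = ancestral.genes[ancestral.control_region_index:] \
        + ancestral.genes[:ancestral.control_region_index]
    n = len(genes)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}]")
    rng = np.random.default_rng(seed)
    extra = sorted(rng.choice(np.arange(1, n), size=k - 1, replace=False)) \
        if k > 1 else []
    cuts = [0] + [int(c) for c in extra]
    blocks = []
    for ci, start in enumerate(cuts):
        end = cuts[ci + 1] if ci + 1 < len(cuts) else n
        blocks.append(list(genes[start:end]))
    minis = [Minichromosome(genes=tuple(_map_to_transcription(b)))
             for b in blocks]
    events = []
    for _ in range(n_rearrangements):
        while True:
            src = int(rng.integers(0, len(minis)))
            if len(minis[src].genes) > 1:
                break
        gi = int(rng.integers(0, len(minis[src].genes)))
        gene_copy = minis[src].genes[gi]
        remaining = minis[src].genes[:gi] + minis[src].genes[gi + 1:]
        dst = int(rng.integers(0, len(minis)))
        flip = bool(rng.random() < 0.5)
        moved = (replace(gene_copy, orientation=-gene_copy.orientation)
                 if flip else gene_copy)
        minis[src] = Minichromosome(genes=remaining)
        pos = int(rng.integers(0, len(minis[dst].genes) + 1))
        dst_genes = minis[dst].genes[:pos] + (moved,) + minis[dst].genes[pos:]
        minis[dst] = Minichromosome(genes=dst_genes)
        events.append({"gene": gene_copy.symbol.name, "from": src, "to": dst,
                       "position": pos, "flipped": flip})
    karyotype = MitoKaryotype(species=f"synthetic_k{k}",
                              minichromosomes=tuple(minis),
                              source="simulated fragmentation")
    truth = {"cuts": cuts, "events": events}
    return karyotype, truth


def _map_to_transcription(block: list[GeneCopy]) -> list[GeneCopy]:
    """Reverse minus-strand map runs into transcription reading order."""
    out: list[GeneCopy] = []
    run: list[GeneCopy] = []
    for g in block:
        if run and g.orientation != run[-1].orientation:
            out.extend(reversed(run) if run[-1].orientation == -1 else run)
            run = []
        run.append(g)
    if run:
        out.extend(reversed(run) if run[-1].orientation == -1 else run)
    return out


# ---------------------------------------------------------------------------
# sequences

def simulate_minichromosome_sequences(karyotype: MitoKaryotype,
                                      config: SimulationConfig
                                      ) -> tuple[dict[str, str], dict]:
    """Build a circular sequence per minichromosome: coding region (gene
    placeholders, duplicates identical) followed by the shared NCR.

    The NCR ends in a conserved 20-bp anchor motif, so after rotation
    normalization on the motif the coding region starts right after it.
    NCR copies across minichromosomes diverge by ``ncr_divergence``
    (default 1%, comfortably above the 97% identity floor observed in
    fragmented louse genomes).
    """
    rng = np.random.default_rng(config.seed)
    scale = config.gene_length_scale
    gene_seqs = {}
    for name in PROTEIN_GENES + RRNA_GENES + TRNA_GENES:
        length = max(30, int(round(config.gene_lengths[name] * scale)))
        gene_seqs[name] = _random_seq(rng, length, 0.35)
    master_ncr, repeat_layout = _build_ncr(rng, config)
    anchor = _random_seq(rng, 20, config.ncr_gc_fraction)
    sequences: dict[str, str] = {}
    truth: dict = {"gene_sequences": gene_seqs, "anchor": anchor,
                   "repeat_layout": repeat_layout, "ncr": {}, "coding": {},
                   "templates": {}}
    for mi, mc in enumerate(karyotype.minichromosomes):
        coding = _coding_sequence(mc, gene_seqs)
        ncr = _shuffle_mutate(rng, master_ncr, config.ncr_divergence / 2)
        if config.private_insert_bp and mi == 0:
            ncr += _random_seq(rng, config.private_insert_bp,
                               config.ncr_gc_fraction)
        ncr += anchor
        seq = coding + ncr
        sequences[mc.label] = seq
        truth["coding"][mc.label] = (0, len(coding))
        truth["ncr"][mc.label] = (len(coding), len(seq))
        truth["templates"][mc.label] = seq
    return sequences, truth


def _coding_sequence(mc: Minichromosome, gene_seqs: dict[str, str]) -> str:
    """Physical coding-region sequence: transcription-ordered minus runs are
    laid down in reverse map order as reverse complements."""
    parts: list[str] = []
    run: list[GeneCopy] = []

    def flush():
        if not run:
            return
        if run[0].orientation == -1:
            parts.extend(reverse_complement(gene_seqs[g.symbol.name])
                         for g in reversed(run))
        else:
            parts.extend(gene_seqs[g.symbol.name] for g in run)
        run.clear()

    for g in mc.genes:
        if run and g.orientation != run[-1].orientation:
            flush()
        run.append(g)
    flush()
    return "".join(parts)


def _build_ncr(rng, config: SimulationConfig):
    """Random GC-controlled background with the configured repeat arrays."""
    gc = config.ncr_gc_fraction
    arrays = []
    layout = []
    total_repeat = 0
    for spec in config.ncr_repeat_specs:
        if spec.unit_length <= 0 or spec.copies <= 0:
            continue
        unit = _random_seq(rng, spec.unit_length, gc)
        per_copy = (1 - spec.identity) / 2  # so copies differ pairwise by ~1-identity
        arr = "".join(_shuffle_mutate(rng, unit, per_copy)
                      for _ in range(spec.copies))
        arrays.append(arr)
        total_repeat += len(arr)
    background = max(0, config.ncr_length_bp - total_repeat)
    n_gaps = len(arrays) + 1
    gap = background // n_gaps
    pieces = []
    pos = 0
    for i, arr in enumerate(arrays):
        pad = gap if i < n_gaps - 1 else 0
        pieces.append(_random_seq(rng, pad, gc))
        pos += pad
        spec = config.ncr_repeat_specs[i]
        layout.append({"unit_length": spec.unit_length, "copies": spec.copies,
                       "start": pos, "identity": spec.identity})
        pieces.append(arr)
        pos += len(arr)
    pieces.append(_random_seq(rng, background - gap * len(arrays), gc))
    return "".join(pieces), layout


def coding_amplicons(sequences: dict[str, str], truth: dict,
                     flank: int = 60) -> dict[str, str]:
    """Linear coding-region amplicons with short conserved-NCR flanks.

    Mimics priming from conserved NCR motifs close to the coding region:
    each amplicon is ``flank`` bp of upstream NCR + the coding region +
    ``flank`` bp of downstream NCR.  Keeping the flank shorter than the
    assembler's minimum overlap prevents the near-identical shared NCR from
    chimerizing distinct minichromosomes, which is exactly why the real
    protocol amplified coding regions."""
    out = {}
    for label, seq in sequences.items():
        a, b = truth["coding"][label]
        up = seq[-flank:] if flank else ""
        down = seq[b:b + flank]
        out[label] = up + seq[a:b] + down
    return out


# ---------------------------------------------------------------------------
# reads

def simulate_reads(templates: dict[str, str], config: SimulationConfig,
                   circular: bool = True) -> tuple[list[Read], dict]:
    """Sample reads from each template under the configured profile.

    Circular templates get wrap-around start positions.  Heteroplasmy is
    injected by giving each read covering a configured site the minor
    allele with the site's frequency; substitution errors follow.
    """
    if config.coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng(config.seed)
    profile = config.read_profile
    reads: list[Read] = []
    truth: dict = {"reads": {}, "minor_alleles": {}}
    minor_base: dict[tuple[str, int], str] = {}
    for site in config.heteroplasmy_sites:
        ref = templates[site.template][site.position]
        alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
        minor_base[(site.template, site.position)] = alt
        truth["minor_alleles"][(site.template, site.position)] = alt
    for name in sorted(templates):
        seq = templates[name]
        L = len(seq)
        mean_len = profile.fixed_length or profile.length_mean
        n_reads = math.ceil(config.coverage * L / mean_len)
        doubled = seq + seq
        for i in range(n_reads):
            if profile.fixed_length:
                rlen = profile.fixed_length
            else:
                while True:
                    rlen = int(round(rng.normal(profile.length_mean,
                                                profile.length_sd)))
                    if profile.length_min <= rlen <= profile.length_max:
                        break
            if circular:
                rlen = min(rlen, L)
                start = int(rng.integers(0, L))
                rseq = doubled[start:start + rlen]
            else:
                # overhanging starts are clipped so amplicon ends get the
                # same coverage as the interior; drop tiny clipped stubs
                raw = int(rng.integers(-(rlen - 1), L))
                start = max(0, raw)
                end = min(L, raw + rlen)
                if end - start < 50:
                    continue
                rlen = end - start
                rseq = seq[start:end]
            for site in config.heteroplasmy_sites:
                if site.template != name:
                    continue
                off = (site.position - start) % L if circular \
                    else site.position - start
                if 0 <= off < rlen and rng.random() < site.frequency:
                    rseq = rseq[:off] + minor_base[(name, site.position)] \
                        + rseq[off + 1:]
            rseq = _mutate(rng, rseq, config.error_rate)
            rid = f"{name}_r{i:05d}"
            reads.append(Read(rid, rseq, quality="I" * rlen,
                              platform=profile.name))
            truth["reads"][rid] = {"template": name, "start": start,
                                   "length": rlen}
    return reads, truth


# ---------------------------------------------------------------------------
# paralog pairs

def simulate_paralog_pair(n_species: int, regime: str, seed: int = 0,
                          n_sites: int = 72,
                          root_depth: float = 0.45,
                          species_depth: float = 0.15,
                          conversion_rate: float | None = None,
                          conversion_tract: tuple[int, int] | str | None = None,
                          anticodon_positions: tuple[int, int, int] = (35, 36, 37),
                          ) -> tuple[AlignedSeqSet, dict]:
    """Evolve a trnL1/trnL2 pair across *n_species* under one regime.

    The paralogs duplicate at the root (total depth ``root_depth``
    substitutions/site) and species split simultaneously at
    ``species_depth``; each paralog then evolves independently down its
    terminal branch.  Under ``"concerted"`` gene-conversion events (Poisson
    with mean ``conversion_rate``, default 5 per terminal branch) copy a
    random tract between the two paralogs of a species; the three anticodon
    sites are frozen and never converted, so converted pairs still differ
    at exactly those positions.  ``conversion_tract="full"`` forces one
    full-length conversion per species.
    """
    if n_species < 2:
        raise ValueError("need at least 2 species")
    if regime not in ("independent", "concerted"):
        raise ValueError(f"unknown regime {regime!r}")
    rng = np.random.default_rng(seed)
    if conversion_rate is None:
        conversion_rate = 5.0 if regime == "concerted" else 0.0
    frozen = {p - 1 for p in anticodon_positions}
    root = _random_seq(rng, n_sites, 0.40)
    # per-site distinct triplets, never touched afterwards, so paralogs
    # always differ at exactly these three positions
    l1_anti, l2_anti = "ACT", "GTA"
    seq_l1 = _with_sites(root, anticodon_positions, l1_anti)
    seq_l2 = _with_sites(root, anticodon_positions, l2_anti)
    trunk = max(root_depth - species_depth, 0.0)
    anc_l1 = _mutate(rng, seq_l1, trunk, frozen)
    anc_l2 = _mutate(rng, seq_l2, trunk, frozen)
    records: dict[str, str] = {}
    events: dict[str, list] = {}
    for si in range(n_species):
        sp = f"sp{si + 1:02d}"
        l1 = _mutate(rng, anc_l1, species_depth, frozen)
        l2 = _mutate(rng, anc_l2, species_depth, frozen)
        events[sp] = []
        if conversion_tract == "full":
            n_events = 1
        else:
            n_events = int(rng.poisson(conversion_rate))
        for _ in range(n_events):
            if conversion_tract == "full":
                a, b = 0, n_sites
            elif conversion_tract is not None:
                a, b = conversion_tract
            else:
                # conversion tracts cover at least half of a short tRNA gene
                span = int(rng.integers(n_sites // 2, n_sites + 1))
                a = int(rng.integers(0, n_sites - span + 1))
                b = a + span
            donor_is_l1 = bool(rng.random() < 0.5)
            donor, acceptor = (l1, l2) if donor_is_l1 else (l2, l1)
            converted = "".join(
                acceptor[i] if i in frozen or not (a <= i < b) else donor[i]
                for i in range(n_sites))
            if donor_is_l1:
                l2 = converted
            else:
                l1 = converted
            events[sp].append({"tract": (a, b), "donor": "L1" if donor_is_l1 else "L2"})
        records[f"{sp}|L1"] = l1
        records[f"{sp}|L2"] = l2
    truth = {"regime": regime, "conversion_events": events,
             "anticodon_positions": anticodon_positions,
             "ancestors": {"L1": anc_l1, "L2": anc_l2}}
    return AlignedSeqSet(records), truth


def _with_sites(seq: str, positions, bases: str) -> str:
    arr = list(seq)
    for p, b in zip(positions, bases):
        arr[p - 1] = b
    return "".join(arr)
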