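import random

import numpy as np
import pytest

from mitokaryo.assembly import (AssemblyParams, Contig, Placement, Read,
                                ROCHE_PARAMS, assemble, call_heteroplasmy,
                                find_tandem_repeats, gc_fraction,
                                read_fasta_sequences, rotate_normalize,
                                reverse_complement, write_fastq, read_fastq)
from mitokaryo.simulate import (SimulationConfig, simulate_reads)


def random_seq(rng, n, gc=0.5):
    return "".join(rng.choices("ACGT", weights=[(1 - gc) / 2, gc / 2,
                                                gc / 2, (1 - gc) / 2], k=n))


def tiling_reads(template, read_len, step, circular=True):
    """Deterministic error-free reads tiling a template."""
    L = len(template)
    doubled = template + template
    reads = []
    starts = range(0, L, step) if circular else range(0, L - read_len + 1, step)
    for i, s in enumerate(starts):
        seq = doubled[s:s + read_len] if circular else template[s:s + read_len]
        reads.append(Read(f"r{i:04d}", seq))
    if not circular and (L - read_len) % step:
        reads.append(Read("rlast", template[-read_len:]))
    return reads


class TestReadValidation:
    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            Read("r1", "")

    def test_illegal_characters_rejected(self):
        with pytest.raises(ValueError):
            Read("r1", "ACGU")


class TestAssemble:
    def test_empty_read_set_errors(self):
        with pytest.raises(ValueError):
            assemble([])

    def test_insufficient_overlap_gives_two_contigs(self):
        rng = random.Random(1)
        template = random_seq(rng, 350)
        r1, r2 = Read("a", template[:200]), Read("b", template[150:])
        contigs = assemble([r1, r2])  # 50 bp overlap < 100 bp minimum
        assert len(contigs) == 2

    def test_sufficient_overlap_merges(self):
        rng = random.Random(2)
        template = random_seq(rng, 350)
        r1, r2 = Read("a", template[:230]), Read("b", template[120:])
        contigs = assemble([r1, r2])  # 110 bp overlap
        assert len(contigs) == 1
        assert contigs[0].consensus == template
        assert not contigs[0].circular

    def test_circular_template_exact_recovery(self):
        """Error-free tiling reads reconstruct random circles exactly up to
        rotation (seeded sizes 1-4 kb)."""
        rng = random.Random(3)
        for size in (1000, 2500, 4000):
            template = random_seq(rng, size)
            reads = tiling_reads(template, 300, 150)
            contigs = assemble(reads)
            assert len(contigs) == 1
            c = contigs[0]
            assert c.circular
            assert len(c.consensus) == size
            assert c.consensus in template + template

    def test_identity_threshold_monotonicity(self):
        """Raising min_overlap_identity never increases accepted merges."""
        rng = random.Random(4)
        template = random_seq(rng, 1500)
        reads = tiling_reads(template, 300, 150)
        # sprinkle mismatches on half the reads
        noisy = []
        for i, r in enumerate(reads):
            seq = list(r.sequence)
            if i % 2:
                for pos in rng.sample(range(len(seq)), 20):
                    seq[pos] = "ACGT"[(("ACGT".index(seq[pos])) + 1) % 4]
            noisy.append(Read(r.id, "".join(seq)))
        merges = []
        for ident in (0.80, 0.90, 0.95, 0.999):
            params = AssemblyParams(100, ident, 0.10, 10)
            contigs = assemble(noisy, params)
            merges.append(len(noisy) - len(contigs))
        assert merges == sorted(merges, reverse=True)

    def test_consensus_majority_on_disagreement(self):
        # three coextensive reads; one carries a variant (sequence must be
        # non-repetitive or reads also merge at shifted offsets)
        rng = random.Random(6)
        base = random_seq(rng, 240)
        pos = 120
        alt = "ACGT"[("ACGT".index(base[pos]) + 1) % 4]
        variant = base[:pos] + alt + base[pos + 1:]
        reads = [Read("a", base), Read("b", base), Read("c", variant)]
        contigs = assemble(reads)
        assert len(contigs) == 1
        assert contigs[0].consensus == base


def make_contig(columns):
    """Build a single-column-resolution contig from per-column base counts
    via stacked one-base reads."""
    placements = []
    consensus = []
    rid = 0
    for col, counts in enumerate(columns):
        best = max(sorted(counts), key=lambda b: counts[b])
        consensus.append(best)
        for base, n in sorted(counts.items()):
            for _ in range(n):
                placements.append(Placement(f"p{rid}", col, base))
                rid += 1
    return Contig(consensus="".join(consensus), circular=False,
                  placements=placements)


class TestHeteroplasmy:
    def test_inclusive_boundary_called(self):
        contig = make_contig([{"A": 45, "G": 5}])
        calls = call_heteroplasmy(contig, 50, 0.10)
        assert len(calls) == 1
        assert calls[0].minor == "G"
        assert calls[0].minor_frequency == pytest.approx(0.10)

    def test_below_frequency_not_called(self):
        contig = make_contig([{"A": 46, "G": 4}])
        assert call_heteroplasmy(contig, 50, 0.10) == []

    def test_below_coverage_not_called(self):
        contig = make_contig([{"A": 40, "G": 9}])
        assert call_heteroplasmy(contig, 50, 0.10) == []

    def test_matches_brute_force_filter(self):
        """Caller agrees with a direct per-column re-derivation."""
        rng = random.Random(9)
        columns = []
        for _ in range(300):
            cov = rng.randint(30, 120)
            minor = rng.randint(0, cov // 2)
            columns.append({"A": cov - minor, "C": minor})
        contig = make_contig(columns)
        got = {(c.position, c.minor_frequency) for c in
               call_heteroplasmy(contig, 50, 0.10)}
        expected = set()
        for pos, counts in enumerate(columns, start=1):
            cov = counts["A"] + counts["C"]
            if cov >= 50 and counts["C"] > 0 and counts["C"] / cov >= 0.10:
                expected.add((pos, counts["C"] / cov))
        assert got == expected


class TestTandemRepeats:
    def test_perfect_short_repeat(self):
        anns = find_tandem_repeats("ACGTACGTACGT", min_unit=4)
        assert len(anns) == 1
        assert anns[0].unit_length == 4
        assert anns[0].copies == pytest.approx(3.0)
        assert anns[0].mean_identity == pytest.approx(1.0)

    def test_negative_control_random_sequence(self):
        rng = random.Random(12)
        seq = random_seq(rng, 2000)
        anns = find_tandem_repeats(seq, min_unit=100, min_identity=0.8)
        assert anns == []

    def test_too_short_sequence_errors(self):
        with pytest.raises(ValueError):
            find_tandem_repeats("ACGT", min_unit=4)

    def test_degraded_array_detected(self):
        rng = random.Random(13)
        unit = random_seq(rng, 150)
        copies = []
        for _ in range(4):
            seq = list(unit)
            for pos in rng.sample(range(150), 10):  # ~7% per-copy divergence
                seq[pos] = "ACGT"[("ACGT".index(seq[pos]) + 1) % 4]
            copies.append("".join(seq))
        seq = random_seq(rng, 300) + "".join(copies) + random_seq(rng, 300)
        anns = find_tandem_repeats(seq, min_unit=100, min_identity=0.75)
        assert len(anns) == 1
        assert abs(anns[0].unit_length - 150) <= 5
        assert round(anns[0].copies) == 4


class TestRotateNormalize:
    def test_rotation_idempotent(self):
        rng = random.Random(14)
        template = random_seq(rng, 600)
        anchor = template[200:220]
        contig = Contig(consensus=template[100:] + template[:100],
                        circular=True, placements=[])
        once = rotate_normalize(contig, anchor)
        twice = rotate_normalize(once, anchor)
        assert once.consensus == twice.consensus
        assert once.consensus.startswith(anchor)

    def test_reverse_complement_normalizes_to_same(self):
        rng = random.Random(15)
        template = random_seq(rng, 600)
        anchor = template[50:70]
        fwd = Contig(consensus=template, circular=True, placements=[])
        rev = Contig(consensus=reverse_complement(template), circular=True,
                     placements=[])
        assert rotate_normalize(fwd, anchor).consensus == \
            rotate_normalize(rev, anchor).consensus

    def test_linear_contig_rejected(self):
        with pytest.raises(ValueError):
            rotate_normalize(Contig("ACGT", False, []), "AC")

    def test_absent_anchor_rejected(self):
        with pytest.raises(ValueError):
            rotate_normalize(Contig("ACGTACGT", True, []), "TTTTT")


class TestSequenceHelpers:
    def test_gc_fraction(self):
        assert gc_fraction("GGCC") == 1.0
        assert gc_fraction("ATGC") == 0.5

    def test_fasta_reader_on_synthetic_file(self, tmp_path):
        path = tmp_path / "synthetic_accessions.fasta"
        path.write_text(">acc1 synthetic stand-in\nACGTACGT\n>acc2\nGGCC\n")
        seqs = read_fasta_sequences(path)
        assert seqs == {"acc1": "ACGTACGT", "acc2": "GGCC"}

    def test_fastq_round_trip(self, tmp_path):
        reads = [Read("a", "ACGT", quality="IIII"), Read("b", "GGTT")]
        path = tmp_path / "r.fastq"
        write_fastq(reads, path)
        back = read_fastq(path)
        assert [(r.id, r.sequence) for r in back] == \
            [("a", "ACGT"), ("b", "GGTT")]


def test_reconstructed_ncr_gc_matches_template():
    """Error-free reads preserve the template's GC fraction exactly."""
    rng = random.Random(16)
    template = random_seq(rng, 1200, gc=0.40)
    reads = tiling_reads(template, 300, 150)
    contigs = assemble(reads)
    assert len(contigs) == 1
    assert gc_fraction(contigs[0].consensus) == \
        pytest.approx(gc_fraction(template))
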