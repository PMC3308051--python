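"""Demultiplexer, mini-aligner and trim-realign loop contracts."""

import numpy as np
import pytest

from polycap.read_prep import (
    AlignerParams,
    MULTI_HIT,
    NO_HIT,
    ReadRecord,
    ReferenceIndex,
    align_read,
    align_reads,
    demultiplex,
    iterative_trim_align,
)
from polycap.synthetic_tetraploid import revcomp, simulate_reads, simulate_references, SimConfig

Q35 = chr(33 + 35)


def _read(seq, rid="r1", qual=None):
    return ReadRecord(rid, seq, qual if qual is not None else Q35 * len(seq))


def _random_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


class TestDemultiplex:
    TAGS = {"AT": "Ld", "GAT": "Ld", "CCAGT": "Td", "": "Td"}

    def test_tag_assignment_and_trimming(self):
        assigned, rejected = demultiplex([_read("ATGGCAAAA")], self.TAGS)
        assert [r.sequence for r in assigned["Ld"]] == ["GGCAAAA"]
        assert rejected == []

    def test_longest_prefix_wins(self):
        assigned, _ = demultiplex([_read("GATTCAAAA")], self.TAGS)
        (r,) = assigned["Ld"]
        assert r.sequence == "TCAAAA"  # GAT matched, not AT

    def test_no_tag_class_collects_unmatched(self):
        assigned, rejected = demultiplex([_read("TTTTTTTT")], self.TAGS)
        assert [r.sequence for r in assigned["Td"]] == ["TTTTTTTT"]
        assert rejected == []

    def test_low_quality_tag_rejected(self):
        qual = chr(33 + 10) + Q35 * 7  # phred 10 within first four bases
        _, rejected = demultiplex([_read("ATGGCAAA", qual=qual)], self.TAGS)
        assert len(rejected) == 1

    def test_partition_invariant(self, rng):
        reads = [_read(_random_seq(rng, 40), rid=f"r{i}") for i in range(200)]
        assigned, rejected = demultiplex(reads, self.TAGS)
        assert sum(len(v) for v in assigned.values()) + len(rejected) == 200

    def test_without_no_tag_class_unmatched_rejected(self):
        assigned, rejected = demultiplex([_read("TTTTTTTT")],
                                         {"AT": "Ld", "CCAGT": "Td"})
        assert len(rejected) == 1


@pytest.fixture(scope="module")
def reference():
    rng = np.random.default_rng(123)
    seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 3000))
    dup = seq[100:160]
    # plant an exact duplicate of a 60-mer on a second target
    seq2 = ("".join("ACGT"[i] for i in rng.integers(0, 4, 1000)) + dup
            + "".join("ACGT"[i] for i in rng.integers(0, 4, 500)))
    return {"t1": seq, "t2": seq2}


@pytest.fixture(scope="module")
def index(reference):
    return ReferenceIndex(reference)


def _mutate_at(seq, positions):
    out = list(seq)
    for p in positions:
        out[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[p]]
    return "".join(out)


class TestAligner:
    def test_exact_unique_read_aligns(self, reference, index):
        read = _read(reference["t1"][500:540])
        res = align_read(read, index)
        assert res.alignment is not None
        assert (res.alignment.target, res.alignment.pos,
                res.alignment.mismatches) == ("t1", 500, 0)

    def test_reverse_strand_alignment(self, reference, index):
        read = _read(revcomp(reference["t1"][700:740]))
        res = align_read(read, index)
        a = res.alignment
        assert a is not None and (a.target, a.pos, a.strand) == ("t1", 700, "-")
        assert a.aligned_seq == reference["t1"][700:740]

    def test_duplicated_sequence_suppressed_as_ambiguous(self, reference, index):
        read = _read(reference["t1"][110:150])  # inside the planted duplicate
        res = align_read(read, index)
        assert res.alignment is None and res.reason == MULTI_HIT

    def test_three_seed_mismatches_rejected(self, reference, index):
        read = _read(_mutate_at(reference["t1"][500:540], [2, 9, 20]))
        res = align_read(read, index)
        assert res.alignment is None and res.reason == NO_HIT

    def test_two_seed_plus_one_tail_mismatch_accepted(self, reference, index):
        read = _read(_mutate_at(reference["t1"][500:540], [2, 9, 35]))
        res = align_read(read, index)
        assert res.alignment is not None and res.alignment.mismatches == 3

    def test_four_total_mismatches_rejected(self, reference, index):
        read = _read(_mutate_at(reference["t1"][500:540], [2, 9, 32, 36]))
        assert align_read(read, index).reason == NO_HIT

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError):
            ReferenceIndex({})

    def test_brute_force_oracle_equivalence(self, reference, index, rng):
        """Seeded lookup reports exactly what an exhaustive scanner finds."""
        params = AlignerParams()

        def oracle(seq):
            hits = []
            for name, ref in reference.items():
                L = len(seq)
                for strand, q in (("+", seq), ("-", revcomp(seq))):
                    seed = min(params.seed_length, L)
                    lo, hi = (0, seed) if strand == "+" else (L - seed, L)
                    for s in range(len(ref) - L + 1):
                        w = ref[s:s + L]
                        nm = sum(a != b for a, b in zip(q, w))
                        nm_seed = sum(a != b for a, b in
                                      zip(q[lo:hi], w[lo:hi]))
                        if nm <= params.max_total_mismatches and \
                                nm_seed <= params.max_seed_mismatches:
                            hits.append((name, s, strand))
            return hits

        reads = []
        for _ in range(60):
            t = "t1" if rng.random() < 0.7 else "t2"
            s = int(rng.integers(0, len(reference[t]) - 40))
            seq = reference[t][s:s + 40]
            k = int(rng.integers(0, 5))
            seq = _mutate_at(seq, list(rng.choice(40, size=k, replace=False)))
            if rng.random() < 0.5:
                seq = revcomp(seq)
            reads.append(seq)
        reads += [_random_seq(rng, 40) for _ in range(10)]
        reads.append(reference["t1"][105:145])  # ambiguous by construction

        for seq in reads:
            res = align_read(_read(seq), index, params)
            expected = set(oracle(seq))
            if len(expected) == 1:
                ((t, s, strand),) = expected
                assert res.alignment is not None
                assert (res.alignment.target, res.alignment.pos,
                        res.alignment.strand) == (t, s, strand)
            elif len(expected) > 1:
                assert res.reason == MULTI_HIT
            else:
                assert res.reason == NO_HIT


class TestIterativeTrim:
    STRICT = AlignerParams(max_seed_mismatches=0, max_total_mismatches=0)

    def test_intronic_tail_trimmed_from_three_prime(self, reference, index, rng):
        read = _read(reference["t1"][400:432] + _mutate_at(_random_seq(rng, 8), []))
        aligned, exhausted = iterative_trim_align([read], index, self.STRICT)
        (a,) = aligned
        assert (a.pos, a.trim3, a.trim5, len(a.aligned_seq)) == (400, 8, 0, 32)

    def test_eleven_residual_bases_exhaust_the_length_floor(self, reference,
                                                            index):
        # removing all 11 foreign bases would leave 29 < 30 -> exhausted
        junk = _mutate_at(reference["t1"][432:443], range(11))
        read = _read(reference["t1"][400:429] + junk)
        aligned, exhausted = iterative_trim_align([read], index, self.STRICT)
        assert aligned == [] and len(exhausted) == 1

    def test_nine_residual_bases_align_at_31(self, reference, index):
        junk = _mutate_at(reference["t1"][431:440], range(9))
        read = _read(reference["t1"][400:431] + junk)
        aligned, _ = iterative_trim_align([read], index, self.STRICT)
        (a,) = aligned
        assert (a.trim3, len(a.aligned_seq)) == (9, 31)

    def test_five_prime_junk_trimmed(self, reference, index):
        junk = _mutate_at(reference["t1"][395:400], range(5))
        read = _read(junk + reference["t1"][400:435])
        aligned, _ = iterative_trim_align([read], index, self.STRICT)
        (a,) = aligned
        assert (a.pos, a.trim5, a.trim3) == (400, 5, 0)

    def test_fully_foreign_read_exhausts(self, index, rng):
        read = _read(_random_seq(rng, 40))
        aligned, exhausted = iterative_trim_align([read], index, self.STRICT)
        assert aligned == [] and len(exhausted) == 1

    def test_no_alignment_shorter_than_min_length(self, reference, index, rng):
        reads = [_read(reference["t1"][i * 50:i * 50 + 30]
                       + _random_seq(rng, 10), rid=f"r{i}") for i in range(10)]
        aligned, _ = iterative_trim_align(reads, index, self.STRICT, min_length=30)
        assert all(len(a.aligned_seq) >= 30 for a in aligned)


class TestSimulatedRecall:
    def test_exonic_reads_from_reference_homoeolog_all_align(self):
        cfg = SimConfig(n_genes=4, seed=13, seq_error_rate=0.0,
                        n_paralog_genes=0, n_homoeolog_deletions=0,
                        n_pav_genes=0, n_duplicated_families=0)
        targets, copies, truth = simulate_references(cfg)
        reads = simulate_reads(truth, cfg)
        refs = {g: t.seq for g, t in targets.items()}
        index = ReferenceIndex(refs)
        origin = {g: t.origin_genome for g, t in targets.items()}
        exonic = []
        for acc in cfg.accessions:
            tag = cfg.tag_table[acc]
            for r in reads[acc]:
                _, gene, label, start, strand, _ = r.id.split("|")
                if label != origin[gene]:
                    continue
                frag = r.sequence[len(tag):]
                probe = revcomp(frag) if strand == "-" else frag
                if probe in refs[gene]:  # exonic-only fragment
                    exonic.append(ReadRecord(r.id, frag, Q35 * len(frag)))
        assert len(exonic) > 100
        aligned, no_hit, multi = align_reads(exonic, index)
        assert len(no_hit) == 0
        assert len(aligned) + len(multi) == len(exonic)
        assert len(multi) == 0
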