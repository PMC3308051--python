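"""Read demultiplexing and ungapped unique-placement alignment.

The aligner reproduces the semantics of short-read mapping with a mismatch-
limited seed and unique-placement reporting: a read is reported only if
exactly one end-to-end placement (either strand) has at most
``max_seed_mismatches`` in its first ``seed_length`` bases and at most
``max_total_mismatches`` overall; reads with two or more qualifying placements
are suppressed as ambiguous.  Unaligned reads are rescued by iteratively
trimming one base from the 3' (preferred) or 5' end and re-aligning, down to a
30-bp floor — this recovers reads that straddle exon-intron junctions when
aligning genomic fragments against a cDNA reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .synthetic_tetraploid import revcomp

_PART = 9  # pigeonhole seed-part length for candidate lookup

NO_HIT = "no_hit"
MULTI_HIT = "multi_hit"


@dataclass
class ReadRecord:
    """A (possibly tag-trimmed) read with its phred33 quality string."""

    id: str
    sequence: str
    quality: str
    accession: Optional[str] = None
    trim5: int = 0
    trim3: int = 0

    def __post_init__(self):
        if len(self.sequence) != len(self.quality):
            raise ValueError(f"{self.id}: sequence/quality length mismatch")


@dataclass(frozen=True)
class AlignerParams:
    seed_length: int = 28
    max_seed_mismatches: int = 2
    max_total_mismatches: int = 3
    unique_only: bool = True

    def __post_init__(self):
        if self.max_seed_mismatches < 0 or self.max_total_mismatches < 0:
            raise ValueError("mismatch caps must be >= 0")


@dataclass
class Alignment:
    read_id: str
    target: str
    pos: int  # 0-based reference offset
    strand: str  # '+' or '-'
    mismatches: int
    aligned_seq: str  # reference-oriented read sequence (revcomp for '-')
    accession: Optional[str] = None
    trim5: int = 0
    trim3: int = 0

    @property
    def length(self) -> int:
        return len(self.aligned_seq)


@dataclass
class AlignmentResult:
    alignment: Optional[Alignment]
    reason: Optional[str] = None  # NO_HIT | MULTI_HIT when alignment is None


class TagTableError(ValueError):
    pass


def demultiplex(
    reads: Iterable[ReadRecord],
    tag_table: Dict[str, str],
    min_tag_quality: int = 15,
) -> Tuple[Dict[str, List[ReadRecord]], List[ReadRecord]]:
    """Assign tagged reads to accessions and trim the tag.

    ``tag_table`` maps tag sequence -> accession; the empty-string key, if
    present, defines a no-tag class that collects reads matching no tag.
    Reads whose first four bases include a phred33 quality below
    ``min_tag_quality`` are rejected outright.  The longest matching tag
    prefix wins, so shorter tags may be prefixes of longer ones.
    """
    for tag in tag_table:
        if any(b not in "ACGT" for b in tag):
            raise TagTableError(f"tag {tag!r} contains non-ACGT characters")
    tags = sorted((t for t in tag_table if t), key=len, reverse=True)
    no_tag_acc = tag_table.get("")

    assigned: Dict[str, List[ReadRecord]] = {acc: [] for acc in set(tag_table.values())}
    rejected: List[ReadRecord] = []
    for read in reads:
        head_q = read.quality[:4]
        if len(head_q) < 4 or any(ord(c) - 33 < min_tag_quality for c in head_q):
            rejected.append(read)
            continue
        hit = next((t for t in tags if read.sequence.startswith(t)), None)
        if hit is not None:
            n = len(hit)
            assigned[tag_table[hit]].append(
                ReadRecord(read.id, read.sequence[n:], read.quality[n:],
                           accession=tag_table[hit])
            )
        elif no_tag_acc is not None:
            assigned[no_tag_acc].append(
                ReadRecord(read.id, read.sequence, read.quality, accession=no_tag_acc)
            )
        else:
            rejected.append(read)
    return assigned, rejected


class ReferenceIndex:
    """Exact 9-mer lookup index over a reference set.

    With a 28-bp seed allowing <=2 mismatches, at least one of three disjoint
    9-mers inside the seed's first 27 bases must match exactly (pigeonhole),
    so exact part lookup enumerates every qualifying placement.
    """

    def __init__(self, references: Dict[str, str]):
        if not references:
            raise ValueError("empty reference set")
        self.references = {name: seq.upper() for name, seq in references.items()}
        index: Dict[str, List[Tuple[str, int]]] = {}
        for name, seq in self.references.items():
            for i in range(len(seq) - _PART + 1):
                index.setdefault(seq[i : i + _PART], []).append((name, i))
        self._index = index

    def lookup(self, part: str) -> Sequence[Tuple[str, int]]:
        return self._index.get(part, ())


def _count_mismatches(query: str, window: str, seed_slice: Tuple[int, int],
                      cap_seed: int, cap_total: int) -> Optional[int]:
    """Total mismatches, or None if either cap is exceeded."""
    s0, s1 = seed_slice
    nm_seed = 0
    nm_total = 0
    for i, (a, b) in enumerate(zip(query, window)):
        if a != b:
            nm_total += 1
            if nm_total > cap_total:
                return None
            if s0 <= i < s1:
                nm_seed += 1
                if nm_seed > cap_seed:
                    return None
    return nm_total


def _placements(seq: str, index: ReferenceIndex, params: AlignerParams):
    """All (target, pos, strand, nm) placements satisfying both caps."""
    L = len(seq)
    seed = min(params.seed_length, L)
    refs = index.references
    rc = revcomp(seq)
    candidates = set()
    if seed >= 3 * _PART:
        for j in (0, _PART, 2 * _PART):
            for t, p in index.lookup(seq[j : j + _PART]):
                s = p - j
                if 0 <= s and s + L <= len(refs[t]):
                    candidates.add((t, s, "+"))
        for j in (L - 3 * _PART, L - 2 * _PART, L - _PART):
            for t, p in index.lookup(rc[j : j + _PART]):
                s = p - j
                if 0 <= s and s + L <= len(refs[t]):
                    candidates.add((t, s, "-"))
    else:  # short-seed fallback: exhaustive scan (tiny references only)
        for t, ref in refs.items():
            for s in range(len(ref) - L + 1):
                candidates.add((t, s, "+"))
                candidates.add((t, s, "-"))
    out = []
    for t, s, strand in candidates:
        window = refs[t][s : s + L]
        query = seq if strand == "+" else rc
        seed_slice = (0, seed) if strand == "+" else (L - seed, L)
        nm = _count_mismatches(query, window, seed_slice,
                               params.max_seed_mismatches, params.max_total_mismatches)
        if nm is not None:
            out.append((t, s, strand, nm))
    return out


def align_read(
    read: ReadRecord, index: ReferenceIndex, params: AlignerParams = AlignerParams()
) -> AlignmentResult:
    """Align one read end-to-end; unique placements only."""
    hits = _placements(read.sequence, index, params)
    if not hits:
        return AlignmentResult(None, NO_HIT)
    if len(hits) > 1 and params.unique_only:
        return AlignmentResult(None, MULTI_HIT)
    t, s, strand, nm = min(hits, key=lambda h: (h[3], h[0], h[1]))
    oriented = read.sequence if strand == "+" else revcomp(read.sequence)
    return AlignmentResult(
        Alignment(read.id, t, s, strand, nm, oriented,
                  accession=read.accession, trim5=read.trim5, trim3=read.trim3)
    )


def align_reads(
    reads: Iterable[ReadRecord],
    index: ReferenceIndex,
    params: AlignerParams = AlignerParams(),
):
    """Bulk alignment; returns (alignments, no_hit_reads, multi_hit_reads)."""
    aligned: List[Alignment] = []
    no_hit: List[ReadRecord] = []
    multi: List[ReadRecord] = []
    for read in reads:
        res = align_read(read, index, params)
        if res.alignment is not None:
            aligned.append(res.alignment)
        elif res.reason == MULTI_HIT:
            multi.append(read)
        else:
            no_hit.append(read)
    return aligned, no_hit, multi


def iterative_trim_align(
    reads: Iterable[ReadRecord],
    index: ReferenceIndex,
    params: AlignerParams = AlignerParams(),
    min_length: int = 30,
):
    """Rescue unaligned reads by one-base 3'/5' trimming and re-alignment.

    Breadth-first over trim states ordered by total bases removed, with the
    3'-trimmed candidate of each state tried before the 5'-trimmed one: the
    loop returns the alignment reachable with the fewest trims, preferring
    3' trims on ties.  A state that aligns ambiguously is pruned — trimming
    only removes mismatches, so every placement valid for a read stays valid
    for its sub-reads and ambiguity cannot resolve by further trimming.
    Reads that reach ``min_length`` without a unique placement are exhausted.
    """
    from collections import deque

    aligned: List[Alignment] = []
    exhausted: List[ReadRecord] = []
    for read in reads:
        seq, qual = read.sequence, read.quality
        L = len(seq)
        found = None
        queue = deque([(0, 0)])
        seen = {(0, 0)}
        while queue:
            t5, t3 = queue.popleft()
            if L - t5 - t3 < min_length:
                continue
            sub = ReadRecord(read.id, seq[t5 : L - t3], qual[t5 : L - t3],
                             accession=read.accession,
                             trim5=read.trim5 + t5, trim3=read.trim3 + t3)
            res = align_read(sub, index, params)
            if res.alignment is not None:
                found = res.alignment
                break
            if res.reason == MULTI_HIT:
                continue  # pruned: ambiguity is monotone under trimming
            for child in ((t5, t3 + 1), (t5 + 1, t3)):  # 3' trim first
                if child not in seen:
                    seen.add(child)
                    queue.append(child)
        if found is not None:
            aligned.append(found)
        else:
            exhausted.append(read)
    return aligned, exhausted


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_fastq(path) -> List[ReadRecord]:
    from Bio import SeqIO

    out = []
    for rec in SeqIO.parse(str(path), "fastq"):
        qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
        out.append(ReadRecord(rec.id, str(rec.seq).upper(), qual))
    return out


def read_tag_table(path) -> Dict[str, str]:
    """Two-column TSV (tag, accession); tag '-' denotes the no-tag class."""
    table: Dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            tag, acc = line.split("\t")[:2]
            table["" if tag == "-" else tag] = acc
    return table


def write_alignments_tsv(alignments: Sequence[Alignment], path) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\taccession\ttarget\tpos\tstrand\tmismatches\t"
                 "trim5\ttrim3\taligned_seq\n")
        for a in alignments:
            fh.write(f"{a.read_id}\t{a.accession or ''}\t{a.target}\t{a.pos}\t"
                     f"{a.strand}\t{a.mismatches}\t{a.trim5}\t{a.trim3}\t{a.aligned_seq}\n")


def read_alignments_tsv(path) -> List[Alignment]:
    out = []
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            rid, acc, target, pos, strand, nm, t5, t3, seq = line.rstrip("\n").split("\t")
            out.append(Alignment(rid, target, int(pos), strand, int(nm), seq,
                                 accession=acc or None, trim5=int(t5), trim3=int(t3)))
    return out


def write_sam(alignments: Sequence[Alignment], references: Dict[str, str], path) -> None:
    """Minimal SAM export (QNAME, FLAG, RNAME, POS 1-based, NM tag)."""
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for name, seq in references.items():
            fh.write(f"@SQ\tSN:{name}\tLN:{len(seq)}\n")
        for a in alignments:
            flag = 16 if a.strand == "-" else 0
            fh.write(f"{a.read_id}\t{flag}\t{a.target}\t{a.pos + 1}\t255\t"
                     f"{a.length}M\t*\t0\t0\t{a.aligned_seq}\t*\tNM:i:{a.mismatches}\n")
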