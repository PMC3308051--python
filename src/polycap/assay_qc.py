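"""Capture-assay design QC: GC screen and k-mer abundance index.

A k-mer (default 32-mer, the largest fitting a 64-bit word at 2 bits per
base) frequency index over a genome lets a designer flag bait targets whose
sequence is over-represented — repetitive or multi-copy targets soak up
reads and destroy coverage uniformity.  Counting is strand-specific by
default, matching a cDNA-against-genome screen; windows containing ambiguous
bases are skipped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np

_BASE_TO_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_TO_BASE = "ACGT"


def encode_kmer(kmer: str) -> int:
    """2-bit packing of an unambiguous DNA k-mer (k <= 32)."""
    if len(kmer) > 32:
        raise ValueError("k must be <= 32 to fit one 64-bit word")
    value = 0
    for base in kmer:
        value = (value << 2) | _BASE_TO_BITS[base]
    return value


def decode_kmer(value: int, k: int) -> str:
    out = []
    for _ in range(k):
        out.append(_BITS_TO_BASE[value & 3])
        value >>= 2
    return "".join(reversed(out))


def _revcomp_code(value: int, k: int) -> int:
    out = 0
    for _ in range(k):
        out = (out << 2) | (3 - (value & 3))
        value >>= 2
    return out


@dataclass
class KmerIndex:
    k: int
    counts: Dict[int, int] = field(default_factory=dict)
    canonical: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def count(self, kmer: str) -> int:
        code = encode_kmer(kmer)
        if self.canonical:
            code = min(code, _revcomp_code(code, self.k))
        return self.counts.get(code, 0)


def _windows(seq: str, k: int):
    """Yield 2-bit codes of all unambiguous k-windows (rolling)."""
    mask = (1 << (2 * k)) - 1
    value = 0
    run = 0
    for base in seq:
        bits = _BASE_TO_BITS.get(base)
        if bits is None:
            run = 0
            value = 0
            continue
        value = ((value << 2) | bits) & mask
        run += 1
        if run >= k:
            yield value


def build_kmer_index(
    sequences: Iterable[str], k: int = 32, canonical: bool = False
) -> KmerIndex:
    """Enumerate and count every unambiguous k-mer window.

    ``canonical=True`` merges each k-mer with its reverse complement
    (off by default: the screen is strand-specific).
    """
    if k > 32:
        raise ValueError("k must be <= 32")
    if k < 1:
        raise ValueError("k must be >= 1")
    counts: Dict[int, int] = {}
    for seq in sequences:
        for code in _windows(seq.upper(), k):
            if canonical:
                code = min(code, _revcomp_code(code, k))
            counts[code] = counts.get(code, 0) + 1
    return KmerIndex(k=k, counts=counts, canonical=canonical)


def target_abundance(target_sequence: str, index: KmerIndex) -> float:
    """Median genome-index frequency over the target's k-mer windows.

    A single-copy target scores ~1, an absent one 0, a repetitive one the
    repeat's copy number.
    """
    k = index.k
    if len(target_sequence) < k:
        raise ValueError(f"target shorter than k={k}")
    freqs = []
    for code in _windows(target_sequence.upper(), k):
        if index.canonical:
            code = min(code, _revcomp_code(code, k))
        freqs.append(index.counts.get(code, 0))
    if not freqs:
        raise ValueError("target has no unambiguous k-mer window")
    return float(np.median(freqs))


def flag_repetitive_targets(
    abundances: Dict[str, float], percentile: float = 99.0
) -> Set[str]:
    """Targets whose median k-mer frequency exceeds the given percentile."""
    if not abundances:
        return set()
    cutoff = float(np.percentile(list(abundances.values()), percentile))
    return {t for t, a in abundances.items() if a > cutoff}


def gc_content(sequence: str) -> float:
    """(G+C) fraction; the capture sweet spot is roughly 0.35-0.65."""
    if not sequence:
        raise ValueError("empty sequence")
    s = sequence.upper()
    return (s.count("G") + s.count("C")) / len(s)


def gc_screen(sequence: str, lo: float = 0.35, hi: float = 0.65) -> bool:
    """True when the bait's GC content falls inside the efficient range."""
    return lo <= gc_content(sequence) <= hi


def write_kmer_index_tsv(index: KmerIndex, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#k={index.k}\tcanonical={index.canonical}\n")
        for code in sorted(index.counts):
            fh.write(f"{decode_kmer(code, index.k)}\t{index.counts[code]}\n")
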