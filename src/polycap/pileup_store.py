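"""Per-base, per-accession allele counts and coverage summaries.

The pileup is the coordinate frame for all variant and structural calling:
for every reference target it holds an ``(L, 5)`` count matrix per accession
over the A/C/G/T/N alphabet.  Coverage summaries report the median depth of
coverage (MDC, computed over *all* target bases, zero-coverage bases
included) per accession and combined, plus breadth-of-coverage fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

BASE_ORDER = "ACGTN"
_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


def encode_bases(seq: str) -> np.ndarray:
    """Map a DNA string to integer codes A=0 C=1 G=2 T=3, other=4 (N)."""
    return _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]


class Pileup:
    """Allele-count matrices keyed by target and accession."""

    def __init__(self, references: Dict[str, str], accessions: Sequence[str]):
        self.references = references
        self.accessions = list(accessions)
        self.counts: Dict[str, Dict[str, np.ndarray]] = {
            t: {acc: np.zeros((len(seq), 5), dtype=np.int32) for acc in accessions}
            for t, seq in references.items()
        }

    def add_alignment(self, aln) -> None:
        target = self.counts.get(aln.target)
        if target is None:
            raise KeyError(f"unknown target {aln.target!r}")
        L = len(aln.aligned_seq)
        if aln.pos < 0 or aln.pos + L > len(self.references[aln.target]):
            raise ValueError(
                f"alignment {aln.read_id} exceeds bounds of {aln.target}"
            )
        acc = aln.accession
        if acc not in target:
            raise KeyError(f"unknown accession {acc!r}")
        codes = encode_bases(aln.aligned_seq)
        target[acc][np.arange(aln.pos, aln.pos + L), codes] += 1

    def depth(self, target: str, accession: Optional[str] = None) -> np.ndarray:
        """Per-base depth for one accession, or summed over all if None."""
        mats = self.counts[target]
        if accession is not None:
            return mats[accession].sum(axis=1)
        return sum(m.sum(axis=1) for m in mats.values())

    def column(self, target: str, position: int) -> Dict[str, Dict[str, int]]:
        """Allele->count map per accession at one position (non-zero only)."""
        out = {}
        for acc, mat in self.counts[target].items():
            row = mat[position]
            out[acc] = {BASE_ORDER[i]: int(row[i]) for i in range(5) if row[i] > 0}
        return out

    def total_depth_sum(self) -> int:
        return int(sum(m.sum() for mats in self.counts.values() for m in mats.values()))


def clip_alignment_ends(alignments: Iterable, n_bases: int) -> List:
    """Shorten every alignment by ``n_bases`` at each end.

    Residual non-reference sequence (intronic overhang on junction reads,
    adapter remnants) concentrates at read ends and shows up as systematic
    artifact alleles near exon boundaries; clipping the terminal bases before
    counting removes that support at a small, uniform cost in depth.
    Alignments too short to survive the clip are dropped.
    """
    import dataclasses

    if n_bases <= 0:
        return list(alignments)
    out = []
    for a in alignments:
        L = len(a.aligned_seq)
        if L <= 2 * n_bases:
            continue
        out.append(dataclasses.replace(
            a, pos=a.pos + n_bases, aligned_seq=a.aligned_seq[n_bases : L - n_bases]))
    return out


def build_pileup(alignments: Iterable, references: Dict[str, str],
                 accessions: Optional[Sequence[str]] = None) -> Pileup:
    """Accumulate alignments into a pileup; every aligned base counts once."""
    alignments = list(alignments)
    if accessions is None:
        accessions = sorted({a.accession for a in alignments if a.accession})
    pile = Pileup(references, accessions)
    for aln in alignments:
        pile.add_alignment(aln)
    return pile


@dataclass
class CoverageSummary:
    target: str
    mdc: Dict[str, float]  # per-accession MDC
    mdc_combined: float
    breadth_ge1: float
    breadth_ge2: float

    def __post_init__(self):
        assert 0.0 <= self.breadth_ge1 <= 1.0 and 0.0 <= self.breadth_ge2 <= 1.0


def coverage_summary(pileup: Pileup, target: str) -> CoverageSummary:
    per_acc = {acc: float(np.median(pileup.depth(target, acc)))
               for acc in pileup.accessions}
    combined = pileup.depth(target)
    L = combined.size
    return CoverageSummary(
        target=target,
        mdc=per_acc,
        mdc_combined=float(np.median(combined)),
        breadth_ge1=float((combined >= 1).sum() / L),
        breadth_ge2=float((combined >= 2).sum() / L),
    )


def coverage_summaries(pileup: Pileup) -> Dict[str, CoverageSummary]:
    return {t: coverage_summary(pileup, t) for t in pileup.counts}


def expected_mdc(total_aligned_bases: float, total_target_length: float) -> float:
    """Expected depth if aligned bases spread uniformly over the targets."""
    if total_target_length <= 0:
        raise ValueError("total_target_length must be > 0")
    return total_aligned_bases / total_target_length


def fold_enrichment(on_target_fraction: float, genomic_target_fraction: float) -> float:
    """Enrichment of target sequence relative to its genomic proportion."""
    if not (0 < genomic_target_fraction <= 1):
        raise ValueError("genomic_target_fraction must lie in (0, 1]")
    if not (0 < on_target_fraction <= 1):
        raise ValueError("on_target_fraction must lie in (0, 1]")
    return on_target_fraction / genomic_target_fraction


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_pileup_tsv(pileup: Pileup, path) -> None:
    """Long-format pileup: target, pos, accession, A, C, G, T, N."""
    with open(path, "w") as fh:
        fh.write("target\tpos\taccession\tA\tC\tG\tT\tN\n")
        for target, mats in pileup.counts.items():
            for acc, mat in mats.items():
                nz = np.flatnonzero(mat.sum(axis=1))
                for pos in nz:
                    row = mat[pos]
                    fh.write(f"{target}\t{pos}\t{acc}\t" +
                             "\t".join(str(int(x)) for x in row) + "\n")


def read_pileup_tsv(path, references: Dict[str, str]) -> Pileup:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    accs = sorted(df["accession"].unique())
    pile = Pileup(references, accs)
    for row in df.itertuples(index=False):
        mat = pile.counts[row.target][row.accession]
        mat[row.pos] = [row.A, row.C, row.G, row.T, row.N]
    return pile


def write_summary_tsv(summaries: Dict[str, CoverageSummary], path) -> None:
    with open(path, "w") as fh:
        accs = sorted(next(iter(summaries.values())).mdc) if summaries else []
        fh.write("target\t" + "\t".join(f"mdc_{a}" for a in accs) +
                 "\tmdc_combined\tbreadth_ge1\tbreadth_ge2\n")
        for t, s in summaries.items():
            fh.write(f"{t}\t" + "\t".join(f"{s.mdc[a]:g}" for a in accs) +
                     f"\t{s.mdc_combined:g}\t{s.breadth_ge1:.4f}\t{s.breadth_ge2:.4f}\n")


def write_bedgraph(pileup: Pileup, path, accession: Optional[str] = None) -> None:
    """Depth track in BEDGraph format (combined depth unless accession given)."""
    with open(path, "w") as fh:
        for target in pileup.counts:
            depth = pileup.depth(target, accession)
            start = 0
            for i in range(1, depth.size + 1):
                if i == depth.size or depth[i] != depth[start]:
                    fh.write(f"{target}\t{start}\t{i}\t{int(depth[start])}\n")
                    start = i
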