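"""Synthetic allotetraploid (AABB) exon-capture simulator.

Generates a set of cDNA-like gene targets for a tetraploid species carrying two
homoeologous subgenomes (A and B) diverged by a configurable fraction ``d`` in
coding sequence, two accessions (a cultivated ``Ld``-like and a wild ``Td``-like
line) carrying lineage-specific SNPs at per-region rates, plus structural
events: diverged paralogs, homoeolog deletions (full or partial), whole-gene
presence/absence variation (PAV) and gene-family duplications.

Genomic copies of every gene carry introns, and capture-style single-end reads
are drawn from the *genomic* sequence so a predictable fraction of reads
straddles exon-intron junctions and fails naive end-to-end alignment against
the cDNA reference.  Per-copy sampling depth is Poisson with a mean scaled by a
divergence-dependent capture-efficiency multiplier (two-fold loss per 2%
divergence from the bait/reference copy).

Every planted event is recorded in a :class:`TruthSet` so downstream detectors
can be scored for recovery.  Identical configuration (including the seed)
yields byte-identical FASTA/FASTQ output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

ALPHABET = "ACGT"
_ALPH_U8 = np.frombuffer(b"ACGT", dtype=np.uint8)
STOP_CODONS = ("TAA", "TAG", "TGA")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

ACCESSION_LD = "Ld"
ACCESSION_TD = "Td"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


class SimConfigError(ValueError):
    """Raised when a simulation configuration is internally inconsistent."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic tetraploid.

    Defaults mirror the capture experiment the simulator emulates: 40-bp
    single-end reads at mean per-copy depth lambda = 13, 2% coding divergence
    between the A and B subgenomes, cDNA composition 4% 5'UTR / 65% CDS /
    31% 3'UTR, and lineage SNP densities of 1.3 (CDS), 2.0 (5'UTR) and
    1.6 (3'UTR) per kb.
    """

    n_genes: int = 50
    gene_length_range: Tuple[int, int] = (900, 1500)
    utr5_frac: float = 0.04
    cds_frac: float = 0.65
    utr3_frac: float = 0.31
    intron_count_range: Tuple[int, int] = (1, 3)
    intron_length_range: Tuple[int, int] = (60, 200)
    divergence_d: float = 0.02
    utr_divergence: Optional[float] = None  # None -> same as divergence_d
    snp_rate_cds: float = 0.0013
    snp_rate_utr5: float = 0.002
    snp_rate_utr3: float = 0.0016
    n_paralog_genes: int = 2
    paralog_divergence: float = 0.05
    n_homoeolog_deletions: int = 2
    n_partial_deletions: int = 0
    n_reciprocal_deletions: int = 0
    n_pav_genes: int = 1
    n_duplicated_families: int = 1
    duplication_extra_copies: int = 2
    duplication_divergence: float = 0.005
    read_length: int = 40
    mean_depth_lambda: float = 13.0
    seq_error_rate: float = 0.002
    capture_bias: bool = True
    base_quality: int = 35
    tag_table: Dict[str, str] = field(
        default_factory=lambda: {ACCESSION_LD: "AT", ACCESSION_TD: "CCAGT"}
    )
    seed: int = 0

    @property
    def accessions(self) -> Tuple[str, ...]:
        return tuple(self.tag_table)

    def validate(self) -> None:
        fracs = (self.utr5_frac, self.cds_frac, self.utr3_frac)
        if any(not (0.0 <= f <= 1.0) for f in fracs):
            raise SimConfigError("cDNA region fractions must lie in [0, 1]")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise SimConfigError("utr5_frac + cds_frac + utr3_frac must sum to 1")
        if self.read_length < 30:
            raise SimConfigError("read_length must be >= 30")
        if not (0.0 <= self.divergence_d <= 1.0):
            raise SimConfigError("divergence_d must lie in [0, 1]")
        if self.gene_length_range[0] > self.gene_length_range[1]:
            raise SimConfigError("gene_length_range must be (lo, hi) with lo <= hi")
        if self.gene_length_range[0] < self.read_length:
            raise SimConfigError(
                "genes shorter than one read cannot host capture fragments")
        if len(self.tag_table) != 2:
            raise SimConfigError("exactly two accessions are required")
        n_events = (
            self.n_paralog_genes
            + self.n_homoeolog_deletions
            + self.n_reciprocal_deletions
            + self.n_pav_genes
            + self.n_duplicated_families
        )
        if n_events > self.n_genes:
            raise SimConfigError(
                f"{n_events} structural events requested but only "
                f"{self.n_genes} genes available to host them"
            )
        min_cds = 3 * max(3, round(self.gene_length_range[0] * self.cds_frac / 3))
        if min_cds < 9:
            raise SimConfigError("genes too short to host an ORF (CDS < 9 bp)")
        if min_cds + round(self.gene_length_range[0] * self.utr5_frac) > self.gene_length_range[0]:
            raise SimConfigError("gene_length_range too short for the region fractions")
        for tag in self.tag_table.values():
            if any(b not in ALPHABET for b in tag):
                raise SimConfigError(f"tag {tag!r} contains non-ACGT characters")
            if self.read_length - len(tag) < 30:
                raise SimConfigError(f"tag {tag!r} leaves fewer than 30 template bases")


# ---------------------------------------------------------------------------
# truth records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GssRecord:
    gene: str
    position: int  # 0-based cDNA coordinate
    allele_a: str  # base carried by the A-subgenome copy
    allele_b: str
    region: str


@dataclass(frozen=True)
class SnpRecord:
    gene: str
    position: int
    accession: str
    genome: str  # 'A' or 'B': the subgenome copy carrying the derived allele
    ancestral: str
    derived: str
    region: str


@dataclass(frozen=True)
class DeletionRecord:
    gene: str
    accession: str
    genome: str
    kind: str  # 'full' or 'partial'
    span: Optional[Tuple[int, int]] = None  # cDNA span for partial deletions


@dataclass(frozen=True)
class PavRecord:
    gene: str
    accession: str  # accession missing the gene


@dataclass(frozen=True)
class ParalogRecord:
    gene: str
    divergence: float


@dataclass(frozen=True)
class DuplicationRecord:
    gene: str
    accession: str  # accession with extra copies
    copies: Dict[str, int] = field(hash=False, default=None)  # accession -> copy count

    def __hash__(self):  # copies dict is informational only
        return hash((self.gene, self.accession))


@dataclass
class SourceCopy:
    """One physical gene copy present in one accession's genome."""

    gene: str
    accession: str
    label: str  # 'A', 'B', 'P' (paralog), 'A.dup1', ...
    cdna: str
    genomic: str
    divergence: float  # substitution fraction vs the reference cDNA


@dataclass
class TargetRef:
    """An annotated cDNA reference target (the bait/alignment frame)."""

    gene: str
    seq: str
    utr5: Tuple[int, int]
    cds: Tuple[int, int]
    utr3: Tuple[int, int]
    origin_genome: str  # which homoeolog the reference copy represents


@dataclass
class TruthSet:
    """Ground-truth ledger of every planted feature and event."""

    config: SimConfig
    targets: Dict[str, TargetRef]
    gss: List[GssRecord]
    snps: List[SnpRecord]
    paralogs: List[ParalogRecord]
    deletions: List[DeletionRecord]
    pav: List[PavRecord]
    duplications: List[DuplicationRecord]
    source_copies: Dict[str, List[SourceCopy]]  # accession -> copies
    introns: Dict[str, List[Tuple[int, int]]]  # gene -> [(cdna_pos, length)]

    def single_copy_genes(self) -> List[str]:
        """Genes with no paralogs or duplications (safe for MDC calibration)."""
        multi = {p.gene for p in self.paralogs} | {d.gene for d in self.duplications}
        return [g for g in self.targets if g not in multi]

    def gss_positions(self) -> set:
        return {(r.gene, r.position) for r in self.gss}

    def snp_positions(self) -> set:
        return {(r.gene, r.position) for r in self.snps}


# ---------------------------------------------------------------------------
# sequence construction helpers
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return bytes(_ALPH_U8[rng.integers(0, 4, n)]).decode()


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons-2) non-stop sense codons + one stop codon."""
    body = []
    for _ in range(n_codons - 2):
        codon = _random_seq(rng, 3)
        while codon in STOP_CODONS:
            codon = _random_seq(rng, 3)
        body.append(codon)
    stop = STOP_CODONS[rng.integers(0, 3)]
    return "ATG" + "".join(body) + stop


def _mutate(
    seq: str,
    rate: float,
    rng: np.random.Generator,
    protected: Sequence[int] = (),
) -> Tuple[str, List[Tuple[int, str, str]]]:
    """Per-base substitution at ``rate``; returns new sequence and changes."""
    if rate <= 0 or not seq:
        return seq, []
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    if protected:
        protected_set = set(protected)
        hits = [h for h in hits if h not in protected_set]
    out = list(seq)
    changes = []
    for pos in hits:
        old = out[pos]
        alts = [b for b in ALPHABET if b != old]
        new = alts[rng.integers(0, 3)]
        out[pos] = new
        changes.append((int(pos), old, new))
    return "".join(out), changes


def _region_of(pos: int, target: TargetRef) -> str:
    if pos < target.utr5[1]:
        return "utr5"
    if pos < target.cds[1]:
        return "cds"
    return "utr3"


def capture_efficiency(divergence_from_reference: float) -> float:
    """Relative capture/sampling efficiency of a fragment vs its bait.

    Hybridization efficiency halves for every 2% of sequence divergence from
    the reference copy the baits were designed on, i.e. ``0.5**(d/0.02)``:
    an identical sequence captures at full efficiency, a homoeolog at 2%
    divergence at half efficiency.
    """
    if divergence_from_reference < 0:
        raise ValueError("divergence must be non-negative")
    if divergence_from_reference > 1:
        raise ValueError("divergence is a fraction in [0, 1]")
    return 0.5 ** (divergence_from_reference / 0.02)


def _hamming_frac(a: str, b: str) -> float:
    return sum(x != y for x, y in zip(a, b)) / len(a)


# ---------------------------------------------------------------------------
# reference + truth generation
# ---------------------------------------------------------------------------


def _build_gene(
    cfg: SimConfig, rng: np.random.Generator, idx: int
) -> Tuple[TargetRef, Dict[str, str], List[GssRecord], List[Tuple[int, int]], Dict[str, List[str]]]:
    """Construct one gene: ancestral cDNA, A/B homoeologs, introns."""
    gene = f"gene{idx:04d}"
    length = int(rng.integers(cfg.gene_length_range[0], cfg.gene_length_range[1] + 1))
    utr5_len = round(length * cfg.utr5_frac)
    cds_len = 3 * max(3, round(length * cfg.cds_frac / 3))
    utr3_len = length - utr5_len - cds_len
    if utr3_len < 0:
        raise SimConfigError(f"{gene}: drawn length {length} cannot host the CDS")

    utr5 = _random_seq(rng, utr5_len)
    cds = _random_cds(rng, cds_len // 3)
    utr3 = _random_seq(rng, utr3_len)
    ancestral = utr5 + cds + utr3

    d_cds = cfg.divergence_d
    d_utr = cfg.divergence_d if cfg.utr_divergence is None else cfg.utr_divergence

    # A homoeolog keeps the ancestral state; B diverges at rate d.
    # The start codon is protected so both copies annotate cleanly.
    b_utr5, ch5 = _mutate(utr5, d_utr, rng)
    b_cds, chc = _mutate(cds, d_cds, rng, protected=(0, 1, 2))
    b_utr3, ch3 = _mutate(utr3, d_utr, rng)
    cdna_a = ancestral
    cdna_b = b_utr5 + b_cds + b_utr3

    origin = "A" if idx % 2 == 0 else "B"
    ref_seq = cdna_a if origin == "A" else cdna_b
    target = TargetRef(
        gene=gene,
        seq=ref_seq,
        utr5=(0, utr5_len),
        cds=(utr5_len, utr5_len + cds_len),
        utr3=(utr5_len + cds_len, length),
        origin_genome=origin,
    )

    gss = []
    for off, changes in ((0, ch5), (utr5_len, chc), (utr5_len + cds_len, ch3)):
        for pos, old, new in changes:
            p = off + pos
            gss.append(GssRecord(gene, p, old, new, _region_of(p, target)))

    # introns: shared positions between homoeologs, sequences diverge at d
    n_introns = int(rng.integers(cfg.intron_count_range[0], cfg.intron_count_range[1] + 1))
    lo, hi = 40, length - 40
    positions = sorted(
        int(p) for p in rng.choice(np.arange(lo, hi), size=n_introns, replace=False)
    ) if n_introns and hi > lo + n_introns else []
    introns: List[Tuple[int, int]] = []
    intron_seqs = {"A": [], "B": []}
    for p in positions:
        ilen = int(rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1))
        iseq_a = _random_seq(rng, ilen)
        iseq_b, _ = _mutate(iseq_a, d_cds, rng)
        introns.append((p, ilen))
        intron_seqs["A"].append(iseq_a)
        intron_seqs["B"].append(iseq_b)

    return target, {"A": cdna_a, "B": cdna_b}, gss, introns, intron_seqs


def _insert_introns(cdna: str, introns: List[Tuple[int, int]], seqs: List[str]) -> str:
    parts = []
    prev = 0
    for (pos, _), iseq in zip(introns, seqs):
        parts.append(cdna[prev:pos])
        parts.append(iseq)
        prev = pos
    parts.append(cdna[prev:])
    return "".join(parts)


def _cdna_to_genomic(pos: int, introns: List[Tuple[int, int]]) -> int:
    return pos + sum(ilen for ipos, ilen in introns if ipos <= pos)


def simulate_references(config: SimConfig):
    """Generate references, per-accession genomic copies and the truth set.

    Returns ``(targets, source_copies, truth)`` where ``targets`` maps gene id
    to :class:`TargetRef` (the cDNA alignment frame, one representative
    homoeolog per gene, alternating A/B), ``source_copies`` maps accession to
    the list of intron-containing :class:`SourceCopy` genomic sequences reads
    are drawn from, and ``truth`` is the full :class:`TruthSet`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    accs = list(config.accessions)

    targets: Dict[str, TargetRef] = {}
    homoeologs: Dict[str, Dict[str, str]] = {}
    all_gss: List[GssRecord] = []
    introns_by_gene: Dict[str, List[Tuple[int, int]]] = {}
    intron_seqs_by_gene: Dict[str, Dict[str, List[str]]] = {}

    for i in range(config.n_genes):
        target, cdnas, gss, introns, iseqs = _build_gene(config, rng, i)
        targets[target.gene] = target
        homoeologs[target.gene] = cdnas
        all_gss.extend(gss)
        introns_by_gene[target.gene] = introns
        intron_seqs_by_gene[target.gene] = iseqs

    genes = list(targets)
    gss_pos = {(r.gene, r.position) for r in all_gss}

    # assign structural-event genes on disjoint gene sets (deterministic draw)
    n_events = (
        config.n_paralog_genes
        + config.n_homoeolog_deletions
        + config.n_reciprocal_deletions
        + config.n_pav_genes
        + config.n_duplicated_families
    )
    event_genes = list(rng.choice(genes, size=n_events, replace=False)) if n_events else []
    cursor = 0

    def take(n):
        nonlocal cursor
        out = event_genes[cursor : cursor + n]
        cursor += n
        return [str(g) for g in out]

    paralog_genes = take(config.n_paralog_genes)
    deletion_genes = take(config.n_homoeolog_deletions)
    reciprocal_genes = take(config.n_reciprocal_deletions)
    pav_genes = take(config.n_pav_genes)
    dup_genes = take(config.n_duplicated_families)

    # lineage SNPs: per accession, per region, on one homoeolog copy each
    snps: List[SnpRecord] = []
    snp_by_gene_acc: Dict[Tuple[str, str], List[SnpRecord]] = {}
    rates = {"utr5": config.snp_rate_utr5, "cds": config.snp_rate_cds, "utr3": config.snp_rate_utr3}
    for acc in accs:
        for gene in genes:
            target = targets[gene]
            spans = {"utr5": target.utr5, "cds": target.cds, "utr3": target.utr3}
            gene_snps = []
            for region, (s, e) in spans.items():
                if e <= s:
                    continue
                hits = s + np.flatnonzero(rng.random(e - s) < rates[region])
                for pos in hits:
                    pos = int(pos)
                    if (gene, pos) in gss_pos:
                        continue  # SNP/GSS coordinate sets disjoint by design
                    if region == "cds" and pos < target.cds[0] + 3:
                        continue  # keep the start codon intact
                    genome = "A" if rng.random() < 0.5 else "B"
                    anc = homoeologs[gene][genome][pos]
                    alts = [b for b in ALPHABET if b != anc]
                    der = alts[rng.integers(0, 3)]
                    rec = SnpRecord(gene, pos, acc, genome, anc, der, region)
                    gene_snps.append(rec)
                    gss_pos.add((gene, pos))  # also keeps SNPs mutually disjoint
            snps.extend(gene_snps)
            snp_by_gene_acc[(gene, acc)] = gene_snps

    # structural events
    paralogs = [ParalogRecord(g, config.paralog_divergence) for g in paralog_genes]
    paralog_cdna: Dict[str, str] = {}
    for g in paralog_genes:
        t = targets[g]
        mut, _ = _mutate(
            homoeologs[g]["A"], config.paralog_divergence, rng,
            protected=range(t.cds[0], t.cds[0] + 3),
        )
        paralog_cdna[g] = mut

    deletions: List[DeletionRecord] = []
    for i, g in enumerate(deletion_genes):
        acc = accs[rng.integers(0, 2)]
        genome = "A" if rng.random() < 0.5 else "B"
        if i < config.n_partial_deletions:
            L = len(targets[g].seq)
            span_len = int(rng.integers(L // 2, max(L // 2 + 1, L - 40)))
            start = int(rng.integers(0, L - span_len + 1))
            deletions.append(DeletionRecord(g, acc, genome, "partial", (start, start + span_len)))
        else:
            deletions.append(DeletionRecord(g, acc, genome, "full"))
    for g in reciprocal_genes:
        # accession 0 loses the A copy, accession 1 loses the B copy
        deletions.append(DeletionRecord(g, accs[0], "A", "full"))
        deletions.append(DeletionRecord(g, accs[1], "B", "full"))

    pav = [PavRecord(g, accs[rng.integers(0, 2)]) for g in pav_genes]

    duplications: List[DuplicationRecord] = []
    dup_cdnas: Dict[str, List[str]] = {}
    for i, g in enumerate(dup_genes):
        acc = accs[i % 2]
        extras = []
        t = targets[g]
        for _ in range(config.duplication_extra_copies):
            mut, _ = _mutate(
                homoeologs[g]["A"], config.duplication_divergence, rng,
                protected=range(t.cds[0], t.cds[0] + 3),
            )
            extras.append(mut)
        dup_cdnas[g] = extras
        copies = {a: 2 for a in accs}
        copies[acc] = 2 + config.duplication_extra_copies
        duplications.append(DuplicationRecord(g, acc, copies))

    # materialize per-accession source copies
    pav_lookup = {(r.gene, r.accession) for r in pav}
    del_lookup = {(r.gene, r.accession, r.genome): r for r in deletions}
    dup_lookup = {r.gene: r for r in duplications}

    source_copies: Dict[str, List[SourceCopy]] = {acc: [] for acc in accs}
    for acc in accs:
        for gene in genes:
            if (gene, acc) in pav_lookup:
                continue
            target = targets[gene]
            introns = introns_by_gene[gene]
            iseqs = intron_seqs_by_gene[gene]
            acc_snps = snp_by_gene_acc.get((gene, acc), [])
            for genome in ("A", "B"):
                rec = del_lookup.get((gene, acc, genome))
                if rec is not None and rec.kind == "full":
                    continue
                cdna = list(homoeologs[gene][genome])
                for s in acc_snps:
                    if s.genome == genome:
                        cdna[s.position] = s.derived
                cdna = "".join(cdna)
                genomic = _insert_introns(cdna, introns, iseqs[genome])
                if rec is not None and rec.kind == "partial":
                    gs = _cdna_to_genomic(rec.span[0], introns)
                    ge = _cdna_to_genomic(rec.span[1], introns)
                    genomic = genomic[:gs] + genomic[ge:]
                div = _hamming_frac(cdna, target.seq)
                source_copies[acc].append(
                    SourceCopy(gene, acc, genome, cdna, genomic, div)
                )
            if gene in paralog_cdna:
                cdna = paralog_cdna[gene]
                genomic = _insert_introns(cdna, introns, iseqs["A"])
                source_copies[acc].append(
                    SourceCopy(gene, acc, "P", cdna, genomic, _hamming_frac(cdna, target.seq))
                )
            dup = dup_lookup.get(gene)
            if dup is not None and dup.accession == acc:
                for k, cdna in enumerate(dup_cdnas[gene], 1):
                    genomic = _insert_introns(cdna, introns, iseqs["A"])
                    source_copies[acc].append(
                        SourceCopy(gene, acc, f"A.dup{k}", cdna, genomic,
                                   _hamming_frac(cdna, target.seq))
                    )

    truth = TruthSet(
        config=config,
        targets=targets,
        gss=all_gss,
        snps=snps,
        paralogs=paralogs,
        deletions=deletions,
        pav=pav,
        duplications=duplications,
        source_copies=source_copies,
        introns=introns_by_gene,
    )
    return targets, source_copies, truth


# ---------------------------------------------------------------------------
# read simulation
# ---------------------------------------------------------------------------


@dataclass
class SimRead:
    id: str
    sequence: str
    quality: str
    accession: str


def simulate_reads(truth: TruthSet, config: SimConfig) -> Dict[str, List[SimRead]]:
    """Draw capture-style tagged reads from every genomic source copy.

    Per copy, the number of reads is Poisson with mean
    ``lambda * efficiency * L / fragment_length`` so that per-base depth is
    approximately ``lambda * efficiency``.  The accession tag is prepended and
    the read trimmed to ``read_length`` total bases; truth origin is encoded in
    the read id as ``accession|gene|copy|genomic_start|strand|serial``.

    Returns a dict with one entry per accession plus ``"pool"``, the combined
    read pool (concatenation in accession order).
    """
    if config.mean_depth_lambda <= 0:
        raise ValueError("mean_depth_lambda must be > 0")
    rng = np.random.default_rng(config.seed + 1_000_003)
    qual_char = chr(33 + config.base_quality)
    reads: Dict[str, List[SimRead]] = {acc: [] for acc in config.accessions}
    serial = 0
    for acc in config.accessions:
        tag = config.tag_table[acc]
        frag_len = config.read_length - len(tag)
        for copy in truth.source_copies[acc]:
            L = len(copy.genomic)
            if L < frag_len:
                continue
            eff = capture_efficiency(copy.divergence) if config.capture_bias else 1.0
            lam = config.mean_depth_lambda * eff * L / frag_len
            n = int(rng.poisson(lam))
            if n == 0:
                continue
            starts = rng.integers(0, L - frag_len + 1, n)
            strands = rng.random(n) < 0.5
            for start, minus in zip(starts, strands):
                frag = copy.genomic[start : start + frag_len]
                if minus:
                    frag = revcomp(frag)
                if config.seq_error_rate > 0:
                    errs = np.flatnonzero(rng.random(frag_len) < config.seq_error_rate)
                    if errs.size:
                        fl = list(frag)
                        for e in errs:
                            alts = [b for b in ALPHABET if b != fl[e]]
                            fl[e] = alts[rng.integers(0, 3)]
                        frag = "".join(fl)
                strand = "-" if minus else "+"
                rid = f"{acc}|{copy.gene}|{copy.label}|{int(start)}|{strand}|{serial}"
                serial += 1
                seq = tag + frag
                reads[acc].append(SimRead(rid, seq, qual_char * len(seq), acc))
    pool: List[SimRead] = []
    for acc in config.accessions:
        pool.extend(reads[acc])
    reads["pool"] = pool
    return reads


# ---------------------------------------------------------------------------
# plain-text writers (FASTA / FASTQ / TSV truth tables)
# ---------------------------------------------------------------------------


def write_reference_fasta(targets: Dict[str, TargetRef], path) -> None:
    with open(path, "w") as fh:
        for gene, t in targets.items():
            fh.write(
                f">{gene} utr5={t.utr5[0]}-{t.utr5[1]} cds={t.cds[0]}-{t.cds[1]} "
                f"utr3={t.utr3[0]}-{t.utr3[1]} origin={t.origin_genome}\n"
            )
            for i in range(0, len(t.seq), 80):
                fh.write(t.seq[i : i + 80] + "\n")


def write_fastq(reads: Sequence[SimRead], path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{r.quality}\n")


def write_truth_tables(truth: TruthSet, outdir) -> None:
    """One TSV per event class, 0-based half-open coordinates."""
    import os

    os.makedirs(outdir, exist_ok=True)

    def tsv(name, header, rows):
        with open(os.path.join(outdir, name), "w") as fh:
            fh.write("\t".join(header) + "\n")
            for row in rows:
                fh.write("\t".join(str(x) for x in row) + "\n")

    tsv("truth_gss.tsv", ["gene", "position", "allele_a", "allele_b", "region"],
        [(r.gene, r.position, r.allele_a, r.allele_b, r.region) for r in truth.gss])
    tsv("truth_snps.tsv",
        ["gene", "position", "accession", "genome", "ancestral", "derived", "region"],
        [(r.gene, r.position, r.accession, r.genome, r.ancestral, r.derived, r.region)
         for r in truth.snps])
    tsv("truth_paralogs.tsv", ["gene", "divergence"],
        [(r.gene, r.divergence) for r in truth.paralogs])
    tsv("truth_deletions.tsv", ["gene", "accession", "genome", "kind", "start", "end"],
        [(r.gene, r.accession, r.genome, r.kind,
          r.span[0] if r.span else "", r.span[1] if r.span else "")
         for r in truth.deletions])
    tsv("truth_pav.tsv", ["gene", "accession"],
        [(r.gene, r.accession) for r in truth.pav])
    tsv("truth_duplications.tsv", ["gene", "accession", "copies"],
        [(r.gene, r.accession, ";".join(f"{a}={n}" for a, n in r.copies.items()))
         for r in truth.duplications])
    tsv("truth_gene_models.tsv",
        ["gene", "utr5_start", "utr5_end", "cds_start", "cds_end",
         "utr3_start", "utr3_end", "origin"],
        [(t.gene, t.utr5[0], t.utr5[1], t.cds[0], t.cds[1], t.utr3[0], t.utr3[1],
          t.origin_genome) for t in truth.targets.values()])
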