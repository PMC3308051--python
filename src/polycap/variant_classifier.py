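"""Variable-site detection and GSS/SNP classification with artifact filters.

In an allotetraploid alignment against a single representative cDNA per gene,
a variable site within one accession (an intra-species variable site, IVS) can
reflect either fixed divergence between the two subgenomes (a genome-specific
site, GSS: IVS in *both* accessions with the same allele pair) or a lineage
mutation (SNP: IVS in exactly one accession, the other monomorphic for one of
the two alleles).  Paralog alignment artifacts masquerade as IVSs with skewed
allele-depth ratios; they are removed by a log2 variant-coverage-ratio filter
whose thresholds are calibrated on validated true/false IVS sets so that the
false-IVS discovery rate stays below a target (5% by default).

Additional filters: targets with unusually high median depth (99th percentile
of single-copy-gene MDCs) are excluded as likely repeats/multigene families; a
SNP requires >=8 reads supporting the monomorphic line; SNP calls can be
unmasked as hidden GSSs by scanning the raw read pool for the missing second
variant embedded in its flanking sequence context ("flank rescue").
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .pileup_store import BASE_ORDER, Pileup, CoverageSummary, encode_bases
from .synthetic_tetraploid import revcomp

LABEL_GSS = "GSS"
LABEL_SNP = "SNP"
LABEL_FILTERED = "filtered"

REASON_HIGH_MDC = "high_mdc_target"
REASON_LOW_MONO = "low_mono_coverage"
REASON_RATIO = "ratio_out_of_range"
REASON_FLANK = "flank_rescued"
REASON_TRIALLELIC = "triallelic"
REASON_NO_IVS = "no_ivs"  # each line monomorphic for a different allele
REASON_HOMOEOLOG_TARGET = "homoeolog_deletion_target"  # SNPs demoted on deleted genes


@dataclass
class ClassifierConfig:
    min_variant_reads: int = 2
    min_variant_frac: float = 0.1  # within-accession minor-allele frequency gate
    min_mono_coverage: int = 8
    mdc_percentile: float = 99.0
    mdc_cutoff_override: Optional[float] = None
    log2_upper: Dict[str, float] = field(default_factory=lambda: {"Ld": 1.6, "Td": 1.0})
    log2_lower: Optional[Dict[str, float]] = None  # None -> -upper per accession
    max_mono_discordant: int = 1  # sequencing-error tolerance on the mono side
    target_false_ivs_rate: float = 0.05
    flank_length: int = 40
    flank_max_mismatches: int = 3
    flank_min_overlap: int = 20

    def __post_init__(self):
        if not (0 < self.mdc_percentile <= 100):
            raise ValueError("mdc_percentile must lie in (0, 100]")
        for v in self.log2_upper.values():
            if not math.isfinite(v):
                raise ValueError("log2 thresholds must be finite")

    def lower_threshold(self, accession: str) -> float:
        if self.log2_lower is not None:
            return self.log2_lower[accession]
        return -self.log2_upper[accession]


@dataclass
class VariableSite:
    target: str
    position: int
    ref_base: str
    counts: Dict[str, Dict[str, int]]  # accession -> allele -> reads
    alleles: Tuple[str, str]  # the two pooled-majority alleles
    n_alleles: int  # alleles with >= min_variant_reads pooled support
    is_ivs: Dict[str, bool]

    def allele_count(self, accession: str, allele: str) -> int:
        return self.counts.get(accession, {}).get(allele, 0)

    def depth(self, accession: str) -> int:
        return sum(self.counts.get(accession, {}).values())


@dataclass
class SiteCall:
    site: VariableSite
    label: str  # GSS | SNP | filtered
    lineage: Optional[str] = None  # accession carrying the derived allele
    ancestral: Optional[str] = None
    derived: Optional[str] = None
    filter_reason: Optional[str] = None

    def __post_init__(self):
        if self.label == LABEL_SNP and (self.lineage is None or self.derived is None):
            raise ValueError("SNP calls need lineage and allele states")


@dataclass
class TheoryParams:
    """Inputs of the missed-second-variant error model."""

    lambda_cov: float
    divergence_d: float
    target_length_L: int

    @property
    def t_expected_sites(self) -> float:
        """Expected number of divergent sites over the targets (d * L)."""
        return self.divergence_d * self.target_length_L


# ---------------------------------------------------------------------------
# site discovery
# ---------------------------------------------------------------------------


def call_variable_sites(
    pileup: Pileup,
    config: ClassifierConfig = ClassifierConfig(),
    exclude_targets: Set[str] = frozenset(),
) -> List[VariableSite]:
    """Positions where a second allele has >= ``min_variant_reads`` support.

    The site's allele pair is the two pooled-majority bases (ties broken by
    base order).  A site enters only if the second allele reaches both the
    read minimum and the ``min_variant_frac`` allele frequency *within at
    least one accession* — a read apiece in each line, or an isolated pair of
    error reads under a deep column, is the signature of stray mismatches
    (sequencing error, residual intronic bases on junction reads), not of a
    variant.  Per-accession IVS flags mark accessions holding at least one
    read of each allele.  N columns never define alleles.
    """
    sites: List[VariableSite] = []
    for target, mats in pileup.counts.items():
        if target in exclude_targets:
            continue
        pooled = sum(mats.values())[:, :4]  # ignore N
        part = np.sort(pooled, axis=1)
        variable = part[:, -2] >= config.min_variant_reads
        for pos in np.flatnonzero(variable):
            row = pooled[pos]
            order = np.argsort(-row, kind="stable")
            a1, a2 = BASE_ORDER[order[0]], BASE_ORDER[order[1]]
            supported = False
            for mat in mats.values():
                second = int(mat[pos, order[1]])
                depth = int(mat[pos, :4].sum())
                if second >= config.min_variant_reads and depth > 0 and \
                        second / depth >= config.min_variant_frac:
                    supported = True
                    break
            if not supported:
                continue
            n_alleles = int((row >= config.min_variant_reads).sum())
            counts = {
                acc: {BASE_ORDER[i]: int(mat[pos, i]) for i in range(4) if mat[pos, i] > 0}
                for acc, mat in mats.items()
            }
            is_ivs = {
                acc: counts[acc].get(a1, 0) >= 1 and counts[acc].get(a2, 0) >= 1
                for acc in mats
            }
            sites.append(
                VariableSite(
                    target=target,
                    position=int(pos),
                    ref_base=pileup.references[target][pos],
                    counts=counts,
                    alleles=(a1, a2),
                    n_alleles=n_alleles,
                    is_ivs=is_ivs,
                )
            )
    return sites


def mdc_target_filter(
    summaries: Dict[str, CoverageSummary],
    single_copy_gene_ids: Sequence[str],
    config: ClassifierConfig = ClassifierConfig(),
    combined: bool = True,
) -> Tuple[float, Set[str]]:
    """High-coverage target exclusion.

    The cutoff is the ``mdc_percentile`` (99th) percentile of the MDC
    distribution over known single-copy genes (or an explicit override);
    every target whose MDC is >= the cutoff is excluded from variant calling
    as a likely repeat or multigene family.  ``combined`` selects the summed
    two-accession depth (default) versus the per-accession maximum.
    """
    ids = [g for g in single_copy_gene_ids if g in summaries]
    if not ids:
        raise ValueError("single-copy gene set is empty")

    def mdc_of(s: CoverageSummary) -> float:
        return s.mdc_combined if combined else max(s.mdc.values())

    if config.mdc_cutoff_override is not None:
        cutoff = float(config.mdc_cutoff_override)
    else:
        cutoff = float(np.percentile([mdc_of(summaries[g]) for g in ids],
                                     config.mdc_percentile))
    excluded = {t for t, s in summaries.items() if mdc_of(s) >= cutoff}
    return cutoff, excluded


def log2_variant_ratio(site: VariableSite, accession: str) -> float:
    """log2(reference-matching variant reads / alternative variant reads)."""
    a1, a2 = site.alleles
    if site.ref_base == a1:
        ref_allele, alt_allele = a1, a2
    elif site.ref_base == a2:
        ref_allele, alt_allele = a2, a1
    else:
        raise ValueError(
            f"reference base {site.ref_base!r} is not one of the site alleles {site.alleles}"
        )
    ref_n = site.allele_count(accession, ref_allele)
    alt_n = site.allele_count(accession, alt_allele)
    if ref_n < 1 or alt_n < 1:
        raise ValueError("both variants need >= 1 read to form a ratio")
    return math.log2(ref_n / alt_n)


def calibrate_ratio_thresholds(
    true_ivs_ratios: Sequence[float],
    false_ivs_ratios: Sequence[float],
    target_rate: float = 0.05,
) -> float:
    """Largest upper log2-ratio threshold keeping the false-IVS rate in check.

    Scans the merged observed ratio values for the largest threshold ``u``
    such that, among sites with ratio <= u, the fraction drawn from the false
    set is <= ``target_rate``.  If no threshold attains the rate the minimum
    observed ratio is returned with a warning.
    """
    t = np.sort(np.asarray(true_ivs_ratios, dtype=float))
    f = np.sort(np.asarray(false_ivs_ratios, dtype=float))
    if t.size == 0:
        raise ValueError("true-IVS ratio sample is empty")
    candidates = np.unique(np.concatenate([t, f]))
    for u in candidates[::-1]:
        nt = int(np.searchsorted(t, u, side="right"))
        nf = int(np.searchsorted(f, u, side="right"))
        if nt + nf and nf / (nt + nf) <= target_rate:
            return float(u)
    warnings.warn("no ratio threshold attains the target false-IVS rate; "
                  "returning the minimum observed ratio")
    return float(candidates[0])


def calibrate_from_reference_sets(
    sites: Sequence["VariableSite"],
    true_positions: Set,
    multi_copy_targets: Set[str],
    accessions: Sequence[str],
    target_rate: float = 0.05,
    min_sample: int = 10,
) -> Dict[str, float]:
    """Per-accession upper thresholds from validated site sets.

    Mirrors the empirical calibration on re-sequenced genes: observed log2
    ratios at known-true IVS positions form the true sample, ratios at
    variable sites inside known multi-copy (paralogous/duplicated) genes that
    are not known variants form the false sample.  Accessions whose true
    sample is smaller than ``min_sample`` keep no entry (caller falls back to
    its configured threshold).
    """
    out: Dict[str, float] = {}
    for acc in accessions:
        true_r, false_r = [], []
        for site in sites:
            if not site.is_ivs.get(acc) or site.ref_base not in site.alleles:
                continue
            key = (site.target, site.position)
            if key in true_positions:
                true_r.append(log2_variant_ratio(site, acc))
            elif site.target in multi_copy_targets:
                false_r.append(log2_variant_ratio(site, acc))
        if len(true_r) >= min_sample:
            out[acc] = calibrate_ratio_thresholds(true_r, false_r, target_rate)
    return out


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------


def _monomorphic_state(site: VariableSite, accession: str,
                       config: ClassifierConfig) -> Optional[str]:
    """Major allele if the accession is monomorphic for a site allele.

    Tolerates up to ``max_mono_discordant`` reads of other bases (sequencing
    error); returns None if the side is not cleanly monomorphic.
    """
    counts = site.counts.get(accession, {})
    if not counts:
        return None
    major = max(counts, key=lambda b: (counts[b], -BASE_ORDER.index(b)))
    if major not in site.alleles:
        return None
    discordant = sum(n for b, n in counts.items() if b != major)
    if discordant > config.max_mono_discordant:
        return None
    return major


def classify_site(site: VariableSite, config: ClassifierConfig = ClassifierConfig()) -> SiteCall:
    """Label one variable site as GSS, SNP or filtered-with-reason.

    GSS: IVS in both accessions (same pooled allele pair).  SNP: IVS in
    exactly one accession, the other monomorphic for one of the two alleles
    at depth >= ``min_mono_coverage``; the shared allele is ancestral, the
    unshared one derived, and the IVS-bearing accession is the derived
    lineage.  The log2 ratio filter applies to every IVS; sites with more
    than two supported alleles are set aside as triallelic.
    """
    if site.n_alleles > 2:
        return SiteCall(site, LABEL_FILTERED, filter_reason=REASON_TRIALLELIC)

    ivs_accs = [acc for acc, flag in site.is_ivs.items() if flag]

    if site.ref_base in site.alleles:
        for acc in ivs_accs:
            ratio = log2_variant_ratio(site, acc)
            if not (config.lower_threshold(acc) <= ratio <= config.log2_upper[acc]):
                return SiteCall(site, LABEL_FILTERED, filter_reason=REASON_RATIO)

    if len(ivs_accs) == 2:
        return SiteCall(site, LABEL_GSS)

    if len(ivs_accs) == 1:
        lineage = ivs_accs[0]
        other = next(acc for acc in site.is_ivs if acc != lineage)
        mono = _monomorphic_state(site, other, config)
        if mono is None:
            return SiteCall(site, LABEL_FILTERED, filter_reason=REASON_TRIALLELIC)
        if site.depth(other) < config.min_mono_coverage:
            return SiteCall(site, LABEL_FILTERED, filter_reason=REASON_LOW_MONO)
        derived = site.alleles[1] if mono == site.alleles[0] else site.alleles[0]
        return SiteCall(site, LABEL_SNP, lineage=lineage, ancestral=mono, derived=derived)

    # no IVS anywhere: each accession monomorphic for a different allele —
    # the footprint of reciprocal homoeolog loss, handled by the structural
    # detectors rather than the site taxonomy
    return SiteCall(site, LABEL_FILTERED, filter_reason=REASON_NO_IVS)


# ---------------------------------------------------------------------------
# flank rescue
# ---------------------------------------------------------------------------


class ReadPoolScanner:
    """Mismatch-tolerant substring scan over a raw read pool (both strands)."""

    def __init__(self, sequences: Iterable[str]):
        by_len: Dict[int, List[np.ndarray]] = {}
        for seq in sequences:
            for s in (seq, revcomp(seq)):
                by_len.setdefault(len(s), []).append(encode_bases(s))
        self._mats = {L: np.vstack(rows) for L, rows in by_len.items() if L > 0}

    @property
    def n_reads(self) -> int:
        return sum(m.shape[0] for m in self._mats.values()) // 2

    def find(self, query: str, site_index: int, max_mismatches: int,
             min_overlap: int) -> bool:
        """Any read matching ``query`` with <= max_mismatches over an overlap
        of >= min_overlap that covers (and agrees at) ``site_index``?"""
        q = encode_bases(query)
        Lq = q.size
        for L, mat in self._mats.items():
            for off in range(-(L - 1), Lq):
                a = max(0, -off)  # read-local start of overlap
                b = max(0, off)   # query-local start of overlap
                v = min(L - a, Lq - b)
                if v < min_overlap or not (b <= site_index < b + v):
                    continue
                ridx = site_index - off
                cand = mat[mat[:, ridx] == q[site_index]]
                if cand.shape[0] == 0:
                    continue
                mm = (cand[:, a : a + v] != q[b : b + v]).sum(axis=1)
                if (mm <= max_mismatches).any():
                    return True
        return False


def flank_rescue(
    snp_call: SiteCall,
    raw_reads,
    references: Dict[str, str],
    config: ClassifierConfig = ClassifierConfig(),
) -> bool:
    """Test whether a SNP call is a hidden GSS whose diverged reads failed
    to align.

    Builds a query from the reference context centred on the site with the
    candidate missing variant (the derived allele) substituted, then scans the
    *monomorphic* accession's raw reads, both strands, for a match with at
    most ``flank_max_mismatches`` mismatches covering the site.  A hit means
    the second variant exists in that line after all — the call is demoted
    (filtered/flank_rescued).
    """
    if snp_call.label != LABEL_SNP:
        raise ValueError("flank_rescue applies to SNP calls only")
    site = snp_call.site
    ref = references[site.target]
    half = config.flank_length // 2
    start = max(0, site.position - half)
    end = min(len(ref), start + config.flank_length)
    start = max(0, min(start, end - config.flank_length))
    if end - start < config.flank_length:
        warnings.warn(f"{site.target}:{site.position}: flank window shrunk to "
                      f"{end - start} bp at target edge")
    site_index = site.position - start
    query = ref[start:end]
    query = query[:site_index] + snp_call.derived + query[site_index + 1 :]

    scanner = raw_reads if isinstance(raw_reads, ReadPoolScanner) else \
        ReadPoolScanner(raw_reads)
    if scanner.n_reads == 0:
        return False
    return scanner.find(query, site_index, config.flank_max_mismatches,
                        config.flank_min_overlap)


def apply_flank_rescue(
    calls: List[SiteCall],
    reads_by_accession: Dict[str, Iterable[str]],
    references: Dict[str, str],
    config: ClassifierConfig = ClassifierConfig(),
) -> List[SiteCall]:
    """Demote SNP calls whose missing variant hides in the raw read pool."""
    scanners = {acc: seqs if isinstance(seqs, ReadPoolScanner) else ReadPoolScanner(seqs)
                for acc, seqs in reads_by_accession.items()}
    out = []
    for call in calls:
        if call.label == LABEL_SNP:
            mono_acc = next(a for a in call.site.is_ivs if a != call.lineage)
            if mono_acc in scanners and flank_rescue(call, scanners[mono_acc],
                                                     references, config):
                call = SiteCall(call.site, LABEL_FILTERED, filter_reason=REASON_FLANK)
        out.append(call)
    return out


# ---------------------------------------------------------------------------
# theory + validation arithmetic
# ---------------------------------------------------------------------------


def expected_missed_variant_sites(theory: TheoryParams) -> float:
    """Expected count of divergent sites with only one variant sequenced.

    With Poisson depth lambda and equal variant frequencies, the chance that
    all reads at a site carry the same variant is ``2 exp(-lambda)`` (capped
    at 1); multiplying by the expected number of divergent sites ``d * L``
    gives the expected count of such single-variant sites.
    """
    if theory.lambda_cov <= 0:
        raise ValueError("lambda must be > 0")
    p_one = min(1.0, 2.0 * math.exp(-theory.lambda_cov))
    return p_one * theory.t_expected_sites


def validation_confusion(called: Set, truth: Set) -> Dict[str, Optional[float]]:
    """False positive / false negative rates of a call set against a truth set.

    Sets are keyed however the caller likes (typically (target, position)).
    FPR = fraction of calls absent from the truth; FNR = fraction of truth
    never called.  An empty call set leaves the FPR undefined (None).
    """
    called = set(called)
    truth = set(truth)
    shared = len(called & truth)
    fpr = (len(called) - shared) / len(called) if called else None
    fnr = (len(truth) - shared) / len(truth) if truth else None
    return {
        "false_positive_rate": fpr,
        "false_negative_rate": fnr,
        "shared": shared,
        "n_called": len(called),
        "n_truth": len(truth),
    }


# ---------------------------------------------------------------------------
# synthetic ratio mixtures (calibration experiments)
# ---------------------------------------------------------------------------


def simulate_ivs_ratio_mixture(
    n_true: int,
    n_false: int,
    lam: float = 13.0,
    ref_bias: float = 0.55,
    false_ref_frac: float = 0.75,
    rng: Optional[np.random.Generator] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Draw log2 allele-depth ratios for true and paralog-inflated false IVSs.

    True IVSs: site depth Poisson(lam), reference-matching reads binomial
    with a mild reference capture bias (``ref_bias``) around the expected 1:1.
    False IVSs: paralog contamination adds a third aligned copy carrying the
    reference base, pushing the expectation to 3:1 (``false_ref_frac``).
    Sites are conditioned on both variants being observed (>=1 read each),
    since only those enter the IVS set.
    """
    rng = rng or np.random.default_rng()

    def draw(n: int, p: float) -> np.ndarray:
        out = np.empty(n)
        filled = 0
        while filled < n:
            m = max(64, 2 * (n - filled))
            depth = rng.poisson(lam, m)
            depth = depth[depth >= 2]
            ref = rng.binomial(depth, p)
            ok = (ref >= 1) & (ref < depth)
            ref, depth = ref[ok], depth[ok]
            take = min(n - filled, ref.size)
            out[filled : filled + take] = np.log2(ref[:take] / (depth[:take] - ref[:take]))
            filled += take
        return out

    return draw(n_true, ref_bias), draw(n_false, false_ref_frac)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_site_calls_tsv(calls: Sequence[SiteCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tpos\tref\talleles\tlabel\tlineage\tancestral\tderived\t"
                 "filter_reason\tcounts\n")
        for c in calls:
            s = c.site
            counts = ";".join(
                f"{acc}:" + ",".join(f"{b}={n}" for b, n in sorted(cnt.items()))
                for acc, cnt in sorted(s.counts.items())
            )
            fh.write(f"{s.target}\t{s.position}\t{s.ref_base}\t{''.join(s.alleles)}\t"
                     f"{c.label}\t{c.lineage or ''}\t{c.ancestral or ''}\t"
                     f"{c.derived or ''}\t{c.filter_reason or ''}\t{counts}\n")


def write_vcf(calls: Sequence[SiteCall], references: Dict[str, str], path) -> None:
    """Minimal VCF 4.2 with CLASS/LINEAGE/ANC/DER INFO keys."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=CLASS,Number=1,Type=String,Description="GSS or SNP">\n')
        fh.write('##INFO=<ID=LINEAGE,Number=1,Type=String,Description="derived lineage">\n')
        fh.write('##INFO=<ID=ANC,Number=1,Type=String,Description="ancestral allele">\n')
        fh.write('##INFO=<ID=DER,Number=1,Type=String,Description="derived allele">\n')
        for name, seq in references.items():
            fh.write(f"##contig=<ID={name},length={len(seq)}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in calls:
            s = c.site
            ref = s.ref_base
            alt = next((a for a in s.alleles if a != ref), s.alleles[1])
            if c.label == LABEL_FILTERED:
                filt, info = c.filter_reason, "."
            else:
                filt = "PASS"
                info = f"CLASS={c.label}"
                if c.label == LABEL_SNP:
                    info += f";LINEAGE={c.lineage};ANC={c.ancestral};DER={c.derived}"
            fh.write(f"{s.target}\t{s.position + 1}\t.\t{ref}\t{alt}\t.\t{filt}\t{info}\n")
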