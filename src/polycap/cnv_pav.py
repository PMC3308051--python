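"""Copy-number, presence/absence and homoeolog-deletion detection.

Two complementary detectors:

* a depth-ratio detector tiling each target with 500-bp windows (250-bp
  step), testing each window's between-accession read-count ratio with a
  log-ratio normal approximation, and calling a CNV when at least four
  windows are significant with a consistent sign;
* a variant-pattern detector using allele representation at variable sites —
  a gene where one accession shows only a single variant at more than 70% of
  its variable sites has lost one homoeologous copy in that accession;
  reciprocal losses (each line retaining a different subgenome's copy) leave
  both lines single but for different alleles.

Whole-gene PAV is called directly from median depths (MDC 0 in one line,
>= 10 in the other).  The mechanism behind a depth CNV is inferred from the
target's variable-site count: no variable sites points at a deletion, an
excess over the non-CNV baseline at a multigene-family copy-number change.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.stats import norm

from .pileup_store import CoverageSummary
from .variant_classifier import VariableSite

KIND_CNV = "cnv"
KIND_CNV_DUP = "cnv_duplication"
KIND_CNV_DEL = "cnv_deletion"
KIND_PAV = "pav"
KIND_HOMOEOLOG_DEL = "homoeolog_deletion"
KIND_RECIPROCAL_DEL = "reciprocal_deletion"


@dataclass
class WindowCount:
    target: str
    start: int
    end: int
    x: int  # reads from accession 1
    y: int  # reads from accession 2
    nx: int  # library totals
    ny: int
    log2_ratio: float = float("nan")
    p_value: float = float("nan")


@dataclass
class StructuralCall:
    target: str
    kind: str
    accession: Optional[str]  # affected accession; None for reciprocal (both)
    evidence: Dict[str, object] = field(default_factory=dict)


def eligible_targets(
    summaries: Dict[str, CoverageSummary], breadth_min: float = 0.7
) -> Set[str]:
    """Targets with at least ``breadth_min`` of their bases covered >= 1x."""
    return {t for t, s in summaries.items() if s.breadth_ge1 >= breadth_min}


def tile_windows(length: int, window: int = 500, step: int = 250) -> List[Tuple[int, int]]:
    """500/250 sliding windows; a target shorter than one window gets a single
    full-length window; trailing fragments shorter than the step are dropped."""
    if length <= window:
        return [(0, length)]
    out = []
    for s in range(0, length, step):
        e = min(s + window, length)
        if e - s >= step:
            out.append((s, e))
        if e == length:
            break
    return out


def window_ratio_test(x: int, y: int, nx: int, ny: int) -> Tuple[float, float]:
    """Between-accession coverage ratio test for one window.

    The library-size-normalised ratio r = (x/nx)/(y/ny) is tested with the
    delta-method normal approximation z = ln(r) / sqrt(1/x + 1/y); zero
    counts get a 0.5 continuity correction.  Returns (log2 ratio, two-sided
    p-value).
    """
    if nx <= 0 or ny <= 0:
        raise ValueError("library totals must be positive")
    if x + y <= 0:
        raise ValueError("window has no reads in either accession")
    xx = x if x > 0 else 0.5
    yy = y if y > 0 else 0.5
    r = (xx / nx) / (yy / ny)
    z = math.log(r) / math.sqrt(1.0 / xx + 1.0 / yy)
    p = 2.0 * norm.sf(abs(z))
    return math.log2(r), float(min(1.0, p))


def count_windows(
    read_starts: Dict[str, Sequence[int]],
    target: str,
    length: int,
    library_totals: Dict[str, int],
    accessions: Sequence[str],
    window: int = 500,
    step: int = 250,
) -> List[WindowCount]:
    """Tabulate per-window read counts (reads assigned by start position)."""
    acc1, acc2 = accessions
    s1 = np.sort(np.asarray(read_starts.get(acc1, []), dtype=int))
    s2 = np.sort(np.asarray(read_starts.get(acc2, []), dtype=int))
    out = []
    for s, e in tile_windows(length, window, step):
        x = int(np.searchsorted(s1, e) - np.searchsorted(s1, s))
        y = int(np.searchsorted(s2, e) - np.searchsorted(s2, s))
        w = WindowCount(target, s, e, x, y, library_totals[acc1], library_totals[acc2])
        if x + y > 0:
            w.log2_ratio, w.p_value = window_ratio_test(x, y, w.nx, w.ny)
        out.append(w)
    return out


def call_cnv(
    windows: Sequence[WindowCount],
    accessions: Sequence[str],
    alpha: float = 0.001,
    min_sig_windows: int = 4,
) -> Optional[StructuralCall]:
    """CNV when >= ``min_sig_windows`` windows are significant with one sign.

    For targets too short to tile ``min_sig_windows`` windows the requirement
    is scaled down to the number of windows available.
    """
    if not windows:
        return None
    required = min(min_sig_windows, len(windows))
    sig = [w for w in windows if not math.isnan(w.p_value) and w.p_value < alpha]
    if len(sig) < required:
        return None
    n_pos = sum(1 for w in sig if w.log2_ratio > 0)
    n_neg = sum(1 for w in sig if w.log2_ratio < 0)
    if n_pos and n_neg:
        return None  # gain and loss cannot coexist in one event
    higher = accessions[0] if n_pos else accessions[1]
    return StructuralCall(
        target=windows[0].target,
        kind=KIND_CNV,
        accession=higher,
        evidence={
            "n_significant": len(sig),
            "n_windows": len(windows),
            "mean_log2_ratio": float(np.mean([w.log2_ratio for w in sig])),
            "alpha": alpha,
        },
    )


def cnv_mechanism(
    call: StructuralCall,
    variable_site_count: int,
    baseline_mean: float,
    accessions: Sequence[str],
) -> StructuralCall:
    """Infer the mechanism behind a depth CNV from its variable-site count.

    No variable sites: the copy missing in the lower-coverage accession was
    deleted.  More variable sites than the non-CNV baseline: extra diverged
    copies of a multigene family in the higher-coverage accession.  Counts in
    between stay ambiguous.  A duplication excess within one baseline
    standard deviation (Poisson, sqrt of the mean) is flagged low-confidence.
    """
    higher = call.accession
    lower = next(a for a in accessions if a != higher)
    ev = dict(call.evidence)
    ev["variable_site_count"] = variable_site_count
    ev["baseline_mean"] = baseline_mean
    if variable_site_count == 0:
        return StructuralCall(call.target, KIND_CNV_DEL, lower, ev)
    if variable_site_count > baseline_mean:
        ev["low_confidence_margin"] = (
            variable_site_count <= baseline_mean + math.sqrt(max(baseline_mean, 1.0))
        )
        return StructuralCall(call.target, KIND_CNV_DUP, higher, ev)
    ev["mechanism"] = "ambiguous"
    return StructuralCall(call.target, KIND_CNV, higher, ev)


def call_pav(
    target: str,
    mdc_by_accession: Dict[str, float],
    min_present: float = 10,
) -> Optional[StructuralCall]:
    """Whole-gene absence: zero MDC in one line, >= ``min_present`` in the other."""
    (a1, m1), (a2, m2) = sorted(mdc_by_accession.items())
    absent = None
    if m1 == 0 and m2 >= min_present:
        absent, present_mdc = a1, m2
    elif m2 == 0 and m1 >= min_present:
        absent, present_mdc = a2, m1
    if absent is None:
        return None
    return StructuralCall(target, KIND_PAV, absent,
                          {"mdc": dict(mdc_by_accession), "min_present": min_present})


def homoeolog_deletion(
    target: str,
    sites: Sequence[VariableSite],
    accessions: Sequence[str],
    single_variant_fraction_min: float = 0.7,
    min_sites: int = 3,
    consistency_min: float = 0.7,
) -> Optional[StructuralCall]:
    """Homoeolog loss from allele representation at a gene's variable sites.

    Over the gene's variable sites where both accessions have coverage, an
    accession that lost one subgenome copy shows a single variant wherever
    the intact accession shows two; a single-variant fraction above
    ``single_variant_fraction_min`` (strict) calls the deletion.  When *both*
    accessions are single at most sites but retain different alleles — split
    consistently by whether the retained base matches the reference copy —
    the gene carries a reciprocal deletion (each line kept a different
    subgenome's copy).  Genes with fewer than ``min_sites`` comparable sites
    are not assessed.
    """
    acc1, acc2 = accessions
    n = 0
    single1 = single2 = single_both = 0
    both_votes = []  # True when acc1's retained allele matches the reference
    for site in sites:
        p1 = [a for a in site.alleles if site.allele_count(acc1, a) >= 1]
        p2 = [a for a in site.alleles if site.allele_count(acc2, a) >= 1]
        if not p1 or not p2:
            continue
        n += 1
        if len(p1) == 1 and len(p2) == 2:
            single1 += 1
        elif len(p2) == 1 and len(p1) == 2:
            single2 += 1
        elif len(p1) == 1 and len(p2) == 1 and p1[0] != p2[0]:
            single_both += 1
            both_votes.append(p1[0] == site.ref_base)
    if n < min_sites:
        return None
    f1, f2, fb = single1 / n, single2 / n, single_both / n
    evidence = {
        "n_sites": n,
        "single_variant_fraction": {acc1: f1, acc2: f2},
        "both_single_fraction": fb,
    }
    if fb > single_variant_fraction_min and both_votes:
        consistency = sum(both_votes) / len(both_votes)
        evidence["phase_consistency"] = consistency
        if consistency >= consistency_min or consistency <= 1 - consistency_min:
            return StructuralCall(target, KIND_RECIPROCAL_DEL, None, evidence)
    if f1 > single_variant_fraction_min and f2 <= single_variant_fraction_min:
        return StructuralCall(target, KIND_HOMOEOLOG_DEL, acc1, evidence)
    if f2 > single_variant_fraction_min and f1 <= single_variant_fraction_min:
        return StructuralCall(target, KIND_HOMOEOLOG_DEL, acc2, evidence)
    return None


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_windows_bed(windows: Iterable[WindowCount], path) -> None:
    """Window table as BED with log2-ratio and p-value score columns."""
    with open(path, "w") as fh:
        fh.write("#target\tstart\tend\tx\ty\tlog2_ratio\tp_value\n")
        for w in windows:
            fh.write(f"{w.target}\t{w.start}\t{w.end}\t{w.x}\t{w.y}\t"
                     f"{w.log2_ratio:.4f}\t{w.p_value:.3e}\n")


def write_structural_calls_tsv(calls: Iterable[StructuralCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tkind\taccession\tevidence\n")
        for c in calls:
            ev = ";".join(f"{k}={v}" for k, v in c.evidence.items())
            fh.write(f"{c.target}\t{c.kind}\t{c.accession or 'both'}\t{ev}\n")
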