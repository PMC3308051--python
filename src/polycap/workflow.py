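"""End-to-end orchestration: simulate -> prep -> pileup -> classify -> CNV/PAV
-> annotate, under one seed, with a run report.

Every stage consumes and produces plain in-memory objects (and, when an
output directory is given, plain-text FASTA/FASTQ/TSV files), so any stage is
independently inspectable and re-runnable.  When the simulator's truth set is
available the report includes per-class confusion (false positive / false
negative rates) and structural-event recovery.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np

from . import cnv_pav, effect_annotator, pileup_store, read_prep, variant_classifier
from .effect_annotator import GeneModel
from .read_prep import AlignerParams, ReadRecord
from .synthetic_tetraploid import (
    SimConfig,
    TruthSet,
    simulate_reads,
    simulate_references,
    write_fastq,
    write_reference_fasta,
    write_truth_tables,
)
from .variant_classifier import ClassifierConfig, LABEL_FILTERED, LABEL_GSS, LABEL_SNP

log = logging.getLogger("polycap.workflow")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    aligner: AlignerParams = field(default_factory=AlignerParams)
    min_read_length: int = 30
    min_tag_quality: int = 15
    rescue_max_mismatches: int = 1  # stricter budget for the trim-realign loop
    pileup_end_clip: int = 4  # alignment bases ignored at each read end
    breadth_min: float = 0.7
    cnv_alpha: float = 0.001
    cnv_min_windows: int = 4
    pav_min_present: float = 10
    homoeolog_min_fraction: float = 0.7
    homoeolog_min_sites: int = 3
    flank_rescue_enabled: bool = True
    calibrate_thresholds: bool = True
    outdir: Optional[str] = None

    def __post_init__(self):
        # one seed governs every stochastic stage
        accs = list(self.sim.accessions)
        for acc in accs:
            self.classifier.log2_upper.setdefault(acc, 1.6)


def _stage(name):
    log.info("[%s] start", name)


def run_pipeline(config: RunConfig) -> Dict[str, object]:
    """Execute all stages and return the run report (a JSON-able dict)."""
    sim_cfg = config.sim
    accs = list(sim_cfg.accessions)

    _stage("simulate")
    targets, _copies, truth = simulate_references(sim_cfg)
    reads = simulate_reads(truth, sim_cfg)
    references = {g: t.seq for g, t in targets.items()}
    pool = reads["pool"]

    _stage("demultiplex")
    tag_to_acc = {tag: acc for acc, tag in sim_cfg.tag_table.items()}
    records = [ReadRecord(r.id, r.sequence, r.quality) for r in pool]
    assigned, rejected = read_prep.demultiplex(records, tag_to_acc,
                                               config.min_tag_quality)

    _stage("align")
    index = read_prep.ReferenceIndex(references)
    # the rescue loop hunts for the exon-spanning portion of junction reads;
    # a tight mismatch budget stops it from accepting shifted placements
    # that still carry intronic bases
    rescue_params = dataclasses.replace(
        config.aligner,
        max_seed_mismatches=min(config.aligner.max_seed_mismatches,
                                config.rescue_max_mismatches),
        max_total_mismatches=config.rescue_max_mismatches)
    alignments = []
    unaligned_by_acc: Dict[str, List[str]] = {acc: [] for acc in accs}
    n_no_hit = n_multi = n_trim_rescued = n_trim_exhausted = 0
    for acc in accs:
        aligned, no_hit, multi = read_prep.align_reads(assigned.get(acc, []),
                                                       index, config.aligner)
        rescued, exhausted = read_prep.iterative_trim_align(
            no_hit, index, rescue_params, config.min_read_length)
        alignments.extend(aligned)
        alignments.extend(rescued)
        unaligned_by_acc[acc] = [r.sequence for r in exhausted + multi]
        n_no_hit += len(no_hit)
        n_multi += len(multi)
        n_trim_rescued += len(rescued)
        n_trim_exhausted += len(exhausted)

    _stage("pileup")
    counted = pileup_store.clip_alignment_ends(alignments, config.pileup_end_clip)
    pileup = pileup_store.build_pileup(counted, references, accs)
    summaries = pileup_store.coverage_summaries(pileup)

    _stage("mdc_filter")
    single_copy = truth.single_copy_genes()
    cutoff, excluded = variant_classifier.mdc_target_filter(
        summaries, single_copy, config.classifier)

    _stage("variant_calling")
    sites = variant_classifier.call_variable_sites(pileup, config.classifier,
                                                   exclude_targets=excluded)

    calibrated = {}
    if config.calibrate_thresholds:
        # empirical per-accession thresholds, mirroring calibration on
        # re-sequenced genes: planted GSS positions are the validated true
        # IVSs, variable sites inside known multi-copy genes the false ones
        multi_copy = ({p.gene for p in truth.paralogs}
                      | {d.gene for d in truth.duplications})
        calibrated = variant_classifier.calibrate_from_reference_sets(
            sites, truth.gss_positions(), multi_copy, accs,
            config.classifier.target_false_ivs_rate)
        config.classifier.log2_upper.update(calibrated)

    calls = [variant_classifier.classify_site(s, config.classifier) for s in sites]

    if config.flank_rescue_enabled:
        _stage("flank_rescue")
        # the missing second variant, if it exists, sits in reads too
        # diverged to align — scanning the unaligned pool suffices
        calls = variant_classifier.apply_flank_rescue(
            calls, unaligned_by_acc, references, config.classifier)

    _stage("cnv_pav")
    eligible = cnv_pav.eligible_targets(summaries, config.breadth_min)
    library_totals = {
        acc: sum(1 for a in alignments if a.accession == acc) for acc in accs
    }
    starts: Dict[str, Dict[str, List[int]]] = {t: {a: [] for a in accs}
                                               for t in references}
    for a in alignments:
        starts[a.target][a.accession].append(a.pos)

    sites_by_target: Dict[str, List] = {}
    for s in sites:
        sites_by_target.setdefault(s.target, []).append(s)

    structural: List[cnv_pav.StructuralCall] = []
    cnv_candidates = []
    for t in sorted(eligible):
        windows = cnv_pav.count_windows(starts[t], t, len(references[t]),
                                        library_totals, accs)
        call = cnv_pav.call_cnv(windows, accs, config.cnv_alpha,
                                config.cnv_min_windows)
        if call is not None:
            cnv_candidates.append(call)
    n_var = {t: len(sites_by_target.get(t, [])) for t in eligible}
    cnv_targets = {c.target for c in cnv_candidates}
    non_cnv_counts = [n for t, n in n_var.items() if t not in cnv_targets]
    baseline = float(np.mean(non_cnv_counts)) if non_cnv_counts else 0.0
    for call in cnv_candidates:
        structural.append(cnv_pav.cnv_mechanism(
            call, n_var.get(call.target, 0), baseline, accs))

    for t, s in summaries.items():
        pav = cnv_pav.call_pav(t, s.mdc, config.pav_min_present)
        if pav is not None:
            structural.append(pav)

    for t in sorted(eligible):
        hd = cnv_pav.homoeolog_deletion(
            t, sites_by_target.get(t, []), accs,
            config.homoeolog_min_fraction, config.homoeolog_min_sites)
        if hd is not None:
            structural.append(hd)

    # a gene called as a homoeolog deletion reinterprets its single-variant
    # sites: they reflect the lost subgenome copy, not lineage mutations
    deletion_targets = {c.target for c in structural
                        if c.kind in (cnv_pav.KIND_HOMOEOLOG_DEL,
                                      cnv_pav.KIND_RECIPROCAL_DEL)}
    calls = [
        variant_classifier.SiteCall(
            c.site, LABEL_FILTERED,
            filter_reason=variant_classifier.REASON_HOMOEOLOG_TARGET)
        if c.label == LABEL_SNP and c.site.target in deletion_targets else c
        for c in calls
    ]

    _stage("annotate")
    models = {
        g: GeneModel(g, t.utr5, t.cds, t.utr3) for g, t in targets.items()
    }
    effects: List[effect_annotator.EffectCall] = []
    for c in calls:
        s = c.site
        model = models[s.target]
        if c.label == LABEL_SNP:
            effects.append(effect_annotator.classify_effect(
                c.ancestral, c.derived, s.position, model, references[s.target],
                lineage=c.lineage))
        elif c.label == LABEL_GSS:
            # GSS orientation is arbitrary: reference allele vs alternative
            ref_allele = s.ref_base if s.ref_base in s.alleles else s.alleles[0]
            alt = next(a for a in s.alleles if a != ref_allele)
            effects.append(effect_annotator.classify_effect(
                ref_allele, alt, s.position, model, references[s.target],
                lineage=None))

    # ------------------------------------------------------------------
    # report
    # ------------------------------------------------------------------
    _stage("report")
    call_tally = {LABEL_GSS: 0, LABEL_SNP: 0, LABEL_FILTERED: 0}
    filter_tally: Dict[str, int] = {}
    for c in calls:
        call_tally[c.label] += 1
        if c.label == LABEL_FILTERED:
            filter_tally[c.filter_reason] = filter_tally.get(c.filter_reason, 0) + 1

    called_gss = {(c.site.target, c.site.position) for c in calls
                  if c.label == LABEL_GSS}
    called_snp = {(c.site.target, c.site.position) for c in calls
                  if c.label == LABEL_SNP}
    confusion = {
        "GSS": variant_classifier.validation_confusion(called_gss,
                                                       truth.gss_positions()),
        "SNP": variant_classifier.validation_confusion(called_snp,
                                                       truth.snp_positions()),
    }
    # allele fidelity of recovered GSSs: the called pooled allele pair must
    # be the planted A/B pair
    planted_pair = {(r.gene, r.position): frozenset((r.allele_a, r.allele_b))
                    for r in truth.gss}
    recovered = [c for c in calls if c.label == LABEL_GSS
                 and (c.site.target, c.site.position) in planted_pair]
    n_exact = sum(1 for c in recovered
                  if frozenset(c.site.alleles)
                  == planted_pair[(c.site.target, c.site.position)])
    confusion["GSS"]["allele_pair_exact"] = (
        n_exact / len(recovered) if recovered else None)

    truth_pav = {(r.gene, r.accession) for r in truth.pav}
    called_pav = {(c.target, c.accession) for c in structural
                  if c.kind == cnv_pav.KIND_PAV}
    full_deletions = {(r.gene, r.accession) for r in truth.deletions
                      if r.kind == "full"}
    reciprocal_truth = {g for g, n in
                        ((g, sum(1 for r in truth.deletions if r.gene == g))
                         for g in {r.gene for r in truth.deletions}) if n > 1}
    called_hd = {(c.target, c.accession) for c in structural
                 if c.kind == cnv_pav.KIND_HOMOEOLOG_DEL}
    called_recip = {c.target for c in structural
                    if c.kind == cnv_pav.KIND_RECIPROCAL_DEL}

    structural_tally: Dict[str, int] = {}
    for c in structural:
        structural_tally[c.kind] = structural_tally.get(c.kind, 0) + 1

    effect_tally: Dict[str, int] = {}
    for e in effects:
        effect_tally[e.effect] = effect_tally.get(e.effect, 0) + 1

    report: Dict[str, object] = {
        "config": {"n_genes": sim_cfg.n_genes, "lambda": sim_cfg.mean_depth_lambda,
                   "divergence_d": sim_cfg.divergence_d, "seed": sim_cfg.seed},
        "reads": {
            "total": len(pool),
            "per_accession": {acc: len(reads[acc]) for acc in accs},
            "demux_assigned": {acc: len(assigned.get(acc, [])) for acc in accs},
            "demux_rejected": len(rejected),
        },
        "alignment": {
            "aligned_direct": len(alignments) - n_trim_rescued,
            "trim_rescued": n_trim_rescued,
            "trim_exhausted": n_trim_exhausted,
            "multi_hit": n_multi,
            "total_aligned": len(alignments),
        },
        "coverage": {
            "mean_mdc_combined": float(np.mean(
                [s.mdc_combined for s in summaries.values()])),
            "n_targets": len(summaries),
            "n_eligible_breadth": len(eligible),
        },
        "mdc_filter": {"cutoff": cutoff, "n_excluded": len(excluded),
                       "excluded": sorted(excluded)},
        "ratio_thresholds": dict(config.classifier.log2_upper),
        "site_calls": {**call_tally, "filtered_by_reason": filter_tally,
                       "n_variable_sites": len(sites)},
        "structural": {
            "tally": structural_tally,
            "pav_recovered": sorted(called_pav & truth_pav),
            "pav_truth": sorted(truth_pav),
            "homoeolog_deletions_called": sorted(called_hd),
            "homoeolog_deletions_truth": sorted(full_deletions),
            "reciprocal_called": sorted(called_recip),
            "reciprocal_truth": sorted(reciprocal_truth),
        },
        "effects": effect_tally,
        "confusion": confusion,
    }

    if config.outdir:
        _write_outputs(config, targets, reads, alignments, pileup, summaries,
                       calls, structural, effects, truth, report, references)
    return report


def _write_outputs(config, targets, reads, alignments, pileup, summaries,
                   calls, structural, effects, truth, report, references):
    outdir = config.outdir
    os.makedirs(outdir, exist_ok=True)
    write_reference_fasta(targets, os.path.join(outdir, "reference.fa"))
    for acc in config.sim.accessions:
        write_fastq(reads[acc], os.path.join(outdir, f"reads_{acc}.fastq"))
    write_truth_tables(truth, os.path.join(outdir, "truth"))
    read_prep.write_alignments_tsv(alignments, os.path.join(outdir, "alignments.tsv"))
    pileup_store.write_summary_tsv(summaries, os.path.join(outdir, "coverage.tsv"))
    variant_classifier.write_site_calls_tsv(calls, os.path.join(outdir, "site_calls.tsv"))
    variant_classifier.write_vcf(calls, references, os.path.join(outdir, "site_calls.vcf"))
    cnv_pav.write_structural_calls_tsv(structural,
                                       os.path.join(outdir, "structural_calls.tsv"))
    effect_annotator.write_effects_tsv(effects, os.path.join(outdir, "effects.tsv"))
    with open(os.path.join(outdir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
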