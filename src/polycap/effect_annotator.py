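"""Coding-effect annotation of classified sites on cDNA gene models.

Maps each site into the 5'UTR/CDS/3'UTR structure of its target, translates
ancestral and derived codons under the standard nuclear genetic code, and
classifies changes as synonymous, non-synonymous, stop-gain (premature stop)
or stop-loss (an ancestral stop reverting to a sense codon, restoring the
ORF).  Regional mutation densities (per covered kb) and Fisher-exact /
Benjamini-Hochberg GO-term enrichment of non-synonymous versus synonymous
changes complete the downstream summary.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

EFFECT_SYNONYMOUS = "synonymous"
EFFECT_NONSYNONYMOUS = "nonsynonymous"
EFFECT_STOP_GAIN = "stop_gain"
EFFECT_STOP_LOSS = "stop_loss"
EFFECT_UTR = "utr"
EFFECT_UNKNOWN = "unknown"

CODING_EFFECTS = (EFFECT_NONSYNONYMOUS, EFFECT_STOP_GAIN, EFFECT_STOP_LOSS)


@dataclass(frozen=True)
class GeneModel:
    """cDNA-coordinate gene structure: contiguous UTR5 | CDS | UTR3 spans."""

    target: str
    utr5: Tuple[int, int]
    cds: Tuple[int, int]
    utr3: Tuple[int, int]

    def __post_init__(self):
        if not (self.utr5[1] == self.cds[0] and self.cds[1] == self.utr3[0]):
            raise ValueError(f"{self.target}: spans must be contiguous")
        if (self.cds[1] - self.cds[0]) % 3 != 0:
            raise ValueError(f"{self.target}: CDS length not divisible by 3")

    @property
    def length(self) -> int:
        return self.utr3[1]

    def validate_orf(self, sequence: str) -> None:
        cds = sequence[self.cds[0] : self.cds[1]]
        if not cds.startswith("ATG"):
            raise ValueError(f"{self.target}: CDS does not start with ATG")
        if GENETIC_CODE.get(cds[-3:]) != "*":
            raise ValueError(f"{self.target}: CDS does not end with a stop codon")


@dataclass
class EffectCall:
    target: str
    position: int
    region: str  # utr5 | cds | utr3
    effect: str
    ancestral: str
    derived: str
    anc_codon: Optional[str] = None
    der_codon: Optional[str] = None
    anc_aa: Optional[str] = None
    der_aa: Optional[str] = None
    lineage: Optional[str] = None

    def __post_init__(self):
        if self.region != "cds" and self.effect not in (EFFECT_UTR, EFFECT_UNKNOWN):
            raise ValueError("non-CDS sites carry the utr effect")


def locate_region(position: int, model: GeneModel):
    """Region of a cDNA position; for CDS also (codon index, codon offset)."""
    if not (0 <= position < model.length):
        raise ValueError(f"position {position} outside cDNA of {model.target}")
    if position < model.utr5[1]:
        return "utr5", None, None
    if position < model.cds[1]:
        off = position - model.cds[0]
        return "cds", off // 3, off % 3
    return "utr3", None, None


def translate_codon(codon: str) -> Optional[str]:
    """Amino acid (``*`` for stop) or None for ambiguous bases."""
    return GENETIC_CODE.get(codon.upper())


def classify_effect(
    ancestral: str,
    derived: str,
    position: int,
    model: GeneModel,
    sequence: str,
    lineage: Optional[str] = None,
) -> EffectCall:
    """Classify a single-base change at ``position`` of the target cDNA.

    The codon context is taken from the reference sequence with the
    ancestral/derived allele substituted at the site, so the classification
    is independent of which allele the reference copy happens to carry.
    UTR sites are labelled ``utr``; a change between two stop codons leaves
    the protein unchanged and is synonymous.
    """
    if ancestral == derived:
        raise ValueError("ancestral and derived alleles must differ")
    region, codon_idx, codon_off = locate_region(position, model)
    if region != "cds":
        return EffectCall(model.target, position, region, EFFECT_UTR,
                          ancestral, derived, lineage=lineage)
    cstart = model.cds[0] + 3 * codon_idx
    context = sequence[cstart : cstart + 3]
    anc_codon = context[:codon_off] + ancestral + context[codon_off + 1 :]
    der_codon = context[:codon_off] + derived + context[codon_off + 1 :]
    anc_aa = translate_codon(anc_codon)
    der_aa = translate_codon(der_codon)
    if anc_aa is None or der_aa is None:
        log.warning("%s:%d ambiguous base in codon context", model.target, position)
        effect = EFFECT_UNKNOWN
    elif anc_aa == der_aa:
        effect = EFFECT_SYNONYMOUS
    elif der_aa == "*":
        effect = EFFECT_STOP_GAIN
    elif anc_aa == "*":
        effect = EFFECT_STOP_LOSS
    else:
        effect = EFFECT_NONSYNONYMOUS
    return EffectCall(model.target, position, region, effect, ancestral, derived,
                      anc_codon, der_codon, anc_aa, der_aa, lineage=lineage)


def density_by_region(
    effect_calls: Iterable[EffectCall],
    covered_lengths: Mapping[str, float],
) -> pd.DataFrame:
    """Mutations per covered kilobase, split by lineage and region.

    ``covered_lengths`` maps region -> covered bp; regions with zero covered
    length are omitted.
    """
    rows = []
    counts: Dict[Tuple[str, str], int] = {}
    for c in effect_calls:
        key = (c.lineage or "all", c.region)
        counts[key] = counts.get(key, 0) + 1
    lineages = sorted({k[0] for k in counts}) or ["all"]
    for lineage in lineages:
        for region, bp in covered_lengths.items():
            if bp <= 0:
                continue
            n = counts.get((lineage, region), 0)
            rows.append({"lineage": lineage, "region": region, "count": n,
                         "covered_bp": bp, "per_kb": 1000.0 * n / bp})
    return pd.DataFrame(rows)


CountsByLineage = Mapping[str, Mapping[str, int]]


def protein_change_summary(
    calls: Union[Iterable[EffectCall], CountsByLineage],
) -> Dict[str, object]:
    """Protein-coding changes (non-synonymous + stop-gain + stop-loss).

    Accepts either classified :class:`EffectCall` records or a precomputed
    ``{lineage: {effect: count}}`` table.  Reports per-lineage coding-change
    counts, the overall total, and each lineage's share of it.
    """
    if isinstance(calls, Mapping):
        counts = {lin: dict(effects) for lin, effects in calls.items()}
    else:
        counts = {}
        for c in calls:
            lin = c.lineage or "all"
            counts.setdefault(lin, {})
            counts[lin][c.effect] = counts[lin].get(c.effect, 0) + 1
    per_lineage = {
        lin: sum(effects.get(e, 0) for e in CODING_EFFECTS)
        for lin, effects in counts.items()
    }
    total = sum(per_lineage.values())
    share = {lin: (n / total if total else 0.0) for lin, n in per_lineage.items()}
    return {"per_lineage": per_lineage, "total": total, "share": share,
            "by_effect": counts}


def go_enrichment(
    gene_effects: pd.DataFrame,
    gene_to_go: Mapping[str, Iterable[str]],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-GO-term 2x2 Fisher test of non-synonymous vs synonymous changes.

    ``gene_effects`` needs columns ``gene``, ``nonsynonymous``, ``synonymous``
    (per-gene counts).  For each term the table contrasts in-group against
    out-of-group counts; two-sided Fisher exact p-values are corrected with
    Benjamini-Hochberg, and terms are labelled over-/under-represented by the
    in-group odds.  Terms with a degenerate margin are skipped with a log
    entry.
    """
    df = gene_effects.set_index("gene")
    terms: Dict[str, List[str]] = {}
    for gene, gos in gene_to_go.items():
        if gene not in df.index:
            continue
        for go in gos:
            terms.setdefault(go, []).append(gene)
    total_non = int(df["nonsynonymous"].sum())
    total_syn = int(df["synonymous"].sum())
    rows = []
    for go, genes in sorted(terms.items()):
        in_non = int(df.loc[genes, "nonsynonymous"].sum())
        in_syn = int(df.loc[genes, "synonymous"].sum())
        out_non = total_non - in_non
        out_syn = total_syn - in_syn
        table = [[in_non, in_syn], [out_non, out_syn]]
        if min(in_non + in_syn, out_non + out_syn,
               in_non + out_non, in_syn + out_syn) == 0:
            log.info("GO %s skipped: degenerate margins %s", go, table)
            continue
        _, p = fisher_exact(table, alternative="two-sided")
        in_rate = in_non / (in_non + in_syn)
        out_rate = out_non / (out_non + out_syn)
        rows.append({
            "go_term": go, "n_genes": len(genes),
            "in_nonsyn": in_non, "in_syn": in_syn,
            "out_nonsyn": out_non, "out_syn": out_syn,
            "p_value": float(p),
            "direction": ("over-represented" if in_rate > out_rate
                          else "under-represented" if in_rate < out_rate
                          else "equal"),
        })
    result = pd.DataFrame(rows)
    if result.empty:
        return result.reindex(columns=["go_term", "n_genes", "in_nonsyn", "in_syn",
                                       "out_nonsyn", "out_syn", "p_value",
                                       "direction", "fdr", "significant"])
    reject, q, _, _ = multipletests(result["p_value"], alpha=fdr, method="fdr_bh")
    result["fdr"] = q
    result["significant"] = reject
    return result


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_gene_models_tsv(path) -> Dict[str, GeneModel]:
    """Gene models from the simulator's truth table layout."""
    models = {}
    df = pd.read_csv(path, sep="\t")
    for row in df.itertuples(index=False):
        models[row.gene] = GeneModel(
            row.gene,
            (int(row.utr5_start), int(row.utr5_end)),
            (int(row.cds_start), int(row.cds_end)),
            (int(row.utr3_start), int(row.utr3_end)),
        )
    return models


def read_go_map_tsv(path) -> Dict[str, List[str]]:
    """Two-column TSV (gene, GO term), aggregated per gene."""
    out: Dict[str, List[str]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            gene, go = line.split("\t")[:2]
            out.setdefault(gene, []).append(go)
    return out


def write_effects_tsv(calls: Sequence[EffectCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("target\tposition\tregion\teffect\tancestral\tderived\t"
                 "anc_codon\tder_codon\tanc_aa\tder_aa\tlineage\n")
        for c in calls:
            fh.write(f"{c.target}\t{c.position}\t{c.region}\t{c.effect}\t"
                     f"{c.ancestral}\t{c.derived}\t{c.anc_codon or ''}\t"
                     f"{c.der_codon or ''}\t{c.anc_aa or ''}\t{c.der_aa or ''}\t"
                     f"{c.lineage or ''}\n")
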