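"""De novo mutation cataloguing from two caller call sets.

The pipeline intersects two call sets per sample, removes variants seen
in the matched ancestor, applies read-support and allele-fraction
filters that depend on the local copy number, then annotates coding
effect and promoter assignment.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from ._vcf import VARIANT_COLUMNS, classify_variant, read_vcf, write_vcf  # noqa: F401
from .genome import GenomeAnnotation, revcomp
from .karyocall import KaryotypeCall

MIN_READS = 5
AF_DUPLICATED = 0.40
AF_OTHER = 0.80
PROMOTER_MAX_DIST = 750

CATALOG_COLUMNS = VARIANT_COLUMNS + [
    "on_dup", "region", "effect", "gene", "promoter_gene", "annotatable",
]


def normalize_key(chrom: str, pos: int, ref: str, alt: str) -> tuple[str, int, str, str]:
    """Parsimony-normalized variant key (trim shared suffix, then prefix).

    Approximates left-alignment across VCF dialects without requiring the
    reference sequence; identical events written with redundant padding
    collapse to one key.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return chrom, pos, ref, alt


def _keyed(calls: pd.DataFrame) -> pd.DataFrame:
    calls = pd.DataFrame(calls).copy()
    keys = [normalize_key(r.chrom, int(r.pos), r.ref, r.alt) for r in calls.itertuples()]
    calls["vkey"] = keys
    if calls["vkey"].duplicated().any():
        dup = calls.loc[calls["vkey"].duplicated(), "vkey"].iloc[0]
        raise ValueError(f"duplicate variant key within one call set: {dup}")
    return calls


def intersect_callers(calls_a: pd.DataFrame, calls_b: pd.DataFrame) -> pd.DataFrame:
    """Consensus call set: keys present in both callers.

    Read counts (DP/AD) are taken from caller A.
    """
    a = _keyed(calls_a)
    b = _keyed(calls_b)
    out = a[a["vkey"].isin(set(b["vkey"]))].drop(columns="vkey").reset_index(drop=True)
    return out


def _segment_cn(karyotype: KaryotypeCall, chrom: str, pos1: int) -> int:
    seg = karyotype.segments
    hit = seg[(seg["chrom"] == chrom) & (seg["start"] < pos1) & (pos1 <= seg["end"])]
    if len(hit) == 0:
        return 1
    return int(hit.iloc[0]["cn"])


def filter_denovo(consensus: pd.DataFrame, ancestor_variants: pd.DataFrame,
                  karyotype: KaryotypeCall,
                  min_reads: int = MIN_READS,
                  af_dup: float = AF_DUPLICATED,
                  af_other: float = AF_OTHER) -> pd.DataFrame:
    """De novo mutations: ancestor-subtracted, read-support and AF filtered.

    A variant on a CN-2 segment of the sample's own karyotype must reach
    alt fraction >= ``af_dup``; elsewhere >= ``af_other``. Variants whose
    key occurs in the ancestor set are eliminated.
    """
    for t in (af_dup, af_other):
        if not 0.0 <= t <= 1.0:
            raise ValueError("allele-fraction thresholds must lie in [0, 1]")
    if min_reads < 0:
        raise ValueError("min_reads must be nonnegative")
    cons = _keyed(consensus)
    anc_keys = set(_keyed(ancestor_variants)["vkey"]) if len(ancestor_variants) else set()
    keep = []
    on_dup_flags = []
    for r in cons.itertuples():
        if r.vkey in anc_keys:
            continue
        dp, ad = int(r.dp), int(r.ad)
        if dp < min_reads:
            continue
        on_dup = _segment_cn(karyotype, r.chrom, int(r.pos)) == 2
        threshold = af_dup if on_dup else af_other
        if dp == 0 or ad / dp < threshold:
            continue
        keep.append(r.Index)
        on_dup_flags.append(on_dup)
    out = cons.loc[keep].drop(columns="vkey").reset_index(drop=True)
    out["on_dup"] = on_dup_flags if keep else pd.Series(dtype=bool)
    return out


def annotate_effect(mut: pd.Series, genome: GenomeAnnotation) -> pd.Series:
    """Attach region/effect to one mutation (1-based position).

    Substitutions in CDS are translated with the standard codon table:
    stop gain -> nonsense, amino-acid change -> missense, same amino acid
    -> silent. CDS indels get region 'coding' and effect 'coding_indel'
    (outside the three substitution classes). A CDS whose length is not a
    multiple of 3 marks the mutation unannotatable.
    """
    mut = mut.copy()
    pos0 = int(mut["pos"]) - 1
    g = genome.genes
    hit = g[(g["chrom"] == mut["chrom"]) & (g["start"] <= pos0) & (pos0 < g["end"])]
    mut["annotatable"] = True
    mut["gene"] = None
    mut["promoter_gene"] = None
    if len(hit) == 0:
        mut["region"] = "noncoding"
        mut["effect"] = "noncoding"
        return mut
    gene = hit.iloc[0]
    mut["region"] = "coding"
    mut["gene"] = gene["gene_id"]
    if mut["vtype"] != "substitution":
        mut["effect"] = "coding_indel"
        return mut
    cds_len = gene["end"] - gene["start"]
    if cds_len % 3 != 0:
        mut["annotatable"] = False
        mut["effect"] = "unannotatable"
        return mut
    seq = genome.seqs[mut["chrom"]][gene["start"]:gene["end"]]
    if gene["strand"] == "+":
        i = pos0 - gene["start"]
        base = mut["alt"].upper()
    else:
        seq = revcomp(seq)
        i = (gene["end"] - 1) - pos0
        base = revcomp(mut["alt"].upper())
    codon_start = (i // 3) * 3
    codon = seq[codon_start:codon_start + 3]
    new_codon = codon[: i % 3] + base + codon[i % 3 + 1:]
    old_aa = str(Seq(codon).translate())
    new_aa = str(Seq(new_codon).translate())
    if new_aa == old_aa:
        mut["effect"] = "silent"
    elif new_aa == "*":
        mut["effect"] = "nonsense"
    else:
        mut["effect"] = "missense"
    return mut


def assign_promoter(mut: pd.Series, genome: GenomeAnnotation,
                    max_dist: int = PROMOTER_MAX_DIST,
                    require_upstream: bool = True) -> pd.Series:
    """Assign a noncoding mutation to the gene with the nearest TSS.

    Eligible TSSs lie within ``max_dist`` bp; with ``require_upstream``
    the variant must sit upstream of the TSS on the gene's strand. Exact
    distance ties go to the gene with the smaller chromosome coordinate.
    """
    mut = mut.copy()
    if mut.get("region") != "noncoding":
        return mut
    pos0 = int(mut["pos"]) - 1
    g = genome.genes[genome.genes["chrom"] == mut["chrom"]]
    if len(g) == 0:
        mut["promoter_gene"] = None
        return mut
    tss = g["start"].where(g["strand"] == "+", g["end"] - 1)
    dist = (tss - pos0).abs()
    ok = dist <= max_dist
    if require_upstream:
        upstream = np.where(g["strand"] == "+", pos0 < tss, pos0 > tss)
        ok &= upstream
    cand = g[ok].assign(_dist=dist[ok])
    if len(cand) == 0:
        mut["promoter_gene"] = None
        return mut
    cand = cand.sort_values(["_dist", "start"], kind="stable")
    mut["promoter_gene"] = cand.iloc[0]["gene_id"]
    return mut


def annotate_catalogue(catalogue: pd.DataFrame, genome: GenomeAnnotation,
                       max_dist: int = PROMOTER_MAX_DIST,
                       require_upstream: bool = True) -> pd.DataFrame:
    """Apply effect and promoter annotation to every catalogued mutation."""
    rows = []
    for _, row in catalogue.iterrows():
        m = annotate_effect(row, genome)
        m = assign_promoter(m, genome, max_dist=max_dist, require_upstream=require_upstream)
        rows.append(m)
    if not rows:
        return pd.DataFrame(columns=CATALOG_COLUMNS)
    return pd.DataFrame(rows).reset_index(drop=True)


def write_catalogue_tsv(catalogue: pd.DataFrame, path) -> None:
    catalogue.to_csv(path, sep="\t", index=False)


def write_catalogue_vcf(catalogue: pd.DataFrame, path, sample: str) -> None:
    df = catalogue.copy()
    for col in ("region", "effect", "promoter_gene", "on_dup"):
        if col not in df:
            df[col] = "."
    df = df.fillna({"region": ".", "effect": ".", "promoter_gene": ".", "on_dup": "."})
    write_vcf(df, path, sample, info_cols={
        "REGION": "region", "EFFECT": "effect",
        "PROMOTER_GENE": "promoter_gene", "ON_DUP": "on_dup",
    })
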