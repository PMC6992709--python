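"""Minimal single-sample VCF reading/writing for call-set tables.

Call sets travel as plain uncompressed VCF with AD/DP FORMAT fields; the
in-memory representation is a pandas DataFrame with VARIANT_COLUMNS.
"""
from __future__ import annotations

import pandas as pd

VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "vtype", "dp", "ad"]

_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}
"""


def classify_variant(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return "substitution"
    return "insertion" if len(alt) > len(ref) else "deletion"


def write_vcf(calls: pd.DataFrame, path, sample: str, info_cols: dict[str, str] | None = None) -> None:
    """Write a call table as minimal VCF. ``info_cols`` maps INFO tag ->
    DataFrame column name for optional annotations."""
    with open(path, "w") as fh:
        if info_cols:
            for tag in info_cols:
                fh.write(f'##INFO=<ID={tag},Number=1,Type=String,Description="{tag}">\n')
        fh.write(_HEADER.format(sample=sample))
        for r in calls.itertuples():
            info = "."
            if info_cols:
                parts = [f"{tag}={getattr(r, col)}" for tag, col in info_cols.items()]
                info = ";".join(parts)
            ad = f"{int(r.dp) - int(r.ad)},{int(r.ad)}"
            fh.write(
                f"{r.chrom}\t{int(r.pos)}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\tDP:AD\t{int(r.dp)}:{ad}\n"
            )


def read_vcf(path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            chrom, pos, _id, ref, alt = fields[:5]
            dp, ad = 0, 0
            if len(fields) >= 10:
                fmt = fields[8].split(":")
                vals = fields[9].split(":")
                d = dict(zip(fmt, vals))
                dp = int(d.get("DP", 0))
                if "AD" in d:
                    ad = int(d["AD"].split(",")[-1])
            rows.append((chrom, int(pos), ref, alt, classify_variant(ref, alt), dp, ad))
    return pd.DataFrame(rows, columns=VARIANT_COLUMNS)
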