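"""Copy-number and karyotype inference from windowed read coverage.

Coverage is compared to a euploid reference sample, log2 ratios are
segmented by recursive binary splitting, and segments are called at copy
number 1 or 2. Chromosome status and change events relative to an
ancestor call are derived from segment geometry alone.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: linear-ratio threshold separating copy number 1 from 2 (midpoint rule)
CN_THRESHOLD = 1.5
#: fraction of chromosome length at CN 2 required to call a whole disome
STATUS_FRACTION = 0.95

WINDOW_COLUMNS = ["chrom", "start", "end", "count"]
SEGMENT_COLUMNS = ["chrom", "start", "end", "mean_ratio", "cn"]


@dataclass
class CoverageProfile:
    """Windowed read counts for one sample."""

    sample: str
    windows: pd.DataFrame  # chrom, start, end, count

    def __post_init__(self) -> None:
        self.windows = pd.DataFrame(self.windows, columns=WINDOW_COLUMNS).reset_index(drop=True)
        if (self.windows["count"] < 0).any():
            raise ValueError("window counts must be nonnegative")
        for _, g in self.windows.groupby("chrom", sort=False):
            starts = g["start"].to_numpy()
            ends = g["end"].to_numpy()
            if not (np.diff(starts) > 0).all() or not (ends > starts).all():
                raise ValueError("windows must be sorted and non-overlapping")
            if len(g) > 1 and not (starts[1:] == ends[:-1]).all():
                raise ValueError("windows must tile each chromosome")

    @property
    def total_reads(self) -> int:
        return int(self.windows["count"].sum())

    def write_bedgraph(self, path) -> None:
        self.windows.to_csv(path, sep="\t", header=False, index=False)

    @classmethod
    def read_bedgraph(cls, path, sample: str) -> "CoverageProfile":
        win = pd.read_csv(path, sep="\t", header=None, names=WINDOW_COLUMNS,
                          dtype={"chrom": str})
        return cls(sample=sample, windows=win)


@dataclass
class RatioTrack:
    """Per-window coverage ratio of a sample to the euploid reference."""

    sample: str
    windows: pd.DataFrame  # chrom, start, end, ratio, log2_ratio, masked

    def chrom_values(self, chrom: str, include_masked: bool = False) -> pd.DataFrame:
        g = self.windows[self.windows["chrom"] == chrom]
        if not include_masked:
            g = g[~g["masked"]]
        return g


@dataclass
class KaryotypeCall:
    """Per-chromosome copy-number status derived from segments."""

    sample: str
    segments: pd.DataFrame  # chrom, start, end, mean_ratio, cn
    status: dict[str, str]  # chrom -> euploid | disomic | partial
    metadata: dict = field(default_factory=dict)

    def cn2_fraction(self, chrom: str) -> float:
        seg = self.segments[self.segments["chrom"] == chrom]
        total = (seg["end"] - seg["start"]).sum()
        if total == 0:
            return 0.0
        dup = seg.loc[seg["cn"] == 2, "end"].sub(seg.loc[seg["cn"] == 2, "start"]).sum()
        return float(dup) / float(total)

    def to_json(self, path) -> None:
        doc = {
            "sample": self.sample,
            "status": self.status,
            "segments": self.segments.to_dict(orient="records"),
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "KaryotypeCall":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            sample=doc["sample"],
            segments=pd.DataFrame(doc["segments"], columns=SEGMENT_COLUMNS),
            status=doc["status"],
            metadata=doc.get("metadata", {}),
        )


def normalize_coverage(sample: CoverageProfile, wt: CoverageProfile,
                       masked_regions: list[tuple[str, int, int]] | None = None) -> RatioTrack:
    """Library-size-normalized per-window ratio of ``sample`` to ``wt``.

    ratio(w) = (c_s(w)/T_s) / (c_wt(w)/T_wt). Windows where the reference
    count is zero (or falling in a masked region) are flagged and excluded
    from downstream segmentation.
    """
    s, w = sample.windows, wt.windows
    if len(s) != len(w) or not (
        (s["chrom"].values == w["chrom"].values).all()
        and (s["start"].values == w["start"].values).all()
        and (s["end"].values == w["end"].values).all()
    ):
        raise ValueError("sample and reference window grids differ")
    t_s, t_w = sample.total_reads, wt.total_reads
    if t_s == 0:
        raise ValueError("sample has no mapped reads")
    wt_counts = w["count"].to_numpy(dtype=float)
    nonzero = wt_counts > 0
    if nonzero.mean() < 0.99:
        raise ValueError("reference coverage is zero in more than 1% of windows")
    ratio = np.full(len(s), np.nan)
    ratio[nonzero] = (s["count"].to_numpy(dtype=float)[nonzero] / t_s) / (
        wt_counts[nonzero] / t_w
    )
    masked = ~nonzero
    if masked_regions:
        for chrom, start, end in masked_regions:
            hit = (s["chrom"] == chrom) & (s["start"] < end) & (s["end"] > start)
            masked |= hit.to_numpy()
    out = s[["chrom", "start", "end"]].copy()
    out["ratio"] = ratio
    with np.errstate(divide="ignore"):
        out["log2_ratio"] = np.log2(np.maximum(ratio, 2.0 ** -16))
    out["masked"] = masked
    return RatioTrack(sample=sample.sample, windows=out)


def _single_split(x: np.ndarray) -> tuple[float, int]:
    """Best single split of ``x``: (SSE reduction, split index).

    The split index i partitions x into x[:i] and x[i:]; the first index
    achieving the maximal reduction is returned (deterministic).
    """
    n = len(x)
    csum = np.cumsum(x)
    csq = np.cumsum(x * x)
    sse_total = csq[-1] - csum[-1] ** 2 / n
    i = np.arange(1, n)
    sse_l = csq[i - 1] - csum[i - 1] ** 2 / i
    rs = csum[-1] - csum[i - 1]
    rq = csq[-1] - csq[i - 1]
    sse_r = rq - rs ** 2 / (n - i)
    gain = sse_total - (sse_l + sse_r)
    k = int(np.argmax(gain))
    return float(gain[k]), int(i[k])


def _binary_segment(x: np.ndarray, penalty: float, sigma2: float) -> list[int]:
    """Recursive binary segmentation; returns sorted interior breakpoints.

    A split is kept when its SSE reduction exceeds the BIC-style
    threshold penalty * sigma2 * log(n); log(n) matches the null scaling
    of the maximum spurious gain over n windows.
    """
    breaks: list[int] = []
    threshold = penalty * sigma2 * np.log(max(len(x), 2))

    def recurse(lo: int, hi: int) -> None:
        if hi - lo < 2:
            return
        gain, k = _single_split(x[lo:hi])
        if gain > threshold and gain > 0:
            breaks.append(lo + k)
            recurse(lo, lo + k)
            recurse(lo + k, hi)

    recurse(0, len(x))
    return sorted(breaks)


def segment_ratio(track: RatioTrack, penalty: float = 10.0) -> pd.DataFrame:
    """Segment the log2 ratio track into candidate copy-number segments.

    Splits are accepted when the within-segment SSE reduction exceeds
    ``penalty`` times a robust noise-variance estimate (median absolute
    successive difference). Adjacent segments with equal called CN are
    merged. Returns a DataFrame with SEGMENT_COLUMNS.
    """
    if penalty <= 0:
        raise ValueError("penalty must be positive")
    segs = []
    for chrom in track.windows["chrom"].unique():
        g = track.chrom_values(chrom)
        if len(g) < 2:
            raise ValueError(f"chromosome {chrom} has fewer than 2 usable windows")
        x = g["log2_ratio"].to_numpy()
        d = np.diff(x)
        sigma = 1.4826 * np.median(np.abs(d)) / np.sqrt(2.0)
        sigma2 = sigma * sigma
        breaks = _binary_segment(x, penalty, sigma2)
        starts_w = [0] + breaks
        ends_w = breaks + [len(x)]
        chrom_end = int(track.windows.loc[track.windows["chrom"] == chrom, "end"].max())
        g_start = g["start"].to_numpy()
        for j, (a, b) in enumerate(zip(starts_w, ends_w)):
            seg_start = 0 if j == 0 else int(g_start[a])
            seg_end = chrom_end if j == len(starts_w) - 1 else int(g_start[b])
            mean_ratio = float(g["ratio"].to_numpy()[a:b].mean())
            cn = 2 if mean_ratio >= CN_THRESHOLD else 1
            segs.append((chrom, seg_start, seg_end, mean_ratio, cn))
    df = pd.DataFrame(segs, columns=SEGMENT_COLUMNS)
    return _merge_equal_cn(df)


def _merge_equal_cn(segments: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for chrom, g in segments.groupby("chrom", sort=False):
        cur = None
        for _, s in g.iterrows():
            if cur is not None and cur["cn"] == s["cn"]:
                w1 = cur["end"] - cur["start"]
                w2 = s["end"] - s["start"]
                cur["mean_ratio"] = (cur["mean_ratio"] * w1 + s["mean_ratio"] * w2) / (w1 + w2)
                cur["end"] = s["end"]
            else:
                if cur is not None:
                    rows.append(cur)
                cur = s.to_dict()
        rows.append(cur)
    return pd.DataFrame(rows, columns=SEGMENT_COLUMNS)


def _status_from_segments(segments: pd.DataFrame, chrom_lengths: dict[str, int] | None = None
                          ) -> dict[str, str]:
    status = {}
    for chrom, g in segments.groupby("chrom", sort=False):
        total = float((g["end"] - g["start"]).sum())
        dup = float((g.loc[g["cn"] == 2, "end"] - g.loc[g["cn"] == 2, "start"]).sum())
        frac = dup / total if total else 0.0
        if frac >= STATUS_FRACTION:
            status[chrom] = "disomic"
        elif frac <= 1.0 - STATUS_FRACTION:
            status[chrom] = "euploid"
        else:
            status[chrom] = "partial"
    return status


def call_karyotype(segments: pd.DataFrame, ancestor: KaryotypeCall | None = None,
                   sample: str = "sample") -> tuple[KaryotypeCall, pd.DataFrame]:
    """Karyotype status per chromosome plus change events vs an ancestor.

    Change labels: ``retained``, ``whole_loss``, ``partial_loss``,
    ``segmental_amplification``. With no ancestor the change table is
    empty. The 95% length-fraction rule used for chromosome status is
    recorded in the call metadata.
    """
    segments = pd.DataFrame(segments, columns=SEGMENT_COLUMNS)
    status = _status_from_segments(segments)
    call = KaryotypeCall(
        sample=sample,
        segments=segments,
        status=status,
        metadata={"cn_threshold": CN_THRESHOLD, "status_fraction": STATUS_FRACTION},
    )
    changes = []
    if ancestor is not None:
        for chrom in segments["chrom"].unique():
            anc_frac = ancestor.cn2_fraction(chrom)
            evo_frac = call.cn2_fraction(chrom)
            seg = segments[segments["chrom"] == chrom]
            cn1 = seg[seg["cn"] == 1]
            cn2 = seg[seg["cn"] == 2]
            if anc_frac >= STATUS_FRACTION:
                if evo_frac >= STATUS_FRACTION:
                    label, bps = "retained", []
                elif evo_frac <= 1.0 - STATUS_FRACTION:
                    label, bps = "whole_loss", []
                else:
                    label = "partial_loss"
                    bps = [(int(r.start), int(r.end)) for r in cn1.itertuples()]
            else:
                if evo_frac <= 1.0 - STATUS_FRACTION:
                    label, bps = "retained", []
                elif evo_frac >= STATUS_FRACTION:
                    label = "segmental_amplification"  # whole-chromosome gain
                    bps = []
                else:
                    label = "segmental_amplification"
                    bps = [(int(r.start), int(r.end)) for r in cn2.itertuples()]
            changes.append({"chrom": chrom, "change": label, "breakpoints": bps})
    return call, pd.DataFrame(changes, columns=["chrom", "change", "breakpoints"])


def gene_ratio(track: RatioTrack, genes: pd.DataFrame) -> pd.Series:
    """Per-gene coverage ratio: window ratios averaged weighted by overlap."""
    out = {}
    win = track.windows[~track.windows["masked"]]
    for _, g in genes.iterrows():
        w = win[(win["chrom"] == g.chrom) & (win["start"] < g.end) & (win["end"] > g.start)]
        if len(w) == 0:
            out[g.gene_id] = np.nan
            continue
        overlap = np.minimum(w["end"], g.end) - np.maximum(w["start"], g.start)
        out[g.gene_id] = float(np.average(w["ratio"], weights=overlap))
    return pd.Series(out, name=track.sample)


def write_segments_bed(segments: pd.DataFrame, path) -> None:
    """Segments as BED: chrom, start, end, name(mean ratio), score=CN."""
    with open(path, "w") as fh:
        for r in segments.itertuples():
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.mean_ratio:.4f}\t{r.cn}\n")
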