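"""Expression pipeline: CPM filtering, RLE normalization, dosage medians,
the distance/shift-towards-reference statistic, linear-model differential
expression and gene-set enrichment."""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mutstats import bh_adjust

FC_THRESHOLD = 1.5
FDR_LEVEL = 0.1


@dataclass
class ExpressionMatrix:
    """Raw gene x sample counts plus sample metadata.

    ``meta`` columns: sample, strain, role (WT | ancestor | evolved),
    dup_chrom, ancestor (sample id of the matched ancestor; WT/ancestor
    rows may be empty).
    """

    counts: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = set(self.counts.columns) - set(self.meta["sample"])
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")

    def library_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def write_tsv(self, counts_path, meta_path=None) -> None:
        self.counts.to_csv(counts_path, sep="\t", index_label="gene")
        if meta_path is not None:
            self.meta.to_csv(meta_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, counts_path, meta_path) -> "ExpressionMatrix":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        meta = pd.read_csv(meta_path, sep="\t")
        return cls(counts=counts, meta=meta)


@dataclass
class NormalizedMatrix:
    """Size-factor normalized expression: linear and log2 (pseudocount 1)."""

    linear: pd.DataFrame
    log2: pd.DataFrame
    size_factors: pd.Series
    meta: pd.DataFrame


@dataclass
class ShiftResult:
    sample: str
    ancestor: str
    gene_set: list[str]
    d_anc: float
    d_evo: float
    normalized_distance: float
    shift: float
    defined: bool = True
    metadata: dict = field(default_factory=dict)


def filter_cpm(matrix: ExpressionMatrix, min_cpm: float = 1.0,
               min_fraction: float = 0.5) -> ExpressionMatrix:
    """Keep genes with >= min_cpm in at least ceil(min_fraction * n)
    samples ('at least half' is inclusive)."""
    if matrix.counts.empty:
        raise ValueError("empty expression matrix")
    lib = matrix.library_sizes()
    if (lib <= 0).any():
        raise ValueError("all samples need positive library sizes")
    cpm = matrix.counts.div(lib, axis=1) * 1e6
    need = math.ceil(min_fraction * matrix.counts.shape[1])
    keep = (cpm >= min_cpm).sum(axis=1) >= need
    return ExpressionMatrix(counts=matrix.counts[keep], meta=matrix.meta)


def rle_normalize(matrix: ExpressionMatrix, pseudocount: float = 1.0) -> NormalizedMatrix:
    """Relative-log-expression size factors (median ratio to per-gene
    geometric means over genes expressed in all samples)."""
    counts = matrix.counts
    if counts.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    nonzero = (counts > 0).all(axis=1)
    if not nonzero.any():
        raise ValueError("no gene with nonzero counts in all samples")
    ref = counts[nonzero]
    log_geomean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref).sub(log_geomean, axis=0), axis=0))
    factors = pd.Series(factors, index=counts.columns, name="size_factor")
    linear = counts.div(factors, axis=1)
    log2 = np.log2(linear + pseudocount)
    return NormalizedMatrix(linear=linear, log2=log2, size_factors=factors,
                            meta=matrix.meta)


def chromosome_dosage(norm: NormalizedMatrix, gene_chroms: pd.Series,
                      disome_chrom: str, sample: str, wt_sample: str,
                      min_genes: int = 10) -> float:
    """Median linear-scale ratio sample/WT over the genes of one chromosome."""
    genes = gene_chroms[gene_chroms == disome_chrom].index
    genes = [g for g in genes if g in norm.linear.index]
    if len(genes) < min_genes:
        raise ValueError(f"fewer than {min_genes} genes on {disome_chrom}")
    s = norm.linear.loc[genes, sample]
    w = norm.linear.loc[genes, wt_sample]
    ok = w > 0
    if ok.sum() < min_genes:
        raise ValueError("too few genes with nonzero reference expression")
    return float((s[ok] / w[ok]).median())


def expression_shift(norm: NormalizedMatrix, evolved: str, ancestor: str,
                     wt: str, fc_threshold: float = FC_THRESHOLD) -> ShiftResult:
    """Shift towards the reference transcriptome.

    Gene set G: |log2(anc) - log2(WT)| >= log2(fc_threshold). Distances
    are Euclidean in log2 space over G; shift = 1 - D_evo/D_anc.
    """
    log2 = norm.log2
    dev_anc = log2[ancestor] - log2[wt]
    gene_set = log2.index[dev_anc.abs() >= np.log2(fc_threshold)]
    if len(gene_set) == 0:
        return ShiftResult(sample=evolved, ancestor=ancestor, gene_set=[],
                           d_anc=0.0, d_evo=0.0, normalized_distance=np.nan,
                           shift=np.nan, defined=False)
    d_anc = float(np.sqrt((dev_anc[gene_set] ** 2).sum()))
    dev_evo = log2.loc[gene_set, evolved] - log2.loc[gene_set, wt]
    d_evo = float(np.sqrt((dev_evo ** 2).sum()))
    nd = d_evo / d_anc
    return ShiftResult(sample=evolved, ancestor=ancestor,
                       gene_set=list(gene_set), d_anc=d_anc, d_evo=d_evo,
                       normalized_distance=nd, shift=1.0 - nd,
                       metadata={"fc_threshold": fc_threshold})


def shift_from_log_columns(wt: np.ndarray, anc: np.ndarray, evo: np.ndarray,
                           fc_threshold: float = FC_THRESHOLD) -> ShiftResult:
    """Shift computed directly from three log2 expression vectors."""
    idx = pd.Index([f"g{i}" for i in range(len(wt))])
    log2 = pd.DataFrame({"WT": wt, "anc": anc, "evo": evo}, index=idx)
    norm = NormalizedMatrix(linear=2.0 ** log2, log2=log2,
                            size_factors=pd.Series(1.0, index=log2.columns),
                            meta=pd.DataFrame({"sample": log2.columns}))
    return expression_shift(norm, "evo", "anc", "WT", fc_threshold=fc_threshold)


def _linear_model_tests(Y: np.ndarray, X: np.ndarray, coef_idx: int
                        ) -> tuple[np.ndarray, np.ndarray, int]:
    """Per-gene OLS of Y (samples x genes) on shared design X; t test on
    one coefficient. Genes with zero residual variance get NaN p."""
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    df = n - rank
    if df <= 0:
        raise ValueError("zero residual degrees of freedom")
    xtx_inv = np.linalg.pinv(X.T @ X)
    B = xtx_inv @ X.T @ Y
    resid = Y - X @ B
    s2 = (resid ** 2).sum(axis=0) / df
    # distinguish constant genes (undefined test, NaN) from exact fits
    # (machine-limited p -> 0); both leave only float residue in s2
    scale = (Y ** 2).mean(axis=0) + 1e-300
    zero_var = Y.var(axis=0) < 1e-14 * scale
    exact_fit = (s2 < 1e-14 * scale) & ~zero_var
    s2 = np.where(s2 < 1e-14 * scale, 0.0, s2)
    var_coef = s2 * xtx_inv[coef_idx, coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_coef > 0, B[coef_idx] / np.sqrt(var_coef), np.nan)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    pvals[~np.isfinite(t)] = np.nan
    pvals[exact_fit & (np.abs(B[coef_idx]) > 0)] = 0.0
    pvals[zero_var] = np.nan
    return B[coef_idx], pvals, df


def common_de(norm: NormalizedMatrix, include_strain_covariate: bool = True,
              fdr: float = FDR_LEVEL) -> pd.DataFrame:
    """Evolved-vs-ancestor differential expression with a shared model.

    Fits per gene: log2 expression ~ evolved indicator (+ strain block by
    default, so contrasts are within strain). Returns gene, log2fc, p, q,
    significant. Constant genes get NaN p and are excluded from BH.
    """
    meta = norm.meta
    used = meta[meta["role"].isin(["ancestor", "evolved"])]
    samples = list(used["sample"])
    roles = used.set_index("sample")["role"]
    if (roles == "evolved").sum() < 2 or (roles == "ancestor").sum() < 2:
        raise ValueError("need >= 2 samples per level")
    evolved = (roles.loc[samples] == "evolved").to_numpy(dtype=float)
    cols = [evolved]
    if include_strain_covariate:
        strains = used.set_index("sample")["strain"].loc[samples]
        for s in strains.unique():
            cols.append((strains == s).to_numpy(dtype=float))
    else:
        cols.append(np.ones(len(samples)))
    X = np.column_stack(cols)
    Y = norm.log2[samples].to_numpy()
    coef, pvals, _ = _linear_model_tests(Y.T, X, coef_idx=0)
    q = bh_adjust(pvals)
    return pd.DataFrame({
        "gene": norm.log2.index,
        "log2fc": coef,
        "p": pvals,
        "q": q,
        "significant": q <= fdr,
    }).set_index("gene")


def shift_association(norm: NormalizedMatrix, shifts: pd.Series,
                      fdr: float = FDR_LEVEL) -> pd.DataFrame:
    """Regression of evolved-line expression on the numeric shift value.

    ``shifts`` indexes evolved sample ids; returns per gene the slope,
    p, BH q and direction of association.
    """
    shifts = shifts.dropna()
    if len(shifts) < 4:
        raise ValueError("need >= 4 evolved lines with defined shift")
    if float(np.var(shifts)) == 0.0:
        raise ValueError("shift covariate is constant")
    samples = list(shifts.index)
    X = np.column_stack([shifts.to_numpy(dtype=float), np.ones(len(samples))])
    Y = norm.log2[samples].to_numpy()
    slope, pvals, _ = _linear_model_tests(Y.T, X, coef_idx=0)
    q = bh_adjust(pvals)
    return pd.DataFrame({
        "gene": norm.log2.index,
        "slope": slope,
        "p": pvals,
        "q": q,
        "significant": q <= fdr,
        "direction": np.where(slope > 0, "positive", "negative"),
    }).set_index("gene")


def set_enrichment(selected: set, universe: set,
                   annotation_sets: dict[str, set]) -> pd.DataFrame:
    """One-sided hypergeometric over-representation tests with BH."""
    if not universe:
        raise ValueError("empty universe")
    selected = set(selected) & set(universe)
    rows = []
    for name, genes in annotation_sets.items():
        in_universe = set(genes) & set(universe)
        k = len(selected & in_universe)
        # P(X >= k), X ~ Hypergeom(N=|universe|, K=|set|, n=|selected|)
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(in_universe), len(selected)))
        rows.append({"set": name, "overlap": k, "set_size": len(in_universe),
                     "selected": len(selected), "universe": len(universe), "p": p})
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["non_informative"] = selected == set(universe)
    return out


def read_gmt(path) -> dict[str, set]:
    sets: dict[str, set] = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) >= 3:
                sets[parts[0]] = set(g for g in parts[2:] if g)
    return sets
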