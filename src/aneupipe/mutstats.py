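"""Mutation rate, spectrum and localization statistics.

Apparent rates follow u = m/(n*g) with standard error sqrt(u/(n*g)).
Type-specific rates are composition-normalized by the genomic AT/GC
fractions; spectra use strand-collapsed (pyrimidine-reference) classes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeAnnotation, revcomp

#: default reference genome length (bp); calibrated so the packaged
#: per-strain counts reproduce the worked-example rates; configurable.
DEFAULT_GENOME_LENGTH = 1.212e7
DEFAULT_GENERATIONS = 1200
DEFAULT_CODING_P0 = 0.74

#: strand-collapsed substitution classes (pyrimidine reference base)
SIX_CLASSES = ["C:G>T:A", "C:G>A:T", "C:G>G:C", "T:A>C:G", "T:A>A:T", "T:A>G:C"]

_PYR = {"C", "T"}
_CLASS_OF = {
    ("C", "T"): "C:G>T:A", ("G", "A"): "C:G>T:A",
    ("C", "A"): "C:G>A:T", ("G", "T"): "C:G>A:T",
    ("C", "G"): "C:G>G:C", ("G", "C"): "C:G>G:C",
    ("T", "C"): "T:A>C:G", ("A", "G"): "T:A>C:G",
    ("T", "A"): "T:A>A:T", ("A", "T"): "T:A>A:T",
    ("T", "G"): "T:A>G:C", ("A", "C"): "T:A>G:C",
}

#: COSMIC channel order: 6 pyrimidine substitutions x 16 flank contexts
SUB_TYPES_96 = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
CHANNELS_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUB_TYPES_96
    for five in "ACGT"
    for three in "ACGT"
]


@dataclass
class RateEstimate:
    m: float
    n: float
    g: float
    u: float
    se: float


def apparent_rate(m: float, n: float = DEFAULT_GENOME_LENGTH,
                  g: float = DEFAULT_GENERATIONS) -> RateEstimate:
    """Apparent mutation rate u = m/(n*g), se = sqrt(u/(n*g))."""
    if m < 0:
        raise ValueError("mutation count must be nonnegative")
    if n <= 0 or g <= 0:
        raise ValueError("genome length and generations must be positive")
    u = m / (n * g)
    se = float(np.sqrt(u / (n * g)))
    return RateEstimate(m=m, n=n, g=g, u=u, se=se)


def substitution_class(ref: str, alt: str) -> str:
    try:
        return _CLASS_OF[(ref.upper(), alt.upper())]
    except KeyError:
        raise ValueError(f"not a single-base substitution: {ref}>{alt}") from None


def spectrum_counts(mutations: pd.DataFrame) -> pd.Series:
    """Counts per strand-collapsed class for the substitutions in a catalogue."""
    counts = pd.Series(0, index=SIX_CLASSES, dtype=int)
    subs = mutations[mutations["vtype"] == "substitution"]
    for r in subs.itertuples():
        counts[substitution_class(r.ref, r.alt)] += 1
    return counts


def per_type_rates(mutations: pd.DataFrame, genome: GenomeAnnotation | None = None,
                   g: float = DEFAULT_GENERATIONS, n: float | None = None,
                   f_gc: float | None = None) -> pd.Series:
    """Composition-normalized class rates m_class / (n * f * g).

    f is the genomic GC fraction for C:G-origin classes and the AT
    fraction for T:A-origin classes.
    """
    if genome is not None:
        n = n if n is not None else genome.genome_length
        f_gc = f_gc if f_gc is not None else genome.f_gc
    if n is None or f_gc is None:
        raise ValueError("need a genome annotation or explicit n and f_gc")
    if not 0.0 <= f_gc <= 1.0:
        raise ValueError("GC fraction must lie in [0, 1]")
    f_at = 1.0 - f_gc
    if abs(f_at + f_gc - 1.0) > 1e-9:
        raise ValueError("AT and GC fractions must sum to 1")
    counts = spectrum_counts(mutations)
    rates = {}
    for cls, m in counts.items():
        f = f_gc if cls.startswith("C:G") else f_at
        rates[cls] = m / (n * f * g) if f > 0 else np.nan
    return pd.Series(rates, name="rate")


def binomial_two_sided(successes: int, trials: int, p0: float,
                       method: str = "double_tail") -> float:
    """Two-sided exact binomial p-value.

    ``double_tail`` doubles the smaller exact tail and caps at 1;
    ``minlike`` sums all outcomes with probability <= the observed one
    (scipy's default two-sided definition).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("null probability must lie in (0, 1)")
    if trials < 1 or not 0 <= successes <= trials:
        raise ValueError("invalid successes/trials")
    if method == "minlike":
        return float(stats.binomtest(successes, trials, p0).pvalue)
    lower = float(stats.binom.cdf(successes, trials, p0))
    upper = float(stats.binom.sf(successes - 1, trials, p0))
    return min(1.0, 2.0 * min(lower, upper))


def localization_test(counts: pd.DataFrame, method: str = "double_tail") -> pd.DataFrame:
    """Binomial localization tests with BH adjustment across one family.

    ``counts`` needs columns ``strain, successes, trials, p0``. Returns
    the table with two-sided ``p`` and BH-adjusted ``q`` appended.
    """
    counts = pd.DataFrame(counts).copy()
    pvals = [
        binomial_two_sided(int(r.successes), int(r.trials), float(r.p0), method=method)
        for r in counts.itertuples()
    ]
    counts["p"] = pvals
    counts["q"] = bh_adjust(np.asarray(pvals))
    return counts


def chromosome_p0(chrom_lengths: dict[str, int], dup_chrom: str,
                  double_duplicated: bool = False) -> float:
    """Null probability for duplicated-chromosome localization.

    By default the single-copy chromosome lengths are used; with
    ``double_duplicated`` the extra copy contributes to both numerator
    and denominator.
    """
    total = sum(chrom_lengths.values())
    dup = chrom_lengths[dup_chrom]
    if double_duplicated:
        return 2 * dup / (total + dup)
    return dup / total


def bh_adjust(pvals: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values; NaNs are left out of the family."""
    pvals = np.asarray(pvals, dtype=float)
    out = np.full(pvals.shape, np.nan)
    ok = ~np.isnan(pvals)
    if ok.sum():
        out[ok] = multipletests(pvals[ok], method="fdr_bh")[1]
    return out


def _pyrimidine_context(ref: str, alt: str, context: str) -> tuple[str, str, str]:
    if ref.upper() not in _PYR:
        return revcomp(ref), revcomp(alt), revcomp(context)
    return ref.upper(), alt.upper(), context.upper()


def genome_trinucleotide_freqs(genome: GenomeAnnotation) -> pd.Series:
    """Pyrimidine-collapsed trinucleotide frequencies of the genome."""
    if genome.seqs is None:
        raise ValueError("spectrum normalization requires genome sequence")
    counts: dict[str, int] = {}
    for seq in genome.seqs.values():
        for i in range(len(seq) - 2):
            tri = seq[i:i + 3]
            if tri[1] not in _PYR:
                tri = revcomp(tri)
            counts[tri] = counts.get(tri, 0) + 1
    total = sum(counts.values())
    return pd.Series({k: v / total for k, v in counts.items()})


def spectrum96(mutations: pd.DataFrame, genome: GenomeAnnotation,
               normalize_by_context: bool = True) -> pd.Series:
    """96-channel pyrimidine-centred spectrum, context-normalized, sum 1."""
    subs = mutations[mutations["vtype"] == "substitution"]
    if len(subs) == 0:
        raise ValueError("empty mutation set")
    if genome.seqs is None:
        raise ValueError("spectrum96 requires genome sequence")
    counts = pd.Series(0.0, index=CHANNELS_96)
    for r in subs.itertuples():
        pos0 = int(r.pos) - 1
        seq = genome.seqs[r.chrom]
        if pos0 < 1 or pos0 >= len(seq) - 1:
            continue  # no flanking context at chromosome ends
        context = seq[pos0 - 1:pos0 + 2]
        ref, alt, context = _pyrimidine_context(r.ref, r.alt, context)
        channel = f"{context[0]}[{ref}>{alt}]{context[2]}"
        counts[channel] += 1
    if normalize_by_context:
        freqs = genome_trinucleotide_freqs(genome)
        for ch in CHANNELS_96:
            tri = ch[0] + ch[2] + ch[-1]
            f = freqs.get(tri, np.nan)
            counts[ch] = counts[ch] / f if f and f > 0 else 0.0
    total = counts.sum()
    if total <= 0:
        raise ValueError("no context-resolvable substitutions")
    return counts / total


def signature_similarity(spectrum: pd.Series, signatures: pd.DataFrame) -> pd.Series:
    """Cosine similarity of a spectrum to each reference signature, sorted
    descending. Channel order must match."""
    v = np.asarray(spectrum, dtype=float)
    if np.linalg.norm(v) == 0:
        raise ValueError("zero-norm spectrum")
    sims = {}
    for name in signatures.columns:
        s = signatures[name].to_numpy(dtype=float)
        ns = np.linalg.norm(s)
        if ns == 0:
            raise ValueError(f"zero-norm signature {name}")
        sims[name] = float(v @ s / (np.linalg.norm(v) * ns))
    return pd.Series(sims).sort_values(ascending=False)


def read_signature_matrix(path) -> pd.DataFrame:
    """Signature matrix TSV: 96 rows (channel labels in first column) x k
    signature columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if len(df) != 96:
        raise ValueError("signature matrix must have 96 channel rows")
    return df


def count_length_correlation(mean_counts, lengths) -> tuple[float, float]:
    """Pearson correlation of per-strain mean counts with duplicated-
    chromosome lengths; two-sided p from the t transform (n-2 df)."""
    x = np.asarray(mean_counts, dtype=float)
    y = np.asarray(lengths, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 strains")
    if np.var(x) == 0 or np.var(y) == 0:
        raise ValueError("zero variance in input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
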