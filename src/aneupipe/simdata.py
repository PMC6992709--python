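"""Synthetic disome-evolution experiments with ground truth.

Generates a genome annotation, per-line karyotypes and de novo mutation
sets, windowed coverage, two-caller variant observations, expression
counts and growth curves, all with the statistical structure the
analysis modules assume. Every draw is keyed to ``SimConfig.seed`` so
identical configs give byte-identical outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import GenomeAnnotation, GENE_COLUMNS, random_sequence
from .karyocall import CoverageProfile
from ._vcf import VARIANT_COLUMNS, classify_variant
from .exprshift import ExpressionMatrix
from .growthfit import GrowthCurve

_BASES = np.array(["A", "C", "G", "T"])

# stream tags so each operation draws from an independent substream
_STREAMS = {"genome": 0, "lineages": 1, "coverage": 2, "variants": 3,
            "expression": 4, "growth": 5}


def _rng(config: "SimConfig", stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(
        entropy=config.seed, spawn_key=(_STREAMS[stream],)))


@dataclass
class SimConfig:
    """Parameters of a simulated evolution experiment.

    Defaults are scaled down (~1.2 Mb genome) so demo pipelines and tests
    run in seconds; rates and design mirror a 12-disome, 3-line,
    1200-generation serial-dilution experiment.
    """

    n_chromosomes: int = 6
    chrom_lengths: tuple[int, ...] = (120_000, 240_000, 180_000, 300_000,
                                      150_000, 210_000)
    coding_fraction: float = 0.74
    gc_fraction: float = 0.38
    n_disomes: int = 4
    lines_per_strain: int = 3
    generations: int = 1200
    lambda_sub: float = 7.9
    lambda_ind: float = 3.75
    dup_bias: float = 3.0
    dosage_factor: float = 1.8
    attenuation: float | tuple[float, float] = (0.1, 0.9)
    karyotype_event_probs: dict[str, float] = field(default_factory=lambda: {
        "whole_loss": 0.05, "partial_loss": 0.05, "segmental_amplification": 0.05})
    depth: float = 50.0
    window_size: int = 100
    nb_dispersion: float = 0.05
    af_noise: float = 0.02
    fp_per_caller: float = 2.0
    n_background: int = 20
    expr_mean: float = 500.0
    expr_log_sd: float = 1.0
    expr_dispersion: float = 0.01
    n_shift_genes: int = 0
    shift_gene_slope: float = 1.5
    libsize_range: tuple[float, float] = (0.8, 1.25)
    base_doubling: float = 90.0
    disome_slowdown: float = 1.5
    growth_hours: float = 24.0
    od_noise: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.chrom_lengths = tuple(int(x) for x in self.chrom_lengths)
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ValueError("chrom_lengths must have n_chromosomes entries")
        for frac in (self.coding_fraction, self.gc_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(n <= 0 for n in self.chrom_lengths):
            raise ValueError("chromosome lengths must be positive")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.dup_bias < 0:
            raise ValueError("dup_bias must be nonnegative")
        if self.dosage_factor <= 0:
            raise ValueError("dosage_factor must be positive")
        if self.n_disomes > self.n_chromosomes:
            raise ValueError("cannot have more disomes than chromosomes")
        if sum(self.karyotype_event_probs.values()) > 1.0 + 1e-12:
            raise ValueError("karyotype event probabilities must sum to <= 1")
        a = self.attenuation
        vals = a if isinstance(a, tuple) else (a,)
        if any(not 0.0 <= v <= 1.0 for v in vals):
            raise ValueError("attenuation must lie in [0, 1]")


@dataclass
class TrueMutation:
    chrom: str
    pos: int  # 1-based, VCF-style anchor
    ref: str
    alt: str
    vtype: str
    region: str  # coding | noncoding
    on_dup: bool


@dataclass
class LineTruth:
    """Ground truth for one sample (ancestor, evolved line, or WT)."""

    sample: str
    strain: str
    role: str  # WT | ancestor | evolved
    dup_chrom: str | None
    ancestor: str | None
    karyotype: dict[str, list[tuple[int, int, int]]]  # chrom -> (start, end, cn)
    mutations: list[TrueMutation]
    karyotype_event: str  # retained | whole_loss | partial_loss | segmental_amplification
    dosage: float
    attenuation: float
    doubling_time: float

    def cn_at(self, chrom: str, pos0: int) -> int:
        for start, end, cn in self.karyotype[chrom]:
            if start <= pos0 < end:
                return cn
        raise ValueError(f"position {chrom}:{pos0} outside karyotype segments")


@dataclass
class Truth:
    """Complete ground truth: genome plus per-sample records."""

    genome: GenomeAnnotation
    lines: list[LineTruth]
    config: SimConfig

    def by_sample(self) -> dict[str, LineTruth]:
        return {ln.sample: ln for ln in self.lines}

    def evolved(self) -> list[LineTruth]:
        return [ln for ln in self.lines if ln.role == "evolved"]

    def to_json(self, path) -> None:
        doc = {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "lines": [
                {**{k: v for k, v in asdict(ln).items() if k != "mutations"},
                 "mutations": [asdict(m) for m in ln.mutations]}
                for ln in self.lines
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# genome


def make_genome(config: SimConfig) -> GenomeAnnotation:
    """Random annotated genome with the configured coding fraction.

    Gene (CDS) intervals are non-overlapping, lengths are multiples of 3,
    and intergenic gaps are sized so the realized CDS fraction matches
    ``coding_fraction`` to within rounding. Repeat loci (breakpoint
    anchors) are placed at fixed window-aligned fractions of each
    chromosome.
    """
    if config.coding_fraction > 0.98:
        raise ValueError(
            "coding_fraction > 0.98 leaves no room for intergenic gaps/promoters")
    rng = _rng(config, "genome")
    names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    chrom_lengths = dict(zip(names, config.chrom_lengths))
    rows = []
    gid = 0
    c = config.coding_fraction
    for name, length in chrom_lengths.items():
        if c <= 0:
            continue
        target_coding = int(round(c * length))
        lens: list[int] = []
        while sum(lens) < target_coding:
            lens.append(int(3 * rng.integers(100, 600)))  # 300-1797 bp CDS
        excess = sum(lens) - target_coding
        lens[-1] -= (excess // 3) * 3
        if lens[-1] < 30:
            lens.pop()
        n_genes = len(lens)
        total_gap = length - sum(lens)
        gap, rem = divmod(total_gap, n_genes + 1)
        pos = gap + rem
        for l in lens:
            strand = "+" if rng.random() < 0.5 else "-"
            rows.append((f"g{gid:05d}", name, pos, pos + l, strand))
            gid += 1
            pos += l + gap
    genes = pd.DataFrame(rows, columns=GENE_COLUMNS)
    w = config.window_size
    repeat_loci = {
        name: sorted({(int(f * length) // w) * w for f in (0.3, 0.6, 0.8)})
        for name, length in chrom_lengths.items()
    }
    seqs = {name: random_sequence(rng, length, config.gc_fraction)
            for name, length in chrom_lengths.items()}
    return GenomeAnnotation(chrom_lengths=chrom_lengths, genes=genes, seqs=seqs,
                            gc_fraction=config.gc_fraction, repeat_loci=repeat_loci)


# ---------------------------------------------------------------------------
# lineages


def _whole_karyotype(genome: GenomeAnnotation, dup_chrom: str | None
                     ) -> dict[str, list[tuple[int, int, int]]]:
    return {
        c: [(0, n, 2 if c == dup_chrom else 1)]
        for c, n in genome.chrom_lengths.items()
    }


def _apply_event(genome: GenomeAnnotation, dup_chrom: str, event: str,
                 rng: np.random.Generator) -> dict[str, list[tuple[int, int, int]]]:
    kar = _whole_karyotype(genome, dup_chrom)
    if event == "whole_loss":
        kar[dup_chrom] = [(0, genome.chrom_lengths[dup_chrom], 1)]
    elif event == "partial_loss":
        loci = genome.repeat_loci[dup_chrom]
        bp = int(loci[rng.integers(len(loci))])
        end = genome.chrom_lengths[dup_chrom]
        kar[dup_chrom] = [(0, bp, 2), (bp, end, 1)]
    elif event == "segmental_amplification":
        others = [c for c in genome.chromosomes if c != dup_chrom]
        target = others[rng.integers(len(others))]
        loci = genome.repeat_loci[target]
        bp = int(loci[rng.integers(len(loci))])
        end = genome.chrom_lengths[target]
        kar[target] = [(0, bp, 1), (bp, end, 2)]
    return kar


def _draw_attenuation(config: SimConfig, rng: np.random.Generator) -> float:
    a = config.attenuation
    if isinstance(a, tuple):
        return float(rng.uniform(a[0], a[1]))
    return float(a)


def _draw_mutations(genome: GenomeAnnotation, config: SimConfig,
                    dup_chrom: str | None, rng: np.random.Generator
                    ) -> list[TrueMutation]:
    n_sub = int(rng.poisson(config.lambda_sub))
    n_ind = int(rng.poisson(config.lambda_ind))
    chroms = genome.chromosomes
    weights = np.array([
        genome.chrom_lengths[c] * (config.dup_bias if c == dup_chrom else 1.0)
        for c in chroms
    ], dtype=float)
    if weights.sum() == 0:
        return []
    weights /= weights.sum()
    muts: list[TrueMutation] = []
    used_pos: set[tuple[str, int]] = set()
    for vtype_group, n in (("substitution", n_sub), ("indel", n_ind)):
        placed = 0
        while placed < n:
            chrom = chroms[rng.choice(len(chroms), p=weights)]
            length = genome.chrom_lengths[chrom]
            if vtype_group == "substitution":
                pos0 = int(rng.integers(0, length))
                ref = genome.seqs[chrom][pos0]
                alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            else:
                indel_len = int(rng.integers(1, 11))  # 1-10 bp
                if rng.random() < 0.5 and length > indel_len + 2:  # deletion
                    pos0 = int(rng.integers(0, length - indel_len - 1))
                    ref = genome.seqs[chrom][pos0:pos0 + indel_len + 1]
                    alt = ref[0]
                else:  # insertion
                    pos0 = int(rng.integers(0, length))
                    ref = genome.seqs[chrom][pos0]
                    alt = ref + "".join(rng.choice(list("ACGT"),
                                                   size=int(rng.integers(1, 11))))
            if (chrom, pos0) in used_pos:  # keep one event per site
                continue
            used_pos.add((chrom, pos0))
            placed += 1
            region = "coding" if genome.gene_at(chrom, pos0) else "noncoding"
            muts.append(TrueMutation(
                chrom=chrom, pos=pos0 + 1, ref=ref, alt=alt,
                vtype=classify_variant(ref, alt), region=region,
                on_dup=chrom == dup_chrom))
    return muts


def simulate_lineages(genome: GenomeAnnotation, config: SimConfig) -> Truth:
    """Draw per-line ground truth: mutations, karyotype events, dosage,
    attenuation and growth parameters.

    Samples: one euploid reference 'WT', per disomic strain one ancestor
    'D{k}_anc' and ``lines_per_strain`` evolved lines, plus evolved WT
    lines. Ancestors carry zero de novo mutations.
    """
    rng = _rng(config, "lineages")
    lines: list[LineTruth] = []
    lines.append(LineTruth(
        sample="WT", strain="WT", role="WT", dup_chrom=None, ancestor=None,
        karyotype=_whole_karyotype(genome, None), mutations=[],
        karyotype_event="retained", dosage=1.0, attenuation=0.0,
        doubling_time=config.base_doubling))
    events = list(config.karyotype_event_probs)
    probs = np.array([config.karyotype_event_probs[e] for e in events])
    strains = [("WT", None)] + [
        (f"D{k + 1}", genome.chromosomes[k % len(genome.chromosomes)])
        for k in range(config.n_disomes)
    ]
    for strain, dup_chrom in strains:
        anc_doubling = (config.base_doubling if dup_chrom is None
                        else config.base_doubling * config.disome_slowdown)
        anc_sample = None
        if dup_chrom is not None:
            anc_sample = f"{strain}_anc"
            lines.append(LineTruth(
                sample=anc_sample, strain=strain, role="ancestor",
                dup_chrom=dup_chrom, ancestor=None,
                karyotype=_whole_karyotype(genome, dup_chrom), mutations=[],
                karyotype_event="retained", dosage=config.dosage_factor,
                attenuation=0.0, doubling_time=anc_doubling))
        for j in range(config.lines_per_strain):
            u = rng.random()
            event = "retained"
            acc = 0.0
            for e, p in zip(events, probs):
                acc += p
                if u < acc:
                    event = e
                    break
            if dup_chrom is None:
                event = "retained"
                kar = _whole_karyotype(genome, None)
            elif event == "retained":
                kar = _whole_karyotype(genome, dup_chrom)
            else:
                kar = _apply_event(genome, dup_chrom, event, rng)
            atten = _draw_attenuation(config, rng)
            muts = _draw_mutations(genome, config, dup_chrom, rng)
            evolved_doubling = (config.base_doubling
                                + (anc_doubling - config.base_doubling) * (1.0 - atten))
            lines.append(LineTruth(
                sample=f"{strain}_L{j + 1}", strain=strain, role="evolved",
                dup_chrom=dup_chrom, ancestor=anc_sample or "WT",
                karyotype=kar, mutations=muts, karyotype_event=event,
                dosage=config.dosage_factor if dup_chrom else 1.0,
                attenuation=atten, doubling_time=evolved_doubling))
    return Truth(genome=genome, lines=lines, config=config)


# ---------------------------------------------------------------------------
# coverage


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float
             ) -> np.ndarray:
    """Negative binomial with mean mu, var mu + dispersion*mu^2; the
    dispersion -> 0 limit is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 1e-12:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def _windows(chrom: str, length: int, window: int) -> pd.DataFrame:
    starts = np.arange(0, length, window)
    ends = np.minimum(starts + window, length)
    return pd.DataFrame({"chrom": chrom, "start": starts, "end": ends})


def simulate_coverage(truth: Truth, config: SimConfig | None = None
                      ) -> dict[str, CoverageProfile]:
    """Windowed read counts per sample: NB(mean = depth x copy number).

    Windows tile each chromosome half-open with the last one truncated.
    """
    config = config or truth.config
    if config.depth <= 0:
        raise ValueError("depth must be positive")
    rng = _rng(config, "coverage")
    genome = truth.genome
    grid = pd.concat(
        [_windows(c, n, config.window_size) for c, n in genome.chrom_lengths.items()],
        ignore_index=True)
    frac = (grid["end"] - grid["start"]) / config.window_size
    profiles = {}
    for ln in truth.lines:
        cn = np.empty(len(grid))
        for i, r in enumerate(grid.itertuples()):
            cn[i] = ln.cn_at(r.chrom, int(r.start))
        mean = config.depth * cn * frac.to_numpy()
        counts = _nb_draw(rng, mean, config.nb_dispersion)
        win = grid.copy()
        win["count"] = counts
        profiles[ln.sample] = CoverageProfile(sample=ln.sample, windows=win)
    return profiles


# ---------------------------------------------------------------------------
# variant observations


def _observe(rng: np.random.Generator, mut: TrueMutation, cn: int,
             config: SimConfig) -> tuple[int, int]:
    dp = max(int(rng.poisson(config.depth * cn)), 1)
    center = 1.0 / cn
    af = float(np.clip(rng.normal(center, config.af_noise), 0.0, 1.0))
    ad = int(round(dp * af))
    return dp, min(ad, dp)


def _false_positives(rng: np.random.Generator, genome: GenomeAnnotation,
                     n: int, taken: set, config: SimConfig) -> list[tuple]:
    rows = []
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    w = lengths / lengths.sum()
    while len(rows) < n:
        chrom = chroms[rng.choice(len(chroms), p=w)]
        pos0 = int(rng.integers(0, genome.chrom_lengths[chrom]))
        ref = genome.seqs[chrom][pos0]
        alt = str(rng.choice([b for b in "ACGT" if b != ref]))
        key = (chrom, pos0 + 1, ref, alt)
        if key in taken:
            continue
        taken.add(key)
        dp = max(int(rng.poisson(config.depth)), 1)
        ad = int(round(dp * float(np.clip(rng.normal(0.9, config.af_noise), 0, 1))))
        rows.append((chrom, pos0 + 1, ref, alt, "substitution", dp, min(ad, dp)))
    return rows


def simulate_variant_observations(truth: Truth, config: SimConfig | None = None
                                  ) -> dict[str, tuple[pd.DataFrame, pd.DataFrame]]:
    """Two call sets (caller A, caller B) per sample.

    True mutations appear in both callers with read support ~ depth and
    alt fraction centred on 1/copy-number. Each caller additionally emits
    caller-unique false positives; strain-level background variants are
    present in the ancestor and all its evolved lines.
    """
    config = config or truth.config
    rng = _rng(config, "variants")
    genome = truth.genome
    chroms = genome.chromosomes
    lengths = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    w = lengths / lengths.sum()
    # strain-level background (pre-experiment) variants; placed away from
    # any true de novo site so keys never collide
    truth_sites = {(m.chrom, m.pos) for ln in truth.lines for m in ln.mutations}
    background: dict[str, list[tuple]] = {}
    strains = sorted({ln.strain for ln in truth.lines})
    for strain in strains:
        seen: set = set(truth_sites)
        rows = []
        while len(rows) < config.n_background:
            chrom = chroms[rng.choice(len(chroms), p=w)]
            pos0 = int(rng.integers(0, genome.chrom_lengths[chrom]))
            if (chrom, pos0 + 1) in seen:
                continue
            seen.add((chrom, pos0 + 1))
            ref = genome.seqs[chrom][pos0]
            alt = str(rng.choice([b for b in "ACGT" if b != ref]))
            rows.append((chrom, pos0 + 1, ref, alt))
        background[strain] = rows
    out = {}
    for ln in truth.lines:
        taken = set()
        rows_true = []
        bg = background.get(ln.strain, [])
        for chrom, pos, ref, alt in bg:
            cn = ln.cn_at(chrom, pos - 1)
            dp, ad = _observe(rng, TrueMutation(chrom, pos, ref, alt,
                                                "substitution", "noncoding", False),
                              cn, config)
            rows_true.append((chrom, pos, ref, alt, "substitution", dp, ad))
            taken.add((chrom, pos, ref, alt))
        for mut in ln.mutations:
            cn = ln.cn_at(mut.chrom, mut.pos - 1)
            dp, ad = _observe(rng, mut, cn, config)
            rows_true.append((mut.chrom, mut.pos, mut.ref, mut.alt, mut.vtype, dp, ad))
            taken.add((mut.chrom, mut.pos, mut.ref, mut.alt))
        n_fp_a = int(rng.poisson(config.fp_per_caller))
        n_fp_b = int(rng.poisson(config.fp_per_caller))
        fp_a = _false_positives(rng, genome, n_fp_a, taken, config)
        fp_b = _false_positives(rng, genome, n_fp_b, taken, config)
        calls_a = pd.DataFrame(rows_true + fp_a, columns=VARIANT_COLUMNS)
        # caller B re-estimates read support for shared variants
        rows_b = []
        for chrom, pos, ref, alt, vtype, dp, ad in rows_true:
            af = ad / dp if dp else 0.0
            dp_b = max(int(rng.poisson(max(dp, 1))), 1)
            ad_b = int(round(dp_b * float(np.clip(
                rng.normal(af, config.af_noise), 0.0, 1.0))))
            rows_b.append((chrom, pos, ref, alt, vtype, dp_b, min(ad_b, dp_b)))
        calls_b = pd.DataFrame(rows_b + fp_b, columns=VARIANT_COLUMNS)
        sort_cols = ["chrom", "pos", "ref", "alt"]
        out[ln.sample] = (
            calls_a.sort_values(sort_cols, kind="stable").reset_index(drop=True),
            calls_b.sort_values(sort_cols, kind="stable").reset_index(drop=True),
        )
    return out


# ---------------------------------------------------------------------------
# expression


def shift_gene_ids(truth: Truth, config: SimConfig | None = None) -> list[str]:
    """Genes whose evolved-line expression tracks the attenuation value
    (the last ``n_shift_genes`` genes on the last, never-duplicated
    chromosome)."""
    config = config or truth.config
    if config.n_shift_genes <= 0:
        return []
    genes = truth.genome.genes
    last_chrom = truth.genome.chromosomes[-1]
    pool = genes.loc[genes["chrom"] == last_chrom, "gene_id"]
    return list(pool.tail(config.n_shift_genes))


def simulate_expression(truth: Truth, config: SimConfig | None = None
                        ) -> ExpressionMatrix:
    """NB gene counts: duplicated-segment genes get the dosage factor,
    evolved lines shrink log-deviations from WT by (1 - attenuation).
    Designated shift genes move by slope x attenuation (log2) in evolved
    lines only."""
    config = config or truth.config
    if config.dosage_factor <= 0:
        raise ValueError("dosage_factor must be positive")
    rng = _rng(config, "expression")
    genome = truth.genome
    genes = genome.genes
    base = config.expr_mean * np.exp(
        rng.normal(0.0, config.expr_log_sd, size=len(genes))
        - 0.5 * config.expr_log_sd ** 2)
    shift_mask = genes["gene_id"].isin(shift_gene_ids(truth, config)).to_numpy()
    counts = {}
    meta_rows = []
    for ln in truth.lines:
        on_cn2 = np.array([
            ln.cn_at(g.chrom, int(g.start)) == 2 for g in genes.itertuples()
        ])
        log_dev = np.where(on_cn2, np.log(ln.dosage), 0.0)
        if ln.role == "evolved":
            log_dev = log_dev * (1.0 - ln.attenuation)
            log_dev = log_dev + np.where(
                shift_mask,
                np.log(2.0) * config.shift_gene_slope * ln.attenuation, 0.0)
        lib = float(rng.uniform(*config.libsize_range))
        mean = base * np.exp(log_dev) * lib
        counts[ln.sample] = _nb_draw(rng, mean, config.expr_dispersion)
        meta_rows.append({"sample": ln.sample, "strain": ln.strain,
                          "role": ln.role, "dup_chrom": ln.dup_chrom or "",
                          "ancestor": ln.ancestor or ""})
    mat = pd.DataFrame(counts, index=genes["gene_id"].to_numpy())
    return ExpressionMatrix(counts=mat, meta=pd.DataFrame(meta_rows))


# ---------------------------------------------------------------------------
# growth


def simulate_growth(truth: Truth, config: SimConfig | None = None
                    ) -> dict[str, GrowthCurve]:
    """Logistic OD600 curves sampled at 15-minute intervals."""
    config = config or truth.config
    rng = _rng(config, "growth")
    t = np.arange(0.0, config.growth_hours * 60.0 + 1e-9, 15.0)
    curves = {}
    # low inoculum so the early log-phase slope is within ~0.5% of the
    # intrinsic rate after the equilibration discard
    od0, capacity = 0.002, 1.0
    for ln in truth.lines:
        r = np.log(2.0) / ln.doubling_time
        expo = np.exp(r * t)
        od = capacity * od0 * expo / (capacity + od0 * (expo - 1.0))
        if config.od_noise > 0:
            od = od * np.exp(rng.normal(0.0, config.od_noise, size=len(t)))
        curves[ln.sample] = GrowthCurve(time=t, od=od, replicate=ln.sample)
    return curves
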