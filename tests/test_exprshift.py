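import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from aneupipe import exprshift, simdata
from aneupipe.exprshift import (
    ExpressionMatrix,
    NormalizedMatrix,
    chromosome_dosage,
    common_de,
    expression_shift,
    filter_cpm,
    rle_normalize,
    set_enrichment,
    shift_association,
    shift_from_log_columns,
)

from conftest import small_config


def matrix(counts, samples=None, roles=None, strains=None):
    counts = pd.DataFrame(counts)
    counts.columns = samples or [f"s{i}" for i in range(counts.shape[1])]
    counts.index = [f"g{i}" for i in range(counts.shape[0])]
    meta = pd.DataFrame({
        "sample": counts.columns,
        "strain": strains or ["st"] * counts.shape[1],
        "role": roles or ["evolved"] * counts.shape[1],
        "dup_chrom": "",
        "ancestor": "",
    })
    return ExpressionMatrix(counts=counts, meta=meta)


class TestFilterCpm:
    def test_half_inclusive_kept(self):
        m = matrix(np.array([[1, 1, 0, 0]]) , samples=list("abcd"))
        m.counts.loc["g0"] = [1, 1, 0, 0]
        # library sizes 1e6 via a filler gene
        filler = pd.DataFrame([[10**6 - 1] * 4], index=["filler"],
                              columns=m.counts.columns)
        m = ExpressionMatrix(counts=pd.concat([m.counts, filler]), meta=m.meta)
        out = filter_cpm(m)
        assert "g0" in out.counts.index

    def test_quarter_dropped(self):
        counts = pd.DataFrame({
            "a": [0, 10**6], "b": [0, 10**6], "c": [0, 10**6], "d": [1, 10**6]},
            index=["g0", "filler"])
        m = ExpressionMatrix(counts=counts, meta=pd.DataFrame({
            "sample": list("abcd"), "strain": "st", "role": "evolved",
            "dup_chrom": "", "ancestor": ""}))
        out = filter_cpm(m)
        assert "g0" not in out.counts.index

    def test_identity_when_all_pass(self):
        m = matrix(np.full((5, 4), 1000))
        out = filter_cpm(m)
        pd.testing.assert_frame_equal(out.counts, m.counts)

    def test_empty_rejected(self):
        m = matrix(np.full((1, 2), 10))
        m.counts = m.counts.iloc[:0]
        with pytest.raises(ValueError):
            filter_cpm(m)


class TestRleNormalize:
    def test_hand_example_size_factors(self):
        m = matrix([[10, 20], [30, 60], [100, 200]])
        norm = rle_normalize(m)
        np.testing.assert_allclose(norm.size_factors, [0.7071, 1.4142],
                                   atol=5e-5)
        pd.testing.assert_series_equal(norm.log2["s0"], norm.log2["s1"],
                                       check_names=False)

    def test_identical_samples_equal_factors(self):
        m = matrix(np.tile([[7], [70], [700]], (1, 3)))
        norm = rle_normalize(m)
        assert norm.size_factors.nunique() == 1

    def test_doubling_scales_factor_only(self):
        rng = np.random.default_rng(11)
        base = rng.poisson(100, size=(40, 4)) + 1
        m1 = rle_normalize(matrix(base))
        doubled = base.copy()
        doubled[:, 1] *= 2
        m2 = rle_normalize(matrix(doubled))
        # the doubled sample's factor doubles relative to the others
        r1 = m1.size_factors["s1"] / m1.size_factors["s0"]
        r2 = m2.size_factors["s1"] / m2.size_factors["s0"]
        assert r2 == pytest.approx(2 * r1, rel=1e-9)
        # normalized expression is unchanged up to one global constant
        scale = (m2.linear / m1.linear).to_numpy()
        np.testing.assert_allclose(scale, scale.flat[0], rtol=1e-9)

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        counts = rng.poisson(100, size=(50, 4))
        m = matrix(counts)
        norm = rle_normalize(m)
        perm = ["s2", "s0", "s3", "s1"]
        m2 = ExpressionMatrix(counts=m.counts[perm], meta=m.meta)
        norm2 = rle_normalize(m2)
        for s in perm:
            assert norm2.size_factors[s] == pytest.approx(norm.size_factors[s])

    def test_constant_gene_added_does_not_change_factors(self):
        rng = np.random.default_rng(3)
        counts = pd.DataFrame(rng.poisson(100, size=(50, 3)),
                              columns=list("abc"))
        counts.index = [f"g{i}" for i in range(50)]
        meta = pd.DataFrame({"sample": list("abc"), "strain": "st",
                             "role": "evolved", "dup_chrom": "", "ancestor": ""})
        f1 = rle_normalize(ExpressionMatrix(counts=counts, meta=meta)).size_factors
        with_const = pd.concat([
            counts, pd.DataFrame([[100, 100, 100]], index=["const"],
                                 columns=list("abc"))])
        f2 = rle_normalize(ExpressionMatrix(counts=with_const, meta=meta)
                           ).size_factors
        # a gene at the median ratio leaves the median (factor) unchanged
        np.testing.assert_allclose(f1, f2, rtol=0.02)

    def test_no_common_gene_rejected(self):
        m = matrix([[0, 5], [5, 0]])
        with pytest.raises(ValueError):
            rle_normalize(m)


class TestChromosomeDosage:
    def _norm(self, ratios, wt_val=100.0):
        n = len(ratios)
        linear = pd.DataFrame({
            "WT": np.full(n, wt_val),
            "anc": wt_val * np.asarray(ratios),
        }, index=[f"g{i}" for i in range(n)])
        return NormalizedMatrix(linear=linear, log2=np.log2(linear + 1),
                                size_factors=pd.Series(1.0, index=linear.columns),
                                meta=pd.DataFrame({"sample": linear.columns}))

    def test_all_ratios_two(self):
        norm = self._norm([2.0] * 12)
        chroms = pd.Series("chr1", index=norm.linear.index)
        assert chromosome_dosage(norm, chroms, "chr1", "anc", "WT") == 2.0

    def test_median_of_three(self):
        norm = self._norm([1.8, 2.0, 2.2] * 4)
        chroms = pd.Series("chr1", index=norm.linear.index)
        assert chromosome_dosage(norm, chroms, "chr1", "anc", "WT") == \
            pytest.approx(2.0)

    def test_too_few_genes_rejected(self):
        norm = self._norm([2.0] * 5)
        chroms = pd.Series("chr1", index=norm.linear.index)
        with pytest.raises(ValueError):
            chromosome_dosage(norm, chroms, "chr1", "anc", "WT")

    def test_generative_recovery(self):
        # duplicated chromosome must stay a minority of the transcriptome
        # (as in a real karyotype) for RLE's majority-unchanged assumption
        cfg = simdata.SimConfig(
            n_chromosomes=2, chrom_lengths=(760_000, 6_840_000), n_disomes=1,
            lines_per_strain=1, dosage_factor=1.8, seed=10,
            expr_mean=1000.0, expr_dispersion=0.002,
            karyotype_event_probs={"whole_loss": 0.0})
        truth = simdata.simulate_lineages(simdata.make_genome(cfg), cfg)
        expr = simdata.simulate_expression(truth)
        norm = rle_normalize(filter_cpm(expr))
        chroms = truth.genome.genes.set_index("gene_id")["chrom"]
        assert (chroms == "chr1").sum() >= 500
        d = chromosome_dosage(norm, chroms, "chr1", "D1_anc", "WT")
        assert 1.7 <= d <= 1.9


class TestExpressionShift:
    def test_hand_computed_half(self):
        wt = np.zeros(4)
        anc = np.array([1.0, -1.2, 0.3, 0.9])
        evo = np.array([0.5, -0.6, 0.3, 0.45])
        res = shift_from_log_columns(wt, anc, evo)
        assert sorted(res.gene_set) == ["g0", "g1", "g3"]
        assert res.d_anc == pytest.approx(math.sqrt(1 + 1.44 + 0.81))
        assert res.d_evo == pytest.approx(0.9014, abs=1e-4)
        assert res.shift == pytest.approx(0.5, abs=1e-9)

    def test_evolved_equals_ancestor_shift_zero(self):
        wt = np.zeros(5)
        anc = np.array([1.0, -1.0, 2.0, 0.0, 0.7])
        res = shift_from_log_columns(wt, anc, anc.copy())
        assert res.shift == pytest.approx(0.0)

    def test_evolved_equals_wt_shift_one(self):
        wt = np.zeros(5)
        anc = np.array([1.0, -1.0, 2.0, 0.0, 0.7])
        res = shift_from_log_columns(wt, anc, wt.copy())
        assert res.shift == pytest.approx(1.0)

    def test_scaling_linearity(self):
        rng = np.random.default_rng(4)
        wt = rng.normal(size=30)
        anc = wt + rng.normal(0, 1.5, size=30)
        for c in (0.0, 0.25, 0.6, 1.0):
            evo = wt + c * (anc - wt)
            res = shift_from_log_columns(wt, anc, evo)
            assert res.shift == pytest.approx(1.0 - c, abs=1e-9)

    def test_log_base_invariance(self):
        # expressing the log columns in base e or 10 instead of 2 scales
        # D_evo and D_anc by the same constant: the shift is unchanged
        rng = np.random.default_rng(5)
        wt = rng.normal(size=20)
        anc = wt + rng.normal(0, 1.2, size=20)
        evo = wt + 0.4 * (anc - wt)
        res2 = shift_from_log_columns(wt, anc, evo)
        for base in (math.e, 10.0):
            k = math.log(2.0, base)  # log_b x = k * log2 x
            res_b = shift_from_log_columns(wt * k, anc * k, evo * k,
                                           fc_threshold=1.5 ** k)
            assert res_b.gene_set == res2.gene_set
            assert res_b.d_anc == pytest.approx(k * res2.d_anc, rel=1e-9)
            assert res_b.normalized_distance == pytest.approx(
                res2.normalized_distance, rel=1e-9)
            assert res_b.shift == pytest.approx(res2.shift, rel=1e-9)

    def test_empty_gene_set_undefined(self):
        res = shift_from_log_columns(np.zeros(3), np.zeros(3), np.zeros(3))
        assert not res.defined

    def test_rank_order_matches_attenuation(self):
        # Spearman >= 0.9 between generative attenuation and recovered shift
        rhos = []
        for seed in range(5):
            cfg = simdata.SimConfig(
                seed=seed,
                karyotype_event_probs={"whole_loss": 0.0})
            truth = simdata.simulate_lineages(simdata.make_genome(cfg), cfg)
            expr = simdata.simulate_expression(truth)
            norm = rle_normalize(filter_cpm(expr))
            att, shf = [], []
            for ln in truth.evolved():
                if ln.dup_chrom is None:
                    continue
                res = expression_shift(norm, ln.sample, ln.ancestor, "WT")
                att.append(ln.attenuation)
                shf.append(res.shift)
            rhos.append(stats.spearmanr(att, shf).statistic)
        assert np.mean(rhos) >= 0.9


class TestCommonDE:
    def _norm_from_log2(self, log2, meta):
        return NormalizedMatrix(linear=2.0 ** log2, log2=log2,
                                size_factors=pd.Series(1.0, index=log2.columns),
                                meta=meta)

    def _meta(self, n_anc, n_evo, strains=None):
        samples = [f"a{i}" for i in range(n_anc)] + [f"e{i}" for i in range(n_evo)]
        roles = ["ancestor"] * n_anc + ["evolved"] * n_evo
        if strains is None:
            strains = ["st"] * (n_anc + n_evo)
        return pd.DataFrame({"sample": samples, "strain": strains,
                             "role": roles, "dup_chrom": "", "ancestor": ""})

    def test_power_for_strong_shift(self):
        # uniform log2 shift 2, sd 0.3: detected at q <= 0.1 in >=95/100 seeds
        n_anc, n_evo = 12, 32
        meta = self._meta(n_anc, n_evo)
        detected = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            null = rng.normal(0, 0.3, size=(100, n_anc + n_evo))
            signal = rng.normal(0, 0.3, size=n_anc + n_evo)
            signal[n_anc:] += 2.0
            log2 = pd.DataFrame(np.vstack([signal, null]),
                                index=[f"g{i}" for i in range(101)],
                                columns=meta["sample"])
            de = common_de(self._norm_from_log2(log2, meta))
            detected += bool(de.loc["g0", "significant"])
        assert detected >= 95

    def test_fdr_control_global_null(self):
        # realized average false discovery proportion <= 0.15 at q <= 0.1
        n_anc, n_evo = 6, 18
        meta = self._meta(n_anc, n_evo)
        fdps = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            log2 = pd.DataFrame(rng.normal(size=(2000, n_anc + n_evo)),
                                index=[f"g{i}" for i in range(2000)],
                                columns=meta["sample"])
            de = common_de(self._norm_from_log2(log2, meta))
            n_sig = int(de["significant"].sum())
            fdps.append(n_sig / max(n_sig, 1) if n_sig else 0.0)
        assert np.mean(fdps) <= 0.15

    def test_constant_gene_na_excluded(self):
        meta = self._meta(3, 3)
        rng = np.random.default_rng(0)
        log2 = pd.DataFrame(rng.normal(size=(4, 6)),
                            index=list("wxyz"), columns=meta["sample"])
        log2.loc["w"] = 5.0
        de = common_de(self._norm_from_log2(log2, meta))
        assert np.isnan(de.loc["w", "p"])
        assert np.isnan(de.loc["w", "q"])

    def test_requires_two_per_level(self):
        meta = self._meta(1, 3)
        log2 = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"],
                            columns=meta["sample"])
        with pytest.raises(ValueError):
            common_de(self._norm_from_log2(log2, meta))

    def test_strain_covariate_absorbs_strain_effects(self):
        # a strain-specific offset must not masquerade as evolved-vs-ancestor
        meta = self._meta(6, 6, strains=["s1", "s1", "s2", "s2", "s3", "s3",
                                         "s1", "s1", "s2", "s2", "s3", "s3"])
        rng = np.random.default_rng(9)
        offsets = {"s1": 0.0, "s2": 3.0, "s3": -2.0}
        base = rng.normal(0, 0.2, size=(50, 12))
        for j, s in enumerate(meta["strain"]):
            base[:, j] += offsets[s]
        log2 = pd.DataFrame(base, index=[f"g{i}" for i in range(50)],
                            columns=meta["sample"])
        de = common_de(self._norm_from_log2(log2, meta))
        assert int(de["significant"].sum()) == 0


class TestShiftAssociation:
    def test_exact_linear_gene(self):
        rng = np.random.default_rng(1)
        shifts = pd.Series(rng.uniform(0, 1, size=10),
                           index=[f"e{i}" for i in range(10)])
        log2 = pd.DataFrame(rng.normal(size=(5, 10)),
                            index=[f"g{i}" for i in range(5)],
                            columns=shifts.index)
        log2.loc["g0"] = shifts.values
        norm = NormalizedMatrix(linear=2.0 ** log2, log2=log2,
                                size_factors=pd.Series(1.0, index=log2.columns),
                                meta=pd.DataFrame({"sample": log2.columns}))
        res = shift_association(norm, shifts)
        assert res.loc["g0", "slope"] == pytest.approx(1.0)
        assert res.loc["g0", "p"] < 1e-12
        assert res.loc["g0", "direction"] == "positive"

    def test_null_p_uniform(self):
        rng = np.random.default_rng(2)
        shifts = pd.Series(rng.uniform(0, 1, size=12),
                           index=[f"e{i}" for i in range(12)])
        log2 = pd.DataFrame(rng.normal(size=(1000, 12)),
                            index=[f"g{i}" for i in range(1000)],
                            columns=shifts.index)
        norm = NormalizedMatrix(linear=2.0 ** log2, log2=log2,
                                size_factors=pd.Series(1.0, index=log2.columns),
                                meta=pd.DataFrame({"sample": log2.columns}))
        res = shift_association(norm, shifts)
        ks = stats.kstest(res["p"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_constant_shift_rejected(self):
        shifts = pd.Series(0.5, index=[f"e{i}" for i in range(6)])
        log2 = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 6)),
                            columns=shifts.index)
        norm = NormalizedMatrix(linear=2.0 ** log2, log2=log2,
                                size_factors=pd.Series(1.0, index=log2.columns),
                                meta=pd.DataFrame({"sample": log2.columns}))
        with pytest.raises(ValueError):
            shift_association(norm, shifts)

    def test_generative_recovery_of_shift_genes(self):
        cfg = simdata.SimConfig(
            seed=8, n_disomes=4, lines_per_strain=3, n_shift_genes=50,
            shift_gene_slope=1.5,
            karyotype_event_probs={"whole_loss": 0.0})
        truth = simdata.simulate_lineages(simdata.make_genome(cfg), cfg)
        expr = simdata.simulate_expression(truth)
        norm = rle_normalize(filter_cpm(expr))
        shifts = {}
        for ln in truth.evolved():
            if ln.dup_chrom is None:
                continue
            res = expression_shift(norm, ln.sample, ln.ancestor, "WT")
            shifts[ln.sample] = res.shift
        assoc = shift_association(norm, pd.Series(shifts))
        targets = [g for g in simdata.shift_gene_ids(truth, cfg)
                   if g in assoc.index]
        assert len(targets) >= 45
        frac = assoc.loc[targets, "significant"].mean()
        assert frac >= 0.80


class TestSetEnrichment:
    def test_hypergeometric_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        selected = {f"g{i}" for i in range(10)}
        annotation = {"setA": {f"g{i}" for i in range(5)} |
                               {f"g{i}" for i in range(50, 55)}}
        out = set_enrichment(selected, universe, annotation)
        # enumeration oracle: P(X >= 5), X ~ Hypergeom(100, 10, 10)
        oracle = sum(
            math.comb(10, k) * math.comb(90, 10 - k) / math.comb(100, 10)
            for k in range(5, 11))
        assert out.iloc[0]["p"] == pytest.approx(oracle, rel=1e-9)

    def test_zero_overlap_not_flagged(self):
        universe = {f"g{i}" for i in range(50)}
        out = set_enrichment({"g0", "g1"}, universe,
                             {"s": {"g40", "g41", "g42"}})
        assert out.iloc[0]["p"] >= 0.5

    def test_selected_equals_universe_non_informative(self):
        universe = {f"g{i}" for i in range(20)}
        out = set_enrichment(universe, universe, {"s": {"g0", "g1"}})
        assert bool(out.iloc[0]["non_informative"])
        assert out.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_universe_rejected(self):
        with pytest.raises(ValueError):
            set_enrichment(set(), set(), {"s": {"a"}})

    def test_gmt_roundtrip(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("setA\tdesc\tg1\tg2\tg3\nsetB\tdesc\tg4\n")
        sets = exprshift.read_gmt(path)
        assert sets == {"setA": {"g1", "g2", "g3"}, "setB": {"g4"}}
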