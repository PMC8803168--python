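import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from elsplice import qtl
from elsplice import synthetic_data as sd
from elsplice.io_formats import GenomicInterval, GenotypeMatrix, PhenotypeMatrix


def _gm(dosages, positions=None, samples=None):
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if positions is None:
        positions = np.arange(m) * 100 + 10
    variants = pd.DataFrame({
        "variant_id": [f"v{i}" for i in range(m)], "chrom": "chr1",
        "pos": positions, "ref": "A", "alt": "G"}).set_index("variant_id")
    return GenotypeMatrix(samples or [f"s{i}" for i in range(n)], variants, dosages)


class TestRankNormalize:
    def test_monotone_and_centred(self, rng):
        x = rng.normal(size=51)
        z = qtl.rank_normalize(x)
        assert np.all(np.diff(z[np.argsort(x)]) >= 0)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)

    def test_ties_averaged(self):
        z = qtl.rank_normalize(np.array([1.0, 1.0, 2.0, 3.0]))
        assert z[0] == z[1]

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            qtl.rank_normalize(np.ones(10))


class TestMafFilter:
    def test_strict_threshold(self):
        # MAF exactly 0.05 must drop; 0.051 must stay
        n = 1000
        d_exact = np.r_[np.ones(100), np.zeros(900)]       # f = 0.05
        d_above = np.r_[np.ones(102), np.zeros(898)]       # f = 0.051
        gm = _gm(np.column_stack([d_exact, d_above]))
        kept = qtl.maf_filter(gm, 0.05)
        assert list(kept.variants.index) == ["v1"]

    def test_monomorphic_all_dropped(self, caplog):
        gm = _gm(np.zeros((50, 3)))
        kept = qtl.maf_filter(gm)
        assert kept.n_variants == 0


class TestCisAssociate:
    def test_perfect_association(self, rng):
        g = rng.binomial(2, 0.4, size=(100, 1)).astype(float)
        out = qtl.cis_associate(g[:, 0], g)
        assert out["r"].iloc[0] == pytest.approx(1.0)
        assert out["p"].iloc[0] < 1e-50

    def test_null_p_uniform(self):
        rng = np.random.default_rng(5)
        y = rng.normal(size=500)
        G = rng.binomial(2, 0.3, size=(500, 1000)).astype(float)
        out = qtl.cis_associate(y, G)
        assert sps.kstest(out["p"].dropna(), "uniform").pvalue > 0.01

    def test_planted_slope_recovered(self):
        rng = np.random.default_rng(9)
        G = rng.binomial(2, 0.3, size=(300, 1)).astype(float)
        y = 0.5 * G[:, 0] + rng.normal(size=300)
        out = qtl.cis_associate(y, G)
        se = 1.0 / (np.std(G[:, 0]) * np.sqrt(300))
        assert abs(out["slope"].iloc[0] - 0.5) < 1.96 * se * 1.5

    def test_zero_variance_variant_skipped(self, rng):
        G = np.column_stack([np.ones(60), rng.binomial(2, 0.3, 60)]).astype(float)
        out = qtl.cis_associate(rng.normal(size=60), G)
        assert np.isnan(out["r"].iloc[0]) and np.isfinite(out["r"].iloc[1])

    def test_too_few_samples(self, rng):
        with pytest.raises(ValueError):
            qtl.cis_associate(rng.normal(size=10),
                              rng.binomial(2, 0.3, size=(10, 2)).astype(float))


class TestGeneLevelPermutation:
    def test_perfect_association_passes(self, rng):
        G = rng.binomial(2, 0.4, size=(100, 20)).astype(float)
        passed, r_max = qtl.gene_level_permutation(G[:, 3], G, n_perm=200, seed=0)
        assert passed
        assert r_max.size == 200

    def test_seed_determinism(self, rng):
        y = rng.normal(size=80)
        G = rng.binomial(2, 0.3, size=(80, 10)).astype(float)
        _, r1 = qtl.gene_level_permutation(y, G, n_perm=150, seed=42)
        _, r2 = qtl.gene_level_permutation(y, G, n_perm=150, seed=42)
        np.testing.assert_array_equal(r1, r2)

    def test_min_permutations_enforced(self, rng):
        with pytest.raises(ValueError):
            qtl.gene_level_permutation(rng.normal(size=50),
                                       rng.binomial(2, .3, (50, 5)).astype(float),
                                       n_perm=50)


class TestBhFdr:
    def test_hand_computed_step_up(self):
        np.testing.assert_allclose(qtl.bh_fdr([0.01]), [0.01])
        np.testing.assert_allclose(qtl.bh_fdr([0.01, 0.02, 0.9]),
                                   [0.03, 0.03, 0.9])
        assert (qtl.bh_fdr(np.ones(5)) >= 1.0 - 1e-12).all()

    def test_matches_brute_force_step_up(self):
        rng = np.random.default_rng(3)

        def brute(p):
            p = np.asarray(p)
            m = p.size
            order = np.argsort(p)
            q = np.empty(m)
            prev = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                prev = min(prev, p[i] * m / rank)
                q[i] = prev
            return q

        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(qtl.bh_fdr(p), brute(p), atol=1e-12)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            qtl.bh_fdr([0.5, 1.5])


def test_genotype_sign_flip_invariance(rng):
    y = rng.normal(size=200)
    G = rng.binomial(2, 0.3, size=(200, 8)).astype(float)
    a = qtl.cis_associate(y, G)
    b = qtl.cis_associate(y, 2.0 - G)
    np.testing.assert_allclose(a["slope"], -b["slope"], atol=1e-12)
    np.testing.assert_allclose(a["r"], -b["r"], atol=1e-12)
    np.testing.assert_allclose(a["p"], b["p"], atol=1e-12)
    p1, _ = qtl.gene_level_permutation(y, G, n_perm=150, seed=1)
    p2, _ = qtl.gene_level_permutation(y, 2.0 - G, n_perm=150, seed=1)
    assert p1 == p2


class TestTriplets:
    def _sig(self, rows):
        return pd.DataFrame(rows, columns=["variant_id", "trait_id", "tad"])

    def test_predict_targets_set_logic(self):
        elnc = self._sig([("v1", "L1", "t1"), ("v2", "L2", "t2")])
        pcg = self._sig([("v1", "G1", "t1"), ("v9", "G2", "t2"), ("v2", "G3", "t9")])
        pairs = qtl.predict_targets(elnc, pcg)
        assert pairs.to_records(index=False).tolist() == [("L1", "G1", "t1")]

    def test_exclusion_rules_and_audit_flags(self):
        sq = self._sig([("v1", "iA", "t1"), ("v2", "iB", "t1")])
        eq = self._sig([("v1", "G1", "t1"), ("v2", "G1", "t1")])
        elnc_eq = self._sig([("v1", "L1", "t1")])
        gene_map = pd.Series({"iA": "L1", "iB": "L1"})
        out = qtl.build_joint_triplets(sq, eq, elnc_eqtls=elnc_eq,
                                       mediator_gene=gene_map)
        v1 = out[out["variant_id"] == "v1"].iloc[0]
        v2 = out[out["variant_id"] == "v2"].iloc[0]
        assert v1["excluded_elnc_eqtl"] and not v1["included"]
        assert v2["included"]

    def test_brute_force_fixture_agreement(self):
        variants = [f"v{i}" for i in range(5)]
        sq = self._sig([(v, "iA", "t1") for v in variants])
        eq = self._sig([(v, "G1", "t1") for v in ["v0", "v1", "v3"]])
        elnc_eq = self._sig([("v0", "L1", "t1")])
        tgt_sq = pd.DataFrame({"variant_id": ["v3"], "trait_id": ["G1"]})
        gene_map = pd.Series({"iA": "L1"})
        out = qtl.build_joint_triplets(sq, eq, elnc_eqtls=elnc_eq,
                                       target_sqtls=tgt_sq, mediator_gene=gene_map)
        included = set(out.loc[out["included"], "variant_id"])
        # oracle by explicit set logic
        joint = {"v0", "v1", "v3"}
        expect = {v for v in joint if v != "v0" and v != "v3"}
        assert included == expect

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            qtl.build_joint_triplets(self._sig([]), self._sig([]), mode="banana")


class TestZscoreSlope:
    def test_values_and_sign(self):
        assert qtl.zscore_to_slope(0.0, 0.3, 1000) == 0.0
        expect = 5 / np.sqrt(2 * 0.3 * 0.7 * (1000 + 25))
        assert qtl.zscore_to_slope(5.0, 0.3, 1000) == pytest.approx(expect)
        assert qtl.zscore_to_slope(5.0, 0.3, 1000) == pytest.approx(0.2410, abs=1e-4)
        assert qtl.zscore_to_slope(-2.0, 0.1, 500) < 0

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            qtl.zscore_to_slope(1.0, 0.0, 100)
        with pytest.raises(ValueError):
            qtl.zscore_to_slope(1.0, 0.5, 0)


def test_replication_check_rules():
    disc = pd.DataFrame({"variant_id": ["v1", "v2", "v3"],
                         "trait_id": ["g", "g", "g"],
                         "slope": [1.0, 1.0, 1.0]})
    rep = pd.DataFrame({"variant_id": ["v1", "v2", "v3"],
                        "trait_id": ["g", "g", "g"],
                        "slope": [0.5, -0.5, 0.5],
                        "p": [1e-5, 1e-5, 0.9]})
    out = qtl.replication_check(disc, rep)
    assert out.set_index("variant_id")["replicated"].tolist() == [True, False, False]


class TestCisQtlModel:
    def test_planted_sqtl_found_and_summary(self):
        rng = np.random.default_rng(11)
        n = 150
        G = rng.binomial(2, 0.3, size=(n, 5)).astype(float)
        gm = _gm(G, positions=np.arange(5) * 1000 + 100)
        y = 0.8 * G[:, 2] + rng.normal(size=n)
        values = pd.DataFrame([np.clip((y - y.min()) / np.ptp(y), 0, 1)],
                              index=["chr1:100:200:clu1"], columns=gm.samples)
        pm = PhenotypeMatrix(values, kind="splicing")
        tads = [GenomicInterval("chr1", 0, 10_000, ".", "tad0")]
        res = qtl.CisQtlModel(pm, gm, tads, n_perm=200, seed=0).fit()
        sig = res.significant()
        assert "v2" in set(sig["variant_id"])
        assert res.best_per_trait()["variant_id"].iloc[0] == "v2"
        assert "traits with >=1 QTL:  1" in res.summary()

    def test_trait_without_tad_skipped(self, caplog):
        rng = np.random.default_rng(1)
        gm = _gm(rng.binomial(2, 0.3, size=(60, 2)).astype(float))
        pm = PhenotypeMatrix(pd.DataFrame([rng.random(60)],
                                          index=["chr2:5:6:c"], columns=gm.samples),
                             kind="splicing")
        res = qtl.CisQtlModel(pm, gm, [GenomicInterval("chr1", 0, 10_000)],
                              n_perm=100).fit()
        assert res.records.empty
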