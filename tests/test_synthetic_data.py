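import json

import numpy as np
import pandas as pd
import pytest

from elsplice import io_formats as io
from elsplice import qtl
from elsplice import synthetic_data as sd
from elsplice.splicing import compute_psi


class TestConfigs:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            sd.CohortConfig(n_samples=1)
        with pytest.raises(ValueError):
            sd.CohortConfig(maf_range=(0.3, 0.1))
        with pytest.raises(ValueError):
            sd.CohortConfig(maf_range=(0.0, 0.1))
        with pytest.raises(ValueError):
            sd.MediationScenario(model="banana")
        with pytest.raises(ValueError):
            sd.MediationScenario(model="causal", beta_EB=0.5)
        with pytest.raises(ValueError):
            sd.MediationScenario(model="independent", beta_AB=0.5)
        with pytest.raises(ValueError):
            sd.EvolutionScenario(constraint_ratio=1.5)


class TestGenotypes:
    def test_fixed_half_frequency_dosage_mean(self):
        cfg = sd.CohortConfig(n_samples=4, n_variants=200,
                              maf_range=(0.5, 0.5), seed=0)
        gm = sd.simulate_genotypes(cfg)
        means = gm.dosages.mean(axis=0)
        # each variant mean lies in Binomial(8, .5)/4 support around 1.0
        assert means.min() >= 0 and means.max() <= 2
        assert abs(means.mean() - 1.0) < 0.1

    def test_pooled_frequency_within_3se(self):
        cfg = sd.CohortConfig(n_samples=50, n_variants=10_000,
                              maf_range=(0.05, 0.05), seed=1)
        gm = sd.simulate_genotypes(cfg)
        f_hat = gm.dosages.mean() / 2.0
        se = np.sqrt(0.05 * 0.95 / (2 * 50 * 10_000))
        assert abs(f_hat - 0.05) <= 3 * se

    def test_seed_determinism(self):
        cfg = sd.CohortConfig(n_samples=20, n_variants=30, seed=9)
        g1 = sd.simulate_genotypes(cfg)
        g2 = sd.simulate_genotypes(cfg)
        np.testing.assert_array_equal(g1.dosages, g2.dosages)

    def test_ld_copy_correlated(self):
        cfg = sd.CohortConfig(n_samples=500, n_variants=2, seed=3)
        gm = sd.add_ld_copy(sd.simulate_genotypes(cfg), "v00000", "v_ld",
                            flip_prob=0.1, pos=999, seed=3)
        r = np.corrcoef(gm.dosages[:, 0], gm.dosages[:, 2])[0, 1]
        assert r > 0.7


class TestMediationTriplets:
    def test_causal_partial_correlation_vanishes(self):
        scn = sd.MediationScenario(model="causal", beta_EA=0.8, beta_AB=0.8,
                                   noise_sd=1e-5)
        d = sd.simulate_mediation_triplets(50, scn, sd.CohortConfig(n_samples=200,
                                                                   seed=0))
        from elsplice.causal import triplet_stats
        st = triplet_stats(d.E, d.A, d.B)
        assert np.median(np.abs(st["r_EB_A"])) < 0.05

    def test_independent_no_ab_edge(self):
        scn = sd.MediationScenario(model="independent", beta_EA=0.8, beta_AB=0.0,
                                   beta_EB=0.8, noise_sd=1e-5)
        d = sd.simulate_mediation_triplets(50, scn, sd.CohortConfig(n_samples=200,
                                                                    seed=1))
        from elsplice.causal import triplet_stats
        st = triplet_stats(d.E, d.A, d.B)
        assert np.median(np.abs(st["r_AB_E"])) < 0.05

    def test_ols_recovers_planted_effect(self):
        scn = sd.MediationScenario(model="causal", beta_EA=0.8, beta_AB=0.7)
        d = sd.simulate_mediation_triplets(1, scn,
                                           sd.CohortConfig(n_samples=500, seed=2))
        e, a = d.E[0], d.A[0]
        slope = np.polyfit(e, a, 1)[0]
        se = 1.0 / (e.std() * np.sqrt(500))
        assert abs(slope - 0.8) < 1.96 * se * 1.5

    def test_frame_shape(self):
        scn = sd.MediationScenario(model="undecided", beta_AB=0.5, beta_EB=0.5)
        d = sd.simulate_mediation_triplets(3, scn, sd.CohortConfig(n_samples=10))
        assert d.to_frame().shape == (30, 3)


class TestJunctionCounts:
    def test_no_effect_high_depth_psi_half(self):
        dosage = np.ones(200)
        tab = sd.simulate_junction_counts([0.5, 0.5], 0.0, dosage, depth=5000,
                                          seed=0)
        psi = compute_psi(tab)
        assert abs(psi.iloc[0].mean() - 0.5) < 0.01

    def test_zero_depth_all_missing(self):
        tab = sd.simulate_junction_counts([0.5, 0.5], 1.0, np.ones(10), depth=0)
        assert (tab.counts.to_numpy() == 0).all()
        assert compute_psi(tab).isna().all().all()

    def test_simplex_validation(self):
        with pytest.raises(ValueError):
            sd.simulate_junction_counts([0.5, 0.6], 0.0, np.ones(5), depth=10)

    def test_two_intron_effect_is_logit_shift(self):
        # dosage 1 with effect b shifts logit PSI of intron 0 by exactly b
        dosage = np.r_[np.zeros(4000), np.ones(4000)]
        tab = sd.simulate_junction_counts([0.6, 0.4], -1.0, dosage, depth=2000,
                                          seed=1)
        psi = compute_psi(tab)
        p0 = psi.iloc[0, :4000].mean()
        p1 = psi.iloc[0, 4000:].mean()
        logit = lambda p: np.log(p / (1 - p))
        assert logit(p0) - logit(p1) == pytest.approx(1.0, abs=0.05)

    def test_planted_effect_recoverable_downstream(self):
        rng = np.random.default_rng(5)
        dosage = rng.binomial(2, 0.3, size=300).astype(float)
        tab = sd.simulate_junction_counts([0.5, 0.5], 1.0, dosage, depth=50, seed=5)
        psi = compute_psi(tab)
        y = qtl.rank_normalize(psi.iloc[0].to_numpy())
        out = qtl.cis_associate(y, dosage[:, None])
        assert out["slope"].iloc[0] > 0
        assert out["p"].iloc[0] < 0.01


class TestSequencePairs:
    def test_zero_rate_identical_pairs(self):
        feats, ars = sd.simulate_sequence_pairs(
            sd.EvolutionScenario(neutral_rate=0.0, n_motifs=3, seed=0))
        for seg in feats + ars:
            assert seg.alignment.seq1 == seg.alignment.seq2

    def test_constrained_motifs_diverge_less(self):
        feats, ars = sd.simulate_sequence_pairs(
            sd.EvolutionScenario(neutral_rate=0.5, constraint_ratio=0.2,
                                 n_motifs=15, seed=1))
        pdist = lambda a: np.mean([x != y for x, y in zip(a.seq1, a.seq2)])
        assert (np.median([pdist(f.alignment) for f in feats])
                < np.median([pdist(a.alignment) for a in ars]))

    def test_ars_local_to_motifs(self):
        feats, ars = sd.simulate_sequence_pairs(
            sd.EvolutionScenario(neutral_rate=0.3, n_motifs=2, n_ar_segments=4,
                                 seed=2))
        for f in feats:
            local = [a for a in ars if abs(
                (a.interval.start + a.interval.end) / 2
                - (f.interval.start + f.interval.end) / 2) <= 1_000_000]
            assert len(local) >= 4


class TestDafTable:
    def test_values_in_open_unit_interval(self):
        t = sd.simulate_daf_table({"AR": 2000, "elncRNA-motif": 2000}, 0.3, seed=0)
        assert (t["daf"] > 0).all() and (t["daf"] < 1).all()

    def test_shift_enriches_low_daf(self):
        t = sd.simulate_daf_table({"AR": 5000, "elncRNA-motif": 5000}, 0.4, seed=1)
        low = t.groupby("snp_class")["daf"].apply(lambda d: (d < 0.1).mean())
        assert low["elncRNA-motif"] > low["AR"] + 0.1

    def test_zero_shift_matches_neutral(self):
        from elsplice.evolution import daf_compare
        t = sd.simulate_daf_table({"AR": 4000, "elncRNA-motif": 4000}, 0.0, seed=2)
        orr, p = daf_compare(t.loc[t.snp_class == "elncRNA-motif", "daf"],
                             t.loc[t.snp_class == "AR", "daf"])
        assert 0.8 < orr < 1.25
        assert p > 0.01

    def test_round_trips_through_polarisation(self):
        from elsplice.evolution import daf_spectrum
        t = sd.simulate_daf_table({"AR": 500}, 0.0, seed=3)
        back = daf_spectrum(t.drop(columns="daf"))
        np.testing.assert_allclose(back["daf"], t["daf"], atol=1e-12)


class TestCohort:
    def test_cohort_round_trips_and_structure(self, tmp_path):
        truth = sd.simulate_cohort(tmp_path, n_samples=40, n_loci=5,
                                   causal_fraction=0.6, seed=0)
        assert truth.causal_fraction == pytest.approx(0.6)
        gm = io.read_genotypes(tmp_path / "genotypes.vcf")
        assert gm.n_samples == 40 and gm.n_variants == 15
        ts = io.read_gtf(tmp_path / "transcripts.gtf")
        assert len(ts) == 10
        tab = io.read_intron_clusters(tmp_path / "counts.tsv")
        assert tab.introns["cluster"].nunique() == 5
        expr = io.read_phenotypes(tmp_path / "expression.tsv")
        assert len(expr.traits) == 10
        with open(tmp_path / "truth.json") as fh:
            j = json.load(fh)
        assert set(j["locus_models"]) == {f"ELNC{i:03d}" for i in range(5)}

    def test_cohort_deterministic(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        sd.simulate_cohort(d1, n_samples=20, n_loci=3, seed=7)
        sd.simulate_cohort(d2, n_samples=20, n_loci=3, seed=7)
        for name in ("genotypes.vcf", "counts.tsv", "expression.tsv",
                     "transcripts.gtf", "truth.json"):
            assert (d1 / name).read_text() == (d2 / name).read_text()
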