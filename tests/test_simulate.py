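import numpy as np
import pandas as pd
import pytest
from scipy.stats import chisquare, kstest

from prstrat.genio import hard_call
from prstrat.simulate import (SimulationConfig, TrueModel, simulate_cohort,
                              simulate_discovery_sumstats, theoretical_auc)


class TestConfigValidation:
    def test_maf_range_bounds(self):
        with pytest.raises(ValueError):
            SimulationConfig(maf_range=(0.001, 0.5), seed=1)

    def test_apoe_freqs_sum(self):
        with pytest.raises(ValueError):
            SimulationConfig(apoe_freqs=(0.2, 0.2, 0.2), seed=1)

    def test_overlap_feasibility(self):
        with pytest.raises(ValueError):
            SimulationConfig(n_cases=600, n_controls=600, discovery_n=500,
                             overlap_fraction=1.0, seed=1)


class TestSimulateCohort:
    def test_determinism(self):
        cfg = SimulationConfig(n_cases=50, n_controls=50, n_snps=30, seed=123)
        m1, s1, mod1 = simulate_cohort(cfg)
        m2, s2, mod2 = simulate_cohort(cfg)
        np.testing.assert_array_equal(m1.probs, m2.probs)
        pd.testing.assert_frame_equal(s1, s2)
        np.testing.assert_array_equal(mod1.snp_betas, mod2.snp_betas)

    def test_probability_triples_valid(self, small_cohort):
        _, matrix, _, _ = small_cohort
        assert (matrix.probs >= 0).all()
        np.testing.assert_allclose(matrix.probs.sum(axis=2), 1.0, atol=1e-9)

    def test_quota_and_labels(self, small_cohort):
        cfg, matrix, samples, _ = small_cohort
        assert (samples["status"] == "case").sum() == cfg.n_cases
        assert (samples["status"] == "control").sum() == cfg.n_controls
        assert matrix.n_snps == cfg.n_snps
        assert samples["apoe_genotype"].notna().all()

    def test_apoe_snps_consistent_with_labels(self, small_cohort):
        # the two APOE SNPs must carry the E4/E2 allele counts of the label
        _, matrix, samples, model = small_cohort
        idx = {s: j for j, s in enumerate(matrix.snp_meta["snp_id"])}
        # recover true dosage as argmax of unblurred entries where exact
        e4 = samples["apoe_genotype"].str.count("E4").to_numpy()
        e2 = samples["apoe_genotype"].str.count("E2").to_numpy()
        hc = hard_call(matrix, threshold=0.5)
        d4 = hc.dosage[:, idx["rs429358"]]
        d2 = hc.dosage[:, idx["rs7412"]]
        ok4 = np.isfinite(d4)
        ok2 = np.isfinite(d2)
        # hard calls at 0.5 recover the truth except blurred entries
        assert (d4[ok4] == e4[ok4]).mean() > 0.95
        assert (d2[ok2] == e2[ok2]).mean() > 0.95

    def test_hardy_weinberg_apoe(self):
        # null APOE effects: no ascertainment distortion of genotype freqs
        cfg = SimulationConfig(n_cases=2500, n_controls=2500, n_snps=10,
                               n_causal=0, apoe_betas=(0.0, 0.0), seed=77)
        _, samples, _ = simulate_cohort(cfg)
        f2, f3, f4 = cfg.apoe_freqs
        expected = {
            "E2E2": f2 * f2, "E2E3": 2 * f2 * f3, "E2E4": 2 * f2 * f4,
            "E3E3": f3 * f3, "E3E4": 2 * f3 * f4, "E4E4": f4 * f4,
        }
        obs = samples["apoe_genotype"].value_counts()
        labels = list(expected)
        f_obs = np.array([obs.get(l, 0) for l in labels], dtype=float)
        f_exp = np.array([expected[l] * len(samples) for l in labels])
        stat, p = chisquare(f_obs, f_exp)
        assert p > 0.001

    def test_ld_rho_zero_gives_uncorrelated_adjacent_snps(self):
        cfg = SimulationConfig(n_cases=1000, n_controls=1000, n_snps=80,
                               n_causal=0, apoe_betas=(0.0, 0.0), ld_rho=0.0,
                               info_range=(1.0, 1.0), seed=21)
        matrix, _, _ = simulate_cohort(cfg)
        d = hard_call(matrix).dosage[:, :-2]  # background SNPs only
        r2 = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
              for j in range(d.shape[1] - 1)]
        assert np.mean(r2) < 0.02

    def test_ld_rho_high_gives_correlated_adjacent_snps(self):
        cfg = SimulationConfig(n_cases=500, n_controls=500, n_snps=42,
                               n_causal=0, apoe_betas=(0.0, 0.0), ld_rho=0.9,
                               ld_block_size=10, info_range=(1.0, 1.0), seed=22)
        matrix, _, _ = simulate_cohort(cfg)
        d = hard_call(matrix).dosage[:, :-2]
        within = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
                  for j in range(39) if (j + 1) % 10 != 0]
        across = [np.corrcoef(d[:, j], d[:, j + 1])[0, 1] ** 2
                  for j in range(39) if (j + 1) % 10 == 0]
        assert np.mean(within) > 0.3
        assert np.mean(across) < 0.05

    def test_realized_maf_floor(self):
        cfg = SimulationConfig(n_cases=1000, n_controls=1000, n_snps=100,
                               n_causal=0, apoe_betas=(0.0, 0.0),
                               maf_range=(0.01, 0.5), info_range=(1.0, 1.0),
                               ld_rho=0.0, seed=31)
        matrix, _, _ = simulate_cohort(cfg)
        e = matrix.expected_dosage().mean(axis=0)[:-2] / 2.0
        maf = np.minimum(e, 1 - e)
        assert maf.min() >= 0.009

    def test_infeasible_case_quota_raises_with_bound(self):
        cfg = SimulationConfig(n_cases=200, n_controls=10, n_snps=10,
                               n_causal=0, apoe_betas=(0.0, 0.0),
                               intercept=-12.0, seed=5)
        with pytest.raises(RuntimeError, match="draws"):
            simulate_cohort(cfg)


class TestDiscoverySumstats:
    def test_determinism(self, small_cohort):
        cfg, matrix, samples, model = small_cohort
        s1 = simulate_discovery_sumstats(cfg, model, None)
        s2 = simulate_discovery_sumstats(cfg, model, None)
        pd.testing.assert_frame_equal(s1, s2)

    def test_beta_consistency_single_causal(self):
        # one causal SNP with known beta, no APOE effect, big discovery n
        cfg = SimulationConfig(n_cases=50, n_controls=50, n_snps=10, n_causal=0,
                               apoe_betas=(0.0, 0.0), ld_rho=0.0,
                               discovery_n=20_000, seed=8)
        _, _, model = simulate_cohort(cfg)
        betas = np.zeros(cfg.n_snps)
        betas[0] = 0.5
        model = TrueModel(snp_betas=betas,
                          apoe_effect_by_genotype=model.apoe_effect_by_genotype,
                          intercept=0.0, snp_meta=model.snp_meta, config=cfg)
        ss = simulate_discovery_sumstats(cfg, model, None)
        row = ss.iloc[0]
        assert abs(row["BETA"] - 0.5) < 3 * row["SE"]

    def test_null_pvalues_uniform(self):
        cfg = SimulationConfig(n_cases=50, n_controls=50, n_snps=202,
                               n_causal=0, apoe_betas=(0.0, 0.0), ld_rho=0.0,
                               discovery_n=2000, seed=13)
        _, _, model = simulate_cohort(cfg)
        ss = simulate_discovery_sumstats(cfg, model, None)
        bg = ss["ok"] & ~ss["SNP"].isin(["rs429358", "rs7412"])
        pvals = ss.loc[bg, "P"].to_numpy()
        stat, p = kstest(pvals, "uniform")
        assert p > 0.01

    def test_overlap_reuses_test_samples(self, small_cohort):
        cfg, matrix, samples, model = small_cohort
        import dataclasses
        cfg1 = dataclasses.replace(cfg, overlap_fraction=1.0,
                                   discovery_n=len(samples))
        hc = hard_call(matrix)
        ss = simulate_discovery_sumstats(cfg1, model, (samples, hc))
        # n_used cannot exceed the test-cohort size: no fresh samples drawn
        assert ss["ok"].any()

    def test_overlap_inflates_auc(self):
        # paired comparison: scoring with overlap=1 beats overlap=0 on average
        from prstrat.clumping import greedy_prune
        from prstrat.prs import ScoreSpec, compute_prs
        from prstrat.evaluate import auc_mann_whitney
        import dataclasses
        diffs = []
        for seed in range(30):
            cfg = SimulationConfig(n_cases=150, n_controls=150, n_snps=120,
                                   n_causal=30, effect_sd=0.1, ld_rho=0.0,
                                   info_range=(0.98, 1.0), discovery_n=300,
                                   seed=seed)
            matrix, samples, model = simulate_cohort(cfg)
            hc = hard_call(matrix)
            case = (samples["status"] == "case").to_numpy()
            aucs = {}
            for frac in (0.0, 1.0):
                c = dataclasses.replace(cfg, overlap_fraction=frac)
                ss = simulate_discovery_sumstats(c, model, (samples, hc))
                ok = ss[ss["ok"]]
                retained = greedy_prune(ok, hc)
                prs = compute_prs(hc, ok, retained, ScoreSpec(p_threshold=0.5))
                z = prs["z_score"].to_numpy()
                aucs[frac] = auc_mann_whitney(z[case], z[~case])
            diffs.append(aucs[1.0] - aucs[0.0])
        assert np.mean(diffs) > 0
        assert (np.array(diffs) > 0).mean() > 0.6


class TestTheoreticalAUC:
    def test_zero_difference(self):
        assert theoretical_auc(1.0, 1.0, 1.0) == pytest.approx(0.5)

    def test_separation_limit(self):
        assert theoretical_auc(20.0, 0.0, 1.0) == pytest.approx(1.0, abs=1e-9)

    def test_hand_value(self):
        # Phi(1.19 / sqrt(2)) evaluated numerically
        assert theoretical_auc(1.19, 0.0, 1.0) == pytest.approx(0.7999, abs=5e-4)

    def test_nonpositive_sd(self):
        with pytest.raises(ValueError):
            theoretical_auc(1.0, 0.0, 0.0)
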