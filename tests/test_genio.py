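import numpy as np
import pandas as pd
import pytest

from prstrat.genio import (GenotypeProbabilityMatrix, SampleRecord, compute_maf,
                           hard_call, make_sample_table, qc_filter, read_gen,
                           read_sample, read_sumstats, write_gen, write_sample,
                           write_sumstats)
from conftest import gpm_from_probs, make_meta, probs_from_dosage


def _write_pair(tmp_path, gen_text, n_samples):
    gen = tmp_path / "x.gen"
    gen.write_text(gen_text)
    sample = tmp_path / "x.sample"
    lines = ["ID_1 ID_2 missing sex phenotype", "0 0 0 D B"]
    lines += [f"S{i} S{i} 0 1 0" for i in range(1, n_samples + 1)]
    sample.write_text("\n".join(lines) + "\n")
    return gen, sample


class TestReadGen:
    def test_single_line_parse(self, tmp_path):
        gen, sample = _write_pair(tmp_path, "1 rs1 100 A G 1 0 0\n", 1)
        m = read_gen(gen, sample)
        assert m.n_samples == 1 and m.n_snps == 1
        np.testing.assert_allclose(m.probs[0, 0], [1, 0, 0])
        row = m.snp_meta.iloc[0]
        assert (row["alleleA"], row["alleleB"]) == ("A", "G")
        assert row["chrom"] == "1" and row["pos"] == 100

    def test_renormalization_with_warning(self, tmp_path, caplog):
        gen, sample = _write_pair(tmp_path, "1 rs1 100 A G 0.5 0.5 0.1\n", 1)
        with caplog.at_level("WARNING"):
            m = read_gen(gen, sample)
        np.testing.assert_allclose(m.probs[0, 0],
                                   [0.5 / 1.1, 0.5 / 1.1, 0.1 / 1.1])
        assert any("renormalized" in r.message for r in caplog.records)

    def test_sample_count_mismatch(self, tmp_path):
        gen, sample = _write_pair(tmp_path, "1 rs1 100 A G 1 0 0 0 1 0\n", 3)
        with pytest.raises(ValueError, match="expected"):
            read_gen(gen, sample)

    def test_malformed_line_names_line_number(self, tmp_path):
        gen, sample = _write_pair(
            tmp_path, "1 rs1 100 A G 1 0 0\n1 rs2 200 A G 1 0\n", 1)
        with pytest.raises(ValueError, match="line 2"):
            read_gen(gen, sample)

    def test_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        raw = rng.dirichlet([1, 1, 1], size=(20, 7))
        m = gpm_from_probs(raw, meta=make_meta(7, info=0.93))
        write_gen(m, tmp_path / "y.gen", tmp_path / "y.info.tsv")
        samples = make_sample_table(
            [SampleRecord(sample_id=s) for s in m.sample_ids])
        write_sample(samples, tmp_path / "y.sample")
        back = read_gen(tmp_path / "y.gen", tmp_path / "y.sample",
                        tmp_path / "y.info.tsv")
        np.testing.assert_allclose(back.probs, m.probs, atol=1e-6)
        np.testing.assert_allclose(back.snp_meta["info_score"], 0.93, atol=1e-6)
        assert back.sample_ids == m.sample_ids


class TestSampleIO:
    def test_round_trip_with_apoe(self, tmp_path):
        samples = make_sample_table([
            SampleRecord("A1", "male", "case", "E3E4"),
            SampleRecord("A2", "female", "control", None),
        ])
        write_sample(samples, tmp_path / "s.sample")
        back = read_sample(tmp_path / "s.sample")
        assert back["status"].tolist() == ["case", "control"]
        assert back["sex"].tolist() == ["male", "female"]
        assert back["apoe_genotype"].tolist()[0] == "E3E4"
        assert back["apoe_genotype"].isna().tolist() == [False, True]

    def test_bad_status_rejected(self):
        with pytest.raises(ValueError):
            SampleRecord("A1", "male", "affected")


class TestHardCall:
    @pytest.mark.parametrize("triple,expected", [
        ((0.95, 0.03, 0.02), 0.0),
        ((0.40, 0.40, 0.20), np.nan),
        ((0.05, 0.91, 0.04), 1.0),
        ((0.90, 0.05, 0.05), np.nan),  # strict: max must exceed threshold
    ])
    def test_examples(self, triple, expected):
        m = gpm_from_probs(np.array([[triple]]), meta=make_meta(1))
        got = hard_call(m, 0.9).dosage[0, 0]
        if np.isnan(expected):
            assert np.isnan(got)
        else:
            assert got == expected

    def test_threshold_domain(self):
        m = gpm_from_probs(np.array([[[1.0, 0, 0]]]), meta=make_meta(1))
        with pytest.raises(ValueError):
            hard_call(m, 0.2)


class TestMAF:
    def test_monomorphic_a(self):
        m = gpm_from_probs(probs_from_dosage(np.zeros((4, 1))))
        assert compute_maf(m, 0) == 0.0

    def test_folding(self):
        m = gpm_from_probs(probs_from_dosage(np.full((4, 1), 2)))
        assert compute_maf(m, 0) == 0.0

    def test_hand_value(self):
        m = gpm_from_probs(probs_from_dosage(np.array([[0], [1]])))
        assert compute_maf(m, 0) == pytest.approx(0.25)


class TestQCFilter:
    def _matrix(self, infos, dosage_cols):
        probs = probs_from_dosage(np.column_stack(dosage_cols))
        meta = make_meta(len(infos))
        meta["info_score"] = infos
        return gpm_from_probs(probs, meta=meta)

    def test_info_boundary(self):
        # 50 samples all het -> MAF 0.5 passes for both SNPs
        col = np.ones(50)
        m = self._matrix([0.79, 0.80], [col, col])
        out = qc_filter(m)
        assert out.snp_meta["snp_id"].tolist() == ["rs2"]

    def test_maf_boundary(self):
        # expected-dosage MAF exactly 0.009 vs 0.010 over 1000 samples
        col_fail = np.zeros(1000); col_fail[:18] = 1    # 18/2000 = 0.009
        col_pass = np.zeros(1000); col_pass[:20] = 1    # 20/2000 = 0.010
        m = self._matrix([1.0, 1.0], [col_fail, col_pass])
        out = qc_filter(m)
        assert out.snp_meta["snp_id"].tolist() == ["rs2"]

    def test_identity_when_all_pass(self):
        col = np.ones(10)
        m = self._matrix([0.9, 0.95], [col, col])
        out = qc_filter(m)
        np.testing.assert_array_equal(out.probs, m.probs)

    def test_idempotent(self, small_cohort):
        _, matrix, _, _ = small_cohort
        once = qc_filter(matrix)
        twice = qc_filter(once)
        assert once.snp_meta["snp_id"].tolist() == twice.snp_meta["snp_id"].tolist()
        np.testing.assert_array_equal(once.probs, twice.probs)

    def test_empty_result_warns_not_raises(self, caplog):
        col = np.zeros(10)  # MAF 0 -> everything excluded
        m = self._matrix([1.0], [col])
        with caplog.at_level("WARNING"):
            out = qc_filter(m)
        assert out.n_snps == 0


class TestSumstatsIO:
    def test_round_trip(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1", "rs2"], "CHR": ["1", "2"], "BP": [100, 200],
            "A1": ["G", "C"], "A2": ["A", "T"],
            "BETA": [0.123456, -0.2], "SE": [0.05, 0.04], "P": [0.01, 0.5],
        })
        write_sumstats(df, tmp_path / "ss.tsv")
        back = read_sumstats(tmp_path / "ss.tsv")
        np.testing.assert_allclose(back["BETA"], df["BETA"], rtol=1e-5)
        assert back["SNP"].tolist() == ["rs1", "rs2"]

    def test_invalid_se_rejected(self, tmp_path):
        df = pd.DataFrame({
            "SNP": ["rs1"], "CHR": ["1"], "BP": [100], "A1": ["G"], "A2": ["A"],
            "BETA": [0.1], "SE": [0.0], "P": [0.5],
        })
        df.to_csv(tmp_path / "bad.tsv", sep="\t", index=False)
        with pytest.raises(ValueError, match="SE"):
            read_sumstats(tmp_path / "bad.tsv")


class TestInvariants:
    def test_hardcall_maf_matches_generating_frequency(self):
        from prstrat.simulate import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(n_cases=1000, n_controls=1000, n_snps=60,
                               n_causal=0, apoe_betas=(0.0, 0.0), ld_rho=0.0,
                               info_range=(1.0, 1.0), seed=9)
        matrix, _, model = simulate_cohort(cfg)
        hc = hard_call(matrix)
        freq = np.nanmean(hc.dosage, axis=0) / 2.0
        maf_called = np.minimum(freq, 1 - freq)
        truth = model.snp_meta["allele_freq_B"].to_numpy()
        truth = np.minimum(truth, 1 - truth)
        assert np.max(np.abs(maf_called - truth)) < 0.02
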