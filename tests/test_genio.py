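import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import stackgs as sg
from stackgs.genio import EmptyQCResultError, GenotypeParseError


VCF_HEADER = """##fileformat=VCFv4.2
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\ts1\ts2\ts3
"""


def _write(path, text):
    path.write_text(text)
    return str(path)


class TestReadGenotypes:
    def test_csv_read_back(self, tmp_path):
        p = _write(tmp_path / "g.csv", "id,m1,m2\na,0,1\nb,2,2\n")
        g = sg.read_genotypes(p, format="csv")
        np.testing.assert_array_equal(g.values, [[0, 1], [2, 2]])
        assert g.sample_ids == ["a", "b"]
        assert g.marker_ids == ["m1", "m2"]

    def test_vcf_gt_mapping_and_missing(self, tmp_path):
        body = (
            "1\t100\trs1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
            "1\t200\trs2\tC\tT\t.\tPASS\t.\tGT\t1/0\t./.\t0|0\n"
        )
        p = _write(tmp_path / "g.vcf", VCF_HEADER + body)
        g = sg.read_genotypes(p, format="vcf")
        assert g.sample_ids == ["s1", "s2", "s3"]
        assert g.marker_ids == ["rs1", "rs2"]
        np.testing.assert_array_equal(g.values[:, 0], [0, 1, 2])
        assert g.values[0, 1] == 1
        assert np.isnan(g.values[1, 1])
        assert g.values[2, 1] == 0

    def test_vcf_multiallelic_rejected(self, tmp_path):
        body = "1\t300\trs3\tA\tG,T\t.\tPASS\t.\tGT\t0/1\t0/2\t1/2\n"
        p = _write(tmp_path / "bad.vcf", VCF_HEADER + body)
        with pytest.raises(GenotypeParseError, match="multi-allelic"):
            sg.read_genotypes(p, format="vcf")

    def test_malformed_csv_raises(self, tmp_path):
        p = _write(tmp_path / "bad.csv", "id,m1\na,zero\n")
        with pytest.raises(GenotypeParseError):
            sg.read_genotypes(p, format="csv")

    @pytest.mark.parametrize("fmt", ["raw", "csv"])
    def test_round_trip(self, tmp_path, small_sim, fmt):
        _, g, _, _ = small_sim
        path = tmp_path / f"rt.{fmt}"
        sg.write_genotypes(g, path, format=fmt)
        back = sg.read_genotypes(path, format=fmt)
        np.testing.assert_array_equal(back.values, g.values)
        assert back.sample_ids == g.sample_ids
        assert back.marker_ids == g.marker_ids

    def test_raw_round_trip_with_missing(self, tmp_path):
        g = sg.GenotypeMatrix(
            np.array([[0.0, np.nan], [2.0, 1.0], [1.0, 0.0]]),
            ["a", "b", "c"],
            ["m1", "m2"],
        )
        path = tmp_path / "miss.raw"
        sg.write_genotypes(g, path, format="raw")
        back = sg.read_genotypes(path, format="raw")
        np.testing.assert_array_equal(np.isnan(back.values), np.isnan(g.values))
        np.testing.assert_array_equal(back.values[~np.isnan(g.values)].ravel(),
                                      g.values[~np.isnan(g.values)].ravel())

    def test_phenotype_round_trip(self, tmp_path, small_sim):
        _, _, y, _ = small_sim
        path = tmp_path / "y.tsv"
        sg.write_phenotypes(y, path)
        back = sg.read_phenotypes(path)
        np.testing.assert_allclose(back.to_numpy(), y.to_numpy())
        assert list(back.index) == list(y.index)


def _geno_from_counts(n0, n1, n2):
    vals = np.concatenate([np.zeros(n0), np.ones(n1), np.full(n2, 2.0)])
    return sg.GenotypeMatrix(vals[:, None], [f"s{i}" for i in range(len(vals))], ["m"])


class TestMarkerStats:
    def test_perfect_hwe_proportions(self):
        st = sg.marker_stats(_geno_from_counts(25, 50, 25))
        assert st["maf"].iloc[0] == pytest.approx(0.5)
        assert st["hwe_p"].iloc[0] == pytest.approx(1.0)

    def test_extreme_hwe_departure(self):
        # chi2 = 25 + 50 + 25 = 100 for (50, 0, 50)
        st = sg.marker_stats(_geno_from_counts(50, 0, 50))
        assert st["hwe_p"].iloc[0] < 1e-20
        assert st["hwe_p"].iloc[0] == pytest.approx(sps.chi2.sf(100.0, 1))

    def test_against_textbook_chi_square(self, small_sim):
        _, g, _, _ = small_sim
        st = sg.marker_stats(g)
        for j in [0, 17, 123]:
            col = g.values[:, j]
            n = len(col)
            counts = [(col == k).sum() for k in (0, 1, 2)]
            p = (counts[1] + 2 * counts[2]) / (2 * n)
            exp = [n * (1 - p) ** 2, 2 * n * p * (1 - p), n * p**2]
            chi2 = sum((o - e) ** 2 / e for o, e in zip(counts, exp) if e > 0)
            assert st["hwe_p"].iloc[j] == pytest.approx(sps.chi2.sf(chi2, 1), abs=1e-12)

    def test_call_rate_and_all_missing(self):
        vals = np.array([[0.0, np.nan], [1.0, np.nan], [2.0, np.nan], [np.nan, np.nan]])
        g = sg.GenotypeMatrix(vals, ["a", "b", "c", "d"], ["m1", "m2"])
        st = sg.marker_stats(g)
        assert st["call_rate"].iloc[0] == pytest.approx(0.75)
        assert st["call_rate"].iloc[1] == 0.0
        assert np.isnan(st["maf"].iloc[1]) and np.isnan(st["hwe_p"].iloc[1])

    def test_sample_order_invariance(self, small_sim):
        _, g, _, _ = small_sim
        rng = np.random.default_rng(0)
        perm = rng.permutation(g.n)
        gp = sg.GenotypeMatrix(
            g.values[perm], [g.sample_ids[i] for i in perm], g.marker_ids
        )
        pd.testing.assert_frame_equal(sg.marker_stats(g), sg.marker_stats(gp))


class TestApplyQC:
    def _planted(self):
        """10 markers, 3 known failures: monomorphic (maf=0), low call rate,
        gross HWE violation."""
        rng = np.random.default_rng(42)
        n = 200
        vals = rng.binomial(2, 0.3, size=(n, 10)).astype(float)
        vals[:, 2] = 0.0  # maf failure
        vals[: n // 2, 5] = np.nan  # call rate 0.5
        vals[:, 8] = np.tile([0.0, 2.0], n // 2)  # no heterozygotes at p=0.5
        return sg.GenotypeMatrix(vals, [f"s{i}" for i in range(n)], [f"m{j}" for j in range(10)])

    def test_planted_failures_counted(self):
        g = self._planted()
        kept, rep = sg.apply_qc(g, sg.QCThresholds(0.05, 0.95, 1e-5))
        assert rep.n_markers_out == 7
        assert kept.m == 7
        assert rep.n_failed_maf == 1
        assert rep.n_failed_cr == 1
        assert rep.n_failed_hwe == 1
        assert "m2" not in kept.marker_ids
        assert "m5" not in kept.marker_ids
        assert "m8" not in kept.marker_ids
        assert kept.marker_ids == [m for m in g.marker_ids if m in kept.marker_ids]

    def test_strict_inequality_at_zero_thresholds(self):
        g = self._planted()
        sub = sg.GenotypeMatrix(
            np.nan_to_num(g.values, nan=0.0), g.sample_ids, g.marker_ids
        )
        kept, rep = sg.apply_qc(sub, sg.QCThresholds(0.0, 0.0, 0.0))
        # only the maf == 0 marker fails "maf > 0"
        assert "m2" not in kept.marker_ids
        assert rep.n_markers_out == 9

    def test_call_rate_threshold(self):
        g = self._planted()
        _, rep = sg.apply_qc(g, sg.QCThresholds(0.0, 0.95, 0.0))
        assert rep.n_failed_cr == 1

    def test_idempotent(self):
        g = self._planted()
        t = sg.QCThresholds(0.05, 0.95, 1e-5)
        once, _ = sg.apply_qc(g, t)
        twice, rep2 = sg.apply_qc(once, t)
        np.testing.assert_array_equal(once.values, twice.values)
        assert rep2.n_markers_in == rep2.n_markers_out

    def test_empty_result_error(self):
        g = self._planted()
        with pytest.raises(EmptyQCResultError):
            sg.apply_qc(g, sg.QCThresholds(0.49, 1.0, 0.99))

    def test_presets(self):
        assert sg.QC_PRESETS["beef"].maf_min == 0.05
        assert sg.QC_PRESETS["beef"].hwe_p_min == 1e-5
        assert sg.QC_PRESETS["dairy"].maf_min == 0.01
        assert sg.QC_PRESETS["dairy"].hwe_p_min == 1e-4


class TestImputeMissing:
    def test_complete_input_unchanged(self, small_sim):
        _, g, _, _ = small_sim
        out = sg.impute_missing(g)
        np.testing.assert_array_equal(out.values, g.values)

    def test_mean_imputation_value(self):
        g = sg.GenotypeMatrix(
            np.array([[0.0], [2.0], [np.nan]]), ["a", "b", "c"], ["m"]
        )
        out = sg.impute_missing(g)
        assert out.values[2, 0] == pytest.approx(1.0)

    def test_allele_frequency_conserved(self):
        rng = np.random.default_rng(1)
        vals = rng.binomial(2, 0.3, size=(100, 20)).astype(float)
        mask = rng.random(vals.shape) < 0.1
        vals[mask] = np.nan
        g = sg.GenotypeMatrix(vals, [f"s{i}" for i in range(100)], [f"m{j}" for j in range(20)])
        before = np.nanmean(g.values, axis=0) / 2
        after = sg.impute_missing(g).values.mean(axis=0) / 2
        np.testing.assert_allclose(after, before, atol=1e-12)

    def test_all_missing_marker_rejected(self):
        g = sg.GenotypeMatrix(
            np.array([[0.0, np.nan], [1.0, np.nan]]), ["a", "b"], ["m1", "m2"]
        )
        with pytest.raises(ValueError, match="all genotypes missing"):
            sg.impute_missing(g)
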