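"""The RAD-style generator: determinism, missingness, depths, calibration."""

import numpy as np
import pytest
from scipy import stats as sps

from conftest import folded_neutral_expectation
from demearc.models import ConstraintError
from demearc.sitetable import MISSING, write_vcf
from demearc.synthdata import (
    SimulationConfig,
    apply_missingness,
    assign_depths,
    generate,
    simulate_dataset,
)

CONST_10K = {"N_DEME": 1e4, "N_ANC": 1e4, "T_0": 5000.0}


class TestConfigValidation:
    @pytest.mark.parametrize("kwargs", [
        {"n_loci": 0},
        {"locus_length_bp": 0},
        {"mu": 0.0},
        {"samples_per_deme": (0,)},
        {"missing_rate": 1.0},
        {"locus_dropout_rate": -0.1},
        {"depth_mean_range": (0.0, 10.0)},
        {"depth_mean_range": (20.0, 10.0)},
    ])
    def test_invalid_rejected(self, kwargs):
        base = dict(n_loci=10, samples_per_deme=(4,), mu=1e-8)
        base.update(kwargs)
        with pytest.raises(ValueError):
            SimulationConfig(**base)

    def test_deme_count_must_match_model(self):
        config = SimulationConfig(n_loci=5, samples_per_deme=(4, 4), mu=1e-8)
        with pytest.raises(ValueError, match="deme"):
            simulate_dataset("CONST", CONST_10K, config)

    def test_constraint_violations_named(self):
        config = SimulationConfig(n_loci=5, samples_per_deme=(4,), mu=1e-8)
        with pytest.raises(ConstraintError, match="N_ANC_range"):
            simulate_dataset("CONST", {**CONST_10K, "N_ANC": 5e4}, config)


class TestDeterminism:
    def test_same_seed_byte_identical_export(self, tmp_path):
        config = SimulationConfig(
            n_loci=120, samples_per_deme=(5,), mu=2.8e-7,
            missing_rate=0.2, locus_dropout_rate=0.1, rng_seed=9)
        paths = []
        for name in ("a.vcf", "b.vcf"):
            data = generate("CONST", CONST_10K, config)
            write_vcf(data.site_table, tmp_path / name)
            paths.append(tmp_path / name)
        assert paths[0].read_bytes() == paths[1].read_bytes()

    def test_truth_file_records_model_and_seed(self, tmp_path, small_dataset):
        small_dataset.write_truth(tmp_path / "truth.txt")
        text = (tmp_path / "truth.txt").read_text()
        assert "model = CONST" in text
        assert "param.N_DEME = 10000" in text
        assert "rng_seed = 42" in text


class TestMissingness:
    @staticmethod
    def _clean(n_loci=400, n_ind=10, seed=1):
        config = SimulationConfig(
            n_loci=n_loci, samples_per_deme=(n_ind,), mu=2.8e-7,
            missing_rate=0.0, rng_seed=seed)
        return simulate_dataset("CONST", CONST_10K, config)

    def test_zero_rates_identity(self):
        data = self._clean(50)
        out = apply_missingness(data, 0.0, 0.0, rng_seed=3)
        assert out.site_table is data.site_table

    def test_realized_rate_within_two_points(self):
        data = self._clean(1200, 10)
        out = apply_missingness(data, 0.30, 0.10, rng_seed=4)
        realized = (out.site_table.genotypes == MISSING).mean()
        expected = 0.10 + 0.90 * 0.30
        assert abs(realized - expected) < 0.02

    def test_pure_genotype_dropout_band(self):
        data = self._clean(1000, 10)
        out = apply_missingness(data, 0.35, 0.0, rng_seed=5)
        realized = (out.site_table.genotypes == MISSING).mean()
        assert 0.33 <= realized <= 0.37

    def test_total_locus_dropout_blanks_everything(self):
        data = self._clean(30)
        out = apply_missingness(data, 0.0, 1.0, rng_seed=6)
        assert (out.site_table.genotypes == MISSING).all()

    def test_rate_of_one_rejected(self):
        data = self._clean(10)
        with pytest.raises(ValueError):
            apply_missingness(data, 1.0, 0.0, rng_seed=1)


class TestDepths:
    def test_sample_means_in_band_at_low_dispersion(self):
        config = SimulationConfig(
            n_loci=10, samples_per_deme=(6,), mu=2.8e-7, missing_rate=0.0,
            rng_seed=7)
        data = simulate_dataset("CONST", CONST_10K, config)
        out = assign_depths(data, (30.0, 30.0), rng_seed=8, dispersion=0.05)
        means = out.site_table.depth.mean(axis=0)
        assert ((means >= 27) & (means <= 33)).all()

    def test_missing_genotypes_get_zero_depth(self):
        config = SimulationConfig(
            n_loci=40, samples_per_deme=(6,), mu=2.8e-7, missing_rate=0.0,
            rng_seed=9)
        data = simulate_dataset("CONST", CONST_10K, config)
        data = apply_missingness(data, 0.3, 0.0, rng_seed=10)
        out = assign_depths(data, (18.0, 77.0), rng_seed=11)
        missing = out.site_table.genotypes == MISSING
        assert (out.site_table.depth[missing] == 0).all()
        assert (out.site_table.depth[~missing] >= 0).all()

    def test_same_seed_identical_depths(self):
        data = self._dataset()
        a = assign_depths(data, (18.0, 77.0), rng_seed=12)
        b = assign_depths(data, (18.0, 77.0), rng_seed=12)
        assert np.array_equal(a.site_table.depth, b.site_table.depth)

    @staticmethod
    def _dataset():
        config = SimulationConfig(
            n_loci=30, samples_per_deme=(5,), mu=2.8e-7, missing_rate=0.0,
            rng_seed=13)
        return simulate_dataset("CONST", CONST_10K, config)

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            assign_depths(self._dataset(), (0.0, 10.0), rng_seed=1)


class TestCoalescentCalibration:
    def test_pi_matches_4Nmu_within_three_se(self):
        # scaled-up mutation rate keeps the check fast; E[pi] = 4 N mu
        config = SimulationConfig(
            n_loci=1500, samples_per_deme=(10,), mu=2.8e-7,
            missing_rate=0.0, rng_seed=14)
        data = simulate_dataset("CONST", CONST_10K, config)
        table = data.site_table
        ref_n, alt_n = table.allele_counts()
        n_lin = ref_n + alt_n
        num = ref_n.astype(float) * alt_n
        den = n_lin.astype(float) * (n_lin - 1) / 2
        per_locus_num = np.bincount(table.locus_index, weights=num)
        per_locus_den = np.bincount(table.locus_index, weights=den)
        per_locus_pi = per_locus_num / per_locus_den
        pi_hat = num.sum() / den.sum()
        se = per_locus_pi.std(ddof=1) / np.sqrt(len(per_locus_pi))
        expected = 4 * 1e4 * 2.8e-7
        assert abs(pi_hat - expected) <= 3 * se

    def test_folded_sfs_consistent_with_neutral_shape(self):
        # one seed at ~12k segregating sites; the 20-seed version of this
        # check runs in the acceptance suite at the 5,000-locus scale
        config = SimulationConfig(
            n_loci=25_000, samples_per_deme=(10,), mu=2.8e-8,
            missing_rate=0.0, rng_seed=15)
        data = simulate_dataset("CONST", CONST_10K, config)
        table = data.site_table
        ref_n, alt_n = table.allele_counts()
        minor = np.minimum(ref_n, alt_n)[table.is_variant]
        counts = np.bincount(minor, minlength=11)[1:]
        probs = folded_neutral_expectation(20)
        stat, p = sps.chisquare(counts, counts.sum() * probs)
        assert counts.sum() > 10_000
        assert p > 0.01

    def test_zero_divergence_symmetry(self):
        from demearc.divstats import dxy_between, pi_within

        config = SimulationConfig(
            n_loci=800, samples_per_deme=(6, 6), mu=2.8e-7,
            missing_rate=0.0, rng_seed=16)
        data = simulate_dataset(
            "ISO1", {"N_DEME1": 1e4, "N_DEME2": 1e4, "N_ANC": 1e4,
                     "T_DIV": 10.0}, config)
        table = data.site_table
        a = [s for s in table.samples if s.startswith("deme1_")]
        b = [s for s in table.samples if s.startswith("deme2_")]
        dxy = dxy_between(table, a, b, 0.5).value
        pi_a = pi_within(table, a, 0.5).value
        pi_b = pi_within(table, b, 0.5).value
        assert dxy == pytest.approx((pi_a + pi_b) / 2, rel=0.1)

    def test_dxy_nondecreasing_in_divergence_time(self):
        from demearc.divstats import dxy_between

        means = []
        for tdiv in (200.0, 1500.0, 6000.0):
            values = []
            for rep in range(6):
                config = SimulationConfig(
                    n_loci=250, samples_per_deme=(4, 4), mu=2.8e-7,
                    missing_rate=0.0, rng_seed=1000 + 17 * rep + int(tdiv))
                data = simulate_dataset(
                    "ISO1", {"N_DEME1": 1e4, "N_DEME2": 1e4, "N_ANC": 1e4,
                             "T_DIV": tdiv}, config)
                table = data.site_table
                a = [s for s in table.samples if s.startswith("deme1_")]
                b = [s for s in table.samples if s.startswith("deme2_")]
                values.append(dxy_between(table, a, b, 0.5).value)
            means.append(np.mean(values))
        assert means[0] < means[1] < means[2]


def test_multiallelic_sites_are_dropped_and_counted():
    config = SimulationConfig(
        n_loci=300, samples_per_deme=(8,), mu=5e-6, missing_rate=0.0,
        rng_seed=18)
    data = simulate_dataset("CONST", CONST_10K, config)
    table = data.site_table
    assert data.site_table.n_multiallelic_dropped > 0
    ref_n, alt_n = table.allele_counts()
    assert ((table.genotypes <= 2) & (table.genotypes >= -1)).all()
    assert (alt_n[~table.is_variant] == 0).all()
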