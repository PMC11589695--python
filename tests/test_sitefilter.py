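"""Depth masking, presence/MAC filters, thinning and the theta filter."""

import numpy as np
import pytest

from conftest import make_table, random_genotypes
from demearc.sitefilter import (
    DepthMaskError,
    LocusThetaRecord,
    apply_blacklist,
    filter_mac,
    filter_site_presence,
    flag_overmerged,
    locus_theta,
    mask_by_depth,
    read_blacklist,
    recompute_alleles,
    thin_first_variant,
    write_blacklist,
)
from demearc.sitetable import MISSING


class TestMaskByDepth:
    def test_constant_depth_no_masking(self):
        g = np.zeros((40, 4), dtype=np.int8)
        table = make_table(g, depth=np.full((40, 4), 20))
        masked, report = mask_by_depth(table, min_dp=5, high_percentile=0.975)
        assert report["rule_low_dp_masked"] == 0
        assert report["rule_high_dp_masked"] == 0
        assert np.array_equal(masked.genotypes, table.genotypes)

    def test_jittered_depth_masks_at_most_quantile_share(self):
        rng = np.random.default_rng(0)
        n_sites, n_samples = 400, 6
        depth = 20 + rng.integers(0, 12, size=(n_sites, n_samples))
        table = make_table(np.zeros((n_sites, n_samples), np.int8), depth=depth)
        _, report = mask_by_depth(table, min_dp=0, high_percentile=0.975)
        per_sample_cap = int(np.ceil(0.025 * n_sites))
        assert report["rule_high_dp_masked"] <= per_sample_cap * n_samples

    def test_single_low_genotype_masked(self):
        depth = np.full((3, 3), 20)
        depth[1, 2] = 4
        table = make_table(np.ones((3, 3), np.int8), depth=depth)
        masked, report = mask_by_depth(table, min_dp=5, high_percentile=1.0)
        assert report["rule_low_dp_masked"] == 1
        assert masked.genotypes[1, 2] == MISSING
        untouched = np.ones((3, 3), bool)
        untouched[1, 2] = False
        assert (masked.genotypes[untouched] == 1).all()

    def test_identity_settings(self):
        rng = np.random.default_rng(1)
        depth = rng.integers(0, 50, size=(30, 4))
        table = make_table(np.ones((30, 4), np.int8), depth=depth)
        masked, _ = mask_by_depth(table, min_dp=0, high_percentile=1.0)
        assert np.array_equal(masked.genotypes, table.genotypes)

    def test_missing_depth_is_configuration_error(self):
        table = make_table(np.ones((2, 2), np.int8))
        with pytest.raises(DepthMaskError, match="disable"):
            mask_by_depth(table)


class TestRecomputeAlleles:
    def test_fully_masked_alt_becomes_invariant(self):
        table = make_table([[1, 0, MISSING], [1, 1, 0]])
        g = table.genotypes.copy()
        g[0] = [MISSING, 0, MISSING]  # the only ALT copy is now masked
        table = make_table(g)
        table.alt[0] = "T"
        out = recompute_alleles(table)
        assert out.alt[0] == "."
        assert out.alt[1] == "T"

    def test_fixed_alt_relabelled(self):
        table = make_table([[2, 2, 2]], alt=np.array(["T"], object))
        out = recompute_alleles(table)
        assert out.alt[0] == "."
        assert out.ref[0] == "T"
        assert (out.genotypes[0] == 0).all()


class TestPresenceFilter:
    def test_at_least_boundary(self):
        # 10 individuals; genotyped in 5 -> retained at 50%, in 4 -> dropped
        g5 = [0] * 5 + [MISSING] * 5
        g4 = [0] * 4 + [MISSING] * 6
        table = make_table([g5, g4])
        out = filter_site_presence(table, 0.5, table.samples)
        assert out.n_sites == 1
        assert out.positions[0] == table.positions[0]

    def test_full_presence_on_gappy_table_empties(self, caplog):
        table = make_table([[0, MISSING], [MISSING, 0]])
        with caplog.at_level("WARNING", logger="demearc"):
            out = filter_site_presence(table, 1.0, table.samples)
        assert out.n_sites == 0
        assert any("removed every site" in r.message for r in caplog.records)

    def test_empty_scope_rejected(self):
        table = make_table([[0, 0]])
        with pytest.raises(ValueError, match="nonempty"):
            filter_site_presence(table, 0.5, [])


class TestMacFilter:
    @pytest.mark.parametrize("dosages,min_mac,kept", [
        # minor allele count 2 (singleton-adjacent) < 3 -> removed
        ([1, 1] + [0] * 8, 3, False),
        ([1] * 10, 3, True),   # counts (10, 10)
        ([1, 1] + [0] * 8, 0, True),
    ])
    def test_mac_rule(self, dosages, min_mac, kept):
        table = make_table([dosages])
        out = filter_mac(table, min_mac)
        assert (out.n_sites == 1) is kept

    def test_invariant_sites_untouched(self):
        table = make_table([[0, 0, 0], [1, 0, 0]])
        out = filter_mac(table, 3)
        assert list(out.alt) == ["."]


class TestThinning:
    def test_first_variant_kept(self):
        # locus 1: invariant at 5, variants at 12 and 40; locus 2: variant at 7
        table = make_table(
            [[0, 0], [0, 1], [1, 1], [1, 0]],
            locus_index=[0, 0, 0, 1],
            positions=[5, 12, 40, 7],
        )
        out = thin_first_variant(table)
        assert out.n_sites == 2
        assert list(out.positions) == [12, 7]
        assert out.is_variant.all()

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        table = make_table(
            random_genotypes(rng, 30, 4, missing=0.2),
            locus_index=rng.integers(0, 10, 30), n_loci=10)
        once = thin_first_variant(table)
        twice = thin_first_variant(once)
        assert np.array_equal(once.genotypes, twice.genotypes)
        assert np.array_equal(once.positions, twice.positions)

    def test_locus_without_variants_contributes_nothing(self):
        table = make_table([[0, 0]], locus_index=[0])
        assert thin_first_variant(table).n_sites == 0


class TestLocusTheta:
    def test_watterson_value(self):
        # locus with S = 5 variant sites, 2 diploids fully genotyped (n = 4)
        g = np.ones((5, 2), np.int8)
        table = make_table(g, locus_index=[0] * 5)
        (rec,) = locus_theta(table)
        assert rec.S == 5
        assert rec.n_bar == 4.0
        assert rec.theta_w == pytest.approx(5 / (1 + 1 / 2 + 1 / 3))
        assert rec.theta_w == pytest.approx(2.7273, abs=1e-4)

    def test_zero_segregating_sites(self):
        table = make_table([[0, 0], [0, 0]])
        (rec,) = locus_theta(table)
        assert rec.S == 0 and rec.theta_w == 0.0

    def test_theta_decreasing_in_n(self):
        thetas = []
        for n_dip in (2, 4, 8):
            g = np.ones((3, n_dip), np.int8)
            (rec,) = locus_theta(make_table(g))
            thetas.append(rec.theta_w)
        assert thetas == sorted(thetas, reverse=True)

    def test_uncomputable_when_no_lineages(self):
        g = np.array([[MISSING, MISSING]], np.int8)
        (rec,) = locus_theta(make_table(g))
        assert not rec.computable


class TestOvermergeFlag:
    @staticmethod
    def _records(values):
        return [LocusThetaRecord(f"locus_{i}", 1, 4.0, v, True)
                for i, v in enumerate(values, 1)]

    def test_linear_grid_top_five(self):
        records = self._records([i / 1000 for i in range(1, 1001)])
        flagged = flag_overmerged(records, 0.995)
        assert flagged == {f"locus_{i}" for i in range(996, 1001)}

    def test_all_equal_flags_nothing(self):
        assert flag_overmerged(self._records([1.0] * 300)) == set()

    def test_flag_count_bound(self):
        rng = np.random.default_rng(3)
        for pct in (0.9, 0.995):
            values = rng.exponential(1.0, size=700)
            flagged = flag_overmerged(self._records(values), pct)
            assert len(flagged) <= int(np.ceil((1 - pct) * 700)) + 1

    def test_exchangeable_flag_rate_near_half_percent(self):
        rng = np.random.default_rng(4)
        records = self._records(rng.gamma(2.0, 1.0, size=10_000))
        flagged = flag_overmerged(records, 0.995)
        # binomial(10000, 0.005) central 95% interval
        assert 36 <= len(flagged) <= 64

    def test_few_loci_warns(self, caplog):
        with caplog.at_level("WARNING", logger="demearc"):
            flag_overmerged(self._records([1.0, 2.0, 3.0]))
        assert any("unstable" in r.message for r in caplog.records)


class TestBlacklist:
    def test_identity_and_total_removal(self):
        rng = np.random.default_rng(5)
        table = make_table(random_genotypes(rng, 20, 3),
                           locus_index=rng.integers(0, 5, 20), n_loci=5)
        same, report = apply_blacklist(table, set())
        assert same.n_sites == table.n_sites and report["n_sites_removed"] == 0
        empty, _ = apply_blacklist(table, set(map(str, table.locus_names)))
        assert empty.n_sites == 0

    def test_unknown_ids_warn_and_are_ignored(self, caplog):
        table = make_table([[0, 1]], locus_index=[0])
        with caplog.at_level("WARNING", logger="demearc"):
            out, report = apply_blacklist(table, {"locus_1", "nope"})
        assert out.n_sites == 0
        assert report["n_unknown_ids"] == 1

    def test_blacklist_of_180_removes_exactly_180_loci(self):
        # one site per locus over a 19,294-locus table
        n_loci = 19_294
        g = np.zeros((n_loci, 2), np.int8)
        table = make_table(g, locus_index=np.arange(n_loci), n_loci=n_loci)
        blacklist = {f"locus_{i}" for i in range(1, 181)}
        out, report = apply_blacklist(table, blacklist)
        assert report["n_loci_with_sites_removed"] == 180
        assert out.n_sites == n_loci - 180

    def test_file_roundtrip(self, tmp_path):
        ids = {"locus_2", "locus_10"}
        write_blacklist(ids, tmp_path / "bl.txt")
        assert read_blacklist(tmp_path / "bl.txt") == ids


def test_filter_composition_yields_subset_and_preserves_genotypes():
    rng = np.random.default_rng(6)
    g = random_genotypes(rng, 100, 6, missing=0.3)
    depth = rng.integers(0, 60, size=g.shape)
    table = make_table(g, depth=depth,
                       locus_index=rng.integers(0, 20, 100), n_loci=20)
    masked, _ = mask_by_depth(table, 5, 0.975)
    out = filter_mac(filter_site_presence(masked, 0.5, table.samples), 2)
    # retained sites are a subset with unchanged retained genotype values
    key = {(int(l), int(p)): i for i, (l, p) in
           enumerate(zip(table.locus_index, table.positions))}
    for i in range(out.n_sites):
        src = key[(int(out.locus_index[i]), int(out.positions[i]))]
        orig = masked.genotypes[src]
        assert np.array_equal(out.genotypes[i], orig)
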