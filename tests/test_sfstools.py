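"""Projection, folding, spectrum construction and eligibility rules."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import folded_projection_oracle, make_table, random_genotypes
from demearc.sfstools import (
    FoldedSFS,
    JointFoldedSFS,
    build_folded_sfs,
    build_joint_folded_sfs,
    check_eligibility,
    choose_projection,
    fold_2d,
    project_site,
    read_sfs,
    site_allele_counts,
    write_sfs,
)
from demearc.sitetable import MISSING


class TestProjectSite:
    def test_hypergeometric_example(self):
        v = project_site(d=1, n=4, m=2)
        assert v == pytest.approx([0.5, 0.5, 0.0])

    def test_identity_projection_is_indicator(self):
        v = project_site(d=3, n=6, m=6)
        expected = np.zeros(7)
        expected[3] = 1.0
        assert v == pytest.approx(expected)

    def test_monomorphic_site_projects_to_zero_class(self):
        v = project_site(d=0, n=8, m=4)
        assert v[0] == pytest.approx(1.0)
        assert v[1:] == pytest.approx(np.zeros(4))

    def test_projection_larger_than_sample_rejected(self):
        with pytest.raises(ValueError):
            project_site(1, 4, 6)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(st.integers(2, 20).flatmap(
        lambda n: st.tuples(st.just(n), st.integers(0, n), st.integers(2, n))))
    def test_vectors_sum_to_one(self, ndm):
        n, d, m = ndm
        assert project_site(d, n, m).sum() == pytest.approx(1.0, abs=1e-12)


class TestSiteAlleleCounts:
    def test_presence_boundary_inclusive(self):
        # 10 individuals, threshold 0.7: 7 genotyped kept, 6 dropped
        g7 = [1] * 7 + [MISSING] * 3
        g6 = [1] * 6 + [MISSING] * 4
        table = make_table([g7, g6], locus_index=[0, 1], n_loci=2)
        (minor,), (lineages,), kept = site_allele_counts(
            table, [table.samples], 0.7)
        assert len(kept) == 1
        assert lineages[0] == 14

    def test_known_counts(self):
        g = np.array([[0, 1, 2, MISSING], [2, 2, 1, 2]], np.int8)
        table = make_table(g, locus_index=[0, 1], n_loci=2)
        (minor,), (lineages,), kept = site_allele_counts(
            table, [table.samples], 0.5)
        # site 1: alt 3 of 6 -> minor is ALT (tie) = 3
        # site 2: alt 7 of 8 -> minor is REF = 1
        assert list(minor) == [3, 1]
        assert list(lineages) == [6, 8]

    def test_overlapping_demes_rejected(self):
        table = make_table([[0, 1]])
        with pytest.raises(ValueError, match="overlap"):
            site_allele_counts(table, [table.samples, table.samples], 0.5)


class TestBuildFoldedSfs:
    def test_monomorphic_only_mass_in_entry_zero(self):
        table = make_table(np.zeros((10, 6), np.int8))
        # no variant sites at all -> empty spectrum
        sfs = build_folded_sfs(table, table.samples, 3, 0.7)
        assert sfs.counts[1:] == pytest.approx(np.zeros(3))

    def test_identity_projection_then_fold(self):
        g = np.array([[1] * 3 + [0] * 3], np.int8)  # d = 3 of n = 12
        table = make_table(g)
        sfs = build_folded_sfs(table, table.samples, 6, 0.5)
        expected = np.zeros(7)
        expected[3] = 1.0
        assert sfs.counts == pytest.approx(expected)

    def test_matches_exhaustive_subsample_oracle(self):
        rng = np.random.default_rng(21)
        g = rng.binomial(2, rng.uniform(0.1, 0.9, 100)[:, None],
                         size=(100, 4)).astype(np.int8)
        table = make_table(g, locus_index=np.arange(100), n_loci=100)
        sfs = build_folded_sfs(table, table.samples, 2, min_presence=1.0)
        (minor,), (lineages,), kept = site_allele_counts(
            table, [table.samples], 1.0)
        oracle = folded_projection_oracle(minor, 8, 4)
        assert sfs.counts == pytest.approx(oracle, abs=1e-9)

    def test_mass_conservation(self):
        rng = np.random.default_rng(22)
        g = random_genotypes(rng, 200, 8, missing=0.2)
        table = make_table(g, locus_index=np.arange(200), n_loci=200)
        sfs = build_folded_sfs(table, table.samples, 5, 0.7)
        total = sfs.counts.sum()
        assert total == pytest.approx(sfs.provenance["n_sites_used"])

    def test_low_coverage_sites_dropped_not_fatal(self):
        g = np.array([[1, 1, MISSING, MISSING]], np.int8)
        table = make_table(g)
        sfs = build_folded_sfs(table, table.samples, 3, min_presence=0.25)
        assert sfs.provenance["n_sites_dropped_low_coverage"] == 1

    def test_presence_monotonicity(self):
        rng = np.random.default_rng(23)
        g = random_genotypes(rng, 300, 8, missing=0.35)
        table = make_table(g, locus_index=np.arange(300), n_loci=300)
        retained = []
        for presence in (0.5, 0.7, 0.9):
            (minor,), _, kept = site_allele_counts(
                table, [table.samples], presence)
            retained.append(len(kept))
        assert retained == sorted(retained, reverse=True)


class TestJointFoldedSfs:
    def test_fixed_difference_lands_in_folded_corner_cell(self):
        g = np.array([[0] * 6 + [2] * 6], np.int8)
        table = make_table(g)
        jsfs = build_joint_folded_sfs(
            table, table.samples[:6], table.samples[6:], 6, 0.5)
        assert jsfs.counts[0, 12] == pytest.approx(1.0)
        assert jsfs.segregating_mass == pytest.approx(1.0)

    def test_symmetric_demes_give_fold_transpose_symmetry(self):
        rng = np.random.default_rng(24)
        half = rng.binomial(2, rng.uniform(0.1, 0.9, 150)[:, None],
                            size=(150, 6)).astype(np.int8)
        g = np.hstack([half, half])
        table = make_table(g, locus_index=np.arange(150), n_loci=150)
        ab = build_joint_folded_sfs(
            table, table.samples[:6], table.samples[6:], 6, 0.5)
        ba = build_joint_folded_sfs(
            table, table.samples[6:], table.samples[:6], 6, 0.5)
        assert ab.counts == pytest.approx(ba.counts.T)

    def test_mass_conservation(self):
        rng = np.random.default_rng(25)
        g = random_genotypes(rng, 250, 14, missing=0.15)
        table = make_table(g, locus_index=np.arange(250), n_loci=250)
        jsfs = build_joint_folded_sfs(
            table, table.samples[:7], table.samples[7:], 6, 0.7)
        unmasked_plus_monomorphic = jsfs.counts.sum()
        assert unmasked_plus_monomorphic == pytest.approx(
            jsfs.provenance["n_sites_used"])

    def test_corners_masked(self):
        table = make_table(np.array([[1] * 12], np.int8))
        jsfs = build_joint_folded_sfs(
            table, table.samples[:6], table.samples[6:], 6, 0.5)
        assert jsfs.mask[0, 0] and jsfs.mask[12, 12]


def test_fold_2d_pairs_and_center():
    u = np.arange(25, dtype=float).reshape(5, 5)
    folded, kept = fold_2d(u)
    assert folded.sum() == pytest.approx(u.sum())
    assert kept[2, 2]  # self-symmetric centre keeps its own mass
    assert folded[2, 2] == u[2, 2]
    assert folded[0, 1] == u[0, 1] + u[4, 3]
    assert not kept[4, 3]


class TestChooseProjection:
    def test_picks_feasible_candidate_and_records_choice(self, small_dataset):
        from demearc.sitefilter import thin_first_variant

        table = thin_first_variant(small_dataset.site_table)
        sfs = choose_projection(table, table.samples, (5, 6, 7), 0.7)
        assert sfs.provenance["projection_individuals"] in (5, 6, 7)
        assert sfs.provenance["projection_candidates"] == [5, 6, 7]

    def test_infeasible_candidates_rejected(self):
        table = make_table([[0, 1, 1]])
        with pytest.raises(ValueError):
            choose_projection(table, table.samples, (5, 6, 7))


class TestEligibility:
    def test_small_deme_ineligible(self):
        sfs = FoldedSFS(np.zeros(6), 10, provenance={"n_sites_used": 5000})
        report = check_eligibility(sfs, 6)
        assert not report.eligible
        assert any("6 sampled individuals" in r for r in report.reasons)

    def test_pair_variant_boundary(self):
        def jsfs_with(n_sites):
            counts = np.zeros((13, 13))
            _, kept = fold_2d(counts)
            return JointFoldedSFS(counts, 12, 12, kept,
                                  provenance={"n_sites_used": n_sites})
        assert not check_eligibility(jsfs_with(1999), (8, 8)).eligible
        assert check_eligibility(jsfs_with(2000), (8, 8)).eligible

    def test_eligible_pair(self):
        counts = np.zeros((13, 13))
        _, kept = fold_2d(counts)
        jsfs = JointFoldedSFS(counts, 12, 12, kept,
                              provenance={"n_sites_used": 3000})
        report = check_eligibility(jsfs, (8, 10))
        assert report.eligible and report.reasons == ()


class TestSfsIO:
    def test_1d_roundtrip(self, tmp_path):
        sfs = FoldedSFS(np.array([3.0, 10.5, 4.25, 2.0]), 6,
                        provenance={"deme": "d1"})
        write_sfs(sfs, tmp_path / "sfs.txt")
        back = read_sfs(tmp_path / "sfs.txt")
        assert back.n_lineages == 6
        assert back.counts == pytest.approx(sfs.counts)
        assert back.monomorphic_masked

    def test_2d_roundtrip(self, tmp_path):
        rng = np.random.default_rng(26)
        raw = rng.random((5, 5))
        counts, kept = fold_2d(raw)
        jsfs = JointFoldedSFS(counts, 4, 4, kept)
        write_sfs(jsfs, tmp_path / "jsfs.txt")
        back = read_sfs(tmp_path / "jsfs.txt")
        assert back.counts == pytest.approx(jsfs.counts)
        assert np.array_equal(back.mask, jsfs.mask)
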