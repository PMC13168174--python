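"""Marker QC, imputation, GRM, PCA, and file round-trips."""
import numpy as np
import pandas as pd
import pytest

import soyclass as sc
from soyclass.markers import EmptyMarkerSetError

from conftest import make_markers


class TestQCFilter:
    def test_removes_monomorphic_and_high_missing(self, rng):
        # 10 markers: 2 monomorphic, 1 with 25% missing, 7 clean
        n = 20
        codes = rng.integers(0, 3, size=(n, 10)).astype(float)
        codes[:, 0] = 2.0
        codes[:, 1] = 0.0
        codes[:5, 2] = np.nan  # 25% missing
        for j in range(3, 10):   # ensure polymorphic
            codes[0, j], codes[1, j] = 0.0, 2.0
        filtered, log = sc.qc_filter(make_markers(codes))
        assert filtered.n_markers == 7
        assert set(log["marker_id"]) == {"m0", "m1", "m2"}
        assert "monomorphic" in log.set_index("marker_id").loc["m0", "reason"]

    def test_boundary_twenty_percent_missing_removed(self, rng):
        codes = rng.integers(0, 3, size=(10, 3)).astype(float)
        for j in range(3):
            codes[0, j], codes[1, j] = 0.0, 2.0
        codes[2:4, 0] = np.nan  # exactly 20% missing -> removed (inclusive)
        codes[2, 1] = np.nan    # 10% -> kept
        filtered, log = sc.qc_filter(make_markers(codes), max_missing=0.20)
        assert list(filtered.marker_ids) == ["m1", "m2"]

    def test_clean_matrix_is_identity(self, rng):
        codes = rng.integers(0, 3, size=(15, 8)).astype(float)
        codes[0], codes[1] = 0.0, 2.0
        filtered, log = sc.qc_filter(make_markers(codes))
        assert filtered.n_markers == 8 and log.empty
        np.testing.assert_array_equal(filtered.codes, codes)

    def test_all_removed_is_an_error(self):
        codes = np.full((6, 4), 1.0)
        with pytest.raises(EmptyMarkerSetError):
            sc.qc_filter(make_markers(codes))


class TestImputation:
    def test_complete_matrix_unchanged(self, rng):
        codes = rng.integers(0, 3, size=(12, 6)).astype(float)
        out = sc.impute_markers(make_markers(codes), seed=0)
        np.testing.assert_array_equal(out.codes, codes)

    def test_perfect_predictor_recovered_exactly(self, rng):
        # marker 1 is an exact copy of marker 0 with 10% of its cells masked
        n = 60
        codes = rng.integers(0, 3, size=(n, 8)).astype(float)
        codes[:, 1] = codes[:, 0]
        mask = rng.choice(n, size=6, replace=False)
        truth = codes[:, 1].copy()
        codes[mask, 1] = np.nan
        out = sc.impute_markers(make_markers(codes), seed=7, n_trees=60)
        np.testing.assert_array_equal(out.codes[:, 1], truth)

    def test_beats_mode_filling(self):
        """Aggregate per-cell match rate over seeds is at least mode-filling's."""
        hits_rf = hits_mode = total = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            truth = r.integers(0, 3, size=(50, 100)).astype(float)
            # correlated block structure so markers carry signal about each other
            truth[:, 1::2] = truth[:, ::2]
            codes = truth.copy()
            miss = r.random(codes.shape) < 0.05
            codes[miss] = np.nan
            out = sc.impute_markers(make_markers(codes), seed=seed,
                                    n_trees=25, max_iter=1)
            modes = np.array([pd.Series(codes[:, j]).mode().iloc[0]
                              for j in range(codes.shape[1])])
            hits_rf += int((out.codes[miss] == truth[miss]).sum())
            hits_mode += int((np.broadcast_to(modes, codes.shape)[miss] == truth[miss]).sum())
            total += int(miss.sum())
        assert hits_rf >= hits_mode

    def test_observed_cells_never_altered(self, rng):
        codes = rng.integers(0, 3, size=(30, 12)).astype(float)
        miss = rng.random(codes.shape) < 0.1
        masked = codes.copy()
        masked[miss] = np.nan
        out = sc.impute_markers(make_markers(masked), seed=3, n_trees=20)
        np.testing.assert_array_equal(out.codes[~miss], codes[~miss])
        assert not np.isnan(out.codes).any()

    def test_deterministic_given_seed(self, rng):
        codes = rng.integers(0, 3, size=(30, 10)).astype(float)
        codes[rng.random(codes.shape) < 0.1] = np.nan
        a = sc.impute_markers(make_markers(codes), seed=5, n_trees=20)
        b = sc.impute_markers(make_markers(codes), seed=5, n_trees=20)
        np.testing.assert_array_equal(a.codes, b.codes)

    def test_all_missing_column_rejected(self, rng):
        codes = rng.integers(0, 3, size=(10, 4)).astype(float)
        codes[:, 2] = np.nan
        with pytest.raises(ValueError, match="every cell missing"):
            sc.impute_markers(make_markers(codes))


class TestGRM:
    def test_hand_computed_two_genotype_example(self):
        # one marker coded (0, 2): p = 0.5, denominator = 0.5
        grm = sc.compute_grm(make_markers([[0.0], [2.0]]))
        assert grm.denom == pytest.approx(0.5)
        np.testing.assert_allclose(grm.values, [[2.0, -2.0], [-2.0, 2.0]])

    def test_duplicated_rows_share_relationship(self, rng):
        codes = rng.integers(0, 3, size=(6, 40)).astype(float)
        codes[3] = codes[2]
        G = sc.compute_grm(make_markers(codes)).values
        assert G[2, 2] == pytest.approx(G[3, 3], abs=1e-12)
        assert G[2, 3] == pytest.approx(G[2, 2], abs=1e-12)

    def test_matches_bruteforce_loop(self, rng):
        M = rng.integers(0, 3, size=(10, 50)).astype(float)
        grm = sc.compute_grm(make_markers(M))
        p = M.mean(axis=0) / 2
        denom = 2 * np.sum(p * (1 - p))
        Z = M - 2 * p
        for i in range(10):
            for k in range(10):
                expect = sum(Z[i, j] * Z[k, j] for j in range(50)) / denom
                assert grm.values[i, k] == pytest.approx(expect, abs=1e-10)

    def test_invariant_to_marker_and_genotype_order(self, rng):
        M = rng.integers(0, 3, size=(8, 30)).astype(float)
        perm_m = rng.permutation(30)
        perm_g = rng.permutation(8)
        base = sc.compute_grm(make_markers(M)).values
        shuffled = sc.compute_grm(make_markers(M[np.ix_(perm_g, perm_m)])).values
        np.testing.assert_allclose(shuffled, base[np.ix_(perm_g, perm_g)], atol=1e-10)

    def test_monomorphic_input_rejected(self):
        with pytest.raises(ValueError, match="denominator"):
            sc.compute_grm(make_markers(np.full((5, 3), 2.0)))

    def test_missing_input_rejected(self):
        codes = np.array([[0.0, np.nan], [2.0, 1.0]])
        with pytest.raises(ValueError, match="complete"):
            sc.compute_grm(make_markers(codes))

    def test_qc_then_grm_never_divides_by_zero(self, rng):
        codes = rng.integers(0, 3, size=(10, 6)).astype(float)
        codes[0, :3], codes[1, :3] = 0.0, 2.0
        codes[:, 3:] = 1.0  # monomorphic block
        filtered, _ = sc.qc_filter(make_markers(codes))
        grm = sc.compute_grm(filtered)
        assert grm.denom > 0


class TestPCA:
    def test_identical_genotypes_identical_scores(self, rng):
        codes = rng.integers(0, 3, size=(10, 25)).astype(float)
        codes[4] = codes[3]
        res = sc.pca_markers(make_markers(codes), k=3)
        np.testing.assert_allclose(res.scores[3], res.scores[4], atol=1e-8)

    def test_divergent_families_separate(self):
        from sklearn.metrics import silhouette_score

        cfg = sc.small_config(seed=9, n_families=2, lines_per_family=20,
                              n_checks=2, n_markers=150, maf_range=(0.3, 0.5))
        markers = sc.simulate_markers(cfg)
        lines = markers.subset_genotypes(~markers.genotype_meta["is_check"].to_numpy())
        res = sc.pca_markers(lines, k=2)
        labels = [g.split("-")[0] for g in lines.genotype_ids]
        assert silhouette_score(res.scores, labels) > 0

    def test_explained_fractions_valid(self, rng):
        codes = rng.integers(0, 3, size=(12, 30)).astype(float)
        res = sc.pca_markers(make_markers(codes), k=5)
        assert res.explained_variance_fraction.sum() <= 1 + 1e-9
        assert np.all(np.diff(res.explained_variance_fraction) <= 1e-12)

    def test_k_beyond_rank_reduced_with_warning(self, rng):
        codes = rng.integers(0, 3, size=(4, 30)).astype(float)
        with pytest.warns(UserWarning):
            res = sc.pca_markers(make_markers(codes), k=10)
        assert res.scores.shape[1] <= 4


class TestIO:
    def test_marker_csv_roundtrip(self, rng, tmp_path):
        codes = rng.integers(0, 3, size=(8, 10)).astype(float)
        codes[0, 0] = np.nan
        mk = make_markers(codes)
        from soyclass.io import read_marker_csv, write_marker_csv
        write_marker_csv(mk, tmp_path / "m.csv")
        back = read_marker_csv(tmp_path / "m.csv")
        np.testing.assert_array_equal(back.codes, codes)
        assert list(back.genotype_ids) == list(mk.genotype_ids)

    def test_vcf_roundtrip(self, rng, tmp_path):
        from soyclass.io import read_vcf, write_vcf

        codes = rng.integers(0, 3, size=(6, 12)).astype(float)
        codes[1, 2] = np.nan
        mk = make_markers(codes)
        write_vcf(mk, tmp_path / "m.vcf")
        back = read_vcf(tmp_path / "m.vcf")
        np.testing.assert_array_equal(back.codes, codes)
        assert list(back.marker_ids) == list(mk.marker_ids)

    def test_pheno_validation(self):
        with pytest.raises(ValueError, match="missing columns"):
            from soyclass.io import validate_phenotypes
            validate_phenotypes(pd.DataFrame({"genotype": ["a"]}))
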