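"""Histograms, PCA on coordinates, LDA on amplitudes, and clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import adjusted_rand_score

from hemensd.exceptions import DimensionError
from hemensd.feature_analysis import (
    CLUSTER_METHODS,
    cluster_nsd,
    lda_nsd,
    nsd_histograms,
    pca_coordinates,
)
from hemensd.mode_basis import MODE_NAMES
from hemensd.nsd_engine import nsd_table
from hemensd.synthetic_fixtures import DistortionSpec, make_distorted_heme


def two_group_hemes(ref, basis, n_per_group, sigma=0.05, mode="saddling",
                    amp=0.5, seed0=9000):
    hemes, labels = [], []
    for i in range(2 * n_per_group):
        sign = 1.0 if i % 2 == 0 else -1.0
        hemes.append(
            make_distorted_heme(
                DistortionSpec(amplitudes={mode: sign * amp}, sigma=sigma,
                               seed=seed0 + i),
                ref, basis,
            )
        )
        labels.append("plus" if sign > 0 else "minus")
    return hemes, labels


@pytest.fixture(scope="module")
def two_groups(ref, basis):
    hemes, labels = two_group_hemes(ref, basis, 100)
    return nsd_table(hemes, ref, basis), labels


class TestHistograms:
    def test_offset_groups_separate_in_saddling(self, two_groups):
        df, labels = two_groups
        res = nsd_histograms(df, labels)
        assert res.status == "ok"
        means = df.groupby(pd.Series(labels, index=df.index))["saddling"].mean()
        se = df["saddling"].std() / np.sqrt(len(df) / 2)
        assert abs((means["plus"] - means["minus"]) - 1.0) < 3 * se

    def test_counts_conserved_across_groups(self, two_groups):
        df, labels = two_groups
        res = nsd_histograms(df, labels)
        for mode in MODE_NAMES:
            total = sum(int(c.sum()) for c, _ in res.distributions[mode].values())
            assert total == res.n_used == len(df)

    def test_resolution_filter(self, two_groups):
        df, labels = two_groups
        res_col = [1.5] * (len(df) // 2) + [2.5] * (len(df) - len(df) // 2)
        res = nsd_histograms(df, labels, resolution=res_col,
                             resolution_max=2.0)
        assert res.n_used == len(df) // 2

    def test_empty_selection_is_status_not_crash(self, two_groups):
        df, labels = two_groups
        res = nsd_histograms(df, labels, resolution=[8.0] * len(df),
                             resolution_max=1.4)
        assert res.status == "empty"

    def test_zero_distortions_single_bin(self, ref, basis):
        hemes = [make_distorted_heme(DistortionSpec(), ref, basis)
                 for _ in range(6)]
        df = nsd_table(hemes, ref, basis)
        res = nsd_histograms(df, ["g"] * 6)
        for mode in MODE_NAMES:
            counts, _ = res.distributions[mode]["g"]
            assert int(counts.sum()) == 6
            assert np.count_nonzero(counts) == 1

    def test_out_of_range_threshold_rejected(self, two_groups):
        df, labels = two_groups
        with pytest.raises(ValueError):
            nsd_histograms(df, labels, resolution_max=9.0)


class TestPCA:
    def test_one_factor_construction(self, ref, basis, rng):
        """Variance only along saddling: PC1 takes all variance and aligns
        with the saddling mode."""
        amps = rng.normal(0, 0.3, 40)
        structs = [
            make_distorted_heme(
                DistortionSpec(amplitudes={"saddling": float(a)}), ref, basis
            ).coords
            for a in amps
        ]
        res = pca_coordinates(structs, basis)
        assert res.contribution_ratios[0] >= 0.99
        assert abs(res.mode_inner_products.iloc[0]["saddling"]) >= 0.99

    def test_projections_centered_at_origin(self, ref, basis, rng):
        structs = [
            make_distorted_heme(
                DistortionSpec(amplitudes={"ruffling": float(a)}), ref, basis
            ).coords
            for a in rng.normal(0, 0.2, 20)
        ]
        res = pca_coordinates(structs, basis)
        assert np.allclose(res.projections.mean(axis=0), 0.0, atol=1e-9)

    def test_two_orthogonal_modes_variance_ratio(self, ref, basis, rng):
        """Injected variances 4:1 give contribution ratios ~0.8/0.2."""
        structs = []
        for _ in range(400):
            a = float(rng.normal(0, 0.2))
            b = float(rng.normal(0, 0.1))
            structs.append(
                make_distorted_heme(
                    DistortionSpec(amplitudes={"saddling": a, "ruffling": b}),
                    ref, basis,
                ).coords
            )
        res = pca_coordinates(structs, basis)
        assert res.contribution_ratios[0] == pytest.approx(0.8, abs=0.05)
        assert res.contribution_ratios[1] == pytest.approx(0.2, abs=0.05)

    def test_eigenvector_orthonormality_and_ratio_bounds(self, ref, basis, rng):
        structs = [
            make_distorted_heme(
                DistortionSpec(amplitudes={}, sigma=0.05, seed=i), ref, basis
            ).coords
            for i in range(30)
        ]
        res = pca_coordinates(structs, basis)
        g = res.eigenvectors @ res.eigenvectors.T
        assert np.max(np.abs(g - np.eye(len(g)))) < 1e-8
        assert np.all(res.contribution_ratios >= 0)
        assert res.contribution_ratios.sum() <= 1.0 + 1e-9

    def test_atom_subset_selection(self, ref, basis, rng):
        structs = [
            make_distorted_heme(
                DistortionSpec(amplitudes={"saddling": float(a)}), ref, basis
            ).coords
            for a in rng.normal(0, 0.3, 10)
        ]
        res = pca_coordinates(structs, basis,
                              fit_atoms=["FE", "NA", "NB", "NC", "ND"],
                              pca_atoms=["FE", "NA", "NB", "NC", "ND"])
        v = res.eigenvectors[0].reshape(25, 3)
        assert np.all(v[5:] == 0.0)  # carbons excluded from the PCA selection

    def test_single_structure_rejected(self, ref, basis):
        with pytest.raises(DimensionError):
            pca_coordinates([ref.coords], basis)


class TestLDA:
    def test_separates_saddling_groups(self, two_groups, basis):
        df, labels = two_groups
        res = lda_nsd(df, labels, basis)
        assert res.separation == 100.0
        sad = abs(res.direction[MODE_NAMES.index("saddling")])
        assert sad >= 0.95

    def test_matches_sklearn_direction(self, two_groups, basis):
        df, labels = two_groups
        res = lda_nsd(df, labels, basis)
        sk = LinearDiscriminantAnalysis(solver="lsqr").fit(
            df[list(MODE_NAMES)].to_numpy(), labels
        )
        w_sk = sk.coef_[0] / np.linalg.norm(sk.coef_[0])
        assert abs(w_sk @ res.direction) >= 0.999

    def test_scale_equivariance(self, two_groups, basis):
        df, labels = two_groups
        res1 = lda_nsd(df, labels, basis)
        res2 = lda_nsd(df[list(MODE_NAMES)] * 2.0, labels, basis)
        assert abs(res1.direction @ res2.direction) >= 0.999

    def test_relabeled_identical_groups_show_no_signal(self, ref, basis):
        hemes = [
            make_distorted_heme(DistortionSpec(sigma=0.05, seed=100 + i),
                                ref, basis)
            for i in range(60)
        ]
        df = nsd_table(hemes, ref, basis)
        labels = ["a", "b"] * 30
        res = lda_nsd(df, labels, basis)
        pooled_sd = np.std(res.projections)
        assert abs(res.group_means[0] - res.group_means[1]) < pooled_sd

    def test_ridge_applied_on_singular_covariance(self, two_groups, basis):
        df, labels = two_groups
        degenerate = df.copy()
        degenerate["breathing"] = 0.0
        res = lda_nsd(degenerate, labels, basis)
        assert res.ridge_applied
        assert np.all(np.isfinite(res.direction))

    def test_feature_vector_is_mode_combination(self, two_groups, basis):
        df, labels = two_groups
        res = lda_nsd(df, labels, basis)
        rebuilt = basis.matrix.T @ res.direction
        rebuilt /= np.linalg.norm(rebuilt)
        assert np.allclose(rebuilt, res.feature_vector)

    def test_three_groups_rejected(self, two_groups, basis):
        df, labels = two_groups
        bad = list(labels)
        bad[0] = "third"
        with pytest.raises(DimensionError):
            lda_nsd(df, bad, basis)


class TestClustering:
    def test_well_separated_blobs_recovered_by_kmeans(self, two_groups):
        df, labels = two_groups
        res = cluster_nsd(df, labels, "K-means", seed=0)
        assert adjusted_rand_score(labels, res.labels) >= 0.99

    @pytest.mark.parametrize("method", CLUSTER_METHODS)
    def test_every_method_returns_k_clusters(self, two_groups, method):
        df, labels = two_groups
        res = cluster_nsd(df, labels, method, seed=0)
        assert res.n_clusters == 2
        assert res.contingency.to_numpy().sum() == len(df)

    def test_single_blob_forced_to_two_clusters(self, ref, basis):
        hemes = [
            make_distorted_heme(DistortionSpec(sigma=0.02, seed=300 + i),
                                ref, basis)
            for i in range(20)
        ]
        df = nsd_table(hemes, ref, basis)
        labels = ["x", "y"] * 10
        res = cluster_nsd(df, labels, "K-means", seed=0)
        assert res.contingency.to_numpy().sum() == 20

    def test_deterministic_given_seed(self, two_groups):
        df, labels = two_groups
        r1 = cluster_nsd(df, labels, "Gaussian mixture", seed=0)
        r2 = cluster_nsd(df, labels, "Gaussian mixture", seed=0)
        assert np.array_equal(r1.labels, r2.labels)

    def test_unknown_method_rejected(self, two_groups):
        df, labels = two_groups
        with pytest.raises(ValueError):
            cluster_nsd(df, labels, "DBSCAN")
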