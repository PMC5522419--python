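"""Loading-model fit, projection, score summaries, and serialization."""

import numpy as np
import pytest

import sersmix as sx
from sersmix.exceptions import GridMismatchError, LowVarianceWarning, RankError, SampleLookupError
from tests.conftest import make_study


def pure_collection(n_components=2, reps=3, noise=0.0, seed=0):
    """Small labelled training set on a shared grid."""
    grid = np.linspace(600, 700, 26)
    rng = np.random.default_rng(seed)
    bases = rng.uniform(0, 10, size=(n_components, grid.size))
    spectra = []
    for i in range(n_components):
        for r in range(1, reps + 1):
            inten = bases[i] + (rng.normal(0, noise, grid.size) if noise else 0.0)
            spectra.append(
                sx.RamanSpectrum(grid, inten, f"pure-{i}", r, component_label=f"C{i}")
            )
    return sx.SpectraCollection(spectra, grid)


class TestFit:
    def test_two_noiseless_components_one_pc_explains_everything(self):
        model = sx.fit_loading_model(pure_collection(2), n_components=1)
        assert abs(model.explained_variance_fraction[0] - 1.0) < 1e-10

    def test_four_noiseless_components_span_three_dimensions(self):
        model = sx.fit_loading_model(pure_collection(4), n_components=3)
        assert abs(model.explained_variance_fraction.sum() - 1.0) < 1e-10

    def test_default_retains_c_minus_1_components(self):
        for c in (2, 3, 4):
            model = sx.fit_loading_model(pure_collection(c))
            assert model.n_pc == c - 1

    def test_matches_independent_svd_oracle(self):
        """Cross-check loadings/variances against sklearn's PCA on the same data."""
        sklearn = pytest.importorskip("sklearn.decomposition")
        pure = pure_collection(3, reps=4, noise=0.5, seed=5)
        model = sx.fit_loading_model(pure, n_components=2)
        ref = sklearn.PCA(n_components=2, svd_solver="full").fit(pure.to_matrix())
        np.testing.assert_allclose(
            model.explained_variance_fraction, ref.explained_variance_ratio_, rtol=1e-10
        )
        for ours, theirs in zip(model.loadings, ref.components_):
            sign = np.sign(ours @ theirs)
            np.testing.assert_allclose(ours, sign * theirs, atol=1e-10)

    def test_duplicated_replicates_leave_model_unchanged(self):
        pure = pure_collection(2, reps=2, noise=0.3, seed=7)
        doubled = sx.SpectraCollection(
            list(pure)
            + [
                sx.RamanSpectrum(s.shift, s.intensity, s.sample_id, s.spot_index + 10,
                                 s.component_label)
                for s in pure
            ],
            pure.common_grid,
        )
        m1 = sx.fit_loading_model(pure, 1)
        m2 = sx.fit_loading_model(doubled, 1)
        np.testing.assert_allclose(m1.loadings, m2.loadings, atol=1e-9)
        np.testing.assert_allclose(m1.mean_spectrum, m2.mean_spectrum, atol=1e-12)
        np.testing.assert_allclose(m1.component_scores, m2.component_scores, atol=1e-9)

    def test_deterministic_bit_identical(self):
        pure = pure_collection(3, reps=3, noise=0.2, seed=11)
        m1 = sx.fit_loading_model(pure)
        m2 = sx.fit_loading_model(pure)
        assert np.array_equal(m1.loadings, m2.loadings)

    def test_sign_convention_largest_entry_positive(self):
        model = sx.fit_loading_model(pure_collection(4, noise=0.1, seed=3))
        for row in model.loadings:
            assert row[np.argmax(np.abs(row))] > 0

    def test_rank_error_when_too_many_components(self):
        with pytest.raises(RankError):
            sx.fit_loading_model(pure_collection(2, reps=2), n_components=4)

    def test_unlabeled_training_spectrum_rejected(self):
        pure = pure_collection(2)
        bad = sx.SpectraCollection(
            list(pure) + [sx.RamanSpectrum(pure.common_grid, np.ones(26), "X", 1)],
            pure.common_grid,
        )
        with pytest.raises(ValueError, match="component_label"):
            sx.fit_loading_model(bad)


class TestProjection:
    def test_training_mean_projects_to_zero(self):
        pure = pure_collection(3, noise=0.2, seed=1)
        model = sx.fit_loading_model(pure)
        mean = sx.RamanSpectrum(model.grid, model.mean_spectrum, "mean", 1)
        scores = sx.project(sx.SpectraCollection([mean], model.grid), model)
        np.testing.assert_allclose(scores.to_numpy(), 0.0, atol=1e-10)

    def test_training_spectra_reproduce_stored_scores(self):
        pure = pure_collection(3, noise=0.2, seed=2)
        model = sx.fit_loading_model(pure)
        scores = sx.project(pure, model)
        np.testing.assert_allclose(
            scores.to_numpy(), model.training_scores.to_numpy(), atol=1e-10
        )

    def test_mean_plus_loading_scores_unit_vector(self):
        pure = pure_collection(4, noise=0.3, seed=9)
        model = sx.fit_loading_model(pure)
        s = sx.RamanSpectrum(model.grid, model.mean_spectrum + model.loadings[0], "L", 1)
        scores = sx.project(sx.SpectraCollection([s], model.grid), model)
        expected = np.zeros(model.n_pc)
        expected[0] = 1.0
        np.testing.assert_allclose(scores.to_numpy()[0], expected, atol=1e-10)

    def test_reconstruction_residual_orthogonal_to_loadings(self):
        pure = pure_collection(4, reps=5, noise=0.4, seed=13)
        model = sx.fit_loading_model(pure, 2)
        X = pure.to_matrix() - model.mean_spectrum
        scores = X @ model.loadings.T
        residual = X - scores @ model.loadings
        np.testing.assert_allclose(residual @ model.loadings.T, 0.0, atol=1e-8)

    def test_grid_mismatch_rejected(self):
        pure = pure_collection(2)
        model = sx.fit_loading_model(pure)
        other = np.linspace(600, 700, 11)
        coll = sx.SpectraCollection(
            [sx.RamanSpectrum(other, np.ones(11), "X", 1)], other
        )
        with pytest.raises(GridMismatchError):
            sx.project(coll, model)


class TestMeanScores:
    def test_single_spot_mean_is_that_spot(self):
        pure = pure_collection(2)
        model = sx.fit_loading_model(pure)
        scores = sx.project(pure, model)
        one = scores.iloc[[0]]
        means = sx.mean_scores(one)
        np.testing.assert_allclose(means["PC1"].iloc[0], one["PC1"].iloc[0])

    def test_two_spot_example(self):
        import pandas as pd

        scores = pd.DataFrame(
            {"PC1": [1.0, 3.0], "PC2": [3.0, 1.0]},
            index=pd.MultiIndex.from_tuples([("S", 1), ("S", 2)],
                                            names=["sample_id", "spot_index"]),
        )
        means = sx.mean_scores(scores)
        assert means.loc["S", "PC1"] == 2.0 and means.loc["S", "PC2"] == 2.0

    def test_eight_spots_match_elementwise_average_oracle(self, binary_study, binary_model):
        from sersmix.spectra import preprocess

        prepped = preprocess(binary_study.mixtures, grid=binary_model.grid)
        scores = sx.project(prepped, binary_model)
        means = sx.mean_scores(scores)
        for sid in scores.index.get_level_values(0).unique():
            oracle = scores.loc[sid].to_numpy().mean(axis=0)
            np.testing.assert_allclose(means.loc[sid, ["PC1"]].to_numpy(), oracle[:1],
                                       rtol=1e-12)

    def test_unknown_sample_id_rejected(self, binary_study, binary_model):
        from sersmix.spectra import preprocess

        scores = sx.project(preprocess(binary_study.mixtures, grid=binary_model.grid),
                            binary_model)
        with pytest.raises(SampleLookupError):
            sx.mean_scores(scores, sample_ids=["nope"])


class TestVarianceReport:
    def test_noiseless_data_cumulative_unity(self):
        model = sx.fit_loading_model(pure_collection(3), 2)
        report = sx.explained_variance_report(model)
        assert abs(report["cumulative"].iloc[-1] - 1.0) < 1e-10

    def test_warns_below_99_percent(self):
        # one PC for 4 well-separated components cannot reach 99%
        model = sx.fit_loading_model(pure_collection(4, noise=0.1, seed=21), 1)
        with pytest.warns(LowVarianceWarning):
            sx.explained_variance_report(model)

    def test_simulated_binary_with_additive_noise_pc1_dominates(self):
        """At additive noise 1% of max peak, PC1 carries >99% of variance."""
        study = make_study(additive_sigma=0.01, seed=7)
        model = sx.fit_pure_references(study.pure)
        assert model.explained_variance_fraction[0] > 0.99


def test_model_serialization_round_trip(tmp_path, binary_model):
    path = tmp_path / "model.json"
    binary_model.save(path)
    back = sx.LoadingModel.load(path)
    np.testing.assert_array_equal(back.loadings, binary_model.loadings)
    np.testing.assert_array_equal(back.mean_spectrum, binary_model.mean_spectrum)
    np.testing.assert_array_equal(back.component_scores, binary_model.component_scores)
    assert back.component_names == binary_model.component_names
    assert back.preprocessing == binary_model.preprocessing
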