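"""CRIME pipeline: LIME surrogate, flattening, latent clustering, region
scoring and weighted cosine matching."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score, silhouette_score

from sersquant.crime import (
    LimeExplanation,
    VAESpec,
    cluster_contexts,
    context_regions,
    cosine_similarity,
    fit_latent,
    flatten_explanations,
    lime_explain,
    match_context,
    segment_map_for,
)
from sersquant.spectra import Spectrum, SpectrumState

from conftest import make_uniform_spectrum


def _linear_segment_model(segs, coef):
    def model(X):
        X = np.atleast_2d(X)
        means = np.stack([X[:, a:b].mean(axis=1) for a, b in segs], axis=1)
        return means @ coef

    return model


class TestLimeExplain:
    def test_recovers_linear_model_weights(self):
        rng = np.random.default_rng(5)
        L = 250
        segs = segment_map_for(L)
        coef = rng.normal(size=len(segs))
        model = _linear_segment_model(segs, coef)
        y = rng.uniform(0.2, 1.0, size=L)
        expl = lime_explain(model, y, n_samples=512, seed=1)
        off = y.min()
        true_w = np.array(
            [coef[j] * (y[a:b].mean() - off) for j, (a, b) in enumerate(segs)]
        )
        assert cosine_similarity(expl.feature_weights, true_w) >= 0.99

    def test_constant_model_gives_null_weights(self, rng):
        y = rng.uniform(0, 1, size=100)
        expl = lime_explain(lambda X: np.full(np.atleast_2d(X).shape[0], 3.0),
                            y, n_samples=128, seed=0)
        assert np.max(np.abs(expl.feature_weights)) < 1e-8

    def test_fixed_seed_reproducible(self, rng):
        y = rng.uniform(0, 1, size=100)
        model = lambda X: np.atleast_2d(X).sum(axis=1)
        a = lime_explain(model, y, n_samples=64, seed=7)
        b = lime_explain(model, y, n_samples=64, seed=7)
        np.testing.assert_array_equal(a.feature_weights, b.feature_weights)

    def test_underdetermined_surrogate_rejected(self, rng):
        y = rng.uniform(0, 1, size=500)
        with pytest.raises(ValueError, match="n_samples"):
            lime_explain(lambda X: np.atleast_2d(X).sum(axis=1), y,
                         n_samples=4, seed=0)

    def test_limits_ordered(self, rng):
        y = rng.uniform(0, 1, size=100)
        expl = lime_explain(lambda X: np.atleast_2d(X).sum(axis=1), y,
                            n_samples=64, seed=0)
        lo, hi = expl.perturbation_limits
        assert np.all(lo <= hi)


def _toy_explanations(n, S, rng, archetypes=None):
    segmap = segment_map_for(S * 25)
    rows, labels = [], []
    for i in range(n):
        if archetypes is not None:
            k = i % len(archetypes)
            w = archetypes[k] + rng.normal(0, 0.03, S)
            labels.append(k)
        else:
            w = rng.normal(size=S)
        lo = rng.uniform(0, 0.1, S)
        rows.append(LimeExplanation(w, (lo, lo + rng.uniform(0.3, 0.6, S)),
                                    0.0, segmap))
    return rows, labels


class TestFlatten:
    def test_shape_is_n_by_3s(self, rng):
        rows, _ = _toy_explanations(6, 10, rng)
        assert flatten_explanations(rows).shape == (6, 30)

    def test_identical_explanations_identical_rows(self, rng):
        rows, _ = _toy_explanations(1, 8, rng)
        flat = flatten_explanations(rows * 4)
        assert np.all(flat == flat[0])

    def test_columns_minmax_normalized(self, rng):
        rows, _ = _toy_explanations(12, 9, rng)
        flat = flatten_explanations(rows)
        span = flat.max(axis=0) - flat.min(axis=0)
        nz = span > 0
        np.testing.assert_allclose(flat[:, nz].min(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(flat[:, nz].max(axis=0), 1.0, atol=1e-12)

    def test_inconsistent_segment_maps_rejected(self, rng):
        rows, _ = _toy_explanations(2, 8, rng)
        other = LimeExplanation(
            np.zeros(4), (np.zeros(4), np.zeros(4)), 0.0, segment_map_for(100)
        )
        with pytest.raises(ValueError, match="segment maps"):
            flatten_explanations(rows + [other])


@pytest.fixture(scope="module")
def planted():
    rng = np.random.default_rng(11)
    S = 24
    w1 = np.zeros(S)
    w1[2:5] = 1.0
    w2 = np.zeros(S)
    w2[18:22] = -1.0
    rows, labels = _toy_explanations(60, S, rng, archetypes=[w1, w2])
    flat = flatten_explanations(rows)
    latent = fit_latent(flat, seed=2)
    return latent, labels


class TestLatentAndClustering:

    def test_latent_is_two_dimensional(self, planted):
        latent, _ = planted
        assert latent.shape[1] == 2

    def test_archetypes_separate_in_latent_space(self, planted):
        latent, labels = planted
        assert silhouette_score(latent, labels) > 0.5

    def test_kmeans_recovers_planted_archetypes(self, planted):
        latent, labels = planted
        found = cluster_contexts(latent, k=2, seed=0)
        assert adjusted_rand_score(labels, found) == 1.0

    def test_latent_deterministic_under_seed(self, rng):
        rows, _ = _toy_explanations(12, 8, rng)
        flat = flatten_explanations(rows)
        np.testing.assert_array_equal(fit_latent(flat, seed=5),
                                      fit_latent(flat, seed=5))

    def test_too_few_instances_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            fit_latent(np.zeros((5, 6)), seed=0)

    def test_degenerate_rows_warn(self):
        with pytest.warns(UserWarning, match="identical"):
            fit_latent(np.ones((12, 6)), VAESpec(epochs=2), seed=0)

    def test_k_one_rejected(self, rng):
        with pytest.raises(ValueError, match="k must be"):
            cluster_contexts(rng.normal(size=(10, 2)), k=1)

    def test_k_equals_n_gives_singletons(self, rng):
        labels = cluster_contexts(rng.normal(size=(8, 2)), k=8, seed=0)
        assert len(np.unique(labels)) == 8

    def test_latent_dim_fixed_at_two(self):
        with pytest.raises(ValueError, match="fixed at 2"):
            VAESpec(latent_dim=3)


class TestContextRegions:
    def test_single_member_mean_equals_member(self, rng):
        rows, _ = _toy_explanations(1, 20, rng)
        spectra = rng.uniform(0, 1, size=(1, 20 * 25))
        rep = context_regions(rows, spectra, seed=0)
        np.testing.assert_array_equal(rep.mean_explanation.feature_weights,
                                      rows[0].feature_weights)

    def test_mean_of_members_is_exact(self, rng):
        rows, _ = _toy_explanations(5, 20, rng)
        spectra = rng.uniform(0, 1, size=(5, 20 * 25))
        rep = context_regions(rows, spectra, seed=0)
        np.testing.assert_allclose(
            rep.mean_explanation.feature_weights,
            np.mean([r.feature_weights for r in rows], axis=0),
        )

    def test_dominant_weighted_peak_ranks_first(self):
        S = 20
        segmap = segment_map_for(S * 25)
        w = np.full(S, 0.01)
        w[7] = 5.0
        spectrum = np.full(S * 25, 0.05)
        spectrum[7 * 25 : 8 * 25] = 1.0
        expl = LimeExplanation(w, (np.zeros(S), np.ones(S)), 0.0, segmap)
        rep = context_regions([expl], spectrum[None, :], seed=0)
        a, b, score = rep.top_regions[0]
        assert a <= 7 * 25 < b

    def test_at_most_five_top_region_clusters(self, rng):
        rows, _ = _toy_explanations(3, 30, rng)
        spectra = rng.uniform(0, 1, size=(3, 30 * 25))
        rep = context_regions(rows, spectra, seed=0)
        starts = {a for a, _, _ in rep.top_regions}
        scores = {s for _, _, s in rep.top_regions}
        assert len(scores) <= 5  # five clusters, possibly split into runs

    def test_fewer_segments_than_clusters_warns(self, rng):
        rows, _ = _toy_explanations(2, 6, rng)
        spectra = rng.uniform(0, 1, size=(2, 6 * 25))
        with pytest.warns(UserWarning, match="reducing"):
            context_regions(rows, spectra, seed=0)

    def test_empty_context_rejected(self):
        with pytest.raises(ValueError, match="no members"):
            context_regions([], np.zeros((0, 10)))


class TestCosineSimilarity:
    def test_identical_vectors(self):
        v = np.array([1.0, 2.0, 3.0])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal_and_opposite(self):
        assert cosine_similarity([1, 0], [0, 1]) == pytest.approx(0.0)
        assert cosine_similarity([1, 2], [-1, -2]) == pytest.approx(-1.0)

    def test_reference_value(self):
        assert cosine_similarity([1, 2, 3], [4, 5, 6]) == pytest.approx(
            0.974632, abs=1e-6
        )

    def test_positive_rescaling_invariance(self, rng):
        a, b = rng.normal(size=20), rng.normal(size=20)
        assert cosine_similarity(3.7 * a, b) == pytest.approx(
            cosine_similarity(a, 0.2 * b)
        )

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_similarity(np.zeros(3), np.ones(3))


class TestMatchContext:
    def _report(self, rng, S=8, width=25):
        rows, _ = _toy_explanations(1, S, rng)
        spectrum = rng.uniform(0.1, 1.0, size=S * width)
        return context_regions(rows, spectrum[None, :], seed=0), spectrum

    def test_identical_reference_scores_one(self, rng):
        rep, spectrum = self._report(rng)
        ref = make_uniform_spectrum(spectrum, SpectrumState.NORMALIZED)
        matches = match_context(rep, [("self", ref)])
        assert matches[0][1] == pytest.approx(1.0)

    def test_uniform_weights_reduce_to_plain_cosine(self, rng):
        S, width = 8, 25
        segmap = segment_map_for(S * width)
        expl = LimeExplanation(np.ones(S), (np.zeros(S), np.ones(S)), 0.0, segmap)
        spectrum = rng.uniform(0.1, 1.0, size=S * width)
        rep = context_regions([expl], spectrum[None, :], seed=0)
        other = rng.uniform(0.1, 1.0, size=S * width)
        ref = make_uniform_spectrum(other, SpectrumState.NORMALIZED)
        matches = match_context(rep, [("o", ref)])
        assert matches[0][1] == pytest.approx(cosine_similarity(spectrum, other))

    def test_grid_mismatch_rejected(self, rng):
        rep, _ = self._report(rng)
        ref = make_uniform_spectrum(rng.uniform(size=10), SpectrumState.NORMALIZED)
        with pytest.raises(ValueError, match="grid length"):
            match_context(rep, [("bad", ref)])

    def test_matches_sorted_descending(self, rng):
        rep, spectrum = self._report(rng)
        refs = [
            ("noise1", make_uniform_spectrum(rng.uniform(size=spectrum.size))),
            ("self", make_uniform_spectrum(spectrum)),
            ("noise2", make_uniform_spectrum(rng.uniform(size=spectrum.size))),
        ]
        matches = match_context(rep, refs)
        sims = [s for _, s in matches]
        assert sims == sorted(sims, reverse=True)
        assert matches[0][0] == "self"
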