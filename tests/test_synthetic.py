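"""Generator tests: design counts, ground-truth relationships, determinism."""

import numpy as np
import pandas as pd
import pytest
from dataclasses import replace
from scipy.special import expit, logit

from gestaltmem import (
    GenerativeParams,
    ParameterError,
    generate_feature_vectors,
    generate_image_population,
    generate_test_images,
    simulate_categorization_study,
    simulate_rating_study,
    simulate_search_study,
)
from gestaltmem.association import spearman_corr


class TestImagePopulation:
    def test_design_size(self, traits):
        assert len(traits) == 14 * 44 == 616
        assert traits["category"].nunique() == 14
        assert traits.groupby("category").size().eq(44).all()

    def test_memorability_in_unit_interval(self, memorability):
        assert memorability["score"].between(0, 1).all()

    def test_null_effects_give_constant_memorability(self):
        params = GenerativeParams(
            seed=0, w_good_mem=0.0, w_dist_mem=0.0, noise_sd=0.0, mem_offset=0.0
        )
        _, traits, _ = generate_image_population(params)
        assert np.allclose(traits["memorability"], 0.5)

    def test_goodness_memorability_link_matches_oracle(self):
        # Independent Monte-Carlo oracle: regenerate logit(m) from the model
        # formula with a separate random stream and compare corr(g, logit m).
        params = GenerativeParams(seed=123, n_categories=10,
                                  n_images_per_category=500)
        _, traits, _ = generate_image_population(params)
        observed = np.corrcoef(traits["goodness"],
                               logit(traits["memorability"]))[0, 1]
        rng = np.random.default_rng(20240917)
        n = 200_000
        g = rng.normal(0, params.trait_sd, n)
        d = rng.normal(0, params.trait_sd, n)
        eps = rng.normal(0, params.noise_sd, n)
        lm = params.mem_offset + params.w_good_mem * g + params.w_dist_mem * d + eps
        expected = np.corrcoef(g, lm)[0, 1]
        assert observed == pytest.approx(expected, abs=0.03)

    def test_deterministic_under_seed(self, default_params, traits):
        _, traits2, _ = generate_image_population(default_params)
        pd.testing.assert_frame_equal(traits, traits2)

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            GenerativeParams(trait_sd=0.0)
        with pytest.raises(ParameterError):
            GenerativeParams(n_categories=0)
        with pytest.raises(ParameterError):
            GenerativeParams(rating_thresholds=(1.0, 0.5))


class TestCategorizationStudy:
    def test_trial_counts(self, study1_trials):
        per_participant = study1_trials.groupby("participant_id").size()
        assert (per_participant == 616).all()
        congruent = study1_trials.groupby("participant_id")["congruent"].sum()
        assert (congruent == 308).all()

    def test_mean_congruent_responses_per_image(self, study1_trials):
        # 147 participants x half congruent -> about 74 responses per image.
        cong = study1_trials[study1_trials["congruent"]]
        per_image = cong.groupby("image_id").size()
        assert per_image.mean() == pytest.approx(73.5, abs=0.5)

    def test_noiseless_ceiling_all_correct(self, traits, default_params):
        params = replace(default_params, lapse_rate=0.0, nonresponse_rate=0.0,
                         accuracy_offset=60.0, participant_sd=1e-9,
                         n_participants_study1=5)
        trials = simulate_categorization_study(traits, params)
        assert trials["correct"].all()

    def test_nonresponse_recorded_incorrect(self, study1_trials):
        assert not (study1_trials["correct"] & ~study1_trials["responded"]).any()

    def test_odd_category_size_extra_goes_congruent(self):
        params = GenerativeParams(seed=3, n_categories=2, n_images_per_category=5,
                                  n_participants_study1=6,
                                  images_per_participant_study2=5)
        _, traits, _ = generate_image_population(params)
        trials = simulate_categorization_study(traits, params)
        per_cat = trials.groupby(["participant_id", "category"])["congruent"].sum()
        assert (per_cat == 3).all()


class TestSearchStudy:
    def test_trial_counts_and_subsetting(self, study2_trials):
        per_participant = study2_trials.groupby("participant_id").size()
        assert (per_participant == 420).all()  # 30 images x 14 categories
        per_cat = study2_trials.groupby(["participant_id", "category"]).size()
        assert (per_cat == 30).all()

    def test_expected_responses_per_image(self, study2_trials):
        per_image = study2_trials.groupby("image_id").size()
        assert per_image.mean() == pytest.approx(75 * 30 / 44, abs=2.0)

    def test_outcome_invariants(self, study2_trials, default_params):
        timeouts = study2_trials["outcome"] == "timeout"
        assert (study2_trials.loc[timeouts, "rt"] == 6.0).all()
        assert (study2_trials.loc[~timeouts, "rt"] <= 6.0).all()
        assert (study2_trials["rt"] > 0).all()

    def test_degenerate_dispersion_collapses_rts(self):
        params = GenerativeParams(
            seed=1, n_categories=4, n_images_per_category=10,
            n_participants_study2=10, images_per_participant_study2=6,
            rt_scale=1e-12, rt_participant_sd=0.0, w_good_rt=0.0, w_dist_rt=0.0,
            rt_location=0.5, wrong_click_rate=0.0,
        )
        _, traits, _ = generate_image_population(params)
        trials = simulate_search_study(traits, params)
        assert np.allclose(trials["rt"], np.exp(0.5), atol=1e-9)

    def test_wrong_click_fraction_matches_binomial_oracle(self):
        params = GenerativeParams(seed=5, n_categories=4,
                                  n_images_per_category=44,
                                  n_participants_study2=850,
                                  wrong_click_rate=0.03)
        _, traits, _ = generate_image_population(params)
        trials = simulate_search_study(traits, params)
        assert len(trials) >= 10**5
        frac = (trials["outcome"] == "wrong_click").mean()
        assert frac == pytest.approx(0.03, abs=0.005)

    def test_oversized_subset_rejected(self):
        with pytest.raises(ParameterError):
            GenerativeParams(images_per_participant_study2=45)


class TestRatingStudy:
    def test_ratings_in_bounds(self, study3_trials):
        assert study3_trials["rating"].between(-3, 3).all()

    def test_mean_ratings_per_image_near_design(self, study3_trials):
        per_image = study3_trials.groupby("image_id").size()
        assert per_image.mean() == pytest.approx(44, abs=8)

    def test_floor_case_all_minimum(self, small_population, small_params):
        _, traits, _ = small_population
        params = replace(small_params, rating_noise_sd=0.0, participant_sd=0.0,
                         rating_thresholds=(50.0, 51.0, 52.0, 53.0, 54.0, 55.0))
        trials = simulate_rating_study(traits, params)
        assert (trials["rating"] == -3).all()

    def test_mean_rating_monotone_in_latent(self):
        params = GenerativeParams(seed=9, n_categories=4,
                                  n_images_per_category=30,
                                  n_participants_study3=2000,
                                  mean_blocks_completed=4.0)
        _, traits, _ = generate_image_population(params)
        trials = simulate_rating_study(traits, params)
        means = trials.groupby("image_id")["rating"].mean()
        rho = spearman_corr(means.reindex(traits.index), traits["distinctiveness"])
        assert rho > 0.99


class TestFeatureVectors:
    def test_shape_and_determinism(self, traits, default_params):
        fv = generate_feature_vectors(traits, 8, default_params)
        assert fv.shape == (616, 9)  # category + 8 feature columns
        fv2 = generate_feature_vectors(traits, 8, default_params)
        pd.testing.assert_frame_equal(fv, fv2)

    def test_null_scaling_breaks_distance_link(self, traits, default_params):
        params = replace(default_params, w_dist_feat=0.0)
        fv = generate_feature_vectors(traits, 8, params)
        x = fv[[c for c in fv.columns if c != "category"]].to_numpy()
        dist = np.empty(len(fv))
        for c, idx in fv.groupby("category").groups.items():
            loc = fv.index.get_indexer(idx)
            dist[loc] = np.linalg.norm(x[loc] - x[loc].mean(axis=0), axis=1)
        r = np.corrcoef(dist, traits["distinctiveness"])[0, 1]
        assert abs(r) < 0.1

    def test_distance_to_centroid_tracks_distinctiveness(self):
        params = GenerativeParams(seed=21, n_categories=4,
                                  n_images_per_category=250)
        _, traits, _ = generate_image_population(params)
        fv = generate_feature_vectors(traits, 16, params)
        x = fv[[c for c in fv.columns if c != "category"]].to_numpy()
        dist = np.empty(len(fv))
        for c, idx in fv.groupby("category").groups.items():
            loc = fv.index.get_indexer(idx)
            dist[loc] = np.linalg.norm(x[loc] - x[loc].mean(axis=0), axis=1)
        r = np.corrcoef(dist, traits["distinctiveness"])[0, 1]
        assert r > 0.8

    def test_far_separated_categories_have_same_category_neighbors(self):
        params = GenerativeParams(seed=2, n_categories=2,
                                  n_images_per_category=20,
                                  feature_center_sd=500.0,
                                  images_per_participant_study2=20)
        _, traits, _ = generate_image_population(params)
        fv = generate_feature_vectors(traits, 4, params)
        x = fv[[c for c in fv.columns if c != "category"]].to_numpy()
        cats = fv["category"].to_numpy()
        d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d2, np.inf)
        nn = d2.argmin(axis=1)
        assert (cats[nn] == cats).all()

    def test_dim_too_small_rejected(self, traits, default_params):
        with pytest.raises(ParameterError):
            generate_feature_vectors(traits, 1, default_params)


class TestTestImages:
    def test_constant_image_spectrum_at_dc(self):
        from gestaltmem.masks import RasterImage

        img = RasterImage(np.full((16, 16, 3), 0.5))
        spec = np.abs(np.fft.fft2(img.pixels[:, :, 0]))
        assert spec[0, 0] > 0
        assert np.all(spec.ravel()[1:] < 1e-9 * spec[0, 0])

    def test_default_fixture_size_and_determinism(self):
        imgs = generate_test_images(2, size=512, seed=4)
        assert all(im.shape == (512, 512) for im in imgs)
        imgs2 = generate_test_images(2, size=512, seed=4)
        for a, b in zip(imgs, imgs2):
            np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_pixels_in_range(self):
        for im in generate_test_images(8, size=32, seed=1):
            assert im.pixels.min() >= 0.0 and im.pixels.max() <= 1.0

    def test_small_size_rejected(self):
        with pytest.raises(ParameterError):
            generate_test_images(1, size=4, seed=0)
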