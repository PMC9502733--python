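"""Generator contracts: exact degenerate cases, 1:2 structure, determinism."""

import numpy as np
import pandas as pd
import pytest

from ploidycal import (
    ImageSceneSpec,
    SampleSpec,
    generate_cohort,
    generate_event_sample,
    generate_image_sample,
)


def test_zero_noise_sample_is_exact():
    spec = SampleSpec(
        n_cells=100, mu_2N=100.0, cv=0.0, frac_4N=0.0, frac_debris=0.0,
        icm_scale=1.3, fcm_scale=0.5, seed=1,
    )
    s = generate_event_sample(spec)
    assert np.all(s.icm_features["dna"].to_numpy() == 100.0 * 1.3)
    assert np.all(s.fcm_events["fsc_area"].to_numpy() == 100.0 * 0.5)


def test_population_mean_ratio_is_two_within_3se():
    spec = SampleSpec(n_cells=4000, cv=0.04, frac_4N=0.25, frac_debris=0.0, seed=9)
    s = generate_event_sample(spec)
    dna = s.icm_features["dna"].to_numpy()
    pop = s.truth["population"].to_numpy()
    m2, m4 = dna[pop == "2N"], dna[pop == "4N"]
    ratio = m4.mean() / m2.mean()
    # delta-method SE of the ratio of independent sample means
    se = ratio * np.sqrt(
        m4.var(ddof=1) / (len(m4) * m4.mean() ** 2)
        + m2.var(ddof=1) / (len(m2) * m2.mean() ** 2)
    )
    assert abs(ratio - 2.0) < 3 * se


def test_2n_mean_within_99ci_of_direct_draw():
    """Monte-Carlo oracle: the 2N ICM mean matches an independent direct
    draw from Normal(mu*icm_scale, cv*mu*icm_scale)."""
    spec = SampleSpec(n_cells=2000, cv=0.03, frac_4N=0.25, frac_debris=0.1,
                      icm_scale=0.8, seed=7)
    s = generate_event_sample(spec)
    vals = s.icm_features["dna"][s.truth["population"] == "2N"].to_numpy()
    mu = spec.mu_2N * spec.icm_scale
    se = spec.cv * mu / np.sqrt(len(vals))
    assert abs(vals.mean() - mu) < 2.576 * se


def test_ratio_invariant_to_global_scales():
    base = dict(n_cells=1000, cv=0.05, frac_4N=0.3, frac_debris=0.05, seed=3)
    a = generate_event_sample(SampleSpec(**base, icm_scale=1.0))
    b = generate_event_sample(SampleSpec(**base, icm_scale=4.2))
    pop = a.truth["population"]
    for s in (a, b):
        dna = s.icm_features["dna"]
        r = dna[pop == "4N"].mean() / dna[pop == "2N"].mean()
        np.testing.assert_allclose(r, 2.0, atol=0.02)
    np.testing.assert_allclose(
        b.icm_features["dna"], 4.2 * a.icm_features["dna"], rtol=1e-12
    )


def test_too_few_cells_refused():
    with pytest.raises(ValueError, match="n_cells"):
        SampleSpec(n_cells=20)


def test_event_sample_deterministic():
    spec = SampleSpec(n_cells=500, seed=123)
    a, b = generate_event_sample(spec), generate_event_sample(spec)
    pd.testing.assert_frame_equal(a.icm_features, b.icm_features)
    pd.testing.assert_frame_equal(a.fcm_events, b.fcm_events)
    pd.testing.assert_frame_equal(a.truth, b.truth)


class TestImageScene:
    def test_rasters_share_dimensions_and_labels_consecutive(self, zero_noise_scene):
        img, truth = zero_noise_scene
        assert img.intensity.shape == img.labels.shape
        np.testing.assert_array_equal(
            np.unique(img.labels), np.arange(len(truth) + 1)
        )

    def test_truth_iod_equals_painted_increment_sum(self, zero_noise_scene):
        """With no noise and flat background the recorded ground truth is
        the exact sum of painted intensity above background, per object."""
        img, truth = zero_noise_scene
        bg = 200.0
        for _, row in truth.iterrows():
            mask = img.labels == row.object_id
            painted = img.intensity[mask].sum() - bg * mask.sum()
            assert painted == row.true_iod
            assert mask.sum() == row.true_area

    def test_placement_failure_names_constraint(self):
        spec = SampleSpec(n_cells=200, seed=1)
        scene = ImageSceneSpec(image_size=(64, 64), min_separation=10.0, seed=1)
        with pytest.raises(RuntimeError, match="min_separation"):
            generate_image_sample(spec, scene)

    def test_image_sample_deterministic(self):
        spec = SampleSpec(n_cells=50, seed=8)
        scene = ImageSceneSpec(image_size=(420, 420), seed=3)
        a, _ = generate_image_sample(spec, scene)
        b, _ = generate_image_sample(spec, scene)
        np.testing.assert_array_equal(a.intensity, b.intensity)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestCohort:
    def test_outlier_flags_match_request(self):
        samples, truth = generate_cohort(
            17, SampleSpec(n_cells=100, seed=4), outlier_indices=(0, 11, 16),
            outlier_scale=0.3,
        )
        assert truth["is_outlier"].sum() == 3
        assert list(truth.index[truth["is_outlier"]]) == [0, 11, 16]
        base = truth.loc[1, "icm_scale"]
        np.testing.assert_allclose(
            truth.loc[truth["is_outlier"], "icm_scale"], 0.3 * base
        )

    def test_no_jitter_means_identical_scales(self):
        _, truth = generate_cohort(6, SampleSpec(n_cells=100, seed=4))
        assert truth["icm_scale"].nunique() == 1

    def test_cohort_regeneration_bit_identical(self):
        a, ta = generate_cohort(4, SampleSpec(n_cells=200, seed=77),
                                icm_scale_jitter=0.1)
        b, tb = generate_cohort(4, SampleSpec(n_cells=200, seed=77),
                                icm_scale_jitter=0.1)
        pd.testing.assert_frame_equal(ta, tb)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x.icm_features, y.icm_features)
            pd.testing.assert_frame_equal(x.fcm_events, y.fcm_events)

    def test_outlier_index_out_of_range(self):
        with pytest.raises(IndexError):
            generate_cohort(3, SampleSpec(n_cells=100), outlier_indices=(5,))
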