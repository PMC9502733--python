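"""Fuzzy c-means contracts, uncertainty filtering, population labeling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.cluster import KMeans

from ploidycal import (
    FuzzyCMeans,
    PopulationRatioError,
    SampleSpec,
    filter_uncertain,
    fuzzy_cmeans,
    generate_event_sample,
    label_populations,
)
from ploidycal.pipeline import PipelineSettings, analyze_icm_sample


def _blobs(rng, centers, n_per=60, sd=0.15):
    return np.vstack(
        [np.asarray(c) + sd * rng.standard_normal((n_per, len(c))) for c in centers]
    )


def test_equidistant_point_splits_membership(rng):
    half = _blobs(rng, [(5, 0)], sd=0.1)
    X = np.vstack([half, -half, [[0.0, 0.0]]])  # exactly mirror-symmetric
    clust = fuzzy_cmeans(X, c=2, seed=1)
    u = clust.predict_membership(np.array([[0.0, 0.0]]))[0]
    np.testing.assert_allclose(u, [0.5, 0.5], atol=1e-3)


def test_point_on_center_gets_full_membership(rng):
    X = _blobs(rng, [(0, 0), (10, 10)])
    clust = fuzzy_cmeans(X, c=2, seed=1)
    u = clust.predict_membership(clust.cluster_centers_[:1])[0]
    assert u[0] == 1.0 and u[1] == 0.0


def test_memberships_row_normalized(rng):
    X = rng.uniform(0, 100, size=(300, 2))
    clust = fuzzy_cmeans(X, c=3, seed=2)
    np.testing.assert_allclose(clust.membership_.sum(axis=1), 1.0, atol=1e-9)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(seed=st.integers(0, 10_000), m=st.floats(1.3, 3.0))
def test_membership_normalization_property(seed, m):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((50, 2)) * rng.uniform(0.5, 20)
    clust = FuzzyCMeans(c=3, m=m, random_state=seed).fit(X)
    np.testing.assert_allclose(clust.membership_.sum(axis=1), 1.0, atol=1e-9)
    assert clust.membership_.min() >= 0 and clust.membership_.max() <= 1


def test_argmax_labels_match_kmeans_on_separated_blobs(rng):
    X = _blobs(rng, [(0, 0), (12, 0), (0, 12)])
    cm = fuzzy_cmeans(X, c=3, seed=3)
    km = KMeans(n_clusters=3, n_init=10, random_state=0).fit(X)
    # identical partitions up to label permutation
    from scipy.stats import mode

    agreement = 0
    for k in range(3):
        mapped = mode(km.labels_[cm.labels_ == k]).mode
        agreement += int(((cm.labels_ == k) & (km.labels_ == mapped)).sum())
    assert agreement == len(X)


def test_small_fuzzifier_approaches_kmeans(rng):
    X = _blobs(rng, [(0, 0), (8, 8)], sd=0.5)
    cm = FuzzyCMeans(c=2, m=1.05, random_state=4).fit(X)
    km = KMeans(n_clusters=2, n_init=10, random_state=0).fit(X)
    same = (cm.labels_ == km.labels_).mean()
    assert same in (0.0, 1.0) or max(same, 1 - same) == 1.0


def test_nonconvergence_flagged(rng):
    X = rng.uniform(0, 1, size=(100, 2))
    clust = FuzzyCMeans(c=3, max_iter=2, tol=1e-12, random_state=0).fit(X)
    assert clust.converged_ is False


def test_invalid_parameters_rejected(rng):
    X = rng.uniform(0, 1, size=(10, 2))
    with pytest.raises(ValueError, match="fuzzifier"):
        FuzzyCMeans(c=2, m=1.0).fit(X)
    with pytest.raises(ValueError, match="points"):
        FuzzyCMeans(c=11).fit(X)


class TestFilterUncertain:
    def _clust(self, rng):
        return fuzzy_cmeans(_blobs(rng, [(0, 0), (10, 0), (0, 10)]), c=3, seed=1)

    def test_threshold_semantics(self, rng):
        clust = self._clust(rng)
        maxu = clust.membership_.max(axis=1)
        kept = filter_uncertain(clust, threshold=0.9)
        np.testing.assert_array_equal(kept, maxu >= 0.9)

    def test_threshold_just_above_uniform_keeps_strict_argmax(self, rng):
        clust = self._clust(rng)
        kept = filter_uncertain(clust, threshold=1.0 / 3 + 1e-9)
        strict = clust.membership_.max(axis=1) > 1.0 / 3
        assert kept[strict].all()

    @pytest.mark.parametrize("bad", [0.2, 1.0 / 3, 1.1])
    def test_out_of_range_threshold_rejected(self, rng, bad):
        with pytest.raises(ValueError, match="threshold"):
            filter_uncertain(self._clust(rng), threshold=bad)


class TestLabelPopulations:
    def test_ascending_dna_order_names_clusters(self, rng):
        X = _blobs(rng, [(0, 30), (0, 100), (0, 200)], sd=1.0)
        clust = fuzzy_cmeans(X, c=3, seed=5)
        dna_centers = clust.cluster_centers_[:, 1]
        out = label_populations(clust, dna_centers, threshold=0.5)
        for name, center in (("debris", 30), ("2N", 100), ("4N", 200)):
            sel = out["population"] == name
            assert sel.any()
            np.testing.assert_allclose(X[sel.to_numpy(), 1].mean(), center, atol=5)

    def test_ratio_guard_flags_misclustered_sample(self, rng):
        X = _blobs(rng, [(0, 100), (0, 120), (0, 130)], sd=1.0)
        clust = fuzzy_cmeans(X, c=3, seed=5)
        with pytest.raises(PopulationRatioError):
            label_populations(clust, clust.cluster_centers_[:, 1], threshold=0.5)

    def test_label_invariant_to_cluster_index_permutation(self, rng):
        X = _blobs(rng, [(0, 30), (0, 100), (0, 200)], sd=1.0)
        a = fuzzy_cmeans(X, c=3, seed=5)
        b = fuzzy_cmeans(X, c=3, seed=17)  # different init => index shuffle
        out_a = label_populations(a, a.cluster_centers_[:, 1], threshold=0.5)
        out_b = label_populations(b, b.cluster_centers_[:, 1], threshold=0.5)
        np.testing.assert_array_equal(out_a["population"], out_b["population"])


def test_ground_truth_recovery_on_synthetic_sample():
    """The full per-sample ICM stage recovers at least 95% of the
    generator's non-debris population labels."""
    sample = generate_event_sample(SampleSpec(n_cells=2000, seed=31), "s")
    res = analyze_icm_sample(sample.icm_features, "s", PipelineSettings(), seed=7)
    assigned = res["assignment"]["population"].to_numpy()
    truth = sample.truth["population"].to_numpy()
    scorable = (np.isin(truth, ["2N", "4N"])) & (assigned != "unassigned")
    assert scorable.mean() > 0.7
    assert (assigned[scorable] == truth[scorable]).mean() >= 0.95
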