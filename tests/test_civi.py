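import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import calinski_harabasz_score

from clusterbma.civi import (
    CiviSpec,
    calinski_harabasz,
    ch_pairwise_centroid,
    compute_civi,
    get_index,
    normalise_weights,
    register_index,
    s_dbw,
)
from clusterbma.core import AllocationMatrix, labels_to_allocation
from clusterbma.synthetic_data import SimSpec, generate_clusters

# fixed 6-point configuration: two tight blobs around (0,0) and (10,0)
SIX_POINTS = np.array(
    [[0.1, 0.0], [-0.1, 0.1], [0.0, -0.1], [10.1, 0.0], [9.9, 0.1], [10.0, -0.1]]
)
SIX_LABELS = np.array([1, 1, 1, 2, 2, 2])


def _ch_sums_of_squares_oracle(x, labels):
    """Literal BGSS/WGSS transcription with explicit loops."""
    n, k = x.shape[0], np.unique(labels).size
    grand = x.mean(axis=0)
    bgss = wgss = 0.0
    for lab in np.unique(labels):
        pts = x[labels == lab]
        c = pts.mean(axis=0)
        bgss += len(pts) * np.sum((c - grand) ** 2)
        for p in pts:
            wgss += np.sum((p - c) ** 2)
    return (bgss / (k - 1)) / (wgss / (n - k))


class TestCalinskiHarabasz:
    def test_matches_hand_sums_of_squares(self):
        expected = _ch_sums_of_squares_oracle(SIX_POINTS, SIX_LABELS)
        assert calinski_harabasz(SIX_POINTS, SIX_LABELS) == pytest.approx(
            expected, rel=1e-12
        )

    def test_agrees_with_sklearn(self, rng):
        x = rng.normal(size=(60, 3))
        labels = rng.integers(1, 4, size=60)
        assert calinski_harabasz(x, labels) == pytest.approx(
            calinski_harabasz_score(x, labels), rel=1e-9
        )

    def test_separated_blobs_beat_random_labelling(self, rng):
        shuffled = rng.permutation(SIX_LABELS)
        while np.unique(shuffled[:3]).size == 1:  # avoid recreating the blobs
            shuffled = rng.permutation(SIX_LABELS)
        assert calinski_harabasz(SIX_POINTS, SIX_LABELS) > calinski_harabasz(
            SIX_POINTS, shuffled
        )

    def test_invariant_to_relabelling_and_point_order(self, rng):
        base = calinski_harabasz(SIX_POINTS, SIX_LABELS)
        assert calinski_harabasz(SIX_POINTS, 3 - SIX_LABELS) == pytest.approx(base)
        order = rng.permutation(6)
        assert calinski_harabasz(SIX_POINTS[order], SIX_LABELS[order]) == pytest.approx(
            base
        )

    def test_undefined_cases_raise(self):
        with pytest.raises(ValueError):
            calinski_harabasz(SIX_POINTS, np.ones(6, dtype=int))
        with pytest.raises(ValueError):
            calinski_harabasz(np.zeros((6, 2)), SIX_LABELS)

    def test_pairwise_centroid_variant_differs_for_three_clusters(self):
        x = np.array([[0.0, 0], [0.2, 0], [5, 0], [5.2, 0], [10, 0], [10.2, 0.2]])
        labels = np.array([1, 1, 2, 2, 3, 3])
        standard = calinski_harabasz(x, labels)
        printed = ch_pairwise_centroid(x, labels)
        assert printed != pytest.approx(standard, rel=1e-3)


class TestSDbw:
    def test_density_term_vanishes_for_far_compact_clusters(self):
        x = np.vstack([SIX_POINTS[:3], SIX_POINTS[3:] + [100.0, 0.0]])
        scat_only = s_dbw(x, SIX_LABELS)
        # with Dens_bw = 0 the score reduces to Scat
        sigma = [np.linalg.norm(x[SIX_LABELS == g].var(axis=0)) for g in (1, 2)]
        scat = np.mean(sigma) / np.linalg.norm(x.var(axis=0))
        assert scat_only == pytest.approx(scat, rel=1e-12)

    def test_duplicating_points_leaves_scat_unchanged(self):
        x = np.vstack([SIX_POINTS[:3], SIX_POINTS[3:] + [100.0, 0.0]])
        doubled = np.vstack([x, x])
        labels2 = np.concatenate([SIX_LABELS, SIX_LABELS])
        assert s_dbw(doubled, labels2) == pytest.approx(s_dbw(x, SIX_LABELS), rel=1e-12)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            s_dbw(np.zeros((6, 2)), SIX_LABELS)

    def test_lower_for_better_separated_data(self):
        near = generate_clusters(SimSpec(3, 40, 2, -0.15, seed=3))
        far = generate_clusters(SimSpec(3, 40, 2, 0.4, seed=3))
        assert s_dbw(far.features, far.labels) < s_dbw(near.features, near.labels)


class TestComputeCivi:
    def test_hard_dispatch_equals_direct_call(self, three_blobs):
        alloc = labels_to_allocation(three_blobs.labels, k=3)
        spec = get_index("calinski_harabasz")
        assert compute_civi(spec, three_blobs.features, alloc) == pytest.approx(
            calinski_harabasz(three_blobs.features, three_blobs.labels)
        )

    def test_soft_allocation_scored_via_crisp_projection(self, three_blobs, rng):
        hard = labels_to_allocation(three_blobs.labels, k=3).values
        soft = 0.7 * hard + 0.3 * rng.dirichlet(np.ones(3), size=hard.shape[0])
        soft_alloc = AllocationMatrix(soft / soft.sum(axis=1, keepdims=True))
        spec = get_index("calinski_harabasz")
        labels = np.argmax(soft_alloc.values, axis=1) + 1
        assert compute_civi(spec, three_blobs.features, soft_alloc) == pytest.approx(
            calinski_harabasz(three_blobs.features, labels)
        )

    def test_unknown_index_rejected(self):
        with pytest.raises(KeyError):
            get_index("no_such_index")
        with pytest.raises(KeyError):
            CiviSpec("no_such_index", "maximise")

    def test_registry_is_pluggable(self, three_blobs):
        register_index("always_one", lambda x, labels: 1.0, "maximise")
        alloc = labels_to_allocation(three_blobs.labels, k=3)
        assert compute_civi(get_index("always_one"), three_blobs.features, alloc) == 1.0


class TestNormaliseWeights:
    def test_equal_scores_give_uniform_weights(self):
        w = normalise_weights([5.0, 5.0, 5.0, 5.0], "maximise")
        np.testing.assert_allclose(w.normalised, 0.25)

    def test_maximise_is_proportional(self):
        w = normalise_weights([100.0, 300.0], "maximise")
        np.testing.assert_allclose(w.normalised, [0.25, 0.75])

    def test_minimise_is_reciprocal(self):
        w = normalise_weights([2.0, 2.0, 4.0], "minimise")
        np.testing.assert_allclose(w.normalised, [0.4, 0.4, 0.2])

    @given(
        scores=st.lists(st.floats(0.01, 1e6), min_size=2, max_size=8),
        direction=st.sampled_from(["maximise", "minimise"]),
        scale=st.floats(0.001, 1000.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_sum_to_one_and_scale_invariance(self, scores, direction, scale):
        raw = np.array(scores)
        w1 = normalise_weights(raw, direction).normalised
        w2 = normalise_weights(raw * scale, direction).normalised
        assert abs(w1.sum() - 1.0) < 1e-10
        np.testing.assert_allclose(w1, w2, rtol=1e-9)
        assert np.all(w1 > 0)

    def test_invalid_scores_rejected(self):
        with pytest.raises(ValueError):
            normalise_weights([1.0, -2.0], "maximise")
        with pytest.raises(ValueError):
            normalise_weights([1.0, 0.0], "minimise")
        with pytest.raises(ValueError):
            normalise_weights([0.0, 0.0], "maximise")
        with pytest.raises(ValueError):
            normalise_weights([np.inf, 1.0], "maximise")


def test_civi_trends_with_separation():
    """Mean CH rises and mean S_Dbw falls as planted separation grows."""
    ch_means, sdbw_means = [], []
    for sep in (-0.15, -0.05, 0.1):
        ch_vals, sdbw_vals = [], []
        for rep in range(10):
            data = generate_clusters(SimSpec(3, 60, 2, sep, seed=500 + rep))
            ch_vals.append(calinski_harabasz(data.features, data.labels))
            sdbw_vals.append(s_dbw(data.features, data.labels))
        ch_means.append(np.mean(ch_vals))
        sdbw_means.append(np.mean(sdbw_vals))
    assert ch_means[0] < ch_means[1] < ch_means[2]
    assert sdbw_means[0] > sdbw_means[1] > sdbw_means[2]
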