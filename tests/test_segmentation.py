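"""Weighted DBSCAN, local maxima and cluster splitting against brute-force oracles."""

import numpy as np
import pytest

from imcseg import (
    LabelMap,
    detect_local_maxima,
    points_from_weight_map,
    segment_weight_map,
    split_clusters,
    weighted_dbscan,
    WeightMap,
)

from conftest import make_channel

# ------------------------------------------------------------- oracle


def dbscan_oracle(points, eps, min_weight):
    """O(n²) weighted DBSCAN with the package's deterministic tie rules.

    Core iff the weight of all points within Manhattan distance eps (self
    included) sums to >= min_weight; clusters are density-connected core
    components ordered by their first core pixel (row-major); border points
    join the nearest core point, equidistant ties to the lowest cluster id.
    Returns {(row, col): cluster_id}; noise points are omitted.
    """
    pts = [(int(r), int(c), float(w)) for r, c, w in points]
    n = len(pts)
    nbrs = [
        [
            j
            for j in range(n)
            if abs(pts[i][0] - pts[j][0]) + abs(pts[i][1] - pts[j][1]) <= eps
        ]
        for i in range(n)
    ]
    core = [sum(pts[j][2] for j in nbrs[i]) >= min_weight for i in range(n)]

    comp = [-1] * n
    comps = []
    for i in range(n):
        if core[i] and comp[i] == -1:
            members = [i]
            comp[i] = len(comps)
            stack = [i]
            while stack:
                u = stack.pop()
                for v in nbrs[u]:
                    if core[v] and comp[v] == -1:
                        comp[v] = len(comps)
                        stack.append(v)
                        members.append(v)
            comps.append(members)

    order = sorted(
        range(len(comps)), key=lambda k: min((pts[i][0], pts[i][1]) for i in comps[k])
    )
    cid = {}
    for rank, k in enumerate(order, start=1):
        for i in comps[k]:
            cid[i] = rank

    labels = {}
    for i in range(n):
        if core[i]:
            labels[(pts[i][0], pts[i][1])] = cid[i]
    for i in range(n):
        if core[i]:
            continue
        cand = [
            (
                abs(pts[i][0] - pts[j][0]) + abs(pts[i][1] - pts[j][1]),
                cid[j],
            )
            for j in nbrs[i]
            if core[j]
        ]
        if cand:
            labels[(pts[i][0], pts[i][1])] = min(cand)[1]
    return labels


def canonical(labels: dict):
    """Relabel a {coord: id} partition by first appearance in row-major order."""
    remap = {}
    out = {}
    for coord in sorted(labels):
        lab = labels[coord]
        if lab not in remap:
            remap[lab] = len(remap) + 1
        out[coord] = remap[lab]
    return out


def labelmap_to_dict(lm: LabelMap):
    rr, cc = np.nonzero(lm.data)
    return {(int(r), int(c)): int(lm.data[r, c]) for r, c in zip(rr, cc)}


def random_points(rng, size=16, fill=0.35, unit_weights=False):
    mask = rng.random((size, size)) < fill
    pts = []
    for r, c in np.argwhere(mask):
        w = 1.0 if unit_weights else float(rng.uniform(0.05, 1.0))
        pts.append((int(r), int(c), w))
    return pts


def neighborhood_core_set(points, eps, min_weight):
    """Core points straight from the definition (independent of clustering)."""
    return {
        (r, c)
        for r, c, _ in points
        if sum(
            w2
            for r2, c2, w2 in points
            if abs(r - r2) + abs(c - c2) <= eps
        )
        >= min_weight
    }


# -------------------------------------------------------- weighted DBSCAN


def test_empty_input_gives_all_background():
    lm = weighted_dbscan([], shape=(8, 8), eps=2, min_weight=4)
    assert lm.n_regions == 0
    np.testing.assert_array_equal(lm.data, 0)


def test_isolated_pixel_is_noise():
    lm = weighted_dbscan([(3, 3, 1.0)], shape=(8, 8), eps=2, min_weight=4)
    assert lm.n_regions == 0


def test_plus_shape_forms_single_cluster():
    pts = [(2, 2, 1.0), (1, 2, 1.0), (3, 2, 1.0), (2, 1, 1.0), (2, 3, 1.0)]
    lm = weighted_dbscan(pts, shape=(5, 5), eps=2, min_weight=4)
    got = labelmap_to_dict(lm)
    assert canonical(got) == canonical(dbscan_oracle(pts, 2, 4))
    assert lm.n_regions == 1
    assert len(got) == 5


@pytest.mark.parametrize("unit_weights", [False, True])
def test_matches_bruteforce_oracle_on_random_maps(unit_weights):
    """50 random 16×16 maps; unit weights exercise the classical-DBSCAN reduction."""
    rng = np.random.default_rng(7 if unit_weights else 5)
    for _ in range(50):
        pts = random_points(rng, unit_weights=unit_weights)
        lm = weighted_dbscan(pts, shape=(16, 16), eps=2, min_weight=4)
        assert canonical(labelmap_to_dict(lm)) == canonical(dbscan_oracle(pts, 2, 4))


def test_result_invariant_to_point_order(rng):
    pts = random_points(rng)
    lm1 = weighted_dbscan(pts, shape=(16, 16), eps=2, min_weight=4)
    shuffled = list(pts)
    rng.shuffle(shuffled)
    lm2 = weighted_dbscan(shuffled, shape=(16, 16), eps=2, min_weight=4)
    np.testing.assert_array_equal(lm1.data, lm2.data)


def test_adding_a_point_never_destroys_a_core(rng):
    for _ in range(20):
        pts = random_points(rng, size=10, fill=0.3)
        occupied = {(r, c) for r, c, _ in pts}
        free = [(r, c) for r in range(10) for c in range(10) if (r, c) not in occupied]
        extra = free[rng.integers(len(free))]
        before = neighborhood_core_set(pts, 2, 4)
        after = neighborhood_core_set(pts + [(extra[0], extra[1], 0.9)], 2, 4)
        assert before <= after


def test_weighted_dbscan_input_validation():
    with pytest.raises(ValueError):
        weighted_dbscan([(0, 0, 1.0), (0, 0, 0.5)], shape=(4, 4), eps=2, min_weight=4)
    with pytest.raises(ValueError):
        weighted_dbscan([(9, 0, 1.0)], shape=(4, 4), eps=2, min_weight=4)
    with pytest.raises(ValueError):
        weighted_dbscan([(0, 0, 0.0)], shape=(4, 4), eps=2, min_weight=4)


def test_sklearn_agrees_on_cores_and_core_partition(rng):
    """Cross-check the weighted-core semantics against scikit-learn's DBSCAN."""
    DBSCAN = pytest.importorskip("sklearn.cluster").DBSCAN
    for _ in range(10):
        pts = random_points(rng)
        X = np.array([(r, c) for r, c, _ in pts], dtype=float)
        sw = np.array([w for _, _, w in pts])
        db = DBSCAN(eps=2, min_samples=4, metric="manhattan", leaf_size=3).fit(
            X, sample_weight=sw
        )
        sk_cores = {tuple(map(int, X[i])) for i in db.core_sample_indices_}
        assert sk_cores == neighborhood_core_set(pts, 2, 4)
        # core partitions agree up to label permutation
        lm = weighted_dbscan(pts, shape=(16, 16), eps=2, min_weight=4)
        ours = labelmap_to_dict(lm)
        pairing = {}
        for i in db.core_sample_indices_:
            coord = tuple(map(int, X[i]))
            sk_lab = db.labels_[i]
            assert pairing.setdefault(sk_lab, ours[coord]) == ours[coord]
        assert len(set(pairing.values())) == len(pairing)


def test_points_from_weight_map_roundtrip(rng):
    w = np.zeros((8, 8))
    w[2, 3] = 0.5
    w[5, 5] = 1.0
    pts = points_from_weight_map(WeightMap(w))
    assert sorted(pts) == [(2, 3, 0.5), (5, 5, 1.0)]
    lm1 = weighted_dbscan(pts, shape=(8, 8), eps=2, min_weight=1)
    lm2 = segment_weight_map(WeightMap(w), eps=2, min_weight=1)
    np.testing.assert_array_equal(lm1.data, lm2.data)


# ----------------------------------------------------------- local maxima


def render_blob(shape, center, amp=10.0, sigma=3.0):
    H, W = shape
    rr, cc = np.mgrid[0:H, 0:W]
    return amp * np.exp(
        -((rr - center[0]) ** 2 + (cc - center[1]) ** 2) / (2 * sigma**2)
    )


def test_all_zero_image_has_no_maxima():
    assert detect_local_maxima(make_channel(np.zeros((10, 10)))) == set()


def test_single_blob_has_one_maximum_at_center():
    img = render_blob((41, 41), (20, 20))
    assert detect_local_maxima(make_channel(img)) == {(20, 20)}


def test_two_blobs_give_two_maxima():
    img = render_blob((41, 61), (20, 15)) + render_blob((41, 61), (20, 45))
    assert detect_local_maxima(make_channel(img)) == {(20, 15), (20, 45)}


def test_plateau_merges_to_lexicographically_smallest():
    img = np.zeros((5, 7))
    img[2, 2] = img[2, 3] = img[2, 4] = 5.0  # flat 3-pixel ridge
    assert detect_local_maxima(make_channel(img)) == {(2, 2)}


def test_footprint_radius_controls_merging():
    img = np.zeros((9, 21))
    img[4, 4] = img[4, 12] = 5.0  # 8 px apart
    assert detect_local_maxima(make_channel(img), footprint_radius=1) == {
        (4, 4),
        (4, 12),
    }
    # within a radius-9 footprint the weaker equal peak is no longer separate,
    # but equal-valued peaks that see each other merge into one plateau
    assert detect_local_maxima(make_channel(img), footprint_radius=9) == {(4, 4)}


# -------------------------------------------------------- cluster splitting


def test_single_maximum_leaves_cluster_unchanged():
    labels = LabelMap(np.pad(np.ones((3, 3), int), 1))
    out = split_clusters(labels, {(2, 2)})
    np.testing.assert_array_equal(out.data, labels.data)


def test_line_cluster_split_with_tie_rule():
    labels = LabelMap(np.ones((1, 9), int))
    out = split_clusters(labels, {(0, 1), (0, 7)})
    expected = np.array([[1, 1, 1, 1, 1, 2, 2, 2, 2]])  # col 4 ties -> (0,1)
    np.testing.assert_array_equal(out.data, expected)


def test_dumbbell_split_matches_nearest_maximum_oracle():
    img = render_blob((24, 40), (12, 12), sigma=4) + render_blob(
        (24, 40), (12, 26), sigma=4
    )
    mask = img > 0.8  # one connected dumbbell
    from scipy import ndimage

    n_comp = ndimage.label(mask)[1]
    assert n_comp == 1
    labels = LabelMap(mask.astype(int))
    maxima = detect_local_maxima(make_channel(img))
    assert maxima == {(12, 12), (12, 26)}
    out = split_clusters(labels, maxima)
    assert out.n_regions == 2
    ms = sorted(maxima)
    for r, c in np.argwhere(mask):
        d = [(r - mr) ** 2 + (c - mc) ** 2 for mr, mc in ms]
        expected = 1 + int(np.argmin(d))
        # label ids are ordered by first member pixel: left half first
        assert out.data[r, c] == expected


def test_split_conserves_pixels_and_never_merges(rng):
    arr = np.zeros((20, 20), int)
    arr[2:8, 2:8] = 1
    arr[12:18, 10:19] = 2
    labels = LabelMap(arr)
    maxima = {(3, 3), (6, 6), (14, 12), (14, 17), (16, 13)}
    out = split_clusters(labels, maxima)
    assert out.n_regions == 5
    np.testing.assert_array_equal(out.data > 0, arr > 0)
    # never merges: every output region lies inside exactly one input region
    for k in range(1, out.n_regions + 1):
        parents = np.unique(arr[out.data == k])
        assert len(parents) == 1


def test_cluster_without_maxima_is_retained():
    labels = LabelMap(np.pad(np.ones((2, 2), int), 1))
    out = split_clusters(labels, set())
    np.testing.assert_array_equal(out.data, labels.data)
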