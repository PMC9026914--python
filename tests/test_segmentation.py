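import heapq
import warnings

import numpy as np
import pytest

from mitohcs.segmentation import (
    N_BINS,
    LabelMap,
    ThresholdSpec,
    compute_threshold,
    filter_objects,
    identify_primary,
    identify_secondary_propagation,
    identify_tertiary,
    measure_objects,
)

# ---------------------------------------------------------------------------
# exhaustive-search threshold oracles (independent of the implementation)


def _hist(values):
    return np.bincount(
        np.clip((np.asarray(values).ravel() * N_BINS).astype(int), 0, N_BINS - 1),
        minlength=N_BINS,
    ).astype(float)


def _mid_tie(scores, maximize=True):
    """Index of the middle element of the tied-optimum plateau (the shared
    tie-break convention: an empty histogram gap thresholds mid-gap)."""
    scores = np.asarray(scores, float)
    best = scores.max() if maximize else scores.min()
    eps = 1e-12 * max(abs(best), 1.0)
    tied = np.flatnonzero(scores >= best - eps) if maximize else np.flatnonzero(
        scores <= best + eps
    )
    return int(tied[len(tied) // 2])


def otsu2_oracle(values):
    hist = _hist(values)
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    scores = np.full(N_BINS - 1, -np.inf)
    for t in range(N_BINS - 1):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        if w0 == 0 or w1 == 0:
            continue
        m0 = (hist[: t + 1] * centers[: t + 1]).sum() / w0
        m1 = (hist[t + 1 :] * centers[t + 1 :]).sum() / w1
        scores[t] = w0 * w1 * (m0 - m1) ** 2
    return (_mid_tie(scores) + 1) / N_BINS


def otsu3_oracle(values, middle_class):
    hist = _hist(values)
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    wc = np.concatenate([[0.0], np.cumsum(hist)])
    mc = np.concatenate([[0.0], np.cumsum(hist * centers)])
    scores = {}
    for t1 in range(1, N_BINS - 1):
        for t2 in range(t1 + 1, N_BINS):
            s = 0.0
            for lo, hi in ((0, t1), (t1, t2), (t2, N_BINS)):
                w = wc[hi] - wc[lo]
                if w > 0:
                    m = mc[hi] - mc[lo]
                    s += m * m / w
            scores[(t1, t2)] = s
    best = max(scores.values())
    eps = 1e-12 * max(abs(best), 1.0)
    tied = [pair for pair, s in scores.items() if s >= best - eps]
    idx = 0 if middle_class == "foreground" else 1
    cuts = sorted({pair[idx] for pair in tied})
    return cuts[len(cuts) // 2] / N_BINS


def li_oracle(values):
    hist = _hist(values)
    centers = (np.arange(N_BINS) + 0.5) / N_BINS
    etas = np.full(N_BINS - 1, np.inf)
    for t in range(N_BINS - 1):
        w0 = hist[: t + 1].sum()
        w1 = hist[t + 1 :].sum()
        s0 = (hist[: t + 1] * centers[: t + 1]).sum()
        s1 = (hist[t + 1 :] * centers[t + 1 :]).sum()
        eta = 0.0
        if s0 > 0:
            eta -= s0 * np.log(s0 / w0)
        if s1 > 0:
            eta -= s1 * np.log(s1 / w1)
        etas[t] = eta
    return (_mid_tie(etas, maximize=False) + 1) / N_BINS


def random_bimodal(rng, shape=(64, 64)):
    a = rng.normal(0.25, 0.08, shape)
    b = rng.normal(0.7, 0.08, shape)
    pick = rng.random(shape) < rng.uniform(0.2, 0.8)
    return np.clip(np.where(pick, a, b), 0, 1)


class TestThresholds:
    def test_otsu2_two_level(self, make_image):
        img = np.concatenate([np.full(100, 0.1), np.full(100, 0.9)]).reshape(10, 20)
        thr = compute_threshold(make_image(img), ThresholdSpec(method="otsu2"))
        assert 0.1 < thr < 0.9
        assert np.all((img > thr) == (img == 0.9))
        assert abs(thr - otsu2_oracle(img)) <= 1 / N_BINS

    def test_otsu3_middle_class_assignment(self, make_image):
        img = np.repeat([0.1, 0.5, 0.9], 100).reshape(10, 30)
        lo = compute_threshold(
            make_image(img), ThresholdSpec(method="otsu3", middle_class="foreground")
        )
        hi = compute_threshold(
            make_image(img), ThresholdSpec(method="otsu3", middle_class="background")
        )
        assert np.all((img > lo) == (img >= 0.5))  # middle kept
        assert np.all((img > hi) == (img == 0.9))  # middle dropped
        assert abs(lo - otsu3_oracle(img, "foreground")) <= 1 / N_BINS
        assert abs(hi - otsu3_oracle(img, "background")) <= 1 / N_BINS

    def test_constant_image_degenerate(self, make_image):
        img = make_image(np.full((8, 8), 0.3))
        with pytest.warns(UserWarning, match="degenerate"):
            thr = compute_threshold(img, ThresholdSpec(method="otsu2"))
        assert thr == pytest.approx(0.3, abs=1 / N_BINS)
        assert not np.any(img.pixels > thr)

    @pytest.mark.parametrize("method", ["otsu2", "min_cross_entropy"])
    def test_oracle_agreement_on_random_images(self, make_image, rng, method):
        oracle = {"otsu2": otsu2_oracle, "min_cross_entropy": li_oracle}[method]
        for _ in range(20):
            img = random_bimodal(rng)
            thr = compute_threshold(make_image(img), ThresholdSpec(method=method))
            assert abs(thr - oracle(img)) <= 1 / N_BINS + 1e-12

    def test_otsu3_oracle_agreement_on_random_images(self, make_image, rng):
        for _ in range(5):
            img = random_bimodal(rng, (32, 32))
            for mc in ("foreground", "background"):
                thr = compute_threshold(
                    make_image(img), ThresholdSpec(method="otsu3", middle_class=mc)
                )
                assert abs(thr - otsu3_oracle(img, mc)) <= 1 / N_BINS + 1e-12

    def test_li_lies_between_gaussian_means(self, make_image, rng):
        img = random_bimodal(rng)
        thr = compute_threshold(make_image(img), ThresholdSpec(method="min_cross_entropy"))
        assert 0.25 < thr < 0.7

    def test_adaptive_grid_within_bounds(self, make_image, rng):
        img = random_bimodal(rng, (128, 128))
        spec = ThresholdSpec(scope="adaptive", method="otsu2", window=51, bounds=(0.2, 0.8))
        grid = compute_threshold(make_image(img), spec)
        assert grid.shape == img.shape
        assert grid.min() >= 0.2 and grid.max() <= 0.8

    def test_manual_threshold(self, make_image):
        spec = ThresholdSpec(method="manual", manual_value=0.42)
        assert compute_threshold(make_image(np.zeros((4, 4))), spec) == 0.42

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            ThresholdSpec(window=4)
        with pytest.raises(ValueError):
            ThresholdSpec(method="manual")
        with pytest.raises(ValueError):
            ThresholdSpec(bounds=(0.9, 0.1))


# ---------------------------------------------------------------------------


def disk_image(n, center, radius, value=0.9, background=0.05):
    Y, X = np.mgrid[0:n, 0:n]
    img = np.full((n, n), background)
    img[(Y - center[0]) ** 2 + (X - center[1]) ** 2 <= radius**2] = value
    return img


class TestIdentifyPrimary:
    SPEC = ThresholdSpec(method="otsu2")

    def test_single_disk_area(self, make_image):
        img = disk_image(64, (32, 32), 10)
        labels = identify_primary(make_image(img), self.SPEC, (5, 50))
        assert labels.n_objects == 1
        area = (labels.labels == 1).sum()
        assert abs(area - np.pi * 100) < 0.05 * np.pi * 100

    def test_small_object_rejected_by_diameter(self, make_image):
        img = disk_image(64, (16, 16), 10)
        img = np.maximum(img, disk_image(64, (48, 48), 2))
        labels = identify_primary(make_image(img), self.SPEC, (8, 40))
        assert labels.n_objects == 1

    def test_border_exclusion(self, make_image):
        img = disk_image(64, (0, 32), 10)
        labels = identify_primary(make_image(img), self.SPEC, (5, 50), exclude_border=True)
        assert labels.n_objects == 0

    def test_labels_are_compact(self, make_image, rng):
        img = np.clip(rng.random((64, 64)), 0, 1)
        labels = identify_primary(make_image(img), self.SPEC, (1, 64))
        ids = labels.label_ids
        assert np.array_equal(ids, np.arange(1, len(ids) + 1))


def propagation_dijkstra_oracle(image, seeds, mask, regularization):
    """Exhaustive shortest-path assignment on the pixel grid (heapq Dijkstra)."""
    nr, nc = image.shape
    region = mask | (seeds > 0)
    dist = np.full((nr, nc), np.inf)
    label = np.zeros((nr, nc), int)
    heap = []
    for r, c in zip(*np.nonzero(seeds)):
        dist[r, c] = 0.0
        label[r, c] = seeds[r, c]
        heapq.heappush(heap, (0.0, int(seeds[r, c]), r, c))
    while heap:
        d, lab, r, c = heapq.heappop(heap)
        if d > dist[r, c] + 1e-15:
            continue
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                r2, c2 = r + dr, c + dc
                if not (0 <= r2 < nr and 0 <= c2 < nc) or not region[r2, c2]:
                    continue
                step = abs(image[r, c] - image[r2, c2]) + regularization * np.hypot(dr, dc)
                nd = d + step
                if nd < dist[r2, c2] - 1e-15:
                    dist[r2, c2] = nd
                    label[r2, c2] = lab
                    heapq.heappush(heap, (nd, lab, r2, c2))
    return label


class TestPropagation:
    def test_single_seed_fills_single_basin(self, make_image):
        img = disk_image(48, (24, 24), 12)
        seeds = np.zeros((48, 48), int)
        seeds[24, 24] = 1
        out = identify_secondary_propagation(
            make_image(img), LabelMap(seeds), ThresholdSpec(method="otsu2"), 0.05
        )
        assert np.array_equal(out.as_mask(), img > 0.5)

    def test_two_seeds_divide_at_bisector(self, make_image):
        img = np.full((20, 40), 0.9)
        seeds = np.zeros((20, 40), int)
        seeds[10, 8] = 1
        seeds[10, 31] = 2
        spec = ThresholdSpec(method="manual", manual_value=0.5)
        out = identify_secondary_propagation(make_image(img), LabelMap(seeds), spec, 0.05)
        oracle = propagation_dijkstra_oracle(img, seeds, img > 0.5, 0.05)
        # same cost model: agreement away from exact ties (within 1 px of bisector)
        cols = np.arange(40)
        left = out.labels[:, cols < 19]
        right = out.labels[:, cols > 20]
        assert np.all(left == 1) and np.all(right == 2)
        disagreement = (out.labels != oracle).mean()
        assert disagreement < 0.06

    def test_large_regularization_approaches_nearest_seed(self, make_image):
        img = np.full((30, 30), 0.9)
        seeds = np.zeros((30, 30), int)
        seeds[5, 5] = 1
        seeds[24, 24] = 2
        spec = ThresholdSpec(method="manual", manual_value=0.5)
        out = identify_secondary_propagation(make_image(img), LabelMap(seeds), spec, 100.0)
        Y, X = np.mgrid[0:30, 0:30]
        d1 = np.hypot(Y - 5, X - 5)
        d2 = np.hypot(Y - 24, X - 24)
        clear = np.abs(d1 - d2) > 1.5  # away from the tie zone
        expected = np.where(d1 < d2, 1, 2)
        assert (out.labels[clear] == expected[clear]).mean() > 0.98

    def test_partition_and_label_correspondence(self, make_image, rng):
        img = np.clip(rng.random((40, 40)) * 0.3 + 0.5, 0, 1)
        seeds = np.zeros((40, 40), int)
        seeds[10, 10] = 1
        seeds[30, 30] = 2
        seeds[10, 30] = 3
        spec = ThresholdSpec(method="manual", manual_value=0.4)
        out = identify_secondary_propagation(make_image(img), LabelMap(seeds), spec, 0.05)
        assert set(out.label_ids) == {1, 2, 3}
        # above-threshold pixels are fully assigned
        assert np.all(out.labels[img > 0.4] > 0)
        # each secondary object contains its seed
        for sid in (1, 2, 3):
            assert np.all(out.labels[seeds == sid] == sid)

    def test_seed_below_threshold_keeps_itself(self, make_image):
        img = np.full((16, 16), 0.1)
        img[2:5, 2:5] = 0.9
        seeds = np.zeros((16, 16), int)
        seeds[3, 3] = 1
        seeds[12, 12] = 2  # in dark area
        spec = ThresholdSpec(method="manual", manual_value=0.5)
        with pytest.warns(UserWarning, match="below threshold"):
            out = identify_secondary_propagation(make_image(img), LabelMap(seeds), spec, 0.05)
        assert (out.labels == 2).sum() == 1
        assert out.labels[12, 12] == 2


class TestTertiary:
    def test_nested_subtraction(self):
        sec = np.zeros((20, 20), int)
        sec[2:12, 2:12] = 1  # area 100
        pri = np.zeros((20, 20), int)
        pri[4:10, 4:9] = 1  # area 30, nested
        ter = identify_tertiary(LabelMap(sec), LabelMap(pri))
        assert (ter.labels == 1).sum() == 70

    def test_partial_overlap(self):
        sec = np.zeros((20, 20), int)
        sec[0:10, 0:10] = 1  # area 100
        pri = np.zeros((20, 20), int)
        pri[8:14, 0:5] = 1  # area 30, overlap 10 (rows 8-9)
        ter = identify_tertiary(LabelMap(sec), LabelMap(pri))
        assert (ter.labels == 1).sum() == 90

    def test_empty_primary_is_identity(self):
        sec = np.zeros((10, 10), int)
        sec[2:6, 2:6] = 1
        ter = identify_tertiary(LabelMap(sec), LabelMap(np.zeros((10, 10), int)))
        assert np.array_equal(ter.labels, sec)

    def test_orphan_primary_warns(self):
        sec = np.zeros((10, 10), int)
        sec[0:4, 0:4] = 1
        pri = np.zeros((10, 10), int)
        pri[6:8, 6:8] = 5
        with pytest.warns(UserWarning, match="without matching"):
            identify_tertiary(LabelMap(sec), LabelMap(pri))

    def test_exact_area_identity(self, rng):
        """area(secondary) = area(tertiary) + area(secondary ∩ primary) per object."""
        sec = rng.integers(0, 4, (50, 50))
        pri = np.where(rng.random((50, 50)) < 0.3, sec, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ter = identify_tertiary(LabelMap(sec), LabelMap(pri))
        for lab in (1, 2, 3):
            a_sec = (sec == lab).sum()
            a_int = ((pri == lab) & (sec == lab)).sum()
            assert (ter.labels == lab).sum() == a_sec - a_int


class TestFilterObjects:
    def _three_objects(self):
        labels = np.zeros((40, 80), int)
        labels[0:5, 0:6] = 1      # area 30
        labels[10:20, 0:10] = 2   # area 100
        labels[22:38, 20:60] = 3  # area 640
        return LabelMap(labels)

    def test_area_criterion(self):
        lm = self._three_objects()
        meas = measure_objects(lm)
        out = filter_objects(lm, meas, [("area", 50, 500)])
        assert out.n_objects == 1
        assert (out.labels == 1).sum() == 100  # relabeled survivor

    def test_eccentricity_removes_line(self):
        labels = np.zeros((20, 20), int)
        labels[10, 2:18] = 1  # 1-px line, eccentricity ~ 1
        labels[2:8, 2:8] = 2
        lm = LabelMap(labels)
        out = filter_objects(lm, measure_objects(lm), [("eccentricity", 0.0, 0.95)])
        assert out.n_objects == 1

    def test_no_criteria_is_identity(self):
        lm = self._three_objects()
        out = filter_objects(lm, measure_objects(lm), [])
        assert np.array_equal(out.labels, lm.labels)

    def test_idempotent(self):
        lm = self._three_objects()
        crit = [("area", 50, 1000)]
        once = filter_objects(lm, measure_objects(lm), crit)
        twice = filter_objects(once, measure_objects(once), crit)
        assert np.array_equal(once.labels, twice.labels)

    def test_unknown_feature_lists_available(self):
        lm = self._three_objects()
        with pytest.raises(KeyError, match="available"):
            filter_objects(lm, measure_objects(lm), [("bogus", 0, 1)])

    def test_drop_border(self):
        lm = self._three_objects()  # objects 1 and 2 touch the border
        out = filter_objects(lm, measure_objects(lm), [], drop_border=True)
        assert out.n_objects == 1
        assert (out.labels == 1).sum() == 640  # the interior object survives


class TestMeasurements:
    def test_integrated_equals_mean_times_area(self, make_image, rng):
        labels = np.zeros((30, 30), int)
        labels[5:15, 5:15] = 1
        labels[20:28, 20:25] = 2
        img = make_image(rng.random((30, 30)))
        meas = measure_objects(LabelMap(labels), {"ch": img})
        for lab in (1, 2):
            expect = img.pixels[labels == lab].sum()
            assert meas.loc[lab, "integrated_ch"] == pytest.approx(expect, abs=1e-9)
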