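"""Tests for the pixel-wise Spearman correlation map."""

import dataclasses
from itertools import permutations

import numpy as np
import pytest
from scipy.stats import rankdata

from blotmap.corrmap import (
    detect_regions,
    pixelwise_spearman,
    region_statistic,
    render_correlation_map,
    significance_mask,
    SignificanceMasks,
)
from blotmap.errors import DegenerateInputError, ParameterError, StateError
from blotmap.prep import CovariateVector, GelImage, ImageStack, preprocess_stack
from blotmap.stats import spearman
from blotmap.synthetic import generate_study

from conftest import brute_spearman


def _stack_from_array(data, kind="continuous"):
    """Wrap an (n, h, w) array as an aligned/normalized stack."""
    ids = [f"s{i}" for i in range(len(data))]
    stack = ImageStack(
        [GelImage(np.asarray(d, dtype=float), sid) for d, sid in zip(data, ids)],
        aligned=True,
        normalized=True,
    )
    return stack, ids


class TestPixelwiseSpearman:
    def test_monotone_pixel_reaches_r_one(self, rng):
        n = 8
        data = rng.uniform(1, 2, (n, 4, 4))
        cov = np.arange(n, dtype=float)
        data[:, 1, 2] = np.exp(cov)  # strictly increasing in covariate
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, cov))
        assert cmap.r[1, 2] == pytest.approx(1.0)
        assert cmap.p[1, 2] == pytest.approx(np.finfo(float).tiny)

    def test_constant_pixel_is_undefined_not_zero(self, rng):
        n = 6
        data = rng.uniform(1, 2, (n, 3, 3))
        data[:, 0, 0] = 7.0
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, np.arange(n, dtype=float)))
        assert cmap.undefined_mask[0, 0]
        assert np.isnan(cmap.r[0, 0])
        assert not cmap.undefined_mask[1, 1]

    @pytest.mark.parametrize("n", [5, 7, 9, 12])
    def test_matches_brute_force_oracle(self, n, rng):
        data = rng.integers(0, 9, (n, 8, 8)).astype(float)
        cov = rng.normal(size=n)
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, cov))
        for y in range(8):
            for x in range(8):
                vals = data[:, y, x]
                if np.unique(vals).size < 2:
                    assert cmap.undefined_mask[y, x]
                else:
                    assert cmap.r[y, x] == pytest.approx(
                        brute_spearman(vals, cov), abs=1e-12
                    )

    def test_exact_permutation_p_matches_enumeration(self, rng):
        n = 6
        data = rng.integers(0, 5, (n, 3, 3)).astype(float)
        cov = rng.normal(size=n)
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(
            stack, CovariateVector(ids, cov), p_mode="exact"
        )
        cov_ranks = rankdata(cov)
        for y in range(3):
            for x in range(3):
                vals = data[:, y, x]
                if np.unique(vals).size < 2:
                    continue
                r_obs = abs(brute_spearman(vals, cov))
                count = 0
                for perm in permutations(range(n)):
                    r_p = brute_spearman(vals, cov_ranks[list(perm)])
                    if abs(r_p) >= r_obs - 1e-12:
                        count += 1
                assert cmap.p[y, x] == pytest.approx(count / 720)

    def test_antisymmetry_under_covariate_negation(self, rng):
        data = rng.uniform(0, 1, (9, 6, 6))
        cov = rng.normal(size=9)
        stack, ids = _stack_from_array(data)
        a = pixelwise_spearman(stack, CovariateVector(ids, cov))
        b = pixelwise_spearman(stack, CovariateVector(ids, -cov))
        np.testing.assert_allclose(a.r, -b.r, atol=1e-14)
        np.testing.assert_allclose(a.p, b.p, atol=1e-14)

    def test_monotone_intensity_transform_invariance(self, rng):
        data = rng.uniform(0.1, 5.0, (8, 5, 5))
        cov = rng.normal(size=8)
        stack, ids = _stack_from_array(data)
        warped, _ = _stack_from_array(np.exp(data) + data**3)
        a = pixelwise_spearman(stack, CovariateVector(ids, cov))
        b = pixelwise_spearman(warped, CovariateVector(ids, cov))
        np.testing.assert_allclose(a.r, b.r, atol=1e-12)

    def test_missing_covariate_drops_sample(self, rng):
        data = rng.uniform(0, 1, (8, 4, 4))
        cov = rng.normal(size=8)
        cov[3] = np.nan
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, cov))
        assert cmap.n == 7

    def test_unprepped_stack_rejected(self, rng):
        data = rng.uniform(0, 1, (6, 4, 4))
        ids = [f"s{i}" for i in range(6)]
        stack = ImageStack([GelImage(d, i) for d, i in zip(data, ids)])
        with pytest.raises(StateError):
            pixelwise_spearman(stack, CovariateVector(ids, np.arange(6.0)))

    def test_constant_covariate_rejected(self, rng):
        data = rng.uniform(0, 1, (6, 4, 4))
        stack, ids = _stack_from_array(data)
        with pytest.raises(DegenerateInputError):
            pixelwise_spearman(stack, CovariateVector(ids, np.ones(6)))

    def test_null_covariate_p_calibration(self):
        # Under an independent covariate every pixel is a true null;
        # with i.i.d. noise pixels the tests are independent, so the
        # p<0.05 rate must sit within 3 binomial SEs of 0.05.
        rng = np.random.default_rng(404)
        n, h, w = 21, 128, 128
        data = rng.normal(100.0, 10.0, (n, h, w))
        cov = rng.normal(size=n)
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, cov))
        frac = float((cmap.p < 0.05).mean())
        se = np.sqrt(0.05 * 0.95 / (h * w))
        assert abs(frac - 0.05) < 3 * se


class TestSignificanceMask:
    def test_alpha_bounds_enforced(self, rng):
        data = rng.uniform(0, 1, (6, 3, 3))
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, np.arange(6.0)))
        for alpha in (0.0, 1.0, -0.1, 1.5):
            with pytest.raises(ParameterError):
                significance_mask(cmap, alpha)

    def test_weak_map_gives_empty_masks(self, rng):
        data = rng.uniform(0, 1, (8, 6, 6))
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, rng.normal(size=8)))
        cmap.p[:] = 0.5
        masks = significance_mask(cmap, 0.005)
        assert not masks.positive.any() and not masks.negative.any()

    def test_masks_split_by_sign(self, rng):
        n = 12
        cov = np.arange(n, dtype=float)
        data = rng.uniform(0, 1, (n, 2, 2))
        data[:, 0, 0] = cov  # perfect positive
        data[:, 1, 1] = -cov  # perfect negative
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, cov))
        masks = significance_mask(cmap, 0.005)
        assert masks.positive[0, 0] and not masks.negative[0, 0]
        assert masks.negative[1, 1] and not masks.positive[1, 1]

    def test_planted_spot_core_detected(self):
        # FL planted at rho 0.8, n=21: at least 90% of the FL spot-core
        # pixels must enter the positive mask at alpha=0.005, averaged
        # over 50 seeds.  Core masks are translated into the aligned
        # stack's frame (the reference sample's coordinates).
        from blotmap.synthetic import translate_image, vpa_study_config

        hits, total = 0, 0
        for seed in range(50):
            cfg = vpa_study_config(seed=seed)
            stack, cov, truth = generate_study(cfg)
            prepped, _ = preprocess_stack(stack)
            cmap = pixelwise_spearman(prepped, cov)
            masks = significance_mask(cmap, 0.005)
            core = cfg.region_mask("FL", n_sigma=0.75)
            dy0, dx0 = (int(s) for s in truth.shifts[0])
            core = translate_image(core.astype(float), dy0, dx0, 0.0) > 0.5
            hits += int(masks.positive[core].sum())
            total += int(core.sum())
        assert hits / total >= 0.90


class TestDetectRegions:
    def test_planted_region_recovered_in_most_seeds(self):
        # Type recovery: a planted rho=0.8 region at n=21 is detected
        # (>= 50% overlap with the true spot cores) in >= 90% of seeds
        # at alpha=0.005, min_area=20.  Note the feasibility boundary:
        # per-pixel p < 0.005 at n = 21 requires |r| > 0.594, so planted
        # coefficients at or just above 0.5 cannot clear this alpha at
        # the pixel level no matter how clean the data.
        from blotmap.prep import preprocess_stack as prep
        from blotmap.synthetic import translate_image, vpa_study_config

        ok, N = 0, 50
        for seed in range(N):
            cfg = vpa_study_config(seed=seed)
            stack, cov, truth = generate_study(cfg)
            prepped, _ = prep(stack)
            masks = significance_mask(pixelwise_spearman(prepped, cov), 0.005)
            regions = detect_regions(masks, min_area=20)
            dy0, dx0 = (int(v) for v in truth.shifts[0])
            core = cfg.region_mask("FL", n_sigma=1.0)
            core = translate_image(core.astype(float), dy0, dx0, 0.0) > 0.5
            det = np.zeros_like(core)
            for r in regions:
                if r.sign == "positive":
                    det |= r.mask
            ok += (det & core).sum() / core.sum() >= 0.5
        assert ok / N >= 0.90

    def test_empty_masks_give_no_regions(self):
        z = np.zeros((10, 10), dtype=bool)
        assert detect_regions(SignificanceMasks(z, z), min_area=5) == []

    def test_two_disjoint_blobs_found(self):
        pos = np.zeros((20, 20), dtype=bool)
        pos[2:6, 2:6] = True
        pos[10:15, 10:15] = True
        neg = np.zeros_like(pos)
        regions = detect_regions(SignificanceMasks(pos, neg), min_area=4)
        assert len(regions) == 2
        assert {r.sign for r in regions} == {"positive"}

    def test_min_area_filters_speckle(self):
        pos = np.zeros((10, 10), dtype=bool)
        pos[3:5, 3:5] = True  # 4 px
        neg = np.zeros_like(pos)
        assert detect_regions(SignificanceMasks(pos, neg), min_area=5) == []

    def test_diagonal_touch_is_one_region(self):
        # 8-connectivity merges diagonal neighbours
        pos = np.zeros((6, 6), dtype=bool)
        pos[0:2, 0:2] = True
        pos[2, 2] = True
        neg = np.zeros_like(pos)
        regions = detect_regions(SignificanceMasks(pos, neg), min_area=1)
        assert len(regions) == 1


class TestRegionStatistic:
    def test_single_pixel_region_equals_map_value(self, rng):
        data = rng.uniform(0, 1, (9, 5, 5))
        cov = rng.normal(size=9)
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, cov))
        region = np.zeros((5, 5), dtype=bool)
        region[2, 3] = True
        res = region_statistic(stack, CovariateVector(ids, cov), region)
        assert res.r == pytest.approx(cmap.r[2, 3], abs=1e-12)
        assert res.p == pytest.approx(cmap.p[2, 3], abs=1e-12)

    def test_matches_cohort_spearman_on_exported_sums(self, rng):
        data = rng.uniform(0, 1, (10, 6, 6))
        cov = rng.normal(size=10)
        stack, ids = _stack_from_array(data)
        region = np.zeros((6, 6), dtype=bool)
        region[1:4, 2:5] = True
        res = region_statistic(stack, CovariateVector(ids, cov), region)
        sums = data[:, region].sum(axis=1)
        ref = spearman(sums, cov)
        assert res.r == pytest.approx(ref.r, abs=1e-14)
        assert res.t == pytest.approx(ref.t, abs=1e-12)

    def test_zero_variance_region_flagged_undefined(self):
        data = np.ones((6, 4, 4))
        stack, ids = _stack_from_array(data)
        region = np.ones((4, 4), dtype=bool)
        res = region_statistic(
            stack, CovariateVector(ids, np.arange(6.0)), region
        )
        assert np.isnan(res.r)

    def test_empty_region_rejected(self, rng):
        data = rng.uniform(0, 1, (6, 4, 4))
        stack, ids = _stack_from_array(data)
        with pytest.raises(ParameterError):
            region_statistic(
                stack,
                CovariateVector(ids, np.arange(6.0)),
                np.zeros((4, 4), dtype=bool),
            )


class TestRender:
    def test_perfect_positive_pixel_is_pure_red(self, rng):
        n = 12
        cov = np.arange(n, dtype=float)
        data = rng.uniform(0, 1, (n, 3, 3))
        data[:, 1, 1] = cov
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, cov))
        rgb = render_correlation_map(cmap, alpha=0.005)
        assert tuple(rgb[1, 1]) == (255, 0, 0)

    def test_nonsignificant_map_is_uniform_gray(self, rng):
        data = rng.uniform(0, 1, (8, 4, 4))
        stack, ids = _stack_from_array(data)
        cmap = pixelwise_spearman(stack, CovariateVector(ids, rng.normal(size=8)))
        cmap.p[:] = 0.5
        rgb = render_correlation_map(cmap, alpha=0.005)
        assert np.all(rgb == 128)

    def test_covariate_negation_swaps_red_and_blue(self, rng):
        n = 14
        data = rng.uniform(0, 1, (n, 8, 8))
        cov = rng.normal(size=n)
        data[:, 2, 2] = cov + rng.normal(0, 1e-3, n)
        data[:, 5, 5] = -cov + rng.normal(0, 1e-3, n)
        stack, ids = _stack_from_array(data)
        a = render_correlation_map(
            pixelwise_spearman(stack, CovariateVector(ids, cov)), alpha=0.05
        )
        b = render_correlation_map(
            pixelwise_spearman(stack, CovariateVector(ids, -cov)), alpha=0.05
        )
        np.testing.assert_array_equal(a[..., 0], b[..., 2])
        np.testing.assert_array_equal(a[..., 2], b[..., 0])
        np.testing.assert_array_equal(a[..., 1], b[..., 1])
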