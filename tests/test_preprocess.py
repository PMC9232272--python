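from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from octmoco import synth
from octmoco.datamodel import SurfaceTrace
from octmoco.errors import FormatError, NoSurfaceError
from octmoco.preprocess import (
    GradientImage,
    PreprocessConfig,
    adaptive_threshold,
    correlate2d_replicate,
    fit_surface,
    gaussian_kernel2d,
    gaussian_smooth,
    gradient_image,
    initial_surface,
    largest_component,
    preprocess_bscan,
    refine_surface,
    remove_saturation,
)

# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def conv_oracle(img, kernel):
    """Brute-force dense cross-correlation with replicate padding and
    anchor (floor((k-1)/2)) — written independently of the implementation."""
    kh, kw = kernel.shape
    ah, aw = (kh - 1) // 2, (kw - 1) // 2
    H, W = img.shape
    out = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            acc = 0.0
            for u in range(kh):
                for v in range(kw):
                    ii = min(max(i + u - ah, 0), H - 1)
                    jj = min(max(j + v - aw, 0), W - 1)
                    acc += img[ii, jj] * kernel[u, v]
            out[i, j] = acc
    return out


def label_oracle(mask):
    """Exhaustive 8-connected component labelling by BFS."""
    H, W = mask.shape
    labels = np.zeros((H, W), int)
    nxt = 0
    for i in range(H):
        for j in range(W):
            if mask[i, j] and labels[i, j] == 0:
                nxt += 1
                stack = [(i, j)]
                labels[i, j] = nxt
                while stack:
                    a, b = stack.pop()
                    for da in (-1, 0, 1):
                        for db in (-1, 0, 1):
                            x, y = a + da, b + db
                            if (0 <= x < H and 0 <= y < W and mask[x, y]
                                    and labels[x, y] == 0):
                                labels[x, y] = nxt
                                stack.append((x, y))
    return labels, nxt


# ---------------------------------------------------------------------------
# gaussian_smooth
# ---------------------------------------------------------------------------


class TestGaussianSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((30, 20), 7.25)
        np.testing.assert_allclose(gaussian_smooth(img), img, atol=1e-12)

    def test_impulse_matches_bruteforce_oracle(self, rng):
        img = np.zeros((16, 12))
        img[7, 5] = 1.0
        k = gaussian_kernel2d(10, 4.0)
        np.testing.assert_allclose(gaussian_smooth(img), conv_oracle(img, k),
                                   atol=1e-10)

    def test_random_image_matches_oracle(self, rng):
        img = rng.random((14, 17))
        k = gaussian_kernel2d(10, 4.0)
        np.testing.assert_allclose(gaussian_smooth(img), conv_oracle(img, k),
                                   atol=1e-10)

    @given(a=st.floats(-3, 3), b=st.floats(-3, 3), seed=st.integers(0, 2**16))
    @settings(max_examples=20, deadline=None)
    def test_linearity(self, a, b, seed):
        r = np.random.default_rng(seed)
        i1, i2 = r.random((12, 11)), r.random((12, 11))
        lhs = gaussian_smooth(a * i1 + b * i2)
        rhs = a * gaussian_smooth(i1) + b * gaussian_smooth(i2)
        np.testing.assert_allclose(lhs, rhs, atol=1e-9)

    def test_rejects_non_2d(self):
        with pytest.raises(FormatError):
            gaussian_smooth(np.zeros(5))


# ---------------------------------------------------------------------------
# remove_saturation
# ---------------------------------------------------------------------------


class TestRemoveSaturation:
    def test_constant_image_maps_to_zero(self):
        img = np.full((50, 9), 3.3)
        out = remove_saturation(img)
        np.testing.assert_allclose(out, 0.0, atol=1e-12)

    def test_matches_columnwise_moving_average_oracle(self, rng):
        img = rng.random((44, 8))
        expected = img - conv_oracle(img, np.full((40, 1), 1.0 / 40.0))
        np.testing.assert_allclose(remove_saturation(img), expected, atol=1e-10)

    def test_column_dc_removed(self, rng):
        img = rng.random((48, 10))
        img2 = img.copy()
        img2[:, 4] += 123.0  # depth-constant stripe
        out1, out2 = remove_saturation(img), remove_saturation(img2)
        np.testing.assert_allclose(out1[:, 4], out2[:, 4], atol=1e-10)
        np.testing.assert_allclose(out1, out2, atol=1e-10)

    def test_too_shallow_image_rejected(self):
        with pytest.raises(FormatError, match="shorter"):
            remove_saturation(np.zeros((39, 5)))


# ---------------------------------------------------------------------------
# adaptive_threshold
# ---------------------------------------------------------------------------


class TestAdaptiveThreshold:
    def test_two_level_band_selected(self, small_cfg):
        img = np.zeros((32, 40))
        img[10:13] = 10.0
        cfg = PreprocessConfig(threshold_window=8, border_crop=8)
        mask = adaptive_threshold(img, cfg)
        np.testing.assert_array_equal(mask, img > 0)

    def test_constant_image_all_background(self, small_cfg):
        mask = adaptive_threshold(np.full((40, 40), 5.0), small_cfg)
        assert not mask.any()

    def test_window_larger_than_image_rejected(self):
        with pytest.raises(FormatError):
            adaptive_threshold(np.zeros((16, 16)),
                               PreprocessConfig(threshold_window=64))

    def test_surface_band_is_largest_component(self, small_protocol,
                                               small_surface, small_cfg):
        # checked against simulator ground truth over several seeds
        from octmoco.preprocess import _axis_local_mean  # noqa: F401
        for seed in range(3):
            b = synth.render_bscan(small_surface, "fast", 24,
                                   small_protocol.n_fast, small_protocol.n_depth,
                                   seed=seed)
            sm = gaussian_smooth(b.pixels, small_cfg)
            sat = remove_saturation(sm, small_cfg)
            mask = adaptive_threshold(sat, small_cfg)
            comp = largest_component(mask, source=sat)
            truth = small_surface.z(np.arange(small_protocol.n_fast), 24.0)
            rows = comp.argmax(axis=0)  # top of component per column
            assert comp.any(axis=0).all()
            assert np.mean(np.abs(rows - truth) < 10) > 0.95


# ---------------------------------------------------------------------------
# largest_component
# ---------------------------------------------------------------------------


class TestLargestComponent:
    def test_single_component_identity(self):
        mask = np.zeros((10, 10), bool)
        mask[2:5, 3:7] = True
        np.testing.assert_array_equal(largest_component(mask), mask)

    def test_large_blob_wins_vs_oracle(self, rng):
        mask = np.zeros((32, 32), bool)
        mask[2:12, 2:12] = True     # 100 px
        mask[20:22, 20:25] = True   # 10 px
        got = largest_component(mask)
        labels, n = label_oracle(mask)
        sizes = [(labels == k).sum() for k in range(1, n + 1)]
        expected = labels == (int(np.argmax(sizes)) + 1)
        np.testing.assert_array_equal(got, expected)
        assert got.sum() == 100

    def test_random_masks_match_oracle(self, rng):
        for _ in range(5):
            mask = rng.random((24, 18)) > 0.7
            if not mask.any():
                continue
            got = largest_component(mask)
            labels, n = label_oracle(mask)
            sizes = [(labels == k).sum() for k in range(1, n + 1)]
            assert got.sum() == max(sizes)
            # the result must be exactly one oracle component
            ids = np.unique(labels[got])
            assert ids.size == 1 and ids[0] != 0

    def test_tie_broken_by_brightest_source(self):
        mask = np.zeros((10, 10), bool)
        mask[1:3, 1:3] = True
        mask[6:8, 6:8] = True
        src = np.zeros((10, 10))
        src[7, 7] = 5.0
        got = largest_component(mask, source=src)
        assert got[7, 7] and not got[1, 1]

    def test_empty_mask_raises(self):
        with pytest.raises(NoSurfaceError):
            largest_component(np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# initial_surface
# ---------------------------------------------------------------------------


class TestInitialSurface:
    def test_flat_band(self):
        comp = np.zeros((160, 30), bool)
        comp[100:104] = True
        trace = initial_surface(comp)
        np.testing.assert_array_equal(trace.depths, 100.0)
        assert trace.valid.all()

    def test_gap_interpolated_and_flagged(self):
        comp = np.zeros((50, 20), bool)
        comp[10, :5] = True
        comp[20, 10:] = True
        trace = initial_surface(comp)
        assert not trace.valid[5:10].any()
        np.testing.assert_allclose(trace.depths[5:10],
                                   np.interp(np.arange(5, 10), [4, 10], [10, 20]))

    def test_edge_columns_nearest_fill(self):
        comp = np.zeros((50, 10), bool)
        comp[30, 3:7] = True
        trace = initial_surface(comp)
        np.testing.assert_array_equal(trace.depths[:3], 30.0)
        np.testing.assert_array_equal(trace.depths[7:], 30.0)

    def test_empty_component_raises(self):
        with pytest.raises(NoSurfaceError):
            initial_surface(np.zeros((5, 5), bool))


# ---------------------------------------------------------------------------
# gradient_image
# ---------------------------------------------------------------------------


class TestGradientImage:
    def test_constant_image_zero(self):
        g = gradient_image(np.full((20, 20), 4.0))
        np.testing.assert_allclose(g.values, 0.0, atol=1e-18)

    def test_step_edge_matches_hand_convolution(self):
        # horizontal step edge (surface-like); hand-convolve the default
        # axial-derivative kernels on a 5x5 patch
        img = np.zeros((5, 5))
        img[3:, :] = 1.0
        sob = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], float)
        pre = np.array([[1, 1, 1], [0, 0, 0], [-1, -1, -1]], float)
        expected = conv_oracle(img, sob) ** 2 + conv_oracle(img, pre) ** 2
        np.testing.assert_allclose(gradient_image(img).values, expected,
                                   atol=1e-12)

    def test_printed_orientation_uses_transposed_kernels(self, rng):
        img = rng.random((9, 9))
        cfg = PreprocessConfig(gradient_kernels="printed")
        sob = np.array([[1, 2, 1], [0, 0, 0], [-1, -2, -1]], float).T
        pre = np.array([[1, 1, 1], [0, 0, 0], [-1, -1, -1]], float).T
        expected = conv_oracle(img, sob) ** 2 + conv_oracle(img, pre) ** 2
        np.testing.assert_allclose(gradient_image(img, cfg).values, expected,
                                   atol=1e-10)

    @given(seed=st.integers(0, 2**16))
    @settings(max_examples=15, deadline=None)
    def test_nonnegative(self, seed):
        img = np.random.default_rng(seed).normal(size=(12, 10))
        assert (gradient_image(img).values >= 0).all()

    def test_sqrt_option(self, rng):
        img = rng.random((10, 10))
        f = gradient_image(img).values
        fs = gradient_image(img, PreprocessConfig(gradient_sqrt=True)).values
        np.testing.assert_allclose(fs, np.sqrt(f), rtol=1e-12)


# ---------------------------------------------------------------------------
# refine_surface
# ---------------------------------------------------------------------------


def refine_oracle(depths, F, w):
    """Exhaustive per-column window scan with the documented tie rules."""
    out = np.empty_like(depths)
    n_rows = F.shape[0]
    for col, d in enumerate(depths):
        z0 = int(round(d))
        cands = range(max(0, z0 - w), min(n_rows, z0 + w + 1))
        best = max(cands, key=lambda r: (F[r, col], -abs(r - z0), -r))
        out[col] = best
    return out


class TestRefineSurface:
    def test_max_at_initial_keeps_trace(self, rng):
        F = rng.random((60, 15))
        depths = rng.integers(20, 40, 15).astype(float)
        for col, d in enumerate(depths):
            F[int(d), col] = 10.0
        trace = SurfaceTrace(depths, np.ones(15, bool))
        out = refine_surface(trace, GradientImage(F))
        np.testing.assert_array_equal(out.depths, depths)

    def test_uniform_offset_shift(self):
        F = np.zeros((80, 12))
        depths = np.full(12, 30.0)
        F[37, :] = 1.0  # unique max at +7
        out = refine_surface(SurfaceTrace(depths, np.ones(12, bool)),
                             GradientImage(F))
        np.testing.assert_array_equal(out.depths, 37.0)

    def test_matches_exhaustive_oracle(self, rng):
        F = rng.random((50, 20))
        depths = rng.uniform(5, 45, 20)
        trace = SurfaceTrace(depths, np.ones(20, bool))
        out = refine_surface(trace, GradientImage(F))
        np.testing.assert_array_equal(out.depths,
                                      refine_oracle(depths, F, 15))

    def test_window_clipped_at_border(self):
        F = np.zeros((40, 3))
        F[18, :] = 1.0  # inside [0, 18] window of initial depth 3
        out = refine_surface(SurfaceTrace(np.full(3, 3.0), np.ones(3, bool)),
                             GradientImage(F))
        np.testing.assert_array_equal(out.depths, 18.0)
        # nothing beyond row 18 can be selected
        F2 = np.zeros((40, 3))
        F2[19, :] = 1.0
        out2 = refine_surface(SurfaceTrace(np.full(3, 3.0), np.ones(3, bool)),
                              GradientImage(F2))
        assert (out2.depths <= 18).all()

    def test_shape_mismatch_rejected(self):
        with pytest.raises(FormatError):
            refine_surface(SurfaceTrace(np.zeros(5), np.ones(5, bool)),
                           GradientImage(np.zeros((10, 6))))


# ---------------------------------------------------------------------------
# fit_surface
# ---------------------------------------------------------------------------


def normal_equations_oracle(xs, zs, order):
    """Least-squares fit by exact rational normal equations (V^T V) P = V^T Z
    solved with Fraction Gaussian elimination."""
    m, n = len(xs), order + 1
    V = [[Fraction(xs[i]) ** (order - j) for j in range(n)] for i in range(m)]
    A = [[sum(V[k][i] * V[k][j] for k in range(m)) for j in range(n)]
         for i in range(n)]
    b = [sum(V[k][i] * Fraction(zs[k]) for k in range(m)) for i in range(n)]
    # gaussian elimination with partial pivot (exact)
    for col in range(n):
        piv = max(range(col, n), key=lambda r: abs(A[r][col]))
        A[col], A[piv] = A[piv], A[col]
        b[col], b[piv] = b[piv], b[col]
        for r in range(col + 1, n):
            f = A[r][col] / A[col][col]
            for c in range(col, n):
                A[r][c] -= f * A[col][c]
            b[r] -= f * b[col]
    sol = [Fraction(0)] * n
    for r in range(n - 1, -1, -1):
        s = b[r] - sum(A[r][c] * sol[c] for c in range(r + 1, n))
        sol[r] = s / A[r][r]
    # sol is highest-power-first; return ascending
    return [float(c) for c in reversed(sol)]


class TestFitSurface:
    def test_exact_quartic_recovered(self, rng):
        coeffs = rng.normal(size=5) * [100, 1, 0.01, 1e-4, 1e-6]
        x = np.arange(60.0)
        z = sum(c * x**k for k, c in enumerate(coeffs))
        fit = fit_surface(SurfaceTrace(z, np.ones(60, bool)), order=4)
        np.testing.assert_allclose(fit.coeffs, coeffs,
                                   rtol=1e-8, atol=1e-10)

    def test_constant_trace(self):
        fit = fit_surface(SurfaceTrace(np.full(20, 42.0), np.ones(20, bool)),
                          order=4)
        assert fit.coeffs[0] == pytest.approx(42.0, abs=1e-10)
        np.testing.assert_allclose(fit.coeffs[1:], 0.0, atol=1e-10)

    def test_matches_rational_normal_equations_oracle(self):
        # 12-point noisy instance with exact-rational reference solution
        xs = list(range(12))
        zs = [Fraction(num, 8) for num in
              [801, 795, 790, 788, 780, 779, 775, 772, 770, 765, 764, 760]]
        expected = normal_equations_oracle(xs, zs, order=4)
        trace = SurfaceTrace(np.array([float(z) for z in zs]),
                             np.ones(12, bool))
        fit = fit_surface(trace, order=4)
        np.testing.assert_allclose(fit.coeffs, expected, atol=1e-9)

    def test_only_valid_columns_used(self, rng):
        x = np.arange(40.0)
        z = 3.0 + 0.5 * x
        z_noisy = z.copy()
        z_noisy[::7] = 9999.0
        valid = np.ones(40, bool)
        valid[::7] = False
        fit = fit_surface(SurfaceTrace(z_noisy, valid), order=2)
        np.testing.assert_allclose(fit.coeffs[:2], [3.0, 0.5], atol=1e-8)

    def test_residual_monotone_in_order(self, rng):
        z = rng.normal(50, 5, 30)
        trace = SurfaceTrace(z, np.ones(30, bool))
        cols = np.arange(30)
        resid = []
        for order in range(2, 7):
            fit = fit_surface(trace, order=order)
            resid.append(np.sum((fit(cols) - z) ** 2))
        assert all(b <= a + 1e-9 for a, b in zip(resid, resid[1:]))

    def test_rank_deficient_rejected(self):
        trace = SurfaceTrace(np.array([1.0, 2.0, 3.0]),
                             np.array([True, True, True]))
        with pytest.raises(FormatError):
            fit_surface(trace, order=4)


# ---------------------------------------------------------------------------
# preprocess_bscan (composition)
# ---------------------------------------------------------------------------


class TestPreprocessBscan:
    def test_noise_free_fit_accuracy(self, small_protocol, small_surface,
                                     small_cfg):
        noise = synth.NoiseConfig(speckle=False)
        b = synth.render_bscan(small_surface, "fast", 24,
                               small_protocol.n_fast, small_protocol.n_depth,
                               noise=noise, seed=0)
        cols = np.arange(small_protocol.n_fast)
        truth = small_surface.z(cols, 24.0)
        trace, fit = preprocess_bscan(b, small_cfg)
        rms = np.sqrt(np.mean((fit(cols) - truth) ** 2))
        assert rms <= 0.5
        assert np.mean(np.abs(fit(cols) - truth) <= 1.0) >= 0.99
        # initial segmentation (pre-refinement) stays within the smoothing
        # spread of the truth; bound frozen from the simulator oracle
        sm = gaussian_smooth(b.pixels, small_cfg)
        comp = largest_component(adaptive_threshold(
            remove_saturation(sm, small_cfg), small_cfg))
        init = initial_surface(comp)
        assert np.max(np.abs(init.depths - truth)) <= 7.0

    def test_saturation_stripes_do_not_degrade_fit(self, small_protocol,
                                                   small_surface, small_cfg):
        cols = np.arange(small_protocol.n_fast)
        truth = small_surface.z(cols, 24.0)
        errs = {}
        for label, stripes in (("clean", 0), ("striped", 4)):
            rmss = []
            for seed in range(3):
                noise = synth.NoiseConfig(saturation_stripes=stripes)
                b = synth.render_bscan(small_surface, "fast", 24,
                                       small_protocol.n_fast,
                                       small_protocol.n_depth,
                                       noise=noise, seed=seed)
                _, fit = preprocess_bscan(b, small_cfg)
                rmss.append(np.sqrt(np.mean((fit(cols) - truth) ** 2)))
            errs[label] = np.mean(rmss)
        assert errs["striped"] <= 2.0 * errs["clean"] + 0.25

    def test_pure_noise_raises_no_surface(self, small_cfg, rng):
        img = rng.exponential(1.0, (160, 96))
        with pytest.raises(NoSurfaceError):
            preprocess_bscan(img, small_cfg)
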