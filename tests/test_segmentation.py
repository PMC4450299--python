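"""Split-Bregman convex segmentation: oracles, fixed points, invariances."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import ndimage

import lungfield as lf
from lungfield.edges import EdgeMap
from lungfield.model import dice_coefficient
from lungfield.segmentation import (
    RegionFits,
    SegmentationParams,
    SplitBregmanState,
    _alpha_field,
    _lbf_kernel,
    _sweep_python,
    bregman_update,
    data_speed,
    fill_holes,
    gauss_seidel_sweep,
    grad_forward,
    init_levelset,
    local_fits,
    region_means,
    segment,
    shrink,
)


def _ones_edge(shape):
    return EdgeMap(values=np.ones(shape, dtype=np.uint8), threshold_used=0.0)


def _zeros_edge(shape):
    return EdgeMap(values=np.zeros(shape, dtype=np.uint8), threshold_used=0.0)


class TestInitLevelset:
    def test_all_lung(self):
        with pytest.warns(UserWarning):  # degenerate: everything foreground
            phi = init_levelset(np.full((8, 8), -800.0), -500.0)
        assert (phi == 1).all()

    def test_all_tissue(self):
        with pytest.warns(UserWarning):  # degenerate: everything background
            phi = init_levelset(np.full((8, 8), 0.0), -500.0)
        assert (phi == 0).all()

    def test_phantom_air_spaces(self, clean_slice):
        img, truth = clean_slice
        phi = init_levelset(img, -500.0)
        inside = phi > 0.5
        # lung + trachea interiors are all foreground
        assert inside[truth.lung_without_nodules].all()
        assert inside[truth.trachea].all()


class TestRegionMeans:
    def test_binary_halves(self):
        img = np.where(np.arange(10)[None, :] < 5, 2.0, 8.0) * np.ones((10, 10))
        phi = (np.arange(10)[None, :] < 5).astype(float) * np.ones((10, 10))
        c1, c2 = region_means(img, phi)
        assert c1 == pytest.approx(2.0) and c2 == pytest.approx(8.0)

    def test_uniform_phi_gives_global_mean(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(12, 12))
        c1, c2 = region_means(img, np.full((12, 12), 0.5))
        assert c1 == pytest.approx(img.mean()) and c2 == pytest.approx(img.mean())

    def test_matches_weighted_sum_oracle(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(9, 9)) * 100
        phi = rng.random((9, 9))
        c1, c2 = region_means(img, phi)
        assert c1 == pytest.approx((phi * img).sum() / phi.sum(), abs=1e-10)
        assert c2 == pytest.approx(((1 - phi) * img).sum() / (1 - phi).sum(), abs=1e-10)

    def test_vanishing_weight_falls_back_to_global_mean(self):
        img = np.arange(16.0).reshape(4, 4)
        c1, c2 = region_means(img, np.zeros((4, 4)))
        assert c1 == pytest.approx(img.mean())


class TestLocalFits:
    def test_constant_image(self):
        img = np.full((10, 10), 4.0)
        phi = np.zeros((10, 10))
        phi[3:7, 3:7] = 1.0
        fits = local_fits(img, phi)
        assert np.allclose(fits.f1, 4.0) and np.allclose(fits.f2, 4.0)
        assert np.allclose(fits.e1, 0.0, atol=1e-9) and np.allclose(fits.e2, 0.0, atol=1e-9)

    def test_degenerate_membership_uses_global_mean(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(10, 10))
        fits = local_fits(img, np.ones((10, 10)))  # M2 == 0 everywhere
        assert np.allclose(fits.f2, img.mean())

    def test_energy_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        img = rng.normal(size=(16, 16)) * 10
        phi = rng.random((16, 16))
        omega = 1.0
        fits = local_fits(img, phi, omega)
        kernel = _lbf_kernel(omega)
        half = kernel.shape[0] // 2
        for f, e in ((fits.f1, fits.e1), (fits.f2, fits.e2)):
            fpad = np.pad(f, half, mode="edge")
            expected = np.zeros_like(img)
            for i in range(16):
                for j in range(16):
                    win = fpad[i:i + kernel.shape[0], j:j + kernel.shape[1]]
                    expected[i, j] = (kernel * (img[i, j] - win) ** 2).sum()
            assert np.max(np.abs(e - expected)) < 1e-8


class TestDataSpeed:
    def test_zero_when_fits_agree(self):
        img = np.full((6, 6), 3.0)
        z = np.zeros((6, 6))
        fits = RegionFits(c1=3.0, c2=3.0, f1=img, f2=img, e1=z, e2=z)
        s = data_speed(img, fits, _ones_edge((6, 6)), SegmentationParams())
        assert np.allclose(s, 0.0)

    def test_global_term_direct_value(self):
        # g* == 1 literally, I=0, c1=1, c2=3 -> F1 = 0.9 * (-1 + 9), s = -7.2
        img = np.zeros((4, 4))
        z = np.zeros((4, 4))
        fits = RegionFits(c1=1.0, c2=3.0, f1=z, f2=z, e1=z, e2=z)
        params = SegmentationParams(invert_edge_map=False)
        s = data_speed(img, fits, _ones_edge((4, 4)), params)
        assert np.allclose(s, -7.2)

    def test_sign_drives_phi_toward_matching_phase(self):
        """Inside a dark object tracked by c1, s < 0 (pushes phi up)."""
        img = np.where(np.arange(20)[None, :] < 10, -800.0, 0.0) * np.ones((20, 20))
        phi = (img < -500).astype(float)
        fits = local_fits(img, phi)
        s = data_speed(img, fits, _zeros_edge((20, 20)),
                       SegmentationParams(invert_edge_map=True))
        interior = (slice(5, 15), slice(2, 6))
        exterior = (slice(5, 15), slice(14, 18))
        assert (s[interior] < 0).all()
        assert (s[exterior] > 0).all()


class TestGaussSeidel:
    @pytest.mark.parametrize("value", [0.0, 0.5, 1.0])
    def test_constant_phi_fixed_point(self, value):
        phi = np.full((8, 8), value)
        state = SplitBregmanState.zeros((8, 8))
        out = gauss_seidel_sweep(phi, state, np.zeros((8, 8)), SegmentationParams())
        assert np.array_equal(out, phi)

    def test_clamping(self):
        params = SegmentationParams()
        state = SplitBregmanState.zeros((6, 6))
        big = np.full((6, 6), 1e9)
        assert (gauss_seidel_sweep(np.full((6, 6), 0.5), state, -big, params) == 1.0).all()
        assert (gauss_seidel_sweep(np.full((6, 6), 0.5), state, big, params) == 0.0).all()

    def test_nonfinite_speed_rejected(self):
        state = SplitBregmanState.zeros((4, 4))
        s = np.zeros((4, 4))
        s[1, 1] = np.nan
        with pytest.raises(ValueError):
            gauss_seidel_sweep(np.zeros((4, 4)), state, s, SegmentationParams())

    def test_python_and_compiled_sweeps_agree(self):
        rng = np.random.default_rng(4)
        phi = rng.random((12, 12))
        g = rng.normal(size=(12, 12)) * 0.1
        from lungfield.segmentation import _sweep_fast

        a = phi.copy()
        b = phi.copy()
        _sweep_python(a, g)
        _sweep_fast(b, g)
        assert np.array_equal(a, b)

    def test_converges_to_dense_solver_solution(self):
        """With d = b = 0 the subproblem is the graph-Laplacian (Poisson)
        system screened by the clamped pixels: pixels pinned at 0/1 by a
        strong speed act as Dirichlet anchors and the free pixels must match
        a dense linear solve of the anchored system to < 1e-6."""
        rng = np.random.default_rng(5)
        m = n = 8
        params = SegmentationParams()
        s = rng.normal(size=(m, n)) * 1e-5 * (params.lam / params.mu)
        anchors_one = [(0, 0), (3, 4), (7, 7)]
        anchors_zero = [(0, 7), (6, 1)]
        for ij in anchors_one:
            s[ij] = -10.0  # strongly negative speed -> phi clamps at 1
        for ij in anchors_zero:
            s[ij] = +10.0
        state = SplitBregmanState.zeros((m, n))
        phi = np.full((m, n), 0.5)
        for _ in range(2000):
            phi = gauss_seidel_sweep(phi, state, s, params)
        assert all(phi[ij] == 1.0 for ij in anchors_one)
        assert all(phi[ij] == 0.0 for ij in anchors_zero)

        # dense oracle: solve the free subsystem with the anchors as data
        anchored = {ij: 1.0 for ij in anchors_one}
        anchored.update({ij: 0.0 for ij in anchors_zero})
        free = [(i, j) for i in range(m) for j in range(n) if (i, j) not in anchored]
        pos = {ij: k for k, ij in enumerate(free)}
        A = np.zeros((len(free), len(free)))
        b = np.zeros(len(free))
        for i, j in free:
            k = pos[(i, j)]
            b[k] = -(params.mu / params.lam) * s[i, j]
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ii, jj = i + di, j + dj
                if not (0 <= ii < m and 0 <= jj < n):
                    continue
                A[k, k] += 1.0
                if (ii, jj) in anchored:
                    b[k] += anchored[(ii, jj)]
                else:
                    A[k, pos[(ii, jj)]] = -1.0
        dense = np.linalg.solve(A, b)
        assert (dense > 0).all() and (dense < 1).all()  # truly interior
        err = max(abs(phi[ij] - dense[pos[ij]]) for ij in free)
        assert err < 1e-6

    def test_monotone_descent_with_fixed_coefficients(self):
        """Each sweep is projected coordinate descent of the augmented
        quadratic (fixed s, d, b): the objective never increases."""
        rng = np.random.default_rng(6)
        params = SegmentationParams()

        def energy(phi, s, state):
            # forward differences over existing grid edges (replicate boundary)
            cx = (state.dx - state.bx)[:-1, :]
            cy = (state.dy - state.by)[:, :-1]
            dx = phi[1:, :] - phi[:-1, :]
            dy = phi[:, 1:] - phi[:, :-1]
            quad = ((dx - cx) ** 2).sum() + ((dy - cy) ** 2).sum()
            return params.mu * (phi * s).sum() + 0.5 * params.lam * quad

        for trial in range(10):
            phi = rng.random((12, 12))
            s = rng.normal(size=(12, 12)) * 1e-4
            state = SplitBregmanState(
                dx=rng.normal(size=(12, 12)) * 0.1,
                dy=rng.normal(size=(12, 12)) * 0.1,
                bx=rng.normal(size=(12, 12)) * 0.1,
                by=rng.normal(size=(12, 12)) * 0.1,
            )
            e_prev = energy(phi, s, state)
            for _ in range(5):
                phi = gauss_seidel_sweep(phi, state, s, params)
                e = energy(phi, s, state)
                assert e <= e_prev + 1e-9
                e_prev = e


class TestShrink:
    @pytest.mark.parametrize("z,theta,expected", [
        (0.0, 3.0, 0.0), (5.0, 2.0, 3.0), (-5.0, 2.0, -3.0), (1.0, 2.0, 0.0),
    ])
    def test_scalar_cases(self, z, theta, expected):
        assert shrink(np.array(z), theta) == pytest.approx(expected)

    def test_is_proximal_map_of_l1(self):
        rng = np.random.default_rng(7)
        grid = np.linspace(-15, 15, 30001)
        for _ in range(100):
            z = rng.uniform(-10, 10)
            theta = rng.uniform(0, 5)
            obj = 0.5 * (grid - z) ** 2 + theta * np.abs(grid)
            best = grid[np.argmin(obj)]
            assert abs(float(shrink(np.array(z), theta)) - best) < 1e-3

    @given(st.floats(-100, 100), st.floats(-100, 100), st.floats(0, 50))
    def test_lipschitz_and_odd(self, a, b, theta):
        sa = float(shrink(np.array(a), theta))
        sb = float(shrink(np.array(b), theta))
        assert abs(sa - sb) <= abs(a - b) + 1e-12
        assert float(shrink(np.array(-a), theta)) == pytest.approx(-sa)

    def test_vector_shrink_threshold_on_magnitude(self):
        z = np.array([[3.0], [4.0]])  # magnitude 5
        out = shrink(z, 2.5, axis=0)
        assert np.allclose(out, z * 0.5)


class TestBregmanUpdate:
    def test_zero_threshold_copies_gradient_and_zeroes_b(self):
        rng = np.random.default_rng(8)
        phi = rng.random((10, 10))
        state = SplitBregmanState(
            dx=np.zeros((10, 10)), dy=np.zeros((10, 10)),
            bx=rng.normal(size=(10, 10)), by=rng.normal(size=(10, 10)),
        )
        # g = 0 everywhere -> shrink is the identity -> b_new = 0
        new = bregman_update(phi, state, _zeros_edge((10, 10)), lam=1e3,
                             invert_edge_map=False)
        gx, gy = grad_forward(phi)
        assert np.allclose(new.dx, state.bx + gx)
        assert np.allclose(new.bx, 0.0) and np.allclose(new.by, 0.0)

    def test_all_zero_fields_stay_zero(self):
        state = SplitBregmanState.zeros((6, 6))
        new = bregman_update(np.full((6, 6), 0.3), state, _ones_edge((6, 6)), 1e3,
                             invert_edge_map=False)
        assert not new.dx.any() and not new.bx.any()

    def test_matches_per_pixel_loop_oracle(self):
        rng = np.random.default_rng(9)
        phi = rng.random((8, 8))
        g = rng.integers(0, 2, size=(8, 8)).astype(np.uint8)
        lam = 10.0
        state = SplitBregmanState(
            dx=rng.normal(size=(8, 8)), dy=rng.normal(size=(8, 8)),
            bx=rng.normal(size=(8, 8)), by=rng.normal(size=(8, 8)),
        )
        new = bregman_update(phi, state, EdgeMap(g, 0.0), lam, invert_edge_map=False)
        gx, gy = grad_forward(phi)
        for i in range(8):
            for j in range(8):
                zx = state.bx[i, j] + gx[i, j]
                zy = state.by[i, j] + gy[i, j]
                mag = np.hypot(zx, zy)
                theta = g[i, j] / lam
                scale = max(mag - theta, 0.0) / mag if mag > 0 else 0.0
                assert abs(new.dx[i, j] - zx * scale) < 1e-12
                assert abs(new.by[i, j] - (zy - zy * scale)) < 1e-12


class TestSegment:
    def test_two_phase_noisy_disk(self, two_phase_image):
        img, truth = two_phase_image
        res = segment(img)
        assert dice_coefficient(res.mask, truth) >= 0.98
        assert res.c1 < res.c2  # radiolucent phase reported first

    def test_initial_contour_invariance(self, two_phase_image):
        img, truth = two_phase_image
        init1 = np.zeros(img.shape)
        init1[20:60, 20:60] = 1.0
        init2 = np.zeros(img.shape)
        init2[70:120, 40:110] = 1.0
        m1 = segment(img, init=init1).mask
        m2 = segment(img, init=init2).mask
        assert dice_coefficient(m1, m2) >= 0.99

    def test_phi_stays_in_unit_interval_through_run(self, two_phase_image):
        """Replicates the outer loop, asserting 0 <= phi <= 1 after every sweep."""
        img, _ = two_phase_image
        params = SegmentationParams(max_outer_iters=30)
        from lungfield.edges import edge_indicator

        gstar = edge_indicator(img)
        phi = init_levelset(img, params.hu_init_threshold)
        state = SplitBregmanState.zeros(img.shape)
        for _ in range(params.max_outer_iters):
            fits = local_fits(img, phi, params.omega)
            s = data_speed(img, fits, gstar, params)
            phi = gauss_seidel_sweep(phi, state, s, params)
            assert phi.min() >= 0.0 and phi.max() <= 1.0
            state = bregman_update(phi, state, gstar, params.lam,
                                   params.invert_edge_map)

    def test_invariant_under_hu_offset(self, two_phase_image):
        img, _ = two_phase_image
        offset = 250.0
        a = segment(img, SegmentationParams(max_outer_iters=40))
        b = segment(img + offset,
                    SegmentationParams(max_outer_iters=40,
                                       hu_init_threshold=-500.0 + offset))
        assert np.array_equal(a.mask, b.mask)

    def test_local_term_handles_boundary_inhomogeneity(self):
        """A smeared step with a perpendicular intensity ramp: the combined
        model stays within 2 px of the true boundary where a purely global
        fit (beta'->0, weight 1 everywhere) errs by more."""
        rows, cols = np.mgrid[0:64, 0:64]
        rng = np.random.default_rng(5)
        step = ndimage.gaussian_filter(np.where(cols < 32, 0.0, 60.0), 3.0)
        img = step + 0.8 * (rows - 32) + rng.normal(0, 1.0, (64, 64))
        init = (cols >= 30).astype(float)

        def max_boundary_err(mask):
            errs = []
            for r in range(64):
                cs = np.flatnonzero(mask[r])
                errs.append(abs(cs[0] - 32) if len(cs) else 32)
            return max(errs)

        full = segment(img, init=init)
        err_full = max_boundary_err(~full.mask)  # bright phase
        pg = SegmentationParams(alpha_prime=0.9, beta_prime=1e-12,
                                invert_edge_map=False)
        glob = segment(img, params=pg, init=init,
                       gstar=_ones_edge((64, 64)))
        err_glob = max_boundary_err(~glob.mask)
        assert err_full <= 2
        assert err_glob > 2

    def test_nonconvergence_warns(self, two_phase_image):
        img, _ = two_phase_image
        with pytest.warns(UserWarning):
            # an unreachable tolerance forces the iteration cap
            res = segment(img, SegmentationParams(max_outer_iters=2, tol=-1.0))
        assert not res.converged


class TestFillHoles:
    def test_solid_disk_unchanged(self):
        from skimage.draw import disk

        m = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 10)
        m[rr, cc] = True
        assert np.array_equal(fill_holes(m), m)

    def test_annulus_becomes_disk(self):
        from skimage.draw import disk

        m = np.zeros((40, 40), bool)
        rr, cc = disk((20, 20), 12)
        m[rr, cc] = True
        solid = m.copy()
        rr, cc = disk((20, 20), 6)
        m[rr, cc] = False
        assert np.array_equal(fill_holes(m), solid)

    def test_punched_hole_in_phantom_lung(self, phantom_slice):
        _, truth = phantom_slice
        m = truth.lung_without_nodules.copy()
        m[120:123, 70:73] = False  # 3-px hole in the left lung interior
        filled = fill_holes(m)
        assert np.array_equal(filled, truth.lung_without_nodules)
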