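import itertools

import numpy as np
import pytest
from scipy.optimize import linprog

from shapecut import features as ft
from shapecut.volume_io import Volume


# ---------------------------------------------------------------------------
# feature stack
# ---------------------------------------------------------------------------

class TestFeatureStack:
    def test_constant_volume(self):
        fs = ft.feature_stack(Volume(np.full((6, 6, 6), 7.0)), sigma_blur=1.0)
        assert np.all(fs.x[..., 0] == 7.0)
        assert np.allclose(fs.x[..., 1], 7.0, atol=1e-12)

    def test_impulse_matches_convolution_oracle(self):
        # oracle: dense separable convolution with the sampled Gaussian kernel
        data = np.zeros((9, 9, 9))
        data[4, 4, 4] = 1.0
        fs = ft.feature_stack(Volume(data), sigma_blur=1.0)

        radius = int(4.0 * 1.0 + 0.5)
        x = np.arange(-radius, radius + 1, dtype=float)
        k = np.exp(-0.5 * x**2)
        k /= k.sum()
        oracle = np.zeros((9, 9, 9))
        for i, j, l in itertools.product(range(9), repeat=3):
            di, dj, dl = i - 4, j - 4, l - 4
            if max(abs(di), abs(dj), abs(dl)) <= radius:
                oracle[i, j, l] = k[di + radius] * k[dj + radius] * k[dl + radius]
        assert np.allclose(fs.x[..., 1], oracle, atol=1e-12)

    def test_impulse_mass_preserved(self):
        data = np.zeros((11, 11, 11))
        data[5, 5, 5] = 1.0
        fs = ft.feature_stack(Volume(data), sigma_blur=1.0)
        assert fs.x[..., 1].sum() == pytest.approx(1.0, abs=1e-6)

    def test_bad_sigma(self):
        with pytest.raises(ValueError):
            ft.feature_stack(Volume(np.zeros((3, 3, 3))), sigma_blur=0.0)


# ---------------------------------------------------------------------------
# Gaussian model and data term
# ---------------------------------------------------------------------------

class TestGaussianModel:
    def test_constant_region_floored_identity(self):
        x = np.full((10, 2), 5.0)
        m = ft.fit_gaussian(x)
        assert m.mu == pytest.approx([5.0, 5.0])
        assert np.allclose(m.sigma, ft.COV_ABS_FLOOR * np.eye(2))
        assert m.regularized

    def test_hand_computed_covariance(self):
        # channel-0 values {0, 0, 2, 2}: unbiased variance = 4/3
        x = np.array([[0.0, 0.0], [0.0, 0.0], [2.0, 0.0], [2.0, 0.0]])
        m = ft.fit_gaussian(x)
        assert m.mu == pytest.approx([1.0, 0.0])
        assert m.sigma[0, 0] == pytest.approx(4.0 / 3.0, rel=1e-5)

    def test_permutation_invariance(self, rng):
        x = rng.random((20, 2))
        m1 = ft.fit_gaussian(x)
        m2 = ft.fit_gaussian(x[rng.permutation(20)])
        assert np.allclose(m1.mu, m2.mu)
        assert np.allclose(m1.sigma, m2.sigma)

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            ft.fit_gaussian(np.zeros((2, 2)))

    def test_from_feature_stack_region(self, rng):
        fs = ft.feature_stack(Volume(rng.random((6, 6, 6))), 1.0)
        region = np.zeros((6, 6, 6), dtype=bool)
        region[1:4, 1:4, 1:4] = True
        m = ft.fit_gaussian(fs, region)
        assert np.allclose(m.mu, fs.x[region].mean(axis=0))


class TestDataTerm:
    def test_at_mean_1d(self):
        m = ft.GaussianModel(mu=np.array([0.0]), sigma=np.array([[1.0]]))
        assert ft.data_term([0.0], m) == pytest.approx(0.5 * np.log(2 * np.pi), abs=1e-12)

    def test_two_sigma_1d(self):
        m = ft.GaussianModel(mu=np.array([0.0]), sigma=np.array([[1.0]]))
        assert ft.data_term([2.0], m) == pytest.approx(0.5 * np.log(2 * np.pi) + 2.0, abs=1e-12)

    def test_identity_2d_closed_form(self, rng):
        m = ft.GaussianModel(mu=np.array([1.0, -1.0]), sigma=np.eye(2))
        for _ in range(10):
            x = rng.normal(size=2)
            expect = np.log(2 * np.pi) + 0.5 * ((x - m.mu) ** 2).sum()
            assert ft.data_term(x, m) == pytest.approx(expect, abs=1e-12)

    def test_mahalanobis_identity(self, rng):
        # data_term(x) - data_term(mu) == 0.5 * Mahalanobis^2(x)
        a = rng.random((3, 3))
        m = ft.GaussianModel(mu=rng.random(3), sigma=a @ a.T + np.eye(3))
        for _ in range(20):
            x = rng.normal(size=3) * 3
            diff = x - m.mu
            maha2 = diff @ np.linalg.solve(m.sigma, diff)
            gap = ft.data_term(x, m) - ft.data_term(m.mu, m)
            assert gap == pytest.approx(0.5 * maha2, rel=1e-9, abs=1e-12)


# ---------------------------------------------------------------------------
# local binary patterns
# ---------------------------------------------------------------------------

def oracle_vlbp(data, c, P, R, L, plane):
    """Independent scalar evaluation: threshold each interpolated neighbor."""
    from shapecut.features import _plane_offsets, _sample_trilinear

    offs = _plane_offsets(P, R, L, plane)
    gc = data[tuple(c)]
    code = 0
    for k in range(P):
        point = np.asarray(c, float) + offs[k]
        gp = _sample_trilinear(data, point)
        code += (1 << k) if gp - gc >= 0 else 0
    return code


class TestVlbpCode:
    def test_constant_volume_all_ones(self):
        v = Volume(np.full((7, 7, 7), 3.3))
        assert ft.vlbp_code(v, (3, 3, 3), P=8) == 255

    def test_strict_maximum_gives_zero(self):
        data = np.zeros((5, 5, 5))
        data[2, 2, 2] = 10.0
        assert ft.vlbp_code(Volume(data), (2, 2, 2), P=8) == 0

    def test_random_centers_match_bitwise_oracle(self, rng):
        data = rng.random((5, 5, 5))
        for _ in range(20):
            c = tuple(rng.integers(1, 4, 3))
            for plane in ("xy", "xz", "yz"):
                got = ft.vlbp_code(data, c, L=2, P=8, R=1.0, plane=plane)
                assert got == oracle_vlbp(data, c, 8, 1.0, 2, plane)

    def test_gray_shift_and_scale_invariance(self, rng):
        data = rng.random((6, 6, 6))
        c = (3, 3, 3)
        base = ft.vlbp_code(data, c)
        assert ft.vlbp_code(data + 11.0, c) == base
        assert ft.vlbp_code(data * 4.0, c) == base

    def test_plane_codes_match_scalar(self, rng):
        data = rng.random((6, 6, 6))
        codes = ft.lbp_plane_codes(data, P=8, R=1.0, L=2)
        for pi, plane in enumerate(ft.PLANE_ORDER):
            for _ in range(10):
                c = tuple(rng.integers(0, 6, 3))
                assert codes[pi][c] == ft.vlbp_code(data, c, L=2, P=8, R=1.0, plane=plane)


class TestLbpTopHistograms:
    def test_constant_volume_point_mass(self):
        v = np.full((9, 9, 9), 2.0)
        seeds = np.zeros((9, 9, 9), dtype=bool)
        seeds[4, 4, 4] = True
        hists = ft.lbp_top_histograms(v, (3, 3, 3), P=8, R=1.0, seed_region=seeds)
        # every histogram: point mass at code 255 -> cumulative 0...0 then 1
        expect = np.zeros(256)
        expect[255] = 1.0
        expect = np.cumsum(expect)
        assert np.allclose(hists.H, expect[None, None, :], atol=1e-6)
        for p in [(0, 0, 0), (4, 4, 4), (8, 8, 8)]:
            assert ft.appearance_term(hists, p) == pytest.approx(0.0, abs=1e-4)

    def test_two_texture_volume(self, rng):
        # constant left half, salt-pepper right half; seeds deep left
        data = np.zeros((16, 12, 12))
        data[8:] = rng.choice([-1.0, 1.0], size=(8, 12, 12))
        seeds = np.zeros((16, 12, 12), dtype=bool)
        seeds[1:3, 4:8, 4:8] = True
        hists = ft.lbp_top_histograms(data, (5, 5, 3), P=8, R=1.0, seed_region=seeds)
        deep_left = ft.appearance_term(hists, (2, 6, 6))
        deep_right = ft.appearance_term(hists, (13, 6, 6))
        assert deep_left == pytest.approx(0.0, abs=1e-6)
        assert deep_right > 1.0

    def test_degenerate_window_is_point_mass(self, rng):
        data = rng.random((7, 7, 7))
        seeds = np.ones((7, 7, 7), dtype=bool)
        hists = ft.lbp_top_histograms(data, (1, 1, 1), P=8, R=1.0, seed_region=seeds)
        codes = ft.lbp_plane_codes(data, P=8, R=1.0, L=2)
        for _ in range(10):
            c = tuple(np.random.default_rng(4).integers(0, 7, 3))
            r = hists.row(c)
            for pi in range(3):
                expect = np.zeros(256)
                expect[codes[pi][c]] = 1.0
                assert np.allclose(hists.H[r, pi], np.cumsum(expect), atol=1e-6)

    def test_window_too_large_errors(self):
        with pytest.raises(ValueError):
            ft.lbp_top_histograms(np.zeros((4, 4, 4)), (9, 9, 9), 8, 1.0,
                                  np.ones((4, 4, 4), dtype=bool))


# ---------------------------------------------------------------------------
# Wasserstein / appearance
# ---------------------------------------------------------------------------

def lp_transport_1d(pa, pb):
    """LP oracle for 1D optimal transport with |i-j| ground cost."""
    n = len(pa)
    cost = np.abs(np.subtract.outer(np.arange(n), np.arange(n))).ravel().astype(float)
    a_eq = np.zeros((2 * n, n * n))
    for i in range(n):
        a_eq[i, i * n:(i + 1) * n] = 1
        a_eq[n + i, i::n] = 1
    res = linprog(cost, A_eq=a_eq[:-1], b_eq=np.concatenate([pa, pb])[:-1],
                  bounds=(0, None), method="highs")
    assert res.status == 0
    return res.fun


class TestWassersteinL1:
    def test_identity(self, rng):
        h = np.cumsum(rng.random(8))
        h /= h[-1]
        assert ft.wasserstein_l1(h, h) == 0.0

    def test_point_mass_translation(self):
        a = np.zeros(8); a[0] = 1.0
        b = np.zeros(8); b[3] = 1.0
        assert ft.wasserstein_l1(np.cumsum(a), np.cumsum(b)) == pytest.approx(3.0)

    def test_matches_lp_oracle(self, rng):
        for _ in range(50):
            pa = rng.random(8); pa /= pa.sum()
            pb = rng.random(8); pb /= pb.sum()
            got = ft.wasserstein_l1(np.cumsum(pa), np.cumsum(pb))
            assert got == pytest.approx(lp_transport_1d(pa, pb), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ft.wasserstein_l1(np.ones(4), np.ones(5))

    def test_metric_properties(self, rng):
        hs = []
        for _ in range(6):
            p = rng.random(16); p /= p.sum()
            hs.append(np.cumsum(p))
        for a, b, c in itertools.combinations(range(6), 3):
            dab = ft.wasserstein_l1(hs[a], hs[b])
            dbc = ft.wasserstein_l1(hs[b], hs[c])
            dac = ft.wasserstein_l1(hs[a], hs[c])
            assert dab >= 0
            assert dab == pytest.approx(ft.wasserstein_l1(hs[b], hs[a]))
            assert dac <= dab + dbc + 1e-12


class TestAppearanceTerm:
    def test_direct_evaluation(self):
        # per-plane WD (0.2, 0.4, 0.0), sigma0^2 (0.1, 0.2, 0.1) -> 2 + 2 + 0
        nbins = 4
        H0 = np.tile(np.cumsum([0.25, 0.25, 0.25, 0.25]), (3, 1))
        H = np.empty((1, 3, nbins), dtype=np.float32)
        for pi, wd in enumerate([0.2, 0.4, 0.0]):
            h = H0[pi].copy()
            h[0] += wd  # shifts cumulative by wd in one entry
            H[0, pi] = h
        hists = ft.LBPHistograms(coords=np.array([[0, 0, 0]]), H=H, H0=H0,
                                 sigma0_sq=np.array([0.1, 0.2, 0.1]), nbins=nbins)
        assert ft.appearance_term(hists, (0, 0, 0)) == pytest.approx(4.0, rel=1e-6)
        assert ft.appearance_values(hists)[0] == pytest.approx(4.0, rel=1e-6)

    def test_scaling_sigma0(self):
        nbins = 4
        H0 = np.tile(np.cumsum([0.25, 0.25, 0.25, 0.25]), (3, 1))
        H = np.empty((1, 3, nbins), dtype=np.float32)
        for pi in range(3):
            h = H0[pi].copy(); h[1] += 0.3
            H[0, pi] = h
        s0 = np.array([0.1, 0.2, 0.3])
        h1 = ft.LBPHistograms(np.array([[0, 0, 0]]), H, H0, s0, nbins)
        h2 = ft.LBPHistograms(np.array([[0, 0, 0]]), H, H0, 2 * s0, nbins)
        assert ft.appearance_term(h1, (0, 0, 0)) == pytest.approx(
            2 * ft.appearance_term(h2, (0, 0, 0)), rel=1e-6)


# ---------------------------------------------------------------------------
# spin descriptor
# ---------------------------------------------------------------------------

def oracle_spin(data, p, r, bins, sigma_d, sigma_i):
    """Brute-force voxel-by-voxel accumulation of the descriptor kernel."""
    nb_d, nb_i = bins
    vals, ds = [], []
    for off in itertools.product(range(-r, r + 1), repeat=3):
        d = np.sqrt(sum(o * o for o in off))
        if d > r:
            continue
        q = tuple(np.clip(np.asarray(p) + off, 0, np.asarray(data.shape) - 1))
        vals.append(data[q])
        ds.append(d)
    vals = np.asarray(vals)
    lo, hi = vals.min(), vals.max()
    desc = np.zeros(bins)
    for val, d in zip(vals, ds):
        u_d = d / r * nb_d
        for bd in range(nb_d):
            wd = np.exp(-((u_d - (bd + 0.5)) ** 2) / (2 * sigma_d**2))
            if hi == lo:
                desc[bd, 0] += wd
                continue
            u_i = (val - lo) / (hi - lo) * nb_i
            for bi in range(nb_i):
                wi = np.exp(-((u_i - (bi + 0.5)) ** 2) / (2 * sigma_i**2))
                desc[bd, bi] += wd * wi
    return desc / desc.sum()


class TestSpinDescriptor:
    def test_constant_patch_intensity_column_zero(self):
        v = np.full((11, 11, 11), 4.0)
        desc = ft.spin_descriptor(v, (5, 5, 5), r=4)
        assert desc.sum() == pytest.approx(1.0)
        assert np.all(desc[:, 1:] == 0.0)
        assert np.all(desc[:, 0] > 0.0)

    def test_rotation_invariance(self, rng):
        data = rng.random((9, 9, 9))
        center = (4, 4, 4)
        ref = ft.spin_descriptor(data, center, r=3)
        for k in range(1, 4):
            for axes in [(0, 1), (0, 2), (1, 2)]:
                rot = np.rot90(data, k=k, axes=axes)
                got = ft.spin_descriptor(rot, center, r=3)
                assert np.allclose(got, ref, atol=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        data = rng.random((9, 9, 9)) * 50
        for _ in range(5):
            p = tuple(rng.integers(2, 7, 3))
            got = ft.spin_descriptor(data, p, r=4, sigma_d=0.5, sigma_i=0.5)
            expect = oracle_spin(data, p, 4, (4, 4), 0.5, 0.5)
            assert np.allclose(got, expect, atol=1e-12)

    def test_unit_mass(self, rng):
        data = rng.random((9, 9, 9))
        descs = ft.spin_descriptors(data, rng.integers(0, 9, (20, 3)), r=4)
        assert np.allclose(descs.sum(axis=(1, 2)), 1.0, atol=1e-12)
        assert descs.min() >= 0.0


# ---------------------------------------------------------------------------
# EMD
# ---------------------------------------------------------------------------

def lp_emd_2d(ha, hb):
    """LP transport oracle with L1 ground distance on the bin grid."""
    nr, nc = ha.shape
    n = nr * nc
    idx = np.arange(n)
    r, c = idx // nc, idx % nc
    cost = (np.abs(r[:, None] - r[None, :]) + np.abs(c[:, None] - c[None, :])).ravel().astype(float)
    a_eq = np.zeros((2 * n, n * n))
    for i in range(n):
        a_eq[i, i * n:(i + 1) * n] = 1
        a_eq[n + i, i::n] = 1
    res = linprog(cost, A_eq=a_eq[:-1],
                  b_eq=np.concatenate([ha.ravel(), hb.ravel()])[:-1],
                  bounds=(0, None), method="highs")
    assert res.status == 0
    return res.fun


class TestEmd:
    def test_identity(self, rng):
        h = rng.random((4, 4)); h /= h.sum()
        assert ft.emd_weight(h, h) == pytest.approx(0.0, abs=1e-12)

    def test_corner_to_corner(self):
        a = np.zeros((4, 4)); a[0, 0] = 1.0
        b = np.zeros((4, 4)); b[3, 3] = 1.0
        assert ft.emd(a, b) == pytest.approx(6.0, abs=1e-12)
        assert ft.emd_weight(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_matches_lp_oracle(self, rng):
        for trial in range(50):
            ha = rng.random((4, 4))
            hb = rng.random((4, 4))
            if trial % 3 == 0:  # include sparse descriptors
                ha *= rng.random((4, 4)) < 0.4
                if ha.sum() == 0:
                    ha[0, 0] = 1.0
            ha /= ha.sum()
            hb /= hb.sum()
            assert ft.emd(ha, hb) == pytest.approx(lp_emd_2d(ha, hb), abs=1e-9)

    def test_symmetry_and_triangle(self, rng):
        hs = []
        for _ in range(5):
            h = rng.random((4, 4)); h /= h.sum()
            hs.append(h)
        for a, b, c in itertools.combinations(range(5), 3):
            dab = ft.emd(hs[a], hs[b])
            assert dab == pytest.approx(ft.emd(hs[b], hs[a]), abs=1e-12)
            assert ft.emd(hs[a], hs[c]) <= dab + ft.emd(hs[b], hs[c]) + 1e-9

    def test_unnormalized_rejected(self):
        with pytest.raises(ValueError, match="normalized"):
            ft.emd(np.ones((4, 4)), np.ones((4, 4)) / 16.0)

    def test_range(self, rng):
        for _ in range(20):
            ha = rng.random((4, 4)); ha /= ha.sum()
            hb = rng.random((4, 4)); hb /= hb.sum()
            w = ft.emd_weight(ha, hb)
            assert 0.0 <= w <= 1.0
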