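import numpy as np
import pytest
from scipy.spatial import cKDTree

from scalepat.imaging import (
    NormalField,
    decode_normal_map,
    detect_scales,
    encode_normal_map,
    extract_scale_colors,
    match_pair,
    mean_curvature,
    read_normal_map,
    similarity_transform,
    unify_network,
    write_normal_map,
)
from scalepat.lattice import build_hex_lattice
from scalepat.synth import BumpGridSpec, gen_matched_pair, gen_normal_map


def hemisphere_normals(R=50.0, half=30):
    x = np.arange(-half, half + 1.0)
    X, Y = np.meshgrid(x, x)
    Z = np.sqrt(R * R - X**2 - Y**2)
    return np.stack([X / R, Y / R, Z / R], axis=-1), X, Y


class TestDecode:
    def test_midpoint_triplet_maps_to_up_normal(self):
        img = np.zeros((2, 2, 3), np.uint16)
        img[..., 0] = img[..., 1] = 32768
        img[..., 2] = 65535
        nf = decode_normal_map(img)
        assert np.allclose(nf.normals[..., 2], 1.0, atol=1e-4)

    def test_endpoint_mapping_before_renormalization(self):
        img = np.zeros((1, 1, 3), np.uint16)
        img[..., 2] = 65535
        raw = 2.0 * img.astype(float) / 65535.0 - 1.0
        assert np.allclose(raw[0, 0], [-1.0, -1.0, 1.0])

    def test_round_trip_and_file_io(self, tmp_path, rng):
        n = rng.normal(size=(8, 8, 3))
        n[..., 2] = np.abs(n[..., 2]) + 0.5
        n /= np.linalg.norm(n, axis=-1, keepdims=True)
        enc = encode_normal_map(n)
        path = tmp_path / "nm.tif"
        write_normal_map(str(path), enc)
        nf = read_normal_map(str(path))
        assert np.abs(nf.normals - n).max() < 2.0 / 65535.0

    def test_wrong_bit_depth_rejected(self):
        with pytest.raises(ValueError):
            decode_normal_map(np.zeros((4, 4, 3), np.uint8))


class TestMeanCurvature:
    def test_constant_normal_gives_zero(self):
        n = np.zeros((12, 12, 3))
        n[..., 2] = 1.0
        H = mean_curvature(NormalField(n))
        assert np.nanmax(np.abs(H)) == 0.0

    def test_hemisphere_curvature_within_two_percent(self):
        n, X, Y = hemisphere_normals()
        H = mean_curvature(NormalField(n, pitch=1.0))
        inside = (X**2 + Y**2) < (0.8 * 50.0) ** 2
        vals = np.abs(H[inside & np.isfinite(H)])
        assert abs(vals.mean() - 1.0 / 50.0) < 0.02 / 50.0
        assert np.abs(vals - 1.0 / 50.0).max() < 0.02 / 50.0 * 5

    def test_quadratic_height_field_curvature_converges(self):
        a, b = 0.003, 0.001

        def H_at_origin(pitch):
            half = 10
            x = np.arange(-half, half + 1.0) * pitch
            X, Y = np.meshgrid(x, x)
            zx, zy = 2 * a * X, 2 * b * Y
            n = np.stack([-zx, -zy, np.ones_like(X)], -1)
            n /= np.linalg.norm(n, axis=-1, keepdims=True)
            H = mean_curvature(NormalField(n, pitch=pitch))
            return H[half, half]

        # H -> -(a + b) as pitch -> 0 (sign set by the outward-normal convention)
        errs = [abs(abs(H_at_origin(p)) - (a + b)) for p in (1.0, 0.5, 0.25)]
        assert errs[0] >= errs[1] >= errs[2]
        assert errs[2] < 1e-6


@pytest.fixture(scope="module")
def bump_image():
    spec = BumpGridSpec(nx=8, ny=8, S=1.0, sigma=0.28, p=1.0, height=0.3,
                        arrangement="square")
    enc, normals, Z, pitch = gen_normal_map(spec, resolution=30)
    return enc, pitch


class TestDetectScales:
    def test_recovers_all_64_bump_centers(self, bump_image):
        enc, pitch = bump_image
        H = mean_curvature(decode_normal_map(enc, pitch))
        centers, lattice, labels = detect_scales(H, s=20)
        true_px = np.array(
            [[(i + 0.5) / pitch - 0.5, (j + 0.5) / pitch - 0.5]
             for j in range(8) for i in range(8)]
        )
        assert len(centers) == 64
        d, idx = cKDTree(true_px).query(centers)
        assert len(set(idx)) == 64
        assert d.max() < 2.0  # s / 10

    def test_rerun_is_deterministic(self, bump_image):
        enc, pitch = bump_image
        H = mean_curvature(decode_normal_map(enc, pitch))
        c1, _, _ = detect_scales(H, s=20)
        c2, _, _ = detect_scales(H, s=20)
        assert np.array_equal(c1, c2)

    def test_single_bump(self):
        spec = BumpGridSpec(nx=1, ny=1, arrangement="square")
        enc, _, _, pitch = gen_normal_map(spec, resolution=30)
        H = mean_curvature(decode_normal_map(enc, pitch))
        centers, lattice, _ = detect_scales(H, s=20)
        assert len(centers) == 1
        assert lattice is None

    def test_count_invariant_under_monotone_rescaling(self, bump_image):
        enc, pitch = bump_image
        H = mean_curvature(decode_normal_map(enc, pitch))
        c1, _, _ = detect_scales(H, s=20)
        c2, _, _ = detect_scales(2.5 * H + 7.0, s=20)
        assert len(c1) == len(c2)

    def test_flat_field_rejected(self):
        with pytest.raises(ValueError):
            detect_scales(np.zeros((100, 100)), s=20)


@pytest.fixture(scope="module")
def small_lattice():
    from shapely.geometry import Polygon

    from scalepat.lattice import build_voronoi_lattice

    centers = np.array(
        [[(i + 0.5) * 30.0, (j + 0.5) * 30.0] for j in range(3) for i in range(3)]
    )
    region = Polygon([(0, 0), (90, 0), (90, 90), (0, 90)])
    return build_voronoi_lattice(centers, region)


class TestExtractColors:
    def test_uniform_image_gives_uniform_color(self, small_lattice):
        img = np.full((90, 90, 3), 0.4)
        colors, extras = extract_scale_colors(img, small_lattice, s=30)
        assert not extras["flagged"].any()
        assert np.allclose(colors.colors, colors.colors[0], atol=1e-9)
        assert np.abs(colors.colors - extras["median"]).max() < 1e-9

    def test_dark_rim_pixels_are_excluded(self, small_lattice):
        img = np.full((90, 90, 3), 0.6)
        # darken a band along every cell boundary (within s/10 = 3 px)
        for k in (30, 60):
            img[k - 2:k + 2, :, :] = 0.05
            img[:, k - 2:k + 2, :] = 0.05
        colors, extras = extract_scale_colors(img, small_lattice, s=30)
        ref = extract_scale_colors(np.full((90, 90, 3), 0.6), small_lattice, s=30)[0]
        assert np.abs(colors.colors - ref.colors).max() < 1e-6

    def test_summaries_agree_on_symmetric_distributions(self, small_lattice, rng):
        base = np.full((90, 90, 3), 0.5)
        img = np.clip(base + rng.normal(0, 0.008, base.shape), 0, 1)
        colors, extras = extract_scale_colors(img, small_lattice, s=30)
        assert np.abs(colors.colors - extras["median"]).max() < 1.0
        assert np.abs(colors.colors - extras["mode"]).max() < 1.0


class TestMatchPair:
    def test_identity_pair_matches_everything(self, hex1010):
        A = hex1010.centers
        m = match_pair(A, A.copy(), {0: 0, 1: 1, 2: 2})
        assert len(m) == hex1010.n_scales
        assert all(m[i] == i for i in m)

    def test_known_similarity_with_dropout_matches_truth(self, hex1010):
        A, B, truth = gen_matched_pair(
            hex1010, (0.15, 1.25, np.array([5.0, -3.0])), jitter_sd=0.0,
            dropout=0.05, seed=3,
        )
        seeds = {}
        for i in range(hex1010.n_scales):
            if truth[i] >= 0:
                seeds[i] = truth[i]
            if len(seeds) == 3:
                break
        m = match_pair(A, B, seeds)
        kept = truth >= 0
        assert all(m.get(i, -2) == truth[i] for i in np.where(kept)[0])
        assert not any(truth[i] == -1 and i in m for i in range(len(A)))

    def test_heavy_jitter_collapses_match_rate(self, hex1010):
        A, B, truth = gen_matched_pair(
            hex1010, (0.0, 1.0, np.zeros(2)), jitter_sd=1.5, dropout=0.0, seed=1
        )  # jitter ~ S >> epsilon
        m = match_pair(A, B, {0: truth[0], 1: truth[1], 2: truth[2]})
        assert len(m) / hex1010.n_scales < 0.10 + 3 / hex1010.n_scales

    def test_symmetric_on_noise_free_pairs(self, hex66):
        A, B, truth = gen_matched_pair(hex66, (0.1, 1.1, np.array([2.0, 1.0])), 0, 0, 0)
        fwd = match_pair(A, B, {0: truth[0], 1: truth[1], 2: truth[2]})
        inv_seeds = {truth[0]: 0, truth[1]: 1, truth[2]: 2}
        bwd = match_pair(B, A, inv_seeds)
        assert all(bwd.get(b, -2) == a for a, b in fwd.items())

    def test_too_few_seeds_rejected(self, hex66):
        with pytest.raises(ValueError):
            match_pair(hex66.centers, hex66.centers, {0: 0, 1: 1})


class TestSimilarity:
    def test_identity(self, hex66):
        theta, s, t = similarity_transform(hex66.centers, hex66.centers)
        assert theta == pytest.approx(0.0, abs=1e-12)
        assert s == pytest.approx(1.0, abs=1e-12)
        assert np.allclose(t, 0.0)

    def test_recovers_known_rotation_and_scale(self, hex66):
        th, sc = 0.1, 1.2
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        target = hex66.centers  # reference = transformed target
        ref = sc * target @ R.T + np.array([3.0, -1.0])
        theta, s, t = similarity_transform(ref, target)
        assert theta == pytest.approx(th, abs=1e-6)
        assert s == pytest.approx(sc, abs=1e-6)

    def test_closed_form_beats_random_candidates(self, hex66, rng):
        th, sc = 0.3, 0.8
        R = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        target = hex66.centers
        ref = sc * target @ R.T + np.array([1.0, 2.0])
        theta, s, t = similarity_transform(ref, target)

        def err(theta_, s_):
            R_ = np.array(
                [[np.cos(theta_), -np.sin(theta_)], [np.sin(theta_), np.cos(theta_)]]
            )
            tp = target - target.mean(0)
            pred = tp @ (s_ * R_).T + ref.mean(0)
            return ((ref - pred) ** 2).sum()

        e_star = err(theta, s)
        cand = np.column_stack([rng.uniform(-np.pi, np.pi, 10000),
                                rng.uniform(0.1, 3.0, 10000)])
        e_rand = np.array([err(a, b) for a, b in cand])
        assert e_star <= e_rand.min() + 1e-9


class TestUnifyNetwork:
    def _series(self, lattice, T=3, theta=0.0, s=1.0):
        sets = [lattice.centers.copy()]
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        for t in range(1, T):
            sets.append(s * lattice.centers @ R.T + np.array([t * 1.0, 0.0]))
        matches = {
            (0, t): {i: i for i in range(lattice.n_scales)} for t in range(1, T)
        }
        return sets, matches

    def test_identical_time_points_give_identity_transform(self, hex66):
        sets, matches = self._series(hex66, theta=0.0, s=1.0)
        sets = [hex66.centers.copy() for _ in range(3)]
        net = unify_network(sets, matches)
        for theta, s, t in net.transforms:
            assert theta == pytest.approx(0.0, abs=1e-9)
            assert s == pytest.approx(1.0, abs=1e-9)
        assert net.lattice.n_scales == hex66.n_scales

    def test_recovers_known_rotation_scale(self, hex66):
        sets, matches = self._series(hex66, T=2, theta=0.1, s=1.2)
        net = unify_network(sets, matches)
        theta, s, _ = net.transforms[1]
        assert theta == pytest.approx(-0.1, abs=1e-6) or theta == pytest.approx(0.1, abs=1e-6)
        assert s == pytest.approx(1 / 1.2, abs=1e-6) or s == pytest.approx(1.2, abs=1e-6)

    def test_component_missing_a_time_point_is_excluded(self, hex66):
        sets = [hex66.centers.copy() for _ in range(3)]
        full = {i: i for i in range(hex66.n_scales)}
        m01 = dict(full)
        m02 = dict(full)
        del m02[5]  # scale 5 unmatched at time 2
        net = unify_network(sets, {(0, 1): m01, (0, 2): m02})
        assert net.lattice.n_scales == hex66.n_scales - 1
        assert 5 not in net.node_ids[:, 0]
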