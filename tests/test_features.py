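import itertools
import math

import numpy as np
import pytest
from scipy import stats

from somseg.features import (
    FEATURE_NAMES,
    GLCM,
    HARALICK_NAMES,
    INVERSE_VARIANCE,
    FeatureMatrix,
    WindowSpec,
    compute_glcm,
    extract_features,
    first_order_features,
    glcm_offsets,
    global_intensity_probability,
    haralick_features,
    local_histogram_features,
    quantize,
    voxel_haralick,
)
from somseg.io_volume import Volume, coords_from_linear


# ---------------------------------------------------------------------------
# independent oracles (pure Python, no shared code with the implementation)
# ---------------------------------------------------------------------------


def glcm_oracle(window, offset, levels, symmetric=True):
    """Brute-force pair enumeration over every voxel of the window."""
    counts = np.zeros((levels, levels))
    nx, ny, nz = window.shape
    dx, dy, dz = offset
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                X, Y, Z = x + dx, y + dy, z + dz
                if 0 <= X < nx and 0 <= Y < ny and 0 <= Z < nz:
                    counts[window[x, y, z], window[X, Y, Z]] += 1
    return counts + counts.T if symmetric else counts


def haralick_oracle(P):
    """Naive double-loop Haralick statistics in canonical order."""
    N = P.shape[0]
    px = [sum(P[i, j] for j in range(N)) for i in range(N)]
    py = [sum(P[i, j] for i in range(N)) for j in range(N)]
    mu_x = sum(i * px[i] for i in range(N))
    mu_y = sum(j * py[j] for j in range(N))
    var_x = sum((i - mu_x) ** 2 * px[i] for i in range(N))
    var_y = sum((j - mu_y) ** 2 * py[j] for j in range(N))

    energy = entropy = contrast = homog = dissim = 0.0
    corr_num = shade = tend = sum_avg = 0.0
    for i in range(N):
        for j in range(N):
            p = P[i, j]
            energy += p * p
            if p > 0:
                entropy -= p * math.log2(p)
            contrast += (i - j) ** 2 * p
            homog += p / (1 + (i - j) ** 2)
            dissim += abs(i - j) * p
            corr_num += (i - mu_x) * (j - mu_y) * p
            shade += (i + j - mu_x - mu_y) ** 3 * p
            tend += (i + j - mu_x - mu_y) ** 2 * p
            sum_avg += (i + j) * p
    denom = math.sqrt(var_x * var_y)
    correlation = corr_num / denom if denom > 1e-12 else 0.0
    pd = [sum(P[i, j] for i in range(N) for j in range(N) if abs(i - j) == k) for k in range(N)]
    mu_d = sum(k * pd[k] for k in range(N))
    diff_var = sum((k - mu_d) ** 2 * pd[k] for k in range(N))
    return np.array(
        [energy, entropy, correlation, contrast, homog, var_x, sum_avg,
         dissim, shade, tend, P.max(), diff_var]
    )


# ---------------------------------------------------------------------------
# quantize
# ---------------------------------------------------------------------------


class TestQuantize:
    def test_range_endpoints(self):
        data = np.arange(256, dtype=float).reshape(4, 8, 8)
        vol = Volume(data=data, mask=np.ones(data.shape, bool))
        q = quantize(vol, 16)
        assert q.data.min() == 0
        assert q.data.max() == 15
        assert q.data[tuple(np.argwhere(data == 255)[0])] == 15

    def test_constant_image_all_zero(self, caplog):
        vol = Volume(data=np.full((4, 4, 4), 7.0), mask=np.ones((4, 4, 4), bool))
        q = quantize(vol, 16)
        assert (q.data == 0).all()

    def test_monotone_pairwise(self, rng):
        data = rng.uniform(-10, 50, size=(8, 8, 8))
        vol = Volume(data=data, mask=np.ones(data.shape, bool))
        q = quantize(vol, 4)
        flat_raw, flat_q = data.ravel(), q.data.ravel()
        order = np.argsort(flat_raw)
        assert (np.diff(flat_q[order]) >= 0).all()

    def test_levels_validation(self, random_volume):
        with pytest.raises(ValueError):
            quantize(random_volume, 1)


# ---------------------------------------------------------------------------
# offsets
# ---------------------------------------------------------------------------


class TestOffsets:
    def test_thirteen_directions(self):
        assert len(glcm_offsets()) == 13

    def test_union_with_negations_covers_all_27(self):
        offs = glcm_offsets()
        full = set(offs) | {(-a, -b, -c) for a, b, c in offs} | {(0, 0, 0)}
        assert full == set(itertools.product((-1, 0, 1), repeat=3))
        assert len(full) == 27

    def test_no_antipodal_pair(self):
        offs = set(glcm_offsets())
        for a, b, c in offs:
            assert (-a, -b, -c) not in offs

    def test_distance_scaling(self):
        assert all(
            set(np.abs(o)) <= {0, 2} for o in np.array(glcm_offsets(distance=2))
        )

    def test_exact_canonical_vectors(self):
        assert glcm_offsets() == [
            (0, 1, 0), (-1, 1, 0), (-1, 0, 0), (-1, -1, 0), (0, 1, -1),
            (0, 0, 1), (0, -1, -1), (-1, 0, -1), (1, 0, -1), (-1, 1, -1),
            (1, -1, -1), (-1, -1, -1), (1, 1, -1),
        ]


# ---------------------------------------------------------------------------
# compute_glcm
# ---------------------------------------------------------------------------


class TestComputeGLCM:
    def test_constant_window(self):
        # 3x3x3 constant window, offset (0,0,-1): w^2*(w-1) = 18 ordered
        # pairs before symmetrization, 36 after adding the transpose.
        window = np.full((3, 3, 3), 2)
        pre = compute_glcm(window, (0, 0, -1), 4, symmetric=False)
        assert pre.counts[2, 2] == 18
        assert pre.counts.sum() == 18
        post = compute_glcm(window, (0, 0, -1), 4)
        assert post.counts[2, 2] == 36
        assert post.counts.sum() == 36

    def test_presym_total_is_analytic(self, rng):
        for w in (3, 5):
            window = rng.integers(0, 4, size=(w, w, w))
            g = compute_glcm(window, (0, 0, -1), 4, symmetric=False)
            assert g.counts.sum() == w * w * (w - 1)

    def test_symmetry_by_construction(self, rng):
        window = rng.integers(0, 5, size=(3, 3, 3))
        for off in glcm_offsets():
            g = compute_glcm(window, off, 5)
            np.testing.assert_array_equal(g.counts, g.counts.T)

    def test_matches_enumeration_oracle(self, rng):
        for _ in range(20):
            window = rng.integers(0, 4, size=(3, 3, 3))
            for off in glcm_offsets():
                got = compute_glcm(window, off, 4).counts
                want = glcm_oracle(window, off, 4)
                np.testing.assert_array_equal(got, want)

    def test_oversized_offset_gives_zero_matrix(self):
        g = compute_glcm(np.zeros((3, 3, 3), dtype=int), (0, 0, 5), 4)
        assert g.counts.sum() == 0

    def test_normalized_sums_to_one(self, rng):
        window = rng.integers(0, 4, size=(3, 3, 3))
        g = compute_glcm(window, (0, 1, 0), 4)
        assert g.normalized().sum() == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# haralick_features
# ---------------------------------------------------------------------------


class TestHaralick:
    names = dict(zip(HARALICK_NAMES, range(12)))

    def test_single_entry_degenerate(self):
        P = np.zeros((8, 8))
        P[3, 3] = 1.0
        f = haralick_features(P)
        n = self.names
        assert f[n["energy"]] == pytest.approx(1.0)
        assert f[n["entropy"]] == pytest.approx(0.0)
        assert f[n["contrast"]] == pytest.approx(0.0)
        assert f[n["dissimilarity"]] == pytest.approx(0.0)
        assert f[n["maximum_probability"]] == pytest.approx(1.0)
        assert f[n["homogeneity"]] == pytest.approx(1.0)

    def test_uniform_4x4_closed_form(self):
        P = np.full((4, 4), 1 / 16)
        f = haralick_features(P)
        assert f[self.names["energy"]] == pytest.approx(1 / 16)
        assert f[self.names["entropy"]] == pytest.approx(4.0)
        assert f[self.names["correlation"]] == pytest.approx(0.0, abs=1e-12)

    def test_matches_naive_oracle(self, rng):
        for _ in range(30):
            N = int(rng.integers(2, 9))
            M = rng.random((N, N))
            M = M + M.T  # symmetric, like a real GLCM
            P = M / M.sum()
            got = haralick_features(P)
            want = haralick_oracle(P)
            np.testing.assert_allclose(got, want, atol=1e-10)

    def test_empty_glcm_gives_zeros(self):
        g = GLCM(counts=np.zeros((4, 4)), direction=(0, 1, 0))
        np.testing.assert_array_equal(haralick_features(g), np.zeros(12))

    def test_non_normalized_input_normalized_with_warning(self, caplog):
        P = np.full((4, 4), 1.0)  # sums to 16
        with caplog.at_level("WARNING"):
            f = haralick_features(P)
        assert f[self.names["energy"]] == pytest.approx(1 / 16)
        assert any("normaliz" in r.message for r in caplog.records)


# ---------------------------------------------------------------------------
# voxel_haralick
# ---------------------------------------------------------------------------


def _quantized_volume(rng, shape=(8, 8, 8), levels=4):
    data = rng.integers(0, levels, size=shape)
    return Volume(data=data, mask=np.ones(shape, bool))


class TestVoxelHaralick:
    def test_constant_volume(self):
        vol = Volume(data=np.full((6, 6, 6), 3), mask=np.ones((6, 6, 6), bool))
        fm = voxel_haralick(vol, WindowSpec(quantization_levels=4))
        n = dict(zip(HARALICK_NAMES, range(12)))
        np.testing.assert_allclose(fm.values[:, n["energy"]], 1.0)
        np.testing.assert_allclose(fm.values[:, n["entropy"]], 0.0, atol=1e-12)

    def test_interior_voxel_matches_per_window_assembly(self, rng):
        vol = _quantized_volume(rng)
        spec = WindowSpec(quantization_levels=4)
        fm = voxel_haralick(vol, spec)
        # hand-assemble the descriptor of voxel (4, 4, 4)
        window = vol.data[3:6, 3:6, 3:6]
        feats = np.mean(
            [
                haralick_features(compute_glcm(window, off, 4))
                for off in glcm_offsets()
            ],
            axis=0,
        )
        x, y, z = coords_from_linear(fm.voxel_index, vol.shape)
        row = np.flatnonzero((x == 4) & (y == 4) & (z == 4))[0]
        np.testing.assert_allclose(fm.values[row], feats, atol=1e-10)

    def test_border_voxel_matches_reflected_window(self, rng):
        vol = _quantized_volume(rng, shape=(5, 5, 5))
        spec = WindowSpec(quantization_levels=4)
        fm = voxel_haralick(vol, spec)
        padded = np.pad(vol.data, 1, mode="reflect")
        window = padded[0:3, 0:3, 0:3]  # window of voxel (0,0,0)
        feats = np.mean(
            [
                haralick_features(compute_glcm(window, off, 4))
                for off in glcm_offsets()
            ],
            axis=0,
        )
        x, y, z = coords_from_linear(fm.voxel_index, vol.shape)
        row = np.flatnonzero((x == 0) & (y == 0) & (z == 0))[0]
        np.testing.assert_allclose(fm.values[row], feats, atol=1e-10)

    def test_skip_policy_drops_border_voxels(self, rng):
        vol = _quantized_volume(rng, shape=(6, 6, 6))
        fm = voxel_haralick(vol, WindowSpec(quantization_levels=4, border_policy="skip"))
        assert fm.n_voxels == 4 * 4 * 4

    def test_rotation_invariance_about_z(self, rng):
        # 90-degree rotation in the (x, y) plane permutes the 26 signed
        # directions among themselves, so direction-averaged features of
        # matched voxels agree exactly.
        vol = _quantized_volume(rng, shape=(7, 7, 7))
        spec = WindowSpec(quantization_levels=4)
        fm = voxel_haralick(vol, spec)
        rot = Volume(
            data=np.rot90(vol.data, k=1, axes=(0, 1)).copy(),
            mask=np.ones(vol.shape, bool),
        )
        fm_rot = voxel_haralick(rot, spec)
        v0 = fm.values.reshape(7, 7, 7, 12, order="F")
        v1 = fm_rot.values.reshape(7, 7, 7, 12, order="F")
        v1_back = np.rot90(v1, k=-1, axes=(0, 1))
        np.testing.assert_allclose(v0, v1_back, atol=1e-10)


# ---------------------------------------------------------------------------
# first-order features
# ---------------------------------------------------------------------------


class TestFirstOrder:
    def test_constant_volume(self):
        vol = Volume(data=np.full((5, 5, 5), 9.0), mask=np.ones((5, 5, 5), bool))
        fm = first_order_features(vol)
        np.testing.assert_allclose(fm.values[:, 0], 9.0)
        np.testing.assert_allclose(fm.values[:, 1], 9.0)
        np.testing.assert_allclose(fm.values[:, 2], 0.0, atol=1e-9)

    def test_window_of_0_to_26(self):
        data = np.zeros((5, 5, 5))
        data[1:4, 1:4, 1:4] = np.arange(27).reshape(3, 3, 3)
        vol = Volume(data=data, mask=np.ones((5, 5, 5), bool))
        fm = first_order_features(vol)
        x, y, z = coords_from_linear(fm.voxel_index, vol.shape)
        row = np.flatnonzero((x == 2) & (y == 2) & (z == 2))[0]
        assert fm.values[row, 1] == pytest.approx(13.0)
        assert fm.values[row, 2] == pytest.approx(60.0 + 2 / 3)

    def test_central_intensity_is_identity(self, random_volume):
        fm = first_order_features(random_volume)
        x, y, z = coords_from_linear(fm.voxel_index, random_volume.shape)
        np.testing.assert_allclose(fm.values[:, 0], random_volume.data[x, y, z])


# ---------------------------------------------------------------------------
# local histogram features
# ---------------------------------------------------------------------------


class TestLocalHistogram:
    def test_constant_window(self):
        vol = Volume(data=np.full((5, 5, 5), 3), mask=np.ones((5, 5, 5), bool))
        fm = local_histogram_features(vol, WindowSpec(quantization_levels=8))
        mean, var, energy, entropy, skew, kurt, mode = fm.values[0]
        assert energy == pytest.approx(1.0)
        assert entropy == pytest.approx(0.0)
        assert var == pytest.approx(0.0)
        assert skew == 0.0 and kurt == 0.0
        assert mode == 3

    def test_27_distinct_levels_entropy(self):
        data = np.zeros((5, 5, 5), dtype=int)
        data[1:4, 1:4, 1:4] = np.arange(27).reshape(3, 3, 3)
        vol = Volume(data=data, mask=np.ones((5, 5, 5), bool))
        fm = local_histogram_features(vol, WindowSpec(quantization_levels=27))
        x, y, z = coords_from_linear(fm.voxel_index, vol.shape)
        row = np.flatnonzero((x == 2) & (y == 2) & (z == 2))[0]
        assert fm.values[row, 3] == pytest.approx(np.log2(27))

    def test_matches_scalar_oracle(self, rng):
        vol = Volume(data=rng.integers(0, 8, size=(6, 6, 6)), mask=np.ones((6, 6, 6), bool))
        fm = local_histogram_features(vol, WindowSpec(quantization_levels=8))
        padded = np.pad(vol.data, 1, mode="reflect")
        x, y, z = coords_from_linear(fm.voxel_index, vol.shape)
        for row in rng.choice(fm.n_voxels, size=10, replace=False):
            cx, cy, cz = x[row] + 1, y[row] + 1, z[row] + 1
            sample = padded[cx - 1 : cx + 2, cy - 1 : cy + 2, cz - 1 : cz + 2].ravel()
            h = np.bincount(sample, minlength=8) / 27
            want = [
                sample.mean(),
                sample.var(),
                (h**2).sum(),
                -sum(p * math.log2(p) for p in h if p > 0),
                stats.skew(sample),
                stats.kurtosis(sample, fisher=False),
                np.argmax(h),
            ]
            np.testing.assert_allclose(fm.values[row], want, atol=1e-10)


# ---------------------------------------------------------------------------
# global intensity probability
# ---------------------------------------------------------------------------


class TestGlobalProbability:
    def test_constant_region(self):
        vol = Volume(data=np.full((4, 4, 4), 5), mask=np.ones((4, 4, 4), bool))
        fm = global_intensity_probability(vol, WindowSpec(quantization_levels=8))
        np.testing.assert_allclose(fm.values[:, 0], 1.0)

    def test_two_level_symmetry(self):
        data = np.zeros((4, 4, 4), dtype=int)
        data[2:] = 1
        vol = Volume(data=data, mask=np.ones((4, 4, 4), bool))
        fm = global_intensity_probability(vol, WindowSpec(quantization_levels=2))
        np.testing.assert_allclose(fm.values[:, 0], 0.5)

    def test_counting_oracle(self, rng):
        data = rng.integers(0, 4, size=(6, 6, 6))
        vol = Volume(data=data, mask=np.ones((6, 6, 6), bool))
        fm = global_intensity_probability(vol, WindowSpec(quantization_levels=4))
        x, y, z = coords_from_linear(fm.voxel_index, vol.shape)
        V = data.size
        for row in range(0, fm.n_voxels, 17):
            level = data[x[row], y[row], z[row]]
            assert fm.values[row, 0] == pytest.approx((data == level).sum() / V)


# ---------------------------------------------------------------------------
# extract_features
# ---------------------------------------------------------------------------


class TestExtractFeatures:
    def test_full_set_is_23_columns(self, small_phantom):
        vol, _ = small_phantom
        fm = extract_features(vol)
        assert fm.n_features == 23
        assert fm.feature_names == FEATURE_NAMES
        assert np.isfinite(fm.values).all()

    def test_selected_subset_projection(self, small_phantom):
        vol, _ = small_phantom
        full = extract_features(vol)
        one = extract_features(vol, selected=["energy"])
        assert one.feature_names == ("energy",)
        np.testing.assert_allclose(
            one.values[:, 0], full.values[:, list(FEATURE_NAMES).index("energy")]
        )

    def test_eleven_feature_subset(self, small_phantom):
        vol, _ = small_phantom
        names = [
            "energy", "contrast", "homogeneity", "cluster_shade",
            INVERSE_VARIANCE, "central_intensity", "window_mean",
            "window_variance", "hist_energy", "hist_skewness", "hist_kurtosis",
        ]
        fm = extract_features(vol, selected=names)
        assert fm.n_features == 11
        assert set(fm.feature_names) == set(names)

    def test_unknown_feature_name_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(KeyError, match="unknown feature"):
            extract_features(vol, selected=["nonsense"])

    def test_range_scaled_columns(self, small_phantom):
        vol, _ = small_phantom
        fm = extract_features(vol)
        assert (fm.values.min(axis=0) >= 0.0).all()
        assert (fm.values.max(axis=0) <= 1.0).all()
        spans = fm.values.max(axis=0) - fm.values.min(axis=0)
        assert ((np.isclose(spans, 1.0)) | (spans == 0)).all()

    def test_zscore_scaling_option(self, small_phantom):
        vol, _ = small_phantom
        fm = extract_features(vol, scale="zscore")
        np.testing.assert_allclose(fm.values.mean(axis=0), 0.0, atol=1e-9)
        sds = fm.values.std(axis=0)
        assert ((np.isclose(sds, 1.0)) | (sds == 0)).all()

    def test_unknown_scale_rejected(self, small_phantom):
        vol, _ = small_phantom
        with pytest.raises(ValueError, match="unknown scale"):
            extract_features(vol, scale="mad")

    def test_tsv_round_trip(self, tmp_path, small_phantom):
        vol, _ = small_phantom
        fm = extract_features(vol, selected=["energy", "central_intensity"])
        path = tmp_path / "features.tsv"
        fm.to_tsv(path)
        back = FeatureMatrix.from_tsv(path)
        assert back.feature_names == fm.feature_names
        assert back.grid_shape == fm.grid_shape
        np.testing.assert_allclose(back.values, fm.values)
        np.testing.assert_array_equal(back.voxel_index, fm.voxel_index)
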