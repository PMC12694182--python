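import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp
from scipy.ndimage import label as ndi_label

from holostain.optics import OpticalConfig
from holostain.preprocess import (
    MASK_THRESHOLD,
    CentroidSet,
    RegistrationError,
    compose_target,
    crop_pairs,
    default_min_area_px,
    fluo_to_mask,
    gradient_channels,
    register_by_centroids,
    split_counts,
    split_manifest,
)
from holostain.simulate import (
    CellPopulationSpec,
    FluorescenceParams,
    render_fluorescence,
    sample_cell_field,
)


def brute_force_shift_subtract(phi: np.ndarray):
    """Independent oracle: explicit pixel loops for the one-pixel
    shift-and-subtract rule with replicate padding."""
    h, w = phi.shape
    gx = np.zeros_like(phi)
    gy = np.zeros_like(phi)
    for i in range(h):
        for j in range(w):
            gx[i, j] = phi[i, j] - phi[i, j - 1] if j > 0 else 0.0
            gy[i, j] = phi[i, j] - phi[i - 1, j] if i > 0 else 0.0
    return gx, gy


class TestGradientChannels:
    def test_constant_phase_gives_zero_gradients(self):
        stack = gradient_channels(np.full((16, 16), 1.3), normalize=False)
        np.testing.assert_array_equal(stack.channels[0], 0.0)
        np.testing.assert_array_equal(stack.channels[1], 0.0)

    def test_linear_ramp_gives_constant_gradients(self):
        y, x = np.mgrid[0:20, 0:20].astype(float)
        stack = gradient_channels(0.3 * x + 0.7 * y, normalize=False)
        np.testing.assert_allclose(stack.channels[0][:, 1:], 0.3, atol=1e-12)
        np.testing.assert_allclose(stack.channels[1][1:, :], 0.7, atol=1e-12)

    def test_matches_brute_force_oracle_exactly(self):
        rng = np.random.default_rng(5)
        phi = rng.normal(size=(24, 31))
        stack = gradient_channels(phi, normalize=False)
        gx, gy = brute_force_shift_subtract(phi)
        np.testing.assert_array_equal(stack.channels[0], gx)
        np.testing.assert_array_equal(stack.channels[1], gy)
        np.testing.assert_array_equal(stack.channels[2], phi)

    @settings(max_examples=25, deadline=None)
    @given(
        hnp.arrays(
            np.float64,
            hnp.array_shapes(min_dims=2, max_dims=2, min_side=2, max_side=12),
            elements=st.floats(-100, 100, allow_nan=False),
        )
    )
    def test_oracle_equality_property(self, phi):
        stack = gradient_channels(phi, normalize=False)
        gx, gy = brute_force_shift_subtract(phi)
        np.testing.assert_array_equal(stack.channels[0], gx)
        np.testing.assert_array_equal(stack.channels[1], gy)

    def test_normalization_recorded_and_invertible(self):
        rng = np.random.default_rng(6)
        phi = rng.normal(size=(16, 16))
        stack = gradient_channels(phi)
        assert stack.channels.min() >= 0.0 and stack.channels.max() <= 1.0
        off, scale = stack.norm_params[2]
        np.testing.assert_allclose(stack.channels[2] * scale + off, phi, atol=1e-12)


class TestFluoToMask:
    def test_two_disjoint_disks_recovered(self):
        img = np.zeros((128, 128))
        yy, xx = np.mgrid[0:128, 0:128]
        d1 = (yy - 40) ** 2 + (xx - 40) ** 2 <= 15**2
        d2 = (yy - 90) ** 2 + (xx - 90) ** 2 <= 12**2
        img[d1 | d2] = 1.0
        mask = fluo_to_mask(img, blur_sigma=1.0, min_area_px=50)
        _, n = ndi_label(mask)
        assert n == 2
        # recovered support stays close to the true disks
        assert (mask & ~(d1 | d2)).sum() < 0.15 * (d1 | d2).sum()

    def test_blank_image_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty mask"):
            mask = fluo_to_mask(np.zeros((64, 64)), blur_sigma=0.0)
        assert not mask.any()

    def test_leakage_excluded_over_seeds(self, small_cfg):
        """PBMC bleed-through never survives Otsu + cleanup: across 10
        seeded fields, no isolated PBMC contributes mask pixels."""
        spec = CellPopulationSpec(cells_per_field=50, ratio_pbmc_to_tumor=10)
        min_area = default_min_area_px(small_cfg, spec)
        for seed in range(10):
            field = sample_cell_field(spec, small_cfg, seed=200 + seed)
            fluo = render_fluorescence(field, seed=seed)
            mask = fluo_to_mask(fluo, min_area_px=min_area)
            blur_reach = 3 * fluo.params.psf_sigma
            for c in field.pbmc_cells:
                near_tumor = any(
                    np.hypot(c.row - t.row, c.col - t.col)
                    < c.radius_px + t.radius_px + blur_reach
                    for t in field.tumor_cells
                )
                if near_tumor:
                    continue
                assert not mask[int(c.row), int(c.col)]

    def test_tumor_count_recovery_20_fields(self, small_cfg):
        """Component count matches the number of tumor-cell groups
        (adherent tumors merge, as documented) to within one per field."""
        min_area = default_min_area_px(small_cfg, CellPopulationSpec())
        checked_exact = 0
        for seed in range(20):
            ratio = (10, 50, 1000)[seed % 3]
            spec = CellPopulationSpec(cells_per_field=50, ratio_pbmc_to_tumor=ratio)
            field = sample_cell_field(spec, small_cfg, seed=400 + seed)
            fluo = render_fluorescence(field, seed=seed)
            mask = fluo_to_mask(fluo, min_area_px=min_area)
            _, n_found = ndi_label(mask)
            _, n_groups = ndi_label(field.cancer_mask)
            assert abs(n_found - n_groups) <= 1
            if n_groups == len(field.tumor_cells):  # no adherent merges
                assert n_found == len(field.tumor_cells)
                checked_exact += 1
        assert checked_exact >= 5  # the exact branch was actually exercised

    def test_fixed_threshold_mode(self):
        img = np.zeros((64, 64))
        img[20:30, 20:30] = 1.0
        mask = fluo_to_mask(img, blur_sigma=0.0, threshold_mode="fixed",
                            fixed_threshold=0.5, opening_radius_px=0)
        assert mask.sum() == 100


class TestComposeTarget:
    def test_empty_mask_is_half_range_phase(self):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2, size=(32, 32))
        t = compose_target(phi, np.zeros((32, 32), bool))
        norm = (phi - phi.min()) / (phi.max() - phi.min())
        np.testing.assert_allclose(t.image, 0.5 * norm, atol=1e-12)

    def test_full_mask_saturates(self):
        t = compose_target(np.ones((8, 8)), np.ones((8, 8), bool))
        np.testing.assert_array_equal(t.image, 1.0)

    def test_threshold_recovers_mask_exactly(self):
        rng = np.random.default_rng(1)
        phi = rng.uniform(0, 2.5, size=(64, 64))
        mask = rng.random((64, 64)) > 0.8
        t = compose_target(phi, mask)
        np.testing.assert_array_equal(t.image >= MASK_THRESHOLD, mask)

    def test_recomputable_from_parts(self):
        rng = np.random.default_rng(2)
        phi = rng.uniform(0, 2.5, size=(32, 32))
        mask = rng.random((32, 32)) > 0.7
        a = compose_target(phi, mask)
        b = compose_target(phi, mask)
        np.testing.assert_array_equal(a.image, b.image)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            compose_target(np.zeros((8, 8)), np.zeros((9, 9), bool))


class TestRegistration:
    def _points(self, n, seed, span=400.0):
        rng = np.random.default_rng(seed)
        return rng.uniform(20, span, size=(n, 2))

    def test_pure_shift_recovered_exactly(self):
        pts = self._points(30, 0)
        a = CentroidSet(pts)
        b = CentroidSet(pts + [17.0, -4.0])
        (dx, dy), matches, residual = register_by_centroids(a, b)
        assert (dx, dy) == (17.0, -4.0)
        assert residual == 0.0
        assert len(matches) == 30

    def test_jittered_shift_monte_carlo(self):
        """sigma=0.5 px jitter on 50 points: mean |error| < 0.2 px per
        axis over 100 seeds."""
        errs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            pts = self._points(50, seed)
            shifted = pts + [23.0, 11.0] + rng.normal(0, 0.5, size=pts.shape)
            (dx, dy), _, _ = register_by_centroids(
                CentroidSet(pts), CentroidSet(shifted)
            )
            errs.append([abs(dx - 23.0), abs(dy - 11.0)])
        mean_err = np.mean(errs, axis=0)
        assert (mean_err < 0.2).all()

    def test_robust_to_spurious_points(self):
        for seed in range(5):
            rng = np.random.default_rng(1000 + seed)
            pts = self._points(40, seed)
            shifted = pts + [9.0, -13.0] + rng.normal(0, 0.3, size=pts.shape)
            spurious = rng.uniform(0, 400, size=(12, 2))  # 30% clutter
            b = CentroidSet(np.vstack([shifted, spurious]))
            (dx, dy), _, _ = register_by_centroids(CentroidSet(pts), b)
            assert abs(dx - 9.0) < 0.5 and abs(dy + 13.0) < 0.5

    def test_too_few_points_rejected(self):
        with pytest.raises(RegistrationError, match="at least 3"):
            register_by_centroids(
                CentroidSet(np.zeros((2, 2))), CentroidSet(np.zeros((5, 2)))
            )

    def test_ambiguous_offset_histogram_rejected(self):
        # two well-separated candidate shifts with equal support
        base = self._points(20, 3)
        b = CentroidSet(np.vstack([base[:10] + [50.0, 0.0], base[10:] + [-50.0, 0.0]]))
        with pytest.raises(RegistrationError, match="ambiguous"):
            register_by_centroids(CentroidSet(base), b, max_match_dist=5.0)


class TestCrops:
    def _stack_target(self, side=64):
        rng = np.random.default_rng(0)
        phi = rng.uniform(0, 2, size=(side, side))
        stack = gradient_channels(phi)
        target = compose_target(phi, phi > 1.5)
        return stack, target

    def test_full_size_crop_is_whole_image(self):
        stack, target = self._stack_target(64)
        crops = crop_pairs(stack, target, size=64, n=1, seed=0)
        assert crops[0]["origin"] == (0, 0)
        np.testing.assert_array_equal(crops[0]["input"], stack.channels)
        np.testing.assert_array_equal(crops[0]["target"], target.image)

    def test_same_seed_same_origins(self):
        stack, target = self._stack_target(64)
        a = crop_pairs(stack, target, size=32, n=5, seed=3)
        b = crop_pairs(stack, target, size=32, n=5, seed=3)
        assert [c["origin"] for c in a] == [c["origin"] for c in b]

    def test_capacity_error(self):
        stack, target = self._stack_target(64)
        with pytest.raises(ValueError, match="origins available"):
            crop_pairs(stack, target, size=32, n=10_000, seed=0)

    def test_crops_coregistered_with_truth(self, small_cfg, cell_spec):
        """Crops taken at the same origin from the stack and the target
        stay aligned with the ground-truth cells."""
        field = sample_cell_field(cell_spec, small_cfg, seed=31)
        stack = gradient_channels(field.phase)
        target = compose_target(field.phase, field.cancer_mask)
        crops = crop_pairs(stack, target, size=128, n=4, seed=1)
        for crop in crops:
            r0, c0 = crop["origin"]
            for c in field.tumor_cells:
                r, co = int(round(c.row)) - r0, int(round(c.col)) - c0
                if 0 <= r < 128 and 0 <= co < 128:
                    assert crop["target"][r, co] == 1.0  # stain saturated at the centroid


class TestSplit:
    def test_split_counts_arithmetic(self):
        assert split_counts(1500) == (900, 300, 300)
        assert split_counts(5) == (3, 1, 1)
        assert split_counts(8) == (5, 2, 1)  # remainders train-first
        assert split_counts(100) == (60, 20, 20)

    def _entries(self, donors, ratios, per_combo, unseen=()):
        out = []
        for d in donors:
            for r in ratios:
                for k in range(per_combo):
                    out.append(
                        {
                            "example_id": f"{d}_r{r}_c{k}",
                            "donor_id": d,
                            "ratio": r,
                            "split": "unseen" if d in unseen else None,
                        }
                    )
        return out

    def test_paper_scale_split(self):
        entries = self._entries([f"d{i}" for i in range(5)], [10, 50, 1000], 100)
        split_manifest(entries, seed=0)
        counts = {s: sum(1 for e in entries if e["split"] == s) for s in ("train", "val", "test")}
        assert counts == {"train": 900, "val": 300, "test": 300}
        assert counts["train"] + counts["val"] == 1200

    def test_unseen_pool_quarantined(self):
        entries = self._entries(
            ["d0", "u0", "u1"], [10, 50, 1000], 100, unseen=("u0", "u1")
        )
        split_manifest(entries, seed=1)
        unseen = [e for e in entries if e["donor_id"].startswith("u")]
        assert len(unseen) == 600
        assert all(e["split"] == "unseen" for e in unseen)

    def test_split_disjoint_exhaustive_reproducible(self):
        entries = self._entries(["d0", "d1"], [10, 50], 10)
        split_manifest(entries, seed=7)
        assert all(e["split"] in ("train", "val", "test") for e in entries)
        first = {e["example_id"]: e["split"] for e in entries}
        for e in entries:
            e["split"] = None
        split_manifest(entries, seed=7)
        assert first == {e["example_id"]: e["split"] for e in entries}

    def test_stratified_within_donor_ratio(self):
        entries = self._entries(["d0", "d1"], [10, 50], 20)
        split_manifest(entries, seed=0)
        for d in ("d0", "d1"):
            for r in (10, 50):
                grp = [e for e in entries if e["donor_id"] == d and e["ratio"] == r]
                counts = {s: sum(1 for e in grp if e["split"] == s) for s in ("train", "val", "test")}
                assert counts == {"train": 12, "val": 4, "test": 4}

    def test_small_stratum_warns(self):
        entries = self._entries(["d0"], [10], 3)
        with pytest.warns(UserWarning, match="stratum"):
            split_manifest(entries, seed=0)
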