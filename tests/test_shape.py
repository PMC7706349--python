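"""Elliptic Fourier descriptors, mean shapes, rasterization, autoencoder,
and shape-based clustering."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from rootscape.imaging import BinaryMask, ShapeOutline
from rootscape.shape import (
    ConvAutoencoder,
    EFDSet,
    efd_transform,
    mean_efd,
    mean_shape_pipeline,
    rasterize_shape,
    reconstruct_outline,
    reconstruction_error,
    shape_clusters,
    train_autoencoder,
)
from rootscape.synthetic import generate_shape_family


def _ellipse(a=2.0, b=1.0, n=4096) -> ShapeOutline:
    theta = np.linspace(0.0, 2.0 * np.pi, n, endpoint=False)
    return ShapeOutline(np.column_stack([a * np.cos(theta), b * np.sin(theta)]))


def _quadrature_efd(points: np.ndarray, n_harmonics: int) -> np.ndarray:
    """Independent oracle: dense midpoint quadrature of the Fourier integrals
    of the piecewise-linear contour in its chain-length parameter."""
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)
    dt = np.hypot(d[:, 0], d[:, 1])
    t_knots = np.concatenate([[0.0], np.cumsum(dt)])
    T = t_knots[-1]
    m = 4000  # quadrature points per period unit of resolution
    s = (np.arange(m * len(d)) + 0.5) * (T / (m * len(d)))
    x = np.interp(s, t_knots, closed[:, 0])
    y = np.interp(s, t_knots, closed[:, 1])
    ds = T / (m * len(d))
    out = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        cosn = np.cos(2 * np.pi * n * s / T)
        sinn = np.sin(2 * np.pi * n * s / T)
        out[n - 1] = (
            2.0 / T * np.sum(x * cosn) * ds,
            2.0 / T * np.sum(x * sinn) * ds,
            2.0 / T * np.sum(y * cosn) * ds,
            2.0 / T * np.sum(y * sinn) * ds,
        )
    return out


class TestEfdTransform:
    def test_ellipse_is_single_harmonic_in_generating_parameter(self):
        """Semi-axes (2, 1): first harmonic (2, 1), higher harmonics < 1e-6."""
        efd = efd_transform(_ellipse(), 5, parameterization="uniform")
        a, b, c, d = efd.harmonics[0]
        assert a == pytest.approx(2.0, abs=2e-6)
        assert abs(b) < 1e-6 and abs(c) < 1e-6
        assert d == pytest.approx(1.0, abs=2e-6)
        assert np.abs(efd.harmonics[1:]).max() < 1e-6
        assert np.hypot(*efd.offset) < 1e-6

    def test_circle_descriptor(self):
        efd = efd_transform(_ellipse(3.0, 3.0), 3)
        a, b, c, d = efd.harmonics[0]
        assert abs(a) == pytest.approx(3.0, abs=1e-5)
        assert abs(d) == pytest.approx(3.0, abs=1e-5)
        assert np.abs(efd.harmonics[1:]).max() < 1e-5

    def test_square_coefficients_match_quadrature_oracle(self):
        square = ShapeOutline(
            np.array([[0.0, 0.0], [1.0, 0.0], [1.0, 1.0], [0.0, 1.0]])
        )
        efd = efd_transform(square, 6)
        oracle = _quadrature_efd(square.points, 6)
        assert np.abs(efd.harmonics - oracle).max() < 1e-6

    def test_offset_is_contour_mean_position(self):
        shifted = ShapeOutline(_ellipse().points + [5.0, -3.0])
        efd = efd_transform(shifted, 2)
        assert efd.offset[0] == pytest.approx(5.0, abs=1e-6)
        assert efd.offset[1] == pytest.approx(-3.0, abs=1e-6)

    def test_degenerate_contour_rejected(self):
        # fewer than 3 distinct points never forms a closed contour
        with pytest.raises(ValueError):
            ShapeOutline(np.zeros((5, 2)))
        with pytest.raises(ValueError):
            ShapeOutline(np.array([[0.0, 0.0], [1.0, 1.0]] * 3))


class TestMeanEfd:
    def test_identity_for_identical_sets(self):
        efd = efd_transform(_ellipse(n=512), 4)
        mean = mean_efd([efd, efd, efd])
        assert np.allclose(mean.harmonics, efd.harmonics)
        assert mean.offset == pytest.approx(efd.offset)

    def test_two_sets_average_to_midpoint(self):
        e1 = efd_transform(_ellipse(2.0, 1.0, n=512), 4)
        e2 = efd_transform(_ellipse(4.0, 3.0, n=512), 4)
        mean = mean_efd([e1, e2])
        assert np.allclose(mean.harmonics, (e1.harmonics + e2.harmonics) / 2)

    def test_mean_of_ellipses_reconstructs_mean_ellipse(self):
        e1 = efd_transform(_ellipse(2.0, 1.0), 3, parameterization="uniform")
        e2 = efd_transform(_ellipse(4.0, 3.0), 3, parameterization="uniform")
        rec = reconstruct_outline(mean_efd([e1, e2]), 1, 360, align=False)
        x, y = rec.points[:, 0], rec.points[:, 1]
        assert np.abs(x**2 / 9.0 + y**2 / 4.0 - 1.0).max() < 1e-5

    def test_mixed_harmonic_counts_rejected(self):
        e1 = efd_transform(_ellipse(n=256), 3)
        e2 = efd_transform(_ellipse(n=256), 5)
        with pytest.raises(ValueError, match="same number of harmonics"):
            mean_efd([e1, e2])

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            mean_efd([])

    def test_commutes_with_uniform_scaling(self):
        outlines = generate_shape_family("beard", 3, 0.2, seed=1)
        sets = [efd_transform(o, 6) for o in outlines]
        scaled_sets = [
            efd_transform(ShapeOutline(o.points * 2.5), 6) for o in outlines
        ]
        assert np.allclose(
            mean_efd(scaled_sets).harmonics, 2.5 * mean_efd(sets).harmonics,
            atol=1e-9,
        )


class TestReconstruct:
    def test_one_harmonic_ellipse_is_exact(self):
        """The 1-harmonic synthesis of an ellipse's descriptors traces the
        ellipse to 1e-6 relative."""
        efd = efd_transform(_ellipse(), 1, parameterization="uniform")
        rec = reconstruct_outline(efd, 1, n_points=720, align=False)
        x, y = rec.points[:, 0], rec.points[:, 1]
        assert np.abs(x**2 / 4.0 + y**2 - 1.0).max() < 1e-6

    def test_truncation_error_non_increasing(self):
        outline = generate_shape_family("umbrella", 1, 0.0, seed=0)[0]
        errors = [reconstruction_error(outline, n) for n in range(1, 12)]
        assert all(a >= b - 1e-9 for a, b in zip(errors, errors[1:]))

    def test_alignment_contract(self):
        outline = generate_shape_family("drought", 1, 0.1, seed=2)[0]
        rec = reconstruct_outline(efd_transform(outline, 8), 5, align=True)
        assert rec.points[:, 1].min() == pytest.approx(0.0, abs=1e-9)
        assert rec.points[:, 0].mean() == pytest.approx(0.0, abs=1e-9)

    def test_round_trip_reproduces_coefficients(self):
        """transform -> synthesize -> transform at equal N is stable to 1e-6
        (uniform parameter, where synthesis sampling matches)."""
        outline = generate_shape_family("beard", 1, 0.0, seed=0)[0]
        e1 = efd_transform(outline, 8, parameterization="uniform")
        rec = reconstruct_outline(e1, 8, n_points=8192, align=False)
        e2 = efd_transform(rec, 8, parameterization="uniform")
        rel = np.abs(e1.harmonics - e2.harmonics).max() / np.abs(e1.harmonics).max()
        assert rel < 1e-6

    def test_too_many_harmonics_rejected(self):
        efd = efd_transform(_ellipse(n=256), 3)
        with pytest.raises(ValueError, match="stored"):
            reconstruct_outline(efd, 5)


@pytest.fixture(scope="module")
def disk_mask():
    yy, xx = np.mgrid[:110, :90]
    mask = (yy - 50) ** 2 / 900 + (xx - 40) ** 2 / 225 <= 1.0
    return BinaryMask(mask=mask, px_per_cm=20.0)


@pytest.fixture(scope="module")
def tiny_images():
    imgs = []
    for fam in ("umbrella", "beard"):
        for outline in generate_shape_family(fam, 8, 0.2, seed=0):
            imgs.append(rasterize_shape(outline, 32))
    return np.array(imgs, dtype=float)


class TestMeanShapePipeline:
    def test_identical_masks_equal_single_mask_profile(self, disk_mask):
        single, efd_single = mean_shape_pipeline([disk_mask], dilate_kernel_px=5)
        many, efd_many = mean_shape_pipeline([disk_mask] * 14, dilate_kernel_px=5)
        assert np.allclose(efd_single.harmonics, efd_many.harmonics)
        assert np.allclose(single.points, many.points)

    def test_translation_invariance_of_profile(self, disk_mask):
        rolled = BinaryMask(
            mask=np.roll(np.roll(disk_mask.mask, 6, axis=0), 8, axis=1),
            px_per_cm=20.0,
        )
        p1, _ = mean_shape_pipeline([disk_mask], dilate_kernel_px=5)
        p2, _ = mean_shape_pipeline([rolled], dilate_kernel_px=5)
        assert np.allclose(p1.points, p2.points, atol=1e-6)

    def test_distinct_families_yield_distinct_profiles(self):
        masks = {}
        for fam in ("umbrella", "drought"):
            outline = generate_shape_family(fam, 1, 0.0, seed=0)[0]
            masks[fam] = BinaryMask(rasterize_shape(outline, 96), px_per_cm=10.0)
        _, e1 = mean_shape_pipeline([masks["umbrella"]], dilate_kernel_px=3)
        _, e2 = mean_shape_pipeline([masks["drought"]], dilate_kernel_px=3)
        assert np.abs(e1.harmonics[:5] - e2.harmonics[:5]).max() > 1.0

    def test_zero_usable_masks_raises(self):
        with pytest.raises(ValueError):
            mean_shape_pipeline([])


class TestRasterize:
    def test_output_is_square_with_full_height(self):
        outline = generate_shape_family("beard", 1, 0.1, seed=3)[0]
        img = rasterize_shape(outline, 64)
        assert img.shape == (64, 64)
        rows = np.nonzero(img.any(axis=1))[0]
        assert rows.min() == 0 and rows.max() == 63  # height fills the side

    def test_padding_is_width_only_and_symmetric(self):
        outline = generate_shape_family("drought", 1, 0.0, seed=0)[0]
        img = rasterize_shape(outline, 64)
        cols = np.nonzero(img.any(axis=0))[0]
        left, right = cols.min(), 63 - cols.max()
        assert abs(int(left) - int(right)) <= 1

    def test_filled_area_matches_shoelace(self):
        outline = generate_shape_family("umbrella", 1, 0.0, seed=0)[0]
        img = rasterize_shape(outline, 64)
        pts = outline.points
        h = pts[:, 1].max() - pts[:, 1].min()
        scale = 63.0 / h
        expected = abs(outline.signed_area()) * scale**2
        assert img.sum() == pytest.approx(expected, rel=0.02)

    def test_wide_outline_rejected(self):
        wide = ShapeOutline(
            np.array([[0.0, 0.0], [10.0, 0.0], [10.0, 2.0], [0.0, 2.0]])
        )
        with pytest.raises(ValueError, match="wider than tall"):
            rasterize_shape(wide, 64)


class TestAutoencoder:
    def test_training_reduces_loss(self, tiny_images):
        _, history = train_autoencoder(tiny_images, epochs=10, seed=0)
        assert history[-1] < history[0]

    def test_latent_dimension_is_eight(self, tiny_images):
        model, _ = train_autoencoder(tiny_images, epochs=2, seed=0)
        assert model.encode(tiny_images).shape == (len(tiny_images), 8)
        assert model.fingerprint()["latent_dim"] == 8

    def test_same_seed_identical_history(self, tiny_images):
        _, h1 = train_autoencoder(tiny_images, epochs=5, seed=4)
        _, h2 = train_autoencoder(tiny_images, epochs=5, seed=4)
        assert h1 == h2

    def test_too_few_images_rejected(self):
        with pytest.raises(ValueError, match="at least 16"):
            train_autoencoder(np.zeros((4, 32, 32)), epochs=1, seed=0)

    def test_non_square_rejected(self):
        with pytest.raises(ValueError, match="square"):
            train_autoencoder(np.zeros((20, 32, 40)), epochs=1, seed=0)

    def test_side_must_be_divisible_by_eight(self):
        with pytest.raises(ValueError, match="divisible by 8"):
            ConvAutoencoder(side=30)


class TestShapeClusters:
    def test_three_separated_blobs_recovered_exactly(self):
        rng = np.random.default_rng(0)
        blobs = [rng.normal(c, 0.1, size=(10, 8)) for c in (0.0, 5.0, 10.0)]
        feats = pd.DataFrame(np.vstack(blobs),
                             index=[f"g{i}" for i in range(30)])
        truth = np.repeat([0, 1, 2], 10)
        assignment = shape_clusters(feats, k=3, seed=0)
        assert adjusted_rand_score(truth, assignment.labels.to_numpy()) == 1.0

    def test_every_genotype_gets_exactly_one_label(self):
        rng = np.random.default_rng(1)
        feats = pd.DataFrame(rng.normal(size=(40, 8)),
                             index=[f"g{i}" for i in range(40)])
        assignment = shape_clusters(feats, k=8, seed=0)
        assert len(assignment.labels) == 40
        assert assignment.labels.notna().all()
        assert assignment.k == 8

    def test_wss_non_increasing_in_k(self):
        from sklearn.cluster import KMeans

        rng = np.random.default_rng(2)
        X = rng.normal(size=(60, 8))
        wss = [
            KMeans(n_clusters=k, n_init=25, random_state=0).fit(X).inertia_
            for k in (2, 4, 6, 8)
        ]
        assert all(a >= b for a, b in zip(wss, wss[1:]))

    def test_order_scores_drive_labeling(self):
        rng = np.random.default_rng(3)
        blobs = [rng.normal(c, 0.1, size=(5, 8)) for c in (0.0, 5.0)]
        feats = pd.DataFrame(np.vstack(blobs),
                             index=[f"g{i}" for i in range(10)])
        scores = pd.Series(
            [0.0] * 5 + [9.0] * 5, index=feats.index
        )  # second blob is the high performer
        assignment = shape_clusters(feats, k=2, seed=0, order_scores=scores)
        assert set(assignment.labels.iloc[5:]) == {"A"}

    def test_k_larger_than_panel_rejected(self):
        feats = pd.DataFrame(np.zeros((3, 8)))
        with pytest.raises(ValueError, match="exceeds"):
            shape_clusters(feats, k=5, seed=0)


class TestEndToEndShapeClustering:
    def test_three_families_recovered_by_autoencoder_kmeans(self):
        """Rasterize -> autoencoder -> k-means recovers the three synthetic
        silhouette families (single seed; the multi-seed median is exercised
        by the acceptance suite)."""
        images, labels = [], []
        for fi, fam in enumerate(("umbrella", "beard", "drought")):
            for outline in generate_shape_family(fam, 12, 0.15, seed=fi):
                images.append(rasterize_shape(outline, 64))
                labels.append(fi)
        images = np.array(images, dtype=float)
        model, _ = train_autoencoder(images, epochs=40, seed=0)
        feats = pd.DataFrame(model.encode(images),
                             index=[f"g{i}" for i in range(len(images))])
        assignment = shape_clusters(feats, k=3, seed=0)
        ari = adjusted_rand_score(labels, assignment.labels.to_numpy())
        assert ari >= 0.8
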