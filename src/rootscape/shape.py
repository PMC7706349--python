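"""Root shape analysis: elliptic Fourier descriptors, mean-shape profiles,
and shape-based clusters.

A closed root-silhouette outline is decomposed into elliptic Fourier
descriptors (EFD): for each harmonic n the four coefficients (a_n, b_n, c_n,
d_n) describe an ellipse whose superposition traces the contour, with the
offset (A0, C0) locating its centroid.  Genotype mean shapes are
coefficient-wise averages of per-plant descriptors, reconstructed at N = 5
harmonics to low-pass the outline down to its basic shape.  For clustering,
mean-shape silhouettes are rasterized to square binary images, compressed to
8-dimensional feature vectors by a convolutional autoencoder, and grouped by
k-means with Euclidean distance.

Two contour parameterizations are supported.  ``"arclength"`` (default) is
the classic chain-length formulation; ``"uniform"`` treats vertices as
equally spaced in the curve parameter, under which an ellipse sampled
uniformly in angle is exactly one harmonic.  Pixel-chain outlines are
near-equally spaced, so the choice is immaterial for image-derived shapes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage import draw as _skdraw
from sklearn.cluster import KMeans

from ._autoencoder import ConvAutoencoder, train_autoencoder
from .imaging import BinaryMask, ShapeOutline, dilate_mask, extract_outline
from .popgen import ClusterAssignment, cluster_labels

__all__ = [
    "EFDSet",
    "LatentFeatures",
    "efd_transform",
    "mean_efd",
    "reconstruct_outline",
    "mean_shape_pipeline",
    "rasterize_shape",
    "train_autoencoder",
    "ConvAutoencoder",
    "shape_clusters",
]


@dataclass
class EFDSet:
    """Elliptic Fourier coefficients for one closed outline.

    ``harmonics`` is (N, 4) with rows (a_n, b_n, c_n, d_n); ``offset`` is
    (A0, C0).
    """

    harmonics: np.ndarray
    offset: tuple[float, float]
    n_points: int = 0

    def __post_init__(self):
        self.harmonics = np.asarray(self.harmonics, dtype=float).reshape(-1, 4)
        if self.harmonics.shape[0] < 1:
            raise ValueError("need at least one harmonic")
        if not np.all(np.isfinite(self.harmonics)):
            raise ValueError("coefficients must be finite")
        self.offset = (float(self.offset[0]), float(self.offset[1]))

    @property
    def n_harmonics(self) -> int:
        return self.harmonics.shape[0]

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.harmonics, columns=["a", "b", "c", "d"])
        df.index = pd.RangeIndex(1, len(df) + 1, name="harmonic")
        return df


@dataclass
class LatentFeatures:
    """Per-genotype 8-d autoencoder features with the encoder fingerprint."""

    features: pd.DataFrame  # genotype x 8
    fingerprint: dict

    def __post_init__(self):
        if self.features.shape[1] != self.fingerprint.get("latent_dim", 8):
            raise ValueError("feature dimension disagrees with fingerprint")


def _parameter_steps(points: np.ndarray, parameterization: str) -> np.ndarray:
    closed = np.vstack([points, points[:1]])
    d = np.diff(closed, axis=0)
    if parameterization == "arclength":
        dt = np.hypot(d[:, 0], d[:, 1])
        if np.any(dt <= 0):
            keep = dt > 0
            if keep.sum() < 3:
                raise ValueError("degenerate (zero-length) contour")
            # collapse coincident consecutive points
            return d[keep], dt[keep]
        return d, dt
    if parameterization == "uniform":
        return d, np.ones(len(d))
    raise ValueError(f"unknown parameterization {parameterization!r}")


def efd_transform(
    outline: ShapeOutline,
    n_harmonics: int = 15,
    parameterization: str = "arclength",
) -> EFDSet:
    """Elliptic Fourier descriptors of a closed outline.

    Kuhl–Giardina coefficients of the contour parameterized by cumulative
    chain length (or by uniform vertex steps, see module docstring).
    """
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    d, dt = _parameter_steps(outline.points, parameterization)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    if T <= 0:
        raise ValueError("degenerate (zero-length) contour")
    phi = 2.0 * np.pi * t / T

    harmonics = np.empty((n_harmonics, 4))
    for n in range(1, n_harmonics + 1):
        const = T / (2.0 * n**2 * np.pi**2)
        d_cos = np.cos(n * phi[1:]) - np.cos(n * phi[:-1])
        d_sin = np.sin(n * phi[1:]) - np.sin(n * phi[:-1])
        harmonics[n - 1] = (
            const * np.sum(d[:, 0] / dt * d_cos),
            const * np.sum(d[:, 0] / dt * d_sin),
            const * np.sum(d[:, 1] / dt * d_cos),
            const * np.sum(d[:, 1] / dt * d_sin),
        )

    # offset (A0, C0): average position over the parameter
    xi = np.cumsum(d[:, 0]) - d[:, 0] / dt * t[1:]
    delta = np.cumsum(d[:, 1]) - d[:, 1] / dt * t[1:]
    a0 = (
        np.sum(d[:, 0] / (2.0 * dt) * (t[1:] ** 2 - t[:-1] ** 2))
        + np.sum(xi * dt)
    ) / T + outline.points[0, 0]
    c0 = (
        np.sum(d[:, 1] / (2.0 * dt) * (t[1:] ** 2 - t[:-1] ** 2))
        + np.sum(delta * dt)
    ) / T + outline.points[0, 1]
    return EFDSet(
        harmonics=harmonics, offset=(a0, c0), n_points=outline.n_points
    )


def reconstruction_error(
    outline: ShapeOutline,
    n_harmonics: int,
    parameterization: str = "arclength",
) -> float:
    """RMS truncation error of the N-harmonic Fourier synthesis.

    Computed exactly via Parseval: the L2 norm (over the contour parameter)
    of the difference between the piecewise-linear contour and its projection
    onto harmonics 1..N.  Non-increasing in ``n_harmonics`` by construction.
    """
    d, dt = _parameter_steps(outline.points, parameterization)
    t = np.concatenate([[0.0], np.cumsum(dt)])
    T = t[-1]
    closed = np.vstack([outline.points, outline.points[:1]])
    # ||f||^2 = (1/T) sum over segments of int (x^2 + y^2) dt, exact for
    # piecewise-linear segments
    p0, p1 = closed[:-1], closed[1:]
    seg = dt * ((p0**2 + p0 * p1 + p1**2).sum(axis=1)) / 3.0
    norm2 = float(seg.sum()) / T
    efd = efd_transform(outline, n_harmonics, parameterization)
    a0, c0 = efd.offset
    energy = a0**2 + c0**2 + 0.5 * float(np.sum(efd.harmonics**2))
    return float(np.sqrt(max(norm2 - energy, 0.0)))


def mean_efd(sets: list[EFDSet]) -> EFDSet:
    """Coefficient-wise arithmetic mean of descriptor sets (equal N)."""
    if not sets:
        raise ValueError("need at least one descriptor set")
    n = sets[0].n_harmonics
    if any(s.n_harmonics != n for s in sets):
        raise ValueError("all sets must share the same number of harmonics")
    harmonics = np.mean([s.harmonics for s in sets], axis=0)
    offset = tuple(np.mean([s.offset for s in sets], axis=0))
    return EFDSet(
        harmonics=harmonics,
        offset=offset,
        n_points=int(np.mean([s.n_points for s in sets])),
    )


def reconstruct_outline(
    efd: EFDSet,
    n_harmonics: int = 5,
    n_points: int = 200,
    align: bool = True,
) -> ShapeOutline:
    """Truncated Fourier synthesis of an outline from its descriptors.

    With ``align`` the profile is placed in the comparison frame: topmost
    point at vertical coordinate 0 and horizontally centered at 0.  Without
    it the stored offset is used.
    """
    if n_harmonics > efd.n_harmonics:
        raise ValueError(
            f"requested {n_harmonics} harmonics but only "
            f"{efd.n_harmonics} stored"
        )
    if n_harmonics < 1:
        raise ValueError("n_harmonics must be >= 1")
    s = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    x = np.zeros(n_points)
    y = np.zeros(n_points)
    for n in range(1, n_harmonics + 1):
        a, b, c, d = efd.harmonics[n - 1]
        x += a * np.cos(n * s) + b * np.sin(n * s)
        y += c * np.cos(n * s) + d * np.sin(n * s)
    if align:
        x = x - x.mean()
        y = y - y.min()
    else:
        x = x + efd.offset[0]
        y = y + efd.offset[1]
    outline = ShapeOutline(points=np.column_stack([x, y]))
    if outline.signed_area() < 0:
        outline = ShapeOutline(points=outline.points[::-1])
    return outline


def mean_shape_pipeline(
    masks: list[BinaryMask],
    dilate_kernel_px: int = 50,
    n_harmonics_store: int = 15,
    n_harmonics: int = 5,
    n_points: int = 200,
) -> tuple[ShapeOutline, EFDSet]:
    """Genotype mean-shape profile from its replicate masks.

    Each mask is dilated (square kernel, default 50 px) so the fragmented
    root silhouette becomes one solid blob the Fourier transform can follow,
    its outline extracted and transformed; descriptors are averaged across
    replicates and the mean reconstructed at ``n_harmonics`` (default 5)
    to keep only the basic shape.  Masks whose outline extraction fails are
    excluded with a warning.
    """
    if not masks:
        raise ValueError("need at least one mask")
    sets = []
    for i, mask in enumerate(masks):
        try:
            dilated = dilate_mask(mask, dilate_kernel_px)
            outline = extract_outline(dilated)
            sets.append(efd_transform(outline, n_harmonics_store))
        except ValueError as err:
            warnings.warn(f"mask {i} excluded from mean shape: {err}",
                          stacklevel=2)
    if not sets:
        raise ValueError("no usable masks for the mean shape")
    mean_set = mean_efd(sets)
    profile = reconstruct_outline(
        mean_set, n_harmonics=n_harmonics, n_points=n_points
    )
    return profile, mean_set


def rasterize_shape(outline: ShapeOutline, side_px: int = 64) -> np.ndarray:
    """Filled binary silhouette on a square canvas, width-padded.

    The outline is scaled so its height maps to the full canvas side and
    padded symmetrically along the width direction only.

    Raises
    ------
    ValueError
        If the scaled shape is wider than the canvas (width padding cannot
        square it).
    """
    pts = outline.points.copy()
    height = pts[:, 1].max() - pts[:, 1].min()
    width = pts[:, 0].max() - pts[:, 0].min()
    if height <= 0 or width <= 0:
        raise ValueError("outline has zero extent")
    scale = (side_px - 1) / height
    if width * scale > side_px - 1:
        raise ValueError(
            "outline wider than tall: width padding cannot make it square"
        )
    x = (pts[:, 0] - pts[:, 0].min()) * scale
    y = (pts[:, 1] - pts[:, 1].min()) * scale
    x = x + (side_px - 1 - x.max()) / 2.0  # symmetric width padding
    img = np.zeros((side_px, side_px), dtype=bool)
    rr, cc = _skdraw.polygon(y, x, shape=img.shape)
    img[rr, cc] = True
    return img


def shape_clusters(
    latents: LatentFeatures | pd.DataFrame,
    k: int = 8,
    seed: int = 0,
    n_init: int = 25,
    order_scores: pd.Series | None = None,
) -> ClusterAssignment:
    """Shape-based clusters (SBC): k-means on autoencoder latent features.

    Clusters are relabeled A.. by decreasing mean of ``order_scores`` over
    member genotypes (typically the mean of the 13 z-scored traits); without
    scores, by decreasing cluster size.  Ties break by cluster size.
    """
    feats = latents.features if isinstance(latents, LatentFeatures) else latents
    n = len(feats)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genotypes ({n})")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
    raw = km.fit_predict(feats.to_numpy(dtype=float))
    labels = pd.Series(raw, index=feats.index, name="SBC")
    sizes = labels.value_counts()
    if order_scores is not None:
        means = order_scores.reindex(feats.index).groupby(labels).mean()
        ordering = sorted(
            means.index, key=lambda c: (-means[c], -sizes[c])
        )
    else:
        ordering = list(sizes.index)  # by decreasing size
    alphabet = cluster_labels(len(ordering))
    mapping = {raw_label: alphabet[i] for i, raw_label in enumerate(ordering)}
    return ClusterAssignment(
        labels=labels.map(mapping),
        method="SBC",
        meta={"k": k, "seed": seed, "n_init": n_init},
    )
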