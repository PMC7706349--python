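"""Root image segmentation, skeletonization, and outline extraction.

Seedlings are imaged on blue germination paper.  Segmentation is a single hue
threshold in HSV space: pixels with hue above 175 degrees are background (blue
paper), everything else is root foreground.  When the background is
oversaturated by light reflection that rule misfires (most of the frame reads
as foreground); the fallback converts to Lab and thresholds the lightness
channel with Otsu's method, taking the smaller class as the root.

Coordinates are row-major with the origin at the top-left corner; depth
increases downward (+row).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import imageio.v3 as iio
import numpy as np
from scipy import ndimage
from skimage import color, filters, measure, morphology

__all__ = [
    "RootImage",
    "BinaryMask",
    "Skeleton",
    "ShapeOutline",
    "SegmentationError",
    "EmptySkeletonError",
    "segment_root",
    "skeletonize_mask",
    "dilate_mask",
    "extract_outline",
    "read_image",
    "write_image",
]

#: Hue threshold (degrees) above which a pixel is blue-paper background.
HUE_BACKGROUND_DEG = 175.0

#: Foreground fraction beyond which the hue rule is deemed to have failed
#: (oversaturated background misread as root) and the Lab fallback is used.
LAB_FALLBACK_FRACTION = 0.5

#: Connected components smaller than this (pixels) are removed as paper-texture
#: noise before the largest component is retained.
MIN_COMPONENT_PX = 20


class SegmentationError(ValueError):
    """Raised when no root foreground can be recovered from an image.

    Carries the foreground fractions seen under each rule for diagnostics.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class EmptySkeletonError(ValueError):
    """Raised when a mask thins to nothing."""


@dataclass
class RootImage:
    """An RGB root scan with its raster scale and plant metadata."""

    rgb: np.ndarray  # H x W x 3, uint8
    px_per_cm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.rgb = np.asarray(self.rgb)
        if self.rgb.ndim != 3 or self.rgb.shape[2] != 3:
            raise ValueError("rgb must be an HxWx3 array")
        if self.rgb.shape[0] < 1 or self.rgb.shape[1] < 1:
            raise ValueError("image must be non-empty")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")


@dataclass
class BinaryMask:
    """Boolean root mask (True = root) at a known scale."""

    mask: np.ndarray  # H x W, bool
    px_per_cm: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")

    @property
    def area_px(self) -> int:
        return int(self.mask.sum())


# 8-neighbour offsets; the first four define each undirected edge once.
_HALF_NEIGHBOURS = ((0, 1), (1, 0), (1, 1), (1, -1))
_ALL_NEIGHBOURS = tuple(
    (dr, dc) for dr in (-1, 0, 1) for dc in (-1, 0, 1) if (dr, dc) != (0, 0)
)


@dataclass
class Skeleton:
    """One-pixel-wide medial skeleton with its 8-connected pixel graph.

    Edge weights are 1 px for orthogonal and sqrt(2) px for diagonal steps, so
    ``length_px`` approximates the arc length of the thinned structure.
    """

    image: np.ndarray  # H x W, bool
    px_per_cm: float

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=bool)
        rows, cols = np.nonzero(self.image)
        self.pixels = np.column_stack([rows, cols])
        self._index = {(int(r), int(c)): i for i, (r, c) in enumerate(self.pixels)}
        edges = []
        weights = []
        for i, (r, c) in enumerate(self.pixels):
            r, c = int(r), int(c)
            for dr, dc in _HALF_NEIGHBOURS:
                j = self._index.get((r + dr, c + dc))
                if j is None:
                    continue
                if dr != 0 and dc != 0:
                    # prune a diagonal edge already spanned by orthogonal steps
                    if (r + dr, c) in self._index or (r, c + dc) in self._index:
                        continue
                    weights.append(np.sqrt(2.0))
                else:
                    weights.append(1.0)
                edges.append((i, j))
        self.edges = np.array(edges, dtype=int).reshape(-1, 2)
        self.edge_weights = np.asarray(weights)

    @property
    def n_pixels(self) -> int:
        return len(self.pixels)

    @property
    def length_px(self) -> float:
        return float(self.edge_weights.sum())

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_pixels, dtype=int)
        for i, j in self.edges:
            deg[i] += 1
            deg[j] += 1
        return deg

    def neighbors(self, i: int) -> Iterator[int]:
        """Graph neighbours of pixel ``i`` (redundant diagonals pruned)."""
        r, c = (int(v) for v in self.pixels[i])
        for dr, dc in _ALL_NEIGHBOURS:
            j = self._index.get((r + dr, c + dc))
            if j is None:
                continue
            if dr != 0 and dc != 0:
                if (r + dr, c) in self._index or (r, c + dc) in self._index:
                    continue
            yield j


@dataclass
class ShapeOutline:
    """Ordered closed contour of a shape, counter-clockwise.

    ``points`` is an (N, 2) array of (x, y) pixel coordinates with y increasing
    downward; the first point is implicitly joined to the last.  Orientation is
    counter-clockwise when the y axis is flipped upward (signed area > 0).
    """

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(np.unique(self.points, axis=0)) < 3:
            raise ValueError("outline needs at least 3 distinct points")

    @property
    def n_points(self) -> int:
        return len(self.points)

    def signed_area(self) -> float:
        """Shoelace area in math convention (y up); positive = CCW."""
        x = self.points[:, 0]
        y = -self.points[:, 1]
        return 0.5 * float(
            np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
        )


def read_image(path, px_per_cm: float, meta: dict | None = None) -> RootImage:
    """Load a PNG/JPEG root scan."""
    arr = iio.imread(path)
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    return RootImage(rgb=arr, px_per_cm=px_per_cm, meta=meta or {})


def write_image(path, image: RootImage | BinaryMask) -> None:
    """Write an image or mask as PNG."""
    if isinstance(image, BinaryMask):
        iio.imwrite(path, (image.mask * np.uint8(255)))
    else:
        iio.imwrite(path, image.rgb.astype(np.uint8))


def _clean_mask(fg: np.ndarray) -> np.ndarray | None:
    """Despeckle and keep the largest connected component; None if empty."""
    fg = morphology.remove_small_objects(fg, max_size=MIN_COMPONENT_PX - 1)
    if not fg.any():
        return None
    labels = measure.label(fg, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


def segment_root(image: RootImage) -> BinaryMask:
    """Segment root foreground from blue-paper background.

    Hue rule first (H > 175 deg is background); Lab-lightness Otsu fallback
    when the hue rule labels more than half of the frame as foreground.

    Raises
    ------
    SegmentationError
        If no foreground survives despeckling under either rule.
    """
    rgb = image.rgb.astype(float) / 255.0
    hue_deg = color.rgb2hsv(rgb)[:, :, 0] * 360.0
    fg = hue_deg <= HUE_BACKGROUND_DEG
    hue_fraction = float(fg.mean())
    diagnostics = {"hue_foreground_fraction": hue_fraction}

    if hue_fraction > LAB_FALLBACK_FRACTION:
        lightness = color.rgb2lab(rgb)[:, :, 0]
        thresh = filters.threshold_otsu(lightness)
        above = lightness > thresh
        # roots are thin: the smaller class is the foreground
        fg = above if above.mean() <= 0.5 else ~above
        diagnostics["lab_foreground_fraction"] = float(fg.mean())
        diagnostics["lab_threshold"] = float(thresh)

    cleaned = _clean_mask(fg)
    if cleaned is None:
        raise SegmentationError(
            "no root foreground found under hue or Lab rules", diagnostics
        )
    return BinaryMask(mask=cleaned, px_per_cm=image.px_per_cm, meta=dict(image.meta))


def skeletonize_mask(mask: BinaryMask) -> Skeleton:
    """Thin a mask to its 1-pixel-wide medial skeleton.

    Raises
    ------
    EmptySkeletonError
        If the mask is empty.
    """
    if not mask.mask.any():
        raise EmptySkeletonError("cannot skeletonize an empty mask")
    skel = morphology.skeletonize(mask.mask)
    if not skel.any():
        # degenerate thin input: the mask is already its own skeleton
        skel = mask.mask.copy()
    return Skeleton(image=skel, px_per_cm=mask.px_per_cm)


def dilate_mask(mask: BinaryMask, kernel_px: int = 50) -> BinaryMask:
    """Morphological dilation with a square ``kernel_px`` structuring element."""
    if kernel_px < 1:
        raise ValueError("kernel_px must be >= 1")
    if kernel_px == 1:
        return BinaryMask(mask=mask.mask.copy(), px_per_cm=mask.px_per_cm,
                          meta=dict(mask.meta))
    dilated = ndimage.binary_dilation(
        mask.mask, structure=np.ones((kernel_px, kernel_px), dtype=bool)
    )
    return BinaryMask(mask=dilated, px_per_cm=mask.px_per_cm, meta=dict(mask.meta))


def _moore_trace(mask: np.ndarray) -> np.ndarray:
    """Trace the boundary pixels of the largest component, ordered.

    Moore-neighbour tracing with Jacob's stopping criterion.  Returns (N, 2)
    array of (row, col) boundary pixel coordinates.
    """
    rows, cols = np.nonzero(mask)
    start = (int(rows[0]), int(cols[0]))  # row-major scan: topmost-leftmost

    # clockwise neighbour order starting north
    cw = ((-1, 0), (-1, 1), (0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1))
    offset_index = {off: k for k, off in enumerate(cw)}

    def inside(p):
        r, c = p
        return 0 <= r < mask.shape[0] and 0 <= c < mask.shape[1] and mask[r, c]

    boundary = [start]
    backtrack = (start[0], start[1] - 1)  # entered scanning from the west
    current = start
    second = None
    max_steps = 8 * mask.size
    for _ in range(max_steps):
        off = (backtrack[0] - current[0], backtrack[1] - current[1])
        k0 = offset_index[off]
        nxt = None
        for step in range(1, 9):
            k = (k0 + step) % 8
            cand = (current[0] + cw[k][0], current[1] + cw[k][1])
            if inside(cand):
                nxt = cand
                backtrack = (current[0] + cw[(k - 1) % 8][0],
                             current[1] + cw[(k - 1) % 8][1])
                break
        if nxt is None:  # isolated pixel
            break
        if current == start and second is not None and nxt == second:
            break  # back at the start about to repeat the first move
        if second is None:
            second = nxt
        if nxt != start:
            boundary.append(nxt)
        current = nxt
    return np.array(boundary, dtype=float)


def extract_outline(mask: BinaryMask) -> ShapeOutline:
    """Ordered closed boundary contour of the largest component, CCW.

    Raises
    ------
    ValueError
        If the mask is empty or degenerate (fewer than 3 boundary pixels).
    """
    if not mask.mask.any():
        raise ValueError("cannot extract an outline from an empty mask")
    labels = measure.label(mask.mask, connectivity=2)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    largest = labels == counts.argmax()
    trace = _moore_trace(largest)
    points = trace[:, ::-1]  # (row, col) -> (x, y)
    outline = ShapeOutline(points=points)
    if outline.signed_area() < 0:
        outline = ShapeOutline(points=points[::-1])
    return outline
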