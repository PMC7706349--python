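"""Root system architecture trait extraction from mask + skeleton.

Computes the full measured/derived trait set of the imaging pipeline: lengths
(TRL, PRL, SRL, band splits), extents (DEP, WID), areas (CVA, NWA, band
splits, rhizosphere), counts (lateral branches, per-row crossings), angles
(lateral root angle from the vertical axis), and centroid-based depth ratios.

Conventions
-----------
* The primary root path is the maximal-depth geodesic from the topmost
  skeleton node (taproot morphology).
* "Upper one-third" bands are defined on the depth extent of the root system,
  not the image frame.
* The lateral root angle is measured from the vertical axis: 0 deg = steep,
  90 deg = horizontal emergence.
* Undefined quantities (no laterals, zero lower-band length, ...) propagate
  as NaN, never as zero.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import dijkstra
from scipy.spatial import cKDTree
from skimage import measure, morphology

from .imaging import BinaryMask, Skeleton

__all__ = ["TraitVector", "extract_traits", "compute_growth_rates", "TRAIT_NAMES"]

_FIELDS = (
    "TRL TRL_GR PRL TRLUpper TRLLower DEP WID CVA RHZO VOL LRA SOL2 LED "
    "NLR LRB MED MAX TRArea PRA TRAUpper TRALower WDR SOL NWA BSH SRL "
    "SRL_PRL SRL_LRB MSL DIA PER COM COP CMT CMM CMB CPT CPM CPB"
).split()


@dataclass
class TraitVector:
    """One plant's trait measurements; cm-based units, NaN = undefined."""

    TRL: float = np.nan
    TRL_GR: float = np.nan
    PRL: float = np.nan
    TRLUpper: float = np.nan
    TRLLower: float = np.nan
    DEP: float = np.nan
    WID: float = np.nan
    CVA: float = np.nan
    RHZO: float = np.nan
    VOL: float = np.nan
    LRA: float = np.nan
    SOL2: float = np.nan
    LED: float = np.nan
    NLR: float = np.nan
    LRB: float = np.nan
    MED: float = np.nan
    MAX: float = np.nan
    TRArea: float = np.nan
    PRA: float = np.nan
    TRAUpper: float = np.nan
    TRALower: float = np.nan
    WDR: float = np.nan
    SOL: float = np.nan
    NWA: float = np.nan
    BSH: float = np.nan
    SRL: float = np.nan
    SRL_PRL: float = np.nan
    SRL_LRB: float = np.nan
    MSL: float = np.nan
    DIA: float = np.nan
    PER: float = np.nan
    COM: float = np.nan
    COP: float = np.nan
    CMT: float = np.nan
    CMM: float = np.nan
    CMB: float = np.nan
    CPT: float = np.nan
    CPM: float = np.nan
    CPB: float = np.nan

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


TRAIT_NAMES: tuple[str, ...] = tuple(_FIELDS)


def _primary_path(skeleton: Skeleton) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the primary-root path and geodesic distances from the top.

    The path is the geodesic from the topmost skeleton pixel to the deepest
    reachable pixel (greedy-deepest at ties: among deepest rows, the pixel
    with the largest geodesic distance).
    """
    pts = skeleton.pixels
    n = len(pts)
    top = int(np.lexsort((pts[:, 1], pts[:, 0]))[0])  # topmost, then leftmost
    if n == 1:
        return np.array([top]), np.zeros(1)
    graph = csr_matrix(
        (
            np.concatenate([skeleton.edge_weights, skeleton.edge_weights]),
            (
                np.concatenate([skeleton.edges[:, 0], skeleton.edges[:, 1]]),
                np.concatenate([skeleton.edges[:, 1], skeleton.edges[:, 0]]),
            ),
        ),
        shape=(n, n),
    )
    dist, pred = dijkstra(graph, indices=top, return_predecessors=True)
    reachable = np.isfinite(dist)
    deepest_row = pts[reachable, 0].max()
    candidates = np.where(reachable & (pts[:, 0] == deepest_row))[0]
    target = int(candidates[np.argmax(dist[candidates])])
    path = [target]
    while path[-1] != top:
        path.append(int(pred[path[-1]]))
    return np.array(path[::-1]), dist


def _row_run_counts(skel_img: np.ndarray) -> np.ndarray:
    """Number of distinct root crossings (pixel runs) per occupied row."""
    counts = []
    for row in skel_img:
        cols = np.nonzero(row)[0]
        if cols.size == 0:
            continue
        counts.append(1 + int(np.sum(np.diff(cols) > 1)))
    return np.asarray(counts)


def _centroid_ratio(rows: np.ndarray, rmin: int, extent: int) -> float:
    if rows.size == 0:
        return np.nan
    return float((rows.mean() - rmin + 0.5) / extent)


def extract_traits(
    mask: BinaryMask, skeleton: Skeleton, day: float | None = None
) -> TraitVector:
    """Measure the full RSA trait set from a mask and its skeleton.

    ``day`` is accepted for interface symmetry (growth rates are computed
    across days by :func:`compute_growth_rates`, not here).
    """
    if skeleton.n_pixels == 0:
        raise ValueError("skeleton is empty")
    scale = mask.px_per_cm
    m = mask.mask
    tv = TraitVector()

    # --- lengths -----------------------------------------------------------
    tv.TRL = skeleton.length_px / scale
    path, _ = _primary_path(skeleton)
    primary = set(int(i) for i in path)
    path_pts = skeleton.pixels[path]
    seg_len = (
        np.hypot(*np.diff(path_pts, axis=0).T) if len(path) > 1 else np.array([])
    )
    tv.PRL = float(seg_len.sum()) / scale
    tv.SRL = max(tv.TRL - tv.PRL, 0.0)

    # --- extents -----------------------------------------------------------
    rows, cols = np.nonzero(m)
    rmin, rmax = int(rows.min()), int(rows.max())
    cmin, cmax = int(cols.min()), int(cols.max())
    extent = rmax - rmin + 1
    tv.DEP = extent / scale
    tv.WID = (cmax - cmin + 1) / scale
    tv.WDR = tv.WID / tv.DEP if tv.DEP > 0 else np.nan

    # --- areas -------------------------------------------------------------
    hull = morphology.convex_hull_image(m)
    tv.CVA = float(hull.sum()) / scale**2
    tv.NWA = float(m.sum()) / scale**2
    tv.TRArea = tv.NWA
    tv.SOL = tv.NWA / tv.CVA if tv.CVA > 0 else np.nan
    tv.SOL2 = tv.CVA / tv.NWA if tv.NWA > 0 else np.nan
    tv.PER = float(measure.perimeter(m)) / scale

    # 2 mm disc dilation computed as a distance-transform threshold
    rhizo_px = max(0.2 * scale, 1.0)
    dt_bg = ndimage.distance_transform_edt(~m)
    tv.RHZO = float((dt_bg <= rhizo_px).sum()) / scale**2

    # --- depth bands (on the root's depth extent) --------------------------
    upper_cut = rmin + extent / 3.0
    lower_cut = rmin + 2.0 * extent / 3.0
    e_rows = (
        skeleton.pixels[skeleton.edges[:, 0], 0]
        + skeleton.pixels[skeleton.edges[:, 1], 0]
    ) / 2.0
    upper_edges = e_rows < upper_cut
    tv.TRLUpper = float(skeleton.edge_weights[upper_edges].sum()) / scale
    tv.TRLLower = tv.TRL - tv.TRLUpper
    tv.LED = tv.TRLUpper / tv.TRLLower if tv.TRLLower > 0 else np.nan

    band_top = rows < upper_cut
    band_bottom = rows >= lower_cut
    band_mid = ~band_top & ~band_bottom
    tv.TRAUpper = float(band_top.sum()) / scale**2
    tv.TRALower = float((~band_top).sum()) / scale**2

    # --- diameter / volume / primary corridor ------------------------------
    dt = ndimage.distance_transform_edt(m)
    sk_rows, sk_cols = skeleton.pixels[:, 0], skeleton.pixels[:, 1]
    radii_px = np.maximum(dt[sk_rows, sk_cols] - 0.5, 0.5)
    tv.DIA = float(np.mean(2.0 * radii_px)) / scale
    if len(path) > 1:
        r_path = np.maximum(dt[path_pts[:, 0], path_pts[:, 1]] - 0.5, 0.5)
        r_seg = (r_path[:-1] + r_path[1:]) / 2.0 / scale
        tv.VOL = float(np.sum(np.pi * r_seg**2 * seg_len / scale))
    else:
        tv.VOL = 0.0

    tree = cKDTree(skeleton.pixels)
    _, nearest = tree.query(np.column_stack([rows, cols]))
    on_primary = np.isin(nearest, path)
    tv.PRA = float(on_primary.sum()) / scale**2

    # --- branching structure -----------------------------------------------
    departing = 0
    attachments: list[tuple[int, int]] = []  # (primary pixel, lateral pixel)
    for i in primary:
        for j in skeleton.neighbors(i):
            if j not in primary:
                departing += 1
                attachments.append((i, j))
    tv.LRB = float(departing)
    degrees = skeleton.degrees()
    tv.NLR = float(sum(1 for i in primary if degrees[i] >= 3))

    tv.SRL_PRL = tv.LRB / tv.PRL if tv.PRL > 0 else np.nan
    if tv.LRB > 0:
        tv.SRL_LRB = tv.SRL / tv.LRB
        tv.MSL = tv.SRL / tv.LRB
    # else: stay NaN (no laterals)

    # --- lateral root angles -----------------------------------------------
    angles = []
    for origin, first in attachments:
        # walk ~20 px into the lateral to get its initial direction
        start_pt = skeleton.pixels[origin]
        prev, cur = origin, first
        travelled = float(np.hypot(*(skeleton.pixels[cur] - start_pt)))
        while travelled < 20.0:
            nxt = [
                j
                for j in skeleton.neighbors(cur)
                if j != prev and j not in primary
            ]
            if not nxt:
                break
            prev, cur = cur, nxt[0]
            travelled = float(np.hypot(*(skeleton.pixels[cur] - start_pt)))
        d_row, d_col = skeleton.pixels[cur] - start_pt
        if d_row == 0 and d_col == 0:
            continue
        angles.append(float(np.degrees(np.arctan2(abs(d_col), abs(d_row)))))
    tv.LRA = float(np.median(angles)) if angles else np.nan

    # --- per-row crossing counts -------------------------------------------
    run_counts = _row_run_counts(skeleton.image)
    tv.MED = float(np.median(run_counts))
    tv.MAX = float(run_counts.max())
    tv.BSH = tv.MAX / tv.MED if tv.MED > 0 else np.nan

    # --- centroid depth ratios ---------------------------------------------
    tv.COM = _centroid_ratio(rows, rmin, extent)
    tv.CMT = _centroid_ratio(rows[band_top], rmin, extent)
    tv.CMM = _centroid_ratio(rows[band_mid], rmin, extent)
    tv.CMB = _centroid_ratio(rows[band_bottom], rmin, extent)
    sk_top = sk_rows < upper_cut
    sk_bottom = sk_rows >= lower_cut
    sk_mid = ~sk_top & ~sk_bottom
    tv.COP = _centroid_ratio(sk_rows, rmin, extent)
    tv.CPT = _centroid_ratio(sk_rows[sk_top], rmin, extent)
    tv.CPM = _centroid_ratio(sk_rows[sk_mid], rmin, extent)
    tv.CPB = _centroid_ratio(sk_rows[sk_bottom], rmin, extent)
    return tv


def compute_growth_rates(table: pd.DataFrame) -> pd.DataFrame:
    """Fill TRL_GR (cm/day) per (genotype, replicate) across imaging days.

    At day 6 the rate is TRL_6 / 6 (growth from germination at length 0); at
    later days it is the difference quotient against the previous recorded
    day.  A missing earlier day leaves TRL_GR missing, never zero.
    """
    required = {"genotype", "replicate", "day", "TRL"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"table lacks required columns: {sorted(missing)}")
    out = table.copy()
    if "TRL_GR" not in out.columns:
        out["TRL_GR"] = np.nan
    for (_, _), grp in out.groupby(["genotype", "replicate"], sort=False):
        grp = grp.sort_values("day")
        trl = grp["TRL"].to_numpy(dtype=float)
        days = grp["day"].to_numpy(dtype=float)
        gr = np.full(len(grp), np.nan)
        for i in range(len(grp)):
            if days[i] == 6:
                gr[i] = trl[i] / 6.0
            elif i > 0 and np.isfinite(trl[i]) and np.isfinite(trl[i - 1]):
                gr[i] = (trl[i] - trl[i - 1]) / (days[i] - days[i - 1])
        out.loc[grp.index, "TRL_GR"] = gr
    n_unfilled = int(out["TRL_GR"].isna().sum())
    if n_unfilled:
        warnings.warn(
            f"{n_unfilled} observations lack an earlier day; TRL_GR left missing",
            stacklevel=2,
        )
    return out
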