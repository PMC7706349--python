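"""Synthetic study generator: phenotypes, root images, SNPs, shape families.

Every downstream stage of the pipeline can be exercised against known ground
truth without any external data:

* phenotypes follow the random-effects model y_ik = mu + g_i + b_k + e_ik with
  chosen variance components (genotypic, block, residual);
* seedling root images are rendered from a 2-D stochastic growth model (a
  downward random-walk taproot with Poisson-process lateral roots) on a blue
  background so the hue-threshold segmentation applies;
* SNP matrices follow the Balding–Nichols model: subpopulation allele
  frequencies drawn Beta(p(1-F)/F, (1-p)(1-F)/F) around an ancestral
  frequency p, dosages Binomial(2, p_subpop);
* closed root-silhouette outlines come from a catalogue of shape families
  (umbrella / beard / drought) with controlled within-family jitter.

All generators are pure functions of (config, seed); per-operation substreams
are derived by stable hashing so stages do not share randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml
from skimage import color as _skcolor
from skimage import draw as _skdraw
from skimage import morphology as _skmorph

from ._rng import substream
from .imaging import BinaryMask, RootImage, ShapeOutline
from .popgen import SnpMatrix

__all__ = [
    "SyntheticStudyConfig",
    "RootGrowthParams",
    "SnpParams",
    "GroundTruth",
    "RenderError",
    "simulate_phenotypes",
    "simulate_root_system",
    "simulate_snp_matrix",
    "generate_shape_family",
    "render_mask",
    "SHAPE_FAMILIES",
    "load_config",
    "save_config",
]


class RenderError(ValueError):
    """Raised when a root system cannot be rendered on the requested canvas."""


@dataclass
class RootGrowthParams:
    """Per-genotype growth parameters for the 2-D root renderer.

    elongation_rate_cm_day : taproot elongation (cm/day)
    branch_intensity_per_cm : Poisson intensity of lateral emergence along the
        taproot (branches/cm)
    branch_angle_mean_deg / branch_angle_sd_deg : lateral emergence angle from
        the vertical axis (degrees; 0 = steep, 90 = horizontal)
    tortuosity : s.d. (radians) of the per-step heading noise of the taproot
    diameter_px : stroke diameter of the rendered root (pixels)
    lateral_length_fraction : maximum lateral length as a fraction of taproot
        length (laterals shorten linearly toward the tip)
    """

    elongation_rate_cm_day: float = 4.0
    branch_intensity_per_cm: float = 2.0
    branch_angle_mean_deg: float = 65.0
    branch_angle_sd_deg: float = 10.0
    tortuosity: float = 0.04
    diameter_px: int = 3
    lateral_length_fraction: float = 0.3

    def __post_init__(self):
        if self.elongation_rate_cm_day <= 0:
            raise ValueError("elongation rate must be positive")
        if self.branch_intensity_per_cm < 0:
            raise ValueError("branch intensity must be non-negative")
        if self.diameter_px < 1:
            raise ValueError("diameter must be at least 1 px")


@dataclass
class SnpParams:
    """Balding–Nichols population-structure parameters."""

    n_markers: int = 1000
    n_subpops: int = 8
    fst: float = 0.3
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0

    def __post_init__(self):
        if self.n_markers < 1:
            raise ValueError("need at least 1 marker")
        if self.n_subpops < 1:
            raise ValueError("need at least 1 subpopulation")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("F must be in [0, 1)")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")


@dataclass
class SyntheticStudyConfig:
    """All generative parameters of a synthetic study.

    The phenotype block mirrors the random-effects model: ``mu`` the grand
    mean, ``sigma_g2`` genotypic variance, ``sigma_b2`` block (growth chamber)
    variance, ``sigma_e2`` residual variance, with ``n_replicates`` plants per
    genotype assigned round-robin to ``n_blocks`` chambers, imaged on ``days``
    after germination.
    """

    n_genotypes: int = 292
    n_replicates: int = 14
    days: tuple[int, ...] = (6, 9, 12)
    mu: float = 10.0
    sigma_g2: float = 1.0
    sigma_b2: float = 0.0
    sigma_e2: float = 2.0
    n_blocks: int = 2
    traits: dict[str, dict] | None = None  # optional per-trait overrides
    root_params: RootGrowthParams = field(default_factory=RootGrowthParams)
    snp_params: SnpParams = field(default_factory=SnpParams)
    px_per_cm: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.root_params, dict):
            self.root_params = RootGrowthParams(**self.root_params)
        if isinstance(self.snp_params, dict):
            self.snp_params = SnpParams(**self.snp_params)
        for name in ("sigma_g2", "sigma_b2", "sigma_e2"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")
        if self.n_genotypes < 1:
            raise ValueError("n_genotypes must be >= 1")
        if self.n_blocks < 1:
            raise ValueError("n_blocks must be >= 1")
        if self.px_per_cm <= 0:
            raise ValueError("px_per_cm must be positive")
        self.days = tuple(int(d) for d in self.days)
        if any(b <= a for a, b in zip(self.days, self.days[1:])):
            raise ValueError("days must be strictly increasing")
        if self.traits is not None:
            for trait, spec in self.traits.items():
                unknown = set(spec) - {"mu", "sigma_g2", "sigma_b2", "sigma_e2"}
                if unknown:
                    raise ValueError(
                        f"unknown variance keys for trait {trait!r}: {unknown}"
                    )
                for key in ("sigma_g2", "sigma_b2", "sigma_e2"):
                    if spec.get(key, 0.0) < 0:
                        raise ValueError(f"{trait}: {key} must be >= 0")

    def genotype_ids(self) -> list[str]:
        width = len(str(self.n_genotypes))
        return [f"G{i + 1:0{width}d}" for i in range(self.n_genotypes)]


@dataclass
class GroundTruth:
    """Known generative quantities attached to a synthetic artifact."""

    genetic_effects: pd.DataFrame | None = None  # genotype x (trait, day)
    block_effects: dict | None = None
    root: dict | None = None  # PRL/DEP/lateral count/angles per image
    subpop_labels: np.ndarray | None = None
    subpop_freqs: np.ndarray | None = None  # K x markers
    ancestral_freqs: np.ndarray | None = None
    family_labels: list[str] | None = None


# ---------------------------------------------------------------------------
# phenotypes


def simulate_phenotypes(
    config: SyntheticStudyConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a long trait table under y_ik = mu + g_i + b_k + e_ik.

    Genotype, block, and residual effects are independent zero-mean normal
    draws with the configured variances; replicates are assigned round-robin
    to blocks.  Each (trait, day) stratum draws its own effects.  Returns the
    long table (genotype, replicate, block, day, one column per trait) and the
    true genotype effects.
    """
    if config.n_genotypes * config.n_replicates < 4:
        raise ValueError("need at least 4 observations")
    rng = substream(config.seed, "phenotypes")
    traits = config.traits or {
        "value": {
            "mu": config.mu,
            "sigma_g2": config.sigma_g2,
            "sigma_b2": config.sigma_b2,
            "sigma_e2": config.sigma_e2,
        }
    }
    genotypes = config.genotype_ids()
    n_g, n_r = config.n_genotypes, config.n_replicates
    blocks = np.arange(n_r) % config.n_blocks

    base = pd.DataFrame(
        {
            "genotype": np.repeat(genotypes, n_r),
            "replicate": np.tile(np.arange(1, n_r + 1), n_g),
            "block": np.tile(blocks + 1, n_g),
        }
    )
    frames = []
    g_records = {}
    b_records = {}
    for day in config.days:
        frame = base.copy()
        frame["day"] = day
        for trait, spec in traits.items():
            mu = spec.get("mu", config.mu)
            sg = np.sqrt(spec.get("sigma_g2", config.sigma_g2))
            sb = np.sqrt(spec.get("sigma_b2", config.sigma_b2))
            se = np.sqrt(spec.get("sigma_e2", config.sigma_e2))
            g = rng.normal(0.0, sg, size=n_g) if sg > 0 else np.zeros(n_g)
            b = (
                rng.normal(0.0, sb, size=config.n_blocks)
                if sb > 0
                else np.zeros(config.n_blocks)
            )
            e = (
                rng.normal(0.0, se, size=n_g * n_r)
                if se > 0
                else np.zeros(n_g * n_r)
            )
            frame[trait] = (
                mu
                + np.repeat(g, n_r)
                + np.tile(b[blocks], n_g)
                + e
            )
            g_records[(trait, day)] = g
            b_records[(trait, day)] = b
        frames.append(frame)
    table = pd.concat(frames, ignore_index=True)
    effects = pd.DataFrame(g_records, index=genotypes)
    effects.columns = pd.MultiIndex.from_tuples(
        effects.columns, names=["trait", "day"]
    )
    truth = GroundTruth(genetic_effects=effects, block_effects=b_records)
    return table, truth


# ---------------------------------------------------------------------------
# root images


def _grow_primary(
    rng: np.random.Generator, length_px: float, step_px: float, tortuosity: float
) -> np.ndarray:
    """Downward random walk of the taproot; returns (N, 2) (x, y) polyline."""
    n_steps = max(int(round(length_px / step_px)), 1)
    heading = 0.0  # angle from vertical, radians
    pts = [(0.0, 0.0)]
    x = y = 0.0
    for _ in range(n_steps):
        heading += rng.normal(0.0, tortuosity)
        heading = float(np.clip(heading, -np.pi / 4, np.pi / 4))
        x += step_px * np.sin(heading)
        y += step_px * np.cos(heading)
        pts.append((x, y))
    return np.asarray(pts)


def _polyline_length(pts: np.ndarray) -> float:
    return float(np.sum(np.hypot(*np.diff(pts, axis=0).T)))


def render_mask(
    polylines: list[np.ndarray],
    diameter_px: int,
    margin_px: int = 20,
    canvas_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Rasterize polylines ((x, y) px, y down) onto a boolean canvas.

    Returns (mask, origin) where ``origin`` is the (x, y) canvas offset that
    was added to the input coordinates.
    """
    allpts = np.vstack(polylines)
    xmin, ymin = allpts.min(axis=0)
    xmax, ymax = allpts.max(axis=0)
    pad = margin_px + diameter_px
    height = int(np.ceil(ymax - ymin)) + 2 * pad
    width = int(np.ceil(xmax - xmin)) + 2 * pad
    if canvas_shape is not None:
        if canvas_shape[0] < height or canvas_shape[1] < width:
            raise RenderError(
                f"canvas {canvas_shape} too small for root extent "
                f"({height}, {width})"
            )
        height, width = canvas_shape
    origin = (pad - xmin, pad - ymin)
    mask = np.zeros((height, width), dtype=bool)
    for line in polylines:
        pts = np.round(line + origin).astype(int)
        for (x0, y0), (x1, y1) in zip(pts[:-1], pts[1:]):
            rr, cc = _skdraw.line(y0, x0, y1, x1)
            keep = (rr >= 0) & (rr < height) & (cc >= 0) & (cc < width)
            mask[rr[keep], cc[keep]] = True
    if diameter_px > 1:
        mask = _skmorph.dilation(mask, footprint=_skmorph.disk(diameter_px // 2))
    return mask, origin


#: Background (blue germination paper) and root foreground colors in HSV.
BACKGROUND_HSV = (220.0 / 360.0, 0.60, 0.75)
ROOT_HSV = (40.0 / 360.0, 0.45, 0.92)


def _colorize(mask: np.ndarray) -> np.ndarray:
    hsv = np.empty(mask.shape + (3,), dtype=float)
    hsv[...] = BACKGROUND_HSV
    hsv[mask] = ROOT_HSV
    rgb = _skcolor.hsv2rgb(hsv)
    return (rgb * 255).astype(np.uint8)


def simulate_root_system(
    genotype_params: RootGrowthParams,
    day: float,
    px_per_cm: float,
    seed: int,
    canvas_shape: tuple[int, int] | None = None,
    meta: dict | None = None,
) -> tuple[RootImage, GroundTruth]:
    """Render one seedling root system and its analytic ground truth.

    The taproot is a downward random walk of recorded arc length; laterals
    are a Poisson process along it with sampled emergence angles, shortening
    linearly toward the root tip.  The render uses a blue background and a
    root-colored foreground so the hue-threshold segmentation rule applies.
    """
    if day <= 0:
        raise ValueError("day must be positive")
    rng = np.random.default_rng(seed)
    p = genotype_params
    step_px = 2.0
    primary_len_px = p.elongation_rate_cm_day * day * px_per_cm
    primary = _grow_primary(rng, primary_len_px, step_px, p.tortuosity)
    arc = np.concatenate(
        [[0.0], np.cumsum(np.hypot(*np.diff(primary, axis=0).T))]
    )
    prl_px = arc[-1]

    # laterals: Poisson process along the taproot arc
    lam = p.branch_intensity_per_cm * prl_px / px_per_cm
    n_lat = int(rng.poisson(lam)) if lam > 0 else 0
    polylines = [primary]
    angles = []
    lat_lengths_px = []
    for _ in range(n_lat):
        s = rng.uniform(0.05, 0.95) * prl_px
        idx = int(np.searchsorted(arc, s))
        idx = min(idx, len(primary) - 1)
        base_pt = primary[idx]
        theta = float(
            np.clip(rng.normal(p.branch_angle_mean_deg, p.branch_angle_sd_deg),
                    5.0, 90.0)
        )
        side = rng.choice((-1.0, 1.0))
        length = p.lateral_length_fraction * prl_px * (1.0 - s / prl_px)
        length = max(length, 4.0 * step_px)
        direction = np.array(
            [side * np.sin(np.deg2rad(theta)), np.cos(np.deg2rad(theta))]
        )
        n_seg = max(int(length / step_px), 2)
        ts = np.linspace(0.0, length, n_seg + 1)
        lat = base_pt + ts[:, None] * direction[None, :]
        polylines.append(lat)
        angles.append(theta)
        lat_lengths_px.append(_polyline_length(lat))

    mask, _ = render_mask(
        polylines, p.diameter_px, canvas_shape=canvas_shape
    )
    rgb = _colorize(mask)
    image = RootImage(rgb=rgb, px_per_cm=px_per_cm, meta=meta or {})
    depth_px = max(pl[:, 1].max() for pl in polylines) - min(
        pl[:, 1].min() for pl in polylines
    )
    truth = GroundTruth(
        root={
            "PRL_cm": prl_px / px_per_cm,
            "DEP_cm": depth_px / px_per_cm,
            "LRB": n_lat,
            "lateral_angles_deg": angles,
            "TRL_cm": (prl_px + sum(lat_lengths_px)) / px_per_cm,
        }
    )
    return image, truth


# ---------------------------------------------------------------------------
# SNPs


def simulate_snp_matrix(
    snp_params: SnpParams, n_per_subpop: int, seed: int
) -> tuple[SnpMatrix, GroundTruth]:
    """Balding–Nichols structured SNP matrix with known subpopulation truth."""
    p = snp_params
    if n_per_subpop < 1:
        raise ValueError("need at least 1 genotype per subpopulation")
    rng = np.random.default_rng(seed)
    lo, hi = p.maf_range
    ancestral = rng.uniform(lo, hi, size=p.n_markers)
    if p.fst <= 0.0:
        raise ValueError("F must be strictly positive (use a tiny F for ~0)")
    a = ancestral * (1.0 - p.fst) / p.fst
    b = (1.0 - ancestral) * (1.0 - p.fst) / p.fst
    subpop_freqs = rng.beta(a, b, size=(p.n_subpops, p.n_markers))
    dosages = np.concatenate(
        [
            rng.binomial(2, subpop_freqs[k], size=(n_per_subpop, p.n_markers))
            for k in range(p.n_subpops)
        ],
        axis=0,
    ).astype(float)
    if p.missing_rate > 0:
        miss = rng.random(dosages.shape) < p.missing_rate
        dosages[miss] = np.nan
    labels = np.repeat(np.arange(p.n_subpops), n_per_subpop)
    ids = [f"S{k}_I{i}" for k in range(p.n_subpops) for i in range(n_per_subpop)]
    markers = [f"M{j + 1}" for j in range(p.n_markers)]
    snps = SnpMatrix(dosages=dosages, genotype_ids=ids, marker_ids=markers)
    truth = GroundTruth(
        subpop_labels=labels,
        subpop_freqs=subpop_freqs,
        ancestral_freqs=ancestral,
    )
    return snps, truth


# ---------------------------------------------------------------------------
# shape families


def _width_profile_umbrella(t: np.ndarray) -> np.ndarray:
    return 0.95 - 0.70 * t**1.5


def _width_profile_beard(t: np.ndarray) -> np.ndarray:
    return 0.42 - 0.12 * t


def _width_profile_drought(t: np.ndarray) -> np.ndarray:
    return 0.55 * (1.0 - t) ** 2 + 0.06


#: Catalogue of silhouette families: name -> (width profile, width px, height px).
SHAPE_FAMILIES = {
    "umbrella": (_width_profile_umbrella, 150.0, 280.0),
    "beard": (_width_profile_beard, 90.0, 240.0),
    "drought": (_width_profile_drought, 70.0, 300.0),
}


def generate_shape_family(
    family_id: str, n: int, jitter: float, seed: int, n_points: int = 80
) -> list[ShapeOutline]:
    """Sample ``n`` closed, simple, CCW outlines from a silhouette family.

    Outlines are symmetric width profiles over depth; ``jitter`` perturbs the
    half-width profile multiplicatively (smooth low-frequency noise), so the
    polygons remain simple for any jitter < 1.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if family_id not in SHAPE_FAMILIES:
        raise ValueError(
            f"unknown shape family {family_id!r}; "
            f"choose from {sorted(SHAPE_FAMILIES)}"
        )
    profile, width_px, height_px = SHAPE_FAMILIES[family_id]
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, 1.0, n_points)
    base_half = profile(t) * width_px / 2.0
    outlines = []
    for _ in range(n):
        if jitter > 0:
            # smooth multiplicative noise from a few random harmonics
            phase = rng.uniform(0, 2 * np.pi, size=3)
            amp = rng.normal(0.0, jitter, size=3)
            wiggle = sum(
                a * np.sin((k + 1) * np.pi * t + ph)
                for k, (a, ph) in enumerate(zip(amp, phase))
            )
            half = base_half * np.clip(1.0 + wiggle, 0.15, 3.0)
            scale = 1.0 + rng.normal(0.0, jitter / 2.0)
            half = half * max(scale, 0.2)
        else:
            half = base_half
        y = t * height_px
        right = np.column_stack([half, y])
        left = np.column_stack([-half[::-1], y[::-1]])
        pts = np.vstack([right, left])
        # drop duplicate seam points at top and bottom
        keep = np.ones(len(pts), dtype=bool)
        keep[len(right)] = np.any(pts[len(right)] != pts[len(right) - 1])
        pts = pts[keep]
        outline = ShapeOutline(points=pts)
        if outline.signed_area() < 0:
            outline = ShapeOutline(points=pts[::-1])
        outlines.append(outline)
    return outlines


# ---------------------------------------------------------------------------
# config IO


def save_config(config: SyntheticStudyConfig, path) -> None:
    """Write a study config as YAML."""
    payload = asdict(config)
    payload["days"] = list(config.days)
    payload["root_params"] = asdict(config.root_params)
    sp = asdict(config.snp_params)
    sp["maf_range"] = list(config.snp_params.maf_range)
    payload["snp_params"] = sp
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_config(path) -> SyntheticStudyConfig:
    """Load and validate a study config from YAML."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    if not isinstance(payload, dict):
        raise ValueError("config must be a YAML mapping")
    known = set(SyntheticStudyConfig.__dataclass_fields__)
    unknown = set(payload) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    if "snp_params" in payload and "maf_range" in (payload["snp_params"] or {}):
        payload["snp_params"]["maf_range"] = tuple(
            payload["snp_params"]["maf_range"]
        )
    if "days" in payload:
        payload["days"] = tuple(payload["days"])
    return SyntheticStudyConfig(**payload)
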