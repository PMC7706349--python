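"""End-to-end study orchestration.

``run_study`` executes the full analysis in dependency order on a synthetic
study (or pre-extracted trait/SNP tables): simulate -> segment -> traits ->
outlier fences -> mixed models / BLUPs / heritability -> ideotype scores ->
phenotype clusters -> SNP clusters + FST -> mean shapes -> shape clusters ->
cross-tabulations.  Every stage writes its output under the run directory and
is recorded (path + checksum) in a MANIFEST.json, so a report is fully
traceable and a rerun with the same config and seed is bit-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from ._rng import derive_seed, substream
from .iroot import DEFAULT_CATEGORIES, RankTable, cross_tabulate, score_categories
from .imaging import segment_root, skeletonize_mask
from .pheno_stats import (
    THIRTEEN_TRAITS,
    RootTraitModel,
    phenotype_clusters,
    remove_outliers,
)
from .popgen import (
    ClusterAssignment,
    filter_snps,
    fst_matrix,
    genotype_clusters,
    nei_distance,
    snp_pca,
)
from .shape import (
    LatentFeatures,
    mean_shape_pipeline,
    rasterize_shape,
    shape_clusters,
    train_autoencoder,
)
from .synthetic import (
    RootGrowthParams,
    SyntheticStudyConfig,
    load_config,
    simulate_phenotypes,
    simulate_root_system,
    simulate_snp_matrix,
)
from .traits import compute_growth_rates, extract_traits

__all__ = ["StudyReport", "run_study", "make_descriptive_table", "DEFAULT_TRAIT_SPECS"]

logger = logging.getLogger("rootscape")

#: Default generative settings for the 13 ideotype traits (day-9 scale means
#: with strong genotypic signal, mirroring a high-replication seedling study).
DEFAULT_TRAIT_SPECS: dict[str, dict] = {
    "TRL": {"mu": 215.0, "sigma_g2": 900.0, "sigma_b2": 90.0, "sigma_e2": 1800.0},
    "PRL": {"mu": 35.0, "sigma_g2": 25.0, "sigma_b2": 2.0, "sigma_e2": 50.0},
    "WID": {"mu": 16.0, "sigma_g2": 9.0, "sigma_b2": 0.9, "sigma_e2": 18.0},
    "CVA": {"mu": 287.0, "sigma_g2": 2000.0, "sigma_b2": 200.0, "sigma_e2": 4000.0},
    "LRB": {"mu": 71.0, "sigma_g2": 100.0, "sigma_b2": 10.0, "sigma_e2": 200.0},
    "VOL": {"mu": 152.0, "sigma_g2": 600.0, "sigma_b2": 60.0, "sigma_e2": 1200.0},
    "LRA": {"mu": 86.0, "sigma_g2": 4.0, "sigma_b2": 0.4, "sigma_e2": 8.0},
    "SOL2": {"mu": 130.0, "sigma_g2": 100.0, "sigma_b2": 10.0, "sigma_e2": 200.0},
    "LED": {"mu": 2.6, "sigma_g2": 0.2, "sigma_b2": 0.02, "sigma_e2": 0.4},
    "RHZO": {"mu": 3700.0, "sigma_g2": 2.5e5, "sigma_b2": 2.5e4, "sigma_e2": 5e5},
    "TRLUpper": {"mu": 142.0, "sigma_g2": 500.0, "sigma_b2": 50.0, "sigma_e2": 1000.0},
    "Root_weight": {"mu": 0.09, "sigma_g2": 4e-4, "sigma_b2": 4e-5, "sigma_e2": 8e-4},
}


@dataclass
class StudyReport:
    """Paths, checksums, and headline tables of one study run."""

    run_dir: Path
    config_hash: str
    seed: int
    outputs: dict[str, str] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    descriptive: pd.DataFrame | None = None
    assignments: dict[str, ClusterAssignment] = field(default_factory=dict)
    ranks: RankTable | None = None
    fst: pd.DataFrame | None = None
    crosstabs: dict | None = None

    def record(self, name: str, path: Path) -> None:
        self.outputs[name] = str(path)
        self.checksums[name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write_manifest(self) -> Path:
        manifest = {
            "package_version": __version__,
            "config_hash": self.config_hash,
            "seed": self.seed,
            "outputs": self.outputs,
            "checksums": self.checksums,
        }
        path = self.run_dir / "MANIFEST.json"
        path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return path


def make_descriptive_table(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    days: list[int] | None = None,
) -> pd.DataFrame:
    """Descriptive statistics + heritability per trait and day.

    For each (trait, day): mean, median, min, max, SD over raw observations,
    entry-mean H^2 from the fitted random-effects model, and the genotype
    F-test p-value (significance of the genotype effect).  Constant traits
    report SD 0 and undefined H^2.
    """
    meta_cols = {"genotype", "replicate", "block", "day"}
    if traits is None:
        traits = [
            c
            for c in table.columns
            if c not in meta_cols and pd.api.types.is_numeric_dtype(table[c])
        ]
    if days is None:
        days = sorted(table["day"].unique())
    rows = []
    for trait in traits:
        for day in days:
            values = table.loc[table["day"] == day, trait].dropna()
            row = {
                "trait": trait,
                "day": day,
                "mean": values.mean(),
                "median": values.median(),
                "min": values.min(),
                "max": values.max(),
                "sd": values.std(ddof=1),
            }
            if values.nunique() <= 1:
                row.update({"H2": np.nan, "genotype_p": np.nan})
            else:
                try:
                    res = RootTraitModel(table, trait, day=day).fit()
                    row["H2"] = res.heritability()
                    row["genotype_p"] = res.f_pvalue
                except ValueError:
                    row.update({"H2": np.nan, "genotype_p": np.nan})
            rows.append(row)
    return pd.DataFrame(rows)


def _genotype_growth_params(
    base: RootGrowthParams, rng: np.random.Generator
) -> RootGrowthParams:
    """Per-genotype growth parameters scattered around the panel means."""
    return RootGrowthParams(
        elongation_rate_cm_day=base.elongation_rate_cm_day
        * float(rng.lognormal(0.0, 0.15)),
        branch_intensity_per_cm=base.branch_intensity_per_cm
        * float(rng.lognormal(0.0, 0.25)),
        branch_angle_mean_deg=float(
            np.clip(rng.normal(base.branch_angle_mean_deg, 8.0), 20.0, 88.0)
        ),
        branch_angle_sd_deg=base.branch_angle_sd_deg,
        tortuosity=base.tortuosity,
        diameter_px=base.diameter_px,
        lateral_length_fraction=float(
            np.clip(
                base.lateral_length_fraction * rng.lognormal(0.0, 0.2),
                0.1,
                0.6,
            )
        ),
    )


def _synthetic_metadata(
    genotypes: list[str], subpop: np.ndarray, rng: np.random.Generator
) -> pd.DataFrame:
    """Country / maturity group / growth habit metadata keyed to ancestry."""
    countries = ["China", "Japan", "Korea", "Russia", "USA", "Other"]
    habits = ["determinate", "semideterminate", "indeterminate"]
    country = [
        countries[s % len(countries)]
        if rng.random() < 0.7
        else countries[int(rng.integers(len(countries)))]
        for s in subpop
    ]
    return pd.DataFrame(
        {
            "country": country,
            "maturity_group": rng.integers(1, 5, size=len(genotypes)),
            "growth_habit": [
                habits[int(i)] for i in rng.integers(0, 3, size=len(genotypes))
            ],
            "diversity": rng.choice(
                ["landrace", "elite", "diverse"],
                p=[0.9, 0.06, 0.04],
                size=len(genotypes),
            ),
        },
        index=pd.Index(genotypes, name="genotype"),
    )


def run_study(
    config: SyntheticStudyConfig | str | Path,
    out_dir: str | Path = "study_run",
    k_clusters: int = 8,
    n_image_replicates: int = 3,
    autoencoder_epochs: int = 60,
    resume: bool = False,
) -> StudyReport:
    """Execute the full study pipeline on a synthetic config.

    Stages run in dependency order; each writes CSV/JSON outputs under
    ``out_dir`` and registers them in the report manifest.  Identical
    (config, seed) pairs produce identical checksums.  With ``resume`` the
    expensive imaging stage is reloaded from an existing traits CSV.

    Raises
    ------
    ValueError
        Before execution, when the config's trait block is missing a trait
        required by the ideotype/cluster stages (the error names it).
    """
    if not isinstance(config, SyntheticStudyConfig):
        config = load_config(config)
    run_dir = Path(out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)

    trait_specs = dict(config.traits) if config.traits else dict(DEFAULT_TRAIT_SPECS)
    required = [t for t in THIRTEEN_TRAITS if t != "TRL_GR"]
    missing = [t for t in required if t not in trait_specs]
    if missing:
        raise ValueError(
            f"config trait block is missing required trait columns: {missing}"
        )
    config_payload = json.dumps(
        {
            "n_genotypes": config.n_genotypes,
            "n_replicates": config.n_replicates,
            "days": config.days,
            "traits": sorted(trait_specs),
            "seed": config.seed,
            "k": k_clusters,
        },
        sort_keys=True,
    )
    report = StudyReport(
        run_dir=run_dir,
        config_hash=hashlib.sha256(config_payload.encode()).hexdigest()[:16],
        seed=config.seed,
    )

    # -- stage 1: phenotypes -------------------------------------------------
    logger.info("stage phenotypes: simulating trait table")
    pheno_cfg = SyntheticStudyConfig(
        n_genotypes=config.n_genotypes,
        n_replicates=config.n_replicates,
        days=config.days,
        n_blocks=config.n_blocks,
        traits=trait_specs,
        root_params=config.root_params,
        snp_params=config.snp_params,
        px_per_cm=config.px_per_cm,
        seed=config.seed,
    )
    path = run_dir / "traits_raw.csv"
    if resume and path.exists():
        logger.info("resume: reloading %s", path)
        table = pd.read_csv(path)
    else:
        table, _ = simulate_phenotypes(pheno_cfg)
        if "TRL" in table.columns:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                table = compute_growth_rates(table)
        table.to_csv(path, index=False)
    report.record("traits_raw", path)

    # -- stage 2: outlier fences --------------------------------------------
    logger.info("stage outliers: Tukey fences per (trait, day)")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        filtered, outlier_report = remove_outliers(table)
    path = run_dir / "traits_filtered.csv"
    filtered.to_csv(path, index=False)
    report.record("traits_filtered", path)
    path = run_dir / "outliers.csv"
    outlier_report.to_csv(path, index=False)
    report.record("outliers", path)

    # -- stage 3: mixed models / BLUPs / heritability ------------------------
    logger.info("stage mixed models: variance components and BLUPs")
    trait_cols = [c for c in trait_specs] + (
        ["TRL_GR"] if "TRL_GR" in filtered.columns else []
    )
    descriptive = make_descriptive_table(filtered, traits=trait_cols)
    path = run_dir / "descriptive.csv"
    descriptive.to_csv(path, index=False)
    report.record("descriptive", path)
    report.descriptive = descriptive

    focus_day = 9 if 9 in config.days else config.days[-1]
    blup_cols = {}
    for trait in trait_cols:
        try:
            res = RootTraitModel(filtered, trait, day=focus_day).fit()
            blup_cols[trait] = res.blups
        except (ValueError, KeyError):
            continue
    blups = pd.DataFrame(blup_cols)
    path = run_dir / f"blups_day{focus_day}.csv"
    blups.to_csv(path, index_label="genotype")
    report.record("blups", path)

    # -- stage 4: ideotype scores -------------------------------------------
    logger.info("stage iroot: rank-sum ideotype scores at day %s", focus_day)
    ranks = score_categories(blups, DEFAULT_CATEGORIES)
    path = run_dir / "iroot_scores.csv"
    ranks.scores.to_csv(path, index_label="genotype")
    report.record("iroot_scores", path)
    report.ranks = ranks

    # -- stage 5: phenotype-based clusters ----------------------------------
    logger.info("stage pbc: phenotype clusters (complete linkage)")
    k_pheno = min(k_clusters, len(blups))
    pbc = phenotype_clusters(blups, k=k_pheno)
    report.assignments["PBC"] = pbc

    # -- stage 6: SNP clusters and FST ---------------------------------------
    logger.info("stage popgen: SNP simulation, GBC, FST")
    n_per = int(np.ceil(config.n_genotypes / config.snp_params.n_subpops))
    snps, snp_truth = simulate_snp_matrix(
        config.snp_params, n_per, seed=derive_seed(config.seed, "snps")
    )
    keep = np.arange(config.n_genotypes)
    genotype_ids = pheno_cfg.genotype_ids()
    snps.dosages = snps.dosages[keep]
    snps.genotype_ids = genotype_ids
    subpop = snp_truth.subpop_labels[keep]
    snps = filter_snps(snps)
    path = run_dir / "snps_filtered.csv"
    snps.to_csv(path)
    report.record("snps_filtered", path)

    dist = nei_distance(snps)
    gbc = genotype_clusters(dist, k=min(k_clusters, len(genotype_ids)))
    report.assignments["GBC"] = gbc
    (run_dir / "gbc_tree.nwk").write_text(gbc.newick)
    report.record("gbc_tree", run_dir / "gbc_tree.nwk")

    scores, fractions = snp_pca(snps)
    pd.DataFrame(
        {"PC": np.arange(1, 11), "variance_fraction": fractions[:10]}
    ).to_csv(run_dir / "pca_variance.csv", index=False)
    report.record("pca_variance", run_dir / "pca_variance.csv")

    fst = fst_matrix(snps, gbc)
    path = run_dir / "fst_matrix.csv"
    fst.to_csv(path)
    report.record("fst_matrix", path)
    report.fst = fst

    # -- stage 7: mean shapes and shape clusters -----------------------------
    logger.info("stage shape: renders, mean shapes, autoencoder, SBC")
    shape_rng = substream(config.seed, "shape-genotypes")
    silhouettes = []
    usable_genotypes = []
    for gid in genotype_ids:
        params = _genotype_growth_params(config.root_params, shape_rng)
        masks = []
        for rep in range(n_image_replicates):
            img, _ = simulate_root_system(
                params,
                day=focus_day,
                px_per_cm=config.px_per_cm,
                seed=derive_seed(config.seed, f"image:{gid}:{rep}"),
                meta={"genotype": gid, "replicate": rep, "day": focus_day},
            )
            try:
                masks.append(segment_root(img))
            except ValueError as err:
                logger.warning("segmentation failed for %s rep %s: %s",
                               gid, rep, err)
        if not masks:
            continue
        # the solid-blob dilation kernel is resolution-dependent: 50 px at
        # the reference 100 px/cm raster scale
        kernel = max(int(round(50.0 * config.px_per_cm / 100.0)), 5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            profile, _ = mean_shape_pipeline(masks, dilate_kernel_px=kernel)
        try:
            silhouettes.append(rasterize_shape(profile, 64))
            usable_genotypes.append(gid)
        except ValueError as err:
            logger.warning("rasterization failed for %s: %s", gid, err)

    sbc = None
    if len(silhouettes) >= 16:
        images = np.array(silhouettes, dtype=float)
        model, history = train_autoencoder(
            images,
            epochs=autoencoder_epochs,
            seed=derive_seed(config.seed, "autoencoder"),
        )
        latents = LatentFeatures(
            features=pd.DataFrame(
                model.encode(images),
                index=pd.Index(usable_genotypes, name="genotype"),
            ),
            fingerprint=model.fingerprint(),
        )
        latents.features.to_csv(run_dir / "shape_latents.csv")
        report.record("shape_latents", run_dir / "shape_latents.csv")
        z = (blups - blups.mean()) / blups.std(ddof=1)
        order_scores = z.mean(axis=1)
        sbc = shape_clusters(
            latents,
            k=min(k_clusters, len(usable_genotypes)),
            seed=derive_seed(config.seed, "sbc-kmeans"),
            order_scores=order_scores,
        )
        report.assignments["SBC"] = sbc
    else:
        logger.warning(
            "only %d usable mean shapes; shape clustering skipped",
            len(silhouettes),
        )

    # -- stage 8: cross-tabulations ------------------------------------------
    logger.info("stage crosstabs: Table-4-style summaries")
    metadata = _synthetic_metadata(
        genotype_ids, subpop, substream(config.seed, "metadata")
    )
    metadata.to_csv(run_dir / "metadata.csv")
    report.record("metadata", run_dir / "metadata.csv")
    assignments = [a for a in report.assignments.values()]
    crosstabs = cross_tabulate(
        assignments, ranks, metadata=metadata, trait_values=blups
    )
    flat = {}
    for method, bundle in crosstabs.items():
        for name, frame in bundle.items():
            flat[f"{method}.{name}"] = frame.to_dict()
    (run_dir / "crosstabs.json").write_text(
        json.dumps(flat, indent=2, sort_keys=True, default=str)
    )
    report.record("crosstabs", run_dir / "crosstabs.json")
    report.crosstabs = crosstabs

    # assignments as one CSV
    frame = pd.DataFrame(
        {name: a.labels for name, a in report.assignments.items()}
    )
    frame.to_csv(run_dir / "cluster_assignments.csv", index_label="genotype")
    report.record("cluster_assignments", run_dir / "cluster_assignments.csv")

    report.write_manifest()
    return report
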