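"""Phenotype statistics: outlier fences, mixed-model BLUPs, heritability,
Tukey HSD, collinearity, trait correlation, and phenotype-based clusters.

The central model is the one-observation random-effects model

    y_ik = mu + g_i + b_k + e_ik

with genotype effects g ~ N(0, sigma_g^2), block (growth chamber) effects
b ~ N(0, sigma_b^2), and residuals e ~ N(0, sigma_e^2); all factors random.
``RootTraitModel.fit()`` estimates the variance components by Henderson-III
quadratic forms (which coincide with REML under the balanced designs used
here), solves Henderson's mixed-model equations for the BLUPs, and reports
broad-sense heritability on an entry-mean basis,

    H^2 = sigma_g^2 / (sigma_g^2 + sigma_e^2 / r),

with r the number of replications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist, squareform

from .popgen import ClusterAssignment, cluster_labels

__all__ = [
    "VarianceComponents",
    "RootTraitModel",
    "RootTraitResults",
    "GroupComparison",
    "CollinearityReport",
    "THIRTEEN_TRAITS",
    "remove_outliers",
    "fit_mixed_model",
    "heritability",
    "tukey_hsd",
    "vif",
    "trait_correlation_cluster",
    "phenotype_clusters",
]

#: The 13 root traits used for ideotype categories and phenotype clusters.
THIRTEEN_TRAITS = (
    "TRL", "PRL", "WID", "CVA", "LRB", "VOL", "LRA", "SOL2", "LED",
    "RHZO", "TRL_GR", "TRLUpper", "Root_weight",
)


@dataclass
class VarianceComponents:
    """Estimated variance components of the random-effects model."""

    sigma_g2: float
    sigma_b2: float
    sigma_e2: float
    mu: float
    trait: str | None = None
    day: int | None = None

    def __post_init__(self):
        for name in ("sigma_g2", "sigma_b2", "sigma_e2"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


def heritability(vc: VarianceComponents, r: int) -> float:
    """Broad-sense heritability on an entry-mean basis, in [0, 1].

    Returns NaN when the denominator sigma_g^2 + sigma_e^2 / r is zero.
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    denom = vc.sigma_g2 + vc.sigma_e2 / r
    if denom <= 0:
        return np.nan
    return vc.sigma_g2 / denom


# ---------------------------------------------------------------------------
# outlier fences


def remove_outliers(
    table: pd.DataFrame,
    traits: list[str] | None = None,
    min_stratum: int = 4,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tukey boxplot outlier removal within each (trait, day) stratum.

    Observations outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR] are set to missing for
    that trait (the row is kept for the other traits).  Strata with fewer
    than ``min_stratum`` non-missing observations are skipped with a warning.

    Returns (filtered table, report) where the report lists the number
    removed per (trait, day).
    """
    if "day" not in table.columns:
        raise ValueError("table must carry a 'day' column")
    meta_cols = {"genotype", "replicate", "block", "day"}
    if traits is None:
        traits = [
            c
            for c in table.columns
            if c not in meta_cols and pd.api.types.is_numeric_dtype(table[c])
        ]
    out = table.copy()
    records = []
    for trait in traits:
        for day, idx in out.groupby("day").groups.items():
            values = out.loc[idx, trait]
            n_obs = values.notna().sum()
            if n_obs < min_stratum:
                if n_obs > 0:
                    warnings.warn(
                        f"stratum ({trait}, day {day}) has {n_obs} < "
                        f"{min_stratum} observations; fences skipped",
                        stacklevel=2,
                    )
                records.append({"trait": trait, "day": day, "removed": 0})
                continue
            q1, q3 = values.quantile([0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
            bad = (values < lo) | (values > hi)
            out.loc[values.index[bad.fillna(False)], trait] = np.nan
            records.append(
                {"trait": trait, "day": day, "removed": int(bad.sum())}
            )
    return out, pd.DataFrame.from_records(records)


# ---------------------------------------------------------------------------
# mixed model


class RootTraitModel:
    """Random-effects model for one trait at one imaging day.

    Parameters
    ----------
    table : long trait table with columns genotype, block (optional), day,
        and the trait column.
    trait : trait column to model.
    day : imaging day to subset; None uses all rows.

    Examples
    --------
    >>> results = RootTraitModel(table, "TRL", day=9).fit()
    >>> results.variance_components.sigma_g2  # doctest: +SKIP
    >>> results.heritability()                # doctest: +SKIP
    """

    def __init__(self, table: pd.DataFrame, trait: str, day: int | None = None):
        if trait not in table.columns:
            raise KeyError(f"trait column {trait!r} not in table")
        sub = table if day is None else table[table["day"] == day]
        sub = sub[sub[trait].notna()]
        if sub.empty:
            raise ValueError(f"no observations for trait {trait!r} at day {day}")
        counts = sub.groupby("genotype")[trait].size()
        if (counts >= 2).sum() < 2:
            raise ValueError("need >= 2 genotypes with >= 2 replicates")
        self.trait = trait
        self.day = day
        self.y = sub[trait].to_numpy(dtype=float)
        self.genotype = sub["genotype"].to_numpy()
        has_blocks = "block" in sub.columns and sub["block"].nunique() > 1
        self.block = sub["block"].to_numpy() if has_blocks else None
        self.genotype_ids = list(pd.unique(self.genotype))
        self.nobs = len(self.y)

    @classmethod
    def from_dataframe(
        cls, table: pd.DataFrame, trait: str, day: int | None = None
    ) -> "RootTraitModel":
        return cls(table, trait, day)

    def _dummies(self, values, categories) -> np.ndarray:
        index = {c: j for j, c in enumerate(categories)}
        Z = np.zeros((len(values), len(categories)))
        for i, v in enumerate(values):
            Z[i, index[v]] = 1.0
        return Z

    def fit(self) -> "RootTraitResults":
        """Estimate variance components and BLUPs.

        Henderson-III quadratic forms give (sigma_g^2, sigma_b^2, sigma_e^2);
        negative solutions are truncated at zero (boundary estimates).  BLUPs
        solve Henderson's mixed-model equations at the estimated components.
        """
        y = self.y
        n = self.nobs
        Zg = self._dummies(self.genotype, self.genotype_ids)
        ones = np.ones((n, 1))
        if self.block is not None:
            block_ids = list(pd.unique(self.block))
            Zb = self._dummies(self.block, block_ids)
        else:
            block_ids, Zb = [], None

        def proj_basis(M: np.ndarray) -> np.ndarray:
            q, r = np.linalg.qr(M)
            keep = np.abs(np.diag(r)) > 1e-10 * max(np.abs(np.diag(r)).max(), 1)
            return q[:, keep]

        Q_base = proj_basis(ones)
        Q_bg = proj_basis(
            np.hstack([ones, Zb, Zg]) if Zb is not None else np.hstack([ones, Zg])
        )
        sse = float(y @ y - (Q_bg.T @ y) @ (Q_bg.T @ y))
        df_e = n - Q_bg.shape[1]
        if df_e <= 0:
            raise ValueError("no residual degrees of freedom")
        sigma_e2 = max(sse / df_e, 0.0)

        def component(Z_target, Z_other):
            """SS and coefficient for one factor adjusted for the other."""
            cols = [ones] + ([Z_other] if Z_other is not None else [])
            Q_red = proj_basis(np.hstack(cols))
            ss = float(
                (Q_bg.T @ y) @ (Q_bg.T @ y) - (Q_red.T @ y) @ (Q_red.T @ y)
            )
            df = Q_bg.shape[1] - Q_red.shape[1]
            coef = float(
                np.sum((Q_bg.T @ Z_target) ** 2)
                - np.sum((Q_red.T @ Z_target) ** 2)
            )
            return ss, df, coef

        ss_g, df_g, c_g = component(Zg, Zb)
        sigma_g2 = max((ss_g - df_g * sigma_e2) / c_g, 0.0) if c_g > 0 else 0.0
        if Zb is not None:
            ss_b, df_b, c_b = component(Zb, Zg)
            sigma_b2 = (
                max((ss_b - df_b * sigma_e2) / c_b, 0.0) if c_b > 0 else 0.0
            )
        else:
            sigma_b2 = 0.0

        mu, g_blup, b_blup = self._solve_mme(
            Zg, Zb, sigma_g2, sigma_b2, sigma_e2
        )
        # genotype-effect F test (Table-2-style significance stars)
        ms_g = ss_g / df_g if df_g > 0 else np.nan
        f_stat = ms_g / sigma_e2 if sigma_e2 > 0 else np.inf
        p_value = (
            float(stats.f.sf(f_stat, df_g, df_e)) if np.isfinite(f_stat) else 0.0
        )
        vc = VarianceComponents(
            sigma_g2=sigma_g2,
            sigma_b2=sigma_b2,
            sigma_e2=sigma_e2,
            mu=mu,
            trait=self.trait,
            day=self.day,
        )
        blups = pd.Series(
            mu + g_blup, index=pd.Index(self.genotype_ids, name="genotype"),
            name=self.trait,
        )
        reps = pd.Series(self.genotype).value_counts()
        return RootTraitResults(
            model=self,
            variance_components=vc,
            blups=blups,
            block_blups=pd.Series(b_blup, index=block_ids)
            if block_ids
            else pd.Series(dtype=float),
            f_statistic=f_stat,
            f_pvalue=p_value,
            df=(df_g, df_e),
            n_replicates=int(round(reps.median())),
        )

    def _solve_mme(self, Zg, Zb, sigma_g2, sigma_b2, sigma_e2):
        """Henderson's mixed-model equations at fixed variance components."""
        n = self.nobs
        ones = np.ones((n, 1))
        blocks = [ones]
        penalties = [0.0]
        if sigma_g2 > 0:
            blocks.append(Zg)
            penalties.extend([sigma_e2 / sigma_g2] * Zg.shape[1])
        if Zb is not None and sigma_b2 > 0:
            blocks.append(Zb)
            penalties.extend([sigma_e2 / sigma_b2] * Zb.shape[1])
        W = np.hstack(blocks)
        A = W.T @ W + np.diag(penalties)
        # guard the fixed intercept against singularity when sigma_e2 = 0
        sol = np.linalg.solve(A + 1e-12 * np.eye(A.shape[0]), W.T @ self.y)
        mu = float(sol[0])
        pos = 1
        if sigma_g2 > 0:
            g = sol[pos : pos + Zg.shape[1]]
            pos += Zg.shape[1]
        else:
            g = np.zeros(Zg.shape[1])
        if Zb is not None and sigma_b2 > 0:
            b = sol[pos : pos + Zb.shape[1]]
        else:
            b = np.zeros(Zb.shape[1] if Zb is not None else 0)
        return mu, np.asarray(g), np.asarray(b)


@dataclass
class RootTraitResults:
    """Fitted variance components, BLUPs, and diagnostics for one trait/day."""

    model: RootTraitModel
    variance_components: VarianceComponents
    blups: pd.Series
    block_blups: pd.Series
    f_statistic: float
    f_pvalue: float
    df: tuple[int, int]
    n_replicates: int

    def heritability(self, r: int | None = None) -> float:
        """Entry-mean broad-sense heritability; r defaults to the median
        replicate count of the fitted data."""
        return heritability(self.variance_components, r or self.n_replicates)

    def summary(self) -> str:
        vc = self.variance_components
        lines = [
            "Root trait random-effects model",
            "=" * 46,
            f"trait: {vc.trait}    day: {vc.day}    n obs: {self.model.nobs}",
            f"genotypes: {len(self.blups)}    replications (median): "
            f"{self.n_replicates}",
            "-" * 46,
            f"mu        {vc.mu:12.5g}",
            f"sigma_g^2 {vc.sigma_g2:12.5g}",
            f"sigma_b^2 {vc.sigma_b2:12.5g}",
            f"sigma_e^2 {vc.sigma_e2:12.5g}",
            f"H^2 (entry-mean) {self.heritability():8.4f}",
            f"genotype F({self.df[0]}, {self.df[1]}) = "
            f"{self.f_statistic:.4g}, p = {self.f_pvalue:.3g}",
            "=" * 46,
        ]
        return "\n".join(lines)


def fit_mixed_model(
    table: pd.DataFrame, trait: str, day: int | None = None
) -> tuple[VarianceComponents, pd.Series]:
    """Convenience wrapper: fit the model and return (components, BLUPs)."""
    results = RootTraitModel(table, trait, day).fit()
    return results.variance_components, results.blups


# ---------------------------------------------------------------------------
# Tukey HSD


@dataclass
class GroupComparison:
    """Tukey honestly-significant-difference comparison of k groups."""

    q: float
    mse: float
    group_sizes: list[int]
    means: np.ndarray
    hsd: pd.DataFrame  # pairwise thresholds
    differences: pd.DataFrame  # pairwise |mean difference|
    significant: pd.DataFrame  # pairwise flags
    alpha: float


def tukey_hsd(
    groups: list[np.ndarray],
    alpha: float = 0.05,
    names: list[str] | None = None,
) -> GroupComparison:
    """Tukey's HSD over k groups.

    HSD for a pair (a, a') is q * sqrt(MSE/2 * (1/S_a + 1/S_a')) with q the
    studentized-range quantile at ``alpha`` for k groups and N - k error
    degrees of freedom; pairs whose absolute mean difference exceeds their
    HSD are flagged significant.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) < 2 for g in groups):
        raise ValueError("each group needs at least 2 observations")
    names = names or [f"group{i + 1}" for i in range(k)]
    sizes = [len(g) for g in groups]
    n_total = sum(sizes)
    means = np.array([g.mean() for g in groups])
    sse = sum(float(np.sum((g - g.mean()) ** 2)) for g in groups)
    df_e = n_total - k
    mse = sse / df_e
    q = float(stats.studentized_range.ppf(1.0 - alpha, k, df_e))

    hsd = pd.DataFrame(np.nan, index=names, columns=names)
    diffs = pd.DataFrame(np.nan, index=names, columns=names)
    sig = pd.DataFrame(False, index=names, columns=names)
    for a in range(k):
        for b in range(a + 1, k):
            threshold = q * np.sqrt(0.5 * mse * (1 / sizes[a] + 1 / sizes[b]))
            delta = abs(means[a] - means[b])
            hsd.iloc[a, b] = hsd.iloc[b, a] = threshold
            diffs.iloc[a, b] = diffs.iloc[b, a] = delta
            flag = bool(delta > threshold)
            sig.iloc[a, b] = sig.iloc[b, a] = flag
    return GroupComparison(
        q=q, mse=mse, group_sizes=sizes, means=means,
        hsd=hsd, differences=diffs, significant=sig, alpha=alpha,
    )


# ---------------------------------------------------------------------------
# collinearity


@dataclass
class CollinearityReport:
    """Per-predictor multiple-R^2, VIF = 1/(1 - R^2), and VIF > 5 flags."""

    r_squared: pd.Series
    vif: pd.Series
    flagged: pd.Series
    threshold: float = 5.0


def vif(predictors: pd.DataFrame | np.ndarray, threshold: float = 5.0) -> CollinearityReport:
    """Variance inflation factors of a predictor matrix.

    Each predictor is regressed (with intercept) on all the others; exact
    collinearity yields VIF = +inf.  Predictors with VIF above ``threshold``
    (default 5) are flagged.
    """
    X = pd.DataFrame(predictors)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 predictors")
    if X.shape[0] <= X.shape[1]:
        raise ValueError("need more rows than predictors")
    names = list(X.columns)
    values = X.to_numpy(dtype=float)
    r2s, vifs = [], []
    for j in range(values.shape[1]):
        yj = values[:, j]
        others = np.delete(values, j, axis=1)
        A = np.column_stack([np.ones(len(yj)), others])
        coef, *_ = np.linalg.lstsq(A, yj, rcond=None)
        resid = yj - A @ coef
        tss = float(np.sum((yj - yj.mean()) ** 2))
        if tss <= 0:
            r2 = 0.0
        else:
            r2 = 1.0 - float(np.sum(resid**2)) / tss
        r2 = min(max(r2, 0.0), 1.0)
        r2s.append(r2)
        vifs.append(np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2))
    r2_series = pd.Series(r2s, index=names, name="R_squared")
    vif_series = pd.Series(vifs, index=names, name="VIF")
    return CollinearityReport(
        r_squared=r2_series,
        vif=vif_series,
        flagged=vif_series > threshold,
        threshold=threshold,
    )


# ---------------------------------------------------------------------------
# trait correlation clustering and phenotype-based clusters


def trait_correlation_cluster(
    blups: pd.DataFrame, min_pairs: int = 10
) -> tuple[pd.DataFrame, np.ndarray, float]:
    """Pearson correlation of traits over genotypes + complete-linkage tree.

    Uses pairwise-complete observations; pairs with fewer than ``min_pairs``
    genotypes are reported missing.  Zero-variance traits are excluded with a
    warning.  Returns (correlation matrix, linkage, cumulative correlation
    intensity = sum of |r| over unique off-diagonal pairs).
    """
    if blups.shape[1] < 3 or blups.shape[0] < 3:
        raise ValueError("need at least 3 traits and 3 genotypes")
    variances = blups.var(axis=0, skipna=True)
    keep = variances > 0
    if not keep.all():
        dropped = list(variances.index[~keep])
        warnings.warn(
            f"zero-variance traits excluded from correlation: {dropped}",
            stacklevel=2,
        )
    data = blups.loc[:, keep]
    corr = data.corr(method="pearson", min_periods=min_pairs)
    iu = np.triu_indices(corr.shape[0], k=1)
    intensity = float(np.nansum(np.abs(corr.to_numpy()[iu])))
    dist = 1.0 - corr.fillna(0.0).to_numpy()
    np.fill_diagonal(dist, 0.0)
    Z = hierarchy.linkage(squareform(dist, checks=False), method="complete")
    return corr, Z, intensity


def phenotype_clusters(
    blups: pd.DataFrame,
    traits: tuple[str, ...] = THIRTEEN_TRAITS,
    k: int = 8,
) -> ClusterAssignment:
    """Phenotype-based clusters (PBC) from z-scored trait BLUPs.

    Hierarchical clustering (complete linkage, Euclidean) cut at ``k``;
    clusters are relabeled A.. by decreasing mean z-score across the traits,
    so high-performing genotypes constitute cluster A.  Raw (unflipped)
    z-scores are used for every trait, including SOL2 and LRA.
    """
    missing = [t for t in traits if t not in blups.columns]
    if missing:
        raise KeyError(f"missing trait columns: {missing}")
    X = blups.loc[:, list(traits)].dropna()
    n = len(X)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genotypes ({n})")
    z = (X - X.mean()) / X.std(ddof=1)
    z = z.fillna(0.0)
    Z = hierarchy.linkage(pdist(z.to_numpy()), method="complete")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    labels = pd.Series(flat, index=X.index, name="PBC")
    overall = z.mean(axis=1)
    order = (
        overall.groupby(labels).mean().sort_values(ascending=False).index.tolist()
    )
    alphabet = cluster_labels(len(order))
    mapping = {raw: alphabet[i] for i, raw in enumerate(order)}
    return ClusterAssignment(
        labels=labels.map(mapping), method="PBC", linkage=Z,
        meta={"traits": list(traits)},
    )
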