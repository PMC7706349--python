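"""SNP preprocessing, genetic distance, clustering, PCA, and Hudson FST.

The genotype panel is a genotype x marker dosage matrix (0/1/2 minor-allele
counts, NaN for missing calls).  Markers are filtered on minor allele
frequency, individuals are compared by allele sharing (1 - shared-allele
fraction as distance), and genotype-based clusters (GBC) come from Ward
linkage on that distance.  The number of clusters can be chosen from the
inflection of a BIC curve over k-means fits on leading principal components.
Between-group differentiation uses the Hudson FST estimator

    FST = [(p1-p2)^2 - p1(1-p1)/(n1-1) - p2(1-p2)/(n2-1)]
          / [p1(1-p2) + p2(1-p1)]

with the mean across markers taken as a ratio of averages.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

__all__ = [
    "SnpMatrix",
    "DistanceMatrix",
    "ClusterAssignment",
    "BicSelection",
    "filter_snps",
    "nei_distance",
    "genotype_clusters",
    "select_k_bic",
    "snp_pca",
    "hudson_fst",
    "fst_matrix",
    "cluster_labels",
]


def cluster_labels(k: int) -> list[str]:
    """Ordered cluster label alphabet: 'A'..'Z' then numeric."""
    if k <= 26:
        return list(string.ascii_uppercase[:k])
    return [str(i + 1) for i in range(k)]


@dataclass
class SnpMatrix:
    """Genotype x marker dosage matrix with missing-data support.

    ``dosages`` holds minor-allele counts in {0, 1, 2} with NaN for missing
    calls (heterozygote = 1).
    """

    dosages: np.ndarray
    genotype_ids: list[str]
    marker_ids: list[str]

    def __post_init__(self):
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (genotypes x markers)")
        n, m = self.dosages.shape
        self.genotype_ids = list(self.genotype_ids)
        self.marker_ids = list(self.marker_ids)
        if len(self.genotype_ids) != n or len(self.marker_ids) != m:
            raise ValueError("id lists inconsistent with dosage dimensions")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_genotypes(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def allele_frequency(self) -> np.ndarray:
        """Per-marker frequency of the counted allele from non-missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosages, axis=0) / 2.0

    def maf(self) -> np.ndarray:
        """Per-marker minor allele frequency, in [0, 0.5]."""
        p = self.allele_frequency()
        return np.minimum(p, 1.0 - p)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.genotype_ids, columns=self.marker_ids
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index_label="genotype")

    @classmethod
    def from_csv(cls, path) -> "SnpMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(
            dosages=df.to_numpy(dtype=float),
            genotype_ids=[str(g) for g in df.index],
            marker_ids=[str(m) for m in df.columns],
        )

    @classmethod
    def from_vcf(cls, path) -> "SnpMatrix":
        """Read biallelic sites from a VCF (GT field) as minor-allele dosages."""
        from cyvcf2 import VCF

        vcf = VCF(str(path))
        samples = list(vcf.samples)
        rows, ids = [], []
        for variant in vcf:
            if len(variant.ALT) != 1:
                continue  # biallelic sites only
            gts = variant.gt_types  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
            dose = np.where(gts == 0, 0.0,
                            np.where(gts == 1, 1.0,
                                     np.where(gts == 3, 2.0, np.nan)))
            rows.append(dose)
            ids.append(variant.ID or f"{variant.CHROM}:{variant.POS}")
        if not rows:
            raise ValueError("no biallelic sites found in VCF")
        return cls(
            dosages=np.array(rows).T, genotype_ids=samples, marker_ids=ids
        )


@dataclass
class DistanceMatrix:
    """Symmetric genotype x genotype distance matrix with zero diagonal."""

    values: np.ndarray
    ids: list[str]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        n = self.values.shape[0]
        if self.values.shape != (n, n):
            raise ValueError("distance matrix must be square")
        if not np.allclose(self.values, self.values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.values), 0.0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.nanmin(self.values) < -1e-12:
            raise ValueError("distances must be non-negative")
        self.ids = list(self.ids)
        if len(self.ids) != n:
            raise ValueError("ids inconsistent with matrix size")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


@dataclass
class ClusterAssignment:
    """Genotype -> ordered cluster label (A.., per method ordering rule)."""

    labels: pd.Series  # index = genotype id, values = labels
    method: str  # "GBC" | "PBC" | "SBC"
    linkage: np.ndarray | None = None
    newick: str | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.labels.isna().any():
            raise ValueError("every genotype must receive a label")

    @property
    def k(self) -> int:
        return self.labels.nunique()

    def members(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def relabeled(self, order: list[str]) -> "ClusterAssignment":
        """Return a copy with clusters renamed so ``order`` maps to A, B, ..."""
        alphabet = cluster_labels(len(order))
        mapping = {old: alphabet[i] for i, old in enumerate(order)}
        return ClusterAssignment(
            labels=self.labels.map(mapping),
            method=self.method,
            linkage=self.linkage,
            newick=self.newick,
            meta=dict(self.meta),
        )


def filter_snps(snps: SnpMatrix, maf_min: float = 0.05) -> SnpMatrix:
    """Drop monomorphic markers and markers with MAF below ``maf_min``.

    MAF is computed from non-missing dosages; markers at exactly ``maf_min``
    are retained.
    """
    maf = snps.maf()
    keep = (maf >= maf_min) & (maf > 0.0) & ~np.isnan(maf)
    if not keep.any():
        raise ValueError("all markers removed by MAF/monomorphism filter")
    return SnpMatrix(
        dosages=snps.dosages[:, keep],
        genotype_ids=snps.genotype_ids,
        marker_ids=[m for m, k in zip(snps.marker_ids, keep) if k],
    )


def nei_distance(snps: SnpMatrix) -> DistanceMatrix:
    """Allele-sharing genetic distance between individual genotypes.

    Similarity between two genotypes is the mean, over markers where both are
    called, of the shared-allele fraction (2 - |dose_i - dose_j|) / 2; the
    distance is one minus that similarity.  Not guaranteed to be metric.
    """
    X = snps.dosages
    n = snps.n_genotypes
    if n < 2:
        raise ValueError("need at least 2 genotypes")
    D = np.zeros((n, n))
    called = ~np.isnan(X)
    for i in range(n - 1):
        diff = np.abs(X[i] - X[i + 1:])  # NaN where either is missing
        overlap = (called[i] & called[i + 1:]).sum(axis=1)
        if (overlap == 0).any():
            bad = i + 1 + int(np.argmax(overlap == 0))
            raise ValueError(
                f"genotypes {snps.genotype_ids[i]!r} and "
                f"{snps.genotype_ids[bad]!r} share no called markers"
            )
        sim = np.nanmean((2.0 - diff) / 2.0, axis=1)
        D[i, i + 1:] = 1.0 - sim
        D[i + 1:, i] = D[i, i + 1:]
    return DistanceMatrix(values=np.maximum(D, 0.0), ids=snps.genotype_ids)


def _tree_to_newick(linkage_matrix: np.ndarray, leaf_names: list[str]) -> str:
    tree = hierarchy.to_tree(linkage_matrix)

    def recurse(node, parent_height):
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{leaf_names[node.id]}:{length:.6g}"
        left = recurse(node.left, node.dist)
        right = recurse(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return recurse(tree, tree.dist) + ";"


def genotype_clusters(dist: DistanceMatrix, k: int = 8) -> ClusterAssignment:
    """Ward-linkage clusters on a genetic distance matrix (GBC).

    Labels A.. are assigned in dendrogram leaf order (left to right); the tree
    is also exported as newick.
    """
    n = len(dist.ids)
    if k > n:
        raise ValueError(f"k={k} exceeds the number of genotypes ({n})")
    Z = hierarchy.linkage(dist.condensed(), method="ward")
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    leaf_order = hierarchy.leaves_list(Z)
    seen: list[int] = []
    for leaf in leaf_order:
        if flat[leaf] not in seen:
            seen.append(flat[leaf])
    alphabet = cluster_labels(len(seen))
    mapping = {raw: alphabet[i] for i, raw in enumerate(seen)}
    labels = pd.Series(
        [mapping[c] for c in flat], index=dist.ids, name="GBC"
    )
    return ClusterAssignment(
        labels=labels,
        method="GBC",
        linkage=Z,
        newick=_tree_to_newick(Z, dist.ids),
    )


@dataclass
class BicSelection:
    """Selected cluster count with the full BIC curve (index k = 1..k_max)."""

    k: int
    bic: np.ndarray
    flat: bool = False


def _spherical_bic(X: np.ndarray, km: KMeans) -> float:
    """x-means style BIC (higher is better) for a spherical Gaussian mixture."""
    n, d = X.shape
    k = km.n_clusters
    rss = float(km.inertia_)
    if n <= k:
        return -np.inf
    sigma2 = rss / (d * (n - k))
    sigma2 = max(sigma2, 1e-300)
    counts = np.bincount(km.labels_, minlength=k).astype(float)
    counts = counts[counts > 0]
    loglik = (
        float(np.sum(counts * np.log(counts / n)))
        - 0.5 * n * d * np.log(2.0 * np.pi * sigma2)
        - 0.5 * d * (n - k)
    )
    n_params = (k - 1) + k * d + 1
    return loglik - 0.5 * n_params * np.log(n)


def select_k_bic(
    snps_or_scores: "SnpMatrix | np.ndarray",
    k_max: int,
    *,
    n_components: int = 10,
    seed: int = 0,
) -> BicSelection:
    """Choose the cluster count from the inflection of a k-means BIC curve.

    k-means is run for k = 1..k_max (on leading PCA scores when a SnpMatrix is
    given); the selected k maximizes the negative second difference of the BIC
    curve — the point where improvement stops.  Degenerate (all-equal) data
    returns 1, as does a curve whose maximum sits at k = 1.
    """
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if isinstance(snps_or_scores, SnpMatrix):
        scores, _ = snp_pca(snps_or_scores)
        X = scores[:, : min(n_components, scores.shape[1])]
    else:
        X = np.asarray(snps_or_scores, dtype=float)
    if np.allclose(X, X[0]):
        return BicSelection(k=1, bic=np.full(k_max, np.nan), flat=True)

    bic = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(X)
        bic[k - 1] = _spherical_bic(X, km)

    span = np.nanmax(bic) - np.nanmin(bic)
    flat = span < 0.05 * max(abs(np.nanmedian(bic)), 1.0)
    if int(np.nanargmax(bic)) == 0:
        return BicSelection(k=1, bic=bic, flat=flat)
    if k_max == 2:
        return BicSelection(k=2, bic=bic, flat=flat)
    # second difference exists for interior k = 2..k_max-1
    d2 = bic[2:] - 2.0 * bic[1:-1] + bic[:-2]
    k_sel = int(np.argmin(d2)) + 2
    return BicSelection(k=k_sel, bic=bic, flat=flat)


def snp_pca(snps: SnpMatrix) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the dosage matrix: mean-impute, center columns, eigendecompose.

    Returns (scores, variance_fractions); fractions sum to 1 over all
    components.  Columns are centered but not scaled to unit variance.
    """
    if snps.n_genotypes < 2 or snps.n_markers < 2:
        raise ValueError("need at least 2 genotypes and 2 markers")
    X = snps.dosages.copy()
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
    nan_idx = np.where(np.isnan(X))
    X[nan_idx] = col_mean[nan_idx[1]]
    X = X - X.mean(axis=0)
    total_var = float(np.sum(X**2))
    if total_var <= 0.0:
        raise ValueError("zero total variance after centering")
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    scores = U * s
    fractions = s**2 / total_var
    return scores, fractions


def _group_frequencies(
    X: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker allele frequency and non-missing sample count."""
    called = ~np.isnan(X)
    n = called.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore"):
        p = np.nansum(X, axis=0) / (2.0 * np.where(n > 0, n, np.nan))
    return p, n


def hudson_fst(
    snps: SnpMatrix,
    group_a: list[str] | np.ndarray,
    group_b: list[str] | np.ndarray,
) -> tuple[np.ndarray, float]:
    """Hudson FST between two groups of genotypes.

    Returns (per-marker FST, mean FST), where the mean is the ratio of the
    mean numerator to the mean denominator across markers (robust to
    near-zero denominators).  Markers with a zero denominator are excluded
    from the per-marker vector and from both averages.
    """
    index = {g: i for i, g in enumerate(snps.genotype_ids)}
    try:
        ia = [index[g] for g in group_a]
        ib = [index[g] for g in group_b]
    except KeyError as err:
        raise KeyError(f"unknown genotype id {err.args[0]!r}") from err
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("each group needs at least 2 genotypes (n-1 division)")

    p1, n1 = _group_frequencies(snps.dosages[ia])
    p2, n2 = _group_frequencies(snps.dosages[ib])
    ok = (n1 >= 2) & (n2 >= 2) & ~np.isnan(p1) & ~np.isnan(p2)

    num = (
        (p1 - p2) ** 2
        - p1 * (1.0 - p1) / (n1 - 1.0)
        - p2 * (1.0 - p2) / (n2 - 1.0)
    )
    den = p1 * (1.0 - p2) + p2 * (1.0 - p1)
    ok &= den > 0.0
    if not ok.any():
        raise ValueError("no marker with a non-zero FST denominator")
    per_marker = num[ok] / den[ok]
    mean_fst = float(np.mean(num[ok]) / np.mean(den[ok]))
    return per_marker, mean_fst


def fst_matrix(snps: SnpMatrix, assignment: ClusterAssignment) -> pd.DataFrame:
    """Symmetric matrix of pairwise mean Hudson FST between clusters.

    Cluster pairs where either side has fewer than 2 genotypes are NaN.
    """
    labels = sorted(assignment.labels.unique())
    out = pd.DataFrame(0.0, index=labels, columns=labels)
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            ga, gb = assignment.members(la), assignment.members(lb)
            if len(ga) < 2 or len(gb) < 2:
                value = np.nan
            else:
                _, value = hudson_fst(snps, ga, gb)
            out.loc[la, lb] = value
            out.loc[lb, la] = value
    return out
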