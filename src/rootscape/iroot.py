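"""Informative-root (iRoot) ideotype scoring.

Genotypes are ranked per trait (rank 1 = most favorable) with a per-trait
favorability direction, and each ideotype category scores a genotype by the
sum of its ranks over the category's constituent traits; lower rank sums are
better.  Five categories are shipped:

* nutrient foraging — wide, fast-growing, top-heavy root systems
  (WID+, TRL_GR+, TRLUpper+);
* drought tolerant — "steep, deep, and cheap": long primary root, fast
  growth, steep lateral angles, low solidity (PRL+, LRA-, SOL2-, TRL_GR+);
* umbrella — long taproot with wide, shallow lateral spread
  (PRL+, WID+, CVA+, LRA+, LED+);
* beard — dense, narrow, uniformly distributed fibrous systems
  (TRL+, WID-, LRB+, LRA-, SOL2-, LED-);
* maximum — maximal overall root growth
  (TRL+, PRL+, WID+, CVA+, LRB+, VOL+, RHZO+, Root_weight+).

Scoring is restricted to the 9-days-after-germination BLUPs in the study
design; the functions themselves are day-agnostic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import yaml

from .popgen import ClusterAssignment

__all__ = [
    "IRootCategory",
    "RankTable",
    "DEFAULT_CATEGORIES",
    "rank_trait",
    "score_categories",
    "cross_tabulate",
    "load_categories",
    "save_categories",
]

HIGHER = "higher_favorable"
LOWER = "lower_favorable"


@dataclass(frozen=True)
class IRootCategory:
    """An ideotype: a named set of (trait, favorability direction) pairs."""

    name: str
    traits: tuple[tuple[str, str], ...]

    def __post_init__(self):
        for trait, direction in self.traits:
            if direction not in (HIGHER, LOWER):
                raise ValueError(
                    f"{self.name}: direction for {trait} must be "
                    f"{HIGHER!r} or {LOWER!r}"
                )

    @property
    def trait_names(self) -> list[str]:
        return [t for t, _ in self.traits]


DEFAULT_CATEGORIES: tuple[IRootCategory, ...] = (
    IRootCategory(
        "nutrient_foraging",
        (("WID", HIGHER), ("TRL_GR", HIGHER), ("TRLUpper", HIGHER)),
    ),
    IRootCategory(
        "drought_tolerant",
        (("PRL", HIGHER), ("LRA", LOWER), ("SOL2", LOWER), ("TRL_GR", HIGHER)),
    ),
    IRootCategory(
        "umbrella",
        (
            ("PRL", HIGHER),
            ("WID", HIGHER),
            ("CVA", HIGHER),
            ("LRA", HIGHER),
            ("LED", HIGHER),
        ),
    ),
    IRootCategory(
        "beard",
        (
            ("TRL", HIGHER),
            ("WID", LOWER),
            ("LRB", HIGHER),
            ("LRA", LOWER),
            ("SOL2", LOWER),
            ("LED", LOWER),
        ),
    ),
    IRootCategory(
        "maximum",
        (
            ("TRL", HIGHER),
            ("PRL", HIGHER),
            ("WID", HIGHER),
            ("CVA", HIGHER),
            ("LRB", HIGHER),
            ("VOL", HIGHER),
            ("RHZO", HIGHER),
            ("Root_weight", HIGHER),
        ),
    ),
)


@dataclass
class RankTable:
    """Per-trait ranks, per-category rank sums, and per-category ranks."""

    trait_ranks: pd.DataFrame  # genotype x trait (1 = best)
    scores: pd.DataFrame  # genotype x category rank sums
    category_ranks: pd.DataFrame  # genotype x category rank (1 = best)

    def top(self, category: str, n: int = 10) -> list[str]:
        """The n top-ranked genotypes for one category."""
        return list(self.category_ranks[category].nsmallest(n).index)


def rank_trait(values: pd.Series, direction: str = HIGHER) -> pd.Series:
    """Direction-aware ranks: 1 = most favorable; ties get average ranks.

    ``higher_favorable`` ranks the largest value 1; ``lower_favorable`` the
    smallest.  Missing values rank last (after every non-missing value).
    """
    if direction not in (HIGHER, LOWER):
        raise ValueError(f"unknown direction {direction!r}")
    values = pd.Series(values, dtype=float)
    if values.notna().sum() < 2:
        raise ValueError("need at least 2 non-missing values to rank")
    ascending = direction == LOWER
    ranks = values.rank(ascending=ascending, method="average", na_option="bottom")
    return ranks


def score_categories(
    blups: pd.DataFrame,
    categories: tuple[IRootCategory, ...] = DEFAULT_CATEGORIES,
) -> RankTable:
    """Score every genotype against every ideotype category.

    ``blups`` is a genotype x trait table (one imaging day).  For each
    category the score is the sum of the direction-aware trait ranks; the
    category rank orders genotypes by ascending score (ties averaged).

    Raises
    ------
    KeyError
        If a category's constituent trait column is absent.
    """
    involved: list[str] = []
    for cat in categories:
        for trait, _ in cat.traits:
            if trait not in blups.columns:
                raise KeyError(
                    f"category {cat.name!r} needs missing trait column "
                    f"{trait!r}"
                )
            if trait not in involved:
                involved.append(trait)

    rank_cache: dict[tuple[str, str], pd.Series] = {}

    def ranks_for(trait: str, direction: str) -> pd.Series:
        key = (trait, direction)
        if key not in rank_cache:
            rank_cache[key] = rank_trait(blups[trait], direction)
        return rank_cache[key]

    # the trait-rank matrix uses one uniform convention (1 = numerically
    # highest); category scores apply each category's own direction
    trait_ranks = pd.DataFrame(
        {t: ranks_for(t, HIGHER) for t in involved}, index=blups.index
    )
    scores = pd.DataFrame(index=blups.index)
    for cat in categories:
        scores[cat.name] = sum(ranks_for(t, d) for t, d in cat.traits)
    category_ranks = scores.rank(ascending=True, method="average")
    return RankTable(
        trait_ranks=trait_ranks, scores=scores, category_ranks=category_ranks
    )


def cross_tabulate(
    assignments: list[ClusterAssignment],
    ranks: RankTable,
    metadata: pd.DataFrame | None = None,
    trait_values: pd.DataFrame | None = None,
    pbc_method: str = "PBC",
) -> dict[str, dict[str, pd.DataFrame]]:
    """Summary cross-tabulations per clustering (counts, means, mean ranks).

    For each assignment (GBC / PBC / SBC): counts of genotypes by each
    categorical metadata column, per-cluster means of the trait columns, the
    per-cluster mean iRoot rank for every category, and — when a PBC
    assignment is among ``assignments`` — the mean PBC value per cluster
    (PBC A -> 1, ..., H -> 8) and per metadata country.

    Raises
    ------
    KeyError
        If an assignment covers genotypes absent from the rank table.
    """
    genotypes = set(ranks.category_ranks.index)
    for assignment in assignments:
        missing = sorted(set(assignment.labels.index) - genotypes)
        if missing:
            raise KeyError(
                f"{assignment.method}: genotypes missing from ranks: "
                f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
            )

    pbc = next((a for a in assignments if a.method == pbc_method), None)
    pbc_numeric = None
    if pbc is not None:
        order = sorted(pbc.labels.unique())
        pbc_numeric = pbc.labels.map({lab: i + 1 for i, lab in enumerate(order)})

    out: dict[str, dict[str, pd.DataFrame]] = {}
    for assignment in assignments:
        labels = assignment.labels
        bundle: dict[str, pd.DataFrame] = {}
        if metadata is not None:
            meta = metadata.reindex(labels.index)
            for col in meta.columns:
                bundle[f"counts_{col}"] = (
                    pd.crosstab(meta[col], labels).sort_index(axis=1)
                )
        if trait_values is not None:
            bundle["trait_means"] = (
                trait_values.reindex(labels.index).groupby(labels).mean()
            )
        bundle["iroot_mean_rank"] = (
            ranks.category_ranks.reindex(labels.index).groupby(labels).mean()
        )
        if pbc_numeric is not None:
            bundle["pbc_mean"] = (
                pbc_numeric.reindex(labels.index)
                .groupby(labels)
                .mean()
                .to_frame("PBC_mean")
            )
        out[assignment.method] = bundle

    if pbc_numeric is not None and metadata is not None and "country" in metadata:
        out["by_country"] = {
            "pbc_mean": pbc_numeric.groupby(
                metadata.reindex(pbc_numeric.index)["country"]
            )
            .mean()
            .to_frame("PBC_mean")
        }
    return out


def save_categories(categories: tuple[IRootCategory, ...], path) -> None:
    """Write category definitions as editable YAML."""
    payload = {
        cat.name: {trait: direction for trait, direction in cat.traits}
        for cat in categories
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def load_categories(path) -> tuple[IRootCategory, ...]:
    """Load category definitions from YAML."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return tuple(
        IRootCategory(name, tuple(traits.items()))
        for name, traits in payload.items()
    )
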