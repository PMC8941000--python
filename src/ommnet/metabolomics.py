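"""Substrate depletion/production profiling from untargeted metabolomics.

Feature intensities from spent media are compared against fresh medium by a
per-feature two-sample t-test (Welch by default). A feature is *depleted* by
a strain when its mean intensity drops significantly below fresh medium and
*produced* when it rises. Depleted sets are then compared between strains by
asymmetric percentage overlap,

    percent[i][j] = 100 * |D_i & D_j| / |D_i|,

the fraction of strain i's depleted set also depleted by strain j, and
aggregated per phylum into exclusive Euler-diagram region counts.

No multiple-testing correction is applied by default; Benjamini-Hochberg is
available via ``correction="bh"`` but changes the calls relative to raw
per-feature p < alpha thresholds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .growth import CorrelationResult, InhibitionMatrix, correlate

logger = logging.getLogger(__name__)

__all__ = [
    "FeatureTable",
    "DepletionProfile",
    "OverlapMatrix",
    "SetPartition",
    "call_feature_changes",
    "fraction_altered",
    "overlap_matrix",
    "phylum_partition",
    "shared_count_vs_distance",
    "overlap_vs_inhibition",
    "round_half_up",
    "DepletionModel",
    "DepletionResults",
]


def round_half_up(x: float, decimals: int = 1) -> float:
    """Round with ties away from zero (report convention, e.g. 8.9 / 25.8)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


class FeatureTable:
    """Feature x sample intensity matrix with per-sample condition metadata.

    Parameters
    ----------
    intensities : DataFrame
        Rows = feature ids, columns = sample ids, non-negative intensities.
        Features from both ionization modes live in one universe; ids should
        be mode-prefixed upstream if modes were measured separately.
    sample_meta : DataFrame
        Indexed by sample id with columns ``condition`` (fresh-medium label
        or strain id), ``replicate`` and optionally ``mode``.
    """

    def __init__(
        self,
        intensities: pd.DataFrame,
        sample_meta: pd.DataFrame,
        fresh_label: str = "fresh",
    ):
        if intensities.index.has_duplicates:
            raise ValueError("duplicate feature ids in intensity matrix")
        missing = set(intensities.columns) - set(sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        if (intensities.values < 0).any():
            raise ValueError("intensities must be non-negative")
        self.intensities = intensities
        self.sample_meta = sample_meta.loc[list(intensities.columns)]
        self.fresh_label = fresh_label
        counts = self.sample_meta.groupby("condition").size()
        thin = counts[counts < 2]
        if not thin.empty:
            raise ValueError(
                f"conditions with fewer than 2 replicates: {list(thin.index)}"
            )
        if fresh_label not in counts.index:
            raise ValueError(f"no samples for fresh-medium condition {fresh_label!r}")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.intensities.index)

    @property
    def strains(self) -> list[str]:
        return sorted(
            c for c in self.sample_meta["condition"].unique() if c != self.fresh_label
        )

    def condition_matrix(self, condition: str) -> np.ndarray:
        cols = self.sample_meta.index[self.sample_meta["condition"] == condition]
        return self.intensities[list(cols)].to_numpy(dtype=float)


@dataclass(frozen=True)
class DepletionProfile:
    """Significantly depleted/produced feature sets for one strain."""

    strain_id: str
    depleted: frozenset
    produced: frozenset
    stats: pd.DataFrame  # per feature: mean_fresh, mean_strain, p_value


@dataclass(frozen=True)
class SetPartition:
    """Exclusive Euler-region sizes over phylum-level unions of depleted sets."""

    groups: dict
    region_sizes: dict

    @property
    def union_size(self) -> int:
        return sum(self.region_sizes.values())


def call_feature_changes(
    table: FeatureTable,
    alpha: float = 0.05,
    equal_var: bool = False,
    log_transform: bool = False,
    correction: str | None = None,
) -> list[DepletionProfile]:
    """Per-strain depleted/produced feature calls versus fresh medium.

    Each feature is tested with a two-sided two-sample t-test of the strain
    replicates against the fresh-medium replicates (Welch unless
    ``equal_var=True``). Zero-variance features (identical in both groups)
    are skipped with a warning.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    fresh = table.condition_matrix(table.fresh_label)
    if log_transform:
        fresh = np.log10(fresh + 1.0)
    profiles = []
    feature_index = pd.Index(table.feature_ids)
    for strain in table.strains:
        mat = table.condition_matrix(strain)
        if log_transform:
            mat = np.log10(mat + 1.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t, p = stats.ttest_ind(mat, fresh, axis=1, equal_var=equal_var)
        degenerate = ~np.isfinite(p)
        if degenerate.any():
            logger.warning(
                "%d zero-variance features skipped for strain %s",
                int(degenerate.sum()),
                strain,
            )
        p_use = p.copy()
        if correction == "bh":
            ok = np.isfinite(p)
            p_use[ok] = stats.false_discovery_control(p[ok], method="bh")
        elif correction is not None:
            raise ValueError(f"unknown correction {correction!r}")
        mean_fresh = fresh.mean(axis=1)
        mean_strain = mat.mean(axis=1)
        sig = np.isfinite(p_use) & (p_use < alpha)
        depleted = feature_index[sig & (mean_strain < mean_fresh)]
        produced = feature_index[sig & (mean_strain > mean_fresh)]
        profiles.append(
            DepletionProfile(
                strain_id=strain,
                depleted=frozenset(depleted),
                produced=frozenset(produced),
                stats=pd.DataFrame(
                    {
                        "mean_fresh": mean_fresh,
                        "mean_strain": mean_strain,
                        "p_value": p,
                    },
                    index=feature_index,
                ),
            )
        )
    return profiles


def fraction_altered(
    profiles: Sequence[DepletionProfile], total_features: int
) -> float:
    """Percentage of the feature universe altered by at least one strain.

    Counted on the union of depleted and produced sets over all strains,
    reported at two decimals.
    """
    if total_features <= 0:
        raise ValueError("total_features must be positive")
    union: set = set()
    for p in profiles:
        union |= p.depleted | p.produced
    if len(union) > total_features:
        raise ValueError("altered-feature union exceeds the feature universe")
    return round_half_up(100.0 * len(union) / total_features, 2)


class OverlapMatrix:
    """Asymmetric depleted-set overlaps: counts and row-relative percentages."""

    def __init__(self, counts: pd.DataFrame, percent: pd.DataFrame, set_sizes: pd.Series):
        self.counts = counts
        self.percent = percent
        self.set_sizes = set_sizes
        self.strains = list(counts.index)

    def percent_rounded(self, decimals: int = 1) -> pd.DataFrame:
        return self.percent.map(lambda v: round_half_up(v, decimals))

    def pair_counts(self) -> pd.Series:
        """Shared-feature counts for the unordered strain pairs."""
        out = {}
        for a, b in itertools.combinations(self.strains, 2):
            out[(a, b)] = int(self.counts.loc[a, b])
        return pd.Series(out)


def overlap_matrix(profiles: Sequence[DepletionProfile]) -> OverlapMatrix:
    """Pairwise intersections of depleted sets, relative to each row strain."""
    strains = [p.strain_id for p in profiles]
    sets = {p.strain_id: p.depleted for p in profiles}
    counts = pd.DataFrame(0, index=strains, columns=strains, dtype=int)
    percent = pd.DataFrame(0.0, index=strains, columns=strains, dtype=float)
    for a in strains:
        if not sets[a]:
            logger.warning("strain %s has an empty depleted set; percent row is 0", a)
        for b in strains:
            shared = len(sets[a] & sets[b])
            counts.loc[a, b] = shared
            percent.loc[a, b] = 100.0 * shared / len(sets[a]) if sets[a] else 0.0
    sizes = pd.Series({s: len(sets[s]) for s in strains})
    return OverlapMatrix(counts, percent, sizes)


def phylum_partition(
    profiles: Sequence[DepletionProfile], taxonomy: Mapping[str, str]
) -> SetPartition:
    """Exclusive region sizes of phylum-level depleted-set unions.

    Every feature in the overall union is assigned to the exact subset of
    phyla whose member strains deplete it; region sizes therefore sum to the
    union size.
    """
    unlabeled = [p.strain_id for p in profiles if p.strain_id not in taxonomy]
    if unlabeled:
        raise ValueError(f"strains without phylum labels: {unlabeled}")
    groups: dict[str, set] = {}
    for p in profiles:
        groups.setdefault(taxonomy[p.strain_id], set()).update(p.depleted)
    phyla = sorted(groups)
    union = set().union(*groups.values()) if groups else set()
    region_sizes: dict[frozenset, int] = {}
    for feature in union:
        members = frozenset(ph for ph in phyla if feature in groups[ph])
        region_sizes[members] = region_sizes.get(members, 0) + 1
    return SetPartition(groups={ph: frozenset(g) for ph, g in groups.items()},
                        region_sizes=region_sizes)


def shared_count_vs_distance(
    overlap: OverlapMatrix, distances: pd.DataFrame, method: str = "pearson"
) -> CorrelationResult:
    """Correlate shared depleted-feature counts with patristic distances.

    Uses the S*(S-1)/2 unordered strain pairs; a negative coefficient means
    phylogenetically close strains share more substrates.
    """
    strains = [s for s in overlap.strains if s in distances.index]
    if set(strains) != set(overlap.strains):
        missing = set(overlap.strains) - set(strains)
        raise ValueError(f"strains missing from the distance matrix: {sorted(missing)}")
    xs, ys = [], []
    for a, b in itertools.combinations(strains, 2):
        xs.append(float(distances.loc[a, b]))
        ys.append(float(overlap.counts.loc[a, b]))
    return correlate(xs, ys, method=method)


def overlap_vs_inhibition(
    overlap: OverlapMatrix, inhibition: InhibitionMatrix, method: str = "pearson"
) -> CorrelationResult:
    """Correlate substrate overlap with growth inhibition in the matching SM.

    For every ordered (producer, consumer) pair with producer != consumer the
    x value is the consumer-relative overlap with the producer's depleted set
    and the y value is the consumer's d_AUC in the producer's SM. A negative
    coefficient means larger overlap, stronger inhibition.
    """
    strains = [s for s in overlap.strains if s in inhibition.d_auc.index]
    if set(strains) != set(overlap.strains):
        missing = set(overlap.strains) - set(strains)
        raise ValueError(f"strains missing from the inhibition matrix: {sorted(missing)}")
    xs, ys = [], []
    for producer in strains:
        for consumer in strains:
            if producer == consumer:
                continue
            xs.append(float(overlap.percent.loc[consumer, producer]))
            ys.append(float(inhibition.d_auc.loc[producer, consumer]))
    return correlate(xs, ys, method=method)


class DepletionModel:
    """Depletion-profile analysis of a metabolomic feature table."""

    def __init__(self, table: FeatureTable):
        self.table = table

    @classmethod
    def from_dataframes(
        cls,
        intensities: pd.DataFrame,
        sample_meta: pd.DataFrame,
        fresh_label: str = "fresh",
    ) -> "DepletionModel":
        return cls(FeatureTable(intensities, sample_meta, fresh_label=fresh_label))

    def fit(
        self,
        alpha: float = 0.05,
        equal_var: bool = False,
        log_transform: bool = False,
        correction: str | None = None,
    ) -> "DepletionResults":
        profiles = call_feature_changes(
            self.table,
            alpha=alpha,
            equal_var=equal_var,
            log_transform=log_transform,
            correction=correction,
        )
        return DepletionResults(self, profiles, alpha)


class DepletionResults:
    def __init__(
        self, model: DepletionModel, profiles: list[DepletionProfile], alpha: float
    ):
        self.model = model
        self.profiles = profiles
        self.alpha = alpha
        self.by_strain = {p.strain_id: p for p in profiles}

    def fraction_altered(self, total_features: int | None = None) -> float:
        total = total_features or len(self.model.table.feature_ids)
        return fraction_altered(self.profiles, total)

    def overlap_matrix(self) -> OverlapMatrix:
        return overlap_matrix(self.profiles)

    def phylum_partition(self, taxonomy: Mapping[str, str]) -> SetPartition:
        return phylum_partition(self.profiles, taxonomy)

    def depleted_counts(self) -> pd.Series:
        return pd.Series({p.strain_id: len(p.depleted) for p in self.profiles})

    def summary(self) -> str:
        total = len(self.model.table.feature_ids)
        lines = [
            "Metabolomic depletion profiles",
            f"  features: {total}, strains: {len(self.profiles)}, alpha: {self.alpha}",
            f"  altered by >=1 strain: {self.fraction_altered():.2f}%",
            "",
            "  strain        depleted  produced",
        ]
        for p in self.profiles:
            lines.append(f"  {p.strain_id:<12}  {len(p.depleted):>7}  {len(p.produced):>8}")
        return "\n".join(lines)
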