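"""Growth-curve phenotyping and spent-media inhibition analysis.

Monocultures of a defined community are grown in fresh medium and in the
sterile spent medium (SM) of every other member. Each OD600 time series is
summarised into an area under the curve (AUC, OD*h), a maximum specific
growth rate (h^-1, sliding-window log-linear fit) and a rate class. Growth
in a producer's SM relative to fresh medium yields the normalized
inhibition factor

    d_AUC = (AUC_SM - AUC_fresh) / AUC_fresh

computed from replicate means; d_AUC < -0.5 is called strong inhibition.
Supernatant pH is tracked as a telescoping pair of deltas
(pH change after growth in fresh medium, and the further change after a
second strain grows in the SM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

STRONG_INHIBITION_THRESHOLD = -0.5
FAST_RATE_THRESHOLD = 1.5
INTERMEDIATE_RATE_THRESHOLD = 1.0

__all__ = [
    "GrowthCurve",
    "GrowthSummary",
    "InhibitionRecord",
    "InhibitionMatrix",
    "PhRecord",
    "CorrelationResult",
    "blank_correct",
    "compute_auc",
    "estimate_growth_rate",
    "classify_growth_rate",
    "summarize_curve",
    "compute_inhibition_factor",
    "build_inhibition_matrix",
    "compute_delta_ph",
    "correlate",
    "SpentMediaModel",
    "SpentMediaResults",
]


@dataclass(frozen=True)
class GrowthCurve:
    """A single replicate OD600 time series for one strain in one medium.

    ``medium_id`` is either the fresh-medium label (e.g. ``"AF"``) or the
    identifier of the strain whose spent medium was used.
    """

    strain_id: str
    medium_id: str
    replicate: int
    times: np.ndarray
    od: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        od = np.asarray(self.od, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "od", od)
        if times.ndim != 1 or od.ndim != 1 or len(times) != len(od):
            raise ValueError("times and od must be 1-d arrays of equal length")
        if len(times) < 3:
            raise ValueError("a growth curve needs at least 3 timepoints")
        if not np.all(np.diff(times) > 0):
            raise ValueError("times must be strictly increasing")
        if not (np.all(np.isfinite(times)) and np.all(np.isfinite(od))):
            raise ValueError("times and od must be finite")
        if self.replicate < 1:
            raise ValueError("replicate must be a positive integer")


@dataclass(frozen=True)
class GrowthSummary:
    strain_id: str
    medium_id: str
    auc: float
    growth_rate: float
    max_od: float
    rate_class: str


@dataclass(frozen=True)
class InhibitionRecord:
    """d_AUC of one consumer strain in one producer's spent medium."""

    producer_strain: str
    consumer_strain: str
    auc_sm_mean: float
    auc_fresh_mean: float
    d_auc: float
    strong_inhibition: bool


@dataclass(frozen=True)
class PhRecord:
    strain_id: str
    medium_id: str
    ph_fresh: float
    ph_sm: float
    ph_dsm: float | None
    delta_ph_sm: float
    delta_ph_dsm: float | None


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    n: int
    method: str


def blank_correct(curve: GrowthCurve, blank_value: float) -> GrowthCurve:
    """Subtract a blank OD reading, clipping negative values to zero."""
    if not np.isfinite(blank_value):
        raise ValueError("blank_value must be finite")
    return replace(curve, od=np.clip(curve.od - blank_value, 0.0, None))


def compute_auc(curve: GrowthCurve) -> float:
    """Trapezoidal area under the OD curve over the recorded interval (OD*h)."""
    if len(curve.times) < 2:
        raise ValueError("AUC needs at least 2 points")
    return float(np.trapezoid(curve.od, curve.times))


def estimate_growth_rate(
    curve: GrowthCurve, window_points: int = 5, min_od: float = 0.02
) -> float:
    """Maximum specific growth rate from sliding-window log-linear fits.

    The slope of ln(OD) versus time is fitted on every contiguous window of
    ``window_points`` readings whose OD values all exceed ``min_od``; the
    largest slope is returned, floored at zero. Returns 0 (with a logged
    warning) when no window is eligible.
    """
    if window_points < 3:
        raise ValueError("window_points must be >= 3")
    if min_od <= 0:
        raise ValueError("min_od must be positive")
    eligible = curve.od > min_od
    n = len(curve.times)
    best = -np.inf
    log_od = np.where(eligible, np.log(np.where(eligible, curve.od, 1.0)), np.nan)
    for start in range(0, n - window_points + 1):
        stop = start + window_points
        if not eligible[start:stop].all():
            continue
        slope = np.polyfit(curve.times[start:stop], log_od[start:stop], 1)[0]
        best = max(best, slope)
    if not np.isfinite(best):
        logger.warning(
            "no window of %d points above OD %.3g for %s in %s; growth rate set to 0",
            window_points,
            min_od,
            curve.strain_id,
            curve.medium_id,
        )
        return 0.0
    return float(max(best, 0.0))


def classify_growth_rate(rate: float) -> str:
    """Rate class: fast (> 1.5 h^-1), intermediate (> 1 h^-1), else slow."""
    if rate < 0:
        raise ValueError("growth rate must be non-negative")
    if rate > FAST_RATE_THRESHOLD:
        return "fast"
    if rate > INTERMEDIATE_RATE_THRESHOLD:
        return "intermediate"
    return "slow"


def summarize_curve(
    curve: GrowthCurve, window_points: int = 5, min_od: float = 0.02
) -> GrowthSummary:
    rate = estimate_growth_rate(curve, window_points=window_points, min_od=min_od)
    return GrowthSummary(
        strain_id=curve.strain_id,
        medium_id=curve.medium_id,
        auc=compute_auc(curve),
        growth_rate=rate,
        max_od=float(curve.od.max()),
        rate_class=classify_growth_rate(rate),
    )


def compute_inhibition_factor(
    auc_sm: Sequence[float],
    auc_fresh: Sequence[float],
    producer_strain: str = "producer",
    consumer_strain: str = "consumer",
    threshold: float = STRONG_INHIBITION_THRESHOLD,
) -> InhibitionRecord:
    """d_AUC from replicate means; strong inhibition at d_AUC strictly below -0.5."""
    auc_sm = np.asarray(list(auc_sm), dtype=float)
    auc_fresh = np.asarray(list(auc_fresh), dtype=float)
    if auc_sm.size == 0 or auc_fresh.size == 0:
        raise ValueError("replicate AUC lists must be non-empty")
    fresh_mean = float(auc_fresh.mean())
    if fresh_mean <= 0:
        raise ValueError("mean fresh-medium AUC must be positive for d_AUC")
    sm_mean = float(auc_sm.mean())
    d_auc = (sm_mean - fresh_mean) / fresh_mean
    return InhibitionRecord(
        producer_strain=producer_strain,
        consumer_strain=consumer_strain,
        auc_sm_mean=sm_mean,
        auc_fresh_mean=fresh_mean,
        d_auc=d_auc,
        strong_inhibition=bool(d_auc < threshold),
    )


class InhibitionMatrix:
    """Producer x consumer d_AUC matrix with strong-inhibition summaries.

    Rows index the strain whose spent medium was used (producer), columns the
    strain growing in it.
    """

    def __init__(self, d_auc: pd.DataFrame, strong: pd.DataFrame):
        self.d_auc = d_auc
        self.strong = strong
        self.strains = list(d_auc.index)

    @property
    def per_producer_strong_counts(self) -> pd.Series:
        """Per producer: number of consumers (incl. self) strongly inhibited."""
        return self.strong.sum(axis=1).astype(int)

    @property
    def strongly_inhibiting_producers(self) -> list[str]:
        """Producers whose SM strongly inhibits at least one *other* strain."""
        off_diag = self.strong.copy()
        np.fill_diagonal(off_diag.values, False)
        return [s for s in self.strains if off_diag.loc[s].any()]

    def to_frame(self) -> pd.DataFrame:
        return self.d_auc.copy()

    def plot(self, ax=None):
        """Heatmap of d_AUC values (rows = SM producer, columns = strain)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        im = ax.imshow(self.d_auc.values, cmap="RdBu", vmin=-1, vmax=1)
        ax.set_xticks(range(len(self.strains)), self.strains, rotation=90)
        ax.set_yticks(range(len(self.strains)), self.strains)
        ax.set_xlabel("growing strain")
        ax.set_ylabel("spent-medium producer")
        ax.figure.colorbar(im, ax=ax, label="d_AUC")
        return ax


def build_inhibition_matrix(
    records: Iterable[InhibitionRecord], strains: Sequence[str]
) -> InhibitionMatrix:
    """Assemble a full S x S inhibition matrix; every pair must be present."""
    strains = list(strains)
    d = pd.DataFrame(np.nan, index=strains, columns=strains, dtype=float)
    s = pd.DataFrame(False, index=strains, columns=strains, dtype=bool)
    for rec in records:
        d.loc[rec.producer_strain, rec.consumer_strain] = rec.d_auc
        s.loc[rec.producer_strain, rec.consumer_strain] = rec.strong_inhibition
    missing = [
        (p, c) for p in strains for c in strains if not np.isfinite(d.loc[p, c])
    ]
    if missing:
        raise ValueError(f"missing producer/consumer pairs: {missing}")
    return InhibitionMatrix(d, s)


def compute_delta_ph(
    ph_fresh: float,
    ph_sm: float,
    ph_dsm: float | None = None,
    strain_id: str = "",
    medium_id: str = "",
) -> PhRecord:
    """pH deltas: after growth in fresh medium, and after growth in the SM.

    The record telescopes: ph_fresh + delta_ph_sm + delta_ph_dsm = ph_dsm.
    """
    for name, value in (("ph_fresh", ph_fresh), ("ph_sm", ph_sm), ("ph_dsm", ph_dsm)):
        if value is not None and not (0.0 <= value <= 14.0):
            raise ValueError(f"{name}={value} outside the pH scale [0, 14]")
    return PhRecord(
        strain_id=strain_id,
        medium_id=medium_id,
        ph_fresh=ph_fresh,
        ph_sm=ph_sm,
        ph_dsm=ph_dsm,
        delta_ph_sm=ph_sm - ph_fresh,
        delta_ph_dsm=None if ph_dsm is None else ph_dsm - ph_sm,
    )


def correlate(
    x: Sequence[float], y: Sequence[float], method: str = "pearson"
) -> CorrelationResult:
    """Pearson (default) or Spearman correlation with a two-sided p-value."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d and of equal length")
    if len(x) < 3:
        raise ValueError("correlation needs at least 3 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("x and y must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in x or y; correlation undefined")
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(
        r=float(res.statistic), p_value=float(res.pvalue), n=len(x), method=method
    )


class SpentMediaModel:
    """Spent-media growth assay, built from a long-format OD table.

    Parameters
    ----------
    od : DataFrame
        Columns ``strain, medium, replicate, time_h, od600``. ``medium`` is
        the fresh-medium label for fresh-medium growth or the producer strain
        id for growth in that strain's spent medium.
    ph : DataFrame, optional
        Columns ``strain, medium, ph_fresh, ph_sm, ph_dsm``.
    """

    def __init__(
        self,
        od: pd.DataFrame,
        ph: pd.DataFrame | None = None,
        fresh_medium: str = "AF",
        blank: float = 0.0,
        window_points: int = 5,
        min_od: float = 0.02,
        fresh_ph: float = 7.0,
    ):
        required = {"strain", "medium", "replicate", "time_h", "od600"}
        if not required.issubset(od.columns):
            raise ValueError(f"OD table must have columns {sorted(required)}")
        self.od = od
        self.ph = ph
        self.fresh_medium = fresh_medium
        self.blank = blank
        self.window_points = window_points
        self.min_od = min_od
        self.fresh_ph = fresh_ph

    @classmethod
    def from_dataframe(cls, od: pd.DataFrame, **kwargs) -> "SpentMediaModel":
        return cls(od, **kwargs)

    def _curves(self) -> list[GrowthCurve]:
        curves = []
        for (strain, medium, rep), grp in self.od.groupby(
            ["strain", "medium", "replicate"], sort=False
        ):
            grp = grp.sort_values("time_h")
            curve = GrowthCurve(
                strain_id=str(strain),
                medium_id=str(medium),
                replicate=int(rep),
                times=grp["time_h"].to_numpy(),
                od=grp["od600"].to_numpy(),
            )
            curves.append(blank_correct(curve, self.blank))
        return curves

    def fit(self, threshold: float = STRONG_INHIBITION_THRESHOLD) -> "SpentMediaResults":
        curves = self._curves()
        rows = []
        for c in curves:
            s = summarize_curve(c, self.window_points, self.min_od)
            rows.append(
                dict(
                    strain=s.strain_id,
                    medium=s.medium_id,
                    replicate=c.replicate,
                    auc=s.auc,
                    growth_rate=s.growth_rate,
                    max_od=s.max_od,
                    rate_class=s.rate_class,
                )
            )
        summaries = pd.DataFrame(rows)
        strains = sorted(summaries["strain"].unique())

        fresh = summaries[summaries["medium"] == self.fresh_medium]
        fresh_auc = {s: g["auc"].to_numpy() for s, g in fresh.groupby("strain")}
        missing_fresh = [s for s in strains if s not in fresh_auc]
        if missing_fresh:
            raise ValueError(f"no fresh-medium curves for strains: {missing_fresh}")

        records = []
        sm = summaries[summaries["medium"] != self.fresh_medium]
        for (consumer, producer), grp in sm.groupby(["strain", "medium"]):
            records.append(
                compute_inhibition_factor(
                    grp["auc"].to_numpy(),
                    fresh_auc[consumer],
                    producer_strain=str(producer),
                    consumer_strain=str(consumer),
                    threshold=threshold,
                )
            )
        # fresh-medium-only tables yield growth summaries without a matrix
        matrix = build_inhibition_matrix(records, strains) if records else None

        ph_records = []
        if self.ph is not None:
            for _, row in self.ph.iterrows():
                ph_records.append(
                    compute_delta_ph(
                        ph_fresh=float(row.get("ph_fresh", self.fresh_ph)),
                        ph_sm=float(row["ph_sm"]),
                        ph_dsm=None
                        if pd.isna(row.get("ph_dsm", np.nan))
                        else float(row["ph_dsm"]),
                        strain_id=str(row["strain"]),
                        medium_id=str(row["medium"]),
                    )
                )
        return SpentMediaResults(self, summaries, matrix, ph_records)


class SpentMediaResults:
    """Fitted spent-media assay: per-curve summaries + inhibition matrix."""

    def __init__(
        self,
        model: SpentMediaModel,
        summaries: pd.DataFrame,
        inhibition: InhibitionMatrix | None,
        ph_records: list[PhRecord],
    ):
        self.model = model
        self.summaries = summaries
        self.inhibition = inhibition
        self.ph_records = ph_records

    def fresh_medium_summaries(self) -> pd.DataFrame:
        """Replicate-mean growth summaries in fresh medium, per strain."""
        fresh = self.summaries[self.summaries["medium"] == self.model.fresh_medium]
        agg = fresh.groupby("strain")[["auc", "growth_rate", "max_od"]].mean()
        agg["rate_class"] = agg["growth_rate"].map(classify_growth_rate)
        return agg

    def summary(self) -> str:
        mat = self.inhibition
        lines = [
            "Spent-media growth assay",
            f"  strains: {self.summaries['strain'].nunique()}",
            f"  fresh medium: {self.model.fresh_medium}",
            "",
            "  strain        GR (h^-1)  class         AUC (OD*h)",
        ]
        for strain, row in self.fresh_medium_summaries().iterrows():
            lines.append(
                f"  {strain:<12}  {row['growth_rate']:>8.2f}  {row['rate_class']:<12}"
                f"  {row['auc']:>9.2f}"
            )
        lines.append("")
        if mat is not None:
            lines.append(
                "  producers strongly inhibiting >=1 other strain: "
                f"{len(mat.strongly_inhibiting_producers)} "
                f"({', '.join(mat.strongly_inhibiting_producers)})"
            )
        else:
            lines.append("  (no spent-media curves; inhibition matrix not computed)")
        return "\n".join(lines)
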