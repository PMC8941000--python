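"""Pairwise interaction typing from qPCR-quantified co-cultures.

For every strain i in a pairwise co-culture the endpoint ratio

    r_bm = m_i,co(72 h) / m_i,mono(72 h)

compares its absolute abundance (16S rRNA gene copies) in co-culture with
the matched monoculture, replicate-paired by experiment. A two-sided
one-sample t-test of the n replicate ratios against 1 assigns each strain a
sign (+ / 0 / -), and the unordered sign pair determines the ecological
interaction type:

    (+,+) mutualism      (+,0) commensalism   (0,0) neutralism
    (0,-) amensalism     (-,-) competition    (+,-) predation

Cq values are converted to copies through per-strain standard curves,
copies = dilution * 10^((cq - intercept)/slope); the per-sample
normalization constant cancels in r_bm.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, replace
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "StandardCurve",
    "QuantResult",
    "RbmResult",
    "InteractionEdge",
    "INTERACTION_TYPES",
    "quantify_from_cq",
    "compute_rbm",
    "classify_effect",
    "interaction_type",
    "build_interaction_network",
    "CocultureModel",
    "InteractionNetworkResults",
]

INTERACTION_TYPES = {
    frozenset({"+"}): "mutualism",
    frozenset({"+", "0"}): "commensalism",
    frozenset({"0"}): "neutralism",
    frozenset({"0", "-"}): "amensalism",
    frozenset({"-"}): "competition",
    frozenset({"+", "-"}): "predation",
}


@dataclass(frozen=True)
class StandardCurve:
    """qPCR calibration: Cq = intercept + slope * log10(copies).

    The amplification efficiency implied by the slope, 10^(-1/slope) - 1,
    must be plausible (0 < efficiency <= 1.2).
    """

    strain_id: str
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValueError("standard-curve slope must be negative")
        eff = self.efficiency
        if not 0 < eff <= 1.2:
            raise ValueError(
                f"implied amplification efficiency {eff:.3f} outside (0, 1.2]"
            )

    @property
    def efficiency(self) -> float:
        return 10 ** (-1.0 / self.slope) - 1.0


class QuantResult(NamedTuple):
    copies: float
    out_of_range: bool


def quantify_from_cq(
    cq: float,
    curve: StandardCurve,
    dilution_factor: float = 1.0,
    calibration_range: tuple[float, float] | None = None,
) -> QuantResult:
    """Absolute copies from a Cq value via the strain's standard curve."""
    if not np.isfinite(cq):
        raise ValueError("cq must be finite")
    if dilution_factor <= 0:
        raise ValueError("dilution_factor must be positive")
    copies = dilution_factor * 10 ** ((cq - curve.intercept) / curve.slope)
    out = False
    if calibration_range is not None:
        lo, hi = sorted(calibration_range)
        out = not (lo <= cq <= hi)
    return QuantResult(float(copies), out)


@dataclass(frozen=True)
class RbmResult:
    """Per-strain co-culture/monoculture abundance ratio and its sign call."""

    strain_id: str
    partner_id: str
    per_replicate_ratios: tuple
    mean_ratio: float
    p_value: float | None = None
    sign: str | None = None


def compute_rbm(
    co: Sequence[float],
    mono: Sequence[float],
    strain_id: str = "",
    partner_id: str = "",
) -> RbmResult:
    """Experiment-paired per-replicate ratios co/mono and their mean.

    Replicates with zero monoculture copies are excluded with a warning; if
    none remain the pair is rejected.
    """
    co = np.asarray(list(co), dtype=float)
    mono = np.asarray(list(mono), dtype=float)
    if co.shape != mono.shape:
        raise ValueError("co and mono must have matched replicate counts")
    usable = mono > 0
    if not usable.all():
        logger.warning(
            "%d replicate(s) with zero monoculture copies excluded for %s vs %s",
            int((~usable).sum()),
            strain_id,
            partner_id,
        )
    if not usable.any():
        raise ValueError("no usable replicates: all monoculture copies are zero")
    ratios = co[usable] / mono[usable]
    return RbmResult(
        strain_id=strain_id,
        partner_id=partner_id,
        per_replicate_ratios=tuple(float(r) for r in ratios),
        mean_ratio=float(ratios.mean()),
    )


def classify_effect(
    result: RbmResult, alpha: float = 0.05, log_ratio: bool = False
) -> RbmResult:
    """Sign the effect by a two-sided one-sample t-test of the ratios vs 1.

    With ``log_ratio=True`` the test is on log(ratios) against 0, which is
    better behaved for skewed ratio distributions but departs from the plain
    ratio-scale test. Zero-variance replicate sets are signed by direction.
    """
    ratios = np.asarray(result.per_replicate_ratios, dtype=float)
    if len(ratios) < 2:
        raise ValueError("classify_effect needs at least 2 replicate ratios")
    if log_ratio:
        sample, null = np.log(ratios), 0.0
    else:
        sample, null = ratios, 1.0
    if np.ptp(sample) == 0:
        if sample[0] == null:
            return replace(result, p_value=1.0, sign="0")
        logger.warning(
            "degenerate zero-variance ratios for %s vs %s; sign set by direction",
            result.strain_id,
            result.partner_id,
        )
        return replace(result, p_value=0.0, sign="+" if sample[0] > null else "-")
    t = stats.ttest_1samp(sample, null)
    p = float(t.pvalue)
    if p >= alpha:
        sign = "0"
    else:
        sign = "+" if result.mean_ratio > 1 else "-"
    return replace(result, p_value=p, sign=sign)


def interaction_type(sign_a: str, sign_b: str) -> str:
    """Ecological type from the unordered pair of r_bm signs."""
    for s in (sign_a, sign_b):
        if s not in {"+", "0", "-"}:
            raise ValueError(f"invalid sign token {s!r}")
    return INTERACTION_TYPES[frozenset({sign_a, sign_b})]


@dataclass(frozen=True)
class InteractionEdge:
    strain_a: str
    strain_b: str
    sign_a: str
    sign_b: str
    type: str
    rbm_a: RbmResult
    rbm_b: RbmResult


def build_interaction_network(
    abundances: pd.DataFrame,
    alpha: float = 0.05,
    endpoint_h: float = 72.0,
    log_ratio: bool = False,
) -> "InteractionNetworkResults":
    """Assemble the typed pairwise network from mono- and co-culture copies.

    ``abundances`` is a long table with columns ``strain, culture_type
    (mono|pair), partner, timepoint_h, replicate, copies``. Every unordered
    strain pair must be measured at the endpoint for both members, along
    with every monoculture.
    """
    model = CocultureModel(abundances, endpoint_h=endpoint_h)
    return model.fit(alpha=alpha, log_ratio=log_ratio)


class CocultureModel:
    """Co-culture outcome model over endpoint qPCR abundances."""

    def __init__(self, abundances: pd.DataFrame, endpoint_h: float = 72.0):
        required = {"strain", "culture_type", "partner", "timepoint_h", "replicate", "copies"}
        if not required.issubset(abundances.columns):
            raise ValueError(f"abundance table must have columns {sorted(required)}")
        self.abundances = abundances
        self.endpoint_h = endpoint_h
        end = abundances[abundances["timepoint_h"] == endpoint_h]
        self.strains = sorted(end.loc[end["culture_type"] == "mono", "strain"].unique())

    @classmethod
    def from_dataframe(cls, abundances: pd.DataFrame, **kwargs) -> "CocultureModel":
        return cls(abundances, **kwargs)

    @classmethod
    def from_cq(
        cls,
        qpcr: pd.DataFrame,
        standards: Iterable[StandardCurve],
        dilution_factor: float = 1.0,
        **kwargs,
    ) -> "CocultureModel":
        """Build from a Cq table by absolute quantification per strain."""
        curves = {c.strain_id: c for c in standards}
        missing = set(qpcr["strain"].unique()) - set(curves)
        if missing:
            raise ValueError(f"no standard curve for strains: {sorted(missing)}")
        df = qpcr.copy()
        df["copies"] = [
            quantify_from_cq(cq, curves[s], dilution_factor).copies
            if np.isfinite(cq)
            else 0.0
            for cq, s in zip(df["cq"], df["strain"])
        ]
        if "censored" in df.columns:
            df.loc[df["censored"].astype(bool), "copies"] = 0.0
        return cls(df.drop(columns=["cq"]), **kwargs)

    def _endpoint(self) -> pd.DataFrame:
        return self.abundances[self.abundances["timepoint_h"] == self.endpoint_h]

    def fit(self, alpha: float = 0.05, log_ratio: bool = False) -> "InteractionNetworkResults":
        end = self._endpoint()
        mono = {
            s: g.sort_values("replicate")["copies"].to_numpy()
            for s, g in end[end["culture_type"] == "mono"].groupby("strain")
        }
        pairs = end[end["culture_type"] == "pair"]
        co: dict[tuple[str, str], np.ndarray] = {
            (str(s), str(p)): g.sort_values("replicate")["copies"].to_numpy()
            for (s, p), g in pairs.groupby(["strain", "partner"])
        }
        missing = []
        for a, b in itertools.combinations(self.strains, 2):
            if (a, b) not in co:
                missing.append((a, b))
            if (b, a) not in co:
                missing.append((b, a))
        if missing:
            raise ValueError(f"missing co-culture measurements: {missing}")

        edges = []
        for a, b in itertools.combinations(self.strains, 2):
            res_a = classify_effect(
                compute_rbm(co[(a, b)], mono[a], a, b), alpha=alpha, log_ratio=log_ratio
            )
            res_b = classify_effect(
                compute_rbm(co[(b, a)], mono[b], b, a), alpha=alpha, log_ratio=log_ratio
            )
            edges.append(
                InteractionEdge(
                    strain_a=a,
                    strain_b=b,
                    sign_a=res_a.sign,
                    sign_b=res_b.sign,
                    type=interaction_type(res_a.sign, res_b.sign),
                    rbm_a=res_a,
                    rbm_b=res_b,
                )
            )
        return InteractionNetworkResults(self, edges, alpha)


class InteractionNetworkResults:
    """Typed interaction edges, census and per-strain negative-effect counts."""

    def __init__(self, model: CocultureModel, edges: list[InteractionEdge], alpha: float):
        self.model = model
        self.edges = edges
        self.alpha = alpha

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def census(self) -> dict:
        counts = {t: 0 for t in sorted(set(INTERACTION_TYPES.values()))}
        for e in self.edges:
            counts[e.type] += 1
        return counts

    @property
    def negative_effect_counts(self) -> pd.Series:
        """Per strain: number of partners it affects negatively.

        Strain a affects partner b negatively when b's sign in the (a, b)
        co-culture is negative.
        """
        counts = {s: 0 for s in self.model.strains}
        for e in self.edges:
            if e.sign_b == "-":
                counts[e.strain_a] += 1
            if e.sign_a == "-":
                counts[e.strain_b] += 1
        return pd.Series(counts)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.edges:
            rows.append(
                dict(
                    strain_a=e.strain_a,
                    strain_b=e.strain_b,
                    sign_a=e.sign_a,
                    sign_b=e.sign_b,
                    type=e.type,
                    mean_rbm_a=e.rbm_a.mean_ratio,
                    mean_rbm_b=e.rbm_b.mean_ratio,
                    p_a=e.rbm_a.p_value,
                    p_b=e.rbm_b.p_value,
                )
            )
        return pd.DataFrame(rows)

    def rbm_matrix(self) -> pd.DataFrame:
        """Mean r_bm values; rows = focal strain, columns = partner."""
        strains = self.model.strains
        mat = pd.DataFrame(np.nan, index=strains, columns=strains)
        for e in self.edges:
            mat.loc[e.strain_a, e.strain_b] = e.rbm_a.mean_ratio
            mat.loc[e.strain_b, e.strain_a] = e.rbm_b.mean_ratio
        return mat

    def summary(self) -> str:
        census = self.census
        lines = [
            "Pairwise interaction network",
            f"  strains: {len(self.model.strains)}, edges: {self.n_edges}, "
            f"alpha: {self.alpha}",
            "  census:",
        ]
        for t, c in census.items():
            lines.append(f"    {t:<13} {c:>3}")
        lines.append("  negative outcomes caused per strain:")
        for s, c in self.negative_effect_counts.items():
            lines.append(f"    {s:<13} {c:>3}")
        return "\n".join(lines)

    def plot(self, ax=None):
        """r_bm heatmap (log2 scale; rows = focal strain, columns = partner)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(6, 5))
        mat = np.log2(self.rbm_matrix().astype(float))
        strains = self.model.strains
        im = ax.imshow(mat.values, cmap="PuOr", vmin=-4, vmax=4)
        ax.set_xticks(range(len(strains)), strains, rotation=90)
        ax.set_yticks(range(len(strains)), strains)
        ax.set_xlabel("partner")
        ax.set_ylabel("focal strain")
        ax.figure.colorbar(im, ax=ax, label="log2 r_bm")
        return ax
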