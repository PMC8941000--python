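"""Serial-passage community composition summaries.

Endpoint qPCR copies from batch-dilution community cultures are converted
to relative abundances (with detection flags), compared between full and
dropout communities per strain, z-scored per strain across conditions, and
ordinated by principal component analysis of the composition matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "relative_abundance",
    "compare_dropout",
    "scale_by_strain",
    "ordinate",
    "OrdinationResult",
    "CommunityModel",
    "CommunityResults",
]

DEFAULT_DETECTION_LIMIT = 1e-4  # relative abundance below which a strain is flagged


def relative_abundance(
    copies: pd.Series, detection_limit: float = DEFAULT_DETECTION_LIMIT
) -> pd.DataFrame:
    """Normalize per-strain copies to fractions; flag below-detection strains.

    Below-detection strains keep their computed fraction but carry
    ``detected=False`` rather than an imputed zero.
    """
    copies = copies.astype(float)
    if (copies < 0).any():
        raise ValueError("copies must be non-negative")
    total = copies.sum()
    if total <= 0:
        raise ValueError("all strains below detection; no composition defined")
    rel = copies / total
    return pd.DataFrame(
        {"copies": copies, "rel_abundance": rel, "detected": rel >= detection_limit}
    )


def compare_dropout(
    full: pd.DataFrame,
    dropout: pd.DataFrame,
    removed_strain: str,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-strain change of absolute abundance when one member is removed.

    ``full`` and ``dropout`` are strains x replicates abundance tables; the
    dropout arm must lack exactly the removed strain. Returns per shared
    strain the fold-change of means (dropout/full), a two-sided two-sample
    t-test p-value and a direction label at ``alpha``.
    """
    if removed_strain in dropout.index:
        raise ValueError(f"{removed_strain!r} still present in the dropout arm")
    shared = [s for s in full.index if s != removed_strain]
    extra = set(dropout.index) - set(shared)
    lacking = set(shared) - set(dropout.index)
    if extra or lacking:
        raise ValueError(
            f"strain sets differ beyond the removed strain: extra={sorted(extra)}, "
            f"missing={sorted(lacking)}"
        )
    if full.shape[1] < 2 or dropout.shape[1] < 2:
        raise ValueError("both arms need at least 2 replicates")
    rows = []
    for s in shared:
        a = full.loc[s].to_numpy(dtype=float)
        b = dropout.loc[s].to_numpy(dtype=float)
        if a.mean() == 0 and b.mean() == 0:
            rows.append(
                dict(strain=s, mean_full=0.0, mean_dropout=0.0, fold_change=np.nan,
                     p_value=np.nan, direction="absent")
            )
            continue
        t = stats.ttest_ind(b, a, equal_var=False)
        fold = b.mean() / a.mean() if a.mean() > 0 else np.inf
        if t.pvalue < alpha:
            direction = "increase" if b.mean() > a.mean() else "decrease"
        else:
            direction = "unchanged"
        rows.append(
            dict(strain=s, mean_full=float(a.mean()), mean_dropout=float(b.mean()),
                 fold_change=float(fold), p_value=float(t.pvalue), direction=direction)
        )
    return pd.DataFrame(rows).set_index("strain")


def scale_by_strain(matrix: pd.DataFrame) -> pd.DataFrame:
    """Z-score each strain (row) across conditions; constant rows become 0."""
    if matrix.shape[1] < 2:
        raise ValueError("scaling needs at least 2 conditions per strain")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        logger.warning(
            "constant abundance rows scaled to zero: %s",
            list(matrix.index[flat]),
        )
    sd[sd == 0] = 1.0
    return pd.DataFrame((values - mean) / sd, index=matrix.index, columns=matrix.columns)


@dataclass(frozen=True)
class OrdinationResult:
    scores: pd.DataFrame  # samples x components
    loadings: pd.DataFrame  # strains x components
    explained_variance_ratio: np.ndarray

    def plot(self, ax=None, hue=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(self.scores.iloc[:, 0], self.scores.iloc[:, 1], c=hue)
        ax.set_xlabel(f"PC1 ({100 * self.explained_variance_ratio[0]:.1f}%)")
        ax.set_ylabel(f"PC2 ({100 * self.explained_variance_ratio[1]:.1f}%)")
        return ax


def ordinate(compositions: pd.DataFrame, n_components: int = 2) -> OrdinationResult:
    """PCA of a samples x strains composition matrix.

    Columns are centered and the covariance matrix eigendecomposed; scores
    are projections onto the leading eigenvectors. Each component's sign is
    fixed so that its largest-magnitude loading is positive. Components
    beyond the matrix rank carry zero explained variance.
    """
    X = compositions.to_numpy(dtype=float)
    n_samples, n_strains = X.shape
    if n_samples < 3:
        raise ValueError("ordination needs at least 3 samples")
    if n_components >= min(n_samples, n_strains):
        raise ValueError("n_components must be < min(samples, strains)")
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = Xc.T @ Xc / (n_samples - 1)
    eigval, eigvec = np.linalg.eigh(cov)
    order = np.argsort(eigval)[::-1]
    eigval = np.clip(eigval[order], 0.0, None)
    eigvec = eigvec[:, order]
    for k in range(eigvec.shape[1]):
        j = np.argmax(np.abs(eigvec[:, k]))
        if eigvec[j, k] < 0:
            eigvec[:, k] = -eigvec[:, k]
    total = eigval.sum()
    ratio = eigval[:n_components] / total if total > 0 else np.zeros(n_components)
    scores = Xc @ eigvec[:, :n_components]
    comp_names = [f"PC{k + 1}" for k in range(n_components)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=compositions.index, columns=comp_names),
        loadings=pd.DataFrame(
            eigvec[:, :n_components], index=compositions.columns, columns=comp_names
        ),
        explained_variance_ratio=ratio,
    )


class CommunityModel:
    """Composition analysis of serial-passage community endpoints.

    ``abundances`` is a long table with columns ``condition, replicate,
    strain, copies`` covering one endpoint per condition/replicate.
    """

    def __init__(self, abundances: pd.DataFrame,
                 detection_limit: float = DEFAULT_DETECTION_LIMIT):
        required = {"condition", "replicate", "strain", "copies"}
        if not required.issubset(abundances.columns):
            raise ValueError(f"abundance table must have columns {sorted(required)}")
        self.abundances = abundances
        self.detection_limit = detection_limit

    @classmethod
    def from_dataframe(cls, abundances: pd.DataFrame, **kwargs) -> "CommunityModel":
        return cls(abundances, **kwargs)

    def fit(self) -> "CommunityResults":
        rows = []
        for (cond, rep), grp in self.abundances.groupby(["condition", "replicate"]):
            copies = grp.set_index("strain")["copies"]
            table = relative_abundance(copies, self.detection_limit)
            for strain, r in table.iterrows():
                rows.append(
                    dict(condition=cond, replicate=rep, strain=strain,
                         copies=r["copies"], rel_abundance=r["rel_abundance"],
                         detected=bool(r["detected"]))
                )
        return CommunityResults(self, pd.DataFrame(rows))


class CommunityResults:
    def __init__(self, model: CommunityModel, composition: pd.DataFrame):
        self.model = model
        self.composition = composition

    def composition_matrix(self, value: str = "rel_abundance") -> pd.DataFrame:
        """Samples x strains matrix; sample index = (condition, replicate)."""
        return self.composition.pivot_table(
            index=["condition", "replicate"], columns="strain", values=value,
            fill_value=0.0,
        )

    def mean_composition(self) -> pd.DataFrame:
        """Condition x strain mean relative abundance."""
        return self.composition.pivot_table(
            index="condition", columns="strain", values="rel_abundance", aggfunc="mean",
            fill_value=0.0,
        )

    def abundance_matrix(self, condition: str) -> pd.DataFrame:
        """Strains x replicates absolute copies for one condition."""
        sub = self.composition[self.composition["condition"] == condition]
        return sub.pivot_table(index="strain", columns="replicate", values="copies")

    def compare_dropout(
        self, full_condition: str, dropout_condition: str, removed_strain: str,
        alpha: float = 0.05,
    ) -> pd.DataFrame:
        return compare_dropout(
            self.abundance_matrix(full_condition),
            self.abundance_matrix(dropout_condition),
            removed_strain,
            alpha=alpha,
        )

    def scaled_by_strain(self) -> pd.DataFrame:
        """Per-strain z-scores of mean absolute abundance across conditions."""
        mat = self.composition.pivot_table(
            index="strain", columns="condition", values="copies", aggfunc="mean",
            fill_value=0.0,
        )
        return scale_by_strain(mat)

    def ordinate(self, n_components: int = 2) -> OrdinationResult:
        return ordinate(self.composition_matrix(), n_components=n_components)

    def summary(self) -> str:
        mean = self.mean_composition()
        lines = ["Community composition (mean relative abundance per condition)"]
        for cond, row in mean.iterrows():
            top = row.sort_values(ascending=False).head(3)
            desc = ", ".join(f"{s}: {v:.1%}" for s, v in top.items())
            lines.append(f"  {cond}: {desc}")
        return "\n".join(lines)
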