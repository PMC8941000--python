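"""In silico twin of the wet-lab workflow, with known ground truth.

A :class:`SyntheticDesign` fixes per-strain logistic growth parameters, a
binary strain x feature resource-usage matrix (which metabolomic features a
strain depletes, and how deeply), pairwise generalized Lotka-Volterra (gLV)
interaction coefficients, a bacteriocin kill matrix and observation-noise
levels. From one design the module generates every input the analysis
stages read:

* monoculture growth curves in fresh and spent media (logistic dynamics;
  the carrying capacity in a producer's spent medium shrinks with the
  fraction of the consumer's resources the producer already depleted,
  and bacteriocin carry-over slows growth),
* metabolomic feature tables with log-normal replicate noise,
* pairwise co-cultures and serial-passage communities under batch-dilution
  gLV dynamics (fixed-step RK4, instantaneous 1:100 dilution every 24 h),
* noisy qPCR readouts of the resulting abundances.

The packaged :func:`default_design` mirrors a 12-member gut community
spanning five phyla: four fast / five intermediate / three slow growers,
one bacteriocin producer with five targets, and a pairwise network of
46 amensal, 7 competitive, 11 neutral, 1 commensal and 1 predatory edges.
All generators are reproducible given (design, seed).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .network import StandardCurve

__all__ = [
    "StrainSpec",
    "NoiseSpec",
    "SyntheticDesign",
    "default_design",
    "default_taxonomy",
    "default_tree_newick",
    "default_standard_curves",
    "integrate_glv",
    "simulate_monoculture",
    "simulate_growth_curves",
    "simulate_spent_media_experiment",
    "simulate_ph_table",
    "simulate_feature_table",
    "simulate_cocultures",
    "simulate_community",
    "simulate_qpcr",
]

COPIES_PER_OD = 2.0e9  # 16S copies per ml per OD600 unit, observation scale
QPCR_MAX_CYCLES = 40.0
EXTINCTION_OD = 1e-12  # abundances below this after dilution are set to zero


@dataclass(frozen=True)
class StrainSpec:
    """Logistic growth parameters of one strain in fresh medium."""

    name: str
    mu: float  # max specific growth rate, h^-1
    carrying_capacity: float  # OD600 units
    initial_od: float = 0.01
    acid_coef: float = 0.0  # pH shift caused by full growth in fresh medium


@dataclass(frozen=True)
class NoiseSpec:
    od_sd: float = 0.005  # additive OD600 noise per reading
    intensity_cv: float = 0.10  # log-normal CV of feature intensities
    cq_sd: float = 0.15  # additive Cq noise, cycles
    abundance_cv: float = 0.20  # log-normal CV of observed copies

    def __post_init__(self) -> None:
        if min(self.od_sd, self.intensity_cv, self.cq_sd, self.abundance_cv) < 0:
            raise ValueError("noise parameters must be non-negative")


@dataclass
class SyntheticDesign:
    """Ground-truth parameterisation of the simulated community."""

    strains: list
    feature_usage: np.ndarray  # strains x features, bool: depleted features
    depletion_depth: np.ndarray  # per feature, fraction of intensity removed
    production_profile: np.ndarray  # strains x features, bool: produced features
    interactions: np.ndarray  # a[i, j] = per-capita effect of strain j on i
    bacteriocin: np.ndarray  # kill[p, t] = kill rate of producer p on target t
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    dilution_factor: float = 0.01
    dilution_period_h: float = 24.0
    production_fold: float = 5.0
    seed: int = 0
    edge_truth: pd.DataFrame | None = None  # designed signs/types, if known

    def __post_init__(self) -> None:
        S = len(self.strains)
        self.feature_usage = np.asarray(self.feature_usage, dtype=bool)
        self.production_profile = np.asarray(self.production_profile, dtype=bool)
        self.interactions = np.asarray(self.interactions, dtype=float)
        self.bacteriocin = np.asarray(self.bacteriocin, dtype=float)
        self.depletion_depth = np.asarray(self.depletion_depth, dtype=float)
        if self.feature_usage.shape[0] != S or self.production_profile.shape != self.feature_usage.shape:
            raise ValueError("resource/production profiles must be strains x features")
        if self.depletion_depth.shape != (self.feature_usage.shape[1],):
            raise ValueError("depletion_depth must be per-feature")
        if np.any((self.depletion_depth < 0) | (self.depletion_depth > 1)):
            raise ValueError("depletion depths must lie in [0, 1]")
        if self.interactions.shape != (S, S) or self.bacteriocin.shape != (S, S):
            raise ValueError("interaction and bacteriocin matrices must be S x S")
        if np.any(np.diag(self.interactions) >= 0):
            raise ValueError("self-interaction coefficients a_ii must be negative")
        if np.any(self.bacteriocin < 0):
            raise ValueError("bacteriocin kill rates must be non-negative")
        if not 0 < self.dilution_factor < 1:
            raise ValueError("dilution factor must lie in (0, 1)")
        for s in self.strains:
            if s.mu <= 0 or s.carrying_capacity <= 0 or s.initial_od <= 0:
                raise ValueError(f"non-positive growth parameters for {s.name}")

    @property
    def strain_names(self) -> list[str]:
        return [s.name for s in self.strains]

    @property
    def n_features(self) -> int:
        return self.feature_usage.shape[1]

    @property
    def mu(self) -> np.ndarray:
        return np.array([s.mu for s in self.strains])

    @property
    def capacity(self) -> np.ndarray:
        return np.array([s.carrying_capacity for s in self.strains])

    def index(self, name: str) -> int:
        return self.strain_names.index(name)

    def effective_interactions(self) -> np.ndarray:
        """gLV matrix with bacteriocin killing folded in (a_tp -= kill_pt)."""
        return self.interactions - self.bacteriocin.T


# ---------------------------------------------------------------------------
# gLV integration

def integrate_glv(
    n0: np.ndarray,
    mu: np.ndarray,
    a: np.ndarray,
    hours: float,
    dt: float = 0.01,
    divergence_limit: float | None = None,
) -> np.ndarray:
    """Fixed-step RK4 integration of dN_i/dt = N_i (mu_i + sum_j a_ij N_j).

    ``n0`` may be a single state vector or a batch (cultures x strains); all
    cultures share ``mu`` and ``a``. Raises on trajectory divergence.
    """
    n = np.asarray(n0, dtype=float).copy()
    steps = int(round(hours / dt))
    limit = divergence_limit if divergence_limit is not None else 1e6 * max(
        1.0, float(np.max(-mu / np.diag(a)))
    )

    def rhs(state: np.ndarray) -> np.ndarray:
        return state * (mu + state @ a.T)

    for _ in range(steps):
        k1 = rhs(n)
        k2 = rhs(n + 0.5 * dt * k1)
        k3 = rhs(n + 0.5 * dt * k2)
        k4 = rhs(n + dt * k3)
        n = n + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        n = np.clip(n, 0.0, None)
        if np.max(n) > limit:
            raise RuntimeError("gLV trajectory diverged; unstable design")
    return n


def _logistic_batch(
    n0: np.ndarray, mu: np.ndarray, k: np.ndarray, times: np.ndarray, dt: float
) -> np.ndarray:
    """Independent logistic trajectories sampled at ``times`` (RK4)."""
    n = np.asarray(n0, dtype=float).copy()
    out = np.empty((len(times), len(n)))
    t = 0.0
    idx = 0
    rate = mu / k

    def rhs(state):
        return state * (mu - rate * state)

    steps_per = [int(round((times[i] - (times[i - 1] if i else 0.0)) / dt)) for i in range(len(times))]
    for i, nsteps in enumerate(steps_per):
        for _ in range(nsteps):
            k1 = rhs(n)
            k2 = rhs(n + 0.5 * dt * k1)
            k3 = rhs(n + 0.5 * dt * k2)
            k4 = rhs(n + dt * k3)
            n = n + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[i] = n
        idx += 1
    return out


# ---------------------------------------------------------------------------
# Spent-media machinery

def _medium_after_growth(design: SyntheticDesign, producer: int) -> np.ndarray:
    """Per-feature remaining fraction after the producer grows to stationary."""
    remaining = np.ones(design.n_features)
    used = design.feature_usage[producer]
    remaining[used] *= 1.0 - design.depletion_depth[used]
    return remaining


def _effective_capacity(
    design: SyntheticDesign, consumer: int, remaining: np.ndarray
) -> float:
    used = design.feature_usage[consumer]
    k = design.strains[consumer].carrying_capacity
    if not used.any():
        return k
    return k * float(remaining[used].mean())


def _effective_rate(design: SyntheticDesign, consumer: int, producer: int | None) -> float:
    """Growth rate in a producer's SM: bacteriocin carry-over slows growth."""
    mu = design.strains[consumer].mu
    if producer is None:
        return mu
    kill = design.bacteriocin[producer, consumer]
    carry = design.strains[producer].carrying_capacity
    return mu * float(np.exp(-kill * carry))


def simulate_monoculture(
    design: SyntheticDesign,
    strain: str,
    medium_state: np.ndarray | None = None,
    seed: int | None = None,
    replicate: int = 1,
    hours: float = 20.0,
    sample_every_h: float = 1.0 / 6.0,
    producer: str | None = None,
    dt: float = 1.0 / 120.0,
):
    """One replicate logistic growth curve, optionally in a spent medium.

    ``medium_state`` is the per-feature remaining-fraction vector of the
    medium (None = fresh); ``producer`` names the SM producer for the
    bacteriocin carry-over penalty and the curve's medium label.
    """
    from .growth import GrowthCurve

    i = design.index(strain)
    remaining = np.ones(design.n_features) if medium_state is None else medium_state
    k_eff = _effective_capacity(design, i, remaining)
    mu_eff = _effective_rate(design, i, None if producer is None else design.index(producer))
    rng = np.random.default_rng(design.seed if seed is None else seed)
    times = np.arange(0.0, hours + 1e-9, sample_every_h)
    traj = _logistic_batch(
        np.array([design.strains[i].initial_od]),
        np.array([mu_eff]),
        np.array([max(k_eff, 1e-6)]),
        times[1:],
        dt,
    )[:, 0]
    od = np.concatenate([[design.strains[i].initial_od], traj])
    od = np.clip(od + rng.normal(0.0, design.noise.od_sd, size=od.shape), 0.0, None)
    return GrowthCurve(
        strain_id=strain,
        medium_id="AF" if producer is None else producer,
        replicate=replicate,
        times=times,
        od=od,
    )


def simulate_growth_curves(
    design: SyntheticDesign, seed: int, replicates: int = 3, hours: float = 20.0
) -> pd.DataFrame:
    """Fresh-medium triplicate growth curves for all strains (long format)."""
    rng = np.random.default_rng(seed)
    return _curves_frame(design, rng, media=[None], replicates=replicates, hours=hours)


def _curves_frame(design, rng, media, replicates, hours, sample_every_h=1.0 / 6.0,
                  dt=1.0 / 120.0) -> pd.DataFrame:
    times = np.arange(0.0, hours + 1e-9, sample_every_h)
    combos = []  # (consumer, producer or None)
    mu_eff, k_eff, n0 = [], [], []
    for producer in media:
        p_idx = None if producer is None else design.index(producer)
        remaining = (
            np.ones(design.n_features)
            if p_idx is None
            else _medium_after_growth(design, p_idx)
        )
        for c, spec in enumerate(design.strains):
            combos.append((spec.name, producer))
            mu_eff.append(_effective_rate(design, c, p_idx))
            k_eff.append(max(_effective_capacity(design, c, remaining), 1e-6))
            n0.append(spec.initial_od)
    traj = _logistic_batch(np.array(n0), np.array(mu_eff), np.array(k_eff), times[1:], dt)
    traj = np.vstack([np.array(n0)[None, :], traj])  # timepoints x combos
    rows = []
    for j, (consumer, producer) in enumerate(combos):
        clean = traj[:, j]
        for rep in range(1, replicates + 1):
            noisy = np.clip(
                clean + rng.normal(0.0, design.noise.od_sd, size=clean.shape), 0.0, None
            )
            rows.append(
                pd.DataFrame(
                    {
                        "strain": consumer,
                        "medium": "AF" if producer is None else producer,
                        "replicate": rep,
                        "time_h": times,
                        "od600": noisy,
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


def simulate_spent_media_experiment(
    design: SyntheticDesign, seed: int, replicates: int = 3, hours: float = 20.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """All producer x consumer SM growth curves plus fresh-medium controls.

    Returns the long-format OD table and a ground-truth table with the
    noiseless expected d_AUC for every (producer, consumer) pair.
    """
    rng = np.random.default_rng(seed)
    media = [None] + design.strain_names
    od = _curves_frame(design, rng, media=media, replicates=replicates, hours=hours)

    # expected d_AUC from the noiseless trajectories
    from .growth import GrowthCurve, compute_auc

    clean = _curves_frame(
        _noiseless(design), np.random.default_rng(0), media=media, replicates=1,
        hours=hours,
    )
    auc = {}
    for (strain, medium), grp in clean.groupby(["strain", "medium"]):
        grp = grp[grp["replicate"] == 1].sort_values("time_h")
        curve = GrowthCurve(strain, medium, 1, grp["time_h"].to_numpy(), grp["od600"].to_numpy())
        auc[(strain, medium)] = compute_auc(curve)
    truth_rows = []
    for producer in design.strain_names:
        for consumer in design.strain_names:
            d = (auc[(consumer, producer)] - auc[(consumer, "AF")]) / auc[(consumer, "AF")]
            truth_rows.append(
                dict(producer=producer, consumer=consumer, expected_d_auc=d)
            )
    return od, pd.DataFrame(truth_rows)


def _noiseless(design: SyntheticDesign) -> SyntheticDesign:
    from dataclasses import replace

    return replace(design, noise=NoiseSpec(0.0, 0.0, 0.0, 0.0))


# ---------------------------------------------------------------------------
# Metabolomics

def simulate_ph_table(design: SyntheticDesign, fresh_ph: float = 7.0) -> pd.DataFrame:
    """Supernatant pH for every producer SM and every consumer DSM.

    Each strain shifts the medium by its acid coefficient, scaled by how
    much growth the medium still supports: growing in a producer's SM a
    consumer realises only the K_eff/K fraction of its fresh-medium shift.
    """
    rows = []
    for p, pspec in enumerate(design.strains):
        ph_sm = float(np.clip(fresh_ph + pspec.acid_coef, 0.0, 14.0))
        remaining = _medium_after_growth(design, p)
        for c, cspec in enumerate(design.strains):
            frac = _effective_capacity(design, c, remaining) / cspec.carrying_capacity
            ph_dsm = float(np.clip(ph_sm + cspec.acid_coef * frac, 0.0, 14.0))
            rows.append(
                dict(strain=cspec.name, medium=pspec.name, ph_fresh=fresh_ph,
                     ph_sm=ph_sm, ph_dsm=ph_dsm)
            )
    return pd.DataFrame(rows)


def simulate_feature_table(
    design: SyntheticDesign,
    n_features: int | None = None,
    seed: int = 0,
    replicates: int = 3,
    baseline_median: float = 1.0e5,
    baseline_sigma: float = 0.8,
):
    """Feature x sample intensity table for fresh medium and every strain's SM.

    Fresh-medium intensities are log-normal around fixed per-feature
    baselines; a strain's samples have its used features reduced by the
    designed depletion depth and its produced features raised by the
    production fold, all with log-normal replicate noise.
    """
    from .metabolomics import FeatureTable

    if n_features is None:
        n_features = design.n_features
    if n_features < design.n_features:
        raise ValueError("n_features smaller than the designed feature universe")
    rng = np.random.default_rng(seed)
    baselines = baseline_median * np.exp(
        rng.normal(0.0, baseline_sigma, size=n_features)
    )
    cv = design.noise.intensity_cv
    sigma = np.sqrt(np.log1p(cv**2))

    def noisy(expected: np.ndarray) -> np.ndarray:
        if sigma == 0:
            return expected.copy()
        return expected * np.exp(
            rng.normal(-0.5 * sigma**2, sigma, size=expected.shape)
        )

    columns, data, meta_rows = [], [], []
    for rep in range(1, replicates + 1):
        sample = f"fresh_r{rep}"
        columns.append(sample)
        data.append(noisy(baselines))
        meta_rows.append(dict(sample_id=sample, condition="fresh", replicate=rep))
    for s, spec in enumerate(design.strains):
        expected = baselines.copy()
        used = np.zeros(n_features, dtype=bool)
        used[: design.n_features] = design.feature_usage[s]
        prod = np.zeros(n_features, dtype=bool)
        prod[: design.n_features] = design.production_profile[s]
        depth = np.zeros(n_features)
        depth[: design.n_features] = design.depletion_depth
        expected[used] *= 1.0 - depth[used]
        expected[prod] *= design.production_fold
        for rep in range(1, replicates + 1):
            sample = f"{spec.name}_r{rep}"
            columns.append(sample)
            data.append(noisy(expected))
            meta_rows.append(dict(sample_id=sample, condition=spec.name, replicate=rep))
    feature_ids = [f"F{i:05d}" for i in range(n_features)]
    intensities = pd.DataFrame(
        np.column_stack(data), index=feature_ids, columns=columns
    )
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    return FeatureTable(intensities, meta, fresh_label="fresh")


# ---------------------------------------------------------------------------
# Co-cultures and communities

def simulate_cocultures(
    design: SyntheticDesign,
    seed: int,
    replicates: int = 3,
    cycles: int = 3,
    dt: float = 0.01,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Batch-dilution gLV dynamics for all monocultures and unordered pairs.

    Each culture starts at total OD 0.01 (split 1:1 for pairs), grows for
    24 h, and is diluted by the design's dilution factor between cycles.
    Copies are observed at every cycle boundary with log-normal noise of CV
    ``noise.abundance_cv``; the returned truth table carries the noiseless
    abundances.
    """
    rng = np.random.default_rng(seed)
    names = design.strain_names
    S = len(names)
    cultures = [(n,) for n in names] + list(itertools.combinations(names, 2))
    n0 = np.zeros((len(cultures), S))
    for c, members in enumerate(cultures):
        for m in members:
            n0[c, design.index(m)] = 0.01 / len(members)
    a_eff = design.effective_interactions()
    mu = design.mu

    states = [n0.copy()]
    n = n0.copy()
    for _ in range(cycles):
        n = integrate_glv(n, mu, a_eff, design.dilution_period_h, dt=dt)
        states.append(n.copy())
        n = n * design.dilution_factor
        n[n < EXTINCTION_OD] = 0.0
    timepoints = [design.dilution_period_h * k for k in range(cycles + 1)]

    cv = design.noise.abundance_cv
    sigma = np.sqrt(np.log1p(cv**2))
    obs_rows, truth_rows = [], []
    for t_idx, t in enumerate(timepoints):
        state = states[t_idx]
        for c, members in enumerate(cultures):
            culture_type = "mono" if len(members) == 1 else "pair"
            culture_id = "+".join(members)
            for m in members:
                true_copies = state[c, design.index(m)] * COPIES_PER_OD
                partner = (
                    "" if culture_type == "mono"
                    else members[0] if m == members[1] else members[1]
                )
                truth_rows.append(
                    dict(strain=m, culture_id=culture_id, culture_type=culture_type,
                         partner=partner, timepoint_h=t, copies=true_copies)
                )
                for rep in range(1, replicates + 1):
                    noise = (
                        1.0 if sigma == 0
                        else np.exp(rng.normal(-0.5 * sigma**2, sigma))
                    )
                    obs_rows.append(
                        dict(strain=m, culture_id=culture_id,
                             culture_type=culture_type, partner=partner,
                             timepoint_h=t, replicate=rep,
                             copies=true_copies * noise)
                    )
    return pd.DataFrame(obs_rows), pd.DataFrame(truth_rows)


def simulate_community(
    design: SyntheticDesign,
    days: int = 10,
    seed: int = 0,
    replicates: int = 10,
    dropout: str | None = None,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Serial-passage community (optionally minus one dropout strain).

    All included strains start at equal OD summing to 0.01 and are diluted
    daily. Returns per-day true and noise-observed copies per replicate.
    """
    if days < 1:
        raise ValueError("days must be >= 1")
    rng = np.random.default_rng(seed)
    names = design.strain_names
    included = [n for n in names if n != dropout]
    if dropout is not None and len(included) == len(names):
        raise ValueError(f"dropout strain {dropout!r} not in the design")
    S = len(names)
    n = np.zeros(S)
    for m in included:
        n[design.index(m)] = 0.01 / len(included)
    a_eff = design.effective_interactions()
    mu = design.mu
    cv = design.noise.abundance_cv
    sigma = np.sqrt(np.log1p(cv**2))

    rows = []
    condition = "full" if dropout is None else f"dropout-{dropout}"
    for day in range(1, days + 1):
        n = integrate_glv(n, mu, a_eff, design.dilution_period_h, dt=dt)
        for m in included:
            true_copies = n[design.index(m)] * COPIES_PER_OD
            for rep in range(1, replicates + 1):
                noise = 1.0 if sigma == 0 else np.exp(rng.normal(-0.5 * sigma**2, sigma))
                rows.append(
                    dict(condition=condition, day=day, strain=m, replicate=rep,
                         true_copies=true_copies, copies=true_copies * noise)
                )
        n = n * design.dilution_factor
        n[n < EXTINCTION_OD] = 0.0
    return pd.DataFrame(rows)


def simulate_qpcr(
    abundances: pd.DataFrame,
    standard_curves: dict,
    cq_sd: float | None = None,
    seed: int = 0,
    max_cycles: float = QPCR_MAX_CYCLES,
) -> pd.DataFrame:
    """qPCR observation model: Cq from copies through each strain's standard.

    Zero-copy samples are censored at the max cycle number and flagged.
    """
    rng = np.random.default_rng(seed)
    df = abundances.copy()
    cqs, censored = [], []
    for strain, copies in zip(df["strain"], df["copies"]):
        curve = standard_curves[strain]
        if copies <= 0:
            cqs.append(max_cycles)
            censored.append(True)
            continue
        cq = curve.intercept + curve.slope * np.log10(copies)
        if cq_sd:
            cq += rng.normal(0.0, cq_sd)
        cqs.append(min(cq, max_cycles))
        censored.append(cq >= max_cycles)
    df["cq"] = cqs
    df["censored"] = censored
    return df


def default_standard_curves(design: SyntheticDesign) -> dict:
    """Per-strain qPCR standards with realistic slopes (efficiency 90-110%)."""
    curves = {}
    for i, name in enumerate(design.strain_names):
        slope = -3.2 - 0.04 * (i % 8)  # -3.2 .. -3.48
        intercept = 35.0 + 0.3 * (i % 5)
        curves[name] = StandardCurve(strain_id=name, slope=slope, intercept=intercept)
    return curves


# ---------------------------------------------------------------------------
# Packaged default design

_STRAIN_TABLE = [
    # name,  mu,  K,   acid
    ("KB1", 1.9, 1.0, -1.1),
    ("YL2", 1.7, 0.6, -0.9),
    ("KB18", 0.7, 0.4, 0.1),
    ("YL27", 1.2, 0.8, -0.8),
    ("YL31", 1.1, 0.7, 0.2),
    ("YL32", 1.3, 0.9, 0.1),
    ("YL44", 0.6, 0.5, 0.2),
    ("YL45", 0.8, 0.6, 0.1),
    ("I46", 1.8, 0.9, -0.4),
    ("I48", 1.4, 1.0, -0.9),
    ("I49", 1.2, 0.7, -0.5),
    ("YL58", 1.8, 1.0, -0.8),
]

_TAXONOMY = {
    "KB1": "Firmicutes", "I49": "Firmicutes", "I46": "Firmicutes",
    "YL58": "Firmicutes", "YL32": "Firmicutes", "YL31": "Firmicutes",
    "KB18": "Firmicutes", "YL2": "Actinobacteria", "YL27": "Bacteroidetes",
    "I48": "Bacteroidetes", "YL44": "Verrucomicrobia", "YL45": "Proteobacteria",
}

_TREE_NEWICK = (
    "(((((KB1:0.05,I49:0.05):0.10,YL2:0.18):0.05,"
    "((YL32:0.04,YL58:0.04):0.06,(I46:0.08,(YL31:0.07,KB18:0.09):0.03):0.02):0.10):0.08,"
    "(YL27:0.10,I48:0.10):0.15):0.05,(YL44:0.30,YL45:0.28):0.06);"
)

# Depleted-feature blocks: (strains sharing the block, number of features).
# Singleton blocks are strain-exclusive; multi-strain blocks create the
# designed substrate overlaps (e.g. KB1/YL2 share exactly 33 features out of
# KB1's 370 and YL2's 128).
_FEATURE_BLOCKS = [
    (("KB1",), 127), (("YL2",), 70), (("KB18",), 120), (("YL27",), 270),
    (("YL31",), 210), (("YL32",), 40), (("YL44",), 32), (("YL45",), 100),
    (("I46",), 130), (("I48",), 50), (("I49",), 95), (("YL58",), 20),
    (("YL27", "I48"), 260),
    (("YL32", "YL58"), 170),
    (("YL27", "I48", "YL32", "YL58"), 40),
    (("KB1", "I46"), 60),
    (("KB1", "YL58"), 50),
    (("KB1", "I48"), 40),
    (("KB1", "YL2"), 33),
    (("KB1", "I49"), 60),
    (("I46", "YL32"), 50),
    (("I46", "YL58"), 40),
    (("YL31", "YL32"), 40),
    (("I49", "YL2"), 25),
    (("YL44", "I48"), 10),
    (("KB18", "YL27"), 30),
    (("YL45", "YL27"), 20),
]

_N_FEATURES = 3092
_PRODUCED_PER_STRAIN = 25
_DEPLETION_DEPTH = 0.9

# Designed pairwise interaction types (the remaining pairs are amensal, the
# higher-ranked strain suppressing the lower-ranked one).
_NEUTRAL_PAIRS = [
    ("KB1", "YL44"), ("KB1", "YL45"), ("KB18", "YL45"), ("YL44", "YL45"),
    ("KB18", "YL2"), ("YL44", "YL2"), ("YL45", "YL2"), ("YL45", "I49"),
    ("YL44", "I49"), ("KB18", "I49"), ("KB18", "YL31"),
]
_COMPETITION_PAIRS = [
    ("KB1", "YL58"), ("YL58", "YL32"), ("YL58", "I48"), ("YL58", "YL27"),
    ("YL58", "I46"), ("I48", "YL27"), ("YL31", "YL32"),
]
_PREDATION = ("KB1", "I46")  # KB1 gains, I46 loses (bacteriocin-mediated)
_COMMENSALISM = ("YL58", "YL45")  # YL45 gains, YL58 unaffected
_BACTERIOCIN_TARGETS = ["YL2", "YL31", "YL32", "I46", "I49"]  # producer KB1
_DOMINANCE = ["KB1", "YL58", "I48", "I46", "YL32", "YL27", "YL31", "I49",
              "YL2", "YL45", "YL44", "KB18"]

# Normalized interaction strengths: x_i* = 1 + c x_j* at two-species
# coexistence, with c = a_ij K_j / mu_i.
_AMENSAL_C = -0.8          # victim settles near 0.2 K  (log2 ~ -2.3)
_COMPETITION_C = -0.9      # both settle near 0.53 K (stable-gLV limit)
_PREDATION_C_GAIN = 12.0   # beneficiary near 4 K
_PREDATION_C_LOSS = -0.1875  # prey near 0.25 K
_COMMENSAL_C = 3.0         # beneficiary near 4 K


def default_taxonomy() -> dict:
    return dict(_TAXONOMY)


def default_tree_newick() -> str:
    return _TREE_NEWICK


def _build_feature_matrices(names: list[str]) -> tuple[np.ndarray, np.ndarray]:
    S = len(names)
    usage = np.zeros((S, _N_FEATURES), dtype=bool)
    cursor = 0
    for strains, count in _FEATURE_BLOCKS:
        for s in strains:
            usage[names.index(s), cursor : cursor + count] = True
        cursor += count
    production = np.zeros((S, _N_FEATURES), dtype=bool)
    for i in range(S):
        production[i, cursor : cursor + _PRODUCED_PER_STRAIN] = True
        cursor += _PRODUCED_PER_STRAIN
    if cursor > _N_FEATURES:
        raise RuntimeError("feature blocks exceed the designed universe")
    return usage, production


def _build_interactions(names, mu, cap) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    S = len(names)
    a = np.zeros((S, S))
    b = np.zeros((S, S))
    for i in range(S):
        a[i, i] = -mu[i] / cap[i]

    def set_c(victim: str, actor: str, c: float, matrix: np.ndarray) -> None:
        v, u = names.index(victim), names.index(actor)
        matrix[v, u] = c * mu[v] / cap[u]

    typed: dict[frozenset, tuple[dict, str]] = {}
    neutral = {frozenset(p) for p in _NEUTRAL_PAIRS}
    for x, y in _NEUTRAL_PAIRS:
        typed[frozenset((x, y))] = ({x: "0", y: "0"}, "neutralism")
    for x, y in _COMPETITION_PAIRS:
        set_c(x, y, _COMPETITION_C, a)
        set_c(y, x, _COMPETITION_C, a)
        typed[frozenset((x, y))] = ({x: "-", y: "-"}, "competition")
    winner, prey = _PREDATION
    set_c(winner, prey, _PREDATION_C_GAIN, a)
    w, p = names.index(winner), names.index(prey)
    b[w, p] = -_PREDATION_C_LOSS * mu[p] / cap[w]  # bacteriocin-mediated loss
    typed[frozenset(_PREDATION)] = ({winner: "+", prey: "-"}, "predation")
    actor, beneficiary = _COMMENSALISM
    set_c(beneficiary, actor, _COMMENSAL_C, a)
    typed[frozenset(_COMMENSALISM)] = ({actor: "0", beneficiary: "+"}, "commensalism")
    for target in _BACTERIOCIN_TARGETS:
        if target == prey:
            continue  # the predation prey is already covered above
        t = names.index(target)
        b[names.index("KB1"), t] = -_AMENSAL_C * mu[t] / cap[names.index("KB1")]
        typed[frozenset(("KB1", target))] = ({"KB1": "0", target: "-"}, "amensalism")
    rank = {n: r for r, n in enumerate(_DOMINANCE)}
    for x, y in itertools.combinations(names, 2):
        key = frozenset((x, y))
        if key in typed:
            continue
        actor, victim = (x, y) if rank[x] < rank[y] else (y, x)
        set_c(victim, actor, _AMENSAL_C, a)
        typed[key] = ({actor: "0", victim: "-"}, "amensalism")

    rows = []
    for x, y in itertools.combinations(sorted(names), 2):
        signs, typ = typed[frozenset((x, y))]
        rows.append(dict(strain_a=x, strain_b=y, sign_a=signs[x], sign_b=signs[y],
                         type=typ))
    return a, b, pd.DataFrame(rows)


def default_design(seed: int = 0, noise: NoiseSpec | None = None) -> SyntheticDesign:
    """The packaged 12-strain design (see module docstring)."""
    strains = [
        StrainSpec(name=n, mu=m, carrying_capacity=k, acid_coef=ac)
        for n, m, k, ac in _STRAIN_TABLE
    ]
    names = [s.name for s in strains]
    usage, production = _build_feature_matrices(names)
    mu = np.array([s.mu for s in strains])
    cap = np.array([s.carrying_capacity for s in strains])
    a, b, edge_truth = _build_interactions(names, mu, cap)
    return SyntheticDesign(
        strains=strains,
        feature_usage=usage,
        depletion_depth=np.full(_N_FEATURES, _DEPLETION_DEPTH),
        production_profile=production,
        interactions=a,
        bacteriocin=b,
        noise=noise or NoiseSpec(),
        seed=seed,
        edge_truth=edge_truth,
    )
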