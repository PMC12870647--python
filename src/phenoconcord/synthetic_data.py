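"""Synthetic cohorts with known ground truth.

The real cohorts this kind of concordance analysis targets are
access-restricted, so every input the pipeline consumes can be simulated
here with controllable structure:

* item-embedding clouds on the unit sphere whose cross-instrument semantic
  overlap is set by a construct-mixture model;
* ordinal sub-score tables drawn through a Gaussian copula with a target
  latent correlation matrix plus a shared severity factor;
* two-rater duplicates obtained by re-binning the same latents under
  independent rater noise;
* scalar and network-time-series biomarkers with specified effect sizes.

Every generator is a pure function of (config, seed): repeat calls with the
same arguments return identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .instruments_io import (
    BiomarkerTable,
    EmbeddingCloudSet,
    Instrument,
    InstrumentCatalog,
    Item,
    ScoreTable,
    Subscore,
    derive_totals,
)

# Cap treated as "infinite" concentration: the cloud collapses to its center.
_CONCENTRATION_CAP = 1e8


# ---------------------------------------------------------------------------
# Example catalog (the four-instrument, twelve-sub-score study layout)
# ---------------------------------------------------------------------------

_EXAMPLE_LAYOUT = [
    ("ADOS", "clinician", [
        ("ADOS_SocAff", "Social Affect", "soc", 6),
        ("ADOS_RRB", "Restricted & Repetitive Behaviors", "rrb", 4),
    ]),
    ("ADIR", "caregiver", [
        ("ADIR_A", "Social Interaction", "soc", 6),
        ("ADIR_B", "Communication", "comm", 6),
        ("ADIR_C", "Restricted & Repetitive Behaviors", "rrb", 4),
        ("ADIR_D", "Early Developmental Impairment", "dev", 3),
    ]),
    ("SRS", "caregiver", [
        ("SRS_Aware", "Social Awareness", "soc", 4),
        ("SRS_Cog", "Social Cognition", "soc", 5),
        ("SRS_Comm", "Social Communication", "comm", 6),
        ("SRS_Mot", "Social Motivation", "soc", 5),
        ("SRS_Mann", "Mannerisms", "rrb", 5),
    ]),
    ("SCQ", "caregiver", [
        ("SCQ_Total", "Total Score", "comm", 8),
    ]),
]

_CONSTRUCT_TEXT = {
    "soc": "difficulty with reciprocal social interaction",
    "comm": "atypical verbal and nonverbal communication",
    "rrb": "restricted interests and repetitive behavior",
    "dev": "early developmental concerns",
}


def example_catalog() -> InstrumentCatalog:
    """A four-instrument catalog mirroring the common ADOS/ADI-R/SRS/SCQ
    sub-score layout, with a small synthetic item bank per sub-score."""
    instruments, subscores, items = [], [], []
    for inst_id, informant, subs in _EXAMPLE_LAYOUT:
        instruments.append(Instrument(id=inst_id, name=inst_id, informant=informant))
        for sub_id, label, construct, n_items in subs:
            subscores.append(Subscore(id=sub_id, instrument_id=inst_id, label=label))
            for j in range(n_items):
                items.append(Item(
                    id=f"{sub_id}_item{j + 1}",
                    subscore_id=sub_id,
                    text=f"{label}: {_CONSTRUCT_TEXT[construct]} (item {j + 1})",
                ))
    return InstrumentCatalog(instruments=instruments, subscores=subscores, items=items)


def example_construct_assignment() -> dict[str, dict[str, float]]:
    """Dominant-construct mixture per sub-score for the example catalog."""
    out: dict[str, dict[str, float]] = {}
    for _, _, subs in _EXAMPLE_LAYOUT:
        for sub_id, _, construct, _ in subs:
            out[sub_id] = {construct: 1.0}
    return out


# ---------------------------------------------------------------------------
# Embedding clouds
# ---------------------------------------------------------------------------

@dataclass
class SemanticSimConfig:
    """Construct-mixture model for synthetic item embeddings.

    Each construct has a center on the unit sphere (supplied or drawn once
    from the seed).  An item of a sub-score picks a construct according to
    the sub-score's mixture weights and is sampled around that center with
    isotropic Gaussian noise of scale ``1/concentration``, then re-projected
    to the sphere; higher concentration means a tighter cloud.
    """

    constructs: list[str]
    assignment: dict[str, dict[str, float]]
    dim: int = 16
    concentration: float | dict[str, float] = 8.0
    items_per_subscore: int | dict[str, int] = 6
    centers: dict[str, np.ndarray] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 2:
            raise ValueError("embedding dimension must be >= 2")
        for sub, weights in self.assignment.items():
            total = sum(weights.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"mixture weights for {sub!r} sum to {total}, not 1")
            if any(w < 0 for w in weights.values()):
                raise ValueError(f"negative mixture weight for {sub!r}")

    def concentration_of(self, subscore_id: str) -> float:
        if isinstance(self.concentration, dict):
            kappa = self.concentration[subscore_id]
        else:
            kappa = self.concentration
        if kappa < 0:
            raise ValueError("concentration must be nonnegative")
        return min(float(kappa), _CONCENTRATION_CAP)

    def n_items_of(self, subscore_id: str, catalog: InstrumentCatalog) -> int:
        from_catalog = len(catalog.items_for(subscore_id))
        if from_catalog:
            return from_catalog
        if isinstance(self.items_per_subscore, dict):
            return int(self.items_per_subscore[subscore_id])
        return int(self.items_per_subscore)


def _construct_centers(cfg: SemanticSimConfig) -> dict[str, np.ndarray]:
    if cfg.centers is not None:
        out = {}
        for c, v in cfg.centers.items():
            v = np.asarray(v, dtype=float)
            out[c] = v / np.linalg.norm(v)
        return out
    rng = np.random.default_rng([cfg.seed, 0])
    centers = {}
    for c in cfg.constructs:
        v = rng.standard_normal(cfg.dim)
        centers[c] = v / np.linalg.norm(v)
    return centers


def generate_item_embeddings(
    cfg: SemanticSimConfig, catalog: InstrumentCatalog
) -> EmbeddingCloudSet:
    """Sample a unit-sphere embedding cloud for every catalog sub-score."""
    centers = _construct_centers(cfg)
    rng = np.random.default_rng([cfg.seed, 1])
    clouds: dict[str, np.ndarray] = {}
    item_ids: dict[str, list[str]] = {}
    for sub in catalog.subscore_ids():
        if sub not in cfg.assignment:
            raise ValueError(f"subscore {sub!r} missing from assignment")
        weights = cfg.assignment[sub]
        names = list(weights)
        probs = np.array([weights[c] for c in names])
        kappa = cfg.concentration_of(sub)
        n = cfg.n_items_of(sub, catalog)
        vecs = np.empty((n, cfg.dim))
        for i in range(n):
            construct = names[rng.choice(len(names), p=probs)]
            center = centers[construct]
            if kappa >= _CONCENTRATION_CAP:
                vecs[i] = center
            else:
                v = center + rng.standard_normal(cfg.dim) / kappa
                vecs[i] = v / np.linalg.norm(v)
        clouds[sub] = vecs
        cat_items = catalog.items_for(sub)
        item_ids[sub] = (
            [it.id for it in cat_items][:n]
            if len(cat_items) == n
            else [f"{sub}_item{i + 1}" for i in range(n)]
        )
    return EmbeddingCloudSet(clouds=clouds, item_ids=item_ids)


# ---------------------------------------------------------------------------
# Ordinal score tables (Gaussian copula)
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Latent-Gaussian model for correlated ordinal sub-scores.

    Latents are multivariate normal with correlation ``latent_corr`` among
    residuals plus a shared severity factor with per-sub-score loadings,
    giving total latent correlation
    ``sqrt(1-l_i^2) sqrt(1-l_j^2) C_ij + l_i l_j``.  Each latent is mapped
    to its ordinal range by equiprobable standard-normal quantile cut-points
    (a Gaussian copula), so rank structure survives binning up to a known
    attenuation.
    """

    n_participants: int
    subscores: list[str]
    latent_corr: np.ndarray
    score_levels: dict[str, tuple[int, int]]
    severity_loading: float | dict[str, float] = 0.0
    rater_noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.latent_corr = np.asarray(self.latent_corr, dtype=float)
        k = len(self.subscores)
        if self.latent_corr.shape != (k, k):
            raise ValueError("latent_corr shape must match subscore count")
        if not np.allclose(self.latent_corr, self.latent_corr.T, atol=1e-12):
            raise ValueError("latent_corr must be symmetric")
        if np.linalg.eigvalsh(self.latent_corr).min() < -1e-8:
            raise ValueError("latent_corr is not positive semidefinite")
        for sub, (lo, hi) in self.score_levels.items():
            if hi - lo + 1 < 2:
                raise ValueError(f"subscore {sub!r} needs >= 2 score levels")

    def loadings(self) -> np.ndarray:
        if isinstance(self.severity_loading, dict):
            lam = np.array([self.severity_loading.get(s, 0.0) for s in self.subscores])
        else:
            lam = np.full(len(self.subscores), float(self.severity_loading))
        if (np.abs(lam) > 1).any():
            raise ValueError("severity loadings must lie in [-1, 1]")
        return lam


def total_latent_corr(cfg: CohortConfig) -> np.ndarray:
    """Effective latent correlation including the severity factor."""
    lam = cfg.loadings()
    d = np.sqrt(1.0 - lam**2)
    sigma = np.outer(d, d) * cfg.latent_corr + np.outer(lam, lam)
    np.fill_diagonal(sigma, 1.0)
    return sigma


def bin_to_ordinal(z: np.ndarray, lo: int, hi: int) -> np.ndarray:
    """Map standard-normal draws to ordinal scores by equiprobable quantile
    cut-points; monotone nondecreasing in z by construction."""
    levels = hi - lo + 1
    cuts = norm.ppf(np.arange(1, levels) / levels)
    return lo + np.searchsorted(cuts, z, side="right")


def _bin_latents(
    latents: pd.DataFrame, cfg: CohortConfig, catalog: InstrumentCatalog
) -> ScoreTable:
    values = pd.DataFrame(index=latents.index)
    for sub in cfg.subscores:
        lo, hi = cfg.score_levels[sub]
        values[sub] = bin_to_ordinal(latents[sub].to_numpy(), lo, hi)
    return ScoreTable(
        values=values,
        totals=derive_totals(values, catalog),
        dataset_id="synthetic",
        latents=latents,
    )


def generate_score_table(cfg: CohortConfig, catalog: InstrumentCatalog) -> ScoreTable:
    """Draw a complete ordinal score table; latents and severity retained."""
    n, k = cfg.n_participants, len(cfg.subscores)
    rng = np.random.default_rng([cfg.seed, 2])
    lam = cfg.loadings()
    d = np.sqrt(1.0 - lam**2)
    # jitter keeps Cholesky stable for singular-but-PSD targets
    chol = np.linalg.cholesky(cfg.latent_corr + 1e-10 * np.eye(k))
    severity = rng.standard_normal(n)
    resid = rng.standard_normal((n, k)) @ chol.T
    latents_arr = resid * d + np.outer(severity, lam)
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")
    latents = pd.DataFrame(latents_arr, index=ids, columns=cfg.subscores)
    table = _bin_latents(latents, cfg, catalog)
    table.severity = pd.Series(severity, index=ids, name="severity")
    return table


def generate_rater_pair(
    table: ScoreTable,
    cfg: CohortConfig,
    catalog: InstrumentCatalog,
    rater_noise_sd: float | None = None,
    seed: int = 0,
) -> tuple[ScoreTable, ScoreTable]:
    """Two-rater duplicates of a synthetic table (e.g. parent vs teacher).

    Each rater observes the same latents corrupted by independent Gaussian
    rater noise before re-binning; ``rater_noise_sd = 0`` returns two
    identical tables.
    """
    if table.latents is None:
        raise ValueError("table has no latent provenance; generate it synthetically")
    sd = cfg.rater_noise_sd if rater_noise_sd is None else float(rater_noise_sd)
    if sd < 0:
        raise ValueError("rater_noise_sd must be >= 0")
    rng = np.random.default_rng([seed, 3])
    out = []
    for _ in range(2):
        noisy = table.latents + rng.standard_normal(table.latents.shape) * sd
        rater = _bin_latents(noisy, cfg, catalog)
        rater.severity = table.severity
        out.append(rater)
    return out[0], out[1]


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------

DEFAULT_NETWORKS = [
    "SalVentAttnA", "SalVentAttnB",
    "ContA", "ContB", "ContC",
    "DefaultA", "DefaultB", "DefaultC",
]

# E[s | s > median] - E[s | s <= median] for standard-normal s, and the
# within-half variance; used to calibrate the median-split effect size.
_HALF_NORMAL_GAP = 2.0 * np.sqrt(2.0 / np.pi)
_HALF_NORMAL_VAR = 1.0 - 2.0 / np.pi


@dataclass
class BiomarkerConfig:
    """Targets for the synthetic biomarker generator.

    ``effect_size`` is the standardized mean difference (Cohen's d) of the
    scalar biomarker between the high- and low-severity halves of the
    cohort; ``imaging_corr`` sets each imaging scalar's Pearson correlation
    with the severity latent; network time series are drawn from a
    multivariate normal with correlation ``network_corr``.
    """

    effect_size: float = 0.0
    imaging_corr: dict[str, float] = field(
        default_factory=lambda: {"total_brain_volume": 0.0, "mean_cortical_thickness": 0.0}
    )
    n_networks: int = 8
    T: int = 150
    network_corr: np.ndarray | None = None
    network_labels: list[str] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.T < 2:
            raise ValueError("time-series length T must be >= 2")
        for name, r in self.imaging_corr.items():
            if abs(r) > 1:
                raise ValueError(f"imaging_corr[{name!r}] must lie in [-1, 1]")
        if self.network_corr is None:
            self.network_corr = np.eye(self.n_networks)
        self.network_corr = np.asarray(self.network_corr, dtype=float)
        if self.network_corr.shape != (self.n_networks, self.n_networks):
            raise ValueError("network_corr shape must be (n_networks, n_networks)")
        if np.linalg.eigvalsh(self.network_corr).min() < -1e-8:
            raise ValueError("network_corr is not positive semidefinite")
        if self.network_labels is None:
            self.network_labels = (
                DEFAULT_NETWORKS
                if self.n_networks == len(DEFAULT_NETWORKS)
                else [f"net{i + 1}" for i in range(self.n_networks)]
            )


def _severity_slope(effect_size: float) -> float:
    """Slope a in  y = a*severity + e  (e ~ N(0,1)) giving the requested
    median-split Cohen's d for standard-normal severity."""
    d = float(effect_size)
    denom = _HALF_NORMAL_GAP**2 - _HALF_NORMAL_VAR * d**2
    if denom <= 0:
        raise ValueError(f"effect_size {d} is unattainable under unit noise")
    return d / np.sqrt(denom)


def generate_biomarkers(
    cfg: BiomarkerConfig,
    table: ScoreTable,
    severity: pd.Series | np.ndarray | None = None,
) -> BiomarkerTable:
    """Scalar biomarkers and network time series tied to cohort severity.

    The PRS-like scalar is ``slope * severity + N(0, 1)`` with the slope
    calibrated so a median split on severity yields the configured
    standardized mean difference.  Imaging scalars are affine in severity
    with noise set by ``imaging_corr`` (|r| = 1 gives zero noise), then
    shifted to realistic units.
    """
    if severity is None:
        severity = table.severity
    if severity is None:
        raise ValueError("severity vector required (table lacks synthetic severity)")
    s = np.asarray(severity, dtype=float)
    if s.size != table.n_participants:
        raise ValueError("severity length must equal the number of participants")
    s_std = (s - s.mean()) / s.std()

    rng = np.random.default_rng([cfg.seed, 4])
    scalars = pd.DataFrame(index=table.values.index)
    scalars["prs"] = _severity_slope(cfg.effect_size) * s_std + rng.standard_normal(s.size)

    units = {"total_brain_volume": (1.2e6, 1.1e5), "mean_cortical_thickness": (2.55, 0.12)}
    for name, r in cfg.imaging_corr.items():
        base = r * s_std + np.sqrt(1.0 - r**2) * rng.standard_normal(s.size)
        loc, scale = units.get(name, (0.0, 1.0))
        scalars[name] = loc + scale * base

    chol = np.linalg.cholesky(cfg.network_corr + 1e-10 * np.eye(cfg.n_networks))
    timeseries = {
        pid: (rng.standard_normal((cfg.T, cfg.n_networks)) @ chol.T).T
        for pid in table.values.index
    }
    return BiomarkerTable(
        scalars=scalars, timeseries=timeseries, network_labels=list(cfg.network_labels)
    )


# ---------------------------------------------------------------------------
# Study-shaped default cohort
# ---------------------------------------------------------------------------

#: Raw-score ranges typical of each instrument's published scoring sheets.
DEFAULT_SCORE_LEVELS: dict[str, tuple[int, int]] = {
    "ADOS_SocAff": (0, 20), "ADOS_RRB": (0, 8),
    "ADIR_A": (0, 30), "ADIR_B": (0, 26), "ADIR_C": (0, 12), "ADIR_D": (0, 5),
    "SRS_Aware": (0, 24), "SRS_Cog": (0, 36), "SRS_Comm": (0, 66),
    "SRS_Mot": (0, 33), "SRS_Mann": (0, 36),
    "SCQ_Total": (0, 39),
}


def block_latent_corr(
    subscores: list[str],
    instrument_of: dict[str, str],
    within: float = 0.7,
    cross: float = 0.25,
) -> np.ndarray:
    """Within-instrument/cross-instrument block correlation matrix,
    projected to the nearest valid correlation matrix if needed."""
    k = len(subscores)
    corr = np.full((k, k), cross)
    for i in range(k):
        for j in range(k):
            if instrument_of[subscores[i]] == instrument_of[subscores[j]]:
                corr[i, j] = within
    np.fill_diagonal(corr, 1.0)
    return nearest_correlation(corr)


def nearest_correlation(mat: np.ndarray, eig_floor: float = 1e-8) -> np.ndarray:
    """Eigenvalue-clip a symmetric matrix and rescale to unit diagonal."""
    mat = (mat + mat.T) / 2.0
    vals, vecs = np.linalg.eigh(mat)
    if vals.min() >= eig_floor:
        return mat
    vals = np.clip(vals, eig_floor, None)
    fixed = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(fixed))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return fixed


def write_simulated_study(
    out_dir,
    seed: int = 0,
    n_participants: int = 500,
    within: float = 0.7,
    cross: float = 0.18,
    severity_loading: float = 0.3,
    effect_size: float = 0.5,
    imaging_corr: dict[str, float] | None = None,
    T: int = 150,
) -> dict:
    """Simulate a full study and write every pipeline input to ``out_dir``.

    Emits ``catalog.json``, ``embeddings.tsv``, ``scores.csv``,
    ``biomarkers.csv``, ``timeseries.csv`` (long format) and
    ``ground_truth.json`` recording the generating targets.  Returns the
    ground-truth dict.
    """
    import json
    from pathlib import Path

    from .instruments_io import (
        save_instrument_catalog,
        write_biomarker_table,
        write_embedding_table,
        write_score_table,
    )

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    catalog = example_catalog()
    save_instrument_catalog(catalog, out / "catalog.json")

    sem_cfg = SemanticSimConfig(
        constructs=sorted(_CONSTRUCT_TEXT),
        assignment=example_construct_assignment(),
        dim=16,
        concentration=8.0,
        seed=seed,
    )
    clouds = generate_item_embeddings(sem_cfg, catalog)
    write_embedding_table(clouds, out / "embeddings.tsv")

    cohort = default_cohort_config(
        catalog, n_participants=n_participants, within=within, cross=cross,
        severity_loading=severity_loading, seed=seed,
    )
    table = generate_score_table(cohort, catalog)
    write_score_table(table, out / "scores.csv")

    bio_cfg = BiomarkerConfig(
        effect_size=effect_size,
        imaging_corr=imaging_corr
        or {"total_brain_volume": 0.15, "mean_cortical_thickness": 0.1},
        T=T,
        seed=seed,
    )
    markers = generate_biomarkers(bio_cfg, table)
    write_biomarker_table(markers, out / "biomarkers.csv")

    rows = []
    for pid, ts in markers.timeseries.items():
        for ni, label in enumerate(markers.network_labels):
            for t in range(ts.shape[1]):
                rows.append((pid, label, t, ts[ni, t]))
    ts_df = pd.DataFrame(rows, columns=["participant_id", "network", "t", "value"])
    ts_df.to_csv(out / "timeseries.csv", index=False, lineterminator="\n",
                 float_format="%.10g")

    truth = {
        "seed": seed,
        "n_participants": n_participants,
        "latent_corr_within": within,
        "latent_corr_cross": cross,
        "severity_loading": severity_loading,
        "effect_size": effect_size,
        "imaging_corr": bio_cfg.imaging_corr,
        "n_networks": bio_cfg.n_networks,
        "T": T,
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=2))
    return truth


def default_cohort_config(
    catalog: InstrumentCatalog,
    n_participants: int = 500,
    within: float = 0.7,
    cross: float = 0.18,
    severity_loading: float = 0.3,
    seed: int = 0,
) -> CohortConfig:
    """Study-shaped cohort: strong within-instrument correlation, weak
    cross-instrument correlation, and a moderate shared severity factor.

    With the default loading 0.3 the severity factor adds 0.09 to every
    latent correlation (scaled by sqrt(1-0.09) per side), so the effective
    cross-instrument latent correlation is about 0.25 and the
    within-instrument one about 0.73 — the weak-cross / strong-within regime
    the concordance analysis is designed to probe."""
    subscores = catalog.subscore_ids()
    inst = {s: catalog.instrument_of(s) for s in subscores}
    levels = {
        s: DEFAULT_SCORE_LEVELS.get(s, (0, 20)) for s in subscores
    }
    return CohortConfig(
        n_participants=n_participants,
        subscores=subscores,
        latent_corr=block_latent_corr(subscores, inst, within=within, cross=cross),
        score_levels=levels,
        severity_loading=severity_loading,
        seed=seed,
    )
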