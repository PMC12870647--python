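"""Bootstrap k-means stratification and cross-instrument cluster overlap.

Participants are clustered separately on each instrument's sub-scores; the
congruence of the two partitions is the percentage of participants placed
in the same cluster after optimally matching cluster labels with the
Hungarian algorithm.  Repeating this over bootstrap resamples yields a
distribution of stratification congruency per (instrument pair, k).

Note the chance floor: because labels are matched optimally before
counting, the expected overlap of two independent partitions exceeds 1/k.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.optimize
from sklearn.cluster import KMeans

from .instruments_io import InstrumentCatalog, ScoreTable


@dataclass
class ClusterAssignment:
    participant_ids: list[str]
    labels: np.ndarray
    k: int
    inertia: float
    seed: int


def kmeans_cluster(
    features: np.ndarray | pd.DataFrame, k: int, seed: int = 0
) -> ClusterAssignment:
    """Lloyd's k-means from k distinct data points chosen uniformly at random.

    One random initialization per call (no multi-restart), deterministic
    given the seed.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if isinstance(features, pd.DataFrame):
        ids = [str(i) for i in features.index]
        x = features.to_numpy(dtype=float)
    else:
        x = np.asarray(features, dtype=float)
        ids = [str(i) for i in range(len(x))]
    if len(x) < k:
        raise ValueError(f"n={len(x)} is smaller than k={k}")
    km = KMeans(n_clusters=k, init="random", n_init=1, random_state=seed).fit(x)
    return ClusterAssignment(
        participant_ids=ids,
        labels=km.labels_.astype(int),
        k=k,
        inertia=float(km.inertia_),
        seed=seed,
    )


def match_overlap(a: ClusterAssignment, b: ClusterAssignment) -> float:
    """Percent of participants co-assigned after optimal label matching.

    Builds the k x k label contingency table and maximizes its trace over
    label permutations with the Hungarian algorithm; ties broken
    deterministically by the solver's lowest-index convention.
    """
    if a.participant_ids != b.participant_ids:
        raise ValueError("assignments cover different participants")
    if a.k != b.k:
        raise ValueError("assignments use different k")
    k, n = a.k, len(a.labels)
    contingency = np.zeros((k, k))
    np.add.at(contingency, (a.labels, b.labels), 1)
    rows, cols = scipy.optimize.linear_sum_assignment(-contingency)
    return 100.0 * float(contingency[rows, cols].sum()) / n


@dataclass
class OverlapDistribution:
    """Bootstrap overlap percentages for one instrument pair and one k."""

    instrument_pair: tuple[str, str]
    k: int
    overlaps: np.ndarray  # length n_boot, percent

    @property
    def median(self) -> float:
        return float(np.median(self.overlaps))

    @property
    def iqr(self) -> tuple[float, float]:
        lo, hi = np.percentile(self.overlaps, [25, 75])
        return float(lo), float(hi)


def standardize_features(values: pd.DataFrame) -> pd.DataFrame:
    """Z-score each sub-score column (population sd)."""
    sd = values.std(axis=0, ddof=0)
    if (sd == 0).any():
        raise ValueError(f"zero-variance subscore {sd.index[(sd == 0).argmax()]!r}")
    return (values - values.mean(axis=0)) / sd


def bootstrap_overlap(
    table: ScoreTable,
    catalog: InstrumentCatalog,
    pair: tuple[str, str],
    k: int,
    n_boot: int = 100,
    seed: int = 0,
) -> OverlapDistribution:
    """Bootstrap distribution of cluster overlap for one instrument pair.

    Per replicate one bootstrap sample of participants (with replacement,
    full n) is drawn and shared by both instruments; each instrument is
    clustered once on its own standardized sub-scores and the matched
    overlap recorded.  Duplicated participants count with multiplicity.
    Replicate seeds derive from the master seed by a counter scheme, so the
    full distribution is reproducible.
    """
    inst_a, inst_b = pair
    cols_a = [c for c in catalog.subscore_ids(inst_a) if c in table.values.columns]
    cols_b = [c for c in catalog.subscore_ids(inst_b) if c in table.values.columns]
    if not cols_a or not cols_b:
        raise ValueError(f"instrument pair {pair} has no subscore columns in the table")
    n = table.n_participants
    if n < k:
        raise ValueError(f"n={n} too small for k={k}")
    feats = standardize_features(table.values[cols_a + cols_b])
    xa = feats[cols_a].to_numpy()
    xb = feats[cols_b].to_numpy()

    rng = np.random.default_rng([seed, 5])
    overlaps = np.empty(n_boot)
    for r in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep_seed = (seed * 1000 + r) % (2**31)
        ca = kmeans_cluster(xa[idx], k, seed=rep_seed)
        cb = kmeans_cluster(xb[idx], k, seed=rep_seed + 1)
        overlaps[r] = match_overlap(ca, cb)
    return OverlapDistribution(instrument_pair=(inst_a, inst_b), k=k, overlaps=overlaps)


def overlap_grid(
    table: ScoreTable,
    catalog: InstrumentCatalog,
    instruments: list[str],
    ks: list[int] = (2, 3, 4, 5),
    n_boot: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Long-format overlap distributions for every instrument pair and k."""
    records = []
    for i, a in enumerate(instruments):
        for b in instruments[i + 1:]:
            for k in ks:
                dist = bootstrap_overlap(table, catalog, (a, b), k, n_boot=n_boot, seed=seed)
                for rep, val in enumerate(dist.overlaps):
                    records.append(
                        {"instrument_a": a, "instrument_b": b, "k": k,
                         "replicate": rep, "overlap_pct": val}
                    )
    return pd.DataFrame.from_records(records)
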