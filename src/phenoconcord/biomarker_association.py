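"""Biomarker-association procedures: group tests, tiered correlations,
and network-connectivity associations.

Three procedures mirror how behavioral scores are usually related to
genomic and imaging measures:

1. *Median-split group test* — participants are split at each behavioral
   score's median into low/high groups and the scalar biomarker (e.g. a
   polygenic risk score) is compared with Welch's unequal-variance t-test,
   with Benjamini-Hochberg FDR correction across the family of scores.
2. *Tiered score-imaging correlations* — Pearson r between each score and
   each imaging scalar, annotated by raw-p tier (p<0.05 significant,
   p<0.15 suggestive).
3. *Connectivity associations* — per-participant network-by-network
   functional connectivity (Pearson correlation of mean BOLD time series),
   with each unique network pair correlated against instrument totals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .instruments_io import BiomarkerTable, ScoreTable, inner_join_participants

TIER_BOUNDS = (0.05, 0.10, 0.15)


def tier_label(p: float) -> str:
    for bound in TIER_BOUNDS:
        if p < bound:
            return f"p<{bound:g}"
    return "ns"


def median_split(scores: pd.Series | np.ndarray) -> np.ndarray:
    """Split values at the median; ties at the median go to the low group.

    Returns a boolean array, True = high group.  All-equal input leaves the
    high group empty and is an error.
    """
    x = np.asarray(scores, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 values for a median split")
    high = x > np.median(x)
    if not high.any():
        raise ValueError("degenerate split: no values above the median")
    return high


@dataclass
class GroupTestResult:
    score: str
    t: float
    df: float
    p: float
    n_low: int
    n_high: int
    p_adjusted: float | None = None
    significant: bool | None = None


def welch_t_test(x: np.ndarray, y: np.ndarray, score: str = "") -> GroupTestResult:
    """Welch's two-sample t-test with Satterthwaite degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both groups need n >= 2")
    if x.std(ddof=1) == 0 and y.std(ddof=1) == 0 and x.mean() == y.mean():
        raise ValueError("zero variance in both groups with zero spread")
    res = scipy.stats.ttest_ind(x, y, equal_var=False)
    return GroupTestResult(
        score=score, t=float(res.statistic), df=float(res.df),
        p=float(res.pvalue), n_low=x.size, n_high=y.size,
    )


def bh_fdr(pvals: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (rejection flags, adjusted p-values)."""
    pvals = np.asarray(pvals, dtype=float)
    if pvals.size == 0:
        return np.array([], dtype=bool), np.array([])
    reject, p_adj, _, _ = multipletests(pvals, alpha=q, method="fdr_bh")
    return reject, p_adj


def median_split_tests(
    table: ScoreTable,
    biomarkers: BiomarkerTable,
    biomarker: str = "prs",
    instruments: list[str] | None = None,
    q: float = 0.05,
) -> list[GroupTestResult]:
    """Welch tests of a scalar biomarker across median-split halves of each
    instrument total, BH-corrected across the instrument family."""
    table, biomarkers = inner_join_participants(table, biomarkers)
    instruments = instruments or list(table.totals.columns)
    marker = biomarkers.scalars[biomarker].to_numpy(dtype=float)
    results = []
    for inst in instruments:
        high = median_split(table.totals[inst])
        res = welch_t_test(marker[high], marker[~high], score=inst)
        res.n_low, res.n_high = int((~high).sum()), int(high.sum())
        results.append(res)
    reject, p_adj = bh_fdr(np.array([r.p for r in results]), q=q)
    for r, rej, pa in zip(results, reject, p_adj):
        r.significant = bool(rej)
        r.p_adjusted = float(pa)
    return results


@dataclass
class TieredAssociation:
    score: str
    biomarker: str
    r: float
    p: float
    tier: str


def tiered_correlations(
    table: ScoreTable,
    biomarkers: BiomarkerTable,
    scores: list[str] | None = None,
    metrics: list[str] | None = None,
) -> list[TieredAssociation]:
    """Pearson r between each behavioral score and each imaging metric,
    annotated by raw-p significance tier (no FDR; tiers are descriptive)."""
    table, biomarkers = inner_join_participants(table, biomarkers)
    if table.n_participants < 4:
        raise ValueError("fewer than 4 joined participants")
    scores = scores or list(table.values.columns)
    metrics = metrics or [c for c in biomarkers.scalars.columns if c != "prs"]
    out = []
    for sc in scores:
        x = (table.values[sc] if sc in table.values.columns else table.totals[sc])
        for m in metrics:
            r, p = scipy.stats.pearsonr(x, biomarkers.scalars[m])
            out.append(TieredAssociation(score=sc, biomarker=m, r=float(r),
                                         p=float(p), tier=tier_label(float(p))))
    return out


# ---------------------------------------------------------------------------
# Functional connectivity
# ---------------------------------------------------------------------------

@dataclass
class ConnectivityMatrix:
    """Network-by-network Pearson connectivity for one participant."""

    labels: list[str]
    entries: np.ndarray  # (N, N), symmetric, unit diagonal

    @property
    def unique_pairs(self) -> np.ndarray:
        """Upper-triangle values flattened in row-major order (length
        N(N-1)/2)."""
        n = len(self.labels)
        iu = np.triu_indices(n, k=1)
        return self.entries[iu]

    def pair_labels(self) -> list[tuple[str, str]]:
        n = len(self.labels)
        return [(self.labels[i], self.labels[j])
                for i in range(n) for j in range(i + 1, n)]


def connectivity_matrix(ts: np.ndarray, labels: list[str] | None = None) -> ConnectivityMatrix:
    """Pearson correlation between network-mean time series.

    ``ts`` is (n_networks, T) with T >= 3; a constant row is an error since
    its correlation is undefined.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2 or ts.shape[1] < 3:
        raise ValueError("time series must be (n_networks, T) with T >= 3")
    n = ts.shape[0]
    labels = labels or [f"net{i + 1}" for i in range(n)]
    sd = ts.std(axis=1)
    if (sd == 0).any():
        raise ValueError(f"constant time series for network {labels[int((sd == 0).argmax())]!r}")
    return ConnectivityMatrix(labels=list(labels), entries=np.corrcoef(ts))


def connectivity_associations(
    conns: dict[str, ConnectivityMatrix],
    totals: pd.DataFrame,
) -> pd.DataFrame:
    """Correlate every unique network-pair connectivity with each total score.

    ``conns`` maps participant id -> ConnectivityMatrix (identical network
    ordering); ``totals`` is participants x instruments.  Returns a long
    edge-list DataFrame with one row per (network pair, instrument): Pearson
    r, p, tier, and the cohort mean |connectivity| as edge weight for
    circle-plot rendering.
    """
    pids = list(totals.index)
    missing = [p for p in pids if p not in conns]
    if missing:
        raise ValueError(f"participants without connectivity: {missing[:3]}...")
    first = conns[pids[0]]
    pair_labels = first.pair_labels()
    mat = np.vstack([conns[p].unique_pairs for p in pids])  # (n, n_pairs)
    rows = []
    for j, (na, nb) in enumerate(pair_labels):
        edge = mat[:, j]
        weight = float(np.abs(edge).mean())
        for inst in totals.columns:
            r, p = scipy.stats.pearsonr(edge, totals[inst])
            rows.append({
                "network_a": na, "network_b": nb, "instrument": inst,
                "r": float(r), "p": float(p), "tier": tier_label(float(p)),
                "mean_abs_connectivity": weight,
            })
    return pd.DataFrame(rows)


def group_tests_frame(results: list[GroupTestResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "score": r.score, "t": r.t, "df": r.df, "p": r.p,
        "n_low": r.n_low, "n_high": r.n_high,
        "p_adjusted": r.p_adjusted, "significant": r.significant,
    } for r in results])


def tiered_frame(assocs: list[TieredAssociation]) -> pd.DataFrame:
    return pd.DataFrame([{
        "score": a.score, "biomarker": a.biomarker, "r": a.r, "p": a.p, "tier": a.tier,
    } for a in assocs])
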