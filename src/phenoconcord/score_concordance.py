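"""Participant-level sub-score correlations and semantic-behavioral alignment.

Two matrices drive this stage: the semantic-similarity matrix ``w`` over
sub-scores (from the optimal-transport stage) and the Pearson correlation
matrix ``a`` of participant raw scores.  For each sub-score ``i`` the
alignment coefficient ``beta_i`` is the no-intercept least-squares slope of
``a_i`` on ``w_i`` over the off-diagonal entries:

    beta_i = <w_i, a_i> / <w_i, w_i>

A beta near 1 means participant-level score correlations track semantic
similarity; a beta near 0 means semantically overlapping sub-scores are
behaviorally unrelated.  Signed correlations are used in the regression;
magnitudes are provided for heatmap display only.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments_io import ScoreTable
from .semantic_similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class CorrelationMatrix:
    """Pairwise Pearson correlations of raw sub-scores across participants."""

    subscores: list[str]
    entries: pd.DataFrame  # signed r
    n_used: int

    @property
    def magnitudes(self) -> pd.DataFrame:
        """|r| view used for heatmap display."""
        return self.entries.abs()

    def row(self, subscore_id: str) -> np.ndarray:
        others = [s for s in self.subscores if s != subscore_id]
        return self.entries.loc[subscore_id, others].to_numpy(dtype=float)

    def cross_instrument_values(self, instrument_of: dict[str, str]) -> np.ndarray:
        """Off-diagonal entries whose two sub-scores belong to different
        instruments (each unordered pair once)."""
        vals = []
        for i, a in enumerate(self.subscores):
            for b in self.subscores[i + 1:]:
                if instrument_of[a] != instrument_of[b]:
                    vals.append(self.entries.loc[a, b])
        return np.array(vals)


def correlation_matrix(
    table: ScoreTable, subscores: list[str] | None = None
) -> CorrelationMatrix:
    """Pearson correlation matrix over all complete participants.

    Tables are complete by construction, so every pair uses the same n.
    """
    subscores = subscores or list(table.values.columns)
    data = table.values[subscores]
    if len(data) < 3:
        raise ValueError("need at least 3 complete participants")
    variances = data.var(axis=0, ddof=0)
    zero = variances[variances == 0]
    if len(zero):
        raise ValueError(f"zero-variance subscore {zero.index[0]!r}")
    corr = np.corrcoef(data.to_numpy(dtype=float), rowvar=False)
    entries = pd.DataFrame(corr, index=subscores, columns=subscores)
    return CorrelationMatrix(subscores=list(subscores), entries=entries, n_used=len(data))


@dataclass
class AlignmentResult:
    """Per-sub-score no-intercept regression slopes of a_i on w_i."""

    beta: pd.Series  # NaN where w_i is all zero

    def to_frame(self) -> pd.DataFrame:
        return self.beta.rename("beta").to_frame()


def alignment_coefficients(
    sim: SimilarityMatrix, corr: CorrelationMatrix
) -> AlignmentResult:
    """Closed-form beta_i = <w_i, a_i>/<w_i, w_i> per sub-score row.

    Both matrices must share the same sub-score ordering; the diagonal is
    excluded from every row.  An all-zero similarity row leaves beta
    undefined (reported as NaN with a warning).
    """
    if sim.subscores != corr.subscores:
        raise ValueError("similarity and correlation matrices order subscores differently")
    betas = {}
    for s in sim.subscores:
        w = sim.row(s)
        a = corr.row(s)
        denom = float(w @ w)
        if denom == 0.0:
            logger.warning("subscore %s: all-zero similarity row, beta undefined", s)
            betas[s] = np.nan
        else:
            betas[s] = float(w @ a) / denom
    return AlignmentResult(beta=pd.Series(betas, name="beta"))
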