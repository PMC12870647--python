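"""Threshold-based diagnostic classification and cross-instrument agreement.

Each instrument classifies a participant as "diagnosed" when its total
score meets a cutoff (``total`` rule), or when every listed sub-score meets
its own cutoff (``subscore_conjunction`` rule, the conventional ADI-R
usage: A >= 10, B >= 7, C >= 3).  Agreement between two instruments is the
percentage of participants receiving the same label on both, and Cohen's
kappa corrects that for chance agreement implied by the two marginals.

Cutoffs are inclusive (score >= threshold diagnoses) by default; a strict
(>) mode is available via ``strict=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .instruments_io import ScoreTable

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ThresholdRule:
    """Diagnostic rule: ``total`` cutoff or sub-score conjunction.

    ``thresholds`` maps an instrument id (kind="total") or sub-score ids
    (kind="subscore_conjunction") to integer cutoffs in raw-score units.
    """

    kind: str
    thresholds: dict[str, int] = field(default_factory=dict)
    strict: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ("total", "subscore_conjunction"):
            raise ValueError(f"unknown rule kind {self.kind!r}")
        if not self.thresholds:
            raise ValueError("rule needs at least one threshold")
        if any(t < 0 for t in self.thresholds.values()):
            raise ValueError("thresholds must be >= 0")
        if self.kind == "total" and len(self.thresholds) != 1:
            raise ValueError("total rule takes exactly one threshold")


def classify(table: ScoreTable, rule: ThresholdRule) -> pd.Series:
    """Boolean diagnosis per participant under the rule."""
    def meets(series: pd.Series, cutoff: int) -> pd.Series:
        return series > cutoff if rule.strict else series >= cutoff

    if rule.kind == "total":
        (inst, cutoff), = rule.thresholds.items()
        if inst not in table.totals.columns:
            raise KeyError(f"instrument total {inst!r} not in table")
        return meets(table.totals[inst], cutoff)
    verdict = pd.Series(True, index=table.values.index)
    for sub, cutoff in rule.thresholds.items():
        if sub not in table.values.columns:
            raise KeyError(f"subscore {sub!r} not in table")
        verdict &= meets(table.values[sub], cutoff)
    return verdict


def agreement(d_a: pd.Series | np.ndarray, d_b: pd.Series | np.ndarray) -> float:
    """Percent of participants with the same diagnostic label on both tests."""
    d_a = np.asarray(d_a, dtype=bool)
    d_b = np.asarray(d_b, dtype=bool)
    if d_a.shape != d_b.shape:
        raise ValueError("diagnosis vectors differ in length")
    return 100.0 * float((d_a == d_b).mean())


@dataclass
class KappaResult:
    kappa: float
    p_observed: float
    p_chance: float
    n: int


def cohen_kappa(d_a: pd.Series | np.ndarray, d_b: pd.Series | np.ndarray) -> KappaResult:
    """Two-rater binary Cohen's kappa from the 2x2 contingency table.

    Degenerate case: if both classifications are constant and equal,
    p_o = p_e = 1 and kappa is reported as 1 (logged); constant but unequal
    labels fall through to the formula.
    """
    d_a = np.asarray(d_a, dtype=bool)
    d_b = np.asarray(d_b, dtype=bool)
    if d_a.shape != d_b.shape:
        raise ValueError("diagnosis vectors differ in length")
    n = d_a.size
    if n < 1:
        raise ValueError("need at least one participant")
    p_o = float((d_a == d_b).mean())
    pa, pb = float(d_a.mean()), float(d_b.mean())
    p_e = pa * pb + (1 - pa) * (1 - pb)
    if p_e >= 1.0:
        logger.warning("degenerate kappa: both classifications constant and equal")
        kappa = 1.0 if p_o == 1.0 else (p_o - p_e)  # p_e==1 forces p_o==1 in practice
    else:
        kappa = (p_o - p_e) / (1 - p_e)
    return KappaResult(kappa=kappa, p_observed=p_o, p_chance=p_e, n=n)


@dataclass
class AgreementGrid:
    """Percent agreement (and kappa) over a grid of cutoff pairs."""

    thresholds_a: list[int]
    thresholds_b: list[int]
    agreement_pct: pd.DataFrame  # index = A cutoffs, columns = B cutoffs
    kappa: pd.DataFrame

    def to_long(self) -> pd.DataFrame:
        rows = []
        for ta in self.thresholds_a:
            for tb in self.thresholds_b:
                rows.append({
                    "threshold_a": ta, "threshold_b": tb,
                    "agreement_pct": self.agreement_pct.loc[ta, tb],
                    "kappa": self.kappa.loc[ta, tb],
                })
        return pd.DataFrame(rows)


def agreement_grid(
    table: ScoreTable,
    instrument_a: str,
    instrument_b: str,
    grid_a: list[int],
    grid_b: list[int],
    strict: bool = False,
) -> AgreementGrid:
    """Grid search of total-score cutoffs for two instruments.

    Emits the heatmap-ready agreement table of percent consistently
    classified participants, with Cohen's kappa alongside.
    """
    grid_a, grid_b = list(grid_a), list(grid_b)
    if not grid_a or not grid_b:
        raise ValueError("threshold grids must be nonempty")
    agree = np.empty((len(grid_a), len(grid_b)))
    kap = np.empty_like(agree)
    for i, ta in enumerate(grid_a):
        da = classify(table, ThresholdRule("total", {instrument_a: ta}, strict=strict))
        for j, tb in enumerate(grid_b):
            db = classify(table, ThresholdRule("total", {instrument_b: tb}, strict=strict))
            agree[i, j] = agreement(da, db)
            kap[i, j] = cohen_kappa(da, db).kappa
    return AgreementGrid(
        thresholds_a=grid_a,
        thresholds_b=grid_b,
        agreement_pct=pd.DataFrame(agree, index=grid_a, columns=grid_b),
        kappa=pd.DataFrame(kap, index=grid_a, columns=grid_b),
    )


#: Conventional cutoff pair bracketed by the default grids below.
DEFAULT_GRID_ADOS = list(range(5, 15))          # total 5..14
DEFAULT_GRID_ADIR = list(range(20, 41, 2))      # total 20..40 step 2
CONVENTIONAL_ADOS_TOTAL = 9
CONVENTIONAL_ADIR_CONJUNCTION = {"ADIR_A": 10, "ADIR_B": 7, "ADIR_C": 3}
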