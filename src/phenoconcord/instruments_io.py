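"""Data model and I/O for assessment instruments, scores, embeddings and biomarkers.

The catalog is the backbone of every analysis stage: it declares which
instruments exist (e.g. ADOS, ADI-R, SRS, SCQ), which sub-scores belong to
each instrument, and which free-text items are aggregated into each
sub-score.  Participant score tables, item-embedding tables and biomarker
tables are all validated against it.

File formats
------------
* catalog: JSON or YAML with top-level keys ``instruments``, ``subscores``,
  ``items`` (see ``examples/catalog.json``)
* score and biomarker tables: comma-delimited UTF-8 with a header row
* embedding tables: tab-delimited, one row per item (``item_id`` followed by
  the embedding coordinates)
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

INFORMANTS = {"caregiver", "clinician", "teacher"}


class CatalogError(ValueError):
    """Raised when a catalog or a table fails validation against it."""


@dataclass(frozen=True)
class Instrument:
    id: str
    name: str
    informant: str = "caregiver"
    #: when True the instrument total must equal the sum of its sub-scores
    derived_total: bool = True


@dataclass(frozen=True)
class Subscore:
    id: str
    instrument_id: str
    label: str


@dataclass(frozen=True)
class Item:
    id: str
    subscore_id: str
    text: str


@dataclass
class InstrumentCatalog:
    """Instruments, their sub-scores, and item membership.

    Invariants (enforced by :meth:`validate`, called on construction):
    every item maps to exactly one declared sub-score, every sub-score to
    exactly one declared instrument, and all ids are unique within their
    namespace.
    """

    instruments: list[Instrument] = field(default_factory=list)
    subscores: list[Subscore] = field(default_factory=list)
    items: list[Item] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    # -- lookups -----------------------------------------------------------
    def subscore_ids(self, instrument_id: str | None = None) -> list[str]:
        if instrument_id is None:
            return [s.id for s in self.subscores]
        return [s.id for s in self.subscores if s.instrument_id == instrument_id]

    def instrument_ids(self) -> list[str]:
        return [i.id for i in self.instruments]

    def instrument_of(self, subscore_id: str) -> str:
        for s in self.subscores:
            if s.id == subscore_id:
                return s.instrument_id
        raise CatalogError(f"unknown subscore {subscore_id!r}")

    def get_instrument(self, instrument_id: str) -> Instrument:
        for i in self.instruments:
            if i.id == instrument_id:
                return i
        raise CatalogError(f"unknown instrument {instrument_id!r}")

    def items_for(self, subscore_id: str) -> list[Item]:
        return [it for it in self.items if it.subscore_id == subscore_id]

    # -- validation --------------------------------------------------------
    def validate(self) -> None:
        for name, ids in (
            ("instrument", [i.id for i in self.instruments]),
            ("subscore", [s.id for s in self.subscores]),
            ("item", [it.id for it in self.items]),
        ):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise CatalogError(f"duplicate {name} id {i!r}")
                seen.add(i)
        instr_ids = {i.id for i in self.instruments}
        for s in self.subscores:
            if s.instrument_id not in instr_ids:
                raise CatalogError(
                    f"subscore {s.id!r} references unknown instrument {s.instrument_id!r}"
                )
        sub_ids = {s.id for s in self.subscores}
        for it in self.items:
            if it.subscore_id not in sub_ids:
                raise CatalogError(
                    f"item {it.id!r} references unknown subscore {it.subscore_id!r}"
                )
        for i in self.instruments:
            if i.informant not in INFORMANTS:
                raise CatalogError(
                    f"instrument {i.id!r}: informant must be one of {sorted(INFORMANTS)}"
                )

    # -- (de)serialization -------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "InstrumentCatalog":
        instruments = [
            Instrument(
                id=str(rec["id"]),
                name=str(rec.get("name", rec["id"])),
                informant=str(rec.get("informant", "caregiver")),
                derived_total=bool(rec.get("derived_total", True)),
            )
            for rec in d.get("instruments", [])
        ]
        subscores = [
            Subscore(
                id=str(rec["id"]),
                instrument_id=str(rec["instrument"]),
                label=str(rec.get("label", rec["id"])),
            )
            for rec in d.get("subscores", [])
        ]
        items = [
            Item(
                id=str(rec["id"]),
                subscore_id=str(rec["subscore"]),
                text=str(rec.get("text", "")),
            )
            for rec in d.get("items", [])
        ]
        return cls(instruments=instruments, subscores=subscores, items=items)

    def to_dict(self) -> dict:
        return {
            "instruments": [
                {
                    "id": i.id,
                    "name": i.name,
                    "informant": i.informant,
                    "derived_total": i.derived_total,
                }
                for i in self.instruments
            ],
            "subscores": [
                {"id": s.id, "instrument": s.instrument_id, "label": s.label}
                for s in self.subscores
            ],
            "items": [
                {"id": it.id, "subscore": it.subscore_id, "text": it.text}
                for it in self.items
            ],
        }


def load_instrument_catalog(path: str | Path) -> InstrumentCatalog:
    """Load and validate a catalog from a JSON or YAML file.

    The format is decided by extension (``.json`` vs ``.yaml``/``.yml``);
    anything else is parsed as YAML, of which JSON is a subset.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if data is None:
        data = {}
    return InstrumentCatalog.from_dict(data)


def save_instrument_catalog(catalog: InstrumentCatalog, path: str | Path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(catalog.to_dict(), indent=2), encoding="utf-8")
    else:
        path.write_text(yaml.safe_dump(catalog.to_dict()), encoding="utf-8")


# ---------------------------------------------------------------------------
# Score tables
# ---------------------------------------------------------------------------

@dataclass
class ScoreTable:
    """Participants x sub-score grid of raw ordinal scores.

    ``values`` is indexed by participant id with one column per sub-score;
    ``totals`` carries one column per instrument.  Tables are *complete* by
    contract: rows with any missing sub-score are dropped at load time, no
    imputation is performed.  ``latents``/``severity`` are optional synthetic
    provenance (the latent Gaussian draws behind the ordinal scores) used by
    the rater-duplicate generator and ground-truth checks.
    """

    values: pd.DataFrame
    totals: pd.DataFrame
    dataset_id: str = "default"
    latents: pd.DataFrame | None = None
    severity: pd.Series | None = None

    @property
    def participants(self) -> list[str]:
        return list(self.values.index)

    @property
    def n_participants(self) -> int:
        return len(self.values)

    def subscore(self, subscore_id: str) -> pd.Series:
        return self.values[subscore_id]

    def total(self, instrument_id: str) -> pd.Series:
        return self.totals[instrument_id]


def derive_totals(values: pd.DataFrame, catalog: InstrumentCatalog) -> pd.DataFrame:
    """Sum each instrument's sub-score columns into a totals grid."""
    totals = {}
    for inst in catalog.instruments:
        cols = [c for c in catalog.subscore_ids(inst.id) if c in values.columns]
        if cols:
            totals[inst.id] = values[cols].sum(axis=1)
    return pd.DataFrame(totals, index=values.index)


def load_score_table(
    path: str | Path,
    catalog: InstrumentCatalog,
    dataset_id: str | None = None,
) -> ScoreTable:
    """Read a participant score CSV, drop incomplete rows, derive totals.

    The header must contain ``participant_id`` plus sub-score columns known
    to the catalog.  Optional ``<instrument>_total`` columns are validated
    (exactly, tolerance 0) against the sub-score sum for instruments whose
    total is derived; instruments flagged ``derived_total: false`` skip the
    check and the provided column is used as-is.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"participant_id": str})
    if "participant_id" not in df.columns:
        raise CatalogError(f"{path}: missing participant_id column")
    df = df.set_index("participant_id")

    known_subs = set(catalog.subscore_ids())
    total_cols = {}
    for col in df.columns:
        if col in known_subs:
            continue
        if col.endswith("_total") and col[: -len("_total")] in catalog.instrument_ids():
            total_cols[col[: -len("_total")]] = col
            continue
        raise CatalogError(f"{path}: unknown column {col!r}")

    sub_cols = [c for c in df.columns if c in known_subs]
    for col in sub_cols + list(total_cols.values()):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise CatalogError(f"{path}: non-numeric cell at row {row!r}, column {col!r}")
        df[col] = coerced

    complete = df[sub_cols].notna().all(axis=1)
    n_dropped = int((~complete).sum())
    if n_dropped:
        logger.warning("%s: dropped %d incomplete participant row(s)", path, n_dropped)
    df = df.loc[complete]

    values = df[sub_cols]
    values.index.name = "participant_id"
    totals = derive_totals(values, catalog)
    for inst_id, col in total_cols.items():
        provided = df[col]
        inst = catalog.get_instrument(inst_id)
        if inst.derived_total and inst_id in totals.columns:
            mismatch = provided != totals[inst_id]
            if mismatch.any():
                row = mismatch.idxmax()
                raise CatalogError(
                    f"{path}: total column {col!r} disagrees with sub-score sum "
                    f"at participant {row!r}"
                )
        totals[inst_id] = provided
    return ScoreTable(values=values, totals=totals, dataset_id=dataset_id or path.stem)


def write_score_table(table: ScoreTable, path: str | Path) -> None:
    """Write the sub-score grid as CSV (integer scores round-trip exactly)."""
    out = table.values.copy()
    out.index.name = "participant_id"
    out.to_csv(path)


# ---------------------------------------------------------------------------
# Embedding clouds
# ---------------------------------------------------------------------------

@dataclass
class EmbeddingCloudSet:
    """Per-sub-score clouds of unit-norm item-embedding vectors."""

    clouds: dict[str, np.ndarray]
    item_ids: dict[str, list[str]]

    @property
    def dim(self) -> int:
        first = next(iter(self.clouds.values()))
        return first.shape[1]

    def subscores(self) -> list[str]:
        return list(self.clouds)


def normalize_rows(arr: np.ndarray, item_ids: list[str] | None = None) -> np.ndarray:
    """Project each row onto the unit sphere; zero rows are an error."""
    arr = np.asarray(arr, dtype=float)
    norms = np.linalg.norm(arr, axis=1)
    zero = norms < 1e-300
    if zero.any():
        idx = int(np.argmax(zero))
        name = item_ids[idx] if item_ids else f"row {idx}"
        raise ValueError(f"zero-norm embedding vector for item {name}")
    return arr / norms[:, None]


def load_embedding_table(path: str | Path, catalog: InstrumentCatalog) -> EmbeddingCloudSet:
    """Read an item-embedding TSV and group vectors by catalog sub-score.

    Rows are ``item_id`` followed by D numeric columns; all rows must share
    the same D.  Vectors are unit-normalized on load.
    """
    path = Path(path)
    rows: list[tuple[str, np.ndarray]] = []
    dim: int | None = None
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            item_id, coords = parts[0], parts[1:]
            if lineno == 1 and not _is_numeric(coords[0]):
                continue  # header row
            vec = np.array([float(c) for c in coords])
            if dim is None:
                dim = vec.size
            elif vec.size != dim:
                raise ValueError(
                    f"{path}: ragged embedding dimensions (row {lineno} has "
                    f"{vec.size}, expected {dim})"
                )
            rows.append((item_id, vec))

    item_to_sub = {it.id: it.subscore_id for it in catalog.items}
    grouped: dict[str, list[tuple[str, np.ndarray]]] = {}
    for item_id, vec in rows:
        if item_id not in item_to_sub:
            raise CatalogError(f"{path}: item {item_id!r} absent from catalog")
        grouped.setdefault(item_to_sub[item_id], []).append((item_id, vec))

    clouds, ids = {}, {}
    for sub, pairs in grouped.items():
        names = [p[0] for p in pairs]
        clouds[sub] = normalize_rows(np.vstack([p[1] for p in pairs]), names)
        ids[sub] = names
    return EmbeddingCloudSet(clouds=clouds, item_ids=ids)


def write_embedding_table(clouds: EmbeddingCloudSet, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for sub in clouds.subscores():
            for item_id, vec in zip(clouds.item_ids[sub], clouds.clouds[sub]):
                coords = "\t".join(repr(float(x)) for x in vec)
                fh.write(f"{item_id}\t{coords}\n")


def _is_numeric(token: str) -> bool:
    try:
        float(token)
        return True
    except ValueError:
        return False


# ---------------------------------------------------------------------------
# Biomarkers
# ---------------------------------------------------------------------------

@dataclass
class BiomarkerTable:
    """Per-participant scalar biomarkers and optional network time series.

    ``scalars`` holds named columns such as a polygenic risk score (unitless),
    total brain volume (mm^3) or mean cortical thickness (mm).  ``timeseries``
    maps participant id -> (n_networks, T) BOLD-like array, with shared
    ``network_labels``.
    """

    scalars: pd.DataFrame
    timeseries: dict[str, np.ndarray] = field(default_factory=dict)
    network_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        vals = self.scalars.to_numpy(dtype=float)
        if vals.size and not np.isfinite(vals).all():
            raise ValueError("biomarker scalar columns must be finite")
        for pid, ts in self.timeseries.items():
            ts = np.asarray(ts, dtype=float)
            if ts.ndim != 2 or ts.shape[1] < 2:
                raise ValueError(f"participant {pid}: time series must be 2-D with T >= 2")
            if (ts.std(axis=1) == 0).any():
                raise ValueError(f"participant {pid}: constant time-series row")

    @property
    def participants(self) -> list[str]:
        return list(self.scalars.index)


def load_biomarker_table(path: str | Path) -> BiomarkerTable:
    """Read scalar biomarkers from CSV (``participant_id`` + named columns)."""
    df = pd.read_csv(path, dtype={"participant_id": str}).set_index("participant_id")
    return BiomarkerTable(scalars=df)


def write_biomarker_table(table: BiomarkerTable, path: str | Path) -> None:
    out = table.scalars.copy()
    out.index.name = "participant_id"
    out.to_csv(path)


def load_timeseries_long(path: str | Path) -> tuple[dict[str, np.ndarray], list[str]]:
    """Read long-format network time series.

    Columns: ``participant_id, network, t, value``.  Returns per-participant
    (n_networks, T) arrays with a shared network-label ordering.
    """
    df = pd.read_csv(path, dtype={"participant_id": str, "network": str})
    labels = sorted(df["network"].unique())
    out: dict[str, np.ndarray] = {}
    for pid, grp in df.groupby("participant_id"):
        pivot = grp.pivot(index="network", columns="t", values="value")
        out[pid] = pivot.reindex(labels).to_numpy(dtype=float)
    return out, labels


def inner_join_participants(
    table: ScoreTable, biomarkers: BiomarkerTable
) -> tuple[ScoreTable, BiomarkerTable]:
    """Align a score table and biomarker table on shared participant ids.

    Inner join by exact id match; the number of excluded participants from
    each side is logged.
    """
    shared = table.values.index.intersection(biomarkers.scalars.index)
    n_s = len(table.values) - len(shared)
    n_b = len(biomarkers.scalars) - len(shared)
    if n_s or n_b:
        logger.info(
            "participant join excluded %d score-only and %d biomarker-only ids", n_s, n_b
        )
    sub_scores = ScoreTable(
        values=table.values.loc[shared],
        totals=table.totals.loc[shared],
        dataset_id=table.dataset_id,
    )
    sub_bio = BiomarkerTable(
        scalars=biomarkers.scalars.loc[shared],
        timeseries={p: ts for p, ts in biomarkers.timeseries.items() if p in set(shared)},
        network_labels=biomarkers.network_labels,
    )
    return sub_scores, sub_bio
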