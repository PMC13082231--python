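"""Domain types and I/O for depth-resolved amplicon (ASV) time-series tables.

The central container is :class:`AbundanceTable`, a taxa x samples matrix of
nonnegative values in either ``counts`` or ``relative`` mode, with one
:class:`Sample` (collection year/month, cruise, depth) per column.  Relative
mode means every sample column is closed to sum 1 — the compositional form
used throughout the periodicity analyses.
"""

from __future__ import annotations

import csv
import json
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Season",
    "season_of_month",
    "Sample",
    "AbundanceTable",
    "TaxonAnnotation",
    "consensus_ecotype",
    "ConsensusConflictError",
    "ParseError",
    "read_abundance_table",
    "write_abundance_table",
    "read_metadata",
    "read_annotations",
    "to_relative_abundance",
]

CLOSURE_TOL = 1e-9


class Season(str, Enum):
    """Calendar season of the northern-hemisphere oceanographic convention."""

    WINTER = "winter"
    SPRING = "spring"
    SUMMER = "summer"
    FALL = "fall"


# Dec/Jan/Feb = winter, Mar/Apr/May = spring, Jun/Jul/Aug = summer,
# Sep/Oct/Nov = fall.  Membership is by calendar month only.
_SEASON_BY_MONTH = {
    12: Season.WINTER, 1: Season.WINTER, 2: Season.WINTER,
    3: Season.SPRING, 4: Season.SPRING, 5: Season.SPRING,
    6: Season.SUMMER, 7: Season.SUMMER, 8: Season.SUMMER,
    9: Season.FALL, 10: Season.FALL, 11: Season.FALL,
}

SEASON_ORDER = (Season.WINTER, Season.SPRING, Season.SUMMER, Season.FALL)


def season_of_month(month: int) -> Season:
    """Map a calendar month (1-12) to its season."""
    if month not in _SEASON_BY_MONTH:
        raise ValueError(f"month must be in 1..12, got {month!r}")
    return _SEASON_BY_MONTH[month]


class ParseError(ValueError):
    """Raised when an input file violates the table contract."""


class ConsensusConflictError(ValueError):
    """Two different ecotype labels each supported by >= 2 sources."""


@dataclass(frozen=True)
class Sample:
    """One water-column sample: collection time and depth coordinates."""

    sample_id: str
    cruise_id: str
    year: int
    month: int
    depth_m: float

    def __post_init__(self) -> None:
        if not 1 <= self.month <= 12:
            raise ValueError(f"sample {self.sample_id!r}: month {self.month} not in 1..12")
        if self.depth_m <= 0:
            raise ValueError(f"sample {self.sample_id!r}: depth_m must be > 0")


@dataclass
class AbundanceTable:
    """Taxa x samples nonnegative matrix with an explicit normalization mode."""

    taxa: list[str]
    samples: list[Sample]
    values: np.ndarray
    mode: str = "counts"  # "counts" | "relative"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.taxa), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.samples)} samples"
            )
        if len(set(self.taxa)) != len(self.taxa):
            dup = [t for t, c in Counter(self.taxa).items() if c > 1]
            raise ValueError(f"duplicate taxon ids: {dup}")
        ids = [s.sample_id for s in self.samples]
        if len(set(ids)) != len(ids):
            dup = [s for s, c in Counter(ids).items() if c > 1]
            raise ValueError(f"duplicate sample ids: {dup}")
        if np.any(self.values < 0):
            raise ValueError("abundance values must be nonnegative")
        if self.mode not in ("counts", "relative"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "relative":
            colsums = self.values.sum(axis=0)
            bad = np.where(np.abs(colsums - 1.0) > 1e-6)[0]
            if bad.size:
                raise ValueError(
                    f"relative-mode columns must sum to 1; offending sample "
                    f"{self.samples[bad[0]].sample_id!r} sums to {colsums[bad[0]]:.6g}"
                )

    @property
    def sample_ids(self) -> list[str]:
        return [s.sample_id for s in self.samples]

    def depths(self) -> list[float]:
        """Distinct depths in order of first appearance."""
        seen: dict[float, None] = {}
        for s in self.samples:
            seen.setdefault(s.depth_m, None)
        return list(seen)

    def restrict_depth(self, depth_m: float) -> "AbundanceTable":
        """Sub-table of samples collected at one depth (order preserved)."""
        idx = [i for i, s in enumerate(self.samples) if s.depth_m == depth_m]
        if not idx:
            raise KeyError(f"no samples at depth {depth_m} m")
        return AbundanceTable(
            taxa=list(self.taxa),
            samples=[self.samples[i] for i in idx],
            values=self.values[:, idx],
            mode=self.mode,
        )

    def taxon_values(self, taxon_id: str) -> np.ndarray:
        return self.values[self.taxa.index(taxon_id)]


def to_relative_abundance(table: AbundanceTable) -> AbundanceTable:
    """Close each sample column to relative abundances summing to 1."""
    if table.mode == "relative":
        return table
    colsums = table.values.sum(axis=0)
    zero = np.where(colsums == 0)[0]
    if zero.size:
        raise ValueError(
            f"cannot close all-zero sample column {table.samples[zero[0]].sample_id!r}"
        )
    return AbundanceTable(
        taxa=list(table.taxa),
        samples=list(table.samples),
        values=table.values / colsums,
        mode="relative",
    )


@dataclass
class TaxonAnnotation:
    """Lineage plus per-source ecotype labels for one taxon.

    ``ecotype_labels`` maps annotation-source name to a label or None
    (missing).  Missing labels never count toward a consensus.
    """

    taxon_id: str
    lineage: list[str] = field(default_factory=list)
    ecotype_labels: dict[str, str | None] = field(default_factory=dict)


def consensus_ecotype(labels: list[str | None]) -> str:
    """Consensus label supported by at least two annotation sources.

    Missing labels (None or empty string) are skipped.  Returns
    ``"unassigned"`` when no label is shared by >= 2 sources; raises
    :class:`ConsensusConflictError` if two different labels each are.
    """
    counts = Counter(l for l in labels if l)
    winners = [l for l, c in counts.items() if c >= 2]
    if len(winners) > 1:
        raise ConsensusConflictError(
            f"conflicting consensus: {sorted(winners)} each supported by >= 2 sources"
        )
    return winners[0] if winners else "unassigned"


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def _parse_cell(raw: str, row_label: str, col_label: str) -> float:
    try:
        v = float(raw)
    except ValueError:
        raise ParseError(
            f"non-numeric value {raw!r} at taxon {row_label!r}, sample {col_label!r}"
        ) from None
    if not np.isfinite(v):
        raise ParseError(f"non-finite value at taxon {row_label!r}, sample {col_label!r}")
    if v < 0:
        raise ParseError(
            f"negative value {raw!r} at taxon {row_label!r}, sample {col_label!r}"
        )
    return v


def _placeholder_samples(sample_ids: list[str]) -> list[Sample]:
    # A matrix file alone carries no collection metadata; neutral coordinates
    # are attached until a metadata file supplies the real ones.
    return [
        Sample(sample_id=sid, cruise_id="", year=1, month=1, depth_m=1.0)
        for sid in sample_ids
    ]


def _read_tsv(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh, delimiter="\t"))
    if not rows or len(rows[0]) < 2:
        raise ParseError(f"{path}: expected a header row with at least one sample id")
    sample_ids = rows[0][1:]
    ncol = len(sample_ids)
    taxa: list[str] = []
    data: list[list[float]] = []
    for r, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) - 1 != ncol:
            raise ParseError(
                f"{path}: ragged row {r} ({len(row) - 1} values, expected {ncol})"
            )
        taxa.append(row[0])
        data.append([
            _parse_cell(cell, row[0], sample_ids[j]) for j, cell in enumerate(row[1:])
        ])
    return taxa, sample_ids, np.asarray(data, dtype=float)


def _read_biom_json(path: Path) -> tuple[list[str], list[str], np.ndarray]:
    with open(path) as fh:
        doc = json.load(fh)
    try:
        taxa = [r["id"] for r in doc["rows"]]
        sample_ids = [c["id"] for c in doc["columns"]]
        mtype = doc["matrix_type"]
        data = doc["data"]
    except (KeyError, TypeError) as exc:
        raise ParseError(f"{path}: not a BIOM v1 JSON table ({exc})") from None
    values = np.zeros((len(taxa), len(sample_ids)))
    if mtype == "dense":
        arr = np.asarray(data, dtype=float)
        if arr.shape != values.shape:
            raise ParseError(f"{path}: dense data shape {arr.shape} mismatches ids")
        values = arr
    elif mtype == "sparse":
        for i, j, v in data:
            values[int(i), int(j)] = v
    else:
        raise ParseError(f"{path}: unsupported matrix_type {mtype!r}")
    for (i, j) in zip(*np.where(values < 0)):
        raise ParseError(
            f"{path}: negative value at taxon {taxa[i]!r}, sample {sample_ids[j]!r}"
        )
    return taxa, sample_ids, values


def read_abundance_table(
    path: str | Path,
    format: str = "tsv",
    metadata: str | Path | None = None,
) -> AbundanceTable:
    """Read a taxa x samples count matrix from TSV or BIOM v1 JSON.

    The TSV dialect is: header row of sample ids, first column taxon id,
    tab-separated, unquoted numerics.  When ``metadata`` is given, sample
    ids in the matrix must all be present in the metadata file and collection
    coordinates are attached from it.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        taxa, sample_ids, values = _read_tsv(path)
    elif format == "biom-json":
        taxa, sample_ids, values = _read_biom_json(path)
    else:
        raise ValueError(f"unknown format {format!r} (expected 'tsv' or 'biom-json')")
    if metadata is not None:
        meta = read_metadata(metadata)
        missing = [sid for sid in sample_ids if sid not in meta]
        if missing:
            raise ParseError(f"sample ids absent from metadata: {missing}")
        samples = [meta[sid] for sid in sample_ids]
    else:
        samples = _placeholder_samples(sample_ids)
    return AbundanceTable(taxa=taxa, samples=samples, values=values, mode="counts")


def write_abundance_table(
    table: AbundanceTable, path: str | Path, format: str = "tsv"
) -> None:
    """Write a table as TSV or dense BIOM v1 JSON (lossless round trip)."""
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", quoting=csv.QUOTE_NONE)
            w.writerow(["taxon_id", *table.sample_ids])
            for i, taxon in enumerate(table.taxa):
                w.writerow([taxon, *[repr(float(v)) for v in table.values[i]]])
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "Biological Observation Matrix 1.0.0",
            "format_url": "http://biom-format.org",
            "type": "OTU table",
            "generated_by": "tidepulse",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": [len(table.taxa), len(table.samples)],
            "rows": [{"id": t, "metadata": None} for t in table.taxa],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.values.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> dict[str, Sample]:
    """Read sample metadata CSV (sample_id, cruise_id, year, month, depth_m)."""
    df = pd.read_csv(path)
    required = {"sample_id", "cruise_id", "year", "month", "depth_m"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: metadata missing columns {sorted(missing)}")
    out: dict[str, Sample] = {}
    for rec in df.itertuples(index=False):
        sid = str(rec.sample_id)
        if sid in out:
            raise ParseError(f"{path}: duplicate sample id {sid!r}")
        out[sid] = Sample(
            sample_id=sid,
            cruise_id=str(rec.cruise_id),
            year=int(rec.year),
            month=int(rec.month),
            depth_m=float(rec.depth_m),
        )
    return out


def read_annotations(path: str | Path) -> dict[str, TaxonAnnotation]:
    """Read taxon annotations: column ``taxon_id``, optional ``lineage``
    (semicolon-separated ranks), every other column one annotation source.
    Empty cells are missing labels."""
    df = pd.read_csv(path, dtype=str).fillna("")
    if "taxon_id" not in df.columns:
        raise ParseError(f"{path}: annotation file must have a taxon_id column")
    sources = [c for c in df.columns if c not in ("taxon_id", "lineage")]
    out: dict[str, TaxonAnnotation] = {}
    for _, row in df.iterrows():
        tid = row["taxon_id"]
        lineage = [p for p in row.get("lineage", "").split(";") if p]
        labels = {src: (row[src] or None) for src in sources}
        out[tid] = TaxonAnnotation(taxon_id=tid, lineage=lineage, ecotype_labels=labels)
    return out
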