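"""Readers and writers for the tab-delimited dialects the tool consumes.

Four plain-text inputs, all strictly TAB separated, UTF-8, decimal point:

* a *sample information* table whose first column holds unique sample ids and
  whose numeric columns are flagged by a ``(numeric)`` suffix in the header,
  including the survival time and the event indicator (0 = alive, 1 = death);
* a *marker annotation* table (marker id, chromosome, position in base pairs,
  optional gene and cytoband columns);
* a markers x samples *data matrix* (copy number on the linear copy scale, or
  expression on the linear signal scale), first column marker ids;
* an optional *array list* -- an ordered subset of sample ids, one per line,
  used to restrict and order downstream analyses.

Missing values may be written as an empty cell, ``NA``, ``na`` or ``NaN``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING_TOKENS = frozenset({"", "NA", "na", "NaN", "nan"})

DEFAULT_TIME_COLUMN = "Survival(numeric)"
DEFAULT_EVENT_COLUMN = "Event(numeric)"

#: rank of the standard human chromosome labels; anything else sorts after.
_CHROM_RANK = {**{str(i): i for i in range(1, 23)}, "X": 23, "Y": 24}


def chromosome_sort_key(label: str) -> tuple[int, str]:
    """Orderable key for chromosome labels: 1..22, X, Y, then others by name."""
    lab = str(label)
    if lab.lower().startswith("chr"):
        lab = lab[3:]
    return (_CHROM_RANK.get(lab, 1000), lab)


def _replace_missing(series: pd.Series) -> pd.Series:
    return series.where(~series.astype(str).str.strip().isin(MISSING_TOKENS))


def _to_numeric(series: pd.Series) -> pd.Series:
    return pd.to_numeric(_replace_missing(series).astype(object), errors="coerce")


# ---------------------------------------------------------------------------
# sample information
# ---------------------------------------------------------------------------


@dataclass
class SampleTable:
    """Per-sample clinical table keyed by sample id.

    ``data`` is indexed by sample id; columns ending in ``(numeric)`` are
    floats (NaN = missing), all other columns are strings (NaN = missing).
    The survival time / event indicator columns are named by ``time_col``
    and ``event_col``.
    """

    data: pd.DataFrame
    time_col: str = DEFAULT_TIME_COLUMN
    event_col: str = DEFAULT_EVENT_COLUMN
    id_col: str = "Sample"

    @property
    def ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> np.ndarray:
        return self.data[self.time_col].to_numpy(dtype=float)

    @property
    def event(self) -> np.ndarray:
        return self.data[self.event_col].to_numpy(dtype=float)

    @property
    def covariate_columns(self) -> list[str]:
        return [
            c
            for c in self.data.columns
            if c.endswith("(numeric)") and c not in (self.time_col, self.event_col)
        ]

    def covariate(self, name: str) -> np.ndarray:
        if name not in self.data.columns:
            raise KeyError(f"no sample-information column named {name!r}")
        return pd.to_numeric(self.data[name], errors="coerce").to_numpy(dtype=float)

    def subset(self, ids: Sequence[str]) -> "SampleTable":
        missing = [i for i in ids if i not in self.data.index]
        if missing:
            raise ValueError(f"unknown sample id(s): {', '.join(missing)}")
        return replace(self, data=self.data.loc[list(ids)])

    def survival_data(self):
        from .survival_stats import SurvivalData

        return SurvivalData(time=self.time, event=self.event, ids=self.ids)

    def write(self, path: str | Path) -> None:
        self.data.to_csv(path, sep="\t", na_rep="NA", index_label=self.id_col)


def read_sample_info(
    path: str | Path,
    time_col: str = DEFAULT_TIME_COLUMN,
    event_col: str = DEFAULT_EVENT_COLUMN,
) -> SampleTable:
    """Read a tab-delimited sample information file.

    The first column is the sample identifier; columns whose header ends in
    ``(numeric)`` are parsed as numbers, with unparseable cells recorded as
    missing.  A sample whose time/event pair is only half present has both
    treated as missing (and is later omitted from survival analyses).
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.shape[1] < 2 or raw.empty:
        raise ValueError(f"{path}: sample information file needs a header and data rows")
    id_col = raw.columns[0]
    ids = raw[id_col].astype(str).str.strip()
    dup = ids[ids.duplicated()]
    if len(dup):
        raise ValueError(f"{path}: duplicate sample id(s): {', '.join(sorted(set(dup)))}")

    out = pd.DataFrame(index=pd.Index(ids, name=id_col))
    for col in raw.columns[1:]:
        if col.endswith("(numeric)"):
            out[col] = _to_numeric(raw[col]).to_numpy()
        else:
            out[col] = _replace_missing(raw[col].astype(str).str.strip()).to_numpy()

    for col in (time_col, event_col):
        if col not in out.columns:
            raise ValueError(
                f"{path}: required survival column {col!r} not found "
                f"(available numeric columns: {[c for c in out.columns if c.endswith('(numeric)')]})"
            )

    ev = out[event_col]
    bad = ev.notna() & ~ev.isin([0.0, 1.0])
    if bad.any():
        sample = out.index[bad][0]
        raise ValueError(
            f"{path}: event indicator {event_col!r} must be 0 or 1; "
            f"sample {sample!r} has value {ev[bad].iloc[0]!r}"
        )
    tm = out[time_col]
    neg = tm.notna() & (tm < 0)
    if neg.any():
        sample = out.index[neg][0]
        raise ValueError(f"{path}: negative survival time for sample {sample!r}")

    half = tm.isna() ^ ev.isna()
    if half.any():
        logger.warning(
            "%s: %d sample(s) with only one of time/event present; both set missing",
            path,
            int(half.sum()),
        )
        out.loc[half, [time_col, event_col]] = np.nan

    return SampleTable(data=out, time_col=time_col, event_col=event_col, id_col=id_col)


# ---------------------------------------------------------------------------
# marker annotation
# ---------------------------------------------------------------------------

_MARKER_ALIASES = ("marker_id", "marker", "snp", "snp_id", "probe_set", "id")
_CHROM_ALIASES = ("chromosome", "chrom", "chr")
_POS_ALIASES = ("position", "pos", "physical_position")


@dataclass
class MarkerAnnotation:
    """Genome annotation for matrix rows, sorted by (chromosome, position).

    ``table`` has columns ``marker_id``, ``chromosome``, ``position`` (1-based
    base pairs) and optionally ``gene`` and ``cytoband``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        self.table = self.table.reset_index(drop=True)

    @property
    def n_markers(self) -> int:
        return len(self.table)

    @property
    def marker_ids(self) -> np.ndarray:
        return self.table["marker_id"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.table["chromosome"].to_numpy()

    @property
    def positions(self) -> np.ndarray:
        return self.table["position"].to_numpy()

    def chromosome_blocks(self) -> list[tuple[str, int, int]]:
        """Contiguous row ranges per chromosome as (label, start, stop)."""
        blocks: list[tuple[str, int, int]] = []
        chroms = self.chromosomes
        start = 0
        for i in range(1, len(chroms) + 1):
            if i == len(chroms) or chroms[i] != chroms[start]:
                blocks.append((str(chroms[start]), start, i))
                start = i
        return blocks

    def subset_rows(self, indices: np.ndarray) -> "MarkerAnnotation":
        return MarkerAnnotation(self.table.iloc[indices].reset_index(drop=True))

    def locate(self, marker_id: str) -> int:
        hits = np.flatnonzero(self.marker_ids == marker_id)
        if len(hits) == 0:
            raise KeyError(f"marker {marker_id!r} not in annotation")
        return int(hits[0])

    def find_gene(self, pattern: str) -> pd.DataFrame:
        """Exact-or-substring match against the gene column."""
        if "gene" not in self.table.columns:
            raise KeyError("annotation has no gene column")
        genes = self.table["gene"].fillna("")
        hit = (genes == pattern) | genes.str.contains(pattern, case=False, regex=False)
        return self.table[hit]

    def write(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t", na_rep="NA", index=False)


def _find_column(columns: Sequence[str], aliases: Sequence[str], what: str) -> str:
    lower = {c.lower().replace(" ", "_"): c for c in columns}
    for a in aliases:
        if a in lower:
            return lower[a]
    raise ValueError(f"annotation file lacks a {what} column (tried {aliases})")


def read_annotation(path: str | Path) -> MarkerAnnotation:
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty:
        raise ValueError(f"{path}: empty annotation file")
    cols = list(raw.columns)
    m_col = _find_column(cols, _MARKER_ALIASES, "marker id")
    c_col = _find_column(cols, _CHROM_ALIASES, "chromosome")
    p_col = _find_column(cols, _POS_ALIASES, "position")

    table = pd.DataFrame(
        {
            "marker_id": raw[m_col].astype(str).str.strip(),
            "chromosome": raw[c_col].astype(str).str.strip(),
            "position": pd.to_numeric(raw[p_col], errors="raise").astype(np.int64),
        }
    )
    for opt in ("gene", "cytoband"):
        match = [c for c in cols if c.lower() == opt]
        if match:
            table[opt] = _replace_missing(raw[match[0]].astype(str).str.strip()).to_numpy()

    if table["marker_id"].duplicated().any():
        dup = table["marker_id"][table["marker_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate marker id {dup!r}")
    if (table["position"] < 0).any():
        raise ValueError(f"{path}: negative position")

    key = [chromosome_sort_key(c) for c in table["chromosome"]]
    order = pd.DataFrame({"key": key, "pos": table["position"]}).sort_values(
        ["key", "pos"], kind="mergesort"
    ).index
    return MarkerAnnotation(table.loc[order])


# ---------------------------------------------------------------------------
# data matrix
# ---------------------------------------------------------------------------


@dataclass
class GenomeMatrix:
    """A markers x samples value matrix in genome order.

    Copy numbers are stored on the linear copy scale (diploid = 2), never
    log2 ratios; expression is on the linear signal scale.
    """

    values: np.ndarray
    annotation: MarkerAnnotation
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("matrix values must be 2-D (markers x samples)")
        if self.values.shape[0] != self.annotation.n_markers:
            raise ValueError(
                f"matrix has {self.values.shape[0]} rows but annotation has "
                f"{self.annotation.n_markers} markers"
            )
        if self.sample_ids and len(self.sample_ids) != self.values.shape[1]:
            raise ValueError("sample_ids length does not match matrix columns")

    @property
    def n_markers(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def with_values(self, values: np.ndarray) -> "GenomeMatrix":
        return GenomeMatrix(values, self.annotation, list(self.sample_ids))

    def subset_samples(self, ids: Sequence[str]) -> "GenomeMatrix":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValueError(f"unknown sample id(s) in matrix: {', '.join(missing)}")
        cols = [index[s] for s in ids]
        return GenomeMatrix(self.values[:, cols], self.annotation, list(ids))

    def write(self, path: str | Path) -> None:
        df = pd.DataFrame(
            self.values, index=self.annotation.marker_ids, columns=self.sample_ids
        )
        df.to_csv(path, sep="\t", na_rep="NA", index_label="marker_id")


def read_matrix(path: str | Path, annotation: MarkerAnnotation) -> GenomeMatrix:
    """Read a markers x samples matrix and align rows to genome order.

    Rows absent from the annotation are dropped (logged); the returned
    matrix carries the annotation subset in matching order.
    """
    raw = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if raw.empty or raw.shape[1] < 2:
        raise ValueError(f"{path}: matrix file has no data section")
    marker_col = raw.columns[0]
    markers = raw[marker_col].astype(str).str.strip()
    if markers.duplicated().any():
        dup = markers[markers.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate matrix row for marker {dup!r}")
    values = np.column_stack([_to_numeric(raw[c]).to_numpy() for c in raw.columns[1:]])
    sample_ids = [str(c) for c in raw.columns[1:]]

    row_of = {m: i for i, m in enumerate(markers)}
    keep_mask = np.array([m in row_of for m in annotation.marker_ids])
    if not keep_mask.any():
        raise ValueError(f"{path}: no overlap between matrix markers and annotation")
    n_dropped = len(markers) - int(keep_mask.sum())
    if n_dropped:
        logger.info("%s: dropped %d matrix row(s) absent from annotation", path, n_dropped)
    ann = annotation.subset_rows(np.flatnonzero(keep_mask))
    rows = [row_of[m] for m in ann.marker_ids]
    aligned = values[rows]

    if np.isnan(aligned).all(axis=1).any():
        raise ValueError(f"{path}: matrix row of entirely missing values")
    if np.isnan(aligned).all(axis=0).any():
        raise ValueError(f"{path}: matrix column of entirely missing values")
    return GenomeMatrix(aligned, ann, sample_ids)


# ---------------------------------------------------------------------------
# array list
# ---------------------------------------------------------------------------


def read_array_list(path: str | Path, table: SampleTable) -> list[str]:
    """Read an ordered sample-id list; every id must exist in the table."""
    lines = [ln.strip() for ln in Path(path).read_text(encoding="utf-8").splitlines()]
    ids = [ln for ln in lines if ln]
    if not ids:
        raise ValueError(f"{path}: empty array list file")
    seen: set[str] = set()
    for s in ids:
        if s in seen:
            raise ValueError(f"{path}: duplicate sample id {s!r} in array list")
        seen.add(s)
        if s not in table.data.index:
            raise ValueError(f"{path}: array list sample {s!r} not in sample information")
    return ids


def write_array_list(ids: Sequence[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(ids) + "\n", encoding="utf-8")
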