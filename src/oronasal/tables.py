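"""Genus-by-sample abundance tables, sample metadata, and compositional transforms.

The :class:`AbundanceTable` is the substrate for every downstream stage: it wraps
a taxa x samples :class:`pandas.DataFrame` together with a mode flag saying
whether the cells are raw counts, per-sample fractions (columns sum to one), or
arbitrary nonnegative scaled values (e.g. total-sum-scaled to 10^6).

All screening thresholds downstream are expressed as *fractions* (0.01% ->
1e-4, 1% -> 1e-2); rendering as percent happens only at the I/O boundary.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GROUPS",
    "NICHES",
    "AGE_CLASSES",
    "METADATA_COLUMNS",
    "COUNTS",
    "RELATIVE",
    "SCALED",
    "AbundanceTable",
    "Stratum",
    "load_table",
    "write_table",
    "load_metadata",
    "write_metadata",
    "validate_metadata",
    "check_linkage",
    "select_samples",
    "aggregate_to_genus",
    "to_relative",
    "group_mean_relative",
    "top_n_genera",
]

GROUPS = ("healthy", "CP", "postoperative")
NICHES = ("oral", "nasal")
AGE_CLASSES = ("child", "adolescent")
METADATA_COLUMNS = ("sample_id", "subject_id", "group", "niche", "age_class")

COUNTS = "counts"
RELATIVE = "relative"
SCALED = "scaled"
_MODES = (COUNTS, RELATIVE, SCALED)

_REL_TOL = 1e-9


@dataclass(frozen=True)
class Stratum:
    """A (group, niche, age_class) sample subset; ``None`` fields are wildcards."""

    group: str | None = None
    niche: str | None = None
    age_class: str | None = None

    def label(self) -> str:
        return "_".join(str(v) for v in (self.group, self.age_class, self.niche) if v is not None)


@dataclass
class AbundanceTable:
    """Taxa x samples abundance matrix with a counts/relative/scaled mode flag."""

    data: pd.DataFrame
    mode: str = COUNTS

    def __post_init__(self) -> None:
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon names: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dupes}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.number):
            raise ValueError("abundance values must be numeric")
        if values.size and np.nanmin(values) < 0:
            i, j = np.argwhere(values < 0)[0]
            raise ValueError(
                f"negative value at taxon {self.data.index[i]!r}, sample {self.data.columns[j]!r}"
            )
        if self.mode == RELATIVE:
            sums = values.sum(axis=0)
            bad = np.where(np.abs(sums - 1.0) > _REL_TOL)[0]
            if bad.size:
                raise ValueError(
                    f"relative-mode column {self.data.columns[bad[0]]!r} sums to "
                    f"{sums[bad[0]]!r}, expected 1"
                )

    # -- convenience accessors -------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    @property
    def samples(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def subset_samples(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return AbundanceTable(self.data.loc[:, list(sample_ids)].copy(), self.mode)

    def copy(self) -> "AbundanceTable":
        return AbundanceTable(self.data.copy(), self.mode)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def load_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read a genus table from TSV (canonical) or BIOM v1-style JSON.

    TSV dialect: first column holds taxon names, header row holds sample ids,
    cells are nonnegative numbers. Row and column order is preserved. Returned
    tables are in counts mode.
    """
    path = Path(path)
    if format == "tsv":
        return _load_tsv(path)
    if format == "biom-json":
        return _load_biom_json(path)
    raise ValueError(f"format must be 'tsv' or 'biom-json', got {format!r}")


def _load_tsv(path: Path) -> AbundanceTable:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
    if not header.strip():
        raise ValueError(f"{path}: no data rows")
    sample_ids = header.split("\t")[1:]
    seen: set[str] = set()
    for sid in sample_ids:
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
    try:
        raw = pd.read_csv(path, sep="\t", header=0, index_col=0, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: no data rows") from None
    if raw.shape[0] == 0:
        raise ValueError(f"{path}: no data rows")
    if raw.index.has_duplicates:
        dupes = raw.index[raw.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate taxon name(s) {dupes}")
    numeric = pd.DataFrame(index=raw.index, columns=sample_ids, dtype=float)
    for col in sample_ids:
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.index[converted.isna() & raw[col].astype(str).str.strip().ne("")]
        if converted.isna().any():
            taxon = converted.index[converted.isna()][0] if not len(bad) else bad[0]
            raise ValueError(f"{path}: non-numeric cell at taxon {taxon!r}, sample {col!r}")
        if (converted < 0).any():
            taxon = converted.index[converted < 0][0]
            raise ValueError(f"{path}: negative cell at taxon {taxon!r}, sample {col!r}")
        numeric[col] = converted
    if np.allclose(numeric.to_numpy() % 1, 0):
        numeric = numeric.astype(np.int64)
    return AbundanceTable(numeric, COUNTS)


def _load_biom_json(path: Path) -> AbundanceTable:
    with open(path, "r", encoding="utf-8") as fh:
        doc = json.load(fh)
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    n_rows, n_cols = doc["shape"]
    values = np.zeros((n_rows, n_cols), dtype=float)
    if doc.get("matrix_type", "dense") == "sparse":
        for i, j, v in doc["data"]:
            values[int(i), int(j)] = v
    else:
        values[:] = np.asarray(doc["data"], dtype=float)
    frame = pd.DataFrame(values, index=taxa, columns=samples)
    if np.allclose(frame.to_numpy() % 1, 0):
        frame = frame.astype(np.int64)
    return AbundanceTable(frame, COUNTS)


def write_table(table: AbundanceTable, path: str | Path) -> None:
    """Write the table as canonical TSV (row order preserved, UTF-8)."""
    table.data.to_csv(path, sep="\t", index_label="taxon", lineterminator="\n")


def validate_metadata(metadata: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in METADATA_COLUMNS if c not in metadata.columns]
    if missing:
        raise ValueError(f"metadata missing column(s) {missing}")
    if metadata["sample_id"].duplicated().any():
        dupes = metadata.loc[metadata["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"duplicate sample_id in metadata: {dupes}")
    for col, allowed in (("group", GROUPS), ("niche", NICHES), ("age_class", AGE_CLASSES)):
        bad = sorted(set(metadata[col]) - set(allowed))
        if bad:
            raise ValueError(f"metadata column {col!r} has invalid value(s) {bad}; allowed {allowed}")
    return metadata


def load_metadata(path: str | Path) -> pd.DataFrame:
    metadata = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(metadata)


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.loc[:, list(METADATA_COLUMNS)].to_csv(path, sep="\t", index=False, lineterminator="\n")


def check_linkage(table: AbundanceTable, metadata: pd.DataFrame) -> None:
    """Every sample in the table must have exactly one metadata row."""
    counts = metadata["sample_id"].value_counts()
    missing = [s for s in table.samples if s not in counts.index]
    if missing:
        raise ValueError(f"samples without metadata: {missing}")


def select_samples(
    metadata: pd.DataFrame,
    group: str | None = None,
    niche: str | None = None,
    age_class: str | None = None,
) -> list[str]:
    mask = pd.Series(True, index=metadata.index)
    for col, value in (("group", group), ("niche", niche), ("age_class", age_class)):
        if value is not None:
            mask &= metadata[col] == value
    return metadata.loc[mask, "sample_id"].tolist()


# ---------------------------------------------------------------------------
# Transforms
# ---------------------------------------------------------------------------

def aggregate_to_genus(
    table: AbundanceTable,
    taxonomy_map: Mapping[str, str],
    drop_unclassified: bool = False,
) -> AbundanceTable:
    """Sum input rows (e.g. OTUs) into genus rows according to ``taxonomy_map``.

    Unmapped input taxa are an error; ``"unclassified"`` is kept as its own row
    unless ``drop_unclassified`` is set (which renormalizes relative tables).
    """
    offenders = [t for t in table.taxa if t not in taxonomy_map]
    if offenders:
        raise ValueError(f"taxa absent from taxonomy map: {offenders}")
    mapped = pd.Index([taxonomy_map[t] for t in table.taxa])
    aggregated = table.data.groupby(mapped, sort=False).sum()
    if drop_unclassified and "unclassified" in aggregated.index:
        aggregated = aggregated.drop(index="unclassified")
        if table.mode == RELATIVE:
            sums = aggregated.sum(axis=0)
            if (sums <= 0).any():
                bad = aggregated.columns[(sums <= 0)][0]
                raise ValueError(f"sample {bad!r} has no classified taxa left to renormalize")
            aggregated = aggregated / sums
    return AbundanceTable(aggregated, table.mode)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each sample column by its total; a no-op (with warning) on relative input."""
    if table.mode == RELATIVE:
        warnings.warn("to_relative called on a relative-mode table; returning it unchanged")
        return table
    sums = table.data.sum(axis=0)
    zero = sums.index[sums <= 0]
    if len(zero):
        raise ValueError(f"sample {zero[0]!r} has zero total abundance")
    return AbundanceTable((table.data / sums).astype(float), RELATIVE)


def group_mean_relative(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    group: str,
    niche: str,
    age_class: str | None = None,
) -> pd.Series:
    """Per-genus arithmetic mean of per-sample relative abundances in one stratum.

    This is the "content" statistic the translocation thresholds are applied to.
    """
    ids = select_samples(metadata, group=group, niche=niche, age_class=age_class)
    ids = [s for s in ids if s in table.data.columns]
    if not ids:
        raise ValueError(f"no samples match group={group!r}, niche={niche!r}, age_class={age_class!r}")
    if table.mode == RELATIVE:
        sub = table.data.loc[:, ids]
    else:
        sub = to_relative(table.subset_samples(ids)).data
    return sub.mean(axis=1)


def top_n_genera(
    table: AbundanceTable,
    metadata: pd.DataFrame,
    group: str,
    niche: str,
    n: int,
    age_class: str | None = None,
) -> list[tuple[str, float]]:
    """Genera ranked by descending group-mean relative abundance (ties: by name)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    means = group_mean_relative(table, metadata, group, niche, age_class=age_class)
    ranked = sorted(means.items(), key=lambda item: (-item[1], item[0]))
    return ranked[: min(n, len(ranked))]
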