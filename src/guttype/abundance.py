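"""Count/abundance table data model, I/O, taxonomy collapse, and prevalence.

The central container is :class:`AbundanceTable`, a thin wrapper around a
pandas DataFrame held samples x taxa in memory.  On disk tables follow the
common amplicon convention of taxa rows x sample columns; the orientation is
recorded by the header sentinel of the first column (``taxon_id`` or
``sample_id``) and auto-detected on read.

A "relative" table holds per-sample proportions (each row sums to one); a
"counts" table holds nonnegative read counts.  Prevalence treats any strictly
positive value as detection.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")

__all__ = [
    "AbundanceTable",
    "TaxonomyMap",
    "FormatError",
    "DegenerateSampleError",
    "read_table",
    "write_table",
    "read_metadata",
    "write_metadata",
    "collapse_to_level",
    "to_relative",
    "prevalence",
]


class FormatError(ValueError):
    """A file violated the table format contract (ragged, negative, duplicate ids)."""


class DegenerateSampleError(ValueError):
    """One or more samples carry no reads at all."""


_REL_TOL = 1e-9


@dataclass
class AbundanceTable:
    """Sample x taxon matrix of counts or relative abundances.

    Parameters
    ----------
    data:
        DataFrame indexed by sample id with taxon ids as columns.
    kind:
        ``"counts"`` or ``"relative"``.
    level:
        Taxonomic rank label of the columns (e.g. ``"family"`` or ``"otu"``).
    """

    data: pd.DataFrame
    kind: str = "counts"
    level: str = "otu"

    def __post_init__(self) -> None:
        if self.kind not in ("counts", "relative"):
            raise ValueError(f"kind must be 'counts' or 'relative', got {self.kind!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids: {dupes}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].tolist()
            raise FormatError(f"duplicate taxon ids: {dupes}")
        values = self.data.to_numpy(dtype=float)
        if np.isnan(values).any():
            bad = self.data.index[np.isnan(values).any(axis=1)].tolist()
            raise FormatError(f"non-numeric or missing cells in samples: {bad}")
        if (values < 0).any():
            bad = self.data.index[(values < 0).any(axis=1)].tolist()
            raise FormatError(f"negative values in samples: {bad}")
        if self.kind == "relative":
            sums = values.sum(axis=1)
            if not np.allclose(sums, 1.0, atol=1e-6, rtol=0):
                bad = self.data.index[np.abs(sums - 1.0) > 1e-6].tolist()
                raise ValueError(f"relative rows must sum to 1; offending samples: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_taxa(self) -> int:
        return self.data.shape[1]

    def subset(self, sample_ids: Sequence[str]) -> "AbundanceTable":
        """Restrict to the given samples, preserving order of *sample_ids*."""
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise LookupError(f"unknown sample ids: {missing}")
        return replace(self, data=self.data.loc[list(sample_ids)])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AbundanceTable):
            return NotImplemented
        return (
            self.kind == other.kind
            and self.level == other.level
            and self.data.shape == other.data.shape
            and list(self.data.index) == list(other.data.index)
            and list(self.data.columns) == list(other.data.columns)
            and np.allclose(self.values, other.values, atol=1e-9, rtol=0)
        )


@dataclass
class TaxonomyMap:
    """taxon id -> ranked lineage (kingdom..species); missing ranks flagged None."""

    lineages: dict[str, dict[str, str | None]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for taxon, lineage in self.lineages.items():
            for rank in RANKS:
                lineage.setdefault(rank, None)

    def rank_name(self, taxon_id: str, level: str) -> str | None:
        if taxon_id not in self.lineages:
            raise LookupError(f"taxon {taxon_id!r} missing from taxonomy")
        return self.lineages[taxon_id].get(level)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        frame = pd.read_csv(path, sep="\t", index_col=0, dtype=str, comment="#")
        lineages: dict[str, dict[str, str | None]] = {}
        for taxon, row in frame.iterrows():
            lineages[str(taxon)] = {
                rank: (None if pd.isna(row.get(rank)) or row.get(rank) == "" else str(row[rank]))
                for rank in RANKS
                if rank in frame.columns
            }
        return cls(lineages)

    def to_tsv(self, path: str | Path) -> None:
        frame = pd.DataFrame.from_dict(self.lineages, orient="index")
        frame = frame.reindex(columns=list(RANKS))
        frame.index.name = "taxon_id"
        frame.to_csv(path, sep="\t")


def read_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read a count table from TSV or dense BIOM-style JSON.

    TSV tables may be taxa x samples (first header cell ``taxon_id``, the
    on-disk default) or samples x taxa (first header cell ``sample_id``).
    """
    path = Path(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "biom-json":
        return _read_biom_json(path)
    raise ValueError(f"unknown format {format!r}")


def _read_tsv(path: Path) -> AbundanceTable:
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    except pd.errors.ParserError as exc:
        raise FormatError(f"cannot parse {path}: {exc}") from exc
    sentinel = (frame.index.name or "").strip().lower()
    frame = frame.apply(pd.to_numeric, errors="coerce")
    if sentinel == "sample_id":
        data = frame
    else:
        data = frame.T  # taxa-rows layout is the disk default
    data.index = data.index.astype(str)
    data.columns = data.columns.astype(str)
    data.index.name = "sample_id"
    return AbundanceTable(data=data, kind="counts")


def _read_biom_json(path: Path) -> AbundanceTable:
    with open(path) as fh:
        doc = json.load(fh)
    if doc.get("matrix_type") != "dense":
        raise FormatError("only dense BIOM-style JSON is supported")
    taxa = [row["id"] for row in doc["rows"]]
    samples = [col["id"] for col in doc["columns"]]
    matrix = np.asarray(doc["data"], dtype=float)
    if matrix.shape != (len(taxa), len(samples)):
        raise FormatError(
            f"data shape {matrix.shape} does not match rows x columns "
            f"({len(taxa)}, {len(samples)})"
        )
    data = pd.DataFrame(matrix.T, index=pd.Index(samples, name="sample_id"), columns=taxa)
    return AbundanceTable(data=data, kind="counts")


def write_table(
    table: AbundanceTable,
    path: str | Path,
    format: str = "tsv",
    header_lines: Iterable[str] = (),
) -> None:
    """Write taxa x samples TSV (or dense BIOM-style JSON)."""
    path = Path(path)
    if format == "tsv":
        disk = table.data.T
        disk.index.name = "taxon_id"
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            disk.to_csv(fh, sep="\t")
    elif format == "biom-json":
        doc = {
            "id": None,
            "format": "1.0.0",
            "type": "OTU table",
            "matrix_type": "dense",
            "matrix_element_type": "float",
            "shape": [table.n_taxa, table.n_samples],
            "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
            "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
            "data": table.values.T.tolist(),
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample-metadata TSV indexed by sample id."""
    frame = pd.read_csv(path, sep="\t", index_col=0, comment="#")
    frame.index = frame.index.astype(str)
    frame.index.name = "sample_id"
    if "bmi" in frame.columns:
        bad = frame.index[frame["bmi"].notna() & (frame["bmi"] <= 0)].tolist()
        if bad:
            raise FormatError(f"non-positive BMI for samples: {bad}")
    return frame


def write_metadata(metadata: pd.DataFrame, path: str | Path, header_lines: Iterable[str] = ()) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        metadata.to_csv(fh, sep="\t")


def collapse_to_level(table: AbundanceTable, taxonomy: TaxonomyMap, level: str) -> AbundanceTable:
    """Sum member taxa into one group per distinct lineage value at *level*.

    Taxa with no classification at *level* are pooled into a single
    ``unclassified_<level>`` group, so per-sample totals are preserved exactly.
    """
    if level not in RANKS:
        raise ValueError(f"unknown rank {level!r}; expected one of {RANKS}")
    groups: dict[str, str] = {}
    for taxon in table.taxon_ids:
        name = taxonomy.rank_name(taxon, level)
        groups[taxon] = name if name else f"unclassified_{level}"
    collapsed = table.data.T.groupby(table.data.columns.map(groups), sort=False).sum().T
    collapsed.columns.name = None
    return AbundanceTable(data=collapsed, kind=table.kind, level=level)


def to_relative(table: AbundanceTable) -> AbundanceTable:
    """Divide each cell by its sample total; result rows sum to one."""
    if table.kind != "counts":
        raise ValueError("to_relative expects a counts table")
    totals = table.values.sum(axis=1)
    zero = totals <= 0
    if zero.any():
        bad = [s for s, z in zip(table.sample_ids, zero) if z]
        raise DegenerateSampleError(f"samples with zero total counts: {bad}")
    data = table.data.div(pd.Series(totals, index=table.data.index), axis=0)
    return AbundanceTable(data=data, kind="relative", level=table.level)


def prevalence(table: AbundanceTable, group: Sequence[str] | None = None) -> pd.Series:
    """Per-taxon fraction of samples with a strictly positive value, in [0, 1]."""
    if group is None:
        sub = table.data
    else:
        group = list(group)
        if not group:
            raise ValueError("prevalence group must be nonempty")
        missing = [s for s in group if s not in table.data.index]
        if missing:
            raise LookupError(f"unknown sample ids: {missing}")
        sub = table.data.loc[group]
    return (sub > 0).mean(axis=0)
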