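"""Shared data model and file I/O for multi-site herd microbiota analysis.

The pipeline works on three inputs: an ASV count table (samples x ASVs,
integer read counts), a per-sample metadata sheet (animal, body site, time
point, animal group, genomic scores, negative-control flag) and a rooted
phylogenetic tree whose leaves are ASV identifiers.  This module defines the
in-memory containers for those objects, the removal log that makes every
filtering decision replayable, and readers/writers for the plain-text
formats the pipeline exchanges (TSV, BIOM 1.0 JSON, newick).

Conventions
-----------
* Sample and ASV identifiers are case-sensitive and whitespace-trimmed.
* TSV count tables are samples-as-rows by default; an ``asvs_as_rows`` flag
  transposes at read/write time because both dialects exist in the wild.
* Only the two genomic scores (``sm_score``, ``bc_score``) may be missing in
  the metadata; every other field of a non-control sample is required.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from io import StringIO
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from skbio import TreeNode

#: Body sites sampled on each animal.
SITES = ("oral", "nasal", "vaginal", "milk")
#: Pseudo-site used for negative (extraction/kit) control samples.
CONTROL_SITE = "control"
#: Sampling occasions: one week pre-partum, then 1, 3 and 7 months in milk.
TIMEPOINTS = ("-1W", "1M", "3M", "7M")
#: Animal groups (calving batches, which also differ in diet/housing).
GROUPS = ("G1", "G2", "G3")

METADATA_COLUMNS = (
    "animal_id",
    "site",
    "time",
    "group",
    "sm_score",
    "bc_score",
    "quarter",
    "is_control",
)


class FormatError(ValueError):
    """A file violates its format contract (duplicate IDs, bad header, ...)."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for i in ids:
        if i in seen:
            raise FormatError(f"duplicate {what} ID: {i!r}")
        seen.add(i)


class AsvCountTable:
    """Integer read counts, samples x ASVs.

    Parameters
    ----------
    sample_ids, asv_ids : sequences of unique strings
    counts : array-like of shape (n_samples, n_asvs)
        Non-negative integers.  Float inputs are accepted only when every
        cell is integral (e.g. a table read back from TSV).
    """

    __slots__ = ("sample_ids", "asv_ids", "counts", "_sidx", "_aidx")

    def __init__(self, sample_ids: Sequence[str], asv_ids: Sequence[str], counts) -> None:
        sample_ids = [str(s).strip() for s in sample_ids]
        asv_ids = [str(a).strip() for a in asv_ids]
        _check_unique(sample_ids, "sample")
        _check_unique(asv_ids, "ASV")
        arr = np.asarray(counts)
        if arr.ndim != 2 or arr.shape != (len(sample_ids), len(asv_ids)):
            raise ValueError(
                f"counts shape {arr.shape} does not match "
                f"({len(sample_ids)} samples, {len(asv_ids)} ASVs)"
            )
        if not np.issubdtype(arr.dtype, np.integer):
            if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr))):
                raise ValueError("counts must be finite integers")
            arr = arr.astype(np.int64)
        else:
            arr = arr.astype(np.int64, copy=True)
        if arr.size and arr.min() < 0:
            raise ValueError("counts must be non-negative")
        self.sample_ids = list(sample_ids)
        self.asv_ids = list(asv_ids)
        self.counts = arr
        self._sidx = {s: i for i, s in enumerate(self.sample_ids)}
        self._aidx = {a: j for j, a in enumerate(self.asv_ids)}

    # -- basic queries -----------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_asvs(self) -> int:
        return len(self.asv_ids)

    def sample_index(self, sample_id: str) -> int:
        return self._sidx[sample_id]

    def asv_index(self, asv_id: str) -> int:
        return self._aidx[asv_id]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def sample_counts(self, sample_id: str) -> np.ndarray:
        return self.counts[self._sidx[sample_id]]

    # -- subsetting --------------------------------------------------------
    def select_samples(self, sample_ids: Sequence[str]) -> "AsvCountTable":
        idx = [self._sidx[s] for s in sample_ids]
        return AsvCountTable(list(sample_ids), self.asv_ids, self.counts[idx])

    def select_asvs(self, asv_ids: Sequence[str]) -> "AsvCountTable":
        idx = [self._aidx[a] for a in asv_ids]
        return AsvCountTable(self.sample_ids, list(asv_ids), self.counts[:, idx])

    def drop_asvs(self, asv_ids: Iterable[str]) -> "AsvCountTable":
        drop = set(asv_ids)
        unknown = drop - set(self.asv_ids)
        if unknown:
            raise ValueError(f"unknown ASV IDs: {sorted(unknown)}")
        keep = [a for a in self.asv_ids if a not in drop]
        return self.select_asvs(keep)

    def drop_samples(self, sample_ids: Iterable[str]) -> "AsvCountTable":
        drop = set(sample_ids)
        unknown = drop - set(self.sample_ids)
        if unknown:
            raise ValueError(f"unknown sample IDs: {sorted(unknown)}")
        keep = [s for s in self.sample_ids if s not in drop]
        return self.select_samples(keep)

    # -- conversion --------------------------------------------------------
    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.asv_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "AsvCountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AsvCountTable):
            return NotImplemented
        return (
            self.sample_ids == other.sample_ids
            and self.asv_ids == other.asv_ids
            and np.array_equal(self.counts, other.counts)
        )

    def __repr__(self) -> str:
        return f"<AsvCountTable {self.n_samples} samples x {self.n_asvs} ASVs>"


# ---------------------------------------------------------------------------
# Count-table I/O
# ---------------------------------------------------------------------------

def read_asv_table(path, format: str = "tsv", asvs_as_rows: bool = False) -> AsvCountTable:
    """Read a count table from TSV or BIOM 1.0 JSON.

    TSV tables are samples-as-rows unless ``asvs_as_rows`` is set, in which
    case the table is transposed at read time.
    """
    if format == "tsv":
        return _read_tsv_table(path, asvs_as_rows)
    if format in ("biom-json", "biom"):
        return _read_biom_json(path)
    raise ValueError(f"unknown count-table format: {format!r}")


def write_asv_table(table: AsvCountTable, path, format: str = "tsv", asvs_as_rows: bool = False) -> None:
    if format == "tsv":
        df = table.to_dataframe()
        if asvs_as_rows:
            df = df.T
        df.to_csv(path, sep="\t", index_label="id")
    elif format in ("biom-json", "biom"):
        _write_biom_json(table, path)
    else:
        raise ValueError(f"unknown count-table format: {format!r}")


def _read_tsv_table(path, asvs_as_rows: bool) -> AsvCountTable:
    # pandas silently mangles duplicate column headers, so check them raw.
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
    _check_unique([h.strip() for h in header[1:]], "column")
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"duplicate row ID: {dup!r}")
    if asvs_as_rows:
        df = df.T
    arr = df.to_numpy()
    if arr.size and not np.issubdtype(arr.dtype, np.number):
        raise ValueError("count table contains non-numeric cells")
    if arr.size and not np.all(np.isfinite(arr.astype(float))):
        raise ValueError("count table contains NaN/inf cells")
    return AsvCountTable.from_dataframe(df)


_BIOM_FORMAT = "Biological Observation Matrix 1.0.0"


def _write_biom_json(table: AsvCountTable, path) -> None:
    # Minimal sparse BIOM 1.0 writer.  BIOM rows are observations (ASVs),
    # columns are samples.  ``date`` is left empty so outputs are
    # byte-reproducible.
    rows_idx, cols_idx = np.nonzero(table.counts.T)
    data = [
        [int(r), int(c), int(table.counts[c, r])]
        for r, c in zip(rows_idx.tolist(), cols_idx.tolist())
    ]
    obj = {
        "id": None,
        "format": _BIOM_FORMAT,
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": "holoshare",
        "date": "",
        "matrix_type": "sparse",
        "matrix_element_type": "int",
        "shape": [table.n_asvs, table.n_samples],
        "rows": [{"id": a, "metadata": None} for a in table.asv_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, separators=(",", ":"))


def _read_biom_json(path) -> AsvCountTable:
    with open(path, "r", encoding="utf-8") as fh:
        obj = json.load(fh)
    asv_ids = [r["id"] for r in obj["rows"]]
    sample_ids = [c["id"] for c in obj["columns"]]
    n_asvs, n_samples = obj["shape"]
    counts = np.zeros((n_samples, n_asvs), dtype=np.int64)
    if obj.get("matrix_type") == "dense":
        dense = np.asarray(obj["data"])
        if dense.shape != (n_asvs, n_samples):
            raise FormatError("BIOM dense data does not match declared shape")
        counts = dense.T
    else:
        for r, c, v in obj["data"]:
            counts[c, r] = v
    return AsvCountTable(sample_ids, asv_ids, counts)


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

class SampleMetadata:
    """Per-sample metadata indexed by sample ID.

    Non-control samples must carry ``animal_id``, ``site``, ``time`` and
    ``group``; control samples are flagged with ``is_control`` and the
    pseudo-site ``control`` and need none of those.  The two genomic scores
    may be missing (NaN) and are simply excluded from models that use them.
    """

    def __init__(self, df: pd.DataFrame) -> None:
        df = df.copy()
        df.index = df.index.astype(str).str.strip()
        if df.index.duplicated().any():
            dup = df.index[df.index.duplicated()][0]
            raise FormatError(f"duplicate sample ID in metadata: {dup!r}")
        for col in METADATA_COLUMNS:
            if col not in df.columns:
                if col in ("quarter",):
                    df[col] = pd.NA
                else:
                    raise FormatError(f"metadata missing required column {col!r}")
        df["is_control"] = df["is_control"].map(_parse_bool)
        for col in ("animal_id", "site", "time", "group", "quarter"):
            df[col] = df[col].astype("string").str.strip()
        for col in ("sm_score", "bc_score"):
            df[col] = pd.to_numeric(df[col], errors="raise")
        self._validate(df)
        self.df = df[list(METADATA_COLUMNS)]

    @staticmethod
    def _validate(df: pd.DataFrame) -> None:
        valid_sites = set(SITES) | {CONTROL_SITE}
        for sid, row in df.iterrows():
            site = row["site"]
            if pd.isna(site) or site not in valid_sites:
                raise ValueError(f"sample {sid!r}: unknown site {site!r}")
            is_ctrl = bool(row["is_control"])
            if is_ctrl != (site == CONTROL_SITE):
                raise ValueError(
                    f"sample {sid!r}: is_control flag inconsistent with site {site!r}"
                )
            if not is_ctrl:
                for col in ("animal_id", "time", "group"):
                    if pd.isna(row[col]) or row[col] == "":
                        raise ValueError(f"non-control sample {sid!r} missing {col!r}")
                if row["time"] not in TIMEPOINTS:
                    raise ValueError(
                        f"sample {sid!r}: unknown time point {row['time']!r}"
                    )
                if row["group"] not in GROUPS:
                    raise ValueError(f"sample {sid!r}: unknown group {row['group']!r}")

    # -- queries -----------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.df.index)

    @property
    def control_ids(self) -> list[str]:
        return list(self.df.index[self.df["is_control"]])

    @property
    def non_control_ids(self) -> list[str]:
        return list(self.df.index[~self.df["is_control"]])

    def subset(self, sample_ids: Sequence[str]) -> "SampleMetadata":
        return SampleMetadata(self.df.loc[list(sample_ids)])

    def column(self, name: str) -> pd.Series:
        return self.df[name]

    def samples_where(self, **conditions) -> list[str]:
        """Sample IDs matching equality conditions, e.g. site='oral', time='1M'."""
        mask = pd.Series(True, index=self.df.index)
        for col, val in conditions.items():
            mask &= self.df[col] == val
        return list(self.df.index[mask])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SampleMetadata):
            return NotImplemented
        return self.df.equals(other.df)

    def __repr__(self) -> str:
        return f"<SampleMetadata {len(self.df)} samples ({len(self.control_ids)} controls)>"


def _parse_bool(v) -> bool:
    if isinstance(v, (bool, np.bool_)):
        return bool(v)
    if isinstance(v, (int, np.integer, float)) and not pd.isna(v):
        return bool(int(v))
    s = str(v).strip().lower()
    if s in ("true", "t", "yes", "1"):
        return True
    if s in ("false", "f", "no", "0", ""):
        return False
    raise ValueError(f"cannot parse boolean flag {v!r}")


def read_metadata(path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    meta.df.to_csv(path, sep="\t", index_label="sample_id")


# ---------------------------------------------------------------------------
# Phylogenetic tree
# ---------------------------------------------------------------------------

class PhylogeneticTree:
    """Rooted tree over ASVs with non-negative branch lengths.

    Wraps a :class:`skbio.TreeNode`.  Missing branch lengths on non-root
    nodes are rejected at construction (no silent zero-fill); a missing root
    length is treated as 0, which is immaterial to every metric computed on
    the tree.
    """

    def __init__(self, tree: TreeNode) -> None:
        if tree.length is None:
            tree.length = 0.0
        names = []
        for node in tree.traverse(include_self=False):
            if node.length is None:
                raise FormatError("tree has a branch without a length")
            if node.length < 0:
                raise FormatError("tree has a negative branch length")
            if node.is_tip():
                names.append(node.name)
        if any(n is None for n in names):
            raise FormatError("tree has unnamed leaves")
        _check_unique(names, "leaf")
        self.tree = tree
        self._leaf_names = sorted(names)

    @property
    def leaf_names(self) -> list[str]:
        """Leaf labels in deterministic (sorted) order."""
        return list(self._leaf_names)

    @property
    def n_leaves(self) -> int:
        return len(self._leaf_names)

    def total_branch_length(self) -> float:
        return float(
            sum(node.length for node in self.tree.traverse(include_self=False))
        )

    @classmethod
    def from_newick(cls, newick: str) -> "PhylogeneticTree":
        # convert_underscores=False: underscores in ASV IDs are literal
        return cls(
            TreeNode.read(StringIO(newick), format="newick", convert_underscores=False)
        )

    def to_newick(self) -> str:
        out = StringIO()
        self.tree.write(out, format="newick")
        return out.getvalue()

    def __repr__(self) -> str:
        return f"<PhylogeneticTree {self.n_leaves} leaves>"


def read_tree(path) -> PhylogeneticTree:
    return PhylogeneticTree(
        TreeNode.read(str(path), format="newick", convert_underscores=False)
    )


def write_tree(tree: PhylogeneticTree, path) -> None:
    tree.tree.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """Symmetric pairwise dissimilarities with an explicit sample order."""

    __slots__ = ("ids", "data")

    def __init__(self, ids: Sequence[str], data) -> None:
        ids = [str(i) for i in ids]
        _check_unique(ids, "sample")
        arr = np.asarray(data, dtype=float)
        n = len(ids)
        if arr.shape != (n, n):
            raise ValueError(f"distance matrix shape {arr.shape} != ({n}, {n})")
        if not np.allclose(arr, arr.T, atol=1e-10):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(arr), 0.0, atol=1e-10):
            raise ValueError("distance matrix diagonal is not zero")
        if arr.size and arr.min() < -1e-12:
            raise ValueError("distance matrix has negative entries")
        arr = np.clip((arr + arr.T) / 2.0, 0.0, None)
        np.fill_diagonal(arr, 0.0)
        self.ids = list(ids)
        self.data = arr

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        pos = {s: i for i, s in enumerate(self.ids)}
        idx = [pos[s] for s in ids]
        return DistanceMatrix(list(ids), self.data[np.ix_(idx, idx)])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.ids, columns=self.ids)

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index_label="id")

    @classmethod
    def read_tsv(cls, path) -> "DistanceMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(list(df.index.astype(str)), df.to_numpy())

    def __repr__(self) -> str:
        return f"<DistanceMatrix {len(self.ids)} samples>"


# ---------------------------------------------------------------------------
# Removal log
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RemovalRecord:
    entity_id: str
    entity_kind: str  # "asv" | "sample"
    rule_id: str
    values: dict = field(default_factory=dict)


class RemovalLog:
    """Ordered record of every ASV/sample removed by a filtering rule.

    Replaying the log against the original input table reproduces the
    filtered table exactly, which is the auditable contract of the whole
    filtering chain.
    """

    def __init__(self, records: Iterable[RemovalRecord] = ()) -> None:
        self.records: list[RemovalRecord] = list(records)

    def add(self, entity_id: str, entity_kind: str, rule_id: str, values: dict | None = None) -> None:
        if entity_kind not in ("asv", "sample"):
            raise ValueError(f"unknown entity kind {entity_kind!r}")
        self.records.append(RemovalRecord(entity_id, entity_kind, rule_id, values or {}))

    def extend(self, other: "RemovalLog") -> None:
        self.records.extend(other.records)

    def removed_ids(self, kind: str) -> list[str]:
        return [r.entity_id for r in self.records if r.entity_kind == kind]

    def replay(self, table: AsvCountTable) -> AsvCountTable:
        """Apply every recorded removal, in order, to ``table``."""
        out = table
        for rec in self.records:
            if rec.entity_kind == "asv":
                out = out.drop_asvs([rec.entity_id])
            else:
                out = out.drop_samples([rec.entity_id])
        return out

    def to_dataframe(self) -> pd.DataFrame:
        rows = [
            {
                "entity_id": r.entity_id,
                "entity_kind": r.entity_kind,
                "rule_id": r.rule_id,
                "values": json.dumps(r.values, sort_keys=True),
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=["entity_id", "entity_kind", "rule_id", "values"])

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# Relative abundance
# ---------------------------------------------------------------------------

def relative_abundance(table: AsvCountTable) -> np.ndarray:
    """Per-sample relative abundances (rows sum to 1).

    Raises ``ValueError`` naming the first offending sample if any sample
    has a zero read total.
    """
    totals = table.sample_totals()
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"sample {table.sample_ids[zero[0]]!r} has zero total reads; "
            "cannot compute relative abundance"
        )
    return table.counts / totals[:, None]
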