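"""Readers, writers and validated containers for the pipeline's external formats.

Everything tabular is tab-separated UTF-8 with '.' as the decimal separator.
Sample and taxon order is preserved exactly as found in the file; nothing is
sorted silently. Trees are Newick; distance matrices are square TSV with
matching row and column headers.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.io import NewickFormatError, UnrecognizedFormatError


class FormatError(ValueError):
    """A file does not conform to the expected on-disk format."""


class DesignError(ValueError):
    """Sample metadata violates the paired pre/post study design."""


TIMEPOINTS = ("pre", "post")
YES_NO = ("yes", "no")
SOURCES = ("faeces", "ileostomy_effluent")
METADATA_COLUMNS = ("sample_id", "subject_id", "timepoint", "ileostomy", "sdd", "source")


@dataclass
class CountTable:
    """Integer abundance matrix, samples (rows) by taxa (columns).

    Invariants enforced on construction: non-negative integer entries,
    unique sample and taxon labels, dimensions matching the label lists.
    """

    sample_ids: list[str]
    taxon_ids: list[str]
    counts: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.taxon_ids = [str(t) for t in self.taxon_ids]
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise FormatError(f"counts must be 2-D, got shape {counts.shape}")
        if counts.shape != (len(self.sample_ids), len(self.taxon_ids)):
            raise FormatError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.taxon_ids)} taxa"
            )
        if counts.size and not np.issubdtype(counts.dtype, np.integer):
            if not np.all(np.isfinite(counts)) or np.any(counts != np.floor(counts)):
                i, j = np.argwhere((counts != np.floor(counts)) | ~np.isfinite(counts))[0]
                raise FormatError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"taxon {self.taxon_ids[j]!r}: {counts[i, j]!r}"
                )
        counts = counts.astype(np.int64)
        if counts.size and counts.min() < 0:
            i, j = np.argwhere(counts < 0)[0]
            raise FormatError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"taxon {self.taxon_ids[j]!r}: {counts[i, j]}"
            )
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids in count table")
        if len(set(self.taxon_ids)) != len(self.taxon_ids):
            raise FormatError("duplicate taxon ids in count table")
        self.counts = counts

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.taxon_ids)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def select_samples(self, sample_ids: list[str]) -> "CountTable":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in sample_ids if s not in pos]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        idx = [pos[s] for s in sample_ids]
        return CountTable(list(sample_ids), list(self.taxon_ids), self.counts[idx])

    def equals(self, other: "CountTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.taxon_ids == other.taxon_ids
            and np.array_equal(self.counts, other.counts)
        )


def read_count_table(path: str | Path) -> CountTable:
    """Read a samples-by-taxa TSV (header = taxon ids, first column = sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.name is None and df.empty and df.shape[1] == 0:
        return CountTable([], [], np.zeros((0, 0), dtype=np.int64))
    values = np.empty(df.shape, dtype=np.int64)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = raw[i, j]
            try:
                x = float(cell)
            except (TypeError, ValueError):
                raise FormatError(
                    f"non-numeric count at sample {df.index[i]!r}, "
                    f"taxon {df.columns[j]!r}: {cell!r}"
                ) from None
            if not np.isfinite(x) or x != int(x):
                raise FormatError(
                    f"non-integer count at sample {df.index[i]!r}, "
                    f"taxon {df.columns[j]!r}: {cell!r}"
                )
            if x < 0:
                raise FormatError(
                    f"negative count at sample {df.index[i]!r}, "
                    f"taxon {df.columns[j]!r}: {cell!r}"
                )
            values[i, j] = int(x)
    return CountTable(list(df.index.astype(str)), list(df.columns.astype(str)), values)


def write_count_table(table: CountTable, path: str | Path) -> None:
    df = table.to_dataframe()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def validate_metadata(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a sample-metadata frame against the paired-design invariants.

    Raises :class:`DesignError` on: duplicate sample ids, more than one pre
    or post sample per subject, subject-level factors (ileostomy, sdd)
    varying within a subject, or ileostomy-effluent source attached to a
    preoperative sample or a non-ileostomy subject. A subject with only one
    of the two samples is legal (missingness is part of the design).
    """
    missing_cols = [c for c in METADATA_COLUMNS if c not in df.columns]
    if missing_cols:
        raise FormatError(f"metadata missing required columns: {missing_cols}")
    df = df.loc[:, list(METADATA_COLUMNS)].astype(str)
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DesignError(f"duplicate sample id {dup!r}")
    for col, allowed in (("timepoint", TIMEPOINTS), ("ileostomy", YES_NO), ("sdd", YES_NO), ("source", SOURCES)):
        bad = set(df[col]) - set(allowed)
        if bad:
            raise FormatError(f"invalid {col} value(s) {sorted(bad)}; allowed: {allowed}")
    for subject, grp in df.groupby("subject_id", sort=False):
        for tp in TIMEPOINTS:
            if (grp["timepoint"] == tp).sum() > 1:
                raise DesignError(f"subject {subject!r} has more than one {tp!r} sample")
        for col in ("ileostomy", "sdd"):
            if grp[col].nunique() > 1:
                raise DesignError(f"{col} varies within subject {subject!r}")
    effluent = df["source"] == "ileostomy_effluent"
    bad = effluent & ((df["timepoint"] != "post") | (df["ileostomy"] != "yes"))
    if bad.any():
        sid = df.loc[bad, "sample_id"].iloc[0]
        raise DesignError(
            f"sample {sid!r}: ileostomy_effluent source requires timepoint=post and ileostomy=yes"
        )
    return df.reset_index(drop=True)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read and validate a sample-metadata TSV."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return validate_metadata(df)


def write_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_newick(path_or_str: str | Path) -> TreeNode:
    """Read a rooted Newick tree.

    Branch lengths absent from the file are set to 0.0 (with a warning for
    non-root edges); this keeps phylogenetic diversity and UniFrac defined
    while contributing nothing to them.
    """
    source = str(path_or_str)
    try:
        if "(" in source or ";" in source:
            tree = TreeNode.read(io.StringIO(source), format="newick")
        else:
            tree = TreeNode.read(source, format="newick")
    except (NewickFormatError, UnrecognizedFormatError) as exc:
        raise FormatError(f"invalid Newick: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=True):
        if node.length is None:
            if not node.is_root():
                n_missing += 1
            node.length = 0.0
    if n_missing:
        warnings.warn(
            f"{n_missing} branch(es) had no length in the Newick source; set to 0.0",
            stacklevel=2,
        )
    return tree


def write_newick(tree: TreeNode, path: str | Path) -> None:
    tree.write(str(path), format="newick")


def tree_leaf_names(tree: TreeNode) -> list[str]:
    return [tip.name for tip in tree.tips()]


def check_taxa_in_tree(taxon_ids: list[str], tree: TreeNode) -> None:
    """Raise if any taxon lacks exactly one leaf in the tree."""
    leaves = tree_leaf_names(tree)
    counts = pd.Series(leaves).value_counts()
    missing = [t for t in taxon_ids if t not in counts.index]
    if missing:
        raise KeyError(f"taxa absent from tree: {missing[:5]}" + ("..." if len(missing) > 5 else ""))
    dup = [t for t in taxon_ids if counts[t] > 1]
    if dup:
        raise KeyError(f"taxa mapping to multiple leaves: {dup[:5]}")


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    """Read a square TSV distance matrix with matching row/column headers."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index.astype(str)) != list(df.columns.astype(str)):
        raise FormatError("distance matrix row and column headers differ")
    try:
        return DistanceMatrix(df.to_numpy(dtype=float), ids=list(df.index.astype(str)))
    except Exception as exc:  # skbio validates symmetry / zero diagonal
        raise FormatError(f"invalid distance matrix: {exc}") from exc


def write_distance_matrix(dm: DistanceMatrix, path: str | Path) -> None:
    df = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", float_format="%.12g")
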