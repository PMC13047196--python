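"""Readers, writers and validation for OTU tables, sample metadata and trees.

All tabular files are UTF-8 tab-separated text with a header row; the first
column holds sample identifiers. Trees are Newick. Readers validate and
reject malformed input instead of coercing it.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

#: measured physicochemical variables carried by a SampleFrame
ENV_VARS = (
    "TN", "NH4", "NO3", "AP", "AK", "TS",
    "pH", "moisture", "OM", "density", "unit_weight",
)

DESIGN_COLS = ("group", "stage", "replicate")


class FormatError(ValueError):
    """Malformed input file (duplicates, negatives, non-integer counts)."""


class AlignmentError(ValueError):
    """Sample identifiers do not match between count table and metadata."""


class DegenerateSampleError(ValueError):
    """A sample with zero total counts where positive totals are required."""


@dataclass
class CountTable:
    """Samples x taxa matrix of non-negative integer abundances."""

    counts: pd.DataFrame  # index = sample ids, columns = taxon ids

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise FormatError(f"duplicate taxon ids: {dups}")
        if df.shape[0] < 2 or df.shape[1] < 2:
            raise FormatError("count table needs at least 2 samples and 2 taxa")
        arr = df.to_numpy()
        if not np.isfinite(arr).all():
            raise FormatError("counts must be finite")
        if (arr < 0).any():
            raise FormatError("counts must be non-negative")
        if not np.allclose(arr, np.round(arr)):
            raise FormatError("counts must be integers")
        self.counts = df.astype(np.int64)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.counts.to_numpy()

    def restrict_samples(self, sample_ids) -> "CountTable":
        return CountTable(self.counts.loc[list(sample_ids)].copy())


@dataclass
class SampleFrame:
    """Per-sample design factors (group, stage, replicate) and environment."""

    frame: pd.DataFrame  # index = sample ids
    env_vars: tuple = field(default=ENV_VARS)

    def __post_init__(self) -> None:
        df = self.frame
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise FormatError(f"duplicate sample ids: {dups}")
        missing = [c for c in DESIGN_COLS if c not in df.columns]
        if missing:
            raise FormatError(f"metadata missing design columns: {missing}")
        present_env = [v for v in self.env_vars if v in df.columns]
        if present_env:
            env = df[present_env].to_numpy(dtype=float)
            if not np.isfinite(env).all():
                raise FormatError("environmental values must be finite")
        self.env_vars = tuple(present_env)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def env(self) -> pd.DataFrame:
        return self.frame[list(self.env_vars)].astype(float)

    def groups(self) -> list:
        seen: list = []
        for g in self.frame["group"]:
            if g not in seen:
                seen.append(g)
        return seen

    def samples_in_group(self, group) -> list[str]:
        mask = self.frame["group"] == group
        return list(self.frame.index[mask])


def read_count_table(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric counts in column {col!r}")
    return CountTable(df)


def write_count_table(table: CountTable, path) -> None:
    table.counts.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path) -> SampleFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = None
    return SampleFrame(df)


def write_metadata(meta: SampleFrame, path) -> None:
    meta.frame.to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    tree = TreeNode.read(str(path), format="newick")
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise FormatError("tree has branches without lengths")
        if node.length < 0:
            raise FormatError("tree has negative branch lengths")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


def align(table: CountTable, meta: SampleFrame) -> tuple[CountTable, SampleFrame]:
    """Harmonize sample order between table and metadata.

    The table's order wins. Any sample present on one side only is an error.
    """
    t, m = set(table.sample_ids), set(meta.sample_ids)
    if t != m:
        only_t = sorted(t - m)
        only_m = sorted(m - t)
        raise AlignmentError(
            f"sample mismatch: only in table {only_t}; only in metadata {only_m}"
        )
    frame = meta.frame.loc[table.sample_ids].copy()
    return table, SampleFrame(frame)


def check_tree_covers(table: CountTable, tree: TreeNode) -> list[str]:
    """Return taxa of the table missing from the tree's tips."""
    tips = {t.name for t in tree.tips()}
    return [t for t in table.taxon_ids if t not in tips]


def relative_abundance(table: CountTable) -> pd.DataFrame:
    """Row-normalize counts; each row sums to 1."""
    arr = table.matrix.astype(float)
    sums = arr.sum(axis=1)
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        bad = [table.sample_ids[i] for i in zero]
        raise DegenerateSampleError(f"samples with zero total counts: {bad}")
    return pd.DataFrame(
        arr / sums[:, None], index=table.counts.index, columns=table.counts.columns
    )
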