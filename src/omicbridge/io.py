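"""Readers and writers for the on-disk formats the pipeline consumes and emits.

Tables are TSV with samples in rows (first column = sample id), UTF-8,
decimal point. Trees are newick. Networks export to GraphML (via networkx)
or a flat edge TSV that round-trips the edge multiset.
"""

from __future__ import annotations

import dataclasses
import io as _io
import json
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd
import networkx as nx
from skbio import TreeNode


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# sample metadata


REQUIRED_METADATA_COLUMNS = ("sample", "subject", "group", "timepoint")


@dataclasses.dataclass
class SampleMetadata:
    """Per-sample design information: subject, group label, timepoint."""

    frame: pd.DataFrame  # indexed by sample id; columns subject, group, timepoint

    def __post_init__(self) -> None:
        if self.frame.index.duplicated().any():
            dups = self.frame.index[self.frame.index.duplicated()].tolist()
            raise FormatError(f"duplicate sample ids in metadata: {dups}")
        pairs = self.frame[["subject", "timepoint"]]
        if pairs.duplicated().any():
            bad = pairs[pairs.duplicated()].to_records(index=False).tolist()
            raise FormatError(f"(subject, timepoint) pairs repeated: {bad}")

    @property
    def samples(self) -> list[str]:
        return list(self.frame.index)

    def group_of(self) -> pd.Series:
        return self.frame["group"]

    def subset(self, samples: Iterable[str]) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(samples)].copy())


@dataclasses.dataclass
class AbundanceTable:
    """Taxon count table, samples × taxa, nonnegative integers."""

    counts: pd.DataFrame  # index = sample ids, columns = taxon ids
    taxonomy: pd.Series | None = None  # optional lineage per taxon

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise FormatError("duplicate sample ids in abundance table")
        if self.counts.columns.duplicated().any():
            raise FormatError("duplicate taxon ids in abundance table")
        if (self.counts.values < 0).any():
            raise FormatError("negative counts in abundance table")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.index)

    @property
    def taxa(self) -> list[str]:
        return list(self.counts.columns)

    def relative(self) -> pd.DataFrame:
        """Per-sample closure to proportions."""
        totals = self.counts.sum(axis=1)
        if (totals == 0).any():
            zeros = totals.index[totals == 0].tolist()
            raise FormatError(f"samples with zero total count: {zeros}")
        return self.counts.div(totals, axis=0)


@dataclasses.dataclass
class FeatureTable:
    """Continuous nonnegative feature table (metabolites or indicators)."""

    values: pd.DataFrame  # index = sample ids, columns = feature ids
    annotation: pd.DataFrame | None = None  # optional per-feature m/z, rt, name

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError("duplicate sample ids in feature table")
        if self.values.columns.duplicated().any():
            raise FormatError("duplicate feature ids in feature table")
        vals = self.values.values
        if not np.isfinite(vals).all():
            raise FormatError("non-finite values in feature table")
        if (vals < 0).any():
            raise FormatError("negative values in feature table")

    @property
    def samples(self) -> list[str]:
        return list(self.values.index)

    @property
    def features(self) -> list[str]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# table I/O


def _read_tsv(path: str | Path, transpose: bool = False) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if transpose:
        df = df.T
    return df


def read_metadata(path: str | Path) -> SampleMetadata:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "subject": str})
    missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"metadata missing required columns: {missing}")
    df = df.set_index("sample")
    return SampleMetadata(df[["subject", "group", "timepoint"]])


def read_abundance_table(
    path: str | Path,
    metadata_path: str | Path | None = None,
    transpose: bool = False,
) -> tuple[AbundanceTable, SampleMetadata | None]:
    """Read a count TSV (and optionally join sample metadata).

    Every cell must parse as a nonnegative integer; a fractional or negative
    cell raises a FormatError naming the offending row and column. Samples
    present in the table but absent from the metadata raise an error listing
    the orphan ids.
    """
    raw = _read_tsv(path, transpose=transpose)
    arr = np.empty(raw.shape, dtype=np.int64)
    for j, col in enumerate(raw.columns):
        numeric = pd.to_numeric(raw[col], errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 0)
        if bad.any():
            row = raw.index[bad.values.nonzero()[0][0]]
            raise FormatError(
                f"non-integer or negative count at sample {row!r}, taxon {col!r}: "
                f"{raw.loc[row, col]!r}"
            )
        arr[:, j] = numeric.astype(np.int64)
    table = AbundanceTable(pd.DataFrame(arr, index=raw.index, columns=raw.columns))
    metadata = None
    if metadata_path is not None:
        metadata = read_metadata(metadata_path)
        orphans = sorted(set(table.samples) - set(metadata.samples))
        if orphans:
            raise FormatError(f"samples absent from metadata: {orphans}")
    return table, metadata


def read_feature_table(
    path: str | Path,
    annotation_path: str | Path | None = None,
    transpose: bool = False,
) -> FeatureTable:
    df = _read_tsv(path, transpose=transpose).astype(float)
    annotation = None
    if annotation_path is not None:
        annotation = pd.read_csv(annotation_path, sep="\t", index_col=0)
    return FeatureTable(df, annotation)


def write_table(frame: pd.DataFrame, path: str | Path, index_label: str = "sample") -> None:
    frame.to_csv(path, sep="\t", index_label=index_label)


def write_metadata(metadata: SampleMetadata, path: str | Path) -> None:
    metadata.frame.to_csv(path, sep="\t", index_label="sample")


# ---------------------------------------------------------------------------
# trees


def read_newick(source: str | Path) -> TreeNode:
    """Parse a rooted newick tree; leaf labels must be unique, lengths ≥ 0."""
    if isinstance(source, str) and source.rstrip().endswith(";"):
        handle: object = _io.StringIO(source)
    else:
        handle = str(source)
    try:
        tree = TreeNode.read(handle, format="newick")
    except Exception as exc:  # skbio NewickFormatError
        raise FormatError(f"newick parse error: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        raise FormatError("duplicate leaf labels in tree")
    for node in tree.traverse():
        if node.length is not None and node.length < 0:
            raise FormatError(f"negative branch length at node {node.name!r}")
    return tree


def total_branch_length(tree: TreeNode) -> float:
    return float(sum(n.length or 0.0 for n in tree.traverse()))


# ---------------------------------------------------------------------------
# networks

EDGE_TSV_COLUMNS = [
    "source",
    "target",
    "source_type",
    "target_type",
    "measure",
    "score",
    "sign",
    "p",
    "q",
]


def network_to_graph(nodes: dict[str, str], edges: Iterable) -> nx.Graph:
    """Build a networkx Graph from {node id: type} and edge records.

    Edge records are any objects with .source/.target/.measure/.score/.sign/.p/.q
    attributes (the network module's Edge dataclass).
    """
    g = nx.Graph()
    for node, node_type in nodes.items():
        g.add_node(node, node_type=node_type)
    for e in edges:
        g.add_edge(
            e.source,
            e.target,
            measure=e.measure,
            score=float(e.score),
            sign=int(e.sign),
            p=float(e.p),
            q=float(e.q),
        )
    return g


def write_network(nodes: dict[str, str], edges: list, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a typed network as GraphML or as a flat edge TSV."""
    if format == "graphml":
        nx.write_graphml(network_to_graph(nodes, edges), str(path))
    elif format == "edge_tsv":
        rows = [
            {
                "source": e.source,
                "target": e.target,
                "source_type": nodes[e.source],
                "target_type": nodes[e.target],
                "measure": e.measure,
                "score": e.score,
                "sign": e.sign,
                "p": e.p,
                "q": e.q,
            }
            for e in edges
        ]
        pd.DataFrame(rows, columns=EDGE_TSV_COLUMNS).to_csv(path, sep="\t", index=False)
    else:
        raise FormatError(f"unknown network format: {format!r}")


def read_edge_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"source": str, "target": str})
    missing = [c for c in EDGE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"edge TSV missing columns: {missing}")
    return df


# ---------------------------------------------------------------------------
# JSON config / results


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")
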