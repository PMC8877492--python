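"""Readers and writers for every external representation the pipeline touches.

External table dialect: ZOTU tables are written with rows = ZOTUs and
columns = samples (the common amplicon convention), with an optional final
``taxonomy`` column holding a semicolon-delimited rank path.  Internally the
count matrix is oriented samples x ZOTUs, which is the natural orientation
for the distance/ordination math downstream.

All writers are deterministic: the same in-memory object always produces a
byte-identical file (fixed column order, floats formatted with ``%.6g``).
"""

from __future__ import annotations

import io as _io
import json
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "FormatError",
    "ZotuTable",
    "METADATA_COLUMNS",
    "ENV_VARIABLES",
    "read_zotu_table",
    "write_zotu_table",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "write_graph",
    "read_graph",
    "write_json",
]

FLOAT_FMT = "%.6g"

#: canonical metadata column order; covariates carry the units noted in the
#: metadata docs (depth m, temperature degC, nutrients uM, chlorophyll
#: fractions ug/L, picoplankton abundances cells/mL).
METADATA_COLUMNS = [
    "sample_id",
    "habitat",
    "station",
    "depth",
    "latitude",
    "longitude",
    "temperature",
    "salinity",
    "PO4",
    "NO2NO3",
    "SiO2",
    "NH4",
    "chl_gt20",
    "chl_2_20",
    "chl_lt2",
    "HP_abundance",
    "PPE_abundance",
]

#: environmental covariates usable as community drivers.  NH4 is excluded
#: from the default driver list because it is missing (below detection) in
#: most subsurface-chlorophyll-maximum samples and would knock out pairs.
ENV_VARIABLES = [
    "depth",
    "temperature",
    "salinity",
    "PO4",
    "NO2NO3",
    "SiO2",
    "chl_gt20",
    "chl_2_20",
    "chl_lt2",
    "HP_abundance",
    "PPE_abundance",
]

HABITATS = ("surface", "SCM")


class FormatError(ValueError):
    """Raised when an external file violates the format contract."""


@dataclass
class ZotuTable:
    """Integer count matrix (samples x ZOTUs) with ids and taxonomy.

    Attributes
    ----------
    counts : ndarray of int, shape (n_samples, n_zotus)
    sample_ids : list of unique str
    zotu_ids : list of unique str
    taxonomy : list of str per ZOTU (semicolon rank path, may be empty)
    """

    counts: np.ndarray
    sample_ids: list[str]
    zotu_ids: list[str]
    taxonomy: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D matrix")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise FormatError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise FormatError("counts must be >= 0")
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.zotu_ids = [str(z) for z in self.zotu_ids]
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise FormatError("duplicate sample ids")
        if len(set(self.zotu_ids)) != len(self.zotu_ids):
            raise FormatError("duplicate ZOTU ids")
        if self.counts.shape != (len(self.sample_ids), len(self.zotu_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.zotu_ids)} ZOTUs"
            )
        if not self.taxonomy:
            self.taxonomy = [""] * len(self.zotu_ids)
        if len(self.taxonomy) != len(self.zotu_ids):
            raise FormatError("taxonomy length does not match ZOTU count")

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_zotus(self) -> int:
        return self.counts.shape[1]

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def relative_abundance(self) -> np.ndarray:
        """Counts row-normalised to proportions (samples x ZOTUs)."""
        totals = self.sample_totals().astype(float)
        if (totals == 0).any():
            bad = self.sample_ids[int(np.argmax(totals == 0))]
            raise FormatError(f"sample {bad!r} has zero total count")
        return self.counts / totals[:, None]

    def select_zotus(self, keep: np.ndarray | list[int]) -> "ZotuTable":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return ZotuTable(
            counts=self.counts[:, keep],
            sample_ids=list(self.sample_ids),
            zotu_ids=[self.zotu_ids[i] for i in keep],
            taxonomy=[self.taxonomy[i] for i in keep],
        )

    def select_samples(self, keep: list[str]) -> "ZotuTable":
        idx = [self.sample_ids.index(s) for s in keep]
        return ZotuTable(
            counts=self.counts[idx, :],
            sample_ids=list(keep),
            zotu_ids=list(self.zotu_ids),
            taxonomy=list(self.taxonomy),
        )


# ---------------------------------------------------------------------------
# ZOTU table TSV
# ---------------------------------------------------------------------------

def read_zotu_table(path) -> ZotuTable:
    """Read a ZOTU table TSV (rows = ZOTUs, columns = samples).

    The first column holds ZOTU ids; an optional trailing ``taxonomy``
    column holds rank paths.  Raises :class:`FormatError` on duplicate ids,
    non-integer counts, or an all-zero sample column (named in the message).
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    if df.shape[1] < 2:
        raise FormatError("ZOTU table needs an id column and >= 1 sample")
    id_col = df.columns[0]
    zotu_ids = df[id_col].tolist()
    if len(set(zotu_ids)) != len(zotu_ids):
        dupes = sorted({z for z in zotu_ids if zotu_ids.count(z) > 1})
        raise FormatError(f"duplicated ZOTU id(s): {dupes}")
    has_tax = df.columns[-1].lower() == "taxonomy"
    sample_cols = list(df.columns[1 : -1 if has_tax else None])
    if len(set(sample_cols)) != len(sample_cols):
        raise FormatError("duplicated sample id(s) in header")
    taxonomy = (
        df["taxonomy"].fillna("").tolist() if has_tax else [""] * len(zotu_ids)
    )
    try:
        mat = df[sample_cols].astype(float).to_numpy()
    except ValueError as exc:
        raise FormatError(f"non-numeric count in table: {exc}") from exc
    if not np.allclose(mat, np.round(mat)):
        raise FormatError("non-integer counts in table")
    counts = np.round(mat).astype(np.int64).T  # -> samples x ZOTUs
    totals = counts.sum(axis=1)
    if (totals == 0).any():
        bad = sample_cols[int(np.argmax(totals == 0))]
        raise FormatError(f"sample {bad!r} has no reads (empty column)")
    return ZotuTable(counts, sample_cols, zotu_ids, taxonomy)


def write_zotu_table(table: ZotuTable, path) -> None:
    """Write a ZOTU table TSV (rows = ZOTUs, columns = samples + taxonomy)."""
    with open(path, "w", newline="\n") as fh:
        fh.write("#ZOTU_ID\t" + "\t".join(table.sample_ids) + "\ttaxonomy\n")
        for j, zid in enumerate(table.zotu_ids):
            row = "\t".join(str(int(c)) for c in table.counts[:, j])
            fh.write(f"{zid}\t{row}\t{table.taxonomy[j]}\n")


# ---------------------------------------------------------------------------
# Metadata TSV
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read sample metadata; missing covariates are the literal ``NA``.

    Returns a DataFrame indexed by ``sample_id``.  Unknown habitat labels
    raise :class:`FormatError`; missing values load as NaN, never as zero.
    """
    df = pd.read_csv(path, sep="\t", header=0, dtype=str, keep_default_na=False)
    required = {"sample_id", "habitat"}
    if not required.issubset(df.columns):
        raise FormatError(f"metadata must contain columns {sorted(required)}")
    bad = set(df["habitat"]) - set(HABITATS)
    if bad:
        raise FormatError(
            f"unknown habitat label(s) {sorted(bad)}; expected {list(HABITATS)}"
        )
    if df["sample_id"].duplicated().any():
        raise FormatError("duplicated sample_id in metadata")
    out = df.set_index("sample_id")
    for col in out.columns:
        if col in ("habitat", "station"):
            continue
        out[col] = pd.to_numeric(out[col].replace({"NA": None, "": None}))
    return out


def write_metadata(meta: pd.DataFrame, path) -> None:
    """Write metadata TSV with fixed column order and NA for missing."""
    cols = [c for c in METADATA_COLUMNS if c != "sample_id" and c in meta.columns]
    cols += [c for c in meta.columns if c not in cols]
    with open(path, "w", newline="\n") as fh:
        fh.write("sample_id\t" + "\t".join(cols) + "\n")
        for sid, row in meta[cols].iterrows():
            cells = []
            for c in cols:
                v = row[c]
                if isinstance(v, str):
                    cells.append(v)
                elif v is None or (isinstance(v, float) and math.isnan(v)):
                    cells.append("NA")
                elif isinstance(v, (int, np.integer)):
                    cells.append(str(int(v)))
                else:
                    cells.append(FLOAT_FMT % float(v))
            fh.write(str(sid) + "\t" + "\t".join(cells) + "\n")


# ---------------------------------------------------------------------------
# Trees
# ---------------------------------------------------------------------------

def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree; duplicate leaf names are a format error."""
    tree = TreeNode.read(str(path), format="newick")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise FormatError(f"duplicate leaf name(s) in tree: {dupes}")
    return tree


def write_newick(tree: TreeNode, path) -> None:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    with open(path, "w", newline="\n") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

def write_distance_matrix(dm, path) -> None:
    """Write a labeled square distance matrix as TSV (``%.6g`` floats)."""
    ids = list(dm.ids)
    data = np.asarray(dm.data)
    with open(path, "w", newline="\n") as fh:
        fh.write("\t" + "\t".join(ids) + "\n")
        for i, sid in enumerate(ids):
            fh.write(sid + "\t" + "\t".join(FLOAT_FMT % v for v in data[i]) + "\n")


def read_distance_matrix(path):
    from skbio import DistanceMatrix

    df = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


# ---------------------------------------------------------------------------
# Graphs
# ---------------------------------------------------------------------------

def write_graph(network: nx.Graph, path, fmt: str = "graphml") -> None:
    """Export a co-occurrence network preserving node and edge attributes.

    Supported formats: ``graphml`` and ``gml``.
    """
    fmt = fmt.lower()
    if fmt == "graphml":
        nx.write_graphml(network, path, named_key_ids=True)
    elif fmt == "gml":
        nx.write_gml(network, path)
    else:
        raise FormatError(f"unsupported graph format {fmt!r}")


def read_graph(path, fmt: str = "graphml") -> nx.Graph:
    fmt = fmt.lower()
    if fmt == "graphml":
        return nx.read_graphml(path)
    if fmt == "gml":
        return nx.read_gml(path)
    raise FormatError(f"unsupported graph format {fmt!r}")


def write_json(obj, path) -> None:
    """Write JSON deterministically (sorted keys, fixed float repr)."""

    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", newline="\n") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=default)
        fh.write("\n")
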