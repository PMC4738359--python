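"""Diversity metrics on rarefied OTU tables.

The unit of analysis is an OTU table: a taxa x samples matrix of
non-negative integer counts, typically produced by 97%-identity clustering
of amplicon reads, filtered of singletons and rarefied to an even depth.
From it we compute per-sample Shannon diversity (in bits by default),
observed richness, and Faith's phylogenetic diversity against a supplied
newick tree.
"""

from __future__ import annotations

import io
import json
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)

#: Rarefaction depths used for the two marker genes in the source surveys.
RAREFACTION_PRESETS = {"16S": 25113, "ITS": 23588}

CLASSIC_HEADER = "#OTU ID"


@dataclass
class OtuTable:
    """Taxa x samples count matrix with validated identifiers.

    Parameters
    ----------
    counts : pandas.DataFrame
        Rows are taxa, columns are samples, values non-negative integers.
    """

    counts: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.counts
        if df.index.has_duplicates:
            dups = df.index[df.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate taxon identifiers: {dups}")
        if df.columns.has_duplicates:
            dups = df.columns[df.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        arr = df.to_numpy()
        if arr.size:
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("counts must be numeric")
            if np.any(~np.isfinite(arr)):
                raise ValueError("counts must be finite")
            if np.any(arr < 0):
                bad = df.index[(arr < 0).any(axis=1)].tolist()
                raise ValueError(f"negative counts in rows: {bad}")
            if np.any(arr != np.floor(arr)):
                bad = df.index[(arr != np.floor(arr)).any(axis=1)].tolist()
                raise ValueError(f"non-integer counts in rows: {bad}")
        self.counts = df.astype(np.int64)

    @property
    def taxa(self) -> list:
        return list(self.counts.index)

    @property
    def samples(self) -> list:
        return list(self.counts.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)


def read_otu_table(path, format: str = "classic_tsv") -> OtuTable:
    """Read an OTU table from classic TSV or BIOM-JSON.

    Classic TSV: tab-separated, taxa as rows, samples as columns, first
    header cell ``#OTU ID``.  BIOM: the JSON (v1.0) encoding.
    """
    if format == "classic_tsv":
        with open(path) as fh:
            header = fh.readline().rstrip("\n")
        cells = header.split("\t")
        if not cells or cells[0] != CLASSIC_HEADER:
            raise ValueError(
                f"classic OTU TSV must start with '{CLASSIC_HEADER}', got {cells[0]!r}"
            )
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if df.isna().any().any():
            bad = df.index[df.isna().any(axis=1)].tolist()
            raise ValueError(f"ragged or missing values in rows: {bad}")
        return OtuTable(df)
    if format == "biom":
        with open(path) as fh:
            doc = json.load(fh)
        taxa = [r["id"] for r in doc["rows"]]
        samples = [c["id"] for c in doc["columns"]]
        mat = np.zeros((len(taxa), len(samples)))
        if doc.get("matrix_type") == "sparse":
            for i, j, v in doc["data"]:
                mat[i, j] = v
        else:
            mat[:] = np.asarray(doc["data"])
        return OtuTable(pd.DataFrame(mat, index=taxa, columns=samples))
    raise ValueError(f"unknown format: {format!r}")


def write_otu_table(table: OtuTable, path) -> None:
    """Write classic TSV with the conventional '#OTU ID' leading cell."""
    df = table.counts.copy()
    df.index.name = CLASSIC_HEADER
    df.to_csv(path, sep="\t")


def remove_singletons(table: OtuTable) -> OtuTable:
    """Drop taxa whose total count across all samples equals 1."""
    totals = table.counts.sum(axis=1)
    return OtuTable(table.counts.loc[totals != 1])


def rarefy(table: OtuTable, depth: int, seed: int = 0) -> OtuTable:
    """Subsample each sample to ``depth`` reads without replacement.

    A single rarefaction draw per sample (no repeat-averaging). Samples
    whose total falls below ``depth`` are dropped with a logged warning, so
    every retained column sums to exactly ``depth``.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.sample_totals()
    keep = totals[totals >= depth].index
    dropped = [s for s in table.samples if s not in set(keep)]
    if dropped:
        msg = f"rarefy: dropping {len(dropped)} sample(s) below depth {depth}: {dropped}"
        logger.warning(msg)
        warnings.warn(msg, stacklevel=2)
    out = {}
    for s in keep:
        col = table.counts[s].to_numpy()
        # hypergeometric draw == subsampling reads without replacement
        out[s] = rng.multivariate_hypergeometric(col, depth)
    df = pd.DataFrame(out, index=table.taxa, columns=keep)
    return OtuTable(df)


def shannon(table: OtuTable, base: float = 2.0) -> pd.Series:
    """Shannon diversity H = -sum p_i log_base(p_i), per sample.

    Base 2 (bits) by default; pass ``base=np.e`` for nats.
    """
    totals = table.sample_totals()
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        raise ValueError(f"empty samples: {empty}")
    p = table.counts.to_numpy(dtype=float) / totals.to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, p * np.log(p), 0.0)
    h = -terms.sum(axis=0) / np.log(base)
    return pd.Series(h, index=table.samples, name="shannon")


def richness(table: OtuTable) -> pd.Series:
    """Number of taxa observed (count > 0) per sample."""
    r = (table.counts.to_numpy() > 0).sum(axis=0)
    return pd.Series(r, index=table.samples, name="richness")


def _tree_maps(tree: TreeNode):
    """Per-node parent and branch-length lookups, tips by name."""
    tips = {}
    for tip in tree.tips():
        if tip.name is None:
            raise ValueError("tree contains an unlabelled tip")
        tips[tip.name] = tip
    return tips


def faith_pd(
    table: OtuTable, tree: TreeNode | str, include_root: bool = True
) -> pd.Series:
    """Faith's phylogenetic diversity per sample.

    Total branch length of the minimal subtree connecting a sample's
    observed taxa.  By default the stem path up to the tree root is
    included (classic Faith / QIIME-1 convention); ``include_root=False``
    restricts to the subtree spanning the observed tips only (branch
    lengths below their most recent common ancestor).
    """
    if isinstance(tree, str):
        tree = TreeNode.read(io.StringIO(tree))
    tips = _tree_maps(tree)
    missing = [t for t in table.taxa if t not in tips]
    if missing:
        raise ValueError(f"taxa absent from tree: {missing}")

    arr = table.counts.to_numpy()
    taxa = table.taxa
    node_by_id = {id(n): n for n in tree.traverse(include_self=False)}
    out = {}
    for j, s in enumerate(table.samples):
        observed = [taxa[i] for i in np.nonzero(arr[:, j])[0]]
        if not observed:
            out[s] = 0.0
            continue
        # union of tip-to-root edges
        edges = set()
        for name in observed:
            node = tips[name]
            while node.parent is not None:
                edges.add(id(node))
                node = node.parent
        # deterministic summation order (tree traversal, not set order)
        pd_val = sum(
            (node_by_id[e].length or 0.0)
            for e in node_by_id
            if e in edges
        )
        # a root carrying its own edge length counts toward the stem
        pd_val += tree.length or 0.0
        if not include_root:
            # subtract the shared stem: edges above the observed tips' MCA
            if len(observed) == 1:
                anc = tips[observed[0]]
            else:
                anc = tree.lowest_common_ancestor(observed)
            node = anc
            while node.parent is not None:
                pd_val -= node.length or 0.0
                node = node.parent
            pd_val -= tree.length or 0.0
        out[s] = pd_val
    return pd.Series(out, name="faith_pd").reindex(table.samples)


@dataclass
class DiversityProfile:
    """Per-sample diversity summary at a fixed rarefaction depth."""

    table: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="sample_id")


def diversity_profile(
    table: OtuTable,
    tree: TreeNode | str | None = None,
    rarefaction_depth: int | None = None,
    base: float = 2.0,
) -> DiversityProfile:
    """Compute Shannon (bits), richness and optionally Faith's PD per sample."""
    cols = {
        "shannon_bits": shannon(table, base=base),
        "richness": richness(table),
    }
    if tree is not None:
        cols["faith_pd"] = faith_pd(table, tree)
    df = pd.DataFrame(cols)
    df["rarefaction_depth"] = (
        rarefaction_depth if rarefaction_depth is not None else table.sample_totals()
    )
    return DiversityProfile(df)
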