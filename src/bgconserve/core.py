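"""Trees, trait tables and distances.

The central object is :class:`Phylogeny`, a rooted, branch-length-bearing
tree stored in flat arrays (postorder-indexed) for fast vectorised
traversals.  Parsing, pruning and polytomy handling are delegated to
dendropy; all numerical work happens on the arrays.

Tip indices run ``0 .. n_tips-1`` (order of first postorder encounter);
internal nodes follow in postorder, so iterating internal indices in
ascending order is a postorder sweep and descending order a preorder sweep.
The root is always the last index.
"""

from __future__ import annotations

import io
import logging
import random
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

logger = logging.getLogger("bgconserve")

#: Substitute for zero branch lengths wherever a statistic divides by a
#: branch length (contrast weights).  Distances are never altered.
ZERO_BRANCH_EPS = 1e-8

#: Default vocabulary of biosynthetic gene cluster classes.  Any column
#: set is accepted; this list only orders output when nothing else does.
BGC_CLASSES = [
    "NRPS",
    "RiPPs",
    "Terpene",
    "Aryl_polyene",
    "Beta-lactone",
    "Hserlactone",
    "Siderophore",
    "PKS_NRP_Hybrids",
    "PKS_other",
    "PKSI",
    "Others",
]


class TreeError(ValueError):
    """Raised for malformed or unusable trees."""


# ---------------------------------------------------------------------------
# Phylogeny
# ---------------------------------------------------------------------------


class Phylogeny:
    """Rooted phylogenetic tree over uniquely labelled tips.

    Parameters
    ----------
    parent : array of int
        Parent index per node; the root has parent ``-1``.
    blen : array of float
        Branch length above each node (root entry ignored, stored as 0).
    labels : list of str
        Tip labels; ``labels[i]`` names tip node ``i``.

    Nodes must already be in postorder (children before parents, tips
    first).  Use :func:`read_newick` / :meth:`from_newick` to build one.
    """

    def __init__(self, parent: np.ndarray, blen: np.ndarray, labels: list[str]):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.blen = np.asarray(blen, dtype=float)
        self.labels = list(labels)
        self.n_tips = len(self.labels)
        self.n_nodes = len(self.parent)
        if len(set(self.labels)) != self.n_tips:
            raise TreeError("duplicate tip labels")
        if np.any(~np.isfinite(self.blen)) or np.any(self.blen < 0):
            raise TreeError("branch lengths must be finite and >= 0")
        children: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                if p <= i:
                    raise TreeError("nodes are not in postorder")
                children[p].append(i)
        self.children = [np.asarray(c, dtype=np.int64) for c in children]
        self._depths: np.ndarray | None = None
        self._tip_counts: np.ndarray | None = None

    # -- construction -------------------------------------------------

    @classmethod
    def from_dendropy(
        cls, tree: dendropy.Tree, assume_unit_lengths: bool = False
    ) -> "Phylogeny":
        post = list(tree.postorder_node_iter())
        tips = [nd for nd in post if nd.is_leaf()]
        internals = [nd for nd in post if not nd.is_leaf()]
        order = tips + internals
        index = {id(nd): i for i, nd in enumerate(order)}
        labels = []
        for nd in tips:
            lab = nd.taxon.label if nd.taxon is not None else nd.label
            if lab is None:
                raise TreeError("unlabelled tip")
            labels.append(str(lab))
        n = len(order)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n)
        for nd in order:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                length = nd.edge.length
                if length is None:
                    if assume_unit_lengths:
                        length = 1.0
                    else:
                        raise TreeError(
                            "missing branch length (pass assume_unit_lengths=True "
                            "to substitute 1.0)"
                        )
                blen[i] = float(length)
        return cls(parent, blen, labels)

    @classmethod
    def from_newick(
        cls, newick: str, assume_unit_lengths: bool = False
    ) -> "Phylogeny":
        tree = _parse_newick(io.StringIO(newick))
        return cls.from_dendropy(tree, assume_unit_lengths=assume_unit_lengths)

    def to_dendropy(self) -> dendropy.Tree:
        return _parse_newick(io.StringIO(self.to_newick()))

    def to_newick(self) -> str:
        parts: list[str] = [""] * self.n_nodes
        for i in range(self.n_nodes):
            if i < self.n_tips:
                parts[i] = _quote_label(self.labels[i])
            else:
                inner = ",".join(
                    f"{parts[c]}:{self.blen[c]:.12g}" for c in self.children[i]
                )
                parts[i] = f"({inner})"
        return parts[self.n_nodes - 1] + ";"

    # -- basic properties ---------------------------------------------

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    def is_binary(self) -> bool:
        return all(
            len(self.children[i]) == 2 for i in range(self.n_tips, self.n_nodes)
        )

    def depths(self) -> np.ndarray:
        """Root-to-node path length for every node (root depth 0)."""
        if self._depths is None:
            d = np.zeros(self.n_nodes)
            for i in range(self.n_nodes - 2, -1, -1):  # preorder, skip root
                d[i] = d[self.parent[i]] + self.blen[i]
            self._depths = d
        return self._depths

    def tip_counts(self) -> np.ndarray:
        """Number of descendant tips per node (1 for tips)."""
        if self._tip_counts is None:
            c = np.zeros(self.n_nodes, dtype=np.int64)
            c[: self.n_tips] = 1
            for i in range(self.n_tips, self.n_nodes):
                c[i] = sum(c[j] for j in self.children[i])
            self._tip_counts = c
        return self._tip_counts

    def total_branch_length(self) -> float:
        return float(self.blen.sum() - self.blen[self.root])

    def height(self) -> float:
        return float(self.depths()[: self.n_tips].max())

    def mean_node_tip_distance(self) -> np.ndarray:
        """Per node, the mean path length from the node to its descendant tips."""
        d = self.depths()
        s = np.zeros(self.n_nodes)
        s[: self.n_tips] = d[: self.n_tips]
        for i in range(self.n_tips, self.n_nodes):
            s[i] = sum(s[j] for j in self.children[i])
        return s / self.tip_counts() - d

    def descendant_tips(self, node: int) -> list[int]:
        if node < self.n_tips:
            return [node]
        out: list[int] = []
        stack = [node]
        while stack:
            u = stack.pop()
            if u < self.n_tips:
                out.append(u)
            else:
                stack.extend(self.children[u])
        return sorted(out)

    # -- distances ----------------------------------------------------

    def cophenetic(self) -> DistanceMatrix:
        """Tip-to-tip path-length (cophenetic) distance matrix."""
        shared = self._shared_depth_matrix()
        d = self.depths()[: self.n_tips]
        mat = d[:, None] + d[None, :] - 2.0 * shared
        np.fill_diagonal(mat, 0.0)
        return DistanceMatrix(mat, ids=self.labels)

    def shared_path_matrix(self) -> np.ndarray:
        """C matrix: C[i, j] = root-to-LCA path length; C[i, i] = tip depth.

        This is the Brownian-motion covariance structure of the tree (up to
        the rate), used by Pagel's lambda.
        """
        shared = self._shared_depth_matrix()
        np.fill_diagonal(shared, self.depths()[: self.n_tips])
        return shared

    def _shared_depth_matrix(self) -> np.ndarray:
        n = self.n_tips
        shared = np.zeros((n, n))
        d = self.depths()
        tipsets: dict[int, np.ndarray] = {
            i: np.array([i], dtype=np.int64) for i in range(n)
        }
        for u in range(n, self.n_nodes):
            merged = np.empty(0, dtype=np.int64)
            for k in self.children[u]:
                g = tipsets.pop(k)
                if merged.size:
                    shared[np.ix_(merged, g)] = d[u]
                    shared[np.ix_(g, merged)] = d[u]
                merged = np.concatenate([merged, g])
            tipsets[u] = merged
        return shared

    # -- manipulation -------------------------------------------------

    def resolve_polytomies(self, seed: int = 0) -> "Phylogeny":
        """Return a strictly bifurcating tree.

        Multifurcations are resolved by repeatedly joining two
        randomly-chosen children under a new zero-length edge, so all
        tip-to-tip distances are unchanged.  Binary input is returned
        unchanged (same object).
        """
        if self.is_binary():
            return self
        rng = random.Random(seed)
        tree = self.to_dendropy()
        for nd in list(tree.postorder_node_iter()):
            kids = nd.child_nodes()
            while len(kids) > 2:
                i, j = sorted(rng.sample(range(len(kids)), 2))
                a, b = kids[i], kids[j]
                nd.remove_child(a)
                nd.remove_child(b)
                newnode = dendropy.Node()
                newnode.edge.length = 0.0
                newnode.add_child(a)
                newnode.add_child(b)
                nd.add_child(newnode)
                kids = nd.child_nodes()
        return Phylogeny.from_dendropy(tree)

    def prune_to(self, keep: list[str]) -> "Phylogeny":
        keep_set = set(keep)
        missing = keep_set - set(self.labels)
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)[:5]} ...")
        if keep_set == set(self.labels):
            return self
        tree = self.to_dendropy()
        tree.retain_taxa_with_labels(sorted(keep_set))
        # retain_taxa can leave the root with a single child; suppress it
        tree.suppress_unifurcations()
        return Phylogeny.from_dendropy(tree)

    def tip_index(self, labels) -> np.ndarray:
        pos = {lab: i for i, lab in enumerate(self.labels)}
        return np.array([pos[lab] for lab in labels], dtype=np.int64)

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Phylogeny {self.n_tips} tips, {self.n_nodes} nodes>"


def _quote_label(label: str) -> str:
    if any(ch in label for ch in " ():;,[]'\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _parse_newick(stream) -> dendropy.Tree:
    try:
        return dendropy.Tree.get(
            file=stream,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several parse error types
        raise TreeError(f"newick parse failure: {exc}") from exc


def read_newick(path: str, assume_unit_lengths: bool = False) -> Phylogeny:
    """Read a rooted tree from a newick file.

    Internal node labels and bootstrap annotations are tolerated and
    ignored; quoted labels are supported.  Branch lengths are required
    unless ``assume_unit_lengths`` substitutes 1.0 everywhere.
    """
    with open(path) as fh:
        tree = _parse_newick(fh)
    return Phylogeny.from_dendropy(tree, assume_unit_lengths=assume_unit_lengths)


def write_newick(tree: Phylogeny, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")


def resolve_polytomies(tree: Phylogeny, seed: int = 0) -> Phylogeny:
    """Functional wrapper around :meth:`Phylogeny.resolve_polytomies`."""
    return tree.resolve_polytomies(seed=seed)


def cophenetic_matrix(tree: Phylogeny) -> DistanceMatrix:
    """Functional wrapper around :meth:`Phylogeny.cophenetic`."""
    return tree.cophenetic()


# ---------------------------------------------------------------------------
# TraitTable
# ---------------------------------------------------------------------------


@dataclass
class TraitTable:
    """Genomes x BGC-class count matrix with optional per-genome metadata.

    ``counts`` is indexed by genome ID; columns are class names.  The
    optional ``metadata`` frame shares the index and typically carries a
    ``dataset`` label and taxonomy ranks down to ``genus``.
    """

    counts: pd.DataFrame
    metadata: pd.DataFrame | None = None

    def __post_init__(self):
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate genome IDs")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate class names")
        vals = self.counts.to_numpy()
        if not np.issubdtype(vals.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(vals < 0):
            raise ValueError("negative counts")
        if not np.allclose(vals, np.round(vals)):
            raise ValueError("counts must be integers")
        self.counts = self.counts.astype(np.int64)
        if self.metadata is not None:
            self.metadata = self.metadata.loc[self.counts.index]

    @property
    def genome_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def class_names(self) -> list[str]:
        return list(self.counts.columns)

    def binarize(self) -> "TraitTable":
        """Presence/absence view: entry 1 iff count >= 1.  Idempotent."""
        binary = (self.counts >= 1).astype(np.int64)
        return TraitTable(binary, self.metadata)

    def subset(self, genome_ids: list[str]) -> "TraitTable":
        meta = self.metadata.loc[genome_ids] if self.metadata is not None else None
        return TraitTable(self.counts.loc[genome_ids], meta)

    @classmethod
    def from_tsv(cls, counts_path: str, metadata_path: str | None = None) -> "TraitTable":
        counts = pd.read_csv(counts_path, sep="\t", index_col=0)
        counts.index = counts.index.astype(str)
        meta = None
        if metadata_path is not None:
            meta = pd.read_csv(metadata_path, sep="\t", index_col=0)
            meta.index = meta.index.astype(str)
        return cls(counts, meta)

    def to_tsv(self, counts_path: str, metadata_path: str | None = None) -> None:
        self.counts.to_csv(counts_path, sep="\t")
        if metadata_path is not None and self.metadata is not None:
            self.metadata.to_csv(metadata_path, sep="\t")


def binarize(table: TraitTable) -> TraitTable:
    """Functional wrapper around :meth:`TraitTable.binarize`."""
    return table.binarize()


def align_tree_table(
    tree: Phylogeny, table: TraitTable, policy: str = "intersect"
) -> tuple[Phylogeny, TraitTable]:
    """Reconcile tree tips and table rows onto a common, ordered label set.

    ``strict`` demands identical label sets; ``intersect`` prunes both to
    the shared set (dropped labels are logged).  The returned table rows
    follow the tree's tip order.
    """
    tree_set = set(tree.labels)
    table_set = set(table.genome_ids)
    common = tree_set & table_set
    if not common:
        raise ValueError("tree and table share no labels")
    if policy == "strict":
        if tree_set != table_set:
            raise ValueError(
                f"label sets differ: {len(tree_set - table_set)} only in tree, "
                f"{len(table_set - tree_set)} only in table"
            )
    elif policy == "intersect":
        dropped = (tree_set | table_set) - common
        if dropped:
            logger.info(
                "align_tree_table: dropping %d labels: %s",
                len(dropped),
                sorted(dropped)[:10],
            )
        tree = tree.prune_to(sorted(common))
    else:
        raise ValueError(f"unknown policy {policy!r}")
    table = table.subset(list(tree.labels))
    return tree, table
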