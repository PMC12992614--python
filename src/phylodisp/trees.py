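"""Phylogenetic structures: tree I/O, patristic distances, consensus trees and
the phylogenetic variance-covariance matrix.

The variance-covariance matrix C of a Brownian-motion trait on a rooted tree
has C_ij equal to the shared root-to-MRCA path length of species i and j, and
C_ii equal to the root-to-tip depth.  It is the covariance structure used by
every model-fitting stage of this package.  Consensus trees are built by
neighbor-joining on a (mean) patristic distance matrix with branch lengths
re-fitted by nonnegative least squares, so an additive input matrix is
reproduced exactly.
"""
from __future__ import annotations

import io
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy.optimize import nnls

__all__ = [
    "TreeParseError",
    "PhyloCov",
    "read_trees",
    "patristic_matrix",
    "mean_patristic",
    "consensus_tree",
    "phylo_vcv",
    "lambda_transform",
]


class TreeParseError(ValueError):
    """Raised when a Newick document cannot be parsed."""


@dataclass
class PhyloCov:
    """Species-labeled phylogenetic covariance matrix.

    Attributes
    ----------
    matrix : pandas.DataFrame
        Symmetric positive semi-definite matrix, species labels on both axes.
    correlation : bool
        True if scaled to unit diagonal (correlation form).
    """

    matrix: pd.DataFrame
    correlation: bool = False

    @property
    def species(self) -> list[str]:
        return list(self.matrix.index)

    def values(self) -> np.ndarray:
        return self.matrix.to_numpy()

    def subset(self, species) -> "PhyloCov":
        return PhyloCov(self.matrix.loc[list(species), list(species)], self.correlation)


def _leaf_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def read_trees(source) -> list[dendropy.Tree]:
    """Read one or more trees from a Newick document.

    Parameters
    ----------
    source : str or path-like or file-like
        Newick text, a path to a Newick file, or an open text handle.
        Multiple trees are separated by ``;``.

    Returns
    -------
    list of dendropy.Tree
        All trees share a taxon namespace.  If leaf sets differ across trees
        a warning is issued and every tree is pruned to the common leaf set.

    Raises
    ------
    TreeParseError
        On malformed Newick (the message names the 1-based tree index) or a
        tree with fewer than two leaves.
    """
    if hasattr(source, "read"):
        text = source.read()
    else:
        s = str(source)
        p = Path(s)
        is_path = ("(" not in s) and ("\n" not in s)
        text = p.read_text() if is_path and p.exists() else s
    chunks = [c.strip() for c in text.split(";") if c.strip()]
    if not chunks:
        raise TreeParseError("no trees found in input")
    tns = dendropy.TaxonNamespace()
    trees: list[dendropy.Tree] = []
    for i, chunk in enumerate(chunks, start=1):
        try:
            tree = dendropy.Tree.get(
                data=chunk + ";",
                schema="newick",
                taxon_namespace=tns,
                suppress_internal_node_taxa=True,
            )
        except Exception as exc:  # dendropy raises several error types
            raise TreeParseError(f"malformed Newick in tree {i}: {exc}") from exc
        if len(tree.leaf_nodes()) < 2:
            raise TreeParseError(f"tree {i} has fewer than 2 leaves")
        trees.append(tree)
    leaf_sets = [frozenset(_leaf_labels(t)) for t in trees]
    common = frozenset.intersection(*leaf_sets)
    if any(ls != common for ls in leaf_sets):
        warnings.warn(
            f"trees do not share a leaf set; pruning to the {len(common)} common leaves",
            stacklevel=2,
        )
        if len(common) < 2:
            raise TreeParseError("common leaf set across trees has fewer than 2 leaves")
        for t in trees:
            t.retain_taxa_with_labels(list(common))
    return trees


def _check_branch_lengths(tree: dendropy.Tree) -> None:
    for edge in tree.preorder_edge_iter():
        if edge.tail_node is None:
            continue  # root edge
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.taxon else "<internal>"
            raise ValueError(f"missing branch length on edge above node {name!r}")


def patristic_matrix(tree: dendropy.Tree) -> pd.DataFrame:
    """Pairwise path-length (patristic) distances between all leaves.

    d(i, j) is the sum of branch lengths on the path between leaves i and j;
    the diagonal is zero.  Missing branch lengths raise rather than being
    silently treated as zero.
    """
    _check_branch_lengths(tree)
    labels = sorted(_leaf_labels(tree))
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in pdm.taxon_iter()}
    n = len(labels)
    d = np.zeros((n, n))
    for a in range(n):
        for b in range(a + 1, n):
            d[a, b] = d[b, a] = pdm.patristic_distance(taxa[labels[a]], taxa[labels[b]])
    return pd.DataFrame(d, index=labels, columns=labels)


def mean_patristic(trees: list[dendropy.Tree]) -> pd.DataFrame:
    """Element-wise arithmetic mean of the per-tree patristic matrices.

    All trees must share a leaf set; if not, the intersection is used and a
    warning issued.  An intersection below 3 leaves is an error.
    """
    if not trees:
        raise ValueError("need at least one tree")
    mats = [patristic_matrix(t) for t in trees]
    common = sorted(set.intersection(*(set(m.index) for m in mats)))
    if any(len(m) != len(common) for m in mats):
        warnings.warn("trees do not share a leaf set; averaging over the intersection",
                      stacklevel=2)
        if len(common) < 3:
            raise ValueError("common leaf set has fewer than 3 species")
    stacked = np.stack([m.loc[common, common].to_numpy() for m in mats])
    return pd.DataFrame(stacked.mean(axis=0), index=common, columns=common)


def _validate_distance_matrix(dist: pd.DataFrame) -> np.ndarray:
    d = dist.to_numpy(dtype=float)
    if d.shape[0] != d.shape[1] or list(dist.index) != list(dist.columns):
        raise ValueError("distance matrix must be square with matching labels")
    if not np.allclose(d, d.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    if (d < -1e-12).any():
        raise ValueError("distance matrix must be nonnegative")
    if not np.allclose(np.diag(d), 0.0, atol=1e-10):
        raise ValueError("distance matrix must have a zero diagonal")
    return d


def consensus_tree(dist: pd.DataFrame) -> dendropy.Tree:
    """Least-squares consensus tree from a (mean) patristic distance matrix.

    Topology is estimated by neighbor-joining on ``dist``; branch lengths are
    then re-fitted by nonnegative least squares so that the returned tree's
    patristic distances minimize the sum of squared deviations from ``dist``
    given that topology.  Additive matrices are reproduced exactly.
    """
    d = _validate_distance_matrix(dist)
    labels = list(dist.index)
    n = len(labels)
    if n < 3:
        raise ValueError("need at least 3 species for a consensus tree")
    buf = io.StringIO()
    buf.write("," + ",".join(labels) + "\n")
    for i, lab in enumerate(labels):
        buf.write(lab + "," + ",".join(f"{v:.17g}" for v in d[i]) + "\n")
    buf.seek(0)
    pdm = dendropy.PhylogeneticDistanceMatrix.from_csv(src=buf, delimiter=",")
    tree = pdm.nj_tree()

    # NNLS branch lengths: one indicator column per edge, one row per leaf pair.
    idx = {lab: k for k, lab in enumerate(labels)}
    edges = [e for e in tree.preorder_edge_iter() if e.tail_node is not None]
    masks = []
    for e in edges:
        mask = np.zeros(n, dtype=bool)
        for leaf in e.head_node.leaf_iter():
            mask[idx[leaf.taxon.label]] = True
        masks.append(mask)
    ii, jj = np.triu_indices(n, k=1)
    A = np.stack([m[ii] ^ m[jj] for m in masks], axis=1).astype(float)
    b = d[ii, jj]
    lengths, _ = nnls(A, b)
    for e, ln in zip(edges, lengths):
        e.length = float(ln)
    if tree.seed_node.edge is not None:
        tree.seed_node.edge.length = None
    return tree


def phylo_vcv(tree: dendropy.Tree, correlation: bool = False) -> PhyloCov:
    """Phylogenetic variance-covariance matrix of a rooted tree.

    C_ij is the root-to-MRCA depth shared by leaves i and j; C_ii is the
    root-to-leaf depth.  With ``correlation=True`` the matrix is rescaled to
    unit diagonal, C_ij / sqrt(C_ii C_jj).
    """
    nchild = len(tree.seed_node.child_nodes())
    if len(tree.leaf_nodes()) > 2 and nchild != 2:
        raise ValueError(
            "tree appears unrooted (root has %d children); root it first, e.g. "
            "by midpoint or outgroup rooting" % nchild
        )
    dist = patristic_matrix(tree)
    labels = list(dist.index)
    depth = {}
    for leaf in tree.leaf_node_iter():
        total, node = 0.0, leaf
        while node.parent_node is not None:
            total += node.edge.length
            node = node.parent_node
        depth[leaf.taxon.label] = total
    dv = np.array([depth[s] for s in labels])
    C = (dv[:, None] + dv[None, :] - dist.to_numpy()) / 2.0
    C[np.abs(C) < 1e-12] = 0.0
    if correlation:
        dgn = np.sqrt(np.diag(C))
        if (dgn <= 0).any():
            raise ValueError("zero root-to-tip depth; cannot scale to correlation")
        C = C / np.outer(dgn, dgn)
        np.fill_diagonal(C, 1.0)
    return PhyloCov(pd.DataFrame(C, index=labels, columns=labels), correlation=correlation)


def lambda_transform(cov: PhyloCov, lam: float) -> PhyloCov:
    """Pagel-style signal transform: off-diagonal entries scaled by ``lam``.

    ``lam`` must lie in [0, 1]; the diagonal is untouched, so positive
    semi-definiteness is preserved (the result is a convex combination of the
    original matrix and its diagonal).
    """
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"lambda must be in [0, 1], got {lam}")
    C = cov.matrix.to_numpy().copy()
    dgn = np.diag(C).copy()
    C *= lam
    np.fill_diagonal(C, dgn)
    return PhyloCov(pd.DataFrame(C, index=cov.matrix.index, columns=cov.matrix.columns),
                    cov.correlation)


def save_matrix(m: pd.DataFrame, path) -> None:
    m.to_csv(path, sep="\t", float_format="%.12g")


def load_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
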