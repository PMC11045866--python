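"""Between-sample dissimilarities: Bray-Curtis and weighted UniFrac.

Both metrics quantify how far a participant's gut community moved between
two samples (e.g. before and after a dietary intervention) and feed the
microbiota-shift stage of donor ranking.

Weighted UniFrac is computed in a single post-order traversal of a rooted
phylogeny: for every branch i with length b_i, let p_i be the proportion of
a sample's total abundance carried by taxa descending through that branch;
the distance is

    sum_i b_i |p_i^x - p_i^y|  /  sum_i b_i (p_i^x + p_i^y)

(the proportion-weighted, normalized form; the raw numerator is available
behind ``normalized=False``).  The normalized form lies in [0, 1] and is
invariant to rescaling either sample's total count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "DistanceResult",
    "read_tree",
    "bray_curtis",
    "weighted_unifrac",
    "paired_shift",
    "shift_table",
    "write_distance_matrix",
]


@dataclass(frozen=True)
class DistanceResult:
    pair: tuple[str, str]
    value: float
    metric: str


def read_tree(source) -> TreeNode:
    """Read a rooted Newick tree with branch lengths.

    A root with other than two children is taken to be an unrooted tree and
    rejected (midpoint-root it externally first).  Missing branch lengths on
    non-root nodes are an error; internal multifurcations are accepted.
    """
    tree = TreeNode.read(source) if not isinstance(source, TreeNode) else source
    children = tree.children
    if len(children) != 2:
        raise ValueError(
            "tree root must be bifurcating (2 children); unrooted input is "
            "not accepted - midpoint-root the tree externally first"
        )
    for node in tree.traverse(include_self=False):
        if node.length is None:
            raise ValueError(f"node {node.name!r} lacks a branch length")
        if node.length < 0:
            raise ValueError(f"node {node.name!r} has negative branch length")
    names = [t.name for t in tree.tips()]
    if len(set(names)) != len(names):
        raise ValueError("duplicate leaf labels in tree")
    return tree


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y), in [0, 1]."""
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if np.any(xa < 0) or np.any(ya < 0):
        raise ValueError("abundances must be nonnegative")
    denom = float((xa + ya).sum())
    if denom == 0:
        raise ValueError("both vectors are all-zero")
    return float(np.abs(xa - ya).sum() / denom)


def _tip_index(tree: TreeNode, taxa) -> dict[str, int]:
    tip_names = {t.name for t in tree.tips()}
    taxa = list(taxa)
    extra = [t for t in taxa if t not in tip_names]
    if extra:
        raise ValueError(f"taxa absent from tree leaves: {extra}")
    return {t: i for i, t in enumerate(taxa)}


def weighted_unifrac(x, y, tree: TreeNode, taxa=None, normalized: bool = True) -> float:
    """Weighted UniFrac between two abundance vectors on a shared tree.

    Parameters
    ----------
    x, y : array-like
        Abundances indexed by ``taxa`` (or by tree tip order if omitted).
    tree : skbio.TreeNode
        Rooted tree with branch lengths; leaves must cover all taxa.
    taxa : sequence of str, optional
        Labels aligning vector positions to tree leaves.
    normalized : bool
        Divide by sum_i b_i (p_i^x + p_i^y) so the result lies in [0, 1];
        if False, return the raw branch-weighted proportion difference.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    if np.any(xa < 0) or np.any(ya < 0):
        raise ValueError("abundances must be nonnegative")
    tips = list(tree.tips())
    if taxa is None:
        taxa = [t.name for t in tips]
    if len(taxa) != len(xa):
        raise ValueError("taxa labels must match vector length")
    idx = _tip_index(tree, taxa)
    tx, ty = xa.sum(), ya.sum()
    if tx == 0 or ty == 0:
        raise ValueError("zero-total sample")
    px_leaf = xa / tx
    py_leaf = ya / ty

    num = 0.0
    den = 0.0
    # single post-order pass accumulating descendant proportions per branch
    masses: dict[int, tuple[float, float]] = {}
    for node in tree.postorder(include_self=True):
        if node.is_tip():
            if node.name in idx:
                mx, my = px_leaf[idx[node.name]], py_leaf[idx[node.name]]
            else:
                mx = my = 0.0  # tree leaf not in the table carries no mass
        else:
            child_masses = [masses.pop(id(c)) for c in node.children]
            mx = sum(m[0] for m in child_masses)
            my = sum(m[1] for m in child_masses)
        masses[id(node)] = (mx, my)
        if node.parent is not None and node.length:
            num += node.length * abs(mx - my)
            den += node.length * (mx + my)
    if not normalized:
        return float(num)
    if den == 0:
        return 0.0
    return float(num / den)


def paired_shift(pre, post, tree: TreeNode, taxa=None) -> tuple[float, float]:
    """Bray-Curtis and weighted UniFrac between a participant's paired
    pre- and post-intervention samples."""
    bc = bray_curtis(pre, post)
    wu = weighted_unifrac(pre, post, tree, taxa=taxa)
    return bc, wu


def shift_table(table, tree: TreeNode, pairs) -> pd.DataFrame:
    """Per-participant paired shifts from an abundance table.

    Parameters
    ----------
    table : AbundanceTable or DataFrame (samples x taxa)
    tree : rooted phylogeny covering the taxa
    pairs : mapping participant -> (pre_sample_id, post_sample_id)

    Returns a DataFrame indexed by participant with columns
    ``bc_shift`` and ``wu_shift``.
    """
    frame = getattr(table, "counts", None)
    frame = frame if frame is not None else pd.DataFrame(table)
    taxa = list(frame.columns)
    rows = {}
    for participant, (pre_id, post_id) in pairs.items():
        for sid in (pre_id, post_id):
            if sid not in frame.index:
                raise ValueError(
                    f"participant {participant!r}: sample {sid!r} missing"
                )
        bc, wu = paired_shift(
            frame.loc[pre_id].to_numpy(), frame.loc[post_id].to_numpy(),
            tree, taxa=taxa,
        )
        rows[participant] = {"bc_shift": bc, "wu_shift": wu}
    return pd.DataFrame.from_dict(rows, orient="index")


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    """Write a square pairwise distance matrix as TSV with ids on both axes."""
    dm.to_csv(path, sep="\t")
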