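"""Phylogeny input and cophenetic (tip-to-tip) distances.

Trees are handled with scikit-bio ``TreeNode`` objects read from Newick.
The only quantity the assembly analyses need from the tree is the
cophenetic distance matrix: the sum of branch lengths along the path
between every pair of tips.
"""

from __future__ import annotations

import io

import pandas as pd
from skbio import TreeNode

__all__ = ["read_newick", "parse_newick", "cophenetic_matrix", "write_newick"]


def parse_newick(newick: str) -> TreeNode:
    """Parse a Newick string into a tree, validating tip labels."""
    tree = TreeNode.read(io.StringIO(newick), format="newick")
    tips = [t.name for t in tree.tips()]
    if any(name is None for name in tips):
        raise ValueError("tree has unlabeled tips")
    if len(set(tips)) != len(tips):
        raise ValueError("duplicate tip labels")
    return tree


def read_newick(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths from a file."""
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def cophenetic_matrix(tree: TreeNode) -> pd.DataFrame:
    """Tip-to-tip path-length distances as a labeled symmetric DataFrame."""
    dm = tree.tip_tip_distances()
    return pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids))
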