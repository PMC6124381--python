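"""Sequential binary partitions and their orthonormal contrast matrices.

An SBP splits the D parts of a composition into a hierarchy of D-1 binary
contrasts: the first split divides all parts into a "+" group and a "-"
group, and each subsequent split subdivides one of the groups already
formed. Encoded as a D x (D-1) sign matrix (entries -1/0/+1), the SBP is
equivalent to a rooted strictly binary tree whose leaves are the parts.
Each column j defines one ilr balance through the orthonormal contrast row

    +(1/r) * sqrt(r*s/(r+s))  on the r parts signed +1,
    -(1/s) * sqrt(r*s/(r+s))  on the s parts signed -1,

so that applying the contrast matrix to log-transformed data yields the
balance scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import TreeNode

from .core import BalanceLookupError, StructuralError

__all__ = [
    "SbpMatrix",
    "ContrastMatrix",
    "MergeTree",
    "validate_sbp",
    "sbp_to_contrast",
    "tree_to_sbp",
    "sbp_to_tree",
    "order_balances",
    "read_newick",
    "write_newick",
]


# ---------------------------------------------------------------------------
# Types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SbpMatrix:
    """Validated SBP sign matrix: components as rows, balances as columns.

    Construct through :func:`validate_sbp`; the dataclass itself performs
    no checking so that internal code can rebuild trusted instances.
    """

    signs: pd.DataFrame

    @property
    def component_ids(self) -> list:
        return list(self.signs.index)

    @property
    def balance_ids(self) -> list:
        return list(self.signs.columns)

    @property
    def n_components(self) -> int:
        return self.signs.shape[0]

    def plus_set(self, balance_id) -> frozenset:
        col = self.signs[balance_id]
        return frozenset(col.index[col == 1])

    def minus_set(self, balance_id) -> frozenset:
        col = self.signs[balance_id]
        return frozenset(col.index[col == -1])

    def support(self, balance_id) -> frozenset:
        col = self.signs[balance_id]
        return frozenset(col.index[col != 0])


@dataclass(frozen=True)
class ContrastMatrix:
    """Orthonormal ilr basis: balances as rows, components as columns.

    ``r`` and ``s`` give, per balance, the number of parts on the "+" and
    "-" side of the contrast.
    """

    weights: pd.DataFrame
    r: pd.Series
    s: pd.Series

    @property
    def balance_ids(self) -> list:
        return list(self.weights.index)

    @property
    def component_ids(self) -> list:
        return list(self.weights.columns)

    @property
    def values(self) -> np.ndarray:
        return self.weights.to_numpy(dtype=float)


@dataclass(frozen=True)
class MergeTree:
    """Rooted strictly binary tree over components (wraps skbio TreeNode)."""

    root: TreeNode

    def __post_init__(self):
        names = []
        for node in self.root.traverse():
            if node.is_tip():
                names.append(node.name)
            elif len(node.children) != 2:
                raise StructuralError(
                    f"tree node {node.name!r} has {len(node.children)} "
                    "children; a merge tree must be strictly binary"
                )
        if len(set(names)) != len(names):
            raise StructuralError("duplicate leaf labels in merge tree")
        if None in names or len(names) < 2:
            raise StructuralError("merge tree needs >= 2 uniquely labeled leaves")

    @property
    def leaf_ids(self) -> list:
        return [tip.name for tip in self.root.tips()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaf_ids)

    def bipartitions(self) -> set:
        """Unordered {first-child leafset, second-child leafset} pairs."""
        out = set()
        for node in self.root.non_tips(include_self=True):
            left, right = node.children
            out.add(frozenset({
                frozenset(t.name for t in left.tips(include_self=True)),
                frozenset(t.name for t in right.tips(include_self=True)),
            }))
        return out


def read_newick(source) -> MergeTree:
    """Parse a Newick string or file into a MergeTree.

    Child order in the Newick string defines first/second child.
    """
    if isinstance(source, str) and "(" in source:
        handle = io.StringIO(source)
    else:
        handle = str(source)
    tree = TreeNode.read(handle, format="newick")
    return MergeTree(tree)


def write_newick(tree: MergeTree, path=None) -> str:
    buf = io.StringIO()
    tree.root.write(buf, format="newick")
    text = buf.getvalue()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_sbp(signs: pd.DataFrame) -> SbpMatrix:
    """Validate a labeled sign matrix as a sequential binary partition.

    The check is order-agnostic: columns may appear in any order. Structural
    requirements: D-1 columns for D component rows; entries in {-1, 0, +1};
    every column has at least one +1 and one -1; and the supports form the
    nested (laminar) hierarchy of a binary merge tree — exactly one column
    spans all components, every other column's support coincides with the
    "+" or "-" group of another column, and every group of two or more
    parts is subdivided by exactly one column.
    """
    if not isinstance(signs, pd.DataFrame):
        signs = pd.DataFrame(signs)
    values = signs.to_numpy()
    if not np.isin(values, (-1, 0, 1)).all():
        bad = sorted(set(values.ravel()) - {-1, 0, 1})
        raise StructuralError(f"SBP entries must be -1/0/+1; found {bad}")
    signs = signs.astype(int)
    D, m = signs.shape
    if m != D - 1:
        raise StructuralError(
            f"SBP for {D} components must have {D - 1} columns, got {m}"
        )
    if pd.Index(signs.index).has_duplicates or pd.Index(signs.columns).has_duplicates:
        raise StructuralError("duplicate component or balance labels in SBP")

    comps = frozenset(signs.index)
    supports = {}
    plus, minus = {}, {}
    for col in signs.columns:
        c = signs[col]
        p = frozenset(c.index[c == 1])
        n = frozenset(c.index[c == -1])
        if not p or not n:
            raise StructuralError(
                f"SBP column {col!r} must contain at least one +1 and one -1"
            )
        supp = p | n
        if supp in supports:
            raise StructuralError(
                f"SBP columns {supports[supp]!r} and {col!r} split the same group"
            )
        supports[supp] = col
        plus[col], minus[col] = p, n

    if comps not in supports:
        raise StructuralError("SBP has no root column spanning all components")
    # every non-root support must be the +set or -set of some column, and
    # every multi-part +/- set must itself be split by exactly one column
    halves = set()
    for col in signs.columns:
        for side in (plus[col], minus[col]):
            if len(side) >= 2:
                halves.add(side)
                if side not in supports:
                    raise StructuralError(
                        f"group {sorted(side)} created by column {col!r} "
                        "is never subdivided; SBP is not hierarchical"
                    )
    for supp, col in supports.items():
        if supp != comps and supp not in halves:
            raise StructuralError(
                f"column {col!r} splits group {sorted(supp)} which is not a "
                "+/- group of any other column; SBP is not hierarchical"
            )
    return SbpMatrix(signs)


# ---------------------------------------------------------------------------
# Contrast matrix
# ---------------------------------------------------------------------------

def sbp_to_contrast(sbp: SbpMatrix) -> ContrastMatrix:
    """Derive the orthonormal (D-1) x D contrast matrix from an SBP.

    Row j carries +(1/r)*sqrt(rs/(r+s)) on the r positively signed parts
    and -(1/s)*sqrt(rs/(r+s)) on the s negatively signed parts; rows sum
    to zero and are mutually orthonormal, so the balance of a sample x is
    the dot product of the row with ln(x).
    """
    signs = sbp.signs.to_numpy(dtype=float)  # D x (D-1)
    r = (signs == 1).sum(axis=0).astype(float)
    s = (signs == -1).sum(axis=0).astype(float)
    coef = np.sqrt(r * s / (r + s))
    weights = np.where(signs == 1, coef / r, np.where(signs == -1, -coef / s, 0.0))
    wdf = pd.DataFrame(weights.T, index=sbp.signs.columns, columns=sbp.signs.index)
    return ContrastMatrix(
        weights=wdf,
        r=pd.Series(r.astype(int), index=sbp.signs.columns, name="r"),
        s=pd.Series(s.astype(int), index=sbp.signs.columns, name="s"),
    )


# ---------------------------------------------------------------------------
# Tree <-> SBP
# ---------------------------------------------------------------------------

def tree_to_sbp(tree: MergeTree, flip: bool = False,
                balance_prefix: str = "z") -> SbpMatrix:
    """Convert a merge tree to an SBP, one column per internal node.

    Leaves under the first child get +1, leaves under the second child -1
    (reversed when ``flip`` is set — the sign orientation is a convention:
    it changes the sign of the balance scores, never their magnitude).
    Columns are emitted in preorder, root first, and named
    ``z1..z{D-1}`` by default.
    """
    leaf_ids = tree.leaf_ids
    internal = [n for n in tree.root.preorder() if not n.is_tip()]
    cols = {}
    names = []
    for k, node in enumerate(internal, start=1):
        first, second = node.children
        col = pd.Series(0, index=pd.Index(leaf_ids), dtype=int)
        col[[t.name for t in first.tips(include_self=True)]] = 1
        col[[t.name for t in second.tips(include_self=True)]] = -1
        if flip:
            col = -col
        name = f"{balance_prefix}{k}"
        cols[name] = col
        names.append(name)
    return validate_sbp(pd.DataFrame(cols, columns=names))


def sbp_to_tree(sbp: SbpMatrix) -> MergeTree:
    """Invert an SBP into its merge tree; the "+" group becomes first child."""
    by_support = {sbp.support(b): b for b in sbp.balance_ids}

    def build(group: frozenset) -> TreeNode:
        if len(group) == 1:
            (leaf,) = group
            return TreeNode(name=leaf)
        col = by_support[group]
        return TreeNode(children=[build(sbp.plus_set(col)),
                                  build(sbp.minus_set(col))])

    return MergeTree(build(frozenset(sbp.component_ids)))


# ---------------------------------------------------------------------------
# Display ordering
# ---------------------------------------------------------------------------

def balance_depths(sbp: SbpMatrix) -> pd.Series:
    """Depth of each balance in the SBP hierarchy (root split = 0).

    The depth of a balance is the number of other columns whose support
    strictly contains its own — i.e. its distance from the root of the
    merge tree.
    """
    supports = {b: sbp.support(b) for b in sbp.balance_ids}
    depths = {}
    for b, supp in supports.items():
        depths[b] = sum(1 for other in supports.values() if supp < other)
    return pd.Series(depths, name="depth")


def order_balances(sbp: SbpMatrix, selected, variances) -> list:
    """Order balances for display: base of the tree at the top.

    Selected balances are sorted by ascending depth of their support in the
    SBP hierarchy; ties are broken by descending variance, then by original
    column order. Deterministic and stable.
    """
    all_ids = sbp.balance_ids
    selected = list(selected)
    unknown = [b for b in selected if b not in all_ids]
    if unknown:
        raise BalanceLookupError(f"unknown balance ids: {unknown}")
    variances = pd.Series(variances)
    missing = [b for b in selected if b not in variances.index]
    if missing:
        raise BalanceLookupError(f"no variance available for: {missing}")
    depths = balance_depths(sbp)
    position = {b: i for i, b in enumerate(all_ids)}
    return sorted(selected,
                  key=lambda b: (depths[b], -float(variances[b]), position[b]))
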