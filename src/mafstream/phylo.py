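"""Block-wise distance-based phylogenetics.

Distance estimation (Kimura 2-parameter and observed), agglomerative tree
building (NJ, BioNJ, UPGMA, WPGMA) with deterministic tie-breaking,
rerooting on an outgroup, leaf pruning, and triplet-topology tallies.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .model import MafBlock, MafError

_UNAMBIGUOUS = frozenset("ACGT")
_TRANSITIONS = frozenset({("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")})


# ---------------------------------------------------------------------------
# tree structure


@dataclass
class TreeNode:
    """Node of a (possibly multifurcating) phylogeny.

    ``length`` is the branch length to the parent (None at the root).
    """

    label: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return [leaf for c in self.children for leaf in c.leaves()]

    def leaf_names(self) -> list[str]:
        return [leaf.label for leaf in self.leaves()]

    def copy(self) -> "TreeNode":
        return TreeNode(self.label, self.length, [c.copy() for c in self.children])

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({to_newick(self)!r})"


def to_newick(node: TreeNode, _top: bool = True) -> str:
    if node.is_leaf:
        s = node.label or ""
    else:
        s = "(" + ",".join(to_newick(c, False) for c in node.children) + ")"
        if node.label:
            s += node.label
    if node.length is not None:
        s += f":{node.length:g}"
    return s + ";" if _top else s


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string (plain labels, optional branch lengths)."""
    text = text.strip()
    if text.endswith(";"):
        text = text[:-1]
    pos = 0

    def parse_node() -> TreeNode:
        nonlocal pos
        node = TreeNode()
        if pos < len(text) and text[pos] == "(":
            pos += 1
            while True:
                node.children.append(parse_node())
                if pos >= len(text):
                    raise MafError("unbalanced parentheses in Newick string")
                if text[pos] == ",":
                    pos += 1
                    continue
                if text[pos] == ")":
                    pos += 1
                    break
                raise MafError(f"unexpected character {text[pos]!r} in Newick string")
        start = pos
        while pos < len(text) and text[pos] not in ",():;":
            pos += 1
        label = text[start:pos].strip()
        if label:
            node.label = label
        if pos < len(text) and text[pos] == ":":
            pos += 1
            start = pos
            while pos < len(text) and text[pos] not in ",();":
                pos += 1
            node.length = float(text[start:pos])
        return node

    root = parse_node()
    if pos != len(text):
        raise MafError(f"trailing characters in Newick string: {text[pos:]!r}")
    return root


def leaf_path_lengths(tree: TreeNode) -> dict[frozenset, float]:
    """Sum of branch lengths between every pair of leaves."""
    dists: dict[frozenset, float] = {}

    def walk(node: TreeNode) -> list[tuple[str, float]]:
        if node.is_leaf:
            return [(node.label, 0.0)]
        below: list[list[tuple[str, float]]] = []
        for child in node.children:
            w = child.length or 0.0
            below.append([(name, d + w) for name, d in walk(child)])
        for group_a, group_b in itertools.combinations(below, 2):
            for name_a, da in group_a:
                for name_b, db in group_b:
                    dists[frozenset((name_a, name_b))] = da + db
        return [pair for group in below for pair in group]

    walk(tree)
    return dists


# ---------------------------------------------------------------------------
# distances


def kimura_distance(text1: str, text2: str) -> float | None:
    """Kimura 2-parameter distance between two gapped texts.

    Over columns where both rows hold unambiguous residues, computes the
    transition proportion P (A<->G, C<->T) and transversion proportion Q,
    then d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q).  Returns None when no
    column is comparable or either log argument is <= 0 (saturation).
    """
    if len(text1) != len(text2):
        raise MafError(
            f"sequence length mismatch: {len(text1)} != {len(text2)}"
        )
    sites = transitions = transversions = 0
    for a, b in zip(text1.upper(), text2.upper()):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        sites += 1
        if a != b:
            if (a, b) in _TRANSITIONS:
                transitions += 1
            else:
                transversions += 1
    if sites == 0:
        return None
    p = transitions / sites
    q = transversions / sites
    w1 = 1.0 - 2.0 * p - q
    w2 = 1.0 - 2.0 * q
    if w1 <= 0.0 or w2 <= 0.0:
        return None
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


def observed_distance(text1: str, text2: str) -> float | None:
    """Raw mismatch proportion over comparable columns (None if none)."""
    if len(text1) != len(text2):
        raise MafError(
            f"sequence length mismatch: {len(text1)} != {len(text2)}"
        )
    sites = mismatches = 0
    for a, b in zip(text1.upper(), text2.upper()):
        if a not in _UNAMBIGUOUS or b not in _UNAMBIGUOUS:
            continue
        sites += 1
        if a != b:
            mismatches += 1
    return mismatches / sites if sites else None


@dataclass
class DistanceMatrix:
    """Symmetric labelled matrix of pairwise distances (NaN marks NA)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise MafError(
                f"distance matrix shape {self.values.shape} does not match "
                f"{n} labels"
            )

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.labels.index(a), self.labels.index(b)])

    def has_na(self) -> bool:
        return bool(np.isnan(self.values).any())


DISTANCE_METHODS = {"kimura": kimura_distance, "observed": observed_distance}


def distance_matrix(block: MafBlock, method: str = "kimura") -> DistanceMatrix:
    """All-pairs distances between the rows of *block*."""
    if method not in DISTANCE_METHODS:
        raise ValueError(f"unknown distance method {method!r}")
    fn = DISTANCE_METHODS[method]
    labels = block.species
    if len(labels) != len(set(labels)):
        raise MafError("duplicate species in block: distance matrix undefined")
    if len(labels) < 2:
        raise MafError("distance matrix requires at least 2 rows")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            v = fn(block.sequences[i].text, block.sequences[j].text)
            d[i, j] = d[j, i] = math.nan if v is None else v
    return DistanceMatrix(labels, d)


# ---------------------------------------------------------------------------
# tree building

TREE_METHODS = ("nj", "bionj", "upgma", "wpgma")


def build_tree(matrix: DistanceMatrix, method: str = "bionj") -> TreeNode:
    """Agglomerate *matrix* into a phylogeny.

    NJ/BioNJ produce an unrooted tree (trifurcating root); UPGMA/WPGMA
    produce rooted ultrametric trees.  Negative branch lengths are clamped
    to 0.  Tie-breaking is deterministic: the first minimal pair in row
    order wins.  NA entries abort with an error instructing upstream
    filtering.
    """
    method = method.lower()
    if method not in TREE_METHODS:
        raise ValueError(f"unknown tree method {method!r}")
    if matrix.has_na():
        raise MafError(
            "distance matrix contains NA (saturated) entries; filter blocks "
            "upstream before tree building"
        )
    n = len(matrix.labels)
    if n < 2:
        raise MafError("tree building requires at least 2 taxa")
    if method in ("nj", "bionj"):
        return _neighbor_joining(matrix, variance_weighted=(method == "bionj"))
    return _pgma(matrix, weighted=(method == "wpgma"))


def _neighbor_joining(matrix: DistanceMatrix, variance_weighted: bool) -> TreeNode:
    nodes = [TreeNode(label) for label in matrix.labels]
    d = matrix.values.astype(float).copy()
    v = d.copy()  # variance estimates (BioNJ); unused for plain NJ
    active = list(range(len(nodes)))

    if len(active) == 2:
        half = max(d[active[0], active[1]], 0.0) / 2.0
        for i in active:
            nodes[i].length = half
        return TreeNode(children=[nodes[i] for i in active])

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        best_q = math.inf
        for a_idx in range(m):
            for b_idx in range(a_idx + 1, m):
                i, j = active[a_idx], active[b_idx]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if q < best_q - 1e-12:
                    best_q = q
                    best = (i, j)
        i, j = best
        li = d[i, j] / 2.0 + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        nodes[i].length = li
        nodes[j].length = lj
        parent = TreeNode(children=[nodes[i], nodes[j]])

        if variance_weighted and v[i, j] > 0:
            s = sum(v[j, k] - v[i, k] for k in active if k not in (i, j))
            lam = 0.5 + s / (2.0 * (m - 2) * v[i, j])
            lam = min(max(lam, 0.0), 1.0)
        else:
            lam = 0.5

        # reuse slot i for the new node, deactivate j
        new_d = {}
        new_v = {}
        for k in active:
            if k in (i, j):
                continue
            if variance_weighted:
                new_d[k] = lam * (d[i, k] - li) + (1.0 - lam) * (d[j, k] - lj)
                new_v[k] = lam * v[i, k] + (1.0 - lam) * v[j, k] - lam * (1.0 - lam) * v[i, j]
            else:
                new_d[k] = (d[i, k] + d[j, k] - d[i, j]) / 2.0
        for k, val in new_d.items():
            d[i, k] = d[k, i] = val
        if variance_weighted:
            for k, val in new_v.items():
                v[i, k] = v[k, i] = val
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    la = max((d[a, b] + d[a, c] - d[b, c]) / 2.0, 0.0)
    lb = max((d[a, b] + d[b, c] - d[a, c]) / 2.0, 0.0)
    lc = max((d[a, c] + d[b, c] - d[a, b]) / 2.0, 0.0)
    nodes[a].length = la
    nodes[b].length = lb
    nodes[c].length = lc
    return TreeNode(children=[nodes[a], nodes[b], nodes[c]])


def _pgma(matrix: DistanceMatrix, weighted: bool) -> TreeNode:
    # UPGMA averages over cluster sizes; WPGMA averages the two distances.
    nodes = [TreeNode(label) for label in matrix.labels]
    heights = [0.0] * len(nodes)
    sizes = [1] * len(nodes)
    d = matrix.values.astype(float).copy()
    active = list(range(len(nodes)))
    while len(active) > 1:
        best = None
        best_d = math.inf
        for a_idx in range(len(active)):
            for b_idx in range(a_idx + 1, len(active)):
                i, j = active[a_idx], active[b_idx]
                if d[i, j] < best_d - 1e-12:
                    best_d = d[i, j]
                    best = (i, j)
        i, j = best
        height = d[i, j] / 2.0
        nodes[i].length = max(height - heights[i], 0.0)
        nodes[j].length = max(height - heights[j], 0.0)
        parent = TreeNode(children=[nodes[i], nodes[j]])
        for k in active:
            if k in (i, j):
                continue
            if weighted:
                val = (d[i, k] + d[j, k]) / 2.0
            else:
                val = (sizes[i] * d[i, k] + sizes[j] * d[j, k]) / (
                    sizes[i] + sizes[j]
                )
            d[i, k] = d[k, i] = val
        nodes[i] = parent
        heights[i] = height
        sizes[i] += sizes[j]
        active.remove(j)
    root = nodes[active[0]]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# tree surgery


def reroot_with_outgroup(tree: TreeNode, species: str) -> TreeNode:
    """Root the tree on the edge leading to the *species* leaf (midpoint).

    If the species is absent the tree is returned untouched with a warning.
    Rerooting an already-correctly-rooted tree is the identity.
    """
    import logging

    if species not in tree.leaf_names():
        logging.getLogger("mafstream").warning(
            "outgroup %r not found in tree; left unrooted", species
        )
        return tree
    # already rooted on the outgroup edge: idempotent
    if len(tree.children) == 2 and any(
        c.is_leaf and c.label == species for c in tree.children
    ):
        return tree

    tree = tree.copy()
    parents: dict[int, TreeNode | None] = {id(tree): None}

    def index(node: TreeNode) -> None:
        for c in node.children:
            parents[id(c)] = node
            index(c)

    index(tree)
    leaf = next(l for l in tree.leaves() if l.label == species)
    edge = leaf.length if leaf.length is not None else 0.0
    old_parent = parents[id(leaf)]

    # reverse the path from old_parent up to the old root
    path = []
    node = old_parent
    while node is not None:
        path.append(node)
        node = parents[id(node)]
    for child, parent in zip(path, path[1:]):
        parent.children.remove(child)
        child.children.append(parent)
        parent.length = child.length
    old_root = path[-1]
    if len(old_root.children) == 1:  # suppress the degree-2 old root
        only = old_root.children[0]
        grand = path[-2] if len(path) >= 2 else None
        if grand is not None:
            grand.children.remove(old_root)
            grand.children.append(only)
            only.length = (only.length or 0.0) + (old_root.length or 0.0)

    new_base = old_parent
    new_base.children.remove(leaf)
    leaf.length = edge / 2.0
    new_base.length = edge / 2.0
    if len(new_base.children) == 1:  # fuse a degree-2 node under the new root
        only = new_base.children[0]
        only.length = (only.length or 0.0) + new_base.length
        new_base = only
    return TreeNode(children=[leaf, new_base])


def drop_species(tree: TreeNode, species: str) -> TreeNode:
    """Remove the *species* leaf, fusing the resulting degree-2 node
    (branch lengths summed).  Absent species: identity with a warning."""
    import logging

    if species not in tree.leaf_names():
        logging.getLogger("mafstream").warning(
            "species %r not in tree; nothing dropped", species
        )
        return tree
    tree = tree.copy()

    def prune(node: TreeNode) -> TreeNode | None:
        if node.is_leaf:
            return None if node.label == species else node
        kept = [c for c in (prune(c) for c in node.children) if c is not None]
        if not kept:
            return None
        if len(kept) == 1 and len(node.children) > 1:
            only = kept[0]
            if node.length is not None and only.length is not None:
                only.length += node.length
            else:
                only.length = node.length if only.length is None else only.length
            return only
        node.children = kept
        return node

    result = prune(tree)
    if result is None:
        raise MafError("dropping species emptied the tree")
    if result is not tree:
        result.length = None  # promoted to root
    return result


def topology_tally(
    trees,
    triplet: tuple[str, str, str],
    outgroup: str | None = None,
) -> dict:
    """Classify each tree by which pair of *triplet* is the cherry.

    Trees are rooted via *outgroup* when given (otherwise taken as rooted).
    Returns counts keyed by sorted label pair, plus ``"unresolved"``.
    """
    a, b, c = triplet
    counts: dict = {
        tuple(sorted((a, b))): 0,
        tuple(sorted((a, c))): 0,
        tuple(sorted((b, c))): 0,
        "unresolved": 0,
    }
    for tree in trees:
        names = set(tree.leaf_names())
        if not {a, b, c} <= names:
            raise MafError(f"tree lacks triplet species {triplet}")
        rooted = reroot_with_outgroup(tree, outgroup) if outgroup else tree
        paths = {}
        for label in (a, b, c):

            def find(node: TreeNode, target: str, acc: list) -> list | None:
                acc = acc + [id(node)]
                if node.is_leaf:
                    return acc if node.label == target else None
                for child in node.children:
                    hit = find(child, target, acc)
                    if hit is not None:
                        return hit
                return None

            paths[label] = find(rooted, label, [])

        def mrca_depth(x: str, y: str) -> int:
            depth = 0
            for u, w in zip(paths[x], paths[y]):
                if u != w:
                    break
                depth += 1
            return depth

        d_ab, d_ac, d_bc = mrca_depth(a, b), mrca_depth(a, c), mrca_depth(b, c)
        best = max(d_ab, d_ac, d_bc)
        winners = [
            pair
            for pair, depth in (
                (tuple(sorted((a, b))), d_ab),
                (tuple(sorted((a, c))), d_ac),
                (tuple(sorted((b, c))), d_bc),
            )
            if depth == best
        ]
        if len(winners) == 1:
            counts[winners[0]] += 1
        else:
            counts["unresolved"] += 1
    return counts
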