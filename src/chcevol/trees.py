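"""Rooted binary phylogenies: Newick I/O, branch transforms, trait simulation.

Trees are kept as a light node structure.  Branch-length transformations
implement the three phylogenetic classes of the trait-macroevolution models:

* pure-phylogenetic — the tree as given (change along every branch);
* nonphylogenetic — a star phylogeny (divergence independent of topology),
  tip branch lengths either the original root-to-tip path lengths
  ("distance" tempo) or all equal;
* punctuated — at every bifurcation one daughter branch retains the
  ancestral value (its edge length is set to 0) and the other changes; a
  per-node assignment picks the changing daughter.

Tempo classes rescale the changing branches: "distance" keeps original
lengths, "equal" sets them to 1, "free" takes them as free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import dendropy
import numpy as np

from .errors import InvalidInputError


@dataclass
class Node:
    label: str | None = None
    length: float | None = None  # edge length to parent; None at the root
    children: list["Node"] = field(default_factory=list)

    @property
    def is_tip(self) -> bool:
        return not self.children


class Phylogeny:
    """A rooted binary tree with labeled tips and nonnegative branch lengths."""

    def __init__(self, root: Node, validate: bool = True):
        self.root = root
        if validate:
            self._validate()
        self._flat: dict | None = None

    # -- construction -------------------------------------------------------
    def _validate(self) -> None:
        tips = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_tip:
                if not node.label:
                    raise InvalidInputError("unlabeled tip in tree")
                tips.append(node.label)
            else:
                if len(node.children) != 2:
                    raise InvalidInputError(
                        f"tree is not strictly bifurcating: node with "
                        f"{len(node.children)} children"
                    )
                stack.extend(node.children)
            if node is not self.root and node.length is not None and node.length < 0:
                raise InvalidInputError("negative branch length")
        if len(tips) < 2:
            raise InvalidInputError("tree needs at least 2 tips")
        if len(set(tips)) != len(tips):
            raise InvalidInputError("duplicate tip labels")

    # -- basic structure ----------------------------------------------------
    def _flatten(self) -> dict:
        """Preorder indexing of nodes with tip and internal bookkeeping."""
        if self._flat is not None:
            return self._flat
        preorder: list[Node] = []

        def walk(node: Node) -> None:
            preorder.append(node)
            for ch in node.children:
                walk(ch)

        walk(self.root)
        tips = [n for n in preorder if n.is_tip]
        internals = [n for n in preorder if not n.is_tip]
        tip_index = {id(n): k for k, n in enumerate(tips)}
        # per internal node, per child: boolean tip-membership vectors
        member: dict[int, np.ndarray] = {}

        def tipset(node: Node) -> np.ndarray:
            vec = np.zeros(len(tips), dtype=bool)
            if node.is_tip:
                vec[tip_index[id(node)]] = True
            else:
                for ch in node.children:
                    key = id(ch)
                    if key not in member:
                        member[key] = tipset(ch)
                    vec |= member[key]
            return vec

        for n in internals:
            for ch in n.children:
                if id(ch) not in member:
                    member[id(ch)] = tipset(ch)
        self._flat = {
            "preorder": preorder,
            "tips": tips,
            "internals": internals,
            "tip_index": tip_index,
            "member": member,
        }
        return self._flat

    @property
    def n_tips(self) -> int:
        return len(self._flatten()["tips"])

    @property
    def tip_labels(self) -> list[str]:
        return [n.label for n in self._flatten()["tips"]]

    @property
    def internal_nodes(self) -> list[Node]:
        return self._flatten()["internals"]

    @property
    def has_all_lengths(self) -> bool:
        return all(
            n.length is not None
            for n in self._flatten()["preorder"]
            if n is not self.root
        )

    def clone(self) -> "Phylogeny":
        def copy(node: Node) -> Node:
            return Node(label=node.label, length=node.length,
                        children=[copy(c) for c in node.children])

        return Phylogeny(copy(self.root), validate=False)

    # -- metrics ------------------------------------------------------------
    def root_to_tip(self) -> np.ndarray:
        """Path length from root to each tip (tip order = preorder)."""
        flat = self._flatten()
        depth = np.zeros(len(flat["tips"]))

        def walk(node: Node, d: float) -> None:
            if node.is_tip:
                depth[flat["tip_index"][id(node)]] = d
            for ch in node.children:
                walk(ch, d + _len(ch))

        walk(self.root, 0.0)
        return depth

    def covariance(self) -> np.ndarray:
        """C_ij = shared root-to-MRCA path length (unit-rate BM covariance)."""
        flat = self._flatten()
        n = len(flat["tips"])
        C = np.zeros((n, n))

        def walk(node: Node, d: float) -> np.ndarray:
            if node.is_tip:
                k = flat["tip_index"][id(node)]
                C[k, k] = d
                vec = np.zeros(n, dtype=bool)
                vec[k] = True
                return vec
            sets = []
            for ch in node.children:
                sets.append(walk(ch, d + _len(ch)))
            for a in range(len(sets)):
                for b in range(a + 1, len(sets)):
                    C[np.ix_(sets[a], sets[b])] = d
                    C[np.ix_(sets[b], sets[a])] = d
            out = sets[0]
            for s in sets[1:]:
                out = out | s
            return out

        walk(self.root, 0.0)
        return C

    def patristic_distances(self) -> np.ndarray:
        """Pairwise path lengths between tips."""
        C = self.covariance()
        d = np.diag(C)
        return d[:, None] + d[None, :] - 2 * C

    # -- serialization ------------------------------------------------------
    def to_newick(self) -> str:
        def fmt(node: Node) -> str:
            if node.is_tip:
                core = node.label or ""
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")"
                if node.label:
                    core += node.label
            if node is not self.root and node.length is not None:
                core += f":{node.length:.12g}"
            return core

        return fmt(self.root) + ";"


def _len(node: Node) -> float:
    return 0.0 if node.length is None else float(node.length)


def read_newick(text: str) -> Phylogeny:
    """Parse a Newick string into a validated binary phylogeny."""
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise InvalidInputError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        label = None
        if dnode.taxon is not None:
            label = dnode.taxon.label
        elif dnode.label:
            label = dnode.label
        node = Node(label=label, length=dnode.edge.length)
        node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    root = convert(dtree.seed_node)
    # dendropy sometimes wraps a single root child; collapse unifurcations
    while len(root.children) == 1:
        child = root.children[0]
        if root.length or child.length:
            child.length = (_len(root) + _len(child)) or child.length
        root = child
        root.length = None
    return Phylogeny(root)


def read_newick_file(path) -> Phylogeny:
    with open(path, "r", encoding="utf-8") as fh:
        text = "".join(
            line for line in fh if not line.lstrip().startswith("#")
        )
    return read_newick(text)


PHYLO_CLASSES = ("pure_phylogenetic", "nonphylogenetic", "punctuated")
TEMPOS = ("distance", "equal", "free")


def _star(labels: Sequence[str], lengths: Sequence[float]) -> Phylogeny:
    root = Node()
    # star phylogenies are multifurcating by design; bypass the binary check
    root.children = [
        Node(label=l, length=float(t)) for l, t in zip(labels, lengths)
    ]
    return Phylogeny(root, validate=False)


def transform_tree(
    tree: Phylogeny,
    phylo_class: str,
    tempo: str,
    branch_params: Sequence[float] | None = None,
    punct_assignment: Sequence[int] | None = None,
) -> Phylogeny:
    """Apply a phylogenetic-class / tempo transformation to branch lengths.

    ``punct_assignment`` gives, per internal node in preorder, the index
    (0/1) of the daughter that *changes*; the other daughter's edge length
    becomes 0.  ``branch_params`` supplies free-tempo lengths, ordered by
    the non-root preorder edges (pure), tips (nonphylogenetic), or internal
    nodes in preorder (punctuated: one changing edge each).
    """
    if phylo_class not in PHYLO_CLASSES:
        raise InvalidInputError(f"unknown phylogenetic class {phylo_class!r}")
    if tempo not in TEMPOS:
        raise InvalidInputError(f"unknown tempo {tempo!r}")
    if branch_params is not None and np.any(np.asarray(branch_params) < 0):
        raise InvalidInputError("negative branch parameter")
    if tempo == "distance" and not tree.has_all_lengths:
        raise InvalidInputError("distance tempo requires branch lengths")

    if phylo_class == "nonphylogenetic":
        labels = tree.tip_labels
        n = len(labels)
        if tempo == "distance":
            lengths = tree.root_to_tip()
        elif tempo == "equal":
            lengths = np.ones(n)
        else:
            if branch_params is None or len(branch_params) != n:
                raise InvalidInputError(
                    f"nonphylogenetic/free needs {n} branch parameters"
                )
            lengths = np.asarray(branch_params, dtype=float)
        return _star(labels, lengths)

    out = tree.clone()
    edges = [n for n in out._flatten()["preorder"] if n is not out.root]

    if phylo_class == "pure_phylogenetic":
        if tempo == "equal":
            for e in edges:
                e.length = 1.0
        elif tempo == "free":
            if branch_params is None or len(branch_params) != len(edges):
                raise InvalidInputError(
                    f"pure_phylogenetic/free needs {len(edges)} branch parameters"
                )
            for e, b in zip(edges, branch_params):
                e.length = float(b)
        out._flat = None
        return out

    # punctuated
    internals = out.internal_nodes
    if punct_assignment is None or len(punct_assignment) != len(internals):
        raise InvalidInputError(
            f"punctuated transform needs a daughter assignment of length "
            f"{len(internals)}"
        )
    if tempo == "free" and (
        branch_params is None or len(branch_params) != len(internals)
    ):
        raise InvalidInputError(
            f"punctuated/free needs {len(internals)} branch parameters"
        )
    for k, node in enumerate(internals):
        change = int(punct_assignment[k])
        if change not in (0, 1):
            raise InvalidInputError("punctuated assignment entries must be 0/1")
        for ci, child in enumerate(node.children):
            if ci != change:
                child.length = 0.0
            elif tempo == "distance":
                child.length = _len(child)
            elif tempo == "equal":
                child.length = 1.0
            else:
                child.length = float(branch_params[k])
    out._flat = None
    return out


def simulate_trait(
    tree: Phylogeny,
    phylo_class: str,
    tempo: str,
    rate: float = 1.0,
    root_state: float = 0.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    branch_params: Sequence[float] | None = None,
) -> dict[str, float]:
    """Simulate tip trait values under one of the nine models.

    Brownian increments Normal(0, rate * transformed branch length) are
    accumulated root-to-tip on the transformed tree; punctuated classes draw
    the changing daughter uniformly at random at every bifurcation.
    """
    if rate < 0:
        raise InvalidInputError("rate must be >= 0")
    if rng is None:
        rng = np.random.default_rng(seed)
    assignment = None
    if phylo_class == "punctuated":
        n_int = len(tree.internal_nodes)
        assignment = rng.integers(0, 2, size=n_int)
    t = transform_tree(tree, phylo_class, tempo,
                       branch_params=branch_params,
                       punct_assignment=assignment)
    values: dict[str, float] = {}

    def walk(node: Node, value: float) -> None:
        for ch in node.children:
            v = value
            el = _len(ch) * rate
            if el > 0:
                v = value + rng.normal(0.0, np.sqrt(el))
            if ch.is_tip:
                values[ch.label] = v
            else:
                walk(ch, v)

    walk(t.root, float(root_state))
    return values


def yule_tree(
    n_tips: int,
    birth_rate: float = 1.0,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    ultrametric: bool = True,
    labels: Sequence[str] | None = None,
    depth: float | None = 1.0,
) -> Phylogeny:
    """Simulate a pure-birth (Yule) tree.

    With ``ultrametric=True`` all tips are contemporaneous; ``depth`` (if
    given) rescales the tree to that root-to-tip height.  Tip labels default
    to t1..tn assigned in random order.
    """
    if n_tips < 2:
        raise InvalidInputError("need at least 2 tips")
    if rng is None:
        rng = np.random.default_rng(seed)
    if labels is None:
        labels = [f"t{k + 1}" for k in range(n_tips)]
    elif len(labels) != n_tips:
        raise InvalidInputError("label count does not match n_tips")

    # birth times: at k lineages the wait is Exp(k * birth_rate)
    root = Node()
    a = Node(length=0.0)
    b = Node(length=0.0)
    root.children = [a, b]
    active = [a, b]
    elapsed = 0.0
    while len(active) < n_tips:
        k = len(active)
        wait = rng.exponential(1.0 / (k * birth_rate))
        elapsed += wait
        for node in active:
            node.length += wait
        pick = int(rng.integers(0, k))
        parent = active.pop(pick)
        c1, c2 = Node(length=0.0), Node(length=0.0)
        parent.children = [c1, c2]
        active.extend([c1, c2])
    final_wait = rng.exponential(1.0 / (len(active) * birth_rate))
    elapsed += final_wait
    for node in active:
        node.length += final_wait
    order = rng.permutation(n_tips)
    for node, k in zip(active, order):
        node.label = labels[int(k)]
    tree = Phylogeny(root)
    if not ultrametric:
        # jitter terminal branches so root-to-tip depths differ
        for node in active:
            node.length = float(node.length * rng.uniform(0.5, 1.5))
        tree._flat = None
    if depth is not None:
        height = float(tree.root_to_tip().max())
        scale = depth / height
        for n in tree._flatten()["preorder"]:
            if n is not tree.root and n.length is not None:
                n.length = float(n.length * scale)
        tree._flat = None
    return tree
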