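"""Rooted leaf-labelled trees with branch lengths.

The tree model is deliberately small: mutable nodes with parent/child
links, optional branch lengths (expected substitutions per site unless a
caller says otherwise) and a free-form annotation dict.  Everything
downstream (topology enumeration, likelihood, coalescent simulation,
triplet extraction, phylogenetic signal) is built on this class.
"""

from __future__ import annotations

from typing import Callable, Iterator, Optional, Sequence


class TreeError(ValueError):
    """Raised for structurally invalid trees or invalid tree operations."""


class TreeNode:
    __slots__ = ("name", "length", "children", "parent", "annotations")

    def __init__(self, name: Optional[str] = None,
                 length: Optional[float] = None) -> None:
        self.name = name
        self.length = length
        self.children: list[TreeNode] = []
        self.parent: Optional[TreeNode] = None
        self.annotations: dict = {}

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"TreeNode({self.name!r}, len={self.length})"


class RootedTree:
    """A rooted tree addressed through its root node."""

    def __init__(self, root: TreeNode) -> None:
        self.root = root

    # ------------------------------------------------------------------
    # traversal
    # ------------------------------------------------------------------
    def postorder(self) -> Iterator[TreeNode]:
        stack: list[tuple[TreeNode, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves()]

    def n_leaves(self) -> int:
        return sum(1 for n in self.postorder() if n.is_leaf)

    # ------------------------------------------------------------------
    # validation / predicates
    # ------------------------------------------------------------------
    def validate(self) -> None:
        names = self.leaf_names()
        if any(n is None for n in names):
            raise TreeError("all leaves must be named")
        dupes = {n for n in names if names.count(n) > 1}
        if dupes:
            raise TreeError(f"duplicate leaf labels: {sorted(dupes)}")
        for node in self.postorder():
            if node.length is not None:
                if not (node.length == node.length) or node.length in (
                        float("inf"), float("-inf")):
                    raise TreeError(f"non-finite branch length on {node.name}")
                if node.length < 0:
                    raise TreeError(f"negative branch length on {node.name}")

    def is_binary(self) -> bool:
        return all(len(n.children) in (0, 2) for n in self.postorder())

    def is_ultrametric(self, tol: float = 1e-9) -> bool:
        depths = self.leaf_depths()
        vals = list(depths.values())
        return max(vals) - min(vals) <= tol

    # ------------------------------------------------------------------
    # geometry
    # ------------------------------------------------------------------
    def leaf_depths(self) -> dict[str, float]:
        """Root-to-tip path length per leaf (missing lengths count as 0)."""
        depth: dict[TreeNode, float] = {self.root: 0.0}
        out: dict[str, float] = {}
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + (node.length or 0.0)
            if node.is_leaf:
                out[node.name] = depth[node]
        return out

    def node_depths(self) -> dict[TreeNode, float]:
        depth: dict[TreeNode, float] = {self.root: 0.0}
        for node in self.preorder():
            if node is not self.root:
                depth[node] = depth[node.parent] + (node.length or 0.0)
        return depth

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder()
                   if n is not self.root)

    def mrca(self, labels: Sequence[str]) -> TreeNode:
        want = set(labels)
        below: dict[TreeNode, set[str]] = {}
        for node in self.postorder():
            if node.is_leaf:
                below[node] = {node.name} & want
            else:
                s: set[str] = set()
                for c in node.children:
                    s |= below[c]
                below[node] = s
            if below[node] == want:
                return node
        raise TreeError(f"labels {sorted(want)} not all present in tree")

    # ------------------------------------------------------------------
    # manipulation
    # ------------------------------------------------------------------
    def copy(self) -> "RootedTree":
        def rec(node: TreeNode) -> TreeNode:
            new = TreeNode(node.name, node.length)
            new.annotations = dict(node.annotations)
            for c in node.children:
                new.add_child(rec(c))
            return new

        return RootedTree(rec(self.root))

    def scale_lengths(self, factor: float) -> "RootedTree":
        out = self.copy()
        for node in out.postorder():
            if node.length is not None:
                node.length *= factor
        return out

    def map_leaf_names(self, fn: Callable[[str], str]) -> "RootedTree":
        out = self.copy()
        for leaf in out.leaves():
            leaf.name = fn(leaf.name)
        return out

    def restrict(self, labels: Sequence[str]) -> "RootedTree":
        """Induced subtree on ``labels`` with path lengths preserved.

        Unary internal nodes created by the restriction are suppressed and
        their branch lengths summed.
        """
        keep = set(labels)
        missing = keep - set(self.leaf_names())
        if missing:
            raise TreeError(f"labels not in tree: {sorted(missing)}")

        def rec(node: TreeNode) -> Optional[TreeNode]:
            if node.is_leaf:
                if node.name in keep:
                    return TreeNode(node.name, node.length)
                return None
            kept = [rec(c) for c in node.children]
            kept = [k for k in kept if k is not None]
            if not kept:
                return None
            if len(kept) == 1:
                child = kept[0]
                if child.length is not None and node.length is not None:
                    child.length += node.length
                elif node.length is not None:
                    child.length = node.length
                return child
            new = TreeNode(node.name, node.length)
            for k in kept:
                new.add_child(k)
            return new

        new_root = rec(self.root)
        if new_root is None:
            raise TreeError("restriction removed every leaf")
        new_root.length = None
        return RootedTree(new_root)

    def reroot_with_outgroup(self, outgroup: str,
                             fraction: float = 0.5) -> "RootedTree":
        """Reroot so ``outgroup`` is one of the root's two children.

        The root is placed on the edge subtending the outgroup leaf,
        splitting that branch at ``fraction`` (measured from the leaf).
        A pre-existing root of degree 2 is suppressed on the ingroup side.
        """
        tree = self.copy()
        target = None
        for leaf in tree.leaves():
            if leaf.name == outgroup:
                target = leaf
                break
        if target is None:
            raise TreeError(f"outgroup {outgroup!r} not in tree")
        if target.parent is tree.root and len(tree.root.children) == 2:
            return tree  # already rooted on the outgroup edge

        # path from the outgroup's parent up to the old root
        path = []
        node = target.parent
        while node is not None:
            path.append(node)
            node = node.parent
        up_lengths = [p.length for p in path]

        # detach every path node from its parent
        target.parent.children.remove(target)
        target.parent = None
        for i, node in enumerate(path):
            node.parent = None
            if i + 1 < len(path):
                path[i + 1].children.remove(node)

        new_root = TreeNode(None, None)
        old_len = target.length
        if old_len is not None:
            target.length = old_len * fraction
            rest = old_len * (1.0 - fraction)
        else:
            rest = None
        new_root.add_child(target)
        path[0].length = rest
        new_root.add_child(path[0])
        # flip: each former parent becomes the child of its former child
        for i in range(len(path) - 1):
            path[i + 1].length = up_lengths[i]
            path[i].add_child(path[i + 1])
        # suppress old root if it became unary
        out = RootedTree(new_root)
        for node in list(out.postorder()):
            if node.parent is not None and len(node.children) == 1:
                child = node.children[0]
                if child.length is not None or node.length is not None:
                    child.length = (child.length or 0.0) + (node.length or 0.0)
                gp = node.parent
                gp.children[gp.children.index(node)] = child
                child.parent = gp
        return out

    # ------------------------------------------------------------------
    # identity
    # ------------------------------------------------------------------
    def topology_id(self) -> str:
        """Canonical Newick string ignoring branch lengths.

        Children are ordered by their canonical substring, so two trees
        have the same id iff they are isomorphic as rooted leaf-labelled
        topologies.
        """

        def rec(node: TreeNode) -> str:
            if node.is_leaf:
                return node.name
            parts = sorted(rec(c) for c in node.children)
            return "(" + ",".join(parts) + ")"

        return rec(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"RootedTree<{self.topology_id()}>"


def cherry(a: str, b: str) -> RootedTree:
    root = TreeNode()
    root.add_child(TreeNode(a))
    root.add_child(TreeNode(b))
    return RootedTree(root)
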