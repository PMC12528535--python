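"""Strict Newick reading and writing.

Supports quoted labels ('...' with '' escaping), branch lengths, internal
node labels and polytomies.  Parse errors carry the character offset.
"""

from __future__ import annotations

from .tree import RootedTree, TreeNode, TreeError


class NewickError(ValueError):
    def __init__(self, message: str, offset: int) -> None:
        super().__init__(f"{message} (at character {offset})")
        self.offset = offset


_SPECIALS = set("(),:;'")


class _Parser:
    def __init__(self, text: str) -> None:
        self.text = text
        self.pos = 0

    def error(self, msg: str) -> NewickError:
        return NewickError(msg, self.pos)

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def parse(self) -> RootedTree:
        self.skip_ws()
        node = self.parse_node()
        self.skip_ws()
        if self.peek() != ";":
            raise self.error("expected ';' terminating the tree")
        self.pos += 1
        self.skip_ws()
        if self.pos != len(self.text):
            raise self.error("trailing characters after ';'")
        tree = RootedTree(node)
        names = tree.leaf_names()
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise TreeError(f"duplicate leaf labels: {dupes}")
        return tree

    def parse_node(self) -> TreeNode:
        self.skip_ws()
        node = TreeNode()
        if self.peek() == "(":
            self.pos += 1
            while True:
                node.add_child(self.parse_node())
                self.skip_ws()
                ch = self.peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise self.error("expected ',' or ')' in subtree")
            node.name = self.parse_label(optional=True)
        else:
            node.name = self.parse_label(optional=False)
        self.skip_ws()
        if self.peek() == ":":
            self.pos += 1
            node.length = self.parse_number()
        return node

    def parse_label(self, optional: bool) -> str | None:
        self.skip_ws()
        if self.peek() == "'":
            self.pos += 1
            out = []
            while True:
                if self.pos >= len(self.text):
                    raise self.error("unterminated quoted label")
                ch = self.text[self.pos]
                if ch == "'":
                    if self.text[self.pos:self.pos + 2] == "''":
                        out.append("'")
                        self.pos += 2
                        continue
                    self.pos += 1
                    return "".join(out)
                out.append(ch)
                self.pos += 1
        start = self.pos
        while (self.pos < len(self.text)
               and self.text[self.pos] not in _SPECIALS
               and not self.text[self.pos].isspace()):
            self.pos += 1
        label = self.text[start:self.pos]
        if not label:
            if optional:
                return None
            raise self.error("expected a leaf label")
        return label

    def parse_number(self) -> float:
        self.skip_ws()
        start = self.pos
        while (self.pos < len(self.text)
               and self.text[self.pos] not in _SPECIALS
               and not self.text[self.pos].isspace()):
            self.pos += 1
        token = self.text[start:self.pos]
        try:
            return float(token)
        except ValueError:
            self.pos = start
            raise self.error(f"invalid branch length {token!r}") from None


def parse_newick(text: str) -> RootedTree:
    """Parse a single Newick string into a :class:`RootedTree`."""
    return _Parser(text).parse()


def _needs_quoting(label: str) -> bool:
    return any(c in _SPECIALS or c.isspace() for c in label)


def _fmt_label(label: str) -> str:
    if _needs_quoting(label):
        return "'" + label.replace("'", "''") + "'"
    return label


def _fmt_length(x: float) -> str:
    # repr gives the shortest string that round-trips exactly
    return repr(float(x))


def write_newick(tree: RootedTree, lengths: bool = True) -> str:
    def rec(node: TreeNode) -> str:
        if node.is_leaf:
            s = _fmt_label(node.name)
        else:
            s = "(" + ",".join(rec(c) for c in node.children) + ")"
            if node.name:
                s += _fmt_label(node.name)
        if lengths and node.length is not None:
            s += ":" + _fmt_length(node.length)
        return s

    return rec(tree.root) + ";"


def read_newick_file(path) -> list[RootedTree]:
    """Read a multi-tree Newick file (one tree per line; blank lines ok)."""
    trees = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line:
                trees.append(parse_newick(line))
    return trees


def write_newick_file(trees, path, lengths: bool = True) -> None:
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(write_newick(tree, lengths=lengths) + "\n")
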