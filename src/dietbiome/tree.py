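"""Rooted phylogenetic trees with Newick round-tripping.

Small, dependency-free tree representation: enough to generate random
trees, read/write Newick, and run the post-order traversals that the
UniFrac computation needs. Multifurcations are allowed; only branch
lengths and leaf labels matter downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator


@dataclass
class TreeNode:
    """A node in a rooted tree; ``length`` is the branch to its parent."""

    name: str | None = None
    length: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        """Yield nodes children-before-parents, iteratively (no recursion limit)."""
        stack: list[tuple[TreeNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded or node.is_leaf:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> list[str]:
        return [n.name for n in self.leaves() if n.name is not None]

    def total_branch_length(self) -> float:
        return sum(n.length for n in self.postorder() if n.length is not None)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return write_newick(self)


class NewickError(ValueError):
    """Raised on malformed Newick input."""


def _tokenize(text: str) -> Iterator[str]:
    i, n = 0, len(text)
    while i < n:
        c = text[i]
        if c in "(),:;":
            yield c
            i += 1
        elif c.isspace():
            i += 1
        elif c in "'\"":
            j = text.find(c, i + 1)
            if j < 0:
                raise NewickError("unterminated quoted label")
            yield text[i + 1 : j]
            i = j + 1
        else:
            j = i
            while j < n and text[j] not in "(),:;" and not text[j].isspace():
                j += 1
            yield text[i:j]
            i = j


def parse_newick(text: str) -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode` tree."""
    root = TreeNode()
    current = root
    stack: list[TreeNode] = []
    awaiting_length = False
    seen_semicolon = False
    for tok in _tokenize(text):
        if seen_semicolon:
            raise NewickError("content after terminating semicolon")
        if tok == "(":
            child = TreeNode()
            current.children.append(child)
            stack.append(current)
            current = child
            awaiting_length = False
        elif tok == ",":
            if not stack:
                raise NewickError("comma outside parentheses")
            sibling = TreeNode()
            stack[-1].children.append(sibling)
            current = sibling
            awaiting_length = False
        elif tok == ")":
            if not stack:
                raise NewickError("unbalanced parentheses")
            current = stack.pop()
            awaiting_length = False
        elif tok == ":":
            awaiting_length = True
        elif tok == ";":
            seen_semicolon = True
        elif awaiting_length:
            try:
                current.length = float(tok)
            except ValueError as exc:
                raise NewickError(f"bad branch length {tok!r}") from exc
            awaiting_length = False
        else:
            current.name = tok
    if stack:
        raise NewickError("unbalanced parentheses")
    if len(root.children) == 1 and root.name is None and root.length is None:
        # "(...)label;" wraps a single top-level clade; unwrap it
        root = root.children[0]
    return root


def _needs_quotes(name: str) -> bool:
    return any(c in "(),:;'\" \t\n" for c in name)


def write_newick(root: TreeNode) -> str:
    """Serialize a tree to a Newick string (with branch lengths)."""

    parts: dict[int, str] = {}
    for node in root.postorder():
        label = node.name or ""
        if label and _needs_quotes(label):
            label = "'" + label.replace("'", "''") + "'"
        body = (
            "(" + ",".join(parts.pop(id(c)) for c in node.children) + ")"
            if node.children
            else ""
        )
        suffix = f":{node.length!r}" if node.length is not None else ""
        parts[id(node)] = body + label + suffix
    return parts[id(root)] + ";"


def read_newick_file(path) -> TreeNode:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_newick_file(root: TreeNode, path) -> None:
    with open(path, "w") as fh:
        fh.write(write_newick(root) + "\n")
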