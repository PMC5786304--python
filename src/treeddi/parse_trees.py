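"""Bracketed constituency-tree ingestion, binarization, and per-node
annotation with the subtree-containment flag and propagated relative
distances.

Trees arrive as Penn-Treebank-style S-expressions (one per line, aligned
by line number with the instance file).  After :func:`binarize` every
internal node has exactly two children, which is what the binary
tree-LSTM recursion requires.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .features import relative_distance

__all__ = [
    "ParseNode",
    "TreeError",
    "read_bracketed",
    "write_bracketed",
    "binarize",
    "annotate",
    "propagate_distance",
]


def propagate_distance(left: int, right: int) -> int:
    """Internal-node distance: the child value of smaller magnitude; on
    an exact |.| tie the left child's value wins (deterministic)."""
    return left if abs(left) <= abs(right) else right

MERGE_SUFFIX = "|merge"


class TreeError(ValueError):
    pass


@dataclass
class ParseNode:
    """A constituency-tree node.

    Leaves carry the aligned token and its index; after :func:`annotate`
    every node additionally carries ``containment`` and the distance pair
    ``(d1, d2)`` to the two target drugs.
    """

    label: str
    children: list["ParseNode"] = field(default_factory=list)
    token: Optional[str] = None
    leaf_index: Optional[int] = None
    containment: Optional[bool] = None
    d1: Optional[int] = None
    d2: Optional[int] = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def is_annotated(self) -> bool:
        return self.containment is not None and self.d1 is not None

    def leaves(self) -> list["ParseNode"]:
        if self.is_leaf:
            return [self]
        out: list[ParseNode] = []
        for child in self.children:
            out.extend(child.leaves())
        return out

    def iter_nodes(self) -> Iterator["ParseNode"]:
        """Post-order traversal (children before parent)."""
        for child in self.children:
            yield from child.iter_nodes()
        yield self

    def to_sexpr(self) -> str:
        if self.is_leaf:
            return self.token if self.token is not None else self.label
        inner = " ".join(c.to_sexpr() for c in self.children)
        return f"({self.label} {inner})"


def _leaf(token: str) -> ParseNode:
    return ParseNode(label=token, token=token)


def read_bracketed(sexpr: str) -> ParseNode:
    """Parse one bracketed tree; bare atoms are token leaves.

    Unary chains are preserved as read; use :func:`binarize` to obtain a
    strictly binary tree.
    """
    pos = 0
    n = len(sexpr)

    def error(msg: str) -> TreeError:
        return TreeError(f"{msg} at position {pos}")

    def skip_ws() -> None:
        nonlocal pos
        while pos < n and sexpr[pos].isspace():
            pos += 1

    def parse_node() -> ParseNode:
        nonlocal pos
        skip_ws()
        if pos >= n:
            raise error("unexpected end of input")
        if sexpr[pos] != "(":
            start = pos
            while pos < n and not sexpr[pos].isspace() and sexpr[pos] not in "()":
                pos += 1
            if pos == start:
                raise error("expected token")
            return _leaf(sexpr[start:pos])
        pos += 1  # consume '('
        skip_ws()
        start = pos
        while pos < n and not sexpr[pos].isspace() and sexpr[pos] not in "()":
            pos += 1
        label = sexpr[start:pos]
        if not label:
            raise error("missing node label")
        children = []
        while True:
            skip_ws()
            if pos >= n:
                raise error("unbalanced parentheses: missing ')'")
            if sexpr[pos] == ")":
                pos += 1
                break
            children.append(parse_node())
        if not children:
            raise error(f"node {label!r} has no children")
        return ParseNode(label=label, children=children)

    root = parse_node()
    skip_ws()
    if pos != n:
        raise error("trailing content after tree")
    return root


def write_bracketed(root: ParseNode) -> str:
    return root.to_sexpr()


def binarize(node: ParseNode) -> ParseNode:
    """Return a strictly binary copy of ``node``.

    Unary internal chains collapse into their child; n-ary nodes are
    right-branch-collapsed with auxiliary ``label|merge`` nodes.  Leaf
    order is preserved; auxiliary labels never affect features.
    """
    if node.is_leaf:
        return _leaf(node.token if node.token is not None else node.label)
    if len(node.children) == 1:
        return binarize(node.children[0])
    children = [binarize(c) for c in node.children]

    def collapse(label: str, kids: list[ParseNode]) -> ParseNode:
        if len(kids) == 2:
            return ParseNode(label=label, children=kids)
        head, rest = kids[0], kids[1:]
        aux_label = label if label.endswith(MERGE_SUFFIX) else label + MERGE_SUFFIX
        return ParseNode(label=label, children=[head, collapse(aux_label, rest)])

    return collapse(node.label, children)


def annotate(
    root: ParseNode,
    tokens: Sequence[str],
    target1: int,
    target2: int,
    sentence_id: str = "?",
) -> ParseNode:
    """Annotate a binary tree with containment flags and distances.

    Leaves are aligned positionally to ``tokens`` (count must match; the
    leaf token is set from the list, since parses are produced on the
    preprocessed token string).  Internal nodes take, per component, the
    child distance of smaller absolute value (ties go to the left child)
    and the OR of the children's containment flags.
    """
    leaves = root.leaves()
    if len(leaves) != len(tokens):
        raise TreeError(
            f"sentence {sentence_id}: {len(leaves)} leaves vs "
            f"{len(tokens)} tokens — parse/token misalignment"
        )
    n = len(tokens)
    for idx in (target1, target2):
        if not (0 <= idx < n):
            raise TreeError(f"sentence {sentence_id}: target index {idx} invalid")
    for i, leaf in enumerate(leaves):
        leaf.token = tokens[i]
        leaf.label = tokens[i]
        leaf.leaf_index = i
        leaf.containment = i in (target1, target2)
        leaf.d1 = relative_distance(i, target1)
        leaf.d2 = relative_distance(i, target2)

    def visit(node: ParseNode) -> None:
        if node.is_leaf:
            return
        if len(node.children) != 2:
            raise TreeError(
                f"sentence {sentence_id}: node {node.label!r} has "
                f"{len(node.children)} children; binarize first"
            )
        left, right = node.children
        visit(left)
        visit(right)
        node.containment = bool(left.containment or right.containment)
        node.d1 = propagate_distance(left.d1, right.d1)
        node.d2 = propagate_distance(left.d2, right.d2)

    visit(root)
    return root
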