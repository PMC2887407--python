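"""Phylogenies whose branches carry class labels.

Branch-partitioned codon models assign one dN/dS ratio per branch class
(for a gene duplication: pre-duplication branches, the two post-duplication
stem branches, and the two paralog crown clades).  Classes are attached to
branches either with PAML-style inline ``#tag`` suffixes in the Newick
string (``(A#1,B)#1:0.1``) or with a separate two-column TSV mapping node
labels to class names; unlabeled branches fall back to a default class.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import dendropy

__all__ = ["TreeNode", "LabeledTree", "DEFAULT_CLASS"]

DEFAULT_CLASS = "0"


@dataclass
class TreeNode:
    """One node; the edge to its parent carries ``length`` and ``cls``."""

    name: str | None = None
    length: float | None = None
    cls: str = DEFAULT_CLASS
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["TreeNode"]:
        for child in self.children:
            yield from child.postorder()
        yield self


class LabeledTree:
    """A (possibly unrooted) phylogeny with branch classes and lengths.

    Branch lengths are expected substitutions per codon.  An unrooted tree
    is represented by a basal polytomy; likelihoods under reversible models
    do not depend on the root placement.
    """

    def __init__(self, root: TreeNode):
        self.root = root
        names = [n.name for n in root.postorder() if n.is_leaf()]
        if len(set(names)) != len(names):
            raise ValueError("duplicate taxon names in tree")
        if any(n is None for n in names):
            raise ValueError("every leaf must be named")

    # -- construction -------------------------------------------------------

    @classmethod
    def from_newick(
        cls,
        newick: str,
        labels: dict[str, str] | None = None,
        default_class: str = DEFAULT_CLASS,
    ) -> "LabeledTree":
        """Parse Newick with optional ``#class`` tags or a label map.

        ``labels`` maps node names (leaf or internal) to branch classes and
        overrides inline tags.
        """
        dt = dendropy.Tree.get(
            data=newick,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )

        def convert(dnode) -> TreeNode:
            raw = None
            if dnode.taxon is not None:
                raw = dnode.taxon.label
            elif dnode.label is not None:
                raw = dnode.label
            name, tag = _split_tag(raw)
            node = TreeNode(
                name=name,
                length=dnode.edge.length,
                cls=tag if tag is not None else default_class,
                children=[convert(c) for c in dnode.child_nodes()],
            )
            return node

        root = convert(dt.seed_node)
        tree = cls(root)
        if labels:
            tree.apply_labels(labels, default_class=None)
        return tree

    @classmethod
    def from_files(
        cls, newick_path, labels_path=None, default_class: str = DEFAULT_CLASS
    ) -> "LabeledTree":
        with open(newick_path) as fh:
            newick = fh.read()
        labels = read_label_map(labels_path) if labels_path else None
        return cls.from_newick(newick, labels=labels, default_class=default_class)

    def apply_labels(self, labels: dict[str, str], default_class: str | None) -> None:
        """Set branch classes from a node-name -> class map."""
        for node in self.root.postorder():
            if node.name is not None and node.name in labels:
                node.cls = labels[node.name]
            elif default_class is not None:
                node.cls = default_class

    # -- queries ------------------------------------------------------------

    @property
    def taxa(self) -> list[str]:
        return [n.name for n in self.root.postorder() if n.is_leaf()]

    def branches(self) -> list[TreeNode]:
        """All nodes except the root, i.e. one entry per branch."""
        return [n for n in self.root.postorder() if n is not self.root]

    @property
    def classes(self) -> set[str]:
        return {b.cls for b in self.branches()}

    @property
    def n_branches(self) -> int:
        return len(self.branches())

    def has_lengths(self) -> bool:
        return all(b.length is not None for b in self.branches())

    def total_length(self) -> float:
        return sum(b.length or 0.0 for b in self.branches())

    def copy(self) -> "LabeledTree":
        def dup(n: TreeNode) -> TreeNode:
            return TreeNode(n.name, n.length, n.cls, [dup(c) for c in n.children])

        return LabeledTree(dup(self.root))

    def set_lengths(self, lengths: Iterable[float]) -> None:
        """Assign branch lengths in the order of :meth:`branches`."""
        lengths = list(lengths)
        branches = self.branches()
        if len(lengths) != len(branches):
            raise ValueError("wrong number of branch lengths")
        for b, t in zip(branches, lengths):
            if t < 0:
                raise ValueError("negative branch length")
            b.length = float(t)

    def get_lengths(self) -> list[float]:
        return [b.length if b.length is not None else 0.0 for b in self.branches()]

    # -- serialization ------------------------------------------------------

    def to_newick(self, classes: bool = False) -> str:
        """Render Newick; with ``classes`` True, branch classes become #tags."""

        def render(n: TreeNode) -> str:
            if n.is_leaf():
                s = n.name or ""
            else:
                s = "(" + ",".join(render(c) for c in n.children) + ")"
                if n.name:
                    s += n.name
            if classes and n is not self.root:
                s += f"#{n.cls}"
            if n.length is not None and n is not self.root:
                s += f":{n.length!r}"
            return s

        return render(self.root) + ";"

    def write(self, newick_path, labels_path=None, classes: bool = True) -> None:
        """Write Newick (with inline #class tags by default, so internal
        branch classes survive the round trip) and optionally a labels TSV
        for the named nodes."""
        with open(newick_path, "w") as fh:
            fh.write(self.to_newick(classes=classes) + "\n")
        if labels_path is not None:
            with open(labels_path, "w") as fh:
                fh.write("node\tclass\n")
                auto = 0
                for node in self.root.postorder():
                    if node is self.root:
                        continue
                    if node.name is None:
                        auto += 1
                        continue
                    fh.write(f"{node.name}\t{node.cls}\n")


def _split_tag(label: str | None) -> tuple[str | None, str | None]:
    if label is None:
        return None, None
    if "#" in label:
        name, tag = label.rsplit("#", 1)
        return (name or None), tag
    return label, None


def read_label_map(path) -> dict[str, str]:
    """Read a two-column node -> class TSV (header optional)."""
    out: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"bad label line: {line!r}")
            if parts[0] == "node" and parts[1] == "class":
                continue
            out[parts[0]] = parts[1]
    return out
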