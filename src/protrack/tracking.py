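"""Experiment provenance: the experiment graph and the experiment tree.

Related experiments are cross-linked by their internal IDs with directed
parent→child edges (sample or product of the parent used in the child).
Multiple parents are allowed — pooling several gels into one MS run is a
DAG, not a strict tree — but cycles never are: acyclicity is checked
eagerly at link time.  The "experiment tree" shown in reports is the
depth-first expansion of the child edges below a root; when the underlying
sub-DAG shares nodes between branches the shared nodes are repeated in each
branch, which is the usual tree rendering of provenance.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

from .errors import CycleError, DuplicateError, NotFoundError, ValidationError


@dataclass(frozen=True)
class ExperimentEdge:
    parent: int
    child: int
    created_order: int


@dataclass
class ExperimentTreeNode:
    id: int
    type: str
    title: str
    children: list["ExperimentTreeNode"] = field(default_factory=list)

    def to_text(self, depth: int = 0) -> str:
        """Indented plain-text rendering, two spaces per depth level."""
        lines = [f"{'  ' * depth}{self.id} [{self.type}] {self.title}"]
        for child in self.children:
            lines.append(child.to_text(depth + 1))
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"id": self.id, "type": self.type, "title": self.title,
                "children": [c.to_dict() for c in self.children]}

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    def count_at_depth(self, depth: int) -> int:
        if depth == 0:
            return 1
        return sum(c.count_at_depth(depth - 1) for c in self.children)

    def node_ids(self) -> list[int]:
        out = [self.id]
        for c in self.children:
            out.extend(c.node_ids())
        return out


def link(store, parent: int, child: int, actor: str | None = None
         ) -> ExperimentEdge:
    """Associate ``child`` as generated from ``parent``.

    Both experiments must exist and belong to the same project.  A link
    whose child predates its parent only warns — the temporal ordering is
    advisory, instrument clocks being what they are — but self-links,
    duplicate edges and anything that would close a cycle are rejected.
    """
    prow = store._experiment_row(parent)
    crow = store._experiment_row(child)
    if parent == child:
        raise ValidationError(f"experiment {parent} cannot be its own parent")
    if prow["project_id"] != crow["project_id"]:
        raise ValidationError(
            f"experiments {parent} and {child} belong to different projects")
    if _has_edge(store, parent, child):
        raise DuplicateError(f"edge {parent}->{child} already exists")
    if parent in _reachable(store, child, "down"):
        raise CycleError(
            f"linking {parent}->{child} would create a cycle")
    if crow["date"] and prow["date"] and crow["date"] < prow["date"]:
        warnings.warn(
            f"child experiment {child} ({crow['date']}) predates parent"
            f" {parent} ({prow['date']})", stacklevel=2)
    order = store.conn.execute(
        "SELECT COALESCE(MAX(created_order), 0) + 1 FROM edges").fetchone()[0]
    with store.conn:
        store.conn.execute(
            "INSERT INTO edges(parent, child, created_order) VALUES (?,?,?)",
            (parent, child, order))
    store.record_action(actor, "link", child)
    return ExperimentEdge(parent, child, order)


def _has_edge(store, parent: int, child: int) -> bool:
    return store.conn.execute(
        "SELECT 1 FROM edges WHERE parent=? AND child=?",
        (parent, child)).fetchone() is not None


def parents(store, exp_id: int) -> set[int]:
    store._experiment_row(exp_id)
    return {r["parent"] for r in store.conn.execute(
        "SELECT parent FROM edges WHERE child=?", (exp_id,))}


def children(store, exp_id: int) -> set[int]:
    store._experiment_row(exp_id)
    return {r["child"] for r in store.conn.execute(
        "SELECT child FROM edges WHERE parent=?", (exp_id,))}


def _reachable(store, start: int, direction: str) -> set[int]:
    """Transitive closure from ``start`` along edges ('down' = descendants)."""
    step = children if direction == "down" else parents
    seen: set[int] = set()
    frontier = [start]
    while frontier:
        node = frontier.pop()
        for nxt in step(store, node):
            if nxt not in seen:
                seen.add(nxt)
                frontier.append(nxt)
    seen.discard(start)
    return seen


def descendants(store, exp_id: int) -> set[int]:
    store._experiment_row(exp_id)
    return _reachable(store, exp_id, "down")


def ancestors(store, exp_id: int) -> set[int]:
    store._experiment_row(exp_id)
    return _reachable(store, exp_id, "up")


def build_tree(store, root: int) -> ExperimentTreeNode:
    """Depth-first experiment tree below ``root``, children ordered by
    internal ID.  Acyclicity bounds the depth, so plain recursion is safe."""
    row = store._experiment_row(root)
    node = ExperimentTreeNode(row["id"], row["type"], row["title"])
    for child_id in sorted(children(store, root)):
        node.children.append(build_tree(store, child_id))
    return node


def roots_of(store, exp_id: int) -> list[int]:
    """Parentless ancestors of an experiment (itself, if parentless)."""
    anc = ancestors(store, exp_id) | {exp_id}
    return sorted(a for a in anc if not parents(store, a))


def trace_origin(store, exp_id: int) -> list[tuple[int, list]]:
    """Walk back to the first experiment(s) in the tree: the parentless
    ancestors, each paired with its samples — the first experiment's record
    carries the information on the sample that started the analysis."""
    return [(root, store.get_experiment(root).samples)
            for root in roots_of(store, exp_id)]
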