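"""SWC neurite-reconstruction I/O and basic tree interrogation.

SWC is the standard plain-text format for neuron reconstructions: one node
per line with columns ``id type x y z radius parent`` (parent −1 marks the
root).  Manual tracers (e.g. SNT) export one file per traced nerve; group
labels such as ExA/InA or aboral/central/oral are not part of the format and
are carried in a sidecar CSV mapping ``trace,group,reaches_skin``.

Coordinates are micrometres throughout; no unit conversion is attempted.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import DegenerateInputError, SWCParseError, SWCStructureError

#: Group labels recognised by downstream statistics.
KNOWN_GROUPS = ("ExA", "InA", "aboral", "central", "oral", "untagged")


@dataclass(frozen=True)
class SWCNode:
    """One point of a reconstruction: id, structure code, position, radius, parent."""

    node_id: int
    type_code: int
    x: float
    y: float
    z: float
    radius: float
    parent_id: int  # -1 for the root

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z], dtype=float)


@dataclass
class NeuriteTrace:
    """A single traced nerve: a rooted tree of 3D points with radii.

    Parameters
    ----------
    name
        Identifier, typically the SWC file stem.
    nodes
        Node list in file order.  Child-before-parent order is accepted.
    group
        Anatomical group label (``ExA``, ``InA``, ``aboral``, ``central``,
        ``oral`` or ``untagged``).
    reaches_skin
        True if this nerve was traced all the way to the skin; used to pick
        the normalization length for Sholl and trajectory analyses.
    """

    name: str
    nodes: list[SWCNode]
    group: str = "untagged"
    reaches_skin: bool = False

    _index: dict[int, int] = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        ids = [n.node_id for n in self.nodes]
        if len(set(ids)) != len(ids):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SWCStructureError(f"duplicate node_id {dup} in trace {self.name!r}")
        id_set = set(ids)
        roots = [n.node_id for n in self.nodes if n.parent_id == -1]
        if len(roots) != 1:
            raise SWCStructureError(
                f"trace {self.name!r} has {len(roots)} roots "
                f"({roots if roots else 'none'}); exactly one node must have parent -1"
            )
        for n in self.nodes:
            if n.parent_id != -1 and n.parent_id not in id_set:
                raise SWCStructureError(
                    f"node {n.node_id} references missing parent {n.parent_id}"
                )
            if n.radius < 0:
                raise SWCStructureError(f"node {n.node_id} has negative radius")
        self._index = {n.node_id: k for k, n in enumerate(self.nodes)}
        # reject cycles: walk each node to the root
        for n in self.nodes:
            seen = set()
            cur = n
            while cur.parent_id != -1:
                if cur.node_id in seen:
                    raise SWCStructureError(
                        f"cycle detected through node {cur.node_id}"
                    )
                seen.add(cur.node_id)
                cur = self.nodes[self._index[cur.parent_id]]

    @property
    def root(self) -> SWCNode:
        return next(n for n in self.nodes if n.parent_id == -1)

    def node(self, node_id: int) -> SWCNode:
        return self.nodes[self._index[node_id]]

    def coords(self) -> np.ndarray:
        """(n, 3) array of node coordinates in file order."""
        return np.array([[n.x, n.y, n.z] for n in self.nodes], dtype=float)

    def edges(self) -> np.ndarray:
        """(m, 2, 3) array of parent→child coordinate pairs."""
        out = [
            [self.node(n.parent_id).xyz, n.xyz]
            for n in self.nodes
            if n.parent_id != -1
        ]
        return np.array(out, dtype=float).reshape(-1, 2, 3)

    def children_map(self) -> dict[int, list[int]]:
        kids: dict[int, list[int]] = {n.node_id: [] for n in self.nodes}
        for n in self.nodes:
            if n.parent_id != -1:
                kids[n.parent_id].append(n.node_id)
        return kids

    def leaf_nodes(self) -> list[SWCNode]:
        kids = self.children_map()
        return [n for n in self.nodes if not kids[n.node_id]]

    def transformed(self, rotation: np.ndarray | None = None,
                    translation: Sequence[float] | None = None) -> "NeuriteTrace":
        """Return a copy with coordinates rigidly transformed (rotate then shift)."""
        R = np.eye(3) if rotation is None else np.asarray(rotation, dtype=float)
        t = np.zeros(3) if translation is None else np.asarray(translation, dtype=float)
        new_nodes = []
        for n in self.nodes:
            p = R @ n.xyz + t
            new_nodes.append(replace(n, x=p[0], y=p[1], z=p[2]))
        return NeuriteTrace(self.name, new_nodes, self.group, self.reaches_skin)


@dataclass
class TraceSet:
    """A collection of traces sharing an axis convention.

    ``axis_convention`` names which coordinate axis runs proximal–distal and
    which oral–aboral, e.g. ``{"proximal_distal": "z", "oral_aboral": "y"}``.
    """

    traces: list[NeuriteTrace]
    axis_convention: dict[str, str] = field(
        default_factory=lambda: {"proximal_distal": "z", "oral_aboral": "y"}
    )
    units: str = "um"

    def __post_init__(self) -> None:
        names = [t.name for t in self.traces]
        if len(set(names)) != len(names):
            dup = next(n for n in names if names.count(n) > 1)
            raise ValueError(f"duplicate trace name {dup!r} in TraceSet")

    def __iter__(self):
        return iter(self.traces)

    def __len__(self) -> int:
        return len(self.traces)


@dataclass(frozen=True)
class Tip:
    """A terminal point of a trace, labelled with its group of origin."""

    point: tuple[float, float, float]
    group: str
    trace_name: str

    @property
    def xyz(self) -> np.ndarray:
        return np.array(self.point, dtype=float)


@dataclass
class TipSet:
    """Labelled termination points of one or more traces.

    ``projection_axis`` names the coordinate dropped when the tips are
    projected to the plane of the sucker circle (default the proximal–distal
    axis, conventionally ``z``).
    """

    tips: list[Tip]
    projection_axis: str = "z"

    def __len__(self) -> int:
        return len(self.tips)

    def points(self) -> np.ndarray:
        return np.array([t.point for t in self.tips], dtype=float).reshape(-1, 3)

    def groups(self) -> list[str]:
        return [t.group for t in self.tips]


def _parse_swc_line(raw: str, lineno: int) -> SWCNode:
    parts = raw.split()
    if len(parts) != 7:
        raise SWCParseError(
            f"expected 7 whitespace-delimited fields, got {len(parts)}", lineno
        )
    try:
        return SWCNode(
            node_id=int(parts[0]),
            type_code=int(parts[1]),
            x=float(parts[2]),
            y=float(parts[3]),
            z=float(parts[4]),
            radius=float(parts[5]),
            parent_id=int(parts[6]),
        )
    except ValueError as exc:
        raise SWCParseError(str(exc), lineno) from exc


def read_swc(path: str | Path, group: str | None = None,
             reaches_skin: bool = False, name: str | None = None) -> NeuriteTrace:
    """Read one SWC file into a validated :class:`NeuriteTrace`.

    Both space- and tab-delimited files are accepted; ``#`` comment lines and
    blank lines are ignored; node ids need not be consecutive and children
    may precede their parents (the tree is validated after a full pass).

    Raises
    ------
    SWCParseError
        On a malformed line (reports the 1-based line number).
    SWCStructureError
        On duplicate ids, dangling parents, multiple roots or cycles.
    """
    path = Path(path)
    nodes: list[SWCNode] = []
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            stripped = raw.strip()
            if not stripped or stripped.startswith("#"):
                continue
            nodes.append(_parse_swc_line(stripped, lineno))
    if not nodes:
        raise SWCParseError("file contains no data lines", None)
    return NeuriteTrace(
        name=name if name is not None else path.stem,
        nodes=nodes,
        group=group if group is not None else "untagged",
        reaches_skin=reaches_skin,
    )


def write_swc(trace: NeuriteTrace, path: str | Path) -> None:
    """Write a trace as standard 7-column SWC; inverse of :func:`read_swc`.

    Coordinates are emitted with ``repr`` precision so a round trip preserves
    them bit-for-bit.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# SWC export of trace {trace.name}\n")
        fh.write("# id type x y z radius parent\n")
        for n in trace.nodes:
            fh.write(
                f"{n.node_id} {n.type_code} {n.x!r} {n.y!r} {n.z!r} "
                f"{n.radius!r} {n.parent_id}\n"
            )


def read_label_sidecar(path: str | Path) -> dict[str, tuple[str, bool]]:
    """Read a ``trace,group,reaches_skin`` CSV into ``{name: (group, flag)}``."""
    out: dict[str, tuple[str, bool]] = {}
    with Path(path).open(newline="") as fh:
        for row in csv.DictReader(fh):
            flag = str(row.get("reaches_skin", "")).strip().lower() in (
                "1", "true", "yes",
            )
            out[row["trace"].strip()] = (row["group"].strip(), flag)
    return out


def read_traces(paths: Iterable[str | Path],
                labels: dict[str, tuple[str, bool]] | None = None,
                **traceset_kwargs) -> TraceSet:
    """Read several SWC files, applying sidecar labels by trace name."""
    traces = []
    for p in paths:
        t = read_swc(p)
        if labels and t.name in labels:
            t.group, t.reaches_skin = labels[t.name]
        traces.append(t)
    return TraceSet(traces, **traceset_kwargs)


def path_length(trace: NeuriteTrace) -> float:
    """Total cable length: sum of Euclidean parent–child edge lengths (μm)."""
    e = trace.edges()
    if e.size == 0:
        return 0.0
    return float(np.linalg.norm(e[:, 1] - e[:, 0], axis=1).sum())


def extract_tips(traces: TraceSet | Iterable[NeuriteTrace],
                 projection_axis: str | None = None) -> TipSet:
    """Collect the termination points (leaf nodes) of every trace.

    Each tip carries its trace's group label.  For a trace with at least two
    nodes a root that happens to be childless is not a tip; a root-only trace
    contributes no tips.  An empty input yields an empty :class:`TipSet`.
    """
    if isinstance(traces, TraceSet):
        axis = traces.axis_convention.get("proximal_distal", "z")
        iterable = traces.traces
    else:
        axis = "z"
        iterable = list(traces)
    if projection_axis is not None:
        axis = projection_axis
    tips: list[Tip] = []
    for t in iterable:
        if len(t.nodes) < 2:
            continue
        root_id = t.root.node_id
        for n in t.leaf_nodes():
            if n.node_id == root_id:
                continue
            tips.append(Tip((n.x, n.y, n.z), t.group, t.name))
    return TipSet(tips, projection_axis=axis)


def validate_swc(path: str | Path) -> dict:
    """Diagnostics for one SWC file: node/tip counts, length, or the error."""
    try:
        trace = read_swc(path)
    except (SWCParseError, SWCStructureError) as exc:
        return {"path": str(path), "valid": False, "error": str(exc)}
    return {
        "path": str(path),
        "valid": True,
        "n_nodes": len(trace.nodes),
        "n_tips": len([n for n in trace.leaf_nodes()
                       if n.node_id != trace.root.node_id or len(trace.nodes) == 1]),
        "path_length_um": path_length(trace),
        "root_id": trace.root.node_id,
    }
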