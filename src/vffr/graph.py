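"""Coronary vessel graphs: data model, validation, stenosis editing, vein pruning, JSON I/O.

A :class:`VesselGraph` is a set of directed segments between nodes. Flow
direction is encoded by edge orientation, from ostium outward; after vein
pruning every connected component must be a directed tree rooted at one
ostium. Lengths and diameters are in millimetres, wall characteristic speed
in m/s.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "VesselNode",
    "VesselSegment",
    "StenosisSpec",
    "VesselGraph",
    "ValidationReport",
    "GraphError",
    "GraphSchemaError",
    "UnknownSegmentError",
    "InvalidStenosisError",
    "VeinPruneError",
    "validate_graph",
    "apply_stenosis",
    "prune_nonarterial",
    "read_graph",
    "write_graph",
]

SCHEMA_VERSION = 1
NODE_KINDS = frozenset({"ostium", "junction", "terminal", "internal"})
SEGMENT_LABELS = frozenset({"aorta", "artery", "vein"})


class GraphError(ValueError):
    """Base class for vessel-graph errors."""


class GraphSchemaError(GraphError):
    """Malformed or incompatible graph file."""


class UnknownSegmentError(GraphError):
    """Referenced segment id does not exist."""


class InvalidStenosisError(GraphError):
    """Stenosis parameters outside their admissible range."""


class VeinPruneError(GraphError):
    """Vein pruning would disconnect an FFR site from every ostium."""


@dataclass(frozen=True)
class VesselNode:
    """A graph node: ostium (tree root), junction, terminal leaf or internal point."""

    id: str
    kind: str
    position: tuple[float, float, float]  # mm, world coordinates

    def __post_init__(self) -> None:
        if self.kind not in NODE_KINDS:
            raise GraphError(f"unknown node kind {self.kind!r}")
        object.__setattr__(self, "position", tuple(float(c) for c in self.position))


@dataclass(frozen=True)
class VesselSegment:
    """A directed vessel segment carrying geometry and wall properties.

    ``effective_diameter < reference_diameter`` exactly on stenosed edges;
    ``ffr_site`` marks edges at which virtual FFR is sampled.
    """

    id: str
    from_node: str
    to_node: str
    length: float  # mm
    reference_diameter: float  # mm
    effective_diameter: float  # mm
    wall_speed_c0: float  # m/s
    label: str = "artery"
    ffr_site: bool = False

    def __post_init__(self) -> None:
        if self.label not in SEGMENT_LABELS:
            raise GraphError(f"unknown segment label {self.label!r}")

    @property
    def is_stenosed(self) -> bool:
        return self.effective_diameter < self.reference_diameter


@dataclass(frozen=True)
class StenosisSpec:
    """Focal narrowing: fractional diameter reduction over a fraction of a segment."""

    segment_id: str
    diameter_reduction: float  # fraction of diameter removed, in (0, 1)
    extent_fraction: float = 1.0  # fraction of segment length affected, in (0, 1]


@dataclass
class ValidationReport:
    ok: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


@dataclass
class VesselGraph:
    """Directed vessel graph with named ostium roots."""

    nodes: dict[str, VesselNode]
    segments: dict[str, VesselSegment]
    ostia: list[str]

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_lists(
        cls,
        nodes: Iterable[VesselNode],
        segments: Iterable[VesselSegment],
        ostia: Iterable[str],
    ) -> "VesselGraph":
        node_map: dict[str, VesselNode] = {}
        for n in nodes:
            if n.id in node_map:
                raise GraphSchemaError(f"duplicate node id {n.id!r}")
            node_map[n.id] = n
        seg_map: dict[str, VesselSegment] = {}
        for s in segments:
            if s.id in seg_map:
                raise GraphSchemaError(f"duplicate segment id {s.id!r}")
            seg_map[s.id] = s
        return cls(nodes=node_map, segments=seg_map, ostia=list(ostia))

    def copy(self) -> "VesselGraph":
        return VesselGraph(dict(self.nodes), dict(self.segments), list(self.ostia))

    # -- topology queries -----------------------------------------------------

    def out_segments(self, node_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.from_node == node_id]

    def in_segments(self, node_id: str) -> list[VesselSegment]:
        return [s for s in self.segments.values() if s.to_node == node_id]

    def adjacency(self) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
        """(outgoing, incoming) maps node id -> list of segment ids, sorted."""
        out: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        inc: dict[str, list[str]] = {nid: [] for nid in self.nodes}
        for sid in sorted(self.segments):
            s = self.segments[sid]
            if s.from_node in out:
                out[s.from_node].append(sid)
            if s.to_node in inc:
                inc[s.to_node].append(sid)
        return out, inc

    def total_length(self) -> float:
        return sum(s.length for s in self.segments.values())

    def ffr_sites(self) -> list[str]:
        return sorted(sid for sid, s in self.segments.items() if s.ffr_site)

    def reachable_from_ostia(self) -> set[str]:
        """Segment ids reachable by directed traversal from any listed ostium."""
        out, _ = self.adjacency()
        seen_nodes: set[str] = set()
        seen_segs: set[str] = set()
        stack = [o for o in self.ostia if o in self.nodes]
        while stack:
            nid = stack.pop()
            if nid in seen_nodes:
                continue
            seen_nodes.add(nid)
            for sid in out.get(nid, []):
                if sid not in seen_segs:
                    seen_segs.add(sid)
                    stack.append(self.segments[sid].to_node)
        return seen_segs


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def _components(graph: VesselGraph) -> list[set[str]]:
    """Weakly connected components as sets of node ids (isolated nodes included)."""
    parent = {nid: nid for nid in graph.nodes}

    def find(a: str) -> str:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for s in graph.segments.values():
        if s.from_node in parent and s.to_node in parent:
            ra, rb = find(s.from_node), find(s.to_node)
            if ra != rb:
                parent[ra] = rb
    comps: dict[str, set[str]] = {}
    for nid in graph.nodes:
        comps.setdefault(find(nid), set()).add(nid)
    return list(comps.values())


def _has_cycle(graph: VesselGraph, segment_ids: Iterable[str]) -> bool:
    out: dict[str, list[str]] = {}
    for sid in segment_ids:
        s = graph.segments[sid]
        out.setdefault(s.from_node, []).append(s.to_node)
    WHITE, GRAY, BLACK = 0, 1, 2
    color: dict[str, int] = {}

    for start in out:
        if color.get(start, WHITE) != WHITE:
            continue
        stack: list[tuple[str, int]] = [(start, 0)]
        color[start] = GRAY
        while stack:
            node, idx = stack[-1]
            nbrs = out.get(node, [])
            if idx < len(nbrs):
                stack[-1] = (node, idx + 1)
                nxt = nbrs[idx]
                c = color.get(nxt, WHITE)
                if c == GRAY:
                    return True
                if c == WHITE:
                    color[nxt] = GRAY
                    stack.append((nxt, 0))
            else:
                color[node] = BLACK
                stack.pop()
    return False


def validate_graph(graph: VesselGraph, *, arterial_only: bool = False) -> ValidationReport:
    """Check structural and tree invariants; returns a report, never raises.

    With ``arterial_only`` the cycle/rooting checks are restricted to
    non-vein segments (vein-contaminated graphs are allowed to fail them
    until :func:`prune_nonarterial` has run).
    """
    v: list[str] = []
    seg_ids = [
        sid
        for sid, s in graph.segments.items()
        if not (arterial_only and s.label == "vein")
    ]

    for sid, s in graph.segments.items():
        if s.from_node not in graph.nodes or s.to_node not in graph.nodes:
            v.append(f"unknown endpoint on segment {sid}")
        if not s.length > 0:
            v.append(f"nonpositive length on segment {sid}")
        if not s.reference_diameter > 0 or not s.effective_diameter > 0:
            v.append(f"nonpositive diameter on segment {sid}")
        elif s.effective_diameter > s.reference_diameter + 1e-12:
            v.append(f"effective diameter exceeds reference on segment {sid}")
        if not s.wall_speed_c0 > 0:
            v.append(f"nonpositive wall speed on segment {sid}")

    if any("unknown endpoint" in msg for msg in v):
        return ValidationReport(False, v)

    out, inc = graph.adjacency()
    for nid, node in graph.nodes.items():
        if node.kind == "ostium" and inc[nid]:
            v.append(f"ostium {nid} has incoming segment")
        if node.kind == "terminal" and out[nid]:
            v.append(f"terminal {nid} has outgoing segment")
    for oid in graph.ostia:
        if oid not in graph.nodes:
            v.append(f"listed ostium {oid} not in graph")

    if _has_cycle(graph, seg_ids):
        v.append("cycle detected")
    else:
        # rooting: each component with segments must contain exactly one
        # in-degree-0 node, and it must be a listed ostium
        sub_nodes = set()
        indeg: dict[str, int] = {}
        for sid in seg_ids:
            s = graph.segments[sid]
            sub_nodes.update((s.from_node, s.to_node))
            indeg[s.to_node] = indeg.get(s.to_node, 0) + 1
            indeg.setdefault(s.from_node, indeg.get(s.from_node, 0))
        sub = VesselGraph(
            {nid: graph.nodes[nid] for nid in sub_nodes},
            {sid: graph.segments[sid] for sid in seg_ids},
            [o for o in graph.ostia if o in sub_nodes],
        )
        for comp in _components(sub):
            roots = [nid for nid in comp if indeg.get(nid, 0) == 0]
            if len(roots) > 1:
                v.append(f"multiple roots in component: {sorted(roots)}")
            elif not roots:
                v.append("component without root")
            elif roots[0] not in graph.ostia:
                v.append(f"component rooted at non-ostium node {roots[0]}")

    orphan = {nid for nid in graph.nodes if not out[nid] and not inc[nid]}
    for nid in sorted(orphan):
        if graph.nodes[nid].kind != "ostium" or nid not in graph.ostia:
            v.append(f"orphan node {nid}")

    return ValidationReport(not v, v)


# ---------------------------------------------------------------------------
# stenosis editing
# ---------------------------------------------------------------------------


def _lerp(a: tuple[float, ...], b: tuple[float, ...], t: float) -> tuple[float, ...]:
    return tuple(ai + t * (bi - ai) for ai, bi in zip(a, b))


def apply_stenosis(graph: VesselGraph, spec: StenosisSpec) -> VesselGraph:
    """Narrow a segment, splitting it so the stenotic extent is its own edge.

    The stenotic sub-edge gets ``effective_diameter = reference × (1 − reduction)``
    and is marked as an FFR site; proximal/distal remainders keep the
    reference diameter. Total length is conserved exactly.
    """
    if spec.segment_id not in graph.segments:
        raise UnknownSegmentError(f"unknown segment id {spec.segment_id!r}")
    if not 0.0 < spec.diameter_reduction < 1.0:
        raise InvalidStenosisError(
            f"diameter_reduction must be in (0, 1), got {spec.diameter_reduction}"
        )
    if not 0.0 < spec.extent_fraction <= 1.0:
        raise InvalidStenosisError(
            f"extent_fraction must be in (0, 1], got {spec.extent_fraction}"
        )

    g = graph.copy()
    seg = g.segments[spec.segment_id]
    narrowed = seg.reference_diameter * (1.0 - spec.diameter_reduction)

    if spec.extent_fraction >= 1.0:
        g.segments[seg.id] = replace(seg, effective_diameter=narrowed, ffr_site=True)
        return g

    e = spec.extent_fraction
    l_side = seg.length * (1.0 - e) / 2.0
    l_sten = seg.length - 2.0 * l_side  # exact complement: conserves total length
    p0 = g.nodes[seg.from_node].position
    p1 = g.nodes[seg.to_node].position
    n0 = VesselNode(f"{seg.id}__s0", "internal", _lerp(p0, p1, (1 - e) / 2))
    n1 = VesselNode(f"{seg.id}__s1", "internal", _lerp(p0, p1, (1 + e) / 2))
    if n0.id in g.nodes or n1.id in g.nodes:
        raise GraphError(f"segment {seg.id} already split")
    g.nodes[n0.id] = n0
    g.nodes[n1.id] = n1
    del g.segments[seg.id]
    g.segments[f"{seg.id}__prox"] = replace(
        seg, id=f"{seg.id}__prox", to_node=n0.id, length=l_side, ffr_site=False
    )
    g.segments[f"{seg.id}__sten"] = replace(
        seg,
        id=f"{seg.id}__sten",
        from_node=n0.id,
        to_node=n1.id,
        length=l_sten,
        effective_diameter=narrowed,
        ffr_site=True,
    )
    g.segments[f"{seg.id}__dist"] = replace(
        seg, id=f"{seg.id}__dist", from_node=n1.id, length=l_side, ffr_site=False
    )
    return g


# ---------------------------------------------------------------------------
# vein pruning
# ---------------------------------------------------------------------------


def prune_nonarterial(graph: VesselGraph) -> VesselGraph:
    """Remove every vein-labeled segment (and nodes left isolated by that).

    Raises :class:`VeinPruneError` if an FFR site would lose its only path
    from an ostium.
    """
    g = graph.copy()
    vein_ids = [sid for sid, s in g.segments.items() if s.label == "vein"]
    for sid in vein_ids:
        del g.segments[sid]

    used = set()
    for s in g.segments.values():
        used.update((s.from_node, s.to_node))
    for nid in [n for n in g.nodes if n not in used]:
        if nid not in g.ostia:
            del g.nodes[nid]

    reachable = g.reachable_from_ostia()
    for sid in g.ffr_sites():
        if sid not in reachable:
            raise VeinPruneError(
                f"pruning veins disconnects FFR site {sid!r} from every ostium"
            )
    return g


# ---------------------------------------------------------------------------
# JSON I/O (schema v1)
# ---------------------------------------------------------------------------

_REQUIRED_SEGMENT_FIELDS = (
    "id",
    "from",
    "to",
    "length_mm",
    "reference_diameter_mm",
    "effective_diameter_mm",
    "wall_speed_m_s",
)


def graph_to_dict(graph: VesselGraph) -> dict:
    return {
        "schema_version": SCHEMA_VERSION,
        "nodes": [
            {"id": n.id, "kind": n.kind, "position_mm": list(n.position)}
            for n in (graph.nodes[k] for k in sorted(graph.nodes))
        ],
        "segments": [
            {
                "id": s.id,
                "from": s.from_node,
                "to": s.to_node,
                "length_mm": s.length,
                "reference_diameter_mm": s.reference_diameter,
                "effective_diameter_mm": s.effective_diameter,
                "wall_speed_m_s": s.wall_speed_c0,
                "label": s.label,
                "ffr_site": s.ffr_site,
            }
            for s in (graph.segments[k] for k in sorted(graph.segments))
        ],
        "ostia": list(graph.ostia),
    }


def graph_from_dict(data: Mapping) -> VesselGraph:
    if not isinstance(data, Mapping):
        raise GraphSchemaError("graph document must be a JSON object")
    version = data.get("schema_version")
    if version != SCHEMA_VERSION:
        raise GraphSchemaError(
            f"unsupported schema_version {version!r}; expected {SCHEMA_VERSION}"
        )
    try:
        nodes = [
            VesselNode(str(n["id"]), str(n["kind"]), tuple(n["position_mm"]))
            for n in data["nodes"]
        ]
    except (KeyError, TypeError) as exc:
        raise GraphSchemaError(f"malformed node entry: {exc}") from exc
    segments = []
    for rec in data["segments"]:
        missing = [f for f in _REQUIRED_SEGMENT_FIELDS if f not in rec]
        if missing:
            raise GraphSchemaError(
                f"segment entry missing required field(s) {missing}"
            )
        segments.append(
            VesselSegment(
                id=str(rec["id"]),
                from_node=str(rec["from"]),
                to_node=str(rec["to"]),
                length=float(rec["length_mm"]),
                reference_diameter=float(rec["reference_diameter_mm"]),
                effective_diameter=float(rec["effective_diameter_mm"]),
                wall_speed_c0=float(rec["wall_speed_m_s"]),
                label=str(rec.get("label", "artery")),
                ffr_site=bool(rec.get("ffr_site", False)),
            )
        )
    graph = VesselGraph.from_lists(nodes, segments, [str(o) for o in data["ostia"]])
    report = validate_graph(graph, arterial_only=True)
    if not report.ok:
        raise GraphSchemaError("graph violates invariants: " + "; ".join(report.violations))
    return graph


def read_graph(path: str | Path) -> VesselGraph:
    with open(path, "r", encoding="utf-8") as fh:
        try:
            data = json.load(fh)
        except json.JSONDecodeError as exc:
            raise GraphSchemaError(f"not valid JSON: {exc}") from exc
    return graph_from_dict(data)


def write_graph(graph: VesselGraph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(graph_to_dict(graph), fh, indent=1)
        fh.write("\n")
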