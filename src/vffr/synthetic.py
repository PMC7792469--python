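"""Synthetic inputs: coronary trees, voxel phantoms and paired-FFR cohorts.

Every generator is a pure function of (spec, seed): same seed, same output.
Trees follow Murray's law at bifurcations (parent^3 = sum child^3) with a
randomized flow split; phantoms rasterize the tree as capsules on a
configurable voxel grid, optionally adding a vein tube and calcification
blobs; cohorts run the modelling pipeline per patient and synthesize
"invasive" references by perturbing the virtual values with a bias, a
per-patient offset and per-vessel noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .diagnostics import PairedFfr
from .graph import (
    StenosisSpec,
    VesselGraph,
    VesselNode,
    VesselSegment,
    apply_stenosis,
    validate_graph,
)
from .imaging import ImagingError, VoxelVolume
from .personalize import CalibrationConfig, FfrResult, PatientRecord, evaluate_ffr

__all__ = [
    "TreeSpec",
    "PhantomSpec",
    "PhantomResult",
    "CohortSpec",
    "SyntheticError",
    "make_coronary_tree",
    "make_voxel_phantom",
    "sample_patient_record",
    "make_cohort",
]


class SyntheticError(ValueError):
    pass


# ---------------------------------------------------------------------------
# coronary trees
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeSpec:
    n_generations: int = 3
    root_diameter_mm: float = 4.0
    min_diameter_mm: float = 2.2
    murray_exponent: float = 3.0
    wall_speed_m_s: float = 12.0
    segment_length_range_mm: tuple[float, float] = (22.0, 32.0)
    branch_angle_range_deg: tuple[float, float] = (22.0, 38.0)
    flow_split_range: tuple[float, float] = (0.38, 0.62)
    clearance_mm: float = 2.0  # min surface gap between non-adjacent branches


def _rotate(v: np.ndarray, axis: np.ndarray, angle: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    return (
        v * math.cos(angle)
        + np.cross(axis, v) * math.sin(angle)
        + axis * float(np.dot(axis, v)) * (1 - math.cos(angle))
    )


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(v[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, ref)
    return p / np.linalg.norm(p)


def _segment_distance(p1, q1, p2, q2) -> float:
    """Minimum distance between 3D segments [p1,q1] and [p2,q2]."""
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = float(np.dot(d1, d1))
    e = float(np.dot(d2, d2))
    f = float(np.dot(d2, r))
    c = float(np.dot(d1, r))
    b = float(np.dot(d1, d2))
    denom = a * e - b * b
    s = np.clip((b * f - c * e) / denom, 0.0, 1.0) if denom > 1e-12 else 0.0
    t = (b * s + f) / e if e > 1e-12 else 0.0
    if t < 0.0:
        t = 0.0
        s = np.clip(-c / a, 0.0, 1.0) if a > 1e-12 else 0.0
    elif t > 1.0:
        t = 1.0
        s = np.clip((b - c) / a, 0.0, 1.0) if a > 1e-12 else 0.0
    return float(np.linalg.norm((p1 + s * d1) - (p2 + t * d2)))


def make_coronary_tree(
    seed: int, n_generations: int = 3, spec: TreeSpec | None = None
) -> VesselGraph:
    """Deterministic binary coronary tree obeying Murray's law.

    Branches terminate when either the generation budget is exhausted or a
    child diameter would fall below the modelled minimum (2 mm). Candidate
    branch directions that would bring non-adjacent segments closer than the
    configured clearance are resampled (deterministically).
    """
    spec = spec or TreeSpec(n_generations=n_generations)
    if n_generations < 1:
        raise SyntheticError("n_generations must be >= 1")
    if spec.root_diameter_mm < spec.min_diameter_mm:
        raise SyntheticError(
            f"root diameter {spec.root_diameter_mm} mm below the "
            f"{spec.min_diameter_mm} mm minimum"
        )
    rng = np.random.default_rng(seed)

    nodes: list[VesselNode] = []
    segments: list[VesselSegment] = []
    placed: list[tuple[np.ndarray, np.ndarray, float, int]] = []  # p, q, radius, parent_seg_idx
    counter = {"n": 0, "s": 0}

    def new_node(kind: str, pos: np.ndarray) -> str:
        nid = f"n{counter['n']}"
        counter["n"] += 1
        nodes.append(VesselNode(nid, kind, tuple(pos)))
        return nid

    def add_segment(frm: str, to: str, length: float, dia: float) -> int:
        sid = f"s{counter['s']}"
        counter["s"] += 1
        segments.append(
            VesselSegment(sid, frm, to, length, dia, dia, spec.wall_speed_m_s)
        )
        return len(segments) - 1

    def collides(p: np.ndarray, q: np.ndarray, radius: float, parent_idx: int) -> bool:
        for idx, (pp, qq, rr, pidx) in enumerate(placed):
            if idx == parent_idx or pidx == parent_idx:
                continue  # the parent itself and siblings share a node
            d = _segment_distance(p, q, pp, qq)
            if d < radius + rr + spec.clearance_mm:
                return True
        return False

    root_dir = np.array([0.15, 0.25, 0.95])
    root_dir /= np.linalg.norm(root_dir)
    root_pos = np.zeros(3)
    root_id = new_node("ostium", root_pos)

    def grow(
        from_id: str,
        pos: np.ndarray,
        direction: np.ndarray,
        diameter: float,
        depth: int,
        parent_idx: int,
    ) -> None:
        length = rng.uniform(*spec.segment_length_range_mm) * (
            0.75 + 0.25 * diameter / spec.root_diameter_mm
        )
        end = pos + direction * length
        radius = diameter / 2.0
        for _ in range(24):
            if not collides(pos, end, radius, parent_idx):
                break
            ang = math.radians(rng.uniform(10.0, 25.0))
            direction = _rotate(direction, _rotate(_perp(direction), direction, rng.uniform(0, 2 * math.pi)), ang)
            direction /= np.linalg.norm(direction)
            end = pos + direction * length
        seg_idx = None
        q_split = rng.uniform(*spec.flow_split_range)
        exp = spec.murray_exponent
        d1 = diameter * q_split ** (1.0 / exp)
        d2 = diameter * (1.0 - q_split) ** (1.0 / exp)
        terminal = depth >= spec.n_generations or min(d1, d2) < spec.min_diameter_mm

        kind = "terminal" if terminal else "junction"
        end_id = new_node(kind, end)
        seg_idx = add_segment(from_id, end_id, length, diameter)
        placed.append((pos.copy(), end.copy(), radius, parent_idx))
        if terminal:
            return
        normal = _perp(direction)
        azimuth = rng.uniform(0.0, 2.0 * math.pi)
        plane_normal = _rotate(normal, direction, azimuth)
        a1 = math.radians(rng.uniform(*spec.branch_angle_range_deg))
        a2 = -math.radians(rng.uniform(*spec.branch_angle_range_deg))
        for dia, ang in ((d1, a1), (d2, a2)):
            child_dir = _rotate(direction, plane_normal, ang)
            child_dir /= np.linalg.norm(child_dir)
            grow(end_id, end, child_dir, dia, depth + 1, seg_idx)

    spec = replace(spec, n_generations=n_generations)
    grow(root_id, root_pos, root_dir, spec.root_diameter_mm, 1, -1)

    graph = VesselGraph.from_lists(nodes, segments, [root_id])
    report = validate_graph(graph)
    if not report.ok:  # pragma: no cover - construction guarantees validity
        raise SyntheticError("generated tree invalid: " + "; ".join(report.violations))
    return graph


# ---------------------------------------------------------------------------
# voxel phantoms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    spacing_mm: float = 0.5  # isotropic
    lumen_intensity: float = 400.0
    background_intensity: float = 0.0
    noise_sd: float = 0.0
    with_aorta: bool = True
    aorta_diameter_mm: float = 20.0
    vein: bool = False
    vein_touching: bool = False
    vein_diameter_mm: float = 3.0
    calcification: bool = False
    calcification_intensity: float = 900.0
    margin_mm: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_intensity <= self.background_intensity:
            raise SyntheticError("lumen intensity must exceed background")
        if self.spacing_mm <= 0:
            raise SyntheticError("spacing must be positive")


@dataclass
class PhantomResult:
    volume: VoxelVolume
    truth: VesselGraph  # includes vein-labeled edges when flagged
    seeds: list[tuple[int, int, int]]  # segmentation seeds (voxel indices)
    aorta_axis: tuple[np.ndarray, np.ndarray] | None


def _paint_capsule(
    data: np.ndarray,
    origin: np.ndarray,
    spacing: float,
    p: np.ndarray,
    q: np.ndarray,
    radius: float,
    value: float,
) -> None:
    lo = np.minimum(p, q) - radius - spacing
    hi = np.maximum(p, q) + radius + spacing
    i0 = np.maximum(np.floor((lo - origin) / spacing).astype(int), 0)
    i1 = np.minimum(np.ceil((hi - origin) / spacing).astype(int) + 1, data.shape)
    if np.any(i0 >= i1):
        return
    zz, yy, xx = np.meshgrid(
        *[np.arange(i0[k], i1[k]) for k in range(3)], indexing="ij"
    )
    pts = origin + np.stack([zz, yy, xx], axis=-1) * spacing
    d = q - p
    ll = float(np.dot(d, d))
    if ll < 1e-12:
        dist = np.linalg.norm(pts - p, axis=-1)
    else:
        t = np.clip(np.einsum("...k,k->...", pts - p, d) / ll, 0.0, 1.0)
        proj = p + t[..., None] * d
        dist = np.linalg.norm(pts - proj, axis=-1)
    sub = data[i0[0] : i1[0], i0[1] : i1[1], i0[2] : i1[2]]
    sub[dist <= radius] = value


def make_voxel_phantom(
    graph: VesselGraph, spec: PhantomSpec | None = None
) -> PhantomResult:
    """Rasterize a vessel graph into a contrast-CT-like voxel phantom.

    Lumen voxels are those within the segment radius of the centerline
    (effective diameter, i.e. the stenosed lumen). An aorta tube is placed
    tangent to the tree root so ostium detection has a contact surface.
    """
    spec = spec or PhantomSpec()
    h = spec.spacing_mm
    min_dia = min(s.effective_diameter for s in graph.segments.values())
    if min_dia / h < 2.0:
        raise SyntheticError(
            f"spacing {h} mm too coarse for thinnest segment ({min_dia:.2f} mm across)"
        )
    rng = np.random.default_rng(spec.seed)

    pos = {nid: np.asarray(n.position, float) for nid, n in graph.nodes.items()}
    pts = np.array(list(pos.values()))
    max_r = max(s.effective_diameter for s in graph.segments.values()) / 2.0
    lo = pts.min(axis=0) - (max_r + spec.margin_mm)
    hi = pts.max(axis=0) + (max_r + spec.margin_mm)

    truth = graph.copy()
    aorta_axis = None
    extra_capsules: list[tuple[np.ndarray, np.ndarray, float, float]] = []

    if spec.with_aorta:
        root = graph.ostia[0]
        out_segs = graph.out_segments(root)
        d0 = pos[out_segs[0].to_node] - pos[root]
        d0 = d0 / np.linalg.norm(d0)
        r_a = spec.aorta_diameter_mm / 2.0
        center = pos[root] - d0 * (r_a - 0.25)  # slight overlap; contact via dilation
        axis = _perp(d0)
        half = 14.0
        pa, qa = center - axis * half, center + axis * half
        extra_capsules.append((pa, qa, r_a, spec.lumen_intensity))
        aorta_axis = (pa, qa)
        lo = np.minimum(lo, np.minimum(pa, qa) - r_a - spec.margin_mm)
        hi = np.maximum(hi, np.maximum(pa, qa) + r_a + spec.margin_mm)

    if spec.vein:
        segs = sorted(graph.segments.values(), key=lambda s: s.id)
        midpoints = [0.5 * (pos[s.from_node] + pos[s.to_node]) for s in segs]
        i, j = 0, len(midpoints) - 1
        pv = midpoints[i]
        qv = midpoints[j]
        if not spec.vein_touching:
            # search deterministically for an offset that clears every artery
            # segment and the aorta
            direction = midpoints[j] - midpoints[i]
            n0 = _perp(direction / max(np.linalg.norm(direction), 1e-9))
            r_v = spec.vein_diameter_mm / 2.0
            clearance = r_v + max_r + 1.5
            placed = None
            for k in range(24):
                mag = max_r + r_v + 2.5 + 1.5 * (k // 4)
                ang = (k % 4) * math.pi / 2.0
                n = _rotate(n0, direction / np.linalg.norm(direction), ang)
                cand_p = midpoints[i] + n * mag
                cand_q = midpoints[j] + n * mag
                ok = all(
                    _segment_distance(cand_p, cand_q, pos[sg.from_node], pos[sg.to_node])
                    >= clearance
                    for sg in segs
                )
                if ok and spec.with_aorta and aorta_axis is not None:
                    ok = (
                        _segment_distance(cand_p, cand_q, aorta_axis[0], aorta_axis[1])
                        >= r_v + spec.aorta_diameter_mm / 2.0 + 1.5
                    )
                if ok:
                    placed = (cand_p, cand_q)
                    break
            if placed is None:
                raise SyntheticError("could not place a non-touching vein tube")
            pv, qv = placed
        extra_capsules.append((pv, qv, spec.vein_diameter_mm / 2.0, spec.lumen_intensity))
        v0 = VesselNode("vein_n0", "internal", tuple(pv))
        v1 = VesselNode("vein_n1", "internal", tuple(qv))
        truth.nodes[v0.id] = v0
        truth.nodes[v1.id] = v1
        truth.segments["vein_s0"] = VesselSegment(
            "vein_s0",
            v0.id,
            v1.id,
            float(np.linalg.norm(qv - pv)),
            spec.vein_diameter_mm,
            spec.vein_diameter_mm,
            2.0,
            label="vein",
        )
        lo = np.minimum(lo, np.minimum(pv, qv) - spec.vein_diameter_mm - spec.margin_mm)
        hi = np.maximum(hi, np.maximum(pv, qv) + spec.vein_diameter_mm + spec.margin_mm)

    shape = tuple(int(math.ceil((hi[k] - lo[k]) / h)) + 1 for k in range(3))
    data = np.full(shape, spec.background_intensity, dtype=np.float64)
    origin = lo

    for s in sorted(graph.segments.values(), key=lambda s: s.id):
        _paint_capsule(
            data, origin, h, pos[s.from_node], pos[s.to_node], s.effective_diameter / 2.0,
            spec.lumen_intensity,
        )
    for pa, qa, r, val in extra_capsules:
        _paint_capsule(data, origin, h, pa, qa, r, val)

    if spec.calcification:
        segs = sorted(graph.segments.values(), key=lambda s: s.id)
        for _ in range(rng.integers(1, 4)):
            s = segs[int(rng.integers(len(segs)))]
            t = rng.uniform(0.3, 0.7)
            center_line = pos[s.from_node] + t * (pos[s.to_node] - pos[s.from_node])
            direction = pos[s.to_node] - pos[s.from_node]
            n = _rotate(_perp(direction / np.linalg.norm(direction)), direction, rng.uniform(0, 2 * math.pi))
            blob_r = rng.uniform(0.8, 1.2)
            c = center_line + n * (s.effective_diameter / 2.0 + 0.6 * blob_r)
            _paint_capsule(data, origin, h, c, c, blob_r, spec.calcification_intensity)

    if spec.noise_sd > 0:
        data = data + rng.normal(0.0, spec.noise_sd, size=data.shape)

    volume = VoxelVolume(data, (h, h, h), tuple(origin))

    seeds = []
    root = graph.ostia[0]
    first = sorted(graph.out_segments(root), key=lambda s: s.id)[0]
    probe = 0.5 * (pos[root] + pos[first.to_node])
    seeds.append(tuple(int(round(c)) for c in (probe - origin) / h))
    if spec.with_aorta and aorta_axis is not None:
        mid = 0.5 * (aorta_axis[0] + aorta_axis[1])
        seeds.append(tuple(int(round(c)) for c in (mid - origin) / h))

    return PhantomResult(volume=volume, truth=truth, seeds=seeds, aorta_axis=aorta_axis)


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 31
    seed: int = 0
    vessels_per_patient: tuple[float, float, float] = (0.55, 0.30, 0.15)  # P(1),P(2),P(3)
    severity_range: tuple[float, float] = (0.45, 0.75)  # diameter stenosis
    extent_range: tuple[float, float] = (0.25, 0.55)  # fraction of host segment
    bias: float = 0.0  # mean of (virtual - invasive)
    sd_patient: float = 0.0  # per-patient offset SD
    sd_vessel: float = 0.0  # per-vessel residual SD
    invasive_clip: tuple[float, float] = (0.05, 1.0)
    n_generations: int = 3
    mode: str = "steady"  # solver mode for the virtual values

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise SyntheticError("n_patients must be >= 1")
        if min(self.sd_patient, self.sd_vessel) < 0:
            raise SyntheticError("noise SDs must be non-negative")
        if abs(sum(self.vessels_per_patient) - 1.0) > 1e-9:
            raise SyntheticError("vessels_per_patient must sum to 1")


def sample_patient_record(rng: np.random.Generator, patient_id: str) -> PatientRecord:
    """Plausible record fields spanning the calibration age brackets."""
    height = float(rng.normal(170.7, 8.0))
    weight = float(rng.normal(81.6, 10.0))
    return PatientRecord(
        id=patient_id,
        age=float(rng.uniform(42.0, 80.0)),
        sex="m" if rng.random() < 0.71 else "f",
        height_cm=height,
        weight_kg=weight,
        sbp=float(np.clip(rng.normal(133.4, 9.0), 100, 180)),
        dbp=float(np.clip(rng.normal(84.0, 5.0), 55, 100)),
        hr=float(np.clip(rng.normal(65.2, 5.0), 45, 100)),
        smoking=bool(rng.random() < 0.28),
    )


def make_cohort(
    spec: CohortSpec,
    runner: Callable[[VesselGraph, PatientRecord, dict], FfrResult] | None = None,
    calibration: CalibrationConfig | None = None,
) -> PairedFfr:
    """Simulated paired virtual/invasive cohort.

    Per patient: a seeded tree, 1-3 lesioned vessels with diameter stenoses
    sampled from ``severity_range``, virtual FFR from the model runner, and
    invasive FFR = virtual - (bias + patient offset + vessel noise), clipped.
    """
    rng = np.random.default_rng(spec.seed)
    if runner is None:

        def runner(graph, record, vessel_of_site):  # type: ignore[misc]
            return evaluate_ffr(
                graph,
                record,
                calibration=calibration,
                vessel_of_site=vessel_of_site,
                mode=spec.mode,
            )

    patient_ids, vessel_ids, virtual, invasive = [], [], [], []
    for p in range(spec.n_patients):
        pid = f"P{p:03d}"
        tree_seed = int(rng.integers(0, 2**31 - 1))
        record = sample_patient_record(rng, pid)
        tree = make_coronary_tree(tree_seed, n_generations=spec.n_generations)

        candidates = sorted(
            sid for sid, s in tree.segments.items() if s.length * spec.extent_range[0] >= 2.0
        )
        n_vessels = 1 + int(rng.choice(3, p=spec.vessels_per_patient))
        n_vessels = min(n_vessels, len(candidates))
        chosen = [
            candidates[i]
            for i in sorted(rng.choice(len(candidates), size=n_vessels, replace=False))
        ]

        g = tree
        vessel_of_site: dict[str, str] = {}
        for k, sid in enumerate(chosen):
            severity = float(rng.uniform(*spec.severity_range))
            extent = float(rng.uniform(*spec.extent_range))
            g = apply_stenosis(g, StenosisSpec(sid, severity, extent))
            site = f"{sid}__sten" if extent < 1.0 else sid
            vessel_of_site[site] = f"V{k}"

        try:
            result = runner(g, record, vessel_of_site)
        except Exception as exc:
            raise SyntheticError(f"model runner failed for patient {pid}: {exc}") from exc

        offset = rng.normal(0.0, spec.sd_patient) if spec.sd_patient > 0 else 0.0
        for vessel in sorted(result.vessel_ffr):
            v = result.vessel_ffr[vessel]
            noise = rng.normal(0.0, spec.sd_vessel) if spec.sd_vessel > 0 else 0.0
            inv = v - (spec.bias + offset + noise)
            inv = float(np.clip(inv, *spec.invasive_clip))
            patient_ids.append(pid)
            vessel_ids.append(vessel)
            virtual.append(min(float(v), 1.2))
            invasive.append(inv)

    return PairedFfr(patient_ids, vessel_ids, np.array(virtual), np.array(invasive))
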