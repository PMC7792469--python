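"""Patient-specific model parameters, hyperemia, virtual FFR and ischemia calls.

Maps a patient record (pressures, heart rate, age) onto the 1D model:
inflow waveform from SBP/DBP/HR, wall speed from an age-bracket lookup, and
terminal resistances distributed by Murray's law (R proportional to D^-3)
and scaled so baseline coronary flow is a configured fraction of estimated
cardiac output. Hyperemia divides every terminal resistance by a factor
(default 3.5). FFR at a marked site is the cycle-averaged pressure at the
distal end of the stenotic edge over the cycle-averaged ostium pressure;
a vessel is called ischemic iff FFR < 0.80 (strict), a patient iff any of
their vessels is.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq

from .graph import VesselGraph, validate_graph
from .hemo import (
    FlowSolution,
    NumericalConfig,
    SteadySolution,
    TerminalOutlet,
    Waveform,
    build_inflow_waveform,
    solve_steady,
    solve_unsteady,
    total_inflow,
)

__all__ = [
    "PatientRecord",
    "CalibrationConfig",
    "PersonalizedModel",
    "FfrResult",
    "PersonalizeError",
    "personalize",
    "induce_hyperemia",
    "compute_ffr",
    "compute_ffr_steady",
    "evaluate_ffr",
    "classify_vessel",
    "classify_patient",
    "records_from_csv",
]

FFR_THRESHOLD = 0.80
DEFAULT_HYPEREMIA_FACTOR = 3.5


class PersonalizeError(ValueError):
    pass


@dataclass(frozen=True)
class PatientRecord:
    """Clinical fields used for model personalization."""

    id: str
    age: float
    sex: str = "u"
    height_cm: float | None = None
    weight_kg: float | None = None
    sbp: float | None = None  # mmHg, at scan time
    dbp: float | None = None
    hr: float | None = None  # bpm
    history_mi: bool = False
    history_pci: bool = False
    smoking: bool = False

    @property
    def bmi(self) -> float | None:
        if self.height_cm and self.weight_kg:
            return self.weight_kg / (self.height_cm / 100.0) ** 2
        return None

    def require_hemodynamics(self) -> None:
        missing = [k for k in ("sbp", "dbp", "hr") if getattr(self, k) is None]
        if missing:
            raise PersonalizeError(
                f"patient {self.id}: missing required field(s) {missing}"
            )
        if not self.sbp > self.dbp:  # type: ignore[operator]
            raise PersonalizeError(f"patient {self.id}: SBP must exceed DBP")
        if not self.hr > 0:  # type: ignore[operator]
            raise PersonalizeError(f"patient {self.id}: HR must be positive")


@dataclass(frozen=True)
class CalibrationConfig:
    """Population-level calibration knobs (all config-exposed)."""

    # age brackets (upper edge, c0 m/s); wall speed stiffens with age
    c0_by_age: tuple[tuple[float, float], ...] = (
        (50.0, 10.0),
        (65.0, 12.0),
        (math.inf, 14.0),
    )
    coronary_flow_fraction: float = 0.04  # of cardiac output, at baseline
    stroke_volume_ml: float = 70.0
    murray_exponent: float = 3.0
    p_out_mmhg: float = 8.0
    hyperemia_factor: float = DEFAULT_HYPEREMIA_FACTOR

    def c0_for_age(self, age: float) -> float:
        for upper, c0 in self.c0_by_age:
            if age <= upper:
                return c0
        return self.c0_by_age[-1][1]


@dataclass
class PersonalizedModel:
    """Everything the solver needs for one patient."""

    graph: VesselGraph
    waveform: Waveform
    terminals: dict[str, TerminalOutlet]
    hyperemia_factor: float = 1.0  # 1.0 == baseline
    baseline_flow_ml_s: float = 0.0


def _terminal_nodes(graph: VesselGraph) -> list[str]:
    out, inc = graph.adjacency()
    return sorted(nid for nid in graph.nodes if inc[nid] and not out[nid])


def personalize(
    graph: VesselGraph,
    record: PatientRecord,
    calibration: CalibrationConfig | None = None,
) -> PersonalizedModel:
    """Build a personalized model: waveform, wall speeds, terminal resistances."""
    calibration = calibration or CalibrationConfig()
    record.require_hemodynamics()
    report = validate_graph(graph)
    if not report.ok:
        raise PersonalizeError("invalid graph: " + "; ".join(report.violations))

    waveform = build_inflow_waveform(record.sbp, record.dbp, record.hr)  # type: ignore[arg-type]
    c0 = calibration.c0_for_age(record.age)
    g = graph.copy()
    for sid, s in list(g.segments.items()):
        g.segments[sid] = replace(s, wall_speed_c0=c0)

    # Murray split of terminal resistance, scaled to the target baseline flow.
    # Calibration runs on the *reference* (un-stenosed) network: microvascular
    # resistance belongs to the distal bed, not to the lesion.
    term_nodes = _terminal_nodes(g)
    if not term_nodes:
        raise PersonalizeError("graph has no terminal nodes")
    diam = {nid: g.in_segments(nid)[0].reference_diameter for nid in term_nodes}
    weights = {nid: d ** -calibration.murray_exponent for nid, d in diam.items()}

    ref = g.copy()
    for sid, s in list(ref.segments.items()):
        ref.segments[sid] = replace(s, effective_diameter=s.reference_diameter)

    cardiac_output = calibration.stroke_volume_ml * record.hr / 60.0  # mL/s
    q_target = calibration.coronary_flow_fraction * cardiac_output
    map_mmhg = waveform.mean_pressure()

    def flow_at(log_scale: float) -> float:
        scale = math.exp(log_scale)
        terms = {
            nid: TerminalOutlet(scale * weights[nid], calibration.p_out_mmhg)
            for nid in term_nodes
        }
        sol = solve_steady(ref, terms, map_mmhg)
        return total_inflow(sol, ref) - q_target

    lo, hi = -10.0, 15.0
    if flow_at(lo) < 0:
        raise PersonalizeError(
            "cannot reach target coronary flow: network resistance too high"
        )
    log_scale = brentq(flow_at, lo, hi, xtol=1e-10)
    scale = math.exp(log_scale)
    terminals = {
        nid: TerminalOutlet(scale * weights[nid], calibration.p_out_mmhg)
        for nid in term_nodes
    }
    return PersonalizedModel(
        graph=g,
        waveform=waveform,
        terminals=terminals,
        hyperemia_factor=1.0,
        baseline_flow_ml_s=q_target,
    )


def induce_hyperemia(
    model: PersonalizedModel, factor: float = DEFAULT_HYPEREMIA_FACTOR
) -> PersonalizedModel:
    """Divide every terminal resistance by ``factor`` (microvascular dilation)."""
    if factor < 1.0:
        raise PersonalizeError(f"hyperemia factor must be >= 1, got {factor}")
    terminals = {
        nid: TerminalOutlet(t.resistance / factor, t.p_out)
        for nid, t in model.terminals.items()
    }
    return PersonalizedModel(
        graph=model.graph,
        waveform=model.waveform,
        terminals=terminals,
        hyperemia_factor=model.hyperemia_factor * factor,
        baseline_flow_ml_s=model.baseline_flow_ml_s,
    )


def _root_ostium(graph: VesselGraph, segment_id: str) -> str:
    """Ostium node at the root of the tree containing a segment."""
    _, inc = graph.adjacency()
    nid = graph.segments[segment_id].from_node
    seen = set()
    while inc[nid]:
        if nid in seen:
            raise PersonalizeError("cycle encountered while walking to the root")
        seen.add(nid)
        nid = graph.segments[inc[nid][0]].from_node
    if nid not in graph.ostia:
        raise PersonalizeError(f"segment {segment_id} is not rooted at an ostium")
    return nid


def _inlet_segment(graph: VesselGraph, ostium: str) -> str:
    out_segs = graph.out_segments(ostium)
    if not out_segs:
        raise PersonalizeError(f"ostium {ostium} has no outgoing segment")
    return sorted(out_segs, key=lambda s: s.id)[0].id


def compute_ffr(
    solution: FlowSolution, graph: VesselGraph, site_segment_id: str
) -> float:
    """FFR at a marked site from an unsteady solution (must be converged)."""
    seg = graph.segments.get(site_segment_id)
    if seg is None or not seg.ffr_site:
        raise PersonalizeError(f"segment {site_segment_id!r} is not a marked FFR site")
    if not solution.converged:
        raise PersonalizeError("solution did not reach periodic convergence")
    ostium = _root_ostium(graph, site_segment_id)
    p_a = solution.mean_pressure(_inlet_segment(graph, ostium), "start")
    p_d = solution.mean_pressure(site_segment_id, "end")
    return p_d / p_a


def compute_ffr_steady(
    solution: SteadySolution, graph: VesselGraph, site_segment_id: str
) -> float:
    """FFR at a marked site from a steady solution (fast mode)."""
    seg = graph.segments.get(site_segment_id)
    if seg is None or not seg.ffr_site:
        raise PersonalizeError(f"segment {site_segment_id!r} is not a marked FFR site")
    ostium = _root_ostium(graph, site_segment_id)
    return solution.node_pressure[seg.to_node] / solution.node_pressure[ostium]


@dataclass
class FfrResult:
    """Per-site FFR with per-vessel and per-patient ischemia calls."""

    site_ffr: dict[str, float]
    vessel_ffr: dict[str, float]
    vessel_ischemic: dict[str, bool]
    patient_ischemic: bool
    threshold: float = FFR_THRESHOLD


def classify_vessel(ffr: float, threshold: float = FFR_THRESHOLD) -> bool:
    """Ischemia is confirmed iff FFR is strictly below threshold."""
    if not 0 < ffr <= 1.2:
        raise PersonalizeError(f"FFR value {ffr} outside (0, 1.2]")
    return ffr < threshold


def classify_patient(
    vessel_ffrs: Sequence[float], threshold: float = FFR_THRESHOLD
) -> bool:
    """Positive iff at least one vessel is positive."""
    if len(vessel_ffrs) == 0:
        raise PersonalizeError("patient has no vessels to classify")
    return any(classify_vessel(v, threshold) for v in vessel_ffrs)


def evaluate_ffr(
    graph: VesselGraph,
    record: PatientRecord,
    *,
    calibration: CalibrationConfig | None = None,
    hyperemia_factor: float | None = None,
    vessel_of_site: Mapping[str, str] | None = None,
    threshold: float = FFR_THRESHOLD,
    mode: str = "unsteady",
    numerics: NumericalConfig | None = None,
) -> FfrResult:
    """Full per-patient chain: personalize, induce hyperemia, solve, read FFR.

    ``mode`` selects the unsteady solver or the steady fast mode.
    ``vessel_of_site`` maps site segment ids to vessel names; unmapped sites
    each count as their own vessel.
    """
    calibration = calibration or CalibrationConfig()
    factor = calibration.hyperemia_factor if hyperemia_factor is None else hyperemia_factor
    sites = graph.ffr_sites()
    if not sites:
        raise PersonalizeError("graph has no marked FFR sites")

    model = induce_hyperemia(personalize(graph, record, calibration), factor)
    if mode == "steady":
        steady = solve_steady(model.graph, model.terminals, model.waveform.mean_pressure())
        site_ffr = {s: compute_ffr_steady(steady, model.graph, s) for s in sites}
    elif mode == "unsteady":
        sol = solve_unsteady(
            model.graph, model.terminals, model.waveform, numerics or NumericalConfig()
        )
        site_ffr = {s: compute_ffr(sol, model.graph, s) for s in sites}
    else:
        raise PersonalizeError(f"unknown mode {mode!r}")

    vessel_sites: dict[str, list[str]] = {}
    for s in sites:
        vessel = (vessel_of_site or {}).get(s, s)
        vessel_sites.setdefault(vessel, []).append(s)
    vessel_ffr = {v: min(site_ffr[s] for s in ss) for v, ss in vessel_sites.items()}
    vessel_ischemic = {v: classify_vessel(f, threshold) for v, f in vessel_ffr.items()}
    return FfrResult(
        site_ffr=site_ffr,
        vessel_ffr=vessel_ffr,
        vessel_ischemic=vessel_ischemic,
        patient_ischemic=classify_patient(list(vessel_ffr.values()), threshold),
        threshold=threshold,
    )


def records_from_csv(path: str | Path) -> list[PatientRecord]:
    """Read patient records from the documented CSV layout."""
    import pandas as pd

    df = pd.read_csv(path)
    required = {"id", "age"}
    missing = required - set(df.columns)
    if missing:
        raise PersonalizeError(f"records CSV missing columns {sorted(missing)}")

    def opt(row, key):
        if key not in row or pd.isna(row[key]):
            return None
        return float(row[key])

    records = []
    for _, row in df.iterrows():
        records.append(
            PatientRecord(
                id=str(row["id"]),
                age=float(row["age"]),
                sex=str(row.get("sex", "u")),
                height_cm=opt(row, "height_cm"),
                weight_kg=opt(row, "weight_kg"),
                sbp=opt(row, "sbp"),
                dbp=opt(row, "dbp"),
                hr=opt(row, "hr"),
                history_mi=bool(row.get("history_mi", False)),
                history_pci=bool(row.get("history_pci", False)),
                smoking=bool(row.get("smoking", False)),
            )
        )
    return records
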