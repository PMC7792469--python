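"""Diagnostic concordance of virtual vs invasive FFR.

Confusion tables with Wilson score intervals, ROC/AUC via rank concordance,
Bland–Altman agreement and Spearman correlation. Ground-truth positive is
invasive FFR strictly below the threshold (default 0.80); the same strict
rule applies to the virtual side.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "PairedFfr",
    "ConfusionTable",
    "ProportionCI",
    "RocCurve",
    "DiagnosticsError",
    "wilson_interval",
    "confusion_table",
    "proportion_metrics",
    "roc_auc",
    "bland_altman",
    "spearman_rho",
    "metrics_report",
    "round_half_up",
]

DEFAULT_THRESHOLD = 0.80
_Z_975 = 1.959964  # two-sided 95% normal quantile, as conventionally tabulated


class DiagnosticsError(ValueError):
    pass


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (report display convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PairedFfr:
    """Paired per-vessel measurements: one row per (patient, vessel)."""

    patient_id: list[str]
    vessel_id: list[str]
    virtual: np.ndarray
    invasive: np.ndarray

    def __post_init__(self) -> None:
        self.virtual = np.asarray(self.virtual, dtype=float)
        self.invasive = np.asarray(self.invasive, dtype=float)
        n = len(self.patient_id)
        if not (len(self.vessel_id) == self.virtual.size == self.invasive.size == n):
            raise DiagnosticsError("column length mismatch")
        for name, col in (("virtual", self.virtual), ("invasive", self.invasive)):
            if col.size and (np.any(col <= 0) or np.any(col > 1.2)):
                raise DiagnosticsError(f"{name} FFR values must lie in (0, 1.2]")
        keys = list(zip(self.patient_id, self.vessel_id))
        if len(set(keys)) != n:
            raise DiagnosticsError("duplicate (patient, vessel) pair")

    def __len__(self) -> int:
        return len(self.patient_id)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PairedFfr":
        import pandas as pd

        df = pd.read_csv(path)
        required = {"patient_id", "vessel_id", "virtual_ffr", "invasive_ffr"}
        missing = required - set(df.columns)
        if missing:
            raise DiagnosticsError(f"cohort CSV missing columns {sorted(missing)}")
        return cls(
            [str(p) for p in df["patient_id"]],
            [str(v) for v in df["vessel_id"]],
            df["virtual_ffr"].to_numpy(float),
            df["invasive_ffr"].to_numpy(float),
        )

    def to_csv(self, path: str | Path) -> None:
        import pandas as pd

        pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "vessel_id": self.vessel_id,
                "virtual_ffr": self.virtual,
                "invasive_ffr": self.invasive,
            }
        ).to_csv(path, index=False)


@dataclass(frozen=True)
class ConfusionTable:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise DiagnosticsError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


@dataclass(frozen=True)
class ProportionCI:
    """Binomial proportion with a two-sided Wilson score interval, in percent."""

    estimate: float
    lower: float
    upper: float
    x: int
    n: int
    level: float = 0.95
    defined: bool = True

    def rounded(self, ndigits: int = 2) -> tuple[float, float, float]:
        return (
            round_half_up(self.estimate, ndigits),
            round_half_up(self.lower, ndigits),
            round_half_up(self.upper, ndigits),
        )


def wilson_interval(x: int, n: int, level: float = 0.95) -> ProportionCI:
    """Plain Wilson score interval (no continuity correction), percent scale."""
    if n <= 0:
        return ProportionCI(float("nan"), float("nan"), float("nan"), x, n, level, False)
    if not 0 <= x <= n:
        raise DiagnosticsError(f"x={x} outside [0, n={n}]")
    z = _Z_975 if level == 0.95 else float(stats.norm.ppf(1 - (1 - level) / 2))
    p = x / n
    z2 = z * z
    denom = 1.0 + z2 / n
    center = (p + z2 / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z2 / (4 * n * n)) / denom
    lo = min(max(0.0, center - half), p)
    hi = max(min(1.0, center + half), p)
    return ProportionCI(100 * p, 100 * lo, 100 * hi, x, n, level)


def _patient_calls(paired: PairedFfr, threshold: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-patient positives (any vessel below threshold), both methods."""
    patients = sorted(set(paired.patient_id))
    virt = np.zeros(len(patients), dtype=bool)
    inva = np.zeros(len(patients), dtype=bool)
    index = {p: i for i, p in enumerate(patients)}
    for pid, v, r in zip(paired.patient_id, paired.virtual, paired.invasive):
        i = index[pid]
        virt[i] |= v < threshold
        inva[i] |= r < threshold
    return virt, inva


def confusion_table(
    paired: PairedFfr,
    threshold: float = DEFAULT_THRESHOLD,
    *,
    per_patient: bool = False,
) -> ConfusionTable:
    """2×2 counts with invasive < threshold as ground truth (strict on both sides)."""
    if len(paired) == 0:
        raise DiagnosticsError("empty paired input")
    if per_patient:
        pred, truth = _patient_calls(paired, threshold)
    else:
        pred = paired.virtual < threshold
        truth = paired.invasive < threshold
    return ConfusionTable(
        tp=int(np.sum(pred & truth)),
        fp=int(np.sum(pred & ~truth)),
        fn=int(np.sum(~pred & truth)),
        tn=int(np.sum(~pred & ~truth)),
    )


def proportion_metrics(
    table: ConfusionTable, level: float = 0.95
) -> dict[str, ProportionCI]:
    """Sensitivity, specificity, PPV and NPV, each with a Wilson interval.

    A metric with zero denominator is returned flagged undefined rather than
    propagating NaN comparisons downstream.
    """
    pairs = {
        "sensitivity": (table.tp, table.tp + table.fn),
        "specificity": (table.tn, table.tn + table.fp),
        "ppv": (table.tp, table.tp + table.fp),
        "npv": (table.tn, table.tn + table.fn),
    }
    return {name: wilson_interval(x, n, level) for name, (x, n) in pairs.items()}


@dataclass
class RocCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_auc(paired: PairedFfr, threshold: float = DEFAULT_THRESHOLD) -> RocCurve:
    """Empirical ROC of the score (1 − virtual FFR) against invasive truth.

    AUC is the Mann–Whitney concordance probability; tied scores count 0.5,
    which equals the trapezoidal area under the empirical curve.
    """
    if len(paired) == 0:
        raise DiagnosticsError("empty paired input")
    labels = paired.invasive < threshold
    scores = 1.0 - paired.virtual
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DiagnosticsError("ROC requires both classes present")

    ranks = stats.rankdata(scores)  # mid-ranks
    auc = (ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)

    order = np.argsort(-scores, kind="stable")
    sorted_scores = scores[order]
    sorted_labels = labels[order]
    distinct = np.r_[np.nonzero(np.diff(sorted_scores))[0], sorted_scores.size - 1]
    tps = np.cumsum(sorted_labels)[distinct]
    fps = np.cumsum(~sorted_labels)[distinct]
    tpr = np.r_[0.0, tps / n_pos]
    fpr = np.r_[0.0, fps / n_neg]
    thresholds = np.r_[np.inf, sorted_scores[distinct]]
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds, auc=float(auc))


def bland_altman(paired: PairedFfr) -> dict[str, float]:
    """Mean/SD of (virtual − invasive) with 1.96·SD limits of agreement."""
    if len(paired) < 2:
        raise DiagnosticsError("Bland–Altman requires n >= 2")
    diff = paired.virtual - paired.invasive
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return {
        "bias": bias,
        "sd": sd,
        "loa_lower": bias - 1.96 * sd,
        "loa_upper": bias + 1.96 * sd,
        "n": len(paired),
    }


def spearman_rho(paired: PairedFfr) -> float:
    """Spearman rank correlation: Pearson correlation of mid-ranks."""
    if len(paired) < 3:
        raise DiagnosticsError("Spearman requires n >= 3")
    if np.ptp(paired.virtual) == 0 or np.ptp(paired.invasive) == 0:
        raise DiagnosticsError("constant column has undefined rank correlation")
    rv = stats.rankdata(paired.virtual)
    ri = stats.rankdata(paired.invasive)
    return float(np.corrcoef(rv, ri)[0, 1])


def metrics_report(
    paired: PairedFfr, threshold: float = DEFAULT_THRESHOLD, level: float = 0.95
) -> dict:
    """Full concordance report: per-vessel and per-patient metrics, ROC, BA, rho."""
    out: dict = {"threshold": threshold, "n_pairs": len(paired)}
    for scope, per_patient in (("per_vessel", False), ("per_patient", True)):
        table = confusion_table(paired, threshold, per_patient=per_patient)
        metrics = proportion_metrics(table, level)
        out[scope] = {
            "table": {"tp": table.tp, "fp": table.fp, "fn": table.fn, "tn": table.tn},
            "metrics": {
                name: {
                    "estimate_pct": round_half_up(ci.estimate) if ci.defined else None,
                    "ci_lower_pct": round_half_up(ci.lower) if ci.defined else None,
                    "ci_upper_pct": round_half_up(ci.upper) if ci.defined else None,
                    "x": ci.x,
                    "n": ci.n,
                    "defined": ci.defined,
                }
                for name, ci in metrics.items()
            },
        }
    try:
        out["roc_auc_pct"] = round_half_up(100 * roc_auc(paired, threshold).auc)
    except DiagnosticsError as exc:
        out["roc_auc_pct"] = None
        out["roc_auc_note"] = str(exc)
    ba = bland_altman(paired)
    out["bland_altman"] = {k: (v if isinstance(v, int) else float(v)) for k, v in ba.items()}
    try:
        out["spearman_rho"] = spearman_rho(paired)
    except DiagnosticsError as exc:
        out["spearman_rho"] = None
        out["spearman_note"] = str(exc)
    return out


def write_report(report: Mapping, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=1)
        fh.write("\n")
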