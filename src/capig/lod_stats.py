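"""Sensitivity and limit-of-detection statistics.

Sensitivity per translocation family is reported as detected/total with
a Wald (normal-approximation) binomial confidence interval,

    p_hat +/- z * sqrt(p_hat * (1 - p_hat) / n),   z = 1.96,

computed from the 2-dp-rounded point estimate, with bounds rounded to
2 dp and *not* truncated to [0, 1] — with two samples a 50% estimate
legitimately prints (−0.19, 1.19). Dilution-series results are
summarised as marker x condition detection matrices, and longitudinal
marker tracking reuses the same matrix structure over timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .clump import TranslocationCall
from .vdj_filter import CloneRecord

__all__ = [
    "SensitivityEstimate",
    "Marker",
    "DetectionMatrix",
    "MarkerTrack",
    "sensitivity_ci",
    "aggregate_detection",
    "detection_matrix",
    "lowest_detected_dilution",
    "marker_tracks",
]


@dataclass(frozen=True)
class SensitivityEstimate:
    detected: int
    total: int
    point: float
    ci_low: float
    ci_high: float
    z: float = 1.96

    def __str__(self) -> str:
        return f"{self.detected}/{self.total}\t{self.point:.2f} ({self.ci_low:.2f}–{self.ci_high:.2f})"


def sensitivity_ci(detected: int, total: int, z: float = 1.96) -> SensitivityEstimate:
    """Wald binomial CI on detected/total, 2-dp rounding, unclipped bounds."""
    if total < 1:
        raise ValueError("total must be >= 1")
    if not 0 <= detected <= total:
        raise ValueError("need 0 <= detected <= total")
    p = round(detected / total, 2)
    margin = z * math.sqrt(p * (1.0 - p) / total)
    return SensitivityEstimate(
        detected=detected,
        total=total,
        point=p,
        ci_low=round(p - margin, 2),
        ci_high=round(p + margin, 2),
        z=z,
    )


def aggregate_detection(family_counts: Iterable[tuple[int, int]]) -> float:
    """Pooled detection fraction: sum(detected) / sum(total)."""
    counts = list(family_counts)
    num = sum(d for d, _ in counts)
    den = sum(t for _, t in counts)
    if den == 0:
        raise ValueError("total count is zero")
    return num / den


@dataclass(frozen=True)
class Marker:
    """A trackable clone-specific marker."""

    marker_id: str
    kind: str  # translocation, vdj or mutation
    breakpoint_a: Optional[tuple[str, int]] = None
    breakpoint_b: Optional[tuple[str, int]] = None
    cdr3_nt: Optional[str] = None


DETECTED, NOT_DETECTED, NOT_ASSAYED = "detected", "not_detected", "not_assayed"


@dataclass
class DetectionMatrix:
    markers: list[Marker]
    conditions: list[str]
    cells: dict[tuple[str, str], str] = field(default_factory=dict)  # (marker_id, condition)

    def status(self, marker_id: str, condition: str) -> str:
        return self.cells[(marker_id, condition)]

    def row(self, marker_id: str) -> list[str]:
        return [self.cells[(marker_id, c)] for c in self.conditions]

    def to_dataframe(self) -> pd.DataFrame:
        data = {c: [self.cells[(m.marker_id, c)] for m in self.markers] for c in self.conditions}
        return pd.DataFrame(data, index=[m.marker_id for m in self.markers])


def _call_matches_marker(call: TranslocationCall, marker: Marker, tol: int) -> bool:
    if marker.breakpoint_a is None or marker.breakpoint_b is None:
        return False
    for bp1, bp2 in (
        (marker.breakpoint_a, marker.breakpoint_b),
        (marker.breakpoint_b, marker.breakpoint_a),
    ):
        if (
            call.chrom_a == bp1[0]
            and call.chrom_b == bp2[0]
            and abs(call.pos_a - bp1[1]) <= tol
            and abs(call.pos_b - bp2[1]) <= tol
        ):
            return True
    return False


def _detected_in_condition(marker: Marker, evidence, tol: int, include_equivocal: bool) -> bool:
    ok_status = {"confirmed", "equivocal"} if include_equivocal else {"confirmed"}
    if marker.kind == "vdj":
        return any(
            isinstance(item, CloneRecord) and item.cdr3_nt == marker.cdr3_nt for item in evidence
        )
    return any(
        isinstance(item, TranslocationCall)
        and item.status in ok_status
        and _call_matches_marker(item, marker, tol)
        for item in evidence
    )


def detection_matrix(
    calls_by_condition: Mapping[str, Sequence],
    markers: Sequence[Marker],
    conditions: Optional[Sequence[str]] = None,
    tol: int = 10,
    include_equivocal: bool = True,
) -> DetectionMatrix:
    """Score every marker against the verified calls of every condition.

    Evidence lists may mix TranslocationCalls (matched by breakpoints
    within +/- ``tol`` bp) and CloneRecords (matched by exact CDR3).
    Conditions listed but missing from the mapping are ``not_assayed``.
    """
    conds = list(conditions) if conditions is not None else list(calls_by_condition)
    matrix = DetectionMatrix(markers=list(markers), conditions=conds)
    for marker in markers:
        for cond in conds:
            if cond not in calls_by_condition:
                matrix.cells[(marker.marker_id, cond)] = NOT_ASSAYED
            else:
                hit = _detected_in_condition(
                    marker, calls_by_condition[cond], tol, include_equivocal
                )
                matrix.cells[(marker.marker_id, cond)] = DETECTED if hit else NOT_DETECTED
    return matrix


def lowest_detected_dilution(
    row: Sequence[str], dilution_order: Sequence[str]
) -> Optional[str]:
    """Most dilute condition with a detected cell; None if never detected.

    ``dilution_order`` lists labels from least to most dilute; gaps are
    allowed (detection need not be contiguous).
    """
    if len(row) != len(dilution_order):
        raise ValueError("row and dilution_order length mismatch")
    best = None
    for status, label in zip(row, dilution_order):
        if status == DETECTED:
            best = label
    return best


@dataclass
class MarkerTrack:
    patient_id: str
    marker_id: str
    marker_class: str  # translocation, vdj or mutation
    statuses: dict[str, str] = field(default_factory=dict)  # timepoint -> status
    allelic_fractions: dict[str, float] = field(default_factory=dict)


def marker_tracks(matrix: DetectionMatrix, patient_id: str) -> list[MarkerTrack]:
    """View a detection matrix as per-marker longitudinal tracks."""
    return [
        MarkerTrack(
            patient_id=patient_id,
            marker_id=m.marker_id,
            marker_class=m.kind,
            statuses={c: matrix.cells[(m.marker_id, c)] for c in matrix.conditions},
        )
        for m in matrix.markers
    ]
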