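"""Operational-efficiency indicators for larval source management.

The two headline indicators compare a drone/AI-assisted workflow with
conventional manual LSM across matched sub-districts:

* **TPDUA** (total person-days per unit area): labor intensity,
  ``(1/S) * sum_i W_i * D_i`` over work phases *i* with ``W_i`` workers
  and ``D_i`` workdays in an operation area of ``S`` km2.
* **Sites per pack**: larvicide-use efficiency, waterbodies sprayed per
  larvicide pack applied.

Group summaries use Tukey hinges for quartiles — the median of each
half-sample, halves including the middle value at odd n — because with
four districts per arm the hinge is the midpoint of each pair, which is
the convention the study's interquartile ranges follow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    Arm,
    DetectionRecord,
    SprayLog,
    SubDistrict,
    WorkPhaseRecord,
)

__all__ = [
    "EfficiencySummary",
    "GroupSummary",
    "total_person_days",
    "compute_tpdua",
    "sites_per_pack",
    "detection_ratio",
    "high_risk_ratio",
    "group_summary",
    "population_adjusted_rate",
    "round_display",
    "efficiency_report",
]


def round_display(x: float, ndigits: int = 2) -> float:
    """Round half away from zero for display (2.905 -> 2.91).

    Indicators are always computed at full precision; this rounding is
    applied only when rendering report tables.
    """
    q = Decimal(1).scaleb(-ndigits)
    # pre-round far below display precision so binary float fuzz
    # (e.g. 6.0649999999999995 for (5.41+6.72)/2) cannot flip the tie
    return float(
        Decimal(repr(round(float(x), 10))).quantize(q, rounding=ROUND_HALF_UP)
    )


@dataclass(frozen=True)
class EfficiencySummary:
    sub_district: str
    total_person_days: int
    tpdua: float  # person-days per km2
    sites_per_pack: float | None
    detection_ratio: float | None
    high_risk_ratio: float | None


@dataclass(frozen=True)
class GroupSummary:
    """Per-arm summary: mean, median and Tukey-hinge quartiles."""

    arm: Arm
    mean: float
    median: float
    q1: float
    q3: float
    n: int

    def __post_init__(self):
        if not (self.q1 <= self.median <= self.q3):
            raise ValueError("quartiles must satisfy q1 <= median <= q3")
        if self.n < 1:
            raise ValueError("n must be >= 1")


def total_person_days(phases: Iterable[WorkPhaseRecord]) -> int:
    """Sum of workers x days over work phases of one sub-district.

    An empty phase list yields 0 so partially-logged districts aggregate
    safely.
    """
    phases = list(phases)
    if len({p.sub_district for p in phases}) > 1:
        raise ValueError("phases must belong to a single sub-district")
    return sum(p.person_days for p in phases)


def compute_tpdua(phases: Iterable[WorkPhaseRecord], area_km2: float) -> float:
    """Total person-days per km2 for one sub-district, at full precision."""
    if area_km2 <= 0:
        raise ValueError("area_km2 must be > 0")
    return total_person_days(phases) / area_km2


def sites_per_pack(log: SprayLog) -> float:
    """Waterbodies sprayed per larvicide pack applied."""
    if log.packs_per_month <= 0:
        raise ValueError("packs_per_month must be > 0")
    return log.sprayed_sites / log.packs_per_month


def detection_ratio(rec: DetectionRecord) -> float:
    """Drone-found over manually-scouted waterbody counts."""
    if rec.sites_manual == 0:
        raise ValueError(f"{rec.sub_district}: detection ratio undefined "
                         "when no sites were found manually")
    return rec.sites_drone / rec.sites_manual


def high_risk_ratio(log: SprayLog) -> float:
    """Fraction of found waterbodies classified high-risk (hence sprayed)."""
    if log.found_sites == 0:
        raise ValueError(f"{log.sub_district}: no found sites")
    return log.sprayed_sites / log.found_sites


def _tukey_hinges(sorted_values: Sequence[float]) -> tuple[float, float]:
    n = len(sorted_values)
    half = (n + 1) // 2  # halves include the middle value when n is odd
    lower = sorted_values[:half]
    upper = sorted_values[n - half:]
    return float(np.median(lower)), float(np.median(upper))


def group_summary(values: Sequence[float], arm: Arm | str) -> GroupSummary:
    """Mean, median and Tukey-hinge quartiles of an arm's indicator values."""
    values = [float(v) for v in values]
    if not values:
        raise ValueError("cannot summarize an empty group")
    s = sorted(values)
    q1, q3 = _tukey_hinges(s)
    return GroupSummary(
        arm=Arm(arm),
        mean=float(np.mean(values)),
        median=float(np.median(s)),
        q1=q1,
        q3=q3,
        n=len(values),
    )


def population_adjusted_rate(cases: int, population: int) -> float:
    """Malaria cases per person per month (monthly count / population)."""
    if population <= 0:
        raise ValueError("population must be > 0")
    if cases < 0:
        raise ValueError("cases must be >= 0")
    return cases / population


def efficiency_report(
    subdistricts: Sequence[SubDistrict],
    workphases: Sequence[WorkPhaseRecord],
    spray_logs: Sequence[SprayLog] = (),
    detections: Sequence[DetectionRecord] = (),
) -> pd.DataFrame:
    """Per-district indicator table plus per-arm mean/median/IQR rows.

    Arm-level averages are means of the per-district indicator values
    (not ratios of arm totals), matching how the study's summary rows are
    derived.
    """
    sprays = {s.sub_district: s for s in spray_logs}
    dets = {d.sub_district: d for d in detections}
    rows = []
    by_arm: dict[Arm, list[dict]] = {Arm.intervention: [], Arm.control: []}
    for d in subdistricts:
        phases = [p for p in workphases if p.sub_district == d.name]
        pdays = total_person_days(phases)
        tpdua = compute_tpdua(phases, d.area_km2)
        spray = sprays.get(d.name)
        det = dets.get(d.name)
        row = {
            "sub_district": d.name,
            "arm": d.arm.value,
            "total_person_days": pdays,
            "tpdua": tpdua,
            "sites_per_pack": sites_per_pack(spray) if spray else math.nan,
            "high_risk_ratio": high_risk_ratio(spray) if spray else math.nan,
            "detection_ratio": (
                detection_ratio(det) if det and det.sites_manual else math.nan
            ),
        }
        rows.append(row)
        by_arm[d.arm].append(row)

    for arm, arm_rows in by_arm.items():
        if not arm_rows:
            continue
        tp = group_summary([r["tpdua"] for r in arm_rows], arm)
        summary = {
            "sub_district": f"{arm.value} average",
            "arm": arm.value,
            "total_person_days": float(
                np.mean([r["total_person_days"] for r in arm_rows])
            ),
            "tpdua": tp.mean,
            "tpdua_median": tp.median,
            "tpdua_q1": tp.q1,
            "tpdua_q3": tp.q3,
        }
        spp = [r["sites_per_pack"] for r in arm_rows if not math.isnan(r["sites_per_pack"])]
        if spp:
            sp = group_summary(spp, arm)
            summary.update(
                sites_per_pack=sp.mean,
                sites_per_pack_median=sp.median,
                sites_per_pack_q1=sp.q1,
                sites_per_pack_q3=sp.q3,
            )
        rows.append(summary)
    return pd.DataFrame(rows)
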