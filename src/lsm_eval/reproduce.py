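"""One-shot harness recomputing every fixture-derivable headline quantity.

Each check recomputes an indicator from the packaged study tables with
the package's own operations and compares it, at its printed precision,
with the value the source tables print. The report is deterministic:
every quantity here is a closed-form function of the fixtures.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

from . import economics, efficiency, entomology, inference_stats
from .core_io import Arm, Genus, load_study_fixtures
from .efficiency import round_display

__all__ = ["Check", "reproduce_study"]


@dataclass(frozen=True)
class Check:
    name: str
    expected: float
    computed: float
    tolerance: float
    passed: bool


def _check(checks: list[Check], name: str, expected: float, computed: float,
           tolerance: float = 0.0) -> None:
    checks.append(Check(
        name=name, expected=expected, computed=float(computed),
        tolerance=tolerance,
        passed=abs(float(computed) - expected) <= tolerance + 1e-12,
    ))


# printed per-district values: (tpdua_2dp, sites_per_pack)
_PRINTED = {
    "Nkwantanang": (5.32, 146), "Abaam": (4.85, 182),
    "Takyiman": (2.82, 178), "Asuom": (2.99, 170),
    "Abodom": (12.24, 36), "Subi": (5.41, 50),
    "Pramkese": (7.74, 48), "Kade": (6.72, 105),
}
_PRINTED_DETECTION = {
    "Nkwantanang": 4.53, "Abaam": 4.23, "Takyiman": 1.83, "Asuom": 4.68,
}


def reproduce_study(fixtures_dir: str | Path | None = None) -> dict:
    """Recompute all fixture-based headline results; return a report dict.

    ``fixtures_dir`` overrides the packaged tables (used to demonstrate
    that a perturbed table is caught by the harness).
    """
    bundle = load_study_fixtures(fixtures_dir)
    checks: list[Check] = []

    # labor efficiency: TPDUA per district and per arm
    tpdua: dict[str, float] = {}
    for d in bundle.subdistricts:
        value = efficiency.compute_tpdua(bundle.phases_for(d.name), d.area_km2)
        tpdua[d.name] = value
        _check(checks, f"tpdua/{d.name}", _PRINTED[d.name][0],
               round_display(value))
    # summary rows are derived from the printed (2-decimal) per-district
    # values, so the group summaries take the display-rounded indicators
    arm_values = {
        arm: [round_display(tpdua[d.name]) for d in bundle.subdistricts
              if d.arm == arm]
        for arm in Arm
    }
    gi = efficiency.group_summary(arm_values[Arm.intervention], Arm.intervention)
    gc = efficiency.group_summary(arm_values[Arm.control], Arm.control)
    _check(checks, "tpdua/intervention_mean", 4.00, round_display(gi.mean))
    _check(checks, "tpdua/control_mean", 8.03, round_display(gc.mean))
    _check(checks, "tpdua/intervention_median", 3.92, round_display(gi.median))
    _check(checks, "tpdua/intervention_q1", 2.91, round_display(gi.q1))
    _check(checks, "tpdua/intervention_q3", 5.09, round_display(gi.q3))
    _check(checks, "tpdua/control_median", 7.23, round_display(gc.median))
    _check(checks, "tpdua/control_q1", 6.07, round_display(gc.q1))
    _check(checks, "tpdua/control_q3", 9.99, round_display(gc.q3))
    u = inference_stats.mann_whitney_exact(
        arm_values[Arm.intervention], arm_values[Arm.control]
    )
    _check(checks, "tpdua/mannwhitney_u", 0.0, u.u_statistic)
    _check(checks, "tpdua/mannwhitney_p", 0.029, round_display(u.p_two_sided, 3))

    # larvicide efficiency: sites per pack
    spp: dict[str, float] = {}
    for log in bundle.spray_logs:
        value = efficiency.sites_per_pack(log)
        spp[log.sub_district] = value
        _check(checks, f"sites_per_pack/{log.sub_district}",
               _PRINTED[log.sub_district][1], value)
    arms = {d.name: d.arm for d in bundle.subdistricts}
    spp_arm = {
        arm: [v for k, v in spp.items() if arms[k] == arm] for arm in Arm
    }
    si = efficiency.group_summary(spp_arm[Arm.intervention], Arm.intervention)
    sc = efficiency.group_summary(spp_arm[Arm.control], Arm.control)
    _check(checks, "sites_per_pack/intervention_mean", 169, round_display(si.mean, 0))
    _check(checks, "sites_per_pack/control_mean", 60, round_display(sc.mean, 0))
    _check(checks, "sites_per_pack/intervention_median", 174.0, si.median)
    _check(checks, "sites_per_pack/intervention_q1", 158.0, si.q1)
    _check(checks, "sites_per_pack/intervention_q3", 180.0, si.q3)
    _check(checks, "sites_per_pack/control_median", 49.0, sc.median)
    _check(checks, "sites_per_pack/control_q1", 42.0, sc.q1)
    _check(checks, "sites_per_pack/control_q3", 77.5, sc.q3)
    us = inference_stats.mann_whitney_exact(
        spp_arm[Arm.intervention], spp_arm[Arm.control]
    )
    _check(checks, "sites_per_pack/mannwhitney_u", 0.0, us.u_statistic)
    # larvicide needed per treated site fell by 1 - 60/169 ~ 64.5%
    reduction = 1.0 - sc.mean / si.mean
    _check(checks, "sites_per_pack/per_site_reduction_pct", 64.5,
           round_display(100 * reduction, 1), tolerance=0.5)

    # detection: drone vs manual scouting
    for det in bundle.detections:
        _check(checks, f"detection_ratio/{det.sub_district}",
               _PRINTED_DETECTION[det.sub_district],
               round_display(efficiency.detection_ratio(det)))
    drone = sum(d.sites_drone for d in bundle.detections)
    manual = sum(d.sites_manual for d in bundle.detections)
    _check(checks, "detection_ratio/total", 3.61, round_display(drone / manual))

    # economics: wage derivation
    wage = economics.derive_daily_wage(economics.WageParams())
    _check(checks, "economics/daily_wage", 207.4, round_display(wage, 1))
    _check(checks, "economics/adjusted_monthly_salary", 4148,
           round_display(economics.WageParams().adjusted_monthly_salary, 0))

    # entomology: catch composition and genus-by-site contingency
    summary = entomology.summarize_catches(list(bundle.trap_catches))
    _check(checks, "entomology/total_insects", 964, summary.total_insects)
    _check(checks, "entomology/total_mosquitoes", 783, summary.total_mosquitoes)
    _check(checks, "entomology/mosquito_share_pct", 81.2,
           round_display(100 * summary.mosquito_share, 1))
    _check(checks, "entomology/culex_pct", 90.8,
           round_display(100 * summary.genus_proportions[Genus.Culex], 1))
    _check(checks, "entomology/aedes_pct", 4.73,
           round_display(100 * summary.genus_proportions[Genus.Aedes], 2))
    _check(checks, "entomology/anopheles_pct", 4.34,
           round_display(100 * summary.genus_proportions[Genus.Anopheles], 2))
    _check(checks, "entomology/male_pct", 24.5,
           round_display(100 * summary.sex_proportions["male"], 1))
    _check(checks, "entomology/female_pct", 75.5,
           round_display(100 * summary.sex_proportions["female"], 1))
    chi = inference_stats.chi_square_test(bundle.contingency.to_numpy())
    _check(checks, "entomology/chi2", 33.63, round_display(chi.statistic))
    _check(checks, "entomology/chi2_df", 2, chi.df)

    n_passed = sum(c.passed for c in checks)
    return {
        "n_checks": len(checks),
        "n_passed": n_passed,
        "all_passed": n_passed == len(checks),
        "checks": [asdict(c) for c in checks],
    }
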