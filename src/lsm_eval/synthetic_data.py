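"""Synthetic inputs with the statistical structure the analyses assume.

Three generators make every pipeline stage testable without field data:

* **Waterbody tables** — the six categorical features are drawn
  independently from configurable marginals and the larval-presence
  label from a Bernoulli whose log-odds are additive over the drawn
  category levels. Because the feature space is a finite lattice
  (7*2*4*2*2*3 = 672 cells), the generator also returns the exact
  per-cell presence probabilities, from which the Bayes-optimal
  classifier and its accuracy/precision/recall can be computed in
  closed form — the oracle against which a learned classifier's
  recovery is judged.
* **Operation logs** — arm-specific work-phase effort (separate mapping
  and spraying phases for intervention districts, one combined phase
  for controls), drone/manual detection counts, and spray logs in which
  control districts treat every found site while intervention districts
  treat the high-risk fraction.
* **Trap-catch series** — weekly multinomial genus draws dominated by
  Culex, with a separate non-target by-catch stream, mirroring the
  observed catch composition.

Default weight magnitudes are ordered so waterbody type and visual
turbidity carry the most signal, echoing the feature-importance ranking
seen in the field model, and the intercept puts baseline prevalence
near 0.5, echoing the observed high-risk ratios (0.56-0.75). All
randomness flows through one seeded NumPy generator.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import (
    FEATURE_LEVELS,
    Arm,
    DetectionRecord,
    Genus,
    Sex,
    SprayLog,
    SubDistrict,
    TrapCatchRecord,
    WaterbodyFeatures,
    WorkPhaseRecord,
)

__all__ = [
    "PhaseEffort",
    "GeneratorConfig",
    "GroundTruth",
    "gen_waterbodies",
    "gen_operation_log",
    "gen_trap_catches",
    "default_config",
]

FEATURE_NAMES = tuple(FEATURE_LEVELS)

_DEFAULT_MARGINALS: dict[str, dict] = {
    "waterbody_type": {
        "drainage ditches": 0.22, "swampy area": 0.18, "reservoir": 0.08,
        "puddle made by rain": 0.25, "rice paddy": 0.12,
        "upland rice field": 0.07, "other agricultural field": 0.08,
    },
    "origin": {"artificial": 0.55, "natural": 0.45},
    "area_size_class": {"very_small": 0.15, "small": 0.30,
                        "medium": 0.40, "large": 0.15},
    "vegetation_inside": {False: 0.55, True: 0.45},
    "vegetation_around": {False: 0.40, True: 0.60},
    "visual_turbidity": {"clean": 0.30, "turbid": 0.45, "very turbid": 0.25},
}

# additive log-odds; magnitudes ordered type > turbidity > veg_inside >
# origin > veg_around > area, mimicking the field model's RFI ranking
_DEFAULT_WEIGHTS: dict[str, dict] = {
    "waterbody_type": {
        "drainage ditches": 1.2, "swampy area": 0.8, "reservoir": -1.0,
        "puddle made by rain": 0.6, "rice paddy": 1.0,
        "upland rice field": -0.6, "other agricultural field": -0.8,
    },
    "visual_turbidity": {"clean": -1.1, "turbid": 0.3, "very turbid": 1.2},
    "vegetation_inside": {False: -0.55, True: 0.55},
    "origin": {"artificial": -0.6, "natural": 0.6},
    "vegetation_around": {False: -0.4, True: 0.4},
    "area_size_class": {"very_small": -0.3, "small": -0.1,
                        "medium": 0.1, "large": 0.3},
}


@dataclass(frozen=True)
class PhaseEffort:
    """Effort model for one work phase: fixed crew size and a mean
    workday rate per km2 (days ~ 1 + Poisson(rate * area))."""

    workers: int
    mean_days_per_km2: float

    def __post_init__(self):
        if self.workers < 1:
            raise ValueError("workers must be >= 1")
        if self.mean_days_per_km2 < 0:
            raise ValueError("mean_days_per_km2 must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    n_waterbodies: int = 4000  # emulates the ~4k labelled survey scale
    feature_marginals: Mapping[str, Mapping] = field(
        default_factory=lambda: _DEFAULT_MARGINALS
    )
    risk_weights: Mapping[str, Mapping] = field(
        default_factory=lambda: _DEFAULT_WEIGHTS
    )
    risk_intercept: float = -0.57  # puts lattice prevalence near 0.5
    arm_effort: Mapping[str, Mapping[str, PhaseEffort]] = field(
        default_factory=lambda: {
            "intervention": {
                "mapping": PhaseEffort(2, 0.5),
                "spraying": PhaseEffort(3, 0.4),
            },
            "control": {"combined": PhaseEffort(6, 1.0)},
        }
    )
    high_risk_spray_fraction: float = 0.62  # within the observed 0.56-0.75
    site_density_drone_per_km2: float = 90.0
    site_density_manual_per_km2: float = 25.0
    packs_per_km2: float = 0.25
    genus_mix: Mapping[str, float] = field(
        default_factory=lambda: {
            "Culex": 0.909, "Aedes": 0.047, "Anopheles": 0.043,
            "Mansonia": 0.001,
        }
    )
    mean_weekly_mosquitoes: float = 45.0
    mean_weekly_non_target: float = 11.0
    female_fraction: float = 0.755
    weeks: int = 16
    sites: tuple[str, ...] = ("site_A", "site_B")
    random_seed: int = 0

    def __post_init__(self):
        if self.n_waterbodies < 0:
            raise ValueError("n_waterbodies must be >= 0")
        if self.weeks < 1:
            raise ValueError("weeks must be >= 1")
        if not 0 <= self.high_risk_spray_fraction <= 1:
            raise ValueError("high_risk_spray_fraction must lie in [0, 1]")
        for name, probs in self.feature_marginals.items():
            levels = FEATURE_LEVELS[name]
            if set(probs) != set(levels):
                raise ValueError(f"marginals for {name!r} must cover {levels}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ValueError(f"marginals for {name!r} must sum to 1")
        mix_total = sum(self.genus_mix.values())
        if abs(mix_total - 1.0) > 1e-9:
            raise ValueError("genus_mix must sum to 1")


def default_config(**overrides) -> GeneratorConfig:
    return GeneratorConfig(**overrides)


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class GroundTruth:
    """Exact generating process over the finite feature lattice.

    ``lattice`` has one row per feature combination with its probability
    mass ``cell_mass`` (product of marginals) and true presence
    probability ``p_presence``; the Bayes rule labels a cell high-risk
    iff ``p_presence >= 0.5``.
    """

    lattice: pd.DataFrame

    @property
    def prevalence(self) -> float:
        """Marginal P(larvae present) under the generating process."""
        return float((self.lattice.cell_mass * self.lattice.p_presence).sum())

    def bayes_metrics(self) -> dict[str, float]:
        """Exact accuracy/precision/recall of the Bayes rule at 0.5."""
        mass = self.lattice.cell_mass.to_numpy()
        p = self.lattice.p_presence.to_numpy()
        pred = p >= 0.5
        tp = float((mass * p)[pred].sum())
        fp = float((mass * (1 - p))[pred].sum())
        fn = float((mass * p)[~pred].sum())
        tn = float((mass * (1 - p))[~pred].sum())
        return {
            "accuracy": tp + tn,
            "precision": tp / (tp + fp) if tp + fp else float("nan"),
            "recall": tp / (tp + fn) if tp + fn else float("nan"),
        }

    def presence_probability(self, features: WaterbodyFeatures) -> float:
        mask = np.ones(len(self.lattice), dtype=bool)
        for name in FEATURE_NAMES:
            mask &= self.lattice[name].to_numpy() == getattr(features, name)
        return float(self.lattice.loc[mask, "p_presence"].iloc[0])


def _build_lattice(cfg: GeneratorConfig) -> pd.DataFrame:
    rows = []
    for combo in itertools.product(*(FEATURE_LEVELS[n] for n in FEATURE_NAMES)):
        mass, logit = 1.0, cfg.risk_intercept
        for name, level in zip(FEATURE_NAMES, combo):
            mass *= cfg.feature_marginals[name][level]
            logit += cfg.risk_weights[name][level]
        rows.append(dict(zip(FEATURE_NAMES, combo),
                         cell_mass=mass, p_presence=float(_sigmoid(logit))))
    lattice = pd.DataFrame(rows)
    assert abs(lattice.cell_mass.sum() - 1.0) < 1e-9
    return lattice


def gen_waterbodies(
    cfg: GeneratorConfig | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Draw a labelled waterbody feature table and its exact ground truth.

    Returns a DataFrame with the six feature columns plus
    ``larvae_present`` (0/1) and ``p_presence`` (the true per-row
    probability), and the full-lattice :class:`GroundTruth`.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.random_seed)
    truth = GroundTruth(lattice=_build_lattice(cfg))
    n = cfg.n_waterbodies
    data: dict[str, np.ndarray] = {}
    logit = np.full(n, cfg.risk_intercept)
    for name in FEATURE_NAMES:
        levels = list(FEATURE_LEVELS[name])
        probs = [cfg.feature_marginals[name][lv] for lv in levels]
        idx = rng.choice(len(levels), size=n, p=probs)
        data[name] = np.asarray(levels, dtype=object)[idx]
        weights = np.asarray([cfg.risk_weights[name][lv] for lv in levels])
        logit += weights[idx]
    p = _sigmoid(logit)
    frame = pd.DataFrame(data, columns=list(FEATURE_NAMES))
    frame["larvae_present"] = (rng.random(n) < p).astype(int)
    frame["p_presence"] = p
    return frame, truth


def frame_to_features(frame: pd.DataFrame) -> list[WaterbodyFeatures]:
    """Convert generated rows into validated feature records."""
    return [
        WaterbodyFeatures(**{n: row[n] for n in FEATURE_NAMES})
        for _, row in frame.iterrows()
    ]


def gen_operation_log(
    districts: Sequence[SubDistrict],
    cfg: GeneratorConfig | None = None,
) -> tuple[list[WorkPhaseRecord], list[SprayLog], list[DetectionRecord]]:
    """Arm-specific work phases, spray logs and detection counts.

    Intervention districts get separate mapping and spraying phases and
    treat ``round(found * high_risk_spray_fraction)`` sites; control
    districts get one combined phase and treat every found site.
    """
    cfg = cfg or GeneratorConfig()
    if not districts:
        raise ValueError("districts must be non-empty")
    rng = np.random.default_rng(cfg.random_seed)
    phases, sprays, detections = [], [], []
    for d in districts:
        effort = cfg.arm_effort[d.arm.value]
        for phase_name, ph in effort.items():
            days = 1 + int(rng.poisson(ph.mean_days_per_km2 * d.area_km2))
            phases.append(WorkPhaseRecord(d.name, phase_name, ph.workers, days))
        drone = int(rng.poisson(cfg.site_density_drone_per_km2 * d.area_km2))
        manual = int(rng.poisson(cfg.site_density_manual_per_km2 * d.area_km2))
        detections.append(DetectionRecord(d.name, drone, manual))
        if d.arm == Arm.intervention:
            found = drone  # drone mapping drives the intervention workflow
            sprayed = int(round(found * cfg.high_risk_spray_fraction))
        else:
            found = manual
            sprayed = found
        found = max(found, 1)
        sprayed = min(max(sprayed, 0), found)
        packs = max(0.5, round(cfg.packs_per_km2 * d.area_km2 * 2) / 2)
        sprays.append(SprayLog(d.name, found, sprayed, packs))
    return phases, sprays, detections


def gen_trap_catches(cfg: GeneratorConfig | None = None) -> list[TrapCatchRecord]:
    """Weekly multinomial trap catches per site, Culex-dominant.

    Mosquito totals per site-week are Poisson around
    ``mean_weekly_mosquitoes``, split across genera by ``genus_mix``
    and across sexes binomially; a separate Poisson stream adds
    non-target by-catch of unknown sex.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.random_seed)
    genera = list(cfg.genus_mix)
    mix = np.asarray([cfg.genus_mix[g] for g in genera])
    records: list[TrapCatchRecord] = []
    for site in cfg.sites:
        for week in range(1, cfg.weeks + 1):
            total = int(rng.poisson(cfg.mean_weekly_mosquitoes))
            counts = rng.multinomial(total, mix)
            for genus, c in zip(genera, counts):
                if c == 0:
                    continue
                females = int(rng.binomial(c, cfg.female_fraction))
                if females:
                    records.append(
                        TrapCatchRecord(site, week, Genus(genus), Sex.female, females)
                    )
                if c - females:
                    records.append(
                        TrapCatchRecord(site, week, Genus(genus), Sex.male, c - females)
                    )
            nt = int(rng.poisson(cfg.mean_weekly_non_target))
            if nt:
                records.append(
                    TrapCatchRecord(site, week, Genus.non_target, Sex.unknown, nt)
                )
    return records
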