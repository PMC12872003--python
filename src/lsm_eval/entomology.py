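"""Aggregation of CDC light-trap catches.

Summaries follow the conventions of the field trial's entomological
reporting: genus and sex proportions are fractions of the *mosquito*
total (non-target by-catch excluded from the denominator), while the
mosquito share itself is a fraction of all insects captured. The
genus-by-site contingency table drops genera below a minimum total count
(default 2), which is how a single stray specimen of a genus is excluded
before a chi-square comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .core_io import Genus, TrapCatchRecord

__all__ = ["CatchSummary", "summarize_catches", "weekly_series", "build_contingency"]

MOSQUITO_GENERA = (Genus.Anopheles, Genus.Aedes, Genus.Culex, Genus.Mansonia)


@dataclass(frozen=True)
class CatchSummary:
    total_insects: int
    total_mosquitoes: int
    genus_counts: dict[Genus, int]  # includes non_target
    genus_proportions: dict[Genus, float]  # mosquito genera / mosquito total
    sex_counts: dict[str, int]  # mosquitoes only
    sex_proportions: dict[str, float]
    site_totals: dict[str, int]  # mosquitoes per site

    @property
    def mosquito_share(self) -> float:
        """Mosquitoes as a fraction of all insects captured."""
        return self.total_mosquitoes / self.total_insects


def summarize_catches(records: Iterable[TrapCatchRecord]) -> CatchSummary:
    """Aggregate trap-catch records into totals, shares and site totals."""
    records = list(records)
    if not records:
        raise ValueError("no trap-catch records to summarize")
    genus_counts = {g: 0 for g in Genus}
    sex_counts: dict[str, int] = {}
    site_totals: dict[str, int] = {}
    for r in records:
        genus_counts[r.genus] += r.count
        if r.genus != Genus.non_target:
            sex_counts[r.sex.value] = sex_counts.get(r.sex.value, 0) + r.count
            site_totals[r.site] = site_totals.get(r.site, 0) + r.count
    total_insects = sum(genus_counts.values())
    total_mosquitoes = sum(genus_counts[g] for g in MOSQUITO_GENERA)
    if total_mosquitoes == 0:
        raise ValueError("no mosquitoes among the records")
    return CatchSummary(
        total_insects=total_insects,
        total_mosquitoes=total_mosquitoes,
        genus_counts=genus_counts,
        genus_proportions={
            g: genus_counts[g] / total_mosquitoes for g in MOSQUITO_GENERA
        },
        sex_counts=sex_counts,
        sex_proportions={
            s: c / total_mosquitoes for s, c in sex_counts.items()
        },
        site_totals=site_totals,
    )


def weekly_series(
    records: Iterable[TrapCatchRecord],
    site: str,
    include_non_target: bool = False,
) -> list[tuple[int, int]]:
    """Per-week catch totals for one site, ascending, gaps filled with 0.

    Weeks run from 1 to the last week observed anywhere in ``records``
    (all sites share one trapping calendar), so a site with no catches
    in a mid-study week reports an explicit zero. Non-target insects are
    excluded by default, matching the mosquito time-series reporting.
    """
    records = list(records)
    sites = {r.site for r in records}
    if site not in sites:
        raise ValueError(f"site {site!r} not present in records")
    last_week = max(r.week_index for r in records)
    totals = dict.fromkeys(range(1, last_week + 1), 0)
    for r in records:
        if r.site != site:
            continue
        if not include_non_target and r.genus == Genus.non_target:
            continue
        totals[r.week_index] += r.count
    return sorted(totals.items())


def build_contingency(
    records: Iterable[TrapCatchRecord],
    sites: Sequence[str],
    min_genus_total: int = 2,
) -> tuple[pd.DataFrame, list[tuple[str, int]]]:
    """Genus-by-site mosquito count table with a rare-genus exclusion rule.

    Rows are mosquito genera whose total across the two sites is at
    least ``min_genus_total``; excluded genera are returned alongside
    with their counts. Non-target insects never enter the table.
    """
    if len(sites) != 2:
        raise ValueError("exactly two sites are required")
    records = list(records)
    present = {r.site for r in records}
    for s in sites:
        if s not in present:
            raise ValueError(f"site {s!r} not present in records")
    counts = {g: {s: 0 for s in sites} for g in MOSQUITO_GENERA}
    for r in records:
        if r.genus in counts and r.site in counts[r.genus]:
            counts[r.genus][r.site] += r.count
    kept, excluded = [], []
    for g in MOSQUITO_GENERA:
        total = sum(counts[g].values())
        if total >= min_genus_total:
            kept.append(g)
        else:
            excluded.append((g.value, total))
    table = pd.DataFrame(
        [[counts[g][s] for s in sites] for g in kept],
        index=[g.value for g in kept],
        columns=list(sites),
        dtype=int,
    )
    return table, excluded
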