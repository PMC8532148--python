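"""Batch fitting and group-wise comparison of oil-sample cohorts.

Reproduces the screening logic used for regional olive-oil surveys:
every sample carries decay curves at 2 MHz (fitted with two
components, labelled "a" short / "b" long) and at 100 MHz (fitted
mono-exponentially on the most intense spectral region), and the two
regional groups are compared descriptively through the overlap of
their per-quantity [min, max] ranges.  No inferential test is applied;
the conclusion of interest is whether the ranges coincide, not whether
means differ significantly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .decay import DecayCurve, RelaxationFit, fit_decay

__all__ = [
    "SampleRecord",
    "GroupSummary",
    "CohortComparison",
    "CohortError",
    "run_cohort",
    "summarize_groups",
    "QUANTITIES",
    "DEFAULT_OVERLAP_THRESHOLD",
]

#: tidy-table quantity columns, all in ms
QUANTITIES = (
    "T1a_2MHz",
    "T1b_2MHz",
    "T2a_2MHz",
    "T2b_2MHz",
    "T1_100MHz",
    "T2_100MHz",
)

DEFAULT_OVERLAP_THRESHOLD = 0.5

#: below this Larmor frequency the spectrum is a single broad line and
#: decays are decomposed into two components; above it, the most
#: intense spectral region is integrated and fitted mono-exponentially
LOW_FIELD_MHZ = 10.0


class CohortError(ValueError):
    pass


@dataclass
class SampleRecord:
    """One oil sample: identity, group label, curves and (after
    :func:`run_cohort`) the fits per curve."""

    sample_id: str
    group: str
    curves: dict[str, DecayCurve] = field(default_factory=dict)
    fits: dict[str, RelaxationFit] = field(default_factory=dict)
    truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.group:
            raise CohortError("group must be nonempty")


@dataclass
class GroupSummary:
    """Descriptive statistics for one group.

    ``stats`` maps quantity name to count/mean/sd/min/max (ms); ``sd``
    is nan and the quantity is listed in ``flags`` when the group has
    fewer than two values.  ``overlap`` holds the range-overlap
    coefficient against the other group, |intersection| / |union| of
    the two [min, max] intervals, in [0, 1].
    """

    group: str
    stats: dict[str, dict[str, float]]
    overlap: dict[str, float] = field(default_factory=dict)
    flags: list[str] = field(default_factory=list)


@dataclass
class CohortComparison:
    summaries: dict[str, GroupSummary]
    overlap: dict[str, float]
    verdict: str
    threshold: float


def _quantity_key(curve: DecayCurve) -> tuple[str, int] | None:
    t = "T1" if curve.sequence_kind == "inversion_recovery" else "T2"
    if curve.larmor_mhz < LOW_FIELD_MHZ:
        return t, 2
    return t, 1


def run_cohort(
    records: list[SampleRecord],
) -> tuple[list[SampleRecord], pd.DataFrame, list[str]]:
    """Fit every curve of every sample and build the tidy table.

    Low-field (2 MHz) curves get a two-component fit; high-field
    (100 MHz) curves a mono fit.  A failed fit is reported in the
    returned failure log and leaves nan in the table; the run
    continues.  Returns (records-with-fits, tidy table, failures).
    """
    if not records:
        raise CohortError("empty cohort")
    rows = []
    failures: list[str] = []
    for rec in records:
        if not rec.curves:
            failures.append(f"{rec.sample_id}: no curves")
            continue
        row: dict[str, object] = {"sample_id": rec.sample_id, "group": rec.group}
        for key, curve in rec.curves.items():
            kind = _quantity_key(curve)
            if kind is None:
                continue
            t_name, n_comp = kind
            try:
                fit = fit_decay(curve, n_comp)
            except Exception as exc:  # defensive: fit_decay returns failures
                failures.append(f"{rec.sample_id}/{key}: {exc}")
                continue
            rec.fits[key] = fit
            if not fit.converged:
                failures.append(f"{rec.sample_id}/{key}: {fit.message}")
                continue
            if n_comp == 2:
                row[f"{t_name}a_2MHz"] = fit.components[0].time_constant * 1e3
                row[f"{t_name}b_2MHz"] = fit.components[1].time_constant * 1e3
            else:
                row[f"{t_name}_100MHz"] = fit.components[0].time_constant * 1e3
        rows.append(row)
    tidy = pd.DataFrame(rows)
    for q in QUANTITIES:
        if q not in tidy.columns:
            tidy[q] = math.nan
    return records, tidy[["sample_id", "group", *QUANTITIES]], failures


def _range_overlap(lo1, hi1, lo2, hi2) -> float:
    inter = max(0.0, min(hi1, hi2) - max(lo1, lo2))
    union = max(hi1, hi2) - min(lo1, lo2)
    if union == 0:
        return 1.0  # both ranges are the same single point
    return inter / union


def summarize_groups(
    tidy: pd.DataFrame,
    threshold: float = DEFAULT_OVERLAP_THRESHOLD,
) -> CohortComparison:
    """Per-group descriptive statistics and the range-overlap verdict.

    Requires exactly two groups (each with at least one fitted sample);
    a group with fewer than two values for some quantity has undefined
    SD there and is flagged.  The verdict is "similar" when the range
    overlap reaches ``threshold`` for every quantity, else "distinct".
    """
    groups = sorted(g for g in tidy["group"].unique())
    if len(groups) != 2:
        raise CohortError(f"need exactly 2 groups, got {groups}")

    summaries: dict[str, GroupSummary] = {}
    for g in groups:
        sub = tidy[tidy["group"] == g]
        stats: dict[str, dict[str, float]] = {}
        flags: list[str] = []
        for q in QUANTITIES:
            vals = sub[q].dropna().to_numpy()
            if vals.size == 0:
                stats[q] = dict(
                    count=0, mean=math.nan, sd=math.nan, min=math.nan, max=math.nan
                )
                flags.append(f"{q}: no values")
                continue
            sd = float(np.std(vals, ddof=1)) if vals.size >= 2 else math.nan
            if vals.size < 2:
                flags.append(f"{q}: SD undefined (n={vals.size})")
            stats[q] = dict(
                count=int(vals.size),
                mean=float(np.mean(vals)),
                sd=sd,
                min=float(np.min(vals)),
                max=float(np.max(vals)),
            )
        summaries[g] = GroupSummary(group=g, stats=stats, flags=flags)

    g1, g2 = groups
    overlap: dict[str, float] = {}
    for q in QUANTITIES:
        s1, s2 = summaries[g1].stats[q], summaries[g2].stats[q]
        if s1["count"] == 0 or s2["count"] == 0:
            overlap[q] = math.nan
            continue
        overlap[q] = _range_overlap(s1["min"], s1["max"], s2["min"], s2["max"])
    for g in groups:
        summaries[g].overlap = dict(overlap)

    finite = [v for v in overlap.values() if not math.isnan(v)]
    verdict = (
        "similar" if finite and all(v >= threshold for v in finite) else "distinct"
    )
    return CohortComparison(
        summaries=summaries, overlap=overlap, verdict=verdict, threshold=threshold
    )
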