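"""Longitudinal response classification for day-indexed network summaries.

Imaged tumour vasculature is summarised per day by a vessel count and
a perfused-vessel count (or a precomputed perfusion fraction).  The
pruning phase runs from the day of irradiation (Day 0) to the last day
on which the vessel count decreased, before the first subsequent
increase (the onset of angiogenic regrowth).  A vasculature is
classified as group A if its perfusion fraction rose over that phase
and group B otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Sequence

import pandas as pd

__all__ = [
    "NetworkTimeSeries",
    "ResponseClassification",
    "NoPruningPhaseError",
    "pruning_phase_end",
    "classify_response",
    "classify_table",
]


class NoPruningPhaseError(ValueError):
    """The vessel count never decreased: no pruning phase exists."""


@dataclass(frozen=True)
class NetworkTimeSeries:
    """Day-indexed vessel and perfusion counts for one vasculature.

    ``days`` must be strictly increasing and include Day 0 (the day of
    irradiation).  Perfusion may be given as raw perfused counts or as
    precomputed fractions; counts take precedence when both are
    present.
    """

    label: str
    days: Sequence[int]
    n_vessels_by_day: Sequence[int]
    perfused_by_day: Optional[Sequence[int]] = None
    perfusion_fraction_by_day: Optional[Sequence[float]] = None

    def validate(self) -> None:
        days = list(self.days)
        if len(days) < 2:
            raise ValueError("need at least two recorded days")
        if any(b <= a for a, b in zip(days, days[1:])):
            raise ValueError("days must be strictly increasing")
        if 0 not in days:
            raise ValueError("Day 0 (irradiation) must be present")
        if len(self.n_vessels_by_day) != len(days):
            raise ValueError("n_vessels_by_day length mismatch")
        if self.perfused_by_day is None and self.perfusion_fraction_by_day is None:
            raise ValueError("need perfused counts or perfusion fractions")
        if self.perfused_by_day is not None:
            if len(self.perfused_by_day) != len(days):
                raise ValueError("perfused_by_day length mismatch")
            for p, n in zip(self.perfused_by_day, self.n_vessels_by_day):
                if p > n:
                    raise ValueError("perfused count exceeds vessel count")

    def perfusion_fraction(self, day: int) -> float:
        i = list(self.days).index(day)
        if self.perfused_by_day is not None:
            return self.perfused_by_day[i] / self.n_vessels_by_day[i]
        return float(self.perfusion_fraction_by_day[i])


@dataclass(frozen=True)
class ResponseClassification:
    label: str
    final_day: int
    p_day0: float
    p_final: float
    delta_P: float
    delta_pct_P: Optional[float]
    group: str


def pruning_phase_end(series: NetworkTimeSeries) -> int:
    """Last day on which the vessel count decreased, before regrowth.

    Scans forward from Day 0; a decrease relative to the previous
    recorded day extends the phase, and the first increase after at
    least one decrease ends the scan.  Raises
    :class:`NoPruningPhaseError` if the count never decreases.
    """
    series.validate()
    days = list(series.days)
    counts = list(series.n_vessels_by_day)
    start = days.index(0)
    last_decrease: Optional[int] = None
    for i in range(start + 1, len(days)):
        if counts[i] < counts[i - 1]:
            last_decrease = days[i]
        elif counts[i] > counts[i - 1] and last_decrease is not None:
            break
    if last_decrease is None:
        raise NoPruningPhaseError(
            f"{series.label}: vessel count never decreased after Day 0")
    return last_decrease


def classify_response(series: NetworkTimeSeries) -> ResponseClassification:
    """Perfusion change over the pruning phase and the group label.

    ``ΔP = P(final day) − P(Day 0)`` and its relative counterpart
    ``Δ%P = ΔP/P(Day 0) × 100``; the group is A for a strict increase
    and B otherwise (a tie counts as non-increase).  When P(Day 0) is
    zero the relative measure is undefined and reported as ``None``.
    """
    final_day = pruning_phase_end(series)
    p0 = series.perfusion_fraction(0)
    p_final = series.perfusion_fraction(final_day)
    delta = p_final - p0
    delta_pct = delta / p0 * 100.0 if p0 > 0 else None
    return ResponseClassification(
        label=series.label,
        final_day=final_day,
        p_day0=p0,
        p_final=p_final,
        delta_P=delta,
        delta_pct_P=delta_pct,
        group="A" if delta > 0 else "B",
    )


def classify_table(csv_path: str | Path) -> pd.DataFrame:
    """Classify every vasculature in a long-format CSV.

    Expects columns ``label, day, n_vessels, n_perfused``; returns one
    row per label with the perfusion fractions, differences, and group.
    """
    df = pd.read_csv(csv_path)
    required = {"label", "day", "n_vessels", "n_perfused"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns {sorted(missing)}")
    rows = []
    for label, sub in df.groupby("label", sort=True):
        sub = sub.sort_values("day")
        series = NetworkTimeSeries(
            label=str(label),
            days=sub["day"].tolist(),
            n_vessels_by_day=sub["n_vessels"].tolist(),
            perfused_by_day=sub["n_perfused"].tolist(),
        )
        r = classify_response(series)
        rows.append({"label": r.label, "P_day0": r.p_day0,
                     "P_final": r.p_final, "delta_P": r.delta_P,
                     "delta_pct_P": r.delta_pct_P, "group": r.group})
    return pd.DataFrame(rows)
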