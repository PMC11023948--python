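"""Multi-period comparison of ESP decline.

Given the cumulative change indicator (ESPDcum) of two consecutive
periods per city and service, a city's trajectory is *accelerating* when
the later period deteriorates more (delta = d2 − d1 below −ε), *slowing*
when it deteriorates less (delta above +ε) and *stable* inside the ±ε
band. ε defaults to 0, in which case only an exact tie is stable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .exceptions import InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "ACCELERATING",
    "SLOWING",
    "STABLE",
    "classify_trend",
    "PeriodComparison",
    "compare_periods",
    "AggregateTrend",
    "aggregate_reduction",
    "consistency_census",
]

ACCELERATING = "accelerating"
SLOWING = "slowing"
STABLE = "stable"


def classify_trend(d1: float, d2: float, epsilon: float = 0.0) -> str:
    """Label the trajectory of decline between two periods.

    Deterioration is encoded as negative ESPDcum, so a more negative later
    value (delta < −ε) means the decline is accelerating.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be >= 0")
    if d1 is None or d2 is None or d1 != d1 or d2 != d2:
        raise InsufficientDataError("both period values are required")
    delta = d2 - d1
    if delta < -epsilon:
        return ACCELERATING
    if delta > epsilon:
        return SLOWING
    return STABLE


@dataclass(frozen=True)
class PeriodComparison:
    city: str
    service: str
    d1: float  # ESPDcum, earlier period
    d2: float  # ESPDcum, later period
    delta: float
    trend: str


def compare_periods(
    d1_table: Mapping[tuple[str, str], float],
    d2_table: Mapping[tuple[str, str], float],
    epsilon: float = 0.0,
) -> pd.DataFrame:
    """Join two period tables keyed by (city, service) into a trend table.

    Cities present in only one period are excluded and logged, mirroring
    the phased exclusion of cities that lack early-epoch data.
    """
    keys = sorted(set(d1_table) & set(d2_table))
    dropped = sorted({c for c, _ in set(d1_table) ^ set(d2_table)})
    if dropped:
        logger.info("cities missing a period, excluded from trends: %s", dropped)
    rows = []
    for city, service in keys:
        d1, d2 = float(d1_table[(city, service)]), float(d2_table[(city, service)])
        rows.append(
            PeriodComparison(
                city=city,
                service=service,
                d1=d1,
                d2=d2,
                delta=d2 - d1,
                trend=classify_trend(d1, d2, epsilon),
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass(frozen=True)
class AggregateTrend:
    """Percentage change of summed deterioration between two periods."""

    percent_change: float
    n_cities: int


def aggregate_reduction(
    comparisons: pd.DataFrame, city_subset: Optional[Iterable[str]] = None
) -> AggregateTrend:
    """Aggregate percentage change of decline over a set of cities.

    percent_change = 100·(Σd2 − Σd1)/|Σd1|: positive when the combined
    deterioration shrank (decline slowing), negative when it grew.
    """
    df = comparisons
    if city_subset is not None:
        df = df[df["city"].isin(set(city_subset))]
    s1, s2 = df["d1"].sum(), df["d2"].sum()
    if s1 == 0:
        raise InsufficientDataError(
            "aggregate reduction undefined: earlier-period sum is zero"
        )
    return AggregateTrend(
        percent_change=float(100.0 * (s2 - s1) / abs(s1)),
        n_cities=df["city"].nunique(),
    )


def consistency_census(comparisons: pd.DataFrame) -> pd.Series:
    """Per-city label over all services: always-accelerating / always-slowing / mixed."""

    def _label(trends: Sequence[str]) -> str:
        if all(t == ACCELERATING for t in trends):
            return "always-accelerating"
        if all(t == SLOWING for t in trends):
            return "always-slowing"
        return "mixed"

    return comparisons.groupby("city")["trend"].agg(_label).rename("consistency")
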