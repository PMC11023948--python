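"""Pearson correlation of indicator dynamics with city covariates.

Covariates are socio-economic and environmental descriptors per city:
population growth ratio (%), urban expansion ratio (%), population
density (persons/km²), GDP per capita, latitude (°), yearly sunny hours
and mean annual temperature (°C). Correlations are computed on
pairwise-complete observations (city panels differ per factor) and the
coefficient is reported raw — p-values accompany it but are never used
to filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import AlignmentError, InsufficientDataError

logger = logging.getLogger(__name__)

__all__ = [
    "COVARIATE_COLUMNS",
    "CorrelationResult",
    "pearson",
    "correlate_indicators",
]

COVARIATE_COLUMNS = (
    "population_growth_ratio",
    "urban_expansion_ratio",
    "population_density",
    "gdp_per_capita",
    "latitude",
    "sunny_hours",
    "mean_temperature",
)


@dataclass(frozen=True)
class CorrelationResult:
    indicator: str
    covariate: str
    r: float  # NaN when undefined (constant input)
    n_pairs: int
    p_value: float


def pearson(
    x: Sequence[float],
    y: Sequence[float],
    indicator: str = "x",
    covariate: str = "y",
) -> CorrelationResult:
    """Product-moment correlation on pairwise-complete pairs.

    Missing values (NaN) are deleted pairwise; at least 3 complete pairs
    are required. A constant vector leaves r undefined (NaN, logged)
    rather than raising.
    """
    xa, ya = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if xa.shape != ya.shape:
        raise ValueError("x and y must have equal length")
    keep = ~(np.isnan(xa) | np.isnan(ya))
    xa, ya = xa[keep], ya[keep]
    n = int(xa.size)
    if n < 3:
        raise InsufficientDataError(
            f"pearson({indicator}, {covariate}): {n} complete pairs, need >= 3"
        )
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        logger.warning(
            "pearson(%s, %s): constant vector, correlation undefined", indicator, covariate
        )
        return CorrelationResult(indicator, covariate, float("nan"), n, float("nan"))
    res = stats.pearsonr(xa, ya)
    return CorrelationResult(indicator, covariate, float(res.statistic), n, float(res.pvalue))


def correlate_indicators(
    indicator_table: pd.DataFrame,
    covariates: pd.DataFrame,
    pairs: Optional[Iterable[tuple[str, str]]] = None,
    city_col: str = "city",
) -> pd.DataFrame:
    """Correlate indicator columns with covariate columns across cities.

    Both tables carry one row per city (``city_col``). ``pairs`` lists the
    (indicator column, covariate column) combinations to evaluate; by
    default every numeric indicator column is crossed with every known
    covariate column present. Output is a long-format table: indicator,
    covariate, r, n_pairs, p_value.
    """
    merged = indicator_table.merge(covariates, on=city_col, how="inner", suffixes=("", "_cov"))
    if merged.empty:
        raise AlignmentError("no overlapping cities between indicator and covariate tables")
    if pairs is None:
        ind_cols = [
            c
            for c in indicator_table.columns
            if c != city_col and pd.api.types.is_numeric_dtype(indicator_table[c])
        ]
        cov_cols = [c for c in COVARIATE_COLUMNS if c in covariates.columns]
        pairs = [(i, c) for i in ind_cols for c in cov_cols]
    rows = []
    for ind, cov in pairs:
        res = pearson(merged[ind], merged[cov], indicator=ind, covariate=cov)
        rows.append(res.__dict__)
    return pd.DataFrame(rows)
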