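"""The five ESP indicators and change-count summaries.

Let S(c, e) be the matrix score of LULC class c for service e, A_p the
area of patch p (ha), A_tot the study-area surface and A_tot.ch the total
transformed surface. The indicators are:

* ESPcum   — cumulative potential: Σ S(c_p, e)·A_p, optionally divided by
  A_tot (the *density* form, a per-hectare score in [5, 100]).
* ESPD_p   — per-patch potential change: S(new) − S(old), area-free.
* ESPDcum  — cumulative change: Σ ESPD_p·A_p, optionally / A_tot.
* ESPDmean — arithmetic mean of ESPD_p over altered patches.
* ESPDch.i — area-weighted mean change over the altered surface only:
  Σ ESPD_p·A_p / A_tot.ch.

Negative change values indicate deterioration of potential. Totals
(score·ha) support within-city bookkeeping; densities are comparable
across cities of different size.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Iterable, Optional, Sequence, Union

import pandas as pd

from .exceptions import EmptyInputError, InsufficientDataError
from .geodata import (
    SCOPE_URBAN,
    ChangeRecord,
    M2_PER_HA,
    Mosaic,
)
from .matrix import ESCode, ESPMatrix

__all__ = [
    "esp_cum",
    "espd_p",
    "espd_cum",
    "espd_mean",
    "espd_chi",
    "count_changes",
    "change_intensity",
    "IndicatorResult",
    "compute_all",
]


def esp_cum(
    mosaic: Mosaic,
    m: ESPMatrix,
    e: Union[ESCode, str],
    normalization: str = "total",
) -> float:
    """Cumulative ESP of a mosaic for one service.

    ``total`` returns Σ S·A_p in score·ha; ``density`` divides by A_tot,
    giving an area-weighted mean score bounded by the matrix range.
    """
    if mosaic.n == 0:
        raise EmptyInputError("esp_cum: empty mosaic")
    total = sum(m.lookup(p.lulc, e) * p.area for p in mosaic.patches)
    if normalization == "total":
        return float(total)
    if normalization == "density":
        return float(total / mosaic.a_tot)
    raise ValueError(f"unknown normalization {normalization!r}")


def espd_p(rec: ChangeRecord, m: ESPMatrix, e: Union[ESCode, str]) -> float:
    """Per-patch potential change: new score minus old score (area-free)."""
    return m.lookup(rec.new_lulc, e) - m.lookup(rec.old_lulc, e)


def espd_cum(
    records: Sequence[ChangeRecord],
    a_tot: float,
    m: ESPMatrix,
    e: Union[ESCode, str],
    normalization: str = "total",
) -> float:
    """Cumulative potential change over a change set.

    ``total`` is Σ ESPD_p·A_p (score·ha); ``density`` divides by ``a_tot``.
    An empty change set is a valid no-change case and returns 0.
    """
    if a_tot <= 0:
        raise ValueError("a_tot must be positive")
    total = sum(espd_p(r, m, e) * r.area for r in records)
    if normalization == "total":
        return float(total)
    if normalization == "density":
        return float(total / a_tot)
    raise ValueError(f"unknown normalization {normalization!r}")


def espd_mean(
    records: Sequence[ChangeRecord],
    m: ESPMatrix,
    e: Union[ESCode, str],
    area_weighted: bool = False,
) -> float:
    """Mean potential change per altered patch.

    The default is the plain arithmetic mean of the area-free ESPD_p
    values (zero-change records count in the denominator). With
    ``area_weighted=True`` each patch contributes ESPD_p·A_p instead,
    i.e. the mean of per-patch change totals.
    """
    if not records:
        raise InsufficientDataError("espd_mean undefined for an empty change set")
    if area_weighted:
        return float(sum(espd_p(r, m, e) * r.area for r in records) / len(records))
    return float(sum(espd_p(r, m, e) for r in records) / len(records))


def espd_chi(
    records: Sequence[ChangeRecord], m: ESPMatrix, e: Union[ESCode, str]
) -> float:
    """Change impact: area-weighted mean ESPD_p over the altered surface only."""
    if not records:
        raise InsufficientDataError("espd_chi undefined for an empty change set")
    a_ch = sum(r.area for r in records)
    return float(sum(espd_p(r, m, e) * r.area for r in records) / a_ch)


def count_changes(
    records: Sequence[ChangeRecord], m: ESPMatrix, e: Union[ESCode, str]
) -> tuple[int, int]:
    """(n_changed, n_nonzero): all records vs. records with ESPD_p != 0.

    Transitions between classes that share a score for the service (common
    for drinking water, where most classes sit at the floor value) change
    the land cover without affecting the indicator; the non-zero count
    isolates the alterations that actually moved the potential.
    """
    n_changed = len(records)
    n_nonzero = sum(1 for r in records if espd_p(r, m, e) != 0)
    return n_changed, n_nonzero


#: default class grouping for change_intensity: artificial surfaces are the
#: 1xxxx codes; natural, semi-natural and agricultural surfaces the rest.
ARTIFICIAL_CODES = frozenset(
    {
        "11100", "11210", "11220", "11230", "11240", "11300", "12100", "12210",
        "12220", "12230", "12300", "12400", "13100", "13300", "13400", "14100",
        "14200",
    }
)
NATURAL_CODES = frozenset(
    {"21000", "22000", "23000", "24000", "25000", "31000", "32000", "33000",
     "40000", "50000"}
)


def change_intensity(
    records: Sequence[ChangeRecord],
    a_tot: float,
    natural: frozenset[str] = NATURAL_CODES,
    artificial: frozenset[str] = ARTIFICIAL_CODES,
) -> float:
    """Artificialization intensity in m² of qualifying change per ha of study area.

    A record qualifies when its previous class is natural/semi-natural (or
    agricultural) and its new class is artificial. The class grouping is a
    configurable table.
    """
    if a_tot <= 0:
        raise ValueError("a_tot must be positive")
    qualifying = sum(
        r.area for r in records if r.old_lulc in natural and r.new_lulc in artificial
    )
    return float(qualifying * M2_PER_HA / a_tot)


@dataclass(frozen=True)
class IndicatorResult:
    """All indicator outputs for one (city, scope, service) cell."""

    city: str
    scope: str  # 'urban' or 'metropolitan'
    service: str
    epoch_old: str
    epoch_new: str
    espcum_old_total: float
    espcum_old_density: float
    espcum_total: float
    espcum_density: float
    espdcum_total: float
    espdcum_density: float
    espdmean: Optional[float]
    espd_chi: Optional[float]
    n_changed: int
    n_nonzero: int
    a_tot: float
    a_tot_ch: float
    change_intensity: float


def _scope_view(mosaic: Optional[Mosaic], records, scope: str):
    """Restrict mosaic/records to a reporting scope.

    'urban' keeps the urban-core tags; 'metropolitan' is the full set
    (urban core plus metropolitan remainder).
    """
    if scope == "metropolitan":
        return mosaic, list(records)
    sub = mosaic.subset(SCOPE_URBAN) if mosaic is not None else None
    return sub, [r for r in records if r.scope == SCOPE_URBAN]


def compute_all(
    city: str,
    old_mosaic: Optional[Mosaic],
    new_mosaic: Optional[Mosaic],
    records: Sequence[ChangeRecord],
    m: ESPMatrix,
    services: Optional[Iterable[Union[ESCode, str]]] = None,
    scopes: Sequence[str] = ("urban", "metropolitan"),
) -> pd.DataFrame:
    """Compute every indicator for one city, all scopes and services.

    Mosaics must already be scope-tagged (see
    :func:`espdyn.geodata.scope_patches`) when the urban scope is
    requested. Either mosaic may be omitted (``None``) for a pure
    change-product workflow; ESPcum columns are then NaN. Output rows are
    deterministically ordered by (scope, service).
    """
    svc = [ESCode.coerce(s) for s in (services or list(ESCode))]
    rows: list[IndicatorResult] = []
    for scope in scopes:
        om, recs = _scope_view(old_mosaic, records, scope)
        nm, _ = _scope_view(new_mosaic, [], scope)
        if nm is not None and nm.n:
            a_tot = nm.a_tot
        elif om is not None and om.n:
            a_tot = om.a_tot
        else:
            a_tot = float("nan")
        a_ch = float(sum(r.area for r in recs))
        for e in svc:
            has_old = om is not None and om.n > 0
            has_new = nm is not None and nm.n > 0
            n_changed, n_nonzero = count_changes(recs, m, e)
            rows.append(
                IndicatorResult(
                    city=city,
                    scope=scope,
                    service=e.value,
                    epoch_old=old_mosaic.epoch if old_mosaic else "",
                    epoch_new=new_mosaic.epoch if new_mosaic else "",
                    espcum_old_total=esp_cum(om, m, e, "total") if has_old else math.nan,
                    espcum_old_density=esp_cum(om, m, e, "density") if has_old else math.nan,
                    espcum_total=esp_cum(nm, m, e, "total") if has_new else math.nan,
                    espcum_density=esp_cum(nm, m, e, "density") if has_new else math.nan,
                    espdcum_total=espd_cum(recs, a_tot, m, e, "total")
                    if a_tot == a_tot
                    else math.nan,
                    espdcum_density=espd_cum(recs, a_tot, m, e, "density")
                    if a_tot == a_tot
                    else math.nan,
                    espdmean=espd_mean(recs, m, e) if recs else None,
                    espd_chi=espd_chi(recs, m, e) if recs else None,
                    n_changed=n_changed,
                    n_nonzero=n_nonzero,
                    a_tot=a_tot,
                    a_tot_ch=a_ch,
                    change_intensity=change_intensity(recs, a_tot)
                    if a_tot == a_tot
                    else math.nan,
                )
            )
    return pd.DataFrame([asdict(r) for r in rows])
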