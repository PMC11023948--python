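"""Patch mosaics, change layers and spatial scoping.

A *patch* is a polygon of homogeneous land use — the minimum analysis
unit. A *mosaic* is the set of patches covering one study area at one
epoch. A *change record* mirrors one row of a land-cover change product:
the transformed patch's previous and current class codes plus its area.

Geometric inputs are read from GeoJSON (or constructed in memory with
shapely); attribute tables in delimited text support a geometry-free
workflow. All geometric computation assumes coordinates in a projected
equal-area CRS with metre units (the Urban Atlas native LAEA family), so
planar areas divided by 10 000 are hectares. Inputs in geographic
coordinates must be projected upstream.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from shapely.geometry import shape as _shape
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .exceptions import (
    AreaError,
    CoverageError,
    EmptyInputError,
    ModeError,
)
from .matrix import normalize_code

logger = logging.getLogger(__name__)

__all__ = [
    "M2_PER_HA",
    "Patch",
    "Mosaic",
    "ChangeRecord",
    "BoundarySet",
    "read_mosaic",
    "read_change_layer",
    "resolve_area",
    "scope_patches",
    "derive_change",
    "write_mosaic",
]

M2_PER_HA = 10_000.0

SCOPE_URBAN = "urban"
SCOPE_METRO = "metro_remainder"


@dataclass(frozen=True)
class Patch:
    """One homogeneous LULC polygon: class code, area in ha, optional geometry."""

    patch_id: str
    lulc: str
    area: float  # hectares
    geometry: Optional[BaseGeometry] = None
    scope: Optional[str] = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise AreaError(f"patch {self.patch_id}: area must be > 0, got {self.area}")
        object.__setattr__(self, "lulc", normalize_code(self.lulc))


@dataclass(frozen=True)
class BoundarySet:
    """Urban-core and functional-urban-area (FUA) boundaries for one city."""

    urban_core: BaseGeometry
    fua: BaseGeometry
    city: str = ""

    def __post_init__(self) -> None:
        outside = self.urban_core.difference(self.fua).area
        if self.urban_core.area > 0 and outside / self.urban_core.area > 0.005:
            logger.warning(
                "boundary set %s: %.2f%% of the urban core falls outside the FUA",
                self.city,
                100 * outside / self.urban_core.area,
            )


@dataclass(frozen=True)
class Mosaic:
    """All patches of one study area at one epoch."""

    patches: tuple[Patch, ...]
    epoch: str = ""
    boundary_set: Optional[BoundarySet] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "patches", tuple(self.patches))
        ids = [p.patch_id for p in self.patches]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate patch ids in mosaic: {dupes}")

    @property
    def a_tot(self) -> float:
        """Total surface of the study area in hectares."""
        return float(sum(p.area for p in self.patches))

    @property
    def n(self) -> int:
        return len(self.patches)

    def subset(self, scope: str) -> "Mosaic":
        return Mosaic(
            patches=tuple(p for p in self.patches if p.scope == scope),
            epoch=self.epoch,
            boundary_set=self.boundary_set,
        )

    def class_census(self) -> pd.Series:
        """Total area (ha) per LULC class."""
        s = pd.Series(dtype=float)
        for p in self.patches:
            s[p.lulc] = s.get(p.lulc, 0.0) + p.area
        return s.sort_index()


@dataclass(frozen=True)
class ChangeRecord:
    """One transformed patch: previous code, current code, area in ha."""

    patch_id: str
    old_lulc: str
    new_lulc: str
    area: float  # hectares
    scope: Optional[str] = None
    geometry: Optional[BaseGeometry] = None

    def __post_init__(self) -> None:
        if self.area <= 0:
            raise AreaError(f"change record {self.patch_id}: area must be > 0")
        object.__setattr__(self, "old_lulc", normalize_code(self.old_lulc))
        object.__setattr__(self, "new_lulc", normalize_code(self.new_lulc))
        if self.old_lulc == self.new_lulc:
            raise ValueError(
                f"change record {self.patch_id}: old and new class are identical "
                f"({self.old_lulc}); unchanged rows must be dropped upstream"
            )


def resolve_area(
    *,
    geometry: Optional[BaseGeometry] = None,
    area_attr: Optional[float] = None,
    policy: str = "geometry-first",
    patch_id: str = "?",
) -> float:
    """Resolve a patch area in hectares from geometry and/or an attribute.

    Under ``geometry-first`` the planar geometry area wins and a
    disagreement beyond 1% with the attribute is logged; under
    ``attribute-first`` the attribute wins when present.
    """
    if policy not in ("geometry-first", "attribute-first"):
        raise ValueError(f"unknown area policy {policy!r}")
    geom_ha = geometry.area / M2_PER_HA if geometry is not None else None
    if geom_ha is None and area_attr is None:
        raise AreaError(f"patch {patch_id}: neither geometry nor area attribute available")
    if policy == "attribute-first" and area_attr is not None:
        return float(area_attr)
    if geom_ha is None:
        return float(area_attr)
    if area_attr is not None and area_attr > 0:
        rel = abs(geom_ha - area_attr) / area_attr
        if rel > 0.01:
            logger.warning(
                "patch %s: geometry area %.4f ha disagrees with attribute %.4f ha "
                "(%.1f%%); using geometry",
                patch_id, geom_ha, area_attr, 100 * rel,
            )
    return float(geom_ha)


def _read_features(path: Union[str, Path]) -> list[dict]:
    path = Path(path)
    if path.suffix.lower() in (".geojson", ".json"):
        payload = json.loads(path.read_text())
        return payload.get("features", [])
    raise ValueError(
        f"unsupported vector format {path.suffix!r}: use GeoJSON, or a CSV "
        "attribute table via the tabular reader"
    )


def read_mosaic(
    path: Union[str, Path],
    code_field: str = "code",
    epoch: str = "",
    id_field: Optional[str] = None,
    area_field: Optional[str] = None,
    policy: str = "geometry-first",
) -> Mosaic:
    """Read a patch mosaic from a GeoJSON layer or a CSV attribute table.

    One patch per feature/row; class codes are normalized to 5-digit form
    and validated against the nomenclature. Invalid polygon geometries are
    repaired with a zero-width buffer.
    """
    path = Path(path)
    patches: list[Patch] = []
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path, dtype={code_field: str})
        if df.empty:
            raise EmptyInputError(f"{path}: empty attribute table")
        for i, row in df.iterrows():
            pid = str(row[id_field]) if id_field else str(i)
            area = resolve_area(
                area_attr=float(row[area_field or "area"]), policy=policy, patch_id=pid
            )
            scope = row["scope"] if "scope" in df.columns and pd.notna(row["scope"]) else None
            patches.append(
                Patch(patch_id=pid, lulc=str(row[code_field]), area=area, scope=scope)
            )
    else:
        features = _read_features(path)
        if not features:
            raise EmptyInputError(f"{path}: no features in layer")
        for i, feat in enumerate(features):
            props = feat.get("properties", {})
            pid = str(props[id_field]) if id_field else str(props.get("id", i))
            geom = _shape(feat["geometry"])
            if not geom.is_valid:
                geom = geom.buffer(0)
            attr = float(props[area_field]) if area_field and area_field in props else None
            area = resolve_area(geometry=geom, area_attr=attr, policy=policy, patch_id=pid)
            patches.append(
                Patch(
                    patch_id=pid,
                    lulc=str(props[code_field]),
                    area=area,
                    geometry=geom,
                    scope=props.get("scope"),
                )
            )
    return Mosaic(patches=tuple(patches), epoch=epoch)


def read_change_layer(
    path: Union[str, Path],
    old_field: str = "code_old",
    new_field: str = "code_new",
    id_field: Optional[str] = None,
    area_field: Optional[str] = None,
    policy: str = "geometry-first",
) -> list[ChangeRecord]:
    """Read a change product; rows with identical old/new code are dropped.

    An empty file is a valid "no change" case and yields an empty list.
    The number of dropped unchanged rows is logged.
    """
    path = Path(path)
    records: list[ChangeRecord] = []
    dropped = 0

    def _append(pid, old, new, area, geom=None, scope=None):
        nonlocal dropped
        if normalize_code(old) == normalize_code(new):
            dropped += 1
            return
        records.append(
            ChangeRecord(
                patch_id=pid, old_lulc=old, new_lulc=new, area=area,
                geometry=geom, scope=scope,
            )
        )

    if path.suffix.lower() == ".csv":
        try:
            df = pd.read_csv(path, dtype={old_field: str, new_field: str})
        except pd.errors.EmptyDataError:
            return []
        for i, row in df.iterrows():
            pid = str(row[id_field]) if id_field else str(i)
            area = resolve_area(
                area_attr=float(row[area_field or "area"]), policy=policy, patch_id=pid
            )
            scope = row["scope"] if "scope" in df.columns and pd.notna(row["scope"]) else None
            _append(pid, str(row[old_field]), str(row[new_field]), area, scope=scope)
    else:
        for i, feat in enumerate(_read_features(path)):
            props = feat.get("properties", {})
            pid = str(props[id_field]) if id_field else str(props.get("id", i))
            geom = _shape(feat["geometry"])
            if not geom.is_valid:
                geom = geom.buffer(0)
            attr = float(props[area_field]) if area_field and area_field in props else None
            area = resolve_area(geometry=geom, area_attr=attr, policy=policy, patch_id=pid)
            _append(pid, str(props[old_field]), str(props[new_field]), area, geom,
                    scope=props.get("scope"))
    if dropped:
        logger.info("%s: dropped %d unchanged (old==new) rows", path, dropped)
    return records


def _scope_one(item, core: BaseGeometry, mode: str):
    """Yield item(s) with scope tags; may split a patch at the core boundary."""
    geom = item.geometry
    if mode == "centroid":
        if geom is None:
            raise ModeError(f"{item.patch_id}: centroid scoping needs geometry")
        tag = SCOPE_URBAN if core.contains(geom.centroid) else SCOPE_METRO
        yield replace(item, scope=tag)
        return
    if geom is None:
        raise ModeError(f"{item.patch_id}: split scoping needs geometry")
    inside = geom.intersection(core)
    frac = inside.area / geom.area if geom.area > 0 else 0.0
    if frac >= 1 - 1e-9:
        yield replace(item, scope=SCOPE_URBAN)
    elif frac <= 1e-9:
        yield replace(item, scope=SCOPE_METRO)
    else:
        outside = geom.difference(core)
        # attribute area is allocated by geometric fraction so split areas
        # sum to the original exactly
        yield replace(
            item,
            patch_id=f"{item.patch_id}@u",
            area=item.area * frac,
            geometry=inside,
            scope=SCOPE_URBAN,
        )
        yield replace(
            item,
            patch_id=f"{item.patch_id}@m",
            area=item.area * (1 - frac),
            geometry=outside,
            scope=SCOPE_METRO,
        )


def scope_patches(
    obj: Union[Mosaic, Sequence[ChangeRecord]],
    boundaries: BoundarySet,
    mode: str = "split",
):
    """Tag patches/records as urban-core or metropolitan-remainder.

    ``split`` (default) partitions boundary-straddling geometries at the
    urban-core boundary, conserving total area; ``centroid`` assigns each
    item whole to the side holding its centroid. The metropolitan level
    is the union of both scopes, so no area is discarded.
    """
    if mode not in ("split", "centroid"):
        raise ModeError(f"unknown scoping mode {mode!r}")
    core = boundaries.urban_core
    if isinstance(obj, Mosaic):
        out: list[Patch] = []
        for p in obj.patches:
            out.extend(_scope_one(p, core, mode))
        return Mosaic(patches=tuple(out), epoch=obj.epoch, boundary_set=boundaries)
    out_r: list[ChangeRecord] = []
    for r in obj:
        out_r.extend(_scope_one(r, core, mode))
    return out_r


def derive_change(old: Mosaic, new: Mosaic, *, tolerance: float = 0.005) -> list[ChangeRecord]:
    """Derive change records from two epochs of the same study area.

    With geometries on both sides this is a boolean-difference overlay:
    every region whose class differs between the epochs becomes a record.
    Without geometries, patches are joined on ``patch_id`` and a class
    flip yields one full-area record. Identical coverage is asserted
    up front (total areas within ``tolerance``, relative).
    """
    if old.a_tot <= 0 or new.a_tot <= 0:
        raise EmptyInputError("derive_change requires non-empty mosaics")
    if abs(old.a_tot - new.a_tot) / old.a_tot > tolerance:
        raise CoverageError(
            f"mosaics do not cover the same area: {old.a_tot:.3f} vs {new.a_tot:.3f} ha"
        )
    have_geom = all(p.geometry is not None for p in old.patches) and all(
        p.geometry is not None for p in new.patches
    )
    records: list[ChangeRecord] = []
    if have_geom:
        old_geoms = [p.geometry for p in old.patches]
        tree = STRtree(old_geoms)
        k = 0
        for np_ in new.patches:
            for idx in tree.query(np_.geometry):
                op = old.patches[int(idx)]
                if op.lulc == np_.lulc:
                    continue
                inter = np_.geometry.intersection(op.geometry)
                area_ha = inter.area / M2_PER_HA
                if area_ha <= 1e-9:
                    continue
                records.append(
                    ChangeRecord(
                        patch_id=f"ch{k}:{op.patch_id}->{np_.patch_id}",
                        old_lulc=op.lulc,
                        new_lulc=np_.lulc,
                        area=area_ha,
                        scope=np_.scope,
                        geometry=inter,
                    )
                )
                k += 1
    else:
        old_by_id = {p.patch_id: p for p in old.patches}
        for np_ in new.patches:
            op = old_by_id.get(np_.patch_id)
            if op is None or op.lulc == np_.lulc:
                continue
            if op.area > 0 and abs(op.area - np_.area) / op.area > 0.001:
                logger.warning(
                    "patch %s: area changed %.4f -> %.4f ha across epochs; "
                    "using the new-epoch area",
                    np_.patch_id, op.area, np_.area,
                )
            records.append(
                ChangeRecord(
                    patch_id=np_.patch_id,
                    old_lulc=op.lulc,
                    new_lulc=np_.lulc,
                    area=np_.area,
                    scope=np_.scope,
                )
            )
    return records


def write_mosaic(mosaic: Mosaic, path: Union[str, Path]) -> None:
    """Write a mosaic to GeoJSON (with geometry) or CSV (without)."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame(
            {
                "patch_id": [p.patch_id for p in mosaic.patches],
                "code": [p.lulc for p in mosaic.patches],
                "area": [p.area for p in mosaic.patches],
                "scope": [p.scope for p in mosaic.patches],
            }
        ).to_csv(path, index=False)
        return
    features = []
    for p in mosaic.patches:
        if p.geometry is None:
            raise AreaError(f"patch {p.patch_id} has no geometry; write to CSV instead")
        features.append(
            {
                "type": "Feature",
                "properties": {
                    "id": p.patch_id,
                    "code": p.lulc,
                    "area": p.area,
                    "scope": p.scope,
                },
                "geometry": p.geometry.__geo_interface__,
            }
        )
    path.write_text(json.dumps({"type": "FeatureCollection", "features": features}))


def change_records_to_frame(records: Iterable[ChangeRecord]) -> pd.DataFrame:
    """Tabular view of change records (one row per record)."""
    return pd.DataFrame(
        {
            "patch_id": [r.patch_id for r in records],
            "code_old": [r.old_lulc for r in records],
            "code_new": [r.new_lulc for r in records],
            "area": [r.area for r in records],
            "scope": [r.scope for r in records],
        }
    )
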