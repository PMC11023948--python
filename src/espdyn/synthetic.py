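"""Synthetic study scenarios with known ground truth.

Real inputs to the pipeline are multi-epoch Urban Atlas patch mosaics,
change products, city boundaries and covariate tables. This module
generates structurally equivalent synthetic inputs so every stage is
testable without external data:

* mosaics — patches with classes drawn from a configurable census and
  lognormal areas, laid out either as a plain attribute table or as
  non-overlapping rectangular strips with a rectangular urban-core
  boundary (geometry mode);
* transitions — per-period class conversions driven by a transition
  weight table whose defaults encode urbanization pressure (forests,
  pastures and herbaceous land converting to extraction/dump sites,
  construction, industry and dense discontinuous fabric), so change
  scenarios are decline-dominated by construction;
* covariates — per-city factors built to a target Pearson correlation ρ
  with a designated indicator via the standard Gaussian construction
  ρ·z + √(1−ρ²)·ε, affine-mapped to plausible ranges.

Every generator is a pure function of its spec: randomness flows from the
spec seed through per-operation spawn keys, so adding one generator call
never perturbs the draws of another.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from shapely.geometry import box
from shapely.ops import unary_union

from .exceptions import SpecError
from .geodata import (
    SCOPE_METRO,
    SCOPE_URBAN,
    BoundarySet,
    ChangeRecord,
    M2_PER_HA,
    Mosaic,
    Patch,
)
from .matrix import UA_CLASSES

__all__ = [
    "MosaicSpec",
    "TransitionSpec",
    "CovariateSpec",
    "DEFAULT_CLASS_WEIGHTS",
    "DEFAULT_TRANSITION_WEIGHTS",
    "generate_mosaic",
    "apply_transitions",
    "simulate_periods",
    "generate_covariates",
    "table1_scenario",
]

# spawn-key ids per operation: stable stream splitting
_OP_MOSAIC = 1
_OP_TRANSITION = 2
_OP_COVARIATE = 3


def _rng(seed: int, op: int, counter: int = 0) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(op, counter)))


#: default class census of a synthetic functional urban area: artificial
#: surfaces a minority share, agriculture and forest dominating the
#: hinterland — the typical composition the pipeline is pointed at.
DEFAULT_CLASS_WEIGHTS: Mapping[str, float] = {
    "11100": 0.02,
    "11210": 0.03,
    "11220": 0.03,
    "11230": 0.03,
    "11240": 0.02,
    "11300": 0.01,
    "12100": 0.04,
    "12210": 0.01,
    "12220": 0.02,
    "12230": 0.01,
    "12300": 0.005,
    "12400": 0.005,
    "13100": 0.01,
    "13300": 0.02,
    "13400": 0.01,
    "14100": 0.03,
    "14200": 0.02,
    "21000": 0.14,
    "22000": 0.03,
    "23000": 0.10,
    "24000": 0.05,
    "25000": 0.02,
    "31000": 0.20,
    "32000": 0.06,
    "33000": 0.02,
    "40000": 0.02,
    "50000": 0.04,
}

#: default per-period conversion pressure: natural and semi-natural
#: donors feeding extraction/dump sites, construction, industry and dense
#: discontinuous fabric.
_URBAN_SINKS: Mapping[str, float] = {
    "13100": 0.25,
    "13300": 0.20,
    "12100": 0.18,
    "11210": 0.12,
    "11220": 0.10,
    "12220": 0.08,
    "14200": 0.07,
}
DEFAULT_TRANSITION_WEIGHTS: Mapping[str, Mapping[str, float]] = {
    "31000": _URBAN_SINKS,
    "23000": _URBAN_SINKS,
    "32000": _URBAN_SINKS,
    "21000": _URBAN_SINKS,
    "24000": _URBAN_SINKS,
}


@dataclass(frozen=True)
class MosaicSpec:
    """Recipe for one synthetic mosaic."""

    n_patches: int = 200
    class_weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_WEIGHTS)
    )
    area_distribution: tuple = ("lognormal", 1.0, 1.0)  # ('fixed', ha) | ('lognormal', mu, sigma)
    core_fraction: float = 0.25
    layout: str = "tabular"  # 'tabular' | 'grid-geometry'
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patches < 1:
            raise SpecError("n_patches must be >= 1")
        total = sum(self.class_weights.values())
        if abs(total - 1.0) > 1e-9:
            raise SpecError(f"class_weights must sum to 1, got {total}")
        if any(w < 0 for w in self.class_weights.values()):
            raise SpecError("class_weights must be non-negative")
        for c in self.class_weights:
            if c not in UA_CLASSES:
                raise SpecError(f"unknown class code in weights: {c}")
        if not (0.0 <= self.core_fraction <= 1.0):
            raise SpecError("core_fraction must be in [0, 1]")
        if self.layout not in ("tabular", "grid-geometry"):
            raise SpecError(f"unknown layout {self.layout!r}")


@dataclass(frozen=True)
class TransitionSpec:
    """Recipe for per-period class conversions."""

    transition_weights: Mapping[str, Mapping[str, float]] = field(
        default_factory=lambda: dict(DEFAULT_TRANSITION_WEIGHTS)
    )
    change_fraction: float = 0.05
    n_periods: int = 1
    split_probability: float = 0.3  # chance that a selected patch only partially converts
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.change_fraction < 1.0):
            raise SpecError("change_fraction must be in [0, 1)")
        if not (0.0 <= self.split_probability <= 1.0):
            raise SpecError("split_probability must be in [0, 1]")
        if self.n_periods < 1:
            raise SpecError("n_periods must be >= 1")
        for old, sinks in self.transition_weights.items():
            if old not in UA_CLASSES:
                raise SpecError(f"unknown donor class {old}")
            s = sum(sinks.values())
            if abs(s - 1.0) > 1e-9:
                raise SpecError(f"transition weights for {old} sum to {s}, expected 1")
            for new in sinks:
                if new not in UA_CLASSES:
                    raise SpecError(f"transition to unknown code {new}")


@dataclass(frozen=True)
class CovariateSpec:
    """Recipe for covariates with known correlation to an indicator."""

    rho: Mapping[str, float] = field(default_factory=dict)  # covariate name -> target ρ
    seed: int = 0

    def __post_init__(self) -> None:
        for name, r in self.rho.items():
            if abs(r) > 1.0:
                raise SpecError(f"target correlation for {name} outside [-1, 1]: {r}")


_STRIP_HEIGHT_M = 1000.0


def _sample_areas(spec: MosaicSpec, rng: np.random.Generator) -> np.ndarray:
    kind = spec.area_distribution[0]
    if kind == "fixed":
        return np.full(spec.n_patches, float(spec.area_distribution[1]))
    if kind == "lognormal":
        _, mu, sigma = spec.area_distribution
        return rng.lognormal(mean=mu, sigma=sigma, size=spec.n_patches)
    raise SpecError(f"unknown area distribution {kind!r}")


def generate_mosaic(spec: MosaicSpec, epoch: str = "t0"):
    """Generate a mosaic; grid layout also returns its boundary set.

    Grid layout tiles vertical strips (width proportional to patch area,
    fixed 1 km height) left to right, with a rectangular urban core
    covering the leftmost ``core_fraction`` of the total area — an
    analytically tractable geometry for split-mode scoping. Tabular
    layout carries no geometry and tags the leading patches as urban
    until the core area share is reached.

    Returns ``(Mosaic, BoundarySet | None)``.
    """
    rng = _rng(spec.seed, _OP_MOSAIC)
    codes = list(spec.class_weights)
    probs = np.array([spec.class_weights[c] for c in codes])
    drawn = rng.choice(len(codes), size=spec.n_patches, p=probs)
    areas = _sample_areas(spec, rng)
    total = float(areas.sum())

    patches: list[Patch] = []
    if spec.layout == "grid-geometry":
        widths = areas * M2_PER_HA / _STRIP_HEIGHT_M
        x = 0.0
        for i, (ci, a, w) in enumerate(zip(drawn, areas, widths)):
            geom = box(x, 0.0, x + w, _STRIP_HEIGHT_M)
            patches.append(
                Patch(patch_id=f"p{i}", lulc=codes[ci], area=float(a), geometry=geom)
            )
            x += w
        core_x = spec.core_fraction * x
        boundaries = BoundarySet(
            urban_core=box(0.0, 0.0, core_x, _STRIP_HEIGHT_M) if core_x > 0 else box(0, 0, 0, 0),
            fua=box(0.0, 0.0, x, _STRIP_HEIGHT_M),
            city="synthetic",
        )
        return Mosaic(patches=tuple(patches), epoch=epoch), boundaries

    cum = 0.0
    for i, (ci, a) in enumerate(zip(drawn, areas)):
        scope = SCOPE_URBAN if cum < spec.core_fraction * total else SCOPE_METRO
        cum += a
        patches.append(Patch(patch_id=f"p{i}", lulc=codes[ci], area=float(a), scope=scope))
    return Mosaic(patches=tuple(patches), epoch=epoch), None


def apply_transitions(
    mosaic: Mosaic, spec: TransitionSpec, period: int = 0, epoch: str = ""
) -> tuple[Mosaic, list[ChangeRecord]]:
    """Advance a mosaic one period, returning the new mosaic and its change set.

    Patches whose class appears in the transition table are eligible;
    each is selected with the probability that makes the expected
    transformed share of the *total* area equal ``change_fraction``. A
    selected patch converts wholly, or — with ``split_probability`` —
    only a uniform fraction of it, mimicking partial patch transformation
    in real change products. The emitted records are exactly consistent
    with the two mosaics, so overlay-derived change reproduces them.
    """
    rng = _rng(spec.seed, _OP_TRANSITION, period)
    eligible = [p for p in mosaic.patches if p.lulc in spec.transition_weights]
    a_el = sum(p.area for p in eligible)
    new_patches: list[Patch] = []
    records: list[ChangeRecord] = []
    if a_el == 0 or spec.change_fraction == 0:
        return Mosaic(mosaic.patches, epoch=epoch or mosaic.epoch, boundary_set=mosaic.boundary_set), []
    # mean transformed fraction of a selected patch: 1-s + s*E[U(0.25,0.75)]
    factor = 1.0 - 0.5 * spec.split_probability
    p_sel = min(1.0, spec.change_fraction * mosaic.a_tot / (a_el * factor))

    for p in mosaic.patches:
        sinks = spec.transition_weights.get(p.lulc)
        if sinks is None or rng.random() >= p_sel:
            new_patches.append(p)
            continue
        sink_codes = list(sinks)
        new_code = sink_codes[rng.choice(len(sink_codes), p=np.array(list(sinks.values())))]
        partial = rng.random() < spec.split_probability
        frac = float(rng.uniform(0.25, 0.75)) if partial else 1.0
        conv_area = p.area * frac
        conv_geom = rem_geom = None
        if p.geometry is not None:
            minx, miny, maxx, maxy = p.geometry.bounds
            cut = maxx - (maxx - minx) * frac
            conv_geom = box(cut, miny, maxx, maxy).intersection(p.geometry)
            rem_geom = box(minx, miny, cut, maxy).intersection(p.geometry)
        converted = Patch(
            patch_id=f"{p.patch_id}#t{period}",
            lulc=new_code,
            area=conv_area,
            geometry=conv_geom,
            scope=p.scope,
        )
        new_patches.append(converted)
        if frac < 1.0:
            new_patches.append(
                Patch(
                    patch_id=p.patch_id,
                    lulc=p.lulc,
                    area=p.area - conv_area,
                    geometry=rem_geom,
                    scope=p.scope,
                )
            )
        records.append(
            ChangeRecord(
                patch_id=converted.patch_id,
                old_lulc=p.lulc,
                new_lulc=new_code,
                area=conv_area,
                scope=p.scope,
                geometry=conv_geom,
            )
        )
    return (
        Mosaic(tuple(new_patches), epoch=epoch or mosaic.epoch, boundary_set=mosaic.boundary_set),
        records,
    )


def simulate_periods(
    mosaic: Mosaic, spec: TransitionSpec, epochs: Optional[Sequence[str]] = None
) -> list[tuple[Mosaic, list[ChangeRecord]]]:
    """Run ``spec.n_periods`` consecutive transitions from a starting mosaic."""
    out = []
    current = mosaic
    for k in range(spec.n_periods):
        epoch = epochs[k] if epochs else f"t{k + 1}"
        current, recs = apply_transitions(current, spec, period=k, epoch=epoch)
        out.append((current, recs))
    return out


#: plausible affine targets (mean, sd) per covariate for readable tables
_COVARIATE_SCALES: Mapping[str, tuple[float, float]] = {
    "population_growth_ratio": (3.0, 4.0),
    "urban_expansion_ratio": (5.0, 3.0),
    "population_density": (1500.0, 700.0),
    "gdp_per_capita": (35000.0, 15000.0),
    "latitude": (50.0, 8.0),
    "sunny_hours": (1900.0, 400.0),
    "mean_temperature": (10.0, 4.0),
}


def generate_covariates(
    indicator: Union[pd.Series, Mapping[str, float]],
    spec: CovariateSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Build a covariate table with known correlation to an indicator.

    ``indicator`` maps city label to the indicator value (e.g. ESPDcum
    density). For each requested covariate with target correlation ρ, the
    standardized indicator z is mixed with fresh Gaussian noise as
    ρ·z + √(1−ρ²)·ε and affine-mapped onto a plausible covariate range.
    Returns the covariate table and a ground-truth record
    (covariate, target_rho).
    """
    s = pd.Series(indicator, dtype=float)
    if len(s) < 3:
        raise SpecError("at least 3 cities are required")
    if s.std(ddof=0) == 0:
        raise SpecError("indicator is constant; correlation targets are unattainable")
    z = (s - s.mean()) / s.std(ddof=0)
    table = pd.DataFrame({"city": s.index})
    truth_rows = []
    for k, (name, rho) in enumerate(sorted(spec.rho.items())):
        rng = _rng(spec.seed, _OP_COVARIATE, k)
        noise = rng.standard_normal(len(s))
        zc = rho * z.to_numpy() + np.sqrt(1.0 - rho**2) * noise
        mean, sd = _COVARIATE_SCALES.get(name, (0.0, 1.0))
        table[name] = mean + sd * zc
        truth_rows.append({"covariate": name, "target_rho": rho})
    return table, pd.DataFrame(truth_rows)


def table1_scenario() -> tuple[Mosaic, Mosaic, BoundarySet]:
    """The published three-patch worked example, with geometry.

    A 20 ha mosaic (one 1-ha square per grid cell): in 2012 patch P1 is
    12 ha of forest (31000), P2 5 ha of arable land (21000) and P3 3 ha
    of continuous urban fabric (11100). By 2018, 3 ha of forest became
    arable and 2 ha became urban fabric, leaving 7/8/5 ha. The boundary
    set wraps the full mosaic as FUA with a 6 ha core in the south-west
    corner.
    """
    side = 100.0  # 1 ha cells

    def cells(ij):
        return unary_union([box(i * side, j * side, (i + 1) * side, (j + 1) * side) for i, j in ij])

    fabric12 = [(0, 0), (1, 0), (2, 0)]
    arable12 = [(3, 0), (4, 0), (3, 1), (4, 1), (4, 2)]
    all_cells = [(i, j) for i in range(5) for j in range(4)]
    forest12 = [c for c in all_cells if c not in fabric12 + arable12]

    fabric18 = fabric12 + [(0, 1), (1, 1)]
    arable18 = arable12 + [(3, 2), (3, 3), (4, 3)]
    forest18 = [c for c in all_cells if c not in fabric18 + arable18]

    def mosaic(fab, ara, fo, epoch):
        return Mosaic(
            patches=(
                Patch("P1", "31000", float(len(fo)), geometry=cells(fo)),
                Patch("P2", "21000", float(len(ara)), geometry=cells(ara)),
                Patch("P3", "11100", float(len(fab)), geometry=cells(fab)),
            ),
            epoch=epoch,
        )

    boundaries = BoundarySet(
        urban_core=box(0, 0, 300, 200), fua=box(0, 0, 500, 400), city="toy"
    )
    return mosaic(fabric12, arable12, forest12, "2012"), mosaic(fabric18, arable18, forest18, "2018"), boundaries
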