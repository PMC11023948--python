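"""Expert matrix: ESP scores per (LULC class, ecosystem service) pair.

The expert-matrix method assigns each land-use/land-cover (LULC) class a
relative ecosystem-services-potential (ESP) score between 5 (minimal
potential) and 100 (maximal potential) for each ecosystem service. The
matrix used here covers the 27 Urban Atlas LULC classes and six services
shortlisted as most relevant to the urban and metropolitan context:
biodiversity integrity (I1), drinking water (P1), flood protection (R1),
air quality (R2), water purification (R3) and recreation & tourism (C1).

The bundled default matrix (``data/expert_matrix_synthetic.csv``) is a
synthetic reconstruction: it satisfies every published anchor value of the
adapted matrix (forest biodiversity score 70, arable 30, continuous urban
fabric 5; the open-spaces class averaging 22 with range 10–50; exactly 18
of 27 classes at the floor score of 5 for drinking water; global minimum
5) but the remaining cells are plausible interpolations in the
Burkhard/Müller scoring tradition, not the original elicited values. Any
alternative matrix in the same CSV layout is a drop-in replacement.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

from .exceptions import (
    FeasibilityError,
    MatrixCompletenessError,
    NomenclatureError,
    ScoreRangeError,
)

__all__ = [
    "ESCode",
    "UA_CLASSES",
    "SCORE_MIN",
    "SCORE_MAX",
    "normalize_code",
    "ESPMatrix",
    "load_matrix",
    "default_matrix",
    "distribute_subclass_scores",
    "merge_class_scores",
    "MatrixSummary",
    "matrix_summary",
]

SCORE_MIN = 5.0
SCORE_MAX = 100.0


class ESCode(str, enum.Enum):
    """The six ecosystem services scored by the matrix."""

    I1 = "I1"
    P1 = "P1"
    R1 = "R1"
    R2 = "R2"
    R3 = "R3"
    C1 = "C1"

    @property
    def label(self) -> str:
        return _ES_LABELS[self]

    @classmethod
    def coerce(cls, value: Union["ESCode", str]) -> "ESCode":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().upper())
        except ValueError:
            raise NomenclatureError(
                f"unknown ecosystem-service code {value!r}; "
                f"expected one of {[c.value for c in cls]}"
            ) from None


_ES_LABELS: Mapping[ESCode, str] = {
    ESCode.I1: "biodiversity integrity",
    ESCode.P1: "drinking water",
    ESCode.R1: "flood protection",
    ESCode.R2: "air quality",
    ESCode.R3: "water purification",
    ESCode.C1: "recreation & tourism",
}

#: Canonical Urban Atlas nomenclature: 27 classes, 5-digit codes.
UA_CLASSES: Mapping[str, str] = {
    "11100": "Continuous urban fabric (S.L. > 80%)",
    "11210": "Discontinuous dense urban fabric",
    "11220": "Discontinuous medium density urban fabric",
    "11230": "Discontinuous low density urban fabric",
    "11240": "Discontinuous very low density urban fabric",
    "11300": "Isolated structures",
    "12100": "Industrial, commercial, public, military and private units",
    "12210": "Fast transit roads and associated land",
    "12220": "Other roads and associated land",
    "12230": "Railways and associated land",
    "12300": "Port areas",
    "12400": "Airports",
    "13100": "Mineral extraction and dump sites",
    "13300": "Construction sites",
    "13400": "Land without current use",
    "14100": "Green urban areas",
    "14200": "Sports and leisure facilities",
    "21000": "Arable land (annual crops)",
    "22000": "Permanent crops",
    "23000": "Pastures",
    "24000": "Complex and mixed cultivation patterns",
    "25000": "Orchards",
    "31000": "Forests",
    "32000": "Herbaceous vegetation associations",
    "33000": "Open spaces with little or no vegetation",
    "40000": "Wetlands",
    "50000": "Water",
}


def normalize_code(code: Union[str, int], *, strict: bool = True) -> str:
    """Normalize an LULC class code to canonical 5-digit form.

    Both 4-digit codes (``3100``, the radar-chart style) and 5-digit codes
    (``31000``) are in circulation; 4-digit codes are right-padded with
    zeros. Thousands separators and whitespace are stripped, so ``"11,100"``
    is accepted. With ``strict=True`` (default) the result must be one of
    the 27 canonical Urban Atlas classes.
    """
    text = str(code).strip().replace(",", "").replace(" ", "")
    if not text.isdigit() or len(text) not in (4, 5):
        raise NomenclatureError(f"malformed LULC code {code!r}")
    text = text.ljust(5, "0")
    if strict and text not in UA_CLASSES:
        raise NomenclatureError(
            f"LULC code {code!r} (normalized {text}) is not in the "
            f"27-class Urban Atlas nomenclature"
        )
    return text


@dataclass(frozen=True)
class ESPMatrix:
    """A validated, complete 27-class x 6-service score matrix.

    ``scores`` is indexed by 5-digit class code with one column per
    service code; ``provenance`` is a free-text source note.
    """

    scores: pd.DataFrame
    provenance: str = ""
    labels: Mapping[str, str] = field(default_factory=lambda: dict(UA_CLASSES))

    def __post_init__(self) -> None:
        df = self.scores
        expected_cols = [c.value for c in ESCode]
        missing_cols = [c for c in expected_cols if c not in df.columns]
        if missing_cols:
            raise MatrixCompletenessError(f"missing service columns: {missing_cols}")
        df = df[expected_cols].astype(float)
        missing_rows = sorted(set(UA_CLASSES) - set(df.index))
        if missing_rows:
            raise MatrixCompletenessError(
                f"matrix incomplete: no row for class(es) {missing_rows}"
            )
        extra = sorted(set(df.index) - set(UA_CLASSES))
        if extra:
            raise NomenclatureError(f"matrix contains unknown class code(s) {extra}")
        for code, row in df.iterrows():
            for svc, val in row.items():
                if pd.isna(val):
                    raise MatrixCompletenessError(f"missing score in cell ({code}, {svc})")
                if not (SCORE_MIN <= val <= SCORE_MAX):
                    raise ScoreRangeError(
                        f"score {val} in cell ({code}, {svc}) outside "
                        f"[{SCORE_MIN:g}, {SCORE_MAX:g}]"
                    )
        object.__setattr__(self, "scores", df.sort_index())

    def lookup(self, code: Union[str, int], service: Union[ESCode, str]) -> float:
        """ESP score of LULC class ``code`` for ``service``; no silent default."""
        c = normalize_code(code)
        e = ESCode.coerce(service)
        return float(self.scores.at[c, e.value])

    @property
    def classes(self) -> Sequence[str]:
        return list(self.scores.index)

    @property
    def services(self) -> Sequence[str]:
        return [c.value for c in ESCode]


def load_matrix(source, *, provenance: str = "") -> ESPMatrix:
    """Load and validate an expert matrix from a delimited text file.

    The expected layout is ``code,label,I1,P1,R1,R2,R3,C1`` with one row
    per LULC class; codes may be 4- or 5-digit and are normalized.
    """
    df = pd.read_csv(source, dtype={"code": str})
    if "code" not in df.columns:
        raise MatrixCompletenessError("matrix file lacks a 'code' column")
    df["code"] = [normalize_code(c) for c in df["code"]]
    labels = dict(UA_CLASSES)
    if "label" in df.columns:
        labels.update(zip(df["code"], df["label"].astype(str)))
    score_cols = [c.value for c in ESCode if c.value in df.columns]
    scores = df.set_index("code")[score_cols]
    return ESPMatrix(scores=scores, provenance=provenance or str(source), labels=labels)


def default_matrix() -> ESPMatrix:
    """The bundled synthetic reconstruction of the adapted expert matrix."""
    ref = resources.files("espdyn.data").joinpath("expert_matrix_synthetic.csv")
    with resources.as_file(ref) as path:
        return load_matrix(
            path,
            provenance=(
                "bundled synthetic reconstruction anchored to the published "
                "matrix facts (not the original elicited values)"
            ),
        )


def distribute_subclass_scores(
    parent_score: float, n_sub: int, lower: float, upper: float
) -> list[float]:
    """Split one parent-class score over ``n_sub`` ordered subclasses.

    Used when a coarse-nomenclature class (e.g. discontinuous urban fabric)
    is subdivided by settlement density in the finer nomenclature. The
    returned scores are equally spaced and symmetric about the parent, so
    the group mean equals ``parent_score`` exactly, and every value stays
    within ``[lower, upper]`` (bounds set by the neighbouring artificial
    and natural classes). The list is non-increasing: the first entry is
    the least dense subclass (highest score for services degraded by
    artificialization), the last the densest.

    The spacing step defaults to 10 score points, shrunk when the bounds
    leave less room; degenerate bounds collapse all subclasses onto the
    parent value.
    """
    if n_sub < 1:
        raise FeasibilityError("n_sub must be >= 1")
    if not (lower <= parent_score <= upper):
        raise FeasibilityError(
            f"parent score {parent_score} outside bounds [{lower}, {upper}]: "
            "group mean cannot be preserved"
        )
    if n_sub == 1:
        return [float(parent_score)]
    max_offset = (n_sub - 1) / 2.0
    headroom = min(parent_score - lower, upper - parent_score)
    step = min(10.0, headroom / max_offset)
    return [float(parent_score + step * (max_offset - i)) for i in range(n_sub)]


def merge_class_scores(scores: Iterable[float]) -> float:
    """Average several class scores into one (e.g. merging the water classes)."""
    vals = [float(v) for v in scores]
    if not vals:
        raise ValueError("merge_class_scores requires a non-empty list")
    for v in vals:
        if not (SCORE_MIN <= v <= SCORE_MAX):
            raise ScoreRangeError(f"score {v} outside [{SCORE_MIN:g}, {SCORE_MAX:g}]")
    return float(np.mean(vals))


@dataclass(frozen=True)
class MatrixSummary:
    """Per-class mean/min/max and a per-service score census."""

    per_class: pd.DataFrame  # index: code; columns: mean, min, max
    service_census: pd.DataFrame  # columns: service, score, n_classes

    def classes_at_score(self, service: Union[ESCode, str], score: float) -> int:
        e = ESCode.coerce(service).value
        sub = self.service_census
        hit = sub[(sub["service"] == e) & (np.isclose(sub["score"], score))]
        return int(hit["n_classes"].sum())


def matrix_summary(m: ESPMatrix) -> MatrixSummary:
    """Summarize a matrix: class-wise statistics and the score census.

    The per-class mean is over the six services; the census counts, for
    each service, how many classes sit at each distinct score (e.g. how
    many classes share the floor value of 5 for drinking water).
    """
    per_class = pd.DataFrame(
        {
            "mean": m.scores.mean(axis=1),
            "min": m.scores.min(axis=1),
            "max": m.scores.max(axis=1),
        }
    )
    census = (
        m.scores.melt(var_name="service", value_name="score", ignore_index=False)
        .groupby(["service", "score"])
        .size()
        .rename("n_classes")
        .reset_index()
    )
    return MatrixSummary(per_class=per_class, service_census=census)
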