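"""Mitral valve lesion complexity score and surgical technique score.

The complexity score is a weighted sum over echocardiographic lesion
features of the mitral apparatus (leaflets, annulus, sub-valvular
structures).  Each lesion carries an integer weight; the total stratifies
patients into *simple* (score <= 4), *intermediate* (5-8) and *complex*
(>= 9) groups.  The technique score counts the principal repair maneuvers
used on a valve, with chordal replacement counted once per resuspended
segment.

The default weights are clinical conventions, not fitted quantities, so
they are kept in a :class:`WeightTable` that can be overridden from a
mapping (e.g. parsed YAML).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields
from enum import Enum
from types import MappingProxyType
from typing import Mapping

from .errors import ValidationError

__all__ = [
    "LeafletMorphology",
    "LeafletMotion",
    "Stratum",
    "EchoFeatures",
    "WeightTable",
    "ComplexityBreakdown",
    "RepairTechniques",
    "complexity_score",
    "assign_stratum",
    "technique_score",
    "PROLAPSE_FIELDS",
    "DEFAULT_WEIGHTS",
]


class LeafletMorphology(str, Enum):
    NORMAL = "normal"
    THICKENING = "thickening"
    REDUNDANT = "redundant"


class LeafletMotion(str, Enum):
    NORMAL = "normal"
    EXCESSIVE = "excessive"
    RESTRICTION = "restriction"


class Stratum(str, Enum):
    SIMPLE = "simple"
    INTERMEDIATE = "intermediate"
    COMPLEX = "complex"


#: Carpentier segments and commissures that can prolapse, in declared order.
PROLAPSE_FIELDS = (
    "prolapse_p1",
    "prolapse_p2",
    "prolapse_p3",
    "prolapse_a1",
    "prolapse_a2",
    "prolapse_a3",
    "prolapse_anterolateral_commissure",
    "prolapse_posteromedial_commissure",
)

_BOOL_FIELDS = PROLAPSE_FIELDS + (
    "ruptured_chordae",
    "calc_leaflet",
    "calc_annulus",
    "calc_chordae",
    "commissure_fusion",
)


def _coerce_enum(enum_cls, value, field_name: str):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(value)
    except ValueError:
        allowed = ", ".join(m.value for m in enum_cls)
        raise ValidationError(
            f"{field_name}: unknown value {value!r} (allowed: {allowed})",
            field=field_name,
        ) from None


@dataclass(frozen=True)
class EchoFeatures:
    """One patient's categorical echocardiographic lesion profile.

    ``vegetation_class`` and ``perforation_cleft_class`` are ordinal count
    classes 0, 1, 2 where 2 means ">= 2 lesions".
    """

    prolapse_p1: bool = False
    prolapse_p2: bool = False
    prolapse_p3: bool = False
    prolapse_a1: bool = False
    prolapse_a2: bool = False
    prolapse_a3: bool = False
    prolapse_anterolateral_commissure: bool = False
    prolapse_posteromedial_commissure: bool = False
    ruptured_chordae: bool = False
    leaflet_morphology: LeafletMorphology = LeafletMorphology.NORMAL
    calc_leaflet: bool = False
    calc_annulus: bool = False
    calc_chordae: bool = False
    commissure_fusion: bool = False
    vegetation_class: int = 0
    perforation_cleft_class: int = 0
    leaflet_motion: LeafletMotion = LeafletMotion.NORMAL

    def __post_init__(self):
        for name in _BOOL_FIELDS:
            value = getattr(self, name)
            if not isinstance(value, (bool,)):
                if value in (0, 1):  # tolerate 0/1 from tabular input
                    object.__setattr__(self, name, bool(value))
                else:
                    raise ValidationError(
                        f"{name}: expected a boolean flag, got {value!r}", field=name
                    )
        object.__setattr__(
            self,
            "leaflet_morphology",
            _coerce_enum(LeafletMorphology, self.leaflet_morphology, "leaflet_morphology"),
        )
        object.__setattr__(
            self,
            "leaflet_motion",
            _coerce_enum(LeafletMotion, self.leaflet_motion, "leaflet_motion"),
        )
        for name in ("vegetation_class", "perforation_cleft_class"):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value not in (0, 1, 2):
                raise ValidationError(
                    f"{name}: expected count class 0, 1 or 2, got {value!r}", field=name
                )

    @classmethod
    def field_names(cls) -> tuple[str, ...]:
        return tuple(f.name for f in fields(cls))


def _check_weight_map(name: str, mapping: Mapping, keys: tuple) -> Mapping:
    if set(mapping) != set(keys):
        raise ValidationError(
            f"{name}: expected keys {sorted(map(str, keys))}, got {sorted(map(str, mapping))}",
            field=name,
        )
    for key, value in mapping.items():
        if not isinstance(value, int) or isinstance(value, bool) or value < 0:
            raise ValidationError(
                f"{name}[{key}]: weights must be non-negative integers, got {value!r}",
                field=name,
            )
    return MappingProxyType(dict(mapping))


@dataclass(frozen=True)
class WeightTable:
    """Weights of the complexity score components.

    Defaults follow the published convention: posterior segments 1 point,
    anterior segments and commissures 2, ruptured chordae 1, morphology
    0/1/3 (normal/thickening/redundant), calcification 1/3/3
    (leaflet/annulus/chordae), commissure fusion 2, perforation-or-cleft
    and vegetation count classes 0/1/2, leaflet motion 0/1/2
    (normal/excessive/restriction).

    ``pooled_vegetation_perforation`` switches to the variant that pools
    vegetation with perforation/cleft into one category scoring 1 when a
    single such lesion is present and 4 when more than one is.
    """

    p_segment: int = 1
    a_segment: int = 2
    commissure_prolapse: int = 2
    ruptured_chordae: int = 1
    morphology: Mapping[LeafletMorphology, int] = field(
        default_factory=lambda: {
            LeafletMorphology.NORMAL: 0,
            LeafletMorphology.THICKENING: 1,
            LeafletMorphology.REDUNDANT: 3,
        }
    )
    calc_leaflet: int = 1
    calc_annulus: int = 3
    calc_chordae: int = 3
    commissure_fusion: int = 2
    perforation_cleft: Mapping[int, int] = field(
        default_factory=lambda: {0: 0, 1: 1, 2: 2}
    )
    vegetation: Mapping[int, int] = field(default_factory=lambda: {0: 0, 1: 1, 2: 2})
    motion: Mapping[LeafletMotion, int] = field(
        default_factory=lambda: {
            LeafletMotion.NORMAL: 0,
            LeafletMotion.EXCESSIVE: 1,
            LeafletMotion.RESTRICTION: 2,
        }
    )
    pooled_vegetation_perforation: bool = False
    pooled_single: int = 1
    pooled_multiple: int = 4

    def __post_init__(self):
        for name in (
            "p_segment",
            "a_segment",
            "commissure_prolapse",
            "ruptured_chordae",
            "calc_leaflet",
            "calc_annulus",
            "calc_chordae",
            "commissure_fusion",
            "pooled_single",
            "pooled_multiple",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ValidationError(
                    f"{name}: weights must be non-negative integers, got {value!r}",
                    field=name,
                )
        object.__setattr__(
            self,
            "morphology",
            _check_weight_map(
                "morphology",
                {_coerce_enum(LeafletMorphology, k, "morphology"): v for k, v in self.morphology.items()},
                tuple(LeafletMorphology),
            ),
        )
        object.__setattr__(
            self,
            "motion",
            _check_weight_map(
                "motion",
                {_coerce_enum(LeafletMotion, k, "motion"): v for k, v in self.motion.items()},
                tuple(LeafletMotion),
            ),
        )
        object.__setattr__(
            self,
            "perforation_cleft",
            _check_weight_map(
                "perforation_cleft",
                {int(k): v for k, v in self.perforation_cleft.items()},
                (0, 1, 2),
            ),
        )
        object.__setattr__(
            self,
            "vegetation",
            _check_weight_map(
                "vegetation", {int(k): v for k, v in self.vegetation.items()}, (0, 1, 2)
            ),
        )

    @classmethod
    def from_mapping(cls, overrides: Mapping | None) -> "WeightTable":
        """Build a weight table from a (possibly partial) mapping; omitted
        keys keep their defaults."""
        if not overrides:
            return cls()
        known = {f.name for f in fields(cls)}
        unknown = set(overrides) - known
        if unknown:
            raise ValidationError(
                f"unknown weight keys: {sorted(unknown)}", field="weights"
            )
        base = cls()
        kwargs = {}
        for name in known:
            if name in overrides:
                default = getattr(base, name)
                value = overrides[name]
                if isinstance(default, Mapping):
                    merged = dict(default)
                    for key, v in dict(value).items():
                        if isinstance(next(iter(default)), Enum):
                            key = type(next(iter(default)))(key)
                        else:
                            key = int(key)
                        merged[key] = v
                    kwargs[name] = merged
                else:
                    kwargs[name] = value
        return cls(**kwargs)

    @property
    def max_score(self) -> int:
        """Maximum attainable total on an all-max lesion profile."""
        total = (
            3 * self.p_segment
            + 3 * self.a_segment
            + 2 * self.commissure_prolapse
            + self.ruptured_chordae
            + max(self.morphology.values())
            + self.calc_leaflet
            + self.calc_annulus
            + self.calc_chordae
            + self.commissure_fusion
            + max(self.motion.values())
        )
        if self.pooled_vegetation_perforation:
            total += max(self.pooled_single, self.pooled_multiple)
        else:
            total += max(self.perforation_cleft.values()) + max(self.vegetation.values())
        return total


DEFAULT_WEIGHTS = WeightTable()


@dataclass(frozen=True)
class ComplexityBreakdown:
    """Per-component contributions to the complexity score.

    ``contributions`` holds only the non-zero terms, keyed by component
    name; ``total`` is their sum.
    """

    contributions: Mapping[str, int]
    total: int

    def __post_init__(self):
        object.__setattr__(
            self, "contributions", MappingProxyType(dict(self.contributions))
        )
        if self.total != sum(self.contributions.values()):
            raise ValidationError(
                f"total {self.total} != sum of contributions "
                f"{sum(self.contributions.values())}",
                field="total",
            )


def complexity_score(
    features: EchoFeatures, weights: WeightTable = DEFAULT_WEIGHTS
) -> ComplexityBreakdown:
    """Score one lesion profile.

    Returns the weighted contribution of every present lesion and the
    total.  All weights are non-negative, so adding a lesion can never
    lower the total.
    """
    if not isinstance(features, EchoFeatures):
        features = EchoFeatures(**features)  # type: ignore[arg-type]
    contrib: dict[str, int] = {}

    for name in PROLAPSE_FIELDS:
        if getattr(features, name):
            if "commissure" in name:
                w = weights.commissure_prolapse
            elif name.startswith("prolapse_p"):
                w = weights.p_segment
            else:
                w = weights.a_segment
            contrib[name] = w
    if features.ruptured_chordae:
        contrib["ruptured_chordae"] = weights.ruptured_chordae
    contrib["morphology"] = weights.morphology[features.leaflet_morphology]
    if features.calc_leaflet:
        contrib["calc_leaflet"] = weights.calc_leaflet
    if features.calc_annulus:
        contrib["calc_annulus"] = weights.calc_annulus
    if features.calc_chordae:
        contrib["calc_chordae"] = weights.calc_chordae
    if features.commissure_fusion:
        contrib["commissure_fusion"] = weights.commissure_fusion
    if weights.pooled_vegetation_perforation:
        n_lesions = features.vegetation_class + features.perforation_cleft_class
        if n_lesions == 1:
            contrib["vegetation_perforation_cleft"] = weights.pooled_single
        elif n_lesions > 1:
            contrib["vegetation_perforation_cleft"] = weights.pooled_multiple
    else:
        contrib["vegetation"] = weights.vegetation[features.vegetation_class]
        contrib["perforation_cleft"] = weights.perforation_cleft[
            features.perforation_cleft_class
        ]
    contrib["motion"] = weights.motion[features.leaflet_motion]

    contrib = {k: v for k, v in contrib.items() if v != 0}
    return ComplexityBreakdown(contributions=contrib, total=sum(contrib.values()))


#: Strata boundaries: simple <= _SIMPLE_MAX < intermediate <= _INTERMEDIATE_MAX < complex
_SIMPLE_MAX = 4
_INTERMEDIATE_MAX = 8


def assign_stratum(total: int) -> Stratum:
    """Map a complexity total to its stratum (simple 0-4, intermediate 5-8,
    complex >= 9).

    The published strata start at 1; a total of 0 (no scored lesion) is
    mapped to *simple* with a warning rather than rejected.
    """
    if not isinstance(total, int) or isinstance(total, bool):
        raise ValidationError(f"total must be an integer, got {total!r}", field="total")
    if total < 0:
        raise ValidationError(f"total must be >= 0, got {total}", field="total")
    if total == 0:
        warnings.warn(
            "complexity score 0 (no scored lesion) mapped to the simple stratum",
            stacklevel=2,
        )
    if total <= _SIMPLE_MAX:
        return Stratum.SIMPLE
    if total <= _INTERMEDIATE_MAX:
        return Stratum.INTERMEDIATE
    return Stratum.COMPLEX


@dataclass(frozen=True)
class RepairTechniques:
    """Principal maneuvers used to repair one valve.

    ``chordal_segments_resuspended`` counts leaflet segments resuspended by
    artificial or native chords (each counts one point).  ``ring_revision``
    (revision of the annuloplasty ring during a re-repair) implies
    ``re_repair``.
    """

    annuloplasty: bool = False
    chordal_segments_resuspended: int = 0
    cleft_closures: int = 0
    leaflet_resections: int = 0
    vegetation_removals: int = 0
    commissurotomies: int = 0
    re_repair: bool = False
    ring_revision: bool = False

    def __post_init__(self):
        for name in (
            "chordal_segments_resuspended",
            "cleft_closures",
            "leaflet_resections",
            "vegetation_removals",
            "commissurotomies",
        ):
            value = getattr(self, name)
            if not isinstance(value, int) or isinstance(value, bool) or value < 0:
                raise ValidationError(
                    f"{name}: expected a non-negative integer count, got {value!r}",
                    field=name,
                )
        if self.ring_revision and not self.re_repair:
            raise ValidationError(
                "ring_revision requires re_repair", field="ring_revision"
            )


def technique_score(t: RepairTechniques, commissurotomy_weight: int = 1) -> int:
    """Number of principal repair techniques used on a valve.

    Each maneuver counts 1; chordal replacement counts once per
    resuspended segment; a re-repair adds 1 and a ring revision during
    re-repair adds a further 1.  ``commissurotomy_weight`` is the score
    per incised commissure (default 1; some conventions count 2).
    """
    if not isinstance(t, RepairTechniques):
        raise ValidationError(f"expected RepairTechniques, got {type(t).__name__}")
    if commissurotomy_weight < 0:
        raise ValidationError(
            "commissurotomy_weight must be >= 0", field="commissurotomy_weight"
        )
    return (
        int(t.annuloplasty)
        + t.chordal_segments_resuspended
        + t.cleft_closures
        + t.leaflet_resections
        + t.vegetation_removals
        + t.commissurotomies * commissurotomy_weight
        + int(t.re_repair)
        + int(t.ring_revision)
    )
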