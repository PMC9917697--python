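"""Complexity and technique scoring: golden cases, properties, config."""

import dataclasses

import pytest
from hypothesis import given, settings

from mvpipeline.errors import ValidationError
from mvpipeline.scoring import (
    DEFAULT_WEIGHTS,
    EchoFeatures,
    LeafletMorphology,
    LeafletMotion,
    RepairTechniques,
    Stratum,
    WeightTable,
    assign_stratum,
    complexity_score,
    technique_score,
)

from conftest import echo_features_strategy


def brute_force_total(f: EchoFeatures) -> int:
    """Independent oracle: explicit (condition, weight) list of the default
    scoring convention, summed directly."""
    pairs = [
        (f.prolapse_p1, 1),
        (f.prolapse_p2, 1),
        (f.prolapse_p3, 1),
        (f.prolapse_a1, 2),
        (f.prolapse_a2, 2),
        (f.prolapse_a3, 2),
        (f.prolapse_anterolateral_commissure, 2),
        (f.prolapse_posteromedial_commissure, 2),
        (f.ruptured_chordae, 1),
        (f.leaflet_morphology is LeafletMorphology.THICKENING, 1),
        (f.leaflet_morphology is LeafletMorphology.REDUNDANT, 3),
        (f.calc_leaflet, 1),
        (f.calc_annulus, 3),
        (f.calc_chordae, 3),
        (f.commissure_fusion, 2),
        (f.perforation_cleft_class == 1, 1),
        (f.perforation_cleft_class == 2, 2),
        (f.vegetation_class == 1, 1),
        (f.vegetation_class == 2, 2),
        (f.leaflet_motion is LeafletMotion.EXCESSIVE, 1),
        (f.leaflet_motion is LeafletMotion.RESTRICTION, 2),
    ]
    return sum(w for cond, w in pairs if cond)


WORKED_CASES = [
    # isolated A1 prolapse + one cleft: 2 + 1
    (dict(prolapse_a1=True, perforation_cleft_class=1), 3),
    # A1+A2+A3 prolapse with excessive motion: 3 x 2 + 1
    (
        dict(prolapse_a1=True, prolapse_a2=True, prolapse_a3=True,
             leaflet_motion="excessive"),
        7,
    ),
    # A2+A3 + posteromedial commissure prolapse, redundant leaflet: 2 x 2 + 2 + 3
    (
        dict(prolapse_a2=True, prolapse_a3=True,
             prolapse_posteromedial_commissure=True,
             leaflet_morphology="redundant"),
        9,
    ),
    # rheumatic profile: thickening + chordal calcification + fusion + restriction
    (
        dict(leaflet_morphology="thickening", calc_chordae=True,
             commissure_fusion=True, leaflet_motion="restriction"),
        8,
    ),
    (dict(), 0),
]


@pytest.mark.parametrize("kwargs,expected", WORKED_CASES)
def test_complexity_worked_cases(kwargs, expected):
    breakdown = complexity_score(EchoFeatures(**kwargs))
    assert breakdown.total == expected
    assert sum(breakdown.contributions.values()) == expected
    if expected == 0:
        assert dict(breakdown.contributions) == {}


def test_breakdown_components_named():
    b = complexity_score(EchoFeatures(prolapse_a1=True, perforation_cleft_class=1))
    assert dict(b.contributions) == {"prolapse_a1": 2, "perforation_cleft": 1}


@settings(derandomize=True, max_examples=200)
@given(echo_features_strategy())
def test_complexity_matches_brute_force_oracle(features):
    assert complexity_score(features).total == brute_force_total(features)


@settings(derandomize=True, max_examples=100)
@given(echo_features_strategy())
def test_monotone_in_every_lesion(features):
    """Setting an absent flag or raising an ordinal never lowers the total."""
    base = complexity_score(features).total
    for name in (
        "prolapse_p1", "prolapse_a2", "ruptured_chordae", "calc_annulus",
        "commissure_fusion",
    ):
        if not getattr(features, name):
            bumped = dataclasses.replace(features, **{name: True})
            assert complexity_score(bumped).total >= base
    for name in ("vegetation_class", "perforation_cleft_class"):
        value = getattr(features, name)
        if value < 2:
            bumped = dataclasses.replace(features, **{name: value + 1})
            assert complexity_score(bumped).total >= base


def test_max_score_reached_on_all_max_profile():
    all_max = EchoFeatures(
        prolapse_p1=True, prolapse_p2=True, prolapse_p3=True,
        prolapse_a1=True, prolapse_a2=True, prolapse_a3=True,
        prolapse_anterolateral_commissure=True,
        prolapse_posteromedial_commissure=True,
        ruptured_chordae=True,
        leaflet_morphology="redundant",
        calc_leaflet=True, calc_annulus=True, calc_chordae=True,
        commissure_fusion=True,
        vegetation_class=2, perforation_cleft_class=2,
        leaflet_motion="restriction",
    )
    # 3x1 + 3x2 + 2x2 + 1 + 3 + (1+3+3) + 2 + 2 + 2 + 2
    total = complexity_score(all_max).total
    assert total == DEFAULT_WEIGHTS.max_score == 32


@pytest.mark.parametrize(
    "total,expected",
    [
        (3, Stratum.SIMPLE),
        (4, Stratum.SIMPLE),
        (5, Stratum.INTERMEDIATE),
        (8, Stratum.INTERMEDIATE),
        (9, Stratum.COMPLEX),
        (30, Stratum.COMPLEX),
    ],
)
def test_stratum_boundaries(total, expected):
    assert assign_stratum(total) is expected


def test_strata_partition_all_totals():
    for total in range(1, 31):
        strata = [s for s in Stratum if assign_stratum(total) is s]
        assert len(strata) == 1


def test_stratum_zero_warns_simple():
    with pytest.warns(UserWarning):
        assert assign_stratum(0) is Stratum.SIMPLE


def test_stratum_rejects_negative():
    with pytest.raises(ValidationError):
        assign_stratum(-1)


@pytest.mark.parametrize(
    "kwargs,expected",
    [
        (dict(chordal_segments_resuspended=2, annuloplasty=True), 3),
        (dict(cleft_closures=1, annuloplasty=True), 2),
        (dict(chordal_segments_resuspended=4, annuloplasty=True), 5),
        (dict(), 0),
        (dict(annuloplasty=True, commissurotomies=2, re_repair=True,
              ring_revision=True), 5),
    ],
)
def test_technique_score_cases(kwargs, expected):
    assert technique_score(RepairTechniques(**kwargs)) == expected


def test_commissurotomy_weight_configurable():
    t = RepairTechniques(annuloplasty=True, commissurotomies=2)
    assert technique_score(t) == 3
    assert technique_score(t, commissurotomy_weight=2) == 5


def test_technique_negative_count_rejected():
    with pytest.raises(ValidationError):
        RepairTechniques(cleft_closures=-1)


def test_ring_revision_requires_re_repair():
    with pytest.raises(ValidationError):
        RepairTechniques(ring_revision=True)


def test_unknown_enum_value_names_field():
    with pytest.raises(ValidationError, match="leaflet_morphology"):
        EchoFeatures(leaflet_morphology="thickened")


def test_count_class_out_of_range_rejected():
    with pytest.raises(ValidationError, match="vegetation_class"):
        EchoFeatures(vegetation_class=3)


def test_pooled_variant_scores_single_and_multiple():
    weights = WeightTable(pooled_vegetation_perforation=True)
    one = EchoFeatures(vegetation_class=1)
    several = EchoFeatures(vegetation_class=1, perforation_cleft_class=1)
    assert complexity_score(one, weights).total == 1
    assert complexity_score(several, weights).total == 4
    assert complexity_score(EchoFeatures(), weights).total == 0


def test_weight_table_partial_override():
    w = WeightTable.from_mapping({"a_segment": 3, "motion": {"excessive": 2}})
    assert w.a_segment == 3
    assert w.motion[LeafletMotion.EXCESSIVE] == 2
    assert w.motion[LeafletMotion.RESTRICTION] == 2  # default retained
    assert w.p_segment == 1


def test_weight_table_rejects_unknown_key_and_negative():
    with pytest.raises(ValidationError):
        WeightTable.from_mapping({"nope": 1})
    with pytest.raises(ValidationError):
        WeightTable(a_segment=-2)
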