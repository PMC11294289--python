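"""Worked-example data: published VOX assessment tables and profiles.

A 6x4 binary response matrix from one assessment of a 3-year-old boy with
ASD, a five-timepoint longitudinal descriptor series for the same child,
and a four-child cross-sectional descriptor comparison.  They serve as
executable documentation and as ground truth in the test suite.

The property radius ``C`` is never printed in the source tables; the value
12 is recovered from the internal consistency of every reported
``(A, R, Q)`` triple under ``Q = A * (C - R)`` (see
:func:`inferred_property_radius`).  Axis values for the longitudinal Times
1-3 and for three of the four cross-sectional children are likewise not
printed; only their descriptors are reproduced here.
"""

from __future__ import annotations

from .plp_geometry import ShapeDescriptors
from .vox_data import AxisValues, SpeakerRecord, VoxDataset, VoxTrial

#: Radius of the property-space circle consistent with every published
#: (A, R, Q) row: solving Q = A(C - R) for C gives 12.0 (to rounding) in
#: all nine rows.  Instrument-specific in general; not a package default.
INFERRED_PROPERTY_RADIUS = 12.0


def inferred_property_radius() -> float:
    """Property radius consistent with the published descriptor tables."""
    return INFERRED_PROPERTY_RADIUS


#: (response form, tact, mand, echoic, sequelic) — the published 6x4 matrix.
_TABLE2_ROWS = (
    ("iPad", 0, 0, 1, 0),
    ("Guitar", 1, 0, 1, 0),
    ("Spider", 1, 0, 1, 1),
    ("Lion", 1, 1, 1, 0),
    ("Phone", 1, 0, 0, 0),
    ("Step on it", 1, 1, 1, 0),
)


def assessment_dataset() -> VoxDataset:
    """The published single-round VOX matrix of a 3-year-old boy with ASD.

    Six speaker-selected response forms, each probed under all four operant
    conditions; column totals are (tact=5, mand=2, echoic=5, sequelic=1).
    """
    trials = []
    for form, tact, mand, echoic, sequelic in _TABLE2_ROWS:
        for cond, emitted in (
            ("tact", tact),
            ("mand", mand),
            ("echoic", echoic),
            ("sequelic", sequelic),
        ):
            trials.append(
                VoxTrial(
                    speaker_id="boy-3y",
                    session=0,
                    response_form=form,
                    condition=cond,
                    emitted=emitted,
                )
            )
    speaker = SpeakerRecord(
        speaker_id="boy-3y", age=(3, 0), sex="male", diagnosis="ASD"
    )
    return VoxDataset(trials=trials, speaker=speaker)


def worked_profile_values() -> AxisValues:
    """Axis values of the worked radar-chart example.

    Vertices (12,0), (0,10), (-8,0), (0,-12); area 220; centroid
    (1.33, -0.67) at two decimals.
    """
    return AxisValues(tact=12, mand=10, echoic=12, sequelic=8)


def longitudinal_rows() -> list[dict]:
    """The published five-timepoint descriptor series (ages 3-5, biannual).

    Values are as printed: ``area`` for Times 1-3 is inferred (flagged
    ``area_inferred=True``) because the printed area row is typeset
    ambiguously; the inference resolves it via Q = A(12 - R).  Times 2-3
    carry ``q_divergent=True``: recomputing Q from the printed rounded A and
    R differs from the printed Q in the second decimal (the source worked
    from unrounded internal values).
    """
    rows = [
        dict(age="3:04", area=4.0, centroidal_distance=1.49, first_moment=42.04,
             area_inferred=True, q_divergent=False),
        dict(age="4:00", area=84.0, centroidal_distance=3.33, first_moment=728.00,
             area_inferred=True, q_divergent=True),
        dict(age="4:05", area=80.0, centroidal_distance=2.40, first_moment=767.70,
             area_inferred=True, q_divergent=True),
        dict(age="4:11", area=220.0, centroidal_distance=1.49, first_moment=2312.04,
             area_inferred=False, q_divergent=False),
        dict(age="5:05", area=288.0, centroidal_distance=0.00, first_moment=3456.00,
             area_inferred=False, q_divergent=False),
    ]
    return rows


def longitudinal_known_axis_values() -> dict[str, AxisValues]:
    """Axis values known for the longitudinal series.

    Only the last two timepoints are reconstructible: Time 4 is the worked
    radar-chart example and Time 5 is the balanced all-12 profile (area 288,
    centroid at the origin).
    """
    return {
        "4:11": worked_profile_values(),
        "5:05": AxisValues(tact=12, mand=12, echoic=12, sequelic=12),
    }


def cross_speaker_records() -> list[dict]:
    """The published four-child cross-sectional comparison.

    Each entry has the speaker metadata and the reported descriptors
    (``ShapeDescriptors.from_reported`` with the inferred C = 12).  Child
    C's axis values (tact=2, sequelic=1, mand=echoic=0) are inferred from
    the printed area 1.00 and centroid (-0.33, -0.67) — a single-quadrant
    profile; the other children's axis values are not recoverable from the
    printed descriptors.
    """
    c = INFERRED_PROPERTY_RADIUS
    return [
        dict(
            speaker=SpeakerRecord(
                speaker_id="child-A", age=(4, 5), sex="male",
                race_ethnicity="African American/Non-Hispanic",
                home_languages=("English",), diagnosis="ASD",
            ),
            descriptors=ShapeDescriptors.from_reported(
                area=146.67, centroidal_distance=3.14, property_radius=c,
                first_moment=1299.07, centroid=(3.0, -0.5),
            ),
        ),
        dict(
            speaker=SpeakerRecord(
                speaker_id="child-B", age=(6, 0), sex="female",
                race_ethnicity="White/Hispanic",
                home_languages=("English", "Spanish"), diagnosis="ASD",
            ),
            descriptors=ShapeDescriptors.from_reported(
                area=154.00, centroidal_distance=3.40, property_radius=c,
                first_moment=1324.50, centroid=(3.33, 0.67),
            ),
        ),
        dict(
            speaker=SpeakerRecord(
                speaker_id="child-C", age=(3, 9), sex="female",
                race_ethnicity="African American/Hispanic",
                home_languages=("English",), diagnosis="ASD",
            ),
            descriptors=ShapeDescriptors.from_reported(
                area=1.00, centroidal_distance=0.75, property_radius=c,
                first_moment=11.25, centroid=(-1 / 3, -2 / 3),
                axis_values=AxisValues(tact=2, mand=0, echoic=0, sequelic=1),
            ),
        ),
        dict(
            speaker=SpeakerRecord(
                speaker_id="child-D", age=(3, 10), sex="male",
                race_ethnicity="White/Hispanic",
                home_languages=("Spanish",), diagnosis="neurotypical",
            ),
            descriptors=ShapeDescriptors.from_reported(
                area=272.0, centroidal_distance=0.44, property_radius=c,
                first_moment=3143.11,
            ),
        ),
    ]
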