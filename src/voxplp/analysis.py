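"""Statistics over polygonal language profiles.

Three concerns live here: the related-samples test of functional
independence of the verbal operants (Cochran's Q on the binary
responses-by-conditions matrix), longitudinal descriptor series for one
speaker assessed repeatedly, and pairwise comparison of profiles across
speakers or timepoints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .plp_geometry import RadarConfig, ShapeDescriptors, describe
from .vox_data import OPERANTS, AxisValues, SpeakerRecord, VoxDataset


@dataclass(frozen=True)
class IndependenceTestResult:
    """Result of the related-samples functional-independence test."""

    statistic: float
    df: int
    p_value: float
    n_informative_rows: int
    method: str = "asymptotic"
    degenerate: bool = False

    def significant(self, alpha: float = 0.05) -> bool:
        """Whether operant emission rates differ at the given level (default .05)."""
        return self.p_value < alpha


def _as_matrix(data: VoxDataset | np.ndarray | Sequence[Sequence[int]]) -> np.ndarray:
    if isinstance(data, VoxDataset):
        matrix = data.response_matrix().to_numpy()
    else:
        matrix = np.asarray(data)
    if matrix.ndim != 2:
        raise ValueError("expected a 2-D binary responses-by-conditions matrix")
    if not np.isin(matrix, (0, 1)).all():
        raise ValueError("response matrix must be binary (0/1)")
    return matrix.astype(np.int64)


def _cochran_statistic(matrix: np.ndarray) -> float:
    """Cochran's Q: Qc = (k-1) * (k * sum(Cj^2) - N^2) / (k * N - sum(Ri^2)).

    Cj are column (condition) totals, Ri row (response block) totals,
    N the grand total, k the number of conditions.  Rows that are all-0 or
    all-1 contribute equally to numerator and denominator corrections and
    leave the statistic unchanged.  Returns NaN when the denominator is
    zero (every row constant: no within-row variation to test).
    """
    k = matrix.shape[1]
    col = matrix.sum(axis=0)
    row = matrix.sum(axis=1)
    n_total = int(matrix.sum())
    denom = k * n_total - int((row**2).sum())
    if denom == 0:
        return math.nan
    return (k - 1) * (k * int((col**2).sum()) - n_total**2) / denom


def related_samples_test(
    data: VoxDataset | np.ndarray | Sequence[Sequence[int]],
    method: str = "asymptotic",
    n_permutations: int = 10_000,
    seed: int | None = None,
) -> IndependenceTestResult:
    """Test functional independence of the operants on a binary VOX matrix.

    Each response form (within a session) is a block probed once under every
    condition; Cochran's Q tests whether emission proportions differ across
    the conditions.  ``method="asymptotic"`` refers the statistic to a
    chi-square with ``k - 1`` degrees of freedom; ``method="permutation"``
    instead permutes each block's responses across conditions (the exchange
    that the null of no condition effect allows) and reports a Monte Carlo
    p-value — preferable for the very small matrices typical of a single
    assessment round.

    When every row is constant (all 0 or all 1) the statistic is undefined:
    the result carries ``degenerate=True``, a NaN statistic and p = 1.
    """
    if method not in ("asymptotic", "permutation"):
        raise ValueError(f"unknown method {method!r}")
    matrix = _as_matrix(data)
    if matrix.shape[0] < 2:
        raise ValueError("need at least 2 response-form rows")
    k = matrix.shape[1]
    df = k - 1
    row = matrix.sum(axis=1)
    n_informative = int(((row > 0) & (row < k)).sum())

    q_obs = _cochran_statistic(matrix)
    if math.isnan(q_obs):
        return IndependenceTestResult(
            statistic=math.nan,
            df=df,
            p_value=1.0,
            n_informative_rows=n_informative,
            method=method,
            degenerate=True,
        )

    if method == "asymptotic":
        p = float(stats.chi2.sf(q_obs, df))
    else:
        rng = np.random.default_rng(seed)
        exceed = 0
        for _ in range(n_permutations):
            perm = rng.permuted(matrix, axis=1)
            q = _cochran_statistic(perm)
            if not math.isnan(q) and q >= q_obs - 1e-12:
                exceed += 1
        p = (1 + exceed) / (1 + n_permutations)
    return IndependenceTestResult(
        statistic=float(q_obs),
        df=df,
        p_value=p,
        n_informative_rows=n_informative,
        method=method,
    )


def _age_to_months(age: tuple[int, int] | str) -> int:
    if isinstance(age, str):
        years, months = age.split(":")
        age = (int(years), int(months))
    years, months = age
    if years < 0 or not 0 <= months <= 11:
        raise ValueError(f"invalid age {age!r}; expected (years, months in [0, 11])")
    return 12 * years + months


def _age_label(age: tuple[int, int] | str) -> str:
    if isinstance(age, str):
        years, months = (int(p) for p in age.split(":"))
    else:
        years, months = age
    return f"{years}:{months:02d}"


@dataclass(frozen=True)
class Timepoint:
    age: str  # YY:MM
    axis_values: AxisValues
    descriptors: ShapeDescriptors


@dataclass(frozen=True)
class SeriesRecord:
    """One speaker's descriptor series over strictly increasing ages."""

    speaker: SpeakerRecord
    timepoints: tuple[Timepoint, ...]

    def to_frame(self) -> pd.DataFrame:
        """Tidy longitudinal report: one row per timepoint (Age, A, R, Q)."""
        return pd.DataFrame(
            {
                "age": [t.age for t in self.timepoints],
                "area": [t.descriptors.area for t in self.timepoints],
                "centroidal_distance": [
                    t.descriptors.centroidal_distance for t in self.timepoints
                ],
                "first_moment": [t.descriptors.first_moment for t in self.timepoints],
            }
        )

    def to_rows(self) -> list[dict]:
        """Flat descriptor rows in the serialization schema of vox_data."""
        rows = []
        for t in self.timepoints:
            d = t.descriptors
            cx, cy = d.centroid if d.centroid is not None else (None, None)
            rows.append(
                {
                    "speaker_id": self.speaker.speaker_id,
                    "age": t.age,
                    **t.axis_values.as_dict(),
                    "area": d.area,
                    "centroid_x": cx,
                    "centroid_y": cy,
                    "centroidal_distance": d.centroidal_distance,
                    "first_moment": d.first_moment,
                    "property_radius": d.property_radius,
                    "ordering": "|".join(d.axis_order),
                }
            )
        return rows


def longitudinal_series(
    inputs: Iterable[tuple[tuple[int, int] | str, AxisValues]],
    config: RadarConfig,
    speaker: SpeakerRecord | None = None,
) -> SeriesRecord:
    """Compute descriptors for an age-ordered sequence of assessments.

    ``inputs`` is an ordered iterable of ``(age, axis_values)`` with ages as
    ``(years, months)`` or ``"Y:M"`` strings; ages must be strictly
    increasing.  Descriptors are computed per timepoint under the one shared
    radar configuration.
    """
    pairs = list(inputs)
    if not pairs:
        raise ValueError("need at least one timepoint")
    months = [_age_to_months(age) for age, _ in pairs]
    if any(b <= a for a, b in zip(months, months[1:])):
        raise ValueError("ages must be strictly increasing")
    timepoints = tuple(
        Timepoint(age=_age_label(age), axis_values=vals, descriptors=describe(vals, config))
        for age, vals in pairs
    )
    if speaker is None:
        speaker = SpeakerRecord(speaker_id="unknown")
    return SeriesRecord(speaker=speaker, timepoints=timepoints)


@dataclass(frozen=True)
class ProfileComparison:
    """Signed descriptor differences between two profiles (a minus b)."""

    delta_area: float
    delta_centroidal_distance: float | None
    delta_first_moment: float | None
    centroid_separation: float | None
    axis_differences: dict[str, float] | None

    def reversed(self) -> "ProfileComparison":
        def neg(v):
            return None if v is None else -v

        return ProfileComparison(
            delta_area=-self.delta_area,
            delta_centroidal_distance=neg(self.delta_centroidal_distance),
            delta_first_moment=neg(self.delta_first_moment),
            centroid_separation=self.centroid_separation,
            axis_differences=None
            if self.axis_differences is None
            else {k: -v for k, v in self.axis_differences.items()},
        )


def compare_profiles(a: ShapeDescriptors, b: ShapeDescriptors) -> ProfileComparison:
    """Quantify the difference between two profiles measured alike.

    Both descriptor sets must share the same property radius and axis
    ordering; otherwise sizes and moments are not commensurable and a
    ``ValueError`` is raised.  Per-axis differences are reported when both
    sides carry axis values; centroid separation when both centroids are
    defined.
    """
    if a.property_radius != b.property_radius:
        raise ValueError(
            f"profiles measured against different property radii "
            f"({a.property_radius} vs {b.property_radius})"
        )
    if a.axis_order != b.axis_order:
        raise ValueError(
            f"profiles use different axis orderings ({a.axis_order} vs {b.axis_order})"
        )

    def sub(x, y):
        return None if x is None or y is None else x - y

    separation = None
    if a.centroid is not None and b.centroid is not None:
        separation = math.dist(a.centroid, b.centroid)
    axis_diff = None
    if a.axis_values is not None and b.axis_values is not None:
        axis_diff = {
            name: getattr(a.axis_values, name) - getattr(b.axis_values, name)
            for name in OPERANTS
        }
    return ProfileComparison(
        delta_area=a.area - b.area,
        delta_centroidal_distance=sub(a.centroidal_distance, b.centroidal_distance),
        delta_first_moment=sub(a.first_moment, b.first_moment),
        centroid_separation=separation,
        axis_differences=axis_diff,
    )
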