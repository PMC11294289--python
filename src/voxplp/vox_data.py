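"""Data model and I/O for verbal operant experimental (VOX) assessment records.

A VOX analysis probes the same speaker-selected verbal response forms under
four pure sources of stimulus control — tact, mand, echoic, and sequelic —
and records emission (1) or non-emission (0) of each response under each
condition.  The per-operant totals of such a binary response matrix are the
axis values of one polygonal language profile.

This module owns the trial-level record types, CSV/JSON readers and writers,
and a seeded Bernoulli generator for synthetic response matrices.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: The four verbal operant conditions, in the canonical column order of a
#: VOX response matrix (extraverbal pair first, then the intraverbal pair).
OPERANTS: tuple[str, ...] = ("tact", "mand", "echoic", "sequelic")

#: Canonical column order of the trial-level CSV schema.
TRIAL_COLUMNS: tuple[str, ...] = (
    "speaker_id",
    "session",
    "response_form",
    "condition",
    "emitted",
)


def _normalize_condition(label: str, *, row: int | None = None) -> str:
    cond = str(label).strip().lower()
    if cond not in OPERANTS:
        where = f" (row {row})" if row is not None else ""
        raise ValueError(
            f"unknown operant condition {label!r}{where}; "
            f"expected one of {OPERANTS}"
        )
    return cond


@dataclass(frozen=True)
class VoxTrial:
    """One probe: a response form assessed under one operant condition."""

    speaker_id: str
    session: int
    response_form: str
    condition: str
    emitted: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "condition", _normalize_condition(self.condition))
        if self.session < 0:
            raise ValueError(f"session must be non-negative, got {self.session}")
        if self.emitted not in (0, 1):
            raise ValueError(f"emitted must be 0 or 1, got {self.emitted!r}")


@dataclass(frozen=True)
class SpeakerRecord:
    """Demographic metadata attached to one speaker's assessments."""

    speaker_id: str
    age: tuple[int, int] | None = None  # (years, months), months in [0, 11]
    sex: str | None = None
    race_ethnicity: str | None = None
    home_languages: tuple[str, ...] = ()
    diagnosis: str | None = None

    def __post_init__(self) -> None:
        if self.age is not None:
            years, months = self.age
            if years < 0 or not 0 <= months <= 11:
                raise ValueError(f"invalid age {self.age}; months must be in [0, 11]")

    @property
    def age_label(self) -> str | None:
        """Age formatted as YY:MM, the convention of assessment reports."""
        if self.age is None:
            return None
        return f"{self.age[0]}:{self.age[1]:02d}"


@dataclass(frozen=True)
class AxisValues:
    """Per-operant totals (or frequencies) feeding one radar profile."""

    tact: float
    mand: float
    echoic: float
    sequelic: float

    def __post_init__(self) -> None:
        for name in OPERANTS:
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"axis value {name}={v!r} is not finite")
            if v < 0:
                raise ValueError(f"axis value {name}={v!r} is negative")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in OPERANTS}

    def as_tuple(self, order: Sequence[str] = OPERANTS) -> tuple[float, ...]:
        """Values in the given axis order (defaults to tact, mand, echoic, sequelic)."""
        return tuple(getattr(self, name) for name in order)

    def scaled(self, k: float) -> "AxisValues":
        return AxisValues(**{name: k * getattr(self, name) for name in OPERANTS})


@dataclass
class VoxDataset:
    """An ordered collection of VOX trials, optionally with speaker metadata.

    A complete assessment probes every response form once under each of the
    four operant conditions within a session, with at least three unique
    response forms per session.  ``validate(strict=True)`` enforces that
    contract; by default incomplete probe grids are tolerated with a warning
    (archival records may be partial) and missing probes count as
    not-emitted in totals.
    """

    trials: list[VoxTrial] = field(default_factory=list)
    speaker: SpeakerRecord | None = None

    def __len__(self) -> int:
        return len(self.trials)

    def __iter__(self):
        return iter(self.trials)

    @property
    def sessions(self) -> tuple[int, ...]:
        return tuple(sorted({t.session for t in self.trials}))

    def to_frame(self) -> pd.DataFrame:
        """Trial-level data as a DataFrame in canonical column order."""
        if not self.trials:
            return pd.DataFrame(columns=list(TRIAL_COLUMNS))
        return pd.DataFrame(
            [
                (t.speaker_id, t.session, t.response_form, t.condition, t.emitted)
                for t in self.trials
            ],
            columns=list(TRIAL_COLUMNS),
        )

    def response_matrix(self, session: int | None = None) -> pd.DataFrame:
        """Binary responses-by-conditions matrix.

        Rows are (session, response_form) blocks, columns the four operants.
        Missing probes are filled with 0 (not emitted).  This is the layout
        of a printed VOX data table and the input to the related-samples
        independence test.
        """
        frame = self.to_frame()
        if session is not None:
            frame = frame[frame["session"] == session]
        if frame.empty:
            return pd.DataFrame(columns=list(OPERANTS))
        wide = frame.pivot_table(
            index=["session", "response_form"],
            columns="condition",
            values="emitted",
            aggfunc="sum",
            fill_value=0,
            sort=False,
        )
        return wide.reindex(columns=list(OPERANTS), fill_value=0).astype(int)

    def validate(self, strict: bool = False) -> "VoxDataset":
        """Check the complete-grid contract; warn (default) or raise (strict)."""
        problems: list[str] = []
        frame = self.to_frame()
        for sess, group in frame.groupby("session"):
            forms = group["response_form"].unique()
            if len(forms) < 3:
                problems.append(
                    f"session {sess} probes only {len(forms)} response forms (< 3)"
                )
            counts = group.groupby("response_form")["condition"].agg(
                lambda c: (len(c), c.nunique())
            )
            for form, (n, uniq) in counts.items():
                if n != 4 or uniq != 4:
                    problems.append(
                        f"session {sess}, response {form!r}: probed under {uniq} "
                        f"distinct conditions in {n} trials (expected all 4, once each)"
                    )
        if problems:
            msg = "incomplete probe grid: " + "; ".join(problems)
            if strict:
                raise ValueError(msg)
            logger.warning(msg)
        return self


def concat(datasets: Iterable[VoxDataset]) -> VoxDataset:
    """Concatenate datasets, preserving trial order; metadata from the first."""
    datasets = list(datasets)
    trials = [t for d in datasets for t in d.trials]
    speaker = datasets[0].speaker if datasets else None
    return VoxDataset(trials=trials, speaker=speaker)


def parse_trials(
    source: str | Path | IO[str],
    speaker: SpeakerRecord | None = None,
) -> VoxDataset:
    """Read a trial-level VOX CSV into a validated dataset.

    The canonical schema is ``speaker_id, session, response_form, condition,
    emitted`` with a header row.  Condition labels are matched
    case-insensitively and stored lower-case.  Unknown columns are ignored
    with a logged warning; ``speaker_id`` and ``session`` may be omitted and
    default to ``"unknown"`` and 0.  Row order is preserved.
    """
    frame = pd.read_csv(source, dtype={"response_form": str, "speaker_id": str})
    frame.columns = [str(c).strip().lower() for c in frame.columns]

    extra = [c for c in frame.columns if c not in TRIAL_COLUMNS]
    if extra:
        logger.warning("ignoring unknown columns: %s", ", ".join(extra))

    for required in ("response_form", "condition", "emitted"):
        if required not in frame.columns:
            raise ValueError(f"missing required column {required!r}")
    if "speaker_id" not in frame.columns:
        frame["speaker_id"] = "unknown"
    if "session" not in frame.columns:
        frame["session"] = 0

    trials: list[VoxTrial] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        emitted = getattr(row, "emitted")
        if emitted not in (0, 1):
            raise ValueError(f"emitted must be 0 or 1, got {emitted!r} (row {i})")
        trials.append(
            VoxTrial(
                speaker_id=str(getattr(row, "speaker_id")),
                session=int(getattr(row, "session")),
                response_form=str(getattr(row, "response_form")),
                condition=_normalize_condition(getattr(row, "condition"), row=i),
                emitted=int(emitted),
            )
        )
    return VoxDataset(trials=trials, speaker=speaker)


def write_trials(dataset: VoxDataset, sink: str | Path | IO[str]) -> None:
    """Write a dataset as canonical trial-level CSV (round-trip stable)."""
    frame = dataset.to_frame()
    frame.to_csv(sink, index=False, lineterminator="\n")


def operant_totals(
    dataset: VoxDataset,
    session: int | None = None,
    aggregation: str = "sum",
) -> AxisValues:
    """Per-operant response totals over the selected trials.

    ``aggregation="sum"`` (default) returns raw summed frequencies — the
    totals row of a printed VOX table.  ``aggregation="mean"`` divides by the
    number of sessions selected, giving per-session mean frequencies; both
    are supported because multi-round assessments may be reported either
    way.  An empty selection yields all-zero axis values.
    """
    if aggregation not in ("sum", "mean"):
        raise ValueError(f"aggregation must be 'sum' or 'mean', got {aggregation!r}")
    totals = dict.fromkeys(OPERANTS, 0)
    sessions: set[int] = set()
    for t in dataset.trials:
        if session is not None and t.session != session:
            continue
        totals[t.condition] += t.emitted
        sessions.add(t.session)
    if aggregation == "mean" and sessions:
        n = len(sessions)
        totals = {k: v / n for k, v in totals.items()}
    return AxisValues(**totals)


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a seeded synthetic VOX response matrix.

    Emission under each operant condition is an independent Bernoulli draw
    with a per-operant probability, mimicking the binary structure of a real
    assessment table.  Identical seeds reproduce identical datasets.
    """

    n_responses: int = 6
    n_sessions: int = 1
    emission_probabilities: tuple[float, float, float, float] = (0.8, 0.3, 0.8, 0.2)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_responses < 1 or self.n_sessions < 1:
            raise ValueError("n_responses and n_sessions must be positive")
        if len(self.emission_probabilities) != len(OPERANTS):
            raise ValueError("need one emission probability per operant")
        for p in self.emission_probabilities:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"emission probability {p!r} outside [0, 1]")


def generate_synthetic(spec: SyntheticSpec) -> VoxDataset:
    """Draw a synthetic VOX dataset: n_responses x 4 operants x n_sessions."""
    import numpy as np

    rng = np.random.default_rng(spec.seed)
    width = max(2, len(str(spec.n_responses)))
    trials: list[VoxTrial] = []
    for sess in range(spec.n_sessions):
        for r in range(spec.n_responses):
            form = f"r{r + 1:0{width}d}"
            for cond, p in zip(OPERANTS, spec.emission_probabilities):
                emitted = int(rng.random() < p)
                trials.append(
                    VoxTrial(
                        speaker_id="synthetic",
                        session=sess,
                        response_form=form,
                        condition=cond,
                        emitted=emitted,
                    )
                )
    return VoxDataset(trials=trials, speaker=SpeakerRecord(speaker_id="synthetic"))


# ---------------------------------------------------------------------------
# Descriptor tables (the shape of a longitudinal or cross-speaker report)

#: Canonical column order of the descriptor-row schema, version 1.
DESCRIPTOR_COLUMNS: tuple[str, ...] = (
    "speaker_id",
    "age",
    "tact",
    "mand",
    "echoic",
    "sequelic",
    "area",
    "centroid_x",
    "centroid_y",
    "centroidal_distance",
    "first_moment",
    "property_radius",
    "ordering",
)

#: Descriptor cells reported at 2 decimals in the human-readable CSV.
_ROUNDED = ("area", "centroid_x", "centroid_y", "centroidal_distance", "first_moment")

DESCRIPTOR_SCHEMA_VERSION = 1


def _coerce_rows(records: Iterable) -> list[dict]:
    rows: list[dict] = []
    for rec in records:
        if hasattr(rec, "to_rows"):
            rows.extend(rec.to_rows())
        elif isinstance(rec, Mapping):
            rows.append(dict(rec))
        else:
            raise TypeError(
                f"cannot serialize record of type {type(rec).__name__}; "
                "expected a mapping or an object with to_rows()"
            )
    return rows


def write_descriptors(
    records: Iterable,
    sink: str | Path | IO[str],
    fmt: str = "csv",
) -> None:
    """Serialize descriptor rows (longitudinal/cross-speaker report shape).

    ``records`` may be flat mappings keyed by :data:`DESCRIPTOR_COLUMNS` or
    objects exposing ``to_rows()`` (e.g. a longitudinal series record).  The
    CSV form is human-readable with A, centroid, R and Q rounded to 2
    decimals; the JSON form keeps full floating precision and round-trips
    exactly through :func:`read_descriptors`.
    """
    rows = _coerce_rows(records)
    if fmt == "csv":
        frame = pd.DataFrame(rows, columns=list(DESCRIPTOR_COLUMNS))
        for col in _ROUNDED:
            frame[col] = frame[col].map(
                lambda v: "" if v is None or (isinstance(v, float) and math.isnan(v))
                else f"{float(v):.2f}"
            )
        frame.to_csv(sink, index=False, lineterminator="\n")
    elif fmt == "json":
        doc = {"schema_version": DESCRIPTOR_SCHEMA_VERSION, "records": rows}
        if isinstance(sink, (str, Path)):
            Path(sink).write_text(json.dumps(doc, indent=2) + "\n")
        else:
            json.dump(doc, sink, indent=2)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")


def read_descriptors(source: str | Path | IO[str], fmt: str = "json") -> list[dict]:
    """Parse descriptor rows written by :func:`write_descriptors`."""
    if fmt == "json":
        if isinstance(source, (str, Path)):
            doc = json.loads(Path(source).read_text())
        else:
            doc = json.load(source)
        return list(doc["records"])
    if fmt == "csv":
        frame = pd.read_csv(source, dtype={"speaker_id": str, "age": str})
        return frame.to_dict(orient="records")
    raise ValueError(f"unknown format {fmt!r}; expected 'csv' or 'json'")
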