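"""Core record types shared across the pipeline.

A :class:`PatientTimeline` is the raw unit of input: one patient's visits in
chronological order plus an optional death time.  Times are integer-valued
days since an arbitrary per-patient epoch (day of first recorded contact is
conventionally day 0 after cohort splitting).  A :class:`CohortEntry` is an
eligible, labelled patient ready for temporal windowing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

#: canonical modality names, in the order similarity computations iterate them
MODALITY_NAMES = ("diagnosis", "prescription", "procedure", "labs_vitals")

#: required length of the labs/vitals modality vector (30 most common labs
#: and vitals)
LABS_VITALS_DIM = 30

# calendar approximations used throughout: 1 year = 365 d, 6 months = 183 d,
# 2 years = 730 d
DAYS_PER_YEAR = 365
DAYS_PER_HALF_YEAR = 183
OBSERVATION_WINDOW_DAYS = 730
BUFFER_DAYS = 30
PREDICTION_WINDOW_DAYS = 365


@dataclass
class VisitRecord:
    """A single medical visit.

    At least one of ``note_text`` / ``note_embedding`` must be present for an
    observed visit.  ``modalities`` maps modality name -> 1-D float vector;
    the ``labs_vitals`` vector, when present, has length 30.
    """

    time: float
    note_text: Optional[str] = None
    note_embedding: Optional[np.ndarray] = None
    modalities: dict[str, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if self.note_text is None and self.note_embedding is None:
            raise ValueError(
                f"visit at t={self.time}: needs note_text or note_embedding"
            )
        lv = self.modalities.get("labs_vitals")
        if lv is not None and len(lv) != LABS_VITALS_DIM:
            raise ValueError(
                f"labs_vitals must have length {LABS_VITALS_DIM}, got {len(lv)}"
            )


@dataclass
class PatientTimeline:
    """One patient's ordered visits with an optional death time (days)."""

    patient_id: str
    visits: list[VisitRecord]
    death_time: Optional[float] = None

    def validate(self) -> None:
        if not self.visits:
            raise ValueError(f"patient {self.patient_id}: no visits")
        times = [v.time for v in self.visits]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError(
                f"patient {self.patient_id}: visit times must be strictly "
                "increasing"
            )
        for v in self.visits:
            v.validate()


@dataclass
class CohortEntry:
    """An eligible, labelled patient.

    ``index_time`` is the first observation visit; observation visits lie in
    ``[index_time, index_time + 730]``; ``anchor_time`` (start of the one-year
    prediction window) is the last observation visit plus a 30-day buffer;
    ``label`` is 1 iff death falls in ``(anchor_time, anchor_time + 365]``.
    """

    patient_id: str
    index_time: float
    observation_visits: list[VisitRecord]
    label: int
    anchor_time: float

    def with_visits(self, visits: list[VisitRecord]) -> "CohortEntry":
        return replace(self, observation_visits=visits)


MISSING = None  # a grid slot with no visit


@dataclass
class IntervalGrid:
    """A patient's visits aligned onto K fixed six-month interval slots.

    ``slots[i]`` is the :class:`VisitRecord` kept for interval *i* (the most
    recent visit falling in ``[index + i*183, index + (i+1)*183)``) or
    ``None`` when the interval holds no visit.
    """

    patient_id: str
    index_time: float
    slots: list[Optional[VisitRecord]]
    n_intervals: int = 4
    interval_days: int = DAYS_PER_HALF_YEAR

    @property
    def missing_fraction(self) -> float:
        return sum(s is None for s in self.slots) / len(self.slots)

    def missing_slot_ids(self) -> list[int]:
        return [i for i, s in enumerate(self.slots) if s is None]


# slot provenance tags
PROV_OBSERVED = "observed"
PROV_ZERO = "zero"
PROV_LOCF = "locf"
PROV_MULTIMODAL = "multimodal"
PROV_GENERATED = "generated"


@dataclass
class HarmonizedSequence:
    """Fixed-length embedding sequence with per-slot provenance.

    ``vectors`` has shape (L, d); ``provenance[i]`` records which mechanism
    produced slot i.  Invariant: provenance == "zero" implies the slot vector
    is exactly the zero vector.
    """

    patient_id: str
    vectors: np.ndarray
    provenance: list[str]
    missing_fraction: float

    def __post_init__(self) -> None:
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2:
            raise ValueError("vectors must be a (L, d) array")
        if len(self.provenance) != self.vectors.shape[0]:
            raise ValueError("provenance length must match sequence length")
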