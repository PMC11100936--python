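"""Cohort construction: splitting, eligibility, labelling, balancing.

Rules, in pipeline order:

1. **Split** — visits occurring more than two years (730 d) after a
   segment's first visit start a new pseudo-patient (greedy left-to-right;
   segments share the original death time and get ``id_s<k>`` suffixes).
2. **Eligibility** — the patient must have at least two visits 1–2 years
   apart, read as: some visit pair with gap in [365, 730] days.  An
   alternative reading (>=2 visits inside a 2-year span) is available via
   ``mode="span"``.
3. **Label** — the one-year prediction window starts at the last observation
   visit plus a 30-day buffer (``anchor``); label 1 iff death falls in
   ``(anchor, anchor + 365]``.  Patients who die between index and anchor
   are excluded so no input visit can postdate, or abut, the death.
4. **Balance** — the majority class is randomly downsampled without
   replacement to a 50/50 cohort.
"""

from __future__ import annotations

from typing import Optional

import numpy as np

from .records import (
    BUFFER_DAYS,
    OBSERVATION_WINDOW_DAYS,
    PREDICTION_WINDOW_DAYS,
    CohortEntry,
    PatientTimeline,
)


def split_timeline(
    timeline: PatientTimeline, horizon_days: float = OBSERVATION_WINDOW_DAYS
) -> list[PatientTimeline]:
    """Greedy left-to-right segmentation into <=2-year pseudo-patients.

    A segment starts at the earliest unassigned visit and absorbs every visit
    within ``horizon_days`` of its own first visit.  Segments partition the
    visits.  Single-segment timelines keep the original id unchanged.
    """
    segments: list[list] = []
    current: list = []
    start: Optional[float] = None
    for v in timeline.visits:
        if start is None or v.time - start > horizon_days:
            if current:
                segments.append(current)
            current, start = [], v.time
        current.append(v)
    if current:
        segments.append(current)
    if len(segments) == 1:
        return [PatientTimeline(timeline.patient_id, segments[0], timeline.death_time)]
    return [
        PatientTimeline(f"{timeline.patient_id}_s{k}", seg, timeline.death_time)
        for k, seg in enumerate(segments)
    ]


def is_eligible(
    timeline: PatientTimeline,
    min_gap_days: float = 365.0,
    max_gap_days: float = OBSERVATION_WINDOW_DAYS,
    mode: str = "gap",
) -> bool:
    """Check the two-visits-1-to-2-years-apart rule on a split timeline.

    ``mode="gap"`` (default): some visit pair has a gap in
    [min_gap_days, max_gap_days].  ``mode="span"``: at least two visits lie
    within a max_gap_days span (trivially true for any split timeline with
    >=2 visits).
    """
    times = [v.time for v in timeline.visits]
    if len(times) < 2:
        return False
    if mode == "span":
        return any(
            times[j] - times[i] <= max_gap_days
            for i in range(len(times))
            for j in range(i + 1, len(times))
        )
    if mode != "gap":
        raise ValueError(f"unknown eligibility mode {mode!r}")
    return any(
        min_gap_days <= times[j] - times[i] <= max_gap_days
        for i in range(len(times))
        for j in range(i + 1, len(times))
    )


def label_and_filter(
    timeline: PatientTimeline,
    buffer_days: float = BUFFER_DAYS,
    prediction_days: float = PREDICTION_WINDOW_DAYS,
) -> Optional[CohortEntry]:
    """Label an eligible split timeline, or return None if excluded.

    Excluded when the death time falls inside [index, last visit + buffer]:
    such patients may have died during an input visit or the buffer, so their
    label would be ill-defined.
    """
    index_time = timeline.visits[0].time
    anchor = timeline.visits[-1].time + buffer_days
    death = timeline.death_time
    if death is not None and index_time <= death <= anchor:
        return None
    label = int(
        death is not None and anchor < death <= anchor + prediction_days
    )
    return CohortEntry(
        patient_id=timeline.patient_id,
        index_time=index_time,
        observation_visits=list(timeline.visits),
        label=label,
        anchor_time=anchor,
    )


def downsample_balanced(
    entries: list[CohortEntry], seed: int
) -> list[CohortEntry]:
    """Downsample the majority class to a 50/50 cohort (seeded, order-stable).

    The minority class is kept whole; majority members are chosen uniformly
    without replacement.  Output preserves the input ordering of the kept
    entries.
    """
    pos = [i for i, e in enumerate(entries) if e.label == 1]
    neg = [i for i, e in enumerate(entries) if e.label == 0]
    if not pos or not neg:
        raise ValueError("both labels must be present to balance the cohort")
    rng = np.random.default_rng(seed)
    if len(pos) > len(neg):
        keep_major = rng.choice(pos, size=len(neg), replace=False)
        kept = set(keep_major) | set(neg)
    else:
        keep_major = rng.choice(neg, size=len(pos), replace=False)
        kept = set(keep_major) | set(pos)
    return [e for i, e in enumerate(entries) if i in kept]


def build_cohort(
    timelines: list[PatientTimeline],
    seed: int,
    horizon_days: float = OBSERVATION_WINDOW_DAYS,
    eligibility_mode: str = "gap",
    balance: bool = True,
) -> list[CohortEntry]:
    """Full cohort pipeline: split -> eligibility -> label/filter -> balance."""
    entries: list[CohortEntry] = []
    for tl in timelines:
        for seg in split_timeline(tl, horizon_days):
            if not is_eligible(seg, mode=eligibility_mode):
                continue
            entry = label_and_filter(seg)
            if entry is not None:
                entries.append(entry)
    if balance:
        entries = downsample_balanced(entries, seed)
    return entries
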