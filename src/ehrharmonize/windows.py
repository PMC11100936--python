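"""Temporal windowing: map a cohort entry onto K six-month interval slots.

The first observation visit is the index.  Slot ``i`` covers the half-open
window ``[index + i*183, index + (i+1)*183)``; when several visits fall in
one slot the most recent is kept; an empty slot is MISSING.  Slot 0 always
holds the index visit.  With the default constants (K=4, 183-day intervals,
730-day observation window) no visit can fall past the grid, but a guard is
retained for other configurations.
"""

from __future__ import annotations

import logging

from .records import DAYS_PER_HALF_YEAR, CohortEntry, IntervalGrid

logger = logging.getLogger(__name__)


def build_grid(
    entry: CohortEntry,
    n_intervals: int = 4,
    interval_days: int = DAYS_PER_HALF_YEAR,
) -> IntervalGrid:
    """Assign each observation visit to its interval, keeping the latest.

    Order-independent: shuffled visit input produces an identical grid.
    Visits at or beyond ``index + n_intervals * interval_days`` are dropped
    with a warning.
    """
    if not entry.observation_visits:
        raise ValueError(f"entry {entry.patient_id}: no observation visits")
    index = entry.index_time
    slots = [None] * n_intervals
    for v in entry.observation_visits:
        offset = v.time - index
        if offset < 0:
            raise ValueError(
                f"entry {entry.patient_id}: visit before index time"
            )
        i = int(offset // interval_days)
        if i >= n_intervals:
            logger.warning(
                "patient %s: visit at day %+.0f beyond the %d-slot grid; dropped",
                entry.patient_id, offset, n_intervals,
            )
            continue
        if slots[i] is None or v.time > slots[i].time:
            slots[i] = v
    return IntervalGrid(
        patient_id=entry.patient_id,
        index_time=index,
        slots=slots,
        n_intervals=n_intervals,
        interval_days=interval_days,
    )
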