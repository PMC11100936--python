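from __future__ import annotations

import numpy as np
import pytest

from ehrharmonize.records import IntervalGrid, PatientTimeline, VisitRecord


def make_timeline(days, death=None, pid="p0") -> PatientTimeline:
    return PatientTimeline(
        pid,
        [VisitRecord(time=float(t), note_text=f"note day {t}") for t in days],
        death,
    )


def make_grid(pattern, pid="target", index_time=0.0, dim=6, rng=None,
              n_modalities=2, modality_dim=5) -> IntervalGrid:
    """Grid from a pattern like [1, 0, 0, 1] (1 = observed visit).

    Observed slots get random embeddings and random modality vectors.
    """
    rng = rng or np.random.default_rng(0)
    slots = []
    for i, present in enumerate(pattern):
        if not present:
            slots.append(None)
            continue
        slots.append(VisitRecord(
            time=index_time + i * 183 + 1,
            note_text=f"{pid} note for interval {i}",
            note_embedding=rng.normal(size=dim),
            modalities={
                f"mod{k}": rng.normal(size=modality_dim)
                for k in range(n_modalities)
            },
        ))
    return IntervalGrid(pid, index_time, slots)


def random_pool(seed, n_patients=20, dim=6, n_modalities=3, drop_modality_p=0.2):
    """Random grids with varied missingness and occasional absent modalities."""
    rng = np.random.default_rng(seed)
    grids = []
    for p in range(n_patients):
        while True:
            pattern = rng.integers(0, 2, size=4)
            if pattern.any():
                break
        slots = []
        for i, present in enumerate(pattern):
            if not present:
                slots.append(None)
                continue
            modalities = {
                f"mod{k}": rng.normal(size=4)
                for k in range(n_modalities)
                if rng.uniform() > drop_modality_p
            }
            slots.append(VisitRecord(
                time=i * 183.0,
                note_text=f"p{p} i{i}",
                note_embedding=rng.normal(size=dim),
                modalities=modalities,
            ))
        grids.append(IntervalGrid(f"p{p:03d}", 0.0, slots))
    return grids


@pytest.fixture(scope="session")
def small_sim():
    """A 300-patient synthetic cohort shared across tests."""
    from ehrharmonize.simulate import SimConfig, generate_cohort

    return generate_cohort(SimConfig(n_patients=300, seed=42))
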