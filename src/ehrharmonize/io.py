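"""JSONL record schema and serialization.

One patient per line::

    {"patient_id": "...", "death_time": 812.0 | null,
     "visits": [{"time": 0, "note_text": "...", "note_embedding": [...]|null,
                 "modalities": {"diagnosis": [...], "prescription": [...],
                                "procedure": [...], "labs_vitals": [30 floats]}}]}

Reads are schema-validated; a malformed line raises an error naming its line
number, and duplicate patient ids are rejected.  ``read_records(write_records(x))``
round-trips exactly (embeddings are serialized at full float precision).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np

from .records import (
    CohortEntry,
    HarmonizedSequence,
    IntervalGrid,
    PatientTimeline,
    VisitRecord,
)


class RecordSchemaError(ValueError):
    """A JSONL line violating the patient-record schema."""


def _visit_to_json(v: VisitRecord) -> dict:
    return {
        "time": v.time,
        "note_text": v.note_text,
        "note_embedding": None if v.note_embedding is None
        else [float(x) for x in v.note_embedding],
        "modalities": {k: [float(x) for x in vec] for k, vec in v.modalities.items()},
    }


def _visit_from_json(obj: dict, where: str) -> VisitRecord:
    if not isinstance(obj, dict) or "time" not in obj:
        raise RecordSchemaError(f"{where}: visit must be an object with a 'time' field")
    emb = obj.get("note_embedding")
    modalities = obj.get("modalities") or {}
    if not isinstance(modalities, dict):
        raise RecordSchemaError(f"{where}: 'modalities' must be an object")
    v = VisitRecord(
        time=float(obj["time"]),
        note_text=obj.get("note_text"),
        note_embedding=None if emb is None else np.asarray(emb, dtype=float),
        modalities={k: np.asarray(vec, dtype=float) for k, vec in modalities.items()},
    )
    try:
        v.validate()
    except ValueError as e:
        raise RecordSchemaError(f"{where}: {e}") from None
    return v


def write_records(timelines: list[PatientTimeline], path: Union[str, Path]) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for tl in timelines:
            fh.write(json.dumps({
                "patient_id": tl.patient_id,
                "death_time": tl.death_time,
                "visits": [_visit_to_json(v) for v in tl.visits],
            }) + "\n")


def read_records(path: Union[str, Path]) -> list[PatientTimeline]:
    path = Path(path)
    timelines: list[PatientTimeline] = []
    seen: set[str] = set()
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as e:
                raise RecordSchemaError(f"line {lineno}: malformed JSON ({e.msg})") from None
            where = f"line {lineno}"
            if not isinstance(obj, dict) or "patient_id" not in obj:
                raise RecordSchemaError(f"{where}: record needs a 'patient_id'")
            pid = str(obj["patient_id"])
            if pid in seen:
                raise RecordSchemaError(f"{where}: duplicate patient_id {pid!r}")
            seen.add(pid)
            visits_raw = obj.get("visits")
            if not isinstance(visits_raw, list) or not visits_raw:
                raise RecordSchemaError(f"{where}: 'visits' must be a nonempty list")
            death = obj.get("death_time")
            tl = PatientTimeline(
                patient_id=pid,
                visits=[_visit_from_json(v, f"{where}, visit {k}")
                        for k, v in enumerate(visits_raw)],
                death_time=None if death is None else float(death),
            )
            try:
                tl.validate()
            except ValueError as e:
                raise RecordSchemaError(f"{where}: {e}") from None
            timelines.append(tl)
    return timelines


# ---------------------------------------------------------------------------
# intermediate artifacts (cohort entries, interval grids, sequences)
# ---------------------------------------------------------------------------

def write_entries(entries: list[CohortEntry], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for e in entries:
            fh.write(json.dumps({
                "patient_id": e.patient_id,
                "index_time": e.index_time,
                "anchor_time": e.anchor_time,
                "label": e.label,
                "visits": [_visit_to_json(v) for v in e.observation_visits],
            }) + "\n")


def read_entries(path: Union[str, Path]) -> list[CohortEntry]:
    entries = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            entries.append(CohortEntry(
                patient_id=str(obj["patient_id"]),
                index_time=float(obj["index_time"]),
                anchor_time=float(obj["anchor_time"]),
                label=int(obj["label"]),
                observation_visits=[
                    _visit_from_json(v, f"line {lineno}, visit {k}")
                    for k, v in enumerate(obj["visits"])
                ],
            ))
    return entries


def write_grids(grids: list[IntervalGrid], path: Union[str, Path]) -> None:
    with Path(path).open("w") as fh:
        for g in grids:
            fh.write(json.dumps({
                "patient_id": g.patient_id,
                "index_time": g.index_time,
                "n_intervals": g.n_intervals,
                "interval_days": g.interval_days,
                "slots": [None if s is None else _visit_to_json(s) for s in g.slots],
            }) + "\n")


def read_grids(path: Union[str, Path]) -> list[IntervalGrid]:
    grids = []
    with Path(path).open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            obj = json.loads(line)
            grids.append(IntervalGrid(
                patient_id=str(obj["patient_id"]),
                index_time=float(obj["index_time"]),
                n_intervals=int(obj["n_intervals"]),
                interval_days=int(obj["interval_days"]),
                slots=[None if s is None
                       else _visit_from_json(s, f"line {lineno}, slot {k}")
                       for k, s in enumerate(obj["slots"])],
            ))
    return grids


def write_sequences(seqs: list[HarmonizedSequence], path: Union[str, Path]) -> None:
    """Dense array stack in .npz plus per-patient provenance metadata."""
    path = Path(path)
    np.savez(
        path,
        vectors=np.stack([s.vectors for s in seqs]),
        missing_fraction=np.array([s.missing_fraction for s in seqs]),
        patient_ids=np.array([s.patient_id for s in seqs]),
        provenance=np.array([s.provenance for s in seqs]),
    )


def read_sequences(path: Union[str, Path]) -> list[HarmonizedSequence]:
    with np.load(Path(path), allow_pickle=False) as data:
        return [
            HarmonizedSequence(
                patient_id=str(pid),
                vectors=vec,
                provenance=[str(p) for p in prov],
                missing_fraction=float(fr),
            )
            for pid, vec, prov, fr in zip(
                data["patient_ids"], data["vectors"],
                data["provenance"], data["missing_fraction"],
            )
        ]
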