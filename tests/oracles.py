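"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive results from first principles (pair
enumeration, exhaustive candidate search) and share no code with the
production paths they verify.
"""

from __future__ import annotations

import numpy as np


def concordant_pair_auc(scores, labels) -> float:
    """AUC as the concordant-pair fraction with half credit for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = len(pos) * len(neg)
    conc = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                conc += 1.0
            elif p == q:
                conc += 0.5
    return conc / total


def _cos(u, v) -> float:
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def brute_force_donor(target_grid, donor_grids, slot_id):
    """Exhaustively find the best donor (patient_id, slot, embedding) for one
    missing slot, re-deriving the query, the masking, the shared-modality
    mean-cosine score and the (donor id, slot) tie-break from the rules.
    """
    # query: slot-level modalities if a visit is present, else per-modality
    # mean over the target's observed slots
    slot = target_grid.slots[slot_id]
    if slot is not None and slot.modalities:
        query = {k: np.asarray(v, float) for k, v in slot.modalities.items()}
    else:
        acc: dict[str, list] = {}
        for s in target_grid.slots:
            if s is None:
                continue
            for k, v in s.modalities.items():
                acc.setdefault(k, []).append(np.asarray(v, float))
        query = {k: np.mean(vs, axis=0) for k, vs in acc.items()}
    if not query:
        return None  # no structured data at all -> zero-vector fallback

    best = None  # (score, donor_id, slot_idx, embedding)
    for g in donor_grids:
        if g.patient_id == target_grid.patient_id:
            continue
        for j, visit in enumerate(g.slots):
            if visit is None or visit.note_embedding is None:
                continue
            sims = [
                _cos(qv, np.asarray(visit.modalities[name], float))
                for name, qv in query.items()
                if name in visit.modalities
            ]
            score = float(np.mean(sims)) if sims else 0.0
            key = (-score, g.patient_id, j)
            if best is None or key < best[0]:
                best = (key, g.patient_id, j, np.asarray(visit.note_embedding, float))
    if best is None:
        raise ValueError("empty donor pool")
    return best[1], best[2], best[3]
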