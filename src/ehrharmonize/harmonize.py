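"""The four gap-filling strategies producing fixed-shape model inputs.

Given per-visit note embeddings (and, for the windowed methods, the K-slot
interval grid), each strategy returns a :class:`HarmonizedSequence` — a fixed
length stack of d-vectors with per-slot provenance:

* ``zero_pad`` — observed embeddings in chronological order, zero vectors to
  a fixed maximum length (the classical variable-length baseline),
* ``locf_fill`` — last observation carried forward along the K-slot grid; a
  gap before the first observation becomes a zero vector,
* ``multimodal_impute`` — cross-patient nearest-neighbour: a missing note
  embedding is copied from the donor visit most similar on the *observed*
  structured modalities (cosine similarity averaged over shared modalities),
  with all of the target patient's own notes masked out of the donor pool,
* ``generative_fill`` — a text generator writes a note for each gap from the
  patient's existing notes; the generated text is preprocessed and embedded
  like any other note.

All strategies leave observed slots bit-identical to their inputs.
"""

from __future__ import annotations

import logging
from typing import Optional, Sequence

import numpy as np

from .embedding import EmbeddingConfig, EmbeddingProvider, preprocess
from .prompting import (
    GenerationParseError,
    TextGenerationProvider,
    build_one_shot,
    build_zero_shot,
    parse_generated,
)
from .records import (
    PROV_GENERATED,
    PROV_LOCF,
    PROV_MULTIMODAL,
    PROV_OBSERVED,
    PROV_ZERO,
    HarmonizedSequence,
    IntervalGrid,
)

logger = logging.getLogger(__name__)

MAX_VISITS = 79  # fixed sequence length for the zero-padding baseline


class DonorPoolError(ValueError):
    """Raised when no eligible donor remains after same-patient masking."""


def _slot_embedding(slot, embedder: Optional[EmbeddingProvider] = None,
                    config: Optional[EmbeddingConfig] = None) -> np.ndarray:
    if slot.note_embedding is not None:
        return np.asarray(slot.note_embedding, dtype=float)
    if slot.note_text is not None and embedder is not None:
        cfg = config or EmbeddingConfig(dim=embedder.dim)
        return embedder.embed(preprocess(slot.note_text, cfg))
    raise ValueError("observed slot has neither an embedding nor usable text")


# ---------------------------------------------------------------------------
# zero padding
# ---------------------------------------------------------------------------

def zero_pad(
    visit_embeddings: Sequence[np.ndarray],
    max_len: int = MAX_VISITS,
    patient_id: str = "",
) -> HarmonizedSequence:
    """Pad a chronological embedding list with zero vectors to ``max_len``."""
    n = len(visit_embeddings)
    if n == 0:
        raise ValueError("at least one visit embedding is required")
    if n > max_len:
        raise ValueError(f"{n} visits exceed the maximum sequence length {max_len}")
    d = len(visit_embeddings[0])
    vectors = np.zeros((max_len, d))
    for i, v in enumerate(visit_embeddings):
        vectors[i] = v
    provenance = [PROV_OBSERVED] * n + [PROV_ZERO] * (max_len - n)
    return HarmonizedSequence(patient_id, vectors, provenance, (max_len - n) / max_len)


# ---------------------------------------------------------------------------
# last observation carried forward
# ---------------------------------------------------------------------------

def locf_fill(
    grid: IntervalGrid,
    embedder: Optional[EmbeddingProvider] = None,
    dim: Optional[int] = None,
) -> HarmonizedSequence:
    """Left-to-right scan carrying the most recent observed embedding forward.

    A missing slot with no prior observation (missing first visit) gets the
    zero vector.
    """
    observed = [s for s in grid.slots if s is not None]
    if dim is None:
        if not observed:
            raise ValueError("dim must be given for an all-missing grid")
        dim = len(_slot_embedding(observed[0], embedder))
    vectors = np.zeros((grid.n_intervals, dim))
    provenance: list[str] = []
    last: Optional[np.ndarray] = None
    for i, slot in enumerate(grid.slots):
        if slot is not None:
            last = _slot_embedding(slot, embedder)
            vectors[i] = last
            provenance.append(PROV_OBSERVED)
        elif last is not None:
            vectors[i] = last
            provenance.append(PROV_LOCF)
        else:
            provenance.append(PROV_ZERO)
    return HarmonizedSequence(grid.patient_id, vectors, provenance, grid.missing_fraction)


# ---------------------------------------------------------------------------
# multimodal cross-patient imputation
# ---------------------------------------------------------------------------

def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; the zero vector is defined to have similarity 0."""
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(np.dot(u, v) / (nu * nv))


def _query_modalities(grid: IntervalGrid, slot_id: int) -> dict[str, np.ndarray]:
    """Per-modality query for a missing slot.

    Uses the slot's own modality vector when a visit is present (possible
    when only the note is missing), otherwise the mean of that modality over
    the patient's observed slots.
    """
    slot = grid.slots[slot_id]
    query: dict[str, np.ndarray] = {}
    if slot is not None and slot.modalities:
        for name, vec in slot.modalities.items():
            query[name] = np.asarray(vec, dtype=float)
        return query
    pooled: dict[str, list[np.ndarray]] = {}
    for s in grid.slots:
        if s is None:
            continue
        for name, vec in s.modalities.items():
            pooled.setdefault(name, []).append(np.asarray(vec, dtype=float))
    for name, vecs in pooled.items():
        query[name] = np.mean(vecs, axis=0)
    return query


def _candidate_pool(
    target_id: str, donor_grids: Sequence[IntervalGrid], same_slot_only: bool,
    slot_id: int,
):
    """(donor_id, slot_idx, visit) pool sorted for deterministic tie-breaks."""
    pool = []
    for g in sorted(donor_grids, key=lambda g: g.patient_id):
        if g.patient_id == target_id:
            continue  # same-patient masking
        for j, visit in enumerate(g.slots):
            if visit is None or visit.note_embedding is None:
                continue
            if same_slot_only and j != slot_id:
                continue
            pool.append((g.patient_id, j, visit))
    return pool


def score_candidate(
    query: dict[str, np.ndarray], visit, aggregate: str = "mean"
) -> float:
    """Similarity between a modality query and a candidate donor visit.

    Mean (default) or median ("majority" variant) of cosine similarities over
    the modalities available in both; 0 when none are shared.
    """
    sims = [
        cosine(qvec, np.asarray(visit.modalities[name], dtype=float))
        for name, qvec in query.items()
        if name in visit.modalities
    ]
    if not sims:
        return 0.0
    return float(np.median(sims)) if aggregate == "majority" else float(np.mean(sims))


def multimodal_impute(
    target_grid: IntervalGrid,
    donor_grids: Sequence[IntervalGrid],
    aggregate: str = "mean",
    same_slot_only: bool = False,
    embedder: Optional[EmbeddingProvider] = None,
    dim: Optional[int] = None,
) -> HarmonizedSequence:
    """Fill missing note embeddings from the most similar other-patient visit.

    For each missing slot the query is the target's structured-modality
    profile (slot-level when present, else the patient-level mean); every
    observed visit of every *other* patient is a candidate, scored by cosine
    similarity over the modalities shared with the query; the best
    candidate's note embedding is copied.  Ties break to the lower donor id,
    then the earlier slot.  A target with no structured data at all falls
    back to the zero vector.
    """
    observed = [s for s in target_grid.slots if s is not None]
    if dim is None:
        if not observed:
            raise ValueError("dim must be given for an all-missing grid")
        dim = len(_slot_embedding(observed[0], embedder))
    vectors = np.zeros((target_grid.n_intervals, dim))
    provenance: list[str] = []
    for i, slot in enumerate(target_grid.slots):
        if slot is not None:
            vectors[i] = _slot_embedding(slot, embedder)
            provenance.append(PROV_OBSERVED)
            continue
        pool = _candidate_pool(target_grid.patient_id, donor_grids, same_slot_only, i)
        if not pool:
            raise DonorPoolError(
                f"no donor visits remain for patient {target_grid.patient_id!r} "
                "after same-patient masking"
            )
        query = _query_modalities(target_grid, i)
        if not query:
            provenance.append(PROV_ZERO)
            continue
        best_score, best_visit = -np.inf, None
        for _, _, visit in pool:  # pool is tie-break sorted
            s = score_candidate(query, visit, aggregate)
            if s > best_score:
                best_score, best_visit = s, visit
        vectors[i] = np.asarray(best_visit.note_embedding, dtype=float)
        provenance.append(PROV_MULTIMODAL)
    return HarmonizedSequence(
        target_grid.patient_id, vectors, provenance, target_grid.missing_fraction
    )


def multimodal_impute_batch(
    grids: Sequence[IntervalGrid],
    aggregate: str = "mean",
    embedder: Optional[EmbeddingProvider] = None,
    dim: Optional[int] = None,
    block: int = 512,
) -> list[HarmonizedSequence]:
    """Vectorised multimodal imputation over a whole cohort.

    Every grid serves as donor pool for every other; scoring, masking and
    tie-breaking are identical to :func:`multimodal_impute` (which remains
    the readable per-patient reference), but similarities are computed as
    blocked matrix products.  Only ``aggregate="mean"`` is vectorised.
    """
    if aggregate != "mean":
        return [multimodal_impute(g, grids, aggregate=aggregate,
                                  embedder=embedder, dim=dim) for g in grids]
    # candidate pool, sorted by (patient_id, slot) for first-argmax tie-breaks
    cands = []
    for g in sorted(grids, key=lambda g: g.patient_id):
        for j, v in enumerate(g.slots):
            if v is not None and v.note_embedding is not None:
                cands.append((g.patient_id, j, v))
    if not cands:
        raise DonorPoolError("no candidate visits with note embeddings")
    cand_pids = np.array([c[0] for c in cands])
    cand_emb = np.stack([np.asarray(c[2].note_embedding, float) for c in cands])
    modality_names = sorted({m for _, _, v in cands for m in v.modalities})
    cand_mod = {}
    for name in modality_names:
        dims = {len(v.modalities[name]) for _, _, v in cands if name in v.modalities}
        dm = dims.pop()
        mat = np.zeros((len(cands), dm))
        for k, (_, _, v) in enumerate(cands):
            if name in v.modalities:
                mat[k] = v.modalities[name]
        norms = np.linalg.norm(mat, axis=1)
        nz = norms > 0
        mat[nz] /= norms[nz, None]
        cand_mod[name] = mat

    # queries: one per (grid, missing slot)
    queries, owners = [], []  # owners[i] = (grid index, slot index)
    for gi, g in enumerate(grids):
        for i in g.missing_slot_ids():
            queries.append(_query_modalities(g, i))
            owners.append((gi, i))

    cand_present = {
        name: np.array([name in v.modalities for _, _, v in cands])
        for name in modality_names
    }
    chosen = np.full(len(queries), -1, dtype=int)
    for lo in range(0, len(queries), block):
        hi = min(lo + block, len(queries))
        nq = hi - lo
        total = np.zeros((nq, len(cands)))
        count = np.zeros((nq, len(cands)))
        for name in modality_names:
            # absent or zero-norm rows are zero vectors, so the matrix
            # product already yields similarity 0 for them
            qmat = np.zeros((nq, cand_mod[name].shape[1]))
            qhas = np.zeros(nq, dtype=bool)
            for r, q in enumerate(queries[lo:hi]):
                if name in q:
                    qhas[r] = True
                    nrm = np.linalg.norm(q[name])
                    if nrm > 0:
                        qmat[r] = q[name] / nrm
            total += qmat @ cand_mod[name].T
            count += np.outer(qhas, cand_present[name])
        scores = np.where(count > 0, total / np.maximum(count, 1), 0.0)
        for r in range(nq):
            gi, _ = owners[lo + r]
            mask = cand_pids == grids[gi].patient_id
            row = scores[r].copy()
            row[mask] = -np.inf
            if np.all(np.isinf(row)):
                continue  # no donors; handled below as error
            if queries[lo + r]:
                chosen[lo + r] = int(np.argmax(row))

    out: list[HarmonizedSequence] = []
    qptr = 0
    for gi, g in enumerate(grids):
        observed = [s for s in g.slots if s is not None]
        d = dim if dim is not None else len(_slot_embedding(observed[0], embedder))
        vectors = np.zeros((g.n_intervals, d))
        provenance: list[str] = []
        for i, slot in enumerate(g.slots):
            if slot is not None:
                vectors[i] = _slot_embedding(slot, embedder)
                provenance.append(PROV_OBSERVED)
                continue
            k = chosen[qptr]
            if not queries[qptr]:
                provenance.append(PROV_ZERO)
            elif k < 0:
                raise DonorPoolError(
                    f"no donor visits remain for patient {g.patient_id!r}"
                )
            else:
                vectors[i] = cand_emb[k]
                provenance.append(PROV_MULTIMODAL)
            qptr += 1
        out.append(HarmonizedSequence(g.patient_id, vectors, provenance,
                                      g.missing_fraction))
    return out


# ---------------------------------------------------------------------------
# generative gap filling
# ---------------------------------------------------------------------------

def generative_fill(
    target_grid: IntervalGrid,
    provider: TextGenerationProvider,
    embedder: EmbeddingProvider,
    mode: str = "zero_shot",
    example: Optional[tuple[str, str]] = None,
    embed_config: Optional[EmbeddingConfig] = None,
) -> HarmonizedSequence:
    """Generate a note per gap, then preprocess and embed it like any note.

    One provider call per grid.  Unparseable provider output is retried
    once; slots still unfilled after the retry fall back to carry-forward
    with a warning.  A grid without gaps never calls the provider.
    """
    cfg = embed_config or EmbeddingConfig(dim=embedder.dim)
    missing = target_grid.missing_slot_ids()
    if not missing:
        vectors = np.stack(
            [_slot_embedding(s, embedder, cfg) for s in target_grid.slots]
        )
        return HarmonizedSequence(
            target_grid.patient_id, vectors,
            [PROV_OBSERVED] * target_grid.n_intervals, 0.0,
        )

    slot_texts = [
        None if s is None else (s.note_text or "(note text unavailable)")
        for s in target_grid.slots
    ]
    if mode == "one_shot":
        if example is None:
            raise ValueError("one_shot mode requires an example pair")
        bundle = build_one_shot(example, slot_texts)
    elif mode == "zero_shot":
        bundle = build_zero_shot(slot_texts)
    else:
        raise ValueError(f"unknown prompting mode {mode!r}")

    notes: dict[int, str] = {}
    for attempt in range(2):
        try:
            notes = parse_generated(provider.generate(bundle.text), missing)
            break
        except GenerationParseError:
            if attempt == 1:
                logger.warning(
                    "patient %s: generation unparseable after retry; falling "
                    "back to carry-forward for slots %s",
                    target_grid.patient_id, missing,
                )

    dim = embedder.dim
    vectors = np.zeros((target_grid.n_intervals, dim))
    provenance: list[str] = []
    locf_seq = locf_fill(target_grid, embedder, dim=dim) if not notes else None
    for i, slot in enumerate(target_grid.slots):
        if slot is not None:
            vectors[i] = _slot_embedding(slot, embedder, cfg)
            provenance.append(PROV_OBSERVED)
        elif notes:
            vectors[i] = embedder.embed(preprocess(notes[i], cfg))
            provenance.append(PROV_GENERATED)
        else:
            vectors[i] = locf_seq.vectors[i]
            provenance.append(locf_seq.provenance[i])
    return HarmonizedSequence(
        target_grid.patient_id, vectors, provenance, target_grid.missing_fraction
    )
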