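"""Gap-filling strategies: fixtures, invariants, oracle equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ehrharmonize.embedding import EmbeddingConfig, HashingEmbedder
from ehrharmonize.harmonize import (
    DonorPoolError,
    generative_fill,
    locf_fill,
    multimodal_impute,
    multimodal_impute_batch,
    zero_pad,
)
from ehrharmonize.prompting import MockProvider
from ehrharmonize.records import IntervalGrid, VisitRecord

from conftest import make_grid, random_pool
from oracles import brute_force_donor


def grid_from_vectors(vectors, pid="p"):
    """IntervalGrid whose observed slots carry the given embeddings."""
    slots = [
        None if v is None else VisitRecord(
            time=i * 183.0, note_text=f"note {i}", note_embedding=np.asarray(v))
        for i, v in enumerate(vectors)
    ]
    return IntervalGrid(pid, 0.0, slots)


class TestZeroPad:
    def test_three_visits_pad_to_full_length(self):
        rng = np.random.default_rng(0)
        vecs = [rng.normal(size=8) for _ in range(3)]
        seq = zero_pad(vecs, max_len=79)
        assert seq.vectors.shape == (79, 8)
        assert seq.provenance == ["observed"] * 3 + ["zero"] * 76

    @given(st.integers(1, 79), st.integers(0, 1000))
    @settings(deadline=None, max_examples=60)
    def test_prefix_preserved_and_tail_zero(self, n, seed):
        rng = np.random.default_rng(seed)
        vecs = [rng.normal(size=5) for _ in range(n)]
        seq = zero_pad(vecs, max_len=79)
        assert seq.vectors.shape[0] == 79
        assert np.array_equal(seq.vectors[:n], np.asarray(vecs))
        assert not seq.vectors[n:].any()
        assert seq.missing_fraction == pytest.approx((79 - n) / 79)

    def test_full_sequence_unpadded(self):
        vecs = [np.ones(3)] * 4
        seq = zero_pad(vecs, max_len=4)
        assert seq.provenance == ["observed"] * 4

    def test_overflow_and_empty_rejected(self):
        with pytest.raises(ValueError):
            zero_pad([np.ones(3)] * 5, max_len=4)
        with pytest.raises(ValueError):
            zero_pad([], max_len=4)


class TestLocf:
    def test_carry_forward_fixture(self):
        v1, v4 = np.full(4, 1.0), np.full(4, 4.0)
        seq = locf_fill(grid_from_vectors([v1, None, None, v4]))
        assert np.array_equal(seq.vectors, np.stack([v1, v1, v1, v4]))
        assert seq.provenance == ["observed", "locf", "locf", "observed"]

    def test_missing_first_visit_gets_zero_vector(self):
        v2 = np.full(4, 2.0)
        seq = locf_fill(grid_from_vectors([None, v2, None, None]))
        assert np.array_equal(seq.vectors,
                              np.stack([np.zeros(4), v2, v2, v2]))
        assert seq.provenance == ["zero", "observed", "locf", "locf"]

    def test_fully_observed_identity(self):
        vecs = [np.full(3, i + 1.0) for i in range(4)]
        seq = locf_fill(grid_from_vectors(vecs))
        assert np.array_equal(seq.vectors, np.stack(vecs))
        assert seq.provenance == ["observed"] * 4

    def test_no_zero_vector_after_first_observation(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            pattern = rng.integers(0, 2, size=4)
            pattern[rng.integers(0, 4)] = 1
            vecs = [rng.normal(size=3) + 10 if p else None for p in pattern]
            seq = locf_fill(grid_from_vectors(vecs))
            first = next(i for i, p in enumerate(pattern) if p)
            assert all(seq.vectors[i].any() for i in range(first, 4))


def _mod_visit(embedding, modalities, time=0.0):
    return VisitRecord(time=time, note_text="n", note_embedding=embedding,
                       modalities=modalities)


class TestMultimodalImpute:
    def test_exact_match_donor_wins_over_orthogonal(self):
        q = np.array([1.0, 0.0, 0.0])
        target = IntervalGrid("t", 0.0, [
            _mod_visit(np.zeros(4), {"m": q}),
            None, None,
            _mod_visit(np.zeros(4), {"m": q}, time=3 * 183.0),
        ])
        donor_match = IntervalGrid("a", 0.0, [
            _mod_visit(np.full(4, 7.0), {"m": q * 2}), None, None, None])
        donor_ortho = IntervalGrid("b", 0.0, [
            _mod_visit(np.full(4, 9.0), {"m": np.array([0.0, 1.0, 0.0])}),
            None, None, None])
        seq = multimodal_impute(target, [donor_ortho, donor_match])
        assert np.array_equal(seq.vectors[1], np.full(4, 7.0))
        assert seq.provenance[1] == "multimodal"

    def test_same_patient_pool_rejected(self):
        target = make_grid([1, 0, 1, 1], pid="t")
        with pytest.raises(DonorPoolError):
            multimodal_impute(target, [target])

    def test_never_selects_own_patient(self):
        grids = random_pool(seed=3, n_patients=8)
        for g in grids:
            if not g.missing_slot_ids():
                continue
            seq = multimodal_impute(g, grids)
            own = [np.asarray(s.note_embedding) for s in g.slots if s is not None]
            for i in g.missing_slot_ids():
                if seq.provenance[i] == "multimodal":
                    assert not any(np.array_equal(seq.vectors[i], v) for v in own)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_enumeration(self, seed):
        grids = random_pool(seed=seed, n_patients=15)
        for g in grids:
            seq = multimodal_impute(g, grids)
            for i in g.missing_slot_ids():
                expected = brute_force_donor(g, grids, i)
                if expected is None:
                    assert seq.provenance[i] == "zero"
                else:
                    _, _, emb = expected
                    assert np.array_equal(seq.vectors[i], emb)

    def test_donor_order_invariance(self):
        grids = random_pool(seed=11, n_patients=10)
        target = next(g for g in grids if g.missing_slot_ids())
        a = multimodal_impute(target, grids)
        b = multimodal_impute(target, list(reversed(grids)))
        assert np.array_equal(a.vectors, b.vectors)

    @pytest.mark.parametrize("seed", range(3))
    def test_batch_path_equals_reference(self, seed):
        grids = random_pool(seed=100 + seed, n_patients=12)
        batch = multimodal_impute_batch(grids)
        for g, bseq in zip(grids, batch):
            ref = multimodal_impute(g, grids)
            assert np.array_equal(bseq.vectors, ref.vectors)
            assert bseq.provenance == ref.provenance


class TestGenerativeFill:
    @pytest.fixture()
    def embedder(self):
        return HashingEmbedder(EmbeddingConfig(dim=6))

    def test_generated_slots_embed_the_mock_notes(self, embedder):
        from ehrharmonize.prompting import build_zero_shot, parse_generated
        from ehrharmonize.embedding import preprocess

        grid = make_grid([1, 0, 1, 0], pid="g")
        provider = MockProvider(seed=1)
        seq = generative_fill(grid, provider, embedder)
        slot_texts = [None if s is None else s.note_text for s in grid.slots]
        bundle = build_zero_shot(slot_texts)
        notes = parse_generated(provider.generate(bundle.text),
                                bundle.missing_slot_ids)
        cfg = EmbeddingConfig(dim=6)
        for i in bundle.missing_slot_ids:
            assert np.array_equal(seq.vectors[i],
                                  embedder.embed(preprocess(notes[i], cfg)))
            assert seq.provenance[i] == "generated"

    def test_no_missing_slots_provider_never_called(self, embedder):
        class ExplodingProvider:
            def generate(self, prompt):
                raise AssertionError("provider must not be called")

        grid = make_grid([1, 1, 1, 1], dim=6)
        seq = generative_fill(grid, ExplodingProvider(), embedder)
        assert seq.provenance == ["observed"] * 4

    def test_deterministic(self, embedder):
        grid = make_grid([1, 0, 0, 1], dim=6)
        a = generative_fill(grid, MockProvider(seed=2), embedder)
        b = generative_fill(grid, MockProvider(seed=2), embedder)
        assert np.array_equal(a.vectors, b.vectors)

    def test_unparseable_provider_falls_back_to_locf(self, embedder, caplog):
        class GarbageProvider:
            calls = 0

            def generate(self, prompt):
                type(self).calls += 1
                return "not a delimited response"

        grid = make_grid([1, 0, 0, 1], dim=6)
        import logging

        with caplog.at_level(logging.WARNING):
            seq = generative_fill(grid, GarbageProvider(), embedder)
        assert GarbageProvider.calls == 2  # one retry
        locf = locf_fill(grid, dim=6)
        assert np.array_equal(seq.vectors, locf.vectors)
        assert any("falling back" in r.message for r in caplog.records)

    def test_one_shot_requires_example(self, embedder):
        grid = make_grid([1, 0, 1, 1], dim=6)
        with pytest.raises(ValueError, match="example"):
            generative_fill(grid, MockProvider(), embedder, mode="one_shot")


class TestObservedSlotsUntouched:
    """All strategies must leave observed slots bit-identical."""

    def test_all_methods_preserve_observed_vectors(self):
        grids = random_pool(seed=21, n_patients=8, dim=6)
        embedder = HashingEmbedder(EmbeddingConfig(dim=6))
        for g in grids:
            observed = {i: np.asarray(s.note_embedding)
                        for i, s in enumerate(g.slots) if s is not None}
            for seq in (
                locf_fill(g, dim=6),
                multimodal_impute(g, grids, dim=6),
                generative_fill(g, MockProvider(seed=0), embedder),
            ):
                for i, v in observed.items():
                    assert np.array_equal(seq.vectors[i], v)
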