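"""Synthetic EHR generator: determinism, informativeness, emission structure."""

import numpy as np
import pytest

from ehrharmonize.cohort import build_cohort
from ehrharmonize.records import LABS_VITALS_DIM
from ehrharmonize.simulate import (
    SimConfig,
    generate_cohort,
    oracle_impute,
    render_note_text,
)
from conftest import make_grid


def _visit_counts(sim):
    return np.array([len(t.visits) for t in sim.timelines])


def _death_indicator(sim):
    return np.array([t.death_time is not None for t in sim.trajectories], float)


class TestGenerateCohort:
    def test_seeded_determinism_bit_exact(self):
        a = generate_cohort(SimConfig(n_patients=3, seed=7))
        b = generate_cohort(SimConfig(n_patients=3, seed=7))
        for ta, tb in zip(a.timelines, b.timelines):
            assert ta.patient_id == tb.patient_id
            assert ta.death_time == tb.death_time
            for va, vb in zip(ta.visits, tb.visits):
                assert va.time == vb.time
                assert va.note_text == vb.note_text
                assert np.array_equal(va.note_embedding, vb.note_embedding)
                for k in va.modalities:
                    assert np.array_equal(va.modalities[k], vb.modalities[k])

    def test_modality_blocks_shape_and_sign(self):
        sim = generate_cohort(SimConfig(n_patients=5, seed=3))
        v = sim.timelines[0].visits[0]
        assert set(v.modalities) == {"diagnosis", "prescription", "procedure",
                                     "labs_vitals"}
        assert len(v.modalities["labs_vitals"]) == LABS_VITALS_DIM
        for name in ("diagnosis", "prescription", "procedure"):
            assert np.all(v.modalities[name] >= 0)  # counts-like

    def test_mcar_visit_process_uncorrelated_with_death(self):
        sim = generate_cohort(SimConfig(
            n_patients=2000, seed=2, visit_rate_health_coef=0.0))
        r = np.corrcoef(_visit_counts(sim), _death_indicator(sim))[0, 1]
        assert abs(r) < 0.1

    def test_informative_missingness_sicker_visit_more(self):
        sim = generate_cohort(SimConfig(
            n_patients=2000, seed=1, visit_rate_health_coef=0.5))
        nv = _visit_counts(sim)
        died = _death_indicator(sim).astype(bool)
        assert nv[died].mean() > nv[~died].mean()

    def test_visit_counts_linear_in_base_rate_under_mcar(self):
        # rates are high enough that the >=1-visit zero-truncation of the
        # Poisson count (every patient must have a visit) is negligible
        means = []
        for rate in (2.0, 4.0):
            sim = generate_cohort(SimConfig(
                n_patients=2000, seed=11, visit_rate_health_coef=0.0,
                visit_rate_base=rate))
            means.append(_visit_counts(sim).mean())
        assert means[1] / means[0] == pytest.approx(2.0, rel=0.1)

    def test_noiseless_emissions_match_latent_state_exactly(self):
        sim = generate_cohort(SimConfig(n_patients=5, seed=9, noise_sd=0.0))
        for tl, traj in zip(sim.timelines, sim.trajectories):
            for v in tl.visits:
                expected = sim.note_matrix @ traj.state_at(v.time)
                assert np.array_equal(v.note_embedding, expected)

    def test_label_prevalence_monotone_in_hazard_coef(self):
        prevalences = []
        for coef in (0.5, 1.0, 1.5):
            sim = generate_cohort(SimConfig(
                n_patients=2000, seed=5, hazard_coef=coef))
            entries = build_cohort(sim.timelines, seed=0, balance=False)
            prevalences.append(np.mean([e.label for e in entries]))
        assert prevalences[0] <= prevalences[1] <= prevalences[2]

    def test_every_patient_has_a_visit_and_invalid_config_rejected(self):
        sim = generate_cohort(SimConfig(n_patients=50, seed=0,
                                        visit_rate_base=0.3))
        assert all(len(t.visits) >= 1 for t in sim.timelines)
        with pytest.raises(ValueError):
            SimConfig(n_patients=0)
        with pytest.raises(ValueError):
            SimConfig(n_patients=1, embed_dim=1)


class TestRenderNoteText:
    def test_deterministic_given_state_and_stream(self):
        state = np.array([0.5, -0.2, 1.0, 0.0])
        a = render_note_text(state, np.random.default_rng(3))
        b = render_note_text(state, np.random.default_rng(3))
        assert a == b

    def test_high_severity_state_uses_severe_template(self):
        state = np.array([3.0, 0.0, 0.0, 0.0])
        assert "severe" in render_note_text(state, np.random.default_rng(0))

    def test_verbosity_exceeds_encoder_window(self):
        state = np.zeros(4)
        text = render_note_text(state, np.random.default_rng(0), verbosity=10)
        assert len(text.split()) > 512


class TestOracleImpute:
    def test_fully_observed_grid_is_identity(self, small_sim):
        traj = small_sim.trajectories[0]
        grid = make_grid([1, 1, 1, 1], pid=traj.patient_id, dim=16)
        seq = oracle_impute(grid, traj, small_sim.note_matrix)
        for i, slot in enumerate(grid.slots):
            assert np.array_equal(seq.vectors[i], slot.note_embedding)
        assert seq.provenance == ["observed"] * 4

    def test_missing_slots_get_noiseless_midpoint_emission(self, small_sim):
        traj = small_sim.trajectories[1]
        grid = make_grid([1, 0, 0, 0], pid=traj.patient_id, dim=16)
        seq = oracle_impute(grid, traj, small_sim.note_matrix)
        for i in (1, 2, 3):
            t_mid = grid.index_time + (i + 0.5) * grid.interval_days
            expected = small_sim.note_matrix @ traj.state_at(t_mid)
            assert np.allclose(seq.vectors[i], expected)
            assert seq.provenance[i] == "generated"

    def test_patient_mismatch_rejected(self, small_sim):
        grid = make_grid([1, 0, 0, 0], pid="someone_else")
        with pytest.raises(ValueError, match="does not match"):
            oracle_impute(grid, small_sim.trajectories[0], small_sim.note_matrix)
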