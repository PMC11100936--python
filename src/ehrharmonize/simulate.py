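"""Synthetic longitudinal EHR generator.

Real discharge-summary corpora with linked mortality are access-restricted,
so this module generates patient timelines that carry the statistical
structure the downstream analysis assumes:

* a latent health state ``h(t)`` per patient following a Gaussian random walk
  on a 30-day tick (linearly interpolated between ticks); coordinate 0 is the
  "sickness" axis,
* visit times from an inhomogeneous Poisson process whose log-intensity is
  ``log(visit_rate_base / 365) + visit_rate_health_coef * h1(t)`` — with a
  positive coefficient, sicker patients visit more often (informative
  missingness, as in ICU/ED populations); at zero the visit process is
  independent of health (MCAR),
* per-visit emissions correlated through the shared state: a note embedding
  ``A h(t) + eps``, code-block modality vectors ``softplus(B_k h(t) + eps_k)``
  plus a linear labs/vitals block, and a templated clinical-style note text
  rendering discretised symptoms and severity from ``h(t)``,
* a death time from a proportional-hazards mechanism with log-hazard
  ``log(baseline_hazard) + hazard_coef * h1(t)``, allowed to fall inside the
  observation window or the 30-day buffer so the cohort builder's exclusion
  rule is exercised.

Everything is bit-reproducible from ``SimConfig`` (including the seed).
An oracle imputer is provided for upper-bound comparisons: it fills missing
grid slots with the *noiseless* emission ``A h(t_mid)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .records import (
    LABS_VITALS_DIM,
    PROV_GENERATED,
    PROV_OBSERVED,
    HarmonizedSequence,
    IntervalGrid,
    PatientTimeline,
    VisitRecord,
)

# dimensions of the dense code-block modality vectors (counts-like)
CODE_BLOCK_DIM = 20

#: days past the observation horizon over which the latent walk and the
#: hazard are extended, so deaths can land after buffer + prediction window
#: and labels are nontrivial
POST_HORIZON_DAYS = 365 + 30 + 365


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic cohort.

    ``embed_dim`` defaults to 16 for desk-scale work; set 768 to mirror a
    clinical-BERT-sized embedding.  ``visit_rate_base`` is in visits/year;
    ``visit_rate_health_coef`` couples sickness to visit intensity (its sign
    controls informative vs anti-informative missingness).
    """

    n_patients: int
    seed: int = 0
    horizon_days: float = 730.0
    embed_dim: int = 16
    latent_dim: int = 4
    n_modalities: int = 4
    visit_rate_base: float = 2.0
    visit_rate_health_coef: float = 0.5
    noise_sd: float = 0.3
    hazard_coef: float = 1.0
    baseline_hazard: float = 2e-4
    latent_step_sd: float = 0.15
    tick_days: float = 30.0
    note_verbosity: int = 1

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.horizon_days <= 0:
            raise ValueError("horizon_days must be > 0")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be >= 1")
        if not 1 <= self.n_modalities <= 4:
            raise ValueError("n_modalities must be in 1..4")
        if self.visit_rate_base <= 0:
            raise ValueError("visit_rate_base must be > 0")

    @property
    def modality_dims(self) -> dict[str, int]:
        names = ("diagnosis", "prescription", "procedure", "labs_vitals")
        dims = (CODE_BLOCK_DIM, CODE_BLOCK_DIM, CODE_BLOCK_DIM, LABS_VITALS_DIM)
        return dict(list(zip(names, dims))[: self.n_modalities])


@dataclass
class LatentTrajectory:
    """Ground-truth latent health path for one synthetic patient."""

    patient_id: str
    tick_times: np.ndarray  # (T,)
    tick_values: np.ndarray  # (T, latent_dim)
    death_time: Optional[float] = None

    def state_at(self, t: float) -> np.ndarray:
        """Piecewise-linear evaluation of h(t); clamped at the ends."""
        t = float(np.clip(t, self.tick_times[0], self.tick_times[-1]))
        out = np.empty(self.tick_values.shape[1])
        for j in range(self.tick_values.shape[1]):
            out[j] = np.interp(t, self.tick_times, self.tick_values[:, j])
        return out


@dataclass
class SimulatedCohort:
    """Timelines plus the latent ground truth and emission matrices."""

    timelines: list[PatientTimeline]
    trajectories: list[LatentTrajectory]
    note_matrix: np.ndarray  # A: (embed_dim, latent_dim)
    modality_matrices: dict[str, np.ndarray] = field(default_factory=dict)


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


# ---------------------------------------------------------------------------
# note text rendering
# ---------------------------------------------------------------------------

_SEVERITY_BANDS = [  # on the sickness coordinate h1
    (-np.inf, "stable"),
    (0.0, "mild"),
    (1.0, "moderate"),
    (2.0, "severe"),
]

_SYMPTOMS = [
    ("dyspnea on exertion", "breathing comfortably"),
    ("intermittent chest pain", "no chest pain reported"),
    ("persistent fatigue", "energy levels adequate"),
    ("lower extremity edema", "no peripheral edema"),
    ("recurrent dizziness", "no dizziness"),
    ("poor appetite", "appetite preserved"),
]

_PLANS = {
    "stable": "continue current regimen and routine follow up in six months",
    "mild": "adjust medication dosing and follow up in three months",
    "moderate": "escalate therapy, order repeat laboratory panel, close follow up",
    "severe": "urgent specialist referral, consider admission, daily monitoring",
}

_FILLER = (
    "the patient was counseled regarding medication adherence diet and "
    "activity and all questions were answered in detail during the visit"
)


def severity_label(sickness: float) -> str:
    label = _SEVERITY_BANDS[0][1]
    for threshold, name in _SEVERITY_BANDS[1:]:
        if sickness >= threshold:
            label = name
    return label


def render_note_text(
    state: np.ndarray, rng: np.random.Generator, verbosity: int = 1
) -> str:
    """Render a clinical-style note from a latent state.

    Deterministic given ``state`` and the generator stream.  ``verbosity``
    appends filler paragraphs (~75 words each) so notes longer than 512 words
    are achievable and truncation paths get exercised.
    """
    state = np.asarray(state, dtype=float)
    sev = severity_label(state[0])
    sentences = [
        f"patient presents for scheduled evaluation with {sev} overall disease burden."
    ]
    for j, (bad, good) in enumerate(_SYMPTOMS):
        coord = state[(j + 1) % len(state)] if len(state) > 1 else state[0]
        jitter = rng.normal(0.0, 0.25)
        sentences.append(
            f"review of systems notable for {bad}." if coord + jitter > 0.3
            else f"review of systems: {good}."
        )
    sentences.append(f"assessment: condition is {sev}.")
    sentences.append(f"plan: {_PLANS[sev]}.")
    for k in range(max(0, verbosity - 1)):
        sentences.append(f"{_FILLER} (continued note section {k + 1}). " * 5)
    return " ".join(sentences)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

def _sample_latent_walk(
    rng: np.random.Generator, config: SimConfig
) -> tuple[np.ndarray, np.ndarray]:
    span = config.horizon_days + POST_HORIZON_DAYS
    n_ticks = int(np.ceil(span / config.tick_days)) + 1
    times = np.arange(n_ticks) * config.tick_days
    steps = rng.normal(0.0, config.latent_step_sd, size=(n_ticks, config.latent_dim))
    steps[0] = rng.normal(0.0, 1.0, size=config.latent_dim)  # initial state
    values = np.cumsum(steps, axis=0)
    return times, values


def _sample_visit_times(
    rng: np.random.Generator, traj: LatentTrajectory, config: SimConfig
) -> np.ndarray:
    """Thinning sampler for the inhomogeneous Poisson visit process.

    Resamples the whole process until at least one visit lands in the window,
    so every synthetic patient has >= 1 visit.
    """
    horizon = config.horizon_days
    in_window = traj.tick_times <= horizon + config.tick_days
    h1 = traj.tick_values[in_window, 0]
    daily_base = config.visit_rate_base / 365.0
    coef = config.visit_rate_health_coef
    lam_max = daily_base * float(np.exp(np.max(coef * h1))) if coef != 0 else daily_base
    lam_max = max(lam_max, 1e-12)
    for _ in range(1000):
        n_cand = rng.poisson(lam_max * horizon)
        if n_cand == 0:
            continue
        cand = np.sort(rng.uniform(0.0, horizon, size=n_cand))
        if coef != 0:
            h1_at = np.interp(cand, traj.tick_times, traj.tick_values[:, 0])
            accept_p = daily_base * np.exp(coef * h1_at) / lam_max
        else:
            accept_p = np.full(n_cand, daily_base / lam_max)
        keep = rng.uniform(size=n_cand) < accept_p
        times = np.unique(np.floor(cand[keep]))  # integer days, deduplicated
        if times.size:
            return times
    raise RuntimeError("visit process failed to produce a visit in 1000 attempts")


def _sample_death_time(
    rng: np.random.Generator, traj: LatentTrajectory, config: SimConfig
) -> Optional[float]:
    """Proportional hazards with piecewise-constant hazard per 30-day tick."""
    haz = config.baseline_hazard * np.exp(
        config.hazard_coef * traj.tick_values[:, 0]
    )
    widths = np.diff(traj.tick_times)
    cum = np.concatenate([[0.0], np.cumsum(haz[:-1] * widths)])
    target = rng.exponential(1.0)
    if target >= cum[-1]:
        return None
    idx = int(np.searchsorted(cum, target, side="right") - 1)
    t = traj.tick_times[idx] + (target - cum[idx]) / haz[idx]
    return float(t)


def generate_cohort(config: SimConfig) -> SimulatedCohort:
    """Generate ``config.n_patients`` synthetic timelines.

    Emission matrices are drawn once per cohort; each patient then gets an
    independent substream, so the output is bit-identical for an identical
    config and invariant to generation order.
    """
    master = np.random.default_rng(config.seed)
    note_matrix = master.normal(
        0.0, 1.0, size=(config.embed_dim, config.latent_dim)
    ) / np.sqrt(config.latent_dim)
    modality_matrices = {
        name: master.normal(0.0, 1.0, size=(dim, config.latent_dim))
        / np.sqrt(config.latent_dim)
        for name, dim in config.modality_dims.items()
    }

    timelines: list[PatientTimeline] = []
    trajectories: list[LatentTrajectory] = []
    for i in range(config.n_patients):
        rng = np.random.default_rng([config.seed, 7919 + i])
        pid = f"p{i:06d}"
        tick_times, tick_values = _sample_latent_walk(rng, config)
        traj = LatentTrajectory(pid, tick_times, tick_values)
        visit_times = _sample_visit_times(rng, traj, config)
        traj.death_time = _sample_death_time(rng, traj, config)
        visits = []
        for t in visit_times:
            h = traj.state_at(float(t))
            emb = note_matrix @ h + rng.normal(0.0, config.noise_sd, config.embed_dim)
            modalities = {}
            for name, B in modality_matrices.items():
                raw = B @ h + rng.normal(0.0, config.noise_sd, B.shape[0])
                modalities[name] = raw if name == "labs_vitals" else _softplus(raw)
            text = render_note_text(h, rng, config.note_verbosity)
            visits.append(
                VisitRecord(
                    time=float(t),
                    note_text=text,
                    note_embedding=emb,
                    modalities=modalities,
                )
            )
        tl = PatientTimeline(pid, visits, traj.death_time)
        tl.validate()
        timelines.append(tl)
        trajectories.append(traj)
    return SimulatedCohort(timelines, trajectories, note_matrix, modality_matrices)


# ---------------------------------------------------------------------------
# oracle imputer
# ---------------------------------------------------------------------------

def oracle_impute(
    grid: IntervalGrid, trajectory: LatentTrajectory, note_matrix: np.ndarray
) -> HarmonizedSequence:
    """Best-case imputer: fill missing slots with the noiseless emission.

    A missing slot i gets ``A h(t_mid)`` where ``t_mid`` is the slot's
    midpoint.  Observed slots keep their embeddings untouched.  This is an
    upper bound no data-driven imputer can see (it reads the simulation's
    ground truth), used only for comparison.
    """
    if grid.patient_id != trajectory.patient_id:
        raise ValueError(
            f"grid patient {grid.patient_id!r} does not match trajectory "
            f"patient {trajectory.patient_id!r}"
        )
    d = note_matrix.shape[0]
    vectors = np.zeros((grid.n_intervals, d))
    provenance = []
    for i, slot in enumerate(grid.slots):
        if slot is not None:
            if slot.note_embedding is None:
                raise ValueError("observed slot lacks an embedding")
            vectors[i] = slot.note_embedding
            provenance.append(PROV_OBSERVED)
        else:
            t_mid = grid.index_time + (i + 0.5) * grid.interval_days
            vectors[i] = note_matrix @ trajectory.state_at(t_mid)
            provenance.append(PROV_GENERATED)
    return HarmonizedSequence(
        grid.patient_id, vectors, provenance, grid.missing_fraction
    )
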