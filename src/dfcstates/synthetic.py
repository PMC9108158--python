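"""Ground-truthed synthetic cohorts of state-switching ROI time series.

Each subject's brain is modelled as switching among a small number of latent
connectivity states.  A first-order Markov chain with a high self-transition
probability generates the state sequence over volumes; given the state, each
volume's ROI signal vector is an independent draw from a zero-mean Gaussian
whose correlation matrix has a network-block structure (stronger correlation
within the DMN/CCN/SMN/OCN blocks than between them).  States differ only in
their correlation level — the "low", "middle" and "high" connectivity states
— and diagnostic groups differ by a multiplicative scaling of all
off-diagonal correlations (controls strongest, the memory-complaint group
weakest).  A composite cognitive score is generated as a linear function of
the subject's true mean connectivity plus demographic terms and Gaussian
noise, so that covariate-adjusted correlation between connectivity and
cognition is positive by construction.

Every generated quantity is returned alongside its ground truth (latent
state per volume, true state covariances, score coefficients) so that the
analysis pipeline can be validated against what was actually simulated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dfc import RoiTimeSeries, fisher_z, vectorize_upper
from .metrics import Parcellation, default_parcellation

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "CohortMember",
    "make_state_covariance",
    "simulate_state_sequence",
    "simulate_subject",
    "simulate_scores_and_covariates",
    "simulate_cohort_truth",
    "simulate_cohort",
    "state_mean_strengths",
]

# Group-level demographic distributions (mean, sd) and female fraction for
# the three diagnostic groups of an elderly memory-clinic cohort: normal
# controls (NC), subjective cognitive decline (SCD), Alzheimer's disease
# (AD).  Units: age and education in years, framewise displacement in mm.
DEMOGRAPHICS = {
    "NC": {"age": (62.57, 8.67), "education": (10.85, 5.06), "fd": (0.25, 0.12),
           "female_frac": 34 / 60},
    "SCD": {"age": (64.90, 8.31), "education": (11.65, 4.53), "fd": (0.22, 0.13),
            "female_frac": 24 / 40},
    "AD": {"age": (70.86, 9.87), "education": (8.84, 5.65), "fd": (0.27, 0.12),
           "female_frac": 33 / 50},
}


# Per-subject connectivity scale factors are clipped to this interval so
# that every scaled correlation stays strictly inside (-1, 1).
SUBJECT_SCALE_CLIP = (0.5, 1.4)


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults define the reference cohort.

    ``state_rho_within`` sets each latent state's within-network correlation
    (the between-network level defaults to half of it), giving low, middle
    and high connectivity states.  ``group_scale`` multiplies all
    off-diagonal correlations per diagnostic group, ordered SCD < AD < NC so
    the control group has the strongest connectivity in every state.
    ``subject_scale_sd`` adds stable inter-subject variability: each subject
    carries a multiplicative connectivity factor 1 + N(0, sd) (clipped to
    ``SUBJECT_SCALE_CLIP``) applied on top of the group scale, emulating the
    large trait-like differences in overall connectivity strength seen in
    real cohorts — the variation that makes a connectivity-cognition
    correlation estimable.
    """

    n_rois: int = 160
    n_volumes: int = 229
    tr_seconds: float = 2.0
    n_states: int = 3
    state_rho_within: tuple[float, ...] = (0.15, 0.40, 0.70)
    state_rho_between: tuple[float, ...] | None = None
    self_transition_prob: float = 0.95
    group_scale: tuple[tuple[str, float], ...] = (("NC", 1.0), ("SCD", 0.80), ("AD", 0.90))
    n_per_group: tuple[tuple[str, int], ...] = (("NC", 60), ("SCD", 40), ("AD", 50))
    subject_scale_sd: float = 0.15
    ar_coeff: float = 0.0
    score_intercept: float = 15.0
    score_slope: float = 20.0
    score_age_coeff: float = -0.08
    score_edu_coeff: float = 0.10
    score_noise_sd: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_states < 2:
            raise ValueError("need at least 2 states")
        if not 0.0 <= self.self_transition_prob <= 1.0:
            raise ValueError("self_transition_prob must be in [0, 1]")
        if len(self.state_rho_within) != self.n_states:
            raise ValueError("state_rho_within must have one entry per state")
        if self.state_rho_between is not None and len(self.state_rho_between) != self.n_states:
            raise ValueError("state_rho_between must have one entry per state")
        if not -1.0 <= self.ar_coeff <= 1.0:
            raise ValueError("ar_coeff must be in [-1, 1]")
        for rho in list(self.state_rho_within) + list(self.rho_between):
            if not abs(rho) < 1:
                raise ValueError("correlation targets must lie in (-1, 1)")
        if self.subject_scale_sd < 0:
            raise ValueError("subject_scale_sd must be non-negative")
        for _, scale in self.group_scale:
            for rho in list(self.state_rho_within) + list(self.rho_between):
                if not abs(rho * scale * SUBJECT_SCALE_CLIP[1]) < 1:
                    raise ValueError("scaled correlations must stay in (-1, 1)")

    @property
    def rho_between(self) -> tuple[float, ...]:
        if self.state_rho_between is not None:
            return self.state_rho_between
        return tuple(r / 2.0 for r in self.state_rho_within)

    @property
    def groups(self) -> dict[str, float]:
        return dict(self.group_scale)

    @property
    def group_sizes(self) -> dict[str, int]:
        return dict(self.n_per_group)


@dataclass
class CohortMember:
    """One subject's identity and latent truth needed for score generation."""

    subject_id: str
    group: str
    state_sequence: np.ndarray
    subject_scale: float
    true_mean_connectivity: float


def _draw_subject_scale(config: SyntheticConfig, rng: np.random.Generator) -> float:
    lo, hi = SUBJECT_SCALE_CLIP
    return float(np.clip(1.0 + config.subject_scale_sd * rng.standard_normal(), lo, hi))


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    state_sequences: dict[str, np.ndarray]
    state_covariances: dict[str, np.ndarray]  # group -> (k, R, R)
    state_mean_z: dict[str, np.ndarray]  # group -> per-state true mean Fisher z
    score_coefficients: dict[str, float]


def make_state_covariance(
    n_rois: int,
    network_labels,
    rho_within: float,
    rho_between: float,
) -> np.ndarray:
    """Network-block correlation matrix for one latent state.

    Entry (i, j) is ``rho_within`` when ROIs i and j share a network and
    ``rho_between`` otherwise; the diagonal is 1.  If the block pattern is
    not positive definite it is repaired by diagonal loading and
    re-normalised to unit diagonal; an irreparable matrix raises.
    """
    if not (abs(rho_within) < 1 and abs(rho_between) < 1):
        raise ValueError("correlations must lie in (-1, 1)")
    labels = np.asarray(network_labels)
    if labels.shape != (n_rois,):
        raise ValueError("network_labels must have length n_rois")
    same = labels[:, None] == labels[None, :]
    cov = np.where(same, rho_within, rho_between)
    np.fill_diagonal(cov, 1.0)
    min_eig = float(np.linalg.eigvalsh(cov)[0])
    if min_eig <= 0:
        cov = cov + (abs(min_eig) + 1e-6) * np.eye(n_rois)
        d = np.sqrt(np.diag(cov))
        cov = cov / np.outer(d, d)
        if float(np.linalg.eigvalsh(cov)[0]) <= 0:
            raise ValueError("state covariance not positive definite after repair")
    return cov


def simulate_state_sequence(
    n_volumes: int,
    n_states: int,
    self_transition_prob: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """First-order Markov state sequence with uniform start.

    The chain stays in its current state with probability
    ``self_transition_prob`` and otherwise jumps to one of the other states
    with equal probability.
    """
    if n_volumes < 1:
        raise ValueError("n_volumes must be >= 1")
    if not 0.0 <= self_transition_prob <= 1.0:
        raise ValueError("self_transition_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    seq = np.empty(n_volumes, dtype=int)
    seq[0] = rng.integers(n_states)
    if n_states == 1:
        return np.zeros(n_volumes, dtype=int)
    stay = rng.random(n_volumes - 1) < self_transition_prob
    jumps = rng.integers(n_states - 1, size=n_volumes - 1)
    for t in range(1, n_volumes):
        if stay[t - 1]:
            seq[t] = seq[t - 1]
        else:
            j = jumps[t - 1]
            seq[t] = j if j < seq[t - 1] else j + 1
    return seq


def _scaled_covariance(base: np.ndarray, scale: float) -> np.ndarray:
    """Scale all off-diagonal correlations by ``scale`` (diagonal stays 1)."""
    n = base.shape[0]
    return np.eye(n) + scale * (base - np.eye(n))


def _state_covariances(config: SyntheticConfig, parcellation: Parcellation) -> np.ndarray:
    labels = np.asarray(parcellation.networks)
    return np.stack(
        [
            make_state_covariance(config.n_rois, labels, rw, rb)
            for rw, rb in zip(config.state_rho_within, config.rho_between)
        ]
    )


def state_mean_strengths(
    config: SyntheticConfig, group: str, subject_scale: float = 1.0
) -> np.ndarray:
    """True per-state mean Fisher-z connectivity for one group.

    The mean over distinct ROI pairs of atanh applied to the scaled state
    correlation matrix — the value the analysis pipeline's per-state global
    mean estimates.  ``subject_scale`` folds in a subject's individual
    connectivity factor (1.0 gives the group-typical value).
    """
    parcellation = default_parcellation(config.n_rois)
    covs = _state_covariances(config, parcellation)
    scale = config.groups[group] * subject_scale
    return np.array(
        [float(fisher_z(vectorize_upper(_scaled_covariance(c, scale))).mean()) for c in covs]
    )


def simulate_subject(
    config: SyntheticConfig,
    group: str,
    seed: int | np.random.Generator | None = None,
    state_sequence: np.ndarray | None = None,
    subject_scale: float | None = None,
    subject_id: str = "synthetic",
    parcellation: Parcellation | None = None,
) -> tuple[RoiTimeSeries, np.ndarray]:
    """Simulate one subject's ROI time series plus its latent state sequence.

    At each volume the signal is a draw from a zero-mean Gaussian whose
    correlation matrix is the group- and subject-scaled covariance of the
    current latent state.  With ``ar_coeff`` a > 0, successive volumes share
    an AR(1) factor: x_t = a x_{t-1} + sqrt(1-a^2) e_t with e_t
    state-distributed.  When ``subject_scale`` or ``state_sequence`` is not
    given it is drawn from the subject's stream (factor first, then chain),
    matching the draw order used by :func:`simulate_cohort_truth`.
    """
    if group not in config.groups:
        raise ValueError(f"unknown group {group!r}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if parcellation is None:
        parcellation = default_parcellation(config.n_rois)
    if subject_scale is None:
        subject_scale = _draw_subject_scale(config, rng)
    covs = _state_covariances(config, parcellation)
    scale = config.groups[group] * subject_scale
    chols = [np.linalg.cholesky(_scaled_covariance(c, scale)) for c in covs]
    if state_sequence is None:
        state_sequence = simulate_state_sequence(
            config.n_volumes, config.n_states, config.self_transition_prob, rng
        )
    innov = rng.standard_normal((config.n_volumes, config.n_rois))
    data = np.empty((config.n_volumes, config.n_rois))
    for t, s in enumerate(state_sequence):
        shock = innov[t] @ chols[s].T
        if config.ar_coeff != 0.0 and t > 0:
            data[t] = config.ar_coeff * data[t - 1] + np.sqrt(
                1.0 - config.ar_coeff**2
            ) * shock
        else:
            data[t] = shock
    ts = RoiTimeSeries(
        subject_id=subject_id,
        data=data,
        tr_seconds=config.tr_seconds,
        roi_ids=parcellation.roi_ids,
    )
    return ts, np.asarray(state_sequence)


def _true_mean_connectivity(
    state_sequence: np.ndarray, state_mean_z: np.ndarray
) -> float:
    """Occupancy-weighted mean of the true per-state mean Fisher-z values."""
    occ = np.bincount(state_sequence, minlength=state_mean_z.size)
    return float((occ / occ.sum()) @ state_mean_z)


def simulate_cohort_truth(config: SyntheticConfig) -> tuple[list[CohortMember], GroundTruth]:
    """Generate the cohort's latent structure without emitting signals.

    Draws every subject's state sequence and computes its true mean
    connectivity; cheap enough for repeated-simulation studies.  Subject
    seeds are spawned deterministically from ``config.seed``, so the full
    cohort (:func:`simulate_cohort`) shares the same latent truth.
    """
    parcellation = default_parcellation(config.n_rois)
    covs = _state_covariances(config, parcellation)
    mean_z = {g: state_mean_strengths(config, g) for g in config.groups}
    members: list[CohortMember] = []
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(sum(config.group_sizes.values()))
    i = 0
    for group, n in config.group_sizes.items():
        for j in range(n):
            rng = np.random.default_rng(subject_seeds[i])
            factor = _draw_subject_scale(config, rng)
            seq = simulate_state_sequence(
                config.n_volumes, config.n_states, config.self_transition_prob, rng
            )
            s = config.groups[group] * factor
            subj_mean_z = np.array(
                [
                    float(fisher_z(vectorize_upper(_scaled_covariance(c, s))).mean())
                    for c in covs
                ]
            )
            members.append(
                CohortMember(
                    subject_id=f"sub-{group}{j:03d}",
                    group=group,
                    state_sequence=seq,
                    subject_scale=factor,
                    true_mean_connectivity=_true_mean_connectivity(seq, subj_mean_z),
                )
            )
            i += 1
    truth = GroundTruth(
        state_sequences={m.subject_id: m.state_sequence for m in members},
        state_covariances={
            g: np.stack([_scaled_covariance(c, s) for c in covs])
            for g, s in config.groups.items()
        },
        state_mean_z=mean_z,
        score_coefficients={
            "intercept": config.score_intercept,
            "slope": config.score_slope,
            "age": config.score_age_coeff,
            "education": config.score_edu_coeff,
            "noise_sd": config.score_noise_sd,
        },
    )
    return members, truth


def simulate_scores_and_covariates(
    cohort: list[CohortMember],
    config: SyntheticConfig,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Demographics, motion and a composite cognitive score per subject.

    Sex, age, education and mean framewise displacement are drawn from
    group-specific distributions; the composite score is
    ``intercept + slope * true_mean_connectivity + age and education terms +
    Gaussian noise``, so connectivity and cognition are positively related
    after covariate adjustment.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    rows = []
    for m in cohort:
        demo = DEMOGRAPHICS.get(m.group, DEMOGRAPHICS["NC"])
        sex = "F" if rng.random() < demo["female_frac"] else "M"
        age = rng.normal(*demo["age"])
        edu = max(0.0, rng.normal(*demo["education"]))
        fd = max(0.01, rng.normal(*demo["fd"]))
        score = (
            config.score_intercept
            + config.score_slope * m.true_mean_connectivity
            + config.score_age_coeff * (age - 65.0)
            + config.score_edu_coeff * edu
            + rng.normal(0.0, config.score_noise_sd)
        )
        rows.append(
            {
                "subject_id": m.subject_id,
                "group": m.group,
                "sex": sex,
                "age": age,
                "education_years": edu,
                "fd_mean": fd,
                "composite_score": score,
                "true_mean_connectivity": m.true_mean_connectivity,
            }
        )
    return pd.DataFrame(rows)


def simulate_cohort(
    config: SyntheticConfig,
) -> tuple[list[RoiTimeSeries], pd.DataFrame, GroundTruth]:
    """Full cohort: time series per subject, manifest table, ground truth.

    Deterministic in ``config.seed``: subject signal streams and the
    manifest stream are spawned from it.
    """
    members, truth = simulate_cohort_truth(config)
    parcellation = default_parcellation(config.n_rois)
    root = np.random.SeedSequence(config.seed)
    subject_seeds = root.spawn(len(members))
    subjects: list[RoiTimeSeries] = []
    for m, ss in zip(members, subject_seeds):
        rng = np.random.default_rng(ss)
        # replay the factor and chain draws so the emission stream continues
        # the same per-subject stream used by simulate_cohort_truth
        factor = _draw_subject_scale(config, rng)
        seq = simulate_state_sequence(
            config.n_volumes, config.n_states, config.self_transition_prob, rng
        )
        assert factor == m.subject_scale and np.array_equal(seq, m.state_sequence)
        ts, _ = simulate_subject(
            config,
            m.group,
            seed=rng,
            state_sequence=m.state_sequence,
            subject_scale=m.subject_scale,
            subject_id=m.subject_id,
            parcellation=parcellation,
        )
        subjects.append(ts)
    manifest_rng = np.random.default_rng(root.spawn(1)[0])
    manifest = simulate_scores_and_covariates(members, config, manifest_rng)
    return subjects, manifest, truth
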