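"""Synthetic SvH cohorts, simulated team submissions, and reader pairs.

No public score sheets exist for the kind of cohort this harness evaluates,
so every pipeline stage is exercised on synthetic data with the qualitative
statistics of real rheumatoid-arthritis cohorts:

* a fraction of patients with no radiographic damage at all (all-zero
  sheets — such patients exist in any RA cohort and anchor the lowest
  weight bin);
* right-skewed overall totals: medians around 10-15 points with an IQR of
  roughly 5-40 and a long tail reaching a few hundred, far below the
  448-point ceiling;
* per-joint zero inflation even in damaged patients.

The generative model draws a log-normal latent severity per patient and
turns it into per-location integer scores via a binomial thinning of each
location's cap, with gamma-distributed per-location susceptibility
providing overdispersion.  Team submissions perturb the truth on the log
scale — the scale the evaluation metric measures — so a team's configured
error SD is directly the weighted-RMSE magnitude it should score at.  A
shared cohort-level error field lets teams be error-correlated, emulating
model families that fail on the same patients.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .svh_model import (
    JointAreaRegistry,
    ScoreSheet,
    SchemeError,
    SubmissionSet,
    cohort_joint_frame,
    cohort_totals_frame,
    default_registry,
)

__all__ = [
    "CohortConfig",
    "TeamNoiseConfig",
    "generate_cohort",
    "generate_submission",
    "generate_reader_pair",
]


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic ground-truth cohort.

    ``zero_inflation`` is the probability that a patient has no damage at
    all.  The latent severity is log-normal in the scipy parameterisation:
    ``severity = severity_scale * exp(severity_sigma * z)`` with standard
    normal ``z``, so ``severity_scale`` is the median severity and the
    ``severity_scale -> 0`` limit degenerates to an all-zero cohort.
    ``severity_halfmax`` is the severity at which a location is expected to
    reach half its cap, controlling how severity maps to scores.
    ``joint_dispersion`` spreads damage unevenly across locations (gamma
    susceptibility with variance equal to the dispersion).
    """

    n_patients: int = 188
    seed: int = 0
    zero_inflation: float = 0.10
    severity_scale: float = 1.0
    severity_sigma: float = 1.4
    severity_halfmax: float = 44.0
    joint_dispersion: float = 0.5

    def validate(self) -> None:
        if self.n_patients < 1:
            raise SchemeError("n_patients must be >= 1")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise SchemeError("zero_inflation must be in [0, 1]")
        if self.severity_scale < 0 or self.severity_sigma < 0 or self.joint_dispersion < 0:
            raise SchemeError("severity_scale, severity_sigma and joint_dispersion must be >= 0")
        if self.severity_halfmax <= 0:
            raise SchemeError("severity_halfmax must be > 0")


@dataclass(frozen=True)
class TeamNoiseConfig:
    """Error structure of one simulated team's predictions.

    ``error_sd`` is the SD of the log-scale error applied to every term,
    i.e. approximately the weighted RMSE the team scores against its own
    truth.  ``bias`` shifts the log-scale prediction additively.
    ``correlation_weight`` in [0, 1] mixes an independent error with a
    cohort-level shared field (two teams with weights ``c1, c2`` and the
    same ``shared_seed`` have error correlation ``c1*c2``); ``rounding``
    mimics teams that submit integer scores.
    """

    team_id: str
    error_sd: float = 0.3
    bias: float = 0.0
    correlation_weight: float = 0.0
    rounding: bool = False
    seed: int = 0
    shared_seed: int = 1

    def validate(self) -> None:
        if self.error_sd < 0:
            raise SchemeError("error_sd must be >= 0")
        if not 0.0 <= self.correlation_weight <= 1.0:
            raise SchemeError("correlation_weight must be in [0, 1]")


def generate_cohort(
    config: CohortConfig,
    registry: Optional[JointAreaRegistry] = None,
) -> List[ScoreSheet]:
    """Draw a synthetic ground-truth cohort; deterministic under the seed.

    With probability ``zero_inflation`` a patient is damage-free.
    Otherwise their latent severity ``S ~ LogNormal`` sets, per location, a
    damage probability ``p = S*g / (S*g + halfmax)`` (``g`` the location's
    gamma susceptibility) and the integer score is ``Binomial(cap, p)`` —
    zero-inflated per joint, right-skewed in the totals, and always within
    each location's cap, so every sheet passes validation by construction.
    """
    config.validate()
    registry = registry or default_registry()
    rng = np.random.default_rng(config.seed)
    caps = np.array([a.max_score for a in registry])
    n_loc = len(registry)
    sheets: List[ScoreSheet] = []
    for i in range(config.n_patients):
        pid = f"P{i+1:04d}"
        if rng.random() < config.zero_inflation:
            scores = np.zeros(n_loc, dtype=int)
        else:
            severity = config.severity_scale * math.exp(
                config.severity_sigma * rng.standard_normal())
            # dispersions below ~1e-12 are numerically homogeneous (the gamma
            # shape parameter would overflow)
            if config.joint_dispersion > 1e-12:
                shape = 1.0 / config.joint_dispersion
                g = rng.gamma(shape, scale=config.joint_dispersion, size=n_loc)
            else:
                g = np.ones(n_loc)
            sg = severity * g
            p = np.where(np.isfinite(sg), sg / (sg + config.severity_halfmax), 1.0)
            scores = rng.binomial(caps, p)
        sheets.append(ScoreSheet(pid, {a: int(v) for a, v in zip(registry, scores)}))
    return sheets


def _log_error_field(
    shape: Tuple[int, ...],
    noise: TeamNoiseConfig,
    rng: np.random.Generator,
    shared_rng: np.random.Generator,
) -> np.ndarray:
    """Log-scale error: sigma * (c*shared + sqrt(1-c^2)*independent) + bias."""
    c = noise.correlation_weight
    shared = shared_rng.standard_normal(shape)
    indep = rng.standard_normal(shape)
    z = c * shared + math.sqrt(max(0.0, 1.0 - c * c)) * indep
    return noise.error_sd * z + noise.bias


def generate_submission(
    truth: Sequence[ScoreSheet],
    noise: TeamNoiseConfig,
    registry: Optional[JointAreaRegistry] = None,
) -> SubmissionSet:
    """Simulate one team's predictions against a ground-truth cohort.

    Every term (each joint score and each patient overall total) is
    perturbed on the log scale: ``y = expm1(log1p(s) + eps)``, clipped to
    the location's legal range.  Overall totals receive their own error
    draw rather than being summed from the noisy joints, mimicking teams
    that estimate overall damage separately; this keeps the configured SD
    interpretable on all three subchallenges.  With zero SD and bias the
    submission is an exact copy of the truth.
    """
    noise.validate()
    registry = registry or default_registry()
    joints = cohort_joint_frame(truth, registry)
    totals = cohort_totals_frame(truth)["Overall_Tol"]
    rng = np.random.default_rng(noise.seed)
    shared_rng = np.random.default_rng(noise.shared_seed)
    caps = np.array([registry.area_for_column(c).max_score for c in joints.columns], dtype=float)

    eps_joints = _log_error_field(joints.shape, noise, rng, shared_rng)
    eps_totals = _log_error_field((len(totals),), noise, rng, shared_rng)

    pred_joints = np.expm1(np.log1p(joints.to_numpy(dtype=float)) + eps_joints)
    pred_joints = np.clip(pred_joints, 0.0, caps[None, :])
    pred_totals = np.expm1(np.log1p(totals.to_numpy(dtype=float)) + eps_totals)
    pred_totals = np.clip(pred_totals, 0.0, float(registry.max_total()))
    if noise.rounding:
        pred_joints = np.round(pred_joints)
        pred_totals = np.round(pred_totals)

    return SubmissionSet(
        team_id=noise.team_id,
        joint_scores=pd.DataFrame(pred_joints, index=joints.index, columns=joints.columns),
        overall=pd.Series(pred_totals, index=joints.index),
    )


def generate_reader_pair(
    truth: Sequence[ScoreSheet],
    reader_sds: Tuple[float, float] = (0.3, 0.3),
    seed: int = 0,
    registry: Optional[JointAreaRegistry] = None,
) -> Tuple[List[ScoreSheet], List[ScoreSheet]]:
    """Two independent expert readers' integer re-scores of the same cohort.

    Each reader perturbs every joint score on the log scale with their own
    SD, then rounds and clips to the location's cap — valid integer score
    sheets that can feed the inter-reader CV summary and mean-of-readers
    evaluation.  Both SDs zero reproduces the truth exactly.
    """
    if len(reader_sds) != 2 or any(sd < 0 for sd in reader_sds):
        raise SchemeError("reader_sds must be two non-negative SDs")
    registry = registry or default_registry()
    joints = cohort_joint_frame(truth, registry)
    caps = np.array([registry.area_for_column(c).max_score for c in joints.columns], dtype=float)
    rng = np.random.default_rng(seed)
    out: List[List[ScoreSheet]] = []
    s = joints.to_numpy(dtype=float)
    for sd in reader_sds:
        eps = sd * rng.standard_normal(s.shape)
        scores = np.clip(np.round(np.expm1(np.log1p(s) + eps)), 0.0, caps[None, :]).astype(int)
        sheets = [
            ScoreSheet(pid, {a: int(v) for a, v in zip(registry, row)})
            for pid, row in zip(joints.index, scores)
        ]
        out.append(sheets)
    return out[0], out[1]
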