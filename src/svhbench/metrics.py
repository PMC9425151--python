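"""Evaluation metrics for SvH score predictions.

The headline metric is a patient-weighted RMSE on log-transformed scores:
each compared term contributes a residual ``d = ln(1+y) - ln(1+s)`` (adding 1
avoids log 0 for undamaged joints), and the metric is

    sqrt( sum_i w_i d_i^2 / sum_i w_i )

with the patient weight ``w_i = 2**threshold(bin)`` taken from an 8-bin
partition of the patient's ground-truth overall total.  The bins are
0, 1, 2-3, 4-7, 8-20, 21-55, 56-148 and >148; each bin's threshold is the
natural log of its upper limit, except that the first two bins use 0 and 1
and the open-ended bin uses 6.  Weighting damps the influence of the many
near-zero patients and of the rare very high totals, so that all severity
ranges contribute comparably to the leaderboard.

Three subchallenges reuse the same formula with different comparison units:

* ``sc1`` — one term per patient, on overall totals (overall damage);
* ``sc2`` — one term per JSN joint area (42 per patient);
* ``sc3`` — one term per erosion location (44 per patient).

Weights always come from the ground-truth totals, so they are identical
across teams — a requirement for fair ranking.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from lifelines.utils import concordance_index as _lifelines_concordance
from scipy import stats

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
    "WeightBin",
    "WEIGHT_BINS",
    "SUBCHALLENGES",
    "MetricResult",
    "ReaderCV",
    "assign_bin",
    "bin_threshold",
    "patient_weight",
    "patient_weights",
    "weighted_rmse",
    "patient_rmse_components",
    "spearman_metric",
    "concordance_index",
    "flag_outliers",
    "outlier_rate",
    "reader_cv",
]

SUBCHALLENGES = ("sc1", "sc2", "sc3")

#: damage type whose per-location scores form the comparison units; ``None``
#: means patient-level overall totals.
_SC_UNITS = {"sc1": None, "sc2": "jsn", "sc3": "erosion"}


@dataclass(frozen=True)
class WeightBin:
    """One bin of the patient-weight scheme.

    ``upper is None`` marks the open-ended top bin.  ``threshold`` is
    ``ln(upper)`` except for the stated exceptions (bins 0 and 1, and 6 for
    the open-ended bin); the patient weight is ``2**threshold``.
    """

    index: int
    lower: int
    upper: Optional[int]
    threshold: float

    @property
    def weight(self) -> float:
        return 2.0 ** self.threshold

    def contains(self, total: float) -> bool:
        if total < self.lower:
            return False
        return self.upper is None or total < self.upper + 1


def _build_bins() -> Tuple[WeightBin, ...]:
    bounds = [(0, 0), (1, 1), (2, 3), (4, 7), (8, 20), (21, 55), (56, 148), (149, None)]
    bins = []
    for i, (lo, hi) in enumerate(bounds):
        if i == 0:
            thr = 0.0
        elif i == 1:
            thr = 1.0
        elif hi is None:
            thr = 6.0
        else:
            thr = math.log(hi)
        bins.append(WeightBin(i, lo, hi, thr))
    return tuple(bins)


WEIGHT_BINS: Tuple[WeightBin, ...] = _build_bins()

# upper edges for vectorised searchsorted lookup (open bin -> +inf)
_BIN_UPPERS = np.array([b.upper if b.upper is not None else np.inf for b in WEIGHT_BINS])
_BIN_WEIGHTS = np.array([b.weight for b in WEIGHT_BINS])


def bin_threshold(bin_index: int) -> float:
    """Threshold of the ``bin_index``-th weight bin (0-7)."""
    if not 0 <= bin_index < len(WEIGHT_BINS):
        raise SchemeError(f"bin index {bin_index} out of range 0-7")
    return WEIGHT_BINS[bin_index].threshold


def assign_bin(overall_total: float) -> WeightBin:
    """Map a non-negative overall total to its weight bin.

    Real-valued totals are bucketed by the integer range containing their
    floor, making the partition total on the non-negative reals.
    """
    if not np.isfinite(overall_total) or overall_total < 0:
        raise SchemeError(f"overall total must be finite and >= 0, got {overall_total!r}")
    idx = int(np.searchsorted(_BIN_UPPERS, math.floor(overall_total), side="left"))
    return WEIGHT_BINS[idx]


def patient_weight(truth: Union[ScoreSheet, float]) -> float:
    """Weight ``2**threshold`` for a patient's ground-truth overall total."""
    total = truth.overall_total if isinstance(truth, ScoreSheet) else truth
    return assign_bin(total).weight


def patient_weights(totals: np.ndarray) -> np.ndarray:
    """Vectorised :func:`patient_weight` over an array of totals."""
    totals = np.asarray(totals, dtype=float)
    if np.any(~np.isfinite(totals)) or np.any(totals < 0):
        raise SchemeError("overall totals must be finite and >= 0")
    idx = np.searchsorted(_BIN_UPPERS, np.floor(totals), side="left")
    return _BIN_WEIGHTS[idx]


@dataclass(frozen=True)
class MetricResult:
    """A scalar metric value with its provenance."""

    subchallenge: str
    team_id: str
    value: float
    n_patients: int
    n_terms: int

    def __float__(self) -> float:
        return float(self.value)


def _aligned_arrays(
    truth: Sequence[ScoreSheet],
    submission: SubmissionSet,
    subchallenge: str,
    registry: JointAreaRegistry,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray, List[str]]:
    """Return (S, Y, w_patient, patient_ids): truth and prediction matrices
    of shape (n_patients, n_units) plus per-patient weights."""
    if subchallenge not in SUBCHALLENGES:
        raise SchemeError(f"unknown subchallenge {subchallenge!r}")
    ids = [s.patient_id for s in truth]
    if not ids:
        raise SchemeError("empty truth cohort")
    submission.check_alignment(ids, registry)
    totals = np.array([s.overall_total for s in truth], dtype=float)
    w = patient_weights(totals)
    unit = _SC_UNITS[subchallenge]
    if unit is None:
        S = totals[:, None]
        Y = submission.overall.reindex(ids).to_numpy()[:, None]
    else:
        cols = registry.column_keys(unit)
        S = cohort_joint_frame(truth, registry)[cols].to_numpy(dtype=float)
        Y = submission.joint_scores.reindex(ids)[cols].to_numpy(dtype=float)
    return S, Y, w, ids


def patient_rmse_components(
    truth: Sequence[ScoreSheet],
    submission: SubmissionSet,
    subchallenge: str,
    registry: Optional[JointAreaRegistry] = None,
) -> Tuple[np.ndarray, np.ndarray]:
    """Per-patient aggregates ``(A_p, W_p)`` of the weighted RMSE.

    ``A_p = w_p * sum_j d_pj^2`` and ``W_p = w_p * n_units``; the full-cohort
    metric is ``sqrt(A.sum() / W.sum())``.  Because a patient's weight
    depends only on their own ground-truth total, the metric on any patient
    resample is ``sqrt(A[idx].sum() / W[idx].sum())`` — the identity the
    bootstrap machinery exploits.
    """
    registry = registry or default_registry()
    S, Y, w, _ = _aligned_arrays(truth, submission, subchallenge, registry)
    D = np.log1p(Y) - np.log1p(S)
    A = w * (D ** 2).sum(axis=1)
    W = w * D.shape[1]
    return A, W


def weighted_rmse(
    truth: Sequence[ScoreSheet],
    submission: SubmissionSet,
    subchallenge: str,
    registry: Optional[JointAreaRegistry] = None,
) -> MetricResult:
    """Patient-weighted RMSE of log(score+1) residuals for one subchallenge."""
    registry = registry or default_registry()
    S, Y, w, ids = _aligned_arrays(truth, submission, subchallenge, registry)
    D = np.log1p(Y) - np.log1p(S)
    num = float((w[:, None] * D ** 2).sum())
    den = float(w.sum() * D.shape[1])
    return MetricResult(
        subchallenge=subchallenge,
        team_id=submission.team_id,
        value=math.sqrt(num / den),
        n_patients=len(ids),
        n_terms=D.size,
    )


def spearman_metric(
    truth: Sequence[ScoreSheet],
    submission: SubmissionSet,
    subchallenge: str,
    registry: Optional[JointAreaRegistry] = None,
) -> float:
    """Spearman rank correlation over the subchallenge's comparison units.

    Returns ``nan`` when either vector is constant (correlation undefined).
    """
    registry = registry or default_registry()
    S, Y, _, _ = _aligned_arrays(truth, submission, subchallenge, registry)
    s, y = S.ravel(), Y.ravel()
    if s.size < 3:
        raise SchemeError("Spearman metric needs at least 3 comparison units")
    if np.all(s == s[0]) or np.all(y == y[0]):
        return float("nan")
    rho, _ = stats.spearmanr(s, y)
    return float(rho)


def concordance_index(
    metric_values_a: Sequence[float],
    metric_values_b: Sequence[float],
) -> float:
    """Agreement between two orderings of the same teams, in [0, 1].

    Fraction of comparable team pairs ordered identically by both metric
    lists: 1 = same ordering, 0.5 = random, 0 = inverse.  Pairs tied in the
    first list are not comparable; pairs tied only in the second count half.
    """
    a = np.asarray(metric_values_a, dtype=float)
    b = np.asarray(metric_values_b, dtype=float)
    if a.shape != b.shape:
        raise SchemeError("metric lists must pair the same teams")
    if a.size < 2:
        raise SchemeError("concordance index needs at least 2 teams")
    return float(_lifelines_concordance(a, b))


def flag_outliers(
    truth: Sequence[ScoreSheet],
    submission: SubmissionSet,
    subchallenge: str,
    cutoff: float = 3.0,
    registry: Optional[JointAreaRegistry] = None,
) -> pd.DataFrame:
    """Flag (patient, unit) pairs whose raw-score discrepancy is large.

    The default rule flags ``|y - s| >= cutoff`` on the raw score scale —
    a deterministic stand-in for the challenge's visual review of
    significantly discordant joints.  Returns a tidy frame with columns
    ``patient_id, unit, truth, predicted, abs_diff``.
    """
    if not np.isfinite(cutoff) or cutoff <= 0:
        raise SchemeError(f"cutoff must be positive, got {cutoff!r}")
    registry = registry or default_registry()
    S, Y, _, ids = _aligned_arrays(truth, submission, subchallenge, registry)
    unit = _SC_UNITS[subchallenge]
    unit_names = ["Overall_Tol"] if unit is None else registry.column_keys(unit)
    diff = np.abs(Y - S)
    rows = []
    for i, j in zip(*np.nonzero(diff >= cutoff)):
        rows.append((ids[i], unit_names[j], S[i, j], Y[i, j], diff[i, j]))
    return pd.DataFrame(rows, columns=["patient_id", "unit", "truth", "predicted", "abs_diff"])


def outlier_rate(n_flagged: int, n_total: int) -> float:
    """Percentage of flagged scores, rounded to one decimal place."""
    if n_total <= 0:
        raise SchemeError("n_total must be positive")
    if not 0 <= n_flagged <= n_total:
        raise SchemeError("n_flagged must be within [0, n_total]")
    return round(100.0 * n_flagged / n_total, 1)


@dataclass(frozen=True)
class ReaderCV:
    """Mean per-patient coefficient of variation between two expert readers."""

    value: float
    n_used: int
    n_zero_excluded: int

    def __float__(self) -> float:
        return float(self.value)


def reader_cv(
    reader1_totals: Sequence[float],
    reader2_totals: Sequence[float],
) -> ReaderCV:
    """Inter-reader variability of paired per-patient totals.

    For each patient the CV of the pair is ``SD(a, b) / mean(a, b)`` (sample
    SD, ddof=1); the result averages these over patients.  Pairs with zero
    mean carry no information and are excluded but counted.
    """
    a = np.asarray(reader1_totals, dtype=float)
    b = np.asarray(reader2_totals, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise SchemeError("reader totals must be equal-length 1-d pairings")
    if a.size == 0:
        raise SchemeError("empty reader pairing")
    mean = (a + b) / 2.0
    sd = np.abs(a - b) / math.sqrt(2.0)  # ddof=1 SD of two values
    keep = mean > 0
    n_excluded = int((~keep).sum())
    if not keep.any():
        return ReaderCV(0.0, 0, n_excluded)
    return ReaderCV(float((sd[keep] / mean[keep]).mean()), int(keep.sum()), n_excluded)
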