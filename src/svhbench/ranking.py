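"""Bootstrap reproducibility analysis and submission ranking.

Point estimates of the weighted RMSE order teams, but say nothing about how
stable that ordering is under sampling of the evaluation cohort.  Following
the challenge-scoring tradition, stability is assessed by resampling the
cohort (radiographic sets, i.e. patient rows, with replacement at full
cohort size), rescoring every submission on each resample, and summarising
pairwise dominance with a Bayes factor

    K = (#iterations the reference scores strictly better)
      / (#iterations the challenger scores strictly better)

against a designated reference submission (normally the top performer).
Iterations where the two metrics tie exactly are excluded from both counts,
which keeps K symmetric under swapping the pair.  K > 3 declares the
challenger worse than the reference, 1/K > 3 declares it better, anything
else is a statistical tie.  A paired t-test on the bootstrap metric vectors
with Benjamini-Hochberg correction across teams serves as a secondary
comparison.

Patient weights are recomputed on each resample: a patient drawn twice
counts twice, with the weight implied by their own ground-truth total.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .metrics import MetricResult, patient_rmse_components
from .svh_model import JointAreaRegistry, ScoreSheet, SchemeError, SubmissionSet, default_registry

__all__ = [
    "BootstrapMatrix",
    "BayesFactorReport",
    "bootstrap_metrics",
    "bayes_factor",
    "rank_submissions",
    "pairwise_t_fdr",
    "BAYES_FACTOR_TIE_CUTOFF",
]

#: Bayes factors up to this value (inclusive) are statistical ties.
BAYES_FACTOR_TIE_CUTOFF = 3.0


@dataclass
class BootstrapMatrix:
    """Iterations x teams table of metric values from patient resampling.

    ``indices`` logs the resampled patient row indices (shape ``(B, n)``)
    so any iteration can be audited or replayed; the same resample is shared
    by every team within an iteration.
    """

    subchallenge: str
    n_iterations: int
    values: pd.DataFrame  # index: iteration, columns: team_id
    seed: Optional[int]
    indices: np.ndarray

    @property
    def teams(self) -> List[str]:
        return list(self.values.columns)

    def to_long_frame(self) -> pd.DataFrame:
        """Tidy (iteration, team, value) view for CSV persistence."""
        long = self.values.reset_index().melt(
            id_vars="iteration", var_name="team_id", value_name="value")
        return long.sort_values(["iteration", "team_id"], ignore_index=True)


def bootstrap_metrics(
    truth: Sequence[ScoreSheet],
    submissions: Sequence[SubmissionSet],
    subchallenge: str,
    n_iterations: int = 1000,
    seed: Optional[int] = None,
    registry: Optional[JointAreaRegistry] = None,
    indices: Optional[np.ndarray] = None,
) -> BootstrapMatrix:
    """Score every submission on ``n_iterations`` patient-level resamples.

    ``indices`` overrides the random resampling with explicit patient row
    indices (shape ``(B, n)``) — e.g. a single identity row reproduces the
    full-cohort metrics exactly.  Results are reproducible given ``seed``.
    """
    if len(truth) < 2:
        raise SchemeError("bootstrap needs at least 2 patients")
    if not submissions:
        raise SchemeError("no submissions to bootstrap")
    n = len(truth)
    if indices is None:
        if n_iterations < 1:
            raise SchemeError("n_iterations must be >= 1")
        rng = np.random.default_rng(seed)
        indices = rng.integers(0, n, size=(n_iterations, n))
    else:
        indices = np.asarray(indices)
        if indices.ndim != 2 or indices.min() < 0 or indices.max() >= n:
            raise SchemeError("explicit resample indices out of range")
        n_iterations = indices.shape[0]
    registry = registry or default_registry()
    cols: Dict[str, np.ndarray] = {}
    for sub in submissions:
        if sub.team_id in cols:
            raise SchemeError(f"duplicate team_id {sub.team_id!r}")
        A, W = patient_rmse_components(truth, sub, subchallenge, registry)
        num = A[indices].sum(axis=1)
        den = W[indices].sum(axis=1)
        cols[sub.team_id] = np.sqrt(num / den)
    values = pd.DataFrame(cols)
    values.index.name = "iteration"
    return BootstrapMatrix(
        subchallenge=subchallenge,
        n_iterations=n_iterations,
        values=values,
        seed=seed,
        indices=indices,
    )


@dataclass
class BayesFactorReport:
    """Per-team Bayes factors versus a reference submission.

    ``table`` columns: ``team_id, ref_wins, team_wins, ties, bayes_factor,
    classification`` where classification is the challenger's status
    relative to the reference (``better`` / ``tied`` / ``worse``).
    """

    subchallenge: str
    reference_team: str
    table: pd.DataFrame

    def classification(self, team_id: str) -> str:
        row = self.table.loc[self.table["team_id"] == team_id]
        if row.empty:
            raise SchemeError(f"unknown team {team_id!r}")
        return str(row["classification"].iloc[0])

    def bayes_factor(self, team_id: str) -> float:
        row = self.table.loc[self.table["team_id"] == team_id]
        if row.empty:
            raise SchemeError(f"unknown team {team_id!r}")
        return float(row["bayes_factor"].iloc[0])


def _classify(K: float) -> str:
    # challenger's status relative to the reference (lower metric is better)
    if K > BAYES_FACTOR_TIE_CUTOFF:
        return "worse"
    if K < 1.0 / BAYES_FACTOR_TIE_CUTOFF:
        return "better"
    return "tied"


def bayes_factor(matrix: BootstrapMatrix, reference_team: str) -> BayesFactorReport:
    """Bayes factor of every team against ``reference_team``.

    Within each iteration the submission with the strictly lower metric
    wins; exact ties are excluded from both counts.  ``K = ref wins / team
    wins``; a zero denominator with a positive numerator yields ``inf``, and
    an all-tie column (e.g. the reference against itself) yields ``K = 1``,
    classified tied.
    """
    if reference_team not in matrix.values.columns:
        raise SchemeError(f"reference team {reference_team!r} not in bootstrap matrix")
    ref = matrix.values[reference_team].to_numpy()
    rows = []
    for team in matrix.teams:
        vals = matrix.values[team].to_numpy()
        ref_wins = int((ref < vals).sum())
        team_wins = int((vals < ref).sum())
        ties = matrix.n_iterations - ref_wins - team_wins
        if ref_wins == 0 and team_wins == 0:
            K = 1.0
        elif team_wins == 0:
            K = math.inf
        else:
            K = ref_wins / team_wins
        rows.append((team, ref_wins, team_wins, ties, K, _classify(K)))
    table = pd.DataFrame(
        rows,
        columns=["team_id", "ref_wins", "team_wins", "ties", "bayes_factor", "classification"],
    )
    return BayesFactorReport(matrix.subchallenge, reference_team, table)


def rank_submissions(
    metric_values: Union[Mapping[str, float], Sequence[MetricResult]],
) -> List[str]:
    """Teams ordered by ascending metric (lower weighted RMSE is better).

    Exact ties break lexicographically by team id, which keeps the
    leaderboard deterministic.
    """
    if not isinstance(metric_values, Mapping):
        metric_values = {m.team_id: float(m) for m in metric_values}
    if not metric_values:
        raise SchemeError("no teams to rank")
    return sorted(metric_values, key=lambda t: (metric_values[t], t))


def pairwise_t_fdr(matrix: BootstrapMatrix, reference_team: str) -> pd.DataFrame:
    """Paired t-test of each team's bootstrap metrics against the reference.

    Benjamini-Hochberg correction is applied across the non-reference teams.
    A zero-variance difference vector (e.g. the reference against itself, or
    a bit-identical clone) cannot be tested; it is reported with ``p = q =
    1`` and ``degenerate = True``.  Returns columns ``team_id, t_stat,
    p_value, q_value, degenerate``.
    """
    if reference_team not in matrix.values.columns:
        raise SchemeError(f"reference team {reference_team!r} not in bootstrap matrix")
    if matrix.n_iterations < 2:
        raise SchemeError("paired t-test needs at least 2 bootstrap iterations")
    ref = matrix.values[reference_team].to_numpy()
    teams = [t for t in matrix.teams if t != reference_team]
    t_stats, p_values, degenerate = [], [], []
    for team in teams:
        diff = matrix.values[team].to_numpy() - ref
        if np.allclose(diff.std(ddof=1), 0.0):
            t_stats.append(float("nan"))
            p_values.append(1.0)
            degenerate.append(True)
        else:
            t, p = stats.ttest_rel(matrix.values[team].to_numpy(), ref)
            t_stats.append(float(t))
            p_values.append(float(p))
            degenerate.append(False)
    if teams:
        _, q_values, _, _ = multipletests(p_values, method="fdr_bh")
    else:
        q_values = []
    return pd.DataFrame({
        "team_id": teams,
        "t_stat": t_stats,
        "p_value": p_values,
        "q_value": list(q_values),
        "degenerate": degenerate,
    })
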