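"""Cumulative mean ensembles of ranked submissions ("wisdom of crowds").

For each subchallenge the submissions are ordered by full-cohort weighted
RMSE and aggregated cumulatively: the top performer alone, the top 2, the
top 3, and so on, by taking the arithmetic mean of the members' predicted
scores per (patient, joint area) and per patient-level total.  Each
ensemble is then scored like any submission and compared with the top
individual model via the bootstrap Bayes factor, with the Spearman
correlation as an alternative outcome metric.

Averaging happens on the raw predicted-score scale; the metric's log
transform applies afterwards.  When member errors are independent on the
log scale with equal SD sigma, the ensemble's log-residual SD contracts
approximately like sigma/sqrt(k) — the variance-reduction mechanism behind
ensembles beating the best individual model.  A team whose errors are
decorrelated from the leaders can therefore improve the ensemble even when
its own metric is mediocre.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import spearman_metric, weighted_rmse, _aligned_arrays
from .ranking import bayes_factor, bootstrap_metrics, rank_submissions
from .svh_model import (
    JointAreaRegistry,
    ScoreSheet,
    SchemeError,
    SubmissionSet,
    default_registry,
)

__all__ = [
    "EnsembleSeries",
    "mean_ensemble",
    "ensemble_series",
    "pairwise_submission_correlation",
]


def mean_ensemble(
    members: Sequence[SubmissionSet],
    team_id: Optional[str] = None,
) -> SubmissionSet:
    """Arithmetic mean of the members' predictions, per joint and per total.

    All members must share the same patient set and joint-area grid.  The
    patient-level totals are the means of the members' own totals (not
    recomputed from the ensembled joints): the overall prediction is an
    independent per-member estimate, so it is averaged like any other term.
    A single member passes through bit-identically.
    """
    if not members:
        raise SchemeError("ensemble needs at least 1 member")
    first = members[0]
    index = first.joint_scores.index
    columns = first.joint_scores.columns
    for m in members[1:]:
        if not m.joint_scores.index.equals(index) or not m.joint_scores.columns.equals(columns):
            raise SchemeError(
                f"submission grid mismatch between {first.team_id!r} and {m.team_id!r}")
    if team_id is None:
        team_id = "ensemble_top%d" % len(members) if len(members) > 1 else first.team_id
    if len(members) == 1:
        return SubmissionSet(team_id, first.joint_scores.copy(), first.overall.copy())
    joints = sum(m.joint_scores.to_numpy() for m in members) / len(members)
    overall = sum(m.overall.to_numpy() for m in members) / len(members)
    return SubmissionSet(
        team_id,
        pd.DataFrame(joints, index=index, columns=columns),
        pd.Series(overall, index=index),
    )


@dataclass
class EnsembleSeries:
    """Cumulative top-k ensemble evaluation for one subchallenge.

    ``table`` columns: ``k, members, weighted_rmse, spearman, bayes_factor,
    classification`` — classification being the ensemble's status versus the
    top individual model under the bootstrap Bayes factor.  ``ensembles``
    holds the k-th ensemble submission for downstream reuse.
    """

    subchallenge: str
    member_order: List[str]
    table: pd.DataFrame
    ensembles: List[SubmissionSet]


def ensemble_series(
    truth: Sequence[ScoreSheet],
    submissions: Sequence[SubmissionSet],
    subchallenge: str,
    n_iterations: int = 1000,
    seed: Optional[int] = None,
    registry: Optional[JointAreaRegistry] = None,
) -> EnsembleSeries:
    """Build and evaluate cumulative mean ensembles of the ranked teams.

    Teams are ranked by full-cohort weighted RMSE; for each ``k`` the top-k
    mean ensemble is scored (weighted RMSE and Spearman) and compared with
    the top individual submission by the bootstrap Bayes factor.  All
    ensembles share one set of bootstrap resamples, pairing the variance of
    the comparison; the ``k = 1`` ensemble is the top submission itself and
    is classified tied by construction.
    """
    registry = registry or default_registry()
    if not submissions:
        raise SchemeError("no submissions to ensemble")
    by_team = {s.team_id: s for s in submissions}
    full = {s.team_id: float(weighted_rmse(truth, s, subchallenge, registry))
            for s in submissions}
    order = rank_submissions(full)
    top = by_team[order[0]]

    # one shared resample set for every k (paired comparison)
    rng = np.random.default_rng(seed)
    indices = rng.integers(0, len(truth), size=(n_iterations, len(truth)))

    rows, ensembles = [], []
    for k in range(1, len(order) + 1):
        members = [by_team[t] for t in order[:k]]
        ens = mean_ensemble(members, team_id=f"ensemble_top{k}")
        rmse_k = float(weighted_rmse(truth, ens, subchallenge, registry))
        rho_k = spearman_metric(truth, ens, subchallenge, registry)
        if k == 1:
            K, cls = 1.0, "tied"
        else:
            pair = SubmissionSet("__top__", top.joint_scores.copy(), top.overall.copy())
            matrix = bootstrap_metrics(
                truth, [pair, ens], subchallenge,
                registry=registry, indices=indices)
            report = bayes_factor(matrix, "__top__")
            K = report.bayes_factor(ens.team_id)
            cls = report.classification(ens.team_id)
        rows.append((k, ";".join(order[:k]), rmse_k, rho_k, K, cls))
        ensembles.append(ens)
    table = pd.DataFrame(
        rows,
        columns=["k", "members", "weighted_rmse", "spearman", "bayes_factor", "classification"],
    )
    return EnsembleSeries(subchallenge, order, table, ensembles)


def pairwise_submission_correlation(
    submissions: Sequence[SubmissionSet],
    subchallenge: str,
    registry: Optional[JointAreaRegistry] = None,
) -> pd.DataFrame:
    """Team x team Spearman correlation matrix of the predictions.

    Correlations are over the subchallenge's comparison units (patient
    totals for sc1, per-joint scores otherwise).  Symmetric with unit
    diagonal; a constant prediction vector yields ``nan`` against every
    other team (undefined rank correlation).
    """
    if len(submissions) < 2:
        raise SchemeError("pairwise correlation needs at least 2 submissions")
    registry = registry or default_registry()
    vectors = {}
    for s in submissions:
        if subchallenge == "sc1":
            v = s.overall.to_numpy()
        elif subchallenge == "sc2":
            v = s.joint_scores[registry.column_keys("jsn")].to_numpy().ravel()
        elif subchallenge == "sc3":
            v = s.joint_scores[registry.column_keys("erosion")].to_numpy().ravel()
        else:
            raise SchemeError(f"unknown subchallenge {subchallenge!r}")
        vectors[s.team_id] = v
    teams = list(vectors)
    mat = pd.DataFrame(np.eye(len(teams)), index=teams, columns=teams)
    for i, a in enumerate(teams):
        for b in teams[i + 1:]:
            va, vb = vectors[a], vectors[b]
            if np.all(va == va[0]) or np.all(vb == vb[0]):
                rho = float("nan")
            else:
                rho, _ = stats.spearmanr(va, vb)
            mat.loc[a, b] = mat.loc[b, a] = float(rho)
    return mat
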