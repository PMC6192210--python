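"""Rank-based cross-validation: leave-one-out and repeated k-fold.

Each held-out known interaction is rescored by a model trained without it
and ranked against ALL unidentified pairs of the full grid (training
positives are never counted as negatives).  The ROC is swept over rank
thresholds; the AUC is the tie-corrected Mann-Whitney statistic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.stats import rankdata

from bidiffusion import baselines as _baselines
from bidiffusion import diffusion as _diffusion
from bidiffusion.data import InteractionNetwork
from bidiffusion.similarity import SimilarityMatrix

Scorer = Callable[[InteractionNetwork], np.ndarray]


@dataclass
class CvReport:
    protocol: str
    per_unit_auc: list[float]
    mean_auc: float
    sd_auc: float
    roc_points: list[tuple[float, float]]
    per_test_ranks: dict[tuple[str, str], float]
    seed: int | None = None
    repeats: int = 1
    k: int | None = None
    method: str = ""


# ---------------------------------------------------------------------------
# ROC / ranking primitives


def roc_auc(pos_scores, neg_scores) -> tuple[float, list[tuple[float, float]]]:
    """AUC (tie-corrected Mann-Whitney) and ROC points by threshold sweep.

    Ties contribute 1/2; the ROC starts at (0, 0), ends at (1, 1) and steps
    at every distinct score threshold (positives scoring >= threshold count
    as predicted positive).
    """
    pos = np.asarray(pos_scores, dtype=float)
    neg = np.asarray(neg_scores, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both score lists must be nonempty")

    combined = np.concatenate([pos, neg])
    ranks = rankdata(combined)  # average-rank convention handles ties
    auc = (ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0) / (
        pos.size * neg.size
    )

    thresholds = np.unique(combined)[::-1]
    points = [(0.0, 0.0)]
    for t in thresholds:
        tpr = float((pos >= t).mean())
        fpr = float((neg >= t).mean())
        points.append((fpr, tpr))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return float(auc), points


def rank_of_pair(
    scores: np.ndarray,
    pair: tuple[int, int],
    candidates: list[tuple[int, int]] | np.ndarray,
) -> float:
    """Average-rank of a held-out pair among itself plus the candidates.

    rank = 1 + (# candidates scoring strictly higher) + 1/2 (# ties).
    """
    scores = np.asarray(scores, dtype=float)
    cand = [tuple(c) for c in candidates]
    if tuple(pair) in cand:
        raise ValueError("the test pair must be held out of the candidate set")
    s = scores[pair[0], pair[1]]
    cand_scores = np.array([scores[i, j] for i, j in cand])
    higher = int((cand_scores > s).sum())
    ties = int((cand_scores == s).sum())
    return 1.0 + higher + 0.5 * ties


# ---------------------------------------------------------------------------
# scorer factory


def make_scorer(
    method: str,
    lnc_sim: SimilarityMatrix | None = None,
    mir_sim: SimilarityMatrix | None = None,
    config: _baselines.BaselineConfig | None = None,
    epsilon: float = _diffusion.DEFAULT_EPSILON,
    seed: int = 0,
) -> Scorer:
    """Bind a scoring method and its fixed inputs into network -> scores.

    Methods: ``eplmi`` (two-way diffusion), ``cf_lnc``, ``cf_mir``, ``svd``,
    ``lfm``, ``katz``, ``random``.
    """
    config = config or _baselines.BaselineConfig(seed=seed)
    rng = np.random.default_rng(seed)

    def scorer(network: InteractionNetwork) -> np.ndarray:
        if method == "eplmi":
            return _diffusion.predict(network, lnc_sim, mir_sim, epsilon=epsilon).values
        if method == "cf_lnc":
            return _baselines.cf_scores(network, lnc_sim, side="lnc").values
        if method == "cf_mir":
            return _baselines.cf_scores(network, mir_sim, side="mir").values
        if method == "svd":
            rank = min(config.svd_rank, network.nl, network.nm)
            return _baselines.svd_scores(network, rank=rank).values
        if method == "lfm":
            return _baselines.lfm_scores(network, config).values
        if method == "katz":
            return _baselines.katz_scores(
                network, lnc_sim, mir_sim, beta=config.katz_beta,
                kmax=config.katz_kmax,
            ).values
        if method == "random":
            return _baselines.random_scores(network, rng).values
        raise ValueError(f"unknown method {method!r}")

    return scorer


# ---------------------------------------------------------------------------
# cross-validation protocols


def _roc_from_quantiles(neg_fracs: np.ndarray) -> list[tuple[float, float]]:
    """ROC over rank thresholds from each test sample's fraction of
    negatives ranked above it."""
    points = [(0.0, 0.0)]
    for t in np.unique(neg_fracs):
        points.append((float(t), float((neg_fracs <= t).mean())))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    return points


def loocv(network: InteractionNetwork, scorer: Scorer, method: str = "") -> CvReport:
    """Leave each known interaction out in turn, rescore, and rank it
    against all unidentified pairs of the full grid.

    The global AUC is the mean over held-out edges of the fraction of
    unidentified pairs they outscore (ties count 1/2) — the Mann-Whitney
    statistic of the pooled rank construction.
    """
    A = network.adjacency
    unid = A == 0
    n_neg = int(unid.sum())
    if n_neg == 0:
        raise ValueError("no unidentified pairs to rank against")
    edge_idx = list(zip(*np.nonzero(A)))
    per_edge_auc = []
    per_test_ranks: dict[tuple[str, str], float] = {}
    for i, j in edge_idx:
        A_train = A.copy()
        A_train[i, j] = 0.0
        scores = scorer(network.with_adjacency(A_train))
        s = scores[i, j]
        neg = scores[unid]
        below = float((neg < s).sum()) + 0.5 * float((neg == s).sum())
        per_edge_auc.append(below / n_neg)
        rank = 1.0 + (n_neg - below)
        per_test_ranks[(network.lnc_ids[i], network.mir_ids[j])] = rank

    aucs = np.array(per_edge_auc)
    roc = _roc_from_quantiles(1.0 - aucs)
    mean_auc = float(aucs.mean())
    return CvReport(
        protocol="loocv",
        per_unit_auc=[mean_auc],
        mean_auc=mean_auc,
        sd_auc=0.0,
        roc_points=roc,
        per_test_ranks=per_test_ranks,
        method=method,
    )


def kfold_cv(
    network: InteractionNetwork,
    scorer: Scorer,
    k: int = 5,
    repeats: int = 50,
    seed: int = 0,
    method: str = "",
) -> CvReport:
    """Repeated k-fold cross-validation over known edges.

    Per repeat, edges are partitioned uniformly at random into k folds of
    roughly equal size (stream seeded as seed + repeat index); per fold the
    model is trained on the remaining edges and the AUC of held-out
    positives against all unidentified pairs of the full grid is recorded.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    A = network.adjacency
    edge_idx = np.array(np.nonzero(A)).T
    n_edges = len(edge_idx)
    if k > n_edges:
        raise ValueError(f"k={k} exceeds the number of known edges ({n_edges})")
    unid = A == 0

    per_fold_auc: list[float] = []
    roc_points: list[tuple[float, float]] | None = None
    for rep in range(repeats):
        rng = np.random.default_rng(seed + rep)
        order = rng.permutation(n_edges)
        folds = np.array_split(order, k)
        for fold in folds:
            A_train = A.copy()
            for idx in fold:
                i, j = edge_idx[idx]
                A_train[i, j] = 0.0
            scores = scorer(network.with_adjacency(A_train))
            pos = np.array([scores[i, j] for i, j in edge_idx[fold]])
            neg = scores[unid]
            auc, points = roc_auc(pos, neg)
            per_fold_auc.append(auc)
            if roc_points is None:
                roc_points = points

    aucs = np.array(per_fold_auc)
    return CvReport(
        protocol="kfold",
        per_unit_auc=[float(a) for a in aucs],
        mean_auc=float(aucs.mean()),
        sd_auc=float(aucs.std(ddof=1)) if len(aucs) > 1 else 0.0,
        roc_points=roc_points or [],
        per_test_ranks={},
        seed=seed,
        repeats=repeats,
        k=k,
        method=method,
    )
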