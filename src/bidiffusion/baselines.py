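"""Classical link-prediction baselines sharing the diffusion scorer's inputs.

Five methods: memory-based collaborative filtering on either side,
truncated-SVD reconstruction, a latent factor model fit by gradient
descent, and the Katz walk-counting index on the heterogeneous graph.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from bidiffusion.data import InteractionNetwork
from bidiffusion.diffusion import ScoreMatrix
from bidiffusion.similarity import SimilarityMatrix

logger = logging.getLogger(__name__)


@dataclass
class BaselineConfig:
    method: str = "cf_lnc"
    svd_rank: int = 20
    lfm_factors: int = 20
    lfm_reg: float = 0.01
    lfm_lr: float = 0.01
    lfm_epochs: int = 200
    katz_beta: float = 0.01
    katz_kmax: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.svd_rank < 1 or self.lfm_factors < 1:
            raise ValueError("ranks/factor counts must be >= 1")
        if self.katz_kmax < 1:
            raise ValueError("katz_kmax must be >= 1")


def cf_scores(
    network: InteractionNetwork, sim: SimilarityMatrix, side: str = "lnc"
) -> ScoreMatrix:
    """Memory-based collaborative filtering.

    lnc side: score(a, b) = sum_{l != a} sim(a, l) A(l, b) / sum_{l != a}
    sim(a, l); mir side is the transpose construction.  Self-similarity is
    excluded from the neighborhood.  Entities whose off-diagonal similarity
    sums to zero get all-zero scores (logged).
    """
    if side not in ("lnc", "mir"):
        raise ValueError(f"side must be 'lnc' or 'mir', got {side!r}")
    A = network.adjacency
    n_expected = network.nl if side == "lnc" else network.nm
    if sim.n != n_expected:
        raise ValueError(
            f"{side}-side CF needs a {n_expected}x{n_expected} similarity, got {sim.n}"
        )
    S0 = np.array(sim.values, dtype=float)
    np.fill_diagonal(S0, 0.0)
    denom = S0.sum(axis=1)
    dead = denom == 0
    if dead.any():
        logger.warning("%d entities have zero similarity mass; their scores are 0",
                       int(dead.sum()))
    denom = np.where(dead, 1.0, denom)
    if side == "lnc":
        values = (S0 @ A) / denom[:, None]
        values[dead, :] = 0.0
    else:
        values = (A @ S0) / denom[None, :]
        values[:, dead] = 0.0
    return ScoreMatrix(values, {"method": f"cf_{side}"})


def svd_scores(network: InteractionNetwork, rank: int = 20) -> ScoreMatrix:
    """Rank-truncated SVD reconstruction of A, shifted to be nonnegative."""
    A = network.adjacency
    if not 1 <= rank <= min(A.shape):
        raise ValueError(f"rank must be in [1, {min(A.shape)}], got {rank}")
    U, s, Vt = np.linalg.svd(A, full_matrices=False)
    recon = (U[:, :rank] * s[:rank]) @ Vt[:rank]
    return ScoreMatrix(recon - recon.min(), {"method": "svd", "rank": rank})


def lfm_scores(network: InteractionNetwork, config: BaselineConfig) -> ScoreMatrix:
    """Latent factor model, all unobserved cells treated as 0.

    Minimizes sum over all cells of (A - P Q^T)^2 plus L2 regularization by
    full-batch gradient descent from a seeded random start; scores are
    P Q^T shifted to be nonnegative.
    """
    A = network.adjacency
    rng = np.random.default_rng(config.seed)
    f = config.lfm_factors
    P = 0.1 * rng.standard_normal((network.nl, f))
    Q = 0.1 * rng.standard_normal((network.nm, f))
    lr, reg = config.lfm_lr, config.lfm_reg
    losses = []
    with np.errstate(over="ignore", invalid="ignore"):
        for epoch in range(config.lfm_epochs):
            E = P @ Q.T - A
            loss = float((E**2).sum() + reg * ((P**2).sum() + (Q**2).sum()))
            if not np.isfinite(loss):
                raise FloatingPointError(
                    "latent factor fit diverged; try a smaller learning rate"
                )
            losses.append(loss)
            gP = 2.0 * (E @ Q) + 2.0 * reg * P
            gQ = 2.0 * (E.T @ P) + 2.0 * reg * Q
            P -= lr * gP
            Q -= lr * gQ
    values = P @ Q.T
    logger.debug("lfm: loss %0.4g -> %0.4g over %d epochs",
                 losses[0], losses[-1], len(losses))
    return ScoreMatrix(
        values - values.min(),
        {
            "method": "lfm",
            "factors": f,
            "reg": reg,
            "lr": lr,
            "epochs": config.lfm_epochs,
            "seed": config.seed,
            "loss_trajectory": losses,
        },
    )


def katz_scores(
    network: InteractionNetwork,
    lnc_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    beta: float = 0.01,
    kmax: int = 4,
) -> ScoreMatrix:
    """Truncated Katz index on the heterogeneous graph.

    The walk graph is M = [[LS0, A], [A^T, MS0]] with zero-diagonal
    similarity blocks (self-loops must not inflate walk counts); the score
    is the lncRNA-miRNA block of sum_{k=1..kmax} beta^k M^k.
    """
    if kmax < 1:
        raise ValueError("kmax must be >= 1")
    A = network.adjacency
    nl, nm = A.shape
    LS0 = np.array(lnc_sim.values, dtype=float)
    MS0 = np.array(mir_sim.values, dtype=float)
    np.fill_diagonal(LS0, 0.0)
    np.fill_diagonal(MS0, 0.0)
    M = np.block([[LS0, A], [A.T, MS0]])
    radius = float(np.max(np.abs(np.linalg.eigvalsh((M + M.T) / 2.0))))
    if radius > 0 and beta >= 1.0 / radius:
        logger.warning(
            "katz beta=%g is >= 1/spectral radius (%g); truncated series may "
            "be dominated by long walks", beta, 1.0 / radius,
        )
    total = np.zeros_like(M)
    Mk = np.eye(M.shape[0])
    for k in range(1, kmax + 1):
        Mk = Mk @ M
        total += beta**k * Mk
    return ScoreMatrix(
        total[:nl, nl:], {"method": "katz", "beta": beta, "kmax": kmax}
    )


def random_scores(network: InteractionNetwork, rng: np.random.Generator) -> ScoreMatrix:
    """Uniform random scores; the null reference for evaluation."""
    return ScoreMatrix(rng.random(network.adjacency.shape), {"method": "random"})
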