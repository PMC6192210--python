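"""Two-way resource-diffusion scoring of all lncRNA-miRNA pairs.

The scorer builds two similarity-weighted copies of the bipartite adjacency
A (one weighted from the lncRNA side, one from the miRNA side), replaces
zeros with a tiny epsilon so every row/column sum is positive, and sends one
unit of resource from each node forward across the graph and back.  The
landed resource, averaged over the two weighted graphs and the two starting
sides, is the score of each pair.

With C the column-normalized and R the row-normalized weighted matrix, the
lncRNA-side pass is (C @ R.T) @ A and the miRNA-side pass is A @ (C.T @ R);
both redistribute the observed interaction profile A along two-hop resource
paths, so each pass conserves the total mass of A.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from bidiffusion.data import InteractionNetwork
from bidiffusion.similarity import SimilarityMatrix

DEFAULT_EPSILON = 1e-11


@dataclass
class WeightedNetworkPair:
    """The two similarity-weighted adjacencies, strictly positive after
    epsilon replacement."""

    A_l: np.ndarray  # lncRNA-similarity weighting: LS @ A, zeros -> eps
    A_m: np.ndarray  # miRNA-similarity weighting: A @ MS, zeros -> eps
    epsilon: float = DEFAULT_EPSILON

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.A_l.shape != self.A_m.shape:
            raise ValueError("weighted networks must share a shape")
        if (self.A_l <= 0).any() or (self.A_m <= 0).any():
            raise ValueError("weighted networks must be strictly positive")


@dataclass
class DiffusionResources:
    """Column- and row-normalized resource shares of one weighted network.

    Every column of ``C`` and every row of ``R`` sums to 1.
    """

    C: np.ndarray
    R: np.ndarray


@dataclass
class ScoreMatrix:
    """Scores for every lncRNA-miRNA pair plus provenance."""

    values: np.ndarray
    provenance: dict

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ValueError("scores must be finite")


def weighted_networks(
    network: InteractionNetwork,
    lnc_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    epsilon: float = DEFAULT_EPSILON,
) -> WeightedNetworkPair:
    """Build A_l = LS @ A and A_m = A @ MS, then replace zeros by epsilon.

    A_l[i, j] totals the similarity of lncRNA i to the lncRNAs interacting
    with miRNA j; A_m[i, j] totals the similarity of miRNA j to the miRNAs
    interacting with lncRNA i.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if not (lnc_sim.prepared and mir_sim.prepared):
        raise ValueError("similarity matrices must be prepared before weighting")
    if lnc_sim.n != network.nl:
        raise ValueError(f"lncRNA similarity is {lnc_sim.n}x{lnc_sim.n}, need {network.nl}")
    if mir_sim.n != network.nm:
        raise ValueError(f"miRNA similarity is {mir_sim.n}x{mir_sim.n}, need {network.nm}")
    A = network.adjacency
    A_l = lnc_sim.values @ A
    A_m = A @ mir_sim.values
    A_l[A_l == 0] = epsilon
    A_m[A_m == 0] = epsilon
    return WeightedNetworkPair(A_l=A_l, A_m=A_m, epsilon=epsilon)


def forward_resources(W: np.ndarray) -> DiffusionResources:
    """Normalize a strictly positive weighted matrix into resource shares.

    ``C[l, m] = W[l, m] / sum_i W[i, m]`` (columns sum to 1; row l is the
    resource vector of lncRNA l over miRNAs) and
    ``R[l, m] = W[l, m] / sum_j W[l, j]`` (rows sum to 1; column m is the
    resource vector of miRNA m over lncRNAs).
    """
    W = np.asarray(W, dtype=float)
    if (W <= 0).any():
        raise ValueError("forward_resources requires strictly positive weights")
    C = W / W.sum(axis=0, keepdims=True)
    R = W / W.sum(axis=1, keepdims=True)
    return DiffusionResources(C=C, R=R)


def _one_sided_passes(A: np.ndarray, W: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    res = forward_resources(W)
    ss_lnc = (res.C @ res.R.T) @ A
    ss_mir = A @ (res.C.T @ res.R)
    return ss_lnc, ss_mir


def two_way_diffusion(
    network: InteractionNetwork, pair: WeightedNetworkPair
) -> ScoreMatrix:
    """Run the forward-backward diffusion on both weighted networks.

    The final score is the equal-weight average of the lncRNA-side and
    miRNA-side passes over A_l and A_m.  Total score mass equals the number
    of known interactions.
    """
    A = network.adjacency
    if pair.A_l.shape != A.shape:
        raise ValueError("weighted networks do not match the interaction network")
    terms = []
    for W in (pair.A_l, pair.A_m):
        ss_lnc, ss_mir = _one_sided_passes(A, W)
        terms.extend([ss_lnc, ss_mir])
    values = sum(terms) / 4.0
    return ScoreMatrix(
        values=values,
        provenance={"method": "two_way_diffusion", "epsilon": pair.epsilon},
    )


def predict(
    network: InteractionNetwork,
    lnc_sim: SimilarityMatrix,
    mir_sim: SimilarityMatrix,
    epsilon: float = DEFAULT_EPSILON,
) -> ScoreMatrix:
    """Score every pair: weighted networks -> resource shares -> diffusion."""
    if lnc_sim.entity_ids != network.lnc_ids:
        raise ValueError("lncRNA similarity ids are not aligned with the network")
    if mir_sim.entity_ids != network.mir_ids:
        raise ValueError("miRNA similarity ids are not aligned with the network")
    pair = weighted_networks(network, lnc_sim, mir_sim, epsilon=epsilon)
    result = two_way_diffusion(network, pair)
    result.provenance.update(
        {
            "method": "eplmi_two_way_diffusion",
            "epsilon": epsilon,
            "lnc_sim_kind": lnc_sim.kind,
            "mir_sim_kind": mir_sim.kind,
            "nl": network.nl,
            "nm": network.nm,
            "n_edges": network.n_edges,
        }
    )
    return result
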