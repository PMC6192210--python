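"""Planted-block synthetic data: bipartite networks whose lncRNA and miRNA
blocks preferentially interact, with block-correlated expression profiles.

Entities are assigned to blocks round-robin; an edge (l, m) is drawn
Bernoulli(p_in) when l and m carry the same block index and Bernoulli(p_out)
otherwise.  Every entity's profile is its block's template (scaled standard
normal, drawn once per block per side) plus independent Gaussian noise, so
within-block profile correlation exceeds between-block correlation — the
planted analogue of the coherence pattern the scorer exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from bidiffusion.data import ExpressionProfileSet, InteractionNetwork


@dataclass
class SyntheticParams:
    n_lnc: int = 60
    n_mir: int = 40
    n_blocks: int = 4
    p_in: float = 0.5
    p_out: float = 0.03
    n_conditions_lnc: int = 22
    n_conditions_mir: int = 172
    block_signal: float = 1.0
    noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_blocks > min(self.n_lnc, self.n_mir):
            raise ValueError("n_blocks must not exceed either side's size")
        if not (0 <= self.p_out < self.p_in <= 1):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")


@dataclass
class SyntheticDataset:
    network: InteractionNetwork
    lnc_profiles: ExpressionProfileSet
    mir_profiles: ExpressionProfileSet
    lnc_blocks: dict[str, int]
    mir_blocks: dict[str, int]
    params: SyntheticParams
    removed_edges: list[tuple[str, str]] = field(default_factory=list)


def _profiles(
    prefix: str,
    n_entities: int,
    n_conditions: int,
    blocks: np.ndarray,
    n_blocks: int,
    signal: float,
    noise_sd: float,
    rng: np.random.Generator,
) -> ExpressionProfileSet:
    templates = signal * rng.standard_normal((n_blocks, n_conditions))
    values = templates[blocks] + rng.normal(0.0, noise_sd, (n_entities, n_conditions))
    ids = [f"{prefix}{i + 1:04d}" for i in range(n_entities)]
    labels = [f"cond{j + 1}" for j in range(n_conditions)]
    return ExpressionProfileSet(ids, labels, values)


def generate(params: SyntheticParams | None = None, **overrides) -> SyntheticDataset:
    """Generate one dataset; identical params + seed give identical output."""
    if params is None:
        params = SyntheticParams(**overrides)
    elif overrides:
        params = replace(params, **overrides)
    rng = np.random.default_rng(params.seed)

    lnc_blocks = np.arange(params.n_lnc) % params.n_blocks
    mir_blocks = np.arange(params.n_mir) % params.n_blocks
    same_block = lnc_blocks[:, None] == mir_blocks[None, :]
    prob = np.where(same_block, params.p_in, params.p_out)

    adjacency = (rng.random(prob.shape) < prob).astype(float)
    if adjacency.sum() == 0:  # one resample before giving up
        adjacency = (rng.random(prob.shape) < prob).astype(float)
        if adjacency.sum() == 0:
            raise ValueError("sampled network has no edges")

    lnc_profiles = _profiles(
        "L", params.n_lnc, params.n_conditions_lnc, lnc_blocks,
        params.n_blocks, params.block_signal, params.noise_sd, rng,
    )
    mir_profiles = _profiles(
        "M", params.n_mir, params.n_conditions_mir, mir_blocks,
        params.n_blocks, params.block_signal, params.noise_sd, rng,
    )
    network = InteractionNetwork(
        list(lnc_profiles.entity_ids), list(mir_profiles.entity_ids), adjacency
    )
    return SyntheticDataset(
        network=network,
        lnc_profiles=lnc_profiles,
        mir_profiles=mir_profiles,
        lnc_blocks=dict(zip(lnc_profiles.entity_ids, lnc_blocks.tolist())),
        mir_blocks=dict(zip(mir_profiles.entity_ids, mir_blocks.tolist())),
        params=params,
    )


def degrade(
    dataset: SyntheticDataset, fraction_edges_removed: float, seed: int = 0
) -> SyntheticDataset:
    """Remove a uniform random fraction of edges, recording them as ground
    truth for recovery experiments."""
    if not 0 <= fraction_edges_removed < 1:
        raise ValueError("fraction_edges_removed must be in [0, 1)")
    net = dataset.network
    edges = net.edges()
    n_remove = int(round(fraction_edges_removed * len(edges)))
    if n_remove == 0:
        return replace(dataset, removed_edges=[])
    if n_remove >= len(edges):
        raise ValueError("removal would empty the network")
    rng = np.random.default_rng(seed)
    chosen = rng.choice(len(edges), size=n_remove, replace=False)
    removed = [edges[i] for i in sorted(chosen)]
    adjacency = net.adjacency.copy()
    li = {e: i for i, e in enumerate(net.lnc_ids)}
    mi = {e: i for i, e in enumerate(net.mir_ids)}
    for lnc, mir in removed:
        adjacency[li[lnc], mi[mir]] = 0.0
    return replace(
        dataset,
        network=net.with_adjacency(adjacency),
        removed_edges=removed,
    )


def shuffle_partners(
    network: InteractionNetwork, focal_side: str = "lnc", seed: int = 0
) -> InteractionNetwork:
    """Null model: each focal node keeps its degree but draws a uniform
    random partner set.  Used for coherence null-behavior checks."""
    rng = np.random.default_rng(seed)
    A = network.adjacency if focal_side == "lnc" else network.adjacency.T
    out = np.zeros_like(A)
    n_partners = A.shape[1]
    for f in range(A.shape[0]):
        d = int(A[f].sum())
        if d:
            out[f, rng.choice(n_partners, size=d, replace=False)] = 1.0
    if focal_side != "lnc":
        out = out.T
    return network.with_adjacency(out)
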