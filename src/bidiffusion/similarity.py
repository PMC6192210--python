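"""Similarity kernels over one node class.

Three kernels are provided: Pearson correlation of expression profiles,
annotation-set overlap, and global-alignment sequence similarity.  Before a
kernel can weight the diffusion it must be passed through
:func:`prepare_similarity`, which clips negatives and pins the diagonal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from Bio import Align

from bidiffusion.data import AnnotationSetCollection, ExpressionProfileSet, SequenceSet

logger = logging.getLogger(__name__)

_SYMMETRY_TOL = 1e-9


@dataclass
class SimilarityMatrix:
    """Square symmetric similarity over one node class."""

    entity_ids: list[str]
    values: np.ndarray
    kind: str
    prepared: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.entity_ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix must be square over entity_ids")
        if not np.allclose(self.values, self.values.T, atol=_SYMMETRY_TOL):
            raise ValueError("similarity matrix is not symmetric")

    @property
    def n(self) -> int:
        return len(self.entity_ids)

    def subset(self, ids: list[str]) -> "SimilarityMatrix":
        index = {e: i for i, e in enumerate(self.entity_ids)}
        rows = [index[e] for e in ids]
        return replace(self, entity_ids=list(ids), values=self.values[np.ix_(rows, rows)])


def pearson_similarity(profiles: ExpressionProfileSet) -> SimilarityMatrix:
    """Pairwise Pearson correlation of expression profiles.

    The correlation of profiles ``a`` and ``b`` is their centered dot
    product divided by the product of centered norms.  Constant profiles
    have undefined correlation; every pair involving one gets similarity 0
    (logged), and the diagonal is always 1.
    """
    X = profiles.values
    centered = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    constant = norms == 0
    if constant.any():
        logger.warning(
            "%d constant profiles (undefined correlation), similarity set to 0: %s",
            constant.sum(),
            [e for e, c in zip(profiles.entity_ids, constant) if c][:10],
        )
    safe = np.where(constant, 1.0, norms)
    values = (centered @ centered.T) / np.outer(safe, safe)
    values[constant, :] = 0.0
    values[:, constant] = 0.0
    np.fill_diagonal(values, 1.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(list(profiles.entity_ids), values, kind="expression")


def set_overlap_similarity(
    sets: AnnotationSetCollection, normalization: str = "product"
) -> SimilarityMatrix:
    """Annotation-set overlap similarity.

    ``product``: ``|A n B| / (|A| * |B|)`` — identical sets of size n score
    1/n.  ``geometric``: ``|A n B| / sqrt(|A| * |B|)`` (Ochiai) — identical
    sets score 1.
    """
    if normalization not in ("product", "geometric"):
        raise ValueError(f"unknown normalization {normalization!r}")
    ids = sets.entity_ids
    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        a = sets[ids[i]]
        for j in range(i, n):
            b = sets[ids[j]]
            inter = len(a & b)
            denom = len(a) * len(b)
            if normalization == "geometric":
                denom = np.sqrt(denom)
            values[i, j] = values[j, i] = inter / denom
    return SimilarityMatrix(ids, values, kind="functional")


def sequence_similarity(
    seqs: SequenceSet,
    match: float = 2.0,
    mismatch: float = -1.0,
    gap_open: float = -0.5,
    gap_extend: float = -0.1,
    normalization: str = "self_geometric",
) -> SimilarityMatrix:
    """Needleman-Wunsch global alignment similarity with affine gaps.

    Raw scores are symmetric and S(a, a) = match * len(a).  Under
    ``self_geometric`` normalization the score is
    ``S(a,b) / sqrt(S(a,a) * S(b,b))`` clipped to [0, 1].
    """
    if normalization not in ("none", "self_geometric"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if not (gap_open <= gap_extend <= 0):
        raise ValueError("affine gap scores require gap_open <= gap_extend <= 0")
    ids = seqs.entity_ids
    # alignment alphabet is DNA; U in RNA input maps onto T
    prepped = {e: seqs[e].replace("U", "T") for e in ids}

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend

    n = len(ids)
    values = np.zeros((n, n))
    for i in range(n):
        values[i, i] = match * len(prepped[ids[i]])
        for j in range(i + 1, n):
            s = aligner.score(prepped[ids[i]], prepped[ids[j]])
            values[i, j] = values[j, i] = s
    if normalization == "self_geometric":
        self_scores = np.diag(values).copy()
        values = values / np.sqrt(np.outer(self_scores, self_scores))
        values = np.clip(values, 0.0, 1.0)
    return SimilarityMatrix(ids, values, kind="sequence")


def prepare_similarity(
    sim: SimilarityMatrix,
    clip_negative: bool = True,
    self_similarity: float = 1.0,
) -> SimilarityMatrix:
    """Make a kernel usable as diffusion weights.

    Negative entries are clipped to 0 (resource shares must be nonnegative)
    and the diagonal is overwritten with ``self_similarity``.
    """
    values = np.array(sim.values, dtype=float)
    if not np.allclose(values, values.T, atol=_SYMMETRY_TOL):
        raise ValueError("similarity matrix is not symmetric")
    if not np.isfinite(values).all():
        raise ValueError("similarity matrix has non-finite entries")
    if clip_negative:
        values = np.clip(values, 0.0, None)
    np.fill_diagonal(values, self_similarity)
    values = (values + values.T) / 2.0
    return SimilarityMatrix(list(sim.entity_ids), values, kind=sim.kind, prepared=True)


def write_similarity(sim: SimilarityMatrix, path) -> None:
    """Write a labeled square TSV matrix."""
    import pandas as pd

    pd.DataFrame(sim.values, index=sim.entity_ids, columns=sim.entity_ids).to_csv(
        path, sep="\t", float_format="%.15g"
    )


def read_similarity(path, kind: str = "expression", prepared: bool = False) -> SimilarityMatrix:
    """Read a labeled square TSV matrix written by :func:`write_similarity`."""
    import pandas as pd

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return SimilarityMatrix(
        [str(e) for e in frame.index], frame.to_numpy(dtype=float), kind=kind,
        prepared=prepared,
    )
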