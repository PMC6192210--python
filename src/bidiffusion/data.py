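"""Core data model and plain-text readers/writers.

All matrices are indexed by id order; id order is first-appearance order in
the source file.  Files are TSV/CSV with tab-vs-comma auto-detection (an
explicit ``delimiter`` argument overrides detection).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

# significant digits used when writing scores; round-trips to >= 12 digits
_SCORE_FMT = "{:.15g}"


@dataclass
class InteractionNetwork:
    """Binary bipartite adjacency between lncRNAs (rows) and miRNAs (columns).

    Attributes
    ----------
    lnc_ids, mir_ids : list of str
        Ordered unique identifiers for the two node classes.
    adjacency : ndarray of shape (nl, nm)
        0/1 matrix; ``adjacency[i, j] == 1`` iff the interaction is known.
    """

    lnc_ids: list[str]
    mir_ids: list[str]
    adjacency: np.ndarray

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        nl, nm = self.adjacency.shape
        if nl != len(self.lnc_ids) or nm != len(self.mir_ids):
            raise ValueError("adjacency shape does not match id lists")
        if len(set(self.lnc_ids)) != nl:
            raise ValueError("duplicate lncRNA ids")
        if len(set(self.mir_ids)) != nm:
            raise ValueError("duplicate miRNA ids")
        vals = np.unique(self.adjacency)
        if not np.isin(vals, (0.0, 1.0)).all():
            raise ValueError("adjacency entries must be 0 or 1")
        if self.n_edges == 0:
            raise ValueError("network has no interactions")

    @property
    def nl(self) -> int:
        return len(self.lnc_ids)

    @property
    def nm(self) -> int:
        return len(self.mir_ids)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum())

    @property
    def n_unidentified(self) -> int:
        """Number of pairs with no known interaction: nl*nm - n_edges."""
        return self.nl * self.nm - self.n_edges

    def edges(self) -> list[tuple[str, str]]:
        """Known pairs as (lncRNA id, miRNA id), row-major order."""
        ii, jj = np.nonzero(self.adjacency)
        return [(self.lnc_ids[i], self.mir_ids[j]) for i, j in zip(ii, jj)]

    def with_adjacency(self, adjacency: np.ndarray) -> "InteractionNetwork":
        """Same node sets with a different edge set (used by cross-validation)."""
        return InteractionNetwork(self.lnc_ids, self.mir_ids, adjacency)


@dataclass
class ExpressionProfileSet:
    """Real-valued entities x conditions matrix of expression levels."""

    entity_ids: list[str]
    condition_labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.entity_ids), len(self.condition_labels)):
            raise ValueError("profile matrix shape does not match labels")
        if len(set(self.entity_ids)) != len(self.entity_ids):
            raise ValueError("duplicate entity ids")
        if len(self.condition_labels) < 2:
            raise ValueError("at least two conditions are required")
        if not np.isfinite(self.values).all():
            raise ValueError("profiles contain non-finite values")

    @property
    def n_conditions(self) -> int:
        return len(self.condition_labels)

    def subset(self, ids: Sequence[str]) -> "ExpressionProfileSet":
        index = {e: i for i, e in enumerate(self.entity_ids)}
        rows = [index[e] for e in ids]
        return ExpressionProfileSet(list(ids), self.condition_labels, self.values[rows])


@dataclass
class AnnotationSetCollection:
    """Entity id -> finite set of term identifiers (target genes, function labels)."""

    sets: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        for entity, terms in self.sets.items():
            if not terms:
                raise ValueError(f"entity {entity!r} has an empty term set")

    def __contains__(self, entity: str) -> bool:
        return entity in self.sets

    def __getitem__(self, entity: str) -> frozenset[str]:
        return self.sets[entity]

    @property
    def entity_ids(self) -> list[str]:
        return list(self.sets)


@dataclass
class SequenceSet:
    """Entity id -> upper-case nucleotide string over {A, C, G, U/T, N}."""

    sequences: dict[str, str]

    def __post_init__(self) -> None:
        for entity, seq in self.sequences.items():
            if not seq:
                raise ValueError(f"empty sequence for {entity!r}")

    def __contains__(self, entity: str) -> bool:
        return entity in self.sequences

    def __getitem__(self, entity: str) -> str:
        return self.sequences[entity]

    @property
    def entity_ids(self) -> list[str]:
        return list(self.sequences)


# ---------------------------------------------------------------------------
# readers


def _detect_delimiter(line: str) -> str:
    return "\t" if "\t" in line else ","


def read_interaction_table(
    path: str | Path,
    delimiter: str | None = None,
    header: bool | None = None,
) -> InteractionNetwork:
    """Read a two-column (lncRNA id, miRNA id) interaction table.

    Duplicate rows are collapsed to a single edge.  Id order is
    first-appearance order.  When ``header`` is None, a header line is
    assumed iff the first row's fields never reappear in their columns.
    """
    path = Path(path)
    raw = path.read_text().splitlines()
    rows: list[tuple[str, str]] = []
    for lineno, line in enumerate(raw, start=1):
        if not line.strip():
            continue
        if delimiter is None:
            delimiter = _detect_delimiter(line)
        parts = [p.strip() for p in line.split(delimiter)]
        if len(parts) < 2 or not parts[0] or not parts[1]:
            raise ValueError(f"{path}: malformed row at line {lineno}: {line!r}")
        rows.append((parts[0], parts[1]))
    if not rows:
        raise ValueError(f"{path}: no interactions")

    if header is None:
        # a header is assumed only when the first row's tokens never reappear
        # while other ids do repeat (so non-overlap is informative)
        col0 = [r[0] for r in rows[1:]]
        col1 = [r[1] for r in rows[1:]]
        reuse = len(set(col0)) < len(col0) or len(set(col1)) < len(col1)
        header = (
            len(rows) > 1
            and reuse
            and rows[0][0] not in col0
            and rows[0][1] not in col1
        )
    n_raw = len(rows)
    if header:
        rows = rows[1:]
        if not rows:
            raise ValueError(f"{path}: no interactions")

    lnc_ids: list[str] = []
    mir_ids: list[str] = []
    lnc_index: dict[str, int] = {}
    mir_index: dict[str, int] = {}
    edges: set[tuple[int, int]] = set()
    for lnc, mir in rows:
        if lnc not in lnc_index:
            lnc_index[lnc] = len(lnc_ids)
            lnc_ids.append(lnc)
        if mir not in mir_index:
            mir_index[mir] = len(mir_ids)
            mir_ids.append(mir)
        edges.add((lnc_index[lnc], mir_index[mir]))

    adjacency = np.zeros((len(lnc_ids), len(mir_ids)))
    for i, j in edges:
        adjacency[i, j] = 1.0
    logger.info(
        "read %d rows from %s -> %d distinct interactions (%d lncRNAs x %d miRNAs)",
        n_raw, path, len(edges), len(lnc_ids), len(mir_ids),
    )
    return InteractionNetwork(lnc_ids, mir_ids, adjacency)


def write_interaction_table(
    network: InteractionNetwork, path: str | Path, delimiter: str = "\t"
) -> None:
    """Write the edge list as a two-column delimited file."""
    lines = [f"{lnc}{delimiter}{mir}" for lnc, mir in network.edges()]
    Path(path).write_text("\n".join(lines) + "\n")


def read_expression_profiles(
    path: str | Path, delimiter: str | None = None
) -> ExpressionProfileSet:
    """Read a delimited expression table: header of condition labels, one
    row per entity (first column = entity id).

    Rows containing any missing or non-numeric value are dropped with a log
    message; duplicated entity ids are an error.
    """
    path = Path(path)
    if delimiter is None:
        with open(path) as fh:
            first = fh.readline()
        delimiter = _detect_delimiter(first)
    frame = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str)
    if frame.shape[1] < 2:
        raise ValueError(f"{path}: need at least 2 conditions, got {frame.shape[1]}")
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].unique().tolist()
        raise ValueError(f"{path}: duplicate entity ids: {dupes}")
    numeric = frame.apply(pd.to_numeric, errors="coerce")
    keep = numeric.notna().all(axis=1)
    dropped = numeric.index[~keep].tolist()
    if dropped:
        logger.warning(
            "%s: dropped %d rows with missing/non-numeric values: %s",
            path, len(dropped), dropped[:10],
        )
    numeric = numeric.loc[keep]
    return ExpressionProfileSet(
        [str(e) for e in numeric.index],
        [str(c) for c in numeric.columns],
        numeric.to_numpy(dtype=float),
    )


def read_annotation_sets(path: str | Path) -> AnnotationSetCollection:
    """Read "entity<TAB>term1,term2,..." rows into term sets.

    Terms are deduplicated per entity; repeated entities are unioned; rows
    with an empty term list are skipped with a warning.
    """
    path = Path(path)
    sets: dict[str, set[str]] = {}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        entity, _, rest = line.partition("\t")
        entity = entity.strip()
        terms = {t.strip() for t in rest.split(",") if t.strip()}
        if not entity or not terms:
            logger.warning("%s: line %d has no terms, skipped", path, lineno)
            continue
        sets.setdefault(entity, set()).update(terms)
    return AnnotationSetCollection({e: frozenset(t) for e, t in sets.items()})


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a FASTA file; the header token up to the first whitespace is the
    id.  Sequences are upper-cased; both U and T are accepted."""
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        if record.id in sequences:
            raise ValueError(f"{path}: duplicate id {record.id!r}")
        seq = str(record.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {record.id!r}")
        sequences[record.id] = seq
    if not sequences:
        raise ValueError(f"{path}: no FASTA records")
    return SequenceSet(sequences)


# ---------------------------------------------------------------------------
# entity alignment


def align_entities(
    network: InteractionNetwork,
    lnc_feature_ids: Iterable[str] | None = None,
    mir_feature_ids: Iterable[str] | None = None,
) -> InteractionNetwork:
    """Restrict the network to entities that have the required features.

    Entities absent from the given id collections are dropped, as are
    entities left with no edges by that restriction (the method cannot score
    featureless or isolated nodes).  Raises if no edges remain.
    """
    lnc_keep = np.ones(network.nl, dtype=bool)
    mir_keep = np.ones(network.nm, dtype=bool)
    if lnc_feature_ids is not None:
        covered = set(lnc_feature_ids)
        lnc_keep = np.array([e in covered for e in network.lnc_ids])
    if mir_feature_ids is not None:
        covered = set(mir_feature_ids)
        mir_keep = np.array([e in covered for e in network.mir_ids])

    A = network.adjacency[np.ix_(lnc_keep, mir_keep)]
    # restriction can isolate nodes on either side; iterate to a fixed point
    lnc_live = np.ones(A.shape[0], dtype=bool)
    mir_live = np.ones(A.shape[1], dtype=bool)
    while True:
        new_lnc = A[:, mir_live].sum(axis=1) > 0
        new_mir = A[lnc_live].sum(axis=0) > 0
        if (new_lnc == lnc_live).all() and (new_mir == mir_live).all():
            break
        lnc_live, mir_live = new_lnc, new_mir
    A = A[np.ix_(lnc_live, mir_live)]
    if A.size == 0 or A.sum() == 0:
        raise ValueError("entity alignment leaves no interactions")

    lnc_ids = [e for e, k in zip(network.lnc_ids, lnc_keep) if k]
    lnc_ids = [e for e, k in zip(lnc_ids, lnc_live) if k]
    mir_ids = [e for e, k in zip(network.mir_ids, mir_keep) if k]
    mir_ids = [e for e, k in zip(mir_ids, mir_live) if k]
    logger.info(
        "align_entities: dropped %d lncRNAs and %d miRNAs",
        network.nl - len(lnc_ids), network.nm - len(mir_ids),
    )
    return InteractionNetwork(lnc_ids, mir_ids, A)


# ---------------------------------------------------------------------------
# score output


def write_score_table(
    scores: np.ndarray,
    network: InteractionNetwork,
    candidates_path: str | Path,
    known_path: str | Path,
) -> None:
    """Write ranked prediction output.

    ``candidates_path`` gets, per miRNA, the unidentified lncRNA candidates
    ranked by descending score; ``known_path`` gets the scores of all known
    pairs (descending).  Ties break by lexicographic id so the output is
    deterministic.  Columns: rank, lncRNA, miRNA, score.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.shape != network.adjacency.shape:
        raise ValueError(
            f"score shape {scores.shape} does not match network "
            f"({network.nl}, {network.nm})"
        )

    header = "rank\tlncRNA\tmiRNA\tscore"
    cand_lines = [header]
    for j, mir in sorted(enumerate(network.mir_ids), key=lambda t: t[1]):
        rows = [
            (network.lnc_ids[i], scores[i, j])
            for i in range(network.nl)
            if network.adjacency[i, j] == 0
        ]
        rows.sort(key=lambda r: (-r[1], r[0]))
        for rank, (lnc, s) in enumerate(rows, start=1):
            cand_lines.append(f"{rank}\t{lnc}\t{mir}\t{_SCORE_FMT.format(s)}")
    Path(candidates_path).write_text("\n".join(cand_lines) + "\n")

    known = [
        (network.lnc_ids[i], network.mir_ids[j], scores[i, j])
        for i, j in zip(*np.nonzero(network.adjacency))
    ]
    known.sort(key=lambda r: (-r[2], r[0], r[1]))
    known_lines = [header]
    for rank, (lnc, mir, s) in enumerate(known, start=1):
        known_lines.append(f"{rank}\t{lnc}\t{mir}\t{_SCORE_FMT.format(s)}")
    Path(known_path).write_text("\n".join(known_lines) + "\n")


def read_score_table(path: str | Path) -> pd.DataFrame:
    """Read back a score table written by :func:`write_score_table`."""
    return pd.read_csv(path, sep="\t")
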