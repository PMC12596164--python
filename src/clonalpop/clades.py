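"""Pairwise identity matrices, hierarchical clade assignment and timelines.

Synthetic "ANI" is exact per-site identity over equal-length concatenated
gene sequences; externally computed whole-genome identity matrices are
ingested from labeled square TSV/CSV files (percent or fraction scale).
Clades are flat clusters of an average-linkage dendrogram on 1 - identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

__all__ = [
    "IdentityMatrix",
    "CladeAssignment",
    "CladeTimeline",
    "pairwise_identity",
    "read_ani_matrix",
    "cluster_clades",
    "species_check",
    "clade_relative_abundance",
    "dendrogram_newick",
]


@dataclass(frozen=True)
class IdentityMatrix:
    """Symmetric pairwise identity values in [0, 1] with unit diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match the number of ids")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate isolate ids")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("identity matrix is not symmetric")
        if not np.all(np.diag(v) == 1.0):
            raise ValueError("identity matrix diagonal must be exactly 1")
        if v.min() < 0.0 or v.max() > 1.0:
            raise ValueError("identity values must lie in [0, 1]")

    def min_off_diagonal(self) -> float:
        if len(self.ids) < 2:
            raise ValueError("need at least 2 isolates")
        v = self.values.copy()
        np.fill_diagonal(v, np.inf)
        return float(v.min())

    def reorder(self, ids: Sequence[str]) -> "IdentityMatrix":
        index = {x: i for i, x in enumerate(self.ids)}
        perm = [index[x] for x in ids]
        return IdentityMatrix(tuple(ids), self.values[np.ix_(perm, perm)])


@dataclass(frozen=True)
class CladeAssignment:
    """Flat clade labels from cutting the identity dendrogram.

    Clades are numbered 1..k by first appearance in input id order.
    """

    ids: tuple[str, ...]
    clade_of: dict[str, int]
    linkage: str
    cut_identity: float

    @property
    def n_clades(self) -> int:
        return len(set(self.clade_of.values()))

    def labels(self) -> list[int]:
        return [self.clade_of[i] for i in self.ids]


@dataclass(frozen=True)
class CladeTimeline:
    """Per-time-point clade fractions among sampled isolates."""

    time_points: tuple[str, ...]
    fractions: pd.DataFrame  # index = time points, columns = clade indices
    counts: pd.Series  # isolates per time point
    persistence: pd.DataFrame  # per clade: first/last time point, n points seen


# ---------------------------------------------------------------------------
# identity
# ---------------------------------------------------------------------------

def pairwise_identity(sequences: Sequence[tuple[str, str]]) -> IdentityMatrix:
    """Exact per-site identity between equal-length ungapped sequences."""
    if len(sequences) < 2:
        raise ValueError("need at least 2 sequences")
    ids = tuple(sid for sid, _ in sequences)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    lengths = {len(seq) for _, seq in sequences}
    if len(lengths) != 1:
        raise ValueError(f"ragged input: sequence lengths {sorted(lengths)}")
    L = lengths.pop()
    if L == 0:
        raise ValueError("zero-length sequences")
    mat = np.frombuffer(
        "".join(seq for _, seq in sequences).encode("ascii"), dtype="S1"
    ).reshape(len(ids), L)
    if b"-" in mat:
        raise ValueError("gapped sequences are not allowed in pairwise_identity")
    n = len(ids)
    values = np.ones((n, n), dtype=float)
    for i in range(n):
        eq = (mat[i + 1 :] == mat[i]).mean(axis=1)
        values[i, i + 1 :] = eq
        values[i + 1 :, i] = eq
    return IdentityMatrix(ids, values)


def read_ani_matrix(path: str | Path) -> IdentityMatrix:
    """Read a labeled square identity matrix from TSV/CSV.

    Percent-scale matrices (values > 1.5) are rescaled to fractions with a
    logged notice.  Asymmetry within 1e-6 is symmetrized by averaging with
    a warning; larger asymmetry is an error.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab", ".txt") else ","
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.shape[0] != df.shape[1]:
        raise ValueError(f"{path}: matrix is not square ({df.shape[0]}x{df.shape[1]})")
    rows = [str(x) for x in df.index]
    cols = [str(x) for x in df.columns]
    if rows != cols:
        if set(rows) == set(cols):
            df = df[rows]
            cols = rows
        else:
            raise ValueError(f"{path}: row and column labels disagree")
    values = df.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError(f"{path}: matrix contains missing values")
    if values.max() > 1.5:
        logger.info("%s: percent-scale identities detected; rescaling to [0, 1]", path)
        values = values / 100.0
    asym = np.abs(values - values.T).max()
    if asym > 1e-6:
        raise ValueError(f"{path}: matrix asymmetric beyond tolerance (max |d|={asym:.3g})")
    if asym > 0:
        logger.warning("%s: symmetrizing matrix (max asymmetry %.3g)", path, asym)
        values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return IdentityMatrix(tuple(rows), values)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------

def _linkage(matrix: IdentityMatrix, method: str) -> tuple[np.ndarray, list[str]]:
    # Sorting ids lexicographically first makes scipy's index-order
    # tie-breaking equivalent to a smallest-lexicographic-pair rule.
    order = sorted(range(len(matrix.ids)), key=lambda i: matrix.ids[i])
    sorted_ids = [matrix.ids[i] for i in order]
    dist = 1.0 - matrix.values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    condensed = squareform(dist, checks=False)
    return hierarchy.linkage(condensed, method=method), sorted_ids


def cluster_clades(
    matrix: IdentityMatrix,
    cut_identity: float,
    linkage: str = "average",
) -> CladeAssignment:
    """Agglomerative clustering on 1 - identity, cut at 1 - cut_identity.

    A cut above the maximum off-diagonal identity yields singletons, which
    is allowed.  Clades are renumbered by first appearance in input order.
    """
    if not 0.0 < cut_identity <= 1.0:
        raise ValueError("cut_identity must be in (0, 1]")
    Z, sorted_ids = _linkage(matrix, linkage)
    flat = hierarchy.fcluster(Z, t=1.0 - cut_identity, criterion="distance")
    raw = dict(zip(sorted_ids, (int(x) for x in flat)))
    renumber: dict[int, int] = {}
    clade_of: dict[str, int] = {}
    for iid in matrix.ids:
        r = raw[iid]
        if r not in renumber:
            renumber[r] = len(renumber) + 1
        clade_of[iid] = renumber[r]
    return CladeAssignment(
        ids=matrix.ids, clade_of=clade_of, linkage=linkage, cut_identity=cut_identity
    )


def species_check(
    matrix: IdentityMatrix, species_threshold: float = 0.95
) -> tuple[float, bool]:
    """Minimum off-diagonal identity and whether it clears the threshold."""
    m = matrix.min_off_diagonal()
    return m, m >= species_threshold


def dendrogram_newick(matrix: IdentityMatrix, linkage: str = "average") -> str:
    """Newick export of the identity dendrogram; branch lengths are
    differences of merge heights (1 - identity)."""
    Z, sorted_ids = _linkage(matrix, linkage)
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{sorted_ids[node.id]}:{length:.10g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:.10g}"

    if tree.is_leaf():
        return f"({sorted_ids[tree.id]}:0);"
    left = render(tree.left, tree.dist)
    right = render(tree.right, tree.dist)
    return f"({left},{right});"


# ---------------------------------------------------------------------------
# timelines
# ---------------------------------------------------------------------------

def clade_relative_abundance(
    assignment: CladeAssignment | Mapping[str, int],
    metadata: pd.DataFrame,
) -> CladeTimeline:
    """Per-time-point clade fractions from the isolate metadata table.

    ``metadata`` needs columns ``isolate_id`` and ``time_point``; time
    points keep their order of first appearance.  Clades never observed at
    a time point are reported as 0; time points with zero isolates are
    omitted with a notice.
    """
    clade_of = assignment.clade_of if isinstance(assignment, CladeAssignment) else dict(assignment)
    missing = [i for i in metadata["isolate_id"] if i not in clade_of]
    if missing:
        raise ValueError(f"isolates without clade assignment (e.g. {missing[0]!r})")

    tps = list(dict.fromkeys(str(t) for t in metadata["time_point"]))
    clades = sorted(set(clade_of[i] for i in metadata["isolate_id"]))
    counts = {}
    frac_rows = {}
    kept_tps = []
    for tp in tps:
        block = metadata[metadata["time_point"].astype(str) == tp]
        n = len(block)
        if n == 0:
            logger.info("time point %r has no isolates; omitted", tp)
            continue
        kept_tps.append(tp)
        counts[tp] = n
        labels = [clade_of[i] for i in block["isolate_id"]]
        frac_rows[tp] = {c: labels.count(c) / n for c in clades}

    fractions = pd.DataFrame.from_dict(frac_rows, orient="index", dtype=float)
    fractions = fractions.reindex(index=kept_tps, columns=clades).fillna(0.0)
    counts_series = pd.Series(counts, name="n_isolates").reindex(kept_tps)

    persistence_rows = []
    for c in clades:
        seen = [tp for tp in kept_tps if fractions.loc[tp, c] > 0]
        persistence_rows.append(
            {
                "clade": c,
                "first_seen": seen[0] if seen else None,
                "last_seen": seen[-1] if seen else None,
                "n_time_points": len(seen),
            }
        )
    persistence = pd.DataFrame(persistence_rows).set_index("clade")
    return CladeTimeline(
        time_points=tuple(kept_tps),
        fractions=fractions,
        counts=counts_series,
        persistence=persistence,
    )
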