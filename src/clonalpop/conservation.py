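"""Gene-conservation scoring from per-column Shannon entropy of protein alignments.

The central statistic is the per-gene conservation score: the Shannon
entropy of every alignment column, summed and divided by the alignment
length.  A fully conserved gene scores exactly 0; diversity at any column
raises the score.  Two-group comparisons (e.g. biosynthetic genes versus
housekeeping genes) are provided as Welch/Student t-tests and as exact or
Monte-Carlo permutation tests on the mean score difference.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinAlignment",
    "EntropyProfile",
    "GroupComparison",
    "translate_cds",
    "column_entropy",
    "gene_entropy_score",
    "compare_groups",
    "conservation_report",
]

#: residues ignored when counting column composition
_UNINFORMATIVE = frozenset("-X")

# Maximum number of distinct group relabelings enumerated exhaustively by
# the permutation test before falling back to Monte-Carlo sampling.
EXACT_PERMUTATION_LIMIT = 200_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ProteinAlignment:
    """An aligned set of protein sequences for one gene.

    Rows must be equal length; residues are amino-acid letters plus the
    gap character ``-``, the unknown character ``X`` and the stop ``*``.
    """

    gene: str
    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError(
                f"{self.gene}: {len(self.ids)} ids but {len(self.rows)} rows"
            )
        if len(set(self.ids)) != len(self.ids):
            raise ValueError(f"{self.gene}: duplicate sequence ids")
        if self.rows:
            L = len(self.rows[0])
            ragged = [i for i, r in zip(self.ids, self.rows) if len(r) != L]
            if ragged:
                raise ValueError(
                    f"{self.gene}: ragged alignment rows (e.g. {ragged[0]!r}); "
                    "supply pre-aligned sequences of equal length"
                )

    @property
    def length(self) -> int:
        """Number of alignment columns."""
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    def column(self, i: int) -> str:
        return "".join(row[i] for row in self.rows)


@dataclass(frozen=True)
class EntropyProfile:
    """Per-column entropies of one gene's alignment and the summary score.

    ``score`` equals ``sum(per_column) / L`` where ``L`` is the alignment
    length in columns.
    """

    gene: str
    per_column: tuple[float, ...]
    score: float
    n_sequences: int
    log_base: float

    def __post_init__(self) -> None:
        if self.per_column and any(h < 0 for h in self.per_column):
            raise ValueError(f"{self.gene}: negative column entropy")


@dataclass(frozen=True)
class GroupComparison:
    """Result of a two-group comparison of per-gene conservation scores."""

    target_scores: tuple[float, ...]
    reference_scores: tuple[float, ...]
    method: str
    alternative: str
    t_statistic: float
    df: float
    p_two_sided: float
    p_one_sided_greater: float
    p_permutation_two_sided: float | None = None
    p_permutation_greater: float | None = None
    n_permutations: int | None = None
    exact: bool | None = None
    degenerate: bool = False

    @property
    def p_permutation(self) -> float | None:
        """Permutation p-value for the requested alternative."""
        if self.alternative == "greater":
            return self.p_permutation_greater
        return self.p_permutation_two_sided


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

def _codon_maps(table: int) -> tuple[dict[str, str], frozenset[str], frozenset[str]]:
    tbl = CodonTable.unambiguous_dna_by_id[table]
    return dict(tbl.forward_table), frozenset(tbl.stop_codons), frozenset(tbl.start_codons)


def translate_cds(
    cds: str,
    table: int = 11,
    *,
    record_id: str | None = None,
    apply_start_rule: bool = False,
) -> str:
    """Translate a coding sequence to protein with the bacterial code.

    Codons containing ``N`` become ``X``.  A single trailing stop codon is
    trimmed; internal stop codons are emitted as ``*`` with a logged
    warning.  With ``apply_start_rule`` an alternative initiator codon
    (e.g. GTG, TTG under table 11) is translated as ``M``.
    """
    name = record_id or "<cds>"
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise ValueError(f"{name}: CDS length {len(seq)} is not a multiple of 3")
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"{name}: invalid nucleotide characters {sorted(bad)}")

    forward, stops, starts = _codon_maps(table)
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    if codons and codons[-1] in stops:
        codons = codons[:-1]

    residues: list[str] = []
    internal_stops = 0
    for i, codon in enumerate(codons):
        if "N" in codon:
            residues.append("X")
        elif codon in stops:
            residues.append("*")
            internal_stops += 1
        else:
            aa = forward[codon]
            if i == 0 and apply_start_rule and codon in starts:
                aa = "M"
            residues.append(aa)
    if internal_stops:
        logger.warning("%s: %d internal stop codon(s) translated as '*'", name, internal_stops)
    return "".join(residues)


# ---------------------------------------------------------------------------
# entropy
# ---------------------------------------------------------------------------

def column_entropy(column: Iterable[str], base: float = 2.0) -> float:
    """Shannon entropy of one alignment column.

    Gaps (``-``) and unknowns (``X``) are excluded from the counts; the
    denominator is the number of informative residues.  A column with no
    informative residue contributes 0.  An empty column is an error.
    """
    residues = list(column)
    if not residues:
        raise ValueError("empty alignment column")
    counts: dict[str, int] = {}
    for r in residues:
        if r in _UNINFORMATIVE:
            continue
        counts[r] = counts.get(r, 0) + 1
    total = sum(counts.values())
    if total == 0:
        return 0.0
    h = 0.0
    for c in counts.values():
        p = c / total
        h -= p * math.log(p)
    return h / math.log(base)


def gene_entropy_score(alignment: ProteinAlignment, base: float = 2.0) -> EntropyProfile:
    """Length-standardized summed per-column entropy of one gene.

    Invariant to row order and to duplicating the full row set.
    """
    if alignment.n_sequences < 2:
        raise ValueError(
            f"{alignment.gene}: need at least 2 sequences, got {alignment.n_sequences}"
        )
    L = alignment.length
    if L == 0:
        raise ValueError(f"{alignment.gene}: zero-length alignment")
    # column-wise counting on a byte matrix; rows are already equal length
    mat = np.frombuffer("".join(alignment.rows).encode("ascii"), dtype="S1").reshape(
        alignment.n_sequences, L
    )
    per_column = tuple(
        column_entropy(mat[:, j].tobytes().decode("ascii"), base=base) for j in range(L)
    )
    score = sum(per_column) / L
    return EntropyProfile(
        gene=alignment.gene,
        per_column=per_column,
        score=score,
        n_sequences=alignment.n_sequences,
        log_base=base,
    )


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

def _mean_diff(values: np.ndarray, idx: Sequence[int], n1: int) -> float:
    mask = np.zeros(len(values), dtype=bool)
    mask[list(idx)] = True
    return float(values[mask].mean() - values[~mask].mean())


def _permutation_pvalues(
    target: np.ndarray,
    reference: np.ndarray,
    *,
    force_mc: bool = False,
    n_mc: int = 20_000,
    seed: int | None = None,
) -> tuple[float, float, int, bool]:
    """Exact (or Monte-Carlo) permutation p-values of the mean difference.

    Returns (p_two_sided, p_greater, n_permutations, exact).  The exact
    test enumerates every C(n1+n2, n1) relabeling; the observed labeling is
    one of them, so p >= 1 / n_permutations.
    """
    pooled = np.concatenate([target, reference])
    n1 = len(target)
    n = len(pooled)
    observed = float(target.mean() - reference.mean())
    eps = 1e-12

    n_exact = math.comb(n, n1)
    if not force_mc and n_exact <= EXACT_PERMUTATION_LIMIT:
        ge = 0
        two = 0
        for idx in itertools.combinations(range(n), n1):
            stat = _mean_diff(pooled, idx, n1)
            if stat >= observed - eps:
                ge += 1
            if abs(stat) >= abs(observed) - eps:
                two += 1
        return two / n_exact, ge / n_exact, n_exact, True

    rng = np.random.default_rng(seed)
    ge = 0
    two = 0
    for _ in range(n_mc):
        perm = rng.permutation(n)
        stat = float(pooled[perm[:n1]].mean() - pooled[perm[n1:]].mean())
        if stat >= observed - eps:
            ge += 1
        if abs(stat) >= abs(observed) - eps:
            two += 1
    # add-one correction keeps Monte-Carlo p-values valid (never 0)
    return (two + 1) / (n_mc + 1), (ge + 1) / (n_mc + 1), n_mc, False


def compare_groups(
    target_scores: Sequence[float],
    reference_scores: Sequence[float],
    alternative: str = "greater",
    method: str = "welch",
    seed: int | None = None,
    n_mc: int = 20_000,
) -> GroupComparison:
    """Compare two lists of per-gene conservation scores.

    ``method`` selects the primary test: ``welch`` (default), ``student``,
    ``permutation_exact`` or ``permutation_mc``.  t-statistics are always
    reported; permutation p-values are computed for the permutation
    methods.  ``alternative='greater'`` tests target mean > reference mean.
    """
    if alternative not in ("two_sided", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    if method not in ("welch", "student", "permutation_exact", "permutation_mc"):
        raise ValueError(f"unknown method {method!r}")
    target = np.asarray(target_scores, dtype=float)
    reference = np.asarray(reference_scores, dtype=float)
    is_perm = method.startswith("permutation")
    min_n = 1 if is_perm else 2
    if len(target) < min_n or len(reference) < min_n:
        raise ValueError(
            f"each group needs >= {min_n} values for method {method!r} "
            f"(got {len(target)} and {len(reference)})"
        )

    equal_var = method == "student"
    # exact constancy check (std() suffers float cancellation on constants)
    degenerate = bool(
        np.ptp(target) == 0.0
        and np.ptp(reference) == 0.0
        and (len(target) == 0 or len(reference) == 0 or target[0] == reference[0])
    )
    if degenerate or (len(target) < 2 or len(reference) < 2):
        t_stat, df, p_two, p_greater = 0.0, float("nan"), 1.0, 1.0
        degenerate = True
    else:
        res = stats.ttest_ind(target, reference, equal_var=equal_var)
        t_stat = float(res.statistic)
        df = float(res.df)
        p_two = float(res.pvalue)
        res_g = stats.ttest_ind(target, reference, equal_var=equal_var, alternative="greater")
        p_greater = float(res_g.pvalue)
        if math.isnan(t_stat):
            # zero variance in both groups with equal means
            t_stat, p_two, p_greater, degenerate = 0.0, 1.0, 1.0, True

    p_perm_two = p_perm_greater = None
    n_perm = exact = None
    if is_perm:
        p_perm_two, p_perm_greater, n_perm, exact = _permutation_pvalues(
            target,
            reference,
            force_mc=(method == "permutation_mc"),
            n_mc=n_mc,
            seed=seed,
        )

    return GroupComparison(
        target_scores=tuple(float(x) for x in target),
        reference_scores=tuple(float(x) for x in reference),
        method=method,
        alternative=alternative,
        t_statistic=t_stat,
        df=df,
        p_two_sided=p_two,
        p_one_sided_greater=p_greater,
        p_permutation_two_sided=p_perm_two,
        p_permutation_greater=p_perm_greater,
        n_permutations=n_perm,
        exact=exact,
        degenerate=degenerate,
    )


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

def conservation_report(
    alignments: Mapping[str, ProteinAlignment],
    group_map: Mapping[str, str],
    *,
    base: float = 2.0,
    method: str = "welch",
    alternative: str = "greater",
    seed: int | None = None,
) -> tuple[pd.DataFrame, GroupComparison | None, dict[str, EntropyProfile]]:
    """Score every gene and compare the target group against the reference.

    ``group_map`` assigns each gene to ``target``, ``reference`` or
    ``other``.  Genes with fewer than 2 sequences are excluded with a
    logged warning.  Rows are ordered by (group, gene) so repeated runs on
    identical input are byte-identical when serialized.
    """
    valid_groups = {"target", "reference", "other"}
    for gene in alignments:
        grp = group_map.get(gene)
        if grp is None:
            raise ValueError(f"gene {gene!r} missing from the group map")
        if grp not in valid_groups:
            raise ValueError(f"gene {gene!r} has unknown group {grp!r}")

    profiles: dict[str, EntropyProfile] = {}
    rows = []
    for gene in sorted(alignments):
        aln = alignments[gene]
        if aln.n_sequences < 2:
            logger.warning("gene %s excluded: only %d sequence(s)", gene, aln.n_sequences)
            continue
        prof = gene_entropy_score(aln, base=base)
        profiles[gene] = prof
        rows.append(
            {
                "gene": gene,
                "group": group_map[gene],
                "n_sequences": prof.n_sequences,
                "length": aln.length,
                "score": prof.score,
            }
        )
    table = pd.DataFrame(rows, columns=["gene", "group", "n_sequences", "length", "score"])
    table = table.sort_values(["group", "gene"], kind="mergesort").reset_index(drop=True)

    target = table.loc[table["group"] == "target", "score"].tolist()
    reference = table.loc[table["group"] == "reference", "score"].tolist()
    comparison = None
    min_n = 1 if method.startswith("permutation") else 2
    if len(target) >= min_n and len(reference) >= min_n:
        comparison = compare_groups(
            target, reference, alternative=alternative, method=method, seed=seed
        )
    else:
        logger.warning(
            "group comparison skipped: %d target and %d reference genes", len(target), len(reference)
        )
    return table, comparison, profiles
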