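import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from clonalpop.conservation import (
    ProteinAlignment,
    column_entropy,
    compare_groups,
    conservation_report,
    gene_entropy_score,
    translate_cds,
)


def naive_score(rows, base=2.0):
    """Independent count-and-sum oracle for the entropy score."""
    L = len(rows[0])
    total = 0.0
    for j in range(L):
        column = [r[j] for r in rows]
        informative = [c for c in column if c not in "-X"]
        n = len(informative)
        if n == 0:
            continue
        h = 0.0
        for residue in set(informative):
            p = informative.count(residue) / n
            h -= p * math.log(p, base)
        total += h
    return total / L


# ---------------------------------------------------------------------------
# translation
# ---------------------------------------------------------------------------

class TestTranslateCds:
    def test_standard_codons(self):
        assert translate_cds("ATGAAA") == "MK"

    def test_trailing_stop_trimmed(self):
        assert translate_cds("ATGAAATAA") == "MK"

    def test_alternative_start_rule(self):
        assert translate_cds("GTGGCC", apply_start_rule=True) == "MA"
        assert translate_cds("GTGGCC") == "VA"

    def test_n_codon_becomes_x(self):
        assert translate_cds("ATGANA") == "MX"

    def test_internal_stop_emitted_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="clonalpop.conservation"):
            assert translate_cds("ATGTAAAAA", record_id="g1") == "M*K"
        assert any("internal stop" in m for m in caplog.messages)

    def test_length_error_names_record(self):
        with pytest.raises(ValueError, match="rec7"):
            translate_cds("ATGAA", record_id="rec7")

    def test_invalid_characters(self):
        with pytest.raises(ValueError, match="invalid nucleotide"):
            translate_cds("ATGAAR")


# ---------------------------------------------------------------------------
# column entropy
# ---------------------------------------------------------------------------

class TestColumnEntropy:
    def test_single_residue_zero(self):
        assert column_entropy("AAAAA") == 0.0

    def test_symmetric_two_state_one_bit(self):
        assert column_entropy("AAVV") == pytest.approx(1.0, abs=1e-12)

    def test_uniform_four_two_bits(self):
        assert column_entropy("AVLI") == pytest.approx(2.0, abs=1e-12)

    def test_111_to_1_hand_formula(self):
        expected = -(111 / 112 * math.log2(111 / 112) + 1 / 112 * math.log2(1 / 112))
        assert column_entropy("A" * 111 + "V") == pytest.approx(expected, abs=1e-12)

    def test_empty_column_error(self):
        with pytest.raises(ValueError, match="empty"):
            column_entropy("")

    def test_gaps_and_x_excluded(self):
        assert column_entropy("AA--XX") == 0.0
        assert column_entropy("AV--") == pytest.approx(1.0, abs=1e-12)

    def test_all_gap_column_contributes_zero(self):
        assert column_entropy("----") == 0.0

    def test_natural_log_base(self):
        assert column_entropy("AV", base=math.e) == pytest.approx(math.log(2), abs=1e-12)

    def test_stop_symbol_participates(self):
        assert column_entropy("A*") == pytest.approx(1.0, abs=1e-12)


# ---------------------------------------------------------------------------
# gene score
# ---------------------------------------------------------------------------

def aln(rows, gene="g"):
    return ProteinAlignment(gene=gene, ids=tuple(f"s{i}" for i in range(len(rows))), rows=tuple(rows))


class TestGeneEntropyScore:
    def test_identical_rows_score_zero(self):
        profile = gene_entropy_score(aln(["MKLV" * 75] * 112))
        assert profile.score == 0.0
        assert len(profile.per_column) == 300

    def test_one_split_column_in_ten(self):
        rows = ["AAAAAAAAAA"] * 56 + ["AAAAAAAAAV"] * 56
        profile = gene_entropy_score(aln(rows))
        assert profile.score == pytest.approx(0.1, abs=1e-12)

    def test_score_equals_sum_over_length(self):
        rows = ["MKV", "MAV", "MKI"]
        profile = gene_entropy_score(aln(rows))
        assert profile.score == pytest.approx(sum(profile.per_column) / 3, abs=0)

    def test_row_order_invariance(self):
        rows = ["MKVA", "MAVL", "MKIA", "MKIA"]
        s1 = gene_entropy_score(aln(rows)).score
        s2 = gene_entropy_score(aln(rows[::-1])).score
        assert s1 == s2

    def test_duplication_invariance(self):
        rows = ["MKVA", "MAVL", "MKIA"]
        s1 = gene_entropy_score(aln(rows)).score
        s3 = gene_entropy_score(aln(rows * 3)).score
        assert s1 == pytest.approx(s3, abs=1e-12)

    def test_added_divergent_residue_increases_entropy(self):
        base = ["MKVA"] * 5
        h0 = gene_entropy_score(aln(base)).per_column[0]
        h1 = gene_entropy_score(aln(base + ["WKVA"])).per_column[0]
        assert h1 > h0

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError, match="at least 2"):
            gene_entropy_score(aln(["MKV"]))

    def test_ragged_rows_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            aln(["MKV", "MK"])

    def test_entropy_bounds(self, rng):
        residues = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(20):
            n = int(rng.integers(2, 30))
            L = int(rng.integers(1, 15))
            rows = ["".join(rng.choice(residues, size=L)) for _ in range(n)]
            profile = gene_entropy_score(aln(rows))
            bound = math.log2(min(21, n))
            assert all(0.0 <= h <= bound + 1e-12 for h in profile.per_column)

    def test_matches_naive_oracle_small_random(self, rng):
        residues = np.array(list("ACDEFGHIKL-X*"))
        for _ in range(100):
            n = int(rng.integers(2, 6))
            L = int(rng.integers(1, 7))
            rows = ["".join(rng.choice(residues, size=L)) for _ in range(n)]
            assert gene_entropy_score(aln(rows)).score == pytest.approx(
                naive_score(rows), abs=1e-12
            )


@settings(max_examples=50, deadline=None)
@given(
    st.lists(
        st.text(alphabet="ACDG-", min_size=4, max_size=4), min_size=2, max_size=6
    ),
    st.permutations(range(6)),
)
def test_property_row_permutation_invariance(rows, perm):
    permuted = [rows[i] for i in [p for p in perm if p < len(rows)]]
    if sorted(permuted) != sorted(rows):
        permuted = rows[::-1]
    s1 = gene_entropy_score(aln(rows)).score
    s2 = gene_entropy_score(aln(permuted, gene="g2")).score
    assert s1 == pytest.approx(s2, abs=1e-12)


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------

class TestCompareGroups:
    def test_identical_constant_groups_permutation_p_one(self):
        res = compare_groups([0.1, 0.1, 0.1], [0.1, 0.1, 0.1], method="permutation_exact")
        assert res.p_permutation_greater == 1.0
        assert res.p_permutation_two_sided == 1.0
        assert res.degenerate

    def test_exact_permutation_oracle_one_in_twenty(self):
        res = compare_groups([2, 3, 4], [0, 0, 0], alternative="greater", method="permutation_exact")
        assert res.n_permutations == 20
        assert res.exact is True
        assert res.p_permutation_greater == pytest.approx(1 / 20, abs=0)

    def test_permutation_p_at_least_one_over_partitions(self, rng):
        for _ in range(10):
            a = list(rng.normal(size=4))
            b = list(rng.normal(size=3))
            res = compare_groups(a, b, method="permutation_exact")
            assert res.p_permutation_greater >= 1 / res.n_permutations
            assert res.p_permutation_two_sided >= 1 / res.n_permutations

    def test_welch_matches_scipy(self):
        from scipy import stats

        a, b = [0.2, 0.5, 0.9, 0.4], [0.1, 0.15, 0.2]
        res = compare_groups(a, b, method="welch")
        ref = stats.ttest_ind(a, b, equal_var=False)
        assert res.t_statistic == pytest.approx(ref.statistic)
        assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_student_matches_scipy(self):
        from scipy import stats

        a, b = [0.2, 0.5, 0.9], [0.1, 0.15, 0.2]
        res = compare_groups(a, b, method="student")
        ref = stats.ttest_ind(a, b, equal_var=True)
        assert res.t_statistic == pytest.approx(ref.statistic)

    def test_zero_variance_equal_means_flagged(self):
        res = compare_groups([1.0, 1.0], [1.0, 1.0], method="welch")
        assert res.degenerate
        assert res.p_two_sided == 1.0
        assert not math.isnan(res.t_statistic)

    def test_monte_carlo_deterministic_under_seed(self):
        a, b = [2.0, 3.0, 4.0], [0.0, 0.5, 1.0]
        r1 = compare_groups(a, b, method="permutation_mc", seed=7, n_mc=2000)
        r2 = compare_groups(a, b, method="permutation_mc", seed=7, n_mc=2000)
        assert r1.p_permutation_greater == r2.p_permutation_greater
        assert r1.exact is False

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            compare_groups([1, 2], [3, 4], method="bootstrap")

    def test_group_size_preconditions(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_groups([1.0], [2.0, 3.0], method="welch")
        # permutation allows single-value groups
        res = compare_groups([5.0], [0.0, 0.1], method="permutation_exact")
        assert res.p_permutation_greater == pytest.approx(1 / 3)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

class TestConservationReport:
    def make_alignments(self):
        return {
            "b1": aln(["MKV", "MAV", "MKV"], "b1"),
            "b2": aln(["MKV", "MKI", "MAV"], "b2"),
            "h1": aln(["MKV", "MKV", "MKV"], "h1"),
            "h2": aln(["MKV", "MKV", "MKI"], "h2"),
        }

    def groups(self):
        return {"b1": "target", "b2": "target", "h1": "reference", "h2": "reference"}

    def test_rows_ordered_and_tagged(self):
        table, comparison, profiles = conservation_report(self.make_alignments(), self.groups())
        assert list(table["gene"]) == ["h1", "h2", "b1", "b2"]
        assert list(table["group"]) == ["reference", "reference", "target", "target"]
        assert comparison is not None

    def test_deterministic_tsv(self, tmp_path):
        out = []
        for _ in range(2):
            table, _, _ = conservation_report(self.make_alignments(), self.groups())
            path = tmp_path / "report.tsv"
            table.to_csv(path, sep="\t", index=False, float_format="%.10g")
            out.append(path.read_bytes())
        assert out[0] == out[1]

    def test_small_gene_excluded_with_warning(self, caplog):
        alignments = self.make_alignments()
        alignments["tiny"] = ProteinAlignment("tiny", ("s0",), ("MKV",))
        groups = {**self.groups(), "tiny": "other"}
        with caplog.at_level("WARNING", logger="clonalpop.conservation"):
            table, _, _ = conservation_report(alignments, groups)
        assert "tiny" not in set(table["gene"])
        assert any("excluded" in m for m in caplog.messages)

    def test_missing_group_rejected(self):
        with pytest.raises(ValueError, match="group map"):
            conservation_report(self.make_alignments(), {"b1": "target"})

    def test_unknown_group_rejected(self):
        groups = {**self.groups(), "b1": "blue"}
        with pytest.raises(ValueError, match="unknown group"):
            conservation_report(self.make_alignments(), groups)
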