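"""Diversity statistics against independent oracles and invariances."""

import math

import numpy as np
import pytest

from conftest import random_alignment
from haplodrift.alignment import alignment_from_strings
from haplodrift.stats import (
    TajimaConstants,
    diversity_stats,
    nucleotide_diversity,
    segregating_sites,
    tajima_significance,
    tajimas_d,
    tajimas_d_from_summary,
    watterson_theta,
)

VALID = {b"A", b"C", b"G", b"T"}


# ---------------------------------------------------------------- oracles
def brute_force_pi(aln):
    """pi by an explicit double loop over all pairs and all columns."""
    matrix = aln.matrix
    n, L = matrix.shape
    keep = [c for c in range(L) if all(matrix[i, c] in VALID for i in range(n))]
    total = 0
    for i in range(n):
        for j in range(i + 1, n):
            total += sum(1 for c in keep if matrix[i, c] != matrix[j, c])
    pairs = n * (n - 1) / 2
    return total / (pairs * len(keep))


def brute_force_S(aln):
    matrix = aln.matrix
    n, L = matrix.shape
    count = 0
    for c in range(L):
        col = [matrix[i, c] for i in range(n)]
        if all(b in VALID for b in col) and len(set(col)) > 1:
            count += 1
    return count


def direct_constant_tajima(aln):
    """Tajima's D evaluated symbol-by-symbol in a separate code path."""
    matrix = aln.matrix
    n, L = matrix.shape
    S = brute_force_S(aln)
    if n < 4 or S == 0:
        return float("nan")
    keep = [c for c in range(L) if all(matrix[i, c] in VALID for i in range(n))]
    k_total = 0
    for i in range(n):
        for j in range(i + 1, n):
            k_total += sum(1 for c in keep if matrix[i, c] != matrix[j, c])
    k = k_total / (n * (n - 1) / 2)
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return (k - S / a1) / math.sqrt(e1 * S + e2 * S * (S - 1))


# ------------------------------------------------------------ unit checks
class TestSegregatingSites:
    def test_identical_sequences(self):
        aln = alignment_from_strings(["ACGT"] * 3)
        assert segregating_sites(aln) == 0

    def test_triallelic_column_counts_once(self):
        aln = alignment_from_strings(["AAGT", "ACGT", "ATGA"])
        # column 2 triallelic (A/C/T), column 4 biallelic (T/A)
        assert segregating_sites(aln) == 2

    def test_requires_two_sequences(self):
        with pytest.raises(ValueError):
            segregating_sites(alignment_from_strings(["ACGT"]))


class TestNucleotideDiversity:
    def test_identical_sequences_zero(self):
        pi, sd = nucleotide_diversity(alignment_from_strings(["ACGT" * 10] * 4))
        assert pi == 0.0 and sd == 0.0

    def test_single_difference_pair(self):
        seq = "A" * 100
        other = "C" + "A" * 99
        pi, _ = nucleotide_diversity(alignment_from_strings([seq, other]))
        assert pi == pytest.approx(0.01)

    def test_sd_positive_when_variable(self):
        _, sd = nucleotide_diversity(alignment_from_strings(["AAAA", "AAAC", "AACC"]))
        assert sd > 0


class TestWattersonTheta:
    def test_direct_formula_n2(self):
        # n=2 -> a1=1; 3 differences over 100 sites
        seqs = ["A" * 100, "CCC" + "A" * 97]
        assert watterson_theta(alignment_from_strings(seqs)) == pytest.approx(0.03)

    def test_zero_when_monomorphic(self):
        assert watterson_theta(alignment_from_strings(["ACGT"] * 5)) == 0.0

    def test_integer_recovery(self):
        """theta_w * a1 * L recovers S exactly on gap-free alignments."""
        rng = np.random.default_rng(7)
        for _ in range(20):
            aln = random_alignment(rng)
            S = segregating_sites(aln)
            theta = watterson_theta(aln)
            a1 = TajimaConstants.from_n(aln.n).a1
            assert round(theta * a1 * aln.L) == S


class TestTajimasD:
    def test_undefined_cases_are_nan(self):
        assert math.isnan(tajimas_d(alignment_from_strings(["ACGT"] * 5)))
        aln3 = alignment_from_strings(["AAGT", "ACGT", "ATGA"])
        assert math.isnan(tajimas_d(aln3))  # n = 3 < 4

    def test_matches_direct_constant_oracle(self):
        """Main implementation vs the symbol-by-symbol oracle, 100 random
        small alignments, 1e-9."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(100):
            aln = random_alignment(rng)
            expected = direct_constant_tajima(aln)
            got = tajimas_d(aln)
            if math.isnan(expected):
                assert math.isnan(got)
            else:
                assert got == pytest.approx(expected, abs=1e-9)
                checked += 1
        assert checked >= 90  # random ACGT alignments are almost surely variable

    def test_independent_of_analyzed_length(self):
        """D depends only on (n, S, k): padding with monomorphic columns
        changes L but not D."""
        aln = alignment_from_strings(["ACGTAA", "ACGTAC", "AAGTAC", "ACTTAC"])
        padded = alignment_from_strings(
            [s + "G" * 50 for s in ["ACGTAA", "ACGTAC", "AAGTAC", "ACTTAC"]]
        )
        assert tajimas_d(padded) == pytest.approx(tajimas_d(aln), abs=1e-12)


class TestInvariances:
    def test_pi_matches_brute_force(self):
        rng = np.random.default_rng(99)
        for _ in range(100):
            aln = random_alignment(rng, n=int(rng.integers(2, 11)), L=int(rng.integers(5, 51)))
            pi, _ = nucleotide_diversity(aln)
            assert pi == pytest.approx(brute_force_pi(aln), abs=1e-12)

    def test_statistics_invariant_under_row_permutation(self):
        rng = np.random.default_rng(5)
        aln = random_alignment(rng, n=6, L=30)
        perm = aln.subset(list(np.array(aln.sample_ids)[rng.permutation(6)]))
        assert segregating_sites(perm) == segregating_sites(aln)
        assert nucleotide_diversity(perm)[0] == pytest.approx(
            nucleotide_diversity(aln)[0]
        )
        d1, d2 = tajimas_d(aln), tajimas_d(perm)
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_statistics_invariant_under_state_relabeling(self):
        rng = np.random.default_rng(6)
        aln = random_alignment(rng, n=5, L=40)
        swap = {b"A": b"G", b"G": b"A", b"C": b"T", b"T": b"C"}
        relabeled = alignment_from_strings(
            [
                b"".join(swap[bytes(b)] for b in row).decode()
                for row in aln.matrix
            ]
        )
        assert segregating_sites(relabeled) == segregating_sites(aln)
        assert nucleotide_diversity(relabeled)[0] == pytest.approx(
            nucleotide_diversity(aln)[0]
        )


class TestSignificance:
    def test_zero_is_never_significant(self):
        assert tajima_significance(0.0, 10) is False

    def test_undefined_d_returns_none(self):
        assert tajima_significance(float("nan"), 10) is None

    @pytest.mark.parametrize(
        "d, n, expected",
        [
            (-1.93676, 26, True),   # strongly negative, starred
            (-1.04304, 13, False),  # moderate, unstarred
            (-1.25619, 14, False),
            (-1.82472, 40, True),
            (-2.08002, 103, True),
        ],
    )
    def test_starring_pattern(self, d, n, expected):
        """Beta-approximation null reproduces the published starring."""
        assert tajima_significance(d, n) is expected


class TestSummaryRoute:
    def test_from_summary_agrees_with_alignment_route(self, toy_alignment):
        from haplodrift.stats import _total_pairwise_differences

        clean = toy_alignment.complete_deletion()
        S = segregating_sites(clean)
        pairs = clean.n * (clean.n - 1) // 2
        k = _total_pairwise_differences(clean.matrix) / pairs
        assert tajimas_d_from_summary(clean.n, S, k) == pytest.approx(
            tajimas_d(toy_alignment), abs=1e-12
        )


class TestDiversityStatsRow:
    def test_row_is_consistent(self, toy_alignment):
        row = diversity_stats(toy_alignment, group="toy")
        assert row.n == 4 and row.L == 12
        assert row.S == segregating_sites(toy_alignment)
        a1 = TajimaConstants.from_n(4).a1
        assert row.theta_w == pytest.approx(row.S / (a1 * row.L))
        assert row.significant in (True, False)
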