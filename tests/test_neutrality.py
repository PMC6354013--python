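"""Neutrality statistics against independent brute-force oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flaxpop.io import HaplotypeAlignment
from flaxpop.neutrality import (
    TwoLocusCounts,
    collapse_alleles,
    diversity_stats,
    fu_li_star,
    ld_r,
    neutrality_report,
    ramos_onsins_r2,
    tajimas_d,
)

from conftest import FIXTURE_EXPECTED


# ---------------------------------------------------------------------------
# independent direct-formula oracle: literal transcription of the published
# definitions using brute-force pairwise counting, no code shared with the
# implementation under test
# ---------------------------------------------------------------------------


def oracle_stats(rows):
    mat = np.array([list(s) for s in rows])
    n, L = mat.shape
    pi = np.mean(
        [(mat[i] != mat[j]).sum() for i, j in itertools.combinations(range(n), 2)]
    )
    S = sum(len(set(mat[:, j])) > 1 for j in range(L))
    eta_s = 0
    u = np.zeros(n)
    for j in range(L):
        col = mat[:, j]
        if len(set(col)) < 2:
            continue
        for a in set(col):
            if (col == a).sum() == 1:
                eta_s += 1
                u[np.argmax(col == a)] += 1
    return n, L, S, float(pi), eta_s, u


def oracle_tajima(rows):
    n, _, S, pi, _, _ = oracle_stats(rows)
    if S == 0:
        return float("nan")
    a1 = sum(1 / i for i in range(1, n))
    a2 = sum(1 / i**2 for i in range(1, n))
    b1 = (n + 1) / (3 * (n - 1))
    b2 = 2 * (n**2 + n + 3) / (9 * n * (n - 1))
    c1 = b1 - 1 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    return (pi - S / a1) / math.sqrt(c1 / a1 * S + c2 / (a1**2 + a2) * S * (S - 1))


def oracle_fu_li_star(rows):
    n, _, S, pi, eta_s, _ = oracle_stats(rows)
    if S == 0 or n < 3:
        return float("nan"), float("nan")
    a = sum(1 / i for i in range(1, n))
    b = sum(1 / i**2 for i in range(1, n))
    anext = a + 1 / n
    c = 2 * (n * a - 2 * (n - 1)) / ((n - 1) * (n - 2))
    d = c + (n - 2) / (n - 1) ** 2 + 2 / (n - 1) * (
        1.5 - (2 * anext - 3) / (n - 2) - 1 / n
    )
    vD = ((n / (n - 1)) ** 2 * b + a**2 * d - 2 * n * a * (a + 1) / (n - 1) ** 2) / (
        a**2 + b
    )
    uD = n / (n - 1) * (a - n / (n - 1)) - vD
    d_star = ((n / (n - 1)) * S - a * eta_s) / math.sqrt(uD * S + vD * S**2)
    vF = (
        (2 * n**3 + 110 * n**2 - 255 * n + 153) / (9 * n**2 * (n - 1))
        + 2 * (n - 1) * a / n**2
        - 8 * b / n
    ) / (a**2 + b)
    uF = ((4 * n**2 + 19 * n + 3 - 12 * (n + 1) * anext) / (3 * n * (n - 1))) / a - vF
    f_star = (pi - (n - 1) / n * eta_s) / math.sqrt(uF * S + vF * S**2)
    return d_star, f_star


def oracle_r2(rows):
    n, _, S, pi, _, u = oracle_stats(rows)
    if S == 0:
        return float("nan")
    return math.sqrt(np.mean((u - pi / 2) ** 2)) / S


def random_alignment(rng, n=None, sites=20):
    n = n or int(rng.integers(4, 11))
    mat = rng.choice(list("ACGT"), size=(n, sites), p=[0.7, 0.1, 0.1, 0.1])
    return HaplotypeAlignment((f"h{i}", "".join(row)) for i, row in enumerate(mat))


# ---------------------------------------------------------------------------


class TestCollapseAlleles:
    def test_identical_sequences_one_allele(self):
        aln = HaplotypeAlignment([("a", "ACGT"), ("b", "ACGT"), ("c", "ACGT")])
        groups = collapse_alleles(aln)
        assert len(groups) == 1 and len(groups[0][1]) == 3

    def test_all_distinct(self):
        aln = HaplotypeAlignment([("a", "ACGT"), ("b", "ACGA"), ("c", "ACGG")])
        assert len(collapse_alleles(aln)) == 3

    def test_n_masking_recovers_templates(self, rng):
        templates = ["AAAAAAAA", "AAAATTTT", "TTTTAAAA", "TTTTTTTT"]
        recs = []
        for i in range(10):
            t = list(templates[i % 4])
            for j in rng.choice(8, size=2, replace=False):
                t[j] = "N"
            recs.append((f"h{i}", "".join(t)))
        groups = collapse_alleles(HaplotypeAlignment(recs))
        # brute-force check: compatible pairs (ignoring N) land together
        assert len(groups) == 4
        member_of = {m: g for g, (_, ms) in enumerate(groups) for m in ms}
        for (id_a, seq_a), (id_b, seq_b) in itertools.combinations(recs, 2):
            same_template = (int(id_a[1:]) % 4) == (int(id_b[1:]) % 4)
            assert (member_of[id_a] == member_of[id_b]) == same_template

    def test_ordering_by_size(self):
        aln = HaplotypeAlignment(
            [("a", "AAAA"), ("b", "TTTT"), ("c", "TTTT"), ("d", "TTTT")]
        )
        groups = collapse_alleles(aln)
        assert groups[0][1] == ["b", "c", "d"]


class TestNeutralityStatistics:
    def test_invariant_alignment_undefined_not_zero(self):
        aln = HaplotypeAlignment([("a", "AAAA"), ("b", "AAAA"), ("c", "AAAA")])
        assert math.isnan(tajimas_d(aln))
        assert all(math.isnan(v) for v in fu_li_star(aln))
        assert math.isnan(ramos_onsins_r2(aln))

    def test_tajima_zero_at_n2(self):
        aln = HaplotypeAlignment([("a", "AAAA"), ("b", "TTAA")])
        assert tajimas_d(aln) == pytest.approx(0.0, abs=1e-12)

    def test_fixture_values(self, toy_alignment):
        assert tajimas_d(toy_alignment) == pytest.approx(
            FIXTURE_EXPECTED["tajima_d"], abs=1e-12
        )
        d_star, f_star = fu_li_star(toy_alignment)
        assert d_star == pytest.approx(FIXTURE_EXPECTED["fu_li_d_star"], abs=1e-12)
        assert f_star == pytest.approx(FIXTURE_EXPECTED["fu_li_f_star"], abs=1e-12)
        assert ramos_onsins_r2(toy_alignment) == pytest.approx(
            FIXTURE_EXPECTED["r2"], abs=1e-12
        )
        stats = diversity_stats(toy_alignment)
        assert (stats.S, stats.singletons) == (5, 2)
        assert stats.pi == pytest.approx(7 / 3)
        assert stats.theta_w == pytest.approx(5 / sum(1 / i for i in range(1, 6)))

    def test_fixture_matches_dendropy_tajima(self, toy_alignment):
        dendropy = pytest.importorskip("dendropy")
        from dendropy.calculate import popgenstat

        dna = dendropy.DnaCharacterMatrix.from_dict(dict(toy_alignment.records))
        assert tajimas_d(toy_alignment) == pytest.approx(
            popgenstat.tajimas_d(dna), abs=1e-9
        )

    def test_all_singletons_negative_d_star(self):
        # 10 sequences, every mutation carried by exactly one sequence
        recs = [("h0", "A" * 9)]
        for i in range(9):
            seq = ["A"] * 9
            seq[i] = "T"
            recs.append((f"h{i+1}", "".join(seq)))
        d_star, _ = fu_li_star(HaplotypeAlignment(recs[:10]))
        assert d_star < 0

    def test_r2_closed_form_n2(self):
        # n=2, S=4: both sequences carry 4 singletons, k = 4
        aln = HaplotypeAlignment([("a", "AAAA"), ("b", "TTTT")])
        # R2 = sqrt(((4-2)^2 + (4-2)^2)/2) / 4 = 0.5
        assert ramos_onsins_r2(aln) == pytest.approx(0.5, abs=1e-12)

    def test_agreement_with_oracle_on_random_alignments(self, rng):
        for _ in range(100):
            aln = random_alignment(rng)
            rows = [seq for _, seq in aln.records]
            assert tajimas_d(aln) == pytest.approx(oracle_tajima(rows), abs=1e-9)
            od, of = oracle_fu_li_star(rows)
            d_star, f_star = fu_li_star(aln)
            assert d_star == pytest.approx(od, abs=1e-9)
            assert f_star == pytest.approx(of, abs=1e-9)
            assert ramos_onsins_r2(aln) == pytest.approx(oracle_r2(rows), abs=1e-9)

    def test_complete_deletion_of_gap_columns(self):
        with_gaps = HaplotypeAlignment(
            [("a", "A-AAT"), ("b", "ANTAT"), ("c", "AATAA")]
        )
        without = HaplotypeAlignment([("a", "AAT"), ("b", "AAT"), ("c", "TAA")])
        assert diversity_stats(with_gaps).S == diversity_stats(without).S

    def test_report_composes_individual_statistics(self, toy_alignment):
        row = neutrality_report(toy_alignment)
        assert row["tajima_d"] == tajimas_d(toy_alignment)
        assert row["r2"] == ramos_onsins_r2(toy_alignment)
        assert row["haplotype_count"] == len(collapse_alleles(toy_alignment))


class TestLdR:
    def test_complete_coupling(self):
        assert ld_r(TwoLocusCounts(0.5, 0.0, 0.0, 0.5)) == pytest.approx(1.0)

    def test_independence(self):
        # joint = product of marginals with p1 = 0.4, p2 = 0.3
        c = TwoLocusCounts(0.12, 0.28, 0.18, 0.42)
        assert ld_r(c) == pytest.approx(0.0, abs=1e-12)

    def test_printed_formula_example(self):
        assert ld_r(TwoLocusCounts(0.4, 0.1, 0.1, 0.4)) == pytest.approx(0.6)

    def test_monomorphic_locus_undefined(self):
        assert math.isnan(ld_r(TwoLocusCounts(0.6, 0.4, 0.0, 0.0)))

    @given(
        st.tuples(
            st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1), st.floats(0.01, 1)
        )
    )
    @settings(max_examples=200, deadline=None)
    def test_bounded_and_sign_flips_on_label_swap(self, raw):
        total = sum(raw)
        c = TwoLocusCounts(*(v / total for v in raw))
        r = ld_r(c)
        assert -1.0 - 1e-12 <= r <= 1.0 + 1e-12
        assert ld_r(c.swap_locus1()) == pytest.approx(-r, abs=1e-9)

    def test_numerator_equals_classical_d(self):
        c = TwoLocusCounts(0.4, 0.1, 0.1, 0.4)
        d_products = c.j11 * c.j22 - c.j12 * c.j21
        d_classic = c.j11 - c.p1 * c.p2
        assert d_products == pytest.approx(d_classic, abs=1e-12)
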