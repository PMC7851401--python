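"""Scoring and trio QC: matching, filters, HWE exact test, inheritance."""

import itertools
import math

import numpy as np
import pytest

from joindel.evaluate import (
    TrioGenotypes,
    de_novo_candidates,
    expected_de_novo,
    filter_calls,
    genotype_matrix,
    hwe_exact_pvalue,
    hwe_filter,
    match_callsets,
    mendelian_consistent,
    mendelian_error_rate,
    parse_bed,
    reciprocal_overlap,
    transmission_rate,
)
from joindel.vcfout import DeletionCall, SampleCall


class TestReciprocalOverlap:
    def test_half_overlap(self):
        assert reciprocal_overlap(("c", 100, 200), ("c", 150, 250)) == 0.5

    def test_identical(self):
        assert reciprocal_overlap(("c", 5, 50), ("c", 5, 50)) == 1.0

    def test_disjoint_and_cross_contig(self):
        assert reciprocal_overlap(("c", 0, 10), ("c", 10, 20)) == 0.0
        assert reciprocal_overlap(("c1", 0, 10), ("c2", 0, 10)) == 0.0

    def test_asymmetric_sizes_take_min(self):
        # [0,100) vs [0,400): intersection 100 -> min(1.0, 0.25)
        assert reciprocal_overlap(("c", 0, 100), ("c", 0, 400)) == 0.25


class TestMatchCallsets:
    def test_self_match_is_perfect(self):
        ivs = [("c", 0, 100), ("c", 500, 900)]
        res = match_callsets(ivs, ivs)
        assert res.recall == 1.0 and res.precision == 1.0 and res.f1 == 1.0

    def test_one_to_one_constraint(self):
        truth = [("c", 0, 1000)]
        calls = [("c", 0, 1000), ("c", 10, 1010)]
        res = match_callsets(calls, truth)
        assert res.recall == 1.0
        assert res.precision == 0.5  # second call is a false positive

    def test_threshold_rule(self):
        truth = [("c", 0, 1000)]
        barely = [("c", 508, 1508)]  # reciprocal overlap 492/1000 < 0.5
        res = match_callsets(barely, truth)
        assert res.recall == 0.0 and res.precision == 0.0
        ok = [("c", 490, 1490)]
        assert match_callsets(ok, truth).recall == 1.0


def _call(start, length, gts=("0/1",), gq=60, contig="c"):
    samples = [
        SampleCall((0, 0, 0), g, gq, genotyped=g != "./.") for g in gts
    ]
    return DeletionCall(contig, start, length, samples, af=0.1)


class TestFilterCalls:
    def test_size_rule(self):
        calls = [_call(0, 400), _call(0, 500), _call(0, 10_000), _call(0, 10_001)]
        out = filter_calls(calls)
        assert [c.length for c in out] == [500, 10_000]

    def test_any_overlap_with_exclude_region_removes(self):
        calls = [_call(1000, 600)]
        assert filter_calls(calls, exclude_regions=[("c", 1599, 2000)]) == []
        assert len(filter_calls(calls, exclude_regions=[("c", 1600, 2000)])) == 1

    def test_include_regions_require_containment(self):
        calls = [_call(1000, 600)]
        assert len(filter_calls(calls, include_regions=[("c", 0, 2000)])) == 1
        assert filter_calls(calls, include_regions=[("c", 0, 1500)]) == []

    def test_empty_filters_are_identity(self):
        calls = [_call(0, 600), _call(0, 900)]
        assert filter_calls(calls, size_range=(0, 10**9)) == calls

    def test_gq_masking(self):
        call = _call(0, 600, gts=("0/1", "0/1"), gq=10)
        out = filter_calls([call], gq_min=20)
        assert out == []  # both genotypes masked -> call dropped

    def test_malformed_bed_names_line(self, tmp_path):
        bad = tmp_path / "x.bed"
        bad.write_text("chr1\t10\t20\nchr1\tbroken\n")
        with pytest.raises(ValueError, match="x.bed:2"):
            parse_bed(str(bad))


def brute_force_hwe(n00, n01, n11):
    """Enumerate all genotype configurations with the same allele counts,
    in exact rational arithmetic."""
    from fractions import Fraction

    n = n00 + n01 + n11
    n_alt = 2 * n11 + n01

    def prob(h):
        hom_alt = (n_alt - h) // 2
        hom_ref = n - h - hom_alt
        return Fraction(
            math.factorial(n)
            * math.factorial(n_alt)
            * math.factorial(2 * n - n_alt)
            * 2**h,
            math.factorial(hom_ref)
            * math.factorial(h)
            * math.factorial(hom_alt)
            * math.factorial(2 * n),
        )

    hs = [h for h in range(n_alt % 2, min(n_alt, 2 * n - n_alt) + 1, 2)]
    probs = {h: prob(h) for h in hs}
    p_obs = probs[n01]
    return float(sum(p for p in probs.values() if p <= p_obs))


class TestHWE:
    def test_perfect_proportions_kept(self):
        assert hwe_filter((25, 50, 25))

    def test_het_deficit_dropped(self):
        assert not hwe_filter((50, 0, 50))

    def test_monomorphic_kept(self):
        assert hwe_exact_pvalue(40, 0, 0) == 1.0
        assert hwe_exact_pvalue(0, 0, 40) == 1.0

    @pytest.mark.parametrize(
        "counts",
        [(25, 50, 25), (10, 5, 10), (30, 10, 2), (7, 23, 20), (0, 50, 0), (3, 1, 46)],
    )
    def test_matches_brute_force_enumeration(self, counts):
        assert hwe_exact_pvalue(*counts) == pytest.approx(
            brute_force_hwe(*counts), rel=1e-9
        )

    def test_random_counts_match_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(30):
            n = int(rng.integers(2, 50))
            n00 = int(rng.integers(0, n + 1))
            n01 = int(rng.integers(0, n - n00 + 1))
            n11 = n - n00 - n01
            assert hwe_exact_pvalue(n00, n01, n11) == pytest.approx(
                brute_force_hwe(n00, n01, n11), rel=1e-9, abs=1e-12
            )


class TestMendelian:
    def test_impossible_child(self):
        assert not mendelian_consistent("0/0", "0/0", "0/1")

    def test_table_counts_hom_parent_violation(self):
        # a 0/1 x 1/1 couple cannot have a 0/0 child
        assert not mendelian_consistent("0/1", "1/1", "0/0")
        assert mendelian_consistent("0/1", "1/1", "0/1")
        assert mendelian_consistent("0/1", "1/1", "1/1")

    def test_classification_is_exhaustive_and_parent_symmetric(self):
        gts = ["0/0", "0/1", "1/1"]
        for f, m, c in itertools.product(gts, repeat=3):
            assert isinstance(mendelian_consistent(f, m, c), bool)
            assert mendelian_consistent(f, m, c) == mendelian_consistent(m, f, c)

    def test_all_reference_trios_ignored(self):
        trios = [
            TrioGenotypes("s1", "t1", "0/0", "0/0", "0/0"),
            TrioGenotypes("s2", "t1", "0/1", "0/0", "0/1"),
            TrioGenotypes("s3", "t1", "./.", "0/1", "0/1"),
        ]
        rate, per_trio = mendelian_error_rate(trios)
        assert rate == 0.0
        assert per_trio == {"t1": 1}

    def test_error_rate_counts(self):
        trios = [
            TrioGenotypes("s1", "t1", "0/0", "0/0", "0/1"),  # error
            TrioGenotypes("s2", "t1", "0/1", "0/0", "0/1"),  # consistent
            TrioGenotypes("s3", "t2", "0/1", "0/1", "1/1"),  # consistent
        ]
        rate, _ = mendelian_error_rate(trios)
        assert rate == pytest.approx(1 / 3)


class TestTransmission:
    def test_printed_unique_trio_counts(self):
        """1714 untransmitted and 1680 transmitted unique single-parent
        sites give a 49.50% transmission rate."""
        trios = []
        for k in range(1714):
            trios.append(TrioGenotypes(f"u{k}", "t1", "0/1", "0/0", "0/0"))
        for k in range(1680):
            trios.append(TrioGenotypes(f"t{k}", "t1", "0/1", "0/0", "0/1"))
        rate = transmission_rate(trios, mode="unique_single_parent")
        assert round(rate, 2) == 49.50

    def test_all_transmitted(self):
        trios = [
            TrioGenotypes(f"s{k}", "t1", "0/0", "0/1", "0/1") for k in range(10)
        ]
        assert transmission_rate(trios) == 100.0

    def test_multi_trio_sites_excluded_in_unique_mode(self):
        trios = [
            TrioGenotypes("shared", "t1", "0/1", "0/0", "0/1"),
            TrioGenotypes("shared", "t2", "0/1", "0/0", "0/0"),
            TrioGenotypes("only", "t1", "0/1", "0/0", "0/1"),
        ]
        assert transmission_rate(trios, mode="unique_single_parent") == 100.0
        assert transmission_rate(trios, mode="single_parent") == pytest.approx(
            100.0 * 2 / 3
        )

    def test_undefined_without_informative_sites(self):
        trios = [TrioGenotypes("s", "t1", "1/1", "1/1", "1/1")]
        assert transmission_rate(trios) is None

    def test_simulated_mendelian_trios_near_fifty_percent(self):
        """Genotype-level trios under Mendelian transmission: zero errors
        and a transmission rate inside the 95% binomial interval of 50%."""
        from joindel.evaluate import trio_table_from_calls
        from joindel.simulate import simulate_deletion_set, simulate_trios
        from joindel.vcfout import DeletionCall, SampleCall

        dels = simulate_deletion_set(300, contig_length=30_000_000, seed=21)
        cohort, ped = simulate_trios(dels, 40, seed=22)
        gt_str = {0: "0/0", 1: "0/1", 2: "1/1"}
        calls = []
        for j, d in enumerate(sorted(dels, key=lambda d: d.start)):
            jj = dels.index(d)
            samples = [
                SampleCall((0, 0, 0), gt_str[int(g)], 99)
                for g in cohort.genotypes[:, jj]
            ]
            calls.append(DeletionCall(d.contig, d.start, d.length, samples))
        table = trio_table_from_calls(calls, cohort.sample_ids, ped)
        rate, _ = mendelian_error_rate(table)
        assert rate == 0.0
        tr = transmission_rate(table, mode="single_parent")
        informative = sum(
            1
            for t in table
            if not t.ignored and sorted((t.father, t.mother)) == ["0/0", "0/1"]
            and t.child in ("0/0", "0/1")
        )
        half_width = 100 * 1.96 * math.sqrt(0.25 / informative)
        assert abs(tr - 50.0) <= half_width


class TestDeNovo:
    def test_candidate_requires_confident_trio(self):
        good = TrioGenotypes("s1", "t1", "0/0", "0/0", "0/1", 60, 60, 60)
        low_gq = TrioGenotypes("s2", "t1", "0/0", "0/0", "0/1", 60, 60, 30)
        carrier_parent = TrioGenotypes("s3", "t1", "0/1", "0/0", "0/1", 60, 60, 60)
        out = de_novo_candidates([good, low_gq, carrier_parent], gq_min=50)
        assert out == [good]

    @pytest.mark.parametrize(
        "args,expected", [((7, 258, 49), 1.33), ((0, 10, 5), 0.0), ((7, 258, 258), 7.0)]
    )
    def test_expected_count_scaling(self, args, expected):
        assert expected_de_novo(*args) == expected


class TestGenotypeMatrix:
    def test_allele_counts_and_monomorphic_drop(self):
        calls = [
            _call(0, 600, gts=("0/1", "1/1", "0/0")),
            _call(5000, 700, gts=("0/0", "0/0", "0/0")),  # uninformative
            _call(9000, 800, gts=("./.", "0/1", "0/0")),
        ]
        df = genotype_matrix(calls, ["A", "B", "C"])
        assert df.shape == (3, 2)
        assert list(df.iloc[:, 0]) == [1.0, 2.0, 0.0]
        assert np.isnan(df.iloc[0, 1])
        assert df.iloc[1, 1] == 1.0
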