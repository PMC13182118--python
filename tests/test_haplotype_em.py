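import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from milkvar.errors import CombinatorialLimitError, MilkvarError
from milkvar.haplotype_em import (
    GenotypeMatrix,
    SiteInfo,
    assign_best_pairs,
    em_by_breed,
    em_estimate,
    enumerate_compatible_pairs,
    expected_occurrences,
    hard_occurrences,
)
from .em_oracle import brute_force_em, compatible_ordered_pairs


def matrix(rows, breeds=None):
    rows = np.asarray(rows)
    n, m = rows.shape
    sites = [SiteInfo("6", 100 + j, "A", "G", cds_offset=j + 1) for j in range(m)]
    samples = [f"I{i}" for i in range(n)]
    return GenotypeMatrix(rows, sites, samples, breeds or ["X"] * n)


class TestEnumeratePairs:
    def test_hom_ref_single_pair(self):
        assert enumerate_compatible_pairs([0, 0, 0]) == [("000", "000")]

    def test_single_het_single_pair(self):
        assert enumerate_compatible_pairs([1, 0]) == [("00", "10")]

    def test_double_het_two_pairs(self):
        pairs = set(enumerate_compatible_pairs([1, 1]))
        assert pairs == {("00", "11"), ("01", "10")}

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=6))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_count_matches_brute_force(self, g):
        """2^(k-1) unordered pairs for k het sites, verified against direct
        enumeration of all ordered haplotype pairs."""
        pairs = enumerate_compatible_pairs(g)
        k = sum(1 for x in g if x == 1)
        assert len(pairs) == max(1, 2 ** (k - 1))
        haps = ["".join(b) for b in itertools.product("01", repeat=len(g))]
        ordered = compatible_ordered_pairs(g, haps)
        assert {tuple(sorted(p)) for p in ordered} == set(pairs)

    def test_het_cap(self):
        with pytest.raises(CombinatorialLimitError):
            enumerate_compatible_pairs([1] * 25)


class TestEmEstimate:
    def test_phase_unambiguous_equals_gene_counting(self):
        """With no multi-het individuals the EM fixed point is the allele count."""
        rows = [[0, 0], [1, 0], [2, 0], [0, 1], [0, 2], [2, 2]]
        est = em_estimate(matrix(rows))
        n_chrom = 2 * len(rows)
        counts = {"00": 0.0, "10": 0.0, "01": 0.0, "11": 0.0}
        for r in rows:
            (h1, h2) = enumerate_compatible_pairs(r)[0]
            counts[h1] += 1
            counts[h2] += 1
        for h, c in counts.items():
            assert est.frequencies.get(h, 0.0) == pytest.approx(c / n_chrom, abs=1e-9)

    def test_double_het_worked_example(self):
        """One hom-ref + one double-het individual: mass concentrates on the
        (00, 11) phase, giving frequencies 0.75 / 0.25."""
        est = em_estimate(matrix([[0, 0], [1, 1]]))
        assert est.converged
        assert est.frequencies["00"] == pytest.approx(0.75, abs=1e-6)
        assert est.frequencies["11"] == pytest.approx(0.25, abs=1e-6)
        assert est.frequencies["01"] == pytest.approx(0.0, abs=1e-6)
        assert est.frequencies["10"] == pytest.approx(0.0, abs=1e-6)

    def test_single_het_individual_is_symmetric(self):
        est = em_estimate(matrix([[1]]))
        assert est.frequencies == {"0": 0.5, "1": 0.5}

    def test_empty_matrix_rejected(self):
        with pytest.raises(MilkvarError):
            em_estimate(matrix(np.zeros((0, 2), dtype=int)))

    def test_loglik_monotone_and_frequencies_normalised(self):
        rng = np.random.default_rng(7)
        rows = rng.integers(0, 3, size=(30, 4))
        est = em_estimate(matrix(rows))
        assert sum(est.frequencies.values()) == pytest.approx(1.0, abs=1e-9)
        trace = est.loglik_trace
        assert all(b >= a - 1e-9 for a, b in zip(trace, trace[1:]))

    @given(st.integers(0, 10_000))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_agrees_with_brute_force_oracle(self, seed):
        """Random instances with <=4 sites, <=20 individuals: the grouped EM
        matches plain enumeration EM to 1e-10."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(1, 21))
        m = int(rng.integers(1, 5))
        rows = rng.integers(0, 3, size=(n, m))
        est = em_estimate(matrix(rows), tol=1e-12, max_iter=20_000)
        oracle = brute_force_em([list(map(int, r)) for r in rows], tol=1e-12, max_iter=20_000)
        for h, f in oracle.items():
            assert est.frequencies.get(h, 0.0) == pytest.approx(f, abs=1e-10)

    def test_non_convergence_reported_not_raised(self):
        est = em_estimate(matrix([[1, 1], [1, 1], [0, 0]]), tol=0.0, max_iter=3)
        assert not est.converged and est.iterations == 3


class TestParameterRecovery:
    def test_recovery_within_three_se(self):
        """200 replicates of 400 chromosomes from 4 haplotypes at
        0.4/0.3/0.2/0.1: at least 95% of estimates fall within 3*SE of truth."""
        haps = ["00", "01", "10", "11"]
        truth = np.array([0.4, 0.3, 0.2, 0.1])
        n_ind = 200
        rng = np.random.default_rng(20_240_401)
        hits = total = 0
        for _ in range(200):
            draws = rng.choice(4, size=2 * n_ind, p=truth)
            rows = [
                [int(haps[a][j]) + int(haps[b][j]) for j in range(2)]
                for a, b in zip(draws[::2], draws[1::2])
            ]
            est = em_estimate(matrix(rows))
            for h, f in zip(haps, truth):
                se = np.sqrt(f * (1 - f) / (2 * n_ind))
                hits += abs(est.frequencies.get(h, 0.0) - f) <= 3 * se
                total += 1
        assert hits / total >= 0.95


class TestAssignBestPairs:
    def test_unambiguous_individual_has_posterior_one(self):
        gm = matrix([[2, 0], [1, 0]])
        est = em_estimate(gm)
        a = assign_best_pairs(gm, est)
        assert a[0].pair == ("10", "10") and a[0].posterior == pytest.approx(1.0)
        assert a[1].pair == ("00", "10") and a[1].posterior == pytest.approx(1.0)

    def test_double_het_resolved_by_frequencies(self):
        gm = matrix([[0, 0], [1, 1]])
        est = em_estimate(gm)
        a = assign_best_pairs(gm, est)
        assert a[1].pair == ("00", "11")
        assert a[1].posterior == pytest.approx(1.0, abs=1e-6)

    def test_tie_broken_lexicographically(self):
        gm = matrix([[1, 1]])
        est = em_estimate(gm)  # symmetric: all four haplotypes at 0.25
        a = assign_best_pairs(gm, est)
        assert a[0].pair == ("00", "11") and a[0].posterior == pytest.approx(0.5)

    def test_hard_and_expected_occurrences_agree_when_unambiguous(self):
        gm = matrix([[2, 0], [1, 0], [0, 0]])
        est = em_estimate(gm)
        hard = hard_occurrences(assign_best_pairs(gm, est))
        soft = expected_occurrences(gm, est)
        for h, c in hard.items():
            assert soft[h] == pytest.approx(c, abs=1e-6)


class TestBreedLevel:
    def test_breed_runs_seeded_from_cohort(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 3, size=(40, 3))
        breeds = ["A"] * 25 + ["B" if i % 5 else "C" for i in range(15)]
        gm = matrix(rows, breeds=breeds)
        cohort = em_estimate(gm)
        per_breed = em_by_breed(gm, cohort)
        assert set(per_breed) <= {"A", "B", "C"}
        for est in per_breed.values():
            assert sum(est.frequencies.values()) == pytest.approx(1.0, abs=1e-9)

    def test_small_breeds_skipped(self):
        gm = matrix([[0, 0], [1, 0], [1, 1]], breeds=["A", "A", "Solo"])
        per_breed = em_by_breed(gm, em_estimate(gm), min_samples=2)
        assert "Solo" not in per_breed and "A" in per_breed
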