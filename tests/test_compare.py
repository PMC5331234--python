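"""Library comparison set arithmetic, fold enrichment, potency statistics."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from yfrag.compare import (
    PotencyRecord,
    compare_libraries,
    correlate_abundance_potency,
    fold_enrichment,
    rank_fragments,
    split_by_potency,
)
from yfrag.synthetic import make_potency_records

seqs = st.text(alphabet="ACGT", min_size=15, max_size=20)
inventory = st.dictionaries(seqs, st.integers(min_value=1, max_value=500),
                            min_size=0, max_size=25)


class TestCompareLibraries:
    def test_example_sets(self):
        cmp_ = compare_libraries(
            [("x" * 15, 1), ("y" * 15, 2), ("z" * 15, 3)],
            [("y" * 15, 4), ("w" * 15, 5)],
        )
        assert cmp_.unique_to_a == {"x" * 15, "z" * 15}
        assert cmp_.unique_to_b == {"w" * 15}
        assert cmp_.shared == {"y" * 15}

    def test_identical_libraries(self):
        lib = [("A" * 15, 3), ("C" * 15, 1)]
        cmp_ = compare_libraries(lib, lib)
        assert cmp_.unique_to_a == cmp_.unique_to_b == frozenset()
        assert cmp_.shared == {"A" * 15, "C" * 15}

    @given(a=inventory, b=inventory)
    def test_sets_disjoint_and_conserved(self, a, b):
        cmp_ = compare_libraries(list(a.items()), list(b.items()))
        assert not (cmp_.unique_to_a & cmp_.unique_to_b)
        assert not (cmp_.unique_to_a & cmp_.shared)
        assert not (cmp_.unique_to_b & cmp_.shared)
        assert len(cmp_.unique_to_a) + len(cmp_.shared) == len(a)
        assert len(cmp_.unique_to_b) + len(cmp_.shared) == len(b)

    @given(a=inventory, b=inventory)
    def test_symmetry_swaps_sets_and_inverts_enrichment(self, a, b):
        fwd = compare_libraries(list(a.items()), list(b.items()))
        rev = compare_libraries(list(b.items()), list(a.items()))
        assert fwd.unique_to_a == rev.unique_to_b
        assert fwd.shared == rev.shared
        for seq in fwd.shared:
            f = fold_enrichment(seq, fwd, pseudocount=0)
            r = fold_enrichment(seq, rev, pseudocount=0)
            assert f * r == pytest.approx(1.0)


class TestFoldEnrichment:
    def _cmp(self, ca, cb):
        return compare_libraries(list(ca.items()), list(cb.items()))

    def test_equal_counts_give_unity(self):
        cmp_ = self._cmp({"A" * 15: 100}, {"A" * 15: 100})
        assert fold_enrichment("A" * 15, cmp_, pseudocount=0) == 1.0

    def test_mirrors_reported_ratio_arithmetic(self):
        cmp_ = self._cmp({"A" * 15: 157}, {"A" * 15: 10})
        assert fold_enrichment("A" * 15, cmp_, pseudocount=0) == pytest.approx(15.7)

    def test_pseudocount_guards_division_by_zero(self):
        cmp_ = self._cmp({"A" * 15: 5}, {})
        assert fold_enrichment("A" * 15, cmp_, pseudocount=1) == pytest.approx(6.0)

    def test_self_comparison_is_unity_any_normalization(self):
        lib = {"A" * 15: 7, "C" * 15: 100}
        cmp_ = self._cmp(lib, lib)
        for norm in ("raw", "per_million"):
            assert fold_enrichment("C" * 15, cmp_, norm, 0) == pytest.approx(1.0)

    def test_absent_sequence_rejected(self):
        cmp_ = self._cmp({"A" * 15: 5}, {"C" * 15: 2})
        with pytest.raises(ValueError):
            fold_enrichment("G" * 15, cmp_)


class TestRankFragments:
    def test_top_n_with_ties_lexicographic(self):
        lib = [("a" * 15, 5), ("b" * 15, 9), ("c" * 15, 1)]
        assert rank_fragments(lib, 2) == [("b" * 15, 9), ("a" * 15, 5)]

    def test_n_larger_than_table(self):
        lib = [("a" * 15, 5)]
        assert rank_fragments(lib, 10) == lib

    def test_rank_one_matches_truth_maximum(self, refset):
        from yfrag.synthetic import SimConfig, simulate_reads
        from collections import Counter

        cfg = SimConfig(n_reads=600, sub_rate=0.0, ins_rate=0.0, seed=20)
        reads, truths = simulate_reads(refset, cfg)
        counts = Counter(t.fragment_sequence for t in truths
                         if t.true_class == "Y_RNA")
        lib = sorted(counts.items())
        top_seq, top_count = rank_fragments(lib, 1)[0]
        assert top_count == max(counts.values())


class TestPotency:
    def test_split_by_sign_with_zero_non_potent(self):
        records = [PotencyRecord("a", 3.0, 1.0), PotencyRecord("b", -2.0, 1.0),
                   PotencyRecord("c", 0.1, 1.0), PotencyRecord("d", 0.0, 1.0)]
        potent, non_potent = split_by_potency(records)
        assert [r.donor_id for r in potent] == ["a", "c"]
        assert [r.donor_id for r in non_potent] == ["b", "d"]

    def test_all_negative_gives_empty_potent_group(self):
        records = [PotencyRecord(str(i), -float(i + 1), 1.0) for i in range(3)]
        potent, non_potent = split_by_potency(records)
        assert potent == [] and len(non_potent) == 3

    def test_perfect_monotone_spearman(self):
        records = [PotencyRecord(str(i), float(i - 3), 10.0 * (i + 1))
                   for i in range(6)]
        result = correlate_abundance_potency(records)
        assert result.coefficient == pytest.approx(1.0)

    def test_spearman_invariant_to_monotone_transform(self):
        base = make_potency_records(seed=4)
        transformed = [
            PotencyRecord(r.donor_id, r.delta_ef, math.log1p(r.abundance) ** 2)
            for r in base
        ]
        a = correlate_abundance_potency(base).coefficient
        b = correlate_abundance_potency(transformed).coefficient
        assert a == pytest.approx(b)

    def test_independent_permutations_match_exact_null(self):
        """Shuffled abundances at n=6: the fraction of |rho| < 0.5 draws
        matches the exact permutation null (506/720), and the mean
        coefficient is near zero."""
        from itertools import permutations

        exact = sum(
            abs(correlate_abundance_potency(
                [PotencyRecord(str(i), float(i), float(p[i]) + 1.0)
                 for i in range(6)]
            ).coefficient) < 0.5
            for p in permutations(range(6))
        ) / 720.0
        assert exact == pytest.approx(506 / 720)

        rng = np.random.default_rng(99)
        deltas = [4.0, 2.0, 1.0, -1.0, -2.0, -4.0]
        abundances = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
        n_trials = 200
        coeffs = []
        for _ in range(n_trials):
            perm = rng.permutation(6)
            records = [PotencyRecord(str(i), deltas[i], abundances[perm[i]])
                       for i in range(6)]
            coeffs.append(correlate_abundance_potency(records).coefficient)
        frac_small = sum(abs(c) < 0.5 for c in coeffs) / n_trials
        se = math.sqrt(exact * (1 - exact) / n_trials)
        assert abs(frac_small - exact) < 3 * se
        assert abs(sum(coeffs) / n_trials) < 0.15  # null mean is 0

    def test_group_means_recover_constructed_ratio(self):
        """Potent-group mean is built 3x the non-potent mean; the sample
        means must agree within 3 SE of the per-donor gamma noise."""
        pm, npm, n_rep = 3000.0, 1000.0, 25
        tot_p = tot_np = 0.0
        for seed in range(n_rep):
            result = correlate_abundance_potency(make_potency_records(seed=seed))
            tot_p += result.potent_mean
            tot_np += result.non_potent_mean
        se_p = (pm / 3.0) / math.sqrt(3 * n_rep)  # gamma sd = mean/3, 3 donors
        se_np = (npm / 3.0) / math.sqrt(3 * n_rep)
        assert abs(tot_p / n_rep - pm) < 3 * se_p
        assert abs(tot_np / n_rep - npm) < 3 * se_np

    def test_zero_variance_flagged_with_means_intact(self):
        records = [PotencyRecord(str(i), float(i - 1), 5.0) for i in range(4)]
        result = correlate_abundance_potency(records)
        assert result.undefined
        assert math.isnan(result.coefficient)
        assert result.potent_mean == pytest.approx(5.0)
        assert result.non_potent_mean == pytest.approx(5.0)

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            correlate_abundance_potency([PotencyRecord("a", 1.0, 1.0),
                                         PotencyRecord("b", -1.0, 2.0)])
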