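import itertools

import numpy as np
import pytest
from scipy import stats

from paleokaryo.dominance import (
    binomial_dominance_test,
    chi_square_cross_check,
    classify_blocks,
    fit_two_step_partition,
    retention_counts,
    rosid_labels,
    rosid_reference_assignment,
    rosid_triplets,
)


def exact_two_sided_p(n1, n2):
    """Independent oracle: minimum-likelihood tail enumeration of B(n, 1/2)."""
    n = n1 + n2
    pmf = stats.binom.pmf(np.arange(n + 1), n, 0.5)
    return float(pmf[pmf <= pmf[n1] * (1 + 1e-12)].sum())


class TestBinomialTest:
    def test_symmetric_counts_not_significant(self):
        p, sig = binomial_dominance_test(25, 25)
        assert p == pytest.approx(1.0)
        assert not sig

    def test_strong_imbalance_significant(self):
        p, sig = binomial_dominance_test(50, 10)
        assert p == pytest.approx(exact_two_sided_p(50, 10), rel=1e-9)
        assert sig

    def test_alpha_boundary_is_strict(self):
        p, _ = binomial_dominance_test(50, 10)
        _, sig = binomial_dominance_test(50, 10, alpha=p)
        assert not sig  # "lower than alpha" is strict, so p == alpha fails

    def test_zero_total_returns_na(self):
        p, sig = binomial_dominance_test(0, 0)
        assert np.isnan(p) and not sig

    def test_matches_enumeration_for_all_n_up_to_200(self):
        rng = np.random.default_rng(0)
        for n in range(1, 201):
            for n1 in {0, n, int(rng.integers(0, n + 1)), n // 2}:
                p, _ = binomial_dominance_test(n1, n - n1)
                assert p == pytest.approx(exact_two_sided_p(n1, n - n1),
                                          rel=1e-9, abs=1e-12)

    def test_type_i_error_control(self):
        rng = np.random.default_rng(1)
        alpha = 0.05
        n = 200
        hits = 0
        reps = 2000
        draws = rng.binomial(n, 0.5, size=reps)
        for d in draws:
            _, sig = binomial_dominance_test(int(d), n - int(d), alpha=alpha)
            hits += sig
        rate = hits / reps
        assert rate < alpha + 3 * np.sqrt(alpha * (1 - alpha) / reps)

    def test_chi_square_cross_check_agrees_asymptotically(self):
        pb, _ = binomial_dominance_test(300, 240)
        pc = chi_square_cross_check(300, 240)
        assert pb == pytest.approx(pc, rel=0.15)


class TestClassifyBlocks:
    def table(self, counts_by_block, triplets):
        import pandas as pd

        from paleokaryo.dominance import RetentionTable
        df = pd.DataFrame({"G": counts_by_block})
        return RetentionTable(counts=df, triplets=triplets)

    def test_one_sensitive_member(self):
        t = self.table({"b1": 100, "b2": 100, "b3": 20}, [("b1", "b2", "b3")])
        labels = {c.block: c.label for c in classify_blocks(t)}
        assert labels == {"b1": "D", "b2": "D", "b3": "S"}

    def test_no_bias_triplet_flagged(self):
        t = self.table({"b1": 50, "b2": 50, "b3": 50}, [("b1", "b2", "b3")])
        calls = classify_blocks(t)
        assert all(c.label == "D" and c.no_bias for c in calls)

    def test_degenerate_all_zero(self):
        t = self.table({"b1": 0, "b2": 0, "b3": 0}, [("b1", "b2", "b3")])
        assert all(c.label == "NA" for c in classify_blocks(t))


class TestTwoStepPartition:
    def brute_force_consistency(self, labels, triplets):
        """Oracle: scan all 6^t assignments explicitly."""
        expected = {"A": "D", "B": "S", "C": "D"}
        best = -1
        for combo in itertools.product(itertools.permutations("ABC"),
                                       repeat=len(triplets)):
            score = sum(
                labels[b] == expected[s]
                for t, perm in zip(triplets, combo)
                for b, s in zip(t, perm)
            )
            best = max(best, score)
        return best

    def test_all_dominant_best_is_fourteen(self):
        triplets = rosid_triplets()
        labels = {b: "D" for t in triplets for b in t}
        part = fit_two_step_partition(labels, triplets)
        assert part.consistency == 14
        assert part.consistency == self.brute_force_consistency(labels, triplets)

    def test_matches_brute_force_on_random_labels(self):
        rng = np.random.default_rng(5)
        triplets = rosid_triplets()[:4]  # keep the 6^4 oracle cheap
        for _ in range(5):
            labels = {b: ("D" if rng.random() < 0.6 else "S")
                      for t in triplets for b in t}
            part = fit_two_step_partition(labels, triplets)
            assert part.consistency == self.brute_force_consistency(labels, triplets)

    def test_result_invariant_to_triplet_order(self):
        triplets = rosid_triplets()
        labels = rosid_labels()
        a = fit_two_step_partition(labels, triplets,
                                   reference=rosid_reference_assignment())
        b = fit_two_step_partition(labels, triplets[::-1],
                                   reference=rosid_reference_assignment())
        assert a.consistency == b.consistency
        assert a.assignment == b.assignment

    def test_incomplete_labels_rejected(self):
        with pytest.raises(ValueError):
            fit_two_step_partition({"A1": "D"}, rosid_triplets())

    def test_published_labels_give_twenty_of_twentyone(self):
        part = fit_two_step_partition(rosid_labels(), rosid_triplets(),
                                      reference=rosid_reference_assignment())
        assert part.consistency == 20
        assert part.exceptions == ["A14"]
        ref = rosid_reference_assignment()
        assert part.assignment == ref


class TestRetentionAndRecovery:
    def test_identity_and_deleted_block(self, noloss_bundle):
        b = noloss_bundle
        anc = {blk: b.ancestor_order[b.block_of_chrom[blk]]
               for blk in b.post_wgd_order}
        painting = {"hexaploid": {c: c for c in b.hexaploid().chromosomes}}
        t = retention_counts(anc, [b.hexaploid()], painting,
                             triplets=rosid_triplets())
        assert (t.counts["hexaploid"] == 50).all()

    def test_fractionation_counts_near_binomial_expectation(self,
                                                            fractionated_bundle):
        b = fractionated_bundle
        anc = {blk: b.ancestor_order[b.block_of_chrom[blk]]
               for blk in b.post_wgd_order}
        painting = {"hexaploid": {c: c for c in b.hexaploid().chromosomes}}
        t = retention_counts(anc, [b.hexaploid()], painting,
                             triplets=rosid_triplets())
        n = 200
        for blk, sub in b.block_subgenome.items():
            p = {"A": 0.9, "B": 0.4, "C": 0.95}[sub]
            got = t.counts.at[blk, "hexaploid"]
            # 3 sigma around Binomial(n, p); protection adds a few genes
            assert got >= n * p - 3 * np.sqrt(n * p * (1 - p))
            assert got <= n * p + 3 * np.sqrt(n * p * (1 - p)) + 10

    def test_planted_dominance_detected_with_high_power(self):
        # study condition: counts pooled over nine genomes, >= 50 genes per block
        rng = np.random.default_rng(11)
        detected = 0
        reps = 200
        for _ in range(reps):
            n1 = rng.binomial(9 * 50, 0.9)
            n2 = rng.binomial(9 * 50, 0.4)
            _, sig = binomial_dominance_test(int(n1), int(n2))
            detected += sig
        assert detected / reps > 0.99
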