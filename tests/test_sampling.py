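from collections import Counter

import numpy as np
import pytest

from paircraft import (
    BatchPlan, PairKey, SequenceRecord, TypePair, check_type_distribution,
    make_batches, sample_negatives, stratified_split,
)
from conftest import random_positives, random_typed_pool


def _seqs(**kwargs):
    return {sid: SequenceRecord(sid, "ACGU", t) for sid, t in kwargs.items()}


class TestSampleNegatives:
    def test_single_eligible_candidate(self):
        seqs = _seqs(a="miRNA", b="lncRNA", c="lncRNA")
        negs = sample_negatives({PairKey("a", "b")}, seqs, n=20, seed=0)
        assert negs == {PairKey("a", "c")}

    def test_emits_exactly_n_when_pool_allows(self):
        seqs = _seqs(a="miRNA", b="lncRNA",
                     **{f"d{i:02d}": "lncRNA" for i in range(40)})
        negs = sample_negatives({PairKey("a", "b")}, seqs, n=20, seed=1)
        assert len(negs) == 20
        assert all("a" in p.ids for p in negs)
        assert PairKey("a", "b") not in negs

    def test_empty_pool_yields_zero_negatives(self):
        seqs = _seqs(a="miRNA", b="lncRNA")
        assert sample_negatives({PairKey("a", "b")}, seqs, n=20, seed=0) == set()

    def test_brute_force_verification_on_random_instance(self):
        """Every emitted negative satisfies all four corruption conditions."""
        rng = np.random.default_rng(17)
        seqs = random_typed_pool(rng, n_per_type=50)
        positives = random_positives(rng, seqs, 500)
        negatives = sample_negatives(positives, seqs, n=5, seed=23)
        assert negatives
        anchors = {}
        for pos in sorted(positives):
            anchors.setdefault(pos.first_id, set()).add(
                seqs[pos.second_id].rna_type)
        for neg in negatives:
            # canonical pair, not a self pair, disjoint from positives
            assert neg.first_id != neg.second_id
            assert neg not in positives
            # type-constrained: the corrupted member's type matches the type
            # of a partner its anchor actually interacts with
            assert seqs[neg.second_id].rna_type in anchors.get(
                neg.first_id, set()) or seqs[neg.first_id].rna_type in anchors.get(
                neg.second_id, set())
        # global dedup: a set cannot hold duplicates, but check count sanity
        assert len(negatives) <= 5 * len(positives)

    def test_type_distribution_preserved_without_exhaustion(self):
        """With ample pools, each positive contributes exactly n same-type
        negatives, so the type-pair distributions agree exactly."""
        rng = np.random.default_rng(3)
        seqs = random_typed_pool(rng, n_per_type=80)
        positives = random_positives(rng, seqs, 60)
        negatives = sample_negatives(positives, seqs, n=3, seed=5)
        assert len(negatives) == 3 * len(positives)
        _, _, max_diff = check_type_distribution(positives, negatives, seqs)
        assert max_diff == pytest.approx(0.0, abs=1e-12)

    def test_determinism_under_seed(self):
        rng = np.random.default_rng(9)
        seqs = random_typed_pool(rng, n_per_type=30)
        positives = random_positives(rng, seqs, 40)
        a = sample_negatives(positives, seqs, n=4, seed=77)
        b = sample_negatives(positives, seqs, n=4, seed=77)
        assert a == b


class TestCheckTypeDistribution:
    def test_identical_sets_have_zero_difference(self):
        seqs = _seqs(a="miRNA", b="lncRNA", c="miRNA", d="lncRNA")
        pos = {PairKey("a", "b"), PairKey("c", "d")}
        _, _, diff = check_type_distribution(pos, pos, seqs)
        assert diff == 0.0

    def test_hand_enumerated_difference(self):
        seqs = _seqs(a="miRNA", b="lncRNA", c="lncRNA", d="snoRNA", e="snoRNA")
        pos = {PairKey("a", "b"), PairKey("a", "d")}       # 1/2 mi-lnc, 1/2 mi-sno
        neg = {PairKey("a", "c"), PairKey("a", "e"), PairKey("b", "d")}
        dp, dn, diff = check_type_distribution(pos, neg, seqs)
        # negatives: 1/3 mi-lnc, 1/3 mi-sno, 1/3 lnc-sno -> max diff = 1/3
        assert diff == pytest.approx(1 / 3)


class TestStratifiedSplit:
    def _uniform_pool(self, n, rna_type="miRNA", label=1, tag=""):
        seqs = {}
        pairs = []
        for i in range(n):
            a, b = f"{rna_type}{tag}a{i}", f"{rna_type}{tag}b{i}"
            seqs[a] = SequenceRecord(a, "ACGU", rna_type)
            seqs[b] = SequenceRecord(b, "ACGU", rna_type)
            pairs.append((PairKey(a, b), label))
        return seqs, pairs

    def test_default_fractions_single_stratum(self):
        seqs, pairs = self._uniform_pool(100)
        bundle = stratified_split(pairs, seqs, seed=0)
        assert (len(bundle.test), len(bundle.validation), len(bundle.train)) == (10, 18, 72)

    def test_two_strata_proportional_test_allocation(self):
        s1, p1 = self._uniform_pool(80, "miRNA")
        s2, p2 = self._uniform_pool(20, "lncRNA")
        seqs = {**s1, **s2}
        bundle = stratified_split(p1 + p2, seqs, seed=1)
        by_type = Counter(seqs[p.first_id].rna_type for p, _ in bundle.test)
        assert by_type == {"miRNA": 8, "lncRNA": 2}

    def test_deterministic_under_seed(self):
        seqs, pairs = self._uniform_pool(50)
        b1 = stratified_split(pairs, seqs, seed=4)
        b2 = stratified_split(pairs, seqs, seed=4)
        assert b1.train == b2.train and b1.validation == b2.validation and b1.test == b2.test

    def test_single_member_stratum_goes_to_train(self):
        s1, p1 = self._uniform_pool(20, "miRNA")
        s2, p2 = self._uniform_pool(1, "snRNA")
        bundle = stratified_split(p1 + p2, {**s1, **s2}, seed=0)
        assert p2[0] in bundle.train

    def test_disjointness_enforced(self):
        seqs, pairs = self._uniform_pool(30)
        bundle = stratified_split(pairs, seqs, seed=2)
        all_pairs = [p for p, _ in bundle.all_pairs]
        assert len(all_pairs) == len(set(all_pairs)) == 30


class TestBatches:
    def test_batch_plan_rounding(self):
        plan = BatchPlan(m=10, r=0.7)
        assert (plan.m_n, plan.m_p) == (7, 3)
        assert BatchPlan(m=512, r=0.7).m_n == 358

    def test_degenerate_mix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            BatchPlan(m=10, r=0.01)

    def test_batch_composition_and_epoch_length(self):
        negs = [("n", i) for i in range(100)]
        poss = [("p", i) for i in range(9)]
        batches = list(make_batches(poss, negs, m=10, r=0.7, seed=0))
        assert len(batches) == 14  # floor(100 / 7) full batches, 2 unused
        for b in batches:
            assert sum(1 for x in b if x[0] == "n") == 7
            assert sum(1 for x in b if x[0] == "p") == 3
        used_negs = [x for b in batches for x in b if x[0] == "n"]
        assert len(set(used_negs)) == len(used_negs) == 98  # without replacement

    def test_single_positive_repeats_with_replacement(self):
        batches = list(make_batches([("p", 0)], [("n", i) for i in range(20)],
                                    m=10, r=0.7, seed=1))
        for b in batches:
            assert sum(1 for x in b if x == ("p", 0)) == 3

    def test_epochwise_coverage_is_uniform(self):
        """Over many epochs every negative is consumed equally often."""
        negs = list(range(21))
        poss = [100]
        counts = Counter()
        for epoch in range(50):
            for b in make_batches(poss, negs, m=10, r=0.7, seed=1000 + epoch):
                counts.update(x for x in b if x != 100)
        assert max(counts.values()) - min(counts.values()) <= 1
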