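"""The statistical engine: KS scores, bootstrap nulls, p-values, FDR, repo."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from reposcan import (
    NullDistribution,
    RankedInstance,
    Signature,
    SignatureDB,
    bootstrap_null,
    empirical_p,
    fdr_adjust,
    ks_score,
    make_instance,
    repo,
    restrict_to_instance,
)


def _instance(n: int) -> RankedInstance:
    return RankedInstance(genes=tuple(f"g{i}" for i in range(1, n + 1)))


def _sig_at_ranks(inst: RankedInstance, ranks) -> set[str]:
    return {inst.genes[r - 1] for r in ranks}


def _oracle_ks(ranks, n):
    """Direct evaluation of the two running maxima over all j, in exact
    rational arithmetic so the a == b tie is decided without rounding."""
    from fractions import Fraction as F

    V = sorted(ranks)
    t = len(V)
    a = max(F(j, t) - F(V[j - 1], n) for j in range(1, t + 1))
    b = max(F(V[j - 1], n) - F(j - 1, t) for j in range(1, t + 1))
    return float(a) if a > b else -float(b)


class TestKsScore:
    @pytest.mark.parametrize(
        "n,ranks,expected",
        [
            (10, {1, 2}, 0.8),       # top block: 1 - t/n
            (10, {9, 10}, -0.9),     # bottom block: -(n-t+1)/n
            (10, {3, 7}, -0.3),      # exact tie a == b resolves to -b
            (6, {2, 3, 5}, -1 / 3),
        ],
    )
    def test_reference_values(self, n, ranks, expected):
        inst = _instance(n)
        score = ks_score(inst, _sig_at_ranks(inst, ranks))
        assert score.value == pytest.approx(expected, abs=1e-12)
        assert score.value == pytest.approx(_oracle_ks(ranks, n), abs=1e-12)

    def test_tie_components(self):
        inst = _instance(10)
        score = ks_score(inst, _sig_at_ranks(inst, {3, 7}))
        assert score.a == pytest.approx(0.3)
        assert score.b == pytest.approx(0.3)
        assert score.value == pytest.approx(-0.3)

    def test_empty_signature_error(self, instance10):
        with pytest.raises(ValueError, match="empty"):
            ks_score(instance10, set())

    def test_foreign_gene_is_contract_violation(self, instance10):
        with pytest.raises(ValueError, match="not in instance"):
            ks_score(instance10, {"g1", "nope"})

    @given(st.data())
    @settings(deadline=None, derandomize=True, max_examples=150)
    def test_matches_direct_oracle_and_bounds(self, data):
        n = data.draw(st.integers(2, 40))
        t = data.draw(st.integers(1, n))
        ranks = data.draw(
            st.sets(st.integers(1, n), min_size=t, max_size=t)
        )
        inst = _instance(n)
        score = ks_score(inst, _sig_at_ranks(inst, ranks))
        assert score.value == pytest.approx(_oracle_ks(ranks, n), abs=1e-12)
        assert score.a >= 0
        assert score.b > 0
        # -1 is attained exactly at t=1, rank n (b = n/n); +1 never is
        assert -1 <= score.value < 1
        assert score.value <= 1 - len(ranks) / n + 1e-12
        assert score.value >= -(n - len(ranks) + 1) / n - 1e-12

    @given(st.data())
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_rank_invariance_under_relabeling(self, data):
        """The score depends only on rank positions, never on gene labels."""
        n = data.draw(st.integers(3, 30))
        t = data.draw(st.integers(1, n))
        ranks = data.draw(st.sets(st.integers(1, n), min_size=t, max_size=t))
        inst_a = _instance(n)
        inst_b = RankedInstance(genes=tuple(f"XX{i}" for i in range(n)))
        sa = ks_score(inst_a, _sig_at_ranks(inst_a, ranks))
        sb = ks_score(inst_b, _sig_at_ranks(inst_b, ranks))
        assert sa.value == sb.value

    @pytest.mark.parametrize("n", [6, 8, 10])
    def test_single_gene_promotion_monotonicity(self, n):
        """Moving one signature gene to a strictly better rank never
        decreases a and never increases b (checked by full enumeration)."""
        inst = _instance(n)
        for t in range(1, n + 1):
            for ranks in itertools.combinations(range(1, n + 1), t):
                base = ks_score(inst, _sig_at_ranks(inst, ranks))
                rset = set(ranks)
                for r in ranks:
                    for better in range(1, r):
                        if better in rset:
                            continue
                        moved = (rset - {r}) | {better}
                        new = ks_score(inst, _sig_at_ranks(inst, moved))
                        assert new.a >= base.a - 1e-12
                        assert new.b <= base.b + 1e-12


class TestBootstrapNull:
    def test_one_null_per_unique_length(self, instance10):
        nulls = bootstrap_null(instance10, [2, 2, 3], B=50, seed=1)
        assert set(nulls) == {2, 3}
        assert all(nd.B == 50 for nd in nulls.values())

    def test_full_length_resamples_are_all_identical(self, instance10):
        nulls = bootstrap_null(instance10, [10], B=25, seed=1)
        assert np.all(nulls[10].scores == -1 / 10)

    def test_same_seed_bitwise_identical(self, instance10):
        a = bootstrap_null(instance10, [3, 5], B=200, seed=9)
        b = bootstrap_null(instance10, [3, 5], B=200, seed=9)
        for length in (3, 5):
            assert np.array_equal(a[length].scores, b[length].scores)

    def test_length_null_independent_of_other_lengths(self, instance10):
        """Each length's null comes from its own substream, so requesting
        extra lengths does not perturb an existing one."""
        alone = bootstrap_null(instance10, [4], B=100, seed=3)
        together = bootstrap_null(instance10, [2, 4, 7], B=100, seed=3)
        assert np.array_equal(alone[4].scores, together[4].scores)

    def test_invalid_lengths_error(self, instance10):
        with pytest.raises(ValueError):
            bootstrap_null(instance10, [11], B=10, seed=1)
        with pytest.raises(ValueError):
            bootstrap_null(instance10, [0], B=10, seed=1)

    def test_scores_respect_ks_bounds(self):
        inst = make_instance(100, seed=0)
        nulls = bootstrap_null(inst, [1, 7, 50], B=500, seed=11)
        for length, nd in nulls.items():
            assert nd.scores.max() <= 1 - length / 100 + 1e-12
            assert nd.scores.min() >= -(100 - length + 1) / 100 - 1e-12


class TestEmpiricalP:
    def _null(self, scores, length=2):
        scores = np.asarray(scores, dtype=float)
        return NullDistribution(length=length, scores=scores,
                                B=len(scores), seed=0)

    def _obs(self, value, t=2, n=10):
        inst = _instance(n)
        # fabricate an observed score via a real signature then compare value
        from reposcan import KSScore
        return KSScore(value=value, a=max(value, 0.0), b=max(-value, 0.1),
                       t=t, n=n)

    def test_observed_above_all_nulls(self):
        null = self._null(np.linspace(-0.5, 0.5, 100))
        assert empirical_p(self._obs(0.9), null) == 0.0
        assert empirical_p(self._obs(0.9), null, add_one=True) == 1 / 101

    def test_observed_below_all_nulls(self):
        null = self._null(np.linspace(0.1, 0.5, 100))
        assert empirical_p(self._obs(-0.9), null) == 1.0

    def test_median_observed_gives_half(self):
        rng = np.random.default_rng(4)
        scores = rng.normal(size=10_001)
        null = self._null(scores)
        med = float(np.median(scores))
        p = empirical_p(self._obs(med), null)
        assert p == (scores > med).sum() / len(scores)
        assert abs(p - 0.5) < 0.02

    def test_exact_equality_does_not_count_by_default(self):
        null = self._null([0.2, 0.2, 0.4, 0.6])
        assert empirical_p(self._obs(0.2), null) == 2 / 4

    def test_length_mismatch_error(self):
        null = self._null([0.1], length=3)
        with pytest.raises(ValueError, match="length"):
            empirical_p(self._obs(0.5, t=2), null)


class TestFdrAdjust:
    def _bh_oracle(self, p):
        """Hand step-up: q_(i) = min over k >= i of p_(k) * m / k, clipped."""
        m = len(p)
        order = np.argsort(p, kind="stable")
        q = np.empty(m)
        running = 1.0
        for pos in range(m - 1, -1, -1):
            i = order[pos]
            running = min(running, p[i] * m / (pos + 1))
            q[i] = running
        return q

    def test_reference_triple(self):
        assert fdr_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])

    def test_at_the_ceiling_and_singleton(self):
        assert fdr_adjust([1.0, 1.0]) == pytest.approx([1.0, 1.0])
        assert fdr_adjust([0.4]) == pytest.approx([0.4])

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])
        with pytest.raises(ValueError):
            fdr_adjust([-0.1])

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    @settings(deadline=None, derandomize=True, max_examples=100)
    def test_matches_stepup_oracle(self, p):
        assert fdr_adjust(p) == pytest.approx(self._bh_oracle(np.array(p)))


class TestRepo:
    def test_planted_top_block_has_smallest_p(self):
        inst = make_instance(200, seed=1)
        sigs = [Signature("top", frozenset(inst.genes[:5]))]
        rng = np.random.default_rng(2)
        for i in range(20):
            idx = rng.choice(200, size=5, replace=False)
            sigs.append(Signature(f"null{i:02d}",
                                  frozenset(inst.genes[j] for j in idx)))
        results = repo(inst, SignatureDB(signatures=tuple(sigs)),
                       B=1000, seed=3)
        assert results[0].compound_id == "top"
        assert results[0].p == min(r.p for r in results)

    def test_identical_signatures_share_all_statistics(self, instance10):
        genes = frozenset({"g2", "g5"})
        db = SignatureDB(
            signatures=tuple(Signature(f"d{i}", genes) for i in range(4))
        )
        results = repo(instance10, db, B=500, seed=7)
        assert len({(r.ks, r.p, r.q) for r in results}) == 1
        # ties broken by compound_id for a deterministic order
        assert [r.compound_id for r in results] == ["d0", "d1", "d2", "d3"]

    def test_determinism(self):
        inst = make_instance(100, seed=5)
        from reposcan import make_null_db
        db = make_null_db(inst, m=15, length_law=(2, 10), seed=8)
        a = repo(inst, db, B=300, seed=21)
        b = repo(inst, db, B=300, seed=21)
        assert a == b

    def test_row_conservation_with_dropped_signatures(self, instance10):
        db = SignatureDB(
            signatures=(
                Signature("in1", frozenset({"g1", "g2"})),
                Signature("in2", frozenset({"g9"})),
                Signature("out", frozenset({"zz"})),
            )
        )
        results = repo(instance10, db, B=100, seed=1)
        kept = restrict_to_instance(db, instance10).n_compounds
        dropped = db.n_compounds - kept
        assert len(results) + dropped == db.n_compounds

    def test_sorted_by_p_then_ks_then_id(self):
        inst = make_instance(500, seed=2)
        from reposcan import make_null_db
        db = make_null_db(inst, m=30, length_law=(2, 20), seed=3)
        results = repo(inst, db, B=200, seed=4)
        keys = [(r.p, -r.ks, r.compound_id) for r in results]
        assert keys == sorted(keys)

    def test_q_nondecreasing_in_p(self):
        inst = make_instance(300, seed=9)
        from reposcan import make_null_db
        db = make_null_db(inst, m=40, length_law=(2, 15), seed=10)
        results = repo(inst, db, B=200, seed=11)
        by_p = sorted(results, key=lambda r: r.p)
        qs = [r.q for r in by_p]
        assert qs == sorted(qs)
        assert all(0 <= r.q <= 1 for r in results)
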