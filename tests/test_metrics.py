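"""Entropy, mutual information, VI, normalized VI, match ratio.

The VI worked values on the partitions of a 4-element set are pinned
exactly; metric axioms, convex additivity, n-invariance, and the
dual-route identity (VI via the entropy sum vs. via the meet partition)
are checked on seeded random partitions.  Mutual information is
cross-checked against scikit-learn's independent implementation.
"""

import math

import pytest

import delimetrics as dm
from delimetrics.partition import meet

from conftest import random_pair

TOL = 1e-9


class TestEntropy:
    def test_single_block_zero(self):
        assert dm.entropy(dm.build_partition([["a", "b", "c", "d"]])) == 0.0

    def test_equal_halves_one_bit(self):
        assert dm.entropy(dm.build_partition([["a", "b"], ["c", "d"]])) == pytest.approx(1.0)

    def test_quarter_quarter_half(self):
        # -(1/4 log 1/4 + 1/4 log 1/4 + 1/2 log 1/2) = 1.5 bits
        p = dm.build_partition([["a"], ["b"], ["c", "d"]])
        assert dm.entropy(p) == pytest.approx(1.5)

    def test_bounded_by_log_n(self, rng):
        for _ in range(30):
            p = dm.random_partition(int(rng.integers(1, 30)), rng)
            h = dm.entropy(p)
            assert -TOL <= h <= math.log2(p.n) + TOL

    def test_matches_scipy_oracle(self, rng):
        from scipy.stats import entropy as scipy_entropy

        for _ in range(10):
            p = dm.random_partition(20, rng)
            assert dm.entropy(p) == pytest.approx(
                scipy_entropy(dm.block_probabilities(p), base=2), abs=TOL
            )

    def test_natural_log_base_option(self):
        p = dm.build_partition([["a", "b"], ["c", "d"]])
        assert dm.entropy(p, base=math.e) == pytest.approx(math.log(2))


class TestMutualInformation:
    def test_trivial_partition_gives_zero(self, abcd):
        for p in abcd.values():
            assert dm.mutual_information(p, abcd["one_block"]) == pytest.approx(0.0)

    def test_self_information_is_entropy(self, rng):
        for _ in range(10):
            p = dm.random_partition(int(rng.integers(2, 25)), rng)
            assert dm.mutual_information(p, p) == pytest.approx(dm.entropy(p), abs=TOL)

    def test_halves_vs_singletons(self, abcd):
        assert dm.mutual_information(abcd["halves"], abcd["singletons"]) == pytest.approx(1.0)

    def test_symmetric_and_bounded(self, rng):
        for _ in range(50):
            u, v = random_pair(rng)
            mi = dm.mutual_information(u, v)
            assert mi == pytest.approx(dm.mutual_information(v, u), abs=TOL)
            assert -TOL <= mi <= min(dm.entropy(u), dm.entropy(v)) + TOL

    def test_matches_sklearn_oracle(self, rng):
        """Independent route: sklearn's MI on element-wise block labels."""
        from sklearn.metrics import mutual_info_score

        for _ in range(20):
            u, v = random_pair(rng, n_max=25)
            elems = sorted(u.elements)
            lu = [u.blocks.index(u.block_of(e)) for e in elems]
            lv = [v.blocks.index(v.block_of(e)) for e in elems]
            expected = mutual_info_score(lu, lv) / math.log(2)
            assert dm.mutual_information(u, v) == pytest.approx(expected, abs=1e-9)


class TestJointEntropy:
    def test_self_joint_is_entropy(self, abcd):
        for p in abcd.values():
            assert dm.joint_entropy(p, p) == pytest.approx(dm.entropy(p), abs=TOL)

    def test_halves_vs_singletons(self, abcd):
        assert dm.joint_entropy(abcd["halves"], abcd["singletons"]) == pytest.approx(2.0)

    def test_trivial_partner_adds_nothing(self, abcd):
        for p in abcd.values():
            assert dm.joint_entropy(abcd["one_block"], p) == pytest.approx(
                dm.entropy(p), abs=TOL
            )

    def test_identities_and_bounds(self, rng):
        for _ in range(50):
            u, v = random_pair(rng)
            h1, h2 = dm.entropy(u), dm.entropy(v)
            mi = dm.mutual_information(u, v)
            jh = dm.joint_entropy(u, v)
            assert jh == pytest.approx(h1 + h2 - mi, abs=TOL)
            assert jh == pytest.approx(dm.entropy(meet(u, v)), abs=TOL)
            assert max(h1, h2) - TOL <= jh <= h1 + h2 + TOL


class TestViDistance:
    def test_worked_values(self, abcd):
        """The canonical 4-element worked examples, exact in bits."""
        assert dm.vi_distance(abcd["one_block"], abcd["halves"]) == pytest.approx(1.0, abs=1e-6)
        assert dm.vi_distance(abcd["a_b_cd"], abcd["halves"]) == pytest.approx(0.5, abs=1e-6)
        assert dm.vi_distance(abcd["one_block"], abcd["singletons"]) == pytest.approx(2.0, abs=1e-6)
        assert dm.vi_distance(abcd["halves"], abcd["singletons"]) == pytest.approx(1.0, abs=1e-6)

    def test_half_split_invariant_to_rest_clustering(self):
        """Splitting half the data in two costs 1/2 bit regardless of the rest."""
        u = dm.build_partition([["a", "b"], ["c"], ["d"]])
        v = dm.build_partition([["a", "b"], ["c", "d"]])
        assert dm.vi_distance(u, v) == pytest.approx(0.5, abs=1e-6)
        u2 = dm.build_partition([["a"], ["b"], ["c"], ["d"]])
        v2 = dm.build_partition([["a"], ["b"], ["c", "d"]])
        assert dm.vi_distance(u2, v2) == pytest.approx(0.5, abs=1e-6)

    def test_dual_route_identity(self, rng):
        """Eq-sum route equals meet-entropy route: H1+H2-2I == 2 H(meet)-H1-H2."""
        for _ in range(100):
            u, v = random_pair(rng)
            h1, h2 = dm.entropy(u), dm.entropy(v)
            via_mi = dm.vi_distance(u, v)
            via_meet = 2.0 * dm.entropy(meet(u, v)) - h1 - h2
            assert via_mi == pytest.approx(via_meet, abs=TOL)

    def test_metric_axioms_on_random_triples(self, rng):
        """Non-negativity, symmetry, identity, triangle inequality (200 triples)."""
        checked = 0
        for model, alpha in (("uniform", None), ("crp", 0.8), ("crp", 3.0)):
            for _ in range(67):
                n = int(rng.integers(2, 31))
                kw = {"model": model} if alpha is None else {"model": model, "crp_alpha": alpha}
                u = dm.random_partition(n, rng, **kw)
                v = dm.random_partition(n, rng, **kw)
                w = dm.random_partition(n, rng, **kw)
                duv = dm.vi_distance(u, v)
                assert duv >= 0
                assert duv == pytest.approx(dm.vi_distance(v, u), abs=TOL)
                assert dm.vi_distance(u, u) == pytest.approx(0.0, abs=TOL)
                if u == v:
                    assert duv == pytest.approx(0.0, abs=TOL)
                else:
                    assert duv > 1e-12
                assert dm.vi_distance(u, w) <= duv + dm.vi_distance(v, w) + TOL
                checked += 1
        assert checked >= 200

    def test_convex_additivity_on_disjoint_unions(self, rng):
        """VI on a disjoint union is the size-weighted mix of the part VIs."""
        for _ in range(100):
            n1 = int(rng.integers(2, 12))
            n2 = int(rng.integers(2, 12))
            e1 = [f"x{i}" for i in range(n1)]
            e2 = [f"y{i}" for i in range(n2)]
            a1 = dm.random_partition(n1, rng, elements=e1)
            a2 = dm.random_partition(n1, rng, elements=e1)
            b1 = dm.random_partition(n2, rng, elements=e2)
            b2 = dm.random_partition(n2, rng, elements=e2)
            u = dm.build_partition(list(a1.blocks) + list(b1.blocks))
            v = dm.build_partition(list(a2.blocks) + list(b2.blocks))
            n = n1 + n2
            expected = (n1 / n) * dm.vi_distance(a1, a2) + (n2 / n) * dm.vi_distance(b1, b2)
            assert dm.vi_distance(u, v) == pytest.approx(expected, abs=TOL)

    @pytest.mark.parametrize("m", [2, 3, 10])
    def test_n_invariance_under_element_replication(self, rng, m):
        """Replicating every element m times leaves H, I and VI unchanged."""
        for _ in range(10):
            u, v = random_pair(rng, n_max=15)

            def replicate(p):
                return dm.build_partition(
                    [[f"{lab}#{r}" for lab in blk for r in range(m)] for blk in p.blocks]
                )

            ur, vr = replicate(u), replicate(v)
            assert dm.entropy(ur) == pytest.approx(dm.entropy(u), abs=TOL)
            assert dm.mutual_information(ur, vr) == pytest.approx(
                dm.mutual_information(u, v), abs=TOL
            )
            assert dm.vi_distance(ur, vr) == pytest.approx(dm.vi_distance(u, v), abs=TOL)

    def test_vanishing_singleton_split(self):
        """VI(all together | one split off) shrinks with n; MR stays at 0."""
        prev = None
        for n in range(2, 60):
            labs = [f"s{i}" for i in range(n)]
            whole = dm.build_partition([labs])
            split = dm.build_partition([[labs[0]], labs[1:]])
            vi = dm.vi_distance(whole, split)
            if prev is not None:
                assert vi < prev
            prev = vi
            assert dm.match_ratio(whole, split) == 0.0
        labs = [f"s{i}" for i in range(1000)]
        vi1000 = dm.vi_distance(
            dm.build_partition([labs]), dm.build_partition([[labs[0]], labs[1:]])
        )
        assert vi1000 < 0.02
        # the split cost is exactly the binary entropy H2(1/n)
        h2 = -(1 / 1000) * math.log2(1 / 1000) - (999 / 1000) * math.log2(999 / 1000)
        assert vi1000 == pytest.approx(h2, abs=TOL)

    def test_incomparable_domains_raise(self):
        u = dm.build_partition([["a", "b"]])
        v = dm.build_partition([["a", "c"]])
        with pytest.raises(dm.IncomparableDomainsError):
            dm.vi_distance(u, v)
        with pytest.raises(dm.IncomparableDomainsError):
            dm.match_ratio(u, v)


class TestBounds:
    def test_upper_bound_function(self):
        assert dm.vi_upper_bound(n=4) == pytest.approx(2.0)
        assert dm.vi_upper_bound(max_k=2) == pytest.approx(2.0)
        assert dm.vi_upper_bound(n=1) == 0.0
        # the tighter bound applies when both are given
        assert dm.vi_upper_bound(n=100, max_k=2) == pytest.approx(2.0)
        with pytest.raises(ValueError):
            dm.vi_upper_bound()

    def test_bound_attained_at_n4(self, abcd):
        assert dm.vi_distance(abcd["one_block"], abcd["singletons"]) == pytest.approx(
            dm.vi_upper_bound(n=4)
        )

    def test_random_pairs_respect_both_bounds(self, rng):
        for _ in range(100):
            u, v = random_pair(rng)
            vi = dm.vi_distance(u, v)
            bound = dm.vi_upper_bound(
                n=u.n, max_k=max(u.num_blocks, v.num_blocks)
            )
            assert vi <= bound + TOL


class TestNormalizedVi:
    def test_identity_is_zero(self, rng):
        for _ in range(10):
            p = dm.random_partition(int(rng.integers(2, 20)), rng)
            assert dm.normalized_vi(p, p) == pytest.approx(0.0, abs=TOL)

    def test_extreme_pair_is_one(self, abcd):
        assert dm.normalized_vi(abcd["one_block"], abcd["singletons"]) == pytest.approx(1.0)

    def test_halves_vs_singletons(self, abcd):
        assert dm.normalized_vi(abcd["halves"], abcd["singletons"]) == pytest.approx(0.5)

    def test_both_trivial_is_zero(self):
        p = dm.build_partition([["a", "b", "c"]])
        assert dm.normalized_vi(p, p) == 0.0

    def test_in_unit_interval(self, rng):
        for variant in ("joint-entropy", "two-log-k", "log-n"):
            for _ in range(40):
                u, v = random_pair(rng)
                nvi = dm.normalized_vi(u, v, variant=variant)
                assert 0.0 <= nvi <= 1.0

    def test_unknown_variant_rejected(self, abcd):
        with pytest.raises(ValueError, match="variant"):
            dm.normalized_vi(abcd["halves"], abcd["singletons"], variant="nope")


class TestMatchRatio:
    def test_worked_values(self, abcd):
        assert dm.match_ratio(abcd["one_block"], abcd["halves"]) == 0.0
        assert dm.match_ratio(abcd["halves"], abcd["a_b_cd"]) == pytest.approx(0.4)
        assert dm.match_ratio(abcd["a_b_cd"], abcd["singletons"]) == pytest.approx(4 / 7)
        assert dm.match_ratio(abcd["halves"], abcd["singletons"]) == 0.0

    def test_one_block_vs_any_two_block_is_zero(self):
        one = dm.build_partition([["a", "b", "c", "d"]])
        for blocks in ([["a", "b"], ["c", "d"]], [["a"], ["b", "c", "d"]], [["b"], ["a", "c", "d"]]):
            assert dm.match_ratio(one, dm.build_partition(blocks)) == 0.0

    def test_self_is_one(self, rng):
        for _ in range(10):
            p = dm.random_partition(int(rng.integers(1, 20)), rng)
            assert dm.match_ratio(p, p) == 1.0

    def test_symmetric_unit_interval(self, rng):
        for _ in range(50):
            u, v = random_pair(rng)
            mr = dm.match_ratio(u, v)
            assert mr == dm.match_ratio(v, u)
            assert 0.0 <= mr <= 1.0


class TestCompareAll:
    def test_grid_shape_and_self_pairs(self, abcd):
        ps = dm.PartitionSet(list(abcd.values()))
        records = dm.compare_all(ps)
        assert len(records) == 16
        selfs = [r for r in records if r.label_1 == r.label_2]
        assert len(selfs) == 4
        for r in selfs:
            assert r.vi_distance == pytest.approx(0.0, abs=TOL)
            assert r.match_ratio == 1.0

    def test_single_partition(self):
        ps = dm.PartitionSet([dm.build_partition([["a", "b"]])])
        records = dm.compare_all(ps)
        assert len(records) == 1
        assert records[0].vi_distance == 0.0

    def test_reproduces_worked_values(self, abcd):
        ps = dm.PartitionSet(list(abcd.values()))
        rec = {(r.label_1, r.label_2): r for r in dm.compare_all(ps)}
        assert rec[("one_block", "halves")].vi_distance == pytest.approx(1.0, abs=1e-6)
        assert rec[("a_b_cd", "halves")].vi_distance == pytest.approx(0.5, abs=1e-6)
        assert rec[("one_block", "singletons")].vi_distance == pytest.approx(2.0, abs=1e-6)
        assert rec[("halves", "singletons")].vi_distance == pytest.approx(1.0, abs=1e-6)
        assert rec[("halves", "a_b_cd")].match_ratio == pytest.approx(0.4)

    def test_record_internal_identities(self, rng):
        ps = dm.random_partition_set(dm.GeneratorConfig(n_elements=10, n_partitions=6, seed=5))
        for r in dm.compare_all(ps):
            assert r.vi_distance == pytest.approx(
                r.H_1 + r.H_2 - 2 * r.mutual_information, abs=TOL
            )
            assert r.joint_entropy == pytest.approx(
                r.H_1 + r.H_2 - r.mutual_information, abs=TOL
            )
            assert 0 <= r.mutual_information <= min(r.H_1, r.H_2) + TOL
            assert 0 <= r.vi_normalized <= 1
            assert 0 <= r.match_ratio <= 1
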