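"""Closure, the two RAF criteria, maxRAF, subRAF poset, irrRAFs, co-RAFs."""

import random

import pytest

from rafnet import (
    Reaction,
    ReactionSystem,
    SystemTooLargeError,
    ValidationError,
    all_sub_rafs,
    closure,
    irr_rafs,
    is_co_raf,
    is_raf,
    is_reflexively_autocatalytic,
    max_raf,
    union_raf,
)
from conftest import brute_force_rafs, small_test_systems


def make(types, foodset, reactions, catalysis):
    def side(x):
        return (x,) if isinstance(x, str) else tuple(x)

    return ReactionSystem(
        types, [Reaction(rid, side(a), side(b)) for rid, a, b in reactions],
        catalysis, foodset,
    )


CHAIN = make(
    "abc", "a", [("r1", "a", "b"), ("r2", "b", "c")], [("a", "r1"), ("a", "r2")]
)


class TestClosure:
    def test_single_reaction_adds_product(self, eq2):
        res = closure(eq2)
        assert res.available == {"GC", "PC", "mC", "b1C"}
        assert res.order == ("r1",)

    def test_empty_foodset_generates_nothing(self, eq2):
        res = closure(eq2, foodset=())
        assert res.available == frozenset() and res.order == ()

    def test_chain_fires_in_dependency_order(self):
        res = closure(CHAIN)
        assert res.available == {"a", "b", "c"}
        assert res.order == ("r1", "r2")

    def test_unknown_reaction_id(self, eq2):
        with pytest.raises(ValidationError):
            closure(eq2, subset={"nope"})

    @pytest.mark.parametrize("q", small_test_systems(12, seed0=50), ids=lambda q: f"R{len(q.reactions)}")
    def test_monotone_and_idempotent(self, q):
        res = closure(q)
        assert q.foodset <= res.available
        again = closure(q, foodset=res.available)
        assert again.available == res.available


class TestCriteria:
    def test_foodset_catalyst_satisfies_ra(self, eq2):
        res = is_reflexively_autocatalytic(eq2, {"r1"})
        assert res.is_ra and not res.uncatalyzed

    def test_uncatalyzed_reaction_fails_ra(self, eq2):
        bare = ReactionSystem(eq2.types, eq2.reactions.values(), [], eq2.foodset)
        res = is_reflexively_autocatalytic(bare, {"r1"})
        assert not res.is_ra and res.uncatalyzed == {"r1"}

    def test_mutual_catalysis_through_products(self):
        q = make(
            ["f1", "f2", "x", "y"], ["f1", "f2"],
            [("r1", "f1", "x"), ("r2", "f2", "y")],
            [("y", "r1"), ("x", "r2")],
        )
        res = is_raf(q, {"r1", "r2"})
        assert res.is_ra and res.is_f_generated and res.is_raf

    def test_single_reaction_raf_certificate(self, eq2):
        res = is_raf(eq2, {"r1"})
        assert res.is_raf and res.is_ra and res.is_f_generated
        assert res.closure.available == {"GC", "PC", "mC", "b1C"}

    def test_empty_subset_is_not_a_raf(self, eq2):
        res = is_raf(eq2, set())
        assert not res.is_raf and res.is_ra and res.is_f_generated

    def test_reactant_produced_only_by_excluded_reaction(self):
        q = make(
            "abc", "a", [("r1", "a", "b"), ("r2", "b", "c")],
            [("a", "r1"), ("a", "r2")],
        )
        res = is_raf(q, {"r2"})
        assert not res.is_raf and res.ungenerated == {"r2"}
        assert is_raf(q, {"r1", "r2"}).is_raf


class TestMaxRaf:
    def test_worked_single_reaction_system(self, eq2):
        assert max_raf(eq2).subset == {"r1"}

    def test_no_catalysis_means_no_raf(self, eq2):
        bare = ReactionSystem(eq2.types, eq2.reactions.values(), [], eq2.foodset)
        res = max_raf(bare)
        assert res.subset == frozenset() and not res.is_raf

    def test_no_raf_fixture(self, no_raf_system):
        assert max_raf(no_raf_system).subset == frozenset()

    @pytest.mark.parametrize("q", small_test_systems(10, seed0=7), ids=lambda q: f"R{len(q.reactions)}")
    def test_matches_brute_force_union(self, q):
        rafs = brute_force_rafs(q)
        union = frozenset().union(*rafs) if rafs else frozenset()
        assert max_raf(q).subset == union

    def test_restricted_to_subset(self, final_clive_system):
        assert max_raf(final_clive_system, subset={"r2", "r3"}).subset == {"r2", "r3"}

    def test_restriction_with_no_support_is_empty(self):
        # r2 feeds on r1's product; alone it cannot be F-generated
        assert max_raf(CHAIN, subset={"r2"}).subset == frozenset()

    def test_order_independence_under_shuffles(self):
        for q in small_test_systems(5, seed0=99):
            reference = max_raf(q).subset
            rng = random.Random(1234)
            for _ in range(20):
                rids = list(q.reactions)
                rng.shuffle(rids)
                shuffled = ReactionSystem(
                    q.types, [q.reactions[r] for r in rids], q.catalysis, q.foodset
                )
                assert max_raf(shuffled).subset == reference

    def test_adding_catalysis_never_destroys_a_raf(self):
        rng = random.Random(5)
        for q in small_test_systems(10, seed0=31):
            before = max_raf(q).subset
            t = rng.choice(sorted(q.types))
            r = rng.choice(sorted(q.reactions))
            q2 = ReactionSystem(
                q.types, q.reactions.values(), set(q.catalysis) | {(t, r)}, q.foodset
            )
            assert before <= max_raf(q2).subset


class TestSubRafPoset:
    def test_single_raf_system(self, eq2):
        assert all_sub_rafs(eq2) == [frozenset({"r1"})]

    def test_no_raf_system_yields_empty_list(self, no_raf_system):
        assert all_sub_rafs(no_raf_system) == []

    def test_size_cap_enforced(self, eq2):
        with pytest.raises(SystemTooLargeError):
            all_sub_rafs(eq2, limit=0)

    def test_unique_maximal_element_is_max_raf(self, final_clive_system):
        subs = all_sub_rafs(final_clive_system)
        top = max_raf(final_clive_system).subset
        assert max(subs, key=len) == top
        assert all(s <= top for s in subs)

    def test_closed_under_pairwise_union(self, final_clive_system):
        subs = all_sub_rafs(final_clive_system)
        as_set = set(subs)
        for s in subs:
            for t in subs:
                assert s | t in as_set


class TestIrrRafs:
    def test_three_in_final_worked_example(self, final_clive_system):
        irr = irr_rafs(final_clive_system, "exhaustive")
        assert irr == [frozenset({"r1"}), frozenset({"r2"}), frozenset({"r3"})]
        assert frozenset().union(*irr) == max_raf(final_clive_system).subset

    def test_single_reaction_raf_is_irreducible(self, eq2):
        assert irr_rafs(eq2, "exhaustive") == [frozenset({"r1"})]

    def test_removing_any_reaction_from_an_irr_raf_kills_it(self, final_clive_system):
        for s in irr_rafs(final_clive_system, "exhaustive"):
            for rid in s:
                assert not max_raf(final_clive_system, subset=s - {rid}).subset

    def test_sampled_subset_of_exhaustive_across_seeds(self, final_clive_system):
        exhaustive = set(irr_rafs(final_clive_system, "exhaustive"))
        for seed in range(50):
            sampled = irr_rafs(final_clive_system, "sampled", seed=seed, n_samples=5)
            assert set(sampled) <= exhaustive

    def test_sampled_mode_requires_seed(self, eq2):
        with pytest.raises(ValueError, match="seed"):
            irr_rafs(eq2, "sampled")


@pytest.fixture
def extended(eq2):
    # r2 consumes the base RAF's product b1C and is catalyzed by it
    reactions = list(eq2.reactions.values()) + [Reaction("r2", ("b1C",), ("e",))]
    return ReactionSystem(
        set(eq2.types) | {"e"}, reactions,
        set(eq2.catalysis) | {("b1C", "r2")}, eq2.foodset,
    )


class TestCoRafAndUnion:
    def test_dependent_addition_is_a_co_raf(self, extended):
        assert not is_raf(extended, {"r2"}).is_raf
        assert is_co_raf(extended, {"r2"}, {"r1"})

    def test_addition_that_is_itself_a_raf_is_not_a_co_raf(self, final_clive_system):
        assert not is_co_raf(final_clive_system, {"r2"}, {"r1"})

    def test_empty_addition_rejected(self, extended):
        with pytest.raises(ValidationError, match="non-empty"):
            is_co_raf(extended, set(), {"r1"})

    def test_base_must_be_a_raf(self, extended):
        with pytest.raises(ValidationError, match="not a RAF"):
            is_co_raf(extended, {"r1"}, {"r2"})

    def test_union_of_disjoint_rafs(self, final_clive_system):
        res = union_raf(final_clive_system, {"r1"}, {"r2"})
        assert res.is_raf and res.subset == {"r1", "r2"}

    def test_union_is_idempotent(self, eq2):
        assert union_raf(eq2, {"r1"}, {"r1"}).subset == {"r1"}

    def test_union_rejects_non_raf_input(self, no_raf_system):
        with pytest.raises(ValidationError, match="not a RAF"):
            union_raf(no_raf_system, {"r1"}, {"r2"})

    def test_all_pairwise_unions_on_example_poset(self, final_clive_system):
        subs = all_sub_rafs(final_clive_system)
        for s in subs:
            for t in subs:
                assert union_raf(final_clive_system, s, t).is_raf
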