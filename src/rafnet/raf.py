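"""RAF detection: closure, the two RAF criteria, maxRAF, subRAFs, irrRAFs.

A non-empty reaction subset R' of a catalytic reaction system Q = (X, R, C, F)
is a **RAF** when

1. it is *reflexively autocatalytic* (RA): every reaction in R' has at least
   one catalyst that is in the foodset F or among the products of R'; and
2. it is *F-generated*: every reactant of every reaction in R' lies in the
   closure of F under R' — the least set W ⊇ F such that any reaction in R'
   with all reactants in W has its products in W.

Catalyst availability plays no role in the closure/F-generated criterion;
the two criteria are checked independently and combined.

The maxRAF (union of all RAFs, unique maximal element of the subRAF poset)
is computed by the polynomial-time interleaved-pruning fixed point: starting
from all of R, repeatedly compute W = closure(F, R') and delete reactions
whose reactants are not all in W or that have no catalyst in W.  At the
fixed point the surviving set, if non-empty, is a RAF and contains every
RAF, hence is the maxRAF.  ``all_sub_rafs`` is the brute-force enumeration
(exponential — capped), used as the in-package certificate for the poset
structure; irreducible RAFs come either from that enumeration (minimal
elements) or from a seeded random-shrinking sampler that scales to larger
systems.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Optional, Sequence

from .reaction_system import ReactionSystem, ValidationError

__all__ = [
    "ClosureResult",
    "RafResult",
    "SystemTooLargeError",
    "closure",
    "is_reflexively_autocatalytic",
    "is_raf",
    "max_raf",
    "all_sub_rafs",
    "irr_rafs",
    "is_co_raf",
    "union_raf",
    "analysis_report",
]


class SystemTooLargeError(ValueError):
    """Raised when exhaustive enumeration is requested beyond the size cap."""


@dataclass(frozen=True)
class ClosureResult:
    """Least fixed point of firing reactions from the foodset.

    ``available`` is the closure set (always ⊇ F); ``order`` is one
    admissible firing order — each listed reaction has all its reactants
    available before its position.  Reactions whose reactants never become
    available are absent from ``order``.
    """

    available: frozenset[str]
    order: tuple[str, ...]


@dataclass(frozen=True)
class RafResult:
    """Certificate for the two RAF criteria on a reaction subset."""

    subset: frozenset[str]
    is_ra: bool
    is_f_generated: bool
    is_raf: bool
    closure: ClosureResult
    uncatalyzed: frozenset[str] = frozenset()
    ungenerated: frozenset[str] = frozenset()

    def __post_init__(self):
        assert self.is_ra == (not self.uncatalyzed)
        assert self.is_f_generated == (not self.ungenerated)
        assert self.is_raf == (bool(self.subset) and self.is_ra and self.is_f_generated)


def _subset_or_all(q: ReactionSystem, subset: Optional[Iterable[str]]) -> frozenset[str]:
    if subset is None:
        return frozenset(q.reactions)
    return q.reaction_subset(subset)


def closure(
    q: ReactionSystem,
    subset: Optional[Iterable[str]] = None,
    foodset: Optional[Iterable[str]] = None,
) -> ClosureResult:
    """Closure of the foodset under a reaction subset (default: all of R).

    Starts from F and repeatedly fires any reaction whose reactants are all
    available, adding its products, until nothing changes.  Catalysts are
    ignored here by design.
    """
    sub = _subset_or_all(q, subset)
    avail = set(q.foodset if foodset is None else foodset)
    pending = sorted(sub)  # sorted => deterministic admissible order
    order: list[str] = []
    changed = True
    while changed and pending:
        changed = False
        still = []
        for rid in pending:
            r = q.reactions[rid]
            if r.reactant_set <= avail:
                avail |= r.product_set
                order.append(rid)
                changed = True
            else:
                still.append(rid)
        pending = still
    return ClosureResult(frozenset(avail), tuple(order))


def _evaluate(q: ReactionSystem, sub: frozenset[str]) -> RafResult:
    cl = closure(q, sub)
    products: set[str] = set()
    for rid in sub:
        products |= q.reactions[rid].product_set
    ra_pool = q.foodset | products
    cat_map: dict[str, set[str]] = {rid: set() for rid in sub}
    for c, rid in q.catalysis:
        if rid in cat_map:
            cat_map[rid].add(c)
    uncatalyzed = frozenset(rid for rid in sub if not cat_map[rid] & ra_pool)
    ungenerated = frozenset(
        rid for rid in sub if not q.reactions[rid].reactant_set <= cl.available
    )
    is_ra = not uncatalyzed
    is_fgen = not ungenerated
    return RafResult(
        subset=sub,
        is_ra=is_ra,
        is_f_generated=is_fgen,
        is_raf=bool(sub) and is_ra and is_fgen,
        closure=cl,
        uncatalyzed=uncatalyzed,
        ungenerated=ungenerated,
    )


def is_reflexively_autocatalytic(q: ReactionSystem, subset: Iterable[str]) -> RafResult:
    """RA criterion: every reaction catalyzed by something in F ∪ products(R')."""
    return _evaluate(q, _subset_or_all(q, subset))


def is_raf(q: ReactionSystem, subset: Iterable[str]) -> RafResult:
    """Full RAF certificate: non-empty ∧ RA ∧ F-generated."""
    return _evaluate(q, _subset_or_all(q, subset))


def max_raf(q: ReactionSystem, subset: Optional[Iterable[str]] = None) -> RafResult:
    """The unique maximal RAF within ``subset`` (default: all reactions).

    Interleaved-pruning fixed point; an empty surviving set means the
    (sub)system contains no RAF.  The result is independent of reaction
    iteration order because each sweep removes exactly the reactions that
    fail either criterion against the current closure.
    """
    cur = set(_subset_or_all(q, subset))
    cat_map: dict[str, set[str]] = {rid: set() for rid in cur}
    for c, rid in q.catalysis:
        if rid in cat_map:
            cat_map[rid].add(c)
    while True:
        w = closure(q, cur).available
        keep = {
            rid
            for rid in cur
            if q.reactions[rid].reactant_set <= w and cat_map[rid] & w
        }
        if keep == cur:
            break
        cur = keep
    return _evaluate(q, frozenset(cur))


def all_sub_rafs(q: ReactionSystem, limit: int = 14) -> list[frozenset[str]]:
    """All RAFs of ``q`` by exhaustive scan of non-empty reaction subsets.

    Exponential in |R|; refuses systems with more than ``limit`` reactions.
    Output sorted canonically (by size, then by sorted reaction ids).  The
    collection is a poset under inclusion: closed under union, with the
    maxRAF as its unique maximal element when non-empty.
    """
    rids = sorted(q.reactions)
    m = len(rids)
    if m > limit:
        raise SystemTooLargeError(
            f"|R| = {m} exceeds the exhaustive-enumeration cap ({limit})"
        )
    found: list[frozenset[str]] = []
    for mask in range(1, 1 << m):
        sub = frozenset(rids[i] for i in range(m) if mask >> i & 1)
        if _evaluate(q, sub).is_raf:
            found.append(sub)
    found.sort(key=lambda s: (len(s), sorted(s)))
    return found


def irr_rafs(
    q: ReactionSystem,
    mode: str = "exhaustive",
    seed: Optional[int] = None,
    n_samples: int = 30,
    limit: int = 14,
) -> list[frozenset[str]]:
    """Irreducible RAFs: RAFs containing no smaller RAF.

    ``mode="exhaustive"`` takes the minimal elements of the subRAF poset
    (subject to the enumeration cap).  ``mode="sampled"`` (requires ``seed``)
    repeatedly shrinks the maxRAF: remove a random reaction and recompute the
    maxRAF inside the remainder, until no single removal leaves any RAF —
    which certifies irreducibility.  Sampling may miss irrRAFs but never
    returns a reducible one; results are deduplicated and sorted.
    """
    if mode == "exhaustive":
        subs = all_sub_rafs(q, limit=limit)
        return [s for s in subs if not any(t < s for t in subs)]
    if mode != "sampled":
        raise ValueError(f"unknown mode {mode!r}")
    if seed is None:
        raise ValueError("sampled mode requires a seed")
    top = max_raf(q).subset
    if not top:
        return []
    rng = random.Random(seed)
    results: set[frozenset[str]] = set()
    for _ in range(n_samples):
        cur = set(top)
        essential: set[str] = set()
        while True:
            candidates = sorted(cur - essential)
            if not candidates:
                break
            rng.shuffle(candidates)
            progressed = False
            for rid in candidates:
                inner = max_raf(q, subset=cur - {rid}).subset
                if inner:
                    cur = set(inner)
                    essential &= cur
                    progressed = True
                    break
                essential.add(rid)
            if not progressed:
                break
        results.add(frozenset(cur))
    return sorted(results, key=lambda s: (len(s), sorted(s)))


def is_co_raf(
    q: ReactionSystem, addition: Iterable[str], base: Iterable[str]
) -> bool:
    """True iff ``addition`` is a co-RAF of the RAF ``base``.

    A co-RAF is a non-empty reaction set that is not itself a RAF but forms
    one when united with ``base``.  ``base`` must be a RAF and ``addition``
    non-empty and disjoint from it.
    """
    base_set = q.reaction_subset(base)
    add_set = q.reaction_subset(addition)
    if not is_raf(q, base_set).is_raf:
        raise ValidationError("base is not a RAF")
    if not add_set:
        raise ValidationError("addition must be non-empty")
    if add_set & base_set:
        raise ValidationError("addition must be disjoint from base")
    return (not is_raf(q, add_set).is_raf) and is_raf(q, add_set | base_set).is_raf


def union_raf(
    q: ReactionSystem, r1: Iterable[str], r2: Iterable[str]
) -> RafResult:
    """Union of two RAFs — always itself a RAF (why the maxRAF is unique)."""
    s1, s2 = q.reaction_subset(r1), q.reaction_subset(r2)
    for s, name in ((s1, "r1"), (s2, "r2")):
        if not is_raf(q, s).is_raf:
            raise ValidationError(f"{name} is not a RAF")
    return is_raf(q, s1 | s2)


def analysis_report(
    q: ReactionSystem,
    exhaustive_cap: int = 14,
    seed: int = 0,
    n_samples: int = 30,
) -> dict:
    """JSON-ready summary: maxRAF, irrRAFs, subRAF count, certificates.

    Falls back to sampled irrRAF search (and omits the subRAF count) when the
    system exceeds the exhaustive cap.
    """
    mr = max_raf(q)
    report: dict = {
        "report_version": 1,
        "n_reactions": len(q.reactions),
        "maxRAF": sorted(mr.subset),
        "certificates": {
            "maxRAF": {
                "is_RA": mr.is_ra,
                "is_F_generated": mr.is_f_generated,
                "is_RAF": mr.is_raf,
                "closure": sorted(mr.closure.available),
                "order": list(mr.closure.order),
            }
        },
    }
    if len(q.reactions) <= exhaustive_cap:
        subs = all_sub_rafs(q, limit=exhaustive_cap)
        report["subRAF_count"] = len(subs)
        report["irrRAFs"] = [sorted(s) for s in irr_rafs(q, "exhaustive", limit=exhaustive_cap)]
        report["irrRAF_mode"] = "exhaustive"
    else:
        report["subRAF_count"] = None
        report["irrRAFs"] = [sorted(s) for s in irr_rafs(q, "sampled", seed=seed, n_samples=n_samples)]
        report["irrRAF_mode"] = "sampled"
    return report
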