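"""Shared fixtures and the independent brute-force RAF oracle.

The oracle re-implements the two RAF criteria directly from their
definitions (closure by naive repeated sweeps, catalysis pooled from
F ∪ products) over every non-empty reaction subset.  It shares no code with
``rafnet.raf`` so that maxRAF results are certified by an independent route.
"""

from __future__ import annotations

import pytest

from rafnet import (
    PolymerModelParams,
    binary_polymer_system,
    build_clive_thera,
    mind_to_system,
    random_mind,
    subsample_reactions,
)
from rafnet.datasets import load_fixture


def brute_force_rafs(q):
    """All RAFs of q by definition-level exhaustive scan (independent oracle)."""
    rids = sorted(q.reactions)
    m = len(rids)
    assert m <= 14, "oracle is exponential; keep test systems small"
    cat = {rid: set() for rid in rids}
    for c, rid in q.catalysis:
        cat[rid].add(c)
    rafs = []
    for mask in range(1, 1 << m):
        sub = [rids[i] for i in range(m) if mask >> i & 1]
        # F-generated: closure of F under sub covers every reactant
        avail = set(q.foodset)
        changed = True
        while changed:
            changed = False
            for rid in sub:
                r = q.reactions[rid]
                if set(r.reactants) <= avail and not set(r.products) <= avail:
                    avail |= set(r.products)
                    changed = True
        if not all(set(q.reactions[rid].reactants) <= avail for rid in sub):
            continue
        # reflexively autocatalytic: catalyst in F or among sub's products
        pool = set(q.foodset)
        for rid in sub:
            pool |= set(q.reactions[rid].products)
        if all(cat[rid] & pool for rid in sub):
            rafs.append(frozenset(sub))
    return rafs


def small_test_systems(count, seed0=0, max_reactions=12):
    """Mixed battery of small seeded systems: subsampled binary-polymer
    chemistries and random cognitive networks bridged to reaction systems."""
    systems = []
    n_polymer = (count * 3) // 5
    probs = [0.02, 0.05, 0.1, 0.2]
    for i in range(n_polymer):
        p = probs[i % len(probs)]
        q = binary_polymer_system(PolymerModelParams(3, 2, p, seed0 + i))
        systems.append(subsample_reactions(q, max_reactions, seed0 + 1000 + i))
    for i in range(count - n_polymer):
        mind = random_mind(
            n_items=16,
            n_reactions=max_reactions,
            catalysis_prob=0.08,
            derived_fraction=max_reactions / 16,
            seed=seed0 + 2000 + i,
        )
        systems.append(mind_to_system(mind))
    return systems


@pytest.fixture(scope="session")
def eq2():
    return load_fixture("eq2")


@pytest.fixture(scope="session")
def no_raf_system():
    return load_fixture("no_raf")


@pytest.fixture(scope="session")
def clive_thera():
    return build_clive_thera()


@pytest.fixture(scope="session")
def final_clive_system(clive_thera):
    return mind_to_system(clive_thera.client)
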