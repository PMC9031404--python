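"""Seeded generators: the binary polymer model and random cognitive networks.

The binary polymer model is the classic toy chemistry for studying the
emergence of autocatalytic sets: types are all binary strings up to a
maximum length ``n``; the foodset is the strings of length ≤ ``t`` (the
monomers and short oligomers assumed freely available); reactions are all
ordered ligations ``a + b -> ab`` with ``|ab| ≤ n``; and catalysis assigns
each (type, reaction) pair independently with probability ``p``.  Only the
ligation direction is represented (the minimal, cleavage-free variant).  As
``p`` grows, the system crosses a sharp phase transition from containing no
RAF to almost surely containing one; :func:`phase_experiment` traces that
curve.

``random_mind`` builds random — but invariant-satisfying — cognitive
networks for property testing of the cognitive layer.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .cognitive import Mind
from .raf import max_raf
from .reaction_system import Reaction, ReactionSystem, ValidationError

__all__ = [
    "PolymerModelParams",
    "binary_polymer_system",
    "polymer_reaction_count",
    "phase_experiment",
    "subsample_reactions",
    "random_mind",
]


@dataclass(frozen=True)
class PolymerModelParams:
    """Parameters of the binary polymer model.

    max_length: longest polymer ``n`` (≥ 2); food_max_length: ``t``, the
    length bound of the freely available foodset (default 2, the customary
    monomer+dimer foodset); catalysis_prob: per-(type, reaction) Bernoulli
    probability ``p``; seed: RNG seed for the catalysis draw.
    """

    max_length: int
    food_max_length: int = 2
    catalysis_prob: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.max_length < 2:
            raise ValidationError("max_length must be >= 2")
        if not 1 <= self.food_max_length <= self.max_length:
            raise ValidationError("need 1 <= food_max_length <= max_length")
        if not 0.0 <= self.catalysis_prob <= 1.0:
            raise ValidationError("catalysis_prob must be in [0, 1]")


def _all_strings(max_len: int) -> list[str]:
    out: list[str] = []
    for length in range(1, max_len + 1):
        out.extend("".join(bits) for bits in itertools.product("01", repeat=length))
    return out


def polymer_reaction_count(max_length: int) -> int:
    """Closed-form count of ligations a+b->ab with |ab| <= max_length.

    A product of length L has L-1 ordered splits and there are 2^L products:
    sum_{L=2..n} (L-1) * 2^L.
    """
    return sum((L - 1) * 2**L for L in range(2, max_length + 1))


def binary_polymer_system(params: PolymerModelParams) -> ReactionSystem:
    """Instantiate the binary polymer model as a :class:`ReactionSystem`.

    Reaction ids are ``"{a}_{b}"`` for the ligation ``a + b -> ab``.  The
    catalysis draw is a single vectorized Bernoulli sample over all
    (type, reaction) pairs, so the system is reproducible from the seed
    independently of iteration order.
    """
    types = _all_strings(params.max_length)
    foodset = [s for s in types if len(s) <= params.food_max_length]
    reactions: list[Reaction] = []
    for ab in types:
        if len(ab) < 2:
            continue
        for cut in range(1, len(ab)):
            a, b = ab[:cut], ab[cut:]
            reactions.append(Reaction(f"{a}_{b}", (a, b), (ab,)))
    reactions.sort(key=lambda r: r.id)

    catalysis: list[tuple[str, str]] = []
    p = params.catalysis_prob
    stypes = sorted(types)  # canonical axis order -> platform-independent draw
    if p > 0:
        rng = np.random.default_rng(params.seed)
        hits = rng.random((len(stypes), len(reactions))) < p
        ti, ri = np.nonzero(hits)
        catalysis = [(stypes[i], reactions[j].id) for i, j in zip(ti.tolist(), ri.tolist())]

    return ReactionSystem(types, reactions, catalysis, foodset)


def subsample_reactions(q: ReactionSystem, k: int, seed: int) -> ReactionSystem:
    """Random sub-system with ``k`` of q's reactions (same X and F).

    Handy for producing small systems amenable to exhaustive RAF enumeration
    while keeping the polymer structure.
    """
    rids = sorted(q.reactions)
    if k > len(rids):
        raise ValidationError(f"cannot take {k} of {len(rids)} reactions")
    rng = np.random.default_rng(seed)
    keep = [rids[i] for i in rng.choice(len(rids), size=k, replace=False)]
    return q.restrict(keep)


def phase_experiment(
    n: int,
    t: int,
    p_grid: Sequence[float],
    replicates: int,
    seed: int,
    max_n: int = 8,
    max_replicates: int = 100,
    override_bounds: bool = False,
) -> pd.DataFrame:
    """RAF-emergence curve of the binary polymer model across catalysis rates.

    For each ``p`` in ``p_grid``, generates ``replicates`` independent
    systems (sub-seed of replicate ``r`` at grid point ``i`` derived by the
    counter scheme ``seed * 10_000 + i * 100 + r``, so any replicate is
    reproducible in isolation) and records the fraction with a non-empty
    maxRAF and the mean maxRAF size.  Desk-scale bounds (n ≤ 8,
    replicates ≤ 100) guard against accidental huge runs; pass
    ``override_bounds=True`` to exceed them.
    """
    if not override_bounds and (n > max_n or replicates > max_replicates):
        raise ValidationError(
            f"n={n}, replicates={replicates} exceed desk-scale bounds "
            f"(n <= {max_n}, replicates <= {max_replicates}); "
            "pass override_bounds=True to force"
        )
    rows = []
    for i, p in enumerate(p_grid):
        found = 0
        sizes = []
        for r in range(replicates):
            sub_seed = seed * 10_000 + i * 100 + r
            q = binary_polymer_system(
                PolymerModelParams(n, t, float(p), sub_seed)
            )
            m = max_raf(q).subset
            found += bool(m)
            sizes.append(len(m))
        rows.append(
            {
                "p": float(p),
                "replicates": replicates,
                "raf_fraction": found / replicates,
                "mean_maxraf_size": float(np.mean(sizes)),
            }
        )
    return pd.DataFrame(rows)


def plot_phase_curve(table: pd.DataFrame, path: str) -> None:
    """Optional visual of the phase curve (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(table["p"], table["raf_fraction"], marker="o")
    ax.set_xscale("symlog", linthresh=1e-4)
    ax.set_xlabel("catalysis probability p")
    ax.set_ylabel("fraction of systems with a RAF")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def random_mind(
    n_items: int,
    n_reactions: int,
    catalysis_prob: float,
    derived_fraction: float,
    seed: int,
) -> Mind:
    """A random cognitive network satisfying all Mind invariants.

    ``round(n_items * derived_fraction)`` items are foodset-derived, each the
    product of its own redescription whose reactants and catalyst are drawn
    from the items already present (so provenance chains always ground in the
    foodset).  Foodset provenance is sampled from innate/individual (social
    provenance needs a source mind, which a standalone generated mind lacks).
    Extra catalysis edges are added per (item, reaction) pair with
    probability ``catalysis_prob``.  Requires ``n_reactions`` equal to the
    number of derived items (each reaction makes exactly one new MR).
    """
    n_derived = round(n_items * derived_fraction)
    n_food = n_items - n_derived
    if n_food < 1:
        raise ValidationError("need at least one foodset item")
    if n_reactions != n_derived:
        raise ValidationError(
            f"n_reactions ({n_reactions}) must equal the derived-item count "
            f"({n_derived} = round(n_items * derived_fraction))"
        )
    rng = np.random.default_rng(seed)
    mind = Mind(f"mind{seed}")
    for i in range(n_food):
        prov = "innate" if rng.random() < 0.25 else "individual"
        mind.add_foodset_item(f"x{i}", f"foodset item {i}", prov)
    for j in range(n_derived):
        pool = sorted(mind.items)
        k = int(rng.integers(1, min(3, len(pool)) + 1))
        reactants = [pool[i] for i in rng.choice(len(pool), size=k, replace=False)]
        catalyst = pool[int(rng.integers(len(pool)))]
        mind.redescribe(reactants, catalyst, f"derived item {j}", product_id=f"y{j}")
    if catalysis_prob > 0 and mind.reactions:
        items = sorted(mind.items)
        rids = sorted(mind.reactions)
        hits = rng.random((len(items), len(rids))) < catalysis_prob
        for i, j in zip(*np.nonzero(hits)):
            mind.catalysis.add((items[int(i)], rids[int(j)]))
    return mind
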