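# Methods

## Model

A catalytic reaction system is Q = (X, R, C, F). Reactant/product sides are
multisets (chemistry allows `a + a -> b`), but all availability logic —
closure, the RAF criteria — operates on the underlying sets of distinct
types: the F-generated criterion is about whether a type is *obtainable*,
not about stoichiometric bookkeeping, and the model carries no counts or
kinetics. Multiplicity therefore affects serialization and display only.

A non-empty R′ ⊆ R is a RAF iff (1) every r ∈ R′ has a catalyst in
F ∪ products(R′) (reflexive autocatalysis) and (2) every reactant of R′ is
in cl_{R′}(F), the closure of F under R′ (F-generated). The two criteria
are deliberately independent: catalysts play no role in closure. Both are
computed by `is_raf`, which returns a certificate (the closure set, an
admissible firing order, and the per-reaction failure lists `uncatalyzed` /
`ungenerated`).

### maxRAF reduction

`max_raf` iterates, from R′ = R: compute W = cl_{R′}(F); delete every
reaction with a reactant outside W or with no catalyst in W; repeat to a
fixed point. Each sweep removes exactly the reactions that cannot belong to
any RAF inside the current set, so the fixed point contains every RAF and —
when non-empty — is itself a RAF: the unique maximal one. The loop is
O(|R|² · reaction size) in the worst case. Order independence follows from
the sweep semantics (deletions are computed against W, not incrementally);
the test suite additionally certifies the result against a definition-level
brute-force scan of all non-empty subsets on ~100 seeded systems with
|R| ≤ 12, and under 20 random permutations of reaction insertion order.

### SubRAF poset, irreducible RAFs, co-RAFs

`all_sub_rafs` enumerates all RAFs by brute force (refusing systems beyond a
cap, default 14 reactions): the collection is a poset under inclusion, closed
under pairwise union, with the maxRAF as unique maximal element. Irreducible
RAFs (`irr_rafs`) are its minimal elements in exhaustive mode; in sampled
mode a working RAF is repeatedly shrunk — remove a random reaction, recompute
the maxRAF of the remainder — until no single removal leaves any RAF, which
certifies irreducibility (any proper subRAF would survive inside some
single-reaction removal). Sampling can miss irrRAFs but never reports a
reducible set; it takes a mandatory seed and deduplicates across restarts.
`is_co_raf` checks the definitional pair of conditions (not a RAF alone,
RAF when united with the base); `union_raf` validates both inputs and
returns the certified union.

## Cognitive instantiation

A `Mind` i holds mental representations X_i partitioned by provenance into
the foodset F_i (innate I_i; social S_i[x_j] with source mind and item;
individual S_i[ℓ]) and the derived set ¬F_i (each item recording the single
redescription that produced it). The partition, reference integrity, and
groundedness (every derived item's derivation DAG bottoms out in F_i) are
construction invariants, not post-hoc checks:

- `add_foodset_item` accepts only innate/individual provenance;
- `transmit` is the only way to obtain social items, and it always lands in
  the *recipient's foodset* regardless of the item's status in the source —
  the generational rule: one mind's creative product is the next mind's raw
  material. The origin-mind tag propagates unchanged, so novelty stays
  attributable to the mind it first arose in;
- `redescribe` is the only way to create derived items; it creates the
  reaction, one catalysis edge, and the product atomically.

`provenance_chain` returns the derivation DAG (items and reactions;
catalysts attached as reaction attributes but not recursively expanded —
a catalyst enables a recoding, it is not its material).

### Impact weights and inhibition

The underlying framework supports only ordinal claims about how strongly a
RAF shapes interpretation, so impact weights are annotations with a
deliberately simple multiplicative rule: registering a RAF label starts it
at 1.0; a supporting event multiplies by 1 + α, an inhibitory item by
1 − β (defaults α = β = 0.5, configurable per mind; 0 < β < 1 keeps weights
strictly positive). Only the direction of change is contractual; absolute
values are not meaningful. Inhibition never structurally blocks a reaction —
RAF detection with hard inhibition is a much harder computational problem,
and the modeled phenomenon is a weakening of a tendency, not its removal —
so inhibition edges live entirely outside the RA/F-generated checks.
"Attractor-state" language about an entrenched belief is represented by the
weight alone; no dynamical-systems simulation is attempted, since the
framework specifies no dynamics.

### The packaged worked example

`build_clive_thera` scripts a dyadic session between a client (Clive) and a
therapist (Thera) as an event log replayed from empty minds (kinds: add,
transmit, react, inhibit, reweight; step labels 1a–7b matching the scenario's
panel annotations). Milestones: the belief "I am stupid" (b1C) forms by
redescription of two memories catalyzed by an insult incident; the client's
self-account transmits to the therapist (her mental model of him); her praise
(BC) and humor-reframe (LC) arrive as social foodset items, the praise
inhibiting the belief RAF; her prompt (qT) catalyzes the reinterpretation of
the bad grade as a video-game joke (VC), which inhibits the belief RAF again;
her laughter (lT) catalyzes the new belief "I am funny" (b2C).

One genuinely ambiguous point is whether the joke-as-told (JC) and the
reinterpreted memory (VC) are one representation or two; the scenario's own
set-update line for the final reaction conflicts with its reaction arrow.
This package keeps them distinct: VC remains foodset-derived, while JC — the
direct in-session experience of telling the joke and getting a laugh — is a
foodset item and the reactant of the final redescription. Under the
alternative one-item reading the final mind has two irreducible RAFs; the
two-item reading yields the three irreducible RAFs {r1}, {r2}, {r3} (whose
union is the maxRAF) that the scenario describes, and is the packaged form.
Therapist-side mirror items (CT etc.) can optionally be folded into the
analyzed system (`rafnet example clive-thera --include-therapist-mirrors`);
being foodset copies with no reactions, they never change the maxRAF.

## Generators

**Binary polymer model.** Types are binary strings of length 1..n; the
foodset is all strings of length ≤ t (default t = 2, the customary
monomer-plus-dimer foodset); reactions are all ordered ligations
`a + b -> ab` with |ab| ≤ n (the ligation-only, cleavage-free variant — the
minimal classic formulation); catalysis is an independent Bernoulli(p) draw
per (type, reaction) pair, vectorized over canonically sorted axes so a seed
fully determines the system on any platform. Expected catalysis events per
reaction are p·|X| (126·p at n = 6), which locates the phase transition near
p ≈ 1/|X|; the default experiment grid {0, 0.002, 0.005, 0.01, 0.02, 0.04,
0.08, 1} brackets it. `phase_experiment` derives the replicate seed by the
counter scheme `seed·10000 + grid_index·100 + replicate`, so any single
replicate is reproducible in isolation; desk-scale bounds (n ≤ 8,
replicates ≤ 100) must be explicitly overridden.

**Random minds.** `random_mind` builds invariant-correct minds through the
public API itself (each derived item via `redescribe` over already-present
items), so property tests exercise exactly the states reachable in normal
use. Foodset provenance is sampled from innate/individual only — social
provenance requires a source mind, which a standalone generated mind lacks;
transmission behavior is tested separately with explicit mind pairs.

## What the synthetic data does and does not show

The generators produce structurally faithful but semantically empty
networks: random polymer chemistries probe the algorithms across the
no-RAF/RAF transition, and random minds probe the provenance machinery at
scale. Neither captures properties of real conceptual networks — meaningful
content, graded association strengths, context-dependent catalysis, or any
empirical distribution of network shape — so green tests certify algorithmic
correctness and invariant preservation, not claims about real minds or real
therapy. The worked example is a hypothetical, illustrative scenario, not
clinical data.

## Numerical and design choices

- All returned collections are canonically sorted (reactions by id; subset
  lists by size then ids); the only RNG uses are the generators and sampled
  irrRAF search, both seed-mandatory.
- Closure returns one deterministic admissible firing order (sorted sweep).
- Exhaustive enumeration caps at 14 reactions (2^14 subsets) by default;
  `analysis_report` falls back to sampled irrRAF search above the cap and
  reports which mode it used.
- Serialization is canonical, versioned (`format_version: 1`), and
  round-trip exact; the text dialect auto-declares types from foodset and
  reaction lines only when no `X:` line is present — an explicit universe
  makes unknown references an error rather than a silent declaration.
- Problem sizes in the test suite and acceptance script (systems with
  ≤ 12 reactions for brute-force certification; polymer n = 6 with 25
  replicates per grid point; 200 random minds) are chosen as the smallest
  scales at which the certified properties are non-trivial, keeping the
  whole suite fast enough to run routinely.

## Known limitations

- No kinetics, concentrations, or stochastic dynamics; no RAF evolution
  under selective proliferation.
- Inhibition is ordinal annotation only (see above); no model of trust,
  motivation, or other moderating variables of a real dyadic interaction.
- Exhaustive subRAF/irrRAF enumeration is exponential and capped; sampled
  irrRAF search is sound but not complete.
- The binary polymer model omits cleavage reactions; phase-transition
  locations shift under other variants.
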