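"""Minds as catalytic reaction networks of mental representations.

This module instantiates the RAF machinery for cognitive networks.  Each
:class:`Mind` ``i`` holds a set of mental representations (MRs) ``X_i``
partitioned into

* the **foodset** ``F_i`` — MRs that came into existence *outside* the
  network: innate knowledge (``I_i``), socially learned content
  (``S_i[x_j]``, carrying the source mind and source item), and individually
  learned content from direct experience (``S_i[l]``); and
* the **foodset-derived** set ``¬F_i`` — MRs produced *inside* the network
  by representational redescription (RR), the cognitive analogue of a
  catalyzed reaction: reactant MRs are recoded into a new product MR, the
  recoding triggered ("catalyzed") by another MR or an external stimulus.

Every MR carries an origin-mind tag so that novelty can be traced to the
mind in which it first arose, even after social transmission: what was
foodset-derived for the originator arrives as *foodset* in the recipient.

Impact weights annotate how strongly a (labelled) RAF of the mind shapes
interpretation.  The network formalism only supports ordinal claims here, so
the update rule is deliberately simple and multiplicative: a supporting
event multiplies a RAF's weight by ``1 + alpha``, an inhibitory (belief-
inconsistent) item by ``1 - beta``; weights stay strictly positive and only
their order matters.  Inhibition weakens — it never structurally blocks a
reaction, so it plays no part in RAF detection itself.

``build_clive_thera`` packages the worked dyadic example of a therapist
(Thera) reshaping a client's (Clive) belief network over one session, as an
event log that replays deterministically from empty minds.
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field, asdict
from typing import Iterable, Optional, Sequence

import networkx as nx

from .reaction_system import Reaction, ReactionSystem, ValidationError, _check_token

__all__ = [
    "Provenance",
    "MentalRepresentation",
    "Mind",
    "SessionEvent",
    "Dyad",
    "transmit",
    "provenance_chain",
    "mind_to_system",
    "apply_event",
    "replay",
    "replay_until",
    "impact_trajectory",
    "build_clive_thera",
    "clive_thera_log",
    "BELIEF_STUPID",
    "JOKE_RAF",
    "BELIEF_FUNNY",
]

FOODSET_KINDS = frozenset({"innate", "social", "individual"})
PROVENANCE_KINDS = FOODSET_KINDS | {"derived"}


@dataclass(frozen=True)
class Provenance:
    """Where an MR came from.

    kind "innate" (I_i), "individual" (S_i[l]), "social" (S_i[x_j]; records
    the source mind and item), or "derived" (¬F_i; records the single
    producing reaction).
    """

    kind: str
    source_mind: Optional[str] = None
    source_item: Optional[str] = None
    reaction: Optional[str] = None

    def __post_init__(self):
        if self.kind not in PROVENANCE_KINDS:
            raise ValidationError(f"unknown provenance kind {self.kind!r}")
        if self.kind == "social" and (self.source_mind is None or self.source_item is None):
            raise ValidationError("social provenance requires source_mind and source_item")
        if self.kind == "derived" and self.reaction is None:
            raise ValidationError("derived provenance requires the producing reaction id")
        if self.kind in ("innate", "individual") and (
            self.source_mind or self.source_item or self.reaction
        ):
            raise ValidationError(f"{self.kind} provenance carries no source fields")


@dataclass(frozen=True)
class MentalRepresentation:
    """One node of a cognitive network: an id, a human-readable label, the
    mind the content originally arose in, and its provenance."""

    id: str
    label: str
    origin_mind: str
    provenance: Provenance

    def __post_init__(self):
        _check_token(self.id, "mental representation")


@dataclass
class Mind:
    """One individual's cognitive network.

    ``items`` is X_i; the foodset/derived split is induced by provenance and
    exposed as properties.  ``rafs`` maps a human label to the reaction set
    it names; ``impact`` carries that RAF's strictly positive weight.
    """

    id: str
    alpha: float = 0.5  # relative weight gain per supporting event
    beta: float = 0.5   # relative weight loss per inhibitory event
    items: dict[str, MentalRepresentation] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    catalysis: set[tuple[str, str]] = field(default_factory=set)
    inhibitions: set[tuple[str, str]] = field(default_factory=set)
    rafs: dict[str, frozenset[str]] = field(default_factory=dict)
    impact: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if not (self.alpha > 0 and 0 < self.beta < 1):
            raise ValidationError("need alpha > 0 and 0 < beta < 1 to keep weights positive")

    # -- structure ----------------------------------------------------------
    @property
    def foodset(self) -> frozenset[str]:
        """F_i — item ids with innate/social/individual provenance."""
        return frozenset(i for i, mr in self.items.items() if mr.provenance.kind != "derived")

    @property
    def derived(self) -> frozenset[str]:
        """¬F_i — item ids produced by this mind's own reactions."""
        return frozenset(i for i, mr in self.items.items() if mr.provenance.kind == "derived")

    def _add(self, mr: MentalRepresentation) -> MentalRepresentation:
        if mr.id in self.items:
            raise ValidationError(f"mind {self.id!r} already holds item {mr.id!r}")
        self.items[mr.id] = mr
        return mr

    def add_foodset_item(
        self, item_id: str, label: str, provenance: str = "individual"
    ) -> MentalRepresentation:
        """Add an innate or individually learned MR to F_i.

        Social items must arrive via :func:`transmit`; derived items only via
        :meth:`redescribe` (the F_i / ¬F_i partition is enforced).
        """
        if provenance not in ("innate", "individual"):
            raise ValidationError(
                f"add_foodset_item accepts innate/individual provenance, not {provenance!r}"
            )
        return self._add(
            MentalRepresentation(item_id, label, self.id, Provenance(provenance))
        )

    def redescribe(
        self,
        reactants: Sequence[str],
        catalyst: str,
        product_label: str,
        product_id: Optional[str] = None,
        reaction_id: Optional[str] = None,
    ) -> tuple[Reaction, MentalRepresentation]:
        """Representational redescription: reactant MRs -> one new derived MR.

        Creates the reaction, a catalysis edge ``(catalyst, reaction)``, and
        the product as a member of ¬F_i.  Unary reactions are allowed.
        """
        if not reactants:
            raise ValidationError("redescription needs at least one reactant")
        missing = [x for x in list(reactants) + [catalyst] if x not in self.items]
        if missing:
            raise ValidationError(f"mind {self.id!r} lacks items {missing}")
        rid = reaction_id or f"r{len(self.reactions) + 1}"
        if rid in self.reactions:
            raise ValidationError(f"duplicate reaction id {rid!r}")
        pid = product_id or f"d{len(self.items) + 1}"
        if pid in self.items:
            raise ValidationError(f"mind {self.id!r} already holds item {pid!r}")
        reaction = Reaction(rid, tuple(reactants), (pid,))
        product = MentalRepresentation(
            pid, product_label, self.id, Provenance("derived", reaction=rid)
        )
        self.reactions[rid] = reaction
        self.catalysis.add((catalyst, rid))
        self._add(product)
        return reaction, product

    # -- impact weights -----------------------------------------------------
    def register_raf(self, label: str, reactions: Iterable[str], weight: float = 1.0) -> None:
        """Name a RAF (a reaction subset) so its impact can be tracked."""
        if weight <= 0:
            raise ValidationError("impact weights must be strictly positive")
        unknown = set(reactions) - self.reactions.keys()
        if unknown:
            raise ValidationError(f"unknown reactions {sorted(unknown)}")
        self.rafs[label] = frozenset(reactions)
        self.impact[label] = float(weight)

    def support_raf(self, raf_label: str) -> float:
        """A supporting catalysis event: strictly increases the RAF's weight."""
        if raf_label not in self.impact:
            raise ValidationError(f"unknown RAF label {raf_label!r}")
        self.impact[raf_label] *= 1.0 + self.alpha
        return self.impact[raf_label]

    def declare_inhibition(self, item_id: str, raf_label: str) -> float:
        """Record that ``item_id`` is inconsistent with the labelled RAF.

        The RAF's impact weight strictly decreases but stays positive; the
        RAF's structure (and hence RAF detection) is untouched.
        """
        if item_id not in self.items:
            raise ValidationError(f"mind {self.id!r} lacks item {item_id!r}")
        if raf_label not in self.impact:
            raise ValidationError(f"unknown RAF label {raf_label!r}")
        self.inhibitions.add((item_id, raf_label))
        self.impact[raf_label] *= 1.0 - self.beta
        return self.impact[raf_label]

    def to_json(self) -> dict:
        return {
            "id": self.id,
            "alpha": self.alpha,
            "beta": self.beta,
            "items": [
                {**asdict(mr), "provenance": {k: v for k, v in asdict(mr.provenance).items() if v is not None}}
                for _, mr in sorted(self.items.items())
            ],
            "reactions": [
                {"id": rid, "reactants": list(r.reactants), "products": list(r.products)}
                for rid, r in sorted(self.reactions.items())
            ],
            "catalysis": sorted(list(e) for e in self.catalysis),
            "inhibitions": sorted(list(e) for e in self.inhibitions),
            "rafs": {k: sorted(v) for k, v in sorted(self.rafs.items())},
            "impact": dict(sorted(self.impact.items())),
        }


def transmit(
    source: Mind,
    item_id: str,
    target: Mind,
    new_id: Optional[str] = None,
    label: Optional[str] = None,
) -> MentalRepresentation:
    """Social transmission of an MR from one mind to another.

    The copy always lands in the *target's foodset* with social provenance —
    even if the item was foodset-derived in the source (the generational
    rule: one mind's creative product is the next mind's raw material).  The
    origin-mind tag of the source item is propagated unchanged.
    """
    if item_id not in source.items:
        raise ValidationError(f"mind {source.id!r} lacks item {item_id!r}")
    src = source.items[item_id]
    nid = new_id or item_id
    mr = MentalRepresentation(
        nid,
        label or src.label,
        src.origin_mind,
        Provenance("social", source_mind=source.id, source_item=item_id),
    )
    return target._add(mr)


def provenance_chain(mind: Mind, item_id: str) -> nx.DiGraph:
    """Derivation DAG of an item: how it traces back to the foodset.

    Nodes are item ids (``kind="item"``) and reaction ids (``kind="reaction"``,
    with the catalyst ids as a node attribute); edges run reactant -> reaction
    -> product.  A foodset item yields the trivial single-node DAG.  Catalyst
    provenance is *not* expanded — catalysts enable a redescription but are
    not its material.
    """
    if item_id not in mind.items:
        raise ValidationError(f"mind {mind.id!r} lacks item {item_id!r}")
    g = nx.DiGraph()
    stack = [item_id]
    while stack:
        iid = stack.pop()
        mr = mind.items[iid]
        in_food = mr.provenance.kind != "derived"
        if iid not in g:
            g.add_node(iid, kind="item", foodset=in_food, label=mr.label)
        if in_food:
            continue
        rid = mr.provenance.reaction
        if rid in g:
            continue
        r = mind.reactions[rid]
        catalysts = sorted(c for c, r2 in mind.catalysis if r2 == rid)
        g.add_node(rid, kind="reaction", catalysts=catalysts)
        g.add_edge(rid, iid)
        for a in r.reactant_set:
            if a not in g:
                amr = mind.items[a]
                g.add_node(a, kind="item", foodset=amr.provenance.kind != "derived",
                           label=amr.label)
                stack.append(a)
            g.add_edge(a, rid)
    return g


def mind_to_system(mind: Mind) -> ReactionSystem:
    """Bridge to the RAF algorithms: X = items, R, C, F = foodset.

    Inhibition edges and impact weights are annotations of the cognitive
    layer and are dropped.
    """
    return ReactionSystem(
        types=mind.items.keys(),
        reactions=mind.reactions.values(),
        catalysis=mind.catalysis,
        foodset=mind.foodset,
    )


# ---------------------------------------------------------------------------
# Session logs and replay
# ---------------------------------------------------------------------------

EVENT_KINDS = frozenset({"add", "transmit", "react", "inhibit", "reweight"})


@dataclass(frozen=True)
class SessionEvent:
    """One step of a dyadic interaction; ``step`` labels match the worked
    example's panel annotations ("1a" ... "7b")."""

    kind: str
    actor: str
    payload: dict
    step: str

    def __post_init__(self):
        if self.kind not in EVENT_KINDS:
            raise ValidationError(f"unknown event kind {self.kind!r}")


@dataclass
class Dyad:
    """Two minds plus the ordered event log that produced them."""

    client: Mind
    therapist: Mind
    log: list[SessionEvent] = field(default_factory=list)

    def mind(self, mind_id: str) -> Mind:
        for m in (self.client, self.therapist):
            if m.id == mind_id:
                return m
        raise ValidationError(f"unknown mind {mind_id!r}")

    def to_json(self) -> dict:
        return {
            "minds": [self.client.to_json(), self.therapist.to_json()],
            "log": [asdict(e) for e in self.log],
        }


def apply_event(dyad: Dyad, event: SessionEvent) -> None:
    """Apply one event to the dyad (mutating the involved mind)."""
    mind = dyad.mind(event.actor)
    p = event.payload
    if event.kind == "add":
        mind.add_foodset_item(p["item_id"], p["label"], p.get("provenance", "individual"))
    elif event.kind == "transmit":
        transmit(mind, p["item"], dyad.mind(p["target"]), new_id=p.get("new_id"),
                 label=p.get("label"))
    elif event.kind == "react":
        mind.redescribe(
            p["reactants"], p["catalyst"], p["product_label"],
            product_id=p.get("product_id"), reaction_id=p.get("reaction_id"),
        )
    elif event.kind == "inhibit":
        mind.declare_inhibition(p["item"], p["raf_label"])
    elif event.kind == "reweight":
        if p["op"] == "register":
            mind.register_raf(p["raf_label"], p["reactions"], p.get("weight", 1.0))
        elif p["op"] == "support":
            mind.support_raf(p["raf_label"])
        else:
            raise ValidationError(f"unknown reweight op {p['op']!r}")


def replay(
    log: Sequence[SessionEvent],
    client_id: str = "Clive",
    therapist_id: str = "Thera",
    alpha: float = 0.5,
    beta: float = 0.5,
) -> Dyad:
    """Rebuild a dyad from empty minds by applying every event in order.

    Deterministic: two replays of the same log yield equal dyads.
    """
    dyad = Dyad(Mind(client_id, alpha, beta), Mind(therapist_id, alpha, beta))
    for ev in log:
        apply_event(dyad, ev)
        dyad.log.append(ev)
    return dyad


def replay_until(log: Sequence[SessionEvent], step: str, **kwargs) -> Dyad:
    """Replay the log prefix up to and including the last event labelled ``step``."""
    idxs = [i for i, ev in enumerate(log) if ev.step == step]
    if not idxs:
        raise ValidationError(f"no event with step label {step!r}")
    return replay(log[: idxs[-1] + 1], **kwargs)


def impact_trajectory(
    log: Sequence[SessionEvent],
    mind_id: str = "Clive",
    client_id: str = "Clive",
    therapist_id: str = "Thera",
    alpha: float = 0.5,
    beta: float = 0.5,
) -> list[tuple[str, dict[str, float]]]:
    """Impact-weight snapshot of one mind after every event of a replay."""
    dyad = Dyad(Mind(client_id, alpha, beta), Mind(therapist_id, alpha, beta))
    traj: list[tuple[str, dict[str, float]]] = []
    for ev in log:
        apply_event(dyad, ev)
        traj.append((ev.step, dict(dyad.mind(mind_id).impact)))
    return traj


# ---------------------------------------------------------------------------
# The packaged worked example: Clive (client) and Thera (therapist)
# ---------------------------------------------------------------------------

BELIEF_STUPID = "belief-i-am-stupid"
JOKE_RAF = "video-game-joke"
BELIEF_FUNNY = "belief-i-am-funny"


def clive_thera_log() -> list[SessionEvent]:
    """Event log of the therapist–client worked example.

    Session outline (step labels match the figure-panel annotations of the
    scenario this example models):

    * intake — Clive's foodset: GC (D− in high-school math), PC (rejected
      after a job interview), mC (his wife calling him a "moron": the
      catalyzing incident), CC (his own account of his concerns).
    * 1a/1b — confirmation bias as redescription: GC + PC →[mC] b1C
      ("I am stupid"), a derived item; the belief RAF {r1} is registered.
    * eq3 — Clive's account CC is socially transmitted to Thera (CT), the
      seed of her mental model of him.
    * 2/3 — Thera's praise BT ("brilliant problem solver") transmitted to
      Clive as BC; being inconsistent with b1C it inhibits the belief RAF.
    * 4 — Thera models laughing off a mishap; the reframe LT arrives as LC.
    * 5 — Thera's prompt qT ("other reasons for the bad grade?") arrives in
      Clive's foodset so it can act as a catalyst.
    * 6a/6b — GC →[qT] VC: Clive reinterprets the bad grade as a joke about
      video games (derived); the joke both forms a second RAF and further
      inhibits the belief RAF.
    * 7a/7b — Thera laughs (lT transmitted); the in-session experience of
      telling the joke, JC, enters Clive's foodset, and JC →[lT] b2C
      ("I am funny") forms a third RAF.

    A note on JC vs VC: the source scenario is ambiguous about whether the
    joke-as-told (JC) and the reinterpreted memory (VC) are one
    representation or two, and its set-update line for the final reaction
    conflicts with its own reaction arrow.  This fixture keeps them
    distinct — VC stays foodset-derived, while JC (the direct in-session
    experience of joking and being laughed at) is a foodset item.  Under
    the one-item reading the final mind has two irreducible RAFs, not the
    three the scenario describes; the two-item reading reproduces the
    described structure exactly and is the one packaged here.
    """
    E = SessionEvent
    C, T = "Clive", "Thera"
    return [
        E("add", C, {"item_id": "GC", "label": "memory: got a D- in high-school math"}, "intake"),
        E("add", C, {"item_id": "PC", "label": "memory: didn't get the job after the interview"}, "intake"),
        E("add", C, {"item_id": "mC", "label": "wife called me a 'moron' (catalyzing incident)"}, "intake"),
        E("add", C, {"item_id": "CC", "label": "Clive's account of his concerns"}, "intake"),
        E("react", C, {"reactants": ["GC", "PC"], "catalyst": "mC",
                       "product_id": "b1C", "product_label": "belief: I am stupid",
                       "reaction_id": "r1"}, "1b"),
        E("reweight", C, {"op": "register", "raf_label": BELIEF_STUPID, "reactions": ["r1"]}, "1b"),
        E("transmit", C, {"item": "CC", "target": T, "new_id": "CT"}, "eq3"),
        E("add", T, {"item_id": "BT", "label": "observation: Clive is a brilliant problem solver"}, "2"),
        E("transmit", T, {"item": "BT", "target": C, "new_id": "BC"}, "2"),
        E("inhibit", C, {"item": "BC", "raf_label": BELIEF_STUPID}, "3"),
        E("add", T, {"item_id": "LT", "label": "reframe: laughing off one's own clumsiness"}, "4"),
        E("transmit", T, {"item": "LT", "target": C, "new_id": "LC"}, "4"),
        E("add", T, {"item_id": "qT", "label": "prompt: other reasons for the bad grade?"}, "5"),
        E("transmit", T, {"item": "qT", "target": C}, "5"),
        E("react", C, {"reactants": ["GC"], "catalyst": "qT",
                       "product_id": "VC", "product_label": "joke: I spent all my time on video games",
                       "reaction_id": "r2"}, "6b"),
        E("reweight", C, {"op": "register", "raf_label": JOKE_RAF, "reactions": ["r2"]}, "6b"),
        E("inhibit", C, {"item": "VC", "raf_label": BELIEF_STUPID}, "6b"),
        E("add", T, {"item_id": "lT", "label": "Thera laughs at Clive's joke"}, "7a"),
        E("transmit", T, {"item": "lT", "target": C}, "7a"),
        E("add", C, {"item_id": "JC", "label": "experience: told the video-game joke in session"}, "7a"),
        E("react", C, {"reactants": ["JC"], "catalyst": "lT",
                       "product_id": "b2C", "product_label": "belief: I am funny",
                       "reaction_id": "r3"}, "7b"),
        E("reweight", C, {"op": "register", "raf_label": BELIEF_FUNNY, "reactions": ["r3"]}, "7b"),
    ]


def build_clive_thera(alpha: float = 0.5, beta: float = 0.5) -> Dyad:
    """The fully scripted therapist–client dyad (see :func:`clive_thera_log`)."""
    return replay(clive_thera_log(), alpha=alpha, beta=beta)
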