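"""Catalytic reaction systems and their serialization.

A catalytic reaction system is a tuple Q = (X, R, C, F): a set ``X`` of
entity types, a set ``R`` of reactions (each with a reactant multiset and a
product multiset over X), a catalysis relation ``C`` between types and
reactions, and a foodset ``F ⊆ X`` of types that are present without having
to be produced.  This is the substrate on which RAF (reflexively
autocatalytic, F-generated) detection operates; the systems themselves are
purely structural — no rate constants, kinetics, or concentrations.

Two interchangeable on-disk dialects are defined here (neither is a standard
format; both are inventions of this package):

* a line-oriented **text dialect** (``#`` comments)::

      # format_version: 1
      X: GC, PC, b1C, mC
      F: GC, PC, mC
      r1: GC + PC -> b1C
      cat: mC r1

* a **JSON document**::

      {"format_version": 1,
       "types": [...], "foodset": [...],
       "reactions": [{"id": ..., "reactants": [...], "products": [...]}],
       "catalysis": [{"catalyst": ..., "reaction": ...}]}

Writing is canonical (everything sorted by id), so ``parse(write(q)) == q``
and ``write`` is idempotent byte-for-byte.
"""

from __future__ import annotations

import json
import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Union

FORMAT_VERSION = 1

__all__ = [
    "EntityType",
    "Reaction",
    "ReactionSystem",
    "ReactionSystemError",
    "ParseError",
    "ValidationError",
    "parse_system",
    "write_system",
    "to_dot",
]


class ReactionSystemError(ValueError):
    """Base error for this module."""


class ParseError(ReactionSystemError):
    """Malformed input text; carries the 1-based line number where known."""

    def __init__(self, message: str, line: Optional[int] = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


class ValidationError(ReactionSystemError):
    """Structurally invalid system (dangling references, bad ids, ...)."""


# Tokens may not contain whitespace or characters with syntactic meaning in
# the text dialect: + , [ ] -> → : # "
_TOKEN_RE = re.compile(r"^[^\s+,\[\]:#\">→]+$")


def _check_token(tok: str, what: str) -> str:
    if not tok or not _TOKEN_RE.match(tok) or "->" in tok:
        raise ValidationError(f"invalid {what} id {tok!r}")
    return tok


def EntityType(id: str) -> str:  # noqa: N802 - factory named after the concept
    """Validate and return an entity-type id (types are plain string tokens)."""
    return _check_token(id, "entity type")


def _as_multiset(ids: Iterable[str]) -> tuple[str, ...]:
    return tuple(sorted(ids))


@dataclass(frozen=True)
class Reaction:
    """A reaction ``A -> B`` with reactant multiset A and product multiset B.

    Multisets are stored as sorted tuples (so ``a + a -> b`` keeps the
    multiplicity 2 through serialization); availability logic elsewhere uses
    the underlying *sets* of distinct ids only.
    """

    id: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]

    def __post_init__(self):
        _check_token(self.id, "reaction")
        if not self.reactants or not self.products:
            raise ValidationError(f"reaction {self.id!r}: reactants and products must be non-empty")
        object.__setattr__(self, "reactants", _as_multiset(self.reactants))
        object.__setattr__(self, "products", _as_multiset(self.products))
        for t in self.reactants + self.products:
            _check_token(t, "entity type")

    @property
    def reactant_set(self) -> frozenset[str]:
        return frozenset(self.reactants)

    @property
    def product_set(self) -> frozenset[str]:
        return frozenset(self.products)


@dataclass(frozen=True)
class ReactionSystem:
    """The tuple Q = (X, R, C, F).

    ``reactions`` maps reaction id -> :class:`Reaction`; ``catalysis`` is a
    set of ``(catalyst type id, reaction id)`` pairs (duplicates collapse).
    All invariants (foodset ⊆ types, reference integrity, id uniqueness) are
    enforced at construction.
    """

    types: frozenset[str]
    reactions: Mapping[str, Reaction]
    catalysis: frozenset[tuple[str, str]]
    foodset: frozenset[str]

    def __init__(
        self,
        types: Iterable[str],
        reactions: Iterable[Reaction],
        catalysis: Iterable[tuple[str, str]],
        foodset: Iterable[str],
    ):
        tset = frozenset(_check_token(t, "entity type") for t in types)
        rmap: dict[str, Reaction] = {}
        for r in reactions:
            if r.id in rmap:
                raise ValidationError(f"duplicate reaction id {r.id!r}")
            rmap[r.id] = r
        cset = frozenset((str(c), str(rid)) for c, rid in catalysis)
        fset = frozenset(foodset)

        if not fset <= tset:
            raise ValidationError(f"foodset not a subset of types: {sorted(fset - tset)}")
        for r in rmap.values():
            missing = (r.reactant_set | r.product_set) - tset
            if missing:
                raise ValidationError(f"reaction {r.id!r} references undeclared types {sorted(missing)}")
        for c, rid in cset:
            if c not in tset:
                raise ValidationError(f"catalysis edge references undeclared type {c!r}")
            if rid not in rmap:
                raise ValidationError(f"catalysis edge references unknown reaction {rid!r}")

        object.__setattr__(self, "types", tset)
        object.__setattr__(self, "reactions", dict(sorted(rmap.items())))
        object.__setattr__(self, "catalysis", cset)
        object.__setattr__(self, "foodset", fset)

    # -- convenience -------------------------------------------------------
    def catalysts_of(self, reaction_id: str) -> frozenset[str]:
        """All types catalyzing ``reaction_id``."""
        if reaction_id not in self.reactions:
            raise ValidationError(f"unknown reaction {reaction_id!r}")
        return frozenset(c for c, rid in self.catalysis if rid == reaction_id)

    def reaction_subset(self, ids: Iterable[str]) -> frozenset[str]:
        """Validate a reaction-id subset and return it as a frozenset."""
        ids = frozenset(ids)
        unknown = ids - self.reactions.keys()
        if unknown:
            raise ValidationError(f"unknown reaction ids {sorted(unknown)}")
        return ids

    def restrict(self, reaction_ids: Iterable[str]) -> "ReactionSystem":
        """Sub-system with the same X and F but only the given reactions."""
        keep = self.reaction_subset(reaction_ids)
        return ReactionSystem(
            self.types,
            [self.reactions[r] for r in keep],
            [(c, r) for c, r in self.catalysis if r in keep],
            self.foodset,
        )

    def __eq__(self, other):
        if not isinstance(other, ReactionSystem):
            return NotImplemented
        return (
            self.types == other.types
            and self.reactions == other.reactions
            and self.catalysis == other.catalysis
            and self.foodset == other.foodset
        )

    def __hash__(self):
        return hash((self.types, tuple(sorted(self.reactions)), self.catalysis, self.foodset))


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

def _split_ids(body: str, lineno: int) -> list[str]:
    ids = [t.strip() for t in body.split(",")]
    ids = [t for t in ids if t]
    if not ids:
        raise ParseError("empty id list", lineno)
    return ids


def _parse_text(text: str, strict: bool) -> ReactionSystem:
    declared_types: list[str] = []
    saw_x = False
    foodset: list[str] = []
    reactions: list[Reaction] = []
    catalysis: list[tuple[str, str]] = []
    seen_rids: set[str] = set()

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ParseError(f"expected '<keyword>:' or '<rid>:' in {line!r}", lineno)
        head, body = (part.strip() for part in line.split(":", 1))
        if head == "X":
            saw_x = True
            declared_types.extend(_split_ids(body, lineno))
        elif head == "F":
            foodset.extend(_split_ids(body, lineno))
        elif head == "cat":
            parts = body.split()
            if len(parts) != 2:
                raise ParseError(f"cat line needs '<typeid> <rid>', got {body!r}", lineno)
            catalysis.append((parts[0], parts[1]))
        else:
            # reaction line:  rid: a + b -> c + d
            arrow = "->" if "->" in body else ("→" if "→" in body else None)
            if arrow is None:
                raise ParseError(f"reaction {head!r} is missing '->'", lineno)
            lhs, rhs = body.split(arrow, 1)
            reactants = [t.strip() for t in lhs.split("+") if t.strip()]
            products = [t.strip() for t in rhs.split("+") if t.strip()]
            if head in seen_rids:
                raise ParseError(f"duplicate reaction id {head!r}", lineno)
            seen_rids.add(head)
            try:
                reactions.append(Reaction(head, tuple(reactants), tuple(products)))
            except ReactionSystemError as e:
                raise ParseError(str(e), lineno) from e

    if strict and not saw_x:
        raise ParseError("strict mode requires an explicit 'X:' declaration")
    if saw_x:
        types: Iterable[str] = declared_types
    else:
        # auto-declare from foodset and reaction participants
        auto = set(foodset)
        for r in reactions:
            auto |= r.reactant_set | r.product_set
        for c, _ in catalysis:
            auto.add(c)
        types = auto
    return ReactionSystem(types, reactions, catalysis, foodset)


def _parse_json(text: str) -> ReactionSystem:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise ParseError(f"invalid JSON: {e.msg}", e.lineno) from e
    if not isinstance(doc, dict):
        raise ParseError("top-level JSON value must be an object")
    version = doc.get("format_version")
    if version != FORMAT_VERSION:
        raise ParseError(f"unsupported format_version {version!r} (expected {FORMAT_VERSION})")
    for key in ("types", "foodset", "reactions", "catalysis"):
        if key not in doc or not isinstance(doc[key], list):
            raise ParseError(f"missing or non-list key {key!r}")
    try:
        reactions = [
            Reaction(r["id"], tuple(r["reactants"]), tuple(r["products"]))
            for r in doc["reactions"]
        ]
        catalysis = [(c["catalyst"], c["reaction"]) for c in doc["catalysis"]]
    except (KeyError, TypeError) as e:
        raise ParseError(f"malformed reaction/catalysis entry: {e}") from e
    return ReactionSystem(doc["types"], reactions, catalysis, doc["foodset"])


def parse_system(text: str, dialect: str = "text", strict: bool = False) -> ReactionSystem:
    """Parse a system from ``text`` in the given dialect ("text" or "json").

    Unknown ids raise :class:`ValidationError` / :class:`ParseError`; nothing
    is ever silently created when an explicit universe (``X:`` line or JSON
    ``types``) is given.
    """
    if dialect == "text":
        return _parse_text(text, strict)
    if dialect == "json":
        return _parse_json(text)
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Writing
# ---------------------------------------------------------------------------

def write_system(q: ReactionSystem, dialect: str = "text") -> str:
    """Canonical serialization: ids sorted, stable across insertion order."""
    if dialect == "text":
        lines = [f"# format_version: {FORMAT_VERSION}"]
        if q.types:
            lines.append("X: " + ", ".join(sorted(q.types)))
        if q.foodset:
            lines.append("F: " + ", ".join(sorted(q.foodset)))
        for rid in sorted(q.reactions):
            r = q.reactions[rid]
            lines.append(f"{rid}: " + " + ".join(r.reactants) + " -> " + " + ".join(r.products))
        for c, rid in sorted(q.catalysis):
            lines.append(f"cat: {c} {rid}")
        return "\n".join(lines) + "\n"
    if dialect == "json":
        doc = {
            "format_version": FORMAT_VERSION,
            "types": sorted(q.types),
            "foodset": sorted(q.foodset),
            "reactions": [
                {"id": rid, "reactants": list(q.reactions[rid].reactants),
                 "products": list(q.reactions[rid].products)}
                for rid in sorted(q.reactions)
            ],
            "catalysis": [
                {"catalyst": c, "reaction": rid} for c, rid in sorted(q.catalysis)
            ],
        }
        return json.dumps(doc, indent=2, sort_keys=True) + "\n"
    raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# DOT export
# ---------------------------------------------------------------------------

def _dot_quote(s: str) -> str:
    return '"' + s.replace("\\", "\\\\").replace('"', '\\"') + '"'


def to_dot(
    q: ReactionSystem,
    highlight: Union[Iterable[str], Iterable[Iterable[str]], None] = None,
    graph_name: str = "raf",
) -> str:
    """Render the bipartite type/reaction graph in DOT.

    Type nodes are ellipses (foodset types drawn filled), reaction nodes are
    boxes; reactant/product edges are solid, catalysis edges dashed.
    ``highlight`` is a reaction subset — or a collection of subsets — each of
    which is emitted as a DOT ``subgraph cluster`` (the pencil-drawn "oval"
    around a RAF in hand diagrams of these systems).
    """
    groups: list[frozenset[str]] = []
    if highlight is not None:
        hl = list(highlight)
        if hl and all(isinstance(x, str) for x in hl):
            groups = [frozenset(hl)]
        else:
            groups = [frozenset(g) for g in hl]
    for g in groups:
        q.reaction_subset(g)  # raises on unknown ids

    out = [f"digraph {graph_name} {{", "  rankdir=LR;"]
    for t in sorted(q.types):
        style = ' style=filled fillcolor="#dddddd"' if t in q.foodset else ""
        out.append(f"  {_dot_quote(t)} [shape=ellipse{style}];")
    clustered = set().union(*groups) if groups else set()
    for rid in sorted(q.reactions):
        if rid not in clustered:
            out.append(f"  {_dot_quote(rid)} [shape=box];")
    for i, g in enumerate(groups):
        out.append(f"  subgraph cluster_{i} {{")
        out.append('    style=rounded; color=blue;')
        for rid in sorted(g):
            out.append(f"    {_dot_quote(rid)} [shape=box];")
        out.append("  }")
    for rid in sorted(q.reactions):
        r = q.reactions[rid]
        for a, mult in sorted(Counter(r.reactants).items()):
            label = f' [label="{mult}"]' if mult > 1 else ""
            out.append(f"  {_dot_quote(a)} -> {_dot_quote(rid)}{label};")
        for b, mult in sorted(Counter(r.products).items()):
            label = f' [label="{mult}"]' if mult > 1 else ""
            out.append(f"  {_dot_quote(rid)} -> {_dot_quote(b)}{label};")
    for c, rid in sorted(q.catalysis):
        out.append(f"  {_dot_quote(c)} -> {_dot_quote(rid)} [style=dashed];")
    out.append("}")
    return "\n".join(out) + "\n"
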