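"""Stoichiometric network model and structural preprocessing.

A metabolic network is held as an ordered collection of metabolites and
reactions, the in-memory form of the stoichiometric matrix S: each reaction
is a column, with negative coefficients for substrates and positive ones for
products. Before constraint construction the network is preprocessed:

* coefficients are scaled to coprime integers per reaction (:func:`integerize`),
* reversible reactions are split into two opposed irreversible copies
  (:func:`split_reversible`),
* knocked-out reactions are removed (:func:`remove_reactions`),
* metabolites are partitioned into basis / target / intermediate sets
  (:func:`partition_compounds`).

Coefficients are exact :class:`fractions.Fraction` values throughout; they are
parsed from decimal strings, never through binary floating point, because the
LCM/GCD arithmetic of integerization is meaningless on floats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Mapping

from .errors import MalformedModelError, UnknownIdError

logger = logging.getLogger(__name__)

#: Suffix appended to the id of the reverse copy of a split reversible reaction.
REVERSE_SUFFIX = "__rev"


def as_fraction(value) -> Fraction:
    """Convert a coefficient to an exact Fraction.

    Accepts ints, Fractions, and decimal/rational strings ("1.5", "2/3").
    Floats are converted through their shortest decimal representation
    (``repr``), which round-trips the intended decimal exactly for values
    like 0.5 or 29.75 as they appear in SBML files.
    """
    if isinstance(value, Fraction):
        return value
    if isinstance(value, bool):
        raise MalformedModelError(f"boolean is not a stoichiometric coefficient: {value!r}")
    if isinstance(value, int):
        return Fraction(value)
    if isinstance(value, float):
        if not math.isfinite(value):
            raise MalformedModelError(f"non-finite stoichiometric coefficient: {value!r}")
        return Fraction(repr(value))
    if isinstance(value, str):
        try:
            return Fraction(value)
        except (ValueError, ZeroDivisionError) as exc:
            raise MalformedModelError(f"unparsable stoichiometric coefficient: {value!r}") from exc
    raise MalformedModelError(f"unsupported coefficient type: {type(value).__name__}")


@dataclass(frozen=True)
class Metabolite:
    """A compound of the network (a row of S)."""

    id: str
    name: str | None = None
    compartment: str | None = None

    def __post_init__(self):
        if not self.id:
            raise MalformedModelError("metabolite id must be non-empty")


@dataclass(frozen=True)
class Reaction:
    """A reaction (a column of S).

    ``stoichiometry`` maps metabolite id to a signed exact coefficient:
    negative for consumed, positive for produced species.
    """

    id: str
    stoichiometry: Mapping[str, Fraction]
    reversible: bool = False
    name: str | None = None

    def __post_init__(self):
        if not self.id:
            raise MalformedModelError("reaction id must be non-empty")
        if not self.stoichiometry:
            raise MalformedModelError(f"reaction {self.id!r} has empty stoichiometry")
        coeffs = {m: as_fraction(c) for m, c in self.stoichiometry.items()}
        for met, coeff in coeffs.items():
            if coeff == 0:
                raise MalformedModelError(f"reaction {self.id!r}: zero coefficient for {met!r}")
        object.__setattr__(self, "stoichiometry", coeffs)

    def negated(self, new_id: str) -> "Reaction":
        """Copy with every coefficient negated (the reverse direction)."""
        return Reaction(
            id=new_id,
            stoichiometry={m: -c for m, c in self.stoichiometry.items()},
            reversible=False,
            name=self.name,
        )


@dataclass(frozen=True)
class Network:
    """An ordered, validated metabolite/reaction collection (the matrix S)."""

    metabolites: tuple[Metabolite, ...]
    reactions: tuple[Reaction, ...]

    def __post_init__(self):
        object.__setattr__(self, "metabolites", tuple(self.metabolites))
        object.__setattr__(self, "reactions", tuple(self.reactions))
        met_ids = [m.id for m in self.metabolites]
        if len(set(met_ids)) != len(met_ids):
            dupes = sorted({i for i in met_ids if met_ids.count(i) > 1})
            raise MalformedModelError(f"duplicate metabolite ids: {dupes}")
        rxn_ids = [r.id for r in self.reactions]
        if len(set(rxn_ids)) != len(rxn_ids):
            dupes = sorted({i for i in rxn_ids if rxn_ids.count(i) > 1})
            raise MalformedModelError(f"duplicate reaction ids: {dupes}")
        known = set(met_ids)
        for rxn in self.reactions:
            missing = set(rxn.stoichiometry) - known
            if missing:
                raise MalformedModelError(
                    f"reaction {rxn.id!r} references unknown metabolites: {sorted(missing)}"
                )

    @property
    def metabolite_ids(self) -> tuple[str, ...]:
        return tuple(m.id for m in self.metabolites)

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.reactions)

    def reaction(self, rxn_id: str) -> Reaction:
        for r in self.reactions:
            if r.id == rxn_id:
                return r
        raise UnknownIdError(f"unknown reaction id: {rxn_id!r}")


@dataclass(frozen=True)
class DirectedNetwork:
    """A network in which every reaction is unidirectional.

    ``reverse_pairs`` records which pairs of reactions originated from one
    reversible reaction, so that a direction constraint (at most one of the
    two active) can be emitted per pair.
    """

    base: Network
    reverse_pairs: frozenset[frozenset[str]] = field(default_factory=frozenset)

    def __post_init__(self):
        object.__setattr__(
            self, "reverse_pairs", frozenset(frozenset(p) for p in self.reverse_pairs)
        )
        known = set(self.base.reaction_ids)
        for rxn in self.base.reactions:
            if rxn.reversible:
                raise MalformedModelError(
                    f"directed network contains reversible reaction {rxn.id!r}"
                )
        by_id = {r.id: r for r in self.base.reactions}
        for pair in self.reverse_pairs:
            if len(pair) != 2:
                raise MalformedModelError(f"reverse pair is not a 2-set: {sorted(pair)}")
            if not pair <= known:
                raise MalformedModelError(
                    f"reverse pair references unknown reactions: {sorted(pair - known)}"
                )
            fwd_id, rev_id = sorted(pair)
            fwd, rev = by_id[fwd_id], by_id[rev_id]
            if {m: -c for m, c in fwd.stoichiometry.items()} != dict(rev.stoichiometry):
                raise MalformedModelError(
                    f"reverse pair ({fwd_id!r}, {rev_id!r}) is not an exact negation"
                )

    @property
    def reaction_ids(self) -> tuple[str, ...]:
        return self.base.reaction_ids


@dataclass(frozen=True)
class CompoundPartition:
    """The disjoint basis (B) / target (T) / intermediate (I) metabolite sets.

    Basis compounds are freely available and unconstrained; targets must show
    strictly positive net production; intermediates may accumulate but not be
    net consumed.
    """

    basis: frozenset[str]
    targets: frozenset[str]
    intermediates: frozenset[str]

    def __post_init__(self):
        object.__setattr__(self, "basis", frozenset(self.basis))
        object.__setattr__(self, "targets", frozenset(self.targets))
        object.__setattr__(self, "intermediates", frozenset(self.intermediates))
        if not self.targets:
            raise MalformedModelError("target set must be non-empty")
        if self.basis & self.targets or self.basis & self.intermediates or self.targets & self.intermediates:
            raise MalformedModelError("basis/target/intermediate sets must be pairwise disjoint")

    @property
    def all_ids(self) -> frozenset[str]:
        return self.basis | self.targets | self.intermediates


def integerize(reaction: Reaction) -> Reaction:
    """Scale a reaction's coefficients to coprime integers.

    Multiplies by the LCM of the coefficient denominators and divides by the
    GCD of the resulting numerators, so the output vector equals the input
    times one positive rational scalar, with collective GCD 1. Direction
    (sign pattern), id, name and reversibility are unchanged; the operation
    is idempotent.
    """
    coeffs = {m: as_fraction(c) for m, c in reaction.stoichiometry.items()}
    lcm = math.lcm(*(c.denominator for c in coeffs.values()))
    ints = {m: int(c * lcm) for m, c in coeffs.items()}
    gcd = math.gcd(*(abs(v) for v in ints.values()))
    return replace(reaction, stoichiometry={m: Fraction(v // gcd) for m, v in ints.items()})


def integerize_network(network: Network) -> Network:
    """Apply :func:`integerize` to every reaction of a network."""
    return replace(network, reactions=tuple(integerize(r) for r in network.reactions))


def split_reversible(network: Network) -> DirectedNetwork:
    """Split each reversible reaction into opposed unidirectional copies.

    The forward copy keeps the original id; the reverse copy gets the id plus
    ``__rev`` and exactly negated stoichiometry. Irreversible reactions are
    copied verbatim. Each split is recorded in ``reverse_pairs``.
    """
    existing = set(network.reaction_ids)
    out: list[Reaction] = []
    pairs: set[frozenset[str]] = set()
    for rxn in network.reactions:
        if not rxn.reversible:
            out.append(rxn)
            continue
        rev_id = rxn.id + REVERSE_SUFFIX
        if rev_id in existing:
            raise MalformedModelError(
                f"cannot split {rxn.id!r}: id {rev_id!r} already exists in the network"
            )
        forward = replace(rxn, reversible=False)
        out.append(forward)
        out.append(rxn.negated(rev_id))
        pairs.add(frozenset({rxn.id, rev_id}))
    return DirectedNetwork(
        base=Network(metabolites=network.metabolites, reactions=tuple(out)),
        reverse_pairs=frozenset(pairs),
    )


def remove_reactions(network: Network, ids: Iterable[str]) -> Network:
    """Return the network without the given reactions (a knockout).

    Unknown ids raise :class:`UnknownIdError` naming the id — a silently
    ignored knockout would invalidate the biology being simulated. Metabolites
    are kept even if orphaned (logged); they only contribute vacuous
    constraints downstream, and pruning would shuffle metabolite indexing.
    """
    ids = list(ids)
    known = set(network.reaction_ids)
    unknown = [i for i in ids if i not in known]
    if unknown:
        raise UnknownIdError(f"cannot remove unknown reaction id(s): {unknown}")
    drop = set(ids)
    kept = tuple(r for r in network.reactions if r.id not in drop)
    referenced = {m for r in kept for m in r.stoichiometry}
    orphans = sorted(set(network.metabolite_ids) - referenced)
    if drop and orphans:
        logger.info("removal left %d orphan metabolite(s): %s", len(orphans), orphans)
    return replace(network, reactions=kept)


def partition_compounds(
    network: Network, basis_ids: Iterable[str], target_ids: Iterable[str]
) -> CompoundPartition:
    """Partition metabolites into basis, target, and intermediate sets.

    Every metabolite not named as basis or target becomes an intermediate.
    """
    basis = frozenset(basis_ids)
    targets = frozenset(target_ids)
    known = set(network.metabolite_ids)
    unknown = sorted((basis | targets) - known)
    if unknown:
        raise UnknownIdError(f"unknown metabolite id(s) in basis/target lists: {unknown}")
    overlap = basis & targets
    if overlap:
        raise MalformedModelError(f"metabolites in both basis and target sets: {sorted(overlap)}")
    return CompoundPartition(
        basis=basis, targets=targets, intermediates=frozenset(known - basis - targets)
    )
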