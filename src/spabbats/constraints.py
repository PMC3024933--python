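"""Constraint system over the two-variable flux representation.

Each directed reaction *i* carries two variables: a positive integer flux
magnitude ``a_i`` in ``[a_min, a_max]`` (a relative measure of the reaction's
contribution) and a Boolean activity flag ``b_i``. The effective flux term in
every balance constraint is the product ``a_i * b_i``.

The system holds, for a directed network and a compound partition:

* one target constraint per target metabolite t:     sum_i s_it a_i b_i >= 1
* one intermediate constraint per intermediate j:    sum_i s_ij a_i b_i >= 0
* one direction constraint per split reversible pair (i, j):  b_i + b_j <= 1
* a cardinality bound on pathway length:             sum_i b_i <= k
* zero or more exclusion (integer-cut) constraints:  sum_{i in K} b_i <= k_op - 1

Basis metabolites contribute no constraint at all. Because coefficients and
magnitudes are integers, the strict "net production > 0" requirement on
targets is encoded exactly as ">= 1" — no epsilon is involved.

ConstraintSystem instances are immutable; :func:`add_exclusion` and
:func:`lower_cardinality` return modified copies, so raising the cardinality
back restores the original satisfiability status trivially.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping

from .errors import MalformedModelError, UnknownIdError
from .network import CompoundPartition, DirectedNetwork

if TYPE_CHECKING:  # pragma: no cover
    from .solver import PathwaySolution

DEFAULT_A_BOUNDS = (1, 1000)


@dataclass(frozen=True)
class FluxVariables:
    """The variable declarations: one (a_i, b_i) pair per directed reaction."""

    reaction_ids: tuple[str, ...]
    a_min: int = DEFAULT_A_BOUNDS[0]
    a_max: int = DEFAULT_A_BOUNDS[1]

    def __post_init__(self):
        object.__setattr__(self, "reaction_ids", tuple(self.reaction_ids))
        if self.a_min < 1:
            raise MalformedModelError(f"a_min must be >= 1, got {self.a_min}")
        if self.a_max < self.a_min:
            raise MalformedModelError(f"a_max ({self.a_max}) < a_min ({self.a_min})")

    @property
    def n(self) -> int:
        return len(self.reaction_ids)


@dataclass(frozen=True)
class BalanceConstraint:
    """sum_i coeff_i * a_i * b_i >= lower, for one non-basis metabolite.

    ``coeffs`` holds only the nonzero integer stoichiometric coefficients.
    ``lower`` is 1 for targets (strict positivity over integers) and 0 for
    intermediates (accumulation allowed, net consumption forbidden).
    """

    metabolite: str
    coeffs: Mapping[str, int]
    lower: int

    def __post_init__(self):
        object.__setattr__(self, "coeffs", dict(self.coeffs))


@dataclass(frozen=True)
class ConstraintSystem:
    """The full constraint conjunction for one pathway query."""

    variables: FluxVariables
    target_constraints: tuple[BalanceConstraint, ...]
    intermediate_constraints: tuple[BalanceConstraint, ...]
    direction_constraints: tuple[tuple[str, str], ...]
    cardinality_k: int
    exclusions: tuple[tuple[frozenset[str], int], ...] = ()

    def __post_init__(self):
        known = set(self.variables.reaction_ids)
        for con in (*self.target_constraints, *self.intermediate_constraints):
            bad = set(con.coeffs) - known
            if bad:
                raise MalformedModelError(
                    f"constraint for {con.metabolite!r} references unknown reactions: {sorted(bad)}"
                )
        for i, j in self.direction_constraints:
            if i not in known or j not in known:
                raise MalformedModelError(f"direction constraint over unknown reactions: ({i}, {j})")
        for kset, k_op in self.exclusions:
            if not kset <= known:
                raise MalformedModelError(
                    f"exclusion references unknown reactions: {sorted(kset - known)}"
                )
            if k_op != len(kset):
                raise MalformedModelError("exclusion bound must equal the excluded set size")

    @property
    def balance_constraints(self) -> tuple[BalanceConstraint, ...]:
        return self.target_constraints + self.intermediate_constraints

    def evaluate(self, active: frozenset[str], magnitudes: Mapping[str, int]) -> list[str]:
        """Check an assignment against every constraint by direct integer arithmetic.

        Returns a list of human-readable violation descriptions (empty = satisfied).
        The effective flux term a_i*b_i is taken as ``magnitudes[i]`` for active
        reactions and 0 otherwise.
        """
        violations: list[str] = []
        known = set(self.variables.reaction_ids)
        stray = active - known
        if stray:
            violations.append(f"active set references unknown reactions: {sorted(stray)}")
            active = active & known
        for rid in sorted(active):
            a = magnitudes.get(rid)
            if a is None:
                violations.append(f"active reaction {rid} has no magnitude")
            elif not (self.variables.a_min <= a <= self.variables.a_max):
                violations.append(
                    f"magnitude a[{rid}]={a} outside "
                    f"[{self.variables.a_min}, {self.variables.a_max}]"
                )
        for con in self.balance_constraints:
            total = sum(c * magnitudes.get(r, 0) for r, c in con.coeffs.items() if r in active)
            if total < con.lower:
                kind = "target" if con.lower >= 1 else "intermediate"
                violations.append(
                    f"{kind} balance for {con.metabolite}: net {total} < {con.lower}"
                )
        for i, j in self.direction_constraints:
            if i in active and j in active:
                violations.append(f"both directions of reversible pair active: ({i}, {j})")
        if len(active) > self.cardinality_k:
            violations.append(
                f"cardinality: {len(active)} active reactions > k={self.cardinality_k}"
            )
        for kset, k_op in self.exclusions:
            if len(active & kset) > k_op - 1:
                violations.append(f"exclusion violated for set {sorted(kset)} (k_op={k_op})")
        return violations


def build_constraints(
    dnet: DirectedNetwork,
    part: CompoundPartition,
    a_bounds: tuple[int, int] = DEFAULT_A_BOUNDS,
    k: int = None,
) -> ConstraintSystem:
    """Assemble the constraint system for a directed, integerized network.

    ``k`` is the cardinality bound on the number of active reactions; it
    defaults to the number of directed reactions (no effective bound).
    """
    ids = dnet.reaction_ids
    if k is None:
        k = len(ids)
    if k < 1:
        raise MalformedModelError(f"cardinality bound k must be >= 1, got {k}")
    net_mets = set(dnet.base.metabolite_ids)
    if part.all_ids != net_mets:
        raise MalformedModelError(
            "compound partition does not cover the network's metabolites exactly"
        )
    if not part.targets:
        raise MalformedModelError("target set must be non-empty")

    # column access: metabolite -> {reaction -> integer coefficient}
    by_met: dict[str, dict[str, int]] = {}
    for rxn in dnet.base.reactions:
        for met, coeff in rxn.stoichiometry.items():
            if coeff.denominator != 1:
                raise MalformedModelError(
                    f"reaction {rxn.id!r} is not integerized (coefficient {coeff} for {met!r})"
                )
            by_met.setdefault(met, {})[rxn.id] = int(coeff)

    targets = tuple(
        BalanceConstraint(metabolite=m, coeffs=by_met.get(m, {}), lower=1)
        for m in sorted(part.targets)
    )
    intermediates = tuple(
        BalanceConstraint(metabolite=m, coeffs=by_met.get(m, {}), lower=0)
        for m in sorted(part.intermediates)
    )
    directions = tuple(tuple(sorted(pair)) for pair in sorted(dnet.reverse_pairs, key=sorted))
    return ConstraintSystem(
        variables=FluxVariables(reaction_ids=ids, a_min=a_bounds[0], a_max=a_bounds[1]),
        target_constraints=targets,
        intermediate_constraints=intermediates,
        direction_constraints=directions,
        cardinality_k=k,
    )


def add_exclusion(system: ConstraintSystem, solution) -> ConstraintSystem:
    """Append the integer cut that forbids a found pathway and all its supersets.

    For a solution with active set K of size k_op, the cut is
    ``sum_{i in K} b_i <= k_op - 1``: any assignment activating all of K
    (hence the solution itself and every superset) becomes infeasible.
    Accepts a :class:`~spabbats.solver.PathwaySolution` or a bare id set.
    """
    kset = frozenset(getattr(solution, "active_set", solution))
    if not kset:
        raise MalformedModelError("cannot exclude an empty active set")
    unknown = kset - set(system.variables.reaction_ids)
    if unknown:
        raise UnknownIdError(f"exclusion references unknown reaction id(s): {sorted(unknown)}")
    return replace(system, exclusions=system.exclusions + ((kset, len(kset)),))


def lower_cardinality(system: ConstraintSystem, k: int) -> ConstraintSystem:
    """Replace the cardinality bound; all other constraints are untouched."""
    if k < 1:
        raise MalformedModelError(f"cardinality bound k must be >= 1, got {k}")
    return replace(system, cardinality_k=k)
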