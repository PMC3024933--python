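"""Satisfiability backends and the two pathway-search drivers.

The search is organised as:

* :func:`solve` — decide one constraint system (SAT with an assignment, or a
  definitive UNSAT), through a pluggable backend;
* :func:`find_shortest` — minimise the cardinality bound k to find a shortest
  pathway, together with an UNSAT certificate at ``k_op - 1``;
* :func:`enumerate_pathways` — alternate shortest-search and exclusion
  (integer-cut) constraints to list pathways in non-decreasing length.

Two backends are provided. ``milp`` encodes the system as a mixed-integer
linear program solved by HiGHS (scipy): the nonlinear product ``a_i * b_i``
is linearised through an auxiliary integer ``f_i`` with the indicator
semantics ``b_i = 0 -> f_i = 0`` and ``b_i = 1 -> a_min <= f_i <= a_max``.
``backtracking`` is an exact depth-first search over activity sets with
interval-propagation search for the magnitudes; it is deliberately simple,
guarded to small instances, and exists to cross-validate the MILP encoding.

Every assignment a backend claims satisfying is re-checked by direct integer
arithmetic before being surfaced; a timeout or resource limit raises
:class:`~spabbats.errors.SolverUnknownError` and is never conflated with
UNSAT.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from . import constraints as C
from .errors import (
    InstanceTooLargeError,
    MalformedModelError,
    SolverUnknownError,
    VerificationError,
)
from .network import CompoundPartition, DirectedNetwork

logger = logging.getLogger(__name__)

DEFAULT_TIMEOUT = 300.0  # seconds per backend call

TERMINATED_EXHAUSTED = "exhausted"
TERMINATED_MAX_PATHWAYS = "max_pathways"
TERMINATED_K_LIMIT = "k_limit"


@dataclass(frozen=True)
class Assignment:
    """One satisfying assignment: the active reactions and their magnitudes.

    Magnitudes are recorded only for active reactions; an inactive reaction's
    a_i is meaningless (its flux term is 0) and is masked out.
    """

    active: frozenset[str]
    magnitudes: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "active", frozenset(self.active))
        object.__setattr__(
            self, "magnitudes", {r: int(a) for r, a in self.magnitudes.items() if r in self.active}
        )


@dataclass(frozen=True)
class PathwaySolution:
    """A verified pathway: active reaction set K, magnitudes, and net balance."""

    active_set: frozenset[str]
    magnitudes: Mapping[str, int]
    k_op: int
    net_production: Mapping[str, int]

    def __post_init__(self):
        object.__setattr__(self, "active_set", frozenset(self.active_set))
        object.__setattr__(self, "magnitudes", dict(self.magnitudes))
        object.__setattr__(self, "net_production", dict(self.net_production))
        if self.k_op != len(self.active_set) or self.k_op < 1:
            raise MalformedModelError("pathway length k_op must equal |active_set| >= 1")

    @property
    def normalized_magnitudes(self) -> dict[str, int]:
        """Magnitudes divided by their collective GCD (relative flux ratios)."""
        g = math.gcd(*self.magnitudes.values())
        return {r: a // g for r, a in self.magnitudes.items()}

    def sort_key(self) -> tuple:
        return (self.k_op, tuple(sorted(self.active_set)))


@dataclass(frozen=True)
class EnumerationResult:
    """Ordered pathway list plus the reason the enumeration stopped.

    ``partition`` is carried along so reports can distinguish targets from
    accumulated intermediates without re-supplying context.
    """

    pathways: tuple[PathwaySolution, ...]
    terminated_by: str
    partition: CompoundPartition | None = None

    def __post_init__(self):
        object.__setattr__(self, "pathways", tuple(self.pathways))
        if self.terminated_by not in (
            TERMINATED_EXHAUSTED,
            TERMINATED_MAX_PATHWAYS,
            TERMINATED_K_LIMIT,
        ):
            raise MalformedModelError(f"unknown termination reason: {self.terminated_by!r}")
        lengths = [p.k_op for p in self.pathways]
        if lengths != sorted(lengths):
            raise MalformedModelError("pathway lengths must be non-decreasing")
        for i, earlier in enumerate(self.pathways):
            for later in self.pathways[i + 1 :]:
                if earlier.active_set <= later.active_set:
                    raise MalformedModelError(
                        "a later pathway may not contain an earlier pathway's active set"
                    )


# ---------------------------------------------------------------------------
# backends


class MilpBackend:
    """HiGHS mixed-integer backend (via scipy.optimize.milp).

    Variables: per reaction i, a binary b_i and an integer f_i standing for
    the product a_i*b_i, linked by a_min*b_i <= f_i <= a_max*b_i. All balance,
    direction, cardinality and exclusion constraints are linear in (b, f).
    """

    name = "milp"

    def __init__(self, timeout: float = DEFAULT_TIMEOUT):
        self.timeout = timeout

    def solve(self, system: C.ConstraintSystem) -> Assignment | None:
        ids = system.variables.reaction_ids
        n = len(ids)
        idx = {r: i for i, r in enumerate(ids)}
        a_min, a_max = system.variables.a_min, system.variables.a_max

        rows, cols, vals, lbs, ubs = [], [], [], [], []

        def add_row(entries: dict[int, float], lb: float, ub: float):
            r = len(lbs)
            for c, v in entries.items():
                rows.append(r)
                cols.append(c)
                vals.append(v)
            lbs.append(lb)
            ubs.append(ub)

        for i in range(n):  # indicator linking: a_min*b_i <= f_i <= a_max*b_i
            add_row({n + i: 1.0, i: -a_min}, 0.0, np.inf)
            add_row({n + i: 1.0, i: -a_max}, -np.inf, 0.0)
        for con in system.balance_constraints:
            add_row({n + idx[r]: float(c) for r, c in con.coeffs.items()}, float(con.lower), np.inf)
        for i, j in system.direction_constraints:
            add_row({idx[i]: 1.0, idx[j]: 1.0}, -np.inf, 1.0)
        add_row({i: 1.0 for i in range(n)}, -np.inf, float(system.cardinality_k))
        for kset, k_op in system.exclusions:
            add_row({idx[r]: 1.0 for r in kset}, -np.inf, float(k_op - 1))

        a_mat = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(lbs), 2 * n), dtype=np.float64
        )
        var_lb = np.concatenate([np.zeros(n), np.zeros(n)])
        var_ub = np.concatenate([np.ones(n), np.full(n, float(a_max))])
        res = milp(
            c=np.zeros(2 * n),
            constraints=[LinearConstraint(a_mat, np.asarray(lbs), np.asarray(ubs))],
            integrality=np.ones(2 * n),
            bounds=Bounds(var_lb, var_ub),
            options={"time_limit": self.timeout, "presolve": True},
        )
        if res.status == 2:  # proven infeasible
            return None
        if res.status != 0 or res.x is None:
            raise SolverUnknownError(
                f"milp backend gave no verdict (status={res.status}: {res.message})"
            )
        b = np.rint(res.x[:n]).astype(int)
        f = np.rint(res.x[n:]).astype(int)
        active = frozenset(ids[i] for i in range(n) if b[i] == 1)
        return Assignment(active=active, magnitudes={ids[i]: int(f[i]) for i in range(n) if b[i]})


class BacktrackingBackend:
    """Exact combinatorial backend for small instances.

    Enumerates candidate activity sets in increasing size (pruned by the
    direction, cardinality and exclusion constraints), and decides magnitude
    feasibility for each candidate by depth-first search with interval
    (bounds-consistency) propagation over the integer magnitudes. Exact —
    UNSAT means a completed exhaustive search — but guarded to at most
    ``max_reactions`` directed reactions.
    """

    name = "backtracking"

    def __init__(self, timeout: float = DEFAULT_TIMEOUT, max_reactions: int = 16):
        self.timeout = timeout
        self.max_reactions = max_reactions

    def solve(self, system: C.ConstraintSystem) -> Assignment | None:
        ids = system.variables.reaction_ids
        if len(ids) > self.max_reactions:
            raise SolverUnknownError(
                f"backtracking backend is limited to {self.max_reactions} directed reactions "
                f"(instance has {len(ids)})"
            )
        a_min, a_max = system.variables.a_min, system.variables.a_max
        pairs = [frozenset(p) for p in system.direction_constraints]
        k = min(system.cardinality_k, len(ids))
        for size in range(1, k + 1):
            for combo in itertools.combinations(ids, size):
                active = frozenset(combo)
                if any(pair <= active for pair in pairs):
                    continue
                if any(len(active & kset) > k_op - 1 for kset, k_op in system.exclusions):
                    continue
                mags = self._feasible_magnitudes(system, combo, a_min, a_max)
                if mags is not None:
                    return Assignment(active=active, magnitudes=dict(zip(combo, mags)))
        return None

    @staticmethod
    def _feasible_magnitudes(
        system: C.ConstraintSystem, combo: Sequence[str], a_min: int, a_max: int
    ) -> tuple[int, ...] | None:
        """Find integer magnitudes in [a_min, a_max] satisfying the balances, or None."""
        active = set(combo)
        pos = {r: i for i, r in enumerate(combo)}
        rows = []
        for con in system.balance_constraints:
            coeffs = [(pos[r], c) for r, c in con.coeffs.items() if r in active]
            if coeffs:
                rows.append((coeffs, con.lower))
            elif con.lower > 0:
                return None  # untouched target can never be produced
        lo = [a_min] * len(combo)
        hi = [a_max] * len(combo)
        return BacktrackingBackend._search(rows, lo, hi)

    @staticmethod
    def _search(rows, lo: list[int], hi: list[int]) -> tuple[int, ...] | None:
        if not BacktrackingBackend._propagate(rows, lo, hi):
            return None
        try:
            branch = next(i for i in range(len(lo)) if lo[i] < hi[i])
        except StopIteration:
            a = tuple(lo)
            ok = all(sum(c * a[i] for i, c in coeffs) >= lower for coeffs, lower in rows)
            return a if ok else None
        for value in range(lo[branch], hi[branch] + 1):  # ascending: prefer small magnitudes
            nlo, nhi = list(lo), list(hi)
            nlo[branch] = nhi[branch] = value
            found = BacktrackingBackend._search(rows, nlo, nhi)
            if found is not None:
                return found
        return None

    @staticmethod
    def _propagate(rows, lo: list[int], hi: list[int]) -> bool:
        """Bounds-consistency fixpoint; False iff a domain empties."""
        changed = True
        while changed:
            changed = False
            for coeffs, lower in rows:
                maxima = [c * (hi[i] if c > 0 else lo[i]) for i, c in coeffs]
                total_max = sum(maxima)
                if total_max < lower:
                    return False
                for (i, c), m in zip(coeffs, maxima):
                    rest = total_max - m
                    # c * a_i >= lower - rest, in exact integer arithmetic
                    if c > 0:
                        bound = max(lo[i], -((rest - lower) // c))  # ceil((lower-rest)/c)
                        if bound > lo[i]:
                            lo[i] = bound
                            changed = True
                    else:
                        bound = min(hi[i], (rest - lower) // (-c))  # floor((rest-lower)/-c)
                        if bound < hi[i]:
                            hi[i] = bound
                            changed = True
                    if lo[i] > hi[i]:
                        return False
        return True


_BACKENDS = {"milp": MilpBackend, "backtracking": BacktrackingBackend}


def get_backend(name: str = "milp", timeout: float = DEFAULT_TIMEOUT):
    try:
        return _BACKENDS[name](timeout=timeout)
    except KeyError:
        raise MalformedModelError(
            f"unknown backend {name!r}; available: {sorted(_BACKENDS)}"
        ) from None


def solve(system: C.ConstraintSystem, backend="milp", timeout: float = DEFAULT_TIMEOUT):
    """Decide one constraint system.

    Returns a verified :class:`Assignment` on SAT, ``None`` on proven UNSAT.
    Every SAT claim from the backend is re-evaluated against the constraint
    semantics by direct integer arithmetic before being returned.
    """
    be = get_backend(backend, timeout) if isinstance(backend, str) else backend
    assignment = be.solve(system)
    if assignment is None:
        return None
    violations = system.evaluate(assignment.active, assignment.magnitudes)
    if violations:
        raise VerificationError(
            f"backend {be.name!r} returned an assignment violating: {violations}"
        )
    return assignment


# ---------------------------------------------------------------------------
# search drivers


def _as_exclusion_sets(exclusions) -> list[frozenset[str]]:
    out = []
    for e in exclusions:
        out.append(frozenset(e.active_set) if isinstance(e, PathwaySolution) else frozenset(e))
    return out


def _to_solution(dnet: DirectedNetwork, assignment: Assignment) -> PathwaySolution:
    net: dict[str, int] = {}
    by_id = {r.id: r for r in dnet.base.reactions}
    for rid in assignment.active:
        a = assignment.magnitudes[rid]
        for met, coeff in by_id[rid].stoichiometry.items():
            net[met] = net.get(met, 0) + int(coeff) * a
    return PathwaySolution(
        active_set=assignment.active,
        magnitudes=assignment.magnitudes,
        k_op=len(assignment.active),
        net_production=net,
    )


def find_shortest(
    dnet: DirectedNetwork,
    part: CompoundPartition,
    a_bounds: tuple[int, int] = C.DEFAULT_A_BOUNDS,
    k_init: int | None = None,
    exclusions: Iterable = (),
    backend="milp",
    strategy: str = "binary",
    timeout: float = DEFAULT_TIMEOUT,
) -> PathwaySolution | None:
    """Find a shortest pathway honoring prior exclusions, or None if none exists.

    Minimality is certified during the search: the returned solution's length
    k_op is such that the same system bounded at k_op - 1 was proven UNSAT
    (for k_op = 1 the bound k = 0 is vacuously infeasible, as targets need
    at least one producing reaction). ``strategy`` selects how the bound is
    tightened: "binary" bisects between 1 and the incumbent's length;
    "linear" mirrors the classical descent through successively smaller k.
    """
    if strategy not in ("binary", "linear"):
        raise MalformedModelError(f"unknown k-search strategy: {strategy!r}")
    be = get_backend(backend, timeout) if isinstance(backend, str) else backend
    system = C.build_constraints(dnet, part, a_bounds=a_bounds, k=k_init)
    for kset in _as_exclusion_sets(exclusions):
        system = C.add_exclusion(system, kset)

    incumbent = solve(system, be)
    if incumbent is None:
        logger.debug("UNSAT at k_init=%d", system.cardinality_k)
        return None
    logger.debug("SAT at k=%d with |K|=%d", system.cardinality_k, len(incumbent.active))

    if strategy == "binary":
        lo, hi = 1, len(incumbent.active)  # invariant: k = lo-1 is known UNSAT
        while lo < hi:
            mid = (lo + hi) // 2
            trial = solve(C.lower_cardinality(system, mid), be)
            if trial is None:
                logger.debug("UNSAT at k=%d", mid)
                lo = mid + 1
            else:
                logger.debug("SAT at k=%d with |K|=%d", mid, len(trial.active))
                incumbent, hi = trial, len(trial.active)
    else:
        while len(incumbent.active) > 1:
            k = len(incumbent.active) - 1
            trial = solve(C.lower_cardinality(system, k), be)
            if trial is None:
                logger.debug("UNSAT at k=%d — minimality certified", k)
                break
            logger.debug("SAT at k=%d with |K|=%d", k, len(trial.active))
            incumbent = trial

    solution = _to_solution(dnet, incumbent)
    _verify_or_raise(dnet, part, solution, a_bounds)
    return solution


def _verify_or_raise(dnet, part, solution, a_bounds):
    from .oracle import verify_solution  # deferred: oracle imports PathwaySolution

    report = verify_solution(dnet, part, solution, a_bounds=a_bounds)
    if not report.satisfied:
        raise VerificationError(
            f"solver surfaced an invalid pathway {sorted(solution.active_set)}: "
            f"{report.violations}"
        )


def enumerate_pathways(
    dnet: DirectedNetwork,
    part: CompoundPartition,
    a_bounds: tuple[int, int] = C.DEFAULT_A_BOUNDS,
    max_pathways: int = 100,
    k_limit: int | None = None,
    backend="milp",
    strategy: str = "binary",
    timeout: float = DEFAULT_TIMEOUT,
) -> EnumerationResult:
    """Enumerate pathways in non-decreasing length via exclusion constraints.

    After each shortest solution, an integer cut over its active set is added
    and the search re-minimised, yielding successively longer alternatives.
    Stops on proven exhaustion (UNSAT), on ``max_pathways``, or when the next
    shortest pathway would exceed ``k_limit``.

    Output order is canonical: each batch of equal-length pathways is sorted
    lexicographically on its sorted reaction ids, and a batch is always
    enumerated to exhaustion before the ``max_pathways`` cut is applied, so
    runs with different caps agree on their common prefix.
    """
    if max_pathways < 1:
        raise MalformedModelError(f"max_pathways must be >= 1, got {max_pathways}")
    found: list[PathwaySolution] = []
    exclusions: list[frozenset[str]] = []
    terminated = None

    def next_solution():
        try:
            return find_shortest(
                dnet, part, a_bounds=a_bounds, exclusions=exclusions,
                backend=backend, strategy=strategy, timeout=timeout,
            )
        except SolverUnknownError as exc:
            exc.partial_result = _canonical_result(found, TERMINATED_EXHAUSTED, part)
            raise

    while True:
        sol = next_solution()
        if sol is None:
            terminated = TERMINATED_EXHAUSTED
            break
        if k_limit is not None and sol.k_op > k_limit:
            terminated = TERMINATED_K_LIMIT
            break
        found.append(sol)
        exclusions.append(sol.active_set)
        if len(found) >= max_pathways:
            # finish the current equal-length batch so canonical order is cap-independent
            batch_len = sol.k_op
            while True:
                nxt = next_solution()
                if nxt is None or nxt.k_op > batch_len:
                    break
                found.append(nxt)
                exclusions.append(nxt.active_set)
            terminated = TERMINATED_MAX_PATHWAYS
            break

    result = _canonical_result(found, terminated, part)
    if terminated == TERMINATED_MAX_PATHWAYS and len(result.pathways) > max_pathways:
        result = EnumerationResult(
            pathways=result.pathways[:max_pathways], terminated_by=terminated, partition=part
        )
    return result


def _canonical_result(found, terminated, part) -> EnumerationResult:
    ordered: list[PathwaySolution] = []
    for _, batch in itertools.groupby(found, key=lambda p: p.k_op):
        ordered.extend(sorted(batch, key=lambda p: tuple(sorted(p.active_set))))
    return EnumerationResult(pathways=tuple(ordered), terminated_by=terminated, partition=part)
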