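"""Independent brute-force ground truth and the runtime solution verifier.

This module deliberately shares no code path with the solver backends: every
check is a direct integer-arithmetic evaluation of the balance semantics
(target net production strictly positive, intermediate net production
non-negative, one direction per reversible pair). :func:`verify_solution`
gates every pathway the solver surfaces; :func:`brute_force_enumerate` is the
exhaustive reference enumerator the test suite compares the solver against on
small instances.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InstanceTooLargeError, UnknownIdError
from .network import CompoundPartition, DirectedNetwork
from .solver import PathwaySolution


@dataclass(frozen=True)
class VerificationReport:
    """Outcome of checking a pathway: satisfied iff no violations."""

    satisfied: bool
    violations: tuple[tuple[str, int], ...]

    def __post_init__(self):
        object.__setattr__(self, "violations", tuple(self.violations))
        assert self.satisfied == (len(self.violations) == 0)


def verify_solution(
    dnet: DirectedNetwork,
    part: CompoundPartition,
    solution: PathwaySolution,
    a_bounds: tuple[int, int] = (1, 1000),
) -> VerificationReport:
    """Re-check a pathway against the balance semantics by exact arithmetic.

    Reports (never raises on) semantic violations: target production < 1,
    intermediate net consumption, both directions of a reversible pair
    active, magnitudes outside bounds, or an inconsistent recorded length /
    net-production map. Unknown reaction ids are a caller error and raise.
    """
    by_id = {r.id: r for r in dnet.base.reactions}
    unknown = solution.active_set - set(by_id)
    if unknown:
        raise UnknownIdError(f"pathway references unknown reaction id(s): {sorted(unknown)}")

    violations: list[tuple[str, int]] = []
    a_min, a_max = a_bounds
    for rid in sorted(solution.active_set):
        a = solution.magnitudes.get(rid)
        if a is None:
            violations.append((f"active reaction {rid} has no magnitude", 0))
        elif not (a_min <= a <= a_max):
            violations.append((f"magnitude of {rid} outside [{a_min}, {a_max}]", a))
    if solution.k_op != len(solution.active_set):
        violations.append(("recorded length k_op != |active_set|", solution.k_op))

    net: dict[str, int] = {}
    for rid in solution.active_set:
        a = solution.magnitudes.get(rid, 0)
        for met, coeff in by_id[rid].stoichiometry.items():
            net[met] = net.get(met, 0) + int(coeff) * a
    for met in sorted(part.targets):
        value = net.get(met, 0)
        if value < 1:
            violations.append((f"target {met} net production not strictly positive", value))
    for met in sorted(part.intermediates):
        value = net.get(met, 0)
        if value < 0:
            violations.append((f"intermediate {met} net consumed", value))
    for pair in dnet.reverse_pairs:
        if pair <= solution.active_set:
            violations.append((f"both directions active: {sorted(pair)}", 2))
    for met, recorded in solution.net_production.items():
        if recorded != net.get(met, 0):
            violations.append((f"recorded net production of {met} inconsistent", recorded))
    return VerificationReport(satisfied=not violations, violations=tuple(violations))


def brute_force_enumerate(
    dnet: DirectedNetwork,
    part: CompoundPartition,
    k_max: int,
    a_max_small: int = 4,
    max_directed: int = 14,
) -> list[tuple[frozenset[str], int]]:
    """Exhaustively list all minimal feasible active sets of size <= k_max.

    Tests every reaction subset (respecting reversible-direction pairs)
    against every integer magnitude vector in [1, a_max_small]^|subset|,
    by direct evaluation of the balance semantics. "Minimal" means no
    feasible proper subset — exactly what the cardinality-plus-exclusion
    iteration of the solver produces. Output is sorted by (size,
    lexicographic ids).

    The magnitude bound is an explicit parameter: for the networks this
    oracle is meant for, feasible pathways only need small integer
    magnitudes, and tests assert per fixture that raising the bound does not
    change the result. Instances beyond ``max_directed`` reactions or
    ``a_max_small > 8`` are refused.
    """
    ids = dnet.reaction_ids
    if len(ids) > max_directed:
        raise InstanceTooLargeError(
            f"oracle limited to {max_directed} directed reactions (got {len(ids)})"
        )
    if a_max_small > 8:
        raise InstanceTooLargeError(f"oracle magnitude bound limited to 8 (got {a_max_small})")

    by_id = {r.id: r for r in dnet.base.reactions}
    pairs = [frozenset(p) for p in dnet.reverse_pairs]
    producers = {  # metabolite -> reactions with positive coefficient
        met: {r.id for r in dnet.base.reactions if r.stoichiometry.get(met, 0) > 0}
        for met in dnet.base.metabolite_ids
    }
    grids: dict[int, np.ndarray] = {}

    def grid(size: int) -> np.ndarray:
        if size not in grids:
            grids[size] = np.array(
                list(itertools.product(range(1, a_max_small + 1), repeat=size)), dtype=np.int64
            )
        return grids[size]

    minimal: list[tuple[frozenset[str], int]] = []
    for size in range(1, min(k_max, len(ids)) + 1):
        for combo in itertools.combinations(sorted(ids), size):
            subset = frozenset(combo)
            if any(found <= subset for found, _ in minimal):
                continue  # contains a known feasible set: not minimal
            if any(pair <= subset for pair in pairs):
                continue
            if _feasible(combo, subset, by_id, part, producers, grid):
                minimal.append((subset, size))
    minimal.sort(key=lambda item: (item[1], tuple(sorted(item[0]))))
    return minimal


def _feasible(combo: Sequence[str], subset, by_id, part, producers, grid) -> bool:
    # cheap necessary conditions before the exhaustive magnitude scan
    for met in part.targets:
        if not (producers[met] & subset):
            return False
    touched: dict[str, list[tuple[int, int]]] = {}
    for pos, rid in enumerate(combo):
        for met, coeff in by_id[rid].stoichiometry.items():
            if met not in part.basis:
                touched.setdefault(met, []).append((pos, int(coeff)))
    for met, entries in touched.items():
        if all(c < 0 for _, c in entries) and (met in part.intermediates or met in part.targets):
            return False  # only consumed: balance can never reach its lower bound

    rows, lowers = [], []
    for met, entries in touched.items():
        row = np.zeros(len(combo), dtype=np.int64)
        for pos, c in entries:
            row[pos] = c
        rows.append(row)
        lowers.append(1 if met in part.targets else 0)
    for met in part.targets:  # untouched targets already rejected above
        if met not in touched:
            return False
    if not rows:
        return False
    a_matrix = np.stack(rows)  # (n_rows, size)
    net = grid(len(combo)) @ a_matrix.T  # (n_vectors, n_rows)
    return bool(np.any(np.all(net >= np.asarray(lowers), axis=1)))
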