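# Methods

## Model

A metabolic network is the stoichiometric matrix **S** (m compounds x n
directed reactions, integer coefficients after preprocessing). A pathway
query partitions the compounds into basis **B** (freely available,
unconstrained), targets **T** (net production strictly positive) and
intermediates **I** (net production non-negative). The deliberate relaxation
relative to steady state is the `>=` on **I**: a candidate pathway is allowed
to accumulate by-products, on the assumption that other pathways operating in
parallel consume them; it is *not* allowed to net-consume an intermediate,
since nothing guarantees the cell holds a sustainable supply of it.

Each directed reaction carries two variables: a Boolean activity b_i and a
positive integer magnitude a_i in [a_min, a_max]. The magnitude is a
*relative* measure of the reaction's contribution within one pathway, not a
physical flux; a_i is meaningful only where b_i is true and is masked out of
reported solutions otherwise. Reported pathways carry both raw magnitudes
and magnitudes normalized by their collective GCD (the relative flux
ratios), since the absolute scale of a_i carries no information.

## Preprocessing

* **Exact coefficients.** Stoichiometries are parsed as exact rationals
  (decimal strings -> `fractions.Fraction`; SBML doubles through their
  shortest decimal representation). GCD/LCM arithmetic on binary floats
  would be meaningless.
* **Integerization** is per reaction: multiply by the LCM of denominators,
  divide by the GCD of the resulting integers. Because a_i is a free
  positive integer, per-reaction positive rescaling leaves the *active-set*
  solution space unchanged; its only effect is on which magnitude ratios are
  reachable inside [a_min, a_max], which is a caveat for extreme
  coefficient ratios, not for the networks treated here.
* **Reversible splitting** replaces each reversible reaction by a forward
  copy (original id) and a reverse copy (id + `__rev`, negated
  stoichiometry), with a direction constraint b_fwd + b_rev <= 1 per pair.
* **Knockouts** remove reactions by exact id; an unknown id is a hard error.
  Orphaned metabolites are kept (they contribute only vacuous constraints).

## Constraint system and backends

For targets the strict requirement "net production > 0" is encoded as
`>= 1`: every left-hand side is a sum of integer products, so the two are
exactly equivalent and no epsilon enters anywhere.

The only nonlinearity is the product a_i * b_i. The backend contract
linearises it through an effective-flux variable f_i with indicator
semantics: b_i = 0 forces f_i = 0, b_i = 1 forces a_min <= f_i <= a_max.
Any engine deciding conjunctions of integer-linear constraints under this
contract can serve. Two are shipped:

* **milp** (default): HiGHS through `scipy.optimize.milp`, with binary b,
  integer f, and the linking rows a_min*b_i <= f_i <= a_max*b_i. A zero
  objective turns the MIP into a pure feasibility check. HiGHS's
  "infeasible" status is a proof, reported as UNSAT; hitting the time limit
  raises a distinct *unknown* error and is never conflated with UNSAT.
* **backtracking**: an exact combinatorial search — candidate activity sets
  in increasing size (pruned by direction, cardinality and exclusion
  constraints), with magnitude feasibility decided by depth-first search
  with interval (bounds-consistency) propagation over the integer
  magnitudes. Guarded to 16 directed reactions; it exists to cross-validate
  the MILP encoding on small instances, not to scale.

Every assignment a backend claims satisfying is re-evaluated by direct
integer arithmetic before being surfaced (twice, in fact: against the
constraint objects, and by the independent verifier in the oracle module,
which recomputes net production straight from the network).

## Search

**Shortest pathway.** The cardinality bound k (sum of b_i <= k) starts at
the number of directed reactions and is minimised by binary search: bisect
between 1 and the incumbent's active-set size, keeping the invariant that
the bound one below the lower end is proven UNSAT. The result is a shortest
pathway *with its minimality certificate* (UNSAT at k_op - 1) produced as a
by-product of the search; for k_op = 1 the certificate is vacuous, since
with no active reaction no target can be produced. A linear-descent mode
(successively smaller k) is kept behind a flag; it visits more solver calls
but yields the same optimum.

**Enumeration.** After each shortest solution with active set K, the integer
cut `sum_{i in K} b_i <= |K| - 1` is added and the search re-minimised. The
cut removes exactly K and its supersets; proper subsets of any feasible
solution of minimal length are already infeasible, so the iteration yields
precisely the *minimal feasible active sets* in non-decreasing size, and a
final UNSAT proves exhaustion. One cut per found pathway; no stronger cuts
are added, to keep the excluded region exactly the published rule.

**Canonical order.** Equal-length pathways have no intrinsic order (the
backend may return them in any sequence). Output is canonicalized by
enumerating each equal-length batch to exhaustion before applying the
`max_pathways` cap, then sorting the batch lexicographically on its sorted
reaction ids. Runs with different caps therefore agree on their common
prefix, and two runs with identical inputs produce byte-identical reports
(report payloads carry no timestamps).

k is re-minimised after every exclusion rather than held fixed; this is what
makes the pathway lengths non-decreasing and the UNSAT terminal a proof of
completeness.

## Oracle

`brute_force_enumerate` is the ground truth for testing: it tries every
reaction subset up to size k_max and every magnitude vector in
[1, a_max_small]^|subset| by direct evaluation, returning all minimal
feasible sets. The magnitude bound (default 4, capped at 8) is an explicit
parameter: feasible pathways on the instance sizes the oracle accepts (<= 14
directed reactions) need only small magnitudes, and the fixture tests assert
that raising the bound does not change the result. Minimality means "no
feasible proper subset" — the same notion the cardinality-plus-exclusion
iteration produces, which is why exact set equality between solver and
oracle is a meaningful test. The central correctness property of the
repository is that equality over hundreds of seeded random networks, with
the solver run at the same magnitude bound as the oracle.

## Defaults and parameters

| parameter | default | meaning |
|---|---|---|
| a_min, a_max | 1, 1000 | magnitude interval; integer, unitless (relative flux) |
| k_init | n directed reactions | initial cardinality bound |
| max_pathways | 10 (CLI) / 100 (library) | enumeration cap |
| k_limit | none | stop once the next shortest pathway would exceed this length |
| backend | milp | `milp` or `backtracking` |
| strategy | binary | `binary` or `linear` k-minimisation |
| timeout | 300 s | per solver call; expiry raises *unknown*, never UNSAT |
| oracle a_max_small | 4 | exhaustive magnitude bound, capped at 8 |

The currency-metabolite basis preset (`currency`) holds ATP, ADP, NAD, NADH,
FAD, FADH2, H2O, H+ and NH4+ — cofactors buffered by the whole system, whose
inclusion in **B** prevents spurious coupling of unrelated pathways. The
substrate under study (glutamate in the fixture) is added to the basis
explicitly; basis membership is always the user's choice, never inferred
from SBML boundary conditions.

## Fixture and synthetic networks

The packaged fixture is the glutamate -> 2-oxoglutarate subnetwork of
*B. subtilis* catabolism: 10 irreversible reactions, 17 metabolites, with
NAD/NADH, H2O, NH4+, H+ and glutamate in the basis and 2-oxoglutarate the
sole target. Its four minimal pathways (three transaminase/deaminase pairs
of length 2, the aspartase route of length 4) are frozen in the fixture spec
and independently confirmed by the brute-force oracle. Cofactor
stoichiometry in the fixture follows standard dehydrogenase/deaminase
chemistry; since all such species are basis members they cannot alter the
pathway set. Pyruvate, the branched-chain 2-oxo acids and oxaloacetate are
deliberately intermediates: that forces each transamination substrate to be
replenished by the rest of its pathway, which is the structural point of the
case study. The same network ships as native TSV/JSON and as SBML under
`src/spabbats/data/`.

`random_network` generates small connected seeded networks (coefficients
|c| <= 3, optional reversible fraction) for the equivalence and monotonicity
suites. These networks emulate the combinatorial structure of metabolic
subnetworks (sparse, small integer coefficients, shared intermediates), not
their biochemistry: passing the property suite shows the solver and encoding
are correct on that structure, not that any particular biological model is
right. Problem sizes in the test and acceptance runs (3-6 metabolites, up to
12 directed reactions, 200 seeds, magnitude bound 4) are chosen so the
exhaustive oracle remains exact ground truth; the solver itself has no such
limits and the MILP backend is the one intended for genome-scale use.

## Degenerate inputs and tie-breaks

Empty target sets, k < 1, zero coefficients, duplicate ids, and unknown ids
in knockouts/partitions/exclusions are hard errors. An unreachable target
yields a clean empty enumeration terminated by `exhausted`. Equal-length
tie-breaks are the canonical lexicographic order described above — an
artifact convention, not a claim about biological priority.

## Known limitations

* No gene-protein-reaction rules, no compartment-aware transport modelling,
  no thermodynamic feasibility, no regulatory (Boolean gene-state)
  constraints.
* Not an elementary-flux-mode enumerator: it finds minimal pathways in order
  of length and can stop early, which is the point, but it does not
  characterise the full flux cone.
* The magnitude interval [1, 1000] bounds reachable flux *ratios* within a
  pathway; pathways requiring more extreme internal ratios would be missed
  (none of the tested instances comes close).
* The backtracking backend and the oracle are exponential by design and
  size-guarded; only the MILP backend is meant for large models.
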