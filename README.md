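# spabbats

Satisfiability-based search for the **shortest stoichiometrically balanced
pathways** between a set of freely available *basis* metabolites and a set of
*target* metabolites in a metabolic network, with enumeration of alternative
pathways in order of increasing reaction count.

## The problem and who this is for

Flux-balance methods constrain every internal metabolite to steady state and
optimize an extrinsic objective. That discards biologically real pathways in
which a by-product accumulates and is cleaned up by the rest of metabolism —
exactly the kind of route a **suppressor mutant** tends to activate when a
canonical pathway is knocked out. This package is for microbiologists and
metabolic engineers who want a short, prioritized list of candidate routes
from substrate to product that (a) are stoichiometrically sustainable and
(b) may let intermediates accumulate.

## The model

Let **S** be the m x n stoichiometric matrix (s_ij = coefficient of compound
j in directed reaction i; reversible reactions are split into two opposed
irreversible copies). Metabolites are partitioned into three disjoint sets:

* **B** (basis): freely available — medium components and currency
  metabolites (ATP, NAD(H), ...). *Unconstrained.*
* **T** (targets): net production must be strictly positive.
* **I** (intermediates): net production must be non-negative
  (accumulation allowed, net consumption forbidden).

Each directed reaction i carries a positive integer flux magnitude
a_i in [a_min, a_max] (default [1, 1000]) and a Boolean activity b_i.
The constraint system is

    for t in T:            sum_i  s_it * a_i * b_i  >= 1
    for j in I:            sum_i  s_ij * a_i * b_i  >= 0
    per reversible pair:   b_i + b_j <= 1
    pathway length:        sum_i  b_i <= k

All quantities are integers, so "> 0" and ">= 1" coincide exactly. Minimizing
k (binary search by default) yields a shortest pathway with an UNSAT
certificate at k_op - 1; adding the integer cut
`sum_{i in K} b_i <= k_op - 1` over its active set K excludes it (and all its
supersets) and re-solving enumerates alternatives in non-decreasing length.

Two interchangeable backends decide the system: `milp` (HiGHS via scipy,
with the product a_i*b_i linearised through an indicator variable) and
`backtracking` (an exact, size-guarded combinatorial search used for
cross-validation). Every surfaced pathway is re-checked by an independent
arithmetic verifier, and on small instances the whole enumeration is tested
against an exhaustive brute-force oracle.

## Worked example

The packaged fixture is the glutamate-utilization network of *Bacillus
subtilis*: can a strain without glutamate dehydrogenase still convert
glutamate (basis, together with the currency metabolites) into
2-oxoglutarate (target)?

```sh
spabbats find --model src/spabbats/data/glutamate.tsv \
    --basis-preset currency --basis glutamate \
    --target oxoglutarate --max-pathways 10
```

prints

```
4 pathway(s); enumeration exhausted

pathway 1 (2 reactions)
  ALD  (a=1, relative flux 1)
  ALT  (a=1, relative flux 1)
  net: oxoglutarate: +1

pathway 2 (2 reactions)
  BCAT_leu  (a=1, relative flux 1)
  BCD_leu  (a=1, relative flux 1)
  net: oxoglutarate: +1

pathway 3 (2 reactions)
  BCAT_val  (a=1, relative flux 1)
  BCD_val  (a=1, relative flux 1)
  net: oxoglutarate: +1

pathway 4 (4 reactions)
  ANSB  (a=1, relative flux 1)
  ASPB  (a=1, relative flux 1)
  CITG  (a=1, relative flux 1)
  MDH  (a=1, relative flux 1)
  net: oxoglutarate: +1
```

Three two-step routes pair a transaminase with the matching deaminase
(alanine via Ald; leucine and valine via Bcd); the four-step route runs
glutamate -> aspartate -> fumarate -> malate -> oxaloacetate through the
aspartase AnsB, regenerating the transamination substrate. Each pathway
nets exactly +1 target per round with every intermediate balanced — the
`net:` line is recomputed from the model and the magnitudes, and
`enumeration exhausted` means a fifth alternative is *provably* absent
(UNSAT), not merely unfound. Knocking out the aspartase
(`--remove-reaction ANSB`) leaves three pathways; knocking out all four
transaminases leaves none.

The same pipeline is available as a library:

```python
import spabbats as sp

fx = sp.glutamate_fixture()
net = sp.integerize_network(fx.network)
dnet = sp.split_reversible(net)
part = sp.partition_compounds(net, fx.basis_ids, fx.target_ids)
result = sp.enumerate_pathways(dnet, part, max_pathways=10)
print([(sorted(p.active_set), p.k_op) for p in result.pathways])
# [(['ALD', 'ALT'], 2), (['BCAT_leu', 'BCD_leu'], 2),
#  (['BCAT_val', 'BCD_val'], 2), (['ANSB', 'ASPB', 'CITG', 'MDH'], 4)]
```

SBML Level 2/3 models are read with `sp.read_sbml(path)`; basis membership
is always an explicit user choice, never inferred from boundary conditions.

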