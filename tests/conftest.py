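from fractions import Fraction

import pytest

import spabbats as sp


def make_network(reactions, reversible=()):
    """Build a Network from {rxn_id: {met: coeff}} dicts."""
    mets = {m for st in reactions.values() for m in st}
    return sp.Network(
        metabolites=tuple(sp.Metabolite(id=m) for m in sorted(mets)),
        reactions=tuple(
            sp.Reaction(
                id=rid,
                stoichiometry={m: Fraction(c) for m, c in st.items()},
                reversible=rid in reversible,
            )
            for rid, st in reactions.items()
        ),
    )


def prepare(network, basis, targets):
    """Integerize, split, partition — the standard preprocessing pipeline."""
    net = sp.integerize_network(network)
    dnet = sp.split_reversible(net)
    part = sp.partition_compounds(net, basis, targets)
    return dnet, part


@pytest.fixture(scope="session")
def glutamate():
    """The preprocessed glutamate-utilization fixture: (spec, dnet, part)."""
    fx = sp.glutamate_fixture()
    dnet, part = prepare(fx.network, fx.basis_ids, fx.target_ids)
    return fx, dnet, part


@pytest.fixture
def chain():
    """Linear chain g -> x -> o with basis {g}, target {o}: one 2-step pathway."""
    net = make_network({"R1": {"g": -1, "x": 1}, "R2": {"x": -1, "o": 1}})
    return prepare(net, {"g"}, {"o"})


def enumerate_all(dnet, part, **kw):
    """Enumeration as (sorted ids, length) pairs, for comparison with the oracle."""
    kw.setdefault("max_pathways", 500)
    result = sp.enumerate_pathways(dnet, part, **kw)
    return [(p.active_set, p.k_op) for p in result.pathways]
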