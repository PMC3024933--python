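"""Packaged test networks.

:func:`glutamate_fixture` is the glutamate-to-2-oxoglutarate subnetwork of
*Bacillus subtilis* catabolism: four transaminase/deaminase routes by which a
strain lacking glutamate dehydrogenase can still convert glutamate to
2-oxoglutarate. The three two-step routes pair a transaminase with the
matching deaminase (Ald for alanine, Bcd for the branched-chain amino acids);
the four-step route runs through aspartate: aspartate aminotransferase
(AspB), aspartase (AnsB), fumarase (CitG) and malate dehydrogenase (Mdh).

Cofactor detail (NAD/NADH, H2O, NH4, H) follows standard dehydrogenase and
deaminase stoichiometry; these species are all basis-set members, hence
unconstrained, so their exact bookkeeping cannot change the pathway set.
Pyruvate, the branched-chain 2-oxo acids and oxaloacetate are deliberately
intermediates, not basis members: that is what forces each transamination
substrate to be replenished by the rest of its pathway.

:func:`random_network` generates small seeded networks for property tests.
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from fractions import Fraction
from importlib.resources import files

from .errors import MalformedModelError
from .network import Metabolite, Network, Reaction

#: Ubiquitous cofactors treated as freely available ("currency metabolites").
#: The study substrate (e.g. glutamate) is added to the basis separately.
CURRENCY_BASIS = ("atp", "adp", "nad", "nadh", "fad", "fadh2", "h2o", "h", "nh4")


@dataclass(frozen=True)
class FixtureSpec:
    """A packaged network together with its query and expected answer."""

    name: str
    network: Network
    basis_ids: frozenset[str]
    target_ids: frozenset[str]
    expected_pathways: tuple[tuple[frozenset[str], int], ...]


_GLUTAMATE_METABOLITES = (
    ("glutamate", "L-glutamate"),
    ("oxoglutarate", "2-oxoglutarate"),
    ("pyruvate", "pyruvate"),
    ("alanine", "L-alanine"),
    ("leucine", "L-leucine"),
    ("methyloxopentanoate", "4-methyl-2-oxo-pentanoate"),
    ("valine", "L-valine"),
    ("methyloxobutanoate", "3-methyl-2-oxo-butanoate"),
    ("aspartate", "L-aspartate"),
    ("oxaloacetate", "oxaloacetate"),
    ("fumarate", "fumarate"),
    ("malate", "L-malate"),
    ("nad", "NAD+"),
    ("nadh", "NADH"),
    ("h2o", "H2O"),
    ("nh4", "NH4+"),
    ("h", "H+"),
)

_GLUTAMATE_REACTIONS = (
    ("ALT", "alanine transaminase",
     {"glutamate": -1, "pyruvate": -1, "oxoglutarate": 1, "alanine": 1}),
    ("ALD", "alanine dehydrogenase (Ald)",
     {"alanine": -1, "nad": -1, "h2o": -1, "pyruvate": 1, "nh4": 1, "nadh": 1, "h": 1}),
    ("BCAT_leu", "branched-chain transaminase, leucine (YbgE/YwaA)",
     {"glutamate": -1, "methyloxopentanoate": -1, "oxoglutarate": 1, "leucine": 1}),
    ("BCD_leu", "leucine dehydrogenase (Bcd)",
     {"leucine": -1, "nad": -1, "h2o": -1, "methyloxopentanoate": 1, "nh4": 1, "nadh": 1, "h": 1}),
    ("BCAT_val", "branched-chain transaminase, valine (YbgE/YwaA)",
     {"glutamate": -1, "methyloxobutanoate": -1, "oxoglutarate": 1, "valine": 1}),
    ("BCD_val", "valine dehydrogenase (Bcd)",
     {"valine": -1, "nad": -1, "h2o": -1, "methyloxobutanoate": 1, "nh4": 1, "nadh": 1, "h": 1}),
    ("ASPB", "aspartate aminotransferase (AspB)",
     {"glutamate": -1, "oxaloacetate": -1, "oxoglutarate": 1, "aspartate": 1}),
    ("ANSB", "aspartase (AnsB)",
     {"aspartate": -1, "fumarate": 1, "nh4": 1}),
    ("CITG", "fumarase (CitG)",
     {"fumarate": -1, "h2o": -1, "malate": 1}),
    ("MDH", "malate dehydrogenase (Mdh)",
     {"malate": -1, "nad": -1, "oxaloacetate": 1, "nadh": 1, "h": 1}),
)


def glutamate_fixture() -> FixtureSpec:
    """The glutamate-utilization network with its four expected pathways."""
    network = Network(
        metabolites=tuple(Metabolite(id=i, name=n) for i, n in _GLUTAMATE_METABOLITES),
        reactions=tuple(
            Reaction(id=i, name=n, stoichiometry={m: Fraction(c) for m, c in st.items()})
            for i, n, st in _GLUTAMATE_REACTIONS
        ),
    )
    basis = frozenset({"nad", "nadh", "h2o", "nh4", "h", "glutamate"})
    expected = (
        (frozenset({"ALT", "ALD"}), 2),
        (frozenset({"BCAT_leu", "BCD_leu"}), 2),
        (frozenset({"BCAT_val", "BCD_val"}), 2),
        (frozenset({"ASPB", "ANSB", "CITG", "MDH"}), 4),
    )
    return FixtureSpec(
        name="glutamate",
        network=network,
        basis_ids=basis,
        target_ids=frozenset({"oxoglutarate"}),
        expected_pathways=expected,
    )


def fixture_path(name: str):
    """Path-like handle to a packaged fixture data file (e.g. "glutamate.tsv")."""
    return files("spabbats").joinpath("data", name)


def random_network(
    n_metabolites: int,
    n_reactions: int,
    reversible_fraction: float = 0.0,
    seed: int = 0,
) -> Network:
    """A seeded, connected random network with small integer coefficients.

    Deterministic for identical arguments. Reaction r_i consumes a metabolite
    already reachable from m0 and produces another (preferring unused ones
    until every metabolite appears), so the metabolite-reaction graph is
    connected; extra substrates/products are sprinkled in with |coeff| <= 3.
    """
    if n_metabolites < 2:
        raise MalformedModelError("random_network needs at least 2 metabolites")
    if n_reactions < 1:
        raise MalformedModelError("random_network needs at least 1 reaction")
    if n_reactions < n_metabolites - 1:
        raise MalformedModelError(
            f"cannot connect {n_metabolites} metabolites with only {n_reactions} reactions"
        )
    if not (0.0 <= reversible_fraction <= 1.0):
        raise MalformedModelError("reversible_fraction must be in [0, 1]")

    rng = random.Random(seed)
    mets = [f"m{i}" for i in range(n_metabolites)]
    used = ["m0"]
    unused = mets[1:]
    n_reversible = int(round(reversible_fraction * n_reactions))
    reversible_idx = set(rng.sample(range(n_reactions), n_reversible))
    reactions = []
    for i in range(n_reactions):
        substrate = rng.choice(used)
        if unused:
            product = unused.pop(0)
            used.append(product)
        else:
            product = rng.choice([m for m in mets if m != substrate])
        stoich = {substrate: -rng.randint(1, 3), product: rng.randint(1, 3)}
        for extra in rng.sample(mets, k=rng.randint(0, 2)):
            if extra not in stoich:
                stoich[extra] = rng.choice([-1, 1]) * rng.randint(1, 3)
        reactions.append(
            Reaction(
                id=f"r{i}",
                stoichiometry={m: Fraction(c) for m, c in stoich.items()},
                reversible=i in reversible_idx,
            )
        )
    return Network(
        metabolites=tuple(Metabolite(id=m) for m in mets), reactions=tuple(reactions)
    )
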