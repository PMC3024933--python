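"""Reading networks (SBML and native TSV/JSON) and writing pathway reports.

Native formats keep stoichiometric coefficients as exact decimal (or p/q)
strings, so a write/read cycle is lossless. The native TSV is one reaction
per line::

    id<TAB>rev|irr<TAB>met:coeff,met:coeff,...

The JSON form carries the same records plus optional metabolite names.

Reports list, per pathway: rank, length, active reactions with raw and
GCD-normalized magnitudes, net production per non-basis metabolite, and the
accumulated intermediates (non-target species with strictly positive net
production — the deliberate relaxation of steady state that distinguishes
this method from flux-balance approaches). Report payloads carry no
timestamps, so they are regenerable byte-identically.
"""

from __future__ import annotations

import json
from fractions import Fraction
from pathlib import Path

from .errors import MalformedModelError, ModelIOError
from .network import CompoundPartition, Metabolite, Network, Reaction, as_fraction
from .solver import EnumerationResult, PathwaySolution


def coeff_to_str(value: Fraction) -> str:
    """Serialize an exact coefficient: integer, terminating decimal, or p/q."""
    value = Fraction(value)
    if value.denominator == 1:
        return str(value.numerator)
    den = value.denominator
    twos = fives = 0
    while den % 2 == 0:
        den //= 2
        twos += 1
    while den % 5 == 0:
        den //= 5
        fives += 1
    if den == 1:  # terminating decimal
        shift = max(twos, fives)
        scaled = value.numerator * 10**shift // value.denominator
        text = str(abs(scaled)).rjust(shift + 1, "0")
        sign = "-" if scaled < 0 else ""
        return f"{sign}{text[:-shift]}.{text[-shift:]}"
    return f"{value.numerator}/{value.denominator}"


# ---------------------------------------------------------------------------
# SBML


def read_sbml(path) -> Network:
    """Read a single-model SBML Level 2/3 file.

    Reactants get negative, products positive coefficients (summed if a
    species appears on both sides); reversibility comes from the reaction's
    ``reversible`` attribute. Boundary/exchange species are kept as ordinary
    metabolites — membership in the basis set is the user's call, never the
    parser's.
    """
    import libsbml

    doc = libsbml.readSBML(str(path))
    errors = [
        doc.getError(i)
        for i in range(doc.getNumErrors())
        if doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
    ]
    if errors:
        first = errors[0]
        raise ModelIOError(
            f"malformed SBML {path}: line {first.getLine()}: {first.getMessage().strip()}"
        )
    model = doc.getModel()
    if model is None:
        raise ModelIOError(f"no model element in SBML file {path}")

    metabolites = tuple(
        Metabolite(
            id=sp.getId(),
            name=sp.getName() or None,
            compartment=sp.getCompartment() or None,
        )
        for sp in model.getListOfSpecies()
    )
    reactions = []
    for rxn in model.getListOfReactions():
        stoich: dict[str, Fraction] = {}
        for ref, sign in ((r, -1) for r in rxn.getListOfReactants()):
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + sign * as_fraction(
                ref.getStoichiometry()
            )
        for ref in rxn.getListOfProducts():
            stoich[ref.getSpecies()] = stoich.get(ref.getSpecies(), Fraction(0)) + as_fraction(
                ref.getStoichiometry()
            )
        stoich = {m: c for m, c in stoich.items() if c != 0}
        if not stoich:
            raise ModelIOError(f"SBML reaction {rxn.getId()!r} has empty net stoichiometry")
        reactions.append(
            Reaction(
                id=rxn.getId(),
                name=rxn.getName() or None,
                stoichiometry=stoich,
                reversible=bool(rxn.getReversible()),
            )
        )
    try:
        return Network(metabolites=metabolites, reactions=tuple(reactions))
    except MalformedModelError as exc:
        raise ModelIOError(f"invalid SBML model {path}: {exc}") from exc


# ---------------------------------------------------------------------------
# native formats


def read_native(path, fmt: str | None = None) -> Network:
    """Read the native TSV or JSON model format (auto-detected by suffix)."""
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    text = path.read_text()
    if fmt == "json":
        return _network_from_json(text, str(path))
    if fmt == "tsv":
        return _network_from_tsv(text, str(path))
    raise ModelIOError(f"unknown native model format: {fmt!r}")


def write_native(network: Network, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = fmt or ("json" if path.suffix.lower() == ".json" else "tsv")
    if fmt == "json":
        path.write_text(network_to_json(network))
    elif fmt == "tsv":
        path.write_text(network_to_tsv(network))
    else:
        raise ModelIOError(f"unknown native model format: {fmt!r}")


def network_to_tsv(network: Network) -> str:
    lines = []
    for rxn in network.reactions:
        pairs = ",".join(
            f"{m}:{coeff_to_str(c)}" for m, c in sorted(rxn.stoichiometry.items())
        )
        lines.append(f"{rxn.id}\t{'rev' if rxn.reversible else 'irr'}\t{pairs}")
    return "\n".join(lines) + "\n"


def _network_from_tsv(text: str, source: str) -> Network:
    reactions = []
    met_ids: dict[str, None] = {}
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ModelIOError(f"{source}:{lineno}: expected 3 tab-separated fields")
        rid, revflag, pairs = parts
        if revflag not in ("rev", "irr"):
            raise ModelIOError(f"{source}:{lineno}: reversibility must be 'rev' or 'irr'")
        stoich: dict[str, Fraction] = {}
        for pair in pairs.split(","):
            met, sep, coeff = pair.rpartition(":")
            if not sep or not met:
                raise ModelIOError(f"{source}:{lineno}: malformed metabolite:coeff pair {pair!r}")
            try:
                stoich[met] = as_fraction(coeff)
            except MalformedModelError as exc:
                raise ModelIOError(f"{source}:{lineno}: {exc}") from exc
            met_ids.setdefault(met)
        try:
            reactions.append(Reaction(id=rid, stoichiometry=stoich, reversible=revflag == "rev"))
        except MalformedModelError as exc:
            raise ModelIOError(f"{source}:{lineno}: {exc}") from exc
    if not reactions:
        raise ModelIOError(f"{source}: a model must define at least one reaction")
    try:
        return Network(
            metabolites=tuple(Metabolite(id=m) for m in met_ids),
            reactions=tuple(reactions),
        )
    except MalformedModelError as exc:
        raise ModelIOError(f"{source}: {exc}") from exc


def network_to_json(network: Network) -> str:
    payload = {
        "metabolites": [
            {
                "id": m.id,
                **({"name": m.name} if m.name else {}),
                **({"compartment": m.compartment} if m.compartment else {}),
            }
            for m in network.metabolites
        ],
        "reactions": [
            {
                "id": r.id,
                **({"name": r.name} if r.name else {}),
                "reversible": r.reversible,
                "stoichiometry": {m: coeff_to_str(c) for m, c in sorted(r.stoichiometry.items())},
            }
            for r in network.reactions
        ],
    }
    return json.dumps(payload, indent=2) + "\n"


def _network_from_json(text: str, source: str) -> Network:
    try:
        payload = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ModelIOError(f"{source}: invalid JSON: {exc}") from exc
    try:
        reactions = tuple(
            Reaction(
                id=rec["id"],
                name=rec.get("name"),
                reversible=bool(rec.get("reversible", False)),
                stoichiometry={m: as_fraction(c) for m, c in rec["stoichiometry"].items()},
            )
            for rec in payload["reactions"]
        )
        if not reactions:
            raise ModelIOError(f"{source}: a model must define at least one reaction")
        declared = {
            rec["id"]: Metabolite(
                id=rec["id"], name=rec.get("name"), compartment=rec.get("compartment")
            )
            for rec in payload.get("metabolites", [])
        }
        for rxn in reactions:
            for met in rxn.stoichiometry:
                declared.setdefault(met, Metabolite(id=met))
        return Network(metabolites=tuple(declared.values()), reactions=reactions)
    except ModelIOError:
        raise
    except (KeyError, TypeError, MalformedModelError) as exc:
        raise ModelIOError(f"{source}: invalid model JSON: {exc}") from exc


# ---------------------------------------------------------------------------
# reports


def result_to_dict(result: EnumerationResult) -> dict:
    """The canonical report payload for an enumeration result."""
    part = result.partition
    pathways = []
    for rank, p in enumerate(result.pathways, start=1):
        normalized = p.normalized_magnitudes
        non_basis_net = {
            m: v
            for m, v in sorted(p.net_production.items())
            if part is None or m not in part.basis
        }
        accumulated = {
            m: v
            for m, v in non_basis_net.items()
            if v > 0 and (part is None or m not in part.targets)
        }
        pathways.append(
            {
                "rank": rank,
                "length": p.k_op,
                "reactions": {
                    r: {"magnitude": p.magnitudes[r], "normalized": normalized[r]}
                    for r in sorted(p.active_set)
                },
                "net_production": non_basis_net,
                "accumulated_intermediates": accumulated,
            }
        )
    return {"n_pathways": len(result.pathways), "terminated_by": result.terminated_by,
            "pathways": pathways}


def result_from_dict(payload: dict, partition: CompoundPartition | None = None) -> EnumerationResult:
    """Rebuild an EnumerationResult from a JSON report payload."""
    pathways = []
    for rec in payload["pathways"]:
        active = frozenset(rec["reactions"])
        magnitudes = {r: int(v["magnitude"]) for r, v in rec["reactions"].items()}
        pathways.append(
            PathwaySolution(
                active_set=active,
                magnitudes=magnitudes,
                k_op=int(rec["length"]),
                net_production={m: int(v) for m, v in rec["net_production"].items()},
            )
        )
    return EnumerationResult(
        pathways=tuple(pathways), terminated_by=payload["terminated_by"], partition=partition
    )


def render_report(result: EnumerationResult, fmt: str = "text") -> str:
    """Render a verified enumeration result as json, tsv, or text."""
    payload = result_to_dict(result)
    if fmt == "json":
        return json.dumps(payload, indent=2) + "\n"
    if fmt == "tsv":
        lines = ["rank\tlength\treactions\tmagnitudes\tnet_production\taccumulated"]
        for rec in payload["pathways"]:
            rxns = ";".join(rec["reactions"])
            mags = ";".join(f"{r}={v['magnitude']}" for r, v in rec["reactions"].items())
            net = ";".join(f"{m}={v}" for m, v in rec["net_production"].items())
            acc = ";".join(f"{m}={v}" for m, v in rec["accumulated_intermediates"].items())
            lines.append(f"{rec['rank']}\t{rec['length']}\t{rxns}\t{mags}\t{net}\t{acc}")
        lines.append(f"# terminated_by: {payload['terminated_by']}")
        return "\n".join(lines) + "\n"
    if fmt == "text":
        lines = [f"{payload['n_pathways']} pathway(s); enumeration {payload['terminated_by']}"]
        for rec in payload["pathways"]:
            lines.append("")
            lines.append(f"pathway {rec['rank']} ({rec['length']} reactions)")
            for r, v in rec["reactions"].items():
                lines.append(f"  {r}  (a={v['magnitude']}, relative flux {v['normalized']})")
            net = ", ".join(f"{m}: {v:+d}" for m, v in rec["net_production"].items() if v != 0)
            lines.append(f"  net: {net}")
            if rec["accumulated_intermediates"]:
                acc = ", ".join(f"{m} (+{v})" for m, v in rec["accumulated_intermediates"].items())
                lines.append(f"  accumulates: {acc}")
        return "\n".join(lines) + "\n"
    raise ModelIOError(f"unknown report format: {fmt!r}")


def write_report(result: EnumerationResult, path, fmt: str = "json") -> None:
    try:
        Path(path).write_text(render_report(result, fmt))
    except OSError as exc:
        raise ModelIOError(f"cannot write report to {path}: {exc}") from exc
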