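"""Stoichiometric hydrogen-economy ledger for anaerobic polyphenol degradation.

The ledger balances chemical reactions exactly (element by element, plus net
charge), collapses multi-step degradation routes into net reactions, and then
"closes" the cofactor books: every NAD+/NADH, NADP+/NADPH and ferredoxin
imbalance left by a route is recycled through an ordered set of
electron-recycling systems (transhydrogenase, Rnf, an electron-bifurcating
[FeFe] hydrogenase and an energy-converting [NiFe] hydrogenase).  What remains
is the route's net molecular-hydrogen demand, the quantity that makes a
polyphenol pathway a competitor of hydrogenotrophic methanogenesis (which
needs 4 H2 per CH4).

Cofactors are represented with pseudo-element moieties (``Nad``, ``Ndp``,
``Fdx``) so each couple is exactly balanced: NADH carries one more H atom and
one more electron than NAD+, and reduced ferredoxin carries two electrons
(charge -2).  All arithmetic is exact (:class:`fractions.Fraction`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from fractions import Fraction
from importlib import resources
from typing import Iterable, Mapping

import yaml

__all__ = [
    "ChemSpecies",
    "Reaction",
    "Route",
    "RecyclingSystem",
    "BalanceReport",
    "H2Balance",
    "ReactionLibrary",
    "LedgerError",
    "parse_formula",
    "check_balance",
    "net_reaction",
    "apply_recycling",
    "h2_per_substrate",
]

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]*)(\d*)")


class LedgerError(ValueError):
    """Raised for unbalanced reactions, unknown species or unclosable books."""


def parse_formula(formula: str) -> dict[str, int]:
    """Parse ``C15H14O6``-style formulas (pseudo-elements allowed) to counts."""
    pos = 0
    counts: dict[str, int] = {}
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise LedgerError(f"unparseable formula {formula!r} at {formula[pos:]!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise LedgerError(f"unparseable formula {formula!r} at {formula[pos:]!r}")
    return counts


@dataclass(frozen=True)
class ChemSpecies:
    name: str
    formula: Mapping[str, int]
    charge: int = 0
    role: str = "metabolite"  # metabolite | cofactor | gas | water | proton


@dataclass
class Reaction:
    """Signed stoichiometry over species names; negative = consumed."""

    reaction_id: str
    stoichiometry: dict[str, Fraction]
    enzyme: str | None = None
    reversible: bool = False

    def coefficient(self, species: str) -> Fraction:
        return self.stoichiometry.get(species, Fraction(0))

    def scaled(self, factor: Fraction) -> "Reaction":
        return Reaction(
            self.reaction_id,
            {s: c * factor for s, c in self.stoichiometry.items()},
            self.enzyme,
            self.reversible,
        )


@dataclass
class Route:
    route_id: str
    substrate: str
    products: list[str]
    reaction_ids: list[str]


@dataclass
class RecyclingSystem:
    """A recycling reaction plus the couple species it is meant to zero."""

    name: str
    reaction: Reaction
    targets: list[str]


@dataclass
class BalanceReport:
    element_residuals: dict[str, Fraction]
    charge_residual: Fraction

    @property
    def balanced(self) -> bool:
        return self.charge_residual == 0 and all(
            v == 0 for v in self.element_residuals.values()
        )


@dataclass
class H2Balance:
    """Net cofactor closure result for one route."""

    route_id: str
    recycling_used: dict[str, Fraction] = field(default_factory=dict)
    h2_in: Fraction = Fraction(0)     # gross H2 entering (explicit + bifurcating uptake)
    h2_out: Fraction = Fraction(0)    # gross H2 leaving (explicit + Fd-driven evolution)
    closed_reaction: Reaction | None = None

    @property
    def h2_consumed(self) -> Fraction:
        """Net H2 consumed per route execution (floored at zero)."""
        return max(Fraction(0), self.h2_in - self.h2_out)

    @property
    def h2_produced(self) -> Fraction:
        return max(Fraction(0), self.h2_out - self.h2_in)


def check_balance(reaction: Reaction, species: Mapping[str, ChemSpecies]) -> BalanceReport:
    """Per-element and charge residuals of a reaction (all zero iff balanced)."""
    elements: dict[str, Fraction] = {}
    charge = Fraction(0)
    for name, coef in reaction.stoichiometry.items():
        sp = species.get(name)
        if sp is None:
            raise LedgerError(f"unknown species {name!r} in reaction {reaction.reaction_id!r}")
        for el, n in sp.formula.items():
            elements[el] = elements.get(el, Fraction(0)) + coef * n
        charge += coef * sp.charge
    return BalanceReport(element_residuals=elements, charge_residual=charge)


def _sum_reactions(reactions: Iterable[Reaction], rid: str) -> Reaction:
    total: dict[str, Fraction] = {}
    for r in reactions:
        for s, c in r.stoichiometry.items():
            total[s] = total.get(s, Fraction(0)) + c
    return Reaction(rid, {s: c for s, c in total.items() if c != 0})


class ReactionLibrary:
    """Species, reactions, routes and recycling systems, loaded from config.

    The shipped default encodes the three catechin degradation routes
    (naringenin, eriodictyol, dihydrokaempferol), phloroglucinol fermentation
    to acetate + butyrate, and the hydrogenotrophic methanogenesis reference.
    """

    def __init__(self, config: Mapping) -> None:
        self.species: dict[str, ChemSpecies] = {}
        for name, entry in config["species"].items():
            self.species[name] = ChemSpecies(
                name=name,
                formula=parse_formula(str(entry["formula"])),
                charge=int(entry.get("charge", 0)),
                role=str(entry.get("role", "metabolite")),
            )
        self.couples: list[tuple[str, str]] = [
            (c["oxidized"], c["reduced"]) for c in config.get("couples", [])
        ]
        self.reactions: dict[str, Reaction] = {}
        for rid, entry in config["reactions"].items():
            self.reactions[rid] = Reaction(
                rid,
                {s: _as_fraction(c) for s, c in entry["stoichiometry"].items()},
                enzyme=entry.get("enzyme"),
                reversible=bool(entry.get("reversible", False)),
            )
        self.recycling: list[RecyclingSystem] = [
            RecyclingSystem(
                name=entry["name"],
                reaction=Reaction(
                    entry["name"],
                    {s: _as_fraction(c) for s, c in entry["stoichiometry"].items()},
                    enzyme=entry.get("enzyme"),
                ),
                targets=list(entry["targets"]),
            )
            for entry in config.get("recycling", [])
        ]
        self.routes: dict[str, Route] = {
            rid: Route(rid, entry["substrate"], list(entry.get("products", [])),
                       list(entry["reactions"]))
            for rid, entry in config.get("routes", {}).items()
        }

    @classmethod
    def default(cls) -> "ReactionLibrary":
        with resources.files("mireomics.data").joinpath("reactions.yaml").open() as fh:
            return cls(yaml.safe_load(fh))

    @classmethod
    def from_yaml(cls, path) -> "ReactionLibrary":
        with open(path) as fh:
            return cls(yaml.safe_load(fh))

    def validate(self) -> None:
        """Check every shipped reaction and recycling system balances exactly."""
        for r in list(self.reactions.values()) + [s.reaction for s in self.recycling]:
            report = check_balance(r, self.species)
            if not report.balanced:
                raise LedgerError(
                    f"reaction {r.reaction_id!r} unbalanced: "
                    f"elements={_nonzero(report.element_residuals)}, "
                    f"charge={report.charge_residual}"
                )


def _as_fraction(value) -> Fraction:
    if isinstance(value, str):
        return Fraction(value)
    return Fraction(value).limit_denominator(10**9) if isinstance(value, float) else Fraction(value)


def _nonzero(d: Mapping[str, Fraction]) -> dict[str, Fraction]:
    return {k: v for k, v in d.items() if v != 0}


def net_reaction(route: Route | str, library: ReactionLibrary) -> Reaction:
    """Coefficient-wise sum of a route, with intermediates required to cancel.

    Metabolite species other than the route substrate and declared terminal
    products must net to zero; a non-cancelling intermediate is an error
    naming the species.
    """
    if isinstance(route, str):
        try:
            route = library.routes[route]
        except KeyError:
            raise LedgerError(f"unknown route {route!r}") from None
    try:
        steps = [library.reactions[rid] for rid in route.reaction_ids]
    except KeyError as e:
        raise LedgerError(f"route {route.route_id!r} references unknown reaction {e}") from None
    net = _sum_reactions(steps, f"net[{route.route_id}]")
    terminal = {route.substrate, *route.products}
    for name, coef in net.stoichiometry.items():
        sp = library.species[name]
        if sp.role == "metabolite" and name not in terminal and coef != 0:
            raise LedgerError(
                f"route {route.route_id!r}: intermediate {name!r} does not cancel "
                f"(net coefficient {coef})"
            )
    report = check_balance(net, library.species)
    if not report.balanced:
        raise LedgerError(f"net reaction of route {route.route_id!r} is unbalanced")
    return net


def apply_recycling(
    net: Reaction,
    library: ReactionLibrary,
    systems: list[RecyclingSystem] | None = None,
    route_id: str = "",
) -> H2Balance:
    """Close the cofactor books of a net reaction with recycling systems.

    Systems are applied in order; each is used the maximal integral number of
    times that drives its declared target couple toward zero.  After the pass,
    every cofactor couple must net to zero, otherwise a :class:`LedgerError`
    reports the residuals.  The net H2 coefficient of the closed reaction is
    the route's hydrogen balance.
    """
    if systems is None:
        systems = library.recycling
    current = dict(net.stoichiometry)
    used: dict[str, Fraction] = {}
    for system in systems:
        times: Fraction | None = None
        for target in system.targets:
            demand = system.reaction.coefficient(target)
            if demand >= 0:
                raise LedgerError(
                    f"recycling system {system.name!r} does not consume its target {target!r}"
                )
            avail = current.get(target, Fraction(0)) / -demand
            times = avail if times is None else min(times, avail)
        times = max(Fraction(0), times if times is not None else Fraction(0))
        if times.denominator != 1:
            times = Fraction(times.numerator // times.denominator)
        if times == 0:
            continue
        used[system.name] = times
        for s, c in system.reaction.stoichiometry.items():
            current[s] = current.get(s, Fraction(0)) + c * times
    residuals = {}
    for ox, red in library.couples:
        for member in (ox, red):
            if current.get(member, Fraction(0)) != 0:
                residuals[member] = current[member]
    if residuals:
        raise LedgerError(
            f"cofactor couples not closable for {route_id or net.reaction_id!r}: "
            f"residuals {residuals}"
        )
    closed = Reaction(f"closed[{route_id or net.reaction_id}]",
                      {s: c for s, c in current.items() if c != 0})
    explicit_in = max(Fraction(0), -net.coefficient("h2"))
    explicit_out = max(Fraction(0), net.coefficient("h2"))
    h2_in = explicit_in
    h2_out = explicit_out
    for system in systems:
        t = used.get(system.name, Fraction(0))
        coef = system.reaction.coefficient("h2")
        if coef < 0:
            h2_in += -coef * t
        elif coef > 0:
            h2_out += coef * t
    return H2Balance(route_id=route_id or net.reaction_id, recycling_used=used,
                     h2_in=h2_in, h2_out=h2_out, closed_reaction=closed)


def h2_per_substrate(route_id: str, library: ReactionLibrary | None = None) -> Fraction:
    """Maximal net H2 consumed per mole of route substrate.

    The three catechin routes (each composed with phloroglucinol fermentation)
    yield 3, 2 and 1 H2 per catechin for the naringenin, eriodictyol and
    dihydrokaempferol routes respectively; the methanogenesis reference
    consumes 4.
    """
    library = library or ReactionLibrary.default()
    route = library.routes.get(route_id)
    if route is None:
        raise LedgerError(f"unknown route {route_id!r}")
    net = net_reaction(route, library)
    balance = apply_recycling(net, library, route_id=route_id)
    substrate_coef = -net.coefficient(route.substrate)
    if substrate_coef <= 0:
        raise LedgerError(f"route {route_id!r} does not consume its substrate")
    return (balance.h2_consumed - balance.h2_produced) / substrate_coef


def route_report(library: ReactionLibrary | None = None) -> "list[dict]":
    """Summary rows (route, substrate, recycling uses, net H2) for all routes."""
    library = library or ReactionLibrary.default()
    rows = []
    for rid, route in library.routes.items():
        net = net_reaction(route, library)
        bal = apply_recycling(net, library, route_id=rid)
        rows.append(
            {
                "route_id": rid,
                "substrate": route.substrate,
                "h2_consumed": bal.h2_consumed,
                "h2_produced": bal.h2_produced,
                "recycling": {k: str(v) for k, v in bal.recycling_used.items()},
            }
        )
    return rows
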