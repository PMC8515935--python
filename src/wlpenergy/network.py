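"""Reaction-network data model and exact carrier-balance flux solver.

A pathway model is a small reaction network in which every reaction may,
besides converting chemical species, produce or consume the reduced form of
one or more redox carrier couples (ferredoxin, NAD(H), NADP(H), ...), make
or spend ATP by substrate-level phosphorylation, and translocate ions across
the cytoplasmic membrane.  Fixing the net formation of a designated product
to one mole and requiring every internal species and every carrier couple to
balance exactly yields a linear system whose unique solution is the flux
distribution drawn in the energy-metabolism schemes of acetogens.

All stoichiometric arithmetic is exact rational (`fractions.Fraction`);
floating point enters only at display and thermodynamics stages.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from numbers import Rational
from typing import Mapping

import sympy

__all__ = [
    "RedoxCouple",
    "Reaction",
    "PathwayModel",
    "FluxSolution",
    "ModelValidationError",
    "UnderdeterminedError",
    "InfeasibleError",
    "build_balance_system",
    "solve_flux",
    "validate_model",
    "parse_rational",
    "model_from_dict",
    "model_to_dict",
    "load_model_json",
    "dump_model_json",
]


class ModelValidationError(ValueError):
    """A pathway model violates a structural invariant."""


class UnderdeterminedError(ValueError):
    """The balance system has free directions (non-unique fluxes)."""

    def __init__(self, message: str, nullity: int, free_reactions: list[str]):
        super().__init__(message)
        self.nullity = nullity
        self.free_reactions = free_reactions


class InfeasibleError(ValueError):
    """The balance system has no admissible solution."""


def parse_rational(value) -> Fraction:
    """Parse an exact rational from an int, Fraction, decimal string or ``"p/q"``.

    Floats are accepted via their shortest decimal repr (so a JSON ``0.5``
    becomes exactly 1/2, and ``3.66`` exactly 183/50).
    """
    if isinstance(value, bool):
        raise TypeError("boolean is not a stoichiometric coefficient")
    if isinstance(value, Rational):
        return Fraction(value)
    if isinstance(value, float):
        return Fraction(repr(value))
    if isinstance(value, str):
        return Fraction(value)
    raise TypeError(f"cannot interpret {value!r} as a rational number")


@dataclass(frozen=True)
class RedoxCouple:
    """An electron-carrier couple (oxidised/reduced pair).

    Parameters
    ----------
    id
        Short name, e.g. ``"Fd"``, ``"NADH"``.  Unique within a model.
    n_electrons
        Electrons transferred per couple turnover; 1 or 2.
    e0_prime_mV
        Standard redox potential at pH 7 in millivolts.  May be a single
        nominal value, a two-value tuple for couples whose two one-electron
        steps differ strongly (flavodoxin), or None when unknown.
    """

    id: str
    n_electrons: int = 2
    e0_prime_mV: float | tuple[float, float] | None = None

    def __post_init__(self):
        if self.n_electrons not in (1, 2):
            raise ModelValidationError(
                f"couple {self.id!r}: n_electrons must be 1 or 2, got {self.n_electrons}"
            )
        if isinstance(self.e0_prime_mV, (list, tuple)):
            object.__setattr__(self, "e0_prime_mV", tuple(float(v) for v in self.e0_prime_mV))

    @property
    def nominal_potential_mV(self) -> float | None:
        """Single nominal potential; midpoint of a two-step couple."""
        e0 = self.e0_prime_mV
        if e0 is None:
            return None
        if isinstance(e0, tuple):
            return sum(e0) / len(e0)
        return float(e0)


@dataclass
class Reaction:
    """One (possibly lumped) reaction of a pathway model.

    ``chem`` maps species name to signed mol per unit flux (negative =
    consumed).  ``carriers`` maps couple id to signed mol of the *reduced*
    form produced (negative means the reduced carrier is consumed, i.e. the
    reaction is driven by that carrier).  ``slp_atp`` is signed mol ATP by
    substrate-level phosphorylation per unit flux.  ``ions_translocated`` is
    the signed count of ions moved vectorially across the membrane per unit
    flux (positive = pumped outward, building the gradient).  Scalar protons
    of bulk chemistry are not tracked.
    """

    id: str
    chem: dict[str, Fraction] = field(default_factory=dict)
    carriers: dict[str, Fraction] = field(default_factory=dict)
    slp_atp: Fraction = Fraction(0)
    ions_translocated: Fraction = Fraction(0)
    reversible: bool = False

    def __post_init__(self):
        self.chem = {s: parse_rational(v) for s, v in self.chem.items()}
        self.carriers = {c: parse_rational(v) for c, v in self.carriers.items()}
        self.slp_atp = parse_rational(self.slp_atp)
        self.ions_translocated = parse_rational(self.ions_translocated)

    def copy(self) -> "Reaction":
        return Reaction(
            id=self.id,
            chem=dict(self.chem),
            carriers=dict(self.carriers),
            slp_atp=self.slp_atp,
            ions_translocated=self.ions_translocated,
            reversible=self.reversible,
        )


@dataclass
class PathwayModel:
    """A reaction network with redox couples and a designated product."""

    reactions: list[Reaction]
    couples: list[RedoxCouple]
    external_species: set[str]
    product: str

    def __post_init__(self):
        self.reactions = list(self.reactions)
        self.couples = list(self.couples)
        self.external_species = set(self.external_species)
        self._check_structure()

    def _check_structure(self):
        seen = set()
        for rxn in self.reactions:
            if rxn.id in seen:
                raise ModelValidationError(f"duplicate reaction id {rxn.id!r}")
            seen.add(rxn.id)
        couple_ids = [c.id for c in self.couples]
        if len(set(couple_ids)) != len(couple_ids):
            raise ModelValidationError("duplicate couple ids")
        known = set(couple_ids)
        for rxn in self.reactions:
            for cid in rxn.carriers:
                if cid not in known:
                    raise ModelValidationError(
                        f"reaction {rxn.id!r} references undeclared couple {cid!r}"
                    )
        if self.product in self.external_species:
            raise ModelValidationError(
                f"product {self.product!r} must not be listed as external"
            )
        if not any(rxn.chem.get(self.product, 0) > 0 for rxn in self.reactions):
            raise ModelValidationError(f"no reaction produces product {self.product!r}")

    @property
    def couple_ids(self) -> list[str]:
        return [c.id for c in self.couples]

    def couple(self, cid: str) -> RedoxCouple:
        for c in self.couples:
            if c.id == cid:
                return c
        raise KeyError(cid)

    def species(self) -> set[str]:
        out: set[str] = set()
        for rxn in self.reactions:
            out.update(rxn.chem)
        return out

    def balanced_species(self) -> list[str]:
        """Internal species (balanced to zero), excluding externals and product."""
        return sorted(
            s
            for s in self.species()
            if s not in self.external_species and s != self.product
        )

    def copy(self) -> "PathwayModel":
        return PathwayModel(
            reactions=[r.copy() for r in self.reactions],
            couples=list(self.couples),
            external_species=set(self.external_species),
            product=self.product,
        )


@dataclass
class FluxSolution:
    """Exact fluxes per mol product with balance residuals and ATP sums."""

    fluxes: dict[str, Fraction]
    residuals: dict[str, Fraction]
    net_ions: Fraction
    slp_sum: Fraction

    def __getitem__(self, reaction_id: str) -> Fraction:
        return self.fluxes[reaction_id]


# --- balance system -------------------------------------------------------

def build_balance_system(model: PathwayModel):
    """Assemble the exact linear system ``A f = b`` of the pathway model.

    Rows: one per balanced (internal) species, one per redox couple (net
    production of the reduced form = 0, which enforces electron
    conservation), and one final row fixing net product formation to 1.
    Columns follow ``model.reactions`` order.

    Returns ``(A, b, row_labels)`` with ``A`` and ``b`` sympy matrices over
    the rationals.
    """
    rows: list[list[sympy.Rational]] = []
    labels: list[str] = []

    def coeff_row(getter) -> list[sympy.Rational]:
        return [sympy.Rational(getter(rxn)) for rxn in model.reactions]

    for sp in model.balanced_species():
        rows.append(coeff_row(lambda r, sp=sp: r.chem.get(sp, Fraction(0))))
        labels.append(f"species:{sp}")
    for cid in model.couple_ids:
        rows.append(coeff_row(lambda r, cid=cid: r.carriers.get(cid, Fraction(0))))
        labels.append(f"couple:{cid}")
    rows.append(coeff_row(lambda r: r.chem.get(model.product, Fraction(0))))
    labels.append(f"product:{model.product}")

    A = sympy.Matrix(rows)
    b = sympy.Matrix([0] * (len(rows) - 1) + [1])
    return A, b, labels


def solve_flux(model: PathwayModel, product_target: Fraction | int = 1) -> FluxSolution:
    """Solve the carrier-balance system for ``product_target`` mol product.

    The solution is exact rational.  Raises :class:`UnderdeterminedError`
    when the system has free directions (reporting the null-space dimension
    and the reactions involved), and :class:`InfeasibleError` when no
    solution exists or an irreversible reaction would need negative flux.
    No objective function is applied: a non-unique system is a hard error,
    never silently regularised.
    """
    A, b, labels = build_balance_system(model)
    target = parse_rational(product_target)
    b = b * sympy.Rational(target)

    nullspace = A.nullspace()
    if nullspace:
        free = sorted(
            {
                model.reactions[i].id
                for vec in nullspace
                for i in range(len(model.reactions))
                if vec[i] != 0
            }
        )
        raise UnderdeterminedError(
            f"balance system is underdetermined: null-space dimension "
            f"{len(nullspace)}; free reactions: {', '.join(free)}",
            nullity=len(nullspace),
            free_reactions=free,
        )

    aug = A.row_join(b)
    if aug.rank() > A.rank():
        raise InfeasibleError("balance system is inconsistent: no flux solution exists")

    sol_set = sympy.linsolve((A, b))
    sol = next(iter(sol_set))
    fluxes = {}
    for rxn, v in zip(model.reactions, sol):
        fr = sympy.Rational(v)
        fluxes[rxn.id] = Fraction(int(fr.p), int(fr.q))

    for rxn in model.reactions:
        if not rxn.reversible and fluxes[rxn.id] < 0:
            raise InfeasibleError(
                f"irreversible reaction {rxn.id!r} requires negative flux "
                f"{fluxes[rxn.id]}"
            )

    residuals: dict[str, Fraction] = {}
    for label in labels[:-1]:
        kind, name = label.split(":", 1)
        total = Fraction(0)
        for rxn in model.reactions:
            coeff = rxn.chem.get(name, Fraction(0)) if kind == "species" else rxn.carriers.get(name, Fraction(0))
            total += fluxes[rxn.id] * coeff
        residuals[label] = total

    net_ions = sum((fluxes[r.id] * r.ions_translocated for r in model.reactions), Fraction(0))
    slp_sum = sum((fluxes[r.id] * r.slp_atp for r in model.reactions), Fraction(0))
    return FluxSolution(fluxes=fluxes, residuals=residuals, net_ions=net_ions, slp_sum=slp_sum)


def validate_model(model: PathwayModel) -> list[tuple[str, str]]:
    """Structural diagnostics as ``(level, message)`` pairs.

    Levels are ``"error"`` (duplicate ids, dangling couple references,
    reactions touching only external species) and ``"warning"`` (couples
    declared but never used).  Construction already rejects hard structural
    errors; this op re-checks them diagnostically for models built by hand
    or loaded from edited files.
    """
    diags: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rxn in model.reactions:
        if rxn.id in seen:
            diags.append(("error", f"duplicate reaction id {rxn.id!r}"))
        seen.add(rxn.id)

    known = set(model.couple_ids)
    used: set[str] = set()
    for rxn in model.reactions:
        for cid in rxn.carriers:
            used.add(cid)
            if cid not in known:
                diags.append(
                    ("error", f"reaction {rxn.id!r} references undeclared couple {cid!r}")
                )
        # a reaction with neither an internal species nor a carrier has an
        # all-zero balance column and cannot be pinned by any solution
        if rxn.chem and not rxn.carriers and all(
            s in model.external_species for s in rxn.chem
        ):
            diags.append(
                ("error", f"reaction {rxn.id!r} touches only external species; it is unconstrained")
            )
    for cid in sorted(known - used):
        diags.append(("warning", f"couple {cid!r} is declared but never used"))
    return diags


# --- JSON (de)serialisation ------------------------------------------------

def _frac_str(x: Fraction) -> str | int:
    return int(x) if x.denominator == 1 else f"{x.numerator}/{x.denominator}"


def model_from_dict(data: Mapping) -> PathwayModel:
    """Build a PathwayModel from the JSON scenario-file layout.

    Top-level keys: ``couples``, ``reactions``, ``external_species``,
    ``product``.  Rational coefficients may be written as numbers or as
    ``"p/q"`` strings.
    """
    try:
        couples = [
            RedoxCouple(
                id=c["id"],
                n_electrons=c.get("n_electrons", 2),
                e0_prime_mV=c.get("e0_prime_mV"),
            )
            for c in data["couples"]
        ]
        reactions = [
            Reaction(
                id=r["id"],
                chem=r.get("chem", {}),
                carriers=r.get("carriers", {}),
                slp_atp=r.get("slp_atp", 0),
                ions_translocated=r.get("ions_translocated", 0),
                reversible=r.get("reversible", False),
            )
            for r in data["reactions"]
        ]
        return PathwayModel(
            reactions=reactions,
            couples=couples,
            external_species=set(data.get("external_species", [])),
            product=data["product"],
        )
    except KeyError as exc:
        raise ModelValidationError(f"model file missing required key: {exc}") from exc


def model_to_dict(model: PathwayModel) -> dict:
    return {
        "couples": [
            {
                "id": c.id,
                "n_electrons": c.n_electrons,
                **(
                    {"e0_prime_mV": list(c.e0_prime_mV) if isinstance(c.e0_prime_mV, tuple) else c.e0_prime_mV}
                    if c.e0_prime_mV is not None
                    else {}
                ),
            }
            for c in model.couples
        ],
        "reactions": [
            {
                "id": r.id,
                "chem": {s: _frac_str(v) for s, v in r.chem.items()},
                "carriers": {c: _frac_str(v) for c, v in r.carriers.items()},
                "slp_atp": _frac_str(r.slp_atp),
                "ions_translocated": _frac_str(r.ions_translocated),
                "reversible": r.reversible,
            }
            for r in model.reactions
        ],
        "external_species": sorted(model.external_species),
        "product": model.product,
    }


def load_model_json(path) -> PathwayModel:
    with open(path, encoding="utf-8") as fh:
        return model_from_dict(json.load(fh))


def dump_model_json(model: PathwayModel, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(model_to_dict(model), fh, indent=1)
        fh.write("\n")
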