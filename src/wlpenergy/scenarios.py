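"""Built-in pathway scenarios for C. ljungdahlii gas fermentation.

Each scenario is one reconstruction of the Wood-Ljungdahl energy metabolism
of *Clostridium ljungdahlii* on CO or on H2 + CO2, lumped to the
carrier-coupled and ATP-coupled steps that determine the ATP yield:

* methyl branch: CO2 -> formate (FDH or the H2-dependent CO2 reductase),
  formate -> formyl-THF (formyl-THF synthetase, costs 1 ATP; the
  cyclohydrolase is folded in), methylene-THF formation (NADPH-dependent
  methylene-THF dehydrogenase), methylene-THF -> methyl-THF (MTHFR, by
  default driven by reduced ferredoxin), and the carrier-free
  methyltransferase/ACS condensation with CO;
* carbonyl branch: CO dehydrogenase, Fd-reducing on CO and run in reverse
  (Fd-consuming, CO-producing) on H2 + CO2;
* energy converters: the ion-translocating Rnf complex (2 H+ per
  Fd_red/NADH couple, reversible), the electron-bifurcating Nfn
  transhydrogenase (NADH + Fd_red <-> 2 NADPH, reversible), and on H2 the
  electron-bifurcating Hyt hydrogenase (2 H2 -> Fd_red + NADPH);
* product branches: Pta/Ack (+1 ATP) to acetate; AOR + NADH-dependent ADH
  to ethanol (acetate re-reduced after the Ack ATP is banked); reverse
  PFOR, acetolactate synthase/decarboxylase and the NADPH-dependent
  2,3-butanediol dehydrogenase to 2,3-butanediol.

Carrier assignments not fixed by direct enzymology on C. ljungdahlii follow
measurements in cell extracts of the close relative C. autoethanogenum; the
set shipped here is the one consistent with all published net-ATP yields.
Scenarios are constructed in code (single source of truth) and round-trip
through the JSON layout of :mod:`wlpenergy.network` so users can export,
edit and re-run any variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

from .network import (
    PathwayModel,
    Reaction,
    RedoxCouple,
    model_from_dict,
    model_to_dict,
    parse_rational,
)
from .energetics import DEFAULT_H_PER_ATP

__all__ = [
    "Scenario",
    "STANDARD_COUPLES",
    "MTHFR_DONORS",
    "list_scenarios",
    "get_scenario",
    "apply_mthfr_donor",
    "gsrp_carrier_cost",
    "scenario_to_dict",
    "scenario_from_dict",
]

#: Reference electron-carrier couples with standard potentials at pH 7 (mV).
#: Clostridial ferredoxin is close to -400 mV at standard state and may
#: approach -500 mV physiologically; flavodoxin is a two-step couple.
STANDARD_COUPLES: dict[str, RedoxCouple] = {
    "Fd": RedoxCouple("Fd", 2, -400.0),
    "Fd_physiological": RedoxCouple("Fd_physiological", 2, -500.0),
    "NADH": RedoxCouple("NADH", 2, -320.0),
    "NADPH": RedoxCouple("NADPH", 2, -320.0),
    "methylene-THF/methyl-THF": RedoxCouple("methylene-THF/methyl-THF", 2, -200.0),
    "Fld": RedoxCouple("Fld", 2, (-430.0, -60.0)),
}

MTHFR_DONORS = ("Fd", "NADH", "bifurcating", "Rnf_coupled")


@dataclass
class Scenario:
    """A pathway model plus the bioenergetic options used to interpret it."""

    name: str
    model: PathwayModel
    h_per_atp: Fraction = DEFAULT_H_PER_ATP
    options: dict = field(default_factory=dict)
    description: str = ""

    def __post_init__(self):
        self.h_per_atp = parse_rational(self.h_per_atp)
        has_aor = any(r.id == "AOR" for r in self.model.reactions)
        route = self.options.get("ethanol_route", "none")
        if (route == "AOR") != has_aor:
            raise ValueError(
                f"scenario {self.name!r}: ethanol_route={route!r} inconsistent "
                f"with AOR reaction {'present' if has_aor else 'absent'}"
            )

    def copy(self) -> "Scenario":
        return Scenario(
            name=self.name,
            model=self.model.copy(),
            h_per_atp=self.h_per_atp,
            options=dict(self.options),
            description=self.description,
        )


# --- reaction builders ----------------------------------------------------

def _couples() -> list[RedoxCouple]:
    return [STANDARD_COUPLES["Fd"], STANDARD_COUPLES["NADH"], STANDARD_COUPLES["NADPH"]]


def _methyl_branch_on_co() -> list[Reaction]:
    """CO2 -> methyl-THF chain as run on CO (FDH takes 1/2 Fd_red + 1/2 NADPH)."""
    return [
        Reaction("CODH", chem={"CO": -1, "CO2": 1}, carriers={"Fd": 1}),
        Reaction("FDH", chem={"CO2": -1, "formate": 1},
                 carriers={"Fd": Fraction(-1, 2), "NADPH": Fraction(-1, 2)}),
        Reaction("FTS", chem={"formate": -1, "formyl-THF": 1}, slp_atp=-1),
        Reaction("MTHFD", chem={"formyl-THF": -1, "methylene-THF": 1}, carriers={"NADPH": -1}),
        Reaction("MTHFR", chem={"methylene-THF": -1, "methyl-THF": 1}, carriers={"Fd": -1}),
        Reaction("ACS", chem={"methyl-THF": -1, "CO": -1, "acetyl-CoA": 1}),
    ]


def _methyl_branch_on_h2() -> list[Reaction]:
    """Methyl + carbonyl branches on H2 + CO2: carrier-free H2-dependent CO2
    reductase makes formate; CODH runs in reverse, consuming Fd_red."""
    return [
        Reaction("Hyt", chem={"H2": -2}, carriers={"Fd": 1, "NADPH": 1}),
        Reaction("HDCR", chem={"CO2": -1, "H2": -1, "formate": 1}),
        Reaction("FTS", chem={"formate": -1, "formyl-THF": 1}, slp_atp=-1),
        Reaction("MTHFD", chem={"formyl-THF": -1, "methylene-THF": 1}, carriers={"NADPH": -1}),
        Reaction("MTHFR", chem={"methylene-THF": -1, "methyl-THF": 1}, carriers={"Fd": -1}),
        Reaction("CODH_rev", chem={"CO2": -1, "CO": 1}, carriers={"Fd": -1}),
        Reaction("ACS", chem={"methyl-THF": -1, "CO": -1, "acetyl-CoA": 1}),
    ]


def _energy_converters() -> list[Reaction]:
    return [
        Reaction("Rnf", carriers={"Fd": -1, "NADH": 1}, ions_translocated=2, reversible=True),
        Reaction("Nfn", carriers={"Fd": -1, "NADH": -1, "NADPH": 2}, reversible=True),
    ]


def _pta_ack() -> Reaction:
    return Reaction("PtaAck", chem={"acetyl-CoA": -1, "acetate": 1}, slp_atp=1)


def _aor_adh() -> list[Reaction]:
    return [
        Reaction("AOR", chem={"acetate": -1, "acetaldehyde": 1}, carriers={"Fd": -1}),
        Reaction("ADH", chem={"acetaldehyde": -1, "ethanol": 1}, carriers={"NADH": -1}),
    ]


def _bdo_branch() -> list[Reaction]:
    return [
        Reaction("PFOR_rev", chem={"acetyl-CoA": -1, "CO2": -1, "pyruvate": 1}, carriers={"Fd": -1}),
        Reaction("ALS_ALDC", chem={"pyruvate": -2, "acetoin": 1, "CO2": 2}),
        Reaction("BDO_DH", chem={"acetoin": -1, "2,3-butanediol": 1}, carriers={"NADPH": -1}),
    ]


def _build_fig5a() -> Scenario:
    model = PathwayModel(
        reactions=_methyl_branch_on_co() + [_pta_ack()] + _energy_converters(),
        couples=_couples(),
        external_species={"CO", "CO2"},
        product="acetate",
    )
    return Scenario(
        name="fig5a_co_acetate",
        model=model,
        options={"substrate": "CO", "product": "acetate",
                 "mthfr_donor": "Fd", "ethanol_route": "none"},
        description="CO fermented to acetate only (Fd-dependent MTHFR); net +0.41 ATP/mol",
    )


def _build_fig5b() -> Scenario:
    model = PathwayModel(
        reactions=_methyl_branch_on_co() + [_pta_ack()] + _aor_adh() + _energy_converters(),
        couples=_couples(),
        external_species={"CO", "CO2"},
        product="ethanol",
    )
    return Scenario(
        name="fig5b_co_ethanol",
        model=model,
        options={"substrate": "CO", "product": "ethanol",
                 "mthfr_donor": "Fd", "ethanol_route": "AOR"},
        description="CO fermented to ethanol via AOR; net +0.95 ATP/mol",
    )


def _build_fig5c() -> Scenario:
    model = PathwayModel(
        reactions=_methyl_branch_on_co() + _bdo_branch() + _energy_converters(),
        couples=_couples(),
        external_species={"CO", "CO2"},
        product="2,3-butanediol",
    )
    return Scenario(
        name="fig5c_co_bdo",
        model=model,
        options={"substrate": "CO", "product": "2,3-butanediol",
                 "mthfr_donor": "Fd", "ethanol_route": "none"},
        description="CO fermented to 2,3-butanediol; net ATP always negative",
    )


def _build_figs7_acetate() -> Scenario:
    model = PathwayModel(
        reactions=_methyl_branch_on_h2() + [_pta_ack()] + _energy_converters(),
        couples=_couples(),
        external_species={"H2", "CO2"},
        product="acetate",
    )
    return Scenario(
        name="figs7_h2_acetate",
        model=model,
        options={"substrate": "H2+CO2", "product": "acetate",
                 "mthfr_donor": "Fd", "ethanol_route": "none"},
        description="H2+CO2 to acetate; reverse Rnf consumes the gradient, net -0.14 ATP/mol",
    )


def _build_figs7_ethanol() -> Scenario:
    model = PathwayModel(
        reactions=_methyl_branch_on_h2() + [_pta_ack()] + _aor_adh() + _energy_converters(),
        couples=_couples(),
        external_species={"H2", "CO2"},
        product="ethanol",
    )
    return Scenario(
        name="figs7_h2_ethanol",
        model=model,
        options={"substrate": "H2+CO2", "product": "ethanol",
                 "mthfr_donor": "Fd", "ethanol_route": "AOR"},
        description="H2+CO2 to ethanol via AOR; net +0.14 ATP/mol",
    )


_BUILDERS = {
    "fig5a_co_acetate": _build_fig5a,
    "fig5b_co_ethanol": _build_fig5b,
    "fig5c_co_bdo": _build_fig5c,
    "figs7_h2_acetate": _build_figs7_acetate,
    "figs7_h2_ethanol": _build_figs7_ethanol,
}


def _donor_variant(base: str, donor: str):
    def build():
        sc = apply_mthfr_donor(_BUILDERS[base](), donor)
        sc.name = f"{base}_mthfr_{donor.lower()}"
        sc.description = f"{_BUILDERS[base]().description}; MTHFR donor set to {donor}"
        return sc
    return build


for _donor in ("NADH", "bifurcating", "Rnf_coupled"):
    _BUILDERS[f"fig5a_co_acetate_mthfr_{_donor.lower()}"] = _donor_variant(
        "fig5a_co_acetate", _donor
    )


def list_scenarios() -> dict[str, str]:
    """Registry names mapped to one-line descriptions."""
    return {name: build().description for name, build in _BUILDERS.items()}


def get_scenario(name: str) -> Scenario:
    """Return a deep, independent copy of a registered scenario."""
    try:
        build = _BUILDERS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; registry: {', '.join(sorted(_BUILDERS))}"
        ) from None
    return build()


def apply_mthfr_donor(scenario: Scenario, donor: str) -> Scenario:
    """Return a copy of the scenario with the MTHFR electron donor replaced.

    ``"Fd"``: one reduced ferredoxin consumed (the characterised enzyme).
    ``"NADH"``: one NADH consumed (non-bifurcating hypothesis).
    ``"bifurcating"``: two NADH consumed, one Fd_red produced
    (electron-bifurcating hypothesis).
    ``"Rnf_coupled"``: one Fd_red consumed while the reaction itself pumps
    two ions (methylene-THF reduction coupled to Rnf-type translocation).
    """
    carriers = {
        "Fd": {"Fd": Fraction(-1)},
        "NADH": {"NADH": Fraction(-1)},
        "bifurcating": {"NADH": Fraction(-2), "Fd": Fraction(1)},
        "Rnf_coupled": {"Fd": Fraction(-1)},
    }
    if donor not in carriers:
        raise ValueError(f"unknown MTHFR donor {donor!r}; choose from {MTHFR_DONORS}")
    out = scenario.copy()
    for rxn in out.model.reactions:
        if rxn.id == "MTHFR":
            rxn.carriers = dict(carriers[donor])
            rxn.ions_translocated = Fraction(2 if donor == "Rnf_coupled" else 0)
            out.options["mthfr_donor"] = donor
            return out
    raise ValueError(f"scenario {scenario.name!r} has no MTHFR reaction")


def gsrp_carrier_cost(route: str) -> dict[str, Fraction]:
    """Electron-carrier cost of the methylene-THF -> acetyl-phosphate segment.

    Through the Wood-Ljungdahl route the segment consumes two reduced
    ferredoxins (MTHFR and the reverse CODH step); through the glycine
    synthase-reductase pathway it consumes one NADH and one NADPH.  Both
    routes move two electron pairs; the difference is purely which carriers
    pay, hence how much chemiosmotic energy the cell forgoes.
    """
    routes = {
        "WLP": {"Fd_red": Fraction(2)},
        "GSRP": {"NADH": Fraction(1), "NADPH": Fraction(1)},
    }
    try:
        return dict(routes[route])
    except KeyError:
        raise ValueError(f"unknown route {route!r}; choose WLP or GSRP") from None


def scenario_to_dict(scenario: Scenario) -> dict:
    """Serialise to the JSON scenario layout (model keys + options block)."""
    data = model_to_dict(scenario.model)
    data["name"] = scenario.name
    data["h_per_atp"] = str(scenario.h_per_atp) if scenario.h_per_atp.denominator != 1 else int(scenario.h_per_atp)
    data["options"] = dict(scenario.options)
    data["description"] = scenario.description
    return data


def scenario_from_dict(data: dict) -> Scenario:
    return Scenario(
        name=data.get("name", "unnamed"),
        model=model_from_dict(data),
        h_per_atp=parse_rational(data.get("h_per_atp", DEFAULT_H_PER_ATP)),
        options=dict(data.get("options", {})),
        description=data.get("description", ""),
    )
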