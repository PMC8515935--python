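"""Synthetic test-data generators.

Emulates the tabular inputs the enzymology analysis consumes — noisy
substrate-saturation series and linear-phase progress curves — and random
balanced toy networks with planted (known) flux solutions for exercising
the stoichiometric solver.  Every generator is a pure function of its spec,
seed included: one explicitly seeded random source per call, no global
state, byte-identical output across runs.

Defaults mirror the characterised ferredoxin-dependent MTHFR: Km 1.46 uM
for reduced ferredoxin, Vmax 91.2 U/mg, with multiplicative Gaussian rate
noise (enzyme-assay error scales with signal).
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .enzymology import KineticDataset, ProgressCurve
from .network import FluxSolution, PathwayModel, Reaction, RedoxCouple

__all__ = [
    "DEFAULT_KM_UM",
    "DEFAULT_VMAX_U_PER_MG",
    "KineticsGenSpec",
    "NetworkGenSpec",
    "gen_saturation",
    "gen_progress_curve",
    "gen_network",
]

DEFAULT_KM_UM = 1.46
DEFAULT_VMAX_U_PER_MG = 91.2


def _default_design(km: float, n: int = 8) -> np.ndarray:
    """Geometric design spanning 0.25x to 16x Km."""
    return km * np.geomspace(0.25, 16.0, n)


@dataclass
class KineticsGenSpec:
    """Parameters of a synthetic substrate-saturation experiment."""

    km_uM: float = DEFAULT_KM_UM
    vmax_U_per_mg: float = DEFAULT_VMAX_U_PER_MG
    concentrations: np.ndarray | None = None
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.km_uM <= 0 or self.vmax_U_per_mg <= 0:
            raise ValueError("km and vmax must be positive")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        if self.concentrations is None:
            self.concentrations = _default_design(self.km_uM)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.concentrations.size == 0:
            raise ValueError("design must contain at least one concentration")


def gen_saturation(spec: KineticsGenSpec) -> KineticDataset:
    """Noisy Michaelis-Menten rates: v_i = Vmax*S_i/(Km+S_i) * (1 + eps_i),
    eps_i ~ Normal(0, noise_cv).  Deterministic under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    s = spec.concentrations
    v_true = spec.vmax_U_per_mg * s / (spec.km_uM + s)
    v = v_true * (1.0 + spec.noise_cv * rng.standard_normal(s.size))
    return KineticDataset(substrate_conc=s, rate=v)


def gen_progress_curve(
    v_true_uM_per_min: float,
    s0_uM: float,
    n_points: int = 10,
    noise_sd_uM: float = 0.0,
    enzyme_ug: float = 0.62,
    seed: int = 0,
    t_max_min: float | None = None,
    volume_mL: float = 1.0,
) -> ProgressCurve:
    """Progress curve with a linear phase and a substrate-exhaustion plateau.

    product(t) = min(v*t, s0) + Gaussian noise, clipped at >= 0, sampled at
    ``n_points`` uniform times on (0, t_max]; ``t_max`` defaults to 1.5x
    the exhaustion time s0/v.  The default enzyme load matches the
    characterised MTHFR assay scale (0.62 ug in 1 mL).
    """
    if v_true_uM_per_min <= 0 or s0_uM <= 0:
        raise ValueError("rate and initial substrate must be positive")
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    rng = np.random.default_rng(seed)
    if t_max_min is None:
        t_max_min = 1.5 * s0_uM / v_true_uM_per_min
    t = np.linspace(0.0, t_max_min, n_points + 1)[1:]
    p = np.minimum(v_true_uM_per_min * t, s0_uM)
    p = np.clip(p + noise_sd_uM * rng.standard_normal(t.size), 0.0, None)
    return ProgressCurve(time_min=t, product_uM=p, enzyme_ug=enzyme_ug, volume_mL=volume_mL)


@dataclass
class NetworkGenSpec:
    """Parameters of a random balanced toy network with a planted solution."""

    n_reactions: int = 4
    n_couples: int = 2
    seed: int = 0

    def __post_init__(self):
        if not (1 <= self.n_reactions <= 6):
            raise ValueError("n_reactions must be in 1..6")
        if not (0 <= self.n_couples <= 3):
            raise ValueError("n_couples must be in 0..3")


def gen_network(spec: NetworkGenSpec) -> tuple[PathwayModel, FluxSolution]:
    """Random chain network with a planted exact flux solution.

    Construction: a conversion chain S0 -> S1 -> ... -> P with random
    positive rational stoichiometries makes the chemistry triangular, hence
    uniquely solvable for 1 mol product; planted fluxes follow by back-
    substitution.  Carrier stoichiometries are drawn at random for all but
    the last carrying reaction of each couple, whose coefficient is chosen
    so the planted fluxes balance the couple exactly — so couple rows are
    consistent by construction and the planted vector is *the* solution.
    Random SLP and translocation coefficients exercise the ATP accounting.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reactions

    def rand_frac(lo=1, hi=4) -> Fraction:
        return Fraction(int(rng.integers(lo, hi + 1)), int(rng.integers(1, 3)))

    species = [f"S{i}" for i in range(n)] + ["P"]
    reactions = []
    for j in range(n):
        a, b = rand_frac(), rand_frac()
        reactions.append(
            Reaction(
                f"R{j}",
                chem={species[j]: -a, species[j + 1]: b},
                slp_atp=Fraction(int(rng.integers(-1, 2))),
                ions_translocated=Fraction(int(rng.integers(-2, 3))),
                reversible=True,
            )
        )

    # planted fluxes by back-substitution: flux_n * b_n = 1; b_j f_j = a_{j+1} f_{j+1}
    fluxes: dict[str, Fraction] = {}
    f = Fraction(1) / reactions[-1].chem["P"]
    fluxes[reactions[-1].id] = f
    for j in range(n - 2, -1, -1):
        demand = -reactions[j + 1].chem[species[j + 1]] * fluxes[reactions[j + 1].id]
        f = demand / reactions[j].chem[species[j + 1]]
        fluxes[reactions[j].id] = f

    couples = [RedoxCouple(f"C{k}", n_electrons=int(rng.integers(1, 3))) for k in range(spec.n_couples)]
    if n >= 2:
        for couple in couples:
            coeffs = {}
            for j in range(n - 1):
                if rng.random() < 0.6:
                    coeffs[reactions[j].id] = Fraction(int(rng.integers(-2, 3)))
            imbalance = sum(
                (fluxes[rid] * c for rid, c in coeffs.items()), Fraction(0)
            )
            # close the couple balance on the final reaction
            coeffs[reactions[-1].id] = -imbalance / fluxes[reactions[-1].id]
            for rxn in reactions:
                c = coeffs.get(rxn.id, Fraction(0))
                if c != 0:
                    rxn.carriers[couple.id] = c
    else:
        couples = []

    model = PathwayModel(
        reactions=reactions,
        couples=couples,
        external_species={"S0"},
        product="P",
    )
    net_ions = sum((fluxes[r.id] * r.ions_translocated for r in reactions), Fraction(0))
    slp_sum = sum((fluxes[r.id] * r.slp_atp for r in reactions), Fraction(0))
    residuals = {f"species:S{i}": Fraction(0) for i in range(1, n)}
    residuals.update({f"couple:{c.id}": Fraction(0) for c in couples})
    planted = FluxSolution(fluxes=fluxes, residuals=residuals, net_ions=net_ions, slp_sum=slp_sum)
    return model, planted
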