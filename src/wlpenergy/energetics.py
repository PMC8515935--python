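"""ATP-yield decomposition and redox thermodynamics.

Net ATP per mol product decomposes into substrate-level phosphorylation
(SLP) and a chemiosmotic term: the net count of ions translocated outward,
divided by the H+/ATP ratio of the F1F0-ATPase.  For *C. ljungdahlii* a
ratio of 3.66 H+/ATP is conventional (11-subunit c ring, as determined in
*C. paradoxum*); plausible c-ring geometries span 2.666 (mitochondria) to 5
(cyanobacteria), hence the sweep operation.

Standard-state redox energetics: for n electrons passing from a donor
couple to an acceptor couple, dG°' = −n·F·(E°'_acceptor − E°'_donor) with
F = 96.485 kJ·V⁻¹·mol⁻¹; negative values are exergonic as written.
"""

from __future__ import annotations

import csv
import decimal
import json
from dataclasses import dataclass
from fractions import Fraction

import pandas as pd

from .network import FluxSolution, RedoxCouple, parse_rational

__all__ = [
    "FARADAY_KJ_PER_V_MOL",
    "DEFAULT_H_PER_ATP",
    "H_PER_ATP_RANGE",
    "EnergyReport",
    "net_atp",
    "sweep_h_per_atp",
    "delta_g_prime",
    "compare_scenarios",
    "round_half_away",
    "write_reports_json",
    "write_reports_csv",
]

#: Faraday constant in kJ per volt per mol of electrons.
FARADAY_KJ_PER_V_MOL = 96.485

#: Conventional H+/ATP ratio for the 11-subunit c ring (exactly as printed).
DEFAULT_H_PER_ATP = Fraction("3.66")

#: Plausible H+/ATP extremes across known c-ring stoichiometries.
H_PER_ATP_RANGE = (Fraction("2.666"), Fraction(5))


def round_half_away(x: Fraction | float, ndigits: int = 2) -> float:
    """Round half away from zero (0.125 -> 0.13, -0.125 -> -0.13)."""
    d = decimal.Decimal(x.numerator) / decimal.Decimal(x.denominator) if isinstance(x, Fraction) else decimal.Decimal(repr(float(x)))
    q = decimal.Decimal(1).scaleb(-ndigits)
    return float(d.quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class EnergyReport:
    """Net-ATP decomposition of a flux solution at a given H+/ATP ratio."""

    slp_atp: Fraction
    chemiosmotic_atp: Fraction
    net_atp: Fraction
    h_per_atp: Fraction
    net_ions: Fraction

    @property
    def display_net_atp(self) -> float:
        """Net ATP rounded to two decimals, half away from zero."""
        return round_half_away(self.net_atp, 2)

    def as_dict(self) -> dict:
        return {
            "slp_atp": float(self.slp_atp),
            "net_ions": float(self.net_ions),
            "h_per_atp": float(self.h_per_atp),
            "chemiosmotic_atp": float(self.chemiosmotic_atp),
            "net_atp": float(self.net_atp),
            "display_net_atp": self.display_net_atp,
        }


def net_atp(solution: FluxSolution, h_per_atp: Fraction | float | str = DEFAULT_H_PER_ATP) -> EnergyReport:
    """Decompose a flux solution into SLP + chemiosmotic ATP per mol product.

    ``h_per_atp`` must be positive; it is parsed exactly (``3.66`` means
    183/50, not the binary float), so the identity
    ``net_atp == slp_atp + net_ions / h_per_atp`` holds without error.
    """
    h = parse_rational(h_per_atp)
    if h <= 0:
        raise ValueError(f"h_per_atp must be positive, got {h}")
    chemi = solution.net_ions / h
    return EnergyReport(
        slp_atp=solution.slp_sum,
        chemiosmotic_atp=chemi,
        net_atp=solution.slp_sum + chemi,
        h_per_atp=h,
        net_ions=solution.net_ions,
    )


def sweep_h_per_atp(
    solution: FluxSolution,
    lo: Fraction | float | str = H_PER_ATP_RANGE[0],
    hi: Fraction | float | str = H_PER_ATP_RANGE[1],
    steps: int = 10,
) -> list[tuple[Fraction, Fraction]]:
    """Net ATP across an inclusive range of H+/ATP ratios.

    Returns ``steps`` evenly spaced ``(h_per_atp, net_atp)`` pairs with both
    endpoints included; the series is monotone in h for fixed net_ions.
    """
    lo = parse_rational(lo)
    hi = parse_rational(hi)
    if not (0 < lo <= hi):
        raise ValueError(f"require 0 < lo <= hi, got lo={lo}, hi={hi}")
    if steps < 2:
        raise ValueError(f"steps must be >= 2, got {steps}")
    out = []
    for i in range(steps):
        h = lo + (hi - lo) * Fraction(i, steps - 1)
        out.append((h, net_atp(solution, h).net_atp))
    return out


def delta_g_prime(donor: RedoxCouple, acceptor: RedoxCouple, n: int) -> float:
    """Standard-state free energy (kJ/mol) of moving n electrons donor -> acceptor.

    dG°' = −n·F·(E°'_acceptor − E°'_donor).  Two-step couples contribute
    their nominal (midpoint) potential.  Negative = exergonic as written;
    antisymmetric under donor/acceptor exchange.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    e_d = donor.nominal_potential_mV
    e_a = acceptor.nominal_potential_mV
    if e_d is None or e_a is None:
        missing = donor.id if e_d is None else acceptor.id
        raise ValueError(f"couple {missing!r} has no standard potential")
    return -n * FARADAY_KJ_PER_V_MOL * (e_a - e_d) / 1000.0


def compare_scenarios(reports: dict[str, EnergyReport]) -> pd.DataFrame:
    """Rank named energy reports by net ATP (descending, ties in input order)."""
    if not reports:
        raise ValueError("at least one report is required")
    rows = [{"scenario": name, **rep.as_dict()} for name, rep in reports.items()]
    df = pd.DataFrame(rows)
    return df.sort_values("net_atp", ascending=False, kind="stable").reset_index(drop=True)


_REPORT_FIELDS = ["scenario", "slp_atp", "net_ions", "h_per_atp", "chemiosmotic_atp", "net_atp", "display_net_atp"]


def write_reports_json(reports: dict[str, EnergyReport], path) -> None:
    payload = [{"scenario": name, **rep.as_dict()} for name, rep in reports.items()]
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)
        fh.write("\n")


def write_reports_csv(reports: dict[str, EnergyReport], path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.DictWriter(fh, fieldnames=_REPORT_FIELDS)
        writer.writeheader()
        for name, rep in reports.items():
            writer.writerow({"scenario": name, **rep.as_dict()})
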