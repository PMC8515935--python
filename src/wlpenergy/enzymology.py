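"""Enzyme-characterisation arithmetic: purification accounting, specific
activities from absorbance slopes and progress curves, Michaelis-Menten fits.

Units follow anaerobic-enzymology convention: one unit (U) is the formation
of 1 umol of product (or consumption of 1 umol of substrate) per minute;
specific activity is U per mg protein.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .energetics import round_half_away

__all__ = [
    "PurificationStep",
    "KineticDataset",
    "ProgressCurve",
    "AssayCalibration",
    "MichaelisMentenFit",
    "FitError",
    "purification_table",
    "activity_from_absorbance",
    "specific_activity_from_progress",
    "fit_michaelis_menten",
    "read_purification_csv",
    "read_kinetics_csv",
    "read_progress_csv",
    "load_mthfr_purification",
]


class FitError(RuntimeError):
    """Nonlinear fit failed to converge; carries the optimiser trace."""

    def __init__(self, message: str, trace: object = None):
        super().__init__(message)
        self.trace = trace


@dataclass(frozen=True)
class PurificationStep:
    """One row of a purification record."""

    name: str
    protein_mg: float
    specific_activity_U_per_mg: float

    def __post_init__(self):
        if self.protein_mg <= 0:
            raise ValueError(f"step {self.name!r}: protein_mg must be > 0")
        if self.specific_activity_U_per_mg < 0:
            raise ValueError(f"step {self.name!r}: specific activity must be >= 0")


@dataclass
class KineticDataset:
    """Substrate-saturation series: concentration (uM) vs rate (U/mg)."""

    substrate_conc: np.ndarray
    rate: np.ndarray

    def __post_init__(self):
        self.substrate_conc = np.asarray(self.substrate_conc, dtype=float)
        self.rate = np.asarray(self.rate, dtype=float)
        if self.substrate_conc.shape != self.rate.shape or self.substrate_conc.ndim != 1:
            raise ValueError("substrate_conc and rate must be 1-D and the same length")
        if np.any(self.substrate_conc < 0):
            raise ValueError("concentrations must be non-negative")
        if np.unique(self.substrate_conc).size < 2:
            raise ValueError("concentrations must not all be identical")


@dataclass
class ProgressCurve:
    """Product formation over time in a fixed-volume assay."""

    time_min: np.ndarray
    product_uM: np.ndarray
    enzyme_ug: float
    volume_mL: float = 1.0

    def __post_init__(self):
        self.time_min = np.asarray(self.time_min, dtype=float)
        self.product_uM = np.asarray(self.product_uM, dtype=float)
        if self.time_min.shape != self.product_uM.shape or self.time_min.ndim != 1:
            raise ValueError("time and product must be 1-D and the same length")
        if np.any(np.diff(self.time_min) <= 0):
            raise ValueError("time must be strictly increasing")
        if np.any(self.product_uM < 0):
            raise ValueError("product concentrations must be non-negative")
        if self.enzyme_ug <= 0 or self.volume_mL <= 0:
            raise ValueError("enzyme mass and volume must be positive")


@dataclass(frozen=True)
class AssayCalibration:
    """Photometric calibration: extinction coefficient and light path.

    The default is the benzyl-viologen assay at 555 nm
    (epsilon = 12.1 mM^-1 cm^-1, 1 cm path).
    """

    epsilon_mM_cm: float = 12.1
    path_cm: float = 1.0

    def __post_init__(self):
        if self.epsilon_mM_cm <= 0 or self.path_cm <= 0:
            raise ValueError("extinction coefficient and path length must be positive")


def purification_table(steps: Sequence[PurificationStep]) -> pd.DataFrame:
    """Derive total activity, yield and fold purification per step.

    The first step (cell extracts) is the reference: total activity there is
    100% yield and fold 1.  ``yield_pct = 100 * total/total_first``;
    ``fold = specific/specific_first``.  Display columns are rounded to one
    decimal, half away from zero; the unrounded columns are kept alongside.
    """
    steps = list(steps)
    if not steps:
        raise ValueError("at least one purification step is required")
    ref = steps[0]
    ref_total = ref.protein_mg * ref.specific_activity_U_per_mg
    if ref_total == 0 or ref.specific_activity_U_per_mg == 0:
        raise ValueError("reference step has zero activity")
    rows = []
    for s in steps:
        total = s.protein_mg * s.specific_activity_U_per_mg
        yield_pct = 100.0 * total / ref_total
        fold = s.specific_activity_U_per_mg / ref.specific_activity_U_per_mg
        rows.append(
            {
                "step": s.name,
                "protein_mg": s.protein_mg,
                "specific_activity_U_per_mg": s.specific_activity_U_per_mg,
                "total_activity_U": total,
                "yield_pct": yield_pct,
                "fold_purification": fold,
                "display_yield_pct": round_half_away(yield_pct, 1),
                "display_fold": round_half_away(fold, 1),
            }
        )
    return pd.DataFrame(rows)


def activity_from_absorbance(
    slope_A_per_min: float,
    calib: AssayCalibration = AssayCalibration(),
    volume_mL: float = 1.0,
    enzyme_mg: float = 1.0,
    stoich_factor: float = 1.0,
) -> float:
    """Specific activity (U/mg) from an absorbance slope.

    Beer-Lambert: rate (mM/min) = slope / (epsilon * path); times the assay
    volume in mL this is umol/min, divided by enzyme mass in mg gives U/mg.
    ``stoich_factor`` converts acceptor turnover to product formation (e.g.
    0.5 when two one-electron dye reductions correspond to one product).
    """
    if volume_mL <= 0 or enzyme_mg <= 0 or stoich_factor <= 0:
        raise ValueError("volume, enzyme mass and stoichiometric factor must be positive")
    rate_mM_per_min = slope_A_per_min / (calib.epsilon_mM_cm * calib.path_cm)
    rate_umol_per_min = rate_mM_per_min * volume_mL
    return rate_umol_per_min / enzyme_mg * stoich_factor


def specific_activity_from_progress(
    curve: ProgressCurve,
    linear_window: tuple[float, float] | None = None,
) -> float:
    """Specific activity (U/mg) from the linear phase of a progress curve.

    Least-squares slope of product concentration vs time over the window
    (inclusive, in minutes; whole curve when None), converted to umol/min
    via the assay volume and divided by enzyme mass in mg.
    """
    t, p = curve.time_min, curve.product_uM
    if linear_window is not None:
        lo, hi = linear_window
        mask = (t >= lo) & (t <= hi)
        t, p = t[mask], p[mask]
    if t.size < 2:
        raise ValueError("linear window must contain at least 2 points")
    slope_uM_per_min = np.polyfit(t, p, 1)[0]
    rate_umol_per_min = slope_uM_per_min * curve.volume_mL / 1000.0
    return rate_umol_per_min / (curve.enzyme_ug / 1000.0)


@dataclass(frozen=True)
class MichaelisMentenFit:
    """Fitted Km (uM), Vmax (U/mg) with asymptotic standard errors."""

    km: float
    vmax: float
    km_se: float
    vmax_se: float
    n_obs: int
    negative_parameters: bool = False


def _lineweaver_burk_init(s: np.ndarray, v: np.ndarray) -> tuple[float, float]:
    """Initial (Km, Vmax) from the double-reciprocal linearisation."""
    ok = (s > 0) & (v > 0)
    if ok.sum() >= 2:
        slope, intercept = np.polyfit(1.0 / s[ok], 1.0 / v[ok], 1)
        if intercept > 0 and slope > 0:
            return slope / intercept, 1.0 / intercept
    # fall back to crude moments when the linearisation is degenerate
    return float(np.median(s[s > 0])) if np.any(s > 0) else 1.0, float(np.max(v))


def fit_michaelis_menten(
    data: KineticDataset,
    weighted_inverse_v2: bool = False,
) -> MichaelisMentenFit:
    """Nonlinear least-squares fit of v = Vmax*S/(Km+S).

    Initialised from a Lineweaver-Burk linearisation; converges when the
    relative parameter change falls below 1e-8 (xtol) within a bounded
    number of iterations.  ``weighted_inverse_v2`` applies 1/v^2 weights
    (relative-error weighting); the default is unweighted.  Returns point
    estimates with asymptotic standard errors from the Jacobian at the
    optimum; non-positive estimates are flagged rather than clipped.
    """
    s, v = data.substrate_conc, data.rate
    if np.unique(s).size < 3:
        raise ValueError("at least 3 distinct substrate concentrations are required")

    w = 1.0 / np.clip(np.abs(v), 1e-300, None) if weighted_inverse_v2 else np.ones_like(v)

    def residuals(theta):
        km, vmax = theta
        return (vmax * s / (km + s) - v) * w

    p0 = _lineweaver_burk_init(s, v)
    res = least_squares(residuals, p0, xtol=1e-8, ftol=1e-15, gtol=1e-15, max_nfev=500 * 3)
    if not res.success:
        raise FitError(f"Michaelis-Menten fit did not converge: {res.message}", trace=res)

    km, vmax = res.x
    dof = max(s.size - 2, 1)
    ssr = float(res.fun @ res.fun)
    jtj = res.jac.T @ res.jac
    try:
        cov = np.linalg.inv(jtj) * ssr / dof
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.array([np.nan, np.nan])
    return MichaelisMentenFit(
        km=float(km),
        vmax=float(vmax),
        km_se=float(se[0]),
        vmax_se=float(se[1]),
        n_obs=int(s.size),
        negative_parameters=bool(km <= 0 or vmax <= 0),
    )


# --- CSV readers (comma-separated, header row, dot decimal) ----------------

def _read_csv(path, required: list[str]) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    return df


def read_purification_csv(path) -> list[PurificationStep]:
    """Columns: name, protein_mg, specific_activity."""
    df = _read_csv(path, ["name", "protein_mg", "specific_activity"])
    steps = []
    for i, row in df.iterrows():
        try:
            steps.append(
                PurificationStep(
                    name=str(row["name"]),
                    protein_mg=float(row["protein_mg"]),
                    specific_activity_U_per_mg=float(row["specific_activity"]),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}: row {i + 1}: {exc}") from exc
    return steps


def read_kinetics_csv(path) -> KineticDataset:
    """Columns: substrate, rate."""
    df = _read_csv(path, ["substrate", "rate"])
    return KineticDataset(df["substrate"].to_numpy(float), df["rate"].to_numpy(float))


def read_progress_csv(path, enzyme_ug: float, volume_mL: float = 1.0) -> ProgressCurve:
    """Columns: time, product."""
    df = _read_csv(path, ["time", "product"])
    return ProgressCurve(
        df["time"].to_numpy(float), df["product"].to_numpy(float),
        enzyme_ug=enzyme_ug, volume_mL=volume_mL,
    )


def load_mthfr_purification() -> list[PurificationStep]:
    """The published purification record of the ferredoxin-dependent MTHFR
    from CO-grown *C. ljungdahlii* (protein and specific-activity columns)."""
    from importlib.resources import files

    return read_purification_csv(files("wlpenergy").joinpath("data/mthfr_co_purification.csv"))
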