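"""Enzyme kinetics, thermal stability and binding thermodynamics.

Estimators and formulas for the quantities used when comparing a
wild-type enzyme with engineered mutants:

* Michaelis-Menten parameters by the double-reciprocal (Lineweaver-Burk)
  linearization, with a direct nonlinear fit as a cross-check;
* the apparent transition-state stabilization difference
  ``ddG = -R T ln[(kcat/Km)_mut / (kcat/Km)_wt]`` (kJ/mol);
* the binding free energy from calorimetric enthalpy/entropy,
  ``dG0 = dH - T dS`` (kcal/mol, dS given in cal/mol/K), and the
  consistency value ``-R T ln Ka``;
* first-order thermal-inactivation rate and half-life ``t1/2 = ln2/k``;
* ``T50`` (temperature retaining 50% of maximal activity, by linear
  interpolation) and ``Tmax`` (grid argmax of an activity profile).

Unit conventions are fixed per function and never converted silently:
kinetics in kJ/mol (R = 8.314 J/mol/K), calorimetry in kcal/mol
(R = 1.98720425e-3 kcal/mol/K).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "R_J", "R_KCAL",
    "KineticsRecord", "ItcRecord", "StabilityEstimates",
    "fit_michaelis_menten_lb", "fit_michaelis_menten_nls",
    "delta_delta_g", "gibbs_from_itc", "dg_from_ka",
    "fit_half_life", "estimate_t50", "estimate_tmax", "fold_change",
    "kinetics_table", "itc_table",
]

R_J = 8.314  # J / mol / K
R_KCAL = 1.98720425e-3  # kcal / mol / K


class FitError(ValueError):
    """A fit is impossible or produced a nonsensical parameter."""


@dataclass
class KineticsRecord:
    enzyme_id: str
    Km: float  # mg/mL
    kcat: float  # 1/s
    kcat_over_Km: float = field(default=None)  # mL/mg/s
    ddG: float | None = None  # kJ/mol vs reference

    def __post_init__(self) -> None:
        if self.Km <= 0 or self.kcat <= 0:
            raise ValueError("Km and kcat must be positive")
        if self.kcat_over_Km is None:
            self.kcat_over_Km = self.kcat / self.Km


@dataclass
class ItcRecord:
    enzyme_id: str
    Ka: float  # 1/M
    dH: float  # kcal/mol
    dS: float  # cal/mol/K
    dG0: float | None = None  # kcal/mol
    ddG0: float | None = None  # kcal/mol vs reference


@dataclass
class StabilityEstimates:
    enzyme_id: str
    k_inact: float | None = None  # 1/min
    t_half: float | None = None  # min
    T50: float | None = None  # Celsius
    Tmax: float | None = None  # Celsius


# ---------------------------------------------------------------------------
# Michaelis-Menten
# ---------------------------------------------------------------------------

def fit_michaelis_menten_lb(points) -> dict:
    """Lineweaver-Burk fit: OLS of 1/v on 1/S.

    ``points`` is a sequence of (S, v) pairs or a DataFrame with columns
    S and v.  Returns Km, Vmax, the raw slope/intercept, and R^2 of the
    double-reciprocal regression.  Vmax = 1/intercept, Km = slope/intercept.
    """
    S, v = _as_sv(points)
    if len(S) < 3:
        raise FitError("need at least 3 points")
    if np.any(S <= 0) or np.any(v <= 0):
        raise FitError("S and v must be positive for a double-reciprocal fit")
    res = stats.linregress(1.0 / S, 1.0 / v)
    if res.intercept <= 0:
        raise FitError(
            f"non-positive intercept {res.intercept:.4g} "
            f"(slope {res.slope:.4g}): Vmax undefined"
        )
    return {
        "Km": res.slope / res.intercept,
        "Vmax": 1.0 / res.intercept,
        "slope": res.slope,
        "intercept": res.intercept,
        "r_squared": res.rvalue**2,
        "method": "lineweaver-burk",
    }


def fit_michaelis_menten_nls(points) -> dict:
    """Direct (unweighted) nonlinear least-squares Michaelis-Menten fit.

    Cross-check for the double-reciprocal estimate; the two differ under
    noise because the reciprocal transform re-weights the errors.
    """
    S, v = _as_sv(points)
    if len(S) < 3:
        raise FitError("need at least 3 points")

    def mm(s, vmax, km):
        return vmax * s / (km + s)

    p0 = (float(v.max()), float(np.median(S)))
    popt, _ = optimize.curve_fit(mm, S, v, p0=p0, maxfev=10000)
    vmax, km = popt
    if km <= 0 or vmax <= 0:
        raise FitError(f"nonlinear fit diverged: Vmax={vmax:.4g}, Km={km:.4g}")
    resid = v - mm(S, *popt)
    ss_tot = ((v - v.mean()) ** 2).sum()
    return {
        "Km": float(km),
        "Vmax": float(vmax),
        "r_squared": float(1 - (resid**2).sum() / ss_tot) if ss_tot > 0 else 1.0,
        "method": "nls",
    }


def _as_sv(points):
    if isinstance(points, pd.DataFrame):
        return points["S"].to_numpy(float), points["v"].to_numpy(float)
    arr = np.asarray(points, dtype=float)
    return arr[:, 0], arr[:, 1]


# ---------------------------------------------------------------------------
# Free-energy formulas
# ---------------------------------------------------------------------------

def delta_delta_g(kk_mut: float, kk_wt: float, T_kelvin: float) -> float:
    """Transition-state stabilization difference, kJ/mol.

    ``-R T ln(kk_mut / kk_wt) / 1000`` with R = 8.314 J/mol/K; negative
    when the mutant is the better catalyst.  The temperature is explicit
    — it must match the temperature of the kinetic assay being compared.
    """
    if kk_mut <= 0 or kk_wt <= 0:
        raise ValueError("catalytic efficiencies must be positive")
    if T_kelvin <= 0:
        raise ValueError("temperature must be positive kelvin")
    return -R_J * T_kelvin * np.log(kk_mut / kk_wt) / 1000.0


def fold_change(kk_mut: float, kk_wt: float) -> float:
    """"N-fold increase" convention: kk_mut/kk_wt - 1."""
    if kk_mut <= 0 or kk_wt <= 0:
        raise ValueError("catalytic efficiencies must be positive")
    return kk_mut / kk_wt - 1.0


def gibbs_from_itc(dH: float, dS: float, T_kelvin: float) -> float:
    """Binding free energy dG0 = dH - T*dS, kcal/mol.

    ``dH`` in kcal/mol and ``dS`` in cal/mol/K, as calorimetry software
    reports them; dS is divided by 1000 before the product.
    """
    if not np.isfinite([dH, dS, T_kelvin]).all():
        raise ValueError("inputs must be finite")
    return dH - T_kelvin * dS / 1000.0


def dg_from_ka(Ka: float, T_kelvin: float) -> float:
    """Consistency value -R T ln Ka, kcal/mol (R = 1.98720425e-3).

    Generally differs from ``gibbs_from_itc`` on the same record because
    calorimetric dH - T dS and van 't Hoff -RT ln Ka carry independent
    experimental errors.
    """
    if Ka <= 0:
        raise ValueError("Ka must be positive")
    return -R_KCAL * T_kelvin * np.log(Ka)


# ---------------------------------------------------------------------------
# Thermal stability estimators
# ---------------------------------------------------------------------------

def fit_half_life(times, residual_activity) -> dict:
    """First-order inactivation fit: OLS of ln(activity) on time.

    Activities are normalized to the first point.  Returns the
    inactivation rate (1/min), the half-life ln2/k (min) and R^2.
    A non-negative slope (no decay) is an error, not a huge half-life.
    """
    t = np.asarray(times, dtype=float)
    a = np.asarray(residual_activity, dtype=float)
    if len(t) < 3:
        raise FitError("need at least 3 time points")
    if np.any(a <= 0):
        raise FitError("activities must be positive for a log-linear fit")
    a = a / a[0]
    res = stats.linregress(t, np.log(a))
    if res.slope >= 0:
        raise FitError(f"no decay: slope {res.slope:.4g} >= 0")
    k = -res.slope
    return {"k_inact": k, "t_half": np.log(2) / k, "r_squared": res.rvalue**2}


def estimate_t50(temps, residual_activity) -> float:
    """Temperature at which half the maximal activity remains (Celsius).

    The profile is normalized to its maximum; the unique downward 0.5
    crossing is located by linear interpolation between the bracketing
    grid temperatures.  No crossing, or more than one, is an error.
    """
    T = np.asarray(temps, dtype=float)
    a = np.asarray(residual_activity, dtype=float)
    if len(T) < 2:
        raise FitError("need at least 2 points")
    a = a / a.max()
    crossings = []
    for i in range(len(T) - 1):
        lo, hi = a[i], a[i + 1]
        if lo == 0.5:
            crossings.append(float(T[i]))
        elif (lo - 0.5) * (hi - 0.5) < 0:
            frac = (0.5 - lo) / (hi - lo)
            crossings.append(float(T[i] + frac * (T[i + 1] - T[i])))
    if a[-1] == 0.5:
        crossings.append(float(T[-1]))
    crossings = sorted(set(round(c, 9) for c in crossings))
    if not crossings:
        raise FitError("activity never crosses 50% of maximum")
    if len(crossings) > 1:
        raise FitError(f"ambiguous profile: multiple 50% crossings at {crossings}")
    return crossings[0]


def estimate_tmax(temps, activity) -> float:
    """Temperature of maximal activity, reported at the measured grid point."""
    T = np.asarray(temps, dtype=float)
    a = np.asarray(activity, dtype=float)
    if len(T) == 0:
        raise FitError("empty profile")
    return float(T[int(np.argmax(a))])


# ---------------------------------------------------------------------------
# Table builders
# ---------------------------------------------------------------------------

def kinetics_table(
    records: list[KineticsRecord], reference_id: str, T_kelvin: float
) -> pd.DataFrame:
    """Per-enzyme kinetics with ddG and fold change vs a reference enzyme."""
    ref = next(r for r in records if r.enzyme_id == reference_id)
    rows = []
    for r in records:
        rows.append(
            {
                "enzyme": r.enzyme_id,
                "Km_mg_per_mL": r.Km,
                "kcat_per_s": r.kcat,
                "kcat_over_Km": r.kcat_over_Km,
                "ddG_kJ_per_mol": delta_delta_g(
                    r.kcat_over_Km, ref.kcat_over_Km, T_kelvin
                ),
                "fold_change": fold_change(r.kcat_over_Km, ref.kcat_over_Km),
            }
        )
    return pd.DataFrame(rows)


def itc_table(
    records: list[ItcRecord], reference_id: str, T_kelvin: float
) -> pd.DataFrame:
    """Per-enzyme binding thermodynamics with dG0 and ddG0 vs a reference."""
    rows = []
    for r in records:
        rows.append(
            {
                "enzyme": r.enzyme_id,
                "Ka_per_M": r.Ka,
                "dH_kcal_per_mol": r.dH,
                "dS_cal_per_mol_K": r.dS,
                "dG0_kcal_per_mol": gibbs_from_itc(r.dH, r.dS, T_kelvin),
                "dG_from_Ka_kcal_per_mol": dg_from_ka(r.Ka, T_kelvin),
            }
        )
    df = pd.DataFrame(rows)
    ref_dg = df.loc[df["enzyme"] == reference_id, "dG0_kcal_per_mol"].iloc[0]
    df["ddG0_kcal_per_mol"] = df["dG0_kcal_per_mol"] - ref_dg
    return df
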