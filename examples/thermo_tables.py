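"""Kinetic and thermodynamic comparison of PG63 and its mutants.

Reproduces the published comparison tables from their raw columns: the
transition-state stabilization difference ddG = -RT ln[(kcat/Km)mut /
(kcat/Km)wt] and fold changes from the kinetic table, and the binding
free energy dG0 = dH - T dS from the ITC table.  Also demonstrates the
thermal-stability estimators on synthetic data with known ground truth.
"""

import numpy as np

from catpi.datasets import (
    DDG_TABLE_TEMPERATURE_K,
    ITC_TEMPERATURE_K,
    PG63_ITC,
    PG63_KINETICS,
)
from catpi.kinetics import (
    estimate_t50,
    fit_half_life,
    fit_michaelis_menten_lb,
    itc_table,
    kinetics_table,
)
from catpi.synth import make_decay, make_kinetics, make_thermal_profile

print("=== kinetics (ddG at 348 K, fold change vs wild type) ===")
kin = kinetics_table(PG63_KINETICS, "wild_type", DDG_TABLE_TEMPERATURE_K)
print(kin.round(2).to_string(index=False))

print("\n=== ITC binding thermodynamics at 298.15 K ===")
itc = itc_table(PG63_ITC, "wild_type", ITC_TEMPERATURE_K)
print(itc.round(2).to_string(index=False))

print("\n=== estimators on synthetic ground truth ===")
decay = make_decay(np.log(2) / 9.6, [0, 5, 10, 20, 40])
fit = fit_half_life(decay["time_min"], decay["activity"])
print(f"half-life from noiseless decay built with t1/2 = 9.6 min: {fit['t_half']:.2f} min")

profile = make_thermal_profile(48.0, list(range(30, 85, 5)))
print(f"T50 from a sigmoid designed at 48 C on a 5 C grid: "
      f"{estimate_t50(profile['temp_C'], profile['activity']):.2f} C")

mm = make_kinetics(Km=2.0, Vmax=10.0, S_values=[0.5, 1, 2, 5, 10])
fit = fit_michaelis_menten_lb(mm)
print(f"Lineweaver-Burk on noiseless rates from (Km=2, Vmax=10): "
      f"Km={fit['Km']:.3f}, Vmax={fit['Vmax']:.3f}")

print()
print(
    "Negative ddG means the mutant stabilizes the catalytic transition"
    "\nstate more than wild type; dG0 columns combine enthalpy and entropy"
    "\nof substrate binding; the estimator block shows each fit inverting"
    "\nits generator exactly at zero noise."
)
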