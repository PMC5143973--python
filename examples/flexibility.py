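"""Flexibility analysis of a conformational ensemble.

Builds a 10-frame ensemble of a 12-residue scaffold in which one residue
jumps between two positions, then computes the Calpha RMSD series
(superposed on frame 0) and the per-residue RMSF about the iterated mean
structure, plus hydrogen bonds with their ensemble occupancy.
"""

import numpy as np

from catpi.ensembles import detect_hbonds, rmsd_series, rmsf_profile
from catpi.synth import make_ensemble, make_scaffold

scaffold = make_scaffold(12, motif_sites={6: "SER"})
ensemble = make_ensemble(scaffold, ("A:1", "A:6"), 0.5, n_frames=10, seed=7)

rmsd = rmsd_series(ensemble)
print("RMSD to frame 0 (A):", np.round(rmsd, 2))

profile = rmsf_profile(ensemble)
print("\nper-residue RMSF (A):")
for key, value in zip(profile.residue_keys, profile.rmsf):
    marker = " <-- mobile residue" if value == profile.rmsf.max() else ""
    print(f"  {key}  {value:6.2f}{marker}")

hbonds = detect_hbonds(ensemble)
print(f"\n{len(hbonds)} hydrogen bonds (heavy-atom mode); top 3 by occupancy:")
for hb in hbonds[:3]:
    print(
        f"  {hb.donor[0]}@{hb.donor[1]} ... {hb.acceptor[0]}@{hb.acceptor[1]}"
        f"  {hb.mean_distance:.2f} A  {hb.occupancy_pct:.0f}%"
    )

print()
print(
    "The displaced residue dominates the RMSF profile; the small residual"
    "\nvalues elsewhere are the share of its motion the superposition onto"
    "\nthe mean structure redistributes across this short chain."
)
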