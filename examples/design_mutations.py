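"""Enumerate and assess Lys/Tyr substitution candidates near targets.

Builds a 30-residue extended scaffold carrying an Arg, a Thr, a Trp and
a Ser, enumerates every residue within 8 A (Cbeta-Cbeta) of a
Lys/Arg/Phe/Tyr/Trp target as a substitution candidate (to Tyr beside a
cation, to Lys beside an aromatic), rebuilds each candidate side chain
over an exhaustive chi-angle grid, and reports the best clash-free
rotamer's geometry and feasibility.
"""

from catpi.design import assess_candidate, enumerate_candidates
from catpi.pipeline import candidates_frame
from catpi.synth import make_scaffold

scaffold = make_scaffold(30, motif_sites={8: "ARG", 10: "THR", 20: "TRP", 22: "SER"})
candidates = enumerate_candidates(scaffold, proximity_cut=8.0)
assessed = [assess_candidate(scaffold, c) for c in candidates]
print(candidates_frame(assessed).to_string(index=False))
print()
print(
    "Each row proposes one point substitution next to an existing target;"
    "\nfeasible=True means some clash-free ideal-geometry rotamer satisfies"
    "\nthe two-rule cation-pi criterion against the partner residue."
)
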