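"""Detect cation-pi interactions in a structure.

Builds a two-residue fixture with a Lys ammonium 4.0 A from a Tyr ring
face (10 deg off the ring normal), scans it with the two-rule criterion
(distance <= 6 A, approach angle <= 60 deg) and prints each evaluated
pair with its geometry and verdict.
"""

from catpi.geometry import scan_structure
from catpi.pipeline import interactions_frame
from catpi.synth import make_pair_fixture

frame = make_pair_fixture("LYS", "TYR", distance=4.0, theta=10.0)
records = scan_structure(frame)
print(interactions_frame(records).to_string(index=False))
print()
print(
    "distance_A is the charged-group mass center to ring centroid distance;"
    "\ntheta_deg the approach angle off the ring normal; satisfied=True means"
    "\nboth rules hold, so this pair counts as a (potential) cation-pi contact."
)
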