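"""Cation-pi interaction geometry.

A cation-pi contact is scored between the positively charged side-chain
group of Lys (ammonium nitrogen NZ) or Arg (guanidinium NE/CZ/NH1/NH2) and
the face of an aromatic ring (Phe/Tyr six-ring; Trp six- and five-rings).
Two geometric rules decide whether a pair counts as a (potential)
interaction:

1. the distance between the mass center of the charged group and the ring
   centroid is at most ``d_cut`` (default 6.0 A, boundary inclusive);
2. the chosen angle is at most ``a_cut`` (default 60 degrees, inclusive).

The angle rule has two conventions, selected by ``angle_mode``:

* ``"axial"`` (default): angle between the ring normal and the
  centroid-to-cation vector, folded to [0, 90] — the face-on criterion,
  defined for both Lys and Arg;
* ``"plane_plane"``: angle between the guanidinium plane and the ring
  plane, folded to [0, 90] — only defined for Arg, falls back to axial
  for Lys.

Ring normals come from the smallest principal axis of the ring atoms, so
their sign is arbitrary; every angle is folded into [0, 90] to be
independent of that sign.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .structures import Residue, ResidueKey, StructureFrame

logger = logging.getLogger(__name__)

__all__ = [
    "CationGroup",
    "AromaticRing",
    "PairGeometry",
    "InteractionRecord",
    "CriteriaConfig",
    "GroupUndefinedError",
    "cation_group",
    "aromatic_rings",
    "pair_geometry",
    "is_cation_pi",
    "scan_structure",
    "CATION_RESIDUES",
    "AROMATIC_RESIDUES",
    "RING_ATOMS",
]

CATION_RESIDUES = {"LYS", "ARG"}
AROMATIC_RESIDUES = {"PHE", "TYR", "TRP"}

# Heavy atoms defining each aromatic ring.
RING_ATOMS: dict[tuple[str, str], list[str]] = {
    ("PHE", "six"): ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    ("TYR", "six"): ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    ("TRP", "six"): ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    ("TRP", "five"): ["CG", "CD1", "CD2", "NE1", "CE2"],
    # His is excluded by default but available via CriteriaConfig.
    ("HIS", "five"): ["CG", "ND1", "CD2", "CE1", "NE2"],
}

_CATION_ATOMS = {"LYS": ["NZ"], "ARG": ["NE", "CZ", "NH1", "NH2"]}
_LYS_HYDROGENS = ["HZ1", "HZ2", "HZ3", "1HZ", "2HZ", "3HZ"]


class GroupUndefinedError(ValueError):
    """A cation group or aromatic ring cannot be built (missing atoms)."""


class DegenerateGeometryError(ValueError):
    """Coincident points make the pair geometry undefined."""


@dataclass(frozen=True)
class CationGroup:
    residue_key: ResidueKey
    res_name: str
    group_atoms: tuple[str, ...]
    mass_center: np.ndarray
    plane_normal: np.ndarray | None = None  # None for Lys


@dataclass(frozen=True)
class AromaticRing:
    residue_key: ResidueKey
    res_name: str
    ring_label: str  # "six" | "five"
    ring_atoms: tuple[str, ...]
    centroid: np.ndarray
    normal: np.ndarray  # unit vector, sign arbitrary


@dataclass(frozen=True)
class PairGeometry:
    distance_d: float  # Angstrom, mass center to ring centroid
    theta_axial: float  # degrees in [0, 90]
    dihedral_pp: float | None = None  # degrees in [0, 90], Arg only


@dataclass(frozen=True)
class InteractionRecord:
    cation: CationGroup
    ring: AromaticRing
    geometry: PairGeometry
    satisfied: bool
    distance_ok: bool
    angle_ok: bool


@dataclass
class CriteriaConfig:
    """Thresholds and conventions of the two-rule criterion."""

    d_cut: float = 6.0  # Angstrom, inclusive
    a_cut: float = 60.0  # degrees, inclusive
    angle_mode: str = "axial"  # "axial" | "plane_plane"
    min_seq_separation: int = 2  # |i - j| below this (same chain) is skipped
    include_histidine: bool = False  # His as neither cation nor pi by default

    def __post_init__(self) -> None:
        if self.d_cut <= 0 or self.a_cut <= 0:
            raise ValueError("cutoffs must be positive")
        if self.angle_mode not in ("axial", "plane_plane"):
            raise ValueError("angle_mode must be 'axial' or 'plane_plane'")


def _atomic_mass(element: str) -> float:
    return gemmi.Element(element).weight


def _plane_normal(coords: np.ndarray) -> np.ndarray:
    """Unit normal of the best-fit plane: smallest principal axis (SVD)."""
    centered = coords - coords.mean(axis=0)
    _, _, vt = np.linalg.svd(centered)
    return vt[-1]


def _fold_angle_deg(cos_value: float) -> float:
    """Angle from |cos| — folds sign-ambiguous axes into [0, 90] degrees."""
    return float(np.degrees(np.arccos(np.clip(abs(cos_value), 0.0, 1.0))))


def cation_group(residue: Residue) -> CationGroup:
    """Build the charged-group descriptor of a Lys or Arg residue.

    Lys: mass-weighted center of NZ plus any HZ hydrogens present (without
    hydrogens this is simply the NZ position); no plane.  Arg: mass-weighted
    center of the guanidinium heavy atoms NE/CZ/NH1/NH2, with a least-squares
    plane normal.
    """
    if residue.res_name not in CATION_RESIDUES:
        raise GroupUndefinedError(
            f"{residue.res_name} {residue.key} is not a cationic residue"
        )
    required = _CATION_ATOMS[residue.res_name]
    missing = [n for n in required if residue.atom(n) is None]
    if missing:
        raise GroupUndefinedError(
            f"{residue.res_name} {residue.key}: missing atoms {missing}"
        )
    names = list(required)
    if residue.res_name == "LYS":
        names += [h for h in _LYS_HYDROGENS if residue.atom(h) is not None]
    coords = residue.coords_of(names)
    masses = np.array(
        [_atomic_mass(residue.atom(n).element) for n in names]
    )
    center = (coords * masses[:, None]).sum(axis=0) / masses.sum()
    normal = None
    if residue.res_name == "ARG":
        normal = _plane_normal(residue.coords_of(required))
    return CationGroup(
        residue_key=residue.key,
        res_name=residue.res_name,
        group_atoms=tuple(names),
        mass_center=center,
        plane_normal=normal,
    )


def aromatic_rings(residue: Residue) -> list[AromaticRing]:
    """Aromatic ring descriptors: one ring for Phe/Tyr, two for Trp.

    Centroid is the unweighted mean of the ring heavy atoms; the normal is
    the smallest principal axis of the ring-atom scatter (sign arbitrary).
    """
    if residue.res_name not in AROMATIC_RESIDUES | {"HIS"}:
        raise GroupUndefinedError(
            f"{residue.res_name} {residue.key} is not an aromatic residue"
        )
    rings = []
    for (res_name, label), names in RING_ATOMS.items():
        if res_name != residue.res_name:
            continue
        missing = [n for n in names if residue.atom(n) is None]
        if missing:
            raise GroupUndefinedError(
                f"{residue.res_name} {residue.key}: missing ring atoms {missing}"
            )
        coords = residue.coords_of(names)
        rings.append(
            AromaticRing(
                residue_key=residue.key,
                res_name=residue.res_name,
                ring_label=label,
                ring_atoms=tuple(names),
                centroid=coords.mean(axis=0),
                normal=_plane_normal(coords),
            )
        )
    return rings


def pair_geometry(cation: CationGroup, ring: AromaticRing) -> PairGeometry:
    """Distance and angle(s) between a charged group and a ring face."""
    vec = cation.mass_center - ring.centroid
    d = float(np.linalg.norm(vec))
    if d < 1e-9:
        raise DegenerateGeometryError(
            f"cation {cation.residue_key} coincides with ring centroid "
            f"{ring.residue_key}"
        )
    theta = _fold_angle_deg(float(np.dot(ring.normal, vec / d)))
    dihedral = None
    if cation.plane_normal is not None:
        dihedral = _fold_angle_deg(
            float(np.dot(ring.normal, cation.plane_normal))
        )
    return PairGeometry(distance_d=d, theta_axial=theta, dihedral_pp=dihedral)


def is_cation_pi(
    geometry: PairGeometry, criteria: CriteriaConfig | None = None
) -> tuple[bool, dict[str, bool]]:
    """Apply the two-rule criterion; both thresholds are inclusive."""
    criteria = criteria or CriteriaConfig()
    eps = 1e-9  # guard: boundary values must not fail to rounding noise
    distance_ok = geometry.distance_d <= criteria.d_cut + eps
    if criteria.angle_mode == "plane_plane" and geometry.dihedral_pp is not None:
        angle = geometry.dihedral_pp
    else:
        angle = geometry.theta_axial
    angle_ok = angle <= criteria.a_cut + eps
    satisfied = distance_ok and angle_ok
    return satisfied, {"distance_ok": distance_ok, "angle_ok": angle_ok}


def _eligible(a: Residue, b: Residue, min_sep: int) -> bool:
    if a.chain_id != b.chain_id:
        return True
    return abs(a.seq_number - b.seq_number) >= min_sep


def scan_structure(
    frame: StructureFrame, criteria: CriteriaConfig | None = None
) -> list[InteractionRecord]:
    """Evaluate every eligible (Lys/Arg) x (Phe/Tyr/Trp) pair of a frame.

    Pairs closer than ``min_seq_separation`` in sequence (same chain) are
    skipped.  For Trp the pair is satisfied if either ring satisfies the
    rules; the reported ring is the satisfied one with the smaller distance
    (or simply the closer ring when neither satisfies).  Residues whose
    groups cannot be built (missing atoms) are skipped with a warning.
    Records are sorted by (satisfied desc, distance asc).
    """
    criteria = criteria or CriteriaConfig()
    cation_names = set(CATION_RESIDUES)
    aromatic_names = set(AROMATIC_RESIDUES)
    if criteria.include_histidine:
        aromatic_names = aromatic_names | {"HIS"}

    cations = []
    for res in frame:
        if res.res_name in cation_names:
            try:
                cations.append((res, cation_group(res)))
            except GroupUndefinedError as exc:
                logger.warning("skipping cation %s: %s", res.key, exc)
    aromatics = []
    for res in frame:
        if res.res_name in aromatic_names:
            try:
                aromatics.append((res, aromatic_rings(res)))
            except GroupUndefinedError as exc:
                logger.warning("skipping aromatic %s: %s", res.key, exc)

    records: list[InteractionRecord] = []
    for cres, cat in cations:
        for ares, rings in aromatics:
            if not _eligible(cres, ares, criteria.min_seq_separation):
                continue
            per_ring = []
            for ring in rings:
                geo = pair_geometry(cat, ring)
                sat, flags = is_cation_pi(geo, criteria)
                per_ring.append((sat, geo.distance_d, ring, geo, flags))
            satisfied_rings = [p for p in per_ring if p[0]]
            pool = satisfied_rings or per_ring
            best = min(pool, key=lambda p: p[1])
            sat, _, ring, geo, flags = best
            records.append(
                InteractionRecord(
                    cation=cat,
                    ring=ring,
                    geometry=geo,
                    satisfied=sat,
                    distance_ok=flags["distance_ok"],
                    angle_ok=flags["angle_ok"],
                )
            )
    records.sort(key=lambda r: (not r.satisfied, r.geometry.distance_d))
    return records
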