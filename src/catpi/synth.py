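"""Seeded synthetic-data generators with known ground truth.

Every input class the analysis consumes can be generated here at desk
scale: residue pairs at an exactly controlled cation-ring distance and
approach angle, conformational ensembles with a designed interaction
occupancy, extended-chain scaffolds for mutation-design tests,
Michaelis-Menten rate tables, first-order inactivation decays, and
sigmoidal thermal-activity profiles.  Each generator is the measurable
inverse of one estimator: at zero noise the estimator recovers the
generator's parameters exactly.

These generators stand in for inputs the real study obtained from
homology modelling and molecular-dynamics simulation; they reproduce the
*geometric and statistical contracts* of those inputs (exact rule
geometry, designed occupancies, known kinetic parameters), not physical
realism.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._build import build_extended_backbone, graft_side_chain, CHI_ATOMS
from .design import DEFAULT_CHI_GRID, _count_clashes
from .geometry import RING_ATOMS
from .structures import Atom, Ensemble, Residue, ResidueKey, StructureFrame

__all__ = [
    "make_pair_fixture",
    "make_ensemble",
    "make_scaffold",
    "make_sequence",
    "make_kinetics",
    "make_decay",
    "make_thermal_profile",
]

_X = np.array([1.0, 0.0, 0.0])
_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])


def _hexagon(radius: float = 1.39) -> np.ndarray:
    ang = np.radians(np.arange(6) * 60.0)
    return np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)


def _mk_res(chain: str, num: int, name3: str, atom_spec: list[tuple[str, str, np.ndarray]],
            serial0: int = 1) -> Residue:
    atoms = [
        Atom(serial=serial0 + i, name=n, element=e, coords=np.asarray(c, float))
        for i, (n, e, c) in enumerate(atom_spec)
    ]
    return Residue(chain_id=chain, seq_number=num, res_name=name3, atoms=atoms)


def _aromatic_residue(aromatic_type: str, num: int) -> Residue:
    """Planar aromatic residue with its six-ring centered at the origin,
    normal along z.  Constructed analytically so ring geometry is exact."""
    hexa = _hexagon()
    if aromatic_type in ("PHE", "TYR"):
        order = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
        spec = [(n, "C", hexa[i]) for i, n in enumerate(order)]
        # CB prolongs the CG vertex outward, in-plane
        cb = hexa[0] * (1.0 + 1.5 / 1.39)
        spec.append(("CB", "C", cb))
        if aromatic_type == "TYR":
            spec.append(("OH", "O", hexa[3] * (1.0 + 1.37 / 1.39)))
        bb_root = cb
    else:  # TRP: six-ring centered at origin, five-ring fused on the
        # CD2-CE2 edge, all in the z=0 plane
        order = ["CD2", "CE2", "CZ2", "CH2", "CZ3", "CE3"]
        spec = [(n, "C", hexa[i]) for i, n in enumerate(order)]
        cd2, ce2 = hexa[0], hexa[1]
        mid = (cd2 + ce2) / 2
        out = mid / np.linalg.norm(mid)  # in-plane, away from six-ring center
        # approximate regular pentagon on the shared edge
        ne1 = mid + out * 1.14 + (ce2 - cd2) * 0.30
        cg = mid + out * 1.14 - (ce2 - cd2) * 0.30
        cd1 = mid + out * 1.90
        spec += [("NE1", "N", ne1), ("CG", "C", cg), ("CD1", "C", cd1)]
        cb = cg + out * 1.5
        spec.append(("CB", "C", cb))
        bb_root = cb
    # stub backbone placed in-plane beyond CB, far from the approach axis
    ca = bb_root + _Y * 1.5 + _X * 0.8
    spec += [
        ("CA", "C", ca),
        ("N", "N", ca + _Y * 1.46),
        ("C", "C", ca + _X * 1.52),
        ("O", "O", ca + _X * 1.52 + _Y * 1.23),
    ]
    return _mk_res("A", num, aromatic_type, spec)


def _cation_residue(cation_type: str, center: np.ndarray, num: int) -> Residue:
    """Lys or Arg residue whose charged-group mass center is exactly at
    ``center``; for Arg the guanidinium plane normal is exactly z."""
    away = center / np.linalg.norm(center) if np.linalg.norm(center) > 1e-9 else _X
    # build the chain receding along `away` so it cannot approach the ring
    if cation_type == "LYS":
        nz = center  # no hydrogens -> mass center is the NZ position
        ce = nz + away * 1.49
        cd = ce + away * 1.02 + _Y * 1.1
        cg = cd + away * 1.02 - _Y * 1.1
        cb = cg + away * 1.02 + _Y * 1.1
        spec = [("NZ", "N", nz), ("CE", "C", ce), ("CD", "C", cd),
                ("CG", "C", cg), ("CB", "C", cb)]
        root = cb
    elif cation_type == "ARG":
        # guanidinium: CZ at the centroid of three symmetric N, so the
        # mass-weighted center of {NE, CZ, NH1, NH2} is CZ itself
        cz = center
        # plane spanned by x and y at height center[2]? No: keep the
        # guanidinium plane parallel to the aromatic plane (normal = z)
        u, v = _X, _Y
        ns = [cz + 1.33 * (np.cos(a) * u + np.sin(a) * v)
              for a in np.radians([90, 210, 330])]
        spec = [("NE", "N", ns[0]), ("CZ", "C", cz),
                ("NH1", "N", ns[1]), ("NH2", "N", ns[2])]
        cd = ns[0] + away * 1.46
        cg = cd + away * 1.02 + _Y * 1.1
        cb = cg + away * 1.02 - _Y * 1.1
        spec += [("CD", "C", cd), ("CG", "C", cg), ("CB", "C", cb)]
        root = cb
    else:
        raise ValueError("cation_type must be LYS or ARG")
    ca = root + away * 1.54
    spec += [
        ("CA", "C", ca),
        ("N", "N", ca + _Y * 1.46),
        ("C", "C", ca + away * 1.52),
        ("O", "O", ca + away * 1.52 + _Y * 1.23),
    ]
    return _mk_res("A", num, cation_type, spec)


def make_pair_fixture(
    cation_type: str,
    aromatic_type: str,
    distance: float,
    theta: float,
) -> StructureFrame:
    """Two-residue frame with exact cation-ring geometry.

    The aromatic six-ring sits in the z=0 plane centered at the origin
    (normal z); the cation mass center is placed at ``distance`` Angstrom
    from the centroid with approach angle ``theta`` degrees off the ring
    normal.  ``pair_geometry`` on the result returns exactly
    (distance, theta) up to floating-point rounding.  Residues are
    numbered 1 and 5 so sequence-separation filters keep the pair.
    """
    if distance <= 0:
        raise ValueError("distance must be positive")
    if not 0 <= theta <= 90:
        raise ValueError("theta must be in [0, 90] degrees")
    th = np.radians(theta)
    center = distance * (np.sin(th) * _X + np.cos(th) * _Z)
    aromatic = _aromatic_residue(aromatic_type.upper(), num=1)
    cation = _cation_residue(cation_type.upper(), center, num=5)
    return StructureFrame(residues=[aromatic, cation])


def make_ensemble(
    base: StructureFrame,
    pair: tuple[ResidueKey | str, ResidueKey | str],
    target_occupancy: float,
    n_frames: int,
    seed: int = 0,
    break_shift: float = 8.0,
) -> Ensemble:
    """Ensemble in which a designed fraction of frames keeps an interaction.

    Exactly ``round(target_occupancy * n_frames)`` frames are copies of
    ``base``; in the remaining frames the second residue of ``pair`` is
    rigidly translated ``break_shift`` Angstrom along +z, taking the pair
    beyond the distance rule.  Frame order is shuffled by ``seed``;
    topology is constant across frames.
    """
    if not 0 <= target_occupancy <= 1:
        raise ValueError("target_occupancy must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("n_frames must be >= 1")
    moved_key = pair[1] if not isinstance(pair[1], str) else ResidueKey.parse(pair[1])
    n_sat = int(np.floor(target_occupancy * n_frames + 0.5))
    flags = np.array([True] * n_sat + [False] * (n_frames - n_sat))
    rng = np.random.default_rng(seed)
    flags = flags[rng.permutation(n_frames)]
    frames = []
    for i, keep in enumerate(flags):
        f = base.copy()
        f.frame_index = i
        if not keep:
            res = f.residue(moved_key)
            for atom in res.atoms:
                atom.coords = atom.coords + _Z * break_shift
        frames.append(f)
    return Ensemble(frames=frames)


def make_scaffold(
    n_residues: int,
    motif_sites: dict[int, str] | None = None,
    seed: int = 0,
    clash_cut: float = 2.0,
) -> StructureFrame:
    """Extended polyalanine scaffold with optional residue-type motifs.

    An ideal-geometry extended backbone carries Ala side chains; residues
    listed in ``motif_sites`` (1-based sequence number -> 3-letter code)
    are rebuilt as the requested type using the first clash-free rotamer
    of the exhaustive chi grid.  Deterministic for a given argument set
    (the seed is part of the generator contract but the construction is
    itself deterministic).
    """
    if n_residues < 5:
        raise ValueError("n_residues must be >= 5")
    motif_sites = motif_sites or {}
    bad = [k for k in motif_sites if not 1 <= k <= n_residues]
    if bad:
        raise ValueError(f"motif sites out of range: {bad}")
    backbone = build_extended_backbone(n_residues)
    residues = []
    for i, bb in enumerate(backbone, start=1):
        base = _mk_res(
            "A", i, "GLY",
            [("N", "N", bb["N"]), ("CA", "C", bb["CA"]),
             ("C", "C", bb["C"]), ("O", "O", bb["O"])],
        )
        residues.append(graft_side_chain(base, motif_sites.get(i, "ALA")))
    frame = StructureFrame(residues=residues)
    # refine motif rotamers: first clash-free chi combination wins
    import itertools

    for num, res_name in sorted(motif_sites.items()):
        key = ResidueKey("A", num)
        n_chi = len(CHI_ATOMS[res_name.upper()])
        if n_chi == 0:
            continue
        site = frame.residue(key)
        for chis in itertools.product(DEFAULT_CHI_GRID, repeat=n_chi):
            candidate = graft_side_chain(site, res_name, chis=chis)
            trial = StructureFrame(
                residues=[candidate if r.key == key else r for r in frame.residues]
            )
            if _count_clashes(trial, key, clash_cut) == 0:
                frame = trial
                break
    return frame


def make_sequence(
    length: int,
    composition: dict[str, int],
    seed: int = 0,
    filler: str = "ACDEGHILMNPQSTV",
) -> str:
    """Random protein sequence with an exact letter composition.

    Positions for the ``composition`` letters are drawn without
    replacement; all other positions are filled from ``filler`` letters
    (which by default excludes every composition-relevant letter of the
    K/R/F/Y/W census alphabet).  Synthetic stand-in: use when a real
    database sequence is unavailable but its composition is known.
    """
    total = sum(composition.values())
    if total > length:
        raise ValueError("composition exceeds sequence length")
    rng = np.random.default_rng(seed)
    seq = rng.choice(list(filler), size=length)
    special = [c for c, n in composition.items() for _ in range(n)]
    pos = rng.choice(length, size=total, replace=False)
    for p, c in zip(pos, special):
        seq[p] = c
    return "".join(seq)


def make_kinetics(
    Km: float,
    Vmax: float,
    S_values: np.ndarray | list[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Michaelis-Menten rate table v = Vmax*S/(Km+S) with multiplicative
    Gaussian noise of coefficient of variation ``noise_cv``."""
    if Km <= 0 or Vmax <= 0:
        raise ValueError("Km and Vmax must be positive")
    S = np.asarray(S_values, dtype=float)
    v = Vmax * S / (Km + S)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        v = v * (1.0 + noise_cv * rng.standard_normal(S.shape))
    return pd.DataFrame({"S": S, "v": v})


def make_decay(
    k_inact: float,
    times: np.ndarray | list[float],
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """First-order inactivation time course, activity = exp(-k t)."""
    if k_inact <= 0:
        raise ValueError("k_inact must be positive")
    t = np.asarray(times, dtype=float)
    a = np.exp(-k_inact * t)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        a = a * (1.0 + noise_cv * rng.standard_normal(t.shape))
    return pd.DataFrame({"time_min": t, "activity": a})


def make_thermal_profile(
    T50: float,
    temps: np.ndarray | list[float],
    steepness: float = 4.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Sigmoidal residual-activity profile with midpoint ``T50`` (Celsius).

    activity(T) = 1 / (1 + exp((T - T50)/steepness)); max-normalization by
    the estimator moves the apparent midpoint slightly when the coldest
    point is below saturation (< ~0.2 C on a 5 C grid with the default
    steepness).
    """
    T = np.asarray(temps, dtype=float)
    if np.any(np.diff(T) <= 0):
        raise ValueError("temps must be strictly increasing")
    a = 1.0 / (1.0 + np.exp((T - T50) / steepness))
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        a = a * (1.0 + noise_cv * rng.standard_normal(T.shape))
    return pd.DataFrame({"temp_C": T, "activity": a})
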