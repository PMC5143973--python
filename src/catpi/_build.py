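"""Internal coordinate builders: ideal side chains and extended backbones.

Ideal residue geometries come from the Chemical Component Dictionary
templates bundled with biotite; side chains are grafted onto a site by
superposing the template N/CA/C onto the site's backbone and chi dihedrals
are set by rotating the downstream atoms about each chi bond.  The peptide
backbone builder places N/CA/C/O with standard bond lengths and angles via
torsion (NeRF-style) construction.
"""

from __future__ import annotations

import numpy as np
from biotite.structure.info import residue as ccd_residue

from .ensembles import kabsch_superpose
from .structures import Atom, Residue

__all__ = [
    "CHI_ATOMS",
    "ideal_side_chain_template",
    "set_chi",
    "measure_chi",
    "graft_side_chain",
    "place_atom_by_zmatrix",
    "build_extended_backbone",
]

# Standard chi dihedral definitions (heavy atoms).
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "ARG": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "LYS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "TYR": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "PHE": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "TRP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "HIS": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "THR": [("N", "CA", "CB", "OG1")],
    "SER": [("N", "CA", "CB", "OG")],
    "ASN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "ASP": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "GLN": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "GLU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "OE1")],
    "ALA": [],
    "GLY": [],
    "VAL": [("N", "CA", "CB", "CG1")],
    "LEU": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "ILE": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "MET": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
            ("CB", "CG", "SD", "CE")],
    "CYS": [("N", "CA", "CB", "SG")],
}

_BACKBONE = ("N", "CA", "C", "O", "OXT")


def ideal_side_chain_template(res_name: str) -> dict[str, np.ndarray]:
    """Heavy-atom coordinates of the CCD ideal conformer, name -> (3,)."""
    arr = ccd_residue(res_name.upper())
    out: dict[str, np.ndarray] = {}
    for name, elem, coord in zip(arr.atom_name, arr.element, arr.coord):
        if elem in ("H", "D") or name == "OXT":
            continue
        out[str(name)] = np.asarray(coord, dtype=float)
    return out


def _bond_graph(coords: dict[str, np.ndarray]) -> dict[str, set[str]]:
    names = list(coords)
    graph: dict[str, set[str]] = {n: set() for n in names}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if np.linalg.norm(coords[a] - coords[b]) < 1.9:
                graph[a].add(b)
                graph[b].add(a)
    return graph


def _downstream(graph: dict[str, set[str]], b: str, c: str) -> set[str]:
    """Atoms reachable from c without crossing the b-c bond (excluding c)."""
    seen = {b, c}
    stack = list(graph[c] - {b})
    out = set()
    while stack:
        x = stack.pop()
        if x in seen:
            continue
        seen.add(x)
        out.add(x)
        stack.extend(graph[x] - seen)
    return out


def _dihedral(p0, p1, p2, p3) -> float:
    """Signed dihedral angle in degrees."""
    b0 = p0 - p1
    b1 = p2 - p1
    b2 = p3 - p2
    b1 = b1 / np.linalg.norm(b1)
    v = b0 - np.dot(b0, b1) * b1
    w = b2 - np.dot(b2, b1) * b1
    x = np.dot(v, w)
    y = np.dot(np.cross(b1, v), w)
    return float(np.degrees(np.arctan2(y, x)))


def _rotation_about_axis(axis: np.ndarray, angle_deg: float) -> np.ndarray:
    axis = axis / np.linalg.norm(axis)
    a = np.radians(angle_deg)
    K = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + np.sin(a) * K + (1 - np.cos(a)) * (K @ K)


def measure_chi(coords: dict[str, np.ndarray], quad: tuple[str, str, str, str]) -> float:
    return _dihedral(*(coords[n] for n in quad))


def set_chi(
    coords: dict[str, np.ndarray],
    quad: tuple[str, str, str, str],
    target_deg: float,
    graph: dict[str, set[str]] | None = None,
) -> dict[str, np.ndarray]:
    """Rotate downstream atoms about the b-c bond to set dihedral a-b-c-d."""
    a, b, c, d = quad
    graph = graph or _bond_graph(coords)
    current = measure_chi(coords, quad)
    delta = target_deg - current
    R = _rotation_about_axis(coords[c] - coords[b], delta)
    pivot = coords[b]
    moved = dict(coords)
    for name in _downstream(graph, b, c):
        moved[name] = R @ (coords[name] - pivot) + pivot
    return moved


def graft_side_chain(
    site: Residue, res_name: str, chis: tuple[float, ...] | None = None
) -> Residue:
    """Replace a residue's side chain with an ideal one of ``res_name``.

    The CCD template is superposed onto the site's N/CA/C; the site keeps
    its own backbone atoms, gains the template's side chain (CB onward),
    and is renamed.  ``chis`` sets the chi dihedrals (one value per
    rotatable chi; missing values keep the template conformation).
    """
    for bb in ("N", "CA", "C"):
        if site.atom(bb) is None:
            raise ValueError(f"site {site.key}: backbone atom {bb} missing")
    template = ideal_side_chain_template(res_name)
    sup = kabsch_superpose(
        np.array([template[n] for n in ("N", "CA", "C")]),
        site.coords_of(["N", "CA", "C"]),
    )
    placed = {n: sup.rotation @ xyz + sup.translation for n, xyz in template.items()}
    # measure/set chi against the true site backbone, not the lsq-fitted copy
    for bb in ("N", "CA", "C"):
        placed[bb] = site.atom(bb).coords.astype(float)
    if chis is not None:
        graph = _bond_graph(placed)
        for quad, value in zip(CHI_ATOMS[res_name.upper()], chis):
            placed = set_chi(placed, quad, value, graph)
    new_atoms: list[Atom] = []
    serial = max((a.serial for a in site.atoms), default=0)
    for atom in site.atoms:  # keep true backbone only
        if atom.name in _BACKBONE and not atom.is_hydrogen:
            new_atoms.append(atom)
    element_of = {n: e for n, e in zip(*_template_names_elements(res_name))}
    for name, xyz in placed.items():
        if name in _BACKBONE:
            continue
        serial += 1
        new_atoms.append(
            Atom(serial=serial, name=str(name), element=str(element_of[name]), coords=xyz)
        )
    return Residue(
        chain_id=site.chain_id,
        seq_number=site.seq_number,
        insertion_code=site.insertion_code,
        res_name=res_name.upper(),
        atoms=new_atoms,
    )


def _template_names_elements(res_name: str) -> tuple[list[str], list[str]]:
    arr = ccd_residue(res_name.upper())
    return list(arr.atom_name), list(arr.element)


# ---------------------------------------------------------------------------
# Backbone construction
# ---------------------------------------------------------------------------

def place_atom_by_zmatrix(
    p1: np.ndarray, p2: np.ndarray, p3: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Place a fourth point at given bond/angle/dihedral from three anchors
    (torsion or NeRF construction): bond to p3, angle at p3 with p2,
    dihedral about p2-p3 relative to p1."""
    b1 = p2 - p1
    b2 = p3 - p2
    b2n = b2 / np.linalg.norm(b2)
    n = np.cross(b1, b2)
    n /= np.linalg.norm(n)
    m = np.cross(n, b2n)
    ang = np.radians(angle_deg)
    dih = np.radians(dihedral_deg)
    d = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return p3 + d[0] * b2n + d[1] * m + d[2] * n


# standard peptide geometry
_N_CA, _CA_C, _C_N, _C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.0, 117.2, 121.7, 120.5


def build_extended_backbone(
    n_residues: int,
    phi: float = -120.0,
    psi: float = 130.0,
    omega: float = 180.0,
) -> list[dict[str, np.ndarray]]:
    """N/CA/C/O coordinates of an extended polypeptide backbone.

    Default (phi, psi) is an extended beta-strand-like conformation; the
    result is a gently twisting chain with ~3.5 A per residue, adequate
    for desk-scale design and enumeration tests (no attempt at a real
    fold's tertiary geometry).
    """
    if n_residues < 1:
        raise ValueError("n_residues must be >= 1")
    res: list[dict[str, np.ndarray]] = []
    first = {
        "N": np.array([0.0, 0.0, 0.0]),
        "CA": np.array([_N_CA, 0.0, 0.0]),
    }
    first["C"] = place_atom_by_zmatrix(
        np.array([0.0, 1.0, 0.0]), first["N"], first["CA"],
        _CA_C, _ANG_N_CA_C, 55.0,
    )
    res.append(first)
    for i in range(1, n_residues):
        prev = res[-1]
        n = place_atom_by_zmatrix(prev["N"], prev["CA"], prev["C"],
                                  _C_N, _ANG_CA_C_N, psi)
        ca = place_atom_by_zmatrix(prev["CA"], prev["C"], n,
                                   _N_CA, _ANG_C_N_CA, omega)
        c = place_atom_by_zmatrix(prev["C"], n, ca,
                                  _CA_C, _ANG_N_CA_C, phi)
        res.append({"N": n, "CA": ca, "C": c})
    for i, r in enumerate(res):
        if i + 1 < len(res):
            next_n = res[i + 1]["N"]
            r["O"] = place_atom_by_zmatrix(next_n, r["CA"], r["C"],
                                           _C_O, _ANG_CA_C_O, 180.0)
        else:
            r["O"] = place_atom_by_zmatrix(r["N"], r["CA"], r["C"],
                                           _C_O, _ANG_CA_C_O, -45.0)
    return res
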