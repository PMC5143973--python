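"""Flexibility and interaction-persistence analysis of conformational ensembles.

Implements least-squares (Kabsch) superposition, per-frame RMSD series,
per-residue RMSF about an iteratively refined mean structure, and
geometric hydrogen-bond detection with per-bond ensemble occupancy.
Default atom selection for superposition/RMSD/RMSF is the alpha carbons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .structures import Atom, Ensemble, Residue, ResidueKey, StructureFrame

logger = logging.getLogger(__name__)

__all__ = [
    "SuperpositionResult",
    "FlexibilityProfile",
    "HBondRecord",
    "LOOP_PRESETS",
    "kabsch_superpose",
    "apply_superposition",
    "rmsd_series",
    "rmsf_profile",
    "detect_hbonds",
    "ca_selection",
]

# Surface-loop windows of the PG63 parallel beta-helix (author numbering),
# shipped as presets for flexibility reports.
LOOP_PRESETS: dict[str, tuple[int, int]] = {
    "T3_loop_1": (90, 106),
    "T3_loop_2": (147, 162),
    "T1_loop": (269, 289),
}

AtomPredicate = Callable[[Residue, Atom], bool]


def ca_selection(residue: Residue, atom: Atom) -> bool:
    return atom.name == "CA"


def heavy_selection(residue: Residue, atom: Atom) -> bool:
    return not atom.is_hydrogen


@dataclass(frozen=True)
class SuperpositionResult:
    rotation: np.ndarray  # 3x3, det = +1
    translation: np.ndarray  # applied after rotation
    rmsd: float


@dataclass
class FlexibilityProfile:
    residue_keys: list[ResidueKey]
    rmsf: np.ndarray  # per residue, Angstrom
    reference: str = "mean-structure"

    def window_mean(self, start: int, stop: int, chain: str | None = None) -> float:
        """Mean RMSF over an inclusive author-numbering window."""
        mask = [
            start <= k.seq_number <= stop and (chain is None or k.chain_id == chain)
            for k in self.residue_keys
        ]
        if not any(mask):
            raise ValueError(f"no residues in window {start}-{stop}")
        return float(self.rmsf[np.asarray(mask)].mean())


@dataclass(frozen=True)
class HBondRecord:
    donor: tuple[ResidueKey, str]  # (residue, atom name)
    acceptor: tuple[ResidueKey, str]
    mean_distance: float  # over frames where the bond is present
    mean_angle: float | None  # D-H...A, None in heavy-atom mode
    occupancy_pct: float


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Optimal least-squares rigid superposition of two point sets.

    Returns the proper rotation R and translation t minimizing the
    (weighted) RMSD of ``R @ mobile + t`` to ``reference``.
    """
    mobile = np.asarray(mobile, dtype=float)
    reference = np.asarray(reference, dtype=float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise ValueError("mobile and reference must be matching (n, 3) arrays")
    n = mobile.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points")
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    wsum = w.sum()
    mob_c = (mobile * w[:, None]).sum(axis=0) / wsum
    ref_c = (reference * w[:, None]).sum(axis=0) / wsum
    mob0 = mobile - mob_c
    ref0 = reference - ref_c
    if np.linalg.matrix_rank(mob0) < 2:
        raise ValueError("degenerate (collinear) configuration")
    # scipy's align_vectors is the Kabsch solution with proper-rotation
    # sign correction built in.
    rot, _ = Rotation.align_vectors(ref0, mob0, weights=w)
    R = rot.as_matrix()
    t = ref_c - R @ mob_c
    moved = mobile @ R.T + t
    rmsd = float(np.sqrt((w[:, None] * (moved - reference) ** 2).sum() / wsum))
    return SuperpositionResult(rotation=R, translation=t, rmsd=rmsd)


def apply_superposition(frame: StructureFrame, sup: SuperpositionResult) -> StructureFrame:
    """Return a copy of the frame with every atom rigidly transformed."""
    out = frame.copy()
    for res in out:
        for atom in res.atoms:
            atom.coords = sup.rotation @ atom.coords + sup.translation
    return out


def _selected_coords(frame: StructureFrame, selection: AtomPredicate) -> np.ndarray:
    rows = [
        a.coords for r in frame for a in r.atoms if selection(r, a)
    ]
    if not rows:
        raise ValueError("atom selection is empty")
    return np.array(rows)


def _selected_keys(frame: StructureFrame, selection: AtomPredicate) -> list[ResidueKey]:
    return [r.key for r in frame for a in r.atoms if selection(r, a)]


def rmsd_series(
    ensemble: Ensemble,
    selection: AtomPredicate = ca_selection,
    reference_frame: int = 0,
) -> np.ndarray:
    """Per-frame RMSD to a reference frame after superposition on the selection."""
    ref = _selected_coords(ensemble[reference_frame], selection)
    out = np.empty(len(ensemble))
    for i, frame in enumerate(ensemble):
        coords = _selected_coords(frame, selection)
        out[i] = kabsch_superpose(coords, ref).rmsd
    return out


def rmsf_profile(
    ensemble: Ensemble,
    selection: AtomPredicate = ca_selection,
    refinement_passes: int = 2,
) -> FlexibilityProfile:
    """Per-residue RMSF about the ensemble mean structure.

    All frames are superposed on an iteratively refined mean structure
    (initially frame 0; ``refinement_passes`` superpose-and-average passes),
    then rmsf_i = sqrt(mean over frames of |x_i - <x_i>|^2) per selected atom.
    """
    if len(ensemble) < 2:
        raise ValueError("RMSF needs at least 2 frames")
    coords = np.array([_selected_coords(f, selection) for f in ensemble])
    mean = coords[0].copy()
    for _ in range(max(1, refinement_passes)):
        aligned = np.empty_like(coords)
        for i in range(coords.shape[0]):
            sup = kabsch_superpose(coords[i], mean)
            aligned[i] = coords[i] @ sup.rotation.T + sup.translation
        mean = aligned.mean(axis=0)
    dev = aligned - mean[None]
    rmsf = np.sqrt((dev**2).sum(axis=2).mean(axis=0))
    return FlexibilityProfile(
        residue_keys=_selected_keys(ensemble[0], selection), rmsf=rmsf
    )


# ---------------------------------------------------------------------------
# Hydrogen bonds
# ---------------------------------------------------------------------------

def _polar_atoms(frame: StructureFrame) -> list[tuple[int, ResidueKey, str, np.ndarray]]:
    out = []
    for ri, res in enumerate(frame):
        for atom in res.atoms:
            if atom.element.upper() in ("N", "O"):
                out.append((ri, res.key, atom.name, atom.coords))
    return out


def _attached_hydrogens(res: Residue, heavy: Atom) -> list[Atom]:
    return [
        a
        for a in res.atoms
        if a.is_hydrogen and np.linalg.norm(a.coords - heavy.coords) < 1.25
    ]


def detect_hbonds(
    ensemble: Ensemble,
    d_cut: float = 3.5,
    angle_cut: float = 120.0,
) -> list[HBondRecord]:
    """Geometric hydrogen bonds with per-bond occupancy over the ensemble.

    A donor-acceptor pair is two N/O atoms of different residues within
    ``d_cut`` Angstrom.  In a structure that carries hydrogens, a donor
    must have an attached hydrogen and the best D-H...A angle must be at
    least ``angle_cut`` degrees; in a hydrogen-free structure (e.g. a
    crystal-derived model) the distance rule alone applies and records
    are undirected (heavy-atom mode).  Records are sorted by occupancy
    desc, then distance.
    """
    n_frames = len(ensemble)
    # pair key -> list of (distance, angle or None) per frame where present
    hits: dict[tuple, list[tuple[float, float | None]]] = {}
    for frame in ensemble:
        polar = _polar_atoms(frame)
        if not polar:
            continue
        frame_has_h = any(a.is_hydrogen for r in frame for a in r.atoms)
        coords = np.array([p[3] for p in polar])
        dmat = cdist(coords, coords)
        n = len(polar)
        for i in range(n):
            for j in range(i + 1, n):
                if polar[i][0] == polar[j][0]:  # same residue
                    continue
                if dmat[i, j] > d_cut:
                    continue
                if not frame_has_h:
                    key = (
                        (polar[i][1], polar[i][2]),
                        (polar[j][1], polar[j][2]),
                    )
                    hits.setdefault(key, []).append((float(dmat[i, j]), None))
                    continue
                # directional: each direction needs an attached hydrogen
                for di, ai in ((i, j), (j, i)):
                    dres = frame.residues[polar[di][0]]
                    datom = dres.atom(polar[di][2])
                    hyds = _attached_hydrogens(dres, datom)
                    if not hyds:
                        continue
                    best = -1.0
                    for h in hyds:
                        v1 = datom.coords - h.coords
                        v2 = coords[ai] - h.coords
                        cosv = np.dot(v1, v2) / (
                            np.linalg.norm(v1) * np.linalg.norm(v2)
                        )
                        best = max(best, np.degrees(np.arccos(np.clip(cosv, -1, 1))))
                    if best < angle_cut:
                        continue
                    key = (
                        (polar[di][1], polar[di][2]),
                        (polar[ai][1], polar[ai][2]),
                    )
                    hits.setdefault(key, []).append((float(dmat[i, j]), best))
    records = []
    for (donor, acceptor), obs in hits.items():
        dists = [o[0] for o in obs]
        angles = [o[1] for o in obs if o[1] is not None]
        records.append(
            HBondRecord(
                donor=donor,
                acceptor=acceptor,
                mean_distance=float(np.mean(dists)),
                mean_angle=float(np.mean(angles)) if angles else None,
                occupancy_pct=100.0 * len(obs) / n_frames,
            )
        )
    records.sort(key=lambda r: (-r.occupancy_pct, r.mean_distance))
    return records
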