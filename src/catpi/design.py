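"""Brute-force in-silico point-mutation design toward new cation-pi contacts.

The design loop mirrors a rational thermostabilization workflow: every
Lys/Arg/Phe/Tyr/Trp residue of the input structure is a *target*; residues
in spatial proximity to a target are candidate sites for substitution to
the complementary partner type (Tyr next to an existing cation, Lys next
to an existing aromatic).  Each candidate side chain is rebuilt with ideal
internal coordinates over an exhaustive chi-angle grid, clash-checked, and
the best clash-free rotamer is tested against the two-rule cation-pi
criterion.  Candidates are finally screened by interaction *occupancy*
over a conformational ensemble (e.g. frames extracted from an MD
trajectory, supplied as a multi-model PDB): the fraction of frames in
which the designed pair satisfies the rules must exceed a threshold
(strictly greater than 50% by default).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.distance import cdist

from ._build import CHI_ATOMS, graft_side_chain
from .geometry import (
    AROMATIC_RESIDUES,
    CATION_RESIDUES,
    CriteriaConfig,
    GroupUndefinedError,
    PairGeometry,
    aromatic_rings,
    cation_group,
    is_cation_pi,
    pair_geometry,
    scan_structure,
)
from .structures import Ensemble, Residue, ResidueKey, StructureFrame

logger = logging.getLogger(__name__)

__all__ = [
    "MutationCandidate",
    "ScreenResult",
    "enumerate_candidates",
    "place_side_chain",
    "assess_candidate",
    "screen_candidates",
    "evaluate_pair_in_frame",
    "DEFAULT_CHI_GRID",
]

TARGET_RESIDUES = CATION_RESIDUES | AROMATIC_RESIDUES
DEFAULT_CHI_GRID = (-60.0, 60.0, 180.0)


@dataclass
class MutationCandidate:
    site: ResidueKey
    wild_res: str
    new_res: str  # "LYS" | "TYR"
    partner: ResidueKey
    partner_res: str
    cb_distance: float  # site-target Cbeta distance used for enumeration
    best_rotamer: tuple[float, ...] | None = None
    placed_geometry: PairGeometry | None = None
    feasible: bool = False
    clash_count: int = 0

    @property
    def label(self) -> str:
        return f"{self.wild_res}{self.site.seq_number}{_ONE.get(self.new_res, 'X')}"


_ONE = {"LYS": "K", "TYR": "Y"}


@dataclass
class ScreenResult:
    candidate: MutationCandidate
    occupancy_pct: float | None
    passes_screen: bool
    n_frames: int = 0


def _anchor_atom(res: Residue) -> np.ndarray | None:
    """Cbeta position used for proximity (Calpha for Gly)."""
    atom = res.atom("CB") or (res.atom("CA") if res.res_name == "GLY" else None)
    return None if atom is None else atom.coords


def enumerate_candidates(
    frame: StructureFrame,
    proximity_cut: float = 8.0,
    exclusions: set[ResidueKey] | None = None,
    criteria: CriteriaConfig | None = None,
) -> list[MutationCandidate]:
    """Enumerate substitution candidates near existing cation-pi targets.

    For every target residue t (Lys/Arg/Phe/Tyr/Trp) and every other
    residue s with Cbeta(s)-Cbeta(t) <= ``proximity_cut`` (Calpha for Gly),
    a candidate s->Tyr (t cationic) or s->Lys (t aromatic) is emitted,
    unless s is excluded, s is already of the requested type, or s already
    forms a satisfied cation-pi interaction with t in the input structure.
    Duplicate (site, new_res) pairs are merged, keeping the nearest partner.
    """
    if proximity_cut <= 0:
        raise ValueError("proximity_cut must be positive")
    exclusions = exclusions or set()
    criteria = criteria or CriteriaConfig()

    already = {
        frozenset((rec.cation.residue_key, rec.ring.residue_key))
        for rec in scan_structure(frame, criteria)
        if rec.satisfied
    }

    best: dict[tuple[ResidueKey, str], MutationCandidate] = {}
    for target in frame:
        if target.res_name not in TARGET_RESIDUES:
            continue
        t_anchor = _anchor_atom(target)
        if t_anchor is None:
            continue
        new_res = "TYR" if target.res_name in CATION_RESIDUES else "LYS"
        for site in frame:
            if site.key == target.key or site.key in exclusions:
                continue
            if site.res_name == new_res:
                continue
            s_anchor = _anchor_atom(site)
            if s_anchor is None:
                continue
            d = float(np.linalg.norm(s_anchor - t_anchor))
            if d > proximity_cut:
                continue
            if frozenset((site.key, target.key)) in already:
                continue
            cand = MutationCandidate(
                site=site.key,
                wild_res=site.res_name,
                new_res=new_res,
                partner=target.key,
                partner_res=target.res_name,
                cb_distance=d,
            )
            key = (site.key, new_res)
            if key not in best or d < best[key].cb_distance:
                best[key] = cand
    return sorted(
        best.values(), key=lambda c: (c.site.chain_id, c.site.seq_number, c.new_res)
    )


def place_side_chain(
    frame: StructureFrame,
    site: ResidueKey | str,
    new_res: str,
    chi_grid: tuple[float, ...] = DEFAULT_CHI_GRID,
) -> list[tuple[tuple[float, ...], StructureFrame]]:
    """Enumerate ideal-geometry rotamers of a substituted side chain.

    Returns ``(rotamer, mutated frame)`` pairs, one per point of the
    exhaustive chi grid (``len(chi_grid) ** n_chi`` placements).  Only the
    mutated residue changes; every other atom keeps bit-identical
    coordinates.
    """
    site_res = frame.residue(site)
    n_chi = len(CHI_ATOMS[new_res.upper()])
    out = []
    for chis in itertools.product(chi_grid, repeat=n_chi):
        mutated = graft_side_chain(site_res, new_res, chis=chis)
        new_frame = StructureFrame(
            residues=[mutated if r.key == site_res.key else r for r in frame.residues],
            frame_index=frame.frame_index,
            label=frame.label,
        )
        out.append((chis, new_frame))
    return out


def _pair_geometry_in_frame(
    frame: StructureFrame, site: ResidueKey, partner: ResidueKey
) -> PairGeometry:
    """Geometry of the (cation, ring) pair formed by two residues.

    Whichever of the two residues is cationic provides the charged group;
    for Trp (or any two-ring aromatic) the closer ring is used.
    """
    a = frame.residue(site)
    b = frame.residue(partner)
    if a.res_name in CATION_RESIDUES:
        cat_res, arom_res = a, b
    elif b.res_name in CATION_RESIDUES:
        cat_res, arom_res = b, a
    else:
        raise GroupUndefinedError(f"neither {site} nor {partner} is cationic")
    cat = cation_group(cat_res)
    geos = [pair_geometry(cat, ring) for ring in aromatic_rings(arom_res)]
    return min(geos, key=lambda g: g.distance_d)


def evaluate_pair_in_frame(
    frame: StructureFrame,
    site: ResidueKey | str,
    partner: ResidueKey | str,
    criteria: CriteriaConfig | None = None,
) -> bool:
    """True when the residue pair satisfies the two-rule criterion."""
    if isinstance(site, str):
        site = ResidueKey.parse(site)
    if isinstance(partner, str):
        partner = ResidueKey.parse(partner)
    geo = _pair_geometry_in_frame(frame, site, partner)
    satisfied, _ = is_cation_pi(geo, criteria)
    return satisfied


def _count_clashes(
    frame: StructureFrame, site: ResidueKey, clash_cut: float
) -> int:
    """New side-chain heavy atoms within clash_cut of any other residue's
    heavy atom."""
    site_res = frame.residue(site)
    side = np.array(
        [
            a.coords
            for a in site_res.heavy_atoms()
            if a.name not in ("N", "CA", "C", "O")
        ]
    )
    if side.size == 0:
        return 0
    others = [
        a.coords
        for r in frame
        if r.key != site
        for a in r.heavy_atoms()
    ]
    if not others:
        return 0
    d = cdist(side, np.array(others))
    return int((d < clash_cut).sum())


def assess_candidate(
    frame: StructureFrame,
    candidate: MutationCandidate,
    criteria: CriteriaConfig | None = None,
    clash_cut: float = 2.5,
    chi_grid: tuple[float, ...] = DEFAULT_CHI_GRID,
) -> MutationCandidate:
    """Place the candidate over the rotamer grid and judge feasibility.

    Among clash-free rotamers the one with the smallest cation-ring
    distance wins; the candidate is feasible when that rotamer satisfies
    the two-rule criterion.  With no clash-free rotamer the candidate is
    infeasible and the minimal clash count is recorded.
    """
    criteria = criteria or CriteriaConfig()
    placements = place_side_chain(frame, candidate.site, candidate.new_res, chi_grid)
    best_free: tuple[float, tuple, PairGeometry] | None = None
    min_clashes = None
    for chis, mut_frame in placements:
        clashes = _count_clashes(mut_frame, candidate.site, clash_cut)
        if min_clashes is None or clashes < min_clashes:
            min_clashes = clashes
        if clashes:
            continue
        try:
            geo = _pair_geometry_in_frame(mut_frame, candidate.site, candidate.partner)
        except GroupUndefinedError as exc:
            logger.warning("candidate %s: %s", candidate.label, exc)
            continue
        if best_free is None or geo.distance_d < best_free[0]:
            best_free = (geo.distance_d, chis, geo)
    out = replace(candidate)
    if best_free is None:
        out.feasible = False
        out.clash_count = int(min_clashes or 0)
        return out
    _, chis, geo = best_free
    out.best_rotamer = chis
    out.placed_geometry = geo
    out.clash_count = 0
    out.feasible = is_cation_pi(geo, criteria)[0]
    return out


def screen_candidates(
    ensemble: Ensemble,
    candidates: list[MutationCandidate],
    criteria: CriteriaConfig | None = None,
    occupancy_threshold: float = 50.0,
) -> list[ScreenResult]:
    """Occupancy screen of candidate pairs over a conformational ensemble.

    For each candidate, the fraction of frames in which its (site,
    partner) pair satisfies the two-rule criterion is the occupancy rate;
    a candidate passes when occupancy is strictly greater than the
    threshold (default 50%).  Frames where the pair cannot be evaluated
    (missing atoms) count as unsatisfied.
    """
    criteria = criteria or CriteriaConfig()
    n = len(ensemble)
    results = []
    for cand in candidates:
        satisfied = 0
        for frame in ensemble:
            try:
                if evaluate_pair_in_frame(frame, cand.site, cand.partner, criteria):
                    satisfied += 1
            except (GroupUndefinedError, KeyError) as exc:
                logger.warning(
                    "candidate %s frame %d uncountable: %s",
                    cand.label, frame.frame_index, exc,
                )
        occ = 100.0 * satisfied / n
        results.append(
            ScreenResult(
                candidate=cand,
                occupancy_pct=occ,
                passes_screen=occ > occupancy_threshold,
                n_frames=n,
            )
        )
    return results
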