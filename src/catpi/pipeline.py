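"""One-call orchestration of the screening analysis.

``run_screen`` chains the stages — interaction scan, candidate
enumeration, rotamer placement/assessment, and (when per-candidate
ensembles are supplied) the occupancy screen — and writes ranked TSV
tables plus a machine-readable JSON report.  Stages degrade gracefully:
without ensembles the ranking rests on single-frame geometry alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .design import assess_candidate, enumerate_candidates, screen_candidates
from .geometry import CriteriaConfig, scan_structure
from .structures import ResidueKey, read_pdb

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_screen", "interactions_frame", "candidates_frame"]


@dataclass
class PipelineConfig:
    criteria: CriteriaConfig = field(default_factory=CriteriaConfig)
    proximity_cut: float = 8.0  # Angstrom, Cbeta-Cbeta
    occupancy_threshold: float = 50.0  # percent, strict >
    clash_cut: float = 2.5  # Angstrom
    hbond_d_cut: float = 3.5
    hbond_angle_cut: float = 120.0
    exclusions: set[str] = field(default_factory=set)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("proximity_cut", "clash_cut", "hbond_d_cut", "hbond_angle_cut"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.occupancy_threshold < 100:
            raise ValueError("occupancy_threshold must be in (0, 100)")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["exclusions"] = sorted(self.exclusions)
        return d


def interactions_frame(records) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "cation_res": f"{r.cation.res_name}:{r.cation.residue_key}",
                "ring_res": f"{r.ring.res_name}:{r.ring.residue_key}",
                "ring_label": r.ring.ring_label,
                "distance_A": round(r.geometry.distance_d, 3),
                "theta_deg": round(r.geometry.theta_axial, 2),
                "dihedral_deg": (
                    round(r.geometry.dihedral_pp, 2)
                    if r.geometry.dihedral_pp is not None
                    else None
                ),
                "satisfied": r.satisfied,
            }
            for r in records
        ]
    )


def candidates_frame(candidates) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "mutation": c.label,
                "site": str(c.site),
                "wild_res": c.wild_res,
                "new_res": c.new_res,
                "partner": str(c.partner),
                "partner_res": c.partner_res,
                "cb_distance_A": round(c.cb_distance, 3),
                "feasible": c.feasible,
                "clash_count": c.clash_count,
                "best_rotamer": (
                    ",".join(f"{x:g}" for x in c.best_rotamer)
                    if c.best_rotamer
                    else None
                ),
                "placed_distance_A": (
                    round(c.placed_geometry.distance_d, 3)
                    if c.placed_geometry
                    else None
                ),
                "placed_theta_deg": (
                    round(c.placed_geometry.theta_axial, 2)
                    if c.placed_geometry
                    else None
                ),
            }
            for c in candidates
        ]
    )


def run_screen(
    config: PipelineConfig,
    structure: str | Path,
    ensembles: dict[str, str | Path] | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Run scan -> design -> assess -> (optional) occupancy screen.

    ``ensembles`` maps a candidate mutation label (e.g. ``"THR10K"`` or a
    site key ``"A:10"``) to a multi-model PDB path holding that mutant's
    conformational ensemble.  Returns the report dict; when ``out_dir``
    is given, also writes interactions.tsv, candidates.tsv, screen.tsv
    and report.json there.
    """
    structure = Path(structure)
    frame = read_pdb(str(structure), model_policy="first")[0]

    records = scan_structure(frame, config.criteria)
    exclusions = {ResidueKey.parse(e) for e in config.exclusions}
    candidates = enumerate_candidates(
        frame, config.proximity_cut, exclusions, config.criteria
    )
    assessed = [
        assess_candidate(frame, c, config.criteria, config.clash_cut)
        for c in candidates
    ]

    screen_rows = []
    warnings: list[str] = []
    if ensembles:
        from .structures import read_pdb as _read

        for cand in assessed:
            key = None
            for k in (cand.label, str(cand.site)):
                if k in ensembles:
                    key = k
                    break
            if key is None:
                continue
            ens = _read(str(ensembles[key]), model_policy="all")
            (result,) = screen_candidates(
                ens, [cand], config.criteria, config.occupancy_threshold
            )
            screen_rows.append(
                {
                    "mutation": cand.label,
                    "site": str(cand.site),
                    "partner": str(cand.partner),
                    "n_frames": result.n_frames,
                    "occupancy_pct": round(result.occupancy_pct, 2),
                    "passes_screen": result.passes_screen,
                }
            )
    else:
        warnings.append("no ensembles supplied; occupancy screen skipped")

    inter_df = interactions_frame(records)
    cand_df = candidates_frame(assessed)
    screen_df = pd.DataFrame(
        screen_rows,
        columns=[
            "mutation", "site", "partner", "n_frames",
            "occupancy_pct", "passes_screen",
        ],
    )

    report = {
        "tool": "catpi",
        "version": __version__,
        "config": config.to_dict(),
        "structure": structure.name,
        "n_interactions_satisfied": int(inter_df["satisfied"].sum())
        if len(inter_df)
        else 0,
        "n_candidates": len(cand_df),
        "n_feasible": int(cand_df["feasible"].sum()) if len(cand_df) else 0,
        "screen": screen_rows,
        "pass_set": sorted(
            r["mutation"] for r in screen_rows if r["passes_screen"]
        ),
        "warnings": warnings,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        inter_df.to_csv(out / "interactions.tsv", sep="\t", index=False)
        cand_df.to_csv(out / "candidates.tsv", sep="\t", index=False)
        screen_df.to_csv(out / "screen.tsv", sep="\t", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
    return report
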