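"""Minimal structural data model with PDB I/O.

An :class:`Ensemble` is an ordered list of :class:`StructureFrame` objects
sharing one topology (same residues, same atom names in the same order) —
the in-memory form of a multi-model PDB file, which is the only trajectory
format this package consumes.  Parsing and writing are delegated to gemmi;
this module adds the altloc/HETATM policy and the frame/topology contract.
"""

from __future__ import annotations

import copy
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple, Sequence

import gemmi
import numpy as np
from Bio.SeqUtils import seq1

__all__ = [
    "Atom",
    "Residue",
    "ResidueKey",
    "StructureFrame",
    "Ensemble",
    "PDBParseError",
    "EmptyStructureError",
    "TopologyError",
    "read_pdb",
    "write_pdb",
    "extract_sequence",
    "write_fasta",
    "residue_census",
    "STANDARD_AA",
]

STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

_WATER = {"HOH", "WAT", "H2O", "DOD"}


class PDBParseError(ValueError):
    """Raised when a PDB file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a file contains no protein ATOM records."""


class TopologyError(ValueError):
    """Raised when frames of an ensemble disagree in residue/atom topology."""


class ResidueKey(NamedTuple):
    """Identity of a residue: chain, author sequence number, insertion code."""

    chain_id: str
    seq_number: int
    insertion_code: str = ""

    def __str__(self) -> str:  # e.g. "A:58" or "A:58A"
        return f"{self.chain_id}:{self.seq_number}{self.insertion_code}"

    @classmethod
    def parse(cls, text: str) -> "ResidueKey":
        chain, _, rest = text.partition(":")
        num = "".join(c for c in rest if c.isdigit() or c == "-")
        icode = rest[len(num):]
        return cls(chain, int(num), icode)


@dataclass
class Atom:
    serial: int
    name: str
    element: str
    coords: np.ndarray  # (3,) float64, Angstrom
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class Residue:
    chain_id: str
    seq_number: int
    res_name: str
    insertion_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.seq_number, self.insertion_code)

    @property
    def is_standard(self) -> bool:
        return self.res_name in STANDARD_AA

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names: Iterable[str]) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if not a.is_hydrogen]

    def coords_of(self, names: Sequence[str]) -> np.ndarray:
        out = []
        for n in names:
            a = self.atom(n)
            if a is None:
                raise KeyError(f"atom {n} missing from {self.res_name} {self.key}")
            out.append(a.coords)
        return np.array(out)


@dataclass
class StructureFrame:
    residues: list[Residue] = field(default_factory=list)
    frame_index: int = 0
    label: str = ""

    def __iter__(self) -> Iterator[Residue]:
        return iter(self.residues)

    def __len__(self) -> int:
        return len(self.residues)

    def chains(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.residues:
            seen.setdefault(r.chain_id, None)
        return list(seen)

    def residue(self, key: ResidueKey | str) -> Residue:
        if isinstance(key, str):
            key = ResidueKey.parse(key)
        for r in self.residues:
            if r.key == key:
                return r
        raise KeyError(f"residue {key} not found")

    def topology_signature(self) -> tuple:
        return tuple(
            (r.chain_id, r.seq_number, r.insertion_code, r.res_name,
             tuple(a.name for a in r.atoms))
            for r in self.residues
        )

    def copy(self) -> "StructureFrame":
        return copy.deepcopy(self)

    def all_atom_coords(self, heavy_only: bool = False) -> np.ndarray:
        rows = []
        for r in self.residues:
            for a in r.atoms:
                if heavy_only and a.is_hydrogen:
                    continue
                rows.append(a.coords)
        return np.array(rows)


@dataclass
class Ensemble:
    frames: list[StructureFrame]
    time_step: float | None = None  # ps per frame, if known

    def __post_init__(self) -> None:
        if not self.frames:
            raise TopologyError("an Ensemble needs at least one frame")
        ref = self.frames[0].topology_signature()
        for i, f in enumerate(self.frames[1:], start=1):
            if f.topology_signature() != ref:
                raise TopologyError(
                    f"frame {i} topology differs from frame 0; "
                    "all frames of an ensemble must share one topology"
                )

    def __len__(self) -> int:
        return len(self.frames)

    def __iter__(self) -> Iterator[StructureFrame]:
        return iter(self.frames)

    def __getitem__(self, i: int) -> StructureFrame:
        return self.frames[i]


# ---------------------------------------------------------------------------
# PDB reading / writing (gemmi-backed)
# ---------------------------------------------------------------------------

def _resolve_altlocs(res: gemmi.Residue) -> list[gemmi.Atom]:
    """Keep one conformer per atom name: highest occupancy, ties by altloc
    ('A' first, then lexicographic; blank altloc sorts last among ties)."""
    by_name: dict[str, list[gemmi.Atom]] = {}
    for a in res:
        by_name.setdefault(a.name, []).append(a)
    chosen = []
    for name, group in by_name.items():
        if len(group) == 1:
            chosen.append(group[0])
            continue
        group.sort(key=lambda a: (-a.occ, a.altloc != "A", a.altloc or "~"))
        chosen.append(group[0])
    chosen.sort(key=lambda a: a.serial)
    return chosen


def read_pdb(
    path: str,
    model_policy: str = "first",
    include_hetero: bool = False,
    include_waters: bool = False,
) -> Ensemble:
    """Read a (possibly multi-model) PDB file into an :class:`Ensemble`.

    Parameters
    ----------
    path:
        PDB file path.
    model_policy:
        ``"first"`` keeps only the first MODEL; ``"all"`` turns every MODEL
        into a frame.
    include_hetero, include_waters:
        HETATM residues and waters are excluded by default.

    Altloc groups are resolved to the highest-occupancy conformer
    (ties: altloc 'A', then lexicographic).
    """
    if model_policy not in ("first", "all"):
        raise ValueError("model_policy must be 'first' or 'all'")
    try:
        st = gemmi.read_pdb(path)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(f"cannot parse {path}: {exc}") from exc

    frames: list[StructureFrame] = []
    models = list(st) if model_policy == "all" else [st[0]]
    for mi, model in enumerate(models):
        residues: list[Residue] = []
        for chain in model:
            for gres in chain:
                het = gres.het_flag == "H"
                water = gres.name in _WATER or gres.is_water()
                if water and not include_waters:
                    continue
                if het and not water and not include_hetero:
                    continue
                atoms = [
                    Atom(
                        serial=a.serial,
                        name=a.name,
                        element=a.element.name,
                        coords=np.array([a.pos.x, a.pos.y, a.pos.z]),
                        altloc=a.altloc or "",
                        occupancy=a.occ,
                    )
                    for a in _resolve_altlocs(gres)
                ]
                residues.append(
                    Residue(
                        chain_id=chain.name,
                        seq_number=gres.seqid.num,
                        insertion_code=(gres.seqid.icode or "").strip(),
                        res_name=gres.name,
                        atoms=atoms,
                    )
                )
        if residues:
            frames.append(StructureFrame(residues=residues, frame_index=mi))
    if not frames or not any(len(f) for f in frames):
        raise EmptyStructureError(f"{path}: no protein ATOM records found")
    return Ensemble(frames=frames)


def write_pdb(ensemble: Ensemble | StructureFrame, path: str) -> None:
    """Write an ensemble as a multi-model PDB (single frame: no MODEL records).

    Coordinates are written to 3 decimals, so read/write round-trips are
    identity up to 1e-3 Angstrom.
    """
    if isinstance(ensemble, StructureFrame):
        ensemble = Ensemble(frames=[ensemble])
    st = gemmi.Structure()
    st.name = "catpi"
    for fi, frame in enumerate(ensemble.frames):
        model = gemmi.Model(fi + 1)
        chains: dict[str, gemmi.Chain] = {}
        serial = 1
        for res in frame.residues:
            ch = chains.get(res.chain_id)
            if ch is None:
                ch = gemmi.Chain(res.chain_id)
                chains[res.chain_id] = ch
            gres = gemmi.Residue()
            gres.name = res.res_name
            gres.seqid = gemmi.SeqId(res.seq_number, res.insertion_code or " ")
            gres.het_flag = "A" if res.is_standard else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.altloc = atom.altloc or "\0"
                ga.serial = serial
                serial += 1
                gres.add_atom(ga)
            ch.add_residue(gres)
        for ch in chains.values():
            model.add_chain(ch)
        st.add_model(model)
    st.setup_entities()
    doc_opts = gemmi.PdbWriteOptions(minimal=True, numbered_ter=False)
    st.write_pdb(path, doc_opts)


# ---------------------------------------------------------------------------
# Sequence utilities
# ---------------------------------------------------------------------------

def extract_sequence(frame: StructureFrame, chain_id: str | None = None) -> str:
    """One-letter sequence of a chain in residue order.

    Non-standard residues map to ``'X'``.  ``chain_id=None`` selects the
    first protein chain in the file.
    """
    chains = frame.chains()
    if not chains:
        raise KeyError("frame has no chains")
    if chain_id is None:
        chain_id = chains[0]
    if chain_id not in chains:
        raise KeyError(f"chain {chain_id!r} not present (have {chains})")
    letters = []
    for r in frame.residues:
        if r.chain_id != chain_id:
            continue
        letters.append(seq1(r.res_name) if r.is_standard else "X")
    return "".join(letters)


def write_fasta(sequence: str, path: str, header: str = "sequence") -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    seqio_write([SeqRecord(Seq(sequence), id=header, description="")], path, "fasta")


def residue_census(
    sequence: str, alphabet: Iterable[str] = ("K", "R", "F", "Y", "W")
) -> tuple[dict[str, int], int]:
    """Count occurrences of each requested one-letter code in a sequence.

    Returns ``(counts, total)`` where total sums over the alphabet only.
    Letters in the sequence outside the one-letter amino-acid alphabet are
    ignored with a warning.
    """
    if not sequence:
        raise ValueError("sequence is empty")
    alphabet = list(dict.fromkeys(alphabet))
    known = set("ACDEFGHIKLMNPQRSTVWYX")
    unknown = set(sequence.upper()) - known
    if unknown:
        warnings.warn(f"ignoring unknown letters in sequence: {sorted(unknown)}")
    counter = Counter(c for c in sequence.upper() if c in known)
    counts = {a: counter.get(a, 0) for a in alphabet}
    return counts, sum(counts.values())
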