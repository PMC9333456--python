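"""Coordinate-model container and PDB/mmCIF input-output.

The in-memory model is deliberately small: ordered chains of residues with
author (1-based) numbering and a per-atom coordinate array.  All reported
residue ranges everywhere in the package are closed intervals ``[first,
last]`` in this numbering.  Parsing and serialisation are delegated to
gemmi; only the conversion into the package's containers lives here.

Altloc policy: the highest-occupancy conformer is kept, ties resolved in
favour of altloc ``A``.  HETATM records are excluded from the polymer.
Nonstandard residues map to ``'X'``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

from .errors import EmptyStructureError, RangeError, StructureFormatError

logger = logging.getLogger(__name__)

BACKBONE = ("N", "CA", "C", "O")

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
_ONE_TO_THREE = {v: k for k, v in _THREE_TO_ONE.items()}


@dataclass
class Atom:
    """A single atom: label, element symbol and position in Angstrom."""

    name: str
    element: str
    position: np.ndarray

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")


@dataclass
class Residue:
    """One residue with author numbering and a name-keyed atom map."""

    seq_id: int
    aa: str
    insertion_code: str = ""
    atoms: dict[str, Atom] = field(default_factory=dict)

    @property
    def has_backbone(self) -> bool:
        return all(name in self.atoms for name in BACKBONE)

    def pos(self, name: str) -> np.ndarray:
        return self.atoms[name].position

    @property
    def ca(self) -> np.ndarray | None:
        atom = self.atoms.get("CA")
        return None if atom is None else atom.position

    def key(self) -> tuple[int, str]:
        return (self.seq_id, self.insertion_code)

    def copy(self) -> "Residue":
        return Residue(
            self.seq_id,
            self.aa,
            self.insertion_code,
            {n: Atom(a.name, a.element, a.position.copy()) for n, a in self.atoms.items()},
        )


@dataclass
class Structure:
    """Ordered chains of residues; the substrate of every structural stage."""

    id: str = ""
    chains: dict[str, list[Residue]] = field(default_factory=dict)

    def add_residue(self, chain_id: str, residue: Residue) -> None:
        chain = self.chains.setdefault(chain_id, [])
        if chain and residue.key() <= chain[-1].key():
            raise ValueError(
                f"chain {chain_id}: residue {residue.key()} breaks strictly "
                f"increasing (seq_id, insertion_code) order after {chain[-1].key()}"
            )
        chain.append(residue)

    def sequence(self, chain_id: str) -> str:
        """One-letter sequence of a chain in residue order ('X' for unknowns)."""
        return "".join(r.aa for r in self.chains[chain_id])

    def extract_region(self, chain_id: str, first: int, last: int) -> "Structure":
        """Residues of the closed interval ``[first, last]`` as a new Structure."""
        if first > last:
            raise RangeError(f"first ({first}) > last ({last})")
        chain = self.chains[chain_id]
        picked = [r.copy() for r in chain if first <= r.seq_id <= last]
        if not picked:
            raise RangeError(
                f"range [{first}, {last}] does not intersect chain {chain_id}"
            )
        out = Structure(id=f"{self.id}_{first}-{last}")
        out.chains[chain_id] = picked
        return out

    def copy(self) -> "Structure":
        out = Structure(id=self.id)
        for cid, chain in self.chains.items():
            out.chains[cid] = [r.copy() for r in chain]
        return out

    def n_residues(self) -> int:
        return sum(len(c) for c in self.chains.values())

    def coords(self, chain_id: str, atom: str = "CA") -> np.ndarray:
        """Stacked positions of one atom type over a chain (residues lacking it skipped)."""
        return np.array(
            [r.pos(atom) for r in self.chains[chain_id] if atom in r.atoms]
        )

    def transform(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Rigidly moved copy: x -> R @ x + t."""
        out = self.copy()
        for chain in out.chains.values():
            for res in chain:
                for atom in res.atoms.values():
                    atom.position = rotation @ atom.position + translation
        return out


def aa_three_to_one(name: str) -> str:
    return _THREE_TO_ONE.get(name.upper(), "X")


def aa_one_to_three(letter: str) -> str:
    return _ONE_TO_THREE.get(letter.upper(), "UNK")


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved in favour of altloc 'A'
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "A"))[0]


def read_structure(path: str | Path, dialect: str | None = None) -> Structure:
    """Read a PDB or mmCIF file into a :class:`Structure`.

    ``dialect`` is ``'pdb'`` or ``'mmcif'``; when omitted it is inferred from
    the file suffix (``.cif`` -> mmCIF, anything else -> PDB).
    """
    path = Path(path)
    if dialect is None:
        dialect = "mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb"
    try:
        if dialect == "pdb":
            st = gemmi.read_pdb(str(path))
        elif dialect == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            raise StructureFormatError(f"unknown dialect: {dialect!r}")
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: {exc}") from exc

    out = Structure(id=st.name or path.stem)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models")
    model = st[0]
    for chain in model:
        for res in chain:
            if res.het_flag == "H" or res.name == "HOH":
                continue
            by_name: dict[str, list[gemmi.Atom]] = {}
            for atom in res:
                by_name.setdefault(atom.name, []).append(atom)
            residue = Residue(
                seq_id=res.seqid.num,
                aa=aa_three_to_one(res.name),
                insertion_code=(res.seqid.icode or "").strip(),
            )
            for name, group in by_name.items():
                atom = _pick_altloc(group)
                residue.atoms[name] = Atom(
                    name=name,
                    element=atom.element.name,
                    position=np.array([atom.pos.x, atom.pos.y, atom.pos.z]),
                )
            try:
                out.add_residue(chain.name, residue)
            except ValueError as exc:
                raise StructureFormatError(f"{path}: {exc}") from exc
    if out.n_residues() == 0:
        raise EmptyStructureError(f"{path}: no polymer residues")
    return out


def write_structure(s: Structure, path: str | Path) -> None:
    """Write a Structure as a PDB file (TER between chains, END at the end)."""
    if s.n_residues() == 0:
        raise EmptyStructureError("refusing to write an empty structure")
    st = gemmi.Structure()
    st.name = s.id or "model"
    model = gemmi.Model("1")
    for cid, chain in s.chains.items():
        gchain = gemmi.Chain(cid)
        for res in chain:
            gres = gemmi.Residue()
            gres.name = aa_one_to_three(res.aa)
            gres.seqid = gemmi.SeqId(res.seq_id, res.insertion_code or " ")
            gres.het_flag = "A"
            for atom in res.atoms.values():
                gatom = gemmi.Atom()
                gatom.name = atom.name
                gatom.element = gemmi.Element(atom.element)
                gatom.pos = gemmi.Position(*atom.position)
                gatom.occ = 1.0
                gres.add_atom(gatom)
            gchain.add_residue(gres)
        model.add_chain(gchain)
    st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (OSError, RuntimeError) as exc:
        raise OSError(f"cannot write {path}: {exc}") from exc
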