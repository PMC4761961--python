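"""Intermolecular H-bond and hydrophobic contact counting for protein-RNA complexes.

Works from heavy-atom coordinates only (docked models and most crystal
structures carry no hydrogens), in the style of Ligplot/Nucplot:

* a hydrogen bond is a donor/acceptor heavy-atom pair — one atom typed on the
  protein side, one on the nucleotide side — at a distance within
  [d_min, d_max], default [2.4, 3.35] A; both donor->acceptor directions are
  tried and each unordered atom pair is reported once;
* a hydrophobic contact is a pair of apolar carbons (per the packaged typing
  tables) within d_max, default 3.9 A.

Typing tables (donors, acceptors, apolar carbons for the 20 amino acids and
4 ribonucleotides) ship as an editable JSON data file.  Atoms are classed as
protein or nucleic by residue name, so swapping the two argument lists
changes labeling only, never counts.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from ._resources import data_path

__all__ = [
    "AtomRecord",
    "HBond",
    "HydrophobicContact",
    "ContactReport",
    "parse_structure",
    "find_hbonds",
    "find_hydrophobic",
    "contact_report",
]

_AA3 = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS ILE LEU LYS MET PHE PRO SER THR TRP TYR VAL".split()
)
_NUC = {"A": "A", "C": "C", "G": "G", "U": "U", "DA": "A", "DC": "C", "DG": "G", "DT": "U"}
_WATERS = frozenset({"HOH", "WAT", "DOD", "H2O"})

DEFAULT_HBOND_DMAX = 3.35
DEFAULT_HBOND_DMIN = 2.4
DEFAULT_HYDROPHOBIC_DMAX = 3.9


@dataclass(frozen=True)
class AtomRecord:
    chain: str
    residue_name: str
    residue_number: int
    atom_name: str
    element: str
    x: float
    y: float
    z: float

    def __post_init__(self) -> None:
        for v in (self.x, self.y, self.z):
            if not np.isfinite(v):
                raise ValueError(f"non-finite coordinate in atom {self.atom_name}")

    @property
    def xyz(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def is_protein(self) -> bool:
        return self.residue_name in _AA3

    @property
    def is_nucleic(self) -> bool:
        return self.residue_name in _NUC


@dataclass(frozen=True)
class HBond:
    donor: AtomRecord
    acceptor: AtomRecord
    distance: float


@dataclass(frozen=True)
class HydrophobicContact:
    atom_a: AtomRecord
    atom_b: AtomRecord
    distance: float


@dataclass(frozen=True)
class ContactReport:
    hbonds: tuple[HBond, ...]
    hydrophobic: tuple[HydrophobicContact, ...]

    @property
    def n_hbonds(self) -> int:
        return len(self.hbonds)

    @property
    def n_hydrophobic(self) -> int:
        return len(self.hydrophobic)

    def to_dict(self) -> dict:
        return {
            "n_hbonds": self.n_hbonds,
            "n_hydrophobic": self.n_hydrophobic,
            "hbonds": [
                {
                    "donor": _atom_label(hb.donor),
                    "acceptor": _atom_label(hb.acceptor),
                    "distance_A": round(hb.distance, 3),
                }
                for hb in self.hbonds
            ],
            "hydrophobic": [
                {
                    "atom_a": _atom_label(hc.atom_a),
                    "atom_b": _atom_label(hc.atom_b),
                    "distance_A": round(hc.distance, 3),
                }
                for hc in self.hydrophobic
            ],
        }

    def write_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("kind\tatom_1\tatom_2\tdistance_A\n")
            for hb in self.hbonds:
                fh.write(
                    f"hbond\t{_atom_label(hb.donor)}\t{_atom_label(hb.acceptor)}"
                    f"\t{hb.distance:.3f}\n"
                )
            for hc in self.hydrophobic:
                fh.write(
                    f"hydrophobic\t{_atom_label(hc.atom_a)}\t{_atom_label(hc.atom_b)}"
                    f"\t{hc.distance:.3f}\n"
                )


def _atom_label(a: AtomRecord) -> str:
    return f"{a.chain}/{a.residue_name}{a.residue_number}/{a.atom_name}"


# ---------------------------------------------------------------------------
# PDB parsing


def parse_structure(pdb_text: str, keep_waters: bool = False) -> list[AtomRecord]:
    """AtomRecords from fixed-column PDB text (ATOM/HETATM lines).

    Alternate locations are resolved to the highest-occupancy conformer
    (ties: altloc 'A'); waters are excluded unless ``keep_waters``.
    Malformed fixed columns are rejected with the offending line number.
    """
    import gemmi

    _precheck_columns(pdb_text)
    structure = gemmi.read_pdb_string(pdb_text)
    structure.setup_entities()
    records: list[AtomRecord] = []
    model = structure[0]
    for chain in model:
        for residue in chain:
            resname = residue.name.strip()
            if resname in _WATERS and not keep_waters:
                continue
            # altloc resolution: best occupancy, ties to the 'A' conformer
            by_name: dict[str, list] = {}
            for atom in residue:
                by_name.setdefault(atom.name, []).append(atom)
            for name, atoms in by_name.items():
                atom = min(atoms, key=lambda a: (-a.occ, a.altloc or "A"))
                records.append(
                    AtomRecord(
                        chain=chain.name,
                        residue_name=resname,
                        residue_number=residue.seqid.num,
                        atom_name=name,
                        element=atom.element.name.upper(),
                        x=atom.pos.x,
                        y=atom.pos.y,
                        z=atom.pos.z,
                    )
                )
    return records


def _precheck_columns(pdb_text: str) -> None:
    for lineno, line in enumerate(pdb_text.splitlines(), start=1):
        if not line.startswith(("ATOM", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(f"line {lineno}: ATOM/HETATM record shorter than 54 columns")
        for lo, hi, what in ((30, 38, "x"), (38, 46, "y"), (46, 54, "z")):
            try:
                float(line[lo:hi])
            except ValueError:
                raise ValueError(
                    f"line {lineno}: malformed {what} coordinate field {line[lo:hi]!r}"
                ) from None


# ---------------------------------------------------------------------------
# typing tables


def _load_typing(path: str | Path | None = None) -> dict:
    with open(data_path("contact_typing.json") if path is None else path) as fh:
        return json.load(fh)


_TYPING = None


def _typing() -> dict:
    global _TYPING
    if _TYPING is None:
        _TYPING = _load_typing()
    return _TYPING


def _protein_role(a: AtomRecord, tables: dict) -> tuple[bool, bool]:
    """(is_donor, is_acceptor) for a protein atom."""
    p = tables["protein"]
    donor = a.atom_name in p["backbone_donors"] or a.atom_name in p["sidechain_donors"].get(
        a.residue_name, ()
    )
    if a.residue_name == "PRO" and a.atom_name == "N":
        donor = False  # proline backbone N carries no H
    acceptor = a.atom_name in p["backbone_acceptors"] or a.atom_name in p[
        "sidechain_acceptors"
    ].get(a.residue_name, ())
    return donor, acceptor


def _nucleotide_role(a: AtomRecord, tables: dict) -> tuple[bool, bool]:
    base = _NUC.get(a.residue_name)
    if base is None:
        return False, False
    n = tables["nucleotide"]
    return (
        a.atom_name in n["donors"].get(base, ()),
        a.atom_name in n["acceptors"].get(base, ()),
    )


def _split_sides(
    atoms_a: Sequence[AtomRecord], atoms_b: Sequence[AtomRecord]
) -> tuple[list[AtomRecord], list[AtomRecord]]:
    """Class atoms by residue identity so argument order is irrelevant."""
    if not atoms_a or not atoms_b:
        raise ValueError("both atom lists must be non-empty")
    protein = [a for a in (*atoms_a, *atoms_b) if a.is_protein]
    nucleic = [a for a in (*atoms_a, *atoms_b) if a.is_nucleic]
    return protein, nucleic


def _cross_pairs(
    prot: Sequence[AtomRecord], nuc: Sequence[AtomRecord], d_max: float
) -> Iterable[tuple[AtomRecord, AtomRecord, float]]:
    if not prot or not nuc:
        return
    pxyz = np.array([a.xyz for a in prot])
    nxyz = np.array([a.xyz for a in nuc])
    tree = cKDTree(nxyz)
    for i, neighbors in enumerate(tree.query_ball_point(pxyz, d_max)):
        for j in neighbors:
            d = float(np.linalg.norm(pxyz[i] - nxyz[j]))
            yield prot[i], nuc[j], d


def find_hbonds(
    protein_atoms: Sequence[AtomRecord],
    rna_atoms: Sequence[AtomRecord],
    d_max: float = DEFAULT_HBOND_DMAX,
    d_min: float = DEFAULT_HBOND_DMIN,
    typing_tables: dict | None = None,
) -> list[HBond]:
    """Intermolecular donor/acceptor heavy-atom pairs within [d_min, d_max]."""
    if d_min < 0 or d_max <= 0 or d_max < d_min:
        raise ValueError("need 0 <= d_min <= d_max")
    tables = _typing() if typing_tables is None else typing_tables
    prot, nuc = _split_sides(protein_atoms, rna_atoms)
    out = []
    for pa, na, d in _cross_pairs(prot, nuc, d_max):
        if d < d_min:
            continue
        p_don, p_acc = _protein_role(pa, tables)
        n_don, n_acc = _nucleotide_role(na, tables)
        if p_don and n_acc:
            out.append(HBond(donor=pa, acceptor=na, distance=d))
        elif p_acc and n_don:
            out.append(HBond(donor=na, acceptor=pa, distance=d))
    out.sort(key=lambda hb: (hb.distance, _atom_label(hb.donor), _atom_label(hb.acceptor)))
    return out


def find_hydrophobic(
    protein_atoms: Sequence[AtomRecord],
    rna_atoms: Sequence[AtomRecord],
    d_max: float = DEFAULT_HYDROPHOBIC_DMAX,
    typing_tables: dict | None = None,
) -> list[HydrophobicContact]:
    """Intermolecular apolar-carbon pairs at distance <= d_max."""
    if d_max <= 0:
        raise ValueError("d_max must be positive")
    tables = _typing() if typing_tables is None else typing_tables
    prot, nuc = _split_sides(protein_atoms, rna_atoms)
    p_apolar = tables["protein"]["apolar_carbons"]
    n_apolar = tables["nucleotide"]["apolar_carbons"]
    prot = [a for a in prot if a.atom_name in p_apolar.get(a.residue_name, ())]
    nuc = [a for a in nuc if a.atom_name in n_apolar.get(_NUC[a.residue_name], ())]
    out = [
        HydrophobicContact(atom_a=pa, atom_b=na, distance=d)
        for pa, na, d in _cross_pairs(prot, nuc, d_max)
    ]
    out.sort(key=lambda hc: (hc.distance, _atom_label(hc.atom_a), _atom_label(hc.atom_b)))
    return out


def contact_report(
    protein_atoms: Sequence[AtomRecord],
    rna_atoms: Sequence[AtomRecord],
    dmax_hbond: float = DEFAULT_HBOND_DMAX,
    dmin_hbond: float = DEFAULT_HBOND_DMIN,
    dmax_hydrophobic: float = DEFAULT_HYDROPHOBIC_DMAX,
) -> ContactReport:
    return ContactReport(
        hbonds=tuple(find_hbonds(protein_atoms, rna_atoms, dmax_hbond, dmin_hbond)),
        hydrophobic=tuple(find_hydrophobic(protein_atoms, rna_atoms, dmax_hydrophobic)),
    )
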