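"""Reading and writing ligand SDF / pocket PDB structures.

Ligands are parsed with RDKit (sanitization deferred so that toy and
nonstandard molecules survive), pockets with Biopython's PDB parser.  The
in-memory records are deliberately plain: element symbols, coordinates in
Angstrom, bond orders, residue identities — everything downstream
featurization needs and nothing more.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import EmptyMoleculeError, EmptyPocketError, ParseError

logger = logging.getLogger(__name__)

# Bond order vocabulary shared with the complex-graph module.
BOND_ORDERS = ("single", "double", "triple", "aromatic")

#: Standard 20 amino acids, three-letter -> one-letter.
THREE_TO_ONE: Dict[str, str] = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}

#: Nonstandard residues retained with a fixed mapping; anything else
#: (and all waters) is dropped with a logged warning.
NONSTANDARD_MAP: Dict[str, str] = {
    "MSE": "M",   # selenomethionine
    "SEC": "C",   # selenocysteine (U), folded onto C for the 20-letter alphabet
}

_WATER_NAMES = {"HOH", "WAT", "DOD"}


@dataclass
class LigandAtom:
    element: str
    coords: np.ndarray  # shape (3,), Angstrom
    formal_charge: int = 0


@dataclass
class Bond:
    i: int
    j: int
    order: str  # one of BOND_ORDERS


@dataclass
class Ligand:
    atoms: List[LigandAtom]
    bonds: List[Bond]
    name: str = "ligand"
    smiles: Optional[str] = None

    def __post_init__(self):
        if not self.atoms:
            raise EmptyMoleculeError(f"ligand {self.name!r} has no atoms")
        n = len(self.atoms)
        for b in self.bonds:
            if b.i == b.j or not (0 <= b.i < n and 0 <= b.j < n):
                raise ParseError(
                    f"ligand {self.name!r}: bond ({b.i},{b.j}) has invalid "
                    f"endpoints for {n} atoms")
            if b.order not in BOND_ORDERS:
                raise ParseError(f"unknown bond order {b.order!r}")
        for a in self.atoms:
            a.coords = np.asarray(a.coords, dtype=float)
            if not np.all(np.isfinite(a.coords)):
                raise ParseError(f"ligand {self.name!r}: non-finite coordinates")

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def elements(self) -> List[str]:
        return [a.element for a in self.atoms]


@dataclass
class Residue:
    name: str      # three-letter code
    chain: str
    seqno: int
    icode: str = " "


@dataclass
class PocketAtom:
    element: str
    coords: np.ndarray
    residue_index: int
    atom_name: str = ""


@dataclass
class Pocket:
    residues: List[Residue]
    atoms: List[PocketAtom]
    sequence: str = ""

    def __post_init__(self):
        if not self.residues or not self.atoms:
            raise EmptyPocketError("pocket has no standard residues/atoms")
        nres = len(self.residues)
        for a in self.atoms:
            a.coords = np.asarray(a.coords, dtype=float)
            if not (0 <= a.residue_index < nres):
                raise ParseError(
                    f"pocket atom owner index {a.residue_index} out of range")
        if not self.sequence:
            self.sequence = pocket_sequence(self)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms])

    @property
    def elements(self) -> List[str]:
        return [a.element for a in self.atoms]


@dataclass
class ComplexSample:
    """One pocket + ligand pair, the atomic unit of training/prediction."""
    ligand: Ligand
    pocket: Pocket
    label: Optional[float] = None  # binding affinity, pK units
    id: str = ""

    def __post_init__(self):
        if self.label is not None and not np.isfinite(self.label):
            raise ParseError(f"sample {self.id!r}: non-finite label")


def pocket_sequence(pocket: Pocket) -> str:
    """One-letter sequence over the mappable residues of a pocket.

    Standard residues map by the usual 3->1 table; MSE/SEC by
    :data:`NONSTANDARD_MAP`; anything else is skipped with a warning.
    """
    letters = []
    for res in pocket.residues:
        one = THREE_TO_ONE.get(res.name) or NONSTANDARD_MAP.get(res.name)
        if one is None:
            logger.warning("skipping unmappable residue %r in sequence",
                           res.name)
            continue
        letters.append(one)
    if not letters:
        raise EmptyPocketError("no mappable residues: empty sequence")
    return "".join(letters)


# ---------------------------------------------------------------------------
# SDF
# ---------------------------------------------------------------------------

_RD_ORDER_TO_STR = {1.0: "single", 2.0: "double", 3.0: "triple", 1.5: "aromatic"}
_STR_TO_RD_ORDER = None  # filled lazily with rdkit BondType values


def _rdkit():
    from rdkit import Chem, RDLogger
    RDLogger.DisableLog("rdApp.error")
    RDLogger.DisableLog("rdApp.warning")
    return Chem


def read_ligand_sdf(path, record: int = 0) -> Ligand:
    """Read one record of an MDL SDF file (V2000 or V3000).

    Parameters
    ----------
    path : path-like
    record : which record of a multi-record file to read (default 0).
    """
    Chem = _rdkit()
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
    if record >= len(supplier):
        raise ParseError(f"{path}: record {record} out of range "
                         f"({len(supplier)} records)")
    mol = supplier[record]
    if mol is None:
        raise ParseError(
            f"{path}: record {record} failed to parse (malformed counts "
            "line or atom/bond block)")
    if mol.GetNumAtoms() == 0:
        raise EmptyMoleculeError(f"{path}: record {record} has zero atoms")
    if mol.GetNumConformers() == 0:
        raise ParseError(f"{path}: record {record} has no coordinates")
    conf = mol.GetConformer()
    atoms = []
    for a in mol.GetAtoms():
        p = conf.GetAtomPosition(a.GetIdx())
        atoms.append(LigandAtom(a.GetSymbol(), np.array([p.x, p.y, p.z]),
                                a.GetFormalCharge()))
    bonds = []
    for b in mol.GetBonds():
        order = _RD_ORDER_TO_STR.get(b.GetBondTypeAsDouble())
        if order is None:
            order = "single"  # queries/dative etc. degrade to single
        bonds.append(Bond(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), order))
    name = mol.GetProp("_Name").strip() if mol.HasProp("_Name") else ""
    smiles = mol.GetProp("SMILES").strip() if mol.HasProp("SMILES") else None
    return Ligand(atoms, bonds, name=name or path.stem, smiles=smiles)


def ligand_to_rdkit(ligand: Ligand, sanitize: bool = True):
    """Rebuild an RDKit Mol (with one 3D conformer) from a Ligand record."""
    Chem = _rdkit()
    from rdkit.Chem import AllChem  # noqa: F401  (registers conformer code)
    from rdkit.Geometry import Point3D

    order_map = {
        "single": Chem.BondType.SINGLE, "double": Chem.BondType.DOUBLE,
        "triple": Chem.BondType.TRIPLE, "aromatic": Chem.BondType.AROMATIC,
    }
    rw = Chem.RWMol()
    for a in ligand.atoms:
        at = Chem.Atom(a.element)
        at.SetFormalCharge(int(a.formal_charge))
        at.SetNoImplicit(True)
        rw.AddAtom(at)
    for b in ligand.bonds:
        rw.AddBond(b.i, b.j, order_map[b.order])
    mol = rw.GetMol()
    conf = Chem.Conformer(len(ligand.atoms))
    for i, a in enumerate(ligand.atoms):
        conf.SetAtomPosition(i, Point3D(*map(float, a.coords)))
    mol.AddConformer(conf)
    mol.SetProp("_Name", ligand.name)
    if sanitize:
        try:
            Chem.SanitizeMol(mol)
        except Exception:  # valence oddities in toy molecules
            mol.UpdatePropertyCache(strict=False)
            Chem.SanitizeMol(
                mol, Chem.SanitizeFlags.SANITIZE_ALL
                ^ Chem.SanitizeFlags.SANITIZE_PROPERTIES
                ^ Chem.SanitizeFlags.SANITIZE_KEKULIZE)
    else:
        mol.UpdatePropertyCache(strict=False)
    return mol


def write_ligand_sdf(ligand: Ligand, path) -> None:
    """Write a Ligand record as a single-record V2000 SDF file."""
    Chem = _rdkit()
    mol = ligand_to_rdkit(ligand, sanitize=False)
    Chem.FastFindRings(mol)  # aromatic bond blocks need ring info
    block = Chem.MolToMolBlock(mol, kekulize=False)
    with open(path, "w") as fh:
        fh.write(block)
        if ligand.smiles:
            fh.write(f">  <SMILES>\n{ligand.smiles}\n\n")
        fh.write("$$$$\n")


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def read_pocket_pdb(path) -> Pocket:
    """Read a binding-pocket PDB file into a Pocket record.

    Waters and unmappable hetero residues are excluded (each drop logged);
    MSE/SEC are retained via :data:`NONSTANDARD_MAP`.  For residues with
    alternate locations the first-seen altLoc variant of each atom is kept.
    Residues are ordered by (chain id, residue number, insertion code).
    """
    from Bio.PDB import PDBParser

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure(path.stem, str(path))
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    models = list(structure)
    if not models:
        raise EmptyPocketError(f"{path}: no ATOM records")
    model = models[0]

    entries = []  # (sort key, biopython residue)
    for chain in model:
        for res in chain:
            het, seqno, icode = res.id
            name = res.get_resname().strip()
            if name in _WATER_NAMES:
                continue
            if name not in THREE_TO_ONE and name not in NONSTANDARD_MAP:
                logger.warning("%s: dropping unmappable residue %s %s%s",
                               path.name, name, chain.id, seqno)
                continue
            entries.append(((chain.id, seqno, icode), chain.id, res))
    if not entries:
        raise EmptyPocketError(f"{path}: no mappable residues")
    entries.sort(key=lambda e: e[0])

    residues: List[Residue] = []
    atoms: List[PocketAtom] = []
    for (chain_id, seqno, icode), _, res in entries:
        ridx = len(residues)
        residues.append(Residue(res.get_resname().strip(), chain_id,
                                seqno, icode or " "))
        seen = set()
        for atom in res.get_unpacked_list():
            if atom.get_name() in seen:  # altLoc: keep first occurrence
                continue
            seen.add(atom.get_name())
            element = (atom.element or atom.get_name()[:1]).strip().capitalize()
            atoms.append(PocketAtom(element, np.array(atom.get_coord(), float),
                                    ridx, atom_name=atom.get_name()))
    return Pocket(residues, atoms)


def write_pocket_pdb(pocket: Pocket, path) -> None:
    """Write a Pocket record as PDB ATOM records (fixed-column format)."""
    lines = []
    serial = 0
    for i, atom in enumerate(pocket.atoms):
        serial += 1
        res = pocket.residues[atom.residue_index]
        name = atom.atom_name or atom.element
        # columns per the PDB v3 fixed format
        pad_name = f" {name:<3s}" if len(name) < 4 else name[:4]
        x, y, z = atom.coords
        lines.append(
            f"ATOM  {serial:5d} {pad_name}{'':1s}{res.name:>3s} "
            f"{res.chain:1s}{res.seqno:4d}{res.icode:1s}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {atom.element.upper():>2s}  ")
    lines.append("TER")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Index files
# ---------------------------------------------------------------------------

def read_index_pdbbind(path) -> Dict[str, float]:
    """PDBbind-style index: whitespace lines ``id resolution year pK ...``
    with ``#`` comment lines.  Returns id -> pK."""
    out: Dict[str, float] = {}
    for ln, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 4:
            raise ParseError(f"{path}:{ln}: expected >=4 fields, got "
                             f"{len(fields)}")
        try:
            out[fields[0]] = float(fields[3])
        except ValueError as exc:
            raise ParseError(f"{path}:{ln}: bad pK field {fields[3]!r}") from exc
    return out


def read_index_csv(path) -> List[Tuple[str, str, str, Optional[float]]]:
    """Native CSV index: ``id,pocket_path,ligand_path[,pK]`` with header."""
    import csv

    rows = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "pocket_path", "ligand_path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"{path}: header must contain {sorted(required)}")
        for row in reader:
            pk = row.get("pK")
            rows.append((row["id"], row["pocket_path"], row["ligand_path"],
                         float(pk) if pk not in (None, "",) else None))
    return rows


def load_samples_csv(index_path) -> List[ComplexSample]:
    """Load complexes listed in a native CSV index (paths relative to it)."""
    base = Path(index_path).parent
    samples = []
    for sid, ppath, lpath, pk in read_index_csv(index_path):
        pocket = read_pocket_pdb(base / ppath)
        ligand = read_ligand_sdf(base / lpath)
        samples.append(ComplexSample(ligand, pocket, label=pk, id=sid))
    return samples
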