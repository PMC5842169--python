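"""Molecule and spectrophore I/O plus basic geometric utilities.

Molecules are plain containers of atoms with explicit 3D coordinates in
Ångström; each SDF record is treated as one independent conformation.
Reading and writing of SDF/MOL goes through RDKit; spectrophore vectors are
written as TSV with the settings snapshot encoded in the header so that a
file is self-describing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard, typing only
    from .engine import SpectrophoreSettings

__all__ = [
    "Atom",
    "Molecule",
    "SpectrophoreRecord",
    "read_sdf",
    "write_sdf",
    "center_of_geometry",
    "transform",
    "write_spectrophores",
    "read_spectrophores",
]


@dataclass
class Atom:
    """A single atom: element symbol, Cartesian position (Å), formal charge.

    ``attached_elements`` lists the element symbols of bonded neighbours and
    is only consulted by the hydrogen lipophilicity rules; it may be empty
    for heavy atoms.
    """

    element: str
    position: np.ndarray
    formal_charge: int = 0
    attached_elements: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,):
            raise ValueError("atom position must be a 3-vector")
        if not np.all(np.isfinite(self.position)):
            raise ValueError("atom position must be finite")
        if not self.element:
            raise ValueError("atom element symbol must be non-empty")


@dataclass
class Molecule:
    """An ordered collection of atoms forming one conformation."""

    title: str
    atoms: list[Atom]

    def __post_init__(self) -> None:
        if len(self.atoms) == 0:
            raise ValueError("a molecule must contain at least one atom")

    @property
    def total_charge(self) -> int:
        return sum(a.formal_charge for a in self.atoms)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def coordinates(self) -> np.ndarray:
        """Return the n_atoms × 3 coordinate array (Å)."""
        return np.array([a.position for a in self.atoms], dtype=float)

    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


@dataclass
class SpectrophoreRecord:
    """A computed spectrophore vector together with its settings snapshot."""

    title: str
    values: np.ndarray
    settings: "SpectrophoreSettings"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        expected = {12 * 4, 18 * 4, 30 * 4}
        if len(self.values) not in expected:
            raise ValueError(
                f"spectrophore length {len(self.values)} not one of {sorted(expected)}"
            )


def center_of_geometry(molecule: Molecule) -> np.ndarray:
    """Unweighted mean of the atomic positions (Å)."""
    return molecule.coordinates().mean(axis=0)


def transform(molecule: Molecule, rotation: np.ndarray, translation: np.ndarray) -> Molecule:
    """Apply ``x -> R @ x + t`` to every atomic position.

    ``rotation`` must be orthonormal; an improper map (det = -1) is accepted
    and produces the mirror image, which is how enantiomers are built in the
    tests.
    """
    rotation = np.asarray(rotation, dtype=float)
    translation = np.asarray(translation, dtype=float)
    if rotation.shape != (3, 3):
        raise ValueError("rotation must be a 3x3 matrix")
    if np.linalg.norm(rotation.T @ rotation - np.eye(3)) > 1e-8:
        raise ValueError("rotation matrix is not orthonormal")
    atoms = [
        Atom(
            element=a.element,
            position=rotation @ a.position + translation,
            formal_charge=a.formal_charge,
            attached_elements=list(a.attached_elements),
        )
        for a in molecule.atoms
    ]
    return Molecule(title=molecule.title, atoms=atoms)


# --------------------------------------------------------------------------
# SDF reading/writing (RDKit-backed)
# --------------------------------------------------------------------------

def _molecule_from_rdkit(rdmol, index: int) -> Molecule:
    from rdkit import Chem

    if rdmol.GetNumAtoms() == 0:
        raise ValueError(f"SDF record {index} contains no atoms")
    if rdmol.GetNumConformers() == 0:
        raise ValueError(f"SDF record {index} has no coordinates")
    conf = rdmol.GetConformer()
    coords = conf.GetPositions()
    atoms = []
    for i, a in enumerate(rdmol.GetAtoms()):
        neighbours = [n.GetSymbol() for n in a.GetNeighbors()]
        atoms.append(
            Atom(
                element=a.GetSymbol(),
                position=coords[i],
                formal_charge=a.GetFormalCharge(),
                attached_elements=neighbours,
            )
        )
    title = rdmol.GetProp("_Name") if rdmol.HasProp("_Name") else ""
    mol = Molecule(title=title, atoms=atoms)
    if np.allclose(coords[:, 2], 0.0) and len(atoms) > 1:
        warnings.warn(
            f"SDF record {index} ({title!r}) looks two-dimensional (all z = 0); "
            "spectrophores require genuine 3D coordinates",
            stacklevel=3,
        )
    if not any(a.element == "H" for a in atoms) and len(atoms) > 1:
        warnings.warn(
            f"SDF record {index} ({title!r}) has no explicit hydrogens; "
            "atomic parameters are defined for explicit H",
            stacklevel=3,
        )
    return mol


def read_sdf(path: str | Path) -> list[Molecule]:
    """Read a multi-record V2000/V3000 SDF (or single MOL) file.

    Each record becomes one :class:`Molecule`; coordinates are preserved as
    stored. Unparsable records raise, naming the record index.
    """
    from rdkit import Chem

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    molecules: list[Molecule] = []
    try:
        supplier = Chem.SDMolSupplier(str(path), sanitize=False, removeHs=False)
        for index, rdmol in enumerate(supplier):
            if rdmol is None:
                raise ValueError(f"could not parse SDF record {index} in {path}")
            molecules.append(_molecule_from_rdkit(rdmol, index))
    except OSError as exc:  # e.g. an empty or truncated file
        raise ValueError(f"could not read SDF file {path}: {exc}") from exc
    if not molecules:
        raise ValueError(f"no molecule records found in {path}")
    return molecules


def write_sdf(molecules: Iterable[Molecule], path: str | Path) -> None:
    """Write molecules as a multi-record V2000 SDF file."""
    from rdkit import Chem
    from rdkit.Geometry import Point3D

    writer = Chem.SDWriter(str(path))
    writer.SetKekulize(False)
    try:
        for mol in molecules:
            rw = Chem.RWMol()
            for atom in mol.atoms:
                a = Chem.Atom(atom.element)
                a.SetFormalCharge(atom.formal_charge)
                a.SetNoImplicit(True)
                rw.AddAtom(a)
            conf = Chem.Conformer(mol.n_atoms)
            for i, atom in enumerate(mol.atoms):
                conf.SetAtomPosition(i, Point3D(*atom.position))
            rw.AddConformer(conf)
            rd = rw.GetMol()
            rd.SetProp("_Name", mol.title)
            writer.write(rd)
    finally:
        writer.close()


# --------------------------------------------------------------------------
# Spectrophore TSV
# --------------------------------------------------------------------------

_SETTINGS_PREFIX = "#settings"


def write_spectrophores(
    records: Sequence[SpectrophoreRecord], path: str | Path, sep: str = "\t"
) -> None:
    """Write spectrophore records as TSV (or CSV via ``sep=','``).

    Column 1 is the record title followed by one column per value, written at
    full double precision (``repr``). The first line encodes the shared
    settings so that a file can be compared safely; records with mixed
    settings are refused.
    """
    records = list(records)
    if records:
        first = records[0].settings
        for rec in records[1:]:
            if rec.settings != first:
                raise ValueError("all records written to one file must share settings")
        n_values = len(records[0].values)
    else:
        first = None
        n_values = 0
    with open(path, "w") as fh:
        if first is not None:
            fh.write(f"{_SETTINGS_PREFIX}{sep}{first.to_header()}\n")
        header = ["title"] + [f"v{i + 1:03d}" for i in range(n_values)]
        fh.write(sep.join(header) + "\n")
        for rec in records:
            fields = [rec.title] + [repr(float(v)) for v in rec.values]
            fh.write(sep.join(fields) + "\n")


def read_spectrophores(path: str | Path, sep: str = "\t") -> list[SpectrophoreRecord]:
    """Read a file written by :func:`write_spectrophores`."""
    from .engine import SpectrophoreSettings

    settings = None
    records: list[SpectrophoreRecord] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"empty spectrophore file: {path}")
    body = lines
    if lines[0].startswith(_SETTINGS_PREFIX):
        settings = SpectrophoreSettings.from_header(
            lines[0].split(sep, 1)[1] if sep in lines[0] else ""
        )
        body = lines[1:]
    if body and body[0].split(sep)[0] == "title":
        body = body[1:]
    if settings is None:
        raise ValueError(f"spectrophore file {path} lacks a settings header")
    for line in body:
        fields = line.split(sep)
        values = np.array([float(v) for v in fields[1:]], dtype=float)
        records.append(SpectrophoreRecord(title=fields[0], values=values, settings=settings))
    return records
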