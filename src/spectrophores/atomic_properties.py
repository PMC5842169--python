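"""The four per-atom property vectors entering the spectrophore.

For every atom *j* the descriptor needs the contribution values A(j, p) of
four weakly correlated properties:

* **partial charge** — electronegativity equalization (EEM): all atoms share
  one molecular electronegativity μ, giving the linear system
  ``chi_i + 2 eta_i q_i + Σ_{j≠i} q_j / (kappa r_ij) = mu`` with the
  constraint ``Σ q_i = total charge``. ``kappa`` converts Å to the calibration
  scale of the parameters (Bohr; kappa = 1/a0 ≈ 1.8897 Å⁻¹).
* **electrophilicity** — the per-atom share of one additional positive unit
  charge, ``e_i = q_i(Q+1) − q_i(Q)``; by linearity this is the EEM solve
  with a zero electronegativity vector and total charge 1 (the EEM Fukui
  response), so ``Σ e_i = 1``.
* **lipophilicity** — a rule-based per-element contribution; hydrogen is
  split into apolar (all neighbours in {C, H}) and polar rows.
* **shape deviation** — the signed deviation ``d_i − mean(d)`` (Å) of each
  atom's distance to the centre of geometry from the average molecular
  radius; it sums to zero by construction.

Parameters live in ``data/atomic_parameters.tsv`` and can be overridden with
a user table of the same format.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from importlib import resources
from pathlib import Path

import numpy as np

from .chem_io import Atom, Molecule, center_of_geometry

__all__ = [
    "ElementParameters",
    "AtomicProperties",
    "BOHR_PER_ANGSTROM",
    "load_parameter_table",
    "lookup_parameters",
    "eem_charges",
    "eem_electrophilicities",
    "lipophilicities",
    "shape_deviations",
    "compute_properties",
]

#: Distance scaling of the EEM off-diagonal terms (Å → Bohr). The published
#: chi/eta calibration reproduces reference EEM charges when interatomic
#: distances are expressed in Bohr.
BOHR_PER_ANGSTROM = 1.0 / 0.52917721092


@dataclass(frozen=True)
class ElementParameters:
    """EEM electronegativity/hardness and lipophilicity for one table row."""

    chi: float
    eta: float
    lipophilicity: float


def _packaged_table() -> Path:
    return Path(str(resources.files("spectrophores") / "data" / "atomic_parameters.tsv"))


@lru_cache(maxsize=8)
def load_parameter_table(path: str | None = None) -> dict[str, ElementParameters]:
    """Parse the parameter table (packaged by default, user-overridable)."""
    table: dict[str, ElementParameters] = {}
    with open(path if path is not None else _packaged_table()) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, chi, eta, lipo = line.split("\t")
            table[key] = ElementParameters(float(chi), float(eta), float(lipo))
    for required in ("H_polar", "H_CH", "OTHER"):
        if required not in table:
            raise ValueError(f"parameter table lacks required row {required!r}")
    return table


def lookup_parameters(atom: Atom, table: dict[str, ElementParameters] | None = None) -> ElementParameters:
    """Select the parameter row for an atom.

    Hydrogen bonded only to carbon or hydrogen takes the apolar H row; any
    other hydrogen (including H with no recorded neighbours) is polar.
    Elements without their own row fall back to the catch-all row.
    """
    table = table if table is not None else load_parameter_table()
    if atom.element == "H":
        neighbours = atom.attached_elements
        if neighbours and all(n in ("C", "H") for n in neighbours):
            return table["H_CH"]
        return table["H_polar"]
    return table.get(atom.element, table["OTHER"])


@dataclass
class AtomicProperties:
    """Per-atom property vectors; all four have length n_atoms."""

    charges: np.ndarray
    lipophilicities: np.ndarray
    shape_deviations: np.ndarray
    electrophilicities: np.ndarray

    def as_matrix(self) -> np.ndarray:
        """n_atoms × 4 matrix in the output block order."""
        return np.column_stack(
            [self.charges, self.lipophilicities, self.shape_deviations, self.electrophilicities]
        )


# --------------------------------------------------------------------------
# EEM
# --------------------------------------------------------------------------

def _eem_matrix(molecule: Molecule, kappa: float, table) -> tuple[np.ndarray, np.ndarray]:
    coords = molecule.coordinates()
    n = molecule.n_atoms
    dist = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
    close = (dist < 1e-8) & ~np.eye(n, dtype=bool)
    if close.any():
        i, j = np.argwhere(close)[0]
        raise ValueError(
            f"EEM system is singular: atoms {i} and {j} occupy the same position"
        )
    params = [lookup_parameters(a, table) for a in molecule.atoms]
    eta = np.array([p.eta for p in params])
    chi = np.array([p.chi for p in params])
    system = np.zeros((n + 1, n + 1))
    with np.errstate(divide="ignore"):
        system[:n, :n] = 1.0 / (kappa * dist)
    system[np.arange(n), np.arange(n)] = 2.0 * eta
    # electronegativity equalization: the common mu is the extra unknown
    system[:n, n] = -1.0
    system[n, :n] = 1.0
    return system, chi


def eem_charges(
    molecule: Molecule,
    kappa: float = BOHR_PER_ANGSTROM,
    table: dict[str, ElementParameters] | None = None,
    total_charge: int | None = None,
) -> np.ndarray:
    """Solve the EEM linear system for the atomic partial charges.

    The returned charges satisfy ``Σ q_i = total_charge`` (the molecule's
    formal charge sum unless overridden).
    """
    n = molecule.n_atoms
    system, chi = _eem_matrix(molecule, kappa, table)
    rhs = np.empty(n + 1)
    rhs[:n] = -chi
    rhs[n] = molecule.total_charge if total_charge is None else total_charge
    return np.linalg.solve(system, rhs)[:n]


def eem_electrophilicities(
    molecule: Molecule,
    kappa: float = BOHR_PER_ANGSTROM,
    table: dict[str, ElementParameters] | None = None,
) -> np.ndarray:
    """Per-atom share of one added positive unit charge (sums to 1)."""
    n = molecule.n_atoms
    system, _ = _eem_matrix(molecule, kappa, table)
    rhs = np.zeros(n + 1)
    rhs[n] = 1.0
    return np.linalg.solve(system, rhs)[:n]


# --------------------------------------------------------------------------
# Rule-based lipophilicity and shape deviation
# --------------------------------------------------------------------------

def lipophilicities(
    molecule: Molecule, table: dict[str, ElementParameters] | None = None
) -> np.ndarray:
    return np.array([lookup_parameters(a, table).lipophilicity for a in molecule.atoms])


def shape_deviations(molecule: Molecule, signed: bool = True) -> np.ndarray:
    """Deviation of each atomic radius from the average molecular radius (Å).

    Signed by default (zero-sum); ``signed=False`` returns absolute
    deviations for cross-checks against implementations that fold the sign.
    """
    coords = molecule.coordinates()
    radii = np.linalg.norm(coords - center_of_geometry(molecule), axis=1)
    deviations = radii - radii.mean()
    return deviations if signed else np.abs(deviations)


def compute_properties(
    molecule: Molecule,
    kappa: float = BOHR_PER_ANGSTROM,
    table: dict[str, ElementParameters] | None = None,
    signed_shape: bool = True,
) -> AtomicProperties:
    """All four property vectors for one molecule."""
    return AtomicProperties(
        charges=eem_charges(molecule, kappa, table),
        lipophilicities=lipophilicities(molecule, table),
        shape_deviations=shape_deviations(molecule, signed=signed_shape),
        electrophilicities=eem_electrophilicities(molecule, kappa, table),
    )
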