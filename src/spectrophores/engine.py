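"""Rotational maximization of cage interaction energies.

For a conformation with atoms *j* carrying property values A(j, p) and a cage
*c* whose 12 points carry signs P(c, i), the interaction energy is

    V(c, p) = -100 · Σ_i Σ_j A(j, p) · P(c, i) / r_ij        [r_ij in Å]

with r_ij the distance between cage point *i* and atom *j*. The -100 factor
scales values to order one and makes attractive interactions positive. The
molecule is centred on its centre of geometry and rotated through a full
Euler grid; at every orientation the box is rebuilt at the requested
resolution and V evaluated for all cages and properties in one vectorized
pass. The spectrophore keeps the per-(cage, property) maximum over all
orientations, ordered property-major (charges, lipophilicities, shape
deviations, electrophilicities), each block in cage-table order.

Rotation convention: ``R(α, β, γ) = Rz(γ) @ Ry(β) @ Rx(α)`` with every angle
on ``{0, step, 2·step, …} < 360°``; the identity (0, 0, 0) comes first. The
grid is closed under composition with x-rotations by multiples of the step,
which yields the grid-aligned rotation invariance exercised in the tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cage_model import (
    CageDefinition,
    CageGeometry,
    STEREO_MODES,
    build_box,
    cage_points,
    load_cage_set,
)
from .chem_io import Molecule, SpectrophoreRecord, center_of_geometry
from .atomic_properties import AtomicProperties, compute_properties

__all__ = [
    "ALLOWED_ACCURACIES",
    "NORMALIZATION_MODES",
    "SpectrophoreSettings",
    "rotation_grid",
    "interaction_energy",
    "spectrophore",
    "normalize",
    "merge_max",
]

ALLOWED_ACCURACIES = (1, 2, 5, 10, 15, 20, 30, 36, 45, 60)
NORMALIZATION_MODES = ("none", "mean", "std", "all")

#: properties in output block order
PROPERTY_NAMES = ("charges", "lipophilicities", "shape_deviations", "electrophilicities")


@dataclass(frozen=True)
class SpectrophoreSettings:
    """Adjustable parameters of a spectrophore calculation.

    accuracy
        Angular step of the rotational grid in degrees; restricted to
        {1, 2, 5, 10, 15, 20, 30, 36, 45, 60}. Default 20°.
    resolution
        Minimum molecule-to-cage distance in Å (> 0). Default 3 Å, the range
        of a typical non-bonded ligand–receptor contact.
    stereospecificity
        Which cage set to use: ``none`` (12 cages), ``unique`` (18), ``all``
        (30).
    normalization
        Per-property-block post-processing: ``none``, ``mean`` (zero mean),
        ``std`` (unit standard deviation), ``all`` (both).
    """

    accuracy: int = 20
    resolution: float = 3.0
    stereospecificity: str = "none"
    normalization: str = "none"

    def __post_init__(self) -> None:
        if self.accuracy not in ALLOWED_ACCURACIES:
            raise ValueError(
                f"accuracy {self.accuracy}° not allowed; valid steps: "
                f"{', '.join(str(a) for a in ALLOWED_ACCURACIES)}"
            )
        if self.resolution <= 0:
            raise ValueError("resolution must be > 0 Å")
        if self.stereospecificity not in STEREO_MODES:
            raise ValueError(
                f"unknown stereospecificity {self.stereospecificity!r}; "
                f"valid modes: {', '.join(STEREO_MODES)}"
            )
        if self.normalization not in NORMALIZATION_MODES:
            raise ValueError(
                f"unknown normalization {self.normalization!r}; "
                f"valid modes: {', '.join(NORMALIZATION_MODES)}"
            )

    @property
    def n_cages(self) -> int:
        return {"none": 12, "unique": 18, "all": 30}[self.stereospecificity]

    @property
    def n_values(self) -> int:
        return self.n_cages * len(PROPERTY_NAMES)

    def to_header(self) -> str:
        return (
            f"accuracy={self.accuracy}\tresolution={self.resolution!r}\t"
            f"stereospecificity={self.stereospecificity}\tnormalization={self.normalization}"
        )

    @classmethod
    def from_header(cls, header: str) -> "SpectrophoreSettings":
        fields = dict(item.split("=", 1) for item in header.split("\t") if "=" in item)
        return cls(
            accuracy=int(fields["accuracy"]),
            resolution=float(fields["resolution"]),
            stereospecificity=fields["stereospecificity"],
            normalization=fields["normalization"],
        )


# --------------------------------------------------------------------------
# Rotation grid
# --------------------------------------------------------------------------

def rotation_grid(step: int) -> np.ndarray:
    """All grid rotations ``Rz(γ) Ry(β) Rx(α)`` as an (n, 3, 3) array.

    Angles run over {0, step, …} < 360° each; the identity is first. The
    parameterization is redundant (several Euler triples can give one
    rotation); only the maximum over the set matters.
    """
    if step not in ALLOWED_ACCURACIES:
        raise ValueError(
            f"step {step}° not allowed; valid steps: "
            f"{', '.join(str(a) for a in ALLOWED_ACCURACIES)}"
        )
    angles = np.deg2rad(np.arange(0, 360, step, dtype=float))
    ca, sa = np.cos(angles), np.sin(angles)
    n = len(angles)
    rx = np.zeros((n, 3, 3))
    rx[:, 0, 0] = 1.0
    rx[:, 1, 1] = ca
    rx[:, 1, 2] = -sa
    rx[:, 2, 1] = sa
    rx[:, 2, 2] = ca
    ry = np.zeros((n, 3, 3))
    ry[:, 1, 1] = 1.0
    ry[:, 0, 0] = ca
    ry[:, 0, 2] = sa
    ry[:, 2, 0] = -sa
    ry[:, 2, 2] = ca
    rz = np.zeros((n, 3, 3))
    rz[:, 2, 2] = 1.0
    rz[:, 0, 0] = ca
    rz[:, 0, 1] = -sa
    rz[:, 1, 0] = sa
    rz[:, 1, 1] = ca
    # loop order alpha (outer), beta, gamma (inner); R = Rz Ry Rx
    out = np.einsum("gij,bjk,akl->abgil", rz, ry, rx)
    return out.reshape(n**3, 3, 3)


# --------------------------------------------------------------------------
# Interaction energies
# --------------------------------------------------------------------------

def interaction_energy(
    props: np.ndarray,
    atom_coords: np.ndarray,
    cage: CageDefinition,
    geometry: CageGeometry,
) -> float:
    """V(c, p) for one property vector, one cage, one fixed orientation."""
    props = np.asarray(props, dtype=float)
    atom_coords = np.atleast_2d(np.asarray(atom_coords, dtype=float))
    signs = np.array(cage.signs, dtype=float)
    dist = np.linalg.norm(geometry.points[:, None, :] - atom_coords[None, :, :], axis=-1)
    if np.any(dist < 1e-8):
        raise ValueError("an atom coincides with a cage point")
    return float(-100.0 * signs @ (1.0 / dist) @ props)


def _max_energies(
    coords: np.ndarray,
    prop_matrix: np.ndarray,
    signs: np.ndarray,
    accuracy: int,
    resolution: float,
) -> np.ndarray:
    """Per-(cage, property) maximum of V over the rotation grid.

    Energies for all cages and properties are accumulated per orientation
    from one distance evaluation per (cage point, atom) pair; orientations
    are processed in chunks to bound memory.
    """
    rotations = rotation_grid(accuracy)
    n_atoms = coords.shape[0]
    best = np.full((signs.shape[0], prop_matrix.shape[1]), -np.inf)
    chunk = max(1, int(2_000_000 // (12 * n_atoms)))
    from .cage_model import _SLOT_FRACTIONS  # slot order shared with cage_points

    for start in range(0, len(rotations), chunk):
        rot = rotations[start : start + chunk]
        moved = np.einsum("kij,nj->kni", rot, coords)
        box_min = moved.min(axis=1) - resolution
        box_max = moved.max(axis=1) + resolution
        points = box_min[:, None, :] + _SLOT_FRACTIONS[None, :, :] * (
            (box_max - box_min)[:, None, :]
        )
        diff = points[:, :, None, :] - moved[:, None, :, :]
        dist = np.sqrt(np.einsum("kinx,kinx->kin", diff, diff))
        if np.any(dist < 1e-8):
            raise ValueError("an atom coincides with a cage point")
        energies = -100.0 * np.einsum("ci,kin,np->kcp", signs, 1.0 / dist, prop_matrix)
        np.maximum(best, energies.max(axis=0), out=best)
    return best


def spectrophore(
    molecule: Molecule,
    props: AtomicProperties | None = None,
    settings: SpectrophoreSettings | None = None,
    cages: Sequence[CageDefinition] | None = None,
) -> SpectrophoreRecord:
    """Compute the spectrophore of one conformation.

    The molecule is translated so its centre of geometry sits at the origin;
    the per-(cage, property) maxima over the rotation grid are assembled
    property-major (each block in cage-table order) and normalized last.
    """
    settings = settings if settings is not None else SpectrophoreSettings()
    props = props if props is not None else compute_properties(molecule)
    cages = list(cages) if cages is not None else load_cage_set(settings.stereospecificity)
    coords = molecule.coordinates() - center_of_geometry(molecule)
    signs = np.array([c.signs for c in cages], dtype=float)
    best = _max_energies(
        coords, props.as_matrix(), signs, settings.accuracy, settings.resolution
    )
    values = best.T.ravel()  # property-major: blocks of n_cages values
    values = normalize(values, settings.normalization, block=len(cages))
    return SpectrophoreRecord(title=molecule.title, values=values, settings=settings)


# --------------------------------------------------------------------------
# Normalization and conformer merging
# --------------------------------------------------------------------------

def normalize(values: np.ndarray, mode: str, block: int) -> np.ndarray:
    """Normalize per property block (block = values per cage set).

    ``mean`` subtracts the block mean, ``std`` divides by the block
    population standard deviation (n-denominator), ``all`` does both. A block
    with (near-)zero spread is left unscaled with a warning.
    """
    if mode not in NORMALIZATION_MODES:
        raise ValueError(
            f"unknown normalization {mode!r}; valid modes: {', '.join(NORMALIZATION_MODES)}"
        )
    values = np.asarray(values, dtype=float)
    if block <= 0 or len(values) % block:
        raise ValueError(f"vector length {len(values)} is not divisible by block {block}")
    if mode == "none":
        return values.copy()
    blocks = values.reshape(-1, block).astype(float)
    if mode in ("mean", "all"):
        blocks = blocks - blocks.mean(axis=1, keepdims=True)
    if mode in ("std", "all"):
        std = np.asarray(blocks).std(axis=1, keepdims=True)
        degenerate = std < 1e-12
        if degenerate.any():
            warnings.warn(
                "spectrophore block with zero spread left unscaled during "
                "std normalization"
            )
        blocks = np.where(degenerate, blocks, blocks / np.where(degenerate, 1.0, std))
    return blocks.ravel()


def merge_max(records: Sequence[SpectrophoreRecord]) -> SpectrophoreRecord:
    """Element-wise maximum over conformer spectrophores of one molecule."""
    records = list(records)
    if not records:
        raise ValueError("merge_max needs at least one record")
    first = records[0]
    for rec in records[1:]:
        if rec.settings != first.settings or len(rec.values) != len(first.values):
            raise ValueError("merge_max requires identical settings and lengths")
    merged = np.max([rec.values for rec in records], axis=0)
    return SpectrophoreRecord(title=first.title, values=merged, settings=first.settings)
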