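"""Artificial cages: sign patterns and geometric placement of the 12 points.

A cage is a rectangular box surrounding the molecule whose 12 edge midpoints
carry values +1 or -1 that sum to zero (six of each sign). A sign pattern is
*non-stereospecific* when it is equivalent to its own inversion image modulo
the 24 proper rotations of the cage; otherwise it is *stereospecific* and
belongs to one of 18 chiral pattern pairs. The shipped table
(``data/cages.tsv``) lists the 12 non-stereospecific and 18 stereospecific
patterns; its provenance is documented in the file header.

Point slot order (box ``[x0,x1] × [y0,y1] × [z0,z1]``, midpoints ``xm,ym,zm``)::

     1 (xm,y0,z1)   2 (x1,ym,z1)   3 (xm,y1,z1)   4 (x0,ym,z1)   top face
     5 (x0,y0,zm)   6 (x1,y0,zm)   7 (x0,y1,zm)   8 (x1,y1,zm)   vertical
     9 (x1,ym,z0)  10 (xm,y0,z0)  11 (x0,ym,z0)  12 (xm,y1,z0)   bottom face

Under this order the 12 non-stereospecific patterns fall into the 12 distinct
inversion-closed rotation-orbit classes and the 18 stereospecific patterns
cover each of the 18 chiral classes exactly once — the unique assignment (up
to cage rotation) for which the shipped table is internally consistent.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

__all__ = [
    "CageDefinition",
    "CageGeometry",
    "CageSetReport",
    "STEREO_MODES",
    "load_cage_set",
    "validate_cage_set",
    "build_box",
    "cage_points",
]

STEREO_MODES = ("none", "unique", "all")


@dataclass(frozen=True)
class CageDefinition:
    """One cage: its table id, the 12-point sign pattern, and its class."""

    id: int
    signs: tuple[int, ...]
    stereospecific: bool

    def __post_init__(self) -> None:
        if len(self.signs) != 12 or any(s not in (-1, 1) for s in self.signs):
            raise ValueError("a cage needs 12 signs, each +1 or -1")


@dataclass
class CageGeometry:
    """The 12 cage point positions for the current box (Å)."""

    points: np.ndarray
    box_min: np.ndarray
    box_max: np.ndarray


# Unit-box edge midpoints in slot order; scaled/shifted by cage_points().
# Encoded as (axis fractions): 0 -> box_min, 1 -> box_max, 0.5 -> midpoint.
_SLOT_FRACTIONS = np.array(
    [
        [0.5, 0.0, 1.0],
        [1.0, 0.5, 1.0],
        [0.5, 1.0, 1.0],
        [0.0, 0.5, 1.0],
        [0.0, 0.0, 0.5],
        [1.0, 0.0, 0.5],
        [0.0, 1.0, 0.5],
        [1.0, 1.0, 0.5],
        [1.0, 0.5, 0.0],
        [0.5, 0.0, 0.0],
        [0.0, 0.5, 0.0],
        [0.5, 1.0, 0.0],
    ]
)


def _data_path() -> Path:
    return Path(str(resources.files("spectrophores") / "data" / "cages.tsv"))


def _parse_cage_table(path: str | Path) -> list[CageDefinition]:
    cages = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cid, stereo, pattern = line.split("\t")
            signs = tuple(1 if ch == "+" else -1 for ch in pattern)
            cages.append(
                CageDefinition(id=int(cid), signs=signs, stereospecific=stereo == "1")
            )
    return cages


def load_cage_set(mode: str = "none", table: str | Path | None = None) -> list[CageDefinition]:
    """Return the cage definitions for a stereospecificity mode.

    ``none`` gives the 12 non-stereospecific cages, ``unique`` the 18
    stereospecific ones, ``all`` all 30. ``table`` overrides the packaged
    sign-pattern table.
    """
    if mode not in STEREO_MODES:
        raise ValueError(
            f"unknown stereospecificity mode {mode!r}; valid modes: {', '.join(STEREO_MODES)}"
        )
    cages = _parse_cage_table(table if table is not None else _data_path())
    if mode == "none":
        return [c for c in cages if not c.stereospecific]
    if mode == "unique":
        return [c for c in cages if c.stereospecific]
    return cages


# --------------------------------------------------------------------------
# Validation: sum-zero / six-six / distinctness / inversion classification
# --------------------------------------------------------------------------

def _octahedral_slot_permutations() -> list[tuple[int, ...]]:
    """Permutations of the 12 slots induced by the 24 proper cube rotations."""
    pts = _SLOT_FRACTIONS - 0.5
    perms = []
    for axes in itertools.permutations(range(3)):
        for flips in itertools.product((1.0, -1.0), repeat=3):
            mat = np.zeros((3, 3))
            for row, (ax, fl) in enumerate(zip(axes, flips)):
                mat[row, ax] = fl
            if abs(np.linalg.det(mat) - 1.0) > 1e-9:
                continue
            mapped = pts @ mat.T
            perm = []
            for p in mapped:
                (idx,) = np.where(np.all(np.abs(pts - p) < 1e-9, axis=1))[0]
                perm.append(int(idx))
            perms.append(tuple(perm))
    return perms


def _inversion_slot_permutation() -> tuple[int, ...]:
    pts = _SLOT_FRACTIONS - 0.5
    perm = []
    for p in -pts:
        (idx,) = np.where(np.all(np.abs(pts - p) < 1e-9, axis=1))[0]
        perm.append(int(idx))
    return tuple(perm)


_ROTATION_PERMS = _octahedral_slot_permutations()
_INVERSION_PERM = _inversion_slot_permutation()


def _orbit(signs: tuple[int, ...]) -> frozenset[tuple[int, ...]]:
    return frozenset(tuple(signs[i] for i in perm) for perm in _ROTATION_PERMS)


def is_inversion_closed(signs: tuple[int, ...]) -> bool:
    """True when the pattern equals its inversion image modulo cage rotations."""
    inverted = tuple(signs[i] for i in _INVERSION_PERM)
    return inverted in _orbit(signs)


@dataclass
class CageSetReport:
    """Outcome of :func:`validate_cage_set`; empty ``violations`` means valid."""

    n_cages: int
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def validate_cage_set(cages: list[CageDefinition]) -> CageSetReport:
    """Check sum-zero, six/six, pairwise distinctness and stereo classification.

    Non-stereospecific cages must be equivalent to their inversion image
    modulo the cage's proper rotations; stereospecific cages must not be.
    """
    report = CageSetReport(n_cages=len(cages))
    seen: dict[tuple[int, ...], int] = {}
    for cage in cages:
        plus = sum(1 for s in cage.signs if s == 1)
        if sum(cage.signs) != 0:
            report.violations.append(f"cage {cage.id}: signs sum to {sum(cage.signs)}, not 0")
        if plus != 6:
            report.violations.append(f"cage {cage.id}: {plus} positive points, expected 6")
        if cage.signs in seen:
            report.violations.append(
                f"cage {cage.id}: duplicate sign pattern of cage {seen[cage.signs]}"
            )
        else:
            seen[cage.signs] = cage.id
        closed = is_inversion_closed(cage.signs)
        if cage.stereospecific and closed:
            report.violations.append(
                f"cage {cage.id}: marked stereospecific but is inversion-closed"
            )
        if not cage.stereospecific and not closed:
            report.violations.append(
                f"cage {cage.id}: marked non-stereospecific but lacks inversion symmetry"
            )
    return report


# --------------------------------------------------------------------------
# Geometry
# --------------------------------------------------------------------------

def build_box(coords: np.ndarray, resolution: float) -> tuple[np.ndarray, np.ndarray]:
    """Axis-aligned box: per-axis min/max of the coordinates ± resolution (Å).

    The box is rebuilt for every molecular orientation so that the minimum
    molecule-to-cage distance stays at the resolution.
    """
    if resolution <= 0:
        raise ValueError("resolution must be > 0 (Å)")
    coords = np.atleast_2d(np.asarray(coords, dtype=float))
    if coords.size == 0:
        raise ValueError("need at least one coordinate to build a box")
    return coords.min(axis=0) - resolution, coords.max(axis=0) + resolution


def cage_points(box_min: np.ndarray, box_max: np.ndarray) -> np.ndarray:
    """The 12 edge midpoints of the box, in the documented slot order."""
    box_min = np.asarray(box_min, dtype=float)
    box_max = np.asarray(box_max, dtype=float)
    if not np.all(box_min < box_max):
        raise ValueError("degenerate box: box_min must be strictly below box_max")
    return box_min + _SLOT_FRACTIONS * (box_max - box_min)


def cage_geometry(coords: np.ndarray, resolution: float) -> CageGeometry:
    box_min, box_max = build_box(coords, resolution)
    return CageGeometry(points=cage_points(box_min, box_max), box_min=box_min, box_max=box_max)
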