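"""Deterministic toy molecules for exercising the full descriptor pipeline.

The descriptor consumes only elements, coordinates and (for hydrogen rules)
bonded-neighbour element lists, so fixtures need sensible geometry rather
than chemical validity. Every generator is fully determined by its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .chem_io import Atom, Molecule

__all__ = ["FixtureSpec", "make_fixture", "make_conformer_family"]

FIXTURE_KINDS = ("single_atom", "diatomic", "triatomic", "chiral_tetrahedron", "random")

_DEFAULT_ELEMENTS = ("C", "N", "O", "S", "H")


@dataclass
class FixtureSpec:
    """Recipe for one toy molecule; the seed fully determines coordinates."""

    kind: str = "random"
    seed: int = 0
    n_atoms: int = 6
    elements: tuple[str, ...] = _DEFAULT_ELEMENTS
    separation: float = 1.2  # diatomic bond length, Å
    title: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in FIXTURE_KINDS:
            raise ValueError(f"unknown fixture kind {self.kind!r}; valid: {FIXTURE_KINDS}")


def _title(spec: FixtureSpec) -> str:
    return spec.title if spec.title is not None else f"{spec.kind}-{spec.seed}"


def make_fixture(spec: FixtureSpec) -> Molecule:
    """Build the molecule described by ``spec``.

    ``single_atom``: one carbon at the origin. ``diatomic``: C and O on the
    x-axis at the stated separation. ``triatomic``: a bent C/N/O triangle.
    ``chiral_tetrahedron``: a carbon with four distinct substituents at
    tetrahedral geometry (its mirror image is a true enantiomer).
    ``random``: ``n_atoms`` atoms drawn in a 6 Å box with minimum pairwise
    separation 1 Å; hydrogens get their nearest heavy atom as neighbour.
    """
    title = _title(spec)
    if spec.kind == "single_atom":
        return Molecule(title, [Atom("C", np.zeros(3))])
    if spec.kind == "diatomic":
        d = spec.separation
        return Molecule(
            title,
            [Atom("C", np.array([0.0, 0.0, 0.0])), Atom("O", np.array([d, 0.0, 0.0]))],
        )
    if spec.kind == "triatomic":
        return Molecule(
            title,
            [
                Atom("C", np.array([0.0, 0.0, 0.0])),
                Atom("N", np.array([1.4, 0.0, 0.0])),
                Atom("O", np.array([0.5, 1.25, 0.0])),
            ],
        )
    if spec.kind == "chiral_tetrahedron":
        # C at the centre, four distinct substituents on tetrahedral axes
        s = 1.5 / np.sqrt(3.0)
        return Molecule(
            title,
            [
                Atom("C", np.zeros(3)),
                Atom("H", np.array([s, s, s]), attached_elements=["C"]),
                Atom("F", np.array([s, -s, -s])),
                Atom("Cl", np.array([-s, s, -s])),
                Atom("Br", np.array([-s, -s, s])),
            ],
        )
    return _random_molecule(spec, title)


def _random_molecule(spec: FixtureSpec, title: str, max_tries: int = 2000) -> Molecule:
    rng = np.random.default_rng(spec.seed)
    if spec.n_atoms < 1:
        raise ValueError("random fixture needs n_atoms >= 1")
    positions: list[np.ndarray] = []
    tries = 0
    while len(positions) < spec.n_atoms:
        candidate = rng.uniform(-3.0, 3.0, size=3)
        if all(np.linalg.norm(candidate - p) >= 1.0 for p in positions):
            positions.append(candidate)
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {spec.n_atoms} atoms at 1 Å separation "
                f"in a 6 Å box after {max_tries} tries"
            )
    symbols = [spec.elements[i] for i in rng.integers(0, len(spec.elements), spec.n_atoms)]
    atoms = []
    heavy = [(i, p) for i, (p, s) in enumerate(zip(positions, symbols)) if s != "H"]
    for i, (pos, sym) in enumerate(zip(positions, symbols)):
        neighbours: list[str] = []
        if sym == "H" and heavy:
            nearest = min(heavy, key=lambda ip: np.linalg.norm(pos - ip[1]))
            neighbours = [symbols[nearest[0]]]
        atoms.append(Atom(sym, pos, attached_elements=neighbours))
    return Molecule(title, atoms)


def make_conformer_family(spec: FixtureSpec, k: int, jitter: float) -> list[Molecule]:
    """k seeded-jitter copies of a fixture, sharing one title.

    Gaussian coordinate noise of scale ``jitter`` (Å) emulates conformational
    spread; ``jitter=0`` yields identical copies.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    base = make_fixture(spec)
    rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x636F6E66]))
    family = []
    for _ in range(k):
        noise = rng.normal(0.0, jitter, size=(base.n_atoms, 3)) if jitter > 0 else 0.0
        atoms = [
            Atom(
                a.element,
                a.position + (noise[i] if jitter > 0 else 0.0),
                a.formal_charge,
                list(a.attached_elements),
            )
            for i, a in enumerate(base.atoms)
        ]
        family.append(Molecule(base.title, atoms))
    return family
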