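import numpy as np
import pytest

from spectrophores import FixtureSpec, Molecule, Atom, make_fixture


@pytest.fixture
def water() -> Molecule:
    return Molecule(
        "water",
        [
            Atom("O", np.array([0.0, 0.0, 0.1173]), attached_elements=["H", "H"]),
            Atom("H", np.array([0.0, 0.7572, -0.4692]), attached_elements=["O"]),
            Atom("H", np.array([0.0, -0.7572, -0.4692]), attached_elements=["O"]),
        ],
    )


@pytest.fixture
def random_molecules() -> list[Molecule]:
    """A small batch of seeded random fixtures (4-8 atoms)."""
    return [
        make_fixture(FixtureSpec(kind="random", seed=seed, n_atoms=4 + seed % 5))
        for seed in range(8)
    ]


def oracle_eem_diatomic(chi1, eta1, chi2, eta2, distance_bohr, total_charge=0.0):
    """Closed-form 3-unknown EEM solve (q1, q2, mu) via Cramer's rule.

    Written against the equalization equations directly, independent of the
    package's matrix assembly.
    """
    g = 1.0 / distance_bohr
    # 2*eta1*q1 + g*q2 - mu = -chi1
    # g*q1 + 2*eta2*q2 - mu = -chi2
    # q1 + q2            = Q
    a = [[2 * eta1, g, -1.0], [g, 2 * eta2, -1.0], [1.0, 1.0, 0.0]]
    b = [-chi1, -chi2, total_charge]

    def det3(m):
        return (
            m[0][0] * (m[1][1] * m[2][2] - m[1][2] * m[2][1])
            - m[0][1] * (m[1][0] * m[2][2] - m[1][2] * m[2][0])
            + m[0][2] * (m[1][0] * m[2][1] - m[1][1] * m[2][0])
        )

    d = det3(a)
    def col_replaced(idx):
        return [[b[i] if j == idx else a[i][j] for j in range(3)] for i in range(3)]

    return det3(col_replaced(0)) / d, det3(col_replaced(1)) / d
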