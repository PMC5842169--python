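"""Independent naive reference implementations used as oracles.

Pure-Python loops with the :mod:`math` module only — no shared distance
computation, no vectorization — following the documented conventions:
rotation ``Rz(γ) Ry(β) Rx(α)`` over angles ``{0, step, …} < 360``, box =
coordinate min/max ± resolution, cage points = box edge midpoints in the
documented slot order.
"""

import math

# slot order: top-face edges 1-4, vertical edges 5-8, bottom-face edges 9-12
SLOT_FRACTIONS = [
    (0.5, 0.0, 1.0),
    (1.0, 0.5, 1.0),
    (0.5, 1.0, 1.0),
    (0.0, 0.5, 1.0),
    (0.0, 0.0, 0.5),
    (1.0, 0.0, 0.5),
    (0.0, 1.0, 0.5),
    (1.0, 1.0, 0.5),
    (1.0, 0.5, 0.0),
    (0.5, 0.0, 0.0),
    (0.0, 0.5, 0.0),
    (0.5, 1.0, 0.0),
]


def rotation_matrix(alpha_deg, beta_deg, gamma_deg):
    a, b, g = (math.radians(x) for x in (alpha_deg, beta_deg, gamma_deg))
    rx = [[1, 0, 0], [0, math.cos(a), -math.sin(a)], [0, math.sin(a), math.cos(a)]]
    ry = [[math.cos(b), 0, math.sin(b)], [0, 1, 0], [-math.sin(b), 0, math.cos(b)]]
    rz = [[math.cos(g), -math.sin(g), 0], [math.sin(g), math.cos(g), 0], [0, 0, 1]]

    def matmul(x, y):
        return [
            [sum(x[i][k] * y[k][j] for k in range(3)) for j in range(3)]
            for i in range(3)
        ]

    return matmul(rz, matmul(ry, rx))


def apply_rotation(rot, point):
    return [sum(rot[i][k] * point[k] for k in range(3)) for i in range(3)]


def box_points(coords, resolution):
    lo = [min(c[k] for c in coords) - resolution for k in range(3)]
    hi = [max(c[k] for c in coords) + resolution for k in range(3)]
    return [
        [lo[k] + f[k] * (hi[k] - lo[k]) for k in range(3)] for f in SLOT_FRACTIONS
    ]


def interaction_energy(prop_values, coords, signs, points):
    total = 0.0
    for i, sign in enumerate(signs):
        for j, value in enumerate(prop_values):
            r = math.dist(points[i], coords[j])
            total += value * sign / r
    return -100.0 * total


def naive_spectrophore(coords, properties, cages, step, resolution):
    """Property-major maximized interaction vector, one energy at a time.

    ``coords``: list of xyz lists; ``properties``: list of per-atom lists in
    block order; ``cages``: list of 12-sign lists.
    """
    n = len(coords)
    cog = [sum(c[k] for c in coords) / n for k in range(3)]
    centred = [[c[k] - cog[k] for k in range(3)] for c in coords]
    angles = list(range(0, 360, step))
    best = [[-math.inf] * len(cages) for _ in properties]
    for alpha in angles:
        for beta in angles:
            for gamma in angles:
                rot = rotation_matrix(alpha, beta, gamma)
                moved = [apply_rotation(rot, c) for c in centred]
                points = box_points(moved, resolution)
                for p, prop_values in enumerate(properties):
                    for c, signs in enumerate(cages):
                        v = interaction_energy(prop_values, moved, signs, points)
                        if v > best[p][c]:
                            best[p][c] = v
    return [v for block in best for v in block]
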