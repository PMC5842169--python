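import numpy as np
import pytest

from spectrophores import (
    Atom,
    FixtureSpec,
    Molecule,
    SpectrophoreRecord,
    SpectrophoreSettings,
    compute_properties,
    interaction_energy,
    load_cage_set,
    make_fixture,
    merge_max,
    normalize,
    rotation_grid,
    spectrophore,
    transform,
)
from spectrophores.cage_model import cage_geometry
from spectrophores.atomic_properties import AtomicProperties

from naive import (
    interaction_energy as naive_interaction_energy,
    box_points as naive_box_points,
    naive_spectrophore,
)


def props_for(molecule):
    return compute_properties(molecule)


class TestRotationGrid:
    @pytest.mark.parametrize("step,count", [(60, 216), (45, 512), (20, 18**3)])
    def test_grid_size(self, step, count):
        assert rotation_grid(step).shape == (count, 3, 3)

    def test_identity_first(self):
        np.testing.assert_allclose(rotation_grid(60)[0], np.eye(3), atol=1e-15)

    def test_disallowed_step(self):
        with pytest.raises(ValueError, match="1, 2, 5, 10, 15, 20, 30, 36, 45, 60"):
            rotation_grid(7)

    def test_all_orthonormal(self):
        grid = rotation_grid(36)
        products = np.einsum("kij,kil->kjl", grid, grid)
        np.testing.assert_allclose(products, np.broadcast_to(np.eye(3), products.shape), atol=1e-12)


class TestInteractionEnergy:
    def test_single_atom_at_cube_centre_is_zero(self):
        geometry = cage_geometry(np.zeros((1, 3)), 3.0)
        for cage in load_cage_set("all"):
            v = interaction_energy(np.array([0.7]), np.zeros((1, 3)), cage, geometry)
            assert abs(v) < 1e-12

    def test_zero_properties_give_zero(self):
        coords = np.array([[0.5, 0.2, -0.1], [-0.4, 0.3, 0.8]])
        geometry = cage_geometry(coords, 3.0)
        cage = load_cage_set("none")[4]
        assert interaction_energy(np.zeros(2), coords, cage, geometry) == 0.0

    def test_matches_term_by_term_oracle(self):
        coords = np.array([[1.0, 0.0, 0.0], [-1.0, 0.0, 0.0]])
        geometry = cage_geometry(coords, 3.0)
        cage = load_cage_set("none")[0]
        value = interaction_energy(np.array([1.0, -1.0]), coords, cage, geometry)
        oracle = naive_interaction_energy(
            [1.0, -1.0], coords.tolist(), list(cage.signs),
            naive_box_points(coords.tolist(), 3.0),
        )
        assert abs(value - oracle) < 1e-10


class TestSpectrophore:
    @pytest.mark.parametrize("stereo,length", [("none", 48), ("unique", 72), ("all", 120)])
    def test_vector_length(self, stereo, length, water):
        settings = SpectrophoreSettings(accuracy=60, stereospecificity=stereo)
        assert len(spectrophore(water, settings=settings).values) == length

    @pytest.mark.parametrize("stereo", ["none", "all"])
    def test_single_atom_all_zero(self, stereo):
        mol = make_fixture(FixtureSpec(kind="single_atom"))
        settings = SpectrophoreSettings(accuracy=45, stereospecificity=stereo)
        np.testing.assert_allclose(spectrophore(mol, settings=settings).values, 0.0, atol=1e-12)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_naive_reimplementation(self, seed):
        mol = make_fixture(FixtureSpec(kind="random", seed=seed, n_atoms=3))
        props = props_for(mol)
        settings = SpectrophoreSettings(accuracy=60)
        fast = spectrophore(mol, props=props, settings=settings).values
        slow = naive_spectrophore(
            mol.coordinates().tolist(),
            props.as_matrix().T.tolist(),
            [list(c.signs) for c in load_cage_set("none")],
            step=60,
            resolution=3.0,
        )
        np.testing.assert_allclose(fast, slow, atol=1e-9)

    def test_translation_invariance_exact(self):
        """Binary-representable coordinates (4 atoms, quarter-Å lattice) keep
        COG removal bit-lossless, so the translated vector matches exactly."""
        mol = Molecule("t", [
            Atom("C", np.array([0.5, -1.25, 0.75])),
            Atom("N", np.array([1.5, 0.25, -0.5])),
            Atom("O", np.array([-0.75, 1.0, 0.25])),
            Atom("S", np.array([0.25, -1.0, 1.5])),
        ])
        moved = transform(mol, np.eye(3), np.array([4.0, -2.0, 8.0]))
        settings = SpectrophoreSettings(accuracy=45)
        a = spectrophore(mol, settings=settings).values
        b = spectrophore(moved, settings=settings).values
        np.testing.assert_array_equal(a, b)

    def test_grid_aligned_rotation_invariance(self):
        mol = make_fixture(FixtureSpec(kind="random", seed=5, n_atoms=4))
        step = 30
        angle = np.deg2rad(2 * step)
        c, s = np.cos(angle), np.sin(angle)
        rx = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        rotated = transform(mol, rx, np.zeros(3))
        settings = SpectrophoreSettings(accuracy=step)
        a = spectrophore(mol, settings=settings).values
        b = spectrophore(rotated, settings=settings).values
        np.testing.assert_allclose(a, b, atol=1e-8)

    def test_positive_scaling_equivariance(self, water):
        """Scaling one property by λ scales exactly that block by λ."""
        settings = SpectrophoreSettings(accuracy=60)
        props = props_for(water)
        base = spectrophore(water, props=props, settings=settings).values
        scaled_props = AtomicProperties(
            charges=props.charges,
            lipophilicities=2.5 * props.lipophilicities,
            shape_deviations=props.shape_deviations,
            electrophilicities=props.electrophilicities,
        )
        scaled = spectrophore(water, props=scaled_props, settings=settings).values
        np.testing.assert_allclose(scaled[12:24], 2.5 * base[12:24], rtol=1e-12)
        np.testing.assert_allclose(np.delete(scaled, np.s_[12:24]),
                                   np.delete(base, np.s_[12:24]), rtol=1e-12)

    def test_resolution_trend(self):
        """Per-block maximum |V| decreases as the cage moves away."""
        mol = make_fixture(FixtureSpec(kind="random", seed=2, n_atoms=5))
        props = props_for(mol)
        maxima = []
        for resolution in (3.0, 5.0, 10.0):
            settings = SpectrophoreSettings(accuracy=30, resolution=resolution)
            values = spectrophore(mol, props=props, settings=settings).values
            maxima.append(np.abs(values.reshape(4, -1)).max(axis=1))
        maxima = np.array(maxima)
        assert np.all(maxima[1] <= maxima[0]) and np.all(maxima[2] <= maxima[1])

    def test_general_rotation_robustness_at_fine_step(self):
        """An off-grid orientation perturbs values only mildly at a 5° step
        (documented 5% bound) and much more at a 60° step."""
        mol = make_fixture(FixtureSpec(kind="triatomic"))
        rng = np.random.default_rng(11)
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(q) < 0:
            q[:, 0] *= -1
        rotated = transform(mol, q, np.zeros(3))

        def deviation(step):
            settings = SpectrophoreSettings(accuracy=step)
            a = spectrophore(mol, settings=settings).values
            b = spectrophore(rotated, settings=settings).values
            return np.abs(a - b) / np.maximum(np.abs(a), 0.05)

        fine = deviation(5)
        assert fine.max() < 0.05
        coarse = deviation(60)
        assert coarse.mean() > fine.mean()

    def test_enantiomers_at_moderate_step(self):
        """Mirror images agree under 'none' cages and differ under 'unique'."""
        mol = make_fixture(FixtureSpec(kind="chiral_tetrahedron"))
        mirror = transform(mol, np.diag([1.0, -1.0, 1.0]), np.zeros(3))
        none = SpectrophoreSettings(accuracy=10)
        a = spectrophore(mol, settings=none).values
        b = spectrophore(mirror, settings=none).values
        assert np.max(np.abs(a - b) / np.maximum(np.abs(a), 0.05)) < 0.05
        unique = SpectrophoreSettings(accuracy=10, stereospecificity="unique")
        ua = spectrophore(mol, settings=unique).values
        ub = spectrophore(mirror, settings=unique).values
        assert np.max(np.abs(ua - ub)) > 0.1


class TestNormalize:
    def _vector(self):
        rng = np.random.default_rng(3)
        return rng.normal(2.0, 1.5, size=48)

    def test_mean_mode_centres_blocks(self):
        out = normalize(self._vector(), "mean", block=12).reshape(4, 12)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)

    def test_all_mode_standardizes_blocks(self):
        out = normalize(self._vector(), "all", block=12).reshape(4, 12)
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-10)

    def test_std_mode_unit_spread(self):
        out = normalize(self._vector(), "std", block=12).reshape(4, 12)
        np.testing.assert_allclose(out.std(axis=1), 1.0, atol=1e-10)

    def test_none_is_identity(self):
        v = self._vector()
        np.testing.assert_array_equal(normalize(v, "none", block=12), v)

    def test_degenerate_block_left_unscaled(self):
        v = np.concatenate([np.full(12, 3.0), np.arange(12.0)])
        with pytest.warns(UserWarning):
            out = normalize(v, "std", block=12)
        np.testing.assert_array_equal(out[:12], v[:12])

    def test_indivisible_length_rejected(self):
        with pytest.raises(ValueError):
            normalize(np.zeros(47), "mean", block=12)


class TestMergeMax:
    def _record(self, values):
        padded = np.concatenate([np.asarray(values, float), np.zeros(48 - len(values))])
        return SpectrophoreRecord("mol", padded, SpectrophoreSettings())

    def test_elementwise_maximum(self):
        merged = merge_max([self._record([1, 5]), self._record([3, 2])])
        np.testing.assert_array_equal(merged.values[:2], [3, 5])

    def test_idempotent(self):
        rec = self._record(np.arange(48))
        merged = merge_max([rec, rec, rec])
        np.testing.assert_array_equal(merged.values, rec.values)

    def test_order_invariant(self):
        records = [self._record(np.roll(np.arange(48), k)) for k in range(4)]
        forward = merge_max(records).values
        backward = merge_max(records[::-1]).values
        np.testing.assert_array_equal(forward, backward)

    def test_mismatched_settings_rejected(self):
        a = self._record([1.0])
        b = SpectrophoreRecord("mol", np.zeros(72),
                               SpectrophoreSettings(stereospecificity="unique"))
        with pytest.raises(ValueError):
            merge_max([a, b])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            merge_max([])
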