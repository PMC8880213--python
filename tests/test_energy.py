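"""Energy backends: benchmark surface, pair terms, interaction sums."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pathfep.constants import CONSTANTS
from pathfep.energy import (
    HarmonicCouplingModel,
    MuellerBrown,
    TwoLayerModel,
    combine_lj,
    coulomb_pair_energy,
    interaction_energy,
    interaction_gradients,
    lj_pair_energy,
    mueller_brown_energy,
    newton_stationary_point,
)
from pathfep.errors import (
    InvalidDistanceError,
    InvalidGeometryError,
    InvalidInputError,
    ShapeError,
)
from pathfep.system import HybridSystem


class TestMuellerBrown:
    def test_origin_value(self):
        # frozen from independent evaluation of the four-Gaussian sum
        assert mueller_brown_energy((0.0, 0.0)) == pytest.approx(-48.4013, abs=1e-3)

    def test_known_minimum(self):
        mb = MuellerBrown()
        x = newton_stationary_point(mb.gradient, mb.hessian, [-0.5, 1.5])
        assert np.allclose(x, [-0.558, 1.442], atol=2e-3)
        assert np.linalg.norm(mb.gradient(x)) < 1e-6
        assert np.all(np.linalg.eigvalsh(mb.hessian(x)) > 0)

    def test_saddle_has_one_negative_eigenvalue(self):
        mb = MuellerBrown()
        x = newton_stationary_point(mb.gradient, mb.hessian, [-0.8, 0.6])
        assert np.allclose(x, [-0.822, 0.624], atol=2e-3)
        eigs = np.linalg.eigvalsh(mb.hessian(x))
        assert np.sum(eigs < 0) == 1

    def test_non_finite_input_rejected(self):
        with pytest.raises(InvalidInputError):
            mueller_brown_energy((np.nan, 0.0))

    def test_gradient_matches_finite_differences(self, rng):
        mb = MuellerBrown()
        h = 1e-6
        for _ in range(50):
            p = rng.uniform([-1.5, -0.5], [1.0, 2.0])
            g = mb.gradient(p)
            fd = np.array([
                (mb.energy(p + h * e) - mb.energy(p - h * e)) / (2 * h)
                for e in np.eye(2)
            ])
            assert np.allclose(g, fd, rtol=1e-5, atol=1e-7)


class TestPairTerms:
    @pytest.mark.parametrize("r,eps,sig,expected", [
        (3.0, 0.5, 3.0, 0.0),                 # zero crossing at r = sigma
        (2 ** (1 / 6) * 3.0, 0.5, 3.0, -0.5),  # minimum depth -epsilon
        (1.7, 0.0, 3.0, 0.0),                  # no well depth, no energy
    ])
    def test_lj_reference_points(self, r, eps, sig, expected):
        assert lj_pair_energy(r, eps, sig) == pytest.approx(expected, abs=1e-12)

    def test_coulomb_unit_charges_at_unit_distance(self):
        assert coulomb_pair_energy(1.0, 1.0, 1.0) == pytest.approx(332.0637)

    def test_coulomb_scaling(self):
        assert coulomb_pair_energy(2.0, 1.0, 1.0) == pytest.approx(
            0.5 * coulomb_pair_energy(1.0, 1.0, 1.0))
        assert coulomb_pair_energy(1.5, 1.0, 0.0) == 0.0

    @pytest.mark.parametrize("bad_r", [0.0, -1.0, np.nan])
    def test_nonpositive_distance_rejected(self, bad_r):
        with pytest.raises(InvalidDistanceError):
            lj_pair_energy(bad_r, 1.0, 1.0)
        with pytest.raises(InvalidDistanceError):
            coulomb_pair_energy(bad_r, 1.0, 1.0)

    def test_pair_symmetry(self, rng):
        for _ in range(20):
            r = rng.uniform(1.0, 6.0)
            qa, qb = rng.normal(size=2)
            assert coulomb_pair_energy(r, qa, qb) == coulomb_pair_energy(r, qb, qa)
            ea, sa, eb, sb = rng.uniform(0.1, 3.0, size=4)
            assert combine_lj(ea, sa, eb, sb) == combine_lj(eb, sb, ea, sa)

    @pytest.mark.parametrize("args,expected", [
        ((1, 1, 1, 1), (1, 1)),
        ((0, 2.0, 0.7, 3.0), (0, 2.5)),
        ((4, 2, 1, 4), (2, 3)),
    ])
    def test_lorentz_berthelot(self, args, expected):
        assert combine_lj(*args) == pytest.approx(expected)


class TestInteractionEnergy:
    def test_zero_charges_and_epsilon(self, random_hybrid):
        sysm = random_hybrid
        sysm.lj_epsilon[:] = 0.0
        sysm.env_charges[:] = 0.0
        result = interaction_energy(sysm.active_positions, np.zeros(5), sysm)
        assert result == (0.0, 0.0, 0.0)

    def test_single_pair_reduction(self):
        sysm = HybridSystem(
            positions=np.array([0.0, 0, 0, 4.0, 0, 0]),
            active_indices=[0], environment_indices=[1],
            env_charges=[-0.4], lj_epsilon=[0.2, 0.3], lj_sigma=[3.0, 3.4],
        )
        q = np.array([0.7])
        _, _, e_int = interaction_energy(sysm.active_positions, q, sysm)
        eps, sig = combine_lj(0.2, 3.0, 0.3, 3.4)
        expected = lj_pair_energy(4.0, eps, sig) + coulomb_pair_energy(4.0, 0.7, -0.4)
        assert e_int == pytest.approx(expected, rel=1e-14)

    def test_matches_double_loop_oracle(self, random_hybrid, rng):
        sysm = random_hybrid
        q = rng.normal(size=5)
        e_vdw, e_es, e_int = interaction_energy(sysm.active_positions, q, sysm)
        ra = sysm.active_positions.reshape(-1, 3)
        rb = sysm.env_positions.reshape(-1, 3)
        brute_vdw = brute_es = 0.0
        for a in range(5):
            for b in range(8):
                d = np.linalg.norm(ra[a] - rb[b])
                eps, sig = combine_lj(sysm.active_lj_epsilon[a],
                                      sysm.active_lj_sigma[a],
                                      sysm.env_lj_epsilon[b],
                                      sysm.env_lj_sigma[b])
                brute_vdw += lj_pair_energy(d, eps, sig)
                brute_es += coulomb_pair_energy(d, q[a], sysm.env_charges[b])
        assert e_vdw == pytest.approx(brute_vdw, rel=1e-10)
        assert e_es == pytest.approx(brute_es, rel=1e-10)
        assert e_int == pytest.approx(brute_vdw + brute_es, rel=1e-10)

    def test_coincident_atoms_rejected(self, random_hybrid):
        sysm = random_hybrid
        env = sysm.env_positions.copy()
        env[0:3] = sysm.active_positions[0:3]
        with pytest.raises(InvalidGeometryError, match="atom 0"):
            interaction_energy(sysm.active_positions, np.zeros(5), sysm, env)

    def test_charge_count_mismatch(self, random_hybrid):
        with pytest.raises(ShapeError):
            interaction_energy(random_hybrid.active_positions, np.zeros(3),
                               random_hybrid)

    def test_gradients_match_finite_differences(self, random_hybrid, rng):
        sysm = random_hybrid
        q = rng.normal(size=5)
        r, R = sysm.active_positions, sysm.env_positions
        ga, ge = interaction_gradients(r, q, sysm)
        h = 1e-5
        for i in rng.choice(r.size, 6, replace=False):
            e = np.zeros(r.size)
            e[i] = h
            fd = (interaction_energy(r + e, q, sysm)[2]
                  - interaction_energy(r - e, q, sysm)[2]) / (2 * h)
            assert ga[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)
        for i in rng.choice(R.size, 6, replace=False):
            e = np.zeros(R.size)
            e[i] = h
            fd = (interaction_energy(r, q, sysm, R + e)[2]
                  - interaction_energy(r, q, sysm, R - e)[2]) / (2 * h)
            assert ge[i] == pytest.approx(fd, rel=1e-5, abs=1e-8)


class TestTwoLayerModel:
    def test_hybrid_gradients_match_finite_differences(self, toy, rng):
        model = toy.model
        r = toy.active_A + 0.2 * rng.normal(size=12)
        R = toy.system.env_positions
        h = 1e-5
        g = model.active_gradient(r, R)
        for i in rng.choice(12, 6, replace=False):
            e = np.zeros(12)
            e[i] = h
            fd = (model.active_energy(r + e, R)
                  - model.active_energy(r - e, R)) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)
        ge = model.env_gradient(r, R)
        for i in rng.choice(R.size, 6, replace=False):
            e = np.zeros(R.size)
            e[i] = h
            fd = (model.environment_energy(r, R + e)
                  - model.environment_energy(r, R - e)) / (2 * h)
            assert ge[i] == pytest.approx(fd, rel=1e-4, abs=1e-6)

    def test_charge_model_chain_rule(self, toy, rng):
        """The active gradient must include the geometry dependence of
        the fitted charges, not just the fixed-charge force."""
        model = toy.model
        r = toy.active_A + 0.1 * rng.normal(size=12)
        R = toy.system.env_positions
        h = 1e-6
        J = toy.charge_model.jacobian(r)
        fd = np.empty_like(J)
        for i in range(12):
            e = np.zeros(12)
            e[i] = h
            fd[:, i] = (toy.charge_model.charges(r + e)
                        - toy.charge_model.charges(r - e)) / (2 * h)
        assert np.allclose(J, fd, atol=1e-8)


class TestHarmonicCouplingModel:
    def test_exact_free_energy_difference(self):
        m = HarmonicCouplingModel(k=2.0)
        assert m.exact_delta_f(0.0, 1.0) == pytest.approx(-0.25)
        assert m.exact_delta_f(1.0, 1.0) == 0.0

    def test_env_gradient(self):
        m = HarmonicCouplingModel(k=1.5)
        R = np.array([0.3, -0.2, 0.7])
        g = m.env_gradient(np.array([0.4]), R)
        h = 1e-7
        fd = np.array([
            (m.environment_energy([0.4], R + h * e)
             - m.environment_energy([0.4], R - h * e)) / (2 * h)
            for e in np.eye(3)
        ])
        assert np.allclose(g, fd, atol=1e-6)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.floats(0.8, 8.0), st.floats(0.01, 2.0), st.floats(1.0, 4.0))
def test_lj_energy_above_minus_epsilon(r, eps, sig):
    """-epsilon is the global minimum of the 12-6 form."""
    assert lj_pair_energy(r, eps, sig) >= -eps - 1e-12


def test_units_are_consistent():
    """Coulomb prefactor equals e^2/Bohr expressed in kcal/mol and Å."""
    k = CONSTANTS.hartree_to_kcalmol * CONSTANTS.bohr_to_angstrom
    assert k == pytest.approx(CONSTANTS.coulomb_k, rel=2e-5)
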