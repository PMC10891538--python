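"""Potential energies, forces, cutoff continuity and gradient exactness."""

import numpy as np
import pytest

from fbdsim import forcefield as ff, topology as tp
from fbdsim.errors import (EscapedBeadError, InvalidParameterError,
                           OverlapError, OverstretchError)

FENE_AT_1P5 = -33.75 * np.log(8.0 / 9.0)        # 3.9751774534...
WALL_AT_HALF = 2 * np.pi * (0.4 * 1024 - 16 + 0.6)  # 2476.8316...


@pytest.mark.parametrize("func,d,expected", [
    (ff.fene_energy, 1.0, 0.0),
    (ff.fene_energy, 1.5, FENE_AT_1P5),
    (ff.harmonic_energy, 1.0, 0.0),
    (ff.harmonic_energy, 1.1, 0.5),
    (ff.harmonic_energy, 0.9, 0.5),
    (ff.wca_energy, 1.0, 1.0),
    (ff.wca_energy, 2 ** (1 / 6), 0.0),
    (ff.wca_energy, 2.0, 0.0),
    (ff.wall_energy, 1.0, 0.0),
    (ff.wall_energy, 0.5, WALL_AT_HALF),
    (ff.wall_energy, 2.0, 0.0),
])
def test_energy_spot_values(func, d, expected):
    assert func(d) == pytest.approx(expected, abs=1e-10)


def test_fene_force_zero_at_equilibrium_and_restoring():
    assert ff.fene_force(1.0) == 0.0
    assert ff.fene_force(1.3) < 0.0   # pulls back for d > sigma
    assert ff.fene_force(0.8) > 0.0   # pushes out for d < sigma


def test_fene_overstretch_errors():
    with pytest.raises(OverstretchError):
        ff.fene_energy(2.5)   # d = sigma + R
    with pytest.raises(OverstretchError):
        ff.fene_force(1.0 - 1.5)


def test_harmonic_symmetry_and_force_sign():
    d = np.array([0.8, 0.9, 1.0, 1.1, 1.2])
    u = ff.harmonic_energy(d)
    np.testing.assert_allclose(u, u[::-1])
    assert ff.harmonic_force(1.1) == pytest.approx(-10.0)


def test_wca_overlap_floor():
    with pytest.raises(OverlapError):
        ff.wca_energy(1e-8)


def test_wall_escape_error():
    with pytest.raises(EscapedBeadError):
        ff.wall_energy(0.0)
    with pytest.raises(EscapedBeadError):
        ff.wall_energy(-0.3)


@pytest.mark.parametrize("func,cut", [
    (ff.wca_energy, 2 ** (1 / 6)),
    (ff.wall_energy, 1.0),
])
def test_energy_continuity_at_cutoff(func, cut):
    for delta in (1e-3, 1e-5, 1e-7):
        assert abs(func(cut - delta)) < 50 * delta


def test_scalar_force_matches_energy_derivative():
    h = 1e-7
    for func_u, func_f, xs in [
            (ff.fene_energy, ff.fene_force, [0.7, 1.0, 1.4, 2.2]),
            (ff.harmonic_energy, ff.harmonic_force, [0.5, 1.0, 1.8]),
            (ff.wca_energy, ff.wca_force, [0.8, 0.95, 1.05]),
            (ff.wall_energy, ff.wall_force, [0.4, 0.7, 0.95])]:
        for x in xs:
            fd = -(func_u(x + h) - func_u(x - h)) / (2 * h)
            assert func_f(x) == pytest.approx(fd, rel=1e-5, abs=1e-5)


def test_invalid_params_rejected():
    with pytest.raises(InvalidParameterError):
        ff.ForceFieldParams(epsilon=-1)
    with pytest.raises(InvalidParameterError):
        ff.ForceFieldParams(bond_type="morse")
    with pytest.raises(InvalidParameterError):
        ff.CylinderGeometry(radius=0)


# ---------------------------------------------------------------------------
# whole-system forces
# ---------------------------------------------------------------------------

def _two_bead_topology():
    bonds = np.array([[0, 1]], dtype=np.int64)
    role = np.zeros(2, dtype=np.int64)
    return tp.PolymerTopology(n_backbone=2, loop_size=2, bonds=bonds,
                              bead_role=role)


def test_bonded_pair_at_equilibrium_has_zero_force():
    topo = _two_bead_topology()
    cfg = tp.Configuration(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
    for bond in ("fene", "harmonic"):
        F, E = ff.total_forces(cfg, topo, ff.ForceFieldParams(bond_type=bond))
        np.testing.assert_allclose(F, 0.0, atol=1e-12)
        assert E == pytest.approx(0.0, abs=1e-12)


def test_single_bead_at_cylinder_center_feels_no_wall():
    topo = _two_bead_topology()
    geom = ff.CylinderGeometry()  # 14.75 x 50.75: center is > sigma away
    cfg = tp.Configuration(np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0]]))
    F, E = ff.total_forces(cfg, topo, ff.ForceFieldParams(bond_type="fene"),
                           geom)
    np.testing.assert_allclose(F, 0.0, atol=1e-12)


def test_newtons_third_law_without_walls(rng):
    topo = tp.build_bottle_brush(3, 4)
    geom = ff.CylinderGeometry(radius=4.0, length_z=10.0)
    base = tp.initial_configuration(topo, geom, seed=2).positions
    for trial in range(5):
        pos = base + rng.normal(0.0, 0.03, base.shape)
        F, _ = ff.total_forces(tp.Configuration(pos), topo,
                               ff.ForceFieldParams(bond_type="harmonic"))
        np.testing.assert_allclose(F.sum(axis=0), 0.0, atol=1e-10)


def finite_difference_check(topo, geom, params, pos, h=1e-5):
    """Max relative error between forces and the central-difference
    gradient of the total energy."""
    F, _ = ff.total_forces(tp.Configuration(pos), topo, params, geom)
    worst = 0.0
    for i in range(pos.shape[0]):
        for a in range(3):
            pp = pos.copy()
            pp[i, a] += h
            pm = pos.copy()
            pm[i, a] -= h
            ep = ff.total_forces(tp.Configuration(pp), topo, params, geom)[1]
            em = ff.total_forces(tp.Configuration(pm), topo, params, geom)[1]
            fd = -(ep - em) / (2 * h)
            worst = max(worst,
                        abs(fd - F[i, a]) / max(1.0, abs(F[i, a])))
    return worst


def test_forces_match_energy_gradient(rng):
    topo = tp.build_bottle_brush(3, 4)
    geom = ff.CylinderGeometry(radius=4.0, length_z=10.0)
    base = tp.initial_configuration(topo, geom, seed=2).positions
    for trial in range(10):
        pos = base + rng.normal(0.0, 0.02, base.shape)
        params = ff.ForceFieldParams(
            bond_type="fene" if trial % 2 else "harmonic")
        assert finite_difference_check(topo, geom, params, pos) < 1e-6


def test_total_forces_propagates_overstretch():
    topo = _two_bead_topology()
    cfg = tp.Configuration(np.array([[0.0, 0.0, 0.0], [2.6, 0.0, 0.0]]))
    with pytest.raises(OverstretchError) as exc:
        ff.total_forces(cfg, topo, ff.ForceFieldParams(bond_type="fene"))
    assert exc.value.bond_index == 0


def test_total_forces_propagates_escape():
    topo = _two_bead_topology()
    geom = ff.CylinderGeometry(radius=2.0, length_z=4.0)
    cfg = tp.Configuration(np.array([[0.0, 0.0, 5.0], [0.0, 0.0, 4.2]]))
    with pytest.raises(EscapedBeadError) as exc:
        ff.total_forces(cfg, topo,
                        ff.ForceFieldParams(bond_type="harmonic"), geom)
    assert exc.value.bead_index == 0
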