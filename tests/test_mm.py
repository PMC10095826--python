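import math

import numpy as np
import pytest

from ffmatch.mm import (Atom, ClassConsistencyError, Configuration,
                        DihedralTerm, HarmonicParam, LJParam,
                        MissingParameterError, ParameterSet, SingularityError,
                        Topology, batch_evaluate, evaluate_energy,
                        evaluate_forces, symmetry_classes)


def _rotation(rng):
    # random proper rotation via QR
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] *= -1
    return q


def make_chain(n=5, seed=0):
    """Bonded n-atom chain with angles and dihedrals, mild charges."""
    rng = np.random.default_rng(seed)
    atoms = [Atom(i, "A" if i % 2 else "B", 12.0, 0.1 * (-1) ** i, True)
             for i in range(n)]
    top = Topology.from_bonds(atoms, [(i, i + 1) for i in range(n - 1)])
    params = ParameterSet(
        bonds={("A", "B"): HarmonicParam(250.0, 1.5),
               ("A", "A"): HarmonicParam(250.0, 1.5),
               ("B", "B"): HarmonicParam(250.0, 1.5)},
        angles={k: HarmonicParam(50.0, 1.9) for k in
                (("A", "B", "A"), ("B", "A", "B"), ("A", "A", "B"),
                 ("B", "B", "A"), ("A", "B", "B"), ("B", "A", "A"))},
        dihedrals={k: [DihedralTerm(1.3, 2, 0.5), DihedralTerm(0.7, 3, 0.0)]
                   for k in (("A", "B", "A", "B"), ("B", "A", "B", "A"),
                             ("A", "A", "B", "B"), ("A", "B", "B", "A"),
                             ("B", "A", "A", "B"), ("B", "B", "A", "A"))},
        lj={"A": LJParam(0.1, 3.2), "B": LJParam(0.15, 3.0)},
    )
    coords = np.zeros((n, 3))
    for i in range(1, n):
        step = rng.standard_normal(3)
        coords[i] = coords[i - 1] + 1.5 * step / np.linalg.norm(step)
    return top, params, coords


def test_equilibrium_bond_energy_zero():
    atoms = [Atom(0, "X", 12.0, 0.0), Atom(1, "X", 12.0, 0.0)]
    top = Topology.from_bonds(atoms, [(0, 1)])
    params = ParameterSet(bonds={("X", "X"): HarmonicParam(300.0, 1.5)},
                          lj={"X": LJParam(0.0, 3.0)})
    e = evaluate_energy(top, params, Configuration([[0, 0, 0], [1.5, 0, 0]]))
    assert e.bond == pytest.approx(0.0, abs=1e-12)
    assert np.allclose(evaluate_forces(
        top, params, Configuration([[0, 0, 0], [1.5, 0, 0]])), 0.0, atol=1e-10)


def _dihedral_geometry(phi):
    """Four atoms with torsion angle phi about the central z-aligned bond."""
    return np.array([
        [1.0, 0.0, -0.5],
        [0.0, 0.0, 0.0],
        [0.0, 0.0, 1.0],
        [math.cos(phi), math.sin(phi), 1.5],
    ])


@pytest.mark.parametrize("phi,expected", [
    (math.pi / 2, 0.0),        # k(1 + cos(2*90deg)) = 0
    (0.0, 4.16),               # 2 * 2.08 at the barrier top
])
def test_dihedral_term_values(phi, expected):
    atoms = [Atom(i, "X", 12.0, 0.0) for i in range(4)]
    top = Topology.from_bonds(atoms, [(0, 1), (1, 2), (2, 3)])
    params = ParameterSet(
        bonds={("X", "X"): HarmonicParam(0.0, 1.5)},
        angles={("X", "X", "X"): HarmonicParam(0.0, 1.9)},
        dihedrals={("X", "X", "X", "X"): [DihedralTerm(2.08, 2, 0.0)]},
        lj={"X": LJParam(0.0, 3.0)})
    e = evaluate_energy(top, params, Configuration(_dihedral_geometry(phi)))
    assert e.dihedral == pytest.approx(expected, abs=1e-10)


def test_dihedral_periodicity_exact():
    atoms = [Atom(i, "X", 12.0, 0.0) for i in range(4)]
    top = Topology.from_bonds(atoms, [(0, 1), (1, 2), (2, 3)])
    params = ParameterSet(
        bonds={("X", "X"): HarmonicParam(0.0, 1.5)},
        angles={("X", "X", "X"): HarmonicParam(0.0, 1.9)},
        dihedrals={("X", "X", "X", "X"): [DihedralTerm(1.7, 3, 0.4)]},
        lj={"X": LJParam(0.0, 3.0)})
    for phi in np.linspace(-math.pi, math.pi, 17):
        e1 = evaluate_energy(top, params,
                             Configuration(_dihedral_geometry(phi))).dihedral
        e2 = evaluate_energy(top, params,
                             Configuration(_dihedral_geometry(phi + 2 * math.pi))).dihedral
        assert e1 == pytest.approx(e2, abs=1e-12)
        # matches the analytic form
        assert e1 == pytest.approx(1.7 * (1 + math.cos(3 * phi - 0.4)), abs=1e-9)


def test_null_hamiltonian_total_zero(rng):
    top, params, coords = make_chain(6)
    null = params.copy()
    for p in null.bonds.values():
        p.k = 0.0
    for p in null.angles.values():
        p.k = 0.0
    for terms in null.dihedrals.values():
        for t in terms:
            t.k = 0.0
    for p in null.lj.values():
        p.epsilon = 0.0
    null_atoms = [Atom(a.index, a.type, a.mass, 0.0, a.heavy)
                  for a in top.atoms]
    top0 = Topology(null_atoms, top.bonds, top.angles, top.dihedrals)
    x = coords + 0.3 * rng.standard_normal(coords.shape)
    assert evaluate_energy(top0, null, Configuration(x)).total == 0.0


def test_total_is_sum_of_components(rng):
    top, params, coords = make_chain(5)
    x = coords + 0.1 * rng.standard_normal(coords.shape)
    e = evaluate_energy(top, params, Configuration(x))
    parts = (e.bond + e.angle + e.dihedral + e.improper + e.lj + e.coulomb
             + e.lj14 + e.coulomb14)
    assert e.total == pytest.approx(parts, rel=1e-15)


def test_forces_match_finite_differences_chain(rng):
    top, params, coords = make_chain(5, seed=3)
    x = coords + 0.1 * rng.standard_normal(coords.shape)
    f = evaluate_forces(top, params, Configuration(x))
    h = 1e-5
    for i in range(5):
        for d in range(3):
            xa, xb = x.copy(), x.copy()
            xa[i, d] += h
            xb[i, d] -= h
            num = -(evaluate_energy(top, params, Configuration(xa)).total
                    - evaluate_energy(top, params, Configuration(xb)).total) / (2 * h)
            assert f[i, d] == pytest.approx(num, abs=1e-5)


def test_rigid_motion_invariance_and_force_covariance(toy_host, rng):
    top, params, meta = toy_host
    x = meta["coords"] + 0.05 * rng.standard_normal(meta["coords"].shape)
    q = _rotation(rng)
    shift = np.array([5.0, -3.0, 2.0])
    x2 = x @ q.T + shift
    e1 = evaluate_energy(top, params, Configuration(x))
    e2 = evaluate_energy(top, params, Configuration(x2))
    assert abs(e1.total - e2.total) < 1e-8
    for comp in ("bond", "angle", "dihedral", "improper"):
        assert abs(getattr(e1, comp) - getattr(e2, comp)) < 1e-8
    f1 = evaluate_forces(top, params, Configuration(x))
    f2 = evaluate_forces(top, params, Configuration(x2))
    assert np.allclose(f2, f1 @ q.T, atol=1e-8)
    assert np.allclose(np.linalg.norm(f2, axis=1),
                       np.linalg.norm(f1, axis=1), atol=1e-8)


def test_newton_zero_net_force(toy_host, rng):
    top, params, meta = toy_host
    for _ in range(5):
        x = meta["coords"] + 0.08 * rng.standard_normal(meta["coords"].shape)
        f = evaluate_forces(top, params, Configuration(x))
        assert np.linalg.norm(f.sum(axis=0)) < 1e-8


def test_missing_parameter_names_the_type():
    atoms = [Atom(0, "Q", 12.0, 0.0), Atom(1, "R", 12.0, 0.0)]
    top = Topology.from_bonds(atoms, [(0, 1)])
    params = ParameterSet(bonds={}, lj={"Q": LJParam(0, 3), "R": LJParam(0, 3)})
    with pytest.raises(MissingParameterError, match=r"Q.*R"):
        evaluate_energy(top, params, Configuration([[0, 0, 0], [1.5, 0, 0]]))


def test_overlapping_nonbonded_pair_raises():
    atoms = [Atom(i, "X", 12.0, 0.1) for i in range(4)]
    top = Topology.from_bonds(atoms, [(0, 1)])
    params = ParameterSet(bonds={("X", "X"): HarmonicParam(300.0, 1.5)},
                          lj={"X": LJParam(0.1, 3.0)})
    coords = np.array([[0, 0, 0], [1.5, 0, 0], [4.0, 0, 0], [4.0, 1e-8, 0.0]])
    with pytest.raises(SingularityError):
        evaluate_energy(top, params, Configuration(coords))


def test_invalid_topology_rejected():
    atoms = [Atom(i, "X", 12.0, 0.0) for i in range(3)]
    with pytest.raises(ValueError):
        Topology(atoms, [(0, 0)])
    with pytest.raises(ValueError):
        Topology(atoms, [(0, 5)])
    with pytest.raises(ValueError):  # angle not backed by bonds
        Topology(atoms, [(0, 1)], angles=[(0, 1, 2)])


def test_exclusions_derived_from_bond_graph():
    atoms = [Atom(i, "X", 12.0, 0.0) for i in range(5)]
    top = Topology.from_bonds(atoms, [(i, i + 1) for i in range(4)])
    assert frozenset((0, 1)) in top.exclusions12
    assert frozenset((0, 2)) in top.exclusions13
    assert frozenset((0, 3)) in top.pairs14
    assert frozenset((0, 4)) not in (top.exclusions12 | top.exclusions13
                                     | top.pairs14)


def test_symmetry_classes_ring(toy_host):
    top, params, meta = toy_host
    cmap = symmetry_classes(top, params)
    ring_bonds = [cmap[("bond", i)] for i, key in
                  enumerate(top.term_keys()["bond"]) if key == ("C", "N")]
    assert len(ring_bonds) == 16              # 8 units x 2 ring bonds
    assert len(set(ring_bonds)) == 1          # one shared class
    # generator metadata is the oracle for the full map
    for kind in ("bond", "angle", "dihedral", "improper"):
        for i, key in enumerate(meta["classes"][kind]):
            assert cmap[(kind, i)] == (kind, key)


def test_symmetry_classes_distinct_angle_types(toy_host):
    top, params, _ = toy_host
    cmap = symmetry_classes(top, params)
    angle_classes = {cmap[("angle", i)] for i in range(len(top.angles))}
    assert len(angle_classes) == len(params.angles)


def test_declared_class_consistency(toy_host):
    top, params, _ = toy_host
    # merging two bond types with different values must fail
    declared = {"shared": [("bond", ("C", "N")), ("bond", ("C", "O"))]}
    with pytest.raises(ClassConsistencyError):
        symmetry_classes(top, params, declared=declared)
    # identical values are accepted and mapped to the declared id
    p2 = params.copy()
    p2.bonds[("C", "O")].k = p2.bonds[("C", "N")].k
    p2.bonds[("C", "O")].eq = p2.bonds[("C", "N")].eq
    cmap = symmetry_classes(top, p2, declared=declared)
    assert cmap[("bond", 0)] == "shared"


def test_negative_force_constant_rejected():
    with pytest.raises(ValueError):
        ParameterSet(bonds={("X", "X"): HarmonicParam(-1.0, 1.5)})


def test_dihedral_periodicity_must_be_positive_integer():
    with pytest.raises(ValueError):
        DihedralTerm(1.0, 0).validate()
    with pytest.raises(ValueError):
        DihedralTerm(1.0, 2.5).validate()


def test_batch_matches_single_frame(toy_host, rng):
    top, params, meta = toy_host
    frames = meta["coords"][None] + 0.05 * rng.standard_normal((7,) + meta["coords"].shape)
    total, comp, forces = batch_evaluate(top, params, frames)
    for f in range(7):
        e = evaluate_energy(top, params, Configuration(frames[f]))
        assert total[f] == pytest.approx(e.total, rel=1e-12)
        ff = evaluate_forces(top, params, Configuration(frames[f]))
        assert np.allclose(forces[f], ff, atol=1e-12)
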