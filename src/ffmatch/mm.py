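"""Classical molecular-mechanics model: topology, parameters, energies, forces.

The functional forms follow the Amber convention:

* bond stretching      ``E = k_b (r - r_eq)^2``
* angle bending        ``E = k_a (theta - theta_eq)^2``
* proper/improper torsion, a sum of periodic terms
                       ``E = k_d [1 + cos(n*phi - delta)]``
* Lennard-Jones 12-6 with Lorentz-Berthelot combining, point-charge Coulomb,
  1-2/1-3 exclusions and scaled 1-4 interactions.

Forces are the exact analytic negative gradients.  Evaluation is vectorised
over frames internally so that fitting against thousands of configurations
stays cheap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

from .constants import COULOMB

__all__ = [
    "Atom",
    "Topology",
    "HarmonicParam",
    "DihedralTerm",
    "LJParam",
    "ParameterSet",
    "Configuration",
    "EnergyBreakdown",
    "MissingParameterError",
    "SingularityError",
    "ClassConsistencyError",
    "evaluate_energy",
    "evaluate_forces",
    "batch_evaluate",
    "symmetry_classes",
    "bond_key",
    "angle_key",
    "dihedral_key",
]


class MissingParameterError(KeyError):
    """A typed term has no entry in the parameter set."""


class SingularityError(ValueError):
    """Two nonbonded atoms closer than the overlap guard (1e-6 A)."""


class ClassConsistencyError(ValueError):
    """Parameters declared to share a symmetry class hold different values."""


# --------------------------------------------------------------------------
# domain types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    index: int
    type: str
    mass: float
    charge: float
    heavy: bool = True
    element: str = ""

    def __post_init__(self):
        if not self.element:
            object.__setattr__(self, "element", self.type[:1].upper() or "X")


def bond_key(ta: str, tb: str) -> tuple:
    return tuple(sorted((ta, tb)))


def angle_key(ta: str, tb: str, tc: str) -> tuple:
    return min((ta, tb, tc), (tc, tb, ta))


def dihedral_key(ta: str, tb: str, tc: str, td: str) -> tuple:
    fwd = (ta, tb, tc, td)
    return min(fwd, fwd[::-1])


@dataclass
class Topology:
    """Connectivity of one molecule plus per-atom metadata.

    Angle/dihedral lists and exclusion sets are derived from the bond graph
    (see :meth:`from_bonds`); explicit construction is validated against it.
    """

    atoms: list
    bonds: list
    angles: list = field(default_factory=list)
    dihedrals: list = field(default_factory=list)
    impropers: list = field(default_factory=list)

    def __post_init__(self):
        self.validate()
        ex12, ex13, p14 = _derive_exclusions(self.n_atoms, self.bonds)
        self.exclusions12 = ex12
        self.exclusions13 = ex13
        self.pairs14 = p14

    # -- basic views -------------------------------------------------------

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def masses(self) -> np.ndarray:
        return np.array([a.mass for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def heavy_mask(self) -> np.ndarray:
        return np.array([a.heavy for a in self.atoms], dtype=bool)

    @property
    def types(self) -> list:
        return [a.type for a in self.atoms]

    # -- construction ------------------------------------------------------

    @classmethod
    def from_bonds(cls, atoms, bonds, impropers=()):
        """Build a topology deriving angles and proper dihedrals from bonds."""
        n = len(atoms)
        adj = [set() for _ in range(n)]
        for i, j in bonds:
            adj[i].add(j)
            adj[j].add(i)
        angles = []
        for j in range(n):
            nb = sorted(adj[j])
            for a in range(len(nb)):
                for b in range(a + 1, len(nb)):
                    angles.append((nb[a], j, nb[b]))
        dihedrals = []
        for j, k in bonds:
            for i in sorted(adj[j] - {k}):
                for l in sorted(adj[k] - {j}):
                    if i != l:
                        dihedrals.append((i, j, k, l))
        return cls(list(atoms), [tuple(b) for b in bonds], angles, dihedrals,
                   [tuple(t) for t in impropers])

    def validate(self):
        n = len(self.atoms)
        for name, terms, size in (("bond", self.bonds, 2),
                                  ("angle", self.angles, 3),
                                  ("dihedral", self.dihedrals, 4),
                                  ("improper", self.impropers, 4)):
            for t in terms:
                if len(t) != size or len(set(t)) != size:
                    raise ValueError(f"malformed {name} term {t}")
                if any(i < 0 or i >= n for i in t):
                    raise ValueError(f"{name} term {t}: atom index out of range")
        bondset = {frozenset(b) for b in self.bonds}
        for (i, j, k) in self.angles:
            if frozenset((i, j)) not in bondset or frozenset((j, k)) not in bondset:
                raise ValueError(f"angle {(i, j, k)} not supported by the bond graph")
        for (i, j, k, l) in self.dihedrals:
            for pair in ((i, j), (j, k), (k, l)):
                if frozenset(pair) not in bondset:
                    raise ValueError(
                        f"dihedral {(i, j, k, l)} not supported by the bond graph")

    # -- typed term keys ---------------------------------------------------

    def term_keys(self):
        t = self.types
        return {
            "bond": [bond_key(t[i], t[j]) for i, j in self.bonds],
            "angle": [angle_key(t[i], t[j], t[k]) for i, j, k in self.angles],
            "dihedral": [dihedral_key(t[i], t[j], t[k], t[l])
                         for i, j, k, l in self.dihedrals],
            "improper": [dihedral_key(t[i], t[j], t[k], t[l])
                         for i, j, k, l in self.impropers],
        }


@dataclass
class HarmonicParam:
    """Force constant + equilibrium value for a bond or angle type."""

    k: float
    eq: float
    fit_k: bool = True
    fit_eq: bool = True

    def validate(self, kind):
        if self.k < 0:
            raise ValueError(f"{kind} force constant must be >= 0, got {self.k}")


@dataclass
class DihedralTerm:
    """One periodic torsion term k*[1 + cos(n*phi - phase)].

    Periodicity ``n`` is structural and never fitted; only the amplitude may
    be fit-enabled.
    """

    k: float
    n: int
    phase: float = 0.0
    fit_k: bool = True

    def validate(self):
        if not (isinstance(self.n, (int, np.integer)) and self.n >= 1):
            raise ValueError(f"dihedral periodicity must be an integer >= 1, got {self.n}")


@dataclass
class LJParam:
    epsilon: float
    sigma: float


@dataclass
class ParameterSet:
    """Complete MM parameter model keyed by atom-type symmetry classes.

    Bonded entries carry fit flags; nonbonded entries (charges live on the
    topology, LJ and 1-4 scales here) are always frozen.
    """

    bonds: dict = field(default_factory=dict)
    angles: dict = field(default_factory=dict)
    dihedrals: dict = field(default_factory=dict)
    impropers: dict = field(default_factory=dict)
    lj: dict = field(default_factory=dict)
    scale14_elec: float = 1.0 / 1.2
    scale14_vdw: float = 0.5

    def __post_init__(self):
        self.validate()

    def validate(self):
        for key, p in self.bonds.items():
            p.validate("bond")
        for key, p in self.angles.items():
            p.validate("angle")
        for terms in list(self.dihedrals.values()) + list(self.impropers.values()):
            for t in terms:
                t.validate()

    def copy(self) -> "ParameterSet":
        return ParameterSet(
            bonds={k: replace(v) for k, v in self.bonds.items()},
            angles={k: replace(v) for k, v in self.angles.items()},
            dihedrals={k: [replace(t) for t in v] for k, v in self.dihedrals.items()},
            impropers={k: [replace(t) for t in v] for k, v in self.impropers.items()},
            lj={k: replace(v) for k, v in self.lj.items()},
            scale14_elec=self.scale14_elec,
            scale14_vdw=self.scale14_vdw,
        )


@dataclass
class Configuration:
    """Cartesian coordinates of one frame (N x 3, angstrom)."""

    coords: np.ndarray
    box: object = None

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coordinates must be an (N, 3) array")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")


@dataclass
class EnergyBreakdown:
    bond: float = 0.0
    angle: float = 0.0
    dihedral: float = 0.0
    improper: float = 0.0
    lj: float = 0.0
    coulomb: float = 0.0
    lj14: float = 0.0
    coulomb14: float = 0.0

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.dihedral + self.improper
                + self.lj + self.coulomb + self.lj14 + self.coulomb14)


# --------------------------------------------------------------------------
# compiled term tables
# --------------------------------------------------------------------------


def _derive_exclusions(n, bonds):
    adj = [set() for _ in range(n)]
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    ex12 = {frozenset(b) for b in bonds}
    ex13 = set()
    p14 = set()
    for j in range(n):
        for i in adj[j]:
            for k in adj[j]:
                if i < k:
                    ex13.add(frozenset((i, k)))
    for i, j in bonds:
        for a in adj[i] - {j}:
            for b in adj[j] - {i}:
                if a != b:
                    pair = frozenset((a, b))
                    if pair not in ex12 and pair not in ex13:
                        p14.add(pair)
    ex13 -= ex12
    return ex12, ex13, p14


class _CompiledModel:
    """Index and parameter arrays for fast, frame-batched evaluation."""

    def __init__(self, top: Topology, params: ParameterSet):
        keys = top.term_keys()
        # bonds
        for key in keys["bond"]:
            if key not in params.bonds:
                raise MissingParameterError(f"no bond parameters for type {key}")
        for key in keys["angle"]:
            if key not in params.angles:
                raise MissingParameterError(f"no angle parameters for type {key}")
        for key in keys["dihedral"]:
            if key not in params.dihedrals:
                raise MissingParameterError(f"no dihedral parameters for type {key}")
        for key in keys["improper"]:
            if key not in params.impropers:
                raise MissingParameterError(f"no improper parameters for type {key}")
        for t in top.types:
            if t not in params.lj:
                raise MissingParameterError(f"no LJ parameters for atom type {t}")

        self.bond_idx = np.array(top.bonds, dtype=int).reshape(-1, 2)
        self.bond_k = np.array([params.bonds[k].k for k in keys["bond"]])
        self.bond_eq = np.array([params.bonds[k].eq for k in keys["bond"]])

        self.angle_idx = np.array(top.angles, dtype=int).reshape(-1, 3)
        self.angle_k = np.array([params.angles[k].k for k in keys["angle"]])
        self.angle_eq = np.array([params.angles[k].eq for k in keys["angle"]])

        def expand_torsions(term_list, param_map, key_list):
            idx, kk, nn, ph = [], [], [], []
            for quad, key in zip(term_list, key_list):
                for term in param_map[key]:
                    idx.append(quad)
                    kk.append(term.k)
                    nn.append(term.n)
                    ph.append(term.phase)
            return (np.array(idx, dtype=int).reshape(-1, 4), np.array(kk),
                    np.array(nn, dtype=float), np.array(ph))

        (self.dih_idx, self.dih_k, self.dih_n, self.dih_phase) = expand_torsions(
            top.dihedrals, params.dihedrals, keys["dihedral"])
        (self.imp_idx, self.imp_k, self.imp_n, self.imp_phase) = expand_torsions(
            top.impropers, params.impropers, keys["improper"])

        # nonbonded pair lists
        n = top.n_atoms
        excluded = top.exclusions12 | top.exclusions13 | top.pairs14
        nb = [(i, j) for i in range(n) for j in range(i + 1, n)
              if frozenset((i, j)) not in excluded]
        self.nb_idx = np.array(nb, dtype=int).reshape(-1, 2)
        p14 = sorted(tuple(sorted(p)) for p in top.pairs14)
        self.p14_idx = np.array(p14, dtype=int).reshape(-1, 2)

        q = top.charges
        eps = np.array([params.lj[t].epsilon for t in top.types])
        sig = np.array([params.lj[t].sigma for t in top.types])

        def pair_params(idx):
            i, j = idx[:, 0], idx[:, 1]
            return (q[i] * q[j],
                    np.sqrt(eps[i] * eps[j]),
                    0.5 * (sig[i] + sig[j]))

        self.nb_qq, self.nb_eps, self.nb_sig = pair_params(self.nb_idx)
        self.p14_qq, self.p14_eps, self.p14_sig = pair_params(self.p14_idx)
        self.scale14_elec = params.scale14_elec
        self.scale14_vdw = params.scale14_vdw
        self.n_atoms = n

        # scatter plans (one per atom-role column of each term family)
        self.scatters = {}
        for name, idx in (("bond", self.bond_idx), ("angle", self.angle_idx),
                          ("dih", self.dih_idx), ("imp", self.imp_idx),
                          ("nb", self.nb_idx), ("p14", self.p14_idx)):
            if len(idx):
                self.scatters[name] = [_Scatter(idx[:, m], n)
                                       for m in range(idx.shape[1])]


class _Scatter:
    """Accumulate per-term (F, T, 3) contributions onto atoms via a single
    sorted reduceat pass (much faster than np.add.at for many frames)."""

    def __init__(self, idx, n_atoms):
        idx = np.asarray(idx, dtype=int)
        order = np.argsort(idx, kind="stable")
        self.order = order
        sorted_idx = idx[order]
        self.atoms, self.starts = np.unique(sorted_idx, return_index=True)

    def add(self, f, contrib):
        c = contrib[:, self.order, :]
        sums = np.add.reduceat(c, self.starts, axis=1)
        f[:, self.atoms, :] += sums


def bond_geometry(r, idx):
    """Distances and their gradients for batched coords r (F,N,3), idx (T,2).

    Returns (dist (F,T), u (F,T,3)) where u = d(dist)/d(r_j) = -d(dist)/d(r_i).
    """
    d = r[:, idx[:, 1], :] - r[:, idx[:, 0], :]
    dist = np.linalg.norm(d, axis=-1)
    return dist, d / dist[..., None]


def angle_geometry(r, idx):
    """Angles theta (F,T) and gradients (gi, gk) of theta w.r.t. the outer
    atoms; the central-atom gradient is -(gi + gk)."""
    i, j, k = (idx[:, m] for m in range(3))
    u = r[:, i, :] - r[:, j, :]
    v = r[:, k, :] - r[:, j, :]
    nu = np.linalg.norm(u, axis=-1)
    nv = np.linalg.norm(v, axis=-1)
    uh = u / nu[..., None]
    vh = v / nv[..., None]
    c = np.clip(np.einsum("fti,fti->ft", uh, vh), -1.0, 1.0)
    theta = np.arccos(c)
    s = np.sqrt(np.maximum(1.0 - c**2, 1e-24))
    gi = (c[..., None] * uh - vh) / (nu * s)[..., None]
    gk = (c[..., None] * vh - uh) / (nv * s)[..., None]
    return theta, gi, gk


def torsion_geometry(r, idx, grads=True):
    """Torsion angles phi (F,T) and, if requested, the four gradient arrays
    d(phi)/d(r_m) (F,T,3) for idx (T,4)."""
    p0, p1, p2, p3 = (r[:, idx[:, m], :] for m in range(4))
    b1 = p1 - p0
    b2 = p2 - p1
    b3 = p3 - p2
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    nb2 = np.linalg.norm(b2, axis=-1)
    x = np.einsum("fti,fti->ft", n1, n2)
    y = np.einsum("fti,fti->ft", np.cross(n1, n2), b2) / np.maximum(nb2, 1e-300)
    phi = np.arctan2(y, x)
    if not grads:
        return phi, None
    n1sq = np.maximum(np.einsum("fti,fti->ft", n1, n1), 1e-300)
    n2sq = np.maximum(np.einsum("fti,fti->ft", n2, n2), 1e-300)
    d1 = -(nb2 / n1sq)[..., None] * n1
    d4 = (nb2 / n2sq)[..., None] * n2
    s12 = (np.einsum("fti,fti->ft", b1, b2) / nb2**2)[..., None]
    s32 = (np.einsum("fti,fti->ft", b3, b2) / nb2**2)[..., None]
    d2 = -(1.0 + s12) * d1 + s32 * d4
    d3 = s12 * d1 - (1.0 + s32) * d4
    return phi, (d1, d2, d3, d4)


def _evaluate(model: _CompiledModel, coords: np.ndarray, want_forces: bool):
    """Core evaluator: coords (F,N,3) -> per-component energies (F,), forces."""
    r = coords
    nf, n = r.shape[0], r.shape[1]
    comp = {k: np.zeros(nf) for k in
            ("bond", "angle", "dihedral", "improper", "lj", "coulomb",
             "lj14", "coulomb14")}
    f = np.zeros((nf, n, 3)) if want_forces else None

    # bonds ---------------------------------------------------------------
    if len(model.bond_idx):
        dist, u = bond_geometry(r, model.bond_idx)
        dr = dist - model.bond_eq
        comp["bond"] = np.sum(model.bond_k * dr**2, axis=-1)
        if want_forces:
            fj = (-2.0 * model.bond_k * dr)[..., None] * u
            sc = model.scatters["bond"]
            sc[1].add(f, fj)
            sc[0].add(f, -fj)

    # angles --------------------------------------------------------------
    if len(model.angle_idx):
        theta, gi, gk = angle_geometry(r, model.angle_idx)
        dth = theta - model.angle_eq
        comp["angle"] = np.sum(model.angle_k * dth**2, axis=-1)
        if want_forces:
            dEdth = (2.0 * model.angle_k * dth)[..., None]
            fi = -dEdth * gi
            fk = -dEdth * gk
            sc = model.scatters["angle"]
            sc[0].add(f, fi)
            sc[2].add(f, fk)
            sc[1].add(f, -(fi + fk))

    # torsions (proper + improper share the machinery) ----------------------
    for label, name, idx, kk, nn, ph in (
            ("dihedral", "dih", model.dih_idx, model.dih_k, model.dih_n,
             model.dih_phase),
            ("improper", "imp", model.imp_idx, model.imp_k, model.imp_n,
             model.imp_phase)):
        if not len(idx):
            continue
        phi, grads = torsion_geometry(r, idx, grads=want_forces)
        comp[label] = np.sum(kk * (1.0 + np.cos(nn * phi - ph)), axis=-1)
        if want_forces:
            g = (-kk * nn * np.sin(nn * phi - ph))[..., None]
            sc = model.scatters[name]
            for m in range(4):
                sc[m].add(f, -g * grads[m])

    # nonbonded -------------------------------------------------------------
    for label_lj, label_q, name, idx, qq, eps, sig, s_vdw, s_q in (
            ("lj", "coulomb", "nb", model.nb_idx, model.nb_qq, model.nb_eps,
             model.nb_sig, 1.0, 1.0),
            ("lj14", "coulomb14", "p14", model.p14_idx, model.p14_qq,
             model.p14_eps, model.p14_sig, model.scale14_vdw,
             model.scale14_elec)):
        if not len(idx):
            continue
        i, j = idx[:, 0], idx[:, 1]
        d = r[:, j, :] - r[:, i, :]
        dist2 = np.einsum("fti,fti->ft", d, d)
        if np.any(dist2 < 1e-12):
            raise SingularityError(
                "overlapping atoms in a nonbonded pair (r < 1e-6 A)")
        dist = np.sqrt(dist2)
        sr6 = (sig**2 / dist2) ** 3
        elj = s_vdw * 4.0 * eps * (sr6**2 - sr6)
        eq = s_q * COULOMB * qq / dist
        comp[label_lj] = np.sum(elj, axis=-1)
        comp[label_q] = np.sum(eq, axis=-1)
        if want_forces:
            dlj = s_vdw * 4.0 * eps * (-12.0 * sr6**2 + 6.0 * sr6) / dist
            dEdr = dlj - eq / dist
            fj = (-dEdr / dist)[..., None] * d
            sc = model.scatters[name]
            sc[1].add(f, fj)
            sc[0].add(f, -fj)

    return comp, f


# --------------------------------------------------------------------------
# public operations
# --------------------------------------------------------------------------


def batch_evaluate(topology: Topology, params: ParameterSet, coords: np.ndarray,
                   forces: bool = True):
    """Evaluate energies (and optionally forces) for a stack of frames.

    Parameters
    ----------
    coords : (F, N, 3) array
    Returns
    -------
    energies : (F,) total energies, kcal/mol
    components : dict of (F,) arrays per energy component
    forces : (F, N, 3) array or None
    """
    coords = np.asarray(coords, dtype=float)
    if coords.ndim != 3 or coords.shape[1] != topology.n_atoms:
        raise ValueError("coords must be (F, N, 3) matching the topology")
    if not np.all(np.isfinite(coords)):
        raise ValueError("coordinates must be finite")
    model = _CompiledModel(topology, params)
    comp, frc = _evaluate(model, coords, forces)
    total = sum(comp.values())
    return total, comp, frc


def evaluate_energy(topology: Topology, params: ParameterSet,
                    config: Configuration) -> EnergyBreakdown:
    """Per-term MM energy record for a single configuration (kcal/mol)."""
    _, comp, _ = batch_evaluate(topology, params, config.coords[None], forces=False)
    return EnergyBreakdown(**{k: float(v[0]) for k, v in comp.items()})


def evaluate_forces(topology: Topology, params: ParameterSet,
                    config: Configuration) -> np.ndarray:
    """Per-atom forces, kcal/(mol A); exact negative gradient of the energy."""
    _, _, frc = batch_evaluate(topology, params, config.coords[None], forces=True)
    return frc[0]


def symmetry_classes(topology: Topology, params: ParameterSet,
                     declared: Mapping | None = None) -> dict:
    """Map each parameterised term instance to its shared-parameter class.

    Classes default to the atom-type keys under which parameters are stored,
    so all instances of one type share one class.  ``declared`` may merge
    type keys into wider classes: ``{class_id: [(kind, key), ...]}``; members
    of a declared class must hold identical parameter values.
    """
    alias = {}
    if declared:
        for cid, members in declared.items():
            vals = []
            for kind, key in members:
                store = getattr(params, kind + "s")
                if key not in store:
                    raise MissingParameterError(f"no {kind} parameters for type {key}")
                entry = store[key]
                if kind in ("bond", "angle"):
                    vals.append((entry.k, entry.eq))
                else:
                    vals.append(tuple((t.k, t.n, t.phase) for t in entry))
                alias[(kind, key)] = cid
            if len({repr(v) for v in vals}) > 1:
                raise ClassConsistencyError(
                    f"declared class {cid!r} members hold different values: {vals}")

    keys = topology.term_keys()
    out = {}
    for kind in ("bond", "angle", "dihedral", "improper"):
        for i, key in enumerate(keys[kind]):
            cls = alias.get((kind, key), (kind, key))
            out[(kind, i)] = cls
    return out
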