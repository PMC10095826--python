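"""Synthetic inputs: toy molecules, ghost-Hamiltonian reference datasets and
binding samples over a known free-energy profile.

A "ghost" parameter set plays the role of the reference Hamiltonian: it
labels sampled configurations with energies and forces so that parameter-
recovery experiments have an exact ground truth.  Everything generated here
is bit-reproducible from (spec, seed).
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constants import KB, V_STANDARD
from .fitting import ReferenceDataset
from .metrics import AffinityTable
from .mm import (Atom, DihedralTerm, HarmonicParam, LJParam, ParameterSet,
                 Topology, _CompiledModel, _evaluate)

__all__ = [
    "GhostSpec",
    "ToyBindingSpec",
    "BindingSamples",
    "make_toy_host",
    "make_diatomic",
    "ghost_reference_dataset",
    "make_binding_trajectory",
    "fixture_table1",
]

#: ring torsional barrier of the stiff toy host, kcal/mol (phase 0, n = 2)
STIFF_RING_AMPLITUDE = 2.08


def make_toy_host(n_units: int = 8, stiffness: str = "stiff"):
    """Closed macrocycle of ``n_units`` repeated N-C(-O)(H on N) units.

    The ring alternates N and C backbone atoms; each C carries a radial O,
    each N a radial H, giving three heavy atom types plus hydrogens and one
    shared symmetry class per term type.  ``stiffness`` selects the ring
    N-C-N-C torsion amplitude: ``"stiff"`` = 2.08 kcal/mol, ``"floppy"`` = 0
    (both with phase 0).

    Returns (topology, parameters, meta); ``meta["classes"]`` records the
    generator's declared class of every term instance.
    """
    if n_units < 3:
        raise ValueError("a ring needs at least 3 units")
    if stiffness not in ("stiff", "floppy"):
        raise ValueError("stiffness must be 'stiff' or 'floppy'")
    ring_amp = STIFF_RING_AMPLITUDE if stiffness == "stiff" else 0.0

    u = n_units
    n_ring = 2 * u
    b = 1.40                         # ring bond length, A
    r_ring = b / (2.0 * math.sin(math.pi / n_ring))
    interior = math.pi - math.pi / u
    side_angle = (2.0 * math.pi - interior) / 2.0

    atoms = []
    coords = []
    bonds = []
    impropers = []
    # backbone: indices 0..2u-1 alternate N (even) / C (odd)
    for m in range(n_ring):
        phi = 2.0 * math.pi * m / n_ring
        pos = np.array([r_ring * math.cos(phi), r_ring * math.sin(phi), 0.0])
        if m % 2 == 0:
            atoms.append(Atom(m, "N", 14.007, -0.30, True, "N"))
        else:
            atoms.append(Atom(m, "C", 12.011, 0.50, True, "C"))
        coords.append(pos)
        bonds.append((m, (m + 1) % n_ring))
    # side atoms: O on each C, H on each N, placed radially outward
    nxt = n_ring
    for m in range(n_ring):
        unit = coords[m] / np.linalg.norm(coords[m])
        if m % 2 == 1:  # C -> O
            atoms.append(Atom(nxt, "O", 15.999, -0.50, True, "O"))
            coords.append(coords[m] + 1.25 * unit)
            bonds.append((m, nxt))
            prev_n = (m - 1) % n_ring
            next_n = (m + 1) % n_ring
            impropers.append((prev_n, next_n, m, nxt))
            nxt += 1
        else:           # N -> H
            atoms.append(Atom(nxt, "H", 1.008, 0.30, False, "H"))
            coords.append(coords[m] + 1.01 * unit)
            bonds.append((m, nxt))
            nxt += 1

    top = Topology.from_bonds(atoms, bonds, impropers=impropers)

    params = ParameterSet(
        bonds={
            ("C", "N"): HarmonicParam(k=300.0, eq=b),
            ("C", "O"): HarmonicParam(k=400.0, eq=1.25),
            ("H", "N"): HarmonicParam(k=350.0, eq=1.01),
        },
        angles={
            ("N", "C", "N"): HarmonicParam(k=60.0, eq=interior),
            ("C", "N", "C"): HarmonicParam(k=55.0, eq=interior),
            ("N", "C", "O"): HarmonicParam(k=70.0, eq=side_angle),
            ("C", "N", "H"): HarmonicParam(k=45.0, eq=side_angle),
        },
        dihedrals={
            ("C", "N", "C", "N"): [DihedralTerm(k=ring_amp, n=2, phase=0.0)],
            ("C", "N", "C", "O"): [DihedralTerm(k=1.10, n=2, phase=math.pi)],
            ("H", "N", "C", "N"): [DihedralTerm(k=1.40, n=3, phase=0.0)],
            ("H", "N", "C", "O"): [DihedralTerm(k=0.90, n=3, phase=0.0)],
        },
        impropers={
            ("N", "N", "C", "O"): [DihedralTerm(k=10.0, n=2, phase=math.pi,
                                                fit_k=False)],
        },
        lj={
            "N": LJParam(0.17, 3.25),
            "C": LJParam(0.086, 3.40),
            "O": LJParam(0.21, 2.96),
            "H": LJParam(0.015, 1.07),
        },
    )

    keys = top.term_keys()
    meta = {
        "n_units": n_units,
        "stiffness": stiffness,
        "coords": np.array(coords),
        "classes": {
            kind: list(keys[kind])
            for kind in ("bond", "angle", "dihedral", "improper")
        },
    }
    return top, params, meta


def make_diatomic(k: float = 300.0, r_eq: float = 1.5,
                  mass: float = 12.011) -> tuple:
    """Single harmonic bond (two uncharged atoms), for closed-form checks."""
    atoms = [Atom(0, "X", mass, 0.0, True, "C"),
             Atom(1, "X", mass, 0.0, True, "C")]
    top = Topology.from_bonds(atoms, [(0, 1)])
    params = ParameterSet(bonds={("X", "X"): HarmonicParam(k=k, eq=r_eq)},
                          lj={"X": LJParam(0.0, 3.0)})
    return top, params


@dataclass
class GhostSpec:
    """How to sample and label a ghost-Hamiltonian reference dataset."""

    temperature: float = 600.0      # high-T gas-phase protocol
    n_frames: int = 2000
    stride: int = 25                # integrator steps between stored frames
    sigma_energy: float = 0.0       # label noise, kcal/mol
    sigma_force: float = 0.0        # label noise per component, kcal/(mol A)
    seed: int = 0
    friction: float = 1.0           # 1/ps
    dt: float = None                # auto from stiffness heuristic if None
    burn_in: int = 1000             # discarded integrator steps per walker
    n_walkers: int = 40             # independent chains integrated in batch
    reference_level: str = "ghost"

    def __post_init__(self):
        if self.n_frames < 2:
            raise ValueError("need at least two frames")
        if min(self.sigma_energy, self.sigma_force) < 0:
            raise ValueError("label noise must be non-negative")


# sampler mobility uses one effective mass for all atoms: the stationary
# distribution is mass-independent and this keeps dt from being throttled by
# the hydrogens
_SAMPLER_MASS = 12.0


def _auto_dt(params: ParameterSet, friction: float) -> float:
    k_max = max([p.k for p in params.bonds.values()] or [1.0])
    # curvature of k*(r-r0)^2 is 2k; keep dt well under the stability limit
    return 0.05 * _SAMPLER_MASS * friction / (2.0 * k_max)


def ghost_reference_dataset(topology: Topology, params: ParameterSet,
                            spec: GhostSpec = None, x0=None) -> ReferenceDataset:
    """Sample gas-phase frames with overdamped Langevin dynamics under the
    ghost parameters and label them with ghost energies/forces (+ optional
    i.i.d. Gaussian noise)."""
    spec = spec or GhostSpec()
    model = _CompiledModel(topology, params)
    n = topology.n_atoms
    if x0 is None:
        raise ValueError("an initial configuration is required")
    x0 = np.array(x0, dtype=float).reshape(n, 3)

    rng = np.random.default_rng(spec.seed)
    dt = spec.dt if spec.dt is not None else _auto_dt(params, spec.friction)
    mob = dt / (_SAMPLER_MASS * spec.friction)
    sig = math.sqrt(2.0 * KB * spec.temperature * dt
                    / (_SAMPLER_MASS * spec.friction))
    # independent walkers integrated as one batch; each runs its own burn-in
    w = max(1, min(spec.n_walkers, spec.n_frames))
    per_walker = -(-spec.n_frames // w)  # ceil
    x = x0[None] + 0.01 * rng.standard_normal((w, n, 3))
    total = spec.burn_in + per_walker * spec.stride
    chunks = []
    for step in range(1, total + 1):
        _, frc = _evaluate(model, x, True)
        x = x + mob * frc + sig * rng.standard_normal((w, n, 3))
        if not np.all(np.isfinite(x)) or np.max(np.abs(x)) > 1e4:
            raise RuntimeError(f"ghost sampling diverged at step {step}; "
                               f"reduce dt (currently {dt:g} ps)")
        if step > spec.burn_in and (step - spec.burn_in) % spec.stride == 0:
            chunks.append(x.copy())
    # interleave walkers so a truncated prefix still mixes chains
    coords = np.concatenate(chunks, axis=0)[:spec.n_frames]
    comp, forces = _evaluate(model, coords, True)
    energies = sum(comp.values())
    if spec.sigma_energy > 0:
        energies = energies + spec.sigma_energy * rng.standard_normal(
            spec.n_frames)
    if spec.sigma_force > 0:
        forces = forces + spec.sigma_force * rng.standard_normal(forces.shape)
    meta = {
        "temperature": spec.temperature,
        "stride": spec.stride,
        "dt": dt,
        "sigma_energy": spec.sigma_energy,
        "sigma_force": spec.sigma_force,
        "seed": spec.seed,
        "reference_level": spec.reference_level,
        "sampling": "overdamped-langevin gas phase",
    }
    return ReferenceDataset(coords=coords, energies=np.asarray(energies),
                            forces=forces, metadata=meta)


# --------------------------------------------------------------------------
# toy binding samples with an exactly known dG0
# --------------------------------------------------------------------------


@dataclass
class ToyBindingSpec:
    """Radial square well with a contact-number proxy CV.

    The radial PMF is W(rho) = -depth for rho < radius and 0 outside, sampled
    over a sphere of radius ``rho_max``; the contact proxy is
    C(rho) = c_amp / (1 + (rho/r_switch)^6).  The exact standard-state
    binding free energy follows from the configurational integral
    K = (1/V0) * integral over the bound region of exp(-beta W) 4 pi rho^2.
    """

    depth: float = 5.0              # kcal/mol
    radius: float = 5.0             # A
    rho_max: float = 10.0           # A, extent of the sampled sphere
    r_switch: float = 3.0           # A, contact-proxy switching distance
    c_amp: float = 5.0              # contact proxy at rho = 0 is ~c_amp
    temperature: float = 298.0
    v_standard: float = V_STANDARD

    def pmf(self, rho):
        rho = np.asarray(rho, dtype=float)
        return np.where(rho < self.radius, -self.depth, 0.0)

    def contact(self, rho):
        return self.c_amp / (1.0 + (np.asarray(rho, dtype=float)
                                    / self.r_switch) ** 6)

    def exact_dg(self) -> float:
        """Closed-form dG0 of the square well (quadrature-free)."""
        kt = KB * self.temperature
        v_eff = math.exp(self.depth / kt) * (4.0 / 3.0) * math.pi \
            * self.radius ** 3
        return -kt * math.log(v_eff / self.v_standard)


@dataclass
class BindingSamples:
    samples: np.ndarray     # (n, 2) columns (rho, C)
    weights: np.ndarray     # (n,)
    dg_exact: float
    spec: ToyBindingSpec


def make_binding_trajectory(spec: ToyBindingSpec, n_samples: int,
                            seed: int = 0) -> BindingSamples:
    """Draw (rho, C) samples from the exact Boltzmann density of the toy
    binding potential (inverse-CDF sampling of p(rho) ~ exp(-beta W) rho^2)."""
    kt = KB * spec.temperature
    grid = np.linspace(0.0, spec.rho_max, 20001)
    dens = np.exp(-spec.pmf(grid) / kt) * grid ** 2
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1])
                                           * np.diff(grid))])
    cdf /= cdf[-1]
    rng = np.random.default_rng(seed)
    rho = np.interp(rng.random(n_samples), cdf, grid)
    c = spec.contact(rho)
    samples = np.column_stack([rho, c])
    return BindingSamples(samples=samples, weights=np.ones(n_samples),
                          dg_exact=spec.exact_dg(), spec=spec)


def fixture_table1() -> AffinityTable:
    """The packaged reference binding-affinity table (8 rows including the
    two G5 protonation variants, one experimental and four computed columns)."""
    ref = importlib.resources.files("ffmatch") / "data" / "table1.tsv"
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    return AffinityTable(df)
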