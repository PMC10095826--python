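"""Collective variables: switching-function contact numbers, radius of
gyration and COM spherical coordinates.

The contact switching function is s(r) = [1-(r/r0)^6]/[1-(r/r0)^12], which is
algebraically identical to 1/(1+(r/r0)^6); the second form removes the 0/0 at
r = r0 (where the value is exactly 1/2) and is the one evaluated here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "ContactSpec",
    "ContactSeries",
    "switching_value",
    "contact_number",
    "contact_series",
    "classify_contact_map",
    "radius_of_gyration",
    "spherical_cv",
    "center_of_mass",
]


@dataclass
class ContactSpec:
    """Atom groups and switching distance for a contact-number CV.

    ``heavy_only`` (the free-energy-analysis convention) drops hydrogens from
    both groups; monitoring runs may disable it to count all atoms.
    """

    group_a: np.ndarray
    group_b: np.ndarray
    r0: float = 6.0
    heavy_only: bool = True

    def __post_init__(self):
        self.group_a = np.asarray(self.group_a, dtype=int)
        self.group_b = np.asarray(self.group_b, dtype=int)
        if self.r0 <= 0:
            raise ValueError("switching distance r0 must be positive")
        if self.group_a.size == 0 or self.group_b.size == 0:
            raise ValueError("contact groups must be non-empty")
        if np.intersect1d(self.group_a, self.group_b).size:
            raise ValueError("contact groups must be disjoint")


@dataclass
class ContactSeries:
    """Per-frame total contact number and its by-A-atom decomposition."""

    total: np.ndarray          # (F,)
    per_atom: np.ndarray       # (F, len(group_a))
    atoms: np.ndarray          # A-group atom indices the columns refer to
    times: np.ndarray = None   # optional frame labels

    def __post_init__(self):
        if self.times is None:
            self.times = np.arange(len(self.total), dtype=float)


def switching_value(r, r0: float = 6.0):
    """Smooth contact weight in (0, 1]; equals 1/2 at r = r0."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("distances must be non-negative")
    if r0 <= 0:
        raise ValueError("r0 must be positive")
    out = 1.0 / (1.0 + (r / r0) ** 6)
    return float(out) if out.ndim == 0 else out


def _effective_groups(spec: ContactSpec, heavy):
    ga, gb = spec.group_a, spec.group_b
    if spec.heavy_only:
        if heavy is None:
            raise ValueError("heavy-atom flags required when heavy_only is set")
        heavy = np.asarray(heavy, dtype=bool)
        ga = ga[heavy[ga]]
        gb = gb[heavy[gb]]
        if ga.size == 0 or gb.size == 0:
            raise ValueError("a contact group is empty after dropping hydrogens")
    return ga, gb


def contact_number(coords: np.ndarray, spec: ContactSpec, heavy=None):
    """Total contact number C and per-A-atom decomposition C_i for one frame.

    Returns ``(C, c_i)`` with ``c_i`` aligned to ``spec.group_a`` (zero for
    atoms dropped by the heavy-only filter), so ``sum(c_i) == C``.
    """
    coords = np.asarray(coords, dtype=float)
    ga, gb = _effective_groups(spec, heavy)
    d = coords[ga][:, None, :] - coords[gb][None, :, :]
    dist = np.linalg.norm(d, axis=-1)
    s = 1.0 / (1.0 + (dist / spec.r0) ** 6)
    ci_eff = s.sum(axis=1)
    ci = np.zeros(len(spec.group_a))
    pos = {a: m for m, a in enumerate(spec.group_a)}
    for a, v in zip(ga, ci_eff):
        ci[pos[a]] = v
    return float(ci_eff.sum()), ci


def contact_series(traj: np.ndarray, spec: ContactSpec, heavy=None,
                   times=None) -> ContactSeries:
    """Contact numbers over a trajectory (F, N, 3), vectorised over frames."""
    traj = np.asarray(traj, dtype=float)
    ga, gb = _effective_groups(spec, heavy)
    d = traj[:, ga, None, :] - traj[:, None, gb, :]
    dist = np.sqrt(np.einsum("fabi,fabi->fab", d, d))
    s = 1.0 / (1.0 + (dist / spec.r0) ** 6)
    ci_eff = s.sum(axis=2)
    ci = np.zeros((traj.shape[0], len(spec.group_a)))
    pos = {a: m for m, a in enumerate(spec.group_a)}
    for m_eff, a in enumerate(ga):
        ci[:, pos[a]] = ci_eff[:, m_eff]
    return ContactSeries(total=ci_eff.sum(axis=1), per_atom=ci,
                         atoms=spec.group_a.copy(),
                         times=None if times is None else np.asarray(times))


_CONTACT_BINS = ((10.0, "red"), (5.0, "green"), (1.0, "blue"))


def classify_contact_map(values):
    """Categorise per-atom contact numbers: red > 10, green (5,10],
    blue (1,5], white <= 1 (strict lower bounds)."""
    v = np.asarray(values, dtype=float)
    if np.any(v < 0):
        raise ValueError("contact numbers must be non-negative")
    out = np.full(v.shape, "white", dtype=object)
    out[v > 1.0] = "blue"
    out[v > 5.0] = "green"
    out[v > 10.0] = "red"
    return out


def center_of_mass(coords, indices, masses=None):
    idx = np.asarray(indices, dtype=int)
    x = np.asarray(coords, dtype=float)[idx]
    if masses is None:
        return x.mean(axis=0)
    w = np.asarray(masses, dtype=float)[idx]
    return (w[:, None] * x).sum(axis=0) / w.sum()


def radius_of_gyration(coords, indices, masses=None, mass_weighted=True):
    """Rg = sqrt(sum m_i |r_i - r_COM|^2 / sum m_i), in angstrom."""
    idx = np.asarray(indices, dtype=int)
    if idx.size < 2:
        raise ValueError("radius of gyration needs at least two atoms")
    x = np.asarray(coords, dtype=float)[idx]
    if mass_weighted:
        if masses is None:
            raise ValueError("masses required for mass-weighted Rg")
        w = np.asarray(masses, dtype=float)[idx]
    else:
        w = np.ones(idx.size)
    com = (w[:, None] * x).sum(axis=0) / w.sum()
    return float(np.sqrt((w * ((x - com) ** 2).sum(axis=1)).sum() / w.sum()))


def spherical_cv(coords, host_indices, guest_indices, masses=None):
    """(rho, theta, phi) of the guest COM about the host COM, lab frame.

    rho in angstrom, theta the polar angle in [0, pi], phi the azimuth in
    (-pi, pi].  At rho = 0 the angles are undefined and returned as NaN.
    """
    ch = center_of_mass(coords, host_indices, masses)
    cg = center_of_mass(coords, guest_indices, masses)
    v = cg - ch
    rho = float(np.linalg.norm(v))
    if rho == 0.0:
        return 0.0, float("nan"), float("nan")
    theta = float(np.arccos(np.clip(v[2] / rho, -1.0, 1.0)))
    phi = float(np.arctan2(v[1], v[0]))
    if phi <= -np.pi:
        phi += 2 * np.pi
    return rho, theta, phi
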