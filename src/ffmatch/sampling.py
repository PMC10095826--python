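"""Desk-scale stochastic sampling: overdamped Langevin dynamics on analytic
potentials, optionally biased by well-tempered metadynamics.

The integrator is Euler-Maruyama,

    x(t+dt) = x(t) - dt/(m*gamma) * grad U + sqrt(2 kT dt / (m*gamma)) * xi,

with friction gamma in 1/ps and the CVs taken to be the coordinates
themselves.  Deposited Gaussian heights follow the well-tempered decay
h = h0 * exp(-V_bias(s)/(kB * dT)) with dT = (bias_factor - 1) * T, and the
free-energy estimate from the final bias is
F(s) = -gamma_f/(gamma_f - 1) * V_bias(s), shifted to min 0.

Reweighting uses the final-bias (constant offset) approximation:
w(s) proportional to exp(+V_final(s)/kT), normalised to mean 1.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import KB
from .thermo import Axis, FESGrid

__all__ = [
    "ToyPotential",
    "MetadConfig",
    "BiasState",
    "LangevinResult",
    "run_langevin",
    "fes_from_bias",
    "reweight_frames",
    "harmonic_well",
    "double_well_1d",
    "SPHERICAL_WIDTHS",
]

#: Default Gaussian widths for the 3 spherical CVs (rho, theta, phi):
#: 1 A (0.1 nm), pi/16, pi/8.
SPHERICAL_WIDTHS = (1.0, math.pi / 16, math.pi / 8)


@dataclass
class ToyPotential:
    """Analytic potential over 1-3 CVs (kcal/mol over angstrom/radian space)."""

    dim: int
    energy: Callable
    gradient: Callable
    domain: tuple                 # (lo array, hi array) divergence guard
    periodic: tuple = None        # per-dim period or None
    description: str = ""

    def __post_init__(self):
        lo, hi = (np.asarray(b, dtype=float) for b in self.domain)
        if lo.shape != (self.dim,) or hi.shape != (self.dim,):
            raise ValueError("domain bounds must match the dimensionality")
        self.domain = (lo, hi)
        if self.periodic is None:
            self.periodic = (None,) * self.dim


def harmonic_well(k: float = 2.0, center: float = 0.0,
                  half_width: float = 30.0) -> ToyPotential:
    """1D harmonic well U = k/2 (x-c)^2 (position variance kT/k)."""
    c = float(center)
    return ToyPotential(
        dim=1,
        energy=lambda x: 0.5 * k * (x[0] - c) ** 2,
        gradient=lambda x: np.array([k * (x[0] - c)]),
        domain=([c - half_width], [c + half_width]),
        description=f"harmonic(k={k})",
    )


def double_well_1d(barrier: float = 3.0, tilt: float = 0.0,
                   spacing: float = 1.0, half_width: float = 2.5) -> ToyPotential:
    """Quartic double well U = barrier*((x/a)^2-1)^2 + tilt*(x/a).

    Minima near +-a; ``tilt`` != 0 makes the well at -a deeper (for tilt>0).
    """
    a = float(spacing)

    def u(x):
        s = x[0] / a
        return barrier * (s * s - 1.0) ** 2 + tilt * s

    def g(x):
        s = x[0] / a
        return np.array([(4.0 * barrier * s * (s * s - 1.0) + tilt) / a])

    return ToyPotential(dim=1, energy=u, gradient=g,
                        domain=([-half_width * a], [half_width * a]),
                        description=f"double_well(barrier={barrier}, tilt={tilt})")


@dataclass
class MetadConfig:
    """Well-tempered metadynamics settings (defaults follow the production
    protocol: 0.24 kcal/mol initial height, 0.5 ps pace, bias factor 20)."""

    height: float = 0.24
    pace_time: float = 0.5          # ps between depositions
    bias_factor: float = 20.0
    widths: tuple = None            # per-CV Gaussian sigma
    temperature: float = 298.0
    grid_points: int = 1024         # bias grid resolution per dimension

    def __post_init__(self):
        if self.height <= 0:
            raise ValueError("initial Gaussian height must be positive")
        if self.bias_factor <= 1:
            raise ValueError("bias factor must exceed 1")
        if self.widths is not None:
            self.widths = tuple(float(w) for w in self.widths)
            if any(w <= 0 for w in self.widths):
                raise ValueError("Gaussian widths must be positive")

    def resolve_widths(self, dim: int) -> tuple:
        if self.widths is not None:
            if len(self.widths) != dim:
                raise ValueError("widths do not match CV dimensionality")
            return self.widths
        if dim == 3:
            return SPHERICAL_WIDTHS
        raise ValueError("Gaussian widths must be given for non-3D CV sets")


@dataclass
class BiasState:
    """Deposited Gaussians (tempered heights) and the summed bias evaluator."""

    centers: np.ndarray            # (n, d)
    heights: np.ndarray            # (n,) heights after tempering
    widths: np.ndarray             # (d,)
    periodic: tuple = None
    truncate: float = 6.0          # evaluate Gaussians out to this many sigma

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.heights = np.asarray(self.heights, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if self.periodic is None:
            self.periodic = (None,) * self.centers.shape[1]

    @property
    def n_hills(self) -> int:
        return 0 if self.centers.size == 0 else self.centers.shape[0]

    def potential(self, points) -> np.ndarray:
        """Total bias at query points (m, d) -> (m,)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if self.n_hills == 0:
            return np.zeros(pts.shape[0])
        out = np.zeros(pts.shape[0])
        cut2 = self.truncate ** 2
        # chunk over hills to bound memory
        step = max(1, int(2e6 // max(pts.shape[0], 1)))
        for a in range(0, self.n_hills, step):
            c = self.centers[a:a + step]
            d = pts[:, None, :] - c[None, :, :]
            for dim, per in enumerate(self.periodic):
                if per:
                    d[..., dim] -= per * np.round(d[..., dim] / per)
            z2 = np.sum((d / self.widths) ** 2, axis=-1)
            contrib = np.where(z2 < cut2 * len(self.widths),
                               np.exp(-0.5 * z2), 0.0)
            out += contrib @ self.heights[a:a + step]
        return out


@dataclass
class LangevinResult:
    positions: np.ndarray          # (frames, d) strided samples (= CV values)
    times: np.ndarray              # (frames,) in ps
    bias_at_frames: np.ndarray     # bias at each stored frame (0 if unbiased)
    bias: BiasState = None
    deposits: np.ndarray = None    # (n_hills, 2+d): time, height, center...


class _GridBias:
    """Regular-grid accumulator for the bias and its gradient (d <= 2)."""

    def __init__(self, lo, hi, widths, periodic, points):
        self.dim = len(lo)
        self.lo = np.asarray(lo, dtype=float)
        self.hi = np.asarray(hi, dtype=float)
        self.widths = np.asarray(widths, dtype=float)
        self.periodic = periodic
        self.axes = [np.linspace(self.lo[i], self.hi[i], points)
                     for i in range(self.dim)]
        self.h = [ax[1] - ax[0] for ax in self.axes]
        shape = tuple(points for _ in range(self.dim))
        self.v = np.zeros(shape)
        self.g = [np.zeros(shape) for _ in range(self.dim)]

    def deposit(self, center, height):
        dists = []
        for i, ax in enumerate(self.axes):
            d = ax - center[i]
            if self.periodic[i]:
                per = self.periodic[i]
                d -= per * np.round(d / per)
            dists.append(d)
        if self.dim == 1:
            d = dists[0]
            gauss = height * np.exp(-0.5 * (d / self.widths[0]) ** 2)
            self.v += gauss
            self.g[0] += gauss * (-d / self.widths[0] ** 2)
        else:
            z = [np.exp(-0.5 * (d / w) ** 2)
                 for d, w in zip(dists, self.widths)]
            gauss = height * z[0][:, None] * z[1][None, :]
            self.v += gauss
            self.g[0] += gauss * (-dists[0] / self.widths[0] ** 2)[:, None]
            self.g[1] += gauss * (-dists[1] / self.widths[1] ** 2)[None, :]

    def value_grad(self, x):
        # nearest-node lookup is enough for the integrator force; values for
        # tempering use linear interpolation along each axis
        if self.dim == 1:
            t = (x[0] - self.lo[0]) / self.h[0]
            i = int(t)
            i = min(max(i, 0), self.v.shape[0] - 2)
            f = t - i
            v = self.v[i] * (1 - f) + self.v[i + 1] * f
            g = self.g[0][i] * (1 - f) + self.g[0][i + 1] * f
            return v, np.array([g])
        idx = []
        frac = []
        for k in range(self.dim):
            t = (x[k] - self.lo[k]) / self.h[k]
            i = int(min(max(t, 0), self.v.shape[k] - 2))
            idx.append(i)
            frac.append(t - i)
        i, j = idx
        fx, fy = frac
        def bilin(a):
            return (a[i, j] * (1 - fx) * (1 - fy) + a[i + 1, j] * fx * (1 - fy)
                    + a[i, j + 1] * (1 - fx) * fy + a[i + 1, j + 1] * fx * fy)
        return bilin(self.v), np.array([bilin(self.g[0]), bilin(self.g[1])])


def run_langevin(potential: ToyPotential, steps: int, dt: float,
                 friction: float = 1.0, temperature: float = 298.0,
                 seed: int = 0, mass: float = 1.0,
                 metad: MetadConfig = None, x0=None,
                 stride: int = 1) -> LangevinResult:
    """Integrate overdamped Langevin dynamics, optionally with WTMetaD bias.

    Stability heuristic: dt should not exceed ~0.1 * m * friction / k_max for
    the stiffest mode.  Trajectories are reproducible for a fixed seed; with
    no bias the samples converge to Boltzmann statistics of the potential.
    """
    d = potential.dim
    lo, hi = potential.domain
    x = np.array(x0, dtype=float) if x0 is not None else 0.5 * (lo + hi)
    if x.shape != (d,):
        raise ValueError("x0 must match the potential dimensionality")
    rng = np.random.default_rng(seed)
    mob = dt / (mass * friction)
    sigma = math.sqrt(2.0 * KB * temperature * dt / (mass * friction))

    grid = None
    hills_c, hills_h, hills_t = [], [], []
    pace = 0
    dT = 0.0
    widths = None
    if metad is not None:
        widths = np.asarray(metad.resolve_widths(d), dtype=float)
        pace = max(1, int(round(metad.pace_time / dt)))
        dT = (metad.bias_factor - 1.0) * metad.temperature
        if d <= 2:
            grid = _GridBias(lo, hi, widths, potential.periodic,
                             metad.grid_points)

    n_frames = steps // stride
    frames = np.empty((n_frames, d))
    frame_bias = np.zeros(n_frames)
    times = (np.arange(n_frames) + 1) * stride * dt

    energy_grad = potential.gradient
    periodic = potential.periodic
    fi = 0
    if d == 1 and grid is not None or (d == 1 and metad is None):
        # scalar fast path
        xs = float(x[0])
        lo0, hi0 = float(lo[0]), float(hi[0])
        per0 = periodic[0]
        noise = None
        block = 65536
        for step in range(1, steps + 1):
            k = (step - 1) % block
            if k == 0:
                noise = rng.standard_normal(min(block, steps - step + 1))
            gb = 0.0
            if grid is not None:
                _, gvec = grid.value_grad(np.array([xs]))
                gb = gvec[0]
            gu = energy_grad(np.array([xs]))[0]
            xs = xs - mob * (gu + gb) + sigma * noise[k]
            if per0:
                span = hi0 - lo0
                if xs < lo0:
                    xs += span
                elif xs >= hi0:
                    xs -= span
            elif xs < lo0 or xs > hi0:
                raise RuntimeError(
                    f"trajectory diverged outside the domain at step {step}")
            if grid is not None and step % pace == 0:
                vb, _ = grid.value_grad(np.array([xs]))
                h = metad.height * math.exp(-vb / (KB * dT))
                grid.deposit(np.array([xs]), h)
                hills_c.append([xs])
                hills_h.append(h)
                hills_t.append(step * dt)
            if step % stride == 0:
                frames[fi, 0] = xs
                if grid is not None:
                    frame_bias[fi], _ = grid.value_grad(np.array([xs]))
                fi += 1
    else:
        bias_state_dyn = BiasState(np.empty((0, d)), np.empty(0),
                                   widths if widths is not None else np.ones(d),
                                   periodic=periodic)
        for step in range(1, steps + 1):
            gu = np.asarray(energy_grad(x), dtype=float)
            gb = np.zeros(d)
            vb = 0.0
            if metad is not None:
                if grid is not None:
                    vb, gb = grid.value_grad(x)
                elif bias_state_dyn.n_hills:
                    vb, gb = _hills_value_grad(bias_state_dyn, x)
            x = x - mob * (gu + gb) + sigma * rng.standard_normal(d)
            for dim in range(d):
                if periodic[dim]:
                    span = hi[dim] - lo[dim]
                    x[dim] = lo[dim] + (x[dim] - lo[dim]) % span
                elif x[dim] < lo[dim] or x[dim] > hi[dim]:
                    raise RuntimeError(
                        f"trajectory diverged outside the domain at step {step}")
            if metad is not None and step % pace == 0:
                if grid is not None:
                    vb, _ = grid.value_grad(x)
                elif bias_state_dyn.n_hills:
                    vb, _ = _hills_value_grad(bias_state_dyn, x)
                else:
                    vb = 0.0
                h = metad.height * math.exp(-vb / (KB * dT))
                if grid is not None:
                    grid.deposit(x, h)
                else:
                    bias_state_dyn.centers = np.vstack([bias_state_dyn.centers, x])
                    bias_state_dyn.heights = np.append(bias_state_dyn.heights, h)
                hills_c.append(x.copy())
                hills_h.append(h)
                hills_t.append(step * dt)
            if step % stride == 0:
                frames[fi] = x
                if metad is not None:
                    if grid is not None:
                        frame_bias[fi], _ = grid.value_grad(x)
                    elif bias_state_dyn.n_hills:
                        frame_bias[fi], _ = _hills_value_grad(bias_state_dyn, x)
                fi += 1

    bias = None
    deposits = None
    if metad is not None:
        centers = np.array(hills_c).reshape(-1, d)
        heights = np.array(hills_h)
        per = tuple((hi[i] - lo[i]) if periodic[i] else None for i in range(d))
        bias = BiasState(centers, heights, widths, periodic=per)
        deposits = np.column_stack([np.array(hills_t), heights, centers]) \
            if len(hills_h) else np.empty((0, 2 + d))
    return LangevinResult(positions=frames, times=times,
                          bias_at_frames=frame_bias, bias=bias,
                          deposits=deposits)


def _hills_value_grad(bias: BiasState, x):
    d = x[None, :] - bias.centers
    for dim, per in enumerate(bias.periodic):
        if per:
            d[:, dim] -= per * np.round(d[:, dim] / per)
    z = d / bias.widths
    e = np.exp(-0.5 * np.sum(z * z, axis=1)) * bias.heights
    v = float(e.sum())
    g = -(e[:, None] * d / bias.widths**2).sum(axis=0)
    return v, g


def fes_from_bias(bias: BiasState, axes: Sequence[Axis], bias_factor: float,
                  temperature: float = 298.0) -> FESGrid:
    """Free-energy surface from the final well-tempered bias:
    F(s) = -gamma/(gamma-1) * V_bias(s), shifted to min 0."""
    if bias.n_hills == 0:
        raise ValueError("no Gaussians deposited; cannot estimate a surface")
    centers = [ax.centers for ax in axes]
    mesh = np.meshgrid(*centers, indexing="ij")
    pts = np.column_stack([m.ravel() for m in mesh])
    v = bias.potential(pts).reshape(mesh[0].shape)
    factor = bias_factor / (bias_factor - 1.0)
    values = -factor * v
    return FESGrid(list(axes), values, mask=np.ones_like(values, dtype=bool))


def reweight_frames(cvs, bias: BiasState, temperature: float) -> np.ndarray:
    """Per-frame unbiasing weights under the final-bias approximation.

    w_i proportional to exp(+V_final(s_i)/kT), normalised to mean 1; the
    largest exponent is shifted out before exponentiation.
    """
    pts = np.atleast_2d(np.asarray(cvs, dtype=float))
    v = bias.potential(pts)
    kt = KB * temperature
    w = np.exp((v - v.max()) / kt)
    return w / w.mean()
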