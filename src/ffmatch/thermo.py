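"""Free-energy surfaces over collective variables and standard-state binding
free energies.

The binding estimator is the two-term form

    dG0 = [F(global minimum) - F(zero-contact decoupled state)]
          + kT * ln(V_u / V0)

with V0 the standard-state volume (1660.54 A^3) and V_u the geometric volume
of the sampled decoupled shell.  The bound-state value is the single lowest
FES bin (not a basin integral), and the decoupled value is the sample-
weighted mean over the low-contact/large-radius region.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constants import KB, V_STANDARD

__all__ = [
    "Axis",
    "FESGrid",
    "StandardStateSpec",
    "DecoupledState",
    "BindingFreeEnergy",
    "build_fes",
    "find_global_min",
    "decoupled_state_value",
    "binding_free_energy",
    "block_sd",
]


@dataclass
class Axis:
    name: str
    edges: np.ndarray
    periodic: bool = False

    def __post_init__(self):
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or self.edges.size < 2:
            raise ValueError("axis needs at least two bin edges")
        if np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.edges)

    @classmethod
    def regular(cls, name, lo, hi, nbins, periodic=False):
        return cls(name, np.linspace(lo, hi, nbins + 1), periodic)


@dataclass
class FESGrid:
    """Gridded free energy over 1-2 CVs, zeroed at its masked minimum.

    ``values`` are kcal/mol where ``mask`` is true and meaningless elsewhere;
    ``counts`` holds the (weighted) sample count behind each bin (zero for
    surfaces built from a bias potential rather than samples).
    """

    axes: list
    values: np.ndarray
    mask: np.ndarray = None
    counts: np.ndarray = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        shape = tuple(len(ax.centers) for ax in self.axes)
        if self.values.shape != shape:
            raise ValueError(f"values shape {self.values.shape} != grid {shape}")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.counts is None:
            self.counts = np.zeros(shape)
        if not self.mask.any():
            raise ValueError("free-energy grid has no populated bins")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("non-finite free energy inside the mask")
        # zero convention: min over masked bins = 0
        self.values = self.values - self.values[self.mask].min()

    @property
    def ndim(self) -> int:
        return len(self.axes)

    def axis(self, name_or_index):
        if isinstance(name_or_index, int):
            return self.axes[name_or_index]
        for ax in self.axes:
            if ax.name == name_or_index:
                return ax
        raise KeyError(f"no axis named {name_or_index!r}")


@dataclass
class StandardStateSpec:
    """Standard-state volume, temperature and (optional) sampled unbound
    volume; when ``sampled_volume`` is None the decoupled-region shell volume
    measured from the FES is used."""

    v_standard: float = V_STANDARD
    temperature: float = 298.0
    sampled_volume: float = None

    def __post_init__(self):
        if self.v_standard <= 0 or self.temperature <= 0:
            raise ValueError("standard-state volume and temperature must be positive")
        if self.sampled_volume is not None and self.sampled_volume <= 0:
            raise ValueError("sampled unbound volume must be positive")


def build_fes(samples, axes: Sequence[Axis], temperature: float,
              weights=None) -> FESGrid:
    """Weighted-histogram free-energy surface.

    F(bin) = -kT ln(weighted count / max weighted count), shifted so the
    minimum over populated bins is zero; unpopulated bins are masked.
    """
    samples = np.atleast_2d(np.asarray(samples, dtype=float))
    if samples.shape[1] != len(axes):
        raise ValueError("sample dimensionality does not match axes")
    hist, _ = np.histogramdd(samples, bins=[ax.edges for ax in axes],
                             weights=weights)
    if hist.sum() == 0:
        raise ValueError("no samples fall inside the grid")
    mask = hist > 0
    values = np.full(hist.shape, np.inf)
    values[mask] = -KB * temperature * np.log(hist[mask] / hist.max())
    return FESGrid(list(axes), values, mask=mask, counts=hist)


def find_global_min(fes: FESGrid):
    """Lowest masked bin; ties broken by the lowest flattened index."""
    flat = np.where(fes.mask.ravel(), fes.values.ravel(), np.inf)
    i = int(np.argmin(flat))
    return np.unravel_index(i, fes.values.shape), float(flat[i])


@dataclass
class DecoupledState:
    value: float        # sample-weighted mean free energy of the region
    volume: float       # geometric 3D volume proxy of the sampled shell, A^3
    n_bins: int


def decoupled_state_value(fes: FESGrid, contact_threshold: float = 0.01,
                          rho_min: float = 0.0, rho_axis=0,
                          contact_axis=1) -> DecoupledState:
    """Reference free energy of the zero-contact decoupled state.

    The region is {C < contact_threshold, rho > rho_min} over a (rho, C)
    surface.  Returns its count-weighted mean free energy and the geometric
    volume 4*pi*rho^2*drho summed over the radial bins present, which serves
    as V_u for the standard-state correction.
    """
    if fes.ndim != 2:
        raise ValueError("decoupled state requires a 2-D (rho, contact) surface")
    rho_ax = fes.axis(rho_axis)
    c_ax = fes.axis(contact_axis)
    i_rho = fes.axes.index(rho_ax)
    i_c = fes.axes.index(c_ax)
    if rho_min >= rho_ax.edges[-1]:
        raise ValueError("rho_min lies beyond the grid; extend the grid or "
                         "sample farther out")
    sel_rho = rho_ax.centers > rho_min
    sel_c = c_ax.centers < contact_threshold
    region = fes.mask.copy()
    region &= sel_rho[:, None] if i_rho == 0 else sel_rho[None, :]
    region &= sel_c[:, None] if i_c == 0 else sel_c[None, :]
    if not region.any():
        raise ValueError(
            "no populated bins in the decoupled region; sample longer or "
            "extend the grid / loosen the contact threshold")
    w = fes.counts[region]
    if w.sum() <= 0:
        w = np.ones_like(w)
    value = float(np.average(fes.values[region], weights=w))
    rho_bins = np.unique(np.nonzero(region)[i_rho])
    volume = float(np.sum(4.0 * np.pi * rho_ax.centers[rho_bins] ** 2
                          * rho_ax.widths[rho_bins]))
    return DecoupledState(value=value, volume=volume, n_bins=int(region.sum()))


@dataclass
class BindingFreeEnergy:
    dg: float            # standard-state binding free energy, kcal/mol
    f_min: float
    f_decoupled: float
    correction: float    # kT ln(V_u/V0)
    v_unbound: float
    min_bin: tuple


def binding_free_energy(fes: FESGrid, std_state: StandardStateSpec = None,
                        contact_threshold: float = 0.01, rho_min: float = 0.0,
                        rho_axis=0, contact_axis=1) -> BindingFreeEnergy:
    """Two-term standard-state binding free energy (negative = favorable)."""
    std_state = std_state or StandardStateSpec()
    min_bin, f_min = find_global_min(fes)
    dec = decoupled_state_value(fes, contact_threshold, rho_min,
                                rho_axis, contact_axis)
    v_u = std_state.sampled_volume if std_state.sampled_volume is not None \
        else dec.volume
    corr = KB * std_state.temperature * np.log(v_u / std_state.v_standard)
    return BindingFreeEnergy(
        dg=float(f_min - dec.value + corr), f_min=f_min, f_decoupled=dec.value,
        correction=float(corr), v_unbound=float(v_u), min_bin=min_bin)


def block_sd(samples, n_blocks: int, estimator: Callable) -> float:
    """Standard deviation (ddof=1) of an estimator over contiguous blocks."""
    samples = np.asarray(samples)
    if n_blocks < 2:
        raise ValueError("need at least two blocks")
    if len(samples) < n_blocks:
        raise ValueError("fewer samples than blocks")
    blocks = np.array_split(samples, n_blocks)
    vals = np.array([estimator(b) for b in blocks], dtype=float)
    return float(np.std(vals, ddof=1))
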