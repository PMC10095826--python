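"""Plain-text serialization: multi-frame XYZ, topology/parameter YAML,
reference datasets, free-energy grids, hills files and index groups.

Conventions: atom indices are 0-based in memory and 1-based in files; floats
are written with ``repr`` precision, so YAML round trips are exact well
beyond 12 significant digits.
"""

from __future__ import annotations

import numpy as np
import yaml

from .fitting import ReferenceDataset
from .mm import (Atom, DihedralTerm, HarmonicParam, LJParam, ParameterSet,
                 Topology)
from .sampling import BiasState
from .thermo import Axis, FESGrid

def _r(x) -> str:
    """repr of a Python float (exact round trip; numpy scalars normalised)."""
    return repr(float(x))


__all__ = [
    "write_xyz", "read_xyz",
    "save_system", "load_system",
    "write_reference_dataset", "read_reference_dataset",
    "write_fes", "read_fes",
    "write_hills", "read_hills",
    "read_groups", "write_groups",
]


# --------------------------------------------------------------------------
# XYZ trajectories
# --------------------------------------------------------------------------


def write_xyz(path, coords, elements, energies=None):
    """Multi-frame XYZ; the comment line carries the frame index and,
    optionally, an energy in kcal/mol."""
    coords = np.atleast_3d(np.asarray(coords, dtype=float))
    if coords.ndim == 2:
        coords = coords[None]
    with open(path, "w") as fh:
        for f, frame in enumerate(coords):
            fh.write(f"{len(elements)}\n")
            comment = f"frame={f}"
            if energies is not None:
                comment += f" energy={_r(energies[f])}"
            fh.write(comment + "\n")
            for el, (x, y, z) in zip(elements, frame):
                fh.write(f"{el} {_r(x)} {_r(y)} {_r(z)}\n")


def read_xyz(path):
    """Returns (coords (F,N,3), elements, energies-or-None)."""
    frames, energies = [], []
    elements = None
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        comment = lines[i + 1]
        e = None
        for tok in comment.split():
            if tok.startswith("energy="):
                e = float(tok[7:])
        energies.append(e)
        els, xyz = [], []
        for row in lines[i + 2:i + 2 + n]:
            parts = row.split()
            els.append(parts[0])
            xyz.append([float(v) for v in parts[1:4]])
        if elements is None:
            elements = els
        frames.append(xyz)
        i += 2 + n
    coords = np.array(frames)
    ee = None if any(e is None for e in energies) else np.array(energies)
    return coords, elements, ee


# --------------------------------------------------------------------------
# topology + parameter set (YAML)
# --------------------------------------------------------------------------


def save_system(path, topology: Topology, params: ParameterSet = None):
    doc = {"topology": {
        "atoms": [{"index": a.index + 1, "type": a.type, "mass": a.mass,
                   "charge": a.charge, "heavy": a.heavy, "element": a.element}
                  for a in topology.atoms],
        "bonds": [[i + 1, j + 1] for i, j in topology.bonds],
        "angles": [[i + 1 for i in t] for t in topology.angles],
        "dihedrals": [[i + 1 for i in t] for t in topology.dihedrals],
        "impropers": [[i + 1 for i in t] for t in topology.impropers],
    }}
    if params is not None:
        doc["parameters"] = {
            "bonds": [{"types": list(k), "k": p.k, "eq": p.eq,
                       "fit_k": p.fit_k, "fit_eq": p.fit_eq}
                      for k, p in sorted(params.bonds.items())],
            "angles": [{"types": list(k), "k": p.k, "eq": p.eq,
                        "fit_k": p.fit_k, "fit_eq": p.fit_eq}
                       for k, p in sorted(params.angles.items())],
            "dihedrals": [{"types": list(k),
                           "terms": [{"k": t.k, "n": int(t.n),
                                      "phase": t.phase, "fit_k": t.fit_k}
                                     for t in terms]}
                          for k, terms in sorted(params.dihedrals.items())],
            "impropers": [{"types": list(k),
                           "terms": [{"k": t.k, "n": int(t.n),
                                      "phase": t.phase, "fit_k": t.fit_k}
                                     for t in terms]}
                          for k, terms in sorted(params.impropers.items())],
            "lj": [{"type": k, "epsilon": p.epsilon, "sigma": p.sigma}
                   for k, p in sorted(params.lj.items())],
            "scale14_elec": params.scale14_elec,
            "scale14_vdw": params.scale14_vdw,
        }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_system(path):
    """Returns (topology, parameters-or-None)."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    t = doc["topology"]
    atoms = [Atom(a["index"] - 1, a["type"], a["mass"], a["charge"],
                  a.get("heavy", True), a.get("element", ""))
             for a in t["atoms"]]
    top = Topology(
        atoms,
        [tuple(i - 1 for i in b) for b in t["bonds"]],
        [tuple(i - 1 for i in b) for b in t.get("angles", [])],
        [tuple(i - 1 for i in b) for b in t.get("dihedrals", [])],
        [tuple(i - 1 for i in b) for b in t.get("impropers", [])],
    )
    params = None
    if "parameters" in doc:
        p = doc["parameters"]
        params = ParameterSet(
            bonds={tuple(e["types"]): HarmonicParam(e["k"], e["eq"],
                                                    e.get("fit_k", True),
                                                    e.get("fit_eq", True))
                   for e in p.get("bonds", [])},
            angles={tuple(e["types"]): HarmonicParam(e["k"], e["eq"],
                                                     e.get("fit_k", True),
                                                     e.get("fit_eq", True))
                    for e in p.get("angles", [])},
            dihedrals={tuple(e["types"]):
                       [DihedralTerm(x["k"], x["n"], x.get("phase", 0.0),
                                     x.get("fit_k", True))
                        for x in e["terms"]]
                       for e in p.get("dihedrals", [])},
            impropers={tuple(e["types"]):
                       [DihedralTerm(x["k"], x["n"], x.get("phase", 0.0),
                                     x.get("fit_k", False))
                        for x in e["terms"]]
                       for e in p.get("impropers", [])},
            lj={e["type"]: LJParam(e["epsilon"], e["sigma"])
                for e in p.get("lj", [])},
            scale14_elec=p.get("scale14_elec", 1.0 / 1.2),
            scale14_vdw=p.get("scale14_vdw", 0.5),
        )
    return top, params


# --------------------------------------------------------------------------
# reference datasets (XYZ + columnar labels)
# --------------------------------------------------------------------------


def write_reference_dataset(stem, dataset: ReferenceDataset, elements):
    """Write <stem>.xyz, <stem>.energies.tsv and <stem>.forces.tsv.

    Units: coordinates A, energies kcal/mol, forces kcal/(mol A).  Metadata
    (temperature, stride, seed, reference level, noise) goes in the header.
    """
    stem = str(stem)
    write_xyz(stem + ".xyz", dataset.coords, elements, dataset.energies)
    header = "".join(f"# {k}: {v}\n" for k, v in sorted(dataset.metadata.items()))
    with open(stem + ".energies.tsv", "w") as fh:
        fh.write("# reference energies, kcal/mol\n" + header)
        fh.write("frame\tenergy\n")
        for f, e in enumerate(dataset.energies):
            fh.write(f"{f}\t{_r(e)}\n")
    with open(stem + ".forces.tsv", "w") as fh:
        fh.write("# reference forces, kcal/(mol A)\n" + header)
        fh.write("frame\tatom\tfx\tfy\tfz\n")
        for f, frame in enumerate(dataset.forces):
            for a, (x, y, z) in enumerate(frame):
                fh.write(f"{f}\t{a + 1}\t{_r(x)}\t{_r(y)}\t{_r(z)}\n")


def read_reference_dataset(stem) -> ReferenceDataset:
    stem = str(stem)
    coords, _, _ = read_xyz(stem + ".xyz")
    meta = {}
    energies = []
    with open(stem + ".energies.tsv") as fh:
        for line in fh:
            if line.startswith("#"):
                if ":" in line:
                    k, _, v = line[1:].partition(":")
                    meta[k.strip()] = v.strip()
                continue
            parts = line.split()
            if parts and parts[0] != "frame":
                energies.append(float(parts[1]))
    forces = np.zeros_like(coords)
    with open(stem + ".forces.tsv") as fh:
        for line in fh:
            if line.startswith("#") or line.startswith("frame"):
                continue
            parts = line.split()
            if len(parts) == 5:
                f, a = int(parts[0]), int(parts[1]) - 1
                forces[f, a] = [float(v) for v in parts[2:5]]
    return ReferenceDataset(coords=coords, energies=np.array(energies),
                            forces=forces, metadata=meta)


# --------------------------------------------------------------------------
# FES grids, hills, index groups
# --------------------------------------------------------------------------


def write_fes(path, fes: FESGrid):
    """Axis headers + free-energy matrix (kcal/mol); masked bins are NaN;
    a second matrix holds the per-bin sample counts."""
    with open(path, "w") as fh:
        fh.write("# free energy surface, kcal/mol; masked bins = nan\n")
        for ax in fes.axes:
            fh.write(f"# axis {ax.name} {_r(ax.edges[0])} {_r(ax.edges[-1])} "
                     f"{len(ax.centers)} periodic={int(ax.periodic)}\n")
        vals = np.where(fes.mask, fes.values, np.nan)
        mat = np.atleast_2d(vals)
        for row in mat:
            fh.write(" ".join(_r(v) for v in row) + "\n")
        fh.write("# counts\n")
        for row in np.atleast_2d(fes.counts):
            fh.write(" ".join(_r(v) for v in row) + "\n")


def read_fes(path) -> FESGrid:
    axes, rows, counts = [], [], []
    target = rows
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# axis"):
                parts = line.split()
                axes.append(Axis.regular(parts[2], float(parts[3]),
                                         float(parts[4]), int(parts[5]),
                                         periodic=parts[6] == "periodic=1"))
            elif line.startswith("# counts"):
                target = counts
            elif line.startswith("#") or not line:
                continue
            else:
                target.append([float(v) for v in line.split()])
    shape = tuple(len(ax.centers) for ax in axes)
    values = np.array(rows).reshape(shape)
    cts = np.array(counts).reshape(shape) if counts else None
    return FESGrid(axes, values, mask=np.isfinite(values), counts=cts)


def write_hills(path, bias: BiasState):
    d = bias.centers.shape[1]
    with open(path, "w") as fh:
        fh.write("# deposited Gaussians: height then center per CV; widths: "
                 + " ".join(_r(w) for w in bias.widths) + "\n")
        fh.write("# periodic: " + " ".join(str(p) for p in bias.periodic) + "\n")
        for h, c in zip(bias.heights, bias.centers):
            fh.write(_r(h) + " " + " ".join(_r(v) for v in c) + "\n")


def read_hills(path) -> BiasState:
    widths = periodic = None
    heights, centers = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("# deposited"):
                widths = [float(v) for v in line.split(":")[-1].split()]
            elif line.startswith("# periodic"):
                periodic = tuple(None if v == "None" else float(v)
                                 for v in line.split(":")[-1].split())
            elif line.strip() and not line.startswith("#"):
                parts = [float(v) for v in line.split()]
                heights.append(parts[0])
                centers.append(parts[1:])
    return BiasState(np.array(centers), np.array(heights), np.array(widths),
                     periodic=periodic)


def write_groups(path, groups: dict):
    with open(path, "w") as fh:
        fh.write("# named atom index groups, 1-based\n")
        for name, idx in groups.items():
            fh.write(f"{name}: " + " ".join(str(i + 1) for i in idx) + "\n")


def read_groups(path) -> dict:
    out = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, _, rest = line.partition(":")
            out[name.strip()] = np.array([int(v) - 1 for v in rest.split()])
    return out
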