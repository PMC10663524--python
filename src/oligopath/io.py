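"""File adapters: spectrum/decay CSV, hole-spec JSON/YAML, multi-MODEL PDB.

The spectrum CSV layout places the f2 ppm axis on the first row and the
f1 ppm axis in the first column (top-left cell blank), so the file opens
meaningfully in any spreadsheet.  Trajectories are exchanged as
multi-MODEL PDB via MDAnalysis; residue/atom naming is preserved, which
is all the geometric analyses need.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .md import GlycineHoleSpec, TrajectoryFrames
from .pithirds import DecayCurve
from .spectra import Spectrum2D

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_decay_csv",
    "write_decay_csv",
    "load_hole_specs",
    "dump_hole_specs",
    "traj_to_pdb",
    "traj_from_pdb",
]


def write_spectrum_csv(spectrum: Spectrum2D, path) -> None:
    n2 = spectrum.axis_f2.size
    header = np.concatenate([[np.nan], spectrum.axis_f2])
    body = np.column_stack([spectrum.axis_f1, spectrum.intensity])
    out = np.vstack([header, body])
    np.savetxt(path, out, delimiter=",", fmt="%.8g")


def read_spectrum_csv(path, label: str | None = None) -> Spectrum2D:
    raw = np.loadtxt(path, delimiter=",")
    axis_f2 = raw[0, 1:]
    axis_f1 = raw[1:, 0]
    return Spectrum2D(axis_f1, axis_f2, raw[1:, 1:],
                      label=label if label is not None else str(path))


def write_decay_csv(curve: DecayCurve, path) -> None:
    df = pd.DataFrame({"t_ms": curve.t, "y": curve.y})
    if curve.y_err is not None:
        df["y_err"] = curve.y_err
    df.to_csv(path, index=False)


def read_decay_csv(path, label: str | None = None) -> DecayCurve:
    df = pd.read_csv(path)
    return DecayCurve(
        t=df["t_ms"].to_numpy(),
        y=df["y"].to_numpy(),
        y_err=df["y_err"].to_numpy() if "y_err" in df.columns else None,
        label=label if label is not None else str(path),
    )


def _spec_to_dict(spec: GlycineHoleSpec) -> dict:
    return {
        "hole_type": spec.hole_type,
        "gly_residues": [list(x) for x in spec.gly_residues],
        "lining_sidechains": [list(x) for x in spec.lining_sidechains],
        "proximity_cutoff": spec.proximity_cutoff,
        "label": spec.label,
    }


def dump_hole_specs(specs, path) -> None:
    """Write hole specs as JSON (.json) or YAML (anything else)."""
    data = [_spec_to_dict(s) for s in specs]
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=1))
    else:
        path.write_text(yaml.safe_dump(data))


def load_hole_specs(path) -> list[GlycineHoleSpec]:
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return [
        GlycineHoleSpec(
            hole_type=d["hole_type"],
            gly_residues=tuple(tuple(x) for x in d["gly_residues"]),
            lining_sidechains=tuple(tuple(x) for x in d["lining_sidechains"]),
            proximity_cutoff=d.get("proximity_cutoff", 5.0),
            label=d.get("label", ""),
        )
        for d in data
    ]


def _guess_element(name: str) -> str:
    for ch in name:
        if ch.isalpha():
            return ch.upper()
    return "X"


def traj_to_pdb(traj: TrajectoryFrames, path) -> None:
    """Write a trajectory as a multi-MODEL PDB file."""
    import MDAnalysis as mda

    top = traj.topology
    n_atoms = len(top)
    res_keys = list(dict.fromkeys(zip(top["chain"], top["resid"], top["resname"])))
    res_index = {k: i for i, k in enumerate(res_keys)}
    atom_resindex = np.array([
        res_index[(c, r, rn)]
        for c, r, rn in zip(top["chain"], top["resid"], top["resname"])
    ])
    seg_keys = list(dict.fromkeys(k[0] for k in res_keys))
    seg_index = {c: i for i, c in enumerate(seg_keys)}
    res_segindex = np.array([seg_index[k[0]] for k in res_keys])

    u = mda.Universe.empty(
        n_atoms, n_residues=len(res_keys), n_segments=len(seg_keys),
        atom_resindex=atom_resindex, residue_segindex=res_segindex,
        trajectory=True,
    )
    u.add_TopologyAttr("names", top["name"].tolist())
    u.add_TopologyAttr("elements", [_guess_element(n) for n in top["name"]])
    u.add_TopologyAttr("resnames", [k[2] for k in res_keys])
    u.add_TopologyAttr("resids", [int(k[1]) for k in res_keys])
    u.add_TopologyAttr("chainIDs", top["chain"].astype(str).tolist())
    u.add_TopologyAttr("segids", [str(c) for c in seg_keys])
    u.load_new(traj.coords.astype(np.float32), order="fac")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        with mda.Writer(str(path), n_atoms, multiframe=True) as w:
            for _ in u.trajectory:
                w.write(u.atoms)


def traj_from_pdb(path, dt_ns: float = 0.1) -> TrajectoryFrames:
    """Read a multi-MODEL PDB into :class:`TrajectoryFrames`.

    PDB files carry no time axis; frame times are ``dt_ns`` apart.
    """
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path))
        coords = np.stack([u.atoms.positions.copy() for _ in u.trajectory])
    chains = (u.atoms.chainIDs if hasattr(u.atoms, "chainIDs")
              else u.atoms.segids)
    top = pd.DataFrame({
        "name": u.atoms.names,
        "resname": u.atoms.resnames,
        "resid": u.atoms.resids,
        "chain": chains,
    })
    times = np.arange(coords.shape[0]) * dt_ns
    return TrajectoryFrames(topology=top, coords=coords.astype(float), times=times)
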