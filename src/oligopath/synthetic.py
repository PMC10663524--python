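"""Synthetic fixtures with known ground truth for every pipeline stage.

Three generators are provided:

* :func:`gen_spectrum_pair` — pairs of 2D Gaussian-crosspeak spectra with
  controlled per-peak ppm shifts, amplitude scaling and noise, for
  validating the inter-spectrum RMSD procedure;
* :func:`gen_decay` — near-Lorentzian decay curves with Gaussian noise at
  the experimental time grid (0–61.4 ms), for parameter-recovery studies;
* :func:`gen_toy_system` — an idealized antiparallel β-sheet tetramer
  (residues 30–42 of Aβ42, Cα spacing 3.8 Å along the strand, 4.8 Å
  between strands) with bead-chain detergents, in which glycine-hole
  filling events, backbone hydrogen bonds and micelle cluster splits are
  *planted* with exact ground truth.

The toy geometry is schematic: ideal strand lattices with named backbone
(N, H, CA, C, O) and Cβ atoms, and 12-carbon bead detergents.  The
analyses it feeds depend only on distances and atom names, not on
force-field realism.  The antiparallel registry aligns Gly33 with Gly38 of
the adjacent strand (and Val36 with Met35), as in the tetramer the
analyses target, so the glycine holes of the lattice carry the same
flanking aliphatic sidechains (Ile32, Leu34, Val36, Val39/40) that line
the holes in the real structure.

Every generator is deterministic given its recipe seed, and truth records
round-trip through JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .md import GlycineHoleSpec, TrajectoryFrames
from .pithirds import DecayCurve, near_lorentzian
from .spectra import Spectrum2D

__all__ = [
    "SpectrumRecipe",
    "DecayRecipe",
    "ToySystemRecipe",
    "ToySystemTruth",
    "default_peaks",
    "gen_spectrum",
    "gen_spectrum_pair",
    "gen_decay",
    "default_hole_specs",
    "gen_toy_system",
]

# ---------------------------------------------------------------------------
# 2D spectra

def default_peaks() -> list[tuple[float, float, float, float, float]]:
    """A small aliphatic/CA-region crosspeak list (c1, c2, amp, s1, s2)."""
    return [
        (58.3, 32.6, 100.0, 0.5, 0.5),
        (52.4, 19.2, 80.0, 0.45, 0.5),
        (62.1, 36.9, 90.0, 0.5, 0.45),
        (36.9, 62.1, 90.0, 0.45, 0.5),
        (25.0, 45.5, 70.0, 0.5, 0.5),
        (45.5, 25.0, 70.0, 0.5, 0.5),
    ]


@dataclass
class SpectrumRecipe:
    """Recipe for a synthetic 2D crosspeak spectrum.

    peaks : list of (center_f1, center_f2, amplitude, sigma_f1, sigma_f2).
    noise_sigma : additive i.i.d. Gaussian noise level.
    spacing, ppm_range : grid; the default 0.2 ppm over 10–75 ppm matches
        the comparison grid so regridding is the identity.
    """

    peaks: list = field(default_factory=default_peaks)
    noise_sigma: float = 0.0
    spacing: float = 0.2
    ppm_range: tuple[float, float] = (10.0, 75.0)
    seed: int = 0

    def __post_init__(self):
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        lo, hi = self.ppm_range
        for c1, c2, amp, s1, s2 in self.peaks:
            if not (lo <= c1 <= hi and lo <= c2 <= hi):
                raise ValueError(f"peak center ({c1}, {c2}) outside ppm_range")
            if s1 <= 0 or s2 <= 0:
                raise ValueError("peak widths must be positive")

    def axis(self) -> np.ndarray:
        lo, hi = self.ppm_range
        n = int(np.floor((hi - lo) / self.spacing + 1e-9)) + 1
        return lo + self.spacing * np.arange(n)


def _render(axis: np.ndarray, peaks, noise_sigma: float, rng, label: str) -> Spectrum2D:
    F1, F2 = np.meshgrid(axis, axis, indexing="ij")
    z = np.zeros_like(F1)
    for c1, c2, amp, s1, s2 in peaks:
        z += amp * np.exp(-((F1 - c1) ** 2) / (2 * s1**2) - ((F2 - c2) ** 2) / (2 * s2**2))
    if noise_sigma > 0:
        z = z + rng.normal(0.0, noise_sigma, size=z.shape)
    return Spectrum2D(axis.copy(), axis.copy(), z, label=label)


def gen_spectrum(recipe: SpectrumRecipe, label: str = "synthetic") -> Spectrum2D:
    """Render a single synthetic spectrum from its recipe."""
    rng = np.random.default_rng(recipe.seed)
    return _render(recipe.axis(), recipe.peaks, recipe.noise_sigma, rng, label)


def gen_spectrum_pair(
    recipe: SpectrumRecipe,
    shift: tuple[float, float] = (0.0, 0.0),
    per_peak_shifts: list | None = None,
    amp_scale: float = 1.0,
) -> tuple[Spectrum2D, Spectrum2D, dict]:
    """Generate a spectrum pair sharing a peak list, the second perturbed.

    ``shift`` applies a uniform (ppm_f1, ppm_f2) displacement to every
    peak of the second spectrum; ``per_peak_shifts`` (same length as the
    peak list) overrides it per peak.  ``amp_scale`` multiplies all second
    -spectrum amplitudes.  Noise is drawn independently for the two
    spectra.  The truth record carries the exact shifts and scale for RMSD
    validation.
    """
    if amp_scale <= 0:
        raise ValueError("amp_scale must be positive")
    rng = np.random.default_rng(recipe.seed)
    axis = recipe.axis()
    a = _render(axis, recipe.peaks, recipe.noise_sigma, rng, "reference")
    if per_peak_shifts is None:
        per_peak_shifts = [shift] * len(recipe.peaks)
    if len(per_peak_shifts) != len(recipe.peaks):
        raise ValueError("per_peak_shifts length must match the peak list")
    shifted = [
        (c1 + d1, c2 + d2, amp * amp_scale, s1, s2)
        for (c1, c2, amp, s1, s2), (d1, d2) in zip(recipe.peaks, per_peak_shifts)
    ]
    b = _render(axis, shifted, recipe.noise_sigma, rng, "perturbed")
    truth = {
        "per_peak_shifts": [list(map(float, d)) for d in per_peak_shifts],
        "amp_scale": float(amp_scale),
        "noise_sigma": float(recipe.noise_sigma),
        "n_peaks": len(recipe.peaks),
    }
    return a, b, truth


# ---------------------------------------------------------------------------
# decay curves

def default_time_grid() -> np.ndarray:
    """Nine recoupling times spanning the 0–61.4 ms experimental window."""
    return np.linspace(0.0, 61.4, 9)


@dataclass
class DecayRecipe:
    """Recipe for synthetic dipolar-recoupling decay curves.

    Defaults mirror the experimental conditions the fits target: a
    half-decay time of a few tens of ms, shape exponent 1.84, the
    0–61.4 ms window, and ~3% intensity noise.
    """

    t_d: float = 36.0
    alpha: float = 1.84
    time_points: np.ndarray = field(default_factory=default_time_grid)
    noise_sigma: float = 0.03
    n_replicates: int = 1
    seed: int = 0

    def __post_init__(self):
        if self.t_d <= 0 or self.alpha <= 0:
            raise ValueError("t_d and alpha must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        self.time_points = np.asarray(self.time_points, dtype=float)


def gen_decay(recipe: DecayRecipe) -> tuple[list[DecayCurve], dict]:
    """Sample noisy near-Lorentzian decay replicates plus the truth record."""
    rng = np.random.default_rng(recipe.seed)
    t = recipe.time_points
    clean = near_lorentzian(t, recipe.t_d, recipe.alpha)
    curves = []
    for r in range(recipe.n_replicates):
        y = clean + (rng.normal(0.0, recipe.noise_sigma, size=t.shape)
                     if recipe.noise_sigma > 0 else 0.0)
        err = np.full_like(t, 1.96 * recipe.noise_sigma) if recipe.noise_sigma > 0 else None
        curves.append(DecayCurve(t=t.copy(), y=y, y_err=err, label=f"replicate_{r}"))
    truth = {"t_d": recipe.t_d, "alpha": recipe.alpha,
             "noise_sigma": recipe.noise_sigma, "n_replicates": recipe.n_replicates}
    return curves, truth


# ---------------------------------------------------------------------------
# toy sheet-in-micelle systems

#: C-terminal strand sequence, residues 30-42 (Aβ42 numbering)
C_STRAND_SEQ = {
    30: "ALA", 31: "ILE", 32: "ILE", 33: "GLY", 34: "LEU", 35: "MET",
    36: "VAL", 37: "GLY", 38: "GLY", 39: "VAL", 40: "VAL", 41: "ILE", 42: "ALA",
}
RESID_LO, RESID_HI = 30, 42

_N_TAIL_CARBONS = 12
_BEAD_SPACING = 1.27  # Å between consecutive tail carbons


@dataclass
class ToySystemRecipe:
    """Recipe for the idealized sheet-in-micelle trajectory.

    n_strands : number of C-strands (default 4, the tetramer); must be
        even for the default glycine-hole table (holes live on strand
        halves (0,1), (2,3), ...).
    strand_spacing, ca_spacing : β-sheet lattice constants in Å.
    fill_rates : planted per-hole filling probabilities, one per hole
        (default: 0.3 for the type II/III holes, 0.1 for type I/IV, as in
        the simulations the toy emulates).
    planted_hbonds : ((donor_chain, donor_resid), (acceptor_chain,
        acceptor_resid)) backbone pairs to plant at 3.0 Å / 180°;
        acceptors on the glycines 33/37/38 are rejected so hole geometry
        stays untouched.
    planted_clusters : number of spatially separated detergent groups in
        the resting micelle (30 Å apart; 3.5 Å spacing within a group).
    n_frames, dt_ns : trajectory length and frame spacing (100 ps, the
        snapshot interval the analyses assume).
    """

    n_strands: int = 4
    arrangement: str = "antiparallel"
    strand_spacing: float = 4.8
    ca_spacing: float = 3.8
    n_detergents: int = 16
    fill_rates: tuple | None = None
    planted_hbonds: tuple = ()
    planted_clusters: int = 1
    n_frames: int = 5000
    dt_ns: float = 0.1
    proximity_cutoff: float = 5.0
    seed: int = 0

    def __post_init__(self):
        if self.arrangement not in ("parallel", "antiparallel"):
            raise ValueError(f"unknown arrangement {self.arrangement!r}")
        if self.n_strands < 2:
            raise ValueError("need at least 2 strands")
        if self.planted_clusters < 1:
            raise ValueError("planted_clusters must be >= 1")
        if self.n_detergents < self.planted_clusters:
            raise ValueError("need at least one detergent per planted cluster")
        if self.fill_rates is not None:
            rates = tuple(float(r) for r in self.fill_rates)
            if any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError("fill_rates must lie in [0, 1]")
            self.fill_rates = rates


@dataclass
class ToySystemTruth:
    """Ground truth planted into a toy trajectory."""

    occupancy: np.ndarray          # (n_frames, n_holes) bool
    fill_rates: tuple
    hole_labels: tuple
    fill_sites: np.ndarray         # (n_holes, 3)
    n_hbonds: int
    hbond_pairs: tuple
    n_clusters_rest: int
    seed: int

    def to_json(self) -> str:
        d = {
            "occupancy": self.occupancy.astype(int).tolist(),
            "fill_rates": list(self.fill_rates),
            "hole_labels": list(self.hole_labels),
            "fill_sites": self.fill_sites.tolist(),
            "n_hbonds": self.n_hbonds,
            "hbond_pairs": [[list(d_), list(a_)] for d_, a_ in self.hbond_pairs],
            "n_clusters_rest": self.n_clusters_rest,
            "seed": self.seed,
        }
        return json.dumps(d)

    @classmethod
    def from_json(cls, text: str) -> "ToySystemTruth":
        d = json.loads(text)
        return cls(
            occupancy=np.asarray(d["occupancy"], dtype=bool),
            fill_rates=tuple(d["fill_rates"]),
            hole_labels=tuple(d["hole_labels"]),
            fill_sites=np.asarray(d["fill_sites"], dtype=float),
            n_hbonds=int(d["n_hbonds"]),
            hbond_pairs=tuple((tuple(p[0]), tuple(p[1])) for p in d["hbond_pairs"]),
            n_clusters_rest=int(d["n_clusters_rest"]),
            seed=int(d["seed"]),
        )


def _strand_chain(s: int) -> str:
    return chr(ord("A") + s)


def _residue_x(recipe: ToySystemRecipe, s: int, resid: int) -> float:
    """Cα x-coordinate; antiparallel odd strands run C-to-N with a one-
    residue registry shift so Gly33 aligns with Gly38 of the neighbor."""
    ca = recipe.ca_spacing
    reversed_ = recipe.arrangement == "antiparallel" and s % 2 == 1
    if reversed_:
        return (RESID_HI - resid) * ca - ca
    return (resid - RESID_LO) * ca


def _build_sheet(recipe: ToySystemRecipe):
    """Template protein coordinates + topology rows."""
    rows, coords = [], []
    for s in range(recipe.n_strands):
        chain = _strand_chain(s)
        y = s * recipe.strand_spacing
        reversed_ = recipe.arrangement == "antiparallel" and s % 2 == 1
        d = -1.0 if reversed_ else 1.0
        for resid in range(RESID_LO, RESID_HI + 1):
            resname = C_STRAND_SEQ[resid]
            x = _residue_x(recipe, s, resid)
            atoms = [
                ("N", (x - d * 1.2, y, 0.0)),
                ("H", (x - d * 1.2, y, 1.0)),
                ("CA", (x, y, 0.0)),
                ("C", (x + d * 1.2, y, 0.0)),
                ("O", (x + d * 1.6, y, 0.0)),
            ]
            if resname != "GLY":
                zside = 1.5 if resid % 2 == 0 else -1.5
                atoms.append(("CB", (x, y, zside)))
            for name, xyz in atoms:
                rows.append({"name": name, "resname": resname, "resid": resid,
                             "chain": chain, "molclass": "protein"})
                coords.append(xyz)
    return rows, coords


def _flanking_lining(recipe: ToySystemRecipe, gly: tuple, face: int):
    """CB-bearing residues flanking the hole's glycines, on the hole face."""
    lining = []
    for chain, resid in gly:
        for r in (resid - 1, resid + 1):
            if not (RESID_LO <= r <= RESID_HI) or C_STRAND_SEQ[r] == "GLY":
                continue
            zside = 1.5 if r % 2 == 0 else -1.5
            if np.sign(zside) == face and (chain, r) not in lining:
                lining.append((chain, r))
    return tuple(lining)


def default_hole_specs(recipe: ToySystemRecipe) -> tuple[list[GlycineHoleSpec], list[int]]:
    """The glycine-hole table of the toy sheet: four types per strand half.

    For each half (strand pair 2h, 2h+1) there are two glycine triplets —
    Gly37/Gly38 of the even strand with Gly33 of the odd strand, and
    Gly33 of the even strand with Gly37/Gly38 of the odd strand — each
    opening onto both sheet faces: types II (front) / IV (back) for the
    first triplet and I (front) / III (back) for the second.  Lining
    sidechains are the lattice's CB-bearing flanking residues on the
    matching face.  Returns (specs, faces) with face +1 (front) or -1.
    """
    if recipe.n_strands % 2:
        raise ValueError("the default hole table requires an even strand count")
    specs, faces = [], []
    for h in range(recipe.n_strands // 2):
        c_even, c_odd = _strand_chain(2 * h), _strand_chain(2 * h + 1)
        t1 = ((c_even, 37), (c_even, 38), (c_odd, 33))
        t2 = ((c_even, 33), (c_odd, 37), (c_odd, 38))
        for hole_type, gly, face in (
            ("II", t1, 1), ("I", t2, 1), ("III", t2, -1), ("IV", t1, -1),
        ):
            lining = _flanking_lining(recipe, gly, face)
            specs.append(GlycineHoleSpec(
                hole_type=hole_type, gly_residues=gly, lining_sidechains=lining,
                proximity_cutoff=recipe.proximity_cutoff,
                label=f"half{h}_{'front' if face > 0 else 'back'}",
            ))
            faces.append(face)
    return specs, faces


def _criterion_groups(rows, coords, hole: GlycineHoleSpec):
    """Atom coordinate groups of the hole criterion (inline oracle)."""
    backbone = ("N", "CA", "C", "O")
    groups = []
    for chain, resid in hole.gly_residues:
        pts = [coords[i] for i, r in enumerate(rows)
               if r["chain"] == chain and r["resid"] == resid and r["name"] in backbone]
        if not pts:
            raise RuntimeError(f"toy build: no backbone atoms for {chain}:{resid}")
        groups.append(np.asarray(pts))
    cb = [coords[i] for i, r in enumerate(rows)
          for chain, resid in hole.lining_sidechains
          if r["chain"] == chain and r["resid"] == resid and r["name"] == "CB"]
    if not cb:
        raise RuntimeError(f"toy build: no lining CB atoms for hole {hole.hole_type}")
    groups.append(np.asarray(cb))
    return groups


def _group_min_dists(p: np.ndarray, groups) -> list[float]:
    return [float(np.min(np.linalg.norm(g - p, axis=1))) for g in groups]


def _solve_fill_sites(rows, coords, holes, faces, cutoff: float) -> np.ndarray:
    """One planting point per hole: satisfies its own criterion with margin
    and fails every other hole's criterion with margin."""
    all_groups = [_criterion_groups(rows, coords, h) for h in holes]
    margin_in, margin_out = cutoff - 0.3, cutoff + 0.3
    sites = np.zeros((len(holes), 3))
    lateral = np.arange(-3.0, 3.01, 0.5)
    heights = (2.6, 3.0, 3.4, 2.2)
    for h, (hole, face) in enumerate(zip(holes, faces)):
        gly_atoms = np.vstack(all_groups[h][:3])
        cx, cy = gly_atoms[:, 0].mean(), gly_atoms[:, 1].mean()
        found = None
        for zc in heights:
            for dx in lateral:
                for dy in lateral:
                    p = np.array([cx + dx, cy + dy, face * zc])
                    if max(_group_min_dists(p, all_groups[h])) > margin_in:
                        continue
                    others_fail = all(
                        max(_group_min_dists(p, all_groups[k])) > margin_out
                        for k in range(len(holes)) if k != h
                    )
                    if others_fail:
                        found = p
                        break
                if found is not None:
                    break
            if found is not None:
                break
        if found is None:
            raise RuntimeError(
                f"toy build: no planting point found for hole {hole.hole_type} "
                f"({hole.label}); adjust the lattice or cutoff")
        # outer tail beads must not trigger any other hole either
        for j in range(1, _N_TAIL_CARBONS):
            bead = found + np.array([0.0, 0.0, face * j * _BEAD_SPACING])
            for k in range(len(holes)):
                if k != h and max(_group_min_dists(bead, all_groups[k])) <= margin_out:
                    raise RuntimeError(
                        f"toy build: tail bead of hole {hole.hole_type} intrudes "
                        f"into hole {holes[k].hole_type}")
        sites[h] = found
    return sites


def _detergent_template(recipe: ToySystemRecipe):
    """Resting detergent rows + coordinates, grouped into planted clusters."""
    rows, coords = [], []
    n, g = recipe.n_detergents, recipe.planted_clusters
    # split molecules into g nearly equal groups; groups separated by a
    # 30 Å gap, molecules 3.5 Å apart (< contact cutoff) within a group
    group_of = [m * g // n for m in range(n)]
    group_start_x, x_cursor = {}, 0.0
    for grp in range(g):
        size = group_of.count(grp)
        group_start_x[grp] = x_cursor
        x_cursor += (size - 1) * 3.5 + 30.0
    within_count: dict[int, int] = {}
    for m in range(n):
        grp = group_of[m]
        w = within_count.get(grp, 0)
        within_count[grp] = w + 1
        x0 = group_start_x[grp] + w * 3.5
        y0, z0 = -30.0, 0.0
        rows.append({"name": "S1", "resname": "SDS", "resid": m + 1,
                     "chain": "S", "molclass": "detergent"})
        coords.append((x0, y0, z0 - 1.5))
        for j in range(_N_TAIL_CARBONS):
            rows.append({"name": f"C{j + 1}", "resname": "SDS", "resid": m + 1,
                         "chain": "S", "molclass": "detergent"})
            coords.append((x0, y0, z0 + j * _BEAD_SPACING))
    return rows, coords


def _plant_hbonds(rows, coords, pairs):
    """Move acceptor O to 3.0 Å from donor N and aim the donor H at it."""
    def find(chain, resid, name):
        for i, r in enumerate(rows):
            if r["chain"] == chain and r["resid"] == resid and r["name"] == name:
                return i
        raise ValueError(f"planted hbond references missing atom {chain}:{resid}:{name}")

    seen_d, seen_a = set(), set()
    for (dc, dr), (ac, ar) in pairs:
        if ar in (33, 37, 38):
            raise ValueError(
                f"planted hbond acceptor {ac}:{ar} is a hole glycine; choose another residue")
        if (dc, dr) == (ac, ar):
            raise ValueError("planted hbond donor and acceptor must differ")
        if (dc, dr) in seen_d or (ac, ar) in seen_a:
            raise ValueError("each donor/acceptor residue may be planted once")
        seen_d.add((dc, dr))
        seen_a.add((ac, ar))
        i_n = find(dc, dr, "N")
        i_h = find(dc, dr, "H")
        i_o = find(ac, ar, "O")
        n = np.asarray(coords[i_n])
        u = np.asarray(coords[i_o]) - n
        u = u / np.linalg.norm(u)
        coords[i_o] = tuple(n + 3.0 * u)
        coords[i_h] = tuple(n + 1.0 * u)


def _verify_hbonds(rows, coords, expected: int,
                   dist_cut: float = 3.5, angle_cut: float = 125.0):
    """Inline double-loop hydrogen-bond count (independent of md module)."""
    donors = []
    for i, r in enumerate(rows):
        if r["molclass"] == "protein" and r["name"] == "N":
            for j, rh in enumerate(rows):
                if (rh["chain"], rh["resid"]) == (r["chain"], r["resid"]) and rh["name"] == "H":
                    donors.append((i, j))
                    break
    count = 0
    for i_n, i_h in donors:
        for k, ra in enumerate(rows):
            if ra["molclass"] != "protein" or ra["name"] != "O":
                continue
            if (ra["chain"], ra["resid"]) == (rows[i_n]["chain"], rows[i_n]["resid"]):
                continue
            n, hh, o = (np.asarray(coords[x]) for x in (i_n, i_h, k))
            if np.linalg.norm(n - o) > dist_cut:
                continue
            v1, v2 = n - hh, o - hh
            cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
            if np.degrees(np.arccos(np.clip(cosang, -1, 1))) >= angle_cut:
                count += 1
    if count != expected:
        raise RuntimeError(
            f"toy build: planted {expected} hydrogen bonds but the template shows {count}")


def gen_toy_system(
    recipe: ToySystemRecipe,
    occupancy: np.ndarray | None = None,
) -> tuple[TrajectoryFrames, ToySystemTruth, list[GlycineHoleSpec]]:
    """Build a toy sheet-in-micelle trajectory with planted events.

    Each glycine hole h is independently occupied in each frame with its
    planted rate (or per the explicit ``occupancy`` matrix); occupancy is
    realized by moving a dedicated detergent so one tail carbon sits at a
    precomputed planting point satisfying the hole's 5 Å criterion — and,
    by construction, no other hole's.  Unfilled detergents rest in the
    planted cluster arrangement 30 Å away from the sheet.

    Returns (trajectory, truth, hole_specs).  The build self-checks its
    geometry with inline distance oracles and raises on any violation.
    """
    holes, faces = default_hole_specs(recipe)
    rates = recipe.fill_rates
    if rates is None:
        rates = tuple(0.3 if h.hole_type in ("II", "III") else 0.1 for h in holes)
    if len(rates) != len(holes):
        raise ValueError(f"fill_rates must have length {len(holes)}, got {len(rates)}")
    any_fill = any(r > 0 for r in rates) or occupancy is not None
    if any_fill and recipe.n_detergents < len(holes):
        raise ValueError(
            f"need >= {len(holes)} detergents to fill holes, got {recipe.n_detergents} "
            "(more simultaneous fills than detergents)")

    prot_rows, prot_coords = _build_sheet(recipe)
    _plant_hbonds(prot_rows, prot_coords, recipe.planted_hbonds)
    _verify_hbonds(prot_rows, prot_coords, len(recipe.planted_hbonds))
    det_rows, det_coords = _detergent_template(recipe)
    rows = prot_rows + det_rows
    coords = [tuple(c) for c in prot_coords] + list(det_coords)

    sites = _solve_fill_sites(rows, coords, holes, faces, recipe.proximity_cutoff)
    # resting detergents must not fill anything
    all_groups = [_criterion_groups(rows, coords, h) for h in holes]
    det_xyz = np.asarray(det_coords)
    for g_idx, hole in enumerate(holes):
        for bead in det_xyz:
            if max(_group_min_dists(bead, all_groups[g_idx])) <= hole.proximity_cutoff + 0.3:
                raise RuntimeError("toy build: a resting detergent encroaches on a hole")

    F, H = recipe.n_frames, len(holes)
    rng = np.random.default_rng(recipe.seed)
    if occupancy is None:
        occupancy = rng.random((F, H)) < np.asarray(rates)
    else:
        occupancy = np.asarray(occupancy, dtype=bool)
        if occupancy.shape != (F, H):
            raise ValueError(f"occupancy must have shape ({F}, {H})")

    base = np.asarray(coords)
    traj_coords = np.broadcast_to(base, (F,) + base.shape).copy()
    n_prot = len(prot_rows)
    atoms_per_det = 1 + _N_TAIL_CARBONS
    for h in range(H):
        det = h  # dedicated filler molecule
        a0 = n_prot + det * atoms_per_det
        fill_xyz = np.zeros((atoms_per_det, 3))
        face = faces[h]
        for j in range(_N_TAIL_CARBONS):
            fill_xyz[1 + j] = sites[h] + np.array([0, 0, face * j * _BEAD_SPACING])
        fill_xyz[0] = sites[h] + np.array(
            [0, 0, face * ((_N_TAIL_CARBONS - 1) * _BEAD_SPACING + 1.5)])
        frames = np.nonzero(occupancy[:, h])[0]
        traj_coords[frames, a0:a0 + atoms_per_det, :] = fill_xyz

    traj = TrajectoryFrames(
        topology=pd.DataFrame(rows),
        coords=traj_coords,
        times=np.arange(F) * recipe.dt_ns,
    )
    truth = ToySystemTruth(
        occupancy=occupancy,
        fill_rates=tuple(float(r) for r in rates),
        hole_labels=tuple(f"{h.hole_type}:{h.label}" for h in holes),
        fill_sites=sites,
        n_hbonds=len(recipe.planted_hbonds),
        hbond_pairs=tuple(recipe.planted_hbonds),
        n_clusters_rest=recipe.planted_clusters,
        seed=recipe.seed,
    )
    return traj, truth, holes
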