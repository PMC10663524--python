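"""Trajectory analyses for β-sheet tetramers in detergent micelles.

The analyses here operate on :class:`TrajectoryFrames` — per-frame
coordinates plus a flat atom table — and implement:

* glycine-hole occupancy: a hole formed by the missing sidechains of
  Gly33/Gly37/Gly38 counts as *filled* in a frame when some single
  detergent tail carbon is simultaneously within the proximity cutoff
  (5 Å, inclusive) of (1) at least one backbone heavy atom (N, CA, C, O)
  on each of the three glycines and (2) the Cβ of at least one sidechain
  lining the hole;
* per-hole filling probabilities (post burn-in occupied-frame fractions,
  averaged over replicate trajectories) and the exact Poisson-binomial
  distribution of the number of holes filled under independence;
* backbone hydrogen-bond counting with donor–acceptor heavy-atom distance
  and donor–hydrogen–acceptor angle cutoffs (3.5 Å / 125°);
* micelle integrity as connected components of the detergent contact
  graph;
* whole-molecule overlap removal for system preparation;
* Savitzky-Golay smoothing and block-wise convergence checks of
  time-series observables.

Coordinates are in Å and times in ns throughout.  No periodic-boundary
imaging is applied; coordinates are assumed already whole/imaged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import cdist
from scipy.stats import f as f_dist

from .errors import MissingAtomsError

__all__ = [
    "TrajectoryFrames",
    "GlycineHoleSpec",
    "HoleFillSeries",
    "HoleFillResult",
    "HoleFillModel",
    "FillCountDistribution",
    "HBondCriteria",
    "MicelleState",
    "BlockConvergenceReport",
    "detect_hole_filled",
    "hole_filled_series",
    "hole_fill_probabilities",
    "fill_count_distribution",
    "count_hbonds",
    "hbond_series",
    "micelle_clusters",
    "remove_overlaps",
    "smooth_series",
    "block_convergence",
]

BACKBONE_HEAVY = ("N", "CA", "C", "O")

_WATER_RESNAMES = {"HOH", "WAT", "TIP3", "SOL", "SPC"}
_ION_RESNAMES = {"NA", "CL", "K", "MG", "CA2", "SOD", "CLA", "NA+", "CL-"}
_DETERGENT_RESNAMES = {"SDS", "DPC", "DET"}


def classify_molecules(topology: pd.DataFrame) -> pd.DataFrame:
    """Fill in ``molclass`` and ``molid`` columns from residue names.

    Non-protein molecules (detergent, water, ion) get one ``molid`` per
    (chain, resid); protein chains get one ``molid`` per chain.
    """
    top = topology.copy()
    if "molclass" not in top.columns:
        resn = top["resname"].str.upper()
        cls = np.where(
            resn.isin(_DETERGENT_RESNAMES), "detergent",
            np.where(resn.isin(_WATER_RESNAMES), "water",
                     np.where(resn.isin(_ION_RESNAMES), "ion", "protein")),
        )
        top["molclass"] = cls
    if "molid" not in top.columns:
        protein = top["molclass"] == "protein"
        keys = np.where(
            protein,
            "chain:" + top["chain"].astype(str),
            top["molclass"].astype(str) + ":" + top["chain"].astype(str)
            + ":" + top["resid"].astype(str),
        )
        top["molid"] = pd.factorize(keys)[0]
    return top


@dataclass(eq=False)
class TrajectoryFrames:
    """Per-frame coordinates plus a flat atom table.

    topology : DataFrame with columns ``name``, ``resname``, ``resid``,
        ``chain`` and (derived if absent) ``molclass`` in
        {protein, detergent, water, ion} and integer ``molid``.
    coords : (n_frames, n_atoms, 3) array, Å.
    times : (n_frames,) frame times in ns.
    """

    topology: pd.DataFrame
    coords: np.ndarray
    times: np.ndarray

    def __post_init__(self):
        self.coords = np.asarray(self.coords, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if self.coords.shape[0] != self.times.size:
            raise ValueError("times length must equal the number of frames")
        if self.coords.shape[1] != len(self.topology):
            raise ValueError("atom count in coords does not match topology")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        required = {"name", "resname", "resid", "chain"}
        missing = required - set(self.topology.columns)
        if missing:
            raise ValueError(f"topology missing columns: {sorted(missing)}")
        self.topology = classify_molecules(self.topology.reset_index(drop=True))

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[1]

    def atom_indices(self, *, chain=None, resid=None, name=None, molclass=None) -> np.ndarray:
        """Indices of atoms matching all the given criteria (scalars or sets)."""
        mask = np.ones(self.n_atoms, dtype=bool)
        for col, val in (("chain", chain), ("resid", resid), ("name", name),
                         ("molclass", molclass)):
            if val is None:
                continue
            if isinstance(val, (str, int, np.integer)):
                mask &= (self.topology[col] == val).to_numpy()
            else:
                mask &= self.topology[col].isin(list(val)).to_numpy()
        return np.nonzero(mask)[0]

    def subset(self, atom_indices: np.ndarray) -> "TrajectoryFrames":
        idx = np.asarray(atom_indices)
        return TrajectoryFrames(
            topology=self.topology.iloc[idx].reset_index(drop=True),
            coords=self.coords[:, idx, :],
            times=self.times.copy(),
        )


def tail_carbon_indices(traj: TrajectoryFrames, tail_names: Sequence[str] | None = None) -> np.ndarray:
    """Indices of detergent tail carbons (names C1..Cn by default)."""
    top = traj.topology
    det = (top["molclass"] == "detergent").to_numpy()
    if tail_names is None:
        is_tail = top["name"].str.fullmatch(r"C\d+").fillna(False).to_numpy()
    else:
        is_tail = top["name"].isin(list(tail_names)).to_numpy()
    idx = np.nonzero(det & is_tail)[0]
    if idx.size == 0:
        raise MissingAtomsError("no detergent tail carbons found in topology")
    return idx


@dataclass(frozen=True)
class GlycineHoleSpec:
    """Definition of one glycine hole on the β-sheet face.

    hole_type : "I" | "II" | "III" | "IV" (which glycines sit on edge vs
        interior strands and which sheet face the hole opens onto).
    gly_residues : exactly three (chain, resid) entries — the Gly33 /
        Gly37 / Gly38 positions, with their chain assignments.
    lining_sidechains : (chain, resid) entries whose Cβ atoms line the
        hole; criterion clause (2).
    proximity_cutoff : Å, inclusive; default 5.
    """

    hole_type: str
    gly_residues: tuple[tuple[str, int], ...]
    lining_sidechains: tuple[tuple[str, int], ...]
    proximity_cutoff: float = 5.0
    label: str = ""

    def __post_init__(self):
        if len(self.gly_residues) != 3:
            raise ValueError("gly_residues must contain exactly three (chain, resid) entries")
        if not self.lining_sidechains:
            raise ValueError("lining_sidechains must be non-empty")
        if self.proximity_cutoff <= 0:
            raise ValueError("proximity_cutoff must be positive")
        object.__setattr__(self, "gly_residues",
                           tuple((str(c), int(r)) for c, r in self.gly_residues))
        object.__setattr__(self, "lining_sidechains",
                           tuple((str(c), int(r)) for c, r in self.lining_sidechains))


def _hole_atom_groups(traj: TrajectoryFrames, hole: GlycineHoleSpec) -> list[np.ndarray]:
    """Atom-index groups for the criterion: one per Gly backbone + lining Cβ set."""
    groups = []
    missing = []
    for chain, resid in hole.gly_residues:
        idx = traj.atom_indices(chain=chain, resid=resid, name=BACKBONE_HEAVY)
        if idx.size == 0:
            missing.append(f"backbone of {chain}:{resid}")
        groups.append(idx)
    cb = []
    for chain, resid in hole.lining_sidechains:
        idx = traj.atom_indices(chain=chain, resid=resid, name="CB")
        if idx.size == 0:
            missing.append(f"CB of {chain}:{resid}")
        cb.append(idx)
    if missing:
        raise MissingAtomsError(
            f"hole {hole.hole_type}{('/' + hole.label) if hole.label else ''}: "
            f"missing atoms: {', '.join(missing)}", missing)
    groups.append(np.concatenate(cb))
    return groups


def _min_dist2_to_group(tails: np.ndarray, group: np.ndarray) -> np.ndarray:
    """Min squared distance from each tail carbon to a group of atoms.

    tails: (F, T, 3); group: (F, G, 3) -> (F, T)
    """
    diff = tails[:, :, None, :] - group[:, None, :, :]
    return np.min(np.einsum("ftgd,ftgd->ftg", diff, diff), axis=2)


def _hole_filled_matrix(traj: TrajectoryFrames, hole: GlycineHoleSpec,
                        tail_idx: np.ndarray, chunk: int = 500) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame (filled, filling molid) for one hole; vectorized over frames."""
    groups = _hole_atom_groups(traj, hole)
    cut2 = hole.proximity_cutoff**2
    F = traj.n_frames
    filled = np.zeros(F, dtype=bool)
    molids = np.full(F, -1, dtype=int)
    tail_molids = traj.topology["molid"].to_numpy()[tail_idx]
    for start in range(0, F, chunk):
        sl = slice(start, min(start + chunk, F))
        tails = traj.coords[sl][:, tail_idx, :]
        ok = np.ones((tails.shape[0], tails.shape[1]), dtype=bool)
        for group in groups:
            gcoords = traj.coords[sl][:, group, :]
            ok &= _min_dist2_to_group(tails, gcoords) <= cut2
        any_ok = ok.any(axis=1)
        filled[sl] = any_ok
        first = np.argmax(ok, axis=1)
        molids[sl] = np.where(any_ok, tail_molids[first], -1)
    return filled, molids


def detect_hole_filled(traj: TrajectoryFrames, frame: int, hole: GlycineHoleSpec,
                       tail_names: Sequence[str] | None = None) -> tuple[bool, int | None]:
    """Is the hole filled in one frame, and by which detergent molecule?

    A single tail carbon must simultaneously satisfy clause (1) — within
    the cutoff of ≥1 backbone heavy atom on *each* of the three glycines —
    and clause (2) — within the cutoff of ≥1 lining-sidechain Cβ.  Two
    carbons each satisfying only part of the criterion do not count.
    """
    tail_idx = tail_carbon_indices(traj, tail_names)
    sub = TrajectoryFrames(traj.topology, traj.coords[frame:frame + 1], traj.times[frame:frame + 1])
    filled, molids = _hole_filled_matrix(sub, hole, tail_idx)
    return bool(filled[0]), (int(molids[0]) if filled[0] else None)


@dataclass
class HoleFillSeries:
    """Per-frame occupancy of one hole in one replicate trajectory."""

    occupied: np.ndarray
    times: np.ndarray
    burn_in: float
    probability: float
    replicate_id: int = 0
    filling_molids: np.ndarray | None = None

    def __post_init__(self):
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError("probability must lie in [0, 1]")


def hole_filled_series(traj: TrajectoryFrames, hole: GlycineHoleSpec,
                       burn_in: float = 10.0, replicate_id: int = 0,
                       tail_names: Sequence[str] | None = None) -> HoleFillSeries:
    """Occupancy time series for one hole; probability over post-burn-in frames."""
    tail_idx = tail_carbon_indices(traj, tail_names)
    filled, molids = _hole_filled_matrix(traj, hole, tail_idx)
    keep = traj.times > burn_in
    if not keep.any():
        raise ValueError(f"no frames beyond the {burn_in} ns burn-in")
    prob = float(filled[keep].mean())
    return HoleFillSeries(occupied=filled, times=traj.times, burn_in=burn_in,
                          probability=prob, replicate_id=replicate_id,
                          filling_molids=molids)


@dataclass
class HoleFillResult:
    """Replicate-averaged per-hole filling probabilities.

    probabilities : (n_holes,) arithmetic means across replicates.
    per_replicate : (n_replicates, n_holes) post-burn-in fractions.
    """

    holes: list[GlycineHoleSpec]
    probabilities: np.ndarray
    per_replicate: np.ndarray
    burn_in: float

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.per_replicate.T,
            columns=[f"replicate_{r}" for r in range(self.per_replicate.shape[0])],
            index=[f"{h.hole_type}:{h.label}" if h.label else h.hole_type for h in self.holes],
        )
        df["mean"] = self.probabilities
        return df


def hole_fill_probabilities(trajs: Sequence[TrajectoryFrames],
                            holes: Sequence[GlycineHoleSpec],
                            burn_in: float = 10.0,
                            tail_names: Sequence[str] | None = None) -> HoleFillResult:
    """Per-hole filling probabilities averaged over replicate trajectories.

    For each replicate, the probability of a hole being filled is the
    fraction of frames (after discarding the first ``burn_in`` ns) in
    which the hole criterion holds; replicates are then averaged
    arithmetically.  Per-replicate values are retained for dispersion
    reporting.
    """
    if not trajs:
        raise ValueError("need at least one replicate trajectory")
    per_rep = np.zeros((len(trajs), len(holes)))
    for r, traj in enumerate(trajs):
        for h, hole in enumerate(holes):
            per_rep[r, h] = hole_filled_series(
                traj, hole, burn_in=burn_in, replicate_id=r, tail_names=tail_names
            ).probability
    return HoleFillResult(holes=list(holes), probabilities=per_rep.mean(axis=0),
                          per_replicate=per_rep, burn_in=burn_in)


@dataclass
class FillCountDistribution:
    """Exact distribution of the number of holes simultaneously filled."""

    pmf: np.ndarray
    p_at_least_one: float
    p_at_least_two: float

    def __post_init__(self):
        self.pmf = np.asarray(self.pmf, dtype=float)
        if abs(self.pmf.sum() - 1.0) > 1e-9:
            raise ValueError("pmf must sum to 1")


@dataclass
class HoleFillModel:
    """Independent-filling model over the glycine holes.

    Each hole h is filled independently with probability ``probs[h]``;
    the number filled then follows a Poisson-binomial distribution
    (binomial in the equal-probability case).
    """

    probs: np.ndarray

    def __post_init__(self):
        self.probs = np.atleast_1d(np.asarray(self.probs, dtype=float))
        if np.any((self.probs < 0) | (self.probs > 1)):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_holes(self) -> int:
        return self.probs.size

    def distribution(self) -> FillCountDistribution:
        return fill_count_distribution(self.probs)


def fill_count_distribution(probs) -> FillCountDistribution:
    """Exact Poisson-binomial pmf by dynamic programming over holes.

    Equivalent to brute-force enumeration over all 2**n occupancy
    patterns, in O(n**2); reduces to the binomial pmf when all
    probabilities are equal.
    """
    model = probs if isinstance(probs, HoleFillModel) else HoleFillModel(probs)
    p = model.probs
    pmf = np.zeros(p.size + 1)
    pmf[0] = 1.0
    for ph in p:
        pmf[1:] = pmf[1:] * (1.0 - ph) + pmf[:-1] * ph
        pmf[0] *= 1.0 - ph
    return FillCountDistribution(
        pmf=pmf,
        p_at_least_one=float(1.0 - pmf[0]),
        p_at_least_two=float(1.0 - pmf[0] - pmf[1]),
    )


@dataclass(frozen=True)
class HBondCriteria:
    """Hydrogen-bond geometric criterion.

    distance_cutoff : donor-to-acceptor heavy-atom distance, Å (≤).
    angle_cutoff : donor–hydrogen–acceptor angle, degrees (≥).
    """

    distance_cutoff: float = 3.5
    angle_cutoff: float = 125.0

    def __post_init__(self):
        if self.distance_cutoff <= 0:
            raise ValueError("distance_cutoff must be positive")
        if not 0.0 < self.angle_cutoff < 180.0:
            raise ValueError("angle_cutoff must lie in (0, 180) degrees")


def _backbone_donors_acceptors(traj: TrajectoryFrames):
    top = traj.topology
    protein = top["molclass"] == "protein"
    n_atoms = top.index[protein & (top["name"] == "N")]
    h_names = {"H", "HN"}
    h_atoms = top[protein & top["name"].isin(h_names)]
    if h_atoms.empty:
        raise MissingAtomsError(
            "no amide hydrogens (H/HN) found: the angle criterion needs hydrogens")
    h_lookup = {(row.chain, row.resid): i for i, row in h_atoms.iterrows()}
    donors, hydrogens = [], []
    for i in n_atoms:
        key = (top.at[i, "chain"], top.at[i, "resid"])
        if key in h_lookup:
            donors.append(i)
            hydrogens.append(h_lookup[key])
    acceptors = top.index[protein & (top["name"] == "O")].to_numpy()
    return np.asarray(donors), np.asarray(hydrogens), acceptors


def count_hbonds(traj: TrajectoryFrames, frame: int,
                 criteria: HBondCriteria = HBondCriteria(),
                 backbone_only: bool = True,
                 donors: np.ndarray | None = None,
                 hydrogens: np.ndarray | None = None,
                 acceptors: np.ndarray | None = None) -> int:
    """Count hydrogen bonds in one frame.

    A donor–acceptor pair is counted when the heavy-atom distance is
    ≤ ``criteria.distance_cutoff`` and the donor–hydrogen–acceptor angle is
    ≥ ``criteria.angle_cutoff``.  By default backbone amide N-H donors and
    backbone carbonyl O acceptors of the protein are used; custom donor /
    hydrogen / acceptor index arrays may be supplied instead (all three
    together).
    """
    custom = [donors, hydrogens, acceptors]
    if any(x is not None for x in custom):
        if any(x is None for x in custom):
            raise ValueError("supply donors, hydrogens and acceptors together")
        D, H, A = (np.asarray(x) for x in custom)
    else:
        if not backbone_only:
            raise NotImplementedError(
                "sidechain donors/acceptors: pass explicit index arrays")
        D, H, A = _backbone_donors_acceptors(traj)
    if D.size == 0 or A.size == 0:
        return 0
    x = traj.coords[frame]
    dist = cdist(x[D], x[A])
    top = traj.topology
    same_res = (
        (top["chain"].to_numpy()[D][:, None] == top["chain"].to_numpy()[A][None, :])
        & (top["resid"].to_numpy()[D][:, None] == top["resid"].to_numpy()[A][None, :])
    )
    cand = np.argwhere((dist <= criteria.distance_cutoff) & ~same_res)
    if cand.size == 0:
        return 0
    di, ai = cand[:, 0], cand[:, 1]
    hd = x[D[di]] - x[H[di]]
    ha = x[A[ai]] - x[H[di]]
    cosang = np.einsum("ij,ij->i", hd, ha) / (
        np.linalg.norm(hd, axis=1) * np.linalg.norm(ha, axis=1))
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    return int(np.count_nonzero(angles >= criteria.angle_cutoff))


def hbond_series(traj: TrajectoryFrames,
                 criteria: HBondCriteria = HBondCriteria(), **kwargs) -> np.ndarray:
    """Hydrogen-bond count per frame."""
    return np.array([count_hbonds(traj, i, criteria, **kwargs)
                     for i in range(traj.n_frames)])


@dataclass
class MicelleState:
    """Cluster decomposition of the detergent molecules in one frame."""

    n_clusters: int
    cluster_sizes: tuple[int, ...]
    contact_cutoff: float

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1 for a non-empty system")
        if len(self.cluster_sizes) != self.n_clusters:
            raise ValueError("cluster_sizes length must equal n_clusters")


def micelle_clusters(traj: TrajectoryFrames, frame: int,
                     contact_cutoff: float = 4.5,
                     tail_names: Sequence[str] | None = None) -> MicelleState:
    """Connected components of the detergent contact graph in one frame.

    Two detergent molecules are in contact when any pair of their tail
    carbons is within ``contact_cutoff`` Å.  The micelle splitting seen in
    oversized micelles shows up as ``n_clusters`` > 1.
    """
    tail_idx = tail_carbon_indices(traj, tail_names)
    molids = traj.topology["molid"].to_numpy()[tail_idx]
    unique_mols, mol_code = np.unique(molids, return_inverse=True)
    n_mol = unique_mols.size
    x = traj.coords[frame][tail_idx]
    close = cdist(x, x) <= contact_cutoff
    ii, jj = np.nonzero(close)
    graph = coo_matrix(
        (np.ones(ii.size), (mol_code[ii], mol_code[jj])), shape=(n_mol, n_mol)
    )
    n_comp, labels = connected_components(graph, directed=False)
    sizes = tuple(sorted(np.bincount(labels, minlength=n_comp).tolist(), reverse=True))
    return MicelleState(n_clusters=int(n_comp), cluster_sizes=sizes,
                        contact_cutoff=contact_cutoff)


def remove_overlaps(traj: TrajectoryFrames, cutoff: float,
                    reference_molclass: str = "protein",
                    removable: Sequence[str] = ("detergent", "water", "ion"),
                    frame: int = 0) -> TrajectoryFrames:
    """Remove whole molecules overlapping the reference selection.

    Any removable molecule (detergent / water / ion) with at least one
    atom strictly within ``cutoff`` Å of any reference atom in the given
    frame is dropped entirely — removal is whole-molecule, as in system
    preparation where clashing detergent or solvent is deleted around a
    placed solute.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    top = traj.topology
    ref_idx = traj.atom_indices(molclass=reference_molclass)
    if ref_idx.size == 0:
        raise MissingAtomsError(f"no atoms of molclass {reference_molclass!r}")
    rem_mask = top["molclass"].isin(list(removable)).to_numpy()
    rem_idx = np.nonzero(rem_mask)[0]
    if rem_idx.size == 0:
        return traj
    dmin = cdist(traj.coords[frame][rem_idx], traj.coords[frame][ref_idx]).min(axis=1)
    bad_atoms = rem_idx[dmin < cutoff]
    bad_mols = set(top["molid"].to_numpy()[bad_atoms].tolist())
    keep = ~top["molid"].isin(bad_mols).to_numpy() | ~rem_mask
    return traj.subset(np.nonzero(keep)[0])


def smooth_series(series, window: int = 501, polyorder: int = 3) -> np.ndarray:
    """Savitzky-Golay smoothing of a time series.

    The window must be odd and no longer than the series; endpoints are
    handled by polynomial fits on truncated windows.  Polynomials of
    degree ≤ ``polyorder`` are reproduced exactly.
    """
    y = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > y.size:
        raise ValueError(f"window {window} exceeds series length {y.size}")
    if polyorder >= window:
        raise ValueError("polyorder must be smaller than window")
    return savgol_filter(y, window_length=window, polyorder=polyorder, mode="interp")


@dataclass
class BlockConvergenceReport:
    """Block-wise convergence check of a time-series observable.

    The series of each replicate is cut into blocks (default 250 ns);
    ``within_variance`` is the variance of block means along single
    trajectories (averaged over replicates) and ``among_variance`` the
    variance of block means across replicates (averaged over blocks) —
    the two are on the same scale.  ``converged`` is True when the
    within-trajectory variance does not significantly exceed the
    among-replicate variance (one-sided F comparison at ``alpha``);
    ``within_le_among`` reports the raw point comparison.
    """

    block_means: np.ndarray
    within_variance: float
    among_variance: float
    within_le_among: bool
    converged: bool
    f_ratio: float
    f_critical: float
    alpha: float
    trajectory_means: np.ndarray


def block_convergence(replicates: Sequence[np.ndarray],
                      times: Sequence[np.ndarray] | None = None,
                      block_span: float = 250.0,
                      block_points: int | None = None,
                      alpha: float = 0.05) -> BlockConvergenceReport:
    """Compare within-trajectory and among-replicate variability.

    Parameters
    ----------
    replicates
        One 1D observable series per replicate trajectory (≥ 2 replicates).
    times
        Optional per-replicate time arrays (ns); with ``block_points``
        unset, the block length in frames is ``block_span`` divided by the
        frame spacing of the first replicate.
    block_span
        Block length in ns (default 250).
    block_points
        Block length in frames, overriding ``block_span``.
    """
    series = [np.asarray(s, dtype=float) for s in replicates]
    if len(series) < 2:
        raise ValueError("need at least 2 replicate series")
    if block_points is None:
        if times is None:
            raise ValueError("supply either times or block_points")
        t0 = np.asarray(times[0], dtype=float)
        dt = float(np.mean(np.diff(t0)))
        block_points = max(int(round(block_span / dt)), 1)
    k = min(s.size // block_points for s in series)
    if k < 2:
        raise ValueError(
            f"series span fewer than 2 blocks of {block_points} points")
    bm = np.stack([
        s[: k * block_points].reshape(k, block_points).mean(axis=1) for s in series
    ])  # (R, k)
    R = bm.shape[0]
    within = float(np.mean(np.var(bm, axis=1, ddof=1)))
    among = float(np.mean(np.var(bm, axis=0, ddof=1)))
    ratio = within / among if among > 0 else np.inf
    dof_within = R * (k - 1)
    dof_among = k * (R - 1)
    fcrit = float(f_dist.ppf(1.0 - alpha, dof_within, dof_among))
    return BlockConvergenceReport(
        block_means=bm,
        within_variance=within,
        among_variance=among,
        within_le_among=bool(within <= among),
        converged=bool(ratio <= fcrit),
        f_ratio=float(ratio),
        f_critical=fcrit,
        alpha=alpha,
        trajectory_means=bm.mean(axis=1),
    )
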