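"""Geometric trajectory analyses against brute-force distance oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import binom, chisquare

from oligopath import md
from oligopath.errors import MissingAtomsError

from conftest import make_traj


# ---------------------------------------------------------------------------
# brute-force oracles (plain loops, independent of the vectorized paths)

def oracle_hole_filled(traj, frame, hole):
    top, x = traj.topology, traj.coords[frame]
    tails = [
        i for i in range(len(top))
        if top.at[i, "molclass"] == "detergent"
        and top.at[i, "name"].startswith("C")
        and top.at[i, "name"][1:].isdigit()
    ]
    def group(chain, resid, names):
        return [i for i in range(len(top))
                if top.at[i, "chain"] == chain and top.at[i, "resid"] == resid
                and top.at[i, "name"] in names]
    groups = [group(c, r, md.BACKBONE_HEAVY) for c, r in hole.gly_residues]
    cb = [i for c, r in hole.lining_sidechains for i in group(c, r, ("CB",))]
    groups.append(cb)
    for t in tails:
        if all(
            min(np.linalg.norm(x[t] - x[a]) for a in g) <= hole.proximity_cutoff
            for g in groups
        ):
            return True
    return False


def oracle_clusters(traj, frame, cutoff):
    """Union-find over detergent molecules."""
    top, x = traj.topology, traj.coords[frame]
    tails = [i for i in range(len(top))
             if top.at[i, "molclass"] == "detergent"
             and top.at[i, "name"].lstrip("C").isdigit()]
    mols = sorted({top.at[i, "molid"] for i in tails})
    parent = {m: m for m in mols}
    def find(m):
        while parent[m] != m:
            parent[m] = parent[parent[m]]
            m = parent[m]
        return m
    for i in tails:
        for j in tails:
            if np.linalg.norm(x[i] - x[j]) <= cutoff:
                mi, mj = find(top.at[i, "molid"]), find(top.at[j, "molid"])
                parent[mi] = mj
    return len({find(m) for m in mols})


# ---------------------------------------------------------------------------
# hole detection

def micro_hole_system(tail_positions, cb_pos=(4.0, 3.0, 0.0)):
    """Three glycines along x plus one lining CB and given tail carbons."""
    rows, coords = [], []
    for resid, x0 in ((33, 0.0), (37, 4.0), (38, 8.0)):
        for name, dx in (("N", -1.0), ("CA", 0.0), ("C", 1.0), ("O", 1.5)):
            rows.append({"name": name, "resname": "GLY", "resid": resid, "chain": "A"})
            coords.append((x0 + dx, 0.0, 0.0))
    rows.append({"name": "CB", "resname": "MET", "resid": 35, "chain": "A"})
    coords.append(cb_pos)
    for i, p in enumerate(tail_positions):
        rows.append({"name": "C1", "resname": "SDS", "resid": 100 + i, "chain": "S"})
        coords.append(p)
    return make_traj(rows, coords)


MICRO_HOLE = md.GlycineHoleSpec(
    hole_type="II",
    gly_residues=(("A", 33), ("A", 37), ("A", 38)),
    lining_sidechains=(("A", 35),),
)


class TestHoleDetection:
    def test_satisfying_tail_carbon_detected(self):
        traj = micro_hole_system([(4.0, 1.5, 0.0)])
        filled, molid = md.detect_hole_filled(traj, 0, MICRO_HOLE)
        assert filled and molid is not None

    def test_tail_too_far_from_one_glycine(self):
        traj = micro_hole_system([(13.0, 1.5, 0.0)])  # > 5 A from Gly33
        filled, molid = md.detect_hole_filled(traj, 0, MICRO_HOLE)
        assert not filled and molid is None

    def test_split_criterion_across_two_carbons_not_counted(self):
        """One carbon near the glycines, another near the lining CB: no
        single carbon satisfies both clauses, so the hole is unfilled."""
        traj = micro_hole_system(
            [(4.0, 1.5, 0.0), (4.0, 9.0, 0.0)], cb_pos=(4.0, 12.0, 0.0)
        )
        filled, _ = md.detect_hole_filled(traj, 0, MICRO_HOLE)
        assert not filled
        assert not oracle_hole_filled(traj, 0, MICRO_HOLE)

    def test_missing_atoms_reported(self):
        traj = micro_hole_system([(4.0, 1.5, 0.0)])
        hole = md.GlycineHoleSpec(
            hole_type="II",
            gly_residues=(("A", 33), ("A", 37), ("B", 38)),
            lining_sidechains=(("A", 35),),
        )
        with pytest.raises(MissingAtomsError, match="B:38"):
            md.detect_hole_filled(traj, 0, hole)

    def test_agrees_with_oracle_on_toy_fixture(self, toy_system_small):
        _, traj, truth, holes = toy_system_small
        for frame in range(traj.n_frames):
            for h, hole in enumerate(holes):
                got, _ = md.detect_hole_filled(traj, frame, hole)
                assert got == oracle_hole_filled(traj, frame, hole)
                assert got == truth.occupancy[frame, h]


class TestHoleProbabilities:
    def test_planted_exact_fraction(self):
        import oligopath.synthetic as sy

        # dt=1 ns -> frames with t > 10 ns are 11..110, i.e. 100 remain;
        # hole 0 occupied in exactly 30 post-burn-in frames
        rec = sy.ToySystemRecipe(n_frames=111, dt_ns=1.0, seed=1)
        occupancy = np.zeros((111, 8), dtype=bool)
        occupancy[11 + np.arange(30), 0] = True
        traj, _, holes = sy.gen_toy_system(rec, occupancy=occupancy)
        res = md.hole_fill_probabilities([traj], holes, burn_in=10.0)
        assert res.probabilities[0] == pytest.approx(0.30)
        assert np.all(res.probabilities[1:] == 0.0)

    def test_replicate_mean(self):
        import oligopath.synthetic as sy

        rec = sy.ToySystemRecipe(n_frames=61, dt_ns=1.0, seed=2)
        occ_a = np.zeros((61, 8), dtype=bool)
        occ_a[11 + np.arange(10), 3] = True  # 0.2 of the 50 post-burn-in frames
        occ_b = np.zeros((61, 8), dtype=bool)
        occ_b[11 + np.arange(20), 3] = True  # 0.4
        ta, _, holes = sy.gen_toy_system(rec, occupancy=occ_a)
        tb, _, _ = sy.gen_toy_system(rec, occupancy=occ_b)
        res = md.hole_fill_probabilities([ta, tb], holes, burn_in=10.0)
        assert res.probabilities[3] == pytest.approx(0.30)
        assert res.per_replicate[:, 3] == pytest.approx([0.2, 0.4])

    def test_all_frames_in_burn_in_is_error(self, toy_system_small):
        _, traj, _, holes = toy_system_small
        with pytest.raises(ValueError, match="burn-in"):
            md.hole_filled_series(traj, holes[0], burn_in=1e6)


class TestFillCountDistribution:
    def test_all_zero_probabilities(self):
        d = md.fill_count_distribution([0.0] * 8)
        assert d.pmf[0] == 1.0 and d.p_at_least_one == 0.0

    def test_study_rates_closed_form(self):
        d = md.fill_count_distribution([0.3] * 4 + [0.1] * 4)
        assert d.p_at_least_one == pytest.approx(1 - 0.7**4 * 0.9**4, abs=1e-12)
        assert d.p_at_least_two > 0.5

    def test_matches_brute_force_enumeration(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            p = rng.random(8)
            d = md.fill_count_distribution(p)
            brute = np.zeros(9)
            for mask in range(256):
                bits = [(mask >> k) & 1 for k in range(8)]
                prob = np.prod([pi if b else 1 - pi for pi, b in zip(p, bits)])
                brute[sum(bits)] += prob
            assert np.allclose(d.pmf, brute, atol=1e-12)

    @settings(derandomize=True, deadline=None, max_examples=40)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=8))
    def test_pmf_is_a_distribution_with_correct_mean(self, p):
        d = md.fill_count_distribution(p)
        assert d.pmf.size == len(p) + 1
        assert np.all(d.pmf >= -1e-15)
        assert d.pmf.sum() == pytest.approx(1.0, abs=1e-12)
        mean = float(np.arange(d.pmf.size) @ d.pmf)
        assert mean == pytest.approx(sum(p), abs=1e-9)

    def test_equal_p_reduces_to_binomial(self):
        d = md.fill_count_distribution([0.2] * 8)
        assert np.allclose(d.pmf, binom.pmf(np.arange(9), 8, 0.2), atol=1e-12)

    def test_occupancy_histogram_matches_poisson_binomial(self, toy_system_5000):
        """Independently planted per-hole fills produce a number-filled
        histogram consistent with the Poisson-binomial model."""
        _, traj, truth, holes = toy_system_5000
        keep = traj.times > 10.0
        counts_per_frame = truth.occupancy[keep].sum(axis=1)
        n = counts_per_frame.size
        expected = md.fill_count_distribution(truth.fill_rates).pmf * n
        observed = np.bincount(counts_per_frame, minlength=9).astype(float)
        # pool tail bins so every expected count is >= 5
        while expected[-1] < 5 and expected.size > 2:
            expected[-2] += expected[-1]
            observed[-2] += observed[-1]
            expected, observed = expected[:-1], observed[:-1]
        stat, pvalue = chisquare(observed, expected)
        assert pvalue > 0.01


class TestHBonds:
    @staticmethod
    def hbond_system(no_distance, angle_deg):
        """Donor N-H and acceptor O with prescribed N...O distance and
        D-H-A angle (N at origin, H at (1,0,0); O placed by solving for
        the H-O length that realizes the requested heavy-atom distance)."""
        a = np.radians(angle_deg)
        h = np.array([1.0, 0.0, 0.0])
        d = np.array([-np.cos(a), np.sin(a), 0.0])  # unit H->O direction
        # |h + L d| = no_distance  =>  L^2 + 2 (h.d) L + 1 - no^2 = 0
        hd = float(h @ d)
        L = -hd + np.sqrt(hd**2 + no_distance**2 - 1.0)
        o = h + L * d
        assert np.linalg.norm(o) == pytest.approx(no_distance, abs=1e-12)
        rows = [
            {"name": "N", "resname": "VAL", "resid": 36, "chain": "A"},
            {"name": "H", "resname": "VAL", "resid": 36, "chain": "A"},
            {"name": "O", "resname": "MET", "resid": 35, "chain": "B"},
        ]
        coords = [(0.0, 0.0, 0.0), tuple(h), tuple(o)]
        return make_traj(rows, coords)

    def test_ideal_geometry_counted(self):
        traj = self.hbond_system(3.0, 165.0)
        assert md.count_hbonds(traj, 0) == 1

    def test_long_distance_rejected(self):
        traj = self.hbond_system(3.6, 165.0)
        assert md.count_hbonds(traj, 0) == 0

    def test_small_angle_rejected(self):
        traj = self.hbond_system(3.0, 120.0)
        assert md.count_hbonds(traj, 0) == 0

    def test_angle_cutoff_boundary(self):
        crit = md.HBondCriteria(distance_cutoff=3.5, angle_cutoff=125.0)
        assert md.count_hbonds(self.hbond_system(3.0, 126.0), 0, crit) == 1
        assert md.count_hbonds(self.hbond_system(3.0, 124.0), 0, crit) == 0

    def test_missing_hydrogens_is_error(self):
        rows = [
            {"name": "N", "resname": "VAL", "resid": 36, "chain": "A"},
            {"name": "O", "resname": "MET", "resid": 35, "chain": "B"},
        ]
        traj = make_traj(rows, [(0, 0, 0), (3, 0, 0)])
        with pytest.raises(MissingAtomsError, match="hydrogens"):
            md.count_hbonds(traj, 0)

    def test_planted_bonds_recovered(self, toy_system_small):
        _, traj, truth, _ = toy_system_small
        assert md.count_hbonds(traj, 0) == truth.n_hbonds


class TestMicelle:
    @staticmethod
    def chain_of_molecules(n, spacing):
        rows, coords = [], []
        for m in range(n):
            rows.append({"name": "C1", "resname": "SDS", "resid": m + 1, "chain": "S"})
            coords.append((m * spacing, 0.0, 0.0))
        return make_traj(rows, coords)

    def test_two_separated_groups(self):
        rows, coords = [], []
        for m in range(6):
            x = m * 3.0 + (30.0 if m >= 3 else 0.0)
            rows.append({"name": "C1", "resname": "SDS", "resid": m + 1, "chain": "S"})
            coords.append((x, 0.0, 0.0))
        state = md.micelle_clusters(make_traj(rows, coords), 0, contact_cutoff=4.5)
        assert state.n_clusters == 2
        assert state.cluster_sizes == (3, 3)

    def test_chain_is_transitively_single_cluster(self):
        traj = self.chain_of_molecules(10, 4.0)
        state = md.micelle_clusters(traj, 0, contact_cutoff=4.5)
        assert state.n_clusters == 1
        assert state.n_clusters == oracle_clusters(traj, 0, 4.5)

    def test_count_monotone_in_cutoff(self):
        traj = self.chain_of_molecules(8, 4.0)
        counts = [md.micelle_clusters(traj, 0, c).n_clusters for c in (1.0, 4.0, 10.0)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_agrees_with_union_find_on_toy_fixture(self, toy_system_small):
        _, traj, _, _ = toy_system_small
        for frame in (0, 30, 59):
            got = md.micelle_clusters(traj, frame, 4.5).n_clusters
            assert got == oracle_clusters(traj, frame, 4.5)


class TestRemoveOverlaps:
    @staticmethod
    def system_with_detergent_at(dmin):
        rows = [
            {"name": "CA", "resname": "ALA", "resid": 30, "chain": "A"},
            {"name": "C1", "resname": "SDS", "resid": 1, "chain": "S"},
            {"name": "C2", "resname": "SDS", "resid": 1, "chain": "S"},
        ]
        coords = [(0.0, 0.0, 0.0), (dmin, 0.0, 0.0), (dmin + 1.3, 0.0, 0.0)]
        return make_traj(rows, coords)

    def test_overlapping_molecule_removed_entirely(self):
        out = md.remove_overlaps(self.system_with_detergent_at(1.5), cutoff=1.6)
        assert (out.topology["molclass"] == "detergent").sum() == 0
        assert out.n_atoms == 1

    def test_cutoff_dependence(self):
        traj = self.system_with_detergent_at(2.0)
        kept = md.remove_overlaps(traj, cutoff=1.6)
        assert (kept.topology["molclass"] == "detergent").sum() == 2
        removed = md.remove_overlaps(traj, cutoff=2.6)
        assert (removed.topology["molclass"] == "detergent").sum() == 0

    def test_no_overlaps_structure_unchanged(self):
        traj = self.system_with_detergent_at(8.0)
        out = md.remove_overlaps(traj, cutoff=2.6)
        assert out.n_atoms == traj.n_atoms
        assert np.allclose(out.coords, traj.coords)

    def test_nonpositive_cutoff_is_error(self):
        with pytest.raises(ValueError, match="positive"):
            md.remove_overlaps(self.system_with_detergent_at(3.0), cutoff=0.0)


class TestSmoothing:
    def test_constant_series_unchanged(self):
        y = np.full(600, 4.2)
        assert np.allclose(md.smooth_series(y, window=501, polyorder=3), y)

    def test_cubic_polynomial_reproduced(self):
        x = np.linspace(-1, 1, 700)
        y = 2 * x**3 - x**2 + 0.5 * x - 3
        assert np.allclose(md.smooth_series(y, window=501, polyorder=3), y, atol=1e-9)

    def test_interior_matches_local_least_squares_oracle(self):
        rng = np.random.default_rng(5)
        y = np.where(np.arange(200) < 100, 0.0, 1.0) + rng.normal(0, 0.05, 200)
        window, order = 21, 3
        smoothed = md.smooth_series(y, window=window, polyorder=order)
        half = window // 2
        for i in (half, 60, 100, 150, 199 - half):
            seg = y[i - half: i + half + 1]
            coef = np.polyfit(np.arange(-half, half + 1), seg, order)
            assert smoothed[i] == pytest.approx(np.polyval(coef, 0.0), abs=1e-8)

    def test_window_validation(self):
        y = np.ones(100)
        with pytest.raises(ValueError, match="odd"):
            md.smooth_series(y, window=10)
        with pytest.raises(ValueError, match="exceeds"):
            md.smooth_series(y, window=501)


class TestBlockConvergence:
    def test_stationary_replicates_flag_converged(self):
        flags = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            reps = [rng.normal(10.0, 1.0, 1000) for _ in range(4)]
            rep = md.block_convergence(reps, block_points=100)
            flags.append(rep.converged)
        assert sum(flags) >= 18  # one-sided comparison at alpha=0.05

    def test_drifting_trajectories_flag_not_converged(self):
        rng = np.random.default_rng(1)
        drift = np.linspace(0.0, 5.0, 1000)
        reps = [rng.normal(10.0, 1.0, 1000) + drift for _ in range(4)]
        rep = md.block_convergence(reps, block_points=100)
        assert not rep.converged and not rep.within_le_among

    def test_block_span_in_time_units(self):
        rng = np.random.default_rng(2)
        times = [np.arange(4000) * 0.1 for _ in range(2)]  # 400 ns at 100 ps
        reps = [rng.normal(0, 1, 4000) for _ in range(2)]
        rep = md.block_convergence(reps, times=times, block_span=100.0)
        assert rep.block_means.shape == (2, 4)

    def test_single_block_is_error(self):
        reps = [np.ones(100), np.ones(100)]
        with pytest.raises(ValueError, match="2 blocks"):
            md.block_convergence(reps, block_points=100)

    def test_single_replicate_is_error(self):
        with pytest.raises(ValueError, match="replicate"):
            md.block_convergence([np.ones(100)], block_points=10)


class TestRotationInvariance:
    def test_geometric_analyzers_invariant(self, toy_system_small):
        _, traj, truth, holes = toy_system_small
        rng = np.random.default_rng(17)
        Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        if np.linalg.det(Q) < 0:
            Q[:, 0] = -Q[:, 0]
        shift = np.array([12.0, -7.0, 3.0])
        rotated = md.TrajectoryFrames(
            topology=traj.topology.copy(),
            coords=traj.coords @ Q.T + shift,
            times=traj.times,
        )
        frame = 0
        assert md.count_hbonds(rotated, frame) == md.count_hbonds(traj, frame)
        assert (md.micelle_clusters(rotated, frame).n_clusters
                == md.micelle_clusters(traj, frame).n_clusters)
        for hole in holes:
            assert (md.detect_hole_filled(rotated, frame, hole)[0]
                    == md.detect_hole_filled(traj, frame, hole)[0])
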