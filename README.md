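# oligopath

Analysis toolkit for the detergent-assisted oligomerization pathway of
amyloid-β (Aβ42): the quantitative steps that connect solid-state NMR
measurements and MD trajectories of a β-sheet tetramer in SDS/DPC
micelles to structural conclusions.

Aβ42 monomers exposed to detergent micelles assemble into a tetramer
whose C-terminal strands (residues 30–42) form an antiparallel β-sheet;
after detergent removal this preformed sheet is incorporated into a
large (~150 kD) oligomer. Testing that picture requires four kinds of
computation, one per module:

* **`oligopath.spectra`** — compare 2D ¹³C-¹³C correlation spectra.
  Spectra are regridded to a common 0.2 ppm grid, thresholded at 4× the
  noise level, scaled by the closed-form least-squares factor
  c = ΣAB/ΣB², and summarized by a normalized intensity RMSD plus a
  ppm-valued RMSD over matched crosspeak centers (2D Gaussian fits,
  nearest-center matching). Two spectra of "the same structure" show a
  position RMSD far below a linewidth.
* **`oligopath.dilution`** — isotopic-dilution combinatorics. For a
  sheet of n strands with adjacency E and labeling fraction f applied at
  the monomer or dimer stage, the module enumerates all labeling
  configurations and computes P(∃ (i,j) ∈ E with both strands labeled) —
  the event a dipolar-recoupling decay is sensitive to. For the
  4-strand sheet at f = ½ this gives 50% (monomer-stage) vs 75%
  (dimer-stage): a faster decay indicates dilution later in assembly.
* **`oligopath.pithirds`** — dipolar-recoupling decay fits. Decays are
  normalized to the t = 0 point and fitted to the near-Lorentzian
  y = 1/[1+(t/t_d)^α] (weighted least squares, α fixed — e.g. 1.84 —
  or free), with 95% CIs from the asymptotic covariance.
* **`oligopath.md`** — trajectory analyses: glycine-hole occupancy (a
  hole formed by the missing sidechains of Gly33/Gly37/Gly38 is filled
  when one detergent tail carbon is within 5 Å of backbone atoms of all
  three glycines *and* of a lining sidechain Cβ), the Poisson-binomial
  model of the number of holes filled, hydrogen-bond counting
  (3.5 Å / 125°), micelle clustering, overlap removal for system
  preparation, Savitzky–Golay smoothing, and block-wise convergence
  checks.
* **`oligopath.synthetic`** — generators for all of the above with
  planted ground truth: Gaussian-crosspeak spectrum pairs, noisy
  near-Lorentzian decays, and an idealized sheet-in-micelle trajectory
  in which hole fills, hydrogen bonds and micelle splits are planted
  exactly.

## Worked example

```python
from oligopath import md, synthetic as sy

recipe = sy.ToySystemRecipe(n_frames=3000, seed=1)
traj, truth, holes = sy.gen_toy_system(recipe)
result = md.hole_fill_probabilities([traj], holes, burn_in=10.0)
dist = md.fill_count_distribution(result.probabilities)
print(dist.p_at_least_one, dist.p_at_least_two)
```

Running `python examples/glycine_holes.py` (which does the above and
more) prints:

```
per-hole filling probabilities (planted -> detected):
  type II  half0_front  0.30 -> 0.308
  type I   half0_front  0.10 -> 0.098
  ...
P(at least one hole filled) = 0.847
P(two or more holes filled) = 0.510
```

The detected per-hole probabilities recover the planted rates (0.3 for
type II/III holes, 0.1 for type I/IV) within binomial error; feeding
them into the independence model says at least one hole is occupied
~85% of the time and two or more are occupied more than half the time —
the level of detergent-tail engagement that stabilizes the sheet.

The other scripts in `examples/` each exercise one capability:
`isotopic_dilution.py` (stage-dependent labeling probabilities),
`pithirds_fit.py` (36 vs 30 ms half-decay discrimination),
`spectral_comparison.py` (intensity/position RMSD between spectrum
pairs), `micelle_and_hbonds.py` (hydrogen bonds, clustering, overlap
removal, convergence).

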