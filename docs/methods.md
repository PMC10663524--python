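# Methods

This note records the models, conventions and numerical choices behind
each module, what the synthetic fixtures do and do not emulate, and the
design decisions that were genuinely open.

## Spectral comparison (`oligopath.spectra`)

A `Spectrum2D` is a gridded intensity map over two strictly increasing
ppm axes. Crosspeaks are fitted by least squares to an axis-aligned 2D
Gaussian plus a constant baseline, initialized from the region maximum
and intensity-weighted second moments; 95% CIs come from the asymptotic
parameter covariance. A flat region or non-convergent fit raises with
diagnostics rather than returning a silent result, and the residual RMS
is reported so callers can flag single-peak fits applied to overlapping
peaks (residual ≫ noise).

Noise is the RMS intensity over a user-supplied union of crosspeak-free
rectangles (≥ 50 grid points required).

Two spectra are compared in three steps:

1. both are bilinearly interpolated onto a common grid — 0.2 ppm
   spacing, anchored at the lower bound of the comparison range (default
   10–75 ppm, closed interval). Bilinear interpolation is monotone and
   exact on linear fields; requesting a range a spectrum does not cover
   is an error naming the missing interval.
2. the counted set is every grid point above `threshold_factor` (default
   4) times the spectrum's own noise level in at least one of the two
   spectra. Thresholding each spectrum against its own noise keeps the
   counted set invariant when either input is rescaled together with its
   noise estimate; a single shared threshold (e.g. the larger of the two
   levels) would not have that property. Thresholding precedes scaling.
3. the second spectrum is multiplied by the closed-form least-squares
   factor c = ΣAB/ΣB² over the counted set.

Two mismatch metrics are then reported. The *intensity RMSD* is
RMS(A − cB)/RMS(A) over the counted set — dimensionless, symmetric
between the inputs, and zero exactly when the spectra are proportional.
The *position RMSD* is in ppm: crosspeaks above threshold are detected
(3×3 local maxima, centers refined by Gaussian fits in a ±1 ppm
window), matched between the spectra greedily shortest-distance-first
within a 1.0 ppm gate (a bijection on the matched set; unmatched peaks
are reported, not penalized), and the per-dimension center deviations
are pooled across both dimensions before taking the RMS. A uniform
planted shift of δ in both dimensions therefore reads back as exactly δ.
The two metrics are deliberately kept side by side: the procedure
operates on intensities, but a ppm-valued figure is how closeness of two
spectra is naturally quoted, and the position metric is the one on that
scale. When no peaks match, the position RMSD is NaN.

## Dilution combinatorics (`oligopath.dilution`)

Strands are nodes of an adjacency graph (default: a path, i.e. each
strand hydrogen-bonded to its immediate neighbors, no wraparound —
matching a flat sheet). A labeling scheme assigns each *unit* — a
monomer, or a dimer of the partition (default: adjacent pairs
{(0,1),(2,3)}) — a labeled flag independently with probability f
(default 0.5, i.e. 1:1 mixing). `enumerate_configs` expands all 2^units
configurations exactly (bounded at 24 strands); `sample_configs` is the
seeded Monte-Carlo check. The quantity of interest is the probability
that at least one adjacent strand pair is fully labeled — read as "two
or more neighboring labeled sites"; for f = ½ on a path of n strands its
complement is the independent-set count Fibonacci(n+2)/2ⁿ, which the
tests verify against brute force for n = 2…12.

`classify_site_sensitivity` reduces site geometry to the minimum
inter-site distance over adjacent strand pairs and compares it to a
5 Å proximity cutoff (inclusive): carbonyl-like sites a strand apart
(~4.8 Å) are dilution-sensitive, sidechain sites ≥ 10 Å apart are not
and serve as negative controls.

The module stops at probabilities and orderings; it does not model the
quantitative mapping from labeled-pair probability to decay rate, which
would require spin dynamics.

## Decay fitting (`oligopath.pithirds`)

The near-Lorentzian y(t) = 1/[1+(t/t_d)^α] has y(0) = 1 and
y(t_d) = ½ identically; α controls the sharpness of the transition. The
fit is weighted least squares (weights from the 95% CI half-widths when
supplied and positive), with t_d initialized from the interpolated
half-crossing. α may be held fixed — the default 1.84 is the shared
exponent under which half-decay times are compared across samples — or
fitted freely; whether the exponent should be common or per-curve is
not decidable from a single dataset, so both modes exist. The optimizer
runs with tight tolerances (1e-14) so noiseless synthetic data is
recovered to ≤ 1e-6 relative error; t_d reaching the search bound
(100× the last time point) or fewer than 4 points or no point below
y = 0.9 are explicit errors. CIs are asymptotic (1.96 × the standard
error from the covariance); no bootstrap is performed.

Normalization divides by the t = 0 (else minimal-t) intensity and
propagates uncertainty by the first-order ratio rule, so an exact
reference simply scales the CIs.

The default synthetic time grid is nine points spanning 0–61.4 ms, the
recoupling-time window of the experiments the fits target; the noise
default (σ = 0.03 of the normalized intensity) is a realistic
peak-height uncertainty at that signal averaging. Under these
conditions 200 paired noisy replicates separate t_d = 36 ms from
30 ms in ≥ 99% of pairs (verified in the acceptance suite).

## Trajectory analyses (`oligopath.md`)

Coordinates are Å, times ns, and no periodic-boundary imaging is
applied — inputs are assumed whole. Atom identity is by (chain, resid,
name) plus a molecule class (protein/detergent/water/ion) derived from
residue names when not supplied.

**Glycine holes.** A hole is specified by three (chain, resid) glycine
positions, a set of lining sidechains, and a 5 Å cutoff (inclusive —
"within 5 Å" is read as ≤). The criterion requires a *single* detergent
tail carbon simultaneously within the cutoff of ≥ 1 backbone heavy atom
(N, CA, C, O) on *each* glycine and of ≥ 1 lining Cβ; two carbons each
satisfying half the criterion do not count. Which chains the three
glycines sit on is part of the spec object, so the user controls the
registry. Per-hole probabilities are occupied-frame fractions after a
10 ns burn-in, averaged arithmetically over replicate trajectories with
per-replicate values retained.

**Fill-count model.** Given per-hole probabilities, the distribution of
the number filled under independence is computed exactly by the
Poisson-binomial dynamic program (equal probabilities reduce it to the
binomial); P(≥1) and P(≥2) are reported. The pipeline property that
independently planted occupancies produce a count histogram consistent
with this model (χ², α = 0.01) is the testable form of the independence
claim.

**Hydrogen bonds.** Donor–acceptor heavy-atom distance ≤ 3.5 Å and
donor–hydrogen–acceptor angle ≥ 125°, the convention of the standard
trajectory tools; backbone N–H donors and carbonyl-O acceptors by
default, with explicit index arrays for anything else. Hydrogens are
required — the criterion is angle-dependent — and their absence is an
error, not a fallback.

**Micelles.** Two detergent molecules are in contact when any pair of
their tail carbons is within the contact cutoff; micelles are connected
components of that graph. The 4.5 Å default cutoff is this package's
choice — micelle splitting is usually judged visually, and no cutoff is
standard — so it is configurable and the cluster count is monotone
nonincreasing in it.

**Overlap removal.** System-preparation style: any removable
(detergent/water/ion) molecule with an atom strictly within the cutoff
of the reference selection is deleted whole, never truncated.

**Smoothing and convergence.** Savitzky–Golay smoothing (default window
501 points, polynomial order 3, endpoint handling by truncated-window
polynomial fits) reproduces polynomials up to the fitted order exactly.
Block convergence cuts each replicate's series into blocks (default
250 ns) and compares the variance of block means along single
trajectories (averaged over replicates) with the variance of block
means across replicates at matched blocks (averaged over blocks). The
two estimators are on the same scale, so for a stationary process their
ratio is ~1; `converged` is a one-sided F comparison at α = 0.05
(within not significantly exceeding among), which tolerates estimator
noise, while the raw `within ≤ among` boolean is also reported. A
drifting (nonstationary) trajectory inflates the within-trajectory
variance and trips the flag; differing means *between* replicates
inflate the among-replicate variance instead and are visible in the
reported per-trajectory means.

## Synthetic fixtures (`oligopath.synthetic`)

The generators exist so every operation above can be validated against
planted ground truth without downloads.

*Spectra* are sums of axis-aligned Gaussians plus i.i.d. noise on the
comparison grid itself (0.2 ppm), so regridding is the identity and
closed-form expectations (scale factors, shift-induced position RMSDs)
hold exactly. *Decays* sample the near-Lorentzian at the experimental
time grid with Gaussian noise.

The *toy sheet-in-micelle system* is an idealized lattice: extended
strands with Cα spacing 3.8 Å, strand spacing 4.8 Å, backbone atoms
(N, H, CA, C, O) at fixed offsets, Cβ on alternating faces by residue
parity, and the Aβ42 C-strand sequence (residues 30–42) on each of four
chains. Antiparallel neighbors run in opposite directions with a
one-residue registry shift so Gly33 aligns with Gly38 of the adjacent
strand (and Val36 with Met35), reproducing the alignment that creates
the glycine holes. The hole table has four types per strand half — the
two glycine triplets (Gly37/38 + neighbor Gly33, and Gly33 + neighbor
Gly37/38), each opening onto both faces — with lining sidechains taken
as the lattice's CB-bearing residues flanking the glycines on the
matching face (which are the same aliphatic residues — Ile32, Leu34,
Val36, Val39/40 — that line the holes in the real structure). Default
fill rates are 0.3 for type II/III and 0.1 for type I/IV holes, the
values observed in the simulations the toy emulates; the default
trajectory is 5000 frames at 100 ps/frame with a 10 ns burn-in.

Detergents are 12-carbon bead chains (1.27 Å spacing) with a head bead,
resting 30 Å from the sheet in one or more planted clusters (3.5 Å
within-group spacing, 30 Å gaps). Each hole has a dedicated filler
molecule; a planting point for every hole is found by grid search such
that it satisfies its own criterion with a 0.3 Å margin and *fails*
every other hole's criterion with the same margin — so planted
occupancy is exact, with no cross-talk between holes (the build
self-verifies this with inline distance checks, including the resting
positions and the outward-pointing tail beads, and raises on any
violation). Hydrogen bonds are planted by moving an acceptor carbonyl O
to 3.0 Å from the donor N along the line of the (re-aimed) N–H, giving
a 180° angle; acceptors on the glycines are rejected so hole geometry
is untouched, and the default lattice has exactly zero hydrogen bonds
otherwise (amide H points off-plane).

What the toy does **not** emulate: force-field energetics, realistic
micelle packing, solvent, thermal backbone fluctuations, periodic
boundaries, or the kinetics of filling events (frames are independent
Bernoulli draws). Passing tests therefore demonstrate the correctness
of the *measurements* — criteria, counters, estimators — not the
physics of any particular trajectory; applying the analyses to real
trajectories exercises exactly the same code paths via the PDB adapter.

## Problem sizes

Exact enumeration handles ≤ 24 strands (2²⁴ configurations); the
default Monte-Carlo checks use 10⁵–2×10⁵ samples. Parameter-recovery
studies use 200 paired replicates per half-decay time. Toy trajectories
used in validation are 5000 frames × ~500 atoms; per-hole occupancy
over such a trajectory evaluates in under a second via the chunked
vectorized path, and all fixtures are generated in memory at run time.

## Known limitations

* Peak matching is greedy; pathological peak clusters within the 1 ppm
  gate could be matched suboptimally compared to an optimal assignment.
* The spectral comparison assumes both spectra cover the full
  comparison range; partial-coverage comparisons are an error rather
  than a masked comparison.
* Hydrogen-bond detection covers backbone donors/acceptors natively;
  sidechain chemistry must be supplied as explicit index arrays.
* `fit_near_lorentzian` CIs are asymptotic and can be optimistic for
  very short curves; the recovery tests quantify actual coverage at the
  default grid.
* The toy lattice fixes sidechain faces by residue parity, which is a
  simplification of real β-sheet geometry; hole lining sets are
  editable configuration, not structural predictions.
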