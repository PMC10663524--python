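"""Glycine-hole filling: detect planted events and model their counts.

The antiparallel C-terminal β-sheet tetramer presents eight 'glycine
holes' — voids left by the missing sidechains of Gly33/Gly37/Gly38 —
that detergent hydrocarbon tails can occupy.  A hole counts as filled
when one tail carbon is within 5 Å of backbone atoms of all three
glycines and of a lining sidechain Cβ.  This script builds a toy
trajectory with known per-hole filling rates, recovers them, and
compares the number-filled distribution with the independent-filling
(Poisson-binomial) model.
"""

import numpy as np

from oligopath import md, synthetic as sy

recipe = sy.ToySystemRecipe(n_frames=3000, seed=1)  # rates: II/III 0.3, I/IV 0.1
traj, truth, holes = sy.gen_toy_system(recipe)
print(f"toy system: {traj.n_atoms} atoms, {traj.n_frames} frames "
      f"({traj.times[-1]:.0f} ns at 100 ps/frame)")

result = md.hole_fill_probabilities([traj], holes, burn_in=10.0)
print("\nper-hole filling probabilities (planted -> detected):")
for hole, rate, p in zip(holes, truth.fill_rates, result.probabilities):
    print(f"  type {hole.hole_type:<3} {hole.label:<12} {rate:.2f} -> {p:.3f}")

dist = md.fill_count_distribution(result.probabilities)
print(f"\nP(at least one hole filled) = {dist.p_at_least_one:.3f}")
print(f"P(two or more holes filled) = {dist.p_at_least_two:.3f}")

keep = traj.times > 10.0
counts = truth.occupancy[keep].sum(axis=1)
observed = np.bincount(counts, minlength=9) / counts.size
print("\nnumber-filled distribution (observed vs independent model):")
for k in range(5):
    print(f"  {k} holes: {observed[k]:.3f} vs {dist.pmf[k]:.3f}")

print()
print("Detected probabilities track the planted rates, and the count")
print("histogram follows the Poisson-binomial model — holes fill")
print("independently, and at least one is occupied ~85% of the time.")
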