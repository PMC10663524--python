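"""When were the β-sheets assembled? Ask the isotopic-dilution statistics.

Mixing ¹³C-labeled and unlabeled material 1:1 before assembly (monomer-
stage dilution) or after dimer formation (dimer-stage dilution) leaves
different fractions of 4-strand sheets with labeled sites on neighboring
strands — the configuration a dipolar-recoupling decay experiment is
sensitive to.  A faster observed decay therefore indicates dilution later
in the assembly pathway.
"""

import numpy as np

from oligopath import dilution as dl

top = dl.SheetTopology(n_strands=4)

for stage in ("monomer", "dimer"):
    scheme = dl.LabelingScheme(stage, labeled_fraction=0.5)
    exact = dl.prob_adjacent_labeled_pair(top, scheme)
    sampled = dl.sample_configs(top, scheme, n_samples=100_000, seed=7)
    freq = sampled.probability(
        lambda flags: any(flags[i] and flags[j] for i, j in top.adjacency)
    )
    print(f"{stage}-stage dilution (1:1): "
          f"P(>=1 adjacent labeled pair) = {exact:.4f} "
          f"(Monte-Carlo check: {freq:.4f})")

# The same enumeration on longer sheets: the no-adjacent-pair probability
# follows the Fibonacci independent-set count on a path.
for n in (4, 6, 8):
    p = dl.prob_adjacent_labeled_pair(
        dl.SheetTopology(n), dl.LabelingScheme("monomer", 0.5))
    print(f"path of {n} strands, monomer-stage: P = {p:.4f}")

# Which labeled sites respond to dilution at all?  A carbonyl site whose
# adjacent-strand distance is 4.8 A is dilution-sensitive; a sidechain
# site >= 10 A from every neighbor is a negative control.
co_like = np.array([[0, 0, 0], [0, 4.8, 0], [0, 9.6, 0], [0, 14.4, 0.0]])
cb_like = np.array([[0, 0, 0], [10.5, 4.8, 0], [0, 9.6, 0], [10.5, 14.4, 0.0]])
for name, coords in (("carbonyl-like", co_like), ("sidechain-like", cb_like)):
    cls = dl.classify_site_sensitivity(coords, top.adjacency)
    print(f"{name} site: min adjacent distance {cls.min_labeled_pair_distance:.1f} A"
          f" -> {cls.label}")

print()
print("Monomer-stage dilution leaves half the tetramers with neighboring")
print("labeled sites; dimer-stage dilution leaves three quarters, so its")
print("dipolar decay is faster at the same overall labeled fraction.")
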