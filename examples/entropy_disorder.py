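"""Chromatin disorder measured by Von Neumann entropy.

Simulates one structured contact map, destroys its architecture by
shuffling contacts within each diagonal (preserving the distance decay),
and compares the entropy of the two.  Structured chromatin concentrates
the correlation spectrum on few modes, so its entropy is lower.
"""

import numpy as np

from hic3d import entropy, matrix, simulate

truth = simulate.make_truth(seed=0)
m = simulate.simulate_contact_map(truth, "condition1", seed=1)
balanced = matrix.kr_balance(m)

structured = entropy.von_neumann_entropy(balanced)

rng = np.random.default_rng(2)
shuffled_data = {}
for chrom, a in balanced.data.items():
    n = a.shape[0]
    sh = np.zeros_like(a)
    idx = np.arange(n)
    for d in range(n):
        vals = np.diagonal(a, offset=d).copy()
        rng.shuffle(vals)
        sh[idx[: n - d], idx[: n - d] + d] = vals
    shuffled_data[chrom] = np.triu(sh) + np.triu(sh, 1).T
shuffled = entropy.von_neumann_entropy(
    matrix.ContactMatrix(genome=balanced.genome, data=shuffled_data,
                         state=matrix.BALANCED))

print(f"{'chromosome':<12}{'VNE structured':>16}{'VNE shuffled':>14}")
for s, sh in zip(structured, shuffled):
    print(f"{s.chromosome:<12}{s.vne:>16.4f}{sh.vne:>14.4f}")
print("\nLower entropy = more ordered chromatin: the planted compartment/"
      "TAD/loop\nstructure is destroyed by the shuffle, so every shuffled "
      "chromosome scores higher.")
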