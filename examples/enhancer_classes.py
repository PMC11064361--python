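"""Enhancer element construction and SE/RE/PE classification.

H3K27ac peaks are merged within 12.5 kb, ranked by aggregate signal, and
split into super-enhancers (SE) and regular enhancers (RE) at the ROSE
tangent cutoff; distal interaction anchors without H3K27ac become poised
enhancers (PE).
"""

import pandas as pd

from hic3d import enhancers, simulate

truth = simulate.make_truth(seed=0)
_, _, peaks = simulate.simulate_chip_tracks(truth, seed=1)

elements = enhancers.merge_rank_elements(peaks)
cutoff, elements = enhancers.rose_classify(elements)
n_se = sum(e.klass == "SE" for e in elements)
print(f"{len(elements)} enhancer elements; ROSE cutoff signal "
      f"{cutoff:.1f} -> {n_se} SE, {len(elements) - n_se} RE")

top = sorted(elements, key=lambda e: -e.signal)[:5]
print("\ntop elements by aggregate signal:")
for e in top:
    print(f"  {e.chrom}:{e.start}-{e.end}  signal {e.signal:8.1f}  {e.klass}")

# distal anchors that lack any H3K27ac element are poised
anchors = pd.DataFrame(
    [{"chrom": l.chrom,
      "start": l.enhancer_bin * truth.genome.resolution,
      "end": (l.enhancer_bin + 1) * truth.genome.resolution}
     for l in truth.loops])
poised = enhancers.classify_poised(anchors, elements)
print(f"\n{int(poised['poised'].sum())} of {len(poised)} distal loop "
      "anchors have no H3K27ac element -> poised enhancers")
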