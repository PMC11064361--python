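"""Promoter-enhancer interaction calling, per-gene regulatory potential
scores (RPS), and differential rewiring between two conditions.

The simulator plants focal loops inside TADs and rewires a fraction of
them between conditions; the caller tests each promoter-candidate pair
against a domain-aware expected model and keeps FDR-controlled,
fold-enriched contacts.  RPS = sum of log10(In) over a gene's retained
interactions.
"""

from hic3d import pei, pipeline, simulate

truth = simulate.make_truth(seed=0)
promoters = truth.genes[truth.genes["gene"].str.startswith("g")]

rps = {}
for k, cond in enumerate(("condition1", "condition2")):
    raw = simulate.simulate_contact_map(truth, cond, seed=20 + k)
    balanced, oe = pipeline.balance_and_oe(raw)
    domains = pipeline.call_tads(balanced, oe)
    records, gene_rps = pipeline.rps_per_gene(balanced, promoters, domains)
    rps[cond] = {g: r.rps for g, r in gene_rps.items()}
    planted = sum(l.active[cond] for l in truth.loops)
    print(f"{cond}: {len(records)} retained interactions "
          f"({planted} loops planted); "
          f"{sum(1 for v in rps[cond].values() if v > 0)} genes with RPS > 0")

for fc, delta, label in [(3.0, 2.0, "strict"), (1.0, 1.0, "sensitive")]:
    diff = pei.differential_rps(rps["condition1"], rps["condition2"],
                                fc_threshold=fc, delta_threshold=delta)
    up = (diff["call"] == "up").sum()
    down = (diff["call"] == "down").sum()
    print(f"\ndifferential RPS ({label}: |log2FC| > {fc}, |delta| > {delta}):"
          f" {up} up, {down} down of {len(diff)} genes")

rewired = sum(1 for l in truth.loops
              if l.active["condition1"] != l.active["condition2"])
print(f"\n(the simulator rewired {rewired} of {len(truth.loops)} loops; "
      "a single gained or lost\nloop shifts RPS by ~log10(In) = 2-3, so "
      "the strict published-style thresholds only\nflag genes that lose "
      "or gain most of their interactions, while the sensitive\nsetting "
      "flags single-loop rewiring)")
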