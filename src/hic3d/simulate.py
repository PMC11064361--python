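"""Two-condition synthetic chromatin-architecture generator with planted
truth.

The generator emulates the statistical structure the pipeline assumes:
power-law distance decay, checkerboard compartments with a small
switching fraction between conditions, nested TADs with rare boundary
changes, focal promoter-enhancer loops with condition-specific rewiring,
heavy-tailed enhancer signal, and expression coupled to compartment
state and regulatory potential.  Every stage emits its ground truth so
recovery can be scored without external data.

Default scale is 4 chromosomes of 250 bins at a 20-kb analog resolution
with 2M contacts per chromosome — minutes of compute on one CPU while
keeping per-pair counts deep enough for the statistics to behave as they
would on real deep maps.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .matrix import RAW, ContactMatrix

CHIP_BIN = 1000

DEFAULTS = dict(
    n_chromosomes=4,
    bins_per_chromosome=250,
    resolution=20_000,
    switch_fraction=0.02,
    n_boundary_changes=2,
    n_loops=12,               # per chromosome
    rewire_fraction=0.3,
    depth=2_000_000,          # contacts per chromosome
    decay_exponent=1.0,
    comp_boost=1.6,
    tad_boost=2.0,
    sub_boost=1.4,
    loop_boost=5.0,
)


@dataclass
class PlantedLoop:
    chrom: str
    promoter_bin: int
    enhancer_bin: int
    gene: str
    active: dict[str, bool]   # condition -> loop present


@dataclass
class PlantedEnhancer:
    chrom: str
    start: int
    end: int
    height: float
    is_super: bool


@dataclass
class ArchitectureTruth:
    """Everything the simulator planted, keyed by condition names
    'condition1' / 'condition2'."""

    genome_spec: dict            # n_chromosomes, bins_per_chromosome, resolution
    compartments: dict[str, dict[str, list[str]]]   # cond -> chrom -> labels
    large_tads: dict[str, dict[str, list[list[int]]]]
    sub_tads: dict[str, dict[str, list[list[int]]]]
    loops: list[PlantedLoop]
    enhancers: list[PlantedEnhancer]
    genes: pd.DataFrame          # gene, chrom, tss
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def genome(self) -> BinnedGenome:
        spec = self.genome_spec
        sizes = {f"chr{i + 1}": spec["bins_per_chromosome"] * spec["resolution"]
                 for i in range(spec["n_chromosomes"])}
        return BinnedGenome(chromsizes=sizes, resolution=spec["resolution"])

    def boundaries(self, condition: str, chrom: str) -> list[int]:
        pts: set[int] = set()
        for s, e in self.large_tads[condition][chrom]:
            pts.update((s, e))
        return sorted(pts)

    def switched_bins(self, chrom: str) -> np.ndarray:
        a = np.array(self.compartments["condition1"][chrom])
        b = np.array(self.compartments["condition2"][chrom])
        return np.flatnonzero(a != b)

    def planted_rps(self, condition: str,
                    loop_boost: float | None = None) -> dict[str, float]:
        """Idealized per-gene regulatory potential implied by the planted
        loops: each active loop contributes log10(loop_boost)."""
        boost = loop_boost if loop_boost is not None else self.params.get(
            "loop_boost", DEFAULTS["loop_boost"])
        out: dict[str, float] = {g: 0.0 for g in self.genes["gene"]}
        for lp in self.loops:
            if lp.active[condition]:
                out[lp.gene] = out.get(lp.gene, 0.0) + float(np.log10(boost))
        return out

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "genome_spec": self.genome_spec,
            "compartments": self.compartments,
            "large_tads": self.large_tads,
            "sub_tads": self.sub_tads,
            "loops": [
                {"chrom": l.chrom, "promoter_bin": l.promoter_bin,
                 "enhancer_bin": l.enhancer_bin, "gene": l.gene,
                 "active": l.active}
                for l in self.loops],
            "enhancers": [
                {"chrom": e.chrom, "start": e.start, "end": e.end,
                 "height": e.height, "is_super": e.is_super}
                for e in self.enhancers],
            "genes": self.genes.to_dict(orient="list"),
            "seed": self.seed,
            "params": self.params,
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def read(cls, path: str) -> "ArchitectureTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            genome_spec=payload["genome_spec"],
            compartments=payload["compartments"],
            large_tads={c: {k: [list(t) for t in v]
                            for k, v in d.items()}
                        for c, d in payload["large_tads"].items()},
            sub_tads={c: {k: [list(t) for t in v]
                          for k, v in d.items()}
                      for c, d in payload["sub_tads"].items()},
            loops=[PlantedLoop(**l) for l in payload["loops"]],
            enhancers=[PlantedEnhancer(**e) for e in payload["enhancers"]],
            genes=pd.DataFrame(payload["genes"]),
            seed=payload["seed"],
            params=payload["params"],
        )


# ---------------------------------------------------------------------------

def _compartment_labels(rng: np.random.Generator, n_bins: int,
                        mean_block: int = 50) -> list[str]:
    """Alternating A/B blocks with geometric block lengths (min 4 bins).

    The default mean block of 50 bins is a megabase at the 20-kb analog
    resolution — compartments are Mb-scale, larger than TADs."""
    labels: list[str] = []
    state = rng.choice(["A", "B"])
    while len(labels) < n_bins:
        block = 4 + rng.geometric(1.0 / (mean_block - 3))
        labels.extend([state] * int(block))
        state = "B" if state == "A" else "A"
    return labels[:n_bins]


def _tads_for_chrom(rng: np.random.Generator, n_bins: int):
    """Large TADs of 20-30 bins, each cut into 2-3 sub-TADs."""
    large: list[list[int]] = []
    cursor = 0
    while cursor < n_bins:
        size = int(rng.integers(20, 31))
        end = min(cursor + size, n_bins)
        if n_bins - end < 12:     # absorb a short tail into the last TAD
            end = n_bins
        large.append([cursor, end])
        cursor = end
    subs: list[list[int]] = []
    for s, e in large:
        k = int(rng.integers(2, 4))
        width = e - s
        if width < k * 5:
            k = max(1, width // 5)
        cuts = sorted(rng.choice(np.arange(s + 5, e - 4), size=k - 1,
                                 replace=False).tolist()) if k > 1 else []
        pts = [s] + [int(c) for c in cuts] + [e]
        # enforce >= 5 bins per sub-TAD by dropping crowding cuts
        cleaned = [pts[0]]
        for p in pts[1:-1]:
            if p - cleaned[-1] >= 5 and pts[-1] - p >= 5:
                cleaned.append(p)
        cleaned.append(pts[-1])
        subs.extend([[cleaned[i], cleaned[i + 1]]
                     for i in range(len(cleaned) - 1)])
    return large, subs


def make_truth(n_chromosomes: int = DEFAULTS["n_chromosomes"],
               bins_per_chromosome: int = DEFAULTS["bins_per_chromosome"],
               switch_fraction: float = DEFAULTS["switch_fraction"],
               n_boundary_changes: int = DEFAULTS["n_boundary_changes"],
               n_loops: int = DEFAULTS["n_loops"],
               rewire_fraction: float = DEFAULTS["rewire_fraction"],
               seed: int = 0,
               resolution: int = DEFAULTS["resolution"]) -> ArchitectureTruth:
    """Plant a two-condition architecture.

    Condition 2 derives from condition 1 by flipping exactly
    ``round(switch_fraction * total_bins)`` compartment bins (in short
    contiguous runs), removing ``n_boundary_changes`` internal large-TAD
    boundaries, and rewiring ``rewire_fraction`` of the loops
    (half become condition-1-specific, half condition-2-specific).
    """
    if not 0 <= switch_fraction <= 1:
        raise ValueError("switch_fraction must be in [0, 1]")
    if min(n_chromosomes, bins_per_chromosome, n_loops) < 1:
        raise ValueError("size parameters must be positive")
    rng = np.random.default_rng(seed)
    chroms = [f"chr{i + 1}" for i in range(n_chromosomes)]

    comp1: dict[str, list[str]] = {}
    large1: dict[str, list[list[int]]] = {}
    sub1: dict[str, list[list[int]]] = {}
    for c in chroms:
        comp1[c] = _compartment_labels(rng, bins_per_chromosome)
        large1[c], sub1[c] = _tads_for_chrom(rng, bins_per_chromosome)

    # --- condition-2 compartments: flip exactly k bins in short runs
    total_bins = n_chromosomes * bins_per_chromosome
    k_switch = int(round(switch_fraction * total_bins))
    comp2 = {c: list(comp1[c]) for c in chroms}
    flipped: set[tuple[str, int]] = set()
    flip = lambda s: "B" if s == "A" else "A"
    while len(flipped) < k_switch:
        c = chroms[int(rng.integers(n_chromosomes))]
        run = min(int(rng.integers(2, 5)), k_switch - len(flipped))
        start = int(rng.integers(0, bins_per_chromosome - run))
        cells = [(c, start + i) for i in range(run)]
        if any(x in flipped for x in cells):
            continue
        for ch, b in cells:
            comp2[ch][b] = flip(comp2[ch][b])
            flipped.add((ch, b))

    # --- condition-2 TADs: remove internal boundaries (merge neighbors)
    internal = [(c, i) for c in chroms
                for i in range(1, len(large1[c]))]
    if n_boundary_changes > len(internal):
        raise ValueError("more boundary changes requested than internal "
                         "boundaries exist")
    removed_idx = rng.choice(len(internal), size=n_boundary_changes,
                             replace=False) if n_boundary_changes else []
    removals: dict[str, set[int]] = {c: set() for c in chroms}
    for ri in removed_idx:
        c, i = internal[int(ri)]
        removals[c].add(large1[c][i][0])   # the boundary bin being removed
    large2: dict[str, list[list[int]]] = {}
    sub2: dict[str, list[list[int]]] = {}
    for c in chroms:
        merged: list[list[int]] = []
        for s, e in large1[c]:
            if merged and s in removals[c]:
                merged[-1] = [merged[-1][0], e]
            else:
                merged.append([s, e])
        large2[c] = merged
        sub2[c] = [list(t) for t in sub1[c]
                   if not (t[0] in removals[c] or t[1] in removals[c])]

    # --- loops and genes
    loops: list[PlantedLoop] = []
    gene_rows = []
    gene_id = 0
    for c in chroms:
        placed = 0
        # a few promoters host multiple loops so enhancer counts vary
        multiplicity = [3, 2] + [1] * n_loops
        while placed < n_loops:
            tad = large1[c][int(rng.integers(len(large1[c])))]
            s, e = tad
            if e - s < 12:
                continue
            p = int(rng.integers(s + 1, e - 8))
            k = min(multiplicity.pop(0), n_loops - placed)
            gene = f"g{c}_{gene_id}"
            gene_id += 1
            gene_rows.append({"gene": gene, "chrom": c,
                              "tss": p * resolution + resolution // 2})
            used = {p}
            for _ in range(k):
                for _try in range(50):
                    off = int(rng.integers(5, min(40, e - s)))
                    q = p + off if p + off < e else p - off
                    if s <= q < e and q not in used:
                        used.add(q)
                        break
                else:
                    continue
                loops.append(PlantedLoop(chrom=c, promoter_bin=p,
                                         enhancer_bin=q, gene=gene,
                                         active={"condition1": True,
                                                 "condition2": True}))
                placed += 1

    n_rewire = int(round(rewire_fraction * len(loops)))
    rewire_idx = rng.choice(len(loops), size=n_rewire, replace=False)
    for pos, li in enumerate(rewire_idx):
        lp = loops[int(li)]
        if pos % 2 == 0:
            lp.active["condition2"] = False   # condition-1-specific
        else:
            lp.active["condition1"] = False   # condition-2-specific

    # --- background genes, biased toward A bins (gene-rich compartment)
    for c in chroms:
        labels = np.array(comp1[c])
        for b in range(0, bins_per_chromosome, 5):
            p_gene = 0.75 if labels[b] == "A" else 0.25
            if rng.random() < p_gene:
                gene_rows.append({
                    "gene": f"bg{c}_{b}", "chrom": c,
                    "tss": b * resolution + int(rng.integers(resolution))})
    genes = pd.DataFrame(gene_rows).drop_duplicates("gene")

    # --- enhancer elements: most loop anchors carry H3K27ac with
    # heavy-tailed heights (so super-enhancers exist); the rest stay
    # unmarked and should surface downstream as poised enhancers
    enhancers: list[PlantedEnhancer] = []
    for c in chroms:
        anchors = sorted({lp.enhancer_bin for lp in loops if lp.chrom == c})
        n_marked = max(2, int(round(0.75 * len(anchors))))
        marked = sorted(rng.choice(len(anchors), size=min(n_marked,
                                                          len(anchors)),
                                   replace=False).tolist())
        heights = rng.lognormal(mean=1.0, sigma=0.6, size=len(marked))
        super_at = set(rng.choice(len(marked), size=min(2, len(marked)),
                                  replace=False).tolist())
        for i, ai in enumerate(marked):
            b = anchors[ai]
            h = float(heights[i] * (20.0 if i in super_at else 1.0))
            start = b * resolution + resolution // 4
            enhancers.append(PlantedEnhancer(
                chrom=c, start=start, end=start + 4000, height=h,
                is_super=i in super_at))

    return ArchitectureTruth(
        genome_spec={"n_chromosomes": n_chromosomes,
                     "bins_per_chromosome": bins_per_chromosome,
                     "resolution": resolution},
        compartments={"condition1": comp1, "condition2": comp2},
        large_tads={"condition1": large1, "condition2": large2},
        sub_tads={"condition1": sub1, "condition2": sub2},
        loops=loops, enhancers=enhancers, genes=genes, seed=seed,
        params=dict(switch_fraction=switch_fraction,
                    n_boundary_changes=n_boundary_changes,
                    n_loops=n_loops, rewire_fraction=rewire_fraction))


# ---------------------------------------------------------------------------

def expected_rates(truth: ArchitectureTruth, condition: str,
                   depth: float = DEFAULTS["depth"],
                   decay_exponent: float = DEFAULTS["decay_exponent"],
                   comp_boost: float = DEFAULTS["comp_boost"],
                   tad_boost: float = DEFAULTS["tad_boost"],
                   sub_boost: float = DEFAULTS["sub_boost"],
                   loop_boost: float = DEFAULTS["loop_boost"],
                   ) -> dict[str, np.ndarray]:
    """Per-chromosome expected contact rate lambda(i,j), scaled so the
    expected total (upper triangle incl. diagonal) equals ``depth``."""
    if decay_exponent < 0:
        raise ValueError("decay exponent must be >= 0")
    if min(comp_boost, tad_boost, sub_boost, loop_boost) < 1:
        raise ValueError("boosts must be >= 1")
    out: dict[str, np.ndarray] = {}
    nb = truth.genome_spec["bins_per_chromosome"]
    for chrom in truth.genome.chromsizes:
        labels = np.array(truth.compartments[condition][chrom])
        idx = np.arange(nb)
        dist = np.abs(np.subtract.outer(idx, idx))
        lam = (1.0 + dist) ** (-decay_exponent)
        same_comp = labels[:, None] == labels[None, :]
        lam *= np.where(same_comp, comp_boost, 1.0)
        tad_id = np.full(nb, -1)
        for k, (s, e) in enumerate(truth.large_tads[condition][chrom]):
            tad_id[s:e] = k
        same_tad = (tad_id[:, None] == tad_id[None, :]) & (tad_id[:, None] >= 0)
        lam *= np.where(same_tad, tad_boost, 1.0)
        sub_id = np.full(nb, -1)
        for k, (s, e) in enumerate(truth.sub_tads[condition][chrom]):
            sub_id[s:e] = k
        same_sub = (sub_id[:, None] == sub_id[None, :]) & (sub_id[:, None] >= 0)
        lam *= np.where(same_sub, sub_boost, 1.0)
        for lp in truth.loops:
            if lp.chrom == chrom and lp.active[condition]:
                lam[lp.promoter_bin, lp.enhancer_bin] *= loop_boost
                lam[lp.enhancer_bin, lp.promoter_bin] *= loop_boost
        total = np.triu(lam).sum()
        lam *= depth / total
        if lam.max() > 1e12:
            raise ValueError("requested depth overflows sane count scale")
        out[chrom] = lam
    return out


def simulate_contact_map(truth: ArchitectureTruth, condition: str = "condition1",
                         depth: float = DEFAULTS["depth"],
                         decay_exponent: float = DEFAULTS["decay_exponent"],
                         comp_boost: float = DEFAULTS["comp_boost"],
                         tad_boost: float = DEFAULTS["tad_boost"],
                         sub_boost: float = DEFAULTS["sub_boost"],
                         loop_boost: float = DEFAULTS["loop_boost"],
                         seed: int = 0) -> ContactMatrix:
    """Draw a raw contact map: Poisson counts around the planted expected
    rates, symmetrized."""
    rng = np.random.default_rng(seed)
    rates = expected_rates(truth, condition, depth, decay_exponent,
                           comp_boost, tad_boost, sub_boost, loop_boost)
    data: dict[str, np.ndarray] = {}
    for chrom, lam in rates.items():
        n = lam.shape[0]
        iu = np.triu_indices(n)
        counts = rng.poisson(lam[iu]).astype(float)
        mat = np.zeros((n, n))
        mat[iu] = counts
        mat = mat + np.triu(mat, 1).T
        data[chrom] = mat
    return ContactMatrix(genome=truth.genome, data=data, state=RAW)


def covariate_tracks(truth: ArchitectureTruth, seed: int = 0,
                     gc_contrast: float = 0.10,
                     gc_noise: float = 0.01) -> pd.DataFrame:
    """Per-bin GC fraction and gene count (columns chrom, bin, gc,
    gene_count).  GC is higher in A-compartment bins (condition 1
    labels), matching the A = GC-rich convention used for orientation."""
    rng = np.random.default_rng(seed)
    res = truth.genome_spec["resolution"]
    rows = []
    counts: dict[tuple[str, int], int] = {}
    for _, g in truth.genes.iterrows():
        key = (g["chrom"], int(g["tss"]) // res)
        counts[key] = counts.get(key, 0) + 1
    for chrom in truth.genome.chromsizes:
        labels = truth.compartments["condition1"][chrom]
        for b, lab in enumerate(labels):
            gc = 0.38 + (gc_contrast if lab == "A" else 0.0) + \
                rng.normal(0, gc_noise)
            rows.append({"chrom": chrom, "bin": b,
                         "gc": float(np.clip(gc, 0, 1)),
                         "gene_count": counts.get((chrom, b), 0)})
    return pd.DataFrame(rows)


def simulate_chip_tracks(truth: ArchitectureTruth, noise_sd: float = 0.5,
                         seed: int = 0, baseline: float = 10.0):
    """IP and input coverage on 1-kb bins plus a peak BED.

    input = flat baseline + Gaussian noise; IP = input + planted element
    heights over each element's bins; peaks = the element intervals.
    Returns (ip, input) dicts chrom -> array and a peaks DataFrame.
    """
    rng = np.random.default_rng(seed)
    genome = truth.genome
    ip: dict[str, np.ndarray] = {}
    inp: dict[str, np.ndarray] = {}
    for chrom, length in genome.chromsizes.items():
        n = length // CHIP_BIN
        base = baseline + rng.normal(0, noise_sd, size=n)
        base = np.clip(base, 0, None)
        track = base.copy()
        for el in truth.enhancers:
            if el.chrom != chrom:
                continue
            track[el.start // CHIP_BIN: el.end // CHIP_BIN] += el.height
        ip[chrom] = track
        inp[chrom] = base
    peaks = pd.DataFrame([
        {"chrom": e.chrom, "start": e.start, "end": e.end,
         "signal": e.height}
        for e in truth.enhancers])
    return ip, inp, peaks


def simulate_expression(truth: ArchitectureTruth, rps_effect: float = 0.6,
                        compartment_effect: float = 0.5,
                        dispersion: float = 0.1, seed: int = 0,
                        n_replicates: int = 5,
                        baseline_mean: float = 50.0) -> pd.DataFrame:
    """Per-gene expression counts per condition and replicate.

    log mean = log(baseline) + rps_effect * planted RPS +
    compartment_effect * [gene bin in compartment A]; counts are
    negative-binomial via the gamma-Poisson mixture with
    Var = mu + dispersion * mu^2.
    """
    rng = np.random.default_rng(seed)
    res = truth.genome_spec["resolution"]
    rows = []
    for condition in ("condition1", "condition2"):
        rps = truth.planted_rps(condition)
        labels = truth.compartments[condition]
        for _, g in truth.genes.iterrows():
            b = int(g["tss"]) // res
            in_a = labels[g["chrom"]][b] == "A"
            logmu = np.log(baseline_mean) + rps_effect * rps.get(g["gene"], 0.0) \
                + compartment_effect * (1.0 if in_a else 0.0)
            mu = float(np.exp(logmu))
            if dispersion > 0:
                shape = 1.0 / dispersion
                lam = rng.gamma(shape, mu / shape, size=n_replicates)
            else:
                lam = np.full(n_replicates, mu)
            counts = rng.poisson(lam)
            for r, cnt in enumerate(counts, start=1):
                rows.append({"gene": g["gene"], "condition": condition,
                             "replicate": r, "count": int(cnt), "mu": mu})
    return pd.DataFrame(rows)
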