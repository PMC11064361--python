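"""A/B compartment calling from the first principal component of the
observed-over-expected correlation matrix, covariate-based sign
orientation, the A-B contact-preference index, and condition switching.

The sign of a raw eigenvector is arbitrary; the convention here (as in
the field) is that compartment A is the gene-rich, GC-rich, active state,
so each chromosome's PC1 is flipped when its Spearman correlation with GC
content is negative.  Gene count breaks ties when the GC correlation is
too weak to trust.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import OE, ContactMatrix

NO_CALL = "."


@dataclass(frozen=True)
class CovariateTrack:
    """Per-bin orientation covariates on one chromosome."""

    gc: np.ndarray          # GC fraction in [0, 1]
    gene_count: np.ndarray  # genes with TSS in the bin, >= 0

    def __post_init__(self) -> None:
        if len(self.gc) != len(self.gene_count):
            raise ValueError("covariate tracks differ in length")
        if np.any((self.gc < 0) | (self.gc > 1)):
            raise ValueError("GC fraction outside [0, 1]")


@dataclass
class CompartmentProfile:
    """Oriented PC1 with A/B labels for one chromosome."""

    chromosome: str
    pc1: np.ndarray            # oriented, unit length over usable bins
    labels: np.ndarray         # 'A' / 'B' / '.' per bin
    orientation_rho: float     # Spearman rho vs the orientation covariate
    flipped: bool
    ab_index: np.ndarray | None = None

    @property
    def percent_a(self) -> float:
        called = np.isin(self.labels, ["A", "B"]).sum()
        return 100.0 * (self.labels == "A").sum() / called if called else float("nan")

    @property
    def percent_b(self) -> float:
        called = np.isin(self.labels, ["A", "B"]).sum()
        return 100.0 * (self.labels == "B").sum() / called if called else float("nan")


@dataclass(frozen=True)
class SwitchEvent:
    chromosome: str
    start_bin: int
    end_bin: int            # half-open
    direction: str          # 'A-to-B' or 'B-to-A'
    span_bp: int


@dataclass(frozen=True)
class SwitchSummary:
    events: list[SwitchEvent]
    switched_bp: int
    genome_fraction: float          # of labeled bins
    percent_a: dict[str, float]     # condition -> %A over labeled bins
    percent_b: dict[str, float]
    gene_switches: pd.DataFrame | None = None


def compute_pc1(oe: ContactMatrix, min_bins: int = 10) -> dict[str, np.ndarray]:
    """First principal component of the Pearson correlation matrix of the
    O/E matrix, per chromosome.

    Masked bins are excluded from the decomposition and re-inserted as
    NaN.  Chromosomes with fewer than ``min_bins`` usable bins, or a
    degenerate (constant) correlation structure, are skipped.
    """
    if oe.state != OE:
        raise ValueError("compute_pc1 expects an observed-over-expected matrix")
    out: dict[str, np.ndarray] = {}
    for chrom, mat in oe.data.items():
        keep = ~oe.masked[chrom]
        n = mat.shape[0]
        pc1 = np.full(n, np.nan)
        sub = mat[np.ix_(keep, keep)]
        if keep.sum() < min_bins:
            continue
        sd = sub.std(axis=0)
        usable = sd > 0
        if usable.sum() < min_bins:
            continue
        corr = np.corrcoef(sub[np.ix_(usable, usable)], rowvar=False)
        w, v = np.linalg.eigh(corr)
        vec = v[:, -1]
        vec = vec / np.linalg.norm(vec)
        inner = np.flatnonzero(keep)[usable]
        pc1[inner] = vec
        out[chrom] = pc1
    return out


def orient_and_label(pc1: np.ndarray, cov: CovariateTrack,
                     chromosome: str = "chr",
                     weak_rho: float = 0.1) -> CompartmentProfile:
    """Orient PC1 so A (positive) correlates positively with GC content,
    then label bins: A where PC1 > 0, B where PC1 < 0, no-call where
    masked (NaN) or exactly 0.

    When |rho(PC1, GC)| < ``weak_rho`` the gene-count covariate decides
    the orientation instead.
    """
    pc1 = np.asarray(pc1, dtype=float)
    if len(pc1) != len(cov.gc):
        raise ValueError("PC1 and covariate lengths differ")
    usable = ~np.isnan(pc1)
    if usable.sum() < 3:
        raise ValueError("too few usable bins to orient")

    def rho_vs(track: np.ndarray) -> float:
        if np.std(track[usable]) == 0:
            raise ValueError("zero-variance covariate")
        r, _ = stats.spearmanr(pc1[usable], track[usable])
        return float(r)

    rho = rho_vs(cov.gc)
    if abs(rho) < weak_rho:
        rho = rho_vs(cov.gene_count.astype(float))
    flipped = rho < 0
    oriented = -pc1 if flipped else pc1.copy()
    labels = np.full(len(pc1), NO_CALL, dtype=object)
    labels[usable & (oriented > 0)] = "A"
    labels[usable & (oriented < 0)] = "B"
    return CompartmentProfile(chromosome=chromosome, pc1=oriented,
                              labels=labels, orientation_rho=abs(rho),
                              flipped=flipped)


def ab_index(oe: ContactMatrix, profile: CompartmentProfile,
             chrom: str | None = None) -> np.ndarray:
    """Per-bin A-B contact preference:
    (meanA - meanB) / (meanA + meanB), self-contact excluded; in [-1, 1].

    NaN where the bin is masked or the chromosome lacks A or B bins.
    """
    chrom = chrom or profile.chromosome
    mat = oe.data[chrom]
    n = mat.shape[0]
    is_a = profile.labels == "A"
    is_b = profile.labels == "B"
    index = np.full(n, np.nan)
    if not is_a.any() or not is_b.any():
        profile.ab_index = index
        return index
    for i in range(n):
        if profile.labels[i] == NO_CALL:
            continue
        row = mat[i]
        a_sel = is_a.copy()
        b_sel = is_b.copy()
        a_sel[i] = False
        b_sel[i] = False
        if not a_sel.any() or not b_sel.any():
            continue
        mean_a = row[a_sel].mean()
        mean_b = row[b_sel].mean()
        denom = mean_a + mean_b
        if denom > 0:
            index[i] = (mean_a - mean_b) / denom
    profile.ab_index = index
    return index


def detect_switches(p1: CompartmentProfile, p2: CompartmentProfile,
                    resolution: int,
                    genes: pd.DataFrame | None = None) -> SwitchSummary:
    """Compare two conditions' compartment labels on one chromosome.

    Contiguous runs of switched bins merge into events; the summary
    reports total switched bp, the fraction of jointly labeled bins that
    switched, and per-condition %A/%B.  ``genes`` (columns gene, chrom,
    tss) are assigned to events by TSS bin.
    """
    if len(p1.labels) != len(p2.labels):
        raise ValueError("profiles are on different binnings")
    l1, l2 = p1.labels, p2.labels
    called = np.isin(l1, ["A", "B"]) & np.isin(l2, ["A", "B"])
    switched = called & (l1 != l2)
    events: list[SwitchEvent] = []
    i = 0
    n = len(l1)
    while i < n:
        if switched[i]:
            j = i
            while j + 1 < n and switched[j + 1] and l1[j + 1] == l1[i]:
                j += 1
            direction = f"{l1[i]}-to-{l2[i]}"
            events.append(SwitchEvent(
                chromosome=p1.chromosome, start_bin=i, end_bin=j + 1,
                direction=direction, span_bp=(j + 1 - i) * resolution))
            i = j + 1
        else:
            i += 1
    switched_bp = sum(e.span_bp for e in events)
    frac = switched.sum() / called.sum() if called.sum() else float("nan")
    gene_df = None
    if genes is not None:
        rows = []
        for _, g in genes.iterrows():
            if g["chrom"] != p1.chromosome:
                continue
            b = int(g["tss"]) // resolution
            if b >= n:
                continue
            direction = "stable"
            if switched[b]:
                direction = f"{l1[b]}-to-{l2[b]}"
            rows.append({"gene": g["gene"], "bin": b, "switch": direction,
                         "state_1": l1[b], "state_2": l2[b]})
        gene_df = pd.DataFrame(rows)
    return SwitchSummary(
        events=events, switched_bp=switched_bp, genome_fraction=float(frac),
        percent_a={"condition1": p1.percent_a, "condition2": p2.percent_a},
        percent_b={"condition1": p1.percent_b, "condition2": p2.percent_b},
        gene_switches=gene_df)
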