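"""H3K27ac signal scoring and enhancer classification.

Enhancer elements are built by merging nearby H3K27ac peaks (within
12.5 kb by default), scored by aggregate signal, and split into
super-enhancers (SE) and regular enhancers (RE) by the ROSE rank-ordering
cutoff: with both rank and signal scaled to the unit interval, the cutoff
sits where the slope of the signal-vs-rank curve equals 1, i.e. where the
curve is furthest below the diagonal.  Distal interaction anchors that
overlap no H3K27ac element are poised enhancers (PE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SignalTrack:
    """log2 IP/input enrichment on fixed 1-kb bins of one chromosome."""

    chromosome: str
    bin_size: int
    ip_density: np.ndarray      # FPKM-like: fragments per kb per million
    input_density: np.ndarray
    signal: np.ndarray          # log2((ip + c) / (input + c))


@dataclass
class EnhancerElement:
    chrom: str
    start: int
    end: int
    signal: float           # aggregate (length-weighted) signal
    rank: int = -1          # 1 = strongest
    klass: str = ""         # 'SE' / 'RE' / 'PE'
    tss_distance: int | None = None


def fpkm(counts: np.ndarray, bin_size: int, library_size: float) -> np.ndarray:
    """Fragments per kilobase per million mapped fragments."""
    if library_size <= 0:
        raise ValueError("library size must be positive")
    return counts / (bin_size / 1000.0) / (library_size / 1e6)


def chip_signal(ip_coverage: np.ndarray, input_coverage: np.ndarray,
                bin_size: int = 1000, pseudocount: float = 0.5,
                chromosome: str = "chr",
                ip_library_size: float | None = None,
                input_library_size: float | None = None) -> SignalTrack:
    """Per-bin enrichment log2((IP + c) / (input + c)) on FPKM scale.

    Library sizes default to the track totals.  Both tracks must share
    one binning.
    """
    ip = np.asarray(ip_coverage, dtype=float)
    inp = np.asarray(input_coverage, dtype=float)
    if ip.shape != inp.shape:
        raise ValueError("IP and input tracks have mismatched binning")
    ip_lib = ip_library_size if ip_library_size is not None else max(ip.sum(), 1.0)
    in_lib = input_library_size if input_library_size is not None else max(inp.sum(), 1.0)
    ipf = fpkm(ip, bin_size, ip_lib)
    inf_ = fpkm(inp, bin_size, in_lib)
    signal = np.log2((ipf + pseudocount) / (inf_ + pseudocount))
    return SignalTrack(chromosome=chromosome, bin_size=bin_size,
                       ip_density=ipf, input_density=inf_, signal=signal)


def merge_rank_elements(peaks: pd.DataFrame,
                        merge_distance: int = 12500) -> list[EnhancerElement]:
    """Merge peaks within ``merge_distance`` into enhancer elements and
    rank them by descending aggregate signal.

    ``peaks`` needs columns chrom, start, end, signal.  Merging is
    transitive (chains of nearby peaks collapse into one element);
    aggregate signal is the length-weighted sum sum(signal * length_kb).
    """
    if peaks.empty:
        return []
    if (peaks["end"] <= peaks["start"]).any():
        raise ValueError("negative or empty peak interval")
    elements: list[EnhancerElement] = []
    for chrom, grp in peaks.groupby("chrom", sort=False):
        grp = grp.sort_values("start")
        cur_s, cur_e, cur_sig = None, None, 0.0
        for _, row in grp.iterrows():
            s, e, sig = int(row["start"]), int(row["end"]), float(row["signal"])
            w = sig * (e - s) / 1000.0
            if cur_s is None:
                cur_s, cur_e, cur_sig = s, e, w
            elif s - cur_e <= merge_distance:
                cur_e = max(cur_e, e)
                cur_sig += w
            else:
                elements.append(EnhancerElement(chrom, cur_s, cur_e, cur_sig))
                cur_s, cur_e, cur_sig = s, e, w
        if cur_s is not None:
            elements.append(EnhancerElement(chrom, cur_s, cur_e, cur_sig))
    elements.sort(key=lambda el: (-el.signal, el.chrom, el.start))
    for r, el in enumerate(elements, start=1):
        el.rank = r
    return elements


def rose_classify(elements: list[EnhancerElement]) -> tuple[float, list[EnhancerElement]]:
    """Split ranked elements into SE / RE at the ROSE tangent cutoff.

    Signals and ranks are scaled to [0, 1] (ascending); the cutoff is the
    ranked position where the scaled curve's slope reaches 1 — found as
    the point furthest below the unit diagonal — and elements with signal
    strictly above the cutoff signal are SE.  With fewer than 2 elements,
    or all signals equal, nothing is SE.

    Returns (cutoff signal, elements with ``klass`` set).
    """
    for el in elements:
        el.klass = "RE"
    if len(elements) < 2:
        return float("inf"), elements
    sig = np.array(sorted(el.signal for el in elements), dtype=float)
    lo, hi = sig[0], sig[-1]
    if hi == lo:
        return float("inf"), elements
    y = (sig - lo) / (hi - lo)
    x = np.arange(len(sig)) / (len(sig) - 1)
    cut_idx = int(np.argmin(y - x))
    cutoff = float(sig[cut_idx])
    for el in elements:
        if el.signal > cutoff:
            el.klass = "SE"
    return cutoff, elements


def classify_poised(anchor_intervals: pd.DataFrame,
                    h3k27ac_elements: list[EnhancerElement]) -> pd.DataFrame:
    """Label distal interaction anchors lacking H3K27ac overlap as PE.

    ``anchor_intervals`` needs columns chrom, start, end; a boolean
    ``poised`` column is returned alongside.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for el in h3k27ac_elements:
        by_chrom.setdefault(el.chrom, []).append((el.start, el.end))
    for chrom in by_chrom:
        by_chrom[chrom].sort()

    def overlaps(chrom: str, s: int, e: int) -> bool:
        for es, ee in by_chrom.get(chrom, []):
            if es >= e:
                break
            if ee > s:
                return True
        return False

    out = anchor_intervals.copy()
    out["poised"] = [
        not overlaps(r["chrom"], int(r["start"]), int(r["end"]))
        for _, r in anchor_intervals.iterrows()
    ]
    return out
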