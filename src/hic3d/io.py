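"""Plain-text I/O: pairs files, dense per-chromosome matrices, bedGraph,
BED and chromosome sizes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genome import BinnedGenome
from .matrix import ContactMatrix, bin_contacts, parse_pairs


def read_pairs_file(path: str, genome: BinnedGenome) -> ContactMatrix:
    """Bin a whitespace-delimited pairs file (chrom1 pos1 chrom2 pos2
    [count]; '#' comments ignored) into a raw contact matrix."""
    with open(path) as fh:
        return bin_contacts(parse_pairs(fh, genome), genome)


def write_pairs_file(path: str, m: ContactMatrix) -> None:
    """Write non-zero upper-triangle entries as binned pairs with counts
    (positions at bin midpoints)."""
    res = m.genome.resolution
    with open(path, "w") as fh:
        fh.write("# chrom1\tpos1\tchrom2\tpos2\tcount\n")
        for chrom, mat in m.data.items():
            iu = np.triu_indices(mat.shape[0])
            vals = mat[iu]
            nz = vals > 0
            for i, j, v in zip(iu[0][nz], iu[1][nz], vals[nz]):
                p1 = i * res + res // 2
                p2 = j * res + res // 2
                fh.write(f"{chrom}\t{p1}\t{chrom}\t{p2}\t{int(round(v))}\n")


def write_dense_matrix(path: str, m: ContactMatrix, chrom: str) -> None:
    """Per-chromosome dense TSV with a header row/column of bin starts."""
    res = m.genome.resolution
    mat = m.data[chrom]
    starts = np.arange(mat.shape[0]) * res
    df = pd.DataFrame(mat, index=starts, columns=starts)
    df.to_csv(path, sep="\t", index_label="start")


def read_dense_matrix(path: str, genome: BinnedGenome, chrom: str,
                      state: str = "raw") -> ContactMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy(dtype=float)
    return ContactMatrix(genome=genome, data={chrom: mat}, state=state)


def write_bedgraph(path: str, chrom: str, values: np.ndarray,
                   bin_size: int) -> None:
    """bedGraph of per-bin values; NaN bins are skipped."""
    with open(path, "w") as fh:
        for i, v in enumerate(values):
            if np.isnan(v):
                continue
            fh.write(f"{chrom}\t{i * bin_size}\t{(i + 1) * bin_size}\t{v:.6g}\n")


def write_bed(path: str, intervals, name_field: bool = True) -> None:
    """BED of (chrom, start, end[, name]) tuples."""
    with open(path, "w") as fh:
        for rec in intervals:
            line = f"{rec[0]}\t{rec[1]}\t{rec[2]}"
            if name_field and len(rec) > 3:
                line += f"\t{rec[3]}"
            fh.write(line + "\n")


def write_chromsizes(path: str, genome: BinnedGenome) -> None:
    with open(path, "w") as fh:
        for chrom, length in genome.chromsizes.items():
            fh.write(f"{chrom}\t{length}\n")
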