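"""Binned genome coordinate system shared by all Hi-C computations.

Bins are 0-based, half-open ``[start, end)`` and tile each chromosome
contiguously; the last bin of a chromosome may be shorter than the
resolution.  The global bin index is dense and contiguous per chromosome,
in the order chromosomes were declared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class BinnedGenome:
    """A set of chromosomes cut into fixed-width bins.

    Parameters
    ----------
    chromsizes
        Mapping of chromosome name to length in bp (insertion order is
        the genome order).
    resolution
        Bin width in bp.
    """

    chromsizes: dict[str, int]
    resolution: int
    _offsets: dict[str, int] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1 bp")
        for name, length in self.chromsizes.items():
            if length < 1:
                raise ValueError(f"chromosome {name} has non-positive length")
        offsets: dict[str, int] = {}
        cursor = 0
        for name in self.chromsizes:
            offsets[name] = cursor
            cursor += self.n_bins(name)
        object.__setattr__(self, "_offsets", offsets)

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chromsizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chromsizes[chrom] // self.resolution)  # ceil div

    @property
    def total_bins(self) -> int:
        return sum(self.n_bins(c) for c in self.chromsizes)

    def bin_of(self, chrom: str, pos: int) -> int:
        """Chromosome-local bin index of a bp position (0-based)."""
        length = self.chromsizes.get(chrom)
        if length is None:
            raise KeyError(f"unknown chromosome: {chrom}")
        if not 0 <= pos < length:
            raise ValueError(f"position {pos} outside {chrom}:[0,{length})")
        return pos // self.resolution

    def bins(self) -> pd.DataFrame:
        """Dense bin table with columns chrom, start, end."""
        frames = []
        for name, length in self.chromsizes.items():
            starts = np.arange(0, length, self.resolution, dtype=np.int64)
            ends = np.minimum(starts + self.resolution, length)
            frames.append(pd.DataFrame({"chrom": name, "start": starts, "end": ends}))
        return pd.concat(frames, ignore_index=True)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BinnedGenome):
            return NotImplemented
        return (
            self.resolution == other.resolution
            and self.chromsizes == other.chromsizes
        )

    def __hash__(self) -> int:
        return hash((self.resolution, tuple(self.chromsizes.items())))


def read_chromsizes(path: str) -> dict[str, int]:
    """Read a two-column (name, length) TSV of chromosome sizes."""
    df = pd.read_csv(path, sep=r"\s+", header=None, names=["chrom", "length"],
                     comment="#")
    return dict(zip(df["chrom"].astype(str), df["length"].astype(int)))
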