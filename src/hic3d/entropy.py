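"""Von Neumann entropy of chromatin contact structure.

The contact matrix of a chromosome is log-transformed, its column-wise
Pearson correlation matrix C is formed, and the entropy of the normalized
eigenvalue spectrum of C is reported.  An ordered chromosome (strong
block/checkerboard structure) concentrates spectral mass on few
eigenvalues and yields low entropy; a disordered one spreads mass and
approaches the ln(n) maximum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .matrix import ContactMatrix


@dataclass(frozen=True)
class EntropyResult:
    chromosome: str
    n: int                       # correlation-matrix dimension (usable bins)
    eigenvalues: np.ndarray      # raw eigenvalues of C, descending
    normalized: np.ndarray       # clipped and normalized to sum 1
    vne: float                   # -sum lam_i ln lam_i, in nats


def entropy_of_spectrum(eigenvalues: np.ndarray) -> tuple[np.ndarray, float]:
    """Clip negative eigenvalues to 0, normalize to sum 1, and return
    (normalized spectrum, entropy in nats) with the 0*ln0 := 0 convention."""
    lam = np.clip(np.asarray(eigenvalues, dtype=float), 0.0, None)
    total = lam.sum()
    if total <= 0:
        raise ValueError("eigenvalue spectrum has no positive mass")
    lam = lam / total
    nz = lam > 0
    vne = float(-(lam[nz] * np.log(lam[nz])).sum())
    return lam, vne


def correlation_matrix(a: np.ndarray, pseudocount: float = 1.0) -> np.ndarray:
    """C = corr(log2(A + pseudocount)), Pearson over columns."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be > 0")
    la = np.log2(a + pseudocount)
    sd = la.std(axis=0)
    if np.any(sd == 0):
        bad = int(np.flatnonzero(sd == 0)[0])
        raise ValueError(f"all-constant column at bin {bad}")
    return np.corrcoef(la, rowvar=False)


def vne_group_comparison(values_a: list[float],
                         values_b: list[float]) -> dict:
    """Contrast per-sample entropy between two groups with a two-sided
    rank-sum test (the group difference is reported, not modeled)."""
    from scipy import stats
    stat, p = stats.mannwhitneyu(values_a, values_b, alternative="two-sided")
    return {"median_a": float(np.median(values_a)),
            "median_b": float(np.median(values_b)),
            "statistic": float(stat), "p_value": float(p)}


def von_neumann_entropy(m: ContactMatrix,
                        pseudocount: float = 1.0) -> list[EntropyResult]:
    """Per-chromosome Von Neumann entropy of the contact correlation matrix.

    Masked (zero-coverage) bins are excluded before the log2 transform;
    at least 3 usable bins are required per chromosome.
    """
    results = []
    for chrom, mat in m.data.items():
        keep = ~m.masked[chrom]
        if keep.sum() < 3:
            raise ValueError(
                f"{chrom}: fewer than 3 non-masked bins ({int(keep.sum())})")
        sub = mat[np.ix_(keep, keep)]
        c = correlation_matrix(sub, pseudocount)
        lam = np.linalg.eigvalsh(c)[::-1]
        norm, vne = entropy_of_spectrum(lam)
        results.append(EntropyResult(chromosome=chrom, n=c.shape[0],
                                     eigenvalues=lam, normalized=norm,
                                     vne=vne))
    return results
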