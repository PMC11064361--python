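"""Contact-matrix ingestion, balancing, normalization and reproducibility.

The central container is :class:`ContactMatrix`: one dense symmetric square
matrix per chromosome, at a fixed resolution, carrying a state flag that
records whether entries are raw counts, balanced counts, or
observed-over-expected ratios.  Only intrachromosomal contacts are kept.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .genome import BinnedGenome

log = logging.getLogger(__name__)

RAW = "raw"
BALANCED = "balanced"
OE = "observed-over-expected"


@dataclass
class ContactMatrix:
    """Per-chromosome symmetric binned contact matrices.

    Attributes
    ----------
    genome
        The binning the matrices live on.
    data
        chromosome -> (n_bins x n_bins) float array, symmetric, entries >= 0.
    state
        One of ``raw``, ``balanced``, ``observed-over-expected``.
    masked
        chromosome -> boolean array marking zero-coverage (no-call) bins.
    dropped_pairs
        Interchromosomal or otherwise rejected input records.
    """

    genome: BinnedGenome
    data: dict[str, np.ndarray]
    state: str = RAW
    masked: dict[str, np.ndarray] = field(default_factory=dict)
    dropped_pairs: int = 0
    # balancing bias vectors: raw(i,j) = balanced(i,j) * bias[i] * bias[j]
    biases: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for chrom, m in self.data.items():
            n = self.genome.n_bins(chrom)
            if m.shape != (n, n):
                raise ValueError(
                    f"{chrom}: matrix shape {m.shape} != bin count {n}")
            if not np.allclose(m, m.T, rtol=1e-8, atol=1e-8):
                raise ValueError(f"{chrom}: matrix is not symmetric")
            if np.any(m < 0):
                raise ValueError(f"{chrom}: negative contact values")
            if chrom not in self.masked:
                self.masked[chrom] = m.sum(axis=0) == 0

    @property
    def chromosomes(self) -> list[str]:
        return list(self.data)

    @property
    def total_contacts(self) -> float:
        """Sum over upper triangles including the diagonal."""
        total = 0.0
        for m in self.data.values():
            total += np.triu(m).sum()
        return total

    def copy(self) -> "ContactMatrix":
        return replace(
            self,
            data={c: m.copy() for c, m in self.data.items()},
            masked={c: v.copy() for c, v in self.masked.items()},
            biases={c: v.copy() for c, v in self.biases.items()},
        )


@dataclass(frozen=True)
class DecayProfile:
    """Mean contact per diagonal distance stratum, one profile per chromosome."""

    means: dict[str, np.ndarray]   # chrom -> mean contact at |i-j| = s
    counts: dict[str, np.ndarray]  # chrom -> number of pairs per stratum


@dataclass(frozen=True)
class ReplicateSimilarity:
    """Stratum-adjusted correlation between two replicate contact maps."""

    sample_a: str
    sample_b: str
    scc: float
    per_chromosome: dict[str, float]
    smoothing_halfwidth: int
    max_distance_bins: int


class MalformedPairError(ValueError):
    pass


def parse_pairs(lines, genome: BinnedGenome):
    """Yield (chromA, posA, chromB, posB, count) from pairs-format lines.

    Whitespace-delimited columns ``chrom1 pos1 chrom2 pos2 [count]``;
    ``#`` comment lines are ignored.  Unknown chromosomes reject the
    record with a warning; malformed lines raise with the line number.
    """
    for lineno, line in enumerate(lines, start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) not in (4, 5):
            raise MalformedPairError(
                f"line {lineno}: expected 4 or 5 columns, got {len(fields)}")
        try:
            c1, p1, c2, p2 = fields[0], int(fields[1]), fields[2], int(fields[3])
            count = int(fields[4]) if len(fields) == 5 else 1
        except ValueError as exc:
            raise MalformedPairError(f"line {lineno}: {exc}") from None
        if c1 not in genome.chromsizes or c2 not in genome.chromsizes:
            log.warning("line %d: unknown chromosome, record rejected", lineno)
            continue
        yield c1, p1, c2, p2, count


def bin_contacts(pairs, genome: BinnedGenome) -> ContactMatrix:
    """Bin contact pairs into per-chromosome raw matrices.

    ``pairs`` is an iterable of (chromA, posA, chromB, posB) or
    (..., count) tuples.  Interchromosomal pairs are counted and dropped;
    intrachromosomal pairs are accumulated symmetrically.
    """
    data = {c: np.zeros((genome.n_bins(c),) * 2) for c in genome.chromsizes}
    dropped = 0
    retained = 0
    for rec in pairs:
        c1, p1, c2, p2 = rec[:4]
        count = rec[4] if len(rec) == 5 else 1
        if c1 != c2:
            dropped += 1
            continue
        i = genome.bin_of(c1, p1)
        j = genome.bin_of(c2, p2)
        m = data[c1]
        if i == j:
            m[i, i] += count
        else:
            m[i, j] += count
            m[j, i] += count
        retained += count
    log.info("binned %d contacts, dropped %d interchromosomal pairs",
             retained, dropped)
    return ContactMatrix(genome=genome, data=data, state=RAW,
                         dropped_pairs=dropped)


# ---------------------------------------------------------------------------
# Balancing

def _kr_scaling(a: np.ndarray, tol: float, max_outer: int) -> np.ndarray | None:
    """Knight-Ruiz scaling vector x such that diag(x) A diag(x) is doubly
    stochastic.  Inner-outer Newton iteration with conjugate-gradient inner
    solves; returns None on non-convergence."""
    n = a.shape[0]
    e = np.ones(n)
    x = e.copy()
    delta, Delta = 0.1, 3.0
    g = 0.9
    etamax = 0.1
    eta = etamax
    stop_tol = tol * 0.5

    v = x * (a @ x)
    rk = 1 - v
    rho_km1 = rk @ rk
    rout = rho_km1
    rold = rout

    mvp = 0  # outer iterations
    while rout > stop_tol ** 2 and mvp < max_outer:
        mvp += 1
        k = 0
        y = e.copy()
        innertol = max(eta ** 2 * rout, stop_tol ** 2)
        rho_km1 = rk @ rk
        # CG solve of the Newton system
        while rho_km1 > innertol:
            k += 1
            if k == 1:
                Z = rk / v
                p = Z.copy()
                rho_km1 = rk @ Z
            else:
                beta = rho_km1 / rho_km2
                p = Z + beta * p
            w = x * (a @ (x * p)) + v * p
            alpha = rho_km1 / (p @ w)
            ap = alpha * p
            ynew = y + ap
            if ynew.min() <= delta:
                if delta == 0:
                    break
                ind = ap < 0
                gamma = ((delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            if ynew.max() >= Delta:
                ind = ynew > Delta
                gamma = ((Delta - y[ind]) / ap[ind]).min()
                y = y + gamma * ap
                break
            y = ynew
            rk = rk - alpha * w
            rho_km2 = rho_km1
            Z = rk / v
            rho_km1 = rk @ Z
            if k > 200:
                break
        x = x * y
        v = x * (a @ x)
        rk = 1 - v
        rho_km1 = rk @ rk
        rout = rho_km1
        rat = rout / rold
        rold = rout
        res_norm = np.sqrt(rout)
        eta = g * rat
        eta = min(max(eta, stop_tol / res_norm if res_norm > 0 else etamax),
                  etamax)
        if not np.all(np.isfinite(x)) or x.min() <= 0:
            return None
    if rout > stop_tol ** 2:
        return None
    return x


def _ipf_scaling(a: np.ndarray, tol: float, max_iter: int) -> np.ndarray | None:
    """Symmetric iterative proportional fitting (Sinkhorn-Knopp) fallback."""
    n = a.shape[0]
    x = np.ones(n)
    for _ in range(max_iter):
        s = x * (a @ x)
        if np.abs(s - 1).max() < tol:
            return x
        x = x / np.sqrt(s)
    return None


def kr_balance(m: ContactMatrix, tolerance: float = 1e-6,
               max_iterations: int = 3000) -> ContactMatrix:
    """Knight-Ruiz balance each chromosome so non-masked row sums are equal.

    Zero-coverage rows are masked first and excluded from balancing; the
    mask is propagated on the result.  The balanced matrix is rescaled so
    its total contact sum matches the input, keeping entries on a
    count-like scale.  Falls back to iterative proportional fitting when
    the KR iteration fails to converge; raises if both fail.
    """
    if m.state != RAW:
        raise ValueError(f"kr_balance expects a raw matrix, got {m.state!r}")
    out: dict[str, np.ndarray] = {}
    masks: dict[str, np.ndarray] = {}
    biases: dict[str, np.ndarray] = {}
    for chrom, mat in m.data.items():
        if np.any(mat < 0):
            raise ValueError(f"{chrom}: negative entries")
        mask = mat.sum(axis=0) == 0
        keep = ~mask
        sub = mat[np.ix_(keep, keep)]
        balanced = np.zeros_like(mat)
        bias = np.full(mat.shape[0], np.nan)
        if keep.sum() >= 2 and sub.sum() > 0:
            scale = sub.sum(axis=0).mean()
            a = sub / scale
            x = _kr_scaling(a, tolerance, max_iterations)
            if x is None:
                log.warning("%s: KR did not converge, falling back to IPF",
                            chrom)
                x = _ipf_scaling(a, tolerance, max_iterations)
            if x is None:
                raise RuntimeError(
                    f"balancing failed to converge on chromosome {chrom}")
            bsub = (x[:, None] * sub / scale) * x[None, :]
            # restore total count scale
            rescale = sub.sum() / bsub.sum() if bsub.sum() > 0 else 1.0
            bsub *= rescale
            balanced[np.ix_(keep, keep)] = bsub
            # balanced = raw * (x_i x_j rescale / scale)
            bias[keep] = 1.0 / (x * np.sqrt(rescale / scale))
        out[chrom] = balanced
        masks[chrom] = mask
        biases[chrom] = bias
    return ContactMatrix(genome=m.genome, data=out, state=BALANCED,
                         masked=masks, dropped_pairs=m.dropped_pairs,
                         biases=biases)


def quantile_normalize(samples: list[ContactMatrix]) -> list[ContactMatrix]:
    """Map every sample's per-chromosome value distribution onto the
    average-quantile reference, preserving within-sample rank order.

    Operates on the upper triangle (diagonal included) and mirrors the
    result; after normalization the sorted value vectors of all samples
    are identical per chromosome.
    """
    if not samples:
        return []
    genome = samples[0].genome
    for s in samples[1:]:
        if s.genome != genome:
            raise ValueError("all samples must share one binned genome")
    results = [s.copy() for s in samples]
    for chrom in genome.chromsizes:
        n = genome.n_bins(chrom)
        iu = np.triu_indices(n)
        vals = np.stack([s.data[chrom][iu] for s in samples])
        order = np.argsort(vals, axis=1, kind="stable")
        ref = np.mean(np.sort(vals, axis=1), axis=0)
        for k, res in enumerate(results):
            newv = np.empty_like(ref)
            newv[order[k]] = ref
            # ties share the mean reference value so equal inputs map equally
            u, inv = np.unique(vals[k], return_inverse=True)
            if len(u) < len(vals[k]):
                sums = np.zeros(len(u))
                cnts = np.zeros(len(u))
                np.add.at(sums, inv, newv)
                np.add.at(cnts, inv, 1)
                newv = (sums / cnts)[inv]
            mat = np.zeros((n, n))
            mat[iu] = newv
            mat = mat + np.triu(mat, 1).T
            res.data[chrom] = mat
    return results


# ---------------------------------------------------------------------------
# Expected model and O/E

def expected_by_distance(m: ContactMatrix) -> DecayProfile:
    """Mean contact at each diagonal distance stratum |i-j| = s."""
    means: dict[str, np.ndarray] = {}
    counts: dict[str, np.ndarray] = {}
    for chrom, mat in m.data.items():
        n = mat.shape[0]
        if n == 0:
            raise ValueError(f"{chrom}: empty matrix")
        mu = np.empty(n)
        cnt = np.empty(n, dtype=np.int64)
        for s in range(n):
            d = np.diagonal(mat, offset=s)
            mu[s] = d.mean()
            cnt[s] = d.size
        means[chrom] = mu
        counts[chrom] = cnt
    return DecayProfile(means=means, counts=counts)


def observed_over_expected(m: ContactMatrix,
                           d: DecayProfile) -> ContactMatrix:
    """Divide each entry by its distance-stratum expectation (0 where the
    expectation is 0)."""
    out: dict[str, np.ndarray] = {}
    for chrom, mat in m.data.items():
        n = mat.shape[0]
        idx = np.abs(np.subtract.outer(np.arange(n), np.arange(n)))
        exp = d.means[chrom][idx]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe = np.where(exp > 0, mat / exp, 0.0)
        out[chrom] = oe
    return ContactMatrix(genome=m.genome, data=out, state=OE,
                         masked={c: v.copy() for c, v in m.masked.items()},
                         dropped_pairs=m.dropped_pairs)


# ---------------------------------------------------------------------------
# Replicate reproducibility (stratum-adjusted correlation, HiCRep-style)

def _scc_one(m1: np.ndarray, m2: np.ndarray, h: int, max_d: int) -> float:
    size = 2 * h + 1
    s1 = ndimage.uniform_filter(m1, size=size, mode="nearest") if h > 0 else m1
    s2 = ndimage.uniform_filter(m2, size=size, mode="nearest") if h > 0 else m2
    num = 0.0
    den = 0.0
    usable = 0
    for d in range(1, max_d + 1):
        x = np.diagonal(s1, offset=d)
        y = np.diagonal(s2, offset=d)
        if x.size < 3:
            continue
        vx, vy = x.var(), y.var()
        if vx == 0 or vy == 0:
            continue
        rho = np.corrcoef(x, y)[0, 1]
        w = x.size * np.sqrt(vx * vy)
        num += w * rho
        den += w
        usable += 1
    if usable == 0 or den == 0:
        raise ValueError("no usable strata (all constant)")
    return float(num / den)


def stratum_adjusted_correlation(m1: ContactMatrix, m2: ContactMatrix,
                                 smoothing_halfwidth: int = 1,
                                 max_distance_bins: int | None = None,
                                 names: tuple[str, str] = ("sample1", "sample2"),
                                 ) -> ReplicateSimilarity:
    """Stratum-adjusted correlation coefficient between two replicates.

    Matrices are mean-filter smoothed, Pearson correlation is computed per
    diagonal stratum, and strata are combined with weights proportional to
    stratum size times the geometric mean of the stratum variances.  The
    default maximum distance is 25% of each chromosome's length in bins.
    """
    if m1.genome != m2.genome:
        raise ValueError("matrices must share one binned genome")
    per_chrom: dict[str, float] = {}
    weights: dict[str, int] = {}
    for chrom in m1.data:
        n = m1.data[chrom].shape[0]
        max_d = max_distance_bins if max_distance_bins is not None else max(
            1, n // 4)
        max_d = min(max_d, n - 1)
        per_chrom[chrom] = _scc_one(m1.data[chrom], m2.data[chrom],
                                    smoothing_halfwidth, max_d)
        weights[chrom] = n
    total_w = sum(weights.values())
    scc = sum(per_chrom[c] * weights[c] for c in per_chrom) / total_w
    return ReplicateSimilarity(
        sample_a=names[0], sample_b=names[1], scc=float(np.clip(scc, -1, 1)),
        per_chromosome=per_chrom,
        smoothing_halfwidth=smoothing_halfwidth,
        max_distance_bins=max_distance_bins if max_distance_bins is not None else -1,
    )
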