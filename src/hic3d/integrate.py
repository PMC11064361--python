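"""Expression joins, threshold-based differential-gene filtering,
phenotype fold-change summaries, and the cross-species ortholog
regulatory partition.

Differential-expression statistics are consumed, never fitted here: the
count models behind them belong to dedicated packages.  A plain
two-group log2 fold-change helper exists for synthetic data only and is
non-inferential.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy import stats


def round_half_up(x: float, decimals: int = 2) -> float:
    """Decimal round-half-up (printed-style rounding, 2.675 -> 2.68)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def filter_degs(table: pd.DataFrame, fdr: float = 0.05,
                min_abs_log2fc: float = 1.5) -> pd.DataFrame:
    """Select differentially expressed genes at FDR < ``fdr`` (strict)
    and |log2FC| >= ``min_abs_log2fc`` (inclusive), split by direction.

    ``table`` needs columns gene, log2fc, fdr; returns the passing rows
    with a ``direction`` column ('up'/'down').
    """
    for col in ("gene", "log2fc", "fdr"):
        if col not in table.columns:
            raise ValueError(f"missing column: {col}")
    keep = (table["fdr"] < fdr) & (table["log2fc"].abs() >= min_abs_log2fc)
    out = table.loc[keep].copy()
    out["direction"] = np.where(out["log2fc"] > 0, "up", "down")
    return out


def naive_log2fc(expr1: np.ndarray, expr2: np.ndarray,
                 pseudo: float = 1.0) -> np.ndarray:
    """Two-group mean log2 fold change for synthetic data; carries no
    inferential weight (no dispersion model, no p-values)."""
    m1 = np.asarray(expr1, dtype=float).mean(axis=-1)
    m2 = np.asarray(expr2, dtype=float).mean(axis=-1)
    return np.log2((m2 + pseudo) / (m1 + pseudo))


def fold_change_summary(phenotypes: pd.DataFrame,
                        decimals: int = 2) -> pd.DataFrame:
    """Fold ratio (treated mean / control mean) per phenotype metric,
    rounded half-up.

    ``phenotypes`` needs columns metric, control_mean, treated_mean.
    """
    if (phenotypes["control_mean"] <= 0).any():
        raise ValueError("control mean must be positive for a fold ratio")
    out = phenotypes.copy()
    out["fold"] = [
        round_half_up(t / c, decimals)
        for c, t in zip(out["control_mean"], out["treated_mean"])
    ]
    return out


def ortholog_partition(table: pd.DataFrame) -> dict:
    """Partition one-to-one orthologs by which species' 3D-genome
    features (compartment switch or differential interaction rewiring)
    regulate them.

    ``table`` needs columns gene_a, gene_b, regulated_a, regulated_b and
    optionally direction_a / direction_b.  Percentages are over the
    regulated-in-either set, rounded half-up to 2 decimals; the
    discordant subset lists shared genes whose regulatory directions
    disagree.
    """
    if table["gene_a"].duplicated().any() or table["gene_b"].duplicated().any():
        raise ValueError("ortholog table is not one-to-one (duplicate ids)")
    a = table["regulated_a"].astype(bool).to_numpy()
    b = table["regulated_b"].astype(bool).to_numpy()
    either = a | b
    a_only = a & ~b
    b_only = ~a & b
    shared = a & b
    n_either = int(either.sum())

    def pct(k: int) -> float | None:
        return round_half_up(100.0 * k / n_either) if n_either else None

    discordant = []
    if {"direction_a", "direction_b"} <= set(table.columns):
        sh = table.loc[shared]
        sel = sh["direction_a"].notna() & sh["direction_b"].notna() & \
            (sh["direction_a"] != sh["direction_b"])
        discordant = sh.loc[sel, "gene_a"].tolist()
    return {
        "n_total": len(table),
        "n_regulated_either": n_either,
        "n_a_only": int(a_only.sum()),
        "n_b_only": int(b_only.sum()),
        "n_shared": int(shared.sum()),
        "pct_a_only": pct(int(a_only.sum())),
        "pct_b_only": pct(int(b_only.sum())),
        "pct_shared": pct(int(shared.sum())),
        "discordant_shared": discordant,
    }


def switch_expression_association(gene_switches: pd.DataFrame,
                                  expression_change: dict[str, float],
                                  deg_genes: set[str] | None = None) -> dict:
    """Summarize expression change by compartment-switch direction.

    ``gene_switches`` needs columns gene, switch (direction strings or
    'stable').  Reports per-direction counts, DEG counts, median
    expression change, and a rank-sum test contrasting B-to-A vs A-to-B
    genes (NA when either group is empty).
    """
    deg_genes = deg_genes or set()
    rows = {}
    groups: dict[str, list[float]] = {}
    for direction, grp in gene_switches.groupby("switch"):
        genes = grp["gene"].tolist()
        deltas = [expression_change[g] for g in genes if g in expression_change]
        groups[direction] = deltas
        rows[direction] = {
            "n_genes": len(genes),
            "n_degs": sum(g in deg_genes for g in genes),
            "median_expression_change": float(np.median(deltas)) if deltas else float("nan"),
        }
    ba = groups.get("B-to-A", [])
    ab = groups.get("A-to-B", [])
    if ba and ab:
        stat, p = stats.mannwhitneyu(ba, ab, alternative="greater")
        test = {"statistic": float(stat), "p_value": float(p)}
    else:
        test = {"statistic": None, "p_value": None}
    return {"by_direction": rows, "b_to_a_vs_a_to_b": test}
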