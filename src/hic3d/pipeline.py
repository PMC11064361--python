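"""Composed end-to-end steps: raw map -> balanced/O-E -> compartments,
TADs, promoter interactions.

These helpers wire the module-level operations together in the order the
analyses expect; every step remains individually accessible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import compartments as comp_mod
from . import domains as dom_mod
from . import matrix as mat_mod
from . import pei as pei_mod


def balance_and_oe(raw: mat_mod.ContactMatrix):
    """KR-balance a raw map and derive its observed-over-expected form."""
    balanced = mat_mod.kr_balance(raw)
    oe = mat_mod.observed_over_expected(
        balanced, mat_mod.expected_by_distance(balanced))
    return balanced, oe


def compartment_profiles(oe: mat_mod.ContactMatrix,
                         covariates: pd.DataFrame,
                         ) -> dict[str, comp_mod.CompartmentProfile]:
    """PC1 per chromosome, oriented by GC (gene count as tiebreak).

    ``covariates`` needs columns chrom, bin, gc, gene_count.
    """
    pc1 = comp_mod.compute_pc1(oe)
    profiles = {}
    for chrom, vec in pc1.items():
        sub = covariates[covariates["chrom"] == chrom].sort_values("bin")
        track = comp_mod.CovariateTrack(
            gc=sub["gc"].to_numpy(), gene_count=sub["gene_count"].to_numpy())
        profiles[chrom] = comp_mod.orient_and_label(vec, track,
                                                    chromosome=chrom)
    return profiles


def call_tads(balanced: mat_mod.ContactMatrix, oe: mat_mod.ContactMatrix,
              di_window: int = 10, is_window: int = 10,
              min_depth: float = 0.1,
              seed: int = 0) -> dict[str, dom_mod.DomainSet]:
    """Large TADs (DI + HMM, junction-strength filtered) partitioned into
    sub-TADs at insulation minima."""
    di = dom_mod.directionality_index(balanced, half_width=di_window)
    ins = dom_mod.insulation_score(balanced, window=is_window)
    out = {}
    for chrom in balanced.data:
        large = dom_mod.di_hmm_domains(di[chrom], seed=seed,
                                       oe=oe.data[chrom])
        out[chrom] = dom_mod.partition_subtads(large, ins[chrom],
                                               min_depth=min_depth)
    return out


def rps_per_gene(balanced: mat_mod.ContactMatrix, promoters: pd.DataFrame,
                 domains: dict[str, dom_mod.DomainSet] | None = None,
                 **pei_kwargs) -> tuple[list, dict]:
    """Call promoter interactions and roll them up to per-gene scores."""
    records = pei_mod.call_peis(balanced, promoters, domains, **pei_kwargs)
    rps = pei_mod.compute_rps(records,
                              gene_universe=list(promoters["gene"]))
    return records, rps
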