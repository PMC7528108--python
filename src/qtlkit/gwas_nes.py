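"""Matched-null enrichment of eQTL effect sizes at GWAS lead SNPs (NES).

For each GWAS lead variant, the statistic of interest is the largest
absolute eQTL slope over all tested exons of all genes within the cis range
of that exact variant ("max individual SNP beta"); the observed statistic is
the median of these maxes over leads. A null distribution is built by
repeatedly matching every lead to a random variant from the tested universe
with a similar number of LD partners, distance to the nearest TSS, number of
nearby genes and MAF, and recomputing the median of maxes. The normalized
enrichment score (NES) is the median of observed/null ratios; the one-sided
p-value is the fraction of ratios below 1.

The matching-bin machinery here is shared with the annotation-overlap
enrichment module, which performs GREGOR-style matched-control sampling on
the same profiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ld import DosageMatrix, _pairwise_r2

log = logging.getLogger(__name__)

N_REPLICATES = 15_000

__all__ = [
    "NesResult",
    "build_match_profiles",
    "assign_bins",
    "candidate_pools",
    "max_abs_beta",
    "max_abs_beta_by_variant",
    "observed_statistic",
    "matched_null_replicates",
    "nes",
]


@dataclass
class NesResult:
    """Normalized enrichment score for one GWAS trait in one tissue."""

    trait: str
    tissue: str
    nes: float
    ci_lower_5pct: float
    p_one_sided: float
    n_replicates: int
    observed_median_of_maxes: float
    null_medians: np.ndarray = field(repr=False)
    n_leads: int = 0


# ---------------------------------------------------------------------------
# SNP matching profiles


def build_match_profiles(
    dosages: DosageMatrix,
    gene_annot: pd.DataFrame,
    ld_r2: float = 0.99,
    ld_window_bp: int = 1_000_000,
    gene_window_bp: int = 1_000_000,
) -> pd.DataFrame:
    """Per-variant matching profile: LD partners, TSS distance, genes, MAF.

    ``gene_annot`` needs columns gene_id, chrom, tss (one row per gene; a
    feature annotation table works after dropping duplicate genes).
    """
    genes = gene_annot.drop_duplicates("gene_id")
    n_ld = np.zeros(dosages.n_variants, dtype=int)
    tss_dist = np.full(dosages.n_variants, np.inf)
    n_genes = np.zeros(dosages.n_variants, dtype=int)

    for chrom in np.unique(dosages.chrom):
        idx = np.flatnonzero(dosages.chrom == chrom)
        pos = dosages.pos[idx]
        # LD partner counts within the window, blockwise on position order
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        start = 0
        i = 0
        while i < len(idx):
            # grow a contiguous chunk no wider than the LD window, then count
            # partners with an all-pairs r2 on the chunk plus its margins
            start = i
            while i < len(idx) and pos[i] - pos[start] <= ld_window_bp:
                i += 1
            lo = np.searchsorted(pos, pos[start] - ld_window_bp)
            hi = np.searchsorted(pos, pos[i - 1] + ld_window_bp, side="right")
            block = idx[lo:hi]
            r2m = _pairwise_r2(dosages.dosages[block])
            np.fill_diagonal(r2m, 0.0)
            within = np.abs(dosages.pos[block][:, None] - dosages.pos[block][None, :]) <= ld_window_bp
            counts = np.nansum((r2m >= ld_r2) & within, axis=1).astype(int)
            # only credit the core chunk (margins are re-counted in their own chunk)
            core = np.isin(block, idx[start:i])
            n_ld[block[core]] = counts[core]

        g = genes[genes["chrom"].astype(str) == str(chrom)]
        if len(g):
            tss = g["tss"].to_numpy(int)
            d = np.abs(dosages.pos[idx][:, None] - tss[None, :])
            tss_dist[idx] = d.min(axis=1)
            n_genes[idx] = (d <= gene_window_bp).sum(axis=1)

    return pd.DataFrame(
        {
            "variant_id": dosages.variant_ids,
            "n_ld_partners": n_ld,
            "tss_distance": tss_dist,
            "n_nearby_genes": n_genes,
            "maf": dosages.maf,
        }
    ).set_index("variant_id")


def assign_bins(profiles: pd.DataFrame) -> pd.DataFrame:
    """Joint matching bins: MAF deciles, 5 log10 distance bins, LD-count
    quartiles, nearby-gene count capped at 3+."""
    out = profiles.copy()
    out["maf_bin"] = pd.qcut(out["maf"], 10, labels=False, duplicates="drop")
    logd = np.log10(1.0 + out["tss_distance"].replace(np.inf, out["tss_distance"].max()))
    edges = np.linspace(logd.min(), logd.max() + 1e-9, 6)
    out["dist_bin"] = np.digitize(logd, edges[1:-1])
    out["ld_bin"] = pd.qcut(out["n_ld_partners"].rank(method="first"), 4, labels=False)
    out["gene_bin"] = np.minimum(out["n_nearby_genes"], 3)
    return out


_RELAX_ORDER = ["gene_bin", "ld_bin", "dist_bin", "maf_bin"]


def candidate_pools(
    leads: list[str],
    binned: pd.DataFrame,
    universe: list[str] | None = None,
    exclude_self: bool = True,
) -> dict[str, np.ndarray]:
    """Universe row positions eligible to stand in for each lead.

    Starts from the exact joint bin and relaxes components in the order
    nearby-gene count, LD count, distance, MAF until the pool is nonempty.
    The lead itself is excluded from its own pool (a matched control must
    be a different variant) unless no other variant matches even after
    full relaxation. Positions index into ``universe`` (default: all
    profiled variants).
    """
    if universe is None:
        universe = list(binned.index)
    uni = binned.loc[universe]
    keys = uni[["maf_bin", "dist_bin", "ld_bin", "gene_bin"]].to_numpy()
    upos = {v: i for i, v in enumerate(universe)}
    pools: dict[str, np.ndarray] = {}
    cols = {"maf_bin": 0, "dist_bin": 1, "ld_bin": 2, "gene_bin": 3}
    for lead in leads:
        if lead not in binned.index:
            raise KeyError(f"lead {lead!r} has no matching profile")
        row = binned.loc[lead, ["maf_bin", "dist_bin", "ld_bin", "gene_bin"]].to_numpy()
        self_pos = upos.get(lead)
        mask = np.all(keys == row, axis=1)
        if exclude_self and self_pos is not None:
            mask[self_pos] = False
        relax = 0
        while not mask.any() and relax < len(_RELAX_ORDER):
            drop = [cols[c] for c in _RELAX_ORDER[: relax + 1]]
            keep = [j for j in range(4) if j not in drop]
            mask = np.all(keys[:, keep] == row[keep], axis=1) if keep else np.ones(len(uni), bool)
            if exclude_self and self_pos is not None:
                mask[self_pos] = False
            relax += 1
            log.info("lead %s: relaxed matching bins (%d component(s))", lead, relax)
        if not mask.any() and self_pos is not None:
            mask[self_pos] = True  # nothing else matches: fall back to self
        pools[lead] = np.flatnonzero(mask)
    return pools


# ---------------------------------------------------------------------------
# statistic


def max_abs_beta(lead: str, eqtl_betas: pd.DataFrame) -> float:
    """Largest absolute slope over all tested exons for this exact variant."""
    rows = eqtl_betas[eqtl_betas["variant_id"] == lead]
    if rows.empty:
        raise KeyError(f"lead {lead!r} untested in the eQTL table")
    return float(rows["slope"].abs().max())


def max_abs_beta_by_variant(eqtl_betas: pd.DataFrame) -> pd.Series:
    """Per-variant max |slope| across all tested exons (vectorized)."""
    return eqtl_betas.assign(a=eqtl_betas["slope"].abs()).groupby("variant_id")["a"].max()


def observed_statistic(leads: list[str], eqtl_betas: pd.DataFrame) -> float:
    """Median over leads of the per-lead max |slope|; untested leads dropped."""
    maxes = max_abs_beta_by_variant(eqtl_betas)
    vals = []
    for lead in leads:
        if lead in maxes.index:
            vals.append(maxes[lead])
        else:
            log.info("lead %s untested; excluded from the observed statistic", lead)
    if not vals:
        raise ValueError("no testable lead")
    return float(np.median(vals))


def matched_null_replicates(
    leads: list[str],
    pools: dict[str, np.ndarray],
    universe_maxes: np.ndarray,
    n_replicates: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Null medians of maxes: one uniform matched draw per lead per replicate."""
    draws = np.empty((n_replicates, len(leads)))
    for j, lead in enumerate(leads):
        pool = pools[lead]
        picks = rng.integers(0, len(pool), size=n_replicates)
        draws[:, j] = universe_maxes[pool[picks]]
    return np.median(draws, axis=1)


def nes(
    leads: list[str],
    profiles: pd.DataFrame,
    eqtl_betas: pd.DataFrame,
    n_replicates: int = N_REPLICATES,
    seed: int | np.random.SeedSequence = 0,
    trait: str = "trait",
    tissue: str = "tissue",
    exclude_self: bool = True,
) -> NesResult:
    """Normalized enrichment score of eQTL effect sizes at GWAS leads.

    ratio_i = observed / null_i over matched-null replicates; NES is the
    median ratio, the one-sided 95% bound is the 5th percentile of ratios,
    and the p-value is the fraction of ratios below 1 (floored below
    1/n_replicates rather than reported as zero).
    """
    if n_replicates < 100:
        raise ValueError("n_replicates must be at least 100")
    maxes = max_abs_beta_by_variant(eqtl_betas)
    testable = [v for v in leads if v in maxes.index]
    if not testable:
        raise ValueError("no testable lead")
    observed = float(np.median([maxes[v] for v in testable]))

    universe = [v for v in maxes.index if v in profiles.index]
    binned = assign_bins(profiles.loc[universe])
    pools = candidate_pools(testable, binned, universe=universe, exclude_self=exclude_self)
    uni_maxes = maxes.loc[universe].to_numpy()

    rng = np.random.default_rng(seed)
    null_medians = matched_null_replicates(testable, pools, uni_maxes, n_replicates, rng)
    ratios = observed / null_medians
    p = float(np.mean(ratios < 1.0))
    if p == 0.0:
        p = 1.0 / (n_replicates + 1.0)
    return NesResult(
        trait=trait,
        tissue=tissue,
        nes=float(np.median(ratios)),
        ci_lower_5pct=float(np.percentile(ratios, 5)),
        p_one_sided=p,
        n_replicates=n_replicates,
        observed_median_of_maxes=observed,
        null_medians=null_medians,
        n_leads=len(testable),
    )
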