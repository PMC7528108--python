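"""Overlap enrichment of eSNPs in genomic features with matched controls.

Implements GREGOR-style enrichment: an input locus (a lead eSNP together
with its high-LD proxies) "overlaps" a feature if the lead or any proxy
intersects one of its intervals; fold enrichment is the number of uniquely
overlapping input loci over the mean number of overlapping matched-control
loci, with controls drawn from the tested-variant universe matched on MAF,
TSS distance, LD-partner count and nearby-gene count. Also provides the
effect-size-by-chromatin-context contrasts (Wilcoxon) and the high/low
effect-size-bin footprint enrichment.

Coordinates are BED-style 0-based half-open; a SNP at 1-based position p is
the interval [p-1, p).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .ld import DosageMatrix, prune_by_ld, proxies
from .gwas_nes import assign_bins, candidate_pools

log = logging.getLogger(__name__)

N_CONTROLS = 500
R2_PROXY = 0.99
STRETCH_MIN_BP = 3000
TYPICAL_MAX_BP = 800

__all__ = [
    "AnnotationTrack",
    "EnrichmentResult",
    "filter_esnps",
    "locus_overlap_flags",
    "matched_control_enrichment",
    "effect_size_by_context",
    "binned_footprint_enrichment",
    "derive_stretch_typical",
    "build_proxy_cache",
]


@dataclass
class AnnotationTrack:
    """Labeled genomic intervals (chromatin states, peaks, footprints).

    ``df`` holds chrom, start (0-based), end (exclusive), label plus any
    extra columns (e.g. strand and motif id for footprint occurrences).
    """

    df: pd.DataFrame
    _trees: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        req = {"chrom", "start", "end", "label"}
        if not req <= set(self.df.columns):
            raise ValueError(f"track needs columns {sorted(req)}")
        if (self.df["start"] >= self.df["end"]).any():
            raise ValueError("intervals must satisfy start < end")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def labels(self) -> list[str]:
        return list(pd.unique(self.df["label"]))

    def subset(self, label: str) -> "AnnotationTrack":
        return AnnotationTrack(self.df[self.df["label"] == label].reset_index(drop=True))

    def _tree(self, chrom: str) -> IntervalTree:
        if chrom not in self._trees:
            sub = self.df[self.df["chrom"].astype(str) == str(chrom)]
            self._trees[chrom] = IntervalTree.from_tuples(
                (int(s), int(e), i) for i, (s, e) in enumerate(zip(sub["start"], sub["end"]))
            )
        return self._trees[chrom]

    def overlaps_snp(self, chrom: str, pos_1based: int) -> bool:
        """Whether any interval contains the SNP (1-based position)."""
        return bool(self._tree(str(chrom)).overlap(pos_1based - 1, pos_1based))

    def write_bed(self, path) -> None:
        cols = ["chrom", "start", "end", "label"] + [
            c for c in self.df.columns if c not in ("chrom", "start", "end", "label")
        ]
        self.df[cols].to_csv(path, sep="\t", index=False, header=False)

    @classmethod
    def read_bed(cls, path, extra_cols: list[str] | None = None) -> "AnnotationTrack":
        names = ["chrom", "start", "end", "label"] + (extra_cols or [])
        df = pd.read_csv(path, sep="\t", header=None, names=names)
        return cls(df)


@dataclass
class EnrichmentResult:
    """Matched-control overlap enrichment for one feature."""

    feature_label: str
    n_input_loci: int
    n_unique_overlaps: int
    mean_control_overlaps: float
    fold: float
    p_enrich: float
    control_overlap_probs: np.ndarray = field(repr=False, default=None)


# ---------------------------------------------------------------------------
# eSNP filtering (MAF floor + LD pruning)


def filter_esnps(
    eqtls: pd.DataFrame,
    dosages: DosageMatrix,
    maf_min: float = 0.2,
    r2_prune: float = 0.8,
    fdr: float = 0.01,
) -> list[str]:
    """Significant eSNPs with MAF >= maf_min, LD-pruned best-first.

    ``eqtls`` needs variant_id, q_value, p_beta (ranking) and maf. Because
    low-MAF variants reach significance only at large effects, the MAF
    floor removes the effect-size/MAF confounding before any effect-size
    based analysis; the pruning keeps the most significant variant of each
    LD clump (pairwise r2 < r2_prune).
    """
    sig = eqtls[(eqtls["q_value"] < fdr) & (eqtls["maf"] >= maf_min)]
    ranked = sig.sort_values("p_beta")["variant_id"].drop_duplicates().tolist()
    return prune_by_ld(ranked, dosages, r2_max=r2_prune)


# ---------------------------------------------------------------------------
# locus-level overlap


def build_proxy_cache(
    dosages: DosageMatrix,
    r2_proxy: float = R2_PROXY,
    window_bp: int = 1_000_000,
) -> dict[str, np.ndarray]:
    """Per-variant row indices of the locus (lead plus r2 >= r2_proxy proxies).

    Precomputing this once amortizes the pairwise-LD work across the many
    feature tracks an enrichment analysis scans.
    """
    from .ld import _pairwise_r2

    cache: dict[str, np.ndarray] = {}
    for chrom in np.unique(dosages.chrom):
        idx = np.flatnonzero(dosages.chrom == chrom)
        pos = dosages.pos[idx]
        order = np.argsort(pos, kind="mergesort")
        idx, pos = idx[order], pos[order]
        i = 0
        while i < len(idx):
            start = i
            while i < len(idx) and pos[i] - pos[start] <= window_bp:
                i += 1
            lo = np.searchsorted(pos, pos[start] - window_bp)
            hi = np.searchsorted(pos, pos[i - 1] + window_bp, side="right")
            block = idx[lo:hi]
            r2m = _pairwise_r2(dosages.dosages[block])
            within = (
                np.abs(dosages.pos[block][:, None] - dosages.pos[block][None, :]) <= window_bp
            )
            hit = np.nan_to_num(r2m) >= r2_proxy
            np.fill_diagonal(hit, True)
            for row_k, vrow in enumerate(block):
                if vrow in idx[start:i]:
                    cache[dosages.variant_ids[vrow]] = block[hit[row_k] & within[row_k]]
    return cache


def locus_overlap_flags(
    variant_ids: list[str],
    dosages: DosageMatrix,
    track: AnnotationTrack,
    r2_proxy: float = R2_PROXY,
    window_bp: int = 1_000_000,
    proxy_cache: dict[str, np.ndarray] | None = None,
) -> np.ndarray:
    """Per-variant flag: the variant or any r2 > r2_proxy proxy hits the track."""
    flags = np.zeros(len(variant_ids), dtype=bool)
    for i, v in enumerate(variant_ids):
        if proxy_cache is not None:
            locus = proxy_cache[v]
        else:
            neigh = proxies(v, dosages, r2_min=r2_proxy, window_bp=window_bp)
            locus = [dosages.index_of(pv) for pv in neigh.variant_ids]
        for j in locus:
            if track.overlaps_snp(dosages.chrom[j], int(dosages.pos[j])):
                flags[i] = True
                break
    return flags


def _poisson_binomial_sf(k: int, probs: np.ndarray) -> float:
    """P(X >= k) for a sum of independent Bernoulli(p_i).

    Exact dynamic-programming convolution up to 50 loci, normal
    approximation with continuity correction beyond.
    """
    n = len(probs)
    if k <= 0:
        return 1.0
    if n <= 50:
        pmf = np.zeros(n + 1)
        pmf[0] = 1.0
        for p in probs:
            pmf[1:] = pmf[1:] * (1 - p) + pmf[:-1] * p
            pmf[0] *= 1 - p
        return float(min(max(pmf[k:].sum(), 0.0), 1.0))
    mu = probs.sum()
    var = float(np.sum(probs * (1 - probs)))
    if var <= 0:
        return 1.0 if k <= mu else 0.0
    return float(stats.norm.sf((k - 0.5 - mu) / np.sqrt(var)))


def matched_control_enrichment(
    input_snps: list[str],
    track: AnnotationTrack,
    dosages: DosageMatrix,
    profiles: pd.DataFrame,
    n_controls: int = N_CONTROLS,
    r2_proxy: float = R2_PROXY,
    seed: int | np.random.SeedSequence = 0,
    universe: list[str] | None = None,
    overlap_flags: pd.Series | None = None,
    proxy_cache: dict | None = None,
    feature_label: str | None = None,
) -> EnrichmentResult:
    """GREGOR-style fold enrichment of input loci in a feature track.

    For each input locus, ``n_controls`` matched variants are drawn from
    the universe (same joint matching bin as the lead, relaxed if empty).
    Fold = unique input-locus overlaps / mean control-set overlaps; the
    p-value is the Poisson-binomial upper tail of the observed overlap
    count under the per-locus control overlap frequencies.

    ``overlap_flags`` may carry precomputed per-variant locus-overlap
    booleans (indexed by variant id) to amortize proxy lookups across
    features.
    """
    if len(track) == 0:
        raise ValueError("empty feature track: fold undefined")
    if universe is None:
        universe = list(profiles.index)
    if overlap_flags is None:
        need = list(dict.fromkeys(list(input_snps) + list(universe)))
        if proxy_cache is None:
            proxy_cache = build_proxy_cache(dosages, r2_proxy=r2_proxy)
        flags = locus_overlap_flags(need, dosages, track, r2_proxy=r2_proxy, proxy_cache=proxy_cache)
        overlap_flags = pd.Series(flags, index=need)

    n_input = len(input_snps)
    obs = int(overlap_flags.loc[list(input_snps)].sum())

    binned = assign_bins(profiles.loc[universe])
    pools = candidate_pools(list(input_snps), binned, universe=universe)
    uni_flags = overlap_flags.loc[list(universe)].to_numpy()

    rng = np.random.default_rng(seed)
    control_probs = np.empty(n_input)
    for i, v in enumerate(input_snps):
        pool = pools[v]
        picks = pool[rng.integers(0, len(pool), size=n_controls)]
        control_probs[i] = float(uni_flags[picks].mean())
    mean_ctrl = float(control_probs.sum())  # expected overlapping loci per control set
    fold = obs / mean_ctrl if mean_ctrl > 0 else np.inf
    p = _poisson_binomial_sf(obs, control_probs)
    return EnrichmentResult(
        feature_label=feature_label or ",".join(map(str, track.labels[:1])),
        n_input_loci=n_input,
        n_unique_overlaps=obs,
        mean_control_overlaps=mean_ctrl,
        fold=float(fold),
        p_enrich=p,
        control_overlap_probs=control_probs,
    )


# ---------------------------------------------------------------------------
# effect sizes by chromatin context


def effect_size_by_context(
    esnps: pd.DataFrame,
    tracks: dict[str, AnnotationTrack],
    dosages: DosageMatrix,
    r2_proxy: float = R2_PROXY,
    min_loci: int = 5,
    proxy_cache: dict | None = None,
) -> tuple[dict[str, np.ndarray], pd.DataFrame]:
    """|slope| distributions per genomic context plus pairwise Wilcoxon tests.

    ``esnps`` needs variant_id and slope (one row per pruned eSNP locus).
    A locus is assigned to every context its lead or a high-LD proxy
    overlaps. Contexts with fewer than ``min_loci`` loci are skipped.
    """
    if proxy_cache is None:
        proxy_cache = build_proxy_cache(dosages, r2_proxy=r2_proxy)
    dists: dict[str, np.ndarray] = {}
    for label, track in tracks.items():
        flags = locus_overlap_flags(
            esnps["variant_id"].tolist(), dosages, track, r2_proxy=r2_proxy, proxy_cache=proxy_cache
        )
        vals = esnps.loc[flags, "slope"].abs().to_numpy()
        if len(vals) < min_loci:
            warnings.warn(f"context {label!r}: only {len(vals)} loci, skipped", stacklevel=2)
            continue
        dists[label] = vals
    rows = []
    labels = list(dists)
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            a, b = dists[labels[i]], dists[labels[j]]
            stat, p = stats.ranksums(a, b)
            rows.append(
                {
                    "context_a": labels[i],
                    "context_b": labels[j],
                    "median_a": float(np.median(a)),
                    "median_b": float(np.median(b)),
                    "statistic": float(stat),
                    "p_wilcoxon": float(p),
                }
            )
    return dists, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# effect-size-binned footprint enrichment


def binned_footprint_enrichment(
    esnps: pd.DataFrame,
    footprints: AnnotationTrack,
    dosages: DosageMatrix,
    profiles: pd.DataFrame,
    bulk_esnps: list[str] | None = None,
    slope_split: float | None = None,
    n_controls: int = 100,
    r2_proxy: float = R2_PROXY,
    fdr: float = 0.01,
    seed: int = 0,
    universe: list[str] | None = None,
    proxy_cache: dict | None = None,
) -> pd.DataFrame:
    """Per-motif fold enrichment in high- vs low-|slope| eSNP bins.

    Stage 1 prefilters motifs by matched-control enrichment over the bulk
    eSNP set at Benjamini-Yekutieli FDR < ``fdr``; stage 2 splits the
    filtered eSNPs into two equally sized bins at ``slope_split`` (median
    |slope| by default) and computes each surviving motif's fold in the
    high and low bins separately.
    """
    esnps = esnps.reset_index(drop=True)
    abs_slope = esnps["slope"].abs()
    if slope_split is None:
        slope_split = float(abs_slope.median())
    order = abs_slope.sort_values().index
    half = len(order) // 2
    low_ids = esnps.loc[order[:half], "variant_id"].tolist()
    high_ids = esnps.loc[order[half:], "variant_id"].tolist()
    if bulk_esnps is None:
        bulk_esnps = esnps["variant_id"].tolist()

    if proxy_cache is None:
        proxy_cache = build_proxy_cache(dosages, r2_proxy=r2_proxy)
    ss = np.random.SeedSequence(seed)
    motifs = footprints.labels
    rows = []
    stage1 = []
    for motif, child in zip(motifs, ss.spawn(len(motifs))):
        sub = footprints.subset(motif)
        try:
            res = matched_control_enrichment(
                bulk_esnps,
                sub,
                dosages,
                profiles,
                n_controls=n_controls,
                r2_proxy=r2_proxy,
                seed=child,
                universe=universe,
                proxy_cache=proxy_cache,
                feature_label=motif,
            )
        except ValueError:
            continue
        if res.n_unique_overlaps == 0:
            continue  # motif never overlaps the input set anywhere
        stage1.append((motif, sub, res, child))
    if not stage1:
        return pd.DataFrame(
            columns=["motif_id", "p_bulk", "q_bulk", "n_bulk_overlaps", "fold_bulk", "fold_high", "fold_low"]
        )
    q_by = multipletests([r.p_enrich for _, _, r, _ in stage1], method="fdr_by")[1]
    for (motif, sub, res, child), q in zip(stage1, q_by):
        if q >= fdr:
            continue
        kids = np.random.SeedSequence(entropy=child.entropy, spawn_key=(99,)).spawn(2)
        hi = matched_control_enrichment(
            high_ids, sub, dosages, profiles, n_controls=n_controls, r2_proxy=r2_proxy,
            seed=kids[0], universe=universe, proxy_cache=proxy_cache, feature_label=motif,
        )
        lo = matched_control_enrichment(
            low_ids, sub, dosages, profiles, n_controls=n_controls, r2_proxy=r2_proxy,
            seed=kids[1], universe=universe, proxy_cache=proxy_cache, feature_label=motif,
        )
        rows.append(
            {
                "motif_id": motif,
                "p_bulk": res.p_enrich,
                "q_bulk": float(q),
                "n_bulk_overlaps": res.n_unique_overlaps,
                "fold_bulk": res.fold,
                "fold_high": hi.fold,
                "fold_low": lo.fold,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# stretch / typical enhancer derivation


def derive_stretch_typical(
    states: AnnotationTrack,
    enhancer_labels: tuple[str, ...] = ("enhancer",),
    stretch_min_bp: int = STRETCH_MIN_BP,
    typical_max_bp: int = TYPICAL_MAX_BP,
) -> tuple[AnnotationTrack, AnnotationTrack]:
    """Split enhancer-class segments into stretch (> 3 kb after merging
    adjacent segments) and typical (< 800 bp) enhancers."""
    enh = states.df[states.df["label"].isin(enhancer_labels)].sort_values(["chrom", "start"])
    merged = []
    for chrom, sub in enh.groupby("chrom", sort=False):
        cur_s, cur_e = None, None
        for s, e in zip(sub["start"], sub["end"]):
            if cur_s is None:
                cur_s, cur_e = int(s), int(e)
            elif int(s) <= cur_e:
                cur_e = max(cur_e, int(e))
            else:
                merged.append((chrom, cur_s, cur_e))
                cur_s, cur_e = int(s), int(e)
        if cur_s is not None:
            merged.append((chrom, cur_s, cur_e))
    mdf = pd.DataFrame(merged, columns=["chrom", "start", "end"])
    mdf["length"] = mdf["end"] - mdf["start"]
    stretch = mdf[mdf["length"] > stretch_min_bp].assign(label="stretch_enhancer")
    typical = mdf[mdf["length"] < typical_max_bp].assign(label="typical_enhancer")
    cols = ["chrom", "start", "end", "label"]
    return AnnotationTrack(stretch[cols].reset_index(drop=True)), AnnotationTrack(
        typical[cols].reset_index(drop=True)
    )
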