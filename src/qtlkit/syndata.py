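"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates a bulk-tissue eQTL cohort: diploid genotypes with block LD and a
realistic MAF spectrum, exon-level expression with planted additive cis
effects, laboratory batch offsets and convex cell-type mixtures, chromatin
state segmentations including > 3 kb stretch-enhancer segments, ATAC peaks,
TF footprint motif occurrences with planted activating/repressive
directionality, and GWAS lead lists with tunable overlap with the planted
causal variants.

LD is generated by a first-order copying chain: within a block, each
haplotype allele is copied from the previous variant with probability
``ld_decay`` and otherwise drawn fresh at that variant's allele frequency,
which yields r2 decaying monotonically with index distance; blocks are
independent. One chromosome is simulated, with the genes' cis windows laid
out back to back; coordinates are 0-based half-open internally and 1-based
in variant positions, matching the dosage-TSV convention.

All randomness flows from a single master seed; each component draws from a
sub-stream at a fixed offset, so identical configs give byte-identical
outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .annot_enrich import AnnotationTrack
from .expr_prep import FeatureMatrix
from .ld import DosageMatrix
from .motif_directionality import BASES, Pwm, write_jaspar

__all__ = [
    "SimConfig",
    "Truth",
    "SimData",
    "simulate_genotypes",
    "simulate_truth",
    "simulate_expression",
    "simulate_annotations",
    "simulate_all",
    "write_all",
]

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# fixed sub-stream offsets per component (single master seed)
_STREAM_GENO = 1
_STREAM_TRUTH = 2
_STREAM_EXPR = 3
_STREAM_ANNOT = 4


@dataclass
class SimConfig:
    """Generator settings; defaults emulate the cohort structure downstream
    stages assume (four processing laboratories, three islet cell classes,
    planted slopes in residual-sd units)."""

    n_samples: int = 200
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 4)
    n_variants_per_cis_window: int = 50
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_block_size: int = 10
    ld_decay: float = 0.9
    eqtl_fraction: float = 0.3
    secondary_fraction: float = 0.2
    slope_mean: float = 0.8  # |slope| in residual-sd units
    slope_sd: float = 0.2
    noise_sd: float = 1.0
    n_cell_types: int = 3
    cell_signature_sd: float = 1.0
    batch_labels: tuple[str, ...] = ("lab1", "lab2", "lab3", "lab4")
    batch_sd: float = 1.0
    baseline_low: float = 50.0
    baseline_high: float = 150.0
    window_bp: int = 1_000_000
    n_gwas_leads: int = 20
    gwas_enriched_fraction: float = 0.5
    n_motifs: int = 6
    motif_flip_prob: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lower <= upper <= 0.5")
        for name in ("eqtl_fraction", "secondary_fraction", "gwas_enriched_fraction"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")

    def stream(self, offset: int) -> np.random.Generator:
        return np.random.default_rng(np.random.SeedSequence(entropy=(int(self.seed), int(offset))))


@dataclass
class Truth:
    """Ground truth of the planted structure."""

    planted_eqtls: pd.DataFrame  # gene_id, variant_id, slope, rank, affected_exons
    cell_fractions: pd.DataFrame  # samples x cell types, rows sum to 1
    motif_directionality: dict[str, str] = field(default_factory=dict)
    gwas_leads: pd.DataFrame | None = None
    batch: np.ndarray | None = None
    sex: np.ndarray | None = None

    def to_json(self, path) -> None:
        payload = {
            "planted_eqtls": self.planted_eqtls.to_dict(orient="records"),
            "cell_fractions": self.cell_fractions.reset_index()
            .rename(columns={"index": "sample_id"})
            .to_dict(orient="records"),
            "motif_directionality": self.motif_directionality,
            "gwas_leads": None
            if self.gwas_leads is None
            else self.gwas_leads.to_dict(orient="records"),
            "batch": None if self.batch is None else list(map(str, self.batch)),
            "sex": None if self.sex is None else [int(v) for v in self.sex],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


@dataclass
class SimData:
    config: SimConfig
    genotypes: DosageMatrix
    expression: FeatureMatrix
    truth: Truth
    states: AnnotationTrack | None = None
    peaks: AnnotationTrack | None = None
    footprints: AnnotationTrack | None = None
    pwms: dict[str, Pwm] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# genotypes


def _window_start(g: int, config: SimConfig) -> int:
    return g * 2 * config.window_bp


def gene_tss(g: int, config: SimConfig) -> int:
    return _window_start(g, config) + config.window_bp


def simulate_genotypes(config: SimConfig) -> DosageMatrix:
    """Diploid dosages from Hardy-Weinberg haplotypes with block-LD copying.

    The returned matrix carries a ``sampled_maf`` attribute with the
    chain-implied expected allele frequency per variant (the quantity the
    realized MAF fluctuates around).
    """
    rng = config.stream(_STREAM_GENO)
    n, v_per = config.n_samples, config.n_variants_per_cis_window
    n_hap = 2 * n
    all_pos, all_dos, vids, sampled = [], [], [], []
    for g in range(config.n_genes):
        start = _window_start(g, config)
        pos = np.sort(rng.choice(2 * config.window_bp - 2, size=v_per, replace=False)) + start + 1
        maf_draw = rng.uniform(config.maf_range[0], config.maf_range[1], size=v_per)
        hap = np.empty((n_hap, v_per), dtype=np.int8)
        eff = np.empty(v_per)
        for j in range(v_per):
            fresh = rng.random(n_hap) < maf_draw[j]
            if j % config.ld_block_size == 0:
                hap[:, j] = fresh
                eff[j] = maf_draw[j]
            else:
                copy = rng.random(n_hap) < config.ld_decay
                hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
                eff[j] = config.ld_decay * eff[j - 1] + (1 - config.ld_decay) * maf_draw[j]
        dos = hap[:n] + hap[n:]
        # monomorphic columns carry no signal: redraw them fresh
        for j in np.flatnonzero(np.ptp(dos, axis=0) == 0):
            for _ in range(100):
                col = (rng.random(n_hap) < maf_draw[j]).astype(np.int8)
                if 0 < col.sum() < n_hap:
                    dos[:, j] = col[:n] + col[n:]
                    eff[j] = maf_draw[j]
                    break
        all_pos.append(pos)
        all_dos.append(dos.T.astype(float))
        vids.extend(f"var_g{g}_{j}" for j in range(v_per))
        sampled.append(eff)
    dosages = DosageMatrix(
        dosages=np.vstack(all_dos),
        variant_ids=vids,
        chrom=np.repeat("chr1", config.n_genes * v_per),
        pos=np.concatenate(all_pos),
        ref=[],
        alt=[],
        sample_ids=[f"S{i}" for i in range(n)],
    )
    base_rng = config.stream(_STREAM_GENO + 100)
    refs, alts = [], []
    for _ in range(dosages.n_variants):
        r, a = base_rng.choice(4, size=2, replace=False)
        refs.append(BASES[r])
        alts.append(BASES[a])
    dosages.ref, dosages.alt = refs, alts
    dosages.sampled_maf = np.concatenate(sampled)
    return dosages


# ---------------------------------------------------------------------------
# truth


def simulate_truth(genotypes: DosageMatrix, config: SimConfig) -> Truth:
    """Plant primary/secondary eQTLs, cell fractions, batches and GWAS leads."""
    rng = config.stream(_STREAM_TRUTH)
    v_per = config.n_variants_per_cis_window
    maf = genotypes.maf
    n_eg = int(round(config.eqtl_fraction * config.n_genes))
    egenes = sorted(rng.choice(config.n_genes, size=n_eg, replace=False))
    n_exons = rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1, size=config.n_genes)

    rows = []
    for g in egenes:
        lo, hi = g * v_per, (g + 1) * v_per
        eligible = np.flatnonzero(maf[lo:hi] >= 0.1) + lo
        if len(eligible) == 0:
            eligible = np.arange(lo, hi)
        primary = int(rng.choice(eligible))
        slope = max(rng.normal(config.slope_mean, config.slope_sd), 0.1) * rng.choice([-1.0, 1.0])
        affected = _affected_exons(rng, int(n_exons[g]))
        rows.append(
            {
                "gene_id": f"gene{g}",
                "variant_id": genotypes.variant_ids[primary],
                "slope": float(slope),
                "rank": 1,
                "affected_exons": affected,
            }
        )
        if rng.random() < config.secondary_fraction:
            sec = _independent_variant(rng, genotypes, primary, eligible)
            if sec is not None:
                slope2 = max(rng.normal(config.slope_mean, config.slope_sd), 0.1) * rng.choice([-1.0, 1.0])
                rows.append(
                    {
                        "gene_id": f"gene{g}",
                        "variant_id": genotypes.variant_ids[sec],
                        "slope": float(slope2),
                        "rank": 2,
                        "affected_exons": _affected_exons(rng, int(n_exons[g])),
                    }
                )
    planted = pd.DataFrame(rows, columns=["gene_id", "variant_id", "slope", "rank", "affected_exons"])

    names = ("beta", "nonbeta", "exocrine") if config.n_cell_types == 3 else tuple(
        f"ct{i + 1}" for i in range(config.n_cell_types)
    )
    fracs = rng.dirichlet(np.ones(config.n_cell_types), size=config.n_samples)
    cell_fractions = pd.DataFrame(fracs, index=[f"S{i}" for i in range(config.n_samples)], columns=names)

    batch = rng.choice(config.batch_labels, size=config.n_samples)
    sex = rng.integers(0, 2, size=config.n_samples)

    gwas = _gwas_leads(rng, genotypes, planted, config)
    truth = Truth(
        planted_eqtls=planted,
        cell_fractions=cell_fractions,
        gwas_leads=gwas,
        batch=batch,
        sex=sex,
    )
    truth.n_exons_per_gene = n_exons
    return truth


def _affected_exons(rng: np.random.Generator, n_exons: int) -> list[int]:
    mask = rng.random(n_exons) < 0.7
    if not mask.any():
        mask[rng.integers(n_exons)] = True
    return [int(i) for i in np.flatnonzero(mask)]


def _independent_variant(rng, genotypes, primary: int, eligible: np.ndarray) -> int | None:
    """A second causal variant with in-sample r2 < 0.05 against the primary."""
    d0 = genotypes.dosages[primary]
    cands = [i for i in eligible if i != primary]
    rng.shuffle(cands)
    for i in cands:
        d = genotypes.dosages[i]
        if np.ptp(d) == 0:
            continue
        r = np.corrcoef(d0, d)[0, 1]
        if r * r < 0.05:
            return int(i)
    return None


def _gwas_leads(rng, genotypes, planted, config) -> pd.DataFrame:
    n_enriched = int(round(config.gwas_enriched_fraction * config.n_gwas_leads))
    causal = planted.sort_values("slope", key=np.abs, ascending=False)["variant_id"].tolist()
    enriched = causal[:n_enriched]
    causal_set = set(planted["variant_id"])
    others = [v for v in genotypes.variant_ids if v not in causal_set]
    background = list(rng.choice(others, size=config.n_gwas_leads - len(enriched), replace=False))
    leads = enriched + background
    idx = [genotypes.index_of(v) for v in leads]
    return pd.DataFrame(
        {
            "trait": "sim_trait",
            "variant_id": leads,
            "chrom": genotypes.chrom[idx],
            "pos": genotypes.pos[idx],
            "on_causal": [v in causal_set for v in leads],
        }
    )


# ---------------------------------------------------------------------------
# expression


def simulate_expression(genotypes: DosageMatrix, truth: Truth, config: SimConfig) -> FeatureMatrix:
    """Exon-level expression with planted additive effects.

    feature = baseline + slope x dosage (affected exons of planted eQTLs)
    + per-gene lab offset + cell-fraction-weighted gene signature +
    Gaussian noise, emitted on a non-negative continuous scale standing in
    for scaled counts.
    """
    rng = config.stream(_STREAM_EXPR)
    n = config.n_samples
    n_exons = getattr(truth, "n_exons_per_gene", None)
    if n_exons is None:
        n_exons = rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1, size=config.n_genes)

    planted_by_gene: dict[str, list] = {}
    for row in truth.planted_eqtls.itertuples(index=False):
        if np.ptp(genotypes.row(row.variant_id)) == 0:
            raise ValueError(f"planted slope on monomorphic variant {row.variant_id}")
        planted_by_gene.setdefault(row.gene_id, []).append(row)

    batch_levels = {b: i for i, b in enumerate(config.batch_labels)}
    batch_idx = np.array([batch_levels[b] for b in truth.batch])
    fracs = truth.cell_fractions.to_numpy()  # n x c

    values, fids, annot_rows = [], [], []
    for g in range(config.n_genes):
        gene_id = f"gene{g}"
        tss = gene_tss(g, config)
        strand = "+" if rng.random() < 0.5 else "-"
        gene_batch = rng.normal(0.0, config.batch_sd, size=len(config.batch_labels))
        gene_sig = rng.normal(0.0, config.cell_signature_sd, size=config.n_cell_types)
        shared = gene_batch[batch_idx] + fracs @ gene_sig
        exon_start = tss
        for e in range(int(n_exons[g])):
            start, end = exon_start, exon_start + int(rng.integers(200, 2000))
            exon_start = end + int(rng.integers(100, 2000))
            baseline = rng.uniform(config.baseline_low, config.baseline_high)
            y = baseline + shared + rng.normal(0.0, config.noise_sd, size=n)
            # planted slopes are in residual-sd units; at zero noise the
            # unit is degenerate and slopes apply on the expression scale
            scale = config.noise_sd if config.noise_sd > 0 else 1.0
            for row in planted_by_gene.get(gene_id, []):
                if e in row.affected_exons:
                    y = y + row.slope * scale * genotypes.row(row.variant_id)
            fid = f"{gene_id}_exon{e}"
            fids.append(fid)
            values.append(np.maximum(y, 0.0))
            annot_rows.append(
                {
                    "feature_id": fid,
                    "gene_id": gene_id,
                    "chrom": "chr1",
                    "start": start,
                    "end": end,
                    "tss": tss,
                    "strand": strand,
                }
            )
    values = pd.DataFrame(np.vstack(values), index=fids, columns=[f"S{i}" for i in range(n)])
    return FeatureMatrix(values=values, annot=pd.DataFrame(annot_rows))


# ---------------------------------------------------------------------------
# annotations: states, peaks, footprints, PWMs


def _make_pwms(rng: np.random.Generator, config: SimConfig) -> tuple[dict[str, Pwm], dict[str, str]]:
    """PWMs of length 12 whose informative positions (IC ~ 1.2 bits) cycle
    through all four bases so any desired allele can be placed under an
    informative argmax position."""
    classes = {}
    pwms = {}
    kinds = ["activating", "repressive", "neutral"]
    for m in range(config.n_motifs):
        kind = kinds[m % 3]
        mat = np.full((12, 4), 0.25)
        for k, pos in enumerate(range(2, 10)):
            row = np.full(4, 0.05)
            row[k % 4] = 0.85
            mat[pos] = row
        # small jitter off the informative positions keeps motifs distinct
        for pos in (0, 1, 10, 11):
            w = rng.dirichlet(np.full(4, 50.0))
            mat[pos] = w
        motif_id = f"motif{m}_{kind[:3]}"
        pwms[motif_id] = Pwm(motif_id=motif_id, matrix=mat)
        classes[motif_id] = kind
    return pwms, classes


def simulate_annotations(
    genotypes: DosageMatrix,
    config: SimConfig,
    truth: Truth | None = None,
) -> tuple[AnnotationTrack, AnnotationTrack, AnnotationTrack, dict[str, Pwm]]:
    """Chromatin states, nested ATAC peaks and TF footprint occurrences.

    Enhancer segments are seeded on the planted causal variants (half
    stretch-class > 3 kb, half typical < 800 bp); footprints are nested in
    peaks nested in those segments, and each footprint occurrence is placed
    so that the motif's preferred base at the SNP position realizes the
    motif's planted directionality (activating / repressive / neutral, with
    ``motif_flip_prob`` noise). Returns (states, peaks, footprints, pwms)
    and records the planted directionality into ``truth``.
    """
    span = int(genotypes.pos.max()) + 1000
    if span < 4000:
        raise ValueError("region shorter than the maximum segment length (4 kb)")
    rng = config.stream(_STREAM_ANNOT)
    pwms, classes = _make_pwms(rng, config)
    if truth is not None:
        truth.motif_directionality = classes

    planted = truth.planted_eqtls if truth is not None else pd.DataFrame(columns=["variant_id", "slope"])
    state_rows, peak_rows, fp_rows = [], [], []
    reserved: list[tuple[int, int]] = []

    motif_ids = list(pwms)
    for i, row in enumerate(planted.itertuples(index=False)):
        vidx = genotypes.index_of(row.variant_id)
        pos0 = int(genotypes.pos[vidx]) - 1  # 0-based
        motif_id = motif_ids[i % len(motif_ids)]
        pwm = pwms[motif_id]
        kind = classes[motif_id]
        eff, ref = genotypes.alt[vidx], genotypes.ref[vidx]
        up_allele = eff if row.slope > 0 else ref  # raises expression
        down_allele = ref if row.slope > 0 else eff
        if kind == "activating":
            desired = up_allele if rng.random() >= config.motif_flip_prob else down_allele
        elif kind == "repressive":
            desired = down_allele if rng.random() >= config.motif_flip_prob else up_allele
        else:
            desired = up_allele if rng.random() < 0.5 else down_allele
        strand = "+" if rng.random() < 0.5 else "-"
        target = desired if strand == "+" else _COMP[desired]
        cands = [
            p
            for p in range(len(pwm))
            if pwm.information_content[p] >= 0.7 and pwm.preferred_base(p) == target
        ]
        offset = int(rng.choice(cands))
        if strand == "+":
            fp_start = pos0 - offset
        else:
            fp_start = pos0 - (len(pwm) - 1 - offset)
        fp_end = fp_start + len(pwm)
        if fp_start < 150:  # too close to the region edge to nest peak/state
            continue
        pad = int(rng.integers(30, 120))
        pk_start, pk_end = fp_start - pad, fp_end + pad
        stretch = i % 2 == 0
        if stretch:
            half = int(rng.integers(1600, 3000))
        else:
            half = int(rng.integers(120, 250))
        en_start = max(0, min(pk_start - 10, pos0 - half))
        en_end = max(pk_end + 10, pos0 + half)
        peak_rows.append((pk_start, pk_end))
        fp_rows.append((fp_start, fp_end, motif_id, strand))
        reserved.append((en_start, en_end))

    # merge overlapping enhancer seeds so the segmentation stays disjoint
    reserved.sort()
    merged: list[tuple[int, int]] = []
    for s, e in reserved:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    reserved = merged
    state_rows.extend((s, e, "enhancer") for s, e in reserved)
    cursor = 0
    bg_states = []
    for s, e in reserved + [(span, span)]:
        gap = 0
        while cursor + 4200 < s:
            kind = rng.choice(["active_tss", "enhancer", "repressed_polycomb", "quiescent"], p=[0.15, 0.15, 0.2, 0.5])
            if kind == "active_tss":
                ln = int(rng.integers(500, 2000))
            elif kind == "enhancer":
                ln = int(rng.integers(300, 790)) if rng.random() < 0.8 else int(rng.integers(3100, 4000))
            else:
                ln = int(rng.integers(2000, 20000))
            ln = min(ln, s - cursor)
            bg_states.append((cursor, cursor + ln, kind))
            # background peaks inside open chromatin
            if kind in ("active_tss", "enhancer") and ln > 400 and rng.random() < 0.5:
                ps = cursor + int(rng.integers(50, ln - 350))
                bg_peak = (ps, ps + int(rng.integers(200, 300)))
                peak_rows.append(bg_peak)
            cursor += ln
            gap += 1
        if cursor < s:
            bg_states.append((cursor, s, "quiescent"))
        cursor = max(cursor, e)

    states = pd.DataFrame(
        sorted(bg_states + state_rows), columns=["start", "end", "label"]
    )
    states.insert(0, "chrom", "chr1")
    # clip negatives from padding at the left edge
    states["start"] = states["start"].clip(lower=0)
    peaks = pd.DataFrame(sorted(peak_rows), columns=["start", "end"])
    peaks.insert(0, "chrom", "chr1")
    peaks["label"] = "peak"
    peaks["start"] = peaks["start"].clip(lower=0)
    fps = pd.DataFrame(fp_rows, columns=["start", "end", "label", "strand"]).sort_values("start")
    fps.insert(0, "chrom", "chr1")

    return (
        AnnotationTrack(states.reset_index(drop=True)),
        AnnotationTrack(peaks.reset_index(drop=True)),
        AnnotationTrack(fps.reset_index(drop=True)[["chrom", "start", "end", "label", "strand"]]),
        pwms,
    )


# ---------------------------------------------------------------------------
# pair-level two-tissue replication emulation


def simulate_replication_pvalues(
    n_pairs: int,
    sharing: float,
    n_samples: int = 150,
    slope: float = 0.8,
    maf: float = 0.3,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Replication-tissue nominal p-values at discovery-significant pairs.

    Each pair carries a true effect in the replication tissue with
    probability ``sharing`` (slope in residual-sd units); the rest are null
    there. Returns (p_values, shared_mask), with p from the same two-sided
    t-test on the dosage-expression correlation the cis scan uses.
    """
    if not 0 <= sharing <= 1:
        raise ValueError("sharing must lie in [0, 1]")
    from scipy import stats as _stats

    rng = np.random.default_rng(np.random.SeedSequence(entropy=(int(seed), 77)))
    d = rng.binomial(2, maf, size=(n_pairs, n_samples)).astype(float)
    shared = rng.random(n_pairs) < sharing
    y = slope * d * shared[:, None] + rng.normal(0.0, 1.0, size=(n_pairs, n_samples))
    dc = d - d.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    num = np.einsum("ij,ij->i", dc, yc)
    den = np.sqrt(np.einsum("ij,ij->i", dc, dc) * np.einsum("ij,ij->i", yc, yc))
    r = np.clip(np.where(den > 0, num / den, 0.0), -1 + 1e-12, 1 - 1e-12)
    df = n_samples - 2
    t = np.abs(r) * np.sqrt(df / (1 - r * r))
    return 2.0 * _stats.t.sf(t, df), shared


# ---------------------------------------------------------------------------
# orchestration


def simulate_all(config: SimConfig) -> SimData:
    """Generate the full synthetic input bundle for one cohort."""
    genotypes = simulate_genotypes(config)
    truth = simulate_truth(genotypes, config)
    expression = simulate_expression(genotypes, truth, config)
    states, peaks, footprints, pwms = simulate_annotations(genotypes, config, truth)
    return SimData(
        config=config,
        genotypes=genotypes,
        expression=expression,
        truth=truth,
        states=states,
        peaks=peaks,
        footprints=footprints,
        pwms=pwms,
    )


def write_all(sim: SimData, outdir) -> None:
    """Write every artifact: dosage/expression/annotation TSVs, covariates,
    BED tracks, JASPAR PWMs, GWAS leads and the truth JSON."""
    from pathlib import Path

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    sim.genotypes.write_tsv(out / "dosages.tsv")
    sim.expression.write_tsv(out / "expression.tsv", out / "features.tsv")
    cov = pd.DataFrame(
        {
            "sample_id": [f"S{i}" for i in range(sim.config.n_samples)],
            "lab": sim.truth.batch,
            "sex": sim.truth.sex,
        }
    )
    cov.to_csv(out / "covariates.tsv", sep="\t", index=False)
    sim.truth.cell_fractions.to_csv(out / "cell_fractions.tsv", sep="\t", index_label="sample_id")
    if sim.states is not None:
        sim.states.write_bed(out / "states.bed")
        sim.peaks.write_bed(out / "peaks.bed")
        sim.footprints.write_bed(out / "footprints.bed")
    if sim.pwms:
        write_jaspar(sim.pwms, out / "motifs.jaspar")
    if sim.truth.gwas_leads is not None:
        sim.truth.gwas_leads.to_csv(out / "gwas_leads.tsv", sep="\t", index=False)
    sim.truth.to_json(out / "truth.json")
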