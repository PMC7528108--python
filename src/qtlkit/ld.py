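"""Linkage-disequilibrium utilities: dosage containers, r2, pruning and proxy lookup.

Dosages are additive alternate-allele counts in [0, 2], either hard calls or
expectations from genotype probabilities. All LD here is computed in-sample
from dosages; a reference panel can be swapped in through the same container.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DosageMatrix",
    "LdNeighborhood",
    "dosage_from_genotype_probs",
    "r2",
    "prune_by_ld",
    "proxies",
]


@dataclass
class DosageMatrix:
    """Variants x samples additive dosage matrix with positions and MAF.

    Parameters
    ----------
    dosages
        Array of shape (n_variants, n_samples) with values in [0, 2].
    variant_ids
        Unique variant identifiers, one per row.
    chrom
        Chromosome name per variant.
    pos
        1-based positions, sorted within each chromosome.
    ref, alt
        Reference and alternate (dosage-counted, i.e. effect) alleles.
    sample_ids
        Sample identifiers, one per column.
    """

    dosages: np.ndarray
    variant_ids: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: list[str] = field(default_factory=list)
    alt: list[str] = field(default_factory=list)
    sample_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.pos = np.asarray(self.pos, dtype=int)
        self.chrom = np.asarray(self.chrom, dtype=object)
        if self.dosages.shape[0] != len(self.variant_ids):
            raise ValueError("dosages rows must match variant_ids")
        if self.dosages.min() < -1e-9 or self.dosages.max() > 2 + 1e-9:
            raise ValueError("dosages must lie in [0, 2]")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValueError(f"positions not sorted within chromosome {c}")
        self._index = {v: i for i, v in enumerate(self.variant_ids)}

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency: min(p, 1-p) with p = mean(dosage)/2."""
        p = self.dosages.mean(axis=1) / 2.0
        return np.minimum(p, 1.0 - p)

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            raise KeyError(f"variant {variant_id!r} not present") from None

    def row(self, variant_id: str) -> np.ndarray:
        return self.dosages[self.index_of(variant_id)]

    def to_frame(self) -> pd.DataFrame:
        """Dosage TSV layout: variant_id, chrom, pos, ref, alt, samples..."""
        meta = pd.DataFrame(
            {
                "variant_id": self.variant_ids,
                "chrom": self.chrom,
                "pos": self.pos,
                "ref": self.ref if self.ref else ["N"] * self.n_variants,
                "alt": self.alt if self.alt else ["N"] * self.n_variants,
            }
        )
        cols = self.sample_ids or [f"S{i}" for i in range(self.n_samples)]
        return pd.concat([meta, pd.DataFrame(self.dosages, columns=cols)], axis=1)

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "DosageMatrix":
        df = pd.read_csv(path, sep="\t")
        meta_cols = ["variant_id", "chrom", "pos", "ref", "alt"]
        samples = [c for c in df.columns if c not in meta_cols]
        return cls(
            dosages=df[samples].to_numpy(float),
            variant_ids=df["variant_id"].tolist(),
            chrom=df["chrom"].to_numpy(),
            pos=df["pos"].to_numpy(),
            ref=df["ref"].tolist(),
            alt=df["alt"].tolist(),
            sample_ids=samples,
        )


@dataclass
class LdNeighborhood:
    """A lead variant together with all its proxies at r2 >= r2_threshold."""

    lead: str
    proxies: list[tuple[str, float]]
    r2_threshold: float

    @property
    def variant_ids(self) -> list[str]:
        return [v for v, _ in self.proxies]


def dosage_from_genotype_probs(p_hom_ref: float, p_het: float, p_hom_alt: float) -> float:
    """Expected alternate-allele dosage from genotype probabilities.

    Computes ``2 * (0.5 * p_het + p_hom_alt)``, the mean of the additive
    genotype code under the given probabilities.
    """
    probs = np.asarray([p_hom_ref, p_het, p_hom_alt], dtype=float)
    if np.any(probs < 0):
        raise ValueError("genotype probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"genotype probabilities must sum to 1, got {probs.sum()}")
    return float(2.0 * (0.5 * p_het + p_hom_alt))


def r2(a: np.ndarray, b: np.ndarray) -> float:
    """Squared Pearson correlation between two dosage vectors.

    Raises ``ValueError`` on a constant vector, for which allelic
    correlation is undefined.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("r2 undefined for a monomorphic (constant) dosage vector")
    r = np.corrcoef(a, b)[0, 1]
    return float(min(r * r, 1.0))


def _pairwise_r2(dosages: np.ndarray) -> np.ndarray:
    """All-pairs r2 for rows of a dosage matrix; constant rows give nan."""
    d = dosages - dosages.mean(axis=1, keepdims=True)
    ss = np.einsum("ij,ij->i", d, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (d @ d.T) / np.sqrt(np.outer(ss, ss))
    return corr**2


def prune_by_ld(
    snps: list[str],
    dosages: DosageMatrix,
    r2_max: float = 0.8,
    window_bp: int = 1_000_000,
) -> list[str]:
    """Greedy LD pruning of a significance-ranked variant list.

    Walks the list best-first and keeps a variant iff its r2 with every
    already-kept variant on the same chromosome within ``window_bp`` is
    strictly below ``r2_max``.
    """
    kept: list[str] = []
    kept_idx: list[int] = []
    for v in snps:
        i = dosages.index_of(v)
        ok = True
        for j in kept_idx:
            if dosages.chrom[i] != dosages.chrom[j]:
                continue
            if abs(int(dosages.pos[i]) - int(dosages.pos[j])) > window_bp:
                continue
            if r2(dosages.dosages[i], dosages.dosages[j]) >= r2_max:
                ok = False
                break
        if ok:
            kept.append(v)
            kept_idx.append(i)
    return kept


def proxies(
    lead: str,
    dosages: DosageMatrix,
    r2_min: float = 0.99,
    window_bp: int = 1_000_000,
) -> LdNeighborhood:
    """All variants within ``window_bp`` of the lead with r2 >= r2_min.

    The lead itself is always included with r2 = 1.
    """
    i = dosages.index_of(lead)
    lead_row = dosages.dosages[i]
    if np.ptp(lead_row) == 0:
        raise ValueError(f"lead {lead!r} is monomorphic")
    in_win = (dosages.chrom == dosages.chrom[i]) & (
        np.abs(dosages.pos - dosages.pos[i]) <= window_bp
    )
    out: list[tuple[str, float]] = [(lead, 1.0)]
    for j in np.flatnonzero(in_win):
        if j == i:
            continue
        row = dosages.dosages[j]
        if np.ptp(row) == 0:
            continue
        val = r2(lead_row, row)
        if val >= r2_min:
            out.append((dosages.variant_ids[j], val))
    return LdNeighborhood(lead=lead, proxies=out, r2_threshold=r2_min)
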