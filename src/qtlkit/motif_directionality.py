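"""TF footprint motif directionality: do motif-preferred alleles raise expression?

For every eSNP falling inside a TF footprint motif occurrence, the eQTL
slope is re-keyed to the motif's most preferred base at the overlapped
position (sign flipped when the preferred base is the non-effect allele).
A motif's directionality fraction is the share of instances where the
preferred base associates with increased expression: near 1 activating,
near 0 repressive, near 0.5 no preference. Deviation from the 0.5 null is
assessed with an exact two-sided binomial test and BH FDR across motifs.

Only instances at informative motif positions (information content >= 0.7
bits) where the effect or non-effect allele is the single most preferred
base are eligible; minus-strand occurrences are handled by mapping the SNP
position and alleles through the reverse complement.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}
IC_MIN = 0.7
MIN_INSTANCES = 10

__all__ = [
    "Pwm",
    "EligibleInstance",
    "DirectionalityResult",
    "instance_eligibility",
    "directionality_fraction",
    "deviation_test",
    "collect_instances",
    "read_jaspar",
    "write_jaspar",
]


@dataclass
class Pwm:
    """Position probability matrix, rows = positions, columns = A, C, G, T."""

    motif_id: str
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValueError("PWM must be positions x 4")
        sums = self.matrix.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            raise ValueError("PWM rows must each sum to 1")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def information_content(self) -> np.ndarray:
        """Per-position IC in bits against a uniform background: 2 + sum p log2 p."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)

    def preferred_base(self, position: int) -> str | None:
        """Single most probable base at a position; None on a tie."""
        row = self.matrix[position]
        top = row.max()
        winners = np.flatnonzero(row >= top - 1e-12)
        if len(winners) != 1:
            return None
        return BASES[winners[0]]

    def reverse_complement(self) -> "Pwm":
        return Pwm(self.motif_id, self.matrix[::-1, ::-1])


@dataclass
class EligibleInstance:
    """One eSNP x footprint-motif overlap passing the eligibility rules."""

    motif_id: str
    variant_id: str
    motif_position: int
    preferred_base: str
    preferred_is_effect: bool
    rekeyed_slope: float


@dataclass
class DirectionalityResult:
    motif_id: str
    n_instances: int
    fraction: float
    p_binomial: float = np.nan
    fdr_q: float = np.nan


def instance_eligibility(
    snp_pos: int,
    effect_allele: str,
    non_effect_allele: str,
    slope: float,
    occ_start: int,
    occ_end: int,
    occ_strand: str,
    pwm: Pwm,
    variant_id: str = "",
    ic_min: float = IC_MIN,
) -> EligibleInstance | None:
    """Eligibility of one eSNP inside one footprint occurrence.

    ``snp_pos`` is 1-based; the occurrence is 0-based half-open and must
    have the PWM's length. Returns None when the SNP misses the occurrence,
    the position is uninformative (IC < ic_min), the preferred base is tied,
    or neither allele is the preferred base.
    """
    pos0 = snp_pos - 1
    if not (occ_start <= pos0 < occ_end):
        return None
    if occ_end - occ_start != len(pwm):
        raise ValueError("occurrence length does not match PWM length")
    if occ_strand == "-":
        offset = (occ_end - 1) - pos0
        eff = _COMP[effect_allele.upper()]
        non = _COMP[non_effect_allele.upper()]
    else:
        offset = pos0 - occ_start
        eff = effect_allele.upper()
        non = non_effect_allele.upper()
    if pwm.information_content[offset] < ic_min:
        return None
    preferred = pwm.preferred_base(offset)
    if preferred is None:
        return None
    if preferred == eff:
        rekeyed = slope
        is_eff = True
    elif preferred == non:
        rekeyed = -slope
        is_eff = False
    else:
        return None
    return EligibleInstance(
        motif_id=pwm.motif_id,
        variant_id=variant_id,
        motif_position=offset,
        preferred_base=preferred,
        preferred_is_effect=is_eff,
        rekeyed_slope=rekeyed,
    )


def directionality_fraction(
    instances: list[EligibleInstance],
    min_instances: int = MIN_INSTANCES,
) -> DirectionalityResult:
    """Fraction of instances where the preferred base raises expression."""
    if not instances:
        raise ValueError("no eligible instances")
    motif_id = instances[0].motif_id
    rekeyed = np.array([i.rekeyed_slope for i in instances])
    nonzero = rekeyed != 0
    if not nonzero.all():
        log.info("motif %s: %d zero-slope instance(s) excluded", motif_id, int((~nonzero).sum()))
    rekeyed = rekeyed[nonzero]
    n = len(rekeyed)
    if n < min_instances:
        raise ValueError(f"motif {motif_id}: {n} instances < required {min_instances}")
    return DirectionalityResult(motif_id=motif_id, n_instances=n, fraction=float(np.mean(rekeyed > 0)))


def deviation_test(results: list[DirectionalityResult], fdr: float = 0.10) -> pd.DataFrame:
    """Exact two-sided binomial test of each fraction against 0.5, BH FDR.

    Returns one row per motif with p, q and a significance flag at the
    requested FDR.
    """
    rows = []
    for r in results:
        k = int(round(r.fraction * r.n_instances))
        p = binomtest(k, r.n_instances, 0.5, alternative="two-sided").pvalue
        rows.append({"motif_id": r.motif_id, "n_instances": r.n_instances, "fraction": r.fraction, "p_binomial": p})
    df = pd.DataFrame(rows)
    if len(df):
        df["fdr_q"] = multipletests(df["p_binomial"], method="fdr_bh")[1]
        df["significant"] = df["fdr_q"] < fdr
    return df


def collect_instances(
    esnps: pd.DataFrame,
    footprints: pd.DataFrame,
    pwms: dict[str, Pwm],
    ic_min: float = IC_MIN,
) -> dict[str, list[EligibleInstance]]:
    """Gather eligible instances per motif from eSNPs and occurrence intervals.

    ``esnps`` needs variant_id, chrom, pos (1-based), effect_allele,
    non_effect_allele, slope; ``footprints`` needs chrom, start, end,
    strand and label (the motif id, keying into ``pwms``).
    """
    by_chrom: dict[str, pd.DataFrame] = {str(c): g for c, g in esnps.groupby(esnps["chrom"].astype(str))}
    out: dict[str, list[EligibleInstance]] = {}
    for occ in footprints.itertuples(index=False):
        motif = getattr(occ, "label")
        pwm = pwms.get(motif)
        if pwm is None:
            continue
        snps = by_chrom.get(str(occ.chrom))
        if snps is None:
            continue
        inside = snps[(snps["pos"] - 1 >= occ.start) & (snps["pos"] - 1 < occ.end)]
        for snp in inside.itertuples(index=False):
            inst = instance_eligibility(
                int(snp.pos),
                snp.effect_allele,
                snp.non_effect_allele,
                float(snp.slope),
                int(occ.start),
                int(occ.end),
                str(getattr(occ, "strand", "+")),
                pwm,
                variant_id=snp.variant_id,
                ic_min=ic_min,
            )
            if inst is not None:
                out.setdefault(motif, []).append(inst)
    return out


# ---------------------------------------------------------------------------
# JASPAR-style PWM text I/O


def write_jaspar(pwms: dict[str, Pwm], path) -> None:
    """Write probability matrices in JASPAR text layout (one row per base)."""
    with open(path, "w") as fh:
        for pwm in pwms.values():
            fh.write(f">{pwm.motif_id}\t{pwm.motif_id}\n")
            for b, col in zip(BASES, pwm.matrix.T):
                vals = " ".join(f"{v:.6f}" for v in col)
                fh.write(f"{b}  [ {vals} ]\n")


def read_jaspar(path) -> dict[str, Pwm]:
    """Read JASPAR-style matrices; counts are normalized to probabilities."""
    from Bio import motifs as bio_motifs

    out: dict[str, Pwm] = {}
    with open(path) as fh:
        for m in bio_motifs.parse(fh, "jaspar"):
            counts = np.array([list(m.counts[b]) for b in BASES]).T  # positions x 4
            probs = counts / counts.sum(axis=1, keepdims=True)
            motif_id = m.matrix_id or m.name
            out[motif_id] = Pwm(motif_id=motif_id, matrix=probs)
    return out
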