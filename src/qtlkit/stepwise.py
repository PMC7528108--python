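"""Forward-backward conditional discovery of independent cis-eQTL signals.

Starting from the permutation-calibrated eGene catalog, a single gene-level
p-value threshold is fixed as the largest beta-adjusted p among eGenes
significant at 1% FDR. The forward stage rescans each eGene's cis window
iteratively, conditioning on all previously discovered signal dosages as
covariates, and appends the best association while it stays below the
threshold. The backward stage retests each forward signal while controlling
for all the others, dropping signals that no longer reach the threshold and
otherwise replacing them with the rescan's best variant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cis_eqtl import FDR_EGENE, MAF_MIN, N_PERM, WINDOW_BP, permutation_pass
from .expr_prep import CovariateSet, FeatureMatrix
from .ld import DosageMatrix

log = logging.getLogger(__name__)

MAX_FORWARD_ITER = 10  # bound on independent signals per gene

__all__ = ["Signal", "SignalSet", "gene_level_threshold", "forward_pass", "backward_pass", "run_stepwise"]


@dataclass
class Signal:
    variant_id: str
    rank: int
    p_beta: float
    record: pd.Series = field(repr=False)
    stage: str = "forward"


@dataclass
class SignalSet:
    gene_id: str
    signals: list[Signal]
    gene_threshold: float

    @property
    def variant_ids(self) -> list[str]:
        return [s.variant_id for s in self.signals]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.signals:
            rows.append(
                {
                    "gene_id": self.gene_id,
                    "signal_rank": s.rank,
                    "variant_id": s.variant_id,
                    "slope": s.record.get("slope", np.nan),
                    "p_beta": s.p_beta,
                    "stage": s.stage,
                }
            )
        return pd.DataFrame(rows)


def gene_level_threshold(egene_p_betas: np.ndarray) -> float:
    """Largest beta-adjusted p-value among the FDR-significant eGenes."""
    p = np.asarray(egene_p_betas, float)
    if p.size == 0:
        raise ValueError("empty eGene set: no threshold can be derived")
    return float(p.max())


def _iteration_seed(seed: int, gene_index: int, iteration: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(entropy=(int(seed), int(gene_index), int(iteration)))


def forward_pass(
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    cov: CovariateSet | None,
    gene_id: str,
    threshold: float,
    n_perm: int = N_PERM,
    seed: int = 0,
    gene_index: int = 0,
    window_bp: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
    max_iter: int = MAX_FORWARD_ITER,
) -> SignalSet:
    """Iterative conditional scans until the best association misses the threshold."""
    signals: list[Signal] = []
    for it in range(max_iter):
        extra = (
            np.column_stack([dosages.row(s.variant_id) for s in signals]) if signals else None
        )
        try:
            _, best = permutation_pass(
                expr,
                dosages,
                cov,
                gene_id,
                window_bp=window_bp,
                maf_min=maf_min,
                n_perm=n_perm,
                seed=_iteration_seed(seed, gene_index, it),
                extra_covariates=extra,
            )
        except ValueError as err:
            warnings.warn(f"gene {gene_id} iteration {it}: {err}; stopping forward pass", stacklevel=2)
            break
        if best is None or best["p_beta"] > threshold:
            break
        if best["variant_id"] in {s.variant_id for s in signals}:
            # conditioning should make a discovered signal untestable; a repeat
            # indicates numerically degenerate dosages, so stop
            break
        signals.append(Signal(best["variant_id"], len(signals) + 1, float(best["p_beta"]), best))
    return SignalSet(gene_id=gene_id, signals=signals, gene_threshold=threshold)


def backward_pass(
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    cov: CovariateSet | None,
    gene_id: str,
    forward: SignalSet,
    n_perm: int = N_PERM,
    seed: int = 0,
    gene_index: int = 0,
    window_bp: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
) -> SignalSet:
    """Retest each forward signal controlling for all the others.

    A signal whose conditional rescan no longer reaches the gene threshold
    is dropped; otherwise the rescan's best variant becomes the signal's
    representative. A single-signal set is returned unchanged (there is
    nothing to condition on).
    """
    if not forward.signals:
        raise ValueError("backward pass requires a non-empty forward signal set")
    if len(forward.signals) == 1:
        return forward
    # signals still in the model; a dropped signal is no longer conditioned on
    current: list[Signal] = list(forward.signals)
    kept: list[Signal] = []
    for i, sig in enumerate(forward.signals):
        others = [s for s in current if s.variant_id != sig.variant_id]
        if not others:
            kept.append(sig)
            continue
        extra = np.column_stack([dosages.row(s.variant_id) for s in others])
        try:
            _, best = permutation_pass(
                expr,
                dosages,
                cov,
                gene_id,
                window_bp=window_bp,
                maf_min=maf_min,
                n_perm=n_perm,
                seed=_iteration_seed(seed, gene_index, 1000 + i),
                extra_covariates=extra,
            )
        except ValueError as err:
            warnings.warn(f"gene {gene_id} backward signal {i}: {err}; dropping", stacklevel=2)
            current = [s for s in current if s.variant_id != sig.variant_id]
            continue
        if best is None or best["p_beta"] > forward.gene_threshold:
            log.info("gene %s: forward signal %s dropped in backward pass", gene_id, sig.variant_id)
            current = [s for s in current if s.variant_id != sig.variant_id]
            continue
        stage = "forward" if best["variant_id"] == sig.variant_id else "backward-replaced"
        if best["variant_id"] in {s.variant_id for s in kept}:
            log.info("gene %s: duplicate representative %s dropped", gene_id, best["variant_id"])
            current = [s for s in current if s.variant_id != sig.variant_id]
            continue
        replacement = Signal(best["variant_id"], len(kept) + 1, float(best["p_beta"]), best, stage)
        kept.append(replacement)
        current = [replacement if s.variant_id == sig.variant_id else s for s in current]
    return SignalSet(gene_id=gene_id, signals=kept, gene_threshold=forward.gene_threshold)


def run_stepwise(
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    cov: CovariateSet | None,
    eqtl_results: pd.DataFrame,
    fdr: float = FDR_EGENE,
    n_perm: int = N_PERM,
    seed: int = 0,
    window_bp: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
) -> pd.DataFrame:
    """Forward-backward conditional analysis over all significant eGenes.

    ``eqtl_results`` is the per-gene table from ``map_cis`` (needs gene_id,
    p_beta, q_value). Returns the concatenated signal table.
    """
    egenes = eqtl_results[eqtl_results["q_value"] < fdr]
    if egenes.empty:
        return pd.DataFrame(columns=["gene_id", "signal_rank", "variant_id", "slope", "p_beta", "stage"])
    threshold = gene_level_threshold(egenes["p_beta"].to_numpy())
    frames = []
    for gi, gene_id in enumerate(egenes["gene_id"]):
        fwd = forward_pass(
            expr, dosages, cov, gene_id, threshold,
            n_perm=n_perm, seed=seed, gene_index=gi, window_bp=window_bp, maf_min=maf_min,
        )
        if not fwd.signals:
            continue
        final = backward_pass(
            expr, dosages, cov, gene_id, fwd,
            n_perm=n_perm, seed=seed, gene_index=gi, window_bp=window_bp, maf_min=maf_min,
        )
        if final.signals:
            frames.append(final.to_frame())
    if not frames:
        return pd.DataFrame(columns=["gene_id", "signal_rank", "variant_id", "slope", "p_beta", "stage"])
    return pd.concat(frames, ignore_index=True)
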