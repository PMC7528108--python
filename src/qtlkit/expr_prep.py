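"""Expression normalization and covariate construction.

The preparation chain mirrors standard bulk RNA-seq eQTL practice: drop
features with too many zero counts, scale each library to a fixed total,
quantile-normalize across samples, and build principal-component covariates
that absorb technical variation (laboratory of origin, batch).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger(__name__)

ZERO_FRACTION_MAX = 0.2
SCALE_TOTAL = 1e7
N_EXPR_PCS_DEFAULT = 25
N_GENO_PCS_DEFAULT = 4

__all__ = [
    "FeatureMatrix",
    "CovariateSet",
    "filter_features",
    "scale_and_quantile_normalize",
    "compute_pcs",
    "residualize",
]


@dataclass
class FeatureMatrix:
    """Expression features (exons or genes) x samples.

    ``values`` is a DataFrame indexed by feature id with sample columns.
    ``annot`` maps each feature to its gene and coordinates and must carry
    columns feature_id, gene_id, chrom, start, end, tss, strand.
    """

    values: pd.DataFrame
    annot: pd.DataFrame

    def __post_init__(self) -> None:
        self.annot = self.annot.set_index("feature_id", drop=False) if (
            self.annot.index.name != "feature_id"
        ) else self.annot
        missing = set(self.values.index) - set(self.annot.index)
        if missing:
            raise ValueError(f"{len(missing)} features missing from annotation")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def gene_of_feature(self) -> pd.Series:
        return self.annot.loc[self.values.index, "gene_id"]

    def tss(self, gene_id: str) -> int:
        rows = self.annot[self.annot["gene_id"] == gene_id]
        if rows.empty:
            raise KeyError(gene_id)
        return int(rows["tss"].iloc[0])

    def genes(self) -> list[str]:
        return list(dict.fromkeys(self.annot.loc[self.values.index, "gene_id"]))

    def features_of_gene(self, gene_id: str) -> list[str]:
        mask = self.gene_of_feature == gene_id
        return list(self.values.index[mask.to_numpy()])

    def with_values(self, values: pd.DataFrame) -> "FeatureMatrix":
        return FeatureMatrix(values=values, annot=self.annot)

    def write_tsv(self, expr_path, annot_path=None) -> None:
        self.values.to_csv(expr_path, sep="\t", index_label="feature_id")
        if annot_path is not None:
            self.annot.to_csv(annot_path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, expr_path, annot_path) -> "FeatureMatrix":
        values = pd.read_csv(expr_path, sep="\t", index_col="feature_id")
        annot = pd.read_csv(annot_path, sep="\t")
        return cls(values=values, annot=annot)


@dataclass
class CovariateSet:
    """Sample-level covariates for the association models.

    Holds expression PCs, genotype PCs, sex and laboratory of origin; the
    design matrix expands the lab factor into dummy columns (first level as
    reference) and never includes the intercept, which the model adds.
    """

    sample_ids: list[str]
    expression_pcs: np.ndarray | None = None
    genotype_pcs: np.ndarray | None = None
    sex: np.ndarray | None = None
    lab: np.ndarray | None = None
    extra: dict[str, np.ndarray] = field(default_factory=dict)

    def design(self) -> tuple[np.ndarray, list[str]]:
        """Numeric covariate matrix (samples x k) and column names, no intercept."""
        n = len(self.sample_ids)
        cols: list[np.ndarray] = []
        names: list[str] = []
        if self.expression_pcs is not None:
            pcs = np.atleast_2d(np.asarray(self.expression_pcs, float))
            if pcs.shape[0] != n:
                pcs = pcs.T
            cols.extend(pcs.T)
            names.extend(f"ePC{i + 1}" for i in range(pcs.shape[1]))
        if self.genotype_pcs is not None:
            pcs = np.atleast_2d(np.asarray(self.genotype_pcs, float))
            if pcs.shape[0] != n:
                pcs = pcs.T
            cols.extend(pcs.T)
            names.extend(f"gPC{i + 1}" for i in range(pcs.shape[1]))
        if self.sex is not None:
            cols.append(np.asarray(self.sex, float))
            names.append("sex")
        if self.lab is not None:
            levels = pd.unique(np.asarray(self.lab))
            for lv in levels[1:]:
                cols.append((np.asarray(self.lab) == lv).astype(float))
                names.append(f"lab[{lv}]")
        for k, v in self.extra.items():
            cols.append(np.asarray(v, float))
            names.append(k)
        if not cols:
            return np.empty((n, 0)), []
        return np.column_stack(cols), names


def filter_features(raw: FeatureMatrix, zero_fraction_max: float = ZERO_FRACTION_MAX) -> FeatureMatrix:
    """Drop features whose zero fraction exceeds the threshold.

    A feature with exactly the threshold fraction of zeros is retained
    (only strictly-greater fractions are removed). Order is preserved.
    """
    vals = raw.values.to_numpy(float)
    if vals.min() < 0:
        raise ValueError("counts must be non-negative")
    zero_frac = (vals == 0).mean(axis=1)
    keep = zero_frac <= zero_fraction_max + 1e-12
    if not keep.any():
        warnings.warn("all features removed by the zero-fraction filter", stacklevel=2)
    return raw.with_values(raw.values.loc[keep])


def scale_and_quantile_normalize(raw: FeatureMatrix, scale_total: float = SCALE_TOTAL) -> FeatureMatrix:
    """Scale each sample column to a fixed total, then quantile-normalize.

    Each column is first multiplied so its total equals ``scale_total``
    (ten million by default, making libraries of different depth
    comparable). Quantile normalization then maps each column's ranks onto
    the mean order statistics across columns; ties receive the mean of the
    target order statistics for their rank span, so the transform is
    idempotent.
    """
    vals = raw.values.to_numpy(float)
    totals = vals.sum(axis=0)
    if np.any(totals <= 0):
        bad = [raw.sample_ids[i] for i in np.flatnonzero(totals <= 0)]
        raise ValueError(f"zero-total sample column(s): {bad}")
    scaled = vals * (scale_total / totals)

    n_feat = scaled.shape[0]
    # target order statistics: mean across samples of each column sorted
    target = np.sort(scaled, axis=0).mean(axis=1)
    out = np.empty_like(scaled)
    for j in range(scaled.shape[1]):
        col = scaled[:, j]
        order = np.argsort(col, kind="mergesort")
        sorted_vals = col[order]
        # tied values get the mean of the target order statistics over
        # their rank span, which preserves column totals
        run_starts = np.r_[0, np.flatnonzero(np.diff(sorted_vals) != 0) + 1]
        run_sums = np.add.reduceat(target, run_starts)
        run_lens = np.diff(np.r_[run_starts, n_feat])
        mapped = np.repeat(run_sums / run_lens, run_lens)
        out[order, j] = mapped
    return raw.with_values(pd.DataFrame(out, index=raw.values.index, columns=raw.values.columns))


def compute_pcs(x: FeatureMatrix, k: int) -> np.ndarray:
    """Top-k principal components of samples from the centered matrix.

    Returns a samples x k matrix with orthonormal columns (left singular
    vectors of the centered samples x features matrix). Sign convention:
    the largest-magnitude entry of each component is positive.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    mat = x.values.to_numpy(float).T  # samples x features
    if k >= min(mat.shape):
        raise ValueError(f"k={k} must be < min(n_samples, n_features)={min(mat.shape)}")
    centered = mat - mat.mean(axis=0)
    u, s, _ = np.linalg.svd(centered, full_matrices=False)
    pcs = u[:, :k]
    flip = np.sign(pcs[np.abs(pcs).argmax(axis=0), np.arange(k)])
    flip[flip == 0] = 1.0
    return pcs * flip


def residualize(x: FeatureMatrix, cov: CovariateSet) -> FeatureMatrix:
    """Replace each feature by its OLS residual on the covariates.

    An intercept is always included, so residuals are centered. Raises on a
    rank-deficient covariate design, naming the collinear columns.
    """
    design, names = cov.design()
    n = design.shape[0]
    if n != len(x.sample_ids):
        raise ValueError("covariates and expression have different sample counts")
    full = np.column_stack([np.ones(n), design])
    rank = np.linalg.matrix_rank(full)
    if rank < full.shape[1]:
        collinear = _collinear_columns(full, ["intercept"] + names)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
    q, _ = np.linalg.qr(full)
    vals = x.values.to_numpy(float)
    resid = vals - (vals @ q) @ q.T
    return x.with_values(pd.DataFrame(resid, index=x.values.index, columns=x.values.columns))


def _collinear_columns(mat: np.ndarray, names: list[str]) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    out = []
    for j in range(1, mat.shape[1]):
        if np.linalg.matrix_rank(mat[:, : j + 1]) == np.linalg.matrix_rank(mat[:, :j]):
            out.append(names[j])
    return out
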