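"""Bulk expression deconvolution and genotype x cell-fraction interaction eQTLs.

Deconvolution estimates per-sample cell-type fractions from bulk expression
by constrained least squares against a log2 signature matrix of marker
genes (top differentially expressed genes of each pure reference population
vs the mixed tissue). Interaction mapping then asks, for known eQTLs,
whether the genotype effect scales with a cell-type fraction, using an
expression ~ dosage + fraction + dosage x fraction model with an empirical
permutation FDR (cell-fraction vector permuted across samples, which
preserves the marginal eQTL).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import nnls

log = logging.getLogger(__name__)

TOP_K = 500
SIG_GENE_COVERAGE_MIN = 0.8
INTERACTION_N_PERM = 100
INTERACTION_FDR = 0.01

__all__ = ["build_signature", "deconvolve", "interaction_scan"]


def _log2p1(x: np.ndarray) -> np.ndarray:
    return np.log2(np.asarray(x, float) + 1.0)


def build_signature(
    reference_sets: dict[str, pd.DataFrame],
    mixed: pd.DataFrame,
    top_k: int = TOP_K,
) -> pd.DataFrame:
    """Marker-gene signature matrix from pure reference populations.

    For each reference group (genes x samples frame), genes are ranked by
    the two-sample t statistic of that group against the mixed samples on
    log2(x+1), largest first, so each contrast contributes the genes most
    upregulated in its pure population (its markers); the union of each
    contrast's top ``top_k`` genes forms the signature gene set, and the
    signature entry is the log2 median expression within the pure group.
    """
    if len(reference_sets) < 2:
        raise ValueError("need at least two reference cell types")
    genes = mixed.index
    mixed_l = _log2p1(mixed.to_numpy())
    selected: list[str] = []
    for name, ref in reference_sets.items():
        if ref.shape[1] < 2:
            raise ValueError(f"reference group {name!r} needs >= 2 samples")
        ref_l = _log2p1(ref.loc[genes].to_numpy())
        t, _ = stats.ttest_ind(ref_l, mixed_l, axis=1, equal_var=False)
        t = np.nan_to_num(t)
        k = min(top_k, len(genes))
        if k < top_k:
            warnings.warn(f"only {k} genes available for top-{top_k} selection", stacklevel=2)
        top = genes[np.argsort(-t)[:k]]
        selected.extend(top)
    union = list(dict.fromkeys(selected))
    sig = pd.DataFrame(
        {name: np.median(_log2p1(ref.loc[union].to_numpy()), axis=1) for name, ref in reference_sets.items()},
        index=union,
    )
    sig = sig[(sig != 0).any(axis=1)]
    return sig


def _simplex_lstsq(S: np.ndarray, x: np.ndarray, tol: float = 1e-9) -> np.ndarray:
    """min ||S f - x||^2 subject to f >= 0 and sum(f) = 1.

    Non-negative least squares on the sum-constraint-augmented system,
    followed by an equality-constrained polish on the active support.
    """
    k = S.shape[1]
    w = 1e6 * max(np.abs(S).max(), 1.0)
    A = np.vstack([S, w * np.ones((1, k))])
    b = np.concatenate([x, [w]])
    f, _ = nnls(A, b)
    support = f > tol
    if support.any():
        Ss = S[:, support]
        m = int(support.sum())
        kkt = np.zeros((m + 1, m + 1))
        kkt[:m, :m] = Ss.T @ Ss
        kkt[:m, m] = 1.0
        kkt[m, :m] = 1.0
        rhs = np.concatenate([Ss.T @ x, [1.0]])
        try:
            sol = np.linalg.solve(kkt, rhs)[:m]
            if np.all(sol >= -tol):
                f = np.zeros(k)
                f[support] = np.maximum(sol, 0.0)
        except np.linalg.LinAlgError:
            pass
    total = f.sum()
    if total <= 0:
        raise ValueError("deconvolution produced an empty support")
    return f / total


def deconvolve(mixed: pd.DataFrame, sig: pd.DataFrame) -> pd.DataFrame:
    """Cell-type fractions per sample by simplex-constrained least squares.

    ``mixed`` is genes x samples on the raw scale (log2(x+1) is applied to
    match the signature); ``sig`` is the signature from
    :func:`build_signature`. Requires at least 80% of signature genes to be
    present in the mixture.
    """
    common = sig.index.intersection(mixed.index)
    if len(common) < SIG_GENE_COVERAGE_MIN * len(sig):
        raise ValueError(
            f"mixture covers only {len(common)}/{len(sig)} signature genes (< 80%)"
        )
    S = sig.loc[common].to_numpy(float)
    if np.linalg.matrix_rank(S) < S.shape[1]:
        corr = np.corrcoef(S.T)
        pairs = [
            f"{sig.columns[i]}~{sig.columns[j]}"
            for i in range(len(sig.columns))
            for j in range(i + 1, len(sig.columns))
            if abs(corr[i, j]) > 0.999
        ]
        raise ValueError(f"rank-deficient signature; collinear cell types: {pairs or 'unknown'}")
    X = _log2p1(mixed.loc[common].to_numpy())
    fracs = np.stack([_simplex_lstsq(S, X[:, j]) for j in range(X.shape[1])])
    return pd.DataFrame(fracs, index=mixed.columns, columns=sig.columns)


# ---------------------------------------------------------------------------
# genotype x cell-fraction interaction


def _interaction_pvals(y: np.ndarray, d: np.ndarray, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Interaction coefficient and p for y ~ 1 + d + f + d*f, batched over
    the rows of F (each row one fraction vector)."""
    n = len(y)
    B = F.shape[0]
    X = np.empty((B, n, 4))
    X[:, :, 0] = 1.0
    X[:, :, 1] = d
    X[:, :, 2] = F
    X[:, :, 3] = d * F
    XtX = np.einsum("bni,bnj->bij", X, X)
    Xty = np.einsum("bni,n->bi", X, y)
    beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
    resid = y[None, :] - np.einsum("bni,bi->bn", X, beta)
    df = n - 4
    sigma2 = np.einsum("bn,bn->b", resid, resid) / df
    XtX_inv = np.linalg.inv(XtX)
    se = np.sqrt(sigma2 * XtX_inv[:, 3, 3])
    t = beta[:, 3] / se
    p = 2.0 * stats.t.sf(np.abs(t), df)
    return beta[:, 3], p


def interaction_scan(
    residual_expr: pd.DataFrame,
    dosages,
    fractions: pd.DataFrame,
    cell_type: str,
    eqtl_pairs: pd.DataFrame,
    n_perm: int = INTERACTION_N_PERM,
    seed: int = 0,
    fdr: float = INTERACTION_FDR,
) -> pd.DataFrame:
    """Genotype-by-cell-fraction interaction test at known eQTLs.

    ``residual_expr`` is a features x samples frame of covariate-adjusted
    expression; ``eqtl_pairs`` needs feature_id (or gene_id matching the
    expression index) and variant_id. The empirical FDR at each observed
    interaction p is the mean number of null discoveries (fraction vector
    permuted jointly across all tests) over the observed discovery count.
    """
    f = fractions[cell_type].to_numpy(float)
    if np.ptp(f) == 0:
        raise ValueError(f"cell fraction {cell_type!r} is constant across samples")
    key = "feature_id" if "feature_id" in eqtl_pairs.columns else "gene_id"
    rng = np.random.default_rng(seed)
    n = len(f)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    F_null = f[perm_idx]

    coefs, p_obs = [], []
    p_null_all = np.empty((len(eqtl_pairs), n_perm))
    for i, row in enumerate(eqtl_pairs.itertuples(index=False)):
        y = residual_expr.loc[getattr(row, key)].to_numpy(float)
        d = dosages.row(row.variant_id)
        c, p = _interaction_pvals(y, d, f[None, :])
        coefs.append(c[0])
        p_obs.append(p[0])
        _, pn = _interaction_pvals(y, d, F_null)
        p_null_all[i] = pn
    p_obs = np.asarray(p_obs)

    # empirical FDR: mean null discoveries / observed discoveries at each p
    order = np.argsort(p_obs)
    sorted_p = p_obs[order]
    null_flat = np.sort(p_null_all.ravel())
    n_null_le = np.searchsorted(null_flat, sorted_p, side="right") / n_perm
    n_obs_le = np.arange(1, len(sorted_p) + 1)
    raw_fdr = np.minimum(n_null_le / n_obs_le, 1.0)
    raw_fdr = np.minimum.accumulate(raw_fdr[::-1])[::-1]
    perm_fdr = np.empty_like(raw_fdr)
    perm_fdr[order] = raw_fdr

    out = eqtl_pairs.copy().reset_index(drop=True)
    out["cell_type"] = cell_type
    out["interaction_coef"] = coefs
    out["p_interaction"] = p_obs
    out["perm_fdr"] = perm_fdr
    out["significant"] = out["perm_fdr"] < fdr
    return out
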