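"""Cis-eQTL mapping: nominal scan, permutation beta-approximation, q-values.

The gene-level testing scheme follows the standard permutation design for
cis scans: for each gene, all features (exons or the gene itself) are tested
against every variant within a +/-1 Mb window of the TSS; significance of the
best association is calibrated by permuting expression sample labels jointly
across the gene's features, recording the minimum nominal p per permutation,
fitting a Beta distribution to those minima by maximum likelihood, and
evaluating its CDF at the observed minimum ("beta-adjusted p"). Genome-wide
FDR uses Storey q-values with a smoothed pi0 estimate.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.interpolate import UnivariateSpline

from .expr_prep import CovariateSet, FeatureMatrix
from .ld import DosageMatrix

log = logging.getLogger(__name__)

WINDOW_BP = 1_000_000
MAF_MIN = 0.01
MAF_MIN_SMALL_COHORT = 0.05  # small-cohort (sorted-cell) mode
N_PERM = 1000
FDR_EGENE = 0.01

__all__ = [
    "PermutationFit",
    "nominal_scan",
    "permutation_pass",
    "qvalues",
    "storey_pi0",
    "map_cis",
    "nominal_table",
    "fit_beta_ml",
]


@dataclass
class PermutationFit:
    """Beta fit to the per-permutation minimum nominal p-values."""

    n_perm: int
    beta_a: float
    beta_b: float
    empirical_min_p: np.ndarray = field(repr=False)
    converged: bool = True

    def p_beta(self, observed_min_p: float) -> float:
        return float(stats.beta.cdf(observed_min_p, self.beta_a, self.beta_b))

    def p_empirical(self, observed_min_p: float) -> float:
        hits = int(np.sum(self.empirical_min_p <= observed_min_p))
        return (1.0 + hits) / (self.n_perm + 1.0)


# ---------------------------------------------------------------------------
# gene-level data preparation


class _GeneData:
    """Residualized, standardized arrays for one gene's cis window."""

    def __init__(
        self,
        expr: FeatureMatrix,
        dosages: DosageMatrix,
        cov: CovariateSet | None,
        gene_id: str,
        window_bp: int,
        maf_min: float,
        extra_covariates: np.ndarray | None = None,
    ) -> None:
        self.gene_id = gene_id
        feats = expr.features_of_gene(gene_id)
        if not feats:
            raise KeyError(f"gene {gene_id!r} has no features")
        self.feature_ids = feats
        self.tss = expr.tss(gene_id)
        gene_rows = expr.annot[expr.annot["gene_id"] == gene_id]
        self.chrom = str(gene_rows["chrom"].iloc[0])
        self.strand = str(gene_rows["strand"].iloc[0]) if "strand" in gene_rows else "+"

        maf = dosages.maf
        mask = (
            (dosages.chrom == self.chrom)
            & (np.abs(dosages.pos - self.tss) <= window_bp)
            & (maf > maf_min)
        )
        self.var_idx = np.flatnonzero(mask)
        self.variant_ids = [dosages.variant_ids[i] for i in self.var_idx]
        self.pos = dosages.pos[self.var_idx]
        self.maf = maf[self.var_idx]
        sign = 1 if self.strand != "-" else -1
        self.tss_distance = (self.pos - self.tss) * sign

        E = expr.values.loc[feats].to_numpy(float)  # F x N
        G = dosages.dosages[self.var_idx]  # V x N
        n = E.shape[1]
        design = [np.ones(n)]
        k = 0
        if cov is not None:
            cmat, _ = cov.design()
            if cmat.shape[1]:
                design.append(cmat)
                k += cmat.shape[1]
        if extra_covariates is not None and np.size(extra_covariates):
            xc = np.atleast_2d(np.asarray(extra_covariates, float))
            if xc.shape[0] != n:
                xc = xc.T
            design.append(xc)
            k += xc.shape[1]
        C = np.column_stack(design)
        if np.linalg.matrix_rank(C) < C.shape[1]:
            raise ValueError("collinear covariate design for gene " + gene_id)
        self.q, _ = np.linalg.qr(C)
        self.df = n - k - 2
        if self.df <= 0:
            raise ValueError("non-positive residual degrees of freedom")

        self.Er = E - (E @ self.q) @ self.q.T
        Gr = G - (G @ self.q) @ self.q.T
        # variants collinear with covariates carry no testable residual signal
        g_ss = np.einsum("ij,ij->i", Gr, Gr)
        raw_ss = np.einsum("ij,ij->i", G - G.mean(1, keepdims=True), G - G.mean(1, keepdims=True))
        self.testable = g_ss > 1e-10 * np.maximum(raw_ss, 1e-30)
        e_ss = np.einsum("ij,ij->i", self.Er, self.Er)
        self.e_sd = np.sqrt(np.maximum(e_ss, 1e-300))
        self.g_sd = np.sqrt(np.maximum(g_ss, 1e-300))
        self.Es = self.Er / self.e_sd[:, None]
        self.Gs = np.where(self.testable[:, None], Gr / self.g_sd[:, None], 0.0)
        self.n = n

    @property
    def n_variants(self) -> int:
        return len(self.var_idx)

    def corr(self, Es: np.ndarray | None = None) -> np.ndarray:
        """F x V correlation matrix of residualized expression vs dosage."""
        Es = self.Es if Es is None else Es
        r = Es @ self.Gs.T
        return np.clip(r, -1.0, 1.0)


def _p_from_r(r: np.ndarray, df: int) -> np.ndarray:
    r2 = np.minimum(r * r, 1.0 - 1e-14)
    t = np.abs(r) * np.sqrt(df / (1.0 - r2))
    return 2.0 * stats.t.sf(t, df)


def nominal_scan(
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    cov: CovariateSet | None,
    gene_id: str,
    window_bp: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
    extra_covariates: np.ndarray | None = None,
) -> pd.DataFrame:
    """All feature x variant nominal associations for one gene.

    For each feature of the gene and each variant with MAF above
    ``maf_min`` within ``window_bp`` of the TSS, fits expression ~ dosage +
    covariates by OLS (via residualization on the covariates, which gives
    identical slopes) and reports slope, standard error and the two-sided
    t-test p-value on n - k - 2 degrees of freedom. Variants collinear with
    the covariates are skipped.
    """
    gd = _GeneData(expr, dosages, cov, gene_id, window_bp, maf_min, extra_covariates)
    if gd.n_variants == 0:
        log.info("gene %s: no variants in window", gene_id)
        return _empty_nominal()
    r = gd.corr()
    p = _p_from_r(r, gd.df)
    slope = r * (gd.e_sd[:, None] / gd.g_sd[None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.abs(r) * np.sqrt(gd.df / np.maximum(1.0 - r * r, 1e-14))
        se = np.where(t > 0, np.abs(slope) / t, np.nan)
    fi, vi = np.meshgrid(np.arange(len(gd.feature_ids)), np.arange(gd.n_variants), indexing="ij")
    out = pd.DataFrame(
        {
            "gene_id": gene_id,
            "feature_id": np.asarray(gd.feature_ids)[fi.ravel()],
            "variant_id": np.asarray(gd.variant_ids)[vi.ravel()],
            "tss_distance": gd.tss_distance[vi.ravel()],
            "maf": gd.maf[vi.ravel()],
            "slope": slope.ravel(),
            "se": se.ravel(),
            "p_nominal": p.ravel(),
        }
    )
    keep = np.tile(gd.testable, len(gd.feature_ids))
    return out.loc[keep].reset_index(drop=True)


def _empty_nominal() -> pd.DataFrame:
    return pd.DataFrame(
        columns=[
            "gene_id",
            "feature_id",
            "variant_id",
            "tss_distance",
            "maf",
            "slope",
            "se",
            "p_nominal",
        ]
    )


def permutation_pass(
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    cov: CovariateSet | None,
    gene_id: str,
    window_bp: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
    n_perm: int = N_PERM,
    seed: int | np.random.SeedSequence = 0,
    permute_residualized: bool = True,
    extra_covariates: np.ndarray | None = None,
) -> tuple[PermutationFit | None, pd.Series | None]:
    """Permutation-calibrated best association for one gene.

    Expression sample labels are permuted jointly across the gene's
    features while genotypes and covariates stay fixed; the minimum nominal
    p over all feature x variant pairs is recorded per permutation, a
    Beta(a, b) distribution is fitted to the minima by maximum likelihood,
    and the gene-level p is the fitted CDF at the observed minimum.

    With ``permute_residualized`` (default) the covariates are regressed
    out once and residual vectors are permuted; the exact mode re-fits the
    covariates within every permutation.

    Returns (fit, best_record) where best_record carries the observed best
    pair with ``p_beta`` and ``p_empirical`` added; (None, None) if the
    window has no testable variant.
    """
    if n_perm < 100:
        warnings.warn("n_perm < 100 gives an unstable beta fit", stacklevel=2)
    gd = _GeneData(expr, dosages, cov, gene_id, window_bp, maf_min, extra_covariates)
    if gd.n_variants == 0 or not gd.testable.any():
        log.info("gene %s: no testable variants in window", gene_id)
        return None, None

    r_obs = gd.corr()
    r_obs = np.where(gd.testable[None, :], r_obs, 0.0)
    p_obs = _p_from_r(r_obs, gd.df)

    rng = np.random.default_rng(seed)
    perms = np.argsort(rng.random((n_perm, gd.n)), axis=1)
    if permute_residualized:
        # permute residual vectors; covariates not re-fit (fast mode)
        max_abs_r = np.zeros(n_perm)
        for f in range(gd.Es.shape[0]):
            Ep = gd.Es[f][perms]  # n_perm x n
            r = np.abs(Ep @ gd.Gs.T)
            np.maximum(max_abs_r, r.max(axis=1), out=max_abs_r)
    else:
        E_raw = expr.values.loc[gd.feature_ids].to_numpy(float)
        max_abs_r = np.zeros(n_perm)
        for b in range(n_perm):
            Ep = E_raw[:, perms[b]]
            Ep = Ep - (Ep @ gd.q) @ gd.q.T
            sd = np.sqrt(np.maximum(np.einsum("ij,ij->i", Ep, Ep), 1e-300))
            r = np.abs((Ep / sd[:, None]) @ gd.Gs.T)
            max_abs_r[b] = r.max()
    max_abs_r = np.clip(max_abs_r, 0.0, 1.0 - 1e-14)
    perm_min_p = _p_from_r(max_abs_r, gd.df)

    a, b_, converged = fit_beta_ml(perm_min_p)
    fit = PermutationFit(
        n_perm=n_perm, beta_a=a, beta_b=b_, empirical_min_p=perm_min_p, converged=converged
    )

    obs_min = float(np.min(np.where(gd.testable[None, :], p_obs, np.inf)))
    best = _select_best(gd, r_obs, p_obs, obs_min)
    best["p_beta"] = fit.p_beta(obs_min)
    best["p_empirical"] = fit.p_empirical(obs_min)
    best["n_variants"] = gd.n_variants
    return fit, best


def _select_best(gd: _GeneData, r: np.ndarray, p: np.ndarray, p_min: float) -> pd.Series:
    """Best pair at the minimum p; ties broken by |tss_distance| then variant id."""
    fi, vi = np.where((p <= p_min) & gd.testable[None, :])
    if len(fi) > 1:
        order = sorted(
            range(len(fi)),
            key=lambda i: (abs(int(gd.tss_distance[vi[i]])), gd.variant_ids[vi[i]]),
        )
        fi, vi = fi[order[:1]], vi[order[:1]]
    f, v = int(fi[0]), int(vi[0])
    slope = r[f, v] * gd.e_sd[f] / gd.g_sd[v]
    r2 = min(r[f, v] ** 2, 1.0 - 1e-14)
    t = abs(r[f, v]) * np.sqrt(gd.df / (1.0 - r2))
    return pd.Series(
        {
            "gene_id": gd.gene_id,
            "feature_id": gd.feature_ids[f],
            "variant_id": gd.variant_ids[v],
            "tss_distance": int(gd.tss_distance[v]),
            "maf": float(gd.maf[v]),
            "slope": float(slope),
            "se": float(abs(slope) / t) if t > 0 else np.nan,
            "p_nominal": float(p[f, v]),
        }
    )


# ---------------------------------------------------------------------------
# beta approximation


def fit_beta_ml(x: np.ndarray, max_iter: int = 100, tol: float = 1e-10) -> tuple[float, float, bool]:
    """Fit Beta(a, b) by Newton maximum likelihood from a moments start.

    Returns (a, b, converged); on non-convergence or a degenerate Newton
    step the method-of-moments estimate is returned with converged=False.
    """
    x = np.clip(np.asarray(x, float), 1e-300, 1.0 - 1e-16)
    n = len(x)
    m, v = float(np.mean(x)), float(np.var(x))
    if v <= 0:
        return 1.0, 1.0, False
    c = m * (1.0 - m) / v - 1.0
    a = max(m * c, 1e-3)
    b = max((1.0 - m) * c, 1e-3)
    a_mom, b_mom = a, b
    slx = float(np.sum(np.log(x)))
    sl1x = float(np.sum(np.log1p(-x)))
    theta = np.array([a, b])
    for _ in range(max_iter):
        a, b = theta
        g = np.array(
            [
                n * (special.digamma(a + b) - special.digamma(a)) + slx,
                n * (special.digamma(a + b) - special.digamma(b)) + sl1x,
            ]
        )
        tri_ab = special.polygamma(1, a + b)
        h = n * np.array(
            [
                [tri_ab - special.polygamma(1, a), tri_ab],
                [tri_ab, tri_ab - special.polygamma(1, b)],
            ]
        )
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            log.info("beta ML Hessian singular; falling back to moments")
            return a_mom, b_mom, False
        new = theta - step
        if not np.all(np.isfinite(new)) or np.any(new <= 0):
            # damped step to stay in the positive orthant
            lam = 1.0
            while lam > 1e-6:
                lam *= 0.5
                new = theta - lam * step
                if np.all(np.isfinite(new)) and np.all(new > 0):
                    break
            else:
                log.info("beta ML left the feasible region; falling back to moments")
                return a_mom, b_mom, False
        if np.max(np.abs(new - theta)) < tol * (1.0 + np.max(np.abs(theta))):
            theta = new
            return float(theta[0]), float(theta[1]), True
        theta = new
    log.info("beta ML did not converge in %d iterations; falling back to moments", max_iter)
    return a_mom, b_mom, False


# ---------------------------------------------------------------------------
# Storey q-values


LAMBDA_GRID = np.round(np.arange(0.05, 0.951, 0.05), 2)


def storey_pi0(p: np.ndarray, lambdas: np.ndarray = LAMBDA_GRID) -> float:
    """Smoother estimate of the null proportion pi0.

    Computes pi0(lambda) = #{p > lambda} / (m (1 - lambda)) over the grid
    and extrapolates to lambda -> 1 with a cubic smoothing spline; the
    estimate is clipped to [0, 1].
    """
    p = np.asarray(p, float)
    m = len(p)
    raw = np.array([np.mean(p > lam) / (1.0 - lam) for lam in lambdas])
    if np.allclose(raw, raw[0]):
        pi0 = raw[-1]
    else:
        try:
            spline = UnivariateSpline(lambdas, raw, k=3)
            pi0 = float(spline(lambdas[-1]))
        except Exception:  # degenerate grid
            pi0 = float(raw[-1])
    return float(np.clip(pi0, 0.0, 1.0))


def qvalues(p: np.ndarray, pi0: float | None = None) -> np.ndarray:
    """Storey q-values; falls back to pi0 = 1 (plain BH) below 100 tests."""
    p = np.asarray(p, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return np.array([])
    if pi0 is None:
        if m < 100:
            log.info("fewer than 100 p-values: using pi0 = 1 (BH)")
            pi0 = 1.0
        else:
            pi0 = storey_pi0(p)
    pi0 = float(min(max(pi0, 1.0 / m), 1.0))
    order = np.argsort(p, kind="mergesort")
    ranked = p[order]
    q = pi0 * m * ranked / np.arange(1, m + 1)
    q = np.minimum.accumulate(q[::-1])[::-1]
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


# ---------------------------------------------------------------------------
# orchestration


def map_cis(
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    cov: CovariateSet | None = None,
    window_bp: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
    n_perm: int = N_PERM,
    seed: int = 0,
    permute_residualized: bool = True,
) -> pd.DataFrame:
    """Permutation pass over all genes plus genome-wide q-values.

    Returns one row per gene with the best feature x variant association,
    its beta-adjusted p-value and the Storey q-value across genes.
    Per-gene permutation seeds are spawned deterministically from ``seed``.
    """
    root = np.random.SeedSequence(seed)
    genes = expr.genes()
    children = root.spawn(len(genes))
    rows = []
    for gene_id, ss in zip(genes, children):
        _, best = permutation_pass(
            expr,
            dosages,
            cov,
            gene_id,
            window_bp=window_bp,
            maf_min=maf_min,
            n_perm=n_perm,
            seed=ss,
            permute_residualized=permute_residualized,
        )
        if best is not None:
            rows.append(best)
    if not rows:
        return pd.DataFrame()
    out = pd.DataFrame(rows).reset_index(drop=True)
    out["q_value"] = qvalues(out["p_beta"].to_numpy())
    return out


def nominal_table(
    expr: FeatureMatrix,
    dosages: DosageMatrix,
    cov: CovariateSet | None = None,
    window_bp: int = WINDOW_BP,
    maf_min: float = MAF_MIN,
) -> pd.DataFrame:
    """Full nominal feature x variant association table over all genes."""
    frames = [
        nominal_scan(expr, dosages, cov, g, window_bp=window_bp, maf_min=maf_min)
        for g in expr.genes()
    ]
    frames = [f for f in frames if len(f)]
    if not frames:
        return _empty_nominal()
    return pd.concat(frames, ignore_index=True)
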