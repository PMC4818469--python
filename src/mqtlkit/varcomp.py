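"""GRM construction and two-component REML variance partitioning.

Methylation variance is split as var(y) = var(g_cis) + var(g_trans) +
var(e) with g_c ~ N(0, sigma_c^2 * GRM_c); the cis GRM uses SNPs within
+/-1 Mb of the CpG and the trans GRM all remaining SNPs. The same machinery
partitions a 0/1 trait into an mQTL component and a rest-of-genome
component, with liability-scale transformation of the observed-scale
estimates.

The REML fitter is average-information (AI) REML with EM fallback on steps
that leave the parameter space or reduce the likelihood, components
clamped at a small positive floor, and standard errors from the inverse AI
matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.special import ndtri

from .datamodel import GenotypeDataset, VarianceDecomposition

logger = logging.getLogger(__name__)

DEFAULT_RELATEDNESS_METH = 0.05
DEFAULT_RELATEDNESS_TRAIT = 0.025
REML_TOL = 1e-6
REML_MAX_ITER = 100


@dataclass
class GRM:
    """Genomic relatedness matrix over a fixed sample set."""

    sample_ids: np.ndarray
    matrix: np.ndarray
    n_snps_used: int

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise ValueError("GRM must be symmetric")


def compute_grm(geno: GenotypeDataset, snp_subset=None) -> GRM:
    """G_ij = (1/m) sum_k (x_ik - 2 p_k)(x_jk - 2 p_k) / (2 p_k (1 - p_k)),
    with p_k the sample allele frequency; missing dosages mean-imputed
    before centering; monomorphic SNPs skipped with a warning."""
    if snp_subset is None:
        idx = np.arange(geno.n_snps)
    else:
        idx = np.asarray(snp_subset)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        elif idx.dtype == object or idx.dtype.kind in "US":
            idx = geno.snp_index(idx)
    if len(idx) == 0:
        raise ValueError("empty SNP subset")
    D = geno.dosage[:, idx].astype(float)
    mean = np.nanmean(D, axis=0)
    mask = ~np.isfinite(D)
    if mask.any():
        D[mask] = np.take(mean, np.nonzero(mask)[1])
    p = D.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        logger.warning("compute_grm: skipping %d monomorphic SNPs", int((~poly).sum()))
        D, p = D[:, poly], p[poly]
    if D.shape[1] == 0:
        raise ValueError("no polymorphic SNPs in subset")
    Z = (D - 2 * p) / np.sqrt(2 * p * (1 - p))
    m = Z.shape[1]
    return GRM(sample_ids=geno.sample_ids, matrix=(Z @ Z.T) / m, n_snps_used=m)


def filter_unrelated(grm: GRM, threshold: float = DEFAULT_RELATEDNESS_METH) -> np.ndarray:
    """Greedy unrelated-subset selection.

    While any off-diagonal relatedness >= threshold remains, drop the
    sample involved in the most such pairs (ties broken by lexicographic
    sample id). Returns the retained sample ids.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    A = grm.matrix.copy()
    np.fill_diagonal(A, 0.0)
    active = np.ones(len(grm.sample_ids), dtype=bool)
    ids = grm.sample_ids
    while True:
        related = (A >= threshold) & active[:, None] & active[None, :]
        counts = related.sum(axis=1)
        if counts.max(initial=0) == 0:
            break
        worst = counts.max()
        tied = np.flatnonzero(counts == worst)
        drop = tied[np.argsort([str(ids[i]) for i in tied])[0]]
        active[drop] = False
    return ids[active]


# ---------------------------------------------------------------------------
# REML


def restricted_loglik(y: np.ndarray, X: np.ndarray, grms: list, sigmas: np.ndarray) -> float:
    """Restricted log-likelihood of y = X beta + sum_c g_c + e at the given
    variance components (residual last), up to an additive constant."""
    n = len(y)
    V = sigmas[-1] * np.eye(n)
    for s, A in zip(sigmas[:-1], grms):
        V = V + s * A
    try:
        c, low = linalg.cho_factor(V, lower=True, check_finite=False)
    except linalg.LinAlgError:
        return -np.inf
    logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
    Vi_y = linalg.cho_solve((c, low), y, check_finite=False)
    Vi_X = linalg.cho_solve((c, low), X, check_finite=False)
    XtViX = X.T @ Vi_X
    sign, logdet_X = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return -np.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    yPy = float(y @ Vi_y - (X.T @ Vi_y) @ beta)
    return -0.5 * (logdet_V + logdet_X + yPy)


def reml_two_component(
    y: np.ndarray,
    X_covariates: np.ndarray | None,
    grm_1: GRM | np.ndarray,
    grm_2: GRM | np.ndarray,
    tol: float = REML_TOL,
    max_iter: int = REML_MAX_ITER,
    name: str = "",
    timepoint: str = "",
) -> VarianceDecomposition:
    """AI-REML fit of the two-GRM model.

    Components are clamped at a small positive floor and re-activated when
    the gradient points inward; an EM step replaces any AI step that leaves
    the parameter space or decreases the restricted likelihood. Standard
    errors come from the inverse average-information matrix (infinite when
    the AI matrix is numerically singular, e.g. identical GRMs).
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    A1 = grm_1.matrix if isinstance(grm_1, GRM) else np.asarray(grm_1, dtype=float)
    A2 = grm_2.matrix if isinstance(grm_2, GRM) else np.asarray(grm_2, dtype=float)
    if X_covariates is None:
        X = np.ones((n, 1))
    else:
        X = np.asarray(X_covariates, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if not np.any(np.all(X == X[0], axis=0)):
            X = np.column_stack([np.ones(n), X])
    if n <= X.shape[1] + 2:
        raise ValueError("n must exceed the covariate count plus 2")

    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("response has zero variance")
    floor = 1e-8 * vy
    sig = np.array([vy / 3, vy / 3, vy / 3])
    mats = [A1, A2, np.eye(n)]
    # an all-zero GRM contributes nothing: pin its component at the floor
    zero_comp = np.array([not A1.any(), not A2.any(), False])
    sig[zero_comp] = floor

    def _parts(s):
        V = s[0] * A1 + s[1] * A2 + s[2] * np.eye(n)
        try:
            c, low = linalg.cho_factor(V, lower=True, check_finite=False)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular covariance at current components; add jitter to the GRMs"
            ) from exc
        logdet_V = 2.0 * np.sum(np.log(np.diag(c)))
        Vi = linalg.cho_solve((c, low), np.eye(n), check_finite=False)
        Vi_X = Vi @ X
        XtViX = X.T @ Vi_X
        XtViX_inv = np.linalg.inv(XtViX)
        P = Vi - Vi_X @ XtViX_inv @ Vi_X.T
        Py = P @ y
        sign, logdet_X = np.linalg.slogdet(XtViX)
        ll = -0.5 * (logdet_V + logdet_X + float(y @ Py))
        return P, Py, ll

    P, Py, ll = _parts(sig)
    converged = False
    it = 0
    ai_inv = None
    for it in range(1, max_iter + 1):
        trPA = np.array([float(np.sum(P * A)) for A in mats])
        APy = [A @ Py for A in mats]
        yPAPy = np.array([float(Py @ w) for w in APy])
        grad = -0.5 * (trPA - yPAPy)
        PAPy = [P @ w for w in APy]
        AI = 0.5 * np.array([[float(APy[i] @ PAPy[j]) for j in range(3)] for i in range(3)])

        # components stuck at the floor with outward gradient stay clamped
        free = ~((sig <= floor * (1 + 1e-9)) & (grad < 0)) & ~zero_comp
        step = np.zeros(3)
        try:
            step[free] = np.linalg.solve(AI[np.ix_(free, free)], grad[free])
        except np.linalg.LinAlgError:
            step[free] = grad[free] / np.maximum(np.diag(AI)[free], 1e-12)
        new = np.maximum(sig + step, floor)
        try:
            P_new, Py_new, ll_new = _parts(new)
        except ValueError:
            ll_new = -np.inf
        if not np.isfinite(ll_new) or ll_new < ll - 1e-10:
            # EM fallback
            new = np.maximum(sig + (sig**2 / n) * (yPAPy - trPA), floor)
            P_new, Py_new, ll_new = _parts(new)
        delta = ll_new - ll
        sig, P, Py, ll = new, P_new, Py_new, ll_new
        try:
            ai_inv = np.linalg.inv(AI)
        except np.linalg.LinAlgError:
            ai_inv = None
        if abs(delta) < tol:
            converged = True
            break

    if ai_inv is not None and np.all(np.isfinite(ai_inv)) and np.linalg.cond(AI) < 1e12:
        se = np.sqrt(np.maximum(np.diag(ai_inv), 0.0))
    else:
        se = np.full(3, np.inf)
        logger.warning("%s: AI matrix singular — non-identifiable components", name or "reml")

    return VarianceDecomposition(
        name=name, timepoint=timepoint,
        v_cis=float(max(sig[0], 0.0)), v_trans=float(max(sig[1], 0.0)), v_resid=float(max(sig[2], 0.0)),
        se_cis=float(se[0]), se_trans=float(se[1]),
        converged=converged, n_iterations=it,
    )


# ---------------------------------------------------------------------------
# probe / trait partitions


def cis_trans_snp_split(geno: GenotypeDataset, probe_chrom, probe_pos: int, window_bp: int = 1_000_000, tag_only: bool = False):
    """(cis_idx, trans_idx) under the +/-window rule, optionally restricted
    to the tagging SNP subset."""
    same = np.array([str(c) == str(probe_chrom) for c in geno.chrom])
    cis = same & (np.abs(geno.pos_bp - int(probe_pos)) <= window_bp)
    pool = geno.tag_set_flag if tag_only else np.ones(geno.n_snps, dtype=bool)
    return np.flatnonzero(cis & pool), np.flatnonzero(~cis & pool)


def partition_probe_variance(
    probe_residuals: np.ndarray,
    geno: GenotypeDataset,
    probe_chrom,
    probe_pos: int,
    window_bp: int = 1_000_000,
    tag_only: bool = False,
    explained_cis: float = np.nan,
    explained_trans: float = np.nan,
    name: str = "",
    timepoint: str = "",
    grm_trans: GRM | None = None,
    grm_all: GRM | None = None,
) -> VarianceDecomposition:
    """Two-GRM REML partition of one probe's residual variance.

    ``explained_cis`` / ``explained_trans`` (sum of marginal r^2 of
    conditionally independent signals) are recorded as supplied. Passing a
    precomputed whole-genome ``grm_all`` lets the trans GRM be formed by
    subtracting the cis contribution, which is much cheaper per probe.
    """
    cis_idx, trans_idx = cis_trans_snp_split(geno, probe_chrom, probe_pos, window_bp, tag_only)
    if len(cis_idx) == 0:
        logger.warning("%s: no cis SNPs within +/-%d bp; v_cis fixed at 0", name, window_bp)
        g2 = grm_trans or compute_grm(geno, trans_idx)
        zero = GRM(g2.sample_ids, np.zeros_like(g2.matrix), 0)
        out = reml_two_component(probe_residuals, None, zero, g2, name=name, timepoint=timepoint)
    else:
        g1 = compute_grm(geno, cis_idx)
        if grm_all is not None:
            m_all, m_cis = grm_all.n_snps_used, g1.n_snps_used
            trans_mat = (m_all * grm_all.matrix - m_cis * g1.matrix) / (m_all - m_cis)
            g2 = GRM(grm_all.sample_ids, (trans_mat + trans_mat.T) / 2, m_all - m_cis)
        else:
            g2 = grm_trans or compute_grm(geno, trans_idx)
        out = reml_two_component(probe_residuals, None, g1, g2, name=name, timepoint=timepoint)
    out.explained_cis = explained_cis
    out.explained_trans = explained_trans
    return out


def liability_transform(h2_observed: float, K: float, P: float) -> float:
    """Observed-scale to liability-scale heritability for an ascertained
    case-control sample: h2_liab = h2_obs * K^2 (1-K)^2 / (z^2 P (1-P)),
    with z the standard normal density at the threshold Phi^-1(1-K)."""
    if not (0 < K < 1 and 0 < P < 1):
        raise ValueError("K and P must lie in (0, 1)")
    z = stats.norm.pdf(ndtri(1 - K))
    return float(h2_observed * K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P)))


def partition_trait_variance(
    trait01: pd.Series,
    geno: GenotypeDataset,
    mqtl_snp_set,
    covariates: np.ndarray | None = None,
    exclude_chroms=("6",),
    prevalence: float | None = None,
    name: str = "trait",
) -> tuple:
    """Two-GRM REML on a 0/1 trait: one component for mQTL SNPs, one for the
    remaining tagging SNPs, both excluding ``exclude_chroms`` (MHC by
    default). Returns ``(decomposition, liability)`` where ``liability``
    maps each component's observed-scale h2 to the liability scale using
    the population prevalence and the sample case proportion.
    """
    mqtl_ids = set(mqtl_snp_set)
    keep_chrom = ~np.isin(np.array([str(c) for c in geno.chrom]), [str(c) for c in exclude_chroms])
    in_mqtl = np.array([s in mqtl_ids for s in geno.snp_ids])
    set1 = np.flatnonzero(in_mqtl & keep_chrom)
    set2 = np.flatnonzero(~in_mqtl & keep_chrom & geno.tag_set_flag)
    if len(set1) == 0:
        raise ValueError("mQTL SNP set empty after chromosome exclusions")
    if len(set2) == 0:
        raise ValueError("complement SNP set empty after chromosome exclusions")
    status = trait01.reindex(geno.sample_ids).dropna()
    sub = geno.subset_samples(np.array([s in set(status.index) for s in geno.sample_ids]))
    y = status.reindex(sub.sample_ids).to_numpy(dtype=float)
    g1 = compute_grm(sub, set1)
    g2 = compute_grm(sub, set2)
    decomp = reml_two_component(y, covariates, g1, g2, name=name)
    P_obs = float(y.mean())
    K = prevalence if prevalence is not None else P_obs
    liability = {
        "h2_liab_mqtl": liability_transform(decomp.h2_cis, K, P_obs),
        "h2_liab_rest": liability_transform(decomp.h2_trans, K, P_obs),
        "K": K,
        "P": P_obs,
    }
    return decomp, liability


def h2_age_regression(decompositions, ages: dict) -> tuple:
    """Pooled OLS of per-probe total SNP heritability on timepoint age.

    ``ages`` maps timepoint label to age in years. Returns (slope per
    year, se).
    """
    rows = [(ages[d.timepoint], d.h2_total) for d in decompositions if d.timepoint in ages]
    if len({a for a, _ in rows}) < 2:
        raise ValueError("need decompositions at >= 2 distinct ages")
    x = np.array([a for a, _ in rows])
    h = np.array([v for _, v in rows])
    X = np.column_stack([np.ones(len(x)), x])
    coef, *_ = np.linalg.lstsq(X, h, rcond=None)
    resid = h - X @ coef
    df = len(x) - 2
    sigma2 = float(resid @ resid) / max(df, 1)
    cov = sigma2 * np.linalg.inv(X.T @ X)
    return float(coef[1]), float(np.sqrt(cov[1, 1]))
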