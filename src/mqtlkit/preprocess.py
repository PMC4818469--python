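"""QC filtering, rank normalization, covariate residualization, ancestry PCs.

The analysis-ready methylation object is produced by rank-normalising each
probe (Blom offsets), then regressing on covariates and carrying the
residuals forward to the association scan — in that order, with an exact
per-pair refit available downstream.
"""

from __future__ import annotations

import logging
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .datamodel import GenotypeDataset, MethylationDataset, ProbeAnnotation

logger = logging.getLogger(__name__)

DEFAULT_MAF_MIN = 0.01
DEFAULT_HWE_P_MIN = 5e-7
DEFAULT_MISSING_MAX = 0.03
DEFAULT_N_PCS = 10


# ---------------------------------------------------------------------------
# SNP QC


def hwe_exact_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg test p-value (sum of genotype probabilities no
    more likely than observed, conditional on allele counts)."""
    if n_hom_minor > n_hom_major:
        n_hom_minor, n_hom_major = n_hom_major, n_hom_minor
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n == 0 or n_minor == 0:
        return 1.0
    # recurrence over possible heterozygote counts with fixed allele counts
    het_max = min(n_minor, 2 * n - n_minor)
    hets = np.arange(n_minor % 2, het_max + 1, 2)
    logp = np.zeros(len(hets))
    for i in range(1, len(hets)):
        h = hets[i]
        # P(h) / P(h-2) = (hom_minor(h-2) * hom_major(h-2) * 4) / (h*(h-1))
        hm = (n_minor - (h - 2)) // 2
        hM = n - (h - 2) - hm
        logp[i] = logp[i - 1] + np.log(4.0 * hm * hM) - np.log(float(h * (h - 1)))
    logp -= logp.max()
    prob = np.exp(logp)
    prob /= prob.sum()
    observed = prob[hets == n_het]
    if observed.size == 0:
        return 1.0
    return float(min(1.0, prob[prob <= observed[0] * (1 + 1e-12)].sum()))


def hwe_chi2_p(n_het: int, n_hom_minor: int, n_hom_major: int) -> float:
    """1-df chi-square Hardy-Weinberg test."""
    n = n_het + n_hom_minor + n_hom_major
    if n == 0:
        return 1.0
    p = (2 * n_hom_minor + n_het) / (2 * n)
    q = 1 - p
    expected = np.array([n * q * q, 2 * n * p * q, n * p * p])
    observed = np.array([n_hom_major, n_het, n_hom_minor])
    if np.any(expected <= 0):
        return 1.0
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(chi2, df=1))


def _genotype_counts(dosage_col: np.ndarray):
    """(n_het, n_hom_minor, n_hom_major) from hard-called dosages."""
    d = dosage_col[np.isfinite(dosage_col)]
    g = np.rint(d).astype(int)
    n2 = int((g == 2).sum())
    n1 = int((g == 1).sum())
    n0 = int((g == 0).sum())
    if n2 > n0:  # orient so that "2" is the minor homozygote
        n0, n2 = n2, n0
    return n1, n2, n0


def qc_filter_snps(
    geno: GenotypeDataset,
    maf_min: float = DEFAULT_MAF_MIN,
    hwe_p_min: float = DEFAULT_HWE_P_MIN,
    missing_max: float = DEFAULT_MISSING_MAX,
    diff_missing_p: float | None = None,
    case_status: pd.Series | None = None,
) -> GenotypeDataset:
    """Remove SNPs failing MAF, Hardy-Weinberg, missingness and (optionally)
    case/control differential-missingness filters.

    The exact HWE test is used below 1,000 samples, chi-square above.
    """
    n, m = geno.dosage.shape
    keep = np.ones(m, dtype=bool)
    removed = {}

    maf = geno.computed_maf()
    fail_maf = ~(maf >= maf_min)
    removed["maf"] = int(fail_maf.sum())
    keep &= ~fail_maf

    miss = np.mean(~np.isfinite(geno.dosage), axis=0)
    fail_miss = miss > missing_max
    removed["missingness"] = int(fail_miss.sum())
    keep &= ~fail_miss

    hwe_fn = hwe_exact_p if n < 1000 else hwe_chi2_p
    fail_hwe = np.zeros(m, dtype=bool)
    for k in np.flatnonzero(keep):
        p = hwe_fn(*_genotype_counts(geno.dosage[:, k]))
        if p < hwe_p_min:
            fail_hwe[k] = True
    removed["hwe"] = int(fail_hwe.sum())
    keep &= ~fail_hwe

    if diff_missing_p is not None and case_status is not None:
        status = case_status.reindex(geno.sample_ids).to_numpy()
        is_case = status == 1
        fail_dm = np.zeros(m, dtype=bool)
        miss_mat = ~np.isfinite(geno.dosage)
        for k in np.flatnonzero(keep):
            table = np.array(
                [
                    [miss_mat[is_case, k].sum(), (~miss_mat[is_case, k]).sum()],
                    [miss_mat[~is_case, k].sum(), (~miss_mat[~is_case, k]).sum()],
                ]
            )
            if table[:, 0].sum() == 0:
                continue
            _, p, _, _ = stats.chi2_contingency(table, correction=False)
            if p < diff_missing_p:
                fail_dm[k] = True
        removed["differential_missingness"] = int(fail_dm.sum())
        keep &= ~fail_dm

    logger.info("SNP QC removal counts: %s", removed)
    if not keep.any():
        raise ValueError("all SNPs removed by QC filters")
    out = geno.subset_snps(keep)
    return replace(out, maf=out.computed_maf())


def qc_filter_probes(
    meth: MethylationDataset, manifest: ProbeAnnotation, drop_flags=frozenset({"multi_mapping", "snp_at_cpg"})
) -> MethylationDataset:
    """Drop probes whose QC flags intersect ``drop_flags``.

    ``potentially_problematic`` probes are retained by default (post hoc
    annotation rather than removal).
    """
    drop_flags = frozenset(drop_flags)
    keep = np.array(
        [not (manifest.flags_of(p) & drop_flags) for p in meth.probe_ids], dtype=bool
    )
    logger.info("probe QC: %d of %d probes retained", int(keep.sum()), meth.n_probes)
    return meth.subset_probes(keep)


# ---------------------------------------------------------------------------
# rank normalization


def rank_normalize(values: np.ndarray) -> np.ndarray:
    """Blom rank-based inverse-normal transform.

    Maps value with (average, tie-aware) rank r among n to
    ``ndtri((r - 3/8) / (n + 1/4))``.
    """
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    x = v[finite]
    if x.size < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.ptp(x) == 0:
        raise ValueError("cannot rank-normalize a constant vector")
    ranks = stats.rankdata(x, method="average")
    out = np.full_like(v, np.nan)
    out[finite] = ndtri((ranks - 0.375) / (x.size + 0.25))
    return out


def rank_normalize_probes(meth: MethylationDataset) -> MethylationDataset:
    values = np.vstack([rank_normalize(row) for row in meth.values])
    return replace(meth, values=values, scale_tag="rank_normal_residual")


# ---------------------------------------------------------------------------
# covariate residualization


def covariate_design(cov: pd.DataFrame, categorical=("batch",), simplex_prefixes=("cell_",)) -> pd.DataFrame:
    """Intercept + numeric covariates + dummy-coded categoricals, with
    constant columns dropped. Raises on a rank-deficient design, naming the
    collinear columns.

    Column groups named by a ``simplex_prefixes`` prefix whose rows sum to
    a constant (cell proportions) lose their last column, since the group
    is otherwise collinear with the intercept.
    """
    cov = cov.copy()
    for prefix in simplex_prefixes:
        group = [c for c in cov.columns if str(c).startswith(prefix)]
        if len(group) >= 2 and np.allclose(np.ptp(cov[group].sum(axis=1)), 0, atol=1e-6):
            cov = cov.drop(columns=group[-1])
    parts = [pd.Series(1.0, index=cov.index, name="intercept")]
    for col in cov.columns:
        if col in categorical:
            dummies = pd.get_dummies(cov[col], prefix=col, drop_first=True, dtype=float)
            parts.extend(dummies[c] for c in dummies.columns)
        else:
            parts.append(cov[col].astype(float))
    X = pd.concat(parts, axis=1)
    variable = [c for c in X.columns if c == "intercept" or X[c].nunique() > 1]
    X = X[variable]
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offenders: columns whose removal restores full rank
        collinear = []
        for c in X.columns:
            if c == "intercept":
                continue
            if np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy()) == rank:
                collinear.append(c)
        raise ValueError(f"rank-deficient covariate design; collinear columns: {collinear}")
    return X


def residualize(
    meth: MethylationDataset, covariates: pd.DataFrame, extra_terms: pd.DataFrame | None = None
) -> MethylationDataset:
    """OLS-residualize every probe on the covariate design.

    Missing methylation values are set to the probe mean first. The output
    carries ``scale_tag='rank_normal_residual'`` and residuals are
    orthogonal to the design to numerical precision.
    """
    cov = covariates.reindex(meth.sample_ids)
    if cov.isna().any().any():
        missing = cov.index[cov.isna().any(axis=1)].tolist()
        raise ValueError(f"covariate rows missing for samples: {missing[:5]}")
    X = covariate_design(cov)
    if extra_terms is not None:
        X = pd.concat([X, extra_terms.reindex(meth.sample_ids)], axis=1)
    Xm = X.to_numpy(dtype=float)

    Y = meth.values.copy()
    row_means = np.nanmean(Y, axis=1)
    nan_mask = ~np.isfinite(Y)
    if nan_mask.any():
        Y[nan_mask] = np.take(row_means, np.nonzero(nan_mask)[0])

    Q, _ = np.linalg.qr(Xm)
    resid = Y - (Y @ Q) @ Q.T
    return replace(meth, values=resid, scale_tag="rank_normal_residual")


def prepare_residuals(meth: MethylationDataset, covariates: pd.DataFrame) -> MethylationDataset:
    """Pipeline default: rank-normalize each probe, then residualize."""
    return residualize(rank_normalize_probes(meth), covariates)


# ---------------------------------------------------------------------------
# ancestry principal components


def _standardize_dosage(dosage: np.ndarray) -> np.ndarray:
    d = dosage.copy()
    col_mean = np.nanmean(d, axis=0)
    nan_mask = ~np.isfinite(d)
    if nan_mask.any():
        d[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    d -= col_mean
    sd = d.std(axis=0)
    sd[sd == 0] = 1.0
    return d / sd


def ld_prune_positional(geno: GenotypeDataset, r2_max: float = 0.2, window_bp: int = 1_000_000) -> np.ndarray:
    """Greedy positional LD pruning: walk SNPs in map order, keep a SNP iff
    its r^2 with every kept SNP within ``window_bp`` is <= ``r2_max``.
    Returns kept SNP indices."""
    Z = _standardize_dosage(geno.dosage)
    n = Z.shape[0]
    kept: list = []
    for k in range(geno.n_snps):
        ok = True
        for j in reversed(kept):
            if geno.chrom[j] != geno.chrom[k] or geno.pos_bp[k] - geno.pos_bp[j] > window_bp:
                break
            r = float(Z[:, j] @ Z[:, k]) / n
            if r * r > r2_max:
                ok = False
                break
        if ok:
            kept.append(k)
    return np.array(kept, dtype=int)


def compute_ancestry_pcs(
    geno: GenotypeDataset,
    n_pcs: int = DEFAULT_N_PCS,
    outlier_sd: float = 5.0,
    outlier_rounds: int = 0,
    prune_r2: float = 0.2,
) -> pd.DataFrame:
    """PCs of the standardized, LD-pruned dosage matrix with optional
    iterative outlier removal (samples beyond ``outlier_sd`` SDs in any
    component dropped, PCs recomputed each round).

    Removed samples get NaN rows in the returned frame.
    """
    if n_pcs > min(geno.n_samples, geno.n_snps):
        raise ValueError("n_pcs exceeds matrix rank bound")
    kept_snps = ld_prune_positional(geno, r2_max=prune_r2)
    Z_all = _standardize_dosage(geno.dosage[:, kept_snps])
    active = np.arange(geno.n_samples)
    for round_ in range(outlier_rounds + 1):
        Z = Z_all[active]
        Z = Z - Z.mean(axis=0)
        U, S, _ = np.linalg.svd(Z, full_matrices=False)
        pcs = U[:, :n_pcs]
        if round_ == outlier_rounds:
            break
        sd = pcs.std(axis=0)
        mean = pcs.mean(axis=0)
        outlier = (np.abs(pcs - mean) > outlier_sd * sd).any(axis=1)
        if not outlier.any():
            break
        active = active[~outlier]
    out = pd.DataFrame(
        np.nan, index=pd.Index(geno.sample_ids, name="sample_id"),
        columns=[f"PC{i+1}" for i in range(n_pcs)],
    )
    out.iloc[active] = pcs
    return out
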