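"""QC filters, rank normalization, residualization and ancestry PCs."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import ndtri

from mqtlkit import preprocess as pp
from mqtlkit import simulate as sim


# ---------------------------------------------------------------------------
# Hardy-Weinberg


def _hwe_exact_bruteforce(n_het, n_hom_minor, n_hom_major):
    """Enumeration oracle: P(het=h | allele counts) via log-factorials."""
    n = n_het + n_hom_minor + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    if n_minor > n:  # orient to true minor allele
        n_minor = 2 * n - n_minor
        n_hom_minor, n_hom_major = n_hom_major, n_hom_minor
    def logprob(h):
        hm = (n_minor - h) // 2
        hM = n - h - hm
        return (
            math.lgamma(n + 1) - math.lgamma(hm + 1) - math.lgamma(h + 1) - math.lgamma(hM + 1)
            + h * math.log(2)
            + math.lgamma(n_minor + 1) + math.lgamma(2 * n - n_minor + 1) - math.lgamma(2 * n + 1)
        )
    hs = list(range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2))
    probs = {h: math.exp(logprob(h)) for h in hs}
    obs = probs[n_het]
    return sum(p for p in probs.values() if p <= obs * (1 + 1e-12))


@pytest.mark.parametrize(
    "counts", [(50, 25, 25), (100, 0, 0), (10, 45, 45), (3, 1, 96), (0, 50, 50)]
)
def test_hwe_exact_matches_enumeration_oracle(counts):
    assert pp.hwe_exact_p(*counts) == pytest.approx(
        _hwe_exact_bruteforce(*counts), rel=1e-9
    )


def test_hwe_chi2_perfect_equilibrium():
    assert pp.hwe_chi2_p(50, 25, 25) == pytest.approx(1.0)


def test_hwe_all_heterozygotes_extreme():
    # 100 hets, 0 homs: expected (25,50,25) under HWE -> chi2 = 100, p << 1e-7
    assert pp.hwe_chi2_p(100, 0, 0) < 1e-7
    assert pp.hwe_exact_p(100, 0, 0) < 1e-7


def test_qc_filter_snps_thresholds(small_geno):
    rng = np.random.default_rng(0)
    n = small_geno.n_samples
    d = small_geno.dosage.copy()
    # SNP 0: rare (MAF ~ 0.005); SNP 1: all hets; SNP 2: 10% missing
    d[:, 0] = 0.0
    d[rng.choice(n, 3, replace=False), 0] = 1.0
    d[:, 1] = 1.0
    d[:, 2] = small_geno.dosage[:, 2]
    d[rng.choice(n, int(0.1 * n), replace=False), 2] = np.nan
    g = dataclasses.replace(small_geno, dosage=d)
    out = pp.qc_filter_snps(g, maf_min=0.01, hwe_p_min=5e-7, missing_max=0.03)
    kept = set(out.snp_ids)
    for k in (0, 1, 2):
        assert small_geno.snp_ids[k] not in kept
    assert out.n_snps >= small_geno.n_snps - 6  # the rest mostly survive


def test_qc_filter_all_removed_raises(small_geno):
    with pytest.raises(ValueError, match="all SNPs removed"):
        pp.qc_filter_snps(small_geno, maf_min=0.6)


def test_qc_filter_probes_counts_and_set_semantics(cohort_bundle):
    manifest = cohort_bundle["manifest"].table.copy()
    meth = cohort_bundle["meth"]["birth"]
    manifest["qc_flags"] = ""
    manifest.iloc[0, manifest.columns.get_loc("qc_flags")] = "multi_mapping"
    manifest.iloc[1, manifest.columns.get_loc("qc_flags")] = "multi_mapping,snp_at_cpg"
    manifest.iloc[2, manifest.columns.get_loc("qc_flags")] = "potentially_problematic"
    from mqtlkit.datamodel import ProbeAnnotation

    annot = ProbeAnnotation(manifest)
    out = pp.qc_filter_probes(meth, annot, drop_flags={"multi_mapping", "snp_at_cpg"})
    # both flagged probes go (the doubly flagged one counted once)
    assert out.n_probes == meth.n_probes - 2
    # potentially_problematic retained by default
    assert manifest.index[2] in set(out.probe_ids)
    # empty drop set is the identity
    assert pp.qc_filter_probes(meth, annot, drop_flags=set()).n_probes == meth.n_probes


# ---------------------------------------------------------------------------
# rank normalization


def test_rank_normalize_blom_oracle():
    out = pp.rank_normalize(np.array([1.2, 3.4, 2.2]))
    expected = ndtri((np.array([1, 3, 2]) - 0.375) / 3.25)
    np.testing.assert_allclose(out, expected, atol=1e-12)
    np.testing.assert_allclose(out, [-0.8694, 0.8694, 0.0], atol=5e-5)


def test_rank_normalize_monotone_invariance():
    rng = np.random.default_rng(1)
    x = rng.normal(size=200)
    np.testing.assert_allclose(
        pp.rank_normalize(x), pp.rank_normalize(np.exp(3 * x + 1)), atol=1e-12
    )


def test_rank_normalize_ties_share_value():
    out = pp.rank_normalize(np.array([1.0, 2.0, 5.0, 5.0]))
    assert out[2] == out[3]
    assert abs(out.mean()) < 1e-12 + abs(out[0] + out[1] + 2 * out[2]) / 4


def test_rank_normalize_rejects_degenerate():
    with pytest.raises(ValueError):
        pp.rank_normalize(np.array([1.0, 1.0, 1.0]))
    with pytest.raises(ValueError):
        pp.rank_normalize(np.array([1.0, 2.0]))


# ---------------------------------------------------------------------------
# residualization


def test_residualize_intercept_only_centres(cohort_bundle):
    meth = cohort_bundle["meth"]["birth"]
    cov = pd.DataFrame(index=pd.Index(meth.sample_ids, name="sample_id"))
    out = pp.residualize(meth, cov)
    np.testing.assert_allclose(
        out.values, meth.values - meth.values.mean(axis=1, keepdims=True), atol=1e-10
    )


def test_residualize_perfect_fit_gives_zero(cohort_bundle):
    meth = cohort_bundle["meth"]["birth"]
    rng = np.random.default_rng(2)
    age = rng.normal(size=meth.n_samples)
    vals = np.outer(rng.normal(size=meth.n_probes), age) + 5.0
    m = dataclasses.replace(meth, values=vals, scale_tag="rank_normal_residual")
    cov = pd.DataFrame({"age": age}, index=pd.Index(meth.sample_ids, name="sample_id"))
    out = pp.residualize(m, cov)
    assert np.abs(out.values).max() < 1e-8


def test_residuals_orthogonal_to_cell_proportions(cohort_bundle, childhood_residuals):
    cov = cohort_bundle["cov"]["childhood"]
    resid = childhood_residuals["resid"]
    for c in [c for c in cov.columns if c.startswith("cell_")][:-1]:
        x = cov[c].reindex(resid.sample_ids).to_numpy()
        x = x - x.mean()
        proj = resid.values @ x / np.linalg.norm(x)
        assert np.abs(proj).max() / np.sqrt(resid.n_samples) < 1e-8


def test_residualize_rank_deficient_names_columns(cohort_bundle):
    meth = cohort_bundle["meth"]["birth"]
    rng = np.random.default_rng(3)
    a = rng.normal(size=meth.n_samples)
    cov = pd.DataFrame(
        {"a": a, "b": 2 * a}, index=pd.Index(meth.sample_ids, name="sample_id")
    )
    with pytest.raises(ValueError, match="collinear"):
        pp.residualize(meth, cov)


# ---------------------------------------------------------------------------
# ancestry PCs


def test_pcs_separate_two_subpopulations():
    rng = np.random.default_rng(4)
    n, m = 200, 120
    # divergent allele frequencies between two groups
    p1, p2 = rng.uniform(0.1, 0.5, m), None
    p2 = np.clip(p1 + rng.choice([-0.3, 0.3], m), 0.05, 0.95)
    d1 = rng.binomial(2, p1, size=(n // 2, m)).astype(float)
    d2 = rng.binomial(2, p2, size=(n // 2, m)).astype(float)
    g = sim.simulate_genotypes(n, n_blocks=12, snps_per_block=10, ld_rho=0.0, seed=5)
    g = dataclasses.replace(g, dosage=np.vstack([d1, d2]))
    pcs = pp.compute_ancestry_pcs(g, n_pcs=4)
    label = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    r = np.corrcoef(pcs["PC1"], label)[0, 1]
    assert abs(r) > 0.9


def test_pcs_orthonormal_and_no_outlier_removal(small_geno):
    pcs = pp.compute_ancestry_pcs(small_geno, n_pcs=5, outlier_rounds=0)
    M = pcs.to_numpy()
    assert not np.isnan(M).any()  # no samples removed
    np.testing.assert_allclose(M.T @ M, np.eye(5), atol=1e-8)


def test_pcs_npcs_validation(small_geno):
    with pytest.raises(ValueError):
        pp.compute_ancestry_pcs(small_geno, n_pcs=10_000)


def test_qc_filters_order_independent(small_geno):
    a = pp.qc_filter_snps(small_geno, maf_min=0.1, hwe_p_min=1e-10, missing_max=0.03)
    b = pp.qc_filter_snps(
        pp.qc_filter_snps(small_geno, maf_min=1e-9, hwe_p_min=1e-10), maf_min=0.1
    )
    assert list(a.snp_ids) == list(b.snp_ids)
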