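"""LD pruning, proxy counts, matched null draws, Fisher's method and the
two enrichment designs."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mqtlkit import enrichment as enr
from mqtlkit import simulate as sim
from mqtlkit.datamodel import GwasSummary


@pytest.fixture(scope="module")
def ld_geno():
    return sim.simulate_genotypes(500, n_blocks=20, snps_per_block=10, ld_rho=0.9, seed=91)


def _uniform_gwas(geno, seed, planted=None, beta_params=(0.5, 1.0)):
    rng = np.random.default_rng(seed)
    p = rng.uniform(size=geno.n_snps)
    if planted is not None:
        mask = np.isin(geno.snp_ids, list(planted))
        p[mask] = rng.beta(*beta_params, size=int(mask.sum()))
    return GwasSummary(
        "trait",
        pd.DataFrame({"snp_id": geno.snp_ids, "chrom": geno.chrom, "pos_bp": geno.pos_bp, "p": p}),
    )


def test_prune_ld_rules(ld_geno):
    # two adjacent SNPs in a rho=0.9 block: only one survives r2_max=0.1
    pair = [ld_geno.snp_ids[0], ld_geno.snp_ids[1]]
    assert len(enr.prune_ld(pair, ld_geno, r2_max=0.1)) == 1
    # SNPs from different blocks are LD-free: identity
    far = [ld_geno.snp_ids[0], ld_geno.snp_ids[10], ld_geno.snp_ids[20]]
    assert enr.prune_ld(far, ld_geno, r2_max=0.1) == far
    with pytest.raises(ValueError):
        enr.prune_ld(far, ld_geno, r2_max=0.0)


def test_prune_ld_order_fixed_by_p(ld_geno):
    snps = [ld_geno.snp_ids[k] for k in (0, 1, 2, 10, 11)]
    lp = [-20.0, -30.0, -10.0, -8.0, -25.0]
    base = set(enr.prune_ld(snps, ld_geno, r2_max=0.1, log10_p=lp))
    perm = np.random.default_rng(92).permutation(len(snps))
    shuffled = set(
        enr.prune_ld([snps[i] for i in perm], ld_geno, r2_max=0.1, log10_p=[lp[i] for i in perm])
    )
    assert base == shuffled
    # the smallest-p SNP of each block is the survivor
    assert ld_geno.snp_ids[1] in base and ld_geno.snp_ids[11] in base


def test_ld_proxy_count_matches_bruteforce():
    g = sim.simulate_genotypes(300, n_blocks=4, snps_per_block=10, ld_rho=0.85, seed=93)
    counts = enr.ld_proxy_count(g)
    Z = (g.dosage - g.dosage.mean(0)) / g.dosage.std(0)
    R2 = (Z.T @ Z / g.n_samples) ** 2
    for k in range(g.n_snps):
        near = (g.chrom == g.chrom[k]) & (np.abs(g.pos_bp - g.pos_bp[k]) <= 1_000_000)
        near[k] = False
        assert counts[k] == int((R2[k, near] > 0.8).sum())


def test_ld_proxy_counts_duplicate_and_ldfree():
    import dataclasses

    g = sim.simulate_genotypes(200, n_blocks=3, snps_per_block=5, ld_rho=0.0, seed=94)
    d = g.dosage.copy()
    d[:, 1] = d[:, 0]
    dup = dataclasses.replace(g, dosage=d)
    counts = enr.ld_proxy_count(dup)
    assert counts[0] >= 1 and counts[1] >= 1
    assert enr.ld_proxy_count(g).max() == 0


def test_matched_draw_preserves_cells(ld_geno):
    rng = np.random.default_rng(95)
    targets = list(rng.choice(ld_geno.snp_ids, 40, replace=False))
    spec = enr.MatchingSpec(n_draws=10, seed=5, relax=True)
    proxies = enr.ld_proxy_count(ld_geno)
    sampler = enr.MatchedNullSampler(ld_geno, targets, spec, proxy_counts=proxies)
    draw = sampler.draw(np.random.default_rng(0))
    assert len(draw) == len(targets)
    assert len(set(draw)) == len(draw)  # distinct within draw
    assert not set(draw) & set(ld_geno.snp_index(targets))  # pool excludes targets
    # identical seed gives identical draw
    d1 = enr.matched_null_draw(targets, ld_geno, spec, proxy_counts=proxies)
    d2 = enr.matched_null_draw(targets, ld_geno, spec, proxy_counts=proxies)
    np.testing.assert_array_equal(d1, d2)


def test_matched_draw_maf_distribution_matches(ld_geno):
    rng = np.random.default_rng(96)
    targets = list(rng.choice(ld_geno.snp_ids, 50, replace=False))
    spec = enr.MatchingSpec(n_draws=200, seed=7, relax=True)
    proxies = enr.ld_proxy_count(ld_geno)
    sampler = enr.MatchedNullSampler(ld_geno, targets, spec, proxy_counts=proxies)
    draws = sampler.draw_matrix(200, np.random.default_rng(1))
    bins = np.linspace(0, 0.5, 11)
    t_hist = np.histogram(ld_geno.maf[ld_geno.snp_index(targets)], bins=bins)[0]
    d_hist = np.histogram(ld_geno.maf[draws.ravel()], bins=bins)[0] / 200.0
    keep = t_hist > 0
    chi2 = float(np.sum((d_hist[keep] - t_hist[keep]) ** 2 / t_hist[keep]))
    assert stats.chi2.sf(chi2, keep.sum() - 1) > 0.01


def test_matched_draw_empty_cell_errors_without_relax():
    import dataclasses

    g = sim.simulate_genotypes(200, n_blocks=4, snps_per_block=5, ld_rho=0.0, seed=97)
    # give the target a unique annotation so its joint cell has no pool SNP
    annot = g.annotation.copy()
    annot[:] = "intronic"
    annot[0] = "5'UTR"
    g = dataclasses.replace(g, annotation=annot)
    spec = enr.MatchingSpec(annotation_mode="annotation_matched", n_draws=5, seed=1)
    with pytest.raises(ValueError, match="cell"):
        enr.MatchedNullSampler(g, [g.snp_ids[0]], spec, proxy_counts=np.zeros(g.n_snps, dtype=int))
    # relax falls back to marginal MAF matching
    spec_relaxed = enr.MatchingSpec(annotation_mode="annotation_matched", n_draws=5, seed=1, relax=True)
    sampler = enr.MatchedNullSampler(g, [g.snp_ids[0]], spec_relaxed, proxy_counts=np.zeros(g.n_snps, dtype=int))
    assert len(sampler.draw(np.random.default_rng(0))) == 1


def test_fisher_combined_values():
    s, df, p = enr.fisher_combined([0.05])
    assert s == pytest.approx(5.9915, abs=1e-4)
    assert df == 2 and p == pytest.approx(0.05, abs=1e-10)
    s2, df2, _ = enr.fisher_combined([0.1, 0.1])
    assert s2 == pytest.approx(9.2103, abs=1e-4)
    # survival oracle
    _, _, p2 = enr.fisher_combined([0.1, 0.1])
    assert p2 == pytest.approx(float(stats.chi2.sf(s2, 4)), abs=1e-10)
    with pytest.raises(ValueError):
        enr.fisher_combined([])


def test_empirical_p_rank_rule():
    from mqtlkit.datamodel import EnrichmentResult

    r = EnrichmentResult("t", 100.0, np.linspace(0, 99, 1000), 10, "genic_only")
    assert r.empirical_p == pytest.approx(1 / 1001)
    r2 = EnrichmentResult("t", -1.0, np.linspace(0, 99, 1000), 10, "genic_only")
    assert r2.empirical_p == 1.0


def test_gwas_enrichment_null_and_power():
    # a panel large enough that matched-null cells are well populated
    geno = sim.simulate_genotypes(400, n_blocks=120, snps_per_block=25, ld_rho=0.8, seed=98)
    proxies = enr.ld_proxy_count(geno)
    # null: uniform GWAS p independent of identity; each run is a fresh
    # experiment with its own target set
    emps = []
    for run in range(40):
        rng = np.random.default_rng(300 + run)
        targets = list(rng.choice(geno.snp_ids, 80, replace=False))
        gwas = _uniform_gwas(geno, 500 + run)
        spec = enr.MatchingSpec(n_draws=400, seed=run, relax=True)
        emps.append(enr.gwas_enrichment(targets, gwas, geno, spec, proxy_counts=proxies).empirical_p)
    assert stats.kstest(emps, "uniform").pvalue > 0.01
    # planted signal: strong rejection
    targets = list(np.random.default_rng(98).choice(geno.snp_ids, 80, replace=False))
    gwas = _uniform_gwas(geno, 999, planted=targets)
    spec = enr.MatchingSpec(n_draws=400, seed=0, relax=True)
    res = enr.gwas_enrichment(targets, gwas, geno, spec, proxy_counts=proxies)
    assert res.empirical_p <= 0.01


def test_gwas_enrichment_too_few_snps_errors(ld_geno):
    gwas = _uniform_gwas(ld_geno, 1)
    spec = enr.MatchingSpec(n_draws=10, seed=0, relax=True)
    with pytest.raises(ValueError, match="fewer than 10"):
        enr.gwas_enrichment(list(ld_geno.snp_ids[:5]), gwas, ld_geno, spec)


def test_trait_varcomp_enrichment_detects_planted_signal():
    """Causal SNPs inside the mQTL set: the mQTL variance component exceeds
    most matched null draws (reduced scale)."""
    g = sim.simulate_genotypes(400, n_blocks=20, snps_per_block=10, ld_rho=0.2, seed=99)
    rng = np.random.default_rng(100)
    causal = rng.choice(g.n_snps, 30, replace=False)
    tspec = sim.TraitSpec(causal_snp_idx=causal, h2_liability=0.6, prevalence=0.3, case_proportion=0.3)
    status, _ = sim.simulate_trait(g, tspec, seed=101)
    spec = enr.MatchingSpec(n_draws=8, seed=3, relax=True)
    res = enr.trait_varcomp_enrichment(
        status, g, list(g.snp_ids[causal]), spec, prevalence=0.3, exclude_chroms=(),
    )
    assert res.empirical_p <= 3 / 9  # observed among the largest


def test_trait_varcomp_enrichment_null_inside_distribution():
    g = sim.simulate_genotypes(300, n_blocks=15, snps_per_block=10, ld_rho=0.2, seed=102)
    rng = np.random.default_rng(103)
    status = pd.Series(rng.integers(0, 2, g.n_samples), index=g.sample_ids)
    targets = list(rng.choice(g.snp_ids, 25, replace=False))
    spec = enr.MatchingSpec(n_draws=8, seed=4, relax=True)
    res = enr.trait_varcomp_enrichment(status, g, targets, spec, prevalence=0.5, exclude_chroms=())
    assert res.empirical_p > 1 / 9
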