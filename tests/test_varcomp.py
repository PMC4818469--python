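"""GRM arithmetic, unrelated filtering, AI-REML against a grid-search
oracle, probe/trait variance partitions and the liability transform."""

import dataclasses
import itertools

import numpy as np
import pytest
from scipy import stats

from mqtlkit import simulate as sim
from mqtlkit import varcomp
from mqtlkit.datamodel import GenotypeDataset


def _grm_from(dosage, ids=None):
    n, m = dosage.shape
    return GenotypeDataset(
        sample_ids=ids if ids is not None else np.array([f"S{i}" for i in range(n)], dtype=object),
        snp_ids=np.array([f"rs{k}" for k in range(m)], dtype=object),
        dosage=dosage,
        chrom=np.array(["1"] * m, dtype=object),
        pos_bp=np.arange(1, m + 1) * 1000,
        alleles=np.tile(np.array([["A", "G"]], dtype=object), (m, 1)),
        maf=np.minimum(dosage.mean(0) / 2, 1 - dosage.mean(0) / 2),
        annotation=np.array(["intronic"] * m, dtype=object),
        tag_set_flag=np.ones(m, dtype=bool),
    )


def test_grm_hand_arithmetic_single_snp():
    g = _grm_from(np.array([[0.0], [2.0]]))
    grm = varcomp.compute_grm(g)
    np.testing.assert_allclose(grm.matrix, [[2.0, -2.0], [-2.0, 2.0]], atol=1e-12)


def test_grm_duplicate_individuals_off_diagonal(small_geno):
    dup = dataclasses.replace(
        small_geno,
        sample_ids=np.concatenate([small_geno.sample_ids, ["DUP"]]),
        dosage=np.vstack([small_geno.dosage, small_geno.dosage[:1]]),
    )
    grm = varcomp.compute_grm(dup)
    n = small_geno.n_samples
    assert grm.matrix[0, n] == pytest.approx(grm.matrix[0, 0], rel=0.05)


def test_grm_off_diagonal_sd_scales_as_inv_sqrt_m():
    g = sim.simulate_genotypes(400, n_blocks=40, snps_per_block=25, ld_rho=0.0, seed=51)
    grm = varcomp.compute_grm(g)
    off = grm.matrix[np.triu_indices_from(grm.matrix, k=1)]
    assert np.std(off) == pytest.approx(1 / np.sqrt(grm.n_snps_used), rel=0.25)
    assert abs(np.mean(np.diag(grm.matrix)) - 1) < 0.1


def test_filter_unrelated_behaviour():
    ids = np.array(["a", "b", "c", "d"], dtype=object)
    M = np.eye(4)
    grm = varcomp.GRM(ids, M, 10)
    assert list(varcomp.filter_unrelated(grm, 0.05)) == list(ids)
    # one duplicated pair: exactly one of the two goes
    M2 = np.eye(4)
    M2[0, 1] = M2[1, 0] = 0.9
    kept = varcomp.filter_unrelated(varcomp.GRM(ids, M2, 10), 0.05)
    assert len(kept) == 3 and ("a" in kept) != ("b" in kept)
    # tighter threshold removes a superset: the 0.9 pair fails both cuts,
    # the 0.03 pair only the tighter one
    M3 = np.eye(4)
    M3[0, 1] = M3[1, 0] = 0.9
    M3[2, 3] = M3[3, 2] = 0.03
    k05 = set(varcomp.filter_unrelated(varcomp.GRM(ids, M3, 10), 0.05))
    k025 = set(varcomp.filter_unrelated(varcomp.GRM(ids, M3, 10), 0.025))
    assert k025 < k05


# ---------------------------------------------------------------------------
# REML


def _toy_instance(seed, n=50):
    g = sim.simulate_genotypes(n, n_blocks=4, snps_per_block=10, ld_rho=0.3, seed=seed)
    A1 = varcomp.compute_grm(g, np.arange(0, 20)).matrix
    A2 = varcomp.compute_grm(g, np.arange(20, 40)).matrix
    rng = np.random.default_rng(900 + seed)
    L1 = np.linalg.cholesky(A1 + 1e-6 * np.eye(n))
    L2 = np.linalg.cholesky(A2 + 1e-6 * np.eye(n))
    y = 0.6 * L1 @ rng.normal(size=n) + 0.5 * L2 @ rng.normal(size=n) + rng.normal(size=n)
    return y, A1, A2


def test_reml_beats_grid_search_oracle():
    """AI-REML's restricted log-likelihood is at least the 20^3 grid
    maximum (within 1e-3) on random small instances."""
    X = np.ones((50, 1))
    for seed in range(6):
        y, A1, A2 = _toy_instance(seed)
        d = varcomp.reml_two_component(y, None, A1, A2)
        ll_hat = varcomp.restricted_loglik(y, X, [A1, A2], np.array([d.v_cis, d.v_trans, d.v_resid]))
        grid = np.linspace(1e-6, 2 * y.var(), 20)
        best = max(
            varcomp.restricted_loglik(y, X, [A1, A2], np.array(s))
            for s in itertools.product(grid, grid, grid)
        )
        assert ll_hat >= best - 1e-3


def test_reml_null_trait_small_h2():
    n = 800
    g = sim.simulate_genotypes(n, n_blocks=20, snps_per_block=20, ld_rho=0.2, seed=53)
    A1 = varcomp.compute_grm(g, np.arange(0, 200)).matrix
    A2 = varcomp.compute_grm(g, np.arange(200, 400)).matrix
    y = np.random.default_rng(54).normal(size=n)
    d = varcomp.reml_two_component(y, None, A1, A2)
    assert d.h2_total < 0.1


def test_reml_identical_grms_flagged_not_silent():
    y, A1, _ = _toy_instance(3)
    d = varcomp.reml_two_component(y, None, A1, A1.copy())
    assert (not d.converged) or not np.isfinite(d.se_cis) or d.se_cis > 10 * max(d.v_cis, 1e-6)


def test_variance_components_nonnegative_fractions_bounded():
    for seed in range(4):
        y, A1, A2 = _toy_instance(seed + 20)
        d = varcomp.reml_two_component(y, None, A1, A2)
        assert d.v_cis >= 0 and d.v_trans >= 0 and d.v_resid >= 0
        assert 0 <= d.h2_total <= 1 + 1e-9


# ---------------------------------------------------------------------------
# probe partition


def test_partition_probe_no_cis_snps_fixes_zero(small_geno):
    rng = np.random.default_rng(55)
    y = rng.normal(size=small_geno.n_samples)
    d = varcomp.partition_probe_variance(
        y, small_geno, probe_chrom="26", probe_pos=1, name="cgX"
    )
    assert d.v_cis == pytest.approx(0.0, abs=1e-6)


def test_partition_probe_recovers_architecture():
    """Mean absolute error of cis/trans h2 across simulated probes stays
    within the tolerance used by the headline recovery check (looser here
    at the smaller test scale)."""
    cohort = sim.CohortSpec(n_children=500, n_mothers=0, seed=56)
    geno = sim.simulate_cohort_genotypes(cohort, n_blocks=30, snps_per_block=20, ld_rho=0.4)
    arch = sim.random_architecture(geno, 8, h2_cis=0.4, h2_trans=0.3, n_trans_snps=30, seed=57)
    from mqtlkit.preprocess import prepare_residuals

    meth, cov, _ = sim.simulate_methylation(geno, cohort, arch)
    res = prepare_residuals(meth["childhood"], cov["childhood"])
    keep = np.array([s in set(res.sample_ids) for s in geno.sample_ids])
    tp_geno = geno.subset_samples(keep)
    grm_all = varcomp.compute_grm(tp_geno)
    sidx = {s: i for i, s in enumerate(res.sample_ids)}
    order = np.array([sidx[s] for s in tp_geno.sample_ids])
    errs_c, errs_t = [], []
    for j, pa in enumerate(arch.probes):
        d = varcomp.partition_probe_variance(
            res.values[j, order], tp_geno, pa.chrom, pa.pos_bp, grm_all=grm_all
        )
        errs_c.append(abs(d.h2_cis - 0.4))
        errs_t.append(abs(d.h2_trans - 0.3))
    assert np.mean(errs_c) < 0.12
    assert np.mean(errs_t) < 0.15


# ---------------------------------------------------------------------------
# liability transform


def test_liability_multiplier_closed_form_half():
    assert varcomp.liability_transform(1.0, 0.5, 0.5) == pytest.approx(np.pi / 2, abs=1e-10)
    assert varcomp.liability_transform(0.0, 0.13, 0.42) == 0.0


def test_liability_self_consistency_oracle():
    K, P = 0.01, 0.5
    h2 = 0.3
    z = float(np.exp(-0.5 * stats.norm.ppf(1 - K) ** 2) / np.sqrt(2 * np.pi))
    expected = h2 * K**2 * (1 - K) ** 2 / (z**2 * P * (1 - P))
    assert varcomp.liability_transform(h2, K, P) == pytest.approx(expected, abs=1e-10)


def test_liability_linear_in_h2():
    m1 = varcomp.liability_transform(0.2, 0.1, 0.4)
    m2 = varcomp.liability_transform(0.4, 0.1, 0.4)
    assert m2 == pytest.approx(2 * m1, rel=1e-12)
    with pytest.raises(ValueError):
        varcomp.liability_transform(0.2, 0.0, 0.4)


# ---------------------------------------------------------------------------
# trait partition


def test_partition_trait_label_swap_symmetry(ldfree_geno):
    rng = np.random.default_rng(58)
    import pandas as pd

    status = pd.Series(
        rng.integers(0, 2, ldfree_geno.n_samples), index=ldfree_geno.sample_ids
    )
    set1 = list(ldfree_geno.snp_ids[:30])
    set2c = np.ones(ldfree_geno.n_snps, dtype=bool)
    # restrict the complement to make the swap exact: tag set = all SNPs
    g = dataclasses.replace(ldfree_geno, tag_set_flag=np.ones(ldfree_geno.n_snps, dtype=bool))
    d1, _ = varcomp.partition_trait_variance(status, g, set1, exclude_chroms=())
    set2 = [s for s in g.snp_ids if s not in set(set1)]
    d2, _ = varcomp.partition_trait_variance(status, g, set2, exclude_chroms=())
    assert d1.v_cis == pytest.approx(d2.v_trans, rel=1e-4, abs=1e-8)
    assert d1.v_trans == pytest.approx(d2.v_cis, rel=1e-4, abs=1e-8)


def test_partition_trait_null_small_components(ldfree_geno):
    import pandas as pd

    rng = np.random.default_rng(59)
    status = pd.Series(
        rng.integers(0, 2, ldfree_geno.n_samples), index=ldfree_geno.sample_ids
    )
    d, liab = varcomp.partition_trait_variance(
        status, ldfree_geno, list(ldfree_geno.snp_ids[:30]), prevalence=0.5, exclude_chroms=()
    )
    assert liab["h2_liab_mqtl"] < 0.1 and liab["h2_liab_rest"] < 0.25


def test_partition_trait_chr6_exclusion(ldfree_geno):
    import pandas as pd

    status = pd.Series(
        np.random.default_rng(60).integers(0, 2, ldfree_geno.n_samples),
        index=ldfree_geno.sample_ids,
    )
    only_chr1 = [s for s, c in zip(ldfree_geno.snp_ids, ldfree_geno.chrom) if c == "1"]
    with pytest.raises(ValueError, match="empty after chromosome"):
        varcomp.partition_trait_variance(status, ldfree_geno, only_chr1, exclude_chroms=("1",))


# ---------------------------------------------------------------------------
# heritability-on-age regression


def test_h2_age_regression_exact_linear_recovery():
    ages = {"t0": 0.0, "t1": 10.0, "t2": 20.0}
    decomps = []
    for tp, a in ages.items():
        h2 = 0.4 - 0.005 * a
        decomps.append(
            varcomp.VarianceDecomposition(
                name="cg", timepoint=tp, v_cis=h2, v_trans=0.0, v_resid=1 - h2
            )
        )
    slope, se = varcomp.h2_age_regression(decomps, ages)
    assert slope == pytest.approx(-0.005, abs=1e-12)


def test_h2_age_regression_constant_gives_null_slope():
    ages = {"t0": 0.0, "t1": 10.0}
    rng = np.random.default_rng(61)
    decomps = [
        varcomp.VarianceDecomposition(
            name=f"cg{j}", timepoint=tp, v_cis=0.3 + 1e-3 * rng.normal(), v_trans=0.0, v_resid=0.7
        )
        for j in range(50)
        for tp in ages
    ]
    slope, se = varcomp.h2_age_regression(decomps, ages)
    assert abs(slope) < 2 * se

    with pytest.raises(ValueError):
        varcomp.h2_age_regression(decomps[:1], {"t0": 0.0})
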