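"""Two-stage association scan: cis/trans rule, screen/exact agreement,
null calibration, sentinel selection, allele-flip symmetry."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from mqtlkit import scan
from mqtlkit import simulate as sim
from mqtlkit.datamodel import MethylationDataset
from mqtlkit.preprocess import rank_normalize


@pytest.mark.parametrize(
    "snp_chrom,snp_pos,probe_chrom,probe_pos,expected",
    [
        ("1", 2_000_000, "1", 1_000_000, "cis"),  # exactly 1 Mb: inclusive
        ("1", 2_000_001, "1", 1_000_000, "trans"),  # one bp beyond
        ("1", 1_000_000, "2", 1_000_000, "trans"),  # different chromosomes
        ("3", 5, "3", 5, "cis"),
    ],
)
def test_cis_trans_boundary(snp_chrom, snp_pos, probe_chrom, probe_pos, expected):
    assert scan.classify_cis_trans(snp_chrom, snp_pos, probe_chrom, probe_pos) == expected


def _residual_meth(values, sample_ids, probe_ids=None, timepoint="childhood"):
    values = np.atleast_2d(values)
    if probe_ids is None:
        probe_ids = [f"cg{j}" for j in range(values.shape[0])]
    return MethylationDataset(
        probe_ids=np.array(probe_ids, dtype=object),
        sample_ids=np.asarray(sample_ids, dtype=object),
        values=values, timepoint=timepoint, age_years=7.0,
        scale_tag="rank_normal_residual",
    )


def test_perfect_association_hits_log10p_floor(small_geno):
    # probe exactly proportional to the dosage: r^2 = 1, p underflows
    g = small_geno.dosage[:, 3]
    y = (g - g.mean()) / g.std()
    meth = _residual_meth(y, small_geno.sample_ids)
    cand = scan.screen_associations(small_geno, meth)
    row = cand.set_index("snp_id").loc[small_geno.snp_ids[3]]
    assert row["log10_p"] == -320.0


def test_screen_matches_per_pair_ols_oracle(childhood_residuals):
    """Stage-1 blocked-correlation p equals per-pair OLS p to 1e-10."""
    resid, geno, order = (childhood_residuals[k] for k in ("resid", "geno", "order"))
    cfg = scan.ScanConfig(p_screen=1.0, p_discovery=1.0)
    cand = scan.screen_associations(geno, resid, cfg)
    rng = np.random.default_rng(6)
    take = rng.choice(len(cand), 100, replace=False)
    pidx = {p: i for i, p in enumerate(resid.probe_ids)}
    for _, row in cand.iloc[take].iterrows():
        k = geno.snp_index([row.snp_id])[0]
        y = resid.values[pidx[row.probe_id], order]
        g = geno.dosage[:, k]
        res = stats.linregress(g, y)
        lp_oracle = np.log10(2) + stats.t.logsf(abs(res.slope / res.stderr), len(y) - 2) / np.log(10)
        assert row.log10_p == pytest.approx(lp_oracle, abs=1e-10)


def test_exact_no_covariates_reproduces_screen(childhood_residuals):
    resid, geno = childhood_residuals["resid"], childhood_residuals["geno"]
    cand = scan.screen_associations(geno, resid, scan.ScanConfig(p_screen=1e-4, p_discovery=1e-4))
    pairs = list(zip(cand["snp_id"], cand["probe_id"]))[:50]
    recs = scan.exact_association(geno, resid, None, pairs)
    lookup = {(r.snp_id, r.probe_id): r for r in recs}
    for _, row in cand.iloc[:50].iterrows():
        assert lookup[(row.snp_id, row.probe_id)].log10_p == pytest.approx(row.log10_p, abs=1e-9)


def test_exact_orthogonal_covariate_leaves_slope(childhood_residuals):
    resid, geno, order = (childhood_residuals[k] for k in ("resid", "geno", "order"))
    import pandas as pd

    pairs = [(geno.snp_ids[0], resid.probe_ids[0])]
    base = scan.exact_association(geno, resid, None, pairs)[0]
    g = geno.dosage[:, 0]
    y = resid.values[0, order]
    rng = np.random.default_rng(7)
    z = rng.normal(size=len(g))
    # orthogonalize z against (1, g, y)
    X = np.column_stack([np.ones(len(g)), g, y])
    z = z - X @ np.linalg.lstsq(X, z, rcond=None)[0]
    cov = pd.DataFrame({"z": z}, index=pd.Index(resid.sample_ids[order], name="sample_id"))
    adj = scan.exact_association(geno, resid, cov, pairs)[0]
    assert adj.slope == pytest.approx(base.slope, abs=1e-8)


def test_exact_recovers_simulated_cis_r2():
    n = 2000
    g = sim.simulate_genotypes(n, n_blocks=2, snps_per_block=5, ld_rho=0.0, seed=31)
    rng = np.random.default_rng(32)
    x = g.dosage[:, 0]
    y = x * np.sqrt(0.5 / x.var()) + rng.normal(0, np.sqrt(0.5), n)
    meth = _residual_meth(rank_normalize(y), g.sample_ids)
    rec = scan.exact_association(g, meth, None, [(g.snp_ids[0], "cg0")])[0]
    assert rec.r2 == pytest.approx(0.5, abs=0.05)


def test_exact_unknown_ids_raise(childhood_residuals):
    with pytest.raises(KeyError):
        scan.exact_association(
            childhood_residuals["geno"], childhood_residuals["resid"], None,
            [("rs_nonexistent", "cg000000")],
        )


def test_null_calibration_uniform():
    """Null scan p-values are uniform: the p<0.05 fraction is binomial and
    KS against U(0,1) does not reject."""
    rng = np.random.default_rng(33)
    g = sim.simulate_genotypes(200, n_blocks=10, snps_per_block=10, ld_rho=0.4, seed=34)
    Y = np.vstack([rank_normalize(rng.normal(size=200)) for _ in range(100)])
    meth = _residual_meth(Y, g.sample_ids)
    lp = scan.screen_pvalue_matrix(g, meth).ravel()  # 10^4 tests
    p = 10.0**lp
    frac = (p < 0.05).mean()
    assert frac == pytest.approx(0.05, abs=3 * np.sqrt(0.05 * 0.95 / p.size))
    assert stats.kstest(p, "uniform").pvalue > 0.01


def test_allele_flip_negates_slope_preserves_p(childhood_residuals):
    resid, geno = childhood_residuals["resid"], childhood_residuals["geno"]
    pairs = [(geno.snp_ids[5], resid.probe_ids[2])]
    a = scan.exact_association(geno, resid, None, pairs)[0]
    flipped = dataclasses.replace(geno, dosage=2.0 - geno.dosage)
    b = scan.exact_association(flipped, resid, None, pairs)[0]
    assert b.slope == pytest.approx(-a.slope, rel=1e-12)
    assert b.log10_p == pytest.approx(a.log10_p, rel=1e-12)


def test_select_sentinels_cis_argmin_and_trans_clumps(small_geno):
    from mqtlkit.datamodel import AssociationRecord

    def rec(snp_i, probe, lp, relation, dist=np.nan):
        return AssociationRecord(
            snp_id=small_geno.snp_ids[snp_i], probe_id=probe, timepoint="t",
            slope=0.5, se=0.05, t_stat=10.0, log10_p=lp, r2=0.1,
            relation=relation, distance_bp=dist,
        )

    # cis: argmin of p among 3 hits; trans: SNPs 0 & 1 are 5 kb apart (one
    # clump), SNP 95 sits on another chromosome (second clump)
    records = [
        rec(10, "cgA", -20, "cis", 100.0),
        rec(11, "cgA", -18, "cis", 200.0),
        rec(12, "cgA", -15, "cis", 300.0),
        rec(0, "cgA", -16, "trans"),
        rec(1, "cgA", -15, "trans"),
        rec(95, "cgA", -17, "trans"),
    ]
    sents = scan.select_sentinels(records, small_geno, p_discovery=1e-14)
    cis = [s for s in sents if s.relation == "cis"]
    trans = [s for s in sents if s.relation == "trans"]
    assert len(cis) == 1 and cis[0].snp_id == small_geno.snp_ids[10]
    assert len(trans) == 2
    assert {t.snp_id for t in trans} == {small_geno.snp_ids[0], small_geno.snp_ids[95]}


def test_scan_config_validation():
    with pytest.raises(ValueError):
        scan.ScanConfig(p_screen=1e-14, p_discovery=1e-7)
    with pytest.raises(ValueError):
        scan.ScanConfig(cis_window_bp=0)
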