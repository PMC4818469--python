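"""Shared fixtures: miniature simulated cohorts built fresh per session."""

import numpy as np
import pytest

from mqtlkit import preprocess as pp
from mqtlkit import simulate as sim


@pytest.fixture(scope="session")
def small_geno():
    """300 samples, 10 LD blocks x 10 SNPs, moderate LD."""
    return sim.simulate_genotypes(
        300, n_blocks=10, snps_per_block=10, ld_rho=0.6, seed=101
    )


@pytest.fixture(scope="session")
def ldfree_geno():
    """1,000 samples, LD-free SNPs for conditional-mapping tests."""
    return sim.simulate_genotypes(
        1000, n_blocks=8, snps_per_block=10, ld_rho=0.0, seed=102
    )


@pytest.fixture(scope="session")
def cohort_bundle():
    """Full miniature cohort: genotypes, architecture, methylation at all
    timepoints, covariates and the simulation truth table."""
    cohort = sim.CohortSpec(n_children=250, n_mothers=150, seed=103)
    geno = sim.simulate_cohort_genotypes(cohort, n_blocks=12, snps_per_block=15, ld_rho=0.5)
    arch = sim.random_architecture(
        geno, 30, h2_cis=0.35, h2_trans=0.1, prob_null=0.3, seed=104
    )
    manifest = sim.probe_manifest(arch, seed=105)
    meth, cov, truth = sim.simulate_methylation(geno, cohort, arch)
    return {
        "cohort": cohort, "geno": geno, "arch": arch, "manifest": manifest,
        "meth": meth, "cov": cov, "truth": truth,
    }


@pytest.fixture(scope="session")
def childhood_residuals(cohort_bundle):
    """Rank-normalised, covariate-residualized childhood methylation plus
    the genotype subset aligned to it."""
    meth = cohort_bundle["meth"]["childhood"]
    resid = pp.prepare_residuals(meth, cohort_bundle["cov"]["childhood"])
    geno = cohort_bundle["geno"]
    keep = np.array([s in set(resid.sample_ids) for s in geno.sample_ids])
    tp_geno = geno.subset_samples(keep)
    sidx = {s: i for i, s in enumerate(resid.sample_ids)}
    order = np.array([sidx[s] for s in tp_geno.sample_ids])
    return {"resid": resid, "geno": tp_geno, "order": order}
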