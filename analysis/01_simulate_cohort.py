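#!/usr/bin/env python
"""Simulate the study cohort: two generations, five timepoints.

Generates LD-block genotypes for 400 children and 400 mothers, a 120-probe
methylation architecture (70% of probes with a cis mQTL at h2_cis = 0.35
and a polygenic trans component at 0.1), and beta-scale methylation at
birth / childhood / adolescence (children) and pregnancy / middle age
(mothers) with environmental variance growing by 1% per year of age.

Writes genotypes, manifest, per-timepoint methylation + covariates, and
the simulation truth table under results/cohort/.
"""

from pathlib import Path

from mqtlkit import io as mio
from mqtlkit import simulate as sim

OUT = Path("results/cohort")
SEED = 20250901

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = sim.CohortSpec(n_children=400, n_mothers=400, seed=SEED)
    geno = sim.simulate_cohort_genotypes(cohort, n_blocks=40, snps_per_block=25, ld_rho=0.6)
    arch = sim.random_architecture(
        geno, n_probes=120, h2_cis=0.35, h2_trans=0.10, prob_null=0.3, seed=SEED + 1
    )
    manifest = sim.probe_manifest(arch, seed=SEED + 2)
    meth, cov, truth = sim.simulate_methylation(geno, cohort, arch)

    mio.write_genotypes(geno, OUT / "genotypes.tsv")
    mio.write_manifest(manifest, OUT / "manifest.tsv")
    for tp, m in meth.items():
        mio.write_methylation(m, OUT / f"methylation_{tp}.tsv")
        mio.write_covariates(cov[tp], OUT / f"covariates_{tp}.tsv")
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    print(f"cohort written to {OUT}: {geno.n_samples} samples, {geno.n_snps} SNPs, "
          f"{len(arch.probes)} probes, {len(meth)} timepoints")

if __name__ == "__main__":
    main()
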