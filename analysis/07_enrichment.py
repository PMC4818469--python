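#!/usr/bin/env python
"""Enrichment of cis mQTL in synthetic GWAS results.

Takes the LD-pruned childhood cis sentinels, builds two synthetic GWAS
traits over the cohort SNP panel — one null (uniform p everywhere) and one
with Beta(0.5,1) p at the mQTL SNPs — and tests each with Fisher's
combined statistic against 1,000 MAF/LD/annotation-matched null draws.
Also reports the mQTL SNP feature distribution. Writes tables under
results/enrichment/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from mqtlkit import io as mio
from mqtlkit.annotation import feature_distribution
from mqtlkit.datamodel import GwasSummary
from mqtlkit.enrichment import MatchingSpec, gwas_enrichment, ld_proxy_count, prune_ld

IN_COHORT = Path("results/cohort")
IN_SCAN = Path("results/scan")
OUT = Path("results/enrichment")
SEED = 20250907

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno = mio.read_genotypes(IN_COHORT / "genotypes.tsv", format="text_dosage")
    sents = [r for r in mio.read_results(IN_SCAN / "sentinels_childhood.tsv") if r.relation == "cis"]
    pruned = prune_ld([r.snp_id for r in sents], geno, r2_max=0.1,
                      log10_p=[r.log10_p for r in sents])
    print(f"{len(sents)} cis sentinels -> {len(pruned)} after LD pruning at r2 > 0.1")

    proxies = ld_proxy_count(geno)
    rng = np.random.default_rng(SEED)
    results = []
    for name, planted in (("null_trait", False), ("mqtl_driven_trait", True)):
        p = rng.uniform(size=geno.n_snps)
        if planted:
            mask = np.isin(geno.snp_ids, pruned)
            p[mask] = rng.beta(0.5, 1.0, size=int(mask.sum()))
        gwas = GwasSummary(name, pd.DataFrame(
            {"snp_id": geno.snp_ids, "chrom": geno.chrom, "pos_bp": geno.pos_bp, "p": p}))
        for mode in ("genic_only", "annotation_matched"):
            spec = MatchingSpec(annotation_mode=mode, n_draws=1000, seed=SEED + 1, relax=True)
            res = gwas_enrichment(pruned, gwas, geno, spec, proxy_counts=proxies)
            results.append(res)
            print(f"{name} [{mode}]: Fisher stat {res.observed_statistic:.1f}, "
                  f"empirical p {res.empirical_p:.4g} over {len(res.null_statistics)} draws")
    mio.write_results(results, OUT / "gwas_enrichment.tsv")

    annot = pd.Series(geno.annotation, index=geno.snp_ids)
    fd = feature_distribution(pruned, annot)
    fd.table.reset_index(names="category").to_csv(OUT / "snp_features.tsv", sep="\t", index=False)

if __name__ == "__main__":
    main()
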