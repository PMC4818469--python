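#!/usr/bin/env python
"""Two-stage mQTL scan at every timepoint.

Reads the simulated cohort from results/cohort/, rank-normalises and
covariate-residualizes methylation, screens all SNP x probe pairs at
p <= 1e-7, refits survivors exactly, and selects sentinel mQTL at the
1e-14 discovery threshold. Writes per-timepoint association and sentinel
tables plus a Table-1-style summary under results/scan/.
"""

from pathlib import Path

import numpy as np

from mqtlkit import io as mio
from mqtlkit.pipeline import summarize_records
from mqtlkit.preprocess import prepare_residuals, qc_filter_probes
from mqtlkit.scan import ScanConfig, exact_association, screen_associations, select_sentinels
from mqtlkit.simulate import DEFAULT_TIMEPOINTS

IN = Path("results/cohort")
OUT = Path("results/scan")

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    geno = mio.read_genotypes(IN / "genotypes.tsv", format="text_dosage")
    manifest = mio.read_manifest(IN / "manifest.tsv")
    cfg = ScanConfig()
    sentinels = {}
    for tp in DEFAULT_TIMEPOINTS:
        meth = mio.read_methylation(
            IN / f"methylation_{tp.label}.tsv", IN / "manifest.tsv",
            timepoint=tp.label, age_years=tp.age_years,
        )
        cov = mio.read_covariates(IN / f"covariates_{tp.label}.tsv")
        resid = prepare_residuals(qc_filter_probes(meth, manifest), cov)
        tp_geno = geno.subset_samples(np.isin(geno.sample_ids, resid.sample_ids))
        cand = screen_associations(tp_geno, resid, cfg)
        recs = exact_association(
            tp_geno, resid, None, list(zip(cand.snp_id, cand.probe_id)),
            probe_annotation=manifest,
        )
        sents = select_sentinels(recs, tp_geno)
        mio.write_results(recs, OUT / f"associations_{tp.label}.tsv")
        mio.write_results(sents, OUT / f"sentinels_{tp.label}.tsv")
        sentinels[tp.label] = sents
        n_cis = sum(r.relation == "cis" for r in sents)
        print(f"{tp.label}: {len(cand)} screened pairs, {len(sents)} sentinels "
              f"({n_cis} cis, {len(sents)-n_cis} trans)")
    summary = summarize_records(sentinels)
    summary.to_csv(OUT / "summary.tsv", sep="\t", index=False)
    print(summary.to_string(index=False))

if __name__ == "__main__":
    main()
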