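#!/usr/bin/env python
"""Temporal stability of mQTL and methylation.

Computes (a) replication rates of each timepoint's sentinel mQTL in every
other timepoint at p <= 1e-7 with sign concordance, (b) per-probe
childhood-adolescence methylation correlations against a permutation null,
stratified by mQTL status, and (c) the coefficient-of-variation change
between childhood and adolescence. Writes tables under results/temporal/.
"""

from pathlib import Path

import pandas as pd

from mqtlkit import io as mio
from mqtlkit.simulate import DEFAULT_TIMEPOINTS
from mqtlkit.temporal import (
    coefficient_of_variation,
    compare_cv,
    cross_time_correlation,
    replication_rate,
    stratify_correlation_by_mqtl,
)

IN_COHORT = Path("results/cohort")
IN_SCAN = Path("results/scan")
OUT = Path("results/temporal")

def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    labels = [tp.label for tp in DEFAULT_TIMEPOINTS]
    sents = {tp: mio.read_results(IN_SCAN / f"sentinels_{tp}.tsv") for tp in labels}
    assoc = {tp: mio.read_results(IN_SCAN / f"associations_{tp}.tsv") for tp in labels}

    rows = []
    for disc in labels:
        for targ in labels:
            if disc == targ or not sents[disc]:
                continue
            s = replication_rate(sents[disc], assoc[targ])
            rows.append({"discovery": disc, "target": targ,
                         "n_discovery": s.n_discovery, "n_replicated": s.n_replicated,
                         "n_untested": s.n_untested, "rate": round(s.rate, 4)})
    rep = pd.DataFrame(rows)
    rep.to_csv(OUT / "replication.tsv", sep="\t", index=False)
    print(rep.pivot(index="discovery", columns="target", values="rate").to_string())

    m1 = mio.read_methylation(IN_COHORT / "methylation_childhood.tsv", IN_COHORT / "manifest.tsv",
                              timepoint="childhood", age_years=7)
    m2 = mio.read_methylation(IN_COHORT / "methylation_adolescence.tsv", IN_COHORT / "manifest.tsv",
                              timepoint="adolescence", age_years=17)
    corr, null = cross_time_correlation(m1, m2, n_permutations=200, seed=7)
    mqtl_probes = {r.probe_id for r in sents["childhood"]}
    strat = stratify_correlation_by_mqtl(corr, mqtl_probes)
    corr.rename("r").to_frame().to_csv(OUT / "cross_time_correlation.tsv", sep="\t")
    print(f"mean r: all probes {corr.mean():.3f}; "
          f"mQTL probes {strat['mean_r_mqtl']:.3f} vs others {strat['mean_r_other']:.3f} "
          f"(Welch p {strat['p']:.2g}); permutation null mean {null.mean():.4f}")

    cv1, cv2 = coefficient_of_variation(m1), coefficient_of_variation(m2)
    change, se = compare_cv(cv1, cv2)
    pd.DataFrame([{"mean_relative_cv_change": change, "se": se}]).to_csv(
        OUT / "cv_change.tsv", sep="\t", index=False
    )
    print(f"CV childhood->adolescence: mean relative change {change:+.3f} (se {se:.3f})")

if __name__ == "__main__":
    main()
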