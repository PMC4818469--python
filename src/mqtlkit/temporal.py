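"""Cross-timepoint stability analyses.

Replication rates of discovery mQTL in other timepoints (sign-concordant
by default), per-probe cross-time correlations with a permutation null,
and coefficient-of-variation comparisons on the beta scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import MethylationDataset

logger = logging.getLogger(__name__)

DEFAULT_P_REPLICATION = 1e-7


@dataclass
class ReplicationSummary:
    discovery_timepoint: str
    target_timepoint: str
    n_discovery: int
    n_replicated: int
    n_untested: int
    p_discovery: float
    p_replication: float

    @property
    def rate(self) -> float:
        return self.n_replicated / self.n_discovery if self.n_discovery else np.nan


def replication_rate(
    discovery_records,
    target_records,
    p_replication: float = DEFAULT_P_REPLICATION,
    require_sign: bool = True,
) -> ReplicationSummary:
    """Fraction of discovery sentinel pairs replicating in the target
    timepoint at ``p_replication`` (and, by default, with the same slope
    sign). Pairs absent from the target results count as non-replicated
    and are reported separately."""
    discovery = list(discovery_records)
    if not discovery:
        raise ValueError("empty discovery set")
    lp = np.log10(p_replication)
    target = {(r.snp_id, r.probe_id): r for r in target_records}
    n_rep = n_untested = 0
    for d in discovery:
        t = target.get((d.snp_id, d.probe_id))
        if t is None:
            n_untested += 1
            continue
        if t.log10_p <= lp and (not require_sign or np.sign(t.slope) == np.sign(d.slope)):
            n_rep += 1
    return ReplicationSummary(
        discovery_timepoint=discovery[0].timepoint,
        target_timepoint=next(iter(target.values())).timepoint if target else "",
        n_discovery=len(discovery),
        n_replicated=n_rep,
        n_untested=n_untested,
        p_discovery=10.0 ** max(r.log10_p for r in discovery),
        p_replication=p_replication,
    )


def cross_time_correlation(
    meth_t1: MethylationDataset,
    meth_t2: MethylationDataset,
    shared_sample_map: dict | None = None,
    n_permutations: int = 100,
    seed: int = 0,
):
    """Per-probe Pearson correlation over shared samples, plus a null
    distribution obtained by permuting one timepoint's sample order.

    ``shared_sample_map`` maps t1 sample ids to t2 sample ids (identity by
    default). Returns ``(r, null_r)`` with ``null_r`` of shape
    ``[n_permutations, n_probes]``.
    """
    if shared_sample_map is None:
        shared_sample_map = {s: s for s in meth_t1.sample_ids if s in set(meth_t2.sample_ids)}
    pairs = [(a, b) for a, b in shared_sample_map.items()
             if a in set(meth_t1.sample_ids) and b in set(meth_t2.sample_ids)]
    if len(pairs) < 3:
        raise ValueError("fewer than 3 shared samples")
    if len(pairs) < 10:
        logger.warning("only %d shared samples; correlations will be noisy", len(pairs))
    i1 = meth_t1.probe_index(meth_t1.probe_ids)  # identity; keeps probe order
    common_probes = [p for p in meth_t1.probe_ids if p in set(meth_t2.probe_ids)]
    j1 = meth_t1.probe_index(common_probes)
    j2 = meth_t2.probe_index(common_probes)
    s1 = {s: i for i, s in enumerate(meth_t1.sample_ids)}
    s2 = {s: i for i, s in enumerate(meth_t2.sample_ids)}
    c1 = np.array([s1[a] for a, _ in pairs])
    c2 = np.array([s2[b] for _, b in pairs])

    A = meth_t1.values[np.ix_(j1, c1)]
    B = meth_t2.values[np.ix_(j2, c2)]
    A = A - A.mean(axis=1, keepdims=True)
    B = B - B.mean(axis=1, keepdims=True)
    sa = A.std(axis=1)
    sb = B.std(axis=1)
    sa[sa == 0] = np.inf
    sb[sb == 0] = np.inf
    n = len(pairs)
    r = (A * B).sum(axis=1) / (n * sa * sb)

    rng = np.random.default_rng(seed)
    null = np.empty((n_permutations, len(common_probes)))
    for k in range(n_permutations):
        perm = rng.permutation(n)
        null[k] = (A * B[:, perm]).sum(axis=1) / (n * sa * sb)
    return pd.Series(r, index=common_probes, name="r"), null


def coefficient_of_variation(meth: MethylationDataset) -> pd.Series:
    """Per-probe CV (sd/mean) of beta-scale methylation."""
    if meth.scale_tag != "beta":
        raise ValueError("CV is defined on the beta scale only")
    mean = np.nanmean(meth.values, axis=1)
    sd = np.nanstd(meth.values, axis=1)
    ok = mean > 1e-6
    if not ok.all():
        logger.warning("excluding %d zero-mean probes from CV", int((~ok).sum()))
    return pd.Series(sd[ok] / mean[ok], index=meth.probe_ids[ok], name="cv")


def compare_cv(cv_t1: pd.Series, cv_t2: pd.Series) -> tuple:
    """Paired mean relative CV change (cv2 - cv1)/cv1 with its SE."""
    common = cv_t1.index.intersection(cv_t2.index)
    rel = (cv_t2[common] - cv_t1[common]) / cv_t1[common]
    return float(rel.mean()), float(rel.std(ddof=1) / np.sqrt(len(rel)))


def stratify_correlation_by_mqtl(correlations: pd.Series, mqtl_probe_set) -> dict:
    """Mean cross-time correlation for probes with vs without an mQTL, with
    a Welch test on the difference."""
    mqtl_probe_set = set(mqtl_probe_set)
    in_set = correlations.index.isin(mqtl_probe_set)
    with_m = correlations[in_set]
    without = correlations[~in_set]
    if len(with_m) == 0 or len(without) == 0:
        if len(with_m) == len(correlations):
            return {"mean_r_mqtl": float(correlations.mean()),
                    "mean_r_other": float(correlations.mean()),
                    "t": 0.0, "p": 1.0, "n_mqtl": len(with_m), "n_other": 0}
        raise ValueError("one of the probe groups is empty")
    t, p = stats.ttest_ind(with_m, without, equal_var=False)
    return {
        "mean_r_mqtl": float(with_m.mean()),
        "mean_r_other": float(without.mean()),
        "t": float(t),
        "p": float(p),
        "n_mqtl": int(len(with_m)),
        "n_other": int(len(without)),
    }
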