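"""Exhaustive two-stage SNP x CpG additive association scan.

Stage 1 screens all pairs by blocked correlation algebra on
covariate-residualized, rank-normalised methylation (per-SNP mean
imputation of missing dosages); stage 2 refits surviving pairs by exact
per-pair OLS (optionally with covariates, listwise deletion of missing
dosages). p-values live in log10 space with a floor at -320; records at
the floor carry the t statistic for ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import LOG10_P_FLOOR, AssociationRecord, GenotypeDataset, MethylationDataset
from .preprocess import covariate_design

DEFAULT_CIS_WINDOW_BP = 1_000_000
DEFAULT_P_SCREEN = 1e-7
DEFAULT_P_DISCOVERY = 1e-14

_LN10 = np.log(10.0)


@dataclass
class ScanConfig:
    p_screen: float = DEFAULT_P_SCREEN
    p_discovery: float = DEFAULT_P_DISCOVERY
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP
    block_size: int = 2000  # probes per tile

    def __post_init__(self) -> None:
        if self.p_discovery > self.p_screen:
            raise ValueError("p_discovery must be <= p_screen")
        if self.cis_window_bp <= 0:
            raise ValueError("cis_window_bp must be positive")


def classify_cis_trans(snp_chrom, snp_pos: int, probe_chrom, probe_pos: int, window_bp: int = DEFAULT_CIS_WINDOW_BP) -> str:
    """cis iff same chromosome and |snp_pos - probe_pos| <= window_bp
    (inclusive boundary)."""
    if snp_pos <= 0 or probe_pos <= 0:
        raise ValueError("positions must be positive")
    if str(snp_chrom) != str(probe_chrom):
        return "trans"
    return "cis" if abs(int(snp_pos) - int(probe_pos)) <= window_bp else "trans"


def log10_p_from_t(t: np.ndarray, df: int) -> np.ndarray:
    """Two-sided log10 p from a t statistic, evaluated in log space."""
    with np.errstate(invalid="ignore"):
        lp = (np.log(2.0) + stats.t.logsf(np.abs(t), df)) / _LN10
    return np.maximum(lp, LOG10_P_FLOOR)


def _impute_standardize_snps(dosage: np.ndarray) -> np.ndarray:
    d = dosage.copy()
    mean = np.nanmean(d, axis=0)
    mask = ~np.isfinite(d)
    if mask.any():
        d[mask] = np.take(mean, np.nonzero(mask)[1])
    d -= d.mean(axis=0)
    sd = d.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic SNPs yield r = 0
    return d / sd


def screen_associations(
    geno: GenotypeDataset, meth: MethylationDataset, config: ScanConfig | None = None
) -> pd.DataFrame:
    """Stage-1 scan: all SNP x probe simple regressions by blocked matrix
    algebra. Returns a DataFrame (snp_id, probe_id, r, t, log10_p) of pairs
    with p <= p_screen."""
    config = config or ScanConfig()
    if meth.scale_tag != "rank_normal_residual":
        raise ValueError("screen expects rank-normalised residual methylation")
    common = [s for s in meth.sample_ids if s in set(geno.sample_ids)]
    n = len(common)
    if n < 4:
        raise ValueError("need at least 4 samples")
    gi = {s: i for i, s in enumerate(geno.sample_ids)}
    mi = {s: i for i, s in enumerate(meth.sample_ids)}
    gidx = np.array([gi[s] for s in common])
    midx = np.array([mi[s] for s in common])

    Z = _impute_standardize_snps(geno.dosage[gidx])  # [n, m]
    Y = meth.values[:, midx].astype(float)
    Y = Y - Y.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    Y = Y / sd

    # p <= p_screen corresponds to |t| >= t_crit, i.e. r^2 >= threshold
    t_crit = stats.t.isf(config.p_screen / 2.0, n - 2)
    r2_crit = t_crit**2 / (t_crit**2 + n - 2)

    out = []
    for start in range(0, meth.n_probes, config.block_size):
        stop = min(start + config.block_size, meth.n_probes)
        R = (Y[start:stop] @ Z) / n  # [probes, snps] correlations
        hit_p, hit_s = np.nonzero(R**2 >= r2_crit * (1 - 1e-12))
        if hit_p.size == 0:
            continue
        r = R[hit_p, hit_s]
        r2 = np.minimum(r**2, 1.0 - 1e-16)
        t = r * np.sqrt((n - 2) / (1 - r2))
        out.append(
            pd.DataFrame(
                {
                    "snp_id": geno.snp_ids[hit_s],
                    "probe_id": meth.probe_ids[start + hit_p],
                    "r": r,
                    "t": t,
                    "log10_p": log10_p_from_t(t, n - 2),
                }
            )
        )
    if not out:
        return pd.DataFrame(columns=["snp_id", "probe_id", "r", "t", "log10_p"])
    df = pd.concat(out, ignore_index=True)
    return df[df["log10_p"] <= np.log10(config.p_screen)].reset_index(drop=True)


def screen_pvalue_matrix(geno: GenotypeDataset, meth: MethylationDataset) -> np.ndarray:
    """All-pairs log10 p matrix [probes, snps]; used for calibration checks."""
    cfg = ScanConfig(p_screen=1.0, p_discovery=1.0)
    n = meth.n_samples
    Z = _impute_standardize_snps(geno.dosage)
    Y = meth.values - meth.values.mean(axis=1, keepdims=True)
    sd = Y.std(axis=1, keepdims=True)
    sd[sd == 0] = np.inf
    Y = Y / sd
    R = (Y @ Z) / n
    r2 = np.minimum(R**2, 1.0 - 1e-16)
    t = R * np.sqrt((n - 2) / (1 - r2))
    return log10_p_from_t(t, n - 2)


def exact_association(
    geno: GenotypeDataset,
    meth: MethylationDataset,
    covariates: pd.DataFrame | None,
    pairs,
    timepoint: str | None = None,
    probe_annotation=None,
    cis_window_bp: int = DEFAULT_CIS_WINDOW_BP,
) -> list:
    """Stage-2 exact OLS per SNP-CpG pair (methylation ~ dosage + covariates).

    ``pairs`` is an iterable of (snp_id, probe_id). Samples with missing
    dosage are dropped listwise per pair. ``r2`` is the partial variance
    explained by the SNP term, t^2/(t^2+df).
    """
    tp = timepoint if timepoint is not None else meth.timepoint
    gi = {s: i for i, s in enumerate(geno.sample_ids)}
    common = [s for s in meth.sample_ids if s in gi]
    gidx = np.array([gi[s] for s in common])
    midx = meth_sample_index = {s: i for i, s in enumerate(meth.sample_ids)}
    m_idx = np.array([meth_sample_index[s] for s in common])

    if covariates is not None:
        X_cov = covariate_design(covariates.reindex(common)).to_numpy(dtype=float)
    else:
        X_cov = np.ones((len(common), 1))

    snp_lookup = {s: i for i, s in enumerate(geno.snp_ids)}
    probe_lookup = {p: i for i, p in enumerate(meth.probe_ids)}
    probe_coord = None
    if probe_annotation is not None:
        probe_coord = probe_annotation.table[["chrom", "pos_bp"]]

    records = []
    for snp_id, probe_id in pairs:
        if snp_id not in snp_lookup:
            raise KeyError(f"unknown SNP id {snp_id!r}")
        if probe_id not in probe_lookup:
            raise KeyError(f"unknown probe id {probe_id!r}")
        k, j = snp_lookup[snp_id], probe_lookup[probe_id]
        g = geno.dosage[gidx, k]
        y = meth.values[j, m_idx]
        ok = np.isfinite(g) & np.isfinite(y)
        X = np.column_stack([g[ok], X_cov[ok]])
        n_ok = int(ok.sum())
        df_resid = n_ok - X.shape[1]
        if df_resid < 1:
            raise ValueError(f"too few complete samples for pair ({snp_id}, {probe_id})")
        XtX = X.T @ X
        coef, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = y[ok] - X @ coef
        sigma2 = float(resid @ resid) / df_resid
        XtX_inv = np.linalg.pinv(XtX)
        se = float(np.sqrt(max(sigma2 * XtX_inv[0, 0], 0.0)))
        t = coef[0] / se if se > 0 else np.sign(coef[0]) * np.inf
        lp = float(log10_p_from_t(np.array([t]), df_resid)[0])
        r2 = float(t**2 / (t**2 + df_resid)) if np.isfinite(t) else 1.0

        relation, dist = "trans", np.nan
        if probe_coord is not None:
            pc, pp = probe_coord.loc[probe_id, "chrom"], int(probe_coord.loc[probe_id, "pos_bp"])
            relation = classify_cis_trans(geno.chrom[k], int(geno.pos_bp[k]), pc, pp, cis_window_bp)
            if str(geno.chrom[k]) == str(pc):
                dist = float(int(geno.pos_bp[k]) - pp)
        records.append(
            AssociationRecord(
                snp_id=snp_id, probe_id=probe_id, timepoint=tp,
                slope=float(coef[0]), se=se, t_stat=float(t), log10_p=lp, r2=r2,
                relation=relation, distance_bp=dist,
            )
        )
    return records


def select_sentinels(records, geno: GenotypeDataset, window_bp: int = DEFAULT_CIS_WINDOW_BP, p_discovery: float = DEFAULT_P_DISCOVERY) -> list:
    """Sentinel selection at the discovery threshold.

    Per CpG: the smallest-p cis SNP (if any) is the cis sentinel; trans
    records are greedily clumped — repeatedly take the smallest-p remaining
    trans SNP and discard others within +/-``window_bp`` on its chromosome —
    one sentinel per clump. Ties break by |t| descending then snp_id.
    """
    lp_max = np.log10(p_discovery)
    snp_lookup = {s: i for i, s in enumerate(geno.snp_ids)}
    by_probe: dict = {}
    for r in records:
        if r.log10_p <= lp_max:
            by_probe.setdefault(r.probe_id, []).append(r)

    sentinels = []
    for probe_id in sorted(by_probe):
        recs = by_probe[probe_id]
        recs.sort(key=lambda r: (r.log10_p, -abs(r.t_stat), r.snp_id))
        cis = [r for r in recs if r.relation == "cis"]
        if cis:
            sentinels.append(cis[0])
        trans = [r for r in recs if r.relation == "trans"]
        while trans:
            best = trans.pop(0)
            sentinels.append(best)
            k = snp_lookup[best.snp_id]
            bc, bp = geno.chrom[k], int(geno.pos_bp[k])
            trans = [
                r
                for r in trans
                if not (
                    str(geno.chrom[snp_lookup[r.snp_id]]) == str(bc)
                    and abs(int(geno.pos_bp[snp_lookup[r.snp_id]]) - bp) <= window_bp
                )
            ]
    return sentinels
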