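"""Mediation of trans mQTL effects by cis methylation.

For a SNP (or allele score) G with both a cis CpG K and a trans CpG B, the
trans slope is estimated twice — B ~ G and B ~ G + K — and the attenuation
1 - beta_adjusted/beta_unadjusted measures how much of the trans effect is
routed through the cis site. Measurement error in K biases attenuation
toward zero; a multiplicative-error sweep quantifies that sensitivity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset

logger = logging.getLogger(__name__)


@dataclass
class MediationRecord:
    snp_or_score_id: str
    cis_probe_id: str
    trans_probe_id: str
    beta_unadjusted: float
    se_unadjusted: float
    beta_adjusted: float
    se_adjusted: float
    error_sd: float = 0.0
    stable: bool = True
    collinear: bool = False

    @property
    def attenuation(self) -> float:
        if self.collinear or self.beta_unadjusted == 0:
            return np.nan
        return 1.0 - self.beta_adjusted / self.beta_unadjusted


def allele_score(geno: GenotypeDataset, independent_cis_snps, weights=None) -> np.ndarray:
    """Weighted dosage sum over independent cis SNPs (weights default to 1).

    Conditional-model slopes are the intended weights."""
    snps = list(independent_cis_snps)
    if not snps:
        raise ValueError("empty SNP list")
    idx = geno.snp_index(snps)
    w = np.ones(len(snps)) if weights is None else np.asarray(weights, dtype=float)
    if len(w) != len(snps):
        raise ValueError("weights length mismatch")
    D = geno.dosage[:, idx].copy()
    mean = np.nanmean(D, axis=0)
    mask = ~np.isfinite(D)
    if mask.any():
        D[mask] = np.take(mean, np.nonzero(mask)[1])
    return D @ w


def _slope_se(y: np.ndarray, X: np.ndarray):
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.pinv(X.T @ X)
    return float(coef[1]), float(np.sqrt(max(cov[1, 1], 0.0)))


def mediation_test(B: np.ndarray, G: np.ndarray, K: np.ndarray, ids=("G", "K", "B")) -> MediationRecord:
    """Two OLS fits: B ~ G and B ~ G + K.

    Attenuation is flagged unstable when the unadjusted slope is within 2
    SEs of zero, and withheld entirely when K is collinear with G
    (r^2 > 0.999)."""
    B, G, K = (np.asarray(v, dtype=float) for v in (B, G, K))
    n = len(B)
    if n < 30:
        raise ValueError("need >= 30 common samples")
    one = np.ones(n)
    b_un, se_un = _slope_se(B, np.column_stack([one, G]))
    r_gk = np.corrcoef(G, K)[0, 1]
    collinear = r_gk**2 > 0.999
    if collinear:
        logger.warning("cis mediator collinear with genotype (r2=%.4f)", r_gk**2)
        b_adj, se_adj = np.nan, np.nan
    else:
        b_adj, se_adj = _slope_se(B, np.column_stack([one, G, K]))
    stable = abs(b_un) > 2 * se_un
    return MediationRecord(
        snp_or_score_id=ids[0], cis_probe_id=ids[1], trans_probe_id=ids[2],
        beta_unadjusted=b_un, se_unadjusted=se_un,
        beta_adjusted=b_adj, se_adjusted=se_adj,
        stable=stable, collinear=collinear,
    )


def measurement_error_sweep(
    B: np.ndarray,
    G: np.ndarray,
    K_true: np.ndarray,
    error_sds=(0.0, 0.25, 0.5, 1.0),
    n_reps: int = 20,
    seed: int = 0,
    multiplicative: bool = True,
) -> pd.DataFrame:
    """Attenuation vs mediator measurement error.

    At each error level the observed mediator is ``K_true * N(1, sd^2)``
    draws (multiplicative, the default) or ``K_true + N(0, sd^2)``
    (additive); the mediation test is repeated ``n_reps`` times and the
    mean and sd of the attenuation are returned per level.
    """
    sds = list(error_sds)
    if any(s < 0 for s in sds) or sorted(sds) != sds:
        raise ValueError("error_sds must be non-negative and increasing")
    rng = np.random.default_rng(seed)
    rows = []
    for sd in sds:
        atts = []
        reps = 1 if sd == 0 else n_reps
        for _ in range(reps):
            if sd == 0:
                K_obs = K_true
            elif multiplicative:
                K_obs = K_true * rng.normal(1.0, sd, size=len(K_true))
            else:
                K_obs = K_true + rng.normal(0.0, sd, size=len(K_true))
            rec = mediation_test(B, G, K_obs)
            atts.append(rec.attenuation)
        rows.append({"error_sd": sd, "mean_attenuation": float(np.mean(atts)),
                     "sd_attenuation": float(np.std(atts, ddof=1)) if len(atts) > 1 else 0.0,
                     "n_reps": reps})
    return pd.DataFrame(rows)


def candidate_triples(signal_sets, trans_sentinels) -> list:
    """Auto-generate (SNP-or-score, cis probe, trans probe) triples: every
    trans sentinel whose SNP belongs to some probe's independent cis set."""
    snp_to_cis_probe = {}
    for ss in signal_sets:
        for s in ss.snp_ids:
            snp_to_cis_probe.setdefault(s, ss.probe_id)
    triples = []
    for r in trans_sentinels:
        if r.relation != "trans":
            continue
        cis_probe = snp_to_cis_probe.get(r.snp_id)
        if cis_probe is not None and cis_probe != r.probe_id:
            triples.append((r.snp_id, cis_probe, r.probe_id))
    return triples
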