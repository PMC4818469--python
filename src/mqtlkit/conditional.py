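"""Stepwise conditional mapping of independent mQTL per CpG.

Forward-backward stepwise OLS on individual-level data: add the candidate
with the smallest conditional p while it clears the entry threshold,
refitting the joint model at each step and dropping previously selected
SNPs whose joint p rises above the threshold. Candidates nearly collinear
with the selected set (r^2 > 0.999) are skipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import GenotypeDataset, MethylationDataset
from .scan import DEFAULT_P_DISCOVERY, log10_p_from_t

logger = logging.getLogger(__name__)

MAX_SIGNALS_PER_PROBE = 10
COLLINEARITY_R2 = 0.999


@dataclass
class IndependentSignalSet:
    """Ordered independent mQTL for one probe with joint-model statistics."""

    probe_id: str
    timepoint: str
    snp_ids: list = field(default_factory=list)
    slopes: list = field(default_factory=list)
    ses: list = field(default_factory=list)
    log10_p: list = field(default_factory=list)  # conditional (joint-model) p
    marginal_r2: list = field(default_factory=list)

    @property
    def sum_r2(self) -> float:
        return float(sum(self.marginal_r2))

    def __len__(self) -> int:
        return len(self.snp_ids)


def _joint_fit(y: np.ndarray, G: np.ndarray):
    """OLS of y on [1, G]; returns slopes, SEs, t, log10 p for the G terms."""
    n = len(y)
    X = np.column_stack([np.ones(n), G])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    df = n - X.shape[1]
    sigma2 = float(resid @ resid) / df
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(sigma2 * np.diag(XtX_inv), 1e-300))
    t = coef / se
    return coef[1:], se[1:], t[1:], log10_p_from_t(t[1:], df)


def _marginal_r2(y: np.ndarray, g: np.ndarray) -> float:
    gy = np.corrcoef(g, y)[0, 1]
    return float(gy * gy)


def stepwise_conditional(
    geno: GenotypeDataset,
    probe_residuals: np.ndarray,
    candidate_snps,
    p_enter: float = DEFAULT_P_DISCOVERY,
    probe_id: str = "",
    timepoint: str = "",
    max_signals: int = MAX_SIGNALS_PER_PROBE,
) -> IndependentSignalSet:
    """Forward-backward stepwise selection of independent signals.

    ``candidate_snps`` are SNP ids pre-filtered to marginal p <= p_enter;
    ``probe_residuals`` is the probe's residual vector aligned to
    ``geno.sample_ids``.
    """
    y = np.asarray(probe_residuals, dtype=float)
    cand_ids = list(candidate_snps)
    result = IndependentSignalSet(probe_id=probe_id, timepoint=timepoint)
    if not cand_ids:
        return result
    idx = geno.snp_index(cand_ids)
    D = geno.dosage[:, idx].copy()
    col_mean = np.nanmean(D, axis=0)
    mask = ~np.isfinite(D)
    if mask.any():
        D[mask] = np.take(col_mean, np.nonzero(mask)[1])

    lp_enter = np.log10(p_enter)
    selected: list = []  # candidate positions
    while len(selected) < max_signals:
        best_pos, best_lp = None, lp_enter
        for c in range(len(cand_ids)):
            if c in selected:
                continue
            g = D[:, c]
            if g.std() == 0:
                continue
            if selected and _r2_with_set(g, D[:, selected]) > COLLINEARITY_R2:
                logger.info(
                    "probe %s: candidate %s collinear with selected set, skipped",
                    probe_id, cand_ids[c],
                )
                continue
            _, _, _, lps = _joint_fit(y, D[:, selected + [c]])
            lp_new = float(lps[-1])
            if lp_new <= best_lp:
                best_pos, best_lp = c, lp_new
        if best_pos is None:
            break
        selected.append(best_pos)
        # backward check: drop previously selected SNPs losing significance
        while True:
            _, _, _, lps = _joint_fit(y, D[:, selected])
            weak = [i for i, lp in enumerate(lps) if lp > lp_enter and selected[i] != best_pos]
            if not weak:
                break
            drop = weak[int(np.argmax([lps[i] for i in weak]))]
            logger.info("probe %s: dropping %s after backward check", probe_id, cand_ids[selected[drop]])
            selected.pop(drop)
    if len(selected) == max_signals:
        logger.warning("probe %s: signal cap (%d) reached", probe_id, max_signals)

    if selected:
        slopes, ses, _, lps = _joint_fit(y, D[:, selected])
        result.snp_ids = [cand_ids[c] for c in selected]
        result.slopes = [float(b) for b in slopes]
        result.ses = [float(s) for s in ses]
        result.log10_p = [float(lp) for lp in lps]
        result.marginal_r2 = [_marginal_r2(y, D[:, c]) for c in selected]
    return result


def _r2_with_set(g: np.ndarray, S: np.ndarray) -> float:
    """R^2 of g regressed on the selected-SNP matrix S (with intercept)."""
    X = np.column_stack([np.ones(len(g)), S])
    coef, *_ = np.linalg.lstsq(X, g, rcond=None)
    fitted = X @ coef
    tot = float(((g - g.mean()) ** 2).sum())
    if tot == 0:
        return 1.0
    res = float(((g - fitted) ** 2).sum())
    return 1.0 - res / tot


def explained_r2(signal_set: IndependentSignalSet, geno: GenotypeDataset, probe_residuals: np.ndarray):
    """(sum of per-SNP marginal r^2, joint-model r^2) for the retained SNPs.

    The sum of marginal r^2 is the headline explained-variance statistic;
    under LD among retained SNPs it can exceed the joint value, so both are
    returned.
    """
    if len(signal_set) == 0:
        raise ValueError("empty signal set")
    y = np.asarray(probe_residuals, dtype=float)
    idx = geno.snp_index(signal_set.snp_ids)
    D = geno.dosage[:, idx].copy()
    col_mean = np.nanmean(D, axis=0)
    mask = ~np.isfinite(D)
    if mask.any():
        D[mask] = np.take(col_mean, np.nonzero(mask)[1])
    sum_marginal = float(sum(_marginal_r2(y, D[:, c]) for c in range(D.shape[1])))
    joint = _r2_of_fit(y, D)
    return sum_marginal, joint


def _r2_of_fit(y: np.ndarray, D: np.ndarray) -> float:
    X = np.column_stack([np.ones(len(y)), D])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    tot = float(((y - y.mean()) ** 2).sum())
    return 1.0 - float(resid @ resid) / tot if tot > 0 else 0.0


def conditional_scan(
    geno: GenotypeDataset,
    meth: MethylationDataset,
    records,
    p_enter: float = DEFAULT_P_DISCOVERY,
    include_trans: bool = False,
) -> list:
    """Run stepwise conditional mapping for every probe with discovery-level
    records. By default only cis candidates enter the stepwise model."""
    by_probe: dict = {}
    lp = np.log10(p_enter)
    for r in records:
        if r.log10_p <= lp and (include_trans or r.relation == "cis"):
            by_probe.setdefault(r.probe_id, []).append(r.snp_id)
    sample_map = {s: i for i, s in enumerate(meth.sample_ids)}
    midx = np.array([sample_map[s] for s in geno.sample_ids])
    out = []
    probe_lookup = {p: i for i, p in enumerate(meth.probe_ids)}
    for probe_id in sorted(by_probe):
        y = meth.values[probe_lookup[probe_id], midx]
        out.append(
            stepwise_conditional(
                geno, y, sorted(set(by_probe[probe_id])), p_enter=p_enter,
                probe_id=probe_id, timepoint=meth.timepoint,
            )
        )
    return out
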