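"""Enrichment of mQTL in complex-trait genetics.

Two designs share the matched-null machinery:

* GWAS enrichment — Fisher's combined chi-square over the GWAS p-values of
  LD-pruned mQTL SNPs, compared with draws of pool SNPs matched on MAF bin,
  LD-proxy-count bin and (optionally) annotation category;
* trait variance-component enrichment — the liability-scale mQTL variance
  component of a case-control trait, compared with the same REML fit run
  on matched null SNP sets.

Empirical p-values use the add-one rank rule (1 + #{null >= observed}) /
(1 + n_draws) and can therefore never be zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .datamodel import EnrichmentResult, GenotypeDataset, GwasSummary

logger = logging.getLogger(__name__)

DEFAULT_LD_PRUNE_R2 = 0.1
DEFAULT_PROXY_R2 = 0.8
DEFAULT_PROXY_WINDOW_BP = 1_000_000
DEFAULT_N_DRAWS_GWAS = 1000
DEFAULT_N_DRAWS_TRAIT = 100

#: SNP annotation categories treated as gene-proximal for the genic pool
GENIC_CATEGORIES = frozenset({"5'UTR", "3'UTR", "intronic", "upstream", "downstream"})

_LD_BIN_EDGES = np.array([0, 1, 2, 5, 10, np.inf])  # {0},{1},{2-4},{5-9},{>=10}


@dataclass
class MatchingSpec:
    """How null SNPs are matched to the target set."""

    maf_bins: np.ndarray = field(default_factory=lambda: np.linspace(0.0, 0.5, 26))
    ld_bin_edges: np.ndarray = field(default_factory=lambda: _LD_BIN_EDGES.copy())
    annotation_mode: str = "annotation_matched"  # or "genic_only"
    n_draws: int = DEFAULT_N_DRAWS_GWAS
    seed: int = 0
    relax: bool = False  # fall back to marginal MAF matching on empty cells

    def __post_init__(self) -> None:
        if self.annotation_mode not in ("genic_only", "annotation_matched"):
            raise ValueError(f"unknown annotation_mode {self.annotation_mode!r}")


# ---------------------------------------------------------------------------
# LD utilities


def _standardized(geno: GenotypeDataset, idx: np.ndarray) -> np.ndarray:
    D = geno.dosage[:, idx].astype(float)
    mean = np.nanmean(D, axis=0)
    mask = ~np.isfinite(D)
    if mask.any():
        D[mask] = np.take(mean, np.nonzero(mask)[1])
    D -= D.mean(axis=0)
    sd = D.std(axis=0)
    sd[sd == 0] = np.inf
    return D / sd


def snp_r2(geno: GenotypeDataset, i: int, j: int) -> float:
    Z = _standardized(geno, np.array([i, j]))
    r = float(Z[:, 0] @ Z[:, 1]) / geno.n_samples
    return r * r


def prune_ld(snp_set, geno: GenotypeDataset, r2_max: float = DEFAULT_LD_PRUNE_R2, log10_p=None) -> list:
    """Greedy LD pruning of a SNP set: iterate SNPs by ascending mQTL p
    (``log10_p`` parallel to ``snp_set``; input order if omitted), keeping
    a SNP iff its r^2 with every kept SNP is <= ``r2_max``."""
    if not (0 < r2_max < 1):
        raise ValueError("r2_max must lie in (0,1)")
    snps = list(snp_set)
    order = np.argsort(log10_p, kind="stable") if log10_p is not None else np.arange(len(snps))
    idx = geno.snp_index(snps)
    Z = _standardized(geno, idx)
    n = geno.n_samples
    kept: list = []
    kept_cols: list = []
    for o in order:
        col = Z[:, o]
        if all((float(col @ Z[:, kc]) / n) ** 2 <= r2_max for kc in kept_cols):
            kept.append(snps[o])
            kept_cols.append(o)
    return kept


def ld_proxy_count(
    geno: GenotypeDataset,
    snp_idx=None,
    r2_min: float = DEFAULT_PROXY_R2,
    window_bp: int = DEFAULT_PROXY_WINDOW_BP,
) -> np.ndarray:
    """Number of other SNPs within +/-``window_bp`` with dosage r^2 >
    ``r2_min``, per SNP (all SNPs by default)."""
    idx = np.arange(geno.n_snps) if snp_idx is None else np.asarray(snp_idx)
    Z = _standardized(geno, np.arange(geno.n_snps))
    n = geno.n_samples
    counts = np.zeros(len(idx), dtype=int)
    for out_i, k in enumerate(idx):
        near = (
            (np.arange(geno.n_snps) != k)
            & (geno.chrom == geno.chrom[k])
            & (np.abs(geno.pos_bp - geno.pos_bp[k]) <= window_bp)
        )
        if near.any():
            r = (Z[:, near].T @ Z[:, k]) / n
            counts[out_i] = int(np.sum(r * r > r2_min))
    return counts


# ---------------------------------------------------------------------------
# matched null draws


def _joint_cells(geno: GenotypeDataset, idx: np.ndarray, spec: MatchingSpec, proxy_counts: np.ndarray):
    maf_bin = np.digitize(geno.maf[idx], spec.maf_bins[1:-1], right=True)
    ld_bin = np.digitize(proxy_counts[idx], spec.ld_bin_edges[1:-1], right=False)
    if spec.annotation_mode == "annotation_matched":
        annot = np.array([str(a) for a in geno.annotation[idx]], dtype=object)
    else:
        annot = np.array(["*"] * len(idx), dtype=object)
    return list(zip(maf_bin.tolist(), ld_bin.tolist(), annot.tolist()))


def _pool_indices(geno: GenotypeDataset, target_idx: np.ndarray, spec: MatchingSpec, pool=None) -> np.ndarray:
    if pool is not None:
        p_idx = geno.snp_index(list(pool)) if not isinstance(pool, np.ndarray) else pool
    else:
        p_idx = np.arange(geno.n_snps)
    if spec.annotation_mode == "genic_only":
        genic = np.array([str(a) in GENIC_CATEGORIES for a in geno.annotation])
        p_idx = p_idx[genic[p_idx]]
    return np.setdiff1d(p_idx, target_idx)


class MatchedNullSampler:
    """Pre-bins a SNP pool so that repeated matched draws are cheap.

    Each target SNP is matched on joint (MAF bin x LD-proxy bin
    [x annotation]) cell; within one draw, targets sharing a cell receive
    distinct pool SNPs.
    """

    def __init__(self, geno: GenotypeDataset, target_snps, spec: MatchingSpec, pool=None, proxy_counts: np.ndarray | None = None):
        self.geno = geno
        self.spec = spec
        self.target_idx = geno.snp_index(list(target_snps))
        if proxy_counts is None:
            proxy_counts = ld_proxy_count(geno)
        self.proxy_counts = proxy_counts
        pool_idx = _pool_indices(geno, self.target_idx, spec, pool)
        pool_cells = _joint_cells(geno, pool_idx, spec, proxy_counts)
        self.cell_pools: dict = {}
        for i, cell in zip(pool_idx, pool_cells):
            self.cell_pools.setdefault(cell, []).append(i)
        self.cell_pools = {c: np.array(v) for c, v in self.cell_pools.items()}

        target_cells = _joint_cells(geno, self.target_idx, spec, proxy_counts)
        self.cell_counts: dict = {}
        for cell in target_cells:
            self.cell_counts[cell] = self.cell_counts.get(cell, 0) + 1
        for cell, need in self.cell_counts.items():
            have = len(self.cell_pools.get(cell, ()))
            if have < need and not spec.relax:
                raise ValueError(
                    f"matched-null cell {cell} has {have} pool SNPs but needs "
                    f"{need}; pass relax=True for marginal MAF matching"
                )
            # relax: cells too small for independent draws fall back to the
            # marginal MAF bin (a pool several times the demand keeps null
            # draws close to independent)
            if spec.relax and have < 10 * need:
                # marginal MAF-bin pool, widened to neighbouring bins until
                # the cell can be drawn several times over
                for width in range(0, len(spec.maf_bins)):
                    maf_only = [
                        i
                        for c, v in self.cell_pools.items()
                        if abs(c[0] - cell[0]) <= width
                        for i in v
                    ]
                    if len(maf_only) >= max(need, min(10 * need, 50)):
                        break
                if len(maf_only) < need:
                    raise ValueError(f"cannot relax cell {cell}: pool exhausted")
                self.cell_pools[cell] = np.unique(np.array(maf_only))

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One matched draw: SNP indices, one per target, distinct across
        the whole draw (relaxed cells may share pool SNPs, so uniqueness is
        enforced globally)."""
        out: list = []
        used: set = set()
        # tightest cells first so shared (relaxed) pools are not exhausted
        order = sorted(
            self.cell_counts.items(),
            key=lambda kv: (len(self.cell_pools[kv[0]]) - kv[1], str(kv[0])),
        )
        for cell, need in order:
            pool = self.cell_pools[cell]
            avail = pool[~np.isin(pool, list(used))] if used else pool
            if len(avail) < need:
                if not self.spec.relax:
                    raise ValueError(f"cell {cell} exhausted after global dedup")
                everything = np.concatenate(list(self.cell_pools.values()))
                extra = np.setdiff1d(everything, np.concatenate([avail, np.array(sorted(used), dtype=int)]))
                avail = np.concatenate([avail, extra])
                if len(avail) < need:
                    raise ValueError(f"cell {cell} exhausted even after relaxation")
            pick = rng.choice(avail, size=need, replace=False)
            used.update(pick.tolist())
            out.append(pick)
        return np.concatenate(out)

    def draw_matrix(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """[n_draws, n_targets] of pool SNP indices."""
        cols = []
        for cell, need in sorted(self.cell_counts.items(), key=lambda kv: str(kv[0])):
            pool = self.cell_pools[cell]
            if len(pool) == need:
                cols.append(np.tile(pool, (n_draws, 1)))
                continue
            # argsort of uniforms = independent permutations per draw
            u = rng.random((n_draws, len(pool)))
            take = np.argsort(u, axis=1)[:, :need]
            cols.append(pool[take])
        return np.concatenate(cols, axis=1)


def matched_null_draw(target_snps, geno: GenotypeDataset, spec: MatchingSpec, pool=None, proxy_counts=None) -> np.ndarray:
    """One matched null draw; returns SNP ids."""
    sampler = MatchedNullSampler(geno, target_snps, spec, pool=pool, proxy_counts=proxy_counts)
    rng = np.random.default_rng(spec.seed)
    return geno.snp_ids[sampler.draw(rng)]


# ---------------------------------------------------------------------------
# Fisher's method


def fisher_combined(p_values) -> tuple:
    """Fisher's combined statistic -2 sum(ln p) with its chi-square df and
    combined p (survival function evaluated in log space)."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    statistic = float(-2.0 * np.sum(np.log(p)))
    df = 2 * p.size
    combined_p = float(np.exp(stats.chi2.logsf(statistic, df)))
    return statistic, df, combined_p


# ---------------------------------------------------------------------------
# enrichment tests


def gwas_enrichment(
    mqtl_snps,
    gwas: GwasSummary,
    geno: GenotypeDataset,
    spec: MatchingSpec,
    pool=None,
    proxy_counts=None,
) -> EnrichmentResult:
    """Fisher-statistic enrichment of mQTL SNPs in one GWAS against matched
    null draws. mQTL SNPs absent from the GWAS are logged and dropped."""
    gwas_p = gwas.table.set_index("snp_id")["p"]
    targets = [s for s in mqtl_snps if s in gwas_p.index]
    dropped = len(list(mqtl_snps)) - len(targets)
    if dropped:
        logger.warning("%s: %d mQTL SNPs absent from GWAS, dropped", gwas.trait_name, dropped)
    if len(targets) < 10:
        raise ValueError(f"{gwas.trait_name}: fewer than 10 mQTL SNPs with GWAS p")

    observed, _, _ = fisher_combined(gwas_p[targets].to_numpy())

    sampler = MatchedNullSampler(geno, targets, spec, pool=pool, proxy_counts=proxy_counts)
    rng = np.random.default_rng(spec.seed)
    # -2 ln p per pool SNP, indexed by genotype SNP position
    neg2ln = -2.0 * np.log(gwas_p.reindex(geno.snp_ids).to_numpy(dtype=float))
    draws = sampler.draw_matrix(spec.n_draws, rng)
    null_stats = np.nansum(neg2ln[draws], axis=1)
    return EnrichmentResult(
        trait_name=gwas.trait_name,
        observed_statistic=observed,
        null_statistics=null_stats,
        n_target_snps=len(targets),
        mode=spec.annotation_mode,
    )


def trait_varcomp_enrichment(
    trait01,
    geno: GenotypeDataset,
    mqtl_snps,
    spec: MatchingSpec,
    covariates=None,
    prevalence: float | None = None,
    exclude_chroms=("6",),
    proxy_counts=None,
    max_nonconverged_frac: float = 0.2,
    trait_name: str = "trait",
) -> EnrichmentResult:
    """Liability-scale mQTL variance component against matched null SNP
    sets (the REML fit repeated per draw)."""
    from .varcomp import partition_trait_variance

    keep_chrom = ~np.isin(np.array([str(c) for c in geno.chrom]), [str(c) for c in exclude_chroms])
    targets = [s for s in mqtl_snps if keep_chrom[geno.snp_index([s])[0]]]
    decomp, liab = partition_trait_variance(
        trait01, geno, targets, covariates=covariates,
        exclude_chroms=exclude_chroms, prevalence=prevalence, name=trait_name,
    )
    observed = liab["h2_liab_mqtl"]

    pool = np.flatnonzero(keep_chrom)
    sampler = MatchedNullSampler(geno, targets, spec, pool=pool, proxy_counts=proxy_counts)
    rng = np.random.default_rng(spec.seed)
    null_stats = []
    n_bad = 0
    for _ in range(spec.n_draws):
        null_ids = geno.snp_ids[sampler.draw(rng)]
        d, l = partition_trait_variance(
            trait01, geno, null_ids, covariates=covariates,
            exclude_chroms=exclude_chroms, prevalence=prevalence, name=trait_name,
        )
        if not d.converged:
            n_bad += 1
        null_stats.append(l["h2_liab_mqtl"])
    if n_bad > max_nonconverged_frac * spec.n_draws:
        raise RuntimeError(
            f"REML failed to converge in {n_bad}/{spec.n_draws} null draws"
        )
    return EnrichmentResult(
        trait_name=trait_name,
        observed_statistic=observed,
        null_statistics=np.array(null_stats),
        n_target_snps=len(targets),
        mode=spec.annotation_mode,
    )
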