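"""Synthetic cohort generation.

The generator emulates the statistical structure of a two-generation,
five-timepoint blood-methylation study: children measured at birth,
childhood and adolescence (the same individuals longitudinally) and their
mothers during pregnancy and in middle age. Methylation at each CpG probe
is driven by

* a *cis* genetic component (one or a few SNPs within +/-1 Mb),
* a polygenic *trans* component (many small effects on distant SNPs),
* cell-composition and batch covariate terms (the confounding that
  covariate adjustment must remove), and
* environmental noise whose standard deviation grows with age — the
  "stable genetics, rising environmental perturbation" scenario.

Genetic contributions are identical across timepoints for shared
individuals; only the environmental draw differs. A truth table records
the realized per-probe variance fractions for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit, ndtri

from .datamodel import (
    GENIC_FEATURE_CATEGORIES,
    ISLAND_RELATION_CATEGORIES,
    SNP_ANNOTATION_CATEGORIES,
    GenotypeDataset,
    MethylationDataset,
    ProbeAnnotation,
)

# share of simulated SNPs per annotation category (roughly array-like:
# mostly intronic/intergenic, few UTR hits)
_SNP_ANNOTATION_PROBS = {
    "5'UTR": 0.03,
    "3'UTR": 0.04,
    "intronic": 0.38,
    "intergenic": 0.30,
    "upstream": 0.08,
    "downstream": 0.07,
    "unannotated": 0.10,
}

_GENIC_FEATURE_PROBS = (0.15, 0.10, 0.35, 0.08, 0.32)
_ISLAND_RELATION_PROBS = (0.30, 0.12, 0.11, 0.05, 0.05, 0.37)

_BLOCK_SPACING_BP = 3_000_000  # keeps cross-block pairs outside the +/-1 Mb cis window
_SNP_SPACING_BP = 5_000


@dataclass
class Timepoint:
    label: str
    age_years: float
    generation: str  # "child" | "mother"


DEFAULT_TIMEPOINTS = (
    Timepoint("birth", 0.0, "child"),
    Timepoint("childhood", 7.0, "child"),
    Timepoint("adolescence", 17.0, "child"),
    Timepoint("pregnancy", 30.0, "mother"),
    Timepoint("middle_age", 48.0, "mother"),
)


@dataclass
class CohortSpec:
    """Sampling design of the synthetic cohort.

    ``env_sd_by_age`` maps age in years to a multiplier on the
    environmental standard deviation; it must be non-decreasing in age when
    emulating the rising-perturbation scenario (the default: +1 % per
    year). Children share identity across the child timepoints, mothers
    across the mother timepoints; the two generations are disjoint
    individuals.
    """

    n_children: int = 400
    n_mothers: int = 400
    timepoints: tuple = DEFAULT_TIMEPOINTS
    env_sd_by_age: dict | None = None
    n_cell_types: int = 6
    n_batches: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.env_sd_by_age is None:
            self.env_sd_by_age = {
                tp.age_years: 1.0 + 0.01 * tp.age_years for tp in self.timepoints
            }
        ages = sorted(self.env_sd_by_age)
        if any(a < 0 for a in ages):
            raise ValueError("ages must be non-negative")

    def env_multiplier(self, age: float) -> float:
        return float(self.env_sd_by_age[age])

    def sample_ids(self, generation: str) -> np.ndarray:
        if generation == "child":
            return np.array([f"C{i:05d}" for i in range(self.n_children)], dtype=object)
        return np.array([f"M{i:05d}" for i in range(self.n_mothers)], dtype=object)


@dataclass
class ProbeArchitecture:
    """Genetic architecture of one probe: causal SNP indices and targets."""

    probe_id: str
    chrom: str
    pos_bp: int
    cis_snp_idx: np.ndarray
    cis_effects: np.ndarray
    trans_snp_idx: np.ndarray
    trans_effects: np.ndarray
    target_h2_cis: float
    target_h2_trans: float

    def __post_init__(self) -> None:
        if self.target_h2_cis + self.target_h2_trans >= 1:
            raise ValueError(
                f"{self.probe_id}: target_h2_cis + target_h2_trans must be < 1"
            )


@dataclass
class MediationMotif:
    """SNP -> cis probe (path a) -> trans probe (path b), direct path c."""

    snp_idx: int
    cis_probe_id: str
    trans_probe_id: str
    a: float
    b: float
    c: float = 0.0


@dataclass
class TraitSpec:
    """Liability-threshold case-control trait."""

    causal_snp_idx: np.ndarray
    h2_liability: float
    prevalence: float  # K
    case_proportion: float  # P, after ascertainment

    def __post_init__(self) -> None:
        if not (0 < self.prevalence <= self.case_proportion < 1):
            raise ValueError("need 0 < K <= P < 1")
        if not (0 <= self.h2_liability < 1):
            raise ValueError("h2_liability must be in [0, 1)")


@dataclass
class ArchitectureSpec:
    probes: list  # of ProbeArchitecture
    mediation_motifs: list = field(default_factory=list)
    trait_spec: TraitSpec | None = None


# ---------------------------------------------------------------------------
# genotypes


def simulate_genotypes(
    n_samples: int,
    n_blocks: int = 20,
    snps_per_block: int = 25,
    maf_range: tuple = (0.05, 0.5),
    ld_rho: float = 0.8,
    seed: int = 0,
    n_chromosomes: int = 5,
    sample_ids: np.ndarray | None = None,
) -> GenotypeDataset:
    """Simulate LD-block genotypes by first-order haplotype copying.

    Within a block all SNPs share one allele frequency; each haplotype's
    allele at SNP j+1 copies SNP j with probability ``ld_rho`` and is drawn
    fresh otherwise, giving adjacent-SNP haplotype correlation exactly
    ``ld_rho``. Blocks are laid >=2 Mb apart so every cross-block pair is a
    trans relation under the +/-1 Mb cis rule.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if not (0 <= ld_rho < 1):
        raise ValueError("ld_rho must be in [0, 1)")
    lo, hi = maf_range
    if not (0.01 < lo < hi <= 0.5):
        raise ValueError("maf_range must lie within (0.01, 0.5]")
    rng = np.random.default_rng(seed)
    m = n_blocks * snps_per_block
    block_maf = rng.uniform(lo, hi, size=n_blocks)

    dosage = np.empty((n_samples, m))
    for b in range(n_blocks):
        p = block_maf[b]
        hap = np.empty((2 * n_samples, snps_per_block), dtype=np.int8)
        hap[:, 0] = rng.random(2 * n_samples) < p
        for j in range(1, snps_per_block):
            fresh = rng.random(2 * n_samples) < p
            copy = rng.random(2 * n_samples) < ld_rho
            hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
        block_dosage = hap[:n_samples] + hap[n_samples:]
        dosage[:, b * snps_per_block : (b + 1) * snps_per_block] = block_dosage

    blocks_per_chrom = int(np.ceil(n_blocks / n_chromosomes))
    chrom = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=np.int64)
    for b in range(n_blocks):
        c = b // blocks_per_chrom + 1
        local = b % blocks_per_chrom
        start = 1_000_000 + local * _BLOCK_SPACING_BP
        sl = slice(b * snps_per_block, (b + 1) * snps_per_block)
        chrom[sl] = str(c)
        pos[sl] = start + np.arange(snps_per_block) * _SNP_SPACING_BP

    cats = np.array(list(_SNP_ANNOTATION_PROBS), dtype=object)
    probs = np.array(list(_SNP_ANNOTATION_PROBS.values()))
    annotation = rng.choice(cats, size=m, p=probs / probs.sum())
    tag_set = rng.random(m) < 0.5
    alleles = np.tile(np.array([["A", "G"]], dtype=object), (m, 1))
    with np.errstate(invalid="ignore"):
        p_hat = dosage.mean(axis=0) / 2.0
    if sample_ids is None:
        sample_ids = np.array([f"S{i:05d}" for i in range(n_samples)], dtype=object)
    return GenotypeDataset(
        sample_ids=sample_ids,
        snp_ids=np.array([f"snp{k:06d}" for k in range(m)], dtype=object),
        dosage=dosage,
        chrom=chrom,
        pos_bp=pos,
        alleles=alleles,
        maf=np.minimum(p_hat, 1 - p_hat),
        annotation=annotation,
        tag_set_flag=tag_set,
    )


def simulate_cohort_genotypes(cohort: CohortSpec, **kwargs) -> GenotypeDataset:
    """Genotypes for the full cohort (children + mothers, disjoint ids)."""
    ids = np.concatenate([cohort.sample_ids("child"), cohort.sample_ids("mother")])
    kwargs.setdefault("seed", cohort.seed)
    return simulate_genotypes(n_samples=len(ids), sample_ids=ids, **kwargs)


# ---------------------------------------------------------------------------
# probe architectures


def random_architecture(
    geno: GenotypeDataset,
    n_probes: int,
    h2_cis: float = 0.2,
    h2_trans: float = 0.15,
    n_cis_snps: int = 1,
    n_trans_snps: int = 20,
    prob_null: float = 0.0,
    seed: int = 0,
) -> ArchitectureSpec:
    """Draw a generic architecture: each probe sits inside one LD block,
    takes its cis SNPs from that block and spreads the trans component over
    ``n_trans_snps`` distant SNPs with equal variance shares.
    """
    rng = np.random.default_rng(seed)
    snp_block = _infer_blocks(geno)
    block_ids = np.unique(snp_block)
    probes = []
    for j in range(n_probes):
        b = block_ids[rng.integers(len(block_ids))]
        members = np.flatnonzero(snp_block == b)
        anchor = members[rng.integers(len(members))]
        null = rng.random() < prob_null
        cis_n = min(n_cis_snps, len(members))
        cis_idx = rng.choice(members, size=cis_n, replace=False)
        far = np.flatnonzero(snp_block != b)
        trans_idx = rng.choice(far, size=min(n_trans_snps, len(far)), replace=False)
        probes.append(
            ProbeArchitecture(
                probe_id=f"cg{j:06d}",
                chrom=str(geno.chrom[anchor]),
                pos_bp=int(geno.pos_bp[anchor]) + 500,
                cis_snp_idx=cis_idx,
                cis_effects=rng.choice([-1.0, 1.0], size=cis_n),
                trans_snp_idx=trans_idx,
                trans_effects=rng.choice([-1.0, 1.0], size=len(trans_idx)),
                target_h2_cis=0.0 if null else h2_cis,
                target_h2_trans=0.0 if null else h2_trans,
            )
        )
    return ArchitectureSpec(probes=probes)


def _infer_blocks(geno: GenotypeDataset) -> np.ndarray:
    """Group SNPs into (chrom, >=2 Mb gap) blocks from coordinates."""
    block = np.zeros(geno.n_snps, dtype=int)
    current = 0
    for k in range(1, geno.n_snps):
        if (
            geno.chrom[k] != geno.chrom[k - 1]
            or geno.pos_bp[k] - geno.pos_bp[k - 1] > 2_000_000
        ):
            current += 1
        block[k] = current
    return block


def probe_manifest(arch: ArchitectureSpec, seed: int = 0, frac_flagged: float = 0.05) -> ProbeAnnotation:
    """Manifest-like annotation table for the simulated probes."""
    rng = np.random.default_rng(seed)
    n = len(arch.probes)
    genic = rng.choice(
        np.array(GENIC_FEATURE_CATEGORIES, dtype=object), size=n, p=_GENIC_FEATURE_PROBS
    )
    island = rng.choice(
        np.array(ISLAND_RELATION_CATEGORIES, dtype=object), size=n, p=_ISLAND_RELATION_PROBS
    )
    flags = np.where(
        rng.random(n) < frac_flagged,
        rng.choice(
            np.array(["multi_mapping", "snp_at_cpg", "potentially_problematic"], dtype=object),
            size=n,
        ),
        "",
    )
    df = pd.DataFrame(
        {
            "chrom": [p.chrom for p in arch.probes],
            "pos_bp": [p.pos_bp for p in arch.probes],
            "genic_feature": genic,
            "island_relation": island,
            "qc_flags": flags,
        },
        index=pd.Index([p.probe_id for p in arch.probes], name="probe_id"),
    )
    return ProbeAnnotation(df)


# ---------------------------------------------------------------------------
# methylation


def _scaled_component(dosage: np.ndarray, idx: np.ndarray, effects: np.ndarray, target_var: float) -> np.ndarray:
    """Linear genetic score rescaled to hit the target variance exactly
    (over the full cohort), or zeros if the target or score variance is 0."""
    if len(idx) == 0 or target_var <= 0:
        return np.zeros(dosage.shape[0])
    g = dosage[:, idx] @ effects
    v = g.var()
    if v <= 0:
        return np.zeros(dosage.shape[0])
    return (g - g.mean()) * np.sqrt(target_var / v)


def simulate_methylation(
    geno: GenotypeDataset,
    cohort: CohortSpec,
    arch: ArchitectureSpec,
    sigmoid_scale: float = 0.35,
):
    """Simulate beta-scale methylation for every timepoint.

    Returns ``(meth_by_timepoint, covariates_by_timepoint, truth)`` where
    ``truth`` is a DataFrame of realized variance fractions per probe per
    timepoint. The genetic contribution of a shared individual is
    bit-identical across timepoints; environmental noise is redrawn with an
    age-dependent standard deviation; cell-composition (Dirichlet) and
    batch terms are added on top of the genetic+environmental latent so
    that covariate residualization has real confounding to remove.
    """
    rng = np.random.default_rng(cohort.seed)
    sample_pos = {s: i for i, s in enumerate(geno.sample_ids)}
    probes = arch.probes
    n_probes = len(probes)

    # fixed (per-individual) genetic components, shared across timepoints
    g_cis = np.zeros((n_probes, geno.n_samples))
    g_trans = np.zeros((n_probes, geno.n_samples))
    for j, pa in enumerate(probes):
        g_cis[j] = _scaled_component(geno.dosage, pa.cis_snp_idx, pa.cis_effects, pa.target_h2_cis)
        g_trans[j] = _scaled_component(geno.dosage, pa.trans_snp_idx, pa.trans_effects, pa.target_h2_trans)

    # mediation motifs rewire the trans probe's genetic input through the
    # cis probe's latent value (handled per-timepoint below)
    motif_by_trans = {m.trans_probe_id: m for m in arch.mediation_motifs}
    probe_pos = {pa.probe_id: j for j, pa in enumerate(probes)}

    baseline = rng.uniform(0.05, 0.95, size=n_probes)
    cell_loadings = rng.normal(0, 0.3, size=(n_probes, cohort.n_cell_types))
    batch_effects = rng.normal(0, 0.15, size=(n_probes, cohort.n_batches))

    meth_by_tp: dict = {}
    cov_by_tp: dict = {}
    truth_rows = []
    for tp in cohort.timepoints:
        ids = cohort.sample_ids(tp.generation)
        n = len(ids)
        if n == 0:
            continue
        cols = np.array([sample_pos[s] for s in ids], dtype=int)
        env_mult = cohort.env_multiplier(tp.age_years)

        cell = rng.dirichlet(np.full(cohort.n_cell_types, 5.0), size=n)
        batch = rng.integers(cohort.n_batches, size=n)
        sex = rng.integers(2, size=n)

        latent = np.empty((n_probes, n))
        env_sd = np.empty(n_probes)
        for j, pa in enumerate(probes):
            env_sd[j] = np.sqrt(max(1.0 - pa.target_h2_cis - pa.target_h2_trans, 1e-12)) * env_mult
        noise = rng.normal(0, 1, size=(n_probes, n)) * env_sd[:, None]
        latent = g_cis[:, cols] + g_trans[:, cols] + noise

        # mediation: trans probe receives b * (cis probe latent) + direct c*G
        for m in arch.mediation_motifs:
            jt = probe_pos[m.trans_probe_id]
            jc = probe_pos[m.cis_probe_id]
            gsnp = geno.dosage[cols, m.snp_idx]
            gsnp = (gsnp - gsnp.mean()) / max(gsnp.std(), 1e-12)
            latent[jt] = latent[jt] + m.b * latent[jc] + m.c * gsnp

        full = latent + (cell @ cell_loadings.T).T + batch_effects[:, batch]
        beta = expit(logit(baseline)[:, None] + sigmoid_scale * full)
        beta = np.clip(beta, 1e-6, 1 - 1e-6)

        meth_by_tp[tp.label] = MethylationDataset(
            probe_ids=np.array([pa.probe_id for pa in probes], dtype=object),
            sample_ids=ids,
            values=beta,
            timepoint=tp.label,
            age_years=tp.age_years,
            scale_tag="beta",
        )
        cov = pd.DataFrame(
            {
                "age": tp.age_years,
                "sex": sex if tp.generation == "child" else 1,
                "batch": batch,
            },
            index=pd.Index(ids, name="sample_id"),
        )
        for c in range(cohort.n_cell_types):
            cov[f"cell_{c}"] = cell[:, c]
        cov_by_tp[tp.label] = cov

        var_tot = latent.var(axis=1)
        for j, pa in enumerate(probes):
            truth_rows.append(
                {
                    "probe_id": pa.probe_id,
                    "timepoint": tp.label,
                    "age_years": tp.age_years,
                    "h2_cis": g_cis[j, cols].var() / var_tot[j] if var_tot[j] > 0 else 0.0,
                    "h2_trans": g_trans[j, cols].var() / var_tot[j] if var_tot[j] > 0 else 0.0,
                    "target_h2_cis": pa.target_h2_cis,
                    "target_h2_trans": pa.target_h2_trans,
                    "cis_snps": ",".join(geno.snp_ids[pa.cis_snp_idx]),
                    "trans_snps": ",".join(geno.snp_ids[pa.trans_snp_idx]),
                }
            )

    truth = pd.DataFrame(truth_rows)
    return meth_by_tp, cov_by_tp, truth


# ---------------------------------------------------------------------------
# traits


def simulate_trait(geno: GenotypeDataset, trait_spec: TraitSpec, seed: int = 0):
    """Liability-threshold case-control trait with optional ascertainment.

    Returns ``(case_status, truth)``: ``case_status`` is a 0/1 Series over
    the ascertained samples (case proportion ``P``); ``truth`` records the
    liability parameters and threshold.
    """
    rng = np.random.default_rng(seed)
    K, P, h2 = trait_spec.prevalence, trait_spec.case_proportion, trait_spec.h2_liability
    idx = np.asarray(trait_spec.causal_snp_idx, dtype=int)
    if h2 > 0 and len(idx) > 0:
        g = geno.dosage[:, idx] @ rng.normal(0, 1, size=len(idx))
        g = (g - g.mean()) / max(g.std(), 1e-12) * np.sqrt(h2)
    else:
        g = np.zeros(geno.n_samples)
    liability = g + rng.normal(0, np.sqrt(max(1 - h2, 1e-12)), size=geno.n_samples)
    threshold = ndtri(1 - K)
    case = liability > threshold

    n_case = int(case.sum())
    ctrl_idx = np.flatnonzero(~case)
    if n_case == 0 or len(ctrl_idx) == 0:
        raise ValueError(
            f"case proportion {P} unattainable: {n_case} cases, "
            f"{len(ctrl_idx)} controls simulated"
        )
    # ascertain toward case fraction P, keeping as many samples as possible
    if n_case / geno.n_samples < P:
        case_keep = np.flatnonzero(case)
        n_ctrl_needed = int(np.floor(n_case * (1 - P) / P))
        ctrl_keep = rng.choice(ctrl_idx, min(n_ctrl_needed, len(ctrl_idx)), replace=False)
    else:
        ctrl_keep = ctrl_idx
        n_case_needed = min(int(np.ceil(len(ctrl_idx) * P / (1 - P))), n_case)
        case_keep = rng.choice(np.flatnonzero(case), n_case_needed, replace=False)
    n_ctrl_needed = len(ctrl_keep)
    n_case = len(case_keep)
    keep = np.concatenate([case_keep, ctrl_keep])
    keep.sort()
    status = pd.Series(case[keep].astype(int), index=geno.sample_ids[keep], name="case")
    truth = {
        "h2_liability": h2,
        "prevalence": K,
        "case_proportion": P,
        "threshold": float(threshold),
        "n_cases": n_case,
        "n_controls": n_ctrl_needed,
        "causal_snps": geno.snp_ids[idx].tolist(),
    }
    return status, truth
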