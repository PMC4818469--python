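"""Core domain containers for the mQTL pipeline.

Conventions used throughout the package:

* coordinates are 1-based (BIM / Illumina-manifest convention);
* SNP-CpG distances are ``pos_snp - pos_cpg`` with sign preserved;
* p-values are carried in log10 space end-to-end, because the discovery
  threshold (1e-14) sits near where naive survival-function evaluation
  starts to underflow;
* missing dosages are stored as NaN — readers mark them, consumers decide
  (the scan mean-imputes per SNP, REML drops samples).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

SNP_ANNOTATION_CATEGORIES = (
    "5'UTR",
    "3'UTR",
    "intronic",
    "intergenic",
    "upstream",
    "downstream",
    "unannotated",
)

GENIC_FEATURE_CATEGORIES = ("TSS-upstream", "5'UTR", "body", "3'UTR", "intergenic")

ISLAND_RELATION_CATEGORIES = (
    "island",
    "N-shore",
    "S-shore",
    "N-shelf",
    "S-shelf",
    "open sea",
)

PROBE_QC_FLAGS = frozenset({"multi_mapping", "snp_at_cpg", "potentially_problematic"})

#: floor for log10 p-values; below this double precision cannot represent p
LOG10_P_FLOOR = -320.0


@dataclass
class GenotypeDataset:
    """Dosage matrix with per-SNP metadata.

    ``dosage`` is ``[n_samples, n_snps]`` with values in [0, 2] or NaN for
    missing genotypes. ``alleles`` holds (effect, other) per SNP.
    """

    sample_ids: np.ndarray
    snp_ids: np.ndarray
    dosage: np.ndarray
    chrom: np.ndarray
    pos_bp: np.ndarray
    alleles: np.ndarray  # [n_snps, 2] of str
    maf: np.ndarray
    annotation: np.ndarray
    tag_set_flag: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.dosage = np.asarray(self.dosage, dtype=float)
        self.pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        self.maf = np.asarray(self.maf, dtype=float)
        if self.dosage.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        finite = self.dosage[np.isfinite(self.dosage)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("dosage values outside [0, 2]")
        if np.any(self.pos_bp <= 0):
            raise ValueError("positions must be strictly positive")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def snp_index(self, snp_ids: Sequence[str]) -> np.ndarray:
        lookup = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return np.array([lookup[s] for s in snp_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - defensive
            raise KeyError(f"unknown SNP id {exc.args[0]!r}") from exc

    def subset_snps(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeDataset(
            sample_ids=self.sample_ids,
            snp_ids=self.snp_ids[idx],
            dosage=self.dosage[:, idx],
            chrom=self.chrom[idx],
            pos_bp=self.pos_bp[idx],
            alleles=self.alleles[idx],
            maf=self.maf[idx],
            annotation=self.annotation[idx],
            tag_set_flag=self.tag_set_flag[idx],
        )

    def subset_samples(self, idx: np.ndarray) -> "GenotypeDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self, sample_ids=self.sample_ids[idx], dosage=self.dosage[idx])

    def computed_maf(self) -> np.ndarray:
        """Minor-allele frequency from non-missing dosages."""
        with np.errstate(invalid="ignore"):
            p = np.nanmean(self.dosage, axis=0) / 2.0
        return np.minimum(p, 1.0 - p)


@dataclass
class ProbeAnnotation:
    """Manifest-like per-probe annotation table.

    ``table`` is indexed by probe_id with columns chrom, pos_bp,
    genic_feature, island_relation, qc_flags (a comma-joined string, possibly
    empty).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"chrom", "pos_bp", "genic_feature", "island_relation", "qc_flags"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"probe annotation missing columns: {sorted(missing)}")
        if self.table.index.duplicated().any():
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate probe annotation rows: {dups[:5]}")
        bad = [
            f
            for flags in self.table["qc_flags"]
            for f in _split_flags(flags)
            if f not in PROBE_QC_FLAGS
        ]
        if bad:
            raise ValueError(f"unknown qc flags: {sorted(set(bad))}")

    def flags_of(self, probe_id: str) -> frozenset:
        return frozenset(_split_flags(self.table.loc[probe_id, "qc_flags"]))

    def __contains__(self, probe_id: str) -> bool:
        return probe_id in self.table.index


def _split_flags(flags: str) -> list:
    if not isinstance(flags, str) or not flags:
        return []
    return [f for f in flags.split(",") if f]


@dataclass
class MethylationDataset:
    """Probe x sample methylation matrix with a timepoint label.

    ``scale_tag`` distinguishes raw beta values in (0, 1) from unbounded
    rank-normalised covariate residuals.
    """

    probe_ids: np.ndarray
    sample_ids: np.ndarray
    values: np.ndarray  # [n_probes, n_samples]
    timepoint: str
    age_years: float
    scale_tag: str = "beta"

    def __post_init__(self) -> None:
        self.probe_ids = np.asarray(self.probe_ids, dtype=object)
        self.sample_ids = np.asarray(self.sample_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if self.scale_tag not in ("beta", "rank_normal_residual"):
            raise ValueError(f"unknown scale_tag {self.scale_tag!r}")
        if self.scale_tag == "beta":
            finite = self.values[np.isfinite(self.values)]
            if finite.size and (finite.min() <= 0 or finite.max() >= 1):
                bad = self.probe_ids[
                    np.nanmin(self.values, axis=1) <= 0
                ].tolist() + self.probe_ids[np.nanmax(self.values, axis=1) >= 1].tolist()
                raise ValueError(
                    f"beta-scale values outside (0,1) for probes: {sorted(set(bad))[:10]}"
                )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def probe_index(self, probe_ids: Sequence[str]) -> np.ndarray:
        lookup = {p: i for i, p in enumerate(self.probe_ids)}
        return np.array([lookup[p] for p in probe_ids], dtype=int)

    def subset_probes(self, idx: np.ndarray) -> "MethylationDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(self, probe_ids=self.probe_ids[idx], values=self.values[idx])

    def subset_samples(self, idx: np.ndarray) -> "MethylationDataset":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return replace(
            self, sample_ids=self.sample_ids[idx], values=self.values[:, idx]
        )


@dataclass
class AssociationRecord:
    """One SNP-CpG association test result."""

    snp_id: str
    probe_id: str
    timepoint: str
    slope: float
    se: float
    t_stat: float
    log10_p: float
    r2: float
    relation: str  # "cis" | "trans"
    distance_bp: float = np.nan  # signed pos_snp - pos_cpg; NaN across chromosomes

    def __post_init__(self) -> None:
        if self.log10_p > 1e-12:
            raise ValueError(f"log10_p must be <= 0, got {self.log10_p}")
        if not (-1e-12 <= self.r2 <= 1 + 1e-12):
            raise ValueError(f"r2 must be in [0,1], got {self.r2}")
        if self.relation not in ("cis", "trans"):
            raise ValueError(f"relation must be cis/trans, got {self.relation!r}")


@dataclass
class GwasSummary:
    """Per-SNP association p-values for one complex trait."""

    trait_name: str
    table: pd.DataFrame  # columns snp_id, chrom, pos_bp, p

    def __post_init__(self) -> None:
        required = {"snp_id", "chrom", "pos_bp", "p"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
        p = self.table["p"].to_numpy(dtype=float)
        if p.size and (p.min() <= 0 or p.max() > 1):
            raise ValueError("GWAS p-values must lie in (0, 1]")

    def p_for(self, snp_ids: Sequence[str]) -> pd.Series:
        return self.table.set_index("snp_id")["p"].reindex(snp_ids)


@dataclass
class VarianceDecomposition:
    """cis / trans / residual variance partition for one probe or trait."""

    name: str
    timepoint: str
    v_cis: float
    v_trans: float
    v_resid: float
    se_cis: float = np.nan
    se_trans: float = np.nan
    explained_cis: float = np.nan
    explained_trans: float = np.nan
    converged: bool = True
    n_iterations: int = 0

    def __post_init__(self) -> None:
        for label, v in (("v_cis", self.v_cis), ("v_trans", self.v_trans), ("v_resid", self.v_resid)):
            if v < -1e-10:
                raise ValueError(f"{label} must be >= 0, got {v}")
        total = self.v_cis + self.v_trans + self.v_resid
        if total > 0 and self.h2_total > 1 + 1e-8:
            raise ValueError("h2 fractions exceed 1")

    @property
    def total(self) -> float:
        return self.v_cis + self.v_trans + self.v_resid

    @property
    def h2_cis(self) -> float:
        return self.v_cis / self.total if self.total > 0 else 0.0

    @property
    def h2_trans(self) -> float:
        return self.v_trans / self.total if self.total > 0 else 0.0

    @property
    def h2_total(self) -> float:
        return self.h2_cis + self.h2_trans


@dataclass
class EnrichmentResult:
    """Observed statistic against a matched-null distribution."""

    trait_name: str
    observed_statistic: float
    null_statistics: np.ndarray
    n_target_snps: int
    mode: str

    def __post_init__(self) -> None:
        self.null_statistics = np.asarray(self.null_statistics, dtype=float)

    @property
    def empirical_p(self) -> float:
        n = len(self.null_statistics)
        # numerically exact ties count as "at least as extreme"
        cut = self.observed_statistic - 1e-9 * max(1.0, abs(self.observed_statistic))
        return (1 + int(np.sum(self.null_statistics >= cut))) / (1 + n)
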