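"""Readers and writers for every external format the pipeline touches.

Formats:

* PLINK bed/bim/fam (variant-major bed) — genotypes;
* tab-separated text dosage (one row per SNP, one column per sample, with
  SNP metadata columns) — genotypes with full annotation metadata;
* tab-separated methylation matrix (first column probe_id, remaining
  columns sample ids) plus a manifest table;
* tab-separated GWAS summary, covariate and result tables.

All writers emit a ``#`` comment header line carrying the package version
and the writer's parameters, which readers skip.
"""

from __future__ import annotations

import logging
from dataclasses import fields as dataclass_fields
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datamodel import (
    AssociationRecord,
    EnrichmentResult,
    GenotypeDataset,
    GwasSummary,
    MethylationDataset,
    ProbeAnnotation,
    VarianceDecomposition,
)

logger = logging.getLogger(__name__)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit PLINK codes -> effect-allele (A1) dosage
_BED_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])


class FormatError(ValueError):
    """Raised when an input file does not match its declared format."""


def _header_line(writer: str, **params) -> str:
    kv = " ".join(f"{k}={v}" for k, v in params.items())
    return f"# mqtlkit {__version__} {writer} {kv}".rstrip()


# ---------------------------------------------------------------------------
# genotypes


def read_genotypes(path, format: str = "plink_bed") -> GenotypeDataset:
    """Read genotypes from PLINK bed/bim/fam or a text dosage table.

    ``path`` is the bed file (or prefix) for ``plink_bed``, the dosage table
    for ``text_dosage``. Missing genotypes are carried as NaN, never
    silently imputed.
    """
    if format == "plink_bed":
        return _read_plink_bed(Path(path))
    if format == "text_dosage":
        return _read_text_dosage(Path(path))
    raise ValueError(f"unknown genotype format {format!r}")


def _read_plink_bed(path: Path) -> GenotypeDataset:
    bed = path if path.suffix == ".bed" else path.with_suffix(".bed")
    bim = bed.with_suffix(".bim")
    fam = bed.with_suffix(".fam")
    for companion in (bed, bim, fam):
        if not companion.exists():
            raise FormatError(f"missing PLINK companion file: {companion}")
    bim_df = pd.read_csv(
        bim,
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos_bp", "a1", "a2"],
        dtype={"chrom": str, "snp_id": str, "a1": str, "a2": str},
    )
    fam_df = pd.read_csv(
        fam,
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
        dtype={"iid": str},
    )
    n_samples, n_snps = len(fam_df), len(bim_df)
    raw = bed.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"bad magic bytes in {bed}: not a variant-major PLINK bed")
    body = np.frombuffer(raw, dtype=np.uint8, offset=3)
    bytes_per_snp = (n_samples + 3) // 4
    if len(body) != bytes_per_snp * n_snps:
        raise FormatError(
            f"{bed} holds {len(body)} data bytes but {bim} declares {n_snps} SNPs "
            f"x {bytes_per_snp} bytes ({bytes_per_snp * n_snps} expected)"
        )
    codes = body.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit fields, sample-fastest within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    expanded = expanded.reshape(n_snps, bytes_per_snp * 4)[:, :n_samples]
    dosage = _BED_CODE_TO_DOSAGE[expanded].T  # [samples, snps]

    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosage, axis=0) / 2.0
    maf = np.minimum(p, 1 - p)
    return GenotypeDataset(
        sample_ids=fam_df["iid"].to_numpy(dtype=object),
        snp_ids=bim_df["snp_id"].to_numpy(dtype=object),
        dosage=dosage,
        chrom=bim_df["chrom"].to_numpy(dtype=object),
        pos_bp=bim_df["pos_bp"].to_numpy(),
        alleles=bim_df[["a1", "a2"]].to_numpy(dtype=object),
        maf=maf,
        annotation=np.array(["unannotated"] * n_snps, dtype=object),
        tag_set_flag=np.ones(n_snps, dtype=bool),
    )


_DOSAGE_META = ["snp_id", "chrom", "pos_bp", "effect_allele", "other_allele", "annotation", "tag_set"]


def _read_text_dosage(path: Path) -> GenotypeDataset:
    if not path.exists():
        raise FormatError(f"missing dosage file: {path}")
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "chrom": str})
    missing = [c for c in _DOSAGE_META if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: dosage header row lacks columns {missing}")
    sample_cols = [c for c in df.columns if c not in _DOSAGE_META]
    if not sample_cols:
        raise FormatError(f"{path}: no sample columns found")
    dosage = df[sample_cols].to_numpy(dtype=float).T
    with np.errstate(invalid="ignore"):
        p = np.nanmean(dosage, axis=0) / 2.0
    return GenotypeDataset(
        sample_ids=np.array(sample_cols, dtype=object),
        snp_ids=df["snp_id"].to_numpy(dtype=object),
        dosage=dosage,
        chrom=df["chrom"].to_numpy(dtype=object),
        pos_bp=df["pos_bp"].to_numpy(),
        alleles=df[["effect_allele", "other_allele"]].to_numpy(dtype=object),
        maf=np.minimum(p, 1 - p),
        annotation=df["annotation"].to_numpy(dtype=object),
        tag_set_flag=df["tag_set"].to_numpy(dtype=bool),
    )


def write_genotypes(geno: GenotypeDataset, path, format: str = "text_dosage") -> None:
    path = Path(path)
    if format == "text_dosage":
        df = pd.DataFrame(
            {
                "snp_id": geno.snp_ids,
                "chrom": geno.chrom,
                "pos_bp": geno.pos_bp,
                "effect_allele": geno.alleles[:, 0],
                "other_allele": geno.alleles[:, 1],
                "annotation": geno.annotation,
                "tag_set": geno.tag_set_flag,
            }
        )
        dosage_cols = pd.DataFrame(geno.dosage.T, columns=geno.sample_ids, index=df.index)
        df = pd.concat([df, dosage_cols], axis=1)
        with open(path, "w") as fh:
            fh.write(_header_line("text_dosage", n_samples=geno.n_samples, n_snps=geno.n_snps) + "\n")
            df.to_csv(fh, sep="\t", index=False)
    elif format == "plink_bed":
        _write_plink_bed(geno, path)
    else:
        raise ValueError(f"unknown genotype format {format!r}")


def _write_plink_bed(geno: GenotypeDataset, path: Path) -> None:
    bed = path if path.suffix == ".bed" else path.with_suffix(".bed")
    n = geno.n_samples
    code = np.full(geno.dosage.T.shape, 1, dtype=np.uint8)  # missing
    d = geno.dosage.T  # [snps, samples]
    code[d == 2] = 0
    code[d == 1] = 2
    code[d == 0] = 3
    pad = (-n) % 4
    if pad:
        code = np.concatenate([code, np.zeros((code.shape[0], pad), dtype=np.uint8)], axis=1)
    packed = (
        code[:, 0::4] | (code[:, 1::4] << 2) | (code[:, 2::4] << 4) | (code[:, 3::4] << 6)
    ).astype(np.uint8)
    bed.write_bytes(_BED_MAGIC + packed.tobytes())
    bim = pd.DataFrame(
        {
            "chrom": geno.chrom,
            "snp_id": geno.snp_ids,
            "cm": 0,
            "pos_bp": geno.pos_bp,
            "a1": geno.alleles[:, 0],
            "a2": geno.alleles[:, 1],
        }
    )
    bim.to_csv(bed.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame(
        {
            "fid": geno.sample_ids,
            "iid": geno.sample_ids,
            "father": 0,
            "mother": 0,
            "sex": 0,
            "pheno": -9,
        }
    )
    fam.to_csv(bed.with_suffix(".fam"), sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# methylation


def read_methylation(
    values_path, manifest_path, timepoint: str = "unknown", age_years: float = np.nan
) -> MethylationDataset:
    """Read a beta-scale methylation matrix and validate against a manifest.

    Probes absent from the manifest are rejected; beta values outside (0,1)
    raise a validation error naming the offending probes.
    """
    manifest = read_manifest(manifest_path)
    df = pd.read_csv(values_path, sep="\t", comment="#", dtype={"probe_id": str})
    if "probe_id" not in df.columns:
        raise FormatError(f"{values_path}: first column must be probe_id")
    df = df.set_index("probe_id")
    unknown = [p for p in df.index if p not in manifest]
    if unknown:
        raise FormatError(
            f"{values_path}: probes missing from manifest: {unknown[:10]}"
        )
    return MethylationDataset(
        probe_ids=df.index.to_numpy(dtype=object),
        sample_ids=np.array(df.columns, dtype=object),
        values=df.to_numpy(dtype=float),
        timepoint=timepoint,
        age_years=age_years,
        scale_tag="beta",
    )


def write_methylation(meth: MethylationDataset, path) -> None:
    df = pd.DataFrame(meth.values, index=pd.Index(meth.probe_ids, name="probe_id"), columns=meth.sample_ids)
    with open(path, "w") as fh:
        fh.write(
            _header_line(
                "methylation",
                timepoint=meth.timepoint,
                age_years=meth.age_years,
                scale_tag=meth.scale_tag,
            )
            + "\n"
        )
        df.to_csv(fh, sep="\t")


def read_manifest(path) -> ProbeAnnotation:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"probe_id": str, "chrom": str}).set_index("probe_id")
    if "qc_flags" not in df.columns:
        df["qc_flags"] = ""
    df["qc_flags"] = df["qc_flags"].fillna("")
    return ProbeAnnotation(df)


def write_manifest(annot: ProbeAnnotation, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("manifest", n_probes=len(annot.table)) + "\n")
        annot.table.to_csv(fh, sep="\t", index_label="probe_id")


# ---------------------------------------------------------------------------
# covariates & GWAS


def read_covariates(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise FormatError(f"{path}: covariate table lacks sample_id column")
    return df.set_index("sample_id")


def write_covariates(cov: pd.DataFrame, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("covariates", n_samples=len(cov)) + "\n")
        cov.to_csv(fh, sep="\t", index_label="sample_id")


def read_gwas_summary(path, trait_name: str | None = None) -> GwasSummary:
    """Read a GWAS summary table; rows with p outside (0,1] are dropped."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"snp_id": str, "chrom": str})
    required = ["snp_id", "chrom", "pos_bp", "p"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: GWAS table lacks columns {missing}")
    p = df["p"].to_numpy(dtype=float)
    bad = ~((p > 0) & (p <= 1))
    if bad.any():
        logger.warning("%s: dropped %d rows with p outside (0,1]", path, int(bad.sum()))
        df = df.loc[~bad]
    dup = df["snp_id"].duplicated()
    if dup.any():
        logger.warning("%s: %d duplicated snp_ids, keeping first", path, int(dup.sum()))
        df = df.loc[~dup]
    name = trait_name if trait_name is not None else Path(path).stem
    return GwasSummary(trait_name=name, table=df.reset_index(drop=True))


def write_gwas_summary(gwas: GwasSummary, path) -> None:
    with open(path, "w") as fh:
        fh.write(_header_line("gwas", trait=gwas.trait_name) + "\n")
        gwas.table.to_csv(fh, sep="\t", index=False)


# ---------------------------------------------------------------------------
# result tables

_ASSOC_COLS = [
    "snp_id", "probe_id", "timepoint", "slope", "se", "t_stat",
    "log10_p", "r2", "relation", "distance_bp",
]
_VARCOMP_COLS = [
    "name", "timepoint", "v_cis", "v_trans", "v_resid", "se_cis", "se_trans",
    "explained_cis", "explained_trans", "converged", "n_iterations",
]
_ENRICH_COLS = ["trait_name", "observed_statistic", "n_target_snps", "mode", "empirical_p", "null_statistics"]


def write_results(records, path) -> None:
    """Write a homogeneous list of result records as a tab-separated table.

    Column order is fixed per record type; ``log10_p`` stays in log space.
    An empty list writes a header-only AssociationRecord table.
    """
    records = list(records)
    kind = type(records[0]).__name__ if records else "AssociationRecord"
    if any(type(r).__name__ != kind for r in records):
        raise ValueError("write_results requires a homogeneous record list")
    if kind == "AssociationRecord":
        cols, rows = _ASSOC_COLS, [[getattr(r, c) for c in _ASSOC_COLS] for r in records]
    elif kind == "VarianceDecomposition":
        cols, rows = _VARCOMP_COLS, [[getattr(r, c) for c in _VARCOMP_COLS] for r in records]
    elif kind == "EnrichmentResult":
        cols = _ENRICH_COLS
        rows = [
            [
                r.trait_name, repr(float(r.observed_statistic)), r.n_target_snps, r.mode,
                repr(float(r.empirical_p)), ";".join(repr(float(v)) for v in r.null_statistics),
            ]
            for r in records
        ]
    else:
        raise ValueError(f"cannot serialise records of type {kind}")
    df = pd.DataFrame(rows, columns=cols)
    with open(path, "w") as fh:
        fh.write(_header_line("results", record_type=kind, n=len(records)) + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.17g")


def read_results(path):
    """Read back a table written by :func:`write_results`."""
    with open(path) as fh:
        header = fh.readline()
    kind = "AssociationRecord"
    for token in header.split():
        if token.startswith("record_type="):
            kind = token.split("=", 1)[1]
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
    if kind == "AssociationRecord":
        return [
            AssociationRecord(
                snp_id=str(r.snp_id), probe_id=str(r.probe_id), timepoint=str(r.timepoint),
                slope=r.slope, se=r.se, t_stat=r.t_stat, log10_p=r.log10_p, r2=r.r2,
                relation=r.relation, distance_bp=r.distance_bp,
            )
            for r in df.itertuples()
        ]
    if kind == "VarianceDecomposition":
        return [
            VarianceDecomposition(
                name=str(r.name), timepoint=str(r.timepoint), v_cis=r.v_cis,
                v_trans=r.v_trans, v_resid=r.v_resid, se_cis=r.se_cis, se_trans=r.se_trans,
                explained_cis=r.explained_cis, explained_trans=r.explained_trans,
                converged=bool(r.converged), n_iterations=int(r.n_iterations),
            )
            for r in df.itertuples(index=False)
        ]
    if kind == "EnrichmentResult":
        return [
            EnrichmentResult(
                trait_name=str(r.trait_name),
                observed_statistic=float(r.observed_statistic),
                null_statistics=np.array([float(v) for v in str(r.null_statistics).split(";") if v]),
                n_target_snps=int(r.n_target_snps),
                mode=str(r.mode),
            )
            for r in df.itertuples(index=False)
        ]
    raise FormatError(f"{path}: unknown record_type {kind!r}")
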