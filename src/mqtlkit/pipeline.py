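"""Configuration-driven orchestration of the full analysis.

Stages run in dependency order on a simulated cohort (or supplied input
files), each writing a tab-separated table plus a log line with its
parameters, derived seed and row counts. One master seed deterministically
derives per-stage seeds by hashing the stage name, so any stage can be
re-run in isolation.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from . import simulate as sim
from .conditional import conditional_scan
from .datamodel import GenotypeDataset
from .enrichment import MatchingSpec, gwas_enrichment, ld_proxy_count, prune_ld
from .mediation import candidate_triples, mediation_test
from .annotation import feature_distribution, trans_chromosomal_fraction
from .preprocess import prepare_residuals, qc_filter_probes, qc_filter_snps
from .scan import ScanConfig, exact_association, screen_associations, select_sentinels
from .temporal import (
    coefficient_of_variation,
    compare_cv,
    cross_time_correlation,
    replication_rate,
)
from .datamodel import GwasSummary

logger = logging.getLogger(__name__)

STAGES = (
    "simulate", "preprocess", "scan", "conditional", "temporal",
    "mediation", "enrichment", "annotation", "summary",
)


@dataclass
class PipelineConfig:
    """Thresholds and cohort scale for one pipeline run."""

    out_dir: str = "results/pipeline"
    seed: int = 0
    # cohort scale (miniature by default)
    n_children: int = 200
    n_mothers: int = 200
    n_blocks: int = 20
    snps_per_block: int = 25
    n_probes: int = 50
    ld_rho: float = 0.6
    h2_cis: float = 0.35
    h2_trans: float = 0.0
    prob_null: float = 0.3
    # thresholds (study defaults)
    p_screen: float = 1e-7
    p_discovery: float = 1e-14
    p_replication: float = 1e-7
    cis_window_bp: int = 1_000_000
    relatedness_meth: float = 0.05
    relatedness_trait: float = 0.025
    ld_prune_r2: float = 0.1
    proxy_r2: float = 0.8
    n_draws_gwas: int = 1000
    n_draws_trait: int = 100
    skip: tuple = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.p_discovery > self.p_screen:
            raise ValueError("p_discovery must be <= p_screen")
        for pname in ("p_screen", "p_discovery", "p_replication"):
            v = getattr(self, pname)
            if not (0 < v <= 1):
                raise ValueError(f"{pname} must lie in (0,1]")
        if not (0 < self.ld_prune_r2 < 1 and 0 < self.proxy_r2 < 1):
            raise ValueError("LD thresholds must lie in (0,1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def config_hash(self) -> str:
        d = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(self).items()
            if k != "out_dir"  # identical analyses hash alike across directories
        }
        return hashlib.sha1(json.dumps(d, sort_keys=True).encode()).hexdigest()[:12]

    def stage_seed(self, stage: str) -> int:
        return int((self.seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31 - 1))


def _write_table(df: pd.DataFrame, path: Path, cfg: PipelineConfig, stage: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# mqtlkit pipeline stage={stage} config={cfg.config_hash()} seed={cfg.stage_seed(stage)}\n")
        df.to_csv(fh, sep="\t", index=False)
    logger.info("stage %s: wrote %d rows to %s", stage, len(df), path)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run every stage on a simulated cohort; returns the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    skip = set(config.skip)

    # --- simulate ----------------------------------------------------------
    cohort = sim.CohortSpec(
        n_children=config.n_children, n_mothers=config.n_mothers,
        seed=config.stage_seed("simulate"),
    )
    geno = sim.simulate_cohort_genotypes(
        cohort, n_blocks=config.n_blocks, snps_per_block=config.snps_per_block,
        ld_rho=config.ld_rho,
    )
    arch = sim.random_architecture(
        geno, config.n_probes, h2_cis=config.h2_cis, h2_trans=config.h2_trans,
        prob_null=config.prob_null, seed=config.stage_seed("architecture"),
    )
    manifest = sim.probe_manifest(arch, seed=config.stage_seed("manifest"))
    meth_by_tp, cov_by_tp, truth = sim.simulate_methylation(geno, cohort, arch)
    mio.write_genotypes(geno, out / "genotypes.tsv")
    mio.write_manifest(manifest, out / "manifest.tsv")
    _write_table(truth, out / "truth.tsv", config, "simulate")

    # --- preprocess + scan per timepoint ------------------------------------
    records_by_tp: dict = {}
    sentinels_by_tp: dict = {}
    resid_by_tp: dict = {}
    scan_cfg = ScanConfig(
        p_screen=config.p_screen, p_discovery=config.p_discovery,
        cis_window_bp=config.cis_window_bp,
    )
    for tp_label, meth in meth_by_tp.items():
        meth_qc = qc_filter_probes(meth, manifest)
        resid = prepare_residuals(meth_qc, cov_by_tp[tp_label])
        resid_by_tp[tp_label] = resid
        if "scan" in skip:
            continue
        tp_geno = geno.subset_samples(
            np.array([s in set(resid.sample_ids) for s in geno.sample_ids])
        )
        cand = screen_associations(tp_geno, resid, scan_cfg)
        records = exact_association(
            tp_geno, resid, None, list(zip(cand["snp_id"], cand["probe_id"])),
            probe_annotation=manifest, cis_window_bp=config.cis_window_bp,
        )
        records_by_tp[tp_label] = records
        sentinels_by_tp[tp_label] = select_sentinels(
            records, tp_geno, window_bp=config.cis_window_bp, p_discovery=config.p_discovery
        )
        mio.write_results(records, out / f"scan_{tp_label}.tsv")
        mio.write_results(sentinels_by_tp[tp_label], out / f"sentinels_{tp_label}.tsv")

    # --- conditional at the childhood timepoint ------------------------------
    signal_sets = []
    if "conditional" not in skip and "childhood" in records_by_tp:
        resid = resid_by_tp["childhood"]
        tp_geno = geno.subset_samples(
            np.array([s in set(resid.sample_ids) for s in geno.sample_ids])
        )
        signal_sets = conditional_scan(
            tp_geno, resid, records_by_tp["childhood"], p_enter=config.p_discovery
        )
        cond_df = pd.DataFrame(
            [
                {"probe_id": ss.probe_id, "n_signals": len(ss), "snp_ids": ",".join(ss.snp_ids),
                 "sum_r2": ss.sum_r2}
                for ss in signal_sets
            ]
        )
        _write_table(cond_df, out / "conditional_childhood.tsv", config, "conditional")

    # --- temporal ------------------------------------------------------------
    if (
        "temporal" not in skip
        and {"childhood", "adolescence"} <= set(records_by_tp)
        and sentinels_by_tp.get("childhood")
    ):
        rep = replication_rate(
            sentinels_by_tp["childhood"], records_by_tp["adolescence"],
            p_replication=config.p_replication,
        )
        corr, _ = cross_time_correlation(
            meth_by_tp["childhood"], meth_by_tp["adolescence"],
            seed=config.stage_seed("temporal"),
        )
        cv1 = coefficient_of_variation(meth_by_tp["childhood"])
        cv2 = coefficient_of_variation(meth_by_tp["adolescence"])
        dcv, se_dcv = compare_cv(cv1, cv2)
        _write_table(
            pd.DataFrame(
                [{"discovery": "childhood", "target": "adolescence",
                  "n_discovery": rep.n_discovery, "n_replicated": rep.n_replicated,
                  "rate": rep.rate, "mean_r": float(corr.mean()),
                  "mean_cv_change": dcv, "se_cv_change": se_dcv}]
            ),
            out / "temporal.tsv", config, "temporal",
        )

    # --- mediation ------------------------------------------------------------
    if "mediation" not in skip and signal_sets:
        trans_sent = [r for r in sentinels_by_tp.get("childhood", []) if r.relation == "trans"]
        triples = candidate_triples(signal_sets, trans_sent)
        med_rows = []
        resid = resid_by_tp["childhood"]
        tp_geno = geno.subset_samples(
            np.array([s in set(resid.sample_ids) for s in geno.sample_ids])
        )
        pidx = {p: i for i, p in enumerate(resid.probe_ids)}
        sidx = {s: i for i, s in enumerate(resid.sample_ids)}
        order = np.array([sidx[s] for s in tp_geno.sample_ids])
        for snp_id, cis_probe, trans_probe in triples:
            if cis_probe not in pidx or trans_probe not in pidx:
                continue
            g = tp_geno.dosage[:, tp_geno.snp_index([snp_id])[0]]
            rec = mediation_test(
                resid.values[pidx[trans_probe], order], g, resid.values[pidx[cis_probe], order],
                ids=(snp_id, cis_probe, trans_probe),
            )
            med_rows.append(
                {"snp": snp_id, "cis_probe": cis_probe, "trans_probe": trans_probe,
                 "beta_unadjusted": rec.beta_unadjusted, "beta_adjusted": rec.beta_adjusted,
                 "attenuation": rec.attenuation, "stable": rec.stable}
            )
        _write_table(pd.DataFrame(med_rows), out / "mediation.tsv", config, "mediation")

    # --- enrichment (synthetic GWAS over the simulated SNP panel) -------------
    if "enrichment" not in skip and sentinels_by_tp.get("childhood"):
        rng = np.random.default_rng(config.stage_seed("enrichment"))
        cis_sent = [r for r in sentinels_by_tp["childhood"] if r.relation == "cis"]
        pruned = prune_ld(
            [r.snp_id for r in cis_sent], geno, r2_max=config.ld_prune_r2,
            log10_p=[r.log10_p for r in cis_sent],
        )
        if len(pruned) >= 10:
            gwas = GwasSummary(
                trait_name="synthetic_trait",
                table=pd.DataFrame(
                    {"snp_id": geno.snp_ids, "chrom": geno.chrom, "pos_bp": geno.pos_bp,
                     "p": rng.uniform(size=geno.n_snps)}
                ),
            )
            spec = MatchingSpec(
                annotation_mode="annotation_matched", n_draws=min(config.n_draws_gwas, 200),
                seed=config.stage_seed("enrichment"), relax=True,
            )
            res = gwas_enrichment(pruned, gwas, geno, spec)
            mio.write_results([res], out / "enrichment.tsv")

    # --- annotation patterns ---------------------------------------------------
    if "annotation" not in skip and sentinels_by_tp.get("childhood"):
        annot = pd.Series(geno.annotation, index=geno.snp_ids)
        snps = sorted({r.snp_id for r in sentinels_by_tp["childhood"]})
        fd = feature_distribution(snps, annot)
        _write_table(fd.table.reset_index(names="category"), out / "snp_features.tsv", config, "annotation")
        trans_recs = [r for r in records_by_tp["childhood"] if r.relation == "trans"]
        if trans_recs:
            frac = trans_chromosomal_fraction(trans_recs)
            _write_table(
                pd.DataFrame([{"trans_chromosomal_fraction": frac, "n_trans": len(trans_recs)}]),
                out / "trans_fraction.tsv", config, "annotation",
            )

    # --- summary ---------------------------------------------------------------
    _write_table(summarize_records(sentinels_by_tp, signal_sets), out / "summary.tsv", config, "summary")
    return out


def summarize_records(sentinels_by_tp: dict, signal_sets=()) -> pd.DataFrame:
    """Per-timepoint sentinel bookkeeping: cis sentinels, independent trans
    clumps, conditional extras, total mQTL, unique CpGs."""
    rows = []
    extra = sum(max(len(ss) - 1, 0) for ss in signal_sets)
    for tp, sents in sentinels_by_tp.items():
        n_cis = sum(1 for r in sents if r.relation == "cis")
        n_trans = sum(1 for r in sents if r.relation == "trans")
        rows.append(
            {
                "timepoint": tp,
                "cis_sentinels": n_cis,
                "trans_sentinels": n_trans,
                "conditional_extra": extra if tp == "childhood" else np.nan,
                "total_mqtl": n_cis + n_trans + (extra if tp == "childhood" else 0),
                "unique_cpgs": len({r.probe_id for r in sents}),
            }
        )
    if not rows:
        rows.append({"timepoint": "none", "cis_sentinels": 0, "trans_sentinels": 0,
                     "conditional_extra": 0, "total_mqtl": 0, "unique_cpgs": 0})
    return pd.DataFrame(rows)


def summarize(output_dir) -> pd.DataFrame:
    """Re-read pipeline outputs and rebuild the summary table."""
    out = Path(output_dir)
    sents = {}
    for f in sorted(out.glob("sentinels_*.tsv")):
        tp = f.stem.replace("sentinels_", "")
        sents[tp] = mio.read_results(f)
    if not sents:
        raise FileNotFoundError(f"no sentinel tables found under {out}")
    return summarize_records(sents)
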