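"""Descriptive distributions of mQTL and associated CpGs across genomic
features, adjusted for the background representation of each feature among
all tested items."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import MethylationDataset


@dataclass
class FeatureDistribution:
    table: pd.DataFrame  # index: category; columns: count, background, share, bg_share, ratio

    @property
    def shares(self) -> pd.Series:
        return self.table["share"]


def feature_distribution(item_set, annotations: pd.Series, background=None) -> FeatureDistribution:
    """Per-category counts and background-adjusted enrichment ratios.

    ``annotations`` maps item id -> category; ``background`` defaults to
    every annotated item (all tested items). Ratio = item share in
    category / background share.
    """
    items = list(item_set)
    missing = [i for i in items if i not in annotations.index]
    if missing:
        raise ValueError(f"unannotated items: {missing[:10]}")
    bg = list(background) if background is not None else list(annotations.index)
    cats = annotations[bg].value_counts()
    counts = annotations[items].value_counts().reindex(cats.index, fill_value=0)
    share = counts / counts.sum()
    bg_share = cats / cats.sum()
    df = pd.DataFrame(
        {"count": counts, "background": cats, "share": share, "bg_share": bg_share,
         "ratio": share / bg_share}
    )
    return FeatureDistribution(df)


def median_methylation_by_feature(meth: MethylationDataset, probe_sets: dict) -> dict:
    """Distribution of per-probe median beta within each category.

    ``probe_sets`` maps category -> probe id list."""
    if meth.scale_tag != "beta":
        raise ValueError("median methylation is computed on the beta scale")
    medians = pd.Series(np.nanmedian(meth.values, axis=1), index=meth.probe_ids)
    return {cat: medians.reindex([p for p in probes if p in medians.index]).dropna()
            for cat, probes in probe_sets.items()}


def trans_chromosomal_fraction(trans_records) -> float:
    """Share of trans associations with SNP and CpG on different
    chromosomes (identified by an absent same-chromosome distance)."""
    recs = [r for r in trans_records if r.relation == "trans"]
    if not recs:
        raise ValueError("no trans records supplied")
    cross = sum(1 for r in recs if not np.isfinite(r.distance_bp))
    return cross / len(recs)
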