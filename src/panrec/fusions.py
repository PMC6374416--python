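"""Transcript-fusion tallies and recurrence classification.

Fusion events arrive pre-called (one row per sample x fusion pair, with a
confidence tier in 1..4).  A fusion pair is recurrent when it occurs at
least twice across all cancer types.  Pair identity is the ordered
(5' gene, 3' gene) tuple; an unordered aggregation is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GeneModel
from .formatting import format_ratio_percent


@dataclass
class FusionSummary:
    """Tallies of panel fusions: per pair, per gene, per tier, per cancer."""

    pair_counts: pd.DataFrame       # gene5, gene3, n_events, recurrent
    unordered_pair_counts: pd.DataFrame
    gene_summary: pd.DataFrame      # gene_id, n_events, n_partners
    tier_counts: pd.DataFrame       # tier, n_events, fraction, percent
    specimen_fractions: pd.DataFrame  # cancer_type, n_with_fusion, n_specimens
    n_events: int
    n_pairs: int


def _panel_mask(fusions: pd.DataFrame, panel_ids: set[str]) -> pd.Series:
    return fusions["gene5"].isin(panel_ids) | fusions["gene3"].isin(panel_ids)


def tally_fusions(fusions: pd.DataFrame, panel: Sequence[GeneModel],
                  samples: pd.DataFrame | None = None,
                  recurrent_min: int = 2) -> FusionSummary:
    """Count panel fusion events, pairs, partners, tiers, and specimen rates.

    Events are deduplicated per (sample, gene5, gene3).  A pair is recurrent
    when its event count across all cancer types is >= ``recurrent_min``.
    ``samples`` (sample_id, cancer_type) supplies the specimen denominators;
    without it, only samples present in the fusion table are counted.
    """
    panel_ids = {g.gene_id for g in panel}
    f = fusions.loc[_panel_mask(fusions, panel_ids)].drop_duplicates(
        ["sample_id", "gene5", "gene3"]).reset_index(drop=True)

    pair_counts = (f.groupby(["gene5", "gene3"]).size().rename("n_events")
                   .reset_index())
    pair_counts["recurrent"] = pair_counts["n_events"] >= recurrent_min

    lo = np.minimum(f["gene5"], f["gene3"])
    hi = np.maximum(f["gene5"], f["gene3"])
    unordered = (pd.DataFrame({"gene_a": lo, "gene_b": hi}).groupby(
        ["gene_a", "gene_b"]).size().rename("n_events").reset_index())
    unordered["recurrent"] = unordered["n_events"] >= recurrent_min

    gene_rows = []
    for gid in sorted(panel_ids):
        mine = f.loc[(f["gene5"] == gid) | (f["gene3"] == gid)]
        partners = set(mine["gene5"]) | set(mine["gene3"])
        partners.discard(gid)
        gene_rows.append(dict(gene_id=gid, n_events=len(mine),
                              n_partners=len(partners)))
    gene_summary = pd.DataFrame(gene_rows)

    tier_counts = tier_summary(f)

    if samples is not None:
        denom = samples.groupby("cancer_type")["sample_id"].nunique()
    else:
        denom = f.groupby("cancer_type")["sample_id"].nunique()
    with_fusion = f.groupby("cancer_type")["sample_id"].nunique()
    spec = pd.DataFrame({
        "n_specimens": denom,
        "n_with_fusion": with_fusion.reindex(denom.index, fill_value=0).astype(int),
    }).reset_index()
    spec["fraction"] = spec["n_with_fusion"] / spec["n_specimens"]

    return FusionSummary(
        pair_counts=pair_counts,
        unordered_pair_counts=unordered,
        gene_summary=gene_summary,
        tier_counts=tier_counts,
        specimen_fractions=spec,
        n_events=len(f),
        n_pairs=len(pair_counts),
    )


def tier_summary(fusions: pd.DataFrame) -> pd.DataFrame:
    """Event counts and percent per confidence tier (1..4)."""
    if not fusions["tier"].isin([1, 2, 3, 4]).all():
        raise ValueError("tiers must be in 1..4")
    counts = fusions.groupby("tier").size().reindex([1, 2, 3, 4], fill_value=0)
    total = int(counts.sum())
    out = counts.rename("n_events").reset_index()
    out["fraction"] = out["n_events"] / total if total else np.nan
    out["percent"] = [format_ratio_percent(int(k), total) if total else ""
                      for k in out["n_events"]]
    return out


def fusion_recurrence_flags(fusions: pd.DataFrame, panel: Sequence[GeneModel],
                            cancer_types: Sequence[str],
                            recurrent_min: int = 2) -> pd.DataFrame:
    """Per (gene, cancer type): does the gene have a recurrent fusion there?

    A gene scores in a cancer type iff it participates in >= 1 fusion pair
    whose pan-cancer event count is >= ``recurrent_min`` and at least one of
    that pair's events occurred in the cancer type.
    """
    panel_ids = {g.gene_id for g in panel}
    f = fusions.loc[_panel_mask(fusions, panel_ids)].drop_duplicates(
        ["sample_id", "gene5", "gene3"])
    counts = f.groupby(["gene5", "gene3"]).size()
    recurrent_pairs = set(counts.index[counts >= recurrent_min])
    flagged: set[tuple[str, str]] = set()
    for row in f.itertuples():
        if (row.gene5, row.gene3) in recurrent_pairs:
            for gid in (row.gene5, row.gene3):
                if gid in panel_ids:
                    flagged.add((gid, row.cancer_type))
    rows = [dict(gene_id=g.gene_id, cancer_type=ct,
                 fusion_pass=(g.gene_id, ct) in flagged)
            for g in panel for ct in cancer_types]
    return pd.DataFrame(rows)
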