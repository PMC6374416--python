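"""Pan-cancer target prioritization from SCNA, mutation, and fusion evidence.

Per gene and cancer type, the recurrent score counts the evidence channels
with a recurrent event (focal SCNA passing all four criteria, mutation index
>= 2, recurrent fusion) and therefore ranges 0..3; the SCNA channel
contributes at most one point even when a gene has both recurrent gain and
loss in the same cancer type.  The overall recurrent score is the unweighted
sum across cancer types and is the headline ranking statistic; ties break by
overall G-score + overall M-score, then gene id.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import GeneModel
from .formatting import format_ratio_percent, ratio_percent


def recurrent_score(scna_pass: bool, mut_recurrent: bool,
                    fusion_recurrent: bool) -> int:
    """Count of evidence channels with a recurrent event (0..3)."""
    return int(bool(scna_pass)) + int(bool(mut_recurrent)) + int(bool(fusion_recurrent))


def per_cancer_flags(scna_scores: pd.DataFrame, mut_scores: pd.DataFrame,
                     fusion_flags: pd.DataFrame, panel: Sequence[GeneModel],
                     cancer_types: Sequence[str]) -> pd.DataFrame:
    """One row per (gene, cancer type) with the three channel flags, the
    per-cancer recurrent score, and the evidence classes present."""
    base = pd.MultiIndex.from_product(
        [[g.gene_id for g in panel], list(cancer_types)],
        names=["gene_id", "cancer_type"]).to_frame(index=False)

    gain = (scna_scores.loc[(scna_scores["direction"] == "gain")
                            & scna_scores["passes_all"],
                            ["gene_id", "cancer_type"]].assign(scna_gain=True))
    loss = (scna_scores.loc[(scna_scores["direction"] == "loss")
                            & scna_scores["passes_all"],
                            ["gene_id", "cancer_type"]].assign(scna_loss=True))
    out = (base.merge(gain, how="left", on=["gene_id", "cancer_type"])
           .merge(loss, how="left", on=["gene_id", "cancer_type"]))
    out["scna_gain"] = out["scna_gain"].notna()
    out["scna_loss"] = out["scna_loss"].notna()
    out["scna_pass"] = out["scna_gain"] | out["scna_loss"]

    out = out.merge(mut_scores[["gene_id", "cancer_type", "recurrent"]].rename(
        columns={"recurrent": "mut_pass"}), how="left",
        on=["gene_id", "cancer_type"])
    out["mut_pass"] = out["mut_pass"].astype("boolean").fillna(False).astype(bool)

    out = out.merge(fusion_flags[["gene_id", "cancer_type", "fusion_pass"]],
                    how="left", on=["gene_id", "cancer_type"])
    out["fusion_pass"] = out["fusion_pass"].astype("boolean").fillna(False).astype(bool)

    out["recurrent_score"] = (out["scna_pass"].astype(int)
                              + out["mut_pass"].astype(int)
                              + out["fusion_pass"].astype(int))
    return out


def overall_recurrent_score(flags: pd.DataFrame,
                            overall_g: pd.DataFrame | None = None,
                            overall_m: pd.DataFrame | None = None) -> pd.DataFrame:
    """Ranked target table: per-gene sums of the per-cancer recurrent scores.

    Stable descending sort on the overall recurrent score, tie-broken by
    (overall G + overall M, gene id).  Genes with score >= 1 are flagged
    recurrently altered.
    """
    cards = flags.groupby("gene_id").agg(
        overall_recurrent_score=("recurrent_score", "sum"),
        n_cancer_types_with_events=("recurrent_score", lambda s: int((s > 0).sum())),
        n_scna=("scna_pass", "sum"), n_mut=("mut_pass", "sum"),
        n_fusion=("fusion_pass", "sum")).reset_index()
    if overall_g is not None:
        g_tot = overall_g.groupby("gene_id")["overall_g"].sum()
        cards["overall_g"] = cards["gene_id"].map(g_tot).fillna(0.0)
    else:
        cards["overall_g"] = 0.0
    if overall_m is not None:
        cards["overall_m"] = cards["gene_id"].map(
            overall_m.set_index("gene_id")["overall_m"]).fillna(0.0)
    else:
        cards["overall_m"] = 0.0
    cards["recurrently_altered"] = cards["overall_recurrent_score"] >= 1
    cards["tiebreak"] = cards["overall_g"] + cards["overall_m"]
    cards = cards.sort_values(
        ["overall_recurrent_score", "tiebreak", "gene_id"],
        ascending=[False, False, True], kind="mergesort").reset_index(drop=True)
    cards["rank"] = np.arange(1, len(cards) + 1)
    return cards.drop(columns="tiebreak")


def evidence_class_summary(flags: pd.DataFrame) -> pd.DataFrame:
    """Classify each recurrently altered gene's alteration pattern.

    consistent_gain: all SCNA events are gains (mutations/fusions may occur
    only in cancers without SCNA evidence); consistent_loss: all SCNA events
    are losses (mutations alongside losses fit the loss-of-function pattern);
    diverse: gains mixed with losses, or gains mixed with mutations in other
    cancers (gain-of-function dosage plus point mutation); none: no event.
    """
    rows = []
    for gid, grp in flags.groupby("gene_id"):
        n_gain = int(grp["scna_gain"].sum())
        n_loss = int(grp["scna_loss"].sum())
        n_mut = int(grp["mut_pass"].sum())
        n_fus = int(grp["fusion_pass"].sum())
        if n_gain + n_loss + n_mut + n_fus == 0:
            klass = "none"
        elif n_gain and n_loss:
            klass = "diverse"
        elif n_gain and n_mut:
            klass = "diverse"
        elif n_gain:
            klass = "consistent_gain"
        elif n_loss or n_mut:
            klass = "consistent_loss"
        else:
            klass = "fusion_only"
        rows.append(dict(gene_id=gid, n_gain_types=n_gain, n_loss_types=n_loss,
                         n_mut_types=n_mut, n_fusion_types=n_fus,
                         evidence_class=klass))
    return pd.DataFrame(rows)


def summary_percentages(cards: pd.DataFrame, panel: Sequence[GeneModel]
                        ) -> pd.DataFrame:
    """Cohort-level ratio summaries, formatted with the documented
    truncate-to-two-decimals percent rule."""
    n_panel = len(panel)
    rows = []

    def add(label: str, num: int, den: int) -> None:
        rows.append(dict(summary=label, numerator=num, denominator=den,
                         percent=format_ratio_percent(num, den),
                         percent_value=ratio_percent(num, den)))

    add("recurrently_altered", int(cards["recurrently_altered"].sum()), n_panel)
    add("any_scna_evidence", int((cards["n_scna"] > 0).sum()), n_panel)
    add("any_mutation_evidence", int((cards["n_mut"] > 0).sum()), n_panel)
    add("any_fusion_evidence", int((cards["n_fusion"] > 0).sum()), n_panel)
    return pd.DataFrame(rows)
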