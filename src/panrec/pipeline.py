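"""End-to-end convenience driver: cohort in, ranked target table out."""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cohort import CohortBundle, filter_mutations
from .fusions import FusionSummary, fusion_recurrence_flags, tally_fusions
from .mutations import overall_m_score, score_mutations
from .scna import overall_g_score, score_scna
from .targets import (
    evidence_class_summary,
    overall_recurrent_score,
    per_cancer_flags,
    summary_percentages,
)


@dataclass
class PipelineResult:
    """All stage outputs of one analysis run."""

    scna_scores: pd.DataFrame
    overall_g: pd.DataFrame
    mut_scores: pd.DataFrame
    overall_m: pd.DataFrame
    fusion_summary: FusionSummary
    fusion_flags: pd.DataFrame
    flags: pd.DataFrame
    cards: pd.DataFrame
    evidence_classes: pd.DataFrame
    summaries: pd.DataFrame


def analyze_cohort(bundle: CohortBundle, K: int = 1000, seed: int = 0,
                   external_caller_flags: pd.DataFrame | None = None
                   ) -> PipelineResult:
    """Run SCNA, mutation, and fusion recurrence scoring and integrate them."""
    cancer_types = bundle.cancer_types

    scna_scores = score_scna(bundle.segments, bundle.expression, bundle.panel,
                             bundle.genome, samples=bundle.samples,
                             K=K, seed=seed)
    g_overall = overall_g_score(scna_scores)

    muts = filter_mutations(bundle.mutations)
    mut_scores = score_mutations(muts, bundle.panel, bundle.samples, K=K,
                                 seed=seed, external_flags=external_caller_flags)
    m_overall = overall_m_score(mut_scores)

    fusion_summary = tally_fusions(bundle.fusions, bundle.panel,
                                   samples=bundle.samples)
    fusion_flags = fusion_recurrence_flags(bundle.fusions, bundle.panel,
                                           cancer_types)

    flags = per_cancer_flags(scna_scores, mut_scores, fusion_flags,
                             bundle.panel, cancer_types)
    cards = overall_recurrent_score(flags, overall_g=g_overall,
                                    overall_m=m_overall)
    classes = evidence_class_summary(flags)
    summaries = summary_percentages(cards, bundle.panel)

    return PipelineResult(
        scna_scores=scna_scores, overall_g=g_overall,
        mut_scores=mut_scores, overall_m=m_overall,
        fusion_summary=fusion_summary, fusion_flags=fusion_flags,
        flags=flags, cards=cards, evidence_classes=classes,
        summaries=summaries,
    )
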