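"""Expression detectability, co-expression ranking, and pre-ranked GSEA.

Detectability uses the cohort-quantile rule: a gene is detectable in a
cancer type when the 90th percentile of its FPKM across that type's samples
is at least 1 (i.e. at least ~10% of specimens express it).  Genes
detectable in fewer than all cancer types are flagged lineage-restricted,
with the count reported so callers can apply their own cutoff.

Guilt-by-association ranking correlates every panel gene with a query gene
on log2(FPKM+1), per cancer type; the pan-cancer statistic is the mean of
the per-cancer Pearson r (not a pooled correlation), which avoids lineage
confounding.  The ranked list feeds a classic weighted pre-ranked GSEA with
a gene-label permutation null.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionTable

logger = logging.getLogger("panrec")


def detectability(expr: ExpressionTable, q90_min: float = 1.0) -> pd.DataFrame:
    """Per (gene, cancer type): 90th-percentile FPKM and the detectable flag.

    The quantile uses the linear-interpolation convention.  Also reports, per
    gene, in how many cancer types it is detectable and whether it is
    lineage-restricted (detected somewhere but not everywhere).
    """
    rows = []
    cts = sorted(expr.cancer_type.unique())
    for ct in cts:
        cols = expr.samples_of(ct)
        if len(cols) < 10:
            logger.warning("detectability: cancer type %s has only %d samples",
                           ct, len(cols))
        q90 = np.percentile(expr.fpkm[cols].to_numpy(), 90, axis=1)
        for gid, val in zip(expr.genes, q90):
            rows.append(dict(gene_id=gid, cancer_type=ct, q90_fpkm=float(val),
                             detectable=bool(val >= q90_min)))
    out = pd.DataFrame(rows)
    n_det = out.groupby("gene_id")["detectable"].sum().rename("n_detected_types")
    out = out.merge(n_det, on="gene_id")
    out["lineage_restricted"] = (out["n_detected_types"] > 0) & \
        (out["n_detected_types"] < len(cts))
    return out


def coexpression_rank(expr: ExpressionTable, query_gene: str) -> pd.DataFrame:
    """Rank genes by their expression correlation with a query gene.

    Pearson r on log2(FPKM+1) per cancer type; the pan-cancer statistic is
    the mean per-cancer r.  Zero-variance genes in a cancer type get NaN
    there and are excluded from that type's mean.  The query gene itself is
    excluded.  Ties in the final ordering break by gene id.
    """
    if query_gene not in expr.genes:
        raise KeyError(f"query gene {query_gene!r} not in expression table")
    log2 = np.log2(expr.fpkm + 1.0)
    cts = sorted(expr.cancer_type.unique())
    per_ct = {}
    for ct in cts:
        cols = expr.samples_of(ct)
        block = log2[cols]
        q = block.loc[query_gene].to_numpy()
        if np.std(q) == 0:
            logger.warning("coexpression_rank: query has zero variance in %s", ct)
            per_ct[ct] = pd.Series(np.nan, index=expr.genes)
            continue
        x = block.to_numpy()
        xm = x - x.mean(axis=1, keepdims=True)
        qm = q - q.mean()
        denom = np.sqrt((xm ** 2).sum(axis=1) * (qm ** 2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, (xm @ qm) / denom, np.nan)
        per_ct[ct] = pd.Series(r, index=expr.genes)
    out = pd.DataFrame(per_ct)
    out["pan_r"] = out[cts].mean(axis=1)
    out = out.drop(index=query_gene)
    out.index.name = "gene_id"
    # descending by pan-cancer r; deterministic tie-break by gene id
    out = (out.reset_index()
           .sort_values(["pan_r", "gene_id"], ascending=[False, True],
                        kind="mergesort").reset_index(drop=True))
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def enrichment_score(ranked_genes: Sequence[str], statistics: np.ndarray,
                     gene_set: set[str], p: float = 1.0) -> float:
    """Weighted Kolmogorov-Smirnov-like running-sum enrichment score.

    Hits advance the running sum by |statistic|^p (normalized to sum 1 over
    hits); misses decrement by 1/(N - n).  ES is the maximum deviation from
    zero, keeping its sign.
    """
    in_set = np.fromiter((g in gene_set for g in ranked_genes), dtype=bool,
                         count=len(ranked_genes))
    w = np.abs(np.asarray(statistics, dtype=float)) ** p
    return _es_from_mask(in_set, w)


def _es_from_mask(in_set: np.ndarray, weights: np.ndarray) -> float:
    n_total = in_set.size
    n_hits = int(in_set.sum())
    if n_hits == 0 or n_hits == n_total:
        raise ValueError("gene set must be a non-trivial subset of the ranking")
    hit_w = np.where(in_set, weights, 0.0)
    total = hit_w.sum()
    if total == 0:  # all hit statistics are zero: fall back to equal weights
        hit_w = in_set.astype(float)
        total = hit_w.sum()
    step = hit_w / total - (~in_set) / (n_total - n_hits)
    running = np.cumsum(step)
    return float(running[np.argmax(np.abs(running))])


def preranked_gsea(ranking: pd.Series, gene_sets: Mapping[str, set[str]],
                   p: float = 1.0, K: int = 1000, seed: int = 0,
                   min_size: int = 5) -> pd.DataFrame:
    """Pre-ranked GSEA with a gene-label permutation null.

    ``ranking`` maps gene id -> ranking statistic and is sorted descending
    internally.  For each set: ES as in :func:`enrichment_score`; the null is
    K permutations of the gene labels (statistics stay in place); NES is
    ES / mean |null ES| of the same sign; p has the +1 correction; FDR is
    Benjamini-Hochberg across the reported sets.
    """
    ranking = ranking.sort_values(ascending=False, kind="mergesort")
    genes = list(ranking.index)
    stats_arr = ranking.to_numpy(dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for set_id, members in gene_sets.items():
        hits = set(members) & set(genes)
        if len(hits) < min_size:
            logger.warning("preranked_gsea: set %s below min size after "
                           "intersection, skipped", set_id)
            continue
        es = enrichment_score(genes, stats_arr, hits, p=p)
        in_set = np.fromiter((g in hits for g in genes), dtype=bool,
                             count=len(genes))
        w = np.abs(stats_arr) ** p
        null = np.empty(K)
        for k in range(K):
            null[k] = _es_from_mask(in_set[rng.permutation(in_set.size)], w)
        same_sign = null[np.sign(null) == np.sign(es)] if es != 0 else null
        denom = np.abs(same_sign).mean() if same_sign.size else np.nan
        nes = es / denom if denom and np.isfinite(denom) else np.nan
        if es >= 0:
            p_perm = (1.0 + (null >= es).sum()) / (1.0 + K)
        else:
            p_perm = (1.0 + (null <= es).sum()) / (1.0 + K)
        rows.append(dict(gene_set=set_id, n_genes=len(hits), ES=es, NES=nes,
                         p_perm=p_perm))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = multipletests(out["p_perm"], method="fdr_bh")[1]
    return out


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Read gene sets from a GMT file (set id, description, members...)."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: GMT line with fewer than 3 fields: {line!r}")
        sets[parts[0]] = set(parts[2:])
    return sets
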