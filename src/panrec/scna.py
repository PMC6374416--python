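"""Gene-level focal copy-number recurrence scoring.

A light-weight re-expression of the GISTIC-style recurrence analysis at gene
resolution: segments spanning half a chromosome arm or more are removed as
broad events, the remaining segments are collapsed to a length-weighted
gene-level logR per sample, each (gene, sample) gets a five-level status
(-2 deep deletion .. +2 high amplification), and gains and losses are scored
separately with

    G-score = alteration frequency x mean |logR| among altered samples,

equivalently the per-sample mean of the altered-sample amplitudes.  An
empirical significance is obtained by cyclically shifting each sample's
gene-level alteration vector along the genome ordering (which preserves the
sample's alteration burden), with Benjamini-Hochberg correction across the
panel per direction.  A gene x cancer event is called a recurrent,
expression-relevant focal SCNA when it passes all four of: q <= 0.25,
G-score >= 0.1, detectable expression (90th-percentile FPKM >= 1), and a
significantly positive copy-number/expression correlation (Pearson p < 0.001
between log2(FPKM+1) and logR).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import ExpressionTable, GeneModel, GenomeModel, panel_frame
from .expression import detectability

logger = logging.getLogger("panrec")

GAIN, LOSS = "gain", "loss"


# ---------------------------------------------------------------------------
# gene-level collapse
# ---------------------------------------------------------------------------

def gene_level_logR_matrix(segs: pd.DataFrame, panel: Sequence[GeneModel]) -> pd.DataFrame:
    """Length-weighted mean logR of the segments overlapping each gene body.

    Returns a genes x samples DataFrame (genes in genomic order).  Samples
    with no overlapping segment get 0 for that gene.  SEG coordinates are
    1-based inclusive and are converted to half-open internally.
    """
    pf = panel_frame(panel)
    gene_ids = pf["gene_id"].to_numpy()
    sample_ids = pd.Index(pd.unique(segs["sample_id"]))
    n_g, n_s = len(gene_ids), len(sample_ids)
    wsum = np.zeros((n_g, n_s))
    vsum = np.zeros((n_g, n_s))
    sample_pos = {s: j for j, s in enumerate(sample_ids)}

    genes_by_chrom = {
        chrom: (grp.index.to_numpy(), grp["start"].to_numpy(), grp["end"].to_numpy())
        for chrom, grp in pf.groupby("chrom")
    }
    for (sample, chrom), grp in segs.groupby(["sample_id", "chrom"], sort=False):
        hit = genes_by_chrom.get(chrom)
        if hit is None:
            continue
        gi, gs, ge = hit
        s0 = grp["start"].to_numpy() - 1  # half-open
        e0 = grp["end"].to_numpy()
        lr = grp["logR"].to_numpy()
        ov = np.minimum(ge[:, None], e0[None, :]) - np.maximum(gs[:, None], s0[None, :])
        np.clip(ov, 0, None, out=ov)
        j = sample_pos[sample]
        wsum[gi, j] += ov.sum(axis=1)
        vsum[gi, j] += (ov * lr[None, :]).sum(axis=1)

    uncovered = wsum == 0
    if uncovered.any():
        logger.debug("gene_level_logR: %d (gene, sample) pairs with no segment "
                     "coverage set to 0", int(uncovered.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(uncovered, 0.0, vsum / np.where(uncovered, 1.0, wsum))
    return pd.DataFrame(out, index=gene_ids, columns=sample_ids)


def gene_level_logR(segs: pd.DataFrame, gene: GeneModel) -> pd.Series:
    """Per-sample length-weighted mean logR for a single gene."""
    return gene_level_logR_matrix(segs, [gene]).iloc[0]


def remove_broad(segs: pd.DataFrame, genome: GenomeModel,
                 min_arm_fraction: float = 0.5) -> pd.DataFrame:
    """Drop segments spanning >= ``min_arm_fraction`` of any chromosome arm."""
    arms = genome.arms()
    keep = np.ones(len(segs), dtype=bool)
    s0 = segs["start"].to_numpy() - 1
    e0 = segs["end"].to_numpy()
    chrom = segs["chrom"].to_numpy()
    for arm in arms.itertuples():
        on = chrom == arm.chrom
        if not on.any():
            continue
        ov = (np.minimum(e0, arm.end) - np.maximum(s0, arm.start)).clip(min=0)
        broad = on & (ov >= min_arm_fraction * (arm.end - arm.start))
        keep &= ~broad
    return segs.loc[keep].reset_index(drop=True)


def assign_gistic_status(gene_logR, t_low: float = 0.1, t_high: float = 0.9):
    """Five-level copy-number status from the gene-level logR.

    2 if logR > t_high; 1 if t_low < logR <= t_high; symmetric for losses;
    0 otherwise (boundaries use strict '>').
    """
    if not 0 < t_low < t_high:
        raise ValueError("thresholds must satisfy 0 < t_low < t_high")
    x = np.asarray(gene_logR, dtype=float)
    if not np.isfinite(x).all():
        raise ValueError("non-finite logR")
    status = np.zeros(x.shape, dtype=int)
    status[x > t_low] = 1
    status[x > t_high] = 2
    status[x < -t_low] = -1
    status[x < -t_high] = -2
    if np.isscalar(gene_logR):
        return int(status)
    return status


def compute_g_score(statuses, gene_logR, direction: str) -> tuple[float, float, float]:
    """(freq, mean_amp, g_score) for one gene in one direction.

    freq is the fraction of samples whose status has the direction's sign,
    mean_amp the mean |gene logR| over those samples (0 if none), and
    g_score their product.
    """
    status = np.asarray(statuses)
    logr = np.asarray(gene_logR, dtype=float)
    if status.size == 0:
        raise ValueError("empty cohort")
    altered = status > 0 if direction == GAIN else status < 0
    freq = float(altered.mean())
    mean_amp = float(np.abs(logr[altered]).mean()) if altered.any() else 0.0
    return freq, mean_amp, freq * mean_amp


def _direction_contributions(status: np.ndarray, logr: np.ndarray,
                             direction: str) -> np.ndarray:
    """Per (gene, sample) amplitude contribution: |logR| where altered, else 0."""
    altered = status > 0 if direction == GAIN else status < 0
    return np.where(altered, np.abs(logr), 0.0)


def permutation_significance(contributions: np.ndarray, K: int = 1000,
                             seed: int = 0,
                             offsets: np.ndarray | None = None
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Empirical p and BH q for per-gene G-scores under a cyclic-shift null.

    ``contributions`` is the genes x samples amplitude-contribution matrix in
    genomic gene order; the observed G-score of gene g is its row mean.  For
    each permutation, every sample's contribution vector is cyclically
    shifted along the genome by an independent random offset; this preserves
    each sample's alteration burden.  p = (1 + #{null >= observed}) / (1 + K).
    ``offsets`` (K x samples) may be supplied explicitly, e.g. for exhaustive
    enumeration on tiny instances.
    """
    C = np.asarray(contributions, dtype=float)
    n_genes, n_samples = C.shape
    obs = C.mean(axis=1)
    if offsets is None:
        if K < 100:
            logger.warning("permutation_significance: K=%d is small", K)
        rng = np.random.default_rng(seed)
        offsets = rng.integers(0, n_genes, size=(K, n_samples))
    else:
        offsets = np.asarray(offsets)
        K = offsets.shape[0]
    g_idx = np.arange(n_genes)
    null = np.zeros((K, n_genes))
    for s in range(n_samples):
        idx = (g_idx[None, :] - offsets[:, s][:, None]) % n_genes
        null += C[idx, s]
    null /= n_samples
    p_emp = (1.0 + (null >= obs[None, :] - 1e-15).sum(axis=0)) / (1.0 + K)
    q = multipletests(p_emp, method="fdr_bh")[1]
    return p_emp, q


def cn_expression_correlation(gene_logr, fpkm) -> tuple[float, float]:
    """Pearson r and two-sided p between log2(FPKM+1) and the gene logR.

    Returns (nan, nan) when either vector is constant (the correlation
    criterion then fails with reason 'zero variance').
    """
    import warnings

    x = np.asarray(gene_logr, dtype=float)
    y = np.log2(np.asarray(fpkm, dtype=float) + 1.0)
    if x.size < 3:
        raise ValueError("need at least 3 paired samples")
    # guard exact and float-jitter constants (e.g. a noise-free generator)
    if np.ptp(x) == 0 or np.ptp(y) <= 1e-10 * max(1.0, float(np.abs(y).max())):
        return float("nan"), float("nan")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", stats.ConstantInputWarning)
        warnings.simplefilter("ignore", stats.NearConstantInputWarning)
        r, p = stats.pearsonr(y, x)
    if not np.isfinite(r):
        return float("nan"), float("nan")
    return float(r), float(p)


def four_criteria_filter(scores: pd.DataFrame, q_max: float = 0.25,
                         g_min: float = 0.1, corr_p_max: float = 1e-3) -> pd.DataFrame:
    """Add the four per-event criteria flags and their conjunction.

    (1) significantly recurrent (q <= q_max under the permutation null);
    (2) G-score >= g_min; (3) detectable expression; (4) positive
    copy-number/expression correlation with p < corr_p_max.
    """
    out = scores.copy()
    out["crit_recurrent"] = out["q"] <= q_max
    out["crit_gscore"] = out["g_score"] >= g_min
    out["crit_detectable"] = out["detectable"].astype(bool)
    out["crit_correlation"] = ((out["corr_p"] < corr_p_max) & (out["corr_r"] > 0)
                               ).fillna(False)
    out["passes_all"] = (out["crit_recurrent"] & out["crit_gscore"]
                         & out["crit_detectable"] & out["crit_correlation"])
    reasons = []
    for row in out.itertuples():
        why = []
        if not row.crit_recurrent:
            why.append(f"q > {q_max}")
        if not row.crit_gscore:
            why.append(f"G-score < {g_min}")
        if not row.crit_detectable:
            why.append("not detectable")
        if not row.crit_correlation:
            why.append("no positive CN-expression correlation"
                       if np.isfinite(row.corr_p) else "zero variance")
        reasons.append(";".join(why))
    out["fail_reason"] = reasons
    return out


def score_scna(
    segs: pd.DataFrame,
    expr: ExpressionTable,
    panel: Sequence[GeneModel],
    genome: GenomeModel,
    samples: pd.DataFrame | None = None,
    t_low: float = 0.1,
    t_high: float = 0.9,
    K: int = 1000,
    seed: int = 0,
    q_max: float = 0.25,
    g_min: float = 0.1,
    corr_p_max: float = 1e-3,
    detect_q90_min: float = 1.0,
    max_segments: int = 2000,
) -> pd.DataFrame:
    """Full per-cancer SCNA recurrence scoring over a gene panel.

    Returns one row per (gene, cancer type, direction) with frequency,
    amplitude, G-score, permutation p/q, expression detectability,
    copy-number/expression correlation, the four criteria flags and their
    conjunction ``passes_all``.
    """
    pf = panel_frame(panel)
    gene_ids = pf["gene_id"].to_numpy()
    segs = filter_segments_for_focal(segs, genome, max_segments)
    if samples is None:
        samples = pd.DataFrame({"sample_id": expr.samples,
                                "cancer_type": expr.cancer_type.to_numpy()})
    det = detectability(expr, q90_min=detect_q90_min).set_index(
        ["gene_id", "cancer_type"])["detectable"]

    rows = []
    for ci, ct in enumerate(sorted(samples["cancer_type"].unique())):
        ct_samples = samples.loc[samples["cancer_type"] == ct, "sample_id"]
        ct_segs = segs[segs["sample_id"].isin(ct_samples)]
        retained = pd.Index(pd.unique(ct_segs["sample_id"]))
        if len(retained) == 0:
            continue
        logr = gene_level_logR_matrix(ct_segs, panel).reindex(
            index=gene_ids, columns=retained, fill_value=0.0)
        L = logr.to_numpy()
        status = assign_gistic_status(L, t_low, t_high)
        expr_samples = retained.intersection(expr.samples)
        for direction in (GAIN, LOSS):
            C = _direction_contributions(status, L, direction)
            p_emp, q = permutation_significance(
                C, K=K, seed=np.random.SeedSequence([seed, ci]).generate_state(1)[0] % (2**31),
            )
            freq = (C > 0).mean(axis=1)
            with np.errstate(invalid="ignore"):
                mean_amp = np.where(freq > 0, C.sum(axis=1) / np.maximum((C > 0).sum(axis=1), 1), 0.0)
            g = C.mean(axis=1)
            for gi, gid in enumerate(gene_ids):
                if len(expr_samples) >= 3 and gid in expr.genes:
                    r, pc = cn_expression_correlation(
                        logr.loc[gid, expr_samples].to_numpy(),
                        expr.fpkm.loc[gid, expr_samples].to_numpy())
                else:
                    r, pc = float("nan"), float("nan")
                rows.append(dict(
                    gene_id=gid, cancer_type=ct, direction=direction,
                    n_samples=len(retained), freq=float(freq[gi]),
                    mean_amp=float(mean_amp[gi]), g_score=float(g[gi]),
                    p_emp=float(p_emp[gi]), q=float(q[gi]),
                    corr_r=r, corr_p=pc,
                    detectable=bool(det.get((gid, ct), False)),
                ))
    scores = pd.DataFrame(rows)
    return four_criteria_filter(scores, q_max=q_max, g_min=g_min,
                                corr_p_max=corr_p_max)


def filter_segments_for_focal(segs: pd.DataFrame, genome: GenomeModel,
                              max_segments: int = 2000) -> pd.DataFrame:
    """Cohort hygiene for focal scoring: drop hyper-segmented samples, then
    broad (arm-scale) segments."""
    from .cohort import filter_hypersegmented

    return remove_broad(filter_hypersegmented(segs, max_segments), genome)


def overall_g_score(scores: pd.DataFrame) -> pd.DataFrame:
    """Pan-cancer G-score: unweighted sum over (gene, cancer) events passing
    all four criteria, per direction, with the number of contributing cancers."""
    passing = scores[scores["passes_all"]]
    grouped = passing.groupby(["gene_id", "direction"]).agg(
        overall_g=("g_score", "sum"), n_cancer_types=("cancer_type", "nunique"))
    idx = pd.MultiIndex.from_product(
        [scores["gene_id"].unique(), [GAIN, LOSS]], names=["gene_id", "direction"])
    out = grouped.reindex(idx, fill_value=0).reset_index()
    out["n_cancer_types"] = out["n_cancer_types"].astype(int)
    return out.sort_values(["direction", "overall_g", "gene_id"],
                           ascending=[True, False, True]).reset_index(drop=True)
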