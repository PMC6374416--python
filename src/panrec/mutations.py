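"""Mutation recurrence scoring, annotation, and meta-domain hotspots.

Recurrence integrates several driver-detection methods per gene and cancer
type.  Two light-weight callers are built in:

* a burden caller: the panel-wide silent mutation load estimates a neutral
  per-base rate; each gene's non-silent count is tested against a one-sided
  binomial expectation (the neutral non-silent:silent ratio is taken as 3:1),
  with Benjamini-Hochberg control at q < 0.1;
* a positional-clustering caller: the maximum per-residue mutation count is
  compared with uniform re-placements of the same number of mutations along
  the protein (empirical p with the +1 correction, p < 0.05).

External caller verdicts (e.g. functional-impact or 3D-clustering methods)
can be ingested from a flags table so the mutation index spans 0..5 as with
five callers.  The mutation index x of a gene is the number of callers that
flag it; genes with x >= 2 are recurrently mutated and

    M-score = mutation index x non-silent mutation frequency.

Mutation-level annotation classifies category (missense / truncating /
inframe / silent / other), zygosity (homozygous iff the multiplicity equals
the local total copy number), clonality from the estimated cancer cell
fraction (clonal iff CCF >= 0.9), and timing: a mutation present on more
than one copy must predate the copy-number event, so clonal AND
multiplicity > 1 => early; everything else is late.

The meta-domain hotspot analysis pools mutations from all members of a
shared protein domain onto consensus-alignment columns and tests each
column's count against a binomial null weighted by the column's
aligned-residue occupancy, BH-corrected across columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import GeneModel

logger = logging.getLogger("panrec")

CATEGORY_MAP = {
    "Missense_Mutation": "missense",
    "Nonsense_Mutation": "truncating",
    "Frame_Shift_Ins": "truncating",
    "Frame_Shift_Del": "truncating",
    "Splice_Site": "truncating",
    "Nonstop_Mutation": "truncating",
    "Translation_Start_Site": "truncating",
    "In_Frame_Ins": "inframe",
    "In_Frame_Del": "inframe",
    "Silent": "silent",
}

NON_SILENT = ("missense", "truncating", "inframe", "other")

BUILTIN_CALLERS = ("burden", "cluster")


def classify_category(variant_classification: str) -> str:
    """Map a MAF Variant_Classification string to a mutation category."""
    if not variant_classification:
        raise ValueError("empty variant classification")
    cat = CATEGORY_MAP.get(variant_classification)
    if cat is None:
        logger.debug("unknown variant classification %r -> 'other'",
                     variant_classification)
        return "other"
    return cat


def classify_categories(values: pd.Series) -> pd.Series:
    return values.map(lambda v: classify_category(v))


# ---------------------------------------------------------------------------
# lite callers and the mutation index
# ---------------------------------------------------------------------------

def _nonsilent(muts: pd.DataFrame) -> pd.DataFrame:
    cats = classify_categories(muts["variant_classification"])
    return muts.loc[cats != "silent"]


def burden_caller(muts: pd.DataFrame, panel: Sequence[GeneModel],
                  samples: pd.DataFrame, q_max: float = 0.1,
                  nonsilent_to_silent: float = 3.0,
                  floor_rate: float = 1e-8) -> pd.DataFrame:
    """Per (gene, cancer): one-sided binomial excess of non-silent mutations.

    The background per-base silent rate is estimated panel-wide within each
    cancer type and scaled by the neutral non-silent:silent ratio; BH across
    panel genes, passed iff q < ``q_max``.
    """
    cats = classify_categories(muts["variant_classification"])
    total_len = float(sum(g.end - g.start for g in panel))
    rows = []
    for ct, ct_samples in samples.groupby("cancer_type")["sample_id"]:
        n_samples = ct_samples.nunique()
        ct_mask = muts["sample_id"].isin(set(ct_samples))
        silent_total = int((ct_mask & (cats == "silent")).sum())
        silent_rate = silent_total / (total_len * n_samples)
        if silent_total == 0:
            logger.warning("burden_caller: no silent mutations in %s; using "
                           "floor rate %.2g", ct, floor_rate)
            silent_rate = floor_rate
        bg = min(nonsilent_to_silent * silent_rate, 1.0)
        ns = muts.loc[ct_mask & (cats != "silent")]
        counts = ns.groupby("gene_id").size()
        pvals, gene_ids, stat = [], [], []
        for g in panel:
            k = int(counts.get(g.gene_id, 0))
            n_trials = int(round((g.end - g.start) * n_samples))
            p = float(stats.binom.sf(k - 1, n_trials, bg)) if k > 0 else 1.0
            gene_ids.append(g.gene_id)
            pvals.append(min(p, 1.0))
            stat.append(k)
        q = multipletests(pvals, method="fdr_bh")[1]
        for gid, k, p, qv in zip(gene_ids, stat, pvals, q):
            rows.append(dict(caller_name="burden", gene_id=gid, cancer_type=ct,
                             statistic=float(k), p=p, q=float(qv),
                             passed=bool(qv < q_max)))
    return pd.DataFrame(rows)


def _max_run_per_row(sorted_rows: np.ndarray) -> np.ndarray:
    """Maximum count of any repeated value per row of a row-sorted int array."""
    K, N = sorted_rows.shape
    run = np.ones(K, dtype=int)
    best = np.ones(K, dtype=int)
    for j in range(1, N):
        same = sorted_rows[:, j] == sorted_rows[:, j - 1]
        run = np.where(same, run + 1, 1)
        best = np.maximum(best, run)
    return best


def cluster_caller(muts: pd.DataFrame, panel: Sequence[GeneModel],
                   samples: pd.DataFrame, K: int = 1000, seed: int = 0,
                   p_max: float = 0.05, min_mutations: int = 3) -> pd.DataFrame:
    """Per (gene, cancer): positional clustering of non-silent mutations.

    Statistic: maximum per-residue mutation count.  Null: K uniform
    re-placements of the same number of mutations along the protein.  Genes
    with fewer than ``min_mutations`` positioned mutations are not evaluable
    and reported as not passed.
    """
    rng = np.random.default_rng(seed)
    ns = _nonsilent(muts)
    ns = ns.loc[ns["protein_pos"].notna()]
    rows = []
    plen = {g.gene_id: g.protein_length for g in panel}
    for ct, ct_samples in samples.groupby("cancer_type")["sample_id"]:
        ct_muts = ns.loc[ns["sample_id"].isin(set(ct_samples))]
        by_gene = {gid: grp["protein_pos"].to_numpy(dtype=int)
                   for gid, grp in ct_muts.groupby("gene_id")}
        for g in panel:
            pos = by_gene.get(g.gene_id, np.empty(0, dtype=int))
            if len(pos) < min_mutations:
                rows.append(dict(caller_name="cluster", gene_id=g.gene_id,
                                 cancer_type=ct, statistic=np.nan, p=np.nan,
                                 passed=False, reason="fewer than "
                                 f"{min_mutations} positioned mutations"))
                continue
            obs = int(np.bincount(pos).max())
            L = plen[g.gene_id]
            draws = rng.integers(1, L + 1, size=(K, len(pos)))
            null_max = _max_run_per_row(np.sort(draws, axis=1))
            p = (1.0 + (null_max >= obs).sum()) / (1.0 + K)
            rows.append(dict(caller_name="cluster", gene_id=g.gene_id,
                             cancer_type=ct, statistic=float(obs), p=float(p),
                             passed=bool(p < p_max), reason=""))
    return pd.DataFrame(rows)


def read_caller_flags(path: str | Path) -> pd.DataFrame:
    """Ingest external caller verdicts (TSV: caller_name, gene_id,
    cancer_type, passed)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["caller_name", "gene_id", "cancer_type", "passed"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: caller flags missing columns {missing}")
    df["passed"] = df["passed"].str.lower().isin(["true", "1", "yes", "t"])
    return df


def mutation_index(caller_results: pd.DataFrame,
                   n_callers_configured: int | None = None) -> pd.DataFrame:
    """Count of callers flagging each (gene, cancer type).

    Every configured caller must report exactly once per (gene, cancer);
    duplicates are an error.  The index ranges 0..n_callers_configured.
    """
    dup = caller_results.duplicated(["caller_name", "gene_id", "cancer_type"])
    if dup.any():
        bad = caller_results.loc[dup, ["caller_name", "gene_id", "cancer_type"]]
        raise ValueError(f"duplicate caller reports:\n{bad.head()}")
    callers = caller_results["caller_name"].unique()
    if n_callers_configured is None:
        n_callers_configured = len(callers)
    if len(callers) > n_callers_configured:
        raise ValueError("more callers reported than configured")
    out = (caller_results.groupby(["gene_id", "cancer_type"])["passed"]
           .sum().astype(int).rename("mutation_index").reset_index())
    out["n_callers"] = n_callers_configured
    return out


def m_score(index: int, mut_freq: float) -> float:
    """M-score = mutation index x mutation frequency."""
    if not 0 <= mut_freq <= 1:
        raise ValueError("mut_freq must be in [0, 1]")
    return index * mut_freq


def mutation_frequency(muts: pd.DataFrame, panel: Sequence[GeneModel],
                       samples: pd.DataFrame) -> pd.DataFrame:
    """Fraction of a cancer type's samples with >= 1 non-silent mutation per
    gene.  The denominator is all retained samples of the cancer type."""
    ns = _nonsilent(muts)
    rows = []
    for ct, ct_samples in samples.groupby("cancer_type")["sample_id"]:
        n = ct_samples.nunique()
        ct_muts = ns.loc[ns["sample_id"].isin(set(ct_samples))]
        per_gene = ct_muts.groupby("gene_id")["sample_id"].nunique()
        for g in panel:
            rows.append(dict(gene_id=g.gene_id, cancer_type=ct,
                             mut_freq=float(per_gene.get(g.gene_id, 0)) / n,
                             n_samples=n))
    return pd.DataFrame(rows)


def score_mutations(muts: pd.DataFrame, panel: Sequence[GeneModel],
                    samples: pd.DataFrame, K: int = 1000, seed: int = 0,
                    external_flags: pd.DataFrame | None = None,
                    recurrent_min_index: int = 2) -> pd.DataFrame:
    """Run the configured callers and build the per (gene, cancer) score table.

    Returns gene_id, cancer_type, mut_freq, mutation_index, m_score,
    recurrent, plus one passed-flag column per caller.
    """
    results = [
        burden_caller(muts, panel, samples),
        cluster_caller(muts, panel, samples, K=K, seed=seed),
    ]
    if external_flags is not None:
        results.append(external_flags)
    caller_results = pd.concat(results, ignore_index=True)
    n_callers = caller_results["caller_name"].nunique()
    idx = mutation_index(caller_results, n_callers)
    freq = mutation_frequency(muts, panel, samples)
    out = freq.merge(idx, on=["gene_id", "cancer_type"], how="left")
    out["mutation_index"] = out["mutation_index"].fillna(0).astype(int)
    out["n_callers"] = out["n_callers"].fillna(n_callers).astype(int)
    out["m_score"] = out["mutation_index"] * out["mut_freq"]
    out["recurrent"] = out["mutation_index"] >= recurrent_min_index
    flags = caller_results.pivot_table(index=["gene_id", "cancer_type"],
                                       columns="caller_name", values="passed",
                                       aggfunc="first")
    flags.columns = [f"passed_{c}" for c in flags.columns]
    return out.merge(flags.reset_index(), on=["gene_id", "cancer_type"],
                     how="left")


def overall_m_score(scores: pd.DataFrame, recurrent_only: bool = True) -> pd.DataFrame:
    """Pan-cancer M-score: unweighted sum across cancer types.

    By default only recurrent (mutation index >= 2) cancers contribute,
    mirroring the per-cancer recurrence call; set ``recurrent_only=False``
    to sum all cancers.
    """
    contributing = scores[scores["recurrent"]] if recurrent_only else scores
    grouped = contributing.groupby("gene_id").agg(
        overall_m=("m_score", "sum"),
        n_cancer_types=("cancer_type", "nunique"))
    out = grouped.reindex(scores["gene_id"].unique(), fill_value=0).reset_index()
    out.columns = ["gene_id", "overall_m", "n_cancer_types"]
    out["n_cancer_types"] = out["n_cancer_types"].astype(int)
    return out.sort_values(["overall_m", "gene_id"],
                           ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# mutation-level annotation
# ---------------------------------------------------------------------------

def estimate_ccf(t_alt, t_ref, purity, local_total_cn, multiplicity):
    """Cancer cell fraction from the variant allele fraction.

    ccf = clip( vaf * (purity*CN + 2(1-purity)) / (purity*multiplicity), 0, 1 )

    Accepts scalars or arrays; returns NaN where the depth is zero or an
    input is missing.
    """
    t_alt = np.asarray(t_alt, dtype=float)
    t_ref = np.asarray(t_ref, dtype=float)
    purity = np.asarray(purity, dtype=float)
    cn = np.asarray(local_total_cn, dtype=float)
    mult = np.asarray(multiplicity, dtype=float)
    if np.any(mult[np.isfinite(mult)] < 1):
        raise ValueError("multiplicity must be >= 1")
    if np.any((purity[np.isfinite(purity)] <= 0) | (purity[np.isfinite(purity)] > 1)):
        raise ValueError("purity must be in (0, 1]")
    depth = t_alt + t_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        vaf = np.where(depth > 0, t_alt / depth, np.nan)
        ccf = vaf * (purity * cn + 2.0 * (1.0 - purity)) / (purity * mult)
    ccf = np.clip(ccf, 0.0, 1.0)
    if ccf.ndim == 0:
        return float(ccf)
    return ccf


def classify_clonality(ccf_hat, threshold: float = 0.9):
    """Clonal iff the CCF point estimate is >= ``threshold``."""
    ccf = np.asarray(ccf_hat, dtype=float)
    clonal = ccf >= threshold
    if ccf.ndim == 0:
        return bool(clonal)
    return clonal


def classify_zygosity(multiplicity, local_total_cn):
    """Homozygous iff every local copy carries the mutation."""
    mult = np.asarray(multiplicity)
    cn = np.asarray(local_total_cn)
    zyg = np.where(mult == cn, "homozygous", "heterozygous")
    if zyg.ndim == 0:
        return str(zyg)
    return zyg


def classify_timing(clonal, multiplicity):
    """(relative_to_cn, timing) from clonality and mutation copy number.

    A mutation on >1 copy predates the copy-number event (before_event);
    clonal AND before_event => early, anything else => late.
    """
    clonal_arr = np.asarray(clonal, dtype=bool)
    mult = np.asarray(multiplicity)
    before = mult > 1
    relative = np.where(before, "before_event", "after_event")
    timing = np.where(clonal_arr & before, "early", "late")
    if clonal_arr.ndim == 0:
        return str(relative), str(timing)
    return relative, timing


def annotate_mutations(muts: pd.DataFrame, ccf_clonal_threshold: float = 0.9
                       ) -> pd.DataFrame:
    """Full per-mutation annotation: category, zygosity, CCF, clonality,
    timing.  Mutations with missing CCF inputs are flagged not evaluable and
    excluded from fraction denominators."""
    out = muts.copy()
    out["category"] = classify_categories(out["variant_classification"])
    have = (out[["t_alt_count", "t_ref_count", "purity", "local_total_cn",
                 "multiplicity"]].notna().all(axis=1))
    ccf = np.full(len(out), np.nan)
    if have.any():
        sub = out.loc[have]
        ccf[have.to_numpy()] = estimate_ccf(
            sub["t_alt_count"].to_numpy(float), sub["t_ref_count"].to_numpy(float),
            sub["purity"].to_numpy(float), sub["local_total_cn"].to_numpy(float),
            sub["multiplicity"].to_numpy(float))
    out["ccf_hat"] = ccf
    out["evaluable"] = have & np.isfinite(ccf)
    out["clonal"] = pd.array(
        np.where(out["evaluable"], ccf >= ccf_clonal_threshold, None),
        dtype="boolean")
    zyg = np.where(have, classify_zygosity(
        out["multiplicity"].fillna(-1), out["local_total_cn"].fillna(-2)),
        "not_evaluable")
    out["zygosity"] = np.where(out["evaluable"], zyg, "not_evaluable")
    rel = np.where(out["multiplicity"].fillna(1) > 1, "before_event",
                   "after_event")
    timing = np.where(out["clonal"].fillna(False).to_numpy(bool)
                      & (rel == "before_event"), "early", "late")
    out["relative_to_cn"] = np.where(out["evaluable"], rel, "not_evaluable")
    out["timing"] = np.where(out["evaluable"], timing, "not_evaluable")
    return out


def fraction_summaries(annotations: pd.DataFrame,
                       by: Sequence[str] = ("gene_id",)) -> pd.DataFrame:
    """Fractions of mutation category / zygosity / clonality / timing.

    Fractions are over evaluable mutations (category over all mutations);
    denominators are reported.  Empty denominators yield missing fractions.
    """
    by = list(by)
    rows = []
    for key, grp in annotations.groupby(by):
        key = key if isinstance(key, tuple) else (key,)
        rec: dict = dict(zip(by, key))
        rec["n_mutations"] = len(grp)
        for cat in ("missense", "truncating", "inframe", "silent", "other"):
            rec[f"frac_{cat}"] = (grp["category"] == cat).mean() if len(grp) else np.nan
        ev = grp.loc[grp["evaluable"]]
        rec["n_evaluable"] = len(ev)
        if len(ev):
            rec["frac_clonal"] = ev["clonal"].astype(bool).mean()
            rec["frac_subclonal"] = 1.0 - rec["frac_clonal"]
            rec["frac_homozygous"] = (ev["zygosity"] == "homozygous").mean()
            rec["frac_heterozygous"] = (ev["zygosity"] == "heterozygous").mean()
            rec["frac_early"] = (ev["timing"] == "early").mean()
            rec["frac_late"] = (ev["timing"] == "late").mean()
        else:
            for name in ("clonal", "subclonal", "homozygous", "heterozygous",
                         "early", "late"):
                rec[f"frac_{name}"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# meta-domain hotspots
# ---------------------------------------------------------------------------

@dataclass
class DomainAlignmentMap:
    """Consensus alignment of one protein domain across its member genes.

    ``member_maps`` maps gene_id -> {protein position -> alignment column}
    (columns 1-based, 1..n_columns).  ``similarity`` holds the percent
    sequence similarity per member pair (symmetric keys).
    """

    domain_id: str
    n_columns: int
    member_maps: Mapping[str, Mapping[int, int]]
    similarity: Mapping[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.member_maps:
            raise ValueError("empty alignment map")
        if self.n_columns < 1:
            raise ValueError("alignment must have at least one column")
        for gid, mp in self.member_maps.items():
            for pos, col in mp.items():
                if not 1 <= col <= self.n_columns:
                    raise ValueError(f"{gid}: column {col} outside 1..{self.n_columns}")

    def max_similarity(self, gene_id: str) -> float:
        vals = [v for (a, b), v in self.similarity.items()
                if gene_id in (a, b) and a != b]
        return max(vals, default=1.0)

    @classmethod
    def from_panel(cls, panel: Sequence[GeneModel], domain_id: str
                   ) -> "DomainAlignmentMap":
        """Identity alignment for a synthetic panel whose members share a
        domain of one fixed length: column = position - domain start + 1."""
        members: dict[str, dict[int, int]] = {}
        n_cols = 0
        for g in panel:
            for d in g.domains:
                if d.domain_id == domain_id:
                    members[g.gene_id] = {p: p - d.start + 1
                                          for p in range(d.start, d.end + 1)}
                    n_cols = max(n_cols, d.length)
        if not members:
            raise ValueError(f"no panel member carries domain {domain_id!r}")
        sim = {(a, b): 1.0 for a in members for b in members if a != b}
        return cls(domain_id=domain_id, n_columns=n_cols, member_maps=members,
                   similarity=sim)


def domain_hotspots(muts: pd.DataFrame, alignment: DomainAlignmentMap,
                    min_similarity: float = 0.20, p_max: float = 0.05,
                    q_max: float = 0.05) -> pd.DataFrame:
    """Meta-domain hotspot columns from pooled member mutations.

    Members whose maximum pairwise similarity is below ``min_similarity`` are
    excluded.  Non-silent mutations falling inside a retained member's domain
    span are pooled onto alignment columns; column c with k of N pooled
    mutations is tested against Binomial(N, w_c), where w_c is the fraction
    of aligned residues in column c; one-sided upper tail, BH across occupied
    columns.  Significant iff p < p_max and q < q_max.
    """
    retained = {gid: mp for gid, mp in alignment.member_maps.items()
                if alignment.max_similarity(gid) >= min_similarity}
    if not retained:
        raise ValueError("no members retained after the similarity filter")

    col_occupancy = np.zeros(alignment.n_columns + 1)
    for mp in retained.values():
        for col in mp.values():
            col_occupancy[col] += 1
    total_res = col_occupancy.sum()

    ns = _nonsilent(muts)
    ns = ns.loc[ns["protein_pos"].notna() & ns["gene_id"].isin(retained)]
    counts = np.zeros(alignment.n_columns + 1, dtype=int)
    for gid, grp in ns.groupby("gene_id"):
        mp = retained[gid]
        for pos in grp["protein_pos"].astype(int):
            col = mp.get(pos)
            if col is not None:
                counts[col] += 1
    N = int(counts.sum())

    rows = []
    for col in range(1, alignment.n_columns + 1):
        if col_occupancy[col] == 0:
            continue  # column with no aligned residues
        w = col_occupancy[col] / total_res
        k = int(counts[col])
        p = float(stats.binom.sf(k - 1, N, w)) if N > 0 and k > 0 else 1.0
        rows.append(dict(domain_id=alignment.domain_id, column=col,
                         mutation_count=k, weight=w, p=min(p, 1.0)))
    out = pd.DataFrame(rows)
    if len(out):
        out["fdr_q"] = multipletests(out["p"], method="fdr_bh")[1]
        out["significant"] = (out["p"] < p_max) & (out["fdr_q"] < q_max)
    return out
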