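"""Synthetic multi-cancer cohort generator with planted driver genes.

The generator emulates the statistical structure the scoring pipeline
assumes, so that every downstream stage is testable without any download:

* per-cancer sample groups with lineage-specific expression signatures and a
  copy-number dosage effect on expression (log2(FPKM+1) is linear in the
  gene-level logR);
* segmented copy number as a background of random focal and arm-level
  segments plus planted focal amplifications/deletions (0.5-5 Mb) covering
  driver genes in 30-60% of samples;
* somatic mutations as a per-gene Poisson background with driver genes
  elevated by a multiplier, half of the excess concentrated at a hotspot
  codon inside the gene's first annotated protein domain;
* a clonal/subclonal cancer-cell-fraction mixture with read counts drawn
  binomially at fixed depth, so CCFs are re-estimable from the table;
* rare fusion events with confidence tiers.

Every draw is keyed by ``(seed, cancer-type index)`` so adding a cancer type
does not perturb the ones already generated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import (
    CohortBundle,
    DomainSpan,
    ExpressionTable,
    GeneModel,
    GenomeModel,
    panel_frame,
    validate_panel,
)
from .scna import gene_level_logR_matrix

MB = 1_000_000

_TIER_PROBS = (0.75, 0.125, 0.075, 0.05)

# background variant-classification mix; non-silent:silent is 3:1, the
# neutral coding expectation assumed by the burden caller
_BG_CLASSES = ("Missense_Mutation", "Silent", "Nonsense_Mutation",
               "In_Frame_Del", "3'UTR")
_BG_PROBS = (0.50, 0.25, 0.15, 0.05, 0.05)
_DRIVER_CLASSES = ("Missense_Mutation", "Nonsense_Mutation")
_DRIVER_PROBS = (0.8, 0.2)

_FILTER_TAGS = ("PASS", "wga", "PASS,wga", "germline", "oxog")
_FILTER_PROBS = (0.92, 0.03, 0.01, 0.02, 0.02)


def build_default_genome(n_chroms: int = 8, chrom_length: int = 120 * MB,
                         centromere_frac: float = 0.4) -> GenomeModel:
    """A compact synthetic genome: equal-length chromosomes, fixed centromere."""
    lengths = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    cents = {c: int(centromere_frac * chrom_length) for c in lengths}
    return GenomeModel(chrom_lengths=lengths, centromeres=cents)


def build_default_panel(genome: GenomeModel | None = None, n_genes: int = 73,
                        seed: int = 73) -> list[GeneModel]:
    """A 73-gene writer/reader/eraser panel laid out across the genome.

    Class counts mirror a histone-acetylation modulator panel: 12 writers,
    6 writer_readers, 37 readers, 18 erasers.  Genes are spaced at least
    6 Mb apart so a planted focal event (max 5 Mb) never covers two panel
    genes at once.  Readers carry a BRD domain (110 aa), writers a catalytic
    HAT domain (170 aa), erasers a deacetylase domain (300 aa);
    writer_readers carry both HAT and BRD.
    """
    if genome is None:
        genome = build_default_genome()
    rng = np.random.default_rng(seed)

    classes = (["writer"] * 12 + ["writer_reader"] * 6 + ["reader"] * 37 +
               ["eraser"] * 18)
    if n_genes != len(classes):
        # keep the same proportions for non-default sizes
        base = np.array([12, 6, 37, 18], dtype=float) / 73.0
        counts = np.floor(base * n_genes).astype(int)
        counts[2] += n_genes - counts.sum()
        classes = (["writer"] * counts[0] + ["writer_reader"] * counts[1] +
                   ["reader"] * counts[2] + ["eraser"] * counts[3])
    classes = list(rng.permutation(classes))

    chroms = list(genome.chrom_lengths)
    total = sum(genome.chrom_lengths.values())
    spacing = total / n_genes
    panel: list[GeneModel] = []
    for i in range(n_genes):
        center = (i + 0.5) * spacing + rng.uniform(-1.5 * MB, 1.5 * MB)
        # map the linear coordinate onto a chromosome
        acc = 0
        for chrom in chroms:
            length = genome.chrom_lengths[chrom]
            if center < acc + length:
                pos = int(center - acc)
                break
            acc += length
        plen = int(rng.integers(400, 2001))
        start = int(np.clip(pos, 0, length - 3 * plen - 1))
        fam = classes[i]
        domains: list[DomainSpan] = []
        if fam in ("writer", "writer_reader"):
            hi = plen // 2 - 170 if fam == "writer_reader" else plen - 170
            s = int(rng.integers(1, max(2, hi)))
            domains.append(DomainSpan("HAT_CAT", s, s + 169))
        if fam in ("reader", "writer_reader"):
            lo = plen // 2 if fam == "writer_reader" else 1
            s = int(rng.integers(lo, plen - 110 + 1))
            domains.append(DomainSpan("BRD", s, s + 109))
        if fam == "eraser":
            s = int(rng.integers(1, plen - 300 + 1))
            domains.append(DomainSpan("DEACETYL", s, s + 299))
        panel.append(
            GeneModel(
                gene_id=f"PANEL{i + 1:02d}",
                chrom=chrom,
                start=start,
                end=start + 3 * plen,
                family_class=fam,
                domains=tuple(domains),
                protein_length=plen,
            )
        )
    validate_panel(panel)
    return panel


@dataclass
class GeneratorSpec:
    """All knobs of the synthetic cohort; defaults are the study conditions."""

    n_cancer_types: int = 4
    samples_per_type: int = 150
    panel: Sequence[GeneModel] = field(default_factory=build_default_panel)
    genome: GenomeModel = field(default_factory=build_default_genome)
    planted_amplified: Mapping[str, frozenset[str]] = field(default_factory=dict)
    planted_deleted: Mapping[str, frozenset[str]] = field(default_factory=dict)
    planted_mutated: Mapping[str, frozenset[str]] = field(default_factory=dict)
    amp_logR_mean: float = 0.6
    del_logR_mean: float = -0.6
    background_segment_rate: float = 60.0   # segments per genome per sample
    arm_event_rate: float = 1.0             # broad (whole-arm) events per sample
    dosage_beta: float = 1.0                # log2 expression units per logR unit
    expr_noise_sd: float = 0.5
    baseline_log2_mean: float = 3.0
    baseline_log2_sd: float = 1.0
    lineage_offset_sd: float = 0.7
    background_mut_rate: float = 1.5        # mutations per Mb per sample
    driver_mut_multiplier: float = 15.0
    hotspot_fraction: float = 0.5
    clonal_fraction: float = 0.7
    subclonal_ccf_beta: tuple[float, float] = (2.0, 2.0)
    fusion_rate: float = 0.04               # fusions per sample
    n_fusion_partners: int = 150
    depth: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("background_segment_rate", "arm_event_rate",
                     "background_mut_rate", "fusion_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("hotspot_fraction", "clonal_fraction"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        gene_ids = {g.gene_id for g in self.panel}
        for label, mapping in (("planted_amplified", self.planted_amplified),
                               ("planted_deleted", self.planted_deleted),
                               ("planted_mutated", self.planted_mutated)):
            for ct, genes in mapping.items():
                unknown = set(genes) - gene_ids
                if unknown:
                    raise ValueError(f"{label}[{ct}]: genes not in panel: {sorted(unknown)}")

    @property
    def cancer_types(self) -> list[str]:
        return [f"CT{i + 1:02d}" for i in range(self.n_cancer_types)]


def default_spec(seed: int = 0, n_cancer_types: int = 4,
                 samples_per_type: int = 150, n_amp: int = 3, n_del: int = 3,
                 n_mut: int = 3, **kwargs) -> GeneratorSpec:
    """A GeneratorSpec with disjoint planted driver sets per cancer type.

    Planted genes are distinct across cancer types and evidence classes, so
    planted-truth recovery metrics are unambiguous.
    """
    panel = kwargs.pop("panel", build_default_panel())
    rng = np.random.default_rng([seed, 9001])
    per_ct = n_amp + n_del + n_mut
    cts = [f"CT{i + 1:02d}" for i in range(n_cancer_types)]
    need = per_ct * n_cancer_types
    if need > len(panel):
        raise ValueError("not enough panel genes for disjoint planted sets")
    chosen = [str(g) for g in rng.permutation([g.gene_id for g in panel])[:need]]
    amp: dict[str, frozenset[str]] = {}
    dele: dict[str, frozenset[str]] = {}
    mut: dict[str, frozenset[str]] = {}
    k = 0
    for ct in cts:
        amp[ct] = frozenset(chosen[k:k + n_amp]); k += n_amp
        dele[ct] = frozenset(chosen[k:k + n_del]); k += n_del
        mut[ct] = frozenset(chosen[k:k + n_mut]); k += n_mut
    return GeneratorSpec(
        n_cancer_types=n_cancer_types, samples_per_type=samples_per_type,
        panel=panel, planted_amplified=amp, planted_deleted=dele,
        planted_mutated=mut, seed=seed, **kwargs)


def null_spec(seed: int = 0, **kwargs) -> GeneratorSpec:
    """A cohort with no planted drivers (pure background)."""
    return GeneratorSpec(seed=seed, **kwargs)


@dataclass
class PlantedTruth:
    """Ground truth of a generated cohort."""

    amplified: Mapping[str, frozenset[str]]
    deleted: Mapping[str, frozenset[str]]
    mutated: Mapping[str, frozenset[str]]
    hotspot_codons: Mapping[tuple[str, str], int]  # (gene_id, cancer_type) -> codon
    mutations: pd.DataFrame  # mutation_id, true_ccf, true_clonal, true_timing, is_hotspot


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _draw_segments(rng: np.random.Generator, spec: GeneratorSpec,
                   sample_ids: np.ndarray, cancer_type: str) -> pd.DataFrame:
    genome = spec.genome
    chroms = np.array(list(genome.chrom_lengths))
    lens = np.array([genome.chrom_lengths[c] for c in chroms], dtype=float)
    probs = lens / lens.sum()
    rows: list[pd.DataFrame] = []

    n_samples = len(sample_ids)
    # focal/dispersed background segments
    n_bg = rng.poisson(spec.background_segment_rate, size=n_samples)
    total = int(n_bg.sum())
    if total:
        samp = np.repeat(sample_ids, n_bg)
        ci = rng.choice(len(chroms), size=total, p=probs)
        seg_len = np.exp(rng.uniform(np.log(0.5 * MB), np.log(20 * MB), size=total))
        seg_len = seg_len.astype(int)
        max_start = lens[ci].astype(int) - seg_len
        start0 = (rng.random(total) * np.maximum(max_start, 1)).astype(int)
        rows.append(pd.DataFrame({
            "sample_id": samp, "chrom": chroms[ci], "start": start0 + 1,
            "end": start0 + seg_len, "num_mark": seg_len // 10_000,
            "logR": rng.normal(0.0, 0.15, size=total),
        }))

    # broad whole-arm events (removed by the focal filter downstream)
    arms = genome.arms()
    n_arm = rng.poisson(spec.arm_event_rate, size=n_samples)
    total = int(n_arm.sum())
    if total:
        samp = np.repeat(sample_ids, n_arm)
        ai = rng.integers(0, len(arms), size=total)
        rows.append(pd.DataFrame({
            "sample_id": samp,
            "chrom": arms["chrom"].to_numpy()[ai],
            "start": arms["start"].to_numpy()[ai] + 1,
            "end": arms["end"].to_numpy()[ai],
            "num_mark": (arms["end"].to_numpy()[ai] - arms["start"].to_numpy()[ai]) // 10_000,
            "logR": rng.normal(0.0, 0.2, size=total),
        }))

    # planted focal events covering driver genes
    gene_by_id = {g.gene_id: g for g in spec.panel}
    for planted, mean_lr in ((spec.planted_amplified.get(cancer_type, frozenset()),
                              spec.amp_logR_mean),
                             (spec.planted_deleted.get(cancer_type, frozenset()),
                              spec.del_logR_mean)):
        for gid in sorted(planted):
            gene = gene_by_id[gid]
            penetrance = rng.uniform(0.3, 0.6)
            carriers = sample_ids[rng.random(n_samples) < penetrance]
            k = len(carriers)
            if k == 0:
                continue
            glen = gene.end - gene.start
            seg_len = rng.uniform(max(0.5 * MB, glen + 1), 5 * MB, size=k).astype(int)
            lo = np.maximum(gene.end - seg_len, 0)
            hi = np.minimum(gene.start, genome.chrom_lengths[gene.chrom] - seg_len)
            start0 = (lo + rng.random(k) * np.maximum(hi - lo, 1)).astype(int)
            rows.append(pd.DataFrame({
                "sample_id": carriers, "chrom": gene.chrom, "start": start0 + 1,
                "end": start0 + seg_len, "num_mark": seg_len // 10_000,
                "logR": rng.normal(mean_lr, 0.1, size=k),
            }))

    if not rows:
        return pd.DataFrame(columns=["sample_id", "chrom", "start", "end",
                                     "num_mark", "logR"])
    segs = pd.concat(rows, ignore_index=True)
    return segs.sort_values(["sample_id", "chrom", "start"],
                            kind="mergesort").reset_index(drop=True)


def _draw_mutations(rng: np.random.Generator, spec: GeneratorSpec,
                    sample_ids: np.ndarray, purity: np.ndarray,
                    cancer_type: str, hotspots: dict[tuple[str, str], int],
                    id_offset: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Returns (mutation table, per-mutation truth table)."""
    planted = spec.planted_mutated.get(cancer_type, frozenset())
    n_samples = len(sample_ids)
    recs: list[dict] = []
    mid = id_offset

    for gene in spec.panel:
        lam_bg = spec.background_mut_rate * (gene.end - gene.start) / MB
        is_driver = gene.gene_id in planted
        counts_bg = rng.poisson(lam_bg, size=n_samples)
        counts_dr = (rng.poisson(lam_bg * (spec.driver_mut_multiplier - 1.0),
                                 size=n_samples) if is_driver else
                     np.zeros(n_samples, dtype=int))
        if is_driver and gene.domains:
            dom = gene.domains[0]
            hotspots.setdefault((gene.gene_id, cancer_type),
                                int(rng.integers(dom.start, dom.end + 1)))
        hot_codon = hotspots.get((gene.gene_id, cancer_type))

        for si in np.flatnonzero(counts_bg + counts_dr):
            for j in range(counts_bg[si] + counts_dr[si]):
                driver_excess = j >= counts_bg[si]
                if driver_excess:
                    vc = _DRIVER_CLASSES[rng.choice(2, p=_DRIVER_PROBS)]
                    if hot_codon is not None and rng.random() < spec.hotspot_fraction:
                        ppos = hot_codon
                        vc = "Missense_Mutation"
                        hot = True
                    else:
                        ppos = int(rng.integers(1, gene.protein_length + 1))
                        hot = False
                else:
                    vc = _BG_CLASSES[rng.choice(len(_BG_CLASSES), p=_BG_PROBS)]
                    ppos = int(rng.integers(1, gene.protein_length + 1))
                    hot = False

                clonal = bool(rng.random() < spec.clonal_fraction)
                if clonal:
                    ccf = 1.0
                    if rng.random() < 0.75:
                        mult = 2
                        cn = 2 if rng.random() < 0.3 else 3
                    else:
                        mult, cn = 1, 2
                else:
                    a, b = spec.subclonal_ccf_beta
                    ccf = float(rng.beta(a, b))
                    mult, cn = 1, 2
                p = purity[si]
                vaf = ccf * mult * p / (p * cn + 2.0 * (1.0 - p))
                alt = int(rng.binomial(spec.depth, min(vaf, 1.0)))
                timing = "early" if (clonal and mult > 1) else "late"
                recs.append(dict(
                    mutation_id=f"M{mid:06d}",
                    sample_id=sample_ids[si], gene_id=gene.gene_id,
                    chrom=gene.chrom, pos=gene.start + 3 * (ppos - 1) + 1,
                    protein_pos=ppos, variant_classification=vc,
                    filter_tag=_FILTER_TAGS[rng.choice(len(_FILTER_TAGS),
                                                       p=_FILTER_PROBS)],
                    t_alt_count=alt, t_ref_count=spec.depth - alt,
                    purity=p, local_total_cn=cn, multiplicity=mult,
                    cancer_type=cancer_type,
                    _ccf=ccf, _clonal=clonal, _timing=timing, _hot=hot,
                ))
                mid += 1

    cols = ["mutation_id", "sample_id", "gene_id", "chrom", "pos",
            "protein_pos", "variant_classification", "filter_tag",
            "t_alt_count", "t_ref_count", "purity", "local_total_cn",
            "multiplicity", "cancer_type"]
    if not recs:
        empty = pd.DataFrame(columns=cols)
        truth = pd.DataFrame(columns=["mutation_id", "true_ccf", "true_clonal",
                                      "true_timing", "is_hotspot"])
        return empty, truth
    df = pd.DataFrame(recs)
    truth = df[["mutation_id", "_ccf", "_clonal", "_timing", "_hot"]].rename(
        columns={"_ccf": "true_ccf", "_clonal": "true_clonal",
                 "_timing": "true_timing", "_hot": "is_hotspot"})
    return df[cols], truth


def _draw_fusions(rng: np.random.Generator, spec: GeneratorSpec,
                  sample_ids: np.ndarray, cancer_type: str) -> pd.DataFrame:
    n = rng.poisson(spec.fusion_rate, size=len(sample_ids))
    total = int(n.sum())
    if total == 0:
        return pd.DataFrame(columns=["sample_id", "cancer_type", "gene5",
                                     "gene3", "tier"])
    samp = np.repeat(sample_ids, n)
    panel_ids = np.array([g.gene_id for g in spec.panel])
    pg = panel_ids[rng.integers(0, len(panel_ids), size=total)]
    partner = np.array([f"PR{int(i) + 1:03d}" for i in
                        rng.integers(0, spec.n_fusion_partners, size=total)])
    five_prime = rng.random(total) < 0.5
    tier = rng.choice([1, 2, 3, 4], size=total, p=_TIER_PROBS)
    return pd.DataFrame({
        "sample_id": samp, "cancer_type": cancer_type,
        "gene5": np.where(five_prime, pg, partner),
        "gene3": np.where(five_prime, partner, pg),
        "tier": tier,
    })


def generate_cohort(spec: GeneratorSpec) -> tuple[CohortBundle, PlantedTruth]:
    """Generate a deterministic multi-cancer cohort and its planted truth."""
    panel = list(spec.panel)
    validate_panel(panel)
    pf = panel_frame(panel)
    gene_order = pf["gene_id"].to_numpy()

    rng0 = np.random.default_rng([spec.seed, 0])
    baseline = pd.Series(
        rng0.normal(spec.baseline_log2_mean, spec.baseline_log2_sd,
                    size=len(gene_order)),
        index=gene_order)

    seg_parts, mut_parts, truth_parts, fus_parts = [], [], [], []
    sample_rows = []
    fpkm_parts: list[pd.DataFrame] = []
    labels: dict[str, str] = {}
    hotspots: dict[tuple[str, str], int] = {}
    mid_offset = 0

    for i, ct in enumerate(spec.cancer_types):
        rng = np.random.default_rng([spec.seed, i + 1])
        sample_ids = np.array([f"{ct}-T{j + 1:03d}"
                               for j in range(spec.samples_per_type)])
        purity = rng.uniform(0.3, 0.9, size=len(sample_ids))
        sample_rows.append(pd.DataFrame({"sample_id": sample_ids,
                                         "cancer_type": ct, "purity": purity}))
        labels.update({s: ct for s in sample_ids})

        segs = _draw_segments(rng, spec, sample_ids, ct)
        seg_parts.append(segs)

        # expression with dosage effect on the gene-level logR
        logr = gene_level_logR_matrix(segs, panel)
        logr = logr.reindex(index=gene_order, columns=sample_ids, fill_value=0.0)
        lineage = rng.normal(0.0, spec.lineage_offset_sd, size=len(gene_order))
        noise = rng.normal(0.0, spec.expr_noise_sd,
                           size=(len(gene_order), len(sample_ids)))
        log2 = (baseline.to_numpy()[:, None] + lineage[:, None]
                + spec.dosage_beta * logr.to_numpy() + noise)
        fpkm = np.clip(np.exp2(log2) - 1.0, 0.0, None)
        fpkm_parts.append(pd.DataFrame(fpkm, index=gene_order, columns=sample_ids))

        muts, truth = _draw_mutations(rng, spec, sample_ids, purity, ct,
                                      hotspots, mid_offset)
        mid_offset += len(muts)
        mut_parts.append(muts)
        truth_parts.append(truth)
        fus_parts.append(_draw_fusions(rng, spec, sample_ids, ct))

    def _concat(parts: list[pd.DataFrame]) -> pd.DataFrame:
        filled = [p for p in parts if len(p)]
        if not filled:
            return parts[0]
        return pd.concat(filled, ignore_index=True)

    samples = pd.concat(sample_rows, ignore_index=True)
    expr = ExpressionTable(
        fpkm=pd.concat(fpkm_parts, axis=1),
        cancer_type=pd.Series(labels, name="cancer_type"),
    )
    bundle = CohortBundle(
        panel=panel,
        genome=spec.genome,
        segments=_concat(seg_parts),
        expression=expr,
        mutations=_concat(mut_parts),
        fusions=_concat(fus_parts),
        samples=samples,
    )
    truth = PlantedTruth(
        amplified={ct: frozenset(spec.planted_amplified.get(ct, frozenset()))
                   for ct in spec.cancer_types},
        deleted={ct: frozenset(spec.planted_deleted.get(ct, frozenset()))
                 for ct in spec.cancer_types},
        mutated={ct: frozenset(spec.planted_mutated.get(ct, frozenset()))
                 for ct in spec.cancer_types},
        hotspot_codons=dict(hotspots),
        mutations=_concat(truth_parts),
    )
    return bundle, truth


# ---------------------------------------------------------------------------
# truth recovery
# ---------------------------------------------------------------------------

def truth_recovery_report(
    truth: PlantedTruth,
    calls: Mapping[str, Mapping[str, Iterable[str]]],
    panel: Sequence[GeneModel],
) -> pd.DataFrame:
    """Confusion counts per evidence class and cancer type, plus overall rows.

    ``calls`` maps an evidence class ("amplified", "deleted", "mutated") to a
    per-cancer mapping of called gene sets.  Sensitivity = TP / planted,
    FPR = FP / non-planted panel genes.
    """
    panel_ids = {g.gene_id for g in panel}
    truth_by_class = {"amplified": truth.amplified, "deleted": truth.deleted,
                      "mutated": truth.mutated}
    rows = []
    for klass, per_ct_calls in calls.items():
        if klass not in truth_by_class:
            raise ValueError(f"unknown evidence class {klass!r}")
        truth_map = truth_by_class[klass]
        agg = dict(tp=0, fp=0, fn=0, tn=0)
        for ct in truth_map:
            called = set(per_ct_calls.get(ct, ()))
            unknown = called - panel_ids
            if unknown:
                raise ValueError(f"calls for {klass}/{ct} not in panel: {sorted(unknown)}")
            planted = set(truth_map[ct])
            tp = len(called & planted)
            fp = len(called - planted)
            fn = len(planted - called)
            tn = len(panel_ids) - tp - fp - fn
            rows.append(dict(evidence_class=klass, cancer_type=ct, tp=tp, fp=fp,
                             fn=fn, tn=tn,
                             sensitivity=tp / (tp + fn) if tp + fn else np.nan,
                             fpr=fp / (fp + tn) if fp + tn else np.nan))
            for key, val in zip(("tp", "fp", "fn", "tn"), (tp, fp, fn, tn)):
                agg[key] += val
        rows.append(dict(evidence_class=klass, cancer_type="overall", **agg,
                         sensitivity=(agg["tp"] / (agg["tp"] + agg["fn"])
                                      if agg["tp"] + agg["fn"] else np.nan),
                         fpr=(agg["fp"] / (agg["fp"] + agg["tn"])
                              if agg["fp"] + agg["tn"] else np.nan)))
    return pd.DataFrame(rows)
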