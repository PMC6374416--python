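"""Callers, mutation index/M-score, CCF annotation, and domain hotspots."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from panrec.cohort import GeneModel
from panrec.mutations import (
    CATEGORY_MAP,
    DomainAlignmentMap,
    annotate_mutations,
    burden_caller,
    classify_category,
    classify_clonality,
    classify_timing,
    classify_zygosity,
    cluster_caller,
    domain_hotspots,
    estimate_ccf,
    fraction_summaries,
    m_score,
    mutation_frequency,
    mutation_index,
    overall_m_score,
)

GENE = GeneModel("g1", "chr1", 0, 3000, "reader",
                 domains=(), protein_length=1000)
SAMPLES = pd.DataFrame({"sample_id": [f"s{i}" for i in range(50)],
                        "cancer_type": "CT01"})


def _muts(rows):
    cols = ["sample_id", "gene_id", "variant_classification", "protein_pos"]
    df = pd.DataFrame(rows, columns=cols)
    for c in ("t_alt_count", "t_ref_count", "purity", "local_total_cn",
              "multiplicity"):
        df[c] = np.nan
    return df


class TestCategory:
    @pytest.mark.parametrize("vc,expected", [
        ("Missense_Mutation", "missense"),
        ("Nonsense_Mutation", "truncating"),
        ("Frame_Shift_Del", "truncating"),
        ("Splice_Site", "truncating"),
        ("In_Frame_Ins", "inframe"),
        ("Silent", "silent"),
        ("5'Flank", "other"),
    ])
    def test_mapping_table(self, vc, expected):
        assert classify_category(vc) == expected

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            classify_category("")

    def test_vocabulary_fuzz_matches_table_oracle(self, rng):
        vocab = list(CATEGORY_MAP) + ["RNA", "Intron", "3'UTR"]
        draws = [vocab[i] for i in rng.integers(0, len(vocab), size=500)]
        got = [classify_category(v) for v in draws]
        expect = [CATEGORY_MAP.get(v, "other") for v in draws]
        assert got == expect


class TestBurdenCaller:
    def test_zero_mutations_not_passed(self):
        muts = _muts([("s0", "g1", "Silent", 5)])  # one silent, no non-silent
        out = burden_caller(muts, [GENE], SAMPLES)
        row = out.iloc[0]
        assert row.p == 1.0 and not row.passed

    def test_exact_binomial_tail_with_floor_rate(self):
        """With no silent mutations the caller falls back to the floor rate;
        the p-value equals a hand-summed exact binomial tail."""
        muts = _muts([("s0", "g1", "Missense_Mutation", 10),
                      ("s1", "g1", "Missense_Mutation", 20),
                      ("s2", "g1", "Missense_Mutation", 30)])
        gene = GeneModel("g1", "chr1", 0, 1000, "reader", protein_length=333)
        out = burden_caller(muts, [gene], SAMPLES, floor_rate=1e-6 / 3)
        n_trials = 1000 * 50
        bg = 1e-6
        # exact upper-tail sum (truncated far beyond float precision)
        tail = sum(
            math.comb(n_trials, k) * bg**k * (1 - bg) ** (n_trials - k)
            for k in range(3, 60))
        assert out.iloc[0].p == pytest.approx(tail, rel=1e-9)

    def test_planted_excess_is_flagged(self, small_cohort):
        bundle, truth = small_cohort
        out = burden_caller(bundle.mutations, bundle.panel, bundle.samples)
        out = out.set_index(["gene_id", "cancer_type"])
        hits = sum(out.loc[(g, ct)].passed
                   for ct, genes in truth.mutated.items() for g in genes)
        total = sum(len(v) for v in truth.mutated.values())
        assert hits >= 0.8 * total


class TestClusterCaller:
    def test_maximal_clustering(self):
        gene = GeneModel("g1", "chr1", 0, 1500, "reader", protein_length=500)
        muts = _muts([(f"s{i}", "g1", "Missense_Mutation", 100)
                      for i in range(10)])
        out = cluster_caller(muts, [gene], SAMPLES, K=1000, seed=1)
        assert out.iloc[0].p == pytest.approx(1 / 1001)
        assert out.iloc[0].passed

    def test_three_distinct_positions_L3_p_is_one(self):
        gene = GeneModel("g1", "chr1", 0, 9, "reader", protein_length=3)
        muts = _muts([("s0", "g1", "Missense_Mutation", 1),
                      ("s1", "g1", "Missense_Mutation", 2),
                      ("s2", "g1", "Missense_Mutation", 3)])
        out = cluster_caller(muts, [gene], SAMPLES, K=500, seed=0)
        # observed max per-residue count is 1; every placement has max >= 1
        assert out.iloc[0].p == 1.0

    def test_too_few_positioned_mutations_not_evaluable(self):
        muts = _muts([("s0", "g1", "Missense_Mutation", 1),
                      ("s1", "g1", "Missense_Mutation", 2)])
        out = cluster_caller(muts, [GENE], SAMPLES)
        row = out.iloc[0]
        assert not row.passed and "positioned" in row.reason

    def test_type_one_error_controlled_under_uniform(self, rng):
        """Uniformly placed mutations pass at <= 7% (nominal 5% + margin)."""
        gene = GeneModel("g1", "chr1", 0, 1200, "reader", protein_length=400)
        passes = 0
        n_sim = 150
        for i in range(n_sim):
            pos = rng.integers(1, 401, size=12)
            muts = _muts([(f"s{j}", "g1", "Missense_Mutation", int(p))
                          for j, p in enumerate(pos)])
            out = cluster_caller(muts, [gene], SAMPLES, K=300, seed=i)
            passes += int(out.iloc[0].passed)
        assert passes / n_sim <= 0.07


class TestIndexAndScore:
    def _results(self, flags):
        return pd.DataFrame({
            "caller_name": [f"c{i}" for i in range(len(flags))],
            "gene_id": "g1", "cancer_type": "CT01", "passed": flags,
        })

    def test_count_of_passing_callers(self):
        out = mutation_index(self._results([True, True, False, False, False]), 5)
        assert out.iloc[0].mutation_index == 2

    def test_all_false(self):
        out = mutation_index(self._results([False] * 5), 5)
        assert out.iloc[0].mutation_index == 0

    def test_duplicate_caller_report_is_error(self):
        df = self._results([True, False])
        df["caller_name"] = "same"
        with pytest.raises(ValueError, match="duplicate"):
            mutation_index(df, 5)

    def test_random_flag_tables_match_sum_oracle(self, rng):
        rows = []
        for g in ("a", "b", "c"):
            for ct in ("x", "y"):
                for caller in ("c1", "c2", "c3", "c4", "c5"):
                    rows.append((caller, g, ct, bool(rng.random() < 0.5)))
        df = pd.DataFrame(rows, columns=["caller_name", "gene_id",
                                         "cancer_type", "passed"])
        out = mutation_index(df, 5).set_index(["gene_id", "cancer_type"])
        for g in ("a", "b", "c"):
            for ct in ("x", "y"):
                expect = sum(p for (c, gg, cc, p) in rows
                             if gg == g and cc == ct)
                assert out.loc[(g, ct), "mutation_index"] == expect

    def test_m_score_product(self):
        assert m_score(2, 0.10) == pytest.approx(0.20)
        assert m_score(0, 0.9) == 0.0
        with pytest.raises(ValueError):
            m_score(2, 1.5)

    def test_overall_m_sums_recurrent_cancers(self, rng):
        rows = []
        for g in [f"g{i}" for i in range(8)]:
            for ct in [f"CT{j}" for j in range(4)]:
                idx = int(rng.integers(0, 3))
                freq = float(rng.uniform(0, 0.5))
                rows.append(dict(gene_id=g, cancer_type=ct,
                                 mutation_index=idx, mut_freq=freq,
                                 m_score=idx * freq, recurrent=idx >= 2))
        scores = pd.DataFrame(rows)
        out = overall_m_score(scores).set_index("gene_id")
        for g in [f"g{i}" for i in range(8)]:
            expect = sum(r["m_score"] for r in rows
                         if r["gene_id"] == g and r["recurrent"])
            assert out.loc[g, "overall_m"] == pytest.approx(expect)
        # alternative convention: sum all cancers
        out_all = overall_m_score(scores, recurrent_only=False).set_index("gene_id")
        for g in [f"g{i}" for i in range(8)]:
            expect = sum(r["m_score"] for r in rows if r["gene_id"] == g)
            assert out_all.loc[g, "overall_m"] == pytest.approx(expect)


class TestCcfAndLabels:
    def test_pure_diploid_clonal(self):
        assert estimate_ccf(60, 60, 1.0, 2, 1) == pytest.approx(1.0)

    def test_half_ccf(self):
        assert estimate_ccf(30, 90, 1.0, 2, 1) == pytest.approx(0.5)

    def test_zero_depth_is_missing(self):
        assert np.isnan(estimate_ccf(0, 0, 0.5, 2, 1))

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            estimate_ccf(10, 10, 0.5, 2, 0)
        with pytest.raises(ValueError):
            estimate_ccf(10, 10, 1.5, 2, 1)

    def test_clonality_threshold(self):
        assert classify_clonality(1.0)
        assert classify_clonality(0.9)
        assert not classify_clonality(0.3)

    def test_zygosity(self):
        assert classify_zygosity(2, 2) == "homozygous"
        assert classify_zygosity(1, 2) == "heterozygous"

    @pytest.mark.parametrize("clonal,mult,rel,timing", [
        (True, 2, "before_event", "early"),
        (True, 1, "after_event", "late"),
        (False, 2, "before_event", "late"),
        (False, 1, "after_event", "late"),
    ])
    def test_timing_truth_table(self, clonal, mult, rel, timing):
        assert classify_timing(clonal, mult) == (rel, timing)

    def test_annotation_excludes_unevaluable(self):
        muts = pd.DataFrame({
            "sample_id": ["s0", "s1"], "gene_id": "g1",
            "variant_classification": ["Missense_Mutation", "Silent"],
            "protein_pos": [1, 2],
            "t_alt_count": [60, np.nan], "t_ref_count": [60, np.nan],
            "purity": [1.0, np.nan], "local_total_cn": [2, np.nan],
            "multiplicity": [1, np.nan],
        })
        ann = annotate_mutations(muts)
        assert bool(ann.loc[0, "evaluable"]) and not bool(ann.loc[1, "evaluable"])
        assert ann.loc[1, "timing"] == "not_evaluable"


class TestFractionSummaries:
    def _annotated(self, cats):
        muts = pd.DataFrame({
            "sample_id": [f"s{i}" for i in range(len(cats))],
            "gene_id": "g1",
            "variant_classification": cats,
            "protein_pos": 1,
            "t_alt_count": 60, "t_ref_count": 60, "purity": 1.0,
            "local_total_cn": 2, "multiplicity": 1,
        })
        return annotate_mutations(muts)

    def test_missense_fraction(self):
        ann = self._annotated(["Missense_Mutation"] * 3 + ["Nonsense_Mutation"])
        out = fraction_summaries(ann)
        assert out.iloc[0].frac_missense == pytest.approx(0.75)
        assert out.iloc[0].frac_truncating == pytest.approx(0.25)

    def test_all_unevaluable_gives_missing_fractions(self):
        ann = self._annotated(["Missense_Mutation"] * 2)
        ann["evaluable"] = False
        out = fraction_summaries(ann)
        assert np.isnan(out.iloc[0].frac_clonal)

    def test_matches_counting_oracle(self, rng):
        vocab = ["Missense_Mutation", "Nonsense_Mutation", "Silent",
                 "In_Frame_Del"]
        cats = [vocab[i] for i in rng.integers(0, 4, size=60)]
        ann = self._annotated(cats)
        out = fraction_summaries(ann).iloc[0]
        from panrec.mutations import classify_category as cc
        mapped = [cc(v) for v in cats]
        for cat in ("missense", "truncating", "inframe", "silent"):
            assert out[f"frac_{cat}"] == pytest.approx(
                mapped.count(cat) / len(mapped))


class TestDomainHotspots:
    def _identity_map(self, genes, length):
        members = {g: {p: p for p in range(1, length + 1)} for g in genes}
        sim = {(a, b): 1.0 for a in genes for b in genes if a != b}
        return DomainAlignmentMap("D", length, members, sim)

    def test_extreme_hotspot_is_significant(self):
        amap = self._identity_map(["g1", "g2"], 50)
        muts = _muts([(f"s{i}", "g1", "Missense_Mutation", 7)
                      for i in range(20)])
        out = domain_hotspots(muts, amap)
        sig = out[out.significant]
        assert list(sig.column) == [7]

    def test_no_mutations_no_hotspots(self):
        amap = self._identity_map(["g1"], 10)
        out = domain_hotspots(_muts([]), amap)
        assert not out.significant.any()

    def test_small_instance_matches_exact_binomial(self):
        """L=5, N=6: per-column p equals the hand-summed binomial tail."""
        amap = self._identity_map(["g1"], 5)
        pos = [1, 1, 1, 2, 4, 5]
        muts = _muts([(f"s{i}", "g1", "Missense_Mutation", p)
                      for i, p in enumerate(pos)])
        out = domain_hotspots(muts, amap).set_index("column")
        for col in range(1, 6):
            k = pos.count(col)
            tail = sum(math.comb(6, j) * 0.2**j * 0.8 ** (6 - j)
                       for j in range(k, 7)) if k else 1.0
            assert out.loc[col, "p"] == pytest.approx(tail, rel=1e-9)

    def test_low_similarity_member_excluded(self):
        members = {g: {p: p for p in range(1, 11)} for g in ("g1", "g2", "g3")}
        sim = {("g1", "g2"): 0.9, ("g2", "g1"): 0.9,
               ("g1", "g3"): 0.1, ("g3", "g1"): 0.1,
               ("g2", "g3"): 0.15, ("g3", "g2"): 0.15}
        amap = DomainAlignmentMap("D", 10, members, sim)
        muts = _muts([(f"s{i}", "g3", "Missense_Mutation", 5)
                      for i in range(30)])
        out = domain_hotspots(muts, amap)
        assert out["mutation_count"].sum() == 0  # g3's pile-up is excluded

    def test_from_panel_identity_alignment(self, default_panel):
        amap = DomainAlignmentMap.from_panel(default_panel, "BRD")
        assert amap.n_columns == 110
        some_member = next(iter(amap.member_maps))
        gene = next(g for g in default_panel if g.gene_id == some_member)
        dom = next(d for d in gene.domains if d.domain_id == "BRD")
        assert amap.member_maps[some_member][dom.start] == 1

    def test_empty_map_is_error(self):
        with pytest.raises(ValueError):
            DomainAlignmentMap("D", 10, {})

    def test_uniform_null_false_positive_rate(self, rng, default_panel):
        """Uniformly placed mutations yield significant columns at <= 5%."""
        amap = DomainAlignmentMap.from_panel(default_panel, "DEACETYL")
        members = list(amap.member_maps)
        n_sig = 0
        n_cols = 0
        for i in range(30):
            rows = []
            for j in range(40):
                g = members[rng.integers(0, len(members))]
                pos = list(amap.member_maps[g])
                rows.append((f"s{j}", g, "Missense_Mutation",
                             pos[rng.integers(0, len(pos))]))
            out = domain_hotspots(_muts(rows), amap)
            n_sig += int(out.significant.sum())
            n_cols += len(out)
        assert n_sig / n_cols <= 0.05


def test_mutation_frequency_denominator_is_all_samples(small_cohort):
    bundle, _ = small_cohort
    freq = mutation_frequency(bundle.mutations, bundle.panel, bundle.samples)
    n_ct = bundle.samples.groupby("cancer_type")["sample_id"].nunique()
    assert (freq.groupby("cancer_type")["n_samples"].first() == n_ct).all()
    assert ((freq["mut_freq"] >= 0) & (freq["mut_freq"] <= 1)).all()
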