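"""Data model, barcode deduplication, record filters, and file round-trips."""

import numpy as np
import pandas as pd
import pytest

from panrec.cohort import (
    FUSION_COLUMNS,
    SEG_COLUMNS,
    ExpressionTable,
    GeneModel,
    SampleBarcode,
    filter_hypersegmented,
    filter_mutations,
    read_expression,
    read_fusions,
    read_gene_model,
    read_maf_like,
    read_seg,
    select_unique_samples,
    write_expression,
    write_fusions,
    write_gene_model,
    write_maf_like,
    write_seg,
)
from panrec.simulate import build_default_panel


def _mk(participant, stype, portion, analyte="D", plate="A100", vial="A"):
    return SampleBarcode.parse(
        f"TCGA-{participant}-{stype}{vial}-{portion:02d}{analyte}-{plate}-01")


class TestBarcodes:
    def test_parse_fields(self):
        bc = SampleBarcode.parse("TCGA-AB-1234-01A-11D-A123-01")
        assert bc.participant == "TCGA-AB-1234"
        assert bc.sample_type_code == "01"
        assert bc.portion == 11
        assert bc.analyte == "D"
        assert bc.plate == "A123"

    def test_unparseable_rejected_with_identity(self):
        with pytest.raises(ValueError, match="not-a-barcode"):
            SampleBarcode.parse("not-a-barcode")

    def test_primary_beats_metastatic(self):
        kept = select_unique_samples([_mk("AB-1111", "01", 1), _mk("AB-1111", "06", 1)])
        assert [b.sample_type_code for b in kept] == ["01"]

    def test_single_barcode_is_identity(self):
        bc = _mk("AB-1111", "01", 1)
        assert select_unique_samples([bc]) == [bc]

    def test_portion_tiebreak_prefers_higher(self):
        kept = select_unique_samples([_mk("AB-1111", "01", 1), _mk("AB-1111", "01", 3)])
        assert kept[0].portion == 3

    def test_normal_tissue_priority(self):
        kept = select_unique_samples(
            [_mk("AB-1111", "11", 1), _mk("AB-1111", "10", 1)], tissue="normal")
        assert kept[0].sample_type_code == "10"

    def test_empty_input(self):
        assert select_unique_samples([]) == []

    @staticmethod
    def _oracle_pick(cands, tissue):
        """Independent selection: explicit pairwise rule comparisons."""
        pri = ({"01": 0, "02": 1, "06": 2} if tissue == "tumor"
               else {"10": 0, "11": 1})
        cands = [c for c in cands if c.sample_type_code in pri]
        if not cands:
            return None
        best = cands[0]
        for c in cands[1:]:
            if pri[c.sample_type_code] != pri[best.sample_type_code]:
                if pri[c.sample_type_code] < pri[best.sample_type_code]:
                    best = c
                continue
            a_c = 0 if c.analyte == "D" else 1
            a_b = 0 if best.analyte == "D" else 1
            if a_c != a_b:
                if a_c < a_b:
                    best = c
                continue
            if c.portion != best.portion:
                if c.portion > best.portion:
                    best = c
                continue
            if c.plate > best.plate:
                best = c
        return best

    @pytest.mark.parametrize("tissue", ["tumor", "normal"])
    def test_matches_pairwise_rule_oracle(self, rng, tissue):
        codes = ["01", "02", "06", "10", "11"]
        for trial in range(200):
            n = int(rng.integers(1, 8))
            barcodes = [
                _mk(f"{'AB' if rng.random() < 0.5 else 'CD'}-{int(rng.integers(1, 4)):04d}",
                    codes[rng.integers(0, len(codes))],
                    int(rng.integers(1, 30)),
                    analyte="DGWX"[rng.integers(0, 4)],
                    plate=f"A{int(rng.integers(100, 999))}")
                for _ in range(n)
            ]
            got = {b.participant: b for b in select_unique_samples(barcodes, tissue)}
            by_part: dict = {}
            for b in barcodes:
                by_part.setdefault(b.participant, []).append(b)
            for part, cands in by_part.items():
                want = self._oracle_pick(cands, tissue)
                assert got.get(part) == want

    def test_deduplication_idempotent(self, rng):
        barcodes = [_mk(f"AB-{i:04d}", "01", int(rng.integers(1, 9)))
                    for i in range(5) for _ in range(3)]
        once = select_unique_samples(barcodes)
        assert select_unique_samples(once) == once

    def test_order_independent(self, rng):
        barcodes = [_mk(f"AB-{int(rng.integers(1, 4)):04d}",
                        ["01", "02", "06"][rng.integers(0, 3)],
                        int(rng.integers(1, 9))) for _ in range(12)]
        ref = select_unique_samples(barcodes)
        perm = [barcodes[i] for i in rng.permutation(len(barcodes))]
        assert select_unique_samples(perm) == ref


class TestMutationFilter:
    def test_whole_tag_semantics(self):
        muts = pd.DataFrame({
            "filter_tag": ["PASS", "wga", "PASS;wga", "germline", "PASS,wga"],
            "gene_id": list("abcde"),
        })
        kept = filter_mutations(muts)
        # compound with the ';' separator is one unknown token and is dropped;
        # a comma compound of only PASS/wga tokens is retained
        assert list(kept["gene_id"]) == ["a", "b", "e"]

    def test_empty_table(self):
        out = filter_mutations(pd.DataFrame({"filter_tag": []}))
        assert len(out) == 0

    def test_missing_column_is_config_error(self):
        with pytest.raises(KeyError):
            filter_mutations(pd.DataFrame({"gene_id": ["a"]}))

    def test_random_tags_match_string_oracle(self, rng):
        vocab = ["PASS", "wga", "WGA", "pass", "germline", "oxog",
                 "PASS,wga", "PASS,germline", "PASS;wga", ""]
        tags = [vocab[i] for i in rng.integers(0, len(vocab), size=1000)]
        muts = pd.DataFrame({"filter_tag": tags})
        kept = filter_mutations(muts)

        def oracle(tag):
            return bool(tag) and all(
                t.lower() in ("pass", "wga") for t in tag.split(","))

        assert len(kept) == sum(oracle(t) for t in tags)

    def test_order_independent(self, rng):
        tags = ["PASS", "wga", "oxog", "PASS,wga", "germline"] * 10
        muts = pd.DataFrame({"filter_tag": tags, "i": range(len(tags))})
        ref = set(filter_mutations(muts)["i"])
        shuffled = muts.sample(frac=1, random_state=3)
        assert set(filter_mutations(shuffled)["i"]) == ref


class TestHypersegmented:
    def _segs(self, counts):
        rows = []
        for sample, n in counts.items():
            for i in range(n):
                rows.append((sample, "chr1", 10 * i + 1, 10 * i + 5, 3, 0.0))
        return pd.DataFrame(rows, columns=SEG_COLUMNS)

    def test_strict_inequality_at_threshold(self):
        segs = self._segs({"over": 2001, "at": 2000})
        out = filter_hypersegmented(segs)
        assert set(out["sample_id"]) == {"at"}

    def test_identity_when_under_threshold(self):
        segs = self._segs({"a": 5, "b": 7})
        pd.testing.assert_frame_equal(filter_hypersegmented(segs), segs)

    def test_random_cohort_matches_counting_oracle(self, rng):
        counts = {f"s{i}": int(rng.integers(1, 30)) for i in range(40)}
        segs = self._segs(counts)
        out = filter_hypersegmented(segs, max_segments=15)
        assert set(out["sample_id"]) == {s for s, n in counts.items() if n <= 15}


class TestRoundTrips:
    def test_seg_roundtrip(self, tmp_path):
        segs = pd.DataFrame(
            [("s1", "chr1", 100, 200, 10, 0.5),
             ("s1", "chr2", 1, 50, 5, -0.25),
             ("s2", "chr1", 5, 10, 2, 0.0)],
            columns=SEG_COLUMNS)
        write_seg(segs, tmp_path / "x.seg")
        back = read_seg(tmp_path / "x.seg")
        pd.testing.assert_frame_equal(back, segs)

    def test_firehose_header_dialect(self, tmp_path):
        p = tmp_path / "fh.seg"
        p.write_text("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
                     "s1\tchr1\t100\t200\t10\t0.5\n")
        df = read_seg(p)
        assert list(df.columns) == SEG_COLUMNS
        assert df.loc[0, "logR"] == 0.5 and df.loc[0, "start"] == 100

    def test_seg_malformed_row_names_line(self, tmp_path):
        p = tmp_path / "bad.seg"
        p.write_text("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n"
                     "s1\tchr1\t100\t200\t10\t0.5\n"
                     "s1\tchr1\tnotanumber\t300\t10\t0.5\n")
        with pytest.raises(ValueError, match="line 3"):
            read_seg(p)

    def test_fuzzed_seg_roundtrip(self, rng, tmp_path):
        for trial in range(25):
            n = int(rng.integers(1, 30))
            start = rng.integers(1, 10_000, size=n)
            segs = pd.DataFrame({
                "sample_id": [f"s{int(i)}" for i in rng.integers(0, 4, size=n)],
                "chrom": [f"chr{int(i)}" for i in rng.integers(1, 5, size=n)],
                "start": start,
                "end": start + rng.integers(1, 5_000, size=n),
                "num_mark": rng.integers(1, 100, size=n),
                "logR": np.round(rng.normal(size=n), 6),
            }).sort_values(["sample_id", "chrom", "start"],
                           kind="mergesort").reset_index(drop=True)
            write_seg(segs, tmp_path / "f.seg")
            pd.testing.assert_frame_equal(read_seg(tmp_path / "f.seg"), segs)

    def test_expression_roundtrip(self, tmp_path):
        expr = ExpressionTable(
            fpkm=pd.DataFrame([[1.5, 0.0], [2.25, 7.0]],
                              index=pd.Index(["g1", "g2"], name="gene_id"),
                              columns=["s1", "s2"]),
            cancer_type=pd.Series({"s1": "CT01", "s2": "CT02"}))
        write_expression(expr, tmp_path / "e.tsv", tmp_path / "lab.tsv")
        back = read_expression(tmp_path / "e.tsv", tmp_path / "lab.tsv")
        pd.testing.assert_frame_equal(back.fpkm, expr.fpkm)
        assert back.cancer_type.to_dict() == expr.cancer_type.to_dict()

    def test_maf_roundtrip_and_aliases(self, tmp_path, small_cohort):
        bundle, _ = small_cohort
        muts = bundle.mutations.head(40).reset_index(drop=True)
        write_maf_like(muts, tmp_path / "m.tsv")
        back = read_maf_like(tmp_path / "m.tsv")
        for col in ("sample_id", "gene_id", "protein_pos", "t_alt_count"):
            assert list(back[col]) == list(muts[col])
        # MAF-style headers map onto the canonical names
        p = tmp_path / "alias.tsv"
        p.write_text("Hugo_Symbol\tTumor_Sample_Barcode\tVariant_Classification"
                     "\tFILTER\tProtein_position\n"
                     "BRD9\tTCGA-AB-0001\tMissense_Mutation\tPASS\t17\n")
        df = read_maf_like(p)
        assert df.loc[0, "gene_id"] == "BRD9"
        assert df.loc[0, "protein_pos"] == 17

    def test_fusion_roundtrip_and_tier_validation(self, tmp_path):
        fus = pd.DataFrame(
            [("s1", "CT01", "A", "B", 1), ("s2", "CT01", "B", "C", 4)],
            columns=FUSION_COLUMNS)
        write_fusions(fus, tmp_path / "f.tsv")
        pd.testing.assert_frame_equal(read_fusions(tmp_path / "f.tsv"), fus)
        bad = fus.assign(tier=[1, 9])
        write_fusions(bad, tmp_path / "bad.tsv")
        with pytest.raises(ValueError, match="line 3"):
            read_fusions(tmp_path / "bad.tsv")

    def test_gene_model_roundtrip(self, tmp_path, default_panel):
        write_gene_model(default_panel, tmp_path / "panel.bed")
        back = read_gene_model(tmp_path / "panel.bed")
        assert back == default_panel


class TestGeneModel:
    def test_invariants(self):
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 10, 10, "writer")
        with pytest.raises(ValueError):
            GeneModel("g", "chr1", 0, 300, "histone_fan")

    def test_default_protein_length(self):
        g = GeneModel("g", "chr1", 0, 3000, "reader")
        assert g.protein_length == 1000

    def test_panel_family_classes_exhaustive(self, default_panel):
        classes = {g.family_class for g in default_panel}
        assert classes == {"writer", "reader", "writer_reader", "eraser"}
        assert len(default_panel) == 73
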