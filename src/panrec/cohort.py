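"""Cohort data model, sample-selection rules, and text-format I/O.

The pipeline works on five tabular inputs for one gene panel:

* a BED-like gene model (0-based, half-open coordinates) with the
  writer/reader/eraser family class and protein-domain annotations;
* segmented copy number in SEG format (1-based, inclusive; ``logR`` is the
  log2 copy ratio);
* a gene x sample FPKM expression matrix plus a per-sample cancer-type label;
* a MAF-like somatic mutation table carrying the read counts, tumor purity,
  local total copy number and mutation multiplicity needed for cancer-cell-
  fraction estimation;
* a transcript-fusion event table with a confidence tier in 1..4.

This module also implements the cohort hygiene rules applied before any
scoring: one sample per participant (primary > recurrent > metastatic, native
DNA preferred, then highest portion and plate), whole-tag PASS/WGA mutation
filtering, and exclusion of hyper-segmented copy-number profiles.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("panrec")

FAMILY_CLASSES = ("writer", "reader", "writer_reader", "eraser")

TUMOR_TYPE_PRIORITY = {"01": 0, "02": 1, "06": 2}
NORMAL_TYPE_PRIORITY = {"10": 0, "11": 1}

SEG_COLUMNS = ["sample_id", "chrom", "start", "end", "num_mark", "logR"]
MUTATION_COLUMNS = [
    "sample_id", "gene_id", "chrom", "pos", "protein_pos",
    "variant_classification", "filter_tag", "t_alt_count", "t_ref_count",
    "purity", "local_total_cn", "multiplicity",
]
FUSION_COLUMNS = ["sample_id", "cancer_type", "gene5", "gene3", "tier"]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainSpan:
    """A protein-domain annotation, 1-based inclusive protein coordinates."""

    domain_id: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid domain span {self.domain_id}:{self.start}-{self.end}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class GeneModel:
    """One panel gene: BED-like genomic span plus protein annotation.

    ``start``/``end`` are 0-based half-open.  ``protein_length`` defaults to
    ``(end - start) // 3``, i.e. the synthetic convention that the gene body
    is fully coding.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    family_class: str
    domains: tuple[DomainSpan, ...] = ()
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"{self.gene_id}: start must be < end")
        if self.family_class not in FAMILY_CLASSES:
            raise ValueError(f"{self.gene_id}: unknown family class {self.family_class!r}")
        if self.protein_length is None:
            object.__setattr__(self, "protein_length", (self.end - self.start) // 3)
        for d in self.domains:
            if d.end > self.protein_length:
                raise ValueError(f"{self.gene_id}: domain {d.domain_id} exceeds protein length")

    @property
    def length(self) -> int:
        return self.end - self.start


def validate_panel(panel: Sequence[GeneModel]) -> None:
    ids = [g.gene_id for g in panel]
    if len(set(ids)) != len(ids):
        raise ValueError("gene_id not unique within panel")


def panel_frame(panel: Sequence[GeneModel]) -> pd.DataFrame:
    """Panel as a DataFrame, sorted by genomic coordinate."""
    df = pd.DataFrame(
        {
            "gene_id": [g.gene_id for g in panel],
            "chrom": [g.chrom for g in panel],
            "start": [g.start for g in panel],
            "end": [g.end for g in panel],
            "family_class": [g.family_class for g in panel],
            "protein_length": [g.protein_length for g in panel],
        }
    )
    return df.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class GenomeModel:
    """Chromosome lengths and centromere positions of the genome build."""

    chrom_lengths: Mapping[str, int]
    centromeres: Mapping[str, int]

    def arms(self) -> pd.DataFrame:
        """Arm intervals as a DataFrame (chrom, arm, start, end), half-open."""
        rows = []
        for chrom, length in self.chrom_lengths.items():
            cen = self.centromeres[chrom]
            rows.append((chrom, "p", 0, cen))
            rows.append((chrom, "q", cen, length))
        return pd.DataFrame(rows, columns=["chrom", "arm", "start", "end"])


# barcode text like TCGA-AB-1234-01A-11D-A123-01
_BARCODE_RE = re.compile(
    r"^(?P<participant>[A-Z0-9]+-[A-Z0-9]{2}-[A-Z0-9]{4})"
    r"-(?P<sample_type>\d{2})(?P<vial>[A-Z])"
    r"-(?P<portion>\d{2})(?P<analyte>[A-Z])"
    r"-(?P<plate>[A-Z0-9]+)"
    r"(?:-(?P<center>[A-Z0-9]+))?$"
)


@dataclass(frozen=True)
class SampleBarcode:
    """A parsed TCGA-style aliquot barcode."""

    raw: str
    participant: str
    sample_type_code: str
    vial: str
    portion: int
    analyte: str
    plate: str
    center: str | None = None

    @classmethod
    def parse(cls, text: str) -> "SampleBarcode":
        m = _BARCODE_RE.match(text.strip())
        if m is None:
            raise ValueError(f"unparseable barcode: {text!r}")
        return cls(
            raw=text.strip(),
            participant=m["participant"],
            sample_type_code=m["sample_type"],
            vial=m["vial"],
            portion=int(m["portion"]),
            analyte=m["analyte"],
            plate=m["plate"],
            center=m["center"],
        )


@dataclass
class ExpressionTable:
    """Gene x sample FPKM matrix with a cancer-type label per sample."""

    fpkm: pd.DataFrame
    cancer_type: pd.Series

    def __post_init__(self) -> None:
        self.cancer_type = self.cancer_type.reindex(self.fpkm.columns)
        if self.cancer_type.isna().any():
            missing = list(self.cancer_type.index[self.cancer_type.isna()])
            raise ValueError(f"samples without a cancer_type label: {missing[:5]}")
        if (self.fpkm.to_numpy() < 0).any():
            raise ValueError("FPKM values must be non-negative")

    @property
    def samples(self) -> pd.Index:
        return self.fpkm.columns

    @property
    def genes(self) -> pd.Index:
        return self.fpkm.index

    def samples_of(self, cancer_type: str) -> pd.Index:
        return self.cancer_type.index[self.cancer_type == cancer_type]


@dataclass
class CohortBundle:
    """Aligned per-cancer containers for one gene panel."""

    panel: list[GeneModel]
    genome: GenomeModel
    segments: pd.DataFrame
    expression: ExpressionTable
    mutations: pd.DataFrame
    fusions: pd.DataFrame
    samples: pd.DataFrame  # sample_id, cancer_type (one row per retained sample)

    @property
    def cancer_types(self) -> list[str]:
        return sorted(self.samples["cancer_type"].unique())


# ---------------------------------------------------------------------------
# sample selection and record filters
# ---------------------------------------------------------------------------

def _barcode_sort_key(bc: SampleBarcode, priority: Mapping[str, int]):
    analyte_rank = 0 if bc.analyte == "D" else 1
    # portion and plate are "higher is better"; invert for an ascending sort
    return (priority[bc.sample_type_code], analyte_rank, -bc.portion, _NegStr(bc.plate))


class _NegStr:
    """Wrapper that reverses lexicographic order, for 'max plate wins' sorts."""

    __slots__ = ("s",)

    def __init__(self, s: str):
        self.s = s

    def __lt__(self, other: "_NegStr") -> bool:
        return self.s > other.s

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _NegStr) and self.s == other.s


def select_unique_samples(
    barcodes: Iterable[SampleBarcode | str], tissue: str = "tumor"
) -> list[SampleBarcode]:
    """Keep one aliquot per participant.

    Ordered rules: sample type (tumor 01 > 02 > 06; normal 10 > 11), analyte
    D preferred over G/W/X, then the highest portion number, then the highest
    plate (lexicographic).  Barcodes whose sample type is outside the
    requested tissue's code set are ignored.
    """
    if tissue == "tumor":
        priority = TUMOR_TYPE_PRIORITY
    elif tissue == "normal":
        priority = NORMAL_TYPE_PRIORITY
    else:
        raise ValueError(f"tissue must be 'tumor' or 'normal', got {tissue!r}")

    parsed: list[SampleBarcode] = []
    for bc in barcodes:
        parsed.append(bc if isinstance(bc, SampleBarcode) else SampleBarcode.parse(bc))

    best: dict[str, SampleBarcode] = {}
    for bc in parsed:
        if bc.sample_type_code not in priority:
            continue
        cur = best.get(bc.participant)
        if cur is None or _barcode_sort_key(bc, priority) < _barcode_sort_key(cur, priority):
            best[bc.participant] = bc
    # deterministic output order: by participant
    return [best[p] for p in sorted(best)]


def filter_mutations(muts: pd.DataFrame) -> pd.DataFrame:
    """Retain mutation records tagged PASS or WGA (alone or jointly).

    A tag is a comma-separated list of tokens; a record is kept iff every
    token is PASS or wga (case-insensitive).  Any third token — or an
    unrecognized compound such as "PASS;wga" — disqualifies the record.
    """
    if "filter_tag" not in muts.columns:
        raise KeyError("mutation table lacks a 'filter_tag' column")
    allowed = {"pass", "wga"}

    def _ok(tag: object) -> bool:
        if not isinstance(tag, str) or not tag:
            return False
        tokens = [t.strip().lower() for t in tag.split(",")]
        return all(t in allowed for t in tokens)

    keep = muts["filter_tag"].map(_ok)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_mutations: dropped %d of %d records", dropped, len(muts))
    return muts.loc[keep].reset_index(drop=True)


def filter_hypersegmented(segs: pd.DataFrame, max_segments: int = 2000) -> pd.DataFrame:
    """Drop samples whose copy-number profile has more than ``max_segments`` segments."""
    counts = segs.groupby("sample_id").size()
    bad = set(counts.index[counts > max_segments])
    if bad:
        logger.info("filter_hypersegmented: excluding %d hyper-segmented samples", len(bad))
        return segs.loc[~segs["sample_id"].isin(bad)].reset_index(drop=True)
    return segs


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_FIREHOSE_SEG_ALIASES = {
    "id": "sample_id", "sample": "sample_id", "sample_id": "sample_id",
    "chrom": "chrom", "chromosome": "chrom",
    "loc.start": "start", "start": "start",
    "loc.end": "end", "end": "end",
    "num.mark": "num_mark", "num_mark": "num_mark",
    "seg.mean": "logR", "segment_mean": "logR", "logr": "logR",
}

_MAF_ALIASES = {
    "tumor_sample_barcode": "sample_id",
    "hugo_symbol": "gene_id",
    "chromosome": "chrom",
    "start_position": "pos",
    "protein_position": "protein_pos",
    "filter": "filter_tag",
}
# canonical column names match case-insensitively as well
_MAF_ALIASES.update({c.lower(): c for c in MUTATION_COLUMNS})


def _rename_header(columns: Sequence[str], aliases: Mapping[str, str]) -> dict[str, str]:
    return {c: aliases.get(c.lower(), c) for c in columns}


def _check_numeric(df: pd.DataFrame, path: Path, columns: Sequence[str],
                   required: bool = True) -> pd.DataFrame:
    """Convert columns to numeric, reporting the 1-based data line of a bad row."""
    for col in columns:
        if col not in df.columns:
            if required:
                raise ValueError(f"{path}: missing required column {col!r}")
            continue
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna() & (df[col].astype(str).str.len() > 0)
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # +1 header, +1 1-based
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
        df[col] = converted
    return df


def _warn_unknown_chrom(df: pd.DataFrame, genome: GenomeModel | None, path: Path) -> None:
    if genome is None or "chrom" not in df.columns:
        return
    unknown = set(df["chrom"].unique()) - set(genome.chrom_lengths)
    if unknown:
        logger.warning("%s: unknown chromosomes retained: %s", path, sorted(unknown))


def read_seg(path: str | Path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a Broad/Firehose 6-column SEG file (1-based inclusive coordinates)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=_rename_header(df.columns, _FIREHOSE_SEG_ALIASES))
    missing = [c for c in SEG_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: SEG header missing columns {missing}")
    df = df[SEG_COLUMNS].copy()
    df = _check_numeric(df, path, ["start", "end", "num_mark", "logR"])
    df[["start", "end", "num_mark"]] = df[["start", "end", "num_mark"]].astype(int)
    if not np.isfinite(df["logR"]).all():
        raise ValueError(f"{path}: non-finite logR")
    _warn_unknown_chrom(df, genome, path)
    return df.sort_values(["sample_id", "chrom", "start"], kind="mergesort").reset_index(drop=True)


def write_seg(segs: pd.DataFrame, path: str | Path) -> None:
    out = segs[SEG_COLUMNS].rename(
        columns={"sample_id": "ID", "start": "loc.start", "end": "loc.end",
                 "num_mark": "num.mark", "logR": "seg.mean"}
    )
    out.to_csv(path, sep="\t", index=False)


def read_expression(path: str | Path, labels: str | Path | pd.Series) -> ExpressionTable:
    """Read a genes x samples FPKM TSV (first column gene_id) plus sample labels.

    ``labels`` is either a Series (sample_id -> cancer_type) or the path to a
    two-column TSV with header ``sample_id\tcancer_type``.
    """
    fpkm = pd.read_csv(path, sep="\t", index_col=0)
    fpkm.index.name = "gene_id"
    if isinstance(labels, (str, Path)):
        lab = pd.read_csv(labels, sep="\t", dtype=str)
        labels = lab.set_index("sample_id")["cancer_type"]
    return ExpressionTable(fpkm=fpkm, cancer_type=labels)


def write_expression(expr: ExpressionTable, path: str | Path,
                     labels_path: str | Path) -> None:
    expr.fpkm.to_csv(path, sep="\t")
    expr.cancer_type.rename("cancer_type").rename_axis("sample_id").to_csv(
        labels_path, sep="\t")


def read_maf_like(path: str | Path, genome: GenomeModel | None = None) -> pd.DataFrame:
    """Read a MAF-like mutation TSV; extra columns are passed through."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    df = df.rename(columns=_rename_header(df.columns, _MAF_ALIASES))
    required = ["sample_id", "gene_id", "variant_classification", "filter_tag"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: mutation table missing columns {missing}")
    int_like = ["pos", "t_alt_count", "t_ref_count", "local_total_cn", "multiplicity"]
    df = _check_numeric(df, path, int_like + ["protein_pos", "purity"], required=False)
    for col in int_like:
        if col in df.columns:
            df[col] = df[col].astype("Int64")
    if "protein_pos" in df.columns:
        df["protein_pos"] = df["protein_pos"].astype("Int64")
    _warn_unknown_chrom(df, genome, path)
    return df.reset_index(drop=True)


def write_maf_like(muts: pd.DataFrame, path: str | Path) -> None:
    muts.to_csv(path, sep="\t", index=False)


def read_fusions(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in FUSION_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: fusion table missing columns {missing}")
    df = _check_numeric(df, path, ["tier"])
    df["tier"] = df["tier"].astype(int)
    if not df["tier"].isin([1, 2, 3, 4]).all():
        line = int(np.flatnonzero(~df["tier"].isin([1, 2, 3, 4]).to_numpy())[0]) + 2
        raise ValueError(f"{path}: tier outside 1..4 at line {line}")
    return df[FUSION_COLUMNS + [c for c in df.columns if c not in FUSION_COLUMNS]]


def write_fusions(fusions: pd.DataFrame, path: str | Path) -> None:
    fusions.to_csv(path, sep="\t", index=False)


def _format_domains(domains: tuple[DomainSpan, ...]) -> str:
    if not domains:
        return "."
    return "|".join(f"{d.domain_id}:{d.start}-{d.end}" for d in domains)


def _parse_domains(text: str) -> tuple[DomainSpan, ...]:
    if not text or text == ".":
        return ()
    spans = []
    for part in text.split("|"):
        dom, _, rng = part.partition(":")
        lo, _, hi = rng.partition("-")
        spans.append(DomainSpan(dom, int(lo), int(hi)))
    return tuple(spans)


def read_gene_model(path: str | Path) -> list[GeneModel]:
    """Read a BED-like panel file (0-based half-open) into GeneModel records."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = ["chrom", "start", "end", "gene_id", "family_class",
                "protein_length", "domains"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: gene model missing columns {missing}")
    df = _check_numeric(df, path, ["start", "end", "protein_length"])
    panel = [
        GeneModel(
            gene_id=row.gene_id,
            chrom=row.chrom,
            start=int(row.start),
            end=int(row.end),
            family_class=row.family_class,
            domains=_parse_domains(row.domains),
            protein_length=int(row.protein_length),
        )
        for row in df.itertuples()
    ]
    validate_panel(panel)
    return panel


def write_gene_model(panel: Sequence[GeneModel], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "chrom": [g.chrom for g in panel],
            "start": [g.start for g in panel],
            "end": [g.end for g in panel],
            "gene_id": [g.gene_id for g in panel],
            "family_class": [g.family_class for g in panel],
            "protein_length": [g.protein_length for g in panel],
            "domains": [_format_domains(g.domains) for g in panel],
        }
    )
    df.to_csv(path, sep="\t", index=False)
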