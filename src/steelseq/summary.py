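"""Break-frequency accounting, genomic-region annotation and amplicon profiles.

Provides the per-library frequency report (unique breaks per million aligned
nucleotides), a priority-based partition of the genome into gene-relative
region categories (promoter bins, UTRs, exons, introns, downstream, distal
intergenic) with strand-relative break frequencies per category, reference-set
subtraction for untreated control libraries, and the per-position nucleotide
composition / unique-sequence statistics used for amplicon experiments.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .alignio import AlignedReadRecord, ReferenceGenome, SteelseqError, _iter_records
from .detector import SSBCall

__all__ = [
    "FrequencyReport",
    "RegionModel",
    "CATEGORIES",
    "ssb_frequency",
    "build_region_model",
    "annotate_calls",
    "filter_by_reference_set",
    "filter_canonical",
    "per_position_profile",
    "unique_fraction",
    "unique_percent",
]

#: Region categories in *increasing* priority order; when categories overlap
#: the genome position takes the highest-priority (last painted) label.
CATEGORIES = [
    "distal_intergenic",
    "downstream_3kb",
    "other_intron",
    "first_intron",
    "exon",
    "three_prime_utr",
    "five_prime_utr",
    "promoter_2to3kb",
    "promoter_1to2kb",
    "promoter_0to1kb",
]

_CANONICAL_RE = re.compile(r"^(chr)?([0-9]{1,2}|X|Y|M|MT)$")


@dataclass
class FrequencyReport:
    """Unique breaks per million aligned nucleotides."""

    n_unique_ssbs: int
    aligned_nucleotides: int

    @property
    def ssb_per_million_bp(self) -> float:
        return self.n_unique_ssbs / (self.aligned_nucleotides / 1e6)

    def __str__(self) -> str:
        return (
            f"unique SSBs: {self.n_unique_ssbs}\n"
            f"aligned nucleotides: {self.aligned_nucleotides}\n"
            f"SSBs per million bp: {self.ssb_per_million_bp:.1f}"
        )


def ssb_frequency(n_unique: int, aligned_nt: int) -> FrequencyReport:
    """Exact division; text output rounds to one decimal."""
    if aligned_nt <= 0:
        raise SteelseqError("aligned_nt must be positive")
    return FrequencyReport(n_unique_ssbs=n_unique, aligned_nucleotides=aligned_nt)


@dataclass
class RegionModel:
    """Per-position category and gene-strand labels over the genome.

    ``category`` maps chrom -> uint8 array of indices into CATEGORIES;
    ``gene_strand`` maps chrom -> int8 array (0 none, +1 forward, -1 reverse).
    """

    category: dict[str, np.ndarray]
    gene_strand: dict[str, np.ndarray]
    region_bp: pd.Series = field(default=None)

    def __post_init__(self) -> None:
        if self.region_bp is None:
            counts = np.zeros(len(CATEGORIES), dtype=np.int64)
            for arr in self.category.values():
                counts += np.bincount(arr, minlength=len(CATEGORIES))
            self.region_bp = pd.Series(counts, index=CATEGORIES, name="region_bp")

    def lookup(self, chrom: str, pos: int) -> tuple[str, Optional[str]]:
        arr = self.category.get(chrom)
        if arr is None or not 0 <= pos < arr.size:
            raise SteelseqError(f"position {chrom}:{pos} outside the region model")
        strand_code = int(self.gene_strand[chrom][pos])
        strand = {1: "+", -1: "-", 0: None}[strand_code]
        return CATEGORIES[arr[pos]], strand


def _paint(
    cat: np.ndarray, strand: np.ndarray, start: int, end: int, label: str, gstrand: str
) -> None:
    start = max(0, start)
    end = min(cat.size, end)
    if start >= end:
        return
    cat[start:end] = CATEGORIES.index(label)
    strand[start:end] = 1 if gstrand == "+" else -1


def build_region_model(
    annotation: Union[str, os.PathLike],
    ref_lengths: dict[str, int],
    promoter_bp: int = 3000,
    downstream_bp: int = 3000,
) -> RegionModel:
    """Partition the genome into gene-relative categories from a GTF/GFF3.

    One representative transcript per gene (the longest genomic span); the
    priority order promoter > 5'UTR > 3'UTR > exon > 1st intron > other
    intron > downstream <=3kb > distal intergenic resolves overlaps, with the
    promoter split into 1-kb bins up to 3 kb upstream of the TSS.
    """
    import gffutils

    db = gffutils.create_db(
        os.fspath(annotation),
        ":memory:",
        merge_strategy="create_unique",
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    category = {
        c: np.zeros(L, dtype=np.uint8) for c, L in ref_lengths.items()
    }  # 0 == distal_intergenic
    gene_strand = {c: np.zeros(L, dtype=np.int8) for c, L in ref_lengths.items()}

    genes = list(db.features_of_type("gene"))
    if not genes:
        raise SteelseqError(f"annotation {annotation} contains no gene records")

    reps = []
    for gene in genes:
        if gene.seqid not in ref_lengths:
            raise SteelseqError(
                f"annotation chromosome {gene.seqid!r} absent from reference"
            )
        txs = list(db.children(gene, featuretype=("transcript", "mRNA")))
        if not txs:
            continue
        rep = max(txs, key=lambda t: (t.end - t.start, t.id))
        reps.append((gene, rep))

    # paint in increasing priority: low-priority regions first so later
    # (higher-priority) labels overwrite them
    def layers():
        for gene, tx in reps:
            strand = tx.strand if tx.strand in "+-" else "+"
            s, e = tx.start - 1, tx.end  # to 0-based half-open
            exons = sorted(
                ((x.start - 1, x.end) for x in db.children(tx, featuretype="exon")),
                key=lambda iv: iv[0],
            )
            if not exons:
                exons = [(s, e)]
            introns = [
                (exons[i][1], exons[i + 1][0])
                for i in range(len(exons) - 1)
                if exons[i + 1][0] > exons[i][1]
            ]
            if strand == "-":
                first_intron = introns[-1] if introns else None
            else:
                first_intron = introns[0] if introns else None
            utr5 = [
                (x.start - 1, x.end)
                for x in db.children(tx, featuretype=("five_prime_utr", "five_prime_UTR"))
            ]
            utr3 = [
                (x.start - 1, x.end)
                for x in db.children(tx, featuretype=("three_prime_utr", "three_prime_UTR"))
            ]
            if strand == "+":
                down = (e, e + downstream_bp)
                prom_bins = [
                    (s - 1000, s, "promoter_0to1kb"),
                    (s - 2000, s - 1000, "promoter_1to2kb"),
                    (s - 3000, s - 2000, "promoter_2to3kb"),
                ]
            else:
                down = (s - downstream_bp, s)
                prom_bins = [
                    (e, e + 1000, "promoter_0to1kb"),
                    (e + 1000, e + 2000, "promoter_1to2kb"),
                    (e + 2000, e + 3000, "promoter_2to3kb"),
                ]
            prom_bins = [b for b in prom_bins if b[1] - b[0] <= promoter_bp]

            yield gene.seqid, strand, down, "downstream_3kb"
            for iv in introns:
                if first_intron is None or iv != first_intron:
                    yield gene.seqid, strand, iv, "other_intron"
            if first_intron is not None:
                yield gene.seqid, strand, first_intron, "first_intron"
            for iv in exons:
                yield gene.seqid, strand, iv, "exon"
            for iv in utr3:
                yield gene.seqid, strand, iv, "three_prime_utr"
            for iv in utr5:
                yield gene.seqid, strand, iv, "five_prime_utr"
            for b0, b1, lab in prom_bins:
                yield gene.seqid, strand, (b0, b1), lab

    # group by priority so that between genes the priority order also holds
    by_label: dict[str, list] = {c: [] for c in CATEGORIES}
    for chrom, strand, (a, b), label in layers():
        by_label[label].append((chrom, strand, a, b))
    for label in CATEGORIES[1:]:  # skip distal_intergenic (background)
        for chrom, strand, a, b in by_label[label]:
            _paint(category[chrom], gene_strand[chrom], a, b, label, strand)
    return RegionModel(category=category, gene_strand=gene_strand)


def annotate_calls(
    calls: Iterable[SSBCall],
    model: RegionModel,
    coverage_weight: Optional[float] = None,
) -> pd.DataFrame:
    """Assign each unique call to the category of its interval midpoint and
    tabulate strand-relative break frequencies per category.

    Relative strand is *forward* when the call strand equals the gene strand
    at the assigned position; intergenic calls keep their absolute strand.
    ``coverage_weight`` (total aligned nt / genome size) optionally scales the
    per-category bp denominators into sequenced-bp units.
    """
    seen: set[tuple] = set()
    counts: dict[tuple[str, str], int] = {}
    for c in calls:
        k = c.key()
        if k in seen:
            continue
        seen.add(k)
        mid = (c.start + c.end) // 2
        cat, gstrand = model.lookup(c.chrom, mid)
        if gstrand is None:
            rel = "forward" if c.strand == "+" else "reverse"
        else:
            rel = "forward" if c.strand == gstrand else "reverse"
        counts[(cat, rel)] = counts.get((cat, rel), 0) + 1

    rows = []
    for cat in CATEGORIES:
        bp = int(model.region_bp[cat])
        denom = bp * coverage_weight if coverage_weight else bp
        for rel in ("forward", "reverse"):
            n = counts.get((cat, rel), 0)
            rows.append(
                {
                    "category": cat,
                    "relative_strand": rel,
                    "n_ssbs": n,
                    "region_bp": bp,
                    "ssb_per_million_bp": (n / denom * 1e6) if denom else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def filter_by_reference_set(
    calls: Iterable[SSBCall], reference_calls: Iterable[SSBCall]
) -> list[SSBCall]:
    """Drop calls whose (chrom, start, end, strand) occurs in the reference
    (untreated control) call set."""
    ref_keys = {c.key() for c in reference_calls}
    return [c for c in calls if c.key() not in ref_keys]


def filter_canonical(
    calls: Iterable[SSBCall], pattern: Union[str, re.Pattern] = _CANONICAL_RE
) -> list[SSBCall]:
    """Keep calls on canonical chromosomes (chr1-22, chrX/Y/M by default)."""
    rx = re.compile(pattern) if isinstance(pattern, str) else pattern
    return [c for c in calls if rx.match(c.chrom)]


def _aligned_columns(record: AlignedReadRecord):
    """Yield (ref_pos, kind, payload) for one record: kind in
    {'base','del','ins'}; payload is the read base, None, or inserted string."""
    rpos, qpos = record.start, 0
    for op, n in record.cigar:
        if op in "M=X":
            for i in range(n):
                yield rpos + i, "base", record.seq[qpos + i]
            rpos += n
            qpos += n
        elif op == "I":
            yield rpos, "ins", record.seq[qpos : qpos + n]
            qpos += n
        elif op == "D":
            for i in range(n):
                yield rpos + i, "del", None
            rpos += n
        elif op == "N":
            rpos += n
        elif op == "S":
            qpos += n


def per_position_profile(
    alignments,
    ref: ReferenceGenome,
    window: tuple[str, int, int],
) -> pd.DataFrame:
    """Per-reference-position nucleotide composition over a window.

    Columns %A/%C/%G/%T/%del sum to 100 per covered position (insertions are
    attributed to the following reference position and reported as an extra
    percentage of reads with an insertion there). Zero-coverage rows are NaN.
    """
    chrom, wstart, wend = window
    ref.require(chrom)
    W = wend - wstart
    if W <= 0:
        raise SteelseqError("empty window")
    base_idx = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 5}
    counts = np.zeros((W, 6), dtype=np.int64)  # A C G T del N
    ins_counts = np.zeros(W, dtype=np.int64)
    for rec in _iter_records(alignments):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.chrom != chrom or rec.end <= wstart or rec.start >= wend:
            continue
        for pos, kind, payload in _aligned_columns(rec):
            if not wstart <= pos < wend:
                continue
            i = pos - wstart
            if kind == "base":
                counts[i, base_idx.get(payload, 5)] += 1
            elif kind == "del":
                counts[i, 4] += 1
            else:
                ins_counts[i] += 1

    depth = counts.sum(axis=1)
    refseq = ref.sequences[chrom][wstart:wend]
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(depth[:, None] > 0, counts / depth[:, None] * 100.0, np.nan)
        pct_ins = np.where(depth > 0, ins_counts / depth * 100.0, np.nan)
    df = pd.DataFrame(
        {
            "pos": np.arange(wstart, wend),
            "ref_base": list(refseq),
            "depth": depth,
            "pct_A": pct[:, 0],
            "pct_C": pct[:, 1],
            "pct_G": pct[:, 2],
            "pct_T": pct[:, 3],
            "pct_del": pct[:, 4],
            "pct_N": pct[:, 5],
            "pct_ins": pct_ins,
        }
    )
    return df


def unique_percent(n_unique: int, n_mapped: int) -> int:
    """Unique-sequence share as an integer percentage."""
    if n_mapped <= 0:
        raise SteelseqError("n_mapped must be positive")
    return int(round(n_unique / n_mapped * 100))


def unique_fraction(
    alignments, window: Optional[tuple[str, int, int]] = None
) -> tuple[int, int, int]:
    """Collapse mapped reads on exact sequence; returns (n_mapped, n_unique,
    percent rounded to integer).

    With a window, reads must span it fully and are collapsed on the aligned
    subsequence (insertions included) over the window; otherwise the full
    read sequence is the key.
    """
    n_mapped = 0
    seen: set[str] = set()
    for rec in _iter_records(alignments):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if window is None:
            n_mapped += 1
            seen.add(rec.seq)
            continue
        chrom, wstart, wend = window
        if rec.chrom != chrom or rec.start > wstart or rec.end < wend:
            continue
        n_mapped += 1
        parts: list[str] = []
        for pos, kind, payload in _aligned_columns(rec):
            if kind == "ins":
                if wstart < pos <= wend:
                    parts.append(payload)
            elif wstart <= pos < wend:
                parts.append(payload if kind == "base" else "-")
        seen.add("".join(parts))
    n_unique = len(seen)
    percent = int(round(n_unique / n_mapped * 100)) if n_mapped else 0
    return n_mapped, n_unique, percent
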