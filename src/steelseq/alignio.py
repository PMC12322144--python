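"""Alignment and reference I/O, and per-position mutation extraction.

Converts each primary alignment into a list of per-reference-position
differences (substitutions, deletions, insertion anchors) against the
reference genome, plus read-level error accounting used by the usability
filter ("primary alignments with at most 10% errors").

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Union

import numpy as np
import pysam
from pyfaidx import Fasta

__all__ = [
    "ReferenceGenome",
    "AlignedReadRecord",
    "MutationObservation",
    "ReadErrorStats",
    "load_reference",
    "iter_usable_alignments",
    "extract_mutations",
    "count_aligned_nucleotides",
    "SteelseqError",
]

#: Default ceiling on the per-read error rate for a usable alignment.
DEFAULT_MAX_ERROR_RATE = 0.10

#: Sentinel used when base qualities are absent ("*" in SAM).
QUAL_UNAVAILABLE = 255

_REF_CONSUMING = frozenset("M=XDN")
_READ_CONSUMING = frozenset("M=XIS")


class SteelseqError(Exception):
    """Base error for user-facing failures (bad input, missing chromosome...)."""


@dataclass
class ReferenceGenome:
    """In-memory reference: chromosome name -> uppercase sequence string."""

    sequences: dict[str, str]
    lengths: dict[str, int] = field(default_factory=dict)
    _arrays: dict[str, np.ndarray] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.lengths:
            self.lengths = {name: len(s) for name, s in self.sequences.items()}

    def array(self, chrom: str) -> np.ndarray:
        """Chromosome sequence as a uint8 array of ASCII codes (cached)."""
        arr = self._arrays.get(chrom)
        if arr is None:
            try:
                seq = self.sequences[chrom]
            except KeyError:
                raise SteelseqError(f"chromosome {chrom!r} not present in reference") from None
            arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
            self._arrays[chrom] = arr
        return arr

    def require(self, chrom: str) -> str:
        if chrom not in self.sequences:
            raise SteelseqError(f"chromosome {chrom!r} not present in reference")
        return self.sequences[chrom]


@dataclass
class AlignedReadRecord:
    """One alignment in forward reference orientation.

    ``seq`` and ``quals`` are as stored in SAM, i.e. already presented on the
    forward reference strand regardless of which physical strand was sequenced.
    """

    read_name: str
    chrom: str
    start: int
    cigar: list[tuple[str, int]]
    seq: str
    quals: Optional[list[int]]
    mapq: int = 60
    is_secondary: bool = False
    is_supplementary: bool = False
    is_unmapped: bool = False
    alignment_strand: str = "+"

    @property
    def is_primary(self) -> bool:
        return not (self.is_secondary or self.is_supplementary or self.is_unmapped)

    @property
    def end(self) -> int:
        """Reference end (half-open)."""
        return self.start + sum(n for op, n in self.cigar if op in _REF_CONSUMING)

    @classmethod
    def from_pysam(cls, aln: pysam.AlignedSegment) -> "AlignedReadRecord":
        cigar = []
        if aln.cigartuples:
            ops = "MIDNSHP=XB"
            cigar = [(ops[op], n) for op, n in aln.cigartuples]
        quals = list(aln.query_qualities) if aln.query_qualities is not None else None
        return cls(
            read_name=aln.query_name or "",
            chrom=aln.reference_name or "",
            start=aln.reference_start if aln.reference_start is not None else -1,
            cigar=cigar,
            seq=aln.query_sequence or "",
            quals=quals,
            mapq=aln.mapping_quality,
            is_secondary=aln.is_secondary,
            is_supplementary=aln.is_supplementary,
            is_unmapped=aln.is_unmapped,
            alignment_strand="-" if aln.is_reverse else "+",
        )

    def validate(self) -> None:
        consumed = sum(n for op, n in self.cigar if op in _READ_CONSUMING)
        if consumed != len(self.seq):
            raise SteelseqError(
                f"read {self.read_name}: CIGAR consumes {consumed} read bases "
                f"but sequence has {len(self.seq)}"
            )
        if self.quals is not None and len(self.quals) != len(self.seq):
            raise SteelseqError(f"read {self.read_name}: quality/sequence length mismatch")


@dataclass
class MutationObservation:
    """A difference from the reference at one reference position.

    Insertions are anchored at the reference position *following* the inserted
    bases; ``obs_base`` then holds the full inserted string.
    """

    ref_pos: int
    ref_base: str
    kind: str  # "substitution" | "deletion" | "insertion"
    obs_base: Optional[str]
    qual: Optional[int]


@dataclass
class ReadErrorStats:
    """Edit accounting over the reference span of one alignment."""

    ref_span: int
    n_sub: int
    n_ins_bases: int
    n_del_bases: int

    @property
    def error_rate(self) -> float:
        if self.ref_span == 0:
            return 0.0
        return (self.n_sub + self.n_ins_bases + self.n_del_bases) / self.ref_span


def load_reference(path: Union[str, os.PathLike]) -> ReferenceGenome:
    """Load a (possibly wrapped, multi-record) FASTA, uppercased.

    Raises :class:`SteelseqError` on missing/empty files or duplicate names.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise SteelseqError(f"reference FASTA not found: {path}")
    from pyfaidx import FastaIndexingError

    try:
        fa = Fasta(path, as_raw=True, sequence_always_upper=True, duplicate_action="stop",
                   rebuild=True, build_index=True)
    except (ValueError, FastaIndexingError) as exc:
        # pyfaidx: ValueError on duplicate names, FastaIndexingError on
        # unparseable/empty input
        raise SteelseqError(f"bad FASTA {path}: {exc}") from exc
    sequences = {name: str(fa[name][:]) for name in fa.keys()}
    fa.close()
    if not sequences:
        raise SteelseqError(f"FASTA {path} contains no sequences")
    return ReferenceGenome(sequences)


def _iter_records(alignments) -> Iterator[AlignedReadRecord]:
    """Accept a SAM/BAM path, an open AlignmentFile, or records directly."""
    if isinstance(alignments, (str, os.PathLike)):
        with pysam.AlignmentFile(os.fspath(alignments), check_sq=False) as af:
            for aln in af:
                yield AlignedReadRecord.from_pysam(aln)
    elif isinstance(alignments, pysam.AlignmentFile):
        for aln in alignments:
            yield AlignedReadRecord.from_pysam(aln)
    else:
        for rec in alignments:
            if isinstance(rec, pysam.AlignedSegment):
                rec = AlignedReadRecord.from_pysam(rec)
            yield rec


def extract_mutations(
    record: AlignedReadRecord, ref: ReferenceGenome
) -> tuple[list[MutationObservation], ReadErrorStats]:
    """Walk the CIGAR against the reference and report every difference.

    Returns observations sorted by reference position plus read-level error
    stats. The error-rate denominator is the reference span consumed by
    M/=/X/D (N skips excluded); the numerator counts each substituted base,
    each deleted base and each inserted base -- i.e. the NM-style edit
    distance. Reference ``N`` positions never count as substitutions.
    """
    record.validate()
    chrom_arr = ref.array(record.chrom)
    seq_arr = np.frombuffer(record.seq.encode("ascii"), dtype=np.uint8)
    quals = record.quals

    obs: list[MutationObservation] = []
    rpos = record.start
    qpos = 0
    ref_span = n_sub = n_ins = n_del = 0
    n_code = ord("N")

    for op, n in record.cigar:
        if op in "M=X":
            rb = chrom_arr[rpos : rpos + n]
            if rb.size != n:
                raise SteelseqError(
                    f"read {record.read_name} overruns chromosome {record.chrom}"
                )
            qb = seq_arr[qpos : qpos + n]
            mism = np.nonzero((rb != qb) & (rb != n_code))[0]
            for i in mism.tolist():
                obs.append(
                    MutationObservation(
                        ref_pos=rpos + i,
                        ref_base=chr(rb[i]),
                        kind="substitution",
                        obs_base=chr(qb[i]),
                        qual=quals[qpos + i] if quals is not None else None,
                    )
                )
            n_sub += mism.size
            ref_span += n
            rpos += n
            qpos += n
        elif op == "I":
            inserted = record.seq[qpos : qpos + n]
            q = None
            if quals is not None:
                q = int(round(float(np.mean(quals[qpos : qpos + n]))))
            ref_base = chr(chrom_arr[rpos]) if rpos < chrom_arr.size else "N"
            obs.append(
                MutationObservation(
                    ref_pos=rpos, ref_base=ref_base, kind="insertion",
                    obs_base=inserted, qual=q,
                )
            )
            n_ins += n
            qpos += n
        elif op == "D":
            for i in range(n):
                obs.append(
                    MutationObservation(
                        ref_pos=rpos + i,
                        ref_base=chr(chrom_arr[rpos + i]),
                        kind="deletion",
                        obs_base=None,
                        qual=None,
                    )
                )
            n_del += n
            ref_span += n
            rpos += n
        elif op == "N":
            rpos += n
        elif op == "S":
            qpos += n
        elif op in "HP":
            pass
        else:
            raise SteelseqError(f"unsupported CIGAR op {op!r} in read {record.read_name}")

    obs.sort(key=lambda o: (o.ref_pos, o.kind))
    return obs, ReadErrorStats(ref_span=ref_span, n_sub=n_sub,
                               n_ins_bases=n_ins, n_del_bases=n_del)


def _iter_usable_with_mutations(
    alignments, ref: ReferenceGenome, max_error_rate: float = DEFAULT_MAX_ERROR_RATE
) -> Iterator[tuple[AlignedReadRecord, list[MutationObservation], ReadErrorStats]]:
    """Shared iterator: usability filter plus the mutation calls it required."""
    for rec in _iter_records(alignments):
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.chrom not in ref.sequences:
            raise SteelseqError(
                f"alignment {rec.read_name} references chromosome {rec.chrom!r} "
                f"absent from the reference"
            )
        obs, stats = extract_mutations(rec, ref)
        if stats.error_rate <= max_error_rate:  # inclusive: "at most 10% errors"
            yield rec, obs, stats


def iter_usable_alignments(
    alignments, ref: ReferenceGenome, max_error_rate: float = DEFAULT_MAX_ERROR_RATE
) -> Iterator[AlignedReadRecord]:
    """Yield primary, mapped, non-supplementary alignments with error rate
    at most ``max_error_rate`` (inclusive bound)."""
    for rec, _obs, _stats in _iter_usable_with_mutations(alignments, ref, max_error_rate):
        yield rec


def count_aligned_nucleotides(
    alignments, ref: ReferenceGenome, max_error_rate: float = DEFAULT_MAX_ERROR_RATE
) -> int:
    """Total read bases in M/=/X operations over usable alignments."""
    total = 0
    for rec in iter_usable_alignments(alignments, ref, max_error_rate):
        total += sum(n for op, n in rec.cigar if op in "M=X")
    return total
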