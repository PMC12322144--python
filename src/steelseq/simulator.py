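"""Synthetic nicked-genome libraries with exact alignment truth.

Generates a random reference, places single-strand nicks (at nicking-enzyme
motif sites, at random, or from a BED), applies the error-prone polymerase
resynthesis signature downstream of each nick (every occurrence of the
omitted base in the new strand substituted -- mostly by its transition
partner -- or deleted), layers technology-specific sequencing errors on top,
and emits pre-aligned SAM records whose CIGAR/MD/NM replay exactly to the
read sequence. No aligner is involved: alignments are constructed from the
known edit script, so downstream stages can be tested against exact truth.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Union

import numpy as np

from .alignio import AlignedReadRecord, ReferenceGenome, SteelseqError

__all__ = [
    "NickPlan",
    "SloppySpectrum",
    "SeqErrorModel",
    "TruthRecord",
    "SimulatedLibrary",
    "ERROR_MODELS",
    "make_reference",
    "write_fasta",
    "place_nicks",
    "sloppy_modify",
    "sample_reads",
    "simulate_library",
]

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _revcomp(s: str) -> str:
    return s.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


@dataclass(frozen=True)
class NickPlan:
    """A planned single-strand cut.

    ``nick_pos`` is the forward-coordinate index of the first base 3' of the
    cut on the nicked strand, i.e. the first base degraded and resynthesized.
    """

    chrom: str
    nick_pos: int
    strand: str
    origin: str = "explicit"


@dataclass
class SloppySpectrum:
    """Outcome distribution at omitted-base positions inside the tract.

    Probabilities are expressed on the synthesized strand: ``p_sub`` maps each
    replacement base to its probability and together with ``p_del`` must sum
    to 1 -- the correct base has probability 0 because its dNTP is absent.
    """

    omitted_base: str = "A"
    p_sub: dict[str, float] = field(
        default_factory=lambda: {"G": 0.55, "T": 0.10, "C": 0.10}
    )
    p_del: float = 0.25
    p_ins: float = 0.01
    tract_len_mean: float = 50.0
    tract_len_model: str = "geometric"  # or "fixed"

    def __post_init__(self) -> None:
        self.omitted_base = self.omitted_base.upper()
        if self.omitted_base in self.p_sub:
            raise SteelseqError("spectrum must not replace the omitted base with itself")
        total = sum(self.p_sub.values()) + self.p_del
        if abs(total - 1.0) > 1e-9:
            raise SteelseqError(f"substitution+deletion probabilities sum to {total}, not 1")

    def sample_tract_length(self, rng: np.random.Generator) -> int:
        if self.tract_len_model == "fixed":
            return int(round(self.tract_len_mean))
        return int(rng.geometric(1.0 / self.tract_len_mean))


@dataclass(frozen=True)
class SeqErrorModel:
    """Per-base sequencing-error layer with constant base quality."""

    name: str
    p_sub: float
    p_ins: float
    p_del: float
    qual: int
    read_length: int

    @property
    def total(self) -> float:
        return self.p_sub + self.p_ins + self.p_del


#: Platform realism knobs: configurable, deliberately far below the 10%
#: read-usability bound so the error layer alone never discards reads.
ERROR_MODELS: dict[str, SeqErrorModel] = {
    "illumina": SeqErrorModel("illumina", 1e-3, 5e-5, 5e-5, qual=35, read_length=150),
    "pacbio-hifi": SeqErrorModel("pacbio-hifi", 2e-3, 5e-4, 5e-4, qual=30, read_length=3000),
    "nanopore": SeqErrorModel("nanopore", 2e-2, 1e-2, 1e-2, qual=15, read_length=5000),
    "perfect": SeqErrorModel("perfect", 0.0, 0.0, 0.0, qual=40, read_length=3000),
}


@dataclass
class TruthRecord:
    """Replayable truth for one nick: tract interval and forward-coordinate
    edit script applied to the nicked strand."""

    nick: NickPlan
    tract_start: int
    tract_end: int
    subs: dict[int, str]
    dels: set[int]
    ins: dict[int, str]


def make_reference(
    length: int,
    gc: float = 0.5,
    n_chroms: int = 1,
    seed: int = 0,
    motif: Optional[str] = None,
    n_motifs: int = 0,
    motif_rc_fraction: float = 0.5,
) -> tuple[ReferenceGenome, list[tuple[str, int, str]]]:
    """Seeded i.i.d. random genome with given GC, optionally embedding
    ``n_motifs`` copies of ``motif`` (a ``motif_rc_fraction`` share of them
    reverse-complemented) at recorded non-overlapping positions.

    Returns the genome and the list of (chrom, start, strand) embeddings.
    """
    if length < 1:
        raise SteelseqError("length must be >= 1")
    if not 0.0 < gc < 1.0:
        raise SteelseqError("gc must be in (0, 1)")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    sequences: dict[str, str] = {}
    embedded: list[tuple[str, int, str]] = []
    for ci in range(n_chroms):
        name = f"chr{ci + 1}"
        arr = rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length, p=p)
        if motif and n_motifs:
            m = len(motif)
            margin = 10 + m
            n_here = n_motifs // n_chroms + (1 if ci < n_motifs % n_chroms else 0)
            starts: list[int] = []
            taken = np.zeros(length, dtype=bool)
            while len(starts) < n_here:
                s = int(rng.integers(margin, length - margin))
                if not taken[s - m : s + 2 * m].any():
                    starts.append(s)
                    taken[s : s + m] = True
            for s in sorted(starts):
                strand = "-" if rng.random() < motif_rc_fraction else "+"
                ins = motif if strand == "+" else _revcomp(motif)
                arr[s : s + m] = np.frombuffer(ins.encode(), dtype=np.uint8)
                embedded.append((name, s, strand))
        sequences[name] = arr.tobytes().decode("ascii")
    return ReferenceGenome(sequences), embedded


def write_fasta(ref: ReferenceGenome, path: Union[str, os.PathLike], width: int = 70) -> None:
    with open(os.fspath(path), "w") as fh:
        for name, seq in ref.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def place_nicks(
    ref: ReferenceGenome,
    motif: Optional[str] = None,
    nick_offset: int = 6,
    random_rate: Optional[float] = None,
    bed: Optional[Union[str, os.PathLike]] = None,
    seed: int = 0,
) -> list[NickPlan]:
    """Plan nicks: at motif sites on both strands (deterministic), at a
    Poisson per-bp rate (seeded, strand uniform), or from a BED file."""
    plans: list[NickPlan] = []
    if motif is not None:
        from .sites import find_motif_sites

        track = find_motif_sites(ref, motif, nick_offset=nick_offset)
        for chrom, start, _end, strand, _label in track.sites:
            plans.append(NickPlan(chrom, start, strand, origin="motif"))
    elif random_rate is not None:
        rng = np.random.default_rng(seed)
        for chrom, L in ref.lengths.items():
            n = rng.poisson(random_rate * L)
            pos = np.sort(rng.integers(0, L, size=n))
            strands = rng.choice(np.array(["+", "-"]), size=n)
            for p, s in zip(pos.tolist(), strands.tolist()):
                plans.append(NickPlan(chrom, int(p), s, origin="random"))
    elif bed is not None:
        with open(os.fspath(bed)) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                parts = line.split("\t")
                if len(parts) < 3:
                    raise SteelseqError(f"malformed BED line {ln}: {line!r}")
                chrom, start = parts[0], int(parts[1])
                strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "+"
                plans.append(NickPlan(chrom, start, strand, origin="explicit"))
    else:
        raise SteelseqError("one of motif/random_rate/bed must be given")
    for p in plans:
        if not 0 <= p.nick_pos < ref.lengths[p.chrom]:
            raise SteelseqError(f"nick position {p.nick_pos} outside {p.chrom}")
    return plans


def sloppy_modify(
    ref: ReferenceGenome,
    nick: NickPlan,
    spectrum: SloppySpectrum,
    rng: np.random.Generator,
) -> TruthRecord:
    """Apply the resynthesis signature downstream of one nick.

    Only the nicked strand changes. For a + strand nick the tract runs right
    from ``nick_pos``; for a - strand nick synthesis proceeds 5'->3' along
    the bottom strand, i.e. leftwards in forward coordinates, so the tract
    covers positions at and left of ``nick_pos``. Edits are recorded in
    forward coordinates: on the - strand a replacement base is stored as its
    complement, and the targeted forward base is the complement of the
    omitted base. The synthesized tract never contains the omitted base.
    """
    seq = ref.require(nick.chrom)
    L = ref.lengths[nick.chrom]
    tract_len = spectrum.sample_tract_length(rng)
    if nick.strand == "+":
        t0, t1 = nick.nick_pos, min(L, nick.nick_pos + tract_len)
        fwd_target = spectrum.omitted_base
    else:
        t0, t1 = max(0, nick.nick_pos - tract_len + 1), nick.nick_pos + 1
        fwd_target = _COMP[spectrum.omitted_base]

    repl = list(spectrum.p_sub.items())
    repl_bases = [b for b, _ in repl]
    repl_p = np.array([p for _, p in repl])
    p_any_sub = float(repl_p.sum())
    non_omitted = [b for b in _BASES if b != spectrum.omitted_base]

    subs: dict[int, str] = {}
    dels: set[int] = set()
    ins: dict[int, str] = {}
    for pos in range(t0, t1):
        if seq[pos] == fwd_target:
            if rng.random() < spectrum.p_del / (spectrum.p_del + p_any_sub):
                dels.add(pos)
            else:
                b = repl_bases[int(rng.choice(len(repl_bases), p=repl_p / p_any_sub))]
                subs[pos] = b if nick.strand == "+" else _COMP[b]
        if spectrum.p_ins and rng.random() < spectrum.p_ins:
            b = non_omitted[int(rng.integers(len(non_omitted)))]
            bf = b if nick.strand == "+" else _COMP[b]
            ins[pos] = ins.get(pos, "") + bf
    return TruthRecord(nick=nick, tract_start=t0, tract_end=t1,
                       subs=subs, dels=dels, ins=ins)


@dataclass
class _StrandScript:
    """Merged forward-coordinate edit script for one strand of one chromosome."""

    sub_pos: np.ndarray
    sub_base: list[str]
    del_pos: np.ndarray
    ins_pos: np.ndarray
    ins_str: list[str]

    @classmethod
    def from_truth(cls, truths: list[TruthRecord]) -> "_StrandScript":
        subs: dict[int, str] = {}
        dels: set[int] = set()
        ins: dict[int, str] = {}
        for t in truths:
            subs.update(t.subs)
            dels.update(t.dels)
            ins.update(t.ins)
        for p in dels:
            subs.pop(p, None)
        sp = np.array(sorted(subs), dtype=np.int64)
        ip = np.array(sorted(ins), dtype=np.int64)
        return cls(
            sub_pos=sp,
            sub_base=[subs[p] for p in sp.tolist()],
            del_pos=np.array(sorted(dels), dtype=np.int64),
            ins_pos=ip,
            ins_str=[ins[p] for p in ip.tolist()],
        )

    def slice(self, s: int, e: int) -> tuple[dict[int, str], set[int], dict[int, str]]:
        lo, hi = np.searchsorted(self.sub_pos, (s, e))
        subs = {int(self.sub_pos[i]): self.sub_base[i] for i in range(lo, hi)}
        lo, hi = np.searchsorted(self.del_pos, (s, e))
        dels = set(self.del_pos[lo:hi].tolist())
        lo, hi = np.searchsorted(self.ins_pos, (s + 1, e))
        ins = {int(self.ins_pos[i]): self.ins_str[i] for i in range(lo, hi)}
        return subs, dels, ins


@dataclass
class SimRead:
    """One simulated alignment plus its exact per-read edit script."""

    name: str
    chrom: str
    start: int
    strand: str  # physical strand sequenced; '-' => SAM flag 16
    seq: str
    cigar: list[tuple[str, int]]
    md: str
    nm: int
    qual: int
    truth_subs: dict[int, str]
    truth_dels: set[int]
    truth_ins: dict[int, str]

    def to_record(self) -> AlignedReadRecord:
        return AlignedReadRecord(
            read_name=self.name,
            chrom=self.chrom,
            start=self.start,
            cigar=self.cigar,
            seq=self.seq,
            quals=[self.qual] * len(self.seq),
            mapq=60,
            alignment_strand=self.strand,
        )


def _realize(
    refseq: str, s: int, e: int, subs: dict[int, str], dels: set[int], ins: dict[int, str]
) -> tuple[int, str, list[tuple[str, int]], str, int]:
    """Build (start, seq, cigar, MD, NM) for reference window [s, e) with the
    given edit script. Leading/trailing deletions are trimmed from the span."""
    while s < e and s in dels:
        s += 1
    while e > s and (e - 1) in dels:
        e -= 1
    seq_parts: list[str] = []
    cigar: list[tuple[str, int]] = []
    md_parts: list[str] = []
    md_match = 0
    nm = 0

    def push(op: str, n: int) -> None:
        if n == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    pos = s
    keys = sorted(set(subs) | dels | set(ins))
    keys = [p for p in keys if s <= p < e]
    i = 0
    while i < len(keys):
        p = keys[i]
        gap = p - pos
        if gap:
            seq_parts.append(refseq[pos:p])
            push("M", gap)
            md_match += gap
            pos = p
        if p in ins:
            seq_parts.append(ins[p])
            push("I", len(ins[p]))
            nm += len(ins[p])
        if p in dels:
            # merge the whole deletion run for MD
            run = [p]
            while i + 1 < len(keys) and keys[i + 1] == run[-1] + 1 and keys[i + 1] in dels:
                if keys[i + 1] in ins:  # insertion anchored inside a deletion run
                    break
                run.append(keys[i + 1])
                i += 1
            push("D", len(run))
            md_parts.append(str(md_match))
            md_parts.append("^" + refseq[run[0] : run[-1] + 1])
            md_match = 0
            nm += len(run)
            pos = run[-1] + 1
        elif p in subs:
            seq_parts.append(subs[p])
            push("M", 1)
            md_parts.append(str(md_match))
            md_parts.append(refseq[p])
            md_match = 0
            nm += 1
            pos = p + 1
        else:  # insertion-only key
            pass
        i += 1
    if pos < e:
        seq_parts.append(refseq[pos:e])
        push("M", e - pos)
        md_match += e - pos
    md_parts.append(str(md_match))
    return s, "".join(seq_parts), cigar, "".join(md_parts), nm


def sample_reads(
    ref: ReferenceGenome,
    truths: Union[list[TruthRecord], list[list[TruthRecord]]],
    err: SeqErrorModel,
    coverage: float,
    seed: int = 0,
    read_length: Optional[int] = None,
) -> list[SimRead]:
    """Sample single-end fragments uniformly from both duplex strands.

    ``truths`` is one edit script per molecule copy (a flat list means a
    single copy). Each chromosome copy is a duplex carrying every + nick edit
    on its top strand and every - nick edit on its bottom strand; a fragment
    drawn from a copy/strand shows that strand's edits (in forward
    coordinates, as an aligner would report them) plus its own
    sequencing-error layer.
    """
    rng = np.random.default_rng(seed)
    rlen = int(read_length or err.read_length)
    copies: list[list[TruthRecord]]
    if truths and isinstance(truths[0], TruthRecord):
        copies = [truths]  # type: ignore[list-item]
    else:
        copies = truths or [[]]  # type: ignore[assignment]
    scripts: dict[tuple[int, str, str], _StrandScript] = {}
    for mi, copy in enumerate(copies):
        for chrom in ref.sequences:
            for strand in "+-":
                sel = [t for t in copy
                       if t.nick.chrom == chrom and t.nick.strand == strand]
                scripts[(mi, chrom, strand)] = _StrandScript.from_truth(sel)

    reads: list[SimRead] = []
    chroms = list(ref.sequences)
    lengths = np.array([ref.lengths[c] for c in chroms], dtype=float)
    total = lengths.sum()
    n_reads = int(np.ceil(coverage * total / rlen))
    chrom_choice = rng.choice(len(chroms), size=n_reads, p=lengths / total)
    for idx in range(n_reads):
        chrom = chroms[int(chrom_choice[idx])]
        L = ref.lengths[chrom]
        flen = min(rlen, L)
        s = int(rng.integers(0, L - flen + 1))
        e = s + flen
        strand = "+" if rng.random() < 0.5 else "-"
        mi = int(rng.integers(len(copies)))
        subs, dels, ins = scripts[(mi, chrom, strand)].slice(s, e)
        truth = (dict(subs), set(dels), dict(ins))

        # sequencing-error layer on top of the molecule edits
        refseq = ref.sequences[chrom]
        if err.p_sub > 0:
            k = rng.binomial(flen, err.p_sub)
            for p in (int(x) + s for x in rng.choice(flen, size=k, replace=False)):
                if p in dels:
                    continue
                cur = subs.get(p, refseq[p])
                alts = [b for b in _BASES if b != cur]
                b = alts[int(rng.integers(3))]
                if b == refseq[p]:
                    subs.pop(p, None)
                else:
                    subs[p] = b
        if err.p_del > 0:
            k = rng.binomial(flen, err.p_del)
            for p in (int(x) + s for x in rng.choice(flen, size=k, replace=False)):
                dels.add(p)
                subs.pop(p, None)
        if err.p_ins > 0:
            k = rng.binomial(flen, err.p_ins)
            for p in (int(x) + s for x in rng.choice(flen, size=k, replace=False)):
                if s < p < e:
                    b = _BASES[int(rng.integers(4))]
                    ins[p] = ins.get(p, "") + b

        start, seq, cigar, md, nm = _realize(refseq, s, e, subs, dels, ins)
        if not seq:
            continue
        reads.append(
            SimRead(
                name=f"sim{idx}",
                chrom=chrom,
                start=start,
                strand=strand,
                seq=seq,
                cigar=cigar,
                md=md,
                nm=nm,
                qual=err.qual,
                truth_subs=truth[0],
                truth_dels=truth[1],
                truth_ins=truth[2],
            )
        )
    reads.sort(key=lambda r: (r.chrom, r.start, r.name))
    return reads


@dataclass
class SimulatedLibrary:
    """A simulated, pre-aligned read set with its ground truth."""

    ref: ReferenceGenome
    nicks: list[NickPlan]
    truths: list[list[TruthRecord]]  # one edit script per molecule copy
    reads: list[SimRead]
    params: dict

    def records(self):
        """Generator of alignment records (lazy: per-read quality lists are
        sizeable for long-read models, so records are not kept alive)."""
        for r in self.reads:
            yield r.to_record()

    def write_sam(self, path: Union[str, os.PathLike]) -> None:
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": ln} for c, ln in self.ref.lengths.items()],
            "PG": [{"ID": "steelseq-sim", "PN": "steelseq simulate"}],
        }
        tid = {c: i for i, c in enumerate(self.ref.lengths)}
        mode = "wb" if os.fspath(path).endswith(".bam") else "wh"
        opnum = {"M": 0, "I": 1, "D": 2, "N": 3, "S": 4, "H": 5, "P": 6, "=": 7, "X": 8}
        with pysam.AlignmentFile(os.fspath(path), mode, header=header) as out:
            for r in self.reads:
                a = pysam.AlignedSegment(out.header)
                a.query_name = r.name
                a.reference_id = tid[r.chrom]
                a.reference_start = r.start
                a.mapping_quality = 60
                a.flag = 16 if r.strand == "-" else 0
                a.cigartuples = [(opnum[op], n) for op, n in r.cigar]
                a.query_sequence = r.seq
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(r.qual + 33) * len(r.seq)
                )
                a.set_tag("NM", r.nm)
                a.set_tag("MD", r.md)
                out.write(a)

    def write_fastq(self, path: Union[str, os.PathLike]) -> None:
        with open(os.fspath(path), "w") as fh:
            for r in self.reads:
                seq = _revcomp(r.seq) if r.strand == "-" else r.seq
                fh.write(f"@{r.name}\n{seq}\n+\n{chr(r.qual + 33) * len(seq)}\n")

    def write_truth_bed(self, path: Union[str, os.PathLike]) -> None:
        with open(os.fspath(path), "w") as fh:
            for n in sorted(self.nicks, key=lambda n: (n.chrom, n.nick_pos)):
                fh.write(
                    f"{n.chrom}\t{n.nick_pos}\t{n.nick_pos + 1}\t{n.origin}\t0\t{n.strand}\n"
                )

    def write_manifest(self, path: Union[str, os.PathLike]) -> None:
        with open(os.fspath(path), "w") as fh:
            json.dump(self.params, fh, indent=2, sort_keys=True)
            fh.write("\n")


def simulate_library(
    ref: ReferenceGenome,
    nicks: list[NickPlan],
    tech: str = "pacbio-hifi",
    coverage: float = 30.0,
    spectrum: Optional[SloppySpectrum] = None,
    seed: int = 0,
    read_length: Optional[int] = None,
    n_copies: int = 20,
) -> SimulatedLibrary:
    """Nick, modify and sequence: the full generator behind one library.

    ``n_copies`` independent molecule copies of the genome are nicked and
    modified (each tract length and mutation spectrum redrawn per copy), and
    every read is sampled from one copy -- sequencing libraries draw each
    locus from many distinct template molecules, so a single unlucky short
    tract must not silence a nick in every read.
    """
    spectrum = spectrum or SloppySpectrum()
    try:
        err = ERROR_MODELS[tech]
    except KeyError:
        raise SteelseqError(f"unknown technology {tech!r}; choose from {sorted(ERROR_MODELS)}")
    rng = np.random.default_rng(seed)
    truths = [
        [sloppy_modify(ref, n, spectrum, rng) for n in nicks] for _ in range(n_copies)
    ]
    reads = sample_reads(
        ref, truths, err, coverage, seed=int(rng.integers(2**31)), read_length=read_length
    )
    params = {
        "tech": tech,
        "coverage": coverage,
        "seed": seed,
        "n_nicks": len(nicks),
        "omitted_base": spectrum.omitted_base,
        "tract_len_mean": spectrum.tract_len_mean,
        "error_model": {"p_sub": err.p_sub, "p_ins": err.p_ins, "p_del": err.p_del},
        "read_length": int(read_length or err.read_length),
        "n_copies": n_copies,
    }
    return SimulatedLibrary(ref=ref, nicks=nicks, truths=truths, reads=reads, params=params)
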