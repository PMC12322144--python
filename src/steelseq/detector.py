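"""Signature-event detection, filtering, break-interval calling and output.

The error-prone polymerase resynthesizes the strand downstream of a nick with
one dNTP omitted, so every occurrence of the omitted base in the new strand is
substituted or deleted. In forward reference coordinates that appears as a
maximal run of mutated A positions (break on the + strand) or mutated T
positions (break on the - strand) when dATP was omitted; C/G runs when dCTP
was omitted. The break must lie between the nearest intact target base on the
anchor side (5' flank for A/C runs, 3' flank for T/G runs) and the first
mutated target base of the run.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Optional, Union

import numpy as np
import pysam

from .alignio import (
    DEFAULT_MAX_ERROR_RATE,
    AlignedReadRecord,
    MutationObservation,
    ReferenceGenome,
    SteelseqError,
    _iter_usable_with_mutations,
)

__all__ = [
    "TechnologyProfile",
    "SloppyEvent",
    "SSBCall",
    "PROFILES",
    "get_profile",
    "scan_events",
    "apply_filters",
    "call_ssb",
    "dedupe_calls",
    "detect",
    "mode_targets",
]

#: Anchor side per target base: the omitted base itself is read 5'-anchored,
#: its complement (reverse-strand signature) 3'-anchored.
_ANCHOR_SIDE = {"A": "5", "C": "5", "T": "3", "G": "3"}

#: target bases (plus-strand signature, minus-strand signature) per mode.
_MODE_TARGETS = {"-dATP": ("A", "T"), "-dCTP": ("C", "G")}


def mode_targets(mode: str) -> tuple[str, str]:
    """Map an omitted-dNTP mode to its (+ strand, - strand) target bases."""
    key = mode if mode.startswith("-") else "-" + mode
    key = key.replace("datp", "dATP").replace("dctp", "dCTP")
    try:
        return _MODE_TARGETS[key]
    except KeyError:
        raise SteelseqError(f"unknown mode {mode!r}; expected -dATP or -dCTP") from None


@dataclass(frozen=True)
class TechnologyProfile:
    """Per-platform event filter thresholds (and dedup policy)."""

    name: str
    min_mutated_targets: int
    min_substitutions_in_event: int = 1
    max_read_error_rate: float = DEFAULT_MAX_ERROR_RATE
    min_mean_subst_quality: float = 10.0
    require_quality: bool = True
    dedup: bool = False

    def __post_init__(self) -> None:
        if self.min_mutated_targets < 1:
            raise SteelseqError("min_mutated_targets must be >= 1")
        if self.min_substitutions_in_event > self.min_mutated_targets:
            raise SteelseqError(
                "min_substitutions_in_event cannot exceed min_mutated_targets"
            )


#: Published per-platform thresholds. Short-read calls are positionally
#: deduplicated (PCR duplicates); single-molecule long reads are not.
PROFILES: dict[str, TechnologyProfile] = {
    "pacbio-hifi": TechnologyProfile("pacbio-hifi", min_mutated_targets=5),
    "nanopore": TechnologyProfile(
        "nanopore", min_mutated_targets=5, min_substitutions_in_event=3
    ),
    "illumina-tk6": TechnologyProfile("illumina-tk6", min_mutated_targets=3, dedup=True),
    "illumina-hacat": TechnologyProfile("illumina-hacat", min_mutated_targets=4, dedup=True),
}


def get_profile(name: str, **overrides) -> TechnologyProfile:
    if name == "custom":
        base = {"name": "custom", "min_mutated_targets": 5}
        base.update(overrides)
        return TechnologyProfile(**base)
    try:
        prof = PROFILES[name]
    except KeyError:
        raise SteelseqError(
            f"unknown profile {name!r}; choose from {sorted(PROFILES)} or 'custom'"
        ) from None
    if overrides:
        from dataclasses import replace

        prof = replace(prof, **overrides)
    return prof


@dataclass
class SloppyEvent:
    """A maximal anchored run of mutated target-base positions in one read."""

    read_name: str
    chrom: str
    target_base: str
    mutated_target_positions: list[int]
    n_sub: int
    n_del: int
    anchor_pos: int
    mean_sub_quality: Optional[float]
    read_error_rate: float
    mapq: int

    @property
    def first_mut_pos(self) -> int:
        return self.mutated_target_positions[0]

    @property
    def last_mut_pos(self) -> int:
        return self.mutated_target_positions[-1]

    @property
    def anchor_side(self) -> str:
        return _ANCHOR_SIDE[self.target_base]


@dataclass
class SSBCall:
    """Inferred break interval (0-based half-open candidate positions)."""

    chrom: str
    start: int
    end: int
    strand: str
    read_name: str
    mapq: int
    n_mut_targets: int
    n_sub: int
    n_del: int
    mean_sub_quality: Optional[float]
    source_event: Optional[SloppyEvent] = None

    def key(self) -> tuple:
        return (self.chrom, self.start, self.end, self.strand)

    def bed_fields(self, name: Optional[str] = None) -> list[str]:
        q = "." if self.mean_sub_quality is None else f"{self.mean_sub_quality:.1f}"
        return [
            self.chrom,
            str(self.start),
            str(self.end),
            name if name is not None else self.read_name,
            str(self.mapq),
            self.strand,
            str(self.n_mut_targets),
            str(self.n_sub),
            str(self.n_del),
            q,
        ]


def _observed_segments(record: AlignedReadRecord) -> list[tuple[int, int]]:
    """Contiguous reference intervals covered by M/=/X/D ops (N splits them)."""
    segs: list[tuple[int, int]] = []
    rpos = record.start
    cur_start = None
    for op, n in record.cigar:
        if op in "M=XD":
            if cur_start is None:
                cur_start = rpos
            rpos += n
        elif op == "N":
            if cur_start is not None:
                segs.append((cur_start, rpos))
                cur_start = None
            rpos += n
        # I/S/H/P: no reference consumption, do not break contiguity
    if cur_start is not None:
        segs.append((cur_start, rpos))
    return segs


def scan_events(
    observations: list[MutationObservation],
    record: AlignedReadRecord,
    ref: ReferenceGenome,
    target_base: str,
) -> list[SloppyEvent]:
    """Enumerate every maximal anchored run of mutated target positions.

    A reference target-base position within the aligned span is *mutated* if
    the read substitutes or deletes it, otherwise *intact*. A run is reported
    when it is a maximal block of consecutive mutated target positions whose
    neighbouring target position on the anchor side exists within the same
    contiguous aligned segment and is intact. Runs touching the alignment
    edge (or an N skip) on the anchor side are discarded.
    """
    target_base = target_base.upper()
    if target_base not in _ANCHOR_SIDE:
        raise SteelseqError(f"invalid target base {target_base!r}")
    chrom_arr = ref.array(record.chrom)
    tcode = ord(target_base)

    tpos_parts: list[np.ndarray] = []
    seg_ids: list[np.ndarray] = []
    for si, (s, e) in enumerate(_observed_segments(record)):
        idx = np.nonzero(chrom_arr[s:e] == tcode)[0]
        if idx.size:
            tpos_parts.append(idx + s)
            seg_ids.append(np.full(idx.size, si, dtype=np.int32))
    if not tpos_parts:
        return []
    tpos = np.concatenate(tpos_parts)
    tseg = np.concatenate(seg_ids)

    # mutation status + quality lookup at target positions
    mut_pos = []
    sub_pos = {}
    for o in observations:
        if o.ref_base == target_base and o.kind in ("substitution", "deletion"):
            mut_pos.append(o.ref_pos)
            if o.kind == "substitution":
                sub_pos[o.ref_pos] = o.qual
    mut_arr = np.array(sorted(set(mut_pos)), dtype=np.int64)
    if mut_arr.size == 0:
        return []
    mutated = np.isin(tpos, mut_arr, assume_unique=True)

    events: list[SloppyEvent] = []
    anchor_side = _ANCHOR_SIDE[target_base]
    n = tpos.size
    i = 0
    while i < n:
        if not mutated[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and mutated[j + 1] and tseg[j + 1] == tseg[j]:
            j += 1
        # run covers target indices [i, j]
        if anchor_side == "5":
            ai = i - 1
            anchored = ai >= 0 and not mutated[ai] and tseg[ai] == tseg[i]
        else:
            ai = j + 1
            anchored = ai < n and not mutated[ai] and tseg[ai] == tseg[j]
        if anchored:
            run = tpos[i : j + 1].tolist()
            quals = [sub_pos[p] for p in run if p in sub_pos]
            n_sub = len(quals)
            have_quals = [q for q in quals if q is not None]
            mean_q = float(np.mean(have_quals)) if have_quals else None
            events.append(
                SloppyEvent(
                    read_name=record.read_name,
                    chrom=record.chrom,
                    target_base=target_base,
                    mutated_target_positions=run,
                    n_sub=n_sub,
                    n_del=len(run) - n_sub,
                    anchor_pos=int(tpos[ai]),
                    mean_sub_quality=mean_q,
                    read_error_rate=0.0,
                    mapq=record.mapq,
                )
            )
        i = j + 1
    return events


def apply_filters(
    event: SloppyEvent, profile: TechnologyProfile
) -> tuple[bool, Optional[str]]:
    """Event-level filters; returns (pass, first failing filter name)."""
    if len(event.mutated_target_positions) < profile.min_mutated_targets:
        return False, "min_mutated_targets"
    if event.mean_sub_quality is None:
        if profile.require_quality and event.n_sub > 0:
            return False, "min_mean_subst_quality"
    elif event.mean_sub_quality < profile.min_mean_subst_quality:
        return False, "min_mean_subst_quality"
    if event.n_sub < profile.min_substitutions_in_event:
        return False, "min_substitutions"
    return True, None


def call_ssb(event: SloppyEvent) -> SSBCall:
    """Localize the break interval from an anchored event.

    5'-anchored runs (A/C targets): the break lies between the intact anchor
    base and the first mutated target, i.e. [anchor+1, first_mut+1), + strand.
    3'-anchored runs (T/G targets): [last_mut, anchor), - strand.
    """
    if event.anchor_side == "5":
        start, end, strand = event.anchor_pos + 1, event.first_mut_pos + 1, "+"
    else:
        start, end, strand = event.last_mut_pos, event.anchor_pos, "-"
    return SSBCall(
        chrom=event.chrom,
        start=start,
        end=end,
        strand=strand,
        read_name=event.read_name,
        mapq=event.mapq,
        n_mut_targets=len(event.mutated_target_positions),
        n_sub=event.n_sub,
        n_del=event.n_del,
        mean_sub_quality=event.mean_sub_quality,
        source_event=event,
    )


def dedupe_calls(calls: Iterable[SSBCall], enabled: bool = True) -> list[SSBCall]:
    """Keep one call per (chrom, start, end, strand); ties broken by highest
    mapq, then lexicographically smallest read name. Output coordinate-sorted."""
    calls = list(calls)
    if enabled:
        best: dict[tuple, SSBCall] = {}
        for c in calls:
            k = c.key()
            prev = best.get(k)
            if prev is None or (-c.mapq, c.read_name) < (-prev.mapq, prev.read_name):
                best[k] = c
        calls = list(best.values())
    calls.sort(key=lambda c: (c.chrom, c.start, c.end, c.strand, c.read_name))
    return calls


def detect(
    alignments: Union[str, os.PathLike, Iterable],
    ref: ReferenceGenome,
    profile: TechnologyProfile,
    mode: str = "-dATP",
    out_bed: Optional[Union[str, os.PathLike]] = None,
    out_bam: Optional[Union[str, os.PathLike]] = None,
    log: Optional[Union[str, os.PathLike]] = None,
    dedup: Optional[bool] = None,
) -> tuple[list[SSBCall], dict]:
    """Full pipeline: usable alignments -> mutation extraction -> event scan
    (both strand signatures) -> filters -> break calling -> optional dedup.

    Returns the final calls and a stage-count log dict; optionally writes a
    sorted BED6+4 track (duplicate lines removed), a subset SAM/BAM of reads
    carrying passing events, and a text log.
    """
    plus_t, minus_t = mode_targets(mode)
    do_dedup = profile.dedup if dedup is None else dedup
    stats = {
        "usable_reads": 0,
        "events_scanned": 0,
        "events_pass": 0,
        "fail_min_mutated_targets": 0,
        "fail_min_mean_subst_quality": 0,
        "fail_min_substitutions": 0,
        "calls_before_dedup": 0,
        "calls_final": 0,
    }
    calls: list[SSBCall] = []
    hit_reads: set[str] = set()
    for rec, obs, rstats in _iter_usable_with_mutations(
        alignments, ref, profile.max_read_error_rate
    ):
        stats["usable_reads"] += 1
        for tb in (plus_t, minus_t):
            for ev in scan_events(obs, rec, ref, tb):
                ev.read_error_rate = rstats.error_rate
                stats["events_scanned"] += 1
                ok, reason = apply_filters(ev, profile)
                if ok:
                    stats["events_pass"] += 1
                    calls.append(call_ssb(ev))
                    hit_reads.add(rec.read_name)
                else:
                    stats[f"fail_{reason}"] += 1
    stats["calls_before_dedup"] = len(calls)
    calls = dedupe_calls(calls, enabled=do_dedup)
    stats["calls_final"] = len(calls)

    if out_bed is not None:
        _write_bed(calls, out_bed)
    if out_bam is not None:
        _write_subset_bam(alignments, hit_reads, out_bam)
    if log is not None:
        with open(os.fspath(log), "w") as fh:
            for k, v in stats.items():
                fh.write(f"{k}\t{v}\n")
    return calls, stats


def _write_bed(calls: list[SSBCall], path) -> None:
    # calls arrive coordinate-sorted; byte-identical duplicate lines dropped
    seen: set[str] = set()
    with open(os.fspath(path), "w") as fh:
        for c in calls:
            line = "\t".join(c.bed_fields())
            if line in seen:
                continue
            seen.add(line)
            fh.write(line + "\n")


def _write_subset_bam(alignments, read_names: set[str], path) -> None:
    path = os.fspath(path)
    if not isinstance(alignments, (str, os.PathLike)):
        raise SteelseqError("subset BAM output requires a SAM/BAM input path")
    mode = "wb" if path.endswith(".bam") else "wh"
    with pysam.AlignmentFile(os.fspath(alignments), check_sq=False) as src:
        header = src.header.to_dict()
        header.setdefault("PG", []).append(
            {"ID": "steelseq", "PN": "steelseq", "CL": "steelseq detect"}
        )
        with pysam.AlignmentFile(path, mode, header=header) as dst:
            for aln in src:
                if (
                    aln.query_name in read_names
                    and not aln.is_secondary
                    and not aln.is_supplementary
                    and not aln.is_unmapped
                ):
                    dst.write(aln)
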