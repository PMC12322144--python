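"""Shared test utilities: independent brute-force oracles and toy generators.

The oracles here deliberately re-derive everything from first principles
(plain per-base CIGAR walks, all-subinterval enumeration, all-pairs distance
checks) so they share no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np

from steelseq.alignio import AlignedReadRecord, ReferenceGenome

BASES = "ACGT"
_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


# ---------------------------------------------------------------- CIGAR walk


def walk_alignment(record: AlignedReadRecord, ref: ReferenceGenome):
    """Simple per-base walk: returns (status, segments).

    status: ref_pos -> ("match", base) | ("sub", base, qual) | ("del",)
    segments: list of (start, end) contiguous M/D stretches (N splits them).
    """
    seq = ref.sequences[record.chrom]
    status = {}
    segments = []
    rpos, qpos = record.start, 0
    seg_start = None
    for op, n in record.cigar:
        if op in "M=X":
            if seg_start is None:
                seg_start = rpos
            for i in range(n):
                rb, qb = seq[rpos + i], record.seq[qpos + i]
                q = record.quals[qpos + i] if record.quals is not None else None
                if rb == qb or rb == "N":
                    status[rpos + i] = ("match", qb)
                else:
                    status[rpos + i] = ("sub", qb, q)
            rpos += n
            qpos += n
        elif op == "D":
            if seg_start is None:
                seg_start = rpos
            for i in range(n):
                status[rpos + i] = ("del",)
            rpos += n
        elif op == "N":
            if seg_start is not None:
                segments.append((seg_start, rpos))
                seg_start = None
            rpos += n
        elif op == "I":
            qpos += n
        elif op == "S":
            qpos += n
    if seg_start is not None:
        segments.append((seg_start, rpos))
    return status, segments


def oracle_scan(record: AlignedReadRecord, ref: ReferenceGenome, target: str):
    """All-subinterval brute force: every maximal anchored run of mutated
    target positions, reported as a set of (run tuple, anchor_pos)."""
    status, segments = walk_alignment(record, ref)
    seq = ref.sequences[record.chrom]
    results = set()
    anchor_left = target in ("A", "C")
    for si, (s, e) in enumerate(segments):
        tpos = [p for p in range(s, e) if seq[p] == target]
        mut = [status[p][0] in ("sub", "del") for p in tpos]
        n = len(tpos)
        for i in range(n):
            for j in range(i, n):
                if not all(mut[i : j + 1]):
                    continue
                # maximal
                if i > 0 and mut[i - 1]:
                    continue
                if j < n - 1 and mut[j + 1]:
                    continue
                if anchor_left:
                    if i == 0:
                        continue
                    anchor = tpos[i - 1]
                else:
                    if j == n - 1:
                        continue
                    anchor = tpos[j + 1]
                results.add((tuple(tpos[i : j + 1]), anchor))
    return results


# ------------------------------------------------------------ toy generator


def random_toy(rng: np.random.Generator, burst: bool = True):
    """A random short reference plus one read built from a random edit script.

    Returns (ReferenceGenome, AlignedReadRecord). With ``burst`` a window is
    chosen in which every A (or T) is mutated, emulating the polymerase tract
    so anchored runs actually occur.
    """
    L = int(rng.integers(60, 201))
    seq = "".join(BASES[i] for i in rng.integers(0, 4, size=L))
    a_start = int(rng.integers(0, 10))
    a_end = L - int(rng.integers(0, 10))

    forced = set()
    forced_target = None
    if burst and rng.random() < 0.7:
        forced_target = "A" if rng.random() < 0.5 else "T"
        b0 = int(rng.integers(a_start, max(a_start + 1, a_end - 20)))
        b1 = min(a_end, b0 + int(rng.integers(5, 40)))
        forced = {p for p in range(b0, b1) if seq[p] == forced_target}

    read = []
    quals = []
    cigar: list[tuple[str, int]] = []

    def push(op, n=1):
        if n == 0:
            return
        if cigar and cigar[-1][0] == op:
            cigar[-1] = (op, cigar[-1][1] + n)
        else:
            cigar.append((op, n))

    pos = a_start
    while pos < a_end:
        r = rng.random()
        in_forced = pos in forced
        if in_forced and rng.random() < 0.3:
            push("D", 1)
            pos += 1
            continue
        if in_forced or r < 0.08:
            alts = [b for b in BASES if b != seq[pos]]
            read.append(alts[int(rng.integers(3))])
            quals.append(int(rng.integers(2, 41)))
            push("M", 1)
            pos += 1
        elif r < 0.12 and pos not in (a_start, a_end - 1):
            push("D", 1)
            pos += 1
        elif r < 0.14:
            k = int(rng.integers(1, 4))
            for _ in range(k):
                read.append(BASES[int(rng.integers(4))])
                quals.append(int(rng.integers(2, 41)))
            push("I", k)
        else:
            read.append(seq[pos])
            quals.append(int(rng.integers(2, 41)))
            push("M", 1)
            pos += 1
    # optional soft clips
    pre = int(rng.integers(0, 4))
    post = int(rng.integers(0, 4))
    read = [BASES[int(rng.integers(4))] for _ in range(pre)] + read + [
        BASES[int(rng.integers(4))] for _ in range(post)
    ]
    quals = [30] * pre + quals + [30] * post
    if pre:
        cigar.insert(0, ("S", pre))
    if post:
        cigar.append(("S", post))
    # drop degenerate all-clip reads
    if not any(op in "M=X" for op, _ in cigar):
        return random_toy(rng, burst=burst)

    ref = ReferenceGenome({"toy": seq})
    rec = AlignedReadRecord(
        read_name="toy_read",
        chrom="toy",
        start=a_start,
        cigar=[(op, n) for op, n in cigar],
        seq="".join(read),
        quals=quals,
    )
    return ref, rec


# ------------------------------------------------------- interval brute force


def oracle_window_hit(call, site, w):
    """Direct bedtools-window rule on one pair of intervals."""
    c_chrom, cs, ce = call[0], call[1], call[2]
    s_chrom, ss, se = site[0], site[1], site[2]
    return c_chrom == s_chrom and (cs - w) < se and ss < (ce + w)


def oracle_coincidence(calls, sites, w):
    flags = [any(oracle_window_hit(c, s, w) for s in sites) for c in calls]
    uniq = {}
    for c, f in zip(calls, flags):
        key = (c[0], c[1], c[2])
        uniq[key] = uniq.get(key, False) or f
    frac = sum(uniq.values()) / len(uniq) if uniq else None
    return frac, flags


def mirror_record(record: AlignedReadRecord, L: int) -> AlignedReadRecord:
    """The same alignment against the reverse-complemented reference."""
    return AlignedReadRecord(
        read_name=record.read_name,
        chrom=record.chrom,
        start=L - record.end,
        cigar=list(reversed(record.cigar)),
        seq=revcomp(record.seq),
        quals=list(reversed(record.quals)) if record.quals is not None else None,
        mapq=record.mapq,
    )
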