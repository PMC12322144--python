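"""Nickase motif site scanning, random control tracks, and call/site overlap.

The nicking enzyme used as ground truth (Nt.BsmAI) recognizes GTCTC and cuts
the top strand one spacer base downstream (GTCTCN^N), so the nick point of a
forward match starting at ``m`` is ``m + 6``; a reverse-complement match is
mirrored. Coincidence between break calls and site tracks follows bedtools
``window -w`` semantics: a call counts as explained by a site if the call
interval extended by ``w`` on both sides overlaps the site interval.
"""

from __future__ import annotations

import os
import re
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .alignio import ReferenceGenome, SteelseqError
from .detector import SSBCall

__all__ = [
    "SiteTrack",
    "find_motif_sites",
    "random_site_track",
    "window_coincidence",
    "score_against_truth",
    "read_bed",
    "write_bed",
]

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}
_IUPAC_COMP = {
    "A": "T", "T": "A", "C": "G", "G": "C", "R": "Y", "Y": "R",
    "S": "S", "W": "W", "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N",
}

Interval = tuple  # (chrom, start, end, strand, label)


@dataclass
class SiteTrack:
    """A list of (chrom, start, end, strand, label) intervals."""

    sites: list[Interval]
    provenance: str = "motif"
    _index: dict = field(default_factory=dict, repr=False)

    def __len__(self) -> int:
        return len(self.sites)

    def __iter__(self):
        return iter(self.sites)

    def by_chrom(self) -> dict[str, tuple[list[int], list[int]]]:
        """chrom -> (sorted starts, co-sorted ends); cached."""
        if not self._index:
            tmp: dict[str, list[tuple[int, int]]] = {}
            for chrom, start, end, *_ in self.sites:
                tmp.setdefault(chrom, []).append((start, end))
            for chrom, ivs in tmp.items():
                ivs.sort()
                self._index[chrom] = (
                    [s for s, _ in ivs],
                    sorted(e for _, e in ivs),
                )
            # note: ends sorted independently; valid for the count test below
        return self._index


def _iupac_regex(motif: str) -> str:
    out = []
    for ch in motif.upper():
        if ch not in IUPAC:
            raise SteelseqError(f"invalid IUPAC character {ch!r} in motif {motif!r}")
        bases = IUPAC[ch]
        out.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(out)


def revcomp_motif(motif: str) -> str:
    try:
        return "".join(_IUPAC_COMP[c] for c in reversed(motif.upper()))
    except KeyError as exc:
        raise SteelseqError(f"invalid IUPAC character in motif {motif!r}") from exc


def find_motif_sites(
    ref: ReferenceGenome,
    motif: str = "GTCTC",
    nick_offset: int = 6,
    site_repr: str = "nick-point",
) -> SiteTrack:
    """Scan both strands for the recognition motif (overlapping matches
    included) and record each nick point as a 1-bp interval.

    Forward match at ``m``: nick_pos = m + nick_offset, + strand.
    Reverse-complement match at ``m``: nick_pos = m + len(motif) - nick_offset - 1,
    - strand (the mirrored coordinate). ``site_repr="motif-span"`` records the
    recognition-site interval instead of the nick point.
    """
    if not motif:
        raise SteelseqError("motif must be non-empty")
    fwd = re.compile(f"(?=({_iupac_regex(motif)}))")
    rc = revcomp_motif(motif)
    rev = re.compile(f"(?=({_iupac_regex(rc)}))")
    m_len = len(motif)
    sites: list[Interval] = []
    for chrom, seq in ref.sequences.items():
        L = len(seq)
        for m in fwd.finditer(seq):
            s = m.start()
            nick = s + nick_offset
            if site_repr == "motif-span":
                sites.append((chrom, s, s + m_len, "+", motif))
            elif 0 <= nick < L:
                sites.append((chrom, nick, nick + 1, "+", motif))
        palindromic = rc == motif.upper()
        if not palindromic:
            rev_iter = rev.finditer(seq)
        else:
            rev_iter = fwd.finditer(seq)  # same matches, mirrored nick point
        for m in rev_iter:
            s = m.start()
            nick = s + m_len - nick_offset - 1
            if site_repr == "motif-span":
                sites.append((chrom, s, s + m_len, "-", motif))
            elif 0 <= nick < L:
                sites.append((chrom, nick, nick + 1, "-", motif))
    sites.sort(key=lambda t: (t[0], t[1], t[3]))
    return SiteTrack(sites=sites, provenance="motif")


def random_site_track(ref: ReferenceGenome, n: int, seed: int = 0) -> SiteTrack:
    """n 1-bp sites uniform over the concatenated genome, seeded."""
    if n < 0:
        raise SteelseqError("n must be >= 0")
    rng = np.random.default_rng(seed)
    chroms = list(ref.lengths)
    lengths = np.array([ref.lengths[c] for c in chroms], dtype=float)
    total = lengths.sum()
    sites: list[Interval] = []
    if n and total:
        picks = rng.choice(len(chroms), size=n, p=lengths / total)
        for ci in picks.tolist():
            chrom = chroms[ci]
            p = int(rng.integers(0, ref.lengths[chrom]))
            strand = "+" if rng.random() < 0.5 else "-"
            sites.append((chrom, p, p + 1, strand, "random"))
    sites.sort(key=lambda t: (t[0], t[1]))
    return SiteTrack(sites=sites, provenance="random")


def _as_intervals(calls) -> list[tuple[str, int, int]]:
    out = []
    for c in calls:
        if isinstance(c, SSBCall):
            out.append((c.chrom, c.start, c.end))
        else:
            out.append((c[0], int(c[1]), int(c[2])))
    return out


def window_coincidence(
    calls, sites: SiteTrack, w: int = 10
) -> tuple[Optional[float], list[bool]]:
    """bedtools-window overlap: a call coincides with the track iff the call
    extended by ``w`` bp on both sides overlaps a site interval (half-open).

    Returns (fraction of unique calls coinciding, per-call flags in input
    order). Fraction is None for an empty call set; w=0 is plain intersection.
    """
    ivs = _as_intervals(calls)
    index = sites.by_chrom()
    flags: list[bool] = []
    for chrom, s, e in ivs:
        hit = False
        if chrom in index:
            starts, ends = index[chrom]
            # sites with start < e+w and end > s-w
            n_start_ok = bisect_left(starts, e + w)
            n_end_too_small = bisect_right(ends, s - w)
            hit = n_start_ok > n_end_too_small
        flags.append(hit)
    uniq: dict[tuple, bool] = {}
    for iv, f in zip(ivs, flags):
        uniq[iv] = uniq.get(iv, False) or f
    frac = (sum(uniq.values()) / len(uniq)) if uniq else None
    return frac, flags


def score_against_truth(
    calls, truth: SiteTrack, tol: int = 10
) -> tuple[Optional[float], Optional[float], list[dict]]:
    """Recall/precision of calls against simulator truth nicks.

    A call is *within tol* of a nick iff the call extended by ``tol`` overlaps
    the 1-bp nick interval (same rule as :func:`window_coincidence`). Recall =
    fraction of truth nicks with >= 1 call within tol; precision = fraction of
    calls within tol of some nick; the hit table additionally reports a greedy
    1-to-1 match (closest distance first, ties by coordinate).
    """
    ivs = _as_intervals(calls)
    truth_sites = list(truth.sites)
    # candidate pairs within tol
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ti, (chrom, ts, te, *_) in enumerate(truth_sites):
        by_chrom.setdefault(chrom, []).append((ts, ti))
    for chrom in by_chrom:
        by_chrom[chrom].sort()
    pairs: list[tuple[int, int, int, int]] = []  # (dist, ts, ci, ti)
    call_hit = [False] * len(ivs)
    truth_hit = [False] * len(truth_sites)
    for ci, (chrom, s, e) in enumerate(ivs):
        if chrom not in by_chrom:
            continue
        entries = by_chrom[chrom]
        starts = [t for t, _ in entries]
        lo = bisect_left(starts, s - tol)
        hi = bisect_right(starts, e + tol)
        for ts, ti in entries[lo:hi]:
            # overlap of [s-tol, e+tol) with [ts, ts+1)
            if s - tol < ts + 1 and ts < e + tol:
                call_hit[ci] = True
                truth_hit[ti] = True
                dist = 0 if s <= ts < e else max(s - ts - 1, ts - e, 0)
                pairs.append((dist, ts, ci, ti))
    recall = (sum(truth_hit) / len(truth_sites)) if truth_sites else None
    precision = (sum(call_hit) / len(ivs)) if ivs else None

    pairs.sort()
    used_c: set[int] = set()
    used_t: set[int] = set()
    matches: dict[int, tuple[int, int]] = {}
    for dist, _ts, ci, ti in pairs:
        if ci in used_c or ti in used_t:
            continue
        used_c.add(ci)
        used_t.add(ti)
        matches[ti] = (ci, dist)
    table = []
    for ti, (chrom, ts, te, strand, label) in enumerate(truth_sites):
        m = matches.get(ti)
        table.append(
            {
                "chrom": chrom,
                "nick_pos": ts,
                "strand": strand,
                "hit": truth_hit[ti],
                "matched_call": m[0] if m else None,
                "distance": m[1] if m else None,
            }
        )
    return recall, precision, table


def read_bed(path: Union[str, os.PathLike], provenance: str = "motif") -> SiteTrack:
    sites: list[Interval] = []
    with open(os.fspath(path)) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise SteelseqError(f"malformed BED line {ln} in {path}")
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else "."
            label = parts[3] if len(parts) > 3 else "."
            sites.append((parts[0], int(parts[1]), int(parts[2]), strand, label))
    return SiteTrack(sites=sites, provenance=provenance)


def write_bed(track: SiteTrack, path: Union[str, os.PathLike]) -> None:
    with open(os.fspath(path), "w") as fh:
        for chrom, start, end, strand, label in track.sites:
            fh.write(f"{chrom}\t{start}\t{end}\t{label}\t0\t{strand}\n")
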