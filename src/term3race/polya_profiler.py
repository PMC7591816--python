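"""Poly(A)-site profiling from aligned 3'-RACE reads.

The profiling chain is: per-read 3'-end calls -> per-position raw-count and
RPM (reads per million mapped) tracks -> peaks above an RPM cutoff ->
unique poly(A) sites, where redundant cleavage positions within a grouping
window (35 nt by default, the rice near-upstream-element bound) collapse to
one site represented by the highest-RPM position.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from .construct_io import (
    AlignedRead,
    ConstructLayout,
    OutOfWindowError,
    revcomp,
    to_tt_coordinate,
)

__all__ = [
    "EndCall",
    "SiteProfile",
    "Peak",
    "UniqueSite",
    "detect_polya_tail",
    "extract_end_call",
    "accumulate_profile",
    "call_peaks",
    "cluster_unique_sites",
    "select_major_site",
    "DEFAULT_CUTOFF_RPM",
    "DEFAULT_GROUPING_WINDOW",
]

#: RPM threshold above which a position is called a poly(A) peak (inclusive).
DEFAULT_CUTOFF_RPM = 10_000.0
#: Redundant-cleavage grouping radius in nt (rice NUE bound; use 30 for an
#: Arabidopsis-style analysis).
DEFAULT_GROUPING_WINDOW = 35


@dataclass(frozen=True)
class EndCall:
    """3' end of one mapped read: the last templated base before the tail."""

    tt_position: int  # 1-based TT-local
    tail_evidence: int = 0  # observed A-tail length in the trailing clip
    read_id: str = ""

    def __post_init__(self) -> None:
        if self.tt_position < 1:
            raise ValueError(f"tt_position must be >= 1, got {self.tt_position}")
        if self.tail_evidence < 0:
            raise ValueError("tail_evidence must be >= 0")


@dataclass(frozen=True)
class SiteProfile:
    """Per-position raw-count and RPM track over TT-local coordinates."""

    tt_id: str
    raw_counts: dict[int, int]
    rpm: dict[int, float]
    total_mapped_reads: int


@dataclass(frozen=True)
class Peak:
    tt_position: int
    rpm: float
    raw_count: int


@dataclass
class UniqueSite:
    """A cluster of redundant cleavage peaks treated as one poly(A) site."""

    member_peaks: list[Peak]
    representative_position: int
    span: tuple[int, int]
    total_rpm: float
    is_major: bool = False

    @property
    def representative_peak(self) -> Peak:
        for p in self.member_peaks:
            if p.tt_position == self.representative_position:
                return p
        raise ValueError("representative position not among member peaks")


def detect_polya_tail(clip_seq: str, min_len: int = 5, min_a_frac: float = 0.8) -> Optional[int]:
    """Length of a soft-clipped segment that looks like an untemplated A-tail.

    Returns the clip length when the clip is at least ``min_len`` long and its
    adenosine fraction is at least ``min_a_frac``; otherwise ``None``.  Input
    is the transcript-3'-side clip in transcript orientation.
    """
    n = len(clip_seq)
    if n < min_len:
        return None
    n_a = clip_seq.upper().count("A")
    if n_a / n >= min_a_frac:
        return n
    return None


def extract_end_call(read: AlignedRead, layout: ConstructLayout,
                     min_tail_len: int = 5, min_a_frac: float = 0.8) -> Optional[EndCall]:
    """Call the transcript 3' end of one mapped read, in TT-local coordinates.

    For '+' alignments the 3' end is the rightmost aligned reference base and
    the candidate tail is the trailing soft clip; for '-' alignments the 3'
    end is the leftmost aligned base and the tail is the leading clip
    (reverse-complemented back into transcript orientation).  Insertions at
    the tail junction do not move the end; the call is the last *templated*
    base.  Returns ``None`` when the end falls upstream of TT-local 1.
    """
    if read.alignment_strand == "+":
        end_ref = read.reference_end  # 0-based exclusive == 1-based inclusive last base
        clip = read.trailing_clip_seq
    else:
        end_ref = read.reference_start + 1  # leftmost aligned base, 1-based
        clip = revcomp(read.leading_clip_seq)
    try:
        tt_pos = to_tt_coordinate(end_ref, layout)
    except OutOfWindowError:
        return None
    tail = detect_polya_tail(clip, min_len=min_tail_len, min_a_frac=min_a_frac) or 0
    return EndCall(tt_position=tt_pos, tail_evidence=tail, read_id=read.read_id)


def accumulate_profile(end_calls: Iterable[EndCall], layout: ConstructLayout,
                       total_mapped_reads: int) -> SiteProfile:
    """Sum end calls into a per-position histogram and normalise to RPM.

    ``rpm[p] = raw_counts[p] / total_mapped_reads * 1e6``.  The denominator
    is the number of reads mapped to the construct (sequencing depth), which
    may exceed the number of accepted end calls.
    """
    if total_mapped_reads <= 0:
        raise ValueError("total_mapped_reads must be > 0")
    counts = Counter(call.tt_position for call in end_calls)
    raw = dict(sorted(counts.items()))
    scale = 1e6 / total_mapped_reads
    rpm = {pos: n * scale for pos, n in raw.items()}
    return SiteProfile(tt_id=layout.construct_id, raw_counts=raw, rpm=rpm,
                       total_mapped_reads=total_mapped_reads)


def call_peaks(profile: SiteProfile, cutoff_rpm: float = DEFAULT_CUTOFF_RPM) -> list[Peak]:
    """Positions whose RPM reaches the cutoff (inclusive), sorted by position."""
    return [
        Peak(tt_position=pos, rpm=profile.rpm[pos], raw_count=profile.raw_counts[pos])
        for pos in sorted(profile.rpm)
        if profile.rpm[pos] >= cutoff_rpm
    ]


def cluster_unique_sites(peaks: Sequence[Peak],
                         grouping_window: int = DEFAULT_GROUPING_WINDOW) -> list[UniqueSite]:
    """Group redundant cleavage peaks into unique poly(A) sites.

    Greedy seeded clustering: repeatedly take the highest-RPM unassigned peak
    as seed (ties broken leftmost) and absorb every unassigned peak within
    ``grouping_window`` nt of it.  The seed is the cluster representative, so
    every member lies within the window of the representative and cluster
    spans are bounded by ``2 * grouping_window + 1`` nt.  The result is a
    partition of the input, deterministic and independent of input order;
    sites are returned in position order.
    """
    remaining = sorted(peaks, key=lambda p: p.tt_position)
    sites: list[UniqueSite] = []
    while remaining:
        seed = max(remaining, key=lambda p: (p.rpm, -p.tt_position))
        members = [p for p in remaining
                   if abs(p.tt_position - seed.tt_position) <= grouping_window]
        remaining = [p for p in remaining if p not in members]
        sites.append(
            UniqueSite(
                member_peaks=members,
                representative_position=seed.tt_position,
                span=(members[0].tt_position, members[-1].tt_position),
                total_rpm=sum(p.rpm for p in members),
            )
        )
    sites.sort(key=lambda s: s.representative_position)
    return sites


def select_major_site(sites: Sequence[UniqueSite]) -> UniqueSite:
    """Flag and return the major poly(A) site.

    The major site is the one whose representative peak carries the global
    maximum single-position RPM (highest mRNA abundance); ties break to the
    leftmost representative.  Exactly one site ends up flagged.
    """
    if not sites:
        raise ValueError("no unique sites to select a major site from")
    major = max(sites, key=lambda s: (s.representative_peak.rpm, -s.representative_position))
    for site in sites:
        site.is_major = site is major
    return major
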