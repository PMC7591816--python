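"""Near-upstream-element (NUE) and far-upstream-element (FUE) scanning.

The near-upstream element of a plant terminator sits 10-35 nt upstream of the
cleavage site and houses the poly(A) signal: the canonical AAUAAA, an
AAUAAA-like variant, or an NUE-enriched hexamer.  Observed signals are often
*composites* — overlapping hexamers merged into 9-11 nt motifs such as
AUGAAUAAG (AUGAAU + AAUAAG).  This module scans NUE windows against a
packaged hexamer catalog, merges overlapping hits into composite putative
poly(A) signals (PPSGs), assigns one PPSG per site by class priority, scans
for FUE/GC-rich motifs, and computes aggregate statistics over a set of
terminators.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .construct_io import to_rna

__all__ = [
    "HexamerEntry",
    "MotifHit",
    "CompositeMotif",
    "PPSGAssignment",
    "FueHit",
    "TTSignalSummary",
    "NoOverlapError",
    "builtin_catalog",
    "catalog_by_sequence",
    "catalog_members",
    "scan_window",
    "max_overlap_merge",
    "chain_merge",
    "merge_composites",
    "assign_ppsg",
    "scan_fue",
    "ure_u_content",
    "aggregate_stats",
    "CLASS_PRIORITY",
    "NUE_WINDOW",
]

#: NUE scan window bounds: distances (nt) upstream of the cleavage site.
NUE_WINDOW = (10, 35)

#: Signal-class priority when assigning a PPSG to a site (lower = stronger).
CLASS_PRIORITY = {"canonical": 0, "aauaaa_like": 1, "nue_enriched": 2}


class NoOverlapError(ValueError):
    """Raised when two motifs share no suffix-prefix overlap."""


@dataclass(frozen=True)
class HexamerEntry:
    """One catalog hexamer with its NUE-survey rankings.

    Rank 0 means "not listed" in the corresponding survey and is never
    compared numerically.
    """

    sequence: str  # RNA 6-mer
    class_tag: str  # canonical | aauaaa_like | nue_enriched
    rice_rank: int
    at_rank_a: int
    at_rank_b: int
    note: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != 6 or any(b not in "ACGU" for b in self.sequence):
            raise ValueError(f"catalog sequence must be an RNA 6-mer, got {self.sequence!r}")
        if self.class_tag not in CLASS_PRIORITY:
            raise ValueError(f"unknown class_tag {self.class_tag!r}")

    def rank_display(self) -> str:
        def fmt(r: int) -> str:
            return str(r) if r else "-"
        return f"{fmt(self.rice_rank)} ({fmt(self.at_rank_a)}, {fmt(self.at_rank_b)})"


@dataclass(frozen=True)
class MotifHit:
    """A catalog hexamer occurrence near a poly(A) site."""

    hexamer: HexamerEntry
    tt_start: int  # 1-based TT-local start of the 6-mer
    distance_to_site: int  # nt from the hit's 3'-most base to the site

    @property
    def tt_end(self) -> int:
        return self.tt_start + 5


@dataclass(frozen=True)
class CompositeMotif:
    """Maximal run of overlapping hexamer hits, read off the sequence."""

    sequence: str  # merged RNA string
    tt_span: tuple[int, int]  # 1-based inclusive
    members: tuple[MotifHit, ...]
    classification: str
    contains_AUGAAU: bool

    @property
    def tt_end(self) -> int:
        return self.tt_span[1]


@dataclass(frozen=True)
class PPSGAssignment:
    """The putative poly(A) signal chosen for one unique site (or none)."""

    site_position: int
    composite: Optional[CompositeMotif]
    distance: Optional[int]  # composite 3' end -> site, nt
    rationale: str


@dataclass(frozen=True)
class FueHit:
    motif_kind: str  # gc_rich_stability | u_rich_repeat
    sequence: str  # matched string, RNA
    tt_start: int
    relative_to_site: int  # signed nt offset of the motif start from the site


@lru_cache(maxsize=1)
def builtin_catalog() -> tuple[HexamerEntry, ...]:
    """The packaged NUE hexamer catalog.

    Sixteen hexamers: the canonical AAUAAA; six AAUAAA-like signals validated
    by mutagenesis/linker-scanning studies in plants (AAUAAG, AAUGAA, AAUCAA,
    AAUUAA, UAUAAA, AAGAAA); and nine further hexamers enriched in rice and
    Arabidopsis gene NUEs, with their survey rankings.  AAUGAC is deliberately
    absent: it does not occur in rice or Arabidopsis NUEs.
    """
    path = resources.files("term3race").joinpath("data/nue_hexamers.tsv")
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", dtype={"note": str}).fillna({"note": ""})
    entries = tuple(
        HexamerEntry(
            sequence=row.sequence,
            class_tag=row.class_tag,
            rice_rank=int(row.rice_rank),
            at_rank_a=int(row.at_rank_a),
            at_rank_b=int(row.at_rank_b),
            note=row.note,
        )
        for row in df.itertuples()
    )
    canonical = [e for e in entries if e.class_tag == "canonical"]
    if len(canonical) != 1 or canonical[0].sequence != "AAUAAA":
        raise ValueError("catalog must contain exactly one canonical entry, AAUAAA")
    return entries


def catalog_by_sequence() -> dict[str, HexamerEntry]:
    return {e.sequence: e for e in builtin_catalog()}


def catalog_members(sequence: str,
                    catalog: Optional[Sequence[HexamerEntry]] = None) -> list[tuple[HexamerEntry, int]]:
    """All catalog hexamer occurrences in a sequence.

    Returns ``(entry, start)`` pairs with 1-based starts, sorted by start then
    hexamer.  Overlapping and repeated occurrences are all reported.
    """
    rna = to_rna(sequence)
    if catalog is None:
        catalog = builtin_catalog()
    hits: list[tuple[HexamerEntry, int]] = []
    for entry in catalog:
        start = rna.find(entry.sequence)
        while start != -1:
            hits.append((entry, start + 1))
            start = rna.find(entry.sequence, start + 1)
    hits.sort(key=lambda h: (h[1], h[0].sequence))
    return hits


def scan_window(tt_sequence: str, site_position: int, lo: int = NUE_WINDOW[0],
                hi: int = NUE_WINDOW[1],
                catalog: Optional[Sequence[HexamerEntry]] = None) -> list[MotifHit]:
    """Scan the NUE window of one poly(A) site for catalog hexamers.

    A hexamer counts when any of its six bases lies in the window
    ``[site - hi, site - lo]`` (1-based TT-local, truncated at the sequence
    start).  The distance is measured from the hexamer's 3'-most base to the
    site.  Hits are sorted by start position.
    """
    if not 1 <= site_position <= len(tt_sequence):
        raise ValueError(f"site_position {site_position} outside sequence")
    if lo >= hi:
        raise ValueError(f"window bounds must satisfy lo < hi, got {lo} >= {hi}")
    w_lo = max(1, site_position - hi)
    w_hi = site_position - lo
    if w_hi < 1:
        return []
    hits = [
        MotifHit(hexamer=entry, tt_start=start,
                 distance_to_site=site_position - (start + 5))
        for entry, start in catalog_members(tt_sequence, catalog)
        if start <= w_hi and start + 5 >= w_lo
    ]
    hits.sort(key=lambda h: (h.tt_start, h.hexamer.sequence))
    return hits


def max_overlap_merge(a: str, b: str) -> str:
    """Merge two motifs at their maximal proper suffix(a)/prefix(b) overlap.

    Returns the shortest string with ``a`` as prefix and ``b`` as suffix,
    e.g. AUGAAU + AAUAAG -> AUGAAUAAG.  Requires an overlap of at least 1 nt
    (raises :class:`NoOverlapError` otherwise); a full-length overlap is not
    considered, so merging a motif with itself yields a tandem arrangement
    (AUGAAU + AUGAAU -> AUGAAUGAAU).
    """
    a, b = to_rna(a), to_rna(b)
    for k in range(min(len(a), len(b)) - 1, 0, -1):
        if a[-k:] == b[:k]:
            return a + b[k:]
    raise NoOverlapError(f"no suffix-prefix overlap between {a} and {b}")


def chain_merge(hexamers: Sequence[str]) -> str:
    """Left-to-right fold of :func:`max_overlap_merge` over an ordered list.

    ``(AAUGAA, AUGAAU, AAUAAA, AUAAAU) -> AAUGAAUAAAU`` (11 nt).  Raises
    :class:`NoOverlapError` naming the first non-overlapping pair.
    """
    if not hexamers:
        raise ValueError("empty motif list")
    merged = to_rna(hexamers[0])
    for nxt in hexamers[1:]:
        try:
            merged = max_overlap_merge(merged, nxt)
        except NoOverlapError as exc:
            raise NoOverlapError(f"cannot chain {merged} with {to_rna(nxt)}") from exc
    return merged


def _classify(members: Iterable[MotifHit]) -> str:
    return min((m.hexamer.class_tag for m in members), key=CLASS_PRIORITY.__getitem__)


def merge_composites(hits: Sequence[MotifHit], tt_sequence: str) -> list[CompositeMotif]:
    """Merge hexamer hits that overlap on the sequence into composite PPSGs.

    Hits whose genomic spans overlap by at least 1 nt are merged transitively
    (adjacency without overlap does not merge); each composite's sequence is
    read from the terminator sequence over the union span, its classification
    is the strongest member class, and ``contains_AUGAAU`` marks the presence
    of the AUGAAU hexamer among the members.
    """
    if not hits:
        return []
    rna = to_rna(tt_sequence)
    ordered = sorted(hits, key=lambda h: (h.tt_start, h.hexamer.sequence))
    groups: list[list[MotifHit]] = []
    current = [ordered[0]]
    reach = ordered[0].tt_end
    for hit in ordered[1:]:
        if hit.tt_start <= reach:  # >=1 nt overlap with the growing run
            current.append(hit)
            reach = max(reach, hit.tt_end)
        else:
            groups.append(current)
            current = [hit]
            reach = hit.tt_end
    groups.append(current)
    composites = []
    for group in groups:
        start = min(h.tt_start for h in group)
        end = max(h.tt_end for h in group)
        composites.append(
            CompositeMotif(
                sequence=rna[start - 1: end],
                tt_span=(start, end),
                members=tuple(group),
                classification=_classify(group),
                contains_AUGAAU=any(h.hexamer.sequence == "AUGAAU" for h in group),
            )
        )
    return composites


def assign_ppsg(site_position: int, composites: Sequence[CompositeMotif],
                lo: int = NUE_WINDOW[0], hi: int = NUE_WINDOW[1]) -> PPSGAssignment:
    """Choose the putative poly(A) signal for one site.

    Among the composites from the site's window scan, the strongest class
    wins (canonical > AAUAAA-like > NUE-enriched); within a class, the
    composite nearest the site.  The choice is deterministic and independent
    of the input ordering.  With no composites the assignment is none — the
    signal for such sites is ambiguous.
    """
    if not composites:
        return PPSGAssignment(site_position=site_position, composite=None,
                              distance=None, rationale="none")

    def key(c: CompositeMotif) -> tuple[int, int, int]:
        return (CLASS_PRIORITY[c.classification], site_position - c.tt_end, c.tt_span[0])

    best = min(composites, key=key)
    distance = site_position - best.tt_end
    return PPSGAssignment(
        site_position=site_position,
        composite=best,
        distance=distance,
        rationale=f"{best.classification}@-{distance}",
    )


_GC_RICH = re.compile("CGUGUC..")
_U_RICH_CORE = "UUUGUA"


def scan_fue(tt_sequence: str, site_position: int, upstream_extent: int = 150,
             downstream_extent: int = 35, u_rich_max_mismatch: int = 1) -> list[FueHit]:
    """Scan for far-upstream-element and mRNA-stability motifs around a site.

    Two pattern families are scanned: ``CGUGUCNN`` GC-rich stability motifs
    anywhere within ``[-upstream_extent, +downstream_extent]`` of the site,
    and the U-rich FUE repeat ``UUUGUA`` (with up to ``u_rich_max_mismatch``
    mismatches) within the upstream extent only.  Offsets are the signed
    position of the motif start relative to the site.
    """
    rna = to_rna(tt_sequence)
    hits: list[FueHit] = []
    lo = max(1, site_position - upstream_extent)
    hi = min(len(rna), site_position + downstream_extent)
    for m in _GC_RICH.finditer(rna):
        start = m.start() + 1
        if lo <= start <= hi:
            hits.append(FueHit("gc_rich_stability", m.group(0), start,
                               start - site_position))
    k = len(_U_RICH_CORE)
    for start in range(lo, min(site_position, len(rna) - k + 1) + 1):
        window = rna[start - 1: start - 1 + k]
        if len(window) < k:
            break
        mism = sum(1 for x, y in zip(window, _U_RICH_CORE) if x != y)
        if mism <= u_rich_max_mismatch:
            hits.append(FueHit("u_rich_repeat", window, start, start - site_position))
    hits.sort(key=lambda h: (h.tt_start, h.motif_kind))
    return hits


def ure_u_content(tt_sequence: str, site_position: int, flank: int = 10) -> tuple[float, float]:
    """U fractions of the U-rich element flanks around a cleavage site.

    Returns the uridine fractions of ``[site - flank, site)`` and
    ``(site, site + flank]``, truncated at the sequence edges.  An empty
    (fully truncated) flank yields 0.0.
    """
    rna = to_rna(tt_sequence)
    up = rna[max(0, site_position - 1 - flank): site_position - 1]
    down = rna[site_position: site_position + flank]

    def frac(seg: str) -> float:
        return seg.count("U") / len(seg) if seg else 0.0

    return frac(up), frac(down)


@dataclass(frozen=True)
class TTSignalSummary:
    """Per-terminator inputs to :func:`aggregate_stats`.

    ``ppsg_sequences`` holds one merged PPSG string per site that received a
    non-none assignment; sites with an ambiguous signal contribute nothing.
    """

    tt_id: str
    unique_site_count: int
    ppsg_sequences: tuple[str, ...]


def _round_half_up(x: float) -> int:
    import math
    return math.floor(x + 0.5)


def aggregate_stats(summaries: Sequence[TTSignalSummary], *,
                    contains_query: str = "AUGAAU",
                    exact_query: Optional[str] = None,
                    subset: Optional[Iterable[str]] = None) -> dict:
    """Aggregate PPSG statistics over a set of terminators.

    Returns a dict with: the count and fraction of terminators carrying at
    least one PPSG containing ``contains_query``; the percentage of unique
    poly(A) sites with a non-none assignment (rounded half-up to an integer);
    the min/max unique-site count per terminator; and, when ``exact_query``
    is given, the count of terminators (optionally restricted to ``subset``)
    with a PPSG exactly equal to the query.
    """
    if not summaries:
        raise ValueError("no terminator summaries to aggregate")
    contains_query = to_rna(contains_query)
    n_tts = len(summaries)
    with_query = [s for s in summaries
                  if any(contains_query in p for p in s.ppsg_sequences)]
    total_sites = sum(s.unique_site_count for s in summaries)
    assigned = sum(len(s.ppsg_sequences) for s in summaries)
    stats = {
        "n_tts": n_tts,
        "n_tts_with_query_motif": len(with_query),
        "tts_with_query_motif": tuple(s.tt_id for s in with_query),
        "query_motif": contains_query,
        "n_unique_sites": total_sites,
        "n_assigned_sites": assigned,
        "ppsg_coverage_percent": _round_half_up(100.0 * assigned / total_sites)
        if total_sites else 0,
        "site_count_min": min(s.unique_site_count for s in summaries),
        "site_count_max": max(s.unique_site_count for s in summaries),
    }
    if exact_query is not None:
        exact_query = to_rna(exact_query)
        pool = summaries
        if subset is not None:
            wanted = set(subset)
            pool = [s for s in summaries if s.tt_id in wanted]
        stats["exact_query"] = exact_query
        stats["n_tts_with_exact_ppsg"] = sum(
            any(p == exact_query for p in s.ppsg_sequences) for s in pool
        )
    return stats
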