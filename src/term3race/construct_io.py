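"""Construct coordinate model and file I/O for the terminator pipeline.

A chimeric construct is a single reference sequence carrying a reporter CDS
followed by a transcription terminator (TT).  All reporting uses TT-local
coordinates in which position 1 is the *last base of the reporter CDS* — the
convention used throughout the terminator literature for 3'-RACE profiles —
while internal arithmetic on alignments is 0-based half-open.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ConstructLayout",
    "AlignedRead",
    "LayoutError",
    "OutOfWindowError",
    "SamParseError",
    "load_layout",
    "to_tt_coordinate",
    "from_tt_coordinate",
    "read_alignments",
    "write_sites",
    "read_fasta",
    "write_fasta",
    "to_rna",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def to_rna(seq: str) -> str:
    """Render a DNA string in the RNA alphabet (T->U, uppercase)."""
    return seq.upper().replace("T", "U")


def to_dna(seq: str) -> str:
    """Normalise an RNA or DNA string to the DNA alphabet (U->T, uppercase)."""
    return seq.upper().replace("U", "T")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class LayoutError(ValueError):
    """Raised for a missing or out-of-range construct layout field."""


class OutOfWindowError(ValueError):
    """Raised when a reference position lies upstream of the TT window."""


class SamParseError(ValueError):
    """Raised when the SAM input cannot be parsed."""


@dataclass(frozen=True)
class ConstructLayout:
    """Placement of the terminator on a construct reference.

    ``reporter_cds_end`` is the 1-based reference position of the last base
    of the reporter CDS; by convention that base is TT-local coordinate 1.
    """

    construct_id: str
    reference_length: int
    reporter_cds_end: int
    tt_length: int
    reporter_strand: str = "+"

    def __post_init__(self) -> None:
        if self.reporter_strand not in ("+", "-"):
            raise LayoutError(f"reporter_strand must be '+' or '-', got {self.reporter_strand!r}")
        if not 1 <= self.reporter_cds_end <= self.reference_length:
            raise LayoutError(
                f"reporter_cds_end={self.reporter_cds_end} outside "
                f"[1, reference_length={self.reference_length}]"
            )
        if self.tt_length < 1:
            raise LayoutError(f"tt_length must be >= 1, got {self.tt_length}")
        if self.reporter_strand == "+" and self.reporter_cds_end + self.tt_length - 1 > self.reference_length:
            raise LayoutError(
                f"TT span exceeds reference: reporter_cds_end={self.reporter_cds_end} "
                f"+ tt_length={self.tt_length} - 1 > reference_length={self.reference_length}"
            )

    @property
    def tt_end_reference(self) -> int:
        """1-based reference position of the last TT base."""
        return self.reporter_cds_end + self.tt_length - 1


_LAYOUT_FIELDS = ("construct_id", "reference_length", "reporter_cds_end", "tt_length")


def load_layout(config: str | Mapping) -> ConstructLayout:
    """Build a validated :class:`ConstructLayout` from YAML text or a mapping.

    Raises :class:`LayoutError` naming the offending field.
    """
    if isinstance(config, str):
        try:
            config = yaml.safe_load(config)
        except yaml.YAMLError as exc:  # pragma: no cover - malformed input path
            raise LayoutError(f"unparseable layout config: {exc}") from exc
    if not isinstance(config, Mapping):
        raise LayoutError("layout config must be a mapping")
    for name in _LAYOUT_FIELDS:
        if name not in config:
            raise LayoutError(f"missing layout field: {name}")
    return ConstructLayout(
        construct_id=str(config["construct_id"]),
        reference_length=int(config["reference_length"]),
        reporter_cds_end=int(config["reporter_cds_end"]),
        tt_length=int(config["tt_length"]),
        reporter_strand=str(config.get("reporter_strand", "+")),
    )


def to_tt_coordinate(reference_position: int, layout: ConstructLayout) -> int:
    """Convert a 1-based reference position to a 1-based TT-local position.

    TT-local 1 is ``layout.reporter_cds_end``.  Positions upstream of the
    reporter CDS end raise :class:`OutOfWindowError` so the caller can discard
    the read (3'-RACE primers anchor in the reporter 3' exon; ends upstream
    of the CDS end are artifacts).
    """
    if reference_position < layout.reporter_cds_end:
        raise OutOfWindowError(
            f"reference position {reference_position} upstream of reporter CDS end "
            f"{layout.reporter_cds_end}"
        )
    return reference_position - layout.reporter_cds_end + 1


def from_tt_coordinate(tt_position: int, layout: ConstructLayout) -> int:
    """Inverse of :func:`to_tt_coordinate`; returns the 1-based reference position."""
    if tt_position < 1:
        raise OutOfWindowError(f"TT-local position must be >= 1, got {tt_position}")
    return tt_position + layout.reporter_cds_end - 1


@dataclass(frozen=True)
class AlignedRead:
    """A mapped read, reduced to what end calling and sRNA profiling need.

    ``reference_start``/``reference_end`` form a 0-based half-open interval;
    soft-clipped segments are kept verbatim (reference-forward orientation,
    as stored in SAM).
    """

    read_id: str
    reference_id: str
    alignment_strand: str
    reference_start: int
    reference_end: int
    leading_clip_seq: str = ""
    trailing_clip_seq: str = ""
    mapping_quality: int = 0

    def __post_init__(self) -> None:
        if self.reference_end <= self.reference_start or self.reference_start < 0:
            raise ValueError(
                f"empty or negative reference span [{self.reference_start}, {self.reference_end})"
            )

    @property
    def span_length(self) -> int:
        return self.reference_end - self.reference_start


def _clips(seg: pysam.AlignedSegment) -> tuple[str, str]:
    cig = seg.cigartuples or []
    seq = seg.query_sequence or ""
    leading = trailing = ""
    if cig and cig[0][0] == 4:  # leading soft clip
        leading = seq[: cig[0][1]]
    if cig and cig[-1][0] == 4:  # trailing soft clip
        trailing = seq[len(seq) - cig[-1][1]:] if seq else ""
    return leading, trailing


def read_alignments(sam_path: str | Path) -> tuple[list[AlignedRead], dict[str, int]]:
    """Read a SAM file into :class:`AlignedRead` records.

    Unmapped records are skipped and counted; secondary and supplementary
    records are excluded (the upstream aligner reports a single location per
    read).  Returns ``(reads, skip_counts)`` where ``skip_counts`` has keys
    ``unmapped``, ``secondary``, ``supplementary``; their sum plus
    ``len(reads)`` equals the number of SAM body records.
    """
    reads: list[AlignedRead] = []
    skipped = {"unmapped": 0, "secondary": 0, "supplementary": 0}
    try:
        with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as fh:
            for seg in fh:
                if seg.is_unmapped:
                    skipped["unmapped"] += 1
                    continue
                if seg.is_secondary:
                    skipped["secondary"] += 1
                    continue
                if seg.is_supplementary:
                    skipped["supplementary"] += 1
                    continue
                leading, trailing = _clips(seg)
                reads.append(
                    AlignedRead(
                        read_id=seg.query_name or "",
                        reference_id=seg.reference_name or "",
                        alignment_strand="-" if seg.is_reverse else "+",
                        reference_start=seg.reference_start,
                        reference_end=seg.reference_end,
                        leading_clip_seq=leading,
                        trailing_clip_seq=trailing,
                        mapping_quality=seg.mapping_quality,
                    )
                )
    except ValueError as exc:
        raise SamParseError(f"malformed SAM {sam_path}: {exc}") from exc
    return reads, skipped


SITE_TSV_COLUMNS = ("tt_id", "tt_position", "raw_count", "rpm", "is_major", "cluster_span")


def write_sites(sites: Sequence, layout: ConstructLayout, bed_path: str | Path,
                tsv_path: str | Path) -> None:
    """Write unique poly(A) sites as BED6 (reference coordinates) and TSV.

    BED intervals are 0-based half-open single-base intervals at each site's
    representative position; the TSV reports 1-based TT-local coordinates.
    Sites are written sorted by position.  ``sites`` are
    :class:`~term3race.polya_profiler.UniqueSite` records.
    """
    ordered = sorted(sites, key=lambda s: s.representative_position)
    with open(bed_path, "w") as bed:
        for site in ordered:
            ref_pos = from_tt_coordinate(site.representative_position, layout)  # 1-based
            rep = site.representative_peak
            score = min(1000, int(round(rep.rpm / 1000)))
            bed.write(
                f"{layout.construct_id}\t{ref_pos - 1}\t{ref_pos}\t"
                f"site_tt{site.representative_position}\t{score}\t{layout.reporter_strand}\n"
            )
    with open(tsv_path, "w") as tsv:
        tsv.write("\t".join(SITE_TSV_COLUMNS) + "\n")
        for site in ordered:
            rep = site.representative_peak
            tsv.write(
                f"{layout.construct_id}\t{site.representative_position}\t{rep.raw_count}\t"
                f"{rep.rpm:.6g}\t{int(site.is_major)}\t{site.span[0]}-{site.span[1]}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ``{id: sequence}`` dict (uppercase DNA)."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(records: Mapping[str, str], path: str | Path) -> None:
    recs = [SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()]
    SeqIO.write(recs, str(path), "fasta")
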