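"""Synthetic terminator designer and read simulator.

Generates construct sequences with planted cis-elements (cleavage clusters
with YA-type dinucleotides, NUE poly(A)-signal motifs, FUE/GC-rich motifs)
and simulates 3'-RACE amplicon reads and small-RNA reads with full truth
tables, so every pipeline stage can be tested round-trip without external
sequencing data or an aligner.

The simulator emulates the study conditions this pipeline targets: 3'-RACE
amplicons whose templated 3' ends fall at a handful of cleavage clusters
(multinomial site usage, uniform redundant-cleavage jitter of a few nt),
carrying untemplated poly(A) tails; and strand-pure sense sRNA background
with an optional antisense fraction mimicking RDR6 silencing.  Alignments
are emitted directly (positions are known by construction), so no aligner
is ever run.

All randomness derives from one integer seed through
``numpy.random.SeedSequence`` spawning, so sub-streams (background sequence,
read ends, tails, sRNA strands) are independent and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pysam

from .construct_io import AlignedRead, ConstructLayout, to_dna, to_rna, write_fasta
from .signal_scanner import builtin_catalog
from .srna_silencing import Region

__all__ = [
    "ClusterPlan",
    "NuePlan",
    "FuePlan",
    "TerminatorPlan",
    "SyntheticTruth",
    "SimulatedRace",
    "DesignError",
    "design_tt",
    "simulate_race_reads",
    "simulate_srna",
    "write_sam",
    "default_plan",
]

#: AU-rich background typical of plant 3' UTRs.
DEFAULT_BACKGROUND = {"A": 0.3, "T": 0.3, "C": 0.2, "G": 0.2}
#: Redundant-cleavage jitter (nt, each side of the cluster center).
DEFAULT_JITTER = 3


class DesignError(ValueError):
    """Raised when planted elements collide or a plan is infeasible."""


@dataclass(frozen=True)
class ClusterPlan:
    """One planted cleavage cluster: a poly(A) site with redundant jitter."""

    center: int  # TT-local 1-based position of the last templated base
    weight: float
    jitter: int = DEFAULT_JITTER
    dinucleotide: str = "UA"  # planted at (center-1, center)


@dataclass(frozen=True)
class NuePlan:
    """A poly(A)-signal motif planted upstream of a cleavage cluster."""

    motif: str  # RNA or DNA; may be a composite string such as AUGAAUAAG
    distance: int  # nt from the motif's 3'-most base to the cluster center
    cluster_index: int = 0


@dataclass(frozen=True)
class FuePlan:
    motif: str
    offset: int  # signed offset of the motif start relative to the cluster center
    cluster_index: int = 0


@dataclass(frozen=True)
class TerminatorPlan:
    tt_id: str
    tt_length: int
    clusters: tuple[ClusterPlan, ...]
    nue: tuple[NuePlan, ...] = ()
    fue: tuple[FuePlan, ...] = ()
    background: dict = field(default_factory=lambda: dict(DEFAULT_BACKGROUND))
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.clusters:
            raise DesignError("plan needs at least one cleavage cluster")
        total = sum(c.weight for c in self.clusters)
        if abs(total - 1.0) > 1e-9:
            raise DesignError(f"cluster weights must sum to 1, got {total}")
        for c in self.clusters:
            if c.center < 36:
                raise DesignError(
                    f"cluster center {c.center} < 36: no room for the NUE window"
                )
            if c.center + c.jitter > self.tt_length or c.center - c.jitter < 2:
                raise DesignError(f"cluster at {c.center} (±{c.jitter}) outside the TT")


@dataclass(frozen=True)
class PlantedElement:
    kind: str  # nue | fue | dinucleotide
    sequence: str  # DNA
    tt_start: int  # 1-based inclusive
    tt_end: int
    cluster_index: int


@dataclass(frozen=True)
class SyntheticTruth:
    """Designed sequence plus the registry of everything planted in it."""

    plan: TerminatorPlan
    sequence: str  # DNA, TT-local 1..tt_length
    elements: tuple[PlantedElement, ...]
    expected_unique_sites: int
    expected_major_cluster: int  # index into plan.clusters

    @property
    def tt_id(self) -> str:
        return self.plan.tt_id


def _draw_background(rng: np.random.Generator, n: int, composition: dict) -> np.ndarray:
    bases = np.array(list(composition), dtype="U1")
    probs = np.array([composition[b] for b in bases], dtype=float)
    probs = probs / probs.sum()
    return rng.choice(bases, size=n, p=probs)


def _planted_elements(plan: TerminatorPlan) -> list[PlantedElement]:
    elements: list[PlantedElement] = []
    for i, cluster in enumerate(plan.clusters):
        dn = to_dna(cluster.dinucleotide)
        if len(dn) != 2:
            raise DesignError(f"cluster dinucleotide must be 2 nt, got {dn!r}")
        elements.append(PlantedElement("dinucleotide", dn, cluster.center - 1,
                                       cluster.center, i))
    for spec in plan.nue:
        motif = to_dna(spec.motif)
        center = plan.clusters[spec.cluster_index].center
        end = center - spec.distance
        start = end - len(motif) + 1
        if start < 1:
            raise DesignError(f"NUE motif {spec.motif} extends past the TT start")
        elements.append(PlantedElement("nue", motif, start, end, spec.cluster_index))
    for spec in plan.fue:
        motif = to_dna(spec.motif)
        center = plan.clusters[spec.cluster_index].center
        start = center + spec.offset
        end = start + len(motif) - 1
        if start < 1 or end > plan.tt_length:
            raise DesignError(f"FUE motif {spec.motif} outside the TT")
        elements.append(PlantedElement("fue", motif, start, end, spec.cluster_index))
    elements.sort(key=lambda e: e.tt_start)
    for a, b in zip(elements, elements[1:]):
        if b.tt_start <= a.tt_end:
            raise DesignError(
                f"planted elements collide: {a.kind} {a.sequence} at {a.tt_start}-{a.tt_end} "
                f"vs {b.kind} {b.sequence} at {b.tt_start}-{b.tt_end}"
            )
    return elements


def _policed_windows(plan: TerminatorPlan, lo: int = 10, hi: int = 35) -> list[tuple[int, int]]:
    # Regions whose accidental catalog hexamers could leak into any peak's
    # NUE scan: the scan window of any position within the jitter span,
    # widened by the hexamer length.
    windows = []
    for c in plan.clusters:
        start = max(1, c.center - c.jitter - hi - 5)
        end = min(plan.tt_length, c.center + c.jitter)
        windows.append((start, end))
    return windows


def design_tt(plan: TerminatorPlan) -> SyntheticTruth:
    """Design a terminator sequence realising a :class:`TerminatorPlan`.

    Background bases are drawn from the plan's composition; planted motifs
    are written at their registered positions; accidental catalog hexamers
    inside any cluster's NUE scan region are removed by resampling background
    bases (planted bases are never touched).  Deterministic for a given seed.
    """
    elements = _planted_elements(plan)
    ss = np.random.SeedSequence(plan.seed)
    rng_bg, rng_fix = (np.random.default_rng(s) for s in ss.spawn(2))
    seq = _draw_background(rng_bg, plan.tt_length, plan.background)
    planted_mask = np.zeros(plan.tt_length, dtype=bool)
    for el in elements:
        seq[el.tt_start - 1: el.tt_end] = list(el.sequence)
        planted_mask[el.tt_start - 1: el.tt_end] = True

    catalog_dna = {to_dna(e.sequence) for e in builtin_catalog()}
    bases = np.array(list(plan.background), dtype="U1")
    probs = np.array([plan.background[b] for b in bases], dtype=float)
    probs /= probs.sum()

    for start, end in _policed_windows(plan):
        for _ in range(1000):
            text = "".join(seq[start - 1: end])
            dirty = False
            for i in range(len(text) - 5):
                if text[i: i + 6] in catalog_dna:
                    idx = np.arange(start - 1 + i, start - 1 + i + 6)
                    free = idx[~planted_mask[idx]]
                    if free.size == 0:
                        continue  # hexamer formed entirely by planted bases: intended
                    seq[rng_fix.choice(free)] = rng_fix.choice(bases, p=probs)
                    dirty = True
                    break
            if not dirty:
                break
        else:  # pragma: no cover - pathological compositions only
            raise DesignError("could not clear accidental hexamers from an NUE window")

    weights = [c.weight for c in plan.clusters]
    return SyntheticTruth(
        plan=plan,
        sequence="".join(seq),
        elements=tuple(elements),
        expected_unique_sites=len(plan.clusters),
        expected_major_cluster=int(np.argmax(weights)),
    )


@dataclass
class SimulatedRace:
    """Simulated 3'-RACE run: construct, alignments, and per-read truth."""

    truth: SyntheticTruth
    layout: ConstructLayout
    construct_seq: str  # DNA: reporter context + TT
    reads: list[AlignedRead]
    read_cluster: np.ndarray  # cluster index per read
    read_end_tt: np.ndarray  # planted templated end, TT-local
    read_tail: np.ndarray  # A-tail length per read

    @property
    def total_mapped_reads(self) -> int:
        return len(self.reads)

    def write_outputs(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta({self.layout.construct_id: self.construct_seq},
                    outdir / "construct.fa")
        write_sam(self.reads, self.layout, outdir / "race_reads.sam")
        with open(outdir / "read_truth.tsv", "w") as fh:
            fh.write("read_id\tcluster_index\tend_tt\ttail_length\n")
            for i in range(len(self.reads)):
                fh.write(f"{self.reads[i].read_id}\t{self.read_cluster[i]}\t"
                         f"{self.read_end_tt[i]}\t{self.read_tail[i]}\n")


def simulate_race_reads(truth: SyntheticTruth, n_reads: int = 50_000,
                        tail_length_range: tuple[int, int] = (8, 30),
                        read_length: int = 80, seed: int = 0) -> SimulatedRace:
    """Simulate aligned 3'-RACE amplicon reads from a designed terminator.

    Each read's templated 3' end is drawn from a planted cluster
    (multinomial over the plan weights) and jittered uniformly within the
    cluster's spread; an untemplated A-tail of uniform length in
    ``tail_length_range`` is appended and appears in the alignment as a
    trailing soft clip.  The construct reference is the terminator preceded
    by ``read_length + 19`` nt of reporter context, so TT-local 1 is
    reference position ``read_length + 20``.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be > 0")
    plan = truth.plan
    pad = read_length + 20  # reporter context; reporter CDS ends at `pad`
    ss = np.random.SeedSequence(seed)
    rng_pad, rng_cluster, rng_jitter, rng_tail = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )
    # Reporter context shares the TT background composition except that its
    # last base is the TT's first base (TT-local 1 = last reporter base).
    context = "".join(_draw_background(rng_pad, pad - 1, plan.background))
    construct = context + truth.sequence
    layout = ConstructLayout(
        construct_id=plan.tt_id,
        reference_length=len(construct),
        reporter_cds_end=pad,
        tt_length=plan.tt_length,
    )

    weights = np.array([c.weight for c in plan.clusters], dtype=float)
    centers = np.array([c.center for c in plan.clusters])
    jitters = np.array([c.jitter for c in plan.clusters])
    cluster_idx = rng_cluster.choice(len(weights), size=n_reads, p=weights)
    j = jitters[cluster_idx]
    offsets = rng_jitter.integers(-j, j + 1)
    end_tt = centers[cluster_idx] + offsets
    lo, hi = tail_length_range
    tails = rng_tail.integers(lo, hi + 1, size=n_reads)

    reads = []
    for i in range(n_reads):
        ref_end = pad + int(end_tt[i]) - 1  # 1-based last templated base
        ref_start = max(1, ref_end - read_length + 1)
        reads.append(
            AlignedRead(
                read_id=f"race_{i}",
                reference_id=plan.tt_id,
                alignment_strand="+",
                reference_start=ref_start - 1,
                reference_end=ref_end,
                trailing_clip_seq="A" * int(tails[i]),
                mapping_quality=42,
            )
        )
    return SimulatedRace(
        truth=truth, layout=layout, construct_seq=construct, reads=reads,
        read_cluster=cluster_idx, read_end_tt=end_tt, read_tail=tails,
    )


def simulate_srna(region: Region, mode: str, n_reads: int,
                  antisense_fraction: float = 0.0,
                  length_profile: Optional[dict[int, float]] = None,
                  seed: int = 0) -> list[AlignedRead]:
    """Simulate aligned small-RNA reads over a transgene region.

    ``mode="clean"`` emits only sense-strand reads (no silencing);
    ``mode="silenced"`` emits each read on the antisense strand with
    probability ``antisense_fraction``.  Read lengths are drawn from
    ``length_profile`` over 21-24 nt (uniform by default) and start positions
    uniformly such that reads fit inside the region.
    """
    if mode not in ("clean", "silenced"):
        raise ValueError(f"mode must be 'clean' or 'silenced', got {mode!r}")
    if mode == "clean" and antisense_fraction > 0:
        raise ValueError("antisense_fraction must be 0 in clean mode")
    if mode == "silenced" and not 0 < antisense_fraction <= 1:
        raise ValueError("silenced mode needs antisense_fraction in (0, 1]")
    if length_profile is None:
        length_profile = {n: 0.25 for n in (21, 22, 23, 24)}
    lengths = np.array(sorted(length_profile))
    probs = np.array([length_profile[n] for n in lengths], dtype=float)
    probs /= probs.sum()

    ss = np.random.SeedSequence(seed)
    rng_len, rng_pos, rng_strand = (np.random.default_rng(s) for s in ss.spawn(3))
    read_len = rng_len.choice(lengths, size=n_reads, p=probs)
    max_start = region.end - read_len  # exclusive upper bound for 0-based start
    starts = rng_pos.integers(region.start, np.maximum(region.start + 1, max_start + 1))
    if mode == "silenced":
        antisense = rng_strand.random(n_reads) < antisense_fraction
    else:
        antisense = np.zeros(n_reads, dtype=bool)
    sense_strand = region.strand
    anti_strand = "-" if sense_strand == "+" else "+"
    return [
        AlignedRead(
            read_id=f"srna_{i}",
            reference_id=region.reference_id,
            alignment_strand=anti_strand if antisense[i] else sense_strand,
            reference_start=int(starts[i]),
            reference_end=int(starts[i] + read_len[i]),
            mapping_quality=42,
        )
        for i in range(n_reads)
    ]


def write_sam(reads: Sequence[AlignedRead], layout: ConstructLayout,
              path: str | Path) -> None:
    """Write simulated alignments as SAM (trailing clips become soft clips)."""
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": layout.construct_id, "LN": layout.reference_length}],
    }
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read in reads:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = read.read_id
            seg.reference_id = 0
            seg.reference_start = read.reference_start
            seg.mapping_quality = read.mapping_quality
            seg.flag = 16 if read.alignment_strand == "-" else 0
            aligned = read.span_length
            lead, trail = read.leading_clip_seq, read.trailing_clip_seq
            cigar = ""
            if lead:
                cigar += f"{len(lead)}S"
            cigar += f"{aligned}M"
            if trail:
                cigar += f"{len(trail)}S"
            seg.cigarstring = cigar
            seg.query_sequence = lead + "N" * aligned + trail
            out.write(seg)


def default_plan(seed: int = 0, tt_id: str = "synthTT") -> TerminatorPlan:
    """A maize-polyubiquitin-style terminator plan.

    Two cleavage clusters inside the first 335 nt of the terminator with a
    dominant site near position 195 (weight 0.8) carrying a composite
    AUGAAUAAG signal 20 nt upstream, and a minor site at 280 (weight 0.2)
    with a canonical AAUAAA signal; one GC-rich stability motif downstream of
    the major site.
    """
    return TerminatorPlan(
        tt_id=tt_id,
        tt_length=335,
        clusters=(
            ClusterPlan(center=195, weight=0.8, jitter=3, dinucleotide="UA"),
            ClusterPlan(center=280, weight=0.2, jitter=3, dinucleotide="CA"),
        ),
        nue=(
            NuePlan(motif="AUGAAUAAG", distance=20, cluster_index=0),
            NuePlan(motif="AAUAAA", distance=18, cluster_index=1),
        ),
        fue=(
            FuePlan(motif="CGUGUCUU", offset=12, cluster_index=0),
        ),
        seed=seed,
    )
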