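"""One-command orchestration: profile -> cleavage -> signal scan -> report.

Runs the full terminator analysis for one or more constructs and renders a
machine-readable report in the layout of a per-terminator poly(A)-signal
table (terminator, unique sites, assigned PPSG with cleavage dinucleotides
in parentheses, member hexamers, NUE-survey rankings), alongside the raw
per-position RPM profile suitable for plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .cleavage_annotator import CleavageAnnotation, cleavage_dinucleotide
from .construct_io import (
    AlignedRead,
    ConstructLayout,
    load_layout,
    read_alignments,
    read_fasta,
    write_sites,
)
from .polya_profiler import (
    DEFAULT_CUTOFF_RPM,
    DEFAULT_GROUPING_WINDOW,
    SiteProfile,
    UniqueSite,
    accumulate_profile,
    call_peaks,
    cluster_unique_sites,
    extract_end_call,
    select_major_site,
)
from .signal_scanner import (
    NUE_WINDOW,
    CompositeMotif,
    FueHit,
    PPSGAssignment,
    TTSignalSummary,
    aggregate_stats,
    assign_ppsg,
    merge_composites,
    scan_fue,
    scan_window,
)

__all__ = ["AnalysisParams", "TTResult", "AnalysisBundle", "run_tt", "run_analysis",
           "render_table"]


@dataclass(frozen=True)
class AnalysisParams:
    """Every threshold the analysis uses, logged verbatim in the manifest."""

    cutoff_rpm: float = DEFAULT_CUTOFF_RPM
    grouping_window: int = DEFAULT_GROUPING_WINDOW
    nue_lo: int = NUE_WINDOW[0]
    nue_hi: int = NUE_WINDOW[1]
    fue_upstream: int = 150
    fue_downstream: int = 35
    min_tail_len: int = 5
    min_a_frac: float = 0.8


@dataclass
class TTResult:
    """All per-terminator outputs of one analysis run."""

    tt_id: str
    layout: ConstructLayout
    profile: SiteProfile
    sites: list[UniqueSite]
    major_site: Optional[UniqueSite]
    cleavage: list[CleavageAnnotation]  # one per unique site, site-ordered
    assignments: list[PPSGAssignment]  # one per unique site, site-ordered
    fue_hits: list[FueHit]  # around the major site
    n_end_calls: int
    skipped: dict


@dataclass
class AnalysisBundle:
    results: list[TTResult]
    aggregate: dict
    params: AnalysisParams

    def summaries(self) -> list[TTSignalSummary]:
        return [
            TTSignalSummary(
                tt_id=r.tt_id,
                unique_site_count=len(r.sites),
                ppsg_sequences=tuple(
                    a.composite.sequence for a in r.assignments if a.composite
                ),
            )
            for r in self.results
        ]


def run_tt(tt_id: str, construct_seq: str, layout: ConstructLayout,
           reads: Sequence[AlignedRead], params: AnalysisParams = AnalysisParams(),
           skipped: Optional[dict] = None) -> TTResult:
    """Run the full analysis chain for one construct.

    ``construct_seq`` is the full reference sequence; the terminator-local
    sequence is sliced from it via the layout.  ``reads`` are mapped reads
    only (use :func:`~term3race.construct_io.read_alignments` for SAM input).
    """
    if not reads:
        raise ValueError(f"{tt_id}: no mapped reads")
    tt_seq = construct_seq[layout.reporter_cds_end - 1: layout.tt_end_reference]
    calls = [
        c for c in (
            extract_end_call(r, layout, min_tail_len=params.min_tail_len,
                             min_a_frac=params.min_a_frac)
            for r in reads
        ) if c is not None
    ]
    profile = accumulate_profile(calls, layout, total_mapped_reads=len(reads))
    peaks = call_peaks(profile, cutoff_rpm=params.cutoff_rpm)
    sites = cluster_unique_sites(peaks, grouping_window=params.grouping_window)
    major = select_major_site(sites) if sites else None

    cleavage: list[CleavageAnnotation] = []
    assignments: list[PPSGAssignment] = []
    for site in sites:
        pos = site.representative_position
        cleavage.append(cleavage_dinucleotide(tt_seq, pos))
        hits = scan_window(tt_seq, pos, lo=params.nue_lo, hi=params.nue_hi)
        composites = merge_composites(hits, tt_seq)
        assignments.append(assign_ppsg(pos, composites, lo=params.nue_lo,
                                       hi=params.nue_hi))
    fue_hits = scan_fue(tt_seq, major.representative_position,
                        upstream_extent=params.fue_upstream,
                        downstream_extent=params.fue_downstream) if major else []
    return TTResult(
        tt_id=tt_id, layout=layout, profile=profile, sites=sites,
        major_site=major, cleavage=cleavage, assignments=assignments,
        fue_hits=fue_hits, n_end_calls=len(calls), skipped=skipped or {},
    )


def run_analysis(config: Mapping | str | Path,
                 outdir: Optional[str | Path] = None) -> AnalysisBundle:
    """Run the pipeline for every construct listed in a config.

    ``config`` is a mapping (or path to a YAML file) with optional
    ``params`` overrides and a ``constructs`` list; each construct entry
    supplies ``fasta``, ``layout`` (inline mapping or YAML path) and ``sam``.
    When ``outdir`` is given, all intermediate TSVs, the final table and a
    parameter manifest are written there.  The run is deterministic for
    identical inputs and parameters.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    params = AnalysisParams(**config.get("params", {}))
    entries = config.get("constructs", [])
    if not entries:
        raise ValueError("config lists no constructs")

    results = []
    for entry in entries:
        layout_spec = entry["layout"]
        if isinstance(layout_spec, (str, Path)):
            with open(layout_spec) as fh:
                layout_spec = yaml.safe_load(fh)
        layout = load_layout(layout_spec)
        seqs = read_fasta(entry["fasta"])
        if layout.construct_id not in seqs:
            raise ValueError(
                f"construct {layout.construct_id} not in FASTA {entry['fasta']}"
            )
        reads, skipped = read_alignments(entry["sam"])
        reads = [r for r in reads if r.reference_id == layout.construct_id]
        try:
            results.append(run_tt(layout.construct_id, seqs[layout.construct_id],
                                  layout, reads, params, skipped=skipped))
        except ValueError as exc:
            raise ValueError(f"stage failure for {layout.construct_id}: {exc}") from exc

    summaries = [
        TTSignalSummary(
            tt_id=r.tt_id,
            unique_site_count=len(r.sites),
            ppsg_sequences=tuple(a.composite.sequence for a in r.assignments
                                 if a.composite),
        )
        for r in results
    ]
    aggregate = aggregate_stats(summaries) if any(s.unique_site_count for s in summaries) \
        else {"n_tts": len(summaries), "n_unique_sites": 0}
    bundle = AnalysisBundle(results=results, aggregate=aggregate, params=params)
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def render_table(bundle: AnalysisBundle) -> pd.DataFrame:
    """Render the per-terminator poly(A)-signal table.

    One row per (terminator, assigned PPSG), site-ordered, with the cleavage
    dinucleotides of the member sites in parentheses after the signal string;
    sites with no assignable signal are reported with an empty signal.
    """
    rows = []
    for res in bundle.results:
        for site, ann, assignment in zip(res.sites, res.cleavage, res.assignments):
            comp = assignment.composite
            rows.append({
                "tt_id": res.tt_id,
                "unique_site_count": len(res.sites),
                "site_position": site.representative_position,
                "is_major": site.is_major,
                "ppsg": f"{comp.sequence}({ann.dinucleotide})" if comp else "",
                "ppsg_class": comp.classification if comp else "none",
                "distance": assignment.distance if comp else "",
                "contains_AUGAAU": comp.contains_AUGAAU if comp else False,
                "member_hexamers": ";".join(h.hexamer.sequence for h in comp.members)
                if comp else "",
                "rankings": ";".join(h.hexamer.rank_display() for h in comp.members)
                if comp else "",
            })
    return pd.DataFrame(
        rows,
        columns=["tt_id", "unique_site_count", "site_position", "is_major", "ppsg",
                 "ppsg_class", "distance", "contains_AUGAAU", "member_hexamers",
                 "rankings"],
    )


def profile_plot_data(bundle: AnalysisBundle) -> pd.DataFrame:
    """Long-form RPM-vs-position track for plotting per-terminator profiles."""
    rows = [
        {"tt_id": res.tt_id, "tt_position": pos, "raw_count": res.profile.raw_counts[pos],
         "rpm": res.profile.rpm[pos]}
        for res in bundle.results
        for pos in sorted(res.profile.rpm)
    ]
    return pd.DataFrame(rows, columns=["tt_id", "tt_position", "raw_count", "rpm"])


def write_bundle(bundle: AnalysisBundle, outdir: str | Path) -> None:
    """Write all bundle outputs (TSVs, table, manifest) under ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for res in bundle.results:
        write_sites(res.sites, res.layout, outdir / f"{res.tt_id}.sites.bed",
                    outdir / f"{res.tt_id}.sites.tsv")
    cleavage_rows = [
        {"tt_id": res.tt_id, "site_position": ann.site_position,
         "dinucleotide": ann.dinucleotide, "is_canonical_YA": ann.is_canonical_YA}
        for res in bundle.results for ann in res.cleavage
    ]
    pd.DataFrame(cleavage_rows, columns=["tt_id", "site_position", "dinucleotide",
                                         "is_canonical_YA"]) \
        .to_csv(outdir / "cleavage.tsv", sep="\t", index=False)
    fue_rows = [
        {"tt_id": res.tt_id, "motif_kind": h.motif_kind, "sequence": h.sequence,
         "tt_start": h.tt_start, "relative_to_site": h.relative_to_site}
        for res in bundle.results for h in res.fue_hits
    ]
    pd.DataFrame(fue_rows, columns=["tt_id", "motif_kind", "sequence", "tt_start",
                                    "relative_to_site"]) \
        .to_csv(outdir / "fue.tsv", sep="\t", index=False)
    render_table(bundle).to_csv(outdir / "table_ppsg.tsv", sep="\t", index=False)
    profile_plot_data(bundle).to_csv(outdir / "profile_plot_data.tsv", sep="\t",
                                     index=False)
    pd.DataFrame([bundle.aggregate]).to_csv(outdir / "aggregate.tsv", sep="\t",
                                            index=False)
    manifest = {
        "term3race_version": __version__,
        "params": {k: getattr(bundle.params, k) for k in vars(bundle.params)},
        "n_constructs": len(bundle.results),
    }
    with open(outdir / "manifest.yml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
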