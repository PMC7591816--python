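# Methods

## Coordinate model

Every construct is a single reference sequence: reporter CDS followed by a
transcription terminator (TT). Reported coordinates are 1-based *TT-local*,
with position 1 at the last base of the reporter CDS — the convention used
for terminator poly(A) profiles, which keeps site positions comparable
across constructs that share a terminator but differ upstream. Internally
alignments use 0-based half-open intervals (the pysam convention); the two
conversions (`to_tt_coordinate` / `from_tt_coordinate`) are exact inverses
and are the only place the offset arithmetic lives. Reads whose called 3′
end falls upstream of TT-local 1 are discarded with a counter: 3′-RACE
primers anchor in the reporter 3′ exon, so such ends are artifacts.

Sequences are DNA internally; motifs and report strings are rendered as RNA
(T→U) at presentation, matching how poly(A) signals are written in the
literature.

## End calling

The 3′ end of a mapped read is its last *templated* base: for `+`
alignments the rightmost aligned reference base, for `−` alignments the
leftmost (the transcript 3′ end), with the candidate poly(A) tail taken
from the transcript-3′-side soft clip (reverse-complemented for `−`
alignments). A clip is accepted as tail evidence when it is ≥ 5 nt with
A-fraction ≥ 0.8; tail evidence is recorded but not required — input reads
may already be tail-trimmed, in which case evidence is simply 0. Insertions
at the junction do not move the end; deletions do not change the rightmost
aligned base. Secondary and supplementary alignments are excluded from
counting (the upstream aligner is expected to report one location per
read). Each SAM record contributes one end call; for paired-end amplicon
data the mate carrying the poly(A) junction should be supplied, since
counting both mates of a fragment would double-count.

## Profile, peaks, unique sites

End calls are summed per position (raw counts) and normalised to RPM:
`rpm[p] = raw[p] / total_mapped * 1e6`. The denominator is the number of
reads mapped to the construct; callers may substitute total library reads
by passing their own denominator. Positions with RPM ≥ 10,000 (inclusive —
the conventional reading of a cut-off) are peaks.

Plant polyadenylation machinery produces redundant cleavage positions, so
peaks within a grouping window are one *unique site*. Published practice
states only that sites within a 10–35 nt window group together;
single-linkage chaining under that rule could produce unbounded spans, so
the implementation uses a greedy seeded rule: repeatedly take the
highest-RPM unassigned peak as seed (ties → leftmost) and absorb all
unassigned peaks within ±35 nt of it. This is deterministic, independent of
input order, partitions the peak set, bounds any cluster span at 71 nt, and
makes the seed the cluster representative by construction. The window
default is 35 nt (the rice NUE bound); 30 nt suits an Arabidopsis-style
analysis. The unique site containing the global maximum single-position RPM
is flagged *major* (ties → leftmost).

## Cleavage dinucleotide

The cleavage context is the last two templated bases, positions
(site−1, site), classified against the plant YA consensus (CA/UA). Two-base
context is required; a site at position 1 has none and is an error. The
distribution table reports fractions over whichever site set the caller
supplies (unique-site representatives by default in the pipeline; callers
may annotate all within-cluster positions instead, and should label which).

## NUE scanning and composite signals

The NUE window of a site is `[site−35, site−10]`. A catalog hexamer counts
as a hit when any of its six bases overlaps the window; its distance is
measured from its 3′-most base to the site (this convention matches how
signal-to-site distances such as "14 nt upstream" are quoted; it is
configurable). The catalog (packaged TSV) holds 16 hexamers in three
classes — canonical (AAUAAA), AAUAAA-like, NUE-enriched — each with its
rice rank and two Arabidopsis ranking figures from the genome-wide NUE
surveys, stored verbatim; rank 0 means "not listed" and is never compared
numerically. AAUGAC is deliberately excluded: it does not occur in rice or
Arabidopsis NUEs.

Hits whose spans overlap by ≥ 1 nt merge transitively into *composite*
motifs; adjacency without overlap does not merge. The composite sequence is
read off the terminator over the union span, so it always equals the
left-to-right maximal-overlap chain of its position-sorted members
(`chain_merge`, a fold of `max_overlap_merge`; the merge uses maximal
*proper* suffix-prefix overlap, so merging a motif with itself yields the
tandem form, e.g. AUGAAU+AUGAAU → AUGAAUGAAU). One signal per site is then
assigned: canonical > AAUAAA-like > NUE-enriched, nearest composite first
within a class. The priority rule reflects how signals are named in
practice — A-richness/proximity arguments are invoked only when no
canonical or like motif is present. A site with no composite in its window
gets assignment "none" (signal ambiguous); aggregate statistics report the
assigned fraction as an integer percentage (round-half-up).

The scanner reports *all* catalog members of a composite, including
hexamers that arise only as internal substrings of an overlap (e.g. GAAUAA
inside AUGAAUAAG); published member lists sometimes name only the motifs
considered meaningful, so tests distinguish the listed subset from the full
recovered set.

## FUE and URE

Two generic pattern families are scanned rather than a fixed motif list:
GC-rich stability motifs `CGUGUCNN` anywhere within −150…+35 nt of the
site, and the U-rich FUE repeat `UUUGUA` with ≤ 1 mismatch within the
150-nt upstream extent (both extents and the mismatch tolerance are
parameters). Offsets are signed, motif start relative to the site.
U-content of the ±10 nt cleavage-element flanks is reported separately.

## sRNA silencing screen

Reads overlapping a region by ≥ 1 nt are split by strand relative to the
transgene transcript strand; RPM uses the total genome-matched read count.
Length histograms cover 18–30 nt (others binned). The silencing signature —
antisense 21–24 nt siRNA — is qualitative in the literature ("no antisense
siRNA"); the implementation introduces a quantitative default, antisense
RPM strictly > 5, and always reports the raw RPM and the 21–24 nt antisense
fraction so the call is auditable. Multimapper resolution is left to the
aligner (one reported location per read); the pipeline consumes SAM as
given.

## Synthetic data

The generator emulates the study conditions the pipeline targets. A
terminator plan places cleavage clusters (center, multinomial weight,
jitter, planted YA dinucleotide), NUE motifs at a stated 3′-base distance
upstream of their cluster, and FUE motifs at signed offsets, on an AU-rich
background (A 0.30, U 0.30, C 0.20, G 0.20 — typical of plant 3′ UTRs).
Accidental catalog hexamers inside any cluster's NUE scan region are
removed by resampling background bases (planted bases are never touched);
the rest of the sequence is not policed, since only NUE windows feed the
scanner. Defaults: ±3 nt redundant-cleavage jitter, 335–450 nt terminators
with all sites within ~300 nt of the reporter end, A-tails 8–30 nt,
read length 80 nt, 50,000 reads per library — sizes at which every planted
cluster of weight ≥ 0.05 clears the 10,000-RPM cutoff in expectation with
wide margin. sRNA simulations emit 21–24 nt reads, strand-pure sense in
"clean" mode and Bernoulli-antisense at a stated fraction in "silenced"
mode. All randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning, so sub-streams are independent and
runs are exactly reproducible; alignments are emitted directly (positions
are known by construction), so no aligner is needed anywhere in the tests.

What the simulator does *not* model — sequencing error, PCR duplication,
internal priming on genomic A-stretches, non-uniform within-cluster
cleavage preference — bounds what round-trip tests show: they validate the
counting, clustering, classification and scanning logic under clean
conditions, not robustness to those artifacts on real libraries. In
particular, with uniform jitter the cluster representative is any position
in the jitter span, so cleavage-dinucleotide round trips use zero jitter,
and real internal-priming artifacts would require a filter this pipeline
deliberately does not include.

## Numerical and degenerate-input choices

RPM cutoff boundary inclusive; silencing threshold strictly greater-than;
clustering ties (equal RPM) break leftmost at both seeding and major-site
selection; empty peak lists produce empty site lists (and "no sites" in
reports) but an empty *input* (zero mapped reads, zero total) is an error;
window scans truncate silently at the sequence start; percentage rounding
is half-up. The acceptance-style round-trip checks run at 50,000 reads ×
30 replicates and 1,000 random 300-nt sequences for the scanner oracle —
sizes chosen so the statistical assertions are decisive while the whole
suite stays interactive.

## Known limitations

No replicate-merging statistics, no peak-shape modelling, no
internal-priming filter, no machine-learned signal models, and no
genome-wide hexamer re-ranking (survey ranks are taken as given, including
two Arabidopsis ranking figures stored verbatim without interpretation).
The paired-end ambiguity (which mate carries the junction) is resolved
upstream by the caller's SAM preparation.
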