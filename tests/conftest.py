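"""Shared fixtures: published per-terminator signal-table rows and helpers."""

from __future__ import annotations

import pytest

from term3race.construct_io import ConstructLayout
from term3race.synthetic_data import (
    ClusterPlan,
    NuePlan,
    TerminatorPlan,
    design_tt,
    simulate_race_reads,
)

# Per-terminator poly(A)-signal annotations for the eight study terminators:
# (tt_id, unique poly(A) site count, [(PPSG string, listed member hexamers)]).
# Two of the printed composites additionally contain GAAUAA as an unlisted
# internal catalog hexamer; EXPECTED_EXTRA_MEMBERS records that.
TABLE1 = [
    ("StPinII", 1, [("GAAUAAA", {"AAUAAA", "GAAUAA"})]),
    ("SiUbi2", 2, [("AAUGAAUAAAU", {"AAUGAA", "AUGAAU", "AAUAAA", "AUAAAU"})]),
    ("BdUbi1", 2, [("AUGAAUAAG", {"AUGAAU", "AAUAAG"})]),
    ("BdUbi1-C", 3, [("GAAGAA", {"GAAGAA"}),
                     ("AUGAAUAAG", {"AUGAAU", "AAUAAG"})]),
    ("ZmUbi1", 2, [("AUGAAUAAG", {"AUGAAU", "AAUAAG"}),
                   ("UGAAAUUAA", {"UGAAAU", "AAUUAA"})]),
    ("AtELF1", 3, [("AAUCAAAGGA", {"AAUCAA", "AAAGGA"}),
                   ("AUGAAUGAA", {"AUGAAU", "GAAUGA", "AAUGAA"})]),
    ("AtUBC9", 3, [("UAUAAAAUUU", {"UAUAAA", "AAAUUU"}),
                   ("AAGAAA", {"AAGAAA"})]),
    ("AtUbi10", 2, [("AUGAAUAAG", {"AUGAAU", "AAUAAG"}),
                    ("ACAAGU", {"ACAAGU"})]),
]

EXPECTED_EXTRA_MEMBERS = {
    "AAUGAAUAAAU": {"GAAUAA"},
    "AUGAAUAAG": {"GAAUAA"},
}

MONOCOT_UBQ_TTS = {"ZmUbi1", "BdUbi1", "BdUbi1-C", "SiUbi2"}


@pytest.fixture(scope="session")
def table1_rows():
    return TABLE1


@pytest.fixture
def layout_1000():
    """A ZmUbi1-style layout: reporter CDS ends at reference 1000, 910-nt TT."""
    return ConstructLayout(construct_id="ZmUbi1", reference_length=2000,
                           reporter_cds_end=1000, tt_length=910)


def two_cluster_plan(seed: int, jitter: int = 3) -> TerminatorPlan:
    """Two well-separated cleavage clusters with planted signals."""
    return TerminatorPlan(
        tt_id=f"tt_seed{seed}",
        tt_length=400,
        clusters=(
            ClusterPlan(center=195, weight=0.75, jitter=jitter, dinucleotide="UA"),
            ClusterPlan(center=300, weight=0.25, jitter=jitter, dinucleotide="CA"),
        ),
        nue=(
            NuePlan(motif="AUGAAUAAG", distance=20, cluster_index=0),
            NuePlan(motif="AAUAAA", distance=18, cluster_index=1),
        ),
        seed=seed,
    )


@pytest.fixture(scope="session")
def simulated_run():
    """One designed terminator and a simulated 3'-RACE run (shared, read-only)."""
    truth = design_tt(two_cluster_plan(seed=11))
    sim = simulate_race_reads(truth, n_reads=20_000, seed=11)
    return truth, sim
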