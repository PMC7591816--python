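"""Cleavage-dinucleotide classification for poly(A) sites.

Plant pre-mRNA cleavage shows a YA consensus (Y = U or C) at the junction:
the last two templated bases before the untemplated tail.  This module
classifies each called site's dinucleotide and tabulates the distribution
across sites.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd

from .construct_io import to_rna

__all__ = [
    "CleavageAnnotation",
    "cleavage_dinucleotide",
    "dinucleotide_distribution",
    "CANONICAL_YA",
]

CANONICAL_YA = frozenset({"CA", "UA"})


@dataclass(frozen=True)
class CleavageAnnotation:
    site_position: int  # TT-local 1-based position of the last templated base
    dinucleotide: str  # RNA, e.g. "UA"
    is_canonical_YA: bool

    def __post_init__(self) -> None:
        if len(self.dinucleotide) != 2 or any(b not in "ACGU" for b in self.dinucleotide):
            raise ValueError(f"invalid dinucleotide {self.dinucleotide!r}")
        if self.is_canonical_YA != (self.dinucleotide in CANONICAL_YA):
            raise ValueError("is_canonical_YA inconsistent with dinucleotide")


def cleavage_dinucleotide(tt_sequence: str, site_position: int) -> CleavageAnnotation:
    """Annotate the cleavage dinucleotide of a poly(A) site.

    ``site_position`` is the 1-based TT-local position of the last templated
    base; the dinucleotide is the bases at ``site_position - 1`` and
    ``site_position``, rendered in the RNA alphabet.
    """
    if site_position < 2:
        raise ValueError(
            f"site_position={site_position}: need at least one base of upstream context"
        )
    if site_position > len(tt_sequence):
        raise ValueError(
            f"site_position={site_position} beyond sequence length {len(tt_sequence)}"
        )
    dinuc = to_rna(tt_sequence[site_position - 2: site_position])
    return CleavageAnnotation(
        site_position=site_position,
        dinucleotide=dinuc,
        is_canonical_YA=dinuc in CANONICAL_YA,
    )


def dinucleotide_distribution(annotations: Sequence[CleavageAnnotation]) -> pd.DataFrame:
    """Tabulate cleavage dinucleotide fractions across sites.

    Returns a DataFrame with columns ``dinucleotide, count, fraction,
    is_canonical_YA`` sorted by descending fraction, then alphabetically.
    Fractions sum to 1 over any non-empty input.
    """
    if not annotations:
        raise ValueError("no cleavage annotations to tabulate")
    counts = Counter(a.dinucleotide for a in annotations)
    total = sum(counts.values())
    rows = [
        {
            "dinucleotide": dn,
            "count": n,
            "fraction": n / total,
            "is_canonical_YA": dn in CANONICAL_YA,
        }
        for dn, n in counts.items()
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["fraction", "dinucleotide"], ascending=[False, True]
    ).reset_index(drop=True)


def canonical_ya_fraction(annotations: Sequence[CleavageAnnotation]) -> float:
    """Fraction of sites cleaved at CA or UA."""
    if not annotations:
        raise ValueError("no cleavage annotations")
    return sum(a.is_canonical_YA for a in annotations) / len(annotations)
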