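"""Somatic point-mutation census in junction-abetting switch-region flanks.

For each called junction the donor-side and acceptor-side arm alignments are
walked outward from the junction; aligned columns are compared to the
germline base, substitutions counted, and the examined-base denominator
accumulated.  Microhomology columns belong to both germlines and are excluded
from numerator and denominator, as are gap columns and read-N columns.  The
window is anchored at the junction and capped at 506 examined bases; flanks
shorter than 48 examined bases are flagged not-included, mirroring the
48-506 nt stretches used for switch-region mutation calling.  Frequencies
are reported as raw change/base with no background-error correction.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import pandas as pd

from .junction_call import JunctionCall
from .refio import ReadRecord, SRegionRef

SIDE_DONOR = "donor"
SIDE_ACCEPTOR = "acceptor"

WINDOW_CAP = 506
WINDOW_MIN = 48


@dataclass(frozen=True)
class FlankCensus:
    """Substitution counts over the examined flank of one junction side."""

    read_id: str
    side: str
    examined_bases: int
    n_substitutions: int
    substitution_list: tuple[tuple[int, str, str], ...]
    included: bool

    def __post_init__(self) -> None:
        if self.n_substitutions > self.examined_bases:
            raise ValueError("substitutions cannot exceed examined bases")


def census_flank(
    read: ReadRecord,
    call: JunctionCall,
    side: str,
    donor: SRegionRef,
    acceptor: SRegionRef,
    window_cap: int = WINDOW_CAP,
    window_min: int = WINDOW_MIN,
) -> FlankCensus:
    """Count substitutions in one junction-abetting flank.

    Walks the arm alignment from the junction outward (donor side leftward,
    acceptor side rightward), skipping MH columns, gap columns and read-N
    columns, stopping after ``window_cap`` examined bases.  ``included`` is
    False when fewer than ``window_min`` bases could be examined.
    """
    if not call.qc_pass:
        raise ValueError(f"census requires a qc-passed call (read {read.id!r})")
    if side == SIDE_DONOR:
        arm, ref = call.donor_arm, donor
    elif side == SIDE_ACCEPTOR:
        arm, ref = call.acceptor_arm, acceptor
    else:
        raise ValueError(f"side must be 'donor' or 'acceptor', got {side!r}")
    if arm is None or arm.is_empty:
        raise ValueError(f"read {read.id!r}: no {side} arm alignment")

    assert call.read_break is not None
    mh_lo = call.read_break
    mh_hi = call.read_break + call.mh_len

    cols = list(arm.columns())
    if side == SIDE_DONOR:
        cols.reverse()  # junction-proximal first

    examined = 0
    subs: list[tuple[int, str, str]] = []
    for read_i, ref_j, op in cols:
        if examined >= window_cap:
            break
        if op != "M":
            continue  # gap columns: neither numerator nor denominator
        assert read_i is not None and ref_j is not None
        if mh_lo <= read_i < mh_hi:
            continue  # MH belongs to both germlines: excluded entirely
        rb = read.sequence[read_i]
        if rb == "N":
            continue
        gb = ref.sequence[ref_j]
        examined += 1
        if rb != gb:
            subs.append((read_i, gb, rb))

    subs.sort(key=lambda t: t[0])
    return FlankCensus(
        read_id=read.id,
        side=side,
        examined_bases=examined,
        n_substitutions=len(subs),
        substitution_list=tuple(subs),
        included=examined >= window_min,
    )


def pooled_frequency(censuses: Iterable[FlankCensus], side: str) -> float:
    """Pooled change/base for one side: sum of substitutions over the sum of
    examined bases across included censuses (pooled, not mean-of-ratios)."""
    included = [c for c in censuses if c.side == side and c.included]
    if not included:
        raise ValueError(f"no included censuses on side {side!r}")
    denom = sum(c.examined_bases for c in included)
    if denom == 0:
        raise ValueError("zero examined bases")
    return sum(c.n_substitutions for c in included) / denom


def per_sequence_mean_frequency(censuses: Iterable[FlankCensus], side: str) -> float:
    """Mean of per-sequence change/base ratios (reported alongside the pooled
    estimate; the two differ when examined windows vary in length)."""
    ratios = [
        c.n_substitutions / c.examined_bases
        for c in censuses
        if c.side == side and c.included and c.examined_bases > 0
    ]
    if not ratios:
        raise ValueError(f"no included censuses on side {side!r}")
    return sum(ratios) / len(ratios)


def mutation_count_distribution(
    censuses: Sequence[FlankCensus],
) -> tuple[dict[int, float], int]:
    """Proportion of sequences carrying k substitutions (the pie-chart
    distribution) and the total number of sequences (the pie-center value)."""
    included = [c for c in censuses if c.included]
    if not included:
        raise ValueError("mutation_count_distribution requires >= 1 included census")
    counts = Counter(c.n_substitutions for c in included)
    total = len(included)
    return {k: v / total for k, v in sorted(counts.items())}, total


def census_frame(censuses: Sequence[FlankCensus]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [c.read_id for c in censuses],
            "side": [c.side for c in censuses],
            "examined_bases": [c.examined_bases for c in censuses],
            "n_substitutions": [c.n_substitutions for c in censuses],
            "included": [c.included for c in censuses],
        }
    )
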