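"""Group-level summaries of junction calls and mutation censuses.

Mirrors how switch-junction studies report their libraries: unique junction
sequences only (exact-string deduplication), a fixed-size per-group subsample
(45 unique junctions per group is the convention this follows), violin-ready
microhomology length lists, percent of junctions carrying any microhomology,
and unpaired two-tailed Student t-tests between groups.  Means include
MH-zero junctions.  Raw p-values are reported; no multiple-comparison
adjustment is applied by default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .junction_call import JunctionCall
from .mutation_census import (
    FlankCensus,
    mutation_count_distribution,
    per_sequence_mean_frequency,
    pooled_frequency,
)
from .refio import ReadRecord, write_tsv


@dataclass(frozen=True)
class SideMutationSummary:
    side: str
    total_bases: int
    total_substitutions: int
    change_per_base: float
    per_sequence_mean: float
    count_distribution: Mapping[int, float]
    n_sequences: int


@dataclass(frozen=True)
class GroupSummary:
    group_label: str
    n_unique: int
    n_analyzed: int
    pct_with_mh: float
    mh_mean: float
    mh_min: int
    mh_max: int
    mh_values: tuple[int, ...]
    mutation_summaries: Mapping[str, SideMutationSummary] = field(default_factory=dict)


@dataclass(frozen=True)
class SubsampleResult:
    calls: tuple[JunctionCall, ...]
    exhausted: bool  # True when fewer calls were available than requested


def dedup_junctions(
    calls: Sequence[JunctionCall], reads: Sequence[ReadRecord]
) -> tuple[list[JunctionCall], int]:
    """One representative call per unique full read sequence (exact string
    identity; the first occurrence in input order is kept).  Returns the
    deduplicated calls and the number of duplicates removed."""
    seq_by_id = {r.id: r.sequence for r in reads}
    seen: set[str] = set()
    out: list[JunctionCall] = []
    removed = 0
    for call in calls:
        seq = seq_by_id.get(call.read_id)
        if seq is None:
            raise KeyError(f"call {call.read_id!r} has no matching read")
        if seq in seen:
            removed += 1
            continue
        seen.add(seq)
        out.append(call)
    return out, removed


def subsample(calls: Sequence[JunctionCall], n: int, seed: int) -> SubsampleResult:
    """Uniform sample of ``n`` calls without replacement, deterministic under
    ``seed``; input order is preserved among the sampled calls."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= len(calls):
        return SubsampleResult(calls=tuple(calls), exhausted=n > len(calls))
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(calls), size=n, replace=False).tolist())
    return SubsampleResult(calls=tuple(calls[i] for i in idx), exhausted=False)


def _side_summary(censuses: Sequence[FlankCensus], side: str) -> Optional[SideMutationSummary]:
    included = [c for c in censuses if c.side == side and c.included]
    if not included:
        return None
    dist, total = mutation_count_distribution(included)
    return SideMutationSummary(
        side=side,
        total_bases=sum(c.examined_bases for c in included),
        total_substitutions=sum(c.n_substitutions for c in included),
        change_per_base=pooled_frequency(included, side),
        per_sequence_mean=per_sequence_mean_frequency(included, side),
        count_distribution=dist,
        n_sequences=total,
    )


def summarize_group(
    calls: Sequence[JunctionCall],
    censuses: Sequence[FlankCensus] = (),
    label: str = "",
    n_unique: Optional[int] = None,
) -> GroupSummary:
    """Microhomology and mutation statistics over one group of analyzed calls.

    Means include zero-MH junctions; pct_with_mh is the percentage of calls
    with mh_len >= 1."""
    if not calls:
        raise ValueError("summarize_group requires >= 1 call")
    mh = [c.mh_len for c in calls]
    summaries = {}
    for side in ("donor", "acceptor"):
        s = _side_summary(censuses, side)
        if s is not None:
            summaries[side] = s
    return GroupSummary(
        group_label=label,
        n_unique=n_unique if n_unique is not None else len(calls),
        n_analyzed=len(calls),
        pct_with_mh=100.0 * sum(1 for v in mh if v >= 1) / len(mh),
        mh_mean=float(np.mean(mh)),
        mh_min=int(min(mh)),
        mh_max=int(max(mh)),
        mh_values=tuple(mh),
        mutation_summaries=summaries,
    )


def compare_groups(
    a: Sequence[float], b: Sequence[float], welch: bool = False
) -> tuple[float, float]:
    """Unpaired two-tailed t-test.

    Default is the classical Student test with pooled variance and
    df = n_a + n_b - 2; ``welch=True`` switches to the unequal-variance
    variant.  Groups with zero pooled variance are degenerate."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    ss = ((a - a.mean()) ** 2).sum() + ((b - b.mean()) ** 2).sum()
    if ss == 0:
        raise ValueError("degenerate groups: zero pooled variance")
    t, p = stats.ttest_ind(a, b, equal_var=not welch)
    return float(t), float(p)


def violin_frame(groups: Sequence[GroupSummary]) -> pd.DataFrame:
    rows = [(g.group_label, v) for g in groups for v in g.mh_values]
    return pd.DataFrame(rows, columns=["group", "mh_len"])


def write_violin(groups: Sequence[GroupSummary], path: str | Path) -> Path:
    path = Path(path)
    write_tsv(violin_frame(groups), path)
    return path


def _summary_dict(g: GroupSummary) -> dict:
    d = asdict(g)
    d["mh_values"] = list(g.mh_values)
    d["mutation_summaries"] = {
        side: {**asdict(s), "count_distribution": {str(k): v for k, v in s.count_distribution.items()}}
        for side, s in g.mutation_summaries.items()
    }
    return d


def write_report(
    groups: Sequence[GroupSummary],
    comparisons: Mapping[str, tuple[float, float]],
    path: str | Path,
    config_echo: Optional[Mapping] = None,
) -> Path:
    """Emit the run report: group summaries, pairwise comparisons (t, p),
    config echo and software version, as deterministic JSON."""
    from . import __version__

    payload = {
        "software": {"name": "sxjunction", "version": __version__},
        "groups": [_summary_dict(g) for g in groups],
        "comparisons": {k: {"t": t, "p": p} for k, (t, p) in comparisons.items()},
        "config": dict(config_echo) if config_echo else {},
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path
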