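"""Ground-truthed junction amplicon simulation.

Generates two-segment reads (donor switch-region prefix + acceptor suffix)
with an exactly realized junctional microhomology (MH) drawn from a
configurable distribution, optional untemplated insertions, AID-style point
substitutions in the junction-abetting flanks (with an optional WRC/GYW
hotspot multiplier) and uniform sequencing error.  Every read carries a
ground-truth record so each analysis stage can be scored against the truth.

The requested MH is realized *exactly*: breakpoint pairs are chosen such that
the junction window matches both germline continuations for exactly r bases
and mismatches at both extensions (maximality).  Without this enforcement,
accidental longer homology at the join would corrupt the ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .refio import ReadRecord, SRegionRef, write_fasta, write_fastq, write_tsv

_BASES = "ACGT"


class SimulationError(RuntimeError):
    """Raised when a dataset cannot be simulated under the given config."""


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated junction library.

    Defaults emulate an Smu-sigma-delta style library: ~300 bp merged
    amplicon reads, every junction carrying a 2-13 nt microhomology, and
    flank point-substitution rates of order 1e-2 change/base.
    """

    n_reads: int = 1000
    read_length: int = 300
    mh_distribution: Mapping[int, float] = field(
        default_factory=lambda: {r: 1.0 / 12 for r in range(2, 14)}
    )
    insertion_distribution: Mapping[int, float] = field(default_factory=lambda: {0: 1.0})
    mutation_rate: float = 0.01
    hotspot_multiplier: float = 1.0
    seq_error_rate: float = 0.0
    seed: int = 0
    intra_deletion_mode: bool = False
    min_deletion: int = 20

    def __post_init__(self) -> None:
        if self.n_reads < 0:
            raise ValueError("n_reads must be >= 0")
        if self.read_length < 30:
            raise ValueError("read_length too short")
        for name, dist in (
            ("mh_distribution", self.mh_distribution),
            ("insertion_distribution", self.insertion_distribution),
        ):
            if not dist:
                raise ValueError(f"{name} must be non-empty")
            if any(k < 0 or p < 0 for k, p in dist.items()):
                raise ValueError(f"{name}: lengths and probabilities must be >= 0")
            if abs(sum(dist.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} probabilities must sum to 1")
        for name, rate in (
            ("mutation_rate", self.mutation_rate),
            ("seq_error_rate", self.seq_error_rate),
        ):
            if not 0.0 <= rate <= 0.2:
                raise ValueError(f"{name} must lie in [0, 0.2]")
        if self.hotspot_multiplier < 0:
            raise ValueError("hotspot_multiplier must be >= 0")
        if self.intra_deletion_mode and self.min_deletion <= 0:
            raise ValueError("min_deletion must be positive")

    @classmethod
    def from_json(cls, path: str | Path) -> "SimConfig":
        raw = json.loads(Path(path).read_text())
        for key in ("mh_distribution", "insertion_distribution"):
            if key in raw:
                raw[key] = {int(k): float(v) for k, v in raw[key].items()}
        return cls(**raw)


@dataclass(frozen=True)
class SimTruth:
    """Ground truth for one simulated read.

    donor_break / acceptor_break use the canonical representation where the
    donor arm is maximally extended: read locally equals
    donor[:donor_break] + insertion + acceptor[acceptor_break:].
    """

    read_id: str
    donor_break: int
    acceptor_break: int
    mh_len: int
    insertion_seq: str
    mutation_positions: tuple[tuple[int, str, str], ...]
    error_positions: tuple[tuple[int, str, str], ...]

    def __post_init__(self) -> None:
        if self.mh_len < 0:
            raise ValueError("mh_len must be >= 0")
        if self.mh_len > 0 and self.insertion_seq:
            raise ValueError("a read cannot carry both MH > 0 and an insertion")


# ---------------------------------------------------------------------------
# synthetic references
# ---------------------------------------------------------------------------

SWITCH_MOTIFS = ("AGCTGAGCTG", "GAGCT", "GGGCT", "GGGGAGCT", "TGGGG")


def random_reference(name: str, role: str, length: int, rng: np.random.Generator) -> SRegionRef:
    """Uniform-random A/C/G/T reference (no repeat structure)."""
    seq = "".join(rng.choice(list(_BASES), size=length))
    return SRegionRef(name=name, sequence=seq, role=role)


def synthetic_switch_region(
    name: str,
    role: str,
    length: int,
    rng: np.random.Generator,
    motifs: Sequence[str] = SWITCH_MOTIFS,
    perturb: float = 0.05,
    spacer_prob: float = 0.3,
) -> SRegionRef:
    """Synthetic stand-in for a germline switch region.

    Concatenates short AGCT-family repeat motifs (the pentamer/decamer units
    that dominate Smu and sigma-delta) with random point perturbations and
    occasional 1-3 nt random spacers.  The shared motif vocabulary between two
    such references makes long (>= 10 nt) junctional microhomologies
    realizable, as in real Smu/sigma-delta pairs, while the perturbations keep
    long-range contexts unique.  This is a synthetic sequence, not a genomic
    accession; analyses of real data must supply user-provided references.
    """
    parts: list[str] = []
    total = 0
    while total < length:
        unit = list(motifs[int(rng.integers(len(motifs)))])
        for i in range(len(unit)):
            if rng.random() < perturb:
                unit[i] = _BASES[int(rng.integers(4))]
        parts.append("".join(unit))
        total += len(unit)
        if rng.random() < spacer_prob:
            k = int(rng.integers(1, 4))
            parts.append("".join(rng.choice(list(_BASES), size=k)))
            total += k
    return SRegionRef(name=name, sequence="".join(parts)[:length], role=role)


# ---------------------------------------------------------------------------
# breakpoint enumeration
# ---------------------------------------------------------------------------


def _valid_pair(d8: np.ndarray, a8: np.ndarray, d: int, a: int, r: int) -> bool:
    """True when (d, a) yields MH of exactly r for read = donor[:d]+acceptor[a:]."""
    if d - r < 0 or a - r < 0 or d > d8.size or a > a8.size:
        return False
    if r and not np.array_equal(d8[d - r : d], a8[a - r : a]):
        return False
    # maximality: no extension on either side may match
    if d - r - 1 >= 0 and a - r - 1 >= 0 and d8[d - r - 1] == a8[a - r - 1]:
        return False
    if d < d8.size and a < a8.size and d8[d] == a8[a]:
        return False
    return True


def enumerate_breakpoints_with_mh(
    donor: SRegionRef, acceptor: SRegionRef, r: int
) -> list[tuple[int, int]]:
    """All breakpoint pairs (d, a) whose junction has microhomology exactly r.

    A read assembled as donor[0:d] + acceptor[a:] then has brute-force maximal
    MH of exactly r: donor[d-r:d] == acceptor[a-r:a] and both one-base
    extensions mismatch.  Full enumeration; intended for modest reference
    sizes (the simulator samples pairs lazily for large references).
    """
    from .junction_call import encode

    if r < 0:
        raise ValueError("r must be >= 0")
    if r > min(len(donor), len(acceptor)):
        raise ValueError("r exceeds reference length")
    d8, a8 = encode(donor.sequence), encode(acceptor.sequence)
    out: list[tuple[int, int]] = []
    if r == 0:
        for d in range(0, d8.size + 1):
            for a in range(0, a8.size + 1):
                if _valid_pair(d8, a8, d, a, 0):
                    out.append((d, a))
        return out
    # index acceptor r-mers by end position
    index: dict[bytes, list[int]] = {}
    ab = a8.tobytes()
    for a in range(r, a8.size + 1):
        index.setdefault(ab[a - r : a], []).append(a)
    db = d8.tobytes()
    for d in range(r, d8.size + 1):
        for a in index.get(db[d - r : d], ()):
            if _valid_pair(d8, a8, d, a, r):
                out.append((d, a))
    return out


# ---------------------------------------------------------------------------
# mutation channel
# ---------------------------------------------------------------------------


def hotspot_mask(seq8: np.ndarray) -> np.ndarray:
    """Boolean mask of AID hotspot positions: C of WRC and G of GYW
    (W = A/T, R = A/G, Y = C/T)."""
    n = seq8.size
    mask = np.zeros(n, dtype=bool)
    A, C, G, T = 0, 1, 2, 3
    isW = (seq8 == A) | (seq8 == T)
    isR = (seq8 == A) | (seq8 == G)
    isY = (seq8 == C) | (seq8 == T)
    if n >= 3:
        # WRC: positions i >= 2 with seq[i]==C
        mask[2:] |= (seq8[2:] == C) & isR[1:-1] & isW[:-2]
        # GYW: positions i <= n-3 with seq[i]==G
        mask[:-2] |= (seq8[:-2] == G) & isY[1:-1] & isW[2:]
    return mask


def _mutate_masked(
    seq: str,
    rate: float,
    hotspot_multiplier: float,
    rng: np.random.Generator,
    eligible: Optional[np.ndarray] = None,
) -> tuple[str, list[tuple[int, str, str]]]:
    from .junction_call import encode

    s8 = encode(seq)
    n = s8.size
    p = np.full(n, rate, dtype=float)
    p[hotspot_mask(s8)] = min(1.0, rate * hotspot_multiplier)
    p[s8 >= 4] = 0.0  # never mutate N
    if eligible is not None:
        p[~eligible] = 0.0
    hit = rng.random(n) < p
    positions: list[tuple[int, str, str]] = []
    out = list(seq)
    for i in np.flatnonzero(hit):
        ref = seq[i]
        alts = [b for b in _BASES if b != ref]
        alt = alts[int(rng.integers(3))]
        out[i] = alt
        positions.append((int(i), ref, alt))
    return "".join(out), positions


def mutate_sequence(
    seq: str, rate: float, hotspot_multiplier: float, rng: np.random.Generator
) -> tuple[str, list[tuple[int, str, str]]]:
    """Independently substitute each position with probability ``rate``
    (times ``hotspot_multiplier`` at WRC/GYW positions, capped at 1); the
    substituted base is drawn uniformly from the three alternatives.
    Returns the mutated sequence and the sorted (pos, ref, alt) list."""
    if not 0.0 <= rate <= 0.2:
        raise ValueError("rate must lie in [0, 0.2]")
    return _mutate_masked(seq, rate, hotspot_multiplier, rng)


# ---------------------------------------------------------------------------
# dataset simulation
# ---------------------------------------------------------------------------


def _draw_from(dist: Mapping[int, float], rng: np.random.Generator) -> int:
    keys = sorted(dist)
    probs = np.array([dist[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return int(keys[int(rng.choice(len(keys), p=probs))])


def _sample_pair(
    d8: np.ndarray,
    a8: np.ndarray,
    r: int,
    lo_d: int,
    hi_d: int,
    lo_a: int,
    hi_a: int,
    rng: np.random.Generator,
    intra_min_del: Optional[int],
    cache: dict,
) -> Optional[tuple[int, int]]:
    """Sample one valid (d, a) pair with MH exactly r within the room bounds,
    uniformly over the valid set.  Rejection sampling for r <= 2 (dense),
    cached enumeration for r >= 3 (sparse)."""
    if lo_d > hi_d or lo_a > hi_a:
        return None
    if r <= 2:
        for _ in range(4000):
            d = int(rng.integers(lo_d, hi_d + 1))
            a = int(rng.integers(lo_a, hi_a + 1))
            if intra_min_del is not None and a - d < intra_min_del:
                continue
            if _valid_pair(d8, a8, d, a, r):
                return d, a
        return None
    key = (r, lo_d, hi_d, lo_a, hi_a, intra_min_del)
    if key not in cache:
        ab = a8.tobytes()
        index: dict[bytes, list[int]] = {}
        for a in range(max(r, lo_a), hi_a + 1):
            index.setdefault(ab[a - r : a], []).append(a)
        db = d8.tobytes()
        pairs: list[tuple[int, int]] = []
        for d in range(max(r, lo_d), hi_d + 1):
            for a in index.get(db[d - r : d], ()):
                if intra_min_del is not None and a - d < intra_min_del:
                    continue
                if _valid_pair(d8, a8, d, a, r):
                    pairs.append((d, a))
        cache[key] = pairs
    pairs = cache[key]
    if not pairs:
        return None
    return pairs[int(rng.integers(len(pairs)))]


def simulate_reads(
    config: SimConfig, donor: SRegionRef, acceptor: SRegionRef
) -> tuple[list[ReadRecord], list[SimTruth], int]:
    """Simulate reads and their truth records.

    Returns (reads, truths, n_unrealizable): the number of MH/insertion draws
    that had no compatible breakpoint pair and were resampled.  Raises
    SimulationError when more than half of all draws are unrealizable.
    """
    from .junction_call import encode

    if config.intra_deletion_mode and donor.sequence != acceptor.sequence:
        raise SimulationError("intra_deletion_mode requires donor and acceptor to be the same region")
    rng = np.random.default_rng(config.seed)
    d8, a8 = encode(donor.sequence), encode(acceptor.sequence)
    L = config.read_length
    reads: list[ReadRecord] = []
    truths: list[SimTruth] = []
    cache: dict = {}
    unrealizable = 0
    draws = 0
    max_draws = max(1000, 20 * config.n_reads)
    intra_min = config.min_deletion if config.intra_deletion_mode else None

    for idx in range(config.n_reads):
        while True:
            draws += 1
            if draws > max_draws:
                raise SimulationError(
                    f"too many unrealizable draws ({unrealizable}/{draws}); "
                    "requested MH/insertion lengths are incompatible with the references"
                )
            r = _draw_from(config.mh_distribution, rng)
            ins_len = _draw_from(config.insertion_distribution, rng) if r == 0 else 0
            h_d = (L - ins_len) // 2  # donor bases in the read
            need_a = L - h_d - ins_len  # acceptor bases in the read
            if h_d < r:
                unrealizable += 1
                continue
            lo_d, hi_d = h_d, d8.size
            lo_a, hi_a = max(r, 0), a8.size - need_a
            pair = _sample_pair(d8, a8, r, lo_d, hi_d, lo_a, hi_a, rng, intra_min, cache)
            if pair is None:
                unrealizable += 1
                continue
            d, a = pair
            ins = ""
            if ins_len > 0:
                # the insertion must be untemplated at the junction: every base
                # must mismatch both the donor continuation and the acceptor
                # pre-context, else partial templating shifts the best-scoring
                # breakpoint and corrupts the ground truth
                ok = False
                for _ in range(200):
                    ins = "".join(rng.choice(list(_BASES), size=ins_len))
                    bad = False
                    for i in range(ins_len):
                        if d + i < d8.size and ins[i] == donor.sequence[d + i]:
                            bad = True
                            break
                        if a - ins_len + i >= 0 and ins[i] == acceptor.sequence[a - ins_len + i]:
                            bad = True
                            break
                    if not bad:
                        ok = True
                        break
                if not ok:
                    unrealizable += 1
                    continue
            s = d - h_d
            e = a + need_a
            core = donor.sequence[s:d] + ins + acceptor.sequence[a:e]
            assert len(core) == L
            if ins:
                # ground-truth uniqueness guarantee: the per-base edge checks
                # above cannot exclude shifted partial templating of the
                # insertion, so an assembled clean read may still admit an
                # equally- or better-scoring alternative junction explanation;
                # such draws are resampled
                from .junction_call import call_junction

                probe = call_junction(
                    ReadRecord(id="probe", sequence=core), donor, acceptor,
                    _skip_role_check=True,
                )
                if (
                    probe.donor_break,
                    probe.acceptor_break,
                    probe.mh_len,
                    probe.insertion_seq,
                ) != (d, a, r, ins):
                    unrealizable += 1
                    continue
            break
        jd = h_d  # junction position in the read (end of donor segment)
        eligible = np.ones(L, dtype=bool)
        eligible[jd - r : jd + ins_len] = False  # never mutate MH or insertion
        mutated, mut_pos = _mutate_masked(
            core, config.mutation_rate, config.hotspot_multiplier, rng, eligible
        )
        final, err_pos = _mutate_masked(mutated, config.seq_error_rate, 1.0, rng)
        read_id = f"sim{idx:06d}"
        reads.append(ReadRecord(id=read_id, sequence=final))
        truths.append(
            SimTruth(
                read_id=read_id,
                donor_break=d,
                acceptor_break=a,
                mh_len=r,
                insertion_seq=ins,
                mutation_positions=tuple(mut_pos),
                error_positions=tuple(err_pos),
            )
        )

    if draws and unrealizable / draws > 0.5:
        raise SimulationError(
            f"{unrealizable}/{draws} draws unrealizable (> 50%); "
            "the requested MH distribution does not fit these references"
        )
    return reads, truths, unrealizable


def _format_positions(positions: tuple[tuple[int, str, str], ...]) -> str:
    return ";".join(f"{p}:{ref}>{alt}" for p, ref, alt in positions)


def truth_frame(truths: Sequence[SimTruth]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "read_id": [t.read_id for t in truths],
            "donor_break": [t.donor_break for t in truths],
            "acceptor_break": [t.acceptor_break for t in truths],
            "mh_len": [t.mh_len for t in truths],
            "insertion_seq": [t.insertion_seq if t.insertion_seq else None for t in truths],
            "n_mutations": [len(t.mutation_positions) for t in truths],
            "mutation_positions": [_format_positions(t.mutation_positions) or None for t in truths],
            "n_errors": [len(t.error_positions) for t in truths],
        }
    )


def simulate_dataset(
    config: SimConfig,
    donor: SRegionRef,
    acceptor: SRegionRef,
    out_prefix: str | Path,
    fmt: str = "fasta",
) -> tuple[Path, Path]:
    """Simulate a dataset and write `<prefix>.fasta`/`.fastq` plus
    `<prefix>.truth.tsv`.  Fully reproducible from config.seed."""
    reads, truths, _ = simulate_reads(config, donor, acceptor)
    out_prefix = Path(out_prefix)
    out_prefix.parent.mkdir(parents=True, exist_ok=True)
    if fmt == "fasta":
        reads_path = out_prefix.with_suffix(".fasta")
        write_fasta(reads, reads_path)
    elif fmt == "fastq":
        reads_path = out_prefix.with_suffix(".fastq")
        write_fastq(reads, reads_path)
    else:
        raise ValueError(f"unknown format {fmt!r}")
    truth_path = Path(str(out_prefix) + ".truth.tsv")
    write_tsv(truth_frame(truths), truth_path)
    return reads_path, truth_path
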