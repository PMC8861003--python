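"""Breakpoint calling of S-S recombination junctions by two-arm local alignment.

Each amplicon read is modelled as a donor switch-region prefix joined to an
acceptor suffix, read = donor[0:d] + insertion + acceptor[a:].  The caller
scans every read split point, locally aligning the prefix against the donor
reference and the suffix against the acceptor reference (Smith-Waterman,
linear gaps), picks the split maximizing the summed arm score, exact-match
extends both arms toward the junction, and measures the junctional
microhomology (MH): the maximal junction-spanning read segment that matches
BOTH germline continuations perfectly.  Mismatches (and N) terminate MH.

Conventions:
- donor_break = donor coordinate at the maximal rightward donor extension
  (so donor[0:donor_break] is the longest donor-matching junction prefix);
- acceptor_break = the matching acceptor coordinate in the same
  representation, i.e. read == donor[0:donor_break] + acceptor[acceptor_break:]
  around the junction;
- read_break = the leftmost equivalent breakpoint on the read (start of the
  MH region), so the ambiguity interval is [read_break, read_break + mh + 1).

References are supplied in amplicon orientation (nested primers fix the
orientation); there is no reverse-complement search and no inversion calling.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional

import numpy as np

from .refio import ReadRecord, SRegionRef

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3, "N": 4}

# ASCII translation table: A,C,G,T -> 0..3, anything else (incl. N) -> 4
_TRANS = np.full(256, 4, dtype=np.uint8)
for _b, _c in _ENCODE.items():
    _TRANS[ord(_b)] = _c


def encode(seq: str) -> np.ndarray:
    """Encode DNA to uint8 codes (A,C,G,T -> 0..3, N -> 4; N never matches)."""
    return _TRANS[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@dataclass(frozen=True)
class Scoring:
    """Linear-gap local alignment scores (match > 0, mismatch < 0, gap < 0)."""

    match: int = 1
    mismatch: int = -2
    gap: int = -3

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap >= 0:
            raise ValueError("scoring requires match > 0, mismatch < 0, gap < 0")


@dataclass(frozen=True)
class AlignmentResult:
    """A local alignment of a read interval against a reference interval.

    cigar uses M (aligned column), I (read-only base, gap in reference),
    D (reference-only base, gap in read).  Score is recomputed from the
    counts under the scoring scheme in force.
    """

    read_interval: tuple[int, int]
    ref_interval: tuple[int, int]
    score: int
    n_matches: int
    n_mismatches: int
    n_gap_bases: int
    cigar: str

    @property
    def is_empty(self) -> bool:
        return self.read_interval[0] == self.read_interval[1] and self.n_matches == 0

    @property
    def identity(self) -> float:
        n_cols = self.n_matches + self.n_mismatches + self.n_gap_bases
        return self.n_matches / n_cols if n_cols else 0.0

    def columns(self) -> Iterator[tuple[Optional[int], Optional[int], str]]:
        """Yield (read_pos, ref_pos, op) per alignment column, left to right."""
        i, j = self.read_interval[0], self.ref_interval[0]
        num = ""
        for ch in self.cigar:
            if ch.isdigit():
                num += ch
                continue
            for _ in range(int(num)):
                if ch == "M":
                    yield i, j, "M"
                    i += 1
                    j += 1
                elif ch == "I":
                    yield i, None, "I"
                    i += 1
                elif ch == "D":
                    yield None, j, "D"
                    j += 1
                else:  # pragma: no cover
                    raise ValueError(f"bad cigar op {ch!r}")
            num = ""


_EMPTY_ALIGNMENT = AlignmentResult((0, 0), (0, 0), 0, 0, 0, 0, "")


def _sw_matrix(q8: np.ndarray, r8: np.ndarray, sc: Scoring) -> np.ndarray:
    """Full Smith-Waterman score matrix, linear gaps.

    The within-row horizontal dependency is resolved exactly by a running-max
    scan: H[i,j] = max_t A[j-t] + gap*t where A holds the diagonal/vertical/0
    candidates of row i.
    """
    n, m = q8.size, r8.size
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    offs = sc.gap * np.arange(m, dtype=np.int32)
    match, mismatch, gap = sc.match, sc.mismatch, sc.gap
    for i in range(1, n + 1):
        qi = q8[i - 1]
        sub = np.where((r8 == qi) & (qi < 4) & (r8 < 4), match, mismatch).astype(np.int32)
        a = np.maximum(H[i - 1, :m] + sub, H[i - 1, 1:] + gap)
        np.maximum(a, 0, out=a)
        H[i, 1:] = np.maximum.accumulate(a - offs) + offs
    return H


def _traceback(
    H: np.ndarray, q8: np.ndarray, r8: np.ndarray, sc: Scoring, i: int, j: int
) -> tuple[int, int, list[str]]:
    """Trace one optimal path back from cell (i, j); returns (read_start,
    ref_start, ops left-to-right).  Co-optimal moves prefer M, then D, then I
    (deterministic, biased toward small reference start)."""
    ops: list[str] = []
    while i > 0 and j > 0 and H[i, j] > 0:
        h = H[i, j]
        qi, rj = q8[i - 1], r8[j - 1]
        s = sc.match if (qi == rj and qi < 4 and rj < 4) else sc.mismatch
        if H[i - 1, j - 1] + s == h:
            ops.append("M")
            i -= 1
            j -= 1
        elif H[i, j - 1] + sc.gap == h:
            ops.append("D")
            j -= 1
        elif H[i - 1, j] + sc.gap == h:
            ops.append("I")
            i -= 1
        else:  # pragma: no cover - would indicate a DP inconsistency
            raise AssertionError("traceback failed")
    ops.reverse()
    return i, j, ops


def _ops_to_result(
    q8: np.ndarray,
    r8: np.ndarray,
    sc: Scoring,
    read_start: int,
    ref_start: int,
    ops: list[str],
) -> AlignmentResult:
    i, j = read_start, ref_start
    n_match = n_mis = n_gap = 0
    for op in ops:
        if op == "M":
            if q8[i] == r8[j] and q8[i] < 4:
                n_match += 1
            else:
                n_mis += 1
            i += 1
            j += 1
        elif op == "I":
            n_gap += 1
            i += 1
        else:
            n_gap += 1
            j += 1
    score = n_match * sc.match + n_mis * sc.mismatch + n_gap * sc.gap
    return AlignmentResult(
        read_interval=(read_start, i),
        ref_interval=(ref_start, j),
        score=score,
        n_matches=n_match,
        n_mismatches=n_mis,
        n_gap_bases=n_gap,
        cigar=_compress_ops(ops),
    )


def _compress_ops(ops: list[str]) -> str:
    out: list[str] = []
    i = 0
    while i < len(ops):
        j = i
        while j < len(ops) and ops[j] == ops[i]:
            j += 1
        out.append(f"{j - i}{ops[i]}")
        i = j
    return "".join(out)


_MAX_END_CELLS = 32


def _best_cells(H: np.ndarray, max_row: int, score: int) -> np.ndarray:
    """All cells (i, j) with i <= max_row achieving `score`, row-major order."""
    sub = H[: max_row + 1]
    cells = np.argwhere(sub == score)
    return cells[:_MAX_END_CELLS]


def local_align(query: str, ref: str, scoring: Scoring | None = None) -> AlignmentResult:
    """Optimal Smith-Waterman local alignment with linear gap penalties.

    Among co-optimal alignments, the one with the smallest reference start
    (then smallest read start) is returned.  If no positive-scoring pair of
    segments exists the empty alignment (score 0) is returned.
    """
    if not query or not ref:
        raise ValueError("local_align requires non-empty sequences")
    sc = scoring or Scoring()
    q8, r8 = encode(query), encode(ref)
    H = _sw_matrix(q8, r8, sc)
    smax = int(H.max())
    if smax == 0:
        return _EMPTY_ALIGNMENT
    best: Optional[AlignmentResult] = None
    best_key = None
    for i, j in _best_cells(H, q8.size, smax):
        rs, fs, ops = _traceback(H, q8, r8, sc, int(i), int(j))
        res = _ops_to_result(q8, r8, sc, rs, fs, ops)
        key = (res.ref_interval[0], res.read_interval[0])
        if best_key is None or key < best_key:
            best, best_key = res, key
    assert best is not None
    return best


# ---------------------------------------------------------------------------
# junction calling
# ---------------------------------------------------------------------------

CLASS_DIRECT = "direct"
CLASS_MH = "microhomology"
CLASS_INSERTION = "insertion"


@dataclass(frozen=True)
class CallParams:
    scoring: Scoring = field(default_factory=Scoring)
    min_arm_len: int = 15
    min_arm_identity: float = 0.90
    check_inversion: bool = True


@dataclass(frozen=True)
class JunctionCall:
    read_id: str
    qc_pass: bool
    reasons: tuple[str, ...]
    junction_class: str
    donor_break: Optional[int]
    acceptor_break: Optional[int]
    read_break: Optional[int]
    mh_len: int
    insertion_seq: str
    donor_arm: Optional[AlignmentResult]
    acceptor_arm: Optional[AlignmentResult]
    ambiguity_interval: Optional[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.mh_len > 0 and self.insertion_seq:
            raise ValueError("a junction cannot carry both microhomology and an insertion")
        if self.ambiguity_interval is not None:
            lo, hi = self.ambiguity_interval
            if hi - lo != self.mh_len + 1:
                raise ValueError("ambiguity interval size must equal mh_len + 1")


def _failed_call(read_id: str, reasons: tuple[str, ...]) -> JunctionCall:
    return JunctionCall(
        read_id=read_id,
        qc_pass=False,
        reasons=reasons,
        junction_class=CLASS_DIRECT,
        donor_break=None,
        acceptor_break=None,
        read_break=None,
        mh_len=0,
        insertion_seq="",
        donor_arm=None,
        acceptor_arm=None,
        ambiguity_interval=None,
    )


def _extend_right(q8: np.ndarray, r8: np.ndarray, qi: int, rj: int) -> tuple[int, int]:
    n, m = q8.size, r8.size
    while qi < n and rj < m and q8[qi] == r8[rj] and q8[qi] < 4:
        qi += 1
        rj += 1
    return qi, rj


def _extend_left(q8: np.ndarray, r8: np.ndarray, qi: int, rj: int) -> tuple[int, int]:
    while qi > 0 and rj > 0 and q8[qi - 1] == r8[rj - 1] and q8[qi - 1] < 4:
        qi -= 1
        rj -= 1
    return qi, rj


@dataclass
class _Candidate:
    mh_len: int
    insertion: str
    donor_break: int
    acceptor_break: int
    read_break: int
    De: int
    donor_arm: AlignmentResult
    acceptor_arm: AlignmentResult

    @property
    def sort_key(self):
        return (-self.mh_len, self.donor_break, self.acceptor_break, self.insertion)


def _walk_canonical(
    q8: np.ndarray, d8: np.ndarray, a8: np.ndarray, De: int, Dj: int, As: int, Aj: int, read: str
) -> tuple[int, str, int, int, int, int]:
    """Canonical junction from arm reaches; see _canonical_junction."""
    if De < As:
        return 0, read[De:As], Dj, Aj, De, De
    x = De
    while x - 1 >= As:
        p = x - 1
        dj = Dj - (De - p)  # donor coord of base aligned at read p
        aj = Aj + (p - As)  # acceptor coord of base aligned at read p
        b = q8[p]
        if dj >= 0 and b < 4 and b == d8[dj] and b == a8[aj]:
            x = p
        else:
            break
    mh = De - x
    return mh, "", Dj, Aj + (De - As), x, De


def call_junction(
    read: ReadRecord,
    donor: SRegionRef,
    acceptor: SRegionRef,
    params: CallParams | None = None,
    _skip_role_check: bool = False,
) -> JunctionCall:
    """Call the recombination breakpoint of one read.

    The read prefix is aligned to the donor reference and the suffix to the
    acceptor; the split maximizing the summed local-alignment score is chosen
    (ties resolved by larger microhomology, then leftmost donor break).  Arms
    are exact-match extended toward the junction and the microhomology is the
    maximal overlap matching both germline continuations.
    """
    params = params or CallParams()
    if not _skip_role_check:
        if donor.role != "donor":
            raise ValueError(f"reference {donor.name!r} has role {donor.role!r}, expected donor")
        if acceptor.role != "acceptor":
            raise ValueError(
                f"reference {acceptor.name!r} has role {acceptor.role!r}, expected acceptor"
            )
    n = len(read.sequence)
    if n < 2 * params.min_arm_len:
        return _failed_call(read.id, ("read_too_short",))

    sc = params.scoring
    q8 = encode(read.sequence)
    d8 = encode(donor.sequence)
    a8 = encode(acceptor.sequence)
    qr = q8[::-1].copy()
    ar = a8[::-1].copy()

    Hd = _sw_matrix(q8, d8, sc)
    Ha = _sw_matrix(qr, ar, sc)
    rowmax_d = Hd.max(axis=1)
    rowmax_a = Ha.max(axis=1)
    prefix_best = np.maximum.accumulate(rowmax_d)
    suffix_best_rev = np.maximum.accumulate(rowmax_a)
    # suffix_best[k] = best local score within read[k:]
    suffix_best = suffix_best_rev[::-1].copy()
    total = prefix_best.astype(np.int64) + suffix_best
    tmax = int(total.max())

    if int(prefix_best[-1]) == 0:
        return _failed_call(read.id, ("no_donor_arm",))
    if int(suffix_best[0]) == 0:
        return _failed_call(read.id, ("no_acceptor_arm",))

    if params.check_inversion:
        # would the swapped orientation (acceptor prefix + donor suffix) score
        # strictly better?  Then the read is acceptor-before-donor.
        Hx = _sw_matrix(q8, a8, sc)
        Hy = _sw_matrix(qr, d8[::-1].copy(), sc)
        pb = np.maximum.accumulate(Hx.max(axis=1))
        sb = np.maximum.accumulate(Hy.max(axis=1))[::-1]
        if int((pb.astype(np.int64) + sb).max()) > tmax:
            return _failed_call(read.id, ("inverted",))

    ks = np.flatnonzero(total == tmax)
    if ks.size > 64:
        sel = np.linspace(0, ks.size - 1, 64).astype(int)
        ks = ks[sel]

    candidates: list[_Candidate] = []
    fail_reasons: tuple[str, ...] = ()
    for k in ks:
        k = int(k)
        sd = int(prefix_best[k])
        sa = int(suffix_best[k])
        if sd == 0 or sa == 0:
            fail_reasons = fail_reasons or (("no_donor_arm",) if sd == 0 else ("no_acceptor_arm",))
            continue
        # donor arm: best cell in rows <= k; pick smallest (ref_start, read_start)
        d_cells = _best_cells(Hd, k, sd)
        best_d = None
        best_d_key = None
        for ci, cj in d_cells:
            rs, fs, ops = _traceback(Hd, q8, d8, sc, int(ci), int(cj))
            key = (fs, rs)
            if best_d_key is None or key < best_d_key:
                best_d = (rs, fs, ops, int(ci), int(cj))
                best_d_key = key
        # acceptor arm: best cell in reversed rows <= n - k; the reversed end
        # cell is the forward start, so maximize (j', i') for the smallest
        # forward (acceptor_start, read_start)
        a_cells = _best_cells(Ha, n - k, sa)
        best_ac = None
        best_ac_key = None
        for ci, cj in a_cells:
            key = (int(cj), int(ci))
            if best_ac_key is None or key > best_ac_key:
                best_ac = (int(ci), int(cj))
                best_ac_key = key
        assert best_d is not None and best_ac is not None
        rs_d, fs_d, ops_d, ei_d, ej_d = best_d
        ci_a, cj_a = best_ac
        rs_ar, fs_ar, ops_ar = _traceback(Ha, qr, ar, sc, ci_a, cj_a)
        # map reversed-space acceptor alignment to forward coords
        m_a = a8.size
        a_read_start = n - ci_a
        a_ref_start = m_a - cj_a
        fwd_ops_a = ops_ar[::-1]
        # exact-match extension toward the junction
        De, Dj = _extend_right(q8, d8, ei_d, ej_d)
        As, Aj = _extend_left(q8, a8, a_read_start, a_ref_start)
        mh, ins, dbk, abk, x, De_out = _walk_canonical(q8, d8, a8, De, Dj, As, Aj, read.sequence)
        # build extended arm alignments
        ops_d_ext = ops_d + ["M"] * (De - ei_d)
        donor_arm = _ops_to_result(q8, d8, sc, rs_d, fs_d, ops_d_ext)
        ops_a_ext = ["M"] * (a_read_start - As) + fwd_ops_a
        acceptor_arm = _ops_to_result(q8, a8, sc, As, Aj, ops_a_ext)
        candidates.append(
            _Candidate(mh, ins, dbk, abk, x, De_out, donor_arm, acceptor_arm)
        )

    if not candidates:
        return _failed_call(read.id, fail_reasons or ("no_junction",))

    cand = min(candidates, key=lambda c: c.sort_key)

    reasons: list[str] = []
    d_arm, a_arm = cand.donor_arm, cand.acceptor_arm
    if d_arm.read_interval[1] - d_arm.read_interval[0] < params.min_arm_len:
        reasons.append("donor_arm_short")
    elif d_arm.identity < params.min_arm_identity:
        reasons.append("donor_arm_identity")
    if a_arm.read_interval[1] - a_arm.read_interval[0] < params.min_arm_len:
        reasons.append("acceptor_arm_short")
    elif a_arm.identity < params.min_arm_identity:
        reasons.append("acceptor_arm_identity")
    if d_arm.read_interval[0] > a_arm.read_interval[0]:
        reasons.append("inverted")

    if cand.mh_len > 0:
        jclass = CLASS_MH
    elif cand.insertion:
        jclass = CLASS_INSERTION
    else:
        jclass = CLASS_DIRECT

    return JunctionCall(
        read_id=read.id,
        qc_pass=not reasons,
        reasons=tuple(reasons),
        junction_class=jclass,
        donor_break=cand.donor_break,
        acceptor_break=cand.acceptor_break,
        read_break=cand.read_break,
        mh_len=cand.mh_len,
        insertion_seq=cand.insertion,
        donor_arm=d_arm,
        acceptor_arm=a_arm,
        ambiguity_interval=(cand.read_break, cand.read_break + cand.mh_len + 1),
    )


def call_intra_deletion(
    read: ReadRecord,
    ref: SRegionRef,
    min_deletion: int = 20,
    params: CallParams | None = None,
) -> JunctionCall:
    """Call an intra-S-region deletion: both arms align to the same reference
    and the acceptor break must lie at least ``min_deletion`` nt downstream of
    the donor break.  Reads without such a deletion are qc-failed "no_deletion".
    """
    if min_deletion <= 0:
        raise ValueError("min_deletion must be positive")
    call = call_junction(read, ref, ref, params=params, _skip_role_check=True)
    if call.donor_break is None or call.acceptor_break is None:
        return call
    if call.acceptor_break - call.donor_break < min_deletion:
        return JunctionCall(
            read_id=call.read_id,
            qc_pass=False,
            reasons=call.reasons + ("no_deletion",),
            junction_class=call.junction_class,
            donor_break=call.donor_break,
            acceptor_break=call.acceptor_break,
            read_break=call.read_break,
            mh_len=call.mh_len,
            insertion_seq=call.insertion_seq,
            donor_arm=call.donor_arm,
            acceptor_arm=call.acceptor_arm,
            ambiguity_interval=call.ambiguity_interval,
        )
    return call


# ---------------------------------------------------------------------------
# exhaustive oracle
# ---------------------------------------------------------------------------

_ORACLE_MAX_READ = 200


def oracle_best_junction(
    read: ReadRecord | str, donor: SRegionRef | str, acceptor: SRegionRef | str
) -> tuple[int, int, int, str]:
    """Exhaustive reference oracle for error-free junction reads.

    Enumerates every (donor-arm end, acceptor-arm start) pair, scoring each
    arm as the longest exact (Hamming-run) extension into its reference, and
    returns the maximum-total-match solution canonicalized exactly as
    call_junction canonicalizes: (donor_break, acceptor_break, mh_len,
    insertion).  Intended as an independent test oracle; reads are limited to
    200 nt so full enumeration stays cheap.
    """
    rseq = read.sequence if isinstance(read, ReadRecord) else read
    dseq = donor.sequence if isinstance(donor, SRegionRef) else donor
    aseq = acceptor.sequence if isinstance(acceptor, SRegionRef) else acceptor
    n = len(rseq)
    if n > _ORACLE_MAX_READ:
        raise ValueError(f"oracle_best_junction limited to reads <= {_ORACLE_MAX_READ} nt")
    q8, d8, a8 = encode(rseq), encode(dseq), encode(aseq)
    nd, na = d8.size, a8.size

    # S[i, j]: length of the exact common suffix run of read[:i] and donor[:j]
    S = np.zeros((n + 1, nd + 1), dtype=np.int32)
    for i in range(1, n + 1):
        eq = (d8 == q8[i - 1]) & (q8[i - 1] < 4)
        S[i, 1:] = np.where(eq, S[i - 1, :-1] + 1, 0)
    # P[i, j]: length of the exact common prefix run of read[i:] and acceptor[j:]
    P = np.zeros((n + 1, na + 1), dtype=np.int32)
    for i in range(n - 1, -1, -1):
        eq = (a8 == q8[i]) & (q8[i] < 4)
        P[i, :-1] = np.where(eq, P[i + 1, 1:] + 1, 0)

    Ld = S.max(axis=1)  # best donor run ending at read prefix length e
    Ld_arg = S.argmax(axis=1)  # smallest donor end coordinate among ties
    Ra = P.max(axis=1)  # best acceptor run starting at read position s
    Ra_arg = P.argmax(axis=1)

    T = Ld[:, None].astype(np.int64) + Ra[None, :]
    e_idx, s_idx = np.meshgrid(np.arange(n + 1), np.arange(n + 1), indexing="ij")
    T[e_idx > s_idx] = np.iinfo(np.int64).min
    best_total = int(T.max())
    cand_pairs = np.argwhere(T == best_total)
    if cand_pairs.shape[0] > 200:
        cand_pairs = cand_pairs[:200]

    best: Optional[tuple] = None
    best_key = None
    for e, s in cand_pairs:
        e, s = int(e), int(s)
        je = int(Ld_arg[e])
        ja = int(Ra_arg[s])
        De, Dj = _extend_right(q8, d8, e, je)
        As, Aj = _extend_left(q8, a8, s, ja)
        mh, ins, dbk, abk, x, _ = _walk_canonical(q8, d8, a8, De, Dj, As, Aj, rseq)
        key = (-mh, dbk, abk, ins)
        if best_key is None or key < best_key:
            best = (dbk, abk, mh, ins)
            best_key = key
    assert best is not None
    return best
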