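# Methods

## The junction model

A recombined switch-junction amplicon read is modelled as

```
read = donor[0:d] + insertion + acceptor[a:]
```

with the two germline references supplied in amplicon orientation (nested
primers fix the orientation, so no reverse-complement search is performed and
inversional recombination is out of scope). The junctional **microhomology
(MH)** is defined operationally as the maximal junction-spanning read segment
that matches *both* germline continuations perfectly; a mismatch or an N
terminates it. This is the standard convention for CSR junction structure
analysis and it makes MH unique for a given breakpoint pair. Because the
breakpoint can be placed at any of the MH + 1 equivalent positions, each call
carries an ambiguity interval of exactly that size, and the reported read
breakpoint is canonicalized to the leftmost equivalent position while the
reference breakpoints use the representation with the donor arm maximally
extended (`read == donor[:donor_break] + insertion + acceptor[acceptor_break:]`
locally). Exactly one of {MH > 0, insertion non-empty, direct} holds.

## Junction calling

Calling proceeds in three steps:

1. **Two-arm dynamic scan.** Smith–Waterman score matrices (linear gaps) of
   the read against the donor and of the reversed read against the reversed
   acceptor are computed once each; the within-row horizontal dependency of
   the linear-gap recurrence is resolved exactly with a running-maximum scan,
   so each matrix costs one vectorized pass per read base. For every split
   point k, the best donor-arm score within `read[:k]` plus the best
   acceptor-arm score within `read[k:]` is available from cumulative row
   maxima; the split maximizing the sum is selected.
2. **Canonicalization.** The chosen arms are exact-match extended toward the
   junction; the MH is measured by walking left from the donor arm's maximal
   reach while the read base matches both germlines. If the extended arms do
   not meet, the uncovered read bases are the untemplated insertion.
3. **QC.** Arms must span ≥ `min_arm_len` (default 15 nt) read bases at
   ≥ `min_arm_identity` (default 0.90); reads failing either, or scoring
   better in the swapped (acceptor-before-donor) orientation, are flagged
   rather than raising. Reads shorter than twice the minimum arm length are
   QC-failed as too short.

Scoring defaults are match +1, mismatch −2, gap −3 (linear). The aligner the
original junction libraries were analyzed with is a black box with unstated
parameters; these defaults keep exact dynamic programming tractable and are
echoed in output metadata and configurable throughout. Ties across
co-optimal partitions are resolved by preferring the larger MH, then the
leftmost donor breakpoint, then the leftmost acceptor breakpoint — the same
order implemented in the exhaustive test oracle, so the two routes are
comparable call-for-call.

`oracle_best_junction` is the independent oracle: it enumerates every
(donor-arm end, acceptor-arm start) pair on reads ≤ 200 nt, scoring arms as
exact Hamming runs, and canonicalizes identically. It is used only in tests
and in the acceptance script, never in the calling path.

Intra-region deletions reuse the same machinery with donor = acceptor = one
reference plus the constraint `acceptor_break − donor_break ≥ min_deletion`
(default 20 nt; no published threshold exists for "intra-region deletion",
so the default is explicit and configurable). Reads not meeting it are
QC-failed `no_deletion`.

## Mutation census

For each QC-passed call, each flank is walked from the junction outward along
its arm alignment. Aligned (M) columns are compared to the germline base;
substitutions require both bases in {A,C,G,T}. MH columns belong to both
germlines and are excluded from numerator and denominator, as are gap columns
and read-N columns. The window is junction-anchored and capped at 506
examined bases; flanks with fewer than 48 examined bases are excluded
(`included = False`). Junction-anchoring is the only choice that makes
per-read windows comparable, since amplicons differ in how much of each
region they span. The group frequency is the pooled ratio
Σ substitutions / Σ examined bases (change/base); the mean of per-sequence
ratios is reported alongside. Substitutions only: flank indels are excluded
from the numerator and their columns from the denominator. No background
sequencing-error correction is applied — the simulator instead quantifies the
confound (see below).

Two small, measurable biases are inherent to alignment-based counting and
are left uncorrected:

- **Terminal trimming.** A local alignment never ends on a mismatch, so a
  substitution in the outermost one or two bases of a flank is trimmed out
  of the arm and never examined (≲ 1% of substitutions at ~300-base flanks).
- **Junction-adjacent germline conversion.** A substitution immediately
  adjacent to the MH region that happens to match the *other* germline is
  indistinguishable from a junction shifted by one base; the caller then
  reads a different MH and the census counts the base as germline. At a
  10⁻² rate this affects ~1 read in 25 and is the main reason exact MH
  recovery saturates near 96–98% rather than 100% on mutated reads.

Together these make the pooled estimator low by roughly 2% relative — well
inside the binomial noise at the library sizes used here, and verified to
stay within 3 standard errors of planted rates of 0.005–0.02 in the
acceptance checks.

## Dot matrix

`compute_matrix` records every window pair of two sequences whose ungapped
Hamming identity reaches the threshold, in direct and (optionally)
reverse-complement orientation; the brute-force definition is the contract,
vectorized over the full window-pair grid (fine up to ~10 kb references).
Defaults are window 8 at 0.75 identity, both orientations — the parameters
of the original MacVector analysis are not published, so the defaults are
explicit, configurable and echoed in the output. Both the per-match identity
and the overall match density are exported, so a rendering can map intensity
to either frequency or degree of complementarity.

## Group statistics

Junctions are deduplicated by exact full-read sequence identity (first
occurrence kept) and subsampled without replacement to a fixed group size —
45 unique junctions per group, the convention in switch-junction reporting —
under an explicit seed, since the original selection procedure for published
groups is unstated. Group means of MH length include MH-zero junctions
(required for internal consistency: a group reported with 21% MH-positive
junctions and mean 0.72 nt is only possible zeros-included). Group
comparisons use the classical unpaired two-tailed Student t-test with pooled
variance (df = n₁ + n₂ − 2), with Welch's variant behind a flag; raw
p-values are reported and no multiple-comparison adjustment is applied by
default, mirroring common practice in this literature.

## Simulator

`simulate_reads` is the study-conditions generator. Defaults emulate an
Sμ–σδ-style library: 300 bp merged amplicon reads, MH uniform on 2–13 nt
(every junction MH-positive, spanning the reported range), flank mutation
rate 10⁻² change/base, hotspot multiplier 1 (raise it to model WRC/GYW
targeting; it is left neutral by default so that planted rates equal
realized rates for calibration), no sequencing error. Key guarantees:

- **Exact MH realization.** Breakpoint pairs are drawn only where the r
  junction bases match both germlines and both one-base extensions mismatch
  (maximality), so the brute-force MH of an error-free read equals the drawn
  value. Pairs are sampled uniformly from the valid set: by rejection for
  r ≤ 2 (dense) and from a cached k-mer-indexed enumeration for r ≥ 3
  (sparse). Draws with no compatible pair are counted and resampled; more
  than 50% unrealizable draws is an error.
- **Untemplated insertions.** Insertions occur only on MH = 0 draws (a
  junction cannot carry both). Every insertion base must mismatch both the
  donor continuation and the acceptor pre-context; additionally, because
  shifted partial templating against repeat-rich references cannot be
  excluded by per-base checks, the assembled clean read is verified to admit
  no equally- or better-scoring alternative junction explanation, and the
  draw is resampled otherwise. This keeps the ground truth unique by
  construction for insertion-bearing reads (and is therefore disclosed:
  round-trip recovery of insertions partially reflects this filter, while
  MH and blunt junctions are never filtered this way).
- **Separate channels.** Flank mutations (never inside MH or insertion) are
  applied before uniform sequencing error, and the two are recorded
  separately in the truth, so the census's inability to distinguish them is
  itself measurable: with error rate e and mutation rate m the pooled
  estimate is ≈ m + e.
- **Determinism.** Identical configs (including seed) produce byte-identical
  outputs.

`synthetic_switch_region` builds repeat-rich stand-in references by
concatenating AGCT-family motifs (AGCTGAGCTG, GAGCT, …) with ~5% point
perturbation and occasional 1–3 nt spacers. Two such references share the
motif vocabulary, so long microhomologies (≥ 10 nt) are realizable — as for
real Sμ/σδ pairs — while perturbation keeps ~150 nt arm contexts unique.
What the stand-ins do *not* emulate: the tandem-repeat unit length profile
and G-richness of real switch regions, PCR chimeras and duplicates, indel
sequencing errors, or quality-score error profiles. Passing tests therefore
demonstrate correctness of the junction arithmetic and estimators under the
modelled read structure, not performance on any particular genomic locus;
real analyses must supply user-provided germline references.

## Problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use 1000-read libraries for
recovery/agreement checks (read length 120 nt on random 300-nt references
for the oracle comparison, 300 nt on ~2 kb/1.5 kb synthetic switch regions
otherwise), 200 reads × ~300 examined bases per side and planted rates
{0.005, 0.01, 0.02} for census calibration, and 45-junction subsamples for
group summaries. All randomness flows through explicit integer seeds
(numpy `default_rng`); co-optimal alignment ties break deterministically
(smallest reference start, then smallest read start). Degenerate inputs
fail loudly: empty groups, zero denominators, zero pooled variance and
role-mismatched references raise, while per-read problems (short reads,
weak arms, inverted orientation, absent deletion) are QC flags so that a
library-scale run never aborts on one bad read.

## Known limitations

- Linear (not affine) gap penalties; junctional structures requiring long
  gaps inside an arm are not modelled.
- Chimeric multi-segment reads, translocations and inversions are out of
  scope (inverted reads are QC-flagged).
- The census reports raw change/base; sequencing error inflates it
  additively and is not subtracted.
- The exhaustive oracle is limited to ≤ 200 nt reads by design.
- Paired-end merging, adapter/quality trimming and demultiplexing are
  upstream of this package; inputs are merged single-sequence amplicons.
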