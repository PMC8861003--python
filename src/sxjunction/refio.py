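"""Reading and writing of germline switch-region references and junction reads.

Germline switch (S) region references (Smu, sigma-delta, Sgamma1, ...) are
plain FASTA; junction amplicon reads are FASTA or FASTQ.  All coordinates
anywhere in this package are 0-based, half-open.  Reference sequences must be
unambiguous A/C/G/T; reads may additionally contain N, which never counts as a
match during alignment nor as a mutation in the census.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

REFERENCE_ALPHABET = frozenset("ACGT")
READ_ALPHABET = frozenset("ACGTN")

ROLE_DONOR = "donor"
ROLE_ACCEPTOR = "acceptor"


class RefIOError(ValueError):
    """Raised for malformed reference or read inputs."""


@dataclass(frozen=True)
class SRegionRef:
    """A named germline switch-region sequence.

    role is "donor" (e.g. Smu) or "acceptor" (e.g. sigma-delta, Sgamma1).
    """

    name: str
    sequence: str
    role: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.name:
            raise RefIOError("reference name must be non-empty")
        if not self.sequence:
            raise RefIOError(f"reference {self.name!r}: empty sequence")
        if self.role not in (ROLE_DONOR, ROLE_ACCEPTOR):
            raise RefIOError(
                f"reference {self.name!r}: role must be 'donor' or 'acceptor', got {self.role!r}"
            )
        for i, base in enumerate(self.sequence):
            if base not in REFERENCE_ALPHABET:
                raise RefIOError(
                    f"reference {self.name!r}: invalid base {base!r} at position {i} "
                    "(ambiguity codes are not accepted for references)"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class ReadRecord:
    """One junction amplicon read (assumed pre-merged to a single sequence)."""

    id: str
    sequence: str
    qualities: Optional[tuple[int, ...]] = None
    group_label: str = ""
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        if not self.sequence:
            raise RefIOError(f"read {self.id!r}: empty sequence")
        if self.qualities is not None and len(self.qualities) != len(self.sequence):
            raise RefIOError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.sequence)}"
            )
        for i, base in enumerate(self.sequence):
            if base not in READ_ALPHABET:
                raise RefIOError(f"read {self.id!r}: invalid base {base!r} at position {i}")

    def __len__(self) -> int:
        return len(self.sequence)


def load_references(path: str | os.PathLike, roles: Mapping[str, str]) -> list[SRegionRef]:
    """Load germline switch-region references from FASTA.

    ``roles`` maps record name -> "donor" | "acceptor"; records not listed in
    ``roles`` are skipped, and every listed name must be present in the file.
    Duplicate names and non-ACGT characters are errors.
    """
    refs: list[SRegionRef] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise RefIOError(f"duplicate reference name {rec.id!r} in {path}")
        seen.add(rec.id)
        if rec.id not in roles:
            continue
        refs.append(SRegionRef(name=rec.id, sequence=str(rec.seq), role=roles[rec.id]))
    missing = set(roles) - seen
    if missing:
        raise RefIOError(f"references not found in {path}: {sorted(missing)}")
    return refs


def _detect_format(path: str | os.PathLike) -> str:
    with open(path) as fh:
        for line in fh:
            if line.strip():
                first = line.lstrip()[0]
                if first == ">":
                    return "fasta"
                if first == "@":
                    return "fastq"
                raise RefIOError(f"{path}: cannot detect FASTA/FASTQ (first character {first!r})")
    return "empty"


def load_reads(path: str | os.PathLike, group_label: str = "") -> list[ReadRecord]:
    """Load junction reads from FASTA or FASTQ (auto-detected), in file order."""
    fmt = _detect_format(path)
    if fmt == "empty":
        return []
    reads: list[ReadRecord] = []
    parser = SeqIO.parse(str(path), fmt)
    while True:
        try:
            rec = next(parser)
        except StopIteration:
            break
        except ValueError as exc:
            approx_line = 4 * len(reads) + 1 if fmt == "fastq" else 2 * len(reads) + 1
            raise RefIOError(f"{path}: parse error near line {approx_line}: {exc}") from exc
        quals = rec.letter_annotations.get("phred_quality")
        reads.append(
            ReadRecord(
                id=rec.id,
                sequence=str(rec.seq),
                qualities=tuple(quals) if quals is not None else None,
                group_label=group_label,
            )
        )
    return reads


def trim_constant_flanks(read: ReadRecord, five_prime: str, three_prime: str) -> ReadRecord:
    """Remove exact-match constant (primer-derived) prefix/suffix, at most once each.

    A flank that does not match leaves the sequence unchanged and records a
    flag on the returned read.  Trimming that would empty the read is an error.
    """
    seq = read.sequence
    quals = read.qualities
    flags = list(read.flags)
    five_prime = five_prime.upper()
    three_prime = three_prime.upper()
    start, end = 0, len(seq)
    if five_prime:
        if seq.startswith(five_prime):
            start = len(five_prime)
        else:
            flags.append("five_prime_not_found")
    if three_prime:
        if seq.endswith(three_prime) and len(seq) - len(three_prime) >= start:
            end = len(seq) - len(three_prime)
        else:
            flags.append("three_prime_not_found")
    if start >= end:
        raise RefIOError(f"read {read.id!r}: trimming constant flanks would empty the read")
    return replace(
        read,
        sequence=seq[start:end],
        qualities=quals[start:end] if quals is not None else None,
        flags=tuple(flags),
    )


def write_fasta(records: Iterable[SRegionRef | ReadRecord], path: str | os.PathLike) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.name if isinstance(r, SRegionRef) else r.id, description="")
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def write_fastq(records: Iterable[ReadRecord], path: str | os.PathLike, default_quality: int = 40) -> None:
    seqrecs = []
    for r in records:
        rec = SeqRecord(Seq(r.sequence), id=r.id, description="")
        quals = r.qualities if r.qualities is not None else (default_quality,) * len(r.sequence)
        rec.letter_annotations["phred_quality"] = list(quals)
        seqrecs.append(rec)
    SeqIO.write(seqrecs, str(path), "fastq")


def write_tsv(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Write a tabular output: tab-separated, header row, '.' for missing."""
    df.to_csv(path, sep="\t", index=False, na_rep=".")


def read_tsv(path: str | os.PathLike) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["."], keep_default_na=False)
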