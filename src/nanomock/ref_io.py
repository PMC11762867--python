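"""Reference FASTA input, simulated-read FASTA output, synthetic fixtures.

Sequences are normalized on input: uppercased, and IUPAC ambiguity codes
other than N are replaced by N (conversion counts are logged, not fatal —
real assemblies routinely contain them). Organism labels always come from
the sample design, never from FASTA headers; headers only identify contigs.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, TYPE_CHECKING, Iterable, Iterator

import numpy as np
from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .sim_core import SimulatedRead

logger = logging.getLogger(__name__)

__all__ = [
    "Contig",
    "ReferenceSet",
    "RefIOError",
    "read_fasta",
    "write_fasta",
    "write_reference_fasta",
    "generate_random_reference",
]

DEFAULT_LINE_WIDTH = 80

_VALID = set("ACGTN")


def _build_normalize_table() -> bytes:
    # uppercase every letter, then send any non-ACGTN letter to N;
    # non-letters pass through and are rejected later by the Contig invariant
    table = bytearray(range(256))
    for c in range(256):
        ch = chr(c)
        if ch.isalpha() and ch.isascii():
            up = ch.upper()
            table[c] = ord(up) if up in _VALID else ord("N")
    return bytes(table)


_NORMALIZE = _build_normalize_table()


class RefIOError(ValueError):
    """Malformed or unusable reference input."""


@dataclass(frozen=True)
class Contig:
    """One FASTA record: header token plus normalized sequence."""

    id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __post_init__(self) -> None:
        bad = set(self.sequence) - _VALID
        if bad:
            raise RefIOError(
                f"contig {self.id!r}: unnormalized characters {sorted(bad)!r}"
            )


@dataclass
class ReferenceSet:
    """All contigs backing one organism."""

    organism: str
    contigs: list[Contig] = field(default_factory=list)

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    @property
    def max_contig_length(self) -> int:
        return max(c.length for c in self.contigs)

    def __post_init__(self) -> None:
        if not self.contigs:
            raise RefIOError(f"reference set {self.organism!r} has no contigs")
        ids = [c.id for c in self.contigs]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise RefIOError(
                f"reference set {self.organism!r}: duplicate contig ids {dupes!r}"
            )


def _open_maybe_gzip(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _normalize(raw: str) -> tuple[str, int]:
    """Uppercase and map non-ACGTN letters to N; return (seq, n_replaced)."""
    seq = raw.encode("ascii").translate(_NORMALIZE).decode("ascii")
    upper = raw.upper()
    n_replaced = sum(a != b for a, b in zip(upper, seq))
    return seq, n_replaced


def read_fasta(path: str | Path, organism: str | None = None) -> ReferenceSet:
    """Read a (possibly gzipped) FASTA file into a ReferenceSet.

    Raises RefIOError on an empty file, an empty record, or duplicate
    header tokens. Ambiguity codes other than N become N; the total
    replacement count is logged as a warning.
    """
    path = Path(path)
    if not path.exists():
        raise RefIOError(f"reference file not found: {path}")
    label = organism if organism is not None else path.name.split(".")[0]

    contigs: list[Contig] = []
    seen: set[str] = set()
    replaced = 0
    with _open_maybe_gzip(path) as handle:
        for record in SeqIO.parse(handle, "fasta"):
            if record.id in seen:
                raise RefIOError(f"{path}: duplicate header token {record.id!r}")
            seen.add(record.id)
            seq, n_rep = _normalize(str(record.seq))
            if not seq:
                raise RefIOError(f"{path}: record {record.id!r} has empty sequence")
            replaced += n_rep
            contigs.append(Contig(id=record.id, sequence=seq))
    if not contigs:
        raise RefIOError(f"{path}: no FASTA records found")
    if replaced:
        logger.warning(
            "%s: replaced %d ambiguity base(s) with N", path.name, replaced
        )
    return ReferenceSet(organism=label, contigs=contigs)


def write_fasta(
    reads: Iterable["SimulatedRead"],
    path: str | Path,
    line_width: int = DEFAULT_LINE_WIDTH,
) -> int:
    """Stream reads to a FASTA file; returns the number of records written."""
    if line_width < 1:
        raise ValueError(f"line_width must be >= 1, got {line_width}")
    count = 0
    with open(path, "wt") as handle:
        for read in reads:
            write_fasta_record(handle, read.id, read.sequence, line_width)
            count += 1
    return count


def write_fasta_record(
    handle: IO[str], read_id: str, sequence: str, line_width: int = DEFAULT_LINE_WIDTH
) -> None:
    """Write one wrapped FASTA record to an open text handle."""
    handle.write(">")
    handle.write(read_id)
    handle.write("\n")
    for i in range(0, len(sequence), line_width):
        handle.write(sequence[i : i + line_width])
        handle.write("\n")


def write_reference_fasta(
    refset: ReferenceSet, path: str | Path, line_width: int = DEFAULT_LINE_WIDTH
) -> Path:
    """Write a ReferenceSet to FASTA (one record per contig)."""
    path = Path(path)
    with open(path, "wt") as handle:
        for contig in refset.contigs:
            write_fasta_record(handle, contig.id, contig.sequence, line_width)
    return path


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def generate_random_reference(
    organism: str,
    n_contigs: int,
    contig_length: int,
    gc: float = 0.5,
    seed: int = 0,
) -> ReferenceSet:
    """Synthesize a reference of i.i.d. bases at a target GC fraction.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2. Pure function of its
    arguments: identical calls give byte-identical sequences.
    """
    if not 0.0 <= gc <= 1.0:
        raise ValueError(f"gc must be in [0, 1], got {gc}")
    if n_contigs < 1:
        raise ValueError(f"n_contigs must be >= 1, got {n_contigs}")
    if contig_length < 1:
        raise ValueError(f"contig_length must be >= 1, got {contig_length}")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    contigs = []
    for i in range(n_contigs):
        codes = rng.choice(4, size=contig_length, p=p)
        seq = _BASES[codes].tobytes().decode("ascii")
        contigs.append(Contig(id=f"{organism}_contig{i + 1}", sequence=seq))
    return ReferenceSet(organism=organism, contigs=contigs)


def iter_fasta_headers(path: str | Path) -> Iterator[str]:
    """Yield header tokens of a FASTA file without loading sequences."""
    with _open_maybe_gzip(Path(path)) as handle:
        for line in handle:
            if line.startswith(">"):
                yield line[1:].rstrip("\n").split()[0]
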