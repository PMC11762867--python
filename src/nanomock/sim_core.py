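"""Read-length draws, locus selection, fragment extraction, orchestration.

Read lengths follow a truncated Gaussian (mean, sd) — redrawn while outside
[min_len, min(max_len, longest contig)], clamped after 1000 attempts. The
length model governs the pre-error fragment; insertions and deletions then
perturb the final read length around it.

Loci are uniform over all valid placements: a contig is chosen with
probability proportional to its number of eligible start positions
(length - fragment + 1), then the start uniformly within it. Strand is a
fair coin per read (configurable to forward-only).

Reads stream straight to FASTA as they are generated, so memory stays
bounded by a single read even for host-scale designs.

Read ids are self-describing provenance:
``{organism}|{contig}|{start}|{strand}|{fragment_length}|{serial}``
with 0-based half-open coordinates; a machine-readable truth TSV mirrors
them.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING

import numpy as np

from ._seeds import derive_seed
from .error_model import ErrorProfile, ErrorRecord, ErrorSummary, apply_errors
from .ref_io import Contig, ReferenceSet, read_fasta, write_fasta_record

if TYPE_CHECKING:  # pragma: no cover
    from .design import SampleDesign
    from .reports import ReportBundle

logger = logging.getLogger(__name__)

__all__ = [
    "LengthModel",
    "ReadOrigin",
    "SimulatedRead",
    "SimulationError",
    "draw_length",
    "pick_locus",
    "extract_fragment",
    "reverse_complement",
    "simulate_sample",
    "TRUTH_COLUMNS",
]

MAX_LENGTH_ATTEMPTS = 1000

TRUTH_COLUMNS = (
    "read_id", "organism", "contig", "start", "end", "strand",
    "fragment_length", "n_sub", "n_ins", "n_del",
)


class SimulationError(RuntimeError):
    """Design cannot be simulated against the given references."""


@dataclass(frozen=True)
class LengthModel:
    """Truncated Gaussian read-length model (all units: bases)."""

    mean: float
    sd: float
    min_len: int = 50
    max_len: int | None = None

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("mean must be > 0")
        if self.sd < 0:
            raise ValueError("sd must be >= 0")
        if self.min_len < 1:
            raise ValueError("min_len must be >= 1")
        if self.max_len is not None and self.max_len < self.min_len:
            raise ValueError("max_len must be >= min_len")


@dataclass(frozen=True)
class ReadOrigin:
    """Provenance of a fragment: 0-based half-open [start, end) on a contig."""

    organism: str
    contig: str
    start: int
    end: int
    strand: str | None = None  # '+', '-' or None while undecided

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(f"invalid origin interval [{self.start}, {self.end})")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    @property
    def fragment_length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class SimulatedRead:
    id: str
    sequence: str
    origin: ReadOrigin
    errors: ErrorRecord = field(default_factory=ErrorRecord)


def draw_length(
    model: LengthModel, contig_cap: int, rng: np.random.Generator
) -> int:
    """Draw one integer read length from the truncated Gaussian.

    Rejection-samples within [min_len, min(max_len, contig_cap)] for up to
    1000 attempts, then clamps to the nearest bound (terminal fallback, so
    this never fails).
    """
    if contig_cap < model.min_len:
        raise SimulationError(
            f"contig cap {contig_cap} below minimum read length {model.min_len}"
        )
    hi = contig_cap if model.max_len is None else min(model.max_len, contig_cap)
    x = model.min_len
    for _ in range(MAX_LENGTH_ATTEMPTS):
        x = int(round(rng.normal(model.mean, model.sd)))
        if model.min_len <= x <= hi:
            return x
    return min(max(x, model.min_len), hi)


def pick_locus(
    refset: ReferenceSet, frag_len: int, rng: np.random.Generator
) -> ReadOrigin:
    """Choose a uniform placement of ``frag_len`` across the reference.

    Contigs shorter than the fragment are ineligible; among the rest, each
    is chosen with probability proportional to its eligible start count so
    every placement across the reference is equally likely.
    """
    eligible = [c for c in refset.contigs if c.length >= frag_len]
    if not eligible:
        raise SimulationError(
            f"{refset.organism}: no contig can hold a {frag_len}-base fragment"
        )
    if len(eligible) == 1:
        contig = eligible[0]
    else:
        weights = np.array([c.length - frag_len + 1 for c in eligible], dtype=float)
        contig = eligible[rng.choice(len(eligible), p=weights / weights.sum())]
    start = int(rng.integers(0, contig.length - frag_len + 1))
    return ReadOrigin(
        organism=refset.organism,
        contig=contig.id,
        start=start,
        end=start + frag_len,
    )


_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def extract_fragment(contig: Contig, origin: ReadOrigin) -> str:
    """Extract [start, end); reverse-complement on '-', N complements to N."""
    if origin.end > contig.length:
        raise SimulationError(
            f"origin [{origin.start}, {origin.end}) exceeds contig "
            f"{contig.id!r} of length {contig.length}"
        )
    frag = contig.sequence[origin.start : origin.end]
    if origin.strand == "-":
        return reverse_complement(frag)
    return frag


# ---------------------------------------------------------------------------
# whole-sample orchestration


def _load_references(design: "SampleDesign") -> dict[str, ReferenceSet]:
    cache: dict[str, ReferenceSet] = {}
    refsets: dict[str, ReferenceSet] = {}
    for org in design.organisms():
        if org.reference in cache:
            base = cache[org.reference]
            refsets[org.name] = ReferenceSet(organism=org.name, contigs=base.contigs)
        else:
            rs = read_fasta(org.reference, organism=org.name)
            cache[org.reference] = rs
            refsets[org.name] = rs
    return refsets


def _generate_organism_reads(
    refset: ReferenceSet,
    count: int,
    design: "SampleDesign",
    profile: ErrorProfile,
    rng: np.random.Generator,
):
    """Yield SimulatedReads for one organism (streaming)."""
    model = design.length_model
    cap = refset.max_contig_length
    if cap < model.min_len:
        raise SimulationError(
            f"organism {refset.organism!r}: every contig is shorter than "
            f"min_len {model.min_len}"
        )
    both_strands = design.strand == "both"
    by_id = {c.id: c for c in refset.contigs}
    for serial in range(count):
        frag_len = draw_length(model, cap, rng)
        origin = pick_locus(refset, frag_len, rng)
        strand = "-" if (both_strands and rng.random() < 0.5) else "+"
        origin = replace(origin, strand=strand)
        contig = by_id[origin.contig]
        fragment = extract_fragment(contig, origin)
        sequence, errors = apply_errors(fragment, profile, rng)
        read_id = (
            f"{refset.organism}|{origin.contig}|{origin.start}|{strand}"
            f"|{frag_len}|{serial}"
        )
        yield SimulatedRead(id=read_id, sequence=sequence, origin=origin, errors=errors)


def simulate_sample(
    design: "SampleDesign",
    profile: ErrorProfile,
    outdir: str | Path,
    seed: int | None = None,
) -> "ReportBundle":
    """Generate one full sample: FASTA, truth TSV, and the four reports.

    Per-organism RNG substreams are derived by stable hashing of the sample
    seed and the organism name, so entry order in the config never changes
    another organism's reads. Fully deterministic given the seed.
    """
    from .design import resolve_abundances
    from .reports import ReportBundle, write_reports

    if seed is None:
        seed = design.seed
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    resolved = resolve_abundances(design, seed)
    refsets = _load_references(design)

    # fail fast before writing anything
    for name, rs in refsets.items():
        if resolved.counts[name] > 0 and rs.max_contig_length < design.length_model.min_len:
            raise SimulationError(
                f"organism {name!r}: every contig is shorter than "
                f"min_len {design.length_model.min_len}"
            )

    fasta_path = outdir / f"{design.sample_name}.fasta"
    truth_path = outdir / f"{design.sample_name}_truth.tsv"
    summary = ErrorSummary()
    n_written = 0
    with open(fasta_path, "wt") as fa, open(truth_path, "wt") as truth:
        truth.write("\t".join(TRUTH_COLUMNS) + "\n")
        for name, count in resolved.counts.items():
            org_rng = np.random.default_rng(derive_seed(seed, "organism", name))
            for read in _generate_organism_reads(
                refsets[name], count, design, profile, org_rng
            ):
                write_fasta_record(fa, read.id, read.sequence)
                o, e = read.origin, read.errors
                truth.write(
                    f"{read.id}\t{name}\t{o.contig}\t{o.start}\t{o.end}\t"
                    f"{o.strand}\t{o.fragment_length}\t{e.n_sub}\t{e.n_ins}\t"
                    f"{e.n_del}\n"
                )
                summary.add(name, e, o.fragment_length)
                n_written += 1
            logger.info("%s: wrote %d reads", name, count)

    assert n_written == resolved.total
    bundle = ReportBundle.build(
        design=design,
        profile=profile,
        resolved=resolved,
        error_summary=summary.report(),
        seed=seed,
    )
    write_reports(bundle, outdir)
    return bundle
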