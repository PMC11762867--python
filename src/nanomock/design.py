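"""Sample designs and exact integer read-abundance resolution.

The central guarantee: resolved per-organism counts always sum to the
design total exactly, with no drift. Fractional shares are rounded by
largest-remainder (Hamilton) apportionment — each share is rounded to its
floor and the leftover units go to the largest fractional remainders,
ties broken by declaration order. This is what lets a fixed-total design
emit, say, exactly 500 pathogen reads in every replicate.

Abundance modes:

* ``absolute`` — the organism gets exactly ``value`` reads.
* ``relative`` — ``value`` percent of the design total, apportioned.
* ``random``  — the leftover total is shared among the random-mode entries
  via a symmetric Dirichlet draw (concentration alpha, default 1) and
  apportioned to integers; seeded, hence reproducible.

Resolution order for mixed designs: absolutes are reserved first,
relatives next, randoms share what is left; a host entry flagged
``fill_remainder`` absorbs whatever remains. Over-allocation is a hard
error, never a silent rescale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

from ._seeds import derive_seed
from .sim_core import LengthModel

__all__ = [
    "DesignError",
    "AbundanceSpec",
    "OrganismSpec",
    "TaxonSpec",
    "DilutionSpec",
    "SampleDesign",
    "ResolvedAbundance",
    "largest_remainder",
    "parse_design",
    "design_to_dict",
    "resolve_abundances",
    "distribute_subtaxa",
    "make_dilution_series",
]

MODES = ("absolute", "relative", "random")
SCENARIOS = ("environmental", "host_microbiome")
SPLITS = ("equal", "random")


class DesignError(ValueError):
    """Invalid or inconsistent sample design."""


@dataclass(frozen=True)
class AbundanceSpec:
    mode: str
    value: float | None = None  # reads (absolute) | percent (relative) | None

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise DesignError(f"abundance mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "absolute":
            if self.value is None or self.value < 0 or self.value != int(self.value):
                raise DesignError(
                    f"absolute abundance must be an integer >= 0, got {self.value!r}"
                )
        elif self.mode == "relative":
            if self.value is None or not 0 <= self.value <= 100:
                raise DesignError(
                    f"relative abundance must be in [0, 100], got {self.value!r}"
                )
        elif self.value is not None:
            raise DesignError("random abundance takes no value")


@dataclass(frozen=True)
class OrganismSpec:
    name: str
    reference: str
    abundance: AbundanceSpec | None = None
    taxon: str | None = None


@dataclass(frozen=True)
class TaxonSpec:
    label: str
    abundance: AbundanceSpec
    members: tuple[OrganismSpec, ...]
    split: str = "equal"

    def __post_init__(self) -> None:
        if not self.members:
            raise DesignError(f"taxon {self.label!r} has no members")
        if self.split not in SPLITS:
            raise DesignError(f"split must be one of {SPLITS}, got {self.split!r}")
        for m in self.members:
            if m.abundance is not None:
                raise DesignError(
                    f"taxon {self.label!r}: member {m.name!r} must not carry its "
                    "own abundance (the taxon total is distributed)"
                )


@dataclass(frozen=True)
class DilutionSpec:
    organism: str
    levels: tuple[int, ...]
    replicates: int = 1


@dataclass
class SampleDesign:
    entries: list[OrganismSpec | TaxonSpec]
    seed: int = 0
    sample_name: str = "sample"
    total_reads: int | None = None
    scenario: str = "environmental"
    host: str | None = None
    fill_remainder: bool = False
    length_model: LengthModel = field(default_factory=lambda: LengthModel(2000, 200))
    profile: str = "perfect"
    replicates: int = 1
    random_alpha: float = 1.0
    strand: str = "both"  # or "forward"
    dilution: DilutionSpec | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- helpers -----------------------------------------------------------

    def organisms(self) -> list[OrganismSpec]:
        """Flatten entries to organism specs, taxon members included."""
        out: list[OrganismSpec] = []
        for e in self.entries:
            if isinstance(e, TaxonSpec):
                out.extend(replace(m, taxon=e.label) for m in e.members)
            else:
                out.append(e)
        return out

    def taxon_of(self, organism: str) -> str | None:
        for o in self.organisms():
            if o.name == organism:
                return o.taxon
        return None

    def _entry_abundance(self, entry: OrganismSpec | TaxonSpec) -> AbundanceSpec | None:
        return entry.abundance

    def validate(self) -> None:
        if not self.entries:
            raise DesignError("design has no entries")
        if self.scenario not in SCENARIOS:
            raise DesignError(f"scenario must be one of {SCENARIOS}")
        if self.strand not in ("both", "forward"):
            raise DesignError("strand must be 'both' or 'forward'")
        if self.replicates < 1:
            raise DesignError("replicates must be >= 1")
        if self.total_reads is not None and self.total_reads <= 0:
            raise DesignError("total_reads must be positive")

        names = [o.name for o in self.organisms()]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DesignError(f"duplicate organism names: {dupes!r}")

        if self.host is not None and self.host not in names:
            raise DesignError(f"host organism {self.host!r} not among entries")
        if self.fill_remainder and self.host is None:
            raise DesignError("fill_remainder requires a host organism")

        host_entry = self._host_entry()
        if self.fill_remainder and host_entry is not None:
            if host_entry.abundance is not None:
                raise DesignError(
                    f"host {self.host!r} with fill_remainder must not carry an abundance"
                )

        modes = set()
        for e in self.entries:
            if self.fill_remainder and isinstance(e, OrganismSpec) and e.name == self.host:
                continue
            ab = self._entry_abundance(e)
            if ab is None:
                raise DesignError(
                    f"entry {getattr(e, 'name', getattr(e, 'label', '?'))!r} "
                    "needs an abundance (or mark it as the fill-remainder host)"
                )
            modes.add(ab.mode)

        rel_sum = sum(
            e.abundance.value
            for e in self.entries
            if e.abundance is not None and e.abundance.mode == "relative"
        )
        if rel_sum > 100 + 1e-9:
            raise DesignError(
                f"relative abundances sum to {rel_sum}% (> 100%)"
            )

        if self.fill_remainder and "random" in modes:
            raise DesignError(
                "random-mode entries cannot be combined with a fill-remainder host "
                "(both claim the leftover total)"
            )

        needs_total = bool(modes & {"relative", "random"}) or self.fill_remainder
        if needs_total and self.total_reads is None:
            raise DesignError(
                "total_reads is required with relative/random abundances "
                "or a fill-remainder host"
            )
        if modes == {"absolute"} and not self.fill_remainder:
            implied = sum(
                int(self._entry_abundance(e).value) for e in self.entries  # type: ignore[union-attr]
            )
            if self.total_reads is not None and self.total_reads != implied:
                raise DesignError(
                    f"all-absolute design: total_reads {self.total_reads} != "
                    f"sum of absolute values {implied}"
                )
            self.total_reads = implied

        if self.dilution is not None:
            if self.dilution.organism not in names:
                raise DesignError(
                    f"dilution organism {self.dilution.organism!r} not among entries"
                )

    def _host_entry(self) -> OrganismSpec | None:
        if self.host is None:
            return None
        for e in self.entries:
            if isinstance(e, OrganismSpec) and e.name == self.host:
                return e
        return None  # host inside a taxon is rejected by validate's abundance walk


@dataclass(frozen=True)
class ResolvedAbundance:
    """Exact integer read count per organism; counts sum to total exactly."""

    counts: dict[str, int]
    total: int

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.counts.values()):
            raise DesignError(f"negative resolved count in {self.counts!r}")
        if sum(self.counts.values()) != self.total:
            raise DesignError(
                f"resolved counts sum to {sum(self.counts.values())}, "
                f"expected {self.total}"
            )


# ---------------------------------------------------------------------------
# apportionment


def largest_remainder(shares: Sequence[float], total: int) -> list[int]:
    """Apportion ``total`` units to fractional ``shares`` (Hamilton method).

    Each share gets its floor; the leftover units go to the largest
    fractional remainders, ties broken by position. Requires
    sum(floor(shares)) <= total <= sum(ceil(shares)) so the result stays
    within one unit of every share.
    """
    if total < 0:
        raise ValueError("total must be >= 0")
    if any(s < 0 for s in shares):
        raise ValueError("shares must be >= 0")
    floors = [math.floor(s) for s in shares]
    remainder = total - sum(floors)
    if remainder < 0:
        raise ValueError(
            f"total {total} below the sum of share floors {sum(floors)}"
        )
    fracs = [s - f for s, f in zip(shares, floors)]
    if remainder > sum(1 for f in fracs if f > 0):
        # sum(ceil(shares)) = sum(floors) + #positive fracs < total:
        # no allocation within one unit of every share exists
        raise ValueError(f"total {total} exceeds the sum of share ceilings")
    order = sorted(range(len(shares)), key=lambda i: (-fracs[i], i))
    counts = floors[:]
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def _dirichlet_counts(
    n: int, total: int, alpha: float, rng: np.random.Generator
) -> list[int]:
    """Split ``total`` into n nonnegative integers, Dirichlet(alpha) weights."""
    if n == 1:
        return [total]
    w = rng.dirichlet(np.full(n, alpha))
    return largest_remainder(list(w * total), total)


# ---------------------------------------------------------------------------
# resolution


def distribute_subtaxa(
    taxon_total: int, n: int, split: str = "equal", seed: int = 0
) -> list[int]:
    """Split a taxon's read budget among its members, conserving the total.

    ``equal`` gives floor(total/n) each, remainder to the first members in
    declaration order; ``random`` draws symmetric-Dirichlet weights.
    """
    if taxon_total < 0:
        raise DesignError("taxon_total must be >= 0")
    if n < 1:
        raise DesignError("n must be >= 1")
    if split == "equal":
        base, rem = divmod(taxon_total, n)
        return [base + (1 if i < rem else 0) for i in range(n)]
    if split == "random":
        rng = np.random.default_rng(derive_seed(seed, "subtaxa"))
        return _dirichlet_counts(n, taxon_total, 1.0, rng)
    raise DesignError(f"split must be one of {SPLITS}, got {split!r}")


def resolve_abundances(design: SampleDesign, seed: int | None = None) -> ResolvedAbundance:
    """Resolve a design to exact integer read counts per organism.

    Deterministic given the seed (defaults to the design seed). Raises
    DesignError on over-allocation or an incompletely specified total.
    """
    if seed is None:
        seed = design.seed

    entries = list(design.entries)
    host = design.host if design.fill_remainder else None

    # per-entry (top-level) target counts
    absolutes: dict[int, int] = {}
    relatives: dict[int, float] = {}
    randoms: list[int] = []
    for i, e in enumerate(entries):
        if host is not None and isinstance(e, OrganismSpec) and e.name == host:
            continue
        ab = e.abundance
        assert ab is not None  # validate() guarantees this
        if ab.mode == "absolute":
            absolutes[i] = int(ab.value)  # type: ignore[arg-type]
        elif ab.mode == "relative":
            relatives[i] = float(ab.value)  # type: ignore[arg-type]
        else:
            randoms.append(i)

    if design.total_reads is None:
        raise DesignError("design total is unresolved")
    total = design.total_reads

    counts_by_entry: dict[int, int] = dict(absolutes)
    reserved = sum(absolutes.values())
    if reserved > total:
        raise DesignError(
            f"absolute abundances ({reserved}) exceed total_reads ({total})"
        )

    remaining = total - reserved
    rel_shares = [p / 100.0 * total for p in relatives.values()]
    rel_sum = sum(rel_shares)
    if rel_sum - remaining > 1e-9:
        raise DesignError(
            f"relative abundances claim {rel_sum:.3f} reads but only "
            f"{remaining} remain after absolutes"
        )

    if relatives:
        if randoms or host is not None:
            rel_target = int(math.floor(rel_sum + 0.5))
        else:
            # relatives must complete the total exactly
            if abs(rel_sum - remaining) > 1e-6:
                raise DesignError(
                    f"relative abundances sum to {rel_sum:.3f} reads; {remaining} "
                    "needed to complete the total (add a random entry or a "
                    "fill-remainder host)"
                )
            rel_target = remaining
        rel_counts = largest_remainder(rel_shares, rel_target)
        for idx, c in zip(relatives, rel_counts):
            counts_by_entry[idx] = c
        remaining -= rel_target

    if randoms:
        rng = np.random.default_rng(derive_seed(seed, "random-mode"))
        for idx, c in zip(
            randoms, _dirichlet_counts(len(randoms), remaining, design.random_alpha, rng)
        ):
            counts_by_entry[idx] = c
        remaining = 0
    elif host is None and remaining != 0:
        raise DesignError(
            f"{remaining} reads of the total are unallocated and no random "
            "entry or fill-remainder host can absorb them"
        )

    # expand taxa to members, then place the host remainder
    counts: dict[str, int] = {}
    for i, e in enumerate(entries):
        if isinstance(e, TaxonSpec):
            member_counts = distribute_subtaxa(
                counts_by_entry[i],
                len(e.members),
                e.split,
                derive_seed(seed, "taxon", e.label),
            )
            for m, c in zip(e.members, member_counts):
                counts[m.name] = c
        elif host is not None and e.name == host:
            continue
        else:
            counts[e.name] = counts_by_entry[i]
    if host is not None:
        counts[host] = remaining

    # report in declaration order
    ordered = {o.name: counts[o.name] for o in design.organisms()}
    return ResolvedAbundance(counts=ordered, total=total)


def make_dilution_series(
    base_design: SampleDesign,
    organism: str,
    levels: Sequence[int],
    replicates: int = 1,
) -> list[SampleDesign]:
    """Expand a design into len(levels) x replicates independent designs.

    Each output design pins ``organism`` to an absolute level while the
    fixed total is preserved (a fill-remainder host absorbs the
    difference); child seeds are derived from (base seed, level index,
    replicate index) so replicates are independent yet reproducible.
    """
    names = [o.name for o in base_design.organisms()]
    if organism not in names:
        raise DesignError(f"dilution organism {organism!r} not in design")
    if replicates < 1:
        raise DesignError("replicates must be >= 1")
    if base_design.total_reads is None:
        raise DesignError("dilution series requires a fixed total_reads")
    designs: list[SampleDesign] = []
    for li, level in enumerate(levels):
        if level < 0 or level > base_design.total_reads:
            raise DesignError(
                f"dilution level {level} outside [0, total_reads="
                f"{base_design.total_reads}]"
            )
        for ri in range(replicates):
            entries = []
            for e in base_design.entries:
                if isinstance(e, OrganismSpec) and e.name == organism:
                    entries.append(
                        replace(e, abundance=AbundanceSpec("absolute", level))
                    )
                else:
                    entries.append(e)
            d = replace(
                base_design,
                entries=entries,
                seed=derive_seed(base_design.seed, "dilution", li, ri),
                sample_name=f"{base_design.sample_name}_L{level}_r{ri + 1:03d}",
                replicates=1,
                dilution=None,
            )
            designs.append(d)
    return designs


# ---------------------------------------------------------------------------
# config parsing

_DESIGN_KEYS = {
    "sample_name", "seed", "total_reads", "scenario", "host", "fill_remainder",
    "length_model", "profile", "replicates", "random_alpha", "strand",
    "entries", "dilution",
}
# report-only keys tolerated so a run-parameters JSON replays as a config
_IGNORED_KEYS = {"tool", "tool_version", "resolved_abundance", "seed_override"}


def parse_design(path: str | Path) -> SampleDesign:
    """Parse and validate a design file (YAML or JSON; TSV shortcut).

    Referenced FASTA paths are resolved relative to the config file and
    checked for existence.
    """
    path = Path(path)
    if not path.exists():
        raise DesignError(f"design file not found: {path}")
    if path.suffix in (".tsv", ".txt"):
        data = _parse_tsv_design(path)
    else:
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise DesignError(f"{path}: design must be a mapping")
    return design_from_dict(data, base_dir=path.parent)


def _parse_tsv_design(path: Path) -> dict:
    """Flat organism table: columns organism, reference, mode, value."""
    entries = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        required = ["organism", "reference", "mode", "value"]
        if header[: len(required)] != required:
            raise DesignError(
                f"{path}: TSV design needs columns {required}, got {header!r}"
            )
        for line in fh:
            if not line.strip():
                continue
            org, ref, mode, value = line.rstrip("\n").split("\t")[:4]
            ab: dict = {"mode": mode}
            if value not in ("", "-"):
                ab["value"] = float(value)
            entries.append({"organism": org, "reference": ref, "abundance": ab})
    return {"entries": entries}


def _parse_abundance(raw, where: str) -> AbundanceSpec:
    if isinstance(raw, Mapping):
        mode = raw.get("mode")
        if mode is None:
            raise DesignError(f"{where}: abundance needs a 'mode'")
        return AbundanceSpec(mode=mode, value=raw.get("value"))
    if isinstance(raw, (int, float)):
        return AbundanceSpec(mode="absolute", value=raw)
    if isinstance(raw, str):
        if raw == "random":
            return AbundanceSpec(mode="random")
        if raw.endswith("%"):
            return AbundanceSpec(mode="relative", value=float(raw[:-1]))
    raise DesignError(f"{where}: cannot interpret abundance {raw!r}")


def _parse_organism(raw: Mapping, base_dir: Path, check_refs: bool) -> OrganismSpec:
    if "organism" not in raw or "reference" not in raw:
        raise DesignError(f"organism entry needs 'organism' and 'reference': {raw!r}")
    name = str(raw["organism"])
    ref = Path(raw["reference"])
    if not ref.is_absolute():
        ref = base_dir / ref
    if check_refs and not ref.exists():
        raise DesignError(f"organism {name!r}: reference file not found: {ref}")
    ab = raw.get("abundance")
    return OrganismSpec(
        name=name,
        reference=str(ref),
        abundance=None if ab is None else _parse_abundance(ab, f"organism {name!r}"),
    )


def design_from_dict(
    data: Mapping, base_dir: Path | None = None, check_refs: bool = True
) -> SampleDesign:
    base_dir = base_dir or Path(".")
    unknown = set(data) - _DESIGN_KEYS - _IGNORED_KEYS
    if unknown:
        raise DesignError(f"unknown design keys: {sorted(unknown)!r}")

    entries: list[OrganismSpec | TaxonSpec] = []
    for raw in data.get("entries", []):
        if not isinstance(raw, Mapping):
            raise DesignError(f"each entry must be a mapping, got {raw!r}")
        if "taxon" in raw and "members" in raw:
            members = tuple(
                _parse_organism(m, base_dir, check_refs) for m in raw["members"]
            )
            label = str(raw["taxon"])
            if "abundance" not in raw:
                raise DesignError(f"taxon {label!r} needs an abundance")
            entries.append(
                TaxonSpec(
                    label=label,
                    abundance=_parse_abundance(raw["abundance"], f"taxon {label!r}"),
                    members=members,
                    split=raw.get("split", "equal"),
                )
            )
        else:
            entries.append(_parse_organism(raw, base_dir, check_refs))

    lm_raw = data.get("length_model", {})
    if not isinstance(lm_raw, Mapping):
        raise DesignError("length_model must be a mapping")
    length_model = LengthModel(
        mean=lm_raw.get("mean", 2000),
        sd=lm_raw.get("sd", 200),
        min_len=lm_raw.get("min_len", 50),
        max_len=lm_raw.get("max_len"),
    )

    dilution = None
    if data.get("dilution") is not None:
        d = data["dilution"]
        dilution = DilutionSpec(
            organism=str(d["organism"]),
            levels=tuple(int(v) for v in d["levels"]),
            replicates=int(d.get("replicates", 1)),
        )

    total = data.get("total_reads")
    return SampleDesign(
        entries=entries,
        seed=int(data.get("seed", 0)),
        sample_name=str(data.get("sample_name", "sample")),
        total_reads=None if total is None else int(total),
        scenario=data.get("scenario", "environmental"),
        host=data.get("host"),
        fill_remainder=bool(data.get("fill_remainder", False)),
        length_model=length_model,
        profile=str(data.get("profile", "perfect")),
        replicates=int(data.get("replicates", 1)),
        random_alpha=float(data.get("random_alpha", 1.0)),
        strand=data.get("strand", "both"),
        dilution=dilution,
    )


def design_to_dict(design: SampleDesign) -> dict:
    """Serialize a design to the config schema (round-trips via parse)."""
    entries = []
    for e in design.entries:
        if isinstance(e, TaxonSpec):
            entries.append(
                {
                    "taxon": e.label,
                    "abundance": {"mode": e.abundance.mode, "value": e.abundance.value},
                    "split": e.split,
                    "members": [
                        {"organism": m.name, "reference": m.reference}
                        for m in e.members
                    ],
                }
            )
        else:
            d: dict = {"organism": e.name, "reference": e.reference}
            if e.abundance is not None:
                d["abundance"] = {"mode": e.abundance.mode, "value": e.abundance.value}
            entries.append(d)
    lm = design.length_model
    out = {
        "sample_name": design.sample_name,
        "seed": design.seed,
        "total_reads": design.total_reads,
        "scenario": design.scenario,
        "host": design.host,
        "fill_remainder": design.fill_remainder,
        "length_model": {
            "mean": lm.mean, "sd": lm.sd, "min_len": lm.min_len, "max_len": lm.max_len,
        },
        "profile": design.profile,
        "replicates": design.replicates,
        "random_alpha": design.random_alpha,
        "strand": design.strand,
        "entries": entries,
    }
    if design.dilution is not None:
        out["dilution"] = {
            "organism": design.dilution.organism,
            "levels": list(design.dilution.levels),
            "replicates": design.dilution.replicates,
        }
    return out
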