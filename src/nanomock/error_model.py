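"""Error profiles and base-calling-style error injection.

The event model is a single left-to-right pass over the template fragment.
At each template base exactly one event is drawn from a categorical
distribution {substitution, insertion, deletion, match} (competing risks,
at most one event per base — at realistic long-read error rates this is
indistinguishable from independent Bernoullis but keeps the per-base
bookkeeping exact):

* substitution replaces the base with a different one, favoring the
  transition partner (A<->G, C<->T) with weight ``kappa`` against weight 1
  for each of the two transversion partners — i.e. the transition is chosen
  with probability kappa/(kappa+2). N is never substituted; a substitution
  event landing on N is recounted as a match.
* deletion drops the template base.
* insertion emits the template base followed by k >= 1 extra uniform-random
  bases, k geometric with continuation probability ``ins_extend``.

Preset rate values are representative of recent Guppy/Dorado base-caller
accuracies, not canonical numbers; custom profile files override them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "ErrorProfile",
    "ErrorRecord",
    "ProfileError",
    "PRESETS",
    "load_profile",
    "substitute_base",
    "apply_errors",
    "summarize_errors",
    "ErrorSummary",
]


class ProfileError(ValueError):
    """Invalid error-profile definition."""


@dataclass(frozen=True)
class ErrorProfile:
    """Per-base event rates plus the substitution transition weight."""

    name: str
    rate_sub: float
    rate_ins: float
    rate_del: float
    kappa: float = 2.0
    ins_extend: float = 0.2

    def __post_init__(self) -> None:
        for field_name in ("rate_sub", "rate_ins", "rate_del"):
            if getattr(self, field_name) < 0:
                raise ProfileError(f"{field_name} must be >= 0")
        if self.rate_sub + self.rate_ins + self.rate_del >= 1:
            raise ProfileError(
                "rate_sub + rate_ins + rate_del must be < 1 "
                f"(got {self.rate_sub + self.rate_ins + self.rate_del})"
            )
        if self.kappa < 0:
            raise ProfileError("kappa must be >= 0")
        if not 0 <= self.ins_extend < 1:
            raise ProfileError("ins_extend must be in [0, 1)")

    @property
    def is_zero(self) -> bool:
        return self.rate_sub == 0 and self.rate_ins == 0 and self.rate_del == 0

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ErrorRecord:
    """Exact per-read event counts (inserted/deleted bases, not events)."""

    n_sub: int = 0
    n_ins: int = 0
    n_del: int = 0

    @property
    def total(self) -> int:
        return self.n_sub + self.n_ins + self.n_del


PRESETS: dict[str, ErrorProfile] = {
    "perfect": ErrorProfile("perfect", 0.0, 0.0, 0.0, kappa=2.0, ins_extend=0.0),
    "guppy": ErrorProfile("guppy", 0.025, 0.0125, 0.0125, kappa=2.0, ins_extend=0.2),
    "dorado": ErrorProfile("dorado", 0.005, 0.0025, 0.0025, kappa=2.0, ins_extend=0.2),
}

_PROFILE_KEYS = {"name", "rate_sub", "rate_ins", "rate_del", "kappa", "ins_extend"}


def load_profile(source: str | Path | Mapping) -> ErrorProfile:
    """Resolve a preset name, a YAML/JSON profile file, or a mapping."""
    if isinstance(source, Mapping):
        return _profile_from_mapping(dict(source), "<mapping>")
    name = str(source)
    if name in PRESETS:
        return PRESETS[name]
    path = Path(source)
    if not path.exists():
        raise ProfileError(
            f"unknown preset or missing profile file: {source!r} "
            f"(presets: {sorted(PRESETS)})"
        )
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ProfileError(f"{path}: profile file must contain a mapping")
    return _profile_from_mapping(data, str(path))


def _profile_from_mapping(data: dict, where: str) -> ErrorProfile:
    unknown = set(data) - _PROFILE_KEYS
    if unknown:
        raise ProfileError(f"{where}: unknown profile keys {sorted(unknown)!r}")
    missing = {"rate_sub", "rate_ins", "rate_del"} - set(data)
    if missing:
        raise ProfileError(f"{where}: missing profile keys {sorted(missing)!r}")
    data.setdefault("name", "custom")
    return ErrorProfile(**data)


# base codes: A=0 C=1 G=2 T=3 N=4
_CODE_OF = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_OF[_b] = _i
_BYTE_OF = np.frombuffer(b"ACGTN", dtype=np.uint8)

_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def substitute_base(base: str, kappa: float, rng: np.random.Generator) -> str:
    """Replace one base, transition with probability kappa/(kappa+2)."""
    if base not in _TRANSITION:
        raise ValueError(f"cannot substitute base {base!r}")
    u = rng.random()
    if u < kappa / (kappa + 2):
        return _TRANSITION[base]
    tv = _TRANSVERSIONS[base]
    return tv[0] if u < (kappa + 1) / (kappa + 2) else tv[1]


def apply_errors(
    fragment: str, profile: ErrorProfile, rng: np.random.Generator
) -> tuple[str, ErrorRecord]:
    """Run the error pass over one fragment; returns (read, counts).

    Vectorized with numpy so whole-sample simulation stays fast; the
    semantics are exactly the per-base pass described in the module
    docstring, and identical counts are returned.
    """
    if not fragment:
        raise ValueError("fragment must be nonempty")
    if profile.is_zero:
        return fragment, ErrorRecord()

    codes = _CODE_OF[np.frombuffer(fragment.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    u = rng.random(n)
    # event codes: 0=sub 1=ins 2=del 3=match
    t_sub = profile.rate_sub
    t_ins = t_sub + profile.rate_ins
    t_del = t_ins + profile.rate_del
    events = np.full(n, 3, dtype=np.uint8)
    events[u < t_del] = 2
    events[u < t_ins] = 1
    events[u < t_sub] = 0
    # a substitution landing on N passes through as a match
    events[(events == 0) & (codes == 4)] = 3

    sub_idx = np.nonzero(events == 0)[0]
    ins_idx = np.nonzero(events == 1)[0]
    n_sub = sub_idx.size

    out_codes = codes.copy()
    if n_sub:
        b = codes[sub_idx]
        v = rng.random(n_sub)
        k = profile.kappa
        transition = v < k / (k + 2)
        first_tv = v < (k + 1) / (k + 2)
        repl = np.where(
            transition, b ^ 2, np.where(first_tv, (b + 1) % 4, (b + 3) % 4)
        ).astype(np.uint8)
        out_codes[sub_idx] = repl

    # per-position output multiplicity: match/sub -> 1, del -> 0, ins -> 1+k
    reps = np.ones(n, dtype=np.int64)
    reps[events == 2] = 0
    n_ins = 0
    if ins_idx.size:
        k_extra = rng.geometric(1.0 - profile.ins_extend, size=ins_idx.size)
        reps[ins_idx] = 1 + k_extra
        n_ins = int(k_extra.sum())

    n_del = int((events == 2).sum())
    if n_ins == 0 and n_del == 0:
        read_codes = out_codes
    else:
        read_codes = np.repeat(out_codes, reps)
        if n_ins:
            # positions of the inserted (extra) bases within the output:
            # everything repeated beyond its first copy
            starts = np.cumsum(reps) - reps
            is_first = np.zeros(read_codes.size, dtype=bool)
            is_first[starts[reps > 0]] = True
            inserted = ~is_first
            read_codes = read_codes.copy()
            read_codes[inserted] = rng.integers(
                0, 4, size=n_ins, dtype=np.int64
            ).astype(np.uint8)

    read = _BYTE_OF[read_codes].tobytes().decode("ascii")
    return read, ErrorRecord(n_sub=int(n_sub), n_ins=n_ins, n_del=n_del)


def summarize_errors(
    records: Iterable[ErrorRecord],
    template_bases: int,
    organisms: Sequence[str] | None = None,
) -> dict:
    """Aggregate per-read records into the error-distribution report."""
    if template_bases <= 0:
        raise ValueError("template_bases must be > 0")
    summary = ErrorSummary()
    records = list(records)
    labels = organisms if organisms is not None else ["all"] * len(records)
    if len(labels) != len(records):
        raise ValueError("organisms must parallel records")
    per_org_bases: dict[str, int] = {}
    # template bases split evenly across reads when only the total is known
    share, extra = divmod(template_bases, max(len(records), 1))
    for i, (org, rec) in enumerate(zip(labels, records)):
        summary.add(org, rec, share + (1 if i < extra else 0))
    report = summary.report()
    report["template_bases"] = template_bases
    return report


class ErrorSummary:
    """Streaming accumulator behind the error-distribution report."""

    def __init__(self) -> None:
        self._org: dict[str, list[int]] = {}  # org -> [bases, sub, ins, del, reads]

    def add(self, organism: str, record: ErrorRecord, template_len: int) -> None:
        row = self._org.setdefault(organism, [0, 0, 0, 0, 0])
        row[0] += template_len
        row[1] += record.n_sub
        row[2] += record.n_ins
        row[3] += record.n_del
        row[4] += 1

    @staticmethod
    def _rates(bases: int, sub: int, ins: int, dele: int, reads: int) -> dict:
        denom = bases if bases else 1
        return {
            "template_bases": bases,
            "n_reads": reads,
            "n_sub": sub,
            "n_ins": ins,
            "n_del": dele,
            "rate_sub": sub / denom,
            "rate_ins": ins / denom,
            "rate_del": dele / denom,
            "accuracy": 1.0 - (sub + ins + dele) / denom,
        }

    def report(self) -> dict:
        totals = [0, 0, 0, 0, 0]
        per_org = {}
        for org in sorted(self._org):
            row = self._org[org]
            for i in range(5):
                totals[i] += row[i]
            per_org[org] = self._rates(*row)
        overall = self._rates(*totals)
        overall["per_organism"] = per_org
        return overall
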