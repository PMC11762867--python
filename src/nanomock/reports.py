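"""The four sample reports: abundance, error profile, error distribution,
run parameters.

JSON is the canonical machine format; TSV mirrors the tabular reports for
spreadsheet use. Relative abundances are printed to 3 decimal places —
enough to represent 0.005% exactly. The run-parameters report embeds the
full design, so feeding it back to the CLI as a config replays the sample
byte-for-byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING

from . import __version__
from .error_model import ErrorProfile

if TYPE_CHECKING:  # pragma: no cover
    from .design import ResolvedAbundance, SampleDesign

__all__ = ["ReportBundle", "abundance_report", "run_parameters_report", "write_reports"]


def abundance_report(
    resolved: "ResolvedAbundance", taxon_of=None
) -> list[dict]:
    """Rows of (organism, absolute_RA, relative_RA_percent, taxon) + totals.

    Relative percentages are rounded to 3 decimals; absolute counts sum to
    the sample total exactly.
    """
    if resolved.total <= 0:
        raise ValueError("cannot report abundances for an empty sample")
    rows = []
    for organism, count in resolved.counts.items():
        rows.append(
            {
                "organism": organism,
                "absolute_RA": count,
                "relative_RA_percent": round(count / resolved.total * 100, 3),
                "taxon": taxon_of(organism) if taxon_of else None,
            }
        )
    rows.append(
        {
            "organism": "TOTAL",
            "absolute_RA": resolved.total,
            "relative_RA_percent": round(
                sum(r["relative_RA_percent"] for r in rows), 3
            ),
            "taxon": None,
        }
    )
    return rows


def run_parameters_report(
    design: "SampleDesign",
    profile: ErrorProfile,
    resolved: "ResolvedAbundance",
    seed: int,
) -> dict:
    """Complete replayable run record; a superset of the design schema."""
    from .design import design_to_dict

    record = design_to_dict(design)
    record["seed"] = seed  # effective seed wins over the design-file one
    record["profile"] = profile.name if profile.name in _preset_names() else record["profile"]
    record.update(
        {
            "tool": "nanomock",
            "tool_version": __version__,
            "resolved_abundance": dict(resolved.counts),
        }
    )
    return record


def _preset_names() -> set[str]:
    from .error_model import PRESETS

    return set(PRESETS)


@dataclass(frozen=True)
class ReportBundle:
    """Everything reported about one generated sample."""

    sample_name: str
    abundance: list[dict]
    error_profile: dict
    error_distribution: dict
    run_parameters: dict
    resolved_counts: dict[str, int]
    total_reads: int

    @classmethod
    def build(
        cls,
        design: "SampleDesign",
        profile: ErrorProfile,
        resolved: "ResolvedAbundance",
        error_summary: dict,
        seed: int,
    ) -> "ReportBundle":
        rows = abundance_report(resolved, taxon_of=design.taxon_of)
        rel_sum = rows[-1]["relative_RA_percent"]
        assert abs(rel_sum - 100.0) <= 0.01, rel_sum  # rounding-only slack
        return cls(
            sample_name=design.sample_name,
            abundance=rows,
            error_profile=profile.to_dict(),
            error_distribution=error_summary,
            run_parameters=run_parameters_report(design, profile, resolved, seed),
            resolved_counts=dict(resolved.counts),
            total_reads=resolved.total,
        )


def _write_tsv(path: Path, rows: list[dict], columns: list[str]) -> None:
    with open(path, "wt") as fh:
        fh.write("\t".join(columns) + "\n")
        for row in rows:
            fh.write(
                "\t".join("" if row.get(c) is None else str(row.get(c)) for c in columns)
                + "\n"
            )


def write_reports(bundle: ReportBundle, outdir: str | Path) -> list[Path]:
    """Write the report files next to the sample FASTA; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    stem = bundle.sample_name
    paths = []

    p = outdir / f"{stem}_abundance.tsv"
    _write_tsv(p, bundle.abundance, ["organism", "absolute_RA", "relative_RA_percent", "taxon"])
    paths.append(p)
    p = outdir / f"{stem}_abundance.json"
    p.write_text(json.dumps(bundle.abundance, indent=2) + "\n")
    paths.append(p)

    p = outdir / f"{stem}_error_profile.json"
    p.write_text(json.dumps(bundle.error_profile, indent=2) + "\n")
    paths.append(p)

    dist = bundle.error_distribution
    rows = [
        {"organism": org, **stats} for org, stats in dist.get("per_organism", {}).items()
    ]
    rows.append({"organism": "TOTAL", **{k: v for k, v in dist.items() if k != "per_organism"}})
    p = outdir / f"{stem}_error_distribution.tsv"
    _write_tsv(
        p,
        rows,
        [
            "organism", "n_reads", "template_bases", "n_sub", "n_ins", "n_del",
            "rate_sub", "rate_ins", "rate_del", "accuracy",
        ],
    )
    paths.append(p)
    p = outdir / f"{stem}_error_distribution.json"
    p.write_text(json.dumps(dist, indent=2) + "\n")
    paths.append(p)

    p = outdir / f"{stem}_run_parameters.json"
    p.write_text(json.dumps(bundle.run_parameters, indent=2) + "\n")
    paths.append(p)
    return paths
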