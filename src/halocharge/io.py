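"""Readers, writers and run configuration.

Formats are deliberately plain: FASTA for sequences (Biopython underneath),
tab-separated tables for strain metadata and results, JSON for the trend
report.  Every result file starts with a one-line provenance header
recording the tool version and the resolved run parameters, so a rerun with
the same configuration reproduces the file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import __version__
from .charge import ACIDITY_CUTOFF, DEFAULT_PH, DEFAULT_SCALE, ProteinSequence
from .halotolerance import HalotoleranceClass, SaltRange, StrainMetadata
from .profiling import ProteomeComparison, StrainProfile, TrendReport

__all__ = [
    "RunConfig",
    "FastaParseError",
    "MetadataError",
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "write_strain_profiles",
    "read_strain_profiles",
    "write_comparisons",
    "write_trend_report",
    "provenance_line",
]

METADATA_COLUMNS = [
    "strain_id",
    "domain",
    "required_min_pct",
    "optimal_low_pct",
    "optimal_high_pct",
    "tolerated_max_pct",
    "grows_at_low_salt",
    "class_override",
]


class FastaParseError(ValueError):
    """Raised for malformed FASTA input, with the offending line number."""


class MetadataError(ValueError):
    """Raised for malformed strain metadata tables."""


@dataclass
class RunConfig:
    """Resolved parameters of one pipeline run (written into every output)."""

    ph: float = DEFAULT_PH
    scale_name: str = DEFAULT_SCALE
    cutoff: float = ACIDITY_CUTOFF
    seed: int = 0
    free_termini: bool = True

    def as_provenance(self) -> dict:
        return {
            "halocharge": __version__,
            "scale": self.scale_name,
            "ph": self.ph,
            "cutoff": self.cutoff,
            "seed": self.seed,
            "free_termini": self.free_termini,
        }


def provenance_line(config: Optional[RunConfig] = None, **extra) -> str:
    """``# key=value`` provenance header (no timestamp: reruns are identical)."""
    fields = (config or RunConfig()).as_provenance()
    fields.update(extra)
    return "# " + "\t".join(f"{k}={v}" for k, v in fields.items())


def read_fasta(path: Union[str, Path], has_free_termini: bool = True) -> list[ProteinSequence]:
    """Read a (wrapped or unwrapped) protein FASTA into validated sequences.

    The first header token becomes the record id; the remainder is kept as
    the annotation string used for r-protein name matching.
    """
    path = Path(path)
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}:{lineno}: expected '>' header before sequence data"
                )
            break
        else:
            raise FastaParseError(f"{path}: empty file, no FASTA records")

    records: list[ProteinSequence] = []
    with open(path, encoding="utf-8") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            parts = rec.description.split(maxsplit=1)
            annotation = parts[1] if len(parts) > 1 else ""
            try:
                records.append(
                    ProteinSequence(
                        id=rec.id,
                        residues=str(rec.seq),
                        has_free_termini=has_free_termini,
                        annotation=annotation,
                    )
                )
            except ValueError as exc:
                raise FastaParseError(f"{path}: record {rec.id!r}: {exc}") from exc
    if not records:
        raise FastaParseError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: Iterable[ProteinSequence], path: Union[str, Path], width: int = 60) -> Path:
    """Write sequences as wrapped FASTA; round-trips losslessly via read_fasta."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.annotation) for r in records
    ]
    with open(path, "w", encoding="utf-8", newline="\n") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)
    return path


def _parse_pct(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    text = str(value).strip().rstrip("%").strip()
    if text == "" or text.upper() in {"NA", "NAN", "NONE"}:
        return None
    return float(text)


def _parse_bool(value) -> bool:
    text = str(value).strip().lower()
    if text in {"true", "1", "yes", "y"}:
        return True
    if text in {"false", "0", "no", "n", "", "na", "nan", "none"}:
        return False
    raise MetadataError(f"cannot interpret {value!r} as a boolean")


def read_metadata(path: Union[str, Path]) -> list[StrainMetadata]:
    """Read the strain metadata TSV into typed rows (nulls preserved).

    The header must use exactly the documented column names; unknown
    columns are an error rather than silently ignored.  Percent values may
    carry a trailing ``%``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    unknown = set(df.columns) - set(METADATA_COLUMNS)
    if unknown:
        raise MetadataError(
            f"{path}: unknown metadata column(s): {', '.join(sorted(unknown))}; "
            f"expected a subset of {METADATA_COLUMNS}"
        )
    for required in ("strain_id", "domain"):
        if required not in df.columns:
            raise MetadataError(f"{path}: missing required column {required!r}")

    rows: list[StrainMetadata] = []
    for _, row in df.iterrows():
        try:
            salt = SaltRange(
                required_min=_parse_pct(row.get("required_min_pct")),
                optimal_low=_parse_pct(row.get("optimal_low_pct")),
                optimal_high=_parse_pct(row.get("optimal_high_pct")),
                tolerated_max=_parse_pct(row.get("tolerated_max_pct")),
                grows_at_low_salt=_parse_bool(row.get("grows_at_low_salt", False)),
            )
        except ValueError as exc:
            raise MetadataError(f"{path}: strain {row['strain_id']!r}: {exc}") from exc
        override_raw = row.get("class_override")
        override = None
        if override_raw is not None and str(override_raw).strip() not in {"", "nan", "NA"}:
            override = HalotoleranceClass(str(override_raw).strip())
        rows.append(
            StrainMetadata(
                strain_id=str(row["strain_id"]),
                domain=str(row["domain"]),
                salt=salt,
                class_override=override,
            )
        )
    return rows


def _fmt(value, nd: int = 6) -> str:
    if value is None:
        return ""
    if isinstance(value, float):
        return f"{value:.{nd}g}"
    return str(value)


def write_metadata(
    rows: Sequence[StrainMetadata], path: Union[str, Path], config: Optional[RunConfig] = None
) -> Path:
    """Write strain metadata in the schema read_metadata expects."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [provenance_line(config), "\t".join(METADATA_COLUMNS)]
    for m in rows:
        lines.append(
            "\t".join(
                [
                    m.strain_id,
                    m.domain,
                    _fmt(m.salt.required_min),
                    _fmt(m.salt.optimal_low),
                    _fmt(m.salt.optimal_high),
                    _fmt(m.salt.tolerated_max),
                    str(m.salt.grows_at_low_salt).lower(),
                    m.class_override.value if m.class_override else "",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def write_strain_profiles(
    profiles: Sequence[StrainProfile], path: Union[str, Path], config: Optional[RunConfig] = None
) -> Path:
    """Long-format per-protein charge table, one row per (strain, member)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [
        "strain_id", "domain", "halotolerance_class", "salt_score_pct",
        "protein", "length", "scale", "ph", "net_charge", "acidity_label",
        "n_ambiguous", "n_found", "n_acidic", "missing",
    ]
    lines = [provenance_line(config), "\t".join(header)]
    for p in profiles:
        klass = p.halotolerance_class.value if p.halotolerance_class else ""
        missing = ",".join(p.missing)
        from .catalog import roster_order

        for member in roster_order(p.charges):
            c = p.charges[member]
            lines.append(
                "\t".join(
                    [
                        p.strain_id, p.domain, klass, _fmt(p.salt_score),
                        member, str(c.length), c.scale_name, _fmt(c.ph),
                        f"{c.net_charge:.4f}", c.acidity_label,
                        str(c.n_ambiguous), str(p.n_found), str(p.n_acidic), missing,
                    ]
                )
            )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def read_strain_profiles(path: Union[str, Path]) -> list[StrainProfile]:
    """Rebuild StrainProfile objects from a write_strain_profiles table."""
    from .charge import ChargeResult

    df = pd.read_csv(path, sep="\t", comment="#")
    profiles = []
    for strain_id, group in df.groupby("strain_id", sort=False):
        first = group.iloc[0]
        charges = {}
        for _, row in group.iterrows():
            charges[row["protein"]] = ChargeResult(
                protein_id=f"{strain_id}_{row['protein']}",
                ph=float(row["ph"]),
                scale_name=str(row["scale"]),
                net_charge=float(row["net_charge"]),
                acidity_label=str(row["acidity_label"]),
                length=int(row["length"]),
                n_ambiguous=int(row["n_ambiguous"]),
            )
        missing = (
            str(first["missing"]).split(",")
            if isinstance(first["missing"], str) and str(first["missing"]).strip()
            else []
        )
        klass = (
            HalotoleranceClass(first["halotolerance_class"])
            if isinstance(first["halotolerance_class"], str) and first["halotolerance_class"]
            else None
        )
        profiles.append(
            StrainProfile(
                strain_id=str(strain_id),
                domain=str(first["domain"]),
                halotolerance_class=klass,
                charges=charges,
                n_found=int(first["n_found"]),
                n_acidic=int(first["n_acidic"]),
                missing=missing,
                salt_score=float(first["salt_score_pct"]) if pd.notna(first["salt_score_pct"]) else None,
            )
        )
    return profiles


def write_comparisons(
    comparisons: Sequence[ProteomeComparison],
    path: Union[str, Path],
    config: Optional[RunConfig] = None,
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    header = [
        "strain_id", "n_cluster", "n_rest", "cluster_mean_charge",
        "cluster_median_charge", "rest_mean_charge", "rest_median_charge",
        "fraction_rest_negative",
    ]
    lines = [provenance_line(config), "\t".join(header)]
    for c in comparisons:
        lines.append(
            "\t".join(
                [
                    c.strain_id, str(c.n_cluster), str(c.n_rest),
                    f"{c.cluster_mean_charge:.4f}", f"{c.cluster_median_charge:.4f}",
                    f"{c.rest_mean_charge:.4f}", f"{c.rest_median_charge:.4f}",
                    f"{c.fraction_rest_negative:.4f}",
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n", encoding="utf-8", newline="\n")
    return path


def write_trend_report(
    report: TrendReport, path: Union[str, Path], config: Optional[RunConfig] = None
) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "provenance": (config or RunConfig()).as_provenance(),
        "trend": report.to_dict(),
    }
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n", encoding="utf-8")
    return path
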