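"""Roster of the S10-spc cluster ribosomal proteins and name normalization.

Twenty-one universally conserved r-proteins are encoded by the two adjacent
clusters equivalent to the E. coli *S10* and *spc* operons; the equivalent
cluster in Archaea and Eukarya carries four additional r-protein genes.  The
roster (per domain of life, in operon order) and the legacy-name synonym
table live in an editable YAML file shipped with the package
(``data/s10_spc_roster.yaml``), so corrections are data edits, not code
changes.

Annotation strings from proteome FASTA headers ("50S ribosomal protein L2",
"ribosomal protein L10e", gene tags like "rplB", ...) are mapped to universal
(u/b/e)(L/S)<n> names by case-insensitive word-boundary matching against the
synonym table; anything unmatched is reported as no-match rather than
guessed.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

from .charge import ProteinSequence

__all__ = [
    "RProteinID",
    "ClusterRoster",
    "ExtractionResult",
    "CatalogError",
    "ClusterExtractionError",
    "DOMAINS",
    "load_catalog",
    "roster_for",
    "normalize_name",
    "extract_cluster_proteins",
    "roster_order",
]

logger = logging.getLogger(__name__)

DOMAINS = ("Bacteria", "Archaea", "Eukarya")

_UNIVERSAL_RE = re.compile(r"^(u|b|e)(L|S)\d+$")


class CatalogError(ValueError):
    """Raised for malformed roster data or unknown domains."""


class ClusterExtractionError(ValueError):
    """Raised when a proteome yields no roster member at all."""


@dataclass(frozen=True)
class RProteinID:
    """One roster entry: a universal name plus its legacy synonyms."""

    universal_name: str
    synonyms: frozenset[str] = frozenset()
    non_rprotein: bool = False

    def __post_init__(self) -> None:
        if not self.non_rprotein and not _UNIVERSAL_RE.match(self.universal_name):
            raise CatalogError(
                f"universal name {self.universal_name!r} does not match (u|b|e)(L|S)<integer>"
            )

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.universal_name


@dataclass(frozen=True)
class ClusterRoster:
    """The ordered S10-spc roster for one domain of life."""

    domain: str
    members: tuple[RProteinID, ...]
    optional_members: tuple[RProteinID, ...] = ()

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(m.universal_name for m in self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, name: str) -> bool:
        return name in self.member_names


class _Catalog:
    """Parsed roster file plus a compiled synonym matcher."""

    def __init__(self, raw: dict):
        self.entries: dict[str, RProteinID] = {}
        seen: dict[str, str] = {}
        for name, info in raw["members"].items():
            info = info or {}
            synonyms = tuple(str(s) for s in info.get("synonyms", ()))
            entry = RProteinID(
                universal_name=name,
                synonyms=frozenset(synonyms),
                non_rprotein=bool(info.get("non_rprotein", False)),
            )
            for syn in synonyms + (name,):
                key = syn.lower()
                if key in seen:
                    raise CatalogError(
                        f"synonym {syn!r} appears under both {seen[key]!r} and {name!r}"
                    )
                seen[key] = name
            self.entries[name] = entry

        self.rosters: dict[str, ClusterRoster] = {}
        for domain, spec in raw["domains"].items():
            members = tuple(self._entry(m) for m in spec["members"])
            optional = tuple(self._entry(m) for m in spec.get("optional_members", ()))
            self.rosters[domain] = ClusterRoster(domain, members, optional)

        # One alternation regex, longest synonyms first, so a single search
        # resolves an annotation.  Boundaries exclude letters and digits on
        # both sides ("L2" must not fire inside "L23").
        pairs = []
        for name, entry in self.entries.items():
            for syn in set(entry.synonyms) | {name}:
                pairs.append((syn, name))
        pairs.sort(key=lambda p: (-len(p[0]), p[0]))
        self._text_to_name = {syn.lower(): name for syn, name in pairs}
        alternation = "|".join(re.escape(syn) for syn, _ in pairs)
        self._pattern = re.compile(
            rf"(?<![A-Za-z0-9])({alternation})(?![A-Za-z0-9])", re.IGNORECASE
        )

    def _entry(self, name: str) -> RProteinID:
        try:
            return self.entries[name]
        except KeyError:
            raise CatalogError(f"domain roster references unknown member {name!r}") from None

    def normalize(self, annotation: str) -> Optional[RProteinID]:
        m = self._pattern.search(annotation)
        if m is None:
            return None
        return self.entries[self._text_to_name[m.group(1).lower()]]


@lru_cache(maxsize=4)
def load_catalog(path: Optional[str] = None) -> _Catalog:
    """Load the roster/synonym catalog (the shipped YAML by default)."""
    if path is None:
        text = resources.files("halocharge.data").joinpath("s10_spc_roster.yaml").read_text()
    else:
        text = Path(path).read_text()
    raw = yaml.safe_load(text)
    if not isinstance(raw, dict) or "members" not in raw or "domains" not in raw:
        raise CatalogError("roster file must define 'members' and 'domains'")
    return _Catalog(raw)


def roster_for(domain: str, include_optional: bool = False, path: Optional[str] = None) -> ClusterRoster:
    """The fixed S10-spc roster for ``domain`` (Bacteria/Archaea/Eukarya).

    ``include_optional=True`` appends optional non-r-protein members (the
    eukaryal RNP1 entry) to the returned roster.
    """
    catalog = load_catalog(path)
    try:
        roster = catalog.rosters[domain]
    except KeyError:
        raise CatalogError(
            f"unknown domain {domain!r}; expected one of {', '.join(DOMAINS)}"
        ) from None
    if include_optional and roster.optional_members:
        return ClusterRoster(
            roster.domain, roster.members + roster.optional_members, ()
        )
    return roster


def normalize_name(annotation: str, path: Optional[str] = None) -> Optional[RProteinID]:
    """Map a free-text product/gene annotation to a roster entry, or None.

    >>> normalize_name("50S ribosomal protein L2").universal_name
    'uL2'
    """
    return load_catalog(path).normalize(annotation)


@dataclass
class ExtractionResult:
    """Cluster proteins pulled from an annotated proteome.

    ``proteins`` maps universal names to the selected record (at most one per
    roster member; annotation duplicates resolve to the longest sequence with
    a logged warning).  ``missing`` lists roster members not found.
    """

    proteins: dict[str, ProteinSequence]
    missing: list[str]
    duplicates: dict[str, int] = field(default_factory=dict)

    @property
    def n_found(self) -> int:
        return len(self.proteins)


def extract_cluster_proteins(
    proteome: Iterable[ProteinSequence],
    roster: Union[ClusterRoster, str],
) -> ExtractionResult:
    """Select the S10-spc cluster members from an annotated proteome.

    Records are matched on their ``annotation`` string (falling back to the
    record id).  Raises :class:`ClusterExtractionError` when not a single
    roster member is found.
    """
    if isinstance(roster, str):
        roster = roster_for(roster)
    catalog = load_catalog()
    wanted = set(roster.member_names)
    found: dict[str, ProteinSequence] = {}
    duplicates: dict[str, int] = {}
    for record in proteome:
        entry = catalog.normalize(record.annotation or record.id)
        if entry is None or entry.universal_name not in wanted:
            continue
        name = entry.universal_name
        if name in found:
            duplicates[name] = duplicates.get(name, 1) + 1
            keep = record if len(record) > len(found[name]) else found[name]
            logger.warning(
                "duplicate annotation for %s: keeping longest sequence %r (%d aa)",
                name,
                keep.id,
                len(keep),
            )
            found[name] = keep
        else:
            found[name] = record
    if not found:
        raise ClusterExtractionError(
            "not a usable proteome: no S10-spc cluster member could be identified"
        )
    missing = [m for m in roster.member_names if m not in found]
    return ExtractionResult(proteins=found, missing=missing, duplicates=duplicates)


def roster_order(names: Iterable[str]) -> list[str]:
    """Order arbitrary member names by canonical (eukaryal superset) operon order."""
    full = list(roster_for("Eukarya", include_optional=True).member_names)
    rank = {n: i for i, n in enumerate(full)}
    names = list(names)
    return sorted(names, key=lambda n: (rank.get(n, len(full)), n))
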