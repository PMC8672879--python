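"""Synthetic proteomes spanning the halotolerance spectrum.

The generator emulates the two compositional signals the charge analysis
rests on: (a) halophile proteomes are enriched in acidic residues (D/E) at
the expense of basic ones (K/R), increasingly so with halophilicity, and
(b) the S10-spc cluster r-proteins start from a strongly basic (K/R-boosted)
composition in non-halophiles and lose that charge as halophilicity rises.

A strain is parameterized by a halophilicity ``h`` in [0, 1].  Cluster
proteins are drawn i.i.d. from

    base composition  +  rprotein_basic_boost * (1 - h)  on {K, R}
                      -  acid_shift * h moved from {K, R} to {D, E}

and the rest of the proteome from the base composition with the same
``acid_shift * h`` mass moved from {K, R} to {D, E}.  Compositions are
clipped at zero and renormalized.  The salt-range metadata is a monotone
(piecewise) function of ``h`` chosen so that each fifth of the h axis maps
to one of the five halotolerance classes; it exists to exercise the
classifier, not to model physiology.

Everything is driven by a single integer seed; the same seed reproduces the
same study byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .catalog import ClusterRoster, roster_for
from .charge import ProteinSequence
from .halotolerance import SaltRange, StrainMetadata

__all__ = [
    "AA_ORDER",
    "BASE_COMPOSITION",
    "GeneratorConfig",
    "Strain",
    "Study",
    "CLASS_BANDS",
    "cluster_composition",
    "background_composition",
    "salt_range_for",
    "make_strain",
    "make_study",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
_LUT = np.frombuffer(AA_ORDER.encode("ascii"), dtype=np.uint8)

#: Average amino-acid frequencies of well-annotated proteins (SwissProt
#: background), renormalized to sum to one.
BASE_COMPOSITION: dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0138,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: h-bands mapping to the five halotolerance classes, in order of
#: increasing maximum salt exposure.
CLASS_BANDS: tuple[tuple[float, float, str], ...] = (
    (0.0, 0.2, "non_halophile"),
    (0.2, 0.4, "halotolerant"),
    (0.4, 0.6, "moderate_halophile"),
    (0.6, 0.8, "extremely_halotolerant"),
    (0.8, 1.0, "extreme_halophile"),
)


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic study.

    ``acid_shift`` is the probability mass moved from {K,R} to {D,E} at
    h=1; ``rprotein_basic_boost`` the extra {K,R} mass given to cluster
    proteins at h=0.  ``always_basic_member`` optionally pins one roster
    member to the h=0 cluster composition at every h (a synthetic stand-in
    for the empirically never-acidic uL2).
    """

    seed: int = 0
    n_strains_per_class: int = 4
    base_composition: Mapping[str, float] = field(default_factory=lambda: dict(BASE_COMPOSITION))
    acid_shift: float = 0.06
    rprotein_basic_boost: float = 0.15
    length_range: tuple[int, int] = (90, 260)
    proteome_size: int = 200
    proteome_length_range: tuple[int, int] = (80, 400)
    domain: str = "Bacteria"
    always_basic_member: Optional[str] = None

    def __post_init__(self) -> None:
        try:
            comp = np.array([self.base_composition[aa] for aa in AA_ORDER], dtype=float)
        except KeyError as exc:
            raise ValueError(f"base_composition is missing residue {exc}") from None
        if np.any(comp < 0) or not comp.sum() > 0:
            raise ValueError(
                "base_composition must be non-negative over the 20 residues "
                "(it is renormalized to a probability vector)"
            )
        if not 0.0 <= self.acid_shift <= 1.0 or not 0.0 <= self.rprotein_basic_boost <= 1.0:
            raise ValueError("acid_shift and rprotein_basic_boost must lie in [0, 1]")
        for lo, hi in (self.length_range, self.proteome_length_range):
            if lo < 1 or hi < lo:
                raise ValueError("length ranges must satisfy 1 <= lo <= hi")
        if self.n_strains_per_class < 1:
            raise ValueError("n_strains_per_class must be >= 1")
        if self.proteome_size < 1:
            raise ValueError("proteome_size must be >= 1")

    def _base_vector(self) -> np.ndarray:
        comp = np.array([self.base_composition[aa] for aa in AA_ORDER], dtype=float)
        return comp / comp.sum()


def _shift_kr_to_de(comp: np.ndarray, mass: float) -> np.ndarray:
    """Move ``mass`` of probability from {K,R} to {D,E}, clipping at zero."""
    comp = comp.copy()
    k, r, d, e = (_AA_INDEX[a] for a in "KRDE")
    available = comp[k] + comp[r]
    take = min(mass, available)
    if available > 0:
        frac = take / available
        taken_k, taken_r = comp[k] * frac, comp[r] * frac
        comp[k] -= taken_k
        comp[r] -= taken_r
        de_total = comp[d] + comp[e]
        if de_total > 0:
            comp[d] += take * comp[d] / de_total
            comp[e] += take * comp[e] / de_total
        else:  # degenerate base with no D/E mass: split evenly
            comp[d] += take / 2
            comp[e] += take / 2
    comp = np.clip(comp, 0.0, None)
    return comp / comp.sum()


def cluster_composition(config: GeneratorConfig, h: float) -> np.ndarray:
    """Residue composition of cluster r-proteins at halophilicity ``h``."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"halophilicity h must lie in [0, 1], got {h}")
    comp = config._base_vector()
    boost = config.rprotein_basic_boost * (1.0 - h)
    k, r = _AA_INDEX["K"], _AA_INDEX["R"]
    kr = comp[k] + comp[r]
    comp[k] += boost * comp[k] / kr
    comp[r] += boost * comp[r] / kr
    comp = comp / comp.sum()
    return _shift_kr_to_de(comp, config.acid_shift * h)


def background_composition(config: GeneratorConfig, h: float) -> np.ndarray:
    """Residue composition of the non-cluster proteome at halophilicity ``h``."""
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"halophilicity h must lie in [0, 1], got {h}")
    return _shift_kr_to_de(config._base_vector(), config.acid_shift * h)


def salt_range_for(h: float) -> SaltRange:
    """Map halophilicity ``h`` to a salt-range row.

    Piecewise over the five h-bands; tolerated_max rises monotonically from
    2% (h=0) to 30% and required_min reaches 20% at h=1, so classification
    recovers one class per band without overrides.
    """
    if not 0.0 <= h <= 1.0:
        raise ValueError(f"halophilicity h must lie in [0, 1], got {h}")
    for lo, hi, label in CLASS_BANDS:
        if lo <= h < hi or (h == 1.0 and hi == 1.0):
            t = (h - lo) / (hi - lo)
            break
    if label == "non_halophile":
        return SaltRange(optimal_low=0.0, optimal_high=0.5 + 0.5 * t,
                         tolerated_max=1.0 + 1.0 * t, grows_at_low_salt=True)
    if label == "halotolerant":
        return SaltRange(optimal_low=1.0, optimal_high=3.0,
                         tolerated_max=4.0 + 5.0 * t, grows_at_low_salt=True)
    if label == "moderate_halophile":
        return SaltRange(required_min=3.0, optimal_low=5.0, optimal_high=12.0,
                         tolerated_max=12.0 + 1.0 * t, grows_at_low_salt=False)
    if label == "extremely_halotolerant":
        return SaltRange(optimal_low=2.0, optimal_high=10.0,
                         tolerated_max=16.0 + 9.0 * t, grows_at_low_salt=True)
    # extreme_halophile
    req = 12.0 + 8.0 * t
    return SaltRange(required_min=req, optimal_low=req, optimal_high=req + 4.0,
                     tolerated_max=26.0 + 4.0 * t, grows_at_low_salt=False)


@dataclass
class Strain:
    """One synthetic strain: annotated records plus its metadata row."""

    strain_id: str
    h: float
    records: list[ProteinSequence]
    metadata: StrainMetadata
    cluster_record_ids: frozenset[str]


@dataclass
class Study:
    """A panel of synthetic strains spanning all five classes."""

    config: GeneratorConfig
    strains: list[Strain]

    @property
    def metadata(self) -> list[StrainMetadata]:
        return [s.metadata for s in self.strains]


def _draw_proteins(rng: np.random.Generator, comp: np.ndarray, lengths: np.ndarray) -> list[str]:
    total = int(lengths.sum())
    codes = rng.choice(20, size=total, p=comp)
    seq_bytes = _LUT[codes].tobytes().decode("ascii")
    out, pos = [], 0
    for n in lengths:
        out.append(seq_bytes[pos:pos + int(n)])
        pos += int(n)
    return out


def _annotation_for(member, domain: str) -> str:
    """A realistic product annotation using a legacy synonym."""
    synonyms = sorted(member.synonyms, key=len)
    legacy = synonyms[0] if synonyms else member.universal_name
    subunit = "30S" if "S" in member.universal_name[1:] else "50S"
    if domain == "Eukarya":
        subunit = "40S" if subunit == "30S" else "60S"
    return f"{subunit} ribosomal protein {legacy}"


def make_strain(
    config: GeneratorConfig,
    h: float,
    *,
    index: int = 0,
    strain_id: Optional[str] = None,
) -> Strain:
    """Generate one strain at halophilicity ``h``.

    Deterministic in (config.seed, index, h): the same arguments reproduce
    the same records byte for byte.
    """
    seed = int(config.seed) % (2**31)
    rng = np.random.default_rng([seed, int(index), int(round(h * 1_000_000))])
    if strain_id is None:
        strain_id = f"syn{index:03d}_h{int(round(h * 100)):03d}"
    roster: ClusterRoster = roster_for(config.domain)

    comp_cluster = cluster_composition(config, h)
    comp_rest = background_composition(config, h)

    lo, hi = config.length_range
    lengths = rng.integers(lo, hi + 1, size=len(roster))
    sequences = _draw_proteins(rng, comp_cluster, lengths)

    records: list[ProteinSequence] = []
    for i, member in enumerate(roster.members):
        seq = sequences[i]
        if config.always_basic_member == member.universal_name:
            pinned = np.random.default_rng(
                [seed, int(index), int(round(h * 1_000_000)), 7 + i]
            )
            seq = _draw_proteins(pinned, cluster_composition(config, 0.0),
                                 np.array([lengths[i]]))[0]
        annotation = _annotation_for(member, config.domain)
        if i == 0:
            # study provenance rides along in the first record's header
            annotation = f"{annotation} [seed={seed}]"
        records.append(
            ProteinSequence(
                id=f"{strain_id}_{member.universal_name}",
                residues=seq,
                annotation=annotation,
            )
        )
    cluster_ids = frozenset(r.id for r in records)

    plo, phi = config.proteome_length_range
    rest_lengths = rng.integers(plo, phi + 1, size=config.proteome_size)
    for j, seq in enumerate(_draw_proteins(rng, comp_rest, rest_lengths)):
        records.append(
            ProteinSequence(
                id=f"{strain_id}_p{j:04d}",
                residues=seq,
                annotation="hypothetical protein",
            )
        )

    metadata = StrainMetadata(strain_id=strain_id, domain=config.domain, salt=salt_range_for(h))
    return Strain(strain_id=strain_id, h=h, records=records,
                  metadata=metadata, cluster_record_ids=cluster_ids)


def make_study(config: GeneratorConfig, h_values: Optional[Sequence[float]] = None) -> Study:
    """Generate a strain panel spanning all five halotolerance classes.

    By default each class band contributes ``n_strains_per_class`` strains
    with h spread evenly inside the band; an explicit ``h_values`` sequence
    overrides the sweep.
    """
    if h_values is None:
        h_values = []
        n = config.n_strains_per_class
        for lo, hi, _label in CLASS_BANDS:
            for j in range(n):
                h_values.append(lo + (j + 0.5) * (hi - lo) / n)
    strains = [
        make_strain(config, h, index=i) for i, h in enumerate(h_values)
    ]
    return Study(config=config, strains=strains)
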