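"""Salt-tolerance classification after the Kushner/Kamekura/Ventosa scheme.

Strains are described by their NaCl requirement/tolerance (percent w/v,
convertible to molar via the NaCl formula weight) and assigned one of five
classes:

* **moderate halophile** — grows optimally between 0.5 M and 2.5 M salt;
* **halotolerant** — grows from low salt over a (bounded) range;
* **extremely halotolerant** — grows from low salt up beyond 2.5 M;
* **extreme halophile** — requires at least 2 M salt for growth;
* **non-halophile** — everything confined to low salt.

The literature scheme leaves overlaps open (a strain may satisfy both the
"moderate" and the "halotolerant" descriptors); the decision order below
resolves them, with requirement-based rules outranking tolerance-based ones
because obligate salt requirement is the defining trait of extreme
halophiles.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional

__all__ = [
    "NACL_FW",
    "SATURATION_PCT",
    "MODERATE_OPTIMUM_M",
    "EXTREME_REQUIRED_MIN_M",
    "EXTREMELY_HALOTOLERANT_MIN_M",
    "LOW_SALT_MAX_M",
    "EMPIRICAL_BREAKPOINT_PCT",
    "SaltRange",
    "HalotoleranceClass",
    "StrainMetadata",
    "InsufficientSaltDataError",
    "percent_to_molar",
    "molar_to_percent",
    "classify",
    "salt_score",
]

#: Formula weight of NaCl, g/mol.
NACL_FW = 58.44
#: NaCl saturation in water, percent w/v; upper bound for any stated range.
SATURATION_PCT = 37.0

#: Optimal-growth window defining moderate halophiles (molar).
MODERATE_OPTIMUM_M = (0.5, 2.5)
#: Minimum obligate requirement defining extreme halophiles (molar).
EXTREME_REQUIRED_MIN_M = 2.0
#: Tolerance ceiling beyond which a low-salt grower is *extremely* halotolerant.
EXTREMELY_HALOTOLERANT_MIN_M = 2.5
#: "Low salt": concentrations a non-halophile is confined to.  The scheme
#: itself states no number; 0.5 M (the lower edge of the moderate-halophile
#: optimum) is used.
LOW_SALT_MAX_M = 0.5

#: Empirical breakpoint of the charge analysis: cluster r-protein charges
#: stay mostly basic while tolerance rises to ~15% w/v and drop once
#: halotolerance extends above it.  Kept separate from the class boundaries.
EMPIRICAL_BREAKPOINT_PCT = 15.0


class InsufficientSaltDataError(ValueError):
    """Raised when every salt field of a strain is null."""


def percent_to_molar(p: float) -> float:
    """Convert percent w/v NaCl to mol/L: M = (p * 10) / 58.44."""
    if p < 0:
        raise ValueError(f"negative salt concentration: {p}")
    return p * 10.0 / NACL_FW


def molar_to_percent(m: float) -> float:
    """Inverse of :func:`percent_to_molar`."""
    if m < 0:
        raise ValueError(f"negative salt concentration: {m}")
    return m * NACL_FW / 10.0


class HalotoleranceClass(str, Enum):
    NON_HALOPHILE = "non_halophile"
    HALOTOLERANT = "halotolerant"
    MODERATE_HALOPHILE = "moderate_halophile"
    EXTREMELY_HALOTOLERANT = "extremely_halotolerant"
    EXTREME_HALOPHILE = "extreme_halophile"

    @property
    def ordinal(self) -> int:
        """Rank by increasing salt adaptation (used as a trend ordinal)."""
        order = [
            HalotoleranceClass.NON_HALOPHILE,
            HalotoleranceClass.HALOTOLERANT,
            HalotoleranceClass.MODERATE_HALOPHILE,
            HalotoleranceClass.EXTREMELY_HALOTOLERANT,
            HalotoleranceClass.EXTREME_HALOPHILE,
        ]
        return order.index(self)


@dataclass(frozen=True)
class SaltRange:
    """A strain's stated NaCl requirement/tolerance, percent w/v.

    Null fields mean "not reported".  Where present the fields must be
    ordered ``required_min <= optimal_low <= optimal_high <= tolerated_max``
    and lie within [0, saturation].
    """

    required_min: Optional[float] = None
    optimal_low: Optional[float] = None
    optimal_high: Optional[float] = None
    tolerated_max: Optional[float] = None
    grows_at_low_salt: bool = False

    def __post_init__(self) -> None:
        fields = {
            "required_min": self.required_min,
            "optimal_low": self.optimal_low,
            "optimal_high": self.optimal_high,
            "tolerated_max": self.tolerated_max,
        }
        for name, value in fields.items():
            if value is not None and not 0.0 <= value <= SATURATION_PCT:
                raise ValueError(f"{name}={value} outside [0, {SATURATION_PCT}] % w/v")
        ordered = [v for v in fields.values() if v is not None]
        if any(a > b + 1e-9 for a, b in zip(ordered, ordered[1:])):
            raise ValueError(
                "salt fields must satisfy required_min <= optimal_low <= "
                f"optimal_high <= tolerated_max, got {fields}"
            )

    @property
    def all_null(self) -> bool:
        return all(
            v is None
            for v in (self.required_min, self.optimal_low, self.optimal_high, self.tolerated_max)
        )


def classify(salt: SaltRange) -> HalotoleranceClass:
    """Assign the halotolerance class of a strain from its salt range.

    Decision order (first match wins):

    1. obligate requirement >= 2 M            -> extreme halophile
    2. grows at low salt, tolerates > 2.5 M   -> extremely halotolerant
    3. grows at low salt, tolerates > 0.5 M   -> halotolerant
    4. optimal range within [0.5 M, 2.5 M]    -> moderate halophile
    5. otherwise                              -> non-halophile
    """
    if salt.all_null:
        raise InsufficientSaltDataError("insufficient salt data: all fields are null")
    req_m = percent_to_molar(salt.required_min) if salt.required_min is not None else None
    tol_m = percent_to_molar(salt.tolerated_max) if salt.tolerated_max is not None else None
    opt_lo_m = percent_to_molar(salt.optimal_low) if salt.optimal_low is not None else None
    opt_hi_m = percent_to_molar(salt.optimal_high) if salt.optimal_high is not None else None

    if req_m is not None and req_m >= EXTREME_REQUIRED_MIN_M:
        return HalotoleranceClass.EXTREME_HALOPHILE
    if salt.grows_at_low_salt and tol_m is not None and tol_m > EXTREMELY_HALOTOLERANT_MIN_M:
        return HalotoleranceClass.EXTREMELY_HALOTOLERANT
    if salt.grows_at_low_salt and tol_m is not None and tol_m > LOW_SALT_MAX_M:
        return HalotoleranceClass.HALOTOLERANT
    if (
        opt_lo_m is not None
        and opt_hi_m is not None
        and opt_lo_m >= MODERATE_OPTIMUM_M[0]
        and opt_hi_m <= MODERATE_OPTIMUM_M[1]
    ):
        return HalotoleranceClass.MODERATE_HALOPHILE
    return HalotoleranceClass.NON_HALOPHILE


def salt_score(salt: SaltRange) -> Optional[float]:
    """A scalar "maximum salt exposure" (% w/v) used to rank strains.

    The largest stated concentration among tolerated_max, optimal_high and
    required_min; None when all are null.
    """
    candidates = [
        v for v in (salt.tolerated_max, salt.optimal_high, salt.required_min) if v is not None
    ]
    return max(candidates) if candidates else None


@dataclass(frozen=True)
class StrainMetadata:
    """One row of the strain metadata table."""

    strain_id: str
    domain: str
    salt: SaltRange
    class_override: Optional[HalotoleranceClass] = None

    def effective_class(self) -> HalotoleranceClass:
        """The override when present, otherwise the classified label."""
        if self.class_override is not None:
            return self.class_override
        return classify(self.salt)
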