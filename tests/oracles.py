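"""Independent reference computations the implementation is checked against.

These are deliberately written from first principles and share no code with
the package: a high-precision per-group Henderson-Hasselbalch summation in
Decimal arithmetic, and a fine grid scan for the isoelectric point.
"""

from collections import Counter
from decimal import Decimal, getcontext

import numpy as np

getcontext().prec = 50

_ACIDIC = ("D", "E", "C", "Y")
_BASIC = ("H", "K", "R")


def net_charge_decimal(residues: str, ph: float, scale, free_termini: bool = True) -> float:
    """Per-group charge summation at 50 significant digits."""
    counts = Counter(residues.upper())
    ph_d = Decimal(str(ph))
    ten = Decimal(10)

    def basic_term(n: int, pka: float) -> Decimal:
        return Decimal(n) / (1 + ten ** (ph_d - Decimal(str(pka))))

    def acidic_term(n: int, pka: float) -> Decimal:
        return Decimal(n) / (1 + ten ** (Decimal(str(pka)) - ph_d))

    z = Decimal(0)
    for aa in _BASIC:
        if counts[aa]:
            z += basic_term(counts[aa], scale.side_chain_pka[aa])
    for aa in _ACIDIC:
        if counts[aa]:
            z -= acidic_term(counts[aa], scale.side_chain_pka[aa])
    if free_termini:
        z += basic_term(1, scale.n_term_pka)
        z -= acidic_term(1, scale.c_term_pka)
    return float(z)


def isoelectric_point_grid(residues: str, scale, step: float = 1e-4) -> float:
    """pH minimizing |z| over a uniform grid on [0, 14]."""
    counts = Counter(residues.upper())
    ph = np.arange(0.0, 14.0 + step / 2, step)
    z = np.zeros_like(ph)
    for aa in _BASIC:
        if counts[aa]:
            z += counts[aa] / (1.0 + 10.0 ** (ph - scale.side_chain_pka[aa]))
    for aa in _ACIDIC:
        if counts[aa]:
            z -= counts[aa] / (1.0 + 10.0 ** (scale.side_chain_pka[aa] - ph))
    z += 1.0 / (1.0 + 10.0 ** (ph - scale.n_term_pka))
    z -= 1.0 / (1.0 + 10.0 ** (scale.c_term_pka - ph))
    return float(ph[np.argmin(np.abs(z))])
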