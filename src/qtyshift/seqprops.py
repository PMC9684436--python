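"""Molecular weight and isoelectric point, Expasy compute_pi style.

MW is the sum of average residue masses plus one water; pI is the root of
the Henderson-Hasselbalch net-charge function using the Bjellqvist pK set,
including the residue-specific terminal pK corrections that the Expasy
service applies. Alternate pK sets (EMBOSS, Lehninger) are selectable but
non-default.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import AlphabetError, ParameterError

# Average residue (monomer minus water) masses, Da.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886, "C": 103.1388,
    "E": 129.1155, "Q": 128.1307, "G": 57.0519, "H": 137.1411, "I": 113.1594,
    "L": 113.1594, "K": 128.1741, "M": 131.1926, "F": 147.1766, "P": 97.1167,
    "S": 87.0782, "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    "X": 110.0,   # mean residue mass for ambiguity code
}

WATER_MASS = 18.01524


@dataclass(frozen=True)
class ChargeModel:
    """pK table for ionizable groups.

    Defaults are the Bjellqvist values as used by Expasy's compute_pi:
    side chains D 4.05, E 4.45, C 9.0, Y 10.0, H 5.98, K 10.0, R 12.0;
    C-terminus 3.55 (4.55 after Asp, 4.75 after Glu); N-terminus 7.5 with
    residue-specific overrides (A 7.59, M 7.0, S 6.93, P 8.36, T 6.82,
    V 7.44, E 7.7).
    """

    acidic: dict[str, float] = field(
        default_factory=lambda: {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0}
    )
    basic: dict[str, float] = field(
        default_factory=lambda: {"H": 5.98, "K": 10.0, "R": 12.0}
    )
    pk_cterm: float = 3.55
    pk_nterm: float = 7.5
    pk_nterm_by_residue: dict[str, float] = field(
        default_factory=lambda: {
            "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82, "V": 7.44, "E": 7.7,
        }
    )
    pk_cterm_by_residue: dict[str, float] = field(
        default_factory=lambda: {"D": 4.55, "E": 4.75}
    )

    def __post_init__(self) -> None:
        for pk in (
            *self.acidic.values(), *self.basic.values(),
            self.pk_cterm, self.pk_nterm,
            *self.pk_nterm_by_residue.values(), *self.pk_cterm_by_residue.values(),
        ):
            if not 0.0 < pk < 14.0:
                raise ParameterError(f"pK {pk} outside (0, 14)")


#: EMBOSS iep pK set, selectable alternative.
EMBOSS_MODEL = ChargeModel(
    acidic={"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    basic={"H": 6.5, "K": 10.8, "R": 12.5},
    pk_cterm=3.6, pk_nterm=8.6,
    pk_nterm_by_residue={}, pk_cterm_by_residue={},
)

#: Lehninger textbook pK set, selectable alternative.
LEHNINGER_MODEL = ChargeModel(
    acidic={"D": 3.65, "E": 4.25, "C": 8.18, "Y": 10.07},
    basic={"H": 6.0, "K": 10.53, "R": 12.48},
    pk_cterm=2.34, pk_nterm=9.69,
    pk_nterm_by_residue={}, pk_cterm_by_residue={},
)

CHARGE_MODELS = {"bjellqvist": ChargeModel(), "emboss": EMBOSS_MODEL, "lehninger": LEHNINGER_MODEL}


@dataclass(frozen=True)
class SequenceProperties:
    mw_da: float
    pi: float
    length: int

    @property
    def mw_kda(self) -> float:
        return self.mw_da / 1000.0


def _validated(sequence: str) -> str:
    if not sequence:
        raise AlphabetError("empty sequence")
    bad = set(sequence) - set(AVERAGE_RESIDUE_MASS)
    if bad:
        raise AlphabetError(f"unknown residue letters: {sorted(bad)}")
    return sequence


def molecular_weight(sequence: str) -> float:
    """Average molecular mass in Daltons (residue masses + one water)."""
    seq = _validated(sequence)
    return sum(AVERAGE_RESIDUE_MASS[a] for a in seq) + WATER_MASS


def net_charge(sequence: str, ph: float, model: ChargeModel | None = None) -> float:
    """Net charge in elementary units at a given pH.

    Positive Henderson-Hasselbalch terms for K, R, H and the N-terminus;
    negative for D, E, C, Y and the C-terminus. X contributes nothing.
    Vectorized over ``ph`` when given an array.
    """
    seq = _validated(sequence)
    ph_arr = np.asarray(ph, dtype=float)
    if np.any((ph_arr < 0.0) | (ph_arr > 14.0)):
        raise ParameterError("pH outside [0, 14]")
    model = model or ChargeModel()

    def pos(pk: float, n: float = 1.0):
        return n / (1.0 + 10.0 ** (ph_arr - pk))

    def neg(pk: float, n: float = 1.0):
        return -n / (1.0 + 10.0 ** (pk - ph_arr))

    charge = pos(model.pk_nterm_by_residue.get(seq[0], model.pk_nterm))
    charge = charge + neg(model.pk_cterm_by_residue.get(seq[-1], model.pk_cterm))
    for aa, pk in model.basic.items():
        n = seq.count(aa)
        if n:
            charge = charge + pos(pk, n)
    for aa, pk in model.acidic.items():
        n = seq.count(aa)
        if n:
            charge = charge + neg(pk, n)
    return charge if np.ndim(ph) else float(charge)


def isoelectric_point(
    sequence: str, model: ChargeModel | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    The charge function is strictly decreasing in pH, so sign bisection is
    globally convergent; the bracket is narrowed until it is smaller than
    ``tol`` in pH (well below the 2-decimal reporting precision), which
    also drives |charge| at the returned pH to numerical zero.
    """
    seq = _validated(sequence)
    model = model or ChargeModel()
    lo, hi = 0.0, 14.0
    if net_charge(seq, lo, model) <= 0.0:
        return lo  # cannot happen with an N-terminus present, but be safe
    mid = 7.0
    while hi - lo > tol * 1e-2:
        mid = 0.5 * (lo + hi)
        q = net_charge(seq, mid, model)
        if q == 0.0:
            break
        if q > 0.0:
            lo = mid
        else:
            hi = mid
    return mid


def sequence_properties(sequence: str, model: ChargeModel | None = None) -> SequenceProperties:
    return SequenceProperties(
        mw_da=molecular_weight(sequence),
        pi=isoelectric_point(sequence, model),
        length=len(sequence),
    )


#: per-substitution average-mass deltas implied by the QTY code, Da
QTY_MASS_DELTA = {
    ("L", "Q"): AVERAGE_RESIDUE_MASS["Q"] - AVERAGE_RESIDUE_MASS["L"],
    ("I", "T"): AVERAGE_RESIDUE_MASS["T"] - AVERAGE_RESIDUE_MASS["I"],
    ("V", "T"): AVERAGE_RESIDUE_MASS["T"] - AVERAGE_RESIDUE_MASS["V"],
    ("F", "Y"): AVERAGE_RESIDUE_MASS["Y"] - AVERAGE_RESIDUE_MASS["F"],
}


def mw_delta_from_ledger(substitutions) -> float:
    """Closed-form MW(variant) - MW(native) from a substitution ledger."""
    return sum(
        AVERAGE_RESIDUE_MASS[dst] - AVERAGE_RESIDUE_MASS[src]
        for _, src, dst in substitutions
    )
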