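"""Peptide monoisotopic mass, multiply-charged m/z and molar conversions.

Targets the mass arithmetic of the ComX decapeptide (backbone ADPITRQWGD)
and its active, farnesylated form: the isoprenoid modification adds a net
C15H24 (+204.18780 Da) on the tryptophan indole.  Masses are sums of the
standard monoisotopic residue masses plus one water per peptide; m/z of an
[M + zH]^z+ ion is (M + z * 1.007276) / z.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DomainError, ValidationError

#: Monoisotopic residue masses [Da] of the 20 standard amino acids.
RESIDUE_MASSES = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

WATER_MASS = 18.010565
PROTON_MASS = 1.007276

#: Named modification mass deltas [Da].
MODIFICATIONS = {
    "farnesyl": 204.18780,  # net +C15H24 on the Trp indole
}

#: The unmodified ComX decapeptide backbone.
COMX_BACKBONE = "ADPITRQWGD"


@dataclass(frozen=True)
class PeptideSpec:
    """A peptide sequence with optional modifications and a charge state.

    ``modifications`` entries may be registered names ("farnesyl"), bare
    mass deltas in Da, or ``(name, delta)`` pairs.
    """

    sequence: str
    modifications: tuple = field(default_factory=tuple)
    charge: int = 1

    def __post_init__(self):
        if not self.sequence:
            raise ValidationError("sequence must be non-empty")
        bad = set(self.sequence.upper()) - set(RESIDUE_MASSES)
        if bad:
            raise ValidationError(
                f"unknown residue letter(s): {sorted(bad)}"
            )
        if self.charge < 1:
            raise DomainError("charge must be >= 1")
        object.__setattr__(self, "modifications", tuple(self.modifications))


def _mod_delta(mod) -> float:
    if isinstance(mod, str):
        try:
            return MODIFICATIONS[mod]
        except KeyError:
            raise ValidationError(f"unknown modification {mod!r}") from None
    if isinstance(mod, (tuple, list)) and len(mod) == 2:
        return float(mod[1])
    return float(mod)


def monoisotopic_mass(spec, modifications=()) -> float:
    """Monoisotopic mass [Da] of a peptide.

    ``spec`` may be a :class:`PeptideSpec` or a plain sequence string (with
    ``modifications`` given separately).  The mass is the residue-mass sum
    plus one water plus all modification deltas.
    """
    if isinstance(spec, PeptideSpec):
        seq, mods = spec.sequence, spec.modifications
    else:
        seq, mods = str(spec), tuple(modifications)
        PeptideSpec(seq)  # validate the alphabet
    mass = sum(RESIDUE_MASSES[r] for r in seq.upper()) + WATER_MASS
    return mass + sum(_mod_delta(m) for m in mods)


def mz(mass: float, charge: int) -> float:
    """m/z of an [M + zH]^z+ ion: (mass + charge * 1.007276) / charge."""
    charge = int(charge)
    if charge < 1:
        raise DomainError("charge must be >= 1")
    if not np.isfinite(mass) or mass <= 0:
        raise DomainError("mass must be positive and finite")
    return (mass + charge * PROTON_MASS) / charge


def peptide_mz(spec: PeptideSpec) -> float:
    """m/z of a :class:`PeptideSpec` at its own charge state."""
    return mz(monoisotopic_mass(spec), spec.charge)


def mass_conc_to_molar(conc_ug_per_L: float, molar_mass: float) -> float:
    """Convert a mass concentration [ug/L] to molarity [nmol/L].

    nM = (ug/L) / (g/mol) * 1000.
    """
    if not molar_mass > 0:
        raise DomainError("molar mass must be > 0")
    return conc_ug_per_L / molar_mass * 1000.0
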