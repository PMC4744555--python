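"""Binding free-energy conversions and the hydrophobic-burial estimate.

Standard-state (1 M) free energies of dissociation constants, the
empirical free-energy credit for burying hydrophobic surface area (used
to rationalize the tight binding of fluorophore-labeled nucleotides),
and projection of an affinity given an extra free-energy contribution.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "R_KCAL",
    "AffinityEnergy",
    "dG_from_Kd",
    "Kd_from_dG",
    "burial_dG",
    "project_Kd",
]

#: gas constant in kcal mol^-1 K^-1
R_KCAL = 1.987e-3
#: default assay temperature (25 C)
T_DEFAULT = 298.15


@dataclass(frozen=True)
class AffinityEnergy:
    """A dissociation constant and its standard binding free energy."""

    Kd: float          # molar
    dG: float          # kcal / mol
    temperature: float = T_DEFAULT

    @classmethod
    def from_Kd(cls, Kd: float, temperature: float = T_DEFAULT):
        return cls(Kd=Kd, dG=dG_from_Kd(Kd, temperature),
                   temperature=temperature)


def dG_from_Kd(Kd: float, temperature: float = T_DEFAULT) -> float:
    """Standard binding free energy (kcal/mol) from a molar Kd.

    dG = RT ln(Kd / 1 M); negative for sub-molar dissociation constants.
    """
    if Kd <= 0:
        raise ValueError("Kd must be > 0")
    return R_KCAL * temperature * math.log(Kd)


def Kd_from_dG(dG: float, temperature: float = T_DEFAULT) -> float:
    """Molar dissociation constant from a standard binding free energy."""
    return math.exp(dG / (R_KCAL * temperature))


def burial_dG(buried_area: float, coefficient: float = -15.0) -> float:
    """Free-energy credit (kcal/mol) for burying hydrophobic surface.

    ``buried_area`` in A^2; ``coefficient`` in cal mol^-1 A^-2
    (default -15, the empirical hydrophobic-burial value).
    """
    if buried_area < 0:
        raise ValueError("buried_area must be >= 0")
    return buried_area * coefficient / 1000.0


def project_Kd(base_Kd: float, extra_dG: float,
               temperature: float = T_DEFAULT) -> float:
    """Affinity obtained by adding a free-energy contribution.

    Kd' = Kd exp(extra_dG / RT); a negative extra_dG tightens binding.
    """
    if base_Kd <= 0:
        raise ValueError("base_Kd must be > 0")
    return base_Kd * math.exp(extra_dG / (R_KCAL * temperature))
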