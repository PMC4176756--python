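"""Domain records for reactants and reactions.

A Diels-Alder ligation couples a conjugated diene with a dienophile; the
modelling pipeline only ever sees each reactant through its frontier-orbital
energies (HOMO/LUMO, in hartree) and its total dipole moment (Debye), plus
optional solvent metadata.  Activation barriers are free energies of
activation in kcal/mol.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

#: 1 hartree in electron-volts (CODATA).
HARTREE_TO_EV = 27.211386


class Role(str, enum.Enum):
    """Which side of the [4+2] cycloaddition a reactant plays."""

    DIENE = "diene"
    DIENOPHILE = "dienophile"


class SetLabel(str, enum.Enum):
    """Modelling-set membership of a reaction."""

    TRAIN = "train"
    TEST = "test"
    PREDICTION = "prediction"


class ValidationError(ValueError):
    """A record violates a domain invariant."""


@dataclass(frozen=True)
class ReactantElectronicRecord:
    """Electronic-structure summary of one diene or dienophile.

    Parameters
    ----------
    id : str
        Unique identifier within a reactant table.
    role : Role
        ``diene`` or ``dienophile``.
    e_homo, e_lumo : float
        Frontier-orbital eigenvalues in hartree; ``e_homo < e_lumo``.
    dipole : float, optional
        Total dipole moment in Debye (non-negative).  May be absent when
        parsed from a log without a dipole block, but is mandatory for
        descriptor computation.
    solvent : str, optional
        Solvent label (e.g. "water").
    dielectric : float, optional
        Solvent dielectric constant ε.
    """

    id: str
    role: Role
    e_homo: float
    e_lumo: float
    dipole: Optional[float] = None
    solvent: Optional[str] = None
    dielectric: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "role", Role(self.role))
        if not self.e_homo < self.e_lumo:
            raise ValidationError(
                f"reactant {self.id!r}: e_homo ({self.e_homo}) must be "
                f"strictly below e_lumo ({self.e_lumo})"
            )
        if self.dipole is not None and self.dipole < 0:
            raise ValidationError(
                f"reactant {self.id!r}: dipole must be non-negative, "
                f"got {self.dipole}"
            )


@dataclass(frozen=True)
class ReactionRecord:
    """One diene-dienophile pairing with its (optional) measured barrier.

    ``dg_exp`` is the experimental activation barrier ΔG in kcal/mol; it is
    required for train/test reactions and may be absent for prediction-set
    reactions.
    """

    reaction_id: str
    diene_id: str
    dienophile_id: str
    dg_exp: Optional[float] = None
    set_label: SetLabel = SetLabel.TRAIN

    def __post_init__(self) -> None:
        object.__setattr__(self, "set_label", SetLabel(self.set_label))
        if self.set_label is not SetLabel.PREDICTION and self.dg_exp is None:
            raise ValidationError(
                f"reaction {self.reaction_id!r}: dg_exp is required for "
                f"{self.set_label.value} reactions"
            )
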