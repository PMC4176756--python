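"""Conceptual-DFT reactivity descriptors for diene-dienophile pairs.

From the frontier-orbital eigenvalues of a single reactant the global
reactivity indices follow in closed form (Koopmans: I = -E_HOMO,
A = -E_LUMO):

    chemical potential   mu    = (E_LUMO + E_HOMO) / 2
    electronegativity    chi   = -mu
    absolute hardness    eta   = (E_LUMO - E_HOMO) / 2
    softness             SOF   = 1 / eta
    electrophilicity     omega = chi**2 / (2 * eta)

and for a pair the Sustmann orbital-interaction term combines the two cross
gaps g1 = HOMO_d - LUMO_a and g2 = HOMO_a - LUMO_d as
``delta_e = (g1 + g2) / (g1 * g2)``.

The public vocabulary is the 24-entry descriptor catalogue (energies in
hartree, softness in hartree^-1, dipoles in Debye); every difference entry
is diene minus dienophile.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, List, Sequence

import numpy as np
import pandas as pd

from .records import ReactantElectronicRecord, ReactionRecord, Role


class DegenerateGapError(ValueError):
    """HOMO and LUMO coincide: hardness is zero, softness undefined."""


#: Canonical descriptor names, frozen in catalogue order (index 1..24).
DESCRIPTOR_NAMES: tuple = (
    "homo_d",          # 1
    "lumo_a",          # 2
    "homo_a",          # 3
    "lumo_d",          # 4
    "homo_d_lumo_a",   # 5  HOMO_d - LUMO_a
    "homo_a_lumo_d",   # 6  HOMO_a - LUMO_d
    "delta_e",         # 7  Sustmann orbital-interaction term
    "eta_d",           # 8
    "eta_a",           # 9
    "d_eta",           # 10 eta_d - eta_a
    "chi_d",           # 11
    "chi_a",           # 12
    "d_chi",           # 13 chi_d - chi_a
    "omega_d",         # 14
    "omega_a",         # 15
    "d_omega",         # 16 omega_d - omega_a
    "d_homo",          # 17 HOMO_d - HOMO_a
    "d_lumo",          # 18 LUMO_d - LUMO_a
    "sof_d",           # 19
    "sof_a",           # 20
    "d_sof",           # 21 sof_d - sof_a
    "dm_d",            # 22
    "dm_a",            # 23
    "d_dm",            # 24 dm_d - dm_a
)

N_DESCRIPTORS = len(DESCRIPTOR_NAMES)


@dataclass(frozen=True)
class GlobalReactivityIndices:
    """Global reactivity indices of one reactant (atomic units)."""

    mu: float
    eta: float
    sof: float
    chi: float
    omega: float
    i_pot: float
    e_aff: float


def global_reactivity_indices(r: ReactantElectronicRecord) -> GlobalReactivityIndices:
    """Closed-form global reactivity indices from HOMO/LUMO eigenvalues.

    Raises
    ------
    DegenerateGapError
        If ``e_homo >= e_lumo`` (softness would be undefined).
    """
    if r.e_homo >= r.e_lumo:
        raise DegenerateGapError(
            f"reactant {r.id!r}: degenerate frontier gap "
            f"(e_homo={r.e_homo}, e_lumo={r.e_lumo})"
        )
    mu = (r.e_lumo + r.e_homo) / 2.0
    eta = (r.e_lumo - r.e_homo) / 2.0
    chi = -mu
    return GlobalReactivityIndices(
        mu=mu,
        eta=eta,
        sof=1.0 / eta,
        chi=chi,
        omega=chi * chi / (2.0 * eta),
        i_pot=-r.e_homo,
        e_aff=-r.e_lumo,
    )


def sustmann_delta_e(
    d: ReactantElectronicRecord, a: ReactantElectronicRecord
) -> float:
    """Sustmann orbital-interaction energy term for a reactant pair.

    Symmetric under exchange of the two reactants.  Units: hartree^-1.
    """
    g1 = d.e_homo - a.e_lumo
    g2 = a.e_homo - d.e_lumo
    if g1 == 0.0 or g2 == 0.0:
        raise ZeroDivisionError(
            "singular denominator in orbital-interaction term: a cross "
            f"frontier gap is zero for pair ({d.id!r}, {a.id!r})"
        )
    return (g1 + g2) / (g1 * g2)


class DescriptorVector:
    """The 24-descriptor catalogue for one diene-dienophile pair.

    Entries are addressable by canonical name (``dv["omega_d"]``) or by
    1-based catalogue index (``dv.by_index(14)``).
    """

    __slots__ = ("values",)

    def __init__(self, values: Sequence[float]):
        arr = np.asarray(values, dtype=float)
        if arr.shape != (N_DESCRIPTORS,):
            raise ValueError(
                f"descriptor vector must have exactly {N_DESCRIPTORS} "
                f"entries, got shape {arr.shape}"
            )
        self.values = arr

    def __getitem__(self, name: str) -> float:
        return float(self.values[DESCRIPTOR_NAMES.index(name)])

    def by_index(self, index: int) -> float:
        """Value of catalogue entry ``index`` (1-based)."""
        if not 1 <= index <= N_DESCRIPTORS:
            raise IndexError(f"catalogue index must be in 1..{N_DESCRIPTORS}")
        return float(self.values[index - 1])

    def as_dict(self) -> dict:
        return dict(zip(DESCRIPTOR_NAMES, self.values.tolist()))

    def __repr__(self) -> str:  # pragma: no cover
        return f"DescriptorVector({self.as_dict()!r})"


def descriptor_vector(
    d: ReactantElectronicRecord, a: ReactantElectronicRecord
) -> DescriptorVector:
    """Compute the full 24-descriptor catalogue for a diene-dienophile pair.

    Raises a usage error on role mismatch and a data error when a dipole is
    missing; difference entries are diene minus dienophile.
    """
    if d.role is not Role.DIENE or a.role is not Role.DIENOPHILE:
        raise ValueError(
            f"role mismatch: expected (diene, dienophile), got "
            f"({d.role.value}, {a.role.value}) for ({d.id!r}, {a.id!r})"
        )
    for r in (d, a):
        if r.dipole is None:
            raise ValueError(
                f"reactant {r.id!r} has no dipole moment; dipole descriptors "
                "cannot be computed"
            )
    gd = global_reactivity_indices(d)
    ga = global_reactivity_indices(a)
    de = sustmann_delta_e(d, a)
    return DescriptorVector(
        [
            d.e_homo,                   # homo_d
            a.e_lumo,                   # lumo_a
            a.e_homo,                   # homo_a
            d.e_lumo,                   # lumo_d
            d.e_homo - a.e_lumo,        # homo_d_lumo_a
            a.e_homo - d.e_lumo,        # homo_a_lumo_d
            de,                         # delta_e
            gd.eta,                     # eta_d
            ga.eta,                     # eta_a
            gd.eta - ga.eta,            # d_eta
            gd.chi,                     # chi_d
            ga.chi,                     # chi_a
            gd.chi - ga.chi,            # d_chi
            gd.omega,                   # omega_d
            ga.omega,                   # omega_a
            gd.omega - ga.omega,        # d_omega
            d.e_homo - a.e_homo,        # d_homo
            d.e_lumo - a.e_lumo,        # d_lumo
            gd.sof,                     # sof_d
            ga.sof,                     # sof_a
            gd.sof - ga.sof,            # d_sof
            d.dipole,                   # dm_d
            a.dipole,                   # dm_a
            d.dipole - a.dipole,        # d_dm
        ]
    )


def descriptor_matrix(
    reactants: Iterable[ReactantElectronicRecord],
    reactions: Iterable[ReactionRecord],
) -> pd.DataFrame:
    """Descriptor matrix for a reaction table: one row per reaction.

    Columns: ``reaction_id`` + the 24 canonical descriptor names +
    ``dg_exp`` and ``set_label``.
    """
    by_id = {r.id: r for r in reactants}
    rows: List[dict] = []
    for rx in reactions:
        d = by_id[rx.diene_id]
        a = by_id[rx.dienophile_id]
        row = {"reaction_id": rx.reaction_id}
        row.update(descriptor_vector(d, a).as_dict())
        row["dg_exp"] = rx.dg_exp if rx.dg_exp is not None else np.nan
        row["set_label"] = rx.set_label.value
        rows.append(row)
    return pd.DataFrame(rows, columns=["reaction_id", *DESCRIPTOR_NAMES, "dg_exp", "set_label"])
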