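"""Reading and writing reactant/reaction tables and QC output logs.

Tables are delimited text (comma by default, tab via ``dialect="tsv"``)
with a mandatory header.  Energies are hartree unless a metadata comment
line ``# energy_unit: eV`` declares electron-volts, in which case they are
converted on input (divide by 27.211386).

``extract_from_qc_log`` pulls HOMO/LUMO eigenvalues and the total dipole
from Gaussian-style output text: the last value of the final occupied
eigenvalue block, the first value of the final virtual block, and the
``Tot=`` field of the final dipole line, so multi-cycle optimisation logs
yield converged-geometry values.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass
from typing import List, Optional, Sequence, TextIO, Union

import pandas as pd

from .records import (
    HARTREE_TO_EV,
    ReactantElectronicRecord,
    ReactionRecord,
    Role,
    SetLabel,
    ValidationError,
)

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """The table is structurally malformed (missing column, bad header)."""


class LinkError(ValueError):
    """A reaction references a reactant id that does not exist."""


class QCLogParseError(ValueError):
    """A quantum-chemistry log lacks the expected eigenvalue blocks."""


_REACTANT_COLUMNS = ("id", "role", "e_homo", "e_lumo", "dipole")
_REACTION_COLUMNS = ("reaction_id", "diene_id", "dienophile_id")


def _as_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return open(source, "r", encoding="utf-8")
    return source


def _read_table(source: Union[str, TextIO], dialect: str) -> tuple:
    """Read a delimited table, returning (DataFrame, metadata dict)."""
    if dialect not in ("csv", "tsv"):
        raise FormatError(f"unknown table dialect {dialect!r} (csv or tsv)")
    sep = "," if dialect == "csv" else "\t"
    stream = _as_stream(source)
    text = stream.read()
    meta = {}
    for line in text.splitlines():
        if line.startswith("#") and ":" in line:
            key, _, value = line.lstrip("# ").partition(":")
            meta[key.strip()] = value.strip()
    df = pd.read_csv(
        io.StringIO(text), sep=sep, comment="#", skip_blank_lines=True,
        float_precision="round_trip",
    )
    df.columns = [c.strip() for c in df.columns]
    return df, meta


def read_reactant_table(
    source: Union[str, TextIO], dialect: str = "csv"
) -> List[ReactantElectronicRecord]:
    """Load reactant electronic records from a delimited table.

    Columns ``id,role,e_homo,e_lumo,dipole`` are mandatory; ``solvent``
    and ``dielectric`` optional.  A comment line ``# energy_unit: eV``
    switches orbital energies to eV on input.
    """
    df, meta = _read_table(source, dialect)
    for col in _REACTANT_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"reactant table is missing mandatory column {col!r}")
    unit = meta.get("energy_unit", "hartree").lower()
    if unit in ("ev",):
        scale = 1.0 / HARTREE_TO_EV
    elif unit in ("hartree", "au", "a.u."):
        scale = 1.0
    else:
        raise FormatError(f"unknown energy_unit {unit!r} (hartree or eV)")

    records: List[ReactantElectronicRecord] = []
    seen = set()
    for i, row in df.iterrows():
        rid = str(row["id"])
        if rid in seen:
            raise ValidationError(f"duplicate reactant id {rid!r} in table row {i}")
        seen.add(rid)
        try:
            rec = ReactantElectronicRecord(
                id=rid,
                role=Role(str(row["role"]).strip().lower()),
                e_homo=float(row["e_homo"]) * scale,
                e_lumo=float(row["e_lumo"]) * scale,
                dipole=None if pd.isna(row["dipole"]) else float(row["dipole"]),
                solvent=(
                    str(row["solvent"])
                    if "solvent" in df.columns and not pd.isna(row["solvent"])
                    else None
                ),
                dielectric=(
                    float(row["dielectric"])
                    if "dielectric" in df.columns and not pd.isna(row["dielectric"])
                    else None
                ),
            )
        except ValidationError as exc:
            raise ValidationError(f"table row {i}: {exc}") from exc
        records.append(rec)
    return records


def write_reactant_table(
    records: Sequence[ReactantElectronicRecord],
    dest: Union[str, TextIO],
    dialect: str = "csv",
    energy_unit: str = "hartree",
) -> None:
    """Write reactant records back to a delimited table (round-trip safe)."""
    scale = HARTREE_TO_EV if energy_unit.lower() == "ev" else 1.0
    df = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "role": [r.role.value for r in records],
            "e_homo": [r.e_homo * scale for r in records],
            "e_lumo": [r.e_lumo * scale for r in records],
            "dipole": [r.dipole for r in records],
            "solvent": [r.solvent for r in records],
            "dielectric": [r.dielectric for r in records],
        }
    )
    sep = "," if dialect == "csv" else "\t"
    stream = dest if not isinstance(dest, str) else open(dest, "w", encoding="utf-8")
    stream.write(f"# energy_unit: {energy_unit}\n")
    df.to_csv(stream, sep=sep, index=False)  # repr floats: lossless round-trip
    if isinstance(dest, str):
        stream.close()


def read_reaction_table(
    source: Union[str, TextIO],
    reactants: Sequence[ReactantElectronicRecord],
    dialect: str = "csv",
) -> List[ReactionRecord]:
    """Load the reaction table and check referential integrity.

    Every ``diene_id``/``dienophile_id`` must resolve to a reactant with the
    matching role; ``set_label`` defaults to ``train`` when the column is
    absent.
    """
    df, _ = _read_table(source, dialect)
    for col in _REACTION_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"reaction table is missing mandatory column {col!r}")
    by_id = {r.id: r for r in reactants}
    records: List[ReactionRecord] = []
    for _, row in df.iterrows():
        rx_id = str(row["reaction_id"])
        for col, role in (("diene_id", Role.DIENE), ("dienophile_id", Role.DIENOPHILE)):
            ref = str(row[col])
            if ref not in by_id:
                raise LinkError(
                    f"reaction {rx_id!r}: {col} {ref!r} not found in reactant table"
                )
            if by_id[ref].role is not role:
                raise ValidationError(
                    f"reaction {rx_id!r}: {col} {ref!r} has role "
                    f"{by_id[ref].role.value!r}, expected {role.value!r}"
                )
        dg = None
        if "dg_exp" in df.columns and not pd.isna(row["dg_exp"]):
            dg = float(row["dg_exp"])
        label = SetLabel.TRAIN
        if "set_label" in df.columns and not pd.isna(row["set_label"]):
            label = SetLabel(str(row["set_label"]).strip().lower())
        records.append(
            ReactionRecord(
                reaction_id=rx_id,
                diene_id=str(row["diene_id"]),
                dienophile_id=str(row["dienophile_id"]),
                dg_exp=dg,
                set_label=label,
            )
        )
    return records


@dataclass(frozen=True)
class QCLogExtract:
    """Orbital/dipole values pulled from a QC output log, with provenance."""

    e_homo: float
    e_lumo: float
    dipole: Optional[float]
    homo_line: int
    lumo_line: int
    dipole_line: Optional[int]


_OCC_RE = re.compile(r"Alpha\s+occ\.\s+eigenvalues\s*--\s*(.*)", re.IGNORECASE)
_VIRT_RE = re.compile(r"Alpha\s+virt\.\s+eigenvalues\s*--\s*(.*)", re.IGNORECASE)
_DIPOLE_RE = re.compile(r"Tot\s*=\s*(-?\d+\.\d+)")
# Gaussian prints eigenvalues in fixed columns that may abut for large
# negative values; split on whitespace is sufficient for well-formed logs.
_NUM_RE = re.compile(r"-?\d+\.\d+")


def extract_from_qc_log(log_text: str) -> QCLogExtract:
    """Extract HOMO/LUMO (hartree) and total dipole (Debye) from log text.

    The final run of occupied-eigenvalue lines supplies the HOMO (its last
    value) and the immediately following virtual block supplies the LUMO
    (its first value), so that optimisation logs yield values for the
    converged geometry.  A missing dipole block is tolerated with a warning.
    """
    lines = log_text.splitlines()
    # Collect contiguous occupied/virtual runs with their line numbers.
    runs = []  # (kind, first_line, values...)
    for n, line in enumerate(lines, start=1):
        m = _OCC_RE.search(line)
        kind = None
        if m:
            kind = "occ"
        else:
            m = _VIRT_RE.search(line)
            if m:
                kind = "virt"
        if kind is None:
            continue
        values = [float(v) for v in _NUM_RE.findall(m.group(1))]
        if runs and runs[-1][0] == kind:
            runs[-1][2].extend(values)
            runs[-1][3] = n
        else:
            runs.append([kind, n, values, n])
    occ_runs = [r for r in runs if r[0] == "occ"]
    virt_runs = [r for r in runs if r[0] == "virt"]
    if not occ_runs:
        raise QCLogParseError("no occupied-eigenvalue block found in log")
    if not virt_runs:
        raise QCLogParseError("no virtual-eigenvalue block found in log")
    last_occ = occ_runs[-1]
    following_virts = [r for r in virt_runs if r[1] > last_occ[3]]
    if not following_virts:
        raise QCLogParseError(
            "no virtual-eigenvalue block follows the final occupied block"
        )
    virt = following_virts[0]
    e_homo = last_occ[2][-1]
    e_lumo = virt[2][0]

    dipole = None
    dipole_line = None
    for n, line in enumerate(lines, start=1):
        m = _DIPOLE_RE.search(line)
        if m:
            dipole = float(m.group(1))
            dipole_line = n
    if dipole is None:
        logger.warning("no dipole block found in QC log; dipole left absent")
    return QCLogExtract(
        e_homo=e_homo,
        e_lumo=e_lumo,
        dipole=dipole,
        homo_line=last_occ[3],
        lumo_line=virt[1],
        dipole_line=dipole_line,
    )
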