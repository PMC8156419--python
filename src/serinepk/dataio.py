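"""Dataset reader/writer: a NONMEM-inspired CSV layout, without the quirks.

One row per record.  Columns: ``subject_id, time_h, record_kind, value,
unit, weight_kg, height_cm``.  ``record_kind`` is ``observation`` or
``dose``; observations carry concentrations (µmol/L or mg/100ml), doses
carry amounts (g, mg or µmol).  On read, everything is converted to the
internal µmol / µmol·L⁻¹ scale and each subject's clock is shifted so their
first dose sits at t = 0.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import pandas as pd

from .datatypes import DoseEvent, Observation, SubjectData, umol_to_grams
from .physiology import PhysioConstants, conc_mg_per_100ml_to_umol_per_L

__all__ = ["read_dataset", "write_dataset", "COLUMNS"]

COLUMNS = ["subject_id", "time_h", "record_kind", "value", "unit", "weight_kg", "height_cm"]

_OBS_UNITS = {"umol/L", "mg/100ml"}
_DOSE_UNITS = {"g", "mg", "umol"}


def _to_umol(amount: float, unit: str, constants: PhysioConstants) -> float:
    if unit == "umol":
        return amount
    grams = amount if unit == "g" else amount / 1000.0
    return grams / constants.molar_mass * 1e6


def read_dataset(path: str | Path, constants: PhysioConstants = PhysioConstants()) -> list[SubjectData]:
    """Parse a dataset CSV into per-subject records.

    Raises
    ------
    ValueError
        On an unknown unit (naming the offending row), a subject without a
        dose record, or a duplicate (subject, time, kind) triple.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"subject_id": str})
    missing = [c for c in COLUMNS[:5] if c not in df.columns]
    if missing:
        raise ValueError(f"dataset is missing required columns: {missing}")
    seen: set[tuple[str, float, str]] = set()
    subjects: list[SubjectData] = []
    for sid, grp in df.groupby("subject_id", sort=False):
        doses: list[tuple[float, float]] = []
        obs: list[tuple[float, float]] = []
        weight = height = None
        for idx, row in grp.iterrows():
            kind = row["record_kind"]
            unit = str(row["unit"])
            t = float(row["time_h"])
            v = float(row["value"])
            key = (sid, t, kind)
            if key in seen:
                raise ValueError(f"row {idx}: duplicate record {key}")
            seen.add(key)
            if kind == "dose":
                if unit not in _DOSE_UNITS:
                    raise ValueError(f"row {idx}: unknown dose unit {unit!r}")
                doses.append((t, _to_umol(v, unit, constants)))
            elif kind == "observation":
                if unit not in _OBS_UNITS:
                    raise ValueError(f"row {idx}: unknown concentration unit {unit!r}")
                conc = v if unit == "umol/L" else conc_mg_per_100ml_to_umol_per_L(v, constants)
                obs.append((t, conc))
            else:
                raise ValueError(f"row {idx}: unknown record_kind {kind!r}")
            if "weight_kg" in grp.columns and pd.notna(row.get("weight_kg")):
                weight = float(row["weight_kg"])
            if "height_cm" in grp.columns and pd.notna(row.get("height_cm")):
                height = float(row["height_cm"])
        if not doses:
            raise ValueError(f"subject {sid!r} has no dose record")
        doses.sort()
        shift = doses[0][0]
        subjects.append(
            SubjectData(
                subject_id=str(sid),
                doses=[DoseEvent(t - shift, a) for t, a in doses],
                observations=[Observation(t - shift, c) for t, c in sorted(obs)],
                weight=weight,
                height=height,
            )
        )
    return subjects


def write_dataset(subjects: Sequence[SubjectData], path: str | Path) -> None:
    """Write subjects to the CSV dialect (concentrations µmol/L, doses g)."""
    rows = []
    for s in subjects:
        for d in s.doses:
            rows.append((s.subject_id, d.time, "dose", umol_to_grams(d.amount), "g", s.weight, s.height))
        for o in s.observations:
            rows.append((s.subject_id, o.time, "observation", o.concentration, "umol/L", s.weight, s.height))
    pd.DataFrame(rows, columns=COLUMNS).to_csv(path, index=False)
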