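"""Core record types for the serine PK analysis.

All model state is carried in micromoles (amounts), micromoles per litre
(concentrations) and hours.  Oral doses given in grams are converted with the
molar mass of L-serine (105.09 g/mol) at the I/O boundary, never inside the
model code.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

#: Molar mass of L-serine, g/mol.
SERINE_MOLAR_MASS = 105.09


def grams_to_umol(grams: float, molar_mass: float = SERINE_MOLAR_MASS) -> float:
    """Convert a dose in grams to micromoles."""
    return grams / molar_mass * 1e6


def umol_to_grams(umol: float, molar_mass: float = SERINE_MOLAR_MASS) -> float:
    """Convert an amount in micromoles to grams."""
    return umol * molar_mass / 1e6


@dataclass(frozen=True)
class DoseEvent:
    """One oral bolus entering the gut depot.

    Attributes
    ----------
    time : float
        Dose time in hours on the subject's clock (first dose at 0).
    amount : float
        Dose amount in micromoles (> 0).
    """

    time: float
    amount: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError("dose time must be finite")
        if not (self.amount > 0):
            raise ValueError("dose amount must be positive")


@dataclass(frozen=True)
class Observation:
    """A measured plasma serine concentration (µmol/L) at a time (h)."""

    time: float
    concentration: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.time):
            raise ValueError("observation time must be finite")
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")


@dataclass
class SubjectData:
    """A subject's dose events, observations and optional covariates.

    Times for doses and observations share one clock, shifted so the first
    dose falls at t = 0.
    """

    subject_id: str
    doses: list[DoseEvent]
    observations: list[Observation]
    weight: float | None = None
    height: float | None = None

    def __post_init__(self) -> None:
        if len(self.observations) < 1:
            raise ValueError("a subject needs at least one observation")
        times = [d.time for d in self.doses]
        if times != sorted(times):
            raise ValueError("dose events must be sorted by time")
        if self.doses and abs(self.doses[0].time) > 1e-9:
            raise ValueError("first dose must be at t = 0 on the subject clock")

    @property
    def obs_times(self) -> list[float]:
        return [o.time for o in self.observations]

    @property
    def obs_concentrations(self) -> list[float]:
        return [o.concentration for o in self.observations]


@dataclass(frozen=True)
class StructuralParams:
    """Ratio parameterization of the one-compartment oral model.

    The identifiable ratios are F/V_D (1/L), CL/V_D (1/h, the elimination rate
    constant), k_gen/V_D (µmol/(L·h), endogenous production per volume) and
    the absorption constant k_abs (1/h).  Optional first-order exchange with a
    peripheral compartment (k23 out of, k32 into the central compartment)
    extends the model to two compartments; both default to zero.
    """

    k_abs: float
    f_over_v: float
    cl_over_v: float
    kgen_over_v: float
    k23: float = 0.0
    k32: float = 0.0

    def __post_init__(self) -> None:
        for name in ("k_abs", "f_over_v", "cl_over_v", "kgen_over_v"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")
        for name in ("k23", "k32"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v >= 0):
                raise ValueError(f"{name} must be non-negative, got {v!r}")

    @property
    def is_one_compartment(self) -> bool:
        return self.k23 == 0.0 and self.k32 == 0.0


@dataclass(frozen=True)
class FullParams:
    """The five-parameter (non-ratio) form: V_D, F, k_abs, k_gen, CL.

    Structurally non-identifiable from oral concentration data alone: scaling
    V_D, F, k_gen and CL by a common factor leaves every prediction unchanged.
    Kept for the naive pooled fit, which demonstrates that ill-conditioning.
    F is nominally a fraction but is left unconstrained here on purpose.
    """

    v_d: float
    f: float
    k_abs: float
    k_gen: float
    cl: float

    def __post_init__(self) -> None:
        for name in ("v_d", "f", "k_abs", "k_gen", "cl"):
            v = getattr(self, name)
            if not (math.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be strictly positive, got {v!r}")

    def to_ratios(self) -> StructuralParams:
        """Project onto the identifiable ratio parameterization."""
        return StructuralParams(
            k_abs=self.k_abs,
            f_over_v=self.f / self.v_d,
            cl_over_v=self.cl / self.v_d,
            kgen_over_v=self.k_gen / self.v_d,
        )


def make_subject(
    subject_id: str,
    dose_times: Sequence[float],
    dose_amounts_umol: Sequence[float],
    obs_times: Sequence[float],
    obs_concentrations: Sequence[float],
    weight: float | None = None,
    height: float | None = None,
) -> SubjectData:
    """Convenience constructor from parallel sequences."""
    doses = [DoseEvent(t, a) for t, a in zip(dose_times, dose_amounts_umol)]
    obs = [Observation(t, c) for t, c in zip(obs_times, obs_concentrations)]
    return SubjectData(subject_id, doses, obs, weight=weight, height=height)
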