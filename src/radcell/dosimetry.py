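"""MIRD-schema cellular dosimetry for an unbound radionuclide in culture medium.

The model treats the culture medium (and optionally the cell cytoplasm) as
source regions and the cell / cell nucleus as the target.  Activity decays
purely physically, ``A(t) = A0 * exp(-lambda t)``, so the absorbed dose over
an exposure window ``T`` is

    D(T) = S * Ac * (1 - exp(-lambda T)) / lambda

with ``Ac`` the initial activity concentration (Bq/mL) and ``S`` the mean
absorbed dose per unit cumulated activity concentration (Gy·mL·Bq⁻¹·s⁻¹).
Everything in this module is closed form; times are seconds internally and
days at the user boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import (
    AG111_HALF_LIFE_DAYS,
    DEFAULT_CYTOPLASM_VOLUME_UM3,
    ML_UM3,
    S_CYTOPLASM_TO_NUCLEUS,
    S_MEDIUM_CALIBRATED,
    SECONDS_PER_DAY,
)

__all__ = [
    "RadionuclidePhysics",
    "SValueSet",
    "CellGeometry",
    "ExposurePlan",
    "AG111",
    "DEFAULT_S_VALUES",
    "decay_constant",
    "decay_integral",
    "dose_from_activity",
    "activity_for_dose",
    "equivalent_activity",
    "dose_rate",
    "internalization_excess",
    "plan_exposure",
]


def decay_constant(half_life_s: float) -> float:
    """Physical decay constant ln2 / t_half, s⁻¹.

    Parameters
    ----------
    half_life_s : float
        Half-life in seconds; must be positive.
    """
    if half_life_s <= 0:
        raise ValueError(f"half-life must be positive, got {half_life_s}")
    return math.log(2.0) / half_life_s


@dataclass(frozen=True)
class RadionuclidePhysics:
    """Physical decay data for one radionuclide."""

    name: str
    half_life_days: float

    def __post_init__(self) -> None:
        if self.half_life_days <= 0:
            raise ValueError(
                f"half-life must be positive, got {self.half_life_days} d")

    @property
    def half_life_s(self) -> float:
        return self.half_life_days * SECONDS_PER_DAY

    @property
    def decay_constant(self) -> float:
        """lambda = ln2 / t_half, s⁻¹."""
        return decay_constant(self.half_life_s)


#: Silver-111 (beta-minus emitter, stable daughter Cd-111).
AG111 = RadionuclidePhysics("Ag-111", AG111_HALF_LIFE_DAYS)


@dataclass(frozen=True)
class SValueSet:
    """Mean absorbed dose per unit cumulated activity for the source->target
    pairs of the monolayer exposure geometry.

    ``medium_to_cell`` is per cumulated activity *concentration*
    (Gy·mL·Bq⁻¹·s⁻¹); ``cytoplasm_to_nucleus`` is per cumulated activity
    (Gy·Bq⁻¹·s⁻¹).
    """

    medium_to_cell: float = S_MEDIUM_CALIBRATED
    cytoplasm_to_nucleus: float = S_CYTOPLASM_TO_NUCLEUS
    geometry_note: str = (
        "cell monolayer on dish bottom (half of the full-sphere medium "
        "S-value); ellipsoidal nucleus for the cytoplasmic source")

    def __post_init__(self) -> None:
        if self.medium_to_cell <= 0 or self.cytoplasm_to_nucleus <= 0:
            raise ValueError("S-values must be positive")


DEFAULT_S_VALUES = SValueSet()


@dataclass(frozen=True)
class CellGeometry:
    """Source-region geometry of a single cell (cytoplasm only; the medium
    source is characterised entirely by its S-value)."""

    cytoplasm_volume_um3: float = DEFAULT_CYTOPLASM_VOLUME_UM3

    def __post_init__(self) -> None:
        if self.cytoplasm_volume_um3 < 0:
            raise ValueError("cytoplasm volume must be non-negative")


def decay_integral(exposure_s: float, physics: RadionuclidePhysics = AG111) -> float:
    """Integral of the decay factor, ∫₀ᵀ e^(−λt) dt = (1 − e^(−λT))/λ, in s.

    This is the "effective exposure time": cumulated activity equals the
    initial activity times this factor.  Bounded above by both ``T`` and
    ``1/λ``.
    """
    if exposure_s < 0:
        raise ValueError(f"exposure time must be non-negative, got {exposure_s}")
    lam = physics.decay_constant
    return -math.expm1(-lam * exposure_s) / lam


def dose_rate(t_s: float, ac_kbq_per_ml: float, s_medium: float = S_MEDIUM_CALIBRATED,
              physics: RadionuclidePhysics = AG111) -> float:
    """Instantaneous dose rate S·Ac·e^(−λt), Gy/s."""
    if t_s < 0:
        raise ValueError(f"time must be non-negative, got {t_s}")
    return s_medium * ac_kbq_per_ml * 1e3 * math.exp(-physics.decay_constant * t_s)


def dose_from_activity(ac_kbq_per_ml: float, exposure_days: float,
                       s_medium: float = S_MEDIUM_CALIBRATED,
                       physics: RadionuclidePhysics = AG111) -> float:
    """Absorbed dose (Gy) delivered by initial concentration ``ac`` over
    ``exposure_days`` of pure physical decay: D = S·Ac·(1−e^(−λT))/λ."""
    if ac_kbq_per_ml < 0:
        raise ValueError("activity concentration must be non-negative")
    if s_medium <= 0:
        raise ValueError("S-value must be positive")
    integral = decay_integral(exposure_days * SECONDS_PER_DAY, physics)
    return s_medium * ac_kbq_per_ml * 1e3 * integral


def activity_for_dose(dose_gy: float, exposure_days: float,
                      s_medium: float = S_MEDIUM_CALIBRATED,
                      physics: RadionuclidePhysics = AG111) -> float:
    """Initial activity concentration (kBq/mL) that delivers ``dose_gy``
    over ``exposure_days``; exact algebraic inversion of the dose formula."""
    if dose_gy < 0:
        raise ValueError("dose must be non-negative")
    if s_medium <= 0:
        raise ValueError("S-value must be positive")
    if exposure_days <= 0:
        if dose_gy == 0:
            return 0.0
        raise ValueError("no finite concentration delivers a positive dose "
                         "in zero exposure time")
    integral = decay_integral(exposure_days * SECONDS_PER_DAY, physics)
    return dose_gy / (s_medium * integral) / 1e3


def equivalent_activity(ac_kbq_per_ml: float, from_days: float, to_days: float,
                        physics: RadionuclidePhysics = AG111) -> float:
    """Concentration over ``to_days`` delivering the same dose as
    ``ac_kbq_per_ml`` over ``from_days``.  The S-value cancels:
    Ac' = Ac · I(T_from)/I(T_to)."""
    if ac_kbq_per_ml < 0:
        raise ValueError("activity concentration must be non-negative")
    if from_days <= 0 or to_days <= 0:
        raise ValueError("exposure times must be positive")
    return (ac_kbq_per_ml
            * decay_integral(from_days * SECONDS_PER_DAY, physics)
            / decay_integral(to_days * SECONDS_PER_DAY, physics))


def internalization_excess(s_values: SValueSet = DEFAULT_S_VALUES,
                           geometry: CellGeometry = CellGeometry(),
                           exposure_days: float = 4.0,
                           physics: RadionuclidePhysics = AG111) -> float:
    """Relative nucleus-dose increase from an equal-concentration
    cytoplasmic source added to the medium source.

    With the same activity concentration inside and outside the cell, the
    cytoplasm of volume V holds activity Ac·V, so the extra nucleus dose is
    S(N<-Cy)·Ac·V·I(T) against the medium dose S_med·Ac·I(T): the
    concentration and decay integral cancel and the excess is

        S(N<-Cy) · V_cyto / S_med

    with V in mL.  Returned as a dimensionless fraction (0.0026 = 0.26%).
    """
    if s_values.medium_to_cell <= 0:
        raise ValueError("medium S-value must be positive (zero medium dose)")
    v_ml = geometry.cytoplasm_volume_um3 / ML_UM3
    return s_values.cytoplasm_to_nucleus * v_ml / s_values.medium_to_cell


@dataclass
class ExposurePlan:
    """Planned exposure: target doses and the activity concentrations that
    deliver them over one exposure time."""

    target_doses_gy: list[float]
    exposure_days: float
    activity_kbq_per_ml: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.activity_kbq_per_ml and (
                len(self.activity_kbq_per_ml) != len(self.target_doses_gy)):
            raise ValueError("doses and concentrations must have equal length")
        if any(d < 0 for d in self.target_doses_gy):
            raise ValueError("doses must be non-negative")

    def to_frame(self, round_kbq: bool = False) -> pd.DataFrame:
        ac = np.asarray(self.activity_kbq_per_ml, dtype=float)
        if round_kbq:
            ac = np.round(ac)
        return pd.DataFrame({
            "dose_Gy": self.target_doses_gy,
            "exposure_days": self.exposure_days,
            "activity_kBq_per_mL": ac,
        })

    def to_csv(self, path: str | Path, round_kbq: bool = False) -> None:
        self.to_frame(round_kbq=round_kbq).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ExposurePlan":
        df = pd.read_csv(path)
        required = {"dose_Gy", "exposure_days", "activity_kBq_per_mL"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"exposure-plan CSV missing columns: {sorted(missing)}")
        days = df["exposure_days"].unique()
        if len(days) != 1:
            raise ValueError("exposure-plan CSV must describe a single exposure time")
        return cls(target_doses_gy=df["dose_Gy"].tolist(),
                   exposure_days=float(days[0]),
                   activity_kbq_per_ml=df["activity_kBq_per_mL"].tolist())


def plan_exposure(target_doses_gy: Sequence[float], exposure_days: float,
                  s_medium: float = S_MEDIUM_CALIBRATED,
                  physics: RadionuclidePhysics = AG111) -> ExposurePlan:
    """Compute the activity-concentration series for a dose ladder.

    Concentrations are kept unrounded internally; round only for display.
    """
    ac = [activity_for_dose(d, exposure_days, s_medium, physics)
          for d in target_doses_gy]
    return ExposurePlan(list(target_doses_gy), exposure_days, ac)
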