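"""Physical and chemical constants used throughout the package.

Dosimetry constants follow the MIRD cellular-dosimetry convention:
the medium->cell S-value is expressed per unit cumulated *activity
concentration* (Gy·mL·Bq⁻¹·s⁻¹), the cytoplasm->nucleus S-value per
unit cumulated activity (Gy·Bq⁻¹·s⁻¹).
"""

from __future__ import annotations

import math

SECONDS_PER_DAY: float = 86_400.0

#: Physical half-life of silver-111, days.
AG111_HALF_LIFE_DAYS: float = 7.45

#: Medium->cell S-value, naive reading: half of the published 0.06
#: mGy/(Bq s) for a cell in a radioactive medium sphere, interpreted as
#: mGy·mL/(MBq·s) and halved for cells on the dish bottom (2*pi geometry).
S_MEDIUM_NOMINAL: float = 0.03e-3 / 1e6  # 3.00e-11 Gy·mL/(Bq·s)


def _calibrate_s_medium(dose_gy: float = 4.0,
                        ac_kbq_per_ml: float = 478.0,
                        exposure_days: float = 4.0,
                        half_life_days: float = AG111_HALF_LIFE_DAYS) -> float:
    """Back out the medium S-value from a (dose, concentration, time) triple."""
    lam = math.log(2.0) / (half_life_days * SECONDS_PER_DAY)
    t = exposure_days * SECONDS_PER_DAY
    integral = (1.0 - math.exp(-lam * t)) / lam
    return dose_gy / (ac_kbq_per_ml * 1e3 * integral)


#: Medium->cell S-value calibrated so that 478 kBq/mL over 4 d delivers
#: exactly 4 Gy (the planned exposure series); 2.900e-11 Gy·mL/(Bq·s),
#: ~3.5% below the naive reading.  Default everywhere.
S_MEDIUM_CALIBRATED: float = _calibrate_s_medium()

#: Cytoplasm->nucleus S-value for an ellipsoidal nucleus with a uniform
#: cytoplasmic source, Gy/(Bq·s).
S_CYTOPLASM_TO_NUCLEUS: float = 0.075e-3

#: Default cytoplasm volume, µm³ (order-of-magnitude mammalian cell;
#: an assumption, not a measured value -- flagged in reports).
DEFAULT_CYTOPLASM_VOLUME_UM3: float = 1000.0

# --- Ag-Cl aqueous equilibrium (25 °C, concentrations as activities) ---

#: Solubility product of AgCl(s), M².
AGCL_KSP: float = 1.77e-10
#: Overall formation constant of AgCl(aq), M⁻¹.
AGCL_BETA1: float = 2.0e3
#: Overall formation constant of AgCl2⁻, M⁻².
AGCL2_BETA2: float = 1.86e5

#: Composition of the administered solution: total silver and chloride, M.
SOLUTION_TOTAL_AG: float = 1.23e-7
SOLUTION_TOTAL_CL: float = 2.46e-1

MICROLITER_UM3: float = 1e9  # µm³ per µL
ML_UM3: float = 1e12  # µm³ per mL
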