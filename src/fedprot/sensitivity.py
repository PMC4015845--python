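"""LC-MS detection-limit arithmetic.

Whether a blood protein is observable by LC-ESI-MS/MS comes down to
simple unit conversions: a protein's mass concentration (ng/ml) and
molecular weight give its molarity (a 50 kDa protein at 1 ng/ml sits
near 20 pM), and molarity times processed sample volume times recovery
gives the amount delivered to the column in femtomoles.  Ion traps
identify digests reproducibly around 10 fmol on column and reach their
detection limit near 1 fmol.
"""

from __future__ import annotations

from dataclasses import dataclass

#: fmol on column where identification becomes marginal (ion-trap limit)
DETECTION_LIMIT_FMOL = 1.0
#: fmol on column for reproducible, confident identification
CONFIDENT_LIMIT_FMOL = 10.0


@dataclass(frozen=True)
class DetectionScenario:
    """One detectability question: protein, sample, instrument."""

    mass_concentration_ng_ml: float
    molecular_weight_da: float
    sample_volume_ul: float
    instrument_limit_fmol: float = DETECTION_LIMIT_FMOL
    recovery_fraction: float = 1.0

    def __post_init__(self):
        for name in ("mass_concentration_ng_ml", "molecular_weight_da",
                     "sample_volume_ul", "instrument_limit_fmol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.recovery_fraction <= 1:
            raise ValueError("recovery_fraction must be in (0, 1]")


def molarity_from_mass_conc(mass_concentration_ng_ml: float, molecular_weight_da: float) -> float:
    """Molar concentration in pM from mass concentration and weight.

    1 ng/ml = 1e-6 g/L; dividing by the molecular weight (g/mol) and
    expressing in pM gives ``ng_ml * 1e6 / mw``: 1 ng/ml at 50,000 Da is
    20 pM.
    """
    if mass_concentration_ng_ml <= 0 or molecular_weight_da <= 0:
        raise ValueError("mass concentration and molecular weight must be positive")
    return mass_concentration_ng_ml * 1e6 / molecular_weight_da


def mass_conc_from_molarity(molarity_pm: float, molecular_weight_da: float) -> float:
    """Inverse of :func:`molarity_from_mass_conc` (pM -> ng/ml)."""
    if molarity_pm <= 0 or molecular_weight_da <= 0:
        raise ValueError("molarity and molecular weight must be positive")
    return molarity_pm * molecular_weight_da / 1e6


def amount_on_column(molarity_pm: float, volume_ul: float, recovery_fraction: float = 1.0) -> float:
    """Femtomoles delivered to the column.

    pM times microlitres gives 1e-21 mol, so ``pM * ul * recovery / 1000``
    in fmol: 20 pM from 100 ul at full recovery is 2 fmol.
    """
    if molarity_pm <= 0 or volume_ul <= 0:
        raise ValueError("molarity and volume must be positive")
    if not 0 < recovery_fraction <= 1:
        raise ValueError("recovery_fraction must be in (0, 1]")
    return molarity_pm * volume_ul * recovery_fraction * 1e-3


def detectable(scenario: DetectionScenario) -> tuple[bool, float]:
    """Is the scenario's on-column amount above the instrument limit?

    Returns ``(detectable, margin)`` where margin is the ratio of the
    delivered amount to the limit (>= 1 means detectable).
    """
    pm = molarity_from_mass_conc(
        scenario.mass_concentration_ng_ml, scenario.molecular_weight_da
    )
    fmol = amount_on_column(pm, scenario.sample_volume_ul, scenario.recovery_fraction)
    margin = fmol / scenario.instrument_limit_fmol
    return margin >= 1.0, margin
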