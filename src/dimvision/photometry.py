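"""Light environment of the experiment: illuminances, ND attenuation, target luminances.

The study dims a decision box from a bright baseline with neutral-density (ND)
filters, producing four light levels. Illuminance (lux) characterises the ambient
light; the discrimination task additionally fixes a positive-target luminance
(cd m^-2) per level. All attenuation arithmetic is in log10 units, the standard
unit for ND filters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Optional

#: Illuminance at the waiting perch in the flight cage, lux (constant across levels).
FLIGHT_CAGE_LUX = 1400.0

#: Target diameter in degrees of visual field, and centre-to-centre separation of the
#: two discrimination targets.  Stored as metadata only: the effective viewing
#: distance inside the box is ambiguous, so these angles are not re-derived from the
#: box geometry.
TARGET_ANGLE_DEG = 9.6
TARGET_SEPARATION_DEG = 30.7


@dataclass(frozen=True)
class LightLevel:
    """One ambient light condition of the experiment.

    Attributes
    ----------
    level_id:
        1 (brightest) through 4 (dimmest).
    decision_box_illuminance:
        Lux in the decision box where choices are made.
    flight_cage_illuminance:
        Lux at the waiting perch; constant 1400 across levels.
    nd_attenuation:
        log10 units of ND filtering relative to level 1 (0 for level 1).
    exp2_positive_luminance:
        Fixed luminance (cd m^-2) of the positive target in the discrimination
        task at this level.
    background_luminance:
        Ambient background luminance I_B of Weber's law (dI / I_B = k); may be
        below the birds' detectability at the dimmest levels and is optional.
    """

    level_id: int
    decision_box_illuminance: float
    exp2_positive_luminance: float
    nd_attenuation: float = 0.0
    flight_cage_illuminance: float = FLIGHT_CAGE_LUX
    background_luminance: Optional[float] = None

    def __post_init__(self) -> None:
        if not 1 <= self.level_id <= 4:
            raise ValueError(f"level_id must be in 1..4, got {self.level_id}")
        if self.decision_box_illuminance <= 0:
            raise ValueError("decision_box_illuminance must be positive")
        if self.nd_attenuation < 0:
            raise ValueError("nd_attenuation must be non-negative")


def log_attenuation(source_illuminance: float, target_illuminance: float) -> float:
    """Log10-unit drop from a source to a (dimmer) target illuminance.

    Positive when the target is dimmer than the source; additive over a chain
    of filters.  Both inputs must be strictly positive.
    """
    if source_illuminance <= 0 or target_illuminance <= 0:
        raise ValueError("illuminances must be strictly positive")
    return math.log10(source_illuminance / target_illuminance)


def apply_nd(luminance: float, log_units: float) -> float:
    """Attenuate a luminance (or illuminance) by an ND filter of ``log_units``."""
    if luminance < 0:
        raise ValueError("luminance must be non-negative")
    return luminance * 10.0 ** (-log_units)


def round_log_drop(value: float, decimals: int = 1) -> float:
    """Round a reported log-unit drop to one decimal, half away from zero."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(value) * factor + 0.5), value) / factor


def default_light_levels() -> list[LightLevel]:
    """The four light conditions of the study.

    Decision-box illuminances 469, 28, 1.83 and 0.47 lux; the dimmest value was
    extrapolated by the experimenters from the others and is treated as ground
    truth here.  Positive-target luminances for the discrimination task are 200,
    10.4, 0.68 and 0.19 cd m^-2.
    """
    box_lux = [469.0, 28.0, 1.83, 0.47]
    pos_lum = [200.0, 10.4, 0.68, 0.19]
    levels = []
    for i, (lux, lum) in enumerate(zip(box_lux, pos_lum), start=1):
        levels.append(
            LightLevel(
                level_id=i,
                decision_box_illuminance=lux,
                exp2_positive_luminance=lum,
                nd_attenuation=log_attenuation(box_lux[0], lux),
            )
        )
    return levels


def light_level_table(levels: Optional[list[LightLevel]] = None) -> list[dict]:
    """Serializable plain-text representation (list of key/value rows)."""
    return [asdict(lv) for lv in (levels or default_light_levels())]


def light_levels_from_table(rows: list[dict]) -> list[LightLevel]:
    """Inverse of :func:`light_level_table`."""
    return [LightLevel(**row) for row in rows]
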