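"""Energy-to-CO2eq conversion and emission accounting.

Operational emissions are the product of measured electrical energy and the
yearly averaged carbon intensity of the grid that powered the hardware
(grams CO2eq per kWh).  Facility overhead enters through the power usage
effectiveness (PUE) multiplier; meters that report facility-level energy set
``pue_applied`` and are not multiplied again.  A model's footprint over a
usage horizon is training (paid once) plus per-use inference emissions times
the number of uses.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import (
    CarbonIntensityRecord,
    EmissionDerivation,
    EmissionValue,
    EnergyMeasurement,
    ModelEntry,
    ValidationError,
)

__all__ = [
    "DEFAULT_PUE",
    "EmissionConfig",
    "energy_to_co2eq",
    "mean_per_slide_emission",
    "combined_emission",
]

#: Facility PUE of the reference GPU server room.
DEFAULT_PUE = 1.58


@dataclass(frozen=True)
class EmissionConfig:
    """Conversion parameters: regional carbon intensity and facility PUE."""

    intensity: CarbonIntensityRecord
    pue: float = DEFAULT_PUE

    def __post_init__(self) -> None:
        if self.pue < 1.0:
            raise ValidationError(f"PUE must be >= 1, got {self.pue}")


def energy_to_co2eq(energy: EnergyMeasurement, cfg: EmissionConfig) -> EmissionValue:
    """Convert measured energy to grams CO2eq.

    grams = energy[kWh] x intensity[g/kWh].  If the measurement is a raw
    device reading (``pue_applied`` false) the facility PUE is applied first.
    The derivation (energy, intensity, region) is recorded on the result.
    """
    wh = energy.energy_wh
    if not energy.pue_applied:
        wh *= cfg.pue
    grams = wh / 1000.0 * cfg.intensity.g_per_kwh
    return EmissionValue(
        grams,
        EmissionDerivation(wh, cfg.intensity.g_per_kwh, cfg.intensity.region),
    )


def mean_per_slide_emission(replicates: list[EmissionValue]) -> EmissionValue:
    """Arithmetic mean over replicate per-slide measurements.

    The replicate count is what the bootstrap later resamples, so callers
    should keep the raw list around rather than only the mean.
    """
    if not replicates:
        raise ValidationError("need at least one replicate")
    grams = float(np.mean([r.grams_co2eq for r in replicates]))
    return EmissionValue(grams)


def combined_emission(entry: ModelEntry, n_usage: float) -> EmissionValue:
    """Training emission plus ``n_usage`` inferences (and per-use overhead).

    Affine and non-decreasing in ``n_usage``; the per-use overhead models
    optional extras such as attention-heatmap visualization that require an
    additional inference pass.
    """
    if n_usage < 0:
        raise ValidationError(f"n_usage must be >= 0, got {n_usage}")
    if entry.train_emission is None:
        raise ValidationError(f"model {entry.model_id!r} has no training emission")
    if entry.inference_emission_per_use is None:
        raise ValidationError(f"model {entry.model_id!r} has no inference emission")
    per_use = entry.inference_emission_per_use.grams_co2eq
    if entry.per_use_overhead is not None:
        per_use += entry.per_use_overhead.grams_co2eq
    return EmissionValue(entry.train_emission.grams_co2eq + n_usage * per_use)
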