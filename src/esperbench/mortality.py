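"""Mortality-cost-of-carbon usage budgets.

The mortality cost of carbon estimates that every 4400 metric tons of CO2eq
added over the 2020 baseline cause one temperature-related excess death
globally by 2100.  Treating that mass as a budget, the number of model
inferences a region can run before exhausting it is the budget divided by
the per-use emission — which depends on the regional grid intensity, so
low-carbon grids buy vastly more inferences.  Because intensity multiplies
every model's per-use emission identically, the model ranking by budget is
the same in every country.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import pandas as pd

from .records import (
    BenchmarkSeries,
    CarbonIntensityRecord,
    EnergyMeasurement,
    IntensityTable,
    ValidationError,
)

__all__ = [
    "MCC_GRAMS_PER_DEATH",
    "MortalityConfig",
    "usages_until_one_death",
    "positive_predictions",
    "country_comparison",
]

#: 4400 metric tons CO2eq per excess death, in grams.
MCC_GRAMS_PER_DEATH = 4.4e9


@dataclass(frozen=True)
class MortalityConfig:
    """Mortality-cost constant and optional per-class disease prevalence."""

    mcc_grams_per_death: float = MCC_GRAMS_PER_DEATH
    prevalence: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mcc_grams_per_death <= 0:
            raise ValidationError("mortality cost must be > 0 grams")
        for name, rate in self.prevalence.items():
            if not (0.0 <= rate <= 1.0):
                raise ValidationError(
                    f"prevalence for {name!r} must be in [0,1], got {rate}"
                )


def usages_until_one_death(
    energy_per_use: EnergyMeasurement,
    intensity: CarbonIntensityRecord,
    cfg: MortalityConfig | None = None,
) -> float:
    """Whole inferences runnable before the budget of one excess death is spent.

    floor(mcc / per-use grams), with per-use grams = energy[kWh] x intensity.
    A zero per-use emission (zero energy or a fully carbon-free grid) makes
    the budget unbounded, signalled as ``math.inf`` rather than an error.
    """
    cfg = cfg or MortalityConfig()
    grams_per_use = energy_per_use.energy_kwh * intensity.g_per_kwh
    if grams_per_use == 0.0:
        return math.inf
    return float(math.floor(cfg.mcc_grams_per_death / grams_per_use))


def positive_predictions(
    usages: float, cfg: MortalityConfig, class_name: str
) -> float:
    """Expected positive calls among ``usages`` inferences at the class prevalence."""
    if class_name not in cfg.prevalence:
        raise ValidationError(f"no prevalence configured for class {class_name!r}")
    rate = cfg.prevalence[class_name]
    if math.isinf(usages):
        return math.inf if rate > 0 else 0.0
    return float(math.floor(usages * rate))


def country_comparison(
    series: BenchmarkSeries,
    intensity_table: IntensityTable,
    cfg: MortalityConfig | None = None,
) -> pd.DataFrame:
    """Usage budgets (and positives) for every model in every country.

    One row per (country, model); columns ``g_per_use``, ``usages_budget``
    and one ``positives_<class>`` column per configured prevalence class.
    The within-country ordering of models is intensity-independent and is
    asserted identical across countries.
    """
    cfg = cfg or MortalityConfig()
    if len(intensity_table) == 0:
        raise ValidationError("intensity table is empty")
    for e in series:
        if e.inference_energy is None:
            raise ValidationError(
                f"model {e.model_id!r} has no per-use energy measurement"
            )

    rows = []
    orderings = {}
    for region in intensity_table.regions:
        rec = intensity_table.lookup(region)
        budgets = {}
        for e in series:
            assert e.inference_energy is not None
            budget = usages_until_one_death(e.inference_energy, rec, cfg)
            row = {
                "country": region,
                "model_id": e.model_id,
                "g_per_use": e.inference_energy.energy_kwh * rec.g_per_kwh,
                "usages_budget": budget,
            }
            for cls in cfg.prevalence:
                row[f"positives_{cls}"] = positive_predictions(budget, cfg, cls)
            rows.append(row)
            budgets[e.model_id] = budget
        orderings[region] = sorted(budgets, key=lambda m: (-budgets[m], m))

    distinct = {tuple(v) for v in orderings.values()}
    if len(distinct) > 1:
        raise AssertionError(
            "model ranking by usage budget differs across countries; "
            "per-use energies are inconsistent"
        )
    return pd.DataFrame(rows)
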