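"""Reference fixtures: the published five-model pathology benchmark.

These are the measured values the package's worked examples and acceptance
checks recompute against — five weakly supervised/foundation models
(TransMIL, CLAM, InceptionV3, ViT, Prov-GigaPath) benchmarked on renal cell
carcinoma (RCC) subtyping and kidney transplant (KTX) disease
classification, with energy metered on a V100 DGX node (PUE 1.58) powered
from the German grid.

Provenance caveats, stated here once:

* The German carbon intensity of 361 g/kWh is *recovered*, not sourced: it
  is the emission/energy ratio of the training measurements, consistent to
  <0.1 g/kWh across all five models.  ``recovered_intensity()`` is labeled
  accordingly.
* The reported ViT per-slide inference emission is internally inconsistent
  in the source measurements (0.065 g in the table vs 0.062 g in the
  accompanying text; 361 g/kWh x 0.170 Wh gives 0.061 g).  The fixture
  carries the tabulated 0.065 g unchanged; nothing here "corrects" it.
* For the KTX task only TransMIL's mean macro AUROC (0.763) is published
  directly; the other four AUROCs are back-derived from the published
  score column (M = sqrt(score * exp(norm))) and marked reconstructed.
"""

from __future__ import annotations

from .records import (
    BenchmarkSeries,
    CarbonIntensityRecord,
    EmissionValue,
    EnergyMeasurement,
    IntensityTable,
    Metric,
    ModelEntry,
    PerformanceScore,
    Phase,
    Scope,
)
from .reduction import ReductionPoint, TileConfig

__all__ = [
    "recovered_intensity",
    "illustrative_intensity_table",
    "energy_benchmark",
    "ktx_auroc_series",
    "resolution_sweep_points",
]

#: (model, train kWh, train kg CO2eq, inference Wh/slide, inference g CO2eq/slide)
ENERGY_TABLE = [
    ("TransMIL", 11.263, 4.065, 0.128, 0.046),
    ("CLAM", 11.713, 4.228, 0.132, 0.048),
    ("InceptionV3", 10.584, 3.821, 0.201, 0.073),
    ("ViT", 23.873, 8.618, 0.170, 0.065),
    ("Prov-GigaPath", 42.625, 15.388, 0.63, 0.229),
]

#: KTX-task mean macro AUROCs.  TransMIL's 0.763 is published directly; the
#: rest are reconstructed from the published AUROC-based score column
#: (0.547, 0.391, 0.439, 0.188) by inverting the score formula at w = 1.
KTX_AUROC = {
    "TransMIL": 0.763,
    "CLAM": 0.7437,  # reconstructed
    "InceptionV3": 0.6732,  # reconstructed
    "ViT": 0.6979,  # reconstructed
    "Prov-GigaPath": 0.7149,  # reconstructed
}

#: Resolution sweep for TransMIL on KTX: (pixels, edge µm, g CO2eq/slide, AUROC)
RESOLUTION_TABLE = [
    (224, 1024.0, 0.025, 0.702),
    (224, 256.0, 0.138, 0.762),
    (512, 256.0, 0.383, 0.678),
    (224, 128.0, 1.87, 0.640),
]


def recovered_intensity() -> CarbonIntensityRecord:
    """German grid intensity recovered from the training emission/energy ratio."""
    return CarbonIntensityRecord("DE", 2022, 361.0)


def illustrative_intensity_table() -> IntensityTable:
    """A small multi-country table for mortality-budget comparisons.

    Only the German value is tied to the benchmark (recovered, see module
    docstring); the others are illustrative round numbers spanning
    low-carbon (hydro/nuclear) to coal-heavy grids.
    """
    return IntensityTable(
        [
            recovered_intensity(),
            CarbonIntensityRecord("NO", 2022, 30.0),
            CarbonIntensityRecord("SE", 2022, 45.0),
            CarbonIntensityRecord("FR", 2022, 85.0),
            CarbonIntensityRecord("US", 2022, 390.0),
            CarbonIntensityRecord("PL", 2022, 750.0),
        ]
    )


def energy_benchmark() -> BenchmarkSeries:
    """The five models' measured energies and emissions (no metric scores)."""
    entries = []
    for model, train_kwh, train_kg, infer_wh, infer_g in ENERGY_TABLE:
        entries.append(
            ModelEntry(
                model_id=model,
                scores={},
                train_emission=EmissionValue.from_kg(train_kg),
                inference_emission_per_use=EmissionValue(infer_g),
                train_energy=EnergyMeasurement.from_kwh(
                    train_kwh, Phase.TRAINING, Scope.PER_RUN
                ),
                inference_energy=EnergyMeasurement(
                    infer_wh, Phase.INFERENCE, Scope.PER_SLIDE, n_replicates=15
                ),
            )
        )
    return BenchmarkSeries(tuple(entries), task_label="five-model energy benchmark")


def ktx_auroc_series() -> BenchmarkSeries:
    """KTX task series: published emissions + (partly reconstructed) AUROCs."""
    entries = []
    for entry in energy_benchmark():
        scores = {
            Metric.AUROC: PerformanceScore(Metric.AUROC, KTX_AUROC[entry.model_id])
        }
        entries.append(
            ModelEntry(
                model_id=entry.model_id,
                scores=scores,
                train_emission=entry.train_emission,
                inference_emission_per_use=entry.inference_emission_per_use,
                train_energy=entry.train_energy,
                inference_energy=entry.inference_energy,
            )
        )
    return BenchmarkSeries(tuple(entries), task_label="KTX disease classification")


def resolution_sweep_points() -> list[ReductionPoint]:
    """TransMIL/KTX tile-resolution sweep: four (config, emission, AUROC) points."""
    return [
        ReductionPoint(
            config=TileConfig(pixels, edge_um),
            performance=PerformanceScore(Metric.AUROC, auroc),
            emission_per_slide=EmissionValue(grams),
        )
        for pixels, edge_um, grams, auroc in RESOLUTION_TABLE
    ]
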