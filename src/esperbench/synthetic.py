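"""Synthetic benchmark generation: mock energy meter, model zoo, predictions.

Real carbon benchmarking meters GPU energy during training and inference and
scores predictions on patient cohorts.  Neither is available at desk scale,
so this module provides deterministic stand-ins with known ground truth:

* a **mock meter** whose energy is linear in the number of tiles processed,
  with facility PUE and multiplicative replicate noise — the cost structure
  per-slide measurements actually exhibit;
* a **model-zoo generator** emulating the magnitudes of published
  pathology-model benchmarks (training in the single-to-tens-of-kg CO2eq
  range, inference in the sub-gram-per-slide range at a European grid
  intensity);
* a **binormal prediction simulator** whose two-class macro AUROC has the
  closed form Phi(d'/sqrt(2)), so skill is controllable and recoverable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.special import ndtr

from .emissions import EmissionConfig, energy_to_co2eq, mean_per_slide_emission
from .metrics import PredictionTable, all_metrics
from .records import (
    BenchmarkSeries,
    CarbonIntensityRecord,
    EmissionValue,
    EnergyMeasurement,
    Metric,
    ModelEntry,
    Phase,
    Scope,
    ValidationError,
)

__all__ = [
    "CostModel",
    "SkillSpec",
    "ModelZoo",
    "mock_meter",
    "simulate_predictions",
    "generate_model_zoo",
]

#: Default grid intensity for generated fixtures (central-European mix).
DEFAULT_INTENSITY = CarbonIntensityRecord("DE", 2022, 361.0)

#: Measurement protocol the meter emulates: 1000-tile slides, 1000-slide
#: training set, 300 epochs, 15 inference replicates.
TILES_PER_SLIDE = 1000
TRAIN_SLIDES = 1000
TRAIN_EPOCHS = 300
N_REPLICATES = 15


@dataclass(frozen=True)
class CostModel:
    """Per-model energy cost structure for the mock meter.

    ``wh_per_tile_inference`` is the device-level energy to push one tile
    through the model; training multiplies this by epochs, slides and a
    backprop/amortization factor.  ``noise_cv`` is the coefficient of
    variation of multiplicative replicate noise.
    """

    wh_per_tile_inference: float
    train_multiplier: float = 0.25
    epochs: int = TRAIN_EPOCHS
    pue: float = 1.58
    noise_cv: float = 0.0

    def __post_init__(self) -> None:
        if self.wh_per_tile_inference <= 0 or self.train_multiplier <= 0:
            raise ValidationError("cost-model energies must be > 0")
        if self.epochs <= 0 or self.pue <= 0:
            raise ValidationError("epochs and pue must be > 0")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")


@dataclass(frozen=True)
class SkillSpec:
    """Binormal skill: per-class separation d', cohort size, class count."""

    d_prime: float
    n_cases: int
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.d_prime < 0:
            raise ValidationError("d_prime must be >= 0")
        if self.n_classes < 2:
            raise ValidationError("need at least 2 classes")
        if self.n_cases < self.n_classes:
            raise ValidationError("need at least one case per class")


def mock_meter(
    n_tiles: int,
    cost: CostModel,
    phase: Phase,
    seed: int = 0,
    n_slides: int = TRAIN_SLIDES,
) -> EnergyMeasurement:
    """Deterministic facility-level energy reading for processing tiles.

    Inference: ``n_tiles * wh_per_tile * pue * (1 + eps)`` with
    eps ~ Normal(0, noise_cv) truncated at -0.99 so energy stays positive.
    Training additionally multiplies by epochs, the training-set slide count
    and the backprop multiplier.  The same seed always gives the same value.
    """
    if n_tiles < 0:
        raise ValidationError(f"n_tiles must be >= 0, got {n_tiles}")
    rng = np.random.default_rng(seed)
    eps = max(float(rng.normal(0.0, cost.noise_cv)) if cost.noise_cv > 0 else 0.0, -0.99)
    wh = n_tiles * cost.wh_per_tile_inference * cost.pue * (1.0 + eps)
    if phase is Phase.TRAINING:
        wh *= cost.epochs * cost.train_multiplier * n_slides
        scope = Scope.PER_RUN
    else:
        scope = Scope.PER_SLIDE
    return EnergyMeasurement(wh, phase, scope, n_replicates=1, pue_applied=True)


def simulate_predictions(spec: SkillSpec) -> PredictionTable:
    """Draw a prediction table from the binormal score model.

    Each case's true class is (near-)uniform — one case per class is
    guaranteed so every class is present — and its evidence for class k is
    Normal(d', 1) when k is the true class, Normal(0, 1) otherwise.

    For two classes the evidence is one-dimensional and is mapped to a
    probability by the normal CDF, the textbook binormal ROC model: the
    expected one-vs-rest AUROC is exactly Phi(d'/sqrt(2)).  For three or
    more classes the evidence vector is softmaxed; mixing the classes'
    evidences perturbs each one-vs-rest ranking slightly, so the closed
    form is approximate there.
    """
    rng = np.random.default_rng(spec.seed)
    k, n = spec.n_classes, spec.n_cases
    y = np.concatenate([np.arange(k), rng.integers(0, k, n - k)])
    rng.shuffle(y)
    if k == 2:
        e = rng.normal(0.0, 1.0, size=n)
        e[y == 1] += spec.d_prime
        p1 = ndtr(e)
        probs = np.column_stack([1.0 - p1, p1])
    else:
        z = rng.normal(0.0, 1.0, size=(n, k))
        z[np.arange(n), y] += spec.d_prime
        z -= z.max(axis=1, keepdims=True)
        probs = np.exp(z)
        probs /= probs.sum(axis=1, keepdims=True)
    case_ids = tuple(f"case_{i:05d}" for i in range(n))
    return PredictionTable(case_ids, y, probs)


@dataclass(frozen=True)
class ModelZoo:
    """A generated benchmark plus the raw material behind it: per-model
    prediction tables, emission replicate lists, and cost models."""

    series: BenchmarkSeries
    predictions: Mapping[str, PredictionTable]
    emission_replicates: Mapping[str, list[EmissionValue]]
    cost_models: Mapping[str, CostModel]
    intensity: CarbonIntensityRecord = DEFAULT_INTENSITY


def generate_model_zoo(
    n_models: int,
    seed: int = 0,
    n_cases: int = 300,
    n_classes: int = 3,
    intensity: CarbonIntensityRecord = DEFAULT_INTENSITY,
    noise_cv: float = 0.03,
) -> ModelZoo:
    """Generate a seeded model zoo with realistic emission magnitudes.

    Per-tile inference energies and training multipliers are drawn so that
    training emissions land in roughly 1-30 kg CO2eq and per-slide inference
    emissions in the 0.05-0.25 g range at the default intensity, with skill
    (binormal d') independent of cost so that performance-emission
    trade-offs arise naturally.  Fully deterministic under a fixed seed.
    """
    if n_models < 2:
        raise ValidationError("a zoo needs at least 2 models for a comparison series")
    root = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in root.spawn(3 * n_models)]
    rng = np.random.default_rng(root.spawn(1)[0])

    emission_cfg = EmissionConfig(intensity, pue=1.0)  # meter output is facility-level
    entries = []
    predictions: dict[str, PredictionTable] = {}
    replicates: dict[str, list[EmissionValue]] = {}
    costs: dict[str, CostModel] = {}
    for i in range(n_models):
        model_id = f"model_{i:02d}"
        cost = CostModel(
            wh_per_tile_inference=float(rng.uniform(0.8e-4, 4.0e-4)),
            train_multiplier=float(rng.uniform(0.10, 0.40)),
            noise_cv=noise_cv,
        )
        d_prime = float(rng.uniform(0.5, 3.5))

        train_energy = mock_meter(
            TILES_PER_SLIDE, cost, Phase.TRAINING, seed=child_seeds[3 * i]
        )
        train_emission = energy_to_co2eq(train_energy, emission_cfg)

        rep_seeds = np.random.SeedSequence(child_seeds[3 * i + 1]).spawn(N_REPLICATES)
        rep_energies = [
            mock_meter(
                TILES_PER_SLIDE,
                cost,
                Phase.INFERENCE,
                seed=int(s.generate_state(1)[0] % (2**31)),
            )
            for s in rep_seeds
        ]
        rep_emissions = [energy_to_co2eq(e, emission_cfg) for e in rep_energies]
        mean_emission = mean_per_slide_emission(rep_emissions)
        mean_wh = float(np.mean([e.energy_wh for e in rep_energies]))

        preds = simulate_predictions(
            SkillSpec(d_prime, n_cases, n_classes, seed=child_seeds[3 * i + 2])
        )
        scores = all_metrics(preds)

        entries.append(
            ModelEntry(
                model_id=model_id,
                scores=scores,
                train_emission=train_emission,
                inference_emission_per_use=mean_emission,
                train_energy=train_energy,
                inference_energy=EnergyMeasurement(
                    mean_wh, Phase.INFERENCE, Scope.PER_SLIDE, n_replicates=N_REPLICATES
                ),
            )
        )
        predictions[model_id] = preds
        replicates[model_id] = rep_emissions
        costs[model_id] = cost

    series = BenchmarkSeries(tuple(entries), task_label=f"synthetic_zoo_seed{seed}")
    return ModelZoo(series, predictions, replicates, costs, intensity)
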