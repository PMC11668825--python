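"""Domain types and tabular I/O for carbon-aware model benchmarking.

A benchmark *series* is the set of models compared against each other on one
diagnostic task.  Each entry carries classification performance scores in
[0, 1] together with the operational emissions of training the model once and
of running a single inference (one whole-slide image).  Emission penalties are
range-normalized *within* a series, so the series — not the individual model —
is the unit the scores are defined on.

Canonical internal units are watt-hours for energy and grams CO2eq for
emissions.  Published tables routinely mix kWh/kg (training) with Wh/g
(inference); everything is converted to the canonical pair on load so that no
silent factor-of-1000 error can survive past the reader.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "Metric",
    "Phase",
    "Scope",
    "ValidationError",
    "PerformanceScore",
    "EnergyMeasurement",
    "EmissionValue",
    "CarbonIntensityRecord",
    "ModelEntry",
    "BenchmarkSeries",
    "IntensityTable",
    "load_series",
    "write_series",
    "load_intensity_table",
]


class ValidationError(ValueError):
    """Raised when an input record violates a domain invariant."""


class Metric(str, Enum):
    """The five reported classification metrics, all dimensionless in [0, 1]."""

    AUROC = "auroc"
    BALANCED_ACCURACY = "balanced_accuracy"
    PRECISION = "precision"
    RECALL = "recall"
    F1 = "f1"


class Phase(str, Enum):
    TRAINING = "training"
    INFERENCE = "inference"


class Scope(str, Enum):
    PER_RUN = "per_run"
    PER_SLIDE = "per_slide"


@dataclass(frozen=True)
class PerformanceScore:
    """One measured metric value with an optional confidence interval."""

    metric_name: Metric
    value: float
    ci_low: float | None = None
    ci_high: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise ValidationError(
                f"metric {self.metric_name.value}={self.value!r} outside the "
                f"required range [0,1]"
            )
        if (self.ci_low is None) != (self.ci_high is None):
            raise ValidationError("confidence interval needs both bounds")
        if self.ci_low is not None and self.ci_high is not None:
            if not (self.ci_low <= self.value <= self.ci_high):
                raise ValidationError(
                    f"CI [{self.ci_low}, {self.ci_high}] does not bracket "
                    f"value {self.value}"
                )


@dataclass(frozen=True)
class EnergyMeasurement:
    """Measured electrical energy, canonically in watt-hours.

    ``pue_applied`` records whether the facility power-usage-effectiveness
    multiplier is already folded in (true for facility-level meters, false
    for raw device counters).
    """

    energy_wh: float
    phase: Phase
    scope: Scope
    n_replicates: int = 1
    pue_applied: bool = True

    def __post_init__(self) -> None:
        if self.energy_wh < 0:
            raise ValidationError(f"energy must be >= 0, got {self.energy_wh}")
        if self.n_replicates < 1:
            raise ValidationError("n_replicates must be >= 1")

    @classmethod
    def from_kwh(
        cls,
        energy_kwh: float,
        phase: Phase,
        scope: Scope,
        n_replicates: int = 1,
        pue_applied: bool = True,
    ) -> "EnergyMeasurement":
        return cls(energy_kwh * 1000.0, phase, scope, n_replicates, pue_applied)

    @property
    def energy_kwh(self) -> float:
        return self.energy_wh / 1000.0


@dataclass(frozen=True)
class EmissionDerivation:
    """Provenance of a converted emission: energy, intensity, region."""

    energy_wh: float
    intensity_g_per_kwh: float
    region: str | None = None


@dataclass(frozen=True)
class EmissionValue:
    """A mass of CO2-equivalent emissions in grams (canonical unit)."""

    grams_co2eq: float
    derivation: EmissionDerivation | None = None

    def __post_init__(self) -> None:
        if self.grams_co2eq < 0:
            raise ValidationError(
                f"emission must be >= 0, got {self.grams_co2eq}"
            )

    @classmethod
    def from_kg(cls, kg: float, derivation: EmissionDerivation | None = None) -> "EmissionValue":
        return cls(kg * 1000.0, derivation)

    @property
    def kg_co2eq(self) -> float:
        return self.grams_co2eq / 1000.0

    def __add__(self, other: "EmissionValue") -> "EmissionValue":
        return EmissionValue(self.grams_co2eq + other.grams_co2eq)


@dataclass(frozen=True)
class CarbonIntensityRecord:
    """Yearly averaged grid carbon intensity of a region in g CO2eq per kWh."""

    region: str
    year: int
    g_per_kwh: float

    def __post_init__(self) -> None:
        if self.g_per_kwh < 0:
            raise ValidationError(
                f"carbon intensity must be >= 0, got {self.g_per_kwh} "
                f"for {self.region}/{self.year}"
            )


@dataclass(frozen=True)
class ModelEntry:
    """One model's scores and emissions — a single row of a benchmark table."""

    model_id: str
    scores: Mapping[Metric, PerformanceScore]
    train_emission: EmissionValue | None = None
    inference_emission_per_use: EmissionValue | None = None
    per_use_overhead: EmissionValue | None = None
    train_energy: EnergyMeasurement | None = None
    inference_energy: EnergyMeasurement | None = None

    def score(self, metric: Metric) -> PerformanceScore:
        try:
            return self.scores[metric]
        except KeyError:
            raise ValidationError(
                f"model {self.model_id!r} has no {metric.value} score"
            ) from None


@dataclass(frozen=True)
class BenchmarkSeries:
    """An ordered comparison series of models for one task.

    Emission normalization, and therefore every score, is relative to the
    membership of this series: adding or removing a model can change all
    scores.
    """

    entries: tuple[ModelEntry, ...]
    task_label: str = ""

    def __post_init__(self) -> None:
        if len(self.entries) == 0:
            raise ValidationError("a benchmark series needs at least one entry")
        ids = [e.model_id for e in self.entries]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(f"duplicate model_id(s): {dupes}")
        object.__setattr__(self, "entries", tuple(self.entries))

    def __iter__(self) -> Iterator[ModelEntry]:
        return iter(self.entries)

    def __len__(self) -> int:
        return len(self.entries)

    def __getitem__(self, model_id: str) -> ModelEntry:
        for e in self.entries:
            if e.model_id == model_id:
                return e
        raise KeyError(model_id)

    @property
    def model_ids(self) -> list[str]:
        return [e.model_id for e in self.entries]


class IntensityTable(Sequence[CarbonIntensityRecord]):
    """Carbon-intensity records keyed by (region, year) with latest-year lookup."""

    def __init__(self, records: Sequence[CarbonIntensityRecord]):
        self._records = tuple(records)
        self._by_key: dict[tuple[str, int], CarbonIntensityRecord] = {}
        for rec in self._records:
            self._by_key[(rec.region, rec.year)] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __getitem__(self, i):  # type: ignore[override]
        return self._records[i]

    @property
    def regions(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self._records:
            seen.setdefault(r.region, None)
        return list(seen)

    def lookup(self, region: str, year: int | None = None) -> CarbonIntensityRecord:
        """Return the record for ``region``; latest year unless ``year`` given."""
        if year is not None:
            try:
                return self._by_key[(region, year)]
            except KeyError:
                raise ValidationError(
                    f"no carbon intensity for region {region!r} in {year}"
                ) from None
        candidates = [r for r in self._records if r.region == region]
        if not candidates:
            raise ValidationError(f"region not found: {region!r}")
        return max(candidates, key=lambda r: r.year)


# --- tabular I/O ------------------------------------------------------------

_METRIC_COLUMNS = {m: f"metric_{m.value}" for m in Metric}

_SERIES_COLUMNS = [
    "model_id",
    *_METRIC_COLUMNS.values(),
    "train_energy_kwh",
    "train_co2eq_kg",
    "infer_energy_wh",
    "infer_co2eq_g",
]


def _row_value(row: pd.Series, col: str) -> float | None:
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def _entry_from_row(
    row: pd.Series,
    idx: int,
    intensity: CarbonIntensityRecord | None,
) -> ModelEntry:
    model_id = str(row["model_id"])
    scores: dict[Metric, PerformanceScore] = {}
    for metric, col in _METRIC_COLUMNS.items():
        v = _row_value(row, col)
        if v is None:
            continue
        try:
            scores[metric] = PerformanceScore(metric, v)
        except ValidationError as exc:
            raise ValidationError(f"row {idx} ({model_id!r}): {exc}") from None

    train_energy = inference_energy = None
    v = _row_value(row, "train_energy_kwh")
    if v is not None:
        try:
            train_energy = EnergyMeasurement.from_kwh(v, Phase.TRAINING, Scope.PER_RUN)
        except ValidationError as exc:
            raise ValidationError(f"row {idx} ({model_id!r}): {exc}") from None
    v = _row_value(row, "infer_energy_wh")
    if v is not None:
        try:
            inference_energy = EnergyMeasurement(v, Phase.INFERENCE, Scope.PER_SLIDE)
        except ValidationError as exc:
            raise ValidationError(f"row {idx} ({model_id!r}): {exc}") from None

    def _emission(grams: float | None, energy: EnergyMeasurement | None) -> EmissionValue | None:
        if grams is not None:
            if grams < 0:
                raise ValidationError(
                    f"row {idx} ({model_id!r}): emission must be >= 0, got {grams}"
                )
            return EmissionValue(grams)
        if energy is not None and intensity is not None:
            grams_conv = energy.energy_kwh * intensity.g_per_kwh
            return EmissionValue(
                grams_conv,
                EmissionDerivation(energy.energy_wh, intensity.g_per_kwh, intensity.region),
            )
        return None

    kg = _row_value(row, "train_co2eq_kg")
    train_emission = _emission(None if kg is None else kg * 1000.0, train_energy)
    g = _row_value(row, "infer_co2eq_g")
    inference_emission = _emission(g, inference_energy)

    return ModelEntry(
        model_id=model_id,
        scores=scores,
        train_emission=train_emission,
        inference_emission_per_use=inference_emission,
        train_energy=train_energy,
        inference_energy=inference_energy,
    )


def _frame_to_series(
    df: pd.DataFrame,
    task_label: str,
    intensity: CarbonIntensityRecord | None,
) -> BenchmarkSeries:
    if "model_id" not in df.columns:
        raise ValidationError("missing required column 'model_id'")
    if len(df) == 0:
        raise ValidationError("benchmark file contains no rows")
    entries = [
        _entry_from_row(row, idx, intensity) for idx, (_, row) in enumerate(df.iterrows())
    ]
    return BenchmarkSeries(tuple(entries), task_label=task_label)


def load_series(
    path: str | Path,
    task_label: str = "",
    intensity: CarbonIntensityRecord | None = None,
) -> BenchmarkSeries:
    """Read a benchmark series from CSV or JSON.

    Expected columns: ``model_id``, ``metric_<name>`` for each reported metric,
    ``train_energy_kwh``, ``train_co2eq_kg``, ``infer_energy_wh``,
    ``infer_co2eq_g``.  Emission columns may be omitted when the energy columns
    and an ``intensity`` record are supplied; the conversion is then performed
    on load and recorded in each emission's derivation.  Row order is
    preserved.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            payload = json.load(fh)
        rows = payload["entries"] if isinstance(payload, dict) else payload
        if isinstance(payload, dict) and not task_label:
            task_label = payload.get("task_label", "")
        df = pd.DataFrame(rows)
    else:
        try:
            df = pd.read_csv(path)
        except pd.errors.EmptyDataError:
            raise ValidationError(f"benchmark file is empty: {path}") from None
    return _frame_to_series(df, task_label, intensity)


def series_to_frame(series: BenchmarkSeries) -> pd.DataFrame:
    """Flatten a series into the canonical column layout (kWh/kg + Wh/g)."""
    rows = []
    for e in series:
        row: dict[str, object] = {"model_id": e.model_id}
        for metric, col in _METRIC_COLUMNS.items():
            if metric in e.scores:
                row[col] = e.scores[metric].value
        if e.train_energy is not None:
            row["train_energy_kwh"] = e.train_energy.energy_kwh
        if e.train_emission is not None:
            row["train_co2eq_kg"] = e.train_emission.kg_co2eq
        if e.inference_energy is not None:
            row["infer_energy_wh"] = e.inference_energy.energy_wh
        if e.inference_emission_per_use is not None:
            row["infer_co2eq_g"] = e.inference_emission_per_use.grams_co2eq
        rows.append(row)
    return pd.DataFrame(rows)


def write_series(series: BenchmarkSeries, path: str | Path) -> None:
    """Write a series to CSV or JSON at full stored precision (round-trip safe)."""
    path = Path(path)
    df = series_to_frame(series)
    if path.suffix.lower() == ".json":
        payload = {
            "task_label": series.task_label,
            "entries": json.loads(df.to_json(orient="records")),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)
    else:
        # default str() formatting is shortest-round-trip, so numeric fields
        # survive write->load bit-exactly
        df.to_csv(path, index=False)


def load_intensity_table(path: str | Path) -> IntensityTable:
    """Read a carbon-intensity CSV with columns ``region, year, g_per_kwh``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = {"region", "year", "g_per_kwh"} - set(df.columns)
    if missing:
        raise ValidationError(f"intensity table missing column(s): {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        try:
            records.append(
                CarbonIntensityRecord(str(row["region"]), int(row["year"]), float(row["g_per_kwh"]))
            )
        except ValidationError as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
    return IntensityTable(records)


def with_metric(entry: ModelEntry, score: PerformanceScore) -> ModelEntry:
    """Return a copy of ``entry`` with one metric score replaced."""
    scores = dict(entry.scores)
    scores[score.metric_name] = score
    return replace(entry, scores=scores)
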