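"""The environmentally sustainable performance (ESPer) scores.

A score couples a classification metric M in [0, 1] with the model's
operational CO2eq emissions.  Emissions are range-normalized over the
comparison series — the lowest and highest emissions in the series set the
normalization bounds — and enter through an exponential penalty that both
punishes high emitters non-linearly and avoids division by zero:

    score_i = M_i**2 / exp(w * norm(C_i)),   norm(x) = (x - min C) / (max C - min C)

with weighting factor w in [0, 1]; w = 0 weighs performance only.  The
squared metric rewards highly accurate models.  Two flavours share this form:

* **iESPer** uses the per-inference emission C_i = CO2eq per slide — the
  steady-state cost of one more prediction.
* **fpESPer** (future projection) uses the combined emission
  C_i(n) = CO2eq_train + n_usage * CO2eq_per_use, re-normalizing the series
  at every usage count n.  Training dominates at n = 0 and washes out of the
  ranking as inference accumulates, which is what makes projection curves of
  different models cross.

Scores are series-relative by construction: adding or removing a model moves
the normalization bounds and can change every score in the series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .emissions import combined_emission, mean_per_slide_emission
from .metrics import PredictionTable, all_metrics
from .records import (
    BenchmarkSeries,
    EmissionValue,
    Metric,
    ModelEntry,
    ValidationError,
)

__all__ = [
    "ESPerConfig",
    "ESPerScore",
    "ProjectionSpec",
    "ProjectionCurve",
    "range_normalize",
    "iesper",
    "fpesper",
    "projection_curve",
    "find_crossings",
    "weight_sweep",
    "rank_models",
    "CIInputs",
    "esper_ci",
    "scores_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ESPerConfig:
    """Weighting factor and the metric the score is computed from."""

    w: float = 1.0
    metric: Metric = Metric.AUROC

    def __post_init__(self) -> None:
        if not (0.0 <= self.w <= 1.0):
            raise ValidationError(f"weighting factor w must be in [0,1], got {self.w}")


@dataclass(frozen=True)
class ESPerScore:
    """One model's score with its full breakdown.

    ``value = metric_squared / penalty`` with
    ``penalty = exp(w * normalized_emission)``; since the penalty is >= 1,
    the score never exceeds the squared metric.
    """

    model_id: str
    value: float
    metric_squared: float
    normalized_emission: float
    penalty: float
    w: float
    ci_low: float | None = None
    ci_high: float | None = None


@dataclass(frozen=True)
class ProjectionSpec:
    """Usage horizon for future-projection scoring."""

    annual_usage: float
    years: float
    grid_points: int = 101

    def __post_init__(self) -> None:
        if self.annual_usage < 0:
            raise ValidationError("annual_usage must be >= 0")
        if self.years <= 0:
            raise ValidationError("projection horizon must be > 0 years")
        if self.grid_points < 2:
            raise ValidationError("need at least 2 grid points")


def range_normalize(values: Sequence[float] | np.ndarray) -> np.ndarray:
    """Map values to [0, 1] by (x - min) / (max - min).

    A degenerate series (all values equal, including a single element)
    carries no information to discriminate on, so every output is 0 — which
    also preserves the w = 0 limit of the scores.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValidationError("cannot normalize an empty series")
    if np.any(x < 0):
        raise ValidationError("emissions must be >= 0")
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x)
    return (x - lo) / (hi - lo)


def _score_series(
    series: BenchmarkSeries,
    cfg: ESPerConfig,
    emissions_g: np.ndarray,
) -> list[ESPerScore]:
    norms = range_normalize(emissions_g)
    out = []
    for entry, norm in zip(series, norms):
        m = entry.score(cfg.metric).value
        penalty = float(np.exp(cfg.w * norm))
        out.append(
            ESPerScore(
                model_id=entry.model_id,
                value=m * m / penalty,
                metric_squared=m * m,
                normalized_emission=float(norm),
                penalty=penalty,
                w=cfg.w,
            )
        )
    return out


def _inference_emissions(series: BenchmarkSeries) -> np.ndarray:
    vals = []
    for e in series:
        if e.inference_emission_per_use is None:
            raise ValidationError(f"model {e.model_id!r} has no inference emission")
        vals.append(e.inference_emission_per_use.grams_co2eq)
    return np.asarray(vals)


def iesper(series: BenchmarkSeries, cfg: ESPerConfig | None = None) -> list[ESPerScore]:
    """Inference ESPer: squared metric over the exponential penalty on the
    range-normalized per-use inference emissions of the series."""
    cfg = cfg or ESPerConfig()
    return _score_series(series, cfg, _inference_emissions(series))


def fpesper(
    series: BenchmarkSeries, cfg: ESPerConfig, n_usage: float
) -> list[ESPerScore]:
    """Future-projection ESPer at a cumulative usage count.

    Combined emissions C_i = train + n_usage * per_use are recomputed and
    re-normalized over the series at this n_usage.
    """
    combined = np.asarray(
        [combined_emission(e, n_usage).grams_co2eq for e in series]
    )
    return _score_series(series, cfg, combined)


@dataclass(frozen=True)
class ProjectionCurve:
    """Sampled fpESPer trajectory of one model plus its continuous evaluator.

    ``evaluate(n)`` recomputes the score at any (possibly fractional) usage
    count with the series re-normalized there; crossing refinement bisects
    on this continuous form.
    """

    model_id: str
    years: np.ndarray
    n_usages: np.ndarray
    values: np.ndarray
    evaluate: Callable[[float], float] = field(compare=False, repr=False)


def projection_curve(
    series: BenchmarkSeries,
    cfg: ESPerConfig,
    spec: ProjectionSpec,
) -> dict[str, ProjectionCurve]:
    """Sample every model's fpESPer on a uniform time grid.

    Usage counts are integral: n(t) = round(annual_usage * t).  The
    normalization bounds are recomputed at every grid point, so curves of
    models trading training cost against inference cost can cross.
    """
    years = np.linspace(0.0, spec.years, spec.grid_points)
    n_grid = np.rint(spec.annual_usage * years)

    def _values_at(n: float) -> dict[str, float]:
        return {s.model_id: s.value for s in fpesper(series, cfg, n)}

    sampled = [_values_at(n) for n in n_grid]
    curves = {}
    for model_id in series.model_ids:
        vals = np.asarray([row[model_id] for row in sampled])

        def _eval(n: float, _mid: str = model_id) -> float:
            return _values_at(n)[_mid]

        curves[model_id] = ProjectionCurve(model_id, years, n_grid.copy(), vals, _eval)
    return curves


def projection_frame(curves: Mapping[str, ProjectionCurve]) -> pd.DataFrame:
    """Long-format table (model_id, years, n_usage, fpesper)."""
    rows = []
    for c in curves.values():
        for t, n, v in zip(c.years, c.n_usages, c.values):
            rows.append({"model_id": c.model_id, "years": t, "n_usage": int(n), "fpesper": v})
    return pd.DataFrame(rows)


def find_crossings(
    curve_a: ProjectionCurve,
    curve_b: ProjectionCurve,
    rel_tol: float = 1e-6,
) -> list[float]:
    """Usage counts where two projection curves intersect.

    Sign changes of the sampled difference are bracketed on the shared grid
    and refined by bisection on the continuous formula to the requested
    relative tolerance.  Identical curves (difference zero everywhere)
    return an empty list; only transversal crossings are reported.
    """
    if curve_a.n_usages.shape != curve_b.n_usages.shape or np.any(
        curve_a.n_usages != curve_b.n_usages
    ):
        raise ValidationError("curves must share a usage grid")
    diff = curve_a.values - curve_b.values
    f = lambda n: curve_a.evaluate(n) - curve_b.evaluate(n)
    crossings: list[float] = []
    for i in range(diff.size - 1):
        lo, hi = curve_a.n_usages[i], curve_a.n_usages[i + 1]
        if lo == hi:
            continue
        if diff[i] * diff[i + 1] < 0:
            xtol = max(rel_tol * max(abs(lo), abs(hi), 1.0), 1e-12)
            crossings.append(float(brentq(f, lo, hi, xtol=xtol)))
        elif diff[i] != 0.0 and diff[i + 1] == 0.0:
            # tangent-or-transversal touch exactly at a grid node
            nxt = diff[i + 2 :]
            nonzero = nxt[nxt != 0.0]
            if nonzero.size == 0 or nonzero[0] * diff[i] < 0:
                crossings.append(float(hi))
    return crossings


def rank_models(
    series: BenchmarkSeries,
    scores: Sequence[ESPerScore],
    emissions_g: np.ndarray | None = None,
) -> list[str]:
    """Model ids from best to worst score.

    Ties break toward the lower-emission model, then lexicographically by
    id, so rankings are deterministic.
    """
    if emissions_g is None:
        emissions_g = _inference_emissions(series)
    keyed = sorted(
        zip(scores, emissions_g),
        key=lambda p: (-p[0].value, p[1], p[0].model_id),
    )
    return [s.model_id for s, _ in keyed]


def weight_sweep(
    series: BenchmarkSeries,
    metric: Metric,
    w_grid: Sequence[float],
) -> pd.DataFrame:
    """Scores and rankings across a grid of weighting factors.

    Returns a long-format table (w, model_id, score, rank) with rank 1 the
    best model at that w.
    """
    rows = []
    for w in w_grid:
        cfg = ESPerConfig(w=float(w), metric=metric)
        scores = iesper(series, cfg)
        ranking = rank_models(series, scores)
        rank_of = {mid: r + 1 for r, mid in enumerate(ranking)}
        for s in scores:
            rows.append(
                {"w": float(w), "model_id": s.model_id, "score": s.value, "rank": rank_of[s.model_id]}
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CIInputs:
    """Raw resampling inputs for the bootstrap: per-model prediction tables
    and per-model lists of per-slide emission replicates."""

    predictions: Mapping[str, PredictionTable]
    emission_replicates: Mapping[str, Sequence[EmissionValue]]


def esper_ci(
    series: BenchmarkSeries,
    cfg: ESPerConfig,
    inputs: CIInputs,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict[str, tuple[float, float]]:
    """Percentile-bootstrap 95% intervals for iESPer scores.

    Each replicate resamples every model's cases with replacement
    (performance side) and its energy replicates with replacement (emission
    side), then rescoring the whole series; the 2.5th/97.5th percentiles of
    each model's bootstrap distribution form the interval.  Fully
    reproducible under a fixed seed.
    """
    if n_boot < 100:
        logger.warning("n_boot=%d is small; percentile CIs will be unstable", n_boot)
    for e in series:
        if e.model_id not in inputs.predictions:
            raise ValidationError(f"no predictions for model {e.model_id!r}")
        if e.model_id not in inputs.emission_replicates:
            raise ValidationError(f"no emission replicates for model {e.model_id!r}")

    rng = np.random.default_rng(seed)
    boot: dict[str, list[float]] = {mid: [] for mid in series.model_ids}
    for _ in range(n_boot):
        metric_vals = []
        emissions = []
        for e in series:
            preds = inputs.predictions[e.model_id]
            reps = inputs.emission_replicates[e.model_id]
            # resample cases until the metric is computable (each class needs
            # both positives and negatives for AUROC)
            for _attempt in range(100):
                idx = rng.integers(0, preds.n_cases, preds.n_cases)
                try:
                    m = all_metrics(preds.subset(idx))[cfg.metric].value
                    break
                except ValidationError:
                    continue
            else:
                raise ValidationError(
                    f"could not resample a scoreable bootstrap set for {e.model_id!r}"
                )
            ridx = rng.integers(0, len(reps), len(reps))
            mean_g = mean_per_slide_emission([reps[i] for i in ridx]).grams_co2eq
            metric_vals.append(m)
            emissions.append(mean_g)
        norms = range_normalize(np.asarray(emissions))
        for mid, m, norm in zip(series.model_ids, metric_vals, norms):
            boot[mid].append(m * m / float(np.exp(cfg.w * norm)))

    return {
        mid: (
            float(np.percentile(vals, 2.5)),
            float(np.percentile(vals, 97.5)),
        )
        for mid, vals in boot.items()
    }


def scores_to_frame(scores: Sequence[ESPerScore]) -> pd.DataFrame:
    """Machine-readable score report, one row per model, full precision."""
    return pd.DataFrame(
        [
            {
                "model_id": s.model_id,
                "value": s.value,
                "metric_squared": s.metric_squared,
                "normalized_emission": s.normalized_emission,
                "penalty": s.penalty,
                "w": s.w,
                "ci_low": s.ci_low,
                "ci_high": s.ci_high,
            }
            for s in scores
        ]
    )
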