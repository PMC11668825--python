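"""Data-reduction sweeps: tile size/resolution and tile-fraction analyses.

Whole-slide images are processed as square tiles defined by a physical edge
length (µm) and an output resolution (px).  Shrinking the physical tile
raises the tile count per slide — and with it the per-slide inference energy
— while changing the structural detail the model sees, so resolution choice
trades performance against emissions.  Independently, randomly subsampling a
fraction of a slide's tiles cuts emissions roughly linearly while AUROC
often plateaus well below 100% of tiles.

Each sweep is scored as its *own* comparison series: the configurations in
the sweep set the normalization bounds, and the score picks the
configuration with the best performance-per-emission trade-off.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .esper import ESPerConfig, iesper, scores_to_frame
from .records import (
    BenchmarkSeries,
    EmissionValue,
    ModelEntry,
    PerformanceScore,
    ValidationError,
)

__all__ = [
    "TileConfig",
    "ReductionPoint",
    "tiles_per_slide",
    "resolution_sweep",
    "fraction_sweep",
    "random_tile_subsample",
]


@dataclass(frozen=True)
class TileConfig:
    """A tiling configuration: output pixels per edge, physical µm per edge."""

    pixels: int
    edge_um: float

    def __post_init__(self) -> None:
        if self.pixels <= 0 or self.edge_um <= 0:
            raise ValidationError("tile pixels and edge length must be > 0")

    @property
    def label(self) -> str:
        edge = int(self.edge_um) if float(self.edge_um).is_integer() else self.edge_um
        return f"{self.pixels}px/{edge}um"


@dataclass(frozen=True)
class ReductionPoint:
    """One sweep observation: a config (tiling or fraction), its performance,
    and the per-slide inference emission measured under it."""

    config: TileConfig | float
    performance: PerformanceScore
    emission_per_slide: EmissionValue

    def __post_init__(self) -> None:
        if isinstance(self.config, float) and not (0.0 < self.config <= 1.0):
            raise ValidationError(
                f"tile fraction must be in (0, 1], got {self.config}"
            )

    @property
    def label(self) -> str:
        if isinstance(self.config, TileConfig):
            return self.config.label
        return f"frac={self.config:g}"


def tiles_per_slide(tissue_area_mm2: float, config: TileConfig) -> int:
    """Tiles needed to cover a tissue area: ceil(area / tile area).

    Partial tiles at the boundary still get processed, hence the ceiling.
    Halving the edge length quadruples the count (up to that ceiling).
    """
    if tissue_area_mm2 <= 0:
        raise ValidationError(f"tissue area must be > 0, got {tissue_area_mm2}")
    area_um2 = tissue_area_mm2 * 1e6
    return int(math.ceil(area_um2 / (config.edge_um**2)))


def _points_to_series(points: list[ReductionPoint], task_label: str) -> BenchmarkSeries:
    entries = []
    for p in points:
        entries.append(
            ModelEntry(
                model_id=p.label,
                scores={p.performance.metric_name: p.performance},
                inference_emission_per_use=p.emission_per_slide,
            )
        )
    return BenchmarkSeries(tuple(entries), task_label=task_label)


def _score_sweep(points: list[ReductionPoint], w: float) -> pd.DataFrame:
    metric = points[0].performance.metric_name
    if any(p.performance.metric_name is not metric for p in points):
        raise ValidationError("sweep points mix different performance metrics")
    series = _points_to_series(points, "sweep")
    scores = iesper(series, ESPerConfig(w=w, metric=metric))
    df = scores_to_frame(scores).rename(columns={"model_id": "config"})
    df.insert(1, "emission_g", [p.emission_per_slide.grams_co2eq for p in points])
    df.insert(1, "performance", [p.performance.value for p in points])
    return df


def resolution_sweep(
    points: list[ReductionPoint], w: float = 1.0
) -> tuple[pd.DataFrame, TileConfig]:
    """Score a tile-size/resolution sweep and return the best configuration.

    The argmax of the score wins; exact ties break toward the lower-emission
    configuration.
    """
    if len(points) < 2:
        raise ValidationError("a resolution sweep needs at least 2 points")
    if not all(isinstance(p.config, TileConfig) for p in points):
        raise ValidationError("resolution sweep points must carry TileConfig")
    labels = [p.label for p in points]
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate tile configurations in sweep")
    df = _score_sweep(points, w)
    order = sorted(
        range(len(points)),
        key=lambda i: (-df["value"].iloc[i], df["emission_g"].iloc[i]),
    )
    best = points[order[0]].config
    assert isinstance(best, TileConfig)
    return df, best


def fraction_sweep(
    points: list[ReductionPoint],
    w: float = 1.0,
    plateau_tol: float = 0.005,
) -> tuple[pd.DataFrame, float, float]:
    """Score a tile-fraction sweep.

    Returns ``(table, optimal_fraction, plateau_fraction)`` where the
    optimal fraction maximizes the score and the plateau fraction is the
    smallest fraction whose performance is within ``plateau_tol`` (absolute)
    of the full-tiles value.  Fractions must be strictly increasing and end
    at 1.0, and measured emissions must increase with the fraction.
    """
    if len(points) < 2:
        raise ValidationError("a fraction sweep needs at least 2 points")
    fracs = []
    for p in points:
        if not isinstance(p.config, float):
            raise ValidationError("fraction sweep points must carry float fractions")
        fracs.append(p.config)
    if any(b <= a for a, b in zip(fracs, fracs[1:])):
        raise ValidationError("fractions must be strictly increasing")
    if fracs[-1] != 1.0:
        raise ValidationError("fraction sweep must include the full-tiles point 1.0")
    emis = [p.emission_per_slide.grams_co2eq for p in points]
    if any(b <= a for a, b in zip(emis, emis[1:])):
        raise ValidationError(
            "per-slide emissions must increase strictly with the tile fraction"
        )

    df = _score_sweep(points, w)
    order = sorted(
        range(len(points)),
        key=lambda i: (-df["value"].iloc[i], df["emission_g"].iloc[i]),
    )
    optimal = float(fracs[order[0]])

    full_perf = points[-1].performance.value
    plateau = 1.0
    for p, f in zip(points, fracs):
        if abs(p.performance.value - full_perf) <= plateau_tol:
            plateau = float(f)
            break
    return df, optimal, plateau


def random_tile_subsample(
    tile_ids: list, fraction: float, seed: int
) -> list:
    """Draw floor(fraction * n) tiles uniformly without replacement.

    Seed-reproducible; the output order is the draw order, not the input
    order (at fraction 1 you get all tiles, possibly permuted).
    """
    if not tile_ids:
        raise ValidationError("no tiles to subsample")
    if not (0.0 < fraction <= 1.0):
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    n_keep = int(math.floor(fraction * len(tile_ids)))
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(tile_ids), size=n_keep, replace=False)
    return [tile_ids[i] for i in idx]
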