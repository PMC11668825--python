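import pytest

from esperbench.fixtures import (
    energy_benchmark,
    illustrative_intensity_table,
    ktx_auroc_series,
    recovered_intensity,
    resolution_sweep_points,
)
from esperbench.records import (
    BenchmarkSeries,
    EmissionValue,
    Metric,
    ModelEntry,
    PerformanceScore,
)
from esperbench.synthetic import generate_model_zoo


def make_series(models, task="toy"):
    """Build a series from (model_id, metric_value, train_g, infer_g) tuples."""
    entries = []
    for model_id, m, train_g, infer_g in models:
        entries.append(
            ModelEntry(
                model_id=model_id,
                scores={Metric.AUROC: PerformanceScore(Metric.AUROC, m)},
                train_emission=None if train_g is None else EmissionValue(train_g),
                inference_emission_per_use=EmissionValue(infer_g),
            )
        )
    return BenchmarkSeries(tuple(entries), task_label=task)


@pytest.fixture(scope="session")
def ktx_series():
    return ktx_auroc_series()


@pytest.fixture(scope="session")
def energy_series():
    return energy_benchmark()


@pytest.fixture(scope="session")
def sweep_points():
    return resolution_sweep_points()


@pytest.fixture(scope="session")
def intensity_de():
    return recovered_intensity()


@pytest.fixture(scope="session")
def intensity_table():
    return illustrative_intensity_table()


@pytest.fixture(scope="session")
def small_zoo():
    """A 3-model zoo with a modest cohort; shared across tests for speed."""
    return generate_model_zoo(3, seed=11, n_cases=120, n_classes=3)
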