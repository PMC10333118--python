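import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from tigersynth.panel import NUMERIC_COVARIATES, StudyDataset, validate_study

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_toy_study(
    n_reserves: int = 5,
    years: tuple[int, int] = (2001, 2010),
    intervention: dict[str, int] | None = None,
    losses: dict[str, list[float]] | None = None,
    areas: dict[str, float] | None = None,
    group: str = "G1",
    seed: int = 0,
) -> StudyDataset:
    """Small deterministic study for unit tests.

    Default losses are linear ramps with per-reserve slopes; pass
    ``losses`` to override individual trajectories.
    """
    start, end = years
    n_years = end - start + 1
    ids = [f"R{i:02d}" for i in range(n_reserves)]
    rng = np.random.default_rng(seed)
    rows = []
    for i, rid in enumerate(ids):
        if losses and rid in losses:
            vals = losses[rid]
            assert len(vals) == n_years
        else:
            slope = 1.0 + i
            vals = [slope * (t + 1) for t in range(n_years)]
        for t, v in enumerate(vals):
            rows.append((rid, start + t, float(v)))
    outcomes = pd.DataFrame(rows, columns=["reserve_id", "year", "cumulative_loss_ha"])

    cov = pd.DataFrame({"reserve_id": ids})
    for j, c in enumerate(NUMERIC_COVARIATES):
        cov[c] = 10.0 + j + rng.normal(0, 1, n_reserves)
    cov["age"] = np.abs(cov["age"])
    if areas:
        cov["area_ha"] = [areas.get(rid, 1000.0) for rid in ids]
    else:
        cov["area_ha"] = 1000.0 + 100.0 * np.arange(n_reserves)
    cov["group"] = group

    intervention = intervention or {}
    trt = pd.DataFrame({"reserve_id": ids})
    trt["intervention_year"] = pd.array(
        [intervention.get(rid) for rid in ids], dtype="Int64"
    )

    carbon = pd.DataFrame(
        {
            "reserve_id": ids,
            "agb_c_density": 60.0,
            "bgb_c_density": 20.0,
            "agb_c_se": 10.0,
            "bgb_c_se": 5.0,
            "forest_cover_2010": 800.0,
            "forest_cover_interv": 800.0,
        }
    )
    return validate_study(StudyDataset(outcomes, cov, trt, carbon))


@pytest.fixture
def toy_study():
    return make_toy_study(n_reserves=5, intervention={"R00": 2006})
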