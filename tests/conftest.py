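import numpy as np
import pytest

from myoecv.cohort import load_table1
from myoecv.ecv import R1TimePoint
from myoecv.synthetic import (
    KineticsParams,
    default_schedule,
    render_histology_field,
    simulate_r1_course,
)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


def course_points(tau: float, lambda_true: float = 0.45) -> list[R1TimePoint]:
    params = KineticsParams(lambda_true=lambda_true, exchange_tau=tau)
    course = simulate_r1_course(params, default_schedule())
    return [
        R1TimePoint(float(r["t_min"]), float(r["r1_blood"]), float(r["r1_myo"]))
        for r in course
    ]


@pytest.fixture(scope="session")
def equilibrium_points():
    """Noiseless instantaneous-equilibrium course (ratio exactly lambda)."""
    return course_points(tau=0.0)


@pytest.fixture(scope="session")
def lagged_points():
    """Noiseless course with the default 1.5 min blood-tissue lag."""
    return course_points(tau=1.5)


@pytest.fixture(scope="session")
def histology_field():
    """One fine-resolution field shared by the morphometry tests."""
    return render_histology_field(
        breadth_mean=10.0, breadth_sd=1.5, um_per_px=0.25, cell_density_target=150, seed=42
    )


def add_r1_noise(points, sd, rng):
    return [
        R1TimePoint(
            p.t_min,
            p.r1_blood + (rng.normal(0.0, sd) if p.t_min >= 0 else 0.0),
            p.r1_myo + rng.normal(0.0, sd),
        )
        for p in points
    ]
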