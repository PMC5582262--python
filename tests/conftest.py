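import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import gestag as g

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def curves():
    return g.default_curves()


@pytest.fixture
def normal_params(curves):
    """Nominal normal-pregnancy model: k_i = 5 mg/day, normoglycemic."""
    return g.KineticParams(k_i=5.0, glucose=5.0, curves=curves)


@pytest.fixture
def diabetic_params(curves):
    """Nominal diabetic-pregnancy model: [G] = 8.9 mM under the classic
    glucose-only reabsorption form."""
    return g.KineticParams(k_i=5.0, glucose=8.9, curves=curves, reabs_form="stickle")


@pytest.fixture
def week_grid():
    return np.arange(6.0, 39.0, 2.0)


def make_series(rows):
    """rows: (subject_id, group, week, variable, value[, sd]) tuples."""
    return g.LongitudinalSeries.from_records(rows)


@pytest.fixture
def gfr_noise_free():
    """Noise-free GFR cohort sampled from the default quadratic."""
    curve = g.GFRQuadratic()
    rows = [
        (f"s{i}", "normal", w, "gfr", g.eval_gfr(curve, w))
        for i in range(3)
        for w in (0.0, 16.0, 26.0, 36.0)
    ]
    return make_series(rows)
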