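import numpy as np
import pytest

from facdeg import (
    Factor,
    FactorialModel,
    attach_responses,
    build_full_factorial,
    datasets,
)

# Observed % degradation of the 8-run alkali study, standard order
# (NaOH alternating fastest, then time, then power).
ALKALI_RESPONSES = [0.0, 0.0, 2.0, 8.0, 17.0, 21.0, 28.0, 33.0]

# Published two-decimal coefficients of the saturated fit, by term label.
PUBLISHED_COEFFS = {
    "1": 13.62,
    "X1": 1.88,
    "X2": 4.12,
    "X3": 11.12,
    "X1X2": 0.88,
    "X2X3": 1.62,
    "X1X3": 0.38,
    "X1X2X3": -0.62,
}

# Recovery panels (rows = days) and their published summary statistics.
RECOVERY_PANELS = {
    80.0: [[78.34, 79.43, 81.33], [79.24, 81.09, 80.11], [80.39, 80.43, 82.72]],
    100.0: [[101.69, 99.68, 100.72], [98.75, 97.83, 101.06], [99.85, 102.79, 104.03]],
    120.0: [[118.11, 120.36, 119.62], [120.16, 119.88, 117.44], [119.86, 120.43, 123.34]],
}
PUBLISHED_ANOVA = {  # level -> (WMS, BMS, F), truncated to 2 dp
    80.0: (1.64, 1.72, 1.05),
    100.0: (2.79, 6.79, 2.43),
    120.0: (2.34, 3.82, 1.63),
}
PUBLISHED_RSD = {  # level -> per-day %RSD, truncated to 2 dp
    80.0: (1.89, 1.15, 1.64),
    100.0: (0.99, 1.67, 2.10),
    120.0: (0.96, 1.25, 1.53),
}


@pytest.fixture
def alkali_factors():
    return [
        Factor("naoh", 0.1, 1.0, "N"),
        Factor("time", 15.0, 30.0, "min"),
        Factor("power", 420.0, 700.0, "W"),
    ]


@pytest.fixture
def alkali_design(alkali_factors):
    return attach_responses(build_full_factorial(alkali_factors), ALKALI_RESPONSES)


@pytest.fixture
def bundled_design():
    return datasets.load_alkali_design()


@pytest.fixture
def reduced_published_model(alkali_factors):
    """Reduced model with the published two-decimal coefficients
    (intercept, time, power, time*power); NaOH terms already dropped."""
    return FactorialModel(
        factors=tuple(alkali_factors),
        terms=((), (1,), (2,), (1, 2)),
        coefficients=np.array([13.62, 4.12, 11.12, 1.62]),
    )
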