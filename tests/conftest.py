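import pytest

from fplr.rules import (
    BasinSpec,
    FPLRRule1D,
    FPLRRule2D,
    ScalarRegion,
    StepFunction1D,
    Thresholds,
)


@pytest.fixture
def thresholds():
    return Thresholds(theta_D=1.0, theta_P=1.3)


@pytest.fixture
def basic_rule(thresholds):
    """The illustrative 1D rule: drift to 0.5, depress to 0, potentiate to 1."""
    return FPLRRule1D(
        thresholds=thresholds,
        F=StepFunction1D((1.0, 1.3), (0.5, 0.0, 1.0)),
        eta=StepFunction1D((1.0, 1.3), (0.015, 0.15, 0.25)),
        dt=1.0,
    )


@pytest.fixture
def tristable_rule(thresholds):
    """2D rule with tri-stable pre-depressive drift (DOWN/MIDDLE/UP states)."""
    return FPLRRule2D(
        thresholds=thresholds,
        regions=(
            BasinSpec(
                fixed_points=(0.2, 0.5, 0.8),
                boundaries=(0.0, 0.3, 0.7, 1.0),
                learning_rates=(0.01, 0.02, 0.01),
            ),
            ScalarRegion(F=0.0, eta=0.15),
            ScalarRegion(F=1.0, eta=0.25),
        ),
        dt=1.0,
    )
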