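import numpy as np
import pytest

from rmstqba import Cohort, Coding, OutcomeParams


@pytest.fixture
def paper_outcome():
    """Study-condition outcome parameters: lambda=0.073/month, treatment HR
    0.68 after the 5-month change point, confounder halving the hazard."""
    return OutcomeParams(
        log_lambda=float(np.log(0.073)),
        beta_z=float(np.log(0.68)),
        beta_u=float(np.log(0.5)),
        t0=5.0,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_cohort(
    rng: np.random.Generator,
    n: int = 10,
    coding: Coding = Coding.ZERO_ONE,
    censor_frac: float = 0.3,
) -> Cohort:
    """Small arbitrary cohort with both arms present (not model-generated)."""
    time = rng.exponential(12.0, n)
    event = (rng.random(n) > censor_frac).astype(int)
    arm = rng.integers(0, 2, n)
    arm[0], arm[1] = 1, 0  # both arms guaranteed
    return Cohort(time=time, event=event, arm=arm, coding=coding)
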