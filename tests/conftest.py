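import itertools
from dataclasses import replace

import numpy as np
import pytest

from pulsebp import synth


def morphology_grid() -> list[synth.MorphologyParams]:
    """32 well-formed pulse morphologies spanning reflection strength,
    reflected-wave timing, diastolic amplitude and beat period."""
    base = synth.default_morphology()
    grid = []
    for a_srp, c_srp, a_dp, period in itertools.product(
        (0.40, 0.50, 0.60, 0.70), (0.30, 0.33), (0.25, 0.32), (0.90, 1.05)
    ):
        s = period / base.period
        grid.append(
            replace(
                base,
                a_srp=a_srp,
                a_dp=a_dp,
                c_sep=base.c_sep * s,
                c_srp=c_srp * s,
                c_dp=base.c_dp * s,
                w_sep=base.w_sep * s,
                w_srp=base.w_srp * s,
                w_dp=base.w_dp * s,
                period=period,
            )
        )
    return grid


@pytest.fixture(scope="session")
def grid_morphologies():
    return morphology_grid()


@pytest.fixture(scope="session")
def clean_cohort():
    """Small noise-free cohort shared by feature/model tests."""
    params = synth.CohortParams(
        n=8, seed=11, duration_s=30.0, fs=500.0, cuff_sd_mmhg=0.0
    )
    return synth.generate_cohort(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
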