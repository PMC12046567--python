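import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")

from sleepart.containers import EpochSeries
from sleepart.features import extended_cosine_curve


def make_series(
    counts,
    epoch_s=60,
    start="2020-01-06 12:00:00",
    subject="S0",
    session="A",
    excluded=None,
):
    return EpochSeries(
        subject=subject,
        session=session,
        start=pd.Timestamp(start),
        epoch_s=epoch_s,
        counts=np.asarray(counts, dtype=float),
        excluded=excluded,
    )


def exact_cosine_series(
    days=9,
    epoch_s=15,
    minimum=10.0,
    amplitude=100.0,
    acrophase=14.0,
    alpha=0.2,
    beta=8.0,
    start_clock=12.0,
):
    """Float counts exactly on the extended-cosine mean curve (no noise)."""
    per_h = 3600 // epoch_s
    t = np.arange(days * 24 * per_h) / per_h
    clock = (start_clock + t) % 24.0
    y = extended_cosine_curve(clock, minimum, amplitude, acrophase, alpha, beta)
    return make_series(y, epoch_s=epoch_s)


@pytest.fixture
def small_cohort():
    from sleepart.synthetic import SimConfig, generate_cohort

    return generate_cohort(SimConfig(n_subjects=150, seed=42))
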