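"""Shared fixtures: small logs, arcs and scenarios, all generated in-process."""

import numpy as np
import pytest

from quaarc.dose_engine import BeamModel
from quaarc.plan_log import (ControlPoint, DeliveryLog, DiscretizedArc,
                             LogRecord)


def make_record(t, angle, mu_cum, a=-40.0, b=40.0, n_pairs=4, beam_on=True):
    return LogRecord(time=t, gantry_angle=angle,
                     leaf_a=np.full(n_pairs, a), leaf_b=np.full(n_pairs, b),
                     cumulative_mu=mu_cum, beam_on=beam_on)


def open_field_cp(angle=0.0, mu=10.0, half_width=40.0, n_pairs=4, index=0,
                  cumulative=None):
    return ControlPoint(index=index, gantry_angle=angle,
                        leaf_a=np.full(n_pairs, -half_width),
                        leaf_b=np.full(n_pairs, half_width),
                        mu=mu, cumulative_mu=cumulative or mu)


@pytest.fixture
def simple_log():
    """Five records, two of them without MU advance."""
    recs = (
        make_record(0.0, 170.0, 0.0),
        make_record(0.25, 175.0, 0.0),
        make_record(0.5, 180.0, 5.0),
        make_record(0.75, 185.0, 5.0),
        make_record(1.0, 190.0, 10.0),
    )
    return DeliveryLog(recs)


@pytest.fixture
def ramp_log():
    """Constant dose rate, constant gantry speed: 41 records over 10 s."""
    ts = np.arange(0, 10.25, 0.25)
    recs = tuple(make_record(t, (10.0 + 9.0 * t) % 360.0, 2.0 * t)
                 for t in ts)
    return DeliveryLog(recs)


@pytest.fixture
def beam_model():
    return BeamModel()


@pytest.fixture
def one_cp_arc():
    cp = open_field_cp(mu=100.0)
    return DiscretizedArc((cp,), "coarse", 100.0)
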