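import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from lungstage.staging_maps import TNMCategory
from lungstage.survival_core import CohortRecord

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

#: A fixed anatomic cell for tests where staging is irrelevant.
SOME_CATEGORY = TNMCategory("ADC", "T1a", "N0", "M0")


def make_records(times, events=None, category=SOME_CATEGORY, prefix="p"):
    """Build cohort records from parallel time/event sequences."""
    times = np.asarray(times, dtype=float)
    if events is None:
        events = np.ones(len(times), dtype=int)
    return [
        CohortRecord(patient_id=f"{prefix}{i}", category=category,
                     time=float(t), event=int(e))
        for i, (t, e) in enumerate(zip(times, events))
    ]


def exponential_records(rate, n, seed, snap_months=True, category=SOME_CATEGORY,
                        prefix="p"):
    """Uncensored exponential event times, optionally snapped up to whole months."""
    rng = np.random.default_rng(seed)
    t = rng.exponential(1.0 / rate, size=n)
    if snap_months:
        t = np.ceil(t)
    return make_records(t, category=category, prefix=prefix)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
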