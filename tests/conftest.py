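import numpy as np
import pytest

from ptvmargin.errors import StaticUncertaintyTable
from ptvmargin.logio import CohortLog, FractionLog, TrackingSample


def make_log(
    model_errors,
    prediction_errors,
    *,
    patient_id="P0001",
    fraction_index=1,
    site="lower_left_lung",
    tracking_mode="XLT",
    ck_version="VSI_8_5",
    motion_cm=1.5,
    model_times=None,
    prediction_times=None,
):
    """Build a FractionLog from per-sample (SI, LR, AP) error rows.

    Scalar error entries are broadcast isotropically.  Default cadence:
    model samples every 60 s, prediction samples every 1 s.
    """

    def rows(errors, times, default_step):
        errors = [tuple(np.broadcast_to(np.asarray(e, dtype=float), 3)) for e in errors]
        if times is None:
            times = [default_step * (i + 1) for i in range(len(errors))]
        return list(zip(times, errors))

    samples = [
        TrackingSample(time=t, source="model", error=e)
        for t, e in rows(model_errors, model_times, 60.0)
    ] + [
        TrackingSample(time=t, source="prediction", error=e)
        for t, e in rows(prediction_errors, prediction_times, 1.0)
    ]
    return FractionLog(
        patient_id=patient_id,
        fraction_index=fraction_index,
        site=site,
        tracking_mode=tracking_mode,
        ck_version=ck_version,
        motion_amplitude_cm=motion_cm,
        samples=samples,
    )


@pytest.fixture
def static_table():
    return StaticUncertaintyTable()


@pytest.fixture
def small_log():
    rng = np.random.default_rng(42)
    return make_log(
        rng.normal(0, 1, (5, 3)),
        rng.normal(0, 0.5, (20, 3)),
        prediction_times=[15.0 * (i + 1) for i in range(20)],
    )


@pytest.fixture
def tiny_cohort(small_log):
    other = make_log(
        [(0.1, 0.0, -0.2), (0.3, 0.1, 0.0), (-0.1, 0.2, 0.1)],
        [(0.0, 0.1, 0.0), (0.2, -0.1, 0.1), (0.1, 0.0, -0.1), (0.0, 0.0, 0.0)],
        patient_id="P0002",
    )
    return CohortLog(fractions=[small_log, other])
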