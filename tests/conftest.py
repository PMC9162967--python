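from __future__ import annotations

import numpy as np
import pytest

from oxiburden.trace_model import CreatinineSeries, OximetryTrace, PatientRecord


def make_trace(
    values,
    times=None,
    channel: str = "renal_mean",
    incision: float = 0.0,
    end: float | None = None,
) -> OximetryTrace:
    """Build a trace from values on a unit-minute grid unless times given."""
    values = np.asarray(values, dtype=float)
    if times is None:
        times = np.arange(values.size, dtype=float)
    times = np.asarray(times, dtype=float)
    if end is None:
        end = float(times[-1])
    return OximetryTrace(
        channel=channel, times=times, values=values, incision_time=incision, end_time=end
    )


def make_record(
    patient_id: str = "P1",
    channels: dict[str, tuple[np.ndarray, np.ndarray]] | None = None,
    incision: float = 10.0,
    end: float = 40.0,
    baseline_crea: float = 84.0,
    postop=((2, 90.0),),
    arm: str = "off_pump",
) -> PatientRecord:
    """Patient record with flat 80% traces on [0, end] unless overridden."""
    if channels is None:
        t = np.arange(0.0, end + 0.5, 0.5)
        flat = np.full(t.size, 80.0)
        channels = {
            ch: (t, flat) for ch in ("renal_left", "renal_right", "cerebral", "peripheral")
        }
    traces = {
        ch: OximetryTrace(
            channel=ch,
            times=np.asarray(t, dtype=float),
            values=np.asarray(v, dtype=float),
            incision_time=incision,
            end_time=end,
        )
        for ch, (t, v) in channels.items()
    }
    return PatientRecord(
        patient_id=patient_id,
        traces=traces,
        creatinine=CreatinineSeries(baseline_value=baseline_crea, postop=tuple(postop)),
        arm=arm,
        covariates={"duration_min": end - incision, "n_grafts": 3.0, "age": 63.0},
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240924)
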