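"""Postoperative renal impairment labelling from serum creatinine.

Renal impairment is a serum creatinine rise strictly greater than 10% above
the individual preoperative baseline within the first 7 postoperative days.
This is deliberately more sensitive than the KDIGO/AKIN/RIFLE acute-kidney-
injury stages, which are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trace_model import CreatinineSeries


class UnlabeledError(ValueError):
    """No postoperative creatinine value falls inside the labelling window."""


@dataclass(frozen=True)
class OutcomeLabel:
    patient_id: str
    impaired: bool
    max_relative_rise: float
    day_of_max: int | None


def label_renal_impairment(
    series: CreatinineSeries,
    threshold_frac: float = 0.10,
    window_days: int = 7,
    patient_id: str = "",
) -> OutcomeLabel:
    """Label one patient from their creatinine series.

    ``impaired`` is true iff max over postoperative days 1..``window_days``
    of (value / baseline − 1) exceeds ``threshold_frac`` strictly; a rise of
    exactly the threshold is negative.  Values outside the window (e.g. day
    8) are ignored; if none remain, an :class:`UnlabeledError` is raised.
    """
    in_window = [(d, v) for d, v in series.postop if 1 <= d <= window_days]
    if not in_window:
        raise UnlabeledError(
            f"{patient_id or 'patient'}: no postoperative creatinine within "
            f"days 1..{window_days}"
        )
    rises = [(v / series.baseline_value - 1.0, d) for d, v in in_window]
    max_rise, day = max(rises, key=lambda rd: (rd[0], -rd[1]))
    # strict inequality with a guard so a mathematically exact threshold rise
    # (e.g. 110 vs baseline 100) is not tipped over by float rounding
    return OutcomeLabel(
        patient_id=patient_id,
        impaired=max_rise > threshold_frac + 1e-12,
        max_relative_rise=max_rise,
        day_of_max=day,
    )
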