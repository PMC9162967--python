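"""Oxygenation-derived statistics: baselines, AUT desaturation burdens and the
renal-region-specific differential burden.

The area under the threshold (AUT, %·min) of a saturation signal S(t) below a
level L over the analysis window [incision, end] is

    AUT = ∫ max(L − S(t), 0) dt .

For absolute thresholds L ∈ {90, 80, 70, 60}%; for relative thresholds
L = (1 − f)·baseline with f ∈ {5, 10, 15}%.  Two quadrature modes are
available: ``trapezoid`` (default) integrates the clipped piecewise-linear
interpolant exactly, including the point where the signal crosses the
threshold inside a sample interval; ``rectangle`` is the literal per-sample
reading (deficit at the left sample × interval length).  Sample intervals
longer than the gap tolerance contribute zero burden and are totalled as gap
time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .trace_model import OximetryTrace, PatientRecord


class BurdenError(ValueError):
    """Raised when a burden or baseline cannot be computed."""


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable parameters of the burden panel.

    baseline_window : minutes before incision averaged into the baseline.
    gap_tolerance   : maximum sample spacing (min) still integrated; longer
                      intervals contribute zero burden and are logged.
    integration     : ``trapezoid`` or ``rectangle`` (see module docstring).
    """

    baseline_window: float = 5.0
    gap_tolerance: float = 2.0
    integration: str = "trapezoid"
    absolute_thresholds: tuple[float, ...] = (90.0, 80.0, 70.0, 60.0)
    relative_fractions: tuple[float, ...] = (0.05, 0.10, 0.15)
    peripheral_fractions: tuple[float, ...] = (0.10,)

    def __post_init__(self) -> None:
        if self.integration not in ("trapezoid", "rectangle"):
            raise ValueError(f"unknown integration rule {self.integration!r}")


@dataclass(frozen=True)
class BaselineEstimate:
    channel: str
    value: float
    window: tuple[float, float]
    n_samples: int


@dataclass(frozen=True)
class BurdenResult:
    """One AUT value tagged with its provenance.

    ``kind`` is ``absolute`` (threshold = % saturation level), ``relative``
    (threshold = fraction below the individual baseline) or
    ``renal_specific`` (threshold unused).  ``gap_min`` is the total time in
    the window skipped because of over-tolerance sampling gaps.
    """

    channel: str
    kind: str
    threshold: float | None
    aut: float
    window: tuple[float, float]
    gap_min: float = 0.0

    def __post_init__(self) -> None:
        if self.aut < 0:
            raise BurdenError("negative burden")


@dataclass(frozen=True)
class MergedRenal:
    trace: OximetryTrace
    spearman_rho: float
    n_pairs: int


# ---------------------------------------------------------------------------
# quadrature core


def _clipped_area(
    times: np.ndarray,
    deficit_left: np.ndarray,
    deficit_right: np.ndarray,
    rule: str,
    gap_tolerance: float,
) -> tuple[float, float]:
    """Integrate max(deficit, 0) over consecutive intervals.

    ``deficit_left``/``deficit_right`` give the (threshold − signal) values at
    the left and right end of each interval of ``times``; the deficit is
    treated as linear within an interval.  Returns (area, total gap minutes).
    """
    dt = np.diff(times)
    gap = dt > gap_tolerance
    d0 = deficit_left
    d1 = deficit_right
    if rule == "rectangle":
        area = np.maximum(d0, 0.0) * dt
    else:
        area = np.where(
            (d0 > 0) & (d1 > 0),
            0.5 * (d0 + d1) * dt,
            np.where(
                (d0 > 0) & (d1 <= 0),
                0.5 * d0 * d0 / np.where(d0 != d1, d0 - d1, 1.0) * dt,
                np.where(
                    (d1 > 0) & (d0 <= 0),
                    0.5 * d1 * d1 / np.where(d0 != d1, d1 - d0, 1.0) * dt,
                    0.0,
                ),
            ),
        )
    area = np.where(gap, 0.0, area)
    return float(area.sum()), float(dt[gap].sum())


def _window_series(trace: OximetryTrace) -> tuple[np.ndarray, np.ndarray]:
    """Trace samples restricted to [incision, end], with linearly interpolated
    boundary samples when the trace extends past either endpoint."""
    t0, t1 = trace.incision_time, trace.end_time
    t, v = trace.times, trace.values
    lo = max(t0, t[0])
    hi = min(t1, t[-1])
    if hi <= lo:
        raise BurdenError(
            f"{trace.channel}: no samples in analysis window [{t0}, {t1}]"
        )
    inside = (t > lo) & (t < hi)
    tw = np.concatenate(([lo], t[inside], [hi]))
    vw = np.interp(tw, t, v)
    return tw, vw


def compute_baseline(
    trace: OximetryTrace, window_min: float = 5.0
) -> BaselineEstimate:
    """Mean saturation over the ``window_min`` minutes before incision."""
    start = trace.incision_time - window_min
    mask = (trace.times >= start) & (trace.times < trace.incision_time)
    n = int(mask.sum())
    if n == 0:
        raise BurdenError(
            f"{trace.channel}: no samples in baseline window "
            f"[{start:.1f}, {trace.incision_time:.1f}) min"
        )
    return BaselineEstimate(
        channel=trace.channel,
        value=float(trace.values[mask].mean()),
        window=(start, trace.incision_time),
        n_samples=n,
    )


def aut_absolute(
    trace: OximetryTrace, threshold: float, config: AnalysisConfig | None = None
) -> BurdenResult:
    """Desaturation burden below an absolute saturation level, %·min."""
    config = config or AnalysisConfig()
    if not 0 < threshold <= 100:
        raise BurdenError(f"absolute threshold {threshold} outside (0, 100]")
    tw, vw = _window_series(trace)
    d = threshold - vw
    area, gap = _clipped_area(
        tw, d[:-1], d[1:], config.integration, config.gap_tolerance
    )
    return BurdenResult(
        channel=trace.channel,
        kind="absolute",
        threshold=threshold,
        aut=area,
        window=(trace.incision_time, trace.end_time),
        gap_min=gap,
    )


def aut_relative(
    trace: OximetryTrace,
    baseline: BaselineEstimate,
    frac: float,
    config: AnalysisConfig | None = None,
) -> BurdenResult:
    """Burden below ``(1 − frac) × baseline``, %·min."""
    config = config or AnalysisConfig()
    if not 0 < frac < 1:
        raise BurdenError(f"relative fraction {frac} outside (0, 1)")
    level = (1.0 - frac) * baseline.value
    res = aut_absolute(trace, level, config)
    return BurdenResult(
        channel=trace.channel,
        kind="relative",
        threshold=frac,
        aut=res.aut,
        window=res.window,
        gap_min=res.gap_min,
    )


def merge_renal(left: OximetryTrace, right: OximetryTrace) -> MergedRenal:
    """Bilateral average of left and right renal-region channels.

    At times where both sides have a sample the values are averaged; times
    sampled on one side only keep that side's value.  The Spearman rank
    correlation of the paired (common-time) samples is reported alongside.
    """
    if (left.incision_time, left.end_time) != (right.incision_time, right.end_time):
        raise BurdenError("left/right renal traces carry different event times")
    tl = np.round(left.times, 9)
    tr = np.round(right.times, 9)
    common, il, ir = np.intersect1d(tl, tr, return_indices=True)
    if common.size == 0:
        raise BurdenError("no overlapping samples between renal sides")
    union = np.union1d(tl, tr)
    merged = np.empty_like(union)
    in_l = np.isin(union, tl)
    in_r = np.isin(union, tr)
    vl = np.full(union.shape, np.nan)
    vr = np.full(union.shape, np.nan)
    vl[in_l] = left.values[np.searchsorted(tl, union[in_l])]
    vr[in_r] = right.values[np.searchsorted(tr, union[in_r])]
    merged = np.where(
        in_l & in_r, 0.5 * (vl + vr), np.where(in_l, vl, vr)
    )
    lv, rv = left.values[il], right.values[ir]
    if common.size >= 2 and np.ptp(lv) > 0 and np.ptp(rv) > 0:
        rho = float(stats.spearmanr(lv, rv).statistic)
    else:
        rho = float("nan")  # too few pairs or a constant side
    trace = OximetryTrace(
        channel="renal_mean",
        times=union,
        values=merged,
        incision_time=left.incision_time,
        end_time=left.end_time,
    )
    return MergedRenal(trace=trace, spearman_rho=rho, n_pairs=int(common.size))


def renal_specific_burden(
    renal: OximetryTrace,
    peripheral: OximetryTrace,
    renal_baseline: BaselineEstimate,
    peripheral_baseline: BaselineEstimate,
    config: AnalysisConfig | None = None,
) -> BurdenResult:
    """Renal-region-specific differential deoxygenation burden, %·min.

    Both channels are normalised to percent-of-baseline (baseline ≡ 100%);
    the positive part of (peripheral − renal) — i.e. the renal region sitting
    proportionally deeper below its baseline than the periphery — is
    integrated over the analysis window on the union of both channels' time
    grids.
    """
    config = config or AnalysisConfig()
    if renal_baseline.value <= 0 or peripheral_baseline.value <= 0:
        raise BurdenError("zero baseline in renal-specific burden")
    tr_, vr_ = _window_series(renal)
    tp_, vp_ = _window_series(peripheral)
    grid = np.union1d(np.round(tr_, 9), np.round(tp_, 9))
    rn = np.interp(grid, tr_, vr_) * (100.0 / renal_baseline.value)
    pn = np.interp(grid, tp_, vp_) * (100.0 / peripheral_baseline.value)
    d = pn - rn  # positive where renal is proportionally more desaturated

    # an interval is a gap if it falls inside an over-tolerance gap of either
    # channel's own sampling grid
    mid = 0.5 * (grid[:-1] + grid[1:])
    gap_mask = np.zeros(mid.shape, dtype=bool)
    for tch in (tr_, tp_):
        idx = np.clip(np.searchsorted(tch, mid) - 1, 0, tch.size - 2)
        gap_mask |= (tch[idx + 1] - tch[idx]) > config.gap_tolerance

    dt = np.diff(grid)
    d0, d1 = d[:-1], d[1:]
    if config.integration == "rectangle":
        area = np.maximum(d0, 0.0) * dt
    else:
        area = np.where(
            (d0 > 0) & (d1 > 0),
            0.5 * (d0 + d1) * dt,
            np.where(
                (d0 > 0) & (d1 <= 0),
                0.5 * d0 * d0 / np.where(d0 != d1, d0 - d1, 1.0) * dt,
                np.where(
                    (d1 > 0) & (d0 <= 0),
                    0.5 * d1 * d1 / np.where(d0 != d1, d1 - d0, 1.0) * dt,
                    0.0,
                ),
            ),
        )
    area = np.where(gap_mask, 0.0, area)
    return BurdenResult(
        channel="renal_specific",
        kind="renal_specific",
        threshold=None,
        aut=float(area.sum()),
        window=(renal.incision_time, renal.end_time),
        gap_min=float(dt[gap_mask].sum()),
    )


# ---------------------------------------------------------------------------
# panel


@dataclass
class BurdenPanel:
    """Full per-patient burden panel plus baselines and merge diagnostics."""

    patient_id: str
    baselines: dict[str, BaselineEstimate]
    burdens: dict[str, BurdenResult]
    renal_spearman: float | None = None
    renal_n_pairs: int | None = None

    def as_rows(self) -> list[dict]:
        return [
            {
                "patient_id": self.patient_id,
                "channel": b.channel,
                "kind": b.kind,
                "threshold": b.threshold,
                "aut_pct_min": b.aut,
                "gap_min": b.gap_min,
            }
            for b in self.burdens.values()
        ]


def burden_key(channel: str, kind: str, threshold: float | None) -> str:
    if kind == "absolute":
        return f"{channel}_abs_{threshold:g}"
    if kind == "relative":
        return f"{channel}_rel_{100 * threshold:g}"
    return "renal_specific"


def effective_renal_trace(record: PatientRecord) -> tuple[OximetryTrace, MergedRenal | None]:
    """Bilateral mean when both sides exist, otherwise the available side."""
    has_l = "renal_left" in record.traces
    has_r = "renal_right" in record.traces
    if has_l and has_r:
        merged = merge_renal(record.traces["renal_left"], record.traces["renal_right"])
        return merged.trace, merged
    if "renal_mean" in record.traces:
        return record.traces["renal_mean"], None
    side = record.traces["renal_left" if has_l else "renal_right"]
    return (
        OximetryTrace(
            channel="renal_mean",
            times=side.times,
            values=side.values,
            incision_time=side.incision_time,
            end_time=side.end_time,
        ),
        None,
    )


def burden_panel(
    record: PatientRecord, config: AnalysisConfig | None = None
) -> BurdenPanel:
    """Compute the full burden panel for one analysable record.

    Renal mean and cerebral channels get every absolute and relative
    threshold; the peripheral channel gets only the relative thresholds
    configured for it (default 10%); the renal-specific differential burden
    closes the panel.  Channels absent from the record are skipped.
    """
    config = config or AnalysisConfig()
    if not record.renal_channels or "peripheral" not in record.traces:
        raise BurdenError(
            f"{record.patient_id}: record not analysable (missing renal or peripheral)"
        )
    renal, merged = effective_renal_trace(record)

    baselines: dict[str, BaselineEstimate] = {}
    burdens: dict[str, BurdenResult] = {}

    def _full_panel(trace: OximetryTrace) -> None:
        base = compute_baseline(trace, config.baseline_window)
        baselines[trace.channel] = base
        for thr in config.absolute_thresholds:
            b = aut_absolute(trace, thr, config)
            burdens[burden_key(trace.channel, "absolute", thr)] = b
        for frac in config.relative_fractions:
            b = aut_relative(trace, base, frac, config)
            burdens[burden_key(trace.channel, "relative", frac)] = b

    try:
        _full_panel(renal)
        if "cerebral" in record.traces:
            _full_panel(record.traces["cerebral"])
        peripheral = record.traces["peripheral"]
        pbase = compute_baseline(peripheral, config.baseline_window)
        baselines["peripheral"] = pbase
        for frac in config.peripheral_fractions:
            burdens[burden_key("peripheral", "relative", frac)] = aut_relative(
                peripheral, pbase, frac, config
            )
        burdens["renal_specific"] = renal_specific_burden(
            renal, peripheral, baselines["renal_mean"], pbase, config
        )
    except BurdenError as exc:
        raise BurdenError(f"{record.patient_id}: {exc}") from exc

    return BurdenPanel(
        patient_id=record.patient_id,
        baselines=baselines,
        burdens=burdens,
        renal_spearman=merged.spearman_rho if merged else None,
        renal_n_pairs=merged.n_pairs if merged else None,
    )
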