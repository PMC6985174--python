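"""Baseline estimation, normalization and negative-pulse event detection.

Detection runs on the low-frequency reference channel, where particle volume
dominates the signal and dips are largest; every channel is then measured in
the same window, realizing the cross-frequency co-registration implicit in
simultaneous lock-in demodulation.

Conventions: half-open ``[start, end)`` windows, 0-based sample indices,
times in seconds.  Amplitude of an event on a channel is ``baseline -
minimum`` (raw volts) and its ratio to the baseline (relative, dimensionless).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import median_filter, uniform_filter1d

from .errors import ParameterError, ProcessingError
from .trace import Trace

#: QC flag labels.
FLAG_COINCIDENT = "coincident"
FLAG_INVERTED = "inverted"
FLAG_EMPTY = "empty"
FLAG_SATURATED = "saturated"
FLAG_BASELINE_SHIFT = "baseline_shift"
FLAG_WIDE = "wide"
FLAG_ZERO_REFERENCE = "zero_reference"


@dataclass(frozen=True)
class DetectionParams:
    """Tunable detection settings (all overridable from the config file).

    ``smooth_samples``/``guard_*``/``pad_samples`` default to values derived
    from the transit time at call sites; stored here in samples.
    """

    baseline_window_samples: int = 201
    k_mad: float = 5.0
    min_separation_samples: int = 29
    pad_samples: int = 58
    smooth_samples: int = 29
    guard_offset_samples: int = 115
    guard_len_samples: int = 115
    max_width_samples: int | None = None
    saturation_volts: float | None = None
    max_baseline_shift_rel: float = 0.02
    pulse_sigma_samples: float | None = 14.4

    @classmethod
    def from_acquisition(cls, sampling_rate: float, transit_time: float, **overrides):
        """Derive sample-domain defaults from the acquisition timing."""
        n_transit = sampling_rate * transit_time
        sigma = n_transit / 4.0
        defaults = dict(
            min_separation_samples=max(1, int(round(0.5 * n_transit))),
            pad_samples=max(1, int(round(n_transit))),
            smooth_samples=max(1, int(round(2.0 * sigma))),
            guard_offset_samples=max(1, int(round(2.0 * n_transit))),
            guard_len_samples=max(1, int(round(2.0 * n_transit))),
            max_width_samples=int(round(5.0 * n_transit)),
            pulse_sigma_samples=sigma,
        )
        defaults.update(overrides)
        return cls(**defaults)


def estimate_baseline(channel: np.ndarray, window_samples: int) -> np.ndarray:
    """Rolling-median baseline, edges padded by reflection.

    Robust to transit pulses occupying a minority of the window; idempotent
    on pulse-free traces.
    """
    channel = np.asarray(channel, dtype=float)
    if window_samples < 3 or window_samples % 2 == 0:
        raise ParameterError("window_samples must be odd and >= 3")
    if channel.size < window_samples:
        raise ParameterError(
            f"series of length {channel.size} is shorter than window {window_samples}"
        )
    return median_filter(channel, size=window_samples, mode="reflect")


def normalize(channel: np.ndarray, baseline: np.ndarray) -> np.ndarray:
    """Divide a channel by its baseline so 1.0 marks the quiescent level."""
    channel = np.asarray(channel, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    bad = np.nonzero(baseline <= 0)[0]
    if bad.size:
        raise ProcessingError(
            f"non-positive baseline at sample index {int(bad[0])} "
            f"(value {baseline[bad[0]]!r}); cannot normalize"
        )
    return channel / baseline


def smooth(x: np.ndarray, smooth_samples: int) -> np.ndarray:
    """Moving average (reflect-padded); identity for ``smooth_samples <= 1``."""
    if smooth_samples <= 1:
        return np.asarray(x, dtype=float)
    return uniform_filter1d(np.asarray(x, dtype=float), size=smooth_samples, mode="reflect")


def robust_sigma(x: np.ndarray) -> float:
    """1.4826 * median absolute deviation: Gaussian-consistent noise scale."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


@dataclass
class Window:
    """One candidate event window ``[start, end)`` with QC flags."""

    start: int
    end: int
    flags: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ParameterError("window must be non-empty")
        self.flags = frozenset(self.flags)

    def as_tuple(self) -> tuple[int, int]:
        return (self.start, self.end)


def _runs_below(below: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True, as half-open index pairs."""
    idx = np.flatnonzero(np.diff(np.concatenate(([False], below, [False])).astype(int)))
    return list(zip(idx[::2], idx[1::2]))


def _pad_and_flag(
    runs: list[tuple[int, int]],
    n: int,
    pad_samples: int,
    min_separation_samples: int,
) -> list[Window]:
    padded = [(max(0, s - pad_samples), min(n, e + pad_samples)) for s, e in runs]
    flags: list[set] = [set() for _ in padded]
    for i in range(len(padded) - 1):
        gap = padded[i + 1][0] - padded[i][1]
        if gap < min_separation_samples:
            flags[i].add(FLAG_COINCIDENT)
            flags[i + 1].add(FLAG_COINCIDENT)
    return [Window(s, e, frozenset(fl)) for (s, e), fl in zip(padded, flags)]


def detect_events(
    normalized: np.ndarray,
    k_mad: float = 5.0,
    min_separation_samples: int = 29,
    pad_samples: int = 58,
    smooth_samples: int = 1,
    threshold: float | None = None,
) -> list[Window]:
    """Find negative-going pulse windows on a normalized reference channel.

    A sample opens a candidate when the (optionally smoothed) series falls
    below ``1 - k_mad * sigma_hat`` with ``sigma_hat = 1.4826 * MAD``.
    Maximal sub-threshold runs become windows padded by ``pad_samples`` on
    both sides; windows whose gap is under ``min_separation_samples`` are
    flagged coincident, never merged.  An explicit ``threshold`` overrides
    the MAD rule.  A constant channel yields no events.
    """
    if k_mad <= 0:
        raise ParameterError("k_mad must be > 0")
    x = smooth(normalized, smooth_samples)
    if threshold is None:
        sigma_hat = robust_sigma(x)
        if sigma_hat == 0.0:
            # Noiseless data: any departure below the flat level is a pulse.
            threshold = float(np.median(x)) - 1e-12
        else:
            threshold = 1.0 - k_mad * sigma_hat
    runs = _runs_below(x < threshold)
    return _pad_and_flag(runs, x.size, pad_samples, min_separation_samples)


def brute_force_detect(
    normalized: np.ndarray,
    threshold: float,
    min_separation_samples: int = 0,
    pad_samples: int = 0,
) -> list[Window]:
    """Exhaustive per-sample reference detector (no vectorized shortcuts).

    Certifies :func:`detect_events`: both must return exactly equal windows
    for the same prepared series and threshold.
    """
    runs: list[tuple[int, int]] = []
    in_run = False
    start = 0
    n = len(normalized)
    for i in range(n):
        below = normalized[i] < threshold
        if below and not in_run:
            in_run, start = True, i
        elif not below and in_run:
            in_run = False
            runs.append((start, i))
    if in_run:
        runs.append((start, n))
    padded = []
    for s, e in runs:
        s2 = s - pad_samples
        if s2 < 0:
            s2 = 0
        e2 = e + pad_samples
        if e2 > n:
            e2 = n
        padded.append([s2, e2, set()])
    for i in range(len(padded) - 1):
        if padded[i + 1][0] - padded[i][1] < min_separation_samples:
            padded[i][2].add(FLAG_COINCIDENT)
            padded[i + 1][2].add(FLAG_COINCIDENT)
    return [Window(s, e, frozenset(fl)) for s, e, fl in padded]


def _moving_average_attenuation(m: int, sigma: float) -> float:
    """Peak attenuation of a unit Gaussian pulse under an m-sample moving average."""
    if m <= 1 or sigma <= 0:
        return 1.0
    z = m / (2.0 * sigma)
    return float(sigma * math.sqrt(2.0 * math.pi) / m * math.erf(z / math.sqrt(2.0)))


def measure_peak(
    channel: np.ndarray,
    baseline_series: np.ndarray,
    window: tuple[int, int],
    guard_offset_samples: int = 115,
    guard_len_samples: int = 115,
    smooth_samples: int = 1,
    pulse_sigma_samples: float | None = None,
) -> tuple[float, float, float, float, set]:
    """Peak amplitude of one event on one channel.

    Baseline: median of the rolling-median baseline series over guard regions
    flanking the window (offset so pulse tails cannot leak in).  Minimum: the
    smallest sample of the (optionally smoothed) channel inside the window,
    earliest sample winning ties; when ``pulse_sigma_samples`` is given the
    smoothing attenuation of a Gaussian peak is divided back out.  Returns
    ``(baseline, minimum, amplitude_raw, amplitude_rel, flags)``;
    ``amplitude_raw = baseline - minimum >= 0`` for accepted events.
    """
    s, e = window
    n = len(channel)
    if not (0 <= s < e <= n):
        raise ParameterError(f"invalid window {window!r} for series of length {n}")
    gl0, gl1 = max(0, s - guard_offset_samples - guard_len_samples), max(
        0, s - guard_offset_samples
    )
    gr0, gr1 = min(n, e + guard_offset_samples), min(n, e + guard_offset_samples + guard_len_samples)
    guard = np.concatenate([baseline_series[gl0:gl1], baseline_series[gr0:gr1]])
    if guard.size == 0:
        guard = baseline_series[s:e]
    baseline = float(np.median(guard))

    xs = smooth(channel[s:e], smooth_samples)
    i_min = int(np.argmin(xs))  # argmin returns the earliest minimum
    minimum = float(xs[i_min])
    atten = _moving_average_attenuation(smooth_samples, pulse_sigma_samples or 0.0)
    amp_raw = (baseline - minimum) / atten

    flags: set = set()
    if amp_raw < 0:
        flags.add(FLAG_INVERTED)
    elif amp_raw == 0:
        flags.add(FLAG_EMPTY)
    amp_rel = amp_raw / baseline if baseline > 0 else math.nan
    return baseline, minimum, amp_raw, amp_rel, flags


def measure_events(
    trace: Trace,
    windows: list[Window],
    params: DetectionParams,
) -> pd.DataFrame:
    """Measure every channel of every detected window.

    Returns one row per event: ``event_id, start, end, center_time_s``,
    per-channel ``baseline_v_*, min_v_*, amp_raw_v_*, amp_rel_*`` (indexed by
    channel number in panel order) and a semicolon-joined ``qc_flags`` column.
    """
    n_ch = trace.n_channels
    baselines = [
        estimate_baseline(trace.channels[c], params.baseline_window_samples)
        for c in range(n_ch)
    ]
    ref = trace.panel.reference_index
    rows = []
    for eid, w in enumerate(windows):
        flags = set(w.flags)
        if params.max_width_samples is not None and (w.end - w.start) > params.max_width_samples:
            flags.add(FLAG_WIDE)
        row: dict = {
            "event_id": eid,
            "start": w.start,
            "end": w.end,
        }
        for c in range(n_ch):
            b, m, araw, arel, fl = measure_peak(
                trace.channels[c],
                baselines[c],
                w.as_tuple(),
                params.guard_offset_samples,
                params.guard_len_samples,
                params.smooth_samples,
                params.pulse_sigma_samples,
            )
            if c == ref:
                flags |= fl
                # centre = earliest smoothed minimum of the reference channel
                xs = smooth(trace.channels[c][w.start : w.end], params.smooth_samples)
                row["center_time_s"] = (w.start + int(np.argmin(xs))) / trace.sampling_rate
            if params.saturation_volts is not None and np.any(
                trace.channels[c][w.start : w.end] >= params.saturation_volts
            ):
                flags.add(FLAG_SATURATED)
            row[f"baseline_v_{c}"] = b
            row[f"min_v_{c}"] = m
            row[f"amp_raw_v_{c}"] = araw
            row[f"amp_rel_{c}"] = arel
            if c == ref:
                # left/right guard medians to catch events spanning a baseline step
                gl = baselines[c][
                    max(0, w.start - params.guard_offset_samples - params.guard_len_samples) : max(
                        0, w.start - params.guard_offset_samples
                    )
                ]
                gr = baselines[c][
                    min(trace.n_samples, w.end + params.guard_offset_samples) : min(
                        trace.n_samples,
                        w.end + params.guard_offset_samples + params.guard_len_samples,
                    )
                ]
                if gl.size and gr.size and b > 0:
                    shift = abs(float(np.median(gl)) - float(np.median(gr))) / b
                    if shift > params.max_baseline_shift_rel:
                        flags.add(FLAG_BASELINE_SHIFT)
        row["qc_flags"] = ";".join(sorted(flags))
        rows.append(row)
    columns = ["event_id", "start", "end", "center_time_s"]
    for c in range(n_ch):
        columns += [f"baseline_v_{c}", f"min_v_{c}", f"amp_raw_v_{c}", f"amp_rel_{c}"]
    columns.append("qc_flags")
    if not rows:
        return pd.DataFrame(columns=columns)
    return pd.DataFrame(rows)[columns]


#: QC flags that reject an event outright.
REJECTING_FLAGS = (
    FLAG_COINCIDENT,
    FLAG_INVERTED,
    FLAG_SATURATED,
    FLAG_BASELINE_SHIFT,
    FLAG_WIDE,
    FLAG_EMPTY,
)


def coincidence_and_qc_filter(
    events: pd.DataFrame,
    rejecting_flags: tuple[str, ...] = REJECTING_FLAGS,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split events into accepted rows and a rejection log.

    The rejection log records every removed event with the flags that caused
    the removal, one row per event.
    """
    if events.empty:
        return events.copy(), pd.DataFrame(columns=["event_id", "reason"])
    flag_sets = events["qc_flags"].fillna("").map(
        lambda s: set(s.split(";")) if s else set()
    )
    reject_reason = flag_sets.map(
        lambda fl: ";".join(sorted(fl.intersection(rejecting_flags)))
    )
    rejected_mask = reject_reason != ""
    rejections = pd.DataFrame(
        {
            "event_id": events.loc[rejected_mask, "event_id"].to_numpy(),
            "reason": reject_reason[rejected_mask].to_numpy(),
        }
    )
    return events.loc[~rejected_mask].reset_index(drop=True), rejections


def detect_and_measure(
    trace: Trace,
    params: DetectionParams | None = None,
    transit_time: float | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, list[Window]]:
    """Full detection stage on one trace: returns (accepted, rejections, windows)."""
    if params is None:
        tt = transit_time or trace.meta.get("transit_time", 1e-3)
        params = DetectionParams.from_acquisition(trace.sampling_rate, tt)
    ref_channel = trace.reference_channel()
    baseline = estimate_baseline(ref_channel, params.baseline_window_samples)
    norm = normalize(ref_channel, baseline)
    windows = detect_events(
        norm,
        k_mad=params.k_mad,
        min_separation_samples=params.min_separation_samples,
        pad_samples=params.pad_samples,
        smooth_samples=params.smooth_samples,
    )
    events = measure_events(trace, windows, params)
    accepted, rejections = coincidence_and_qc_filter(events)
    return accepted, rejections, windows
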