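"""Signal conditioning and two-pass artifact rejection.

Raw 1000 Hz binocular traces are low-pass filtered at 6 Hz (zero-phase,
4th-order Butterworth), downsampled to 100 Hz, and cleaned in three stages
per eye, in fixed order:

1. blinks: maximal missing-sample runs, merged when separated by less than
   0.25 s, padded by 150 ms on each side, linearly interpolated;
2. a first temporal-derivative pass at 0.75 SD of the first difference
   (the absolute derivative is compared against the threshold), with a 60 ms
   quiet-period rule locating artifact start/end points, windows extended
   150 ms before and 250 ms after, interpolated;
3. a second, identical derivative pass at 3.5 SD, interpolated.

Every applied window is recorded in a ledger with its source, and per-sample
quality flags distinguish untouched (valid) from interpolated samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal as sps

from .synthetic import RawRecording

__all__ = [
    "VALID",
    "INTERPOLATED",
    "MISSING",
    "FLAG_NAMES",
    "InvalidWindow",
    "PreprocessParams",
    "CleanRecording",
    "RecordingUnusableError",
    "lowpass_downsample",
    "detect_blinks",
    "derivative_pass",
    "interpolate_windows",
    "preprocess_recording",
]

# per-sample quality flags
VALID, INTERPOLATED, MISSING = 0, 1, 2
FLAG_NAMES = {VALID: "valid", INTERPOLATED: "interpolated", MISSING: "missing"}


class RecordingUnusableError(ValueError):
    """Raised when a trace cannot be reconstructed (e.g. fully invalid)."""


@dataclass(frozen=True)
class InvalidWindow:
    """Half-open [start_ms, end_ms) window slated for interpolation."""

    start_ms: float
    end_ms: float
    source: str  # blink | derivative_pass1 | derivative_pass2

    def __post_init__(self) -> None:
        if not self.start_ms < self.end_ms:
            raise ValueError("window must satisfy start < end")


@dataclass(frozen=True)
class PreprocessParams:
    """All conditioning thresholds, with the pipeline's standard defaults."""

    cutoff_hz: float = 6.0
    filter_order: int = 4
    out_rate: float = 100.0
    blink_merge_ms: float = 250.0
    blink_pad_ms: float = 150.0
    pass1_sd: float = 0.75
    pass2_sd: float = 3.5
    quiet_ms: float = 60.0
    deriv_pre_ms: float = 150.0
    deriv_post_ms: float = 250.0
    # population for the derivative SD: the trace as it stands at each pass
    # ("current", default) or the conditioned trace before any interpolation
    # with missing samples excluded ("preinterpolation")
    derivative_sd_source: str = "current"


@dataclass
class CleanRecording:
    """100 Hz conditioned binocular traces with quality flags and ledger."""

    participant: int
    condition: str
    time_ms: np.ndarray
    left: np.ndarray
    right: np.ndarray
    left_flags: np.ndarray
    right_flags: np.ndarray
    windows: pd.DataFrame  # eye, start_ms, end_ms, source
    events: pd.DataFrame
    rate: float
    usable: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_ms": self.time_ms,
                "left_pupil": self.left,
                "right_pupil": self.right,
                "left_quality": [FLAG_NAMES[f] for f in self.left_flags],
                "right_quality": [FLAG_NAMES[f] for f in self.right_flags],
            }
        )


# ---------------------------------------------------------------------------
# Filtering and decimation
# ---------------------------------------------------------------------------

def _nan_runs(values: np.ndarray) -> list[tuple[int, int]]:
    """Maximal NaN runs as half-open sample-index intervals."""
    isnan = np.isnan(values)
    if not isnan.any():
        return []
    padded = np.concatenate([[False], isnan, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def _fill_nan(values: np.ndarray) -> np.ndarray:
    """Linear interpolation over NaN runs, constant extension at edges."""
    out = values.astype(float).copy()
    isnan = np.isnan(out)
    if not isnan.any():
        return out
    if isnan.all():
        raise RecordingUnusableError("trace contains no finite samples")
    idx = np.arange(len(out))
    out[isnan] = np.interp(idx[isnan], idx[~isnan], out[~isnan])
    return out


def lowpass_downsample(
    values: np.ndarray,
    fs: float,
    cutoff_hz: float = 6.0,
    out_rate: float = 100.0,
    order: int = 4,
) -> np.ndarray:
    """Zero-phase Butterworth low-pass followed by decimation.

    The filter runs forward and backward (``sosfiltfilt``), so the passband
    has unit DC gain and no phase distortion. Missing samples are bridged by
    linear interpolation for the filter's sake only and passed through as
    missing in the output. Output length is ``floor(n / q)`` for decimation
    factor ``q = fs / out_rate`` (samples 0, q, 2q, ...).
    """
    values = np.asarray(values, dtype=float)
    if len(values) < fs:
        raise ValueError("need at least 1 s of data for filter warm-up")
    q = fs / out_rate
    if abs(q - round(q)) > 1e-9 or q < 1:
        raise ValueError("fs must be an integer multiple of out_rate")
    q = int(round(q))
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    filled = _fill_nan(values)
    filtered = sps.sosfiltfilt(sos, filled)
    n_out = len(values) // q
    out = filtered[: n_out * q : q].copy()
    out[np.isnan(values[: n_out * q : q])] = np.nan
    return out


# ---------------------------------------------------------------------------
# Blink detection
# ---------------------------------------------------------------------------

def _merge_intervals(ivals: list[tuple[float, float]]) -> list[tuple[float, float]]:
    merged: list[list[float]] = []
    for s, e in sorted(ivals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def detect_blinks(
    values: np.ndarray,
    fs: float,
    merge_gap_ms: float = 250.0,
    pad_ms: float = 150.0,
) -> list[InvalidWindow]:
    """Locate blink windows from missing-sample runs.

    Maximal missing runs separated by less than ``merge_gap_ms`` are merged
    into a single blink; each blink is then padded by ``pad_ms`` on both
    sides and clipped to the recording bounds.
    """
    step = 1000.0 / fs
    total_ms = len(values) * step
    runs = [(s * step, e * step) for s, e in _nan_runs(np.asarray(values, float))]
    if not runs:
        return []
    merged: list[list[float]] = [list(runs[0])]
    for s, e in runs[1:]:
        if s - merged[-1][1] < merge_gap_ms:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    padded = _merge_intervals(
        [(max(0.0, s - pad_ms), min(total_ms, e + pad_ms)) for s, e in merged]
    )
    return [InvalidWindow(s, e, "blink") for s, e in padded]


# ---------------------------------------------------------------------------
# Derivative-threshold artifact detection
# ---------------------------------------------------------------------------

def derivative_pass(
    values: np.ndarray,
    fs: float,
    sd_multiplier: float,
    quiet_ms: float = 60.0,
    pre_ms: float = 150.0,
    post_ms: float = 250.0,
    source: str = "derivative",
    sd_values: np.ndarray | None = None,
) -> list[InvalidWindow]:
    """Artifact windows from a temporal-derivative threshold.

    The threshold is ``sd_multiplier`` times the SD of the first difference
    over the whole recording (optionally of ``sd_values`` when the SD
    population should differ from the scanned trace). Samples whose
    absolute derivative meets the threshold form invalid cores; each core is
    extended to artifact start/end points defined by the quiet-period rule --
    the nearest preceding (following) point after which the absolute
    derivative stays below threshold for ``quiet_ms``. Windows are then
    extended ``pre_ms`` before and ``post_ms`` after, clipped to bounds, and
    merged where they overlap.
    """
    if sd_multiplier <= 0:
        raise ValueError("sd_multiplier must be positive")
    values = np.asarray(values, dtype=float)
    if np.isnan(values).any():
        raise ValueError("derivative pass requires a gap-free trace")
    d = np.abs(np.diff(values))
    ref = np.diff(values if sd_values is None else np.asarray(sd_values, float))
    ref = ref[np.isfinite(ref)]
    sd = float(np.std(ref))
    if sd == 0.0:
        warnings.warn("derivative SD is zero; no artifact windows detected")
        return []
    thr = sd_multiplier * sd
    bad = d >= thr
    if not bad.any():
        return []
    q = max(1, int(round(quiet_ms * fs / 1000.0)))
    step = 1000.0 / fs
    total_ms = len(values) * step

    # maximal runs of above-threshold derivative samples
    padded = np.concatenate([[False], bad, [False]])
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    runs = list(zip(edges[::2], edges[1::2] - 1))  # inclusive derivative indices

    ivals = []
    for a, b in runs:
        s = 0
        for j in range(a, -1, -1):
            lo = max(0, j - q)
            if not bad[lo:j].any():
                s = j
                break
        e = len(d) - 1
        for j in range(b, len(d)):
            if not bad[j + 1 : j + 1 + q].any():
                e = j
                break
        start = max(0.0, s * step - pre_ms)
        end = min(total_ms, (e + 2) * step + post_ms)
        ivals.append((start, end))
    return [InvalidWindow(s, e, source) for s, e in _merge_intervals(ivals)]


# ---------------------------------------------------------------------------
# Interpolation
# ---------------------------------------------------------------------------

def interpolate_windows(
    time_ms: np.ndarray,
    values: np.ndarray,
    flags: np.ndarray,
    windows: list[InvalidWindow],
) -> tuple[np.ndarray, np.ndarray]:
    """Linearly bridge each invalid window between its neighbouring samples.

    Samples inside a window are replaced by the straight line between the
    last sample before the window and the first sample after it, and flagged
    as interpolated; windows touching a recording edge are filled by constant
    extension of the nearest retained sample. Samples outside all windows are
    untouched. Raises :class:`RecordingUnusableError` if the windows jointly
    cover the entire trace.
    """
    values = np.asarray(values, dtype=float).copy()
    flags = np.asarray(flags).copy()
    if not windows:
        return values, flags
    ivals = _merge_intervals([(w.start_ms, w.end_ms) for w in windows])
    inside = np.zeros(len(values), dtype=bool)
    for s, e in ivals:
        inside |= (time_ms >= s) & (time_ms < e)
    if inside.all():
        raise RecordingUnusableError("invalid windows cover the entire trace")
    for s, e in ivals:
        mask = (time_ms >= s) & (time_ms < e)
        if not mask.any():
            continue
        i0, i1 = np.flatnonzero(mask)[[0, -1]]
        before = i0 - 1 if i0 > 0 else None
        after = i1 + 1 if i1 + 1 < len(values) else None
        if before is None and after is None:
            raise RecordingUnusableError("invalid windows cover the entire trace")
        if before is None:
            values[mask] = values[after]
        elif after is None:
            values[mask] = values[before]
        else:
            values[mask] = np.interp(
                time_ms[mask],
                [time_ms[before], time_ms[after]],
                [values[before], values[after]],
            )
        flags[mask] = INTERPOLATED
    return values, flags


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

def preprocess_recording(
    raw: RawRecording, params: PreprocessParams = PreprocessParams()
) -> CleanRecording:
    """Condition one raw recording to a flagged 100 Hz clean recording.

    Per eye: low-pass + downsample, then blink interpolation, then the
    0.75 SD derivative pass, then the 3.5 SD derivative pass, interpolating
    after each detection stage. The ledger records every applied window with
    its source. If any stage finds a trace wholly invalid the recording is
    returned with ``usable=False``.
    """
    fs = raw.sample_rate
    q = int(round(fs / params.out_rate))
    n_out = len(raw.time_ms) // q
    time_out = np.arange(n_out) * (1000.0 / params.out_rate)

    traces, all_flags = {}, {}
    ledger_rows = []
    usable = True
    for eye, rawvals in (("left", raw.left), ("right", raw.right)):
        try:
            blink_windows = detect_blinks(
                rawvals, fs, params.blink_merge_ms, params.blink_pad_ms
            )
            cond = lowpass_downsample(
                rawvals, fs, params.cutoff_hz, params.out_rate, params.filter_order
            )
            sd_ref = cond if params.derivative_sd_source == "preinterpolation" else None
            flags = np.full(n_out, VALID, dtype=np.int8)
            flags[np.isnan(cond)] = MISSING
            trace = np.where(np.isnan(cond), _fill_nan(cond), cond)
            trace, flags = interpolate_windows(time_out, trace, flags, blink_windows)
            stage_windows = [blink_windows]
            for sd_mult, src in (
                (params.pass1_sd, "derivative_pass1"),
                (params.pass2_sd, "derivative_pass2"),
            ):
                wins = derivative_pass(
                    trace,
                    params.out_rate,
                    sd_mult,
                    params.quiet_ms,
                    params.deriv_pre_ms,
                    params.deriv_post_ms,
                    source=src,
                    sd_values=sd_ref,
                )
                trace, flags = interpolate_windows(time_out, trace, flags, wins)
                stage_windows.append(wins)
        except RecordingUnusableError:
            usable = False
            trace = np.full(n_out, np.nan)
            flags = np.full(n_out, MISSING, dtype=np.int8)
            stage_windows = []
        traces[eye] = trace
        all_flags[eye] = flags
        for wins in stage_windows:
            for w in wins:
                ledger_rows.append(
                    {"eye": eye, "start_ms": w.start_ms, "end_ms": w.end_ms, "source": w.source}
                )

    windows = pd.DataFrame(ledger_rows, columns=["eye", "start_ms", "end_ms", "source"])
    return CleanRecording(
        participant=raw.participant,
        condition=raw.condition,
        time_ms=time_out,
        left=traces["left"],
        right=traces["right"],
        left_flags=all_flags["left"],
        right_flags=all_flags["right"],
        windows=windows,
        events=raw.events.copy(),
        rate=params.out_rate,
        usable=usable,
    )
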